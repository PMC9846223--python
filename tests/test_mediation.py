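import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import carepath as cp
from carepath.mediation import (CoefRef, Combo, CoefficientSource,
                                UndefinedEffect, delta_method_se)

OUTCOME = "neonatal_careseeking"


class DictSource(CoefficientSource):
    """Toy coefficient source: {(eq, parent, level): (value, se, significant)}."""

    def __init__(self, cells, cov=None):
        self.cells = cells
        self.cov = cov

    def levels(self, equation, parent):
        return [lvl for (eq, par, lvl) in self.cells if eq == equation
                and par == parent]

    def value(self, ref):
        return self.cells[(ref.equation, ref.parent, ref.level)][0]

    def se(self, ref):
        return self.cells[(ref.equation, ref.parent, ref.level)][1]

    def significant(self, ref):
        return self.cells[(ref.equation, ref.parent, ref.level)][2]

    def covariance(self, refs):
        if self.cov is not None:
            return self.cov
        return np.diag([self.se(r) ** 2 for r in refs])


class TestPathEnumeration:
    def test_anc_has_three_single_mediator_pathways(self, diagram):
        paths = cp.enumerate_paths(diagram, "anc4", max_mediators=1)
        assert [p.mediators[0] for p in paths] == [
            "facility_delivery", "pnc", "knowledge"]

    def test_knowledge_is_direct_only(self, diagram):
        assert cp.enumerate_paths(diagram, "knowledge", max_mediators=1) == []

    def test_restricted_subpopulation_mediator_excluded_by_default(self, diagram):
        default = cp.enumerate_paths(diagram, "anc4", 1)
        widened = cp.enumerate_paths(diagram, "anc4", 1, include_restricted=True)
        extra = {p.mediators for p in widened} - {p.mediators for p in default}
        assert extra == {("maternal_careseeking",)}

    def test_longer_chains_are_a_superset(self, diagram):
        short = {p.mediators for p in cp.enumerate_paths(diagram, "anc4", 1)}
        deep = {p.mediators for p in cp.enumerate_paths(diagram, "anc4", 3)}
        assert short < deep
        assert ("facility_delivery", "pnc") in deep  # ANC -> FD -> PNC -> outcome

    def test_unknown_exposure_errors(self, diagram):
        with pytest.raises(cp.MediationError, match="unknown"):
            cp.enumerate_paths(diagram, "nonexistent", 1)

    @given(st.integers(3, 8), st.integers(0, 2 ** 20), st.integers(1, 3))
    def test_matches_exhaustive_dfs_on_random_dags(self, n_nodes, seed, max_m):
        """Oracle: brute-force DFS over the adjacency of a random DAG."""
        rng = np.random.default_rng(seed)
        names = [f"v{i}" for i in range(n_nodes)]
        edges = [(names[i], names[j])
                 for i in range(n_nodes) for j in range(i + 1, n_nodes)
                 if rng.random() < 0.5]
        edges.append((names[0], names[-1]))  # outcome reachable
        edges = sorted(set(edges))
        variables = [
            cp.VariableSpec(nm, "endogenous" if any(p == nm for _, p in edges)
                            else "exogenous", "binary",
                            family="binomial" if any(p == nm for _, p in edges)
                            else None,
                            levels=("no", "yes"), reference_level="no")
            for nm in names
        ]
        d = cp.PathDiagram(variables=variables,
                           edges=[cp.EdgeSpec(a, b) for a, b in edges],
                           outcome=names[-1])
        adj = {nm: sorted(b for a, b in edges if a == nm) for nm in names}

        def dfs(node, seen):
            if node == names[-1]:
                yield ()
                return
            for nxt in adj[node]:
                if nxt not in seen:
                    for rest in dfs(nxt, seen | {nxt}):
                        if nxt == names[-1]:
                            yield rest
                        else:
                            yield (nxt,) + rest

        oracle = {m for m in dfs(names[0], {names[0]})
                  if 1 <= len(m) <= max_m}
        got = {p.mediators for p in cp.enumerate_paths(d, names[0], max_m)}
        assert got == oracle


class TestAverageRelativeEffect:
    def test_binary_exposure_passes_through(self, fixture_source):
        combo, levels = cp.exposure_level_coefficient(
            fixture_source, OUTCOME, "facility_delivery")
        assert levels == ["yes"]
        assert combo.value(fixture_source) == pytest.approx(math.log(1.30))

    def test_age_on_knowledge_averages_both_starred_levels(self, fixture_source):
        combo, levels = cp.exposure_level_coefficient(
            fixture_source, "knowledge", "mother_age")
        assert levels == ["20-34", "35-49"]
        assert combo.value(fixture_source) == pytest.approx(0.215)

    def test_education_on_anc_averages_significant_logs(self, fixture_source):
        combo, levels = cp.exposure_level_coefficient(
            fixture_source, "anc4", "education")
        assert levels == ["primary_complete", "secondary_incomplete",
                          "secondary_complete_or_higher"]
        expected = np.mean([math.log(x) for x in (1.36, 1.73, 2.62)])
        assert combo.value(fixture_source) == pytest.approx(expected)

    def test_all_levels_mode_includes_nonsignificant(self, fixture_source):
        combo, levels = cp.exposure_level_coefficient(
            fixture_source, "anc4", "education", mode="all")
        assert len(levels) == 4

    def test_no_significant_level_is_undefined(self, fixture_source):
        with pytest.raises(UndefinedEffect):
            cp.exposure_level_coefficient(fixture_source, "knowledge", "wealth")


class TestIndirectEffect:
    def test_anc_via_facility_delivery(self, diagram, fixture_source):
        path = cp.MediatedPath("anc4", ("facility_delivery",), OUTCOME)
        est = cp.indirect_effect(path, fixture_source)
        assert est.value == pytest.approx(math.log(2.53) * math.log(1.30))
        assert cp.round_half_away(est.value, 2) == 0.24

    def test_anc_via_pnc(self, fixture_source):
        path = cp.MediatedPath("anc4", ("pnc",), OUTCOME)
        est = cp.indirect_effect(path, fixture_source)
        assert cp.round_half_away(est.value, 2) == 0.06

    def test_zero_leg_annihilates_product(self):
        src = DictSource({
            ("m", "x", "yes"): (0.0, 0.1, True),
            ("y", "m", "yes"): (0.7, 0.1, True),
        })
        est = cp.indirect_effect(cp.MediatedPath("x", ("m",), "y"), src)
        assert est.value == 0.0

    def test_sign_propagates_as_product_of_leg_signs(self, diagram, fixture_source):
        opts = cp.DecomposeOptions()
        for exposure, mediators in diagram.mediated_pathways.items():
            for mediator in mediators:
                path = cp.MediatedPath(exposure, (mediator,), OUTCOME)
                try:
                    est = cp.indirect_effect(path, fixture_source, opts)
                except UndefinedEffect:
                    continue
                first, _ = cp.exposure_level_coefficient(
                    fixture_source, mediator, exposure)
                leg = cp.lookup_coefficient(
                    fixture_source.table, OUTCOME, mediator,
                    "5+" if mediator == "knowledge" else "yes")
                expected = np.sign(first.value(fixture_source)) * \
                    np.sign(leg["link_estimate"])
                assert np.sign(est.value) == expected


class TestDeltaMethod:
    def test_two_term_closed_form(self):
        b1, b2, s1, s2 = 0.9, -0.4, 0.2, 0.05
        src = DictSource({("m", "x", "yes"): (b1, s1, True),
                          ("y", "m", "yes"): (b2, s2, True)})
        combo = Combo.single(CoefRef("m", "x", "yes")).times(CoefRef("y", "m", "yes"))
        expected = math.sqrt(b2 ** 2 * s1 ** 2 + b1 ** 2 * s2 ** 2)
        assert delta_method_se(combo, src) == pytest.approx(expected)

    def test_zero_coefficient_limit(self):
        b2, s1 = 0.7, 0.3
        src = DictSource({("m", "x", "yes"): (0.0, s1, True),
                          ("y", "m", "yes"): (b2, 0.11, True)})
        combo = Combo.single(CoefRef("m", "x", "yes")).times(CoefRef("y", "m", "yes"))
        assert delta_method_se(combo, src) == pytest.approx(abs(b2) * s1)

    def test_anc_via_fd_interval_close_to_printed(self, fixture_source):
        """Delta CI from printed coefficients with zero cross-covariance
        lands within 0.02 of the published (0.12, 0.39)."""
        path = cp.MediatedPath("anc4", ("facility_delivery",), OUTCOME)
        est = cp.indirect_effect(path, fixture_source)
        assert est.ci_low == pytest.approx(0.12, abs=0.02)
        assert est.ci_high == pytest.approx(0.39, abs=0.03)

    def test_against_parametric_simulation(self, fixture_source):
        """Oracle: sd of the product over draws from independent normals."""
        path = cp.MediatedPath("anc4", ("facility_delivery",), OUTCOME)
        est = cp.indirect_effect(path, fixture_source)
        rng = np.random.default_rng(123)
        b1 = rng.normal(math.log(2.53),
                        (math.log(2.83) - math.log(2.27)) / (2 * cp.Z95), 10_000)
        b2 = rng.normal(math.log(1.30),
                        (math.log(1.48) - math.log(1.14)) / (2 * cp.Z95), 10_000)
        assert est.se == pytest.approx(np.std(b1 * b2, ddof=1), rel=0.05)


class TestDecompose:
    def test_sex_is_direct_only(self, diagram, fixture_source):
        row = cp.decompose("newborn_sex", diagram, fixture_source)
        assert row.total_indirect is None
        assert row.direct.value == pytest.approx(math.log(1.20))
        assert row.total.value == row.direct.value
        assert cp.round_half_away(row.total.value, 2) == 0.18

    def test_education_has_no_direct_effect(self, diagram, fixture_source):
        row = cp.decompose("education", diagram, fixture_source)
        assert row.direct is None
        assert row.total.value == row.total_indirect.value
        assert row.mediation_proportion is None

    @staticmethod
    def _assert_identities(table):
        for row in table.rows:
            parts = sum(pe.estimate.value for pe in row.paths
                        if pe.estimate is not None)
            if row.total_indirect is not None:
                assert row.total_indirect.value == parts
            direct = row.direct.value if row.direct is not None else 0.0
            ti = row.total_indirect.value if row.total_indirect is not None else 0.0
            if row.total is not None:
                assert row.total.value == direct + ti

    def test_additive_identities_exact_on_fixture(self, diagram, fixture_source):
        self._assert_identities(cp.decomposition_table(diagram, fixture_source))

    def test_additive_identities_exact_on_system_fit(self, diagram, system_fit):
        source = cp.SystemCoefficients(system_fit, diagram)
        self._assert_identities(cp.decomposition_table(diagram, source))

    def test_exposure_equal_to_outcome_errors(self, diagram, fixture_source):
        with pytest.raises(cp.MediationError):
            cp.decompose(OUTCOME, diagram, fixture_source)

    def test_mediation_proportion_identity(self, diagram, fixture_source):
        row = cp.decompose("facility_distance", diagram, fixture_source)
        assert row.mediation_proportion == pytest.approx(
            100 * row.total_indirect.value / row.total.value)


class TestDecompositionTable:
    def test_empty_exposure_list_gives_empty_table(self, diagram, fixture_source):
        table = cp.decomposition_table(diagram, fixture_source, exposures=[])
        assert table.rows == []
        assert list(table.to_frame().columns) == [
            "exposure", "mediator", "cell", "estimate", "ci_low", "ci_high",
            "stars"]

    def test_distance_total_and_children_total_indirect(self, diagram,
                                                        fixture_source):
        table = cp.decomposition_table(diagram, fixture_source)
        assert cp.round_half_away(table.row("facility_distance").total.value,
                                  2) == 0.20
        assert cp.round_half_away(
            table.row("living_children").total_indirect.value, 2) == -0.26

    def test_csv_round_trip(self, diagram, fixture_source, tmp_path):
        import pandas as pd

        table = cp.decomposition_table(diagram, fixture_source)
        out = tmp_path / "decomp.csv"
        table.to_csv(out, digits=None)
        back = pd.read_csv(out, keep_default_na=False,
                           dtype={"stars": str, "mediator": str})
        frame = table.to_frame()
        assert len(back) == len(frame)
        np.testing.assert_allclose(back["estimate"], frame["estimate"])

    def test_half_away_from_zero_rounding(self):
        assert cp.round_half_away(0.125, 2) == 0.13
        assert cp.round_half_away(-0.125, 2) == -0.13
        assert cp.round_half_away(0.124999, 2) == 0.12
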