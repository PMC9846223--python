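"""Product-of-coefficients mediation decomposition on the log-odds scale.

Every effect here is a linear combination of products of link-scale
coefficients drawn from a coefficient source (a fitted system or the
published coefficient table):

* direct effect of an exposure — its coefficient in the outcome equation;
* path-specific indirect effect — the product of the coefficients along an
  exposure → mediator(s) → outcome chain;
* total indirect — the sum over mediated pathways; total — direct + total
  indirect (log odds add, unlike odds ratios);
* mediation proportion — 100 × total indirect / total.

Multi-categorical exposures are summarized by their *average relative
effect*: the arithmetic mean of the per-level link-scale coefficients, by
default over the statistically significant levels only.  Standard errors
come from the delta method: for θ = Σ_k w_k Π_j β_kj the gradient is
assembled analytically and SE = sqrt(gᵀ Σ g) with Σ the coefficient
covariance (diagonal for the published table, the assembled joint covariance
for a fitted system).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diagram import PathDiagram
from .fixtures import Z95, lookup_coefficient
from .fitting import SystemFit, significance_label, term_name

__all__ = [
    "CoefRef", "Combo", "EffectEstimate", "MediatedPath", "PathEffect",
    "DecompositionRow", "DecompositionTable", "DecomposeOptions",
    "FixtureCoefficients", "SystemCoefficients", "enumerate_paths",
    "exposure_level_coefficient", "indirect_effect", "delta_method_se",
    "decompose", "decomposition_table", "mediation_proportion",
    "round_half_away",
]


class MediationError(ValueError):
    pass


class UndefinedEffect(Exception):
    """Signals an effect with no statistically defined contribution ('–')."""


@dataclass(frozen=True)
class CoefRef:
    """Address of one link-scale coefficient: equation, parent, level.

    ``level`` is ``None`` for continuous single-term predictors.
    """

    equation: str
    parent: str
    level: str | None


# ---------------------------------------------------------------------------
# coefficient sources
# ---------------------------------------------------------------------------

class CoefficientSource:
    """Uniform access to link-scale coefficients and their covariance."""

    def levels(self, equation: str, parent: str) -> list[str | None]:
        raise NotImplementedError

    def value(self, ref: CoefRef) -> float:
        raise NotImplementedError

    def se(self, ref: CoefRef) -> float:
        raise NotImplementedError

    def significant(self, ref: CoefRef) -> bool:
        raise NotImplementedError

    def covariance(self, refs: Sequence[CoefRef]) -> np.ndarray:
        raise NotImplementedError

    def has_parent(self, equation: str, parent: str) -> bool:
        try:
            return len(self.levels(equation, parent)) > 0
        except KeyError:
            return False


class FixtureCoefficients(CoefficientSource):
    """Published coefficient table as a source.

    Coefficients of different cells are treated as independent (zero
    cross-covariance): the published table reports no covariances.
    Significance follows the printed stars.
    """

    def __init__(self, table: pd.DataFrame):
        self.table = table

    def _row(self, ref: CoefRef) -> pd.Series:
        return lookup_coefficient(self.table, ref.equation, ref.parent, ref.level)

    def levels(self, equation: str, parent: str) -> list[str | None]:
        m = (self.table["equation"] == equation) & (self.table["predictor"] == parent)
        return [lvl if pd.notna(lvl) else None for lvl in self.table.loc[m, "level"]]

    def value(self, ref: CoefRef) -> float:
        return float(self._row(ref)["link_estimate"])

    def se(self, ref: CoefRef) -> float:
        return float(self._row(ref)["link_se"])

    def significant(self, ref: CoefRef) -> bool:
        return bool(self._row(ref)["significant"])

    def covariance(self, refs: Sequence[CoefRef]) -> np.ndarray:
        return np.diag([self.se(r) ** 2 for r in refs])


class SystemCoefficients(CoefficientSource):
    """A fitted :class:`~carepath.fitting.SystemFit` as a source."""

    def __init__(self, fit: SystemFit, diagram: PathDiagram, alpha: float = 0.05):
        self.fit = fit
        self.diagram = diagram
        self.alpha = alpha

    def levels(self, equation: str, parent: str) -> list[str | None]:
        if equation not in self.fit.fits:
            raise KeyError(equation)
        spec = self.diagram.variable(parent)
        terms = self.fit.fits[equation].terms
        if spec.predictor_encoding == "as_continuous" or spec.levels is None:
            return [None] if parent in terms else []
        return [lvl for lvl in spec.nonreference_levels
                if term_name(parent, lvl) in terms]

    def value(self, ref: CoefRef) -> float:
        return self.fit.coef(ref.equation, term_name(ref.parent, ref.level))

    def se(self, ref: CoefRef) -> float:
        return self.fit.se(ref.equation, term_name(ref.parent, ref.level))

    def significant(self, ref: CoefRef) -> bool:
        from scipy.stats import norm

        z = abs(self.value(ref)) / self.se(ref)
        return 2 * norm.sf(z) < self.alpha

    def covariance(self, refs: Sequence[CoefRef]) -> np.ndarray:
        idx = [self.fit.index_of(r.equation, term_name(r.parent, r.level))
               for r in refs]
        return self.fit.joint_cov[np.ix_(idx, idx)]


# ---------------------------------------------------------------------------
# linear combinations of coefficient products
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Combo:
    """θ = Σ_k weight_k · Π_j β(ref_kj); the algebra behind every effect."""

    terms: tuple[tuple[float, tuple[CoefRef, ...]], ...]

    @staticmethod
    def single(ref: CoefRef, weight: float = 1.0) -> "Combo":
        return Combo(((weight, (ref,)),))

    @staticmethod
    def average(refs: Sequence[CoefRef]) -> "Combo":
        w = 1.0 / len(refs)
        return Combo(tuple((w, (r,)) for r in refs))

    def times(self, ref: CoefRef) -> "Combo":
        return Combo(tuple((w, refs + (ref,)) for w, refs in self.terms))

    def plus(self, other: "Combo") -> "Combo":
        return Combo(self.terms + other.terms)

    @property
    def refs(self) -> list[CoefRef]:
        seen: dict[CoefRef, None] = {}
        for _, refs in self.terms:
            for r in refs:
                seen.setdefault(r)
        return list(seen)

    def value(self, source: CoefficientSource) -> float:
        total = 0.0
        for w, refs in self.terms:
            prod = w
            for r in refs:
                prod *= source.value(r)
            total += prod
        return total

    def gradient(self, source: CoefficientSource) -> dict[CoefRef, float]:
        grad: dict[CoefRef, float] = {r: 0.0 for r in self.refs}
        for w, refs in self.terms:
            vals = [source.value(r) for r in refs]
            for i, r in enumerate(refs):
                partial = w
                for j, v in enumerate(vals):
                    if j != i:
                        partial *= v
                grad[r] += partial
        return grad


def delta_method_se(combo: Combo, source: CoefficientSource) -> float:
    """First-order SE of a combination of products: sqrt(gᵀ Σ g)."""
    refs = combo.refs
    grad = combo.gradient(source)
    g = np.array([grad[r] for r in refs])
    sigma = source.covariance(refs)
    if sigma.shape != (len(refs), len(refs)):
        raise MediationError("covariance dimensions do not match referenced terms")
    return float(math.sqrt(max(g @ sigma @ g, 0.0)))


@dataclass(frozen=True)
class EffectEstimate:
    """A log-odds-scale effect with its Wald 95% interval."""

    value: float
    se: float
    kind: str  # direct | path_indirect | total_indirect | total
    combo: Combo | None = field(default=None, compare=False, repr=False)

    @property
    def ci_low(self) -> float:
        return self.value - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.value + Z95 * self.se

    @property
    def stars(self) -> str:
        return significance_label(self.value, self.se) if self.se > 0 else ""


def _estimate(combo: Combo, source: CoefficientSource, kind: str) -> EffectEstimate:
    return EffectEstimate(value=combo.value(source),
                          se=delta_method_se(combo, source),
                          kind=kind, combo=combo)


# ---------------------------------------------------------------------------
# path enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MediatedPath:
    exposure: str
    mediators: tuple[str, ...]
    outcome: str

    def __post_init__(self):
        if not self.mediators:
            raise MediationError("a mediated path needs at least one mediator")
        if len(set(self.mediators)) != len(self.mediators):
            raise MediationError("a path may not repeat a mediator")

    @property
    def nodes(self) -> tuple[str, ...]:
        return (self.exposure, *self.mediators, self.outcome)


def enumerate_paths(diagram: PathDiagram, exposure: str, max_mediators: int = 1,
                    include_restricted: bool = False) -> list[MediatedPath]:
    """All simple directed paths exposure → mediators → outcome.

    Paths have between 1 and ``max_mediators`` intermediate variables.  By
    default, mediators whose own equation is estimated on a strictly smaller
    subpopulation than the outcome's (e.g. care-seeking for a maternal
    complication, defined only within the complication subset) are excluded:
    a product-of-coefficients effect through a variable that is undefined for
    most of the outcome population is not decomposable.  Deterministic order:
    by mediator position in the topological order, then lexicographic.
    """
    import networkx as nx

    if exposure not in diagram:
        raise MediationError(f"unknown exposure {exposure!r}")
    if diagram.outcome == exposure:
        raise MediationError("exposure equals the outcome")
    g = diagram.to_networkx()
    outcome = diagram.outcome
    out_filters = set(diagram.equation_filters(outcome))
    restricted = {
        v.name for v in diagram.endogenous
        if set(diagram.equation_filters(v.name)) > out_filters
    }
    topo_pos = {n: i for i, n in enumerate(nx.topological_sort(g))}

    paths = []
    for nodes in nx.all_simple_paths(g, exposure, outcome, cutoff=max_mediators + 1):
        mediators = tuple(nodes[1:-1])
        if not mediators:
            continue
        if not include_restricted and any(m in restricted for m in mediators):
            continue
        paths.append(MediatedPath(exposure, mediators, outcome))
    paths.sort(key=lambda p: tuple((topo_pos[m], m) for m in p.mediators))
    return paths


# ---------------------------------------------------------------------------
# effects
# ---------------------------------------------------------------------------

@dataclass
class DecomposeOptions:
    """Modes of the decomposition.

    ``are_mode`` controls the average relative effect for multi-categorical
    exposures: ``"significant"`` (default) averages only levels with
    two-sided p < 0.05 — an exposure leg with no significant level renders
    the effect undefined ('–') — while ``"all"`` averages every non-reference
    level.  ``mediator_levels`` pins the coefficient used for a multi-level
    mediator's own effect on the next node (default: its highest level, e.g.
    knowing 5+ danger signs vs none).  ``use_hypothesized_paths`` follows the
    diagram's recorded mediation pathway sets when present; otherwise paths
    come from structural enumeration.
    """

    are_mode: str = "significant"
    max_mediators: int = 1
    use_hypothesized_paths: bool = True
    mediator_levels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.are_mode not in ("significant", "all"):
            raise MediationError(f"unknown are_mode {self.are_mode!r}")


def exposure_level_coefficient(source: CoefficientSource, equation: str,
                               exposure: str, mode: str = "significant",
                               level: str | None = ...) -> tuple[Combo, list[str | None]]:
    """Average-relative-effect combination of an exposure in one equation.

    Single-term exposures pass through; multi-categorical exposures return
    the arithmetic mean over the selected levels.  ``level`` (when given)
    pins a single category.  Raises :class:`UndefinedEffect` when the
    significant-levels mode finds nothing to average.
    """
    levels = source.levels(equation, exposure)
    if not levels:
        raise MediationError(f"{exposure!r} is not a predictor in equation {equation!r}")
    if level is not ...:
        if level not in levels:
            raise MediationError(f"{exposure!r} has no level {level!r} in {equation!r}")
        refs = [CoefRef(equation, exposure, level)]
    else:
        refs = [CoefRef(equation, exposure, lvl) for lvl in levels]
        if mode == "significant":
            refs = [r for r in refs if source.significant(r)]
            if not refs:
                raise UndefinedEffect(
                    f"{exposure} -> {equation}: no significant level"
                )
    return Combo.average(refs), [r.level for r in refs]


def _leg_ref(source: CoefficientSource, equation: str, mediator: str,
             options: DecomposeOptions) -> CoefRef:
    """The mediator's own coefficient in the next equation (one term)."""
    levels = source.levels(equation, mediator)
    if not levels:
        raise MediationError(f"{mediator!r} is not a predictor in {equation!r}")
    if len(levels) == 1:
        lvl = levels[0]
    else:
        lvl = options.mediator_levels.get(mediator, levels[-1])
        if lvl not in levels:
            raise MediationError(f"{mediator!r} has no level {lvl!r} in {equation!r}")
    return CoefRef(equation, mediator, lvl)


def indirect_effect(path: MediatedPath, source: CoefficientSource,
                    options: DecomposeOptions | None = None) -> EffectEstimate:
    """Product-of-coefficients effect along one mediated path.

    The first leg is the exposure's (average relative) coefficient in the
    first mediator's equation; each subsequent leg is the previous node's own
    coefficient in the next equation.  In significant-levels mode a
    non-significant leg renders the whole path undefined
    (:class:`UndefinedEffect`).
    """
    options = options or DecomposeOptions()
    first_eq = path.mediators[0]
    combo, _ = exposure_level_coefficient(source, first_eq, path.exposure,
                                          mode=options.are_mode)
    chain = list(path.mediators) + [path.outcome]
    for prev, nxt in zip(chain[:-1], chain[1:]):
        ref = _leg_ref(source, nxt, prev, options)
        if options.are_mode == "significant" and not source.significant(ref):
            raise UndefinedEffect(f"leg {prev} -> {nxt} is not significant")
        combo = combo.times(ref)
    return _estimate(combo, source, "path_indirect")


def mediation_proportion(total_indirect: float, total: float) -> float:
    """100 × total indirect / total (percent)."""
    if total == 0:
        raise MediationError("mediation proportion undefined for a zero total effect")
    return 100.0 * total_indirect / total


@dataclass
class PathEffect:
    mediators: tuple[str, ...]
    estimate: EffectEstimate | None  # None when undefined ('–')
    note: str = ""


@dataclass
class DecompositionRow:
    """One exposure's full decomposition (one block of the results table)."""

    exposure: str
    paths: list[PathEffect]
    total_indirect: EffectEstimate | None
    direct: EffectEstimate | None
    total: EffectEstimate | None
    mediation_proportion: float | None
    direct_levels: list[str | None] = field(default_factory=list)


def decompose(exposure: str, diagram: PathDiagram, source: CoefficientSource,
              options: DecomposeOptions | None = None) -> DecompositionRow:
    """Full direct/indirect/total decomposition for one exposure.

    The additive identities hold exactly by construction: the total-indirect
    combination concatenates the per-path combinations, and the total
    concatenates direct and total-indirect, so values add with no rounding.
    """
    options = options or DecomposeOptions()
    if exposure == diagram.outcome:
        raise MediationError("exposure equals the outcome")
    if exposure not in diagram:
        raise MediationError(f"unknown exposure {exposure!r}")

    if (options.use_hypothesized_paths and options.max_mediators == 1
            and diagram.mediated_pathways is not None
            and exposure in diagram.mediated_pathways):
        paths = [MediatedPath(exposure, (m,), diagram.outcome)
                 for m in diagram.mediated_pathways[exposure]]
    else:
        paths = enumerate_paths(diagram, exposure, options.max_mediators)

    path_effects: list[PathEffect] = []
    ti_combo: Combo | None = None
    ti_value = 0.0
    for path in paths:
        try:
            est = indirect_effect(path, source, options)
        except UndefinedEffect as exc:
            path_effects.append(PathEffect(path.mediators, None, str(exc)))
            continue
        path_effects.append(PathEffect(path.mediators, est))
        ti_value += est.value
        ti_combo = est.combo if ti_combo is None else ti_combo.plus(est.combo)

    # value summed from the path estimates so the additive identity is exact
    total_indirect = (EffectEstimate(value=ti_value,
                                     se=delta_method_se(ti_combo, source),
                                     kind="total_indirect", combo=ti_combo)
                      if ti_combo is not None else None)

    direct = None
    direct_levels: list[str | None] = []
    if diagram.outcome in [e.child for e in diagram.edges if e.parent == exposure]:
        try:
            d_combo, direct_levels = exposure_level_coefficient(
                source, diagram.outcome, exposure, mode=options.are_mode)
            direct = _estimate(d_combo, source, "direct")
        except UndefinedEffect:
            direct = None

    total_combo = None
    total_value = 0.0
    for part in (direct, total_indirect):
        if part is not None:
            total_value += part.value
            total_combo = part.combo if total_combo is None else total_combo.plus(part.combo)
    total = (EffectEstimate(value=total_value,
                            se=delta_method_se(total_combo, source),
                            kind="total", combo=total_combo)
             if total_combo is not None else None)

    proportion = None
    if direct is not None and total_indirect is not None and total is not None \
            and total.value != 0:
        proportion = mediation_proportion(total_indirect.value, total.value)

    return DecompositionRow(
        exposure=exposure, paths=path_effects, total_indirect=total_indirect,
        direct=direct, total=total, mediation_proportion=proportion,
        direct_levels=direct_levels,
    )


# ---------------------------------------------------------------------------
# the assembled table
# ---------------------------------------------------------------------------

def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (display convention of the results tables)."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass
class DecompositionTable:
    rows: list[DecompositionRow]
    errors: dict[str, str] = field(default_factory=dict)

    def to_frame(self, digits: int | None = None) -> pd.DataFrame:
        """Long-format table (exposure, mediator, cell, estimate, CI, stars).

        ``digits`` applies display rounding (half away from zero); internal
        arithmetic is never rounded.
        """
        def fmt(x: float) -> float:
            return round_half_away(x, digits) if digits is not None else x

        records = []

        def emit(exposure, mediator, cell, est: EffectEstimate | None, value=None):
            if est is None and value is None:
                return
            records.append({
                "exposure": exposure,
                "mediator": mediator,
                "cell": cell,
                "estimate": fmt(est.value if est is not None else value),
                "ci_low": fmt(est.ci_low) if est is not None else np.nan,
                "ci_high": fmt(est.ci_high) if est is not None else np.nan,
                "stars": est.stars if est is not None else "",
            })

        for row in self.rows:
            for pe in row.paths:
                if pe.estimate is not None:
                    emit(row.exposure, "+".join(pe.mediators), "path_indirect",
                         pe.estimate)
            emit(row.exposure, "", "total_indirect", row.total_indirect)
            emit(row.exposure, "", "direct", row.direct)
            emit(row.exposure, "", "total", row.total)
            if row.mediation_proportion is not None:
                records.append({
                    "exposure": row.exposure, "mediator": "",
                    "cell": "mediation_proportion",
                    "estimate": (round_half_away(row.mediation_proportion, 1)
                                 if digits is not None else row.mediation_proportion),
                    "ci_low": np.nan, "ci_high": np.nan, "stars": "",
                })
        return pd.DataFrame.from_records(
            records, columns=["exposure", "mediator", "cell", "estimate",
                              "ci_low", "ci_high", "stars"])

    def to_csv(self, path, digits: int | None = 2) -> None:
        self.to_frame(digits=digits).to_csv(path, index=False)

    def row(self, exposure: str) -> DecompositionRow:
        for r in self.rows:
            if r.exposure == exposure:
                return r
        raise KeyError(exposure)


def decomposition_table(diagram: PathDiagram, source: CoefficientSource,
                        exposures: Sequence[str] | None = None,
                        options: DecomposeOptions | None = None
                        ) -> DecompositionTable:
    """Decompose every requested exposure; per-row failures are flagged, not fatal."""
    from .diagram import PAPER_EXPOSURE_ORDER

    if exposures is None:
        exposures = [e for e in PAPER_EXPOSURE_ORDER if e in diagram]
    rows, errors = [], {}
    for exposure in exposures:
        try:
            rows.append(decompose(exposure, diagram, source, options))
        except MediationError as exc:
            errors[exposure] = str(exc)
    return DecompositionTable(rows=rows, errors=errors)
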