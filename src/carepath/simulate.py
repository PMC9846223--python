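"""Synthetic cluster-survey generator with the diagram as the data model.

The study's raw records are access-restricted, so estimation and
decomposition are exercised on simulated surveys that reproduce the
statistical structure the analysis assumes: exogenous covariates drawn from
the published marginals, endogenous variables generated through the
six-equation DAG with the published link-scale coefficients as ground truth,
nested district/cluster labels, and the two subpopulation flags (reported
neonatal illness; maternal complication).

Intercepts are not published, so they are calibrated by monotone
root-finding until each endogenous marginal matches its published target on
a large simulated population.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .diagram import PathDiagram, VariableSpec, knowledge_category
from .fixtures import load_coefficient_fixture, load_marginal_fixture

logger = logging.getLogger("carepath.simulate")

KNOWLEDGE_MAX = 22  # items on the danger-sign knowledge instrument


class SimulationError(RuntimeError):
    pass


class CalibrationError(SimulationError):
    def __init__(self, message: str, achieved: float | None = None):
        super().__init__(message)
        self.achieved = achieved


# ---------------------------------------------------------------------------
# parameters and design
# ---------------------------------------------------------------------------

@dataclass
class ParamSet:
    """Link-scale truth of the system: intercepts, slopes, residual sd.

    ``coefficients[eq][(parent, level)]`` holds log odds (binomial
    equations) or raw slopes (the gaussian knowledge equation); reference
    levels are implicitly zero.  ``knowledge_sd`` is the residual standard
    deviation of the latent knowledge score before rounding.
    """

    intercepts: dict[str, float]
    coefficients: dict[str, dict[tuple[str, str | None], float]]
    knowledge_sd: float = 1.5

    def coef(self, equation: str, parent: str, level: str | None) -> float:
        return self.coefficients[equation].get((parent, level), 0.0)


@dataclass
class PopulationDesign:
    """Size and structure of a simulated survey.

    Defaults mirror the source survey: 14 districts × 120 clusters × 10
    records (≈16,800; ``n_records`` overrides the total, distributing
    records evenly over clusters), a 50.8% neonatal-illness prevalence, and
    maternal-complication rates of 2993/8765 among mothers of sick neonates
    and 1720/8486 among the rest — together reproducing both the published
    complication-equation subsample (N≈2,993) and the overall complication
    count (N≈4,713).  ``cluster_effect_sd`` adds an optional link-scale
    cluster intercept perturbation (0 by default: the published model has no
    cluster effect) for cluster-robust covariance experiments.
    """

    n_districts: int = 14
    clusters_per_district: int = 120
    records_per_cluster: int = 10
    n_records: int | None = None
    illness_prevalence: float = 0.508
    complication_prevalence_sick: float = 2993 / 8765
    complication_prevalence_healthy: float = 1720 / 8486
    cluster_effect_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_districts", "clusters_per_district", "records_per_cluster"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be >= 1")
        for name in ("illness_prevalence", "complication_prevalence_sick",
                     "complication_prevalence_healthy"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {p}")
        if self.cluster_effect_sd < 0:
            raise SimulationError("cluster_effect_sd must be non-negative")

    @property
    def total_records(self) -> int:
        if self.n_records is not None:
            return self.n_records
        return self.n_districts * self.clusters_per_district * self.records_per_cluster


def default_true_params(diagram: PathDiagram,
                        coefficients: pd.DataFrame | None = None) -> ParamSet:
    """Link-scale ground truth from the published coefficient table.

    Binomial slopes are ln(adjusted OR); the knowledge equation's slopes are
    the printed linear coefficients.  Intercepts start at 0 pending
    :func:`calibrate_intercepts`.
    """
    table = coefficients if coefficients is not None else load_coefficient_fixture()
    edge_set = {(e.parent, e.child) for e in diagram.edges}
    coefs: dict[str, dict[tuple[str, str | None], float]] = {
        v.name: {} for v in diagram.endogenous
    }
    seen_edges = set()
    for _, row in table.iterrows():
        eq, parent = row["equation"], row["predictor"]
        if (parent, eq) not in edge_set:
            raise SimulationError(
                f"fixture coefficient {parent!r} -> {eq!r} has no diagram edge"
            )
        seen_edges.add((parent, eq))
        level = row["level"] if pd.notna(row["level"]) else None
        coefs[eq][(parent, level)] = float(row["link_estimate"])
    missing = edge_set - seen_edges
    if missing:
        raise SimulationError(f"diagram edges without fixture coefficients: {sorted(missing)}")
    return ParamSet(intercepts={v.name: 0.0 for v in diagram.endogenous},
                    coefficients=coefs)


def default_exogenous_marginals(marginals: pd.DataFrame | None = None
                                ) -> dict[str, dict[str, float]]:
    """Per-level probabilities of the exogenous covariates (overall column)."""
    table = marginals if marginals is not None else load_marginal_fixture()
    exo = ("mother_age", "education", "wealth", "living_children",
           "child_death_history", "newborn_sex", "facility_distance",
           "chw_visit", "ds_counseling")
    out: dict[str, dict[str, float]] = {}
    for var in exo:
        sub = table[table["variable"] == var]
        probs = sub["overall_pct"].to_numpy(float)
        probs = probs / probs.sum()  # printed percents round; renormalize
        out[var] = dict(zip(sub["level"], probs))
    return out


def default_endogenous_targets() -> dict[str, float]:
    """Calibration targets: published marginals of the endogenous variables.

    Binomial targets are proportions on each variable's definition domain
    (overall for the maternal-care variables, the complication subset for
    maternal care-seeking, the sick subset for the outcome).  The knowledge
    target is a mean count of 3.0, consistent with the published category
    distribution (3.4% know none, 78.9% know 1–4, 17.6% know 5+).
    """
    return {
        "anc4": 0.273,
        "facility_delivery": 0.522,
        "pnc": 0.434,
        "maternal_careseeking": 0.650,
        "knowledge": 3.0,
        "neonatal_careseeking": 0.365,
    }


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _predictor_series(frame: pd.DataFrame, spec: VariableSpec) -> pd.Series:
    col = frame[spec.name]
    if spec.measurement == "count" and spec.predictor_encoding == "as_levels":
        return col.map(lambda v: knowledge_category(v) if pd.notna(v) else v)
    if spec.na_as_reference:
        col = col.fillna(spec.reference_level)
    return col


def _linear_predictor(frame: pd.DataFrame, diagram: PathDiagram,
                      params: ParamSet, endog: str) -> np.ndarray:
    eta = np.full(len(frame), params.intercepts[endog])
    for parent in diagram.parents(endog):
        pspec = diagram.variable(parent)
        col = _predictor_series(frame, pspec)
        if pspec.predictor_encoding == "as_continuous" or pspec.levels is None:
            eta += params.coef(endog, parent, None) * col.to_numpy(float)
        else:
            for lvl in pspec.nonreference_levels:
                beta = params.coef(endog, parent, lvl)
                if beta != 0.0:
                    eta += beta * (col == lvl).to_numpy(float)
    return eta


def _draw_exogenous(diagram: PathDiagram, marginals: Mapping[str, Mapping[str, float]],
                    n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for spec in diagram.variables:
        if spec.role != "exogenous":
            continue
        dist = marginals.get(spec.name)
        if dist is None:
            raise SimulationError(f"no marginal distribution for {spec.name!r}")
        levels = list(dist)
        unknown = set(levels) - set(spec.levels or levels)
        if unknown:
            raise SimulationError(f"{spec.name}: marginal levels {unknown} not declared")
        probs = np.array([dist[l] for l in levels], float)
        probs = probs / probs.sum()
        cols[spec.name] = rng.choice(levels, size=n, p=probs)
    return pd.DataFrame(cols)


def _labels(design: PopulationDesign) -> pd.DataFrame:
    n = design.total_records
    n_clusters = design.n_districts * design.clusters_per_district
    cluster_idx = np.arange(n) % n_clusters  # even spread when n_records is set
    district_idx = cluster_idx // design.clusters_per_district
    return pd.DataFrame({
        "district": [f"d{i + 1:02d}" for i in district_idx],
        "cluster": [f"d{d + 1:02d}_c{(c % design.clusters_per_district) + 1:03d}"
                    for d, c in zip(district_idx, cluster_idx)],
    })


def generate_population(diagram: PathDiagram, params: ParamSet,
                        design: PopulationDesign,
                        marginals: Mapping[str, Mapping[str, float]] | None = None
                        ) -> pd.DataFrame:
    """Simulate one survey; a pure function of (diagram, params, design).

    Endogenous variables are drawn in topological order — binomial via
    Bernoulli(inverse-logit(η)), the knowledge count via a latent gaussian
    rounded and clipped to [0, 22] — after the illness and complication
    flags.  Variables with a definition domain are stored missing outside it.
    """
    rng = np.random.default_rng(design.seed)
    n = design.total_records
    marginals = marginals if marginals is not None else default_exogenous_marginals()

    frame = pd.concat([_labels(design), _draw_exogenous(diagram, marginals, n, rng)],
                      axis=1)
    frame["sick_neonate"] = rng.random(n) < design.illness_prevalence
    p_comp = np.where(frame["sick_neonate"], design.complication_prevalence_sick,
                      design.complication_prevalence_healthy)
    frame["had_complication"] = rng.random(n) < p_comp

    cluster_codes = pd.factorize(frame["cluster"])[0]
    n_clusters = cluster_codes.max() + 1

    for endog in diagram.topological_order():
        spec = diagram.variable(endog)
        eta = _linear_predictor(frame, diagram, params, endog)
        if design.cluster_effect_sd > 0:
            eta = eta + rng.normal(0.0, design.cluster_effect_sd,
                                   n_clusters)[cluster_codes]
        if spec.family == "binomial":
            draws = rng.random(n) < expit(eta)
            ref, alt = spec.levels
            values = pd.Series(np.where(draws, alt, ref), index=frame.index)
        else:
            latent = eta + rng.normal(0.0, params.knowledge_sd, n)
            values = pd.Series(np.clip(np.rint(latent), 0, KNOWLEDGE_MAX)
                               .astype(int), index=frame.index)
        if spec.domain_flag is not None:
            values = values.where(frame[spec.domain_flag].astype(bool))
        frame[endog] = values
        if spec.measurement == "count" and spec.predictor_encoding == "as_levels":
            frame[f"{endog}_cat"] = frame[endog].map(
                lambda v: knowledge_category(v) if pd.notna(v) else v)

    return frame


# ---------------------------------------------------------------------------
# intercept calibration
# ---------------------------------------------------------------------------

def calibrate_intercepts(params: ParamSet, targets: Mapping[str, float],
                         design: PopulationDesign, diagram: PathDiagram,
                         marginals: Mapping[str, Mapping[str, float]] | None = None,
                         n_sim: int = 200_000, tol: float = 0.005,
                         bracket: float = 30.0) -> ParamSet:
    """Adjust intercepts until simulated marginals hit their targets.

    Works through the equations in topological order on one large simulated
    population: for each equation the intercept is found by monotone
    root-finding (Brent) on the simulated marginal — the mean of
    inverse-logit(c + η) on the variable's definition domain for binomial
    equations, the mean of the rounded/clipped count for the gaussian one —
    then the variable is drawn at the solved intercept to feed its children.
    Deterministic given ``design.seed``.
    """
    rng = np.random.default_rng([design.seed, 910_121])  # calibration stream
    marginals = marginals if marginals is not None else default_exogenous_marginals()

    frame = _draw_exogenous(diagram, marginals, n_sim, rng)
    frame["sick_neonate"] = rng.random(n_sim) < design.illness_prevalence
    p_comp = np.where(frame["sick_neonate"], design.complication_prevalence_sick,
                      design.complication_prevalence_healthy)
    frame["had_complication"] = rng.random(n_sim) < p_comp

    new = ParamSet(intercepts=dict(params.intercepts),
                   coefficients=params.coefficients,
                   knowledge_sd=params.knowledge_sd)

    for endog in diagram.topological_order():
        spec = diagram.variable(endog)
        if endog not in targets:
            raise CalibrationError(f"no calibration target for {endog!r}")
        target = targets[endog]
        new.intercepts[endog] = 0.0
        eta = _linear_predictor(frame, diagram, new, endog)
        domain = (frame[spec.domain_flag].to_numpy(bool)
                  if spec.domain_flag is not None else np.ones(n_sim, bool))

        if spec.family == "binomial":
            if not 0.0 < target < 1.0:
                raise CalibrationError(f"{endog}: binomial target must be in (0,1)")

            def gap(c):
                return float(np.mean(expit(c + eta[domain]))) - target

            achieved_fn = lambda c: float(np.mean(expit(c + eta[domain])))
        else:
            noise = rng.normal(0.0, new.knowledge_sd, n_sim)

            def gap(c):
                counts = np.clip(np.rint(c + eta[domain] + noise[domain]),
                                 0, KNOWLEDGE_MAX)
                return float(counts.mean()) - target

            achieved_fn = lambda c: gap(c) + target

        lo, hi = -bracket, bracket
        if gap(lo) > 0 or gap(hi) < 0:
            raise CalibrationError(
                f"{endog}: target {target} out of reach in [{lo}, {hi}]",
                achieved=achieved_fn(0.0))
        c_star = brentq(gap, lo, hi, xtol=1e-8)
        achieved = achieved_fn(c_star)
        if abs(achieved - target) > tol:
            raise CalibrationError(
                f"{endog}: achieved marginal {achieved:.4f} misses target "
                f"{target:.4f} by more than {tol}", achieved=achieved)
        new.intercepts[endog] = float(c_star)
        logger.info("calibrated %s: intercept %.4f, marginal %.4f",
                    endog, c_star, achieved)

        # draw the variable at the solved intercept to feed child equations
        eta = eta + c_star
        if spec.family == "binomial":
            draws = rng.random(n_sim) < expit(eta)
            ref, alt = spec.levels
            values = pd.Series(np.where(draws, alt, ref), index=frame.index)
        else:
            values = pd.Series(np.clip(np.rint(eta + noise), 0,
                                       KNOWLEDGE_MAX).astype(int),
                               index=frame.index)
        if spec.domain_flag is not None:
            values = values.where(frame[spec.domain_flag].astype(bool))
        frame[endog] = values

    return new


# ---------------------------------------------------------------------------
# dataset I/O (CSV with a sidecar schema)
# ---------------------------------------------------------------------------

def write_dataset(frame: pd.DataFrame, path) -> None:
    """Write records as CSV plus a ``<path>.schema.json`` sidecar."""
    import pathlib

    path = pathlib.Path(path)
    frame.to_csv(path, index=False)
    schema = {c: str(frame[c].dtype) for c in frame.columns}
    path.with_suffix(path.suffix + ".schema.json").write_text(
        json.dumps(schema, indent=1))


def read_dataset(path) -> pd.DataFrame:
    import pathlib

    path = pathlib.Path(path)
    sidecar = path.with_suffix(path.suffix + ".schema.json")
    frame = pd.read_csv(path)
    if sidecar.exists():
        schema = json.loads(sidecar.read_text())
        for col, dtype in schema.items():
            if col in frame.columns and dtype == "bool":
                frame[col] = frame[col].astype(bool)
    return frame
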