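"""Maximum-likelihood fitting of the recursive equation system.

Each endogenous variable is fitted by one generalized linear equation on its
declared subpopulation — logit link for binomial variables, identity link for
the gaussian knowledge equation — in topological order.  Per-equation
coefficient covariances use the robust sandwich estimator A⁻¹BA⁻¹ (HC1 at the
observation level by default, optionally cluster-robust), and the equations'
covariances are assembled into one joint matrix for downstream delta-method
calculus.  Because the system is recursive with distinct parameters per
equation, the likelihood factorizes and the joint covariance is
block-diagonal by default; a stacked-sandwich mode estimates cross-equation
blocks from score cross-products for sensitivity analysis.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .diagram import PathDiagram, VariableSpec, knowledge_category
from .fixtures import Z95

logger = logging.getLogger("carepath.fitting")

_PROB_EDGE = 1e-10  # fitted probabilities this close to 0/1 flag separation


class FitError(RuntimeError):
    """Base class for estimation failures."""


class SeparationError(FitError):
    """Perfect or quasi-perfect separation in a logit equation."""


class RankDeficiencyError(FitError):
    """Collinear design columns."""


class ConvergenceError(FitError):
    """IRLS failed to converge within the iteration budget."""


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def predictor_terms(diagram: PathDiagram, parent: str) -> list[str]:
    """Term names contributed by one parent (reference level omitted)."""
    spec = diagram.variable(parent)
    if spec.predictor_encoding == "as_continuous" or spec.levels is None:
        return [parent]
    return [f"{parent}[{lvl}]" for lvl in spec.nonreference_levels]


def term_name(parent: str, level: str | None) -> str:
    return parent if level is None else f"{parent}[{level}]"


def _predictor_column(data: pd.DataFrame, spec: VariableSpec) -> pd.Series:
    """The column a variable contributes on the predictor side."""
    name = spec.name
    if spec.measurement == "count" and spec.predictor_encoding == "as_levels":
        cat = f"{name}_cat"
        if cat in data.columns:
            return data[cat]
        return data[name].map(lambda v: knowledge_category(v) if pd.notna(v) else v)
    return data[name]


def build_design(data: pd.DataFrame, diagram: PathDiagram, endog: str
                 ) -> tuple[pd.Series, pd.DataFrame]:
    """Response and design matrix for one equation, complete cases only.

    Categorical parents expand to indicator columns against their reference
    level; parents flagged ``na_as_reference`` have missing values coded as
    the reference before the complete-case filter.
    """
    spec = diagram.variable(endog)
    parents = diagram.parents(endog)
    cols: dict[str, pd.Series] = {}
    required = []

    if spec.family == "binomial":
        ref = spec.reference_level
        y = pd.Series(np.where(data[endog].isna(), np.nan,
                               (data[endog] != ref).astype(float)),
                      index=data.index, name=endog)
    else:
        y = pd.to_numeric(data[endog], errors="coerce")
    required.append(y)

    for parent in parents:
        pspec = diagram.variable(parent)
        col = _predictor_column(data, pspec)
        if pspec.na_as_reference:
            col = col.fillna(pspec.reference_level)
        if pspec.predictor_encoding == "as_continuous" or pspec.levels is None:
            num = pd.to_numeric(col, errors="coerce")
            cols[parent] = num
            required.append(num)
        else:
            required.append(col)
            for lvl in pspec.nonreference_levels:
                cols[term_name(parent, lvl)] = (col == lvl).astype(float)

    keep = pd.notna(pd.concat(required, axis=1)).all(axis=1)
    X = pd.DataFrame({"const": 1.0, **cols}, index=data.index)[keep]
    return y[keep], X


# ---------------------------------------------------------------------------
# per-equation fits
# ---------------------------------------------------------------------------

@dataclass
class EquationFit:
    """One fitted link-scale equation with its robust covariance."""

    equation: str
    family: str
    terms: list[str]
    params: np.ndarray
    cov: np.ndarray
    n_used: int
    loglik: float
    converged: bool
    iterations: int
    cov_type: str = "hc1"
    penalized: bool = False
    deviance_trace: list[float] = field(default_factory=list, repr=False)
    # per-observation ingredients retained for sandwich / stacked assembly
    scores: pd.DataFrame = field(repr=False, default=None)
    bread_inv: np.ndarray = field(repr=False, default=None)

    def coef(self, term: str) -> float:
        return float(self.params[self.terms.index(term)])

    def se(self, term: str) -> float:
        i = self.terms.index(term)
        return float(math.sqrt(self.cov[i, i]))

    def conf_int(self, term: str) -> tuple[float, float]:
        b, s = self.coef(term), self.se(term)
        return b - Z95 * s, b + Z95 * s


def _check_rank(X: pd.DataFrame, equation: str) -> None:
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the columns whose removal restores full rank
        bad = []
        cols = list(X.columns)
        for j in range(arr.shape[1]):
            sub = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(cols[j])
        raise RankDeficiencyError(
            f"{equation}: design matrix is rank deficient (rank {rank} < {arr.shape[1]}); "
            f"collinear terms: {bad or cols}"
        )


def _check_separation(equation: str, X: pd.DataFrame, fitted: np.ndarray,
                      params: np.ndarray) -> None:
    at_edge = (fitted < _PROB_EDGE) | (fitted > 1 - _PROB_EDGE)
    if not at_edge.any():
        return
    big = [t for t, b in zip(X.columns, params) if abs(b) > 10]
    raise SeparationError(
        f"{equation}: {int(at_edge.sum())} fitted probabilities within {_PROB_EDGE:g} "
        f"of 0/1; separating term(s): {big or list(X.columns)}"
    )


def fit_glm(data: pd.DataFrame, diagram: PathDiagram, endog: str, *,
            cov_type: str = "hc1", cluster: str | None = None,
            ridge: float = 0.0, maxiter: int = 100) -> EquationFit:
    """Fit one equation of the system by maximum likelihood.

    Binomial equations use logit IRLS (via statsmodels GLM); the gaussian
    equation is ordinary least squares.  ``cov_type`` selects ``"hc1"``
    (robust, default), ``"cluster"`` (with ``cluster`` naming the id column)
    or ``"classical"``.  A small ridge penalty (e.g. 1e-6) may be supplied to
    push through separated toy inputs; it is off by default so the fit has
    exact MLE semantics.
    """
    spec = diagram.variable(endog)
    if spec.role != "endogenous":
        raise FitError(f"{endog} is not endogenous")
    y, X = build_design(data, diagram, endog)
    n, k = X.shape
    if n <= k:
        raise FitError(f"{endog}: {n} complete cases for {k} parameters")
    for parent in diagram.parents(endog):
        pspec = diagram.variable(parent)
        if pspec.levels is not None and pspec.predictor_encoding == "as_levels":
            col = _predictor_column(data.loc[X.index], pspec)
            if pspec.na_as_reference:
                col = col.fillna(pspec.reference_level)
            present = set(col.dropna().unique())
            missing = [l for l in pspec.nonreference_levels if l not in present]
            if missing:
                raise FitError(f"{endog}: no observations at level(s) {missing} of {parent}")
    _check_rank(X, endog)

    yv = y.to_numpy(float)
    Xv = X.to_numpy(float)
    trace: list[float] = []
    if spec.family == "binomial":
        import warnings
        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        model = sm.GLM(yv, Xv, family=sm.families.Binomial())
        if ridge > 0:
            res = model.fit_regularized(alpha=ridge, L1_wt=0.0, maxiter=maxiter)
            params = np.asarray(res.params)
            fitted = expit(Xv @ params)
            llf = float(np.sum(yv * np.log(np.clip(fitted, 1e-300, 1))
                               + (1 - yv) * np.log(np.clip(1 - fitted, 1e-300, 1))))
            converged, iters, penalized = True, maxiter, True
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", PerfectSeparationWarning)
                res = model.fit(maxiter=maxiter, tol=1e-10)
            params = np.asarray(res.params)
            fitted = expit(Xv @ params)
            llf = float(res.llf)
            converged = bool(getattr(res, "converged", True))
            # first finite history entry is the pre-iteration starting value
            trace = [float(d) for d in res.fit_history.get("deviance", [])
                     if np.isfinite(d)][1:]
            iters = len(trace) or maxiter
            penalized = False
            _check_separation(endog, X, fitted, params)
            if not converged:
                raise ConvergenceError(
                    f"{endog}: IRLS did not converge in {maxiter} iterations; "
                    f"deviance trace: {trace}"
                )
            # deviance = -2 loglik + const: the likelihood must never decrease
            worsened = [(a, b) for a, b in zip(trace, trace[1:]) if b > a + 1e-8]
            if worsened:
                raise ConvergenceError(
                    f"{endog}: deviance increased across IRLS iterations: {worsened}"
                )
        resid = yv - fitted
        w = fitted * (1 - fitted)
        bread = Xv.T @ (Xv * w[:, None])
    else:
        res = sm.OLS(yv, Xv).fit()
        params = np.asarray(res.params)
        resid = yv - Xv @ params
        llf = float(res.llf)
        converged, iters, penalized = True, 1, False
        bread = Xv.T @ Xv

    scores = pd.DataFrame(Xv * resid[:, None], index=X.index, columns=X.columns)
    try:
        bread_inv = np.linalg.inv(bread)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"{endog}: singular bread matrix") from exc

    fit = EquationFit(
        equation=endog, family=spec.family, terms=list(X.columns), params=params,
        cov=np.empty((k, k)), n_used=n, loglik=llf, converged=converged,
        iterations=iters, cov_type=cov_type, penalized=penalized,
        deviance_trace=trace, scores=scores, bread_inv=bread_inv,
    )
    if cov_type == "classical":
        if spec.family == "binomial":
            fit.cov = bread_inv
        else:
            sigma2 = float(resid @ resid) / (n - k)
            fit.cov = sigma2 * bread_inv
    else:
        cluster_ids = data.loc[X.index, cluster] if cov_type == "cluster" else None
        if cov_type == "cluster" and cluster is None:
            raise FitError("cov_type='cluster' requires a cluster column name")
        fit.cov = sandwich_covariance(fit, cluster_ids=cluster_ids)
    return fit


def sandwich_covariance(fit: EquationFit,
                        cluster_ids: pd.Series | None = None) -> np.ndarray:
    """Robust covariance A⁻¹BA⁻¹ for a fitted equation.

    The bread A is the observed information (binomial) or X'X (gaussian); the
    meat B sums score outer products per observation (HC1 factor n/(n−k)) or
    per cluster (factor G/(G−1)·(n−1)/(n−k)).
    """
    if not fit.converged:
        raise FitError(f"{fit.equation}: refusing covariance for unconverged fit")
    U = fit.scores.to_numpy(float)
    n, k = U.shape
    if cluster_ids is None:
        meat = U.T @ U
        factor = n / (n - k)
    else:
        g = pd.DataFrame(U, index=cluster_ids.to_numpy()).groupby(level=0).sum()
        G = len(g)
        if G < 2:
            raise FitError(f"{fit.equation}: need at least 2 clusters, got {G}")
        Ug = g.to_numpy(float)
        meat = Ug.T @ Ug
        factor = G / (G - 1) * (n - 1) / (n - k)
    return factor * fit.bread_inv @ meat @ fit.bread_inv


def significance_label(coef: float, se: float) -> str:
    """Two-sided Wald star label: '**' for p<0.01, '*' for p<0.05, else ''."""
    if se <= 0:
        raise ValueError(f"standard error must be positive, got {se}")
    from scipy.stats import norm

    p = 2 * norm.sf(abs(coef) / se)
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# the assembled system
# ---------------------------------------------------------------------------

@dataclass
class FitOptions:
    cov_type: str = "hc1"           # "hc1" | "cluster" | "classical"
    cluster: str | None = None      # cluster id column for cov_type="cluster"
    joint: str = "block_diagonal"   # "block_diagonal" | "stacked_sandwich"
    ridge: float = 0.0


@dataclass
class SystemFit:
    """All equation fits plus the assembled joint covariance."""

    fits: dict[str, EquationFit]
    joint_cov: np.ndarray
    joint_terms: list[tuple[str, str]]  # (equation, term) per joint row
    covariance_mode: str
    cluster: str | None = None

    def index_of(self, equation: str, term: str) -> int:
        return self.joint_terms.index((equation, term))

    def coef(self, equation: str, term: str) -> float:
        return self.fits[equation].coef(term)

    def se(self, equation: str, term: str) -> float:
        return self.fits[equation].se(term)

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "covariance_mode": self.covariance_mode,
            "cluster": self.cluster,
            "joint_terms": [list(t) for t in self.joint_terms],
            "joint_cov": self.joint_cov.tolist(),
            "equations": {
                name: {
                    "family": f.family,
                    "terms": f.terms,
                    "params": f.params.tolist(),
                    "cov": f.cov.tolist(),
                    "n_used": f.n_used,
                    "loglik": f.loglik,
                    "converged": f.converged,
                    "iterations": f.iterations,
                    "cov_type": f.cov_type,
                    "penalized": f.penalized,
                }
                for name, f in self.fits.items()
            },
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SystemFit":
        d = json.loads(text)
        fits = {
            name: EquationFit(
                equation=name, family=e["family"], terms=list(e["terms"]),
                params=np.asarray(e["params"]), cov=np.asarray(e["cov"]),
                n_used=e["n_used"], loglik=e["loglik"], converged=e["converged"],
                iterations=e["iterations"], cov_type=e["cov_type"],
                penalized=e["penalized"],
            )
            for name, e in d["equations"].items()
        }
        return cls(fits=fits, joint_cov=np.asarray(d["joint_cov"]),
                   joint_terms=[tuple(t) for t in d["joint_terms"]],
                   covariance_mode=d["covariance_mode"], cluster=d.get("cluster"))

    def to_table(self) -> pd.DataFrame:
        """Presentation table: exp(coef) with Wald CI and stars per term."""
        rows = []
        for name, f in self.fits.items():
            for term in f.terms:
                b, s = f.coef(term), f.se(term)
                lo, hi = f.conf_int(term)
                is_or = f.family == "binomial"
                rows.append({
                    "equation": name,
                    "term": term,
                    "scale": "or" if is_or else "beta",
                    "estimate": math.exp(b) if is_or else b,
                    "ci_low": math.exp(lo) if is_or else lo,
                    "ci_high": math.exp(hi) if is_or else hi,
                    "link_estimate": b,
                    "link_se": s,
                    "stars": significance_label(b, s) if s > 0 else "",
                    "n": f.n_used,
                })
        return pd.DataFrame(rows)


def subpopulation_mask(data: pd.DataFrame, diagram: PathDiagram, endog: str) -> pd.Series:
    mask = pd.Series(True, index=data.index)
    for flag in diagram.equation_filters(endog):
        if flag not in data.columns:
            raise FitError(f"{endog}: subpopulation flag column {flag!r} missing")
        mask &= data[flag].astype(bool)
    return mask


def fit_system(data: pd.DataFrame, diagram: PathDiagram,
               options: FitOptions | None = None) -> SystemFit:
    """Fit every equation on its subpopulation and assemble the joint covariance."""
    options = options or FitOptions()
    fits: dict[str, EquationFit] = {}
    for endog in diagram.topological_order():
        sub = data[subpopulation_mask(data, diagram, endog)]
        try:
            fits[endog] = fit_glm(
                sub, diagram, endog, cov_type=options.cov_type,
                cluster=options.cluster, ridge=options.ridge,
            )
        except FitError as exc:
            raise FitError(f"equation {endog!r}: {exc}") from exc
        logger.info("fitted %s: n=%d, loglik=%.2f", endog, fits[endog].n_used,
                    fits[endog].loglik)

    joint_terms = [(eq, t) for eq in fits for t in fits[eq].terms]
    p = len(joint_terms)
    joint = np.zeros((p, p))
    offsets: dict[str, int] = {}
    pos = 0
    for eq, f in fits.items():
        offsets[eq] = pos
        joint[pos:pos + len(f.terms), pos:pos + len(f.terms)] = f.cov
        pos += len(f.terms)

    if options.joint == "stacked_sandwich":
        names = list(fits)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                fa, fb = fits[a], fits[b]
                shared = fa.scores.index.intersection(fb.scores.index)
                if len(shared) == 0:
                    continue
                Ua = fa.scores.loc[shared].to_numpy(float)
                Ub = fb.scores.loc[shared].to_numpy(float)
                cross = fa.bread_inv @ (Ua.T @ Ub) @ fb.bread_inv
                ca, cb = offsets[a], offsets[b]
                joint[ca:ca + Ua.shape[1], cb:cb + Ub.shape[1]] = cross
                joint[cb:cb + Ub.shape[1], ca:ca + Ua.shape[1]] = cross.T
    elif options.joint != "block_diagonal":
        raise FitError(f"unknown joint covariance mode {options.joint!r}")

    return SystemFit(fits=fits, joint_cov=joint, joint_terms=joint_terms,
                     covariance_mode=options.joint, cluster=options.cluster)
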