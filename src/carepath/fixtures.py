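"""Packaged transcriptions of the published summary tables.

Three CSV fixtures ship with the package, each carrying provenance columns
(table id, printed row label) for every number:

``table1_marginals.csv``
    Descriptive marginals of the survey population (overall and split by
    healthy/sick neonate).  Used as the default covariate distribution of the
    synthetic-data generator and as calibration targets.
``table2_coefficients.csv``
    The fitted system: adjusted odds ratios (binomial equations) and adjusted
    linear coefficients (the knowledge equation) with 95% CIs and
    significance stars.  Link-scale ground truth for simulation and the
    coefficient source for the published-input mediation decomposition.
``table3_decomposition.csv``
    The published direct/indirect/total decomposition, transcribed verbatim
    (including its internally inconsistent cells, flagged in ``note``).

``table3_curated_cells.csv`` records, cell by cell, which published
decomposition values are reproducible from the printed coefficients and the
justification for each exclusion.
"""

from __future__ import annotations

import hashlib
import math
from importlib import resources
from typing import NamedTuple

import pandas as pd

#: sha256 digests of the packaged fixture files (integrity check).
_DIGESTS = {
    "table1_marginals.csv": "47b51a979ae5a4e6c28572d8f373c616cd76ac4a6cd364db2ef24cd42e31a554",
    "table2_coefficients.csv": "bbbc55a972ac62a1cf86eaf347319e9cbb2332d43ac4598dce61532a78c44b16",
    "table3_decomposition.csv": "b6af150fcf9c030abe2222114195b74bd3b86873e02547683ea54fd33ab0fb52",
    "table3_curated_cells.csv": "25c8fc646d3825d0346da3df1bf3a5baa26c9b8aac364d2afc5a9659d79a5ed8",
    "paper_diagram.yaml": "d09424c22ab098b79a64892f4b2d9ea7925674a08410b6b76bffe30741f67554",
}

Z95 = 1.959964  # two-sided 95% normal quantile, as used for every Wald CI


class FixtureError(RuntimeError):
    """Raised when a packaged fixture is missing or corrupted."""


def fixture_text(name: str, verify: bool = True) -> str:
    """Return the raw text of a packaged fixture, checksum-verified."""
    ref = resources.files("carepath.data").joinpath(name)
    try:
        raw = ref.read_bytes()
    except FileNotFoundError as exc:
        raise FixtureError(f"missing packaged fixture {name!r}") from exc
    if verify:
        digest = hashlib.sha256(raw).hexdigest()
        expected = _DIGESTS.get(name)
        if expected is None:
            raise FixtureError(f"no recorded checksum for fixture {name!r}")
        if digest != expected:
            raise FixtureError(
                f"fixture {name!r} is corrupted: sha256 {digest} != {expected}"
            )
    return raw.decode("utf-8")


def _read_csv(name: str) -> pd.DataFrame:
    from io import StringIO

    return pd.read_csv(StringIO(fixture_text(name)), dtype={"level": str, "mediator": str})


class FixtureTables(NamedTuple):
    coefficients: pd.DataFrame
    decomposition: pd.DataFrame
    marginals: pd.DataFrame


def paper_fixture_tables() -> FixtureTables:
    """Load the three packaged table transcriptions."""
    return FixtureTables(
        coefficients=load_coefficient_fixture(),
        decomposition=load_decomposition_fixture(),
        marginals=load_marginal_fixture(),
    )


def load_coefficient_fixture() -> pd.DataFrame:
    """Fitted-system coefficients with derived link-scale columns.

    Adds ``link_estimate`` (ln AOR for odds-ratio rows, the raw slope for
    linear rows), ``link_se`` backed out of the printed 95% CI as
    (upper − lower)/(2·1.96) on the link scale, and boolean ``significant``
    (any star).
    """
    import numpy as np

    df = _read_csv("table2_coefficients.csv")
    df["stars"] = df["stars"].fillna("")
    is_or = (df["scale"] == "or").to_numpy()
    link = lambda col: np.where(is_or, np.log(df[col].where(is_or, 1.0)), df[col])
    df["link_estimate"] = link("estimate")
    df["link_se"] = (link("ci_high") - link("ci_low")) / (2 * Z95)
    df["significant"] = df["stars"] != ""
    return df


def load_decomposition_fixture() -> pd.DataFrame:
    df = _read_csv("table3_decomposition.csv")
    df["stars"] = df["stars"].fillna("")
    df["mediator"] = df["mediator"].fillna("")
    return df


def load_marginal_fixture() -> pd.DataFrame:
    return _read_csv("table1_marginals.csv")


def load_curated_cells() -> pd.DataFrame:
    df = _read_csv("table3_curated_cells.csv")
    df["mediator"] = df["mediator"].fillna("")
    df["justification"] = df["justification"].fillna("")
    df["included"] = df["included"].astype(bool)
    return df


def lookup_coefficient(df: pd.DataFrame, equation: str, predictor: str,
                       level: str | None = None) -> pd.Series:
    """Return the fixture row for one coefficient cell."""
    m = (df["equation"] == equation) & (df["predictor"] == predictor)
    if level is not None:
        m &= df["level"] == level
    sub = df[m]
    if len(sub) != 1:
        raise KeyError(
            f"coefficient ({equation}, {predictor}, {level}) matched {len(sub)} rows"
        )
    return sub.iloc[0]
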