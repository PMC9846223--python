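"""Path diagrams for recursive systems of link-scale regression equations.

A :class:`PathDiagram` declares the observed variables of a generalized
structural equation model (GSEM), the directed edges between them, the single
outcome variable, and the subpopulation each equation is estimated on.  The
system is fully recursive (acyclic) with no latent variables: every endogenous
variable is the dependent variable of exactly one generalized linear equation
whose predictors are its parents in the diagram.

The built-in diagram (:func:`build_paper_diagram`) encodes a six-equation
model of care-seeking for sick newborns in rural Bangladesh: four-plus
antenatal-care visits (ANC) from a qualified provider, facility delivery,
postnatal care (PNC) from a qualified provider, care-seeking for a maternal
complication, the mother's count of known neonatal danger signs, and
care-seeking for the sick neonate from a qualified provider (the outcome).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import networkx as nx
import yaml

ROLES = ("exogenous", "endogenous")
FAMILIES = ("binomial", "gaussian")
MEASUREMENTS = ("binary", "categorical", "count", "continuous")
ENCODINGS = ("as_levels", "as_continuous")


class DiagramError(ValueError):
    """Raised for malformed diagram configurations."""


@dataclass(frozen=True)
class VariableSpec:
    """One observed variable of the system.

    Parameters
    ----------
    name
        Column name in datasets.
    role
        ``"exogenous"`` (appears only as a predictor) or ``"endogenous"``
        (modeled by an equation; may also be a predictor downstream).
    family
        GLM family of the variable's own equation; required iff endogenous.
    measurement
        ``binary``, ``categorical``, ``count`` or ``continuous``.
    levels
        Ordered category labels; the first is the reference.  For a count
        variable with ``predictor_encoding="as_levels"`` these are the bins
        used when the variable enters other equations as a predictor.
    reference_level
        Reference category (must equal ``levels[0]``).
    predictor_encoding
        How the variable enters equations where it is a parent.
    na_as_reference
        Treat missing values as the reference level on the predictor side.
        Used for variables that are structurally undefined outside their own
        equation's subpopulation (e.g. care-seeking for a maternal
        complication among women who had no complication).
    domain_flag
        Flag column outside which the variable is undefined (stored missing);
        ``None`` for variables observed on every record.
    """

    name: str
    role: str
    measurement: str
    family: str | None = None
    levels: tuple[str, ...] | None = None
    reference_level: str | None = None
    predictor_encoding: str = "as_levels"
    na_as_reference: bool = False
    domain_flag: str | None = None

    def __post_init__(self) -> None:
        if self.levels is not None:
            object.__setattr__(self, "levels", tuple(self.levels))

    @property
    def nonreference_levels(self) -> tuple[str, ...]:
        if self.levels is None:
            return ()
        return tuple(l for l in self.levels if l != self.reference_level)


@dataclass(frozen=True)
class EdgeSpec:
    """A directed edge ``parent -> child``; the child must be endogenous."""

    parent: str
    child: str


@dataclass
class PathDiagram:
    """The DAG of equations.

    ``subpopulation_filters`` maps each endogenous variable to the list of
    boolean flag columns restricting its equation (conjunction).
    ``mediated_pathways`` optionally records the hypothesized mediation
    structure of the underlying conceptual framework: for each exposure, the
    single-mediator pathways the analysis decomposes.  When absent,
    decomposition falls back to structural path enumeration.
    """

    variables: list[VariableSpec]
    edges: list[EdgeSpec]
    outcome: str
    subpopulation_filters: dict[str, tuple[str, ...]] = field(default_factory=dict)
    mediated_pathways: dict[str, tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        self.subpopulation_filters = {
            k: tuple([v] if isinstance(v, str) else v)
            for k, v in self.subpopulation_filters.items()
        }
        if self.mediated_pathways is not None:
            self.mediated_pathways = {
                k: tuple(v) for k, v in self.mediated_pathways.items()
            }
        self._by_name = {v.name: v for v in self.variables}

    # -- accessors ---------------------------------------------------------

    def variable(self, name: str) -> VariableSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise DiagramError(f"unknown variable {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def endogenous(self) -> list[VariableSpec]:
        return [v for v in self.variables if v.role == "endogenous"]

    def parents(self, child: str) -> list[str]:
        return [e.parent for e in self.edges if e.child == child]

    def children(self, parent: str) -> list[str]:
        return [e.child for e in self.edges if e.parent == parent]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(v.name for v in self.variables)
        g.add_edges_from((e.parent, e.child) for e in self.edges)
        return g

    def topological_order(self) -> list[str]:
        """Endogenous variables in a valid fitting order (deterministic)."""
        order = list(
            nx.lexicographical_topological_sort(
                self.to_networkx(), key=lambda n: self._topo_rank(n)
            )
        )
        endo = {v.name for v in self.endogenous}
        return [n for n in order if n in endo]

    def _topo_rank(self, name: str) -> str:
        # stable tie-break: declared variable order
        idx = next(i for i, v in enumerate(self.variables) if v.name == name)
        return f"{idx:04d}"

    def equation_filters(self, endog: str) -> tuple[str, ...]:
        return self.subpopulation_filters.get(endog, ())

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "variables": [
                {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(var).items() if v not in (None, False)}
                for var in self.variables
            ],
            "edges": [{"parent": e.parent, "child": e.child} for e in self.edges],
            "outcome": self.outcome,
            "subpopulations": {k: list(v) for k, v in self.subpopulation_filters.items()},
        }
        if self.mediated_pathways is not None:
            d["mediated_pathways"] = {k: list(v) for k, v in self.mediated_pathways.items()}
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    def config_digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_diagram(diagram: PathDiagram) -> list[str]:
    """Collect every invariant violation; an empty report means valid.

    Violations are data, not exceptions: callers that require validity should
    raise on a non-empty report.
    """
    report: list[str] = []
    names = [v.name for v in diagram.variables]
    for name in set(names):
        if names.count(name) > 1:
            report.append(f"duplicate variable name {name!r}")
    by_name = {v.name: v for v in diagram.variables}

    for v in diagram.variables:
        if v.role not in ROLES:
            report.append(f"{v.name}: role {v.role!r} not in {ROLES}")
        if v.measurement not in MEASUREMENTS:
            report.append(f"{v.name}: measurement {v.measurement!r} not in {MEASUREMENTS}")
        if v.predictor_encoding not in ENCODINGS:
            report.append(f"{v.name}: predictor_encoding {v.predictor_encoding!r} not in {ENCODINGS}")
        if v.role == "endogenous" and v.family is None:
            report.append(f"{v.name}: endogenous variable missing family")
        if v.role == "exogenous" and v.family is not None:
            report.append(f"{v.name}: exogenous variable must not declare a family")
        if v.family is not None and v.family not in FAMILIES:
            report.append(f"{v.name}: family {v.family!r} not in {FAMILIES}")
        if v.levels is not None:
            if v.reference_level != v.levels[0]:
                report.append(
                    f"{v.name}: reference_level {v.reference_level!r} is not the first level"
                )
            if v.measurement == "binary" and len(v.levels) != 2:
                report.append(f"{v.name}: binary variable must have exactly two levels")
        elif v.measurement in ("binary", "categorical"):
            report.append(f"{v.name}: {v.measurement} variable missing levels")

    for e in diagram.edges:
        if e.parent == e.child:
            report.append(f"self-edge {e.parent!r} -> {e.child!r}")
        for end in (e.parent, e.child):
            if end not in by_name:
                report.append(f"edge references unknown variable {end!r}")
        child = by_name.get(e.child)
        if child is not None and child.role != "endogenous":
            report.append(f"edge child {e.child!r} is not endogenous")

    g = diagram.to_networkx()
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        report.append("cycle: " + " -> ".join(a for a, _ in cycle))

    if diagram.outcome not in by_name:
        report.append(f"outcome {diagram.outcome!r} is not a declared variable")
    else:
        out = by_name[diagram.outcome]
        if out.role != "endogenous":
            report.append(f"outcome {diagram.outcome!r} must be endogenous")
        if diagram.children(diagram.outcome):
            report.append(f"outcome {diagram.outcome!r} has outgoing edges")

    for v in diagram.variables:
        if v.role == "endogenous" and not diagram.parents(v.name):
            report.append(f"endogenous variable {v.name!r} has an empty parent set")

    for endog in diagram.subpopulation_filters:
        if endog not in by_name or by_name[endog].role != "endogenous":
            report.append(f"subpopulation filter on non-endogenous variable {endog!r}")

    if diagram.mediated_pathways is not None:
        for exposure, mediators in diagram.mediated_pathways.items():
            if exposure not in by_name:
                report.append(f"mediated pathway for unknown exposure {exposure!r}")
            for m in mediators:
                if m not in by_name or by_name[m].role != "endogenous":
                    report.append(f"mediator {m!r} (exposure {exposure!r}) is not endogenous")
    return report


# ---------------------------------------------------------------------------
# the built-in six-equation diagram
# ---------------------------------------------------------------------------

# The seven background covariates shared by the four maternal-care equations.
_BACKGROUND = (
    "mother_age",
    "education",
    "wealth",
    "living_children",
    "child_death_history",
    "facility_distance",
    "chw_visit",
)

#: Printed order of decomposition rows (maternal-care factors first, then
#: background, child, health-service factors and knowledge).
PAPER_EXPOSURE_ORDER = (
    "anc4",
    "facility_delivery",
    "pnc",
    "mother_age",
    "education",
    "wealth",
    "child_death_history",
    "living_children",
    "newborn_sex",
    "facility_distance",
    "chw_visit",
    "ds_counseling",
    "knowledge",
)


def build_paper_diagram() -> PathDiagram:
    """The six-equation care-seeking diagram with its hypothesized pathways.

    Equation structure follows the fitted system: a predictor is a parent of
    an equation exactly where the model reports an adjusted coefficient for
    it.  Reference categories are the first listed level of each block; for
    distance the reference is "5 km or more", so the coefficient belongs to
    living within 5 km.  Knowledge of neonatal danger signs is dual-coded: a
    0-22 count as a dependent variable (gaussian/identity) and a three-level
    category (0 / 1-4 / 5+) wherever it is a predictor.
    """
    variables = [
        VariableSpec("mother_age", "exogenous", "categorical",
                     levels=("<20", "20-34", "35-49"), reference_level="<20"),
        VariableSpec("education", "exogenous", "categorical",
                     levels=("no_education", "primary_incomplete", "primary_complete",
                             "secondary_incomplete", "secondary_complete_or_higher"),
                     reference_level="no_education"),
        VariableSpec("wealth", "exogenous", "categorical",
                     levels=("lowest", "second", "middle", "fourth", "highest"),
                     reference_level="lowest"),
        VariableSpec("living_children", "exogenous", "categorical",
                     levels=("1", "2-3", "4+"), reference_level="1"),
        VariableSpec("child_death_history", "exogenous", "binary",
                     levels=("no", "yes"), reference_level="no"),
        VariableSpec("newborn_sex", "exogenous", "binary",
                     levels=("female", "male"), reference_level="female"),
        VariableSpec("facility_distance", "exogenous", "binary",
                     levels=("5km_plus", "under_5km"), reference_level="5km_plus"),
        VariableSpec("chw_visit", "exogenous", "binary",
                     levels=("no", "yes"), reference_level="no"),
        VariableSpec("ds_counseling", "exogenous", "binary",
                     levels=("no", "yes"), reference_level="no"),
        VariableSpec("anc4", "endogenous", "binary", family="binomial",
                     levels=("no", "yes"), reference_level="no"),
        VariableSpec("facility_delivery", "endogenous", "binary", family="binomial",
                     levels=("no", "yes"), reference_level="no"),
        VariableSpec("pnc", "endogenous", "binary", family="binomial",
                     levels=("no", "yes"), reference_level="no"),
        VariableSpec("maternal_careseeking", "endogenous", "binary", family="binomial",
                     levels=("no", "yes"), reference_level="no", na_as_reference=True,
                     domain_flag="had_complication"),
        VariableSpec("knowledge", "endogenous", "count", family="gaussian",
                     levels=("0", "1-4", "5+"), reference_level="0",
                     predictor_encoding="as_levels"),
        VariableSpec("neonatal_careseeking", "endogenous", "binary", family="binomial",
                     levels=("no", "yes"), reference_level="no",
                     domain_flag="sick_neonate"),
    ]

    parent_sets: dict[str, tuple[str, ...]] = {
        "anc4": _BACKGROUND,
        "facility_delivery": ("anc4",) + _BACKGROUND,
        "pnc": ("facility_delivery", "anc4") + _BACKGROUND,
        "maternal_careseeking": ("pnc", "facility_delivery", "anc4") + _BACKGROUND,
        # knowledge: no distance, no sex; counseling enters here and in the outcome
        "knowledge": ("pnc", "facility_delivery", "anc4", "mother_age", "education",
                      "wealth", "living_children", "child_death_history", "chw_visit",
                      "ds_counseling"),
        "neonatal_careseeking": ("knowledge", "maternal_careseeking", "pnc",
                                 "facility_delivery", "anc4", "mother_age", "education",
                                 "wealth", "living_children", "child_death_history",
                                 "newborn_sex", "facility_distance", "chw_visit",
                                 "ds_counseling"),
    }
    edges = [EdgeSpec(p, c) for c, parents in parent_sets.items() for p in parents]

    subpops = {name: ("sick_neonate",) for name in parent_sets}
    subpops["maternal_careseeking"] = ("sick_neonate", "had_complication")

    # Hypothesized single-mediator pathways of the conceptual framework, as
    # analyzed.  For mother's age this set is narrower than the full equation
    # adjacency (the framework does not route age through ANC or PNC).
    mediated = {
        "anc4": ("facility_delivery", "pnc", "knowledge"),
        "facility_delivery": ("pnc", "knowledge"),
        "pnc": ("knowledge",),
        "mother_age": ("facility_delivery", "knowledge"),
        "education": ("anc4", "facility_delivery", "pnc", "knowledge"),
        "wealth": ("anc4", "facility_delivery", "pnc"),
        "living_children": ("anc4", "facility_delivery", "pnc", "knowledge"),
        "child_death_history": ("anc4",),
        "newborn_sex": (),
        "facility_distance": ("anc4", "facility_delivery"),
        "chw_visit": ("anc4",),
        "ds_counseling": ("knowledge",),
        "knowledge": (),
        "maternal_careseeking": (),
    }

    return PathDiagram(
        variables=variables,
        edges=edges,
        outcome="neonatal_careseeking",
        subpopulation_filters=subpops,
        mediated_pathways=mediated,
    )


def knowledge_category(count) -> str:
    """Bin a danger-sign knowledge count into its predictor levels."""
    if count <= 0:
        return "0"
    if count <= 4:
        return "1-4"
    return "5+"


# ---------------------------------------------------------------------------
# config loading
# ---------------------------------------------------------------------------

_VARIABLE_KEYS = {"name", "role", "family", "measurement", "levels",
                  "reference_level", "predictor_encoding", "na_as_reference",
                  "domain_flag"}


def load_diagram(config_text: str) -> PathDiagram:
    """Parse a JSON/YAML diagram config, validate it, and return the diagram.

    Raises :class:`DiagramError` naming the offending field on schema
    violations, and with the full violation report on invalid diagrams.
    """
    try:
        raw = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:  # JSON is a YAML subset
        raise DiagramError(f"unparseable config: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise DiagramError("config must be a mapping")
    for key in ("variables", "edges", "outcome"):
        if key not in raw:
            raise DiagramError(f"config missing required field {key!r}")

    variables = []
    for i, entry in enumerate(raw["variables"]):
        if not isinstance(entry, Mapping):
            raise DiagramError(f"variables[{i}] must be a mapping")
        unknown = set(entry) - _VARIABLE_KEYS
        if unknown:
            raise DiagramError(f"variables[{i}]: unknown field(s) {sorted(unknown)}")
        for req in ("name", "role", "measurement"):
            if req not in entry:
                raise DiagramError(f"variables[{i}] missing field {req!r}")
        fam = entry.get("family")
        if fam is not None and fam not in FAMILIES:
            raise DiagramError(
                f"variables[{i}] ({entry['name']}): family {fam!r}; allowed: {FAMILIES}"
            )
        kwargs = dict(entry)
        if "levels" in kwargs and kwargs["levels"] is not None:
            kwargs["levels"] = tuple(str(l) for l in kwargs["levels"])
        if kwargs.get("reference_level") is not None:
            kwargs["reference_level"] = str(kwargs["reference_level"])
        variables.append(VariableSpec(**kwargs))

    edges = []
    for i, entry in enumerate(raw["edges"]):
        if not isinstance(entry, Mapping) or set(entry) != {"parent", "child"}:
            raise DiagramError(f"edges[{i}] must have exactly the fields parent, child")
        edges.append(EdgeSpec(entry["parent"], entry["child"]))

    diagram = PathDiagram(
        variables=variables,
        edges=edges,
        outcome=raw["outcome"],
        subpopulation_filters=dict(raw.get("subpopulations", {})),
        mediated_pathways=(
            {k: tuple(v) for k, v in raw["mediated_pathways"].items()}
            if "mediated_pathways" in raw else None
        ),
    )
    report = validate_diagram(diagram)
    if report:
        raise DiagramError("invalid diagram: " + "; ".join(report))
    return diagram
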