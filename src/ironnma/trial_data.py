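"""Arm-level trial data model, CSV I/O, and evidence-network construction.

The unit of evidence is a randomized trial arm: a treatment node, a count
of non-responders to iron supplementation (the dichotomous "bad" outcome),
and the arm size.  Studies group arms; a Network collects the studies of
one CKD subgroup into a comparison graph whose vertices are treatment
nodes (compound x route x monthly elemental-iron dose band) and whose
edges carry trial and participant counts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .errors import (
    DisconnectedNetworkError,
    DuplicateNodeError,
    EventsExceedTotalError,
    MixedSubgroupError,
    SingleArmStudyError,
    UnknownTreatmentError,
    ValidationError,
)

SUBGROUPS = ("ckd_g3a5", "dialysis")

COMPOUNDS = (
    "iron_sucrose",
    "ferumoxytol",
    "ferric_carboxymaltose",
    "iron_dextran",
    "iron_isomaltoside",
    "iron_gluconate",
    "iron_polymaltose",
    "oral_iron",
    "placebo_no_iron",
)


@dataclass(frozen=True)
class TreatmentNode:
    """A vertex of the evidence network.

    IV nodes are defined by compound and a monthly elemental-iron dose
    band in mg (closed or half-open; ``math.inf`` for an open upper end).
    Oral iron and the no-iron/placebo comparator carry no dose band.
    """

    label: str
    compound: str
    route: str  # "IV" | "PO" | "none"
    dose_band_mg_month: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.compound not in COMPOUNDS:
            raise ValidationError(f"unknown compound {self.compound!r}")
        if self.route not in ("IV", "PO", "none"):
            raise ValidationError(f"unknown route {self.route!r}")
        if self.route == "IV" and self.dose_band_mg_month is None:
            raise ValidationError(f"IV node {self.label!r} requires a dose band")
        if self.route != "IV" and self.dose_band_mg_month is not None:
            raise ValidationError(f"non-IV node {self.label!r} must not carry a dose band")
        if self.dose_band_mg_month is not None:
            lo, hi = self.dose_band_mg_month
            if not (0 <= lo <= hi):
                raise ValidationError(f"invalid dose band for {self.label!r}")


def default_registry() -> dict[str, TreatmentNode]:
    """The shipped treatment-node vocabulary.

    Ten IV dose-band nodes plus oral iron and the distinct no-iron/placebo
    comparator.  The registry is data: pass your own mapping to
    :func:`read_arm_table` to redefine the vocabulary.
    """
    inf = math.inf
    nodes = [
        TreatmentNode("ferumoxytol_1020", "ferumoxytol", "IV", (1020.0, 1020.0)),
        TreatmentNode("fcm_750_1500", "ferric_carboxymaltose", "IV", (750.0, 1500.0)),
        TreatmentNode("fcm_gt1500", "ferric_carboxymaltose", "IV", (1500.0, inf)),
        TreatmentNode("iron_sucrose_ge400", "iron_sucrose", "IV", (400.0, inf)),
        TreatmentNode("iron_sucrose_100_300", "iron_sucrose", "IV", (100.0, 300.0)),
        TreatmentNode("iron_isomaltoside_500", "iron_isomaltoside", "IV", (500.0, 500.0)),
        TreatmentNode("iron_isomaltoside_1000", "iron_isomaltoside", "IV", (1000.0, 1000.0)),
        TreatmentNode("iron_gluconate_1000_1500", "iron_gluconate", "IV", (1000.0, 1500.0)),
        TreatmentNode("iron_polymaltose_500", "iron_polymaltose", "IV", (500.0, 500.0)),
        TreatmentNode("iron_dextran_ge400", "iron_dextran", "IV", (400.0, inf)),
        TreatmentNode("oral_iron", "oral_iron", "PO"),
        TreatmentNode("placebo_no_iron", "placebo_no_iron", "none"),
    ]
    return {n.label: n for n in nodes}


@dataclass(frozen=True)
class StudyArm:
    """One randomized arm: node label, non-responder count, arm size."""

    study_id: str
    node: str
    events: int
    total: int

    def __post_init__(self) -> None:
        if self.total < 1:
            raise ValidationError(f"{self.study_id}/{self.node}: arm size must be >= 1")
        if not 0 <= self.events <= self.total:
            raise EventsExceedTotalError(
                f"{self.study_id}/{self.node}: events {self.events} exceed total {self.total}"
            )


@dataclass(frozen=True)
class Study:
    """A randomized trial: >= 2 arms over distinct nodes, one subgroup.

    The first-listed arm is the study's baseline arm (reference arm b of
    the NMA likelihood); relative-effect posteriors are invariant to this
    convention.
    """

    study_id: str
    subgroup: str
    arms: tuple[StudyArm, ...]

    def __post_init__(self) -> None:
        if self.subgroup not in SUBGROUPS:
            raise ValidationError(
                f"{self.study_id}: unknown subgroup {self.subgroup!r} (expected one of {SUBGROUPS})"
            )
        if len(self.arms) < 2:
            raise SingleArmStudyError(f"{self.study_id}: a study needs >= 2 arms")
        nodes = [a.node for a in self.arms]
        if len(set(nodes)) != len(nodes):
            raise DuplicateNodeError(f"{self.study_id}: duplicate treatment node in arms")
        for a in self.arms:
            if a.study_id != self.study_id:
                raise ValidationError(f"arm study_id {a.study_id!r} != {self.study_id!r}")

    @property
    def baseline(self) -> StudyArm:
        return self.arms[0]


@dataclass
class Network:
    """The comparison graph of one subgroup."""

    subgroup: str
    nodes: dict[str, TreatmentNode]
    studies: list[Study]
    node_participants: dict[str, int] = field(default_factory=dict)
    edges: dict[tuple[str, str], dict] = field(default_factory=dict)

    @property
    def node_labels(self) -> list[str]:
        return sorted(self.nodes)

    def n_studies(self) -> int:
        return len(self.studies)


ARM_COLUMNS = ["study_id", "subgroup", "treatment", "events", "total"]


def read_arm_table(path, registry: dict[str, TreatmentNode] | None = None) -> list[Study]:
    """Read a comma-separated arm table into validated studies.

    The file must carry a header with columns ``study_id, subgroup,
    treatment, events, total``; rows of one study must be contiguous in
    intent but are grouped by study_id in first-appearance order, with
    row order preserved within a study (first row = baseline arm).
    """
    registry = registry if registry is not None else default_registry()
    df = pd.read_csv(path, dtype={"study_id": str, "subgroup": str, "treatment": str})
    missing = [c for c in ARM_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"arm table missing columns: {missing}")
    return _studies_from_frame(df, registry)


def _studies_from_frame(df: pd.DataFrame, registry: dict[str, TreatmentNode]) -> list[Study]:
    studies: list[Study] = []
    for sid, grp in df.groupby("study_id", sort=False):
        subgroups = set(grp["subgroup"])
        if len(subgroups) > 1:
            raise MixedSubgroupError(f"{sid}: mixed subgroups {sorted(subgroups)}")
        arms = []
        for row in grp.itertuples(index=False):
            if row.treatment not in registry:
                raise UnknownTreatmentError(
                    f"{sid}: treatment label {row.treatment!r} not in node registry"
                )
            arms.append(StudyArm(str(sid), row.treatment, int(row.events), int(row.total)))
        studies.append(Study(str(sid), subgroups.pop(), tuple(arms)))
    if not studies:
        raise ValidationError("arm table contains no studies")
    return studies


def write_arm_table(studies: list[Study], path) -> None:
    """Write studies back to the CSV dialect read_arm_table accepts."""
    rows = [
        {
            "study_id": s.study_id,
            "subgroup": s.subgroup,
            "treatment": a.node,
            "events": a.events,
            "total": a.total,
        }
        for s in studies
        for a in s.arms
    ]
    pd.DataFrame(rows, columns=ARM_COLUMNS).to_csv(path, index=False)


def studies_to_json(studies: list[Study]) -> str:
    """Echo of the validated dataset as JSON (arm order preserved)."""
    payload = [
        {
            "study_id": s.study_id,
            "subgroup": s.subgroup,
            "arms": [
                {"treatment": a.node, "events": a.events, "total": a.total} for a in s.arms
            ],
        }
        for s in studies
    ]
    return json.dumps(payload, indent=2)


def build_network(
    studies: list[Study],
    subgroup: str,
    registry: dict[str, TreatmentNode] | None = None,
) -> Network:
    """Restrict to one subgroup and assemble the validated comparison graph.

    Raises :class:`DisconnectedNetworkError` (listing the components) if
    the direct comparisons do not connect all treatment nodes.
    """
    registry = registry if registry is not None else default_registry()
    sub = [s for s in studies if s.subgroup == subgroup]
    if not sub:
        raise ValidationError(f"no studies in subgroup {subgroup!r}")

    g = nx.Graph()
    participants: dict[str, int] = {}
    edges: dict[tuple[str, str], dict] = {}
    for s in sub:
        for a in s.arms:
            g.add_node(a.node)
            participants[a.node] = participants.get(a.node, 0) + a.total
        for i in range(len(s.arms)):
            for j in range(i + 1, len(s.arms)):
                u, v = sorted((s.arms[i].node, s.arms[j].node))
                e = edges.setdefault((u, v), {"n_trials": 0, "n_participants": 0})
                e["n_trials"] += 1
                e["n_participants"] += s.arms[i].total + s.arms[j].total
                g.add_edge(u, v)

    if not nx.is_connected(g):
        raise DisconnectedNetworkError(nx.connected_components(g))

    nodes = {}
    for lbl in g.nodes:
        if lbl not in registry:
            raise UnknownTreatmentError(f"treatment label {lbl!r} not in node registry")
        nodes[lbl] = registry[lbl]
    return Network(subgroup, nodes, sub, participants, edges)


def export_network_summary(network: Network) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables for network-diagram plotting.

    Node size maps to participant totals, edge thickness to trial counts.
    """
    node_rows = [
        {"node": lbl, "participants": network.node_participants[lbl]}
        for lbl in network.node_labels
    ]
    edge_rows = [
        {
            "node_a": u,
            "node_b": v,
            "n_trials": e["n_trials"],
            "n_participants": e["n_participants"],
        }
        for (u, v), e in sorted(network.edges.items())
    ]
    return pd.DataFrame(node_rows), pd.DataFrame(edge_rows)
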