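"""Typed heterogeneous graph container for clinical-trial entities.

The graph holds 18 node types (studies, conditions, drug terms, the
four kinds of result groups, adverse events and organ systems,
baseline/drop/outcome records, statistical methods, standard and
cluster outcomes) and 21 relation types among them.  A declarative
:class:`SchemaSpec` pins the admissible node types, the head/tail type
of every relation, and a cardinality class per relation (for example,
every event group belongs to exactly one study; every adverse event
maps to exactly one organ system).

Nodes carry free-form attribute maps.  Attribute values are stored as
text or numbers; on export a sidecar table declares each attribute's
type so that a round-trip through the tab-separated files reproduces
the graph exactly.
"""

from __future__ import annotations

import csv
import os
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd
import yaml

__all__ = [
    "RelationSpec",
    "SchemaSpec",
    "NodeRecord",
    "EdgeRecord",
    "KnowledgeGraph",
    "Violation",
    "ValidationReport",
    "GraphStatistics",
    "default_schema",
    "validate_graph",
    "graph_statistics",
    "export_graph",
    "load_graph",
    "make_node_id",
]

# cardinality classes: constraint on how many edges of the relation a
# node of the constrained role may/must participate in
EXACTLY_ONE = "exactly_one"
AT_MOST_ONE = "at_most_one"
MANY = "many"


@dataclass(frozen=True)
class RelationSpec:
    """One relation type: name, endpoint types and cardinality class.

    ``constrained`` names the endpoint role ("head" or "tail") whose
    nodes are subject to the cardinality class; with ``exactly_one``
    every node of that endpoint's type must appear in exactly one edge
    of this relation, with ``at_most_one`` in at most one, and with
    ``many`` there is no constraint (``constrained`` is then "").
    """

    name: str
    head: str
    tail: str
    cardinality: str = MANY
    constrained: str = ""


@dataclass
class SchemaSpec:
    node_types: set[str]
    study_specific: dict[str, bool]
    relations: dict[str, RelationSpec]

    def __post_init__(self) -> None:
        for rel in self.relations.values():
            if rel.head not in self.node_types or rel.tail not in self.node_types:
                raise ValueError(
                    f"relation {rel.name!r} references undeclared node type"
                )
            if rel.cardinality not in (EXACTLY_ONE, AT_MOST_ONE, MANY):
                raise ValueError(f"bad cardinality for {rel.name!r}")
            if rel.cardinality != MANY and rel.constrained not in ("head", "tail"):
                raise ValueError(f"constrained role required for {rel.name!r}")

    def to_yaml(self, path) -> None:
        data = {
            "node_types": sorted(self.node_types),
            "study_specific": dict(sorted(self.study_specific.items())),
            "relations": [
                {
                    "name": r.name,
                    "head": r.head,
                    "tail": r.tail,
                    "cardinality": r.cardinality,
                    "constrained": r.constrained,
                }
                for r in self.relations.values()
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SchemaSpec":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(
            node_types=set(data["node_types"]),
            study_specific=dict(data["study_specific"]),
            relations={
                r["name"]: RelationSpec(
                    r["name"], r["head"], r["tail"],
                    r.get("cardinality", MANY), r.get("constrained", ""),
                )
                for r in data["relations"]
            },
        )


_NODE_TYPES: dict[str, bool] = {
    # type name -> is study specific
    "Study": True,
    "Condition": False,
    "DrugTerm": False,
    "EventGroup": True,
    "AdverseEvent": False,
    "Organ": False,
    "BaselineGroup": True,
    "BaselineRecord": True,
    "DropGroup": True,
    "Period": True,
    "DropRecord": True,
    "OutcomeGroup": True,
    "Method": False,
    "OutcomeMeasurement": True,
    "OutcomeAnalysis": True,
    "Outcome": True,
    "StandardOutcome": False,
    "ClusterOutcome": False,
}

_RELATIONS: list[RelationSpec] = [
    RelationSpec("Study-Condition", "Study", "Condition"),
    RelationSpec("Study-EventGroup", "Study", "EventGroup", EXACTLY_ONE, "tail"),
    RelationSpec("Study-BaselineGroup", "Study", "BaselineGroup", EXACTLY_ONE, "tail"),
    RelationSpec("Study-DropGroup", "Study", "DropGroup", EXACTLY_ONE, "tail"),
    RelationSpec("Study-OutcomeGroup", "Study", "OutcomeGroup", EXACTLY_ONE, "tail"),
    RelationSpec("Study-Outcome", "Study", "Outcome", EXACTLY_ONE, "tail"),
    RelationSpec("Study-StudiedDrug", "Study", "DrugTerm"),
    RelationSpec("Study-UsedDrug", "Study", "DrugTerm"),
    RelationSpec("Drug-EventGroup", "DrugTerm", "EventGroup"),
    RelationSpec("EventGroup-AdverseEvent", "EventGroup", "AdverseEvent"),
    RelationSpec("AdverseEvent-Organ", "AdverseEvent", "Organ", EXACTLY_ONE, "head"),
    RelationSpec(
        "BaselineGroup-BaselineRecord", "BaselineGroup", "BaselineRecord",
        EXACTLY_ONE, "tail",
    ),
    RelationSpec("DropGroup-Period", "DropGroup", "Period", EXACTLY_ONE, "tail"),
    RelationSpec("Period-DropRecord", "Period", "DropRecord", EXACTLY_ONE, "tail"),
    RelationSpec(
        "OutcomeGroup-OutcomeMeasurement", "OutcomeGroup", "OutcomeMeasurement",
        AT_MOST_ONE, "tail",
    ),
    RelationSpec("OutcomeGroup-OutcomeAnalysis", "OutcomeGroup", "OutcomeAnalysis"),
    RelationSpec(
        "OutcomeAnalysis-Method", "OutcomeAnalysis", "Method", AT_MOST_ONE, "head",
    ),
    RelationSpec(
        "Outcome-OutcomeAnalysis", "Outcome", "OutcomeAnalysis", AT_MOST_ONE, "tail",
    ),
    RelationSpec(
        "Outcome-OutcomeMeasurement", "Outcome", "OutcomeMeasurement",
        EXACTLY_ONE, "tail",
    ),
    RelationSpec("Outcome-ClusterOutcome", "Outcome", "ClusterOutcome",
                 AT_MOST_ONE, "head"),
    RelationSpec("Outcome-StandardOutcome", "Outcome", "StandardOutcome"),
]

STUDY_ATTR = "nct_id"  # owning-study attribute on study-specific nodes


def default_schema() -> SchemaSpec:
    return SchemaSpec(
        node_types=set(_NODE_TYPES),
        study_specific=dict(_NODE_TYPES),
        relations={r.name: r for r in _RELATIONS},
    )


def make_node_id(node_type: str, local: str) -> str:
    """Globally unique node id: type prefix + local identifier."""
    return f"{node_type.lower()}:{local}"


@dataclass
class NodeRecord:
    node_id: str
    node_type: str
    attributes: dict[str, str | int | float] = field(default_factory=dict)


@dataclass
class EdgeRecord:
    head_id: str
    relation: str
    tail_id: str
    attributes: dict[str, str | int | float] = field(default_factory=dict)


@dataclass(frozen=True)
class Violation:
    kind: str        # "unknown_type" | "missing_study_attr" | "dangling" |
                     # "endpoint_type" | "cardinality" | "unknown_relation"
    message: str
    offending: tuple[str, ...]


ValidationReport = list  # list[Violation]; empty report == valid graph


class KnowledgeGraph:
    """Node/edge container bound to a :class:`SchemaSpec`.

    Construction is permissive; :func:`validate_graph` reports every
    invariant violation instead of raising.
    """

    def __init__(self, schema: SchemaSpec | None = None) -> None:
        self.schema = schema or default_schema()
        self.nodes: dict[str, NodeRecord] = {}
        self.edges: list[EdgeRecord] = []

    def add_node(self, node: NodeRecord) -> NodeRecord:
        existing = self.nodes.get(node.node_id)
        if existing is not None:
            return existing
        self.nodes[node.node_id] = node
        return node

    def add_edge(self, edge: EdgeRecord) -> EdgeRecord:
        self.edges.append(edge)
        return edge

    def nodes_of_type(self, node_type: str) -> list[NodeRecord]:
        return [n for n in self.nodes.values() if n.node_type == node_type]

    def edges_of(self, relation: str) -> list[EdgeRecord]:
        return [e for e in self.edges if e.relation == relation]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        if self.nodes.keys() != other.nodes.keys():
            return False
        for nid, node in self.nodes.items():
            o = other.nodes[nid]
            if node.node_type != o.node_type or node.attributes != o.attributes:
                return False
        key = lambda e: (e.relation, e.head_id, e.tail_id, sorted(e.attributes.items()))
        return sorted(self.edges, key=key) == sorted(other.edges, key=key)


def validate_graph(kg: KnowledgeGraph) -> ValidationReport:
    """Check every schema invariant; return a list of violations.

    Valid graphs yield an empty report.  Checks: declared node types,
    owning-study attribute on study-specific nodes, referential
    integrity of edges, endpoint-type agreement, and per-relation
    cardinality classes.
    """
    report: ValidationReport = []
    schema = kg.schema

    for node in kg.nodes.values():
        if node.node_type not in schema.node_types:
            report.append(Violation(
                "unknown_type",
                f"node {node.node_id!r} has undeclared type {node.node_type!r}",
                (node.node_id,),
            ))
        elif schema.study_specific.get(node.node_type) and node.node_type != "Study":
            if STUDY_ATTR not in node.attributes:
                report.append(Violation(
                    "missing_study_attr",
                    f"study-specific node {node.node_id!r} lacks {STUDY_ATTR!r}",
                    (node.node_id,),
                ))

    # per (relation, constrained node) edge counts
    head_counts: dict[str, Counter] = defaultdict(Counter)
    tail_counts: dict[str, Counter] = defaultdict(Counter)

    for edge in kg.edges:
        rel = schema.relations.get(edge.relation)
        if rel is None:
            report.append(Violation(
                "unknown_relation",
                f"edge uses undeclared relation {edge.relation!r}",
                (edge.head_id, edge.tail_id),
            ))
            continue
        ok = True
        for role, nid in (("head", edge.head_id), ("tail", edge.tail_id)):
            node = kg.nodes.get(nid)
            if node is None:
                report.append(Violation(
                    "dangling",
                    f"{edge.relation} edge references missing {role} {nid!r}",
                    (nid,),
                ))
                ok = False
            else:
                want = rel.head if role == "head" else rel.tail
                if node.node_type != want:
                    report.append(Violation(
                        "endpoint_type",
                        f"{edge.relation} {role} {nid!r} has type "
                        f"{node.node_type!r}, expected {want!r}",
                        (nid,),
                    ))
                    ok = False
        if ok:
            head_counts[edge.relation][edge.head_id] += 1
            tail_counts[edge.relation][edge.tail_id] += 1

    for rel in schema.relations.values():
        if rel.cardinality == MANY:
            continue
        counts = head_counts[rel.name] if rel.constrained == "head" else \
            tail_counts[rel.name]
        ctype = rel.head if rel.constrained == "head" else rel.tail
        for node in kg.nodes.values():
            if node.node_type != ctype:
                continue
            n = counts.get(node.node_id, 0)
            if n > 1 or (n == 0 and rel.cardinality == EXACTLY_ONE):
                report.append(Violation(
                    "cardinality",
                    f"node {node.node_id!r} participates in {n} "
                    f"{rel.name} edges (cardinality {rel.cardinality})",
                    (node.node_id,),
                ))
    return report


@dataclass
class GraphStatistics:
    """Per-type node counts and per-relation head/tail/edge counts."""

    node_counts: pd.DataFrame      # columns: node_type, n_nodes
    relation_counts: pd.DataFrame  # columns: relation, head_type, n_head,
                                   #          tail_type, n_tail, n_edges

    @property
    def total_nodes(self) -> int:
        return int(self.node_counts["n_nodes"].sum())


def graph_statistics(kg: KnowledgeGraph) -> GraphStatistics:
    type_counts = Counter(n.node_type for n in kg.nodes.values())
    node_rows = [
        {"node_type": t, "n_nodes": type_counts.get(t, 0)}
        for t in sorted(kg.schema.node_types)
    ]
    heads: dict[str, set] = defaultdict(set)
    tails: dict[str, set] = defaultdict(set)
    n_edges: Counter = Counter()
    for e in kg.edges:
        heads[e.relation].add(e.head_id)
        tails[e.relation].add(e.tail_id)
        n_edges[e.relation] += 1
    rel_rows = [
        {
            "relation": r.name,
            "head_type": r.head,
            "n_head": len(heads[r.name]),
            "tail_type": r.tail,
            "n_tail": len(tails[r.name]),
            "n_edges": n_edges[r.name],
        }
        for r in kg.schema.relations.values()
    ]
    return GraphStatistics(pd.DataFrame(node_rows), pd.DataFrame(rel_rows))


# ---------------------------------------------------------------------------
# export / load

_SCHEMA_FILE = "schema.yaml"
_NODE_TYPES_FILE = "_node_attribute_types.tsv"
_EDGE_TYPES_FILE = "_edge_attribute_types.tsv"


def _declared_kind(values) -> str:
    kinds = {("int" if isinstance(v, int) and not isinstance(v, bool)
              else "float" if isinstance(v, float) else "text") for v in values}
    if kinds == {"int"}:
        return "int"
    if kinds <= {"int", "float"}:
        return "float"
    return "text"


def _coerce(text: str, kind: str):
    if kind == "int":
        return int(text)
    if kind == "float":
        return float(text)
    return text


def export_graph(kg: KnowledgeGraph, out_dir) -> None:
    """Write one attribute table per node type and one triple table per
    relation type (tab-separated, UTF-8, one header row), plus attribute
    type sidecars and the schema, so the export is self-describing and
    round-trips exactly."""
    os.makedirs(out_dir, exist_ok=True)
    kg.schema.to_yaml(os.path.join(out_dir, _SCHEMA_FILE))

    node_kind_rows = []
    for node_type in sorted(kg.schema.node_types):
        nodes = sorted(kg.nodes_of_type(node_type), key=lambda n: n.node_id)
        attr_names = sorted({a for n in nodes for a in n.attributes})
        for a in attr_names:
            vals = [n.attributes[a] for n in nodes if a in n.attributes]
            node_kind_rows.append(
                {"node_type": node_type, "attribute": a,
                 "kind": _declared_kind(vals)})
        path = os.path.join(out_dir, f"nodes_{node_type}.tsv")
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", quoting=csv.QUOTE_MINIMAL)
            w.writerow(["node_id", *attr_names])
            for n in nodes:
                w.writerow([n.node_id] +
                           [_fmt(n.attributes.get(a)) for a in attr_names])

    edge_kind_rows = []
    for rel in kg.schema.relations.values():
        edges = sorted(
            kg.edges_of(rel.name),
            key=lambda e: (e.head_id, e.tail_id, sorted(e.attributes.items())),
        )
        attr_names = sorted({a for e in edges for a in e.attributes})
        for a in attr_names:
            vals = [e.attributes[a] for e in edges if a in e.attributes]
            edge_kind_rows.append(
                {"relation": rel.name, "attribute": a,
                 "kind": _declared_kind(vals)})
        path = os.path.join(out_dir, f"edges_{rel.name}.tsv")
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", quoting=csv.QUOTE_MINIMAL)
            w.writerow(["head_id", "relation", "tail_id", *attr_names])
            for e in edges:
                w.writerow([e.head_id, e.relation, e.tail_id] +
                           [_fmt(e.attributes.get(a)) for a in attr_names])

    pd.DataFrame(node_kind_rows,
                 columns=["node_type", "attribute", "kind"]).to_csv(
        os.path.join(out_dir, _NODE_TYPES_FILE), sep="\t", index=False)
    pd.DataFrame(edge_kind_rows,
                 columns=["relation", "attribute", "kind"]).to_csv(
        os.path.join(out_dir, _EDGE_TYPES_FILE), sep="\t", index=False)


_MISSING = ""


def _fmt(value) -> str:
    if value is None:
        return _MISSING
    if isinstance(value, float):
        return repr(value)  # round-trips exactly
    return str(value)


def load_graph(in_dir) -> KnowledgeGraph:
    """Load a graph previously written by :func:`export_graph`."""
    schema = SchemaSpec.from_yaml(os.path.join(in_dir, _SCHEMA_FILE))
    kg = KnowledgeGraph(schema)

    nkinds: dict[tuple[str, str], str] = {}
    tpath = os.path.join(in_dir, _NODE_TYPES_FILE)
    if os.path.exists(tpath):
        df = pd.read_csv(tpath, sep="\t", dtype=str)
        nkinds = {(r.node_type, r.attribute): r.kind for r in df.itertuples()}
    ekinds: dict[tuple[str, str], str] = {}
    tpath = os.path.join(in_dir, _EDGE_TYPES_FILE)
    if os.path.exists(tpath):
        df = pd.read_csv(tpath, sep="\t", dtype=str)
        ekinds = {(r.relation, r.attribute): r.kind for r in df.itertuples()}

    for node_type in sorted(schema.node_types):
        path = os.path.join(in_dir, f"nodes_{node_type}.tsv")
        if not os.path.exists(path):
            continue
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            for row in reader:
                attrs = {}
                for name, text in zip(header[1:], row[1:]):
                    if text != _MISSING:
                        attrs[name] = _coerce(
                            text, nkinds.get((node_type, name), "text"))
                kg.add_node(NodeRecord(row[0], node_type, attrs))

    for rel in schema.relations.values():
        path = os.path.join(in_dir, f"edges_{rel.name}.tsv")
        if not os.path.exists(path):
            continue
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            for row in reader:
                attrs = {}
                for name, text in zip(header[3:], row[3:]):
                    if text != _MISSING:
                        attrs[name] = _coerce(
                            text, ekinds.get((rel.name, name), "text"))
                kg.add_edge(EdgeRecord(row[0], row[1], row[2], attrs))
    return kg
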