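"""Study filtering and knowledge-graph assembly from trial tables.

The input is a set of AACT-style relational tables (tab-separated
text).  Studies enter the graph only if they have drug interventions,
outcome analyses, and conditions — applied as a fixed three-stage
cascade with per-stage exclusion counts.  Assembly then builds all 18
node types and 21 relation types: shared condition and drug-term
nodes, study-local group/record/outcome nodes, normalized adverse
events with organ assignments, canonicalized statistical methods,
mined standard outcomes, and outcome-title clusters.
"""

from __future__ import annotations

import logging
import os
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from . import ae_norm, drug_norm, method_norm, outcomes as outcomes_mod
from .ae_norm import TermHierarchy
from .datamodel import (
    EdgeRecord,
    KnowledgeGraph,
    NodeRecord,
    SchemaSpec,
    default_schema,
    make_node_id,
)
from .drug_norm import ARM_GROUP_TYPES, DrugLexicon, DrugMention
from .textnorm import PhrasePatternList

logger = logging.getLogger(__name__)

__all__ = [
    "TrialTables",
    "FilterOutcome",
    "AssembleConfig",
    "load_tables",
    "filter_studies",
    "assemble",
]

_TABLE_COLUMNS = {
    "studies": ["nct_id", "brief_title", "phase", "enrollment", "overall_status"],
    "interventions": ["nct_id", "intervention_type", "name"],
    "conditions": ["nct_id", "name"],
    "result_groups": ["nct_id", "group_id", "result_type", "group_type",
                      "title", "description"],
    "reported_events": ["nct_id", "group_id", "ae_term", "organ_system",
                        "subjects_affected", "subjects_at_risk"],
    "baseline_measurements": ["nct_id", "group_id", "title", "category",
                              "param_value"],
    "milestones": ["nct_id", "group_id", "period", "milestone", "count",
                   "period_order"],
    "drop_withdrawals": ["nct_id", "group_id", "period", "reason", "count"],
    "outcomes": ["outcome_id", "nct_id", "title", "description"],
    "outcome_measurements": ["measurement_id", "nct_id", "outcome_id",
                             "group_id", "param_value", "dispersion"],
    "outcome_analyses": ["analysis_id", "nct_id", "outcome_id", "group_ids",
                         "method", "p_value"],
}

# result_type values mapping result groups onto group node types
_GROUP_NODE_TYPE = {
    "Reported Event": "EventGroup",
    "Baseline": "BaselineGroup",
    "Participant Flow": "DropGroup",
    "Outcome": "OutcomeGroup",
}


@dataclass
class TrialTables:
    """The relational tables the pipeline consumes (pandas frames)."""

    studies: pd.DataFrame
    interventions: pd.DataFrame
    conditions: pd.DataFrame
    result_groups: pd.DataFrame
    reported_events: pd.DataFrame
    baseline_measurements: pd.DataFrame
    milestones: pd.DataFrame
    drop_withdrawals: pd.DataFrame
    outcomes: pd.DataFrame
    outcome_measurements: pd.DataFrame
    outcome_analyses: pd.DataFrame

    def check_referential_integrity(self) -> list[str]:
        """Every nct_id referenced by a child table must exist in
        studies; returns human-readable problem descriptions."""
        known = set(self.studies["nct_id"])
        problems = []
        for name in _TABLE_COLUMNS:
            if name == "studies":
                continue
            df = getattr(self, name)
            missing = sorted(set(df["nct_id"]) - known)
            if missing:
                problems.append(f"{name}: unknown nct_id values {missing[:5]}")
        return problems

    def write(self, out_dir) -> None:
        os.makedirs(out_dir, exist_ok=True)
        for name in _TABLE_COLUMNS:
            getattr(self, name).to_csv(
                os.path.join(out_dir, f"{name}.tsv"), sep="\t", index=False)


def load_tables(in_dir) -> TrialTables:
    """Read the table directory written by :meth:`TrialTables.write`."""
    frames = {}
    for name, cols in _TABLE_COLUMNS.items():
        path = os.path.join(in_dir, f"{name}.tsv")
        if os.path.exists(path):
            df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        else:
            df = pd.DataFrame(columns=cols)
        frames[name] = df
    return TrialTables(**frames)


@dataclass
class FilterOutcome:
    """Result of the staged study filter.

    Stage order is fixed: studies without a drug intervention are
    dropped first, then (among the rest) studies without outcome
    analyses, then studies without conditions.  kept + the three
    exclusion counts always sum to the input study count.
    """

    kept_ids: list[str]
    excluded_no_drug: list[str]
    excluded_no_analysis: list[str]
    excluded_no_condition: list[str]

    @property
    def n_kept(self) -> int:
        return len(self.kept_ids)

    @property
    def exclusions(self) -> tuple[int, int, int]:
        return (len(self.excluded_no_drug), len(self.excluded_no_analysis),
                len(self.excluded_no_condition))


def filter_studies(t: TrialTables) -> FilterOutcome:
    all_ids = set(t.studies["nct_id"])
    drug_rows = t.interventions[
        t.interventions["intervention_type"].str.strip().str.lower() == "drug"]
    has_drug = set(drug_rows["nct_id"])
    has_analysis = set(t.outcome_analyses["nct_id"])
    has_condition = set(t.conditions["nct_id"])

    no_drug = all_ids - has_drug
    rest = all_ids - no_drug
    no_analysis = rest - has_analysis
    rest -= no_analysis
    no_condition = rest - has_condition
    kept = rest - no_condition
    return FilterOutcome(
        kept_ids=sorted(kept),
        excluded_no_drug=sorted(no_drug),
        excluded_no_analysis=sorted(no_analysis),
        excluded_no_condition=sorted(no_condition),
    )


@dataclass
class AssembleConfig:
    """Knobs for graph assembly.

    ``n_clusters`` defaults to min(200, number of outcome titles); the
    override maps reproduce curation passes (raw -> forced canonical).
    """

    schema: SchemaSpec = field(default_factory=default_schema)
    phrase_patterns: PhrasePatternList | None = None
    keywords: tuple[str, ...] = outcomes_mod.DEFAULT_KEYWORDS
    manual_standard_outcomes: tuple[str, ...] = ()
    standard_variant_overrides: dict[str, str] = field(default_factory=dict)
    ae_overrides: dict[str, str] = field(default_factory=dict)
    drug_overrides: dict[str, str] = field(default_factory=dict)
    method_overrides: dict[str, str] = field(default_factory=dict)
    n_clusters: int | None = None
    seed: int = 0


def _restrict(df: pd.DataFrame, kept: set[str]) -> pd.DataFrame:
    return df[df["nct_id"].isin(kept)].reset_index(drop=True)


def _set_attr(attrs: dict, key: str, value) -> None:
    if value is None:
        return
    text = str(value).strip()
    if text and text.lower() != "nan":
        attrs[key] = text


def assemble(
    t: TrialTables,
    hier: TermHierarchy,
    lex: DrugLexicon,
    cfg: AssembleConfig | None = None,
) -> KnowledgeGraph:
    """Filter studies and build the full knowledge graph.

    Rows that reference entities missing from their parent tables are
    skipped with a logged warning.  The returned graph passes
    :func:`trialkg.datamodel.validate_graph` on well-formed inputs.
    """
    cfg = cfg or AssembleConfig()
    kg = KnowledgeGraph(cfg.schema)

    kept = set(filter_studies(t).kept_ids)
    studies = _restrict(t.studies, kept)
    conditions = _restrict(t.conditions, kept)
    groups = _restrict(t.result_groups, kept)
    events = _restrict(t.reported_events, kept)
    baselines = _restrict(t.baseline_measurements, kept)
    milestones = _restrict(t.milestones, kept)
    drops = _restrict(t.drop_withdrawals, kept)
    outcome_rows = _restrict(t.outcomes, kept)
    measurements = _restrict(t.outcome_measurements, kept)
    analyses = _restrict(t.outcome_analyses, kept)

    # --- studies -----------------------------------------------------------
    for row in studies.sort_values("nct_id").itertuples(index=False):
        attrs: dict = {"nct_id": str(row.nct_id)}
        _set_attr(attrs, "brief_title", row.brief_title)
        _set_attr(attrs, "phase", row.phase)
        _set_attr(attrs, "enrollment", row.enrollment)
        _set_attr(attrs, "overall_status", row.overall_status)
        kg.add_node(NodeRecord(make_node_id("Study", str(row.nct_id)),
                               "Study", attrs))

    # --- conditions (shared, case-insensitive identity) --------------------
    seen_cond_edges = set()
    for row in conditions.sort_values(["name", "nct_id"]).itertuples(index=False):
        name = str(row.name).strip()
        if not name:
            continue
        cid = make_node_id("Condition", name.casefold())
        kg.add_node(NodeRecord(cid, "Condition", {"name": name}))
        ekey = (str(row.nct_id), cid)
        if ekey not in seen_cond_edges:
            seen_cond_edges.add(ekey)
            kg.add_edge(EdgeRecord(make_node_id("Study", str(row.nct_id)),
                                   "Study-Condition", cid))

    # --- result groups -> four group node types ----------------------------
    arm_groups: set[tuple[str, str]] = set()
    event_groups: set[tuple[str, str]] = set()
    for row in groups.sort_values(["nct_id", "group_id"]).itertuples(index=False):
        node_type = _GROUP_NODE_TYPE.get(str(row.result_type).strip())
        if node_type is None:
            logger.warning("skipping result group with unknown result_type %r",
                           row.result_type)
            continue
        nct, gid = str(row.nct_id), str(row.group_id)
        nid = make_node_id(node_type, f"{nct}:{gid}")
        attrs = {"nct_id": nct, "group_id": gid}
        _set_attr(attrs, "title", row.title)
        _set_attr(attrs, "description", row.description)
        kg.add_node(NodeRecord(nid, node_type, attrs))
        kg.add_edge(EdgeRecord(make_node_id("Study", nct),
                               f"Study-{node_type}", nid))
        if str(getattr(row, "group_type", "")).strip().lower() in ARM_GROUP_TYPES:
            arm_groups.add((nct, gid))
        if node_type == "EventGroup":
            event_groups.add((nct, gid))

    # --- adverse events ----------------------------------------------------
    known_event_groups = {make_node_id("EventGroup", f"{n}:{g}")
                          for n, g in event_groups}
    ev = events[events.apply(
        lambda r: make_node_id(
            "EventGroup", f"{r['nct_id']}:{r['group_id']}") in known_event_groups,
        axis=1)] if len(events) else events
    if len(ev) < len(events):
        logger.warning("skipped %d reported-event rows with unknown groups",
                       len(events) - len(ev))
    ae_nodes, eg_ae_edges, ae_organ_edges = ae_norm.build_adverse_event_nodes(
        ev, hier, cfg.phrase_patterns, cfg.ae_overrides)
    for n in ae_nodes:
        kg.add_node(n)
    for e in eg_ae_edges:
        kg.add_edge(e)
    for e in ae_organ_edges:
        organ_local = e.tail_id.split(":", 1)[1]
        kg.add_node(NodeRecord(e.tail_id, "Organ", {"name": organ_local}))
        kg.add_edge(e)

    # --- drug mentions -----------------------------------------------------
    mentions: list[DrugMention] = []
    extra = sorted(cfg.drug_overrides)
    drug_interventions = t.interventions[
        (t.interventions["intervention_type"].str.strip().str.lower() == "drug")
        & t.interventions["nct_id"].isin(kept)]
    for row in drug_interventions.sort_values(["nct_id", "name"]).itertuples(
            index=False):
        for surface, _, _ in drug_norm.tag_mentions(str(row.name), lex, extra):
            canonical = drug_norm.normalize_mention(surface, lex,
                                                    cfg.drug_overrides)
            mentions.append(DrugMention(str(row.nct_id), "intervention", None,
                                        surface, canonical))
    for row in groups.sort_values(["nct_id", "group_id"]).itertuples(index=False):
        nct, gid = str(row.nct_id), str(row.group_id)
        for source, text in (("group_title", str(row.title or "")),
                             ("group_description", str(row.description or ""))):
            for surface, _, _ in drug_norm.tag_mentions(text, lex, extra):
                canonical = drug_norm.normalize_mention(surface, lex,
                                                        cfg.drug_overrides)
                mentions.append(DrugMention(nct, source, gid, surface,
                                            canonical))
    drug_nodes, studied_e, used_e, drug_eg_e = drug_norm.assign_drug_edges(
        mentions, arm_groups, event_groups)
    for n in drug_nodes:
        kg.add_node(n)
    for e in (*studied_e, *used_e, *drug_eg_e):
        kg.add_edge(e)

    # --- baseline records --------------------------------------------------
    for i, row in enumerate(
            baselines.sort_values(["nct_id", "group_id"],
                                  kind="stable").itertuples(index=False)):
        nct, gid = str(row.nct_id), str(row.group_id)
        group_node = make_node_id("BaselineGroup", f"{nct}:{gid}")
        if group_node not in kg.nodes:
            logger.warning("skipping baseline row for unknown group %s", gid)
            continue
        nid = make_node_id("BaselineRecord", f"{nct}:{gid}:{i}")
        attrs = {"nct_id": nct}
        _set_attr(attrs, "title", row.title)
        _set_attr(attrs, "category", row.category)
        _set_attr(attrs, "param_value", row.param_value)
        kg.add_node(NodeRecord(nid, "BaselineRecord", attrs))
        kg.add_edge(EdgeRecord(group_node, "BaselineGroup-BaselineRecord", nid))

    # --- periods (from milestones) and drop records ------------------------
    period_nodes: dict[tuple[str, str, str], str] = {}
    mil = milestones.sort_values(["nct_id", "group_id"], kind="stable")
    order_key: dict[tuple[str, str, str], int] = {}
    for i, row in enumerate(mil.itertuples(index=False)):
        key = (str(row.nct_id), str(row.group_id), str(row.period))
        try:
            order = int(str(row.period_order))
        except (TypeError, ValueError):
            order = i  # fall back to row order when no order column value
        order_key.setdefault(key, order)
    for key in sorted(order_key, key=lambda k: (k[0], k[1], order_key[k], k[2])):
        nct, gid, period = key
        group_node = make_node_id("DropGroup", f"{nct}:{gid}")
        if group_node not in kg.nodes:
            logger.warning("skipping milestone for unknown flow group %s", gid)
            continue
        nid = make_node_id("Period", f"{nct}:{gid}:{order_key[key]}")
        sub = mil[(mil["nct_id"] == nct) & (mil["group_id"] == gid)
                  & (mil["period"] == period)]
        attrs = {"nct_id": nct, "title": period,
                 "order": str(order_key[key])}
        for mrow in sub.itertuples(index=False):
            label = str(mrow.milestone).strip().lower()
            if label in ("started", "completed"):
                _set_attr(attrs, label, mrow.count)
        kg.add_node(NodeRecord(nid, "Period", attrs))
        kg.add_edge(EdgeRecord(group_node, "DropGroup-Period", nid))
        period_nodes[key] = nid

    for i, row in enumerate(
            drops.sort_values(["nct_id", "group_id"],
                              kind="stable").itertuples(index=False)):
        key = (str(row.nct_id), str(row.group_id), str(row.period))
        pid = period_nodes.get(key)
        if pid is None:
            logger.warning("skipping drop-withdrawal row for unknown period %r",
                           key)
            continue
        nid = make_node_id("DropRecord", f"{key[0]}:{key[1]}:{i}")
        attrs = {"nct_id": key[0]}
        _set_attr(attrs, "reason", row.reason)
        _set_attr(attrs, "count", row.count)
        kg.add_node(NodeRecord(nid, "DropRecord", attrs))
        kg.add_edge(EdgeRecord(pid, "Period-DropRecord", nid))

    # --- outcomes ----------------------------------------------------------
    outcome_node_ids: dict[str, str] = {}
    ordered_outcomes = outcome_rows.sort_values("outcome_id", kind="stable")
    for row in ordered_outcomes.itertuples(index=False):
        nct, oid = str(row.nct_id), str(row.outcome_id)
        nid = make_node_id("Outcome", oid)
        attrs = {"nct_id": nct}
        _set_attr(attrs, "title", row.title)
        _set_attr(attrs, "description", row.description)
        kg.add_node(NodeRecord(nid, "Outcome", attrs))
        kg.add_edge(EdgeRecord(make_node_id("Study", nct), "Study-Outcome", nid))
        outcome_node_ids[oid] = nid

    # --- outcome measurements ---------------------------------------------
    for row in measurements.sort_values("measurement_id",
                                        kind="stable").itertuples(index=False):
        oid = str(row.outcome_id)
        onode = outcome_node_ids.get(oid)
        if onode is None:
            logger.warning("skipping measurement %s: unknown outcome %s",
                           row.measurement_id, oid)
            continue
        nct = str(row.nct_id)
        nid = make_node_id("OutcomeMeasurement", str(row.measurement_id))
        attrs = {"nct_id": nct}
        _set_attr(attrs, "param_value", row.param_value)
        _set_attr(attrs, "dispersion", row.dispersion)
        kg.add_node(NodeRecord(nid, "OutcomeMeasurement", attrs))
        kg.add_edge(EdgeRecord(onode, "Outcome-OutcomeMeasurement", nid))
        gid = str(row.group_id or "").strip()
        if gid:
            gnode = make_node_id("OutcomeGroup", f"{nct}:{gid}")
            if gnode in kg.nodes:
                kg.add_edge(EdgeRecord(gnode, "OutcomeGroup-OutcomeMeasurement",
                                       nid))
            else:
                logger.warning("measurement %s references unknown outcome "
                               "group %s", row.measurement_id, gid)

    # --- outcome analyses + methods ----------------------------------------
    method_counts = Counter(
        str(m).strip() for m in analyses["method"] if str(m).strip())
    method_map = (method_norm.canonicalize_methods(method_counts,
                                                   cfg.method_overrides)
                  if method_counts else {})
    for row in analyses.sort_values("analysis_id",
                                    kind="stable").itertuples(index=False):
        oid = str(row.outcome_id)
        onode = outcome_node_ids.get(oid)
        if onode is None:
            logger.warning("skipping analysis %s: unknown outcome %s",
                           row.analysis_id, oid)
            continue
        nct = str(row.nct_id)
        nid = make_node_id("OutcomeAnalysis", str(row.analysis_id))
        attrs = {"nct_id": nct}
        _set_attr(attrs, "p_value", row.p_value)
        _set_attr(attrs, "method_raw", row.method)
        kg.add_node(NodeRecord(nid, "OutcomeAnalysis", attrs))
        kg.add_edge(EdgeRecord(onode, "Outcome-OutcomeAnalysis", nid))
        for gid in str(row.group_ids or "").split(";"):
            gid = gid.strip()
            if not gid:
                continue
            gnode = make_node_id("OutcomeGroup", f"{nct}:{gid}")
            if gnode in kg.nodes:
                kg.add_edge(EdgeRecord(gnode, "OutcomeGroup-OutcomeAnalysis",
                                       nid))
            else:
                logger.warning("analysis %s references unknown outcome group "
                               "%s", row.analysis_id, gid)
        raw_method = str(row.method).strip()
        if raw_method:
            canonical = method_map[raw_method]
            mnode = make_node_id("Method", canonical.casefold())
            kg.add_node(NodeRecord(mnode, "Method", {"name": canonical}))
            kg.add_edge(EdgeRecord(nid, "OutcomeAnalysis-Method", mnode))

    # --- standard outcomes -------------------------------------------------
    standards = outcomes_mod.build_standard_outcomes(
        ordered_outcomes, cfg.keywords, list(cfg.manual_standard_outcomes),
        cfg.standard_variant_overrides)
    for s in standards:
        kg.add_node(NodeRecord(make_node_id("StandardOutcome", s.casefold()),
                               "StandardOutcome", {"name": s}))
    for oid, s in outcomes_mod.link_standard_outcomes(ordered_outcomes,
                                                      standards):
        onode = outcome_node_ids.get(oid)
        if onode is not None:
            kg.add_edge(EdgeRecord(onode, "Outcome-StandardOutcome",
                                   make_node_id("StandardOutcome",
                                                s.casefold())))

    # --- cluster outcomes --------------------------------------------------
    titles = [str(r.title) for r in ordered_outcomes.itertuples(index=False)]
    oids = [str(r.outcome_id) for r in ordered_outcomes.itertuples(index=False)]
    if titles:
        k = cfg.n_clusters if cfg.n_clusters is not None else min(200,
                                                                  len(titles))
        report = outcomes_mod.cluster_outcomes(titles, k, seed=cfg.seed)
        for summary in report.clusters:
            cid = make_node_id("ClusterOutcome", str(summary.cluster_id))
            kg.add_node(NodeRecord(cid, "ClusterOutcome", {
                "size": summary.size,
                "descriptive": outcomes_mod.format_weighted_words(
                    summary.descriptive),
                "discriminating": outcomes_mod.format_weighted_words(
                    summary.discriminating),
            }))
        for i, oid in enumerate(oids):
            cid = make_node_id("ClusterOutcome", str(report.assignment[i]))
            kg.add_edge(EdgeRecord(outcome_node_ids[oid],
                                   "Outcome-ClusterOutcome", cid))
    return kg
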