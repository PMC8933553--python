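"""Filter cascade arithmetic and full graph assembly on hand-built and
generated tables."""

import pandas as pd
from trialkg.datamodel import graph_statistics, validate_graph
from trialkg.kg_build import (
    AssembleConfig,
    TrialTables,
    assemble,
    filter_studies,
    load_tables,
)


def _tables(**overrides) -> TrialTables:
    base = {
        "studies": pd.DataFrame(columns=["nct_id", "brief_title", "phase",
                                         "enrollment", "overall_status"]),
        "interventions": pd.DataFrame(columns=["nct_id", "intervention_type",
                                               "name"]),
        "conditions": pd.DataFrame(columns=["nct_id", "name"]),
        "result_groups": pd.DataFrame(columns=[
            "nct_id", "group_id", "result_type", "group_type", "title",
            "description"]),
        "reported_events": pd.DataFrame(columns=[
            "nct_id", "group_id", "ae_term", "organ_system",
            "subjects_affected", "subjects_at_risk"]),
        "baseline_measurements": pd.DataFrame(columns=[
            "nct_id", "group_id", "title", "category", "param_value"]),
        "milestones": pd.DataFrame(columns=[
            "nct_id", "group_id", "period", "milestone", "count",
            "period_order"]),
        "drop_withdrawals": pd.DataFrame(columns=[
            "nct_id", "group_id", "period", "reason", "count"]),
        "outcomes": pd.DataFrame(columns=["outcome_id", "nct_id", "title",
                                          "description"]),
        "outcome_measurements": pd.DataFrame(columns=[
            "measurement_id", "nct_id", "outcome_id", "group_id",
            "param_value", "dispersion"]),
        "outcome_analyses": pd.DataFrame(columns=[
            "analysis_id", "nct_id", "outcome_id", "group_ids", "method",
            "p_value"]),
    }
    base.update(overrides)
    return TrialTables(**base)


class TestFilter:
    def test_staged_exclusions_count_in_order(self):
        # 10 studies: 4 lack drug interventions, 2 of the rest lack
        # analyses, 1 of the rest lacks conditions -> 3 kept
        ids = [f"NCT{i}" for i in range(10)]
        has_drug = ids[4:]
        has_analysis = ids[6:]
        has_condition = ids[7:]
        t = _tables(
            studies=pd.DataFrame({"nct_id": ids, "brief_title": "",
                                  "phase": "", "enrollment": "",
                                  "overall_status": ""}),
            interventions=pd.DataFrame(
                {"nct_id": has_drug + ids[:4],
                 "intervention_type": ["Drug"] * 6 + ["Behavioral"] * 4,
                 "name": "x"}),
            outcome_analyses=pd.DataFrame(
                {"analysis_id": [f"A{i}" for i in range(len(has_analysis))],
                 "nct_id": has_analysis, "outcome_id": "", "group_ids": "",
                 "method": "", "p_value": ""}),
            conditions=pd.DataFrame({"nct_id": has_condition, "name": "c"}),
        )
        fo = filter_studies(t)
        assert fo.exclusions == (4, 2, 1)
        assert fo.n_kept == 3
        assert fo.n_kept + sum(fo.exclusions) == 10

    def test_all_complete_studies_kept(self, corpus):
        t = corpus.tables
        kept = set(corpus.truth.kept_study_ids)
        complete = _tables(
            studies=t.studies[t.studies["nct_id"].isin(kept)],
            interventions=t.interventions,
            conditions=t.conditions,
            outcome_analyses=t.outcome_analyses,
        )
        fo = filter_studies(complete)
        assert fo.exclusions == (0, 0, 0)
        assert fo.n_kept == len(kept)

    def test_kept_set_invariant_to_row_order(self, corpus):
        t = corpus.tables
        shuffled = _tables(**{
            name: getattr(t, name).sample(frac=1.0, random_state=5)
            for name in ("studies", "interventions", "conditions",
                         "result_groups", "reported_events",
                         "baseline_measurements", "milestones",
                         "drop_withdrawals", "outcomes",
                         "outcome_measurements", "outcome_analyses")})
        assert filter_studies(shuffled).kept_ids == \
            filter_studies(t).kept_ids

    def test_matches_generator_ground_truth(self, corpus):
        fo = filter_studies(corpus.tables)
        assert fo.kept_ids == corpus.truth.kept_study_ids
        assert fo.excluded_no_drug == corpus.truth.excluded_no_drug
        assert fo.excluded_no_analysis == corpus.truth.excluded_no_analysis
        assert fo.excluded_no_condition == corpus.truth.excluded_no_condition


class TestAssemble:
    def test_minimal_fixture_hand_counts(self, small_hierarchy,
                                         small_lexicon):
        nct = "NCT0001"
        t = _tables(
            studies=pd.DataFrame([{
                "nct_id": nct, "brief_title": "t", "phase": "Phase 2",
                "enrollment": "10", "overall_status": "Completed"}]),
            interventions=pd.DataFrame([{
                "nct_id": nct, "intervention_type": "Drug",
                "name": "Naltrexone 50 Mg Oral Tablet"}]),
            conditions=pd.DataFrame([{"nct_id": nct, "name": "migraine"}]),
            result_groups=pd.DataFrame([
                {"nct_id": nct, "group_id": "E1",
                 "result_type": "Reported Event", "group_type": "Experimental",
                 "title": "Naltrexone", "description": ""},
                {"nct_id": nct, "group_id": "O1", "result_type": "Outcome",
                 "group_type": "Experimental", "title": "Naltrexone",
                 "description": ""},
            ]),
            reported_events=pd.DataFrame([{
                "nct_id": nct, "group_id": "E1", "ae_term": "Nausea",
                "organ_system": "gastrointestinal disorders",
                "subjects_affected": 1, "subjects_at_risk": 10}]),
            outcomes=pd.DataFrame([{
                "outcome_id": "O-1", "nct_id": nct,
                "title": "Pain on the Visual Analogue Scale (VAS)",
                "description": ""}]),
            outcome_measurements=pd.DataFrame([{
                "measurement_id": "M1", "nct_id": nct, "outcome_id": "O-1",
                "group_id": "O1", "param_value": "1.2", "dispersion": "0.3"}]),
            outcome_analyses=pd.DataFrame([{
                "analysis_id": "A1", "nct_id": nct, "outcome_id": "O-1",
                "group_ids": "O1", "method": "paired t test",
                "p_value": "0.01"}]),
        )
        kg = assemble(t, small_hierarchy, small_lexicon,
                      AssembleConfig(n_clusters=1))
        assert validate_graph(kg) == []
        counts = graph_statistics(kg).node_counts.set_index("node_type")[
            "n_nodes"]
        expected = {
            "Study": 1, "Condition": 1, "DrugTerm": 1, "EventGroup": 1,
            "AdverseEvent": 1, "Organ": 1, "Outcome": 1, "OutcomeGroup": 1,
            "OutcomeMeasurement": 1, "OutcomeAnalysis": 1, "Method": 1,
            "StandardOutcome": 1, "ClusterOutcome": 1,
            "BaselineGroup": 0, "BaselineRecord": 0, "DropGroup": 0,
            "Period": 0, "DropRecord": 0,
        }
        for node_type, n in expected.items():
            assert counts[node_type] == n, node_type
        # the single drug is studied, not merely used
        assert len(kg.edges_of("Study-StudiedDrug")) == 1
        assert len(kg.edges_of("Study-UsedDrug")) == 0
        assert len(kg.edges_of("Drug-EventGroup")) == 1

    def test_empty_kept_set_gives_empty_graph(self, small_hierarchy,
                                              small_lexicon):
        t = _tables(studies=pd.DataFrame([{
            "nct_id": "NCT1", "brief_title": "", "phase": "",
            "enrollment": "", "overall_status": ""}]))
        kg = assemble(t, small_hierarchy, small_lexicon)
        assert len(kg.nodes) == 0 and len(kg.edges) == 0

    def test_generated_fixture_assembles_valid_graph(self, assembled_graph):
        assert validate_graph(assembled_graph) == []

    def test_one_to_one_group_relations(self, assembled_graph):
        s = graph_statistics(assembled_graph)
        nodes = s.node_counts.set_index("node_type")["n_nodes"]
        rels = s.relation_counts.set_index("relation")["n_edges"]
        for group_type in ("EventGroup", "BaselineGroup", "DropGroup",
                           "OutcomeGroup"):
            assert rels[f"Study-{group_type}"] == nodes[group_type]

    def test_rows_with_broken_references_skipped_not_fatal(
            self, small_hierarchy, small_lexicon, corpus):
        t = corpus.tables
        broken = _tables(**{n: getattr(t, n) for n in (
            "studies", "interventions", "conditions", "result_groups",
            "reported_events", "baseline_measurements", "milestones",
            "drop_withdrawals", "outcomes", "outcome_analyses")},
            outcome_measurements=pd.concat([
                t.outcome_measurements,
                pd.DataFrame([{"measurement_id": "MX", "nct_id":
                               corpus.truth.kept_study_ids[0],
                               "outcome_id": "GHOST", "group_id": "O1",
                               "param_value": "1", "dispersion": "1"}]),
            ], ignore_index=True))
        kg = assemble(broken, corpus.hierarchy, corpus.lexicon,
                      AssembleConfig(n_clusters=4))
        assert validate_graph(kg) == []
        assert "outcomemeasurement:MX" not in kg.nodes

    def test_tables_round_trip_through_disk(self, tmp_path, corpus):
        corpus.tables.write(tmp_path)
        loaded = load_tables(tmp_path)
        assert loaded.check_referential_integrity() == []
        assert filter_studies(loaded).kept_ids == \
            filter_studies(corpus.tables).kept_ids
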