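"""Outcome mining and clustering: abbreviation extraction invariants,
the instrument-word filter, standard-outcome linking, and
repeated-bisection clustering against a brute-force partition oracle."""

import re
from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.feature_extraction.text import TfidfVectorizer

from trialkg.outcomes import (
    DEFAULT_KEYWORDS,
    build_standard_outcomes,
    cluster_outcomes,
    find_abbreviations,
    format_weighted_words,
    is_standard_candidate,
    link_standard_outcomes,
)
from trialkg.textnorm import load_stopwords


def satisfies_inorder(pair) -> bool:
    """The extraction invariant: abbreviation characters occur in order
    in the definition (case-insensitive), the first at a word start."""
    d = pair.definition.lower()
    pos = -1
    first = True
    for c in pair.abbreviation.lower():
        if not c.isalnum():
            continue
        pos = d.find(c, pos + 1)
        if pos < 0:
            return False
        if first:
            if pos > 0 and d[pos - 1].isalnum():
                return False
            first = False
    return True


class TestFindAbbreviations:
    @pytest.mark.parametrize("text, expected", [
        ("Gingival Health Measured by Bleeding Index (BI)",
         [("BI", "Bleeding Index")]),
        ("changes in blood oxygenation level-dependent (BOLD)",
         [("BOLD", "blood oxygenation level-dependent")]),
        ("no abbreviations here", []),
        ("Visual Analogue Scale (VAS) and Numeric Rating Scale (NRS)",
         [("VAS", "Visual Analogue Scale"), ("NRS", "Numeric Rating Scale")]),
        ("weights in kilograms (25)", []),          # no letter in short form
        ("some dosage (two hundred milligrams)", []),  # too long / 3 words
    ])
    def test_examples(self, text, expected):
        pairs = find_abbreviations(text)
        assert [(p.abbreviation, p.definition) for p in pairs] == expected

    def test_definition_precedes_abbreviation(self):
        for p in find_abbreviations(
                "Modified Gingival Index (MGI) and Plaque Index (PI)"):
            assert p.def_span[1] <= p.abbr_span[0]

    def test_all_outputs_satisfy_inorder_invariant(self):
        texts = [
            "Hamilton Depression Rating Scale (HDRS) score",
            "Area Under the Curve (AUC) exposure",
            "Forced Expiratory Volume (FEV) at week 4",
            "quality of life (QoL) questionnaire",
        ]
        for t in texts:
            for p in find_abbreviations(t):
                assert satisfies_inorder(p)


class TestKeywordFilter:
    @pytest.mark.parametrize("definition, expected", [
        ("Visual Analogue Scale", True),
        ("Bleeding Index", True),
        ("Body Mass", False),
        ("blood oxygenation level-dependent", True),  # hyphen-split "level"
        ("Heart Rate Variability", True),
        ("Scales of measurement", False),             # "scales" != "scale"
    ])
    def test_examples(self, definition, expected):
        assert is_standard_candidate(definition) is expected

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(
        list(DEFAULT_KEYWORDS) + ["body", "mass", "change", "weekly"]),
        min_size=1, max_size=6))
    def test_matches_regex_oracle(self, words):
        text = " ".join(words)
        oracle = any(
            re.search(rf"(?<![a-z0-9]){re.escape(k)}(?![a-z0-9])", text)
            for k in DEFAULT_KEYWORDS)
        assert is_standard_candidate(text) is oracle


def _outcome_df(rows):
    return pd.DataFrame(rows, columns=["outcome_id", "title", "description"])


class TestStandardOutcomes:
    def test_mined_from_titles(self):
        df = _outcome_df([
            ("o1", "Gingival Health Measured by Bleeding Index (BI)", ""),
            ("o2", "Pain on the Visual Analogue Scale (VAS)", ""),
        ])
        assert build_standard_outcomes(df) == ["Bleeding Index",
                                               "Visual Analogue Scale"]

    def test_manual_addition_present_without_abbreviation(self):
        df = _outcome_df([("o1", "Overall Survival at 5 Years", "")])
        stds = build_standard_outcomes(df,
                                       manual_additions=["Overall Survival"])
        assert stds == ["Overall Survival"]

    def test_empty_inputs_give_empty_set(self):
        assert build_standard_outcomes(_outcome_df([])) == []

    def test_variant_override_folds_spellings(self):
        df = _outcome_df([
            ("o1", "Score on Visual Analog Scale (VAS)", ""),
            ("o2", "Score on Visual Analogue Scale (VAS)", ""),
        ])
        stds = build_standard_outcomes(
            df, variant_overrides={"visual analog scale":
                                   "Visual Analogue Scale"})
        assert stds == ["Visual Analogue Scale"]

    def test_non_candidate_definitions_dropped(self):
        df = _outcome_df([("o1", "change in body mass (BM)", "")])
        assert build_standard_outcomes(df) == []


class TestLinkStandardOutcomes:
    def test_title_with_two_standards_links_twice(self):
        df = _outcome_df([("o1", "Change From Baseline in Platelet Count "
                                 "and White Blood Cell Count", "")])
        links = link_standard_outcomes(
            df, ["Platelet Count", "White Blood Cell Count"])
        assert sorted(links) == [("o1", "Platelet Count"),
                                 ("o1", "White Blood Cell Count")]

    def test_no_substring_no_link(self):
        df = _outcome_df([("o1", "Overall wellbeing", "")])
        assert link_standard_outcomes(df, ["Platelet Count"]) == []

    def test_description_only_match_links(self):
        df = _outcome_df([("o1", "Primary endpoint",
                           "Measured via Platelet Count at week 4")])
        assert link_standard_outcomes(df, ["Platelet Count"]) == \
            [("o1", "Platelet Count")]


TOPIC_A = ["Change From Baseline in Waist Circumference",
           "Mean Waist Circumference at Week 12",
           "Percent Change in Waist Circumference"]
TOPIC_B = ["Change in Systolic Blood Pressure",
           "Mean Diastolic Blood Pressure at Week 8",
           "Ambulatory Blood Pressure Monitoring"]


def brute_force_best_two_partition(titles):
    """Oracle: exhaustive best 2-partition under the summed
    composite-vector-norm criterion on the same TF-IDF representation."""
    vec = TfidfVectorizer(lowercase=True, token_pattern=r"[a-z0-9]+",
                          stop_words=sorted(load_stopwords()), norm="l2",
                          smooth_idf=True)
    x = vec.fit_transform(titles).toarray()
    n = len(titles)
    best, best_crit = None, -1.0
    for bits in product([0, 1], repeat=n - 1):
        assign = (0,) + bits
        a = [i for i in range(n) if assign[i] == 0]
        b = [i for i in range(n) if assign[i] == 1]
        if not a or not b:
            continue
        crit = (np.linalg.norm(x[a].sum(axis=0)) +
                np.linalg.norm(x[b].sum(axis=0)))
        if crit > best_crit:
            best_crit = crit
            best = frozenset({frozenset(a), frozenset(b)})
    return best


class TestClustering:
    def test_recovers_planted_two_topic_corpus_exactly(self):
        titles = TOPIC_A + TOPIC_B
        report = cluster_outcomes(titles, 2, seed=0)
        groups = {}
        for i, c in report.assignment.items():
            groups.setdefault(c, set()).add(i)
        assert set(map(frozenset, groups.values())) == \
            {frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    def test_matches_brute_force_best_partition(self):
        titles = TOPIC_A + TOPIC_B
        report = cluster_outcomes(titles, 2, seed=0)
        groups: dict[int, set] = {}
        for i, c in report.assignment.items():
            groups.setdefault(c, set()).add(i)
        ours = frozenset(map(frozenset, groups.values()))
        assert ours == brute_force_best_two_partition(titles)

    def test_k_equals_one_single_cluster(self):
        report = cluster_outcomes(TOPIC_A, 1, seed=0)
        assert report.clusters[0].size == 3
        assert set(report.assignment.values()) == {0}

    def test_k_larger_than_titles_rejected(self):
        with pytest.raises(ValueError):
            cluster_outcomes(TOPIC_A, 4, seed=0)
        with pytest.raises(ValueError):
            cluster_outcomes(TOPIC_A, 0, seed=0)

    def test_assignment_is_partition_and_sizes_sum(self):
        titles = TOPIC_A + TOPIC_B
        report = cluster_outcomes(titles, 3, seed=1)
        assert sorted(report.assignment) == list(range(len(titles)))
        assert sum(c.size for c in report.clusters) == len(titles)

    def test_percentages_sorted_and_bounded(self):
        report = cluster_outcomes(TOPIC_A + TOPIC_B, 2, seed=0)
        for c in report.clusters:
            for pairs in (c.descriptive, c.discriminating):
                pcts = [p for _, p in pairs]
                assert all(0.0 <= p <= 100.0 for p in pcts)
                assert pcts == sorted(pcts, reverse=True)
                assert len(pairs) <= 5

    def test_seeded_reproducibility(self):
        titles = TOPIC_A + TOPIC_B
        a = cluster_outcomes(titles, 2, seed=42)
        b = cluster_outcomes(titles, 2, seed=42)
        assert a.assignment == b.assignment
        assert [c.descriptive for c in a.clusters] == \
            [c.descriptive for c in b.clusters]

    def test_report_format(self):
        report = cluster_outcomes(TOPIC_A + TOPIC_B, 2, seed=0)
        text = format_weighted_words(report.clusters[0].descriptive)
        assert re.fullmatch(r"([a-z0-9]+ \d+\.\d%)(, [a-z0-9]+ \d+\.\d%)*",
                            text)
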