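"""Seeded generator of trial tables, stand-in dictionaries and ground truth.

Emulates the inputs the pipeline consumes without any downloads: an
AACT-style set of relational tables, an open stand-in for the leveled
adverse-event dictionary (levels 1 and 2 only, since only the
level-1 -> level-2 roll-up is in scope), a drug lexicon with brand /
generic / abbreviation variants and tree codes, and method-name
variants.  Every planted variant is checked at generation time to be
recoverable by the corresponding normalizer (parentheticals and listed
auxiliary phrases only, misspellings within edit distance 3), unless it
is explicitly planted as unmatchable.  Study completeness flags drive
the filter cascade deterministically, and two designated conditions
share drug neighborhoods so that embedding-based similarity and
repurposing retrieval have planted structure to recover.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import os
import string
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ae_norm import TermHierarchy
from .drug_norm import DrugLexicon, LexiconEntry
from .kg_build import TrialTables
from .textnorm import (
    edit_distance,
    remove_phrases,
    simplify_tokens,
    strip_parenthetical,
)

__all__ = ["FixtureConfig", "GroundTruth", "SyntheticFixture", "generate",
           "write_fixture"]

# ---------------------------------------------------------------------------
# invented vocabularies (open stand-ins for licensed dictionaries)

_ORGANS = [
    "gastrointestinal disorders",
    "nervous system disorders",
    "cardiac disorders",
    "skin and subcutaneous tissue disorders",
    "respiratory disorders",
    "renal and urinary disorders",
    "vascular disorders",
    "eye disorders",
]

# level-2 terms with their organ system and optional level-1 children
_AE_VOCAB: list[tuple[str, str, list[str]]] = [
    ("nausea", "gastrointestinal disorders", ["nausea aggravated"]),
    ("abdominal pain", "gastrointestinal disorders",
     ["stomach ache", "abdominal discomfort"]),
    ("constipation", "gastrointestinal disorders", []),
    ("cholecystitis", "gastrointestinal disorders", []),
    ("headache", "nervous system disorders", ["cephalalgia"]),
    ("dizziness", "nervous system disorders", ["vertigo feeling"]),
    ("somnolence", "nervous system disorders", ["excessive drowsiness"]),
    ("tremor", "nervous system disorders", []),
    ("palpitations", "cardiac disorders", ["heart pounding"]),
    ("tachycardia", "cardiac disorders", ["rapid heart beat"]),
    ("bradycardia", "cardiac disorders", []),
    ("rash", "skin and subcutaneous tissue disorders", ["skin eruption"]),
    ("pruritus", "skin and subcutaneous tissue disorders",
     ["generalized itch"]),
    ("alopecia", "skin and subcutaneous tissue disorders", []),
    ("dyspnoea", "respiratory disorders", ["breathing difficulty"]),
    ("cough", "respiratory disorders", ["productive cough"]),
    ("throat tightness", "respiratory disorders", []),
    ("renal impairment", "renal and urinary disorders", []),
    ("dysuria", "renal and urinary disorders", ["painful urination"]),
    ("hypertension", "vascular disorders", ["blood pressure elevation"]),
    ("hypotension", "vascular disorders", []),
    ("flushing", "vascular disorders", ["hot flush"]),
    ("itchy eyes", "eye disorders", ["eye itching", "ocular itching"]),
    ("blurred vision", "eye disorders", ["vision blurring"]),
]

# (generic, brand, abbreviation, canonical term, tree code)
_DRUG_VOCAB: list[tuple[str, str | None, str | None, str, str]] = [
    ("losartan potassium", "cozaar", None, "losartan", "D02.092.471.683.152"),
    ("naltrexone hydrochloride", "revia", None, "naltrexone",
     "D02.705.400.562"),
    ("ibuprofen", "advil", None, "ibuprofen", "D02.241.223.701.430"),
    ("telaprevir", "incivek", "tvr", "telaprevir", "D02.886.645.700"),
    ("tramadol hydrochloride", "ultram", None, "tramadol", "D02.241.223.601"),
    ("diclofenac sodium", "voltaren", None, "diclofenac",
     "D02.241.223.100.380"),
    ("metformin hydrochloride", "glucophage", None, "metformin",
     "D02.078.370.141"),
    ("sertraline hydrochloride", "zoloft", "srt", "sertraline",
     "D02.455.426.392.368"),
    ("umeclidinium bromide", "incruse", "umec", "umeclidinium",
     "D02.675.276.410"),
    ("zelaprine maleate", "zelcor", "zlp", "zelaprine", "D02.455.526.728"),
    ("varostat", "varonex", None, "varostat", "D02.886.030.150"),
    ("quentapib", "quentra", "qtp", "quentapib", "D02.455.326.271"),
    ("dorivex citrate", "doriva", None, "dorivex", "D02.145.074.722"),
    ("melargine", "melarga", None, "melargine", "D02.092.211.111"),
    ("pf-06669571", None, None, "pf-06669571", ""),
]

# lexicon entries whose tree code places them outside the specific-drug
# classes; the tagger must never report these
_NON_DRUG_ENTRIES = [
    ("fixed dose combination", "D26.310", "drug combinations"),
    ("oral tablet", "D26.255.260", "tablets"),
    ("serum biomarker", "D23.101.140", "biomarkers"),
    ("saline solution", "C03.752.100", "sodium chloride"),
]

_CONDITIONS = [
    "type 2 diabetes mellitus", "essential hypertension",
    "chronic obstructive pulmonary disease", "persistent asthma",
    "chronic migraine", "major depressive disorder", "osteoarthritis",
    "rheumatoid arthritis", "chronic hepatitis c", "atrial fibrillation",
    "chronic kidney disease", "psoriasis", "epilepsy", "glaucoma",
    "irritable bowel syndrome",
]

# statistical method bases with in-reach name variants; bases are
# pairwise far apart (squashed edit distance > 3, distinct token sets)
_METHOD_VOCAB: list[tuple[str, list[str]]] = [
    ("paired t test", ["paired t-test", "paired t-tests", "paited t-test",
                       "t-test, paired"]),
    ("analysis of covariance", ["analysis of co-variance",
                                "covariance, analysis of"]),
    ("wilcoxon signed rank", ["wilcoxon signed-rank", "wilcoxon signed ranks"]),
    ("fisher exact", ["fisher's exact", "exact, fisher"]),
    ("log rank", ["log-rank", "logrank"]),
    ("chi squared", ["chi-squared", "chi square"]),
    ("mixed model repeated measures", ["mixed models repeated measures",
                                       "repeated measures, mixed model"]),
    ("kruskal wallis", ["kruskal-wallis", "kruskall wallis"]),
]

# outcome topics: separated vocabularies; some templates define a
# standard measure inline via an "(ABBR)" pattern
_OUTCOME_TOPICS: list[tuple[str, list[str]]] = [
    ("waist circumference", [
        "Change From Baseline in Waist Circumference",
        "Mean Waist Circumference at Week {w}",
        "Percent Change in Waist Circumference",
        "Waist Circumference Reduction at Week {w}",
    ]),
    ("blood pressure", [
        "Change From Baseline in Systolic Blood Pressure",
        "Mean Diastolic Blood Pressure at Week {w}",
        "Ambulatory Blood Pressure Monitoring at Week {w}",
        "Change in Seated Blood Pressure",
    ]),
    ("pain scale", [
        "Pain Intensity Measured by Visual Analogue Scale (VAS)",
        "Change From Baseline in Visual Analogue Scale (VAS) Score",
        "Worst Daily Pain on the Numeric Rating Scale (NRS)",
        "Pain Relief Assessed by Visual Analogue Scale (VAS)",
    ]),
    ("blood counts", [
        "Change From Baseline in Platelet Count and White Blood Cell Count",
        "Absolute Neutrophil Count at Week {w}",
        "Mean Platelet Count During Treatment",
        "White Blood Cell Count Change From Baseline",
    ]),
    ("gingival health", [
        "Gingival Health Measured by Bleeding Index (BI)",
        "Change From Baseline in Modified Gingival Index (MGI)",
        "Plaque Index (PI) at Week {w}",
        "Bleeding Index Improvement at Week {w}",
    ]),
    ("depression severity", [
        "Change From Baseline in Hamilton Depression Rating Scale (HDRS)",
        "Remission Assessed by Hamilton Depression Rating Scale (HDRS)",
        "Montgomery Asberg Depression Rating Scale (MADRS) at Week {w}",
        "Depression Response Rate at Week {w}",
    ]),
]

_AUX_PHRASES = ["Baseline Phase", "Treatment Phase", "for 12 hours",
                "for 2 weeks", "at 24 hours"]
_PARENTHETICALS = ["mild", "moderate", "severe", "investigator assessed",
                   "pitch seemed lower", "self reported"]
_DROP_REASONS = ["Adverse Event", "Lost to Follow-up",
                 "Withdrawal by Subject", "Protocol Violation", "Death"]


@dataclass
class FixtureConfig:
    """Knobs of the generator; defaults define the standard test corpus.

    Counts are absolute; rates are probabilities in [0, 1] of applying
    the corresponding variant transformation to a planted term.
    """

    n_studies: int = 60
    n_missing_drug: int = 20        # excluded at filter stage 1
    n_missing_analysis: int = 10    # excluded at filter stage 2
    n_missing_condition: int = 3    # excluded at filter stage 3
    n_conditions: int = 12
    n_drugs: int = 14
    n_ae_terms: int = 24            # level-2 vocabulary size
    n_outcome_topics: int = 4
    outcomes_per_study: int = 2
    events_per_group: int = 3
    parenthetical_rate: float = 0.15
    aux_phrase_rate: float = 0.15
    simplify_rate: float = 0.10     # stop-word/plural variants
    misspelling_rate: float = 0.15
    drug_variant_rate: float = 0.5  # brand/abbreviation instead of generic
    unmatchable_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_studies, self.n_conditions, self.n_drugs,
                  self.n_ae_terms, self.n_outcome_topics,
                  self.outcomes_per_study, self.events_per_group)
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        rates = (self.parenthetical_rate, self.aux_phrase_rate,
                 self.simplify_rate, self.misspelling_rate,
                 self.drug_variant_rate, self.unmatchable_rate)
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("rates must lie in [0, 1]")
        excluded = (self.n_missing_drug + self.n_missing_analysis +
                    self.n_missing_condition)
        if excluded >= self.n_studies:
            raise ValueError("exclusion roles exceed the study count")
        if self.n_outcome_topics > len(_OUTCOME_TOPICS):
            raise ValueError(
                f"at most {len(_OUTCOME_TOPICS)} outcome topics available")
        if not 3 <= self.n_conditions <= len(_CONDITIONS):
            raise ValueError(
                f"n_conditions must be in [3, {len(_CONDITIONS)}]")
        if not 6 <= self.n_drugs <= len(_DRUG_VOCAB):
            raise ValueError(f"n_drugs must be in [6, {len(_DRUG_VOCAB)}]")
        if self.n_ae_terms > len(_AE_VOCAB):
            raise ValueError(f"at most {len(_AE_VOCAB)} AE terms available")


@dataclass
class GroundTruth:
    """What the generator planted, for verification by tests."""

    ae_variant_to_canonical: dict[str, str] = field(default_factory=dict)
    unmatchable_ae_terms: dict[str, str] = field(default_factory=dict)
    drug_surface_to_canonical: dict[str, str] = field(default_factory=dict)
    method_variant_to_base: dict[str, str] = field(default_factory=dict)
    outcome_topic: dict[str, str] = field(default_factory=dict)
    kept_study_ids: list[str] = field(default_factory=list)
    excluded_no_drug: list[str] = field(default_factory=list)
    excluded_no_analysis: list[str] = field(default_factory=list)
    excluded_no_condition: list[str] = field(default_factory=list)
    studied_pairs: list[tuple[str, str]] = field(default_factory=list)
    used_pairs: list[tuple[str, str]] = field(default_factory=list)
    similar_condition_pair: tuple[str, str] | None = None
    repurposing_pair: tuple[str, str] | None = None


@dataclass
class SyntheticFixture:
    tables: TrialTables
    hierarchy: TermHierarchy
    lexicon: DrugLexicon
    truth: GroundTruth
    config: FixtureConfig


# ---------------------------------------------------------------------------


def _build_hierarchy(n_terms: int) -> tuple[TermHierarchy, list[tuple]]:
    vocab = _AE_VOCAB[:n_terms]
    entries: dict[str, tuple[int, str | None]] = {}
    flat: list[tuple[str, str, str]] = []  # (term, level2 ancestor, organ)
    for term, organ, children in vocab:
        entries[term] = (2, None)
        flat.append((term, term, organ))
        for child in children:
            entries[child] = (1, term)
            flat.append((child, term, organ))
    return TermHierarchy(entries), flat


def _build_lexicon(n_drugs: int) -> DrugLexicon:
    entries = []
    abbrevs = {}
    for generic, brand, abbrev, canonical, code in _DRUG_VOCAB[:n_drugs]:
        has_mesh = bool(code)
        entries.append(LexiconEntry(generic, code or None,
                                    canonical if has_mesh else None,
                                    generic.split()[0]))
        if brand:
            entries.append(LexiconEntry(brand, code or None,
                                        canonical if has_mesh else None,
                                        generic.split()[0]))
        if abbrev:
            abbrevs[abbrev] = generic
        # the bare canonical term is itself a common surface form
        if has_mesh and canonical not in (generic, brand):
            entries.append(LexiconEntry(canonical, code, canonical, None))
    for surface, code, canonical in _NON_DRUG_ENTRIES:
        entries.append(LexiconEntry(surface, code, canonical, None))
    return DrugLexicon(entries, abbrevs)


def _misspell(term: str, rng: np.random.Generator, max_edits: int = 3) -> str:
    """Apply 1..max_edits random letter-level edits (never touching
    spaces, never inserting separators)."""
    letters = string.ascii_lowercase
    n_edits = int(rng.integers(1, max_edits + 1))
    chars = list(term)
    for _ in range(n_edits):
        positions = [i for i, c in enumerate(chars) if c != " "]
        op = rng.choice(["sub", "ins", "del"])
        if op == "del" and len(positions) > 3:
            del chars[int(rng.choice(positions))]
        elif op == "ins":
            i = int(rng.choice(positions))
            chars.insert(i, str(rng.choice(list(letters))))
        else:
            i = int(rng.choice(positions))
            old = chars[i]
            new = str(rng.choice([c for c in letters if c != old]))
            chars[i] = new
    return "".join(chars)


def _nearest_dict_term(term: str, hier: TermHierarchy,
                       limit: int = 3) -> str | None:
    fold = term.casefold()
    best = None
    for cand in hier.terms():
        cf = cand.casefold()
        if abs(len(cf) - len(fold)) > limit:
            continue
        d = edit_distance(fold, cf)
        if d <= limit and (best is None or (d, cand) < best):
            best = (d, cand)
    return best[1] if best else None


def _pluralize(tok: str) -> str | None:
    if tok.endswith(("s", "x", "z", "ch", "sh", "y")):
        return None
    return tok + "s"


def _ae_variant(canonical: str, hier: TermHierarchy, cfg: FixtureConfig,
                rng: np.random.Generator) -> tuple[str, bool]:
    """A surface variant of a dictionary term, guaranteed recoverable by
    the cascade; returns (variant, is_unmatchable)."""
    r = float(rng.random())
    if r < cfg.unmatchable_rate:
        while True:
            tok = "".join(rng.choice(list(string.ascii_lowercase), size=14))
            term = f"protocol deviation {tok}"
            processed = simplify_tokens(remove_phrases(
                strip_parenthetical(term)))
            if hier.lookup(processed) is None and \
                    _nearest_dict_term(processed, hier) is None:
                return term, True
    r -= cfg.unmatchable_rate

    def stages_ok(variant: str, upto: int) -> bool:
        """The cascade stages before the intended one must not divert
        the variant onto a different dictionary term."""
        forms = [variant, strip_parenthetical(variant)]
        forms.append(remove_phrases(forms[-1]))
        forms.append(simplify_tokens(forms[-1]))
        for f in forms[:upto]:
            hit = hier.lookup(f)
            if hit is not None and hit.casefold() != canonical.casefold():
                return False
        return True

    # pick exactly one branch; a branch whose construction check fails
    # falls back to the exact term (never to another variant kind)
    if r < cfg.parenthetical_rate:
        note = str(rng.choice(_PARENTHETICALS))
        v = f"{canonical} ({note})"
        if strip_parenthetical(v).casefold() == canonical.casefold():
            return v, False
        return canonical, False
    r -= cfg.parenthetical_rate
    if r < cfg.aux_phrase_rate:
        phrase = str(rng.choice(_AUX_PHRASES))
        v = (f"Left {canonical}" if rng.random() < 0.3
             else f"{canonical} - {phrase}")
        if remove_phrases(strip_parenthetical(v)).casefold() == \
                canonical.casefold() and stages_ok(v, 2):
            return v, False
        return canonical, False
    r -= cfg.aux_phrase_rate
    if r < cfg.simplify_rate:
        toks = canonical.split()
        plural = _pluralize(toks[-1])
        if plural is not None:
            v = " ".join(toks[:-1] + [plural])
            chain = simplify_tokens(remove_phrases(strip_parenthetical(v)))
            if chain.casefold() == canonical.casefold() and stages_ok(v, 3):
                return v, False
        return canonical, False
    r -= cfg.simplify_rate
    if r < cfg.misspelling_rate:
        for _ in range(10):
            v = _misspell(canonical, rng)
            chain = [v, strip_parenthetical(v)]
            chain.append(remove_phrases(chain[-1]))
            chain.append(simplify_tokens(chain[-1]))
            ok = all(
                hier.lookup(f) is None or
                hier.lookup(f).casefold() == canonical.casefold()
                for f in chain)
            if ok and _nearest_dict_term(chain[-1], hier) == \
                    hier.lookup(canonical):
                return v, False
    return canonical, False


def _render_drug_surface(drug: tuple, rng: np.random.Generator,
                         cfg: FixtureConfig) -> str:
    generic, brand, abbrev, canonical, code = drug
    options = [generic]
    if rng.random() < cfg.drug_variant_rate:
        options = [o for o in (brand, abbrev) if o] or [generic]
    return str(rng.choice(options))


def _expected_canonical(drug: tuple) -> str:
    generic, brand, abbrev, canonical, code = drug
    if code:
        return canonical
    return canonical  # investigational ids normalize to themselves


def generate(cfg: FixtureConfig | None = None) -> SyntheticFixture:
    """Generate the full fixture; deterministic given ``cfg.seed``."""
    cfg = cfg or FixtureConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    hier, ae_flat = _build_hierarchy(cfg.n_ae_terms)
    lex = _build_lexicon(cfg.n_drugs)
    truth = GroundTruth()

    drugs = _DRUG_VOCAB[:cfg.n_drugs]
    conditions = _CONDITIONS[:cfg.n_conditions]
    topics = _OUTCOME_TOPICS[:cfg.n_outcome_topics]

    # planted embedding structure: conditions[0] and conditions[1] share
    # the drug set `shared`; `target` additionally treats conditions[1]
    # but is never co-studied with conditions[0]
    twin_a, twin_b = conditions[0], conditions[1]
    shared = drugs[0:3]
    target = drugs[3]
    aux_drug = drugs[4]          # rescue medication -> UsedDrug
    general_pool = drugs[5:] or drugs[0:3]
    truth.similar_condition_pair = (twin_a, twin_b)
    truth.repurposing_pair = (twin_a, _expected_canonical(target))

    # assign roles
    ids = [f"NCT{40000000 + i:08d}" for i in range(cfg.n_studies)]
    perm = list(rng.permutation(cfg.n_studies))
    no_drug = {ids[i] for i in perm[:cfg.n_missing_drug]}
    k = cfg.n_missing_drug
    no_analysis = {ids[i] for i in perm[k:k + cfg.n_missing_analysis]}
    k += cfg.n_missing_analysis
    no_condition = {ids[i] for i in perm[k:k + cfg.n_missing_condition]}
    kept = [s for s in ids
            if s not in no_drug | no_analysis | no_condition]
    truth.kept_study_ids = sorted(kept)
    truth.excluded_no_drug = sorted(no_drug)
    truth.excluded_no_analysis = sorted(no_analysis)
    truth.excluded_no_condition = sorted(no_condition)

    # twin studies among the kept set: first six kept studies alternate
    n_twin = min(6, len(kept) - 2 if len(kept) > 4 else len(kept))
    twin_assign: dict[str, str] = {}
    for i, s in enumerate(kept[:n_twin]):
        twin_assign[s] = "A" if i % 2 == 0 else "B"

    studies_rows, interventions_rows, conditions_rows = [], [], []
    groups_rows, events_rows, baseline_rows = [], [], []
    milestone_rows, drop_rows = [], []
    outcome_rows, measurement_rows, analysis_rows = [], [], []

    phases = ["Phase 1", "Phase 2", "Phase 3", "Phase 4"]
    method_bases = _METHOD_VOCAB
    for base, variants in method_bases:
        truth.method_variant_to_base[base] = base
        for v in variants:
            truth.method_variant_to_base[v] = base
    method_usage: list[str] = []

    measurement_seq = analysis_seq = 0

    for nct in ids:
        studies_rows.append({
            "nct_id": nct,
            "brief_title": f"A Study of Intervention Safety ({nct})",
            "phase": str(rng.choice(phases)),
            "enrollment": int(rng.integers(20, 200)),
            "overall_status": "Completed",
        })

        # --- interventions & study drugs ---
        if nct in no_drug:
            interventions_rows.append({
                "nct_id": nct, "intervention_type": "Behavioral",
                "name": "Supervised exercise program"})
            study_drugs: list[tuple] = []
        else:
            role = twin_assign.get(nct)
            if role == "A":
                study_drugs = list(shared[:2 + int(rng.integers(0, 2))])
            elif role == "B":
                study_drugs = list(shared[:2]) + [target]
            else:
                n_d = 1 + int(rng.integers(0, 2))
                picks = rng.choice(len(general_pool), size=min(
                    n_d, len(general_pool)), replace=False)
                study_drugs = [general_pool[int(i)] for i in picks]
            for d in study_drugs:
                surface = _render_drug_surface(d, rng, cfg)
                dose = int(rng.integers(1, 20)) * 25
                name = (f"{surface} {dose} Mg Oral Tablet"
                        if rng.random() < 0.7 else surface)
                interventions_rows.append({
                    "nct_id": nct, "intervention_type": "Drug", "name": name})
                truth.drug_surface_to_canonical[surface.casefold()] = \
                    _expected_canonical(d)

        # --- conditions ---
        if nct not in no_condition:
            role = twin_assign.get(nct)
            if role == "A":
                conds = [twin_a]
            elif role == "B":
                conds = [twin_b]
            else:
                n_c = 1 + int(rng.integers(0, 3))
                picks = rng.choice(len(conditions) - 2, size=min(
                    n_c, len(conditions) - 2), replace=False)
                conds = [conditions[2 + int(i)] for i in picks]
            for c in conds:
                conditions_rows.append({"nct_id": nct, "name": c})

        has_results = nct not in no_drug and nct not in no_analysis
        if not has_results:
            continue

        # --- result groups (two arms per result type) ---
        arm_titles = []
        for arm_idx in (1, 2):
            if arm_idx == 1 and study_drugs:
                d = study_drugs[0]
                surface = _render_drug_surface(d, rng, cfg)
                truth.drug_surface_to_canonical[surface.casefold()] = \
                    _expected_canonical(d)
                title = f"{surface} {int(rng.integers(1, 20)) * 25} mg"
                desc = f"Participants received {surface} once daily."
                gtype = "Experimental"
            else:
                title = "Placebo"
                desc = "Participants received matching placebo."
                gtype = "Placebo Comparator"
                if rng.random() < 0.3:
                    aux_surface = aux_drug[0]
                    desc += (f" {aux_surface} was allowed as rescue pain"
                             " reducer as needed.")
                    truth.drug_surface_to_canonical[aux_surface.casefold()] = \
                        _expected_canonical(aux_drug)
                    if not any(aux_drug is d for d in study_drugs):
                        truth.used_pairs.append(
                            (nct, _expected_canonical(aux_drug)))
            arm_titles.append((title, desc, gtype))

        for prefix, result_type in (("E", "Reported Event"), ("B", "Baseline"),
                                    ("P", "Participant Flow"),
                                    ("O", "Outcome")):
            for arm_idx, (title, desc, gtype) in enumerate(arm_titles, 1):
                groups_rows.append({
                    "nct_id": nct, "group_id": f"{prefix}{arm_idx}",
                    "result_type": result_type, "group_type": gtype,
                    "title": title,
                    "description": desc if prefix in ("E", "O") else "",
                })
        for d in study_drugs:
            truth.studied_pairs.append((nct, _expected_canonical(d)))

        # --- reported events ---
        for gid in ("E1", "E2"):
            picks = rng.choice(len(ae_flat), size=min(cfg.events_per_group,
                                                      len(ae_flat)),
                               replace=False)
            for i in picks:
                term, level2, organ = ae_flat[int(i)]
                variant, unmatchable = _ae_variant(term, hier, cfg, rng)
                at_risk = int(rng.integers(20, 120))
                events_rows.append({
                    "nct_id": nct, "group_id": gid, "ae_term": variant,
                    "organ_system": organ,
                    "subjects_affected": int(rng.integers(0, at_risk)),
                    "subjects_at_risk": at_risk,
                })
                if unmatchable:
                    processed = simplify_tokens(remove_phrases(
                        strip_parenthetical(variant)))
                    truth.unmatchable_ae_terms[variant] = processed
                else:
                    truth.ae_variant_to_canonical[variant] = level2

        # --- baselines ---
        for gid in ("B1", "B2"):
            baseline_rows.append({
                "nct_id": nct, "group_id": gid, "title": "Age",
                "category": "", "param_value": round(
                    float(rng.uniform(35, 70)), 1)})
            n_f = int(rng.integers(5, 60))
            baseline_rows.append({
                "nct_id": nct, "group_id": gid, "title": "Sex",
                "category": "Female", "param_value": n_f})
            baseline_rows.append({
                "nct_id": nct, "group_id": gid, "title": "Sex",
                "category": "Male", "param_value": int(rng.integers(5, 60))})

        # --- participant flow: periods and withdrawals ---
        periods = (["Overall Study"] if rng.random() < 0.5
                   else ["Treatment Period 1", "Treatment Period 2"])
        for gid in ("P1", "P2"):
            for order, period in enumerate(periods):
                started = int(rng.integers(20, 120))
                milestone_rows.append({
                    "nct_id": nct, "group_id": gid, "period": period,
                    "milestone": "STARTED", "count": started,
                    "period_order": order})
                milestone_rows.append({
                    "nct_id": nct, "group_id": gid, "period": period,
                    "milestone": "COMPLETED",
                    "count": max(0, started - int(rng.integers(0, 15))),
                    "period_order": order})
                n_r = int(rng.integers(1, 4))
                reason_picks = rng.choice(len(_DROP_REASONS), size=n_r,
                                          replace=False)
                for ri in reason_picks:
                    drop_rows.append({
                        "nct_id": nct, "group_id": gid, "period": period,
                        "reason": _DROP_REASONS[int(ri)],
                        "count": int(rng.integers(0, 8))})

        # --- outcomes, measurements, analyses ---
        for j in range(cfg.outcomes_per_study):
            topic, templates = topics[int(rng.integers(0, len(topics)))]
            title = str(rng.choice(templates)).format(
                w=int(rng.integers(2, 52)))
            oid = f"{nct}-O{j + 1}"
            outcome_rows.append({
                "outcome_id": oid, "nct_id": nct, "title": title,
                "description": f"Assessment of {topic} over the study."})
            truth.outcome_topic[oid] = topic
            for gid in ("O1", "O2"):
                measurement_seq += 1
                measurement_rows.append({
                    "measurement_id": f"M{measurement_seq:06d}",
                    "nct_id": nct, "outcome_id": oid, "group_id": gid,
                    "param_value": round(float(rng.normal(0, 2)), 3),
                    "dispersion": round(float(rng.uniform(0.1, 3.0)), 3)})
            base, variants = method_bases[int(rng.integers(0,
                                                           len(method_bases)))]
            name = (base if rng.random() < 0.6
                    else str(rng.choice(variants)))
            method_usage.append(name)
            analysis_seq += 1
            analysis_rows.append({
                "analysis_id": f"A{analysis_seq:06d}", "nct_id": nct,
                "outcome_id": oid, "group_ids": "O1;O2", "method": name,
                "p_value": round(float(rng.uniform(0.0005, 0.2)), 4)})

    # guarantee each base outranks every one of its variants by count,
    # so the highest-frequency rule elects the base spelling
    usage = pd.Series(method_usage).value_counts().to_dict() \
        if method_usage else {}
    for base, variants in method_bases:
        used_variants = [v for v in variants if v in usage]
        if not used_variants:
            continue
        top_variant = max(usage[v] for v in used_variants)
        if usage.get(base, 0) <= top_variant:
            deficit = top_variant - usage.get(base, 0) + 1
            bumped = 0
            for row in analysis_rows:
                if bumped >= deficit:
                    break
                if row["method"] in used_variants and \
                        usage[row["method"]] > 1:
                    usage[row["method"]] -= 1
                    row["method"] = base
                    usage[base] = usage.get(base, 0) + 1
                    bumped += 1
            while bumped < deficit:
                # no spare variant rows: relabel any of this base's rows
                for row in analysis_rows:
                    if row["method"] in used_variants:
                        usage[row["method"]] -= 1
                        if usage[row["method"]] == 0:
                            truth.method_variant_to_base.pop(row["method"],
                                                             None)
                        row["method"] = base
                        usage[base] = usage.get(base, 0) + 1
                        bumped += 1
                        break
                else:
                    break

    # drop ground-truth entries for variants that no longer occur
    occurring = {row["method"] for row in analysis_rows}
    truth.method_variant_to_base = {
        v: b for v, b in truth.method_variant_to_base.items()
        if v in occurring or v == b}

    tables = TrialTables(
        studies=pd.DataFrame(studies_rows,
                             columns=list(studies_rows[0].keys())),
        interventions=pd.DataFrame(interventions_rows),
        conditions=pd.DataFrame(conditions_rows,
                                columns=["nct_id", "name"]),
        result_groups=pd.DataFrame(groups_rows, columns=[
            "nct_id", "group_id", "result_type", "group_type", "title",
            "description"]),
        reported_events=pd.DataFrame(events_rows, columns=[
            "nct_id", "group_id", "ae_term", "organ_system",
            "subjects_affected", "subjects_at_risk"]),
        baseline_measurements=pd.DataFrame(baseline_rows, columns=[
            "nct_id", "group_id", "title", "category", "param_value"]),
        milestones=pd.DataFrame(milestone_rows, columns=[
            "nct_id", "group_id", "period", "milestone", "count",
            "period_order"]),
        drop_withdrawals=pd.DataFrame(drop_rows, columns=[
            "nct_id", "group_id", "period", "reason", "count"]),
        outcomes=pd.DataFrame(outcome_rows, columns=[
            "outcome_id", "nct_id", "title", "description"]),
        outcome_measurements=pd.DataFrame(measurement_rows, columns=[
            "measurement_id", "nct_id", "outcome_id", "group_id",
            "param_value", "dispersion"]),
        outcome_analyses=pd.DataFrame(analysis_rows, columns=[
            "analysis_id", "nct_id", "outcome_id", "group_ids", "method",
            "p_value"]),
    )
    truth.studied_pairs = sorted(set(truth.studied_pairs))
    truth.used_pairs = sorted(set(truth.used_pairs) -
                              set(truth.studied_pairs))
    return SyntheticFixture(tables, hier, lex, truth, cfg)


def write_fixture(fix: SyntheticFixture, out_dir) -> None:
    """Write tables, dictionaries and ground truth as delimited text."""
    os.makedirs(out_dir, exist_ok=True)
    fix.tables.write(os.path.join(out_dir, "tables"))
    fix.hierarchy.to_file(os.path.join(out_dir, "ae_hierarchy.tsv"))
    fix.lexicon.to_files(os.path.join(out_dir, "drug_lexicon.tsv"),
                         os.path.join(out_dir, "drug_abbreviations.tsv"))
    truth = asdict(fix.truth)
    truth["config"] = asdict(fix.config)
    with open(os.path.join(out_dir, "ground_truth.json"), "w",
              encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, default=list)
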