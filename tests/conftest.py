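"""Shared fixtures: a small hand-built AE hierarchy/lexicon and a
session-scoped generated corpus with its assembled graph."""

import pytest

from trialkg import synthfix
from trialkg.ae_norm import TermHierarchy
from trialkg.drug_norm import DrugLexicon, LexiconEntry
from trialkg.kg_build import AssembleConfig, assemble


@pytest.fixture(scope="session")
def small_hierarchy() -> TermHierarchy:
    return TermHierarchy({
        "Cholecystitis": (2, None),
        "Throat tightness": (2, None),
        "Altered pitch perception": (2, None),
        "Nausea": (2, None),
        "knee pain": (2, None),
        "itchy eyes": (2, None),
        "Eye itching": (1, "itchy eyes"),
        "Ocular itching": (1, "itchy eyes"),
    })


@pytest.fixture(scope="session")
def small_lexicon() -> DrugLexicon:
    entries = [
        LexiconEntry("losartan potassium", "D02.092.471.683.152", "losartan",
                     "losartan"),
        LexiconEntry("cozaar", "D02.092.471.683.152", "losartan", "losartan"),
        LexiconEntry("losartan", "D02.092.471.683.152", "losartan", None),
        LexiconEntry("naltrexone", "D02.705.400.562", "naltrexone", None),
        LexiconEntry("ibuprofen", "D02.241.223.701.430", "ibuprofen", None),
        LexiconEntry("tramadol", "D02.241.223.601", "tramadol", None),
        LexiconEntry("diclofenac", "D02.241.223.100.380", "diclofenac", None),
        LexiconEntry("telaprevir", "D02.886.645.700", "telaprevir", None),
        # non-drug tree-code classes: must never be tagged as drugs
        LexiconEntry("fixed dose combination", "D26.310", "drug combinations",
                     None),
        LexiconEntry("oral tablet", "D26.255.260", "tablets", None),
        LexiconEntry("serum biomarker", "D23.101.140", "biomarkers", None),
        LexiconEntry("saline", "C03.752.100", "sodium chloride", None),
    ]
    return DrugLexicon(entries, {"tvr": "telaprevir"})


@pytest.fixture(scope="session")
def corpus():
    """A generated corpus exercising every variant branch."""
    cfg = synthfix.FixtureConfig(
        seed=11, parenthetical_rate=0.2, aux_phrase_rate=0.2,
        simplify_rate=0.15, misspelling_rate=0.2, unmatchable_rate=0.05)
    return synthfix.generate(cfg)


@pytest.fixture(scope="session")
def assembled_graph(corpus):
    cfg = AssembleConfig(n_clusters=6, seed=11)
    return assemble(corpus.tables, corpus.hierarchy, corpus.lexicon, cfg)
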