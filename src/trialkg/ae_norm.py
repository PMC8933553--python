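"""Adverse-event term normalization and hierarchy roll-up.

Reported adverse-event (AE) terms in trial result tables mix canonical
dictionary terms with study-specific paraphrases: parenthesized
explanations, laterality/phase/time-frame qualifiers, inflected word
forms, and simple misspellings.  The cascade here mirrors how such
terms are mapped onto a leveled AE dictionary (a MedDRA-style
hierarchy): after each successive simplification the term is looked up
case-insensitively, and the first hit wins; as a last resort the term
is mapped to its nearest dictionary entry within edit distance 3.

Matched terms at the most granular level (level 1) are then rolled up
to their level-2 parent, so that synonymous granular terms (e.g. "Eye
itching" and "Ocular itching") collapse onto one adverse-event node.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass

import pandas as pd

from .datamodel import EdgeRecord, NodeRecord, make_node_id
from .textnorm import (
    PhrasePatternList,
    edit_distance,
    remove_phrases,
    simplify_tokens,
    strip_parenthetical,
)

__all__ = [
    "TermHierarchy",
    "AECascadeResult",
    "normalize_ae",
    "rollup_level1",
    "build_adverse_event_nodes",
    "UNKNOWN_ORGAN",
]

UNKNOWN_ORGAN = "unknown organ system"

# cascade stage labels
STAGE_DIRECT = 0
STAGE_PARENTHETICAL = 1
STAGE_PHRASES = 2
STAGE_SIMPLIFY = 3
STAGE_EDIT_RESCUE = 4


class TermHierarchy:
    """Leveled term dictionary: term -> (level 1..5, parent term).

    Lookup is case-insensitive.  Invariants enforced at construction:
    every parent exists in the dictionary, and every level-1 term has a
    parent at level 2.
    """

    def __init__(self, entries: dict[str, tuple[int, str | None]]) -> None:
        self._surface: dict[str, str] = {}          # fold -> canonical surface
        self._level: dict[str, int] = {}            # fold -> level
        self._parent: dict[str, str | None] = {}    # fold -> parent fold
        for term, (level, parent) in entries.items():
            fold = term.strip().casefold()
            if not fold:
                raise ValueError("empty term in hierarchy")
            self._surface[fold] = term.strip()
            self._level[fold] = int(level)
            self._parent[fold] = parent.strip().casefold() if parent else None
        for fold, parent in self._parent.items():
            if parent is not None and parent not in self._surface:
                raise ValueError(
                    f"parent {parent!r} of {self._surface[fold]!r} not in dictionary")
            if self._level[fold] == 1:
                if parent is None or self._level[parent] != 2:
                    raise ValueError(
                        f"level-1 term {self._surface[fold]!r} must have a "
                        "level-2 parent")

    def __len__(self) -> int:
        return len(self._surface)

    def __contains__(self, term: str) -> bool:
        return term.strip().casefold() in self._surface

    def lookup(self, term: str) -> str | None:
        """Canonical surface form for a term, or None if absent."""
        return self._surface.get(term.strip().casefold())

    def level(self, term: str) -> int:
        return self._level[term.strip().casefold()]

    def parent(self, term: str) -> str | None:
        p = self._parent[term.strip().casefold()]
        return self._surface[p] if p is not None else None

    def terms(self) -> list[str]:
        return sorted(self._surface.values())

    @classmethod
    def from_file(cls, path) -> "TermHierarchy":
        """Read a three-column delimited file: term, level, parent."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                         comment="#")
        entries = {}
        for row in df.itertuples(index=False):
            term, level, parent = row[0], row[1], row[2]
            entries[term] = (int(level), parent or None)
        return cls(entries)

    def to_file(self, path) -> None:
        rows = [
            {"term": self._surface[f], "level": self._level[f],
             "parent": self._surface[self._parent[f]] if self._parent[f] else ""}
            for f in sorted(self._surface)
        ]
        pd.DataFrame(rows, columns=["term", "level", "parent"]).to_csv(
            path, sep="\t", index=False)


@dataclass(frozen=True)
class AECascadeResult:
    """Outcome of the cascade for one raw AE term.

    ``stage`` records which simplification produced the dictionary hit
    (0 direct lookup, 1 parenthetical strip, 2 auxiliary-phrase removal,
    3 stop-word/lemma simplification, 4 edit-distance rescue); it is
    None when the term never matched, in which case ``normalized_term``
    is the fully processed input.
    """

    input_term: str
    normalized_term: str
    matched: bool
    stage: int | None


def _nearest_term(term: str, hier: TermHierarchy, limit: int = 3) -> str | None:
    """Nearest dictionary term within ``limit`` edits, exhaustive search
    with a length-difference prefilter; ties broken by (smaller
    distance, lexicographically smallest term)."""
    fold = term.casefold()
    best: tuple[int, str] | None = None
    for cand in hier.terms():
        cf = cand.casefold()
        if abs(len(cf) - len(fold)) > limit:
            continue
        d = edit_distance(fold, cf)
        if d <= limit and (best is None or (d, cand) < best):
            best = (d, cand)
    return best[1] if best else None


def normalize_ae(
    term: str,
    hier: TermHierarchy,
    pats: PhrasePatternList | None = None,
) -> AECascadeResult:
    """Run the normalization cascade for one AE term.

    Stages, each followed by a case-insensitive dictionary lookup that
    stops the cascade on a hit: direct lookup; parenthetical stripping;
    auxiliary-phrase removal; stop-word removal + lemmatization; and
    finally mapping to the nearest dictionary term within edit
    distance 3.
    """
    if not term or not term.strip():
        raise ValueError("empty adverse-event term")
    if len(hier) == 0:
        raise ValueError("empty term dictionary")

    current = term.strip()
    hit = hier.lookup(current)
    if hit is not None:
        return AECascadeResult(term, hit, True, STAGE_DIRECT)

    for stage, transform in (
        (STAGE_PARENTHETICAL, strip_parenthetical),
        (STAGE_PHRASES, lambda t: remove_phrases(t, pats)),
        (STAGE_SIMPLIFY, simplify_tokens),
    ):
        candidate = transform(current)
        if candidate:
            current = candidate
        hit = hier.lookup(current)
        if hit is not None:
            return AECascadeResult(term, hit, True, stage)

    rescue = _nearest_term(current, hier)
    if rescue is not None:
        return AECascadeResult(term, rescue, True, STAGE_EDIT_RESCUE)
    return AECascadeResult(term, current, False, None)


def rollup_level1(term: str, hier: TermHierarchy) -> str:
    """Replace a level-1 dictionary term by its level-2 parent.

    Terms at level 2 or higher are returned unchanged (canonical
    surface form).  Raises KeyError for terms not in the dictionary.
    """
    surface = hier.lookup(term)
    if surface is None:
        raise KeyError(f"{term!r} is not a dictionary term")
    if hier.level(surface) == 1:
        return hier.parent(surface)  # guaranteed level 2 by invariant
    return surface


def build_adverse_event_nodes(
    event_rows: pd.DataFrame,
    hier: TermHierarchy,
    pats: PhrasePatternList | None = None,
    overrides: dict[str, str] | None = None,
):
    """Turn reported-event rows into adverse-event nodes and edges.

    ``event_rows`` columns: nct_id, group_id, ae_term, organ_system,
    subjects_affected, subjects_at_risk.  Returns (nodes, group_edges,
    organ_edges) where nodes are AdverseEvent records (one per distinct
    normalized and rolled-up term), group_edges are
    EventGroup-AdverseEvent edges carrying the per-group counts, and
    organ_edges assign each adverse event to exactly one Organ (the
    majority organ across rows, ties broken lexicographically; missing
    organ values fall back to a designated unknown organ with a
    warning).

    ``overrides`` is a curation map raw term -> forced canonical,
    applied before the cascade.
    """
    overrides = {k.strip().casefold(): v for k, v in (overrides or {}).items()}

    nodes: dict[str, NodeRecord] = {}
    group_edges: dict[tuple[str, str], EdgeRecord] = {}
    organ_votes: dict[str, Counter] = defaultdict(Counter)
    cache: dict[str, tuple[str, bool, str]] = {}

    for row in event_rows.itertuples(index=False):
        raw = str(row.ae_term)
        key = raw.strip().casefold()
        if key not in cache:
            if key in overrides:
                final, matched, stage_label = overrides[key], True, "curated"
            else:
                res = normalize_ae(raw, hier, pats)
                if res.matched:
                    final = rollup_level1(res.normalized_term, hier)
                else:
                    final = res.normalized_term
                matched = res.matched
                stage_label = str(res.stage) if res.stage is not None else "none"
            cache[key] = (final, matched, stage_label)
        final, matched, stage_label = cache[key]

        node_id = make_node_id("AdverseEvent", final.casefold())
        if node_id not in nodes:
            nodes[node_id] = NodeRecord(node_id, "AdverseEvent", {
                "term": final,
                "matched": "true" if matched else "false",
                "stage": stage_label,
            })

        group_node = make_node_id("EventGroup", f"{row.nct_id}:{row.group_id}")
        ekey = (group_node, node_id)
        affected = int(row.subjects_affected)
        at_risk = int(row.subjects_at_risk)
        if ekey in group_edges:
            # same normalized event reported twice for one group
            # (e.g. two granular synonyms): aggregate the counts
            e = group_edges[ekey]
            e.attributes["subjects_affected"] = int(
                e.attributes["subjects_affected"]) + affected
            e.attributes["subjects_at_risk"] = max(
                int(e.attributes["subjects_at_risk"]), at_risk)
        else:
            group_edges[ekey] = EdgeRecord(
                group_node, "EventGroup-AdverseEvent", node_id,
                {"subjects_affected": affected, "subjects_at_risk": at_risk})

        organ = str(getattr(row, "organ_system", "") or "").strip()
        if not organ or organ.lower() == "nan":
            warnings.warn(
                f"missing organ system for AE term {raw!r}; assigning "
                f"{UNKNOWN_ORGAN!r}", stacklevel=2)
            organ = UNKNOWN_ORGAN
        organ_votes[node_id][organ.casefold()] += 1

    organ_edges = []
    for node_id in sorted(nodes):
        votes = organ_votes[node_id]
        # majority vote, lexicographically smallest organ on ties
        best_count = max(votes.values())
        organ = min(o for o, c in votes.items() if c == best_count)
        organ_edges.append(EdgeRecord(
            node_id, "AdverseEvent-Organ", make_node_id("Organ", organ)))

    return list(nodes.values()), list(group_edges.values()), organ_edges
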