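"""Drug-mention tagging, tree-code filtering, and drug-edge assignment.

Drugs surface in trial records under brand names, generic names,
abbreviations and investigational identifiers, inside free text such as
intervention names ("Naltrexone 50 Mg Oral Tablet") or group titles
("tramadol/diclofenac 25/25").  A deterministic lexicon tagger finds
the mentions; a tree-code class filter keeps only surfaces whose
hierarchical code denotes a specific drug (codes under the chemicals-
and-drugs branch, excluding generic preparation/combination/biomarker/
dosage-form classes); and a resolution chain (abbreviation -> canonical
term -> generic name -> the surface itself) collapses variants of one
drug onto a single canonical term.

Per study, canonical terms are split into *studied* drugs (tied to an
intervention record or an arm-defining group) and *used* drugs
(auxiliary mentions such as rescue pain medication); the two edge sets
are disjoint, with "studied" winning on conflict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .datamodel import EdgeRecord, NodeRecord, make_node_id

__all__ = [
    "DrugLexicon",
    "DrugMention",
    "is_drug_code",
    "tag_mentions",
    "normalize_mention",
    "assign_drug_edges",
    "EXCLUDED_CODES",
]

# code classes that do not denote a specific drug: drug combinations,
# pharmaceutical preparations at large, biomarkers, dosage forms
EXCLUDED_CODES = ("D26.310", "D26", "D23.101", "D26.255")


def is_drug_code(code: str, excluded: tuple[str, ...] = EXCLUDED_CODES) -> bool:
    """True iff a dotted tree code denotes a specific drug entity.

    The first segment must start with "D" (the chemicals-and-drugs
    branch) and the code must not equal, nor be a dotted descendant of,
    any excluded class code.
    """
    code = code.strip()
    if not code or not code.split(".", 1)[0].startswith("D"):
        return False
    for ex in excluded:
        if code == ex or code.startswith(ex + "."):
            return False
    return True


@dataclass(frozen=True)
class LexiconEntry:
    surface: str
    tree_code: str | None
    canonical: str | None
    generic: str | None


class DrugLexicon:
    """Surface form -> (tree code, canonical term, generic name) map,
    plus an abbreviation -> full name table.

    Surface forms are unique after case folding.  Surfaces whose tree
    code fails :func:`is_drug_code` are retained in the lexicon but are
    not tagged as drugs.
    """

    def __init__(
        self,
        entries: list[LexiconEntry] | None = None,
        abbreviations: dict[str, str] | None = None,
    ) -> None:
        self._entries: dict[str, LexiconEntry] = {}
        for e in entries or []:
            fold = e.surface.strip().casefold()
            if not fold:
                raise ValueError("empty lexicon surface form")
            if fold in self._entries:
                raise ValueError(f"duplicate lexicon surface {e.surface!r}")
            if not (e.canonical or e.generic):
                raise ValueError(
                    f"lexicon entry {e.surface!r} needs a canonical or generic")
            self._entries[fold] = e
        self.abbreviations = {
            k.strip().casefold(): v.strip()
            for k, v in (abbreviations or {}).items()
        }

    def entry(self, surface: str) -> LexiconEntry | None:
        return self._entries.get(surface.strip().casefold())

    def drug_surfaces(self) -> list[str]:
        """Taggable surfaces: drug-coded entries, uncoded (curated /
        investigational) entries, and known abbreviations; longest first
        for greedy matching."""
        out = {
            f for f, e in self._entries.items()
            if e.tree_code is None or is_drug_code(e.tree_code)
        }
        out.update(self.abbreviations)
        return sorted(out, key=lambda s: (-len(s), s))

    @classmethod
    def from_files(cls, lexicon_path, abbrev_path=None) -> "DrugLexicon":
        """Lexicon: 4-column TSV (surface, tree_code, canonical, generic);
        abbreviations: 2-column TSV (abbreviation, full name)."""
        df = pd.read_csv(lexicon_path, sep="\t", dtype=str,
                         keep_default_na=False, comment="#")
        entries = [
            LexiconEntry(r[0], r[1] or None, r[2] or None, r[3] or None)
            for r in df.itertuples(index=False)
        ]
        abbrevs = {}
        if abbrev_path is not None:
            adf = pd.read_csv(abbrev_path, sep="\t", dtype=str,
                              keep_default_na=False, comment="#")
            abbrevs = {r[0]: r[1] for r in adf.itertuples(index=False)}
        return cls(entries, abbrevs)

    def to_files(self, lexicon_path, abbrev_path=None) -> None:
        rows = [
            {"surface": e.surface, "tree_code": e.tree_code or "",
             "canonical": e.canonical or "", "generic": e.generic or ""}
            for e in sorted(self._entries.values(), key=lambda e: e.surface)
        ]
        pd.DataFrame(rows, columns=["surface", "tree_code", "canonical",
                                    "generic"]).to_csv(
            lexicon_path, sep="\t", index=False)
        if abbrev_path is not None:
            arows = [{"abbreviation": k, "full_name": v}
                     for k, v in sorted(self.abbreviations.items())]
            pd.DataFrame(arows, columns=["abbreviation", "full_name"]).to_csv(
                abbrev_path, sep="\t", index=False)


@dataclass(frozen=True)
class DrugMention:
    """One tagged drug mention with its provenance.

    Intervention-sourced mentions carry no group id; group-sourced
    mentions carry exactly one.
    """

    study_id: str
    source: str  # "intervention" | "group_title" | "group_description"
    group_id: str | None
    surface: str
    canonical: str

    def __post_init__(self) -> None:
        if self.source == "intervention" and self.group_id is not None:
            raise ValueError("intervention mentions must not carry a group id")
        if self.source in ("group_title", "group_description") and \
                self.group_id is None:
            raise ValueError("group-sourced mentions require a group id")


def _is_boundary(text: str, pos: int) -> bool:
    return pos == 0 or pos == len(text) or not (
        text[pos - 1].isalnum() and text[pos].isalnum())


def tag_mentions(
    text: str,
    lex: DrugLexicon,
    extra_surfaces: list[str] | None = None,
) -> list[tuple[str, int, int]]:
    """Find lexicon drug surfaces in free text.

    Case-insensitive, word-boundary, longest-match-first,
    non-overlapping, scanning left to right.  Returns (surface as it
    appears in the text, start, end) triples.  ``extra_surfaces`` adds
    taggable surfaces beyond the lexicon (curation overrides).
    """
    surfaces = lex.drug_surfaces()
    if extra_surfaces:
        pool = set(surfaces) | {s.strip().casefold() for s in extra_surfaces}
        surfaces = sorted(pool, key=lambda s: (-len(s), s))
    if not surfaces:
        return []
    low = text.lower()
    out: list[tuple[str, int, int]] = []
    i, n = 0, len(text)
    while i < n:
        if not _is_boundary(text, i):
            i += 1
            continue
        matched = False
        for s in surfaces:
            end = i + len(s)
            if low.startswith(s, i) and _is_boundary(text, min(end, n)) \
                    and end <= n:
                out.append((text[i:end], i, end))
                i = end
                matched = True
                break
        if not matched:
            i += 1
    return out


def normalize_mention(
    surface: str,
    lex: DrugLexicon,
    overrides: dict[str, str] | None = None,
) -> str:
    """Resolve a tagged surface to its canonical drug term.

    Resolution order: curation override -> abbreviation expansion ->
    lexicon canonical term -> generic name -> the (expanded) surface
    itself.  Investigational identifiers absent from the lexicon thus
    normalize to themselves.
    """
    s = surface.strip()
    fold = s.casefold()
    if overrides and fold in overrides:
        return overrides[fold]
    if fold in lex.abbreviations:
        s = lex.abbreviations[fold]
        fold = s.casefold()
    e = lex.entry(s)
    if e is not None:
        if e.canonical:
            return e.canonical
        if e.generic:
            return e.generic
    return s


# result-group types counted as arm-defining when splitting studied vs
# used drugs; compared case-insensitively
ARM_GROUP_TYPES = frozenset(
    {"experimental", "active comparator", "placebo comparator",
     "sham comparator", "arm"})


def assign_drug_edges(
    mentions: list[DrugMention],
    arm_groups: set[tuple[str, str]] | None = None,
    event_groups: set[tuple[str, str]] | None = None,
):
    """Build DrugTerm nodes and Study/EventGroup drug edges.

    ``arm_groups``/``event_groups`` are sets of (study_id, group_id)
    identifying arm-defining result groups and event groups.  Per
    (study, canonical term): a mention from an intervention record, or
    from the *title* of an arm-defining group (titles name the arm's
    intervention), yields a StudiedDrug edge; terms mentioned only in
    free-text context without an arm tie — group descriptions, or
    groups that do not define an arm — yield a UsedDrug edge.  The two
    sets are disjoint, studied wins.  When ``arm_groups`` is None every
    group is treated as arm-defining.  Mentions sourced from
    event-group text additionally yield Drug-EventGroup edges.

    Returns (nodes, studied_edges, used_edges, drug_event_edges).
    """
    event_groups = event_groups or set()

    nodes: dict[str, NodeRecord] = {}
    studied: set[tuple[str, str]] = set()   # (study, drug node id)
    seen: set[tuple[str, str]] = set()      # any mention
    drug_event: set[tuple[str, str]] = set()

    def node_for(canonical: str) -> str:
        nid = make_node_id("DrugTerm", canonical.casefold())
        if nid not in nodes:
            nodes[nid] = NodeRecord(nid, "DrugTerm", {"term": canonical})
        return nid

    for m in mentions:
        nid = node_for(m.canonical)
        seen.add((m.study_id, nid))
        if m.source == "intervention" or (
                m.source == "group_title" and
                (arm_groups is None or
                 (m.study_id, m.group_id) in arm_groups)):
            studied.add((m.study_id, nid))
        if m.group_id is not None and (m.study_id, m.group_id) in event_groups:
            drug_event.add(
                (nid, make_node_id("EventGroup", f"{m.study_id}:{m.group_id}")))

    used = seen - studied
    mk = lambda pairs, rel: [
        EdgeRecord(make_node_id("Study", s), rel, d)
        for s, d in sorted(pairs)
    ]
    studied_edges = mk(studied, "Study-StudiedDrug")
    used_edges = mk(used, "Study-UsedDrug")
    drug_event_edges = [
        EdgeRecord(d, "Drug-EventGroup", g) for d, g in sorted(drug_event)
    ]
    return (sorted(nodes.values(), key=lambda n: n.node_id),
            studied_edges, used_edges, drug_event_edges)
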