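"""Statistical-analysis method name canonicalization.

Result tables name the same hypothesis test many ways: "paired t test",
"paired t-tests", "paited t-test" (a typo), "t-test, paired" (word
order).  Canonicalization proceeds in three steps: (1) squash each name
(lowercase, strip spaces and punctuation); (2) link squashed forms
within edit distance 3 and take single-linkage connected components,
each component normalizing to its highest-frequency member name;
(3) merge components whose canonical names contain the same words in
any order, again keeping the highest-frequency canonical.  A curation
override file (raw -> forced canonical) is applied last.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from typing import Mapping

import networkx as nx

from .textnorm import edit_distance, squash

__all__ = ["canonicalize_methods", "token_multiset"]

import re

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def token_multiset(name: str) -> tuple[tuple[str, int], ...]:
    """Case-folded token multiset of a raw name, split on whitespace and
    punctuation; hashable for grouping."""
    return tuple(sorted(Counter(_TOKEN_RE.findall(name.lower())).items()))


def canonicalize_methods(
    tbl: Mapping[str, int],
    overrides: Mapping[str, str] | None = None,
    distance_limit: int = 3,
) -> dict[str, str]:
    """Map every raw method name to its canonical name.

    ``tbl`` maps raw name -> occurrence count (>= 1).  The mapping is
    total, deterministic, and invariant under permutation of the input
    order.  Canonical choice within a (merged) component: the member
    raw name with the highest count, ties broken lexicographically.
    """
    if not tbl:
        raise ValueError("empty method name table")
    for name, count in tbl.items():
        if count < 1:
            raise ValueError(f"count for {name!r} must be >= 1")

    # step 1: squash; group raw names sharing a squashed form
    by_squash: dict[str, list[str]] = defaultdict(list)
    for raw in tbl:
        by_squash[squash(raw)].append(raw)

    # step 2: single-linkage components over squashed forms
    forms = sorted(by_squash)
    g = nx.Graph()
    g.add_nodes_from(forms)
    for i, a in enumerate(forms):
        for b in forms[i + 1:]:
            if abs(len(a) - len(b)) > distance_limit:
                continue
            if edit_distance(a, b) <= distance_limit:
                g.add_edge(a, b)

    def pick_canonical(raws: list[str]) -> str:
        return min(raws, key=lambda r: (-tbl[r], r))

    components: list[list[str]] = []   # raw-name members per component
    for comp in nx.connected_components(g):
        raws = sorted(r for f in comp for r in by_squash[f])
        components.append(raws)

    # step 3: merge components whose canonicals share a token multiset
    by_tokens: dict[tuple, list[list[str]]] = defaultdict(list)
    for raws in components:
        by_tokens[token_multiset(pick_canonical(raws))].append(raws)

    mapping: dict[str, str] = {}
    for groups in by_tokens.values():
        merged = sorted(r for raws in groups for r in raws)
        canonical = pick_canonical(merged)
        for r in merged:
            mapping[r] = canonical

    if overrides:
        folded = {k.strip().casefold(): v for k, v in overrides.items()}
        for raw in mapping:
            hit = folded.get(raw.strip().casefold())
            if hit is not None:
                mapping[raw] = hit
    return mapping
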