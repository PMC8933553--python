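"""Shared string primitives for term normalization.

Every normalizer in the package (adverse events, drug mentions,
statistical method names) is built from the same five operations:
Levenshtein edit distance, parenthetical stripping, auxiliary-phrase
removal, stop-word/lemma simplification, and whitespace/punctuation
squashing.  All dictionary matching downstream is case-insensitive, so
these primitives are deliberately conservative about anything other
than casing, punctuation and the configured phrase lists.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources as _ilres

__all__ = [
    "PhrasePatternList",
    "edit_distance",
    "strip_parenthetical",
    "remove_phrases",
    "simplify_tokens",
    "squash",
    "load_stopwords",
    "load_lemma_table",
    "default_phrase_patterns",
]

_WS_RE = re.compile(r"\s+")

_TIME_UNITS = (
    "second|seconds|minute|minutes|min|mins|hour|hours|hr|hrs|day|days|"
    "week|weeks|month|months|year|years"
)


def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance (insert/delete/substitute).

    Plain Levenshtein, no transpositions. Symmetric, zero iff equal.
    """
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def edit_distance_within(a: str, b: str, limit: int) -> int | None:
    """Banded Levenshtein: the distance if it is <= limit, else None.

    Used by the dictionary-rescue stages, where only distances up to a
    small threshold matter and most candidate pairs are far apart.
    """
    if abs(len(a) - len(b)) > limit:
        return None
    d = edit_distance(a, b)
    return d if d <= limit else None


def strip_parenthetical(t: str) -> str:
    """Remove every balanced ``(...)`` span (outermost), collapse spaces.

    Unbalanced parentheses are left untouched.
    """
    out: list[str] = []
    i, n = 0, len(t)
    while i < n:
        if t[i] == "(":
            depth, j = 1, i + 1
            while j < n and depth:
                if t[j] == "(":
                    depth += 1
                elif t[j] == ")":
                    depth -= 1
                j += 1
            if depth == 0:  # balanced span -> drop it
                i = j
                continue
        out.append(t[i])
        i += 1
    return _WS_RE.sub(" ", "".join(out)).strip()


@dataclass
class PhrasePatternList:
    """Ordered list of literal phrases / simple wildcard patterns.

    Wildcards: ``<number>`` matches an integer or decimal literal,
    ``<time-unit>`` matches a clock or calendar unit word. Patterns are
    matched as whole token spans; matching is case-insensitive unless
    ``case_sensitive`` is set.
    """

    patterns: list[str]
    case_sensitive: bool = False
    _compiled: list[re.Pattern] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if any(not p or not p.strip() for p in self.patterns):
            raise ValueError("phrase patterns must be non-empty strings")
        flags = 0 if self.case_sensitive else re.IGNORECASE
        self._compiled = [
            re.compile(self._to_regex(p), flags) for p in self.patterns
        ]

    @staticmethod
    def _to_regex(pattern: str) -> str:
        parts = []
        for tok in pattern.split():
            if tok == "<number>":
                parts.append(r"\d+(?:\.\d+)?")
            elif tok == "<time-unit>":
                parts.append(f"(?:{_TIME_UNITS})")
            else:
                parts.append(re.escape(tok))
        body = r"\s+".join(parts)
        # whole-token-span boundaries: no letter/digit directly adjacent
        return rf"(?<![A-Za-z0-9]){body}(?![A-Za-z0-9])"

    @classmethod
    def from_file(cls, path, case_sensitive: bool = False) -> "PhrasePatternList":
        pats = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    pats.append(line)
        return cls(pats, case_sensitive)


@lru_cache(maxsize=1)
def default_phrase_patterns() -> PhrasePatternList:
    """Auxiliary-word/time-frame list shipped with the package."""
    ref = _ilres.files("trialkg.resources") / "aux_phrases.txt"
    with _ilres.as_file(ref) as path:
        return PhrasePatternList.from_file(path)


_DANGLING_RUN_RE = re.compile(r"\s*([-,])(?:\s*[-,])*\s*")
_EDGE_SEP_RE = re.compile(r"^[\s,\-]+|[\s,\-]+$")


def remove_phrases(t: str, pats: PhrasePatternList | None = None) -> str:
    """Delete matching phrases as whole token spans and tidy separators.

    Dangling ``-``/``,`` left behind by a removal and duplicated spaces
    are cleaned up afterwards.
    """
    if pats is None:
        pats = default_phrase_patterns()
    s = t
    for rx in pats._compiled:
        s = rx.sub(" ", s)
    s = _DANGLING_RUN_RE.sub(r" \1 ", s)
    s = _EDGE_SEP_RE.sub("", s)
    return _WS_RE.sub(" ", s).strip()


@lru_cache(maxsize=1)
def load_stopwords() -> frozenset[str]:
    ref = _ilres.files("trialkg.resources") / "stopwords.txt"
    words = set()
    for line in ref.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line.lower())
    return frozenset(words)


@lru_cache(maxsize=1)
def load_lemma_table() -> dict[str, str]:
    ref = _ilres.files("trialkg.resources") / "lemmas.tsv"
    table: dict[str, str] = {}
    for line in ref.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        form, lemma = line.split("\t")
        table[form.lower()] = lemma.lower()
    return table


_TOKEN_RE = re.compile(r"[a-z0-9]+(?:'[a-z]+)?")


def _lemmatize(tok: str, table: dict[str, str]) -> str:
    if tok in table:
        return table[tok]
    # regular plural suffix rules
    if len(tok) > 3 and tok.endswith("ies"):
        return tok[:-3] + "y"
    if len(tok) > 4 and tok.endswith(("ches", "shes", "sses", "xes", "zes")):
        return tok[:-2]
    if len(tok) > 3 and tok.endswith("s") and not tok.endswith(("ss", "us", "is")):
        return tok[:-1]
    return tok


def simplify_tokens(
    t: str,
    stop_words: frozenset[str] | None = None,
    lemma_table: dict[str, str] | None = None,
) -> str:
    """Lowercase, drop stop words, lemmatize, rejoin with single spaces.

    Deterministic for a fixed stop-word list and lemma table (the
    package ships pinned resource files for both).
    """
    if stop_words is None:
        stop_words = load_stopwords()
    if lemma_table is None:
        lemma_table = load_lemma_table()
    toks = _TOKEN_RE.findall(t.lower())
    return " ".join(
        _lemmatize(tok, lemma_table) for tok in toks if tok not in stop_words
    )


_NON_ALNUM_RE = re.compile(r"[^a-z0-9]+")


def squash(t: str) -> str:
    """Lowercase and strip all whitespace and punctuation.

    ``"paired t test"`` and ``"paired t-tests"`` squash to forms one
    edit apart, which is what the method-name normalizer exploits.
    """
    return _NON_ALNUM_RE.sub("", t.lower())
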