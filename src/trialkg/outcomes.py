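"""Standard outcome-measure extraction and outcome-title clustering.

Outcome titles in trial registries are long phrases that frequently
define a standardized assessment tool inline, e.g. "Gingival Health
Measured by Bleeding Index (BI)".  The Schwartz-Hearst rules pair the
parenthesized short form with its preceding long-form definition;
definitions are then filtered by a fixed list of instrument words
(scale, index, score, test, questionnaire, value, count, inventory,
assessment, level, rate), folded through a variant-override map, and
augmented with manually curated measures to form the set of standard
outcomes.  An outcome links to every standard outcome whose text
appears (case-insensitively) in its title or description.

Independently, all outcome titles are grouped by repeated-bisection
spherical clustering of their TF-IDF vectors, maximizing the sum over
clusters of the norm of the cluster composite vector.  Each cluster is
summarized by five descriptive words (shares of the within-cluster
similarity, from the squared centroid weights) and five discriminating
words (shares of the squared difference between the cluster centroid
and the complement centroid), each with a percentage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_extraction.text import TfidfVectorizer

from .textnorm import load_stopwords

__all__ = [
    "AbbreviationPair",
    "OutcomeClusterReport",
    "ClusterSummary",
    "DEFAULT_KEYWORDS",
    "find_abbreviations",
    "is_standard_candidate",
    "build_standard_outcomes",
    "link_standard_outcomes",
    "cluster_outcomes",
    "format_weighted_words",
]

DEFAULT_KEYWORDS = (
    "scale", "index", "score", "test", "questionnaire", "value",
    "count", "inventory", "assessment", "level", "rate",
)


@dataclass(frozen=True)
class AbbreviationPair:
    """A short form and its long-form definition found in text.

    The definition precedes the parenthesized abbreviation, and each
    character of the abbreviation occurs in order in the definition
    (case-insensitive), the first at a word start.
    """

    abbreviation: str
    definition: str
    abbr_span: tuple[int, int]
    def_span: tuple[int, int]


def _valid_short_form(sf: str) -> bool:
    sf = sf.strip()
    if not (2 <= len(sf) <= 10):
        return False
    if len(sf.split()) > 2:
        return False
    if not any(c.isalpha() for c in sf):
        return False
    return sf[0].isalnum()


def _best_long_form(sf: str, candidate: str) -> int | None:
    """Start index of the long form within ``candidate``, searching
    right to left so that every short-form character matches in order
    and the first matches a word start; None if no alignment exists."""
    s = len(sf) - 1
    l = len(candidate) - 1
    while s >= 0:
        c = sf[s].lower()
        if not c.isalnum():
            s -= 1
            continue
        while l >= 0 and (
            candidate[l].lower() != c
            or (s == 0 and l > 0 and candidate[l - 1].isalnum())
        ):
            l -= 1
        if l < 0:
            return None
        s -= 1
        l -= 1
    return l + 1


def find_abbreviations(t: str) -> list[AbbreviationPair]:
    """Extract (abbreviation, definition) pairs from text, left to
    right, using the Schwartz-Hearst candidate rules."""
    pairs: list[AbbreviationPair] = []
    for m in re.finditer(r"\(([^()]+)\)", t):
        sf = m.group(1).strip()
        if not _valid_short_form(sf):
            continue
        before = t[: m.start()].rstrip()
        # cap the long-form window at min(|sf|+5, |sf|*2) words
        max_words = min(len(sf) + 5, len(sf) * 2)
        words = before.split()
        window = " ".join(words[-max_words:]) if words else ""
        if not window:
            continue
        start = _best_long_form(sf, window)
        if start is None:
            continue
        definition = window[start:].strip()
        if not definition or len(definition) <= len(sf):
            continue
        if sf.lower() in (w.lower() for w in definition.split()):
            continue
        win_off = len(before) - len(window)
        def_start = win_off + start
        pairs.append(AbbreviationPair(
            sf, definition,
            (m.start(1), m.end(1)),
            (def_start, def_start + len(definition)),
        ))
    return pairs


_WORD_RE = re.compile(r"[a-z0-9]+")


def is_standard_candidate(
    definition: str, keywords: tuple[str, ...] = DEFAULT_KEYWORDS
) -> bool:
    """True iff any keyword occurs as a whole word (after punctuation
    splitting, case-insensitive) in the definition."""
    toks = set(_WORD_RE.findall(definition.lower()))
    return any(k.lower() in toks for k in keywords)


def build_standard_outcomes(
    outcome_rows: pd.DataFrame,
    keywords: tuple[str, ...] = DEFAULT_KEYWORDS,
    manual_additions: list[str] | tuple[str, ...] = (),
    variant_overrides: dict[str, str] | None = None,
) -> list[str]:
    """Mine standard outcome measures from outcome titles/descriptions.

    ``outcome_rows`` columns: outcome_id, title, description.  Returns
    the union of keyword-filtered abbreviation definitions (after
    variant-override folding) and manual additions, deduplicated
    case-insensitively, sorted for determinism.
    """
    overrides = {k.strip().casefold(): v
                 for k, v in (variant_overrides or {}).items()}
    found: dict[str, str] = {}

    def add(name: str) -> None:
        name = name.strip()
        if name:
            found.setdefault(name.casefold(), name)

    for row in outcome_rows.itertuples(index=False):
        for text in (str(row.title), str(getattr(row, "description", "") or "")):
            for pair in find_abbreviations(text):
                if not is_standard_candidate(pair.definition, keywords):
                    continue
                add(overrides.get(pair.definition.strip().casefold(),
                                  pair.definition))
    for name in manual_additions:
        add(overrides.get(name.strip().casefold(), name))
    return sorted(found.values(), key=str.casefold)


def link_standard_outcomes(
    outcome_rows: pd.DataFrame, standards: list[str]
) -> list[tuple[str, str]]:
    """(outcome_id, standard) pairs where the standard's text occurs
    case-insensitively as a substring of the outcome title or
    description.  An outcome may link to several standards."""
    folded = [(s, s.casefold()) for s in standards]
    links: list[tuple[str, str]] = []
    for row in outcome_rows.itertuples(index=False):
        hay = (str(row.title) + "\n" +
               str(getattr(row, "description", "") or "")).casefold()
        for surface, fold in folded:
            if fold in hay:
                links.append((str(row.outcome_id), surface))
    return links


@dataclass
class ClusterSummary:
    cluster_id: int
    size: int
    descriptive: list[tuple[str, float]]     # (word, percentage), desc order
    discriminating: list[tuple[str, float]]


@dataclass
class OutcomeClusterReport:
    k: int
    assignment: dict[int, int]               # title index -> cluster id
    clusters: list[ClusterSummary]


def format_weighted_words(pairs: list[tuple[str, float]]) -> str:
    """Render word/percentage pairs as "word 56.4%, word 43.0%, ..."."""
    return ", ".join(f"{w} {p:.1f}%" for w, p in pairs)


def _composite_norm(x: np.ndarray, idx: np.ndarray) -> float:
    return float(np.linalg.norm(x[idx].sum(axis=0)))


def _spherical_bisect(
    x: np.ndarray, idx: np.ndarray, rng: np.random.Generator,
    restarts: int = 8, iters: int = 50,
):
    """Best 2-way split of rows ``idx`` by spherical 2-means; returns
    (left indices, right indices, criterion gain achieved).

    The first restart seeds the two centroids with the least-similar
    document pair (deterministic, robust for well-separated topics);
    the remaining restarts use random seeds.
    """
    base = _composite_norm(x, idx)
    gram = x[idx] @ x[idx].T
    np.fill_diagonal(gram, np.inf)
    far_pair = np.unravel_index(np.argmin(gram), gram.shape)
    best = None
    for attempt in range(restarts):
        if attempt == 0:
            seeds = np.array(far_pair)
        else:
            seeds = rng.choice(len(idx), size=2, replace=False)
        cents = x[idx[seeds]].copy()
        assign = None
        for _ in range(iters):
            sims = x[idx] @ cents.T
            new_assign = np.argmax(sims, axis=1)
            for c in (0, 1):  # reseed an emptied side with its farthest point
                if not np.any(new_assign == c):
                    far = np.argmin(sims[:, 1 - c])
                    new_assign[far] = c
            if assign is not None and np.array_equal(new_assign, assign):
                break
            assign = new_assign
            for c in (0, 1):
                v = x[idx[assign == c]].sum(axis=0)
                n = np.linalg.norm(v)
                cents[c] = v / n if n > 0 else v
        left, right = idx[assign == 0], idx[assign == 1]
        crit = _composite_norm(x, left) + _composite_norm(x, right)
        if best is None or crit > best[2]:
            best = (left, right, crit)
    return best[0], best[1], best[2] - base


def cluster_outcomes(
    titles: list[str],
    k: int,
    seed: int = 0,
    stop_words: frozenset[str] | None = None,
) -> OutcomeClusterReport:
    """Partition outcome titles into ``k`` clusters.

    Titles are tokenized (lowercased, punctuation stripped),
    stop-worded, TF-IDF weighted with smoothed inverse document
    frequency, and unit-length normalized; clusters come from repeated
    bisection maximizing the summed composite-vector norm; per cluster
    the top-5 descriptive and discriminating words are reported with
    percentages in non-increasing order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(titles):
        raise ValueError(f"k={k} exceeds the number of titles ({len(titles)})")
    if stop_words is None:
        stop_words = load_stopwords()

    vec = TfidfVectorizer(
        lowercase=True,
        token_pattern=r"[a-z0-9]+",
        stop_words=sorted(stop_words),
        norm="l2",
        smooth_idf=True,
    )
    x = vec.fit_transform(titles).toarray()
    vocab = np.array(vec.get_feature_names_out())
    rng = np.random.default_rng(seed)

    clusters: list[np.ndarray] = [np.arange(len(titles))]
    while len(clusters) < k:
        best = None
        for ci, idx in enumerate(clusters):
            if len(idx) < 2:
                continue
            left, right, gain = _spherical_bisect(x, idx, rng)
            if best is None or gain > best[3]:
                best = (ci, left, right, gain)
        ci, left, right, _ = best
        clusters[ci] = left
        clusters.append(right)

    # stable cluster ids: order by smallest member index
    clusters.sort(key=lambda idx: int(idx.min()))
    assignment = {int(i): ci for ci, idx in enumerate(clusters) for i in idx}

    total_centroid_sum = x.sum(axis=0)
    summaries = []
    for ci, idx in enumerate(clusters):
        centroid = x[idx].mean(axis=0)
        rest = len(titles) - len(idx)
        comp = ((total_centroid_sum - x[idx].sum(axis=0)) / rest
                if rest else np.zeros_like(centroid))

        def top5(weights: np.ndarray) -> list[tuple[str, float]]:
            denom = float((weights ** 2).sum())
            if denom == 0:
                return []
            pct = 100.0 * (weights ** 2) / denom
            order = sorted(range(len(pct)), key=lambda j: (-pct[j], vocab[j]))
            return [(str(vocab[j]), float(pct[j])) for j in order[:5]
                    if pct[j] > 0]

        summaries.append(ClusterSummary(
            cluster_id=ci,
            size=int(len(idx)),
            descriptive=top5(centroid),
            discriminating=top5(centroid - comp),
        ))
    return OutcomeClusterReport(k=k, assignment=assignment, clusters=summaries)
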