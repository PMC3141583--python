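"""Cross-corpus operations: table intersection, lexicon filtering, item ranking.

These are the steps that connect two disease corpora (keep only pairs found
in both, e.g. a rheumatoid-arthritis corpus against a coronary-heart-disease
corpus) and that bring in a curated term lexicon (keep only pairs touching
herb names, rank herbs by how many records mention them, pull out the star
of pairs around chosen seed terms).
"""

from __future__ import annotations

import warnings
from enum import Enum
from typing import Iterable

from .cooc import DescriptorPair, FrequencyTable
from .corpus_io import Corpus, HerbLexicon, normalize_term

__all__ = [
    "CombinePolicy",
    "intersect_tables",
    "filter_by_lexicon",
    "rank_items",
    "cross_query",
]


class CombinePolicy(str, Enum):
    """How to combine the two frequencies of a pair present in both tables.

    ``min`` is the default: a pair reaches slice level f of the intersection
    iff it reaches level f in *both* corpora, which is the conservative
    reading when the source gives no combination rule.
    """

    MIN = "min"
    SUM = "sum"
    LEFT = "left"
    RIGHT = "right"

    def combine(self, left: int, right: int) -> int:
        if self is CombinePolicy.MIN:
            return min(left, right)
        if self is CombinePolicy.SUM:
            return left + right
        if self is CombinePolicy.LEFT:
            return left
        return right


def intersect_tables(
    left: FrequencyTable,
    right: FrequencyTable,
    policy: CombinePolicy | str = CombinePolicy.MIN,
) -> FrequencyTable:
    """Pairs present in both tables, frequencies combined per policy."""
    policy = CombinePolicy(policy)
    shared = left.pairs() & right.pairs()
    entries = {p: policy.combine(left[p], right[p]) for p in shared}
    label = f"{left.source_label}_{right.source_label}"
    return FrequencyTable(entries, label)


def filter_by_lexicon(
    table: FrequencyTable, lexicon: HerbLexicon, mode: str = "both"
) -> FrequencyTable:
    """Keep pairs whose endpoints match the lexicon (case-insensitive, exact term).

    ``mode="both"`` keeps pairs with *two* lexicon endpoints (item–item
    networks); ``mode="either"`` keeps pairs with at least one (item–concept
    links).  Matching is exact-term, not substring.
    """
    if mode not in ("both", "either"):
        raise ValueError(f"mode must be 'both' or 'either', got {mode!r}")
    if len(lexicon) == 0:
        warnings.warn("empty lexicon: filter result is empty", stacklevel=2)
        return FrequencyTable({}, table.source_label)
    if mode == "both":
        keep = lambda p: p.a in lexicon and p.b in lexicon  # noqa: E731
    else:
        keep = lambda p: p.a in lexicon or p.b in lexicon  # noqa: E731
    entries = {p: f for p, f in table.items() if keep(p)}
    return FrequencyTable(entries, table.source_label)


def rank_items(
    corpus: Corpus, lexicon: HerbLexicon, top_n: int
) -> list[tuple[str, int]]:
    """Lexicon terms ranked by number of records mentioning them.

    Descending by count, ties broken lexicographically; terms mentioned in no
    record are omitted; the list is truncated to ``top_n``.
    """
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    counts: dict[str, int] = {}
    for record in corpus:
        folded = {d.casefold() for d in record.descriptors}
        for term in lexicon:
            if term.casefold() in folded:
                counts[term] = counts.get(term, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_n]


def cross_query(
    table: FrequencyTable, seed_terms: Iterable[str], min_freq: int = 1
) -> FrequencyTable:
    """Pairs with at least one endpoint among the seed terms and frequency >= min_freq.

    This is the verification step of the workflow: having selected seed items
    from one corpus, pull their incident pairs (above a threshold) out of the
    other corpus's table.
    """
    seeds = {normalize_term(t).casefold() for t in seed_terms}
    seeds.discard("")
    if not seeds:
        raise ValueError("seed_terms must be non-empty")
    if min_freq < 1:
        raise ValueError(f"min_freq must be >= 1, got {min_freq}")
    entries = {
        p: f
        for p, f in table.items()
        if f >= min_freq and (p.a.casefold() in seeds or p.b.casefold() in seeds)
    }
    return FrequencyTable(entries, table.source_label)
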