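"""Co-occurrent descriptor pairs and their corpus-wide frequencies.

Two descriptors co-occur when they are indexed on the same record.  A record
with k descriptors yields the k·(k-1)/2 unordered pairs of distinct terms;
the frequency of a pair is the number of records whose pair set contains it.
The frequency table is the raw material for frequency-threshold slicing.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .corpus_io import Corpus, DescriptorRecord, normalize_term

__all__ = [
    "DescriptorPair",
    "FrequencyTable",
    "enumerate_pairs",
    "enumerate_pairs_literal",
    "count_frequencies",
]


@dataclass(frozen=True, order=True)
class DescriptorPair:
    """Canonical unordered pair of distinct descriptors (a < b lexicographically)."""

    a: str
    b: str

    def __post_init__(self) -> None:
        a, b = normalize_term(self.a), normalize_term(self.b)
        if a == b:
            raise ValueError(f"self-pair not allowed: {a!r}")
        if b < a:
            a, b = b, a
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    def __iter__(self) -> Iterator[str]:
        yield self.a
        yield self.b

    def __str__(self) -> str:
        return f"{self.a} -- {self.b}"


def enumerate_pairs(record: DescriptorRecord) -> frozenset[DescriptorPair]:
    """All unordered pairs of distinct descriptors of one record.

    Exactly k(k-1)/2 pairs for k descriptors; empty or singleton records
    yield the empty set.
    """
    terms = sorted(record.descriptors)
    return frozenset(DescriptorPair(x, y) for x, y in combinations(terms, 2))


def enumerate_pairs_literal(record: DescriptorRecord) -> list[tuple[str, str]]:
    """Debug helper: the naive double loop over i = 1..k, j = 1..k.

    Emits k² ordered tuples including self-pairs and both orientations.  This
    is NOT the semantics used anywhere in the pipeline — the worked pair
    table of the method contains only the unordered i<j pairs — but the
    naive variant is kept so the discrepancy stays visible and testable.
    """
    terms = sorted(record.descriptors)
    return [(x, y) for x in terms for y in terms]


@dataclass
class FrequencyTable:
    """Map from canonical descriptor pair to its co-occurrence count."""

    entries: dict[DescriptorPair, int] = field(default_factory=dict)
    source_label: str = ""

    def __post_init__(self) -> None:
        for pair, freq in self.entries.items():
            if freq < 1:
                raise ValueError(f"frequency must be >= 1, got {freq} for {pair}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pair: DescriptorPair) -> bool:
        return pair in self.entries

    def __getitem__(self, pair: DescriptorPair) -> int:
        return self.entries[pair]

    def __iter__(self) -> Iterator[DescriptorPair]:
        return iter(self.entries)

    def items(self) -> Iterable[tuple[DescriptorPair, int]]:
        return self.entries.items()

    def pairs(self) -> frozenset[DescriptorPair]:
        return frozenset(self.entries)

    def vocabulary(self) -> frozenset[str]:
        """All descriptors appearing as an endpoint of some pair."""
        return frozenset(t for pair in self.entries for t in pair)

    # -- persistence: UTF-8 TSV, sorted by descending frequency then pair ----

    def sorted_rows(self) -> list[tuple[str, str, int]]:
        return [
            (p.a, p.b, f)
            for p, f in sorted(self.entries.items(), key=lambda kv: (-kv[1], kv[0]))
        ]

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for a, b, f in self.sorted_rows():
                fh.write(f"{a}\t{b}\t{f}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, source_label: str = "") -> "FrequencyTable":
        path = Path(path)
        entries: dict[DescriptorPair, int] = {}
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(
                        f"{path}: line {lineno}: expected 3 columns, got {len(parts)}"
                    )
                pair = DescriptorPair(parts[0], parts[1])
                entries[pair] = int(parts[2])
        return cls(entries, source_label or path.stem)

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[tuple[str, str] | DescriptorPair, int], label: str = ""
    ) -> "FrequencyTable":
        entries: dict[DescriptorPair, int] = {}
        for key, freq in mapping.items():
            pair = key if isinstance(key, DescriptorPair) else DescriptorPair(*key)
            entries[pair] = entries.get(pair, 0) + freq if pair in entries else freq
        return cls(entries, label)


def count_frequencies(corpus: Corpus) -> FrequencyTable:
    """Tally, over all records, how many records each pair co-occurs in.

    A pair counts once per record regardless of how it is listed there
    (records hold descriptor *sets*).  Pairs absent from every record are
    absent from the table, so all stored frequencies are >= 1.
    """
    counter: Counter[DescriptorPair] = Counter()
    for record in corpus:
        counter.update(enumerate_pairs(record))
    return FrequencyTable(dict(counter), corpus.source_label)
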