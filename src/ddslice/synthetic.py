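"""Seeded synthetic corpora with planted ground truth.

Real citation corpora cannot be redistributed or re-downloaded in a fixed
state, so every operation in this package is exercised against generated
corpora instead: records drawing a handful of descriptors from a heavy-tailed
(power-law rank) vocabulary, optionally with *planted* structures — a pair
forced to co-occur in exactly ``frequency`` records, or a star (one center,
several rim terms, each center–rim edge at a chosen frequency).  The skewed
vocabulary makes slice occupancy thin out as the frequency threshold rises,
the qualitative behaviour of real keyword co-occurrence data.

Planting is exact: each planted structure receives its own records (disjoint
across structures, carrying only that structure's terms), and background
descriptor sets that would accidentally complete a planted edge are redrawn.
Realized frequencies are post-checked by a direct scan, so the returned
ground truth can serve as a test oracle.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .cooc import DescriptorPair
from .corpus_io import Corpus, DescriptorRecord, HerbLexicon

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "PlantingError",
    "generate_corpus",
    "generate_lexicon",
    "table3_fixture",
    "TABLE3_PMID",
    "TABLE3_DESCRIPTORS",
]

_MAX_REDRAWS = 200


class PlantingError(ValueError):
    """Raised when a planted structure cannot be realized exactly."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one synthetic corpus.

    ``planted_pairs`` maps ``((a, b), target_frequency)``; ``planted_stars``
    entries are ``(center, rim_size, per_edge_frequency)``.  ``vocabulary_skew``
    is the power-law exponent s of the rank weights rank^(-s); larger s means
    a heavier head and rarer tail terms.
    """

    n_records: int = 300
    vocab_size: int = 150
    descriptors_per_record: tuple[int, int] = (2, 8)
    vocabulary_skew: float = 1.2
    planted_pairs: tuple[tuple[tuple[str, str], int], ...] = ()
    planted_stars: tuple[tuple[str, int, int], ...] = ()
    seed: int = 0
    source_label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_records < 0:
            raise ValueError("n_records must be >= 0")
        if self.vocab_size < 2:
            raise ValueError("vocab_size must be >= 2")
        lo, hi = self.descriptors_per_record
        if not (1 <= lo <= hi):
            raise ValueError("descriptors_per_record must satisfy 1 <= lo <= hi")
        if self.vocabulary_skew <= 0:
            raise ValueError("vocabulary_skew must be positive")
        for (a, b), freq in self.planted_pairs:
            if freq < 1 or freq > self.n_records:
                raise PlantingError(
                    f"planted pair ({a!r}, {b!r}) target {freq} infeasible "
                    f"for {self.n_records} records"
                )
        for center, rim_size, freq in self.planted_stars:
            if rim_size < 1:
                raise PlantingError(f"star {center!r}: rim size must be >= 1")
            if freq < 1 or freq > self.n_records:
                raise PlantingError(
                    f"star {center!r} per-edge frequency {freq} infeasible"
                )
        demand = sum(f for _, f in self.planted_pairs) + sum(
            rim * f for _, rim, f in self.planted_stars
        )
        if demand > self.n_records:
            raise PlantingError(
                f"planted structures need {demand} records, only "
                f"{self.n_records} available"
            )


@dataclass
class GroundTruth:
    """Exact planted frequencies recorded at generation time."""

    pair_freqs: dict[DescriptorPair, int] = field(default_factory=dict)
    star_rims: dict[str, frozenset[str]] = field(default_factory=dict)
    star_edge_freqs: dict[str, dict[DescriptorPair, int]] = field(default_factory=dict)

    def planted_edges(self) -> frozenset[DescriptorPair]:
        edges = set(self.pair_freqs)
        for per_star in self.star_edge_freqs.values():
            edges.update(per_star)
        return frozenset(edges)


def _vocab(size: int) -> list[str]:
    width = max(3, len(str(size)))
    return [f"T{i:0{width}d}" for i in range(1, size + 1)]


def _star_rim_names(center: str, rim_size: int) -> list[str]:
    return [f"{center}::rim{j}" for j in range(1, rim_size + 1)]


def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus and its planted ground truth, deterministically per seed."""
    rng = random.Random(config.seed)
    vocab = _vocab(config.vocab_size)
    weights = [rank ** -config.vocabulary_skew for rank in range(1, config.vocab_size + 1)]
    lo, hi = config.descriptors_per_record

    # record the planted edges and which terms each record will receive
    truth = GroundTruth()
    additions: dict[int, set[str]] = {}
    pool = list(range(config.n_records))
    rng.shuffle(pool)
    cursor = 0

    def allocate(n: int, edge: DescriptorPair) -> None:
        nonlocal cursor
        for idx in pool[cursor : cursor + n]:
            additions.setdefault(idx, set()).update((edge.a, edge.b))
        cursor += n

    for (a, b), freq in config.planted_pairs:
        pair = DescriptorPair(a, b)
        if pair in truth.pair_freqs:
            raise PlantingError(f"pair {pair} planted twice")
        truth.pair_freqs[pair] = freq
        allocate(freq, pair)

    for center, rim_size, freq in config.planted_stars:
        rim = _star_rim_names(center, rim_size)
        truth.star_rims[center] = frozenset(rim)
        truth.star_edge_freqs[center] = {}
        for rim_node in rim:
            edge = DescriptorPair(center, rim_node)
            truth.star_edge_freqs[center][edge] = freq
            allocate(freq, edge)

    planted_edges = truth.planted_edges()

    records: list[DescriptorRecord] = []
    for idx in range(config.n_records):
        if idx in additions:
            # planted records carry only their structure's terms, so every
            # planted edge frequency is exact by construction
            final = additions[idx]
        else:
            for attempt in range(_MAX_REDRAWS + 1):
                n_terms = rng.randint(lo, hi)
                final = set(rng.choices(vocab, weights=weights, k=n_terms))
                if not any(e.a in final and e.b in final for e in planted_edges):
                    break
            else:
                raise PlantingError(
                    f"record {idx}: could not draw background avoiding planted "
                    f"edges after {_MAX_REDRAWS} redraws"
                )
        records.append(DescriptorRecord(f"R{idx + 1:06d}", frozenset(final)))

    corpus = Corpus(records, config.source_label)

    # post-check: every planted edge realized at exactly its target
    for edge, target in (
        list(truth.pair_freqs.items())
        + [kv for star in truth.star_edge_freqs.values() for kv in star.items()]
    ):
        realized = sum(
            1 for r in records if edge.a in r.descriptors and edge.b in r.descriptors
        )
        if realized != target:
            raise PlantingError(
                f"planted edge {edge} realized at {realized}, target {target}"
            )
    return corpus, truth


def generate_lexicon(n_terms: int, seed: int = 0, prefix: str = "Herb") -> HerbLexicon:
    """A lexicon of ``n_terms`` distinct synthetic terms (order shuffled by seed)."""
    terms = [f"{prefix}-{i:04d}" for i in range(1, n_terms + 1)]
    random.Random(seed).shuffle(terms)
    return HerbLexicon(tuple(terms))


# ---------------------------------------------------------------------------
# The printed worked example: one PubMed citation and its eight headings.

TABLE3_PMID = "20464912"
TABLE3_DESCRIPTORS = (
    "physiopathology",
    "rehabilitation",
    "Evidence-Based Medicine",
    "Humans",
    "Muscle Stretching Exercises",
    "Physical Fitness",
    "Resistance Training",
    "Treatment Outcome",
)


def table3_fixture() -> Corpus:
    """The single worked-example citation: PMID 20464912 with 8 heading terms.

    Its pair enumeration is the canonical check of the co-occurrence step:
    C(8,2) = 28 unordered pairs, no self-pairs, no ordered duplicates.
    """
    record = DescriptorRecord(TABLE3_PMID, frozenset(TABLE3_DESCRIPTORS))
    return Corpus([record], "worked_example")
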