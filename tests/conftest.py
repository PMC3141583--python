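"""Shared fixtures and independent oracles.

The brute-force frequency oracle here is intentionally written against plain
Python containers (no package types in the tally) so it stays an independent
check on the pipeline's counting path.
"""

from __future__ import annotations

from collections import Counter

import pytest

from ddslice.corpus_io import Corpus
from ddslice.synthetic import TABLE3_DESCRIPTORS, table3_fixture

# The 28 unordered pairs printed by the worked example (C(8,2) over the eight
# headings of the example citation), frozen as unordered frozensets.
WORKED_EXAMPLE_PAIRS = frozenset(
    frozenset(pair)
    for pair in [
        ("physiopathology", "rehabilitation"),
        ("physiopathology", "Evidence-Based Medicine"),
        ("physiopathology", "Humans"),
        ("physiopathology", "Muscle Stretching Exercises"),
        ("physiopathology", "Physical Fitness"),
        ("physiopathology", "Resistance Training"),
        ("physiopathology", "Treatment Outcome"),
        ("rehabilitation", "Evidence-Based Medicine"),
        ("rehabilitation", "Humans"),
        ("rehabilitation", "Muscle Stretching Exercises"),
        ("rehabilitation", "Physical Fitness"),
        ("rehabilitation", "Resistance Training"),
        ("rehabilitation", "Treatment Outcome"),
        ("Evidence-Based Medicine", "Humans"),
        ("Evidence-Based Medicine", "Muscle Stretching Exercises"),
        ("Evidence-Based Medicine", "Physical Fitness"),
        ("Evidence-Based Medicine", "Resistance Training"),
        ("Evidence-Based Medicine", "Treatment Outcome"),
        ("Humans", "Muscle Stretching Exercises"),
        ("Humans", "Physical Fitness"),
        ("Humans", "Resistance Training"),
        ("Humans", "Treatment Outcome"),
        ("Muscle Stretching Exercises", "Physical Fitness"),
        ("Muscle Stretching Exercises", "Resistance Training"),
        ("Muscle Stretching Exercises", "Treatment Outcome"),
        ("Physical Fitness", "Resistance Training"),
        ("Physical Fitness", "Treatment Outcome"),
        ("Resistance Training", "Treatment Outcome"),
    ]
)


def brute_force_frequencies(corpus: Corpus) -> dict[frozenset, int]:
    """Independent quadratic tally: for each record, every 2-subset once."""
    tally: Counter[frozenset] = Counter()
    for record in corpus:
        terms = sorted(record.descriptors)
        for i in range(len(terms)):
            for j in range(i + 1, len(terms)):
                tally[frozenset((terms[i], terms[j]))] += 1
    return dict(tally)


@pytest.fixture
def worked_example_corpus() -> Corpus:
    return table3_fixture()


@pytest.fixture
def worked_example_terms() -> tuple[str, ...]:
    return TABLE3_DESCRIPTORS
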