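"""Frequency-threshold slices, level distributions, and discrete set derivatives.

Given a pair-frequency table with maximum frequency k (the hierarchical
parameter), slice_i is the set of pairs with frequency >= i, so the slices
nest: slice_{i+1} ⊆ slice_i and slice_1 is the whole table.  The level
distribution ld_i = slice_i − slice_{i+1} is the set of pairs at frequency
exactly i; the levels partition the pair set.

The discrete derivative differences adjacent levels with *set* difference:
order-1 at level i is ld_i − ld_{i+1}, and each higher order differences the
previous one, losing the top index per step (the derivative at the last point
is undefined).  Because levels at distinct frequencies are disjoint,
ld_i − ld_{i+1} = ld_i, so the derivative series of every order coincides
with the level distribution on its shared level range — the derivative is
constant in the order.  ``verify_constant_derivative`` is the executable form
of that claim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .cooc import DescriptorPair, FrequencyTable

__all__ = [
    "Slice",
    "LevelDistribution",
    "DerivativeSeries",
    "ConstantDerivativeReport",
    "max_frequency",
    "slice_at",
    "level_distribution",
    "all_level_distributions",
    "derivative",
    "verify_constant_derivative",
]


@dataclass(frozen=True)
class Slice:
    """Pairs with frequency >= ``threshold``."""

    threshold: int
    pairs: frozenset[DescriptorPair]


@dataclass(frozen=True)
class LevelDistribution:
    """Pairs with frequency exactly ``level``."""

    level: int
    pairs: frozenset[DescriptorPair]


@dataclass(frozen=True)
class DerivativeSeries:
    """Per-level pair sets at a given derivative order.

    ``levels`` maps level i -> pair set for i = 1..k-m (absent keys mean the
    level is *undefined* at this order, not empty).  Order 0 is the level
    distribution itself.
    """

    order: int
    levels: dict[int, frozenset[DescriptorPair]] = field(default_factory=dict)

    def defined_levels(self) -> list[int]:
        return sorted(self.levels)


def max_frequency(table: FrequencyTable) -> int:
    """Maximum pair frequency in the table; 0 for an empty table."""
    return max(table.entries.values(), default=0)


def slice_at(table: FrequencyTable, i: int) -> Slice:
    """The slice at threshold i: all pairs with frequency >= i.

    Empty slices are legitimate (real corpora show blank levels); i beyond
    the maximum frequency yields the empty slice.
    """
    if i < 1:
        raise ValueError(f"slice threshold must be >= 1, got {i}")
    return Slice(i, frozenset(p for p, f in table.items() if f >= i))


def level_distribution(table: FrequencyTable, i: int) -> LevelDistribution:
    """Pairs at frequency exactly i, as the difference of adjacent slices.

    Computed both by set difference of slice_i and slice_{i+1} and by direct
    frequency lookup; the two routes must agree (internal consistency check).
    """
    if i < 1:
        raise ValueError(f"level must be >= 1, got {i}")
    by_difference = slice_at(table, i).pairs - slice_at(table, i + 1).pairs
    by_lookup = frozenset(p for p, f in table.items() if f == i)
    assert by_difference == by_lookup, (
        f"slice-difference and direct-lookup level {i} disagree"
    )
    return LevelDistribution(i, by_difference)


def all_level_distributions(table: FrequencyTable) -> dict[int, frozenset[DescriptorPair]]:
    """Levels 1..k as a dict (single pass over the table)."""
    k = max_frequency(table)
    levels: dict[int, set[DescriptorPair]] = {i: set() for i in range(1, k + 1)}
    for pair, freq in table.items():
        levels[freq].add(pair)
    return {i: frozenset(s) for i, s in levels.items()}


def derivative(table: FrequencyTable, order: int) -> DerivativeSeries:
    """Discrete derivative series of the given order (>= 1).

    Each differencing step maps level i to prev[i] − prev[i+1] for
    i = 1..k-step, dropping the top index.  When ``order`` >= k no level
    survives; an empty series is returned with a warning.
    """
    if order < 1:
        raise ValueError(f"derivative order must be >= 1, got {order}")
    k = max_frequency(table)
    if order >= k:
        warnings.warn(
            f"derivative order {order} >= max frequency {k}: empty series",
            stacklevel=2,
        )
        return DerivativeSeries(order, {})
    current = all_level_distributions(table)
    for step in range(1, order + 1):
        current = {
            i: current[i] - current[i + 1] for i in range(1, k - step + 1)
        }
    return DerivativeSeries(order, current)


@dataclass(frozen=True)
class ConstantDerivativeReport:
    """Per-(order, level) equality of the derivative series with the level distribution."""

    max_order: int
    checks: dict[tuple[int, int], bool]
    passed: bool

    def failures(self) -> list[tuple[int, int]]:
        return sorted(key for key, ok in self.checks.items() if not ok)


def verify_constant_derivative(
    table: FrequencyTable, max_order: int
) -> ConstantDerivativeReport:
    """Check that derivatives of orders 1..max_order equal the level distribution.

    For each order m and each level i <= k-m, the order-m series at level i
    is compared with the exact-frequency level set ld_i.  Overall pass iff
    every comparison holds; an empty table passes vacuously (no levels).
    """
    if max_order < 2:
        raise ValueError(f"max_order must be >= 2, got {max_order}")
    k = max_frequency(table)
    ld = all_level_distributions(table)
    checks: dict[tuple[int, int], bool] = {}
    for m in range(1, max_order + 1):
        if m >= k:
            continue  # series undefined (empty) at this order
        series = derivative(table, m)
        for i in range(1, k - m + 1):
            checks[(m, i)] = series.levels[i] == ld[i]
    return ConstantDerivativeReport(max_order, checks, all(checks.values()))
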