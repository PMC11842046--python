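"""Exclusive set-intersection counts of tools by field (UpSet-style).

A tool with a dual affiliation belongs to two fields; the UpSet view of the
corpus partitions tools by their *exact* field set, so each tool counts
toward exactly one combination and the counts sum to the number of tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .taxonomy import FieldAssignment, Level

__all__ = ["IntersectionCount", "exclusive_intersections", "top_k_sets"]

COMBINATION_SEP = "&"


@dataclass(frozen=True)
class IntersectionCount:
    """Count of tools whose field set equals exactly this combination."""

    field_combination: frozenset[str]
    count: int

    @property
    def label(self) -> str:
        """Combination rendered with members joined lexicographically."""
        return COMBINATION_SEP.join(sorted(self.field_combination))


def exclusive_intersections(
    assignments: Iterable[FieldAssignment],
    level: Level,
    inclusive: bool = False,
) -> list[IntersectionCount]:
    """Partition tools by their exact field set at ``level``.

    With ``inclusive=True``, a combination's count instead includes every
    tool whose field set is a superset of it (UpSet's "intersection size"
    alternative); the partition property then no longer holds.
    """
    exact: dict[frozenset[str], int] = {}
    for a in assignments:
        combo = a.at_level(level)
        exact[combo] = exact.get(combo, 0) + 1
    if not inclusive:
        return [
            IntersectionCount(combo, n)
            for combo, n in sorted(exact.items(), key=lambda kv: sorted(kv[0]))
        ]
    out = []
    for combo in sorted(exact, key=sorted):
        n = sum(c for other, c in exact.items() if combo <= other)
        out.append(IntersectionCount(combo, n))
    return out


def top_k_sets(
    counts: Iterable[IntersectionCount], k: int = 11
) -> list[IntersectionCount]:
    """The ``k`` largest combinations, descending by count.

    Ties break lexicographically on the rendered combination label, so the
    output is stable under permutation of the input.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ranked = sorted(counts, key=lambda c: (-c.count, c.label))
    return ranked[:k]
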