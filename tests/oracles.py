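"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: tallies are computed by
enumerating every pairwise comparison, and the step-up FDR adjustment is
spelled out from its definition.
"""

from __future__ import annotations

from benchfield.corpus import Corpus


def brute_force_tally(
    corpus: Corpus,
    pairs: list[tuple[str, str]],
    field_map: dict[str, frozenset[str]],
) -> dict[str, tuple[int, int]]:
    """(wins, comparisons) per field for an explicit draw sequence.

    Enumerates every opposing tool in the drawn benchmark one comparison at
    a time: strictly better rank (smaller number) is a win, a tie is a
    comparison without a win.
    """
    out: dict[str, list[int]] = {}
    for tool_id, bm_id in pairs:
        bm = next(b for b in corpus.benchmarks if b.benchmark_id == bm_id)
        my_rank = dict(bm.entries)[tool_id]
        wins = comps = 0
        for other_id, other_rank in bm.entries:
            if other_id == tool_id:
                continue
            comps += 1
            if other_rank > my_rank:
                wins += 1
        for label in field_map[tool_id]:
            acc = out.setdefault(label, [0, 0])
            acc[0] += wins
            acc[1] += comps
    return {f: (w, c) for f, (w, c) in out.items()}


def bh_step_up(p_values: list[float]) -> list[float]:
    """Benjamini–Hochberg adjusted p-values from the textbook definition.

    Sort ascending, scale p_(i) by m/i, enforce monotonicity from the
    largest rank down, cap at 1, return in the original order.
    """
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p_values[i] * m / rank)
        adjusted[i] = min(1.0, running_min)
    return adjusted
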