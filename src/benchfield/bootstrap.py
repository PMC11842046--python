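"""Pairwise-win bootstrap: the study's core accuracy statistic.

Benchmarks use heterogeneous accuracy metrics (sensitivity, MCC, AUROC, ...)
and rank anywhere from a handful to dozens of tools, so raw scores are not
comparable across benchmarks.  The rank-based statistic used here is: within
one benchmark, tool A "wins" against tool B when A is ranked strictly better.
A tool ranked second in a benchmark of 11 tools therefore contributes 9 wins
and 10 comparisons.

To weight the corpus evenly, a bootstrap resamples tools rather than
benchmarks: each replicate draws ``sample_size`` tools uniformly with
replacement, picks one benchmark per draw uniformly among the benchmarks
that rank the drawn tool, and accumulates that draw's wins and comparisons
into every (eligible) field label the tool carries.  Repeating this
``n_replicates`` times yields, per field, a distribution of win proportions
whose mean, percentile confidence interval and Z-score against the null win
proportion of 0.5 are reported.

The Z-score follows the convention ``z = (x - mu) / sigma`` with ``x = 0.5``
(the null expectation for arbitrarily grouped tools), so *negative* z means
a field wins more often than chance; plots and tables also carry ``-z`` so
that higher-is-better matches the win-proportion axis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .corpus import Corpus

__all__ = [
    "WinTally",
    "BootstrapDistribution",
    "BootstrapSummary",
    "pairwise_wins",
    "sample_tool_benchmark_pairs",
    "tally_pairs",
    "bootstrap_replicate",
    "run_bootstrap",
    "summarize",
    "summarize_all",
    "bh_fdr",
    "DEFAULT_SAMPLE_SIZE",
    "DEFAULT_N_REPLICATES",
    "NULL_WIN_PROPORTION",
]

logger = logging.getLogger(__name__)

DEFAULT_SAMPLE_SIZE = 200
DEFAULT_N_REPLICATES = 1000
NULL_WIN_PROPORTION = 0.5


@dataclass(frozen=True)
class WinTally:
    """Accumulated wins/comparisons for one field in one replicate."""

    field_label: str
    level: str
    wins: int
    comparisons: int

    def __post_init__(self) -> None:
        if self.wins > self.comparisons:
            raise ValueError(
                f"{self.field_label}: wins ({self.wins}) exceed comparisons "
                f"({self.comparisons})"
            )

    @property
    def proportion(self) -> float:
        if self.comparisons == 0:
            raise ZeroDivisionError(f"{self.field_label}: no comparisons tallied")
        return self.wins / self.comparisons


@dataclass(frozen=True)
class BootstrapDistribution:
    """Per-replicate win proportions for one field.

    Replicates in which the field received no comparisons contribute
    nothing, so the list may be shorter than the number of replicates run.
    ``n_tools`` is the corpus-wide count of distinct tools carrying the
    field, not a per-replicate quantity.
    """

    field_label: str
    level: str
    replicate_proportions: tuple[float, ...]
    n_tools: int


@dataclass(frozen=True)
class BootstrapSummary:
    """Field-level summary: mean win proportion, CI, Z, p, FDR-adjusted p."""

    field_label: str
    level: str
    n_tools: int
    n_replicates_observed: int
    mean_win_prop: float
    sd: float
    ci_low: float
    ci_high: float
    z: float
    p_raw: float
    p_fdr: float = math.nan

    @property
    def neg_z(self) -> float:
        """Sign-flipped Z, the plotted orientation (higher = more wins)."""
        return -self.z


def pairwise_wins(rank: int, ranks_in_benchmark: Sequence[int]) -> tuple[int, int]:
    """Wins and comparisons contributed by one tool in one benchmark.

    ``comparisons`` is always ``n - 1``; ``wins`` counts the other tools
    with a strictly worse (numerically larger) rank.  A tied tool neither
    wins nor loses the tied comparison, but the comparison still counts.

    >>> pairwise_wins(2, range(1, 12))
    (9, 10)
    """
    ranks = list(ranks_in_benchmark)
    n = len(ranks)
    if n < 2:
        raise ValueError(f"degenerate benchmark: {n} ranked tool(s), need >=2")
    if rank not in ranks:
        raise ValueError(f"rank {rank} is not among the benchmark ranks")
    ranks.remove(rank)  # the tool itself: one occurrence only
    wins = sum(1 for r in ranks if r > rank)
    return wins, n - 1


class _CorpusIndex:
    """Flat numpy view of a corpus for fast replicate tallying.

    For each tool (corpus order) we store the benchmarks ranking it and the
    precomputed (wins, comparisons) of the tool in each, as CSR-style flat
    arrays.  The per-draw benchmark pick is uniform over a tool's segment.
    """

    def __init__(self, corpus: Corpus):
        self.tool_ids = [t.tool_id for t in corpus.tools]
        per_tool: dict[str, list[tuple[str, int, int]]] = {
            tid: [] for tid in self.tool_ids
        }
        for bm in corpus.benchmarks:
            ranks = bm.ranks
            for tid, rank in bm.entries:
                w, c = pairwise_wins(rank, ranks)
                per_tool[tid].append((bm.benchmark_id, w, c))
        counts = np.array([len(per_tool[t]) for t in self.tool_ids], dtype=np.int64)
        self.bm_count = counts
        self.bm_offset = np.concatenate(([0], np.cumsum(counts)[:-1]))
        flat = [item for tid in self.tool_ids for item in per_tool[tid]]
        self.flat_benchmark_ids = [b for b, _, _ in flat]
        self.flat_wins = np.array([w for _, w, _ in flat], dtype=np.int64)
        self.flat_comps = np.array([c for _, _, c in flat], dtype=np.int64)

    def draw(self, rng: np.random.Generator, sample_size: int) -> np.ndarray:
        """Draw ``sample_size`` (tool, benchmark) pairs; returns flat indices.

        Consumes exactly two rng calls: one integer vector (the tool draws)
        and one uniform vector (the per-draw benchmark pick), so a given
        generator state determines the draw sequence exactly.
        """
        t = rng.integers(0, len(self.tool_ids), size=sample_size)
        u = rng.random(sample_size)
        j = np.minimum((u * self.bm_count[t]).astype(np.int64), self.bm_count[t] - 1)
        return self.bm_offset[t] + j


class _FieldIndex:
    """CSR map from tool index to indices of the tool's tallied fields."""

    def __init__(self, index: _CorpusIndex, field_map: Mapping[str, Iterable[str]],
                 eligible: Iterable[str] | None):
        labels = sorted({f for fs in field_map.values() for f in fs})
        if eligible is not None:
            keep = set(eligible)
            labels = [f for f in labels if f in keep]
        self.labels = labels
        pos = {f: i for i, f in enumerate(labels)}
        per_tool = [
            sorted(pos[f] for f in field_map.get(tid, ()) if f in pos)
            for tid in index.tool_ids
        ]
        self.counts = np.array([len(p) for p in per_tool], dtype=np.int64)
        self.offsets = np.concatenate(([0], np.cumsum(self.counts)[:-1]))
        self.flat = np.array(
            [i for p in per_tool for i in p] or [0], dtype=np.int64
        )

    def accumulate(
        self, index: _CorpusIndex, flat_idx: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Sum wins/comparisons per field over one replicate's draws."""
        t = np.searchsorted(
            np.append(index.bm_offset, len(index.flat_wins)), flat_idx, side="right"
        ) - 1
        cnt = self.counts[t]
        total = int(cnt.sum())
        wins = np.zeros(len(self.labels), dtype=np.int64)
        comps = np.zeros(len(self.labels), dtype=np.int64)
        if total == 0:
            return wins, comps
        base = np.repeat(self.offsets[t], cnt)
        starts = np.repeat(np.cumsum(cnt) - cnt, cnt)
        within = np.arange(total) - starts
        f = self.flat[base + within]
        np.add.at(wins, f, np.repeat(index.flat_wins[flat_idx], cnt))
        np.add.at(comps, f, np.repeat(index.flat_comps[flat_idx], cnt))
        return wins, comps


def sample_tool_benchmark_pairs(
    corpus: Corpus,
    rng: np.random.Generator,
    sample_size: int = DEFAULT_SAMPLE_SIZE,
) -> list[tuple[str, str]]:
    """One replicate's draw sequence as explicit (tool_id, benchmark_id) pairs.

    Tools are drawn uniformly with replacement from all corpus tools; each
    draw independently picks one benchmark uniformly among the benchmarks
    ranking that tool (so repeated draws of one tool get fresh picks).
    """
    index = _CorpusIndex(corpus)
    flat_idx = index.draw(rng, sample_size)
    t = np.searchsorted(
        np.append(index.bm_offset, len(index.flat_wins)), flat_idx, side="right"
    ) - 1
    return [
        (index.tool_ids[ti], index.flat_benchmark_ids[fi])
        for ti, fi in zip(t, flat_idx)
    ]


def tally_pairs(
    corpus: Corpus,
    pairs: Sequence[tuple[str, str]],
    field_map: Mapping[str, Iterable[str]],
    level: str = "specific",
    eligible_fields: Iterable[str] | None = None,
) -> list[WinTally]:
    """Tally wins/comparisons per field for an explicit draw sequence.

    The tool's wins in the drawn benchmark are added to every field label
    the tool carries (a dual-affiliation tool contributes its full tally to
    each field, not a split).  Fields outside ``eligible_fields`` are not
    tallied; their tools still count in other tools' comparisons because
    comparisons are within-benchmark counts.
    """
    bm_by_id = {bm.benchmark_id: bm for bm in corpus.benchmarks}
    keep = None if eligible_fields is None else set(eligible_fields)
    wins: dict[str, int] = {}
    comps: dict[str, int] = {}
    for tool_id, bm_id in pairs:
        bm = bm_by_id[bm_id]
        rank = dict(bm.entries)[tool_id]
        w, c = pairwise_wins(rank, bm.ranks)
        for label in field_map.get(tool_id, ()):
            if keep is not None and label not in keep:
                continue
            wins[label] = wins.get(label, 0) + w
            comps[label] = comps.get(label, 0) + c
    return [
        WinTally(field_label=f, level=level, wins=wins[f], comparisons=comps[f])
        for f in sorted(wins)
    ]


def bootstrap_replicate(
    corpus: Corpus,
    field_map: Mapping[str, Iterable[str]],
    eligible_fields: Iterable[str] | None,
    rng: np.random.Generator,
    level: str = "specific",
    sample_size: int = DEFAULT_SAMPLE_SIZE,
) -> list[WinTally]:
    """One bootstrap replicate: draw, then tally per eligible field."""
    return tally_pairs(
        corpus,
        sample_tool_benchmark_pairs(corpus, rng, sample_size),
        field_map,
        level=level,
        eligible_fields=eligible_fields,
    )


def run_bootstrap(
    corpus: Corpus,
    field_map: Mapping[str, Iterable[str]],
    level: str = "specific",
    n_replicates: int = DEFAULT_N_REPLICATES,
    sample_size: int = DEFAULT_SAMPLE_SIZE,
    seed: int | np.random.SeedSequence = 0,
    eligible_fields: Iterable[str] | None = None,
) -> list[BootstrapDistribution]:
    """Run the full bootstrap; one distribution per field with >=1 tallied
    replicate.

    Replicate ``r``'s draws are a pure function of ``(seed, r)``: the seed
    sequence is spawned once into ``n_replicates`` independent child
    streams.  Fields never tallied across all replicates are dropped with a
    warning.
    """
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = ss.spawn(n_replicates)
    index = _CorpusIndex(corpus)
    findex = _FieldIndex(index, field_map, eligible_fields)
    n_fields = len(findex.labels)
    props: list[list[float]] = [[] for _ in range(n_fields)]
    for r in range(n_replicates):
        rng = np.random.default_rng(children[r])
        flat_idx = index.draw(rng, sample_size)
        wins, comps = findex.accumulate(index, flat_idx)
        observed = comps > 0
        for fi in np.nonzero(observed)[0]:
            props[fi].append(wins[fi] / comps[fi])

    tool_counts: dict[str, set[str]] = {}
    for tid, labels in field_map.items():
        for f in labels:
            tool_counts.setdefault(f, set()).add(tid)

    out = []
    for fi, label in enumerate(findex.labels):
        if not props[fi]:
            logger.warning(
                "field %r never received a comparison in %d replicates; dropped",
                label,
                n_replicates,
            )
            continue
        out.append(
            BootstrapDistribution(
                field_label=label,
                level=level,
                replicate_proportions=tuple(props[fi]),
                n_tools=len(tool_counts.get(label, ())),
            )
        )
    return out


def summarize(
    dist: BootstrapDistribution,
    null_value: float = NULL_WIN_PROPORTION,
    two_sided: bool = False,
) -> BootstrapSummary:
    """Summarise one field's replicate distribution.

    The CI is the percentile interval (2.5th/97.5th) of the replicate
    proportions; ``z = (null - mean) / sd`` (sample sd, ddof=1) and the
    p-value is the upper tail of the standard normal at ``|z|`` (one-sided
    by default, i.e. P[X > |z|]; doubled when ``two_sided``).  Degenerate
    sd = 0 yields an infinite-magnitude z with the sign of (null - mean).
    """
    p = np.asarray(dist.replicate_proportions, dtype=float)
    if p.size < 2:
        raise ValueError(
            f"{dist.field_label}: need >=2 replicate proportions, got {p.size}"
        )
    mu = float(p.mean())
    sd = float(p.std(ddof=1))
    ci_low, ci_high = (float(q) for q in np.percentile(p, [2.5, 97.5]))
    if sd == 0.0:
        z = 0.0 if mu == null_value else math.copysign(math.inf, null_value - mu)
        logger.warning(
            "field %r: zero bootstrap sd; z reported as %s", dist.field_label, z
        )
    else:
        z = (null_value - mu) / sd
    p_raw = float(stats.norm.sf(abs(z)))
    if two_sided:
        p_raw = min(1.0, 2.0 * p_raw)
    return BootstrapSummary(
        field_label=dist.field_label,
        level=dist.level,
        n_tools=dist.n_tools,
        n_replicates_observed=p.size,
        mean_win_prop=mu,
        sd=sd,
        ci_low=ci_low,
        ci_high=ci_high,
        z=z,
        p_raw=p_raw,
    )


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    if len(p_values) == 0:
        return []
    return list(multipletests(list(p_values), method="fdr_bh")[1])


def summarize_all(
    dists: Iterable[BootstrapDistribution],
    null_value: float = NULL_WIN_PROPORTION,
    two_sided: bool = False,
) -> list[BootstrapSummary]:
    """Summarise a family of fields and FDR-correct across that family.

    The caller chooses the family; the pipeline applies it per hierarchy
    level (specific, general, expertise corrected separately).
    """
    summaries = [summarize(d, null_value=null_value, two_sided=two_sided) for d in dists]
    adjusted = bh_fdr([s.p_raw for s in summaries])
    return [replace(s, p_fdr=q) for s, q in zip(summaries, adjusted)]
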