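"""Synthetic benchmark corpora with known field effects.

The generator emulates the statistical structure the pipeline assumes: each
tool has a latent quality, fields shift that quality additively, and each
benchmark ranks a random subset of tools by a noisy observation of quality.
Concretely, tool *t* with field set *F(t)* gets

    q_t = mean({delta_f : f in F(t)}) + e_t,     e_t ~ N(0, 1)

and benchmark *b* ranks its tools by ``q_t + eps_bt`` with
``eps_bt ~ N(0, noise_sd)`` drawn fresh per benchmark, rank 1 best.  Ties
are impossible almost surely.  With all deltas zero this is the null model
under which any grouping of tools has expected win proportion 0.5.

The generator is test scaffolding with known ground truth; it makes no
claim that real benchmark corpora follow this model (see the methods note
for what it does and does not emulate).  Defaults mirror the curated study
corpus: 498 tools, 128 benchmarks ranking 3–50 tools each, 1–2 affiliations
per tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

from .corpus import BenchmarkRanking, Corpus, ToolRecord

__all__ = ["SimulationConfig", "generate_corpus", "generate_null_ensemble"]

_METRICS = ("sensitivity", "specificity", "PPV", "AUROC", "MCC", "F1")


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for one synthetic corpus.

    ``field_probs`` are per-label sampling probabilities (uniform when
    omitted); a tool draws one field, plus — with probability
    ``dual_affiliation_prob`` — a second, distinct field from the same
    distribution renormalised over the remaining labels.  ``field_effects``
    maps labels to additive latent-quality shifts (delta); omitted labels
    have delta = 0.
    """

    field_labels: tuple[str, ...]
    n_tools: int = 498
    n_benchmarks: int = 128
    benchmark_size_range: tuple[int, int] = (3, 50)
    field_probs: tuple[float, ...] | None = None
    dual_affiliation_prob: float = 0.2
    field_effects: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.field_labels) < 1:
            raise ValueError("need at least one field label")
        if len(set(self.field_labels)) != len(self.field_labels):
            raise ValueError("field_labels must be distinct")
        lo, hi = self.benchmark_size_range
        if lo < 2:
            raise ValueError(f"minimum benchmark size must be >= 2, got {lo}")
        if hi < lo:
            raise ValueError(f"benchmark_size_range {self.benchmark_size_range} inverted")
        if hi > self.n_tools:
            raise ValueError(
                f"benchmark_size_range max ({hi}) exceeds n_tools ({self.n_tools})"
            )
        if not 0.0 <= self.dual_affiliation_prob <= 1.0:
            raise ValueError("dual_affiliation_prob must be a probability")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.field_probs is not None:
            p = np.asarray(self.field_probs, dtype=float)
            if p.size != len(self.field_labels):
                raise ValueError("field_probs length mismatch")
            if (p < 0).any() or not np.isclose(p.sum(), 1.0):
                raise ValueError("field_probs must be non-negative and sum to 1")
        unknown = set(self.field_effects) - set(self.field_labels)
        if unknown:
            raise ValueError(f"field_effects for unknown labels: {sorted(unknown)}")

    @property
    def deltas(self) -> dict[str, float]:
        return {f: float(self.field_effects.get(f, 0.0)) for f in self.field_labels}


def _generate(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[Corpus, dict[str, frozenset[str]], dict[str, float]]:
    labels = list(config.field_labels)
    n_labels = len(labels)
    probs = (
        np.full(n_labels, 1.0 / n_labels)
        if config.field_probs is None
        else np.asarray(config.field_probs, dtype=float)
    )
    deltas = config.deltas

    width = max(4, len(str(config.n_tools)))
    tool_ids = [f"T{i:0{width}d}" for i in range(1, config.n_tools + 1)]

    field_map: dict[str, frozenset[str]] = {}
    quality = np.empty(config.n_tools)
    for i, tid in enumerate(tool_ids):
        first = labels[rng.choice(n_labels, p=probs)]
        fields = {first}
        if n_labels > 1 and rng.random() < config.dual_affiliation_prob:
            rest = [j for j in range(n_labels) if labels[j] != first]
            p_rest = probs[rest]
            total = p_rest.sum()
            p_rest = np.full(len(rest), 1.0 / len(rest)) if total == 0 else p_rest / total
            fields.add(labels[rng.choice(len(rest), p=p_rest)])
        field_map[tid] = frozenset(fields)
        quality[i] = np.mean([deltas[f] for f in fields]) + rng.standard_normal()

    lo, hi = config.benchmark_size_range
    members = [
        rng.choice(config.n_tools, size=int(rng.integers(lo, hi + 1)), replace=False)
        for _ in range(config.n_benchmarks)
    ]
    # the corpus contract requires every tool in >=1 benchmark; place any
    # uncovered tool into a random benchmark before ranking
    covered = np.zeros(config.n_tools, dtype=bool)
    for m in members:
        covered[m] = True
    for i in np.nonzero(~covered)[0]:
        b = int(rng.integers(config.n_benchmarks))
        members[b] = np.append(members[b], i)

    benchmarks = []
    for b, m in enumerate(members):
        observed = quality[m] + rng.normal(0.0, config.noise_sd, size=len(m))
        order = np.argsort(-observed, kind="stable")  # rank 1 = best
        entries = tuple(
            (tool_ids[m[j]], rank) for rank, j in enumerate(order, start=1)
        )
        benchmarks.append(
            BenchmarkRanking(
                benchmark_id=f"B{b + 1:04d}",
                publication_id=f"P{b // 2 + 1:04d}",
                metric_name=_METRICS[b % len(_METRICS)],
                entries=entries,
            )
        )

    tools = tuple(
        ToolRecord(tool_id=tid, tool_name=f"tool_{tid[1:]}", raw_fields=tuple(sorted(field_map[tid])))
        for tid in tool_ids
    )
    corpus = Corpus(tools=tools, benchmarks=tuple(benchmarks))
    return corpus, field_map, deltas


def generate_corpus(
    config: SimulationConfig,
) -> tuple[Corpus, dict[str, frozenset[str]], dict[str, float]]:
    """Generate one corpus plus its field map and ground-truth deltas.

    Deterministic in ``config.seed``: regenerating with the same config
    yields a byte-identical corpus.  The returned corpus satisfies all
    corpus invariants and is clean under ``validate_corpus`` (benchmark
    sizes stay inside the configured range except when coverage repair adds
    a tool to a full benchmark, which is vanishingly rare at realistic
    sizes).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    return _generate(config, rng)


def generate_null_ensemble(
    config: SimulationConfig, n_corpora: int
) -> Iterator[tuple[Corpus, dict[str, frozenset[str]], dict[str, float]]]:
    """Independent null corpora for calibration studies (type-I error).

    Requires every delta to be zero; raises otherwise.  Corpus *i* is a
    pure function of ``(config.seed, i)`` via spawned seed streams.
    """
    if any(v != 0.0 for v in config.deltas.values()):
        raise ValueError("null ensemble requires all field effects to be zero")
    children = np.random.SeedSequence(config.seed).spawn(n_corpora)
    for child in children:
        yield _generate(config, np.random.default_rng(child))
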