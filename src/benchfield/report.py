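"""End-to-end orchestration and publication-style tables.

``run_analysis`` wires the stages together: read corpus -> map fields ->
size-filter -> bootstrap -> summarise (FDR applied within each hierarchy
level) -> intersections, and writes ``summaries.tsv``, ``intersections.tsv``
and a JSON run log echoing the configuration and seed, so every run is
reproducible from its log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import bootstrap as bs
from . import corpus as cm
from . import taxonomy as tx
from .intersections import exclusive_intersections, top_k_sets

__all__ = ["RunConfig", "StageError", "run_analysis", "forest_table",
           "summaries_frame", "intersections_frame"]

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "level", "field", "n_tools", "mean_win_prop", "ci_low", "ci_high",
    "z", "neg_z", "p_raw", "p_fdr", "n_replicates_observed",
]
INTERSECTION_COLUMNS = ["level", "combination", "count"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one full analysis run."""

    corpus_dir: Path
    out_dir: Path
    taxonomy_path: Path | None = None
    levels: tuple[tx.Level, ...] = ("specific", "general", "expertise")
    n_replicates: int = bs.DEFAULT_N_REPLICATES
    sample_size: int = bs.DEFAULT_SAMPLE_SIZE
    min_field_size: int = tx.DEFAULT_MIN_FIELD_SIZE
    seed: int = 0
    two_sided: bool = False

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.sample_size < 1 or self.min_field_size < 1:
            raise ValueError(
                "n_replicates, sample_size and min_field_size must all be >= 1"
            )
        for level in self.levels:
            if level not in tx.LEVELS:
                raise ValueError(f"unknown level {level!r}")

    def to_jsonable(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["corpus_dir"] = str(self.corpus_dir)
        d["out_dir"] = str(self.out_dir)
        d["taxonomy_path"] = None if self.taxonomy_path is None else str(self.taxonomy_path)
        d["levels"] = list(self.levels)
        return d


def summaries_frame(summaries: Iterable[bs.BootstrapSummary]) -> pd.DataFrame:
    rows = [
        {
            "level": s.level,
            "field": s.field_label,
            "n_tools": s.n_tools,
            "mean_win_prop": s.mean_win_prop,
            "ci_low": s.ci_low,
            "ci_high": s.ci_high,
            "z": s.z,
            "neg_z": s.neg_z,
            "p_raw": s.p_raw,
            "p_fdr": s.p_fdr,
            "n_replicates_observed": s.n_replicates_observed,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def forest_table(
    summaries: Sequence[bs.BootstrapSummary], level: tx.Level
) -> pd.DataFrame:
    """Forest-plot table rows for one level, best mean win proportion first."""
    ordered = sorted(
        (s for s in summaries if s.level == level),
        key=lambda s: (-s.mean_win_prop, s.field_label),
    )
    return summaries_frame(ordered)


def intersections_frame(
    assignments: Sequence[tx.FieldAssignment],
    levels: Iterable[tx.Level],
    top_k: int | None = None,
) -> pd.DataFrame:
    rows = []
    for level in levels:
        counts = exclusive_intersections(assignments, level)
        if top_k is not None:
            counts = top_k_sets(counts, top_k)
        else:
            counts = sorted(counts, key=lambda c: (-c.count, c.label))
        rows += [
            {"level": level, "combination": c.label, "count": c.count} for c in counts
        ]
    return pd.DataFrame(rows, columns=INTERSECTION_COLUMNS)


def run_analysis(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline; returns the written output paths.

    Any stage failure is re-raised as :class:`StageError` naming the stage,
    and partially written outputs are removed first.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "summaries": out / "summaries.tsv",
        "intersections": out / "intersections.tsv",
        "log": out / "run_log.json",
    }
    written: list[Path] = []
    try:
        try:
            corpus_dir = Path(config.corpus_dir)
            corpus = cm.read_corpus(
                corpus_dir / "tools.tsv",
                corpus_dir / "benchmarks.tsv",
                corpus_dir / "rankings.tsv",
            )
            findings = cm.validate_corpus(corpus)
            for f in findings:
                logger.warning("validation: %s %s: %s", f.kind, f.subject, f.message)
        except Exception as exc:
            raise StageError("read_corpus", exc) from exc

        try:
            taxonomy = (
                tx.default_taxonomy()
                if config.taxonomy_path is None
                else tx.load_taxonomy(config.taxonomy_path)
            )
            assignments = tx.assign_all(corpus.tools, taxonomy)
        except Exception as exc:
            raise StageError("field_mapping", exc) from exc

        try:
            level_seeds = np.random.SeedSequence(config.seed).spawn(len(config.levels))
            all_summaries: list[bs.BootstrapSummary] = []
            for level, level_seed in zip(config.levels, level_seeds):
                eligible = tx.filter_fields_by_size(
                    assignments, level, min_n=config.min_field_size
                )
                dists = bs.run_bootstrap(
                    corpus,
                    tx.labels_at_level(assignments, level),
                    level=level,
                    n_replicates=config.n_replicates,
                    sample_size=config.sample_size,
                    seed=level_seed,
                    eligible_fields=eligible,
                )
                all_summaries += bs.summarize_all(dists, two_sided=config.two_sided)
        except Exception as exc:
            raise StageError("bootstrap", exc) from exc

        try:
            frames = [forest_table(all_summaries, level) for level in config.levels]
            summaries_df = pd.concat(frames, ignore_index=True)
            summaries_df.to_csv(paths["summaries"], sep="\t", index=False)
            written.append(paths["summaries"])

            inter_df = intersections_frame(assignments, config.levels)
            inter_df.to_csv(paths["intersections"], sep="\t", index=False)
            written.append(paths["intersections"])

            log = {"config": config.to_jsonable(), "seed": config.seed,
                   "n_tools": corpus.n_tools, "n_benchmarks": corpus.n_benchmarks,
                   "validation_findings": len(findings)}
            paths["log"].write_text(json.dumps(log, indent=2) + "\n", encoding="utf-8")
            written.append(paths["log"])
        except Exception as exc:
            raise StageError("write_outputs", exc) from exc
    except StageError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return paths
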