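"""Benchmark-corpus data model and delimited-file I/O.

A corpus couples two things: the software tools (each carrying the raw
department/field strings of its corresponding author, at most two) and the
benchmark rankings that ordered subsets of those tools by some accuracy
metric.  Everything downstream — field mapping, pairwise-win bootstraps,
set intersections — consumes this container.

The on-disk form is three UTF-8 tab-delimited tables:

``tools.tsv``
    columns ``tool_id``, ``tool_name``, ``raw_fields`` (semicolon-separated,
    at most two entries).
``benchmarks.tsv``
    columns ``benchmark_id``, ``publication_id``, ``metric_name``
    (``.`` for a missing metric name).
``rankings.tsv``
    columns ``benchmark_id``, ``tool_id``, ``rank`` (positive integer;
    rank 1 is best, equal ranks denote ties).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ToolRecord",
    "BenchmarkRanking",
    "Corpus",
    "CorpusError",
    "SchemaError",
    "ReferentialIntegrityError",
    "ValidationFinding",
    "read_corpus",
    "write_corpus",
    "validate_corpus",
    "convert_deposited_repo",
]

TOOLS_COLUMNS = ["tool_id", "tool_name", "raw_fields"]
BENCHMARKS_COLUMNS = ["benchmark_id", "publication_id", "metric_name"]
RANKINGS_COLUMNS = ["benchmark_id", "tool_id", "rank"]

#: benchmark sizes observed in the curated corpus; outside this range is a
#: validation warning, not an error
SIZE_RANGE = (3, 50)
MAX_AFFILIATIONS = 2
MISSING = "."


class CorpusError(ValueError):
    """Base class for corpus construction/parsing failures."""


class SchemaError(CorpusError):
    """A required column is missing or a cell cannot be parsed."""


class ReferentialIntegrityError(CorpusError):
    """A ranking references a tool that does not exist, or a tool is orphaned."""


@dataclass(frozen=True)
class ToolRecord:
    """One software tool and its corresponding author's raw affiliation fields."""

    tool_id: str
    tool_name: str
    raw_fields: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.tool_id:
            raise CorpusError("tool_id must be non-empty")
        if len(self.raw_fields) < 1:
            raise CorpusError(f"tool {self.tool_id!r}: at least one raw field required")


@dataclass(frozen=True)
class BenchmarkRanking:
    """One benchmark's ordered tool ranks, with metric provenance.

    ``entries`` is an ordered tuple of ``(tool_id, rank)``; rank 1 is best
    and equal integer ranks represent ties.
    """

    benchmark_id: str
    publication_id: str
    metric_name: str
    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        # canonical entry order (rank, then tool_id) so equality and file
        # round-trips are insensitive to input row order
        object.__setattr__(
            self, "entries", tuple(sorted(self.entries, key=lambda e: (e[1], e[0])))
        )
        if len(self.entries) < 2:
            raise CorpusError(
                f"benchmark {self.benchmark_id!r}: needs >=2 ranked tools, "
                f"got {len(self.entries)}"
            )
        seen: set[str] = set()
        for tool_id, rank in self.entries:
            if rank < 1:
                raise CorpusError(
                    f"benchmark {self.benchmark_id!r}: rank {rank} for "
                    f"{tool_id!r} is not a positive integer"
                )
            if tool_id in seen:
                raise CorpusError(
                    f"benchmark {self.benchmark_id!r}: tool {tool_id!r} ranked twice"
                )
            seen.add(tool_id)

    @property
    def tool_ids(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.entries)

    @property
    def ranks(self) -> tuple[int, ...]:
        return tuple(r for _, r in self.entries)

    @property
    def n_tools(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class Corpus:
    """A validated collection of tools and the benchmarks that rank them.

    Construction enforces referential integrity in both directions: every
    tool_id referenced by a benchmark must exist, and every tool must appear
    in at least one benchmark.  Integrity violations raise; they are never
    silently repaired.
    """

    tools: tuple[ToolRecord, ...]
    benchmarks: tuple[BenchmarkRanking, ...]
    _tool_index: Mapping[str, ToolRecord] = field(
        init=False, repr=False, compare=False, default=None  # type: ignore[assignment]
    )

    def __post_init__(self) -> None:
        index: dict[str, ToolRecord] = {}
        for tool in self.tools:
            if tool.tool_id in index:
                raise CorpusError(f"duplicate tool_id {tool.tool_id!r}")
            index[tool.tool_id] = tool
        dangling = sorted(
            {
                tid
                for bm in self.benchmarks
                for tid in bm.tool_ids
                if tid not in index
            }
        )
        if dangling:
            raise ReferentialIntegrityError(
                "rankings reference unknown tool_ids: " + ", ".join(dangling)
            )
        ranked = {tid for bm in self.benchmarks for tid in bm.tool_ids}
        orphans = sorted(set(index) - ranked)
        if orphans:
            raise ReferentialIntegrityError(
                "tools appear in no benchmark: " + ", ".join(orphans)
            )
        bm_ids = [bm.benchmark_id for bm in self.benchmarks]
        if len(set(bm_ids)) != len(bm_ids):
            raise CorpusError("duplicate benchmark_id")
        object.__setattr__(self, "_tool_index", index)

    @property
    def n_tools(self) -> int:
        return len(self.tools)

    @property
    def n_benchmarks(self) -> int:
        return len(self.benchmarks)

    def tool(self, tool_id: str) -> ToolRecord:
        return self._tool_index[tool_id]

    def benchmarks_of_tool(self) -> dict[str, list[BenchmarkRanking]]:
        """Map each tool_id to the benchmarks that rank it (corpus order)."""
        out: dict[str, list[BenchmarkRanking]] = {t.tool_id: [] for t in self.tools}
        for bm in self.benchmarks:
            for tid in bm.tool_ids:
                out[tid].append(bm)
        return out


@dataclass(frozen=True)
class ValidationFinding:
    """A non-fatal observation about a corpus (reported, never repaired)."""

    kind: str
    subject: str
    message: str


def _require_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _read_tsv(path: Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, required, path)
    return df


def read_corpus(
    tools_path: str | Path,
    benchmarks_path: str | Path,
    rankings_path: str | Path,
) -> Corpus:
    """Read the three-table TSV corpus into a validated :class:`Corpus`.

    Raw field strings are preserved verbatim (including internal case and
    spacing); normalisation is the taxonomy layer's job.

    Raises
    ------
    SchemaError
        if a required column is absent or a rank fails to parse.
    ReferentialIntegrityError
        if a ranking references an unknown tool_id.
    """
    tools_df = _read_tsv(Path(tools_path), TOOLS_COLUMNS)
    bm_df = _read_tsv(Path(benchmarks_path), BENCHMARKS_COLUMNS)
    rk_df = _read_tsv(Path(rankings_path), RANKINGS_COLUMNS)

    tools = []
    for row in tools_df.itertuples(index=False):
        raw = tuple(s.strip() for s in str(row.raw_fields).split(";") if s.strip())
        tools.append(ToolRecord(str(row.tool_id), str(row.tool_name), raw))

    entries_by_bm: dict[str, list[tuple[str, int]]] = {}
    for row in rk_df.itertuples(index=False):
        try:
            rank = int(row.rank)
        except (TypeError, ValueError) as exc:
            raise SchemaError(
                f"{rankings_path}: rank {row.rank!r} for tool {row.tool_id!r} "
                "is not an integer"
            ) from exc
        entries_by_bm.setdefault(str(row.benchmark_id), []).append(
            (str(row.tool_id), rank)
        )

    benchmarks = []
    for row in bm_df.itertuples(index=False):
        bid = str(row.benchmark_id)
        entries = entries_by_bm.pop(bid, None)
        if entries is None:
            raise ReferentialIntegrityError(
                f"benchmark {bid!r} declared in {benchmarks_path} has no rankings"
            )
        benchmarks.append(
            BenchmarkRanking(
                benchmark_id=bid,
                publication_id=str(row.publication_id),
                metric_name=str(row.metric_name),
                entries=tuple(entries),
            )
        )
    if entries_by_bm:
        raise ReferentialIntegrityError(
            "rankings reference undeclared benchmark_ids: "
            + ", ".join(sorted(entries_by_bm))
        )
    return Corpus(tools=tuple(tools), benchmarks=tuple(benchmarks))


def write_corpus(corpus: Corpus, out_dir: str | Path) -> dict[str, Path]:
    """Write a corpus as the three TSV tables; returns the written paths.

    Output is byte-stable: fixed column order, rows in lexicographic key
    order, and cells containing tabs/newlines quoted per the csv dialect so
    that ``read_corpus(write_corpus(c))`` reproduces ``c`` exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tools": out / "tools.tsv",
        "benchmarks": out / "benchmarks.tsv",
        "rankings": out / "rankings.tsv",
    }

    tools_rows = sorted(
        (t.tool_id, t.tool_name, ";".join(t.raw_fields)) for t in corpus.tools
    )
    bm_rows = sorted(
        (b.benchmark_id, b.publication_id, b.metric_name) for b in corpus.benchmarks
    )
    rk_rows = sorted(
        (b.benchmark_id, tid, str(rank))
        for b in corpus.benchmarks
        for tid, rank in b.entries
    )

    for key, header, rows in (
        ("tools", TOOLS_COLUMNS, tools_rows),
        ("benchmarks", BENCHMARKS_COLUMNS, bm_rows),
        ("rankings", RANKINGS_COLUMNS, rk_rows),
    ):
        with open(paths[key], "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(header)
            writer.writerows(rows)
    return paths


def validate_corpus(corpus: Corpus) -> list[ValidationFinding]:
    """Report non-fatal findings; an empty list means a clean corpus.

    Warns about benchmarks outside the 3–50 size range seen in the curated
    corpus, and tools carrying more than two raw affiliation fields (the
    curation rule keeps only the first two addresses).  Never mutates.
    """
    findings: list[ValidationFinding] = []
    lo, hi = SIZE_RANGE
    for bm in corpus.benchmarks:
        n = bm.n_tools
        if not lo <= n <= hi:
            findings.append(
                ValidationFinding(
                    kind="benchmark_size",
                    subject=bm.benchmark_id,
                    message=f"benchmark ranks {n} tools, outside the usual {lo}-{hi} range",
                )
            )
    for tool in corpus.tools:
        if len(tool.raw_fields) > MAX_AFFILIATIONS:
            findings.append(
                ValidationFinding(
                    kind="affiliation_count",
                    subject=tool.tool_id,
                    message=(
                        f"tool lists {len(tool.raw_fields)} affiliation fields; "
                        f"only the first {MAX_AFFILIATIONS} are used"
                    ),
                )
            )
    return findings


def convert_deposited_repo(repo_dir: str | Path, out_dir: str | Path) -> dict[str, Path]:
    """Convert a checkout of the original curated-corpus repository.

    Stub: the upstream repository's file layout must be inspected against a
    live checkout before this converter can be written; it is not derivable
    from the published description alone.  Raises ``NotImplementedError``
    with pointers for completing the conversion by hand (produce the three
    TSV tables documented in this module, then ``read_corpus`` them).
    """
    raise NotImplementedError(
        "Write tools.tsv / benchmarks.tsv / rankings.tsv (see module docstring) "
        f"from the files in {repo_dir!s}, then load them with read_corpus(). "
        "The upstream layout is not machine-specified, so this step is manual."
    )
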