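"""Mapping raw department strings to a field-of-study hierarchy.

Affiliation strings are analysed at three hierarchical levels, following the
NSF "fields of study" classification:

* **specific** fields (Genetics, Computer Science, Bioinformatics, ...),
  reached from raw strings through a curated synonym map
  (e.g. "Computational Biology" collapses to "Bioinformatics");
* **general** fields (Biological Sciences, Computer Sciences, ...), each
  specific field belonging to exactly one;
* **expertise** classes: *development* (computational / mathematical /
  engineering fields), *domain* (biological and health sciences), and
  *interdisciplinary* — either an inherently interdisciplinary specific
  field (bioinformatics, biostatistics, ...) or a dual affiliation spanning
  both development and domain.

The taxonomy ships as an editable TSV (``data/taxonomy.tsv``) so users can
extend the synonym map or re-seat contested fields without touching code.
Unknown field names fail loudly: silently bucketing them would corrupt the
downstream win tallies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Collection, Iterable, Literal, Mapping

import pandas as pd

from .corpus import ToolRecord

__all__ = [
    "Level",
    "Expertise",
    "Taxonomy",
    "FieldAssignment",
    "TaxonomyError",
    "UnmappedFieldError",
    "load_taxonomy",
    "default_taxonomy",
    "normalize_field_name",
    "classify_expertise",
    "assign_fields",
    "assign_all",
    "labels_at_level",
    "filter_fields_by_size",
]

Level = Literal["specific", "general", "expertise"]
LEVELS: tuple[Level, ...] = ("specific", "general", "expertise")

Expertise = Literal["development", "domain", "interdisciplinary"]
BASE_CLASSES = frozenset({"development", "domain"})

DEFAULT_MIN_FIELD_SIZE = 10


class TaxonomyError(ValueError):
    """Malformed taxonomy table."""


class UnmappedFieldError(KeyError):
    """A raw field string has no entry in the taxonomy.

    Carries the offending raw string so the caller can decide whether to
    extend the taxonomy file or exclude the tool.
    """

    def __init__(self, raw: str):
        super().__init__(raw)
        self.raw = raw

    def __str__(self) -> str:  # KeyError quotes its arg; keep it readable
        return f"field name not in taxonomy: {self.raw!r}"


def _canon_key(raw: str) -> str:
    """Case-insensitive, whitespace-collapsed lookup key."""
    return re.sub(r"\s+", " ", raw.strip()).casefold()


@dataclass(frozen=True)
class Taxonomy:
    """Synonym, hierarchy and expertise maps for fields of study."""

    synonym_map: Mapping[str, str]  # canon_key(raw or alias) -> canonical specific
    specific_to_general: Mapping[str, str]
    general_to_base: Mapping[str, str]  # general field -> development | domain
    interdisciplinary_specifics: frozenset[str]

    def __post_init__(self) -> None:
        bad = set(self.general_to_base.values()) - BASE_CLASSES
        if bad:
            raise TaxonomyError(f"unknown expertise base class(es): {sorted(bad)}")
        stray = self.interdisciplinary_specifics - set(self.specific_to_general)
        if stray:
            raise TaxonomyError(
                f"interdisciplinary fields missing from hierarchy: {sorted(stray)}"
            )

    @property
    def specific_fields(self) -> frozenset[str]:
        return frozenset(self.specific_to_general)

    def base_class_of_specific(self, specific: str) -> str:
        return self.general_to_base[self.specific_to_general[specific]]


@dataclass(frozen=True)
class FieldAssignment:
    """A tool's fields at all three hierarchy levels."""

    tool_id: str
    specific_fields: frozenset[str]
    general_fields: frozenset[str]
    expertise: Expertise

    def at_level(self, level: Level) -> frozenset[str]:
        if level == "specific":
            return self.specific_fields
        if level == "general":
            return self.general_fields
        if level == "expertise":
            return frozenset({self.expertise})
        raise ValueError(f"unknown level {level!r}")


def load_taxonomy(path: str | Path) -> Taxonomy:
    """Load a taxonomy TSV (see ``data/taxonomy.tsv`` for the schema)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["canonical_specific", "general", "base_class", "interdisciplinary_flag"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TaxonomyError(f"{path}: missing column(s): {', '.join(missing)}")

    synonym_map: dict[str, str] = {}
    specific_to_general: dict[str, str] = {}
    general_to_base: dict[str, str] = {}
    interdisciplinary: set[str] = set()

    for row in df.itertuples(index=False):
        specific = row.canonical_specific.strip()
        general = row.general.strip()
        base = row.base_class.strip()
        if base not in BASE_CLASSES:
            raise TaxonomyError(
                f"{path}: {specific!r} has base_class {base!r}; "
                f"expected one of {sorted(BASE_CLASSES)}"
            )
        if specific in specific_to_general:
            raise TaxonomyError(f"{path}: duplicate canonical field {specific!r}")
        if general in general_to_base and general_to_base[general] != base:
            raise TaxonomyError(
                f"{path}: general field {general!r} assigned conflicting base classes"
            )
        specific_to_general[specific] = general
        general_to_base[general] = base
        if row.interdisciplinary_flag.strip() == "1":
            interdisciplinary.add(specific)
        aliases = [specific]
        syn_cell = getattr(row, "synonyms", "") or ""
        aliases += [s for s in syn_cell.split(";") if s.strip()]
        for alias in aliases:
            key = _canon_key(alias)
            prior = synonym_map.get(key)
            if prior is not None and prior != specific:
                raise TaxonomyError(
                    f"{path}: alias {alias!r} maps to both {prior!r} and {specific!r}"
                )
            synonym_map[key] = specific

    return Taxonomy(
        synonym_map=synonym_map,
        specific_to_general=specific_to_general,
        general_to_base=general_to_base,
        interdisciplinary_specifics=frozenset(interdisciplinary),
    )


def default_taxonomy() -> Taxonomy:
    """The taxonomy shipped with the package (fields named in the study)."""
    ref = resources.files("benchfield").joinpath("data/taxonomy.tsv")
    with resources.as_file(ref) as path:
        return load_taxonomy(path)


def normalize_field_name(raw: str, taxonomy: Taxonomy) -> str:
    """Resolve a raw department string to its canonical specific field.

    Lookup is case- and whitespace-insensitive and goes through the synonym
    map, so "  computational biology " resolves to "Bioinformatics".

    Raises :class:`UnmappedFieldError` for names absent from the taxonomy.
    """
    try:
        return taxonomy.synonym_map[_canon_key(raw)]
    except KeyError:
        raise UnmappedFieldError(raw) from None


def classify_expertise(
    specific_fields: Collection[str], taxonomy: Taxonomy
) -> Expertise:
    """Classify a set of canonical specific fields into an expertise class.

    Interdisciplinary if any field is inherently interdisciplinary, or if
    the fields span both the development and domain base classes; otherwise
    the single shared base class.  Two fields of the same base class stay in
    that base class.
    """
    fields = set(specific_fields)
    if not fields:
        raise ValueError("classify_expertise: empty field set")
    if fields & taxonomy.interdisciplinary_specifics:
        return "interdisciplinary"
    bases = {taxonomy.base_class_of_specific(f) for f in fields}
    if len(bases) > 1:
        return "interdisciplinary"
    return next(iter(bases))  # type: ignore[return-value]


def assign_fields(tool: ToolRecord, taxonomy: Taxonomy) -> FieldAssignment:
    """Map a tool's raw affiliation strings through the full hierarchy.

    Only the first two raw fields are used (the curation rule for authors
    listing many addresses).  Propagates :class:`UnmappedFieldError`.
    """
    raw = tool.raw_fields[:2]
    specific = frozenset(normalize_field_name(r, taxonomy) for r in raw)
    general = frozenset(taxonomy.specific_to_general[s] for s in specific)
    expertise = classify_expertise(specific, taxonomy)
    return FieldAssignment(
        tool_id=tool.tool_id,
        specific_fields=specific,
        general_fields=general,
        expertise=expertise,
    )


def assign_all(
    tools: Iterable[ToolRecord], taxonomy: Taxonomy
) -> list[FieldAssignment]:
    return [assign_fields(t, taxonomy) for t in tools]


def labels_at_level(
    assignments: Iterable[FieldAssignment], level: Level
) -> dict[str, frozenset[str]]:
    """tool_id -> set of field labels at the requested hierarchy level."""
    return {a.tool_id: a.at_level(level) for a in assignments}


def filter_fields_by_size(
    assignments: Iterable[FieldAssignment],
    level: Level,
    min_n: int = DEFAULT_MIN_FIELD_SIZE,
) -> frozenset[str]:
    """Fields carried by at least ``min_n`` distinct tools at ``level``.

    Counting happens once, on the full corpus, before any resampling — the
    small-field filter is a property of the corpus, not of a bootstrap
    replicate.
    """
    counts: dict[str, set[str]] = {}
    for a in assignments:
        for label in a.at_level(level):
            counts.setdefault(label, set()).add(a.tool_id)
    return frozenset(label for label, tools in counts.items() if len(tools) >= min_n)
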