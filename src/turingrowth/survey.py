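"""Data model and tallies for the classic-vs-growth pattern survey.

Each taxon record carries two four-level labels (does the group show a
classic Turing colour pattern; does it show a growth-generated one):
``Y`` (at least one species with a clear pattern), ``M`` (maybe - a
potential but unclear pattern), ``N?`` (none found, search not exhaustive),
``N`` (none found, search near-exhaustive).  A growth-pattern ``Y`` must
cite at least one of the four growth-pattern categories (rosettes,
intermediate bands, mixed colours, line-and-dots), involve at least three
motifs and not derive from a pre-existing periodicity (body segments,
petals...).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "LABELS",
    "CATEGORIES",
    "PatternRecord",
    "validate_record",
    "tally_labels",
    "export_tree_annotation",
    "read_records_csv",
    "write_records_csv",
]

LABELS = ("Y", "M", "N?", "N")
CATEGORIES = frozenset({"rosettes", "intermediate_bands", "mixed_colors", "line_and_dots"})

#: Leaf colours for tree annotation (growth pattern dominates classic).
_COLORS = {
    "growth_yes": "#e6b800",     # yellow: growth pattern in >= 1 species
    "growth_maybe": "#f2dd88",   # pale yellow
    "classic_yes": "#2c7fb8",   # blue: only classic patterns
    "classic_maybe": "#a6cbe3", # pale blue
    "none": "#bdbdbd",          # grey: no Turing-like pattern found
}


@dataclass(frozen=True)
class PatternRecord:
    taxon: str
    rank: str = "order"
    example_species: str | None = None
    classic_label: str = "N?"
    growth_label: str = "N?"
    categories: frozenset[str] = frozenset()
    motif_count_at_least_3: bool = False
    based_on_preexisting_periodicity: bool = False
    evidence_url: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "categories", frozenset(self.categories))


def validate_record(record: PatternRecord) -> list[str]:
    """All invariant violations of a record (empty list means valid).

    Violations are data, not exceptions: a survey database is validated in
    bulk and the offending rules reported per record.
    """
    violations = []
    for fieldname, label in (("classic_label", record.classic_label),
                             ("growth_label", record.growth_label)):
        if label not in LABELS:
            violations.append(f"{fieldname}: {label!r} not in four-level scheme {LABELS}")
    unknown = record.categories - CATEGORIES
    if unknown:
        violations.append(f"unknown categories: {sorted(unknown)}")
    if record.growth_label == "Y":
        if not record.categories:
            violations.append("category rule: a growth-pattern 'Y' needs at least one "
                              "of the four growth-pattern categories")
        if not record.motif_count_at_least_3:
            violations.append("periodicity criterion: a pattern needs at least three motifs")
        if record.based_on_preexisting_periodicity:
            violations.append("criterion ii: pattern must not be based on a pre-existing "
                              "periodicity")
    return violations


def _format_pct(p: float) -> str:
    """Percentages at survey precision: integers, except one decimal below 5%."""
    return f"{p:.1f}" if p < 5 else f"{p:.0f}"


def tally_labels(records: Sequence[PatternRecord], group_by_rank: str | None = None) -> pd.DataFrame:
    """Counts and percentages of each label combination.

    Returns one row per (rank, classic label, growth-pattern label) with the
    count, the percentage of the rank's records, and the percentage string
    at survey precision (integer unless < 5%, then one decimal).
    """
    if not records:
        raise ValueError("empty record set")
    if group_by_rank is not None:
        records = [r for r in records if r.rank == group_by_rank]
        if not records:
            raise ValueError(f"no records with rank {group_by_rank!r}")
    df = pd.DataFrame(
        dict(rank=r.rank, classic=r.classic_label, growth=r.growth_label) for r in records
    )
    out = []
    for rank, grp in df.groupby("rank"):
        total = len(grp)
        combos = grp.groupby(["classic", "growth"]).size().reset_index(name="count")
        for row in combos.itertuples():
            pct = 100.0 * row.count / total
            out.append(dict(rank=rank, classic=row.classic, growth=row.growth,
                            count=row.count, total=total, percent=pct,
                            percent_str=_format_pct(pct)))
    return pd.DataFrame(out)


def tally_positive(records: Sequence[PatternRecord], label_field: str = "growth_label",
                   group_by_rank: str | None = None) -> dict:
    """Share of records whose ``label_field`` is 'Y' (survey headline numbers)."""
    if not records:
        raise ValueError("empty record set")
    if group_by_rank is not None:
        records = [r for r in records if r.rank == group_by_rank]
        if not records:
            raise ValueError(f"no records with rank {group_by_rank!r}")
    positive = sum(1 for r in records if getattr(r, label_field) == "Y")
    pct = 100.0 * positive / len(records)
    return dict(positive=positive, total=len(records), percent=pct,
                percent_str=_format_pct(pct))


def _leaf_color(record: PatternRecord) -> str:
    if record.growth_label == "Y":
        return _COLORS["growth_yes"]
    if record.growth_label == "M":
        return _COLORS["growth_maybe"]
    if record.classic_label == "Y":
        return _COLORS["classic_yes"]
    if record.classic_label == "M":
        return _COLORS["classic_maybe"]
    return _COLORS["none"]


def export_tree_annotation(records: Sequence[PatternRecord]) -> str:
    """Leaf colour annotation text (taxon<TAB>hex colour, one per leaf).

    Growth-pattern label takes precedence over the classic one; 'maybe'
    classes map to lighter shades; everything else is grey.  Duplicate taxon
    names are an error (tree leaves must be unique).
    """
    names = [r.taxon for r in records]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise ValueError(f"duplicate taxon names: {dupes}")
    return "\n".join(f"{r.taxon}\t{_leaf_color(r)}" for r in records) + "\n"


# ---------------------------------------------------------------------------
# CSV storage (one record per row; categories semicolon-joined)
# ---------------------------------------------------------------------------

_CSV_FIELDS = ["taxon", "rank", "example_species", "classic_label", "growth_label",
               "categories", "motif_count_at_least_3",
               "based_on_preexisting_periodicity", "evidence_url"]


def write_records_csv(records: Iterable[PatternRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        writer.writeheader()
        for r in records:
            writer.writerow(dict(
                taxon=r.taxon, rank=r.rank, example_species=r.example_species or "",
                classic_label=r.classic_label, growth_label=r.growth_label,
                categories=";".join(sorted(r.categories)),
                motif_count_at_least_3=int(r.motif_count_at_least_3),
                based_on_preexisting_periodicity=int(r.based_on_preexisting_periodicity),
                evidence_url=r.evidence_url or "",
            ))


def read_records_csv(path: str | Path) -> list[PatternRecord]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_CSV_FIELDS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"records CSV missing columns: {sorted(missing)}")
        out = []
        for row in reader:
            cats = frozenset(c for c in row["categories"].split(";") if c)
            out.append(PatternRecord(
                taxon=row["taxon"], rank=row["rank"],
                example_species=row["example_species"] or None,
                classic_label=row["classic_label"], growth_label=row["growth_label"],
                categories=cats,
                motif_count_at_least_3=row["motif_count_at_least_3"] in ("1", "True", "true"),
                based_on_preexisting_periodicity=row["based_on_preexisting_periodicity"]
                in ("1", "True", "true"),
                evidence_url=row["evidence_url"] or None,
            ))
    return out
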