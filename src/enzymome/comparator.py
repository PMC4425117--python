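"""Three-section comparison of the enzyme content of two microbiome groups.

Enzyme identity is EC-number string equality, nothing else: two organisms
"share" an enzyme exactly when both carry a CDS annotated with the same EC
number, regardless of product-name spelling or sequence.  An EC present in
both groups is *identical*; present only in group A, *unique-A*; only in
group B, *unique-B*.  Every (CDS, EC) row of both groups lands in exactly
one section, and counts are row counts — gene copies are included, so the
numbers are deliberately "inflated" relative to distinct-EC counts.

Partial EC numbers ("1.2.3.-") compare as literal strings; no prefix
semantics, which would silently merge whole enzyme classes.
Low-reliability rows participate fully and carry their flag into the
report; reliability is a column, not a filter.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .enzyme_db import (
    NOT_FOUND_SENTINEL,
    EnzymeRecord,
    ec_sort_key,
    lookup_ec,
    records_by_ec,
)
from .genbank_io import GenomeRecord, extract_enzyme_rows

__all__ = [
    "MicrobiomeGroup",
    "ComparisonRow",
    "ComparisonResult",
    "compare",
    "group_with_multiplicity",
    "stats_diff",
    "store_comparison",
    "load_comparison_rows",
]


@dataclass(frozen=True)
class MicrobiomeGroup:
    """A labeled collection of genomes forming one artificial metagenome."""

    label: str
    genomes: tuple[GenomeRecord, ...]

    @property
    def rows(self) -> list[tuple[str, str, str, int]]:
        """Concatenated (gi, organism, ec, reliability) rows, copies kept."""
        out: list[tuple[str, str, str, int]] = []
        for g in self.genomes:
            out.extend(extract_enzyme_rows(g))
        return out


@dataclass(frozen=True)
class ComparisonRow:
    """One report line: who codes which enzyme, and how reliably."""

    gi: str
    organism: str
    ec: str
    ec_name: str
    biochemistry: str
    reliability: int
    group_label: str


@dataclass(frozen=True)
class ComparisonResult:
    """The three-section classification with row-count statistics."""

    label_a: str
    label_b: str
    identical_rows: tuple[ComparisonRow, ...]
    unique_a_rows: tuple[ComparisonRow, ...]
    unique_b_rows: tuple[ComparisonRow, ...]

    @property
    def counts(self) -> tuple[int, int, int]:
        """(n_identical, n_unique_a, n_unique_b) as row counts."""
        return (len(self.identical_rows), len(self.unique_a_rows),
                len(self.unique_b_rows))


def _report_columns(
    ec: str, enzymes: Mapping[str, EnzymeRecord] | None
) -> tuple[str, str]:
    if enzymes is None:
        return "", ""
    rec = lookup_ec(ec, enzymes)
    if rec is None:
        return NOT_FOUND_SENTINEL, NOT_FOUND_SENTINEL
    # DE/CA lines end in "."; the report shows them without it
    return rec.recommended_name.rstrip("."), rec.catalytic_activity.rstrip(".")


def _sorted_section(rows: list[ComparisonRow]) -> tuple[ComparisonRow, ...]:
    return tuple(sorted(rows, key=lambda r: (ec_sort_key(r.ec), r.organism,
                                             r.gi, r.group_label)))


def compare(
    a: MicrobiomeGroup,
    b: MicrobiomeGroup,
    enzyme_records: Iterable[EnzymeRecord] | Mapping[str, EnzymeRecord] | None = None,
) -> ComparisonResult:
    """Classify every enzyme row of both groups as identical or unique.

    ``enzyme_records``, when given, fills the predominant-name and
    biochemistry columns (unknown ECs get a sentinel).  Sections are
    ordered by EC, then organism.  Groups must carry distinct labels.
    """
    if a.label == b.label:
        raise ValueError(f"group labels must differ (both {a.label!r})")
    if not a.genomes or not b.genomes:
        raise ValueError("both groups need at least one genome")
    enzymes = None
    if enzyme_records is not None:
        enzymes = enzyme_records if isinstance(enzyme_records, Mapping) \
            else records_by_ec(enzyme_records)

    rows_a, rows_b = a.rows, b.rows
    ecs_a = {r[2] for r in rows_a}
    ecs_b = {r[2] for r in rows_b}
    shared = ecs_a & ecs_b

    identical: list[ComparisonRow] = []
    unique_a: list[ComparisonRow] = []
    unique_b: list[ComparisonRow] = []
    for label, rows, unique_bucket in (
            (a.label, rows_a, unique_a), (b.label, rows_b, unique_b)):
        for gi, organism, ec, reliability in rows:
            name, chem = _report_columns(ec, enzymes)
            row = ComparisonRow(gi, organism, ec, name, chem, reliability,
                                label)
            (identical if ec in shared else unique_bucket).append(row)

    return ComparisonResult(
        label_a=a.label,
        label_b=b.label,
        identical_rows=_sorted_section(identical),
        unique_a_rows=_sorted_section(unique_a),
        unique_b_rows=_sorted_section(unique_b),
    )


def group_with_multiplicity(
    rows: Sequence[ComparisonRow],
) -> list[tuple[ComparisonRow, int, str]]:
    """Collapse a section per (ec, organism) into display rows with ``×n``.

    Returns ``(representative_row, count, display_organism)`` triples where
    the organism text carries an ``(×n)`` suffix when n ≥ 2 — the gene-copy
    notation of the report.  Expanding each row ``count`` times reproduces
    the input multiset of (ec, organism) pairs.
    """
    order: list[tuple[str, str]] = []
    groups: dict[tuple[str, str], list[ComparisonRow]] = {}
    for row in rows:
        key = (row.ec, row.organism)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(row)
    out = []
    for key in order:
        members = groups[key]
        n = len(members)
        rep = members[0]
        display = rep.organism if n == 1 else f"{rep.organism} (×{n})"
        out.append((rep, n, display))
    return out


def stats_diff(
    later: tuple[int, int, int],
    earlier: tuple[int, int, int],
) -> tuple[int, int, int]:
    """Componentwise ``later − earlier`` of two (identical, unique-A,
    unique-B) count triples; the approximate number of new results a larger
    query produced over a smaller one.  Signed, may be negative."""
    return tuple(l - e for l, e in zip(later, earlier))  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Relational persistence (embedded sqlite store)

_SCHEMA = """
CREATE TABLE IF NOT EXISTS comparison_rows (
    section TEXT NOT NULL,          -- identical | unique_a | unique_b
    gi TEXT NOT NULL,
    organism TEXT NOT NULL,
    ec TEXT NOT NULL,
    ec_name TEXT,
    biochemistry TEXT,
    reliability INTEGER NOT NULL,
    microbiome TEXT NOT NULL
);
CREATE INDEX IF NOT EXISTS idx_rows_ec ON comparison_rows (ec);
"""


def store_comparison(result: ComparisonResult, db_path: str | Path) -> None:
    """Persist the full three-section result into an embedded sqlite file."""
    con = sqlite3.connect(str(db_path))
    try:
        con.executescript(_SCHEMA)
        con.execute("DELETE FROM comparison_rows")
        for section, rows in (
                ("identical", result.identical_rows),
                ("unique_a", result.unique_a_rows),
                ("unique_b", result.unique_b_rows)):
            con.executemany(
                "INSERT INTO comparison_rows VALUES (?,?,?,?,?,?,?,?)",
                [(section, r.gi, r.organism, r.ec, r.ec_name,
                  r.biochemistry, r.reliability, r.group_label)
                 for r in rows])
        con.commit()
    finally:
        con.close()


def load_comparison_rows(
    db_path: str | Path, section: str | None = None
) -> list[tuple]:
    """Query stored rows back, optionally restricted to one section."""
    con = sqlite3.connect(str(db_path))
    try:
        if section is None:
            cur = con.execute(
                "SELECT * FROM comparison_rows ORDER BY section, ec, organism")
        else:
            cur = con.execute(
                "SELECT * FROM comparison_rows WHERE section = ? "
                "ORDER BY ec, organism", (section,))
        return cur.fetchall()
    finally:
        con.close()
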