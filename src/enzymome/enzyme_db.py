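"""ENZYME (ExPASy) flat-file parsing and the enzyme-name index.

The ENZYME database distributes Enzyme Commission nomenclature as a
line-coded flat file: each entry starts with an ``ID`` line carrying the
EC number, followed by ``DE`` (recommended name), ``AN`` (alternative
names), ``CA`` (catalytic activity) and ``CC`` (comment) lines, and ends
with a ``//`` terminator.  Entries whose DE text reads ``Transferred
entry: ...`` or ``Deleted entry.`` are nomenclature tombstones, not real
enzymes; they are parsed but never enter the name index used for de novo
annotation.

The name index maps normalized enzyme names (recommended and alternative)
to the ascending-sorted set of active EC numbers carrying that name.  A
name shared by several EC entries is data, not an error: it is exactly
what forces the "more than one match" annotation outcome downstream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

logger = logging.getLogger(__name__)

__all__ = [
    "EnzymeRecord",
    "NameIndex",
    "EC_PATTERN",
    "normalize_name",
    "ec_sort_key",
    "is_partial_ec",
    "parse_enzyme_dat",
    "serialize_enzyme_dat",
    "build_name_index",
    "lookup_ec",
    "NOT_FOUND_SENTINEL",
]

#: Four dot-separated fields; the last may be "-" for partial (class-level)
#: EC numbers such as "1.2.3.-" that occur in GenBank files.
EC_PATTERN = re.compile(r"^\d+\.\d+\.\d+\.(?:\d+|-)$")

#: Report-column filler used when an EC number has no record in the database.
NOT_FOUND_SENTINEL = "unknown EC"

_TRANSFERRED_RE = re.compile(r"^Transferred entry:\s*(.*)$", re.IGNORECASE)
_DELETED_RE = re.compile(r"^Deleted entry\.?$", re.IGNORECASE)
_EC_IN_TEXT_RE = re.compile(r"\d+\.\d+\.\d+\.(?:\d+|-)")


@dataclass(frozen=True)
class EnzymeRecord:
    """One EC nomenclature entry.

    ``status`` is ``active`` for real enzymes, ``transferred`` for entries
    renumbered elsewhere (``transfer_targets`` holds the destination ECs)
    and ``deleted`` for withdrawn numbers.
    """

    ec_number: str
    recommended_name: str = ""
    alt_names: tuple[str, ...] = ()
    catalytic_activity: str = ""
    status: str = "active"
    transfer_targets: frozenset[str] = frozenset()

    def names(self) -> tuple[str, ...]:
        """Recommended name followed by alternative names."""
        if self.recommended_name:
            return (self.recommended_name, *self.alt_names)
        return self.alt_names

    @property
    def is_partial(self) -> bool:
        return is_partial_ec(self.ec_number)


@dataclass(frozen=True)
class NameIndex:
    """Mapping from normalized enzyme name to ascending EC numbers.

    Only active records contribute; keys are already normalized, so
    :func:`normalize_name` is a fixed point on them.
    """

    entries: Mapping[str, tuple[str, ...]]
    normalization_rule: str = "lowercase/strip-quotes/strip-trailing-periods/collapse-ws"

    def get(self, name: str) -> tuple[str, ...]:
        """ECs indexed under ``name`` (normalized before lookup)."""
        return self.entries.get(normalize_name(name), ())

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return normalize_name(name) in self.entries

    def items(self):
        return self.entries.items()


def normalize_name(name: str) -> str:
    """Canonical form under which enzyme names are compared.

    Lowercase, surrounding quotes stripped, trailing periods stripped,
    runs of whitespace collapsed to single spaces.  ENZYME DE/AN lines end
    in a period while GenBank /product qualifiers do not; normalization
    makes the two comparable.  The function is idempotent.
    """
    s, prev = name, None
    while s != prev:  # iterate so nested quote/period layers cannot survive
        prev = s
        s = s.strip()
        if len(s) >= 2 and s[0] == s[-1] and s[0] in "\"'":
            s = s[1:-1]
        s = s.rstrip(".")
    s = re.sub(r"\s+", " ", s)
    return s.lower()


def is_partial_ec(ec: str) -> bool:
    """True for class-level EC identifiers ending in '-' (e.g. "1.2.3.-")."""
    return ec.endswith(".-")


def ec_sort_key(ec: str) -> tuple:
    """Numeric sort key for dotted EC identifiers; '-' sorts after digits."""
    parts = []
    for p in ec.split("."):
        parts.append((1, 0) if p == "-" else (0, int(p)))
    return tuple(parts)


# ---------------------------------------------------------------------------
# Flat-file parsing

def _finish_record(
    ec: str,
    de_parts: list[str],
    an_parts: list[str],
    ca_parts: list[str],
) -> EnzymeRecord:
    de = " ".join(" ".join(de_parts).split())
    ca = " ".join(" ".join(ca_parts).split())
    # AN lines: each name ends with "."; one AN line holds one name, but a
    # long name may wrap, in which case continuation lines lack the period.
    alt_names: list[str] = []
    buf = ""
    for part in an_parts:
        buf = f"{buf} {part}".strip() if buf else part
        if buf.endswith("."):
            alt_names.append(buf)
            buf = ""
    if buf:
        alt_names.append(buf)

    m = _TRANSFERRED_RE.match(de)
    if m:
        targets = frozenset(_EC_IN_TEXT_RE.findall(m.group(1)))
        return EnzymeRecord(ec, recommended_name=de, status="transferred",
                            transfer_targets=targets)
    if _DELETED_RE.match(de):
        return EnzymeRecord(ec, recommended_name=de, status="deleted")
    return EnzymeRecord(
        ec,
        recommended_name=de,
        alt_names=tuple(alt_names),
        catalytic_activity=ca,
    )


def parse_enzyme_dat(stream: TextIO | Iterable[str]) -> list[EnzymeRecord]:
    """Parse an ENZYME flat file into :class:`EnzymeRecord` objects.

    Records are ``ID ... //`` blocks; multi-line DE and CA fields are joined
    with single spaces.  A malformed ID line (not a valid EC pattern) is
    logged with its line number and the offending block is skipped; a
    truncated final record (no ``//``) is dropped with a warning.  Header
    material before the first ID line (the real file carries a large CC
    banner) is ignored.
    """
    records: list[EnzymeRecord] = []
    ec: str | None = None
    skipping = False
    de: list[str] = []
    an: list[str] = []
    ca: list[str] = []

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        code = line[:2]
        rest = line[5:] if len(line) > 5 else ""
        if code == "//":
            if ec is not None:
                records.append(_finish_record(ec, de, an, ca))
            ec, skipping = None, False
            de, an, ca = [], [], []
            continue
        if code == "ID":
            if ec is not None:
                logger.warning(
                    "line %d: ID line inside unterminated record %s; "
                    "previous record dropped", lineno, ec)
            ec, skipping = None, False
            de, an, ca = [], [], []
            candidate = rest.strip()
            if EC_PATTERN.match(candidate):
                ec = candidate
            else:
                logger.error(
                    "line %d: malformed ID line %r is not an EC number; "
                    "record skipped", lineno, candidate)
                skipping = True
            continue
        if ec is None or skipping:
            continue
        if code == "DE":
            de.append(rest.strip())
        elif code == "AN":
            an.append(rest.strip())
        elif code == "CA":
            ca.append(rest.strip())
        # CC/PR/DR and anything else: not modeled, ignored.

    if ec is not None:
        logger.warning("truncated final record %s (no '//'); dropped", ec)
    return records


def _wrap_field(code: str, text: str, width: int = 73) -> Iterator[str]:
    words = text.split()
    line = ""
    for w in words:
        if line and len(line) + 1 + len(w) > width:
            yield f"{code}   {line}"
            line = w
        else:
            line = f"{line} {w}".strip()
    if line:
        yield f"{code}   {line}"


def serialize_enzyme_dat(records: Sequence[EnzymeRecord]) -> str:
    """Render records back to the flat-file dialect (inverse of parsing)."""
    out: list[str] = []
    for r in records:
        out.append(f"ID   {r.ec_number}")
        if r.recommended_name:
            out.extend(_wrap_field("DE", r.recommended_name))
        for an in r.alt_names:
            out.extend(_wrap_field("AN", an))
        if r.catalytic_activity:
            out.extend(_wrap_field("CA", r.catalytic_activity))
        out.append("//")
    return "\n".join(out) + ("\n" if out else "")


# ---------------------------------------------------------------------------
# Name index and EC lookup

def build_name_index(
    records: Iterable[EnzymeRecord],
    include_alt_names: bool = True,
) -> NameIndex:
    """Index active records by normalized name.

    Each active record contributes its recommended name and (by default)
    every alternative name.  A key claimed by k distinct ECs maps to all k
    in ascending EC order — collisions are preserved, not resolved.
    Transferred and deleted entries never enter the index.
    """
    raw: dict[str, set[str]] = {}
    for rec in records:
        if rec.status != "active":
            continue
        names = (rec.recommended_name, *rec.alt_names) if include_alt_names \
            else (rec.recommended_name,)
        for name in names:
            key = normalize_name(name)
            if key:
                raw.setdefault(key, set()).add(rec.ec_number)
    entries = {
        key: tuple(sorted(ecs, key=ec_sort_key)) for key, ecs in raw.items()
    }
    return NameIndex(entries=entries)


def lookup_ec(
    ec: str,
    records: Iterable[EnzymeRecord] | Mapping[str, EnzymeRecord],
) -> EnzymeRecord | None:
    """Record for ``ec``, or None when the database has no such entry.

    Fills the "predominant name" / "biochemistry" report columns; callers
    substitute :data:`NOT_FOUND_SENTINEL` for a None result so a missing
    EC never aborts a run.
    """
    if isinstance(records, Mapping):
        return records.get(ec)
    for rec in records:
        if rec.ec_number == ec:
            return rec
    return None


def records_by_ec(records: Iterable[EnzymeRecord]) -> dict[str, EnzymeRecord]:
    """EC-keyed dict for repeated :func:`lookup_ec` calls."""
    return {r.ec_number: r for r in records}
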