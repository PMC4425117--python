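"""GenBank genome I/O: CDS-level enzyme evidence in, updated annotations out.

A genome is one GenBank flat file, possibly holding several LOCUS records
(chromosome plus plasmids); all CDS features across all records are merged
into a single :class:`GenomeRecord` because the comparison treats each
organism as one unit.  Features are opaque annotation carriers here — no
coordinates are interpreted and no sequence is read.

Reading and writing go through Biopython's ``SeqIO`` GenBank codec, which
preserves the legacy ``GI:`` field on the VERSION line in both directions.
De novo annotations written back to a file use the standard ``/EC_number``
qualifier; a CDS whose product name matched more than one enzyme carries at
most three ``/EC_number`` qualifiers plus a machine-readable low-reliability
marker (a ``/note`` with a fixed token) so that re-reading the file restores
the reliability flag exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "CdsFeature",
    "GenomeRecord",
    "MULTI_EC_NOTE",
    "read_genbank",
    "read_genome_dir",
    "extract_enzyme_rows",
    "write_genbank_with_annotations",
    "fetch_genbank",
]

#: Fixed token marking a multi-match (reliability 0) de novo annotation
#: inside a /note qualifier.  Parseable, so round-trips are exact.
MULTI_EC_NOTE = "MULTI-EC-LOW-RELIABILITY"

#: Token marking a unique de novo annotation, so that annotation origin
#: survives a write/read cycle.
DE_NOVO_NOTE = "EC-DE-NOVO"


@dataclass(frozen=True)
class CdsFeature:
    """One coding sequence: its product name and EC evidence.

    ``reliability`` is the binary flag of the report: 1 for original
    annotations and unique de novo matches, 0 only for ambiguous
    multi-match de novo annotations.  A CDS without EC numbers keeps the
    conventional value 1.
    """

    feature_index: int
    product: str | None = None
    ec_numbers: tuple[str, ...] = ()
    reliability: int = 1
    annotation_origin: str = "original"


@dataclass(frozen=True)
class GenomeRecord:
    """All CDS features of one organism's GenBank file."""

    gi_accession: str
    organism_name: str
    cds: tuple[CdsFeature, ...] = ()

    @property
    def total_cds(self) -> int:
        return len(self.cds)

    def with_cds(self, cds: Sequence[CdsFeature]) -> "GenomeRecord":
        return replace(self, cds=tuple(cds))


def _gi_of(seqrecord) -> str | None:
    gi = seqrecord.annotations.get("gi")
    if gi:
        return str(gi)
    for feat in seqrecord.features:
        if feat.type == "source":
            for xref in feat.qualifiers.get("db_xref", []):
                if xref.startswith("GI:"):
                    return xref[3:]
    return None


def read_genbank(path: str | Path) -> GenomeRecord:
    """Read a GenBank file (all LOCUS records) into one :class:`GenomeRecord`.

    The GI accession comes from the first record's ``VERSION ... GI:`` field
    (falling back to a ``GI:`` db_xref on the source feature, then to the
    record id); the organism name from its SOURCE/ORGANISM annotation.  A
    file without CDS features is valid and yields ``total_cds == 0`` with a
    warning.
    """
    path = Path(path)
    seqrecords = list(SeqIO.parse(str(path), "genbank"))
    if not seqrecords:
        raise ValueError(f"{path}: no GenBank records found")
    first = seqrecords[0]
    gi = _gi_of(first) or first.id
    organism = first.annotations.get("organism", "") or first.annotations.get(
        "source", "") or "unknown organism"

    cds: list[CdsFeature] = []
    index = 0
    for rec in seqrecords:
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            product = quals.get("product", [None])[0]
            ecs = tuple(quals.get("EC_number", []))
            notes = " ".join(quals.get("note", []))
            if MULTI_EC_NOTE in notes:
                reliability, origin = 0, "de_novo"
            elif DE_NOVO_NOTE in notes:
                reliability, origin = 1, "de_novo"
            else:
                reliability, origin = 1, "original"
            cds.append(CdsFeature(
                feature_index=index,
                product=product,
                ec_numbers=ecs,
                reliability=reliability if ecs else 1,
                annotation_origin=origin,
            ))
            index += 1
    if not cds:
        logger.warning("%s: no CDS features", path)
    return GenomeRecord(gi_accession=gi, organism_name=organism,
                        cds=tuple(cds))


def read_genome_dir(
    directory: str | Path,
    skip_bad_files: bool = False,
) -> list[GenomeRecord]:
    """Read every ``.gb``/``.gbk``/``.gbff`` file in a directory, sorted by name.

    With ``skip_bad_files`` an unreadable file is logged and skipped;
    otherwise it aborts the run.
    """
    directory = Path(directory)
    genomes: list[GenomeRecord] = []
    paths = sorted(p for p in directory.iterdir()
                   if p.suffix.lower() in {".gb", ".gbk", ".gbff"})
    for p in paths:
        try:
            genomes.append(read_genbank(p))
        except Exception:
            if skip_bad_files:
                logger.exception("%s: unreadable, skipped", p)
            else:
                raise
    return genomes


def extract_enzyme_rows(
    record: GenomeRecord,
) -> list[tuple[str, str, str, int]]:
    """One ``(gi, organism, ec, reliability)`` tuple per (CDS, EC) pair.

    Gene copies are deliberately not collapsed: two CDSs annotated with the
    same EC yield two rows, and a CDS carrying k EC numbers yields k rows.
    This is the counting unit of the comparison statistics.
    """
    rows = []
    for cds in record.cds:
        for ec in cds.ec_numbers:
            rows.append((record.gi_accession, record.organism_name, ec,
                         cds.reliability))
    return rows


def write_genbank_with_annotations(
    record: GenomeRecord,
    original_path: str | Path,
    out_path: str | Path,
) -> None:
    """Write ``original_path`` back out with ``record``'s de novo annotations.

    Original qualifiers are untouched.  For each de novo annotated CDS the
    assigned ECs (at most three) are added as ``/EC_number`` qualifiers; a
    multi-match CDS additionally receives a ``/note`` carrying
    :data:`MULTI_EC_NOTE`, a unique match one carrying :data:`DE_NOVO_NOTE`.
    Re-reading the output reproduces ``record``.
    """
    seqrecords = list(SeqIO.parse(str(original_path), "genbank"))
    by_index = {c.feature_index: c for c in record.cds}
    index = 0
    for rec in seqrecords:
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            cds = by_index.get(index)
            index += 1
            if cds is None or cds.annotation_origin != "de_novo":
                continue
            existing = tuple(feat.qualifiers.get("EC_number", []))
            if existing:
                continue  # never touch original annotations
            feat.qualifiers["EC_number"] = list(cds.ec_numbers[:3])
            token = MULTI_EC_NOTE if cds.reliability == 0 else DE_NOVO_NOTE
            feat.qualifiers.setdefault("note", []).append(token)
    with open(out_path, "w") as fh:
        SeqIO.write(seqrecords, fh, "genbank")


def fetch_genbank(
    gi_or_accession: str,
    out_path: str | Path,
    email: str,
) -> Path:
    """Download one GenBank record from NCBI Entrez (network required).

    Optional plumbing for reproducing the published full-genome queries;
    never called by the offline pipeline or tests.
    """
    from Bio import Entrez

    Entrez.email = email
    with Entrez.efetch(db="nucleotide", id=gi_or_accession, rettype="gbwithparts",
                       retmode="text") as handle, open(out_path, "w") as out:
        out.write(handle.read())
    return Path(out_path)
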