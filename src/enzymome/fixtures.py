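"""Synthetic GenBank genomes and mini ENZYME files with known ground truth.

Every pipeline stage — flat-file parsing, name indexing, de novo
annotation, comparison, coverage — is testable offline against fixtures
whose expected outputs are known *by construction*: the generator plants
an explicit EC inventory (shared between the two microbiome groups or
unique to one of them, with gene-copy numbers) and returns the comparison
counts that inventory implies, before and after annotation.

Nucleotide sequences are filler (random ACGT of minimal length); the
features carry all the semantic load, since no pipeline stage reads
sequence content.  A fixed seed yields byte-identical files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .enzyme_db import (
    EnzymeRecord,
    parse_enzyme_dat,
    serialize_enzyme_dat,
)

__all__ = [
    "FixtureSpec",
    "MicrobiomePairTruth",
    "load_bundled_enzyme_records",
    "bundled_enzyme_dat_text",
    "make_enzyme_dat",
    "make_microbiome_pair",
]

_CDS_LEN = 30  # filler span per feature; coordinates are never interpreted


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a synthetic two-microbiome fixture.

    The EC inventory fields fully determine the expected comparison
    counts.  ``product_only_a``/``b`` plant CDSs that carry only a product
    name whose enzyme is known — invisible to a comparison of the original
    files, but picked up by de novo annotation.  ``copy_numbers`` maps an
    EC to its gene-copy count (default 1) in every genome it is planted in.
    """

    n_genomes_a: int = 2
    n_genomes_b: int = 2
    cds_per_genome: int = 12
    plasmid_cds: int = 2  # extra LOCUS per genome when > 0
    shared_ecs: tuple[str, ...] = ("4.4.1.1", "6.3.2.3")
    unique_a_ecs: tuple[str, ...] = ("2.6.1.11", "2.6.1.52")
    unique_b_ecs: tuple[str, ...] = ("4.1.1.50", "5.1.1.12")
    product_only_a: tuple[str, ...] = ()
    product_only_b: tuple[str, ...] = ()
    copy_numbers: dict[str, int] = field(default_factory=dict)
    label_a: str = "Microbiome 1"
    label_b: str = "Microbiome 2"
    # make_enzyme_dat knobs
    include_curated: bool = True
    n_synthetic_enzymes: int = 6
    n_collisions: int = 1
    collision_arity: int = 2
    n_transferred: int = 1
    n_deleted: int = 1


@dataclass(frozen=True)
class MicrobiomePairTruth:
    """Generated fixture directories plus the counts they must produce."""

    dir_a: Path
    dir_b: Path
    label_a: str
    label_b: str
    #: (n_identical, n_unique_a, n_unique_b) over the original files
    expected_counts: tuple[int, int, int]
    #: same, after de novo annotation of the product-only CDSs
    expected_counts_annotated: tuple[int, int, int]
    #: ECs planted per genome file name, for fine-grained assertions
    inventory_a: dict[str, dict[str, int]]
    inventory_b: dict[str, dict[str, int]]


def bundled_enzyme_dat_text() -> str:
    """Raw text of the packaged mini ENZYME flat file."""
    return (resources.files("enzymome") / "data" / "mini_enzyme.dat").read_text()


def load_bundled_enzyme_records() -> list[EnzymeRecord]:
    """Parsed records of the packaged mini ENZYME flat file."""
    return parse_enzyme_dat(bundled_enzyme_dat_text().splitlines(True))


# ---------------------------------------------------------------------------
# ENZYME flat-file fixtures

def _synthetic_ec(i: int) -> str:
    return f"9.{1 + i // 50}.{1 + i % 50}.{1 + i}"


def make_enzyme_dat(
    spec: FixtureSpec,
    seed: int,
    path: str | Path,
) -> tuple[Path, list[EnzymeRecord]]:
    """Write an ENZYME flat-file fixture; return its path and ground truth.

    The file holds (optionally) the curated bundled entries, plus
    ``n_synthetic_enzymes`` synthetic active entries, ``n_collisions``
    planted name collisions (one shared alternative name claimed by
    ``collision_arity`` distinct ECs each), and the requested number of
    transferred and deleted tombstones.
    """
    rng = random.Random(seed)
    records: list[EnzymeRecord] = []
    if spec.include_curated:
        records.extend(load_bundled_enzyme_records())

    n_synth = 0
    for i in range(spec.n_synthetic_enzymes):
        records.append(EnzymeRecord(
            ec_number=_synthetic_ec(n_synth),
            recommended_name=f"Synthetic oxidoreductase {n_synth + 1}.",
            catalytic_activity="Substrate + acceptor = product + "
                               "reduced acceptor.",
        ))
        n_synth += 1
    for c in range(spec.n_collisions):
        shared = f"Shared ambiguous hydrolase {c + 1}."
        for j in range(spec.collision_arity):
            records.append(EnzymeRecord(
                ec_number=_synthetic_ec(n_synth),
                recommended_name=f"Colliding enzyme {c + 1}.{j + 1}.",
                alt_names=(shared,),
                catalytic_activity="A + H2O = B + C.",
            ))
            n_synth += 1
    for t in range(spec.n_transferred):
        target = records[rng.randrange(len(records))].ec_number
        records.append(EnzymeRecord(
            ec_number=_synthetic_ec(n_synth),
            recommended_name=f"Transferred entry: {target}.",
            status="transferred",
            transfer_targets=frozenset({target}),
        ))
        n_synth += 1
    for _ in range(spec.n_deleted):
        records.append(EnzymeRecord(
            ec_number=_synthetic_ec(n_synth),
            recommended_name="Deleted entry.",
            status="deleted",
        ))
        n_synth += 1

    path = Path(path)
    path.write_text(serialize_enzyme_dat(records))
    return path, records


# ---------------------------------------------------------------------------
# GenBank genome fixtures

def _filler_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("acgt") for _ in range(n))


def _make_locus(
    name: str,
    organism: str,
    gi: str,
    cds_specs: list[tuple[str | None, tuple[str, ...]]],
    rng: random.Random,
) -> SeqRecord:
    n = max(len(cds_specs), 1) * _CDS_LEN
    rec = SeqRecord(
        Seq(_filler_seq(rng, n)),
        id=f"{name}.1",
        name=name,
        description=f"{organism} synthetic fixture",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular",
            "data_file_division": "BCT",
            "date": "01-JAN-2015",
            "organism": organism,
            "source": organism,
            "gi": gi,
        },
    )
    rec.features.append(SeqFeature(
        SimpleLocation(0, n), type="source",
        qualifiers={"organism": [organism], "db_xref": [f"GI:{gi}"]}))
    for i, (product, ecs) in enumerate(cds_specs):
        quals: dict[str, list[str]] = {}
        if product is not None:
            quals["product"] = [product]
        if ecs:
            quals["EC_number"] = list(ecs)
        rec.features.append(SeqFeature(
            SimpleLocation(i * _CDS_LEN, (i + 1) * _CDS_LEN, strand=1),
            type="CDS", qualifiers=quals))
    return rec


def _names_for(ecs: tuple[str, ...],
               by_ec: dict[str, EnzymeRecord]) -> dict[str, str]:
    names = {}
    for ec in ecs:
        rec = by_ec.get(ec)
        names[ec] = rec.recommended_name.rstrip(".") if rec else f"enzyme {ec}"
    return names


def _build_group(
    group_tag: str,
    n_genomes: int,
    spec: FixtureSpec,
    planted: tuple[str, ...],
    product_only: tuple[str, ...],
    names: dict[str, str],
    out_dir: Path,
    rng: random.Random,
) -> dict[str, dict[str, int]]:
    """Write one group's genomes; return per-file planted EC inventory."""
    out_dir.mkdir(parents=True, exist_ok=True)
    inventory: dict[str, dict[str, int]] = {}
    # round-robin distribution of planted ECs over genomes, copies expanded
    assignments: list[list[tuple[str, bool]]] = [[] for _ in range(n_genomes)]
    slot = 0
    for ec in planted:
        g = slot % n_genomes
        copies = spec.copy_numbers.get(ec, 1)
        assignments[g].extend((ec, True) for _ in range(copies))
        slot += 1
    for ec in product_only:
        g = slot % n_genomes
        copies = spec.copy_numbers.get(ec, 1)
        assignments[g].extend((ec, False) for _ in range(copies))
        slot += 1

    for g in range(n_genomes):
        organism = f"Synthetica {group_tag.lower()}{g + 1}"
        gi = str(100000000 + rng.randrange(900000000))
        cds_specs: list[tuple[str | None, tuple[str, ...]]] = []
        inv: dict[str, int] = {}
        for ec, with_qualifier in assignments[g]:
            product = names.get(ec, f"enzyme {ec}")
            cds_specs.append((product, (ec,) if with_qualifier else ()))
            if with_qualifier:
                inv[ec] = inv.get(ec, 0) + 1
        while len(cds_specs) < spec.cds_per_genome:
            cds_specs.append(("hypothetical protein", ()))
        locus = f"SYN{group_tag}{g + 1:02d}"
        records = [_make_locus(locus, organism, gi, cds_specs, rng)]
        if spec.plasmid_cds > 0:
            plasmid_cds = [("hypothetical protein", ())] * spec.plasmid_cds
            records.append(_make_locus(f"{locus}P", organism, gi,
                                       plasmid_cds, rng))
        fname = f"genome_{group_tag.lower()}{g + 1}.gb"
        with open(out_dir / fname, "w") as fh:
            SeqIO.write(records, fh, "genbank")
        inventory[fname] = inv
    return inventory


def _expected_counts(
    rows_a: dict[str, int], rows_b: dict[str, int]
) -> tuple[int, int, int]:
    """Set logic over planted inventories: row counts per section."""
    shared = set(rows_a) & set(rows_b)
    n_identical = sum(n for ec, n in rows_a.items() if ec in shared) \
        + sum(n for ec, n in rows_b.items() if ec in shared)
    n_unique_a = sum(n for ec, n in rows_a.items() if ec not in shared)
    n_unique_b = sum(n for ec, n in rows_b.items() if ec not in shared)
    return n_identical, n_unique_a, n_unique_b


def make_microbiome_pair(
    spec: FixtureSpec,
    seed: int,
    out_dir: str | Path,
) -> MicrobiomePairTruth:
    """Generate two directories of GenBank fixtures plus expected counts.

    Product names for planted ECs come from the bundled mini ENZYME file,
    so the product-only CDSs are annotatable against it.  The returned
    truth holds the comparison counts implied by the planted inventory for
    both the original files and the annotated ones.
    """
    overlap = (set(spec.unique_a_ecs) | set(spec.product_only_a)) & \
              (set(spec.unique_b_ecs) | set(spec.product_only_b))
    if overlap:
        raise ValueError(f"ECs planted as unique to both groups: {overlap}")

    rng = random.Random(seed)
    out_dir = Path(out_dir)
    by_ec = {r.ec_number: r for r in load_bundled_enzyme_records()}
    all_ecs = (spec.shared_ecs + spec.unique_a_ecs + spec.unique_b_ecs
               + spec.product_only_a + spec.product_only_b)
    names = _names_for(all_ecs, by_ec)

    dir_a, dir_b = out_dir / "group_a", out_dir / "group_b"
    inv_a = _build_group("A", spec.n_genomes_a, spec,
                         spec.shared_ecs + spec.unique_a_ecs,
                         spec.product_only_a, names, dir_a, rng)
    inv_b = _build_group("B", spec.n_genomes_b, spec,
                         spec.shared_ecs + spec.unique_b_ecs,
                         spec.product_only_b, names, dir_b, rng)

    def total(inv: dict[str, dict[str, int]],
              extra: tuple[str, ...] = ()) -> dict[str, int]:
        rows: dict[str, int] = {}
        for per_file in inv.values():
            for ec, n in per_file.items():
                rows[ec] = rows.get(ec, 0) + n
        for ec in extra:
            rows[ec] = rows.get(ec, 0) + spec.copy_numbers.get(ec, 1)
        return rows

    counts = _expected_counts(total(inv_a), total(inv_b))
    counts_annot = _expected_counts(total(inv_a, spec.product_only_a),
                                    total(inv_b, spec.product_only_b))
    return MicrobiomePairTruth(
        dir_a=dir_a, dir_b=dir_b,
        label_a=spec.label_a, label_b=spec.label_b,
        expected_counts=counts,
        expected_counts_annotated=counts_annot,
        inventory_a=inv_a, inventory_b=inv_b,
    )
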