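"""De novo EC annotation by product-name matching.

Each CDS that lacks EC numbers has its /product text looked up in the
enzyme-name index.  The lookup has exactly three outcomes: no match (the
CDS is left untouched), one unique match (the EC is assigned with
reliability 1), or more than one match (the first three ECs in ascending
order are assigned with reliability 0, flagging the call for manual
curation).  Existing annotations are never altered, which makes
annotation idempotent.

Matching is exact on normalized names by default.  An optional substring
fallback (normalized product contained in an index key, or vice versa)
can be enabled for product strings carrying decorations like strain
suffixes; the stage that produced a match is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .enzyme_db import NameIndex, ec_sort_key, normalize_name
from .genbank_io import CdsFeature, GenomeRecord

__all__ = [
    "AnnotationResult",
    "AnnotationSummary",
    "match_product",
    "annotate_genome",
]

#: At most this many ECs are recorded for an ambiguous multi-match.
MAX_MULTI_ECS = 3

#: Substring fallback only fires on normalized strings at least this long,
#: to keep short generic words from matching everything.
MIN_SUBSTRING_LEN = 4


@dataclass(frozen=True)
class AnnotationResult:
    """Outcome of matching one product name against the name index."""

    outcome: str  # "none" | "unique" | "multiple"
    assigned_ecs: tuple[str, ...] = ()
    reliability: int = 1
    match_stage: str = "exact"  # "exact" | "substring"


@dataclass(frozen=True)
class AnnotationSummary:
    """Per-genome tallies of one annotation pass."""

    total_cds: int
    newly_annotated: int
    multi_flagged: int
    untouched: int
    already_annotated: int


_NO_MATCH = AnnotationResult(outcome="none")


def _classify(ecs: tuple[str, ...], stage: str) -> AnnotationResult:
    if not ecs:
        return _NO_MATCH
    if len(ecs) == 1:
        return AnnotationResult("unique", ecs, reliability=1, match_stage=stage)
    return AnnotationResult("multiple", ecs[:MAX_MULTI_ECS], reliability=0,
                            match_stage=stage)


def match_product(
    product: str,
    index: NameIndex,
    substring_fallback: bool = False,
) -> AnnotationResult:
    """Match one product name; returns the three-outcome classification.

    The same EC reachable through both a recommended and an alternative
    name counts once.  Multi-match ECs are reported in ascending EC order,
    truncated to the first three.
    """
    key = normalize_name(product)
    if not key:
        return _NO_MATCH
    exact = index.entries.get(key, ())
    if exact:
        return _classify(exact, "exact")
    if not substring_fallback or len(key) < MIN_SUBSTRING_LEN:
        return _NO_MATCH
    hits: set[str] = set()
    for idx_key, ecs in index.items():
        if len(idx_key) < MIN_SUBSTRING_LEN:
            continue
        if idx_key in key or key in idx_key:
            hits.update(ecs)
    return _classify(tuple(sorted(hits, key=ec_sort_key)), "substring")


def annotate_genome(
    record: GenomeRecord,
    index: NameIndex,
    mode: str = "unique+multi",
    substring_fallback: bool = False,
) -> tuple[GenomeRecord, AnnotationSummary]:
    """Annotate every EC-less CDS of ``record`` against ``index``.

    ``mode`` is ``"off"`` (no-op), ``"unique-only"`` (apply unambiguous
    matches only) or ``"unique+multi"`` (also record ambiguous matches,
    flagged with reliability 0).  CDSs that already carry EC numbers are
    returned unchanged, so the operation is a fixed point on its output.
    """
    if mode not in {"off", "unique-only", "unique+multi"}:
        raise ValueError(f"unknown annotation mode: {mode!r}")

    new_cds: list[CdsFeature] = []
    newly = multi = untouched = already = 0
    for cds in record.cds:
        if cds.ec_numbers:
            already += 1
            new_cds.append(cds)
            continue
        result = _NO_MATCH
        if mode != "off" and cds.product:
            result = match_product(cds.product, index, substring_fallback)
        if result.outcome == "none" or (
                result.outcome == "multiple" and mode == "unique-only"):
            untouched += 1
            new_cds.append(cds)
            continue
        newly += 1
        if result.outcome == "multiple":
            multi += 1
        new_cds.append(replace(
            cds,
            ec_numbers=result.assigned_ecs,
            reliability=result.reliability,
            annotation_origin="de_novo",
        ))
    summary = AnnotationSummary(
        total_cds=record.total_cds,
        newly_annotated=newly,
        multi_flagged=multi,
        untouched=untouched,
        already_annotated=already,
    )
    return record.with_cds(new_cds), summary
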