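# Methods

## The model

`enzymome` implements a comparative "enzymome" analysis of two microbial
communities modeled as *artificial metagenomes*: instead of assembling and
binning environmental reads, each community is the union of curated,
fully-sequenced single-organism GenBank records chosen from the literature.
The analysis is purely annotation-level text mining. Its core assumptions:

- **EC numbers are the unit of enzyme identity.** Two CDSs encode "the same
  enzyme" iff they carry the same Enzyme Commission number as a literal
  string. This trades resolution (isozymes, substrate ranges, sequence
  divergence) for comparability across heterogeneously annotated genomes.
- **A community's enzymome is the multiset of (CDS, EC) pairs** over its
  genomes. Gene copies are counted, not collapsed; a CDS carrying k EC
  numbers contributes k rows. Comparison counts are therefore row counts
  and deliberately "inflated" relative to distinct-EC counts; the report's
  `(×n)` notation collapses copies for display only.
- **Coverage limits interpretation.** Only a minority of CDSs in public
  genomes carry EC annotations (roughly 12–25 % in well-annotated
  bacterial genomes); absence of an enzyme from a group may reflect missing
  annotation rather than missing catalytic capability. The coverage table
  exists to make this visible.

## Procedure

1. **ENZYME parsing.** The ExPASy flat-file dialect is parsed into records
   (`ID` = EC, `DE` = recommended name, `AN` = alternative names, `CA` =
   catalytic activity; records end at `//`; multi-line DE/CA fields join
   with single spaces). `DE Transferred entry: …` and `DE Deleted entry.`
   mark tombstones: parsed, retrievable by EC lookup, but excluded from the
   name index. Transferred entries are *not* followed to their targets
   during annotation — silent redirection would inflate match counts.
2. **Name index.** Every active record contributes its recommended and
   (by default; `include_alt_names=False` to disable) alternative names
   under a normalization: lowercase, surrounding quotes stripped, trailing
   periods stripped, whitespace collapsed. Trailing-period stripping (and
   hence the whole normalization) is idempotent, so index keys are fixed
   points. A name claimed by k ECs maps to all k in ascending EC order;
   collisions are data.
3. **GenBank reading.** All LOCUS records of a file merge into one genome
   (multi-replicon organisms are one comparison unit; whether plasmids
   belong in the model is the caller's choice of input files). The GI
   accession is taken from the `VERSION … GI:` field, with fallbacks to a
   `GI:` db_xref on the source feature and then the record id. Features
   are opaque annotation carriers: coordinates and sequence are never
   interpreted.
4. **De novo annotation.** Each CDS with a product and no ECs is matched
   exactly on normalized names. Outcomes: none / unique (reliability 1) /
   multiple (first three ECs ascending, reliability 0). Ascending-EC order
   makes multi-match truncation deterministic. The same EC reachable via
   two names counts once. An optional substring fallback (either direction,
   both strings ≥ 4 characters) handles decorated product strings and is
   recorded as the match stage; it is off by default because it is
   aggressive. Existing annotations are never modified, so annotation is
   idempotent.
5. **Write-back.** De novo ECs become standard `/EC_number` qualifiers.
   Multi-match CDSs carry at most three plus a `/note` with the fixed token
   `MULTI-EC-LOW-RELIABILITY`; unique de novo calls carry `EC-DE-NOVO`.
   Machine-readable tokens (rather than free text) keep
   read → write → read round-trips exact, including the reliability flag
   and annotation origin.
6. **Comparison.** EC *e* is "identical" iff at least one row of each group
   carries *e*; otherwise its rows are unique to their group. Every row is
   emitted in exactly one section; sections are ordered by EC then
   organism; the three sections' EC sets are pairwise disjoint and the row
   counts conserve `|rows(A)| + |rows(B)|`. Partial ECs (`1.2.3.-`)
   compare as literal strings — prefix semantics would silently merge
   enzyme classes. Reliability-0 rows participate fully and carry their
   flag into the report (a column, not a filter). Results persist to an
   embedded sqlite store; the canonical report is TSV with a provenance
   header echoing the run configuration.
7. **Coverage.** Per genome: `total_cds`; CDSs with ≥ 1 EC before
   (`ec_cds_original`) and after (`ec_cds_updated`) annotation; multi-flagged
   CDSs; `actual_ec = ec_cds_updated − multi_flagged`;
   `pct = 100·count/total_cds`;
   `pct_increase = 100·(actual_ec − ec_cds_original)/ec_cds_original`.
   The counting unit is the CDS, not the qualifier — a bifunctional CDS with
   two ECs counts once — which is the only convention under which
   "actual = total − multi" is internally consistent in the published
   reference table bundled with the package.

## Numerical choices

- Percentages are exact rationals (`fractions.Fraction`) internally and are
  rounded only for display/export: two decimals, round-half-to-even,
  computed via `decimal.Decimal` on the exact ratio so ties like
  100·27/480 = 5.625 round reproducibly (→ 5.62). This convention
  reproduces all 25 rows of the bundled reference coverage table.
- `pct_increase` is undefined (rendered blank) when a genome had no
  original EC annotations; all percentages are blank for an empty genome.
- Multi-match ordering and every report ordering (EC numeric order with
  `-` sorting last, then organism) are total, so identical inputs and
  configuration yield byte-identical reports.

## Synthetic data generator

`fixtures` emulates the two input formats with known ground truth.
`make_enzyme_dat` writes a valid flat file containing the curated bundled
entries (every EC appearing in the study's result tables), synthetic active
entries, planted name collisions (one shared alternative name claimed by
*m* ECs — forcing the multi-match outcome), and transferred/deleted
tombstones. `make_microbiome_pair` writes two directories of GenBank files
with a planted EC inventory — shared ECs, group-unique ECs, gene-copy
numbers, product-only CDSs (annotatable but initially unannotated) and
`hypothetical protein` filler — plus a plasmid-style second LOCUS per file
to exercise multi-record merging. Defaults are modest (2 genomes per group,
12 + 2 CDSs each) because the semantics, not the scale, carry the tests;
the expected comparison counts returned by the generator are computed from
the inventory by set logic, independently of the comparator.

What the generator does *not* emulate: real community composition or
abundance, messy free-text product names (truncations, gene symbols,
multi-function descriptions), annotation errors, or genome-scale CDS
counts. Passing tests therefore demonstrate the correctness of the
bookkeeping — parsing, matching rules, classification, arithmetic — not the
biological sensitivity of name-based annotation on real GenBank files,
where exact-match recall depends strongly on annotation style and ENZYME
release. Release-dependence of the name set also means multi-match
outcomes can differ between ENZYME versions.

## Design choices where the design was open

- **Exact matching by default, substring opt-in** — the conservative
  operator is reproducible and auditable; the fallback exists because real
  product strings often carry suffixes.
- **Alternative names included by default, with an off switch** — AN lines
  are legitimate synonyms; excluding them is available for studies wanting
  recommended-name-only matching.
- **Merge-all-LOCUS per file** — one organism, one comparison column,
  regardless of replicon structure.
- **Tombstones never annotate** — no transfer-entry resolution.
- **TSV as the canonical report** (with the sqlite store for querying) —
  diffable, testable; any web table is presentation.

## Known limitations

- Name-based annotation has no notion of sequence similarity; it can
  neither annotate unnamed proteins nor detect wrong product names
  (BLAST-style annotation is out of scope).
- EC-string identity treats partial ECs as opaque and distinct from all
  full ECs, and treats genuinely different reactions under one (promiscuous)
  EC as identical.
- Reproducing published full-genome comparison counts requires the exact
  GI-pinned record revisions from NCBI; annotations drift between record
  versions, so re-fetched genomes may yield slightly different counts.
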