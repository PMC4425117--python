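"""Shared fixtures: bundled enzyme data and hand-written GenBank texts."""

import pytest

from enzymome import build_name_index, load_bundled_enzyme_records
from enzymome.enzyme_db import records_by_ec

# A hand-written single-LOCUS genome: 3 CDS, one carrying an original EC.
GENOME_3CDS = """\
LOCUS       SYNTEST1                 180 bp    DNA     circular BCT 01-JAN-2015
DEFINITION  Testus primus synthetic fixture.
ACCESSION   SYNTEST1
VERSION     SYNTEST1.1  GI:900000001
SOURCE      Testus primus
  ORGANISM  Testus primus
            Bacteria.
FEATURES             Location/Qualifiers
     source          1..180
                     /organism="Testus primus"
                     /db_xref="GI:900000001"
     CDS             1..60
                     /product="alcohol dehydrogenase"
                     /EC_number="1.1.1.1"
     CDS             61..120
                     /product="cystathionine gamma-lyase"
     CDS             121..180
                     /product="hypothetical protein"
ORIGIN
        1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
       61 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
      121 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
//
"""

# Two LOCUS records (chromosome + plasmid) of 2 and 3 CDS for one organism.
GENOME_TWO_LOCUS = """\
LOCUS       SYNTEST2                 120 bp    DNA     circular BCT 01-JAN-2015
DEFINITION  Testus secundus chromosome.
ACCESSION   SYNTEST2
VERSION     SYNTEST2.1  GI:900000002
SOURCE      Testus secundus
  ORGANISM  Testus secundus
            Bacteria.
FEATURES             Location/Qualifiers
     source          1..120
                     /organism="Testus secundus"
                     /db_xref="GI:900000002"
     CDS             1..60
                     /product="glutathione synthase"
                     /EC_number="6.3.2.3"
     CDS             61..120
                     /product="2-oxoglutarate synthase"
                     /EC_number="1.2.7.3"
ORIGIN
        1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
       61 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
//
LOCUS       SYNTEST2P                 90 bp    DNA     circular BCT 01-JAN-2015
DEFINITION  Testus secundus plasmid.
ACCESSION   SYNTEST2P
VERSION     SYNTEST2P.1  GI:900000003
SOURCE      Testus secundus
  ORGANISM  Testus secundus
            Bacteria.
FEATURES             Location/Qualifiers
     source          1..90
                     /organism="Testus secundus"
     CDS             1..30
                     /product="2-oxoglutarate synthase"
                     /EC_number="1.2.7.3"
     CDS             31..60
                     /product="bifunctional ligase"
                     /EC_number="6.3.2.2"
                     /EC_number="6.3.2.3"
     CDS             61..90
                     /product="hypothetical protein"
ORIGIN
        1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
       61 acgtacgtac gtacgtacgt acgtacgtac
//
"""


@pytest.fixture(scope="session")
def bundled_records():
    return load_bundled_enzyme_records()


@pytest.fixture(scope="session")
def bundled_index(bundled_records):
    return build_name_index(bundled_records)


@pytest.fixture(scope="session")
def bundled_by_ec(bundled_records):
    return records_by_ec(bundled_records)


@pytest.fixture
def genome_3cds_path(tmp_path):
    p = tmp_path / "testus_primus.gb"
    p.write_text(GENOME_3CDS)
    return p


@pytest.fixture
def genome_two_locus_path(tmp_path):
    p = tmp_path / "testus_secundus.gb"
    p.write_text(GENOME_TWO_LOCUS)
    return p
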