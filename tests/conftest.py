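"""Shared fixtures: flat-file texts built via Biopython, small random helpers."""

from __future__ import annotations

from io import StringIO

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import (
    BeforePosition, CompoundLocation, ExactPosition, SeqFeature, SimpleLocation,
)
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO


def _contig(record_id: str, features: list[SeqFeature], fmt: str,
            organelle: str | None = None) -> str:
    rec = SeqRecord(
        Seq("ACGT" * 100), id=record_id, name=record_id,
        description="synthetic test contig",
        annotations={"organism": "synthetic construct", "molecule_type": "DNA"},
    )
    source_quals = {}
    if organelle:
        source_quals["organelle"] = [organelle]
    rec.features = [SeqFeature(SimpleLocation(0, 400, 1), type="source",
                               qualifiers=source_quals)] + features
    buf = StringIO()
    SeqIO.write([rec], buf, fmt)
    return buf.getvalue()


def cds_feature(parts: list[tuple[int, int]], strand: int, quals: dict,
                fuzzy_first_start: bool = False) -> SeqFeature:
    """parts are 1-based inclusive genomic (start, end) in file order."""
    locs = []
    for i, (start, end) in enumerate(parts):
        s = BeforePosition(start - 1) if (fuzzy_first_start and i == 0) else ExactPosition(start - 1)
        locs.append(SimpleLocation(s, ExactPosition(end), strand))
    loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
    return SeqFeature(loc, type="CDS", qualifiers={k: [v] for k, v in quals.items()})


# 30 + 60 = 90 coding nt -> 29 residues + stop; intron at coding offset 30
TRANSLATION_29 = "MKLSVFLLLVVSTNHICSATDPETFLSKS"


@pytest.fixture(scope="session")
def genbank_text() -> str:
    features = [
        cds_feature([(1, 30), (101, 160)], 1,
                    {"gene": "fwd1", "protein_id": "P1", "db_xref": "GeneID:111",
                     "translation": TRANSLATION_29}),
        cds_feature([(201, 230), (301, 360)], 1,
                    {"protein_id": "P2", "db_xref": "GeneID:222",
                     "translation": TRANSLATION_29},
                    fuzzy_first_start=True),
        cds_feature([(201, 230), (301, 360)], 1,
                    {"db_xref": "GeneID:333", "translation": TRANSLATION_29}),
    ]
    return _contig("TESTCHR1", features, "genbank")


@pytest.fixture(scope="session")
def embl_text() -> str:
    # reverse-strand gene encoding the same exon lengths as fwd1
    features = [
        cds_feature([(1, 30), (101, 160)], -1,
                    {"gene": "rev1", "protein_id": "P3",
                     "translation": TRANSLATION_29}),
    ]
    return _contig("TESTCHR2", features, "embl")


@pytest.fixture(scope="session")
def genbank_mito_text() -> str:
    features = [
        cds_feature([(1, 90)], 1,
                    {"gene": "mt1", "protein_id": "PM1", "db_xref": "GeneID:900",
                     "translation": TRANSLATION_29}),
    ]
    return _contig("TESTMT", features, "genbank", organelle="mitochondrion")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
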