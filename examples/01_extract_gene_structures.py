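"""Map intron positions from a gene structure onto its protein.

Builds a tiny GenBank record in memory, extracts the CDS exon segments, and
shows how each intron's coding-nucleotide offset becomes a lower-case mark on
the protein: residue = offset // 3, phase = offset % 3.
"""

from io import StringIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from ipcon import (
    coding_offsets_of_introns, extract_marked_proteins, marked_fasta_text,
)

record = SeqRecord(
    Seq("ACGT" * 100), id="DEMO1", name="DEMO1", description="demo contig",
    annotations={"organism": "demo organism", "molecule_type": "DNA"},
)
# two exons of 31 and 59 nt -> one intron at coding offset 31 (phase 1)
record.features = [SeqFeature(
    CompoundLocation([SimpleLocation(0, 31, 1), SimpleLocation(100, 159, 1)]),
    type="CDS",
    qualifiers={
        "gene": ["demoA"], "protein_id": ["DEMO_P1"],
        "translation": ["MKLSVFLLLVVSTNHICSATDPETFLSKS"],
    },
)]
buf = StringIO()
SeqIO.write([record], buf, "genbank")

proteins = extract_marked_proteins(buf.getvalue(), "genbank", species="demo")
protein = proteins[0]
offsets = coding_offsets_of_introns_demo = [m.coding_offset for m in protein.marks]
print("intron coding offsets:", offsets)
print("marks (residue, phase):", [(m.residue_index, m.phase) for m in protein.marks])
print(marked_fasta_text(proteins), end="")
# The lower-case 'l' at residue 10 is the codon the phase-1 intron interrupts;
# two marks in the same codon would lower-case the same residue (the
# same-codon conservation criterion).
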