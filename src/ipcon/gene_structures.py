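"""Gene models, intron positions and marked protein sequences.

Intron positions are taken from the exon (CDS segment) structure of a gene
and projected onto the encoded protein: an intron sitting at coding-nucleotide
offset ``k`` (0-based, counted along the spliced CDS) marks protein residue
``k // 3`` with phase ``k % 3``.  Phase 0 means the intron falls between two
codons ("preceding" the marked codon); phases 1 and 2 interrupt it.  In the
marked-FASTA rendering the residue whose codon an intron precedes or
interrupts is written in lower case, so codon-level identity of intron
positions (the "same codon" criterion, at most a 2-nucleotide slide) reduces
to identity of marked residue indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from io import StringIO
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.SeqFeature import CompoundLocation, ExactPosition, SeqFeature

logger = logging.getLogger(__name__)

Strand = Literal["forward", "reverse"]
Organelle = Literal["nuclear", "mitochondrial", "plastid"]


class GeneStructureError(ValueError):
    """Raised for structurally invalid gene models or marked sequences."""


@dataclass(frozen=True, order=True)
class ExonSegment:
    """A CDS segment in genomic coordinates (1-based, inclusive)."""

    start: int
    end: int
    strand: Strand = "forward"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GeneStructureError(f"segment start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneModel:
    """A single spliceform's CDS: ordered exon segments plus identity."""

    gene_id: str
    spliceform_id: str
    species: str
    segments: list[ExonSegment]
    organelle: Organelle = "nuclear"

    def __post_init__(self) -> None:
        if not self.segments:
            raise GeneStructureError(f"{self.spliceform_id}: gene model without segments")

    @property
    def coding_length(self) -> int:
        return sum(seg.length for seg in self.segments)


@dataclass(frozen=True, order=True)
class IntronMark:
    """An intron position in protein coordinates.

    ``residue_index`` is 0-based; ``phase`` is the coding-nucleotide offset of
    the intron modulo 3, or ``None`` when the source format (marked FASTA)
    cannot represent it.
    """

    residue_index: int
    phase: int | None = None

    def __post_init__(self) -> None:
        if self.residue_index < 0:
            raise GeneStructureError(f"negative residue index {self.residue_index}")
        if self.phase is not None and self.phase not in (0, 1, 2):
            raise GeneStructureError(f"phase must be 0, 1 or 2, got {self.phase}")

    @property
    def coding_offset(self) -> int | None:
        if self.phase is None:
            return None
        return self.residue_index * 3 + self.phase


@dataclass
class ProteinRecord:
    """A protein sequence with intron marks.

    ``marks`` may contain two entries for the same residue (different phases);
    they collapse to a single marked residue for rendering and for IPC
    counting, which is codon-level.
    """

    species: str
    gene_id: str
    spliceform_id: str
    sequence: str
    marks: tuple[IntronMark, ...] = ()
    organelle: Organelle = "nuclear"

    def __post_init__(self) -> None:
        self.marks = tuple(sorted(self.marks, key=lambda m: (m.residue_index, m.phase if m.phase is not None else -1)))
        for m in self.marks:
            if m.residue_index >= len(self.sequence):
                raise GeneStructureError(
                    f"{self.key}: mark at residue {m.residue_index} beyond sequence length {len(self.sequence)}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def key(self) -> str:
        """Identifier used in marked FASTA headers and alignments."""
        return f"{self.species}|{self.gene_id}|{self.spliceform_id}"

    @property
    def marked_residues(self) -> frozenset[int]:
        """Distinct marked residue indices (codon-level intron positions)."""
        return frozenset(m.residue_index for m in self.marks)

    @property
    def n_introns(self) -> int:
        return len(self.marked_residues)


# ---------------------------------------------------------------------------
# Flat-file parsing
# ---------------------------------------------------------------------------

def _is_exact(feature: SeqFeature) -> bool:
    loc = feature.location
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    return all(
        isinstance(p.start, ExactPosition) and isinstance(p.end, ExactPosition)
        for p in parts
    )


def _gene_id_for(feature: SeqFeature, dialect: str) -> str | None:
    quals = feature.qualifiers
    if dialect == "embl":
        vals = quals.get("gene")
        if vals:
            return vals[0]
    else:
        for xref in quals.get("db_xref", []):
            if xref.startswith("GeneID:"):
                return xref.split(":", 1)[1]
    return None


def _record_organelle(seqrecord) -> Organelle:
    for feat in seqrecord.features:
        if feat.type == "source":
            org = feat.qualifiers.get("organelle", [""])[0].lower()
            if "mitochond" in org:
                return "mitochondrial"
            if "plastid" in org or "chloroplast" in org:
                return "plastid"
    desc = (seqrecord.description or "").lower()
    if "mitochond" in desc:
        return "mitochondrial"
    return "nuclear"


def parse_gene_records(
    flatfile_text: str,
    dialect: Literal["embl", "genbank"],
    species: str | None = None,
) -> list[tuple[GeneModel, str]]:
    """Parse CDS features from an EMBL or GenBank flat file.

    Returns one ``(GeneModel, translation)`` tuple per usable CDS.  Gene
    identity comes from the ``gene`` qualifier (EMBL) or the ``db_xref
    GeneID`` entry (GenBank); the protein_id qualifier identifies the
    spliceform.  CDS features with fuzzy coordinates (``<``/``>``), without a
    protein_id or without a translation are skipped with a warning.
    """
    if dialect not in ("embl", "genbank"):
        raise ValueError(f"unknown dialect {dialect!r}")
    out: list[tuple[GeneModel, str]] = []
    for seqrecord in SeqIO.parse(StringIO(flatfile_text), dialect):
        sp = species or seqrecord.annotations.get("organism", seqrecord.id)
        organelle = _record_organelle(seqrecord)
        for feat in seqrecord.features:
            if feat.type != "CDS":
                continue
            pid = feat.qualifiers.get("protein_id", [None])[0]
            if pid is None:
                logger.warning("%s: CDS without protein_id skipped", seqrecord.id)
                continue
            if not _is_exact(feat):
                logger.warning("%s: CDS %s has fuzzy coordinates, skipped", seqrecord.id, pid)
                continue
            translation = feat.qualifiers.get("translation", [None])[0]
            if translation is None:
                logger.warning("%s: CDS %s without translation skipped", seqrecord.id, pid)
                continue
            loc = feat.location
            parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
            strands = {p.strand for p in parts}
            if len(strands) != 1 or None in strands:
                logger.warning("%s: CDS %s mixed/unknown strand, skipped", seqrecord.id, pid)
                continue
            strand: Strand = "forward" if strands.pop() >= 0 else "reverse"
            try:
                segments = normalize_segments(
                    [ExonSegment(int(p.start) + 1, int(p.end), strand) for p in parts]
                )
            except GeneStructureError as exc:
                raise GeneStructureError(f"CDS {pid}: {exc}") from exc
            gid = _gene_id_for(feat, dialect) or pid
            out.append(
                (GeneModel(gene_id=gid, spliceform_id=pid, species=sp,
                           segments=segments, organelle=organelle),
                 translation)
            )
    return out


def normalize_segments(segments: Sequence[ExonSegment]) -> list[ExonSegment]:
    """Order segments in coding direction and check for overlaps."""
    if not segments:
        raise GeneStructureError("no segments")
    strand = segments[0].strand
    ordered = sorted(segments, key=lambda s: s.start, reverse=(strand == "reverse"))
    by_pos = sorted(ordered, key=lambda s: s.start)
    for a, b in zip(by_pos, by_pos[1:]):
        if b.start <= a.end:
            raise GeneStructureError(f"overlapping segments {a} and {b}")
    return ordered


def coding_offsets_of_introns(segments: Sequence[ExonSegment]) -> list[int]:
    """Coding-nucleotide offsets of the introns between consecutive segments.

    Offset ``k`` means the intron lies between coding nucleotides ``k-1`` and
    ``k`` (0-based along the spliced CDS); a CDS with one segment has none.
    """
    ordered = normalize_segments(segments)
    offsets: list[int] = []
    total = 0
    for seg in ordered[:-1]:
        total += seg.length
        offsets.append(total)
    return offsets


def mark_protein(model: GeneModel, protein_sequence: str) -> ProteinRecord:
    """Map a gene model's intron offsets onto its protein sequence.

    The protein may be one codon shorter than the CDS (stop codon not
    translated); marks landing in or after the stop codon are dropped with a
    warning rather than clamped.
    """
    length = len(protein_sequence)
    total = model.coding_length
    if total - 3 * length not in (-3, 0, 3):
        raise GeneStructureError(
            f"{model.spliceform_id}: coding length {total} incompatible with "
            f"protein length {length} (allowed slack: one codon)"
        )
    marks = []
    for k in coding_offsets_of_introns(model.segments):
        residue, phase = divmod(k, 3)
        if residue >= length:
            logger.warning(
                "%s: intron at coding offset %d falls in/after the stop codon, dropped",
                model.spliceform_id, k,
            )
            continue
        marks.append(IntronMark(residue, phase))
    return ProteinRecord(
        species=model.species,
        gene_id=model.gene_id,
        spliceform_id=model.spliceform_id,
        sequence=protein_sequence,
        marks=tuple(marks),
        organelle=model.organelle,
    )


# ---------------------------------------------------------------------------
# Spliceform selection
# ---------------------------------------------------------------------------

def select_spliceforms(
    records: Iterable[ProteinRecord],
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Per (species, gene): drop exact duplicates, keep the longest spliceform.

    Exact duplicates (identical sequence and identical marks within one gene)
    are removed first; then only the longest spliceform of each gene is kept,
    ties broken by lexicographically smallest spliceform_id.  Returns
    ``(kept, shorter_pool)`` where the pool holds the discarded shorter
    spliceforms for later re-addition to extended clusters.
    """
    by_gene: dict[tuple[str, str], list[ProteinRecord]] = {}
    for rec in records:
        by_gene.setdefault((rec.species, rec.gene_id), []).append(rec)
    kept: list[ProteinRecord] = []
    pool: list[ProteinRecord] = []
    for key in sorted(by_gene):
        group = sorted(by_gene[key], key=lambda r: r.spliceform_id)
        seen: set[tuple[str, frozenset[int]]] = set()
        unique: list[ProteinRecord] = []
        for rec in group:
            sig = (rec.sequence, rec.marked_residues)
            if sig in seen:
                logger.info("%s: redundant identical copy removed", rec.key)
                continue
            seen.add(sig)
            unique.append(rec)
        best = min(unique, key=lambda r: (-r.length, r.spliceform_id))
        kept.append(best)
        pool.extend(r for r in unique if r is not best)
    return kept, pool


# ---------------------------------------------------------------------------
# Marked FASTA
# ---------------------------------------------------------------------------

def render_marked_sequence(record: ProteinRecord) -> str:
    marked = record.marked_residues
    return "".join(
        c.lower() if i in marked else c.upper()
        for i, c in enumerate(record.sequence)
    )


def write_marked_fasta(records: Iterable[ProteinRecord], handle) -> None:
    """Write records as marked FASTA (lower-case residues = intron marks)."""
    for rec in records:
        header = rec.key if rec.organelle == "nuclear" else f"{rec.key}|{rec.organelle}"
        handle.write(f">{header}\n")
        seq = render_marked_sequence(rec)
        for i in range(0, len(seq), 60):
            handle.write(seq[i:i + 60] + "\n")


def marked_fasta_text(records: Iterable[ProteinRecord]) -> str:
    buf = StringIO()
    write_marked_fasta(records, buf)
    return buf.getvalue()


def parse_marked_fasta(text: str) -> list[ProteinRecord]:
    """Parse marked FASTA; headers are ``species|gene_id|spliceform_id[|organelle]``.

    Intron phases are not representable in this format and come back as
    ``None`` (unknown); residue indices round-trip exactly.
    """
    records: list[ProteinRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        fields = header.split("|")
        if len(fields) not in (3, 4):
            raise GeneStructureError(
                f"line {header_line}: malformed marked-FASTA header {header!r} "
                f"(expected species|gene_id|spliceform_id[|organelle])"
            )
        organelle = fields[3] if len(fields) == 4 else "nuclear"
        if organelle not in ("nuclear", "mitochondrial", "plastid"):
            raise GeneStructureError(f"line {header_line}: unknown organelle {organelle!r}")
        seq = "".join(chunks)
        marks = tuple(IntronMark(i, None) for i, c in enumerate(seq) if c.islower())
        records.append(
            ProteinRecord(
                species=fields[0], gene_id=fields[1], spliceform_id=fields[2],
                sequence=seq.upper(), marks=marks, organelle=organelle,  # type: ignore[arg-type]
            )
        )

    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            header_line = lineno
            chunks = []
        else:
            if header is None:
                raise GeneStructureError(f"line {lineno}: sequence data before first header")
            chunks.append(line)
    flush()
    return records


def extract_marked_proteins(
    flatfile_text: str,
    dialect: Literal["embl", "genbank"],
    species: str | None = None,
) -> list[ProteinRecord]:
    """Flat file -> marked protein records (one per CDS, before spliceform filtering)."""
    out = []
    for model, translation in parse_gene_records(flatfile_text, dialect, species=species):
        try:
            out.append(mark_protein(model, translation))
        except GeneStructureError as exc:
            logger.warning("skipping %s: %s", model.spliceform_id, exc)
    return out
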