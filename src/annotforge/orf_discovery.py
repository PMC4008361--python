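"""Six-frame ORF enumeration in intergenic space.

The search space for proteogenomic discovery: the complement of the
annotated features, translated in all six frames.  Within each frame,
every maximal stop-to-stop interval is scanned for its 5'-most allowed
start codon (ATG/GTG/TTG by default — actinomycete usage, where GTG and
even TTG starts are common and start mis-selection is the classic
high-GC annotation failure).  Stop-free stretches running into a region
edge are retained with a ``partial`` flag rather than discarded, because
broken/frameshifted genes manifest exactly there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import GeneModel, GenomeSequence
from .sequtils import START_CODONS, STOP_CODONS, revcomp, translate

__all__ = [
    "IntergenicRegion",
    "CandidateORF",
    "extract_intergenic",
    "six_frame_orfs",
    "DEFAULT_MIN_AA",
]

DEFAULT_MIN_AA = 30


@dataclass(frozen=True)
class IntergenicRegion:
    chrom: str
    start: int
    end: int
    flanking_gene_ids: tuple[str | None, str | None] = (None, None)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CandidateORF:
    """A candidate protein-coding interval, genome coordinates, half-open."""

    chrom: str
    start: int
    end: int
    strand: str
    frame: int  # 0..2: phase of the reading frame, genome-relative
    protein: str
    start_codon: str | None
    evidence: set = field(default_factory=lambda: {"sixframe"})
    classification: str | None = None
    partial: bool = False
    attributes: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start

    def as_gene_model(self, gene_id: str) -> GeneModel:
        attrs = dict(self.attributes)
        attrs["evidence"] = ",".join(sorted(self.evidence))
        if self.classification:
            attrs["classification"] = self.classification
        if self.partial:
            attrs["partial"] = "true"
            attrs["broken"] = "true"
        return GeneModel(gene_id=gene_id, chrom=self.chrom, start=self.start,
                         end=self.end, strand=self.strand, kind="novel_ORF",
                         attributes=attrs)


def extract_intergenic(
    annotation: Sequence[GeneModel],
    genome: GenomeSequence,
    min_len: int = 1,
) -> list[IntergenicRegion]:
    """Complement of the annotated features, clipped to the genome.

    Regions shorter than ``min_len`` are dropped.  Flanking gene ids name
    the nearest annotated feature on each side (None at genome edges).
    """
    feats = sorted(
        (g for g in annotation if g.chrom == genome.id), key=lambda g: (g.start, g.end)
    )
    regions: list[IntergenicRegion] = []
    cursor = 0
    upstream: str | None = None
    for g in feats:
        s = max(0, min(g.start, genome.length))
        if s > cursor:
            regions.append(IntergenicRegion(genome.id, cursor, s, (upstream, g.gene_id)))
        cursor = max(cursor, min(g.end, genome.length))
        upstream = g.gene_id
    if cursor < genome.length:
        regions.append(IntergenicRegion(genome.id, cursor, genome.length, (upstream, None)))
    return [r for r in regions if r.length >= min_len]


def _scan_frame(
    dna: str,
    frame_offset: int,
    min_nt: int,
    start_codons: Sequence[str],
) -> list[tuple[int, int, str | None, bool]]:
    """ORFs in one frame of a reading-direction sequence.

    Returns (start, end, start_codon, partial) in reading-direction
    coordinates.  ``end`` *includes* the stop codon (the GFF3 CDS
    convention), so candidate spans are directly comparable with gene
    models; the minimum-length test counts coding nt only.  Segments with
    no stop run to the sequence edge and are flagged partial.
    """
    out = []
    n = len(dna)
    i = frame_offset
    starts_in_seg: list[int] = []
    while i + 3 <= n:
        codon = dna[i : i + 3]
        if codon in STOP_CODONS:
            if starts_in_seg:
                s = starts_in_seg[0]
                if i - s >= min_nt:
                    out.append((s, i + 3, dna[s : s + 3], False))
            starts_in_seg = []
        elif codon in start_codons and not starts_in_seg:
            starts_in_seg = [i]
        i += 3
    if starts_in_seg:
        s = starts_in_seg[0]
        if i - s >= min_nt:
            out.append((s, i, dna[s : s + 3], True))
    return out


def six_frame_orfs(
    region: IntergenicRegion,
    genome: GenomeSequence,
    min_aa: int = DEFAULT_MIN_AA,
    start_codons: Sequence[str] = START_CODONS,
) -> list[CandidateORF]:
    """Enumerate candidate ORFs in all six frames of one region.

    ``min_aa`` counts residues excluding the stop; partial ORFs (no stop
    before the region edge) are kept and flagged.  A region of only N
    yields nothing (translation has no start codons there).
    """
    seq = genome.subseq(region.start, region.end)
    rc = revcomp(seq)
    n = len(seq)
    min_nt = 3 * min_aa
    orfs: list[CandidateORF] = []
    for f in range(3):
        for s, e, codon, partial in _scan_frame(seq, f, min_nt, start_codons):
            gs, ge = region.start + s, region.start + e
            orfs.append(
                CandidateORF(chrom=region.chrom, start=gs, end=ge, strand="+",
                             frame=gs % 3, protein=translate(seq[s:e]).rstrip("*"),
                             start_codon=codon, partial=partial)
            )
        for s, e, codon, partial in _scan_frame(rc, f, min_nt, start_codons):
            gs, ge = region.end - e, region.end - s
            orfs.append(
                CandidateORF(chrom=region.chrom, start=gs, end=ge, strand="-",
                             frame=ge % 3, protein=translate(rc[s:e]).rstrip("*"),
                             start_codon=codon, partial=partial)
            )
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def orfs_to_protein_fasta(orfs: Iterable[CandidateORF], path) -> None:
    """Protein FASTA of candidates — the peptide search space."""
    with open(path, "w") as fh:
        for i, o in enumerate(orfs, start=1):
            fh.write(f">orf_{i:05d} {o.chrom}:{o.start}-{o.end}({o.strand})\n{o.protein}\n")
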