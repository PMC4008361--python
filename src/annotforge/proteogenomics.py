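"""Peptide-to-genome mapping, in-frame ORF expansion and confidence filtering.

The proteogenomic workhorse: exact amino-acid matching of identified
peptides against the six-frame translation of the genome, expansion of
uniquely-mapping peptides into full ORFs (downstream to the first
in-frame stop, upstream to the 5'-most allowed start codon below the
bounding stop), classification against the existing annotation, and the
acceptance rules of shotgun proteomics — at least two independent
peptides at >= 95% confidence, or a single confident peptide backed by
transcriptional evidence.

I and L are treated as equivalent during matching by default: collision-
induced dissociation cannot distinguish the isobaric pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import GeneModel, GenomeSequence
from .orf_discovery import CandidateORF
from .sequtils import START_CODONS, STOP_CODONS, collapse_il, revcomp, translate

__all__ = [
    "Placement",
    "PeptideHit",
    "ProteinCall",
    "map_peptides",
    "expand_to_orf",
    "classify_orf",
    "filter_proteins",
    "discover_proteins",
    "CONFIDENCE_THRESHOLD",
    "MIN_PEPTIDES",
]

#: the "95% confident" peptide threshold and the two-peptide protein rule
CONFIDENCE_THRESHOLD = 95.0
MIN_PEPTIDES = 2

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Placement:
    chrom: str
    start: int
    end: int
    strand: str
    frame: int


@dataclass
class PeptideHit:
    peptide: str
    confidence: float
    sample: str = ""
    placements: list[Placement] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.confidence <= 100:
            raise ValueError(f"confidence {self.confidence} outside [0, 100]")

    @property
    def unique(self) -> bool:
        return len(self.placements) == 1


@dataclass
class ProteinCall:
    orf: CandidateORF
    peptides: list[PeptideHit]
    n_conf_peptides: int = 0
    status: str = "needs_rna_validation"
    rna_validated: bool = False


def _frame_index(genome_length: int):
    """Six translated frames with coordinate converters.

    Yields (strand, offset, protein, to_genome) where
    to_genome(aa_start, aa_len) -> (start, end, frame) in genome coords.
    """

    def plus(off):
        def conv(i: int, p: int) -> tuple[int, int, int]:
            s = off + 3 * i
            return s, s + 3 * p, s % 3

        return conv

    def minus(off, L):
        def conv(i: int, p: int) -> tuple[int, int, int]:
            rs = off + 3 * i
            re_ = rs + 3 * p
            return L - re_, L - rs, (L - rs) % 3

        return conv

    return plus, minus


def map_peptides(
    peptides: pd.DataFrame | Sequence[tuple[str, float, str]],
    genome: GenomeSequence,
    il_equivalent: bool = True,
) -> list[PeptideHit]:
    """Exact aa-level placements of each peptide in the six-frame translation.

    Peptides with non-standard residues (B/Z/X/U...) are skipped with a
    warning.  Every placement spans 3x the peptide length in nt.
    """
    if isinstance(peptides, pd.DataFrame):
        rows = list(peptides[["peptide", "confidence", "sample"]].itertuples(index=False))
    else:
        rows = list(peptides)

    L = genome.length
    rc = revcomp(genome.seq)
    plus_conv, minus_conv = _frame_index(L)
    frames = []
    for f in range(3):
        frames.append((translate(genome.seq[f:]), plus_conv(f), "+"))
        frames.append((translate(rc[f:]), minus_conv(f, L), "-"))
    if il_equivalent:
        frames = [(collapse_il(t), conv, st) for t, conv, st in frames]

    hits: list[PeptideHit] = []
    for pep, conf, sample in rows:
        pep = str(pep)
        if set(pep) - _AA20:
            warnings.warn(f"peptide {pep!r} contains non-standard residues; skipped",
                          stacklevel=2)
            continue
        query = collapse_il(pep) if il_equivalent else pep
        placements = []
        for text, conv, strand in frames:
            i = text.find(query)
            while i != -1:
                s, e, frame = conv(i, len(pep))
                placements.append(Placement(genome.id, s, e, strand, frame))
                i = text.find(query, i + 1)
        placements.sort(key=lambda p: (p.start, p.strand))
        hits.append(PeptideHit(peptide=pep, confidence=float(conf), sample=str(sample),
                               placements=placements))
    return hits


def expand_to_orf(
    hit: PeptideHit,
    genome: GenomeSequence,
    max_extension: int = 3000,
    start_codons: Sequence[str] = START_CODONS,
) -> CandidateORF:
    """In-frame expansion of a uniquely-mapping peptide into a full ORF.

    Downstream: to the first in-frame stop codon (included in the span, as
    in a GFF3 CDS).  Upstream: scan codon-by-codon for the bounding stop;
    the ORF starts at the 5'-most allowed start codon below it.  Partial
    flags are raised when no start exists below the bounding stop, or when
    no stop appears within ``max_extension`` nt — the signature of a
    frameshifted/broken gene model.
    """
    if not hit.unique:
        raise ValueError("only uniquely-mapping peptides seed ORF expansion")
    p = hit.placements[0]
    L = genome.length
    if p.strand == "+":
        text = genome.seq
        rs, re_ = p.start, p.end
    else:
        text = revcomp(genome.seq)
        rs, re_ = L - p.end, L - p.start

    # downstream
    k = re_
    down_end = None
    while k + 3 <= L:
        if text[k : k + 3] in STOP_CODONS:
            down_end = k + 3
            break
        k += 3
    partial = down_end is None
    if down_end is None:
        down_end = k  # last full codon boundary before the edge

    # upstream
    k = rs
    best_start = None
    found_stop = False
    scanned = 0
    while k - 3 >= 0 and scanned < max_extension:
        k -= 3
        scanned += 3
        codon = text[k : k + 3]
        if codon in STOP_CODONS:
            found_stop = True
            break
        if codon in start_codons:
            best_start = k
    if text[rs : rs + 3] in start_codons and best_start is None:
        best_start = rs
    if not found_stop and k - 3 >= 0:
        partial = True  # ran out of extension budget in a stop-free frame
    if best_start is None:
        partial = True
        up_start = (k + 3) if found_stop else max(k, rs % 3)
    else:
        up_start = best_start

    if p.strand == "+":
        gs, ge = up_start, down_end
    else:
        gs, ge = L - down_end, L - up_start
    prot = translate(text[up_start:down_end]).rstrip("*")
    codon0 = text[up_start : up_start + 3]
    return CandidateORF(
        chrom=genome.id, start=gs, end=ge, strand=p.strand,
        frame=gs % 3 if p.strand == "+" else ge % 3,
        protein=prot, start_codon=codon0 if codon0 in start_codons else None,
        evidence={"peptide"}, partial=partial,
    )


def _is_hypothetical(gene: GeneModel) -> bool:
    return "hypothetical" in gene.attributes.get("product", "").lower()


def classify_orf(
    orf: CandidateORF,
    annotation: Sequence[GeneModel],
    near_frame_nt: int = 3,
) -> str:
    """novel / confirms_hypothetical / extension / frameshift_flag.

    Same-strand, same-frame overlap with an annotated model confirms or
    extends it; a near-frame offset (boundaries within ``near_frame_nt``
    of an annotated model but a different frame), or a partial expansion
    flush against one, marks a suspected frameshift mis-annotation.
    ORFs with no same-strand overlap — including antisense ones — are
    novel.
    """
    same_strand = [
        g for g in annotation
        if g.chrom == orf.chrom and g.strand == orf.strand
        and g.start < orf.end and orf.start < g.end
    ]
    for g in same_strand:
        same_frame = (orf.frame == g.frame())
        if same_frame:
            if _is_hypothetical(g):
                return "confirms_hypothetical"
            return "extension"
        if min(abs(orf.start - g.start), abs(orf.end - g.end)) <= near_frame_nt:
            return "frameshift_flag"
    if orf.partial:
        for g in annotation:
            if g.chrom == orf.chrom and g.strand == orf.strand and (
                abs(orf.start - g.end) <= near_frame_nt
                or abs(g.start - orf.end) <= near_frame_nt
            ):
                return "frameshift_flag"
    return "novel"


def filter_proteins(
    calls: Iterable[ProteinCall],
    transcription_evidence: Callable[[CandidateORF], bool] | Mapping | None = None,
    confidence_threshold: float = CONFIDENCE_THRESHOLD,
    min_peptides: int = MIN_PEPTIDES,
) -> list[ProteinCall]:
    """Apply the protein-level acceptance rules.

    A call is accepted with >= ``min_peptides`` distinct peptide sequences
    at >= ``confidence_threshold``; a single confident peptide needs RNA
    validation (its ORF transcribed) to be accepted; anything else is
    rejected.  With no transcription evidence supplied, single-peptide
    calls stay ``needs_rna_validation``.
    """
    out = []
    for call in calls:
        confident = {h.peptide for h in call.peptides
                     if h.confidence >= confidence_threshold}
        call.n_conf_peptides = len(confident)
        if call.n_conf_peptides >= min_peptides:
            call.status = "accepted"
        elif call.n_conf_peptides == 1:
            if transcription_evidence is None:
                call.status = "needs_rna_validation"
            else:
                if callable(transcription_evidence):
                    call.rna_validated = bool(transcription_evidence(call.orf))
                else:
                    key = (call.orf.start, call.orf.end, call.orf.strand)
                    call.rna_validated = bool(transcription_evidence.get(key, False))
                call.status = "accepted" if call.rna_validated else "rejected"
                if call.rna_validated:
                    call.orf.evidence.add("transcription")
        else:
            call.status = "rejected"
        out.append(call)
    return out


def discover_proteins(
    peptides: pd.DataFrame | Sequence[tuple[str, float, str]],
    genome: GenomeSequence,
    annotation: Sequence[GeneModel],
    transcription_evidence: Callable[[CandidateORF], bool] | None = None,
    il_equivalent: bool = True,
    max_extension: int = 3000,
    confidence_threshold: float = CONFIDENCE_THRESHOLD,
    min_peptides: int = MIN_PEPTIDES,
) -> list[ProteinCall]:
    """End-to-end peptide-driven protein discovery.

    Unique placements seed ORF expansion; non-unique peptides never seed
    but may support an already-seeded ORF when one of their placements
    lies in-frame inside it.  ORFs seeded by several peptides are merged.
    """
    hits = map_peptides(peptides, genome, il_equivalent=il_equivalent)
    orfs: dict[tuple[int, int, str], ProteinCall] = {}
    supporting: list[PeptideHit] = []
    for hit in hits:
        if not hit.placements:
            continue
        if not hit.unique:
            supporting.append(hit)
            continue
        orf = expand_to_orf(hit, genome, max_extension=max_extension)
        key = (orf.start, orf.end, orf.strand)
        if key not in orfs:
            orf.classification = classify_orf(orf, annotation)
            orfs[key] = ProteinCall(orf=orf, peptides=[])
        orfs[key].peptides.append(hit)
    for hit in supporting:
        for p in hit.placements:
            for (s, e, st), call in orfs.items():
                if (st == p.strand and s <= p.start and p.end <= e
                        and p.frame == call.orf.frame):
                    call.peptides.append(hit)
                    break
    calls = filter_proteins(
        list(orfs.values()), transcription_evidence,
        confidence_threshold=confidence_threshold, min_peptides=min_peptides,
    )
    calls.sort(key=lambda c: (c.orf.start, c.orf.end))
    return calls
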