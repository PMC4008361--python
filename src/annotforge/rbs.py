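"""Ribosome-binding-site inference from small-RNA fragment termini.

During the growth-arrest ("metabolic switch") degradation programme,
stalled ribosomes shield the Shine-Dalgarno region and the codon lattice
from endogenous cleavage, so the 5' termini of surviving 15-50 nt
fragments pile up at the SD window and step with 3 nt periodicity
through the CDS.  This module aggregates fragment termini into metagene
profiles anchored at start/stop codons, detects the protected SD window
globally and per gene, estimates the dominant periodicity of interior
5' termini, and emits per-gene RBS calls.

Offset convention (documented on every output): 0 = the first base of
the anchor codon (the A of ATG); negative offsets are 5'/upstream of it,
in transcript orientation.  The 3' terminus of a half-open fragment
[s, e) is the base e-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import FragmentAlignment, GeneModel, GenomeSequence
from .orf_discovery import CandidateORF

__all__ = [
    "TerminiProfile",
    "RBSCall",
    "metagene_termini",
    "detect_protection_window",
    "estimate_periodicity",
    "call_rbs",
    "DEFAULT_WINDOW",
    "SEARCH_RANGE",
    "DEFAULT_FOLD",
    "DEFAULT_MIN_FRAGMENTS",
]

DEFAULT_WINDOW = 40
#: offset range searched for the protected SD window: the SD sits 4-15 nt
#: upstream of the start, with a small allowance into the codon itself
SEARCH_RANGE = (-20, 3)
DEFAULT_FOLD = 3.0
DEFAULT_MIN_FRAGMENTS = 10
DEFAULT_MIN_PEAK = 5.0
INTERIOR_TRIM = 9  # nt excluded at each CDS end for periodicity


@dataclass
class TerminiProfile:
    """Per-offset 5'/3' termini counts around an anchor, summed over genes."""

    anchor: str  # 'start_codon' or 'stop_codon'
    window: int
    counts5: np.ndarray
    counts3: np.ndarray
    n_genes: int

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.window, self.window + 1)

    def at5(self, offset: int) -> float:
        return float(self.counts5[offset + self.window])

    def at3(self, offset: int) -> float:
        return float(self.counts3[offset + self.window])


@dataclass
class RBSCall:
    gene_id: str
    window: tuple[int, int]  # genome coordinates, half-open
    peak_offset: int
    score: float
    sd_match: bool
    n_fragments: float = 0.0


def _anchor_position(gene: GeneModel | CandidateORF, anchor: str) -> int:
    """Genome coordinate of the first base of the anchor codon."""
    gid_start = gene.start
    gid_end = gene.end
    if anchor == "start_codon":
        return gid_start if gene.strand == "+" else gid_end - 1
    if anchor == "stop_codon":
        return gid_end - 3 if gene.strand == "+" else gid_start + 2
    raise ValueError(f"unknown anchor {anchor!r}")


def _termini_offsets(
    frag: FragmentAlignment, gene: GeneModel | CandidateORF, anchor_pos: int
) -> tuple[int, int]:
    """Signed (5', 3') offsets of a sense fragment in transcript orientation."""
    if gene.strand == "+":
        return frag.start - anchor_pos, (frag.end - 1) - anchor_pos
    return anchor_pos - (frag.end - 1), anchor_pos - frag.start


def metagene_termini(
    fragments: Sequence[FragmentAlignment],
    genes: Sequence[GeneModel | CandidateORF],
    window: int = DEFAULT_WINDOW,
    anchor: str = "start_codon",
) -> TerminiProfile:
    """Aggregate sense-strand fragment termini around the anchor codon.

    Each fragment contributes its (count-weighted) 5' and 3' termini at
    signed offsets; a terminus outside [-window, +window] is simply not
    counted, so genes near contig edges contribute their truncated
    window without bias.
    """
    size = 2 * window + 1
    counts5 = np.zeros(size)
    counts3 = np.zeros(size)
    by_chrom: dict[str, list[FragmentAlignment]] = {}
    for f in fragments:
        by_chrom.setdefault(f.chrom, []).append(f)
    n_genes = 0
    for gene in genes:
        pool = by_chrom.get(gene.chrom, ())
        apos = _anchor_position(gene, anchor)
        contributed = False
        for f in pool:
            if f.strand != gene.strand:
                continue
            o5, o3 = _termini_offsets(f, gene, apos)
            if -window <= o5 <= window:
                counts5[o5 + window] += f.count
                contributed = True
            if -window <= o3 <= window:
                counts3[o3 + window] += f.count
                contributed = True
        if contributed:
            n_genes += 1
    return TerminiProfile(anchor=anchor, window=window, counts5=counts5,
                          counts3=counts3, n_genes=n_genes)


def _window_call(
    counts5: np.ndarray,
    window: int,
    fold: float,
    min_peak: float,
    search: tuple[int, int] = SEARCH_RANGE,
) -> tuple[tuple[int, int] | None, int | None, float]:
    """Protected-run detection on one counts5 array.

    Background is the median count over offsets outside the search range;
    a call requires the peak inside the range to exceed fold x
    max(background, 1) and an absolute peak floor.  Returns
    ((run_lo, run_hi), peak_offset, score); run bounds are inclusive
    offsets.
    """
    offs = np.arange(-window, window + 1)
    in_search = (offs >= search[0]) & (offs <= search[1])
    flank = counts5[~in_search]
    bg = max(float(np.median(flank)), 1.0)
    inside = counts5[in_search]
    if inside.size == 0 or inside.max() < max(fold * bg, min_peak):
        return None, None, 0.0
    peak_idx = int(np.argmax(inside))
    peak_offset = int(offs[in_search][peak_idx])
    score = float(inside.max() / bg)
    # contiguous run around the peak where counts exceed fold x background
    above = inside >= fold * bg
    lo = peak_idx
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak_idx
    while hi < above.size - 1 and above[hi + 1]:
        hi += 1
    run = (int(offs[in_search][lo]), int(offs[in_search][hi]))
    return run, peak_offset, score


def detect_protection_window(
    profile: TerminiProfile,
    genes: Sequence[GeneModel | CandidateORF] | None = None,
    fragments: Sequence[FragmentAlignment] | None = None,
    genome: GenomeSequence | None = None,
    motif: str = "AGGAGG",
    fold: float = DEFAULT_FOLD,
    min_peak: float = DEFAULT_MIN_PEAK,
    min_fragments: float = DEFAULT_MIN_FRAGMENTS,
) -> dict:
    """Global protected window, plus per-gene protection calls.

    The global call runs on the pooled metagene profile; per-gene calls
    repeat the identical test on each gene's own termini (requiring at
    least ``min_fragments`` weighted termini in the search range).
    ``sd_match`` reports an exact or 1-mismatch occurrence of the motif
    within the protected window sequence (always False for an empty
    motif, which decouples motif annotation from window calling).
    """
    run, peak, score = _window_call(profile.counts5, profile.window, fold, min_peak)
    result = {"global_window": run, "global_peak_offset": peak, "global_score": score,
              "per_gene": []}
    if genes is None or fragments is None:
        return result
    for gene in genes:
        prof = metagene_termini(fragments, [gene], window=profile.window,
                                anchor="start_codon")
        offs = prof.offsets
        in_search = (offs >= SEARCH_RANGE[0]) & (offs <= SEARCH_RANGE[1])
        if prof.counts5[in_search].sum() < min_fragments:
            continue
        g_run, g_peak, g_score = _window_call(prof.counts5, prof.window, fold, min_peak)
        if g_run is None:
            continue
        gid = getattr(gene, "gene_id", f"{gene.chrom}:{gene.start}-{gene.end}")
        apos = _anchor_position(gene, "start_codon")
        if gene.strand == "+":
            gwin = (apos + g_run[0], apos + g_run[1] + 1)
        else:
            gwin = (apos - g_run[1], apos - g_run[0] + 1)
        sd = False
        if motif and genome is not None:
            lo = max(0, gwin[0] - len(motif))
            hi = min(genome.length, gwin[1] + len(motif))
            seq = genome.subseq(lo, hi, gene.strand)
            sd = _fuzzy_find(seq, motif, max_mismatch=1)
        result["per_gene"].append(
            RBSCall(gene_id=gid, window=gwin, peak_offset=g_peak, score=g_score,
                    sd_match=sd,
                    n_fragments=float(prof.counts5[in_search].sum()))
        )
    return result


def _fuzzy_find(seq: str, motif: str, max_mismatch: int = 1) -> bool:
    m = len(motif)
    for i in range(len(seq) - m + 1):
        if sum(a != b for a, b in zip(seq[i : i + m], motif)) <= max_mismatch:
            return True
    return False


def interior_termini_counts(
    fragments: Sequence[FragmentAlignment],
    genes: Sequence[GeneModel],
    trim: int = INTERIOR_TRIM,
) -> np.ndarray:
    """Pooled per-offset 5'-termini counts over CDS interiors.

    Offsets are transcript positions relative to the start codon; the
    first and last ``trim`` nt of each CDS are excluded so initiation and
    termination pile-ups do not leak into the elongation-phase signal.
    The pooled vector is as long as the longest contributing CDS.
    """
    max_len = max((g.end - g.start for g in genes), default=0)
    counts = np.zeros(max_len)
    by_chrom: dict[str, list[FragmentAlignment]] = {}
    for f in fragments:
        by_chrom.setdefault(f.chrom, []).append(f)
    for gene in genes:
        glen = gene.end - gene.start
        for f in by_chrom.get(gene.chrom, ()):
            if f.strand != gene.strand:
                continue
            t5 = (f.start - gene.start) if gene.strand == "+" else (gene.end - 1 - f.end + 1)
            if trim <= t5 < glen - trim:
                counts[t5] += f.count
    return counts


def autocorrelation_periodicity(
    counts: np.ndarray, max_lag: int = 10, min_lag: int = 2
) -> tuple[int | None, float]:
    """Dominant period of a count vector by normalized autocorrelation.

    Returns (period, strength); strength is the peak autocorrelation's
    excess over the median across the scanned lags.
    """
    x = np.asarray(counts, dtype=float)
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0 or x.size <= max_lag:
        return None, 0.0
    lags = np.arange(min_lag, max_lag + 1)
    ac = np.array([np.dot(x[:-k], x[k:]) / denom for k in lags])
    best = int(np.argmax(ac))
    strength = float(ac[best] - np.median(ac))
    return int(lags[best]), strength


def estimate_periodicity(
    fragments: Sequence[FragmentAlignment],
    genes: Sequence[GeneModel],
    max_lag: int = 10,
    min_fragments: int = 50,
    min_genes: int = 3,
) -> dict:
    """Dominant periodicity of interior 5' termini across expressed genes.

    Translating ribosomes step one codon at a time, so a translated
    transcript pool shows period 3.  Returns a diagnostic dict with
    ``period`` None when too little signal is present.
    """
    genes = [g for g in genes if g.kind == "CDS"]
    if len(genes) < min_genes:
        return {"period": None, "strength": 0.0, "n_termini": 0,
                "reason": f"fewer than {min_genes} genes"}
    counts = interior_termini_counts(fragments, genes)
    total = float(counts.sum())
    if total < min_fragments:
        return {"period": None, "strength": 0.0, "n_termini": int(total),
                "reason": f"fewer than {min_fragments} interior termini"}
    period, strength = autocorrelation_periodicity(counts, max_lag=max_lag)
    return {"period": period, "strength": strength, "n_termini": int(total)}


def call_rbs(
    genes: Sequence[GeneModel | CandidateORF],
    fragments: Sequence[FragmentAlignment],
    genome: GenomeSequence | None = None,
    motif: str = "AGGAGG",
    window: int = DEFAULT_WINDOW,
    fold: float = DEFAULT_FOLD,
    min_peak: float = DEFAULT_MIN_PEAK,
    min_fragments: float = DEFAULT_MIN_FRAGMENTS,
) -> tuple[list[RBSCall], list[str]]:
    """Per-gene RBS calls plus the ids of genes receiving none.

    Any anchor with a defined start works — annotated genes and novel
    ORFs from the proteogenomic arm alike.
    """
    profile = metagene_termini(fragments, genes, window=window, anchor="start_codon")
    res = detect_protection_window(
        profile, genes=genes, fragments=fragments, genome=genome, motif=motif,
        fold=fold, min_peak=min_peak, min_fragments=min_fragments,
    )
    calls: list[RBSCall] = res["per_gene"]
    called = {c.gene_id for c in calls}
    misses = [getattr(g, "gene_id", f"{g.chrom}:{g.start}-{g.end}")
              for g in genes
              if getattr(g, "gene_id", f"{g.chrom}:{g.start}-{g.end}") not in called]
    return calls, misses


def rbs_calls_to_gene_models(calls: Sequence[RBSCall], chrom: str,
                             strand_of: dict[str, str]) -> list[GeneModel]:
    out = []
    for c in calls:
        out.append(
            GeneModel(
                gene_id=f"rbs_{c.gene_id}", chrom=chrom,
                start=c.window[0], end=c.window[1],
                strand=strand_of.get(c.gene_id, "+"), kind="RBS",
                attributes={"peak_offset": str(c.peak_offset),
                            "score": f"{c.score:.2f}",
                            "sd_match": str(c.sd_match).lower(),
                            "target": c.gene_id},
            )
        )
    return out
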