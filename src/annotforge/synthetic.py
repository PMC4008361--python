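"""Synthetic multi-omics data with planted ground truth.

Generates a toy high-G+C bacterial genome (default 72% G+C, the regime in
which ab initio gene callers struggle because stop codons are depleted),
together with every omics layer the pipeline consumes:

* an "annotated" gene set plus *hidden* genes left out of the emitted GFF3,
* a Shine-Dalgarno motif at a fixed spacer upstream of every start codon,
* one mis-annotated frameshift gene (the annotation is emitted shifted by
  one base relative to the true gene, emulating a missing base in the
  reference assembly),
* per-time-point stranded coverage tracks with dynamic expression and
  planted non-coding transcribed intergenic segments,
* small-RNA fragments with SD-protected 5' termini and a codon-step
  (3 nt periodic) interior population,
* a peptide table with confident true peptides and shuffled decoys,
* a domain/orphan-reaction/ortholog fixture for the metabolic annotator.

Every generator is deterministic under a fixed seed.  Planted genes are
constructed to be *maximal* ORFs: an in-frame stop codon is written just
upstream of the SD region and the spacer is resampled so that no in-frame
start or stop codon sits between that stop and the planted start codon.
This makes "exact coordinate recovery" well defined for the 5'-most-start
expansion convention used downstream.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    CoverageTrack,
    FragmentAlignment,
    GenomeSequence,
    GeneModel,
    FRAGMENT_MIN_LEN,
    FRAGMENT_MAX_LEN,
)
from .sequtils import (
    START_CODONS,
    STOP_CODONS,
    collapse_il,
    revcomp,
    six_frame_translations,
    translate,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_genome",
    "simulate_coverage",
    "simulate_fragments",
    "simulate_peptides",
    "simulate_gsmr_fixture",
    "simulate_all",
    "write_simulation",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions emulated."""

    seed: int = 0
    chrom_id: str = "synth1"
    genome_length: int = 100_000
    gc_content: float = 0.72
    n_annotated_genes: int = 40
    n_hidden_genes: int = 6
    n_hypothetical: int = 6
    n_confirmed_hypothetical: int = 2
    annotated_aa_range: tuple[int, int] = (120, 400)
    hidden_aa_range: tuple[int, int] = (40, 120)
    sd_motif: str = "AGGAGG"
    sd_spacer: int = 7
    frameshift_genes: int = 1
    n_intergenic_transcripts: int = 8
    intergenic_transcript_len: tuple[int, int] = (120, 400)
    min_gap: int = 250
    max_gap: int = 1200
    coverage_depth: float = 30.0
    background_depth: float = 0.05
    n_time_points: int = 6
    fragment_protection_strength: float = 8.0
    fragments_per_gene: float = 150.0
    background_fragments: float = 300.0
    n_decoy_peptides: int = 15
    true_conf_mean: float = 98.0
    true_conf_sd: float = 1.5
    decoy_conf_mean: float = 60.0
    decoy_conf_sd: float = 15.0
    n_orphan_reactions_extra: int = 4
    synteny_k: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if self.sd_spacer < 4 or self.sd_spacer + len(self.sd_motif) > 15 + len(self.sd_motif):
            # SD window must sit 4-15 nt upstream of the start
            raise ValueError("sd_spacer must place the SD 4-15 nt upstream of the start")
        if self.n_time_points < 1:
            raise ValueError("need at least one time point")

    @property
    def sd_offset(self) -> int:
        """Offset of the SD motif 5' end from the start codon (negative)."""
        return -(self.sd_spacer + len(self.sd_motif))


@dataclass
class GroundTruth:
    """Everything planted, for recovery scoring downstream."""

    chrom: str
    genome_length: int
    genes: list[GeneModel] = field(default_factory=list)  # true models, incl. hidden
    annotated: list[GeneModel] = field(default_factory=list)  # emitted GFF3 content
    rbs_positions: dict[str, tuple[int, int]] = field(default_factory=dict)
    frameshift_sites: list[tuple[str, int]] = field(default_factory=list)
    transcribed_segments: list[GeneModel] = field(default_factory=list)
    expression: dict[str, float] = field(default_factory=dict)
    dynamics: dict[str, str] = field(default_factory=dict)
    gene_proteins: dict[str, str] = field(default_factory=dict)
    true_peptides: dict[str, str] = field(default_factory=dict)  # peptide -> gene_id
    decoy_peptides: list[str] = field(default_factory=list)
    gsmr_truth: dict[str, str | None] = field(default_factory=dict)

    @property
    def hidden_genes(self) -> list[GeneModel]:
        return [g for g in self.genes if g.attributes.get("hidden") == "true"]

    @property
    def frameshift_gene_ids(self) -> list[str]:
        return [gid for gid, _ in self.frameshift_sites]

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def to_json_dict(self) -> dict:
        def model(g: GeneModel) -> dict:
            return {
                "gene_id": g.gene_id,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "kind": g.kind,
                "attributes": g.attributes,
            }

        return {
            "chrom": self.chrom,
            "genome_length": self.genome_length,
            "genes": [model(g) for g in self.genes],
            "annotated": [model(g) for g in self.annotated],
            "rbs_positions": {k: list(v) for k, v in self.rbs_positions.items()},
            "frameshift_sites": [list(t) for t in self.frameshift_sites],
            "transcribed_segments": [model(g) for g in self.transcribed_segments],
            "expression": self.expression,
            "dynamics": self.dynamics,
            "true_peptides": self.true_peptides,
            "decoy_peptides": self.decoy_peptides,
            "gsmr_truth": self.gsmr_truth,
        }


# ---------------------------------------------------------------------------
# genome


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    return "".join(rng.choice(_BASES, size=n, p=_base_probs(gc)))


def _sense_codons(rng: np.random.Generator, n: int, gc: float) -> str:
    """n codons sampled base-wise at the target G+C, stop codons resampled."""
    codons = rng.choice(_BASES, size=(n, 3), p=_base_probs(gc))
    joined = np.char.add(np.char.add(codons[:, 0], codons[:, 1]), codons[:, 2])
    while True:
        bad = np.isin(joined, STOP_CODONS)
        if not bad.any():
            return "".join(joined)
        redo = rng.choice(_BASES, size=(int(bad.sum()), 3), p=_base_probs(gc))
        joined[bad] = np.char.add(np.char.add(redo[:, 0], redo[:, 1]), redo[:, 2])


def _gene_cds(rng: np.random.Generator, aa_len: int, gc: float) -> str:
    """A CDS of aa_len residues: start codon, stop-free body, one stop."""
    start = rng.choice(START_CODONS, p=[0.5, 0.35, 0.15])
    body = _sense_codons(rng, aa_len - 1, gc)
    stop = rng.choice(STOP_CODONS, p=[0.2, 0.3, 0.5])
    return start + body + stop


def _upstream_block(rng: np.random.Generator, config: SimulationConfig) -> tuple[str, int]:
    """Upstream cassette (transcript orientation) ending at the start codon.

    Layout at offsets relative to the start codon: an in-frame stop codon at
    -m, pad, the SD motif at sd_offset, then the spacer.  Resamples pad and
    spacer until no in-frame codon between the stop and the start is itself
    a start or stop codon (which would break maximal-ORF recovery).
    Returns (block, m) with len(block) == m.
    """
    u = config.sd_spacer + len(config.sd_motif)
    m = 3 * math.ceil((u + 3) / 3)
    pad_len = m - 3 - u
    stop = rng.choice(STOP_CODONS, p=[0.2, 0.3, 0.5])
    for _ in range(200):
        pad = _random_dna(rng, pad_len, config.gc_content)
        spacer = _random_dna(rng, config.sd_spacer, config.gc_content)
        tail = pad + config.sd_motif + spacer  # length m - 3
        codons = [tail[i : i + 3] for i in range(0, len(tail) - 2, 3)]
        if not any(c in START_CODONS or c in STOP_CODONS for c in codons):
            return stop + tail, m
    raise RuntimeError("could not sample a clean upstream block")


_PROFILE_CYCLE = ("constant", "switch_down", "switch_up", "pulse")


def _dynamics_multipliers(profile: str, n: int) -> np.ndarray:
    t = np.arange(n)
    if profile == "constant":
        return np.ones(n)
    if profile == "switch_down":
        return np.geomspace(1.0, 0.2, n)
    if profile == "switch_up":
        return np.geomspace(0.2, 1.0, n)
    if profile == "pulse":
        mid = (n - 1) / 2
        return 0.3 + 0.7 * np.exp(-0.5 * ((t - mid) / (n / 4)) ** 2)
    raise ValueError(profile)


def simulate_genome(config: SimulationConfig) -> tuple[GenomeSequence, GroundTruth]:
    """Plant genes, SD motifs, a frameshift mis-annotation and expression.

    Raises ``ValueError`` suggesting a larger genome when the requested
    genes cannot be placed without overlap after bounded retries.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_annotated_genes + config.n_hidden_genes

    # per-gene lengths; hidden genes drawn shorter (novel genes are small)
    aa_lens = list(
        rng.integers(config.annotated_aa_range[0], config.annotated_aa_range[1] + 1,
                     size=config.n_annotated_genes)
    ) + list(
        rng.integers(config.hidden_aa_range[0], config.hidden_aa_range[1] + 1,
                     size=config.n_hidden_genes)
    )
    hidden_flags = [False] * config.n_annotated_genes + [True] * config.n_hidden_genes
    order = rng.permutation(n_total)

    # layout: alternating gaps and gene cassettes, bounded retries
    u = config.sd_spacer + len(config.sd_motif)
    m = 3 * math.ceil((u + 3) / 3)
    layout = None
    for _attempt in range(20):
        cursor = int(rng.integers(config.min_gap, config.max_gap + 1))
        slots = []
        gaps = [(0, cursor)]
        ok = True
        for idx in order:
            nt = 3 * (int(aa_lens[idx]) + 1)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                start = cursor + m
                span = (cursor, start + nt)
            else:
                start = cursor
                span = (cursor, start + nt + m)
            end = start + nt
            if span[1] > config.genome_length - config.min_gap:
                ok = False
                break
            slots.append((int(idx), start, end, strand))
            gap = int(rng.integers(config.min_gap, config.max_gap + 1))
            gaps.append((span[1], min(span[1] + gap, config.genome_length)))
            cursor = span[1] + gap
        if ok:
            layout = (slots, gaps)
            break
    if layout is None:
        raise ValueError(
            f"cannot place {n_total} genes in a {config.genome_length} nt genome "
            "without overlap; increase genome_length or reduce gene counts"
        )
    slots, gaps = layout
    gaps[-1] = (gaps[-1][0], config.genome_length)

    # background sequence, then paste cassettes
    seq = np.array(list(_random_dna(rng, config.genome_length, config.gc_content)))
    truth = GroundTruth(chrom=config.chrom_id, genome_length=config.genome_length)
    n_ann_seen = 0
    n_hid_seen = 0
    for idx, start, end, strand in slots:
        hidden = hidden_flags[idx]
        if hidden:
            n_hid_seen += 1
            gene_id = f"HID_{n_hid_seen:03d}"
        else:
            n_ann_seen += 1
            gene_id = f"SYN_{n_ann_seen:04d}"
        cds = _gene_cds(rng, int(aa_lens[idx]), config.gc_content)
        upstream, _m = _upstream_block(rng, config)
        cassette = upstream + cds
        if strand == "+":
            seq[start - m : end] = list(cassette)
            sd = (start + config.sd_offset, start + config.sd_offset + len(config.sd_motif))
        else:
            seq[start : end + m] = list(revcomp(cassette))
            sd = (end - config.sd_offset - len(config.sd_motif), end - config.sd_offset)
        attrs = {"hidden": "true"} if hidden else {}
        gene = GeneModel(gene_id=gene_id, chrom=config.chrom_id, start=start, end=end,
                         strand=strand, kind="CDS", attributes=attrs)
        truth.genes.append(gene)
        truth.rbs_positions[gene_id] = sd
        truth.gene_proteins[gene_id] = translate(cds)[:-1]
    truth.genes.sort(key=lambda g: g.start)

    genome = GenomeSequence(id=config.chrom_id, seq="".join(seq))

    # annotated set: non-hidden genes; hypothetical flags; frameshift shift
    annotated_true = [g for g in truth.genes if g.attributes.get("hidden") != "true"]
    fs_pool = list(range(len(annotated_true)))
    fs_idx = list(rng.choice(fs_pool, size=config.frameshift_genes, replace=False))
    hyp_pool = [i for i in fs_pool if i not in fs_idx]
    hyp_idx = set(rng.choice(hyp_pool, size=min(config.n_hypothetical, len(hyp_pool)),
                             replace=False).tolist())
    for i, g in enumerate(annotated_true):
        attrs = {"product": "hypothetical protein"} if i in hyp_idx else {}
        if i in fs_idx:
            # annotation derived from an assembly copy missing one base:
            # the emitted model sits one base out of frame with the truth
            shifted = GeneModel(gene_id=g.gene_id, chrom=g.chrom, start=g.start + 1,
                                end=g.end + 1, strand=g.strand, kind="CDS",
                                attributes={})
            truth.annotated.append(shifted)
            g.attributes["frameshift"] = "true"
            truth.frameshift_sites.append((g.gene_id, g.start + (g.end - g.start) // 2))
        else:
            truth.annotated.append(
                GeneModel(gene_id=g.gene_id, chrom=g.chrom, start=g.start, end=g.end,
                          strand=g.strand, kind="CDS", attributes=attrs)
            )
            if i in hyp_idx:
                g.attributes["hypothetical"] = "true"

    # non-coding transcribed intergenic segments, planted in large gaps
    lo, hi = config.intergenic_transcript_len
    big_gaps = [(s, e) for s, e in gaps if e - s >= hi + 80]
    pick = rng.permutation(len(big_gaps))[: config.n_intergenic_transcripts]
    for j, gi in enumerate(sorted(pick)):
        gs, ge = big_gaps[gi]
        seg_len = int(rng.integers(lo, hi + 1))
        s0 = int(rng.integers(gs + 30, ge - 30 - seg_len + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        truth.transcribed_segments.append(
            GeneModel(gene_id=f"NCT_{j + 1:03d}", chrom=config.chrom_id, start=s0,
                      end=s0 + seg_len, strand=strand, kind="region",
                      attributes={"noncoding": "true"})
        )

    # expression levels and temporal dynamics for every transcribed unit
    units = truth.genes + truth.transcribed_segments
    for i, unit in enumerate(units):
        truth.expression[unit.gene_id] = float(
            rng.lognormal(mean=np.log(max(config.coverage_depth, 1e-12)), sigma=0.6)
        ) if config.coverage_depth > 0 else 0.0
        truth.dynamics[unit.gene_id] = _PROFILE_CYCLE[i % len(_PROFILE_CYCLE)]
    return genome, truth


# ---------------------------------------------------------------------------
# coverage


def simulate_coverage(
    genome: GenomeSequence, truth: GroundTruth, config: SimulationConfig
) -> list[CoverageTrack]:
    """Stranded per-base Poisson coverage, one pair of tracks per time point."""
    rng = np.random.default_rng(config.seed + 1)
    tracks = []
    units = truth.genes + truth.transcribed_segments
    for t in range(config.n_time_points):
        for strand in "+-":
            lam = np.full(genome.length, config.background_depth, dtype=float)
            for unit in units:
                if unit.strand != strand:
                    continue
                mult = _dynamics_multipliers(truth.dynamics[unit.gene_id],
                                             config.n_time_points)[t]
                lam[unit.start : unit.end] += truth.expression[unit.gene_id] * mult
            tracks.append(
                CoverageTrack(
                    library_id=f"tp{t + 1}{strand}",
                    time_point=f"tp{t + 1}",
                    strand=strand,
                    values=rng.poisson(lam).astype(float),
                )
            )
    return tracks


# ---------------------------------------------------------------------------
# small-RNA fragments


def _phase_weight(strength: float) -> float:
    """Multinomial weight on in-phase 5' termini; 1/3 when strength == 0."""
    return (1.0 + strength) / (3.0 + strength)


def simulate_fragments(
    genome: GenomeSequence, truth: GroundTruth, config: SimulationConfig
) -> list[FragmentAlignment]:
    """Ribosome-protection fragment model.

    Per expressed gene: (a) SD-protected fragments whose 5' termini pile at
    the SD window start, (b) a CDS-interior population whose 5' termini sit
    preferentially in the codon phase of the start (3 nt periodicity), and
    (c) a genome-wide uniform degradation background.  Lengths are uniform
    in the 15-50 nt gel window.
    """
    rng = np.random.default_rng(config.seed + 2)
    w = _phase_weight(config.fragment_protection_strength)
    raw: dict[tuple[int, int, str], int] = {}

    def emit(t5: int, length: int, gene: GeneModel | None, strand: str | None = None) -> None:
        # t5 in transcript coordinates when gene given, else genome coords
        if gene is not None:
            if gene.strand == "+":
                g5 = gene.start + t5
                s, e = g5, g5 + length
                st = "+"
            else:
                g5 = gene.end - 1 - t5
                s, e = g5 - length + 1, g5 + 1
                st = "-"
        else:
            s, e = t5, t5 + length
            st = strand or "+"
        if s < 0 or e > genome.length:
            return
        key = (s, e, st)
        raw[key] = raw.get(key, 0) + 1

    depth = max(config.coverage_depth, 1e-9)
    for gene in truth.genes:
        rel = float(np.clip(truth.expression[gene.gene_id] / depth, 0.3, 3.0))
        glen = gene.length
        interior = np.arange(9, glen - 9)
        if interior.size >= 3:
            phases = interior % 3
            probs = np.where(phases == 0, w, (1 - w) / 2).astype(float)
            # normalise within the available positions of each phase
            for p in range(3):
                mask = phases == p
                if mask.any():
                    probs[mask] /= mask.sum()
            probs /= probs.sum()
            n_int = rng.poisson(config.fragments_per_gene * rel)
            if n_int:
                ts = rng.choice(interior, size=n_int, p=probs)
                lens = rng.integers(FRAGMENT_MIN_LEN, FRAGMENT_MAX_LEN + 1, size=n_int)
                for t5, L in zip(ts, lens):
                    emit(int(t5), int(L), gene)
        n_prot = rng.poisson(6.0 * config.fragment_protection_strength * rel)
        if n_prot:
            jitter = rng.choice([-1, 0, 1], size=n_prot, p=[0.15, 0.7, 0.15])
            lens = rng.integers(FRAGMENT_MIN_LEN, FRAGMENT_MAX_LEN + 1, size=n_prot)
            for j, L in zip(jitter, lens):
                emit(config.sd_offset + int(j), int(L), gene)

    n_bg = rng.poisson(config.background_fragments)
    if n_bg:
        starts = rng.integers(0, genome.length - FRAGMENT_MAX_LEN, size=n_bg)
        lens = rng.integers(FRAGMENT_MIN_LEN, FRAGMENT_MAX_LEN + 1, size=n_bg)
        strands = rng.choice(list("+-"), size=n_bg)
        for s, L, st in zip(starts, lens, strands):
            emit(int(s), int(L), None, strand=str(st))

    return [
        FragmentAlignment(chrom=genome.id, start=s, end=e, strand=st, count=c)
        for (s, e, st), c in sorted(raw.items())
    ]


# ---------------------------------------------------------------------------
# peptides


def _pick_tryptic_peptide(
    rng: np.random.Generator, protein: str, frames: list[str], used: set[str]
) -> str | None:
    """A K/R-terminated 7-30 aa substring of `protein`, unique in the genome."""
    cut_sites = [j for j in range(6, len(protein)) if protein[j] in "KR"]
    if not cut_sites:
        return None
    for _ in range(60):
        j = int(rng.choice(cut_sites))
        max_len = min(30, j + 1)
        if max_len < 7:
            continue
        length = int(rng.integers(7, max_len + 1))
        pep = protein[j - length + 1 : j + 1]
        if pep in used or "*" in pep:
            continue
        target = collapse_il(pep)
        hits = sum(fr.count(target) for fr in frames)
        if hits == 1:
            return pep
    return None


def simulate_peptides(
    truth: GroundTruth,
    config: SimulationConfig,
    genome: GenomeSequence | None = None,
) -> pd.DataFrame:
    """Peptide table (peptide, confidence, sample) with planted truth.

    Hidden genes receive 1-4 tryptic-style peptides (the first hidden gene
    exactly one, to exercise the single-peptide RNA-validation path); the
    frameshift gene's peptides come from the *true* reading frame; a few
    annotated hypothetical genes also receive peptides.  Decoys are shuffled
    true peptides re-checked to be absent from the six-frame translation.
    """
    rng = np.random.default_rng(config.seed + 3)
    frames = (
        [collapse_il(p) for _, _, p in six_frame_translations(genome.seq)]
        if genome is not None
        else [collapse_il(p) for p in truth.gene_proteins.values()]
    )
    used: set[str] = set()
    rows: list[tuple[str, float, str]] = []

    def add_peptides(gene_id: str, k: int) -> None:
        protein = truth.gene_proteins[gene_id]
        for _ in range(k):
            pep = _pick_tryptic_peptide(rng, protein, frames, used)
            if pep is None:
                continue
            used.add(pep)
            truth.true_peptides[pep] = gene_id
            conf = float(np.clip(rng.normal(config.true_conf_mean, config.true_conf_sd),
                                 80.0, 100.0))
            sample = f"tp{int(rng.integers(1, config.n_time_points + 1))}"
            rows.append((pep, round(conf, 2), sample))

    hidden = truth.hidden_genes
    for i, g in enumerate(hidden):
        add_peptides(g.gene_id, 1 if i == 0 else int(rng.integers(2, 5)))
    for gid in truth.frameshift_gene_ids:
        add_peptides(gid, 2)
    hyp = [g for g in truth.genes if g.attributes.get("hypothetical") == "true"]
    for g in hyp[: config.n_confirmed_hypothetical]:
        add_peptides(g.gene_id, int(rng.integers(2, 4)))

    # decoys: shuffled true peptides, guaranteed no in-frame genome match
    true_list = [p for p, _, _ in rows]
    for _ in range(config.n_decoy_peptides):
        if not true_list:
            break
        src = list(true_list[int(rng.integers(len(true_list)))])
        decoy = None
        for _try in range(50):
            rng.shuffle(src)
            cand = "".join(src)
            if cand in used:
                continue
            if sum(fr.count(collapse_il(cand)) for fr in frames) == 0:
                decoy = cand
                break
        if decoy is None:
            continue
        used.add(decoy)
        truth.decoy_peptides.append(decoy)
        conf = float(np.clip(rng.normal(config.decoy_conf_mean, config.decoy_conf_sd),
                             5.0, 94.9))
        sample = f"tp{int(rng.integers(1, config.n_time_points + 1))}"
        rows.append((decoy, round(conf, 2), sample))

    return pd.DataFrame(rows, columns=["peptide", "confidence", "sample"])


# ---------------------------------------------------------------------------
# metabolic-annotation fixture


def simulate_gsmr_fixture(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, list[dict], pd.DataFrame]:
    """Domain table, orphan reactions and ortholog tables with planted truth.

    Structural cases mirrored from the field's recurring situations: a
    duplicated-domain enzyme (two PLDc domains required, multiplicity
    matters), an equal-domain tie broken by synteny, candidates rejected by
    the E-value cut-off, a reaction with no matching gene (left unassigned)
    and a multi-domain ambiguity where no clear candidate exists.
    Populates ``truth.gsmr_truth`` (reaction -> true gene or None).
    """
    rng = np.random.default_rng(config.seed + 4)
    genes = sorted((g for g in truth.genes if g.attributes.get("hidden") != "true"),
                   key=lambda g: g.start)
    gids = [g.gene_id for g in genes]
    role_names = (["ech_true", "cls_true", "cls_single", "cls_badE", "galp", "ppa",
                   "ech_foil", "pemt_a", "pemt_b"]
                  + [f"extra_{i}" for i in range(config.n_orphan_reactions_extra)])
    k = config.synteny_k
    if len(gids) < len(role_names) or len(gids) < 2 * k + 1:
        raise ValueError("not enough annotated genes for the metabolic fixture")
    # the synteny-tie gene needs a full +-k neighbourhood; others can sit anywhere
    mid = [int(i) for i in rng.permutation(np.arange(k, len(gids) - k))]
    ech_idx = mid[0]
    rest = [int(i) for i in rng.permutation(len(gids)) if i != ech_idx]
    role = {"ech_true": gids[ech_idx]}
    for name, idx in zip(role_names[1:], rest):
        role[name] = gids[idx]

    dom_rows: list[tuple[str, str, float, int, int]] = []

    def dom(gene: str, domain: str, evalue: float) -> None:
        s = int(rng.integers(1, 40))
        dom_rows.append((gene, domain, evalue, s, s + int(rng.integers(40, 120))))

    dom(role["cls_true"], "PLDc", 1e-6)
    dom(role["cls_true"], "PLDc", 3e-6)
    dom(role["cls_single"], "PLDc", 1e-5)          # multiplicity foil: one copy
    dom(role["cls_badE"], "PLDc", 0.05)            # fails E < 0.001
    dom(role["cls_badE"], "PLDc", 0.02)
    dom(role["galp"], "GalP_UDP", 2e-7)
    dom(role["galp"], "GalP_UDP", 5e-7)
    dom(role["ppa"], "Pyrophosphatase", 1e-8)
    for g in (role["ech_true"], role["ech_foil"]):
        dom(g, "ECH", 1e-6)
        dom(g, "ECH_C", 1e-6)
    for g, extra in ((role["pemt_a"], "MFS_1"), (role["pemt_b"], "PhaG_MnhG_YufB")):
        dom(g, "PEMT", 1e-5)
        dom(g, extra, 1e-6)
    reactions = [
        {"reaction_id": "RXN_CLS", "required_domains": ["PLDc", "PLDc"], "essential": True},
        {"reaction_id": "RXN_GALP", "required_domains": ["GalP_UDP", "GalP_UDP"],
         "essential": False},
        {"reaction_id": "RXN_PPA", "required_domains": ["Pyrophosphatase"], "essential": False},
        {"reaction_id": "RXN_ECH", "required_domains": ["ECH", "ECH_C"], "essential": False},
        {"reaction_id": "RXN_TK", "required_domains": ["dUTP_kinase"], "essential": True},
        {"reaction_id": "RXN_PEMT", "required_domains": ["PEMT"], "essential": False},
    ]
    truth.gsmr_truth = {
        "RXN_CLS": role["cls_true"],
        "RXN_GALP": role["galp"],
        "RXN_PPA": role["ppa"],
        "RXN_ECH": role["ech_true"],
        "RXN_TK": None,
        "RXN_PEMT": None,
    }
    for i in range(config.n_orphan_reactions_extra):
        d = f"UDOM_{i + 1}"
        g = role[f"extra_{i}"]
        dom(g, d, 10.0 ** -float(rng.integers(5, 10)))
        reactions.append({"reaction_id": f"RXN_X{i + 1}", "required_domains": [d],
                          "essential": False})
        truth.gsmr_truth[f"RXN_X{i + 1}"] = g
    # unrelated single-domain annotations on non-role genes, some above the
    # E-value cut (role genes stay clean so their candidacy is unambiguous)
    role_genes = set(role.values())
    free = [g for g in gids if g not in role_genes]
    for _ in range(30):
        dom(free[int(rng.integers(len(free)))], f"MISC_{int(rng.integers(1, 9))}",
            10.0 ** rng.uniform(-6, 0))

    domains = pd.DataFrame(dom_rows, columns=["gene", "domain", "evalue", "start", "end"])

    # ortholog/neighbourhood tables: focal genome plus two references.
    # ech_true's neighbourhood is conserved in refA; ech_foil's is not.
    og = {gid: f"OG{i + 1:04d}" for i, gid in enumerate(gids)}
    ortho_rows = [("self", gid, og[gid], i) for i, gid in enumerate(gids)]
    k = config.synteny_k
    focal_index = {gid: i for i, gid in enumerate(gids)}
    i_true = focal_index[role["ech_true"]]
    base = 200
    for off in range(-k, k + 1):
        gid = gids[i_true + off]
        if off == 0 or abs(off) <= 3:  # conserve the core neighbourhood
            ortho_rows.append(("refA", f"refA_{base + off}", og[gid], base + off))
    # refB: scattered unrelated orthologs (no coherent neighbourhood)
    scatter = rng.permutation(len(gids))[:15]
    for j, gi in enumerate(scatter):
        ortho_rows.append(("refB", f"refB_{j}", og[gids[int(gi)]], int(rng.integers(0, 500))))
    orthologs = pd.DataFrame(ortho_rows, columns=["genome", "gene", "ortho_group",
                                                  "position_index"])
    return domains, reactions, orthologs


# ---------------------------------------------------------------------------
# drivers


def simulate_all(config: SimulationConfig):
    """Run every simulator; returns (genome, truth, tracks, fragments, peptides,
    domains, reactions, orthologs)."""
    genome, truth = simulate_genome(config)
    tracks = simulate_coverage(genome, truth, config)
    fragments = simulate_fragments(genome, truth, config)
    peptides = simulate_peptides(truth, config, genome=genome)
    domains, reactions, orthologs = simulate_gsmr_fixture(truth, config)
    return genome, truth, tracks, fragments, peptides, domains, reactions, orthologs


def write_simulation(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Materialise a full simulated dataset as the pipeline's input files."""
    from .io_formats import write_bed, write_bedgraph, write_fasta, write_gff3

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, truth, tracks, fragments, peptides, domains, reactions, orthologs = (
        simulate_all(config)
    )
    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fasta"
    write_fasta([genome], paths["genome"])
    paths["annotation"] = outdir / "annotated.gff3"
    write_gff3(truth.annotated, paths["annotation"])
    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1)
    for tr in tracks:
        p = outdir / f"coverage_{tr.time_point}.{tr.strand}.bedgraph"
        write_bedgraph(tr, genome.id, p)
        paths[tr.library_id] = p
    paths["fragments"] = outdir / "fragments.bed"
    write_bed(fragments, paths["fragments"])
    paths["peptides"] = outdir / "peptides.tsv"
    peptides.to_csv(paths["peptides"], sep="\t", index=False)
    paths["domains"] = outdir / "domains.tsv"
    domains.to_csv(paths["domains"], sep="\t", index=False)
    paths["reactions"] = outdir / "reactions.json"
    with open(paths["reactions"], "w") as fh:
        json.dump(reactions, fh, indent=1)
    paths["orthologs"] = outdir / "orthologs.tsv"
    orthologs.to_csv(paths["orthologs"], sep="\t", index=False)
    return paths
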