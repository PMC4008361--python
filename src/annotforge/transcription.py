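"""Transcription detection from per-base coverage tracks.

Libraries are normalised to counts-per-million within each library, then
(optionally) a median-of-ratios factor over annotated genes aligns
libraries of the same strand — the standard two-step used when no
spike-ins exist.  Transcribed intergenic regions are maximal runs of
bases clearing a threshold of k x the intergenic background (with an
absolute floor, since the background median of a sparse track is
typically zero) in at least one time point, gap-merged and length-
filtered.  The same rule, applied to a single ORF, provides the
RNA-validation verdict for single-peptide protein calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CoverageTrack, GeneModel
from .orf_discovery import CandidateORF, IntergenicRegion

__all__ = [
    "ExpressionSummary",
    "normalize_tracks",
    "detect_transcribed_regions",
    "is_transcribed",
    "cumulative_summaries",
    "DEFAULT_K",
    "DEFAULT_MIN_RUN",
    "DEFAULT_MERGE_GAP",
    "DEFAULT_MIN_COVERAGE",
]

DEFAULT_K = 5.0
DEFAULT_MIN_RUN = 50
DEFAULT_MERGE_GAP = 20
#: absolute floor (normalized units) under the k x background threshold;
#: sits above the Poisson tail of untranscribed background so isolated
#: noise bases cannot seed (or gap-merge into) a called run
DEFAULT_MIN_COVERAGE = 5.0
DEFAULT_CV_CUT = 0.5


@dataclass
class ExpressionSummary:
    chrom: str
    start: int
    end: int
    strand: str
    per_time_point_mean: list[float]
    time_points: list[str]
    max_expr: float
    dynamic: bool

    @property
    def length(self) -> int:
        return self.end - self.start


def _strand_matches(track_strand: str, feature_strand: str) -> bool:
    return track_strand == "both" or track_strand == feature_strand


def normalize_tracks(
    tracks: Sequence[CoverageTrack],
    genes: Sequence[GeneModel] | None = None,
) -> list[CoverageTrack]:
    """Counts-per-million per library, then median-of-ratios over genes.

    The between-library factor is computed per strand group over the
    supplied annotated genes (skipped when ``genes`` is None).  An all-zero
    track is an empty library and an error.
    """
    for t in tracks:
        if t.values.sum() == 0:
            raise ValueError(f"empty library: {t.library_id}")
    normed = [
        CoverageTrack(t.library_id, t.time_point, t.strand,
                      t.values * 1e6 / t.values.sum())
        for t in tracks
    ]
    if genes:
        by_strand: dict[str, list[int]] = {}
        for i, t in enumerate(normed):
            by_strand.setdefault(t.strand, []).append(i)
        for strand, idxs in by_strand.items():
            gset = [g for g in genes if _strand_matches(strand, g.strand)]
            if len(gset) < 2 or len(idxs) < 2:
                continue
            means = np.array(
                [[normed[i].values[g.start : g.end].mean() for g in gset] for i in idxs]
            )  # libraries x genes
            with np.errstate(divide="ignore"):
                logm = np.log(means)
            ref = logm.mean(axis=0)  # per-gene geometric mean across libraries
            usable = np.isfinite(ref)
            if usable.sum() < 2:
                continue
            factors = np.exp(np.median(logm[:, usable] - ref[usable], axis=1))
            for i, f in zip(idxs, factors):
                normed[i].values = normed[i].values / f
    return normed


def _runs_above(above: np.ndarray, min_run: int, merge_gap: int) -> list[tuple[int, int]]:
    """Maximal True runs, gap-merged, then length-filtered."""
    if not above.any():
        return []
    padded = np.concatenate([[False], above, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if e - s >= min_run]


def _thresholds(
    tracks: Sequence[CoverageTrack],
    background_mask: np.ndarray | None,
    k: float,
    min_coverage: float,
) -> list[float]:
    out = []
    for t in tracks:
        bg = np.median(t.values[background_mask] if background_mask is not None
                       else t.values)
        out.append(max(k * float(bg), min_coverage))
    return out


def detect_transcribed_regions(
    tracks: Sequence[CoverageTrack],
    intergenic_regions: Sequence[IntergenicRegion],
    k: float = DEFAULT_K,
    min_run: int = DEFAULT_MIN_RUN,
    merge_gap: int = DEFAULT_MERGE_GAP,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    cv_cut: float = DEFAULT_CV_CUT,
) -> list[ExpressionSummary]:
    """Transcribed sub-intervals of the intergenic space, per strand.

    A base is "on" when its coverage clears max(k x background,
    min_coverage) in at least one time point; the background is the median
    coverage over all intergenic positions of that track.  On-runs are
    merged across gaps <= merge_gap and kept when >= min_run nt.
    """
    if not tracks:
        return []
    glen = tracks[0].length
    mask = np.zeros(glen, dtype=bool)
    for r in intergenic_regions:
        mask[r.start : r.end] = True

    summaries: list[ExpressionSummary] = []
    for strand in "+-":
        st_tracks = [t for t in tracks if _strand_matches(t.strand, strand)]
        if not st_tracks:
            continue
        thresholds = _thresholds(st_tracks, mask, k, min_coverage)
        above = np.zeros(glen, dtype=bool)
        for t, thr in zip(st_tracks, thresholds):
            above |= t.values >= thr
        above &= mask
        for r in intergenic_regions:
            sub = above[r.start : r.end]
            for s, e in _runs_above(sub, min_run, merge_gap):
                gs, ge = r.start + s, r.start + e
                means = [float(t.values[gs:ge].mean()) for t in st_tracks]
                mu = float(np.mean(means))
                cv = float(np.std(means) / mu) if mu > 0 else 0.0
                summaries.append(
                    ExpressionSummary(
                        chrom=r.chrom, start=gs, end=ge, strand=strand,
                        per_time_point_mean=means,
                        time_points=[t.time_point for t in st_tracks],
                        max_expr=float(max(means)), dynamic=cv > cv_cut,
                    )
                )
    summaries.sort(key=lambda s: (s.start, s.end, s.strand))
    return summaries


def is_transcribed(
    orf: CandidateORF | GeneModel,
    tracks: Sequence[CoverageTrack],
    k: float = DEFAULT_K,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    background_mask: np.ndarray | None = None,
) -> tuple[bool, float]:
    """RNA-validation verdict for one interval.

    True iff the mean normalized coverage over the interval clears
    max(k x background, min_coverage) in at least one matching-strand
    time point.  Returns (verdict, best mean expression).
    """
    start, end = orf.start, orf.end
    if end <= start:
        raise ValueError("empty interval")
    st_tracks = [t for t in tracks if _strand_matches(t.strand, orf.strand)]
    if not st_tracks:
        return False, 0.0
    thresholds = _thresholds(st_tracks, background_mask, k, min_coverage)
    means = [float(t.values[start:end].mean()) for t in st_tracks]
    verdict = any(m >= thr for m, thr in zip(means, thresholds))
    return verdict, max(means)


def _ecdf(values: Sequence[float]) -> pd.DataFrame:
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        return pd.DataFrame(columns=["value", "ecdf"])
    return pd.DataFrame({"value": v, "ecdf": np.arange(1, v.size + 1) / v.size})


def cumulative_summaries(
    classes: Mapping[str, Sequence[GeneModel | CandidateORF]],
    tracks: Sequence[CoverageTrack] | None = None,
) -> dict[str, pd.DataFrame]:
    """ECDF tables of protein size (aa) and expression per gene class.

    Returns {'size': df, 'expression': df} with columns
    (gene_class, value, ecdf); expression is the max over time points of
    the mean matching-strand coverage (empty when no tracks given).
    Empty classes yield empty tables.
    """
    size_parts, expr_parts = [], []
    for cls, feats in classes.items():
        sizes = [(f.end - f.start) // 3 - 1 for f in feats]
        df = _ecdf(sizes)
        df.insert(0, "gene_class", cls)
        size_parts.append(df)
        if tracks is not None:
            exprs = []
            for f in feats:
                st = [t for t in tracks if _strand_matches(t.strand, f.strand)]
                exprs.append(max((float(t.values[f.start : f.end].mean()) for t in st),
                                 default=0.0))
            de = _ecdf(exprs)
            de.insert(0, "gene_class", cls)
            expr_parts.append(de)
    empty = pd.DataFrame(columns=["gene_class", "value", "ecdf"])
    return {
        "size": pd.concat(size_parts, ignore_index=True) if size_parts else empty,
        "expression": pd.concat(expr_parts, ignore_index=True) if expr_parts else empty,
    }


def plot_ecdfs(tables: dict[str, pd.DataFrame], path) -> None:
    """Cumulative size/expression distributions per gene class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, (name, df) in zip(axes, tables.items()):
        for cls, sub in df.groupby("gene_class"):
            ax.step(sub["value"], sub["ecdf"], where="post", label=cls)
        ax.set_xlabel(name)
        ax.set_ylabel("cumulative frequency")
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
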