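"""End-to-end driver: simulate -> discover -> integrate.

Chains every stage of the re-annotation workflow on a simulated dataset
and optionally materialises all intermediate and final outputs.  Each
stage is also callable on its own through the stage modules; this module
only wires them together.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gsmr, integrator, orf_discovery, proteogenomics, rbs, transcription
from .io_formats import write_bed, write_gff3, GeneModel
from .synthetic import SimulationConfig, simulate_all

log = logging.getLogger("annotforge")

__all__ = ["PipelineResult", "run_simulated_pipeline"]


@dataclass
class PipelineResult:
    config: SimulationConfig
    genome: object
    truth: object
    annotation: list
    intergenic: list
    sixframe_orfs: list
    tracks: list
    summaries: list
    protein_calls: list
    rbs_calls: list
    rbs_misses: list
    periodicity: dict
    assignments: list
    updated: list
    updates: list
    conflicts: list
    report: dict
    timings: dict = field(default_factory=dict)


def run_simulated_pipeline(
    config: SimulationConfig,
    outdir: str | Path | None = None,
    min_aa: int = orf_discovery.DEFAULT_MIN_AA,
    k_threshold: float = transcription.DEFAULT_K,
) -> PipelineResult:
    timings: dict[str, float] = {}

    def tick(stage: str, t0: float) -> None:
        timings[stage] = time.perf_counter() - t0
        log.info("stage %-14s %.2fs", stage, timings[stage])

    t0 = time.perf_counter()
    genome, truth, tracks, fragments, peptides, domains, reactions, orthologs = (
        simulate_all(config)
    )
    tick("simulate", t0)

    annotation = truth.annotated
    t0 = time.perf_counter()
    intergenic = orf_discovery.extract_intergenic(annotation, genome, min_len=60)
    sixframe = [
        o for region in intergenic
        for o in orf_discovery.six_frame_orfs(region, genome, min_aa=min_aa)
    ]
    tick("orfs", t0)

    t0 = time.perf_counter()
    normed = transcription.normalize_tracks(tracks, annotation)
    summaries = transcription.detect_transcribed_regions(normed, intergenic,
                                                         k=k_threshold)
    mask = np.zeros(genome.length, dtype=bool)
    for r in intergenic:
        mask[r.start : r.end] = True

    def tx_evidence(orf) -> bool:
        return transcription.is_transcribed(orf, normed, k=k_threshold)[0]

    tick("transcription", t0)

    t0 = time.perf_counter()
    calls = proteogenomics.discover_proteins(peptides, genome, annotation,
                                             transcription_evidence=tx_evidence)
    tick("proteogenomics", t0)

    t0 = time.perf_counter()
    accepted_novel = [c.orf for c in calls
                      if c.status == "accepted" and c.orf.classification == "novel"]
    anchors = list(annotation) + accepted_novel
    rbs_calls, rbs_misses = rbs.call_rbs(anchors, fragments, genome=genome,
                                         motif=config.sd_motif)
    periodicity = rbs.estimate_periodicity(fragments, annotation)
    tick("rbs", t0)

    t0 = time.perf_counter()
    assignments = gsmr.assign_orphans(reactions, domains, orthologs)
    tick("gsmr", t0)

    t0 = time.perf_counter()
    updated, updates, conflicts = integrator.integrate(
        annotation, calls, summaries, rbs_calls, assignments
    )
    report = integrator.summary_report(updates)
    tick("integrate", t0)

    result = PipelineResult(
        config=config, genome=genome, truth=truth, annotation=annotation,
        intergenic=intergenic, sixframe_orfs=sixframe, tracks=normed,
        summaries=summaries, protein_calls=calls, rbs_calls=rbs_calls,
        rbs_misses=rbs_misses, periodicity=periodicity, assignments=assignments,
        updated=updated, updates=updates, conflicts=conflicts, report=report,
        timings=timings,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir), fragments, peptides)
    return result


def _write_outputs(res: PipelineResult, outdir: Path, fragments, peptides) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    chrom = res.genome.id
    write_gff3(res.updated, outdir / "updated.gff3")
    novel = [u.target for u in res.updates if u.action == "add_gene"]
    write_gff3(novel, outdir / "novel_orfs.gff3")
    regions = [
        GeneModel(f"txr_{i+1:04d}", s.chrom, s.start, s.end, s.strand, "region")
        for i, s in enumerate(res.summaries)
    ]
    write_bed(regions, outdir / "transcribed_regions.bed")
    pd.DataFrame(
        [{"chrom": s.chrom, "start": s.start, "end": s.end, "strand": s.strand,
          "max_expr": s.max_expr, "dynamic": s.dynamic,
          **{f"mean_{tp}": m for tp, m in zip(s.time_points, s.per_time_point_mean)}}
         for s in res.summaries]
    ).to_csv(outdir / "expression_summary.tsv", sep="\t", index=False)
    strand_of = {g.gene_id: g.strand for g in res.updated}
    write_gff3(rbs.rbs_calls_to_gene_models(res.rbs_calls, chrom, strand_of),
               outdir / "rbs_calls.gff3")
    profile = rbs.metagene_termini(fragments, res.annotation)
    pd.DataFrame({"offset": profile.offsets, "counts5": profile.counts5,
                  "counts3": profile.counts3}).to_csv(
        outdir / "metagene_profile.tsv", sep="\t", index=False)
    with open(outdir / "periodicity.json", "w") as fh:
        json.dump(res.periodicity, fh, indent=1)
    gsmr.report_assignments(res.assignments).to_csv(
        outdir / "orphan_assignments.tsv", sep="\t", index=False)
    integrator.write_summary(res.report, outdir / "summary")
    classes = {
        "annotated": [g for g in res.annotation if g.kind == "CDS"],
        "novel": novel,
    }
    tables = transcription.cumulative_summaries(classes, res.tracks)
    for name, df in tables.items():
        df.to_csv(outdir / f"ecdf_{name}.tsv", sep="\t", index=False)
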