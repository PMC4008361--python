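"""Evidence integration into an updated annotation.

Merges the four evidence streams — peptide-backed ORFs, transcribed
intergenic regions, RBS calls and orphan-reaction assignments — into a
single updated feature set with machine-parsable evidence codes
(PEP, TXN, RBS, GSMR) in GFF3 attributes.  The merge is deterministic
and idempotent: integrating the output again with the same evidence
produces zero new updates.  Peptide evidence outranks transcription for
gene existence; nothing is ever deleted, and function reassignments
preserve the previous product name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .gsmr import OrphanAssignment
from .io_formats import GeneModel
from .proteogenomics import ProteinCall
from .rbs import RBSCall
from .transcription import ExpressionSummary

__all__ = ["AnnotationUpdate", "integrate", "summary_report", "RBS_ATTACH_NT"]

#: maximum distance from a protected window to the downstream start codon
RBS_ATTACH_NT = 25


@dataclass
class AnnotationUpdate:
    action: str  # add_gene, confirm_gene, reassign_function, flag_frameshift,
    #              add_rbs, add_transcribed_region
    target: GeneModel
    evidence: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("every update needs at least one evidence record")


def _same_span(a: GeneModel, b) -> bool:
    return a.start == b.start and a.end == b.end and a.strand == b.strand


def integrate(
    annotation: Sequence[GeneModel],
    protein_calls: Sequence[ProteinCall] = (),
    transcribed_regions: Sequence[ExpressionSummary] = (),
    rbs_calls: Sequence[RBSCall] = (),
    orphan_assignments: Sequence[OrphanAssignment] = (),
) -> tuple[list[GeneModel], list[AnnotationUpdate], list[str]]:
    """Merge evidence into (updated feature list, updates, conflict log)."""
    updated = [
        GeneModel(g.gene_id, g.chrom, g.start, g.end, g.strand, g.kind,
                  dict(g.attributes))
        for g in annotation
    ]
    updates: list[AnnotationUpdate] = []
    conflicts: list[str] = []
    genes_by_id = {g.gene_id: g for g in updated}

    # --- peptide-backed ORFs (highest precedence for gene existence)
    accepted = [c for c in protein_calls if c.status == "accepted"]
    n_added = 0
    for call in sorted(accepted, key=lambda c: (c.orf.start, c.orf.end)):
        orf = call.orf
        ev = [("PEP", f"n_peptides={len(call.peptides)}")]
        if "transcription" in orf.evidence:
            ev.append(("TXN", "rna_validated"))
        cls = orf.classification or "novel"
        if cls == "novel":
            if any(f.kind in ("CDS", "novel_ORF") and _same_span(f, orf)
                   for f in updated):
                continue  # already present (idempotent re-run)
            opposite = [f for f in updated if f.kind == "CDS"
                        and f.strand != orf.strand
                        and f.start < orf.end and orf.start < f.end]
            if opposite:
                conflicts.append(
                    f"novel ORF {orf.chrom}:{orf.start}-{orf.end}({orf.strand}) "
                    f"overlaps opposite-strand CDS {opposite[0].gene_id}; both kept"
                )
            n_added += 1
            model = orf.as_gene_model(f"novel_{n_added:04d}")
            model.attributes["n_peptides"] = str(len(call.peptides))
            updated.append(model)
            genes_by_id[model.gene_id] = model
            updates.append(AnnotationUpdate("add_gene", model, ev))
        elif cls in ("confirms_hypothetical", "extension"):
            hit = next((f for f in updated if f.kind == "CDS"
                        and f.strand == orf.strand and f.frame() == orf.frame
                        and f.start < orf.end and orf.start < f.end), None)
            if hit is None or hit.attributes.get("evidence_PEP"):
                continue
            hit.attributes["evidence_PEP"] = str(len(call.peptides))
            if cls == "confirms_hypothetical":
                hit.attributes["confirmed"] = "true"
            updates.append(AnnotationUpdate("confirm_gene", hit, ev))
        elif cls == "frameshift_flag":
            hit = min(
                (f for f in updated if f.kind == "CDS" and f.strand == orf.strand),
                key=lambda f: min(abs(f.start - orf.start), abs(f.end - orf.end)),
                default=None,
            )
            if hit is None or hit.attributes.get("frameshift_suspect"):
                continue
            hit.attributes["frameshift_suspect"] = "true"
            updates.append(AnnotationUpdate("flag_frameshift", hit, ev))

    # --- transcribed intergenic regions (peptide-backed genes take precedence)
    n_regions = 0
    for summ in transcribed_regions:
        covered = any(
            f.kind in ("CDS", "novel_ORF") and f.strand == summ.strand
            and f.start < summ.end and summ.start < f.end
            for f in updated
        )
        if covered:
            continue
        if any(f.kind == "transcribed_region"
               and f.start == summ.start and f.end == summ.end
               and f.strand == summ.strand for f in updated):
            continue
        n_regions += 1
        model = GeneModel(
            gene_id=f"txr_{n_regions:04d}", chrom=summ.chrom, start=summ.start,
            end=summ.end, strand=summ.strand, kind="transcribed_region",
            attributes={"evidence": "TXN", "max_expr": f"{summ.max_expr:.2f}",
                        "dynamic": str(summ.dynamic).lower()},
        )
        updated.append(model)
        updates.append(AnnotationUpdate("add_transcribed_region", model,
                                        [("TXN", f"max_expr={summ.max_expr:.2f}")]))

    # --- RBS calls: attach to the nearest downstream start within reach
    for call in rbs_calls:
        target = genes_by_id.get(call.gene_id)
        if target is None:
            candidates = []
            for f in updated:
                if f.kind not in ("CDS", "novel_ORF"):
                    continue
                dist = (f.start - call.window[1] if f.strand == "+"
                        else call.window[0] - f.end)
                if -3 <= dist <= RBS_ATTACH_NT:
                    candidates.append((dist, f))
            if not candidates:
                conflicts.append(f"RBS call {call.gene_id}: no start within "
                                 f"{RBS_ATTACH_NT} nt; dropped")
                continue
            target = min(candidates, key=lambda t: abs(t[0]))[1]
        if any(f.kind == "RBS" and f.attributes.get("target") == target.gene_id
               for f in updated):
            continue
        model = GeneModel(
            gene_id=f"rbs_{target.gene_id}", chrom=target.chrom,
            start=call.window[0], end=call.window[1], strand=target.strand,
            kind="RBS",
            attributes={"evidence": "RBS", "target": target.gene_id,
                        "peak_offset": str(call.peak_offset),
                        "sd_match": str(call.sd_match).lower()},
        )
        updated.append(model)
        updates.append(AnnotationUpdate(
            "add_rbs", model, [("RBS", f"score={call.score:.2f}")]))

    # --- orphan-reaction assignments: function suggestions, never overwrite
    for a in orphan_assignments:
        if a.verdict != "single_candidate" or a.top is None:
            continue
        gene = genes_by_id.get(a.top.gene_id)
        if gene is None or gene.attributes.get("reaction") == a.reaction_id:
            continue
        old = gene.attributes.get("product")
        if old is not None:
            gene.attributes["previous_product"] = old
        gene.attributes["product"] = f"candidate enzyme for {a.reaction_id}"
        gene.attributes["reaction"] = a.reaction_id
        gene.attributes["evidence_GSMR"] = f"{a.top.best_evalue:g}"
        updates.append(AnnotationUpdate(
            "reassign_function", gene,
            [("GSMR", f"{a.reaction_id} evalue={a.top.best_evalue:g}")]))

    updated.sort(key=lambda f: (f.chrom, f.start, f.end, f.kind))
    return updated, updates, conflicts


def summary_report(updates: Sequence[AnnotationUpdate]) -> dict[str, pd.DataFrame]:
    """Update counts by action (summing to |updates|) and by evidence source."""
    by_action_rows = [{"action": u.action} for u in updates]
    by_source_rows = [{"source": s} for u in updates for s, _ in u.evidence]

    def tally(rows, col):
        if not rows:
            return pd.DataFrame(columns=[col, "count"])
        return (pd.DataFrame(rows).groupby(col).size().reset_index(name="count")
                .sort_values(col).reset_index(drop=True))

    return {"by_action": tally(by_action_rows, "action"),
            "by_source": tally(by_source_rows, "source")}


def write_summary(report: dict[str, pd.DataFrame], basepath) -> None:
    """Emit the summary as both TSV and JSON with identical content."""
    import json
    from pathlib import Path

    base = Path(basepath)
    payload = {}
    for name, df in report.items():
        df.to_csv(base.with_suffix(f".{name}.tsv"), sep="\t", index=False)
        key = df.columns[0]
        payload[name] = {str(r[key]): int(r["count"]) for _, r in df.iterrows()}
    with open(base.with_suffix(".json"), "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
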