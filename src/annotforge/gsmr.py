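"""Candidate-gene assignment for orphan metabolic reactions.

A genome-scale metabolic reconstruction demands reactions whose catalyst
is not yet linked to any gene.  Candidates are found by matching each
reaction's *required domain multiset* (multiplicity matters: a
cardiolipin-synthase-type enzyme needs two PLDc domains on one protein)
against a per-gene protein-domain table filtered at an E-value cut-off
(default 0.001), then ranked with conserved-neighbourhood (synteny)
evidence against reference genomes.  Domain identification itself (HMM
scanning) is an input, not computed here.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "OrphanReaction",
    "Candidate",
    "OrphanAssignment",
    "match_domains",
    "synteny_score",
    "assign_orphans",
    "report_assignments",
    "EVALUE_MAX",
]

EVALUE_MAX = 0.001
DEFAULT_K = 5


@dataclass(frozen=True)
class OrphanReaction:
    reaction_id: str
    required_domains: tuple[str, ...]  # with multiplicity
    essential: bool = False

    @classmethod
    def from_dict(cls, d: Mapping) -> "OrphanReaction":
        return cls(reaction_id=d["reaction_id"],
                   required_domains=tuple(d["required_domains"]),
                   essential=bool(d.get("essential", False)))


@dataclass
class Candidate:
    gene_id: str
    domain_score: float  # fraction of the required multiset matched
    best_evalue: float
    synteny: float = 0.0
    ambiguous_multidomain: bool = False


@dataclass
class OrphanAssignment:
    reaction_id: str
    candidates: list[Candidate] = field(default_factory=list)
    verdict: str = "unassigned"
    essential: bool = False

    @property
    def top(self) -> Candidate | None:
        return self.candidates[0] if self.candidates else None


def _gene_domains(domain_table: pd.DataFrame, evalue_max: float) -> dict[str, list]:
    kept = domain_table[domain_table["evalue"] <= evalue_max]
    out: dict[str, list] = {}
    for row in kept.itertuples(index=False):
        out.setdefault(row.gene, []).append((row.domain, float(row.evalue)))
    return out


def match_domains(
    reaction: OrphanReaction,
    domain_table: pd.DataFrame,
    evalue_max: float = EVALUE_MAX,
) -> list[Candidate]:
    """Genes whose filtered domain multiset covers the requirement.

    The requirement is a multiset: a gene with a single PLDc never
    satisfies {PLDc x2}.  Genes carrying additional *unrelated* domains
    are flagged ambiguous_multidomain — the multi-domain situation that
    prevents a clear functional assignment.
    """
    need = Counter(reaction.required_domains)
    cands: list[Candidate] = []
    for gene, doms in _gene_domains(domain_table, evalue_max).items():
        have = Counter(d for d, _ in doms)
        if any(have[d] < n for d, n in need.items()):
            continue
        relevant_ev = [e for d, e in doms if d in need]
        extra = [d for d in have if d not in need]
        cands.append(
            Candidate(
                gene_id=gene,
                domain_score=1.0,
                best_evalue=min(relevant_ev),
                ambiguous_multidomain=bool(extra),
            )
        )
    return cands


def synteny_score(
    gene_id: str,
    orthologs: pd.DataFrame,
    k: int = DEFAULT_K,
    focal_genome: str = "self",
) -> float:
    """Conserved-neighbourhood score in [0, 1].

    For each reference genome containing an ortholog of the gene, count
    how many of the gene's +-k focal neighbours have an ortholog within
    +-k positions of that ortholog; the score is the best such fraction
    over references (shared / 2k).  Symmetric in genome order by
    construction (shared neighbours are counted pairwise).
    """
    focal = orthologs[orthologs["genome"] == focal_genome].sort_values("position_index")
    row = focal[focal["gene"] == gene_id]
    if row.empty:
        return 0.0
    pos = int(row["position_index"].iloc[0])
    group = row["ortho_group"].iloc[0]
    neigh = focal[(focal["position_index"] >= pos - k) & (focal["position_index"] <= pos + k)
                  & (focal["position_index"] != pos)]
    neigh_groups = set(neigh["ortho_group"])
    best = 0.0
    for ref, sub in orthologs[orthologs["genome"] != focal_genome].groupby("genome"):
        anchor = sub[sub["ortho_group"] == group]
        for rpos in anchor["position_index"]:
            ref_neigh = sub[(sub["position_index"] >= rpos - k)
                            & (sub["position_index"] <= rpos + k)
                            & (sub["position_index"] != rpos)]
            shared = len(neigh_groups & set(ref_neigh["ortho_group"]))
            best = max(best, shared / (2 * k))
    return float(min(best, 1.0))


def assign_orphans(
    reactions: Sequence[OrphanReaction | Mapping],
    domain_table: pd.DataFrame,
    ortholog_table: pd.DataFrame | None = None,
    evalue_max: float = EVALUE_MAX,
    k: int = DEFAULT_K,
) -> list[OrphanAssignment]:
    """Rank candidates per reaction and attach a verdict.

    Ranking is lexicographic: domain completeness, then best E-value,
    then synteny (descending), with gene id as the deterministic last
    resort.  Verdicts: ``unassigned`` (no candidate),
    ``ambiguous_multidomain`` (every candidate carries extra unrelated
    domains), ``single_candidate`` or ``multiple_candidates``.
    """
    out: list[OrphanAssignment] = []
    for rx in reactions:
        if not isinstance(rx, OrphanReaction):
            rx = OrphanReaction.from_dict(rx)
        cands = match_domains(rx, domain_table, evalue_max=evalue_max)
        if ortholog_table is not None:
            for c in cands:
                c.synteny = synteny_score(c.gene_id, ortholog_table, k=k)
        cands.sort(key=lambda c: (-c.domain_score, c.best_evalue, -c.synteny, c.gene_id))
        if not cands:
            verdict = "unassigned"
        elif all(c.ambiguous_multidomain for c in cands):
            verdict = "ambiguous_multidomain"
        elif len(cands) == 1:
            verdict = "single_candidate"
        else:
            verdict = "multiple_candidates"
        out.append(OrphanAssignment(reaction_id=rx.reaction_id, candidates=cands,
                                    verdict=verdict, essential=rx.essential))
    return out


def report_assignments(assignments: Sequence[OrphanAssignment]) -> pd.DataFrame:
    """Flat report; essential reactions left unassigned are flagged."""
    rows = []
    for a in assignments:
        if not a.candidates:
            rows.append({"reaction_id": a.reaction_id, "verdict": a.verdict,
                         "rank": None, "gene_id": None, "best_evalue": None,
                         "synteny": None,
                         "flag": "ESSENTIAL-UNASSIGNED" if a.essential else ""})
            continue
        for i, c in enumerate(a.candidates, start=1):
            rows.append({"reaction_id": a.reaction_id, "verdict": a.verdict,
                         "rank": i, "gene_id": c.gene_id,
                         "best_evalue": c.best_evalue, "synteny": c.synteny,
                         "flag": "ambiguous" if c.ambiguous_multidomain else ""})
    return pd.DataFrame(rows)
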