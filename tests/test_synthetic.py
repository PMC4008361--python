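"""The generator's planted structure: genes, SD geometry, coverage,
fragment model and peptide tables."""

import numpy as np
import pytest
from scipy import stats

from annotforge.sequtils import collapse_il, revcomp, six_frame_translations, translate
from annotforge.synthetic import (
    GroundTruth,
    SimulationConfig,
    simulate_coverage,
    simulate_fragments,
    simulate_genome,
    simulate_peptides,
    _dynamics_multipliers,
)


@pytest.fixture(scope="module")
def small_cfg():
    return SimulationConfig(seed=7, genome_length=40_000, n_annotated_genes=15,
                            n_hidden_genes=3, n_hypothetical=3,
                            n_intergenic_transcripts=3)


@pytest.fixture(scope="module")
def small_sim(small_cfg):
    genome, truth = simulate_genome(small_cfg)
    return small_cfg, genome, truth


class TestGenome:
    def test_deterministic_under_fixed_seed(self, small_cfg):
        g1, t1 = simulate_genome(small_cfg)
        g2, t2 = simulate_genome(small_cfg)
        assert g1.seq == g2.seq
        assert [(g.gene_id, g.start, g.end, g.strand) for g in t1.genes] == [
            (g.gene_id, g.start, g.end, g.strand) for g in t2.genes]

    def test_gc_content_near_target(self, default_dataset):
        seq = default_dataset["genome"].seq
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.72) <= 0.02

    def test_no_hidden_genes_when_disabled(self):
        cfg = SimulationConfig(seed=3, genome_length=40_000, n_annotated_genes=15,
                               n_hidden_genes=0)
        _, truth = simulate_genome(cfg)
        assert truth.hidden_genes == []

    def test_genes_do_not_overlap(self, small_sim):
        _, _, truth = small_sim
        genes = sorted(truth.genes, key=lambda g: g.start)
        for a, b in zip(genes, genes[1:]):
            assert a.end <= b.start

    def test_gene_structure(self, small_sim):
        cfg, genome, truth = small_sim
        for g in truth.genes:
            cds = g.sequence(genome)
            assert len(cds) % 3 == 0
            assert cds[:3] in ("ATG", "GTG", "TTG")
            aa = translate(cds)
            assert aa.endswith("*") and "*" not in aa[:-1]

    def test_sd_window_lies_4_to_15_nt_upstream(self, small_sim):
        cfg, genome, truth = small_sim
        for g in truth.genes:
            s, e = truth.rbs_positions[g.gene_id]
            motif = genome.subseq(s, e, g.strand)
            assert motif == cfg.sd_motif
            spacer = (g.start - e) if g.strand == "+" else (s - g.end)
            assert 4 <= spacer <= 15

    def test_placement_failure_suggests_larger_genome(self):
        cfg = SimulationConfig(seed=0, genome_length=8_000, n_annotated_genes=30,
                               n_hidden_genes=0, n_hypothetical=0)
        with pytest.raises(ValueError, match="genome_length"):
            simulate_genome(cfg)

    def test_frameshift_annotation_offset_by_one(self, default_dataset):
        truth = default_dataset["truth"]
        (fs_id, _site) = truth.frameshift_sites[0]
        true_gene = truth.gene(fs_id)
        annotated = next(g for g in truth.annotated if g.gene_id == fs_id)
        assert annotated.start == true_gene.start + 1
        assert annotated.end == true_gene.end + 1


class TestCoverage:
    def test_hidden_gene_coverage_over_background(self, default_dataset):
        cfg, truth = default_dataset["config"], default_dataset["truth"]
        tracks = default_dataset["tracks"]
        for g in truth.hidden_genes:
            best = max(
                t.values[g.start : g.end].mean()
                for t in tracks if t.strand == g.strand
            )
            assert best > 10 * cfg.background_depth

    def test_switch_down_profile_monotone(self, default_dataset):
        cfg, truth = default_dataset["config"], default_dataset["truth"]
        tracks = default_dataset["tracks"]
        gid = next(g for g, p in truth.dynamics.items() if p == "switch_down")
        unit = next(u for u in truth.genes + truth.transcribed_segments
                    if u.gene_id == gid)
        means = [t.values[unit.start : unit.end].mean()
                 for t in tracks if t.strand == unit.strand]
        diffs = np.diff(means)
        assert (diffs < 0).all()

    def test_zero_depth_gives_all_zero_tracks(self):
        cfg = SimulationConfig(seed=5, genome_length=30_000, n_annotated_genes=10,
                               n_hidden_genes=1, coverage_depth=0.0,
                               background_depth=0.0, n_intergenic_transcripts=2)
        genome, truth = simulate_genome(cfg)
        tracks = simulate_coverage(genome, truth, cfg)
        assert all(t.values.sum() == 0 for t in tracks)

    def test_coverage_total_matches_planted_expression(self, default_dataset):
        cfg, truth = default_dataset["config"], default_dataset["truth"]
        tracks = default_dataset["tracks"]
        units = truth.genes + truth.transcribed_segments
        expected = 0.0
        for u in units:
            mult = _dynamics_multipliers(truth.dynamics[u.gene_id], cfg.n_time_points)
            expected += truth.expression[u.gene_id] * mult.sum() * u.length
        glen = default_dataset["genome"].length
        expected += cfg.background_depth * glen * cfg.n_time_points * 2
        observed = sum(t.values.sum() for t in tracks)
        assert abs(observed - expected) < 5 * np.sqrt(expected)


class TestFragments:
    def test_minus_strand_gene_fragments_on_minus(self):
        # no degradation background, so every fragment near a gene is its own
        cfg = SimulationConfig(seed=2, genome_length=30_000, n_annotated_genes=10,
                               n_hidden_genes=1, background_fragments=0.0,
                               n_intergenic_transcripts=2)
        genome, truth = simulate_genome(cfg)
        frags = simulate_fragments(genome, truth, cfg)
        minus_genes = [g for g in truth.genes if g.strand == "-"]
        assert minus_genes
        for g in minus_genes:
            near = [f for f in frags if f.start < g.end + 60 and g.start - 60 < f.end]
            assert near and all(f.strand == "-" for f in near)

    def test_modal_upstream_5p_offset_is_sd_window_start(self, default_dataset):
        cfg, truth = default_dataset["config"], default_dataset["truth"]
        frags = default_dataset["fragments"]
        offsets = {}
        for g in truth.genes:
            anchor = g.start if g.strand == "+" else g.end - 1
            for f in frags:
                if f.strand != g.strand:
                    continue
                t5 = f.start - anchor if g.strand == "+" else anchor - (f.end - 1)
                if -30 <= t5 < 0:
                    offsets[t5] = offsets.get(t5, 0) + f.count
        modal = max(offsets, key=offsets.get)
        assert modal == -(cfg.sd_spacer + len(cfg.sd_motif))

    def test_no_protection_gives_uniform_phases(self):
        cfg = SimulationConfig(seed=11, fragment_protection_strength=0.0,
                               fragments_per_gene=300.0)
        genome, truth = simulate_genome(cfg)
        frags = simulate_fragments(genome, truth, cfg)
        phase_counts = np.zeros(3)
        n = 0
        for g in truth.genes:
            glen = g.length
            for f in frags:
                if f.strand != g.strand:
                    continue
                t5 = f.start - g.start if g.strand == "+" else g.end - f.end
                if 9 <= t5 < glen - 9:
                    phase_counts[t5 % 3] += f.count
                    n += f.count
        assert n >= 10_000
        _, p = stats.chisquare(phase_counts)
        assert p > 0.01

    def test_fragment_lengths_in_gel_window(self, default_dataset):
        assert all(15 <= f.length <= 50 for f in default_dataset["fragments"])


class TestPeptides:
    def test_true_peptides_in_six_frame_translation(self, default_dataset):
        genome, truth = default_dataset["genome"], default_dataset["truth"]
        frames = [collapse_il(p) for _, _, p in six_frame_translations(genome.seq)]
        for pep in truth.true_peptides:
            assert any(collapse_il(pep) in fr for fr in frames)

    def test_decoys_absent_from_six_frame_translation(self, default_dataset):
        genome, truth = default_dataset["genome"], default_dataset["truth"]
        assert len(truth.decoy_peptides) == default_dataset["config"].n_decoy_peptides
        frames = [collapse_il(p) for _, _, p in six_frame_translations(genome.seq)]
        for pep in truth.decoy_peptides:
            assert not any(collapse_il(pep) in fr for fr in frames)

    def test_every_hidden_gene_has_a_peptide(self, default_dataset):
        truth = default_dataset["truth"]
        with_pep = set(truth.true_peptides.values())
        for g in truth.hidden_genes:
            assert g.gene_id in with_pep
        counts = {}
        for gid in truth.true_peptides.values():
            counts[gid] = counts.get(gid, 0) + 1
        # at least one hidden gene exercises the single-peptide path
        assert any(counts[g.gene_id] == 1 for g in truth.hidden_genes)

    def test_tryptic_shape(self, default_dataset):
        for pep in default_dataset["truth"].true_peptides:
            assert 7 <= len(pep) <= 30 and pep[-1] in "KR"

    def test_frameshift_peptide_absent_from_annotated_translation(self, default_dataset):
        genome, truth = default_dataset["genome"], default_dataset["truth"]
        (fs_id, _), = truth.frameshift_sites
        ann = next(g for g in truth.annotated if g.gene_id == fs_id)
        ann_protein = collapse_il(translate(ann.sequence(genome)))
        peps = [p for p, gid in truth.true_peptides.items() if gid == fs_id]
        assert peps
        for pep in peps:
            assert collapse_il(pep) not in ann_protein
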