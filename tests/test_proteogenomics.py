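"""Peptide mapping, ORF expansion, classification and the acceptance rules."""

import itertools

import pytest

from annotforge.io_formats import GeneModel, GenomeSequence
from annotforge.orf_discovery import CandidateORF
from annotforge.proteogenomics import (
    PeptideHit,
    Placement,
    ProteinCall,
    classify_orf,
    discover_proteins,
    expand_to_orf,
    filter_proteins,
    map_peptides,
)
from annotforge.sequtils import collapse_il, revcomp, translate


class TestMapPeptides:
    def test_planted_peptides_map_to_source_gene(self, default_dataset):
        genome, truth = default_dataset["genome"], default_dataset["truth"]
        rows = [(p, 99.0, "tp1") for p in truth.true_peptides]
        hits = map_peptides(rows, genome)
        for hit in hits:
            gene = truth.gene(truth.true_peptides[hit.peptide])
            assert hit.unique, hit.peptide
            p = hit.placements[0]
            assert p.strand == gene.strand
            assert gene.start <= p.start and p.end <= gene.end
            assert p.end - p.start == 3 * len(hit.peptide)

    def test_decoys_have_zero_placements(self, default_dataset):
        genome, truth = default_dataset["genome"], default_dataset["truth"]
        hits = map_peptides([(p, 50.0, "tp1") for p in truth.decoy_peptides], genome)
        assert all(not h.placements for h in hits)

    def test_soundness_placements_retranslate_to_peptide(self, default_dataset):
        genome, truth = default_dataset["genome"], default_dataset["truth"]
        hits = map_peptides([(p, 99.0, "tp1") for p in truth.true_peptides], genome)
        for hit in hits:
            for p in hit.placements:
                aa = translate(genome.subseq(p.start, p.end, p.strand))
                assert collapse_il(aa) == collapse_il(hit.peptide)

    def test_duplicated_peptide_not_unique(self):
        cds = "ATG" + "GCTAAAGAACGTATTCCGATGAAA" + "TAA"  # M A K E R I P M K *
        genome = GenomeSequence("c", cds + "CCCCCC" + cds)
        (hit,) = map_peptides([("AKERIPMK", 99.0, "s")], genome)
        assert len(hit.placements) == 2 and not hit.unique

    def test_il_equivalence(self):
        # CTT = Leu; peptide queried with Ile matches when I/L collapsed
        genome = GenomeSequence("c", "ATGCTTAAACGTGAAATTAAACGTTAA")
        (hit,) = map_peptides([("MIKREIKR", 99.0, "s")], genome)
        assert hit.unique
        (miss,) = map_peptides([("MIKREIKR", 99.0, "s")], genome, il_equivalent=False)
        assert not miss.placements

    def test_nonstandard_residues_skipped_with_warning(self):
        genome = GenomeSequence("c", "ATGAAATAA")
        with pytest.warns(UserWarning, match="non-standard"):
            hits = map_peptides([("MKXB", 90.0, "s")], genome)
        assert hits == []


class TestExpand:
    def test_recovers_planted_gene_exactly(self, default_dataset):
        genome, truth = default_dataset["genome"], default_dataset["truth"]
        for pep, gid in truth.true_peptides.items():
            gene = truth.gene(gid)
            (hit,) = map_peptides([(pep, 99.0, "s")], genome)
            orf = expand_to_orf(hit, genome)
            assert (orf.start, orf.end, orf.strand) == (gene.start, gene.end,
                                                        gene.strand)
            assert not orf.partial

    def test_no_upstream_start_before_stop_is_partial(self):
        # TAG stop, then GCC codons only (no start), peptide downstream
        genome = GenomeSequence("c", "TAG" + "GCC" * 12 + "AAACGT" + "TAA")
        (hit,) = map_peptides([("AAAAKR", 99.0, "s")], genome)
        assert hit.unique
        orf = expand_to_orf(hit, genome)
        assert orf.partial and orf.start_codon is None

    def test_non_unique_hit_refused(self):
        hit = PeptideHit("MKMK", 99.0, placements=[
            Placement("c", 0, 12, "+", 0), Placement("c", 30, 42, "+", 0)])
        with pytest.raises(ValueError, match="unique"):
            expand_to_orf(hit, GenomeSequence("c", "A" * 60))


class TestClassify:
    annotation = [
        GeneModel("known", "c", 300, 399, "+", kind="CDS"),
        GeneModel("hyp", "c", 600, 699, "+", kind="CDS",
                  attributes={"product": "hypothetical protein"}),
    ]

    def orf(self, start, end, strand="+", partial=False):
        return CandidateORF(chrom="c", start=start, end=end, strand=strand,
                            frame=start % 3 if strand == "+" else end % 3,
                            protein="M" * ((end - start) // 3 - 1),
                            start_codon="ATG", partial=partial)

    def test_no_overlap_is_novel(self):
        assert classify_orf(self.orf(0, 99), self.annotation) == "novel"

    def test_antisense_overlap_is_novel(self):
        assert classify_orf(self.orf(300, 399, strand="-"), self.annotation) == "novel"

    def test_equal_to_hypothetical_confirms(self):
        assert classify_orf(self.orf(600, 699), self.annotation) == \
            "confirms_hypothetical"

    def test_same_frame_longer_is_extension(self):
        assert classify_orf(self.orf(276, 399), self.annotation) == "extension"

    def test_near_frame_offset_is_frameshift_flag(self):
        assert classify_orf(self.orf(301, 400), self.annotation) == "frameshift_flag"

    def test_planted_frameshift_gene_flagged(self, default_dataset):
        genome, truth = default_dataset["genome"], default_dataset["truth"]
        (fs_id, _), = truth.frameshift_sites
        gene = truth.gene(fs_id)
        pep = next(p for p, g in truth.true_peptides.items() if g == fs_id)
        (hit,) = map_peptides([(pep, 99.0, "s")], genome)
        orf = expand_to_orf(hit, genome)
        assert (orf.start, orf.end) == (gene.start, gene.end)
        assert classify_orf(orf, truth.annotated) == "frameshift_flag"


class TestFilterRules:
    """Truth table of the >=2-at-95% and single-peptide+RNA rules."""

    def make_call(self, confidences, classification="novel"):
        orf = CandidateORF(chrom="c", start=0, end=30, strand="+", frame=0,
                           protein="M" * 9, start_codon="ATG",
                           classification=classification)
        peps = [PeptideHit(f"PEPTIDE{'AGSTV'[i]}K", c,
                           placements=[Placement("c", 0, 24, "+", 0)])
                for i, c in enumerate(confidences)]
        return ProteinCall(orf=orf, peptides=peps)

    @pytest.mark.parametrize(
        "confidences,transcribed,expected",
        [
            ([96.0, 96.0], False, "accepted"),       # two confident peptides
            ([96.0, 95.0], False, "accepted"),       # threshold is inclusive
            ([99.0], True, "accepted"),              # single + RNA validation
            ([99.0], False, "rejected"),             # single, not transcribed
            ([94.9, 94.9], True, "rejected"),        # nothing confident
            ([96.0, 94.0], True, "accepted"),        # 1 confident + RNA
            ([96.0, 94.0], False, "rejected"),
            ([], False, "rejected"),
        ],
    )
    def test_acceptance_truth_table(self, confidences, transcribed, expected):
        (call,) = filter_proteins([self.make_call(confidences)],
                                  transcription_evidence=lambda orf: transcribed)
        assert call.status == expected
        if call.status == "accepted":
            assert call.n_conf_peptides >= 2 or call.rna_validated

    def test_distinct_sequences_not_spectral_counts(self):
        call = self.make_call([99.0, 99.0])
        call.peptides[1].peptide = call.peptides[0].peptide  # same sequence twice
        (out,) = filter_proteins([call], transcription_evidence=lambda o: False)
        assert out.n_conf_peptides == 1 and out.status == "rejected"

    def test_no_evidence_leaves_needs_rna_validation(self):
        (call,) = filter_proteins([self.make_call([99.0])],
                                  transcription_evidence=None)
        assert call.status == "needs_rna_validation"

    def test_threshold_monotonicity(self):
        calls = [self.make_call([c1, c2]) for c1, c2 in
                 itertools.product([90.0, 93.0, 96.0, 99.0], repeat=2)]
        accepted_sets = []
        for thr in (99.0, 96.0, 93.0, 90.0):
            out = filter_proteins([self.make_call([c.confidence for c in call.peptides])
                                   for call in calls],
                                  transcription_evidence=lambda o: False,
                                  confidence_threshold=thr)
            accepted_sets.append({i for i, c in enumerate(out)
                                  if c.status == "accepted"})
        for a, b in zip(accepted_sets, accepted_sets[1:]):
            assert a <= b


class TestDiscoverProteins:
    def test_recovery_and_zero_decoys(self, default_dataset):
        d = default_dataset
        calls = discover_proteins(d["peptides"], d["genome"], d["truth"].annotated,
                                  transcription_evidence=lambda orf: True)
        accepted = {(c.orf.start, c.orf.end, c.orf.strand) for c in calls
                    if c.status == "accepted" and c.orf.classification == "novel"}
        hidden = {(g.start, g.end, g.strand) for g in d["truth"].hidden_genes}
        assert hidden <= accepted
        decoys = set(d["truth"].decoy_peptides)
        for c in calls:
            assert not any(h.peptide in decoys for h in c.peptides)

    def test_supporting_nonunique_peptides_attach(self):
        cds = "ATG" + "GCTAAAGAACGTATTCCGATGAAA" + "TAA"
        genome = GenomeSequence("c", "T" * 9 + cds + "CCCCCC")
        rows = [("AKERIPMK", 99.0, "s")]
        calls = discover_proteins(rows, genome, [], il_equivalent=False)
        assert len(calls) == 1 and len(calls[0].peptides) == 1
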