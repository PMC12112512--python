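"""Origin-mechanism rules, de novo criteria and mutation reconstruction."""

import pytest

from genebirth import dating, origin
from genebirth.origin import (
    MECH_DENOVO,
    MECH_DNA,
    MECH_RETRO,
    MECH_UNCLASSIFIED,
    OriginCall,
    check_de_novo_criteria,
    classify_mechanism,
    classify_new_genes,
    find_parent,
    reconstruct_enabling_mutations,
)
from genebirth.io_formats import GeneModel, HomologyHit, ValidationError


def hit(q, t, evalue, bitscore=100.0, species="ref"):
    return HomologyHit(q, t, species, 50.0, evalue, 100, bitscore=bitscore)


def gene(gid, n_exons):
    exons = [(1 + 200 * k, 100 + 200 * k) for k in range(n_exons)]
    return GeneModel(gid, "chr1", exons[0][0], exons[-1][1], "+", exons, 99)


class TestFindParent:
    BRANCHES = {"old1": 1, "old0a": 0, "old0b": 0, "young5": 5}

    def test_old_gene_preferred_over_better_scoring_young_gene(self):
        hits = [hit("c", "old1", 1e-80), hit("c", "young5", 1e-90)]
        assert find_parent("c", hits, self.BRANCHES) == "old1"

    def test_no_hits_gives_none(self):
        assert find_parent("c", [], self.BRANCHES) is None

    def test_equal_evalue_broken_by_bitscore(self):
        hits = [hit("c", "old0a", 1e-50, bitscore=190.0),
                hit("c", "old0b", 1e-50, bitscore=210.0)]
        assert find_parent("c", hits, self.BRANCHES) == "old0b"

    def test_self_hit_ignored(self):
        assert find_parent("old1", [hit("old1", "old1", 0.0)], self.BRANCHES) is None


class TestClassifyMechanism:
    def test_single_exon_child_of_multi_exon_parent_is_retro(self):
        call = classify_mechanism(gene("c", 1), gene("p", 3))
        assert call.mechanism == MECH_RETRO
        assert call.parent_id == "p"

    def test_multi_exon_child_is_dna_duplication(self):
        assert classify_mechanism(gene("c", 2), gene("p", 3)).mechanism == MECH_DNA

    def test_intronless_parent_means_dna_duplication(self):
        # retroposition from an ancestrally intronless parent is undetectable
        assert classify_mechanism(gene("c", 1), gene("p", 1)).mechanism == MECH_DNA

    def test_orphan_failing_denovo_criteria_is_unclassified(self):
        call = classify_mechanism(gene("c", 1), None, denovo_ok=False)
        assert call.mechanism == MECH_UNCLASSIFIED

    def test_call_invariants(self):
        with pytest.raises(ValidationError):
            OriginCall("g", MECH_RETRO, parent_id=None)
        with pytest.raises(ValidationError):
            OriginCall("g", MECH_DENOVO, parent_id="p")


class TestDeNovoCriteria:
    def dna(self, q, species, cov):
        return HomologyHit(q, f"{species}_locus", species, 90.0, 1e-20, 100,
                           query_coverage=cov)

    def prot(self, q, species):
        return HomologyHit(q, f"{species}_prot", species, 40.0, 1e-20, 100)

    def test_two_protein_homologs_in_one_species_fails(self):
        prot = [self.prot("g", "N_vitripennis"), self.prot("g", "N_vitripennis")]
        ok, reason = check_de_novo_criteria("g", prot, [], "T_elegans")
        assert not ok and "criterion 1" in reason

    def test_protein_homolog_in_outgroup_fails(self):
        ok, reason = check_de_novo_criteria("g", [self.prot("g", "T_elegans")],
                                            [], "T_elegans")
        assert not ok and "criterion 1" in reason

    def test_one_dna_hit_per_species_with_good_coverage_passes(self):
        dna = [self.dna("g", "P_venustus", 0.6), self.dna("g", "P_qinghaiensis", 0.3)]
        ok, reason = check_de_novo_criteria("g", [], dna, "T_elegans")
        assert ok and reason is None

    def test_all_dna_coverage_at_or_below_20pct_fails(self):
        dna = [self.dna("g", "P_venustus", 0.20)]
        ok, reason = check_de_novo_criteria("g", [], dna, "T_elegans")
        assert not ok and "criterion 2" in reason


class TestReconstructMutations:
    ORF = "ATGGCTAAGGGCCTACGAGATTGGTTCACC"  # 10 codons, no stops

    def test_identical_sequences_give_no_events(self):
        ev = reconstruct_enabling_mutations(self.ORF, self.ORF)
        assert ev.events == []

    def test_single_nt_deletion_is_one_frameshift(self):
        outgroup = self.ORF[:7] + self.ORF[8:]  # drop one base
        ev = reconstruct_enabling_mutations(self.ORF, outgroup)
        assert ev.n_frameshifts == 1
        assert [e.kind for e in ev.events if e.kind.startswith("frameshift")] \
            == ["frameshift_deletion"]

    def test_in_frame_stop_in_outgroup_reported(self):
        outgroup = self.ORF[:9] + "TAA" + self.ORF[12:]  # codon 4 -> TAA
        ev = reconstruct_enabling_mutations(self.ORF, outgroup)
        assert ev.n_premature_stops == 1
        stop = [e for e in ev.events if e.kind == "premature_stop"][0]
        assert stop.position == 4

    def test_codon_length_insertion_is_not_frameshift(self):
        outgroup = self.ORF[:9] + "GGG" + self.ORF[9:]
        ev = reconstruct_enabling_mutations(self.ORF, outgroup)
        assert ev.n_frameshifts == 0

    def test_event_counts_symmetric_under_swap(self):
        outgroup = self.ORF[:7] + self.ORF[8:17] + "T" + self.ORF[17:]
        fwd = reconstruct_enabling_mutations(self.ORF, outgroup)
        rev = reconstruct_enabling_mutations(outgroup, self.ORF)
        # insertions and deletions exchange; substitution count matches
        assert fwd.n_frameshifts == rev.n_frameshifts
        assert fwd.n_substitutions == rev.n_substitutions

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            reconstruct_enabling_mutations("", self.ORF)


class TestClassifyFixture:
    def _calls(self, fx):
        aged = dating.date_genome(fx.genes, fx.synteny, fx.repeats,
                                  fx.protein_hits, fx.tree)
        new_ids = [a.gene_id for a in aged if a.is_new]
        branch = {a.gene_id: a.branch for a in aged
                  if a.excluded_reason == dating.REASON_NONE}
        models = {g.gene_id: g for g in fx.genes}
        return new_ids, classify_new_genes(
            new_ids, models, branch, fx.paralog_hits, fx.protein_hits,
            fx.dna_hits, sorted(fx.tree.groups[0])[0],
            outgroup_nt=fx.outgroup_nt, orf_nt=fx.cds)

    def test_planted_mechanisms_fully_recovered(self, gene_fixture):
        new_ids, calls = self._calls(gene_fixture)
        truth = gene_fixture.truth.mechanism
        assert all(truth[c.gene_id] == c.mechanism for c in calls)

    def test_calls_partition_new_genes(self, gene_fixture):
        new_ids, calls = self._calls(gene_fixture)
        assert sorted(c.gene_id for c in calls) == sorted(new_ids)
        mechs = {MECH_DNA, MECH_RETRO, MECH_DENOVO, MECH_UNCLASSIFIED}
        assert all(c.mechanism in mechs for c in calls)

    def test_planted_denovo_events_recovered(self, gene_fixture):
        _, calls = self._calls(gene_fixture)
        truth_ev = gene_fixture.truth.denovo_events
        denovo = [c for c in calls if c.mechanism == MECH_DENOVO]
        assert denovo
        for c in denovo:
            assert c.denovo is not None
            assert c.denovo.n_frameshifts >= truth_ev[c.gene_id]["frameshifts"]
            assert c.denovo.n_premature_stops >= truth_ev[c.gene_id]["premature_stops"]
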