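import numpy as np
import pytest

from iqdfam.io import SeqRecord, translate_cds
from iqdfam.kaks import CodonAlignment, ng86_kaks
from iqdfam.simulate import (
    DOMAIN_TEMPLATE,
    FamilySpec,
    _encode_protein,
    _random_protein,
    generate_family_genome,
    mutate_codon_sequence,
)


class TestFamilySpecValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            FamilySpec(n_iqd_genes=-1)

    def test_divergence_target_bound(self):
        with pytest.raises(ValueError, match="0.7"):
            FamilySpec(ks_target=0.8)

    def test_too_few_iqd_genes_for_requested_pairs(self):
        with pytest.raises(ValueError):
            FamilySpec(n_iqd_genes=2, tandem_pairs=1, segmental_blocks=1)


class TestGenerateFamilyGenome:
    def test_deterministic_for_fixed_seed(self):
        a = generate_family_genome(FamilySpec(seed=9, n_iqd_genes=4,
                                              n_background_genes=20,
                                              segmental_blocks=1))
        b = generate_family_genome(FamilySpec(seed=9, n_iqd_genes=4,
                                              n_background_genes=20,
                                              segmental_blocks=1))
        assert [r.sequence for r in a[0]] == [r.sequence for r in b[0]]
        assert {g.gene_id: g.exons for g in a[1].genes} == {
            g.gene_id: g.exons for g in b[1].genes
        }

    def test_no_iqd_genes_leaves_domain_truth_empty(self):
        spec = FamilySpec(n_iqd_genes=0, tandem_pairs=0, segmental_blocks=0,
                          n_background_genes=10)
        _, annotation, truth = generate_family_genome(spec)
        assert truth.domain_locations == {}
        assert len(annotation.genes) == 10

    def test_truth_lists_requested_pair_types(self):
        spec = FamilySpec(n_iqd_genes=4, tandem_pairs=1, segmental_blocks=1,
                          n_background_genes=20)
        _, _, truth = generate_family_genome(spec)
        types = sorted(truth.pair_types.values())
        assert types == ["segmental", "tandem"]

    def test_genes_do_not_fit_is_an_error(self):
        with pytest.raises(ValueError, match="fit"):
            generate_family_genome(
                FamilySpec(chromosome_length=20_000, n_chromosomes=1)
            )

    def test_every_entity_has_one_truth_entry(self, family):
        _, annotation, truth = family
        ids = {g.gene_id for g in annotation.genes}
        assert set(truth.domain_locations) <= ids
        for a, b in truth.pair_types:
            assert {a, b} <= ids
            assert (a, b) in truth.pair_divergence


class TestMutateCodonSequence:
    CDS = SeqRecord("x", _encode_protein("M" + "KVLIDEQRST" * 20,
                                         np.random.default_rng(0)), "dna")

    def test_zero_targets_return_identical_sequence(self):
        out = mutate_codon_sequence(self.CDS, 0.0, 0.0, seed=1)
        assert out.sequence == self.CDS.sequence

    def test_protein_length_unchanged_and_no_stops(self):
        out = mutate_codon_sequence(self.CDS, 0.05, 0.15, seed=2)
        assert len(out.sequence) == len(self.CDS.sequence)
        assert len(translate_cds(out).sequence) == len(
            translate_cds(self.CDS).sequence
        )

    def test_deterministic_per_seed(self):
        a = mutate_codon_sequence(self.CDS, 0.05, 0.15, seed=3)
        b = mutate_codon_sequence(self.CDS, 0.05, 0.15, seed=3)
        assert a.sequence == b.sequence

    def test_saturating_target_is_an_error(self):
        with pytest.raises(ValueError):
            mutate_codon_sequence(self.CDS, 0.05, 0.75, seed=1)

    def test_protected_codons_keep_their_amino_acids(self):
        protected = set(range(10, 30))
        out = mutate_codon_sequence(
            self.CDS, 0.2, 0.2, seed=4, protected_codons=protected
        )
        before = translate_cds(self.CDS).sequence
        after = translate_cds(out).sequence
        assert all(before[i] == after[i] for i in protected)
        assert before != after  # unprotected residues did change

    def test_ng86_recovers_targets_on_average(self):
        # 450-codon sequence, modest divergence, a handful of seeds; the
        # full 50-seed recovery check runs in the acceptance suite
        rng = np.random.default_rng(10)
        cds = SeqRecord("y", _encode_protein(_random_protein(450, rng), rng), "dna")
        kas, kss = [], []
        for seed in range(10):
            mut = mutate_codon_sequence(cds, 0.05, 0.15, seed=seed)
            ka, ks = ng86_kaks(
                CodonAlignment(cds.sequence[:-3], mut.sequence[:-3])
            )
            kas.append(ka)
            kss.append(ks)
        assert np.mean(kas) == pytest.approx(0.05, rel=0.3)
        assert np.mean(kss) == pytest.approx(0.15, rel=0.3)


def test_domain_template_length_and_motif_layout():
    assert len(DOMAIN_TEMPLATE) == 67
    # strict IQ copies at canonical spacings: starts 1, 23, 49 (1-based)
    assert DOMAIN_TEMPLATE[0:11] == DOMAIN_TEMPLATE[22:33] == DOMAIN_TEMPLATE[48:59]
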