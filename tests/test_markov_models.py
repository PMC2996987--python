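import numpy as np
import pytest

from oscan import (
    CodonBasedModel,
    PeriodicMarkovModel,
    analytic_osc_expectation,
    analytic_osc_expectation_dicodon,
    filter_cds,
    generate_cds,
    generate_cds_codon_based,
    train_codon_based,
    train_periodic_markov,
)
from oscan.markov_models import generate_codons
from oscan import _encoding as enc
from oscan.synthetic_data import SynthesisSpec, synth_genome

from conftest import STOPS11, make_genome


class TestPeriodicTraining:
    def test_deterministic_repeat_chain(self, rng):
        g = make_genome(["GCT" * 40] * 3)
        m = train_periodic_markov(g, 2)
        assert m.transition_prob("GC", "T", phase=2) == 1.0
        assert generate_cds(m, 5, rng) == "GCT" * 5

    def test_stop_completions_have_zero_probability(self, medium_genome):
        m = train_periodic_markov(medium_genome, 2)
        # an in-frame TAA/TAG would need A/G after context TA at phase 2
        assert m.transition_prob("TA", "A", phase=2) == 0.0
        assert m.transition_prob("TA", "G", phase=2) == 0.0
        assert m.transition_prob("TG", "A", phase=2) == 0.0

    def test_rows_normalized(self, small_genome):
        for order in (1, 2, 5):
            m = train_periodic_markov(small_genome, order)
            sums = m.probs.sum(axis=2)
            assert np.allclose(sums, 1.0, atol=1e-12)

    def test_order_and_empty_validation(self, small_genome):
        with pytest.raises(ValueError):
            train_periodic_markov(small_genome, 0)
        with pytest.raises(ValueError):
            train_periodic_markov(make_genome([]), 2)

    def test_small_training_set_warns(self):
        g = make_genome(["ATGGCTGCAGCG" * 10])
        with pytest.warns(UserWarning, match="training nt"):
            train_periodic_markov(g, 5)


class TestPeriodicGeneration:
    @pytest.mark.parametrize("order", [2, 5])
    def test_generated_genes_are_stop_free_and_pass_filters(
            self, medium_genome, order, rng):
        m = train_periodic_markov(medium_genome, order)
        seqs = [generate_cds(m, 200, rng) for _ in range(20)]
        from oscan import CodingSequence
        recs = [CodingSequence(id=str(i), organism="sim", sequence=s,
                               genetic_code=11) for i, s in enumerate(seqs)]
        kept, report = filter_cds(recs)
        assert len(kept) == 20 and not report

    def test_same_seed_same_sequence(self, small_genome):
        m = train_periodic_markov(small_genome, 2)
        a = generate_cds(m, 100, np.random.default_rng(5))
        b = generate_cds(m, 100, np.random.default_rng(5))
        assert a == b

    def test_phase_specific_composition_is_reproduced(self, medium_genome):
        from oscan import composition_stats, genome_osc_stats
        m = train_periodic_markov(medium_genome, 2)
        rng = np.random.default_rng(42)
        sim = make_genome([generate_cds(m, 300, rng) for _ in range(120)])
        ref, got = composition_stats(medium_genome), composition_stats(sim)
        for attr in ("gc1", "gc2", "gc3"):
            assert getattr(got, attr) == pytest.approx(getattr(ref, attr), abs=0.01)

    def test_parameter_recovery_quick(self, medium_genome):
        # fuller 1e6-nt recovery is exercised in the acceptance suite
        truth = train_periodic_markov(medium_genome, 2)
        rng = np.random.default_rng(7)
        sim = make_genome([generate_cds(m := truth, 500, rng) for _ in range(200)])
        refit = train_periodic_markov(sim, 2)
        seen = truth.counts.sum(axis=2) >= 2000
        err = np.abs(refit.probs - truth.probs)[seen]
        assert err.max() < 0.03

    def test_json_roundtrip(self, small_genome, rng):
        m = train_periodic_markov(small_genome, 2)
        m2 = PeriodicMarkovModel.from_json(m.to_json())
        assert np.array_equal(m.counts, m2.counts)
        assert generate_cds(m, 50, np.random.default_rng(1)) == \
            generate_cds(m2, 50, np.random.default_rng(1))


TOY = ["ATGGCTGCT"]  # codons ATG, GCT, GCT


class TestCodonModels:
    def test_codon_usage_frequencies(self):
        m = train_codon_based(make_genome(TOY), "codon_usage")
        assert m.codon_freq[enc.codon_index("GCT")] == pytest.approx(2 / 3)
        assert m.codon_freq[enc.codon_index("ATG")] == pytest.approx(1 / 3)

    def test_dicodon_transitions(self):
        m = train_codon_based(make_genome(TOY), "dicodon")
        atg, gct = enc.codon_index("ATG"), enc.codon_index("GCT")
        assert m.dicodon_trans[atg, gct] == 1.0
        assert m.dicodon_trans[gct, gct] == 1.0

    def test_dipeptide_transitions(self):
        m = train_codon_based(make_genome(TOY), "dipeptide")
        met, ala = m.aa_list.index("M"), m.aa_list.index("A")
        assert m.aa_trans[met, ala] == 1.0
        assert m.codon_given_aa[ala, enc.codon_index("GCT")] == 1.0

    def test_unknown_kind_rejected(self, small_genome):
        with pytest.raises(ValueError, match="kind"):
            train_codon_based(small_genome, "hexamer")

    def test_deterministic_generation(self):
        freq = np.zeros(64)
        freq[enc.codon_index("AAA")] = 1.0
        m = CodonBasedModel(kind="codon_usage", table_id=11, codon_freq=freq)
        assert generate_cds_codon_based(m, 4, np.random.default_rng(0)) == "A" * 12

    def test_dicodon_chain_reproduces_toy_gene(self):
        m = train_codon_based(make_genome(TOY), "dicodon")
        s = generate_cds_codon_based(m, 6, np.random.default_rng(0))
        # after the initial codon the chain is deterministic: ...GCT GCT ...
        assert s.endswith("GCT" * 4)

    def test_law_of_large_numbers(self, small_genome):
        m = train_codon_based(small_genome, "codon_usage")
        codons = generate_codons(m, 10 ** 5, np.random.default_rng(3))
        emp = np.bincount(codons, minlength=64) / 10 ** 5
        assert np.abs(emp - m.codon_freq).max() < 0.005

    @pytest.mark.parametrize("kind", ["codon_usage", "dicodon", "dipeptide"])
    def test_generated_codons_exclude_stops(self, medium_genome, kind, rng):
        m = train_codon_based(medium_genome, kind)
        codons = generate_codons(m, 20000, rng)
        smask = enc.stop_mask64(STOPS11)
        assert int(smask[codons].sum()) == 0

    def test_nesting_dicodon_converges_to_codon_usage(self):
        base = synth_genome(SynthesisSpec(n_genes=150, gc_target=0.5,
                                          length_sampler=400, seed=23))
        dic = train_codon_based(base, "dicodon")
        # data were generated i.i.d., so transition rows approach the marginal
        rows = dic.dicodon_trans[dic.codon_freq > 0.005]
        assert np.abs(rows - dic.codon_freq).max() < 0.05

    def test_json_roundtrip(self, small_genome):
        for kind in ("codon_usage", "dicodon", "dipeptide"):
            m = train_codon_based(small_genome, kind)
            m2 = CodonBasedModel.from_json(m.to_json())
            a = generate_cds_codon_based(m, 30, np.random.default_rng(2))
            b = generate_cds_codon_based(m2, 30, np.random.default_rng(2))
            assert a == b


class TestAnalyticExpectation:
    def test_no_thymine_no_oscs(self):
        freq = np.zeros(64)
        freq[enc.codon_index("AAA")] = 1.0
        m = CodonBasedModel(kind="codon_usage", table_id=11, codon_freq=freq)
        assert analytic_osc_expectation(m, 100) == (0.0, 0.0)

    def test_two_codon_hand_enumeration(self):
        freq = np.zeros(64)
        freq[enc.codon_index("TTA")] = 0.5
        freq[enc.codon_index("AAT")] = 0.5
        m = CodonBasedModel(kind="codon_usage", table_id=11, codon_freq=freq)
        e2, e3 = analytic_osc_expectation(m, 11)
        assert e2 == pytest.approx(2.5)  # only (TTA,AAT) junction gives TAA in +2
        assert e3 == pytest.approx(2.5)  # only (AAT,AAT) junction gives TAA in +3
    def test_uniform_diagnostic(self):
        m = CodonBasedModel(kind="codon_usage", table_id=11,
                            codon_freq=np.full(64, 1 / 64))
        e2, e3 = analytic_osc_expectation(m, 2)
        assert e2 == pytest.approx(3 / 64)
        assert e3 == pytest.approx(3 / 64)

    def test_requires_iid_model(self, small_genome):
        m = train_codon_based(small_genome, "dicodon")
        with pytest.raises(ValueError, match="codon_usage"):
            analytic_osc_expectation(m, 100)

    def test_dicodon_oracle_agrees_on_iid_rows(self, small_genome):
        usage = train_codon_based(small_genome, "codon_usage")
        from oscan.synthetic_data import dicodon_from_codon_usage
        chain = dicodon_from_codon_usage(usage.codon_freq, 11)
        e_iid = analytic_osc_expectation(usage, 300)
        e_chain = analytic_osc_expectation_dicodon(chain, 300)
        assert e_chain[0] == pytest.approx(e_iid[0], rel=1e-9)
        assert e_chain[1] == pytest.approx(e_iid[1], rel=1e-9)
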