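import numpy as np
import pandas as pd
import pytest

from notimeth.calling import pair_signals
from notimeth.model import CallState, ConfigError
from notimeth.simulate import (
    ArraySimConfig,
    BisulfiteSimConfig,
    QpcrSimConfig,
    simulate_array_pair,
    simulate_bisulfite,
    simulate_cohort,
    simulate_qpcr,
)


class TestArraySimulator:
    def test_noise_free_md_events_give_exact_half_ratio(self):
        cfg = ArraySimConfig(
            n_sites=25, noise_sd=0.0, missing_rate=0.0, event_prob=1.0,
            background_log2_sd=0.0, seed=1,
        )
        spots, truth = simulate_array_pair(cfg)
        assert (truth == CallState.MD.value).all()
        sig = pair_signals(spots)
        human = sig.loc[truth.index]
        np.testing.assert_allclose(2.0 ** human["log_ratio"], 0.5)

    def test_no_events_means_all_retention_truth(self):
        cfg = ArraySimConfig(n_sites=50, event_prob=0.0, ad_prob=0.0, seed=2)
        _, truth = simulate_array_pair(cfg)
        assert (truth == CallState.RET.value).all()

    def test_planted_md_fraction_is_binomial(self):
        """At p=0.57 over 5000 draws the MD fraction sits within 3 binomial SDs."""
        cfg = ArraySimConfig(n_sites=5000, event_prob=0.57, ad_prob=0.0, seed=3)
        _, truth = simulate_array_pair(cfg)
        frac = (truth == CallState.MD.value).mean()
        sd = np.sqrt(0.57 * 0.43 / 5000)
        assert abs(frac - 0.57) < 3 * sd

    def test_invalid_effects_and_probs_are_config_errors(self):
        with pytest.raises(ConfigError):
            ArraySimConfig(md_effect=1.0)
        with pytest.raises(ConfigError):
            ArraySimConfig(ad_effect=0.9)
        with pytest.raises(ConfigError):
            ArraySimConfig(event_prob=1.5)
        with pytest.raises(ConfigError):
            simulate_array_pair(ArraySimConfig(n_sites=3), site_probs=[0.5, 2.0, 0.1])

    def test_cohort_with_zero_frequencies_is_all_retention(self):
        cfg = ArraySimConfig(n_sites=8, seed=4)
        _, truth = simulate_cohort(cfg, 5, site_probs=np.zeros(8))
        assert (truth == CallState.RET.value).all().all()

    def test_hypermethylator_factor_raises_per_sample_burden(self):
        """With the latent hypermethylator factor on, affected samples carry
        correlated high event burdens; off by default it changes nothing."""
        base = ArraySimConfig(n_sites=200, n_replicates=1, n_controls=0,
                              event_prob=0.1, ad_prob=0.0, seed=21)
        hyper = ArraySimConfig(n_sites=200, n_replicates=1, n_controls=0,
                               event_prob=0.1, ad_prob=0.0, seed=21,
                               hyper_prob=1.0, hyper_gain=0.5)
        _, t0 = simulate_cohort(base, 10)
        _, t1 = simulate_cohort(hyper, 10)
        b0 = (t0 == CallState.MD.value).sum(axis=0)
        b1 = (t1 == CallState.MD.value).sum(axis=0)
        assert b1.mean() > 2 * b0.mean()  # expected 0.55 vs 0.1 per site

    def test_empty_cohort(self):
        cfg = ArraySimConfig(n_sites=8, seed=4)
        cohort, truth = simulate_cohort(cfg, 0)
        assert cohort == {} and truth.shape == (8, 0)

    def test_cohort_frequencies_match_planted_in_expectation(self, printed_freqs):
        """Planted truth at the printed site frequencies recovers the printed
        MD counts in expectation over many simulated cohorts."""
        probs = np.array([f.md_count / f.n_samples for f in printed_freqs])
        cfg = ArraySimConfig(n_sites=19, n_replicates=1, n_controls=0, seed=5)
        counts = np.zeros(19)
        n_rep = 40
        for i in range(n_rep):
            _, truth = simulate_cohort(
                ArraySimConfig(n_sites=19, n_replicates=1, n_controls=0, seed=5 + i),
                23, site_probs=probs,
            )
            counts += (truth == CallState.MD.value).sum(axis=1).to_numpy()
        mean_counts = counts / n_rep
        expected = probs * 23
        se = np.sqrt(23 * probs * (1 - probs) / n_rep)
        assert np.all(np.abs(mean_counts - expected) < 4 * se)


class TestQpcrSimulator:
    def test_no_fold_change_no_noise_gives_identical_ct(self):
        q = simulate_qpcr(QpcrSimConfig(true_fold_change=1.0, ct_replicate_sd=0.0))
        np.testing.assert_allclose(q.ct_tar_tumor, q.ct_tar_normal)

    def test_four_fold_loss_at_full_efficiency_shifts_two_cycles(self):
        q = simulate_qpcr(
            QpcrSimConfig(true_fold_change=0.25, efficiency_tar=1.0, ct_replicate_sd=0.0)
        )
        np.testing.assert_allclose(q.ct_tar_tumor - q.ct_tar_normal, 2.0)

    def test_invalid_efficiency_is_a_config_error(self):
        with pytest.raises(ConfigError):
            QpcrSimConfig(efficiency_tar=0.0)
        with pytest.raises(ConfigError):
            QpcrSimConfig(true_fold_change=-1.0)


class TestBisulfiteSimulator:
    def test_probability_extremes(self):
        full = simulate_bisulfite(BisulfiteSimConfig(per_cpg_meth_prob=1.0, seed=1))
        assert full.matrix.all()
        none = simulate_bisulfite(BisulfiteSimConfig(per_cpg_meth_prob=0.0, seed=1))
        assert not none.matrix.any()

    def test_per_cpg_fractions_are_binomial(self):
        cfg = BisulfiteSimConfig(n_clones=5000, per_cpg_meth_prob=0.9, seed=2)
        cs = simulate_bisulfite(cfg)
        frac = cs.matrix.mean(axis=0)
        sd = np.sqrt(0.9 * 0.1 / 5000)
        assert np.all(np.abs(frac - 0.9) < 3 * sd)

    def test_probability_vector_length_mismatch(self):
        with pytest.raises(ConfigError):
            BisulfiteSimConfig(n_cpg=24, per_cpg_meth_prob=(0.5,) * 10)


class TestReplayability:
    def test_array_pair_same_seed_same_bytes(self):
        cfg = ArraySimConfig(n_sites=20, seed=77)
        a, ta = simulate_array_pair(cfg)
        b, tb = simulate_array_pair(cfg)
        assert a.to_csv() == b.to_csv() and ta.to_csv() == tb.to_csv()

    def test_cohort_same_seed_same_bytes(self):
        cfg = ArraySimConfig(n_sites=12, seed=78)
        (ca, ta), (cb, tb) = simulate_cohort(cfg, 3), simulate_cohort(cfg, 3)
        assert ta.to_csv() == tb.to_csv()
        assert all(ca[s].to_csv() == cb[s].to_csv() for s in ca)

    def test_qpcr_and_bisulfite_same_seed_same_output(self):
        qa = simulate_qpcr(QpcrSimConfig(seed=79))
        qb = simulate_qpcr(QpcrSimConfig(seed=79))
        np.testing.assert_array_equal(qa.ct_tar_tumor, qb.ct_tar_tumor)
        ba = simulate_bisulfite(BisulfiteSimConfig(seed=80))
        bb = simulate_bisulfite(BisulfiteSimConfig(seed=80))
        np.testing.assert_array_equal(ba.matrix, bb.matrix)
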