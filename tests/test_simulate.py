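"""The synthetic metapopulation generator: structure, determinism, artifacts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

import hostrace as hr
from hostrace.filtering import allelic_balance_test
from hostrace.ld import pairwise_r2
from hostrace.popgen import global_fst


class TestGenotypeToLikelihoods:
    def test_zero_depth_is_uninformative(self):
        assert np.allclose(hr.genotype_to_likelihoods(1, 0, 0.01, 0), [1 / 3] * 3)

    def test_error_free_hom_ref_triplet(self):
        # depth 5, no errors: likelihoods ∝ (1, 0.5^5, 0)
        t = hr.genotype_to_likelihoods(0, 5, 0.0, 0)
        assert np.allclose(t, [0.9697, 0.0303, 0.0], atol=5e-5)

    def test_deep_hom_alt_is_confident(self):
        t = hr.genotype_to_likelihoods(2, 30, 0.01, 0)
        assert t[2] > 0.999

    @given(dosage=st.integers(0, 2), depth=st.integers(0, 60),
           err=st.floats(0.0, 0.49), seed=st.integers(0, 10))
    @settings(max_examples=60, deadline=None)
    def test_triplet_is_a_distribution(self, dosage, depth, err, seed):
        t = hr.genotype_to_likelihoods(dosage, depth, err, seed)
        assert t.shape == (3,)
        assert np.all(t >= 0)
        assert abs(t.sum() - 1.0) < 1e-9

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            hr.genotype_to_likelihoods(1, -1, 0.01, 0)
        with pytest.raises(ValueError):
            hr.genotype_to_likelihoods(1, 5, 0.6, 0)


class TestSimulateMetapopulation:
    def test_seeded_determinism(self):
        cfg = hr.SimulationConfig(n_loci=200, n_per_pop=8, seed=42)
        a = hr.simulate_metapopulation(cfg)
        b = hr.simulate_metapopulation(hr.SimulationConfig(n_loci=200, n_per_pop=8, seed=42))
        assert np.array_equal(a.gl_table.probs, b.gl_table.probs)
        assert np.array_equal(a.called_table.dosage, b.called_table.dosage, equal_nan=True)
        assert a.truth.equals(b.truth)
        assert a.popmap.frame.equals(b.popmap.frame)

    def test_probability_triplets_sum_to_one(self, power_dataset):
        sums = power_dataset.gl_table.probs.sum(axis=-1)
        assert np.abs(sums - 1.0).max() < 1e-9

    def test_every_sample_in_popmap(self, power_dataset):
        assert all(s in power_dataset.popmap for s in power_dataset.gl_table.samples)
        assert len(power_dataset.truth) == power_dataset.gl_table.n_loci

    def test_undifferentiated_config_gives_near_zero_fst(self):
        cfg = hr.SimulationConfig(n_loci=2000, n_per_pop=20, delta_p=0.0,
                                  fst_background=0.0, ibd_slope=0.0, ld_block=0,
                                  n_host_loci=0, seed=3)
        ds = hr.simulate_metapopulation(cfg)
        labels = ds.popmap.pop_labels(ds.called_table.samples)
        assert abs(global_fst(ds.called_table.dosage, labels)) < 0.01

    def test_host_divergence_matches_delta_p(self, power_dataset):
        truth = power_dataset.truth
        host = truth.host_divergent.to_numpy()
        for site in power_dataset.popmap.sympatric_sites():
            dif = (truth[f"freq_{site}:Prunus"] - truth[f"freq_{site}:Lonicera"]).abs()
            assert abs(dif[host].mean() - 0.5) < 0.05
            assert dif[~host].max() < 1e-12   # neutral loci identical in expectation

    def test_shared_direction_consistent_across_sites(self, power_dataset):
        truth = power_dataset.truth
        shared = truth.shared.to_numpy()
        sites = power_dataset.popmap.sympatric_sites()
        signs = np.stack([
            np.sign(truth[f"freq_{s}:Prunus"] - truth[f"freq_{s}:Lonicera"])[shared]
            for s in sites])
        assert (signs == signs[0]).all()

    def test_ibd_monotone_in_distance(self):
        rhos = []
        for seed in range(10):
            cfg = hr.SimulationConfig(n_sites=4, n_sympatric=1, n_loci=300,
                                      n_per_pop=10, n_host_loci=0, ld_block=0,
                                      delta_p=0.0, fst_background=0.01,
                                      ibd_slope=2e-4, seed=seed)
            ds = hr.simulate_metapopulation(cfg)
            pm_frame = ds.popmap.frame[ds.popmap.frame.host == "Prunus"]
            pm = hr.PopulationMap(pm_frame.reset_index(drop=True))
            called = ds.called_table.subset_samples(pm.samples)
            fst = hr.pairwise_fst(called, pm)
            iu = np.triu_indices(4, k=1)
            rhos.append(spearmanr(fst.values[iu], ds.distances.values[iu]).statistic)
        assert np.mean(rhos) > 0.8

    def test_ld_block_exceeds_background(self, power_dataset):
        ds = power_dataset
        block_loci = ds.truth.locus[ds.truth.ld_member].tolist()
        samples = ds.popmap.samples_for("S1", "Prunus")
        r2b = pairwise_r2(ds.called_table, samples=samples, loci=block_loci)
        neutral = ds.truth.locus[~ds.truth.host_divergent].tolist()[:120]
        r2n = pairwise_r2(ds.called_table, samples=samples, loci=neutral)
        iu_b = np.triu_indices(len(block_loci), k=1)
        iu_n = np.triu_indices(len(neutral), k=1)
        assert np.nanmean(r2b[iu_b]) > 3.0 * np.nanmean(r2n[iu_n])

    def test_gl_estimator_recovers_truth_frequencies(self):
        cfg = hr.SimulationConfig(n_sites=1, n_sympatric=1, n_loci=600, n_per_pop=40,
                                  n_host_loci=0, ld_block=0, delta_p=0.0,
                                  mean_depth=12.0, seed=17)
        ds = hr.simulate_metapopulation(cfg)
        est = hr.estimate_allele_freq(ds.gl_table,
                                      ds.popmap.samples_for("S1", "Prunus"))
        truth_p = ds.truth["freq_S1:Prunus"].to_numpy()
        assert np.nanmean(np.abs(est.freq - truth_p)) < 0.05

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            hr.simulate_metapopulation(hr.SimulationConfig(n_host_loci=50, n_loci=10))
        with pytest.raises(ValueError):
            hr.simulate_metapopulation(hr.SimulationConfig(delta_p=1.5))
        with pytest.raises(ValueError):
            hr.simulate_metapopulation(hr.SimulationConfig(ld_block=30, n_host_loci=20))


class TestInjectArtifacts:
    def test_no_artifacts_is_identity(self, power_dataset):
        out = hr.inject_artifacts(power_dataset, 0, 0, seed=1)
        assert np.array_equal(out.called_table.dosage,
                              power_dataset.called_table.dosage, equal_nan=True)
        assert not out.truth.paralog_artifact.any()

    def test_paralogs_are_near_universally_heterozygous(self, power_dataset):
        out = hr.inject_artifacts(power_dataset, n_paralog=10, n_imbalance=0, seed=2)
        flagged = out.truth.paralog_artifact.to_numpy()
        assert flagged.sum() == 10
        for site, host in out.popmap.populations():
            sub = out.called_table.subset_samples(out.popmap.samples_for(site, host))
            d = sub.dosage[flagged]
            het = np.nanmean(d == 1.0, axis=1)
            assert (het > 0.9).all()
        # original dataset untouched
        assert not power_dataset.truth.paralog_artifact.any()

    def test_imbalance_detected_by_balance_test(self, power_dataset):
        out = hr.inject_artifacts(power_dataset, n_paralog=0, n_imbalance=10, seed=3)
        flagged = np.flatnonzero(out.truth.imbalance_artifact.to_numpy())
        rejected = 0
        for i in flagged:
            het = out.called_table.dosage[i] == 1.0
            p = allelic_balance_test(out.ref_reads[i][het].sum(),
                                     out.alt_reads[i][het].sum())
            rejected += p < 0.05
        assert rejected >= 8

    def test_too_many_artifacts_rejected(self, power_dataset):
        with pytest.raises(ValueError):
            hr.inject_artifacts(power_dataset, n_paralog=600, n_imbalance=0, seed=0)
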