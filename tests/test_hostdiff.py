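"""Genotype-likelihood allele frequencies, host permutation tests, sharing."""

import numpy as np
import pandas as pd
import pytest

import hostrace as hr
from hostrace.hostdiff import (cross_site_correlation, estimate_allele_freq,
                               host_diff_permutation_test, shared_outlier_mc)
from hostrace.tables import GenotypeLikelihoodTable, PopulationMap

from .conftest import hard_call_table
from .oracles import allele_freq_counting


class TestEstimateAlleleFreq:
    def test_reduces_to_allele_counting_on_hard_calls(self):
        gl = GenotypeLikelihoodTable(
            ["l1"], list("abcd"),
            np.array([[[1, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]], dtype=float))
        assert estimate_allele_freq(gl).freq[0] == pytest.approx(0.375, abs=0)

    def test_uniform_triplets_give_half(self):
        gl = GenotypeLikelihoodTable(["l1"], list("abc"),
                                     np.full((1, 3, 3), 1 / 3))
        assert estimate_allele_freq(gl).freq[0] == pytest.approx(0.5, abs=1e-15)

    def test_direct_evaluation_of_the_formula(self):
        gl = GenotypeLikelihoodTable(
            ["l1"], list("ab"), np.array([[[0.9, 0.1, 0.0], [0.0, 0.2, 0.8]]]))
        # (0.1 + 1.8) / 4
        assert estimate_allele_freq(gl).freq[0] == pytest.approx(0.475, abs=1e-15)

    def test_counting_equivalence_with_missing_data(self):
        gl, dosage, miss = hard_call_table(np.random.default_rng(3))
        est = estimate_allele_freq(gl)
        expected = allele_freq_counting(dosage, miss)
        assert np.allclose(est.freq, expected, atol=0, equal_nan=True)
        assert np.array_equal(est.n, (~miss).sum(axis=1))

    def test_no_data_locus_is_nan_not_zero(self):
        probs = np.full((1, 2, 3), np.nan)
        gl = GenotypeLikelihoodTable(["l1"], list("ab"), probs)
        assert np.isnan(estimate_allele_freq(gl).freq[0])


def _two_host_gl(dosage1, dosage2):
    """Build a gl table + popmap for one site from per-host dosage matrices."""
    d = np.concatenate([dosage1, dosage2], axis=1)
    L, N = d.shape
    probs = np.zeros((L, N, 3))
    for g in (0, 1, 2):
        probs[..., g] = d == g
    n1 = dosage1.shape[1]
    samples = [f"p{j}" for j in range(n1)] + [f"l{j}" for j in range(N - n1)]
    gl = GenotypeLikelihoodTable([f"l{i}" for i in range(L)], samples, probs)
    pm = PopulationMap(pd.DataFrame({
        "sample": samples, "site": ["S1"] * N,
        "host": ["Prunus"] * n1 + ["Lonicera"] * (N - n1)}))
    return gl, pm


class TestHostDiffPermutation:
    def test_identical_host_groups_never_significant(self):
        rng = np.random.default_rng(0)
        block = rng.integers(0, 3, size=(40, 8)).astype(float)
        gl, pm = _two_host_gl(block, block)   # both hosts are the same individuals
        res = host_diff_permutation_test(gl, pm, "S1", n_perm=300, seed=1)
        assert np.allclose(res.delta, 0.0)
        assert not res.significant.any()

    def test_fixed_difference_is_flagged(self):
        d1 = np.zeros((3, 6))
        d2 = np.full((3, 6), 2.0)
        d1[1:] = d2[1:] = 1.0                 # loci 1,2 identical across hosts
        gl, pm = _two_host_gl(d1, d2)
        res = host_diff_permutation_test(gl, pm, "S1", n_perm=2000, seed=2)
        assert res.delta[0] == pytest.approx(-1.0)
        assert res.significant[0]
        assert not res.significant[1:].any()

    def test_host_relabeling_flips_delta_keeps_significance(self, single_site_null):
        ds = single_site_null
        res = host_diff_permutation_test(ds.gl_table, ds.popmap, "S1",
                                         n_perm=400, seed=3)
        swapped = PopulationMap(ds.popmap.frame.copy(), hosts=("Lonicera", "Prunus"))
        res2 = host_diff_permutation_test(ds.gl_table, swapped, "S1",
                                          n_perm=400, seed=3)
        assert np.allclose(res.delta, -res2.delta, atol=1e-12)
        assert np.isclose(np.abs(res.delta), np.abs(res2.delta), atol=1e-12).all()

    def test_type_one_error_near_nominal(self, single_site_null):
        res = host_diff_permutation_test(single_site_null.gl_table,
                                         single_site_null.popmap, "S1",
                                         n_perm=1000, seed=4)
        assert 0.03 < res.significant.mean() < 0.07

    def test_power_increases_with_effect_size(self):
        powers = []
        for dp in (0.2, 0.5):
            cfg = hr.SimulationConfig(n_sites=1, n_sympatric=1, n_loci=300,
                                      n_per_pop=20, delta_p=dp, n_host_loci=30,
                                      shared_fraction=1.0, ld_block=0, seed=6)
            ds = hr.simulate_metapopulation(cfg)
            res = host_diff_permutation_test(ds.gl_table, ds.popmap, "S1",
                                             n_perm=500, seed=6)
            host = ds.truth.host_divergent.to_numpy()
            powers.append(res.significant[host].mean())
        assert powers[1] > powers[0] > 0.2

    def test_single_individual_host_rejected(self):
        gl, pm = _two_host_gl(np.zeros((2, 1)), np.ones((2, 4)))
        with pytest.raises(ValueError, match="2 individuals"):
            host_diff_permutation_test(gl, pm, "S1", n_perm=10, seed=0)


class TestCrossSiteCorrelation:
    def _result(self, site, delta, sig):
        L = len(delta)
        return hr.HostDiffResult(site_id=site, loci=np.array([f"l{i}" for i in range(L)]),
                                 delta=np.asarray(delta, float),
                                 q_low=np.full(L, -1.0), q_high=np.full(L, 1.0),
                                 significant=np.asarray(sig, bool),
                                 p_value=np.full(L, 0.5), n_perm=10, seed=0)

    def test_identical_deltas_full_agreement(self):
        rng = np.random.default_rng(1)
        delta = rng.normal(0, 0.2, 50)
        res = {"A": self._result("A", delta, delta > 0.2),
               "B": self._result("B", delta, delta > 0.2)}
        out = cross_site_correlation(res, "all").iloc[0]
        assert out.r == pytest.approx(1.0)
        assert out.percent_same_direction == pytest.approx(100.0)

    def test_negated_deltas_full_disagreement(self):
        rng = np.random.default_rng(2)
        delta = rng.normal(0, 0.2, 50)
        res = {"A": self._result("A", delta, delta > 0.2),
               "B": self._result("B", -delta, delta > 0.2)}
        out = cross_site_correlation(res, "all").iloc[0]
        assert out.r == pytest.approx(-1.0)
        assert out.percent_same_direction == pytest.approx(0.0)

    def test_significant_subset_correlates_higher_than_all(self, power_dataset):
        ds = power_dataset
        results = {site: host_diff_permutation_test(ds.gl_table, ds.popmap, site,
                                                    n_perm=500, seed=i)
                   for i, site in enumerate(ds.popmap.sympatric_sites())}
        r_all = cross_site_correlation(results, "all")["r"].mean()
        r_both = cross_site_correlation(results, "sig_both")["r"].mean()
        assert r_both > r_all

    def test_empty_subset_is_undefined(self):
        res = {"A": self._result("A", [0.1, 0.2], [False, False]),
               "B": self._result("B", [0.1, 0.2], [False, False])}
        out = cross_site_correlation(res, "sig_both").iloc[0]
        assert np.isnan(out.r) and out.n_loci == 0


class TestSharedOutlierMC:
    def test_duplicated_site_counts_match_per_site_counts(self):
        # two copies of the same site, with unambiguous loci only
        rng = np.random.default_rng(5)
        strong = np.zeros((4, 10)), np.full((4, 10), 2.0)     # fixed differences
        nulls = (rng.integers(0, 3, size=(30, 10)).astype(float),) * 2
        d1 = np.concatenate([strong[0], nulls[0]], axis=0)
        d2 = np.concatenate([strong[1], nulls[1]], axis=0)
        d = np.concatenate([d1, d2, d1, d2], axis=1)
        L, N = d.shape
        probs = np.zeros((L, N, 3))
        for g in (0, 1, 2):
            probs[..., g] = d == g
        samples = [f"s{j}" for j in range(N)]
        gl = GenotypeLikelihoodTable([f"l{i}" for i in range(L)], samples, probs)
        pm = PopulationMap(pd.DataFrame({
            "sample": samples,
            "site": ["X"] * 20 + ["Y"] * 20,
            "host": (["Prunus"] * 10 + ["Lonicera"] * 10) * 2}))
        res = shared_outlier_mc(gl, pm, n_outer=50, n_inner=400, seed=0)
        site_res = host_diff_permutation_test(gl, pm, "X", n_perm=400, seed=1)
        assert res.observed[2] == site_res.significant.sum() == 4

    def test_power_scenario_shared_by_all_exceeds_null(self, power_dataset):
        res = shared_outlier_mc(power_dataset.gl_table, power_dataset.popmap,
                                n_outer=100, n_inner=300, seed=1)
        k_max = max(res.ks)
        assert res.observed[k_max] > res.q_high[k_max]
        assert res.observed[2] >= res.observed[3] >= res.observed[4]

    def test_requires_two_sympatric_sites(self, single_site_null):
        with pytest.raises(ValueError, match="two sympatric"):
            shared_outlier_mc(single_site_null.gl_table, single_site_null.popmap,
                              n_outer=10, n_inner=10, seed=0)
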