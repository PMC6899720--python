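"""Summary statistics, Weir–Cockerham FST and Mantel machinery vs oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import hostrace as hr
from hostrace.popgen import (global_fst, mantel_test, pairwise_fst,
                             partial_mantel_test, population_summary,
                             weir_cockerham_components)
from hostrace.tables import CalledGenotypeTable, DistanceMatrix, PopulationMap

from .oracles import fst_weir_cockerham, mantel_exact_p, pearson, per_locus_summary


def _table(dosage, samples=None):
    L, N = dosage.shape
    samples = samples or [f"s{j}" for j in range(N)]
    return CalledGenotypeTable([f"l{i}" for i in range(L)], samples,
                               np.asarray(dosage, dtype=float))


def _popmap(samples, sites, hosts):
    return PopulationMap(pd.DataFrame({"sample": samples, "site": sites,
                                       "host": hosts}))


class TestPopulationSummary:
    def test_all_heterozygous_locus(self):
        # 10 individuals all het: Ho=1, He=0.5, pi=0.5*(20/19), Fis=-1
        called = _table(np.ones((1, 10)))
        pm = _popmap(called.samples, ["S1"] * 10, ["Prunus"] * 10)
        out = population_summary(called, pm).iloc[0]
        assert out.obs_het == pytest.approx(1.0)
        assert out.exp_het == pytest.approx(0.5)
        assert out.pi == pytest.approx(0.5 * 20 / 19, rel=1e-12)
        assert out.fis == pytest.approx(-1.0)

    def test_monomorphic_locus_contributes_zero_not_fis(self):
        dosage = np.vstack([np.zeros((1, 6)), np.ones((1, 6))])
        called = _table(dosage)
        pm = _popmap(called.samples, ["S1"] * 6, ["Prunus"] * 6)
        out = population_summary(called, pm).iloc[0]
        assert out.exp_het == pytest.approx(0.25)   # mean of 0 and 0.5
        assert out.fis == pytest.approx(-1.0)       # monomorphic excluded

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        dosage = rng.integers(0, 3, size=(50, 10)).astype(float)
        dosage[rng.random((50, 10)) < 0.1] = np.nan
        ok = np.isfinite(dosage).sum(axis=1) >= 2
        dosage = dosage[ok]
        called = _table(dosage)
        pm = _popmap(called.samples, ["S1"] * 10, ["Prunus"] * 10)
        out = population_summary(called, pm).iloc[0]
        ref = [per_locus_summary(row) for row in dosage]
        assert out.obs_het == pytest.approx(np.mean([r[0] for r in ref]), abs=1e-12)
        assert out.exp_het == pytest.approx(np.mean([r[1] for r in ref]), abs=1e-12)
        assert out.pi == pytest.approx(np.mean([r[2] for r in ref]), abs=1e-12)
        fis = [r[3] for r in ref if r[3] is not None]
        assert out.fis == pytest.approx(np.mean(fis), abs=1e-12)
        assert out.fis_ci_low <= out.fis <= out.fis_ci_high


class TestWeirCockerham:
    def test_hand_worked_two_population_locus(self):
        # (AA=4, Aa=2, aa=0) vs (AA=0, Aa=2, aa=4):
        # nbar=6, nc=6, pbar=1/2, s2=2/9, hbar=1/3
        # a=0.2111..., b=-0.01666..., c=1/6 -> theta=0.5846153846
        dosage = np.array([[0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2]], dtype=float)
        labels = np.array([0] * 6 + [1] * 6)
        assert global_fst(dosage, labels) == pytest.approx(0.5846153846153846,
                                                           abs=1e-12)

    def test_fixed_difference_gives_theta_one(self):
        dosage = np.array([[0, 0, 0, 2, 2, 2]], dtype=float)
        assert global_fst(dosage, np.array([0, 0, 0, 1, 1, 1])) == pytest.approx(1.0)

    def test_identically_generated_populations_near_zero(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.1, 0.9, 500)
        dosage = rng.binomial(2, p[:, None], (500, 200)).astype(float)
        theta = global_fst(dosage, np.array([0] * 100 + [1] * 100))
        assert abs(theta) < 0.02

    def test_matches_brute_force_oracle_with_missing_data(self):
        rng = np.random.default_rng(11)
        dosage = rng.integers(0, 3, size=(40, 10)).astype(float)
        dosage[rng.random((40, 10)) < 0.15] = np.nan
        labels = np.array([0] * 5 + [1] * 5)
        assert global_fst(dosage, labels) == pytest.approx(
            fst_weir_cockerham(dosage, labels), abs=1e-12)

    def test_allele_label_swap_invariance(self):
        rng = np.random.default_rng(2)
        dosage = rng.integers(0, 3, size=(30, 12)).astype(float)
        labels = np.array([0] * 6 + [1] * 6)
        assert global_fst(dosage, labels) == pytest.approx(
            global_fst(2.0 - dosage, labels), abs=1e-12)

    def test_pairwise_matrix_shape_and_symmetry(self, power_dataset):
        fst = pairwise_fst(power_dataset.called_table, power_dataset.popmap)
        v = fst.values
        assert np.allclose(v, v.T) and np.allclose(np.diag(v), 0.0)
        assert len(fst.labels) == len(power_dataset.popmap.populations())


def _random_dist(rng, labels):
    m = rng.random((len(labels), len(labels)))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(labels, m)


class TestMantel:
    def test_self_correlation_is_one(self):
        d = _random_dist(np.random.default_rng(0), list("abcde"))
        assert mantel_test(d, d, n_perm=99, seed=0).r == pytest.approx(1.0)

    def test_p_matches_exhaustive_enumeration_four_labels(self):
        rng = np.random.default_rng(3)
        d1 = _random_dist(rng, list("abcd"))
        d2 = _random_dist(rng, list("abcd"))
        exact = mantel_exact_p(d1.values, d2.values)
        # n_perm covering the full group triggers exhaustive enumeration
        res = mantel_test(d1, d2, n_perm=24, seed=1)
        assert res.n_permutations == 24
        assert res.p_value == pytest.approx(exact, abs=1e-12)

    def test_constant_matrix_rejected(self):
        labels = list("abcd")
        ones = DistanceMatrix(labels, 1 - np.eye(4))
        d = _random_dist(np.random.default_rng(0), labels)
        with pytest.raises(ValueError, match="constant"):
            mantel_test(ones, d, n_perm=9, seed=0)

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(12)
        ps = []
        for seed in range(200):
            d1 = _random_dist(rng, list("abcdefgh"))
            d2 = _random_dist(rng, list("abcdefgh"))
            ps.append(mantel_test(d1, d2, n_perm=199, seed=seed).p_value)
        assert kstest(ps, "uniform").pvalue > 0.01


class TestPartialMantel:
    def _orthogonalized(self, rng, d1, d2):
        """A control matrix whose upper triangle is exactly orthogonal to both."""
        n = len(d1.labels)
        iu = np.triu_indices(n, k=1)
        x, y = d1.values[iu], d2.values[iu]
        z = rng.random(len(x))
        basis = np.column_stack([np.ones_like(x), x, y])
        coef, *_ = np.linalg.lstsq(basis, z, rcond=None)
        z = z - basis @ coef
        m = np.zeros((n, n))
        m[iu] = z
        return DistanceMatrix(d1.labels, m + m.T)

    def test_reduces_to_simple_mantel_when_control_orthogonal(self):
        rng = np.random.default_rng(5)
        d1 = _random_dist(rng, list("abcdef"))
        d2 = _random_dist(rng, list("abcdef"))
        d3 = self._orthogonalized(rng, d1, d2)
        pr = partial_mantel_test(d1, d2, d3, n_perm=9, seed=0).r
        simple = mantel_test(d1, d2, n_perm=9, seed=0).r
        assert pr == pytest.approx(simple, abs=1e-12)

    def test_identical_matrices_give_partial_r_one(self):
        rng = np.random.default_rng(6)
        d1 = _random_dist(rng, list("abcde"))
        d3 = self._orthogonalized(rng, d1, d1)
        assert partial_mantel_test(d1, d1, d3, n_perm=9, seed=0).r \
            == pytest.approx(1.0, abs=1e-9)

    def test_matches_closed_form_five_labels(self):
        rng = np.random.default_rng(8)
        d1, d2, d3 = (_random_dist(rng, list("abcde")) for _ in range(3))
        iu = np.triu_indices(5, k=1)
        r12 = pearson(d1.values[iu], d2.values[iu])
        r13 = pearson(d1.values[iu], d3.values[iu])
        r23 = pearson(d2.values[iu], d3.values[iu])
        expected = (r12 - r13 * r23) / np.sqrt((1 - r13 ** 2) * (1 - r23 ** 2))
        assert partial_mantel_test(d1, d2, d3, n_perm=9, seed=0).r \
            == pytest.approx(expected, abs=1e-12)


class TestSampleOrderInvariance:
    def test_statistics_invariant_to_sample_order(self, power_dataset):
        called = power_dataset.called_table
        pm = power_dataset.popmap
        rng = np.random.default_rng(1)
        perm = rng.permutation(called.n_samples)
        shuffled = CalledGenotypeTable(called.loci, called.samples[perm],
                                       called.dosage[:, perm])
        a = population_summary(called, pm)
        b = population_summary(shuffled, pm)
        pd.testing.assert_frame_equal(a, b)
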