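"""Host-associated allele-frequency divergence from genotype likelihoods.

The allele-frequency estimator is the posterior-mean dosage averaged over
individuals, ``P = Σ_i Σ_j g_j p(g_j|D_i) / (2n)`` with g = (0, 1, 2); it
reduces exactly to allele counting when the probability triplets are hard
calls.  Significance of the per-locus host difference ΔP = P_host1 − P_host2
uses a label-permutation null with the empirical 0.025/0.975 quantile rule
(no multiple-testing correction, by design: the flags subset loci for the
cross-site consistency analyses).  The shared-outlier Monte Carlo reassigns
whole individuals to hosts within each site — keeping multilocus genotypes,
and hence LD among loci, intact — and asks how many significant loci would
be shared across sites by chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .tables import GenotypeLikelihoodTable, PopulationMap

# Order-statistic quantile convention: "lower" for the 0.025 and "higher"
# for the 0.975 empirical quantile keeps the two-sided exceedance rate of an
# exchangeable observation at ~0.05 for finite permutation counts.
_QLOW_METHOD = "lower"
_QHIGH_METHOD = "higher"


@dataclass
class AlleleFreqVector:
    pop_id: str
    loci: np.ndarray
    freq: np.ndarray      # NaN where no individual had data
    n: np.ndarray         # individuals contributing per locus


@dataclass
class HostDiffResult:
    site_id: str
    loci: np.ndarray
    delta: np.ndarray          # P_host1 − P_host2 per locus
    q_low: np.ndarray          # empirical 0.025 null quantile
    q_high: np.ndarray         # empirical 0.975 null quantile
    significant: np.ndarray    # delta strictly outside [q_low, q_high]
    p_value: np.ndarray        # auxiliary two-sided permutation p
    n_perm: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "locus": self.loci, "delta": self.delta, "q_low": self.q_low,
            "q_high": self.q_high, "significant": self.significant,
            "p_value": self.p_value,
        })


@dataclass
class SharedOutlierResult:
    observed: dict              # {2: count shared by >=2 sites, 3: ..., 4: ...}
    null_counts: np.ndarray     # (n_outer, len(ks))
    ks: tuple
    q_low: dict
    q_high: dict
    p_value: dict               # P(null >= observed)
    n_outer: int
    n_inner: int
    seed: int


def estimate_allele_freq(gl: GenotypeLikelihoodTable, samples=None,
                         pop_id: str = "") -> AlleleFreqVector:
    """Genotype-likelihood allele-frequency estimate per locus.

    Individuals with a missing (NaN) triplet at a locus are excluded from
    that locus's ``n``; loci with no data get NaN, not 0.
    """
    sub = gl if samples is None else gl.subset_samples(samples)
    e = sub.expected_dosage()          # (L, N)
    valid = np.isfinite(e)
    n = valid.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.nansum(np.where(valid, e, 0.0), axis=1) / (2.0 * n)
    freq[n == 0] = np.nan
    return AlleleFreqVector(pop_id=pop_id, loci=sub.loci, freq=freq, n=n)


def _group_delta(e0: np.ndarray, valid: np.ndarray,
                 a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """ΔP for group-membership weight matrices a, b of shape (N, k)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = (e0 @ a) / (2.0 * (valid @ a))
        pb = (e0 @ b) / (2.0 * (valid @ b))
    return pa - pb


def host_diff_permutation_test(gl: GenotypeLikelihoodTable, popmap: PopulationMap,
                               site: str, n_perm: int = 10000, seed: int = 0,
                               rng: np.random.Generator | None = None,
                               ) -> HostDiffResult:
    """Permutation test of host allele-frequency differences at one site."""
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    host1, host2 = popmap.hosts
    s1 = popmap.samples_for(site, host1)
    s2 = popmap.samples_for(site, host2)
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError(f"site {site}: need >= 2 individuals per host")
    pooled = np.concatenate([s1, s2])
    sub = gl.subset_samples(pooled)
    e = sub.expected_dosage()
    valid = np.isfinite(e)
    e0 = np.where(valid, e, 0.0)
    validf = valid.astype(float)
    n1 = len(s1)
    n_tot = len(pooled)

    obs_a = np.zeros((n_tot, 1))
    obs_a[:n1, 0] = 1.0
    obs_b = 1.0 - obs_a
    delta = _group_delta(e0, validf, obs_a, obs_b)[:, 0]

    if rng is None:
        rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_perm, n_tot)), axis=1)
    perm_a = (order < n1).astype(float).T          # (N, n_perm)
    null = _group_delta(e0, validf, perm_a, 1.0 - perm_a)   # (L, n_perm)

    q_low = np.quantile(null, 0.025, axis=1, method=_QLOW_METHOD)
    q_high = np.quantile(null, 0.975, axis=1, method=_QHIGH_METHOD)
    significant = (delta < q_low) | (delta > q_high)
    with np.errstate(invalid="ignore"):
        exceed = (np.abs(null) >= np.abs(delta)[:, None]).sum(axis=1)
    p = (1.0 + exceed) / (n_perm + 1.0)
    return HostDiffResult(site_id=site, loci=sub.loci, delta=delta,
                          q_low=q_low, q_high=q_high, significant=significant,
                          p_value=p, n_perm=n_perm, seed=seed)


_SUBSETS = ("all", "sig_both", "sig_ge3", "sig_all4")


def cross_site_correlation(results: dict[str, HostDiffResult],
                           subset: str = "all") -> pd.DataFrame:
    """Pairwise consistency of host differences across sympatric sites.

    For each site pair: Pearson r of the per-locus ΔP vectors over the chosen
    locus subset, the percentage of loci with the same ΔP sign (exact zeros
    excluded), and the subset size.  Subsets: ``all`` loci, ``sig_both``
    (significant at both sites of the pair), ``sig_ge3`` (significant in at
    least three sites), ``sig_all4`` (significant at every site).
    """
    if subset not in _SUBSETS:
        raise ValueError(f"subset must be one of {_SUBSETS}")
    sites = list(results)
    if len(sites) < 2:
        raise ValueError("need at least two sites")
    loci = results[sites[0]].loci
    for r in results.values():
        if not np.array_equal(r.loci, loci):
            raise ValueError("per-site results must cover the same loci")
    sig = np.stack([results[s].significant for s in sites], axis=1)
    n_sig = sig.sum(axis=1)

    rows = []
    for sa, sb in combinations(sites, 2):
        da, db = results[sa].delta, results[sb].delta
        if subset == "all":
            mask = np.ones(len(loci), dtype=bool)
        elif subset == "sig_both":
            mask = results[sa].significant & results[sb].significant
        elif subset == "sig_ge3":
            mask = n_sig >= 3
        else:
            mask = n_sig >= len(sites)
        mask = mask & np.isfinite(da) & np.isfinite(db)
        n_loci = int(mask.sum())
        if n_loci >= 2 and np.std(da[mask]) > 0 and np.std(db[mask]) > 0:
            r = float(np.corrcoef(da[mask], db[mask])[0, 1])
        else:
            r = np.nan
        nz = mask & (da != 0) & (db != 0)
        same = float(100.0 * np.mean(np.sign(da[nz]) == np.sign(db[nz]))) \
            if nz.any() else np.nan
        rows.append({"site_a": sa, "site_b": sb, "subset": subset,
                     "r": r, "percent_same_direction": same, "n_loci": n_loci})
    return pd.DataFrame(rows)


def _shared_counts(sig: np.ndarray, ks: tuple) -> np.ndarray:
    n_sig = sig.sum(axis=1)
    return np.array([(n_sig >= k).sum() for k in ks])


def shared_outlier_mc(gl: GenotypeLikelihoodTable, popmap: PopulationMap,
                      n_outer: int = 1000, n_inner: int = 1000, seed: int = 0,
                      alpha_quantiles: tuple = (0.025, 0.975),
                      ) -> SharedOutlierResult:
    """LD-preserving Monte Carlo for counts of outliers shared across sites.

    The observed counts come from the real host labels (inner permutation
    test per site).  Each of ``n_outer`` null replicates randomly reassigns
    whole individuals to hosts within each sympatric site — multilocus
    genotypes stay intact, preserving LD — and is scored with the same inner
    test, giving null distributions for the shared-by-≥k counts.
    """
    sites = popmap.sympatric_sites()
    if len(sites) < 2:
        raise ValueError("need at least two sympatric sites")
    if n_outer < 1 or n_inner < 1:
        raise ValueError("permutation counts must be positive")
    ks = tuple(k for k in (2, 3, 4) if k <= len(sites))
    rng = np.random.default_rng(seed)

    # Pre-extract per-site arrays once; inner tests then reuse them.
    site_data = {}
    host1, host2 = popmap.hosts
    for site in sites:
        s1, s2 = popmap.samples_for(site, host1), popmap.samples_for(site, host2)
        if len(s1) < 2 or len(s2) < 2:
            raise ValueError(f"site {site}: need >= 2 individuals per host")
        sub = gl.subset_samples(np.concatenate([s1, s2]))
        e = sub.expected_dosage()
        valid = np.isfinite(e)
        site_data[site] = (np.where(valid, e, 0.0), valid.astype(float), len(s1))

    def site_significance(e0, validf, n1, labels01, inner_rng):
        n_tot = e0.shape[1]
        a = np.zeros((n_tot, 1))
        a[labels01, 0] = 1.0
        delta = _group_delta(e0, validf, a, 1.0 - a)[:, 0]
        order = np.argsort(inner_rng.random((n_inner, n_tot)), axis=1)
        perm_a = (order < n1).astype(float).T
        null = _group_delta(e0, validf, perm_a, 1.0 - perm_a)
        q_low = np.quantile(null, alpha_quantiles[0], axis=1, method=_QLOW_METHOD)
        q_high = np.quantile(null, alpha_quantiles[1], axis=1, method=_QHIGH_METHOD)
        return (delta < q_low) | (delta > q_high)

    # observed: true labels (the first n1 pooled samples are host1)
    obs_sig = []
    for site in sites:
        e0, validf, n1 = site_data[site]
        obs_sig.append(site_significance(e0, validf, n1, np.arange(n1), rng))
    observed = _shared_counts(np.stack(obs_sig, axis=1), ks)

    null_counts = np.zeros((n_outer, len(ks)), dtype=int)
    for it in range(n_outer):
        rep_sig = []
        for site in sites:
            e0, validf, n1 = site_data[site]
            labels01 = rng.permutation(e0.shape[1])[:n1]
            rep_sig.append(site_significance(e0, validf, n1, labels01, rng))
        null_counts[it] = _shared_counts(np.stack(rep_sig, axis=1), ks)

    q_low, q_high, p = {}, {}, {}
    for j, k in enumerate(ks):
        q_low[k] = float(np.quantile(null_counts[:, j], alpha_quantiles[0],
                                     method=_QLOW_METHOD))
        q_high[k] = float(np.quantile(null_counts[:, j], alpha_quantiles[1],
                                      method=_QHIGH_METHOD))
        p[k] = float((1 + (null_counts[:, j] >= observed[j]).sum()) / (n_outer + 1))
    return SharedOutlierResult(observed={k: int(observed[j]) for j, k in enumerate(ks)},
                               null_counts=null_counts, ks=ks,
                               q_low=q_low, q_high=q_high, p_value=p,
                               n_outer=n_outer, n_inner=n_inner, seed=seed)
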