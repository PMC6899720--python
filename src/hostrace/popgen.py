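"""Summary statistics, Weir–Cockerham FST and (partial) Mantel tests.

Per-SNP estimators follow the usual SNP-data conventions: observed
heterozygosity Ho is the heterozygote fraction, expected heterozygosity
He = 2p(1−p), nucleotide diversity is the unbiased expected heterozygosity
π = 2p(1−p)·2n/(2n−1), and F_IS = 1 − Ho/He at polymorphic loci.  Population
differentiation uses the Weir & Cockerham (1984) θ, combined across loci by
the ratio-of-sums estimator.  Isolation by distance is tested with a Mantel
permutation test; the host effect controlling for geography with a partial
Mantel test that permutes the rows and columns of the first matrix.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import CalledGenotypeTable, DistanceMatrix, PopulationMap


@dataclass
class PopulationSummary:
    pop_id: str
    obs_het: float
    exp_het: float
    pi: float
    fis: float
    fis_ci: tuple[float, float]
    n_loci: int


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    seed: int
    partialled: bool = False
    tail: str = "greater"


def _per_locus_stats(dosage: np.ndarray) -> pd.DataFrame:
    """Ho, He, π, F_IS per locus for one population (rows = loci)."""
    ok = np.isfinite(dosage)
    n = ok.sum(axis=1).astype(float)
    if np.any(n < 1):
        raise ValueError("every locus needs at least one genotyped individual")
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(dosage, axis=1) / (2.0 * n)
        ho = np.nansum(dosage == 1.0, axis=1) / n
        he = 2.0 * p * (1.0 - p)
        pi = he * (2.0 * n) / (2.0 * n - 1.0)
        fis = np.where(he > 0, 1.0 - ho / np.where(he > 0, he, 1.0), np.nan)
    return pd.DataFrame({"p": p, "n": n, "ho": ho, "he": he, "pi": pi, "fis": fis})


def population_summary(called: CalledGenotypeTable, popmap: PopulationMap,
                       ci_level: float = 0.95) -> pd.DataFrame:
    """Across-locus mean Ho/He/π/F_IS per population with a t-based F_IS CI.

    Monomorphic loci contribute zero to the heterozygosity means but are
    excluded from the F_IS mean (F_IS is undefined without variation).
    """
    rows = []
    for site, host in popmap.populations():
        names = popmap.samples_for(site, host)
        if len(names) == 0:
            raise ValueError(f"population {site}:{host} has no samples")
        sub = called.subset_samples(names)
        per = _per_locus_stats(sub.dosage)
        fis = per["fis"].dropna()
        if len(fis) >= 2:
            half = stats.t.ppf(0.5 + ci_level / 2.0, len(fis) - 1) * fis.sem()
            ci = (fis.mean() - half, fis.mean() + half)
        else:
            ci = (np.nan, np.nan)
        rows.append(PopulationSummary(
            pop_id=f"{site}:{host}",
            obs_het=float(per["ho"].mean()),
            exp_het=float(per["he"].mean()),
            pi=float(per["pi"].mean()),
            fis=float(fis.mean()) if len(fis) else np.nan,
            fis_ci=(float(ci[0]), float(ci[1])),
            n_loci=len(per),
        ))
    frame = pd.DataFrame([r.__dict__ for r in rows])
    frame[["fis_ci_low", "fis_ci_high"]] = pd.DataFrame(frame.pop("fis_ci").tolist())
    return frame


def weir_cockerham_components(dosage: np.ndarray, labels: np.ndarray
                              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir & Cockerham (1984) variance components (a, b, c).

    ``dosage`` is (L, N); ``labels`` assigns each sample to a population.
    Loci where fewer than two populations have data get NaN components.
    """
    labels = np.asarray(labels)
    pops = list(dict.fromkeys(labels))
    L = dosage.shape[0]
    ok = np.isfinite(dosage)
    n_i = np.stack([ok[:, labels == g].sum(axis=1) for g in pops], axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = np.stack([np.nansum(dosage[:, labels == g], axis=1) for g in pops], axis=1) \
            / (2.0 * n_i)
        h_i = np.stack([(dosage[:, labels == g] == 1.0).sum(axis=1) for g in pops],
                       axis=1) / n_i

    usable = n_i >= 1
    r = usable.sum(axis=1).astype(float)
    n_i = np.where(usable, n_i, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_sum = n_i.sum(axis=1)
        nbar = n_sum / r
        nc = (n_sum - (n_i ** 2).sum(axis=1) / n_sum) / (r - 1.0)
        pbar = np.nansum(np.where(usable, n_i * p_i, 0.0), axis=1) / n_sum
        s2 = np.nansum(np.where(usable, n_i * (p_i - pbar[:, None]) ** 2, 0.0),
                       axis=1) / ((r - 1.0) * nbar)
        hbar = np.nansum(np.where(usable, n_i * h_i, 0.0), axis=1) / n_sum

        inner = pbar * (1 - pbar) - (r - 1.0) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
    bad = (r < 2) | (nbar <= 1)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def global_fst(dosage: np.ndarray, labels: np.ndarray) -> float:
    """Multi-population θ via the ratio-of-sums across loci."""
    a, b, c = weir_cockerham_components(dosage, labels)
    num = np.nansum(a)
    den = np.nansum(a + b + c)
    return float(num / den) if den != 0 else np.nan


def pairwise_fst(called: CalledGenotypeTable, popmap: PopulationMap) -> DistanceMatrix:
    """Pairwise Weir–Cockerham θ between every pair of populations."""
    pops = popmap.populations()
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    idx = {}
    for pop in pops:
        names = popmap.samples_for(*pop)
        sub_idx = called.sample_indices(names)
        if not np.isfinite(called.dosage[:, sub_idx]).any():
            raise ValueError(f"population {pop[0]}:{pop[1]} has no genotyped individuals")
        idx[pop] = sub_idx
    k = len(pops)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            cols = np.concatenate([idx[pops[i]], idx[pops[j]]])
            labels = np.array([0] * len(idx[pops[i]]) + [1] * len(idx[pops[j]]))
            theta = global_fst(called.dosage[:, cols], labels)
            out[i, j] = out[j, i] = theta
    return DistanceMatrix([f"{s}:{h}" for s, h in pops], out)


def _check_mantel_inputs(*mats: DistanceMatrix) -> None:
    labels = mats[0].labels
    for m in mats[1:]:
        if m.labels != labels:
            raise ValueError("distance matrices must share labels in the same order")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant distance matrix: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def mantel_test(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 10000,
                seed: int = 0, tail: str = "greater") -> MantelResult:
    """Mantel permutation test of matrix correlation.

    The observed statistic is the Pearson correlation of the off-diagonal
    upper triangles; the null permutes rows and columns of ``d2`` jointly.
    One-sided (positive association) by default.  When ``n_perm`` covers the
    full permutation group (small label sets) the null is enumerated
    exhaustively and the p-value is the exact fraction.
    """
    _check_mantel_inputs(d1, d2)
    n = len(d1.labels)
    if n < 3:
        raise ValueError("need at least three labels")
    x = d1.upper()
    r_obs = _pearson(x, d2.upper())
    iu = np.triu_indices(n, k=1)
    count = 0
    if math.factorial(n) <= n_perm:
        perms = list(itertools.permutations(range(n)))
        for perm in perms:
            r_p = _pearson(x, d2.values[np.ix_(perm, perm)][iu])
            if _exceeds(r_p, r_obs, tail):
                count += 1
        p = count / len(perms)
        n_perm = len(perms)
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            r_p = _pearson(x, d2.values[np.ix_(perm, perm)][iu])
            if _exceeds(r_p, r_obs, tail):
                count += 1
        p = (1.0 + count) / (n_perm + 1.0)
    return MantelResult(r=r_obs, p_value=p, n_permutations=n_perm, seed=seed, tail=tail)


def _exceeds(r_p: float, r_obs: float, tail: str) -> bool:
    if tail == "greater":
        return r_p >= r_obs
    if tail == "less":
        return r_p <= r_obs
    return abs(r_p) >= abs(r_obs)


def _partial_r(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    r12 = _pearson(x, y)
    r13 = _pearson(x, z)
    r23 = _pearson(y, z)
    if abs(r13) >= 1.0 or abs(r23) >= 1.0:
        raise ValueError("control matrix collinear with an input matrix")
    return (r12 - r13 * r23) / np.sqrt((1.0 - r13 ** 2) * (1.0 - r23 ** 2))


def partial_mantel_test(d1: DistanceMatrix, d2: DistanceMatrix, d3: DistanceMatrix,
                        n_perm: int = 10000, seed: int = 0,
                        tail: str = "greater", log_d3: bool = False) -> MantelResult:
    """Partial Mantel test of d1 ~ d2 controlling d3 (first-order partial r).

    The null permutes the rows/columns of ``d1`` while keeping the other two
    matrices fixed.  ``log_d3`` applies log(1+x) to the control (geographic)
    distances, for testing against log-transformed distance.
    """
    _check_mantel_inputs(d1, d2, d3)
    n = len(d1.labels)
    if n < 4:
        raise ValueError("need at least four labels")
    y = d2.upper()
    zvals = d3.values.copy()
    if log_d3:
        zvals = np.log1p(zvals)
    iu = np.triu_indices(n, k=1)
    z = zvals[iu]
    r_obs = _partial_r(d1.upper(), y, z)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = _partial_r(d1.values[np.ix_(perm, perm)][iu], y, z)
        if _exceeds(r_p, r_obs, tail):
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return MantelResult(r=float(r_obs), p_value=p, n_permutations=n_perm,
                        seed=seed, partialled=True, tail=tail)
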