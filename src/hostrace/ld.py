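"""Composite linkage disequilibrium (r²) and the random-draw enrichment test.

Genotypes from reduced-representation data are unphased, so LD is measured
as the composite genotypic r²: the squared Pearson correlation of alt-dosage
vectors, pairwise-complete over missing data.  The enrichment test compares
the mean pairwise r² within a focal locus set against a null of equally
sized uniform random draws from all loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables import CalledGenotypeTable


@dataclass
class LDResult:
    stratum: str
    focal: list
    mean_r2_focal: float
    mean_r2_background: float     # all-pairs mean over every locus
    mean_r2_draws: float          # mean of the null draw means
    null: np.ndarray              # (n_draws,) mean r² of random same-size draws
    q_low: float
    q_high: float
    p_value: float
    n_draws: int
    seed: int


def _r2_matrix(dosage: np.ndarray) -> np.ndarray:
    """Pairwise-complete r² between locus rows; monomorphic pairs are NaN."""
    x = np.asarray(dosage, dtype=float)
    m = np.isfinite(x)
    x0 = np.where(m, x, 0.0)
    mf = m.astype(float)
    n = mf @ mf.T
    sx = x0 @ mf.T                 # sum of locus i over samples shared with j
    sxx = (x0 * x0) @ mf.T
    sxy = x0 @ x0.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        var_i = sxx - sx ** 2 / n
        denom = var_i * var_i.T
        r2 = np.where(denom > 0, cov ** 2 / denom, np.nan)
    r2[n < 2] = np.nan
    np.fill_diagonal(r2, np.nan)
    return r2


def pairwise_r2(called: CalledGenotypeTable, samples=None, loci=None) -> np.ndarray:
    """Symmetric r² matrix over the chosen loci and samples (diagonal NaN)."""
    sub = called
    if samples is not None:
        sub = sub.subset_samples(samples)
    if loci is not None:
        sub = sub.subset_loci(loci)
    if sub.n_loci < 2:
        raise ValueError("need at least two loci")
    return _r2_matrix(sub.dosage)


def _mean_offdiag(r2: np.ndarray, idx: np.ndarray | None = None) -> float:
    block = r2 if idx is None else r2[np.ix_(idx, idx)]
    iu = np.triu_indices(block.shape[0], k=1)
    vals = block[iu]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if len(vals) else np.nan


def ld_enrichment_test(called: CalledGenotypeTable, samples=None, focal=None,
                       n_draws: int = 10000, seed: int = 0,
                       stratum: str = "") -> LDResult:
    """Is mean r² within ``focal`` loci higher than random same-size draws?

    ``p = (1 + #{null >= observed}) / (n_draws + 1)``.  Loci monomorphic in
    the sample stratum contribute undefined pairs, which are excluded from
    every mean.
    """
    focal = list(focal)
    if len(focal) < 2:
        raise ValueError("need at least two focal loci")
    if n_draws < 1:
        raise ValueError("n_draws must be positive")
    sub = called if samples is None else called.subset_samples(samples)
    r2 = _r2_matrix(sub.dosage)
    pos = {l: i for i, l in enumerate(sub.loci)}
    try:
        focal_idx = np.array([pos[l] for l in focal], dtype=int)
    except KeyError as e:
        raise KeyError(f"focal locus not in table: {e.args[0]!r}") from None

    observed = _mean_offdiag(r2, focal_idx)
    background = _mean_offdiag(r2)
    rng = np.random.default_rng(seed)
    k = len(focal_idx)
    null = np.empty(n_draws)
    for b in range(n_draws):
        draw = rng.choice(sub.n_loci, size=k, replace=False)
        null[b] = _mean_offdiag(r2, draw)
    finite = null[np.isfinite(null)]
    # ties count as exceedances (conservative); the tiny slack keeps ties
    # that differ only by floating-point summation order
    p = (1.0 + (finite >= observed - 1e-12).sum()) / (len(finite) + 1.0)
    return LDResult(stratum=stratum, focal=focal,
                    mean_r2_focal=observed, mean_r2_background=background,
                    mean_r2_draws=float(finite.mean()) if len(finite) else np.nan,
                    null=null,
                    q_low=float(np.quantile(finite, 0.025)),
                    q_high=float(np.quantile(finite, 0.975)),
                    p_value=float(p), n_draws=n_draws, seed=seed)
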