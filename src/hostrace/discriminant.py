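"""Discriminant analysis of principal components (DAPC) for host assignment.

Dosages are centred per locus (missing values mean-imputed), reduced to
``n_pcs`` principal components, and a linear discriminant with equal group
priors is fitted on the retained PCs.  Per-locus loadings are obtained by
back-projecting the discriminant weights through the PCA rotation, which
reproduces the "loads most strongly" ranking without claiming numerical
identity with any particular DAPC implementation.  Significance of host
assignment uses a label-shuffling randomisation of the mean probability of
assignment to the correct group.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .tables import CalledGenotypeTable


@dataclass
class DiscriminantModel:
    loci: np.ndarray
    samples: np.ndarray
    groups: np.ndarray            # distinct group labels, model order
    labels: np.ndarray            # per-sample group label
    n_pcs: int
    pc_scores: np.ndarray         # (N, n_pcs)
    axes: np.ndarray              # (n_pcs, n_axes) discriminant weights over PCs
    locus_loadings: np.ndarray    # (L, n_axes) back-projected loadings
    scores: np.ndarray            # (N, n_axes) discriminant scores
    proba: np.ndarray             # (N, K) assignment probabilities
    centroids: np.ndarray         # (K, n_axes)

    @property
    def n_axes(self) -> int:
        return self.axes.shape[1]

    def mean_correct_assignment(self) -> float:
        gi = {g: i for i, g in enumerate(self.groups)}
        idx = np.array([gi[l] for l in self.labels])
        return float(self.proba[np.arange(len(idx)), idx].mean())


@dataclass
class AssignmentTestResult:
    observed: float
    null: np.ndarray
    p_value: float
    n_replicates: int
    seed: int


def _prepare_matrix(called: CalledGenotypeTable) -> np.ndarray:
    """Samples-by-loci dosage matrix, mean-imputed and column-centred."""
    x = called.dosage.T.astype(float).copy()
    col_mean = np.nanmean(np.where(np.isfinite(x), x, np.nan), axis=0)
    col_mean = np.nan_to_num(col_mean, nan=0.0)
    miss = ~np.isfinite(x)
    x[miss] = np.broadcast_to(col_mean, x.shape)[miss]
    return x - col_mean


def _fit_lda(pc_scores: np.ndarray, labels: np.ndarray, groups: np.ndarray):
    priors = np.full(len(groups), 1.0 / len(groups))
    lda = LinearDiscriminantAnalysis(solver="svd", priors=priors)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collinear PCs on separable fixtures
        lda.fit(pc_scores, labels)
    return lda


def fit_discriminant(called: CalledGenotypeTable, groups, n_pcs: int) -> DiscriminantModel:
    """Fit the PCA + linear-discriminant model.

    ``groups`` is one label per sample (order of ``called.samples``).
    """
    labels = np.asarray(groups)
    if len(labels) != called.n_samples:
        raise ValueError("one group label per sample required")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least two samples")
    if not (1 <= n_pcs < called.n_samples):
        raise ValueError("need 1 <= n_pcs < number of samples")

    x = _prepare_matrix(called)
    pca = PCA(n_components=n_pcs, svd_solver="full")
    pc_scores = pca.fit_transform(x)
    lda = _fit_lda(pc_scores, labels, uniq)

    n_axes = min(len(uniq) - 1, n_pcs)
    axes = lda.scalings_[:, :n_axes]
    scores = (pc_scores - lda.xbar_) @ axes
    loadings = pca.components_.T @ axes
    proba = lda.predict_proba(pc_scores)
    centroids = np.stack([scores[labels == g].mean(axis=0) for g in uniq])
    return DiscriminantModel(loci=called.loci, samples=called.samples,
                             groups=uniq, labels=labels, n_pcs=n_pcs,
                             pc_scores=pc_scores, axes=axes,
                             locus_loadings=loadings, scores=scores,
                             proba=proba, centroids=centroids)


def assignment_permutation_test(called: CalledGenotypeTable, groups, n_pcs: int,
                                n_replicates: int = 10000, seed: int = 0,
                                ) -> AssignmentTestResult:
    """Randomisation test of the mean correct-assignment probability.

    The PCA does not depend on the labels, so each replicate refits only the
    discriminant on shuffled labels.  ``p = (1 + #{null >= obs}) / (n + 1)``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be positive")
    model = fit_discriminant(called, groups, n_pcs)
    observed = model.mean_correct_assignment()
    labels = model.labels
    gi = {g: i for i, g in enumerate(model.groups)}
    idx = np.array([gi[l] for l in labels])
    rng = np.random.default_rng(seed)
    null = np.empty(n_replicates)
    for b in range(n_replicates):
        shuffled = rng.permutation(len(labels))
        lab_b = labels[shuffled]
        lda = _fit_lda(model.pc_scores, lab_b, model.groups)
        proba = lda.predict_proba(model.pc_scores)
        cols = np.array([gi[l] for l in lab_b])
        null[b] = proba[np.arange(len(lab_b)), cols].mean()
    p = (1.0 + (null >= observed).sum()) / (n_replicates + 1.0)
    return AssignmentTestResult(observed=observed, null=null, p_value=float(p),
                                n_replicates=n_replicates, seed=seed)


def top_loading_loci(model: DiscriminantModel, axis: int = 0,
                     quantile: float = 0.99) -> list:
    """Loci whose |loading| on ``axis`` falls in the top (1 − quantile) tail.

    Returns exactly ``ceil((1 − quantile) · L)`` loci; ties are broken by
    locus order (with a warning when the loadings are degenerate).
    """
    if not (0.0 < quantile < 1.0):
        raise ValueError("quantile must lie in (0, 1)")
    if not (0 <= axis < model.n_axes):
        raise ValueError(f"axis {axis} does not exist (model has {model.n_axes})")
    load = np.abs(model.locus_loadings[:, axis])
    # round before ceil: (1 - 0.99) * 2400 is 24.000000000000021 in floats
    k = math.ceil(round((1.0 - quantile) * len(load), 9))
    order = np.argsort(-load, kind="stable")
    if k and len(np.unique(load)) == 1:
        warnings.warn("all loadings equal; top set resolved by locus order")
    return [model.loci[i] for i in sorted(order[:k])]
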