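"""Independent brute-force reference implementations used only by tests.

Deliberately written loop-by-loop and formula-by-formula, sharing no code
with the package, so the fast vectorized paths can be checked against them.
"""

import itertools
import math

import numpy as np


def fst_weir_cockerham(dosage, labels):
    """Per-locus (a, b, c) and ratio-of-sums theta, straight from the 1984 paper."""
    pops = sorted(set(labels), key=str)
    A = B = C = 0.0
    for row in dosage:
        n_i, p_i, h_i = [], [], []
        for g in pops:
            vals = [row[j] for j in range(len(labels))
                    if labels[j] == g and math.isfinite(row[j])]
            if len(vals) == 0:
                continue
            n_i.append(len(vals))
            p_i.append(sum(vals) / (2.0 * len(vals)))
            h_i.append(sum(1 for v in vals if v == 1) / len(vals))
        r = len(n_i)
        if r < 2:
            continue
        nbar = sum(n_i) / r
        if nbar <= 1:
            continue
        nc = (r * nbar - sum(n ** 2 for n in n_i) / (r * nbar)) / (r - 1)
        pbar = sum(n * p for n, p in zip(n_i, p_i)) / (r * nbar)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)
        a = nbar / nc * (s2 - 1 / (nbar - 1)
                         * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        A, B, C = A + a, B + b, C + c
    return A / (A + B + C)


def per_locus_summary(dosage_row):
    """(Ho, He, pi, Fis) for one locus of one population; Fis None if monomorphic."""
    vals = [v for v in dosage_row if math.isfinite(v)]
    n = len(vals)
    p = sum(vals) / (2.0 * n)
    ho = sum(1 for v in vals if v == 1) / n
    he = 2.0 * p * (1.0 - p)
    pi = he * (2.0 * n) / (2.0 * n - 1.0)
    fis = (1.0 - ho / he) if he > 0 else None
    return ho, he, pi, fis


def pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm ** 2).sum() * (ym ** 2).sum()))


def mantel_exact_p(m1, m2, tail="greater"):
    """Exhaustive-enumeration Mantel p over all label permutations (small n)."""
    n = m1.shape[0]
    iu = np.triu_indices(n, k=1)
    r_obs = pearson(m1[iu], m2[iu])
    count = total = 0
    for perm in itertools.permutations(range(n)):
        perm = list(perm)
        r_p = pearson(m1[iu], m2[np.ix_(perm, perm)][iu])
        total += 1
        if tail == "greater" and r_p >= r_obs:
            count += 1
        elif tail == "two-sided" and abs(r_p) >= abs(r_obs):
            count += 1
    return count / total


def r2_pairwise_complete(x_row, y_row):
    """Squared Pearson correlation over samples where both loci are genotyped."""
    pairs = [(a, b) for a, b in zip(x_row, y_row)
             if math.isfinite(a) and math.isfinite(b)]
    if len(pairs) < 2:
        return None
    xs = [a for a, _ in pairs]
    ys = [b for _, b in pairs]
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        return None
    return pearson(xs, ys) ** 2


def allele_freq_counting(dosage, missing):
    """Counting estimator over non-missing hard calls, per locus."""
    out = []
    for row, mrow in zip(dosage, missing):
        vals = [d for d, m in zip(row, mrow) if not m]
        out.append(sum(vals) / (2.0 * len(vals)) if vals else float("nan"))
    return np.array(out)
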