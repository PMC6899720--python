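"""Candidate-locus selection by intersecting independent evidence sources.

Three sources feed the intersection in the full design: an external
environment-association table (top-Bayes-factor conditioned on top-|rho|),
the strongest DAPC host-discriminant loadings, and multi-site permutation
significance.  A locus supported by at least ``min_support`` sources is a
candidate.  A self-contained two-source mode (loadings + multi-site
significance) applies when no association table is available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .hostdiff import HostDiffResult


@dataclass
class CandidateSet:
    table: pd.DataFrame        # per-locus boolean support flags + support_count
    sources: list
    min_support: int
    venn: dict                 # frozenset of source names -> exclusive cell count

    @property
    def candidates(self) -> list:
        final = self.table.loc[self.table["candidate"], "locus"]
        return list(final)


def _top_fraction(values: np.ndarray, quantile: float) -> np.ndarray:
    """Indices of the ceil((1−q)·L) largest values; stable ties by position."""
    k = math.ceil(round((1.0 - quantile) * len(values), 9))
    order = np.argsort(-values, kind="stable")
    return order[:k]


def select_top_bf_rho(table: pd.DataFrame, bf_quantile: float = 0.99,
                      rho_quantile: float = 0.90) -> set:
    """Association-table rule: top Bayes factors that are also top |rho|.

    ``table`` needs columns ``locus``, ``bayes_factor``, ``rho``.  Returns
    loci in the top (1 − bf_quantile) fraction of Bayes factors AND the top
    (1 − rho_quantile) fraction of |rho|.
    """
    for q in (bf_quantile, rho_quantile):
        if not (0.0 < q < 1.0):
            raise ValueError("quantiles must lie in (0, 1)")
    if len(table) == 0:
        return set()
    required = {"locus", "bayes_factor", "rho"}
    if not required.issubset(table.columns):
        raise ValueError(f"association table needs columns {sorted(required)}")
    if (table["bayes_factor"] < 0).any():
        raise ValueError("Bayes factors must be non-negative")
    bf = table["bayes_factor"].to_numpy(dtype=float)
    rho = np.abs(table["rho"].to_numpy(dtype=float))
    if len(np.unique(bf)) == 1:
        warnings.warn("all Bayes factors equal; top set resolved by locus order")
    loci = table["locus"].to_numpy()
    top_bf = set(loci[_top_fraction(bf, bf_quantile)])
    top_rho = set(loci[_top_fraction(rho, rho_quantile)])
    return top_bf & top_rho


def multi_site_significance(results: dict[str, HostDiffResult],
                            min_sites: int = 3) -> set:
    """Loci whose host difference is significant in at least ``min_sites`` sites."""
    if min_sites > len(results):
        raise ValueError("min_sites exceeds the number of sites")
    sites = list(results)
    loci = results[sites[0]].loci
    sig = np.stack([results[s].significant for s in sites], axis=1)
    return set(loci[sig.sum(axis=1) >= min_sites])


def intersect_evidence(sets: dict[str, set], min_support: int = 2) -> CandidateSet:
    """Per-locus support counts across named evidence sources.

    A locus is a candidate when it appears in at least ``min_support``
    sources.  The ``venn`` attribute holds exclusive cell counts for every
    source combination.
    """
    if len(sets) < 2:
        raise ValueError("need at least two evidence sources")
    if not (2 <= min_support <= len(sets)):
        raise ValueError("need 2 <= min_support <= number of sources")
    sources = list(sets)
    all_loci = sorted(set().union(*sets.values()), key=str)
    rows = []
    for locus in all_loci:
        flags = {src: locus in sets[src] for src in sources}
        count = sum(flags.values())
        rows.append({"locus": locus, **flags, "support_count": count,
                     "candidate": count >= min_support})
    table = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["locus", *sources, "support_count", "candidate"])

    venn = {}
    for r in range(1, len(sources) + 1):
        for combo in combinations(sources, r):
            inside = set.intersection(*(sets[s] for s in combo)) if combo else set()
            outside = set().union(*(sets[s] for s in sources if s not in combo)) \
                if len(combo) < len(sources) else set()
            venn[frozenset(combo)] = len(inside - outside)
    return CandidateSet(table=table, sources=sources,
                        min_support=min_support, venn=venn)
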