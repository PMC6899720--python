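"""SNP filter cascade producing the likelihood and called analysis sets.

Stages, in order: site depth/quality floor, biallelic, per-SNP missingness,
allelic balance of pooled heterozygote reads, minor-allele frequency (the
*likelihood set* stops here), then genotype-quality masking, per-population
heterozygote-excess removal (a paralog-collapse signature) and one-SNP-per-
contig thinning for the *called set*.  Every removal is attributed to the
first failing stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import binomtest

from .tables import CalledGenotypeTable, GenotypeLikelihoodTable, PopulationMap
from .vcfio import RawVariantData, read_vcf

STAGES = ("depth_quality", "biallelic", "missingness", "balance", "maf",
          "gq", "het_excess", "thin")


@dataclass
class FilterParams:
    min_total_depth: int = 50           # summed read depth over all individuals
    min_site_quality: float = 21.0      # VCF QUAL floor
    max_missing_fraction: float = 0.10  # SNP kept if called in >= 90% of samples
    balance_alpha: float = 0.05
    min_maf: float = 0.05
    min_gq: float = 15.0                # genotype-quality floor (called set)
    het_excess_alpha: float = 0.05
    thin_per_contig: bool = True

    def validate(self) -> None:
        for name in ("max_missing_fraction", "balance_alpha", "min_maf",
                     "het_excess_alpha"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.min_total_depth < 0 or self.min_gq < 0:
            raise ValueError("depth and GQ floors must be non-negative")


@dataclass
class FilterReport:
    """Per-stage retention bookkeeping plus a per-locus first-failure reason."""

    stages: pd.DataFrame = field(default_factory=pd.DataFrame)
    reasons: dict = field(default_factory=dict)

    def retained(self, stage: str) -> int:
        row = self.stages.loc[self.stages["stage"] == stage, "n_retained"]
        return int(row.iloc[0])

    def to_tsv(self, path) -> None:
        self.stages.to_csv(path, sep="\t", index=False)


def allelic_balance_test(ref_reads_in_hets: int, alt_reads_in_hets: int) -> float:
    """Exact two-sided binomial test of pooled heterozygote reads against 0.5.

    With no heterozygote reads the test is inapplicable and 1.0 is returned
    (the locus is kept).
    """
    r, a = int(ref_reads_in_hets), int(alt_reads_in_hets)
    if r < 0 or a < 0:
        raise ValueError("read counts must be non-negative")
    total = r + a
    if total == 0:
        return 1.0
    return float(binomtest(max(r, a), total, 0.5, alternative="two-sided").pvalue)


def het_excess_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy–Weinberg test, upper tail (heterozygote excess).

    Enumerates the Levene distribution of heterozygote counts compatible with
    the observed allele counts and returns P(het count >= observed).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("need at least one genotyped individual")
    nA = 2 * n_AA + n_Aa
    na = 2 * n_aa + n_Aa
    hs = np.arange(nA % 2, min(nA, na) + 1, 2)
    logw = (gammaln(n + 1) - gammaln((nA - hs) / 2 + 1) - gammaln(hs + 1)
            - gammaln((na - hs) / 2 + 1) + hs * math.log(2.0))
    w = np.exp(logw - logw.max())
    p = w[hs >= n_Aa].sum() / w.sum()
    return float(min(p, 1.0))


def _genotype_counts(dosage_row: np.ndarray) -> tuple[int, int, int]:
    ok = np.isfinite(dosage_row)
    d = dosage_row[ok]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def run_filter_cascade(raw: RawVariantData | str | Path, popmap: PopulationMap,
                       params: FilterParams | None = None,
                       ) -> tuple[GenotypeLikelihoodTable, CalledGenotypeTable, FilterReport]:
    """Apply the full cascade; returns (likelihood set, called set, report)."""
    params = params or FilterParams()
    params.validate()
    if not isinstance(raw, RawVariantData):
        raw = read_vcf(raw)
    missing_samples = [s for s in raw.samples if s not in popmap]
    if missing_samples:
        raise ValueError(f"VCF samples absent from popmap: {missing_samples[:5]}")

    L = raw.n_loci
    loci = raw.loci
    keep = np.ones(L, dtype=bool)
    reasons: dict[str, str] = {}
    rows = []

    def apply(stage: str, ok: np.ndarray) -> None:
        n_in = int(keep.sum())
        newly_removed = keep & ~ok
        for l in loci[newly_removed]:
            reasons[l] = stage
        keep[:] = keep & ok
        rows.append({"stage": stage, "n_input": n_in, "n_retained": int(keep.sum())})

    # 1. site depth and quality floor
    if raw.ref_depth is not None:
        with np.errstate(invalid="ignore"):
            total_depth = np.nansum(raw.ref_depth + raw.alt_depth, axis=1)
        depth_ok = total_depth >= params.min_total_depth
    else:
        depth_ok = np.ones(L, dtype=bool)
    qual_ok = ~(raw.qual < params.min_site_quality)   # missing QUAL passes
    apply("depth_quality", depth_ok & qual_ok)

    # 2. biallelic
    apply("biallelic", raw.n_alt == 1)

    # 3. missingness
    n_samples = len(raw.samples)
    miss_frac = np.isnan(raw.dosage).sum(axis=1) / max(n_samples, 1)
    apply("missingness", miss_frac <= params.max_missing_fraction)

    # 4. allelic balance among heterozygote reads (pooled per SNP)
    if raw.ref_depth is not None:
        het = raw.dosage == 1.0
        with np.errstate(invalid="ignore"):
            ref_het = np.nansum(np.where(het, raw.ref_depth, 0.0), axis=1)
            alt_het = np.nansum(np.where(het, raw.alt_depth, 0.0), axis=1)
        bal_ok = np.ones(L, dtype=bool)
        for i in np.flatnonzero(keep):
            bal_ok[i] = allelic_balance_test(ref_het[i], alt_het[i]) >= params.balance_alpha
        apply("balance", bal_ok)
    else:
        apply("balance", np.ones(L, dtype=bool))

    # 5. minor allele frequency
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(raw.dosage, axis=1) / 2.0
    maf = np.fmin(freq, 1.0 - freq)
    apply("maf", np.nan_to_num(maf, nan=0.0) >= params.min_maf)

    gl_keep = keep.copy()
    if raw.probs is None:
        raise ValueError("VCF lacks PL/GL fields; cannot build the likelihood set")
    likelihood_set = GenotypeLikelihoodTable(loci[gl_keep], raw.samples,
                                             raw.probs[gl_keep])

    # 6. genotype-quality masking; a SNP whose masked missingness exceeds the
    # floor is removed at this stage
    dosage = raw.dosage.copy()
    low_gq = ~np.isnan(dosage) & ~(raw.gq >= params.min_gq)
    dosage[low_gq] = np.nan
    miss_frac2 = np.isnan(dosage).sum(axis=1) / max(n_samples, 1)
    apply("gq", miss_frac2 <= params.max_missing_fraction)

    # 7. heterozygote excess, tested in each population separately
    pops = popmap.populations()
    sample_idx = {pop: np.array([i for i, s in enumerate(raw.samples)
                                 if s in set(popmap.samples_for(*pop))], dtype=int)
                  for pop in pops}
    hwe_ok = np.ones(L, dtype=bool)
    for i in np.flatnonzero(keep):
        for pop in pops:
            idx = sample_idx[pop]
            if len(idx) == 0:
                continue
            counts = _genotype_counts(dosage[i, idx])
            if sum(counts) == 0:
                continue
            if het_excess_test(*counts) < params.het_excess_alpha:
                hwe_ok[i] = False
                break
    apply("het_excess", hwe_ok)

    # 8. one SNP per RAD contig (first by position)
    if params.thin_per_contig:
        thin_ok = np.zeros(L, dtype=bool)
        best: dict[str, int] = {}
        for i in np.flatnonzero(keep):
            c = raw.contig[i]
            if c not in best or raw.pos[i] < raw.pos[best[c]]:
                best[c] = i
        thin_ok[list(best.values())] = True
        apply("thin", thin_ok | ~keep)
    else:
        apply("thin", np.ones(L, dtype=bool))

    called_set = CalledGenotypeTable(loci[keep], raw.samples, dosage[keep],
                                     raw.gq[keep], raw.contig[keep], raw.pos[keep])
    report = FilterReport(stages=pd.DataFrame(rows), reasons=reasons)
    return likelihood_set, called_set, report
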