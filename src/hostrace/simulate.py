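"""Synthetic ddRADseq metapopulations with known host-divergent loci.

The generator emulates the sampling design the downstream analyses assume:
several geographic sites, a subset of them *sympatric* (carrying fly
populations on both host plants), neutral differentiation that accumulates
with distance, a small set of host-divergent loci whose allele-frequency
shift between hosts is partly shared across sites, a block of host loci in
mutual linkage disequilibrium, and read-depth-based genotype likelihoods.

Model summary
-------------
* Ancestral allele frequencies are uniform on [0.1, 0.9].
* Site frequencies follow a Balding–Nichols stepping-stone chain along the
  site axis: site *s* drifts from site *s−1* with drift parameter
  ``fst_background + ibd_slope * gap_km``, so pairwise neutral
  differentiation grows with pairwise distance (isolation by distance).
* At a host-divergent locus the two host populations of a sympatric site are
  displaced symmetrically around the site frequency by ``±delta_p/2`` with a
  per-locus direction; "shared" loci diverge at every sympatric site with the
  same direction, the rest are private to one site.
* ``ld_block`` host loci share one per-population frequency and are emitted
  from a two-haplotype-class mixture (coupling ``ld_coupling``), which keeps
  the marginal frequency exact while inducing tunable r² among them.
* Genotypes are Hardy–Weinberg draws within population; read depth is
  Poisson(``mean_depth``); alt-read counts are binomial with per-genotype
  alt probability ``[error_rate, 0.5, 1 − error_rate]``; likelihood triplets
  are the normalized binomial likelihoods, calls their argmax.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import CalledGenotypeTable, DistanceMatrix, GenotypeLikelihoodTable, PopulationMap
from .vcfio import probs_to_pl, write_vcf

HOSTS = ("Prunus", "Lonicera")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic metapopulation.

    Defaults are the standard power scenario used throughout the test
    suite: four sympatric sites, 20 diploids per population, 2,000 loci of
    which 20 are host-divergent at all sites (17 of them haplotype-coupled),
    a host allele-frequency displacement of 0.5, and mean read depth 9.74.
    """

    n_sites: int = 4
    n_sympatric: int = 4            # first n_sympatric sites carry both hosts
    n_per_pop: int = 20             # diploid individuals per (site, host) population
    n_loci: int = 2000
    n_host_loci: int = 20
    delta_p: float = 0.5            # host allele-frequency displacement at divergent loci
    shared_fraction: float = 1.0    # fraction of host loci divergent at all sympatric sites
    fst_background: float = 0.02    # per-step drift parameter
    ibd_slope: float = 5e-5         # extra drift per km of between-site gap
    site_spacing_km: float = 250.0
    ld_block: int = 17              # host loci emitted from the coupled-haplotype mixture
    ld_coupling: float = 0.9
    mean_depth: float = 9.74
    error_rate: float = 0.01
    seed: int = 0
    loci_per_contig: int = 1
    hosts: tuple[str, str] = HOSTS

    def validate(self) -> None:
        if not (0 < self.n_sympatric <= self.n_sites):
            raise ValueError("need 1 <= n_sympatric <= n_sites")
        for name in ("n_per_pop", "n_loci"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.n_host_loci <= self.n_loci):
            raise ValueError("n_host_loci must lie in [0, n_loci]")
        if not (0 <= self.ld_block <= max(self.n_host_loci, 0)):
            raise ValueError("ld_block must lie in [0, n_host_loci]")
        for name in ("delta_p", "shared_fraction", "fst_background", "error_rate",
                     "ld_coupling"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.error_rate >= 0.5:
            raise ValueError("error_rate must be < 0.5")
        if self.ibd_slope < 0 or self.mean_depth < 0:
            raise ValueError("ibd_slope and mean_depth must be non-negative")
        if self.loci_per_contig < 1:
            raise ValueError("loci_per_contig must be >= 1")


@dataclass
class SyntheticDataset:
    """A simulated metapopulation with ground truth and read-level detail."""

    config: SimulationConfig
    truth: pd.DataFrame
    gl_table: GenotypeLikelihoodTable
    called_table: CalledGenotypeTable
    popmap: PopulationMap
    distances: DistanceMatrix
    depth: np.ndarray       # (L, N) reads per genotype
    ref_reads: np.ndarray   # (L, N)
    alt_reads: np.ndarray   # (L, N)
    qual: np.ndarray        # (L,) site quality

    def copy(self) -> "SyntheticDataset":
        return SyntheticDataset(
            config=dataclasses.replace(self.config),
            truth=self.truth.copy(),
            gl_table=GenotypeLikelihoodTable(self.gl_table.loci.copy(),
                                             self.gl_table.samples.copy(),
                                             self.gl_table.probs.copy()),
            called_table=CalledGenotypeTable(self.called_table.loci.copy(),
                                             self.called_table.samples.copy(),
                                             self.called_table.dosage.copy(),
                                             None if self.called_table.gq is None
                                             else self.called_table.gq.copy(),
                                             self.called_table.contig.copy(),
                                             self.called_table.pos.copy()),
            popmap=PopulationMap(self.popmap.frame.copy(), self.popmap.hosts),
            distances=DistanceMatrix(list(self.distances.labels), self.distances.values.copy()),
            depth=self.depth.copy(),
            ref_reads=self.ref_reads.copy(),
            alt_reads=self.alt_reads.copy(),
            qual=self.qual.copy(),
        )

    def write(self, outdir) -> dict[str, Path]:
        """Emit VCF + popmap/distance/truth TSVs; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "variants.vcf",
            "popmap": outdir / "popmap.tsv",
            "distances": outdir / "distances.tsv",
            "truth": outdir / "truth.tsv",
        }
        pl = probs_to_pl(np.nan_to_num(self.gl_table.probs, nan=1 / 3))
        write_vcf(paths["vcf"],
                  samples=self.gl_table.samples,
                  contig=self.called_table.contig,
                  pos=self.called_table.pos,
                  qual=self.qual,
                  dosage=self.called_table.dosage,
                  gq=self.called_table.gq,
                  pl=pl,
                  ref_depth=self.ref_reads,
                  alt_depth=self.alt_reads)
        self.popmap.to_tsv(paths["popmap"])
        self.distances.to_tsv(paths["distances"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, fst: float) -> np.ndarray:
    """Draw drifted frequencies around ``p`` with target differentiation ``fst``."""
    if fst <= 0:
        return p.copy()
    p = np.clip(p, 1e-6, 1 - 1e-6)
    scale = (1.0 - fst) / fst
    return rng.beta(p * scale, (1.0 - p) * scale)


def read_likelihoods(alt_reads: np.ndarray, depth: np.ndarray,
                     error_rate: float) -> np.ndarray:
    """Normalized genotype-probability triplets from alt-read counts.

    The per-read alt probability under dosage g in {0,1,2} is
    ``[error_rate, 0.5, 1 − error_rate]``; the binomial coefficient cancels
    in the normalization.  Zero depth yields the uninformative (1/3,1/3,1/3).
    """
    k = np.asarray(alt_reads, dtype=float)
    d = np.asarray(depth, dtype=float)
    q = np.array([error_rate, 0.5, 1.0 - error_rate])
    with np.errstate(divide="ignore", invalid="ignore"):
        loglik = (k[..., None] * np.log(q) + (d - k)[..., None] * np.log1p(-q))
        loglik = np.where(k[..., None] == 0, (d - k)[..., None] * np.log1p(-q), loglik)
        loglik = np.where((d - k)[..., None] == 0, k[..., None] * np.log(q), loglik)
        loglik = np.where(d[..., None] == 0, 0.0, loglik)
    loglik -= loglik.max(axis=-1, keepdims=True)
    lik = np.exp(loglik)
    return lik / lik.sum(axis=-1, keepdims=True)


def genotype_to_likelihoods(alt_dosage: int, depth: int, error_rate: float,
                            seed: int) -> np.ndarray:
    """Simulate reads for one genotype and return its likelihood triplet."""
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not (0.0 <= error_rate < 0.5):
        raise ValueError("error_rate must lie in [0, 0.5)")
    if alt_dosage not in (0, 1, 2):
        raise ValueError("alt_dosage must be 0, 1 or 2")
    rng = np.random.default_rng(seed)
    q = (error_rate, 0.5, 1.0 - error_rate)[alt_dosage]
    k = rng.binomial(depth, q) if depth > 0 else 0
    return read_likelihoods(np.array(k), np.array(depth), error_rate)


def _calls_from_probs(probs: np.ndarray, depth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-probability genotype calls and phred GQ; zero depth is missing."""
    best = probs.argmax(axis=-1).astype(float)
    pbest = probs.max(axis=-1)
    gq = np.minimum(np.rint(-10.0 * np.log10(np.clip(1.0 - pbest, 1e-10, None))), 99.0)
    missing = depth == 0
    best[missing] = np.nan
    gq[missing] = np.nan
    return best, gq


def simulate_metapopulation(config: SimulationConfig) -> SyntheticDataset:
    """Generate a :class:`SyntheticDataset`; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.n_loci
    sites = [f"S{i + 1}" for i in range(config.n_sites)]
    sympatric = sites[: config.n_sympatric]
    positions = np.arange(config.n_sites) * config.site_spacing_km
    dist = np.abs(positions[:, None] - positions[None, :])
    distances = DistanceMatrix(sites, dist)

    # --- per-site neutral frequencies (stepping-stone drift chain) ---
    p0 = rng.uniform(0.1, 0.9, size=L)
    p_site = np.empty((config.n_sites, L))
    p_site[0] = _balding_nichols(rng, p0, config.fst_background)
    for s in range(1, config.n_sites):
        gap = positions[s] - positions[s - 1]
        f_step = config.fst_background + config.ibd_slope * gap
        p_site[s] = _balding_nichols(rng, p_site[s - 1], min(f_step, 0.999))

    # --- host-divergent loci ---
    host_idx = np.sort(rng.choice(L, size=config.n_host_loci, replace=False))
    n_shared = int(round(config.shared_fraction * config.n_host_loci))
    shared_idx = host_idx[:n_shared]
    private_idx = host_idx[n_shared:]
    direction = np.zeros(L, dtype=int)
    direction[shared_idx] = rng.choice([-1, 1], size=len(shared_idx))
    private_site = {}
    for l in private_idx:
        private_site[l] = rng.choice(len(sympatric))
        direction[l] = rng.choice([-1, 1])
    block_idx = shared_idx[: config.ld_block] if len(shared_idx) >= config.ld_block \
        else host_idx[: config.ld_block]
    direction[block_idx] = 1  # a haplotype block shifts as a unit

    # populations: both hosts at sympatric sites, Prunus elsewhere
    populations: list[tuple[str, str]] = []
    for s, site in enumerate(sites):
        populations.append((site, config.hosts[0]))
        if site in sympatric:
            populations.append((site, config.hosts[1]))

    half = config.delta_p / 2.0
    eps = 0.01
    pop_freq: dict[tuple[str, str], np.ndarray] = {}
    for site, host in populations:
        s = sites.index(site)
        p = p_site[s].copy()
        if site in sympatric and config.delta_p > 0 and config.n_host_loci:
            div = list(shared_idx) + [l for l in private_idx
                                      if private_site[l] == sympatric.index(site)]
            div = np.array(sorted(div), dtype=int)
            if len(div):
                lo, hi = min(half + eps, 0.5), max(1.0 - half - eps, 0.5)
                centre = np.clip(p_site[s, div], lo, hi)
                sign = 1.0 if host == config.hosts[0] else -1.0
                p[div] = np.clip(centre + sign * direction[div] * half, 0.0, 1.0)
        pop_freq[(site, host)] = p

    # Block loci share one frequency per population so the haplotype mixture
    # gives them identical marginals and strong mutual LD.  The block is
    # pinned to an intermediate centre (0.5 ± delta_p/2 between hosts) so
    # that it stays polymorphic — and its LD measurable — within each host.
    if len(block_idx) >= 2:
        for site, host in pop_freq:
            if site in sympatric and config.delta_p > 0:
                sign = 1.0 if host == config.hosts[0] else -1.0
                pop_freq[(site, host)][block_idx] = 0.5 + sign * half
            else:
                pop_freq[(site, host)][block_idx] = 0.5

    # --- genotypes ---
    sample_names, site_col, host_col = [], [], []
    dosage_cols = []
    for site, host in populations:
        n = config.n_per_pop
        p = pop_freq[(site, host)]
        dos = rng.binomial(2, np.broadcast_to(p[:, None], (L, n))).astype(float)
        if len(block_idx) >= 2:
            pi = float(p[block_idx[0]])
            q1 = pi + config.ld_coupling * (1.0 - pi)
            q0 = pi * (1.0 - config.ld_coupling)
            z = rng.random((2, n)) < pi                       # haplotype classes
            qhap = np.where(z, q1, q0)                        # (2, n)
            alleles = rng.random((len(block_idx), 2, n)) < qhap[None, :, :]
            dos[block_idx] = alleles.sum(axis=1).astype(float)
        dosage_cols.append(dos)
        tag = "P" if host == config.hosts[0] else "L"
        sample_names += [f"{site}{tag}{i + 1:02d}" for i in range(n)]
        site_col += [site] * n
        host_col += [host] * n
    true_dosage = np.concatenate(dosage_cols, axis=1)
    samples = np.array(sample_names, dtype=object)
    N = len(samples)

    popmap = PopulationMap(pd.DataFrame({"sample": sample_names,
                                         "site": site_col, "host": host_col}),
                           hosts=config.hosts)

    # --- reads, likelihoods, calls ---
    depth = rng.poisson(config.mean_depth, size=(L, N))
    qg = np.array([config.error_rate, 0.5, 1.0 - config.error_rate])
    alt_reads = rng.binomial(depth, qg[true_dosage.astype(int)])
    ref_reads = depth - alt_reads
    probs = read_likelihoods(alt_reads, depth, config.error_rate)
    called, gq = _calls_from_probs(probs, depth)
    qual = np.full(L, 50.0)

    k = config.loci_per_contig
    contig = np.array([f"ctg{i // k:06d}" for i in range(L)], dtype=object)
    pos = np.array([100 * (i % k + 1) for i in range(L)], dtype=int)
    loci = np.array([f"{c}:{p}" for c, p in zip(contig, pos)], dtype=object)

    truth = pd.DataFrame({
        "locus": loci,
        "contig": contig,
        "pos": pos,
        "ancestral_freq": p0,
        "host_divergent": np.isin(np.arange(L), host_idx),
        "shared": np.isin(np.arange(L), shared_idx),
        "ld_member": np.isin(np.arange(L), block_idx),
        "paralog_artifact": False,
        "imbalance_artifact": False,
        "direction": direction,
    })
    for site, host in populations:
        truth[f"freq_{site}:{host}"] = pop_freq[(site, host)]

    gl_table = GenotypeLikelihoodTable(loci, samples, probs)
    called_table = CalledGenotypeTable(loci, samples, called, gq, contig, pos)
    return SyntheticDataset(config=config, truth=truth, gl_table=gl_table,
                            called_table=called_table, popmap=popmap,
                            distances=distances, depth=depth,
                            ref_reads=ref_reads, alt_reads=alt_reads, qual=qual)


def inject_artifacts(dataset: SyntheticDataset, n_paralog: int, n_imbalance: int,
                     seed: int, het_alt_fraction: float = 0.3) -> SyntheticDataset:
    """Plant filterable artifacts into a copy of ``dataset``.

    Paralog-collapse artifacts become heterozygous in every individual with
    covering reads (balanced read counts, certain-het likelihoods); allelic-
    imbalance artifacts keep their calls but have the alt-read fraction of
    heterozygotes skewed to ``het_alt_fraction``.
    """
    if n_paralog < 0 or n_imbalance < 0:
        raise ValueError("artifact counts must be non-negative")
    out = dataset.copy()
    L = out.gl_table.n_loci
    free = np.flatnonzero(~(out.truth["host_divergent"]
                            | out.truth["paralog_artifact"]
                            | out.truth["imbalance_artifact"]).to_numpy())
    if n_paralog + n_imbalance > len(free):
        raise ValueError("not enough unflagged loci for the requested artifacts")
    if n_paralog + n_imbalance == 0:
        return out
    rng = np.random.default_rng(seed)
    chosen = rng.choice(free, size=n_paralog + n_imbalance, replace=False)
    par, imb = np.sort(chosen[:n_paralog]), np.sort(chosen[n_paralog:])

    covered = out.depth[par] > 0
    out.called_table.dosage[par] = np.where(covered, 1.0, np.nan)
    out.called_table.gq[par] = np.where(covered, 99.0, np.nan)
    tri = np.where(covered[..., None],
                   np.array([0.0, 1.0, 0.0]), np.full(3, 1 / 3))
    out.gl_table.probs[par] = tri
    out.alt_reads[par] = out.depth[par] // 2
    out.ref_reads[par] = out.depth[par] - out.alt_reads[par]
    out.truth.loc[par, "paralog_artifact"] = True

    het = out.called_table.dosage[imb] == 1.0
    skew = rng.binomial(out.depth[imb], het_alt_fraction)
    out.alt_reads[imb] = np.where(het, skew, out.alt_reads[imb])
    out.ref_reads[imb] = out.depth[imb] - out.alt_reads[imb]
    out.truth.loc[imb, "imbalance_artifact"] = True
    return out


def make_filter_fixture(outdir, n_samples: int = 40) -> dict:
    """Write a 100-locus VCF with ten known failures per early filter stage.

    Loci 0–9 are triallelic, 10–19 exceed 10% missingness, 20–29 fail the
    allelic-balance test (pooled heterozygote reads skewed 8:2), 30–39 fail
    MAF < 0.05 (one heterozygote), and 40–99 pass every stage.  Returns the
    paths plus the per-stage composition by construction.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    L, N = 100, n_samples
    samples = [f"X{i + 1:02d}" for i in range(N)]
    dosage = np.zeros((L, N))
    gq = np.full((L, N), 99.0)
    ref_d = np.full((L, N), 10.0)
    alt_d = np.zeros((L, N))
    alt = ["C"] * L

    for i in range(0, 10):           # triallelic
        alt[i] = "C,T"
        dosage[i, : N // 2] = 1.0
        ref_d[i], alt_d[i] = 5.0, 5.0
    for i in range(10, 20):          # missingness 20%
        miss = slice(0, max(1, int(np.ceil(0.2 * N))))
        dosage[i, miss] = np.nan
        gq[i, miss] = np.nan
        ref_d[i, miss] = np.nan
        alt_d[i, miss] = np.nan
        dosage[i, N // 2:] = 1.0
        ref_d[i, N // 2:], alt_d[i, N // 2:] = 5.0, 5.0
    for i in range(20, 30):          # allelic imbalance in hets
        dosage[i, : N // 2] = 1.0
        ref_d[i, : N // 2], alt_d[i, : N // 2] = 8.0, 2.0
    for i in range(30, 40):          # MAF below 0.05
        dosage[i, 0] = 1.0
        ref_d[i, 0], alt_d[i, 0] = 5.0, 5.0
    for i in range(40, 100):         # clean: HW-ish 10/20/10 pattern
        dosage[i, : N // 4] = 0.0
        dosage[i, N // 4: 3 * N // 4] = 1.0
        dosage[i, 3 * N // 4:] = 2.0
        ref_d[i, N // 4: 3 * N // 4] = 5.0
        alt_d[i, N // 4: 3 * N // 4] = 5.0
        ref_d[i, 3 * N // 4:] = 0.0
        alt_d[i, 3 * N // 4:] = 10.0

    tri = np.zeros((L, N, 3))
    for g in (0, 1, 2):
        tri[..., g] = (dosage == g)
    tri[np.isnan(dosage)] = 1 / 3
    pl = probs_to_pl(tri)

    contig = np.array([f"fix{i:04d}" for i in range(L)], dtype=object)
    pos = np.full(L, 100, dtype=int)
    vcf = outdir / "fixture.vcf"
    write_vcf(vcf, samples=samples, contig=contig, pos=pos,
              qual=np.full(L, 50.0), dosage=dosage, gq=gq, pl=pl,
              ref_depth=ref_d, alt_depth=alt_d, alt=alt)
    popmap = outdir / "popmap.tsv"
    pd.DataFrame({"sample": samples,
                  "site": ["S1"] * N,
                  "host": [HOSTS[0]] * (N // 2) + [HOSTS[1]] * (N - N // 2)}
                 ).to_csv(popmap, sep="\t", index=False)
    return {"vcf": vcf, "popmap": popmap,
            "composition": {"triallelic": 10, "missingness": 10,
                            "balance": 10, "maf": 10, "clean": 60}}
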