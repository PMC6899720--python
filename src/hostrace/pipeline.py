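"""End-to-end orchestration: inputs (VCF + popmap or simulation) to reports.

``run_pipeline`` sequences the full analysis — filter cascade, summary
statistics and FST, isolation-by-distance and partial Mantel tests, per-site
host permutation tests, cross-site consistency, the LD-preserving
shared-outlier Monte Carlo, the host DAPC with assignment randomisation,
candidate intersection, and LD enrichment — writing TSV reports plus a
machine-readable manifest of seeds and parameters.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .candidates import intersect_evidence, multi_site_significance, select_top_bf_rho
from .discriminant import assignment_permutation_test, fit_discriminant, top_loading_loci
from .filtering import FilterParams, run_filter_cascade
from .hostdiff import cross_site_correlation, host_diff_permutation_test, shared_outlier_mc
from .ld import ld_enrichment_test
from .popgen import mantel_test, pairwise_fst, partial_mantel_test, population_summary
from .simulate import SimulationConfig, simulate_metapopulation
from .tables import CalledGenotypeTable, DistanceMatrix, GenotypeLikelihoodTable, PopulationMap
from .vcfio import RawVariantData, read_vcf


@dataclass
class PipelineConfig:
    """Inputs, stage parameters and seeds for one pipeline run.

    Exactly one of ``simulation`` or ``vcf``+``popmap`` must be given.
    """

    simulation: SimulationConfig | None = None
    vcf: str | None = None
    popmap: str | None = None
    distances: str | None = None
    association_table: str | None = None

    filter_params: FilterParams = field(default_factory=FilterParams)
    n_perm_hostdiff: int = 1000
    mc_outer: int = 200
    mc_inner: int = 500
    n_pcs: int = 10
    dapc_replicates: int = 1000
    loading_quantile: float = 0.99
    bf_quantile: float = 0.99
    rho_quantile: float = 0.90
    min_sites: int = 3
    min_support: int = 2
    ld_draws: int = 2000
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        sim = self.simulation is not None
        files = self.vcf is not None and self.popmap is not None
        if sim == files:
            raise ValueError("provide either a SimulationConfig or VCF+popmap paths")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "simulation" in raw and raw["simulation"] is not None:
            raw["simulation"] = SimulationConfig(**raw["simulation"])
        if "filter_params" in raw:
            raw["filter_params"] = FilterParams(**raw["filter_params"])
        return cls(**raw)


@dataclass
class PipelineResult:
    config: PipelineConfig
    truth: pd.DataFrame | None
    filter_report: object
    summary: pd.DataFrame
    fst: object
    mantel_ibd: object | None
    partial_mantel: object | None
    hostdiff: dict
    cross_site: pd.DataFrame
    shared: object
    dapc: object
    assignment: object
    candidate_set: object
    ld_results: list
    seeds: dict

    @property
    def candidates(self) -> list:
        return self.candidate_set.candidates


def read_inputs(vcf_path, popmap_path, distances_path=None,
                hosts: tuple[str, str] = ("Prunus", "Lonicera")):
    """Parse VCF + popmap (+ distances) into analysis tables.

    PL fields become probability triplets via ``p(g) ∝ 10^(−PL/10)``; GT/GQ
    become dosage calls.  Returns (gl_table, called_table, popmap, distances);
    ``gl_table`` is None (with a warning in the caller's log) when the VCF
    carries neither PL nor GL.
    """
    raw = read_vcf(vcf_path)
    popmap = PopulationMap.from_tsv(popmap_path, hosts=hosts)
    missing = [s for s in raw.samples if s not in popmap]
    if missing:
        raise ValueError(f"VCF samples absent from popmap: {missing[:5]}")
    loci = raw.loci
    gl = None
    if raw.probs is not None:
        gl = GenotypeLikelihoodTable(loci, raw.samples, raw.probs)
    called = CalledGenotypeTable(loci, raw.samples, raw.dosage, raw.gq,
                                 raw.contig, raw.pos)
    dist = DistanceMatrix.from_tsv(distances_path) if distances_path else None
    return gl, called, popmap, dist


def drop_monomorphic(called: CalledGenotypeTable) -> CalledGenotypeTable:
    """Remove loci without variation in the current sample subset."""
    freq = called.allele_frequencies()
    poly = np.isfinite(freq) & (freq > 0) & (freq < 1)
    return called.subset_loci(poly)


def _raw_from_dataset(ds) -> RawVariantData:
    L = ds.gl_table.n_loci
    return RawVariantData(
        samples=ds.gl_table.samples,
        contig=ds.called_table.contig,
        pos=ds.called_table.pos,
        qual=ds.qual,
        n_alt=np.ones(L, dtype=int),
        dosage=ds.called_table.dosage.copy(),
        gq=ds.called_table.gq.copy(),
        probs=ds.gl_table.probs.copy(),
        ref_depth=ds.ref_reads.astype(float),
        alt_depth=ds.alt_reads.astype(float),
    )


def _host_distance(pops: list[tuple[str, str]]) -> DistanceMatrix:
    vals = np.array([[0.0 if h1 == h2 else 1.0 for (_, h2) in pops]
                     for (_, h1) in pops])
    return DistanceMatrix([f"{s}:{h}" for s, h in pops], vals)


def _geo_distance(pops: list[tuple[str, str]], site_dist: DistanceMatrix) -> DistanceMatrix:
    idx = {s: i for i, s in enumerate(site_dist.labels)}
    vals = np.array([[site_dist.values[idx[s1], idx[s2]] for (s2, _) in pops]
                     for (s1, _) in pops])
    return DistanceMatrix([f"{s}:{h}" for s, h in pops], vals)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and (optionally) write the report bundle."""
    config.validate()
    seed_rng = np.random.default_rng(config.seed)
    seeds: dict[str, int] = {}

    def stage_seed(name: str) -> int:
        seeds[name] = int(seed_rng.integers(2 ** 31))
        return seeds[name]

    # --- inputs ---
    truth = None
    distances = None
    if config.simulation is not None:
        ds = simulate_metapopulation(config.simulation)
        raw, popmap, distances, truth = _raw_from_dataset(ds), ds.popmap, ds.distances, ds.truth
    else:
        raw = read_vcf(config.vcf)
        popmap = PopulationMap.from_tsv(config.popmap)
        if config.distances:
            distances = DistanceMatrix.from_tsv(config.distances)

    # --- filtering ---
    gl_set, called_set, report = run_filter_cascade(raw, popmap, config.filter_params)

    # --- summary statistics, FST, Mantel ---
    summary = population_summary(called_set, popmap)
    fst = pairwise_fst(called_set, popmap)
    mantel_ibd = None
    pmantel = None
    if distances is not None and len(popmap.sites) >= 3:
        site_map = PopulationMap(popmap.frame.assign(host=popmap.hosts[0]),
                                 hosts=popmap.hosts)
        site_fst = pairwise_fst(called_set, site_map)
        site_fst.labels = [l.split(":")[0] for l in site_fst.labels]
        geo = distances.reorder(site_fst.labels)
        mantel_ibd = mantel_test(site_fst, geo, n_perm=config.n_perm_hostdiff,
                                 seed=stage_seed("mantel_ibd"))
    sympatric = popmap.sympatric_sites()
    symp_samples = np.concatenate([popmap.samples_for(site) for site in sympatric]) \
        if sympatric else np.array([], dtype=object)
    if distances is not None and len(sympatric) >= 2:
        symp_map = PopulationMap(
            popmap.frame[popmap.frame["site"].isin(sympatric)].reset_index(drop=True),
            hosts=popmap.hosts)
        symp_called = drop_monomorphic(called_set.subset_samples(symp_map.samples))
        pops = symp_map.populations()
        fst_symp = pairwise_fst(symp_called, symp_map)
        pmantel = partial_mantel_test(fst_symp, _host_distance(pops),
                                      _geo_distance(pops, distances),
                                      n_perm=config.n_perm_hostdiff,
                                      seed=stage_seed("partial_mantel"))

    # --- per-site host permutation tests (likelihood set) ---
    hostdiff = {}
    for site in sympatric:
        hostdiff[site] = host_diff_permutation_test(
            gl_set, popmap, site, n_perm=config.n_perm_hostdiff,
            seed=stage_seed(f"hostdiff_{site}"))
    cross = pd.concat([cross_site_correlation(hostdiff, subset=s)
                       for s in ("all", "sig_both", "sig_ge3", "sig_all4")],
                      ignore_index=True) if len(hostdiff) >= 2 else pd.DataFrame()

    # --- shared-outlier Monte Carlo ---
    shared = shared_outlier_mc(gl_set, popmap, n_outer=config.mc_outer,
                               n_inner=config.mc_inner,
                               seed=stage_seed("shared_mc")) \
        if len(sympatric) >= 2 else None

    # --- host DAPC on the sympatric called genotypes ---
    symp_called = drop_monomorphic(called_set.subset_samples(symp_samples))
    host_labels = np.array([popmap.frame.set_index("sample").loc[s, "host"]
                            for s in symp_samples], dtype=object)
    n_pcs = min(config.n_pcs, len(symp_samples) - 1, symp_called.n_loci)
    dapc = fit_discriminant(symp_called, host_labels, n_pcs=n_pcs)
    assignment = assignment_permutation_test(
        symp_called, host_labels, n_pcs=n_pcs,
        n_replicates=config.dapc_replicates, seed=stage_seed("assignment"))

    # --- candidate intersection ---
    evidence = {
        "dapc": set(top_loading_loci(dapc, axis=0, quantile=config.loading_quantile)),
        "multisite": multi_site_significance(hostdiff, min_sites=config.min_sites),
    }
    if config.association_table:
        assoc = pd.read_csv(config.association_table, sep="\t")
        evidence["association"] = select_top_bf_rho(
            assoc, bf_quantile=config.bf_quantile, rho_quantile=config.rho_quantile)
    candidate_set = intersect_evidence(evidence, min_support=config.min_support)

    # --- LD enrichment per stratum ---
    ld_results = []
    focal = [l for l in candidate_set.candidates if l in set(symp_called.loci)]
    if len(focal) >= 2:
        for site in sympatric:
            strata = {f"{site}:pooled": popmap.samples_for(site)}
            for host in popmap.hosts:
                strata[f"{site}:{host}"] = popmap.samples_for(site, host)
            for name, names in strata.items():
                ld_results.append(ld_enrichment_test(
                    symp_called, samples=names, focal=focal,
                    n_draws=config.ld_draws,
                    seed=stage_seed(f"ld_{name}"), stratum=name))

    result = PipelineResult(config=config, truth=truth, filter_report=report,
                            summary=summary, fst=fst, mantel_ibd=mantel_ibd,
                            partial_mantel=pmantel, hostdiff=hostdiff,
                            cross_site=cross, shared=shared, dapc=dapc,
                            assignment=assignment, candidate_set=candidate_set,
                            ld_results=ld_results, seeds=seeds)
    if config.outdir:
        _write_reports(result, Path(config.outdir))
    return result


def _write_reports(res: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    res.filter_report.to_tsv(outdir / "filter_report.tsv")
    res.summary.to_csv(outdir / "population_summary.tsv", sep="\t", index=False)
    res.fst.to_tsv(outdir / "pairwise_fst.tsv")
    for site, hd in res.hostdiff.items():
        hd.to_frame().to_csv(outdir / f"hostdiff_{site}.tsv", sep="\t", index=False)
    if len(res.cross_site):
        res.cross_site.to_csv(outdir / "cross_site_correlation.tsv", sep="\t", index=False)
    if res.shared is not None:
        pd.DataFrame({
            "shared_by_at_least": list(res.shared.observed),
            "observed": list(res.shared.observed.values()),
            "null_q025": [res.shared.q_low[k] for k in res.shared.observed],
            "null_q975": [res.shared.q_high[k] for k in res.shared.observed],
            "p_value": [res.shared.p_value[k] for k in res.shared.observed],
        }).to_csv(outdir / "shared_outliers.tsv", sep="\t", index=False)
    pd.DataFrame({"locus": res.dapc.loci,
                  "loading_axis1": res.dapc.locus_loadings[:, 0]}
                 ).to_csv(outdir / "dapc_loadings.tsv", sep="\t", index=False)
    res.candidate_set.table.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    if res.ld_results:
        pd.DataFrame([{
            "stratum": r.stratum, "mean_r2_focal": r.mean_r2_focal,
            "mean_r2_background": r.mean_r2_background,
            "mean_r2_draws": r.mean_r2_draws, "null_q025": r.q_low,
            "null_q975": r.q_high, "p_value": r.p_value, "n_draws": r.n_draws,
        } for r in res.ld_results]).to_csv(outdir / "ld_enrichment.tsv",
                                           sep="\t", index=False)
    manifest = {
        "package_version": __version__,
        "seed": res.config.seed,
        "stage_seeds": res.seeds,
        "config": _config_dict(res.config),
        "n_candidates": len(res.candidates),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("simulation") and isinstance(d["simulation"].get("hosts"), tuple):
        d["simulation"]["hosts"] = list(d["simulation"]["hosts"])
    return d
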