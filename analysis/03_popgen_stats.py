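#!/usr/bin/env python
"""Summary statistics, pairwise FST, isolation by distance, host effect.

Computes per-population Ho/He/pi/F_IS, the pairwise Weir-Cockerham FST
matrix, a Mantel test of site FST against geographic distance, and a partial
Mantel test of host effect controlling geography.  Tables go to
results/stats/.
"""

from pathlib import Path

from hostrace.filtering import run_filter_cascade
from hostrace.pipeline import _geo_distance, _host_distance, drop_monomorphic
from hostrace.popgen import (mantel_test, pairwise_fst, partial_mantel_test,
                             population_summary)
from hostrace.tables import DistanceMatrix, PopulationMap

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "stats"
OUT.mkdir(parents=True, exist_ok=True)

popmap = PopulationMap.from_tsv(DATA / "popmap.tsv")
distances = DistanceMatrix.from_tsv(DATA / "distances.tsv")
_, called, _ = run_filter_cascade(DATA / "variants.vcf", popmap)

summary = population_summary(called, popmap)
summary.to_csv(OUT / "population_summary.tsv", sep="\t", index=False)
print(summary.round(4).to_string(index=False))

fst = pairwise_fst(called, popmap)
fst.to_tsv(OUT / "pairwise_fst.tsv")

site_map = PopulationMap(popmap.frame.assign(host=popmap.hosts[0]))
site_fst = pairwise_fst(called, site_map)
site_fst.labels = [l.split(":")[0] for l in site_fst.labels]
ibd = mantel_test(site_fst, distances.reorder(site_fst.labels),
                  n_perm=10000, seed=2)
print(f"\nIBD Mantel: r = {ibd.r:.3f}, p = {ibd.p_value:.4g} "
      f"({ibd.n_permutations} permutations)")

pops = popmap.populations()
pm_fst = pairwise_fst(drop_monomorphic(called), popmap)
pm = partial_mantel_test(pm_fst, _host_distance(pops),
                         _geo_distance(pops, distances), n_perm=10000, seed=3)
print(f"partial Mantel (host | geography): r = {pm.r:.3f}, p = {pm.p_value:.4g}")
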