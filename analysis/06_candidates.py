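#!/usr/bin/env python
"""Candidate host-associated loci: >=2-of-N evidence intersection.

Combines the top DAPC loadings (05) with multi-site permutation significance
(04); loci supported by both become candidates.  The per-locus support table
and Venn cell counts go to results/candidates/, and candidates are scored
against the simulation ground truth.
"""

from pathlib import Path

import pandas as pd

from hostrace.candidates import intersect_evidence

ROOT = Path(__file__).resolve().parents[1]
RES = ROOT / "results"
OUT = RES / "candidates"
OUT.mkdir(parents=True, exist_ok=True)

top_dapc = set(pd.read_csv(RES / "dapc" / "top_loadings.tsv", sep="\t")["locus"])
sig = {}
for path in sorted((RES / "hostdiff").glob("hostdiff_*.tsv")):
    t = pd.read_csv(path, sep="\t")
    sig[path.stem] = t.set_index("locus")["significant"]
sig_matrix = pd.DataFrame(sig)
multisite = set(sig_matrix.index[sig_matrix.sum(axis=1) >= 3])

cs = intersect_evidence({"dapc": top_dapc, "multisite": multisite}, min_support=2)
cs.table.to_csv(OUT / "candidates.tsv", sep="\t", index=False)

truth = pd.read_csv(RES / "data" / "truth.tsv", sep="\t")
true_loci = set(truth.locus[truth.host_divergent])
cands = set(cs.candidates)
print(f"evidence sets: dapc={len(top_dapc)}, multisite(>=3 sites)={len(multisite)}")
print(f"candidates (>=2 sources): {len(cands)}")
print(f"recall of truth host loci: {len(cands & true_loci)}/{len(true_loci)}")
print(f"precision: {len(cands & true_loci)}/{len(cands) or 1}")
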