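# Methods

`hostrace` infers host-plant-associated genomic differentiation from
reduced-representation (RADseq-style) SNP data sampled as sympatric
population pairs — pairs of insect populations using different host plants
at the same geographic site.  The inference logic is: if host use restricts
gene flow, a subset of loci should show allele-frequency differences between
hosts that are (i) individually significant under a label-permutation null,
(ii) consistent in identity and direction across independent sympatric
sites, (iii) recoverable by a host discriminant, and (iv) in mutual linkage
disequilibrium.  Every stage is validated end-to-end on a synthetic
metapopulation generator with ground truth, because the statistical
machinery — not any one empirical dataset — is what the package provides.

## Allele frequencies from genotype likelihoods

Low-coverage RADseq genotypes are uncertain; hard calls discard that
uncertainty.  Population allele frequencies are therefore estimated directly
from per-individual genotype-probability triplets:

    P = [ Σ_i Σ_j g_j · p(g_j | D_i) ] / (2n),   g = (0, 1, 2)

where `p(g_j|D_i)` is the normalized likelihood of dosage `g_j` given
individual *i*'s reads and *n* counts individuals with data at the locus.
When the triplets are unit vectors (certain calls) this reduces *exactly*
to the allele-counting estimator — a property the tests assert at machine
precision.  VCF `PL` fields are converted by `p(g) ∝ 10^(−PL/10)`, `GL`
fields by `p(g) ∝ 10^(GL)`.  Note the estimator is shrunk toward 0.5 for
poorly covered individuals (a flat likelihood contributes dosage 1); at the
sample sizes used here the binomial sampling error of the individuals
themselves dominates this shrinkage.

## Per-locus significance and its calibration

The host difference at a locus, ΔP = P_host1 − P_host2, is tested by
shuffling host labels over the site's pooled individuals (group sizes
preserved) and flagging ΔP outside the empirical 0.025/0.975 null
quantiles.  No multiple-testing correction is applied, deliberately: the
flags are used to *subset* loci for cross-site consistency analyses, not as
per-locus discoveries.  Quantiles use the order-statistic convention
(`lower` for 0.025, `higher` for 0.975), which keeps the two-sided
exceedance probability of an exchangeable observation at `2·⌊0.025(B+1)⌋/(B+1)`
≈ 0.05 for finite permutation counts B; interpolated quantiles would
inflate it to ≈ 0.051 at B = 1,000.  An auxiliary two-sided p-value
`(1 + #{|Δ_perm| ≥ |Δ_obs|})/(B + 1)` is reported alongside.

## Shared outliers across sites (LD-preserving Monte Carlo)

Counting loci significant at ≥k of the sympatric sites and comparing with a
naive binomial expectation would ignore correlation among loci.  The null
is therefore built by reassigning *whole individuals* to hosts within each
site — multilocus genotypes stay intact, preserving LD — and rescoring the
per-site significance with the same inner permutation test.  Observed
shared-by-≥k counts are compared with the null's 0.025/0.975 quantiles and
an exceedance p-value.  Inner and outer permutation counts are independent
knobs; the nested test is quadratic in cost, so the defaults (1,000/1,000)
can be reduced for exploratory runs without changing the inference
structure.

## Filter cascade

Ordered stages, each SNP attributed to its first failing stage: (1) summed
read depth ≥ 50 and site quality ≥ 21; (2) biallelic; (3) called in ≥ 90%
of individuals; (4) exact two-sided binomial test of pooled heterozygote
read counts against 0.5 (α = .05) — allelic imbalance is a paralog/mapping
artifact signature; (5) minor allele frequency ≥ 0.05.  The *likelihood
set* stops here.  The *called set* additionally: (6) masks genotypes with
GQ < 15 and drops SNPs whose masked missingness exceeds the floor; (7)
removes SNPs with significant heterozygote *excess* (exact Levene
conditional test, upper tail) in any one population — collapsed paralogs
masquerade as universal heterozygotes; (8) keeps one SNP per RAD contig
(first by position) to limit intra-contig linkage.  Choices that the
surrounding conventions leave open and that we fixed: balance uses reads
pooled across heterozygous individuals; het-excess removal triggers on any
single population (conservative against paralogs); "depth ≥ 50" is read as
site-level summed depth; all are parameters of `FilterParams`.

## Classical statistics

Per-SNP summaries use the SNP-data conventions: Ho = heterozygote fraction,
He = 2p(1−p), π = 2p(1−p)·2n/(2n−1) (unbiased), F_IS = 1 − Ho/He at
polymorphic loci; population values are across-locus means, with a t-based
95% CI for F_IS (the exact CI construction is a free choice; the t-interval
over per-SNP values is the simplest defensible one).  Differentiation is
Weir & Cockerham's (1984) θ with ratio-of-sums combination across loci —
hand-checkable and oracle-tested, in place of any particular pipeline's
AMOVA variant; negative estimates are reported as computed.  Isolation by
distance uses a one-sided Mantel test (upper-triangle Pearson r, rows and
columns of the distance matrix permuted jointly; exhaustive enumeration
when the permutation budget covers the full group).  The host effect
controlling geography uses a first-order partial Mantel test permuting the
FST matrix, with raw or log(1+d) distances.

## Host discriminant (DAPC)

Dosages are mean-imputed, column-centred, reduced to `n_pcs` principal
components, and a linear discriminant with equal priors is fitted on the
retained PCs (PCA + LDA via scikit-learn).  Per-locus loadings are the
discriminant weights back-projected through the PCA rotation — this
reproduces the "loads most strongly" *ranking*; loading magnitudes are not
normalized to match any specific DAPC implementation.  Assignment
significance shuffles group labels and refits only the discriminant (the
PCA is label-free), comparing the observed mean correct-assignment
probability with the null.  The retained-PC count is a config input; no
automated cross-validation is attempted.

## Candidates and LD enrichment

Evidence sources: (a) top-1% |loading| on the host discriminant axis,
(b) significance at ≥3 sympatric sites, and optionally (c) an external
environment-association table filtered to the top-1% Bayes factors that are
also top-10% |rho| (absolute value, since rho carries direction).  Loci
supported by ≥2 sources are candidates; all Venn cells are reported.  Top
fractions take exactly `ceil((1−q)·L)` loci with ties broken by locus order
(and a warning when degenerate).

LD is the composite genotypic r² — squared Pearson correlation of unphased
dosage vectors, pairwise-complete over missing data; loci monomorphic in a
stratum yield undefined pairs, excluded from all means.  Enrichment draws
`|focal|` loci uniformly without replacement `n_draws` times and reports
`p = (1 + #{null mean ≥ observed})/(n_draws + 1)` per population and per
pooled site pair, alongside both the all-pairs background mean and the
draw-based mean (the two coincide in expectation).

## Synthetic metapopulation generator

The generator is first-class, tested code; its defaults define the standard
study conditions.  Structure: ancestral frequencies uniform on [0.1, 0.9]
(so truth loci are not immediately lost to the MAF filter); site
frequencies follow a Balding–Nichols *stepping-stone chain* along the site
axis (site s drifts from site s−1 with parameter
`fst_background + ibd_slope·gap`), chosen over a star model because it
makes pairwise differentiation monotone in pairwise distance — the
isolation-by-distance signature the Mantel stage tests.  Host-divergent
loci displace the two host populations of a sympatric site symmetrically by
±delta_p/2 around the site frequency, with a fixed per-locus direction for
the shared subset (so direction-consistency is testable) and a random
direction for site-private loci.  The LD block is generated from a
two-haplotype-class mixture: with class frequency π, a class-1 haplotype
carries the alt allele with probability π + c(1−π) and a class-0 haplotype
with probability π(1−c); marginals stay exactly π while pairwise haplotype
correlation is c² (dosage r² ≈ c⁴ ≈ 0.66 at the default coupling c = 0.9).
The block is pinned to an intermediate centre (0.5 ± delta_p/2 between
hosts) so it remains polymorphic — and its LD measurable — within each
host race, mirroring real haplotype blocks segregating within races.
Genotypes are Hardy–Weinberg draws; depth is Poisson(`mean_depth`);
alt-reads are binomial with per-genotype alt probability
(e, 0.5, 1−e); likelihood triplets are normalized binomial likelihoods,
calls their argmax with phred-scaled GQ, and zero depth is missing.

What the generator does **not** emulate: per-locus depth heterogeneity
(PCR-duplicate skew), linked neutral variation around the block
(no recombination map or coalescent), allele dropout at restriction sites,
batch effects, or selection dynamics through time.  Passing tests therefore
demonstrate that the *statistical machinery* is correct and calibrated
under the assumed generative model — not that any particular empirical
dataset satisfies those assumptions.

## Problem sizes and numerical choices

Default study conditions: 4 sympatric sites 250 km apart, 20 diploids per
host population, 2,000 biallelic loci, 20 host-divergent loci shared by all
sites at delta_p = 0.5 with 17 of them in the LD block, drift
`fst_background = 0.02` with `ibd_slope = 5·10⁻⁵` per km, error rate 0.01,
mean depth 9.74.  For analyses that live downstream of the called-set
cascade (the DAPC/candidate/LD chain) the scenario uses mean depth 15:
at depth ~10 the GQ ≥ 15 mask removes nearly half of all loci — an
accurate emulation of real pipelines, but one that turns candidate recall
into a lottery over which truth loci happen to survive; at depth 15 the
mask is no longer binding (P[Poisson(15) < 7] ≈ 0.8%) and recall measures
the method rather than the sequencing budget.  The called-set scale
(~1,750–2,000 loci) also keeps the top-1% loading rule at ~18–20 loci,
matching the proportions under which a ≥2-source intersection is
informative.

Permutation counts in tests and the acceptance script are reduced from the
canonical 10,000 (and the 10⁶ LD draws) to 200–10,000 with the inference
structure unchanged; the test suite states each size explicitly.
Monte Carlo p-values use the add-one convention and count ties as
exceedances (with a 10⁻¹² slack so ties differing only by floating-point
summation order still count).  Degenerate inputs: constant distance
matrices, single-individual groups, empty evidence intersections, loci with
no data, and monomorphic strata all raise or propagate NaN explicitly
rather than silently producing numbers.

## Known limitations

* θ and the summary statistics will not numerically match pipelines that
  use different estimator variants (e.g. AMOVA-based FST); the contract is
  the published Weir–Cockerham 1984 definition, oracle-tested.
* DAPC loadings match adegenet in ranking, not magnitude.
* The partial Mantel test inherits the known power/type-I caveats of
  matrix permutation tests; it is one line of evidence among several.
* The GL allele-frequency estimator is biased toward 0.5 at very low depth;
  significance is unaffected (the permutation null shares the bias) but
  reported ΔP magnitudes shrink accordingly.
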