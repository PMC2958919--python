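# Methods

`aflpdelim` re-implements, as one tested pipeline, the multilocus workflow
used to delimit species in a closely related radiation from dominant AFLP
markers and to discriminate incomplete lineage sorting (ILS) from
introgression as causes of species nonmonophyly in a mitochondrial gene
tree.  This note records the models, the conventions behind every numeric
choice, and what the synthetic data does and does not emulate.

## Data model

An AFLP profile is a vector of dominant band phenotypes: present (1), absent
(0) or missing (`?` on disk, −9 in the assignment-program interchange
format).  Missing is a first-class state throughout — no stage coerces it to
absence.  Marker labels of the form `<primer-combination>-<size>` carry the
scored fragment length; sizes are validated against the scoring window of
70–322 bases, outside which fragment calls are not reproducible.  A specimen
with no present band is flagged (it is not a valid AFLP profile) but the
matrix is still constructed so the flag can be inspected.

## Distances, trees, networks

**Jaccard distance.** d = 1 − a/(a+b+c) over markers non-missing in both
specimens (pairwise deletion — our documented choice where common practice
varies), with a = shared presences and b, c the one-sided presences.  Shared
absences carry no homology signal for dominant markers and are excluded by
the definition.  A pair with zero union is an error naming the pair.

**Neighbor joining.** Saitou–Nei with the standard Q-criterion.  Exact ties
resolve to the lowest-index pair (row-major argmin).  Negative limbs are
clamped to zero with the deficit moved to the sibling edge
(Kuhner–Felsenstein), so displayed lengths stay non-negative.  Bootstrap
support resamples marker columns with replacement (loci are the exchangeable
units; specimens are fixed) and reports, per edge of the point-estimate
tree, the percentage of replicate trees containing the same bipartition.

**Neighbor-net.** The two-stage agglomerative selection (cluster pairs by the
NJ Q-criterion on averaged distances, then endpoint nodes by the analogous
node-level criterion; three-into-two chain reductions with weights 2/3 and
1/3, expanded in reverse at the end) yields a circular taxon ordering.
Split weights are estimated by non-negative least squares over all n(n−1)/2
splits compatible with the ordering; splits at or below 1e−8 of the total
weight are dropped (the active-set solver's numerical floor).  On
circular-decomposable inputs (including all tree metrics) the weighted
splits reproduce the input distances exactly, which the tests verify against
a brute-force NNLS oracle built from first principles.

## Gaussian-clustering delimitation

Jaccard distances are embedded by non-metric MDS in four dimensions (the
usual choice for dominant markers), minimizing Kruskal stress-1 by
majorization with monotone (isotonic) regression: one classical-scaling
start plus random starts (20 by default), tolerance 1e−6 on the stress,
500 iterations cap.  Stress-1 is scale-invariant, so the returned
configuration is rescaled to the dissimilarity scale; a collapsed
configuration counts as a perfect fit only when the observed dissimilarities
are themselves all zero.  Known limitation: with strongly clustered data and
small n, non-metric MDS admits degenerate near-zero-stress solutions that
collapse clusters toward points; the rescaling keeps such solutions usable
for clustering, and the reported stress makes them visible (real datasets
with richer rank structure report stress on the order of 0.1).

Gaussian mixtures are fitted by EM for each cluster count (0–100 by default,
capped at n−1; smaller scans are used in tests and stated there) and four
covariance families — spherical-equal, spherical, diagonal, full — from a
Ward hierarchical-clustering initialization.  Covariances carry a
regularization floor of 1e−6 of the data variance, the customary EM
safeguard against collapsed components.  The optional noise component is a
uniform density over the data's bounding box, initialized from
nearest-neighbour cleaning: the k-th nearest-neighbour distances (k = 5) are
modelled as a two-component mixture of the Gamma densities implied by
homogeneous Poisson processes of different rates, fitted by EM, and points
posterior-assigned to the sparse process are the initial noise set.  With
noise enabled, k = 0 (uniform-only) joins the scan.  Model selection
maximizes BIC = 2·loglik − params·ln n; the convention is recorded on the
fit object.  Hard assignments are maximum-posterior, label 0 reserved for
noise.

## Bayesian assignment (with and without admixture)

Band frequencies p_kl get Beta(1,1) priors.  The default likelihood is the
*phenotype* model — the one-bit dominant band is Bernoulli(p_kl) given its
cluster of origin — which is the minimal faithful treatment of dominant
data.  The *recessive-diploid* variant (band = at least one of two allele
copies, P = 1 − (1 − p_kl)²) is an opt-in alternative implemented by data
augmentation: allele copies and their origins are imputed each sweep
(jointly over origin pairs for band-present cells), restoring conjugacy.

Without admixture, each individual has a latent cluster with uniform prior,
updated by Gibbs; with admixture each individual has ancestry
q_i ~ Dirichlet(α, …, α) and every marker (or allele copy) its own origin.
The shared α is updated by a Metropolis step with Gaussian proposal (step
0.025), uniform prior on (0, 10], initial value 1, unless fixed.  Modal
partitions break ties toward the lower label; reported quantities are
invariant to cluster relabeling (runs are aligned greedily by ancestry-column
similarity).

**Evidence and ΔK.**  Each run records the post-burn-in log-likelihood given
the continuous parameters, *marginal over the discrete origins*: with
admixture this is the usual Σ log(Σ_k q_ik · band term); without admixture
the individual's cluster is marginalized under its uniform prior.  The
conventions match, and the evidence proxy L(K) = mean − variance/2
(population variance) then stays within half a log unit of the exact
conjugate marginal on small instances where that can be brute-forced — the
conditional-on-assignment trace does not, overshooting by up to ~1.3 log
units, which is why the marginal convention is the package's choice.  L(K)
remains an approximation; its bias grows with matrix size, so only
comparisons across K, not absolute values, should be interpreted.  Evanno's
ΔK is the across-run mean of |L(K+1) − 2L(K) + L(K−1)| divided by the
across-run standard deviation of L(K) (ddof = 1); it is undefined at the
boundary K values, and K values with zero run-to-run spread are flagged and
excluded from the argmax.

Defaults mirror the standard protocol (10 runs × 100,000 iterations after
10,000 burn-in for the ΔK scan; 5 runs for pairwise admixture; thin 10).
These are hours-scale on matrices of ~150 × ~1500; the tests and the
acceptance script use the documented scaled-down preset (10,000 iterations,
1,000 burn-in) or smaller, stated per use, which the simulated problem sizes
(n ≤ 90, L ≤ 300) support.

**Pairwise admixture screen.**  Two species, K = 2, admixture model, best of
several runs by L(K); clusters anchored to species by mean ancestry of each
species' members; the report lists each individual's ancestry in its own
species' cluster.  Precision bound worth knowing: for a true F1 hybrid
scored at 300 dominant markers with drift F = 0.5 between the parents, the
likelihood itself pins q only to about ±0.06 (one standard deviation), so
individual hybrids can legitimately report 0.55–0.62 own-cluster ancestry.
When the data were generated under Hardy–Weinberg dominant-diploid emission,
the matching recessive-diploid likelihood should be fitted: the phenotype
model then sees a small excess of bands in admixed individuals (Jensen's
inequality on the concave band-probability map) and biases their ancestry
away from 1/2 by up to ~0.1.

## Dirichlet-process clustering

A collapsed Gibbs sampler over partitions: an individual joins an existing
cluster with probability ∝ cluster size × the Beta-Binomial posterior
predictive of its profile (Beta(1,1) per marker, the same phenotype model as
above), or founds a new cluster ∝ α × the prior predictive.  The chain
starts from all singletons — structure is then found by downhill
agglomeration, which mixes far better than splitting a merged start one
element at a time — and scans in random order.  With zero markers the
sampler reduces exactly to the Chinese restaurant process, which the tests
verify against the closed form via the unsigned-Stirling-number recursion.
α is fixed or solved from a prior expected cluster count
(E[k | α, n] = Σ α/(α+i); default E[k] = 5 — the prior the original
analyses used is not recorded anywhere, so the package makes its choice
explicit and the CLI supports a sensitivity scan over `--prior-mean-k`).

The **mean partition** minimizes the summed partition distance (minimum
number of reassignments, computed as n minus a maximum-weight matching of
cluster overlaps) to the posterior sample; the search restarts from the ten
most frequent sampled partitions and hill-climbs by single-element
reassignment, which is exact on the small instances where brute force over
all partitions is feasible (the tests exploit n = 4).

## Gene-tree concordance and causes of discordance

A species is monophyletic when its MRCA clade contains no foreign tips;
with foreign tips forming a single clade it is paraphyletic, otherwise
polyphyletic.  Outlier tips are measured against the maximal all-conspecific
clade holding the plurality of the species' tips.  For each discordant tip
the smallest clade joining it with heterospecific lineages is found by
walking rootward; its height (maximum node-to-leaf path — no ultrametricity
assumed, and "max" rather than "mean" is the documented choice) divided by
the root height is the event's relative depth.  Outgroup tips are excluded
from the normalization by measuring against the ingroup MRCA, so a long
outgroup stem cannot dilute the depths.

The classification combines three criteria with explicit thresholds (both
configurable and reported): relative depth ≥ 0.5 is "deep"; foreign ancestry
≥ 0.10 in the admixture screen is "admixture evidence".  Deep + no
admixture ⇒ incomplete lineage sorting; shallow + admixture ⇒
recent-divergence-or-introgression, deliberately left unresolved because the
two are not distinguishable from these data alone; conflicting or missing
evidence ⇒ ambiguous, with the reason recorded.  The thresholds are the
package's declared conventions — the underlying criteria are qualitative in
the literature — and geography (great-circle distances between carriers of
shared haplotypes versus the species' range span) is reported as a score,
never used as a gate, since a boundary concentration of shared markers can
also reflect a pre-existing cline.

## Composition tests

The chi-square homogeneity test compares per-taxon base counts (gaps and
ambiguities excluded; taxa with no counted sites dropped with a warning)
against the pooled composition, df = (taxa−1)(states−1).  The matched-pairs
(Bowker) test of symmetry builds, per sequence pair, the site-pattern table
over columns where both sequences are unambiguous (pairwise deletion);
statistic Σ (n_ij − n_ji)²/(n_ij + n_ji) over state pairs with a non-zero
discordant sum, df = the number of such pairs, chi-square upper-tail
p-value (p = 1 at df = 0).  The per-class summary is the percentage of
comparable pairs with p < 0.05 (threshold settable).  RY recoding maps
A,G → R and C,T → Y at the selected codon positions, preserves gaps, sends
other ambiguity codes to N, and leaves unselected positions untouched; codon
classes derive from the alignment's declared frame offset — no reading-frame
detection is attempted, so the offset is a required input.

## Synthetic data: what it emulates, what it does not

`simulate_aflp` draws population band frequencies from the Balding–Nichols
construction p_kl ~ Beta(p0(1−F)/F, (1−p0)(1−F)/F) — the correlated-
frequency drift model the Bayesian clustering literature assumes — with a
single shared F by default, ancestral frequencies fixed or Beta-distributed
per marker, individual ancestries one-hot (α = 0) or symmetric-Dirichlet,
optional F1 hybrids (ancestry ½/½ between the first two populations),
outliers with per-marker uniform band probabilities (the target of the noise
component), emission either haploid-band or Hardy–Weinberg dominant-diploid,
optional missing cells, and per-population sampling sites with jitter inside
an island-scale coordinate frame.  Default conditions for recovery
experiments: K = 3, L = 300, F = 0.5, 30 specimens per population — strong,
clean differentiation.  Not emulated: AFLP size homoplasy (co-migrating
non-homologous fragments), linkage, scoring error correlated across lanes.
Passing recovery tests therefore show method correctness under the model's
own assumptions, not robustness to those artefacts.

`simulate_coalescent_tree` wraps msprime's multispecies coalescent on a
sequential species tree (haploid samples, per-species sizes, increasing
divergence times) with an optional pulse introgression event (each recipient
lineage moves to the donor with the stated probability at the stated time).
Deep-divergence settings produce ILS-style deep discordances; a recent pulse
produces shallow ones — the two fixtures behind the discordance
classification.  `simulate_composition_alignment` is column-i.i.d. with
taxon-specific base compositions and an optional shared-column fraction;
there is no tree, which suffices to exercise symmetry statistics but not to
emulate phylogenetically correlated compositional drift.

All generators are bit-reproducible given their seed.

## Problem sizes

The test suite and `scripts/acceptance.py` run everything at simulated desk
scale — n ≤ 90 specimens, L ≤ 300 markers, MCMC chains of 2,000–40,000
sweeps, 1,000 bootstrap replicates, trees of ≤ 14 tips — sizes at which the
exact oracles (brute-force marginals, Stirling recursion, exhaustive
partition search, NNLS over all circular splits) remain computable and the
statistical targets (adjusted Rand ≥ 0.9, 3-standard-error Monte-Carlo
bands) are meaningful.  The library itself has no such limits; the paper-
scale protocol settings are the defaults on the configuration objects.
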