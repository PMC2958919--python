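# aflpdelim

Species delimitation and introgression diagnostics from dominant AFLP
markers, gene trees and alignments.

## The problem

In a radiation of closely related species, a gene tree sequenced from many
individuals per species often contradicts the species classification: some
species' haplotypes do not form exclusive clades.  Three processes can cause
this — inadequate taxonomy, incomplete lineage sorting (ILS, the persistence
of ancestral polymorphism through speciation), and introgression (allele
transfer through hybridization) — and telling them apart requires nuclear
multilocus data alongside the gene tree.  This package implements that
workflow for dominant AFLP markers (anonymous genome-wide presence/absence
bands), end to end:

* **Distances and networks** — Jaccard distances (shared absences excluded,
  as dominant data demand), neighbor-joining trees with marker-bootstrap
  support, and neighbor-net split networks (circular split systems with
  non-negative least-squares weights).
* **Three genotypic-cluster delimitation methods** — Gaussian mixtures with
  an optional uniform noise component on a 4-D non-metric MDS embedding,
  selected by BIC over 0–100 clusters; Bayesian assignment for dominant
  markers with and without admixture, with the evidence proxy
  L(K) = mean − variance/2 and Evanno's ΔK = mean|L″(K)| / sd(L(K)) to choose
  the number of clusters; and Dirichlet-process (Chinese-restaurant-process)
  clustering with a posterior over the cluster count and a mean-partition
  summary.
* **Introgression screening** — pairwise K = 2 admixture analyses reporting
  each individual's ancestry in its own species' cluster.
* **Concordance** — per-species monophyly in a rooted gene tree, relative
  coalescence depths of discordant lineages, and a three-criterion
  classification (depth of coalescence, admixture evidence, geography) into
  ILS / recent-divergence-or-introgression / ambiguous.
* **Composition tests** — chi-square homogeneity of base frequencies across
  taxa, matched-pairs (Bowker) tests of symmetry per codon-position class,
  and RY recoding.
* **Synthetic data** — Balding–Nichols AFLP matrices with known ancestry,
  multispecies-coalescent gene trees with optional introgression pulses
  (via msprime), and compositionally heterogeneous alignments, so every
  stage is testable with ground truth and no downloads.

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

```python
from aflpdelim import (PopModel, simulate_aflp, delimit_gaussian,
                       BayesConfig, pairwise_admixture)

# three drifted populations, 30 specimens each, 300 dominant markers
matrix, meta, truth = simulate_aflp(PopModel(K=3, L=300, F=0.5,
                                             n_per_pop=30, seed=42))

partition, fit, embedding = delimit_gaussian(matrix, dim=4, seed=0,
                                             k_range=range(1, 21))
print(fit.k, fit.family, round(embedding.stress, 4), partition.n_noise)
```

prints

```
3 spherical-equal 0.0 0
```

— the BIC scan selects three clusters (with the shared-spherical covariance
family), the 4-D embedding fits these strongly clustered simulated distances
essentially perfectly (stress ≈ 0; real datasets report ~0.1), and no
specimen is left unassigned.  The partition matches the simulated truth
(adjusted Rand index 1.0).  An admixture screen between two species runs as

```python
ancestry, report = pairwise_admixture(matrix, meta, "sp1", "sp2",
                                      BayesConfig.scaled_down(K=2, admixture=True, seed=1))
print(report["own_cluster_ancestry"].min().round(3))
```

```
0.992
```

— every individual of both species has ≥ 99% inferred ancestry in its own
cluster: no admixture signal, as expected for independently drifted
populations.

The same operations are available from the shell:

```bash
aflpdelim simulate aflp --k 3 --loci 300 --seed 42 --out sim.csv
aflpdelim njtree sim.csv --bootstrap 1000 --seed 1 --out tree.nwk
aflpdelim neighbornet sim.csv --out net.nex          # SplitsTree-readable
aflpdelim delimit gaussian sim.csv --dim 4 --seed 0 --out clusters.csv
aflpdelim dpp sim.csv --cycles 4000 --sample-every 2 --burnin-samples 200 \
    --prior-mean-k 3,5,8 --seed 0 --out dpp.tsv      # prior sensitivity scan
```

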