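"""Synthetic data with known ground truth for every pipeline stage.

Three generators:

* :func:`simulate_aflp` — dominant AFLP matrices from K source populations
  whose band frequencies drift from an ancestral frequency under the
  Balding–Nichols construction ``p_kl ~ Beta(p0(1-F)/F, (1-p0)(1-F)/F)``,
  with per-individual admixture proportions, Hardy–Weinberg dominant-marker
  emission, optional outlier specimens and optional F1 hybrids.
* :func:`simulate_coalescent_tree` — multispecies-coalescent gene trees over a
  sequential (caterpillar) species tree, with an optional pulse introgression
  event moving recipient lineages into the donor population.  Deep discordant
  coalescences emulate retained ancestral polymorphism; shallow ones emulate
  recent introgression.
* :func:`simulate_composition_alignment` — alignments whose taxa have their
  own base compositions (column-i.i.d., no tree), exercising the
  compositional-heterogeneity tests.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import msprime
import numpy as np

from .io_formats import (
    ABSENT,
    MISSING,
    PRESENT,
    AFLPMatrix,
    Alignment,
    GeneTree,
    SpecimenTable,
)

import pandas as pd

__all__ = [
    "PopModel",
    "SimTruth",
    "simulate_aflp",
    "emit_bands",
    "simulate_coalescent_tree",
    "simulate_composition_alignment",
]


@dataclass
class PopModel:
    """Parameters of the K-population dominant-marker generative model.

    F is the per-population drift parameter of the Balding–Nichols Beta;
    ``p0`` is either a fixed ancestral band frequency shared by all markers or
    ``(a, b)`` parameters of a Beta from which per-marker ancestral
    frequencies are drawn.  ``admixture_alpha = 0`` produces pure individuals;
    positive values draw each individual's ancestry from a symmetric
    Dirichlet.  ``hybrid_count`` appends first-generation hybrids with
    ancestry split 50/50 between the first two populations.
    """

    K: int = 3
    L: int = 300
    F: float | Sequence[float] = 0.5
    p0: float | tuple[float, float] = (1.0, 1.0)
    admixture_alpha: float = 0.0
    emission: str = "dominant-diploid"
    n_per_pop: int | Sequence[int] = 30
    outlier_count: int = 0
    hybrid_count: int = 0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1 or self.L < 1:
            raise ValueError("K and L must be >= 1")
        fs = np.atleast_1d(np.asarray(self.F, dtype=float))
        if not ((fs > 0) & (fs < 1)).all():
            raise ValueError("F must lie in (0, 1)")
        if self.admixture_alpha < 0:
            raise ValueError("admixture_alpha must be >= 0")
        if self.emission not in ("haploid-band", "dominant-diploid"):
            raise ValueError(f"unknown emission model {self.emission!r}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def pop_sizes(self) -> list[int]:
        if np.isscalar(self.n_per_pop):
            return [int(self.n_per_pop)] * self.K
        sizes = list(self.n_per_pop)
        if len(sizes) != self.K:
            raise ValueError("n_per_pop length must equal K")
        return [int(s) for s in sizes]

    @property
    def drift(self) -> np.ndarray:
        fs = np.atleast_1d(np.asarray(self.F, dtype=float))
        if fs.size == 1:
            return np.repeat(fs, self.K)
        if fs.size != self.K:
            raise ValueError("F must be scalar or length K")
        return fs


@dataclass
class SimTruth:
    """Ground truth attached to a simulated AFLP matrix."""

    q: np.ndarray                      # n x K ancestry proportions
    p: np.ndarray                      # K x L population band frequencies
    labels: np.ndarray                 # population index per specimen, -1 = outlier
    outlier_flags: np.ndarray          # boolean per specimen
    pop_coordinates: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        if self.q.size and not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("ancestry rows must sum to 1")


def emit_bands(p: np.ndarray, q: np.ndarray, emission: str, rng: np.random.Generator) -> np.ndarray:
    """Draw dominant band phenotypes given population frequencies and ancestries.

    haploid-band: presence ~ Bernoulli(sum_k q_ik p_kl).
    dominant-diploid: presence ~ Bernoulli(1 - (1 - sum_k q_ik p_kl)^2), the
    Hardy–Weinberg probability that at least one of two allele copies carries
    the band.
    """
    mix = q @ p
    if emission == "dominant-diploid":
        prob = 1.0 - (1.0 - mix) ** 2
    elif emission == "haploid-band":
        prob = mix
    else:
        raise ValueError(f"unknown emission model {emission!r}")
    return (rng.random(prob.shape) < prob).astype(np.int8)


#: rough geographic frame for simulated sampling sites (an island-scale box).
_COORD_FRAME = dict(lat0=35.0, lon0=24.0, span_lat=0.5, span_lon=2.0, jitter=0.03)


def simulate_aflp(model: PopModel) -> tuple[AFLPMatrix, SpecimenTable, SimTruth]:
    """Simulate an AFLP matrix plus metadata and ground truth from a PopModel."""
    rng = np.random.default_rng(model.seed)
    K, L = model.K, model.L

    if isinstance(model.p0, tuple):
        a, b = model.p0
        p0 = rng.beta(a, b, size=L)
    else:
        p0 = np.full(L, float(model.p0))
    p0 = np.clip(p0, 1e-6, 1.0 - 1e-6)

    drift = model.drift
    p = np.empty((K, L))
    for k in range(K):
        f = drift[k]
        p[k] = rng.beta(p0 * (1.0 - f) / f, (1.0 - p0) * (1.0 - f) / f)
    p = np.clip(p, 1e-9, 1.0 - 1e-9)

    sizes = model.pop_sizes
    n_pop = sum(sizes)
    labels = np.repeat(np.arange(K), sizes)
    if model.admixture_alpha == 0.0:
        q = np.zeros((n_pop, K))
        q[np.arange(n_pop), labels] = 1.0
    else:
        q = rng.dirichlet(np.full(K, model.admixture_alpha), size=n_pop)
        labels = q.argmax(axis=1)

    if model.hybrid_count:
        if K < 2:
            raise ValueError("hybrids require K >= 2")
        qh = np.zeros((model.hybrid_count, K))
        qh[:, 0] = qh[:, 1] = 0.5
        q = np.vstack([q, qh])
        labels = np.concatenate([labels, np.full(model.hybrid_count, 0)])

    values = emit_bands(p, q, model.emission, rng)

    if model.outlier_count:
        u = rng.random((model.outlier_count, L))
        out_vals = (rng.random((model.outlier_count, L)) < u).astype(np.int8)
        values = np.vstack([values, out_vals])
        qo = np.full((model.outlier_count, K), 1.0 / K)
        q = np.vstack([q, qo])
        labels = np.concatenate([labels, np.full(model.outlier_count, -1)])

    n = values.shape[0]
    outlier_flags = labels == -1
    if model.missing_rate > 0:
        mask = rng.random(values.shape) < model.missing_rate
        values = values.copy()
        values[mask] = MISSING

    # sampling sites: population centres spread across a rectangular frame,
    # individual sites jittered around the centre; outliers placed anywhere.
    fr = _COORD_FRAME
    centres = np.column_stack([
        fr["lat0"] + fr["span_lat"] * rng.random(K),
        fr["lon0"] + fr["span_lon"] * (np.arange(K) + rng.random(K)) / K,
    ])
    lat = np.empty(n)
    lon = np.empty(n)
    for i in range(n):
        if outlier_flags[i]:
            lat[i] = fr["lat0"] + fr["span_lat"] * rng.random()
            lon[i] = fr["lon0"] + fr["span_lon"] * rng.random()
        else:
            c = centres[labels[i]]
            lat[i] = c[0] + fr["jitter"] * rng.standard_normal()
            lon[i] = c[1] + fr["jitter"] * rng.standard_normal()

    ids, species, locality = [], [], []
    counters: dict[str, int] = {}
    for i in range(n):
        name = "outlier" if outlier_flags[i] else f"sp{labels[i] + 1}"
        counters[name] = counters.get(name, 0) + 1
        ids.append(f"{name}_{counters[name]}")
        species.append(name)
        locality.append(f"loc{labels[i] + 1}" if not outlier_flags[i] else "locX")

    markers = [f"pc{j // 253}-{70 + (j % 253)}" for j in range(L)]
    matrix = AFLPMatrix(ids, markers, values)
    meta = SpecimenTable(pd.DataFrame({
        "specimen_id": ids,
        "species_label": species,
        "locality_code": locality,
        "latitude": lat,
        "longitude": lon,
        "mito_group": [None] * n,
    }))
    truth = SimTruth(q=q, p=p, labels=labels, outlier_flags=outlier_flags,
                     pop_coordinates=centres)
    return matrix, meta, truth


# ---------------------------------------------------------------------------
# Coalescent gene trees
# ---------------------------------------------------------------------------

def simulate_coalescent_tree(
    species_sizes: Mapping[str, int] | Sequence[int],
    divergence_times: Sequence[float],
    pop_sizes: float | Sequence[float] = 1.0,
    introgression: tuple[str, str, float, float] | None = None,
    seed: int = 1,
) -> GeneTree:
    """Simulate one gene tree under the multispecies coalescent.

    The species tree is sequential: species 1 and 2 merge at
    ``divergence_times[0]``, their ancestor merges with species 3 at
    ``divergence_times[1]``, and so on (times in generations, increasing
    toward the root).  ``pop_sizes`` are haploid effective sizes (scalar or
    per-species; ancestral populations take the scalar or the first value).
    ``introgression = (donor, recipient, time, probability)`` moves each
    recipient lineage present at ``time`` into the donor population with the
    given probability, the standard pulse model: probability 1 at a recent
    time yields shallow coalescence of recipient tips inside the donor clade,
    while no pulse with deep divergences yields only deep discordance.

    Tips are labelled ``<species>_<k>``.
    """
    if isinstance(species_sizes, Mapping):
        names = list(species_sizes)
        counts = [int(species_sizes[s]) for s in names]
    else:
        counts = [int(c) for c in species_sizes]
        names = [f"S{i + 1}" for i in range(len(counts))]
    if any(c < 1 for c in counts):
        raise ValueError("every species needs at least one lineage")
    n_sp = len(names)
    times = [float(t) for t in divergence_times]
    if n_sp > 1 and len(times) != n_sp - 1:
        raise ValueError("need len(species)-1 divergence times")
    if any(t <= 0 for t in times) or any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("divergence times must be positive and increasing")

    sizes = (
        [float(pop_sizes)] * n_sp if np.isscalar(pop_sizes) else [float(s) for s in pop_sizes]
    )
    anc_size = sizes[0]

    dem = msprime.Demography()
    for name, size in zip(names, sizes):
        dem.add_population(name=name, initial_size=size)
    previous = names[0]
    for j, t in enumerate(times):
        anc = f"anc{j + 1}"
        dem.add_population(name=anc, initial_size=anc_size)
        dem.add_population_split(time=t, derived=[previous, names[j + 1]], ancestral=anc)
        previous = anc
    if introgression is not None:
        donor, recipient, t_event, prob = introgression
        if donor not in names or recipient not in names:
            raise ValueError("introgression donor/recipient must be extant species")
        dem.add_mass_migration(time=float(t_event), source=recipient, dest=donor,
                               proportion=float(prob))
    dem.sort_events()

    ts = msprime.sim_ancestry(
        samples={name: c for name, c in zip(names, counts)},
        demography=dem,
        ploidy=1,
        random_seed=int(seed) % (2**31 - 1) or 1,
    )
    t = ts.first()
    newick = t.as_newick()  # samples labelled n<node_id>
    tree = dendropy.Tree.get(data=newick, schema="newick")
    node_pop = {int(u): ts.node(u).population for u in ts.samples()}
    counters: dict[str, int] = {}
    for leaf in tree.leaf_node_iter():
        node_id = int(leaf.taxon.label[1:])
        sp = names[node_pop[node_id]] if node_pop[node_id] < n_sp else names[0]
        counters[sp] = counters.get(sp, 0) + 1
        leaf.taxon.label = f"{sp}_{counters[sp]}"
    tree.is_rooted = True
    return GeneTree(tree)


# ---------------------------------------------------------------------------
# Compositionally heterogeneous alignments
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_composition_alignment(
    taxon_base_freqs: Mapping[str, Sequence[float]],
    n_sites: int,
    shared_fraction: float = 0.0,
    seed: int = 1,
) -> Alignment:
    """Column-i.i.d. alignment with taxon-specific base composition.

    A ``shared_fraction`` of columns is identical across taxa (drawn from the
    mean composition); the remaining columns are drawn independently per taxon
    from that taxon's own composition.  There is no tree: the generator only
    needs to exercise symmetry/homogeneity statistics, not phylogenetic
    signal.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must be in [0, 1]")
    taxa = list(taxon_base_freqs)
    freqs = np.array([taxon_base_freqs[t] for t in taxa], dtype=float)
    if freqs.shape[1] != 4:
        raise ValueError("base frequencies must have 4 entries (A, C, G, T)")
    if not np.allclose(freqs.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("base frequencies must each sum to 1")

    rng = np.random.default_rng(seed)
    n_taxa = len(taxa)
    n_shared = int(round(shared_fraction * n_sites))
    mean_freq = freqs.mean(axis=0)

    cols = np.empty((n_taxa, n_sites), dtype=np.int64)
    shared = rng.choice(4, size=n_shared, p=mean_freq)
    cols[:, :n_shared] = shared[None, :]
    for i in range(n_taxa):
        cols[i, n_shared:] = rng.choice(4, size=n_sites - n_shared, p=freqs[i])
    # shuffle column order so shared columns are not a contiguous block
    perm = rng.permutation(n_sites)
    cols = cols[:, perm]
    seqs = ["".join(_BASES[row]) for row in cols]
    return Alignment(taxa, seqs, frame_offset=0)
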