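"""Dirichlet-process (Chinese-restaurant-process) clustering of specimens.

The number of clusters and the assignment of specimens to clusters are both
random under a Dirichlet-process prior with concentration ``alpha``: in the
collapsed Gibbs sampler each specimen joins an existing cluster with
probability proportional to the cluster size times the Beta-Binomial
posterior predictive of its marker profile (independent Beta(1,1) priors per
marker, matching the Bernoulli phenotype model of the admixture module), or
founds a new cluster with probability proportional to ``alpha`` times the
prior predictive.

The posterior sample of partitions is summarized by the posterior
distribution over the cluster count k and by the *mean partition* — the
partition minimizing the summed partition distance (minimum number of
element reassignments) to all sampled partitions.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import AFLPMatrix
from .partition import Partition, partition_distance

__all__ = [
    "DPPConfig",
    "PartitionSample",
    "solve_concentration",
    "dpp_gibbs",
    "mean_partition",
    "crp_k_distribution",
]


def solve_concentration(n: int, prior_mean_k: float) -> float:
    """Concentration alpha with prior expected cluster count E[k | alpha, n] =
    sum_{i=0}^{n-1} alpha / (alpha + i) equal to ``prior_mean_k``."""
    if not 1.0 <= prior_mean_k <= n:
        raise ValueError("prior mean cluster count must lie in [1, n]")

    def expected_k(a: float) -> float:
        i = np.arange(n)
        return float((a / (a + i)).sum())

    lo, hi = 1e-9, 1e9
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if expected_k(mid) < prior_mean_k:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


@dataclass
class DPPConfig:
    """MCMC configuration; ``concentration`` may be given directly or solved
    from a prior expected cluster count (the explicit, reproducible default
    being E[k] = 5)."""

    concentration: float | None = None
    prior_mean_k: float | None = 5.0
    cycles: int = 1_000_000
    sample_every: int = 100
    burn_in_samples: int = 4_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.concentration is not None and self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        if self.concentration is None and self.prior_mean_k is None:
            raise ValueError("give concentration or prior_mean_k")
        if self.cycles < self.sample_every:
            raise ValueError("cycles must be >= sample_every")

    def alpha_for(self, n: int) -> float:
        if self.concentration is not None:
            return float(self.concentration)
        return solve_concentration(n, float(self.prior_mean_k))

    @classmethod
    def scaled_down(cls, **kwargs) -> "DPPConfig":
        """Short-chain preset for tests and small simulated matrices."""
        base = dict(cycles=4_000, sample_every=2, burn_in_samples=200)
        base.update(kwargs)
        return cls(**base)


@dataclass
class PartitionSample:
    """Posterior sample of partitions with the induced distribution over k."""

    partitions: list[np.ndarray]
    ids: list[str] | None = None
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not self.partitions:
            raise ValueError("empty partition sample")

    @property
    def k_values(self) -> np.ndarray:
        return np.array([len(set(p.tolist())) for p in self.partitions])

    def k_posterior(self) -> dict[int, float]:
        counts = Counter(self.k_values.tolist())
        total = sum(counts.values())
        return {k: c / total for k, c in sorted(counts.items())}

    def posterior_mode_k(self) -> int:
        post = self.k_posterior()
        return max(post, key=lambda k: (post[k], -k))


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by first appearance (canonical form for hashing)."""
    remap: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    return out


def dpp_gibbs(m: AFLPMatrix, cfg: DPPConfig) -> PartitionSample:
    """Collapsed Gibbs sampling of the Dirichlet-process mixture.

    One cycle = one full reassignment scan over specimens.  Partitions are
    recorded every ``cfg.sample_every`` cycles and the first
    ``cfg.burn_in_samples`` recorded samples discarded.  With zero markers the
    sampler reduces exactly to the Chinese-restaurant-process prior.
    """
    X = m.values.astype(np.int64)
    n, L = X.shape
    obs = X >= 0
    x1 = ((X == 1) & obs).astype(np.float64)
    x0 = ((X == 0) & obs).astype(np.float64)
    alpha = cfg.alpha_for(n)
    rng = np.random.default_rng(cfg.seed)

    # all-singletons start: structure is then found by downhill agglomeration,
    # which mixes far better than splitting a merged cluster one element at a
    # time (the prior-only case is unaffected: any start targets the CRP)
    labels = np.arange(n, dtype=np.int64)
    sizes = [1] * n
    s1 = [x1[i].copy() for i in range(n)]
    s0 = [x0[i].copy() for i in range(n)]

    log_prior_pred = -math.log(2.0)  # Beta(1,1) prior predictive per observed marker

    samples: list[np.ndarray] = []
    n_record = cfg.cycles // cfg.sample_every
    for cycle in range(cfg.cycles):
        for i in rng.permutation(n):
            c = labels[i]
            sizes[c] -= 1
            s1[c] -= x1[i]
            s0[c] -= x0[i]
            if sizes[c] == 0:
                # remove empty cluster, compact labels
                sizes.pop(c)
                s1.pop(c)
                s0.pop(c)
                labels[labels > c] -= 1
            C = len(sizes)
            S1 = np.asarray(s1)
            S0 = np.asarray(s0)
            tot = S1 + S0
            # Beta-Binomial predictive of specimen i's profile per cluster
            logpred = (
                x1[i][None, :] * np.log((1.0 + S1) / (2.0 + tot))
                + x0[i][None, :] * np.log((1.0 + S0) / (2.0 + tot))
            ).sum(axis=1)
            n_obs_i = float(obs[i].sum())
            logw = np.empty(C + 1)
            logw[:C] = np.log(np.asarray(sizes, dtype=float)) + logpred
            logw[C] = math.log(alpha) + n_obs_i * log_prior_pred
            g = rng.gumbel(size=C + 1)
            new_c = int((logw + g).argmax())
            if new_c == C:
                sizes.append(1)
                s1.append(x1[i].copy())
                s0.append(x0[i].copy())
            else:
                sizes[new_c] += 1
                s1[new_c] += x1[i]
                s0[new_c] += x0[i]
            labels[i] = new_c
        if (cycle + 1) % cfg.sample_every == 0:
            samples.append(_canonical(labels))
    if len(samples) <= cfg.burn_in_samples:
        raise ValueError("all samples consumed by burn-in; increase cycles")
    kept = samples[cfg.burn_in_samples:]
    return PartitionSample(kept, list(m.specimen_ids), alpha)


def _total_distance(candidate: np.ndarray, uniques: list[np.ndarray], weights: list[int]) -> int:
    return sum(w * partition_distance(candidate, u) for u, w in zip(uniques, weights))


def mean_partition(s: PartitionSample, n_restarts: int = 10, max_passes: int = 20) -> Partition:
    """Partition minimizing the summed partition distance to the sample.

    Search: the best of the ``n_restarts`` most frequent sampled partitions,
    refined by single-element reassignment hill climbing (moves to any
    existing cluster or to a new singleton) until a full pass yields no
    improvement.  Distances are accumulated over unique sampled partitions
    weighted by multiplicity.
    """
    counts = Counter(tuple(p.tolist()) for p in s.partitions)
    uniques = [np.array(t) for t in counts]
    weights = [counts[tuple(u.tolist())] for u in uniques]
    candidates = [np.array(t) for t, _ in counts.most_common(n_restarts)]
    best = min(candidates, key=lambda c: _total_distance(c, uniques, weights))
    best_cost = _total_distance(best, uniques, weights)
    n = len(best)
    for _ in range(max_passes):
        improved = False
        for i in range(n):
            current = best[i]
            options = set(best.tolist()) - {current}
            options.add(max(best) + 1)  # new singleton cluster
            for opt in options:
                trial = best.copy()
                trial[i] = opt
                cost = _total_distance(_canonical(trial), uniques, weights)
                if cost < best_cost:
                    best = _canonical(trial)
                    best_cost = cost
                    improved = True
        if not improved:
            break
    return Partition(best + 1, list(s.ids) if s.ids is not None else None)


def crp_k_distribution(n: int, alpha: float) -> dict[int, float]:
    """Exact Chinese-restaurant-process distribution of the cluster count:
    P(k | n, alpha) = |s(n, k)| alpha^k / prod_{i=0}^{n-1}(alpha + i), with
    |s(n, k)| the unsigned Stirling numbers of the first kind (recursion
    |s(n+1,k)| = n |s(n,k)| + |s(n,k-1)|)."""
    stirling = np.zeros((n + 1, n + 1))
    stirling[0, 0] = 1.0
    for nn in range(1, n + 1):
        for k in range(1, nn + 1):
            stirling[nn, k] = (nn - 1) * stirling[nn - 1, k] + stirling[nn - 1, k - 1]
    denom = np.prod(alpha + np.arange(n))
    return {
        k: float(stirling[n, k] * alpha ** k / denom)
        for k in range(1, n + 1)
        if stirling[n, k] > 0
    }
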