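"""Bayesian population assignment for dominant markers.

A Gibbs sampler over cluster-specific band frequencies with two ancestry
models:

* **without admixture** — each individual belongs wholly to one of K clusters
  (uniform prior over clusters);
* **with admixture** — each individual carries ancestry proportions
  ``q_i ~ Dirichlet(alpha, ..., alpha)`` and every marker (or allele copy)
  has its own latent cluster of origin; the shared concentration ``alpha``
  is updated by a Metropolis step unless fixed.

Band frequencies get independent Beta(1,1) priors.  Two emission models are
available: the default ``phenotype`` model treats the one-bit dominant band
directly as Bernoulli(p_kl); the opt-in ``recessive-diploid`` model treats
the band as presence of at least one of two allele copies
(P(band) = 1 − (1 − p_kl)²), with allele states imputed by data
augmentation.

Per run the sampler records the post-burn-in log-likelihood series; the
model-evidence proxy is ``L(K) = mean − variance/2`` of that series, and
Evanno's ΔK — the mean absolute second difference of L(K) across runs over
the standard deviation of L(K) — locates the uppermost level of structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .io_formats import AFLPMatrix, SpecimenTable
from .partition import Partition

__all__ = [
    "BayesConfig",
    "AncestryMatrix",
    "RunTrace",
    "DeltaKTable",
    "fit_structure_model",
    "estimate_lnP",
    "run_lnp_table",
    "evanno_delta_k",
    "pairwise_admixture",
]


@dataclass
class BayesConfig:
    """MCMC configuration for the clustering sampler.

    Defaults mirror the standard protocol for this kind of dataset: 10 runs of
    100,000 iterations after 10,000 burn-in for the ΔK scan.  Those are
    hours-scale on large matrices; :meth:`scaled_down` gives a preset suitable
    for tests and small simulated data.
    """

    K: int = 2
    admixture: bool = False
    iterations: int = 100_000
    burn_in: int = 10_000
    thin: int = 10
    runs: int = 10
    alpha: float | None = None        # fixed alpha; None = infer by Metropolis
    alpha_max: float = 10.0
    alpha_step: float = 0.025
    alpha_init: float = 1.0
    emission: str = "phenotype"       # or "recessive-diploid"
    collect_q: bool = False           # keep thinned q samples on the trace
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not self.iterations > self.burn_in >= 0:
            raise ValueError("need iterations > burn_in >= 0")
        if self.runs < 1 or self.thin < 1:
            raise ValueError("runs and thin must be >= 1")
        if self.emission not in ("phenotype", "recessive-diploid"):
            raise ValueError(f"unknown emission model {self.emission!r}")

    @classmethod
    def scaled_down(cls, **kwargs) -> "BayesConfig":
        """Short-chain preset: 10,000 iterations, 1,000 burn-in, thin 10."""
        base = dict(iterations=10_000, burn_in=1_000, thin=10, runs=3)
        base.update(kwargs)
        return cls(**base)


@dataclass
class AncestryMatrix:
    """Posterior-mean ancestry proportions, one row per specimen."""

    ids: list[str]
    q: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape[0] != len(self.ids):
            raise ValueError("q rows must match ids")
        if ((self.q < -1e-12) | (self.q > 1 + 1e-12)).any():
            raise ValueError("ancestry entries must lie in [0, 1]")
        if not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("ancestry rows must sum to 1")


@dataclass
class RunTrace:
    """Post-burn-in sampled log-likelihoods of one run."""

    logliks: np.ndarray
    alpha_samples: np.ndarray | None = None
    alpha_acceptance: float | None = None
    q_samples: np.ndarray | None = None

    @property
    def lnp(self) -> float:
        return estimate_lnP(self.logliks)


def estimate_lnP(trace: Sequence[float] | np.ndarray) -> float:
    """Model-evidence proxy: mean of the log-likelihood series minus half its
    (population) variance."""
    t = np.asarray(trace, dtype=float)
    if t.size == 0:
        raise ValueError("empty trace")
    est = float(t.mean() - t.var(ddof=0) / 2.0)
    if not math.isfinite(est):
        raise ValueError("non-finite evidence estimate")
    return est


# ---------------------------------------------------------------------------
# Gibbs sampler internals
# ---------------------------------------------------------------------------

def _gumbel_argmax(logw: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Exact categorical sampling along the last axis via the Gumbel-max trick."""
    g = rng.gumbel(size=logw.shape)
    return (logw + g).argmax(axis=-1)


def _sample_counts_recessive(x1, p_z, rng):
    """Number of band-carrying allele copies (1 or 2) at present cells."""
    prob2 = p_z / (2.0 - p_z)
    return 1 + (rng.random(p_z.shape) < prob2).astype(np.int64)


def _chain(
    X: np.ndarray, cfg: BayesConfig, rng: np.random.Generator
) -> tuple[np.ndarray, RunTrace, np.ndarray]:
    """One MCMC run.  Returns (posterior-mean q, trace, modal/argmax labels)."""
    n, L = X.shape
    K = cfg.K
    obs = X >= 0
    X1 = ((X == 1) & obs).astype(float)
    X0 = ((X == 0) & obs).astype(float)
    recessive = cfg.emission == "recessive-diploid"

    n_samples = (cfg.iterations - cfg.burn_in) // cfg.thin
    logliks = np.empty(n_samples, dtype=float)
    alpha_trace = np.empty(n_samples, dtype=float) if cfg.admixture else None
    s_idx = 0

    p = rng.beta(1.0, 1.0, size=(K, L))
    eps = 1e-12

    if not cfg.admixture:
        z = rng.integers(0, K, size=n)
        z_counts = np.zeros((n, K), dtype=np.int64)
        for it in range(cfg.iterations):
            # p | z
            Zoh = np.zeros((n, K))
            Zoh[np.arange(n), z] = 1.0
            if recessive:
                p_z = np.clip(p[z, :], eps, 1 - eps)
                copies = _sample_counts_recessive(X1, p_z, rng) * X1
                n1 = Zoh.T @ copies
                n0 = Zoh.T @ (X1 * 2.0 - copies + X0 * 2.0)
            else:
                n1 = Zoh.T @ X1
                n0 = Zoh.T @ X0
            p = rng.beta(1.0 + n1, 1.0 + n0)
            p = np.clip(p, eps, 1 - eps)
            # z | p
            if recessive:
                band = 1.0 - (1.0 - p) ** 2
            else:
                band = p
            ll_ik = X1 @ np.log(band).T + X0 @ np.log(1.0 - band).T
            z = _gumbel_argmax(ll_ik, rng) if K > 1 else np.zeros(n, dtype=int)
            if it >= cfg.burn_in:
                z_counts[np.arange(n), z] += 1
                if (it - cfg.burn_in) % cfg.thin == 0 and s_idx < n_samples:
                    # likelihood given p, marginal over cluster membership
                    # under its uniform prior (consistent with the admixture
                    # trace, which marginalizes per-marker origins given q)
                    logliks[s_idx] = float(
                        logsumexp(ll_ik - math.log(K), axis=1).sum()
                    )
                    s_idx += 1
        q_mean = z_counts / max(z_counts.sum(axis=1)[0], 1)
        # modal assignment, ties toward the lower cluster label (argmax does this)
        labels = z_counts.argmax(axis=1)
        return q_mean, RunTrace(logliks[:s_idx]), labels

    # --- admixture model ---
    alpha = cfg.alpha if cfg.alpha is not None else cfg.alpha_init
    infer_alpha = cfg.alpha is None
    q = rng.dirichlet(np.full(K, alpha), size=n)
    q = np.clip(q, eps, 1.0)
    q /= q.sum(axis=1, keepdims=True)
    q_accum = np.zeros((n, K))
    q_store = np.empty((n_samples, n, K)) if cfg.collect_q else None
    n_accum = 0
    accepts = 0
    proposals = 0
    ploidy = 2 if recessive else 1

    for it in range(cfg.iterations):
        logq = np.log(q)
        logp1 = np.log(p)
        logp0 = np.log(1.0 - p)
        counts = np.zeros((n, K))
        n1 = np.zeros((K, L))
        n0 = np.zeros((K, L))
        if not recessive:
            # per-marker origin: weights q_ik * p or q_ik * (1-p)
            logw = (
                logq[:, :, None]
                + X1[:, None, :] * logp1[None, :, :]
                + X0[:, None, :] * logp0[None, :, :]
            )  # n x K x L
            Zo = _gumbel_argmax(np.transpose(logw, (0, 2, 1)), rng)  # n x L
            for k in range(K):
                mk = (Zo == k) & obs
                counts[:, k] = mk.sum(axis=1)
                n1[k] = (X1 * mk).sum(axis=0)
                n0[k] = (X0 * mk).sum(axis=0)
        else:
            # two allele copies per marker, each with its own origin
            absent_w = logq[:, :, None] + logp0[None, :, :]  # n x K x L
            for copy in range(2):
                # absent cells: copies independent, weight q_k (1-p_kl)
                Zc = _gumbel_argmax(np.transpose(absent_w, (0, 2, 1)), rng)
                if copy == 0:
                    # present cells: joint origin pair then allele states
                    pres = (X == 1)
                    if pres.any():
                        ii, ll_ = np.nonzero(pres)
                        qi = q[ii]                       # m x K
                        pl = p[:, ll_].T                 # m x K
                        joint = (
                            qi[:, :, None] * qi[:, None, :]
                            * (1.0 - (1.0 - pl)[:, :, None] * (1.0 - pl)[:, None, :])
                        )  # m x K x K
                        flat = joint.reshape(len(ii), K * K)
                        pick = _gumbel_argmax(np.log(np.clip(flat, 1e-300, None)), rng)
                        k1 = pick // K
                        k2 = pick % K
                        p1 = pl[np.arange(len(ii)), k1]
                        p2 = pl[np.arange(len(ii)), k2]
                        wa = np.stack(
                            [p1 * (1 - p2), (1 - p1) * p2, p1 * p2], axis=1
                        )
                        astate = _gumbel_argmax(np.log(np.clip(wa, 1e-300, None)), rng)
                        a1 = (astate != 1).astype(np.int64)   # copy 1 carries band
                        a2 = (astate != 0).astype(np.int64)   # copy 2 carries band
                        pres_origin = (ii, ll_, k1, k2, a1, a2)
                    else:
                        pres_origin = None
                if pres_origin is not None:
                    ii, ll_, k1, k2, a1, a2 = pres_origin
                    kc = k1 if copy == 0 else k2
                    ac = a1 if copy == 0 else a2
                    Zc[ii, ll_] = kc
                    np.add.at(n1, (kc, ll_), ac.astype(float))
                    np.add.at(n0, (kc, ll_), (1.0 - ac).astype(float))
                for k in range(K):
                    mk = (Zc == k) & (X == 0)
                    n0[k] += mk.sum(axis=0).astype(float)
                    counts[:, k] += ((Zc == k) & obs).sum(axis=1)
        # q | origins (row-wise Dirichlet via gamma draws)
        gam = rng.standard_gamma(alpha + counts)
        q = gam / gam.sum(axis=1, keepdims=True)
        q = np.clip(q, eps, 1.0)
        q /= q.sum(axis=1, keepdims=True)
        # p | origins
        p = rng.beta(1.0 + n1, 1.0 + n0)
        p = np.clip(p, eps, 1 - eps)
        # alpha | q (Metropolis, shared alpha, uniform prior on (0, alpha_max])
        if infer_alpha:
            proposals += 1
            prop = alpha + rng.normal(0.0, cfg.alpha_step)
            if 0.0 < prop <= cfg.alpha_max:
                cur = n * (gammaln(K * alpha) - K * gammaln(alpha)) + (
                    alpha - 1.0
                ) * np.log(q).sum()
                new = n * (gammaln(K * prop) - K * gammaln(prop)) + (
                    prop - 1.0
                ) * np.log(q).sum()
                if math.log(rng.random() + 1e-300) < new - cur:
                    alpha = prop
                    accepts += 1
        if it >= cfg.burn_in:
            q_accum += q
            n_accum += 1
            if (it - cfg.burn_in) % cfg.thin == 0 and s_idx < n_samples:
                if recessive:
                    miss_copy = q @ (1.0 - p)          # P(one copy lacks band)
                    band_prob = 1.0 - miss_copy ** 2
                else:
                    band_prob = q @ p
                band_prob = np.clip(band_prob, eps, 1 - eps)
                ll = float(
                    (X1 * np.log(band_prob)).sum() + (X0 * np.log(1 - band_prob)).sum()
                )
                logliks[s_idx] = ll
                if alpha_trace is not None:
                    alpha_trace[s_idx] = alpha
                if q_store is not None:
                    q_store[s_idx] = q
                s_idx += 1
    q_mean = q_accum / max(n_accum, 1)
    labels = q_mean.argmax(axis=1)
    trace = RunTrace(
        logliks[:s_idx],
        alpha_trace[:s_idx] if alpha_trace is not None else None,
        accepts / proposals if proposals else None,
        q_store[:s_idx] if q_store is not None else None,
    )
    return q_mean, trace, labels


def _align_to(reference: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Greedy column permutation of q maximizing agreement with reference."""
    K = q.shape[1]
    perm = [-1] * K
    used = set()
    sim = reference.T @ q  # K x K column similarity
    for _ in range(K):
        best = None
        for a in range(K):
            if perm[a] != -1:
                continue
            for b in range(K):
                if b in used:
                    continue
                if best is None or sim[a, b] > best[2]:
                    best = (a, b, sim[a, b])
        perm[best[0]] = best[1]
        used.add(best[1])
    return q[:, perm]


def fit_structure_model(
    m: AFLPMatrix, cfg: BayesConfig
) -> tuple[AncestryMatrix, RunTrace, Partition]:
    """Fit the clustering model; with ``cfg.runs > 1`` the run with the highest
    evidence estimate L(K) is returned (remaining runs are greedily aligned to
    it before discarding, so reported quantities are label-invariant)."""
    X = m.values.astype(np.int64)
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.runs)
    best = None
    for r in range(cfg.runs):
        rng = np.random.default_rng(seeds[r])
        q_mean, trace, labels = _chain(X, cfg, rng)
        if best is None or trace.lnp > best[1].lnp:
            best = (q_mean, trace, labels)
    q_mean, trace, labels = best
    ancestry = AncestryMatrix(list(m.specimen_ids), q_mean / q_mean.sum(axis=1, keepdims=True))
    part = Partition(labels + 1, list(m.specimen_ids))
    return ancestry, trace, part


def run_lnp_table(
    m: AFLPMatrix, k_values: Sequence[int], cfg: BayesConfig
) -> pd.DataFrame:
    """Independent-run evidence estimates for each K: a runs x K table of L(K)."""
    rows = np.empty((cfg.runs, len(k_values)))
    root = np.random.SeedSequence(cfg.seed)
    for j, K in enumerate(k_values):
        sub = np.random.SeedSequence(entropy=root.entropy, spawn_key=(K,)).spawn(cfg.runs)
        kcfg = replace(cfg, K=K)
        X = m.values.astype(np.int64)
        for r in range(cfg.runs):
            rng = np.random.default_rng(sub[r])
            _, trace, _ = _chain(X, kcfg, rng)
            rows[r, j] = trace.lnp
    return pd.DataFrame(rows, columns=list(k_values),
                        index=[f"run{r + 1}" for r in range(cfg.runs)])


@dataclass
class DeltaKTable:
    """Per-K evidence summary with Evanno's ΔK for interior K values."""

    table: pd.DataFrame  # columns: K, mean_L, sd_L, delta_k
    flagged: list[int] = field(default_factory=list)  # K where sd = 0

    @property
    def best_k(self) -> int:
        valid = self.table.dropna(subset=["delta_k"])
        valid = valid[~valid["K"].isin(self.flagged)]
        if valid.empty:
            raise ValueError("no interior K with defined delta K")
        return int(valid.loc[valid["delta_k"].idxmax(), "K"])


def evanno_delta_k(tables: pd.DataFrame | Mapping[int, Sequence[float]]) -> DeltaKTable:
    """Evanno's ΔK from a runs x K table of L(K) estimates.

    ΔK(K) = mean over runs of |L(K+1) − 2 L(K) + L(K−1)| divided by the
    standard deviation (ddof=1) of L(K) over runs; defined for interior K
    only.  K values with zero run-to-run standard deviation are flagged and
    excluded from the argmax.
    """
    if isinstance(tables, Mapping):
        df = pd.DataFrame({int(k): list(v) for k, v in tables.items()})
    else:
        df = tables.copy()
        df.columns = [int(c) for c in df.columns]
    ks = sorted(df.columns)
    if len(ks) < 3:
        raise ValueError("need at least 3 consecutive K values")
    if len(df) < 2:
        raise ValueError("need at least 2 runs per K")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("K values must be consecutive")
    mean_l = df[ks].mean(axis=0)
    sd_l = df[ks].std(axis=0, ddof=1)
    rows = []
    flagged = []
    for k in ks:
        dk = np.nan
        if ks[0] < k < ks[-1]:
            second = (df[k + 1] - 2.0 * df[k] + df[k - 1]).abs().mean()
            if sd_l[k] == 0:
                flagged.append(k)
            else:
                dk = float(second / sd_l[k])
        rows.append(dict(K=k, mean_L=float(mean_l[k]), sd_L=float(sd_l[k]), delta_k=dk))
    return DeltaKTable(pd.DataFrame(rows), flagged)


def pairwise_admixture(
    m: AFLPMatrix,
    meta: SpecimenTable,
    species_a: str,
    species_b: str,
    cfg: BayesConfig | None = None,
) -> tuple[AncestryMatrix, pd.DataFrame]:
    """K=2 admixture scan between two species, the introgression screen.

    The admixture model is fitted to the two species' specimens only, the run
    with the highest evidence among ``cfg.runs`` is analysed, clusters are
    anchored to species by majority assignment, and each individual's
    inferred ancestry in its own species' cluster is reported.
    """
    if cfg is None:
        cfg = BayesConfig(K=2, admixture=True, runs=5)
    if cfg.K != 2:
        raise ValueError("pairwise admixture requires K = 2")
    cfg = replace(cfg, admixture=True)
    species = meta.species_of()
    ids_a = [s for s in m.specimen_ids if species.get(s) == species_a]
    ids_b = [s for s in m.specimen_ids if species.get(s) == species_b]
    for name, ids in ((species_a, ids_a), (species_b, ids_b)):
        if not ids:
            raise ValueError(f"species {name!r} absent from the matrix/metadata")
        if len(ids) < 2:
            import warnings

            warnings.warn(f"species {name!r} has fewer than 2 specimens")
    sub = m.subset(ids_a + ids_b)
    ancestry, trace, part = fit_structure_model(sub, cfg)
    # anchor cluster 0 to species_a by mean ancestry of its members
    na = len(ids_a)
    if ancestry.q[:na, 0].mean() < ancestry.q[na:, 0].mean():
        q = ancestry.q[:, ::-1].copy()
    else:
        q = ancestry.q.copy()
    ancestry = AncestryMatrix(sub.specimen_ids, q)
    own = np.concatenate([q[:na, 0], q[na:, 1]])
    report = pd.DataFrame({
        "specimen_id": sub.specimen_ids,
        "species": [species_a] * na + [species_b] * len(ids_b),
        "own_cluster_ancestry": own,
        "foreign_ancestry": 1.0 - own,
    })
    return ancestry, report
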