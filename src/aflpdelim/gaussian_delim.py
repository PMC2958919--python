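"""Gaussian-clustering species delimitation.

The strategy: embed Jaccard distances in a low-dimensional space by
non-metric multidimensional scaling (four dimensions is the usual choice for
dominant genetic markers), then fit Gaussian mixture models for a range of
cluster counts and covariance families, optionally with a uniform "noise"
component that absorbs outlier specimens, and pick the model with the best
BIC.  Genotypic clusters of the selected model are the provisional species.

BIC convention: ``2 * loglik - n_params * ln(n)``, higher is better (the
mclust tradition); the convention is carried in the fit object so reported
values are unambiguous.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import isotonic_regression
from scipy.special import gammaln

from .distance_nets import DistanceMatrix, jaccard_matrix
from .io_formats import AFLPMatrix
from .partition import Partition

logger = logging.getLogger(__name__)

__all__ = [
    "Embedding",
    "MixtureFit",
    "Partition",
    "nmds_embed",
    "nnclean_flag_noise",
    "fit_gaussian_mixture_bic",
    "delimit_gaussian",
    "COVARIANCE_FAMILIES",
]

COVARIANCE_FAMILIES = ("spherical-equal", "spherical", "diagonal", "full")

#: NMDS defaults: number of initializations, stress tolerance, iteration cap.
NMDS_STARTS = 20
NMDS_TOL = 1e-6
NMDS_MAX_ITER = 500


@dataclass
class Embedding:
    """NMDS configuration: n x d coordinates with the final Kruskal stress-1."""

    coords: np.ndarray
    stress: float
    dim: int
    n_starts: int
    ids: list[str] | None = None
    stress_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stress < 0:
            raise ValueError("stress must be non-negative")


@dataclass
class MixtureFit:
    """Selected Gaussian mixture: parameters, BIC and the hard partition."""

    k: int
    family: str
    weights: np.ndarray
    means: np.ndarray
    covariances: list[np.ndarray]
    noise_proportion: float
    noise_density: float
    loglik: float
    bic: float
    partition: Partition
    bic_convention: str = "2*loglik - params*ln(n), maximize"
    bic_table: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = float(self.weights.sum() + self.noise_proportion)
        if self.k > 0 and not math.isclose(total, 1.0, abs_tol=1e-8):
            raise ValueError("component weights plus noise proportion must sum to 1")


# ---------------------------------------------------------------------------
# Non-metric multidimensional scaling (Kruskal stress-1, majorization)
# ---------------------------------------------------------------------------

def _pairwise(X: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


def _classical_mds(D: np.ndarray, dim: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dim]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def _nmds_single(D: np.ndarray, X0: np.ndarray, tol: float, max_iter: int):
    """Majorization with monotone (isotonic) regression; returns the final
    configuration, stress-1, and the per-iteration stress sequence."""
    n = D.shape[0]
    iu = np.triu_indices(n, 1)
    delta = D[iu]
    order = np.argsort(delta, kind="stable")
    X = X0.copy()
    history: list[float] = []
    stress = np.inf
    for _ in range(max_iter):
        d = _pairwise(X)[iu]
        # monotone regression of configuration distances on observed ranks
        fit = isotonic_regression(d[order]).x
        dhat = np.empty_like(d)
        dhat[order] = fit
        denom = float((d ** 2).sum())
        if denom <= 0:
            # collapsed configuration: a perfect fit only if the observed
            # dissimilarities are all zero too, otherwise a failed start
            stress = 0.0 if float((delta ** 2).sum()) == 0 else np.inf
            history.append(stress)
            break
        new_stress = math.sqrt(float(((d - dhat) ** 2).sum()) / denom)
        history.append(new_stress)
        if abs(stress - new_stress) < tol:
            stress = new_stress
            break
        stress = new_stress
        # Guttman transform toward the disparities
        full_dhat = np.zeros((n, n))
        full_dhat[iu] = dhat
        full_dhat += full_dhat.T
        dX = _pairwise(X)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dX > 0, full_dhat / np.where(dX > 0, dX, 1.0), 0.0)
        B = -ratio
        np.fill_diagonal(B, ratio.sum(axis=1))
        X = (B @ X) / n
        X -= X.mean(axis=0)
    return X, stress, history


def nmds_embed(
    d: DistanceMatrix,
    dim: int = 4,
    starts: int = NMDS_STARTS,
    seed: int = 0,
    tol: float = NMDS_TOL,
    max_iter: int = NMDS_MAX_ITER,
) -> Embedding:
    """Embed a distance matrix by non-metric MDS minimizing Kruskal stress-1.

    One start from the classical-scaling configuration plus ``starts - 1``
    random starts; the lowest-stress solution is returned.  Degenerate case
    ``dim >= n``: any configuration fits perfectly, stress 0 is returned with
    a warning.
    """
    if dim < 1 or starts < 1:
        raise ValueError("dim and starts must be >= 1")
    n = d.n
    if dim >= n:
        logger.warning("embedding dimension %d >= n (%d): degenerate, stress 0", dim, n)
        coords = np.zeros((n, dim))
        coords[:, : n - 1] = _classical_mds(d.values, min(dim, n - 1))
        return Embedding(coords, 0.0, dim, 1, list(d.ids))
    rng = np.random.default_rng(seed)
    scale = d.values[d.values > 0].mean() if (d.values > 0).any() else 1.0
    best = None
    for s in range(starts):
        X0 = (
            _classical_mds(d.values, dim)
            if s == 0
            else rng.standard_normal((n, dim)) * scale
        )
        X, stress, history = _nmds_single(d.values, X0, tol, max_iter)
        if best is None or stress < best[1]:
            best = (X, stress, history)
    X, stress, history = best
    # stress-1 is scale-invariant; return the configuration on the scale of
    # the observed dissimilarities so downstream density models see sensible
    # absolute coordinates even for (near-)degenerate solutions
    iu = np.triu_indices(n, 1)
    dX = _pairwise(X)[iu]
    ssd = float((dX ** 2).sum())
    if ssd > 0:
        X = X * math.sqrt(float((d.values[iu] ** 2).sum()) / ssd)
    return Embedding(X, stress, dim, starts, list(d.ids), history)


# ---------------------------------------------------------------------------
# Nearest-neighbour noise detection (Poisson-process mixture on k-NN distances)
# ---------------------------------------------------------------------------

def nnclean_flag_noise(
    coords: Embedding | np.ndarray, k_nn: int = 5, max_iter: int = 200, tol: float = 1e-10
) -> np.ndarray:
    """Flag scattered (noise) points from k-th nearest-neighbour distances.

    Under a homogeneous Poisson process of rate lambda in p dimensions the
    rescaled k-th nearest-neighbour distance ``D^p`` is Gamma(k, rate
    proportional to lambda).  A two-component mixture of such densities —
    a dense "feature" process and a sparse "clutter" process — is fitted by
    EM and each point classified by its posterior; points assigned to the
    sparse component are flagged as noise.
    """
    X = coords.coords if isinstance(coords, Embedding) else np.asarray(coords, dtype=float)
    n, p = X.shape
    if not 1 <= k_nn < n:
        raise ValueError("k_nn must satisfy 1 <= k_nn < n")
    D = _pairwise(X)
    np.fill_diagonal(D, np.inf)
    dk = np.sort(D, axis=1)[:, k_nn - 1]
    if np.max(dk) <= 0:
        return np.zeros(n, dtype=bool)
    T = dk ** p  # Gamma(k_nn, rate) up to the shared volume constant
    T = np.clip(T, 1e-300, None)
    # init: split at the median
    med = np.median(T)
    hi = T > med
    lam = np.array([
        k_nn / max(T[~hi].mean(), 1e-12) if (~hi).any() else 1.0,
        k_nn / max(T[hi].mean(), 1e-12) if hi.any() else 0.5,
    ])  # [feature (dense), clutter (sparse)]
    pi = np.array([max((~hi).mean(), 1e-3), max(hi.mean(), 1e-3)])
    pi /= pi.sum()
    prev = -np.inf
    for _ in range(max_iter):
        logpdf = (
            k_nn * np.log(lam)[None, :]
            + (k_nn - 1) * np.log(T)[:, None]
            - lam[None, :] * T[:, None]
            - gammaln(k_nn)
        )
        logw = np.log(pi)[None, :] + logpdf
        m = logw.max(axis=1, keepdims=True)
        ll = float((m.squeeze() + np.log(np.exp(logw - m).sum(axis=1))).sum())
        gamma = np.exp(logw - m)
        gamma /= gamma.sum(axis=1, keepdims=True)
        pi = gamma.mean(axis=0)
        lam = k_nn * gamma.sum(axis=0) / np.clip((gamma * T[:, None]).sum(axis=0), 1e-300, None)
        if abs(ll - prev) < tol:
            break
        prev = ll
    clutter = int(np.argmin(lam))  # sparse process has the smaller rate
    return gamma[:, clutter] > 0.5


# ---------------------------------------------------------------------------
# Gaussian mixture with optional uniform noise component
# ---------------------------------------------------------------------------

def _component_logpdf(X: np.ndarray, mean: np.ndarray, cov: np.ndarray, family: str) -> np.ndarray:
    d = X.shape[1]
    diff = X - mean
    if family in ("spherical-equal", "spherical"):
        s2 = float(cov[0, 0])
        return -0.5 * (d * math.log(2 * math.pi * s2) + (diff ** 2).sum(axis=1) / s2)
    if family == "diagonal":
        var = np.diag(cov)
        return -0.5 * (
            d * math.log(2 * math.pi)
            + np.log(var).sum()
            + ((diff ** 2) / var).sum(axis=1)
        )
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular covariance")
    sol = np.linalg.solve(cov, diff.T).T
    return -0.5 * (d * math.log(2 * math.pi) + logdet + (diff * sol).sum(axis=1))


def _n_params(k: int, d: int, family: str, noise: bool) -> int:
    if k == 0:
        return 0
    mixing = k - 1 + (1 if noise else 0)
    means = k * d
    cov = {
        "spherical-equal": 1,
        "spherical": k,
        "diagonal": k * d,
        "full": k * d * (d + 1) // 2,
    }[family]
    return mixing + means + cov


def _var_floor(X: np.ndarray) -> float:
    """Covariance regularization floor: 1e-6 of the data's own variance (the
    customary EM regularization), keeping collapsed components from driving
    the likelihood unbounded."""
    return max(float(X.var()) * 1e-6, 1e-300)


def _m_step_cov(X, gamma_k, mean, family):
    floor = _var_floor(X)
    diff = X - mean
    nk = gamma_k.sum()
    if family in ("spherical-equal", "spherical"):
        s2 = float((gamma_k * (diff ** 2).sum(axis=1)).sum() / (nk * X.shape[1]))
        return np.eye(X.shape[1]) * max(s2, floor)
    if family == "diagonal":
        var = (gamma_k[:, None] * diff ** 2).sum(axis=0) / nk
        return np.diag(np.clip(var, floor, None))
    cov = (gamma_k[:, None] * diff).T @ diff / nk
    return cov + np.eye(X.shape[1]) * floor


def _fit_one(
    X: np.ndarray,
    k: int,
    family: str,
    noise: bool,
    noise_flags: np.ndarray | None,
    max_iter: int = 200,
    tol: float = 1e-8,
):
    """EM for one (k, family); returns dict or None on degeneracy."""
    n, d = X.shape
    lo, hi = X.min(axis=0), X.max(axis=0)
    volume = float(np.prod(np.clip(hi - lo, 1e-12, None)))
    log_unif = -math.log(volume)

    if k == 0:
        if not noise:
            return None
        ll = n * log_unif
        return dict(k=0, family=family, weights=np.zeros(0), means=np.zeros((0, d)),
                    covs=[], pi0=1.0, loglik=ll,
                    bic=2 * ll - _n_params(0, d, family, noise) * math.log(n),
                    resp=np.ones((n, 1)), log_unif=log_unif)

    core = np.ones(n, dtype=bool)
    if noise and noise_flags is not None and noise_flags.any() and (~noise_flags).sum() > k:
        core = ~noise_flags
    Z = linkage(X[core], method="ward")
    init = fcluster(Z, t=k, criterion="maxclust")
    labels = np.zeros(n, dtype=int)
    labels[core] = init
    pi0 = float((labels == 0).mean()) if noise else 0.0
    weights = np.array([(labels == c).mean() for c in range(1, k + 1)])
    if weights.sum() <= 0:
        return None
    weights = weights / weights.sum() * (1.0 - pi0)
    means = np.array([
        X[labels == c].mean(axis=0) if (labels == c).any() else X.mean(axis=0)
        for c in range(1, k + 1)
    ])
    covs = []
    for c in range(1, k + 1):
        members = labels == c
        g = members.astype(float)
        if g.sum() < 2:
            covs.append(np.eye(d) * max(X.var(), _var_floor(X)))
        else:
            covs.append(_m_step_cov(X, g, X[members].mean(axis=0), family))

    prev = -np.inf
    loglik = -np.inf
    resp = None
    try:
        for _ in range(max_iter):
            logp = np.empty((n, k + (1 if noise else 0)))
            for c in range(k):
                logp[:, c] = math.log(max(weights[c], 1e-300)) + _component_logpdf(
                    X, means[c], covs[c], family
                )
            if noise:
                logp[:, k] = math.log(max(pi0, 1e-300)) + log_unif
            m = logp.max(axis=1, keepdims=True)
            dens = np.exp(logp - m)
            loglik = float((m.squeeze() + np.log(dens.sum(axis=1))).sum())
            resp = dens / dens.sum(axis=1, keepdims=True)
            if abs(loglik - prev) < tol * max(1.0, abs(loglik)):
                break
            prev = loglik
            nk = resp[:, :k].sum(axis=0)
            if (nk < 1e-6).any():
                return None
            weights = nk / n
            if noise:
                pi0 = float(resp[:, k].mean())
            means = (resp[:, :k].T @ X) / nk[:, None]
            if family == "spherical-equal":
                num = sum(
                    (resp[:, c] * ((X - means[c]) ** 2).sum(axis=1)).sum() for c in range(k)
                )
                s2 = max(num / (nk.sum() * d), _var_floor(X))
                covs = [np.eye(d) * s2 for _ in range(k)]
            else:
                covs = [_m_step_cov(X, resp[:, c], means[c], family) for c in range(k)]
    except np.linalg.LinAlgError:
        return None
    if not np.isfinite(loglik):
        return None
    bic = 2 * loglik - _n_params(k, d, family, noise) * math.log(n)
    return dict(k=k, family=family, weights=weights, means=means, covs=covs,
                pi0=pi0, loglik=loglik, bic=bic, resp=resp, log_unif=log_unif)


def fit_gaussian_mixture_bic(
    coords: Embedding | np.ndarray,
    k_range=None,
    families=COVARIANCE_FAMILIES,
    noise: bool = False,
    seed: int = 0,
    k_nn: int = 5,
) -> MixtureFit:
    """Scan cluster counts and covariance families, return the best-BIC model.

    For each k the EM is initialized from Ward hierarchical clustering; with
    ``noise=True`` a uniform component over the data's bounding box is added,
    initialized from the nearest-neighbour clean flags, and k = 0 (noise-only
    model) enters the scan.  Hard assignments are maximum-posterior, noise
    labelled 0.
    """
    X = coords.coords if isinstance(coords, Embedding) else np.asarray(coords, dtype=float)
    ids = coords.ids if isinstance(coords, Embedding) else None
    n = X.shape[0]
    if k_range is None:
        k_range = range(0 if noise else 1, min(100, n - 1) + 1)
    k_range = [k for k in k_range]
    if not k_range:
        raise ValueError("empty k_range")
    if any(k > n - 1 or k < 0 for k in k_range):
        raise ValueError("k_range must lie within [0, n-1]")
    noise_flags = nnclean_flag_noise(X, k_nn=min(k_nn, n - 1)) if noise else None

    best = None
    table: dict[tuple[int, str], float] = {}
    for k in k_range:
        fams = families if k > 0 else (families[0],)
        for family in fams:
            fit = _fit_one(X, k, family, noise, noise_flags)
            if fit is None:
                logger.info("k=%d family=%s skipped (degenerate fit)", k, family)
                continue
            table[(k, family)] = fit["bic"]
            if best is None or fit["bic"] > best["bic"]:
                best = fit
    if best is None:
        raise RuntimeError("no mixture model could be fitted")

    k = best["k"]
    if k == 0:
        labels = np.zeros(n, dtype=int)
    else:
        amax = np.asarray(best["resp"]).argmax(axis=1)
        labels = np.where(amax < k, amax + 1, 0)
    part = Partition(labels, list(ids) if ids is not None else None)
    return MixtureFit(
        k=k,
        family=best["family"],
        weights=np.asarray(best["weights"], dtype=float),
        means=np.asarray(best["means"], dtype=float),
        covariances=[np.asarray(c) for c in best["covs"]],
        noise_proportion=float(best["pi0"]),
        noise_density=math.exp(best["log_unif"]),
        loglik=float(best["loglik"]),
        bic=float(best["bic"]),
        partition=part,
        bic_table=table,
    )


def delimit_gaussian(
    m: AFLPMatrix,
    dim: int = 4,
    noise: bool = False,
    seed: int = 0,
    k_range=None,
    starts: int = NMDS_STARTS,
    families=COVARIANCE_FAMILIES,
) -> tuple[Partition, MixtureFit, Embedding]:
    """Full Gaussian-delimitation pipeline on an AFLP matrix.

    Composition: Jaccard distances -> 4-D non-metric MDS -> BIC-selected
    Gaussian mixture (optionally with a uniform noise component).  All
    intermediates are returned for inspection.
    """
    d = jaccard_matrix(m)
    emb = nmds_embed(d, dim=dim, starts=starts, seed=seed)
    fit = fit_gaussian_mixture_bic(emb, k_range=k_range, families=families,
                                   noise=noise, seed=seed)
    return fit.partition, fit, emb
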