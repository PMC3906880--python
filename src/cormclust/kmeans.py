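"""Lloyd's K-means on averaged profiles, and its classification-EM reading.

K-means cannot consume a replicated longitudinal layout directly: each
gene's replicate profiles must first be averaged into a single vector.
:func:`average_replicates` performs that collapse; :func:`fit_kmeans` is a
plain, deterministic Lloyd implementation; and
:func:`kmeans_as_classification_em` runs the equivalent constrained mixture
fit (saturated design, shared scalar variance, equal proportions, hard
assignment) through the EM machinery, which reproduces Lloyd's labels
exactly under matched initialization.

Both routes use the same expanded-form squared distances, the same
lowest-index tie rule, and the same empty-cluster reseeding (move the point
that fits worst — i.e. the farthest from its center), so the equivalence is
exact rather than merely up to convergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ExpressionDataset, Observation


@dataclass
class KmeansFit:
    centers: np.ndarray  # (K, n)
    labels: np.ndarray  # (G,)
    within_ss: float
    n_iter: int
    seed: int | None
    converged: bool = True
    model: str = "kmeans"
    sigma2: float | None = None  # set by the classification-EM route

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "centers": self.centers.tolist(),
            "labels": self.labels.tolist(),
            "within_ss": self.within_ss,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "converged": self.converged,
        }


def average_replicates(ds: ExpressionDataset):
    """Collapse replicates: mean over observed values per (condition, time).

    Returns ``(profiles, meta)`` where ``profiles`` is G x n with NaN where a
    cell is missing in every replicate, and ``meta`` is a DataFrame with the
    condition and time of each output column (in canonical order).
    """
    groups: dict = {}
    for j, o in enumerate(ds.observations):
        groups.setdefault((o.condition, o.time), []).append(j)
    keys = sorted(groups)
    G = ds.n_genes
    profiles = np.full((G, len(keys)), np.nan)
    for c, key in enumerate(keys):
        cols = groups[key]
        vals = ds.values[:, cols]
        msk = ds.mask[:, cols]
        cnt = msk.sum(axis=1)
        tot = np.where(msk, vals, 0.0).sum(axis=1)
        has = cnt > 0
        profiles[has, c] = tot[has] / cnt[has]
    meta = pd.DataFrame({"condition": [k[0] for k in keys], "time": [k[1] for k in keys]})
    return profiles, meta


def _sq_distances(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Expanded-form squared Euclidean distances (matches the mixture algebra)."""
    yty = np.einsum("gi,gi->g", X, X)
    return yty[:, None] - 2.0 * X @ centers.T + np.einsum("ki,ki->k", centers, centers)[None, :]


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int):
    G, _ = X.shape
    K = centers.shape[0]
    centers = centers.copy()
    labels_prev = None
    n_iter = 0
    converged = False
    for it in range(max_iter):
        n_iter = it + 1
        d2 = _sq_distances(X, centers)
        labels = np.argmin(d2, axis=1)
        assigned = d2[np.arange(G), labels]
        sizes = np.bincount(labels, minlength=K)
        for k in np.flatnonzero(sizes == 0):  # reseed from the farthest point
            g_star = int(np.argmax(assigned))
            labels[g_star] = k
            assigned[g_star] = d2[g_star, k]
        if labels_prev is not None and np.array_equal(labels, labels_prev):
            converged = True
            break
        labels_prev = labels
        for k in range(K):
            members = labels == k
            if members.any():
                centers[k] = X[members].mean(axis=0)
    d2 = _sq_distances(X, centers)
    wss = float(np.maximum(d2[np.arange(G), labels], 0.0).sum())
    return labels, centers, wss, n_iter, converged


def _initial_centers(X: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    return X[rng.choice(X.shape[0], size=K, replace=False)].copy()


def _check_profiles(profiles: np.ndarray, K: int) -> np.ndarray:
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2:
        raise ValueError("profiles must be a 2-D matrix")
    if np.isnan(X).any():
        raise ValueError(
            "profiles contain missing cells; complete them first "
            "(drop incomplete time points or mean-impute)"
        )
    if K < 1 or K > X.shape[0]:
        raise ValueError(f"K={K} must be in [1, G={X.shape[0]}]")
    return X


def fit_kmeans(
    profiles: np.ndarray,
    K: int,
    *,
    n_restarts: int = 10,
    max_iter: int = 300,
    seed: int | None = None,
    init: np.ndarray | None = None,
) -> KmeansFit:
    """Lloyd's K-means; best within-cluster sum of squares over restarts.

    ``init`` may be a (K, n) array of starting centers or a length-G integer
    labeling (centers start as the label-group means); when given, a single
    run is performed from it.
    """
    X = _check_profiles(profiles, K)
    starts = []
    if init is not None:
        init = np.asarray(init)
        if init.ndim == 1:
            centers = np.stack([X[init == k].mean(axis=0) for k in range(K)])
        else:
            centers = init.astype(float).copy()
            if centers.shape != (K, X.shape[1]):
                raise ValueError("init centers must be K x n")
        starts.append(centers)
    else:
        root = np.random.default_rng(seed)
        for _ in range(n_restarts):
            starts.append(_initial_centers(X, K, root))
    best = None
    for centers0 in starts:
        labels, centers, wss, n_iter, conv = _lloyd(X, centers0, max_iter)
        if best is None or wss < best.within_ss:
            best = KmeansFit(centers, labels, wss, n_iter, seed, conv)
    return best


def kmeans_as_classification_em(
    profiles: np.ndarray,
    K: int,
    *,
    n_restarts: int = 10,
    max_iter: int = 300,
    seed: int | None = None,
    init: np.ndarray | None = None,
) -> KmeansFit:
    """K-means via the constrained mixture model it implicitly assumes.

    Runs the mixture EM with a saturated design (one coefficient per profile
    position), no random effects, shared scalar variance, proportions fixed
    at 1/K and hard assignment — the classification likelihood whose
    maximization is Lloyd's algorithm.
    """
    from . import clmm  # local import; clmm imports this module at top level
    from .design import GeneDesign

    X = _check_profiles(profiles, K)
    G, n = X.shape
    obs = [Observation("all", "r1", float(t)) for t in range(n)]
    ds = ExpressionDataset([f"g{i}" for i in range(G)], obs, X, np.ones_like(X, dtype=bool))
    eye = np.eye(n)
    zero = np.zeros((n, 0))
    designs = [GeneDesign(eye, zero, n, np.arange(n)) for _ in range(G)]

    if init is not None:
        init = np.asarray(init)
        if init.ndim == 1:
            center_starts = [np.stack([X[init == k].mean(axis=0) for k in range(K)])]
        else:
            center_starts = [init.astype(float).copy()]
    else:
        root = np.random.default_rng(seed)
        center_starts = [_initial_centers(X, K, root) for _ in range(n_restarts)]

    best = None
    for centers0 in center_starts:
        params0 = clmm.ClmmParams(
            pi=np.full(K, 1.0 / K),
            beta=centers0,
            D=np.zeros((K, 0, 0)),
            sigma2=np.ones(K),
        )
        fit = clmm.fit_clmm(
            ds,
            None,
            K,
            designs=designs,
            max_iter=max_iter,
            tol=0.0,
            equal_proportions=True,
            shared_sigma2=True,
            hard_assign=True,
            init=params0,
            seed=seed,
        )
        labels = fit.map_labels
        centers = fit.params.beta
        d2 = _sq_distances(X, centers)
        wss = float(np.maximum(d2[np.arange(G), labels], 0.0).sum())
        if best is None or wss < best.within_ss:
            best = KmeansFit(
                centers, labels, wss, fit.n_iter, seed, fit.converged,
                sigma2=float(fit.params.sigma2[0]),
            )
    return best
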