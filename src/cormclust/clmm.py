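"""Mixtures of linear mixed models for gene clustering, fitted by EM.

The model: gene ``g`` belongs to latent cluster ``u_g = k`` with probability
``pi_k``; given its cluster, the gene's observed expression vector is

    y_g | u_g = k  ~  N( X_g beta_k ,  Z_g D_k Z_g' + sigma2_k I )

where ``X_g`` codes the cluster's mean profile (a B-spline curve in time,
optionally blocked by condition) and ``Z_g b_g`` is a gene-level random
deviation, ``b_g ~ N(0, D_k)``, shared by all of the gene's observations —
in particular by both technical replicates.  Clustering therefore acts on
the systematic, covariate-explained part of expression variation rather
than on the raw measurement vectors.  With ``q = 0`` (no random effects)
the model reduces to a mixture of ordinary linear regressions.

Fitting is by EM, treating both the memberships ``u_g`` and the random
effects ``b_g`` as missing data; the M-step updates are in closed form.
A classification-EM variant (``hard_assign``) collapses posteriors to MAP
indicators before each M-step; with a saturated design, shared scalar
variance and equal proportions this reproduces Lloyd's K-means exactly.

Per-gene likelihood algebra uses the Woodbury identity, so the cost per
gene/cluster is O(p^2 + q^3) after a one-off pass over the raw data;
missing entries are handled by row deletion (missing at random).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from . import kmeans as _kmeans
from .data_model import ExpressionDataset
from .design import DesignSpec, GeneDesign, build_designs, bspline_basis, validate_designs

SIGMA2_FLOOR = 1e-8
LOG2PI = float(np.log(2.0 * np.pi))


class ShapeError(ValueError):
    """Design/parameter dimensions do not conform."""


class NumericalError(RuntimeError):
    """An M-step solve failed (near-empty cluster)."""


class FitError(RuntimeError):
    """Every restart degenerated."""


# ---------------------------------------------------------------------------
# parameters and fit containers


@dataclass
class ClmmParams:
    """Mixture parameters: proportions, coefficients, variance components."""

    pi: np.ndarray  # (K,)
    beta: np.ndarray  # (K, p)
    D: np.ndarray  # (K, q, q), symmetric PSD
    sigma2: np.ndarray  # (K,)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.D = np.asarray(self.D, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        K = self.pi.shape[0]
        if self.D.ndim == 2 and K == 1:  # allow a bare (q, q) for K=1
            self.D = self.D[None]
        if self.D.size == 0:  # lists round-trip empty (K, 0, 0) as (K, 0)
            self.D = np.zeros((K, 0, 0))
        if self.beta.shape[0] != K or self.D.shape[0] != K or self.sigma2.shape[0] != K:
            raise ShapeError("pi, beta, D, sigma2 must agree on K")
        if not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("mixture proportions must sum to 1")

    @property
    def K(self) -> int:
        return self.pi.shape[0]

    @property
    def p(self) -> int:
        return self.beta.shape[1]

    @property
    def q(self) -> int:
        return self.D.shape[1]

    def n_free_parameters(self, equal_proportions: bool, shared_sigma2: bool) -> int:
        K, p, q = self.K, self.p, self.q
        n = K * p + K * (q * (q + 1) // 2)
        n += 0 if equal_proportions else K - 1
        n += 1 if shared_sigma2 else K
        return n


@dataclass
class EStepResult:
    """Posterior memberships and conditional random-effect moments."""

    posterior: np.ndarray  # (G, K)
    bhat: np.ndarray  # (G, K, q): E[b_g | y_g, u_g = k]
    C: np.ndarray  # (G, K, q, q): Cov[b_g | y_g, u_g = k]
    loglik: float  # observed-data mixture log-likelihood
    log_component: np.ndarray  # (G, K): log f_k(y_g)
    log_joint: np.ndarray  # (G, K): log pi_k + log f_k(y_g)


@dataclass
class ClmmFit:
    """A fitted mixture with posteriors, MAP labels and BLUPs."""

    params: ClmmParams
    posterior: np.ndarray
    map_labels: np.ndarray
    blups: np.ndarray  # (G, q), conditional on the MAP cluster
    blup_cov: np.ndarray  # (G, q, q)
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    restart_index: int
    seed: int | None
    genes: list
    conditions: list
    spec: DesignSpec | None
    options: dict = field(default_factory=dict)
    model: str = "clmm"

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    @property
    def K(self) -> int:
        return self.params.K

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.map_labels, minlength=self.K)

    def bic(self, total_n: int) -> float:
        npar = self.params.n_free_parameters(
            bool(self.options.get("equal_proportions", False)),
            bool(self.options.get("shared_sigma2", False)),
        )
        return -2.0 * self.loglik + npar * float(np.log(total_n))

    def cluster_profiles(self, condition, time_grid) -> np.ndarray:
        return fitted_cluster_profile(self, condition, time_grid)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "spec": self.spec.to_dict() if self.spec is not None else None,
            "conditions": list(self.conditions),
            "genes": list(self.genes),
            "options": self.options,
            "seed": self.seed,
            "restart_index": self.restart_index,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "loglik_trace": np.asarray(self.loglik_trace).tolist(),
            "params": {
                "pi": self.params.pi.tolist(),
                "beta": self.params.beta.tolist(),
                "D": self.params.D.tolist(),
                "sigma2": self.params.sigma2.tolist(),
            },
            "posterior": self.posterior.tolist(),
            "map_labels": self.map_labels.tolist(),
            "blups": self.blups.tolist(),
            "blup_cov": self.blup_cov.tolist(),
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "ClmmFit":
        params = ClmmParams(
            np.array(d["params"]["pi"]),
            np.array(d["params"]["beta"]),
            np.array(d["params"]["D"]),
            np.array(d["params"]["sigma2"]),
        )
        return cls(
            params=params,
            posterior=np.array(d["posterior"]),
            map_labels=np.array(d["map_labels"], dtype=int),
            blups=np.array(d["blups"]),
            blup_cov=np.array(d["blup_cov"]),
            loglik_trace=np.array(d["loglik_trace"]),
            n_iter=int(d["n_iter"]),
            converged=bool(d["converged"]),
            restart_index=int(d["restart_index"]),
            seed=d.get("seed"),
            genes=list(d["genes"]),
            conditions=list(d["conditions"]),
            spec=DesignSpec.from_dict(d["spec"]) if d.get("spec") else None,
            options=dict(d.get("options", {})),
            model=d.get("model", "clmm"),
        )

    @classmethod
    def load_json(cls, path) -> "ClmmFit":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# per-gene sufficient statistics


class SuffStats:
    """Per-gene cross products; the EM loop never touches raw vectors again."""

    def __init__(self, ys: Sequence[np.ndarray], designs: Sequence[GeneDesign]):
        G = len(ys)
        p = designs[0].X.shape[1]
        q = designs[0].Z.shape[1]
        self.G, self.p, self.q = G, p, q
        self.ys = list(ys)
        self.designs = list(designs)
        self.n = np.array([d.n for d in designs], dtype=float)
        self.yty = np.array([y @ y for y in ys])
        self.Xty = np.stack([d.X.T @ y for y, d in zip(ys, designs)])
        self.XtX = np.stack([d.X.T @ d.X for d in designs])
        self.Zty = np.stack([d.Z.T @ y for y, d in zip(ys, designs)])
        self.ZtX = np.stack([d.Z.T @ d.X for d in designs])
        self.ZtZ = np.stack([d.Z.T @ d.Z for d in designs])
        self.total_n = int(self.n.sum())

    @classmethod
    def from_dataset(cls, ds: ExpressionDataset, designs: Sequence[GeneDesign]) -> "SuffStats":
        ys = [ds.values[g][ds.mask[g]] for g in range(ds.n_genes)]
        return cls(ys, designs)


def _component_loglik(stats: SuffStats, params: ClmmParams, k: int):
    """log f_k(y_g), BLUP and conditional covariance for every gene, cluster k.

    Uses V_gk^{-1} = (I - Z A Z') / sigma2 with A = (sigma2 I + D Z'Z)^{-1} D,
    so only q x q solves are needed.
    """
    beta = params.beta[k]
    s2 = float(params.sigma2[k])
    D = params.D[k]
    q = stats.q
    rtr = stats.yty - 2.0 * stats.Xty @ beta + np.einsum("gij,i,j->g", stats.XtX, beta, beta)
    rtr = np.maximum(rtr, 0.0)
    if q == 0:
        ll = -0.5 * (stats.n * (LOG2PI + np.log(s2)) + rtr / s2)
        return ll, np.zeros((stats.G, 0)), np.zeros((stats.G, 0, 0))
    s = stats.Zty - np.einsum("gqp,p->gq", stats.ZtX, beta)  # Z_g' (y_g - X_g beta)
    M = np.einsum("ij,gjk->gik", D, stats.ZtZ) + s2 * np.eye(q)[None]
    A = np.linalg.solve(M, np.broadcast_to(D, (stats.G, q, q)))
    bhat = np.einsum("gij,gj->gi", A, s)
    quad = np.maximum(rtr - np.einsum("gi,gi->g", s, bhat), 0.0)
    sign, logdetM = np.linalg.slogdet(M)
    if np.any(sign <= 0):
        raise NumericalError(f"non-PD marginal covariance in cluster {k}")
    logdetV = (stats.n - q) * np.log(s2) + logdetM
    ll = -0.5 * (stats.n * LOG2PI + logdetV + quad / s2)
    C = D[None] - np.einsum("gij,gjk,kl->gil", A, stats.ZtZ, D)
    C = 0.5 * (C + np.swapaxes(C, 1, 2))
    return ll, bhat, C


def _e_step(stats: SuffStats, params: ClmmParams) -> EStepResult:
    G, K, q = stats.G, params.K, stats.q
    logf = np.empty((G, K))
    bhat = np.empty((G, K, q))
    C = np.empty((G, K, q, q))
    for k in range(K):
        logf[:, k], bhat[:, k], C[:, k] = _component_loglik(stats, params, k)
    log_joint = np.log(params.pi)[None, :] + logf
    norm = logsumexp(log_joint, axis=1)
    posterior = np.exp(log_joint - norm[:, None])
    return EStepResult(posterior, bhat, C, float(norm.sum()), logf, log_joint)


def _psd_project(D: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(0.5 * (D + D.T))
    return (V * np.maximum(w, 0.0)) @ V.T


def _m_step(
    stats: SuffStats,
    posterior: np.ndarray,
    bhat: np.ndarray,
    C: np.ndarray,
    *,
    equal_proportions: bool = False,
    shared_sigma2: bool = False,
) -> ClmmParams:
    G, p, q = stats.G, stats.p, stats.q
    K = posterior.shape[1]
    pi = np.full(K, 1.0 / K) if equal_proportions else posterior.sum(axis=0) / G
    beta = np.empty((K, p))
    D = np.empty((K, q, q))
    num = np.empty(K)
    den = np.empty(K)
    for k in range(K):
        w = posterior[:, k]
        Nk = w.sum()
        Sxx = np.einsum("g,gij->ij", w, stats.XtX)
        Xtzb = np.einsum("gqp,gq->gp", stats.ZtX, bhat[:, k])  # X_g' Z_g bhat_gk
        Sxy = np.einsum("g,gp->p", w, stats.Xty - Xtzb)
        try:
            beta[k] = np.linalg.solve(Sxx, Sxy)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"singular normal equations for cluster {k} (near-empty)") from exc
        if q:
            outer = np.einsum("gi,gj->gij", bhat[:, k], bhat[:, k]) + C[:, k]
            D[k] = _psd_project(np.einsum("g,gij->ij", w, outer) / Nk)
        # E || y - X beta_new - Z b ||^2 with b at its conditional moments
        rtr = stats.yty - 2.0 * stats.Xty @ beta[k] + np.einsum("gij,i,j->g", stats.XtX, beta[k], beta[k])
        s = stats.Zty - np.einsum("gqp,p->gq", stats.ZtX, beta[k])
        sq = rtr - 2.0 * np.einsum("gq,gq->g", bhat[:, k], s) + np.einsum(
            "gi,gij,gj->g", bhat[:, k], stats.ZtZ, bhat[:, k]
        )
        tr = np.einsum("gij,gji->g", C[:, k], stats.ZtZ)
        num[k] = w @ (sq + tr)
        den[k] = w @ stats.n
    if shared_sigma2:
        sigma2 = np.full(K, max(num.sum() / den.sum(), SIGMA2_FLOOR))
    else:
        sigma2 = np.maximum(num / den, SIGMA2_FLOOR)
    return ClmmParams(pi, beta, D, sigma2)


# -- spec-facing wrappers ----------------------------------------------------


def marginal_loglik_gene(y_g, design: GeneDesign, k: int, params: ClmmParams) -> float:
    """Marginal Gaussian log-density of one gene's observed vector under cluster k."""
    y_g = np.asarray(y_g, dtype=float)
    if design.X.shape != (y_g.shape[0], params.p) or design.Z.shape[1] != params.q:
        raise ShapeError(
            f"design ({design.X.shape}, Z cols {design.Z.shape[1]}) does not conform "
            f"to y (n={y_g.shape[0]}) and params (p={params.p}, q={params.q})"
        )
    stats = SuffStats([y_g], [design])
    ll, _, _ = _component_loglik(stats, params, k)
    return float(ll[0])


def e_step(ds: ExpressionDataset, designs: Sequence[GeneDesign], params: ClmmParams) -> EStepResult:
    """Posterior memberships, conditional random-effect moments, total log-likelihood."""
    return _e_step(SuffStats.from_dataset(ds, designs), params)


def m_step(
    ds: ExpressionDataset,
    designs: Sequence[GeneDesign],
    e_quantities: EStepResult,
    *,
    equal_proportions: bool = False,
    shared_sigma2: bool = False,
) -> ClmmParams:
    """Closed-form parameter updates given E-step quantities."""
    return _m_step(
        SuffStats.from_dataset(ds, designs),
        e_quantities.posterior,
        e_quantities.bhat,
        e_quantities.C,
        equal_proportions=equal_proportions,
        shared_sigma2=shared_sigma2,
    )


# ---------------------------------------------------------------------------
# initialization


def _mean_profiles(ds: ExpressionDataset) -> np.ndarray:
    """Replicate-averaged per-gene profiles with gene-mean imputation (init only)."""
    profiles, _ = _kmeans.average_replicates(ds)
    out = profiles.copy()
    for g in range(out.shape[0]):
        row = out[g]
        bad = np.isnan(row)
        if bad.any():
            fill = np.nanmean(row) if not bad.all() else 0.0
            row[bad] = fill
    return out


def _params_from_labels(
    stats: SuffStats,
    labels: np.ndarray,
    K: int,
    *,
    equal_proportions: bool,
    shared_sigma2: bool,
) -> ClmmParams:
    """Moment-style starting values from a hard labeling.

    beta_k by pooled per-cluster least squares, sigma2_k from the resulting
    residuals, and D_k from per-gene least-squares random-effect estimates
    (inflated slightly so the EM can move b away from zero).
    """
    G, p, q = stats.G, stats.p, stats.q
    pi = np.full(K, 1.0 / K) if equal_proportions else np.bincount(labels, minlength=K) / G
    pi = np.maximum(pi, 1e-6)
    pi = pi / pi.sum()
    beta = np.empty((K, p))
    sigma2 = np.empty(K)
    D = np.zeros((K, q, q))
    eye_p = np.eye(p)
    for k in range(K):
        members = np.flatnonzero(labels == k)
        if members.size == 0:
            members = np.array([k % G])
        Sxx = stats.XtX[members].sum(axis=0)
        Sxy = stats.Xty[members].sum(axis=0)
        ridge = 1e-10 * max(np.trace(Sxx) / p, 1.0)
        beta[k] = np.linalg.solve(Sxx + ridge * eye_p, Sxy)
        rtr = (
            stats.yty[members]
            - 2.0 * stats.Xty[members] @ beta[k]
            + np.einsum("gij,i,j->g", stats.XtX[members], beta[k], beta[k])
        )
        sigma2[k] = max(rtr.sum() / stats.n[members].sum(), SIGMA2_FLOOR)
        if q:
            s = stats.Zty[members] - np.einsum("gqp,p->gq", stats.ZtX[members], beta[k])
            Mz = stats.ZtZ[members] + 1e-8 * np.eye(q)[None]
            btilde = np.linalg.solve(Mz, s[..., None])[..., 0]
            D[k] = _psd_project(np.einsum("gi,gj->ij", btilde, btilde) / members.size)
            D[k] += 0.1 * sigma2[k] * np.eye(q)
    if shared_sigma2:
        sigma2[:] = sigma2.mean()
    return ClmmParams(pi, beta, D, sigma2)


class _RestartDegenerate(Exception):
    pass


def _run_em(
    stats: SuffStats,
    params: ClmmParams,
    *,
    max_iter: int,
    tol: float,
    equal_proportions: bool,
    shared_sigma2: bool,
    hard_assign: bool,
):
    """One EM run from given starting parameters.

    Soft fits trace the observed-data mixture log-likelihood; classification
    (hard) fits trace the classification log-likelihood — each is the
    monotone objective of its variant.
    """
    G, K = stats.G, params.K
    trace: list = []
    labels_prev = None
    reseed_iters = 0
    converged = False
    est = None
    post = None
    for it in range(max_iter):
        est = _e_step(stats, params)
        if hard_assign:
            labels = np.argmax(est.log_joint, axis=1)
            score = est.log_joint[np.arange(G), labels]
            post = np.zeros((G, K))
            post[np.arange(G), labels] = 1.0
            trace.append(float(score.sum()))
        else:
            labels = np.argmax(est.posterior, axis=1)
            post = est.posterior.copy()
            score = logsumexp(est.log_joint, axis=1)
            trace.append(est.loglik)
        # reseed near-empty clusters from the worst-fitting gene
        sizes = post.sum(axis=0)
        if np.any(sizes < 1.0):
            reseed_iters += 1
            if reseed_iters > 3:
                raise _RestartDegenerate()
            gene_score = score.copy()
            for k in np.flatnonzero(sizes < 1.0):
                g_star = int(np.argmin(gene_score))
                post[g_star] = 0.0
                post[g_star, k] = 1.0
                labels[g_star] = k
                gene_score[g_star] = est.log_joint[g_star, k]
        # convergence
        if hard_assign:
            if labels_prev is not None and np.array_equal(labels, labels_prev):
                converged = True
                break
            labels_prev = labels
        else:
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * (abs(trace[-2]) + 1e-10):
                converged = True
                break
        params = _m_step(
            stats,
            post,
            est.bhat,
            est.C,
            equal_proportions=equal_proportions,
            shared_sigma2=shared_sigma2,
        )
    labels = np.argmax(post, axis=1)
    return params, est, post, labels, np.array(trace), converged


def fit_clmm(
    ds: ExpressionDataset,
    spec: DesignSpec | None,
    K: int,
    *,
    designs: Sequence[GeneDesign] | None = None,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = None,
    equal_proportions: bool = False,
    shared_sigma2: bool = False,
    hard_assign: bool = False,
    init=None,
) -> ClmmFit:
    """Fit the K-cluster mixture by EM with seeded multi-start.

    Default initialization runs Lloyd's K-means on replicate-averaged
    per-gene profiles (gene-mean imputation, used for initialization only)
    and perturbs the resulting labels across restarts; the restart with the
    best final objective wins (ties to the lowest restart index).  Passing
    ``init`` (a :class:`ClmmParams`, or a dict with ``"labels"`` or
    ``"params"``) replaces the multi-start with a single run from that
    start — this is how the Lloyd-matched classification-EM comparison is
    set up.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if designs is None:
        if spec is None:
            raise ValueError("either spec or designs must be given")
        designs = build_designs(ds, spec)
    conditions = ds.conditions
    p = designs[0].X.shape[1]
    validate_designs(designs, p, ds.genes)
    stats = SuffStats.from_dataset(ds, designs)
    options = {
        "K": K,
        "n_restarts": n_restarts,
        "max_iter": max_iter,
        "tol": tol,
        "equal_proportions": equal_proportions,
        "shared_sigma2": shared_sigma2,
        "hard_assign": hard_assign,
    }
    em_kw = dict(
        max_iter=max_iter,
        tol=tol,
        equal_proportions=equal_proportions,
        shared_sigma2=shared_sigma2,
        hard_assign=hard_assign,
    )

    starts: list = []
    if init is not None:
        if isinstance(init, ClmmParams):
            starts.append(("params", init))
        elif isinstance(init, dict) and "params" in init:
            starts.append(("params", init["params"]))
        elif isinstance(init, dict) and "labels" in init:
            starts.append(("labels", np.asarray(init["labels"], dtype=int)))
        else:
            starts.append(("labels", np.asarray(init, dtype=int)))
    else:
        root = np.random.default_rng(seed)
        base_seed = int(root.integers(2**31 - 1))
        profiles = _mean_profiles(ds)
        base = _kmeans.fit_kmeans(profiles, min(K, ds.n_genes), n_restarts=1, seed=base_seed)
        base_labels = base.labels
        for r in range(n_restarts):
            labels = base_labels.copy()
            if r > 0:
                rng = np.random.default_rng([base_seed, r])
                n_jitter = max(1, int(0.1 * ds.n_genes))
                idx = rng.choice(ds.n_genes, size=min(n_jitter, ds.n_genes), replace=False)
                labels[idx] = rng.integers(K, size=idx.size)
            # make sure every cluster is populated at the start
            for k in range(K):
                if not np.any(labels == k):
                    labels[int(np.random.default_rng([base_seed, r, k]).integers(ds.n_genes))] = k
            starts.append(("labels", labels))

    best = None
    for r, (kind, start) in enumerate(starts):
        if kind == "params":
            params0 = start
        else:
            params0 = _params_from_labels(
                stats, start, K, equal_proportions=equal_proportions, shared_sigma2=shared_sigma2
            )
        try:
            result = _run_em(stats, params0, **em_kw)
        except _RestartDegenerate:
            continue
        if best is None or result[4][-1] > best[1][4][-1]:
            best = (r, result)
    if best is None:
        raise FitError("all restarts degenerated; try fewer clusters or different seeds")

    r_best, (params, est, post, labels, trace, converged) = best
    G = stats.G
    q = stats.q
    blups = est.bhat[np.arange(G), labels] if q else np.zeros((G, 0))
    blup_cov = est.C[np.arange(G), labels] if q else np.zeros((G, 0, 0))
    return ClmmFit(
        params=params,
        posterior=post,
        map_labels=labels,
        blups=blups,
        blup_cov=blup_cov,
        loglik_trace=trace,
        n_iter=len(trace),
        converged=converged,
        restart_index=r_best,
        seed=seed,
        genes=list(ds.genes),
        conditions=list(conditions),
        spec=spec,
        options=options,
    )


# ---------------------------------------------------------------------------
# post-fit operations


def blup(fit: ClmmFit, gene) -> np.ndarray:
    """Best linear unbiased prediction of a gene's random effects (MAP cluster)."""
    try:
        g = fit.genes.index(gene)
    except ValueError:
        raise KeyError(f"unknown gene {gene!r}") from None
    return fit.blups[g]


def predict_new_gene(params: ClmmParams, y_new, design_new: GeneDesign):
    """Posterior cluster membership for an unseen gene under frozen parameters.

    This is the explicit prediction rule the mixture provides: no refitting,
    just the E-step arithmetic on the new gene's observed rows (which may be
    a partial profile).
    """
    y_new = np.asarray(y_new, dtype=float)
    if design_new.X.shape != (y_new.shape[0], params.p) or design_new.Z.shape[1] != params.q:
        raise ShapeError(
            f"new design ({design_new.X.shape}, Z cols {design_new.Z.shape[1]}) does not "
            f"conform to params (p={params.p}, q={params.q})"
        )
    stats = SuffStats([y_new], [design_new])
    est = _e_step(stats, params)
    posterior = est.posterior[0]
    return posterior, int(np.argmax(posterior))


def fitted_cluster_profile(fit: ClmmFit, condition, time_grid) -> np.ndarray:
    """Fitted mean curves, one row per cluster, at the given times.

    With condition blocking, the block of coefficients belonging to
    ``condition`` is used; otherwise the single shared block.
    """
    if fit.spec is None:
        raise ValueError("fit carries no design spec; profiles unavailable")
    if condition not in fit.conditions:
        raise KeyError(f"no such condition: {condition!r}")
    basis = bspline_basis(np.asarray(time_grid, dtype=float), fit.spec)
    nb = fit.spec.n_basis
    if fit.spec.condition_blocking:
        b = fit.conditions.index(condition)
        block = fit.params.beta[:, b * nb : (b + 1) * nb]
    else:
        block = fit.params.beta
    return block @ basis.T  # (K, len(grid))
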