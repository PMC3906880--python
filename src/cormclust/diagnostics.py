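"""Model checking, display coordinates, cluster labeling and comparison.

Covers the post-fit workflow for a clustering analysis: residual and BLUP
summaries for checking the mixed-model assumptions, a top-two-eigenvector
display of the observed profiles with projected cluster centers, labeling
of clusters by the order of their first fitted peak, contingency-table
comparison of two clusterings (with an optimal one-to-one label matching
agreement rate), and informative-gene screening by per-gene F-tests with
Benjamini–Hochberg control.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import linear_sum_assignment
from statsmodels.stats.multitest import multipletests

from .clmm import ClmmFit
from .data_model import ExpressionDataset
from .design import DesignSpec, build_designs


# ---------------------------------------------------------------------------
# residuals and BLUP checks


def residuals(fit: ClmmFit, ds: ExpressionDataset, designs=None):
    """Per-gene residual vectors and a per-cluster variance-by-time summary.

    Residuals are ``y_g - X_g beta_k - Z_g bhat_g`` on the observed entries,
    with ``k`` the gene's MAP cluster.  The summary holds the residual
    variance per (cluster, time), pooled over conditions and replicates —
    one row per cluster per distinct time in the dataset.
    """
    if designs is None:
        designs = build_designs(ds, fit.spec)
    times = ds.times
    recs = []
    per_gene = {}
    for g, gene in enumerate(ds.genes):
        k = int(fit.map_labels[g])
        d = designs[g]
        y = ds.values[g][ds.mask[g]]
        r = y - d.X @ fit.params.beta[k]
        if d.Z.shape[1]:
            r = r - d.Z @ fit.blups[g]
        per_gene[gene] = (r, d.obs_indices)
        for res, j in zip(r, d.obs_indices):
            recs.append((k, times[j], res))
    df = pd.DataFrame(recs, columns=["cluster", "time", "residual"])
    all_times = np.unique(times)
    rows = []
    for k in range(fit.K):
        sub = df[df.cluster == k]
        for t in all_times:
            vals = sub.loc[sub.time == t, "residual"].to_numpy()
            rows.append(
                {
                    "cluster": k,
                    "time": t,
                    "n": len(vals),
                    "variance": float(np.var(vals, ddof=1)) if len(vals) > 1 else np.nan,
                    "mean": float(vals.mean()) if len(vals) else np.nan,
                }
            )
    return per_gene, pd.DataFrame(rows)


def blup_summary(fit: ClmmFit) -> pd.DataFrame:
    """Variance of the BLUPs per cluster per random-effect element."""
    rows = []
    for k in range(fit.K):
        members = fit.map_labels == k
        for j in range(fit.blups.shape[1]):
            vals = fit.blups[members, j]
            rows.append(
                {
                    "cluster": k,
                    "element": j,
                    "n": int(members.sum()),
                    "variance": float(np.var(vals, ddof=1)) if members.sum() > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# eigen display


def pca_scores(profiles: np.ndarray, cluster_means: np.ndarray | None = None, center: bool = True):
    """Top-two-eigenvector display coordinates of the observed profiles.

    Eigen-decomposes the (column-centered, by default) data covariance and
    projects genes — and optionally the cluster mean profiles, with the same
    loadings — onto the two leading eigenvectors.  Returns
    ``(scores, center_scores, variance_explained)`` where the last entry is
    the fraction of total variance carried by the two components.  Columns
    with any missing value are dropped first.
    """
    X = np.asarray(profiles, dtype=float)
    keep = ~np.isnan(X).any(axis=0)
    X = X[:, keep]
    if X.shape[1] < 2:
        raise ValueError("need at least 2 complete profile columns")
    mu = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Xc = X - mu
    # SVD of the centered matrix <-> eigen-decomposition of the covariance
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    lam = svals**2
    frac = float(lam[:2].sum() / lam.sum()) if lam.sum() > 0 else 1.0
    loadings = Vt[:2].T  # (n, 2)
    scores = Xc @ loadings
    center_scores = None
    if cluster_means is not None:
        M = np.asarray(cluster_means, dtype=float)[:, keep]
        center_scores = (M - mu) @ loadings
    return scores, center_scores, frac


# ---------------------------------------------------------------------------
# peak-time labeling


def first_peak_time(profile, times) -> float:
    """Time of the first interior local maximum (strictly above both neighbors).

    Falls back to the time of the global maximum when no interior peak
    exists; all ties resolve to the earliest time.
    """
    y = np.asarray(profile, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.shape != t.shape or y.size < 3:
        raise ValueError("profile and times must match, length >= 3")
    interior = np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:]))
    if interior.size:
        return float(t[interior[0] + 1])
    return float(t[int(np.argmax(y))])


def relabel_by_peak(fit: ClmmFit, condition, time_grid) -> ClmmFit:
    """Renumber clusters 1..K by ascending first peak time of their fitted curves.

    Posteriors, labels and parameters are permuted consistently; ties keep
    their original relative order.
    """
    grid = np.asarray(time_grid, dtype=float)
    profiles = fit.cluster_profiles(condition, grid)
    peaks = np.array([first_peak_time(profiles[k], grid) for k in range(fit.K)])
    perm = np.argsort(peaks, kind="stable")  # perm[j] = old index shown at new slot j
    inv = np.empty_like(perm)
    inv[perm] = np.arange(fit.K)
    params = type(fit.params)(
        pi=fit.params.pi[perm],
        beta=fit.params.beta[perm],
        D=fit.params.D[perm],
        sigma2=fit.params.sigma2[perm],
    )
    return dataclasses.replace(
        fit,
        params=params,
        posterior=fit.posterior[:, perm],
        map_labels=inv[fit.map_labels],
    )


# ---------------------------------------------------------------------------
# contingency tables


@dataclass
class CrossTab:
    """Labeled contingency matrix comparing two clusterings of the same genes."""

    row_labels: list
    col_labels: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def agreement(self) -> float:
        """Fraction of genes on the diagonal after the best one-to-one label matching."""
        r, c = linear_sum_assignment(-self.counts)
        return float(self.counts[r, c].sum() / self.grand_total)

    def to_frame(self, margins: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)
        if margins:
            df["total"] = df.sum(axis=1)
            df.loc["total"] = df.sum(axis=0)
        return df

    def to_tsv(self, path, margins: bool = True) -> None:
        self.to_frame(margins=margins).to_csv(path, sep="\t", index_label="cluster")

    @classmethod
    def from_tsv(cls, path) -> "CrossTab":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.drop(index="total", columns="total", errors="ignore")
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=int))


def cross_tab(labels_a, labels_b, row_labels=None, col_labels=None) -> CrossTab:
    """Contingency table of two labelings of the same (ordered) gene set."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings must have equal length")
    rows = sorted(set(a.tolist())) if row_labels is None else list(row_labels)
    cols = sorted(set(b.tolist())) if col_labels is None else list(col_labels)
    ridx = {v: i for i, v in enumerate(rows)}
    cidx = {v: i for i, v in enumerate(cols)}
    counts = np.zeros((len(rows), len(cols)), dtype=int)
    for va, vb in zip(a, b):
        counts[ridx[va], cidx[vb]] += 1
    return CrossTab(rows, cols, counts)


#: names of the bundled reference contingency tables (256-gene yeast
#: cell-cycle benchmark): the mixed-model clustering of the wild-type data
#: against K-means, and the wild-type-only against the joint two-genotype
#: clustering.
REFERENCE_TABLES = ("wt_clmm_vs_kmeans", "wt_clmm_vs_joint_clmm")


def reference_crosstab(name: str) -> CrossTab:
    """Load one of the bundled reference contingency tables by name."""
    if name not in REFERENCE_TABLES:
        raise KeyError(f"unknown reference table {name!r}; options: {REFERENCE_TABLES}")
    ref = importlib.resources.files("cormclust").joinpath(f"data/{name}.tsv")
    with importlib.resources.as_file(ref) as path:
        return CrossTab.from_tsv(path)


# ---------------------------------------------------------------------------
# informative-gene screening


def select_informative_genes(ds: ExpressionDataset, spec: DesignSpec, alpha: float):
    """Screen genes whose profiles show significant systematic time variation.

    Per gene, an ordinary least-squares F-test compares the spline design
    against an intercept-only model on the gene's observed entries (technical
    replicates contribute independent residual rows); p-values are adjusted
    by Benjamini–Hochberg and genes with adjusted p strictly below ``alpha``
    are kept.  Genes with too few observations for the F-test are excluded
    with a warning.

    Returns ``(kept_genes, table)`` where ``table`` has one row per testable
    gene: F statistic, p-value and adjusted p-value.
    """
    designs = build_designs(ds, spec)
    p = designs[0].X.shape[1]
    skipped = [ds.genes[g] for g, d in enumerate(designs) if d.n <= p]
    if skipped:
        warnings.warn(f"excluding {len(skipped)} gene(s) with n <= p from screening: {skipped[:10]}")
    rows = []
    for g, d in enumerate(designs):
        if d.n <= p:
            continue
        y = ds.values[g][ds.mask[g]]
        coef, _, rank, _ = np.linalg.lstsq(d.X, y, rcond=None)
        rss1 = float(np.sum((y - d.X @ coef) ** 2))
        rss0 = float(np.sum((y - y.mean()) ** 2))
        df1 = rank - 1
        df2 = d.n - rank
        if df1 < 1 or df2 < 1:
            continue
        F = max(rss0 - rss1, 0.0) / df1 / max(rss1 / df2, 1e-300)
        pval = float(sps.f.sf(F, df1, df2))
        rows.append({"gene": ds.genes[g], "F": F, "pvalue": pval})
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adjusted"] = multipletests(table["pvalue"].to_numpy(), method="fdr_bh")[1]
        kept = table.loc[table["p_adjusted"] < alpha, "gene"].tolist()
    else:
        kept = []
    return kept, table
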