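"""Generators for data with the statistical structure the mixture models assume.

Two scenarios are provided.  :func:`simulate_clm_figure1` builds a small
cross-sectional benchmark — eight genes in two clusters measured on 100
samples spread over ten levels of a scalar covariate, with cluster-specific
linear trends — the setting where clustering on regression structure beats
clustering on raw profiles most visibly.  :func:`simulate_lwr_timecourse`
emulates a replicated two-genotype cell-cycle time course: periodic cluster
mean curves sampled every 5 minutes over 0–120 min, two conditions (WT and
a mutant with damped amplitude) with two technical replicates each,
condition-specific dropped time points, gene-level random intercepts shared
across a gene's replicates, and missing-at-random masking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ExpressionDataset, Observation, drop_bad_timepoints


@dataclass
class SimSpec:
    """Study conditions for the replicated longitudinal generator.

    Defaults emulate a two-genotype yeast cell-cycle course: 5-min sampling
    over 0–120 min (25 points), two conditions x two technical replicates,
    one bad WT time point (105 min) and three bad mutant points (25, 40,
    55 min), sinusoidal cluster templates with a 60-min period (two cycles)
    and cluster-specific phases, a damped mutant amplitude, gene-level
    random intercepts (sd 0.3) and residual variance 0.0625 on the
    log-ratio scale, with 5% of cells missing at random.
    """

    n_genes: int = 300
    n_clusters: int = 3
    cluster_sizes: tuple | None = None
    template: str = "sinusoid"
    amplitude: float = 1.0
    period: float = 60.0
    phases: tuple | None = None  # minutes, one per cluster
    conditions: tuple = ("WT", "SM")
    condition_amplitude: tuple = (1.0, 0.6)
    n_replicates: int = 2
    times: tuple = tuple(np.arange(0.0, 121.0, 5.0))
    random_effect_sd: float = 0.3
    sigma2: float = 0.0625
    bad_timepoints: dict = field(
        default_factory=lambda: {"WT": (105.0,), "SM": (25.0, 40.0, 55.0)}
    )
    missing_fraction: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_clusters < 1:
            raise ValueError("n_genes and n_clusters must be >= 1")
        if self.cluster_sizes is None:
            base = self.n_genes // self.n_clusters
            sizes = [base] * self.n_clusters
            for i in range(self.n_genes - base * self.n_clusters):
                sizes[i] += 1
            self.cluster_sizes = tuple(sizes)
        if sum(self.cluster_sizes) != self.n_genes:
            raise ValueError("cluster sizes must sum to n_genes")
        if self.phases is None:
            self.phases = tuple(np.linspace(0.0, self.period, self.n_clusters, endpoint=False))
        if len(self.phases) != self.n_clusters:
            raise ValueError("need one phase per cluster")
        if len(self.condition_amplitude) != len(self.conditions):
            raise ValueError("need one amplitude multiplier per condition")
        if self.template != "sinusoid":
            raise ValueError("only the 'sinusoid' template is implemented")
        if self.sigma2 < 0 or self.random_effect_sd < 0:
            raise ValueError("variances must be non-negative")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValueError("missing_fraction must be in [0, 1)")
        for c in self.bad_timepoints:
            if c not in self.conditions:
                raise ValueError(f"bad_timepoints names unknown condition {c!r}")

    def to_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "n_clusters": self.n_clusters,
            "cluster_sizes": list(self.cluster_sizes),
            "template": self.template,
            "amplitude": self.amplitude,
            "period": self.period,
            "phases": list(map(float, self.phases)),
            "conditions": list(self.conditions),
            "condition_amplitude": list(map(float, self.condition_amplitude)),
            "n_replicates": self.n_replicates,
            "times": list(map(float, self.times)),
            "random_effect_sd": self.random_effect_sd,
            "sigma2": self.sigma2,
            "bad_timepoints": {c: list(map(float, t)) for c, t in self.bad_timepoints.items()},
            "missing_fraction": self.missing_fraction,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimSpec":
        d = dict(d)
        for key in ("cluster_sizes", "phases", "times", "conditions", "condition_amplitude"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "bad_timepoints" in d and d["bad_timepoints"] is not None:
            d["bad_timepoints"] = {c: tuple(t) for c, t in d["bad_timepoints"].items()}
        return cls(**d)

    def cluster_curve(self, k: int, condition: str, times) -> np.ndarray:
        """Noise-free cluster mean curve for one condition."""
        times = np.asarray(times, dtype=float)
        mult = self.condition_amplitude[self.conditions.index(condition)]
        return mult * self.amplitude * np.sin(2.0 * np.pi * (times - self.phases[k]) / self.period)


def simulate_lwr_timecourse(spec: SimSpec, seed: int | None = None):
    """Draw a replicated longitudinal dataset from the mixed-model structure.

    Gene value = cluster mean curve (condition-specific amplitude) + its
    gene-level random intercept for that condition (shared by both technical
    replicates) + independent Gaussian noise.  Bad time points are dropped
    per condition and a missing-at-random mask is applied.

    Returns ``(dataset, labels, truth)`` where ``truth`` carries the
    generating spec, the per-gene random intercepts (genes x conditions) and
    the cluster curves on the retained grid.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    labels = np.repeat(np.arange(spec.n_clusters), spec.cluster_sizes)
    obs = [
        Observation(c, f"r{r + 1}", float(t))
        for c in spec.conditions
        for r in range(spec.n_replicates)
        for t in spec.times
    ]
    obs = sorted(obs)
    N = len(obs)
    G = spec.n_genes
    cond_index = {c: i for i, c in enumerate(spec.conditions)}

    b = rng.normal(0.0, spec.random_effect_sd, size=(G, len(spec.conditions)))
    mean = np.empty((G, N))
    for j, o in enumerate(obs):
        ci = cond_index[o.condition]
        for k in range(spec.n_clusters):
            mean[labels == k, j] = spec.cluster_curve(k, o.condition, o.time)
        mean[:, j] += b[:, ci]
    values = mean + rng.normal(0.0, np.sqrt(spec.sigma2), size=(G, N))
    ds = ExpressionDataset([f"gene{g + 1:04d}" for g in range(G)], obs, values, np.ones((G, N), bool))

    removals = [(c, t) for c, ts in spec.bad_timepoints.items() for t in ts]
    if removals:
        ds = drop_bad_timepoints(ds, removals)
    if spec.missing_fraction > 0:
        mar = rng.random(ds.mask.shape) < spec.missing_fraction
        ds.mask &= ~mar

    curves = {}
    retained_times = {}
    for c in spec.conditions:
        tc = np.unique([o.time for o in ds.observations if o.condition == c])
        retained_times[c] = tc
        curves[c] = np.stack([spec.cluster_curve(k, c, tc) for k in range(spec.n_clusters)])
    truth = {
        "spec": spec,
        "random_effects": b,
        "retained_times": retained_times,
        "cluster_curves": curves,
    }
    return ds, labels, truth


# -- cross-sectional two-cluster benchmark -----------------------------------

#: documented constants of the cross-sectional benchmark (the published
#: figure does not print its magnitudes): cluster slopes +/-0.5 per X unit,
#: intercepts centering each line at zero over X = 1..10, gene-specific
#: offsets with sd 0.2, residual sd 0.5.
FIGURE1_SLOPES = (0.5, -0.5)
FIGURE1_OFFSET_SD = 0.2
FIGURE1_NOISE_SD = 0.5


def simulate_clm_figure1(seed: int | None = None, noise_sd: float = FIGURE1_NOISE_SD):
    """Eight genes, two clusters of four, ten X levels x ten samples (N=100).

    Cluster means are linear in the covariate X with cluster-distinct
    slopes; each gene adds a small constant offset; observations add
    independent Gaussian noise.  Returns ``(dataset, labels)``.
    """
    rng = np.random.default_rng(seed)
    G, n_levels, per_level = 8, 10, 10
    labels = np.repeat([0, 1], 4)
    levels = np.arange(1.0, n_levels + 1.0)
    obs = sorted(
        Observation("all", f"s{s + 1:02d}", float(x)) for x in levels for s in range(per_level)
    )
    x = np.array([o.time for o in obs])
    offsets = rng.normal(0.0, FIGURE1_OFFSET_SD, size=G)
    center = (levels[0] + levels[-1]) / 2.0
    mean = np.empty((G, len(obs)))
    for g in range(G):
        slope = FIGURE1_SLOPES[labels[g]]
        mean[g] = slope * (x - center) + offsets[g]
    values = mean + rng.normal(0.0, noise_sd, size=mean.shape)
    ds = ExpressionDataset(
        [f"gene{g + 1}" for g in range(G)], obs, values, np.ones(mean.shape, bool)
    )
    return ds, labels


def truth_table(labels, random_effects=None) -> pd.DataFrame:
    """Truth as a writable table: gene row index, cluster, random effects."""
    df = pd.DataFrame({"gene": np.arange(len(labels)) + 1, "cluster": np.asarray(labels) + 1})
    if random_effects is not None:
        re = np.asarray(random_effects)
        for j in range(re.shape[1]):
            df[f"b{j + 1}"] = re[:, j]
    return df
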