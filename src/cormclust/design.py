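"""B-spline time bases and per-gene fixed/random design matrices.

The fixed-effect design codes each gene's expected profile as a B-spline
curve in time (one coefficient block per condition when condition blocking
is on).  The random-effect design carries the gene-level deviation shared by
all of a gene's observations — both technical replicates of a condition see
the same realized random effect, which is how replication enters the
hierarchical model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml
from scipy.interpolate import BSpline

from .data_model import ExpressionDataset


class DomainError(ValueError):
    """Evaluation point outside the spline's time range."""


class ValidationError(ValueError):
    """Dataset incompatible with the requested design (e.g. too few rows)."""

    def __init__(self, message: str, genes: list | None = None):
        super().__init__(message)
        self.genes = genes or []


RANDOM_DESIGNS = ("per-condition-intercept", "basis-subset", "none")


@dataclass
class DesignSpec:
    """Rules for building spline bases and per-gene design matrices.

    Parameters
    ----------
    degree
        Spline degree (3 = cubic, the default).
    n_interior_knots
        Number of equally spaced interior knots on the open time range.
        With boundary knots at the range ends at full multiplicity the basis
        has ``n_interior_knots + degree + 1`` columns.
    time_range
        Closed interval [t_min, t_max] the basis lives on.
    condition_blocking
        If True, each condition gets its own fixed-effect coefficient block
        (zeros elsewhere), so p = basis width x number of conditions.
    random_design
        "per-condition-intercept" — one gene-level random intercept per
        condition (q = number of conditions); "basis-subset" — random
        coefficients on the first ``q_basis`` basis columns; "none" — no
        random effects (q = 0, the pure mixture-of-linear-models case).
    q_basis
        Number of basis columns receiving random coefficients under
        "basis-subset".
    """

    degree: int = 3
    n_interior_knots: int = 7
    time_range: tuple = (0.0, 120.0)
    condition_blocking: bool = False
    random_design: str = "per-condition-intercept"
    q_basis: int = 1

    def __post_init__(self) -> None:
        if self.degree < 0:
            raise ValueError("degree must be >= 0")
        if self.n_interior_knots < 0:
            raise ValueError("n_interior_knots must be >= 0")
        t0, t1 = self.time_range
        if not t1 > t0:
            raise ValueError("time_range must have t_max > t_min")
        if self.random_design not in RANDOM_DESIGNS:
            raise ValueError(f"random_design must be one of {RANDOM_DESIGNS}")
        if self.random_design == "basis-subset" and not (1 <= self.q_basis <= self.n_basis):
            raise ValueError("q_basis must be in [1, basis width]")

    @property
    def n_basis(self) -> int:
        return self.n_interior_knots + self.degree + 1

    def n_blocks(self, conditions: Sequence) -> int:
        return len(conditions) if self.condition_blocking else 1

    def p(self, conditions: Sequence) -> int:
        return self.n_basis * self.n_blocks(conditions)

    def q(self, conditions: Sequence) -> int:
        if self.random_design == "per-condition-intercept":
            return len(conditions)
        if self.random_design == "basis-subset":
            return self.q_basis
        return 0

    # -- config round-trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "knots": self.n_interior_knots,
            "time_min": float(self.time_range[0]),
            "time_max": float(self.time_range[1]),
            "condition_blocking": self.condition_blocking,
            "random_design": self.random_design,
            "q": self.q_basis,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        return cls(
            degree=int(d.get("degree", 3)),
            n_interior_knots=int(d.get("knots", 7)),
            time_range=(float(d.get("time_min", 0.0)), float(d.get("time_max", 120.0))),
            condition_blocking=bool(d.get("condition_blocking", False)),
            random_design=str(d.get("random_design", "per-condition-intercept")),
            q_basis=int(d.get("q", 1)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "DesignSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class GeneDesign:
    """Per-gene design: fixed rows X_g, random rows Z_g for observed entries."""

    X: np.ndarray  # (n_g, p)
    Z: np.ndarray  # (n_g, q)
    n: int
    obs_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def knot_vector(spec: DesignSpec) -> np.ndarray:
    t0, t1 = map(float, spec.time_range)
    interior = np.linspace(t0, t1, spec.n_interior_knots + 2)[1:-1]
    return np.r_[[t0] * (spec.degree + 1), interior, [t1] * (spec.degree + 1)]


def bspline_basis(times, spec: DesignSpec) -> np.ndarray:
    """Evaluate the B-spline basis at ``times``; rows sum to one.

    The basis has ``spec.n_basis`` columns, spans constants, and is a
    partition of unity on the closed time range.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    t0, t1 = spec.time_range
    if times.size and (times.min() < t0 or times.max() > t1):
        raise DomainError(f"times outside range [{t0}, {t1}]")
    B = BSpline.design_matrix(times, knot_vector(spec), spec.degree, extrapolate=False)
    return B.toarray()


def full_design(observations, conditions: Sequence, spec: DesignSpec):
    """Fixed/random design rows for every observation column (no masking).

    Returns ``(X_full, Z_full)`` of shape (N, p) and (N, q); per-gene designs
    are row subsets of these.
    """
    times = np.array([o.time for o in observations])
    basis = bspline_basis(times, spec)
    N, nb = basis.shape
    cond_of = np.array([conditions.index(o.condition) for o in observations])

    if spec.condition_blocking:
        X = np.zeros((N, nb * len(conditions)))
        for b in range(len(conditions)):
            rows = cond_of == b
            X[rows, b * nb : (b + 1) * nb] = basis[rows]
    else:
        X = basis

    if spec.random_design == "per-condition-intercept":
        Z = np.zeros((N, len(conditions)))
        Z[np.arange(N), cond_of] = 1.0
    elif spec.random_design == "basis-subset":
        Z = basis[:, : spec.q_basis].copy()
    else:
        Z = np.zeros((N, 0))
    return X, Z


def build_designs(ds: ExpressionDataset, spec: DesignSpec) -> list:
    """Per-gene designs: stack the full-design rows of each gene's observed entries."""
    conditions = ds.conditions
    X_full, Z_full = full_design(ds.observations, conditions, spec)
    designs = []
    for g in range(ds.n_genes):
        idx = np.flatnonzero(ds.mask[g])
        designs.append(GeneDesign(X_full[idx], Z_full[idx], len(idx), idx))
    return designs


def validate_designs(designs: Sequence[GeneDesign], p: int, genes: Sequence) -> None:
    """Raise if any gene has fewer observed entries than fixed-effect columns."""
    bad = [genes[g] for g, d in enumerate(designs) if d.n < p]
    if bad:
        raise ValidationError(
            f"{len(bad)} gene(s) have fewer than p={p} observed entries: {bad[:10]}",
            genes=bad,
        )
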