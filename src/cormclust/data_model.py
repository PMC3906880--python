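"""Containers and I/O for replicated longitudinal (LWR) expression data.

Expression values live on the log-ratio scale in a genes x observations
matrix.  Each observation (one microarray measurement column) carries a
``(condition, replicate, time)`` triple; technical replicates of the same
biological sample share a condition label and differ only in replicate.

Missingness is carried by an explicit boolean mask, never by sentinel
numbers.  All downstream likelihoods delete masked rows per gene, which is
the correct treatment when values are missing at random (MAR).  Observation
columns are kept in canonical ``(condition, replicate, time)`` lexicographic
order so that design matrices and fits are reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A table does not have the required columns/layout."""


class DataError(ValueError):
    """A table has the right layout but inconsistent content."""


#: default long-table column names; override via the ``columns`` mapping.
DEFAULT_COLUMNS = {
    "gene": "gene",
    "condition": "condition",
    "replicate": "replicate",
    "time": "time",
    "value": "value",
}


@dataclass(frozen=True, order=True)
class Observation:
    """One measurement column: a (condition, replicate, time) triple.

    The dataclass ordering (condition, then replicate, then time) is the
    canonical observation order used throughout the package.
    """

    condition: str
    replicate: str
    time: float


@dataclass
class ExpressionDataset:
    """Genes x observations expression matrix with metadata and mask.

    Parameters
    ----------
    genes
        Ordered gene identifiers (length G).
    observations
        Ordered :class:`Observation` metadata (length N).  Reordered to
        canonical (condition, replicate, time) order at construction,
        together with the matrix columns.
    values
        G x N array of log-ratio expression values.  Entries with
        ``mask == False`` are treated as missing; their numeric content is
        irrelevant to all fitting code.
    mask
        G x N boolean array, True where a value was observed.
    """

    genes: list
    observations: list
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.observations = list(self.observations)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        G, N = len(self.genes), len(self.observations)
        if G < 1 or N < 1:
            raise DataError("dataset needs at least one gene and one observation")
        if self.values.shape != (G, N) or self.mask.shape != (G, N):
            raise DataError(
                f"values/mask shape {self.values.shape}/{self.mask.shape} "
                f"does not match G={G}, N={N}"
            )
        if len(set(self.genes)) != G:
            raise DataError("duplicate gene identifiers")
        if len(set(self.observations)) != N:
            raise DataError("duplicate (condition, replicate, time) observations")
        if any(o.time < 0 for o in self.observations):
            raise DataError("negative observation time")
        order = sorted(range(N), key=lambda j: self.observations[j])
        if order != list(range(N)):
            self.observations = [self.observations[j] for j in order]
            self.values = self.values[:, order]
            self.mask = self.mask[:, order]

    # -- basic introspection -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    @property
    def conditions(self) -> list:
        """Distinct condition labels in canonical (sorted) order."""
        return sorted({o.condition for o in self.observations})

    @property
    def times(self) -> np.ndarray:
        return np.array([o.time for o in self.observations])

    def gene_index(self, gene) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def obs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": [o.condition for o in self.observations],
                "replicate": [o.replicate for o in self.observations],
                "time": [o.time for o in self.observations],
            }
        )

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            list(self.genes),
            list(self.observations),
            self.values.copy(),
            self.mask.copy(),
        )


# -- long-format I/O ---------------------------------------------------------


def _resolve_columns(columns: Mapping[str, str] | None) -> dict:
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        unknown = set(columns) - set(cols)
        if unknown:
            raise FormatError(f"unknown column roles: {sorted(unknown)}")
        cols.update(columns)
    return cols


def _infer_sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_long_table(
    path,
    columns: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> ExpressionDataset:
    """Read a long-format delimited table into an :class:`ExpressionDataset`.

    The table must have gene, condition, replicate, time and value columns
    (names configurable through ``columns``).  An empty value field marks a
    missing measurement.  A (gene, condition, replicate, time) combination
    absent from the table is likewise missing.  Duplicate combinations are
    rejected.
    """
    cols = _resolve_columns(columns)
    df = pd.read_csv(path, sep=sep or _infer_sep(path), dtype=str, keep_default_na=False)
    missing = [cols[r] for r in ("gene", "condition", "replicate", "time", "value") if cols[r] not in df.columns]
    if missing:
        raise FormatError(f"required column(s) missing: {missing}")
    key = [cols["gene"], cols["condition"], cols["replicate"], cols["time"]]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.loc[dup, key].iloc[0].tolist()
        raise DataError(f"duplicate (gene, condition, replicate, time) row: {first}")

    genes = list(dict.fromkeys(df[cols["gene"]]))
    obs = sorted(
        {
            Observation(str(c), str(r), float(t))
            for c, r, t in zip(df[cols["condition"]], df[cols["replicate"]], df[cols["time"]])
        }
    )
    gidx = {g: i for i, g in enumerate(genes)}
    oidx = {o: j for j, o in enumerate(obs)}
    values = np.full((len(genes), len(obs)), np.nan)
    mask = np.zeros((len(genes), len(obs)), dtype=bool)
    for g, c, r, t, v in zip(
        df[cols["gene"]], df[cols["condition"]], df[cols["replicate"]], df[cols["time"]], df[cols["value"]]
    ):
        i, j = gidx[g], oidx[Observation(str(c), str(r), float(t))]
        v = v.strip()
        if v != "" and v.lower() != "nan":
            values[i, j] = float(v)
            mask[i, j] = True
    return ExpressionDataset(genes, obs, values, mask)


def write_long_table(
    ds: ExpressionDataset,
    path,
    columns: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> None:
    """Write the dataset as a long-format table; masked cells get empty values."""
    cols = _resolve_columns(columns)
    records = []
    for i, g in enumerate(ds.genes):
        for j, o in enumerate(ds.observations):
            records.append(
                {
                    cols["gene"]: g,
                    cols["condition"]: o.condition,
                    cols["replicate"]: o.replicate,
                    cols["time"]: o.time,
                    cols["value"]: ds.values[i, j] if ds.mask[i, j] else "",
                }
            )
    pd.DataFrame.from_records(records).to_csv(path, sep=sep or _infer_sep(path), index=False)


def read_wide_matrix(values_path, metadata_path, sep: str | None = None) -> ExpressionDataset:
    """Read a wide genes x observations matrix plus an observation-metadata table.

    The matrix's first column holds gene identifiers; the remaining column
    headers are observation ids.  The metadata table maps each observation id
    to condition, replicate and time (columns: ``observation``, ``condition``,
    ``replicate``, ``time``).
    """
    vals = pd.read_csv(values_path, sep=sep or _infer_sep(values_path), index_col=0)
    meta = pd.read_csv(metadata_path, sep=sep or _infer_sep(metadata_path), dtype=str)
    need = {"observation", "condition", "replicate", "time"}
    if not need.issubset(meta.columns):
        raise FormatError(f"metadata needs columns {sorted(need)}")
    meta = meta.set_index("observation")
    missing = [c for c in vals.columns if c not in meta.index]
    if missing:
        raise DataError(f"observations without metadata: {missing}")
    obs = [
        Observation(str(meta.loc[c, "condition"]), str(meta.loc[c, "replicate"]), float(meta.loc[c, "time"]))
        for c in vals.columns
    ]
    values = vals.to_numpy(dtype=float)
    return ExpressionDataset(list(vals.index), obs, values, ~np.isnan(values))


# -- editing operations ------------------------------------------------------


def drop_bad_timepoints(
    ds: ExpressionDataset, removals: Iterable[tuple]
) -> ExpressionDataset:
    """Delete every observation matching a (condition, time) pair, all genes.

    Mirrors the removal of technically failed arrays from an experiment; the
    pairs are dropped for every gene and every replicate of that condition.
    """
    removals = [(str(c), float(t)) for c, t in removals]
    conditions = set(ds.conditions)
    for c, _ in removals:
        if c not in conditions:
            raise KeyError(f"no such condition: {c!r}")
    bad = set(removals)
    keep = [j for j, o in enumerate(ds.observations) if (o.condition, o.time) not in bad]
    if not keep:
        raise DataError("removals would delete every observation")
    return ExpressionDataset(
        list(ds.genes),
        [ds.observations[j] for j in keep],
        ds.values[:, keep].copy(),
        ds.mask[:, keep].copy(),
    )


def mask_entries(
    ds: ExpressionDataset, cells: Sequence[tuple]
) -> ExpressionDataset:
    """Return a copy with the listed (gene, observation-index) cells masked.

    ``gene`` may be an identifier or an integer row index.  Values are left
    untouched; only the mask flips (to False) at the listed cells.
    """
    out = ds.copy()
    for gene, j in cells:
        i = gene if isinstance(gene, (int, np.integer)) else out.gene_index(gene)
        if not (0 <= i < out.n_genes):
            raise IndexError(f"gene index {i} out of range")
        if not (0 <= j < out.n_obs):
            raise IndexError(f"observation index {j} out of range")
        out.mask[i, j] = False
    return out


def write_assignments(genes, map_labels, posterior, path, sep: str = "\t") -> None:
    """Write per-gene cluster assignments: gene, map_cluster, posterior_1..K."""
    posterior = np.asarray(posterior)
    K = posterior.shape[1]
    df = pd.DataFrame({"gene": list(genes), "map_cluster": np.asarray(map_labels) + 1})
    for k in range(K):
        df[f"posterior_{k + 1}"] = posterior[:, k]
    df.to_csv(path, sep=sep, index=False)
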