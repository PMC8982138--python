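"""Containers and I/O for paired sequencing-count and concentration tables.

The package works with two per-sample-per-taxon integer tables:

* a count table ``W`` (n samples x q taxa) of sequencing reads, with
  per-sample read depths ``M_i = sum_j W_ij``;
* a concentration table ``V`` (n samples x qobs taxa) of observed absolute
  abundances (e.g., 16S gene copies per swab) for a subset of the taxa.

Both are stored dense, samples as rows, taxa as columns, with string
identifiers.  Files are plain delimited text (CSV, or TSV for ``.tsv``
paths) with a header row of taxon ids and a first column of sample ids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "ConcentrationTable",
    "CovariateDesign",
    "PairedDataset",
    "read_count_table",
    "read_concentration_table",
    "write_count_table",
    "write_concentration_table",
    "align_tables",
    "prevalence_filter",
]


def _check_ids(ids, what):
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValueError(f"duplicate {what}: {dupes}")
    return ids


def _as_int_matrix(X, what, allow_round=False):
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError(f"{what} must be a 2-d matrix, got shape {X.shape}")
    if np.issubdtype(X.dtype, np.floating):
        if not allow_round:
            if not np.allclose(X, np.round(X)):
                raise ValueError(f"{what} contains non-integer entries")
        elif not np.allclose(X, np.round(X)):
            warnings.warn(
                f"{what} contains non-integer values; rounding to the "
                "nearest integer (the observation model is a count model)",
                stacklevel=3,
            )
        X = np.round(X)
    elif not np.issubdtype(X.dtype, np.integer):
        raise ValueError(f"{what} must be numeric, got dtype {X.dtype}")
    X = X.astype(np.int64)
    if (X < 0).any():
        raise ValueError(f"{what} contains negative entries")
    return X


@dataclass(frozen=True)
class CountTable:
    """Sequencing read counts ``W`` with read depths recomputed as row sums."""

    W: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]

    def __post_init__(self):
        W = _as_int_matrix(self.W, "count table W")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "sample_ids", _check_ids(self.sample_ids, "sample_ids"))
        object.__setattr__(self, "taxon_ids", _check_ids(self.taxon_ids, "taxon_ids"))
        if W.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError(
                f"W has shape {W.shape}, expected "
                f"({len(self.sample_ids)}, {len(self.taxon_ids)})"
            )

    @property
    def M(self) -> np.ndarray:
        """Per-sample read depths (row sums of W)."""
        return self.W.sum(axis=1)

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def q(self) -> int:
        return self.W.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=self.sample_ids, columns=self.taxon_ids)


@dataclass(frozen=True)
class ConcentrationTable:
    """Observed concentrations ``V`` for a subset of taxa (integer counts)."""

    V: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]

    def __post_init__(self):
        V = np.asarray(self.V)
        if np.issubdtype(V.dtype, np.floating) and np.isnan(V).any():
            raise ValueError(
                "concentration table V contains missing values; observed "
                "concentrations must be available for every sample and taxon"
            )
        V = _as_int_matrix(V, "concentration table V", allow_round=True)
        object.__setattr__(self, "V", V)
        object.__setattr__(self, "sample_ids", _check_ids(self.sample_ids, "sample_ids"))
        object.__setattr__(self, "taxon_ids", _check_ids(self.taxon_ids, "taxon_ids"))
        if V.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError(
                f"V has shape {V.shape}, expected "
                f"({len(self.sample_ids)}, {len(self.taxon_ids)})"
            )

    @property
    def n(self) -> int:
        return self.V.shape[0]

    @property
    def qobs(self) -> int:
        return self.V.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.V, index=self.sample_ids, columns=self.taxon_ids)


@dataclass(frozen=True)
class CovariateDesign:
    """A single per-sample covariate (binary or real), e.g. case/control."""

    X: np.ndarray
    label: str = "x"

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float).ravel()
        if np.isnan(X).any():
            raise ValueError("covariate contains missing values")
        object.__setattr__(self, "X", X)


@dataclass(frozen=True)
class PairedDataset:
    """An aligned (W, V) pair: observed taxa occupy columns ``0..qobs-1`` of W.

    ``qobs == q`` is permitted (every taxon observed; degenerate but legal,
    used e.g. by the leave-one-taxon-out validation).
    """

    counts: CountTable
    concentrations: ConcentrationTable
    covariates: CovariateDesign | None = None

    def __post_init__(self):
        c, v = self.counts, self.concentrations
        if c.sample_ids != v.sample_ids:
            raise ValueError("sample_ids of counts and concentrations differ")
        if v.qobs > c.q:
            raise ValueError(f"qobs={v.qobs} exceeds q={c.q}")
        if c.taxon_ids[: v.qobs] != v.taxon_ids:
            raise ValueError(
                "observed taxa must occupy the leading columns of W in the "
                "order of the concentration table; use align_tables()"
            )
        if self.covariates is not None and len(self.covariates.X) != c.n:
            raise ValueError("covariate length does not match sample count")

    @property
    def n(self) -> int:
        return self.counts.n

    @property
    def q(self) -> int:
        return self.counts.q

    @property
    def qobs(self) -> int:
        return self.concentrations.qobs

    @property
    def W(self) -> np.ndarray:
        return self.counts.W

    @property
    def V(self) -> np.ndarray:
        return self.concentrations.V

    @property
    def M(self) -> np.ndarray:
        return self.counts.M


def _read_table(path, cls):
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.isnull().any() or df.columns.isnull().any():
        raise ValueError(f"{path}: missing sample or taxon identifiers")
    return cls(
        df.to_numpy(),
        sample_ids=[str(s) for s in df.index],
        taxon_ids=[str(t) for t in df.columns],
    )


def read_count_table(path) -> CountTable:
    """Read a samples-by-taxa count table from delimited text.

    Read depths ``M`` are recomputed as row sums on load.
    """
    return _read_table(path, CountTable)


def read_concentration_table(path) -> ConcentrationTable:
    return _read_table(path, ConcentrationTable)


def _write_table(frame, path):
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    frame.to_csv(path, sep=sep, index_label="sample_id")


def write_count_table(table: CountTable, path) -> None:
    _write_table(table.to_frame(), path)


def write_concentration_table(table: ConcentrationTable, path) -> None:
    _write_table(table.to_frame(), path)


def align_tables(
    counts: CountTable,
    conc: ConcentrationTable,
    covariates: CovariateDesign | None = None,
) -> tuple[PairedDataset, np.ndarray]:
    """Align a count table with a concentration table.

    Rows are reordered to the sample order of ``counts``; columns of W are
    permuted so the taxa of ``conc`` occupy positions ``0..qobs-1`` in the
    order of ``conc.taxon_ids``.  Returns the paired dataset and the column
    permutation applied (``W_aligned = W[:, perm]``).
    """
    missing_taxa = [t for t in conc.taxon_ids if t not in counts.taxon_ids]
    if missing_taxa:
        raise ValueError(f"concentration taxa absent from count table: {missing_taxa}")
    if set(counts.sample_ids) != set(conc.sample_ids):
        raise ValueError("count and concentration tables cover different samples")
    if conc.qobs >= counts.q:
        raise ValueError(
            f"qobs={conc.qobs} must be smaller than q={counts.q} for alignment"
        )
    row_order = [conc.sample_ids.index(s) for s in counts.sample_ids]
    conc = ConcentrationTable(
        conc.V[row_order, :], sample_ids=counts.sample_ids, taxon_ids=conc.taxon_ids
    )
    pos = {t: k for k, t in enumerate(counts.taxon_ids)}
    obs = [pos[t] for t in conc.taxon_ids]
    rest = [k for k in range(counts.q) if k not in set(obs)]
    perm = np.array(obs + rest, dtype=np.int64)
    aligned = CountTable(
        counts.W[:, perm],
        sample_ids=counts.sample_ids,
        taxon_ids=[counts.taxon_ids[k] for k in perm],
    )
    return PairedDataset(aligned, conc, covariates), perm


def prevalence_filter(
    counts: CountTable,
    min_prevalence: float,
    protect: ConcentrationTable | None = None,
) -> CountTable:
    """Drop taxa detected (``W_ij > 0``) in fewer than ``ceil(p * n)`` samples.

    Taxa present in ``protect`` (a paired concentration table) are never
    removed; a warning is emitted instead.
    """
    if not 0.0 <= min_prevalence <= 1.0:
        raise ValueError("min_prevalence must lie in [0, 1]")
    threshold = int(np.ceil(min_prevalence * counts.n))
    n_present = (counts.W > 0).sum(axis=0)
    keep = n_present >= threshold
    if protect is not None:
        protected = np.array([t in set(protect.taxon_ids) for t in counts.taxon_ids])
        rescued = protected & ~keep
        if rescued.any():
            names = [t for t, r in zip(counts.taxon_ids, rescued) if r]
            warnings.warn(
                f"taxa {names} fall below the prevalence threshold but have "
                "observed concentrations; keeping them",
                stacklevel=2,
            )
        keep |= protected
    idx = np.flatnonzero(keep)
    return CountTable(
        counts.W[:, idx],
        sample_ids=counts.sample_ids,
        taxon_ids=[counts.taxon_ids[k] for k in idx],
    )
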