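"""Expression-matrix data model and I/O.

Expression data live on the log scale in a genes x samples matrix with
string identifiers on both axes.  All downstream modelling assumes each
gene row has been centered at zero (variances are deliberately *not*
scaled: the magnitude of log-fold variation is biologically meaningful
and is assumed to transfer across array platforms).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CovariateTable",
    "read_expression",
    "write_expression",
    "read_covariates",
    "write_covariates",
    "center_genes",
    "collapse_replicates",
    "intersect_genes",
    "zero_variance_genes",
]

_CENTER_TOL = 1e-10


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i).strip() for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what} identifiers: {sorted(set(dups))[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log-expression values.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_samples)
        Log-scale expression, finite, no missing values.
    gene_ids, sample_ids : sequences of unique strings
        Row and column identifiers (whitespace-trimmed on construction).
    centered : bool
        True once every gene row has mean zero (see :func:`center_genes`).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    centered: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d genes x samples array")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no NaN/Inf)")
        if self.centered:
            row_means = self.values.mean(axis=1)
            if np.any(np.abs(row_means) > _CENTER_TOL):
                raise ValueError("centered=True but some gene rows have nonzero mean")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, centered: bool = False) -> "ExpressionMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            centered=centered,
        )

    def gene_row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


@dataclass
class CovariateTable:
    """Per-sample covariates for a small experiment.

    condition is a 0/1 indicator (1 = perturbed/case).  pair_id groups
    samples into case-control families (dye-swap pairs, trios, ...);
    every group must contain at least two samples.  time_radians carries
    circadian collection times already converted to angles.
    """

    condition: np.ndarray
    pair_id: np.ndarray | None = None
    time_radians: np.ndarray | None = None
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.condition = np.asarray(self.condition)
        if not np.isin(self.condition, [0, 1]).all():
            raise ValueError("condition must contain only 0/1 indicators")
        self.condition = self.condition.astype(int)
        n = len(self.condition)
        if self.pair_id is not None:
            self.pair_id = np.asarray([str(p) for p in self.pair_id])
            if len(self.pair_id) != n:
                raise ValueError("pair_id length does not match condition length")
            _, counts = np.unique(self.pair_id, return_counts=True)
            if np.any(counts < 2):
                raise ValueError("every pair_id must appear for at least 2 samples")
        if self.time_radians is not None:
            self.time_radians = np.asarray(self.time_radians, dtype=float)
            if len(self.time_radians) != n:
                raise ValueError("time_radians length does not match condition length")
            if not np.all(np.isfinite(self.time_radians)):
                raise ValueError("time_radians must be finite")
        if self.sample_ids is not None:
            self.sample_ids = _check_unique(self.sample_ids, "sample")
            if len(self.sample_ids) != n:
                raise ValueError("sample_ids length does not match condition length")

    @property
    def n_samples(self) -> int:
        return len(self.condition)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path: str | Path, orientation: str = "genes-in-rows"
) -> ExpressionMatrix:
    """Read a delimited expression matrix (TSV by default, CSV by suffix).

    The first column holds gene identifiers and the header row holds
    sample identifiers; ``orientation="genes-in-columns"`` reads the
    transposed layout.
    """
    path = Path(path)
    if orientation not in ("genes-in-rows", "genes-in-columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if orientation == "genes-in-columns":
        frame = frame.T
    body = frame.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        bad = np.argwhere(body.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric cell in {path.name} at gene {frame.index[bad[0]]!r}, "
            f"sample {frame.columns[bad[1]]!r}"
        )
    return ExpressionMatrix.from_frame(body)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    m.to_frame().to_csv(path, sep=_sep_for(path), index_label="gene_id", float_format="%.12g")


def read_covariates(path: str | Path) -> CovariateTable:
    """Read a covariate table with columns sample_id, condition[, pair_id, time_radians]."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path))
    if "sample_id" not in frame or "condition" not in frame:
        raise ValueError("covariate table needs 'sample_id' and 'condition' columns")
    return CovariateTable(
        condition=frame["condition"].to_numpy(),
        pair_id=frame["pair_id"].to_numpy() if "pair_id" in frame else None,
        time_radians=frame["time_radians"].to_numpy() if "time_radians" in frame else None,
        sample_ids=[str(s) for s in frame["sample_id"]],
    )


def write_covariates(cov: CovariateTable, path: str | Path) -> None:
    path = Path(path)
    data: dict[str, object] = {
        "sample_id": cov.sample_ids
        if cov.sample_ids is not None
        else [f"s{i:03d}" for i in range(cov.n_samples)],
        "condition": cov.condition,
    }
    if cov.pair_id is not None:
        data["pair_id"] = cov.pair_id
    if cov.time_radians is not None:
        data["time_radians"] = cov.time_radians
    pd.DataFrame(data).to_csv(path, sep=_sep_for(path), index=False)


def center_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Center every gene row at mean zero.  Variances are left unscaled."""
    centered = m.values - m.values.mean(axis=1, keepdims=True)
    return dataclasses.replace(m, values=centered, centered=True)


def collapse_replicates(
    m: ExpressionMatrix,
    spot_to_gene: Mapping[str, str],
    array_to_subject: Mapping[str, str],
) -> ExpressionMatrix:
    """Average array spots to genes and replicate arrays to subjects.

    Spots mapping to the same gene symbol are averaged row-wise, then
    replicate arrays of the same subject are averaged column-wise (dye
    channels count as plain replicates).  Output rows/columns follow the
    first appearance order of each mapped gene/subject, so identity maps
    leave the matrix unchanged.
    """
    missing_spots = [g for g in m.gene_ids if g not in spot_to_gene]
    if missing_spots:
        raise ValueError(f"unmapped spots: {missing_spots[:5]}")
    missing_arrays = [s for s in m.sample_ids if s not in array_to_subject]
    if missing_arrays:
        raise ValueError(f"unmapped arrays: {missing_arrays[:5]}")

    frame = m.to_frame()
    gene_of = pd.Series([str(spot_to_gene[g]).strip() for g in m.gene_ids], index=frame.index)
    subject_of = pd.Series(
        [str(array_to_subject[s]).strip() for s in m.sample_ids], index=frame.columns
    )
    genes = list(dict.fromkeys(gene_of))
    subjects = list(dict.fromkeys(subject_of))
    by_gene = frame.groupby(gene_of, sort=False).mean().loc[genes]
    collapsed = by_gene.T.groupby(subject_of, sort=False).mean().T.loc[:, subjects]
    return ExpressionMatrix.from_frame(collapsed)


def intersect_genes(
    db: ExpressionMatrix, expt: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to the shared gene set, lexicographically ordered."""
    shared = sorted(set(db.gene_ids) & set(expt.gene_ids))
    if not shared:
        raise ValueError("no gene identifiers in common between the two matrices")

    def _take(m: ExpressionMatrix) -> ExpressionMatrix:
        idx = [m.gene_ids.index(g) for g in shared]
        return dataclasses.replace(
            m, values=m.values[idx], gene_ids=list(shared), sample_ids=list(m.sample_ids)
        )

    return _take(db), _take(expt)


def zero_variance_genes(m: ExpressionMatrix) -> list[str]:
    """Gene ids whose expression is constant across samples.

    Constant genes are degenerate as ridge outcomes; callers exclude or
    flag them before network fitting.
    """
    variances = m.values.var(axis=1)
    return [g for g, v in zip(m.gene_ids, variances) if v == 0.0]
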