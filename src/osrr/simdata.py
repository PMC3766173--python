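"""Synthetic data generators with ground truth, and method-evaluation
metrics.

Two study designs are generated, both built on compound-symmetric
multivariate Gaussian blocks (common unit variance, one shared within-
block correlation), drawn with the exact factor construction

    x_ij = sqrt(rho) * f_i + sqrt(1 - rho) * e_ij

(f a per-sample shared factor, e idiosyncratic noise), which realises
the target covariance exactly rather than through a generic
factorisation.

* Study 1 (coefficient equalisation): a single continuous outcome
  driven by two independent blocks of 100 correlated predictors
  (rho = 0.9) with identical within-block effects +1 and -1, N = 201,
  unit Gaussian noise.  Heavily penalised ridge followed by the
  over-shrinkage rescaling should recover the common block effects.
* Study 2 (differential expression): a database of G = 200 genes by
  N = 100 samples with two compound-symmetric blocks of 100 genes
  (rho = 0.8), plus an independent 20-sample experiment with the same
  correlation structure, split 10 control / 10 treated.  Each gene is
  differentially expressed with probability 0.2; affected genes have
  delta = 1.0 added to or subtracted from the treated samples (fair
  coin per gene).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exprdata import CovariateTable, ExpressionMatrix, write_covariates, write_expression

__all__ = [
    "SimConfig",
    "SimulatedStudy",
    "Study1Data",
    "compound_symmetric_blocks",
    "simulate_study1",
    "simulate_de_study",
    "evaluate_methods",
    "write_study",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic study designs (defaults = study 2)."""

    n_samples_db: int = 100
    n_samples_expt: int = 20
    n_genes: int = 200
    block_sizes: tuple[int, ...] = (100, 100)
    rho: float = 0.8
    noise_sd: float = 1.0
    de_prob: float = 0.2
    de_effect: float = 1.0
    coef_pos: float = 1.0
    coef_neg: float = -1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.block_sizes) != self.n_genes:
            raise ValueError("block sizes must sum to n_genes")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if not 0.0 <= self.de_prob <= 1.0:
            raise ValueError("de_prob must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclass
class SimulatedStudy:
    """A generated database + experiment pair with full ground truth."""

    database: ExpressionMatrix
    experiment: ExpressionMatrix
    covariates: CovariateTable
    truth: pd.DataFrame  # gene_id, is_de, true_delta, block
    config: SimConfig


@dataclass
class Study1Data:
    """Single-outcome design: predictors, outcome and true coefficients."""

    predictors: np.ndarray  # (n_samples, n_predictors)
    outcome: np.ndarray
    true_coef: np.ndarray
    block: np.ndarray  # block index per predictor


def compound_symmetric_blocks(
    rng: np.random.Generator, n_samples: int, block_sizes: Sequence[int], rho: float
) -> np.ndarray:
    """Draw (n_samples, sum(block_sizes)) with unit-variance compound
    symmetry within each block and independence across blocks."""
    cols = []
    for size in block_sizes:
        shared = rng.standard_normal((n_samples, 1))
        idio = rng.standard_normal((n_samples, size))
        cols.append(np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * idio)
    return np.concatenate(cols, axis=1)


def simulate_study1(config: SimConfig | None = None, seed: int | None = None) -> Study1Data:
    """Correlated-predictor regression design (two blocks, effects +-1).

    Defaults: N = 201 samples, two independent blocks of 100 predictors,
    rho = 0.9, coefficients +1 within block 1 and -1 within block 2,
    unit Gaussian noise on the outcome.
    """
    if config is None:
        config = SimConfig(
            n_samples_db=201, n_genes=200, block_sizes=(100, 100), rho=0.9
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)
    X = compound_symmetric_blocks(rng, config.n_samples_db, config.block_sizes, config.rho)
    block = np.concatenate(
        [np.full(size, b) for b, size in enumerate(config.block_sizes)]
    )
    coef = np.where(block == 0, config.coef_pos, config.coef_neg).astype(float)
    y = X @ coef + config.noise_sd * rng.standard_normal(config.n_samples_db)
    return Study1Data(predictors=X, outcome=y, true_coef=coef, block=block)


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(1, n + 1)]


def simulate_de_study(config: SimConfig | None = None, seed: int | None = None) -> SimulatedStudy:
    """Database + small two-condition experiment with planted DE genes.

    The database and the experiment share the block correlation
    structure; a gene is flagged DE with probability ``de_prob`` and its
    treated samples are shifted by +-``de_effect`` (sign a fair coin).
    One master seed spawns independent child streams for the database,
    the experiment, and the DE truth, so each piece is reproducible.
    """
    if config is None:
        config = SimConfig()
    master = np.random.SeedSequence(config.seed if seed is None else seed)
    ss_db, ss_expt, ss_truth = master.spawn(3)

    genes = _gene_ids(config.n_genes)
    db_values = compound_symmetric_blocks(
        np.random.default_rng(ss_db), config.n_samples_db, config.block_sizes, config.rho
    ).T
    database = ExpressionMatrix(
        values=db_values,
        gene_ids=genes,
        sample_ids=[f"db{i:03d}" for i in range(1, config.n_samples_db + 1)],
    )

    n = config.n_samples_expt
    n_control = n // 2
    condition = np.array([0] * n_control + [1] * (n - n_control))
    expt_values = compound_symmetric_blocks(
        np.random.default_rng(ss_expt), n, config.block_sizes, config.rho
    ).T

    rng_truth = np.random.default_rng(ss_truth)
    is_de = rng_truth.random(config.n_genes) < config.de_prob
    sign = np.where(rng_truth.random(config.n_genes) < 0.5, 1.0, -1.0)
    true_delta = np.where(is_de, sign * config.de_effect, 0.0)
    expt_values = expt_values + np.outer(true_delta, condition)

    block = np.concatenate(
        [np.full(size, b) for b, size in enumerate(config.block_sizes)]
    )
    experiment = ExpressionMatrix(
        values=expt_values,
        gene_ids=list(genes),
        sample_ids=[f"s{i:03d}" for i in range(1, n + 1)],
    )
    covariates = CovariateTable(
        condition=condition, sample_ids=list(experiment.sample_ids)
    )
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "is_de": is_de,
            "true_delta": true_delta,
            "block": block,
        }
    )
    return SimulatedStudy(
        database=database,
        experiment=experiment,
        covariates=covariates,
        truth=truth,
        config=config,
    )


def evaluate_methods(
    results: Mapping[str, pd.DataFrame],
    truth: pd.DataFrame,
    cutoffs: Sequence[float] = (0.05, 0.01, 0.001),
    p_column: str = "p_delta",
) -> pd.DataFrame:
    """Power, empirical type-I error and null-uniformity per method.

    For each method's result table, rejections at every cutoff are
    counted separately among truly-DE and non-DE genes, and the
    Kolmogorov-Smirnov distance of the non-DE p-values from Uniform(0,1)
    is reported.
    """
    rows = []
    truth_idx = truth.set_index("gene_id")
    for name, table in results.items():
        if set(table["gene_id"]) != set(truth["gene_id"]):
            raise ValueError(f"gene ids of method {name!r} do not match the truth table")
        merged = table.set_index("gene_id").join(truth_idx[["is_de"]])
        p = merged[p_column].to_numpy()
        de = merged["is_de"].to_numpy(dtype=bool)
        null_p = p[~de]
        ks = stats.kstest(null_p, "uniform").statistic if null_p.size else np.nan
        row: dict[str, object] = {
            "method": name,
            "n_de": int(de.sum()),
            "n_null": int((~de).sum()),
            "ks_null": float(ks),
        }
        for cut in cutoffs:
            rej = p < cut
            row[f"power_{cut}"] = float(rej[de].mean()) if de.any() else np.nan
            row[f"type1_{cut}"] = float(rej[~de].mean()) if (~de).any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write database/experiment/covariates/truth/config as plain text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "database": outdir / "database.tsv",
        "experiment": outdir / "experiment.tsv",
        "covariates": outdir / "covariates.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.json",
    }
    write_expression(study.database, paths["database"])
    write_expression(study.experiment, paths["experiment"])
    write_covariates(study.covariates, paths["covariates"])
    study.truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["config"].write_text(study.config.to_json())
    return paths
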