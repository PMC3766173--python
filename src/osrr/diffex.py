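"""Network-adjusted differential expression testing.

For every gene g the model

    y_g = nu_g * yhat_g + delta_g * x + (pair terms) + eps

is fitted by least squares, where yhat_g is the database-trained network
predictor of g and x the 0/1 condition indicator.  The test of
H0: delta_g = 0 is differential expression *conditional on the gene
network*: shared co-expression variation is absorbed by the predictor
term, which both sharpens the delta estimate and restores approximate
independence between gene-level tests.  Adding the elementwise product
yhat_g * x tests H0: gamma_g = 0, i.e. whether the gene's regulatory
relationships themselves differ between conditions (network disruption).

Dropping the network term recovers the classical pooled-variance
two-sample t-test ("naive" model), which serves as the comparator
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exprdata import CovariateTable, ExpressionMatrix
from .network import NetworkModel, NetworkPrediction

__all__ = [
    "GeneFitResult",
    "ResidualEffect",
    "fit_de_gene",
    "fit_interaction_gene",
    "cosgrove_residual",
    "adjust_pvalues",
    "run_de_analysis",
    "summarize_counts",
]

_PAIRINGS = ("none", "fixed", "random")
_VAR_TOL = 1e-12


@dataclass
class GeneFitResult:
    """Per-gene estimates from the network-adjusted linear model."""

    gene_id: str
    nu_hat: float
    delta_hat: float
    se_delta: float
    p_delta: float
    gamma_hat: float = np.nan
    se_gamma: float = np.nan
    p_gamma: float = np.nan
    q_delta: float = np.nan
    model_tag: str = "osrr"
    degenerate: bool = False

    @property
    def direction(self) -> str:
        return "Up" if self.delta_hat > 0 else "Down"


@dataclass
class ResidualEffect:
    """Residual r = y - B y of one gene, with per-condition means phi."""

    gene_id: str
    residual: np.ndarray
    phi_hat: dict


def _ols(design: np.ndarray, y: np.ndarray, test_col: int) -> tuple[np.ndarray, float, float, float]:
    """OLS fit returning (coef, se, t-based two-sided p, sigma2) for one column."""
    n, p = design.shape
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    df = n - rank
    if df <= 0:
        return coef, np.nan, np.nan, np.nan
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.pinv(design.T @ design)
    se = float(np.sqrt(sigma2 * xtx_inv[test_col, test_col]))
    if se == 0.0 or not np.isfinite(se):
        return coef, se, np.nan, sigma2
    t = coef[test_col] / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return coef, se, float(p), sigma2


def _pair_dummies(pair_id: np.ndarray) -> np.ndarray:
    """Fixed per-pair intercept columns (first pair absorbed by the intercept)."""
    levels = list(dict.fromkeys(pair_id))
    return np.column_stack([(pair_id == lev).astype(float) for lev in levels[1:]]) \
        if len(levels) > 1 else np.empty((len(pair_id), 0))


def _mixed_fit(
    y: np.ndarray, fixed: np.ndarray, groups: np.ndarray, test_col: int
) -> tuple[np.ndarray, float, float] | None:
    """Random-intercept fit (REML); Wald t with residual degrees of freedom.

    Returns None when the pair variance component collapses to the zero
    boundary or the fit fails, in which case the caller refits plain OLS.
    """
    import warnings

    from statsmodels.regression.mixed_linear_model import MixedLM

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = MixedLM(y, fixed, groups=groups).fit(reml=True, method="lbfgs")
        var_re = float(np.asarray(res.cov_re)[0, 0])
    except (np.linalg.LinAlgError, ValueError):
        return None
    if not np.isfinite(var_re) or var_re <= 1e-8:
        return None
    coef = np.asarray(res.fe_params)
    se = float(np.asarray(res.bse_fe)[test_col])
    n_pairs = len(np.unique(groups))
    df = len(y) - fixed.shape[1] - n_pairs
    if df <= 0 or se == 0.0 or not np.isfinite(se):
        return None
    t = coef[test_col] / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return coef, se, float(p)


def _naive_result(
    gene_id: str, y: np.ndarray, cov: CovariateTable, pairing: str, degenerate: bool
) -> GeneFitResult:
    x = cov.condition.astype(float)
    design = [np.ones_like(x), x]
    if pairing == "fixed" and cov.pair_id is not None:
        design.append(_pair_dummies(cov.pair_id))
    X = np.column_stack(design)
    if pairing == "random" and cov.pair_id is not None:
        mixed = _mixed_fit(y, X, cov.pair_id, test_col=1)
        if mixed is not None:
            coef, se, p = mixed
            return GeneFitResult(gene_id, np.nan, float(coef[1]), se, p,
                                 model_tag="naive", degenerate=degenerate)
    coef, se, p, _ = _ols(X, y, test_col=1)
    return GeneFitResult(gene_id, np.nan, float(coef[1]), se, p,
                         model_tag="naive", degenerate=degenerate)


def _check_design(cov: CovariateTable, n: int, pairing: str) -> None:
    if pairing not in _PAIRINGS:
        raise ValueError(f"pairing must be one of {_PAIRINGS}")
    if cov.n_samples != n:
        raise ValueError("covariate table length does not match sample count")
    if len(np.unique(cov.condition)) < 2:
        raise ValueError("condition must contain both levels")
    if n < 4:
        raise ValueError("need at least 4 samples")
    if pairing in ("fixed", "random") and cov.pair_id is None:
        raise ValueError(f"pairing={pairing!r} requires pair_id covariates")


def fit_de_gene(
    y_g: np.ndarray,
    yhat_g: np.ndarray | None,
    cov: CovariateTable,
    pairing: str = "none",
    gene_id: str = "",
) -> GeneFitResult:
    """Test differential expression of one gene conditional on its network.

    nu_g and delta_g are estimated jointly; the p-value for delta is a
    two-sided Wald t-test.  A constant (degenerate) network predictor
    triggers a fallback to the naive model with ``degenerate=True``; with
    no predictor and no pairing, the result is exactly the classical
    pooled-variance two-sample t-test.
    """
    y = np.asarray(y_g, dtype=float)
    _check_design(cov, len(y), pairing)
    if yhat_g is None:
        return _naive_result(gene_id, y, cov, pairing, degenerate=False)
    yhat = np.asarray(yhat_g, dtype=float)
    if yhat.shape != y.shape:
        raise ValueError("y_g and yhat_g must have equal length")
    if np.var(yhat) <= _VAR_TOL:
        return _naive_result(gene_id, y, cov, pairing, degenerate=True)

    x = cov.condition.astype(float)
    cols = [np.ones_like(x), yhat, x]
    if pairing == "fixed":
        cols.append(_pair_dummies(cov.pair_id))
    X = np.column_stack(cols)
    if pairing == "random":
        mixed = _mixed_fit(y, X, cov.pair_id, test_col=2)
        if mixed is not None:
            coef, se, p = mixed
            return GeneFitResult(gene_id, float(coef[1]), float(coef[2]), se, p)
    coef, se, p, _ = _ols(X, y, test_col=2)
    return GeneFitResult(gene_id, float(coef[1]), float(coef[2]), se, p)


def fit_interaction_gene(
    y_g: np.ndarray,
    yhat_g: np.ndarray,
    cov: CovariateTable,
    pairing: str = "none",
    gene_id: str = "",
) -> GeneFitResult:
    """Test condition-dependent rewiring via the yhat x condition interaction.

    gamma_g multiplies the elementwise product of the network predictor
    and the condition indicator; H0: gamma_g = 0 means the gene's
    dependence on its network is the same in both conditions.  An
    interaction column collinear with the main effects (e.g. a predictor
    constant within one condition) yields a degenerate flag instead of a
    crash; delta is then reported from the no-interaction model.
    """
    y = np.asarray(y_g, dtype=float)
    _check_design(cov, len(y), pairing)
    yhat = np.asarray(yhat_g, dtype=float)
    if np.var(yhat) <= _VAR_TOL:
        res = _naive_result(gene_id, y, cov, pairing, degenerate=True)
        res.model_tag = "osrr-interaction"
        return res

    x = cov.condition.astype(float)
    cols = [np.ones_like(x), yhat, x, yhat * x]
    if pairing == "fixed":
        cols.append(_pair_dummies(cov.pair_id))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        base = fit_de_gene(y, yhat, cov, pairing=pairing, gene_id=gene_id)
        base.model_tag = "osrr-interaction"
        base.degenerate = True
        return base
    if pairing == "random":
        mixed = _mixed_fit(y, X, cov.pair_id, test_col=3)
        if mixed is not None:
            coef, se_g, p_g = mixed
            _, se_d, p_d = _mixed_fit(y, X, cov.pair_id, test_col=2) or (coef, np.nan, np.nan)
            return GeneFitResult(gene_id, float(coef[1]), float(coef[2]), se_d, p_d,
                                 gamma_hat=float(coef[3]), se_gamma=se_g, p_gamma=p_g,
                                 model_tag="osrr-interaction")
    coef, se_g, p_g, _ = _ols(X, y, test_col=3)
    _, se_d, p_d, _ = _ols(X, y, test_col=2)
    return GeneFitResult(gene_id, float(coef[1]), float(coef[2]), se_d, p_d,
                         gamma_hat=float(coef[3]), se_gamma=se_g, p_gamma=p_g,
                         model_tag="osrr-interaction")


def cosgrove_residual(
    expt: ExpressionMatrix,
    model: NetworkModel,
    cov: CovariateTable | None = None,
) -> list[ResidualEffect]:
    """Residual-based direct-effect estimate r = y - B y per gene.

    This is the comparator approach in which the network fit is
    subtracted and the residual mean (overall, or per condition when
    covariates are given) estimates the direct perturbation effect phi.
    """
    if not expt.centered:
        raise ValueError("experiment must be centered")
    if list(expt.gene_ids) != list(model.gene_ids):
        raise ValueError("experiment and network gene ids must match in order")
    R = expt.values - model.coefficients @ expt.values
    out = []
    for g, gene in enumerate(expt.gene_ids):
        r = R[g]
        if cov is not None:
            phi = {int(c): float(r[cov.condition == c].mean()) for c in np.unique(cov.condition)}
        else:
            phi = {"all": float(r.mean())}
        out.append(ResidualEffect(gene_id=gene, residual=r, phi_hat=phi))
    return out


def adjust_pvalues(p: Sequence[float], method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: Benjamini-Hochberg step-up (default)
    or Storey's q-value with the pi0 estimate fixed at lambda = 0.5."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    q_bh = multipletests(p, method="fdr_bh")[1]
    if method == "bh":
        return q_bh
    if method == "storey":
        pi0 = min(1.0, float(np.mean(p > 0.5)) / 0.5)
        return np.minimum(pi0 * q_bh, 1.0)
    raise ValueError(f"unknown adjustment method {method!r}")


def run_de_analysis(
    expt: ExpressionMatrix,
    prediction: NetworkPrediction | None,
    cov: CovariateTable,
    pairing: str = "none",
    with_interaction: bool = False,
    adjust: str = "bh",
) -> pd.DataFrame:
    """Gene-by-gene network-adjusted DE analysis over a whole experiment.

    Returns one row per gene, in the experiment's gene order, with
    BH-adjusted q-values and an Up/Down direction column.
    """
    if prediction is not None and list(prediction.gene_ids) != list(expt.gene_ids):
        raise ValueError("prediction gene ids must match the experiment")
    rows = []
    for g, gene in enumerate(expt.gene_ids):
        yhat = prediction.values[g] if prediction is not None else None
        if with_interaction and yhat is not None:
            res = fit_interaction_gene(expt.values[g], yhat, cov, pairing, gene_id=gene)
        else:
            res = fit_de_gene(expt.values[g], yhat, cov, pairing, gene_id=gene)
        rows.append(res)
    table = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "nu_hat": [r.nu_hat for r in rows],
            "delta_hat": [r.delta_hat for r in rows],
            "se_delta": [r.se_delta for r in rows],
            "p_delta": [r.p_delta for r in rows],
            "direction": [r.direction for r in rows],
            "model_tag": [r.model_tag for r in rows],
            "degenerate": [r.degenerate for r in rows],
        }
    )
    table["q_delta"] = adjust_pvalues(table["p_delta"].to_numpy(), method=adjust)
    if with_interaction:
        table["gamma_hat"] = [r.gamma_hat for r in rows]
        table["se_gamma"] = [r.se_gamma for r in rows]
        table["p_gamma"] = [r.p_gamma for r in rows]
        valid = table["p_gamma"].notna()
        q_gamma = np.full(len(table), np.nan)
        if valid.any():
            q_gamma[valid.to_numpy()] = adjust_pvalues(
                table.loc[valid, "p_gamma"].to_numpy(), method=adjust
            )
        table["q_gamma"] = q_gamma
    return table


def summarize_counts(
    table: pd.DataFrame, cutoffs: Iterable[float] = (0.05, 0.01, 0.001, 0.0001)
) -> dict:
    """Counts of significant genes by direction at fixed p-value cutoffs."""
    out: dict[str, dict[str, int]] = {"Up": {}, "Down": {}}
    for cut in cutoffs:
        sig = table[table["p_delta"] < cut]
        out["Up"][str(cut)] = int((sig["direction"] == "Up").sum())
        out["Down"][str(cut)] = int((sig["direction"] == "Down").sum())
    return out
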