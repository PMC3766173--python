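"""Calibration of p-value distributions: beta-uniform mixtures and
permutation nulls.

A well-calibrated genome-wide test produces a p-value histogram that is
uniform for null genes plus a spike near zero for signal.  The
two-parameter beta-uniform mixture (BUM)

    f(p) = pi + (1 - pi) * a * p^(a-1),      0 < a < 1, 0 <= pi <= 1

captures this shape with pi the uniform (null) weight and a the beta
spike sharpness; the ratio pi / f(p) is an empirical-Bayes estimate of
the false-positive rate at p.  Permutation of the condition labels
(within case-control pairs for paired designs) gives a model-free null
histogram to compare against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from .diffex import run_de_analysis
from .exprdata import CovariateTable, ExpressionMatrix
from .network import NetworkPrediction

__all__ = [
    "BumFit",
    "BumMixture",
    "PermutationNull",
    "fit_bum",
    "fpr_at",
    "permutation_null",
]

_P_FLOOR = 1e-12
_MIN_POINTS = 50


@dataclass
class BumFit:
    """Fitted beta-uniform mixture of a p-value histogram."""

    mix_uniform: float
    shape_a: float
    loglik: float
    converged: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.mix_uniform <= 1.0:
            raise ValueError("mix_uniform must lie in [0, 1]")
        if not 0.0 < self.shape_a < 1.0:
            raise ValueError("shape_a must lie in (0, 1)")

    def density(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return self.mix_uniform + (1.0 - self.mix_uniform) * self.shape_a * p ** (
            self.shape_a - 1.0
        )

    def fpr_at(self, p: float) -> float:
        return fpr_at(self, p)


def _nll(params: np.ndarray, logp: np.ndarray) -> float:
    logit_pi, logit_a = params
    pi = 1.0 / (1.0 + np.exp(-logit_pi))
    a = 1.0 / (1.0 + np.exp(-logit_a))
    dens = pi + (1.0 - pi) * a * np.exp((a - 1.0) * logp)
    return -float(np.sum(np.log(np.maximum(dens, 1e-300))))


def fit_bum(p: np.ndarray, n_restarts: int = 5) -> BumFit:
    """Maximum-likelihood BUM fit by bounded quasi-Newton optimisation.

    Parameters are optimised on the logit scale from a small grid of
    deterministic starting points; the pure-uniform boundary (pi = 1) is
    always included as a candidate so the fitted log-likelihood can
    never fall below the uniform model's.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) < _MIN_POINTS:
        raise ValueError(f"need at least {_MIN_POINTS} p-values to fit a mixture")
    if np.any(p == 0.0):
        warnings.warn(
            "p-values of exactly 0 clamped (BUM density is unbounded at 0)",
            stacklevel=2,
        )
        p = np.maximum(p, _P_FLOOR)
    logp = np.log(p)

    starts = list(product([-1.5, 0.0, 1.5], [-2.0, -0.5]))[: max(n_restarts, 1)]
    best, best_nll = None, np.inf
    converged = False
    for x0 in starts:
        res = optimize.minimize(
            _nll, np.asarray(x0), args=(logp,), method="L-BFGS-B",
            bounds=[(-14.0, 14.0), (-14.0, 14.0)],
        )
        if res.fun < best_nll:
            best, best_nll, converged = res.x, res.fun, bool(res.success)
    pi = float(1.0 / (1.0 + np.exp(-best[0])))
    a = float(1.0 / (1.0 + np.exp(-best[1])))
    loglik = -best_nll
    if loglik < 0.0:  # pure uniform (loglik exactly 0) fits better
        return BumFit(mix_uniform=1.0, shape_a=0.5, loglik=0.0, converged=True)
    # snap a numerically saturated logit to the boundary value 1
    if pi > 1.0 - 1e-6:
        pi = 1.0
    return BumFit(mix_uniform=pi, shape_a=a, loglik=loglik, converged=converged)


def fpr_at(fit: BumFit, p: float) -> float:
    """Empirical-Bayes false-positive rate pi / f(p), clipped to [0, 1]."""
    if not 0.0 < p <= 1.0:
        raise ValueError("p must lie in (0, 1]")
    dens = float(fit.density(p))
    if dens == 0.0:
        return 1.0 if fit.mix_uniform == 0.0 else 1.0
    return float(np.clip(fit.mix_uniform / dens, 0.0, 1.0))


class BumMixture(BaseEstimator):
    """scikit-learn style wrapper around :func:`fit_bum`.

    Attributes
    ----------
    mix_uniform_ : float
        Weight of the uniform (null) component.
    shape_a_ : float
        Beta shape parameter of the signal spike, in (0, 1).
    loglik_ : float
        Log-likelihood at the optimum.
    """

    def __init__(self, n_restarts: int = 5):
        self.n_restarts = n_restarts

    def fit(self, X, y=None):
        fit = fit_bum(np.asarray(X, dtype=float).ravel(), n_restarts=self.n_restarts)
        self.mix_uniform_ = fit.mix_uniform
        self.shape_a_ = fit.shape_a
        self.loglik_ = fit.loglik
        self.converged_ = fit.converged
        self.fit_ = fit
        return self

    def predict(self, X):
        """Empirical-Bayes false-positive rate at each p."""
        return np.asarray([fpr_at(self.fit_, float(p)) for p in np.ravel(X)])


@dataclass
class PermutationNull:
    """Null p-values from label permutations, in long format
    (columns: perm, gene_id, p)."""

    n_perm: int
    pvalues: pd.DataFrame
    seed: int
    method: str

    def pooled(self) -> np.ndarray:
        return self.pvalues["p"].to_numpy()

    def histogram(self, bin_width: float = 0.05) -> dict:
        edges = np.round(np.arange(0.0, 1.0 + bin_width / 2, bin_width), 10)
        counts, _ = np.histogram(self.pooled(), bins=edges)
        return {"bin_edges": edges.tolist(), "counts": counts.tolist()}


def _paired_relabelings(
    cov: CovariateTable, n_perm: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Within-pair label swaps: each pair's case/control labels flip or not.

    There are 2^k possible relabelings for k pairs; all are enumerated
    when n_perm covers them, otherwise distinct swap patterns are
    sampled without replacement.
    """
    pairs = list(dict.fromkeys(cov.pair_id))
    k = len(pairs)
    if k == 0:
        raise ValueError("no pairs available to permute")
    total = 2 ** k if k < 63 else np.inf
    if n_perm >= total:
        codes = np.arange(int(total))
    else:
        codes = rng.choice(int(total), size=n_perm, replace=False) if total <= 2**24 \
            else np.unique(rng.integers(0, int(total), size=2 * n_perm))[:n_perm]
    labels = []
    for code in codes:
        cond = cov.condition.copy()
        for j, pair in enumerate(pairs):
            if (int(code) >> j) & 1:
                mask = cov.pair_id == pair
                cond[mask] = 1 - cond[mask]
        labels.append(cond)
    return labels


def permutation_null(
    expt: ExpressionMatrix,
    prediction: NetworkPrediction | None,
    cov: CovariateTable,
    method: str = "osrr",
    n_perm: int = 100,
    seed: int = 0,
    pairing: str = "none",
    relabelings: list[np.ndarray] | None = None,
) -> PermutationNull:
    """Recompute the full per-gene DE test under permuted condition labels.

    Labels are permuted freely for unpaired designs and swapped within
    each case-control pair when pair_id covariates are present (the only
    exchangeable relabeling for a paired design).  ``relabelings``
    bypasses the sampler with an explicit list of label vectors.
    """
    if method not in ("osrr", "naive"):
        raise ValueError("method must be 'osrr' or 'naive'")
    if n_perm < 1 and relabelings is None:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    if relabelings is None:
        if cov.pair_id is not None:
            relabelings = _paired_relabelings(cov, n_perm, rng)
        else:
            relabelings = [rng.permutation(cov.condition) for _ in range(n_perm)]
    frames = []
    use_pred = prediction if method == "osrr" else None
    for i, labels in enumerate(relabelings):
        labels = np.asarray(labels)
        if len(np.unique(labels)) < 2:
            continue
        perm_cov = CovariateTable(
            condition=labels,
            pair_id=cov.pair_id,
            time_radians=cov.time_radians,
            sample_ids=cov.sample_ids,
        )
        table = run_de_analysis(expt, use_pred, perm_cov, pairing=pairing)
        frames.append(
            pd.DataFrame({"perm": i, "gene_id": table["gene_id"], "p": table["p_delta"]})
        )
    if not frames:
        raise ValueError("no valid permutations (all relabelings single-level)")
    return PermutationNull(
        n_perm=len(frames),
        pvalues=pd.concat(frames, ignore_index=True),
        seed=seed,
        method=method,
    )
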