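"""Model comparison and spatial-autocorrelation diagnostics.

Implements the Poisson deviance, DIC with its effective-parameter count
pD, mean squared prediction error over all area-month cells, Pearson
residuals, calibration pairs, and Moran's I under binary,
row-standardized and globally standardized spatial weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .core_data import AdjacencyGraph, weight_matrix


@dataclass
class EvalReport:
    """DIC decomposition plus prediction error for one fitted model."""

    mspe: float
    dbar: float
    d_at_mean: float
    pD: float
    dic: float
    n_cells: int

    def __post_init__(self) -> None:
        if abs(self.pD - (self.dbar - self.d_at_mean)) > 1e-9:
            raise ValueError("pD must equal dbar - d_at_mean")
        if abs(self.dic - (self.dbar + self.pD)) > 1e-9:
            raise ValueError("dic must equal dbar + pD")

    def to_dict(self) -> dict:
        return {"mspe": self.mspe, "dbar": self.dbar,
                "d_at_mean": self.d_at_mean, "pD": self.pD,
                "dic": self.dic, "n_cells": self.n_cells}


@dataclass
class MoranResult:
    statistic: float
    expectation: float
    p_value_permutation: float
    p_value_normal: float
    scheme: str


def poisson_deviance(y: np.ndarray, theta: np.ndarray,
                     N: np.ndarray) -> float:
    """D = -2 log f(y | theta) for y_it ~ Poisson(theta_it N_it),
    including the log(y!) constant."""
    y = np.asarray(y, dtype=float)
    theta = np.asarray(theta, dtype=float)
    N = np.asarray(N, dtype=float)
    mu = theta * N
    if np.any(mu <= 0):
        raise ValueError("nonpositive Poisson mean (theta must be > 0)")
    ll = y * np.log(mu) - mu - special.gammaln(y + 1)
    return float(-2.0 * ll.sum())


def dic_from_samples(deviance_samples: np.ndarray,
                     deviance_at_posterior_mean: float) -> dict:
    """DIC = Dbar + pD with pD = Dbar - D(posterior mean)."""
    d = np.asarray(deviance_samples, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("empty deviance sample")
    dbar = float(d.mean())
    pD = dbar - float(deviance_at_posterior_mean)
    return {"dbar": dbar, "d_at_mean": float(deviance_at_posterior_mean),
            "pD": pD, "dic": dbar + pD}


def mspe(y_observed: np.ndarray, y_predicted: np.ndarray) -> float:
    """Mean squared prediction error over all cells."""
    y = np.asarray(y_observed, dtype=float)
    yhat = np.asarray(y_predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    return float(np.mean((y - yhat) ** 2))


def pearson_residuals(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """(y - mu) / sqrt(mu) under the Poisson variance function."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("nonpositive mean in Pearson residuals")
    return (y - mu) / np.sqrt(mu)


def evaluate_fit(y: np.ndarray, N: np.ndarray, theta_hat: np.ndarray,
                 deviance_samples: np.ndarray) -> EvalReport:
    """Assemble the comparison report for one fit: in-sample MSPE of the
    posterior-mean predicted counts plus the DIC decomposition (plug-in
    deviance at the posterior-mean relative-risk surface)."""
    d_at_mean = poisson_deviance(y, theta_hat, N)
    frag = dic_from_samples(deviance_samples, d_at_mean)
    return EvalReport(mspe=mspe(y, theta_hat * np.asarray(N, dtype=float)),
                      dbar=frag["dbar"], d_at_mean=frag["d_at_mean"],
                      pD=frag["pD"], dic=frag["dic"],
                      n_cells=int(np.size(y)))


def _moran_stat(x: np.ndarray, W: np.ndarray) -> float:
    z = x - x.mean()
    return float(x.size / W.sum() * (z @ W @ z) / (z @ z))


def morans_i(x: np.ndarray, graph: AdjacencyGraph, scheme: str = "row_standardized",
             n_permutations: int = 999,
             seed: int | np.random.Generator = 0) -> MoranResult:
    """Moran's I with permutation and normal-approximation p-values.

    I = n/S0 * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2.
    The permutation p-value is one-sided (clustering: I >= observed)
    over random relabelings of the areas; the normal p-value uses the
    randomization-moments approximation with the same direction.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if np.all(x == x[0]):
        raise ValueError("Moran's I undefined for a constant vector")
    W = weight_matrix(graph, scheme)
    if W.shape[0] != n:
        raise ValueError("x length does not match the graph")
    obs = _moran_stat(x, W)
    expectation = -1.0 / (n - 1)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        if _moran_stat(x[rng.permutation(n)], W) >= obs:
            count += 1
    p_perm = (1 + count) / (1 + n_permutations)

    # randomization moments (Cliff-Ord)
    S0 = W.sum()
    Wsym = W + W.T
    S1 = 0.5 * np.sum(Wsym ** 2)
    S2 = np.sum((W.sum(axis=0) + W.sum(axis=1)) ** 2)
    z = x - x.mean()
    m2 = np.sum(z ** 2) / n
    m4 = np.sum(z ** 4) / n
    b2 = m4 / m2 ** 2
    num = (n * ((n**2 - 3*n + 3) * S1 - n * S2 + 3 * S0**2)
           - b2 * ((n**2 - n) * S1 - 2*n*S2 + 6 * S0**2))
    den = (n - 1) * (n - 2) * (n - 3) * S0**2
    var = num / den - expectation**2
    zscore = (obs - expectation) / np.sqrt(var)
    p_norm = float(stats.norm.sf(zscore))
    return MoranResult(statistic=obs, expectation=expectation,
                       p_value_permutation=float(p_perm),
                       p_value_normal=p_norm, scheme=scheme)


def calibration_pairs(y_observed: np.ndarray,
                      y_estimated: np.ndarray) -> tuple[pd.DataFrame, float]:
    """Long table of (observed, estimated) count pairs plus the slope of
    the least-squares line through the origin (1 = perfect calibration)."""
    y = np.asarray(y_observed, dtype=float).ravel()
    yhat = np.asarray(y_estimated, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError("observed and estimated sizes differ")
    table = pd.DataFrame({"observed": y, "estimated": yhat})
    slope = float(np.sum(y * yhat) / np.sum(yhat ** 2))
    return table, slope
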