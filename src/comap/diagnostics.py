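"""MCMC convergence assessment and model comparison.

Geweke z-scores compare the mean of an early chain segment with a late one
using spectral-density-at-zero standard errors; effective sample size uses
the initial-positive-sequence truncation of the autocorrelation sum; DIC is
mean deviance plus the effective number of parameters
``pD = Dbar - D(posterior mean of mu)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .mcar import ChainOutput

__all__ = [
    "geweke_z",
    "effective_sample_size",
    "autocorrelations",
    "dic",
    "DiagnosticsReport",
    "diagnostics_report",
]


def _autocov(x: np.ndarray, max_lag: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    acov = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        acov[k] = np.dot(xc[: n - k], xc[k:]) / n
    return acov


def _spectral_var(x: np.ndarray, window_frac: float = 0.04) -> float:
    """Variance of the sample mean via a lag-window estimate of the spectral
    density at zero: (gamma_0 + 2 sum_{k<=L} gamma_k) / n with L = 4% of n."""
    n = len(x)
    L = max(1, int(window_frac * n))
    acov = _autocov(x, min(L, n - 1))
    s = acov[0] + 2.0 * acov[1:].sum()
    return max(s, 0.0) / n


def geweke_z(draws: np.ndarray, first_frac: float = 0.1, last_frac: float = 0.5,
             window_frac: float = 0.04) -> float:
    """Geweke convergence z-score for one scalar chain.

    Compares the mean of the first ``first_frac`` of the chain against the
    last ``last_frac``; under convergence z is approximately standard normal.
    Returns NaN for zero-variance chains.
    """
    x = np.asarray(draws, dtype=float)
    n = len(x)
    if n < 100:
        raise ValueError("chain too short for Geweke diagnostic (need >= 100)")
    a = x[: int(first_frac * n)]
    b = x[-int(last_frac * n):]
    va = _spectral_var(a, window_frac)
    vb = _spectral_var(b, window_frac)
    if va + vb == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(va + vb))


def autocorrelations(draws: np.ndarray, max_lag: int = 50) -> np.ndarray:
    """Lag-1..max_lag autocorrelations of a scalar chain."""
    x = np.asarray(draws, dtype=float)
    acov = _autocov(x, min(max_lag, len(x) - 1))
    if acov[0] == 0:
        return np.zeros(len(acov) - 1)
    return acov[1:] / acov[0]


def effective_sample_size(draws: np.ndarray) -> float:
    """ESS = N / (1 + 2 sum_k rho_k) with initial-positive-sequence truncation.

    The autocorrelation sum is truncated at the first lag pair whose summed
    autocorrelation turns nonpositive (Geyer's initial positive sequence).
    Degenerate (constant) chains report N.
    """
    x = np.asarray(draws, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("chain too short for ESS (need >= 10)")
    acov = _autocov(x, n - 1)
    if acov[0] == 0:
        return float(n)
    rho = acov / acov[0]
    s = 0.0
    k = 1
    while k + 1 < n:
        pair = rho[k] + rho[k + 1]
        if pair <= 0:
            break
        s += pair
        k += 2
    return float(n / (1.0 + 2.0 * s))


def dic(chain: ChainOutput, Y: np.ndarray, E: Optional[np.ndarray] = None) -> tuple:
    """Deviance information criterion from the stored per-draw fitted means.

    D(mu) = -2 sum_ij log Poisson(Y_ij | mu_ij); Dbar is the mean over draws;
    pD = Dbar - D(mean over draws of mu); DIC = Dbar + pD.  Cells with
    mu = 0 and Y = 0 are outside the model and skipped.
    """
    if chain.n_draws == 0:
        raise ValueError("empty chain")
    Y = np.asarray(Y, dtype=float)
    mu = chain.mu
    valid = ~np.all(mu == 0, axis=0)

    def deviance(m):
        mm = m[valid]
        yy = Y[valid]
        return float(-2.0 * np.sum(yy * np.log(mm) - mm - gammaln(yy + 1)))

    dbar = float(np.mean([deviance(mu[s]) for s in range(chain.n_draws)]))
    d_at_mean = deviance(mu.mean(axis=0))
    pd_ = dbar - d_at_mean
    return dbar + pd_, dbar, pd_


@dataclass
class DiagnosticsReport:
    """Per-parameter convergence diagnostics and per-model DIC components."""

    geweke: Dict[str, float] = field(default_factory=dict)
    ess: Dict[str, float] = field(default_factory=dict)
    autocorr: Dict[str, np.ndarray] = field(default_factory=dict)
    dic: Optional[float] = None
    mean_deviance: Optional[float] = None
    p_d: Optional[float] = None
    flags: Dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        params = sorted(self.geweke)
        return pd.DataFrame(
            {
                "parameter": params,
                "geweke_z": [self.geweke[p] for p in params],
                "ess": [self.ess[p] for p in params],
                "flag": [self.flags.get(p, "") for p in params],
            }
        )

    def to_json(self, path) -> None:
        payload = {
            "geweke": self.geweke,
            "ess": self.ess,
            "dic": self.dic,
            "mean_deviance": self.mean_deviance,
            "p_d": self.p_d,
            "flags": self.flags,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def _scalar_params(chain: ChainOutput) -> Dict[str, np.ndarray]:
    J = chain.beta.shape[1]
    out = {}
    for j in range(J):
        out[f"beta[{j}]"] = chain.beta[:, j]
        out[f"sigma_sd[{j}]"] = chain.sigma_sd[:, j]
    for p in range(chain.sigma_corr.shape[1]):
        out[f"sigma_corr[{p}]"] = chain.sigma_corr[:, p]
    if chain.rho.ndim == 1:
        out["rho"] = chain.rho
    else:
        for j in range(chain.rho.shape[1]):
            out[f"rho[{j}]"] = chain.rho[:, j]
    return out


def diagnostics_report(chain: ChainOutput, Y=None, max_lag: int = 50) -> DiagnosticsReport:
    """Geweke, ESS and autocorrelations for every scalar hyperparameter of a
    chain (per chain, pooled for DIC)."""
    rep = DiagnosticsReport()
    chain_ids = np.unique(chain.chain_id)
    for name, x in _scalar_params(chain).items():
        zs, esss = [], []
        for c in chain_ids:
            xc = x[chain.chain_id == c]
            if len(xc) >= 100:
                z = geweke_z(xc)
            else:
                z = float("nan")
                rep.flags[name] = "chain too short for Geweke"
            if np.isnan(z) and np.var(xc) == 0:
                rep.flags[name] = "zero-variance chain"
            zs.append(z)
            esss.append(effective_sample_size(xc) if len(xc) >= 10 else float("nan"))
        rep.geweke[name] = float(np.nanmax(np.abs(zs))) if not all(np.isnan(zs)) else float("nan")
        rep.ess[name] = float(np.nansum(esss))
        rep.autocorr[name] = autocorrelations(x, max_lag)
    if Y is not None:
        rep.dic, rep.mean_deviance, rep.p_d = dic(chain, Y)
    return rep
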