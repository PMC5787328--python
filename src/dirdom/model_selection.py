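"""Model comparison by DIC and the log conditional predictive ordinate.

Both criteria work from a draws x records matrix of per-observation
Gaussian log-likelihoods, conditional on all location effects and the
residual variance (the deviance focus appropriate when the compared
models differ only in their SNP-effect priors).  The conditional
predictive ordinate per record is the harmonic mean of its likelihood
over draws, evaluated in log space; higher LogCPO and lower DIC indicate
better fit.
"""

from __future__ import annotations

import warnings
from math import log, pi

import numpy as np
from scipy.special import logsumexp

__all__ = ["pointwise_loglik", "plugin_loglik", "dic", "log_cpo", "compare_table"]

LOG_2PI = log(2.0 * pi)


def pointwise_loglik(fitted: np.ndarray, sigma_e2: np.ndarray, y: np.ndarray) -> np.ndarray:
    """(s, i) entry: log N(y_i ; fitted_i^(s), sigma_e2^(s))."""
    fitted = np.asarray(fitted, dtype=float)
    sigma_e2 = np.asarray(sigma_e2, dtype=float)
    y = np.asarray(y, dtype=float)
    if fitted.shape != (sigma_e2.size, y.size):
        raise ValueError("fitted must be (draws, records)")
    if np.any(sigma_e2 <= 0):
        s = int(np.argmax(sigma_e2 <= 0))
        raise ValueError(f"non-positive residual variance in draw {s}: corrupt chain")
    resid2 = (y[None, :] - fitted) ** 2
    s2 = sigma_e2[:, None]
    out = -0.5 * (LOG_2PI + np.log(s2)) - 0.5 * resid2 / s2
    if not np.isfinite(out).all():
        raise ValueError("non-finite log-likelihood entry")
    return out


def loglik_matrix(draws, y=None) -> np.ndarray:
    """Log-likelihood matrix straight from a PosteriorDraws object."""
    return pointwise_loglik(
        draws.fitted, draws.scalars["sig_e2"].to_numpy(), draws.y if y is None else y
    )


def plugin_loglik(fitted_mean: np.ndarray, sigma_e2_mean: float, y: np.ndarray) -> float:
    """Total log-likelihood at posterior-mean fitted values and residual variance."""
    L = pointwise_loglik(
        np.asarray(fitted_mean, dtype=float)[None, :],
        np.asarray([sigma_e2_mean], dtype=float),
        y,
    )
    return float(L.sum())


def dic(L: np.ndarray, loglik_at_posterior_mean: float) -> tuple[float, float, float]:
    """(DIC, pD, Dbar): Dbar = E[-2 loglik], pD = Dbar - D(at posterior mean)."""
    deviances = -2.0 * L.sum(axis=1)
    dbar = float(deviances.mean())
    p_d = dbar - (-2.0 * loglik_at_posterior_mean)
    if p_d < 0:
        warnings.warn(
            f"negative effective parameter count pD={p_d:.3f} "
            "(posterior may be far from Gaussian)",
            stacklevel=2,
        )
    return dbar + p_d, p_d, dbar


def log_cpo(L: np.ndarray) -> tuple[float, np.ndarray]:
    """(total LogCPO, per-record log CPO_i).

    log CPO_i = log S - logsumexp_s(-loglik(s, i)); the harmonic-mean
    estimator evaluated with the log-sum-exp trick so no draw can
    overflow.
    """
    L = np.asarray(L, dtype=float)
    s = L.shape[0]
    log_cpo_i = np.log(s) - logsumexp(-L, axis=0)
    if not np.isfinite(log_cpo_i).all():
        i = int(np.argmax(~np.isfinite(log_cpo_i)))
        raise ValueError(f"non-finite CPO for record {i}")
    return float(log_cpo_i.sum()), log_cpo_i


def criteria_for_draws(draws) -> dict:
    """DIC, pD, Dbar and LogCPO for one fitted model's pooled draws."""
    L = loglik_matrix(draws)
    at_mean = plugin_loglik(
        draws.fitted.mean(axis=0), float(draws.scalars["sig_e2"].mean()), draws.y
    )
    d, p_d, dbar = dic(L, at_mean)
    lcpo, _ = log_cpo(L)
    return {"DIC": d, "pD": p_d, "Dbar": dbar, "LogCPO": lcpo}


def compare_table(named_draws: dict) -> "pd.DataFrame":  # noqa: F821
    """Comparison report over fitted models, best LogCPO first."""
    import pandas as pd

    hashes = {d.dataset_hash for d in named_draws.values()}
    if len(hashes) > 1:
        raise ValueError("refusing to compare models fitted to different datasets")
    rows = []
    for name, draws in named_draws.items():
        crit = criteria_for_draws(draws)
        crit["model"] = name
        rows.append(crit)
    df = pd.DataFrame(rows)[["model", "LogCPO", "DIC", "pD", "Dbar"]]
    return df.sort_values("LogCPO", ascending=False).reset_index(drop=True)
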