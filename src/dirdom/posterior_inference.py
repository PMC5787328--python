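"""Posterior summaries and MCMC quality control.

Native implementations of the summaries the analysis reports: posterior
mean/SD, shortest (highest-posterior-density) intervals, sign
probabilities, effective sample size by the initial-positive-sequence
autocorrelation rule, and the Geweke window-mean drift diagnostic with
spectral variance estimates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "hpd_interval",
    "sign_probability",
    "effective_sample_size",
    "geweke_z",
    "summarize",
]


def hpd_interval(samples, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ceil(prob * n) sorted samples.

    Ties in width break to the first (lowest) window.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 100:
        raise ValueError(f"need >= 100 samples for an HPD interval, got {n}")
    k = int(np.ceil(prob * n))
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def sign_probability(samples, direction: str = "pos") -> float:
    """Fraction of draws strictly positive (``pos``) or negative (``neg``)."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    if direction == "pos":
        return float(np.mean(x > 0))
    if direction == "neg":
        return float(np.mean(x < 0))
    raise ValueError(f"direction must be 'pos' or 'neg', got {direction!r}")


def _autocorr(x: np.ndarray) -> np.ndarray:
    n = x.size
    x = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real / n
    return acov / acov[0]


def effective_sample_size(samples) -> float:
    """ESS = n / (1 + 2 sum rho_k), initial-positive-sequence truncation.

    Lag autocorrelations are summed in adjacent pairs until a pair sum
    turns non-positive (Geyer's rule); the result is capped at n, and a
    constant chain yields 0 with a warning.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 100:
        raise ValueError(f"need >= 100 samples for an ESS estimate, got {n}")
    if np.ptp(x) == 0:
        warnings.warn("constant chain: ESS undefined, returning 0", stacklevel=2)
        return 0.0
    rho = _autocorr(x)
    tau = 1.0
    k = 1
    while k + 1 < n:
        pair = rho[k] + rho[k + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
        k += 2
    return float(min(n, n / tau))


def _spectral_var_of_mean(x: np.ndarray) -> float:
    """Var of the window mean via the same truncated-autocovariance S(0) estimate."""
    n = x.size
    if np.ptp(x) == 0:
        return 0.0
    rho = _autocorr(x)
    tau = 1.0
    k = 1
    while k + 1 < n:
        pair = rho[k] + rho[k + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
        k += 2
    return float(np.var(x) * tau / n)


def geweke_z(samples, first: float = 0.1, last: float = 0.5) -> float:
    """Z-score comparing the means of the early and late chain windows."""
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 1000:
        raise ValueError(f"need >= 1000 samples for the Geweke diagnostic, got {n}")
    a = x[: int(first * n)]
    b = x[n - int(last * n) :]
    va = _spectral_var_of_mean(a)
    vb = _spectral_var_of_mean(b)
    denom = np.sqrt(va + vb)
    if denom == 0:
        raise ValueError("zero spectral variance (constant chain)")
    return float((a.mean() - b.mean()) / denom)


def summarize(
    draws: pd.DataFrame,
    params: list[str] | None = None,
    prob: float = 0.95,
) -> pd.DataFrame:
    """One summary row per parameter over pooled draws.

    Columns: mean, sd, hpd_low, hpd_high, p_pos, ess, geweke_z (the
    diagnostics are NaN when the chain is too short or degenerate).
    """
    if params is None:
        params = [c for c in draws.columns if c not in ("chain", "iteration")]
    rows = []
    for name in params:
        x = draws[name].to_numpy(dtype=float)
        row = {"parameter": name, "mean": x.mean(), "sd": x.std(ddof=1) if x.size > 1 else 0.0}
        try:
            row["hpd_low"], row["hpd_high"] = hpd_interval(x, prob)
        except ValueError:
            row["hpd_low"] = row["hpd_high"] = np.nan
        row["p_pos"] = sign_probability(x, "pos")
        try:
            row["ess"] = effective_sample_size(x)
        except ValueError:
            row["ess"] = np.nan
        try:
            row["geweke_z"] = geweke_z(x)
        except ValueError:
            row["geweke_z"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
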