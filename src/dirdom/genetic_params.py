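"""Quantitative-genetic quantities derived from SNP effects.

Given per-SNP additive effects a, dominance effects d and counted-allele
frequencies p, the classical (statistical, allele-frequency-weighted)
decomposition gives substitution effects alpha = a + (q - p) d, additive
variance V_A = sum 2 p q alpha^2, dominance variance
V_D = sum (2 p q d)^2, and per-individual breeding values and dominance
deviations.  Inbreeding depression I_D is the expected phenotype change
for a 1-point (0.01) rise in inbreeding, combining the homozygosity
covariate b with the directional part of the dominance effects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "substitution_effects",
    "genetic_variances",
    "variance_ratios",
    "inbreeding_depression",
    "genomic_values",
    "derive_ratio_draws",
]


def _check_lengths(a, d, p):
    a, d, p = (np.asarray(x, dtype=float) for x in (a, d, p))
    if not (a.shape == d.shape == p.shape):
        raise ValueError("a, d and p must have equal lengths")
    return a, d, p


def substitution_effects(a, d, p) -> np.ndarray:
    """alpha_j = a_j + (q_j - p_j) d_j."""
    a, d, p = _check_lengths(a, d, p)
    return a + (1.0 - 2.0 * p) * d


def genetic_variances(a, d, p) -> tuple[float, float]:
    """(V_A, V_D) = (sum 2pq alpha^2, sum (2pq d)^2) under linkage equilibrium."""
    a, d, p = _check_lengths(a, d, p)
    two_pq = 2.0 * p * (1.0 - p)
    alpha = a + (1.0 - 2.0 * p) * d
    return float(np.sum(two_pq * alpha**2)), float(np.sum((two_pq * d) ** 2))


def variance_ratios(v_a, v_d, sigma_c2, sigma_r2, sigma_e2):
    """Heritability h2 and dominance ratio d2 on the full phenotypic variance.

    V_P = V_A + V_D + sigma_c2 + sigma_r2 + sigma_e2 (permanent
    environment and contemporary group both count as phenotypic
    variance).  All arguments may be arrays of per-draw values.
    """
    v_p = (
        np.asarray(v_a, dtype=float)
        + np.asarray(v_d, dtype=float)
        + np.asarray(sigma_c2, dtype=float)
        + np.asarray(sigma_r2, dtype=float)
        + np.asarray(sigma_e2, dtype=float)
    )
    if np.any(v_p <= 0):
        raise ValueError("phenotypic variance must be positive")
    return np.asarray(v_a) / v_p, np.asarray(v_d) / v_p


def inbreeding_depression(b: float, d, p, m: int | None = None) -> float:
    """Expected phenotype change per 1% rise in inbreeding.

    I_D = 0.01 [ b (1/m) sum 2pq - sum 2pq d ]: raising inbreeding by
    F = 0.01 raises expected homozygosity by F times the mean
    heterozygosity (the covariate term) and shrinks each SNP's
    heterozygote frequency by the factor 1 - F (the dominance term).
    """
    d = np.asarray(d, dtype=float)
    p = np.asarray(p, dtype=float)
    if d.shape != p.shape:
        raise ValueError("d and p must have equal lengths")
    if m is None:
        m = d.size
    two_pq = 2.0 * p * (1.0 - p)
    return float(0.01 * (b * two_pq.sum() / m - np.sum(two_pq * d)))


def genomic_values(Zc, Kc_dev, alpha, d) -> tuple[np.ndarray, np.ndarray]:
    """Per-animal breeding values s_a = Zc alpha and dominance deviations s_d.

    ``Zc`` is the frequency-centered additive coding and ``Kc_dev`` the
    classical dominance-deviation coding (2 -> -2q^2, 1 -> 2pq,
    0 -> -2p^2); both population means are zero in expectation.
    """
    Zc = np.asarray(Zc, dtype=float)
    Kc_dev = np.asarray(Kc_dev, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    d = np.asarray(d, dtype=float)
    if Zc.shape[1] != alpha.size or Kc_dev.shape[1] != d.size:
        raise ValueError("design and effect dimensions do not match")
    return Zc @ alpha, Kc_dev @ d


def derive_ratio_draws(scalars: pd.DataFrame) -> pd.DataFrame:
    """Per-draw h2 and d2 appended to a scalar trace (means of per-draw ratios)."""
    h2, d2 = variance_ratios(
        scalars["V_A"], scalars["V_D"], scalars["sig_c2"], scalars["sig_r2"], scalars["sig_e2"]
    )
    out = scalars.copy()
    out["h2"] = h2
    out["d2"] = d2
    return out
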