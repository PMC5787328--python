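"""Gibbs sampler for genomic evaluation with directional dominance.

The observation model for repeated litter-size records is

    y = 1 mu + h b + X t + W r + Q c + Z a + K d + e,

with mu the general mean, b a regression on average individual SNP
homozygosity h (inbreeding depression / heterosis), t fixed parity
effects (4 classes, first constrained to zero), r random
farm-year-month contemporary-group effects, c random permanent
environmental effects of the sow, a and d SNP additive and dominance
effects, and Gaussian residuals e.  Priors are flat for mu, b and t;
N(0, sigma_r2), N(0, sigma_c2), N(0, sigma_a2) for r, c, a; skew
Gaussian (lam |N(0,1)| + N(0, sigma_d2)) for each dominance effect; and
scaled inverse chi-square for the five variances.  The asymmetry
parameter lam carries a flat prior and is sampled through one
half-normal auxiliary variable per SNP.

The four standard models are reductions of this Full model:
SC (lam = 0), AN (b = 0), SN (both zero).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels
from ._kernels import (
    auxiliary_moments,
    dominance_moments,
    lambda_moments,
    loc_moments,
)
from .genotypes import GenotypeMatrix, encode_design, homozygosity_covariate
from .skewnormal import truncnorm_nonneg_sample

__all__ = [
    "PhenotypeTable",
    "ModelSpec",
    "PosteriorDraws",
    "MODELS",
    "model_spec",
    "fit",
    "read_phenotypes",
    "write_phenotypes",
    "update_location_block",
    "update_dominance_effect",
    "update_auxiliary",
    "update_lambda",
    "update_variance",
]

SCALAR_COLS = [
    "mu",
    "b",
    "lam",
    "sig_r2",
    "sig_c2",
    "sig_a2",
    "sig_d2",
    "sig_e2",
    "t2",
    "t3",
    "t4",
    "V_A",
    "V_D",
    "I_D",
]

#: model name -> (include_b, include_lambda)
MODELS = {
    "SN": (False, False),
    "SC": (True, False),
    "AN": (False, True),
    "Full": (True, True),
}


@dataclass
class PhenotypeTable:
    """Record-level litter-size data: animal, parity class, group, phenotype."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        need = ["animal_id", "parity", "group_id", "y"]
        missing = [c for c in need if c not in self.records.columns]
        if missing:
            raise ValueError(f"phenotype table lacks columns {missing}")
        rec = self.records.copy()
        rec["animal_id"] = rec["animal_id"].astype(str)
        rec["group_id"] = rec["group_id"].astype(str)
        rec["parity"] = rec["parity"].astype(int)
        rec["y"] = rec["y"].astype(float)
        if not np.isfinite(rec["y"]).all():
            raise ValueError("non-finite phenotype record")
        if not rec["parity"].between(1, 4).all():
            raise ValueError("parity classes must be in {1, 2, 3, 4} (4 = 4th and later)")
        self.records = rec.reset_index(drop=True)

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def y(self) -> np.ndarray:
        return self.records["y"].to_numpy()


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str, "group_id": str})
    return PhenotypeTable(df)


def write_phenotypes(P: PhenotypeTable, path) -> None:
    P.records.to_csv(path, sep="\t", index=False)


@dataclass
class ModelSpec:
    """Which directional-dominance terms are active, priors, chain settings."""

    include_b: bool = True
    include_lambda: bool = True
    nu: float = 4.2
    scales: dict | None = None  # {"r","c","a","d","e"} -> S2; None = from data
    n_iter: int = 7500
    burn_in: int = 2500
    thin: int = 1
    n_chains: int = 5
    seed: int = 1
    centering: str = "freq"
    effects_stride: int = 0  # store full a/d vectors every k-th kept draw; 0 = never
    check_every: int = 1000
    fixed_variances: dict | None = None  # oracle testing only
    lambda_clamped: bool = False  # sample auxiliaries but pin lambda at 0 (nesting check)

    def __post_init__(self) -> None:
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")

    @property
    def model_name(self) -> str:
        for name, flags in MODELS.items():
            if flags == (self.include_b, self.include_lambda):
                return name
        raise AssertionError

    @property
    def n_keep_per_chain(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


def model_spec(name: str, **kwargs) -> ModelSpec:
    """ModelSpec for one of the four named models (SN, SC, AN, Full)."""
    try:
        b, lam = MODELS[name]
    except KeyError:
        raise ValueError(f"unknown model {name!r}; choose from {sorted(MODELS)}") from None
    return ModelSpec(include_b=b, include_lambda=lam, **kwargs)


@dataclass
class PosteriorDraws:
    """Pooled post-burn-in draws plus the per-record state model selection needs."""

    scalars: pd.DataFrame  # SCALAR_COLS plus chain, iteration
    fitted: np.ndarray  # (total draws, n_records)
    y: np.ndarray
    mean_alpha: np.ndarray  # posterior-mean substitution effects per SNP
    mean_d: np.ndarray
    freqs: np.ndarray
    ind_ids: list[str]
    spec: ModelSpec
    dataset_hash: str
    a_draws: np.ndarray | None = None  # strided full effect vectors
    d_draws: np.ndarray | None = None
    max_resid_err: float = 0.0

    @property
    def n_draws(self) -> int:
        return len(self.scalars)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.scalars.to_csv(outdir / "scalars.tsv", sep="\t", index=False)
        np.save(outdir / "fitted.npy", self.fitted)
        np.save(outdir / "y.npy", self.y)
        eff = pd.DataFrame(
            {"freq": self.freqs, "mean_alpha": self.mean_alpha, "mean_d": self.mean_d}
        )
        eff.to_csv(outdir / "snp_effects.tsv", sep="\t", index=False)
        manifest = {
            "model": self.spec.model_name,
            "include_b": self.spec.include_b,
            "include_lambda": self.spec.include_lambda,
            "seed": self.spec.seed,
            "n_chains": self.spec.n_chains,
            "n_iter": self.spec.n_iter,
            "burn_in": self.spec.burn_in,
            "thin": self.spec.thin,
            "dataset_hash": self.dataset_hash,
            "ind_ids": self.ind_ids,
            "max_resid_err": self.max_resid_err,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, outdir) -> "PosteriorDraws":
        outdir = Path(outdir)
        manifest = json.loads((outdir / "manifest.json").read_text())
        scalars = pd.read_csv(outdir / "scalars.tsv", sep="\t")
        eff = pd.read_csv(outdir / "snp_effects.tsv", sep="\t")
        spec = ModelSpec(
            include_b=manifest["include_b"],
            include_lambda=manifest["include_lambda"],
            n_iter=manifest["n_iter"],
            burn_in=manifest["burn_in"],
            thin=manifest["thin"],
            n_chains=manifest["n_chains"],
            seed=manifest["seed"],
        )
        return cls(
            scalars=scalars,
            fitted=np.load(outdir / "fitted.npy"),
            y=np.load(outdir / "y.npy"),
            mean_alpha=eff["mean_alpha"].to_numpy(),
            mean_d=eff["mean_d"].to_numpy(),
            freqs=eff["freq"].to_numpy(),
            ind_ids=list(manifest["ind_ids"]),
            spec=spec,
            dataset_hash=manifest["dataset_hash"],
            max_resid_err=float(manifest["max_resid_err"]),
        )


def dataset_hash(G: GenotypeMatrix, P: PhenotypeTable) -> str:
    """Stable digest identifying a genotype + phenotype dataset."""
    hsh = hashlib.sha256()
    hsh.update(np.ascontiguousarray(G.counts).tobytes())
    hsh.update("|".join(G.ind_ids).encode())
    hsh.update(P.records.to_csv(index=False).encode())
    return hsh.hexdigest()[:16]


def default_scales(y: np.ndarray, two_pq: np.ndarray) -> dict:
    """Weakly-informative scale hyperparameters from a phenotypic-variance guess.

    The phenotypic variance is partitioned a priori as 10% additive, 5%
    dominance, 5% contemporary group, 10% permanent environment, 70%
    residual; per-SNP scales divide the genetic shares by the summed
    heterozygosity terms that map SNP-effect variance to genetic variance.
    """
    vp = float(np.var(y))
    return {
        "r": 0.05 * vp,
        "c": 0.10 * vp,
        "a": 0.10 * vp / float(two_pq.sum()),
        "d": 0.05 * vp / float((two_pq**2).sum()),
        "e": 0.70 * vp,
    }


def _prepare(G: GenotypeMatrix, P: PhenotypeTable, spec: ModelSpec):
    ind_index = {iid: k for k, iid in enumerate(G.ind_ids)}
    unknown = [aid for aid in P.records["animal_id"].unique() if aid not in ind_index]
    if unknown:
        raise ValueError(f"phenotype records for animals without genotypes: {unknown[:5]}")
    sow = P.records["animal_id"].map(ind_index).to_numpy(dtype=np.int64)
    grp_codes, _ = pd.factorize(P.records["group_id"])
    grp = grp_codes.astype(np.int64)
    par = P.records["parity"].to_numpy(dtype=np.int64) - 1

    Zc, Kc = encode_design(G, centering=spec.centering)
    h_ind = homozygosity_covariate(G)
    # record-level design, SNP-major for contiguous access in the kernel
    Z = np.ascontiguousarray(Zc[sow].T)
    K = np.ascontiguousarray(Kc[sow].T)
    h = h_ind[sow]
    p = G.freqs
    two_pq = 2.0 * p * (1.0 - p)
    return sow, grp, par, h, Z, K, two_pq, 1.0 - 2.0 * p, int(grp.max()) + 1


def fit(G: GenotypeMatrix, P: PhenotypeTable, spec: ModelSpec) -> PosteriorDraws:
    """Run the Gibbs sampler; pooled post-burn-in draws across chains.

    Chains are independent with sub-seeds spawned deterministically from
    ``spec.seed``; a fixed seed yields a bit-identical draw sequence.
    """
    y = P.y
    sow, grp, par, h, Z, K, two_pq, one_minus_2p, n_grp = _prepare(G, P, spec)
    m, n = Z.shape

    scales = spec.scales or default_scales(y, two_pq)
    if spec.fixed_variances is not None:
        fv = spec.fixed_variances
        init_var = np.array([fv["r"], fv["c"], fv["a"], fv["d"], fv["e"]], dtype=float)
    else:
        init_var = np.array([scales[k] for k in ("r", "c", "a", "d", "e")], dtype=float)

    # direction of the b / mean-dominance recentering move: the residual
    # fitted-value change per unit shift is delta * v_dir (near zero because
    # homozygosity and the heterozygote fraction sum to one per record)
    v_dir = h + K.sum(axis=0) / m - (1.0 - float(two_pq.mean()))

    n_keep = spec.n_keep_per_chain
    stride = spec.effects_stride
    n_store = 0 if stride <= 0 else (n_keep + stride - 1) // stride

    chain_seeds = np.random.SeedSequence(spec.seed).generate_state(spec.n_chains)
    scal_all, fitted_all, a_all, d_all = [], [], [], []
    sum_alpha = np.zeros(m)
    sum_d = np.zeros(m)
    worst_resid = 0.0

    for c_idx in range(spec.n_chains):
        scal = np.empty((n_keep, _kernels.N_SCALARS))
        fitted = np.empty((n_keep, n))
        sa = np.zeros(m)
        sd = np.zeros(m)
        a_store = np.empty((max(n_store, 1), m) if stride > 0 else (1, 1))
        d_store = np.empty_like(a_store)
        status, it, resid_err, kept, stored = _kernels.run_chain(
            int(chain_seeds[c_idx] & 0x7FFFFFFF),
            spec.n_iter,
            spec.burn_in,
            spec.thin,
            y,
            sow,
            grp,
            par,
            h,
            Z,
            K,
            (Z**2).sum(axis=1),
            (K**2).sum(axis=1),
            v_dir,
            two_pq,
            one_minus_2p,
            len(G.ind_ids),
            n_grp,
            spec.include_b,
            spec.include_lambda,
            spec.lambda_clamped,
            spec.fixed_variances is not None,
            spec.nu,
            scales["r"],
            scales["c"],
            scales["a"],
            scales["d"],
            scales["e"],
            init_var,
            stride,
            spec.check_every,
            scal,
            fitted,
            sa,
            sd,
            a_store,
            d_store,
        )
        if status == _kernels.STATUS_NONFINITE:
            raise RuntimeError(
                f"chain {c_idx} diverged (non-finite state) at iteration {it}"
            )
        assert kept == n_keep
        worst_resid = max(worst_resid, resid_err)
        df = pd.DataFrame(scal, columns=SCALAR_COLS)
        df.insert(0, "chain", c_idx)
        df.insert(1, "iteration", spec.burn_in + spec.thin * np.arange(n_keep))
        scal_all.append(df)
        fitted_all.append(fitted)
        sum_alpha += sa
        sum_d += sd
        if stride > 0:
            a_all.append(a_store[:stored])
            d_all.append(d_store[:stored])

    total = spec.n_chains * n_keep
    return PosteriorDraws(
        scalars=pd.concat(scal_all, ignore_index=True),
        fitted=np.vstack(fitted_all),
        y=y,
        mean_alpha=sum_alpha / total,
        mean_d=sum_d / total,
        freqs=G.freqs,
        ind_ids=list(G.ind_ids),
        spec=spec,
        dataset_hash=dataset_hash(G, P),
        a_draws=np.vstack(a_all) if a_all else None,
        d_draws=np.vstack(d_all) if d_all else None,
        max_resid_err=worst_resid,
    )


# ---------------------------------------------------------------------------
# Single-update operations (same conditional moments as the compiled kernel)
# ---------------------------------------------------------------------------


def update_location_block(
    w: np.ndarray,
    e: np.ndarray,
    old: float,
    sigma_e2: float,
    prior_prec: float,
    rng: np.random.Generator,
) -> float:
    """Sample one location coefficient and update the residual in place.

    ``prior_prec`` is 0 for flat-prior effects (mu, b, t) and 1/sigma2
    for Gaussian random effects.
    """
    wtw = float(w @ w)
    if wtw == 0.0 and prior_prec == 0.0:
        raise ValueError("flat-prior effect with empty design column is undefined")
    wty = float(w @ e) + wtw * old
    mean, var = loc_moments(wtw, wty, sigma_e2, prior_prec)
    new = rng.normal(mean, np.sqrt(var))
    e += w * (old - new)
    return new


def update_dominance_effect(
    k: np.ndarray,
    e: np.ndarray,
    old_d: float,
    sigma_e2: float,
    sigma_d2: float,
    lam: float,
    u_j: float,
    rng: np.random.Generator,
) -> float:
    """Sample one SNP dominance effect under its conditional skew-normal prior."""
    ktk = float(k @ k)
    kty = float(k @ e) + ktk * old_d
    mean, var = dominance_moments(ktk, kty, sigma_e2, sigma_d2, lam * u_j)
    new = rng.normal(mean, np.sqrt(var))
    e += k * (old_d - new)
    return new


def update_auxiliary(
    d_j: float, lam: float, sigma_d2: float, rng: np.random.Generator
) -> float:
    """Sample the half-normal auxiliary variable of one SNP (truncated normal)."""
    mean, var = auxiliary_moments(d_j, lam, sigma_d2)
    return float(truncnorm_nonneg_sample(mean, var, rng))


def update_lambda(
    u: np.ndarray, d: np.ndarray, sigma_d2: float, rng: np.random.Generator
) -> float:
    """Sample the asymmetry parameter given auxiliaries and dominance effects."""
    sum_uu = float(u @ u)
    if sum_uu == 0.0:
        raise ValueError("degenerate lambda conditional: all auxiliary variables zero")
    mean, var = lambda_moments(float(u @ d), sum_uu, sigma_d2)
    return rng.normal(mean, np.sqrt(var))


def update_variance(
    sum_sq: float, n_terms: int, hyper: tuple[float, float], rng: np.random.Generator
) -> float:
    """Scaled inverse chi-square conditional draw (sum_sq + nu S2) / chi2_{n+nu}."""
    nu, s2 = hyper
    df = n_terms + nu
    if df <= 0:
        raise ValueError("improper variance posterior: n_terms + nu <= 0")
    if sum_sq < 0:
        raise ValueError("sum_sq must be >= 0")
    return (sum_sq + nu * s2) / rng.chisquare(df)
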