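"""Synthetic sow litter-size datasets with known genetic architecture.

The generator emulates the statistical structure the directional-
dominance models assume: several hundred to several thousand sows with
1-5 litter records each, tens of thousands of biallelic SNPs, a litter
size mean near 11.7 piglets with SD near 2.9, variance components of
realistic magnitude, and true directional dominance injected either
through the homozygosity regression (b_true < 0) or a skewed dominance
effect distribution (lambda_true > 0).

Genotypes are drawn SNP-wise with a per-sow inbreeding coefficient F_i
(heterozygote probability 2 p q (1 - F_i)): commercial pig lines vary in
genomic inbreeding, and that variation is what makes the homozygosity
covariate estimable.  Sows are unrelated and SNPs are in linkage
equilibrium, which the effect-level priors of the model also assume.

Defaults at desk scale (500 sows, ~1500 records, 2000 SNPs) keep the
aggregate directional-dominance signal of the large pig datasets:
b_true = -12 piglets per unit homozygosity, and lambda_true chosen so
that m * lambda * sqrt(2/pi) is ~12, the same aggregate trend expressed
through the dominance effects.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genetic_params import genetic_variances, genomic_values, inbreeding_depression, substitution_effects
from .genotypes import (
    MISSING,
    GenotypeMatrix,
    encode_design,
    encode_dominance_deviation,
    homozygosity_covariate,
    write_genotypes,
)
from .gibbs_sampler import PhenotypeTable, write_phenotypes

__all__ = ["SimScenario", "SimData", "simulate", "write_sim", "make_fixture"]


@dataclass
class SimScenario:
    """True parameters and design of one simulated dataset."""

    n_sows: int = 500
    n_snp: int = 2000
    # litter-record count per sow: probabilities for 1..5 records (mean 3)
    records_per_sow_probs: tuple = (0.10, 0.25, 0.30, 0.25, 0.10)
    freq_low: float = 0.05
    freq_high: float = 0.95
    missing_rate: float = 0.01
    f_mean: float = 0.05  # per-sow inbreeding coefficient distribution
    f_sd: float = 0.07
    f_max: float = 0.35
    mu_true: float = 11.7
    b_true: float = -12.0
    lambda_true: float = 0.0075
    sigma_a2_true: float = 1.0e-3  # per-SNP additive effect variance
    sigma_d2_true: float = 1.7e-3  # per-SNP dominance scale variance
    sigma_r2_true: float = 0.16  # farm-year-month
    sigma_c2_true: float = 0.50  # permanent environment
    sigma_e2_true: float = 6.57
    parity_effects: tuple = (0.0, 0.35, 0.45, 0.30)
    n_groups: int | None = None  # default: about 4 records per group
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("sigma_a2_true", "sigma_d2_true", "sigma_r2_true",
                     "sigma_c2_true", "sigma_e2_true"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(sum(self.records_per_sow_probs) - 1.0) > 1e-9:
            raise ValueError("records_per_sow_probs must sum to 1")


@dataclass
class SimData:
    """Simulated genotypes and phenotypes together with the generating truth."""

    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    scenario: SimScenario
    a_true: np.ndarray
    d_true: np.ndarray
    s_a_true: np.ndarray
    s_d_true: np.ndarray
    realized: dict = field(default_factory=dict)


def _draw_genotypes(rng, n_sows, p, f_ind):
    """Counts under the inbreeding model: P(het) = 2pq(1-F)."""
    q = 1.0 - p
    f = f_ind[:, None]
    p_hom2 = p**2 + p * q * f
    p_het = 2.0 * p * q * (1.0 - f)
    u = rng.random((n_sows, p.size))
    counts = np.where(u < p_hom2, 2, np.where(u < p_hom2 + p_het, 1, 0))
    return counts.astype(np.int8)


def simulate(scenario: SimScenario) -> SimData:
    """Draw one dataset from the generative version of the Full model."""
    sc = scenario
    rng = np.random.default_rng(sc.seed)

    p = rng.uniform(sc.freq_low, sc.freq_high, sc.n_snp)
    f_ind = np.clip(rng.normal(sc.f_mean, sc.f_sd, sc.n_sows), 0.0, sc.f_max)
    counts = _draw_genotypes(rng, sc.n_sows, p, f_ind)
    if sc.missing_rate > 0:
        miss = rng.random(counts.shape) < sc.missing_rate
        counts[miss] = MISSING

    ind_ids = [f"sow{i + 1:05d}" for i in range(sc.n_sows)]
    snp_ids = [f"snp{j + 1:05d}" for j in range(sc.n_snp)]
    G = GenotypeMatrix(counts, ind_ids, snp_ids)

    # SNP effects: Gaussian additive, skew-Gaussian dominance
    a = rng.normal(0.0, np.sqrt(sc.sigma_a2_true), sc.n_snp)
    d = sc.lambda_true * np.abs(rng.standard_normal(sc.n_snp)) + rng.normal(
        0.0, np.sqrt(sc.sigma_d2_true), sc.n_snp
    )

    # genotypic values through the same encodings the sampler uses
    Zc, Kc = encode_design(G, centering="freq")
    g_add = Zc @ a
    g_dom = Kc @ d
    h = homozygosity_covariate(G)

    # repeated records
    n_rec_per_sow = 1 + rng.choice(5, size=sc.n_sows, p=sc.records_per_sow_probs)
    sow_of_rec = np.repeat(np.arange(sc.n_sows), n_rec_per_sow)
    parity = np.concatenate([np.minimum(np.arange(1, k + 1), 4) for k in n_rec_per_sow])
    n_rec = sow_of_rec.size
    n_groups = sc.n_groups or max(1, n_rec // 4)
    if n_groups > n_rec:
        raise ValueError(f"n_groups={n_groups} exceeds the number of records {n_rec}")
    grp_of_rec = rng.integers(0, n_groups, n_rec)

    r_eff = rng.normal(0.0, np.sqrt(sc.sigma_r2_true), n_groups)
    c_eff = rng.normal(0.0, np.sqrt(sc.sigma_c2_true), sc.n_sows)
    e = rng.normal(0.0, np.sqrt(sc.sigma_e2_true), n_rec)
    t = np.asarray(sc.parity_effects)

    # b acts on realized per-sow homozygosity; the intercept is parameterized
    # against its sample mean so the phenotype mean stays at mu_true (the
    # fitted model regresses on raw h and absorbs the shift into mu)
    y = (
        sc.mu_true
        + sc.b_true * (h[sow_of_rec] - h.mean())
        + t[parity - 1]
        + r_eff[grp_of_rec]
        + c_eff[sow_of_rec]
        + g_add[sow_of_rec]
        + g_dom[sow_of_rec]
        + e
    )

    P = PhenotypeTable(
        pd.DataFrame(
            {
                "animal_id": [ind_ids[i] for i in sow_of_rec],
                "parity": parity,
                "group_id": [f"grp{g + 1:04d}" for g in grp_of_rec],
                "y": y,
            }
        )
    )

    alpha = substitution_effects(a, d, G.freqs)
    s_a, s_d = genomic_values(Zc, encode_dominance_deviation(G), alpha, d)
    v_a, v_d = genetic_variances(a, d, G.freqs)
    realized = {
        "V_A": v_a,
        "V_D": v_d,
        "I_D": inbreeding_depression(sc.b_true, d, G.freqs),
        "mean_y": float(y.mean()),
        "sd_y": float(y.std()),
        "n_records": int(n_rec),
        "n_groups": int(n_groups),
    }
    return SimData(G, P, sc, a, d, s_a, s_d, realized)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_sim(sim: SimData, outdir, dialect: str = "tsv") -> dict:
    """Write genotypes, phenotypes and the truth file; return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gpath = outdir / ("genotypes.tsv" if dialect == "tsv" else "genotypes.raw")
    ppath = outdir / "phenotypes.tsv"
    tpath = outdir / "truth_snps.tsv"
    apath = outdir / "truth_animals.tsv"
    write_genotypes(sim.genotypes, gpath, dialect=dialect)
    write_phenotypes(sim.phenotypes, ppath)
    pd.DataFrame(
        {
            "snp_id": sim.genotypes.snp_ids,
            "freq": sim.genotypes.freqs,
            "a_true": sim.a_true,
            "d_true": sim.d_true,
        }
    ).to_csv(tpath, sep="\t", index=False)
    pd.DataFrame(
        {"animal_id": sim.genotypes.ind_ids, "s_a_true": sim.s_a_true, "s_d_true": sim.s_d_true}
    ).to_csv(apath, sep="\t", index=False)
    manifest = {
        "scenario": asdict(sim.scenario),
        "realized": sim.realized,
        "files": {
            pth.name: _sha256(pth) for pth in (gpath, ppath, tpath, apath)
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def make_fixture(size: str, outdir=None, seed: int = 20240 + 1):
    """Deterministic fixtures: ``tiny`` (QC tests) or ``desk`` (model runs).

    The tiny fixture is 20 sows x 50 SNPs with planted QC violations:
    SNPs 46-50 have realized minor allele frequency below 0.05, and sows
    1-2 have call rate below 0.95 (their missing calls sit in disjoint
    SNP columns so no extra SNP falls under the call-rate threshold).
    """
    if size == "desk":
        sim = simulate(SimScenario(seed=seed))
    elif size == "tiny":
        sc = SimScenario(
            n_sows=20,
            n_snp=50,
            freq_low=0.30,
            freq_high=0.70,
            missing_rate=0.0,
            n_groups=8,
            seed=seed,
        )
        sim = simulate(sc)
        counts = sim.genotypes.counts
        # plant 5 SNPs with one heterozygote each: realized MAF = 1/40 < 0.05
        for j in range(45, 50):
            counts[:, j] = 0
            counts[j % 20, j] = 1
        # plant 2 sows with 4/50 = 8% missing calls, in disjoint SNP columns
        counts[0, 0:4] = MISSING
        counts[1, 4:8] = MISSING
        sim.genotypes.recompute_freqs()
    else:
        raise ValueError(f"unknown fixture size {size!r}")
    if outdir is not None:
        write_sim(sim, outdir)
    return sim
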