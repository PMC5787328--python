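"""Genotype containers, I/O, quality control and design encodings.

Genotypes are biallelic SNP allele counts in {0, 1, 2} (count of the
reported allele) over individuals, with explicit missingness.  Two text
dialects are read and written: a simple TSV (``id`` column followed by one
column per SNP, missing coded ``NA``) and the PLINK ``.raw`` additive
export (six pedigree columns, then per-SNP counts, missing ``NA``).

The module also produces the quantities the directional-dominance model
needs from genotypes: per-SNP allele frequencies, the per-individual
average-homozygosity covariate h, and the additive/dominance design codes
used both by the Gibbs sampler and by the data simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "QCReport",
    "read_genotypes",
    "write_genotypes",
    "qc_filter",
    "homozygosity_covariate",
    "encode_design",
    "encode_dominance_deviation",
]

MISSING = -1  # internal missing code in the counts array


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele counts with missingness and frequencies.

    ``counts`` is an int8 array with entries in {0, 1, 2} or ``MISSING``;
    ``freqs[j]`` is the frequency p_j of the counted allele at SNP j,
    computed from non-missing calls only.
    """

    counts: np.ndarray
    ind_ids: list[str]
    snp_ids: list[str]
    freqs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int8)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (individuals x SNPs)")
        bad = ~np.isin(self.counts, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"allele count outside {{0,1,2,NA}} at individual "
                f"{self.ind_ids[i]!r}, SNP {self.snp_ids[j]!r}"
            )
        if len(self.ind_ids) != self.counts.shape[0]:
            raise ValueError("ind_ids length does not match counts rows")
        if len(self.snp_ids) != self.counts.shape[1]:
            raise ValueError("snp_ids length does not match counts columns")
        if self.freqs is None:
            self.freqs = self._compute_freqs()
        else:
            self.freqs = np.asarray(self.freqs, dtype=float)

    def _compute_freqs(self) -> np.ndarray:
        obs = self.counts != MISSING
        n_obs = obs.sum(axis=0)
        if (n_obs == 0).any():
            j = int(np.argmin(n_obs))
            raise ValueError(f"SNP {self.snp_ids[j]!r} has no observed calls")
        tot = np.where(obs, self.counts, 0).sum(axis=0)
        return tot / (2.0 * n_obs)

    @property
    def n_ind(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snp(self) -> int:
        return self.counts.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.counts == MISSING

    def recompute_freqs(self) -> None:
        self.freqs = self._compute_freqs()


@dataclass
class QCReport:
    """Summary of a quality-control pass (thresholds and removals)."""

    n_snp_in: int
    n_snp_out: int
    n_ind_in: int
    n_ind_out: int
    removed_snp_ids: list[str]
    removed_ind_ids: list[str]
    maf_min: float
    snp_call_min: float
    ind_call_min: float

    def to_text(self) -> str:
        lines = [
            f"n_snp_in: {self.n_snp_in}",
            f"n_snp_out: {self.n_snp_out}",
            f"n_ind_in: {self.n_ind_in}",
            f"n_ind_out: {self.n_ind_out}",
            f"maf_min: {self.maf_min}",
            f"snp_call_min: {self.snp_call_min}",
            f"ind_call_min: {self.ind_call_min}",
            "removed_snp_ids: " + ",".join(self.removed_snp_ids),
            "removed_ind_ids: " + ",".join(self.removed_ind_ids),
        ]
        return "\n".join(lines) + "\n"


class GenotypeParseError(ValueError):
    pass


def _parse_count_token(tok: str, line_no: int) -> int:
    if tok in ("NA", "na", ""):
        return MISSING
    try:
        v = int(tok)
    except ValueError as exc:
        raise GenotypeParseError(
            f"line {line_no}: allele count {tok!r} is not an integer or NA"
        ) from exc
    if v not in (0, 1, 2):
        raise GenotypeParseError(
            f"line {line_no}: allele count {v} outside {{0,1,2}}"
        )
    return v


def read_genotypes(path, dialect: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from ``tsv`` or ``plink_raw`` text."""
    if dialect not in ("tsv", "plink_raw"):
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise GenotypeParseError(f"{path}: empty genotype file")

    if dialect == "tsv":
        header = lines[0].split("\t")
        if header[0] != "id":
            raise GenotypeParseError(f"{path}: TSV header must start with 'id'")
        snp_ids = header[1:]
        meta_cols, sep = 1, "\t"
    else:
        header = lines[0].split()
        expect = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        if header[:6] != expect:
            raise GenotypeParseError(
                f"{path}: PLINK .raw header must start with {' '.join(expect)}"
            )
        snp_ids = header[6:]
        meta_cols, sep = 6, None

    n_snp = len(snp_ids)
    ind_ids: list[str] = []
    rows = np.empty((len(lines) - 1, n_snp), dtype=np.int8)
    for k, ln in enumerate(lines[1:], start=2):
        parts = ln.split(sep) if sep is None else ln.split(sep)
        if len(parts) != meta_cols + n_snp:
            raise GenotypeParseError(
                f"{path}: line {k} has {len(parts)} fields, "
                f"expected {meta_cols + n_snp}"
            )
        ind_ids.append(parts[1] if dialect == "plink_raw" else parts[0])
        rows[k - 2] = [_parse_count_token(t, k) for t in parts[meta_cols:]]
    return GenotypeMatrix(rows, ind_ids, snp_ids)


def write_genotypes(G: GenotypeMatrix, path, dialect: str = "tsv") -> None:
    """Write ``G`` in one of the supported text dialects."""
    with open(path, "w") as fh:
        if dialect == "tsv":
            fh.write("id\t" + "\t".join(G.snp_ids) + "\n")
            for i, ind in enumerate(G.ind_ids):
                toks = ["NA" if c == MISSING else str(c) for c in G.counts[i]]
                fh.write(ind + "\t" + "\t".join(toks) + "\n")
        elif dialect == "plink_raw":
            fh.write("FID IID PAT MAT SEX PHENOTYPE " + " ".join(G.snp_ids) + "\n")
            for i, ind in enumerate(G.ind_ids):
                toks = ["NA" if c == MISSING else str(c) for c in G.counts[i]]
                fh.write(f"0 {ind} 0 0 0 -9 " + " ".join(toks) + "\n")
        else:
            raise ValueError(f"unknown genotype dialect {dialect!r}")


def qc_filter(
    G: GenotypeMatrix,
    maf_min: float = 0.05,
    snp_call_min: float = 0.95,
    ind_call_min: float = 0.95,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove low-MAF / low-call-rate SNPs, then low-call-rate individuals.

    SNP filters run first on the full individual set, individual filters
    on the retained SNP set; frequencies are recomputed once at the end.
    """
    obs = G.counts != MISSING
    snp_call = obs.mean(axis=0)
    maf = np.minimum(G.freqs, 1.0 - G.freqs)
    keep_snp = (maf >= maf_min) & (snp_call >= snp_call_min)
    if not keep_snp.any():
        raise ValueError("QC removed every SNP")

    obs_kept = obs[:, keep_snp]
    ind_call = obs_kept.mean(axis=1)
    keep_ind = ind_call >= ind_call_min
    if not keep_ind.any():
        raise ValueError("QC removed every individual")

    out = GenotypeMatrix(
        G.counts[np.ix_(keep_ind, keep_snp)],
        [iid for iid, k in zip(G.ind_ids, keep_ind) if k],
        [sid for sid, k in zip(G.snp_ids, keep_snp) if k],
    )
    report = QCReport(
        n_snp_in=G.n_snp,
        n_snp_out=out.n_snp,
        n_ind_in=G.n_ind,
        n_ind_out=out.n_ind,
        removed_snp_ids=[s for s, k in zip(G.snp_ids, keep_snp) if not k],
        removed_ind_ids=[i for i, k in zip(G.ind_ids, keep_ind) if not k],
        maf_min=maf_min,
        snp_call_min=snp_call_min,
        ind_call_min=ind_call_min,
    )
    return out, report


def homozygosity_covariate(G: GenotypeMatrix) -> np.ndarray:
    """Average SNP homozygosity h_i over *observed* calls per individual.

    h_i is the fraction of an individual's non-missing SNPs that are
    homozygous (count 0 or 2); its regression coefficient b in the model
    estimates directional dominance / inbreeding depression.
    """
    obs = G.counts != MISSING
    n_obs = obs.sum(axis=1)
    if (n_obs == 0).any():
        i = int(np.argmin(n_obs))
        raise ValueError(f"individual {G.ind_ids[i]!r} has no observed calls")
    hom = ((G.counts == 0) | (G.counts == 2)).sum(axis=1)
    return hom / n_obs


def _imputed_counts(G: GenotypeMatrix) -> np.ndarray:
    """Counts as float with missing entries mean-imputed to 2 p_j."""
    x = G.counts.astype(float)
    miss = G.missing_mask
    if miss.any():
        fill = np.broadcast_to(2.0 * G.freqs, x.shape)
        x = np.where(miss, fill, x)
    return x


def encode_design(
    G: GenotypeMatrix, centering: str = "freq"
) -> tuple[np.ndarray, np.ndarray]:
    """Additive (Z) and dominance (K) design codes per individual x SNP.

    With ``centering="freq"``: Z_ij = x_ij − 2 p_j and
    K_ij = 1{x_ij = 1} − 2 p_j q_j, so both columns have zero mean in a
    Hardy–Weinberg population; with ``centering="none"`` the raw codes
    x_ij and 1{x_ij = 1}.  Missing genotypes are mean-imputed (x → 2 p_j,
    heterozygote indicator → its expectation 2 p_j q_j).
    """
    if centering not in ("freq", "none"):
        raise ValueError(f"unknown centering {centering!r}")
    p = G.freqs
    if ((p <= 0.0) | (p >= 1.0)).any():
        j = int(np.argmax((p <= 0.0) | (p >= 1.0)))
        raise ValueError(
            f"monomorphic SNP {G.snp_ids[j]!r} (p={p[j]}); run qc_filter first"
        )
    x = _imputed_counts(G)
    het = (G.counts == 1).astype(float)
    if G.missing_mask.any():
        het = np.where(G.missing_mask, np.broadcast_to(2 * p * (1 - p), het.shape), het)
    if centering == "freq":
        return x - 2.0 * p, het - 2.0 * p * (1.0 - p)
    return x, het


def encode_dominance_deviation(G: GenotypeMatrix) -> np.ndarray:
    """Classical dominance-deviation codes: 2→−2q², 1→2pq, 0→−2p².

    This is the orthogonal (breeding-value / dominance-deviation)
    partition used to turn SNP dominance effects into per-individual
    dominance deviations; missing genotypes contribute 0 (their
    expectation under Hardy–Weinberg).
    """
    p = G.freqs
    q = 1.0 - p
    out = np.zeros(G.counts.shape, dtype=float)
    out[G.counts == 2] = np.broadcast_to(-2.0 * q**2, out.shape)[G.counts == 2]
    out[G.counts == 1] = np.broadcast_to(2.0 * p * q, out.shape)[G.counts == 1]
    out[G.counts == 0] = np.broadcast_to(-2.0 * p**2, out.shape)[G.counts == 0]
    return out
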