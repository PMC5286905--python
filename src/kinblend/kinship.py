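"""Genomic relationship matrices, QC, rescaling, and pedigree blending.

Two classical genomic relationship matrices are provided, differing only in
the denominator that normalizes the centered cross-product ``W W'``:

* VanRaden:  ``G_V = W W' / (2 * sum_i p_i q_i)``
* Forni:     ``G_F = W W' / (trace(W W') / m)``  (so ``trace(G_F) = m``)

with ``W`` the column-centered 0/1/2 genotype matrix.  Either can be
rescaled entrywise to the [0, 2] range of the numerator relationship matrix
with a map-minmax affine transform, and blended with A into the kinship
kernel ``K = lambda * G + (1 - lambda) * A``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("kinblend")

__all__ = [
    "GenotypeMatrix",
    "KinshipMatrix",
    "ScalingBounds",
    "LAMBDA_GRID",
    "filter_snps",
    "impute_naive",
    "center_genotypes",
    "build_G_vanraden",
    "build_G_forni",
    "minmax_scale",
    "blend_kernels",
]

#: default blending-weight grid
LAMBDA_GRID = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)

_SYM_TOL = 1e-10


@dataclass
class GenotypeMatrix:
    """Additive-coded biallelic SNP genotypes.

    ``codes`` is an n x p float matrix with entries in {0, 1, 2} (counted
    alleles) or NaN for missing calls; after naive imputation entries may be
    fractional dosages.
    """

    codes: np.ndarray
    individual_ids: list[str]
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.individual_ids), len(self.snp_ids)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.snp_ids)} SNPs"
            )
        observed = self.codes[~np.isnan(self.codes)]
        if observed.size and (observed.min() < 0 or observed.max() > 2):
            raise ValueError("genotype codes must lie in [0, 2]")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def p(self) -> int:
        return self.codes.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        """Per-SNP counted-allele frequency from non-missing entries."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.codes, axis=0) / 2.0

    @property
    def call_rate(self) -> np.ndarray:
        """Per-SNP fraction of non-missing calls."""
        return 1.0 - np.isnan(self.codes).mean(axis=0)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            codes=self.codes[:, mask],
            individual_ids=list(self.individual_ids),
            snp_ids=[s for s, keep in zip(self.snp_ids, mask) if keep],
        )


@dataclass
class KinshipMatrix:
    """A labeled symmetric relatedness matrix (A, G variant, or blend)."""

    values: np.ndarray
    ids: list[str]
    kind: str = "K_blend"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=_SYM_TOL, rtol=0):
            raise ValueError("kinship matrix is not symmetric to 1e-10")

    @property
    def n(self) -> int:
        return len(self.ids)

    def align(self, ids: list[str]) -> "KinshipMatrix":
        """Return the principal submatrix for ``ids`` in the given order."""
        index = {x: i for i, x in enumerate(self.ids)}
        missing = [x for x in ids if x not in index]
        if missing:
            raise KeyError(f"ids absent from kinship matrix: {missing[:5]}")
        idx = np.array([index[x] for x in ids])
        return KinshipMatrix(
            values=self.values[np.ix_(idx, idx)],
            ids=list(ids),
            kind=self.kind,
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class ScalingBounds:
    """Target range for map-minmax rescaling (defaults: the [0, 2] range of A)."""

    s_min: float = 0.0
    s_max: float = 2.0

    def __post_init__(self) -> None:
        if not self.s_max > self.s_min:
            raise ValueError("s_max must exceed s_min")


def filter_snps(
    g: GenotypeMatrix, maf_min: float = 0.01, call_rate_min: float = 0.95
) -> GenotypeMatrix:
    """Drop SNPs with minor-allele frequency below ``maf_min`` or call rate
    below ``call_rate_min`` (QC thresholds of the chicken study)."""
    p = g.allele_freq
    maf = np.minimum(p, 1.0 - p)
    low_maf = maf < maf_min
    low_call = g.call_rate < call_rate_min
    keep = ~(low_maf | low_call)
    logger.info(
        "SNP QC: %d/%d retained (%d low-MAF, %d low call rate)",
        int(keep.sum()), g.p, int(low_maf.sum()), int(low_call.sum()),
    )
    if not keep.any():
        raise ValueError("QC removed every SNP; no polymorphic panel left")
    if keep.all():
        return g
    return g.subset_snps(keep)


def impute_naive(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call with the SNP's mean dosage ``2 p_i``.

    A deliberately simple stand-in for haplotype-based imputation; the
    result is no longer integer-coded.
    """
    missing = np.isnan(g.codes)
    if not missing.any():
        return g
    if np.any(missing.all(axis=0)):
        bad = [s for s, m in zip(g.snp_ids, missing.all(axis=0)) if m]
        raise ValueError(f"SNP(s) with zero call rate cannot be imputed: {bad[:5]}")
    codes = g.codes.copy()
    fill = np.broadcast_to(2.0 * g.allele_freq, codes.shape)
    codes[missing] = fill[missing]
    return GenotypeMatrix(codes, list(g.individual_ids), list(g.snp_ids))


def center_genotypes(g: GenotypeMatrix) -> np.ndarray:
    """Column-centered genotype matrix ``W_ij = codes_ij - 2 p_j``."""
    if np.isnan(g.codes).any():
        raise ValueError("genotypes contain missing entries; impute first")
    return g.codes - 2.0 * g.allele_freq


def build_G_vanraden(g: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden genomic relationship matrix ``W W' / (2 sum p_i q_i)``."""
    W = center_genotypes(g)
    p = g.allele_freq
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic: VanRaden denominator is zero")
    G = (W @ W.T) / denom
    G = 0.5 * (G + G.T)
    return KinshipMatrix(G, list(g.individual_ids), kind="G_V",
                         meta={"denominator": denom, "n_snps": g.p})


def build_G_forni(g: GenotypeMatrix) -> KinshipMatrix:
    """Forni genomic relationship matrix ``W W' / (trace(W W') / m)``."""
    W = center_genotypes(g)
    WWt = W @ W.T
    m = g.n
    denom = np.trace(WWt) / m
    if denom <= 0:
        raise ValueError("trace(WW') is zero: Forni denominator undefined")
    G = WWt / denom
    G = 0.5 * (G + G.T)
    return KinshipMatrix(G, list(g.individual_ids), kind="G_F",
                         meta={"denominator": denom, "n_snps": g.p})


def minmax_scale(G: KinshipMatrix, bounds: ScalingBounds = ScalingBounds()) -> KinshipMatrix:
    """Entrywise affine map of G onto [s_min, s_max].

    ``Gs_ij = (s_max - s_min) * (G_ij - G_min) / (G_max - G_min) + s_min``
    using the global entrywise extrema (diagonal included).  The extreme
    entries map *exactly* onto the bounds.
    """
    gmin, gmax = G.values.min(), G.values.max()
    if gmax <= gmin:
        raise ValueError("constant kinship matrix cannot be min-max scaled")
    scaled = ((bounds.s_max - bounds.s_min) * (G.values - gmin)) / (gmax - gmin) + bounds.s_min
    scaled = 0.5 * (scaled + scaled.T)
    meta = dict(G.meta)
    meta.update({"scaled_from": G.kind, "s_min": bounds.s_min, "s_max": bounds.s_max,
                 "g_min": gmin, "g_max": gmax})
    return KinshipMatrix(scaled, list(G.ids), kind="G_scaled", meta=meta)


def blend_kernels(G: KinshipMatrix, A: KinshipMatrix, lam: float) -> KinshipMatrix:
    """Kinship kernel ``K = lam * G + (1 - lam) * A``.

    ``lam = 0`` returns A unchanged (pedigree BLUP) and ``lam = 1`` returns
    G unchanged, so endpoint results are bit-identical to the single-source
    kernels.  The blend is eigenvalue-checked; a slightly indefinite result
    (smallest eigenvalue in (-1e-6, 0)) is repaired by diagonal jitter,
    anything worse is an error.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"blend weight must be in [0, 1], got {lam}")
    if list(G.ids) != list(A.ids):
        raise ValueError(
            "id order mismatch between G and A; align explicitly before blending"
        )
    if lam == 0.0 or lam == 1.0:
        # endpoint: the single-source kernel, values untouched
        src = A if lam == 0.0 else G
        meta = dict(src.meta)
        meta.update({"lambda": lam, "g_kind": G.kind})
        return KinshipMatrix(src.values.copy(), list(src.ids), kind=src.kind, meta=meta)
    vals = lam * G.values + (1.0 - lam) * A.values
    vals = 0.5 * (vals + vals.T)
    meta = {"lambda": lam, "g_kind": G.kind}
    w_min = float(np.linalg.eigvalsh(vals)[0])
    if w_min < -1e-6:
        raise ValueError(
            f"blended kernel strongly indefinite (min eigenvalue {w_min:.3e})"
        )
    if w_min < 0.0:
        jitter = -w_min + 1e-12
        logger.info("PSD repair: adding %.3e to the blend diagonal", jitter)
        vals = vals + jitter * np.eye(len(A.ids))
        meta["psd_jitter"] = jitter
    return KinshipMatrix(vals, list(A.ids), kind="K_blend", meta=meta)
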