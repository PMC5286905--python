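"""Synthetic populations with known genetic architecture.

Generates a multi-generation half-sib/full-sib pedigree, gene-dropped
unlinked biallelic genotypes, true breeding values with a specified
among-trait genetic covariance Q, residuals with covariance R, and raw
phenotypes contaminated by additive categorical nuisance effects.  Every
downstream stage of the pipeline can therefore be checked against ground
truth.

Two genetic architectures are available:

``infinitesimal``
    Founder breeding values are multivariate normal with covariance Q;
    each offspring is the mid-parent average plus a Mendelian-sampling
    deviation with covariance ``0.5 * (1 - (F_s + F_d) / 2) * Q``.  The
    markers then carry family structure but no causal signal, so the
    pedigree model is the true model.

``pleiotropic_qtl``
    Breeding values are genotype-weighted sums over a random subset of
    loci with correlated per-QTL effect vectors, optionally mixed with an
    infinitesimal polygenic background whose among-trait correlation can
    differ from the QTL effect correlation.  Pedigree-based and
    marker-based correlation estimates can then be made to diverge in a
    chosen direction (missing / excessive / spurious correlation
    phenomena).

All randomness flows from one master seed, split into independent
substreams per stage (pedigree, genotypes, traits) so each stage is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinship import GenotypeMatrix
from .pedigree import Pedigree, inbreeding

__all__ = [
    "SimConfig",
    "SimDataset",
    "default_Q",
    "default_R",
    "simulate_pedigree",
    "gene_drop_genotypes",
    "simulate_traits",
    "simulate",
]


def _cov_from_corr(sd: np.ndarray, corr: np.ndarray) -> np.ndarray:
    return np.outer(sd, sd) * corr


def default_Q() -> np.ndarray:
    """Default 3x3 genetic covariance: unit phenotypic variances with
    heritabilities (0.2, 0.25, 0.3) and genetic correlations
    (0.5, -0.2, -0.2) — the trait structure of a broiler line with a
    growth/growth/reproduction trait trio."""
    h2 = np.array([0.2, 0.25, 0.3])
    rg = np.array([[1.0, 0.5, -0.2], [0.5, 1.0, -0.2], [-0.2, -0.2, 1.0]])
    return _cov_from_corr(np.sqrt(h2), rg)


def default_R() -> np.ndarray:
    """Default 3x3 residual covariance complementing :func:`default_Q`
    (unit phenotypic variances; residual correlations (0.5, -0.05, -0.05))."""
    r = np.array([0.8, 0.75, 0.7])
    re = np.array([[1.0, 0.5, -0.05], [0.5, 1.0, -0.05], [-0.05, -0.05, 1.0]])
    return _cov_from_corr(np.sqrt(r), re)


def _check_spd(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if np.linalg.eigvalsh(M)[0] <= 0:
        raise ValueError(f"{name} must be positive definite")
    return M


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic population.

    Defaults mimic the shape of a commercial broiler pedigree: a founder
    cohort, three non-overlapping offspring generations, dams nested
    within sires (half-sib families of full-sib groups), ~1000 unlinked
    SNPs, and three traits with moderate heritabilities.
    """

    n_founders: int = 120
    n_generations: int = 3
    offspring_per_mating: int = 5
    n_sires: int = 25
    n_dams: int = 75
    n_snps: int = 1000
    n_qtl: int = 100
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    Q_true: np.ndarray = field(default_factory=default_Q)
    R_true: np.ndarray = field(default_factory=default_R)
    architecture: str = "infinitesimal"
    qtl_effect_corr: np.ndarray | None = None
    qtl_variance_frac: float = 1.0
    polygenic_corr: np.ndarray | None = None
    nuisance_levels: dict = field(default_factory=lambda: {"sex": 2, "hatch_week": 6, "pen": 8})
    nuisance_sd: float = 0.5
    intercepts: np.ndarray | None = None
    trait_names: tuple[str, ...] | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_founders", "offspring_per_mating", "n_sires", "n_dams",
                     "n_snps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if not 0 <= self.n_qtl <= self.n_snps:
            raise ValueError("n_qtl must lie in [0, n_snps]")
        lo, hi = self.founder_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("founder_maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.qtl_variance_frac <= 1.0:
            raise ValueError("qtl_variance_frac must lie in [0, 1]")
        Q = _check_spd(self.Q_true, "Q_true")
        R = _check_spd(self.R_true, "R_true")
        if Q.shape != R.shape:
            raise ValueError("Q_true and R_true must have the same shape")
        object.__setattr__(self, "Q_true", Q)
        object.__setattr__(self, "R_true", R)
        T = Q.shape[0]
        names = self.trait_names or tuple(f"trait{t + 1}" for t in range(T))
        if len(names) != T:
            raise ValueError("trait_names length must match Q_true")
        object.__setattr__(self, "trait_names", tuple(names))
        ic = self.intercepts if self.intercepts is not None else np.zeros(T)
        ic = np.asarray(ic, dtype=float)
        if ic.shape != (T,):
            raise ValueError("intercepts must have one entry per trait")
        object.__setattr__(self, "intercepts", ic)
        if self.architecture not in ("infinitesimal", "pleiotropic_qtl"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.qtl_effect_corr is not None:
            C = _check_spd(self.qtl_effect_corr, "qtl_effect_corr")
            if C.shape != Q.shape:
                raise ValueError("qtl_effect_corr must be T x T")
            object.__setattr__(self, "qtl_effect_corr", C)
        if self.polygenic_corr is not None:
            C = _check_spd(self.polygenic_corr, "polygenic_corr")
            if C.shape != Q.shape:
                raise ValueError("polygenic_corr must be T x T")
            object.__setattr__(self, "polygenic_corr", C)

    @property
    def n_traits(self) -> int:
        return self.Q_true.shape[0]

    def substreams(self) -> dict[str, np.random.Generator]:
        """Independent per-stage RNGs derived from the master seed."""
        ped, geno, traits = np.random.SeedSequence(self.seed).spawn(3)
        return {
            "pedigree": np.random.default_rng(ped),
            "genotypes": np.random.default_rng(geno),
            "traits": np.random.default_rng(traits),
        }


@dataclass
class SimDataset:
    """A simulated population together with its generating truth."""

    pedigree: Pedigree
    genotypes: GenotypeMatrix
    true_breeding_values: np.ndarray
    phenotypes_raw: np.ndarray
    residuals: np.ndarray
    nuisance_assignments: pd.DataFrame
    nuisance_effects: np.ndarray
    truth: SimConfig

    @property
    def ids(self) -> list[str]:
        return list(self.pedigree.ids)

    def phenotype_frame(self) -> pd.DataFrame:
        """Raw phenotypes plus nuisance factor levels, indexed by id."""
        df = pd.DataFrame(
            self.phenotypes_raw, index=self.ids, columns=list(self.truth.trait_names)
        )
        df.index.name = "id"
        return pd.concat([df, self.nuisance_assignments], axis=1)

    def breeding_value_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.true_breeding_values, index=self.ids,
            columns=list(self.truth.trait_names),
        )
        df.index.name = "id"
        return df


def simulate_pedigree(config: SimConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Multi-generation pedigree with dams nested within sires.

    Each generation samples ``n_sires + n_dams`` distinct parents from the
    previous generation (no selfing possible), assigns each dam to one
    sire, and produces ``offspring_per_mating`` full sibs per mating, so
    each generation contributes ``n_dams`` full-sib groups grouped into
    half-sib families.
    """
    rng = rng or config.substreams()["pedigree"]
    ids: list[str] = [f"g0_{i + 1:04d}" for i in range(config.n_founders)]
    sire = [-1] * config.n_founders
    dam = [-1] * config.n_founders
    prev = list(range(config.n_founders))
    for g in range(1, config.n_generations + 1):
        need = config.n_sires + config.n_dams
        if len(prev) < need:
            raise ValueError(
                f"generation {g - 1} has {len(prev)} candidates but "
                f"{need} parents are required"
            )
        parents = rng.choice(len(prev), size=need, replace=False)
        sires = [prev[i] for i in parents[: config.n_sires]]
        dams = [prev[i] for i in parents[config.n_sires:]]
        sire_of_dam = rng.integers(0, config.n_sires, size=config.n_dams)
        cur = []
        k = 0
        for j, d in enumerate(dams):
            s = sires[sire_of_dam[j]]
            for _ in range(config.offspring_per_mating):
                k += 1
                cur.append(len(ids))
                ids.append(f"g{g}_{k:04d}")
                sire.append(s)
                dam.append(d)
        prev = cur
    return Pedigree(tuple(ids), np.array(sire, dtype=np.int64),
                    np.array(dam, dtype=np.int64))


def gene_drop_genotypes(
    pedigree: Pedigree, config: SimConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Drop alleles down the pedigree at unlinked biallelic loci.

    Founder allele frequencies are uniform on ``founder_maf_range``; each
    non-founder allele is a fair-coin copy of one of the corresponding
    parent's two alleles, independently per locus.
    """
    rng = rng or config.substreams()["genotypes"]
    n, p = pedigree.n, config.n_snps
    freq = rng.uniform(*config.founder_maf_range, size=p)
    hap = np.zeros((2, n, p), dtype=np.int8)
    for i in range(n):
        for which, parent in ((0, pedigree.sire[i]), (1, pedigree.dam[i])):
            if parent < 0:
                hap[which, i] = rng.random(p) < freq
            else:
                coin = rng.random(p) < 0.5
                hap[which, i] = np.where(coin, hap[0, parent], hap[1, parent])
    codes = (hap[0] + hap[1]).astype(float)
    if config.missing_rate > 0:
        mask = rng.random((n, p)) < config.missing_rate
        codes[mask] = np.nan
    snp_ids = [f"snp{j + 1:05d}" for j in range(p)]
    return GenotypeMatrix(codes, list(pedigree.ids), snp_ids)


def _drop_infinitesimal(
    pedigree: Pedigree, Q: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Breeding values under the infinitesimal model: founders ~ N(0, Q),
    offspring = mid-parent + Mendelian-sampling deviation whose covariance
    is reduced by parental inbreeding."""
    n, T = pedigree.n, Q.shape[0]
    F = inbreeding(pedigree).to_numpy()
    L = np.linalg.cholesky(Q)
    z = rng.standard_normal((n, T))
    g = np.zeros((n, T))
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        mid = np.zeros(T)
        if s >= 0:
            mid += 0.5 * g[s]
        if d >= 0:
            mid += 0.5 * g[d]
        if s >= 0 and d >= 0:
            msv = 0.5 * (1.0 - (F[s] + F[d]) / 2.0)
        elif s >= 0 or d >= 0:
            msv = 0.75 - 0.25 * F[s if s >= 0 else d]
        else:
            msv = 1.0
        g[i] = mid + np.sqrt(msv) * (L @ z[i])
    return g


def simulate_traits(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix | None,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> SimDataset:
    """Breeding values, residuals, nuisance effects, and raw phenotypes.

    In ``pleiotropic_qtl`` mode the QTL component is rescaled by a single
    scalar so its realized genetic covariance matches the targeted share of
    ``trace(Q_true)``; ``qtl_variance_frac < 1`` adds an infinitesimal
    polygenic background with correlation ``polygenic_corr`` carrying the
    remaining share.
    """
    rng = rng or config.substreams()["traits"]
    n, T = pedigree.n, config.n_traits
    Q, R = config.Q_true, config.R_true

    if config.architecture == "infinitesimal":
        g = _drop_infinitesimal(pedigree, Q, rng)
    else:
        if genotypes is None:
            raise ValueError("pleiotropic_qtl architecture requires genotypes")
        if config.n_qtl < 1:
            raise ValueError("pleiotropic_qtl architecture requires n_qtl >= 1")
        codes = genotypes.codes
        if np.isnan(codes).any():
            freq = genotypes.allele_freq
            codes = np.where(np.isnan(codes), 2.0 * freq, codes)
        W = codes - codes.mean(axis=0)
        qtl = rng.choice(genotypes.p, size=config.n_qtl, replace=False)
        C = config.qtl_effect_corr if config.qtl_effect_corr is not None else np.eye(T)
        beta = rng.standard_normal((config.n_qtl, T)) @ np.linalg.cholesky(C).T
        g_qtl = W[:, qtl] @ beta
        frac = config.qtl_variance_frac
        target = frac * np.trace(Q)
        realized = np.trace(np.cov(g_qtl, rowvar=False)) if config.n_qtl else 0.0
        if target > 0 and realized <= 0:
            raise ValueError("QTL component has zero realized variance")
        g = g_qtl * np.sqrt(target / realized) if target > 0 else np.zeros((n, T))
        if frac < 1.0:
            pc = config.polygenic_corr if config.polygenic_corr is not None else np.eye(T)
            sd = np.sqrt(np.diag(Q))
            Q_poly = (1.0 - frac) * _cov_from_corr(sd, pc)
            _check_spd(Q_poly + 1e-12 * np.eye(T), "polygenic covariance")
            g = g + _drop_infinitesimal(pedigree, Q_poly, rng)

    e = rng.standard_normal((n, T)) @ np.linalg.cholesky(R).T

    assign = {}
    nuis = np.zeros((n, T))
    for factor, levels in config.nuisance_levels.items():
        if levels < 2:
            raise ValueError(f"nuisance factor {factor!r} needs >= 2 levels")
        lev = rng.integers(0, levels, size=n)
        effects = rng.standard_normal((levels, T)) * (
            config.nuisance_sd * np.sqrt(np.diag(Q + R))
        )
        assign[factor] = lev
        nuis += effects[lev]
    assignments = pd.DataFrame(assign, index=list(pedigree.ids))
    assignments.index.name = "id"

    y = config.intercepts + nuis + g + e
    return SimDataset(
        pedigree=pedigree,
        genotypes=genotypes,
        true_breeding_values=g,
        phenotypes_raw=y,
        residuals=e,
        nuisance_assignments=assignments,
        nuisance_effects=nuis,
        truth=replace(config),
    )


def simulate(config: SimConfig) -> SimDataset:
    """Run all three stages (pedigree, genotypes, traits) from one seed."""
    streams = config.substreams()
    ped = simulate_pedigree(config, streams["pedigree"])
    geno = gene_drop_genotypes(ped, config, streams["genotypes"])
    return simulate_traits(ped, geno, config, streams["traits"])
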