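"""GBLUP machinery: VanRaden Method-1 GRM, mixed-model equations, PCs, back-solving.

The model is the single-record animal model

    y = Xb + Za + e,   a ~ N(0, G sigma_g^2),   e ~ N(0, I sigma_e^2)

with Z the identity (one record per individual). The GRM is Method 1,
G = Z_c Z_c' / (2 sum_j p_j (1 - p_j)) with Z_c = M - 2p the column-centered
allele counts (missing genotypes mean-imputed). SNP effects are recovered from
GEBVs by the Stranden-Garrick back-solve u = Z_c' G^-1 a / (2 sum p(1-p)),
using the centered gene content so that Z_c u reconstructs a exactly when G is
full rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .data_io import GenotypeMatrix, PhenotypeTable, SnpMap

log = logging.getLogger(__name__)

DEFAULT_RIDGE_FRACTION = 1e-6


class AllMissingError(ValueError):
    """A SNP column with no observed genotypes."""


class DegenerateGrmError(ValueError):
    """All SNPs monomorphic: the Method-1 scale is zero."""


class ConfoundedFixedEffectsError(ValueError):
    """Fixed-effect design matrix is rank deficient."""


def allele_freqs(geno: GenotypeMatrix) -> np.ndarray:
    """Frequency of the counted (second) allele per SNP: mean observed count / 2."""
    if geno.n_individuals < 1:
        raise ValueError("need at least one individual")
    observed = ~np.isnan(geno.values)
    n_obs = observed.sum(axis=0)
    if np.any(n_obs == 0):
        snp = geno.snp_ids[int(np.argmax(n_obs == 0))]
        raise AllMissingError(f"SNP {snp!r} has no observed genotypes")
    with np.errstate(invalid="ignore"):
        p = np.nansum(geno.values, axis=0) / (2.0 * n_obs)
    return p


@dataclass
class Grm:
    """VanRaden Method-1 genomic relationship matrix with its building blocks."""

    matrix: np.ndarray          # n x n, symmetric
    scale: float                # 2 sum_j p_j (1 - p_j)
    freqs: np.ndarray           # p_j per SNP
    zc: np.ndarray              # n x m centered gene content (M - 2p)
    individual_ids: np.ndarray
    map: SnpMap

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def subset(self, row_index: np.ndarray) -> "Grm":
        idx = np.asarray(row_index)
        return Grm(
            matrix=self.matrix[np.ix_(idx, idx)],
            scale=self.scale,
            freqs=self.freqs,
            zc=self.zc[idx],
            individual_ids=self.individual_ids[idx],
            map=self.map,
        )


def build_grm(geno: GenotypeMatrix) -> Grm:
    """Method-1 GRM. Missing genotypes are imputed to the column mean (2p)."""
    p = allele_freqs(geno)
    mono = (p == 0.0) | (p == 1.0)
    if np.any(mono):
        log.warning(
            "%d monomorphic SNPs contribute zero to the GRM scale: %s",
            int(mono.sum()),
            ", ".join(map(str, geno.snp_ids[mono][:10])) + ("..." if mono.sum() > 10 else ""),
        )
    scale = float(2.0 * np.sum(p * (1.0 - p)))
    if scale <= 0.0:
        raise DegenerateGrmError("all SNPs monomorphic; GRM scale is zero")
    m_imputed = np.where(np.isnan(geno.values), 2.0 * p, geno.values)
    zc = m_imputed - 2.0 * p
    g = (zc @ zc.T) / scale
    g = (g + g.T) / 2.0  # enforce exact symmetry against rounding
    return Grm(
        matrix=g,
        scale=scale,
        freqs=p,
        zc=zc,
        individual_ids=geno.individual_ids,
        map=geno.map,
    )


@dataclass(frozen=True)
class VarianceComponents:
    """Additive and residual variances; the shrinkage factor is their ratio."""

    sigma_g2: float
    sigma_e2: float

    def __post_init__(self) -> None:
        if self.sigma_g2 <= 0:
            raise ValueError("sigma_g2 must be positive")
        if self.sigma_e2 < 0:
            raise ValueError("sigma_e2 must be non-negative")

    @property
    def alpha(self) -> float:
        """Shrinkage factor alpha = sigma_e2 / sigma_g2."""
        return self.sigma_e2 / self.sigma_g2

    @classmethod
    def from_h2(cls, h2: float, var_pheno: float) -> "VarianceComponents":
        """Split a phenotypic variance by heritability: sigma_g2 = h2 * var_p."""
        if not 0 < h2 <= 1:
            raise ValueError("h2 must be in (0, 1]")
        return cls(sigma_g2=h2 * var_pheno, sigma_e2=(1.0 - h2) * var_pheno)


@dataclass
class GblupFit:
    """Solutions of the mixed model equations for one trait.

    ``ginv_a`` holds s = G^-1 a (solved without forming G^-1; see solve_mme),
    the quantity the Stranden-Garrick back-solve consumes.
    """

    b: np.ndarray
    a_hat: np.ndarray
    varcomps: VarianceComponents
    grm: Grm                 # restricted to the phenotyped individuals
    ginv_a: np.ndarray       # s with a = G s (equals G^-1 a for full-rank G)
    design_names: list[str]
    trait: str
    ridge: float = 0.0


def _check_full_rank(x: np.ndarray, names: list[str]) -> None:
    r = np.linalg.qr(x, mode="r")
    diag = np.abs(np.diag(r))
    tol = max(x.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    dependent = [names[i] for i in range(len(diag)) if diag[i] <= tol]
    if dependent:
        raise ConfoundedFixedEffectsError(
            f"fixed-effect design is rank deficient; dependent columns: {dependent}"
        )


def solve_mme(
    pheno: PhenotypeTable,
    grm: Grm,
    varcomps: VarianceComponents,
    ridge: float | None = None,
) -> GblupFit:
    """Solve the mixed model equations for fixed effects and GEBVs.

    The Henderson system, scaled by sigma_e2 (R = I sigma_e2, Z = I), is

        [X'X  X'            ] [b]   [X'y]
        [X    I + alpha G^-1] [a] = [y]

    It is solved through the substitution a = G s, which removes G^-1:

        [X'X  X'G        ] [b]   [X'y]
        [X    G + alpha I] [s] = [y]

    The transformed coefficient block G + alpha I is positive definite for
    any PSD G and alpha > 0, so the GRM is never inverted; this keeps the
    back-solve reconstruction identity Z_c u = a exact even though a Method-1
    GRM built from data-estimated frequencies is structurally singular (the
    centered gene content annihilates the ones vector). An explicit ``ridge``
    is added to G's diagonal beforehand if requested (or, logged, when
    alpha = 0 would make the block singular).
    """
    id_pos = {iid: i for i, iid in enumerate(grm.individual_ids)}
    try:
        idx = np.array([id_pos[iid] for iid in pheno.ids])
    except KeyError as e:
        raise KeyError(f"phenotyped individual {e.args[0]!r} absent from GRM") from None
    sub = grm.subset(idx)
    x = pheno.design
    _check_full_rank(x, pheno.design_names)
    n, p = x.shape[0], x.shape[1]
    alpha = varcomps.alpha
    used_ridge = float(ridge) if ridge is not None else 0.0
    g = sub.matrix
    if used_ridge == 0.0 and alpha == 0.0:
        used_ridge = DEFAULT_RIDGE_FRACTION * float(np.mean(np.diag(g)))
        log.warning(
            "alpha = 0 with a possibly singular GRM; adding ridge %.3g", used_ridge
        )
    if used_ridge:
        g = g + used_ridge * np.eye(n)
    coeff = np.empty((p + n, p + n))
    coeff[:p, :p] = x.T @ x
    coeff[:p, p:] = x.T @ g
    coeff[p:, :p] = x
    coeff[p:, p:] = g + alpha * np.eye(n)
    rhs = np.concatenate([x.T @ pheno.y, pheno.y])
    sol = np.linalg.solve(coeff, rhs)
    s = sol[p:]
    fit = GblupFit(
        b=sol[:p],
        a_hat=g @ s,
        varcomps=varcomps,
        grm=sub,
        ginv_a=s,
        design_names=list(pheno.design_names),
        trait=pheno.trait,
        ridge=used_ridge,
    )
    log.info(
        "MME solved for %s: n=%d, p=%d, alpha=%.4g, ridge=%.3g",
        pheno.trait, n, p, alpha, used_ridge,
    )
    return fit


def grm_pcs(grm: Grm, k: int) -> pd.DataFrame:
    """Top-k principal components (eigenvectors) of G, one row per individual.

    Sign convention: each eigenvector's largest-magnitude entry is positive.
    Intended to be appended to a phenotype table as numeric covariates for
    admixed populations.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > grm.n:
        raise ValueError(f"k={k} exceeds the number of individuals ({grm.n})")
    w, v = scipy.linalg.eigh(grm.matrix)
    order = np.argsort(w)[::-1][:k]
    vecs = v[:, order]
    for j in range(vecs.shape[1]):
        lead = np.argmax(np.abs(vecs[:, j]))
        if vecs[lead, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return pd.DataFrame(
        vecs, index=pd.Index(grm.individual_ids, name="id"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )


@dataclass
class SnpEffects:
    """Back-solved per-SNP effects aligned to a SNP map."""

    u_hat: np.ndarray
    map: SnpMap
    trait: str = ""

    def __post_init__(self) -> None:
        self.u_hat = np.asarray(self.u_hat, dtype=np.float64)
        if len(self.u_hat) != len(self.map):
            raise ValueError("effect vector length does not match the SNP map")
        if not np.all(np.isfinite(self.u_hat)):
            raise ValueError("SNP effects contain non-finite values")


def backsolve_effects(fit: GblupFit) -> SnpEffects:
    """Stranden-Garrick back-solve: u = Z_c' G^-1 a / (2 sum p(1-p)).

    Consumes s = G^-1 a straight from the MME solve (computed without forming
    G^-1), so u = Z_c' s / scale and the reconstruction Z_c u = G s = a holds
    to machine precision whenever no explicit ridge was requested.
    """
    if fit.grm.zc.shape[0] != len(fit.a_hat):
        raise ValueError("GEBV vector does not match the GRM individuals")
    u = fit.grm.zc.T @ fit.ginv_a / fit.grm.scale
    return SnpEffects(u_hat=u, map=fit.grm.map, trait=fit.trait)
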