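"""End-to-end orchestration of the two-step framework.

Step 1: genotypes + phenotypes -> GRM -> mixed-model solve per trait ->
back-solved SNP effects. Step 2: sliding-window correlation scan ->
permutation test -> classification. `run_full` drives both steps from a
RunConfig (loadable from YAML), persists artifacts and a run manifest, and
`summarize` condenses a ScanResult into the headline counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_io import (
    PhenotypeTable,
    read_genotypes,
    read_phenotypes,
    read_snp_map,
    write_effects,
    write_scan_table,
)
from .gblup import GblupFit, Grm, VarianceComponents, backsolve_effects, build_grm, grm_pcs, solve_mme
from .inference import PermutationPlan, ScanResult, run_inference
from .scan import ScanParams

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class TraitConfig:
    """Per-trait inputs: phenotype file, column names, and exactly one of
    (heritability, explicit variance components)."""

    phenotypes: str
    trait: str
    fixed: list[str] = field(default_factory=list)
    h2: float | None = None
    sigma_g2: float | None = None
    sigma_e2: float | None = None

    def validate(self) -> None:
        has_h2 = self.h2 is not None
        has_vc = self.sigma_g2 is not None and self.sigma_e2 is not None
        if has_h2 == has_vc:
            raise ValueError(
                f"trait {self.trait!r}: supply exactly one of h2 or (sigma_g2, sigma_e2)"
            )


@dataclass
class RunConfig:
    genotypes: str
    snp_map: str
    trait_a: TraitConfig
    trait_b: TraitConfig
    out_dir: str
    genotype_dialect: str = "tsv"
    window: int = 500
    step: int = 100
    n_perm: int = 10_000
    seed: int = 0
    scheme: str = "permute_both"
    global_r: float | None = None
    pc_count: int = 0
    ridge: float | None = None
    save_grm: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["trait_a"] = TraitConfig(**raw["trait_a"])
        raw["trait_b"] = TraitConfig(**raw["trait_b"])
        return cls(**raw)

    def validate(self) -> None:
        for p in (self.genotypes, self.snp_map, self.trait_a.phenotypes, self.trait_b.phenotypes):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        self.trait_a.validate()
        self.trait_b.validate()
        ScanParams(self.window, self.step)  # validates bounds


def varcomps_for(pheno: PhenotypeTable, tc: TraitConfig) -> VarianceComponents:
    """Explicit components, or an h2 split of the phenotypic variance after
    ordinary-least-squares adjustment for the fixed effects."""
    if tc.sigma_g2 is not None:
        return VarianceComponents(sigma_g2=tc.sigma_g2, sigma_e2=tc.sigma_e2)
    beta, *_ = np.linalg.lstsq(pheno.design, pheno.y, rcond=None)
    resid = pheno.y - pheno.design @ beta
    return VarianceComponents.from_h2(tc.h2, float(np.var(resid)))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def save_grm_files(grm: Grm, prefix: str | Path) -> None:
    """Persist a GRM as little-endian float64 row-major binary plus an id
    sidecar, and as GCTA-style lower-triangle text triplets."""
    prefix = Path(prefix)
    grm.matrix.astype("<f8").tofile(prefix.with_suffix(".grm.bin"))
    with open(prefix.with_suffix(".grm.id"), "w") as fh:
        for iid in grm.individual_ids:
            fh.write(f"{iid}\t{iid}\n")
    with open(prefix.with_suffix(".grm.txt"), "w") as fh:
        for i in range(grm.n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{grm.matrix[i, j]:.10g}\n")


def _fit_trait(
    pheno: PhenotypeTable, grm: Grm, tc: TraitConfig, pcs: pd.DataFrame | None, ridge
) -> GblupFit:
    if pcs is not None:
        aligned = pcs.loc[list(pheno.ids)].to_numpy()
        pheno = pheno.with_covariates(list(pcs.columns), aligned)
    vc = varcomps_for(pheno, tc)
    return solve_mme(pheno, grm, vc, ridge=ridge)


def run_full(config: RunConfig) -> ScanResult:
    """Execute the whole framework; artifacts land in ``config.out_dir``.

    Persists per-trait GEBVs and SNP effects, the scan table, optionally the
    GRM, and a manifest recording seed, parameters, package versions, input
    checksums and stage warnings. Any stage failure removes partial outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "read"
        snp_map = read_snp_map(config.snp_map)
        geno = read_genotypes(config.genotypes, dialect=config.genotype_dialect, snp_map=snp_map)
        pheno_a = read_phenotypes(
            config.trait_a.phenotypes, config.trait_a.trait, config.trait_a.fixed
        )
        pheno_b = read_phenotypes(
            config.trait_b.phenotypes, config.trait_b.trait, config.trait_b.fixed
        )

        stage = "grm"
        grm = build_grm(geno)
        if config.save_grm:
            save_grm_files(grm, out / "grm")
            written += [out / "grm.grm.bin", out / "grm.grm.id", out / "grm.grm.txt"]
        pcs = grm_pcs(grm, config.pc_count) if config.pc_count > 0 else None

        stage = "gblup"
        fits = {}
        for tc, pheno in ((config.trait_a, pheno_a), (config.trait_b, pheno_b)):
            fits[tc.trait] = _fit_trait(pheno, grm, tc, pcs, config.ridge)
            path = out / f"gebv_{tc.trait}.tsv"
            pd.DataFrame(
                {"id": fits[tc.trait].grm.individual_ids, "gebv": fits[tc.trait].a_hat}
            ).to_csv(path, sep="\t", index=False, float_format="%.10g")
            written.append(path)

        stage = "backsolve"
        effects = {}
        for name, fit in fits.items():
            effects[name] = backsolve_effects(fit)
            path = out / f"snp_effects_{name}.tsv"
            write_effects(effects[name], path)
            written.append(path)

        stage = "inference"
        global_sign = None
        if config.global_r is not None:
            if config.global_r == 0:
                raise ValueError("global_r must be nonzero to define a sign")
            global_sign = int(np.sign(config.global_r))
        result = run_inference(
            effects[config.trait_a.trait],
            effects[config.trait_b.trait],
            params=ScanParams(config.window, config.step),
            plan=PermutationPlan(n_perm=config.n_perm, seed=config.seed, scheme=config.scheme),
            global_sign=global_sign,
            trait_names=(config.trait_a.trait, config.trait_b.trait),
        )

        stage = "write"
        scan_path = out / "scan.tsv"
        write_scan_table(result, scan_path)
        written.append(scan_path)
        manifest = {
            "package_version": __version__,
            "numpy_version": np.__version__,
            "seed": config.seed,
            "n_perm": config.n_perm,
            "scheme": config.scheme,
            "window": config.window,
            "step": config.step,
            "pc_count": config.pc_count,
            "global_sign": result.global_sign,
            "alpha": {name: fit.varcomps.alpha for name, fit in fits.items()},
            "ridge": {name: fit.ridge for name, fit in fits.items()},
            "n_individuals": geno.n_individuals,
            "n_snps": geno.n_snps,
            "n_windows": len(result),
            "class_counts": result.class_counts(),
            "input_sha256": {
                "genotypes": _sha256(config.genotypes),
                "snp_map": _sha256(config.snp_map),
                "phenotypes_a": _sha256(config.trait_a.phenotypes),
                "phenotypes_b": _sha256(config.trait_b.phenotypes),
            },
        }
        manifest_path = out / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        written.append(manifest_path)
        return result
    except Exception as e:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {e}") from e


def summarize(result: ScanResult) -> dict:
    """Headline counts: significant vs neutral, driver vs antagonizing, and the
    extreme (largest |r|) window of each significant class with coordinates."""
    counts = result.class_counts()
    defined = counts["driver"] + counts["antagonizing"] + counts["neutral"]
    significant = counts["driver"] + counts["antagonizing"]
    out = {
        "total_windows": len(result),
        "defined_windows": defined,
        "significant": significant,
        "neutral": counts["neutral"],
        "undefined": counts["undefined"],
        "driver": counts["driver"],
        "antagonizing": counts["antagonizing"],
        "significant_pct": 100.0 * significant / defined if defined else float("nan"),
        "neutral_pct": 100.0 * counts["neutral"] / defined if defined else float("nan"),
        "global_sign": result.global_sign,
    }
    for klass in ("driver", "antagonizing"):
        members = [rec for rec in result.records if rec.klass == klass]
        if members:
            best = max(members, key=lambda rec: abs(rec.r))
            out[f"extreme_{klass}"] = {
                "r": best.r,
                "chromosome": best.window.chromosome,
                "start_bp": best.window.start_bp,
                "end_bp": best.window.end_bp,
            }
    return out
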