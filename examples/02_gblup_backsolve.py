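"""GBLUP and SNP-effect back-solving on simulated data.

Builds the VanRaden Method-1 GRM, solves the mixed model equations for one
trait, back-solves per-SNP effects, and verifies the reconstruction identity
Z_c u = a (the back-solved effects regenerate the GEBVs exactly).
"""

import numpy as np

import corrscan as cs

snp_map = cs.uniform_map(2, 600)
geno = cs.simulate_genotypes(300, snp_map, seed=11)
truth = cs.simulate_effect_structure(snp_map, [], background_rho=0.4, seed=12)
pheno, _ = cs.simulate_phenotypes(geno, truth, h2=(0.5, 0.5), seed=13)

grm = cs.build_grm(geno)
print(f"GRM: {grm.n} x {grm.n}, scale 2*sum p(1-p) = {grm.scale:.1f}")
print(f"mean GRM diagonal: {np.mean(np.diag(grm.matrix)):.3f} (~1 under HWE)")

# variance components from the target heritability of the adjusted phenotype
beta, *_ = np.linalg.lstsq(pheno.design, pheno.y, rcond=None)
var_adj = float(np.var(pheno.y - pheno.design @ beta))
vc = cs.VarianceComponents.from_h2(0.5, var_adj)
print(f"sigma_g2 = {vc.sigma_g2:.2f}, sigma_e2 = {vc.sigma_e2:.2f}, alpha = {vc.alpha:.2f}")

fit = cs.solve_mme(pheno, grm, vc)
effects = cs.backsolve_effects(fit)
rel = np.abs(grm.zc @ effects.u_hat - fit.a_hat).max() / np.abs(fit.a_hat).max()
print(f"GEBV sd: {fit.a_hat.std():.3f}; SNP-effect sd: {effects.u_hat.std():.2e}")
print(f"reconstruction max relative error |Zc u - a| / |a|: {rel:.2e}")
# The error is at machine precision: back-solving loses no information
# relative to the GEBVs, it only redistributes them over SNPs.
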