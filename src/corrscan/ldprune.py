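"""LD pruning to approximate linkage equilibrium, and a scan-consistency report.

Pruning follows the classic sliding-window recipe: within each window of
``window`` SNPs, any pair with squared Pearson genotype correlation above
``r2_max`` loses its later member; windows advance by ``step`` SNPs and passes
repeat until none removes a SNP. "LD > 0.5" is interpreted as r^2 > 0.5, the
pairwise-r^2 convention of standard pruning tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import GenotypeMatrix
from .inference import ScanResult

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PruneParams:
    window: int = 500
    step: int = 100
    r2_max: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.r2_max < 1.0):
            raise ValueError("r2_max must be in (0, 1)")
        if not (1 <= self.step <= self.window):
            raise ValueError("require 1 <= step <= window")


def _imputed_centered(geno: GenotypeMatrix) -> np.ndarray:
    vals = geno.values
    with np.errstate(invalid="ignore"):
        means = np.nanmean(vals, axis=0)
    filled = np.where(np.isnan(vals), means, vals)
    return filled - filled.mean(axis=0)


def _prune_block(zc: np.ndarray, params: PruneParams) -> np.ndarray:
    """Greedy left-to-right pruning of one chromosome block.

    Returns a boolean keep-mask over the block's local SNP indices.
    Deterministic: victim is always the later SNP in map order.
    """
    m = zc.shape[1]
    kept = list(range(m))
    norms = np.sqrt(np.einsum("ij,ij->j", zc, zc))
    while True:
        removed_any = False
        start = 0
        while start < len(kept):
            win = kept[start : start + params.window]
            if len(win) >= 2:
                cols = zc[:, win]
                nrm = norms[win]
                with np.errstate(invalid="ignore", divide="ignore"):
                    corr = (cols.T @ cols) / np.outer(nrm, nrm)
                r2 = np.square(np.nan_to_num(corr))
                alive = np.ones(len(win), dtype=bool)
                for i in range(len(win)):
                    if not alive[i]:
                        continue
                    hits = np.nonzero((r2[i, i + 1 :] > params.r2_max) & alive[i + 1 :])[0]
                    alive[i + 1 + hits] = False
                if not alive.all():
                    removed_any = True
                    dead = {win[j] for j in np.nonzero(~alive)[0]}
                    kept = [s for s in kept if s not in dead]
            start += params.step
        if not removed_any:
            break
    mask = np.zeros(m, dtype=bool)
    mask[kept] = True
    return mask


def ld_prune(geno: GenotypeMatrix, params: PruneParams | None = None) -> np.ndarray:
    """Prune SNPs to approximate linkage equilibrium; returns kept SNP ids.

    Works chromosome by chromosome in map order; monomorphic (zero-variance)
    columns never correlate with anything and are always retained.
    """
    params = params or PruneParams()
    zc = _imputed_centered(geno)
    keep = np.zeros(geno.n_snps, dtype=bool)
    for label, start, stop in geno.map.blocks:
        keep[start:stop] = _prune_block(zc[:, start:stop], params)
    log.info(
        "LD pruning kept %d of %d SNPs (window=%d, step=%d, r2>%g removed)",
        int(keep.sum()), geno.n_snps, params.window, params.step, params.r2_max,
    )
    return geno.snp_ids[keep]


def kept_index(geno: GenotypeMatrix, kept_ids: np.ndarray) -> np.ndarray:
    """Column indices of the kept SNPs, in map order."""
    kept = set(kept_ids)
    return np.array([i for i, s in enumerate(geno.snp_ids) if s in kept], dtype=np.intp)


def scan_consistency_report(full: ScanResult, pruned: ScanResult) -> dict:
    """Compare a pruned-genotype scan with the full scan.

    Each pruned window is matched to the full window (same chromosome) whose
    base-pair span contains its midpoint, nearest midpoint on ties. Reports the
    correlation of the matched r estimates and their sign-agreement fraction.
    """
    full_by_chrom: dict[str, list] = {}
    for rec in full.records:
        full_by_chrom.setdefault(rec.window.chromosome, []).append(rec)
    pairs: list[tuple[float, float]] = []
    for rec in pruned.records:
        candidates = full_by_chrom.get(rec.window.chromosome, [])
        overlapping = [
            c for c in candidates
            if c.window.start_bp <= rec.window.midpoint_bp <= c.window.end_bp
        ]
        if not overlapping:
            continue
        best = min(overlapping, key=lambda c: abs(c.window.midpoint_bp - rec.window.midpoint_bp))
        if np.isfinite(rec.r) and np.isfinite(best.r):
            pairs.append((rec.r, best.r))
    if not pairs:
        raise ValueError("no overlapping windows between the two scans (disjoint coordinates?)")
    arr = np.asarray(pairs)
    if len(arr) >= 2 and arr[:, 0].std() > 0 and arr[:, 1].std() > 0:
        r_corr = float(np.corrcoef(arr[:, 0], arr[:, 1])[0, 1])
    else:
        r_corr = float("nan")
    agree = float(np.mean(np.sign(arr[:, 0]) == np.sign(arr[:, 1])))
    return {
        "n_matched": len(arr),
        "r_correlation": r_corr,
        "sign_agreement": agree,
    }
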