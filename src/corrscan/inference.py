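"""Permutation null, Fisher's-Z difference test, Bonferroni correction,
driver/antagonizing classification and percentile ranking.

For each window the observed local correlation r is compared with the mean
r_p of its permutation distribution (genome-wide reshuffles of each trait's
effect vector). Both are Fisher-transformed and the standardized difference

    z = |Z_r - Z_rp| / sqrt(1/(n+3) + 1/(n-3)),   n = window size in SNPs

is referred to the standard normal for a two-tailed p-value. Windows passing
the Bonferroni-corrected 0.05 threshold are classified by the sign of r
relative to the global genetic correlation: same sign = driver, opposite =
antagonizing; non-significant windows are neutral. Significant windows are
ranked by |r| within each class, top first, as a percentage of the class size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .gblup import SnpEffects
from .scan import (
    ScanParams,
    Window,
    _check_aligned,
    scan_pair,
    window_index_matrix,
    windowed_correlations,
)

log = logging.getLogger(__name__)

SIGNIFICANCE_LEVEL = 0.05
_CLAMP = 1.0 - 1e-12


@dataclass(frozen=True)
class PermutationPlan:
    """Permutation-null settings.

    ``permute_both`` reshuffles each trait's genome-wide effect vector
    independently once per iteration; ``permute_one`` reshuffles only trait B.
    """

    n_perm: int = 10_000
    seed: int = 0
    scheme: str = "permute_both"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.scheme not in ("permute_both", "permute_one"):
            raise ValueError(f"unknown permutation scheme {self.scheme!r}")


@dataclass(frozen=True)
class WindowRecord:
    """One window's correlation, test statistics, class label and rank."""

    window: Window
    r: float
    r_p: float = float("nan")
    z_r: float = float("nan")
    z_rp: float = float("nan")
    z_diff: float = float("nan")
    p_raw: float = float("nan")
    p_adj: float = float("nan")
    klass: str = "undefined"
    rank_percent: float = float("nan")


@dataclass
class ScanResult:
    """Ordered window records for one trait pair plus the global-sign context."""

    records: list[WindowRecord]
    params: ScanParams
    global_sign: int
    trait_names: tuple[str, str] = ("trait_a", "trait_b")
    plan: PermutationPlan | None = None

    def __len__(self) -> int:
        return len(self.records)

    def class_counts(self) -> dict[str, int]:
        counts = {"driver": 0, "antagonizing": 0, "neutral": 0, "undefined": 0}
        for rec in self.records:
            counts[rec.klass] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            w = rec.window
            rows.append(
                {
                    "window_index": w.index,
                    "chromosome": w.chromosome,
                    "start_bp": w.start_bp,
                    "end_bp": w.end_bp,
                    "midpoint_bp": w.midpoint_bp,
                    "start_snp": w.abs_start,
                    "end_snp": w.abs_end,
                    "r": rec.r,
                    "r_p": rec.r_p,
                    "z_diff": rec.z_diff,
                    "p_raw": rec.p_raw,
                    "p_bonferroni": rec.p_adj,
                    "class": rec.klass,
                    "rank_percent": rec.rank_percent,
                }
            )
        return pd.DataFrame(rows)


def fisher_z(r):
    """Fisher's variance-stabilizing transform Z = arctanh(r) = 0.5 ln((1+r)/(1-r)).

    Values at or beyond +/-1 are clamped just inside the open interval with a
    warning (permutation means never reach +/-1 in practice).
    """
    arr = np.asarray(r, dtype=np.float64)
    if np.any(np.abs(arr) >= 1.0):
        warnings.warn("correlation at or beyond +/-1 clamped for Fisher transform")
        arr = np.clip(arr, -_CLAMP, _CLAMP)
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or out.ndim == 0 else out


def z_diff_pvalue(r: float, r_p: float, n: int) -> tuple[float, float]:
    """Standardized Fisher-Z difference and its two-tailed normal p-value.

    z = |Z_r - Z_rp| / sqrt(1/(n+3) + 1/(n-3)); p = 2 (1 - Phi(z)).
    """
    if n < 4:
        raise ValueError("window size n must be >= 4")
    se = np.sqrt(1.0 / (n + 3) + 1.0 / (n - 3))
    z = abs(fisher_z(r) - fisher_z(r_p)) / se
    p = 2.0 * norm.sf(z)
    return float(z), float(p)


def bonferroni(p_raw: float, tested: int) -> float:
    """Bonferroni-adjusted p-value: min(1, p_raw * tested)."""
    if tested < 1:
        raise ValueError("tested window count must be >= 1")
    return min(1.0, p_raw * tested)


def classify(r: float, significant: bool, global_sign: int) -> str:
    """Driver / antagonizing / neutral by sign agreement with the global correlation."""
    if global_sign not in (-1, 1):
        raise ValueError("global correlation sign (+1 or -1) required")
    if not significant or r == 0.0:
        # a significant exactly-zero r cannot arise from the Z test; mapped
        # defensively to neutral
        return "neutral"
    return "driver" if np.sign(r) == global_sign else "antagonizing"


def permutation_null(
    e1: SnpEffects,
    e2: SnpEffects,
    windows: list[Window],
    plan: PermutationPlan,
    permutation_source=None,
) -> np.ndarray:
    """Per-window mean of the permutation distribution of r (the null center r_p).

    Each iteration reshuffles the genome-wide effect vector(s) once and
    recomputes every window's correlation from that shared shuffle; the mean
    over iterations is returned. Deterministic given ``plan.seed``.

    ``permutation_source`` (testing hook) may supply an iterable of
    ``(perm_a, perm_b)`` index arrays used in place of random shuffles.
    """
    _check_aligned(e1, e2)
    if not windows:
        return np.empty(0)
    idx = window_index_matrix(windows)
    m = len(e1.map)
    acc = np.zeros(len(windows))
    rng = np.random.default_rng(plan.seed)
    source = iter(permutation_source) if permutation_source is not None else None
    for _ in range(plan.n_perm):
        if source is not None:
            p1, p2 = next(source)
        elif plan.scheme == "permute_both":
            p1 = rng.permutation(m)
            p2 = rng.permutation(m)
        else:  # permute_one: trait A untouched
            p1 = np.arange(m)
            p2 = rng.permutation(m)
        acc += windowed_correlations(e1.u_hat[p1], e2.u_hat[p2], idx)
    return acc / plan.n_perm


def rank_windows(records: list[WindowRecord]) -> list[WindowRecord]:
    """Percentile-rank significant windows by |r| within driver and antagonizing
    classes separately: top window gets the smallest value, 100 * position / size.
    Ties break by genome order. Neutral/undefined windows get no rank."""
    out = list(records)
    for klass in ("driver", "antagonizing"):
        members = [i for i, rec in enumerate(out) if rec.klass == klass]
        members.sort(key=lambda i: (-abs(out[i].r), out[i].window.index))
        size = len(members)
        for pos, i in enumerate(members, start=1):
            out[i] = replace(out[i], rank_percent=100.0 * pos / size)
    return out


def run_inference(
    e1: SnpEffects,
    e2: SnpEffects,
    params: ScanParams | None = None,
    plan: PermutationPlan | None = None,
    global_sign: int | None = None,
    trait_names: tuple[str, str] | None = None,
) -> ScanResult:
    """Full window-level inference for one trait pair.

    Composes the scan, the permutation null, the Fisher-Z difference test,
    Bonferroni correction (multiplier = windows with defined r), sign-based
    classification and within-class percentile ranking.

    ``global_sign`` is normally the sign of the externally estimated global
    genetic correlation; if omitted it falls back to the sign of the
    correlation between the two genome-wide effect vectors (logged).
    """
    params = params or ScanParams()
    plan = plan or PermutationPlan()
    if global_sign is None:
        g = np.corrcoef(e1.u_hat, e2.u_hat)[0, 1]
        if not np.isfinite(g) or g == 0.0:
            raise ValueError("cannot infer global correlation sign from effects")
        global_sign = int(np.sign(g))
        log.info(
            "global sign not supplied; using sign of genome-wide effect correlation "
            "(r=%.4f -> %+d)", g, global_sign,
        )
    if global_sign not in (-1, 1):
        raise ValueError("global correlation sign must be +1 or -1")

    windows, r = scan_pair(e1, e2, params)
    r_p = permutation_null(e1, e2, windows, plan)
    defined = np.isfinite(r)
    tested = int(defined.sum())
    records: list[WindowRecord] = []
    for i, w in enumerate(windows):
        if not defined[i]:
            records.append(WindowRecord(window=w, r=float("nan")))
            continue
        z_r = fisher_z(r[i])
        z_rp = fisher_z(r_p[i])
        z, p = z_diff_pvalue(r[i], r_p[i], w.size)
        p_adj = bonferroni(p, tested)
        significant = p_adj < SIGNIFICANCE_LEVEL
        records.append(
            WindowRecord(
                window=w,
                r=float(r[i]),
                r_p=float(r_p[i]),
                z_r=z_r,
                z_rp=z_rp,
                z_diff=z,
                p_raw=p,
                p_adj=p_adj,
                klass=classify(float(r[i]), significant, global_sign),
            )
        )
    records = rank_windows(records)
    result = ScanResult(
        records=records,
        params=params,
        global_sign=global_sign,
        trait_names=trait_names or (e1.trait or "trait_a", e2.trait or "trait_b"),
        plan=plan,
    )
    log.info("inference done: %s (tested=%d)", result.class_counts(), tested)
    return result
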