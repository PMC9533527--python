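"""Sliding-window layout and local correlations between two traits' SNP effects.

Windows are K SNPs long (default 500) and start every ``step`` SNPs (default
100) within each chromosome; they never span chromosome boundaries and only
full-length windows are formed. Each window's statistic is the plain Pearson
correlation of the two traits' effect slices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import AlignmentError, SnpMap
from .gblup import SnpEffects

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanParams:
    """Window length and step, both in SNPs."""

    window: int = 500
    step: int = 100

    def __post_init__(self) -> None:
        if not (1 <= self.step <= self.window):
            raise ValueError("require 1 <= step <= window")


@dataclass(frozen=True)
class Window:
    """One window: chromosome-local and genome-global SNP offsets plus bp span."""

    index: int
    chromosome: str
    start_idx: int       # 0-based inclusive, within the chromosome block
    end_idx: int
    start_bp: int
    end_bp: int
    midpoint_bp: float
    size: int
    abs_start: int       # 0-based inclusive, genome-wide
    abs_end: int


def make_windows(snp_map: SnpMap, params: ScanParams) -> list[Window]:
    """Enumerate full-length sliding windows chromosome by chromosome.

    A chromosome with fewer than ``window`` SNPs yields no windows (logged):
    the significance test assumes a fixed per-window SNP count. Trailing SNPs
    not covered by a full window are never formed into a short window.
    """
    k, step = params.window, params.step
    windows: list[Window] = []
    index = 0
    for label, start, stop in snp_map.blocks:
        n = stop - start
        if n < k:
            log.warning(
                "chromosome %s has %d SNPs (< window %d); no windows formed", label, n, k
            )
            continue
        for s in range(0, n - k + 1, step):
            a, b = start + s, start + s + k - 1
            sbp = int(snp_map.position[a])
            ebp = int(snp_map.position[b])
            windows.append(
                Window(
                    index=index,
                    chromosome=str(label),
                    start_idx=s,
                    end_idx=s + k - 1,
                    start_bp=sbp,
                    end_bp=ebp,
                    midpoint_bp=(sbp + ebp) / 2.0,
                    size=k,
                    abs_start=a,
                    abs_end=b,
                )
            )
            index += 1
    log.info("built %d windows (K=%d, step=%d) over %d SNPs", len(windows), k, step, len(snp_map))
    return windows


def window_correlation(u1: np.ndarray, u2: np.ndarray) -> float:
    """Pearson correlation of two equal-length effect slices.

    Returns NaN (undefined) when either slice has zero variance; such windows
    are excluded from significance testing downstream.
    """
    u1 = np.asarray(u1, dtype=np.float64)
    u2 = np.asarray(u2, dtype=np.float64)
    if u1.shape != u2.shape or u1.ndim != 1:
        raise ValueError("slices must be 1-D and of equal length")
    if len(u1) < 2:
        raise ValueError("need at least 2 SNPs to correlate")
    x = u1 - u1.mean()
    y = u2 - u2.mean()
    denom = np.sqrt((x @ x) * (y @ y))
    if denom == 0.0:
        return float("nan")
    return float((x @ y) / denom)


def window_index_matrix(windows: list[Window]) -> np.ndarray:
    """W x K matrix of genome-wide SNP indices, one row per window."""
    if not windows:
        return np.empty((0, 0), dtype=np.intp)
    k = windows[0].size
    starts = np.array([w.abs_start for w in windows], dtype=np.intp)
    return starts[:, None] + np.arange(k, dtype=np.intp)[None, :]


def windowed_correlations(x: np.ndarray, y: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Per-window Pearson correlations for all windows at once.

    ``idx`` is the W x K index matrix from :func:`window_index_matrix`.
    Zero-variance windows yield NaN.
    """
    if idx.size == 0:
        return np.empty(0)
    xs = x[idx]
    ys = y[idx]
    xc = xs - xs.mean(axis=1, keepdims=True)
    yc = ys - ys.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", xc, yc)
    denom = np.sqrt(np.einsum("ij,ij->i", xc, xc) * np.einsum("ij,ij->i", yc, yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / denom
    r[denom == 0.0] = np.nan
    return r


def _check_aligned(e1: SnpEffects, e2: SnpEffects) -> None:
    if e1.map != e2.map:
        i = e1.map.first_mismatch(e2.map)
        raise AlignmentError(
            f"effect maps differ at SNP index {i} "
            f"({e1.map.snp_id[i] if i is not None and i < len(e1.map) else '?'})"
        )


def scan_pair(
    e1: SnpEffects, e2: SnpEffects, params: ScanParams | None = None
) -> tuple[list[Window], np.ndarray]:
    """Window layout plus the observed local correlation r for every window."""
    params = params or ScanParams()
    _check_aligned(e1, e2)
    windows = make_windows(e1.map, params)
    r = windowed_correlations(e1.u_hat, e2.u_hat, window_index_matrix(windows))
    n_undef = int(np.isnan(r).sum())
    if n_undef:
        log.warning("%d windows have undefined correlation (zero-variance slice)", n_undef)
    return windows, r
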