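"""Reproducibility statistics for repetition-indexed perfusion maps.

Temporal standard error and coefficient of variation quantify per-voxel
signal stability across repetitions; the split-half spatial Spearman
correlation quantifies how reproducible the *pattern* of a CBF map is
when the acquisition is divided into two halves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

__all__ = [
    "RepetitionStack",
    "voxel_se",
    "voxel_cov",
    "mean_abs_cov",
    "split_half_rs",
    "retest_cov",
    "cov_histogram",
]


@dataclass
class RepetitionStack:
    """Real-valued maps stacked along a leading repetition axis, with a mask."""

    values: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim < 2:
            raise ValueError("values must be (n_rep, ...voxels...)")
        if self.mask is None:
            self.mask = np.ones(self.values.shape[1:], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape[1:]:
                raise ValueError("mask shape must match the voxel shape")

    @property
    def n_rep(self) -> int:
        return self.values.shape[0]


def voxel_se(stack: RepetitionStack) -> np.ndarray:
    """Temporal standard error per voxel: sample SD across reps / sqrt(n)."""
    if stack.n_rep < 2:
        raise ValueError("standard error needs at least 2 repetitions")
    sd = np.std(stack.values, axis=0, ddof=1)
    se = sd / np.sqrt(stack.n_rep)
    return np.where(stack.mask, se, np.nan)


def voxel_cov(stack: RepetitionStack, mean_threshold: float = 1e-6) -> np.ndarray:
    """Coefficient of variation per voxel, percent: 100 * SE / mean.

    Voxels whose |mean| falls below ``mean_threshold`` are numerically
    unstable (near-zero denominator) and come back NaN.
    """
    se = voxel_se(stack)
    mean = np.mean(stack.values, axis=0)
    valid = stack.mask & (np.abs(mean) > mean_threshold)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = 100.0 * se / mean
    return np.where(valid, cov, np.nan)


def mean_abs_cov(stack: RepetitionStack, rel_threshold: float = 0.2) -> float:
    """Robust scalar CoV summary: mean |CoV| over reliably-nonzero voxels.

    The voxelwise CoV is unbounded as the temporal mean crosses zero, which
    happens in voxels with no reproducible signal (and, under noisy
    suppression schemes, in artifact voxels whose sign flips).  For a
    stable map-level summary, voxels whose |mean| falls below
    ``rel_threshold`` times the masked median |mean| are excluded and the
    magnitude of the CoV is averaged over the rest.
    """
    mean = np.mean(stack.values, axis=0)
    med = np.nanmedian(np.abs(mean[stack.mask]))
    reliable = stack.mask & (np.abs(mean) > rel_threshold * med)
    cov = voxel_cov(RepetitionStack(stack.values, reliable))
    return float(np.nanmean(np.abs(cov[reliable])))


def split_half_rs(
    stack: RepetitionStack,
    map_pipeline: Callable[[np.ndarray], np.ndarray] | None = None,
) -> float:
    """Spatial Spearman correlation between first-half and second-half maps.

    The repetitions are split in acquisition order; ``map_pipeline`` turns
    each half-stack into a single map (default: mean across repetitions —
    pass the CBF pipeline to correlate quantitative maps).  Returns NaN
    with a warning-free exit when either half map is constant over the
    mask (rank correlation undefined).
    """
    if stack.n_rep < 2:
        raise ValueError("split-half needs at least 2 repetitions")
    if map_pipeline is None:
        map_pipeline = lambda half: np.mean(half, axis=0)
    half = stack.n_rep // 2
    map_a = map_pipeline(stack.values[:half])
    map_b = map_pipeline(stack.values[half : 2 * half])
    a, b = map_a[stack.mask], map_b[stack.mask]
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size < 3 or np.all(a == a[0]) or np.all(b == b[0]):
        return float("nan")
    rs = stats.spearmanr(a, b).statistic
    return float(rs)


def retest_cov(
    map_a: np.ndarray, map_b: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Voxelwise CoV (percent) of two repeated maps (SE/mean with n=2)."""
    stack = RepetitionStack(np.stack([map_a, map_b]), mask)
    return voxel_cov(stack)


def cov_histogram(
    cov_image: np.ndarray,
    bin_width: float = 1.0,
    upper: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Density-normalized histogram (area 1) of finite CoV values.

    Returns (bin_edges, density).  ``upper`` caps the histogram range;
    values above it fall into the last bin so tail mass is preserved.
    """
    vals = np.asarray(cov_image, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite values to histogram")
    if upper is not None:
        vals = np.clip(vals, None, upper)
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    density, edges = np.histogram(vals, bins=edges, density=True)
    return edges, density
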