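"""Perfusion quantification: single-delay CBF and multi-delay CBF + ATT.

Single-delay CBF uses the standard single-compartment model in which the
labeled bolus decays with the T1 of blood and tissue outflow is neglected:

    f = 6000 * lambda * dM * exp(PLD/T1b)
        / (2 * alpha * T1b[s] * M0 * (1 - exp(-tau/T1b)))

with f in mL/100g/min, lambda the blood-brain partition coefficient
(mL/g), alpha the effective labeling efficiency, tau the labeling
duration and T1b the longitudinal relaxation time of blood.

Multi-delay data are handled in two stages, mirroring common practice:
the arterial transit time (ATT) is estimated first from the
signal-weighted mean of the post-labeling delays (weighted delay, WD),
inverted through the kinetic model's theoretical WD(ATT) curve; CBF then
follows by a linear least-squares fit of the kinetic model amplitude at
the estimated ATT.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "KineticParams",
    "MultiDelaySeries",
    "buxton_signal",
    "cbf_single_delay",
    "weighted_delay",
    "WeightedDelayInverter",
    "att_from_wd",
    "cbf_from_multidelay",
    "fit_multidelay",
    "gaussian_smooth",
]

DEFAULT_PLDS: tuple[float, ...] = (100.0, 100.0, 1275.0, 1800.0, 2100.0)


@dataclass(frozen=True)
class KineticParams:
    """Physical constants of the single-compartment kinetic model.

    ``alpha`` is the *effective* labeling efficiency: the pCASL labeling
    efficiency (~0.85) multiplied by the inversion efficiency squared for
    the two background-suppression pulses the label experiences
    (0.85 * 0.93**2 by default).
    """

    lambda_bp: float = 0.9  # blood-brain partition coefficient, mL/g
    alpha: float = 0.85 * 0.93**2  # effective labeling efficiency
    t1_blood: float = 1664.0  # ms
    tau: float = 1800.0  # labeling duration, ms

    def __post_init__(self) -> None:
        if min(self.lambda_bp, self.alpha, self.t1_blood, self.tau) <= 0:
            raise ValueError("all kinetic parameters must be positive")
        if self.alpha > 1:
            raise ValueError("alpha must be <= 1")


@dataclass
class MultiDelaySeries:
    """Per-PLD perfusion-weighted differences plus the M0 reference.

    ``dm`` has shape (n_pld, ...voxels...); ``m0`` the voxel shape.
    Duplicate PLDs (e.g. two acquisitions at 100 ms) stay as separate
    entries and therefore enter every sum with their acquisition count.
    """

    plds: tuple[float, ...]
    dm: np.ndarray
    m0: np.ndarray

    def __post_init__(self) -> None:
        self.plds = tuple(float(p) for p in self.plds)
        self.dm = np.asarray(self.dm, dtype=float)
        self.m0 = np.asarray(self.m0, dtype=float)
        if self.dm.shape[0] != len(self.plds):
            raise ValueError(
                f"dm leading axis {self.dm.shape[0]} != number of PLDs {len(self.plds)}"
            )
        if self.dm.shape[1:] != self.m0.shape:
            raise ValueError("dm voxel shape must match m0 shape")


def buxton_signal(
    t: float | np.ndarray,
    f: float | np.ndarray,
    att: float | np.ndarray,
    kp: KineticParams = KineticParams(),
) -> np.ndarray:
    """Kinetic-model difference signal dM/M0 at time ``t`` ms after labeling onset.

    Zero before the bolus arrives (t < att); inflow ramp while the bolus
    is delivering (att <= t < att + tau); T1b decay of the accumulated
    bolus afterwards.  ``f`` is CBF in mL/100g/min.  Broadcasts over any
    mix of scalar/array arguments.
    """
    t = np.asarray(t, dtype=float)
    f = np.asarray(f, dtype=float)
    att = np.asarray(att, dtype=float)
    t1b = kp.t1_blood
    t1b_s = t1b / 1000.0
    k = 2.0 * kp.alpha * (f / 6000.0) * t1b_s * np.exp(-att / t1b) / kp.lambda_bp

    dt = t - att
    inflow = k * (1.0 - np.exp(-np.clip(dt, 0.0, None) / t1b))
    plateau = k * (1.0 - np.exp(-kp.tau / t1b)) * np.exp(-(dt - kp.tau) / t1b)
    out = np.where(dt < 0.0, 0.0, np.where(dt < kp.tau, inflow, plateau))
    return out[()] if out.ndim == 0 else out


def cbf_single_delay(
    dm: np.ndarray,
    m0: np.ndarray,
    pld: float,
    kp: KineticParams = KineticParams(),
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Closed-form single-delay CBF (mL/100g/min), assuming ATT <= PLD.

    Exact inverse of :func:`buxton_signal` in the post-bolus regime with
    att = 0.  Voxels with invalid M0 (mask False) are NaN.
    """
    dm = np.asarray(dm, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    t1b = kp.t1_blood
    t1b_s = t1b / 1000.0
    denom = 2.0 * kp.alpha * t1b_s * m0 * (1.0 - np.exp(-kp.tau / t1b))
    with np.errstate(invalid="ignore", divide="ignore"):
        f = 6000.0 * kp.lambda_bp * dm * np.exp(pld / t1b) / denom
    if mask is not None:
        f = np.where(mask, f, np.nan)
    return f


def weighted_delay(series: MultiDelaySeries, min_dm: float = 0.0) -> np.ndarray:
    """Signal-weighted mean delay per voxel: WD = sum(PLD*dM)/sum(dM).

    Duplicate PLDs contribute as separate terms (doubling their weight).
    Voxels whose summed dM is not positive carry no transit information
    and come back NaN.  ``min_dm`` optionally zeroes entries below a
    signal threshold before weighting.
    """
    plds = np.asarray(series.plds, dtype=float)
    dm = series.dm.copy()
    if min_dm > 0:
        dm = np.where(dm >= min_dm, dm, 0.0)
    shape = (len(plds),) + (1,) * (dm.ndim - 1)
    num = np.sum(plds.reshape(shape) * dm, axis=0)
    den = np.sum(dm, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        wd = num / den
    return np.where(den > 0, wd, np.nan)


class WeightedDelayInverter:
    """Theoretical WD(att) curve for a protocol, inverted by interpolation.

    The curve is built by evaluating the kinetic model (unit CBF — WD is
    flow-independent) at the protocol's PLDs over an ATT grid, restricted
    to its largest strictly monotone window before inversion.
    """

    def __init__(
        self,
        plds: Sequence[float],
        kp: KineticParams = KineticParams(),
        att_grid: np.ndarray | None = None,
    ) -> None:
        self.plds = tuple(float(p) for p in plds)
        self.kp = kp
        if att_grid is None:
            att_grid = np.arange(0.0, 3000.0 + 1e-9, 10.0)
        readouts = np.asarray(self.plds) + kp.tau
        sig = buxton_signal(
            readouts[None, :], 60.0, att_grid[:, None], kp
        )  # (n_att, n_pld)
        total = sig.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            wd = (sig * np.asarray(self.plds)[None, :]).sum(axis=1) / total
        valid = total > 0
        att_grid, wd = att_grid[valid], wd[valid]
        # largest window on which the map is strictly increasing
        rising = np.diff(wd) > 0
        best_lo = best_hi = 0
        lo = 0
        for i, r in enumerate(np.append(rising, False)):
            if not r:
                if i - lo > best_hi - best_lo:
                    best_lo, best_hi = lo, i
                lo = i + 1
        self.att_grid = att_grid[best_lo : best_hi + 1]
        self.wd_grid = wd[best_lo : best_hi + 1]
        if self.att_grid.size < 2:
            raise ValueError("WD(att) has no monotone window for this protocol")

    def __call__(self, wd: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Invert WD -> ATT (ms); returns (att, clamped) arrays.

        Values outside the curve's range clamp to the grid ends and are
        flagged.  NaN inputs propagate.
        """
        wd = np.asarray(wd, dtype=float)
        att = np.interp(wd, self.wd_grid, self.att_grid)
        clamped = (wd < self.wd_grid[0]) | (wd > self.wd_grid[-1])
        att = np.where(np.isnan(wd), np.nan, att)
        return att, clamped & ~np.isnan(wd)


def att_from_wd(
    wd: np.ndarray,
    plds: Sequence[float] = DEFAULT_PLDS,
    kp: KineticParams = KineticParams(),
) -> np.ndarray:
    """Convenience wrapper: invert weighted delays to ATT for a protocol."""
    att, _ = WeightedDelayInverter(plds, kp)(wd)
    return att


def cbf_from_multidelay(
    series: MultiDelaySeries,
    att: np.ndarray,
    kp: KineticParams = KineticParams(),
) -> np.ndarray:
    """CBF by linear least squares at a fixed per-voxel ATT.

    The kinetic model is linear in f, so with model shapes
    m_i = buxton_signal(tau + PLD_i; f=1, att) the optimum is
    f = sum(dM_i/M0 * m_i) / sum(m_i^2).  Voxels where the model has no
    support (ATT beyond every readout) or ATT is NaN come back NaN.
    """
    att = np.asarray(att, dtype=float)
    readouts = np.asarray(series.plds) + kp.tau
    shape = (len(series.plds),) + (1,) * att.ndim
    m = buxton_signal(readouts.reshape(shape), 1.0, att[None], kp)
    with np.errstate(invalid="ignore", divide="ignore"):
        dm_frac = series.dm / series.m0
        num = np.sum(dm_frac * m, axis=0)
        den = np.sum(m * m, axis=0)
        f = num / den
    return np.where(den > 0, f, np.nan)


def fit_multidelay(
    series: MultiDelaySeries,
    kp: KineticParams = KineticParams(),
    min_dm: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Full multi-delay pipeline: weighted delay -> ATT -> CBF.

    Returns (cbf, att) maps.
    """
    wd = weighted_delay(series, min_dm=min_dm)
    att = att_from_wd(wd, series.plds, kp)
    cbf = cbf_from_multidelay(series, att, kp)
    return cbf, att


def gaussian_smooth(
    image: np.ndarray,
    voxel_size: Sequence[float],
    fwhm_mm: float = 3.0,
) -> np.ndarray:
    """Separable Gaussian smoothing with a FWHM specified in millimetres.

    sigma = FWHM / (2*sqrt(2*ln 2)) per axis, converted to voxels; edges
    use nearest replication.  NaNs are smoothed with mask renormalization
    so masked-out voxels do not bleed zeros into their neighbours.
    """
    image = np.asarray(image, dtype=float)
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigmas = [sigma_mm / vs for vs in voxel_size]
    if len(sigmas) != image.ndim:
        raise ValueError("voxel_size length must match image dimensionality")
    nan = np.isnan(image)
    if not nan.any():
        return ndimage.gaussian_filter(image, sigmas, mode="nearest")
    filled = np.where(nan, 0.0, image)
    smoothed = ndimage.gaussian_filter(filled, sigmas, mode="nearest")
    weight = ndimage.gaussian_filter((~nan).astype(float), sigmas, mode="nearest")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = smoothed / weight
    return np.where(nan, np.nan, out)
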