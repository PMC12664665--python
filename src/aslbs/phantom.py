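"""Digital brain phantom with pulsatile CSF for end-to-end ASL testing.

The phantom is a coarse compartmental head: a white-matter core ellipsoid
inside a gray-matter shell, lateral-ventricle ellipsoids, an outer CSF
rim (subarachnoid space) and an inferior CSF blob standing in for the
basal cisterns near the brainstem, where pulsation is strongest in vivo.

Each simulated acquisition emits complex control/label volume pairs plus
a noiseless complex M0 reference:

* static tissue signal = per-tissue M0 times the scheme's residual
  longitudinal magnetization at excitation (signed),
* the CSF static signal fluctuates multiplicatively between repetitions
  (cardiac-driven pulsation), and drifts *within* the echo train, which —
  because the z axis is the 3D partition-encoding direction — ghosts CSF
  fluctuation into neighbouring slices after the inverse FFT,
* the perfusion difference injected between control and label is the
  kinetic-model signal for the voxel's true CBF/ATT,
* everything is rotated by a smooth receive-phase field plus a small
  per-volume global phase jitter, and complex Gaussian noise is added.

This emulates the artifact phenomenology that motivates CSF-focused
background suppression; it does not model echo-train T2 decay, motion, or
B0/B1 inhomogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .bloch import BSSequenceTiming, PulseEfficiency, TissueRelaxation, residual_mz
from .quantify import KineticParams, buxton_signal
from .recon import ComplexVolumeSeries

__all__ = [
    "PhantomSpec",
    "AcquisitionSpec",
    "Phantom",
    "SimulatedAcquisition",
    "make_phantom",
    "simulate_acquisition",
    "protocol_presets",
]

TISSUE_LABELS = {"GM": 1, "WM": 2, "CSF": 3}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue parameters and noise model of the digital phantom.

    Tissue M0 values are arbitrary units relative to GM = 1 (CSF is
    brighter because of its long T2 and full water content); CBF and ATT
    defaults are typical adult gray/white values.  ``pulsation_amplitude``
    is the fractional standard deviation of the inter-repetition CSF
    signal fluctuation.
    """

    grid: tuple[int, int, int] = (64, 64, 36)
    voxel_size: tuple[float, float, float] = (3.4, 3.4, 4.0)
    m0: Mapping[str, float] = field(
        default_factory=lambda: {"GM": 1.0, "WM": 0.7, "CSF": 1.2}
    )
    cbf: Mapping[str, float] = field(
        default_factory=lambda: {"GM": 60.0, "WM": 20.0, "CSF": 0.0}
    )
    att: Mapping[str, float] = field(
        default_factory=lambda: {"GM": 1200.0, "WM": 1600.0, "CSF": 0.0}
    )
    ventricle_semiaxes: tuple[float, float, float] = (3.0, 8.0, 4.0)
    cbf_texture: float = 0.25  # fractional smooth spatial CBF heterogeneity
    pulsation_amplitude: float = 0.2
    phase_jitter_sd: float = 0.05  # rad, per-volume global phase wobble
    noise_sd: float = 0.002  # a.u. per channel (real/imag)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 8 for n in self.grid):
            raise ValueError("grid too small for the compartment geometry")
        if self.pulsation_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes must be non-negative")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Protocol skeleton: labeling duration, PLD list, repetitions, readout."""

    plds: tuple[float, ...]
    label_duration: float = 1800.0
    n_pairs: int = 20
    shot_mode: str = "single_shot"
    n_segments: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.shot_mode not in ("single_shot", "segmented"):
            raise ValueError(f"unknown shot_mode {self.shot_mode!r}")
        if self.shot_mode == "segmented" and self.n_segments < 2:
            raise ValueError("segmented mode needs n_segments >= 2")
        object.__setattr__(self, "plds", tuple(float(p) for p in self.plds))


@dataclass
class Phantom:
    """Materialized phantom: label volume, per-compartment masks, truth maps."""

    spec: PhantomSpec
    labels: np.ndarray  # 0 background, 1 GM, 2 WM, 3 CSF
    m0_map: np.ndarray
    cbf_map: np.ndarray
    att_map: np.ndarray
    phase_field: np.ndarray

    def mask(self, tissue: str) -> np.ndarray:
        return self.labels == TISSUE_LABELS[tissue]

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class SimulatedAcquisition:
    """Output of one simulated scan session."""

    control: np.ndarray  # complex, (n_pld, n_pairs, nx, ny, nz)
    label: np.ndarray
    m0: np.ndarray  # complex, (nx, ny, nz)
    plds: tuple[float, ...]
    timings: list[BSSequenceTiming]
    truth_dm: np.ndarray  # noiseless dM/M0-scaled difference, (n_pld, nx, ny, nz)

    def series(self, pld_index: int = 0) -> tuple[
        ComplexVolumeSeries, ComplexVolumeSeries, ComplexVolumeSeries
    ]:
        """(control, label, m0) series objects for one PLD."""
        return (
            ComplexVolumeSeries(self.control[pld_index], role="control"),
            ComplexVolumeSeries(self.label[pld_index], role="label"),
            ComplexVolumeSeries(self.m0, role="m0"),
        )


def _ellipsoid(
    grid: tuple[int, int, int],
    center: tuple[float, float, float],
    semiaxes: tuple[float, float, float],
) -> np.ndarray:
    coords = np.indices(grid, dtype=float)
    acc = np.zeros(grid)
    for c, ctr, ax in zip(coords, center, semiaxes):
        if ax <= 0:
            return np.zeros(grid, dtype=bool)
        acc += ((c - ctr) / ax) ** 2
    return acc <= 1.0


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> Phantom:
    """Build the compartment masks and truth parameter maps.

    Fully deterministic given the spec (the seed only drives the smooth
    receive-phase field, so identical specs give bit-identical phantoms).
    """
    nx, ny, nz = spec.grid
    center = (nx / 2, ny / 2, nz / 2)

    outer = (0.42 * nx, 0.46 * ny, 0.44 * nz)
    brain = _ellipsoid(spec.grid, center, outer)
    # the subarachnoid rim is a fixed fraction of the brain radius so the
    # CSF volume fraction stays grid-independent (~15-25% of brain)
    inner = _ellipsoid(spec.grid, center, tuple(0.94 * ax for ax in outer))
    rim = brain & ~inner
    wm = _ellipsoid(spec.grid, center, (0.22 * nx, 0.28 * ny, 0.25 * nz))
    vent_l = _ellipsoid(
        spec.grid, (nx / 2 - 0.1 * nx, ny / 2, nz / 2), spec.ventricle_semiaxes
    )
    vent_r = _ellipsoid(
        spec.grid, (nx / 2 + 0.1 * nx, ny / 2, nz / 2), spec.ventricle_semiaxes
    )
    blob = _ellipsoid(
        spec.grid, (nx / 2, ny / 2 - 0.18 * ny, 0.16 * nz), (0.1 * nx, 0.1 * ny, 0.12 * nz)
    )

    csf = (rim | vent_l | vent_r | blob) & brain
    wm = wm & brain & ~csf
    gm = brain & ~csf & ~wm
    if not (gm.any() and wm.any() and csf.any()):
        raise ValueError("degenerate geometry: an expected compartment is empty")

    labels = np.zeros(spec.grid, dtype=np.int16)
    labels[gm] = TISSUE_LABELS["GM"]
    labels[wm] = TISSUE_LABELS["WM"]
    labels[csf] = TISSUE_LABELS["CSF"]

    m0_map = np.zeros(spec.grid)
    cbf_map = np.zeros(spec.grid)
    att_map = np.zeros(spec.grid)
    for tissue, lab in TISSUE_LABELS.items():
        sel = labels == lab
        m0_map[sel] = spec.m0[tissue]
        cbf_map[sel] = spec.cbf[tissue]
        att_map[sel] = spec.att[tissue]

    rng = np.random.default_rng(spec.seed)
    if spec.cbf_texture > 0:
        # smooth multiplicative CBF heterogeneity: real perfusion maps are
        # not piecewise constant, and split-half spatial correlation is
        # only meaningful when the truth has spatial structure
        from scipy import ndimage

        field = ndimage.gaussian_filter(
            rng.standard_normal(spec.grid), sigma=2.0, mode="wrap"
        )
        field /= max(field.std(), 1e-12)
        cbf_map *= np.clip(1.0 + spec.cbf_texture * field, 0.2, None)

    coeff = rng.uniform(-1.0, 1.0, size=3)
    xs, ys, zs = np.indices(spec.grid, dtype=float)
    phase_field = 0.5 * (
        coeff[0] * xs / nx + coeff[1] * ys / ny + coeff[2] * zs / nz
    )  # smooth, sub-radian receive phase

    return Phantom(
        spec=spec,
        labels=labels,
        m0_map=m0_map,
        cbf_map=cbf_map,
        att_map=att_map,
        phase_field=phase_field,
    )


def _segment_slices(nz: int, n_segments: int) -> list[slice]:
    edges = np.linspace(0, nz, n_segments + 1).astype(int)
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def _pulsation_field(rng: np.random.Generator, grid: tuple[int, int, int]) -> np.ndarray:
    """Smooth unit-SD random field: the per-volume CSF pulsation state.

    Pulsation amplitude and phase differ between the ventricles, the basal
    cisterns and the subarachnoid space, so the fluctuation is modeled as
    a spatially correlated field rather than a single global draw.
    """
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.standard_normal(grid), sigma=2.0, mode="wrap")
    return field / max(field.std(), 1e-12)


def _pulsed_csf_volume(
    csf_static: np.ndarray,
    amp: float,
    eta: np.ndarray,
    drifts: np.ndarray,
    segments: list[slice],
) -> np.ndarray:
    """CSF static contribution for one volume, pulsated and z-ghosted.

    ``eta`` is the per-volume pulsation field; ``drifts`` holds one
    within-shot drift draw per k-space segment.  The within-shot drift is
    a linear ramp of peak amplitude amp/2 across each segment's kz lines,
    applied in the z-frequency domain, which convolves the CSF signal
    with a ghosting kernel along z.
    """
    vol = csf_static * (1.0 + amp * eta)
    if amp == 0.0:
        return vol
    spectrum = np.fft.fft(vol, axis=-1)
    nz = vol.shape[-1]
    modulation = np.ones(nz)
    for seg, drift in zip(segments, drifts):
        n = seg.stop - seg.start
        if n < 2:
            continue
        ramp = np.linspace(-1.0, 1.0, n)
        modulation[seg] = 1.0 + (amp / 2.0) * drift * ramp
    ghosted = np.fft.ifft(spectrum * modulation, axis=-1)
    return np.real(ghosted)


def simulate_acquisition(
    phantom: Phantom,
    acq: AcquisitionSpec,
    timings: BSSequenceTiming | Sequence[BSSequenceTiming],
    eff: PulseEfficiency = PulseEfficiency(),
    t1s: TissueRelaxation = TissueRelaxation(),
    kp: KineticParams | None = None,
) -> SimulatedAcquisition:
    """Simulate complex control/label series for a protocol on the phantom.

    ``timings`` is one BS timing applied to every PLD, or one per PLD
    (e.g. from :func:`aslbs.optimizer.per_pld_schedule`).  All randomness
    (pulsation, phase jitter, thermal noise) comes from a generator seeded
    by ``phantom.spec.seed``, so identical inputs give bit-identical
    outputs.
    """
    spec = phantom.spec
    if isinstance(timings, BSSequenceTiming):
        timings = [timings] * len(acq.plds)
    timings = list(timings)
    if len(timings) != len(acq.plds):
        raise ValueError("need one BS timing per PLD (or a single shared one)")
    if kp is None:
        kp = KineticParams(tau=acq.label_duration)

    nz = spec.grid[2]
    n_seg = acq.n_segments if acq.shot_mode == "segmented" else 1
    segments = _segment_slices(nz, n_seg)
    t1_map = t1s.as_dict()
    rng = np.random.default_rng(spec.seed + 1)  # offset: phase field used seed

    csf_sel = phantom.mask("CSF")
    m0_csf = np.where(csf_sel, phantom.m0_map, 0.0)
    phase = np.exp(1j * phantom.phase_field)

    n_pld, n_pairs = len(acq.plds), acq.n_pairs
    control = np.empty((n_pld, n_pairs, *spec.grid), dtype=complex)
    label = np.empty_like(control)
    truth_dm = np.empty((n_pld, *spec.grid))

    for ip, (pld, timing) in enumerate(zip(acq.plds, timings)):
        if abs(timing.readout_time - (acq.label_duration + pld)) > 1e-6:
            raise ValueError(
                f"timing readout {timing.readout_time} ms does not match "
                f"label_duration + PLD = {acq.label_duration + pld} ms"
            )
        residual = {
            tissue: residual_mz(timing, t1, eff) for tissue, t1 in t1_map.items()
        }
        static = np.zeros(spec.grid)
        for tissue in ("GM", "WM"):
            static[phantom.mask(tissue)] = (
                spec.m0[tissue] * residual[tissue]
            )
        csf_static = m0_csf * residual["CSF"]

        dm = phantom.m0_map * np.asarray(
            buxton_signal(
                acq.label_duration + pld, phantom.cbf_map, phantom.att_map, kp
            )
        )
        truth_dm[ip] = dm

        for rep in range(n_pairs):
            for is_label in (False, True):
                eta = _pulsation_field(rng, spec.grid)
                drifts = rng.standard_normal(n_seg)
                jitter = rng.normal(0.0, spec.phase_jitter_sd)
                csf_vol = _pulsed_csf_volume(
                    csf_static, spec.pulsation_amplitude, eta, drifts, segments
                )
                real_part = static + csf_vol + (0.0 if is_label else dm)
                vol = real_part * phase * np.exp(1j * jitter)
                if spec.noise_sd > 0:
                    vol = vol + (
                        rng.normal(0.0, spec.noise_sd, spec.grid)
                        + 1j * rng.normal(0.0, spec.noise_sd, spec.grid)
                    )
                (label if is_label else control)[ip, rep] = vol

    m0_vol = phantom.m0_map * phase
    return SimulatedAcquisition(
        control=control,
        label=label,
        m0=m0_vol,
        plds=acq.plds,
        timings=timings,
        truth_dm=truth_dm,
    )


def protocol_presets() -> dict[str, AcquisitionSpec]:
    """Named acquisition protocols used throughout the package.

    ``study1_singleshot`` and ``study1_segmented`` are single-delay
    protocols (labeling 1800 ms, PLD 2200 ms) with 20 and 12 control/label
    pairs; ``study2_multidelay`` is the five-delay protocol with PLDs
    100, 100, 1275, 1800 and 2100 ms (the 100 ms delay acquired twice).
    """
    return {
        "study1_singleshot": AcquisitionSpec(
            plds=(2200.0,), label_duration=1800.0, n_pairs=20,
            shot_mode="single_shot", name="study1_singleshot",
        ),
        "study1_segmented": AcquisitionSpec(
            plds=(2200.0,), label_duration=1800.0, n_pairs=12,
            shot_mode="segmented", n_segments=4, name="study1_segmented",
        ),
        "study2_multidelay": AcquisitionSpec(
            plds=(100.0, 100.0, 1275.0, 1800.0, 2100.0), label_duration=1800.0,
            n_pairs=8, shot_mode="segmented", n_segments=4,
            name="study2_multidelay",
        ),
    }


def get_preset(name: str) -> AcquisitionSpec:
    presets = protocol_presets()
    if name not in presets:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(presets)}"
        )
    return presets[name]
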