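# Methods

## Longitudinal-magnetization model

A background-suppressed pCASL experiment is reduced to a sequence of
instantaneous events acting on the longitudinal magnetization Mz,
expressed as a signed fraction of equilibrium:

1. pre-saturation at t = 0: Mz = 1 − s, with saturation efficiency
   s = 1 by default (ideal crusher, no residual stated for the reference
   designs);
2. T1 recovery between events: Mz(t+Δ) = 1 − (1 − Mz(t))·e^(−Δ/T1);
3. each inversion at its TI (measured from pre-saturation):
   Mz → −β·Mz, with inversion efficiency β.

Pulse durations, slice profiles, B0/B1 inhomogeneity and transverse
magnetization are outside the model. The residual signal is Mz at the
readout time τ + PLD. Default compartment T1s at 3 T: gray matter
1209 ms, white matter 758 ms, CSF 4308 ms, blood 1664 ms.

**Inversion efficiency.** Vendor sequences do not publish β. It is
recovered by `bloch.calibrate_efficiency`, which minimizes the maximum
absolute difference between simulated and observed residual percentages
over a β grid (coarse step 0.005 on [0.80, 1.00], two rounds of tenfold
local refinement, smallest-β tie-break). Against the bundled reference
table for the 1800/2200 ms protocol this lands at β = 0.9305, at which
every one of the nine scheme × tissue cells reproduces the published
value at one-decimal rounding; at β = 0.93 flat, eight of nine cells
round-match and the worst deviation is 0.06 percentage points. The
package default is 0.93; calibration is a one-liner when exactness
matters.

An independent event-stepping simulator (fine time steps, same event
rules) agrees with the closed form to < 1e−9 and is kept in the test
suite as an oracle.

## Timing optimization

The search space is all pairs TI1 < TI2 with 5 ms guard gaps between the
pulses and before the readout (physical pulses have finite width; the
gap is configurable). *Constrained* placement restricts both pulses to
the post-labeling delay, *unconstrained* allows them during labeling as
well (in hardware this requires slab-selective inversion of the imaging
region; that physics is not modeled — only the placement rule changes).

The published constraints name targets but not an exact scalarization,
so the objectives are this package's choices:

* **regular** — minimize max(|GM − 5|, |WM − 5|) subject to all three
  residuals ≥ 0; flagged infeasible when the best miss exceeds 5
  percentage points (a "≈5%" design that can only reach 55% has failed,
  which is exactly the short-PLD situation).
* **enhanced** — feasible iff |GM| < 1 and |WM| < 1 (percent of M0);
  among feasible points minimize |GM| + |WM|.
* **csf** — feasible iff |CSF| < 1; among feasible points minimize
  max(|GM|, |WM|).

Ties break to the earliest TI1, then earliest TI2. The grid (default
1 ms, vectorized closed form) is followed by a 0.1 ms local refinement
around the incumbent; the objective is piecewise smooth and the domain
small, so this is deterministic and exhaustive in practice. Under the
csf scalarization the optimum at the 1800/2200 ms protocol pushes the
CSF residual toward the 1% boundary (≈0.96%) to buy lower tissue
residuals (≈5% vs the 7% of the published timing) — the published
timings remain feasible points, and the optimizer is never worse than
them by construction. Infeasibility is reported as a flagged solution
(the least-violating candidate), never an exception, because "this PLD
cannot be suppressed" is a result.

## Reconstruction

MRI signals are complex; aggressive suppression leaves static
magnetization on either side of zero. The signed scalar per voxel is the
projection onto the M0 phasor, s = Re(S·conj(M0))/|M0|, which is
invariant to any common phase and rejects the quadrature (noise-only)
component. The per-pair perfusion-weighted difference is the projection
difference for the enhanced/csf schemes and |control| − |label| for the
regular scheme (whose design keeps everything positive, matching
standard magnitude processing). Voxels with |M0| below 10% of its
99th-percentile maximum have no usable phase reference and are marked
invalid. The raw voxel phase of M0 is used directly (no phase
smoothing). No motion correction is implemented; the phantom is
motion-free and externally realigned volumes are accepted as inputs.

## Quantification

Single-delay CBF uses the no-outflow single-compartment model (blood-T1
decay only), which is the exact inverse of the kinetic model when the
bolus has fully arrived (ATT ≤ PLD):

    f = 6000·λ·ΔM·e^(PLD/T1b) / (2·α·T1b[s]·M0·(1 − e^(−τ/T1b)))

Defaults: λ = 0.9 mL/g, T1b = 1664 ms, τ = 1800 ms, and effective
labeling efficiency α = 0.85·β² ≈ 0.735 — the pCASL labeling efficiency
multiplied by one factor of β per BS inversion experienced by the label.

The kinetic difference signal ΔM(t)/M0 is zero before the bolus arrives
(t < ATT), an inflow ramp during delivery, and T1b decay afterwards.

Multi-delay estimation is two-stage:

1. **ATT from the weighted delay.** WD = Σ PLDᵢ·ΔMᵢ / Σ ΔMᵢ over all
   acquisitions (the duplicated 100 ms delay enters twice, mirroring its
   acquisition count; PLD, not τ+PLD, is the time coordinate). The
   theoretical WD(ATT) curve is built from the kinetic model on an ATT
   grid (0–3000 ms, 10 ms step; WD is flow-independent), restricted to
   its largest strictly increasing window, and inverted by linear
   interpolation. Out-of-range WDs clamp to the window ends with a flag;
   voxels with non-positive summed ΔM are invalid.
2. **CBF by linear least squares.** The model is linear in f, so with
   shapes mᵢ = ΔM(τ+PLDᵢ; f=1, ATT), f = Σ (ΔMᵢ/M0)·mᵢ / Σ mᵢ². Voxels
   whose ATT lies beyond every readout have no support and are invalid.

Maps are smoothed with a separable 3 mm FWHM Gaussian
(σ = FWHM/(2√(2 ln 2)) per axis in mm, nearest-edge handling,
mask-renormalized so invalid voxels do not bleed zeros); smoothing is
applied to the per-pair difference images before quantification, i.e.
CoV is computed after smoothing.

## Reproducibility metrics

Per voxel over repetitions: SE = sample SD/√n and CoV = 100·SE/mean.
Split-half reproducibility is the Spearman rank correlation between maps
computed from the first and second halves of the repetitions in
acquisition order; rank correlation is insensitive to the outlier voxels
that pulsation artifacts produce. Test–retest CoV for two repeated scans
uses the same SE/mean formula with n = 2.

Two summary conventions matter in the phantom setting:

* The scalar CoV summary is the mean of |CoV| over voxels whose |mean|
  exceeds 20% of the masked median |mean| (`metrics.mean_abs_cov`).
  Signed CoV is unbounded as the temporal mean crosses zero, which
  genuinely happens in artifact voxels under noisy suppression schemes;
  without the magnitude and the reliability threshold the summary is a
  heavy-tailed statistic whose mean carries no information.
* CoV is summarized over perfused tissue (GM ∪ WM) only: true CBF is
  exactly zero in phantom CSF, so a relative error there is meaningless.
  (In vivo, partial-volume effects give CSF voxels nonzero mean CBF; the
  phantom does not model partial volume.) The spatial Spearman, by
  contrast, is computed over the whole brain mask including CSF — there
  the CSF voxels are informative: under CSF-focused suppression they sit
  stably at the bottom of the rank distribution, while under
  tissue-focused suppression their pulsation noise scatters them across
  the whole range between halves.

## Digital phantom

Geometry: a brain ellipsoid on a 64×64×36 grid of 3.4×3.4×4 mm voxels,
containing a WM core ellipsoid, two lateral-ventricle ellipsoids, a
subarachnoid CSF rim whose thickness is 6% of the brain radius (keeping
the CSF fraction of brain voxels near 20% independent of grid size), an
inferior CSF blob standing in for the basal cisterns, and GM elsewhere.
Truth parameters: M0 = 1.0/0.7/1.2 a.u. and CBF = 60/20/0 mL/100g/min
for GM/WM/CSF, ATT = 1200/1600 ms for GM/WM. A smooth multiplicative
texture (±25%, Gaussian-filtered white noise, seeded) modulates CBF
around the compartment means, because real perfusion maps are not
piecewise constant — without spatial structure in the truth, split-half
spatial correlation would measure nothing.

Each simulated volume is built as:

* static signal = per-tissue M0 × the scheme's residual Mz at readout;
* the CSF static part is multiplied by (1 + A·η), where A = 0.2 is the
  pulsation amplitude and η is a smooth spatially correlated unit-SD
  field drawn per volume — pulsation strength and phase differ between
  the ventricles, cisterns and subarachnoid space, so a single global
  draw per volume would be physically wrong (and would make the whole
  compartment fluctuate coherently);
* within-shot pulsation drift: the CSF contribution is Fourier
  transformed along z (the 3D partition-encoding axis), each kz line is
  modulated by a linear ramp of peak amplitude A/2 scaled by a per-shot
  drift draw (per segment in segmented mode), and transformed back.
  This is the minimal mechanism that ghosts CSF fluctuation into
  neighbouring slices, reproducing the observed z-spread of pulsation
  artifacts;
* the perfusion difference (kinetic model at the voxel's true CBF/ATT)
  is added to the control volume;
* the volume is rotated by a smooth receive-phase field plus a small
  per-volume global phase jitter (SD 0.05 rad), and independent complex
  Gaussian noise of SD 0.002 a.u. per channel is added. The noise level
  is set so that a single control–label pair yields a usable GM CBF map
  (per-pair temporal SNR ≈ 3 after 3 mm smoothing), consistent with the
  observed stability of single-pair CSF-BS acquisitions; the M0 volume
  is noiseless.

All randomness flows from one seeded generator, so identical spec + seed
gives bit-identical output.

What the phantom does **not** model: GRASE echo-train T2 decay and its
point-spread function, motion, partial volume, eye/orbit signal, cardiac
waveform structure (pulsation is white across repetitions), and the
slab-selectivity physics of inversion during labeling. Consequently,
passing phantom tests demonstrates internal consistency of the
design/reconstruction/quantification chain and the *direction* of the
scheme comparison under pulsatile CSF noise — not in-vivo effect sizes.

## Problem sizes and defaults in the validation suite

The scheme-comparison property uses the default phantom
(64×64×36, 20 pairs, single delay 2200 ms) across five seeds, with the
ordering (lowest CoV and highest Rs for the CSF scheme) required on
every seed; a run takes a few seconds per scheme and seed. Parameter
recovery uses a 32×32×20 phantom with noise, pulsation and phase jitter
disabled: the five-delay protocol with per-PLD csf-scheme timings must
recover CBF within 2% and ATT within 20 ms (median over GM/WM). Grid
searches in tests use 1 ms steps where the claim is about exhaustiveness
and 2–5 ms elsewhere for speed; results are insensitive to this choice.

## Known limitations

* The WD→ATT inversion assumes the acquired PLD set makes WD monotone in
  ATT over the physiological range; protocols with very sparse delays
  may have a narrow usable window (the inverter restricts itself and
  flags clamped voxels).
* The regular-scheme objective reproduces the *constraint structure* of
  vendor-style designs, not any specific vendor's timing table; the
  published timings for the reference protocol are matched in residuals,
  not recovered TI-for-TI (several timing pairs are near-equivalent in
  residual space).
* `calibrate_efficiency` assumes a single global β for all pulses and
  tissues; per-pulse or per-tissue efficiencies are not identifiable
  from a single residual table.
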