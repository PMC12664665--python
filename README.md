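# aslbs — CSF-focused background suppression for ASL perfusion MRI

Arterial spin labeling (ASL) measures cerebral blood flow (CBF) by
magnetically labeling arterial blood and subtracting a labeled image from
a control image. The perfusion difference is under 1% of the equilibrium
magnetization M0, so fluctuations of the *static* tissue signal —
especially pulsatile CSF — dominate the noise budget. Background
suppression (BS) fights this with a pre-saturation pulse plus inversion
pulses timed so that the longitudinal magnetization Mz of chosen tissue
compartments is near zero at excitation.

`aslbs` is a design-and-analysis toolkit for two-pulse BS in
pseudo-continuous ASL (pCASL). It covers:

* **Mz simulation** (`aslbs.bloch`) — closed-form saturation/relaxation/
  inversion model: Mz(0) = 1 − s after pre-saturation, mono-exponential T1
  recovery between events, and Mz → −β·Mz at each inversion (β = inversion
  efficiency, calibrated from published residual tables when unknown).
* **Timing optimization** (`aslbs.optimizer`) — exhaustive + locally
  refined grid search over inversion times (TI1, TI2) for three schemes:
  *regular* (pulses constrained to the post-labeling delay, residuals kept
  positive near +5%), *enhanced* (|GM|, |WM| < 1% of M0, signs free) and
  *csf* (|CSF| < 1% while minimizing gray/white residuals).
* **Complex reconstruction** (`aslbs.recon`) — when suppression leaves
  magnetization negative, |control| − |label| is wrong; the correct signed
  difference comes from projecting each complex voxel onto the M0 phasor:
  s = Re(S·conj(M0))/|M0|.
* **Quantification** (`aslbs.quantify`) — single-compartment CBF
  f = 6000·λ·ΔM·e^(PLD/T1b) / (2·α·T1b·M0·(1 − e^(−τ/T1b))), and
  multi-delay CBF + arterial transit time (ATT) via the signal-weighted
  delay WD = Σ PLDᵢ·ΔMᵢ / Σ ΔMᵢ inverted through the kinetic model.
* **Reproducibility metrics** (`aslbs.metrics`) — voxelwise temporal SE
  and CoV (= 100·SE/mean), CoV histograms, split-half spatial Spearman
  correlation Rs.
* **Digital phantom** (`aslbs.phantom`) — a compartmental brain (GM shell,
  WM core, ventricles, subarachnoid rim, basal-cistern blob) emitting
  complex control/label/M0 volumes with scheme-dependent static residuals,
  kinetic-model perfusion signal, spatially correlated CSF pulsation with
  z-encoding ghosting, receive phase, and complex thermal noise — so every
  pipeline stage is testable without scanner data.

## Worked example

Design a CSF-suppressing timing for a 1800 ms label / 2200 ms delay
protocol:

```bash
aslbs design --scheme csf --tau 1800 --pld 2200
```

```json
{
  "scheme": "csf",
  "tau_ms": 1800.0,
  "pld_ms": 2200.0,
  "ti_bs1_ms": 1833.2,
  "ti_bs2_ms": 3537.9,
  "residual_gm_pct": -4.95,
  "residual_wm_pct": 4.95,
  "residual_csf_pct": 1.0,
  "feasible": true
}
```

The two inversions at 1833 and 3538 ms after pre-saturation drive CSF to
≈1% of M0 at excitation while gray and white matter land at ∓5% with
opposite signs — which is why the complex projection pathway is needed
downstream.

Compare the three schemes end to end on the phantom (simulate → subtract
→ quantify → metrics):

```python
from aslbs.pipeline import run_pipeline

for scheme in ("regular", "enhanced", "csf"):
    s = run_pipeline(dict(scheme=scheme, tau_ms=1800, plds_ms=[2200],
                          n_pairs=20, seed=0, phantom=dict()))
    print(scheme, round(s["mean_cov_pct"], 1), round(s["split_half_rs"], 2))
```

```
regular  38.6  0.49
enhanced 32.5  0.51
csf      19.8  0.86
```

With pulsatile CSF in the phantom, the CSF-focused scheme roughly halves
the voxelwise CoV of the per-pair CBF maps and raises the split-half
spatial Spearman correlation from ≈0.5 to ≈0.86: suppressing the CSF
signal removes the dominant physiological noise source even in tissue
voxels, because the 3D partition encoding ghosts CSF fluctuation along z.

The same machinery runs from the shell: `aslbs phantom`, `aslbs recon`,
`aslbs quantify`, `aslbs metrics`, `aslbs simulate-mz` and `aslbs run
--config cfg.yaml` (see `--help` on each subcommand). Volumes are NIfTI-1;
complex data travel as `_real`/`_imag` file pairs.

## Documentation

`docs/methods.md` describes the model assumptions, the phantom's noise
physics, parameter defaults and their rationale, and known limitations.
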