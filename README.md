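# phasemct

Modulation-based and propagation-based X-ray phase-contrast micro-CT:
simulation, retrieval, reconstruction and image-quality assessment.

Synchrotron phase-contrast micro-tomography resolves sub-micrometre density
differences in weakly absorbing soft tissue — for example the branching
villous network of a wax-embedded human placenta — that are invisible in
plain attenuation images.  In **modulation-based imaging (MBI)** a wavefront
marker (a hexagonal phase grating of the Talbot-array-illuminator type, or
layers of sandpaper acting as a random diffuser) imprints a reference
pattern on the beam; the specimen's refraction displaces that pattern, and
windowed pattern matching over a set of modulator positions recovers, per
pixel, the transmission `T`, the two pattern displacements `(u_x, u_y)` and
a dark-field factor `D`.  Displacements convert to refraction angles
`α_i = u_i · p / z`, the differential phase `∂Φ/∂i = k α_i` is integrated in
Fourier space, and filtered back-projection yields the refractive-index
decrement `δ`, which maps to electron density via

    ρe = δ k² / (2π r0).

In **propagation-based imaging (PBI)** free-space propagation alone produces
edge fringes and a single-distance low-pass (Paganin) filter with material
ratio `γ = δ/β` retrieves projected thickness.

The package is aimed at beamline scientists and method developers who want a
fully testable, desk-scale model of this analysis chain: a wave-optics
virtual beamline (thin-object specimens, Fresnel propagation, realistic
scintillator PSF and photon noise) generates complete MBI/PBI scan datasets
of a placenta-like phantom with exact ground truth, and every processing
stage — preprocessing, UMPA-style matching, phase integration, Paganin
retrieval, ring suppression, FBP, density conversion, and the metric suite
(visibility, autocorrelation width, Fourier-spectrum resolution, angular
and phase sensitivity, CNR) — is exposed as a library function with
quantitative tests.

## Worked example

```python
import numpy as np
from phasemct import phase_shift_rad, tune_gamma, px_to_um

print("TAI phase shift (rad):", round(phase_shift_rad("silicon", 17.0, 20.0), 4))
print("2*pi/3              :", round(2 * np.pi / 3, 4))
print("gamma tissue/wax    :", round(tune_gamma("soft_tissue", "paraffin", 20.0), 2))
print("speckle 5.82 px     :", round(px_to_um(5.82, 1.28), 2), "um")
```

prints

```
TAI phase shift (rad): 2.0772
2*pi/3              : 2.0944
gamma tissue/wax    : 225.75
speckle 5.82 px     : 7.45 um
```

i.e. a 17 µm silicon etch at 20 keV realises the 2π/3 grating design to
0.8%, the tabulated soft-tissue/paraffin interface ratio comes out near the
literature choice of ~202 (composition-limited agreement), and a 5.82 px
speckle at 1.28 µm pixels is 7.45 µm.

A complete three-arm comparison (MBI with grating, MBI with sandpaper, PBI)
on one shared phantom:

```python
from phasemct import make_config, run_experiment

result = run_experiment(make_config("smoke"), out_dir="out")
print(result.metrics[["dataset", "mean_visibility", "sigma_alpha_x_nrad",
                      "sigma_rho_e", "cnr_mean"]])
```

writes aligned δ and ρe volumes (`out/volumes.h5`), a metric report
(`out/metrics.csv`) and a slice gallery.  On the `benchmark` preset (128³
phantom, 181 angles, 16/20 modulator steps, calibrated photon noise) the
simulated angular sensitivities land in the measured few-hundred-nanoradian
regime of the real instrument (grating ≈ 307/295 nrad, sandpaper ≈
374/359 nrad for the horizontal/vertical channels), and the noise-free
MBI arm recovers the tissue-vs-paraffin δ contrast to within a few percent.

The same stages are available from a shell:

```bash
phasemct simulate --preset smoke --arm mbi_tai --seed 1 --out scan.h5
phasemct retrieve-mbi --in scan.h5 --out proj.h5 --window 1 --search 2
phasemct run-experiment --preset smoke --seed 1 --out results_dir
```

## Layout

- `src/phasemct/synthetic.py` — virtual beamline: screens, phantom,
  Fresnel propagation, frame/scan simulation, HDF5 layout
- `src/phasemct/preprocessing.py` — dark/flat, bad pixels, beam profile,
  drift registration
- `src/phasemct/mbi.py` — windowed pattern matching (T, u, D) and
  displacement→angle→differential-phase conversion
- `src/phasemct/integration.py` — background detrending and Fourier
  integration of gradient fields
- `src/phasemct/pbi.py` — Paganin single-distance retrieval, γ helper
- `src/phasemct/tomography.py` — ring suppression, built-in FBP, electron
  density and attenuation conversions
- `src/phasemct/metrics.py` — quality metric suite
- `src/phasemct/pipeline.py`, `src/phasemct/cli.py` — orchestration and CLI

`docs/methods.md` describes the physical model, the numerical choices and
the known limitations in detail.
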