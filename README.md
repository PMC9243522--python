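# dqobm

Label-free functional imaging of living cells in thick, scattering samples:
quantitative phase reconstruction for oblique back-illumination microscopy
(qOBM) and phasor-based analysis of subcellular phase dynamics (dynamic
qOBM), with a fully ground-truthed synthetic data generator.

## The problem

Adherent cells growing on porous microcarriers inside bioreactors are hard
to monitor: the carriers are optically opaque, and labels would perturb the
product. qOBM images such samples in epi-mode with four LEDs placed around
the objective — multiply scattered photons return through the focal plane
as an oblique virtual source, and opposing-LED image pairs form
differential phase contrast (DPC) images that can be inverted to
quantitative phase. Imaging the same field over time and analyzing each
pixel's temporal phase fluctuations then yields a *functional* image:
subcellular refractive-index dynamics, whose spectral signature differs
between cell populations, are rendered as color.

## The model

**Reconstruction.** For a weak phase object, the normalized DPC image
`I_DPC = (I_a − I_b)/(I_a + I_b)` is linear in the object phase φ with a
transfer function determined by the pupil `P` (binary, cutoff NA/λ) and the
effective source distribution `S`:

    C_DPC(q) = −i ∫ [S(u) − S(u′)] P(u+q) P*(u) d²u / ∫ S(u)|P(u)|² d²u,

where `u′` mirrors `u` along the shear axis. Two orthogonal DPC images
(k = 1, 2) are jointly inverted by Tikhonov-regularized deconvolution

    φ = F⁻¹ { Σ_k Ī_DPC^k C_k* / (Σ_k |C_k|² + α·max_q Σ_k |C_k|²) }.

Four raw frames give one phase image, so a camera at 4 (32) fps yields a
net phase rate of 1 (8) Hz.

**Dynamics.** Each pixel's temporal magnitude spectrum φ̃(f) = |F{φ(t)}| is
summarized by its phasor at a period τ:

    g(τ) = ∫φ̃(f) cos(2πfτ) df / ∫φ̃ df,   s(τ) = ∫φ̃(f) sin(2πfτ) df / ∫φ̃ df.

Exponential spectra φ̃ ∝ e^(−f/f_c) fall on the universal semicircle
s² = g(1−g); mixtures fall on chords between their endmembers. Cells are
segmented from static background and shot noise by an amplitude gate plus
a phasor gate at a prior τ, the masked phasor cloud is decomposed into two
branches sharing a root, and branch + position map to hue in an HSV image
(value = cell mask, saturation = 1).

## Worked example

```python
import numpy as np
from dqobm import (OpticalConfig, make_pupil, default_source, compute_dpc_transfer,
                   rayleigh_resolution, net_phase_rate)
from dqobm.synthetic import synthetic_twin_metrics

cfg = OpticalConfig(wavelength=0.72, numerical_aperture=0.6,
                    pixel_size=0.2, grid_shape=(256, 256))
print(f"pupil cutoff NA/lambda  = {cfg.cutoff:.3f} cycles/um")
print(f"Rayleigh resolution     = {rayleigh_resolution(cfg):.2f} um")
print(f"net phase rate at 4 fps = {net_phase_rate(4.0):.0f} Hz")

m = synthetic_twin_metrics(seed=7)
print(f"cell-mask Jaccard       = {m['mask_jaccard']:.3f}")
print(f"label accuracy          = {m['label_accuracy']:.3f}")
print(f"static-phase correlation= {m['static_correlation']:.3f}")
```

prints

```
pupil cutoff NA/lambda  = 0.833 cycles/um
Rayleigh resolution     = 0.73 um
net phase rate at 4 fps = 1 Hz
cell-mask Jaccard       = 0.949
label accuracy          = 1.000
static-phase correlation= 0.976
```

The first three lines are optical constants of the 40×/0.6 NA, 720 nm
configuration: the pupil's frequency cutoff, the diffraction-limited
resolution (~0.7 μm), and the phase-imaging rate implied by cycling four
LEDs at 4 fps. `synthetic_twin_metrics` then runs the whole pipeline on a
simulated 8-minute, 1 Hz acquisition of a microcarrier carrying two cell
populations with different dynamic corner frequencies (0.005 and 0.05 Hz)
at a photon budget of 10⁴ counts/pixel: the recovered cell mask overlaps
the true cell footprint with Jaccard 0.95, every branch-assigned cell
pixel is attributed to the correct population, and the time-averaged
reconstruction correlates with the true static structure at 0.98 within
the transfer-function passband.

A shell workflow is available through the `dqobm` CLI
(`simulate`, `reconstruct`, `dynamics`, `render`); see `dqobm --help`.

## Documentation

`docs/methods.md` describes the model assumptions, parameter defaults,
what the synthetic generator does and does not emulate, and the numerical
choices (quadrature, DC handling, noise-floor subtraction, phasor binning).
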