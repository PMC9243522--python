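# Methods

## Scope and model assumptions

The package implements the linear weak-object imaging chain of oblique
back-illumination DPC microscopy and the phasor analysis of phase
time-lapses. Key assumptions:

* **Weak object.** DPC formation is linear in phase; the forward model is
  exact for the synthetic data it generates (intensities
  `I_± = B(1 ± DPC)`), and a reasonable approximation for real samples
  with |φ| ≲ 0.5 rad of high-frequency content. The reconstruction itself
  is linear for any amplitude, so smooth objects of several radians
  reconstruct without wrap artifacts (there is no arctangent anywhere).
* **Aberration-free binary pupil.** `P(u) = 1` for |u| ≤ NA/λ. No
  apodization or aberration model is provided.
* **Parametric oblique source.** The effective source created by multiple
  scattering is modeled as a truncated Gaussian lobe in frequency space
  (default: offset 0.5× cutoff along the shear axis, σ = 0.2× cutoff).
  A toy homogeneous random-walk estimator (`monte_carlo_source`) is
  provided as an optional alternative; it reproduces the sign and rough
  scale of the obliquity, not a quantitative tissue simulation. Photons
  count only if they re-cross the focal plane upward, inside the NA cone
  and inside a detection field of view (default radius 80 μm) — the
  lateral offset between LED and field of view is what makes the source
  oblique.
* **2D.** Only the in-plane transfer function is computed; optical
  sectioning is a property of the instrument, not modeled here.

## Transfer function: conventions and discretization

* Frequencies are in cycles/μm on the FFT grid implied by the pixel size
  (standard FFT ordering, DC at index [0, 0]); angles map through
  u = sinθ/λ.
* The numerator integral is a Riemann sum on the image FFT grid; the grid
  cell area cancels between numerator and denominator. The shifted pupil
  `P(u+q)` is evaluated on a doubled frequency range, so no periodic
  wrap-around occurs: frequencies beyond the grid see the true (zero)
  pupil.
* For a real nonnegative source and real pupil the integral is real and
  the physical transfer `C_DPC = −i·num/den` purely imaginary. The stored
  array is the real odd coefficient `R(q) = num/den` with `C = −i·R`;
  `R` is real, odd along the shear axis, and zero at DC.
* The output is antisymmetrized, `R ← (R − reflect(R))/2`. The raw sum is
  odd to rounding everywhere except the self-conjugate Nyquist bins (their
  own mirror under the wrapped reflection f → −f), where a real-valued
  forward model requires exactly zero.
* Degenerate inputs: a source with no mass inside the pupil (denominator
  ≤ 0) raises; a shear-symmetric source yields an identically zero
  transfer, which the deconvolution rejects.

## Reconstruction

* DPC formation is normalized by the pair sum, making the result invariant
  to global intensity rescaling; pixels where an opposing pair sums to
  zero are set to 0 and counted (warning above 1%).
* The Tikhonov weight α is expressed relative to `max_q Σ_k |C_k|²`, so
  its meaning is grid-independent. Default α = 1e-3; forward–inverse
  oracles use 1e-6 (noiseless) where the criterion is sharpness, and
  parameter-recovery checks use 1e-4.
* `C(0) = 0` makes the image mean unobservable; reconstructions are
  reported zero-mean by default.
* Raw frames are grouped strictly sequentially in fours (net phase rate =
  camera fps / 4); a trailing partial set is dropped with a warning.

## Dynamics

* **Spectra.** Per-pixel one-sided DFT magnitudes, no window, unnormalized
  DFT (an on-bin cosine over T samples has magnitude T/2). The DC bin is
  removed before everything downstream: a static offset would dominate
  ∫φ̃ df while carrying no dynamic information. Default detrend is mean
  removal; linear detrending is available for long acquisitions with slow
  drift.
* **Phasors.** Rectangle-rule sums on the DFT frequency grid; `Δf`
  cancels in g and s and appears only in the amplitude ∫φ̃ df.
  Zero-amplitude pixels are flagged invalid. τ defaults follow the net
  rate: τ = 4 s (prior 2.6 s) at 1 Hz, τ = 0.5 s (prior 0.33 s) at 8 Hz.
* **Noise-floor subtraction** (`noise_floor="tail_median"`; default in the
  high-level `analyze_movie`, off in the low-level operations). Shot noise
  propagated through the deconvolution gives every pixel a flat
  magnitude-spectrum pedestal that dominates ∫φ̃ df in background pixels
  and drags all phasors toward the flat-spectrum point. Exponential
  signals decay to nothing in the upper quarter of the frequency axis, so
  its per-pixel median estimates the pedestal; it is subtracted and the
  result clipped at zero.
* **Spatial phasor binning** (`binning_sigma_px`, default 2 px in
  `analyze_movie`). Gaussian smoothing of the magnitude spectra over the
  image axes, equivalent to amplitude-weighted local phasor averaging —
  the standard binning step of phasor analysis. At the slow corner
  frequency (0.005 Hz over 8 min) a pixel's spectrum has only a few
  effective bins, so unbinned per-pixel phasors scatter widely.
* **Segmentation.** A pixel is cell iff its amplitude exceeds the chosen
  quantile (default 0.5) of the amplitude image *and* its phasor at the
  prior τ lies outside both non-signal signatures: the static box near
  (1, 0) (g > 0.95, |s| < 0.05) and a disk of radius 0.25 around the
  analytic flat-spectrum (white-noise) phasor point, whose closed form per
  frequency band is provided by `white_noise_phasor`. The amplitude
  quantile alone cannot isolate cells — it keeps a fixed fraction of
  pixels by construction — so the phasor gate carries the discrimination.
  The segmentation gate uses unsubtracted spectra, where the flat-spectrum
  signature sits exactly at its analytic location.
* **Branches.** Manual mode takes root and endmembers as (g, s) points
  (the programmatic analogue of drawing ROIs on the phasor plot) and
  assigns each pixel to the nearest chord. Auto mode roots the model at
  the static point (1, 0) — the physical junction, since every dynamic
  signature slows toward static — finds the two clusters by 2-means on
  (g, s), uses cluster membership as branch identity, and takes each
  endmember as the above-median-density pixel farthest from the root in
  its cluster. Positions are clipped scalar projections onto the branch
  chord; pixels farther than 3× the median own-chord distance stay
  unassigned. Label-accuracy figures are computed over branch-assigned
  cell pixels, with the unassigned fraction reported separately
  (typically ~3% on the synthetic twin).
* **Rendering.** Branch 1 sweeps red → yellow → green → blue
  (0° → 240°) with position; branch 2 sweeps red → magenta → purple
  (0° → 300° descending), keeping the two branch extremes on opposite
  sides of red. Value is the binary cell mask, saturation 1; unassigned
  in-mask pixels render at the root hue (red) and are logged.

## Synthetic data generator

The generator emulates the desk-scale twin of an 8-minute, 1 Hz
two-population acquisition; its defaults are the study conditions used by
the tests and the acceptance script.

* **Scene** (256² px at 0.2 μm = 51.2 μm field): a microcarrier-like disk
  (radius 40 μm) of band-limited phase texture (pore scale 2 μm, peak
  1.2 rad), with two 11 μm-radius cell disks, one per population.
* **Dynamics**: per-pixel temporal fluctuations with magnitude spectrum
  ∝ e^(−f/f_c), realized by Hermitian spectral shaping of white Gaussian
  noise, exactly rescaled to each pixel's rms amplitude. Populations:
  f_c = 0.005 Hz (slow) and 0.05 Hz (fast), both at 0.15 rad rms — the
  middle of the 0.05–0.2 rad range plausible for subcellular
  refractive-index dynamics; the value is a free parameter of
  `PopulationParams`.
* **Spatial correlation**: fluctuation fields are smoothed to a 0.5 μm
  correlation length *before* masking by the cell regions — real
  subcellular scatterers are at least resolution-sized, and a spatially
  white field would put most of its power outside the DPC passband.
  Masking after smoothing keeps the ground-truth footprint sharp and each
  cell pixel's temporal spectrum exact.
* **Acquisition**: per frame and shear axis, opposing-LED intensities
  `B(1 ± DPC)` at photon budget B (default 10⁴ counts/pixel) with Poisson
  noise; `photon_budget=None` gives the exact noiseless inverse of DPC
  formation, which is what makes the forward–inverse oracles sharp.

**What passing tests do and do not show.** The generator realizes the same
weak-object linear model the analysis assumes, so end-to-end recovery
demonstrates the internal consistency and noise robustness of the chain —
not its accuracy on real tissue, where partial coherence, multiple
scattering within the sample volume, aberrations, stage drift and
non-exponential dynamics all violate the model to some degree.

## Problem sizes

Unit tests run on 64²–128² grids; the end-to-end twin uses the full
256² × 480-frame experiment and completes in well under a minute on one
CPU. Brute-force transfer-function oracles run on 8²–12² grids where the
O(N⁴) double sum is exact and fast.

## Known limitations

* Only two branch populations; more would need a generalized clustering
  step (the BranchModel layout is the extension point).
* The quantitative hue scale is a convention; only the qualitative
  red→blue / red→purple gradients are meaningful.
* The toy photon random walk is qualitative; no layered media, absorption,
  or measured scattering phase functions.
* Absorption imaging is limited to the raw four-frame sum; no absorption
  transfer function is inverted.
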