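# Methods

## The measurement model

An OCT acquisition is a 4D complex field indexed `(z, x, r, y)`: depth
along the beam, fast transverse axis, repeated B-scan frames, slow axis.
Axial motion of a scatterer between the two adjacent A-scans separated by
`Δt_ODT` imprints the Doppler phase

    Δφ = 4π · n · v · cos θ_z · Δt_ODT / λ₀,

with `v` the flow speed, `θ_z` the angle between vessel axis and beam,
`n` the tissue index and `λ₀` the center wavelength. Defaults:
`λ₀ = 1.31 µm`, `Δλ_FWHM = 0.20 µm`, `Δt_ODT = 2.3 ms`,
`Δt_OCA = 0.21 s` between repeated frames, `N = 14` repeats, tissue index
`n = 1.35` (a typical cortex value; the axial PSF width, 2.5 µm, is taken
as a direct parameter rather than derived from the coherence length, whose
usual formula requires an index assumption the instrument description does
not pin down). The effective Doppler pair time is a free parameter: A-scan
rates vary between protocols, so `dt_odt` defaults to 2.3 ms but is not
derived from any scan geometry.

Because `Δt_OCA ≈ 100·Δt_ODT`, angiography integrates two orders of
magnitude more motion than Doppler — the mechanistic reason the stripe
artifacts concentrate in µOCA. In the phantom this asymmetry falls out
naturally: a per-frame axial shift adds a global phase that cancels exactly
in the intra-frame lag-1 product (µODT untouched) while decorrelating the
inter-frame speckle (µOCA corrupted).

## Phantom

`generate_vessel_tree` grows binary trees with Murray-law radii
(`r_child = 2^(-1/3) r_parent`) and speeds scaled so volumetric flow is
conserved exactly at every bifurcation. With the default root radius 8 µm
and root speed 500 µm/s, leaves at depth 4–7 land at radii 1.6–3.2 µm and
speeds 125–200 µm/s — single-voxel capillaries in a plausible velocity
band. `flow_sense = ±1` encodes arterial (root→leaves) versus venous flow.
An optional dive-depth range sends the trunk into deep cortical layers.

`simulate_acquisition` synthesizes fully developed speckle (complex
circular Gaussian, laterally correlated over a 4-px beam and axially over
the PSF), with lumen amplitude 3× parenchyma. Flow voxels carry a
**cumulative** phase ramp along the fast axis, so the lag-1 product of
adjacent A-scans equals the local wrapped `Δφ` exactly — the phase round
trip is exact to float precision on noise-free phantoms. Aliased voxels
(`|Δφ| > π`) are synthesized wrapped and flagged in the truth sidecar.
Across repeats, lumen speckle is remixed with a fresh realization at rate
`1 − exp(−v·Δt_OCA/ℓ)` (decorrelation length `ℓ = 5 µm`), which makes
speckle variance monotone in flow speed. Additive complex detector noise
defaults to 0.05 per quadrature (relative to unit parenchyma amplitude).

`inject_bulk_motion` applies per-frame axial shifts (Fourier sub-voxel
resampling plus the global phase `4πn·δz/λ₀`) and "scrambles": a scrambled
frame is a *collapsed* B-scan — structureless speckle at the frame's RMS
power with uniform random phase, mixed in by amplitude `a ∈ [0, 1]`.
Collapse (rather than an envelope-preserving phase scramble) matters:
intensity-based angiography and correlation-based frame selection only see
the artifact if the intensity structure is destroyed too.

What the phantom does **not** emulate: pulsatility and autoregulation,
spectral-domain effects (fringe sampling, dispersion), vessel wall
scattering, and anatomically realistic tortuosity. Passing tests therefore
demonstrate correctness of the algorithms under the stated forward model,
not performance on any specific animal dataset.

## Reconstruction

µODT: per voxel, the lag-1 complex products along the fast axis are
averaged over all repeats and over a 3×3 (z, x) window before taking the
argument; output stays in rad, `(−π, π]`, not angle-corrected (matching
how such images are displayed); zero-amplitude voxels get phase 0 plus a
low-confidence flag. The `x = 0` column has no preceding A-scan and copies
its neighbor; accuracy statements therefore apply to window-uniform
interior voxels (`phase_interior_mask`).

µOCA: per slow-axis position, frames are selected by Pearson correlation
of log-compressed intensity **restricted to the temporally stable half of
the voxels** (lowest variance across frames). Flowing lumina decorrelate
even between perfectly registered frames, so whole-frame correlation
punishes vessel-dense B-scans; static-parenchyma correlation isolates
genuine bulk motion. The reference frame maximizes the mean correlation to
its `n_select − 1` best partners — a statistic that stays on a clean frame
as long as `n_select` clean frames survive, even when more than half the
repeats are corrupted (a frame's *median* correlation fails exactly there).
Selected frames (default `N′ = 6`, `r > 0.9`, ties to the lower index)
feed the coefficient of variation (population std / mean). Voxels whose
mean intensity is below 0.1× the volume median are zeroed: in dark speckle
the CoV is detector-noise-driven and an en-face MIP of raw CoV drowns in
that salt noise. The unfloored CoV is kept (`OCAVolume.raw`) because
stripe detection wants exactly that background level.

## Stripe removal

Detection: the per-position level is the 30th percentile of the CoV over
the whole (z, x) B-scan — corrupted frames raise every voxel, vessels only
the upper tail, so the low quantile reacts to motion but not to vessel
density. Levels are z-scored against the scan's global median/MAD;
positions above the threshold (default 10) form the bands. Measured clean
phantoms peak at z ≈ 5.5 while collapsed bands sit at z ≈ 120, so 10
doubles the clean extreme with a 10× margin below real artifacts. The
global baseline assumes fewer than about half the positions are corrupted.

Segmentation: optimally oriented flux. By the divergence theorem the
oriented-flux matrix at radius `r` is the Hessian of the Gaussian-smoothed
(mean-subtracted) image convolved with the ball indicator, normalized by
the sphere surface; the response is the rectified negative mean of the
`d−1` cross-sectional eigenvalues, maximal when `r` matches the tube.
Binarization uses hysteresis at Otsu's threshold of the positive response
support (high) and 0.25× that (low), plus an intensity gate at 0.5× Otsu
of the image inside the mask. Rank-based (percentile) thresholds were
rejected: in sparse 3D volumes ~96% of voxels carry tiny positive FFT
ripple, so fixed percentiles land in the noise plateau and flood the mask
(Dice 0.23 on a clean phantom, versus 0.77/0.76/0.95 for the adopted
scheme on clean-3D / noisy-3D / en-face inputs).

Inpainting: a 3-level gated-convolution encoder-decoder (8 base channels,
~7k parameters) maps (occluded mask, occlusion indicator, MIP-gradient
guidance) to fill probabilities. Training is self-supervised: synthetic
vertical stripes (log-uniform widths 4–32 px) are drawn over clean columns
of the same image; genuinely detected stripe columns are occluded in the
input too but carry zero loss weight since their truth is unknown.
Guidance inside synthetic stripes is mixed with shuffled-gradient noise by
a random factor, mimicking real stripes whose gradients retain structure
only partially. Loss: binary cross-entropy, weight 1 inside synthetic
stripes, 0.1 outside, zero in real stripes, with a positive-class weight
`clip(neg/pos, 1, 10)` because vessels are ~12% of a stripe. Adam
(lr 10⁻², global-norm clip 1, linear decay to 10%), batch 4, 300
iterations, 64×64 patches — the desk reference run. Inference averages
predictions over the four axis-flip symmetries and copies every pixel
outside the bands bit-exactly. Typical desk-phantom results: Dice gain
0.16–0.21 over the corrupted baseline, severed vessels re-skeletonize to
one component, in-stripe Dice 0.55–0.70 (the ceiling set by ±1 px
localization on 2–3 px capillaries). The repaired mask multiplies the raw
MIP to give the enhanced angiogram (idempotent, background exactly zero).

## µODT enhancement

A 3-level U-shaped 3D CNN (8 base channels, leaky-ReLU 0.1) is trained on
single noisy volumes; no clean targets exist anywhere in the API. Volumes
are normalized by their 1st–99th |Δφ| percentiles (recorded in the
manifest); enhancement operates on magnitude and reattaches the original
sign, so flow direction can never flip. Per iteration (200 total, 32³
patches preferring vessel content):

* **Vessel Cropping** — random skeleton chains (4–12 voxels) with their
  local-radius sleeve are replaced by background-level noise until the
  requested voxel fraction (default 0.3) is reached; the record localizes
  every dropped voxel;
* **Intensity Remapping** — a monotone piecewise-linear map anchored at the
  volume's intensity quantiles, segment slopes log-uniform in [1/2.5, 2.5]
  (bounded so inversion is learnable; unbounded quantile scrambles made the
  restoration target hopeless). Half the iterations see the identity map,
  anchoring absolute intensity;
* **blind-spot background** — 60% of background voxels are resampled from
  the background median/MAD so their noise cannot be copied; predicting
  them forces regression to the local level, which is the denoising
  mechanism;
* loss — class-balanced L1: dropped segments 2×w, vessels and their 2-voxel
  background shell w = clip(0.5·n_bg/n_vessel, 1, 10), blinded background
  0.5, the rest 0.05, plus 0.1× an L1 consistency term between predictions
  under two independent remaps every 4th iteration. The shell term exists
  because without it dim false positives hugging a highly weighted lumen
  cost nothing and the net smears tubes into halos.

The provisional vessel mask for cropping comes from OOF on the noisy
volume itself, keeping the path self-supervised. Plain ReLU nets this
small die to a constant in 200 iterations and ELU destabilized the He
initialization scale; the leak plus gradient clipping plus lr decay made
training monotone across all tested seeds and noise levels (CNR strictly
increased and skeleton fragments dropped toward the truth count in 8/8
runs at two noise levels). Inference tiles volumes with Hann-window
overlap blending.

On the clean phantom the vessel-mask Dice after enhancement is 0.65–0.73
against the rasterized truth. An absolute 0.9 is not reachable here: even
an oracle threshold on the clean |Δφ| volume scores ≈ 0.76, the loss being
partial volume on 1–2 px capillaries and phase-window bleed, so the tests
pin a floor of 0.65 plus a bounded drop relative to the pre-enhancement
mask instead.

## Quantification

* Orientation: scale-normalized Hessian (σ ∈ {1, 2, 4}, best scale by
  curvature strength); vessel axis = eigenvector of the smallest-magnitude
  eigenvalue; `θ_z = arccos |axis·ẑ|`; isotropic voxels get confidence 0
  and NaN angle. Centerline errors on synthetic cylinders are < 0.1°.
* Angle correction: `v = λ₀Δφ/(4πn·Δt·cos θ_z)`, masked above
  `θ_max = 80°` — near-horizontal flow is reported as uncorrectable rather
  than amplified through the 1/cos divergence.
* Arteriole/venule: per connected tree, each bifurcation votes by whether
  flow enters through the largest-diameter edge and leaves through the
  branches (branching out ⇒ arteriole) or the reverse (branching in ⇒
  venule); signed flow per edge comes from the Doppler sign and the edge's
  axial direction, with near-horizontal edges (|Δz| < 5% of length)
  abstaining. Trees whose largest diameter is ≤ 10 µm are capillary (the
  cutoff is a parameter; no standard value exists), conflicted trees stay
  unclassified with a conflict score.
* Diameter: 2× Euclidean distance transform at queried centerline points.
* Capillary density: large vessels are removed by morphological opening at
  the cutoff radius, the remainder skeletonized; length counts each
  neighbor link once at half its Euclidean step; CD = length / ROI area.
* Flow time series: CBFv per ROI is the mean |Doppler| above a noise
  floor; `ΔCBFv = (CBFv − CBFv₀)/CBFv₀` against the mean over the baseline
  window, so the baseline mean of ΔCBFv is zero by construction.
  Compartment traces are means over member ROIs with population-std
  dispersion. Whether to report phase-based or angle-corrected CBFv is a
  user choice; phase-based (un-corrected) is the default, matching how the
  images themselves are displayed, and is monotone in true speed at fixed
  geometry.

## Pipeline and reproducibility

One global seed fans out to per-stage child seeds by stable hashing of the
stage name, so adding a stage never perturbs its siblings. Configs are
schema-validated (unknown keys rejected). Outputs are written in
deterministic formats (HDF5 without timestamps, uncompressed NIfTI, TIFF
without datetime tags) and the manifest records SHA-256 checksums; the
output directory is excluded from the config hash. Training is pure
numpy/BLAS, so a fixed seed reproduces manifests bit-for-bit on one
platform.

Desk problem sizes used throughout the tests and the acceptance script:
64×64×(4–6)×64–128 acquisitions, 300-iteration inpainting on 64×64
patches, 200-iteration enhancement on 32³ patches; the two pipeline runs
of the determinism check use 60/40 iterations. These sizes were chosen so
the whole chain, including both trainings, completes in minutes on a
single CPU core while every stage still operates in its intended regime.

## Known limitations

* The stripe detector's global-baseline statistic assumes < ~50% of the
  slow axis is corrupted.
* In-stripe mask recovery is continuation-based; vessels running parallel
  to a wide stripe for its full width cannot be recovered.
* The enhancer is trained per-volume (or per small set); no pretrained
  weights are shipped, by design.
* Absolute perfusion calibration and statistical hypothesis testing are
  out of scope.
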