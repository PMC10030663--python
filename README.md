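# odtflow

Optical coherence tomography (OCT) can map the cortical microvasculature of
awake, behaving mice in 3D: **µODT** (Doppler tomography) measures cerebral
blood flow velocity from the phase difference between adjacent A-scans, and
**µOCA** (angiography) maps vessels from speckle decorrelation across
repeated B-scans. In awake animals both are plagued by bulk motion — whole
B-scans collapse into bright stripes in the angiogram and phase noise in the
Doppler image. `odtflow` implements the full processing chain for such
acquisitions:

* reconstruction of µODT (lag-1 complex autocorrelation phase,
  `Δφ = arg Σ E(x)·E*(x−1)`) and µOCA (speckle variance = std/mean of
  intensity across the most mutually correlated `N′ = 6` of `N = 14`
  repeated frames, Pearson `r > 0.9`);
* stripe-artifact removal: robust per-B-scan outlier detection, optimally
  oriented flux (OOF) vessel segmentation, and a **self-supervised**
  gated-convolution inpainting network trained on synthetic stripes drawn
  over the clean area of the same image (no annotations, no clean/noisy
  pairs);
* **self-supervised 3D µODT enhancement**: a small 3D U-shaped CNN trained
  with Intensity Remapping (random monotone intensity maps anchored at the
  volume's own quantiles) and Vessel Cropping (random centerline segments
  replaced by background noise that the net must restore), which suppresses
  background noise and re-links broken vessels;
* vascular quantification: Hessian-based vessel angle θ_z, Doppler angle
  correction `v = λ₀Δφ/(4πn·Δt·cos θ_z)`, arteriole/venule discrimination
  from branching flow direction, diameters from the distance transform,
  skeleton-based capillary density (fill factor), and per-ROI
  `ΔCBFv = (CBFv − CBFv₀)/CBFv₀` time series;
* a physics-based **phantom** (vessel trees with Murray-law branching,
  complex speckle, Doppler phase accumulation, speed-dependent inter-repeat
  decorrelation, bulk-motion injection with ground-truth sidecars) so every
  stage is testable without animal data.

The two neural networks are implemented in a compact numpy/BLAS framework
(`odtflow.nn`) with manual backprop; desk-scale models (3 levels, 8 base
channels) train in well under a minute on one CPU core.

## Worked example

```python
import numpy as np
from odtflow.params import AcquisitionParams
from odtflow import phantom as ph, recon, motion_inpaint as mi

p = AcquisitionParams(n_repeats=6)                 # λ=1.31 µm, Δt=2.3 ms
tree = ph.generate_vessel_tree(7, depth=4,
                               domain=[(0, 128), (0, 128), (0, 256)])
acq = ph.simulate_acquisition(tree, p, seed=1, shape=(64, 64, 128),
                              n_repeats=6)
scr = np.zeros((128, 6)); scr[52:58] = scr[74:77] = 1.0   # motion bursts
acq = ph.inject_bulk_motion(acq, ph.MotionTrace(np.zeros((128, 6)), scr))

oca = recon.oca_volume(acq)
stripes = mi.detect_stripes(oca)
print(stripes.bands)                 # [(52, 58), (74, 77)]

mip = recon.mip_project(oca.data, axis=0)
vness, _ = mi.oof_vesselness(mip, (1, 2, 3))
mask = mi.binarize_vesselness(vness, mip)

cfg = mi.InpaintConfig(iterations=300, seed=3)
pairs = mi.make_inpaint_training_pairs(mask.mask, mip, 200, cfg,
                                       stripes=stripes)
model = mi.train_inpainting(pairs, cfg)
repaired = mi.inpaint_stripes(mask, stripes, model, mip)
enhanced = mi.enhance_oca(mip, repaired)

truth = (acq.truth["label"] > 0).any(axis=0)
def dice(a, b): return 2 * (a & b).sum() / (a.sum() + b.sum())
print(round(dice(mask.mask, truth), 2), "->",
      round(dice(repaired.mask, truth), 2))       # 0.64 -> 0.8
```

The detector finds exactly the two injected motion bursts, and the
detect → inpaint → multiply path lifts the vessel-mask Dice from 0.64
(stripes flood the segmentation) to 0.80 against the construction truth.

The same pipeline runs from the shell:

```bash
odt run --seed 1 --out run1          # phantom → recon → denoise → quant
odt phantom --seed 3 --size 64 64 64 --preset awake --out ph3
odt recon oca --input ph3/acquisition.h5 --out ph3/oca.nii
```

Every run writes a `manifest.json` with per-stage seeds and SHA-256
checksums; re-running with the same config and seed reproduces every output
byte-for-byte.

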