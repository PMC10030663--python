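"""Stripe-artifact removal for µOCA: detection, vesselness, inpainting.

Severe bulk motion collapses whole B-scans into bright stripes spanning
several adjacent slow-axis positions of the en-face µOCA MIP.  The pipeline
here follows the angiography branch of the processing flow:

1. detect corrupted slow-axis bands (robust outliers of the per-position
   speckle-variance level);
2. segment vasculature with optimally oriented flux (OOF) and hysteresis
   binarization;
3. erase the detected bands from the binary vessel mask and recover them
   with a small gated-convolution encoder-decoder trained self-supervised:
   synthetic stripes are drawn over the clean area of the same image, so no
   manual annotation (and no clean/noisy pair) is ever needed.  Gradients of
   the raw MIP in the stripe area enter as a guidance channel;
4. multiply the repaired mask with the raw MIP to produce the enhanced µOCA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from skimage import filters, morphology

from . import nn


# ---------------------------------------------------------------------------
# Stripe detection

@dataclass
class StripeMask:
    """Corrupted slow-axis bands (half-open index intervals) on the MIP."""

    bands: list[tuple[int, int]]
    scores: list[float]
    n_slow: int

    def __post_init__(self):
        prev = -1
        for lo, hi in self.bands:
            if not (0 <= lo < hi <= self.n_slow) or lo <= prev:
                raise ValueError("bands must be disjoint, ordered, in bounds")
            prev = hi - 1

    def columns(self) -> np.ndarray:
        cols = np.zeros(self.n_slow, bool)
        for lo, hi in self.bands:
            cols[lo:hi] = True
        return cols

    @property
    def empty(self) -> bool:
        return not self.bands


def detect_stripes(oca, sensitivity: float = 10.0) -> StripeMask:
    """Detect motion-corrupted slow-axis bands in a µOCA volume or MIP.

    The per-position level (see :func:`stripe_level`) is z-scored against
    the scan's global median/MAD; positions exceeding ``sensitivity`` form
    the bands.  Severe-motion stripes are gross outliers — two orders of
    magnitude above the clean-scan level — so the default threshold sits
    well above the clean null's extremes while keeping an order of
    magnitude of margin below genuine artifacts.  Assumes fewer than about
    half of the positions are corrupted.  Prefer passing the ``OCAVolume``
    (its unfloored ``raw`` CoV is used); a 2D en-face MIP also works.
    """
    arr = _oca_array(oca)
    if not np.isfinite(arr).all():
        raise ValueError("input must be finite")
    z = stripe_statistic(arr)
    above = z > sensitivity
    bands, scores = [], []
    y = 0
    n = len(z)
    while y < n:
        if above[y]:
            y0 = y
            while y < n and above[y]:
                y += 1
            bands.append((y0, y))
            scores.append(float(z[y0:y].max()))
        else:
            y += 1
    return StripeMask(bands, scores, n)


def _oca_array(oca) -> np.ndarray:
    if hasattr(oca, "raw") and oca.raw is not None:
        return np.asarray(oca.raw, np.float64)
    if hasattr(oca, "data"):
        return np.asarray(oca.data, np.float64)
    return np.asarray(oca, np.float64)


def stripe_level(oca) -> np.ndarray:
    """Raw per-slow-axis-position speckle-variance level (30th percentile
    of the B-scan for volumes, column median for MIPs) — monotone in the
    amount of inter-frame decorrelation at that position."""
    arr = _oca_array(oca)
    if arr.ndim == 3:
        return np.percentile(arr, 30.0, axis=(0, 1))
    return np.median(arr, axis=0)


def stripe_statistic(oca) -> np.ndarray:
    """Per-slow-axis-position robust z-score used by ``detect_stripes``.

    For a 3D µOCA volume the per-position level is a low quantile (30th
    percentile) of the speckle variance over the whole (z, x) B-scan:
    corrupted frames decorrelate every voxel — background included — while
    genuine vessels only raise the upper tail, so the low quantile reacts
    to bulk motion but not to vessel density.  A 2D en-face MIP falls back
    to the per-column median.
    """
    stat = stripe_level(oca)
    center = np.median(stat)
    mad = np.median(np.abs(stat - center)) * 1.4826
    if mad <= 0:
        mad = np.std(stat) + 1e-12
    return (stat - center) / mad


# ---------------------------------------------------------------------------
# Optimally oriented flux

def oof_vesselness(image: np.ndarray, radii, sigma: float = 1.0):
    """Optimally-oriented-flux vesselness for bright curvilinear structures.

    The oriented-flux matrix at radius r is the flux of the smoothed image
    gradient through a sphere (circle in 2D) of radius r, as a quadratic
    form in the orientation; by the divergence theorem it equals the Hessian
    of the Gaussian-smoothed image convolved with the ball indicator.  The
    response is the rectified negative mean of the d-1 cross-sectional
    eigenvalues, normalized by the sphere surface (circle perimeter), and is
    maximal when r matches the tube radius.

    Returns ``(response, scale_map)`` with ``response >= 0`` and
    ``scale_map`` the argmax radius per pixel.
    """
    img = np.asarray(image, np.float64)
    nd = img.ndim
    if nd not in (2, 3):
        raise ValueError("image must be 2D or 3D")
    radii = sorted(float(r) for r in radii)
    if not radii or radii[0] <= 0:
        raise ValueError("radii must be non-empty and positive")
    if max(radii) > min(img.shape) / 2:
        raise ValueError("radius exceeds half the image extent")

    # second-derivative (Hessian) components of the smoothed image; the
    # global mean is removed first so a constant image responds exactly
    # zero (discrete derivative kernels have a tiny truncation residual)
    img = img - img.mean()
    axes = range(nd)
    hess = {}
    for i in axes:
        for j in axes:
            if j < i:
                continue
            order = [0] * nd
            order[i] += 1
            order[j] += 1
            hess[(i, j)] = ndimage.gaussian_filter(img, sigma, order=order,
                                                   mode="nearest")
    best = np.zeros(img.shape)
    best_scale = np.full(img.shape, radii[0])
    for r in radii:
        ball = _ball_kernel(r, nd)
        area = (2 * math.pi * r) if nd == 2 else (4 * math.pi * r ** 2)
        q = np.empty(img.shape + (nd, nd))
        for (i, j), h in hess.items():
            flux = signal.fftconvolve(h, ball, mode="same") / area
            q[..., i, j] = flux
            q[..., j, i] = flux
        lam = np.linalg.eigvalsh(q)           # ascending
        if nd == 2:
            resp = np.maximum(0.0, -lam[..., 0])
        else:
            resp = np.maximum(0.0, -(lam[..., 0] + lam[..., 1]) / 2.0)
        take = resp > best
        best[take] = resp[take]
        best_scale[take] = r
    return best, best_scale


def _ball_kernel(r: float, nd: int) -> np.ndarray:
    n = int(math.ceil(r)) * 2 + 1
    c = n // 2
    grid = np.indices((n,) * nd) - c
    return (np.sqrt((grid ** 2).sum(axis=0)) <= r + 1e-9).astype(np.float64)


# ---------------------------------------------------------------------------
# Binarization

@dataclass
class VesselnessMask:
    mask: np.ndarray                     # bool
    provenance: str = "oof"              # 'oof' or 'inpainted'
    inpainted_region: np.ndarray | None = None
    warning: str | None = None


def binarize_vesselness(vesselness: np.ndarray,
                        image: np.ndarray | None = None,
                        low_frac: float = 0.25, gate_frac: float = 0.5,
                        min_size: int = 5) -> VesselnessMask:
    """Hysteresis-threshold a vesselness map and drop small objects.

    The high threshold is Otsu's threshold of the positive response support
    (vesselness scales with image contrast, so rank-based cuts are unstable
    across vessel densities); the low threshold is ``low_frac`` of it.
    When the underlying ``image`` is given, mask voxels must additionally
    exceed ``gate_frac`` times Otsu's threshold of the image inside the
    mask, which trims the halo the flux ball paints around each tube.
    """
    v = np.asarray(vesselness, np.float64)
    if not np.isfinite(v).all():
        raise ValueError("vesselness map must be finite")
    support = v[v > 0]
    if support.size == 0 or v.max() == v.min() or support.max() == support.min():
        return VesselnessMask(np.zeros(v.shape, bool), "oof",
                              warning="degenerate vesselness map")
    hi = filters.threshold_otsu(support)
    lo = low_frac * hi
    mask = filters.apply_hysteresis_threshold(v, lo, hi)
    if image is not None and mask.any():
        img = np.asarray(image, np.float64)
        inside = img[mask]
        if inside.max() > inside.min():
            mask &= img > gate_frac * filters.threshold_otsu(inside)
    mask = morphology.remove_small_objects(mask, max_size=min_size - 1)
    return VesselnessMask(mask.astype(bool), "oof")


# ---------------------------------------------------------------------------
# Self-supervised inpainting

@dataclass
class InpaintConfig:
    iterations: int = 300
    patch_size: int = 64
    batch: int = 4
    lr: float = 1e-2
    base_channels: int = 8
    stripe_width_range: tuple[int, int] = (4, 32)
    stripes_per_patch: tuple[int, int] = (1, 2)
    seed: int = 0
    val_fraction: float = 0.15


@dataclass
class InpaintModel:
    net: nn.UNet
    manifest: dict

    def save(self, stem) -> None:
        nn.save_model(stem, self.net, self.manifest)

    @classmethod
    def load(cls, stem) -> "InpaintModel":
        net = nn.UNet(3, 1, np.random.default_rng(0), nd=2, base=8,
                      gated=True)
        manifest = nn.load_model(stem, net)
        return cls(net, manifest)

    def predict_prob(self, occluded_mask, occlusion, guidance) -> np.ndarray:
        """Occlusion-fill probability, averaged over the four axis-flip
        symmetries (vessel masks have no preferred orientation, so flip
        averaging reduces prediction variance at no training cost)."""
        x = np.stack([occluded_mask, occlusion, guidance]).astype(np.float32)
        acc = np.zeros(x.shape[1:], np.float64)
        for fx in (1, -1):
            for fy in (1, -1):
                xf = np.ascontiguousarray(x[:, ::fx, ::fy])
                z = self.net.forward(xf[None])
                acc += nn.sigmoid(z[0, 0])[::fx, ::fy]
        return (acc / 4.0).astype(np.float32)


def _guidance(mip: np.ndarray) -> np.ndarray:
    g = np.hypot(*np.gradient(np.asarray(mip, np.float64)))
    hi = np.percentile(g, 99)
    return (g / (hi + 1e-12)).clip(0, 2).astype(np.float32)


def make_inpaint_training_pairs(mask: np.ndarray, mip: np.ndarray,
                                n_patches: int,
                                cfg: InpaintConfig | None = None,
                                stripes: StripeMask | None = None,
                                seed: int | None = None):
    """Build (occluded, target, weight) patch tuples from one image.

    Synthetic vertical (slow-axis) stripes of log-uniform width are drawn
    over clean columns of the vessel mask; the original mask is the target.
    Columns inside genuinely detected stripes are occluded in the input too
    but carry zero loss weight — their truth is unknown — so every patch
    position is usable and all clean structure contributes.  Inputs are 3
    channels: occluded mask, occlusion indicator, and a MIP
    gradient-magnitude guidance channel.  Inside synthetic stripes the
    guidance is mixed with shuffled-gradient noise by a random factor,
    mimicking real stripes whose gradients retain structure only partially;
    the net learns to exploit guidance when informative and to fall back on
    mask continuation otherwise.  Deterministic under ``seed``.

    Returns ``(X, Y, W)``: inputs (n, 3, ps, ps), targets (n, 1, ps, ps),
    per-pixel loss weights (n, 1, ps, ps).
    """
    cfg = cfg or InpaintConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    mask = np.asarray(mask, np.float32)
    nx, ny = mask.shape
    ps = cfg.patch_size
    if nx < ps or ny < ps:
        raise ValueError(f"image smaller than patch size {ps}")
    dirty = (stripes.columns() if stripes is not None
             else np.zeros(ny, bool))
    wmin, wmax = cfg.stripe_width_range
    if wmax > ps:
        raise ValueError("stripe width exceeds patch size")
    clean_runs = _max_clean_run(~dirty)
    if clean_runs < wmin:
        raise ValueError("no clean area wide enough for the requested "
                         "stripe widths")
    guid = _guidance(mip)
    out_w = 0.1
    X = np.empty((n_patches, 3, ps, ps), np.float32)
    Y = np.empty((n_patches, 1, ps, ps), np.float32)
    W = np.empty((n_patches, 1, ps, ps), np.float32)
    for k in range(n_patches):
        x0 = int(rng.integers(0, nx - ps + 1))
        y0 = int(rng.integers(0, ny - ps + 1))
        cols_dirty = dirty[y0:y0 + ps]
        tgt = mask[x0:x0 + ps, y0:y0 + ps]
        gpatch = guid[x0:x0 + ps, y0:y0 + ps].copy()
        occluded = tgt.copy()
        occluded[:, cols_dirty] = 0.0
        occ = np.zeros((ps, ps), np.float32)
        occ[:, cols_dirty] = 1.0
        w = np.full((ps, ps), out_w, np.float32)
        w[:, cols_dirty] = 0.0
        n_str = int(rng.integers(cfg.stripes_per_patch[0],
                                 cfg.stripes_per_patch[1] + 1))
        for _ in range(n_str):
            if wmax > wmin:
                width = int(round(math.exp(rng.uniform(math.log(wmin),
                                                       math.log(wmax)))))
            else:
                width = wmin
            width = min(width, ps)
            s0 = int(rng.integers(0, ps - width + 1))
            band = slice(s0, s0 + width)
            occluded[:, band] = 0.0
            occ[:, band] = 1.0
            synth_clean = ~cols_dirty[band]
            w[:, band][:, synth_clean] = 1.0
            keep = rng.uniform(0.0, 1.0)
            g = gpatch[:, band]
            scrambled = rng.permutation(g.ravel()).reshape(g.shape)
            gpatch[:, band] = keep * g + (1 - keep) * scrambled
        X[k, 0] = occluded
        X[k, 1] = occ
        X[k, 2] = gpatch
        Y[k, 0] = tgt
        W[k, 0] = w
    return X, Y, W


def _max_clean_run(clean: np.ndarray) -> int:
    best = run = 0
    for c in clean:
        run = run + 1 if c else 0
        best = max(best, run)
    return best


def _bce_loss_grad(logits, target, w, pos_weight: float = 1.0):
    """Weighted binary cross-entropy; ``pos_weight`` counteracts the
    vessel/background class imbalance inside occluded stripes."""
    w = w * (1.0 + (pos_weight - 1.0) * target)
    p = nn.sigmoid(logits)
    eps = 1e-7
    loss = -(w * (target * np.log(p + eps)
                  + (1 - target) * np.log(1 - p + eps))).mean()
    grad = (w * (p - target) / w.size).astype(np.float32)
    return float(loss), grad


def train_inpainting(pairs, cfg: InpaintConfig | None = None) -> InpaintModel:
    """Train the gated-convolution inpainting net on synthetic-stripe pairs.

    Loss is binary cross-entropy, weighted 1.0 inside occluded stripes and
    0.1 outside so capacity concentrates on recovery.  A held-out fraction
    of the pairs tracks generalization; losses per logging step land in the
    manifest.
    """
    cfg = cfg or InpaintConfig()
    X, Y, W = pairs
    if len(X) < 1:
        raise ValueError("need at least one training pair")
    rng = np.random.default_rng(cfg.seed)
    n_val = max(1, int(len(X) * cfg.val_fraction)) if len(X) > 1 else 0
    perm = rng.permutation(len(X))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0:
        train_idx = perm
    net = nn.UNet(3, 1, rng, nd=2, base=cfg.base_channels, gated=True)
    opt = nn.Adam(net.params(), lr=cfg.lr)
    # vessel pixels are a small minority of the supervised area
    pos = float((W * Y).sum())
    neg = float((W * (1.0 - Y)).sum())
    pos_weight = float(np.clip(neg / max(pos, 1.0), 1.0, 10.0))

    def eval_loss(idx):
        if len(idx) == 0:
            return float("nan")
        tot = 0.0
        for i in idx:
            z = net.forward(X[i:i + 1])
            l, _ = _bce_loss_grad(z, Y[i:i + 1], W[i:i + 1], pos_weight)
            tot += l
        return tot / len(idx)

    init_val = eval_loss(val_idx if n_val else train_idx[:4])
    losses = []
    for it in range(cfg.iterations):
        sel = rng.integers(0, len(train_idx), cfg.batch)
        idx = train_idx[sel]
        xb, yb, wb = X[idx], Y[idx], W[idx]
        z = net.forward(xb)
        loss, grad = _bce_loss_grad(z, yb, wb, pos_weight)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"inpainting training diverged at iteration {it}")
        opt.zero_grad()
        net.backward(grad)
        opt.lr = cfg.lr * (1.0 - 0.9 * it / max(cfg.iterations - 1, 1))
        opt.step()
        losses.append(loss)
    final_val = eval_loss(val_idx if n_val else train_idx[:4])
    k = max(1, len(losses) // 10)
    manifest = {
        "kind": "inpaint", "iterations": cfg.iterations, "seed": cfg.seed,
        "patch_size": cfg.patch_size, "base_channels": cfg.base_channels,
        "init_loss": float(np.mean(losses[:k])),
        "final_loss": float(np.mean(losses[-k:])),
        "init_val_loss": float(init_val), "final_val_loss": float(final_val),
        "losses": [float(v) for v in losses[::10]],
    }
    return InpaintModel(net, manifest)


def inpaint_stripes(mask: VesselnessMask, stripes: StripeMask,
                    model: InpaintModel, guidance_mip: np.ndarray
                    ) -> VesselnessMask:
    """Recover the vessel mask inside detected stripe bands.

    Pixels outside the bands are copied bit-exactly; inside, the model's
    thresholded probability fills the gap.  Provenance is marked
    'inpainted' over the recovered region.
    """
    m = np.asarray(mask.mask, bool)
    nx, ny = m.shape
    if stripes.n_slow != ny:
        raise ValueError("stripe mask does not match image slow axis")
    if stripes.empty:
        return VesselnessMask(m.copy(), mask.provenance,
                              inpainted_region=np.zeros_like(m))
    cols = stripes.columns()
    occluded = m.astype(np.float32)
    occluded[:, cols] = 0.0
    occ = np.zeros((nx, ny), np.float32)
    occ[:, cols] = 1.0
    guid = _guidance(guidance_mip)

    ps = int(model.manifest.get("patch_size", 64))
    prob = np.zeros((nx, ny), np.float64)
    weight = np.zeros((nx, ny), np.float64)
    step = max(1, ps // 2)
    xs = sorted({min(x0, max(0, nx - ps)) for x0 in range(0, nx, step)})
    ys = sorted({min(y0, max(0, ny - ps)) for y0 in range(0, ny, step)})
    for x0 in xs:
        for y0 in ys:
            sl = (slice(x0, x0 + ps), slice(y0, y0 + ps))
            p = model.predict_prob(occluded[sl], occ[sl], guid[sl])
            prob[sl] += p
            weight[sl] += 1.0
    prob /= np.maximum(weight, 1.0)
    out = m.copy()
    region = occ.astype(bool)
    out[region] = prob[region] > 0.5
    return VesselnessMask(out, "inpainted", inpainted_region=region)


def enhance_oca(mip: np.ndarray, mask: VesselnessMask) -> np.ndarray:
    """Mask-multiplication enhancement: zero background, keep vessels."""
    mip = np.asarray(mip)
    m = np.asarray(mask.mask)
    if mip.shape != m.shape:
        raise ValueError(f"shape mismatch {mip.shape} vs {m.shape}")
    return mip * m
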