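"""Self-supervised 3D µODT enhancement via intensity remapping and vessel
cropping.

The enhancer learns vascular features that are invariant to vessel
brightness (Intensity Remapping: random monotone maps drawn from the
volume's own intensity quantiles) and that promote connectivity (Vessel
Cropping: random centerline segments replaced by background-level noise,
which the net must restore).  Training consumes single noisy volumes only —
no clean targets, no noisy/noisy pairs.  A 3-level U-shaped 3D CNN maps a
remapped, cropped patch back to the original patch; because the remap is
unknown to the network, copying the input is not a solution and the
prediction regresses toward the structure shared across augmentations,
which suppresses background noise and re-links broken segments.

Phase-signed Doppler data are enhanced on |dphi| with the sign reattached
afterwards, so enhancement never flips flow direction.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from . import nn
from .motion_inpaint import binarize_vesselness, oof_vesselness
from .recon import ODTVolume


@dataclass
class AugmentationSpec:
    """Intensity-remap and vessel-crop parameters.

    ``n_control`` quantile-anchored control points define each monotone
    piecewise-linear remap; ``crop_fraction`` is the fraction of centerline
    segments dropped; segment lengths are drawn in ``segment_len_range``
    voxels.
    """

    n_control: int = 6
    crop_fraction: float = 0.3
    segment_len_range: tuple[int, int] = (4, 12)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.crop_fraction < 1.0:
            raise ValueError("crop_fraction must lie in [0, 1)")
        if self.n_control < 2:
            raise ValueError("need at least 2 control points")


def draw_remap(volume: np.ndarray, spec: AugmentationSpec,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw monotone control points anchored at the volume's intensity
    quantiles; returns (xs, ys) for ``numpy.interp``.

    Segment slopes are drawn log-uniform in [1/2.5, 2.5] and the endpoints
    re-anchored, so vessels change brightness substantially but the map
    stays invertible in practice — a remap with unbounded slopes would make
    restoring the original intensities from a remapped patch hopeless.
    """
    v = np.asarray(volume, np.float64).ravel()
    qs = np.linspace(0.0, 1.0, spec.n_control)
    xs = np.quantile(v, qs)
    xs = np.maximum.accumulate(xs)
    xs += np.arange(len(xs)) * 1e-9          # strict monotonicity
    span = xs[-1] - xs[0]
    slopes = np.exp(rng.uniform(np.log(1 / 2.5), np.log(2.5),
                                spec.n_control - 1))
    dy = np.diff(xs) * slopes
    ys = xs[0] + np.concatenate([[0.0], np.cumsum(dy)])
    ys = xs[0] + (ys - ys[0]) / max(ys[-1] - ys[0], 1e-12) * span
    ys += np.arange(len(ys)) * 1e-9
    return xs, ys


def intensity_remap(volume: np.ndarray,
                    spec: AugmentationSpec | None = None,
                    control_points: tuple | None = None,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply a strictly monotone piecewise-linear intensity map.

    With no explicit ``control_points`` a map is drawn from the volume's
    empirical quantiles (seeded through ``spec.seed`` unless an ``rng`` is
    passed).  Rank order of voxel intensities is preserved exactly.
    """
    spec = spec or AugmentationSpec()
    vol = np.asarray(volume, np.float64)
    if control_points is None:
        rng = rng or np.random.default_rng(spec.seed)
        xs, ys = draw_remap(vol, spec, rng)
    else:
        xs, ys = (np.asarray(a, np.float64) for a in control_points)
        if (np.diff(xs) <= 0).any() or (np.diff(ys) <= 0).any():
            raise ValueError("control points must be strictly monotone")
    return np.interp(vol, xs, ys).astype(np.float32)


def _skeleton_segments(mask: np.ndarray, seg_len_range, rng
                       ) -> list[np.ndarray]:
    """Skeletonize a mask and chop the skeleton into short voxel chains."""
    skel = morphology.skeletonize(mask)
    coords = np.argwhere(skel)
    if len(coords) == 0:
        return []
    index = {tuple(c): i for i, c in enumerate(coords)}
    visited = np.zeros(len(coords), bool)
    segments = []
    lo, hi = seg_len_range
    order = rng.permutation(len(coords))
    offsets = [np.array(o) for o in np.ndindex(3, 3, 3)
               if o != (1, 1, 1)]
    for start in order:
        if visited[start]:
            continue
        target = int(rng.integers(lo, hi + 1))
        chain = [start]
        visited[start] = True
        cur = coords[start]
        while len(chain) < target:
            nxt = None
            for off in offsets:
                cand = tuple(cur + off - 1)
                j = index.get(cand)
                if j is not None and not visited[j]:
                    nxt = j
                    break
            if nxt is None:
                break
            visited[nxt] = True
            chain.append(nxt)
            cur = coords[nxt]
        segments.append(coords[chain])
    return segments


def vessel_crop(volume: np.ndarray, mask: np.ndarray,
                spec: AugmentationSpec | None = None,
                rng: np.random.Generator | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Drop a fraction of centerline segments, filling with background noise.

    Returns ``(cropped_volume, dropped_record)`` where the record is a
    boolean volume locating every voxel that was replaced.
    """
    spec = spec or AugmentationSpec()
    vol = np.asarray(volume, np.float32).copy()
    m = np.asarray(mask, bool)
    if not m.any():
        raise ValueError("provisional mask is empty")
    rng = rng or np.random.default_rng(spec.seed)
    if spec.crop_fraction == 0.0:
        return vol, np.zeros_like(m)
    segments = _skeleton_segments(m, spec.segment_len_range, rng)
    if not segments:
        return vol, np.zeros_like(m)
    if spec.crop_fraction >= 0.9:
        raise ValueError("crop_fraction too large: no segment would remain")
    # drop random segments (with their local-radius sleeve) until the
    # dropped voxel count reaches crop_fraction of the vessel voxels
    dist = ndimage.distance_transform_edt(m)
    target = spec.crop_fraction * int(m.sum())
    record = np.zeros(m.shape, bool)
    order = rng.permutation(len(segments))
    for i in order:
        if record.sum() >= target:
            break
        pts = segments[i]
        r = float(dist[tuple(pts.T)].max()) + 0.5  # local sleeve radius
        lo = np.maximum(pts.min(axis=0) - int(np.ceil(r)), 0)
        hi = np.minimum(pts.max(axis=0) + int(np.ceil(r)) + 1, m.shape)
        box = tuple(slice(a, b) for a, b in zip(lo, hi))
        sub = np.zeros(tuple(hi - lo), bool)
        sub[tuple((pts - lo).T)] = True
        d = ndimage.distance_transform_edt(~sub)
        record[box] |= (d <= r) & m[box]
    if not record.any():
        return vol, np.zeros_like(m)
    bg = vol[~m]
    bg_med = float(np.median(bg)) if bg.size else 0.0
    bg_mad = float(np.median(np.abs(bg - bg_med)) * 1.4826) if bg.size else 0.0
    vol[record] = (bg_med
                   + bg_mad * rng.standard_normal(int(record.sum()))
                   ).astype(np.float32)
    return vol, record


# ---------------------------------------------------------------------------
# Training

_BALL2 = ndimage.generate_binary_structure(3, 1)
_BALL2 = ndimage.iterate_structure(_BALL2, 2)


@dataclass
class EnhanceConfig:
    iterations: int = 200
    patch: int = 32
    lr: float = 1e-2
    base_channels: int = 8
    seed: int = 0
    consistency_every: int = 4      # add the two-remap consistency term 1/k iters
    oof_radii: tuple = (1.0, 2.0, 3.0)


@dataclass
class EnhanceModel:
    net: nn.UNet
    manifest: dict

    def save(self, stem) -> None:
        nn.save_model(stem, self.net, self.manifest)

    @classmethod
    def load(cls, stem) -> "EnhanceModel":
        net = nn.UNet(1, 1, np.random.default_rng(0), nd=3, base=8,
                      gated=False)
        manifest = nn.load_model(stem, net)
        return cls(net, manifest)


def _normalize(mag: np.ndarray) -> tuple[np.ndarray, float, float]:
    lo, hi = np.percentile(mag, [1.0, 99.0])
    if hi <= lo:
        hi = lo + 1e-6
    return ((mag - lo) / (hi - lo)).astype(np.float32), float(lo), float(hi)


def train_enhancer(volumes, spec: AugmentationSpec | None = None,
                   cfg: EnhanceConfig | None = None) -> EnhanceModel:
    """Train the 3D enhancement net on single noisy µODT volumes.

    Per iteration a random patch is cropped (VC) and remapped (IR); the net
    predicts the original normalized patch.  Composite loss: L1 on dropped
    segments + 0.5x L1 elsewhere + 0.1x consistency between predictions
    under two independent remaps.
    """
    spec = spec or AugmentationSpec()
    cfg = cfg or EnhanceConfig()
    if isinstance(volumes, np.ndarray):
        volumes = [volumes]
    if len(volumes) < 1:
        raise ValueError("need at least one volume")
    rng = np.random.default_rng(cfg.seed)

    prepared = []
    for vol in volumes:
        arr = vol.data if isinstance(vol, ODTVolume) else np.asarray(vol)
        mag = np.abs(arr).astype(np.float32)
        norm, lo, hi = _normalize(mag)
        vness, _ = oof_vesselness(norm, cfg.oof_radii)
        pmask = binarize_vesselness(vness, norm).mask
        prepared.append((norm, pmask, lo, hi))

    net = nn.UNet(1, 1, rng, nd=3, base=cfg.base_channels, gated=False)
    opt = nn.Adam(net.params(), lr=cfg.lr)
    ps = cfg.patch
    losses = []

    min_vessel = max(20, int(0.005 * ps ** 3))

    def sample_patch():
        norm, pmask, _, _ = prepared[int(rng.integers(0, len(prepared)))]
        best, best_count = None, -1
        for _ in range(10):
            c = [int(rng.integers(0, s - ps + 1)) for s in norm.shape]
            sl = tuple(slice(c0, c0 + ps) for c0 in c)
            count = int(pmask[sl].sum())
            if count >= min_vessel:
                return norm[sl], pmask[sl]
            if count > best_count:
                best, best_count = sl, count
        return norm[best], pmask[best]

    for it in range(cfg.iterations):
        patch, pmask = sample_patch()
        if pmask.any() and spec.crop_fraction > 0:
            cropped, record = vessel_crop(patch, pmask, spec, rng)
        else:
            cropped, record = patch.copy(), np.zeros(patch.shape, bool)
        # blind-spot background: resample a fraction of background voxels
        # so the net cannot copy their noise and regresses to the local
        # level instead (the same masking idea vessel cropping applies to
        # the lumen), which is what suppresses background noise
        bg = ~pmask
        bg_vals = cropped[bg]
        bg_med = float(np.median(bg_vals))
        bg_mad = float(np.median(np.abs(bg_vals - bg_med)) * 1.4826)
        blind = bg & (rng.random(patch.shape) < 0.6)
        cropped = cropped.copy()
        cropped[blind] = bg_med + bg_mad * rng.standard_normal(
            int(blind.sum())).astype(np.float32)
        # half the iterations see the identity map, anchoring absolute
        # intensity; the other half see a random remap, teaching invariance
        if rng.random() < 0.5:
            x1 = intensity_remap(cropped, spec, rng=rng)[None, None]
        else:
            x1 = cropped[None, None].astype(np.float32)
        target = patch[None, None]
        # class-balanced weights: the lumen occupies a few percent of the
        # voxels, so without re-weighting the L1 is minimized by the
        # background constant and the net never learns vessels
        n_v = max(int(pmask.sum()), 1)
        n_b = pmask.size - n_v
        w_vessel = float(np.clip(0.5 * n_b / n_v, 1.0, 10.0))
        w = np.full(patch.shape, 0.05, np.float32)
        w[blind] = 0.5
        # the background shell hugging each vessel gets vessel-level weight:
        # without it the net smears tubes outward (halo), since dim false
        # positives next to a 10x-weighted lumen cost almost nothing
        shell = ndimage.binary_dilation(pmask, _BALL2) & ~pmask
        w[shell] = w_vessel
        w[pmask] = w_vessel
        w[record] = 2.0 * w_vessel
        w = w[None, None]

        consistency = (cfg.consistency_every > 0
                       and it % cfg.consistency_every == 0)
        y1 = net.forward(x1)
        r1 = y1 - target
        loss = float(np.mean(w * np.abs(r1)))
        g1 = (w * np.sign(r1) / r1.size).astype(np.float32)
        opt.zero_grad()
        if consistency:
            net2_cache_x = intensity_remap(cropped, spec, rng=rng)[None, None]
            y1_detached = y1.copy()
            net.backward(g1)
            y2 = net.forward(net2_cache_x)
            rc = y2 - y1_detached
            loss += 0.1 * float(np.mean(np.abs(rc)))
            gc = (0.1 * np.sign(rc) / rc.size).astype(np.float32)
            net.backward(gc)
        else:
            net.backward(g1)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"enhancer training diverged at iteration {it}")
        # linear decay to 10% of the base rate over the run
        opt.lr = cfg.lr * (1.0 - 0.9 * it / max(cfg.iterations - 1, 1))
        opt.step()
        losses.append(loss)

    k = max(1, len(losses) // 10)
    manifest = {
        "kind": "enhance", "iterations": cfg.iterations, "seed": cfg.seed,
        "patch": ps, "base_channels": cfg.base_channels,
        "crop_fraction": spec.crop_fraction,
        "normalization": "percentile-1-99 of |dphi|, per volume",
        "init_loss": float(np.mean(losses[:k])),
        "final_loss": float(np.mean(losses[-k:])),
        "losses": [float(v) for v in losses[::5]],
    }
    return EnhanceModel(net, manifest)


def enhance_volume(volume, model: EnhanceModel,
                   tile: int | None = None, overlap: int = 8):
    """Denoise a µODT volume with a trained enhancer.

    The volume's |dphi| is normalized with the same percentile scheme the
    training used, tiled through the net with overlap blending, rescaled,
    and the original sign reattached.  Accepts an ``ODTVolume`` (returned as
    one) or a bare array.
    """
    is_odt = isinstance(volume, ODTVolume)
    arr = volume.data if is_odt else np.asarray(volume)
    sign = np.sign(arr)
    sign[sign == 0] = 1.0
    mag = np.abs(arr).astype(np.float32)
    norm, lo, hi = _normalize(mag)
    ps = tile or int(model.manifest.get("patch", 32))
    if any(s < ps for s in norm.shape):
        raise ValueError("volume smaller than the network tile")
    step = max(1, ps - overlap)
    acc = np.zeros(norm.shape, np.float64)
    wacc = np.zeros(norm.shape, np.float64)
    win1 = np.hanning(ps + 2)[1:-1] + 1e-3
    win = win1[:, None, None] * win1[None, :, None] * win1[None, None, :]
    starts = [sorted({min(s0, n - ps) for s0 in range(0, n, step)})
              for n in norm.shape]
    for z0 in starts[0]:
        for x0 in starts[1]:
            for y0 in starts[2]:
                sl = (slice(z0, z0 + ps), slice(x0, x0 + ps),
                      slice(y0, y0 + ps))
                y = model.net.forward(norm[sl][None, None])[0, 0]
                acc[sl] += y * win
                wacc[sl] += win
    out_norm = (acc / wacc).astype(np.float32)
    out_mag = np.clip(out_norm, 0.0, None) * (hi - lo) + lo
    out_mag = np.clip(out_mag, 0.0, None)
    out = (sign * out_mag).astype(np.float32)
    if is_odt:
        return ODTVolume(out, volume.params, units=volume.units,
                         angle_corrected=volume.angle_corrected)
    return out
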