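"""Doppler (µODT) and angiography (µOCA) reconstruction from repeated B-scans.

µODT: the Doppler frequency shift is derived from the phase difference
between two adjacent A-scans, estimated as the argument of the lag-1 complex
autocorrelation along the fast axis, averaged over a small (z, x) window and
over all repeated frames.  Output stays in phase units (rad, (-pi, pi]);
conversion to velocity and Doppler-angle correction live in
:mod:`odtflow.vessel_quant` because displayed µODT images are conventionally
not angle corrected.

µOCA: the speckle variance (normalized standard deviation, i.e. coefficient
of variation of intensity) across the most mutually correlated subset of the
repeated frames.  Correlation-based frame selection rejects frames
decorrelated by bulk motion before the variance is formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
from scipy import ndimage

from .params import AcquisitionParams
from .phantom import ComplexAcquisition


@dataclass
class ReconConfig:
    """Frame-selection and phase-averaging knobs.

    ``n_select``/``r_threshold`` default to the awake-protocol operating
    point (N' = 6 frames, Pearson r > 0.9).
    """

    n_select: int = 6
    r_threshold: float = 0.9
    phase_window: tuple[int, int] = (3, 3)

    def validate(self, n_repeats: int) -> None:
        if not 2 <= self.n_select <= n_repeats:
            raise ValueError("n_select must lie in [2, n_repeats]")
        if not 0.0 < self.r_threshold < 1.0:
            raise ValueError("r_threshold must lie in (0, 1)")


@dataclass
class ODTVolume:
    """Signed Doppler phase-difference volume, (z, x, y)."""

    data: np.ndarray
    params: AcquisitionParams
    units: str = "rad"
    angle_corrected: bool = False
    low_confidence: np.ndarray | None = None


@dataclass
class OCAVolume:
    """Speckle-variance volume, (z, x, y), dimensionless >= 0.

    ``data`` has the low-SNR floor applied (display/segmentation);
    ``raw`` is the unfloored coefficient of variation, which stripe
    detection prefers because the background noise level is exactly what
    bulk motion perturbs.
    """

    data: np.ndarray
    frames_used: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    raw: np.ndarray | None = None


@dataclass
class SelectionResult:
    indices: list[int]
    warning: bool
    r_corr: np.ndarray


def phase_subtraction_odt(acq: ComplexAcquisition,
                          cfg: ReconConfig | None = None) -> ODTVolume:
    """Reconstruct the Doppler phase-difference volume.

    Per voxel the lag-1 product of adjacent A-scans (adjacent x columns) is
    formed, averaged over all repeats and over ``cfg.phase_window`` (z, x)
    voxels, and its argument taken.  Zero-amplitude voxels get phase 0 and a
    low-confidence flag.
    """
    cfg = cfg or ReconConfig()
    fld = acq.field
    nz, nx, nr, ny = fld.shape
    if nx < 2:
        raise ValueError("need >= 2 A-scans per Doppler pair")
    prod = fld[:, 1:, :, :] * np.conj(fld[:, :-1, :, :])
    prod = prod.mean(axis=2)                       # average over repeats
    # product at fast-axis index x describes the voxel at x (pair x-1, x)
    full = np.empty((nz, nx, ny), np.complex64)
    full[:, 1:, :] = prod
    full[:, 0, :] = prod[:, 0, :]
    wz, wx = cfg.phase_window
    if wz > 1 or wx > 1:
        re = ndimage.uniform_filter(full.real, size=(wz, wx, 1))
        im = ndimage.uniform_filter(full.imag, size=(wz, wx, 1))
        full = re + 1j * im
    amp = np.abs(full)
    low = amp < 1e-12
    dphi = np.angle(full).astype(np.float32)
    dphi[low] = 0.0
    return ODTVolume(dphi, acq.params, units="rad",
                     angle_corrected=False, low_confidence=low)


def _log_compress(frames: np.ndarray) -> np.ndarray:
    return np.log1p(frames / (np.mean(frames) + 1e-30))


def select_correlated_bscans(frames: np.ndarray,
                             cfg: ReconConfig | None = None
                             ) -> SelectionResult:
    """Pick the most mutually correlated repeated frames.

    ``frames`` has shape (R, ...) of intensities.  Correlation is Pearson's
    r between log-compressed frames, restricted to the temporally stable
    half of the voxels (lowest variance across frames): flowing lumina
    decorrelate even between perfectly registered frames, so whole-frame
    correlation would punish vessel-dense cross-sections, while the static
    parenchyma isolates genuine bulk-motion decorrelation.  The reference
    is the frame with the highest mean correlation to its ``n_select - 1``
    best partners, which stays on a clean frame as long as at least
    ``n_select`` clean frames survive — even when more than half the
    repeats are motion corrupted.  Frames with r > ``cfg.r_threshold``
    against the reference qualify; if more than ``n_select`` qualify, the
    ``n_select`` with the highest mean mutual correlation are kept.  Fewer
    than 2 qualifying frames degrades gracefully to the best 2 with a
    warning.  Returned indices are ascending; ties break toward lower
    index.
    """
    cfg = cfg or ReconConfig()
    nrep = frames.shape[0]
    if nrep < 2:
        raise ValueError("need at least 2 frames")
    cfg.validate(nrep)
    flat = _log_compress(np.asarray(frames, np.float64)).reshape(nrep, -1)
    tvar = flat.var(axis=0)
    static = tvar <= np.percentile(tvar, 50.0)
    flat = flat[:, static]
    flat = flat - flat.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(flat, axis=1)
    norm[norm == 0] = 1.0
    corr = (flat @ flat.T) / np.outer(norm, norm)
    np.fill_diagonal(corr, 1.0)
    k = min(cfg.n_select - 1, nrep - 1)
    off = np.where(np.eye(nrep, dtype=bool), -np.inf, corr)
    topk = -np.sort(-off, axis=1)[:, :k]
    ref = int(np.argmax(topk.mean(axis=1)))  # lowest index wins ties
    qualify = np.where(corr[ref] > cfg.r_threshold)[0]
    warning = False
    if len(qualify) < 2:
        warning = True
        order = np.argsort(-corr[ref], kind="stable")
        qualify = np.sort(order[:2])
    if len(qualify) > cfg.n_select:
        sub = corr[np.ix_(qualify, qualify)]
        mutual = (sub.sum(axis=1) - 1.0) / (len(qualify) - 1)
        order = np.argsort(-mutual, kind="stable")
        qualify = np.sort(qualify[order[:cfg.n_select]])
    return SelectionResult(sorted(int(i) for i in qualify), warning,
                           corr[ref])


def speckle_variance_oca(frames: np.ndarray) -> np.ndarray:
    """Coefficient of variation of intensity across frames (axis 0)."""
    frames = np.asarray(frames, np.float64)
    if frames.shape[0] < 2:
        raise ValueError("speckle variance needs >= 2 frames")
    mean = frames.mean(axis=0)
    std = frames.std(axis=0)
    out = np.zeros_like(mean)
    nz = mean != 0
    out[nz] = std[nz] / mean[nz]
    return out.astype(np.float32)


def oca_volume(acq: ComplexAcquisition,
               cfg: ReconConfig | None = None,
               intensity_floor_frac: float = 0.1) -> OCAVolume:
    """Reconstruct µOCA: per slow-axis position, select correlated frames
    and form the speckle variance over the selected subset.

    Voxels whose mean intensity falls below ``intensity_floor_frac`` times
    the volume's median mean-intensity are zeroed: in dark speckle the
    coefficient of variation is driven by detector noise, not by flow.
    """
    cfg = cfg or ReconConfig()
    intens = acq.intensity()                       # (z, x, r, y)
    nz, nx, nr, ny = intens.shape
    cfg.validate(nr)
    data = np.empty((nz, nx, ny), np.float32)
    meanvol = np.empty((nz, nx, ny), np.float32)
    used: list[list[int]] = []
    warns: list[int] = []
    for y in range(ny):
        stack = np.moveaxis(intens[:, :, :, y], 2, 0)   # (r, z, x)
        sel = select_correlated_bscans(stack, cfg)
        data[:, :, y] = speckle_variance_oca(stack[sel.indices])
        meanvol[:, :, y] = stack[sel.indices].mean(axis=0)
        used.append(sel.indices)
        if sel.warning:
            warns.append(y)
    raw = data.copy()
    if intensity_floor_frac > 0:
        data[meanvol < intensity_floor_frac * np.median(meanvol)] = 0.0
    return OCAVolume(data, used, warns, raw=raw)


def mip_project(volume: np.ndarray, axis: int = 0,
                depth_range: tuple[int, int] | None = None) -> np.ndarray:
    """Maximum-intensity projection over ``axis`` within a half-open range."""
    vol = np.asarray(volume)
    if depth_range is not None:
        lo, hi = depth_range
        n = vol.shape[axis]
        if not (0 <= lo < hi <= n):
            raise ValueError(f"empty or out-of-bounds depth range {depth_range}")
        vol = np.take(vol, np.arange(lo, hi), axis=axis)
    return vol.max(axis=axis)


def ratio_image(a, b, floor: float = 1e-3) -> np.ma.MaskedArray:
    """Relative-change volume (b - a) / a, masked where |a| < floor.

    ``a`` and ``b`` may be arrays or ODTVolumes on the same grid and in the
    same units; the result is a masked array, never +-inf.
    """
    ua = a.units if isinstance(a, ODTVolume) else None
    ub = b.units if isinstance(b, ODTVolume) else None
    if ua is not None and ub is not None and ua != ub:
        raise ValueError(f"unit mismatch: {ua} vs {ub}")
    da = a.data if isinstance(a, ODTVolume) else np.asarray(a, float)
    db = b.data if isinstance(b, ODTVolume) else np.asarray(b, float)
    if da.shape != db.shape:
        raise ValueError("volumes must share a grid")
    invalid = np.abs(da) < floor
    safe = np.where(invalid, 1.0, da)
    return np.ma.MaskedArray((db - da) / safe, mask=invalid)


def corrupted_fraction_oca(acq: ComplexAcquisition, z_thresh: float = 5.0
                           ) -> float:
    """Fraction of (y, r) frames whose intensity decorrelates from the
    per-position median frame (robust z on 1 - r)."""
    intens = acq.intensity()
    nz, nx, nr, ny = intens.shape
    bad = 0
    for y in range(ny):
        stack = _log_compress(intens[:, :, :, y].reshape(-1, nr).T)
        stack = stack - stack.mean(axis=1, keepdims=True)
        nrm = np.linalg.norm(stack, axis=1)
        nrm[nrm == 0] = 1.0
        ref = np.median(stack, axis=0)
        ref = ref - ref.mean()
        nref = np.linalg.norm(ref)
        nref = nref if nref > 0 else 1.0
        r = stack @ ref / (nrm * nref)
        bad += int((r < 0.5).sum())
    return bad / (nr * ny)


def corrupted_fraction_odt(acq: ComplexAcquisition, phase_thresh: float = 0.3
                           ) -> float:
    """Fraction of (y, r) frames whose per-frame Doppler map is noisy in
    static tissue (median |dphi| above ``phase_thresh`` rad where the truth
    says no flow)."""
    fld = acq.field
    nz, nx, nr, ny = fld.shape
    static = acq.truth["label"] == 0
    bad = 0
    for y in range(ny):
        for r in range(nr):
            frame = fld[:, :, r, y]
            prod = frame[:, 1:] * np.conj(frame[:, :-1])
            re = ndimage.uniform_filter(prod.real, 3)
            im = ndimage.uniform_filter(prod.imag, 3)
            dphi = np.abs(np.angle(re + 1j * im))
            m = static[:, 1:, y]
            if m.any() and np.median(dphi[m]) > phase_thresh:
                bad += 1
    return bad / (nr * ny)
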