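"""Physics-based phantom: vascular trees, complex OCT forward model, bulk motion.

The phantom replaces animal acquisitions.  It emulates, at the level the
downstream stages care about:

* fully developed speckle (complex circular Gaussian field, lumen brighter
  than parenchyma by a configurable factor);
* Doppler phase accumulation between adjacent A-scans: flow voxels carry a
  cumulative phase ramp along the fast axis so the lag-1 product of adjacent
  A-scans equals the local wrapped Doppler phase exactly;
* inter-repeat speckle decorrelation that grows with flow speed (the contrast
  mechanism of speckle-variance angiography);
* bulk motion: per-frame axial displacement (global phase + sub-voxel
  resampling) and severe per-frame scrambles that decorrelate whole B-scans.

Everything is seeded and ships a ground-truth sidecar so each reconstruction
and quantification stage can be checked against construction values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .params import AcquisitionParams, wrap_phase

# Murray's law for a symmetric bifurcation: r_child = 2^(-1/3) r_parent,
# which together with v_child = 2^(-1/3) v_parent conserves volumetric flow
# exactly (2 * pi * r_c^2 * v_c = pi * r_p^2 * v_p).
MURRAY_RATIO = 2.0 ** (-1.0 / 3.0)

ARTERIOLE, VENULE, CAPILLARY = "arteriole", "venule", "capillary"


@dataclass
class VesselSegment:
    start: np.ndarray          # (z, x, y) um
    end: np.ndarray            # (z, x, y) um
    radius: float              # um
    speed: float               # mean |v| along the axis, um/s
    parent: int | None
    compartment: str = CAPILLARY

    @property
    def direction(self) -> np.ndarray:
        d = self.end - self.start
        n = np.linalg.norm(d)
        return d / n if n > 0 else np.array([1.0, 0.0, 0.0])

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def theta_z_deg(self) -> float:
        """Doppler angle of the segment axis, degrees in [0, 90]."""
        return math.degrees(math.acos(min(1.0, abs(self.direction[0]))))

    @property
    def flow_rate(self) -> float:
        """Volumetric flow pi r^2 v, um^3/s."""
        return math.pi * self.radius ** 2 * self.speed


@dataclass
class VesselTree:
    """Acyclic vessel tree; ``flow_sense=+1`` means flow runs root->leaves."""

    segments: list[VesselSegment]
    flow_sense: int = +1

    def children(self, idx: int) -> list[int]:
        return [i for i, s in enumerate(self.segments) if s.parent == idx]

    def leaves(self) -> list[int]:
        has_child = {s.parent for s in self.segments if s.parent is not None}
        return [i for i in range(len(self.segments)) if i not in has_child]

    def flow_vector(self, idx: int) -> np.ndarray:
        """Velocity vector (um/s, (z,x,y)) of blood in segment ``idx``."""
        s = self.segments[idx]
        return self.flow_sense * s.speed * s.direction

    def check_flow_conservation(self, tol: float = 0.05) -> None:
        for i, s in enumerate(self.segments):
            kids = self.children(i)
            if not kids:
                continue
            q_in = s.flow_rate
            q_out = sum(self.segments[k].flow_rate for k in kids)
            if abs(q_out - q_in) > tol * q_in:
                raise AssertionError(
                    f"flow not conserved at segment {i}: {q_in} vs {q_out}")

    def max_depth_um(self) -> float:
        return max(max(s.start[0], s.end[0]) for s in self.segments)

    def to_json(self) -> str:
        return json.dumps({
            "flow_sense": self.flow_sense,
            "segments": [
                {"start": s.start.tolist(), "end": s.end.tolist(),
                 "radius": s.radius, "speed": s.speed, "parent": s.parent,
                 "compartment": s.compartment}
                for s in self.segments],
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "VesselTree":
        obj = json.loads(text)
        segs = [VesselSegment(np.array(d["start"], float),
                              np.array(d["end"], float),
                              d["radius"], d["speed"], d["parent"],
                              d["compartment"])
                for d in obj["segments"]]
        return cls(segs, obj["flow_sense"])


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = math.cos(angle), math.sin(angle)
    return (v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c))


def generate_vessel_tree(seed: int,
                         depth: int,
                         domain: Sequence[tuple[float, float]],
                         compartment_spec: dict | None = None) -> VesselTree:
    """Grow a binary-branching diving vessel tree inside ``domain``.

    Parameters
    ----------
    seed : int
        All geometry randomness flows from this.
    depth : int
        Number of bifurcation generations (0 = single root segment).
    domain : three (lo, hi) pairs
        Bounding box in um, (z, x, y) order, z increasing into tissue.
    compartment_spec : dict, optional
        Overrides: ``root_radius`` (um, default 8), ``root_speed`` (um/s,
        default 500), ``branch_angle_deg`` (default 35), ``flow_sense``
        (+1 arterial root->leaves, -1 venous), ``capillary_radius_um``
        (radius below which a segment counts as capillary, default 2.5),
        ``dive_depth_range`` ((lo, hi) um target depth of the trunk),
        ``length_ratio`` (default 0.75).
    """
    domain = [(float(lo), float(hi)) for lo, hi in domain]
    if depth < 0:
        raise ValueError("depth must be >= 0")
    for lo, hi in domain:
        if not hi > lo:
            raise ValueError("domain must be a non-empty box")
    spec = {
        "root_radius": 8.0, "root_speed": 500.0, "branch_angle_deg": 35.0,
        "flow_sense": +1, "capillary_radius_um": 2.5,
        "dive_depth_range": None, "length_ratio": 0.75,
    }
    spec.update(compartment_spec or {})
    rng = np.random.default_rng(seed)
    (z0, z1), (x0, x1), (y0, y1) = domain

    start = np.array([z0 + 0.05 * (z1 - z0),
                      x0 + (0.35 + 0.3 * rng.random()) * (x1 - x0),
                      y0 + (0.35 + 0.3 * rng.random()) * (y1 - y0)])
    if spec["dive_depth_range"] is not None:
        lo, hi = spec["dive_depth_range"]
        target_z = float(rng.uniform(lo + 0.25 * (hi - lo),
                                     lo + 0.75 * (hi - lo)))
        max_z = hi
    else:
        target_z = z0 + 0.45 * (z1 - z0)
        max_z = z1
    trunk_dir = np.array([1.0, 0.12 * (rng.random() - 0.5),
                          0.12 * (rng.random() - 0.5)])
    trunk_dir /= np.linalg.norm(trunk_dir)
    trunk_len = (target_z - start[0]) / trunk_dir[0]

    segments: list[VesselSegment] = []

    def clamp(p: np.ndarray) -> np.ndarray:
        return np.array([min(max(p[0], z0), min(z1, max_z)),
                         min(max(p[1], x0), x1),
                         min(max(p[2], y0), y1)])

    def grow(start_pt, direction, radius, speed, length, parent, level):
        end = clamp(start_pt + direction * length)
        idx = len(segments)
        segments.append(VesselSegment(start_pt.copy(), end, radius, speed,
                                      parent))
        if level >= depth:
            return
        for sign in (+1.0, -1.0):
            perp = np.cross(direction, rng.standard_normal(3))
            if np.linalg.norm(perp) < 1e-9:
                perp = np.cross(direction, np.array([0.0, 1.0, 0.0]))
            ang = math.radians(spec["branch_angle_deg"]
                               * (0.8 + 0.4 * rng.random()))
            child_dir = _rotate_about(direction, perp, sign * ang)
            # keep growth heading into tissue but never past the dive floor
            if end[0] >= min(z1, max_z) - 1e-6:
                child_dir[0] = -abs(child_dir[0])
            child_dir /= np.linalg.norm(child_dir)
            grow(end, child_dir, radius * MURRAY_RATIO, speed * MURRAY_RATIO,
                 length * spec["length_ratio"], idx, level + 1)

    grow(start, trunk_dir, spec["root_radius"], spec["root_speed"],
         trunk_len, None, 0)

    cutoff = spec["capillary_radius_um"]
    trunk_kind = ARTERIOLE if spec["flow_sense"] > 0 else VENULE
    for s in segments:
        s.compartment = trunk_kind if s.radius > cutoff else CAPILLARY
    tree = VesselTree(segments, int(spec["flow_sense"]))
    tree.check_flow_conservation()
    return tree


# ---------------------------------------------------------------------------
# Rasterization / ground truth

def rasterize_tree(tree: VesselTree,
                   shape: tuple[int, int, int],
                   pitch: Sequence[float]) -> dict:
    """Paint a tree on a (z, x, y) voxel grid.

    Returns a truth dict with ``label`` (0 bg, 1 arteriole, 2 venule,
    3 capillary), ``speed`` (um/s), ``vz`` signed axial velocity (um/s),
    ``theta_z`` (deg, 90 in background), and ``axis`` unit vectors.
    """
    shape = tuple(int(n) for n in shape)
    pitch = np.asarray(pitch, float)
    label = np.zeros(shape, np.uint8)
    speed = np.zeros(shape, np.float32)
    vz = np.zeros(shape, np.float32)
    theta = np.full(shape, 90.0, np.float32)
    axis = np.zeros(shape + (3,), np.float32)
    kind_code = {ARTERIOLE: 1, VENULE: 2, CAPILLARY: 3}

    centers = [(np.arange(n) + 0.5) * p for n, p in zip(shape, pitch)]
    for idx, seg in enumerate(tree.segments):
        lo = np.minimum(seg.start, seg.end) - seg.radius - pitch
        hi = np.maximum(seg.start, seg.end) + seg.radius + pitch
        sl = []
        empty = False
        for ax in range(3):
            i0 = int(np.searchsorted(centers[ax], lo[ax]))
            i1 = int(np.searchsorted(centers[ax], hi[ax]))
            if i1 <= i0:
                empty = True
                break
            sl.append(slice(i0, i1))
        if empty:
            continue
        zz, xx, yy = np.meshgrid(centers[0][sl[0]], centers[1][sl[1]],
                                 centers[2][sl[2]], indexing="ij")
        pts = np.stack([zz, xx, yy], axis=-1)
        d = seg.end - seg.start
        L2 = float(np.dot(d, d))
        if L2 == 0:
            continue
        t = np.clip(np.einsum("...i,i->...", pts - seg.start, d) / L2, 0, 1)
        closest = seg.start + t[..., None] * d
        dist = np.linalg.norm(pts - closest, axis=-1)
        inside = dist <= seg.radius
        if not inside.any():
            continue
        w = tree.flow_vector(idx)
        region = tuple(sl)
        label[region][inside] = kind_code[seg.compartment]
        speed[region][inside] = seg.speed
        vz[region][inside] = w[0]
        theta[region][inside] = seg.theta_z_deg
        axis[region][inside] = seg.direction
    return {"label": label, "speed": speed, "vz": vz, "theta_z": theta,
            "axis": axis}


# ---------------------------------------------------------------------------
# Forward model

@dataclass
class ComplexAcquisition:
    """4D complex field indexed (z, x, r, y) plus the ground-truth sidecar."""

    field: np.ndarray
    params: AcquisitionParams
    truth: dict = field(default_factory=dict)

    @property
    def shape_zxy(self) -> tuple[int, int, int]:
        nz, nx, nr, ny = self.field.shape
        return nz, nx, ny

    @property
    def n_repeats(self) -> int:
        return self.field.shape[2]

    def intensity(self) -> np.ndarray:
        return (self.field.real ** 2 + self.field.imag ** 2)


DEFAULT_NOISE = {
    "speckle": True,
    "lumen_brightness": 3.0,   # amplitude ratio lumen : parenchyma
    "beam_fwhm_px": 4.0,       # lateral speckle correlation along x, px
    "noise_std": 0.05,         # additive complex noise std per quadrature
    "decorrelation": True,     # speed-dependent inter-repeat decorrelation
    "decorr_length_um": 5.0,   # displacement for 1/e inter-repeat decorrelation
}

NOISE_FREE = {"speckle": False, "noise_std": 0.0, "decorrelation": False}


def _speckle(rng: np.random.Generator, shape, beam_fwhm_px: float,
             axial_sigma_px: float) -> np.ndarray:
    g = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))
    g = g.astype(np.complex64) / math.sqrt(2.0)
    sig_x = beam_fwhm_px / 2.355
    if sig_x > 0 or axial_sigma_px > 0:
        re = ndimage.gaussian_filter(g.real, (axial_sigma_px, sig_x, 0))
        im = ndimage.gaussian_filter(g.imag, (axial_sigma_px, sig_x, 0))
        g = re + 1j * im
        rms = np.sqrt(np.mean(np.abs(g) ** 2))
        g = (g / rms).astype(np.complex64)
    return g


def simulate_acquisition(tree: VesselTree,
                         params: AcquisitionParams,
                         noise: dict | None = None,
                         seed: int = 0,
                         shape: tuple[int, int, int] = (64, 64, 64),
                         n_repeats: int | None = None) -> ComplexAcquisition:
    """Synthesize a repeated-B-scan complex acquisition of ``tree``.

    The field is indexed (z, x, r, y).  Adjacent x columns play the role of
    the two adjacent A-scans differenced for Doppler: flow voxels carry a
    cumulative phase ramp ``cumsum_x(dphi)`` so that
    ``field[:, x+1] * conj(field[:, x])`` has argument ``dphi[:, x+1]``
    exactly.  Repeats share the static speckle; lumen voxels decorrelate
    across repeats at a speed-dependent rate, the contrast exploited by
    speckle-variance angiography.
    """
    cfg = dict(DEFAULT_NOISE)
    cfg.update(noise or {})
    if any(cfg[k] < 0 for k in ("noise_std", "lumen_brightness")):
        raise ValueError("noise levels must be >= 0")
    nz, nx, ny = shape
    nr = int(n_repeats if n_repeats is not None else params.n_repeats)
    rng = np.random.default_rng(seed)

    truth = rasterize_tree(tree, shape, params.voxel_pitch)
    dphi_unwrapped = params.phase_per_axial_speed * truth["vz"]
    dphi = wrap_phase(dphi_unwrapped).astype(np.float32)
    truth["dphi"] = dphi
    truth["aliased"] = np.abs(dphi_unwrapped) > np.pi
    truth["corrupted_frames"] = set()
    truth["params"] = params

    amp = np.where(truth["label"] > 0, cfg["lumen_brightness"], 1.0
                   ).astype(np.float32)
    # cumulative Doppler phase along the fast axis (x)
    ramp = np.cumsum(dphi_unwrapped, axis=1).astype(np.float32)
    carrier = np.exp(1j * ramp).astype(np.complex64)

    axial_sigma_px = (params.axial_psf_fwhm / 2.355) / params.voxel_pitch[0]
    if cfg["speckle"]:
        g0 = _speckle(rng, shape, cfg["beam_fwhm_px"], axial_sigma_px)
    else:
        g0 = np.ones(shape, np.complex64)
    base = (amp * g0 * carrier).astype(np.complex64)

    # inter-repeat mixing coefficient per voxel
    if cfg["decorrelation"]:
        disp = truth["speed"] * params.dt_oca
        rho = np.exp(-disp / cfg["decorr_length_um"]).astype(np.float32)
        rho[truth["label"] == 0] = 1.0
    else:
        rho = np.ones(shape, np.float32)

    fld = np.empty((nz, nx, nr, ny), np.complex64)
    fld[:, :, 0, :] = base
    for r in range(1, nr):
        if (rho == 1.0).all():
            fld[:, :, r, :] = base
            continue
        if cfg["speckle"]:
            gr = _speckle(rng, shape, cfg["beam_fwhm_px"], axial_sigma_px)
        else:
            phases = rng.uniform(-np.pi, np.pi, shape).astype(np.float32)
            gr = np.exp(1j * phases).astype(np.complex64)
        fresh = (amp * gr * carrier).astype(np.complex64)
        mix = rho * base + np.sqrt(1.0 - rho ** 2) * fresh
        fld[:, :, r, :] = mix
    if cfg["noise_std"] > 0:
        fld += (cfg["noise_std"]
                * (rng.standard_normal(fld.shape)
                   + 1j * rng.standard_normal(fld.shape))).astype(np.complex64)
    return ComplexAcquisition(fld, params, truth)


def phase_interior_mask(truth: dict, window: tuple[int, int] = (3, 3),
                        min_dphi: float = 0.05) -> np.ndarray:
    """Vessel voxels whose whole (z, x) phase-averaging window carries one
    uniform, unaliased truth phase.

    Reconstruction averages lag-1 products over a small window, so voxels
    straddling vessel boundaries, segment junctions or aliased neighbors mix
    distinct phases; round-trip accuracy is defined away from those.
    """
    wz, wx = window
    good = (truth["label"] > 0) & ~truth["aliased"] \
        & (np.abs(truth["dphi"]) > min_dphi)
    dphi = truth["dphi"]
    size = (wz, wx + 2, 1)    # +1 x margin: the lag-1 pair looks back one col
    span = (ndimage.maximum_filter(dphi, size=size)
            - ndimage.minimum_filter(dphi, size=size))
    uniform = span < 1e-6
    interior = ndimage.binary_erosion(
        good, np.ones((wz, wx + 2, 1), bool), border_value=0)
    return interior & uniform


# ---------------------------------------------------------------------------
# Bulk motion

@dataclass
class MotionTrace:
    """Per-frame axial displacement and scramble amplitude, indexed (y, r).

    ``dz_um[y, r]`` is the axial displacement of frame (y, r); ``scramble``
    in [0, 1] is the fraction of the frame's field replaced by a fresh
    speckle realization (1 = the severe whole-frame corruption seen during
    instantaneous drift or jittering).  Frames with ``scramble >= 0.5`` are
    flagged as corrupted in the sidecar.
    """

    dz_um: np.ndarray
    scramble: np.ndarray
    flag_threshold: float = 0.5

    def __post_init__(self):
        self.dz_um = np.asarray(self.dz_um, np.float64)
        self.scramble = np.asarray(self.scramble, np.float64)
        if self.dz_um.shape != self.scramble.shape:
            raise ValueError("dz_um and scramble must share shape (ny, nr)")
        if ((self.scramble < 0) | (self.scramble > 1)).any():
            raise ValueError("scramble amplitudes must lie in [0, 1]")

    @property
    def flags(self) -> np.ndarray:
        return self.scramble >= self.flag_threshold

    @classmethod
    def zero(cls, ny: int, nr: int) -> "MotionTrace":
        return cls(np.zeros((ny, nr)), np.zeros((ny, nr)))

    @classmethod
    def random(cls, ny: int, nr: int, seed: int,
               p_scramble: float = 0.1, jitter_um: float = 0.15,
               burst_len: int = 3) -> "MotionTrace":
        """Draw a drift/jitter trace with occasional severe bursts."""
        rng = np.random.default_rng(seed)
        dz = np.cumsum(rng.normal(0.0, jitter_um, (ny, nr)), axis=1)
        scr = np.zeros((ny, nr))
        n_bursts = rng.binomial(ny, p_scramble)
        for _ in range(n_bursts):
            y = int(rng.integers(0, ny))
            r0 = int(rng.integers(0, nr))
            scr[y, r0:r0 + burst_len] = 1.0
        return cls(dz, scr)


def inject_bulk_motion(acq: ComplexAcquisition,
                       trace: MotionTrace,
                       seed: int = 0) -> ComplexAcquisition:
    """Corrupt an acquisition with a bulk-motion trace.

    Axial displacement dz adds the global phase 4*pi*n*dz/lambda0 and a
    sub-voxel Fourier resampling along z; scrambled frames are replaced
    (by amplitude ``a``) with a fresh uniform-phase speckle realization so
    they decorrelate from their neighbors.  The sidecar corrupted-frame set
    records exactly the flagged frames.
    """
    nz, nx, nr, ny = acq.field.shape
    if trace.dz_um.shape != (ny, nr):
        raise ValueError(
            f"trace shape {trace.dz_um.shape} != (ny, nr) = {(ny, nr)}")
    if (trace.dz_um == 0).all() and (trace.scramble == 0).all():
        return acq
    p = acq.params
    rng = np.random.default_rng(seed)
    out = acq.field.copy()
    kz = np.fft.fftfreq(nz)[:, None]
    for y in range(ny):
        for r in range(nr):
            dz = trace.dz_um[y, r]
            a = trace.scramble[y, r]
            if dz != 0.0:
                frame = out[:, :, r, y]
                shift_px = dz / p.voxel_pitch[0]
                spec = np.fft.fft(frame, axis=0)
                spec *= np.exp(-2j * np.pi * kz * shift_px)
                frame = np.fft.ifft(spec, axis=0).astype(np.complex64)
                frame *= np.exp(1j * 4.0 * np.pi * p.n_tissue * dz
                                / p.lambda0).astype(np.complex64)
                out[:, :, r, y] = frame
            if a > 0.0:
                # a collapsed B-scan: structureless speckle at the frame's
                # overall power, uniform random phase
                frame = out[:, :, r, y]
                env = float(np.sqrt(np.mean(np.abs(frame) ** 2)))
                g = (rng.standard_normal(frame.shape)
                     + 1j * rng.standard_normal(frame.shape)) / math.sqrt(2)
                fresh = (env * g).astype(np.complex64)
                out[:, :, r, y] = (math.sqrt(max(0.0, 1 - a ** 2)) * frame
                                   + a * fresh)
    truth = dict(acq.truth)
    corrupted = set(map(tuple, np.argwhere(trace.flags)))  # {(y, r)}
    truth["corrupted_frames"] = corrupted
    truth["motion_trace"] = trace
    return ComplexAcquisition(out, acq.params, truth)
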