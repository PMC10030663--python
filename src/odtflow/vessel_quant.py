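"""Vascular network quantification.

Hessian-based vessel-orientation tracking (Doppler angle theta_z),
angle-corrected velocity, arteriole/venule discrimination from branching
flow direction, diameters from the distance transform, skeleton-based
capillary density (fill factor), and per-ROI flow time series with relative
changes.

Sign convention: the signed Doppler value of a vessel is positive when flow
has a +z (into tissue) axial component.  An arteriolar tree carries flow
from its root toward the branches (branching out); a venular tree collects
flow from branches toward the root (branching in).  At each bifurcation the
trunk (largest-diameter edge) therefore feeds the branches in an arteriole
and drains them in a venule, which is what the per-tree majority vote below
measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import morphology

from .params import AcquisitionParams
from .phantom import VesselTree
from .recon import ODTVolume


def relative_change(value, baseline):
    """(x - x0) / x0 — the shared form of dphi, dCBFv and dD."""
    return (np.asarray(value, float) - baseline) / baseline


# ---------------------------------------------------------------------------
# Orientation

@dataclass
class OrientationField:
    theta_z: np.ndarray          # degrees in [0, 90]; undefined -> flagged
    axis: np.ndarray             # (..., 3) unit vectors (z, x, y)
    confidence: np.ndarray       # [0, 1]; 0 where isotropic/undefined
    scale: np.ndarray | None = None


def hessian_orientation(volume: np.ndarray,
                        scales=(1.0, 2.0, 4.0)) -> OrientationField:
    """Track the vessel axis per voxel with a scale-normalized Hessian.

    The axis is the eigenvector of the smallest-magnitude eigenvalue of the
    Hessian of the Gaussian-smoothed volume (sigma^2-normalized); the best
    scale per voxel maximizes cross-sectional curvature strength.
    theta_z = arccos(|axis . z|).  Isotropic voxels get confidence 0.
    """
    vol = np.asarray(volume, np.float64)
    scales = [float(s) for s in scales]
    if any(s <= 0 for s in scales):
        raise ValueError("scales must be positive")
    best_strength = np.full(vol.shape, -np.inf)
    best_H = np.zeros(vol.shape + (3, 3))
    best_scale = np.zeros(vol.shape)
    for s in scales:
        H = np.empty(vol.shape + (3, 3))
        for i in range(3):
            for j in range(i, 3):
                order = [0, 0, 0]
                order[i] += 1
                order[j] += 1
                d = ndimage.gaussian_filter(vol, s, order=order,
                                            mode="nearest") * s ** 2
                H[..., i, j] = d
                H[..., j, i] = d
        strength = np.sqrt((H ** 2).sum(axis=(-1, -2)))
        take = strength > best_strength
        best_strength[take] = strength[take]
        best_H[take] = H[take]
        best_scale[take] = s
    lam, vec = np.linalg.eigh(best_H)
    order = np.argsort(np.abs(lam), axis=-1)
    lam_sorted = np.take_along_axis(lam, order, axis=-1)
    axis = np.take_along_axis(
        vec, order[..., None, :], axis=-1)[..., 0]
    # confidence: cross-sectional curvature dominating axial curvature
    l1 = np.abs(lam_sorted[..., 0])
    l2 = np.abs(lam_sorted[..., 1])
    l3 = np.abs(lam_sorted[..., 2])
    conf = np.zeros(vol.shape)
    nzero = l3 > 1e-12
    conf[nzero] = np.clip((l2[nzero] - l1[nzero]) / l3[nzero], 0.0, 1.0)
    theta = np.degrees(np.arccos(np.clip(np.abs(axis[..., 0]), 0.0, 1.0)))
    theta[~nzero] = np.nan                    # undefined-flagged
    return OrientationField(theta.astype(np.float32),
                            axis.astype(np.float32),
                            conf.astype(np.float32),
                            best_scale.astype(np.float32))


def angle_correct_velocity(odt: ODTVolume, orient: OrientationField,
                           theta_max: float = 80.0) -> np.ma.MaskedArray:
    """Convert Doppler phase to speed along the vessel axis (um/s).

    v = lambda0 * dphi / (4 pi n dt_odt cos(theta_z)); voxels with
    theta_z > theta_max are masked rather than amplified through the
    1/cos divergence near horizontal flow.
    """
    if odt.units != "rad":
        raise ValueError("expected phase-unit ODT volume")
    if odt.params is None:
        raise ValueError("ODT volume lacks acquisition parameters")
    p = odt.params
    theta = orient.theta_z
    bad = ~np.isfinite(theta) | (theta > theta_max)
    cos = np.cos(np.radians(np.where(bad, 0.0, theta)))
    v_axial = odt.data / p.phase_per_axial_speed
    return np.ma.MaskedArray(v_axial / cos, mask=bad)


# ---------------------------------------------------------------------------
# Vessel graph

def graph_from_tree(tree: VesselTree, params: AcquisitionParams
                    ) -> nx.Graph:
    """Build a centerline graph directly from a phantom tree.

    Edges carry ``mean_doppler`` (signed phase, rad), ``diameter_um``,
    ``theta_z`` and the construction compartment (kept separately as
    ``true_compartment`` so classification can be scored against it).
    """
    g = nx.Graph()
    for i, seg in enumerate(tree.segments):
        a = tuple(np.round(seg.start, 3))
        b = tuple(np.round(seg.end, 3))
        g.add_node(a, pos=np.asarray(seg.start))
        g.add_node(b, pos=np.asarray(seg.end))
        w = tree.flow_vector(i)
        dphi = params.phase_per_axial_speed * w[0]
        g.add_edge(a, b, mean_doppler=float(dphi),
                   diameter_um=2.0 * seg.radius,
                   theta_z=seg.theta_z_deg,
                   true_compartment=seg.compartment,
                   segment=i)
    return g


def classify_arteriole_venule(graph: nx.Graph,
                              orient: OrientationField | None = None,
                              large_vessel_cutoff_um: float = 10.0
                              ) -> nx.Graph:
    """Label edges arteriole / venule / capillary / unclassified.

    Per connected tree, each bifurcation votes: flow leaving the node
    through the branches while entering through the trunk (the
    largest-diameter edge) means branching out (arteriole); the reverse
    means branching in (venule).  Trees whose every edge lies below the
    large-vessel diameter cutoff are capillary; conflicting trees stay
    unclassified with a conflict score.
    """
    g = graph.copy()

    def outward_flow(node, other, data):
        pz = g.nodes[node]["pos"][0]
        oz = g.nodes[other]["pos"][0]
        dz = oz - pz
        length = np.linalg.norm(g.nodes[other]["pos"] - g.nodes[node]["pos"])
        if length == 0 or abs(dz) < 0.05 * length:
            return 0.0                      # horizontal edge: ambiguous
        return math.copysign(1.0, data["mean_doppler"] * dz)

    for comp in nx.connected_components(g):
        edges = list(g.edges(comp, data=True))
        max_diam = max(d["diameter_um"] for _, _, d in edges)
        if max_diam <= large_vessel_cutoff_um:
            for u, v, d in edges:
                d["compartment"] = "capillary"
            continue
        votes = 0
        n_votes = 0
        for node in comp:
            nbrs = list(g[node])
            if len(nbrs) < 3:
                continue
            inc = sorted(((g[node][o]["diameter_um"], o) for o in nbrs),
                         reverse=True)
            trunk = inc[0][1]
            branches = [o for _, o in inc[1:]]
            ft = outward_flow(node, trunk, g[node][trunk])
            fb = [outward_flow(node, o, g[node][o]) for o in branches]
            fb = [f for f in fb if f != 0.0]
            if ft == 0.0 or not fb:
                continue
            branch_dir = np.sign(sum(fb))
            if ft < 0 and branch_dir > 0:
                votes += 1                  # trunk feeds branches
            elif ft > 0 and branch_dir < 0:
                votes -= 1                  # branches merge into trunk
            n_votes += 1
        if votes > 0:
            label = "arteriole"
        elif votes < 0:
            label = "venule"
        else:
            label = "unclassified"
        conflict = 0.0 if n_votes == 0 else 1.0 - abs(votes) / n_votes
        for u, v, d in edges:
            if d["diameter_um"] <= large_vessel_cutoff_um:
                d["compartment"] = "capillary"
            else:
                d["compartment"] = label
            d["conflict"] = conflict
    return g


def edge_table(graph: nx.Graph) -> pd.DataFrame:
    rows = []
    for u, v, d in graph.edges(data=True):
        rows.append({"u": str(u), "v": str(v), **{
            k: d.get(k) for k in ("mean_doppler", "diameter_um", "theta_z",
                                  "compartment", "conflict")}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Density and diameter

@dataclass
class DensityMeasure:
    cd: float                    # skeleton length per ROI area, um/um^2
    length_um: float
    area_um2: float


@dataclass
class DiameterMeasure:
    diameter_um: float
    per_point: np.ndarray


def _skeleton_length(skel: np.ndarray, pitch: float) -> float:
    """Sum of half-distances to skeleton neighbors (counts each link once)."""
    coords = np.argwhere(skel)
    if len(coords) == 0:
        return 0.0
    occupied = set(map(tuple, coords))
    nd = skel.ndim
    total = 0.0
    for c in coords:
        for off in np.ndindex(*(3,) * nd):
            off = np.array(off) - 1
            if (off == 0).all():
                continue
            if tuple(c + off) in occupied:
                total += 0.5 * float(np.linalg.norm(off)) * pitch
    return total


def skeleton_capillary_density(mask, large_vessel_cutoff_um: float,
                               roi: tuple[slice, ...],
                               pitch_um: float = 2.0) -> DensityMeasure:
    """Capillary density: skeleton length of the capillary bed per ROI area.

    Large vessels (local diameter above the cutoff) are removed by
    morphological opening before skeletonizing; the ROI is a tuple of
    half-open slices on the mask grid.
    """
    m = np.asarray(mask, bool)
    sub = m[roi]
    if sub.size == 0:
        raise ValueError("empty ROI")
    r_px = (large_vessel_cutoff_um / 2.0) / pitch_um
    if r_px >= 1.0:
        selem = (morphology.disk(int(round(r_px))) if m.ndim == 2
                 else morphology.ball(int(round(r_px))))
        large = morphology.opening(m, selem)
    else:
        large = np.zeros_like(m)
    cap = m & ~large
    skel = morphology.skeletonize(cap[roi])
    length = _skeleton_length(skel, pitch_um)
    area = float(np.prod(sub.shape)) * pitch_um ** m.ndim
    return DensityMeasure(length / area, length, area)


def vessel_diameter(mask, centerline_points, pitch_um: float = 2.0
                    ) -> DiameterMeasure:
    """Mean diameter along queried centerline points.

    diameter = 2 x Euclidean distance transform at the centerline.
    """
    m = np.asarray(mask, bool)
    pts = np.asarray(centerline_points, int)
    if pts.ndim == 1:
        pts = pts[None]
    vals = m[tuple(pts.T)]
    if not vals.all():
        raise ValueError("centerline point off the vessel mask")
    dist = ndimage.distance_transform_edt(m)
    per_point = 2.0 * dist[tuple(pts.T)] * pitch_um
    return DiameterMeasure(float(per_point.mean()), per_point)


# ---------------------------------------------------------------------------
# Flow time series

@dataclass
class FlowTimeSeries:
    name: str
    compartment: str
    cbfv: np.ndarray             # mean |Doppler| per time point
    delta: np.ndarray            # (CBFv - CBFv0) / CBFv0
    baseline: tuple[int, int]


def roi_flow_timeseries(volumes, rois, baseline: tuple[int, int],
                        noise_floor: float = 0.0):
    """Per-ROI CBFv(t) and relative change, plus compartment mean traces.

    ``volumes`` is a sequence of ODT volumes/arrays (time points);
    ``rois`` maps name -> dict with ``slices`` (tuple of half-open slices)
    and ``compartment``.  CBFv per ROI is the mean |Doppler| over ROI voxels
    above the noise floor; the relative change is taken against the mean
    over the half-open baseline window, making the baseline mean of
    dCBFv zero by construction.
    """
    arrs = [v.data if isinstance(v, ODTVolume) else np.asarray(v)
            for v in volumes]
    if len(arrs) < 2:
        raise ValueError("need at least 2 time points")
    b0, b1 = baseline
    if not (0 <= b0 < b1 <= len(arrs)):
        raise ValueError("baseline window must be non-empty and in range")
    series = []
    for name, spec in rois.items():
        sl = spec["slices"]
        for s, n in zip(sl, arrs[0].shape):
            if s.start < 0 or s.stop > n:
                raise ValueError(f"ROI {name} outside volume")
        vals = []
        for arr in arrs:
            mag = np.abs(arr[sl])
            sel = mag[mag > noise_floor]
            vals.append(float(sel.mean()) if sel.size else 0.0)
        cbfv = np.array(vals)
        base = cbfv[b0:b1].mean()
        delta = relative_change(cbfv, base)
        series.append(FlowTimeSeries(name, spec.get("compartment", "roi"),
                                     cbfv, delta, (b0, b1)))
    comp = {}
    for kind in sorted({s.compartment for s in series}):
        traces = np.stack([s.delta for s in series if s.compartment == kind])
        comp[kind] = {"mean": traces.mean(axis=0),
                      "std": traces.std(axis=0, ddof=0),
                      "n": traces.shape[0]}
    return series, comp
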