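"""End-to-end pipeline driver: phantom -> recon -> denoise -> quant.

One ``PipelineConfig`` (schema-validated; unknown keys rejected) drives a
reproducible run.  A single global seed fans out to per-stage child seeds by
stable hashing of the stage name, so inserting a stage never perturbs its
siblings.  Every run writes a ``RunManifest`` (JSON, atomically) recording
the config hash, child seeds, per-stage outputs with SHA-256 checksums and
wall times; deterministic stages reproduce identical checksums when re-run
with the same config.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import io as oio
from . import __version__
from .params import AcquisitionParams
from .phantom import (MotionTrace, generate_vessel_tree, inject_bulk_motion,
                      simulate_acquisition)
from .recon import ReconConfig, mip_project, oca_volume, phase_subtraction_odt
from .motion_inpaint import (InpaintConfig, binarize_vesselness,
                             detect_stripes, enhance_oca, inpaint_stripes,
                             make_inpaint_training_pairs, oof_vesselness,
                             train_inpainting)
from .odt_enhance import (AugmentationSpec, EnhanceConfig, enhance_volume,
                          train_enhancer)
from .vessel_quant import (classify_arteriole_venule, edge_table,
                           graph_from_tree, hessian_orientation,
                           skeleton_capillary_density)

PRESETS = {
    # motion burst probability per slow-axis position and tree depth
    "awake": {"p_scramble": 0.12, "depth": 4},
    "anesthetized": {"p_scramble": 0.0, "depth": 4},
    "chronic": {"p_scramble": 0.12, "depth": 3},
}


class PhantomStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    size: tuple[int, int, int] = (64, 64, 64)
    n_repeats: int = 14
    depth: int = 4
    root_speed: float = 80.0
    preset: str = "awake"


class ReconStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    n_select: int = 6
    r_threshold: float = 0.9
    phase_window: tuple[int, int] = (3, 3)


class DenoiseOcaStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    sensitivity: float = 10.0
    oof_radii: tuple[float, ...] = (1.0, 2.0, 3.0)
    iterations: int = 300
    n_patches: int = 200
    patch_size: int = 64


class DenoiseOdtStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    iterations: int = 200
    patch: int = 32
    crop_fraction: float = 0.3


class QuantStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    large_vessel_cutoff_um: float = 10.0
    theta_max_deg: float = 80.0


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    outdir: str = "odtflow_run"
    phantom: PhantomStage = Field(default_factory=PhantomStage)
    recon: ReconStage = Field(default_factory=ReconStage)
    denoise_oca: DenoiseOcaStage = Field(default_factory=DenoiseOcaStage)
    denoise_odt: DenoiseOdtStage = Field(default_factory=DenoiseOdtStage)
    quant: QuantStage = Field(default_factory=QuantStage)


def child_seed(seed: int, stage: str) -> int:
    h = hashlib.blake2s(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageFailure(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, log=print) -> dict:
    """Execute enabled stages in dependency order; returns the manifest.

    Partial failure leaves prior stage outputs (and the manifest written so
    far) intact; the manifest records the failed stage.
    """
    t_run = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dump = config.model_dump()
    # the output directory names where results go, not what is computed,
    # so it stays out of the config identity
    hashed = {k: v for k, v in cfg_dump.items() if k != "outdir"}
    cfg_json = json.dumps(hashed, sort_keys=True)
    manifest = {
        "version": __version__,
        "config": cfg_dump,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "stages": {},
        "failed_stage": None,
    }
    state: dict = {}

    def record(stage: str, t0: float, files: list[Path]):
        manifest["stages"][stage] = {
            "seed": child_seed(config.seed, stage),
            "elapsed_s": round(time.time() - t0, 3),
            "outputs": {f.name: _sha256(f) for f in files},
        }
        log(f"[{stage}] seed={child_seed(config.seed, stage)} "
            f"elapsed={manifest['stages'][stage]['elapsed_s']}s "
            f"outputs={len(files)}")

    stages = [
        ("phantom", config.phantom.enabled, _stage_phantom),
        ("recon", config.recon.enabled, _stage_recon),
        ("denoise_oca", config.denoise_oca.enabled, _stage_denoise_oca),
        ("denoise_odt", config.denoise_odt.enabled, _stage_denoise_odt),
        ("quant", config.quant.enabled, _stage_quant),
    ]
    try:
        for name, enabled, fn in stages:
            if not enabled:
                continue
            t0 = time.time()
            files = fn(config, out, state, child_seed(config.seed, name))
            record(name, t0, files)
    except Exception as exc:
        manifest["failed_stage"] = getattr(exc, "stage", name)
        _write_manifest(out, manifest, t_run)
        raise StageFailure(name, exc) from exc
    _write_manifest(out, manifest, t_run)
    return manifest


def _write_manifest(out: Path, manifest: dict, t_run: float) -> None:
    manifest["wall_time_s"] = round(time.time() - t_run, 3)
    tmp = out / ".manifest.tmp"
    tmp.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    os.replace(tmp, out / "manifest.json")


# ---------------------------------------------------------------------------
# Stages

def _stage_phantom(cfg: PipelineConfig, out: Path, state: dict,
                   seed: int) -> list[Path]:
    ph = cfg.phantom
    preset = PRESETS[ph.preset]
    params = AcquisitionParams(n_repeats=ph.n_repeats)
    nz, nx, ny = ph.size
    domain = [(0.0, n * p) for n, p in zip(ph.size, params.voxel_pitch)]
    tree = generate_vessel_tree(seed, preset.get("depth", ph.depth), domain,
                                {"root_speed": ph.root_speed})
    acq = simulate_acquisition(tree, params, seed=seed + 1, shape=ph.size)
    trace = MotionTrace.random(ny, ph.n_repeats, seed + 2,
                               p_scramble=preset["p_scramble"])
    acq = inject_bulk_motion(acq, trace, seed + 3)
    state["tree"], state["acq"], state["params"] = tree, acq, params
    files = []
    fp = out / "acquisition.h5"
    oio.write_acquisition(fp, acq)
    files.append(fp)
    for key in ("label", "dphi", "speed", "theta_z"):
        fp = out / f"truth_{key}.nii"
        oio.write_volume(fp, np.asarray(acq.truth[key], np.float32),
                         pitch=params.voxel_pitch)
        files.append(fp)
    fp = out / "tree.json"
    fp.write_text(tree.to_json())
    files.append(fp)
    return files


def _stage_recon(cfg: PipelineConfig, out: Path, state: dict,
                 seed: int) -> list[Path]:
    rc = ReconConfig(cfg.recon.n_select, cfg.recon.r_threshold,
                     cfg.recon.phase_window)
    acq = state["acq"]
    odt = phase_subtraction_odt(acq, rc)
    oca = oca_volume(acq, rc)
    state["odt"], state["oca"] = odt, oca
    params = state["params"]
    files = []
    for name, vol in (("odt", odt.data), ("oca", oca.data)):
        fp = out / f"{name}.nii"
        oio.write_volume(fp, vol.astype(np.float32), pitch=params.voxel_pitch,
                         units="rad" if name == "odt" else "cov")
        files.append(fp)
        mip = mip_project(np.abs(vol), axis=0)
        fp = out / f"{name}_mip.tif"
        hi = mip.max() or 1.0
        oio.write_volume(fp, (np.clip(mip / hi, 0, 1)
                              * 65535).astype(np.uint16),
                         pitch=params.voxel_pitch, axes="XY")
        files.append(fp)
    return files


def _stage_denoise_oca(cfg: PipelineConfig, out: Path, state: dict,
                       seed: int) -> list[Path]:
    dn = cfg.denoise_oca
    oca = state["oca"]
    mip = mip_project(oca.data, axis=0)
    stripes = detect_stripes(oca, dn.sensitivity)
    vness, _ = oof_vesselness(mip, dn.oof_radii)
    mask = binarize_vesselness(vness, mip)
    icfg = InpaintConfig(iterations=dn.iterations, patch_size=dn.patch_size,
                         seed=seed)
    pairs = make_inpaint_training_pairs(mask.mask, mip, dn.n_patches, icfg,
                                        stripes=stripes)
    model = train_inpainting(pairs, icfg)
    repaired = inpaint_stripes(mask, stripes, model, mip)
    enhanced = enhance_oca(mip, repaired)
    state["oca_mask"], state["oca_enhanced"] = repaired, enhanced
    files = []
    fp = out / "stripes.csv"
    pd.DataFrame({"start": [b[0] for b in stripes.bands],
                  "end": [b[1] for b in stripes.bands],
                  "score": stripes.scores}).to_csv(fp, index=False)
    files.append(fp)
    fp = out / "oca_mask.tif"
    oio.write_volume(fp, repaired.mask.astype(np.uint8) * 255, axes="XY")
    files.append(fp)
    fp = out / "oca_enhanced.tif"
    hi = enhanced.max() or 1.0
    oio.write_volume(fp, (np.clip(enhanced / hi, 0, 1)
                          * 65535).astype(np.uint16), axes="XY")
    files.append(fp)
    model.save(out / "inpaint_model")
    files += [out / "inpaint_model.npz", out / "inpaint_model.json"]
    return files


def _stage_denoise_odt(cfg: PipelineConfig, out: Path, state: dict,
                       seed: int) -> list[Path]:
    dn = cfg.denoise_odt
    odt = state["odt"]
    spec = AugmentationSpec(crop_fraction=dn.crop_fraction, seed=seed)
    ecfg = EnhanceConfig(iterations=dn.iterations, patch=dn.patch, seed=seed)
    model = train_enhancer([odt.data], spec, ecfg)
    enhanced = enhance_volume(odt, model)
    state["odt_enhanced"] = enhanced
    files = []
    fp = out / "odt_enhanced.nii"
    oio.write_volume(fp, enhanced.data.astype(np.float32),
                     pitch=state["params"].voxel_pitch, units="rad")
    files.append(fp)
    model.save(out / "enhance_model")
    files += [out / "enhance_model.npz", out / "enhance_model.json"]
    return files


def _stage_quant(cfg: PipelineConfig, out: Path, state: dict,
                 seed: int) -> list[Path]:
    q = cfg.quant
    params = state["params"]
    pitch = params.voxel_pitch[0]
    files = []
    odt = state.get("odt_enhanced", state.get("odt"))
    data = odt.data if hasattr(odt, "data") else odt
    orient = hessian_orientation(np.abs(data))
    fp = out / "theta_z.nii"
    oio.write_volume(fp, orient.theta_z, pitch=params.voxel_pitch,
                     units="deg")
    files.append(fp)
    # arteriole/venule labels on the centerline graph (construction graph
    # for phantom-driven runs)
    if "tree" in state:
        g = graph_from_tree(state["tree"], params)
        labeled = classify_arteriole_venule(
            g, large_vessel_cutoff_um=q.large_vessel_cutoff_um)
        fp = out / "av_edges.csv"
        edge_table(labeled).to_csv(fp, index=False)
        files.append(fp)
    if "oca_mask" in state:
        m = state["oca_mask"].mask
        roi = tuple(slice(0, s) for s in m.shape)
        dens = skeleton_capillary_density(m, q.large_vessel_cutoff_um, roi,
                                          pitch)
        fp = out / "density.csv"
        pd.DataFrame([{"cd_um_per_um2": dens.cd,
                       "length_um": dens.length_um,
                       "area_um2": dens.area_um2}]).to_csv(fp, index=False)
        files.append(fp)
    return files
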