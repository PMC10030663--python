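"""Shared fixtures.

The expensive artifacts (striped phantom with a trained inpainting model,
noisy phantom with a trained enhancer) are session-scoped so the module
tests and the end-to-end acceptance tests reuse one training run each.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from odtflow.params import AcquisitionParams
from odtflow import phantom as ph
from odtflow import recon
from odtflow import motion_inpaint as mi
from odtflow import odt_enhance as oe


def dice(a, b) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    s = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / s if s else float("nan")


def skeleton_components(mask: np.ndarray) -> int:
    from skimage import morphology as sm

    sk = sm.skeletonize(mask)
    struct = np.ones((3,) * mask.ndim, dtype=int)
    return ndimage.label(sk, structure=struct)[1]


@pytest.fixture(scope="session")
def params6() -> AcquisitionParams:
    return AcquisitionParams(n_repeats=6)


@pytest.fixture(scope="session")
def slow_tree():
    """Depth-3 tree with |dphi| < pi everywhere (root speed 80 um/s)."""
    return ph.generate_vessel_tree(1, 3, [(0, 128), (0, 128), (0, 128)],
                                   {"root_speed": 80.0})


@pytest.fixture(scope="session")
def noise_free_acq(slow_tree, params6):
    return ph.simulate_acquisition(slow_tree, params6, noise=ph.NOISE_FREE,
                                   seed=0, shape=(64, 64, 64), n_repeats=6)


@pytest.fixture(scope="session")
def striped_setup(params6):
    """Speckle phantom with two injected stripe bands plus its µOCA,
    detection result and OOF mask (the corrupted baseline)."""
    tree = ph.generate_vessel_tree(7, 4, [(0, 128), (0, 128), (0, 256)])
    acq = ph.simulate_acquisition(tree, params6, seed=1,
                                  shape=(64, 64, 128), n_repeats=6)
    bands = [(52, 58), (74, 77)]
    scr = np.zeros((128, 6))
    for lo, hi in bands:
        scr[lo:hi, :] = 1.0
    acq_c = ph.inject_bulk_motion(
        acq, ph.MotionTrace(np.zeros((128, 6)), scr), seed=2)
    oca_c = recon.oca_volume(acq_c)
    mip_c = recon.mip_project(oca_c.data, axis=0)
    stripes = mi.detect_stripes(oca_c)
    vness, _ = mi.oof_vesselness(mip_c, (1.0, 2.0, 3.0))
    mask_c = mi.binarize_vesselness(vness, mip_c)
    truth_mask = (acq.truth["label"] > 0).any(axis=0)
    return {
        "tree": tree, "acq_clean": acq, "acq": acq_c, "bands": bands,
        "oca": oca_c, "mip": mip_c, "stripes": stripes, "mask": mask_c,
        "truth_mask": truth_mask,
    }


@pytest.fixture(scope="session")
def inpaint_model(striped_setup):
    """Reference desk-scale training run: 300 iterations, 64x64 patches."""
    cfg = mi.InpaintConfig(iterations=300, patch_size=64, seed=3)
    pairs = mi.make_inpaint_training_pairs(
        striped_setup["mask"].mask, striped_setup["mip"], 200, cfg,
        stripes=striped_setup["stripes"])
    return mi.train_inpainting(pairs, cfg), cfg, pairs


@pytest.fixture(scope="session")
def noisy_odt_setup():
    """Noisy 64^3 Doppler phantom (additive phase noise) plus truth."""
    p = AcquisitionParams(n_repeats=4)
    tree = ph.generate_vessel_tree(3, 4, [(0, 128), (0, 128), (0, 128)],
                                   {"root_speed": 80.0})
    noise = dict(ph.DEFAULT_NOISE)
    noise["noise_std"] = 0.25
    acq = ph.simulate_acquisition(tree, p, noise=noise, seed=1,
                                  shape=(64, 64, 64), n_repeats=4)
    odt = recon.phase_subtraction_odt(acq)
    return {"tree": tree, "params": p, "acq": acq, "odt": odt,
            "label": acq.truth["label"] > 0}


@pytest.fixture(scope="session")
def enhance_model(noisy_odt_setup):
    """Reference desk-scale training run: 200 iterations, 32^3 patches."""
    spec = oe.AugmentationSpec(crop_fraction=0.3, seed=2)
    cfg = oe.EnhanceConfig(iterations=200, patch=32, seed=2)
    model = oe.train_enhancer([noisy_odt_setup["odt"].data], spec, cfg)
    return model, spec, cfg


def oof_mask(volume_or_image, radii=(1.0, 2.0, 3.0)):
    img = np.abs(np.asarray(volume_or_image))
    vness, _ = mi.oof_vesselness(img, radii)
    return mi.binarize_vesselness(vness, img).mask
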