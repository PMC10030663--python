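"""Volume readers/writers (TIFF stack, NIfTI, HDF5) with axis normalization.

Canonical in-memory axis order is (z, x, y) for volumes and (z, x, r, y)
for complex acquisitions, 0-based, z being the beam/depth axis.  Readers
accept data stored in any declared axis order and transpose to canonical;
writers record the axes string, the voxel pitch (um) and units so a
round trip is bit-identical.

HDF5 stores complex fields as paired real/imag datasets (``field_real`` /
``field_imag``); datasets are created with ``track_times=False`` so files
are byte-reproducible.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import tifffile

from .params import AcquisitionParams
from .phantom import ComplexAcquisition

CANONICAL_3D = "ZXY"
CANONICAL_4D = "ZXRY"


class VolumeReadError(IOError):
    pass


def _normalize_axes(data: np.ndarray, axes: str) -> np.ndarray:
    target = CANONICAL_4D if data.ndim == 4 else CANONICAL_3D
    axes = axes.upper()
    if sorted(axes) != sorted(target) or len(axes) != data.ndim:
        raise VolumeReadError(f"cannot normalize axes {axes!r} to {target!r}")
    return data.transpose([axes.index(a) for a in target])


def write_volume(path, data: np.ndarray, pitch=None, units: str = "",
                 axes: str | None = None) -> None:
    """Write a volume as .nii, .tif/.tiff or .h5 based on the suffix."""
    path = Path(path)
    axes = axes or (CANONICAL_4D if data.ndim == 4 else CANONICAL_3D)
    suffix = path.suffix.lower()
    if suffix == ".nii":
        affine = np.eye(4)
        img = nib.Nifti1Image(np.asarray(data), affine)
        if pitch is not None:
            img.header.set_zooms(tuple(pitch) + (1.0,) * (data.ndim - 3))
        img.header["descrip"] = json.dumps(
            {"axes": axes, "units": units})[:79].encode()
        nib.save(img, str(path))
    elif suffix in (".tif", ".tiff"):
        meta = {"axes_order": axes, "units": units}
        if pitch is not None:
            meta["pitch_um"] = list(pitch)
        tifffile.imwrite(str(path), np.asarray(data), metadata=meta,
                         photometric="minisblack")
    elif suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            arr = np.asarray(data)
            if np.iscomplexobj(arr):
                fh.create_dataset("field_real", data=arr.real,
                                  track_times=False)
                fh.create_dataset("field_imag", data=arr.imag,
                                  track_times=False)
            else:
                fh.create_dataset("data", data=arr, track_times=False)
            fh.attrs["axes"] = axes
            fh.attrs["units"] = units
            if pitch is not None:
                fh.attrs["pitch_um"] = list(pitch)
    else:
        raise ValueError(f"unsupported volume format {suffix!r}")


def read_volume(path):
    """Read a volume; returns (array, metadata dict).

    Metadata carries ``pitch_um`` (defaults to unit voxels with a warning
    when absent), ``units`` and the normalized ``axes``.  Arrays come back
    in canonical (z, x, [r,] y) order.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeReadError(f"no such file: {path}")
    suffix = path.suffix.lower()
    pitch = None
    units = ""
    if suffix == ".nii":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        axes = CANONICAL_4D if data.ndim == 4 else CANONICAL_3D
        try:
            desc = json.loads(bytes(img.header["descrip"]).decode().rstrip("\x00"))
            axes = desc.get("axes", axes)
            units = desc.get("units", "")
        except (ValueError, KeyError):
            pass
        pitch = tuple(float(z) for z in img.header.get_zooms()[:3])
    elif suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(str(path)) as tif:
            data = tif.asarray()
            meta = (tif.shaped_metadata or [{}])[0]
        axes = meta.get("axes_order",
                        CANONICAL_4D if data.ndim == 4 else CANONICAL_3D)
        units = meta.get("units", "")
        if "pitch_um" in meta:
            pitch = tuple(float(p) for p in meta["pitch_um"])
    elif suffix in (".h5", ".hdf5"):
        try:
            with h5py.File(path, "r") as fh:
                if "field_real" in fh:
                    data = (np.asarray(fh["field_real"])
                            + 1j * np.asarray(fh["field_imag"])
                            ).astype(np.complex64)
                else:
                    data = np.asarray(fh["data"])
                axes = fh.attrs.get(
                    "axes", CANONICAL_4D if data.ndim == 4 else CANONICAL_3D)
                units = fh.attrs.get("units", "")
                if "pitch_um" in fh.attrs:
                    pitch = tuple(float(p) for p in fh.attrs["pitch_um"])
        except OSError as exc:
            size = path.stat().st_size
            raise VolumeReadError(
                f"failed reading {path} (file size {size} bytes): {exc}"
            ) from exc
    else:
        raise ValueError(f"unsupported volume format {suffix!r}")
    if data.ndim >= 3:
        data = _normalize_axes(data, axes)
        axes = CANONICAL_4D if data.ndim == 4 else CANONICAL_3D
    if pitch is None:
        warnings.warn(f"{path.name}: no voxel-pitch metadata; assuming unit "
                      "voxels", stacklevel=2)
        pitch = (1.0,) * min(data.ndim, 3)
    return data, {"pitch_um": pitch, "units": units, "axes": axes}


def write_acquisition(path, acq: ComplexAcquisition) -> None:
    """Write a complex acquisition plus its acquisition parameters to HDF5."""
    p = acq.params
    with h5py.File(path, "w") as fh:
        fh.create_dataset("field_real", data=acq.field.real,
                          track_times=False)
        fh.create_dataset("field_imag", data=acq.field.imag,
                          track_times=False)
        fh.attrs["axes"] = CANONICAL_4D
        fh.attrs["pitch_um"] = list(p.voxel_pitch)
        fh.attrs["params"] = json.dumps({
            "lambda0": p.lambda0, "delta_lambda": p.delta_lambda,
            "n_tissue": p.n_tissue, "dt_odt": p.dt_odt, "dt_oca": p.dt_oca,
            "n_repeats": p.n_repeats, "voxel_pitch": list(p.voxel_pitch),
            "axial_psf_fwhm": p.axial_psf_fwhm})


def read_acquisition(path) -> ComplexAcquisition:
    with h5py.File(path, "r") as fh:
        field = (np.asarray(fh["field_real"])
                 + 1j * np.asarray(fh["field_imag"])).astype(np.complex64)
        pdict = json.loads(fh.attrs["params"])
    pdict["voxel_pitch"] = tuple(pdict["voxel_pitch"])
    return ComplexAcquisition(field, AcquisitionParams(**pdict))
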