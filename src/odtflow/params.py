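"""Optical and timing constants shared by the phantom and the reconstruction.

The Doppler phase accumulated between two adjacent A-scans by a scatterer
moving with speed ``v`` at angle ``theta_z`` to the beam is

    dphi = 4 * pi * n_tissue * v * cos(theta_z) * dt_odt / lambda0

with ``v`` in um/s, ``lambda0`` in um and ``dt_odt`` in s.  The same constant
links phase back to axial velocity in the reconstruction, so both sides of
the round trip consume one ``AcquisitionParams`` instance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class AcquisitionParams:
    """Source, timing and sampling constants of the swept OCT acquisition.

    Parameters
    ----------
    lambda0 : float
        Center wavelength in um (1.31 um source).
    delta_lambda : float
        Source bandwidth FWHM in um.
    n_tissue : float
        Bulk refractive index of cortical tissue.
    dt_odt : float
        Time between the two adjacent A-scans differenced for Doppler, s.
    dt_oca : float
        Time between adjacent repeated B-scan frames, s.  For awake-animal
        protocols this is roughly two orders of magnitude larger than
        ``dt_odt``, which is why angiography is far more motion sensitive
        than Doppler.
    n_repeats : int
        Repeated B-scan frames acquired per slow-axis position.
    voxel_pitch : tuple of float
        (z, x, y) um per voxel.
    axial_psf_fwhm : float
        Axial point-spread FWHM in tissue, um, taken as a direct parameter.
    """

    lambda0: float = 1.31
    delta_lambda: float = 0.20
    n_tissue: float = 1.35
    dt_odt: float = 2.3e-3
    dt_oca: float = 0.21
    n_repeats: int = 14
    voxel_pitch: tuple[float, float, float] = (2.0, 2.0, 2.0)
    axial_psf_fwhm: float = 2.5

    def __post_init__(self) -> None:
        for name in ("lambda0", "delta_lambda", "n_tissue", "dt_odt",
                     "dt_oca", "axial_psf_fwhm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_repeats < 2:
            raise ValueError("n_repeats must be >= 2")
        if not self.dt_oca > self.dt_odt:
            raise ValueError("dt_oca must exceed dt_odt")
        if len(self.voxel_pitch) != 3 or any(p <= 0 for p in self.voxel_pitch):
            raise ValueError("voxel_pitch must be three positive floats")

    @property
    def phase_per_axial_speed(self) -> float:
        """rad of inter-A-scan phase per um/s of axial velocity."""
        return 4.0 * math.pi * self.n_tissue * self.dt_odt / self.lambda0

    def doppler_phase(self, speed: float, theta_z_deg: float) -> float:
        """Unwrapped Doppler phase for ``speed`` um/s at ``theta_z_deg``."""
        return (self.phase_per_axial_speed * speed
                * math.cos(math.radians(theta_z_deg)))

    def axial_speed(self, dphi: float) -> float:
        """Axial velocity (um/s) producing inter-A-scan phase ``dphi``."""
        return dphi / self.phase_per_axial_speed


def wrap_phase(phi):
    """Wrap phase(s) to the half-open interval (-pi, pi]."""
    import numpy as np

    wrapped = np.mod(np.asarray(phi) + np.pi, 2.0 * np.pi) - np.pi
    # np.mod maps exact multiples of 2*pi to -pi; the convention here is +pi.
    wrapped = np.where(wrapped == -np.pi, np.pi, wrapped)
    if np.isscalar(phi):
        return float(wrapped)
    return wrapped
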