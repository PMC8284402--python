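"""Acquisition geometry for cone-beam near-field imaging.

A divergent (cone) beam from a focal spot illuminates the sample at distance
``z1`` from the focus; the detector sits at ``zD``.  By the Fresnel scaling
theorem such an acquisition is equivalent to a parallel-beam measurement at
the *effective* propagation distance ``D = z1 (zD - z1) / zD``, sampled at
the demagnified pixel ``p / M`` with geometric magnification ``M = zD / z1``.
Everything downstream of this module (propagators, retrieval filters) works
in that equivalent parallel geometry.

Frequencies are expressed in cycles per metre (not angular), so the Fresnel
chirp phase is ``chi_D(f) = pi * lambda * D * |f|**2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import GeometryError

__all__ = [
    "HC_KEV_M",
    "AcquisitionGeometry",
    "magnification",
    "effective_distance",
    "effective_pixel",
    "fresnel_number",
    "wavelength_from_energy",
    "frequency_grid",
    "chirp_phase",
]

#: h*c in keV*m, CODATA-rounded; lambda[m] = HC_KEV_M / E[keV].
HC_KEV_M = 1.23984193e-9


def wavelength_from_energy(energy_kev: float) -> float:
    """X-ray wavelength in metres for a photon energy in keV."""
    if energy_kev <= 0:
        raise GeometryError(f"energy must be positive, got {energy_kev} keV")
    return HC_KEV_M / energy_kev


def magnification(z1: float, zd: float) -> float:
    """Geometric magnification M = zD / z1 of a cone-beam setup.

    ``z1`` is the focus-to-sample distance, ``zd`` the focus-to-detector
    distance, both in metres.  ``z1 == zd`` (sample at the detector, contact
    plane) gives M = 1.
    """
    _check_distances(z1, zd)
    return zd / z1


def effective_distance(z1: float, zd: float) -> float:
    """Effective parallel-beam propagation distance D = z1 (zD - z1) / zD.

    This is the Fresnel-scaling equivalent distance; it vanishes at the
    contact plane (z1 = zD) and peaks at zD/4 for z1 = zD/2.
    """
    _check_distances(z1, zd)
    return z1 * (zd - z1) / zd


def effective_pixel(pixel: float, m: float) -> float:
    """Demagnified (sample-plane) pixel size p / M."""
    if pixel <= 0:
        raise GeometryError(f"pixel must be positive, got {pixel}")
    if m < 1:
        raise GeometryError(f"magnification must be >= 1, got {m}")
    return pixel / m


def fresnel_number(a: float, wavelength: float, distance: float) -> float:
    """Fresnel number F = a^2 / (lambda * L) for a feature of size ``a``.

    F ~ 1 marks the edge-enhancement regime boundary for that feature;
    F << 1 is the holographic regime.  All arguments strictly positive.
    """
    if a <= 0 or wavelength <= 0 or distance <= 0:
        raise GeometryError(
            "fresnel_number requires strictly positive feature size, "
            f"wavelength and distance; got a={a}, lambda={wavelength}, L={distance}"
        )
    return a * a / (wavelength * distance)


def _check_distances(z1: float, zd: float) -> None:
    if z1 <= 0 or zd <= 0:
        raise GeometryError(f"distances must be positive, got z1={z1}, zD={zd}")
    if z1 > zd:
        raise GeometryError(f"inverted geometry: z1={z1} > zD={zd}")


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Cone-beam acquisition geometry.

    Parameters
    ----------
    energy_kev:
        Photon energy in keV.
    z1_m:
        Focus-to-sample distance in metres (0 < z1 < zD).
    zd_m:
        Focus-to-detector distance in metres.
    pixel_m:
        Physical detector pixel size in metres.
    """

    energy_kev: float
    z1_m: float
    zd_m: float
    pixel_m: float

    def __post_init__(self) -> None:
        _check_distances(self.z1_m, self.zd_m)
        if self.z1_m >= self.zd_m:
            raise GeometryError(
                f"sample must sit strictly upstream of the detector: "
                f"z1={self.z1_m} >= zD={self.zd_m}"
            )
        if self.pixel_m <= 0:
            raise GeometryError(f"pixel must be positive, got {self.pixel_m}")
        if self.energy_kev <= 0:
            raise GeometryError(f"energy must be positive, got {self.energy_kev}")

    @property
    def wavelength_m(self) -> float:
        return wavelength_from_energy(self.energy_kev)

    @property
    def magnification(self) -> float:
        return magnification(self.z1_m, self.zd_m)

    @property
    def effective_distance_m(self) -> float:
        return effective_distance(self.z1_m, self.zd_m)

    @property
    def effective_pixel_m(self) -> float:
        return effective_pixel(self.pixel_m, self.magnification)

    def at_z1(self, z1_m: float) -> "AcquisitionGeometry":
        """Same setup with the sample moved to a different focus distance."""
        return AcquisitionGeometry(self.energy_kev, z1_m, self.zd_m, self.pixel_m)


def frequency_grid(shape: tuple[int, int], pixel: float) -> tuple[np.ndarray, np.ndarray]:
    """DFT frequency grids (fy, fx) in cycles per metre, standard DFT ordering.

    Returned arrays broadcast to ``shape`` ((ny, 1) and (1, nx)).
    """
    if pixel <= 0:
        raise GeometryError(f"pixel must be positive, got {pixel}")
    ny, nx = shape
    fy = np.fft.fftfreq(ny, d=pixel)[:, None]
    fx = np.fft.fftfreq(nx, d=pixel)[None, :]
    return fy, fx


def chirp_phase(
    shape: tuple[int, int], pixel: float, wavelength: float, distance: float
) -> np.ndarray:
    """Fresnel chirp phase chi_D(f) = pi * lambda * D * (fx^2 + fy^2), in rad.

    ``distance`` may be negative (back-propagation); chi(0) = 0 always.
    """
    fy, fx = frequency_grid(shape, pixel)
    return np.pi * wavelength * distance * (fx * fx + fy * fy)
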