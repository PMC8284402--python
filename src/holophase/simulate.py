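"""Synthetic phantoms and multi-distance hologram simulation.

The simulator emulates a cone-beam acquisition in which the sample is moved
to several focus distances ``z1``; each position is converted to its
parallel-beam equivalent (effective distance, effective pixel) and the exit
wave of a known phantom is Fresnel-propagated to produce the hologram.
Counting (Poisson) noise at a chosen fluence ``N0`` photons per pixel is the
only noise source; detector PSF and flat-field structure are not modelled.
Holograms are generated on the phantom's own pixel grid, i.e. as if already
magnification-corrected to the sample plane, which is the state the
retrieval methods expect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DataError, GeometryError
from .geometry import AcquisitionGeometry
from .propagate import ComplexWavefield, ObjectMaps, fresnel_propagate, intensity
from .retrieve import HologramStack

__all__ = [
    "Phantom",
    "SimulatedDataset",
    "make_disc_phantom",
    "make_star_phantom",
    "simulate_stack",
    "propagate_object",
]


@dataclass
class Phantom:
    """Test object: a projected-thickness map of a single material, or free
    (phi, B) maps.

    ``thickness`` (m) with material constants ``delta``/``beta`` generates
    ``phi = -(2 pi / lambda) delta t`` and ``B = (2 pi / lambda) beta t`` at
    simulation time; alternatively, arbitrary ``phi``/``b`` maps may be given
    directly (then delta/beta are ignored).
    """

    pixel: float
    thickness: np.ndarray | None = None
    delta: float = 0.0
    beta: float = 0.0
    phi: np.ndarray | None = None
    b: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.thickness is None) == (self.phi is None):
            raise DataError("give either a thickness map or (phi, b) maps")
        if self.thickness is not None:
            self.thickness = np.asarray(self.thickness, dtype=np.float64)
            if np.any(self.thickness < 0):
                raise DataError("thickness must be >= 0")
            if self.beta < 0:
                raise DataError("beta must be >= 0")
        else:
            self.phi = np.asarray(self.phi, dtype=np.float64)
            self.b = np.zeros_like(self.phi) if self.b is None else np.asarray(
                self.b, dtype=np.float64
            )

    @property
    def shape(self) -> tuple[int, int]:
        arr = self.thickness if self.thickness is not None else self.phi
        return arr.shape

    def object_maps(self, wavelength: float) -> ObjectMaps:
        """Phase/absorption maps of this phantom at the given wavelength."""
        if self.thickness is not None:
            k = 2.0 * np.pi / wavelength
            return ObjectMaps(
                phi=-k * self.delta * self.thickness,
                b=k * self.beta * self.thickness,
                pixel=self.pixel,
            )
        return ObjectMaps(phi=self.phi, b=self.b, pixel=self.pixel)


def _disc_thickness(shape, centre_px, radius_px):
    yy = np.arange(shape[0])[:, None] - centre_px[0]
    xx = np.arange(shape[1])[None, :] - centre_px[1]
    rho2 = yy * yy + xx * xx
    t = np.zeros(shape, dtype=np.float64)
    inside = rho2 < radius_px * radius_px
    t[inside] = 2.0 * np.sqrt(radius_px * radius_px - rho2[inside])
    return t


def make_disc_phantom(
    shape: tuple[int, int],
    radii: float | list[float],
    t_max: float,
    delta: float,
    beta: float,
    pixel: float,
    centres: list[tuple[float, float]] | None = None,
) -> Phantom:
    """Spherical-cap disc phantom (projected thickness of spheres).

    ``radii`` and ``centres`` (offsets from the grid centre, (y, x)) are in
    metres; overlapping discs add.  The summed thickness is rescaled so its
    maximum equals ``t_max`` — for a single disc the centre thickness is
    exactly ``t_max``.  Discs must fit inside the grid.
    """
    radii = np.atleast_1d(np.asarray(radii, dtype=np.float64))
    if centres is None:
        if len(radii) != 1:
            raise DataError("centres required for more than one disc")
        centres = [(0.0, 0.0)]
    if len(centres) != len(radii):
        raise DataError("need one centre per radius")
    ny, nx = shape
    t = np.zeros(shape, dtype=np.float64)
    for r, (cy, cx) in zip(radii, centres):
        r_px = r / pixel
        c_px = (ny / 2.0 + cy / pixel, nx / 2.0 + cx / pixel)
        if (
            c_px[0] - r_px < 0
            or c_px[0] + r_px > ny
            or c_px[1] - r_px < 0
            or c_px[1] + r_px > nx
        ):
            raise GeometryError("disc extends beyond the grid")
        t += _disc_thickness(shape, c_px, r_px)
    if t_max < 0:
        raise DataError("t_max must be >= 0")
    peak = t.max()
    if peak > 0 and t_max > 0:
        t *= t_max / peak
    else:
        t[:] = 0.0
    return Phantom(pixel=pixel, thickness=t, delta=delta, beta=beta)


def make_star_phantom(
    shape: tuple[int, int],
    n_spokes: int,
    radius: float,
    t_max: float,
    delta: float,
    beta: float,
    pixel: float,
) -> Phantom:
    """Siemens-star resolution target: ``n_spokes`` angular sectors of
    thickness ``t_max`` inside ``radius`` (m), alternating with gaps of equal
    angle (binarized spoke area fraction 1/2).  ``n_spokes = 0`` gives an
    empty phantom.  The pattern is invariant under rotation by 2*pi/n.
    """
    if n_spokes < 0:
        raise DataError("n_spokes must be >= 0")
    ny, nx = shape
    yy = (np.arange(ny)[:, None] - ny / 2.0) * pixel
    xx = (np.arange(nx)[None, :] - nx / 2.0) * pixel
    t = np.zeros(shape, dtype=np.float64)
    if n_spokes > 0:
        theta = np.arctan2(yy, xx)
        sector = np.floor(theta / (np.pi / n_spokes)).astype(int)
        inside = (yy * yy + xx * xx) < radius * radius
        t[(sector % 2 == 0) & inside] = t_max
    return Phantom(pixel=pixel, thickness=t, delta=delta, beta=beta)


@dataclass
class SimulatedDataset:
    """A simulated hologram stack with its ground truth and noise metadata."""

    stack: HologramStack
    truth: ObjectMaps
    n0_photons: float
    seed: int | None
    z1_list: list[float]


def propagate_object(
    obj: ObjectMaps, wavelength: float, distances, pad: bool = False
) -> np.ndarray:
    """Noiseless Fresnel holograms of an object at several distances."""
    u0 = obj.exit_wave()
    return np.asarray(
        [
            intensity(fresnel_propagate(u0, wavelength, float(d), pad=pad))
            for d in np.atleast_1d(distances)
        ]
    )


def simulate_stack(
    phantom: Phantom,
    geometry: AcquisitionGeometry,
    z1_list: list[float],
    n0_photons: float = math.inf,
    seed: int | None = None,
    pad: bool = False,
) -> SimulatedDataset:
    """Simulate a multi-distance acquisition of ``phantom``.

    For every focus-to-sample distance in ``z1_list`` the effective
    (parallel-beam) distance is derived from ``geometry`` and the phantom's
    exit wave is Fresnel-propagated on its own pixel grid.  With a finite
    fluence ``n0_photons`` each pixel is replaced by a Poisson draw of mean
    ``N0 * I`` rescaled by ``1/N0``; ``n0_photons = inf`` is noiseless.  The
    same seed reproduces the dataset bit for bit.
    """
    if n0_photons <= 0:
        raise DataError(f"n0_photons must be positive, got {n0_photons}")
    for z1 in z1_list:
        if not 0 < z1 < geometry.zd_m:
            raise GeometryError(f"z1={z1} outside (0, zD={geometry.zd_m})")
    wavelength = geometry.wavelength_m
    distances = [geometry.at_z1(z1).effective_distance_m for z1 in z1_list]
    truth = phantom.object_maps(wavelength)
    images = propagate_object(truth, wavelength, distances, pad=pad)
    if math.isfinite(n0_photons):
        rng = np.random.default_rng(seed)
        images = rng.poisson(n0_photons * images).astype(np.float64) / n0_photons
    stack = HologramStack(
        images=images,
        distances=np.asarray(distances),
        pixel=phantom.pixel,
        wavelength=wavelength,
    )
    return SimulatedDataset(
        stack=stack, truth=truth, n0_photons=n0_photons, seed=seed, z1_list=list(z1_list)
    )
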