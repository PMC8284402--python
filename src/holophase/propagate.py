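"""Free-space propagation: full Fresnel operator and its linearizations.

The exit wave of a thin object is ``u(x) = exp(-B(x) + i*phi(x))`` with
``B >= 0`` the absorption exponent and ``phi`` the phase shift (``phi <= 0``
for a positive refractive-index decrement delta, by the convention
``phi = -(2*pi/lambda) * integral(delta) dz``).

Propagation over distance D is implemented as a single-FFT transfer-function
product: ``u_D = IDFT[ H_D * DFT[u] ]`` with ``H_D(f) = exp(-i*chi_D(f))``
and ``chi_D(f) = pi*lambda*D*|f|^2`` (frequencies in cycles per metre).  This
operator is exactly unitary and composes exactly over distances; its periodic
boundary can be mitigated with symmetric edge-padding (``pad=True``), at the
cost of those exact identities.

Two linearized forward models are provided:

* :func:`ctf_forward` — contrast-transfer-function model, first order in the
  *object* (weak phase and absorption, any distance):
  ``DFT[I_D] = delta(f) + 2 sin(chi) DFT[phi] - 2 cos(chi) DFT[B]``.
* :func:`tie_forward` — transport-of-intensity model, first order in the
  *distance* (large Fresnel number, any contrast):
  ``I_D = I0 - (lambda*D / 2*pi) div(I0 grad phi)`` with ``I0 = exp(-2B)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import SamplingError
from .geometry import chirp_phase

__all__ = [
    "ComplexWavefield",
    "ObjectMaps",
    "fresnel_propagate",
    "fresnel_transfer_function",
    "intensity",
    "ctf_forward",
    "tie_forward",
]


@dataclass
class ComplexWavefield:
    """A 2D complex field sampled on a square-pixel grid.

    Parameters
    ----------
    values:
        Complex 2D array, at least 8x8, all finite.
    pixel:
        Sample-plane pixel size in metres (square pixels).
    """

    values: np.ndarray
    pixel: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2:
            raise SamplingError(f"wavefield must be 2D, got ndim={self.values.ndim}")
        if min(self.values.shape) < 8:
            raise SamplingError(f"wavefield too small: {self.values.shape} (need >= 8x8)")
        if self.pixel <= 0:
            raise SamplingError(f"pixel must be positive, got {self.pixel}")
        if not np.all(np.isfinite(self.values)):
            raise SamplingError("wavefield contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ComplexWavefield":
        return ComplexWavefield(self.values.copy(), self.pixel)


@dataclass
class ObjectMaps:
    """Thin-object phase and absorption maps.

    ``phi`` is the phase shift in rad (``phi <= 0`` for delta > 0); ``b`` is
    the dimensionless absorption exponent, ``b >= 0`` so the transmitted
    amplitude ``exp(-b) <= 1``.  The contact-plane intensity is
    ``I0 = exp(-2b)``.
    """

    phi: np.ndarray
    b: np.ndarray
    pixel: float

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        if self.phi.shape != self.b.shape:
            raise SamplingError(
                f"phi/B shape mismatch: {self.phi.shape} vs {self.b.shape}"
            )
        if self.phi.ndim != 2:
            raise SamplingError("object maps must be 2D")
        if self.pixel <= 0:
            raise SamplingError(f"pixel must be positive, got {self.pixel}")
        if np.any(self.b < 0):
            raise SamplingError("absorption exponent B must be >= 0")

    @property
    def contact_intensity(self) -> np.ndarray:
        """Intensity at zero propagation distance, I0 = exp(-2B)."""
        return np.exp(-2.0 * self.b)

    def exit_wave(self) -> ComplexWavefield:
        """u = exp(-B + i*phi)."""
        return ComplexWavefield(np.exp(-self.b + 1j * self.phi), self.pixel)


def fresnel_transfer_function(
    shape: tuple[int, int], pixel: float, wavelength: float, distance: float
) -> np.ndarray:
    """H_D(f) = exp(-i * pi * lambda * D * |f|^2) on the DFT grid."""
    return np.exp(-1j * chirp_phase(shape, pixel, wavelength, distance))


def _pad_symmetric(a: np.ndarray) -> tuple[np.ndarray, tuple[slice, slice]]:
    ny, nx = a.shape
    py, px = ny // 2, nx // 2
    padded = np.pad(a, ((py, ny - py), (px, nx - px)), mode="symmetric")
    return padded, (slice(py, py + ny), slice(px, px + nx))


def fresnel_propagate(
    u: ComplexWavefield, wavelength: float, distance: float, pad: bool = False
) -> ComplexWavefield:
    """Propagate a wavefield over ``distance`` metres (negative = backward).

    Single-FFT transfer-function implementation; exactly unitary and
    additive in distance when ``pad=False``.  With ``pad=True`` the field is
    symmetrically edge-padded to twice its size before the FFT and cropped
    afterwards, which suppresses wrap-around artefacts from the periodic
    boundary but breaks the exact unitarity/composition identities.
    """
    if distance == 0:
        return u.copy()
    values = u.values
    window: tuple[slice, slice] | None = None
    if pad:
        values, window = _pad_symmetric(values)
    h = fresnel_transfer_function(values.shape, u.pixel, wavelength, distance)
    out = np.fft.ifft2(h * np.fft.fft2(values))
    if window is not None:
        out = out[window]
    return ComplexWavefield(out, u.pixel)


def intensity(u: ComplexWavefield) -> np.ndarray:
    """Measured intensity |u|^2, elementwise."""
    return np.abs(u.values) ** 2


def ctf_forward(
    obj: ObjectMaps, wavelength: float, distance: float
) -> np.ndarray:
    """Weak-object (CTF) intensity at distance D.

    Valid for small ``phi`` and ``B``; the phase is transferred by
    ``2 sin(chi_D)`` and absorption by ``-2 cos(chi_D)``.  The DC term is the
    model's own contact intensity 1 - 2*mean(B).
    """
    chi = chirp_phase(obj.phi.shape, obj.pixel, wavelength, distance)
    i_hat = 2.0 * np.sin(chi) * np.fft.fft2(obj.phi) - 2.0 * np.cos(chi) * np.fft.fft2(obj.b)
    return 1.0 + np.real(np.fft.ifft2(i_hat))


def tie_forward(
    obj: ObjectMaps, wavelength: float, distance: float
) -> np.ndarray:
    """Transport-of-intensity intensity at (short) distance D.

    ``I_D = I0 - (lambda*D / 2 pi) * div(I0 * grad phi)`` with spectral
    derivatives (periodic boundary).  First order in D; accurate when the
    Fresnel number of the smallest feature is large.
    """
    i0 = obj.contact_intensity
    fy, fx = np.fft.fftfreq(obj.phi.shape[0], d=obj.pixel)[:, None], \
        np.fft.fftfreq(obj.phi.shape[1], d=obj.pixel)[None, :]
    phi_hat = np.fft.fft2(obj.phi)
    gy = np.real(np.fft.ifft2(2j * np.pi * fy * phi_hat))
    gx = np.real(np.fft.ifft2(2j * np.pi * fx * phi_hat))
    div = np.real(np.fft.ifft2(2j * np.pi * fy * np.fft.fft2(i0 * gy))) + \
        np.real(np.fft.ifft2(2j * np.pi * fx * np.fft.fft2(i0 * gx)))
    return i0 - wavelength * distance / (2.0 * np.pi) * div
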