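"""Direct (filter-based) phase retrieval from near-field holograms.

All methods here are non-iterative Fourier-filter inversions of a linearized
forward model, taking a :class:`HologramStack` of flat-corrected,
background-normalized intensity images at one or more effective propagation
distances:

* :func:`wtie` — weak-absorption transport-of-intensity inversion
  (single distance, Bronnikov-type filter).
* :func:`tiehom` — homogeneous-object (single-material, Paganin-type)
  retrieval; needs the ratio delta/beta; multi-distance generalization by
  least squares.
* :func:`ctf` — weak-object contrast-transfer-function retrieval of both
  phase and absorption by a per-frequency 2x2 least-squares solve.
* :func:`ctf_pure_phase` — CTF specialization for negligible absorption.
* :func:`mixed_approach` — combined CTF/TIE model solving for psi = I0*phi,
  valid at strong absorption and long distance; needs a contact image and
  supports homogeneous / multi-material / heterogeneous low-frequency priors.

Common conventions: the mean (f = 0) phase is unobservable and set to zero;
a Tikhonov term ``alpha`` damps ill-conditioned frequencies, and a floor
``ALPHA_MIN = 1e-12`` is always added to protect the chirp zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, NamedTuple, Sequence

import numpy as np

from .exceptions import DataError, DegenerateDistanceError
from .geometry import chirp_phase

__all__ = [
    "ALPHA_MIN",
    "DEFAULT_ALPHA",
    "EPS_CLIP",
    "HologramStack",
    "Method",
    "Prior",
    "RetrievalConfig",
    "TiehomResult",
    "wtie",
    "tiehom",
    "ctf",
    "ctf_pure_phase",
    "mixed_approach",
    "retrieve",
    "fourier_resample",
]

logger = logging.getLogger(__name__)

#: Tikhonov floor always added so chirp zeros never divide by zero.
ALPHA_MIN = 1e-12
#: Default regularization (relative to the O(1) DC gain of the filters).
DEFAULT_ALPHA = 1e-8
#: Clip floor for logarithms of filtered intensities.
EPS_CLIP = 1e-8


@dataclass
class HologramStack:
    """Per-distance intensity images with their effective geometry.

    Images must be flat/dark-corrected, mutually aligned, resampled to a
    common (effective) pixel, and normalized so the background is ~1.

    Parameters
    ----------
    images:
        Sequence of non-negative 2D arrays, all the same shape.
    distances:
        Effective (parallel-beam equivalent) propagation distance per image,
        in metres; distinct when there is more than one image.
    pixel:
        Common effective pixel size, metres.
    wavelength:
        X-ray wavelength, metres.
    """

    images: np.ndarray
    distances: np.ndarray
    pixel: float
    wavelength: float

    def __post_init__(self) -> None:
        self.images = np.asarray(
            [np.asarray(im, dtype=np.float64) for im in self.images]
        )
        self.distances = np.atleast_1d(np.asarray(self.distances, dtype=np.float64))
        if self.images.ndim != 3:
            raise DataError("images must be a sequence of 2D arrays of equal shape")
        if len(self.images) != len(self.distances):
            raise DataError(
                f"{len(self.images)} images but {len(self.distances)} distances"
            )
        if len(self.images) == 0:
            raise DataError("empty hologram stack")
        if np.any(self.images < 0):
            raise DataError("intensities must be non-negative")
        if len(self.distances) > 1 and len(set(self.distances.tolist())) != len(
            self.distances
        ):
            raise DataError("distances must be distinct")
        if self.pixel <= 0 or self.wavelength <= 0:
            raise DataError("pixel and wavelength must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1:]

    def __len__(self) -> int:
        return len(self.images)

    def chirps(self) -> np.ndarray:
        """chi_D(f) for every distance, stacked along axis 0."""
        return np.asarray(
            [
                chirp_phase(self.shape, self.pixel, self.wavelength, d)
                for d in self.distances
            ]
        )


class Method(str, Enum):
    WTIE = "wtie"
    TIEHOM = "tiehom"
    CTF = "ctf"
    CTF_PURE_PHASE = "ctfpurephase"
    MIXED = "mixed"


class Prior(str, Enum):
    NONE = "none"
    HOMOGENEOUS = "homogeneous"
    MULTIMATERIAL = "multimaterial"
    HETEROGENEOUS = "heterogeneous"


@dataclass
class RetrievalConfig:
    """Algorithm selection and parameters for :func:`retrieve`.

    ``material_thresholds`` are cut values on ln(I0) (increasing); with n
    thresholds, ``material_delta_beta`` lists n+1 ratios, one per bin.
    ``hetero_fn`` maps the absorption exponent B (a beta proxy) to a local
    delta/beta ratio.
    """

    method: Method = Method.CTF
    delta_beta: float = 100.0
    alpha: float = DEFAULT_ALPHA
    prior: Prior = Prior.NONE
    material_thresholds: Sequence[float] = field(default_factory=list)
    material_delta_beta: Sequence[float] = field(default_factory=list)
    hetero_fn: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if isinstance(self.method, str):
            self.method = Method(self.method)
        if isinstance(self.prior, str):
            self.prior = Prior(self.prior)
        if self.alpha < 0:
            raise DataError(f"alpha must be >= 0, got {self.alpha}")
        if self.delta_beta <= 0:
            raise DataError(f"delta/beta must be > 0, got {self.delta_beta}")
        th = list(self.material_thresholds)
        if th and sorted(th) != th:
            raise DataError("material_thresholds must be strictly increasing")
        if th and len(self.material_delta_beta) != len(th) + 1:
            raise DataError(
                "need one delta/beta per material: len(material_delta_beta) "
                "must equal len(material_thresholds) + 1"
            )


class TiehomResult(NamedTuple):
    phi: np.ndarray
    b: np.ndarray
    thickness: np.ndarray | None


def _zero_dc(a_hat: np.ndarray) -> np.ndarray:
    a_hat[0, 0] = 0.0
    return a_hat


def wtie(stack: HologramStack, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Weak-absorption TIE phase retrieval from a single distance.

    Inverts ``DFT[I_D/mean - 1] = 2*pi*lambda*D*|f|^2 * DFT[phi]`` with
    Tikhonov damping: ``phi_hat = data_hat / (2 pi lambda D |f|^2 + alpha)``.
    The first image of the stack is used.  Returns the zero-mean phase map.
    """
    d = float(stack.distances[0])
    if d == 0:
        raise DegenerateDistanceError("WTIE needs a non-zero propagation distance")
    img = stack.images[0]
    contrast = img / img.mean() - 1.0
    denom = 2.0 * chirp_phase(stack.shape, stack.pixel, stack.wavelength, d)
    phi_hat = np.fft.fft2(contrast) / (denom + alpha + ALPHA_MIN)
    return np.real(np.fft.ifft2(_zero_dc(phi_hat)))


def _paganin_filters(stack: HologramStack, delta_beta: float) -> np.ndarray:
    """g_D(f) = 1 + pi*lambda*D*(delta/beta)*|f|^2 per distance."""
    return 1.0 + delta_beta * stack.chirps()


def tiehom(
    stack: HologramStack,
    delta_beta: float,
    alpha: float = 0.0,
    beta: float | None = None,
) -> TiehomResult:
    """Homogeneous-object (Paganin-type) retrieval, single or multi distance.

    With ``gamma = delta/beta`` and filter ``g_D(f) = 1 + pi lambda D gamma
    |f|^2`` the filtered contact intensity is ``A = IDFT[DFT[I_D] / g_D]``
    (single distance) or the least-squares combination
    ``DFT[A] = sum_D g_D DFT[I_D] / (sum_D g_D^2 + alpha)`` (multi distance).
    Then ``B = -ln(A)/2`` and ``phi = gamma * ln(A) / 2``; the projected
    thickness ``t = 2 B lambda / (4 pi beta)`` is returned when ``beta`` is
    given.  A is clipped below at ``EPS_CLIP`` (count logged) before the log.
    """
    if delta_beta <= 0:
        raise DataError(f"delta/beta must be > 0, got {delta_beta}")
    g = _paganin_filters(stack, delta_beta)
    if len(stack) == 1:
        a_hat = np.fft.fft2(stack.images[0]) / g[0]
    else:
        num = np.sum(g * np.fft.fft2(stack.images, axes=(-2, -1)), axis=0)
        a_hat = num / (np.sum(g * g, axis=0) + alpha)
    a = np.real(np.fft.ifft2(a_hat))
    n_clipped = int(np.count_nonzero(a < EPS_CLIP))
    if n_clipped:
        logger.warning("tiehom: clipped %d non-positive pixels before log", n_clipped)
        a = np.clip(a, EPS_CLIP, None)
    log_a = np.log(a)
    b = -0.5 * log_a
    phi = 0.5 * delta_beta * log_a
    thickness = None
    if beta is not None:
        thickness = 2.0 * b * stack.wavelength / (4.0 * np.pi * beta)
    return TiehomResult(phi=phi, b=b, thickness=thickness)


def _ctf_terms(stack: HologramStack):
    chi = stack.chirps()
    s = np.sin(chi)
    c = np.cos(chi)
    data_hat = np.fft.fft2(stack.images - 1.0, axes=(-2, -1))
    return s, c, data_hat


def ctf(
    stack: HologramStack, alpha: float = DEFAULT_ALPHA
) -> tuple[np.ndarray, np.ndarray]:
    """Contrast-transfer-function retrieval of phase and absorption.

    Solves, per spatial frequency, the least-squares problem for the model
    ``DFT[I_D - 1] = 2 sin(chi_D) phi_hat - 2 cos(chi_D) b_hat`` over all
    distances, via the Tikhonov-damped 2x2 normal equations.  Returns
    ``(phi, b)``; the phase mean is set to zero, the absorption mean follows
    from the mean attenuation of the data.
    """
    s, c, data_hat = _ctf_terms(stack)
    a = alpha + ALPHA_MIN
    a11 = 4.0 * np.sum(s * s, axis=0) + a
    a22 = 4.0 * np.sum(c * c, axis=0) + a
    a12 = -4.0 * np.sum(s * c, axis=0)
    b1 = 2.0 * np.sum(s * data_hat, axis=0)
    b2 = -2.0 * np.sum(c * data_hat, axis=0)
    det = a11 * a22 - a12 * a12
    phi_hat = (a22 * b1 - a12 * b2) / det
    b_hat = (a11 * b2 - a12 * b1) / det
    phi = np.real(np.fft.ifft2(_zero_dc(phi_hat)))
    b = np.real(np.fft.ifft2(b_hat))
    return phi, b


def ctf_pure_phase(stack: HologramStack, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """CTF retrieval for a negligibly absorbing object.

    ``phi_hat = sum_D 2 sin(chi_D) DFT[I_D - 1] / (sum_D 4 sin^2(chi_D) +
    alpha)``; zero-mean phase returned.
    """
    s, _, data_hat = _ctf_terms(stack)
    phi_hat = (
        2.0 * np.sum(s * data_hat, axis=0)
        / (4.0 * np.sum(s * s, axis=0) + alpha + ALPHA_MIN)
    )
    return np.real(np.fft.ifft2(_zero_dc(phi_hat)))


def _prior_delta_beta_map(cfg: RetrievalConfig, log_i0: np.ndarray) -> np.ndarray:
    if cfg.prior is Prior.HOMOGENEOUS:
        return np.full_like(log_i0, cfg.delta_beta)
    if cfg.prior is Prior.MULTIMATERIAL:
        if not len(cfg.material_delta_beta):
            raise DataError("multimaterial prior needs material_delta_beta")
        idx = np.digitize(log_i0, np.asarray(cfg.material_thresholds))
        return np.asarray(cfg.material_delta_beta, dtype=np.float64)[idx]
    if cfg.prior is Prior.HETEROGENEOUS:
        if cfg.hetero_fn is None:
            raise DataError("heterogeneous prior needs hetero_fn")
        return np.asarray(cfg.hetero_fn(-0.5 * log_i0), dtype=np.float64)
    raise DataError(f"unknown prior {cfg.prior}")


def mixed_approach(
    stack: HologramStack,
    contact_image: np.ndarray,
    cfg: RetrievalConfig | None = None,
) -> np.ndarray:
    """Mixed CTF/TIE retrieval with an attenuation (contact) image.

    Solves for ``psi = I0 * phi`` in Fourier space from the residual
    holograms ``Delta_D = DFT[I_D] - cos(chi_D) DFT[I0]``:

    ``psi_hat = (sum_D 2 sin(chi_D) Delta_D + alpha * DFT[psi_prior])
    / (sum_D 4 sin^2(chi_D) + alpha)``,

    then ``phi = IDFT[psi_hat] / I0``.  The prior regularizes the
    low-frequency content near the chirp zeros: for a homogeneous object
    ``phi_prior = (delta/beta)/2 * ln I0`` (per-pixel delta/beta for the
    multi-material and heterogeneous variants), ``psi_prior = I0 *
    phi_prior``.  ``I0 <= 0`` pixels are clipped at ``EPS_CLIP``.
    """
    if cfg is None:
        cfg = RetrievalConfig(method=Method.MIXED, prior=Prior.NONE)
    if contact_image is None:
        raise DataError("mixed approach requires a contact (attenuation) image")
    i0 = np.asarray(contact_image, dtype=np.float64)
    if i0.shape != stack.shape:
        raise DataError(f"contact image shape {i0.shape} != stack shape {stack.shape}")
    n_clipped = int(np.count_nonzero(i0 <= 0))
    if n_clipped:
        logger.warning("mixed_approach: clipped %d non-positive I0 pixels", n_clipped)
        i0 = np.clip(i0, EPS_CLIP, None)

    chi = stack.chirps()
    s = np.sin(chi)
    i0_hat = np.fft.fft2(i0)
    delta_hat = np.fft.fft2(stack.images, axes=(-2, -1)) - np.cos(chi) * i0_hat

    if cfg.prior is Prior.NONE:
        prior_hat = 0.0
    else:
        log_i0 = np.log(i0)
        phi_prior = 0.5 * _prior_delta_beta_map(cfg, log_i0) * log_i0
        prior_hat = np.fft.fft2(i0 * phi_prior)

    alpha = cfg.alpha
    psi_hat = (2.0 * np.sum(s * delta_hat, axis=0) + alpha * prior_hat) / (
        4.0 * np.sum(s * s, axis=0) + alpha + ALPHA_MIN
    )
    if cfg.prior is Prior.NONE:
        _zero_dc(psi_hat)
    return np.real(np.fft.ifft2(psi_hat)) / i0


def retrieve(
    stack: HologramStack,
    cfg: RetrievalConfig,
    contact_image: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Dispatch a retrieval per ``cfg.method``; returns named output maps."""
    if cfg.method is Method.WTIE:
        return {"phi": wtie(stack, cfg.alpha)}
    if cfg.method is Method.TIEHOM:
        res = tiehom(stack, cfg.delta_beta, cfg.alpha)
        return {"phi": res.phi, "b": res.b}
    if cfg.method is Method.CTF:
        phi, b = ctf(stack, cfg.alpha)
        return {"phi": phi, "b": b}
    if cfg.method is Method.CTF_PURE_PHASE:
        return {"phi": ctf_pure_phase(stack, cfg.alpha)}
    if cfg.method is Method.MIXED:
        if contact_image is None:
            # fall back to the shortest-distance image as the attenuation image
            idx = int(np.argmin(np.abs(stack.distances)))
            contact_image = stack.images[idx]
        return {"phi": mixed_approach(stack, contact_image, cfg)}
    raise DataError(f"unknown method {cfg.method}")


def fourier_resample(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Resample a (real) image to ``shape`` by Fourier cropping/zero-padding.

    Used to bring multi-distance images, acquired at different effective
    pixels, onto the common (smallest-pixel) grid before stacking.  The mean
    is preserved exactly.
    """
    ny, nx = image.shape
    my, mx = shape
    f = np.fft.fftshift(np.fft.fft2(image))
    out = np.zeros(shape, dtype=np.complex128)

    def _win(n, m):
        # overlapping centred band
        k = min(n, m)
        src = slice((n - k) // 2, (n - k) // 2 + k)
        dst = slice((m - k) // 2, (m - k) // 2 + k)
        return src, dst

    sy, dy = _win(ny, my)
    sx, dx = _win(nx, mx)
    out[dy, dx] = f[sy, sx]
    out *= (my * mx) / (ny * nx)
    return np.real(np.fft.ifft2(np.fft.ifftshift(out)))
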