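"""Shared helpers: smooth random phantoms, Fresnel-simulated stacks, NRMSE."""

from __future__ import annotations

import numpy as np
import pytest

from holophase import HologramStack, ObjectMaps, fresnel_propagate, intensity

# canonical simulated-study parameters: 12.4 keV (lambda = 1 A), micrometre
# detector sampling for the direct filter methods, 50 nm nano-holography
# sampling for the iterative methods (chi ~ 1 at the feature scale there).
WAVELENGTH = 1e-10
PIXEL_UM = 1e-6
PIXEL_NANO = 50e-9


def blob_map(
    shape: tuple[int, int],
    seed: int,
    amp: float,
    sigma_range: tuple[float, float] = (4.0, 12.0),
    n_blobs: int = 8,
) -> np.ndarray:
    """Sum of random Gaussian blobs, rescaled to peak amplitude ``amp``."""
    rng = np.random.default_rng(seed)
    ny, nx = shape
    y, x = np.mgrid[:ny, :nx]
    f = np.zeros(shape)
    for _ in range(n_blobs):
        cy = rng.uniform(0.2 * ny, 0.8 * ny)
        cx = rng.uniform(0.2 * nx, 0.8 * nx)
        s = rng.uniform(*sigma_range)
        f += rng.uniform(0.5, 1.0) * np.exp(-((y - cy) ** 2 + (x - cx) ** 2) / (2 * s * s))
    return amp * f / np.abs(f).max()


def nrmse(estimate: np.ndarray, truth: np.ndarray) -> float:
    """RMS error over the truth's dynamic range, after matching means.

    The mean (f = 0) component is matched because every retrieval method here
    leaves the mean phase unobservable by convention.
    """
    est = estimate - estimate.mean() + truth.mean()
    return float(np.sqrt(np.mean((est - truth) ** 2)) / (truth.max() - truth.min()))


def fresnel_stack(
    obj: ObjectMaps, distances, pad: bool = False
) -> HologramStack:
    """Noiseless full-Fresnel hologram stack of ``obj`` at given distances."""
    u0 = obj.exit_wave()
    imgs = [
        intensity(fresnel_propagate(u0, WAVELENGTH, float(d), pad=pad))
        for d in np.atleast_1d(distances)
    ]
    return HologramStack(
        images=imgs,
        distances=np.atleast_1d(distances),
        pixel=obj.pixel,
        wavelength=WAVELENGTH,
    )


@pytest.fixture
def weak_object() -> ObjectMaps:
    """256^2 weak phantom: |phi| <= 0.01 rad, B <= 0.005."""
    phi = blob_map((256, 256), seed=1, amp=0.01)
    b = blob_map((256, 256), seed=2, amp=0.005)
    return ObjectMaps(phi=phi - phi.mean(), b=b, pixel=PIXEL_UM)
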