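"""Filter-based retrieval: self-consistency oracles and Fresnel recovery."""

import numpy as np
import pytest

from holophase import (
    DataError,
    DegenerateDistanceError,
    HologramStack,
    ObjectMaps,
    RetrievalConfig,
    ctf,
    ctf_forward,
    ctf_pure_phase,
    fourier_resample,
    make_disc_phantom,
    mixed_approach,
    tiehom,
    wtie,
)
from holophase.geometry import chirp_phase

from conftest import WAVELENGTH, PIXEL_UM, blob_map, fresnel_stack, nrmse

LAM = WAVELENGTH
N = 256


def stack_of(images, distances, pixel=PIXEL_UM):
    return HologramStack(images=images, distances=np.atleast_1d(distances),
                         pixel=pixel, wavelength=LAM)


def mode(shape, ky, kx, amp, phase=0.0):
    y, x = np.mgrid[: shape[0], : shape[1]]
    return amp * np.cos(2 * np.pi * (ky * y / shape[0] + kx * x / shape[1]) + phase)


@pytest.fixture(scope="module")
def mode_object():
    """Few-mode phantom with spectral support away from the chirp zeros of
    the distance pair (0.02, 0.05) m — the conditioning the CTF-family
    self-consistency oracles assume."""
    shape = (N, N)
    phi = (mode(shape, 12, 7, 1e-3) + mode(shape, 33, -21, 5e-4, 0.7)
           + mode(shape, 60, 45, 3e-4, 1.3))
    b = mode(shape, 18, -11, 4e-4, 0.3) + mode(shape, 47, 29, 2e-4, 2.1)
    return ObjectMaps(phi=phi, b=b - b.min(), pixel=PIXEL_UM)


MODE_DISTANCES = [0.02, 0.05]


class TestStackValidation:
    def test_rejects_negative_intensity(self):
        with pytest.raises(DataError):
            stack_of([-np.ones((16, 16))], [0.01])

    def test_rejects_duplicate_distances(self):
        ims = [np.ones((16, 16))] * 2
        with pytest.raises(DataError):
            stack_of(ims, [0.01, 0.01])

    def test_rejects_mismatched_lengths(self):
        with pytest.raises(DataError):
            stack_of([np.ones((16, 16))], [0.01, 0.02])


class TestWtie:
    def test_flat_image_gives_zero_phase(self):
        rec = wtie(stack_of([np.ones((64, 64))], [0.01]), alpha=0.0)
        np.testing.assert_allclose(rec, 0.0, atol=1e-12)

    def test_inverts_own_forward_model(self):
        phi = blob_map((N, N), seed=1, amp=1e-3)
        phi -= phi.mean()
        chi = chirp_phase((N, N), PIXEL_UM, LAM, 0.01)
        img = 1.0 + np.real(np.fft.ifft2(2.0 * chi * np.fft.fft2(phi)))
        rec = wtie(stack_of([img], [0.01]), alpha=0.0)
        assert np.abs(rec - phi).max() / np.abs(phi).max() <= 1e-8

    def test_single_mode_recovery_factor(self):
        # phi = eps cos(2 pi f0 x): recovered amplitude scales by
        # 2 pi lam D f0^2 / (2 pi lam D f0^2 + alpha), exactly
        n, k, d, eps, alpha = 128, 9, 0.02, 1e-3, 1e-3
        phi = mode((n, n), 0, k, eps)
        f0 = k / (n * PIXEL_UM)
        den = 2 * np.pi * LAM * d * f0 * f0
        img = 1.0 + np.real(
            np.fft.ifft2(
                2.0 * chirp_phase((n, n), PIXEL_UM, LAM, d) * np.fft.fft2(phi)
            )
        )
        rec = wtie(stack_of([img], [d]), alpha=alpha)
        expected = phi * den / (den + alpha)
        np.testing.assert_allclose(rec, expected, atol=1e-10 * eps)

    def test_zero_distance_rejected(self):
        with pytest.raises(DegenerateDistanceError):
            wtie(stack_of([np.ones((16, 16))], [0.0]))


class TestTiehom:
    def test_flat_stack_gives_empty_object(self):
        res = tiehom(stack_of([np.ones((64, 64))], [0.01]), delta_beta=100.0)
        np.testing.assert_allclose(res.b, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.phi, 0.0, atol=1e-10)

    @pytest.mark.parametrize("n_dist", [1, 3])
    def test_inverts_own_filter(self, n_dist):
        gamma = 500.0
        b = blob_map((N, N), seed=3, amp=0.05)
        i0 = np.exp(-2.0 * b)
        distances = [0.01, 0.02, 0.035][:n_dist]
        imgs = []
        for d in distances:
            g = 1.0 + gamma * chirp_phase((N, N), PIXEL_UM, LAM, d)
            imgs.append(np.real(np.fft.ifft2(g * np.fft.fft2(i0))))
        res = tiehom(stack_of(imgs, distances), delta_beta=gamma, alpha=0.0)
        assert np.abs(res.b - b).max() <= 1e-10
        np.testing.assert_allclose(res.phi, -gamma * res.b, atol=1e-12)

    def test_disc_thickness_recovery_from_fresnel(self):
        # homogeneous disc, F(radius) = 20; interior error away from the rim
        # fringe (width sqrt(lam*D)) below 2% of the peak thickness
        gamma, delta = 500.0, 1e-7
        beta = delta / gamma
        radius, t_max = 30e-6, 2e-6
        ph = make_disc_phantom((N, N), radius, t_max, delta, beta, PIXEL_UM)
        d = radius * radius / (LAM * 20.0)
        stack = fresnel_stack(ph.object_maps(LAM), [d], pad=True)
        res = tiehom(stack, gamma, beta=beta)
        fringe_px = int(np.ceil(np.sqrt(LAM * d) / PIXEL_UM))
        from scipy.ndimage import binary_erosion
        interior = binary_erosion(ph.thickness > 0, iterations=fringe_px)
        err = np.abs(res.thickness - ph.thickness)[interior].max() / t_max
        assert err <= 0.02


class TestCtf:
    def test_zero_contrast_gives_zero_maps(self):
        phi, b = ctf(stack_of([np.ones((64, 64))] * 2, [0.01, 0.03]), alpha=0.0)
        np.testing.assert_allclose(phi, 0.0, atol=1e-12)
        np.testing.assert_allclose(b, 0.0, atol=1e-12)

    def test_inverts_own_forward_model(self, mode_object):
        imgs = [ctf_forward(mode_object, LAM, d) for d in MODE_DISTANCES]
        stack = stack_of(imgs, MODE_DISTANCES)
        phi, b = ctf(stack, alpha=0.0)
        t_phi, t_b = mode_object.phi, mode_object.b
        assert np.abs(phi - t_phi).max() / np.abs(t_phi).max() <= 1e-9
        db = (b - b.mean()) - (t_b - t_b.mean())
        assert np.abs(db).max() / np.abs(t_b - t_b.mean()).max() <= 1e-9

    def test_recovers_weak_phantom_from_fresnel(self, weak_object):
        stack = fresnel_stack(weak_object, [0.02, 0.05, 0.09])
        phi, b = ctf(stack, alpha=1e-8)
        assert nrmse(phi, weak_object.phi) <= 0.02

    def test_nrmse_decreases_with_distance_count(self, weak_object):
        errs = []
        for dist in ([0.05], [0.02, 0.05], [0.02, 0.035, 0.05, 0.09]):
            stack = fresnel_stack(weak_object, dist)
            phi, _ = ctf(stack, alpha=1e-8)
            errs.append(nrmse(phi, weak_object.phi))
        assert errs[0] > errs[1] > errs[2]


class TestCtfPurePhase:
    def test_zero_contrast_gives_zero(self):
        rec = ctf_pure_phase(stack_of([np.ones((64, 64))] * 2, [0.01, 0.03]))
        np.testing.assert_allclose(rec, 0.0, atol=1e-12)

    def test_inverts_own_forward_model(self, mode_object):
        pure = ObjectMaps(mode_object.phi, np.zeros((N, N)), PIXEL_UM)
        imgs = [ctf_forward(pure, LAM, d) for d in MODE_DISTANCES]
        rec = ctf_pure_phase(stack_of(imgs, MODE_DISTANCES), alpha=0.0)
        assert np.abs(rec - pure.phi).max() / np.abs(pure.phi).max() <= 1e-9

    def test_matches_full_ctf_on_pure_phase_data(self, mode_object):
        # with the B-columns dropped the two solvers coincide on B = 0 data
        pure = ObjectMaps(mode_object.phi, np.zeros((N, N)), PIXEL_UM)
        imgs = [ctf_forward(pure, LAM, d) for d in MODE_DISTANCES]
        stack = stack_of(imgs, MODE_DISTANCES)
        a = ctf_pure_phase(stack, alpha=1e-8)
        phi_full, _ = ctf(stack, alpha=1e-8)
        # same model, same data: both recover the true phase tightly (the
        # full solver pays a slightly larger alpha penalty on its 2x2 solve)
        assert np.abs(a - pure.phi).max() / np.abs(pure.phi).max() <= 1e-6
        assert np.abs(phi_full - pure.phi).max() / np.abs(pure.phi).max() <= 1e-5

    def test_recovers_pure_phase_weak_phantom(self):
        phi = blob_map((N, N), seed=9, amp=0.01)
        obj = ObjectMaps(phi - phi.mean(), np.zeros((N, N)), PIXEL_UM)
        stack = fresnel_stack(obj, [0.02, 0.035, 0.05, 0.09])
        rec = ctf_pure_phase(stack, alpha=1e-8)
        assert nrmse(rec, obj.phi) <= 0.02


class TestMixedApproach:
    def test_zero_contrast_gives_zero_phase(self):
        stack = stack_of([np.ones((64, 64))] * 2, [0.01, 0.03])
        rec = mixed_approach(stack, np.ones((64, 64)))
        np.testing.assert_allclose(rec, 0.0, atol=1e-12)

    def test_reduces_to_pure_phase_ctf_without_absorption(self, mode_object):
        pure = ObjectMaps(mode_object.phi, np.zeros((N, N)), PIXEL_UM)
        imgs = [ctf_forward(pure, LAM, d) for d in MODE_DISTANCES]
        stack = stack_of(imgs, MODE_DISTANCES)
        cfg = RetrievalConfig(method="mixed", prior="none", alpha=1e-8)
        a = mixed_approach(stack, np.ones((N, N)), cfg)
        b = ctf_pure_phase(stack, alpha=1e-8)
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_inverts_own_forward_model(self, mode_object):
        # data built from the mixed model itself:
        # DFT[I_D] = cos(chi) DFT[I0] + 2 sin(chi) DFT[I0 * phi]
        i0 = mode_object.contact_intensity
        psi = i0 * mode_object.phi
        psi -= psi.mean()
        phi_truth = psi / i0
        imgs = []
        for d in MODE_DISTANCES:
            chi = chirp_phase((N, N), PIXEL_UM, LAM, d)
            i_hat = np.cos(chi) * np.fft.fft2(i0) + 2.0 * np.sin(chi) * np.fft.fft2(psi)
            imgs.append(np.clip(np.real(np.fft.ifft2(i_hat)), 0.0, None))
        cfg = RetrievalConfig(method="mixed", prior="none", alpha=0.0)
        rec = mixed_approach(stack_of(imgs, MODE_DISTANCES), i0, cfg)
        assert np.abs(rec - phi_truth).max() / np.abs(phi_truth).max() <= 1e-8

    def test_homogeneous_disc_recovery_with_true_prior(self):
        gamma, delta = 200.0, 1e-6
        t_max = 1.0 * LAM / (2 * np.pi * delta)  # peak phase 1 rad
        ph = make_disc_phantom((N, N), 30e-6, t_max, delta, delta / gamma, PIXEL_UM)
        obj = ph.object_maps(LAM)
        stack = fresnel_stack(obj, [0.02, 0.05], pad=True)
        cfg = RetrievalConfig(
            method="mixed", prior="homogeneous", delta_beta=gamma, alpha=1e-8
        )
        rec = mixed_approach(stack, obj.contact_intensity, cfg)
        assert nrmse(rec, obj.phi) <= 0.03

    def test_missing_contact_image_rejected(self):
        stack = stack_of([np.ones((16, 16))], [0.01])
        with pytest.raises(DataError):
            mixed_approach(stack, None)

    def test_multimaterial_prior_selects_per_pixel_ratio(self):
        # two materials split by a threshold on ln I0; prior map must follow it
        i0 = np.ones((64, 64))
        i0[:32] = 0.5
        stack = stack_of([np.ones((64, 64))], [0.02])
        cfg = RetrievalConfig(
            method="mixed",
            prior="multimaterial",
            alpha=1.0,
            material_thresholds=[-0.5],
            material_delta_beta=[100.0, 300.0],
        )
        rec = mixed_approach(stack, i0, cfg)
        assert np.isfinite(rec).all()
        # strong-absorption half must get the low-threshold material ratio:
        # prior phase = gamma/2 * ln I0 < 0 only where I0 < 1
        assert rec[:32].mean() < rec[32:].mean()


class TestFilterProperties:
    def test_linearity_in_the_data(self):
        rng = np.random.default_rng(11)
        d = [0.02, 0.05]

        def contrast_image():
            c = 0.01 * rng.normal(size=(64, 64))
            return 1.0 + c - c.mean()  # exactly unit background

        a = [contrast_image() for _ in d]
        b = [contrast_image() for _ in d]
        # superposition of the *contrast* (images minus unit background)
        mix = [1.0 + 0.3 * (ia - 1.0) + 0.7 * (ib - 1.0) for ia, ib in zip(a, b)]
        for fn in (lambda s: wtie(s, 1e-6), lambda s: ctf_pure_phase(s, 1e-6),
                   lambda s: ctf(s, 1e-6)[0]):
            ra, rb = fn(stack_of(a, d)), fn(stack_of(b, d))
            rm = fn(stack_of(mix, d))
            np.testing.assert_allclose(rm, 0.3 * ra + 0.7 * rb, atol=1e-10)

    def test_alpha_monotonicity_single_mode(self):
        n, k, d = 64, 7, 0.02
        phi = mode((n, n), 0, k, 1e-3)
        img = 1.0 + np.real(
            np.fft.ifft2(2.0 * chirp_phase((n, n), PIXEL_UM, LAM, d) * np.fft.fft2(phi))
        )
        amps = []
        for alpha in (0.0, 1e-4, 1e-2, 1.0):
            rec = wtie(stack_of([img], [d]), alpha=alpha)
            amps.append(np.abs(rec).max())
        assert all(a2 <= a1 + 1e-15 for a1, a2 in zip(amps, amps[1:]))


class TestFourierResample:
    def test_preserves_mean(self):
        rng = np.random.default_rng(3)
        im = 1.0 + 0.1 * rng.normal(size=(64, 64))
        out = fourier_resample(im, (128, 128))
        assert out.shape == (128, 128)
        assert out.mean() == pytest.approx(im.mean(), rel=1e-12)

    def test_band_limited_round_trip(self):
        im = 1.0 + mode((64, 64), 5, 3, 0.1)
        up = fourier_resample(im, (128, 128))
        back = fourier_resample(up, (64, 64))
        np.testing.assert_allclose(back, im, atol=1e-10)
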