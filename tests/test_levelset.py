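"""Level-set core: initialization, local fitting means, evolution,
post-processing, and the no-reinitialization behaviour."""

import numpy as np
import pytest
from scipy import ndimage
from skimage import morphology

from dermseg.config import LevelSetParams, PostprocessParams
from dermseg.errors import DegenerateInputError
from dermseg.levelset import (LevelSetState, dirac, evolve_step, heaviside,
                              init_phi, lbf_force, local_fitting_means,
                              postprocess_mask, segment_hybrid)
from .conftest import jaccard_of


def _disc_image(n=128, r=30, inside=0.2, outside=0.7):
    yy, xx = np.mgrid[:n, :n]
    disc = (yy - n // 2) ** 2 + (xx - n // 2) ** 2 < r * r
    return np.where(disc, inside, outside), disc


class TestInitPhi:
    def test_dark_disc_gives_expanded_bbox(self):
        img, disc = _disc_image()
        state = init_phi(img)
        rows, cols = np.nonzero(disc)
        r0, r1 = rows.min(), rows.max()
        c0, c1 = cols.min(), cols.max()
        dr, dc = 0.10 * (r1 - r0 + 1), 0.10 * (c1 - c0 + 1)
        expected = np.full(img.shape, -2.0)
        expected[int(np.floor(r0 - dr)):int(np.ceil(r1 + dr)) + 1,
                 int(np.floor(c0 - dc)):int(np.ceil(c1 + dc)) + 1] = 2.0
        assert np.array_equal(state.phi, expected)

    def test_largest_dark_component_wins(self):
        img = np.full((96, 96), 0.8)
        img[10:35, 10:35] = 0.2   # 625 px blob
        img[70:77, 70:77] = 0.2   # 49 px blob
        state = init_phi(img)
        pos = state.phi > 0
        assert pos[20, 20]
        assert not pos[73, 73]

    def test_phi_values_are_binary_step(self):
        img, _ = _disc_image()
        assert set(np.unique(init_phi(img).phi)) == {-2.0, 2.0}

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateInputError):
            init_phi(np.full((64, 64), 0.5))


class TestLocalFittingMeans:
    def test_constant_image_both_equal_value(self):
        lum = np.full((64, 64), 0.37)
        phi = np.where(np.arange(64)[:, None] < 32, 2.0, -2.0) * np.ones((64, 64))
        f1, f2 = local_fitting_means(lum, phi, 15, 1.0)
        assert np.allclose(f1, 0.37, atol=1e-6)
        assert np.allclose(f2, 0.37, atol=1e-6)

    def test_two_phase_disc_recovers_constants_in_deep_regions(self):
        """f1 equals the inside constant deep inside the contour and f2
        the outside constant deep outside (where the window sees a
        single phase)."""
        lum, disc = _disc_image(n=128, r=40)
        phi = np.where(disc, 2.0, -2.0)
        window = 15
        f1, f2 = local_fitting_means(lum, phi, window, 1.0)
        dist_in = ndimage.distance_transform_edt(disc)
        dist_out = ndimage.distance_transform_edt(~disc)
        deep_in = dist_in >= window
        deep_out = dist_out >= window
        assert np.abs(f1[deep_in] - 0.2).max() < 1e-3
        assert np.abs(f2[deep_out] - 0.7).max() < 1e-3

    def test_sign_swap_swaps_means(self, rng):
        lum = rng.random((48, 48))
        phi = rng.standard_normal((48, 48))
        f1, f2 = local_fitting_means(lum, phi, 9, 1.0)
        g1, g2 = local_fitting_means(lum, -phi, 9, 1.0)
        assert np.allclose(f1, g2, atol=1e-12)
        assert np.allclose(f2, g1, atol=1e-12)

    def test_means_within_image_range(self, rng):
        lum = 0.2 + 0.6 * rng.random((48, 48))
        phi = rng.standard_normal((48, 48)) * 2
        f1, f2 = local_fitting_means(lum, phi, 15, 1.0)
        for f in (f1, f2):
            assert f.min() >= lum.min() - 1e-6
            assert f.max() <= lum.max() + 1e-6


class TestEvolveStep:
    def test_constant_image_force_zero_and_curvature_only(self):
        """On a constant image the fitting force vanishes and one step of
        curvature + diffusion flips almost nothing of a smooth disc."""
        n = 96
        lum = np.full((n, n), 0.5)
        yy, xx = np.mgrid[:n, :n]
        disc = (yy - n // 2) ** 2 + (xx - n // 2) ** 2 < 30 ** 2
        phi = np.where(disc, 1.0, -1.0) * ndimage.distance_transform_edt(disc)
        phi = phi - ndimage.distance_transform_edt(~disc) * (~disc)
        p = LevelSetParams().validate()
        force = lbf_force(lum, phi, p)
        assert np.abs(force).max() < 1e-6
        state = LevelSetState(phi=phi.astype(float))
        evolve_step(state, lum, p)
        assert state.flipped_history[0] < 0.01

    def test_contrast_inversion_symmetry(self, rng):
        """Inverting the image, swapping lambda1/lambda2 and negating phi
        yields the exactly mirrored evolution."""
        lum = rng.random((48, 48))
        phi0 = np.where(rng.random((48, 48)) < 0.4, 2.0, -2.0)
        p = LevelSetParams(lambda1=1.0, lambda2=2.0).validate()
        q = LevelSetParams(lambda1=2.0, lambda2=1.0).validate()
        s1 = LevelSetState(phi=phi0.copy())
        s2 = LevelSetState(phi=-phi0.copy())
        evolve_step(s1, lum, p)
        evolve_step(s2, np.clip(1.0 - lum, 0, 1), q)
        assert np.allclose(s1.phi, -s2.phi, atol=1e-9)

    def test_bounded_update(self, rng):
        """One step changes phi by no more than the analytic bound from
        the force scale, curvature cap and diffusion stencil."""
        lum = rng.random((48, 48))
        phi = np.clip(rng.standard_normal((48, 48)) * 1.5, -2, 2)
        p = LevelSetParams().validate()
        state = LevelSetState(phi=phi.copy())
        from dermseg.levelset import curvature
        kappa_max = np.abs(curvature(phi)).max()
        delta_max = 1.0 / (np.pi * p.epsilon)
        # e-terms are bounded by 1 on [0,1] images, scaled by force_scale
        bound = (p.dt * delta_max * (p.force_scale * (p.lambda1 + p.lambda2)
                                     + p.mu * kappa_max)
                 + p.rd_steps * p.rd_dt * 8.0 * np.abs(phi).max())
        evolve_step(state, lum, p)
        assert np.abs(state.phi - phi).max() <= bound + 1e-9


class TestSegmentHybrid:
    def test_noise_free_scene_high_jaccard_and_convergence(
            self, clean_scene, clean_scene_enhanced):
        res = segment_hybrid(clean_scene_enhanced)
        assert res.converged
        assert res.iterations < LevelSetParams().max_iter
        assert jaccard_of(res.mask, clean_scene.lesion_mask) >= 0.95
        # contract: the recorded mask matches the sign of the final field
        assert np.array_equal(res.mask, res.phi > 0)

    def test_narrow_band_gradient_stays_moderate(self, clean_scene_enhanced):
        """No-reinitialization contract: mean |grad phi| in the 5-px band
        stays within [0.1, 5] from iteration 10 onward."""
        res = segment_hybrid(clean_scene_enhanced)
        band = [g for g in res.band_grad_history[9:] if np.isfinite(g)]
        assert band
        assert min(band) >= 0.1
        assert max(band) <= 5.0

    def test_flip_fraction_eventually_monotone_in_windows(self, clean_scene_enhanced):
        """Windowed (width 10) mean flip fraction is non-increasing over
        the tail of a noise-free run."""
        p = LevelSetParams().validate()
        state = init_phi(clean_scene_enhanced)
        while state.iteration < p.max_iter and not state.converged:
            evolve_step(state, clean_scene_enhanced, p)
        hist = np.array(state.flipped_history)
        windows = [hist[i:i + 10].mean() for i in range(0, len(hist) - 9, 10)]
        peak = int(np.argmax(windows))
        tail = windows[peak:]
        assert all(b <= a + 1e-9 for a, b in zip(tail, tail[1:]))

    def test_multiscale_consistency(self, clean_scene, clean_scene_enhanced):
        """On a two-phase image whose inhomogeneity scale is much larger
        than 15 px, single-scale and two-scale results agree."""
        res15 = segment_hybrid(clean_scene_enhanced,
                               LevelSetParams(scales=(15,)))
        res2 = segment_hybrid(clean_scene_enhanced,
                              LevelSetParams(scales=(15, 31)))
        assert jaccard_of(res15.mask, res2.mask) >= 0.98

    def test_no_reinitialization_routine_exposed(self):
        import dermseg.levelset as mod
        names = [n for n in dir(mod) if "reinit" in n.lower()
                 or "signed_distance" in n.lower()]
        assert names == []


class TestPostprocess:
    def test_holes_filled_satellite_removed_boundary_grown(self):
        n = 64
        yy, xx = np.mgrid[:n, :n]
        disc = (yy - 30) ** 2 + (xx - 30) ** 2 < 15 ** 2
        raw = disc.copy()
        raw[(yy - 30) ** 2 + (xx - 30) ** 2 < 2 ** 2] = False  # 3-px hole
        raw[55:58, 55:58] = True                               # small satellite
        out = postprocess_mask(raw)
        expected = morphology.dilation(disc, morphology.disk(1))
        assert not out[56, 56]
        assert np.array_equal(out, expected)

    def test_empty_stays_empty(self):
        assert not postprocess_mask(np.zeros((32, 32), bool)).any()

    def test_clean_disc_only_dilated(self):
        n = 64
        yy, xx = np.mgrid[:n, :n]
        disc = (yy - 32) ** 2 + (xx - 32) ** 2 < 14 ** 2
        out = postprocess_mask(disc)
        assert np.array_equal(out, morphology.dilation(disc, morphology.disk(1)))


def test_heaviside_dirac_consistency():
    z = np.linspace(-6, 6, 1001)
    h = heaviside(z, 1.0)
    d = dirac(z, 1.0)
    num = np.gradient(h, z)
    assert np.allclose(num, d, atol=1e-3)
    assert heaviside(np.array([0.0]), 1.0)[0] == pytest.approx(0.5)
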