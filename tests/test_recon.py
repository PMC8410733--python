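"""Projector adjointness, EM fixed point / monotone likelihood, TOF kernel and
post-filter behaviour, and qualitative TOF advantages."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from scipy.optimize import curve_fit

from pedpet import (
    ReconParams,
    ScannerGeometry,
    gaussian_postfilter,
    osem_reconstruct,
    simulate_listmode,
    tof_kernel,
)
from pedpet.listmode import RECORD_DTYPE, ListModeData
from pedpet.projector import FWHM_TO_SIGMA, get_system_matrix
from pedpet.protocol import standard_phantom
from pedpet.fom import snr


@pytest.fixture(scope="module")
def sm(small_geometry):
    return get_system_matrix(small_geometry, 64, 4.073)


class TestAdjointness:
    def _check(self, A, n_pix, blur_sigma, seed):
        rng = np.random.default_rng(seed)
        x = rng.random(n_pix)
        y = rng.random(A.shape[0])
        if blur_sigma:
            n = int(np.sqrt(n_pix))
            bx = gaussian_filter(x.reshape(n, n), blur_sigma,
                                 mode="constant").ravel()
            bty = gaussian_filter((A.T @ y).reshape(n, n), blur_sigma,
                                  mode="constant").ravel()
            lhs, rhs = (A @ bx) @ y, x @ bty
        else:
            lhs, rhs = (A @ x) @ y, x @ (A.T @ y)
        assert abs(lhs - rhs) <= 1e-6 * max(abs(lhs), abs(rhs))

    def test_plain_projector(self, sm):
        self._check(sm.A, 64 * 64, 0.0, 1)

    def test_with_psf_blur(self, sm):
        self._check(sm.A, 64 * 64, 1.2, 2)

    def test_tof_projector(self, sm):
        self._check(sm.A_tof, 64 * 64, 0.0, 3)

    def test_tof_with_psf(self, sm):
        self._check(sm.A_tof, 64 * 64, 1.2, 4)


def test_tof_rows_marginalise_to_plain_projector(sm, small_geometry):
    """Summing the TOF matrix over TOF bins recovers (almost all of) A."""
    row_sum = np.asarray(sm.A_tof.sum(axis=0)).ravel()
    full = np.asarray(sm.A.sum(axis=0)).ravel()
    # kernel truncation beyond 3 sigma loses <1 % of mass
    np.testing.assert_allclose(row_sum, full, rtol=0.01, atol=1e-9)


class TestTofKernel:
    def test_fwhm_at_555ps(self):
        k = tof_kernel(555.0, 200.0)
        assert k.spatial_fwhm_mm == pytest.approx(83.19, abs=0.1)

    def test_weights_sum_to_one(self):
        k = tof_kernel(555.0, 200.0)
        assert k.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_halving_resolution_halves_fwhm(self):
        assert tof_kernel(277.5, 100.0).spatial_fwhm_mm == pytest.approx(
            tof_kernel(555.0, 200.0).spatial_fwhm_mm / 2.0)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            tof_kernel(-1.0, 100.0)


class TestPostfilter:
    def test_zero_fwhm_is_identity(self):
        img = np.random.default_rng(0).random((32, 32))
        np.testing.assert_array_equal(gaussian_postfilter(img, 0.0, 4.0), img)

    def test_uniform_image_unchanged(self):
        img = np.full((32, 32), 3.7)
        np.testing.assert_allclose(gaussian_postfilter(img, 5.0, 4.0), img,
                                   rtol=1e-12)

    def test_sum_preserved_for_interior_support(self):
        img = np.zeros((64, 64))
        img[24:40, 24:40] = 2.0
        out = gaussian_postfilter(img, 6.0, 4.0)
        assert out.sum() == pytest.approx(img.sum(), rel=1e-3)

    def test_point_source_fwhm_recovered(self):
        """A blurred impulse fits back to the requested FWHM within half a voxel."""
        voxel, fwhm = 2.0, 7.0
        img = np.zeros((65, 65))
        img[32, 32] = 1.0
        out = gaussian_postfilter(img, fwhm, voxel)
        x = (np.arange(65) - 32) * voxel
        prof = out[32, :]

        def g(x, a, s):
            return a * np.exp(-x * x / (2 * s * s))

        (a, s), _ = curve_fit(g, x, prof, p0=(prof.max(), 3.0))
        assert FWHM_TO_SIGMA * abs(s) == pytest.approx(fwhm, abs=voxel / 2)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            gaussian_postfilter(np.ones((4, 4)), -1.0, 4.0)


class TestOsem:
    def test_fixed_point_when_data_equals_model(self, small_geometry, small_phantom):
        """If the measured sinogram equals the forward model of the initial
        image, one full OSEM pass leaves the image unchanged."""
        sm_local = get_system_matrix(small_geometry, 64, 4.073)
        aff = sm_local.attenuation_factors(small_phantom.mu_map)
        sens = sm_local.A.T @ aff
        # OSEM starts from 1 inside the scanned region, 0 where never seen
        x0 = (sens > 0).astype(float)
        y = aff * (sm_local.A @ x0)
        lm = ListModeData(geometry=small_geometry,
                          records=np.empty(0, dtype=RECORD_DTYPE),
                          count_scale=1.0, image_grid=(64, 4.073))
        params = ReconParams(variant="OSEM", geometry=small_geometry,
                             iterations=1, subsets=14, postfilter_fwhm=0.0)
        rec = osem_reconstruct(lm, params, mu_map=small_phantom.mu_map,
                               sinogram=y)
        np.testing.assert_allclose(rec.image.ravel(), x0, atol=1e-10)

    def test_mlem_loglikelihood_monotone(self, small_phantom, small_geometry):
        """Full-data EM (subsets=1): Poisson log-likelihood never decreases."""
        for seed in range(3):
            lm = simulate_listmode(small_phantom, small_geometry,
                                   target_prompts=50_000, seed=seed)
            params = ReconParams(variant="OSEM", geometry=small_geometry,
                                 iterations=6, subsets=1)
            rec = osem_reconstruct(lm, params, mu_map=small_phantom.mu_map,
                                   keep_iterations=True)
            ll = np.array(rec.per_iteration_loglik)
            assert np.all(np.diff(ll) >= -1e-6 * np.abs(ll[:-1]))

    def test_noiseless_nrmse_decreases(self, small_phantom, small_geometry):
        """On noiseless data, OSEM error vs the (post-filtered) truth shrinks
        monotonically over the first iterations."""
        from pedpet import forward_project

        # noiseless expected-counts sinogram fed directly into EM
        sino = forward_project(small_phantom, small_geometry, attenuate=True)
        lm = ListModeData(geometry=small_geometry,
                          records=np.empty(0, dtype=RECORD_DTYPE),
                          count_scale=1.0, image_grid=(64, 4.073))
        params = ReconParams(variant="OSEM", geometry=small_geometry,
                             iterations=8, subsets=14)
        rec = osem_reconstruct(lm, params, mu_map=small_phantom.mu_map,
                               keep_iterations=True, sinogram=sino)
        truth = gaussian_postfilter(small_phantom.activity_map, 5.0, 4.073)
        body = small_phantom.masks["body"]
        nrmse = [
            np.sqrt(np.mean((img[body] - truth[body]) ** 2)) / truth[body].mean()
            for img in rec.per_iteration_images
        ]
        assert np.all(np.diff(nrmse) < 0)

    def test_zero_count_data_returns_flagged_zero_image(self, small_geometry):
        lm = ListModeData(geometry=small_geometry,
                          records=np.empty(0, dtype=RECORD_DTYPE),
                          image_grid=(64, 4.073))
        rec = osem_reconstruct(
            lm, ReconParams(variant="OSEM", geometry=small_geometry))
        assert rec.zero_count_warning
        assert np.all(rec.image == 0)

    def test_iterates_nonnegative_all_variants(self, small_listmode,
                                               small_phantom, small_geometry):
        for variant in ("OSEM", "TOF", "PSF", "PSF_TOF"):
            params = ReconParams(variant=variant, geometry=small_geometry,
                                 iterations=2)
            rec = osem_reconstruct(small_listmode, params,
                                   mu_map=small_phantom.mu_map,
                                   keep_iterations=True)
            assert np.all(rec.image >= 0)
            for img in rec.per_iteration_images:
                assert np.all(img >= 0)

    def test_subsets_must_divide_angles(self, small_geometry):
        with pytest.raises(ValueError, match="subsets"):
            ReconParams(variant="OSEM", geometry=small_geometry, subsets=13)

    def test_tof_improves_liver_snr_on_large_body(self):
        """Matched-contrast pair on a large body: SNR(TOF)/SNR(OSEM) > 1.

        Near-converged reconstructions at the protocol's 5:3 non-TOF : TOF
        iteration ratio; the SNR of each arm is averaged over a ring of
        background VOIs and over two noise realizations.
        """
        from pedpet.protocol import GAIN_STUDY_ITERATIONS, background_voi_ring

        ph = standard_phantom(body_diameter=350.0, n_image=128, voxel_size=4.073)
        g = ScannerGeometry(n_angles=84, n_radial_bins=100, radial_bin_size=4.073)
        vois = background_voi_ring(ph)
        gains = []
        for seed in (21, 22):
            lm = simulate_listmode(ph, g, target_prompts=500_000, seed=seed)
            s = {}
            for variant in ("OSEM", "TOF"):
                params = ReconParams(variant=variant, geometry=g,
                                     iterations=GAIN_STUDY_ITERATIONS[variant])
                rec = osem_reconstruct(lm, params, mu_map=ph.mu_map)
                s[variant] = np.mean([snr(rec.image, v, 4.073) for v in vois])
            gains.append(s["TOF"] / s["OSEM"])
        assert np.mean(gains) > 1.0
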