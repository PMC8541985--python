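"""Binocular energy model: Gabor filters, LN elements, populations, sweeps."""

import numpy as np
import pytest

from stereoprf import energy as E
from stereoprf.apertures import bar_aperture
from stereoprf.grid import make_grid
from stereoprf.prf import GaussianPRF, _drive_series
from stereoprf.stimuli import rds_frame


@pytest.fixture(scope="module")
def grid():
    return make_grid(2.0, 10)


class TestGabor:
    def test_zero_on_vertical_line_at_phase_zero(self, grid):
        f = E.gabor_filter(grid, (0.0, 0.0), 0.5, 0.75, 1.0, 0.0)
        centre_col = (grid.width - 1) // 2
        assert np.allclose(f[:, centre_col], 0.0)

    def test_peak_value_at_quadrature_phase(self, grid):
        sigma = 0.5
        f = E.gabor_filter(grid, (0.0, 0.0), sigma, sigma, 1.0, np.pi / 2)
        centre = ((grid.height - 1) // 2, (grid.width - 1) // 2)
        assert f[centre] == pytest.approx(1.0 / (2 * np.pi * sigma**2))

    def test_antiphase_filters_are_negatives(self, grid):
        a = E.gabor_filter(grid, (0.1, -0.2), 0.4, 0.6, 1.5, 0.3)
        b = E.gabor_filter(grid, (0.1, -0.2), 0.4, 0.6, 1.5, 0.3 + np.pi)
        assert np.allclose(a, -b, atol=1e-12)

    def test_sub_pixel_envelope_rejected(self, grid):
        with pytest.raises(ValueError):
            E.gabor_filter(grid, (0, 0), 0.05, 0.075, 1.0, 0.0)


class TestSimpleAndLN:
    def test_zero_image_gives_zero(self, grid):
        f = E.gabor_filter(grid, (0, 0), 0.5, 0.75, 1.0, 0.0)
        assert E.simple_response(f, np.zeros(grid.shape)) == 0.0

    def test_self_image_gives_squared_norm(self, grid):
        f = E.gabor_filter(grid, (0, 0), 0.5, 0.75, 1.0, np.pi / 2)
        v = E.simple_response(f, f, grid.pixel_area)
        assert v == pytest.approx((f**2).sum() * grid.pixel_area)
        assert v > 0

    def test_toy_dot_product(self):
        filt = np.array([[1.0, -2.0, 0.5], [0.0, 3.0, -1.0], [2.0, 0.0, 1.0]])
        img = np.array([[0.5, 1.0, -1.0], [2.0, -0.5, 0.0], [1.0, 1.0, -2.0]])
        # hand-computed: 0.5 - 2 - 0.5 + 0 - 1.5 + 0 + 2 + 0 - 2 = -3.5
        assert E.simple_response(filt, img) == pytest.approx(-3.5)

    def test_shape_mismatch_rejected(self, grid):
        with pytest.raises(ValueError):
            E.simple_response(np.zeros((3, 3)), np.zeros((4, 4)))

    @pytest.mark.parametrize("sl,sr,expected", [(0, 0, 0), (1, -1, 0), (1, 2, 9)])
    def test_ln_element(self, sl, sr, expected):
        assert E.ln_element(sl, sr) == expected


class TestComplexResponse:
    def test_mid_grey_frame_gives_zero(self, grid):
        unit = E.BinocularUnit((0, 0), 0.4, 1.25, 0.2)
        from stereoprf.stimuli import StereoFrame

        frame = StereoFrame(np.zeros(grid.shape, np.float32), np.zeros(grid.shape, np.float32), grid, "test")
        assert E.complex_response(unit, frame) == 0.0

    def test_quadrature_phase_invariance_to_drifting_grating(self):
        """Energy of a full-field grating at the preferred SF is invariant
        to carrier phase (CV < 5%)."""
        g = make_grid(3.0, 10)
        unit = E.BinocularUnit((0, 0), 0.6, 1.0 / 1.2, 0.0)
        x, _ = g.mesh()
        from stereoprf.stimuli import StereoFrame

        vals = []
        for phase in np.linspace(0, 2 * np.pi, 16, endpoint=False):
            img = np.sin(2 * np.pi * unit.spatial_frequency * x + phase).astype(np.float32)
            vals.append(E.complex_response(unit, StereoFrame(img, img.copy(), g, "grating")))
        vals = np.array(vals)
        assert vals.std() / vals.mean() < 0.05

    def test_correlated_beats_uncorrelated_for_tuned_unit(self, grid):
        """A zero-disparity unit responds more, on average, to binocularly
        correlated dots covering its RF than to uncorrelated dots."""
        unit = E.BinocularUnit((0, 0), 0.4, 1.25, 0.0)
        ap = np.ones(grid.shape, dtype=np.uint8)
        rng = np.random.default_rng(5)
        corr, unc = [], []
        for _ in range(60):
            fc = rds_frame(grid, ap, "zero_disparity_correlated", rng=rng)
            corr.append(E.complex_response(unit, fc))
            fu = rds_frame(grid, np.zeros_like(ap), "zero_disparity_correlated", rng=rng)
            unc.append(E.complex_response(unit, fu))
        assert np.mean(corr) > np.mean(unc)

    def test_engine_matches_reference_units(self, grid):
        bar = bar_aperture(grid, n_steps=3, bar_width=1.0)
        rng = np.random.default_rng(3)
        frame = rds_frame(grid, bar.masks[1], "correlated", disparity=0.2, rng=rng)
        units = [
            E.BinocularUnit((0.1, -0.2), 0.5, 1.0, 0.2),
            E.BinocularUnit((0.0, 0.3), 0.5, 2.0, 0.0),
        ]
        win = E._Window(grid, (0, 0), 2.0, 2.0)
        eng = E._CohortEngine(units, win)
        batch = eng.responses(frame.left[None], frame.right[None])[0]
        ref = [E.complex_response(u, frame) for u in units]
        assert np.allclose(batch, ref, rtol=1e-5)


class TestPopulation:
    def test_zero_jitter_centres_identical(self):
        spec = E.PopulationSpec(n_units=10, sizes=(0.5,), position_jitter_sd=0.0, seed=0)
        pop = E.build_population(spec, tuned_disparity=0.1)
        assert all(u.centre == (0.0, 0.0) for u in pop)
        assert all(u.disparity_offset == 0.1 for u in pop)

    def test_jitter_sample_sd(self):
        spec = E.PopulationSpec(n_units=1000, sizes=(0.5,), seed=3)
        pop = E.build_population(spec)
        xs = np.array([u.centre[0] for u in pop])
        assert xs.std() == pytest.approx(0.1, abs=0.01)

    def test_fixed_sf_rule_scaling(self):
        spec = E.PopulationSpec(n_units=5, sizes=(0.2, 1.0, 3.0), seed=0)
        pop = E.build_population(spec)
        for u in pop:
            assert u.spatial_frequency == pytest.approx(0.5 / u.sigma_h)

    def test_variable_rules_span_ranges(self):
        spec = E.PopulationSpec(
            n_units=400, sizes=(1.0,), sf_rule="variable", disparity_rule="jittered", seed=1
        )
        pop = E.build_population(spec, tuned_disparity=0.2)
        mult = np.array([u.spatial_frequency * u.sigma_h for u in pop])
        assert 0.5 <= mult.min() and mult.max() <= 3.5
        deltas = np.array([u.disparity_offset for u in pop])
        assert deltas.std() == pytest.approx(0.25, abs=0.03)
        assert deltas.mean() == pytest.approx(0.2, abs=0.05)

    def test_vertical_aspect_fixed(self):
        u = E.BinocularUnit((0, 0), 0.7, 1.0, 0.0)
        assert u.sigma_v == pytest.approx(1.5 * 0.7)


class TestSweepAndFit:
    @pytest.fixture(scope="class")
    def small_setup(self):
        g = make_grid(3.0, 10)
        bar = bar_aperture(g, n_steps=20, bar_width=1.0)
        spec = E.PopulationSpec(n_units=8, sizes=(0.5,), seed=2)
        pop = E.build_population(spec, tuned_disparity=0.2)
        return g, bar, pop

    def test_sweep_is_seed_reproducible(self, small_setup):
        g, bar, pop = small_setup
        a = E.sweep_response(pop, "correlated_disparity", bar, n_frames=3,
                             rng=np.random.default_rng(9))[0]
        b = E.sweep_response(pop, "correlated_disparity", bar, n_frames=3,
                             rng=np.random.default_rng(9))[0]
        assert np.array_equal(a.responses, b.responses)

    def test_responses_nonnegative(self, small_setup):
        g, bar, pop = small_setup
        s = E.sweep_response(pop, "luminance", bar, n_frames=3, rng=np.random.default_rng(0))[0]
        assert np.all(s.responses >= 0)

    def test_disparity_response_peaks_at_cohort_centre(self, small_setup):
        g, bar, pop = small_setup
        s = E.sweep_response(pop, "correlated_disparity", bar, n_frames=40,
                             rng=np.random.default_rng(1))[0]
        peak_step = int(np.argmax(s.responses))
        assert abs(bar.bar_centres[peak_step]) < 1.0

    def test_zero_disparity_condition_rejects_disparity(self, small_setup):
        g, bar, pop = small_setup
        with pytest.raises(ValueError):
            E.sweep_response(pop, "luminance", bar, stimulus_disparity=0.2, n_frames=2)

    def test_fit_recovers_manufactured_overlap_series(self):
        g = make_grid(5.0, 10)
        bar = bar_aperture(g, n_steps=60, bar_width=1.0)
        series = _drive_series(GaussianPRF(0.0, 0.0, 1.0), bar)
        fit = E.fit_model_prf(2.5 * series + 1.0, bar, (0.0, 0.0))
        assert fit.ok
        assert fit.sigma == pytest.approx(1.0, rel=0.02)

    def test_fit_ignores_constant_offset(self):
        g = make_grid(5.0, 10)
        bar = bar_aperture(g, n_steps=60, bar_width=1.0)
        series = _drive_series(GaussianPRF(0.0, 0.0, 1.5), bar)
        f1 = E.fit_model_prf(series, bar, (0.0, 0.0))
        f2 = E.fit_model_prf(series + 11.0, bar, (0.0, 0.0))
        assert f1.sigma == pytest.approx(f2.sigma, rel=1e-6)

    def test_flat_series_flagged(self):
        g = make_grid(5.0, 10)
        bar = bar_aperture(g, n_steps=30, bar_width=1.0)
        fit = E.fit_model_prf(np.ones(30), bar, (0.0, 0.0))
        assert not fit.ok and np.isnan(fit.sigma)
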