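"""Gaussian pRF forward model, two-stage fitting, CCnorm and filtering."""

import numpy as np
import pandas as pd
import pytest

from stereoprf.apertures import bar_aperture, scan_design, wedge_aperture
from stereoprf.grid import make_grid
from stereoprf.hrf import HRFParams, Timeseries, hrf_kernel
from stereoprf.prf import (
    GaussianPRF,
    GridSpec,
    PredictionBank,
    _convolve_kernel,
    _drive_series,
    ccnorm,
    filter_results,
    fit_vertex,
    gaussian_overlap,
    grid_search,
    highpass_filter,
    predict_timeseries,
    refine_fit,
)

HRF = HRFParams()


@pytest.fixture(scope="module")
def design():
    g = make_grid(10.0, 10)
    return scan_design("chq", "wedge-ccw", g).concatenate(scan_design("chq", "ring-exp", g))


@pytest.fixture(scope="module")
def bank(design):
    return PredictionBank(design, HRF, GridSpec.default(10.0))


class TestOverlap:
    def test_full_field_mask_integrates_to_one(self, field_grid):
        mask = np.ones(field_grid.shape, dtype=np.uint8)
        v = gaussian_overlap(GaussianPRF(1.0, -0.5, 1.5), mask, field_grid)
        assert v == pytest.approx(1.0, abs=0.01)

    def test_empty_mask_is_zero(self, field_grid):
        mask = np.zeros(field_grid.shape, dtype=np.uint8)
        assert gaussian_overlap(GaussianPRF(0, 0, 1.0), mask, field_grid) == 0.0

    def test_half_plane_through_centre_is_half(self, field_grid):
        # boundary placed between pixel centres so the half-plane split is exact
        x, _ = field_grid.mesh()
        mask = (x > 0.65).astype(np.uint8)
        v = gaussian_overlap(GaussianPRF(0.65, 0.0, 1.0), mask, field_grid)
        assert v == pytest.approx(0.5, abs=0.01)

    def test_sub_pixel_sigma_warns(self, field_grid):
        mask = np.ones(field_grid.shape, dtype=np.uint8)
        with pytest.warns(RuntimeWarning):
            gaussian_overlap(GaussianPRF(0, 0, 0.05), mask, field_grid)


class TestPredict:
    def test_all_blank_design_gives_flat_prediction(self, field_grid):
        masks = np.zeros((20, *field_grid.shape), dtype=np.uint8)
        from stereoprf.apertures import ApertureSequence

        seq = ApertureSequence(masks, field_grid, 2.488)
        p = predict_timeseries(GaussianPRF(1, 1, 1), seq, HRF)
        assert np.all(p.values == 0)

    def test_prf_outside_apertures_is_flat(self, design):
        p = predict_timeseries(GaussianPRF(30.0, 0.0, 1.0), design, HRF)
        assert np.allclose(p.values, 0, atol=1e-6)

    def test_single_volume_stimulus_reproduces_hrf(self, field_grid):
        from stereoprf.apertures import ApertureSequence

        masks = np.zeros((40, *field_grid.shape), dtype=np.uint8)
        masks[5] = 1  # full-field stimulus at volume 5
        seq = ApertureSequence(masks, field_grid, 1.0)
        p = predict_timeseries(GaussianPRF(0, 0, 1.0), seq, HRF)
        k = hrf_kernel(HRF, 1.0)
        expected = np.zeros(40)
        expected[5:] = k[:35] * p.values[5:].max() / k.max()
        assert np.corrcoef(p.values, expected)[0, 1] > 0.9999


class TestGridSearch:
    def test_noiseless_grid_vertex_recovered(self, design, bank):
        truth = GaussianPRF(bank.spec.x[14], bank.spec.y[7], bank.spec.sigma[5])
        y = predict_timeseries(truth, design, HRF).values
        seed = grid_search(y, bank)
        assert (seed.x, seed.y, seed.sigma) == (truth.x, truth.y, truth.sigma)

    def test_constant_series_flagged(self, bank):
        assert grid_search(np.ones(len(bank.design)), bank) is None
        assert grid_search(np.full(len(bank.design), np.nan), bank) is None

    def test_exact_tie_breaks_to_lowest_index(self, field_grid):
        # two candidates with bitwise-identical predictions (duplicated grid
        # point; mirror symmetry only ties up to float rounding): the lowest
        # grid index must win deterministically
        ring = scan_design("chq", "ring-exp", field_grid)
        spec = GridSpec(x=np.array([3.0, 3.0]), y=np.array([0.0]), sigma=np.array([1.0]))
        b = PredictionBank(ring, HRF, spec)
        assert np.array_equal(b.zpreds[0], b.zpreds[1])
        y = predict_timeseries(GaussianPRF(3.0, 0.0, 1.0), ring, HRF).values
        r = b.zpreds @ ((y - y.mean()) / y.std()).astype(np.float32)
        assert r[0] == r[1]
        seed = grid_search(y, b)
        assert seed is not None and b.params[0][0] == seed.x


class TestRefine:
    def test_noiseless_recovery_within_two_percent(self, design, bank):
        truth = GaussianPRF(2.0, -1.0, 1.0)
        y = predict_timeseries(truth, design, HRF).values * 3.1 + 7.0
        res = fit_vertex(y, design, HRF, bank)
        assert res.prf.x == pytest.approx(truth.x, abs=0.02 * truth.sigma)
        assert res.prf.y == pytest.approx(truth.y, abs=0.02 * truth.sigma)
        assert res.prf.sigma == pytest.approx(truth.sigma, rel=0.02)
        assert res.variance_explained > 0.999

    def test_refinement_never_worse_than_seed(self, design, bank, rng):
        y = predict_timeseries(GaussianPRF(1.5, 0.5, 0.8), design, HRF).values
        y = y + rng.normal(0, y.std(), y.size)
        seed = grid_search(y, bank)
        from stereoprf.prf import _ols_scale

        seed_r2 = _ols_scale(predict_timeseries(seed, design, HRF).values, y)[2]
        res = refine_fit(y, seed, design, HRF)
        assert res.variance_explained >= seed_r2 - 1e-12

    def test_white_noise_series_explains_nothing(self, design, bank):
        ve = []
        for k in range(10):
            rng = np.random.default_rng(k)
            res = fit_vertex(rng.normal(size=len(design)), design, HRF, bank)
            ve.append(res.variance_explained)
        assert np.median(ve) < 0.1

    def test_scale_invariance_of_parameters(self, design, bank):
        y = predict_timeseries(GaussianPRF(-2.0, 2.0, 1.2), design, HRF).values
        r1 = fit_vertex(y, design, HRF, bank)
        r2 = fit_vertex(5.0 * y, design, HRF, bank)
        assert r1.prf == r2.prf
        assert r2.amplitude == pytest.approx(5.0 * r1.amplitude, rel=1e-9)

    def test_highpass_drift_invariance(self, design, bank):
        """Fits are invariant to drift the 0.02 Hz high-pass removes."""
        y = predict_timeseries(GaussianPRF(1.0, 2.0, 1.0), design, HRF).values
        t = np.arange(len(y)) * design.frame_interval
        # drift on an exact FFT bin below the cut-off, as produced by slow
        # scanner fluctuations the preprocessing removes completely
        f_drift = 4 / (len(y) * design.frame_interval)
        assert f_drift < 0.02
        drift = 0.8 * np.cos(2 * np.pi * f_drift * t + 0.3)
        ya = highpass_filter(y, design.frame_interval)
        yb = highpass_filter(y + drift, design.frame_interval)
        assert np.allclose(ya, yb, atol=1e-9)
        a = fit_vertex(ya, design, HRF, bank)
        b = fit_vertex(yb, design, HRF, bank)
        assert a.prf.sigma == pytest.approx(b.prf.sigma, rel=1e-6)
        assert a.prf.x == pytest.approx(b.prf.x, abs=1e-6)


class TestCCnorm:
    def test_identical_repeats_and_prediction_give_one(self, rng):
        y = rng.normal(size=100)
        assert ccnorm(y, [y.copy(), y.copy()]) == pytest.approx(1.0)

    def test_orthogonal_prediction_gives_zero_mean(self, rng):
        signal = rng.normal(size=2000)
        pred = rng.normal(size=2000)  # independent of the signal
        vals = [
            ccnorm(pred, [signal + np.random.default_rng(s).normal(size=2000) for s in (2 * k, 2 * k + 1)])
            for k in range(20)
        ]
        assert abs(np.nanmean(vals)) < 0.1

    def test_snr_one_calibration(self):
        """Prediction = true signal, two half splits at SNR 1: mean CCnorm
        close to 1 (small Monte-Carlo here; the full calibration lives in
        the acceptance suite)."""
        rng = np.random.default_rng(0)
        sig = rng.normal(size=300)
        vals = []
        for _ in range(200):
            reps = [sig + rng.normal(size=300), sig + rng.normal(size=300)]
            vals.append(ccnorm(sig, reps))
        assert np.mean(vals) == pytest.approx(1.0, abs=0.05)

    def test_unreliable_repeats_flagged(self, rng):
        y = rng.normal(size=50)
        with pytest.warns(RuntimeWarning):
            v = ccnorm(y, [y, -y])  # anti-correlated halves: signal power < 0
        assert np.isnan(v)

    def test_fewer_than_two_repeats_rejected(self, rng):
        with pytest.raises(ValueError):
            ccnorm(rng.normal(size=50), [rng.normal(size=50)])


class TestFilter:
    def toy(self):
        return pd.DataFrame(
            {
                "eccentricity": [0.3, 1.0, 1.0],
                "ccnorm": [0.9, 0.4, 0.6],
                "sigma": [1, 1, 1],
            }
        )

    def test_toy_counts(self):
        kept, counts = filter_results(self.toy())
        assert len(kept) == 1
        assert counts["removed_ccnorm"] == 1
        assert counts["removed_ecc_low"] == 1

    def test_empty_input(self):
        kept, counts = filter_results(self.toy().iloc[:0])
        assert len(kept) == 0 and counts["n_survivors"] == 0

    def test_threshold_is_strict(self):
        df = pd.DataFrame({"eccentricity": [1.0], "ccnorm": [0.5], "sigma": [1]})
        kept, _ = filter_results(df)
        assert len(kept) == 0
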