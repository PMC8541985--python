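"""Synthetic cortex/BOLD generation, mesh smoothing, and result summaries."""

import numpy as np
import pandas as pd
import pytest

from stereoprf.apertures import scan_design
from stereoprf.grid import make_grid
from stereoprf.hrf import HRFParams
from stereoprf.smoothing import smooth_vertex_series
from stereoprf.summary import (
    bin_by_eccentricity,
    report,
    size_ecc_regression,
    size_ratio_curve,
)
from stereoprf.synth import NoiseSpec, SigmaRule, synth_bold, synth_cortex, synth_mesh


@pytest.fixture(scope="module")
def design():
    return scan_design("chq", "wedge-ccw", make_grid(10.0, 10))


class TestSynthCortex:
    def test_constant_rule_gives_constant_sigma(self):
        c = synth_cortex(50, sigma_rules={"a": SigmaRule(1.0, 0.0)}, seed=1)
        assert np.allclose(c.truth["a"]["sigma"], 1.0)

    def test_seed_reproducibility(self):
        a = synth_cortex(40, seed=7)
        b = synth_cortex(40, seed=7)
        for cond in a.truth:
            pd.testing.assert_frame_equal(a.truth[cond], b.truth[cond])

    def test_ground_truth_regression_recovers_slope(self):
        rule = SigmaRule(0.5, 0.2)
        c = synth_cortex(1000, sigma_rules={"a": rule}, seed=3)
        t = c.truth["a"]
        slope = np.polyfit(t.eccentricity, t.sigma, 1)[0]
        assert slope == pytest.approx(0.2, rel=0.05)

    def test_eccentricity_range_respected(self):
        c = synth_cortex(500, ecc_range=(0.5, 7.5), seed=2)
        ecc = c.truth["chequerboard"]["eccentricity"]
        assert ecc.min() >= 0.5 and ecc.max() <= 7.5


class TestSynthBold:
    def test_zero_noise_returns_exact_predictions(self, design):
        c = synth_cortex(5, sigma_rules={"a": SigmaRule(1.0, 0.2)}, seed=1)
        runs, clean = synth_bold(c, "a", design, HRFParams(), n_runs=2,
                                 noise=NoiseSpec(white_sd=0.0, ar1_sd=0.0))
        assert np.array_equal(runs[0], clean)
        assert np.array_equal(runs[1], clean)

    def test_ar1_autocorrelation_matches(self, design):
        c = synth_cortex(300, sigma_rules={"a": SigmaRule(1.0, 0.0)}, seed=1)
        runs, clean = synth_bold(
            c, "a", design, HRFParams(), n_runs=1,
            noise=NoiseSpec(white_sd=0.0, ar1_sd=1.0, ar1_coef=0.4, relative=False),
        )
        noise = runs[0] - clean
        x = noise - noise.mean(axis=1, keepdims=True)
        r1 = (x[:, 1:] * x[:, :-1]).sum() / (x**2).sum()
        assert r1 == pytest.approx(0.4, abs=0.05)

    def test_split_half_reliability_matches_snr(self, design):
        """At white-noise SNR 1, the across-half correlation of one run
        approaches Var(s)/(Var(s)+Var(n)) = 0.5 in expectation."""
        c = synth_cortex(200, sigma_rules={"a": SigmaRule(1.5, 0.1)}, seed=4)
        runs, clean = synth_bold(c, "a", design, HRFParams(), n_runs=2,
                                 noise=NoiseSpec(white_sd=1.0, relative=True))
        r = [np.corrcoef(runs[0][v], runs[1][v])[0, 1] for v in range(200)]
        assert np.mean(r) == pytest.approx(0.5, abs=0.05)

    def test_no_ground_truth_in_bold_output(self, design):
        c = synth_cortex(4, seed=1)
        runs, _ = synth_bold(c, "chequerboard", design, HRFParams(), n_runs=1)
        assert isinstance(runs[0], np.ndarray)  # plain matrix, no truth columns


class TestMeshSmoothing:
    def test_planar_mesh_interior_degree_four(self):
        m = synth_mesh(25, spacing_mm=2.0)
        deg = m.degrees()
        assert deg[12] == 4  # interior vertex of the 5x5 lattice

    def test_vertex_count_and_spacing(self):
        m = synth_mesh(30, spacing_mm=3.0)
        assert m.n_vertices == 30
        d = np.linalg.norm(m.coords[m.edges[:, 0]] - m.coords[m.edges[:, 1]], axis=1)
        assert d.min() == pytest.approx(3.0, rel=0.01)

    def test_spherical_mesh_spacing(self):
        m = synth_mesh(200, spacing_mm=2.0, kind="spherical")
        d = np.linalg.norm(m.coords[m.edges[:, 0]] - m.coords[m.edges[:, 1]], axis=1)
        assert np.median(d) == pytest.approx(2.0, rel=0.01)

    def test_zero_fwhm_is_identity(self, rng):
        m = synth_mesh(36, spacing_mm=2.0)
        x = rng.normal(size=(36, 7))
        assert np.array_equal(smooth_vertex_series(x, m, 0.0), x)

    def test_constant_field_preserved(self):
        m = synth_mesh(49, spacing_mm=1.5)
        x = np.full((49, 3), 2.5)
        assert np.allclose(smooth_vertex_series(x, m, 5.0), 2.5)

    def test_delta_kernel_fwhm_matches_target(self):
        """Smoothing a delta on a fine planar lattice yields a kernel whose
        measured FWHM is within 10% of the 5 mm target."""
        side = 41
        m = synth_mesh(side * side, spacing_mm=0.5)
        x = np.zeros((side * side, 1))
        centre = (side // 2) * side + side // 2
        x[centre] = 1.0
        sm = smooth_vertex_series(x, m, 5.0)[:, 0].reshape(side, side)
        row = sm[side // 2]
        half = row.max() / 2
        above = np.flatnonzero(row >= half)
        fwhm = (above[-1] - above[0] + 1) * 0.5
        assert fwhm == pytest.approx(5.0, rel=0.1)


class TestSummary:
    def toy_results(self):
        return pd.DataFrame(
            {
                "eccentricity": [0.1, 0.2, 0.8, 0.9, 1.0, 1.6],
                "sigma": [1.0, 2.0, 3.0, 5.0, 4.0, 8.0],
            }
        )

    def test_single_vertex_bin_mean(self):
        df = pd.DataFrame({"eccentricity": [1.0], "sigma": [2.5]})
        s = bin_by_eccentricity(df)
        row = s.table.dropna(subset=["mean_sigma"]).iloc[0]
        assert row.mean_sigma == 2.5 and np.isnan(row.sem_sigma)

    def test_half_open_bin_convention(self):
        df = pd.DataFrame({"eccentricity": [0.75], "sigma": [1.0]})
        s = bin_by_eccentricity(df, bin_width=0.75)
        filled = s.table.dropna(subset=["mean_sigma"])
        assert filled.iloc[0].bin_lo == pytest.approx(0.75)  # second bin

    def test_toy_bin_means_match_hand_computation(self):
        s = bin_by_eccentricity(self.toy_results(), bin_width=0.75)
        t = s.table.set_index("bin_lo")
        assert t.loc[0.0, "mean_sigma"] == pytest.approx(1.5)  # (1+2)/2
        assert t.loc[0.75, "mean_sigma"] == pytest.approx(4.0)  # (3+5+4)/3
        assert t.loc[1.5, "mean_sigma"] == pytest.approx(8.0)

    def test_regression_exact_on_linear_input(self):
        df = pd.DataFrame({"eccentricity": np.linspace(1, 6, 12)})
        df["sigma"] = 0.3 * df.eccentricity + 0.7
        slope, intercept, r2 = size_ecc_regression(df, raw=True)
        assert slope == pytest.approx(0.3, rel=1e-6)
        assert intercept == pytest.approx(0.7, rel=1e-6)
        assert r2 == pytest.approx(1.0)
        # binned means of linear data regress to the same line only up to
        # the within-bin placement of the vertices
        s_slope, _, s_r2 = size_ecc_regression(bin_by_eccentricity(df))
        assert s_slope == pytest.approx(0.3, rel=0.1)
        assert s_r2 > 0.99

    def test_regression_zero_slope_on_constant(self):
        df = pd.DataFrame({"eccentricity": np.linspace(1, 6, 12), "sigma": 2.0})
        slope, _, _ = size_ecc_regression(bin_by_eccentricity(df))
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_ratio_curve_identity_and_doubling(self):
        a = self.toy_results()
        b = a.copy()
        r1 = size_ratio_curve(a, b)
        assert np.allclose(r1.ratio, 1.0)
        b2 = a.copy()
        b2["sigma"] /= 2.0
        r2 = size_ratio_curve(a, b2)
        assert np.allclose(r2.ratio, 2.0)

    def test_binning_then_regression_consistency(self):
        """Regression on raw vertices pre-aggregated by the same bins equals
        regression on the binned summary."""
        df = self.toy_results()
        s = bin_by_eccentricity(df)
        t = s.table.dropna(subset=["mean_sigma"])
        agg = pd.DataFrame(
            {"eccentricity": (t.bin_lo + t.bin_hi) / 2, "sigma": t.mean_sigma}
        )
        a = size_ecc_regression(s)
        b = size_ecc_regression(agg, raw=True)
        assert a == pytest.approx(b)

    def test_report_roundtrip_and_empty(self, tmp_path):
        import json

        from stereoprf.summary import save_report

        rep = report(fits={}, filter_counts={}, regressions={})
        assert rep["conditions"] == {} and "size_curves" in rep["missing"]
        p = tmp_path / "r.json"
        save_report(rep, str(p))
        assert json.loads(p.read_text()) == json.loads(json.dumps(rep))

    def test_report_attrition_matches_filter(self):
        from stereoprf.prf import filter_results

        df = pd.DataFrame(
            {"eccentricity": [0.3, 1.0, 2.0], "ccnorm": [0.9, 0.4, 0.7], "sigma": [1, 1, 1]}
        )
        kept, counts = filter_results(df)
        rep = report(fits={"c": kept}, filter_counts={"c": counts})
        assert rep["filter_attrition"]["c"]["n_survivors"] == len(kept)
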