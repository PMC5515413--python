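"""Regression, band partitioning and correlation-profile behaviour.

The OLS oracle here is the closed-form normal-equations solution coded
directly from the textbook formulas, independent of scipy.
"""

import numpy as np
import pytest
from scipy import stats

from halflife_xfer import (Dataset, RegressionFit, assign_clusters,
                           correlation_profile, fit_cluster_regression,
                           fit_global_regression, generate, liverlike_preset,
                           relative_deviation)
from halflife_xfer.clustering import DegenerateLineError
from halflife_xfer.datamodel import InsufficientDataError

from conftest import make_record, true_line_fit


def ols_oracle(x, y):
    """Normal equations: slope = Sxy/Sxx, intercept = ybar - slope*xbar."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xbar, ybar = x.mean(), y.mean()
    slope = np.sum((x - xbar) * (y - ybar)) / np.sum((x - xbar) ** 2)
    return slope, ybar - slope * xbar


def _dataset_on(x, y):
    return Dataset([make_record(pid=f"P{i}", cell=float(xi), tissue=float(yi))
                    for i, (xi, yi) in enumerate(zip(x, y))])


class TestGlobalRegression:
    def test_exact_line_recovered(self):
        x = np.array([10.0, 20, 30, 40, 50])
        ds = _dataset_on(x, 2 * x + 5)
        fit = fit_global_regression(ds)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(5.0, abs=1e-10)
        assert fit.pearson_r == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(5, 200, size=20)
        y = 0.7 * x + 100 + rng.normal(0, 25, size=20)
        y = np.abs(y) + 1
        fit = fit_global_regression(_dataset_on(x, y))
        m, w = ols_oracle(x, y)
        assert fit.slope == pytest.approx(m, abs=1e-10)
        assert fit.intercept == pytest.approx(w, abs=1e-10)

    def test_insufficient_points_raise(self):
        ds = _dataset_on([10, 20], [30, 40])
        with pytest.raises(InsufficientDataError):
            fit_global_regression(ds)

    def test_uncommon_records_ignored_by_fit(self):
        x = np.array([10.0, 20, 30, 40])
        ds = _dataset_on(x, 2 * x + 5)
        ds.records.append(make_record(pid="U", cell=999.0, tissue=None))
        fit = fit_global_regression(ds)
        assert fit.n == 4 and fit.slope == pytest.approx(2.0, abs=1e-12)


class TestRelativeDeviation:
    FIT = RegressionFit(slope=1.0, intercept=0.0, n=10, pearson_r=1.0,
                        p_value=0.0)

    def test_on_line_is_zero(self):
        assert relative_deviation(make_record(cell=50, tissue=50),
                                  self.FIT) == 0.0

    def test_hand_arithmetic(self):
        # (55 - 50) / 50 = 0.10
        d = relative_deviation(make_record(cell=50, tissue=55), self.FIT)
        assert d == pytest.approx(0.10)

    def test_sign_encodes_side_of_line(self):
        assert relative_deviation(make_record(cell=50, tissue=40),
                                  self.FIT) < 0

    def test_degenerate_line_raises(self):
        fit = RegressionFit(slope=-1.0, intercept=0.0, n=10, pearson_r=0,
                            p_value=1)
        with pytest.raises(DegenerateLineError):
            relative_deviation(make_record(cell=50, tissue=55), fit)


class TestAssignClusters:
    def test_all_on_line_all_c2(self):
        x = np.array([10.0, 20, 30, 40])
        ds = _dataset_on(x, 2 * x + 5)
        asn = assign_clusters(ds, fit_global_regression(ds))
        assert asn.sizes == {"C1": 0, "C2": 4, "C3": 0}

    def test_hand_built_band_rule(self):
        fit = RegressionFit(slope=1.0, intercept=0.0, n=10, pearson_r=1.0,
                            p_value=0.0)
        devs = [0.2, 0.15, 0.05, 0.0, -0.05, -0.3]
        ds = _dataset_on([100.0] * 6, [100 * (1 + d) for d in devs])
        asn = assign_clusters(ds, fit)
        got = [asn.labels[f"P{i}"] for i in range(6)]
        assert got == ["C1", "C1", "C2", "C2", "C2", "C3"]

    def test_boundary_exactly_ten_percent_is_c2(self):
        fit = RegressionFit(slope=1.0, intercept=0.0, n=10, pearson_r=1.0,
                            p_value=0.0)
        ds = _dataset_on([100.0, 100.0], [110.0, 90.0])
        asn = assign_clusters(ds, fit)
        assert asn.labels["P0"] == "C2" and asn.labels["P1"] == "C2"

    def test_partition_property(self, liverlike):
        ds, _ = liverlike
        asn = assign_clusters(ds, fit_global_regression(ds))
        assert sum(asn.sizes.values()) == len(ds.common)
        assert set(asn.labels) == {r.protein_id for r in ds.common}

    def test_band_monotonicity_shrinking_width_never_grows_c2(self, liverlike):
        ds, _ = liverlike
        fit = fit_global_regression(ds)
        sizes = [assign_clusters(ds, fit, bw).sizes["C2"]
                 for bw in (0.20, 0.10, 0.05, 0.02)]
        assert sizes == sorted(sizes, reverse=True)

    def test_observed_denominator_option(self):
        fit = RegressionFit(slope=1.0, intercept=0.0, n=10, pearson_r=1.0,
                            p_value=0.0)
        ds = _dataset_on([100.0], [125.0])
        d_fit = assign_clusters(ds, fit).deviations["P0"]
        d_obs = assign_clusters(ds, fit,
                                denominator="observed").deviations["P0"]
        assert d_fit == pytest.approx(0.25)
        assert d_obs == pytest.approx(25 / 125)


class TestClusterRegression:
    def test_exact_line_within_cluster(self):
        x = np.array([10.0, 30, 50, 70, 90, 120])
        ds = _dataset_on(x, 0.6 * x + 141)
        asn = assign_clusters(ds, fit_global_regression(ds))
        fit = fit_cluster_regression(ds, asn, "C2")
        assert fit.slope == pytest.approx(0.6, abs=1e-12)
        assert fit.intercept == pytest.approx(141.0, abs=1e-9)

    def test_matches_oracle_on_cluster_subset(self, liverlike):
        ds, _ = liverlike
        asn = assign_clusters(ds, fit_global_regression(ds))
        by_id = {r.protein_id: r for r in ds.common}
        for c in ("C1", "C2", "C3"):
            members = [by_id[p] for p in asn.members(c)]
            fit = fit_cluster_regression(ds, asn, c)
            m, w = ols_oracle([r.cell_halflife for r in members],
                              [r.tissue_halflife for r in members])
            assert fit.slope == pytest.approx(m, abs=1e-10)
            assert fit.intercept == pytest.approx(w, abs=1e-10)

    def test_too_small_cluster_names_it(self):
        x = np.array([10.0, 20, 30, 40])
        ds = _dataset_on(x, 2 * x + 5)
        asn = assign_clusters(ds, fit_global_regression(ds))
        with pytest.raises(InsufficientDataError, match="C1"):
            fit_cluster_regression(ds, asn, "C1")


class TestCorrelationProfile:
    def test_signs_recovered_and_pch_mask(self):
        corr = {"length": 0.0, "abundance": 0.8, "disorder_count": 0.0,
                "mrna_level": -0.5, "transcription_rate": 0.0,
                "translation_rate": 0.0}
        ds, _ = generate(liverlike_preset(seed=13, n_proteins=1500,
                                          property_correlations=corr))
        asn = assign_clusters(ds, fit_global_regression(ds))
        profile = correlation_profile(ds, asn)
        for c in ("C1", "C2", "C3"):
            assert profile.correlations[c]["abundance"] > 0
            assert profile.correlations[c]["mrna_level"] < 0
            names = list(profile.correlations[c])
            mask = profile.pch_mask[c]
            assert mask[names.index("abundance")]
            assert not mask[names.index("mrna_level")]

    def test_entries_match_textbook_pearson(self, liverlike):
        ds, _ = liverlike
        asn = assign_clusters(ds, fit_global_regression(ds))
        profile = correlation_profile(ds, asn)
        by_id = {r.protein_id: r for r in ds.common}
        members = [by_id[p] for p in asn.members("C2")]
        x = np.log([float(r.abundance) for r in members]).round(4)
        y = np.array([r.tissue_halflife for r in members])
        xc, yc = x - x.mean(), y - y.mean()
        r_oracle = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        assert profile.correlations["C2"]["abundance"] == pytest.approx(
            r_oracle, abs=1e-12)

    def test_zero_variance_property_excluded_with_warning(self):
        fit = RegressionFit(slope=1.0, intercept=0.0, n=12, pearson_r=1.0,
                            p_value=0.0)
        devs = [0.3, 0.4, 0.5, 0.0, 0.02, -0.02, -0.3, -0.4, -0.5]
        rng = np.random.default_rng(0)
        recs = [make_record(pid=f"P{i}", cell=100.0,
                            tissue=100.0 * (1 + d), disorder_count=3,
                            abundance=float(rng.uniform(10, 1000)))
                for i, d in enumerate(devs)]
        ds = Dataset(recs)
        asn = assign_clusters(ds, fit)
        with pytest.warns(UserWarning, match="disorder_count"):
            profile = correlation_profile(ds, asn)
        for c in ("C1", "C2", "C3"):
            names = list(profile.correlations[c])
            assert not profile.pch_mask[c][names.index("disorder_count")]
            assert np.isnan(profile.correlations[c]["disorder_count"])

    def test_within_band_correlation_dominates(self, liverlike):
        ds, _ = liverlike
        fit = fit_global_regression(ds)
        asn = assign_clusters(ds, fit)
        by_id = {r.protein_id: r for r in ds.common}
        c2 = [by_id[p] for p in asn.members("C2")]
        r_c2 = stats.pearsonr([r.cell_halflife for r in c2],
                              [r.tissue_halflife for r in c2]).statistic
        assert r_c2 >= fit.pearson_r
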