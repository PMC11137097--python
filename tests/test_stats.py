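"""Statistics battery: Z-scores, normalization algebra, ANOVA/LSD and
Pearson regression against independent closed-form oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from glymph.cohort import simulate_cohort
from glymph.stats import (CohortModel, group_compare,
                          group_compare_categorical, normalize_biomarkers,
                          normalized_slope_analysis, pearson_regression,
                          vsrad_z)


def _closed_form_line(x, y):
    """Independent oracle: slope/intercept/r from covariance identities."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    sxx = ((x - x.mean()) ** 2).sum()
    syy = ((y - y.mean()) ** 2).sum()
    slope = sxy / sxx
    return slope, y.mean() - slope * x.mean(), sxy / np.sqrt(sxx * syy)


class TestVsradZ:
    @pytest.mark.parametrize("individual, expected", [
        (5.0, 0.0),        # at the control mean
        (4.0, 1.0),        # one SD below the mean -> +1
        (7.0, -2.0),       # two SD above -> -2
    ])
    def test_endpoints(self, individual, expected):
        assert vsrad_z(individual, control_mean=5.0, control_sd=1.0) == expected

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            vsrad_z(5.0, 5.0, 0.0)


class TestPearsonRegression:
    def test_exact_line(self):
        x = np.arange(5.0)
        res = pearson_regression(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r == pytest.approx(1.0)

    def test_matches_closed_form_oracle(self, rng):
        for _ in range(100):
            n = rng.integers(5, 30)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            res = pearson_regression(x, y)
            slope, intercept, r = _closed_form_line(x, y)
            assert res.slope == pytest.approx(slope, abs=1e-12)
            assert res.intercept == pytest.approx(intercept, abs=1e-12)
            assert res.r == pytest.approx(r, abs=1e-12)
            # p from t = r * sqrt((n-2)/(1-r^2))
            t = r * np.sqrt((n - 2) / (1 - r**2))
            assert res.p == pytest.approx(2 * sps.t.sf(abs(t), n - 2), rel=1e-9)

    def test_independent_normals_have_small_r(self, rng):
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        assert abs(pearson_regression(x, y).r) < 0.05

    def test_confidence_band_contains_fit_and_widens(self, rng):
        x = rng.normal(size=40)
        y = 1.5 * x + rng.normal(scale=0.5, size=40)
        res = pearson_regression(x, y)
        grid = np.array([x.mean(), x.mean() + 3 * x.std()])
        lo, hi = res.confidence_band(grid)
        yhat = res.predict(grid)
        assert np.all(lo < yhat) and np.all(yhat < hi)
        assert (hi - lo)[1] > (hi - lo)[0]  # wider away from the centre

    def test_input_validation(self):
        with pytest.raises(ValueError):
            pearson_regression([1.0, 2.0], [1.0, 2.0])          # n < 3
        with pytest.raises(ValueError):
            pearson_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])  # zero var
        with pytest.raises(ValueError):
            pearson_regression([1.0, np.nan, 3.0], [1.0, 2.0, 3.0])


class TestGroupCompare:
    def _table(self, a, b):
        return pd.DataFrame({
            "group": ["CN"] * len(a) + ["AD"] * len(b),
            "v": np.concatenate([a, b]),
        })

    def test_identical_groups_give_f_zero_p_one(self):
        t = self._table(np.ones(5), np.ones(5))
        gc = group_compare(t, "v")
        assert gc.f == 0.0 and gc.p == 1.0
        assert gc.lsd_p[("CN", "AD")] == 1.0

    def test_anova_f_equals_squared_pooled_t(self, rng):
        for _ in range(100):
            a = rng.normal(size=rng.integers(3, 20))
            b = rng.normal(loc=rng.normal(), size=rng.integers(3, 20))
            gc = group_compare(self._table(a, b), "v")
            t, p = sps.ttest_ind(a, b, equal_var=True)
            assert gc.f == pytest.approx(t**2, rel=1e-10)
            assert gc.p == pytest.approx(p, rel=1e-10)
            # for two groups the LSD p equals the ANOVA p
            assert gc.lsd_p[("CN", "AD")] == pytest.approx(p, rel=1e-10)

    def test_group_stats_reported(self, rng):
        a, b = rng.normal(1.44, 0.09, 27), rng.normal(1.29, 0.12, 56)
        gc = group_compare(self._table(a, b), "v")
        assert gc.ns == {"CN": 27, "AD": 56}
        assert gc.means["CN"] == pytest.approx(a.mean())
        assert gc.sds["AD"] == pytest.approx(b.std(ddof=1))

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            group_compare(self._table(np.ones(1), np.ones(5)), "v")

    def test_rejection_rate_matches_noncentral_f_power(self, study_spec):
        """Empirical rejection at alpha=1e-5 over simulated cohorts agrees
        with the noncentral-F power for the generator's group moments."""
        n1, n2 = 27, 56
        m1, s1 = study_spec.alps_group_moments("b1000", "CN")
        m2, s2 = study_spec.alps_group_moments("b1000", "AD")
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        lam = (n1 * n2 / (n1 + n2)) * (m1 - m2) ** 2 / sp2
        fcrit = sps.f.isf(1e-5, 1, n1 + n2 - 2)
        power = sps.ncf.sf(fcrit, 1, n1 + n2 - 2, lam)
        n_sim = 300
        rng = np.random.default_rng(99)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rej = sum(group_compare(simulate_cohort(study_spec, rng),
                                    "alps_b1000").p < 1e-5
                      for _ in range(n_sim))
        se = np.sqrt(power * (1 - power) / n_sim)
        assert rej / n_sim == pytest.approx(power, abs=4 * se)

    def test_sex_ratio_chi_square(self, study_spec):
        df = simulate_cohort(study_spec, 4)
        out = group_compare_categorical(df, "sex")
        assert out["dof"] == 1
        assert 0 < out["p"] <= 1


class TestNormalization:
    def _table(self):
        return pd.DataFrame({
            "group": ["CN", "CN", "AD", "AD"],
            "mmse": [30, 0, 15, 30],
            "vsrad_z": [0.5, 2.5, 1.0, 0.5],
            "centiloid": [0.0, 90.0, 40.0, 10.0],
            "alps_b1000": [1.5, 1.0, 1.2, 1.5],
        })

    def test_printed_equation_endpoints(self):
        norm, consts = normalize_biomarkers(self._table())
        assert consts.alps_max == 1.5
        # MMSE 30 -> 0, MMSE 0 -> 100
        assert norm.nMMSE.tolist()[:2] == [0.0, 100.0]
        # ALPS = ALPS_MAX -> 0, ALPS = 1 -> 100
        assert norm.nDTI_ALPS.iloc[0] == 0.0
        assert norm.nDTI_ALPS.iloc[1] == 100.0
        # VSRAD = VSRAD_MIN -> 0; printed denominator is VSRAD_MAX
        assert norm.nVSRAD.iloc[0] == 0.0
        assert norm.nVSRAD.iloc[1] == pytest.approx((2.5 - 0.5) / 2.5 * 100)

    def test_range_denominator_option(self):
        norm, _ = normalize_biomarkers(self._table(), vsrad_range_denominator=True)
        assert norm.nVSRAD.iloc[1] == pytest.approx(100.0)

    def test_alps_max_at_most_one_rejected(self):
        t = self._table().assign(alps_b1000=[0.9, 0.8, 0.7, 0.95])
        with pytest.raises(ValueError, match="ALPS_MAX"):
            normalize_biomarkers(t)

    def test_normalization_preserves_correlation_magnitude(self, study_spec):
        df = simulate_cohort(study_spec, 21)
        norm, consts = normalize_biomarkers(df)
        raw = pearson_regression(df.centiloid, df.mmse)
        nrm = pearson_regression(df.centiloid, norm.nMMSE)
        assert abs(nrm.r) == pytest.approx(abs(raw.r), abs=1e-12)
        # slope transforms by the affine chain rule
        raw_a = pearson_regression(df.centiloid, df.alps_b1000)
        nrm_a = pearson_regression(df.centiloid, norm.nDTI_ALPS)
        assert nrm_a.slope == pytest.approx(
            raw_a.slope * (-100.0 / (consts.alps_max - 1.0)), rel=1e-12)

    def test_alps_slope_steepest_in_most_cohorts(self, study_spec):
        """On default cohorts the normalized ALPS slope against centiloid
        exceeds the nVSRAD and nMMSE slopes in a clear majority of runs."""
        rng = np.random.default_rng(31)
        wins = 0
        n = 100
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(n):
                fits, _ = normalized_slope_analysis(simulate_cohort(study_spec, rng))
                s = {k: v.slope for k, v in fits.items()}
                wins += s["nDTI_ALPS"] > max(s["nVSRAD"], s["nMMSE"])
        assert wins / n > 0.5


class TestCohortModel:
    def test_fit_produces_all_tables(self, study_spec):
        results = CohortModel(simulate_cohort(study_spec, 8)).fit()
        assert {"mmse", "centiloid", "alps_b1000"} <= set(results.group_summary.index)
        assert len(results.regressions) == 6  # 3 biomarkers x 2 shells
        assert set(results.normalized.index) == {"nDTI_ALPS", "nVSRAD", "nMMSE"}
        txt = results.summary()
        assert "ANOVA" in txt and "ALPS_MAX" in txt

    def test_regression_orientations(self, study_spec):
        results = CohortModel(simulate_cohort(study_spec, 9)).fit()
        reg = results.regressions.set_index(["response", "predictor"])
        # ALPS is the response against MMSE and centiloid ...
        assert ("alps_b1000", "mmse") in reg.index
        assert ("alps_b1000", "centiloid") in reg.index
        # ... and the predictor for the atrophy score
        assert ("vsrad_z", "alps_b1000") in reg.index

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="lacks"):
            CohortModel(pd.DataFrame({"group": ["CN"]}))

    def test_from_tsv_round_trip(self, tmp_path, study_spec):
        df = simulate_cohort(study_spec, 10)
        path = tmp_path / "cohort.tsv"
        df.to_csv(path, sep="\t", index=False)
        results = CohortModel.from_tsv(path).fit()
        direct = CohortModel(df).fit()
        pd.testing.assert_frame_equal(results.group_summary, direct.group_summary,
                                      rtol=1e-12)
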