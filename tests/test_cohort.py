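"""Cohort statistics: normalization, log-log regression, counts, fractions."""

import numpy as np
import pandas as pd
import pytest

import necroquant as nq


def make_rps_table(rng, conditions):
    rows = []
    for label, mean, n in conditions:
        rows.append(pd.DataFrame({"condition": label, "rps": rng.normal(mean, 0.1, n)}))
    return pd.concat(rows, ignore_index=True)


class TestNormalization:
    def test_reference_normalizes_to_one(self, rng):
        df = make_rps_table(rng, [("ref", 3.0, 20), ("test", 1.0, 15)])
        _, summary = nq.normalize_to_reference(df, "ref")
        ref_row = summary.loc[summary["condition"] == "ref"]
        assert float(ref_row["mean"].iloc[0]) == pytest.approx(1.0, rel=1e-12)

    def test_known_reduction_recovered(self):
        df = pd.DataFrame(
            {"condition": ["ref"] * 4 + ["mut"] * 4, "rps": [2.0] * 4 + [2.0 * 0.29] * 4}
        )
        _, summary = nq.normalize_to_reference(df, "ref")
        mut = float(summary.loc[summary["condition"] == "mut", "mean"].iloc[0])
        assert mut == pytest.approx(0.29, rel=1e-12)

    def test_scale_invariance_and_idempotence(self, rng):
        df = make_rps_table(rng, [("ref", 3.0, 10), ("mut", 1.5, 10)])
        _, s1 = nq.normalize_to_reference(df, "ref")
        scaled = df.assign(rps=df["rps"] * 11.0)
        _, s2 = nq.normalize_to_reference(scaled, "ref")
        pd.testing.assert_frame_equal(s1, s2)
        per_cell, _ = nq.normalize_to_reference(df, "ref")
        renorm, _ = nq.normalize_to_reference(
            per_cell.assign(rps=per_cell["normalized"]), "ref"
        )
        np.testing.assert_allclose(renorm["normalized"], per_cell["normalized"])

    def test_missing_reference_rejected(self, rng):
        df = make_rps_table(rng, [("a", 1.0, 5)])
        with pytest.raises(ValueError, match="reference"):
            nq.normalize_to_reference(df, "nope")


class TestLogRegression:
    def test_exact_power_law(self):
        x = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        y = 2.0 * x**1.5
        fit = nq.log_integral_regression(x, y)
        assert fit.slope == pytest.approx(1.5, rel=1e-12)
        assert fit.r == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == fit.r**2

    def test_recovers_generator_coupling_noise_free(self, necrotic_cohort):
        ca = np.array([r.truth.ca_integral for r in necrotic_cohort])
        ps = np.array([r.truth.ps_integral for r in necrotic_cohort])
        fit = nq.log_integral_regression(ca, ps)
        assert fit.slope == pytest.approx(1.0, abs=1e-9)
        assert fit.intercept == pytest.approx(0.3, abs=1e-9)

    def test_moderate_noise_parameter_recovery(self):
        """Across 20 seeded cohorts with multiplicative measurement noise,
        the mean estimated slope stays within 10% and mean r > 0.9.

        Only cells whose PS signal actually appears enter the regression —
        the published correlation is computed over neurons that expose PS,
        and cells that never swell contribute only a noise-floor PS
        integral that is meaningless on a log scale.
        """
        slopes, rs = [], []
        for seed in range(20):
            cfg = nq.scenario_config("mec-4(d)", n_cells=8, seed=seed, noise_sd=0.1)
            ca, ps = [], []
            for i in range(8):
                rec = nq.simulate_cell(cfg, i)
                if nq.detect_onset(rec.ps, 1.2) is None:
                    continue
                ca_tr = nq.IntensityTrace(rec.ca.times, np.clip(rec.ca.values - 1, 0, None))
                ps_tr = nq.IntensityTrace(rec.ps.times, np.clip(rec.ps.values - 1, 0, None))
                x = nq.integrate_trace(ca_tr, nq.FULL_WINDOW)
                y = nq.integrate_trace(ps_tr, nq.FULL_WINDOW)
                if x > 0 and y > 0:
                    ca.append(x)
                    ps.append(y)
            fit = nq.log_integral_regression(np.array(ca), np.array(ps))
            slopes.append(fit.slope)
            rs.append(fit.r)
        assert abs(np.mean(slopes) - 1.0) < 0.1
        assert np.mean(rs) > 0.9

    def test_r_squared_equals_r_squared_exactly(self, rng):
        for _ in range(10):
            x = rng.uniform(1, 100, size=12)
            y = rng.uniform(1, 100, size=12)
            fit = nq.log_integral_regression(x, y)
            assert fit.r_squared == fit.r**2
            assert -1.0 <= fit.r <= 1.0

    def test_rescaling_leaves_r_and_slope_unchanged(self, rng):
        x = rng.uniform(1, 50, size=15)
        y = rng.uniform(1, 50, size=15)
        base = nq.log_integral_regression(x, y)
        scaled = nq.log_integral_regression(3.7 * x, 0.2 * y)
        assert scaled.r == pytest.approx(base.r, rel=1e-12)
        assert scaled.slope == pytest.approx(base.slope, rel=1e-12)

    def test_nonpositive_pairs_rejected_with_listing(self):
        with pytest.raises(ValueError, match="pairs"):
            nq.log_integral_regression([1.0, -2.0, 3.0], [1.0, 2.0, 0.0])


class TestGroupedCounts:
    def test_uniform_counts(self):
        cs = nq.grouped_count_summary([2] * 30, group_size=10)
        assert cs.mean == 2.0
        assert cs.sem == 0.0
        assert not cs.has_partial_group

    def test_matches_independent_grouping_loop(self, rng):
        counts = rng.integers(0, 3, size=47)
        cs = nq.grouped_count_summary(counts, group_size=10)
        # independent recomputation
        means = []
        for start in range(0, 47, 10):
            chunk = counts[start : start + 10]
            means.append(sum(chunk) / len(chunk))
        assert cs.group_means == tuple(means)
        assert cs.mean == pytest.approx(np.mean(means), rel=1e-12)
        assert cs.has_partial_group

    def test_anatomical_maximum_enforced(self):
        with pytest.raises(ValueError, match="maximum"):
            nq.grouped_count_summary([1, 2, 3], group_size=2, max_per_animal=2)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            nq.grouped_count_summary([1, 2], group_size=0)
        with pytest.raises(ValueError):
            nq.grouped_count_summary([-1, 2])


class TestPSPositiveFraction:
    def test_none_above_threshold(self):
        f = nq.ps_positive_fraction([1.0, 1.1, 1.2], threshold=1.5)
        assert f.percent == 0.0

    def test_all_above_threshold(self):
        f = nq.ps_positive_fraction([2.0, 3.0], threshold=1.5)
        assert f.percent == 100.0

    def test_fraction_counts(self):
        f = nq.ps_positive_fraction([1.0, 2.0, 2.0, 1.2], threshold=1.5)
        assert f.n_positive == 2 and f.n_live == 4
        assert f.percent == 50.0


class TestDoseResponse:
    def test_vehicle_only_single_row(self):
        df = pd.DataFrame({"dose": [0] * 5, "rps": [2.0, 2.1, 1.9, 2.0, 2.0]})
        table = nq.dose_response_table(df)
        assert len(table) == 1
        assert float(table["mean"].iloc[0]) == pytest.approx(1.0)

    def test_missing_vehicle_rejected(self):
        df = pd.DataFrame({"dose": [1, 1, 2, 2], "rps": [1, 2, 3, 4.0]})
        with pytest.raises(ValueError, match="vehicle"):
            nq.dose_response_table(df)

    def test_dantrolene_like_doses_monotone_non_increasing(self):
        """Per-dose normalized PS falls as the ER-release gain drops."""
        rows = []
        for dose in (0.0, 1.0, 2.0, 4.0):
            cfg = nq.ScenarioConfig(
                scenario_name=f"dan{dose}",
                er_release_gain=1.0 / (1.0 + 0.35 * dose),
                n_cells=4,
                seed=5,
            )
            for i in range(4):
                rec = nq.simulate_cell(cfg, i)
                rows.append({"dose": dose, "rps": 1.0 + rec.truth.ps_plateau})
        table = nq.dose_response_table(pd.DataFrame(rows))
        assert table.attrs["monotonic_non_increasing"]

    def test_thapsigargin_like_doses_raise_necrotic_counts(self):
        """A reuptake-blocking dose increases the fraction of cells that
        cross the swelling threshold."""
        counts = {}
        for dose in (0.0, 3.0, 6.0):
            cfg = nq.scenario_config("thapsigargin", dose=dose, n_cells=10, seed=0)
            counts[dose] = sum(
                nq.simulate_cell(cfg, i).truth.swelling_onset is not None for i in range(10)
            )
        assert counts[0.0] <= counts[3.0] <= counts[6.0]
        assert counts[6.0] > counts[0.0]


def test_ttest_wrapper_runs(rng):
    res = nq.ttest(rng.normal(0, 1, 10), rng.normal(1, 1, 10))
    assert 0.0 <= res.pvalue <= 1.0
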