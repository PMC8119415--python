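"""Variance decomposition, tests, power, shift/signature maps, slopes."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiomap.stats import (
    DoseResponseTable,
    ecdf,
    ks_normality,
    mean_difference_signature,
    paired_metric_test,
    restitution_curve,
    sample_size_for_change,
    sigma_shift_map,
    tri_vs_mxr_slopes,
    variance_components,
)
from cardiomap.synthetic import VarianceSpec, sample_hierarchical_apds


class TestVarianceComponents:
    def test_all_zero_sds_give_zero_components(self):
        spec = VarianceSpec(sd_beat_ms=0, sd_tissue_ms=0, sd_mold_ms=0, sd_batch_ms=0)
        vc = variance_components(sample_hierarchical_apds(spec, seed=0))
        assert vc.beat_sd_ms == vc.tissue_sd_ms == vc.mold_sd_ms == vc.batch_sd_ms == 0

    def test_order_invariance(self):
        df = sample_hierarchical_apds(VarianceSpec(), seed=1)
        shuffled = df.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a, b = variance_components(df), variance_components(shuffled)
        assert a == b

    def test_shift_invariance_and_scale_equivariance(self):
        df = sample_hierarchical_apds(VarianceSpec(), seed=2)
        base = variance_components(df)
        shifted = variance_components(df.assign(apd_ms=df["apd_ms"] + 123.0))
        for name in ("beat_sd_ms", "tissue_sd_ms", "mold_sd_ms", "batch_sd_ms"):
            assert getattr(shifted, name) == pytest.approx(
                getattr(base, name), rel=1e-9
            )
        scaled = df.assign(apd_ms=df["apd_ms"] * 3.0)
        vc = variance_components(scaled)
        for name in ("beat_sd_ms", "tissue_sd_ms", "mold_sd_ms", "batch_sd_ms"):
            assert getattr(vc, name) == pytest.approx(3.0 * getattr(base, name))

    def test_single_batch_has_no_batch_component(self):
        spec = VarianceSpec(n_batches=1)
        vc = variance_components(sample_hierarchical_apds(spec, seed=3))
        assert math.isnan(vc.batch_sd_ms)
        assert not math.isnan(vc.beat_sd_ms)

    def test_recovers_generating_sds_roughly(self):
        """One draw at the study nesting recovers each component's order."""
        vc = variance_components(sample_hierarchical_apds(VarianceSpec(), seed=4))
        assert vc.beat_sd_ms == pytest.approx(6.4, rel=0.3)
        assert vc.tissue_sd_ms == pytest.approx(36.1, rel=0.3)


class TestKSNormality:
    def test_normal_sample_not_rejected(self):
        rng = np.random.default_rng(0)
        reject = sum(
            ks_normality(rng.normal(330, 21, size=105))[1] < 0.05 for _ in range(100)
        )
        assert reject <= 10

    def test_bimodal_rejected(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(-3, 0.3, 100), rng.normal(3, 0.3, 100)])
        assert ks_normality(x)[1] < 0.01

    def test_affine_invariance_of_statistic(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        s1, _ = ks_normality(x)
        s2, _ = ks_normality(5.0 * x + 100.0)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            ks_normality(np.ones(20))


class TestPairedTest:
    def test_identical_vectors(self):
        x = np.arange(10.0)
        t, p, d = paired_metric_test(x, x)
        assert math.isnan(t) or t == 0.0
        assert d == 0.0

    def test_constant_shift_degenerate(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="degenerate"):
            paired_metric_test(x, x + 10.0)

    def test_detects_real_shift(self):
        rng = np.random.default_rng(3)
        x = rng.normal(300, 10, 35)
        _, p, d = paired_metric_test(x, x + rng.normal(15, 5, 35))
        assert p < 0.001 and d == pytest.approx(15, abs=3)


class TestSampleSize:
    def test_huge_effect_needs_minimum_two(self):
        assert sample_size_for_change(100.0, 0.001, 1.0) == 2

    def test_monotonicity(self):
        ns_rel = [
            sample_size_for_change(100.0, 20.0, rc, power=0.8)
            for rc in (0.05, 0.10, 0.20)
        ]
        assert ns_rel[0] >= ns_rel[1] >= ns_rel[2]
        ns_pow = [
            sample_size_for_change(100.0, 20.0, 0.10, power=pw)
            for pw in (0.5, 0.8, 0.95)
        ]
        assert ns_pow[0] <= ns_pow[1] <= ns_pow[2]

    def test_agrees_with_power_simulation(self):
        """Analytic n within +/-1 of a 20,000-rep simulation oracle."""
        from scipy import stats as sps

        mean, sd, rel, alpha, power = 100.0, 10.0, 0.10, 0.05, 0.80
        n_analytic = sample_size_for_change(mean, sd, rel, alpha=alpha, power=power)

        def sim_power(n, reps=20_000, seed=10):
            rng = np.random.default_rng(seed)
            x = rng.normal(rel * mean, sd, size=(reps, n))
            t, p = sps.ttest_1samp(x, 0.0, axis=1)
            return (p < alpha).mean()

        n_sim = next(n for n in range(2, 100) if sim_power(n) >= power)
        assert abs(n_analytic - n_sim) <= 1

    def test_zero_change_rejected(self):
        with pytest.raises(ValueError):
            sample_size_for_change(100.0, 10.0, 0.0)


def make_dose_table(n_tissues=10, doses=(0.0, 1.0, 10.0), seed=0,
                    shift_by_dose=None, lose_excitability=()):
    """Long-form dose table with normal control values per metric."""
    rng = np.random.default_rng(seed)
    metrics = ["apd80_ms", "apd50_ms"]
    rows = []
    base = {m: rng.normal(300, 20, n_tissues) for m in metrics}
    for dose in doses:
        shift = (shift_by_dose or {}).get(dose, 0.0)
        for m in metrics:
            for t in range(n_tissues):
                excitable = (t, dose) not in lose_excitability
                rows.append(dict(tissue=t, dose=dose, metric=m,
                                 value=base[m][t] + shift, excitable=excitable))
    return DoseResponseTable(data=pd.DataFrame(rows), control_dose=0.0)


class TestShiftMap:
    def test_control_column_self_normalizes(self):
        shift = sigma_shift_map(make_dose_table())
        for metric in ("apd80_ms", "apd50_ms"):
            col = shift.values[(metric, 0.0)]
            assert col.mean() == pytest.approx(0.0, abs=1e-12)
            assert col.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_two_sigma_shift_reads_two(self):
        table = make_dose_table()
        ctrl = table.data[(table.data["dose"] == 0.0)
                          & (table.data["metric"] == "apd80_ms")]["value"]
        mu, sd = ctrl.mean(), ctrl.std(ddof=1)
        table.data.loc[
            (table.data["dose"] == 10.0)
            & (table.data["metric"] == "apd80_ms")
            & (table.data["tissue"] == 0),
            "value",
        ] = mu + 2 * sd
        shift = sigma_shift_map(table)
        assert shift.values[("apd80_ms", 10.0)][0] == pytest.approx(2.0)

    def test_non_excitable_cells_unavailable(self):
        table = make_dose_table(lose_excitability={(3, 10.0)})
        shift = sigma_shift_map(table)
        assert math.isnan(shift.values[("apd80_ms", 10.0)][3])
        assert not math.isnan(shift.values[("apd80_ms", 1.0)][3])


class TestSignatureMap:
    def test_control_column_exactly_zero(self):
        sig = mean_difference_signature(make_dose_table())
        assert (sig.values[0.0] == 0.0).all()
        assert not sig.significant[0.0].any()

    def test_unshifted_dose_not_significant(self):
        sig = mean_difference_signature(make_dose_table())
        assert abs(sig.values.loc["apd80_ms", 1.0]) < 1e-9

    def test_one_sigma_shift_detected(self):
        """A uniform +1 control-SD shift reads ~+1.0 and is significant."""
        table = make_dose_table(n_tissues=35, seed=1)
        ctrl = table.data[(table.data["dose"] == 0.0)
                          & (table.data["metric"] == "apd80_ms")]["value"]
        sd = ctrl.std(ddof=1)
        mask = (table.data["dose"] == 10.0) & (table.data["metric"] == "apd80_ms")
        rng = np.random.default_rng(11)
        table.data.loc[mask, "value"] += sd + rng.normal(0, 2, mask.sum())
        sig = mean_difference_signature(table)
        assert sig.values.loc["apd80_ms", 10.0] == pytest.approx(1.0, abs=0.1)
        assert sig.significant.loc["apd80_ms", 10.0]

    def test_biphasic_series_signs(self):
        """Up at low dose, down at high dose gives a (+, ~0, -) signature."""
        table = make_dose_table(
            n_tissues=35, doses=(0.0, 1.0, 5.0, 50.0), seed=2,
            shift_by_dose={1.0: 25.0, 5.0: 0.0, 50.0: -25.0},
        )
        rng = np.random.default_rng(12)
        ctrl_mask = table.data["dose"] == 0.0
        table.data.loc[~ctrl_mask, "value"] += rng.normal(0, 3, (~ctrl_mask).sum())
        sig = mean_difference_signature(table)
        row = sig.values.loc["apd80_ms"]
        assert row[1.0] > 0.5 and abs(row[5.0]) < 0.2 and row[50.0] < -0.5


class TestCurves:
    def test_ecdf_values(self):
        x, y = ecdf([1.0, 2.0, 3.0])
        assert y[np.searchsorted(x, 2.0)] == pytest.approx(2 / 3)

    @given(shift=st.floats(-100, 100))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_ecdf_translates_with_shift(self, shift):
        vals = np.array([300.0, 310.0, 320.0, 350.0])
        x0, y0 = ecdf(vals)
        x1, y1 = ecdf(vals + shift)
        np.testing.assert_allclose(x1, x0 + shift, atol=1e-9)
        np.testing.assert_array_equal(y0, y1)

    def test_spread_reduces_max_slope(self):
        """Higher variability flattens the cumulative curve."""
        rng = np.random.default_rng(4)
        tight = rng.normal(300, 5, 200)
        wide = rng.normal(300, 50, 200)

        def max_slope(v):
            x, y = ecdf(v)
            dx = np.diff(x)
            return (np.diff(y) / np.where(dx > 0, dx, np.inf)).max()

        assert max_slope(tight) > max_slope(wide)

    def test_restitution_ordering_and_flat(self):
        curve = restitution_curve({800: [250.0, 252.0], 2000: [260.0, 261.0],
                                   1000: [255.0, 254.0]})
        assert list(curve["cycle_length_ms"]) == [800.0, 1000.0, 2000.0]
        flat = restitution_curve({800: [250.0], 1000: [250.0]})
        assert flat["mean_ms"].nunique() == 1

    def test_restitution_single_cl(self):
        curve = restitution_curve({2000: [260.0, 262.0]})
        assert len(curve) == 1


class TestSlopes:
    def test_identical_clouds_z_zero(self):
        rng = np.random.default_rng(5)
        pts = np.column_stack([rng.normal(300, 30, 20), rng.normal(50, 10, 20)])
        cmp_ = tri_vs_mxr_slopes({"ctrl": pts, "dose": pts.copy()}, "ctrl")
        dose = next(s for s in cmp_.slopes if s.dose == "dose")
        assert dose.z_vs_control == pytest.approx(0.0, abs=1e-12)
        assert dose.p_vs_control == pytest.approx(1.0)

    def test_steeper_cloud_detected(self):
        rng = np.random.default_rng(6)
        x = rng.normal(300, 30, 40)
        ctrl = np.column_stack([x, 0.1 * x + rng.normal(0, 3, 40)])
        dose = np.column_stack([x, 0.8 * x + rng.normal(0, 3, 40)])
        cmp_ = tri_vs_mxr_slopes({"c": ctrl, "d": dose}, "c")
        d = next(s for s in cmp_.slopes if s.dose == "d")
        assert d.z_vs_control > 3 and d.p_vs_control < 0.01

    def test_degenerate_x_rejected(self):
        pts = np.column_stack([np.full(5, 300.0), np.arange(5.0)])
        with pytest.raises(ValueError, match="degenerate"):
            tri_vs_mxr_slopes({"c": pts}, "c")

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            tri_vs_mxr_slopes({"c": np.zeros((2, 2))}, "c")
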