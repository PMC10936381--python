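import numpy as np
import pandas as pd
import pytest

from netqc.errors import ValidationError
from netqc.io_tables import FeatureTable
from netqc.normalization import (
    WinsorSpec,
    alignment_report,
    normalize_feature_table,
    winsorize,
)


def _table(samples, values, feature="f1"):
    df = pd.DataFrame({
        "id": [f"c{i}" for i in range(len(values))],
        "sample": samples,
        feature: values,
    })
    return FeatureTable(data=df, feature_names=[feature])


class TestWinsorize:
    def test_linear_interpolation_percentiles_and_rescale(self):
        values = np.arange(101, dtype=float)  # P10 = 10, P90 = 90
        out = winsorize(values)
        assert out[0] == 0.0     # 0 clamps to 10, rescales to 0
        assert out[50] == 0.5
        assert out[100] == 1.0
        assert out[10] == 0.0
        assert out[90] == 1.0

    def test_constant_feature_maps_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = winsorize(np.full(10, 7.0))
        assert np.all(out == 0.0)

    def test_clamping_without_rescale_is_textbook_winsorization(self):
        values = np.arange(101, dtype=float)
        out = winsorize(values, WinsorSpec(rescale=False))
        assert out[0] == 10.0    # exactly P10
        assert out[100] == 90.0  # exactly P90
        assert out[50] == 50.0

    @pytest.mark.parametrize("a,b", [(2.0, 100.0), (0.5, -3.0), (1e3, 0.0)])
    def test_affine_equivariance(self, rng, a, b):
        v = rng.normal(0, 1, 400)
        np.testing.assert_allclose(winsorize(a * v + b), winsorize(v), atol=1e-9)

    def test_missing_values_pass_through(self):
        v = np.array([0.0, np.nan, 1.0, 2.0, 3.0])
        out = winsorize(v)
        assert np.isnan(out[1])
        assert np.isfinite(out[[0, 2, 3, 4]]).all()

    def test_too_few_values_rejected(self):
        with pytest.raises(ValidationError):
            winsorize(np.array([1.0, np.nan]))

    def test_invalid_percentile_band_rejected(self):
        with pytest.raises(ValidationError):
            WinsorSpec(p_low=90, p_high=10)

    def test_monotonicity_preserved_between_clamp_points(self, rng):
        v = rng.normal(0, 1, 300)
        out = winsorize(v)
        interior = (out > 0) & (out < 1)
        order_in = np.argsort(v[interior], kind="stable")
        order_out = np.argsort(out[interior], kind="stable")
        np.testing.assert_array_equal(order_in, order_out)


class TestNormalizeFeatureTable:
    def test_per_sample_normalization_removes_affine_shift_exactly(self, rng):
        v = rng.normal(5, 2, 300)
        t = _table(["s1"] * 300 + ["s2"] * 300, np.concatenate([v, 2 * v + 100]))
        out = normalize_feature_table(t)
        g = out.data.groupby("sample", sort=False)["f1"]
        np.testing.assert_allclose(
            g.get_group("s1").to_numpy(), g.get_group("s2").to_numpy(), atol=1e-9)

    def test_single_sample_per_sample_flag_is_irrelevant(self, rng):
        t = _table(["s1"] * 100, rng.normal(0, 1, 100))
        a = normalize_feature_table(t, WinsorSpec(per_sample=True))
        b = normalize_feature_table(t, WinsorSpec(per_sample=False))
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_missing_values_preserved(self, rng):
        v = rng.normal(0, 1, 50)
        v[7] = np.nan
        t = _table(["s1"] * 50, v)
        out = normalize_feature_table(t)
        assert np.isnan(out.data["f1"].iloc[7])

    def test_tiny_sample_group_passes_through_with_warning(self, rng):
        t = _table(["s1"] * 50 + ["s2"], np.append(rng.normal(0, 1, 50), 3.5))
        with pytest.warns(UserWarning, match="passed through"):
            out = normalize_feature_table(t)
        assert out.data["f1"].iloc[-1] == 3.5

    def test_idempotent_away_from_clamped_tails(self, rng):
        t = _table(["s1"] * 500, rng.normal(0, 1, 500))
        once = normalize_feature_table(t)
        twice = normalize_feature_table(once)
        v1 = once.data["f1"].to_numpy()
        v2 = twice.data["f1"].to_numpy()
        lo, hi = np.percentile(v1, [10, 90])
        interior = (v1 > lo) & (v1 < hi)
        np.testing.assert_allclose(v2[interior], (v1[interior] - lo) / (hi - lo), atol=1e-9)
        # the re-winsorization only re-anchors; interior order is untouched
        assert np.all(np.diff(np.argsort(v2[interior], kind="stable")
                              == np.argsort(v1[interior], kind="stable")) == 0)


class TestAlignmentReport:
    def test_identical_groups_have_zero_divergence(self, rng):
        v = rng.normal(0, 1, 200)
        t = _table(["s1"] * 200 + ["s2"] * 200, np.concatenate([v, v]))
        report = alignment_report(t, t)
        assert report["ks_before"].iloc[0] == 0.0
        assert report["ks_after"].iloc[0] == 0.0

    def test_disjoint_supports_before_statistic_is_one(self, rng):
        t = _table(["s1"] * 100 + ["s2"] * 100,
                   np.concatenate([rng.uniform(0, 1, 100), rng.uniform(10, 11, 100)]))
        report = alignment_report(t, normalize_feature_table(t))
        assert report["ks_before"].iloc[0] == 1.0

    def test_affine_shifted_cores_improve_for_every_feature(self, rng):
        v1 = rng.normal(5, 2, 400)
        v2 = 2 * rng.normal(5, 2, 400) + 100
        t = _table(["s1"] * 400 + ["s2"] * 400, np.concatenate([v1, v2]))
        out = normalize_feature_table(t)
        report = alignment_report(t, out)
        assert report["improved"].all()
        assert report.attrs["fraction_improved"] == 1.0

    def test_requires_exactly_two_samples(self, rng):
        t = _table(["s1"] * 10 + ["s2"] * 10 + ["s3"] * 10, rng.normal(0, 1, 30))
        with pytest.raises(ValidationError):
            alignment_report(t, t)
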