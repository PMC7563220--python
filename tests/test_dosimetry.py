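"""SAR, THQ, |dTHQ|, |dRD| and boxplot statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from htplan.dosimetry import (
    DriveSettings,
    SarMap,
    combine_fields,
    compute_drd,
    compute_dthq,
    compute_sar,
    compute_thq,
    hotspot_mean,
    summarize_boxplot,
)
from htplan.fdtd import ChannelFieldSet


def _random_fieldset(n_channels=4, shape=(12, 12), seed=0) -> ChannelFieldSet:
    rng = np.random.default_rng(seed)
    f = rng.normal(size=(n_channels, *shape, 1)) + 1j * rng.normal(
        size=(n_channels, *shape, 1)
    )
    return ChannelFieldSet(f, spacing_mm=5.0, frequency_hz=1e8, mode="2d")


def _sar_map(sar, htv=None, healthy=None, tissues=None) -> SarMap:
    sar = np.asarray(sar, float)
    if htv is None:
        htv = np.zeros(sar.shape, bool)
        htv.ravel()[: max(1, sar.size // 10)] = True
    if healthy is None:
        healthy = ~htv
    return SarMap(sar, htv, healthy, tissues or {})


class TestCombineFields:
    def test_single_unit_weight_returns_that_channel(self):
        fs = _random_fieldset()
        drive = DriveSettings((1.0, 0.0, 0.0, 0.0))
        assert np.array_equal(combine_fields(fs, drive), fs.fields[0])

    def test_global_phase_leaves_magnitude_unchanged(self):
        fs = _random_fieldset()
        w = np.array([1.0, 0.5j, -0.25, 0.8 + 0.1j])
        base = combine_fields(fs, DriveSettings(tuple(w)))
        rotated = combine_fields(fs, DriveSettings(tuple(w * np.exp(1j * 0.7))))
        np.testing.assert_allclose(np.abs(rotated), np.abs(base), rtol=1e-12)

    def test_doubling_weights_doubles_magnitude(self):
        fs = _random_fieldset()
        w = np.array([1.0, 0.5, 0.2, 0.1]) * np.exp(1j * 0.3)
        base = combine_fields(fs, DriveSettings(tuple(w)))
        double = combine_fields(fs, DriveSettings(tuple(2 * w)))
        np.testing.assert_allclose(np.abs(double), 2 * np.abs(base), rtol=1e-12)

    def test_channel_count_mismatch_rejected(self):
        fs = _random_fieldset(n_channels=4)
        with pytest.raises(ValueError, match="channels"):
            combine_fields(fs, DriveSettings((1.0, 1.0)))

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            DriveSettings((0.0, 0.0))


class TestComputeSar:
    def test_muscle_formula_value(self):
        # sigma |E|^2 / (2 rho) with muscle constants and |E| = 100 V/m
        field = np.full((1, 1, 1), 100.0 + 0.0j)
        sar = compute_sar(field, np.array([[0.708]]), np.array([[1090.0]]))
        assert sar[0, 0] == pytest.approx(0.708 * 100.0**2 / (2 * 1090.0), rel=1e-15)
        assert sar[0, 0] == pytest.approx(3.24770642, rel=1e-8)

    def test_zero_conductivity_gives_zero_sar(self):
        field = np.full((2, 2, 1), 50.0 + 10.0j)
        sar = compute_sar(field, np.zeros((2, 2)), np.full((2, 2), 1908.0))
        assert np.all(sar == 0.0)

    def test_sar_quadruples_when_field_doubles(self):
        rng = np.random.default_rng(1)
        field = rng.normal(size=(5, 5, 1)) + 1j * rng.normal(size=(5, 5, 1))
        sig = np.full((5, 5), 0.7)
        rho = np.full((5, 5), 1000.0)
        np.testing.assert_allclose(
            compute_sar(2 * field, sig, rho), 4 * compute_sar(field, sig, rho),
            rtol=1e-12,
        )

    def test_vector_components_add_in_quadrature(self):
        field = np.zeros((1, 1, 3), complex)
        field[0, 0] = [3.0, 4.0, 0.0]
        sar = compute_sar(field, np.array([[1.0]]), np.array([[500.0]]))
        assert sar[0, 0] == pytest.approx(25.0 / 1000.0, rel=1e-14)

    def test_incongruent_grids_rejected(self):
        with pytest.raises(ValueError, match="congruent"):
            compute_sar(np.zeros((3, 3, 1)), np.zeros((4, 4)), np.ones((4, 4)))


class TestHotspotMean:
    def test_top_percent_of_ramp_is_maximum(self):
        sar = np.arange(1.0, 101.0)
        assert hotspot_mean(sar, np.ones(100, bool), 0.01) == 100.0

    def test_uniform_sar_returns_constant(self):
        sar = np.full(57, 3.3)
        for f in (0.01, 0.33, 1.0):
            assert hotspot_mean(sar, np.ones(57, bool), f) == pytest.approx(3.3)

    def test_full_fraction_is_plain_mean(self):
        rng = np.random.default_rng(2)
        sar = rng.random(321)
        mask = np.ones(321, bool)
        assert hotspot_mean(sar, mask, 1.0) == pytest.approx(sar.mean(), rel=1e-14)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            hotspot_mean(np.ones(5), np.zeros(5, bool), 0.5)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        n=st.integers(1, 400),
        frac=st.floats(0.001, 1.0),
        seed=st.integers(0, 2**16),
        dup=st.booleans(),
    )
    def test_matches_full_sort_oracle_exactly(self, n, frac, seed, dup):
        rng = np.random.default_rng(seed)
        sar = rng.random(n)
        if dup:  # force ties
            sar = np.round(sar, 1)
        mask = rng.random(n) < 0.8
        if not mask.any():
            mask[0] = True
        k = int(np.ceil(frac * mask.sum()))
        oracle = np.sort(sar[mask])[-k:].mean()
        assert hotspot_mean(sar, mask, frac) == oracle


class TestThq:
    def test_uniform_sar_gives_unit_thq(self):
        sm = _sar_map(np.full((20, 20), 2.5))
        assert compute_thq(sm) == pytest.approx(1.0, abs=1e-15)

    def test_target_over_hotspot_arithmetic(self):
        sar = np.zeros(200)
        htv = np.zeros(200, bool)
        htv[:100] = True
        sar[htv] = 2.0
        sar[~htv] = 4.0
        sm = SarMap(sar, htv, ~htv, {})
        assert compute_thq(sm) == pytest.approx(0.5, rel=1e-14)

    def test_zero_field_is_undefined(self):
        sm = _sar_map(np.zeros((10, 10)))
        with pytest.raises(ValueError, match="zero hotspot"):
            compute_thq(sm)

    def test_empty_masks_rejected(self):
        sar = np.ones(10)
        with pytest.raises(ValueError, match="HTV"):
            compute_thq(SarMap(sar, np.zeros(10, bool), np.ones(10, bool), {}))


class TestDthqDrd:
    @pytest.mark.parametrize(
        "thq_n, thq_ref, expected",
        [(0.8, 0.8, 0.0), (0.76, 0.8, 5.0), (0.96, 0.8, 20.0), (0.84, 0.8, 5.0)],
    )
    def test_relative_difference_arithmetic(self, thq_n, thq_ref, expected):
        assert compute_dthq(thq_n, thq_ref) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            compute_dthq(0.5, 0.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.01, 100.0), b=st.floats(0.01, 100.0)
    )
    def test_dthq_nonnegative_and_zero_iff_equal(self, a, b):
        v = compute_dthq(a, b)
        assert v >= 0.0
        if a == b:
            assert v == 0.0

    def test_identical_maps_give_zero_drd_everywhere(self):
        sar = np.random.default_rng(3).random((8, 8))
        masks = {"muscle": np.ones((8, 8), bool)}
        sm = SarMap(sar, np.zeros((8, 8), bool), np.ones((8, 8), bool), masks)
        values, undefined = compute_drd(sm, sm)
        assert values == {"muscle": 0.0}
        assert undefined == []

    def test_twenty_percent_example(self):
        ref = _sar_map(np.full(100, 100.0), tissues={"t": np.ones(100, bool)})
        new = _sar_map(np.full(100, 120.0), tissues={"t": np.ones(100, bool)})
        values, _ = compute_drd(new, ref)
        assert values["t"] == pytest.approx(20.0, abs=1e-12)

    def test_zero_reference_flagged_undefined(self):
        masks = {"bone": np.ones(10, bool)}
        ref = SarMap(np.zeros(10), np.zeros(10, bool), np.ones(10, bool), masks)
        new = SarMap(np.ones(10), np.zeros(10, bool), np.ones(10, bool), masks)
        with pytest.warns(RuntimeWarning, match="bone"):
            values, undefined = compute_drd(new, ref)
        assert undefined == ["bone"]
        assert "bone" not in values


class TestDoseReport:
    def test_threshold_flag_and_summary(self):
        from htplan.dosimetry import DoseReport

        rep = DoseReport(
            scheme="clinical", thq=0.76, sar_htv_mean=2.0,
            sar_hotspot_mean=2.6, dthq_pct=5.0,
            drd_pct={"muscle": 4.0, "urine": 30.0, "sat": 10.0},
        )
        assert rep.thq_acceptable is True  # 5.0 sits at the threshold
        rep_bad = DoseReport("clinical", 0.6, 2.0, 3.3, dthq_pct=23.8)
        assert rep_bad.thq_acceptable is False
        assert DoseReport("detailed", 0.8, 2.0, 2.5).thq_acceptable is None
        summary = rep.drd_summary()
        assert summary["median"] == 10.0


class TestBoxplot:
    def test_singleton_collapses_to_one_value(self):
        s = summarize_boxplot([10.0])
        assert set(s.values()) == {10.0}

    def test_linear_interpolation_percentiles(self):
        # 1..100: quantile q sits at value 1 + 99 q under linear ranks
        s = summarize_boxplot(np.arange(1.0, 101.0))
        assert s["median"] == pytest.approx(50.5)
        assert s["q1"] == pytest.approx(1 + 99 * 0.25)
        assert s["q3"] == pytest.approx(1 + 99 * 0.75)
        assert s["p2.5"] == pytest.approx(1 + 99 * 0.025)
        assert s["p97.5"] == pytest.approx(1 + 99 * 0.975)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_boxplot([])
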