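"""Disparity descriptors, variance summaries and equalization detection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fusefid.datamodel import IntensityRecord
from fusefid.metrics import (
    DisparitySeries,
    constriction_index,
    ddme_variance,
    disparity_series,
    equalization_time,
    norm_diff,
    normalized_intensity,
)
from fusefid.simulate import SimulationConfig, simulate

positive = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)


class TestNormDiff:
    @pytest.mark.parametrize("u, l, expected", [
        (100, 100, 0.0),
        (120, 80, 0.4),
        (3, 0, 2.0),
        (0, 3, -2.0),
    ])
    def test_examples(self, u, l, expected):
        assert norm_diff(u, l) == pytest.approx(expected, abs=1e-12)

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError, match="zero"):
            norm_diff(0, 0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            norm_diff(-1, 2)

    @given(positive, positive)
    def test_antisymmetry(self, a, b):
        assert norm_diff(a, b) == pytest.approx(-norm_diff(b, a), rel=1e-12)

    @given(positive, positive)
    def test_bounded_below_two(self, a, b):
        assert abs(norm_diff(a, b)) < 2.0

    @given(positive, positive, st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, a, b, k):
        assert norm_diff(k * a, k * b) == pytest.approx(norm_diff(a, b), abs=1e-9)

    @given(positive, positive)
    def test_zero_iff_equal(self, a, b):
        if a == b:
            assert norm_diff(a, b) == 0.0
        else:
            assert norm_diff(a, b) != 0.0

    def test_vectorized_matches_scalar(self):
        u = np.array([1.0, 2.0, 3.0])
        l = np.array([3.0, 2.0, 1.0])
        out = norm_diff(u, l)
        assert out == pytest.approx([norm_diff(a, b) for a, b in zip(u, l)])


class TestDisparitySeries:
    def test_equal_tracks_give_zero_series(self, control_sim):
        from fusefid.simulate import make_fixture
        ds, _ = make_fixture("equal_pair")
        s = disparity_series(ds, "dme_compartment", ("A3", "stripe"))
        assert np.all(s.value == 0.0)

    def test_hand_computed_linear_drift(self):
        """Frame-wise values equal the formula applied by hand."""
        from fusefid.datamodel import EmbryoDataset, FlankTrack, TimelineConvention
        t = np.arange(0.0, 101.0, 5.0) - 100.0  # retrospective
        upper = 100.0 + (t + 100.0) / 10.0
        lower = np.full(t.shape, 100.0)
        ds = EmbryoDataset(
            "drift", "control",
            TimelineConvention(t_E=-100.0, t_completion=0.0),
            [FlankTrack("upper", t, upper, t, np.full(t.shape, 10.0)),
             FlankTrack("lower", t, lower, t, np.full(t.shape, 10.0))],
        )
        s = disparity_series(ds, "arc_length")
        expected = [(u - l) / ((u + l) / 2.0) for u, l in zip(upper, lower)]
        assert s.value == pytest.approx(expected, abs=1e-12)

    def test_disjoint_visibility_windows_error(self):
        from fusefid.datamodel import (CompartmentTrack, EmbryoDataset, FlankTrack,
                                       TimelineConvention)
        t = np.arange(-20.0, 1.0, 5.0)
        flanks = [FlankTrack(s, t, np.full(t.shape, 100.0), t, np.full(t.shape, 10.0))
                  for s in ("upper", "lower")]
        w = np.full(t.shape, 10.0)
        cu = CompartmentTrack("A3", "stripe", "upper", t, np.where(t < -10, w, np.nan),
                              t, np.full(t.shape, 5.0))
        cl = CompartmentTrack("A3", "stripe", "lower", t, np.where(t >= -10, w, np.nan),
                              t, np.full(t.shape, 5.0))
        ds = EmbryoDataset("dj", "control",
                           TimelineConvention(t_E=-20.0, t_completion=0.0,
                                              t_F_by_compartment={("A3", "stripe"): 0.0}),
                           flanks, [cu, cl])
        with pytest.raises(ValueError, match="common visible frames"):
            disparity_series(ds, "width", ("A3", "stripe"))

    def test_unknown_pair_lookup_error(self, control_sim):
        _, datasets, _ = control_sim
        with pytest.raises(KeyError):
            disparity_series(datasets[0], "width", ("A8", "stripe"))

    def test_whole_arc_count_series_starts_at_minus_100(self, control_sim):
        _, datasets, _ = control_sim
        s = disparity_series(datasets[0], "dme_arc")
        assert s.t[0] >= -100.0


class TestDdmeVariance:
    def test_brute_force_example(self):
        out = ddme_variance({"e1": [0, 1, 2]})
        assert out.per_embryo_sigma2[0] == pytest.approx(2.0 / 3.0)
        assert out.var_ddme == pytest.approx(2.0 / 3.0)

    def test_identical_deltas_give_zero(self):
        assert ddme_variance({"e1": [1, 1, 1], "e2": [2, 2, 2, 2]}).var_ddme == 0.0

    def test_mean_over_embryos(self):
        # two embryos engineered to sigma^2 = 0.5 and 1.5
        out = ddme_variance({"a": [0, 1, 0, 1], "b": [0, 3, 1, 2]})
        assert out.per_embryo_sigma2 == pytest.approx([0.25, 1.25])
        out2 = ddme_variance({"a": [1, 2], "b": [0, 2]})  # 0.25 and 1.0
        assert out2.var_ddme == pytest.approx(np.mean([0.25, 1.0]))

    def test_against_independent_two_pass_oracle(self, rng):
        """Population variance per embryo then plain mean, to 1e-12."""
        for _ in range(200):
            data = {f"e{i}": rng.integers(0, 4, size=rng.integers(1, 8)).tolist()
                    for i in range(rng.integers(1, 6))}
            # two-pass oracle written from the definition
            sig2 = []
            for deltas in data.values():
                mu = sum(deltas) / len(deltas)
                sig2.append(sum((x - mu) ** 2 for x in deltas) / len(deltas))
            expected = sum(sig2) / len(sig2)
            assert ddme_variance(data).var_ddme == pytest.approx(expected, abs=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ddme_variance({})


class TestConstrictionIndex:
    def test_examples(self):
        assert constriction_index(30.0, 6) == 5.0
        assert constriction_index(7.5, 1) == 7.5

    @given(st.floats(min_value=0.1, max_value=100.0), st.integers(min_value=1, max_value=30))
    def test_linearity_in_width(self, w, n):
        assert constriction_index(2 * w, n) == pytest.approx(2 * constriction_index(w, n))

    def test_zero_cells_domain_error(self):
        with pytest.raises(ValueError):
            constriction_index(10.0, 0)


class TestNormalizedIntensity:
    def test_examples(self):
        rec = IntensityRecord("e", "actin", "en_face", 2.0, 2.0, 5)
        assert normalized_intensity(rec) == 1.0
        rec.I = 3.0
        assert normalized_intensity(rec) == 1.5

    def test_decreasing_intensity_series_is_monotone(self):
        vals = [normalized_intensity(IntensityRecord("e", "actin", s, i, 2.0, 5))
                for s, i in zip(("pre_fusion", "en_face", "interlocked"), (3.0, 2.0, 1.0))]
        assert vals == sorted(vals, reverse=True)

    def test_nonpositive_reference_rejected(self):
        rec = IntensityRecord("e", "actin", "en_face", 2.0, -1.0, 5)
        with pytest.raises(ValueError):
            normalized_intensity(rec)


class TestEqualizationTime:
    def _series(self, values, t0=0.0, dt=5.0):
        t = t0 + dt * np.arange(len(values))
        return DisparitySeries("dme_arc", "whole-arc", t, np.asarray(values, float))

    def test_settles_at_third_frame(self):
        s = self._series([0.4, 0.2, 0.0, 0.0, 0.0])
        assert equalization_time(s, epsilon=0.0, hold=2) == s.t[2]

    def test_never_settles(self):
        s = self._series([0.4, 0.3, 0.2, 0.3, 0.4])
        assert equalization_time(s, epsilon=0.0, hold=2) is None

    def test_transient_dip_does_not_count(self):
        s = self._series([0.4, 0.0, 0.0, 0.3, 0.0, 0.0])
        assert equalization_time(s, epsilon=0.0, hold=2) == s.t[4]

    def test_hold_requires_enough_tail_frames(self):
        s = self._series([0.4, 0.2, 0.0])
        assert equalization_time(s, epsilon=0.0, hold=2) is None

    def test_all_below_returns_first_frame(self):
        s = self._series([0.0, 0.0, 0.0])
        assert equalization_time(s, epsilon=0.0, hold=2) == s.t[0]


def test_simulated_control_equalization_recovered(control_sim):
    """Detected length-equalization within one count frame of the configured truth."""
    cfg, datasets, truth = control_sim
    for ds in datasets:
        s = disparity_series(ds, "arc_length")
        s.detect_equalization()
        expected = truth.equalization[ds.embryo_id]["arc_length"]
        assert s.equalization_time is not None
        assert abs(s.equalization_time - expected) <= 5.0


def test_arc_disparity_declines_and_length_precedes_count(control_sim):
    """Arc-length disparity shrinks between -190 and -100 min and length
    equalizes no later than cell number, per the fusion chronology."""
    cfg, datasets, truth = control_sim
    early, late = [], []
    for ds in datasets:
        s = disparity_series(ds, "arc_length")
        early.append(abs(s.value[np.argmin(np.abs(s.t + 190.0))]))
        late.append(abs(s.value[np.argmin(np.abs(s.t + 100.0))]))
        s.detect_equalization()
        c = disparity_series(ds, "dme_arc")
        c.detect_equalization()
        assert s.equalization_time <= c.equalization_time
    assert np.median(late) < np.median(early)
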