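"""Schema validation, serialization round trips and timeline arithmetic."""

import numpy as np
import pytest

from fusefid.datamodel import (
    AdditionEvent,
    CompartmentTrack,
    EmbryoDataset,
    FlankTrack,
    IntensityRecord,
    TimelineConvention,
    ValidationError,
)
from fusefid.io import read_dataset, replicate_average, to_retrospective, write_dataset
from fusefid.simulate import SimulationConfig, make_fixture, simulate


def _assert_datasets_equal(a, b):
    assert a.embryo_id == b.embryo_id and a.genotype_label == b.genotype_label
    assert a.timeline.t_F_by_compartment == b.timeline.t_F_by_compartment
    for side in ("upper", "lower"):
        fa, fb = a.flank(side), b.flank(side)
        assert np.array_equal(fa.t_L, fb.t_L)
        assert np.array_equal(fa.L, fb.L, equal_nan=True)
        assert np.array_equal(fa.N, fb.N, equal_nan=True)
        if fa.replicate_L is None:
            assert fb.replicate_L is None
        else:
            assert np.array_equal(fa.replicate_L, fb.replicate_L, equal_nan=True)
    assert len(a.compartments) == len(b.compartments)
    for ca, cb in zip(a.compartments, b.compartments):
        assert (ca.segment_id, ca.compartment, ca.side) == (cb.segment_id, cb.compartment, cb.side)
        assert np.array_equal(ca.W, cb.W, equal_nan=True)
        assert np.array_equal(ca.n, cb.n, equal_nan=True)
        assert ca.visible_from == cb.visible_from
    assert len(a.interfaces) == len(b.interfaces)
    for ia, ib in zip(a.interfaces, b.interfaces):
        assert np.array_equal(ia.polyline, ib.polyline)
        assert ia.endpoint_vertex_degrees == ib.endpoint_vertex_degrees
        assert (ia.stage, ia.connects_two_DV, ia.curved_flag) == (
            ib.stage, ib.connects_two_DV, ib.curved_flag)
    assert [(e.segment_id, e.side, e.t_event, e.source, e.delta_n) for e in a.events] == [
        (e.segment_id, e.side, e.t_event, e.source, e.delta_n) for e in b.events]
    assert [(r.marker, r.stage, r.I, r.I_DV, r.n_interfaces) for r in a.intensities] == [
        (r.marker, r.stage, r.I, r.I_DV, r.n_interfaces) for r in b.intensities]
    assert len(a.snapshots) == len(b.snapshots)
    for sa, sb in zip(a.snapshots, b.snapshots):
        assert [(c.has_interlocked_interface, c.dv_length, c.ap_length) for c in sa.cells] == [
            (c.has_interlocked_interface, c.dv_length, c.ap_length) for c in sb.cells]


@pytest.mark.parametrize("store_replicates", [False, True])
def test_write_read_round_trip_is_identity(tmp_path, store_replicates):
    cfg = SimulationConfig(seed=5, n_embryos=1, store_replicates=store_replicates)
    (ds,), _ = simulate(cfg)
    ds2 = read_dataset(write_dataset(ds, tmp_path / "e"))
    _assert_datasets_equal(ds, ds2)


def test_round_trip_preserves_missingness(tmp_path):
    """Peripheral frames before visibility survive as NaN, not zero."""
    (ds,), _ = simulate(SimulationConfig(seed=5, n_embryos=1))
    per = ds.compartment("Lb", "stripe", "upper")
    assert np.isnan(per.W[per.t_W < per.visible_from]).all()
    ds2 = read_dataset(write_dataset(ds, tmp_path / "e"))
    per2 = ds2.compartment("Lb", "stripe", "upper")
    assert np.array_equal(per.W, per2.W, equal_nan=True)


def test_fixture_round_trip_with_empty_interfaces(tmp_path):
    ds, _ = make_fixture("equal_pair")
    assert not ds.interfaces
    path = write_dataset(ds, tmp_path / "f")
    assert (path / "interfaces.tsv").read_text().startswith("embryo_id\t")
    ds2 = read_dataset(path)
    _assert_datasets_equal(ds, ds2)


def _tiny_valid():
    t = np.arange(-20.0, 0.0 + 1e-9, 5.0)
    tl = TimelineConvention(t_E=-20.0, t_completion=0.0,
                            t_F_by_compartment={("A3", "stripe"): 0.0},
                            frame_interval_length=5.0, frame_interval_count=5.0)
    flanks = [FlankTrack(s, t, np.full(t.shape, 100.0), t, np.full(t.shape, 20.0))
              for s in ("upper", "lower")]
    comps = [CompartmentTrack("A3", "stripe", s, t, np.full(t.shape, 12.0),
                              t, np.full(t.shape, 5.0)) for s in ("upper", "lower")]
    return EmbryoDataset("tiny", "control", tl, flanks, comps)


@pytest.mark.parametrize("mutate, match", [
    (lambda d: d.compartments[0].W.__setitem__(1, -1.0), "width"),
    (lambda d: d.compartments[0].n.__setitem__(1, 0.0), "count"),
    (lambda d: d.flanks[0].L.__setitem__(0, 0.0), "positive"),
    (lambda d: d.flanks[0].N.__setitem__(0, -2.0), "non-negative"),
    (lambda d: setattr(d.flanks[0], "side", "lower"), "one upper"),
    (lambda d: setattr(d.compartments[0], "compartment", "middle"), "compartment"),
    (lambda d: d.events.append(
        AdditionEvent("tiny", "A2", "upper", -10.0, "mixer_cell", 1)), "segment"),
    (lambda d: d.events.append(
        AdditionEvent("tiny", "A3", "upper", -10.0, "mixer_cell", 0)), "delta_n"),
    (lambda d: d.intensities.append(
        IntensityRecord("tiny", "actin", "en_face", 1.0, 0.0, 5)), "I_DV"),
    (lambda d: d.intensities.append(
        IntensityRecord("tiny", "gfp", "en_face", 1.0, 1.0, 5)), "marker"),
    (lambda d: setattr(d.timeline, "frame_interval_count", 7.0), "multiple"),
])
def test_single_field_violations_are_rejected(mutate, match):
    ds = _tiny_valid()
    ds.validate()  # starts valid
    mutate(ds)
    with pytest.raises(ValidationError, match=match):
        ds.validate()


def test_unknown_segment_in_events_table_rejected_on_read(tmp_path):
    ds = _tiny_valid()
    path = write_dataset(ds, tmp_path / "d")
    events = path / "events.tsv"
    events.write_text(events.read_text()
                      + "tiny\tA9\tupper\t-10\tmixer_cell\t1\n")
    with pytest.raises(ValidationError, match="A9"):
        read_dataset(path)


def test_negative_width_rejected_on_read(tmp_path):
    ds = _tiny_valid()
    path = write_dataset(ds, tmp_path / "d")
    comp = path / "compartments.tsv"
    comp.write_text(comp.read_text().replace("12\t5", "-1\t5", 1))
    with pytest.raises(ValidationError, match="width"):
        read_dataset(path)


class TestRetrospective:
    def test_affine_shift_to_completion_zero(self):
        ds = _tiny_valid()
        # re-express on a prospective clock 0..190 with completion at 190
        for f in ds.flanks:
            f.t_L = f.t_L + 210.0
            f.t_N = f.t_N + 210.0
        for c in ds.compartments:
            c.t_W = c.t_W + 210.0
            c.t_n = c.t_n + 210.0
        ds.timeline.t_E += 210.0
        ds.timeline.t_completion = 210.0
        ds.timeline.t_F_by_compartment = {
            k: v + 210.0 for k, v in ds.timeline.t_F_by_compartment.items()}
        retro = to_retrospective(ds)
        assert retro.timeline.t_completion == 0.0
        assert retro.flank("upper").t_L[0] == -20.0
        # pairwise differences are conserved exactly
        assert np.array_equal(np.diff(retro.flank("upper").t_L),
                              np.diff(ds.flank("upper").t_L))

    def test_idempotent_on_retrospective_data(self):
        ds = _tiny_valid()
        again = to_retrospective(ds)
        assert again.timeline.t_completion == 0.0
        assert np.array_equal(again.flank("upper").t_L, ds.flank("upper").t_L)

    def test_t_minus_100_arithmetic(self):
        tl = TimelineConvention(t_E=-190.0, t_completion=0.0,
                                t_F_by_compartment={("A3", "stripe"): -30.0})
        assert tl.t_minus("A3", "stripe", 100.0) == -130.0

    def test_missing_completion_frame_is_an_error(self):
        ds = _tiny_valid()
        ds.timeline.t_completion = float("nan")
        with pytest.raises(ValidationError, match="prospective"):
            to_retrospective(ds)


@pytest.mark.parametrize("traces, expected", [
    ([100, 102, 98, 101, 99, 100], 100.0),
    ([7], 7.0),
    ([10, 11, 10, 10, 11, 11], 10.5),
])
def test_replicate_average(traces, expected):
    assert replicate_average(traces) == expected


def test_replicate_average_empty_errors():
    with pytest.raises(ValueError):
        replicate_average([])


def test_stored_flank_length_must_equal_replicate_mean():
    t = np.array([0.0, 1.0])
    reps = np.array([[10.0, 12.0], [10.0, 10.0]])
    good = FlankTrack("upper", t, reps.mean(axis=1), t, np.array([5.0, 5.0]),
                      replicate_L=reps)
    good.validate()
    bad = FlankTrack("upper", t, np.array([10.0, 10.0]), t, np.array([5.0, 5.0]),
                     replicate_L=reps)
    with pytest.raises(ValidationError, match="replicate"):
        bad.validate()
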