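"""Water slab-visit detection, classification and block summaries."""

import numpy as np
import pytest

import memflex as mx
from memflex.permeation import PermeationRecord


def _traj_from_z(zs, box_z=10.0, dt=10.0):
    """Single-atom trajectory from a z sequence."""
    frames = [mx.Frame(t * dt, np.array([5.0, 5.0, box_z]),
                       np.array([[1.0, 1.0, z]])) for t, z in enumerate(zs)]
    return mx.Trajectory(frames)


def test_unwrap_minimum_image():
    traj = _traj_from_z([9.9, 0.1])
    z, bad = mx.unwrap_z(traj, np.array([0]))
    np.testing.assert_allclose(z[:, 0], [9.9, 10.1])
    assert not bad[0]


def test_unwrap_static_atom_unchanged():
    traj = _traj_from_z([5.0] * 6)
    z, bad = mx.unwrap_z(traj, np.array([0]))
    np.testing.assert_allclose(z[:, 0], 5.0)
    assert not bad[0]


def test_unwrap_flags_untrackable_jump():
    traj = _traj_from_z([2.0, 8.0])  # 6 nm jump in a 10 nm box: ambiguous
    _, bad = mx.unwrap_z(traj, np.array([0]))
    assert bad[0]


def _ref(mid=7.0, thick=4.0, frac=0.65):
    half = 0.5 * frac * thick
    return mx.MembraneFrameRef(midplane_z=mid, thickness=thick,
                               slab_lo=mid - half, slab_hi=mid + half,
                               leaflet_of_lipid={}, slab_fraction=frac)


def _water_traj(z_path, box_z=14.0):
    """One-water trajectory plus a refs list with fixed slab [5.7, 8.3]."""
    tmpl = mx.LipidTemplate(residue_name="LIP", phosphate_atom="P",
                            glycerol_central_atom="C2",
                            sn1_carbons=("A1",), sn2_carbons=("B1",))
    atoms = [mx.Atom(1, "P", "LIP", 1, "P"), mx.Atom(2, "C2", "LIP", 1, "C"),
             mx.Atom(3, "A1", "LIP", 1, "C"), mx.Atom(4, "B1", "LIP", 1, "C"),
             mx.Atom(5, "OW", "SOL", 2, "O")]
    topo = mx.apply_lipid_templates(atoms, [tmpl])
    frames = []
    for t, z in enumerate(z_path):
        c = np.array([[1, 1, 9.0], [1, 1, 8.8], [1, 1, 8.5], [1, 1, 8.4],
                      [1.0, 1.0, z]])
        frames.append(mx.Frame(t * 10.0, np.array([5.0, 5.0, box_z]), c))
    traj = mx.Trajectory(frames)
    refs = [_ref() for _ in frames]
    return traj, refs, topo


def test_crossing_detected_with_entry_and_exit_sides():
    z = [10.0, 9.0] + list(np.linspace(8.2, 5.8, 5)) + [5.0, 4.0]
    traj, refs, topo = _water_traj(z)
    recs = mx.detect_permeation_events(traj, refs, topo)
    assert len(recs) == 1
    r = recs[0]
    assert (r.event_class, r.entry_side, r.exit_side) == ("crossing", "upper", "lower")
    assert r.t_entry == pytest.approx(20.0)
    assert r.t_exit == pytest.approx(60.0)


def test_rebound_detected():
    z = [10.0, 8.2, 7.5, 8.2, 10.0]
    traj, refs, topo = _water_traj(z)
    recs = mx.detect_permeation_events(traj, refs, topo)
    assert len(recs) == 1
    assert recs[0].event_class == "rebound"
    assert recs[0].entry_side == recs[0].exit_side == "upper"


def test_bulk_oscillation_yields_no_records():
    z = [10.0, 12.0, 9.0, 11.0, 10.5]
    traj, refs, topo = _water_traj(z)
    assert mx.detect_permeation_events(traj, refs, topo) == []


def test_water_inside_at_final_frame_is_unresolved():
    z = [10.0, 9.0, 8.2, 7.0]
    traj, refs, topo = _water_traj(z)
    recs = mx.detect_permeation_events(traj, refs, topo)
    assert len(recs) == 1
    assert recs[0].event_class == "unresolved"
    assert recs[0].exit_side == "none"


def test_reentrant_visits_give_separate_records():
    z = [10.0, 8.0, 10.0, 8.0, 10.0]
    traj, refs, topo = _water_traj(z)
    recs = mx.detect_permeation_events(traj, refs, topo)
    assert len(recs) == 2
    assert all(r.event_class == "rebound" for r in recs)


def _rec(w, t_entry, cls):
    return PermeationRecord(water_id=w, t_entry=t_entry, t_exit=t_entry + 10,
                            entry_side="upper",
                            exit_side="lower" if cls == "crossing" else
                            ("upper" if cls == "rebound" else "none"),
                            event_class=cls)


def test_summary_percent_visiting_arithmetic():
    """5 crossings + 3 rebounds by 8 distinct waters out of 1000 → 0.8%."""
    recs = [_rec(w, 1000.0 * w + 5, "crossing") for w in range(5)]
    recs += [_rec(100 + w, 1000.0 * w + 7, "rebound") for w in range(3)]
    s = mx.permeation_summary(recs, n_waters=1000, duration=100.0,
                              block_length=100.0)
    assert len(s.per_block) == 1
    assert s.percent_visiting_mean == pytest.approx(0.8)
    assert s.crossings_mean == 5
    assert s.rebounds_mean == 3


def test_summary_empty_records():
    s = mx.permeation_summary([], n_waters=100, duration=100.0)
    assert s.percent_visiting_mean == 0.0
    assert s.percent_visiting_sd == 0.0


def test_summary_three_blocks_and_discard():
    """300 ns at 100 ns blocks → 3 per-block values; SD over the 3."""
    recs = [_rec(w, (50 + 100 * b) * 1000.0, "crossing")
            for b, n in ((0, 3), (1, 2), (2, 1)) for w in range(n)]
    s = mx.permeation_summary(recs, n_waters=100, duration=300.0,
                              block_length=100.0)
    assert list(s.per_block["crossings"]) == [3, 2, 1]
    assert s.crossings_sd == pytest.approx(np.std([3, 2, 1], ddof=1))
    s2 = mx.permeation_summary(recs, n_waters=100, duration=400.0,
                               block_length=100.0, discard=100.0)
    assert list(s2.per_block["crossings"]) == [2, 1, 0]


def test_summary_zero_blocks_is_error():
    with pytest.raises(ValueError, match="zero blocks"):
        mx.permeation_summary([], n_waters=10, duration=50.0, block_length=100.0)


def test_distinct_molecule_counting():
    """A water visiting twice in one block counts once for percent_visiting."""
    recs = [_rec(1, 5000.0, "rebound"), _rec(1, 9000.0, "rebound")]
    s = mx.permeation_summary(recs, n_waters=100, duration=100.0)
    assert s.percent_visiting_mean == pytest.approx(1.0)
    assert s.rebounds_mean == 2


def test_pipeline_recovers_planted_events_and_is_relabel_invariant():
    cfg = mx.GeneratorConfig.preset_small(seed=42, n_cross=4, n_rebound=2,
                                          n_frames=600, n_waters=100)
    topo, traj, truth = mx.make_bilayer_trajectory(cfg)
    refs = mx.trajectory_references(traj, topo)
    recs = mx.detect_permeation_events(traj, refs, topo)
    assert sum(r.event_class == "crossing" for r in recs) == 4
    assert sum(r.event_class == "rebound" for r in recs) == 2
    # record-for-record against planted truth (entry frame and sides)
    planted = {(e["water_index"], e["entry_frame"], e["event_class"],
                e["entry_side"], e["exit_side"]) for e in truth.permeation_events}
    dt = traj.dt
    detected = {(r.water_id, int(round(r.t_entry / dt)), r.event_class,
                 r.entry_side, r.exit_side) for r in recs}
    assert planted == detected
    # joint rigid z-shift of coordinates and refs leaves counts unchanged
    for fr in traj.frames:
        fr.coords[:, 2] += 0.37
    refs2 = [mx.MembraneFrameRef(r.midplane_z + 0.37, r.thickness,
                                 r.slab_lo + 0.37, r.slab_hi + 0.37,
                                 r.leaflet_of_lipid, r.slab_fraction)
             for r in refs]
    recs2 = mx.detect_permeation_events(traj, refs2, topo)
    assert {(r.water_id, r.event_class) for r in recs2} == \
        {(r.water_id, r.event_class) for r in recs}


def test_shrinking_slab_weakly_decreases_visits():
    cfg = mx.GeneratorConfig.preset_small(seed=9, n_cross=3, n_rebound=3,
                                          n_frames=500, n_waters=60)
    topo, traj, _ = mx.make_bilayer_trajectory(cfg)
    counts = []
    for frac in (0.9, 0.65, 0.4, 0.2):
        refs = mx.trajectory_references(traj, topo, slab_fraction=frac)
        counts.append(len(mx.detect_permeation_events(traj, refs, topo)))
    assert all(a >= b for a, b in zip(counts, counts[1:]))
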