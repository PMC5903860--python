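"""Terminal-CH3 velocities, 3-point torsion statistics and protrusions."""

import numpy as np
import pytest

import memflex as mx
from memflex.chain_dynamics import triplet_angles


def test_constant_step_velocity_is_analytic():
    """+0.01 nm in z per 10 ps frame → exactly 1.0 nm/ns."""
    cfg = mx.GeneratorConfig.preset_small(seed=0, n_frames=100, n_waters=10,
                                          ch3_step_z=0.01)
    topo, traj, _ = mx.make_bilayer_trajectory(cfg)
    vel = mx.terminal_velocity(traj, topo, step=10.0)
    assert vel["sn2"].velocity_z == pytest.approx(1.0)
    assert vel["sn2"].velocity_xy == pytest.approx(0.0)


def test_stationary_chain_has_zero_velocity():
    cfg = mx.GeneratorConfig.preset_small(seed=0, n_frames=50, n_waters=10)
    topo, traj, _ = mx.make_bilayer_trajectory(cfg)
    vel = mx.terminal_velocity(traj, topo)
    for label in ("sn1", "sn2"):
        assert vel[label].velocity_z == 0.0
        assert vel[label].velocity_xy == 0.0


def test_random_walk_velocity_matches_planted_mean():
    """Gaussian steps of SD σ per frame: mean |Δz| = σ√(2/π); recovered
    within 3 standard errors over the planted ensemble."""
    sigma = 0.02
    cfg = mx.GeneratorConfig.preset_small(seed=12, n_frames=400, n_waters=10,
                                          ch3_sigma_z=sigma, ch3_sigma_xy=0.015)
    topo, traj, truth = mx.make_bilayer_trajectory(cfg)
    vel = mx.terminal_velocity(traj, topo, step=10.0)
    n_samples = (len(traj) - 1) * len(topo.lipids)
    mu = truth.chain_motion["mean_abs_dz"]            # nm per step
    se = sigma * np.sqrt(1 - 2 / np.pi) / np.sqrt(n_samples)
    expected = mu / 10.0 * 1000.0                     # nm/ns
    tol = 3 * se / 10.0 * 1000.0
    assert abs(vel["sn2"].velocity_z - expected) < tol
    mu_xy = truth.chain_motion["mean_step_xy"]
    assert vel["sn2"].velocity_xy == pytest.approx(mu_xy / 10.0 * 1000.0, rel=0.05)


def test_velocity_invariances():
    cfg = mx.GeneratorConfig.preset_small(seed=5, n_frames=60, n_waters=10,
                                          ch3_sigma_z=0.02, ch3_sigma_xy=0.02)
    topo, traj, _ = mx.make_bilayer_trajectory(cfg)
    v0 = mx.terminal_velocity(traj, topo)
    # global translation
    for fr in traj.frames:
        fr.coords += np.array([0.3, -0.2, 0.5])
    v1 = mx.terminal_velocity(traj, topo)
    assert v1["sn2"].velocity_z == pytest.approx(v0["sn2"].velocity_z)
    assert v1["sn2"].velocity_xy == pytest.approx(v0["sn2"].velocity_xy)
    # rotation about z preserves the in-plane Euclidean step
    th = 0.7
    rot = np.array([[np.cos(th), -np.sin(th), 0],
                    [np.sin(th), np.cos(th), 0], [0, 0, 1]])
    for fr in traj.frames:
        fr.coords = fr.coords @ rot.T
        fr.box = np.array([50.0, 50.0, fr.box[2]])  # avoid wrap after rotation
    v2 = mx.terminal_velocity(traj, topo)
    assert v2["sn2"].velocity_xy == pytest.approx(v0["sn2"].velocity_xy, rel=1e-6)


def test_step_smaller_than_dt_rejected():
    cfg = mx.GeneratorConfig.preset_small(seed=0, n_frames=5, n_waters=5)
    topo, traj, _ = mx.make_bilayer_trajectory(cfg)
    with pytest.raises(ValueError, match="step"):
        mx.terminal_velocity(traj, topo, step=5.0)


def test_straight_chains_have_zero_torsions():
    cfg = mx.GeneratorConfig.preset_small(seed=0, n_frames=5, n_waters=5)
    topo, traj, _ = mx.make_bilayer_trajectory(cfg)
    tor = mx.torsion_frequency(traj, topo)
    assert tor["sn1"].frequency == 0.0
    assert tor["sn2"].frequency == 0.0


def test_planted_bends_counted_once_each():
    """Chains carrying two 60° bends: frequency exactly 2 per chain per
    frame; sn1 chains stay straight."""
    cfg = mx.GeneratorConfig.preset_small(seed=3, n_frames=10, n_waters=5,
                                          bend_count=2, bend_angle=60.0)
    topo, traj, truth = mx.make_bilayer_trajectory(cfg)
    tor = mx.torsion_frequency(traj, topo)
    assert tor["sn2"].frequency == pytest.approx(2.0)
    assert tor["sn1"].frequency == 0.0
    # brute-force per-triplet oracle on the planted geometry
    fr = traj.frames[0]
    chain = topo.lipids[0].sn2
    expected = 0
    for n in range(2, len(chain) - 2):
        a = fr.coords[chain[n - 2]] - fr.coords[chain[n]]
        b = fr.coords[chain[n + 2]] - fr.coords[chain[n]]
        ang = np.degrees(np.arccos(
            np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))))
        if ang < 100.0:
            expected += 1
    assert expected == 2


def test_threshold_is_strict():
    """A planted bend angle equal to the threshold is not counted."""
    cfg = mx.GeneratorConfig.preset_small(seed=3, n_frames=3, n_waters=5,
                                          bend_count=1, bend_angle=60.0)
    topo, traj, _ = mx.make_bilayer_trajectory(cfg)
    chain = topo.lipids[0].sn2
    angles = triplet_angles(traj.frames[0].coords, chain)
    planted = angles.min()
    at_threshold = mx.torsion_frequency(traj, topo, angle_threshold=planted)
    below = mx.torsion_frequency(traj, topo, angle_threshold=planted + 1e-6)
    assert at_threshold["sn2"].frequency == 0.0
    assert below["sn2"].frequency == pytest.approx(1.0)


def test_short_chains_are_excluded():
    tmpl = mx.LipidTemplate(residue_name="LIP", phosphate_atom="P",
                            glycerol_central_atom="C2",
                            sn1_carbons=("A1", "A2", "A3"),
                            sn2_carbons=("B1", "B2", "B3", "B4", "B5"))
    atoms, coords = [], []
    for k, name in enumerate(["P", "C2", "A1", "A2", "A3",
                              "B1", "B2", "B3", "B4", "B5"]):
        atoms.append(mx.Atom(k + 1, name, "LIP", 1, name[0]))
        coords.append([1.0, 1.0, 5.0 - 0.1 * k])
    traj = mx.Trajectory([mx.Frame(0.0, np.array([5, 5, 10.0]),
                                   np.array(coords))])
    topo = mx.apply_lipid_templates(atoms, [tmpl])
    tor = mx.torsion_frequency(traj, topo)
    assert "sn1" not in tor          # 3 carbons: no triplet
    assert tor["sn2"].frequency == 0.0


def test_protrusion_square_wave_counts_up_transitions():
    """A square wave taking the terminal above glycerol n times yields
    exactly n up-transition events; the planted schedule is the oracle."""
    cfg = mx.GeneratorConfig.preset_small(seed=2, n_frames=400, n_waters=5,
                                          protrusion_period=100)
    topo, traj, truth = mx.make_bilayer_trajectory(cfg)
    refs = mx.trajectory_references(traj, topo)
    pro = mx.protrusion_count(traj, topo, refs)
    assert pro["sn2"].events_per_chain_per_block == pytest.approx(
        truth.protrusion["events_per_chain"])
    assert pro["sn1"].events_per_chain_per_block == 0.0


def test_terminal_below_glycerol_never_protrudes():
    cfg = mx.GeneratorConfig.preset_small(seed=2, n_frames=50, n_waters=5)
    topo, traj, _ = mx.make_bilayer_trajectory(cfg)
    refs = mx.trajectory_references(traj, topo)
    pro = mx.protrusion_count(traj, topo, refs)
    assert pro["sn1"].events_per_chain_per_block == 0.0
    assert pro["sn2"].events_per_chain_per_block == 0.0


def test_lower_leaflet_outward_sign_convention():
    """Lower-leaflet terminal below its glycerol counts as protruded."""
    cfg = mx.GeneratorConfig.preset_small(seed=2, n_frames=4, n_waters=5)
    topo, traj, _ = mx.make_bilayer_trajectory(cfg)
    refs = mx.trajectory_references(traj, topo)
    lower = [i for i, lf in refs[0].leaflet_of_lipid.items() if lf == "lower"]
    lip = topo.lipids[lower[0]]
    z_gly = traj.frames[0].coords[lip.glycerol, 2]
    for t, fr in enumerate(traj.frames):
        # outward (below glycerol) on odd frames only: 2 up-transitions
        fr.coords[lip.sn2_terminal, 2] = z_gly - 0.2 if t % 2 else z_gly + 0.1
    pro = mx.protrusion_count(traj, topo, refs)
    n_lower_events = 2 / len(topo.lipids)  # averaged over all sn2 chains
    assert pro["sn2"].events_per_chain_per_block == pytest.approx(n_lower_events)
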