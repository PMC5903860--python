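"""Acyl-chain dynamics metrics: terminal-CH3 velocity, torsion frequency and
protrusion counts, reported per chain position (sn1 vs sn2).

*Velocity* is the sum of distances travelled by each terminal methyl (or
terminal tail bead) over fixed 10 ps steps, divided by total time — reported
separately along the membrane normal (z) and in-plane (Euclidean x-y step
length, with per-axis sums also emitted).

*Torsion* here is a 3-point bend, not a 4-atom dihedral: at each interior
carbon n the angle subtended by carbons n−2 and n+2 is computed, and a
torsion is scored when that angle falls strictly below 100°.

*Protrusion* is an excursion of a chain's terminal carbon outward past its
own lipid's central glycerol carbon along the leaflet normal; an event is
a transition from non-protruded to protruded between consecutive frames,
counted per 100 ns block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .membrane_geometry import MembraneFrameRef
from .traj_io import AnnotatedTopology, Trajectory

logger = logging.getLogger(__name__)

PS_PER_NS = 1000.0
DEFAULT_TORSION_DEG = 100.0


@dataclass
class ChainVelocity:
    chain_label: str
    velocity_z: float    # nm/ns, mean over chains
    velocity_xy: float   # nm/ns, in-plane Euclidean
    velocity_x: float    # nm/ns, per-axis sum of |dx|
    velocity_y: float
    per_chain_z: np.ndarray = field(repr=False, default=None)
    per_chain_xy: np.ndarray = field(repr=False, default=None)


@dataclass
class TorsionResult:
    chain_label: str
    frequency: float              # torsions per chain per frame
    block_means: np.ndarray
    block_sd: float
    angle_threshold: float


@dataclass
class ProtrusionResult:
    chain_label: str
    events_per_chain_per_block: float   # mean over blocks
    block_values: np.ndarray            # per-block events per chain
    block_sd: float


@dataclass
class ChainDynamicsSummary:
    chain_label: str
    velocity_z: float
    velocity_xy: float
    torsion_frequency: float
    torsion_sd: float
    protrusions_per_block: float
    protrusion_sd: float


def _chains(topo: AnnotatedTopology, label: str) -> list[list[int]]:
    return [lip.sn1 if label == "sn1" else lip.sn2 for lip in topo.lipids]


def _block_slices(traj: Trajectory, block_ns: float) -> list[slice]:
    """Partition frames into full blocks of ``block_ns``; when the trajectory
    is shorter than one block, everything forms a single block."""
    if traj.dt is None:
        return [slice(0, len(traj))]
    frames_per_block = int(round(block_ns * PS_PER_NS / traj.dt))
    n_blocks = len(traj) // frames_per_block if frames_per_block > 0 else 0
    if n_blocks < 1:
        return [slice(0, len(traj))]
    return [slice(b * frames_per_block, (b + 1) * frames_per_block)
            for b in range(n_blocks)]


def _sample_sd(v: np.ndarray) -> float:
    return float(np.std(v, ddof=1)) if len(v) > 1 else 0.0


# ---------------------------------------------------------------------------
# terminal velocity
# ---------------------------------------------------------------------------

def terminal_velocity(traj: Trajectory, topo: AnnotatedTopology,
                      step: float = 10.0,
                      max_step_fraction: float = 0.25) -> dict[str, ChainVelocity]:
    """Terminal-carbon velocity rates per chain label.

    Displacements are taken over ``step`` ps intervals (default 10 ps) with
    per-axis minimum-image correction.  ``velocity_z = Σ|Δz| / total time``
    and ``velocity_xy = Σ√(Δx²+Δy²) / total time`` in nm/ns, averaged over
    chains of the same label.  Intervals whose corrected displacement on any
    axis reaches ``max_step_fraction × box`` are skipped (logged).
    """
    dt = traj.dt
    if dt is None:
        raise ValueError("velocity needs a multi-frame trajectory")
    if step < dt:
        raise ValueError(f"step {step} ps < trajectory dt {dt} ps")
    stride = int(round(step / dt))
    if abs(stride * dt - step) > 1e-6 * step:
        raise ValueError(f"step {step} ps is not a multiple of dt {dt} ps")

    out: dict[str, ChainVelocity] = {}
    for label in ("sn1", "sn2"):
        term = np.array([ch[-1] for ch in _chains(topo, label)])
        if term.size == 0:
            continue
        pos = np.stack([fr.coords[term] for fr in traj.frames[::stride]])  # (T, C, 3)
        boxes = np.stack([fr.box for fr in traj.frames[::stride]])
        disp = pos[1:] - pos[:-1]
        disp -= boxes[1:, None, :] * np.round(disp / boxes[1:, None, :])
        bad = (np.abs(disp) >= max_step_fraction * boxes[1:, None, :]).any(axis=2)
        if bad.any():
            logger.warning("%s: %d chain-interval(s) untrackable, skipped",
                           label, int(bad.sum()))
        disp = np.where(bad[:, :, None], np.nan, disp)
        n_used = np.sum(~bad, axis=0)  # per chain
        total_ns = n_used * step / PS_PER_NS
        with np.errstate(invalid="ignore", divide="ignore"):
            vz = np.nansum(np.abs(disp[:, :, 2]), axis=0) / total_ns
            vxy = np.nansum(np.hypot(disp[:, :, 0], disp[:, :, 1]), axis=0) / total_ns
            vx = np.nansum(np.abs(disp[:, :, 0]), axis=0) / total_ns
            vy = np.nansum(np.abs(disp[:, :, 1]), axis=0) / total_ns
        out[label] = ChainVelocity(
            chain_label=label,
            velocity_z=float(np.nanmean(vz)), velocity_xy=float(np.nanmean(vxy)),
            velocity_x=float(np.nanmean(vx)), velocity_y=float(np.nanmean(vy)),
            per_chain_z=vz, per_chain_xy=vxy)
    return out


# ---------------------------------------------------------------------------
# torsions
# ---------------------------------------------------------------------------

def triplet_angles(coords: np.ndarray, chain: list[int]) -> np.ndarray:
    """Angles (degrees) at each interior carbon n of one chain, subtended by
    carbons n−2 and n+2 (vertex at n); length = len(chain) − 4."""
    p = coords[np.asarray(chain)]
    v1 = p[:-4] - p[2:-2]
    v2 = p[4:] - p[2:-2]
    cosang = np.einsum("ij,ij->i", v1, v2) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def torsion_frequency(traj: Trajectory, topo: AnnotatedTopology,
                      angle_threshold: float = DEFAULT_TORSION_DEG,
                      block_ns: float = 100.0) -> dict[str, TorsionResult]:
    """Torsion frequency (bends with angle strictly below ``angle_threshold``
    degrees) per chain per frame, averaged within frames over chains then
    over frames; SD over blocks.  Chains shorter than 5 carbons are excluded.
    """
    out: dict[str, TorsionResult] = {}
    blocks = _block_slices(traj, block_ns)
    for label in ("sn1", "sn2"):
        chains = [ch for ch in _chains(topo, label) if len(ch) >= 5]
        skipped = sum(1 for ch in _chains(topo, label) if len(ch) < 5)
        if skipped:
            logger.warning("%s: %d chain(s) shorter than 5 carbons excluded",
                           label, skipped)
        if not chains:
            continue
        idx = np.array(chains)  # (C, L), equal lengths per label
        per_frame = np.empty(len(traj))
        for t, fr in enumerate(traj.frames):
            p = fr.coords[idx]                       # (C, L, 3)
            v1 = p[:, :-4] - p[:, 2:-2]
            v2 = p[:, 4:] - p[:, 2:-2]
            cosang = np.einsum("cij,cij->ci", v1, v2) / (
                np.linalg.norm(v1, axis=2) * np.linalg.norm(v2, axis=2))
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            per_frame[t] = np.mean(np.sum(ang < angle_threshold, axis=1))
        block_means = np.array([per_frame[s].mean() for s in blocks])
        out[label] = TorsionResult(
            chain_label=label, frequency=float(per_frame.mean()),
            block_means=block_means, block_sd=_sample_sd(block_means),
            angle_threshold=angle_threshold)
    return out


# ---------------------------------------------------------------------------
# protrusions
# ---------------------------------------------------------------------------

def protrusion_count(traj: Trajectory, topo: AnnotatedTopology,
                     refs: list[MembraneFrameRef],
                     block_ns: float = 100.0,
                     hysteresis: float = 0.0) -> dict[str, ProtrusionResult]:
    """Protrusion events of the terminal carbon past its own lipid's glycerol
    central carbon, along the leaflet outward normal.

    A chain is protruded when its terminal z is outward of glycerol z (upper
    leaflet: above; lower leaflet: below); an event is a non-protruded →
    protruded transition between consecutive frames.  ``hysteresis`` (nm)
    requires the terminal to retreat that far inward before a new event can
    be scored (default 0: every crossing counts).
    """
    if len(refs) != len(traj):
        raise ValueError("refs must match the trajectory frame for frame")
    blocks = _block_slices(traj, block_ns)
    out: dict[str, ProtrusionResult] = {}
    for label in ("sn1", "sn2"):
        term = np.array([(lip.sn1 if label == "sn1" else lip.sn2)[-1]
                         for lip in topo.lipids])
        gly = np.array([lip.glycerol for lip in topo.lipids])
        if term.size == 0:
            continue
        # outward signed excursion: positive when terminal is beyond glycerol
        exc = np.empty((len(traj), term.size))
        for t, (fr, ref) in enumerate(zip(traj.frames, refs)):
            sign = np.array([1.0 if ref.leaflet_of_lipid[i] == "upper" else -1.0
                             for i in range(len(topo.lipids))])
            exc[t] = sign * (fr.coords[term, 2] - fr.coords[gly, 2])
        events = np.zeros((len(blocks), term.size))
        armed = np.ones(term.size, dtype=bool)  # may fire on next protrusion
        prot_prev = exc[0] > 0
        armed &= ~prot_prev
        for t in range(1, len(traj)):
            prot = exc[t] > 0
            fire = prot & ~prot_prev & armed if hysteresis > 0 else prot & ~prot_prev
            b = next(i for i, s in enumerate(blocks)
                     if s.start <= t < s.stop or s is blocks[-1])
            events[b] += fire
            if hysteresis > 0:
                armed = np.where(exc[t] < -hysteresis, True,
                                 np.where(prot, False, armed))
            prot_prev = prot
        per_block = events.mean(axis=1)  # events per chain per block
        out[label] = ProtrusionResult(
            chain_label=label,
            events_per_chain_per_block=float(per_block.mean()),
            block_values=per_block, block_sd=_sample_sd(per_block))
    return out


def summarize_chain_dynamics(traj: Trajectory, topo: AnnotatedTopology,
                             refs: list[MembraneFrameRef],
                             step: float = 10.0,
                             angle_threshold: float = DEFAULT_TORSION_DEG,
                             block_ns: float = 100.0) -> list[ChainDynamicsSummary]:
    """Convenience wrapper producing one summary per chain label."""
    vel = terminal_velocity(traj, topo, step=step)
    tor = torsion_frequency(traj, topo, angle_threshold=angle_threshold,
                            block_ns=block_ns)
    pro = protrusion_count(traj, topo, refs, block_ns=block_ns)
    return [
        ChainDynamicsSummary(
            chain_label=label,
            velocity_z=vel[label].velocity_z,
            velocity_xy=vel[label].velocity_xy,
            torsion_frequency=tor[label].frequency,
            torsion_sd=tor[label].block_sd,
            protrusions_per_block=pro[label].events_per_chain_per_block,
            protrusion_sd=pro[label].block_sd,
        )
        for label in ("sn1", "sn2") if label in vel
    ]
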