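"""Water permeation event detection and classification.

A *visit* is a maximal contiguous run of frames in which a water oxygen sits
strictly inside the hydrophobic slab (the central band spanning 65% of the
bilayer thickness by default).  Each visit is classified as a *crossing*
(exit on the opposite side from entry), a *rebound* (exit on the entry
side) or *unresolved* (the trajectory ends with the water still inside).
Visit statistics are aggregated over time blocks (default 100 ns) and
normalised to the total number of water molecules in the system.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .membrane_geometry import MembraneFrameRef
from .traj_io import AnnotatedTopology, Trajectory

logger = logging.getLogger(__name__)

PS_PER_NS = 1000.0


@dataclass
class PermeationRecord:
    water_id: int           # topology atom index of the water oxygen
    t_entry: float          # ps (first frame inside the slab)
    t_exit: float           # ps (last frame inside the slab)
    entry_side: str         # "upper" | "lower"
    exit_side: str          # "upper" | "lower" | "none"
    event_class: str        # "crossing" | "rebound" | "unresolved"

    def __post_init__(self):
        if self.t_exit < self.t_entry:
            raise ValueError("t_exit must be >= t_entry")


@dataclass
class PermeationSummary:
    block_length: float                 # ns
    per_block: pd.DataFrame             # block, crossings, rebounds, unresolved,
                                        # distinct_waters, percent_visiting
    percent_visiting_mean: float
    percent_visiting_sd: float
    crossings_mean: float
    crossings_sd: float
    rebounds_mean: float
    rebounds_sd: float
    n_waters: int
    extras: dict = field(default_factory=dict)


def unwrap_z(traj: Trajectory, atom_idx: np.ndarray,
             max_step_fraction: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Remove periodic z-jumps from per-atom z paths.

    Successive displacements are minimum-image corrected against the
    per-frame box height.  Atoms whose corrected per-frame displacement ever
    reaches ``max_step_fraction × box_z`` cannot be tracked unambiguously
    (the frame spacing is too coarse relative to their motion) and are
    flagged.

    Returns ``(z, untrackable)`` with ``z`` of shape (n_frames, n_atoms) and
    ``untrackable`` a boolean mask per atom.
    """
    atom_idx = np.asarray(atom_idx)
    n_frames = len(traj)
    z = np.empty((n_frames, len(atom_idx)))
    z[0] = traj.frames[0].coords[atom_idx, 2]
    untrackable = np.zeros(len(atom_idx), dtype=bool)
    for t in range(1, n_frames):
        box_z = traj.frames[t].box[2]
        raw = traj.frames[t].coords[atom_idx, 2]
        dz = raw - (z[t - 1] % box_z)
        dz -= box_z * np.round(dz / box_z)
        bad = np.abs(dz) >= max_step_fraction * box_z
        if bad.any() and not untrackable[bad].all():
            logger.warning("frame %d: %d atom(s) moved >= %.2f x box_z in z; "
                           "flagged untrackable", t, int(bad.sum()),
                           max_step_fraction)
        untrackable |= bad
        z[t] = z[t - 1] + dz
    return z, untrackable


def detect_permeation_events(traj: Trajectory,
                             refs: list[MembraneFrameRef],
                             topo: AnnotatedTopology) -> list[PermeationRecord]:
    """Detect slab visits of every water oxygen and classify them.

    Slab membership and sides are evaluated on midplane-relative,
    minimum-image wrapped z, using the per-frame slab bounds in ``refs``.
    A water inside the slab at frame 0 has no observable entry side: if the
    visit ends with an exit it is scored as a rebound from the exit side
    (logged); if it never exits it is unresolved.
    """
    if len(refs) != len(traj):
        raise ValueError("refs must be computed on the same trajectory")
    water_idx = np.array(topo.water_oxygens)
    if water_idx.size == 0:
        return []
    n_frames = len(traj)
    # midplane-relative wrapped z, (n_frames, n_waters)
    dz = np.empty((n_frames, water_idx.size))
    half = np.empty(n_frames)
    for t, (fr, ref) in enumerate(zip(traj.frames, refs)):
        d = fr.coords[water_idx, 2] - ref.midplane_z
        box_z = fr.box[2]
        dz[t] = d - box_z * np.round(d / box_z)
        half[t] = 0.5 * ref.slab_width
    inside = np.abs(dz) < half[:, None]  # strict: slab_lo < z < slab_hi
    side = np.where(dz > 0, "upper", "lower")

    times = traj.times
    records: list[PermeationRecord] = []
    for w in range(water_idx.size):
        col = inside[:, w]
        if not col.any():
            continue
        # maximal runs of True
        padded = np.concatenate(([False], col, [False]))
        starts = np.flatnonzero(padded[1:] & ~padded[:-1])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])  # exclusive
        for s, e in zip(starts, ends):
            exit_side = side[e, w] if e < n_frames else "none"
            if s > 0:
                entry_side = side[s - 1, w]
            elif exit_side != "none":
                entry_side = exit_side  # rebound-consistent inference
                logger.warning("water %d inside slab at frame 0; entry side "
                               "inferred from exit", int(water_idx[w]))
            else:
                entry_side = side[0, w]
                logger.warning("water %d inside slab for the whole trajectory; "
                               "unresolved", int(water_idx[w]))
            if exit_side == "none":
                cls = "unresolved"
            elif exit_side == entry_side:
                cls = "rebound"
            else:
                cls = "crossing"
            records.append(PermeationRecord(
                water_id=int(water_idx[w]),
                t_entry=float(times[s]), t_exit=float(times[e - 1]),
                entry_side=str(entry_side), exit_side=str(exit_side),
                event_class=cls))
    return records


def permeation_summary(records: list[PermeationRecord], n_waters: int,
                       duration: float, block_length: float = 100.0,
                       discard: float = 0.0) -> PermeationSummary:
    """Aggregate permeation records into per-block statistics.

    ``duration``, ``block_length`` and ``discard`` are in ns.  Events are
    assigned to blocks by entry time; events entering before ``discard`` are
    dropped (equilibration).  ``percent_visiting`` counts distinct water
    molecules with at least one visit in the block, as a percentage of
    ``n_waters``; the crossing/rebound tallies count events.  The standard
    deviation is the sample SD over blocks (0 for a single block).
    """
    if n_waters <= 0:
        raise ValueError("n_waters must be > 0")
    usable = duration - discard
    n_blocks = int(np.floor(usable / block_length + 1e-9))
    if n_blocks < 1:
        raise ValueError(
            f"zero blocks: usable duration {usable} ns < block {block_length} ns")
    rows = []
    for b in range(n_blocks):
        lo = discard + b * block_length
        hi = lo + block_length
        in_block = [r for r in records
                    if lo <= r.t_entry / PS_PER_NS < hi]
        distinct = len({r.water_id for r in in_block})
        rows.append({
            "block": b,
            "t_start_ns": lo,
            "crossings": sum(r.event_class == "crossing" for r in in_block),
            "rebounds": sum(r.event_class == "rebound" for r in in_block),
            "unresolved": sum(r.event_class == "unresolved" for r in in_block),
            "distinct_waters": distinct,
            "percent_visiting": 100.0 * distinct / n_waters,
        })
    df = pd.DataFrame(rows)

    def stat(col):
        v = df[col].to_numpy(dtype=float)
        return float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0

    pv_m, pv_s = stat("percent_visiting")
    cr_m, cr_s = stat("crossings")
    rb_m, rb_s = stat("rebounds")
    return PermeationSummary(
        block_length=block_length, per_block=df,
        percent_visiting_mean=pv_m, percent_visiting_sd=pv_s,
        crossings_mean=cr_m, crossings_sd=cr_s,
        rebounds_mean=rb_m, rebounds_sd=rb_s,
        n_waters=n_waters,
        extras={"n_events": len(records)})
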