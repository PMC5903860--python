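"""Synthetic fixtures with planted, machine-readable ground truth.

Three generators cover the three kinds of input the analysis modules
consume:

* :func:`make_bilayer_trajectory` — an idealized planar bilayer (two leaflets
  of rigid lipids around a midplane, aqueous slabs above and below) in which
  designated waters follow scripted z-paths realizing an exact number of
  slab crossings and rebounds, and designated acyl chains follow scripted
  terminal-carbon motion (Gaussian or constant steps), planted bend-angle
  schedules and protrusion square waves;
* :func:`make_tube_frame` — a coarse-grained flat bilayer carrying a
  cylindrical tube of known midsurface radius and length, optionally severed
  at mid-tube or with its pulled patch detached;
* :func:`make_assay_series` — quenching, GUV and GTPase traces with known
  underlying parameters.

These are fixture generators, not simulators: no forces are computed, lipids
are rigid except where scripted, and background waters perform bounded random
walks that never enter the hydrophobic slab.  Exact planted event counts are
deliberately favoured over physical realism so that every analysis operation
has a predictable answer.  All generators are pure functions of their
configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .traj_io import (AnnotatedTopology, Atom, Frame, LipidTemplate,
                      Trajectory, apply_lipid_templates)


@dataclass
class GroundTruth:
    """Planted truth serialized alongside every generated dataset."""
    permeation_events: list[dict] = field(default_factory=list)
    n_cross: int = 0
    n_rebound: int = 0
    chain_motion: dict = field(default_factory=dict)
    torsion: dict = field(default_factory=dict)
    protrusion: dict = field(default_factory=dict)
    tube: dict = field(default_factory=dict)
    defects: dict = field(default_factory=dict)
    assay: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=float))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class GeneratorConfig:
    """Bilayer-trajectory generator settings.

    Defaults emulate the all-atom study system: a 2 × 144-phospholipid patch
    (saturated 18-carbon sn1 chain, polyunsaturated-length 22-carbon sn2
    chain), 4 nm phosphate-to-phosphate thickness, ~30 waters per lipid,
    frames every 10 ps.  ``preset_small`` (2 × 16 lipids) keeps test
    fixtures fast.
    """
    n_lipids_per_leaflet: int = 144
    sn1_length: int = 18
    sn2_length: int = 22
    n_waters: int = 8640
    box_z: float = 14.0
    thickness: float = 4.0
    area_per_lipid: float = 0.64   # nm²
    n_frames: int = 1000
    dt: float = 10.0               # ps
    seed: int = 0
    slab_fraction: float = 0.65
    # planted permeation events
    n_cross: int = 0
    n_rebound: int = 0
    event_duration_frames: int = 20
    # scripted terminal-carbon motion on sn2 chains
    ch3_sigma_z: float = 0.0       # nm, Gaussian step SD per frame (0 = off)
    ch3_sigma_xy: float = 0.0
    ch3_step_z: float = 0.0        # nm, constant +z step per frame (0 = off)
    ch3_step_xy: float = 0.0
    # planted torsion bends on sn2 chains (constant over frames)
    bend_count: int = 0
    bend_angle: float = 60.0       # degrees; keep within (40, 100) so the
                                   # flanking angles stay above 100°
    # protrusion square wave on sn2 chains
    protrusion_period: int = 0     # frames per full cycle (0 = off)
    water_jitter: float = 0.02     # nm, background water step SD

    @classmethod
    def preset_small(cls, **overrides) -> "GeneratorConfig":
        base = dict(n_lipids_per_leaflet=16, n_waters=500, n_frames=1000)
        base.update(overrides)
        return cls(**base)


_CARBON_SPACING = 0.125  # nm between successive chain carbons
_GLYCEROL_DROP = 0.25    # glycerol sits this far inward of the phosphate


def bilayer_template(cfg: GeneratorConfig) -> LipidTemplate:
    return LipidTemplate(
        residue_name="LIP",
        phosphate_atom="P",
        glycerol_central_atom="C2",
        sn1_carbons=tuple(f"A{k}" for k in range(1, cfg.sn1_length + 1)),
        sn2_carbons=tuple(f"B{k}" for k in range(1, cfg.sn2_length + 1)),
    )


def _chain_z(gly_z: float, length: int, sign: float) -> np.ndarray:
    """Carbon z positions descending from glycerol toward the midplane."""
    return gly_z - sign * (0.15 + _CARBON_SPACING * np.arange(length))


def make_bilayer_trajectory(cfg: GeneratorConfig
                            ) -> tuple[AnnotatedTopology, Trajectory, GroundTruth]:
    """Generate an idealized bilayer trajectory with planted ground truth."""
    rng = np.random.default_rng(cfg.seed)
    n_events = cfg.n_cross + cfg.n_rebound
    if n_events > cfg.n_waters:
        raise ValueError("more planted events than waters")
    usable = cfg.n_frames - cfg.event_duration_frames - 10
    if n_events > 0 and usable < n_events:
        raise ValueError("planted events exceed the frame budget")

    # --- static lipid scaffold -------------------------------------------
    n_side = int(np.ceil(np.sqrt(cfg.n_lipids_per_leaflet)))
    box_xy = n_side * np.sqrt(cfg.area_per_lipid)
    box = np.array([box_xy, box_xy, cfg.box_z])
    mid = cfg.box_z / 2.0
    half_t = cfg.thickness / 2.0

    atoms: list[Atom] = []
    coords0: list[np.ndarray] = []
    resid = 0
    atom_id = 0
    lipid_atom_ranges: list[tuple[int, str]] = []  # (first atom index, leaflet)
    spacing = box_xy / n_side
    for sign, leaflet in ((1.0, "upper"), (-1.0, "lower")):
        placed = 0
        for i in range(n_side):
            for j in range(n_side):
                if placed >= cfg.n_lipids_per_leaflet:
                    break
                resid += 1
                x = (i + 0.5) * spacing
                y = (j + 0.5) * spacing
                z_p = mid + sign * half_t
                z_g = mid + sign * (half_t - _GLYCEROL_DROP)
                first = len(atoms)
                lipid_atom_ranges.append((first, leaflet))

                def add(name, xyz):
                    nonlocal atom_id
                    atom_id += 1
                    atoms.append(Atom(atom_id, name, "LIP", resid,
                                      "P" if name == "P" else "C"))
                    coords0.append(np.asarray(xyz, dtype=float))

                add("P", (x, y, z_p))
                add("C2", (x, y, z_g))
                for k, zc in enumerate(_chain_z(z_g, cfg.sn1_length, sign), 1):
                    add(f"A{k}", (x - 0.08, y, zc))
                for k, zc in enumerate(_chain_z(z_g, cfg.sn2_length, sign), 1):
                    add(f"B{k}", (x + 0.08, y, zc))
                placed += 1

    # --- waters -----------------------------------------------------------
    water_first = len(atoms)
    upper_lo, upper_hi = mid + half_t + 0.2, cfg.box_z - 0.1
    lower_lo, lower_hi = 0.1, mid - half_t - 0.2
    for w in range(cfg.n_waters):
        resid += 1
        atom_id += 1
        atoms.append(Atom(atom_id, "OW", "SOL", resid, "O"))
        if w % 2 == 0:
            z0 = rng.uniform(upper_lo, upper_hi)
        else:
            z0 = rng.uniform(lower_lo, lower_hi)
        coords0.append(np.array([rng.uniform(0, box_xy),
                                 rng.uniform(0, box_xy), z0]))

    base = np.array(coords0)
    topo = apply_lipid_templates(atoms, [bilayer_template(cfg)])

    # --- scripted water z-paths -------------------------------------------
    slab_half = 0.5 * cfg.slab_fraction * cfg.thickness
    margin = min(0.1, 0.3 * slab_half)
    n_frames = cfg.n_frames
    water_z = np.empty((n_frames, cfg.n_waters))
    # background bounded random walks within the entry-side bulk
    steps = rng.normal(0.0, cfg.water_jitter, size=(n_frames, cfg.n_waters))
    water_z[0] = base[water_first:, 2]
    for t in range(1, n_frames):
        water_z[t] = water_z[t - 1] + steps[t]
    for w in range(cfg.n_waters):
        lo, hi = (upper_lo, upper_hi) if w % 2 == 0 else (lower_lo, lower_hi)
        water_z[:, w] = _reflect(water_z[:, w], lo, hi)

    events: list[dict] = []
    if n_events:
        classes = ["crossing"] * cfg.n_cross + ["rebound"] * cfg.n_rebound
        entry_frames = np.linspace(5, usable, n_events).astype(int)
        for k, (cls, f_entry) in enumerate(zip(classes, entry_frames)):
            w = k  # one dedicated water per event
            entry_side = "upper" if k % 2 == 0 else "lower"
            path, exit_side, f_exit = _event_path(
                n_frames, f_entry, cfg.event_duration_frames, cls, entry_side,
                mid, slab_half, margin,
                upper_home=0.5 * (upper_lo + upper_hi),
                lower_home=0.5 * (lower_lo + lower_hi))
            water_z[:, w] = path
            events.append({"water_index": water_first + w,
                           "event_class": cls,
                           "entry_frame": int(f_entry),
                           "exit_frame": int(f_exit),
                           "entry_side": entry_side,
                           "exit_side": exit_side})

    # --- scripted chain motion --------------------------------------------
    sn2_term = np.array([lip.sn2_terminal for lip in topo.lipids])
    gly_idx = np.array([lip.glycerol for lip in topo.lipids])
    leaflet_sign = np.array([1.0 if lr[1] == "upper" else -1.0
                             for lr in lipid_atom_ranges])
    n_lip = len(topo.lipids)

    ch3_offsets = np.zeros((n_frames, n_lip, 3))
    truth_chain: dict = {}
    if cfg.ch3_sigma_z > 0 or cfg.ch3_sigma_xy > 0:
        dz = rng.normal(0.0, cfg.ch3_sigma_z, size=(n_frames - 1, n_lip)) \
            if cfg.ch3_sigma_z > 0 else np.zeros((n_frames - 1, n_lip))
        dxy = rng.normal(0.0, cfg.ch3_sigma_xy, size=(n_frames - 1, n_lip, 2)) \
            if cfg.ch3_sigma_xy > 0 else np.zeros((n_frames - 1, n_lip, 2))
        ch3_offsets[1:, :, 2] = np.cumsum(dz, axis=0)
        ch3_offsets[1:, :, :2] = np.cumsum(dxy, axis=0)
        truth_chain = {
            "mode": "gauss",
            "sigma_z": cfg.ch3_sigma_z, "sigma_xy": cfg.ch3_sigma_xy,
            # mean |dz| of a half-normal step
            "mean_abs_dz": cfg.ch3_sigma_z * np.sqrt(2.0 / np.pi),
            "mean_step_xy": cfg.ch3_sigma_xy * np.sqrt(np.pi / 2.0),
        }
    elif cfg.ch3_step_z > 0 or cfg.ch3_step_xy > 0:
        t_arange = np.arange(n_frames)[:, None]
        ch3_offsets[:, :, 2] = cfg.ch3_step_z * t_arange
        ch3_offsets[:, :, 0] = cfg.ch3_step_xy * t_arange
        truth_chain = {"mode": "constant",
                       "step_z": cfg.ch3_step_z, "step_xy": cfg.ch3_step_xy}

    truth_torsion: dict = {}
    bend_disp = np.zeros((n_lip, cfg.sn2_length, 3))
    if cfg.bend_count > 0:
        # displace carbon n laterally by 2·a·cot(θ/2) to make the angle at n
        # (subtended by n−2 and n+2) exactly bend_angle; planted vertices are
        # ≥5 apart so bends do not share triplets
        theta = np.radians(cfg.bend_angle)
        disp = 2.0 * _CARBON_SPACING / np.tan(theta / 2.0)
        vertices = [4 + 5 * m for m in range(cfg.bend_count)]  # 0-based carbon idx
        if vertices[-1] > cfg.sn2_length - 3:
            raise ValueError("too many bends for the sn2 chain length")
        for v in vertices:
            bend_disp[:, v, 0] = disp
        truth_torsion = {"bend_count": cfg.bend_count,
                         "bend_angle": cfg.bend_angle,
                         "vertices": vertices}

    truth_prot: dict = {}
    prot_wave = None
    if cfg.protrusion_period > 0:
        half = cfg.protrusion_period // 2
        phase = (np.arange(n_frames) // half) % 2 == 1  # starts non-protruded
        prot_wave = phase
        n_up = int(np.sum(phase[1:] & ~phase[:-1]))
        truth_prot = {"period_frames": cfg.protrusion_period,
                      "events_per_chain": n_up}

    # --- assemble frames ----------------------------------------------------
    frames: list[Frame] = []
    sn2_idx = np.array([lip.sn2 for lip in topo.lipids])  # (n_lip, L2)
    for t in range(n_frames):
        c = base.copy()
        c[water_first:, 2] = water_z[t]
        if cfg.bend_count > 0:
            c[sn2_idx.ravel()] = (c[sn2_idx.ravel()]
                                  + bend_disp.reshape(-1, 3))
        if truth_chain:
            c[sn2_term] += ch3_offsets[t]
        if prot_wave is not None and prot_wave[t]:
            # park the terminal carbon 0.2 nm outward of its own glycerol
            c[sn2_term, 2] = c[gly_idx, 2] + 0.2 * leaflet_sign
        frames.append(Frame(time=t * cfg.dt, box=box.copy(), coords=c))

    truth = GroundTruth(permeation_events=events, n_cross=cfg.n_cross,
                        n_rebound=cfg.n_rebound, chain_motion=truth_chain,
                        torsion=truth_torsion, protrusion=truth_prot)
    return topo, Trajectory(frames), truth


def _reflect(z: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect a random-walk path into [lo, hi] (billiard reflection)."""
    span = hi - lo
    y = np.mod(z - lo, 2 * span)
    return lo + np.where(y > span, 2 * span - y, y)


def _event_path(n_frames: int, f_entry: int, duration: int, cls: str,
                entry_side: str, mid: float, slab_half: float, margin: float,
                upper_home: float, lower_home: float):
    """Scripted z-path for one planted permeation event.

    The water sits at its home position, enters the slab at ``f_entry``
    (first frame strictly inside), dwells ``duration`` frames inside, and
    exits to the destination side, where it stays.
    """
    z = np.empty(n_frames)
    s = 1.0 if entry_side == "upper" else -1.0
    home_in = upper_home if entry_side == "upper" else lower_home
    if cls == "crossing":
        exit_side = "lower" if entry_side == "upper" else "upper"
        inside = np.linspace(s * (slab_half - margin),
                             -s * (slab_half - margin), duration)
    else:
        exit_side = entry_side
        half = duration // 2
        down = np.linspace(s * (slab_half - margin), s * margin, half)
        up = np.linspace(s * margin, s * (slab_half - margin),
                         duration - half)
        inside = np.concatenate([down, up])
    home_out = upper_home if exit_side == "upper" else lower_home
    z[:f_entry] = home_in
    z[f_entry:f_entry + duration] = mid + inside
    z[f_entry + duration:] = home_out
    f_exit = f_entry + duration  # first frame back outside
    return z, exit_side, f_exit


# ---------------------------------------------------------------------------
# tubes
# ---------------------------------------------------------------------------

_CG_BEADS = ("PO4", "GL1", "C1A", "C2A", "C1B", "C2B")
_CG_HALF_THICKNESS = 1.5  # nm, headgroup to tail end


def cg_template() -> LipidTemplate:
    return LipidTemplate(
        residue_name="CGL", phosphate_atom="PO4", glycerol_central_atom="GL1",
        sn1_carbons=("C1A", "C2A"), sn2_carbons=("C1B", "C2B"))


def make_tube_frame(R: float, L: float, topology: str = "intact",
                    bead_spacing: float = 0.5, seed: int = 0,
                    box_xy: float | None = None,
                    lipid_spacing: float = 0.8,
                    patch_radius: float = 3.0
                    ) -> tuple[AnnotatedTopology, Frame, GroundTruth]:
    """Flat coarse-grained bilayer plus a cylindrical tube of midsurface
    radius ``R`` and length ``L`` (nm), with planted topology.

    ``topology``: ``intact``; ``severed`` (axial gap > 1.5 nm at mid-tube →
    fission); ``patch_detached`` (pulled-patch lipids displaced beyond the
    linkage cutoff → breakage).  The pulled patch is the set of cap lipids
    within ``patch_radius`` of the axis, mirroring a force applied to the
    centre of mass of a 3 nm lipid patch.
    """
    if R <= bead_spacing:
        raise ValueError("R must exceed the bead spacing")
    if L < 0:
        raise ValueError("L must be >= 0")
    if topology not in ("intact", "severed", "patch_detached"):
        raise ValueError(f"unknown topology {topology!r}")
    ht = _CG_HALF_THICKNESS
    if box_xy is None:
        box_xy = max(2 * (R + ht) + 12.0, 20.0)
    base_lo_head = ht       # lower leaflet headgroup level
    base_hi_head = 3 * ht   # upper leaflet headgroup level (mid at 2·ht)
    z_top = base_hi_head + L
    box = np.array([box_xy, box_xy, z_top + 6.0])
    cx = cy = box_xy / 2.0

    atoms: list[Atom] = []
    coords: list[list[float]] = []
    state = {"resid": 0, "atom_id": 0}

    def add_lipid(head_xyz, unit_inward):
        """One 6-bead lipid from head position along the inward unit vector."""
        state["resid"] += 1
        hx, hy, hz = head_xyz
        ux, uy, uz = unit_inward
        offsets = (0.0, bead_spacing, 2 * bead_spacing, 3 * bead_spacing,
                   2 * bead_spacing, 3 * bead_spacing)
        lateral = (0.0, 0.0, 0.1, 0.1, -0.1, -0.1)
        for name, d, lat in zip(_CG_BEADS, offsets, lateral):
            state["atom_id"] += 1
            atoms.append(Atom(state["atom_id"], name, "CGL", state["resid"], "B"))
            # small lateral split between the two chains, perpendicular to u
            px, py = -uy, ux
            if abs(uz) > 0.9:
                px, py = 1.0, 0.0
            coords.append([hx + d * ux + lat * px,
                           hy + d * uy + lat * py,
                           hz + d * uz])
        return state["resid"]

    hole_r = R + ht + 0.7  # base hole around the tube attachment
    n_grid = int(box_xy / lipid_spacing)
    for i in range(n_grid):
        for j in range(n_grid):
            x = (i + 0.5) * lipid_spacing
            y = (j + 0.5) * lipid_spacing
            if np.hypot(x - cx, y - cy) < hole_r:
                continue
            add_lipid((x, y, base_hi_head), (0.0, 0.0, -1.0))
            add_lipid((x, y, base_lo_head), (0.0, 0.0, 1.0))

    tube_resids: list[int] = []
    n_rings = max(1, int(round(L / lipid_spacing))) if L > 0 else 0
    for k in range(n_rings):
        zr = base_hi_head + (k + 0.5) * L / n_rings if n_rings else 0.0
        for r_head, inward in ((R + ht, -1.0), (max(R - ht, 0.3), 1.0)):
            n_phi = max(3, int(round(2 * np.pi * r_head / lipid_spacing)))
            for p in range(n_phi):
                phi = 2 * np.pi * (p + 0.5 * (k % 2)) / n_phi
                ux, uy = inward * np.cos(phi), inward * np.sin(phi)
                head = (cx + r_head * np.cos(phi), cy + r_head * np.sin(phi), zr)
                tube_resids.append(add_lipid(head, (ux, uy, 0.0)))

    # cap: flat disks of headgroups closing the tube top
    cap_resids: list[int] = []
    if L > 0:
        for z_head, inward in ((z_top, -1.0), (z_top - 2 * ht, 1.0)):
            n_rad = max(1, int(round((R + ht) / lipid_spacing)))
            for q in range(n_rad + 1):
                rr = q * (R + ht) / n_rad
                n_phi = max(1, int(round(2 * np.pi * max(rr, 0.3) / lipid_spacing))) \
                    if rr > 0 else 1
                for p in range(n_phi):
                    phi = 2 * np.pi * p / n_phi
                    head = (cx + rr * np.cos(phi), cy + rr * np.sin(phi), z_head)
                    cap_resids.append(add_lipid(head, (0.0, 0.0, inward)))

    topo = apply_lipid_templates(atoms, [cg_template()])
    c = np.array(coords)
    resid_to_lipid = {lip.residue_id: i for i, lip in enumerate(topo.lipids)}

    # pulled patch: cap lipids within patch_radius of the axis (outer disk)
    pulled: set[int] = set()
    for rid in cap_resids:
        li = resid_to_lipid[rid]
        hx, hy, hz = c[topo.lipids[li].phosphate]
        if np.hypot(hx - cx, hy - cy) <= patch_radius and hz > z_top - ht:
            pulled.add(li)

    keep = np.ones(len(atoms), dtype=bool)
    if topology == "severed":
        z_mid = base_hi_head + L / 2.0
        for rid in tube_resids:
            li = resid_to_lipid[rid]
            if abs(c[topo.lipids[li].phosphate][2] - z_mid) < 1.2:
                for a in (topo.lipids[li].phosphate, topo.lipids[li].glycerol,
                          *topo.lipids[li].sn1, *topo.lipids[li].sn2):
                    keep[a] = False
    elif topology == "patch_detached":
        for li in pulled:
            lip = topo.lipids[li]
            for a in (lip.phosphate, lip.glycerol, *lip.sn1, *lip.sn2):
                c[a, 2] += 4.0

    if not keep.all():
        atoms = [a for a, k in zip(atoms, keep) if k]
        c = c[keep]
        topo = apply_lipid_templates(atoms, [cg_template()])
        resid_to_lipid = {lip.residue_id: i for i, lip in enumerate(topo.lipids)}
        pulled = {resid_to_lipid[rid] for rid in cap_resids
                  if rid in resid_to_lipid
                  and np.hypot(c[topo.lipids[resid_to_lipid[rid]].phosphate][0] - cx,
                               c[topo.lipids[resid_to_lipid[rid]].phosphate][1] - cy)
                  <= patch_radius
                  and c[topo.lipids[resid_to_lipid[rid]].phosphate][2] > z_top - ht}

    frame = Frame(time=0.0, box=box, coords=c)
    truth = GroundTruth(tube={"L": L, "R": R, "topology": topology,
                              "pulled_lipids": sorted(pulled),
                              "base_z": base_hi_head})
    return topo, frame, truth


# ---------------------------------------------------------------------------
# defect patches
# ---------------------------------------------------------------------------

_PATCH_TEMPLATE = LipidTemplate(
    residue_name="PAT", phosphate_atom="P", glycerol_central_atom="C2",
    sn1_carbons=("A1", "A2"), sn2_carbons=("B1", "B2"))


def patch_template() -> LipidTemplate:
    return _PATCH_TEMPLATE


def make_defect_patch(window: tuple[float, float, float, float] | None = None,
                      depth: float = 0.15,
                      box_xy: float = 3.0,
                      lipid_spacing: float = 0.3,
                      bead_radius: float = 0.26):
    """Two opposing bead monolayers with a fully covering headgroup layer
    and an optional planted packing defect.

    ``window = (x_lo, x_hi, y_lo, y_hi)`` marks an upper-leaflet region
    whose lipids have their head and glycerol beads made invisible to a
    surface scan (hydrogen-like zero-coverage beads, left at the unchanged
    reference level) while their first aliphatic bead is raised so its
    sphere top sits exactly ``depth`` nm below the neighbourhood glycerol
    level — a defect of known class (shallow ≤ 0.1 nm, deep otherwise),
    position and area.  Returns ``(topo, frame, ref, GroundTruth)``.
    """
    from .membrane_geometry import MembraneFrameRef

    atoms: list[Atom] = []
    coords: list[list[float]] = []
    z_head_u, z_gly_u = 4.0, 3.7
    z_head_l, z_gly_l = 1.0, 1.3
    leaflets: dict[int, str] = {}
    n = int(round(box_xy / lipid_spacing))
    resid = 0
    aid = 0
    lipid_no = 0

    def add(name, x, y, z, element):
        nonlocal aid
        aid += 1
        atoms.append(Atom(aid, name, "PAT", resid, element))
        coords.append([x, y, z])

    for leaf, z_h, z_g, sgn in (("upper", z_head_u, z_gly_u, 1.0),
                                ("lower", z_head_l, z_gly_l, -1.0)):
        for i in range(n):
            for j in range(n):
                resid += 1
                x = (i + 0.5) * lipid_spacing
                y = (j + 0.5) * lipid_spacing
                exposed = (leaf == "upper" and window is not None
                           and window[0] <= x <= window[1]
                           and window[2] <= y <= window[3])
                head_el = "H" if exposed else "B"
                add("P", x, y, z_h, head_el)
                add("C2", x, y, z_g, head_el)
                if exposed:
                    z_a2_top = z_g - depth
                    add("A1", x, y, z_a2_top - bead_radius - 0.6, "B")
                    add("A2", x, y, z_a2_top - bead_radius, "B")
                else:
                    add("A1", x, y, z_g - sgn * 0.5, "B")
                    add("A2", x, y, z_g - sgn * 0.9, "B")
                add("B1", x, y, z_g - sgn * 0.5, "B")
                add("B2", x, y, z_g - sgn * 0.9, "B")
                leaflets[lipid_no] = leaf
                lipid_no += 1

    topo = apply_lipid_templates(atoms, [_PATCH_TEMPLATE])
    frame = Frame(time=0.0, box=np.array([box_xy, box_xy, 6.0]),
                  coords=np.array(coords))
    mid = 0.5 * (z_head_u + z_head_l)
    thickness = z_head_u - z_head_l
    ref = MembraneFrameRef(midplane_z=mid, thickness=thickness,
                           slab_lo=mid - 0.325 * thickness,
                           slab_hi=mid + 0.325 * thickness,
                           leaflet_of_lipid=leaflets, slab_fraction=0.65)
    truth = GroundTruth(defects={} if window is None else {
        "window": list(window),
        "depth": depth,
        "depth_class": "shallow" if depth <= 0.1 else "deep",
        "area": (window[1] - window[0]) * (window[3] - window[2]),
        "leaflet": "upper",
    })
    return topo, frame, ref, truth


# ---------------------------------------------------------------------------
# assay traces
# ---------------------------------------------------------------------------

GTPASE_TIMES_S = (15.0, 45.0, 75.0, 120.0, 180.0, 240.0, 360.0)


def make_assay_series(kind: str, params: dict | None = None, seed: int = 0
                      ) -> tuple[pd.DataFrame | dict, GroundTruth]:
    """Synthetic assay data with planted parameters.

    ``kind="quench"`` → DataFrame (time_s, fluorescence): baseline until
    dithionite addition, an instantaneous fast phase quenching the
    outer-leaflet probe fraction, a slow exponential permeation phase, and a
    Triton step to full quench.

    ``kind="guv"`` → DataFrame of per-vesicle intensities/areas with planted
    permeability and shrinkage.

    ``kind="gtpase"`` → dict with a phosphate time series (linear accrual at
    the planted turnover rate plus Gaussian noise) and a standards table.
    """
    p = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "quench":
        outer = p.get("outer_fraction", 0.5)
        slow_rate = p.get("slow_rate", 0.0)        # s⁻¹
        f_init = p.get("f_init", 1000.0)
        f_bg = p.get("f_bg", 0.0)
        noise = p.get("noise", 0.0)
        t_dith = p.get("t_dithionite", 30.0)
        t_trit = p.get("t_triton", 350.0)
        times = np.arange(0.0, p.get("t_end", 400.0) + 1e-9, p.get("dt", 1.0))
        if noise < 0:
            raise ValueError("negative noise scale")
        # baseline is recorded through t_dith; quenching starts strictly after
        quenched = np.where(
            times <= t_dith, 0.0,
            outer + (1.0 - outer) * (1.0 - np.exp(-slow_rate * (times - t_dith))))
        quenched = np.where(times >= t_trit, 1.0, quenched)
        f = f_bg + (f_init - f_bg) * (1.0 - quenched)
        if noise > 0:
            f = f + rng.normal(0.0, noise, size=f.shape)
        df = pd.DataFrame({"time_s": times, "fluorescence": f})
        truth = GroundTruth(assay={
            "kind": "quench", "outer_fraction": outer,
            "fast_plateau_percent": 100.0 * outer,
            "slow_rate": slow_rate, "t_dithionite": t_dith,
            "t_triton": t_trit})
        return df, truth
    if kind == "guv":
        perm = p.get("permeability_percent", 10.0)
        shrink_printed = p.get("shrinking_percent", 100.0)
        n = p.get("n_vesicles", 20)
        i_ex = p.get("i_ex", 300.0)
        a0 = p.get("a0_um2", 80.0)
        noise = p.get("noise", 0.0)
        if noise < 0:
            raise ValueError("negative noise scale")
        i_in = np.full(n, perm / 100.0 * i_ex)
        ai = np.full(n, 100.0 * a0 / shrink_printed)
        if noise > 0:
            i_in = i_in + rng.normal(0.0, noise, n)
            ai = ai + rng.normal(0.0, noise, n)
        df = pd.DataFrame({"i_in": i_in, "i_ex": i_ex, "a0_um2": a0,
                           "ai_um2": ai})
        truth = GroundTruth(assay={
            "kind": "guv", "permeability_percent": perm,
            "shrinking_percent_printed": shrink_printed,
            "shrinking_percent_consumed": 100.0 * (1.0 - 100.0 / shrink_printed)})
        return df, truth
    if kind == "gtpase":
        rate = p.get("rate_per_s", 2.0)
        dyn = p.get("dynamin_conc_uM", 0.3)
        sigma = p.get("noise_uM", 0.0)
        cal_slope = p.get("cal_slope", 0.004)      # abs per µM
        cal_icpt = p.get("cal_intercept", 0.05)
        times = np.asarray(p.get("times_s", GTPASE_TIMES_S), dtype=float)
        if sigma < 0:
            raise ValueError("negative noise scale")
        phosphate = rate * dyn * times
        if sigma > 0:
            phosphate = phosphate + rng.normal(0.0, sigma, size=times.shape)
        absorbance = cal_icpt + cal_slope * phosphate
        standards = pd.DataFrame({
            "conc_uM": [0.0, 50.0, 100.0, 150.0, 200.0]})
        standards["abs"] = cal_icpt + cal_slope * standards["conc_uM"]
        data = {"series": pd.DataFrame({"time_s": times,
                                        "abs_650": absorbance}),
                "standards": standards, "dynamin_conc_uM": dyn}
        truth = GroundTruth(assay={"kind": "gtpase", "rate_per_s": rate,
                                   "dynamin_conc_uM": dyn, "noise_uM": sigma})
        return data, truth
    raise ValueError(f"unknown assay kind {kind!r}")
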