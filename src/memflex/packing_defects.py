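"""Interfacial lipid packing-defect scanning.

Each leaflet's solvent interface is scanned on a regular x-y grid (default
0.1 nm spacing).  From the solvent side of the leaflet a vertical ray is cast
toward the membrane at every grid point; the first lipid heavy atom whose van
der Waals sphere the ray intersects is the contact atom.  When the contact
atom belongs to the template's aliphatic set, the cell is a packing defect —
a spot where chain atoms are directly solvent-accessible.  The defect depth
is measured below the nearest glycerol central carbon (smallest lateral
distance, searched within a 1.0 nm neighbourhood first): depths up to 0.1 nm
are *shallow*, larger depths are *deep*.  Contiguous defect cells
(4-connectivity, periodic in x-y) merge into individual defects whose areas
are reported per class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .membrane_geometry import MembraneFrameRef
from .traj_io import AnnotatedTopology, Frame

logger = logging.getLogger(__name__)

FLAG_NONE, FLAG_SHALLOW, FLAG_DEEP, FLAG_VOID = 0, 1, 2, -1
DEPTH_THRESHOLD = 0.1  # nm (1 Å); exactly 0.1 classifies shallow

#: van der Waals radii (nm) by element; "B" covers generic coarse beads
DEFAULT_RADII = {"C": 0.17, "H": 0.12, "O": 0.152, "N": 0.155,
                 "P": 0.18, "S": 0.18, "B": 0.26}


@dataclass
class DefectGrid:
    leaflet: str
    grid_spacing: float
    flags: np.ndarray                  # (nx, ny) int
    depth: np.ndarray = field(repr=False, default=None)        # nm, nan if no defect
    contact_atom: np.ndarray = field(repr=False, default=None)  # atom index, -1

    @property
    def cell_area(self) -> float:
        return self.grid_spacing ** 2

    def count(self, flag: int) -> int:
        return int(np.sum(self.flags == flag))


@dataclass
class DefectSummary:
    per_frame: pd.DataFrame   # frame, leaflet, class, n_defects, total_area_nm2
    block_stats: pd.DataFrame  # leaflet, class, mean/sd of counts and areas over blocks


def scan_defects(frame: Frame, topo: AnnotatedTopology, ref: MembraneFrameRef,
                 grid_spacing: float = 0.1,
                 radii: dict[str, float] | None = None,
                 glycerol_neighborhood: float = 1.0,
                 chunk: int = 4096) -> dict[str, DefectGrid]:
    """Ray-cast defect scan of both leaflets of one frame.

    Returns ``{"upper": DefectGrid, "lower": DefectGrid}``.  Grid points with
    no lipid contact at all are flagged as voids and counted separately.
    """
    radii = DEFAULT_RADII if radii is None else radii
    box = frame.box
    nx = max(1, int(round(box[0] / grid_spacing)))
    ny = max(1, int(round(box[1] / grid_spacing)))
    gx = (np.arange(nx) + 0.5) * box[0] / nx
    gy = (np.arange(ny) + 0.5) * box[1] / ny

    out: dict[str, DefectGrid] = {}
    for leaflet in ("upper", "lower"):
        lip_ids = [i for i, lf in ref.leaflet_of_lipid.items() if lf == leaflet]
        atom_idx, atom_r, aliphatic_mask = _leaflet_atoms(topo, lip_ids, radii)
        pos = frame.coords[atom_idx]
        gly_idx = np.array([topo.lipids[i].glycerol for i in lip_ids])
        gly_pos = frame.coords[gly_idx]

        flags = np.full((nx, ny), FLAG_NONE, dtype=int)
        depth = np.full((nx, ny), np.nan)
        contact = np.full((nx, ny), -1, dtype=int)

        pts = np.stack(np.meshgrid(gx, gy, indexing="ij"), axis=-1).reshape(-1, 2)
        sign = 1.0 if leaflet == "upper" else -1.0
        for start in range(0, pts.shape[0], chunk):
            p = pts[start:start + chunk]
            dx = p[:, 0:1] - pos[None, :, 0]
            dy = p[:, 1:2] - pos[None, :, 1]
            dx -= box[0] * np.round(dx / box[0])
            dy -= box[1] * np.round(dy / box[1])
            d2 = dx * dx + dy * dy
            under = d2 <= atom_r[None, :] ** 2
            h = np.where(under, np.sqrt(np.maximum(atom_r[None, :] ** 2 - d2, 0.0)), np.nan)
            # contact height along the ray coming from the solvent side
            zc = pos[None, :, 2] + sign * h
            zc = np.where(under, zc, -np.inf if sign > 0 else np.inf)
            first = np.argmax(zc, axis=1) if sign > 0 else np.argmin(zc, axis=1)
            any_contact = under.any(axis=1)
            z_first = zc[np.arange(p.shape[0]), first]

            # nearest glycerol (lateral, minimum image)
            gdx = p[:, 0:1] - gly_pos[None, :, 0]
            gdy = p[:, 1:2] - gly_pos[None, :, 1]
            gdx -= box[0] * np.round(gdx / box[0])
            gdy -= box[1] * np.round(gdy / box[1])
            gd = np.sqrt(gdx ** 2 + gdy ** 2)
            near = np.where(gd <= glycerol_neighborhood, gd, np.inf)
            g_near = np.argmin(near, axis=1)
            no_near = ~np.isfinite(near[np.arange(p.shape[0]), g_near])
            g_near[no_near] = np.argmin(gd[no_near], axis=1)  # fall back: global nearest
            z_gly = gly_pos[g_near, 2]

            dep = sign * (z_gly - z_first)
            is_defect = any_contact & aliphatic_mask[first]
            cell_flags = np.where(
                ~any_contact, FLAG_VOID,
                np.where(~is_defect, FLAG_NONE,
                         np.where(dep <= DEPTH_THRESHOLD, FLAG_SHALLOW, FLAG_DEEP)))
            ii = (start + np.arange(p.shape[0])) // ny
            jj = (start + np.arange(p.shape[0])) % ny
            flags[ii, jj] = cell_flags
            depth[ii, jj] = np.where(is_defect, dep, np.nan)
            contact[ii, jj] = np.where(any_contact, atom_idx[first], -1)
        n_void = int(np.sum(flags == FLAG_VOID))
        if n_void:
            logger.warning("%s leaflet: %d grid point(s) with no lipid contact "
                           "(voids)", leaflet, n_void)
        out[leaflet] = DefectGrid(leaflet=leaflet, grid_spacing=grid_spacing,
                                  flags=flags, depth=depth, contact_atom=contact)
    return out


def _leaflet_atoms(topo: AnnotatedTopology, lip_ids: list[int],
                   radii: dict[str, float]):
    idx: list[int] = []
    aliph: list[bool] = []
    for i in lip_ids:
        lip = topo.lipids[i]
        members = sorted({lip.phosphate, lip.glycerol, *lip.sn1, *lip.sn2,
                          *lip.aliphatic})
        for a in members:
            if topo.atoms[a].element_or_bead == "H":
                continue
            idx.append(a)
            aliph.append(a in lip.aliphatic)
    r = np.empty(len(idx))
    for k, a in enumerate(idx):
        el = topo.atoms[a].element_or_bead or "C"
        if el not in radii:
            raise KeyError(f"no vdW radius for element/bead {el!r} "
                           f"(atom {topo.atoms[a].atom_name})")
        r[k] = radii[el]
    return np.array(idx, dtype=int), r, np.array(aliph, dtype=bool)


def _periodic_label(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """4-connected component labelling with periodic wrap in both axes."""
    labels, n = ndimage.label(mask, structure=np.array([[0, 1, 0],
                                                        [1, 1, 1],
                                                        [0, 1, 0]]))
    if n == 0:
        return labels, 0
    parent = list(range(n + 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for a, b in zip(labels[0, :], labels[-1, :]):
        if a and b:
            union(a, b)
    for a, b in zip(labels[:, 0], labels[:, -1]):
        if a and b:
            union(a, b)
    remap = {}
    for lbl in range(1, n + 1):
        root = find(lbl)
        remap.setdefault(root, len(remap) + 1)
    flat = np.zeros(n + 1, dtype=int)
    for lbl in range(1, n + 1):
        flat[lbl] = remap[find(lbl)]
    return flat[labels], len(remap)


def count_defects(grid: DefectGrid) -> dict[str, tuple[int, float]]:
    """Merge contiguous cells per class; returns
    ``{class: (n_defects, total_area_nm2)}``."""
    res = {}
    for cls, flag in (("shallow", FLAG_SHALLOW), ("deep", FLAG_DEEP)):
        mask = grid.flags == flag
        _, n = _periodic_label(mask)
        res[cls] = (n, float(mask.sum()) * grid.cell_area)
    return res


def defect_summary(grids: list[dict[str, DefectGrid]],
                   block_ns: float = 100.0,
                   dt_ps: float | None = None) -> DefectSummary:
    """Aggregate per-frame defect grids into counts and areas with block
    statistics.  ``grids`` is one dict per frame as returned by
    :func:`scan_defects`."""
    if not grids:
        raise ValueError("need at least one grid")
    shape = {g.flags.shape for d in grids for g in d.values()}
    if len(shape) > 1:
        raise ValueError(f"inconsistent grid shapes: {sorted(shape)}")
    rows = []
    for t, d in enumerate(grids):
        for leaflet, grid in d.items():
            for cls, (n, area) in count_defects(grid).items():
                rows.append({"frame": t, "leaflet": leaflet, "class": cls,
                             "n_defects": n, "total_area_nm2": area})
    per_frame = pd.DataFrame(rows)

    if dt_ps is not None and len(grids) > 1:
        frames_per_block = max(1, int(round(block_ns * 1000.0 / dt_ps)))
    else:
        frames_per_block = len(grids)
    per_frame["block"] = per_frame["frame"] // frames_per_block
    stats = (per_frame.groupby(["leaflet", "class", "block"])
             [["n_defects", "total_area_nm2"]].mean().reset_index()
             .groupby(["leaflet", "class"])
             [["n_defects", "total_area_nm2"]]
             .agg(["mean", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0]))
    stats.columns = ["count_mean", "count_sd", "area_mean", "area_sd"]
    return DefectSummary(per_frame=per_frame, block_stats=stats.reset_index())
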