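"""Membrane tube geometry, relative bending rigidity, and scission calls.

A membrane tether pulled from a flat bilayer stores bending energy
``E_b = π·K_b·L/R`` (L = tube length, R = tube radius, K_b = bending
modulus).  Tubes pulled from different compositions by the same force over
the same time have stored the same curvature energy, so the ratio of their
L/R values inverts into the ratio of their bending moduli — a *relative*
rigidity, expressed as a percentage of a reference composition.

Geometry extraction on coarse-grained configurations is intentionally
simple and deterministic: the flat-base headgroup level defines ``base_z``,
beads sufficiently above it are tube beads, ``L`` is the maximum headgroup
height above the base, and ``R`` is the tube midsurface radius (mean of the
inner- and outer-leaflet headgroup radii about the pulling axis).

Scission outcomes are classified from single-linkage connected components of
lipid beads: *fission* severs the tube at the neck (the pulled patch leaves
together with tube-body lipids), *breakage* tears out only the lipids where
the force is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .membrane_geometry import _two_means_1d
from .traj_io import AnnotatedTopology, Frame

logger = logging.getLogger(__name__)


@dataclass
class TubeShape:
    axis: np.ndarray          # unit vector (pulling direction)
    base_z: float             # nm, flat-region headgroup level (along axis)
    length_L: float           # nm
    radius_R: float           # nm (nan for flat configurations)
    force_label: float | None = None  # kJ mol^-1 nm^-1
    time_label: float | None = None   # ns
    is_flat: bool = False

    @property
    def LR_ratio(self) -> float:
        if self.is_flat:
            return 0.0
        return self.length_L / self.radius_R


@dataclass
class RigidityEstimate:
    reference_composition: str
    relative_kb: dict[str, float]  # composition -> % of reference K_b


@dataclass
class ScissionCall:
    outcome: str               # intact | fission | breakage | indeterminate
    n_components: int
    rupture_location: str      # neck | pulled_patch | none
    components: list[set] = field(repr=False, default_factory=list)


def _axis_frame(coords: np.ndarray, axis) -> np.ndarray:
    """Rotate coordinates so the pulling axis maps onto +z."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    if np.allclose(axis, [0, 0, 1]):
        return coords
    # orthonormal basis with axis as third column
    helper = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(helper, axis)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return coords @ np.column_stack([u, v, axis])


def fit_tube(frame: Frame, topo: AnnotatedTopology,
             axis=(0.0, 0.0, 1.0),
             base_offset: float = 0.0,
             body_margin_bottom: float = 1.0,
             body_margin_top: float = 3.5,
             min_protrusion: float = 0.5,
             base_window: float = 4.5,
             force_label: float | None = None,
             time_label: float | None = None) -> TubeShape:
    """Extract tube length, radius and L/R from one configuration.

    ``base_z`` is the median headgroup height of the flat region's upper
    (solvent-facing along the axis) leaflet; tube headgroups are those above
    ``base_z + max(2×base roughness, min_protrusion)``.  ``L`` is the maximum
    tube headgroup height above ``base_z`` minus ``base_offset``; ``R`` is
    the mean of the inner and outer leaflet headgroup radii about the axis
    (two-means split of radial distances), measured on the tube body (cap and
    junction excluded via the body margins).  A configuration with no
    headgroups above the threshold is reported as flat (L = 0, R undefined).
    """
    heads = np.array([lip.phosphate for lip in topo.lipids])
    pos = _axis_frame(frame.coords[heads], axis)
    z = pos[:, 2]
    # the flat base holds the lowest headgroups; a window of one bilayer
    # thickness above the minimum captures both base leaflets while keeping
    # the bulk of the tube out even when tube headgroups outnumber the base
    base_cand = z[z < z.min() + base_window]
    _, base_hi, upper_mask = _two_means_1d(base_cand)
    base_level = float(np.median(base_cand[upper_mask]))
    roughness = float(np.std(base_cand[upper_mask]))
    threshold = base_level + max(2.0 * roughness, min_protrusion)

    tube_mask = z > threshold
    if not tube_mask.any():
        logger.info("no headgroups above base level: flat configuration")
        return TubeShape(axis=np.asarray(axis, float), base_z=base_level,
                         length_L=0.0, radius_R=float("nan"),
                         force_label=force_label, time_label=time_label,
                         is_flat=True)
    L = float(z[tube_mask].max() - base_level - base_offset)

    body = tube_mask & (z > base_level + body_margin_bottom) \
        & (z < base_level + L - body_margin_top)
    if not body.any():
        body = tube_mask
    center = np.median(pos[body, :2], axis=0)
    r = np.hypot(pos[body, 0] - center[0], pos[body, 1] - center[1])
    r_in, r_out, _ = _two_means_1d(r)
    R = 0.5 * (r_in + r_out)
    return TubeShape(axis=np.asarray(axis, float), base_z=base_level,
                     length_L=L, radius_R=float(R),
                     force_label=force_label, time_label=time_label)


def relative_rigidity(lr_by_composition: dict[str, float], reference: str,
                      force_labels: dict[str, float] | None = None,
                      time_labels: dict[str, float] | None = None) -> RigidityEstimate:
    """Relative bending moduli from L/R ratios at equal pulling force.

    From ``E_b = π·K_b·L/R`` with equal stored energy across compositions,
    ``K_b(c)/K_b(ref) = (L/R)_ref / (L/R)_c``; returned in percent
    (reference = 100%).
    """
    if reference not in lr_by_composition:
        raise ValueError(f"reference composition {reference!r} missing")
    for label, lr in lr_by_composition.items():
        if lr <= 0:
            raise ValueError(f"L/R must be > 0 (got {lr} for {label!r})")
    for labels, what in ((force_labels, "force"), (time_labels, "time")):
        if labels is not None and len(set(labels.values())) > 1:
            raise ValueError(f"mismatched {what} labels: {labels}; relative "
                             "rigidity requires equal stored energy")
    lr_ref = lr_by_composition[reference]
    rel = {c: 100.0 * lr_ref / lr for c, lr in lr_by_composition.items()}
    return RigidityEstimate(reference_composition=reference, relative_kb=rel)


def lipid_components(frame: Frame, topo: AnnotatedTopology,
                     cutoff: float = 1.2) -> list[set[int]]:
    """Single-linkage connected components of lipids: two lipids connect when
    any of their beads lie within ``cutoff`` (periodic in x-y)."""
    atom_to_lipid: dict[int, int] = {}
    all_atoms: list[int] = []
    for li, lip in enumerate(topo.lipids):
        members = sorted({lip.phosphate, lip.glycerol, *lip.sn1, *lip.sn2})
        for a in members:
            atom_to_lipid[a] = li
            all_atoms.append(a)
    pos = frame.coords[all_atoms].copy()
    box = frame.box
    pos[:, 0] %= box[0]
    pos[:, 1] %= box[1]
    zspan = pos[:, 2].max() - pos[:, 2].min() + 2 * cutoff + 1.0
    pos[:, 2] -= pos[:, 2].min() - cutoff
    tree = cKDTree(pos, boxsize=[box[0], box[1], zspan + 2 * cutoff])
    pairs = tree.query_pairs(cutoff, output_type="ndarray")

    parent = list(range(len(topo.lipids)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        ra, rb = find(atom_to_lipid[all_atoms[a]]), find(atom_to_lipid[all_atoms[b]])
        if ra != rb:
            parent[rb] = ra
    comps: dict[int, set[int]] = {}
    for li in range(len(topo.lipids)):
        comps.setdefault(find(li), set()).add(li)
    return sorted(comps.values(), key=len, reverse=True)


def detect_scission(frame: Frame, topo: AnnotatedTopology,
                    pulled_lipids: set[int], cutoff: float = 1.2,
                    margin: int = 10) -> ScissionCall:
    """Classify a pulled-tube configuration as intact, fission or breakage.

    ``pulled_lipids`` are lipid indices of the patch the force is applied to.
    With ≥2 components, the component holding the majority of the pulled
    patch decides: *breakage* when it contains at most ``margin`` non-patch
    lipids (rupture at the pulled patch), *fission* otherwise (the patch left
    with tube-body lipids: rupture at the neck).
    """
    comps = lipid_components(frame, topo, cutoff)
    if len(comps) == 1:
        return ScissionCall(outcome="intact", n_components=1,
                            rupture_location="none", components=comps)
    if not pulled_lipids:
        logger.warning("empty pulled-lipid set: outcome indeterminate")
        return ScissionCall(outcome="indeterminate", n_components=len(comps),
                            rupture_location="none", components=comps)
    pulled = set(pulled_lipids)
    pulled_comp = max(comps, key=lambda c: len(c & pulled))
    if len(pulled_comp & pulled) < 0.5 * len(pulled):
        logger.warning("pulled patch split across components")
    non_patch = len(pulled_comp - pulled)
    if non_patch <= margin:
        return ScissionCall(outcome="breakage", n_components=len(comps),
                            rupture_location="pulled_patch", components=comps)
    return ScissionCall(outcome="fission", n_components=len(comps),
                        rupture_location="neck", components=comps)
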