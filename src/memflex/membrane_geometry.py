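"""Per-frame bilayer reference geometry and density profiles.

The reference frame of every metric in this package is the bilayer midplane.
Leaflets are split by a deterministic two-means clustering of phosphate z;
thickness is the distance between the two leaflet phosphate means, and the
hydrophobic slab is a band centred on the midplane spanning a configurable
fraction of the thickness (default 0.65, the fraction used to score water
visits to the membrane core).

Slab bounds are computed per frame, so membrane drift or undulation does not
smear the slab over a trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .traj_io import AnnotatedTopology, Frame, Trajectory

logger = logging.getLogger(__name__)

DEFAULT_SLAB_FRACTION = 0.65


class NotPlanarBilayerError(ValueError):
    """Phosphate z distribution does not split into two leaflets."""


@dataclass
class MembraneFrameRef:
    midplane_z: float       # nm
    thickness: float        # nm, phosphate-to-phosphate
    slab_lo: float          # nm
    slab_hi: float          # nm
    leaflet_of_lipid: dict  # lipid index -> "upper" | "lower"
    slab_fraction: float

    @property
    def slab_width(self) -> float:
        return self.slab_hi - self.slab_lo


@dataclass
class DensityProfile:
    bin_edges: np.ndarray       # nm, midplane-relative z
    counts_per_bin: np.ndarray  # number density (count / nm), frame-averaged
    selection_label: str
    n_frames: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def mean_count(self) -> float:
        """Mean in-range selected-atom count per frame (profile integral)."""
        return float(np.sum(self.counts_per_bin) * self.bin_width)


def _two_means_1d(z: np.ndarray, max_iter: int = 100) -> tuple[float, float, np.ndarray]:
    """Deterministic 1-D two-means: centers start at min/max; returns
    (low mean, high mean, boolean mask of the high cluster)."""
    lo, hi = float(z.min()), float(z.max())
    upper = z > 0.5 * (lo + hi)
    for _ in range(max_iter):
        if upper.all() or (~upper).all():
            break
        lo, hi = float(z[~upper].mean()), float(z[upper].mean())
        new_upper = np.abs(z - hi) < np.abs(z - lo)
        if np.array_equal(new_upper, upper):
            break
        upper = new_upper
    return lo, hi, upper


def membrane_reference(frame: Frame, topo: AnnotatedTopology,
                       slab_fraction: float = DEFAULT_SLAB_FRACTION,
                       min_separation: float = 1.0) -> MembraneFrameRef:
    """Compute the bilayer reference geometry for one frame.

    Raises :class:`NotPlanarBilayerError` when the two-means split of
    phosphate z yields leaflet means closer than ``min_separation`` (nm) —
    e.g. for a tubulated or micellar configuration.
    """
    if len(topo.lipids) < 2:
        raise ValueError("need at least 2 lipids with phosphate atoms")
    phos_idx = np.array([lip.phosphate for lip in topo.lipids])
    z = frame.coords[phos_idx, 2]
    mean_lo, mean_hi, _ = _two_means_1d(z)
    if mean_hi - mean_lo < min_separation:
        raise NotPlanarBilayerError(
            f"not a planar bilayer: leaflet phosphate means separated by "
            f"{mean_hi - mean_lo:.3f} nm (< {min_separation} nm)")
    midplane = 0.5 * (mean_lo + mean_hi)
    thickness = mean_hi - mean_lo
    half_slab = 0.5 * slab_fraction * thickness
    leaflets: dict[int, str] = {}
    for i, lip in enumerate(topo.lipids):
        zp = frame.coords[lip.phosphate, 2]
        if zp > midplane:
            leaflets[i] = "upper"
        elif zp < midplane:
            leaflets[i] = "lower"
        else:
            zg = frame.coords[lip.glycerol, 2]
            leaflets[i] = "upper" if zg >= midplane else "lower"
            logger.warning("lipid %d phosphate exactly at midplane; leaflet "
                           "assigned from glycerol z", lip.residue_id)
    return MembraneFrameRef(midplane_z=midplane, thickness=thickness,
                            slab_lo=midplane - half_slab,
                            slab_hi=midplane + half_slab,
                            leaflet_of_lipid=leaflets,
                            slab_fraction=slab_fraction)


def trajectory_references(traj: Trajectory, topo: AnnotatedTopology,
                          slab_fraction: float = DEFAULT_SLAB_FRACTION) -> list[MembraneFrameRef]:
    """Per-frame :func:`membrane_reference` over a trajectory."""
    return [membrane_reference(fr, topo, slab_fraction) for fr in traj.frames]


def resolve_selection(topo: AnnotatedTopology, selection: str) -> np.ndarray:
    """Resolve a role expression to topology atom indices.

    Recognised expressions: ``sn1``, ``sn2``, ``water``, ``phosphate``,
    ``glycerol``, ``terminal``, ``terminal-sn1``, ``terminal-sn2``,
    ``aliphatic``.
    """
    sel = selection.lower()
    if sel == "water":
        idx = list(topo.water_oxygens)
    elif sel == "sn1":
        idx = [i for lip in topo.lipids for i in lip.sn1]
    elif sel == "sn2":
        idx = [i for lip in topo.lipids for i in lip.sn2]
    elif sel == "phosphate":
        idx = [lip.phosphate for lip in topo.lipids]
    elif sel == "glycerol":
        idx = [lip.glycerol for lip in topo.lipids]
    elif sel == "terminal-sn1":
        idx = [lip.sn1_terminal for lip in topo.lipids]
    elif sel == "terminal-sn2":
        idx = [lip.sn2_terminal for lip in topo.lipids]
    elif sel == "terminal":
        idx = [i for lip in topo.lipids for i in (lip.sn1_terminal, lip.sn2_terminal)]
    elif sel == "aliphatic":
        idx = [i for lip in topo.lipids for i in sorted(lip.aliphatic)]
    else:
        raise ValueError(f"unknown selection {selection!r}")
    if not idx:
        raise ValueError(f"selection {selection!r} resolves to no atoms")
    return np.array(sorted(set(idx)))


def density_profile(traj: Trajectory, topo: AnnotatedTopology,
                    selection: str, n_bins: int = 100,
                    slab_fraction: float = DEFAULT_SLAB_FRACTION,
                    z_range: tuple[float, float] | None = None,
                    refs: list[MembraneFrameRef] | None = None) -> DensityProfile:
    """Histogram of selected-atom z relative to the per-frame midplane,
    averaged over frames.

    The default range spans ``[-thickness, +thickness]`` around the midplane
    (mean thickness over frames).  The profile integral equals the mean
    number of selected atoms per frame that fall inside the range.
    """
    idx = resolve_selection(topo, selection)
    if refs is None:
        refs = trajectory_references(traj, topo, slab_fraction)
    if z_range is None:
        t_mean = float(np.mean([r.thickness for r in refs]))
        z_range = (-t_mean, t_mean)
    edges = np.linspace(z_range[0], z_range[1], n_bins + 1)
    total = np.zeros(n_bins)
    for fr, ref in zip(traj.frames, refs):
        dz = fr.coords[idx, 2] - ref.midplane_z
        box_z = fr.box[2]
        dz -= box_z * np.round(dz / box_z)  # minimum image about the midplane
        hist, _ = np.histogram(dz, bins=edges)
        total += hist
    width = edges[1] - edges[0]
    counts_per_bin = total / (len(traj.frames) * width)
    return DensityProfile(bin_edges=edges, counts_per_bin=counts_per_bin,
                          selection_label=selection, n_frames=len(traj.frames))
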