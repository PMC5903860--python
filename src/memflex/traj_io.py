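"""Structure/trajectory parsing and lipid-role annotation.

Internal units are nm for lengths and ps for times throughout the package;
readers are the only place unit conversion happens (PDB Å are divided by 10
on input).  Three plain-text dialects are supported:

* GRO (single- or multi-frame, concatenated blocks),
* PDB (``ATOM``/``HETATM`` records, ``MODEL``/``ENDMDL`` frame delimiters,
  ``CRYST1`` box),
* "frame-text", a minimal diffable frame-sequence format used for synthetic
  trajectories::

      frame <time_ps> <box_x> <box_y> <box_z>
      <atom_id> <x> <y> <z>
      ...

Atoms are annotated with membrane roles (phosphate, central glycerol carbon,
ordered sn1/sn2 acyl carbons, water oxygen) through user-supplied
:class:`LipidTemplate` records, one per lipid residue name.  The same
machinery serves all-atom and coarse-grained systems: for beads, "CH3
terminal" maps to the last tail bead of each chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

#: residue names treated as water unless overridden
DEFAULT_WATER_NAMES = frozenset({"SOL", "TIP3", "W", "WAT", "HOH"})

_REL_TIME_TOL = 1e-6


class ParseError(ValueError):
    """Raised when a structure/trajectory file cannot be parsed."""


class TemplateError(ValueError):
    """Raised when lipid templates do not match the topology."""


@dataclass(frozen=True)
class Atom:
    atom_id: int
    atom_name: str
    residue_name: str
    residue_id: int
    element_or_bead: str = ""


@dataclass(frozen=True)
class LipidTemplate:
    """Maps atom names of one lipid residue to membrane roles.

    ``sn1_carbons``/``sn2_carbons`` are ordered from the ester end to the
    terminal methyl (or terminal tail bead); the last element of each list is
    the chain terminus.  ``aliphatic_atoms`` defaults to all chain carbons
    except the first (carbonyl) carbon of each chain.
    """

    residue_name: str
    phosphate_atom: str
    glycerol_central_atom: str
    sn1_carbons: tuple[str, ...]
    sn2_carbons: tuple[str, ...]
    aliphatic_atoms: frozenset[str] = field(default=frozenset())

    def __post_init__(self):
        sn1, sn2 = tuple(self.sn1_carbons), tuple(self.sn2_carbons)
        object.__setattr__(self, "sn1_carbons", sn1)
        object.__setattr__(self, "sn2_carbons", sn2)
        if set(sn1) & set(sn2):
            raise TemplateError(
                f"template {self.residue_name!r}: sn1 and sn2 carbon lists overlap"
            )
        if not self.aliphatic_atoms:
            object.__setattr__(
                self, "aliphatic_atoms", frozenset(sn1[1:]) | frozenset(sn2[1:])
            )
        else:
            object.__setattr__(self, "aliphatic_atoms", frozenset(self.aliphatic_atoms))

    @property
    def sn1_terminal(self) -> str:
        return self.sn1_carbons[-1]

    @property
    def sn2_terminal(self) -> str:
        return self.sn2_carbons[-1]


@dataclass
class Lipid:
    """One template-resolved lipid residue; all fields are atom indices
    (0-based positions in the topology atom order)."""

    residue_id: int
    residue_name: str
    phosphate: int
    glycerol: int
    sn1: list[int]
    sn2: list[int]
    aliphatic: frozenset[int]

    @property
    def sn1_terminal(self) -> int:
        return self.sn1[-1]

    @property
    def sn2_terminal(self) -> int:
        return self.sn2[-1]


@dataclass
class AnnotatedTopology:
    atoms: list[Atom]
    lipids: list[Lipid]
    water_oxygens: list[int]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_waters(self) -> int:
        return len(self.water_oxygens)


@dataclass
class Frame:
    time: float  # ps
    box: np.ndarray  # (3,) nm, orthorhombic
    coords: np.ndarray  # (n_atoms, 3) nm

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError(f"invalid box {self.box}: components must be > 0")


@dataclass
class Trajectory:
    frames: list[Frame]

    def __post_init__(self):
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        times = self.times
        if len(times) > 1:
            steps = np.diff(times)
            if np.any(steps <= 0):
                raise ValueError("frame times must be strictly increasing")
            ref = steps[0]
            if np.any(np.abs(steps - ref) > _REL_TIME_TOL * max(abs(ref), 1.0)):
                raise ValueError("frame times must be uniformly spaced")
        n = {f.coords.shape[0] for f in self.frames}
        if len(n) != 1:
            raise ValueError(f"frames carry inconsistent atom counts: {sorted(n)}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def dt(self) -> float | None:
        """Frame spacing in ps; ``None`` for a single-frame trajectory."""
        if len(self.frames) < 2:
            return None
        return self.frames[1].time - self.frames[0].time

    @property
    def duration(self) -> float:
        """Total sampled duration in ps (n_frames × dt for uniform spacing)."""
        if self.dt is None:
            return 0.0
        return len(self.frames) * self.dt

    @property
    def n_atoms(self) -> int:
        return self.frames[0].coords.shape[0]


# ---------------------------------------------------------------------------
# GRO
# ---------------------------------------------------------------------------

def _parse_gro_block(lines: list[str], offset: int) -> tuple[list[Atom], Frame, float | None]:
    """Parse one GRO block starting at ``lines[0]``; ``offset`` is the 1-based
    file line number of the title line (for error messages)."""
    if len(lines) < 3:
        raise ParseError(f"line {offset}: truncated GRO block")
    title = lines[0]
    time = None
    if "t=" in title:
        try:
            time = float(title.split("t=")[1].split()[0])
        except (ValueError, IndexError):
            time = None
    try:
        natoms = int(lines[1].strip())
    except ValueError as exc:
        raise ParseError(f"line {offset + 1}: cannot read atom count: {exc}") from exc
    if len(lines) < natoms + 3:
        raise ParseError(f"line {offset + 1}: GRO block declares {natoms} atoms "
                         f"but only {len(lines) - 3} atom lines follow")
    atoms: list[Atom] = []
    coords = np.empty((natoms, 3))
    for i in range(natoms):
        ln = lines[2 + i]
        lineno = offset + 2 + i
        try:
            resid = int(ln[0:5])
            resname = ln[5:10].strip()
            name = ln[10:15].strip()
            atom_id = int(ln[15:20])
            coords[i] = (float(ln[20:28]), float(ln[28:36]), float(ln[36:44]))
        except (ValueError, IndexError) as exc:
            raise ParseError(f"line {lineno}: malformed GRO atom record: {exc}") from exc
        atoms.append(Atom(atom_id, name, resname, resid, _guess_element(name)))
    box_line = lines[2 + natoms].split()
    if len(box_line) < 3:
        raise ParseError(f"line {offset + 2 + natoms}: missing or incomplete box line")
    try:
        box = np.array([float(v) for v in box_line[:3]])
    except ValueError as exc:
        raise ParseError(f"line {offset + 2 + natoms}: malformed box line: {exc}") from exc
    return atoms, Frame(time=time if time is not None else 0.0, box=box, coords=coords), time


def _guess_element(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


def read_gro(path: str | Path) -> tuple[list[Atom], Frame]:
    lines = Path(path).read_text().splitlines()
    atoms, frame, _ = _parse_gro_block(lines, 1)
    return atoms, frame


def write_gro(path: str | Path, atoms: Sequence[Atom], frame: Frame,
              title: str = "memflex") -> None:
    out = [f"{title} t= {frame.time:.3f}", f"{len(atoms):5d}"]
    for atom, xyz in zip(atoms, frame.coords):
        out.append(
            f"{atom.residue_id % 100000:5d}{atom.residue_name:<5s}"
            f"{atom.atom_name:>5s}{atom.atom_id % 100000:5d}"
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        )
    out.append(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _parse_pdb(lines: list[str]) -> tuple[list[Atom], list[np.ndarray], np.ndarray | None]:
    atoms: list[Atom] = []
    models: list[list[tuple[float, float, float]]] = []
    current: list[tuple[float, float, float]] = []
    box = None
    in_model = False
    first_model_done = False
    for lineno, ln in enumerate(lines, start=1):
        rec = ln[:6].strip()
        if rec == "CRYST1":
            try:
                box = np.array([float(ln[6:15]), float(ln[15:24]), float(ln[24:33])]) / 10.0
            except (ValueError, IndexError) as exc:
                raise ParseError(f"line {lineno}: malformed CRYST1 record: {exc}") from exc
        elif rec == "MODEL":
            in_model = True
            current = []
        elif rec == "ENDMDL":
            in_model = False
            models.append(current)
            first_model_done = True
            current = []
        elif rec in ("ATOM", "HETATM"):
            try:
                serial = int(ln[6:11])
                name = ln[12:16].strip()
                resname = ln[17:21].strip()
                resid = int(ln[22:26])
                xyz = (float(ln[30:38]) / 10.0, float(ln[38:46]) / 10.0,
                       float(ln[46:54]) / 10.0)
            except (ValueError, IndexError) as exc:
                raise ParseError(f"line {lineno}: malformed ATOM/HETATM record: {exc}") from exc
            if not first_model_done:
                element = ln[76:78].strip() if len(ln) >= 78 else ""
                atoms.append(Atom(serial, name, resname, resid,
                                  element or _guess_element(name)))
            current.append(xyz)
    if current and not first_model_done:
        models.append(current)
    elif current:
        # trailing coordinates after last ENDMDL; ignore only if empty
        models.append(current)
    coords = [np.array(m) for m in models if m]
    return atoms, coords, box


def read_pdb(path: str | Path) -> tuple[list[Atom], Frame]:
    atoms, coords, box = _parse_pdb(Path(path).read_text().splitlines())
    if not coords:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    if box is None:
        raise ParseError(f"{path}: missing CRYST1 box record")
    return atoms, Frame(time=0.0, box=box, coords=coords[0])


# ---------------------------------------------------------------------------
# frame-text
# ---------------------------------------------------------------------------

def write_frame_text(path: str | Path, traj: Trajectory | Iterable[Frame]) -> None:
    frames = traj.frames if isinstance(traj, Trajectory) else list(traj)
    out: list[str] = ["# memflex frame-text v1"]
    for fr in frames:
        out.append(f"frame {fr.time:.6f} {fr.box[0]:.6f} {fr.box[1]:.6f} {fr.box[2]:.6f}")
        for i, xyz in enumerate(fr.coords, start=1):
            out.append(f"{i} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}")
    Path(path).write_text("\n".join(out) + "\n")


def read_frame_text(path: str | Path) -> Trajectory:
    frames: list[Frame] = []
    time = box = None
    rows: list[list[float]] = []

    def flush(lineno):
        if time is None:
            return
        if not rows:
            raise ParseError(f"line {lineno}: frame block with no atom lines")
        frames.append(Frame(time=time, box=np.array(box), coords=np.array(rows)))

    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        s = ln.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split()
        if parts[0] == "frame":
            flush(lineno)
            if len(parts) != 5:
                raise ParseError(f"line {lineno}: frame header needs time + 3 box components")
            try:
                time = float(parts[1])
                box = [float(v) for v in parts[2:5]]
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed frame header: {exc}") from exc
            rows = []
        else:
            if time is None:
                raise ParseError(f"line {lineno}: coordinate line before any frame header")
            if len(parts) != 4:
                raise ParseError(f"line {lineno}: expected 'id x y z'")
            try:
                rows.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed coordinate line: {exc}") from exc
    flush(-1)
    if not frames:
        raise ParseError(f"{path}: no frames found")
    _check_atom_counts(frames)
    return Trajectory(frames)


# ---------------------------------------------------------------------------
# dispatchers
# ---------------------------------------------------------------------------

def read_structure(path: str | Path, format: str | None = None) -> tuple[list[Atom], Frame]:
    """Read a single structure; returns atoms and one frame (coordinates nm)."""
    fmt = format or _infer_format(path)
    if fmt == "gro":
        return read_gro(path)
    if fmt == "pdb":
        return read_pdb(path)
    raise ValueError(f"unsupported structure format {fmt!r}")


def _infer_format(path) -> str:
    suffix = Path(path).suffix.lower().lstrip(".")
    return {"gro": "gro", "pdb": "pdb", "txt": "frame-text", "frames": "frame-text"}.get(
        suffix, suffix)


def _check_atom_counts(frames: Sequence[Frame]) -> None:
    counts = [f.coords.shape[0] for f in frames]
    if len(set(counts)) > 1:
        raise ParseError(f"frames carry different atom counts: {sorted(set(counts))}")


def read_trajectory(paths: str | Path | Sequence[str | Path],
                    format: str | None = None,
                    dt: float | None = None) -> Trajectory:
    """Read a multi-frame trajectory from one or more files.

    Formats: ``multi-gro`` (concatenated GRO blocks; times from ``t=`` in the
    title line, else ``dt``), ``multi-model-pdb`` (MODEL/ENDMDL; times from
    ``dt``), ``frame-text`` (times carried in-file).  For formats without
    embedded times ``dt`` (ps) must be supplied for trajectories longer than
    one frame.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    fmt = format or _infer_format(paths[0])
    if fmt in ("frame-text", "txt"):
        frames: list[Frame] = []
        for p in paths:
            frames.extend(read_frame_text(p).frames)
        _check_atom_counts(frames)
        return Trajectory(frames)
    if fmt in ("multi-gro", "gro"):
        frames = []
        have_times = True
        for p in paths:
            lines = Path(p).read_text().splitlines()
            pos = 0
            while pos < len(lines) and lines[pos].strip():
                atoms, frame, t = _parse_gro_block(lines[pos:], pos + 1)
                if t is None:
                    have_times = False
                frames.append(frame)
                pos += len(atoms) + 3
                while pos < len(lines) and not lines[pos].strip():
                    pos += 1
        _check_atom_counts(frames)
        if not have_times:
            frames = _apply_dt(frames, dt)
        return Trajectory(frames)
    if fmt in ("multi-model-pdb", "pdb"):
        frames = []
        for p in paths:
            atoms, coords, box = _parse_pdb(Path(p).read_text().splitlines())
            if box is None:
                raise ParseError(f"{p}: missing CRYST1 box record")
            frames.extend(Frame(time=0.0, box=box, coords=c) for c in coords)
        _check_atom_counts(frames)
        return Trajectory(_apply_dt(frames, dt))
    raise ValueError(f"unsupported trajectory format {fmt!r}")


def _apply_dt(frames: list[Frame], dt: float | None) -> list[Frame]:
    if len(frames) > 1 and dt is None:
        raise ValueError("trajectory frames carry no times; supply dt (ps)")
    if len(frames) == 1 and dt is None:
        logger.warning("single-frame trajectory: dt undefined")
        dt = 0.0
    for i, fr in enumerate(frames):
        fr.time = i * (dt or 0.0)
    return frames


# ---------------------------------------------------------------------------
# template annotation
# ---------------------------------------------------------------------------

def apply_lipid_templates(atoms: Sequence[Atom],
                          templates: Sequence[LipidTemplate],
                          water_names: Iterable[str] = DEFAULT_WATER_NAMES,
                          ignore_residues: Iterable[str] = ()) -> AnnotatedTopology:
    """Resolve atom roles from lipid templates.

    Residues are grouped as maximal runs of identical ``(residue_id,
    residue_name)`` in file order.  Every non-water residue must be matched by
    exactly one template or listed in ``ignore_residues``.
    """
    water_names = set(water_names)
    ignore = set(ignore_residues)
    by_name = {t.residue_name: t for t in templates}
    if len(by_name) != len(templates):
        raise TemplateError("duplicate templates for the same residue name")

    lipids: list[Lipid] = []
    water_oxygens: list[int] = []
    unmatched: set[str] = set()

    for resname, resid, idxs in _iter_residues(atoms):
        if resname in water_names:
            water_oxygens.append(_pick_water_oxygen(atoms, idxs))
            continue
        if resname in ignore:
            continue
        tmpl = by_name.get(resname)
        if tmpl is None:
            unmatched.add(resname)
            continue
        name_to_idx: dict[str, int] = {}
        for i in idxs:
            name_to_idx.setdefault(atoms[i].atom_name, i)

        def resolve(name: str) -> int:
            if name not in name_to_idx:
                raise TemplateError(
                    f"residue {resname} {resid}: template atom {name!r} absent")
            return name_to_idx[name]

        sn1 = [resolve(n) for n in tmpl.sn1_carbons]
        sn2 = [resolve(n) for n in tmpl.sn2_carbons]
        aliphatic = frozenset(resolve(n) for n in tmpl.aliphatic_atoms)
        lipids.append(Lipid(
            residue_id=resid, residue_name=resname,
            phosphate=resolve(tmpl.phosphate_atom),
            glycerol=resolve(tmpl.glycerol_central_atom),
            sn1=sn1, sn2=sn2, aliphatic=aliphatic))
    if unmatched:
        raise TemplateError(
            "residues without template (add a template or list them in "
            f"ignore_residues): {sorted(unmatched)}")
    return AnnotatedTopology(atoms=list(atoms), lipids=lipids,
                             water_oxygens=water_oxygens)


def _iter_residues(atoms: Sequence[Atom]):
    """Yield (residue_name, residue_id, atom index list) for maximal runs."""
    idxs: list[int] = []
    key = None
    for i, a in enumerate(atoms):
        k = (a.residue_id, a.residue_name)
        if k != key and idxs:
            yield key[1], key[0], idxs
            idxs = []
        key = k
        idxs.append(i)
    if idxs:
        yield key[1], key[0], idxs


def _pick_water_oxygen(atoms: Sequence[Atom], idxs: list[int]) -> int:
    for i in idxs:
        if atoms[i].atom_name in ("OW", "OH2", "O", "W"):
            return i
    for i in idxs:
        if atoms[i].atom_name.startswith("O"):
            return i
    return idxs[0]  # single-bead CG water


# ---------------------------------------------------------------------------
# YAML config
# ---------------------------------------------------------------------------

def load_templates_config(path: str | Path) -> dict:
    """Load a YAML config with ``templates:``, ``water_names:``,
    ``ignore_residues:`` keys; returns a dict ready to splat into
    :func:`apply_lipid_templates` (minus ``atoms``)."""
    raw = yaml.safe_load(Path(path).read_text())
    templates = [
        LipidTemplate(
            residue_name=t["residue_name"],
            phosphate_atom=t["phosphate_atom"],
            glycerol_central_atom=t["glycerol_central_atom"],
            sn1_carbons=tuple(t["sn1_carbons"]),
            sn2_carbons=tuple(t["sn2_carbons"]),
            aliphatic_atoms=frozenset(t.get("aliphatic_atoms", ())),
        )
        for t in raw.get("templates", [])
    ]
    return {
        "templates": templates,
        "water_names": set(raw.get("water_names", DEFAULT_WATER_NAMES)),
        "ignore_residues": set(raw.get("ignore_residues", ())),
    }
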