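"""Data model for coarse-grained membrane snapshots.

The membrane is represented bead-wise, following the Martini convention of
naming beads (NC3, PO4, GL1, C1A, ...) and grouping them into lipids whose
species-level layout (headgroup beads, phosphodiester bead, ordered acyl
chains) is described by a :class:`LipidTopology`.  All coordinates are stored
in nanometres in an orthorhombic periodic box; PDB input (Angstrom) is
converted on load.

The module also provides the periodic-geometry primitives (minimum-image
distances, wrapping) and leaflet assignment that every downstream analysis
relies on, plus native GRO/PDB readers and a GRO writer.  Only orthorhombic
boxes are supported: triclinic input is rejected loudly rather than silently
sheared.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Box",
    "LipidTopology",
    "Frame",
    "Trajectory",
    "FormatError",
    "UnknownSpeciesError",
    "DegenerateGeometryError",
    "DEFAULT_TOPOLOGIES",
    "minimum_image_distance",
    "minimum_image_vector",
    "wrap_positions",
    "assign_leaflets",
    "load_frames",
    "load_topology",
    "write_frame",
]


class FormatError(ValueError):
    """A coordinate file could not be parsed (message carries the line number)."""


class UnknownSpeciesError(KeyError):
    """A residue name in a coordinate file has no topology entry."""


class DegenerateGeometryError(ValueError):
    """The geometry does not admit the requested operation (e.g. a monolayer
    offered for leaflet assignment)."""


@dataclass(frozen=True)
class Box:
    """Orthorhombic periodic box with edge lengths in nm."""

    Lx: float
    Ly: float
    Lz: float

    def __post_init__(self) -> None:
        for name in ("Lx", "Ly", "Lz"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"box length {name}={v!r} must be finite and > 0")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.Lx, self.Ly, self.Lz], dtype=float)


@dataclass(frozen=True)
class LipidTopology:
    """Bead-level layout of one lipid species.

    Parameters
    ----------
    species : str
        Species name (e.g. ``POPC``, ``PIP2_160``).
    headgroup_beads : tuple of str
        Bead names belonging to the headgroup (phosphodiester bead included
        separately below; for clustering the union of both is used).
    phosphodiester_bead : str
        Name of the phosphodiester bead, ``PO4`` for every species in scope.
        This is the default reference bead for leaflet assignment.
    chains : tuple of tuple of str
        Ordered acyl-chain bead names, glycerol-proximal bead first.
    anchor_bead : str
        Glycerol-proximal bead used as the molecular position reference for
        distance-resolved analyses (``GL1`` for all stock species).
    resname : str
        Residue name used in coordinate files (max 5 characters; defaults
        to the species name truncated to 5).
    """

    species: str
    headgroup_beads: tuple[str, ...]
    phosphodiester_bead: str
    chains: tuple[tuple[str, ...], ...]
    anchor_bead: str = "GL1"
    resname: str = ""

    def __post_init__(self) -> None:
        if not self.resname:
            object.__setattr__(self, "resname", self.species[:5])
        if len(self.resname) > 5:
            raise ValueError(f"resname {self.resname!r} exceeds 5 characters")
        if not self.chains or any(len(c) == 0 for c in self.chains):
            raise ValueError(f"{self.species}: chain lists must be non-empty")
        seen: set[str] = set()
        for chain in self.chains:
            for bead in chain:
                if bead in seen:
                    raise ValueError(
                        f"{self.species}: bead {bead} appears in more than one chain"
                    )
                seen.add(bead)

    @property
    def all_beads(self) -> tuple[str, ...]:
        """Every bead of the species, in canonical file order."""
        out = list(self.headgroup_beads)
        if self.phosphodiester_bead not in out:
            out.append(self.phosphodiester_bead)
        if self.anchor_bead not in out:
            out.append(self.anchor_bead)
        for chain in self.chains:
            out.extend(chain)
        return tuple(dict.fromkeys(out))

    @property
    def contact_beads(self) -> tuple[str, ...]:
        """Beads defining headgroup-level contact (headgroup + phosphodiester)."""
        out = list(self.headgroup_beads)
        if self.phosphodiester_bead not in out:
            out.append(self.phosphodiester_bead)
        return tuple(out)


def _martini_popc() -> LipidTopology:
    return LipidTopology(
        species="POPC",
        headgroup_beads=("NC3",),
        phosphodiester_bead="PO4",
        chains=(("C1A", "D2A", "C3A", "C4A"), ("C1B", "C2B", "C3B", "C4B")),
    )


def _pip2(
    species: str, resname: str, sn1: tuple[str, ...], sn2: tuple[str, ...]
) -> LipidTopology:
    return LipidTopology(
        species=species,
        headgroup_beads=("C1", "C2", "C3", "P4", "P5"),
        phosphodiester_bead="PO4",
        chains=(sn1, sn2),
        resname=resname,
    )


#: Stock Martini-style topologies: POPC plus the three PI(4,5)P2 acyl-chain
#: variants studied (16:0/16:0, 18:1/18:1, 18:0/20:4).
DEFAULT_TOPOLOGIES: dict[str, LipidTopology] = {
    t.species: t
    for t in (
        _martini_popc(),
        _pip2(
            "PIP2_160", "DPP2",
            ("C1A", "C2A", "C3A", "C4A"), ("C1B", "C2B", "C3B", "C4B"),
        ),
        _pip2(
            "PIP2_181", "DOP2",
            ("C1A", "D2A", "C3A", "C4A"), ("C1B", "D2B", "C3B", "C4B"),
        ),
        _pip2(
            "PIP2_SAPI", "SAP2",
            ("C1A", "C2A", "C3A", "C4A", "C5A"), ("D1B", "D2B", "D3B", "D4B"),
        ),
    )
}


@dataclass
class Frame:
    """One coarse-grained membrane snapshot.

    Beads are stored as flat arrays; ``lipid_index`` maps each bead to its
    lipid, ``species`` gives the species name per lipid, and ``leaflet``
    labels each lipid ``upper``/``lower``/``unassigned``.
    """

    box: Box
    positions: np.ndarray  # (n_beads, 3) nm
    bead_names: np.ndarray  # (n_beads,) str
    lipid_index: np.ndarray  # (n_beads,) int
    species: np.ndarray  # (n_lipids,) str
    topology: Mapping[str, LipidTopology]
    leaflet: np.ndarray | None = None  # (n_lipids,) str
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_beads, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        self.bead_names = np.asarray(self.bead_names, dtype=object)
        self.lipid_index = np.asarray(self.lipid_index, dtype=int)
        self.species = np.asarray(self.species, dtype=object)
        if len(self.bead_names) != len(self.positions) or len(self.lipid_index) != len(
            self.positions
        ):
            raise ValueError("bead arrays must share one length")
        if self.leaflet is None:
            self.leaflet = np.full(len(self.species), "unassigned", dtype=object)
        else:
            self.leaflet = np.asarray(self.leaflet, dtype=object)
        for sp in np.unique(self.species):
            if sp not in self.topology:
                raise UnknownSpeciesError(sp)

    # -- bookkeeping ------------------------------------------------------

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_lipids(self) -> int:
        return len(self.species)

    def lipids_matching(self, species: str) -> np.ndarray:
        """Lipid indices whose species equals *species* or starts with it.

        The prefix rule lets ``"PIP2"`` select any of the three PI(4,5)P2
        acyl-chain variants.
        """
        sp = self.species.astype(str)
        return np.flatnonzero((sp == species) | np.char.startswith(sp, species + "_")
                              | np.char.startswith(sp, species))

    def beads_of_lipid(self, lipid: int) -> np.ndarray:
        return np.flatnonzero(self.lipid_index == lipid)

    def bead_position(self, lipid: int, bead_name: str) -> np.ndarray:
        """Position of a named bead of one lipid."""
        mask = (self.lipid_index == lipid) & (self.bead_names == bead_name)
        idx = np.flatnonzero(mask)
        if len(idx) != 1:
            raise KeyError(f"lipid {lipid} has {len(idx)} beads named {bead_name}")
        return self.positions[idx[0]]

    def positions_by_bead(self, lipids: np.ndarray, bead_name: str) -> np.ndarray:
        """Positions of bead *bead_name* for each lipid in *lipids* (in order)."""
        out = np.empty((len(lipids), 3), dtype=float)
        sel = np.flatnonzero(self.bead_names == bead_name)
        by_lipid = {int(self.lipid_index[i]): i for i in sel}
        for k, li in enumerate(lipids):
            try:
                out[k] = self.positions[by_lipid[int(li)]]
            except KeyError:
                raise KeyError(f"lipid {li} has no bead named {bead_name}") from None
        return out

    def census(self) -> dict[str, int]:
        """Lipid counts per species."""
        vals, counts = np.unique(self.species.astype(str), return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def copy(self) -> "Frame":
        return Frame(
            box=self.box,
            positions=self.positions.copy(),
            bead_names=self.bead_names.copy(),
            lipid_index=self.lipid_index.copy(),
            species=self.species.copy(),
            topology=self.topology,
            leaflet=self.leaflet.copy(),
            time=self.time,
        )


@dataclass
class Trajectory:
    """Ordered frames sharing one topology."""

    frames: list[Frame]
    stride_ps: float | None = None

    def __post_init__(self) -> None:
        times = [f.time for f in self.frames]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be monotonically increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]


# ---------------------------------------------------------------------------
# periodic geometry
# ---------------------------------------------------------------------------


def minimum_image_vector(p: np.ndarray, q: np.ndarray, box: Box) -> np.ndarray:
    """Minimum-image displacement q - p (vectorised over leading axes)."""
    d = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
    L = box.lengths
    return d - L * np.round(d / L)


def minimum_image_distance(
    p: np.ndarray, q: np.ndarray, box: Box, in_plane: bool = False
) -> float | np.ndarray:
    """Minimum-image Euclidean distance between positions *p* and *q*.

    With ``in_plane=True`` only the x,y components contribute (distances
    between leaflet-lateral objects).
    """
    d = minimum_image_vector(p, q, box)
    if in_plane:
        d = d[..., :2]
    return np.sqrt(np.sum(d * d, axis=-1))


def wrap_positions(positions: np.ndarray, box: Box) -> np.ndarray:
    """Wrap positions into [0, L) along each axis."""
    return np.mod(positions, box.lengths)


def make_lipids_whole(frame: Frame) -> Frame:
    """Shift beads so each lipid is contiguous under minimum image.

    The first bead of each lipid anchors the molecule; every other bead is
    placed at its minimum-image position relative to that anchor.
    """
    out = frame.copy()
    L = frame.box.lengths
    order = np.argsort(out.lipid_index, kind="stable")
    pos = out.positions
    for lipid in np.unique(out.lipid_index):
        idx = np.flatnonzero(out.lipid_index == lipid)
        anchor = pos[idx[0]]
        d = pos[idx] - anchor
        pos[idx] = anchor + d - L * np.round(d / L)
    del order
    return out


# ---------------------------------------------------------------------------
# leaflet assignment
# ---------------------------------------------------------------------------


def assign_leaflets(
    frame: Frame,
    reference_bead: str | None = None,
    thermal_width: float = 0.5,
    grid_spacing: float = 3.0,
) -> Frame:
    """Split lipids into upper/lower leaflets by reference-bead height.

    Each lipid is located by its reference bead (default: the species'
    phosphodiester bead, PO4).  For flat membranes the split is by sign of z
    relative to the global midplane.  When the membrane undulates strongly —
    the lateral variation of the local mid-surface exceeds half the apparent
    monolayer thickness — a grid-local midplane (cell-mean reference-bead
    height, cell edge ``grid_spacing`` nm) is used instead so that lipids on
    the flanks of an undulation are not misassigned.

    Raises
    ------
    DegenerateGeometryError
        If all reference beads sit within one ``thermal_width`` of the
        midplane (e.g. a monolayer), or if either leaflet would be empty.
    """
    out = frame.copy()
    lipids = np.arange(out.n_lipids)
    ref = np.empty((out.n_lipids, 3), dtype=float)
    for sp in np.unique(out.species.astype(str)):
        bead = reference_bead or out.topology[sp].phosphodiester_bead
        sel = np.flatnonzero(out.species.astype(str) == sp)
        ref[sel] = out.positions_by_bead(sel, bead)

    z = ref[:, 2]
    mid_global = float(np.mean(z))
    half_thickness = float(np.median(np.abs(z - mid_global)))
    if half_thickness < thermal_width:
        raise DegenerateGeometryError(
            "all reference beads lie within one thermal width of the midplane; "
            "cannot split into two leaflets (monolayer or collapsed geometry?)"
        )

    # Local mid-surface on a coarse periodic grid; falls back to the global
    # midplane for cells without beads.
    box = out.box
    nx = max(1, int(round(box.Lx / grid_spacing)))
    ny = max(1, int(round(box.Ly / grid_spacing)))
    xy = np.mod(ref[:, :2], [box.Lx, box.Ly])
    ix = np.minimum((xy[:, 0] / box.Lx * nx).astype(int), nx - 1)
    iy = np.minimum((xy[:, 1] / box.Ly * ny).astype(int), ny - 1)
    cell = ix * ny + iy
    sums = np.bincount(cell, weights=z, minlength=nx * ny)
    counts = np.bincount(cell, minlength=nx * ny)
    local_mid = np.where(counts > 0, sums / np.maximum(counts, 1), mid_global)
    amplitude = float(np.max(np.abs(local_mid[counts > 0] - mid_global))) if np.any(
        counts > 0
    ) else 0.0

    midplane = local_mid[cell] if amplitude > half_thickness / 2 else mid_global
    upper = z > midplane
    if not (np.any(upper) and np.any(~upper)):
        raise DegenerateGeometryError("leaflet split left one side empty")
    out.leaflet = np.where(upper, "upper", "lower").astype(object)
    return out


def leaflet_lipids(frame: Frame, leaflet: str) -> np.ndarray:
    """Indices of lipids carrying the given leaflet label."""
    if frame.leaflet is None:
        raise ValueError("leaflets not assigned")
    return np.flatnonzero(frame.leaflet.astype(str) == leaflet)


# ---------------------------------------------------------------------------
# coordinate-file I/O
# ---------------------------------------------------------------------------


def load_topology(path: str | os.PathLike) -> dict[str, LipidTopology]:
    """Read a species→bead-layout map from a YAML config file.

    Expected layout per species::

        POPC:
          headgroup: [NC3]
          phosphodiester: PO4
          anchor: GL1
          chains:
            - [C1A, D2A, C3A, C4A]
            - [C1B, C2B, C3B, C4B]
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out: dict[str, LipidTopology] = {}
    for name, entry in raw.items():
        out[name] = LipidTopology(
            species=name,
            headgroup_beads=tuple(entry.get("headgroup", ())),
            phosphodiester_bead=entry.get("phosphodiester", "PO4"),
            chains=tuple(tuple(c) for c in entry["chains"]),
            anchor_bead=entry.get("anchor", "GL1"),
            resname=entry.get("resname", ""),
        )
    return out


def _parse_gro_box(line: str, lineno: int) -> Box:
    fields = line.split()
    try:
        vals = [float(v) for v in fields]
    except ValueError as exc:
        raise FormatError(f"line {lineno}: unparseable box line {line!r}") from exc
    if len(vals) == 3:
        return Box(*vals)
    if len(vals) == 9:
        if any(abs(v) > 1e-9 for v in vals[3:]):
            raise FormatError(
                f"line {lineno}: triclinic box vectors are not supported"
            )
        return Box(*vals[:3])
    raise FormatError(f"line {lineno}: box line must have 3 or 9 numbers")


def _read_gro_stream(lines: list[str]) -> Iterable[dict]:
    """Yield raw frame dicts from concatenated GRO text."""
    i = 0
    n_total = len(lines)
    while i < n_total:
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i].rstrip("\n")
        try:
            n_atoms = int(lines[i + 1].split()[0])
        except (IndexError, ValueError) as exc:
            raise FormatError(
                f"line {i + 2}: expected atom count, got {lines[i + 1]!r}"
            ) from exc
        atom_lines = lines[i + 2 : i + 2 + n_atoms]
        if len(atom_lines) < n_atoms:
            raise FormatError(f"line {i + 2}: truncated frame ({n_atoms} atoms declared)")
        box_lineno = i + 2 + n_atoms
        if box_lineno >= n_total:
            raise FormatError(f"line {box_lineno + 1}: missing box line")
        records = []
        for k, line in enumerate(atom_lines):
            lineno = i + 3 + k
            try:
                resid = int(line[0:5])
                resname = line[5:10].strip()
                atomname = line[10:15].strip()
                x = float(line[20:28])
                y = float(line[28:36])
                z = float(line[36:44])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"line {lineno}: unparseable GRO atom line") from exc
            records.append((resid, resname, atomname, x, y, z))
        box = _parse_gro_box(lines[box_lineno], box_lineno + 1)
        time = 0.0
        if "t=" in title:
            try:
                time = float(title.split("t=")[1].split()[0])
            except (IndexError, ValueError):
                time = 0.0
        yield {"records": records, "box": box, "time": time}
        i = box_lineno + 1


def _read_pdb_stream(lines: list[str]) -> Iterable[dict]:
    """Yield raw frame dicts from PDB text (ATOM/HETATM records, Angstrom)."""
    box: Box | None = None
    records: list[tuple] = []
    model_open = False
    n_models = 0
    for lineno, line in enumerate(lines, start=1):
        tag = line[:6].strip()
        if tag == "CRYST1":
            try:
                a, b, c = float(line[6:15]), float(line[15:24]), float(line[24:33])
                al, be, ga = float(line[33:40]), float(line[40:47]), float(line[47:54])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: unparseable CRYST1") from exc
            if any(abs(ang - 90.0) > 1e-3 for ang in (al, be, ga)):
                raise FormatError(f"line {lineno}: non-orthorhombic cell rejected")
            box = Box(a / 10.0, b / 10.0, c / 10.0)
        elif tag == "MODEL":
            model_open = True
            records = []
        elif tag in ("ATOM", "HETATM"):
            try:
                atomname = line[12:16].strip()
                resname = line[17:21].strip()
                resid = int(line[22:26])
                x = float(line[30:38]) / 10.0
                y = float(line[38:46]) / 10.0
                z = float(line[46:54]) / 10.0
            except (ValueError, IndexError) as exc:
                raise FormatError(f"line {lineno}: unparseable ATOM record") from exc
            records.append((resid, resname, atomname, x, y, z))
        elif tag == "ENDMDL":
            if box is None:
                raise FormatError(f"line {lineno}: no CRYST1 box before coordinates")
            yield {"records": records, "box": box, "time": float(n_models)}
            n_models += 1
            records = []
            model_open = False
    if records:
        if box is None:
            raise FormatError("no CRYST1 box in PDB input")
        yield {"records": records, "box": box, "time": float(n_models)}


def _frame_from_records(raw: dict, topology: Mapping[str, LipidTopology]) -> Frame:
    records = raw["records"]
    if not records:
        raise FormatError("frame contains no atoms")
    resids = [r[0] for r in records]
    resnames = [r[1] for r in records]
    # species resolve by coordinate-file residue name (or species name itself)
    by_resname = {t.resname: t.species for t in topology.values()}
    # new lipid whenever resid or resname changes (resids wrap at 100000 in GRO)
    lipid_index = np.zeros(len(records), dtype=int)
    species_list: list[str] = []
    current = -1
    for k in range(len(records)):
        if k == 0 or resids[k] != resids[k - 1] or resnames[k] != resnames[k - 1]:
            current += 1
            name = resnames[k]
            if name in topology:
                species_list.append(name)
            elif name in by_resname:
                species_list.append(by_resname[name])
            else:
                raise UnknownSpeciesError(
                    f"residue {name!r} has no topology entry"
                )
        lipid_index[k] = current
    frame = Frame(
        box=raw["box"],
        positions=np.array([r[3:6] for r in records], dtype=float),
        bead_names=np.array([r[2] for r in records], dtype=object),
        lipid_index=lipid_index,
        species=np.array(species_list, dtype=object),
        topology=topology,
        time=raw["time"],
    )
    return make_lipids_whole(frame)


def load_frames(
    path: str | os.PathLike,
    topology: Mapping[str, LipidTopology] | None = None,
    frame_range: slice | None = None,
) -> Trajectory:
    """Load a Trajectory from a GRO/PDB file or a directory of frame files.

    Multi-frame input is either a concatenated GRO file, a multi-MODEL PDB,
    or a directory whose ``*.gro``/``*.pdb`` files are read in sorted order.
    ``frame_range`` (a slice) selects frames after reading.
    """
    topology = topology if topology is not None else DEFAULT_TOPOLOGIES
    p = Path(path)
    raws: list[dict] = []
    if p.is_dir():
        files = sorted(
            f for f in p.iterdir() if f.suffix.lower() in (".gro", ".pdb")
        )
        if not files:
            raise FormatError(f"directory {p} contains no .gro/.pdb files")
        for f in files:
            raws.extend(_read_any(f))
    else:
        raws = list(_read_any(p))
    frames = [_frame_from_records(r, topology) for r in raws]
    for k, f in enumerate(frames):
        if f.time == 0.0 and k > 0:
            f.time = float(k)
    if frame_range is not None:
        frames = frames[frame_range]
    if not frames:
        raise FormatError(f"{p}: no frames selected")
    return Trajectory(frames=frames)


def _read_any(p: Path) -> Iterable[dict]:
    lines = p.read_text().splitlines()
    if p.suffix.lower() == ".pdb":
        return list(_read_pdb_stream(lines))
    return list(_read_gro_stream(lines))


def write_frame(frame: Frame, path: str | os.PathLike, append: bool = False) -> None:
    """Write a frame as fixed-column GRO (nm).

    ``load_frames(write_frame(f))`` is the identity within the format's
    0.001 nm coordinate precision.
    """
    if frame.n_beads == 0:
        raise ValueError("refusing to write a frame with zero beads")
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write(f"pipnano frame t= {frame.time:.3f}\n")
        fh.write(f"{frame.n_beads}\n")
        for k in range(frame.n_beads):
            resid = (int(frame.lipid_index[k]) + 1) % 100000
            sp = str(frame.species[frame.lipid_index[k]])
            resname = frame.topology[sp].resname if sp in frame.topology else sp[:5]
            atom = str(frame.bead_names[k])[:5]
            x, y, z = frame.positions[k]
            fh.write(
                f"{resid:5d}{resname:<5s}{atom:>5s}{(k + 1) % 100000:5d}"
                f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
            )
        fh.write(f"{frame.box.Lx:10.5f}{frame.box.Ly:10.5f}{frame.box.Lz:10.5f}\n")


def write_trajectory(traj: Trajectory, path: str | os.PathLike) -> None:
    """Write all frames as concatenated GRO."""
    first = True
    for frame in traj:
        write_frame(frame, path, append=not first)
        first = False
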