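"""Trajectory/configuration data model and plain-text readers/writers.

The container types are deliberately small: a :class:`Configuration` is an
``(N, 3)`` coordinate array (Å) with per-atom element symbols, atom names
and named index groups; a :class:`Trajectory` is a stack of configurations
sharing one topology, with strictly increasing times in ps.  Atom indexing
is 0-based everywhere; PDB serial numbers are mapped on read.

Two text formats are supported:

* multi-frame XYZ, with an extended comment line carrying ``t=<ps>``;
* a minimal PDB v3.3 dialect (ATOM/HETATM records only; occupancy,
  altLoc and CONECT are ignored).  Groups are auto-populated per residue
  name and from atom-name patterns (``CA`` → ``backbone_ref``, water
  oxygens → ``water_O``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

from .units import mass_of

__all__ = [
    "Configuration",
    "Trajectory",
    "FormatError",
    "read_xyz",
    "write_xyz",
    "read_pdb_minimal",
    "write_pdb_minimal",
]


class FormatError(ValueError):
    """Raised for malformed XYZ/PDB input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass
class Configuration:
    """One snapshot: coordinates in Å plus atom labels and named groups."""

    coordinates: np.ndarray
    elements: list[str]
    names: list[str] = field(default_factory=list)
    groups: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an (N, 3) array")
        n = self.coordinates.shape[0]
        if n < 1:
            raise ValueError("a Configuration needs at least one atom")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if len(self.elements) != n:
            raise ValueError("elements length does not match atom count")
        if not self.names:
            self.names = list(self.elements)
        if len(self.names) != n:
            raise ValueError("names length does not match atom count")
        clean = {}
        for key, idx in self.groups.items():
            idx = np.asarray(idx, dtype=np.intp)
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise ValueError(f"group {key!r} indexes outside [0, {n})")
            clean[key] = idx
        self.groups = clean

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    @property
    def masses(self) -> np.ndarray:
        return np.array([mass_of(e) for e in self.elements])

    def group(self, name: str) -> np.ndarray:
        try:
            return self.groups[name]
        except KeyError:
            raise KeyError(
                f"no group {name!r}; available: {sorted(self.groups)}"
            ) from None

    def select(self, selection: str | Sequence[int]) -> np.ndarray:
        """Resolve a selection (group name or explicit indices) to indices."""
        if isinstance(selection, str):
            return self.group(selection)
        return np.asarray(selection, dtype=np.intp)

    def with_coordinates(self, coordinates: np.ndarray) -> "Configuration":
        return Configuration(
            np.array(coordinates, dtype=float),
            list(self.elements),
            list(self.names),
            dict(self.groups),
        )

    def copy(self) -> "Configuration":
        return self.with_coordinates(self.coordinates.copy())


class Trajectory:
    """Ordered frames sharing one topology; coordinates kept as one array."""

    def __init__(
        self,
        coords: np.ndarray,
        elements: list[str],
        names: list[str] | None = None,
        groups: Mapping[str, np.ndarray] | None = None,
        times: np.ndarray | None = None,
    ):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must be (n_frames, N, 3)")
        self.coords = coords
        template = Configuration(
            coords[0] if len(coords) else np.zeros((1, 3)),
            list(elements),
            list(names) if names else [],
            dict(groups) if groups else {},
        )
        self.elements = template.elements
        self.names = template.names
        self.groups = template.groups
        if times is None:
            times = np.arange(len(coords), dtype=float)
        times = np.asarray(times, dtype=float)
        if len(times) != len(coords):
            raise ValueError("times length must equal frame count")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        self.times = times

    @classmethod
    def from_configurations(
        cls, frames: Sequence[Configuration], times: np.ndarray | None = None
    ) -> "Trajectory":
        if not frames:
            raise ValueError("need at least one frame")
        first = frames[0]
        for i, f in enumerate(frames[1:], start=1):
            if f.n_atoms != first.n_atoms or f.elements != first.elements:
                raise ValueError(f"frame {i} topology differs from frame 0")
        coords = np.stack([f.coordinates for f in frames])
        return cls(coords, first.elements, first.names, first.groups, times)

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> Configuration:
        return Configuration(
            self.coords[i].copy(), list(self.elements), list(self.names), dict(self.groups)
        )

    def __iter__(self) -> Iterator[Configuration]:
        for i in range(len(self)):
            yield self.frame(i)

    def with_groups(self, groups: Mapping[str, np.ndarray]) -> "Trajectory":
        merged = dict(self.groups)
        merged.update(groups)
        return Trajectory(self.coords, self.elements, self.names, merged, self.times)


_TIME_RE = re.compile(r"\bt\s*=\s*([-+0-9.eE]+)")


def read_xyz(path: str | Path, groups: Mapping[str, np.ndarray] | None = None) -> Trajectory:
    """Read a (multi-frame) XYZ file into a :class:`Trajectory`.

    The comment line of each frame is scanned for ``t=<ps>``; when absent,
    times default to the frame index in ps.  All frames must have the same
    atom count and element order.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[np.ndarray] = []
    elements: list[str] | None = None
    times: list[float] = []
    any_time = False
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            count = int(lines[ln].strip())
        except ValueError:
            raise FormatError(f"expected an atom count, got {lines[ln]!r}", ln + 1)
        if count < 1:
            raise FormatError("atom count must be >= 1", ln + 1)
        if ln + 2 + count > len(lines):
            raise FormatError("truncated frame", len(lines))
        comment = lines[ln + 1]
        m = _TIME_RE.search(comment)
        if m:
            times.append(float(m.group(1)))
            any_time = True
        else:
            times.append(float(len(frames)))
        frame_elems: list[str] = []
        xyz = np.empty((count, 3))
        for k in range(count):
            idx = ln + 2 + k
            if idx >= len(lines):
                raise FormatError("truncated frame", len(lines))
            parts = lines[idx].split()
            if len(parts) < 4:
                raise FormatError(f"malformed atom line {lines[idx]!r}", idx + 1)
            frame_elems.append(parts[0])
            try:
                xyz[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise FormatError(f"non-numeric coordinate in {lines[idx]!r}", idx + 1)
        if elements is None:
            elements = frame_elems
        elif frame_elems != elements:
            raise FormatError(
                f"frame {len(frames)} has different atoms than frame 0", ln + 1
            )
        frames.append(xyz)
        ln += 2 + count
    if not frames:
        raise FormatError("no frames found in XYZ file", 1)
    t = np.asarray(times)
    if not any_time:
        t = np.arange(len(frames), dtype=float)
    return Trajectory(np.stack(frames), elements, groups=groups, times=t)


def write_xyz(path: str | Path, traj: Trajectory | Configuration, decimals: int = 6) -> None:
    """Write a trajectory (or one configuration) as multi-frame XYZ."""
    if isinstance(traj, Configuration):
        traj = Trajectory.from_configurations([traj])
    fmt = f"{{:s}} {{:.{decimals}f}} {{:.{decimals}f}} {{:.{decimals}f}}\n"
    with open(path, "w") as fh:
        for i in range(len(traj)):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"frame {i} t={traj.times[i]:.6f} ps\n")
            for el, xyz in zip(traj.elements, traj.coords[i]):
                fh.write(fmt.format(el, *xyz))


_WATER_RESNAMES = {"HOH", "WAT", "SOL", "TIP", "TIP3", "SPC"}


def _element_from_pdb(name: str, resname: str) -> str:
    stripped = name.strip()
    if resname.strip() in _WATER_RESNAMES and stripped.startswith("O"):
        return "O"
    m = re.match(r"[A-Za-z]", stripped)
    return m.group(0).upper() if m else "C"


def read_pdb_minimal(path: str | Path) -> Configuration:
    """Read ATOM/HETATM records of a PDB v3.3 file into a Configuration.

    Groups are auto-populated: one per residue name (``res_<NAME>``), one
    per residue (``<NAME><resSeq>``, e.g. ``TYR177``), plus ``backbone_ref``
    (atoms named CA outside water) and ``water_O`` (water oxygens).
    """
    coords: list[list[float]] = []
    elements: list[str] = []
    names: list[str] = []
    groups: dict[str, list[int]] = {}
    backbone: list[int] = []
    water_o: list[int] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        record = line[:6].strip()
        if record not in ("ATOM", "HETATM"):
            continue
        if len(line) < 54:
            raise FormatError("ATOM/HETATM record shorter than coordinate fields", ln)
        name = line[12:16]
        resname = line[17:20]
        resseq = line[22:26].strip()
        try:
            xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        except ValueError:
            raise FormatError(f"non-numeric coordinate field in {line!r}", ln)
        i = len(coords)
        coords.append(xyz)
        element_col = line[76:78].strip() if len(line) >= 78 else ""
        elements.append(element_col.capitalize() or _element_from_pdb(name, resname))
        names.append(name.strip())
        rn = resname.strip() or "UNK"
        groups.setdefault(f"res_{rn}", []).append(i)
        if resseq:
            groups.setdefault(f"{rn}{resseq}", []).append(i)
        if rn in _WATER_RESNAMES:
            if name.strip().startswith("O"):
                water_o.append(i)
        elif name.strip() == "CA":
            backbone.append(i)
    if not coords:
        raise FormatError("no ATOM/HETATM records found", 1)
    groups["backbone_ref"] = backbone
    groups["water_O"] = water_o
    return Configuration(
        np.asarray(coords),
        elements,
        names,
        {k: np.asarray(v, dtype=np.intp) for k, v in groups.items()},
    )


def write_pdb_minimal(
    path: str | Path,
    config: Configuration,
    resnames: Sequence[str] | None = None,
    resseqs: Sequence[int] | None = None,
) -> None:
    """Write a Configuration as fixed-width ATOM records (PDB v3.3 subset)."""
    n = config.n_atoms
    if resnames is None:
        resnames = ["MOL"] * n
    if resseqs is None:
        resseqs = [1] * n
    with open(path, "w") as fh:
        for i in range(n):
            x, y, z = config.coordinates[i]
            name = config.names[i][:4]
            fh.write(
                f"ATOM  {i + 1:5d} {name:<4s} {resnames[i][:3]:<3s} A{resseqs[i]:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{config.elements[i]:>2s}\n"
            )
        fh.write("END\n")
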