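"""Residue-annotated structures: PDB read/write, plain-text trajectories, selections.

Coordinates are Angstrom in PDB files and nanometre everywhere inside the
package; the conversion is an exact factor 10 at the file boundary.  The PDB
support is deliberately a narrow fixed-column v3.3 ATOM/HETATM subset — enough
to carry the pseudo-residues the order-parameter metrics need — with strict,
line-numbered parse errors.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptySelectionError, ParseError, ValidationError

#: standard atomic masses (amu) for elements this package encounters
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "F": 18.998, "CL": 35.45, "BR": 79.904,
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    res_name: str
    chain: str
    res_number: int
    element: str
    mass: float
    coord: tuple[float, float, float]  # nm
    record: str = "ATOM"


@dataclass
class Structure:
    """An ordered list of atoms with unique (chain, residue number, atom name)."""

    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for a in self.atoms:
            key = (a.chain, a.res_number, a.name)
            if key in seen:
                raise ValidationError(f"duplicate atom {key}")
            seen.add(key)
            if not all(np.isfinite(a.coord)):
                raise ValidationError(f"non-finite coordinate on atom {key}")

    def __len__(self):
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) array in nm, in file order."""
        return np.array([a.coord for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def residue_numbers(self) -> set[int]:
        return {a.res_number for a in self.atoms}

    def chains(self) -> list[str]:
        out = []
        for a in self.atoms:
            if a.chain not in out:
                out.append(a.chain)
        return out

    def with_coordinates(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValidationError("coordinate array shape mismatch")
        atoms = [
            Atom(a.serial, a.name, a.res_name, a.chain, a.res_number,
                 a.element, a.mass, tuple(xyz), a.record)
            for a, xyz in zip(self.atoms, coords)
        ]
        return Structure(atoms)


@dataclass
class Selection:
    """Ordered atom indices into a parent structure."""

    structure: Structure
    indices: tuple[int, ...]
    label: str = ""

    def __post_init__(self):
        n = len(self.structure)
        for i in self.indices:
            if not (0 <= i < n):
                raise ValidationError(f"selection index {i} out of range")

    def __len__(self):
        return len(self.indices)

    def coordinates(self, frame: np.ndarray | None = None) -> np.ndarray:
        """Selected coordinates (nm), from ``frame`` (n_atoms,3) if given."""
        src = self.structure.coordinates if frame is None else np.asarray(frame)
        return src[list(self.indices)]

    def masses(self) -> np.ndarray:
        return self.structure.masses[list(self.indices)]


def _infer_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        raise ValueError("empty atom name")
    if len(name) >= 2 and name[:2].upper() in ("CL", "BR", "SE") and \
            name[:2].upper() in ATOMIC_MASSES:
        return name[:2].upper()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def read_pdb(source) -> Structure:
    """Parse ATOM/HETATM records from a path, file object or string buffer.

    Coordinates are converted A -> nm; the element is taken from columns
    77-78 when present, otherwise inferred from the atom name; masses come
    from :data:`ATOMIC_MASSES`.  Alternate locations keep the
    highest-occupancy conformer (tie: first encountered).
    """
    close = False
    if isinstance(source, (str,)) and "\n" in source:
        fh = io.StringIO(source)
    elif hasattr(source, "read"):
        fh = source
    else:
        fh = open(source)
        close = True
    try:
        atoms: list[Atom] = []
        best_occ: dict[tuple, tuple[float, int]] = {}  # altloc bookkeeping
        n_lines = 0
        for lineno, raw in enumerate(fh, start=1):
            n_lines += 1
            rec = raw[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            line = raw.rstrip("\n")
            if len(line) < 54:
                raise ParseError("truncated ATOM/HETATM record", lineno)
            try:
                serial = int(line[6:11])
            except ValueError:
                raise ParseError(f"non-numeric serial {line[6:11]!r}", lineno)
            name = line[12:16].strip()
            altloc = line[16].strip()
            res_name = line[17:20].strip()
            chain = line[21].strip() or " "
            try:
                res_number = int(line[22:26])
            except ValueError:
                raise ParseError(f"non-numeric residue number {line[22:26]!r}", lineno)
            xyz = []
            for lo, hi, label in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                try:
                    xyz.append(float(line[lo:hi]) / 10.0)  # A -> nm
                except ValueError:
                    raise ParseError(
                        f"non-numeric {label} field {line[lo:hi]!r}", lineno)
            try:
                occupancy = float(line[54:60]) if line[54:60].strip() else 1.0
            except ValueError:
                raise ParseError(f"non-numeric occupancy {line[54:60]!r}", lineno)
            element = line[76:78].strip().upper() if len(line) >= 77 else ""
            if not element:
                try:
                    element = _infer_element(name)
                except ValueError as exc:
                    raise ParseError(str(exc), lineno)
            if element not in ATOMIC_MASSES:
                raise ParseError(f"unknown element {element!r}", lineno)
            key = (chain, res_number, name)
            if altloc:
                prev = best_occ.get(key)
                if prev is not None:
                    prev_occ, prev_idx = prev
                    if occupancy > prev_occ:
                        atoms[prev_idx] = Atom(
                            serial, name, res_name, chain, res_number,
                            element, ATOMIC_MASSES[element], tuple(xyz), rec)
                        best_occ[key] = (occupancy, prev_idx)
                    continue
                best_occ[key] = (occupancy, len(atoms))
            atoms.append(Atom(serial, name, res_name, chain, res_number,
                              element, ATOMIC_MASSES[element], tuple(xyz), rec))
        if n_lines == 0:
            raise ParseError("empty PDB file")
        return Structure(atoms)
    finally:
        if close:
            fh.close()


def write_pdb(structure: Structure, sink) -> None:
    """Write fixed-column ATOM/HETATM records (nm -> A, 3 decimals) plus END."""
    close = False
    if hasattr(sink, "write"):
        fh = sink
    else:
        fh = open(sink, "w")
        close = True
    try:
        fh.write("REMARK   generated by azogate\n")
        for a in structure.atoms:
            if a.res_number > 9999:
                raise ValidationError(
                    f"residue number {a.res_number} exceeds the PDB format limit 9999")
            if a.serial > 99999:
                raise ValidationError(f"serial {a.serial} exceeds the PDB format limit")
            x, y, z = (10.0 * v for v in a.coord)
            if max(abs(x), abs(y), abs(z)) >= 10000:
                raise ValidationError("coordinate out of PDB fixed-column range")
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            fh.write(
                f"{a.record:<6s}{a.serial:>5d} {name:<4s}{'':1s}{a.res_name:>3s} "
                f"{a.chain:1s}{a.res_number:>4d}{'':4s}"
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"{'':10s}{a.element:>2s}\n")
        fh.write("END\n")
    finally:
        if close:
            fh.close()


def write_trajectory(traj, sink) -> None:
    """Plain-text multi-frame format.

    Per frame: ``FRAME <index> <time_ps> <n_atoms>`` then one ``x y z`` line
    per atom (nm, 6 decimals).  An optional ``# azogate trajectory`` header
    line opens the file.
    """
    close = False
    if hasattr(sink, "write"):
        fh = sink
    else:
        fh = open(sink, "w")
        close = True
    try:
        fh.write("# azogate trajectory\n")
        for idx in range(traj.n_frames):
            frame = traj.frames[idx]
            fh.write(f"FRAME {idx} {traj.times[idx]:.9g} {len(frame)}\n")
            for x, y, z in frame:
                fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
    finally:
        if close:
            fh.close()


def read_trajectory(source):
    """Inverse of :func:`write_trajectory`; returns a Trajectory (energies zero).

    A zero-frame file yields an empty trajectory; a truncated frame raises a
    :class:`ParseError` naming the frame index.
    """
    from .switch_dynamics import Trajectory

    close = False
    if isinstance(source, str) and "\n" in source:
        fh = io.StringIO(source)
    elif hasattr(source, "read"):
        fh = source
    else:
        fh = open(source)
        close = True
    try:
        times, frames = [], []
        lines = iter(enumerate(fh, start=1))
        for lineno, raw in lines:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] != "FRAME" or len(parts) != 4:
                raise ParseError(f"expected FRAME header, got {line!r}", lineno)
            idx, t, n_atoms = int(parts[1]), float(parts[2]), int(parts[3])
            coords = []
            for _ in range(n_atoms):
                try:
                    lineno2, raw2 = next(lines)
                except StopIteration:
                    raise ParseError(
                        f"frame {idx}: expected {n_atoms} atom lines, "
                        f"got {len(coords)}")
                vals = raw2.split()
                if len(vals) != 3:
                    raise ParseError(
                        f"frame {idx}: malformed coordinate line", lineno2)
                coords.append([float(v) for v in vals])
            times.append(t)
            frames.append(coords)
        n = len(times)
        zeros = np.zeros(n)
        frames_arr = np.array(frames) if n else np.zeros((0, 0, 3))
        return Trajectory(np.array(times), frames_arr, zeros, zeros.copy())
    finally:
        if close:
            fh.close()


def select(structure: Structure, chain: str | None = None,
           residue_numbers=None, atom_names=None, label: str = "") -> Selection:
    """Atoms matching all given criteria, in structure order.

    Raises :class:`EmptySelectionError` when nothing matches — the
    centre-of-mass consumers downstream must never receive empty selections.
    """
    residues = set(residue_numbers) if residue_numbers is not None else None
    names = set(atom_names) if atom_names is not None else None
    idx = tuple(
        i for i, a in enumerate(structure.atoms)
        if (chain is None or a.chain == chain)
        and (residues is None or a.res_number in residues)
        and (names is None or a.name in names)
    )
    if not idx:
        raise EmptySelectionError(
            f"selection matched no atoms (chain={chain!r}, "
            f"residues={sorted(residues) if residues else None}, "
            f"atom_names={sorted(names) if names else None})")
    return Selection(structure, idx, label=label)
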