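"""Docking-pose acceptance filtering and ligand RMSD.

Docked placements are screened the way the re-docking study screened them:
a pose is kept only if it sits inside the selected binding site *and* makes
at least one hydrogen-bond-like polar contact with one of the anchor
residues (the R485/E705 side chains or the S654/T655 backbones).  Hydrogen
bonds are approximated by a heavy-atom polar-polar distance criterion
(<= 0.35 nm, boundary inclusive) with no angle term, since docking outputs
frequently lack hydrogens.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .errors import EmptySelectionError, MissingResidueError, ParseError, ValidationError
from .structure_io import ATOMIC_MASSES, Selection, Structure, select
from .traj_metrics import center_of_mass, kabsch_superpose

POLAR_ELEMENTS = ("N", "O")

#: anchor name -> (residue number, atom subset); side-chain polar atoms for
#: the charged anchors, backbone N/O for the domain-2 backbone anchors
DEFAULT_ANCHORS = {
    "R485": (485, ("NE", "NH1", "NH2")),
    "E705": (705, ("OE1", "OE2")),
    "S654-backbone": (654, ("N", "O")),
    "T655-backbone": (655, ("N", "O")),
}

REASON_OUTSIDE = "outside-site"
REASON_NO_HBOND = "no-anchor-hbond"


@dataclass
class DockedPose:
    """A docked ligand placement: atoms (name, element, coord nm), score, rank."""

    atoms: list[tuple[str, str, tuple[float, float, float]]]
    score: float
    rank: int

    def __post_init__(self):
        if len(self.atoms) < 1:
            raise ValidationError("a pose needs at least one atom")
        if self.rank < 1:
            raise ValidationError("rank must be >= 1")

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([a[2] for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES[a[1].upper()] for a in self.atoms])

    def polar_coordinates(self) -> np.ndarray:
        out = [a[2] for a in self.atoms if a[1].upper() in POLAR_ELEMENTS]
        return np.array(out, dtype=float) if out else np.zeros((0, 3))

    def center_of_mass(self) -> np.ndarray:
        m = self.masses
        return m @ self.coordinates / m.sum()


@dataclass(frozen=True)
class SiteSpec:
    """Binding site: residues defining the pocket + an acceptance radius (nm)."""

    residues: tuple[int, ...]
    radius: float = 1.2

    def __post_init__(self):
        if not self.residues:
            raise ValidationError("site spec needs at least one residue")
        if self.radius < 0:
            raise ValidationError("site radius must be >= 0")


@dataclass
class PoseVerdict:
    rank: int
    accepted: bool
    reasons: list[str]


@dataclass
class FilterReport:
    """Per-pose accept/reject verdicts; ``accepted`` iff ``reasons`` empty."""

    verdicts: list[PoseVerdict]

    def __post_init__(self):
        for v in self.verdicts:
            if v.accepted != (not v.reasons):
                raise ValidationError("verdict accepted iff reasons empty")

    @property
    def n_accepted(self) -> int:
        return sum(v.accepted for v in self.verdicts)

    def to_rows(self):
        return [
            {"rank": v.rank, "accepted": v.accepted, "reasons": ",".join(v.reasons) or "-"}
            for v in self.verdicts
        ]


def polar_contact(pose: DockedPose, receptor: Structure, anchor,
                  hbond_cutoff: float = 0.35) -> bool:
    """True iff any ligand polar atom (N, O) lies within ``hbond_cutoff`` nm
    (inclusive) of any polar atom of the anchor residue subset.

    ``anchor`` is ``(residue_number, atom_names)`` or a key of
    :data:`DEFAULT_ANCHORS`.
    """
    if isinstance(anchor, str):
        try:
            anchor = DEFAULT_ANCHORS[anchor]
        except KeyError:
            raise ValidationError(f"unknown anchor {anchor!r}")
    res, atom_names = anchor
    try:
        sel = select(receptor, residue_numbers=[res], atom_names=atom_names)
    except EmptySelectionError:
        raise MissingResidueError(
            f"anchor residue {res} (atoms {list(atom_names)}) missing from receptor")
    anchor_xyz = np.array([
        receptor.atoms[i].coord for i in sel.indices
        if receptor.atoms[i].element in POLAR_ELEMENTS
    ])
    lig_xyz = pose.polar_coordinates()
    if len(anchor_xyz) == 0 or len(lig_xyz) == 0:
        return False
    d = np.linalg.norm(lig_xyz[:, None, :] - anchor_xyz[None, :, :], axis=-1)
    return bool(np.min(d) <= hbond_cutoff)


def inside_site(pose: DockedPose, receptor: Structure, site: SiteSpec) -> bool:
    """True iff the pose COM lies within ``site.radius`` of the site-residue COM."""
    idx: list[int] = []
    for res in site.residues:
        try:
            sel = select(receptor, residue_numbers=[res])
        except EmptySelectionError:
            raise MissingResidueError(f"site residue {res} missing from receptor")
        idx.extend(sel.indices)
    site_com = center_of_mass(Selection(receptor, tuple(idx)))
    return bool(np.linalg.norm(pose.center_of_mass() - site_com) <= site.radius)


def filter_poses(poses, receptor: Structure, site: SiteSpec,
                 anchors=None, hbond_cutoff: float = 0.35) -> FilterReport:
    """Accept a pose iff it is inside the site AND touches >= 1 anchor.

    ``reasons`` lists every failed criterion, so a doubly-bad pose reports
    both :data:`REASON_OUTSIDE` and :data:`REASON_NO_HBOND`.
    """
    poses = list(poses)
    if not poses:
        raise ValidationError("empty pose list")
    anchors = DEFAULT_ANCHORS if anchors is None else anchors
    anchor_items = list(anchors.values()) if isinstance(anchors, dict) else list(anchors)
    verdicts = []
    for pose in poses:
        reasons = []
        if not inside_site(pose, receptor, site):
            reasons.append(REASON_OUTSIDE)
        if not any(polar_contact(pose, receptor, a, hbond_cutoff)
                   for a in anchor_items):
            reasons.append(REASON_NO_HBOND)
        verdicts.append(PoseVerdict(pose.rank, not reasons, reasons))
    return FilterReport(verdicts)


def ligand_rmsd(a: DockedPose, b: DockedPose, superpose: bool = False,
                mappings=None) -> float:
    """Heavy-atom RMSD between two poses, in Angstrom.

    With ``superpose=False`` (the re-docking convention) the poses are
    compared in the common receptor frame; ``superpose=True`` removes the
    optimal rigid transform first.  ``mappings`` is an optional iterable of
    index permutations of ``b`` (symmetry-equivalent atom orderings); the
    minimum RMSD over the identity and all given mappings is returned.
    """
    heavy_a = [i for i, at in enumerate(a.atoms) if at[1].upper() != "H"]
    heavy_b = [i for i, at in enumerate(b.atoms) if at[1].upper() != "H"]
    if len(a.atoms) != len(b.atoms):
        raise ValidationError("pose atom counts differ")
    pa = a.coordinates[heavy_a]
    candidates = [list(range(len(b.atoms)))]
    if mappings:
        candidates.extend(list(m) for m in mappings)
    best = np.inf
    for mapping in candidates:
        if sorted(mapping) != list(range(len(b.atoms))):
            raise ValidationError("mapping must be a permutation of atom indices")
        pb = b.coordinates[mapping][heavy_b]
        if superpose:
            rmsd_nm = kabsch_superpose(pa, pb).rmsd
        else:
            rmsd_nm = float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))
        best = min(best, rmsd_nm)
    return best * 10.0  # nm -> A


def write_pose_file(poses, sink) -> None:
    """Multi-model PDB-like pose file.

    Per pose: ``MODEL n``, ``REMARK SCORE <kJ/mol>``, ``REMARK RANK <n>``,
    HETATM records (nm -> A), ``ENDMDL``.
    """
    close = False
    if hasattr(sink, "write"):
        fh = sink
    else:
        fh = open(sink, "w")
        close = True
    try:
        for n, pose in enumerate(poses, start=1):
            fh.write(f"MODEL {n}\n")
            fh.write(f"REMARK SCORE {pose.score:.6g}\n")
            fh.write(f"REMARK RANK {pose.rank}\n")
            for serial, (name, element, (x, y, z)) in enumerate(pose.atoms, start=1):
                nm = name if len(name) >= 4 else f" {name:<3s}"
                fh.write(
                    f"HETATM{serial:>5d} {nm:<4s} LIG L   1    "
                    f"{10*x:8.3f}{10*y:8.3f}{10*z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"{'':10s}{element.upper():>2s}\n")
            fh.write("ENDMDL\n")
    finally:
        if close:
            fh.close()


def read_pose_file(source) -> list[DockedPose]:
    """Inverse of :func:`write_pose_file`."""
    close = False
    if isinstance(source, str) and "\n" in source:
        fh = io.StringIO(source)
    elif hasattr(source, "read"):
        fh = source
    else:
        fh = open(source)
        close = True
    try:
        poses = []
        atoms: list | None = None
        score = None
        rank = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("MODEL"):
                atoms, score, rank = [], None, None
            elif line.startswith("REMARK SCORE"):
                score = float(line.split()[2])
            elif line.startswith("REMARK RANK"):
                rank = int(line.split()[2])
            elif line.startswith(("HETATM", "ATOM")):
                if atoms is None:
                    raise ParseError("atom record outside MODEL block", lineno)
                name = line[12:16].strip()
                element = line[76:78].strip() or name[0]
                try:
                    xyz = tuple(float(line[lo:hi]) / 10.0
                                for lo, hi in ((30, 38), (38, 46), (46, 54)))
                except ValueError:
                    raise ParseError("non-numeric coordinate field", lineno)
                atoms.append((name, element.upper(), xyz))
            elif line.startswith("ENDMDL"):
                if atoms is None:
                    raise ParseError("ENDMDL without MODEL", lineno)
                if score is None or rank is None:
                    raise ParseError("pose missing REMARK SCORE/RANK", lineno)
                poses.append(DockedPose(atoms, score, rank))
                atoms = None
        return poses
    finally:
        if close:
            fh.close()
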