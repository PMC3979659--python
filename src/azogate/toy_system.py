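"""Toy azobenzene molecular model and its classical ground-state force field.

The model is deliberately minimal: the photo-switching mechanism studied here
is driven entirely by the central C-N=N-C torsion, so a vacuum model with
harmonic bonds, harmonic angles and a periodic double-well dihedral captures
everything the switching protocol needs.  Internal units are nm, kJ/mol, amu
and ps; angles are degrees at every public interface.

The ground-state C-N=N-C term is ``V(phi) = (B/2)(1 - cos 2*phi)``: two minima
per period, at 0 deg (cis) and 180 deg (trans), separated by a barrier ``B``
(default 100 kJ/mol) that makes thermal isomerization at 300 K negligible on
the timescales simulated here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, ValidationError

MASS_C = 12.011
MASS_N = 14.007
#: aggregated CH ring-site mass used by the phenyl variant
MASS_CH = MASS_C + 1.008

# default toy force-field parameters
BOND_K = 2.0e5          # kJ/mol/nm^2
R0_CN = 0.142           # nm
R0_NN = 0.125           # nm
R0_C_RING = 0.148       # nm
R0_RING = 0.139         # nm, aromatic C-C
ANGLE_K = 500.0         # kJ/mol/rad^2
THETA0_CNN = 113.0      # deg
THETA0_RING_ATT = 115.0  # deg, N-C-ipso attachment angle of the phenyl rings
DIHEDRAL_BARRIER = 100.0  # kJ/mol, trans<->cis ground-state barrier
RING_C12 = 1.0e-6       # kJ/mol nm^12, ring-ring steric repulsion


@dataclass(frozen=True)
class AtomSpec:
    """One atom of the toy model; ``charge`` is unused by the vacuum force field."""

    index: int
    name: str
    mass: float
    charge: float = 0.0

    def __post_init__(self):
        if self.mass <= 0:
            raise ValidationError(f"atom {self.index} ({self.name}): mass must be > 0")


@dataclass(frozen=True)
class Topology:
    """Bonded-term lists of the toy force field.

    bonds:  (i, j, k_b [kJ/mol/nm^2], r0 [nm])
    angles: (i, j, k, k_a [kJ/mol/rad^2], theta0 [deg]), j is the vertex
    dihedrals: (i, j, k, l, form, params); form ``"cos2"`` is the double-well
        ``(B/2)(1 - cos 2*phi)`` with params ``(B,)``
    group_pairs: ((idx...), (idx...), c12) purely repulsive ``c12 / r_cm^12``
        term between the mass-weighted centroids of the two atom groups
    """

    atoms: tuple[AtomSpec, ...]
    bonds: tuple[tuple[int, int, float, float], ...]
    angles: tuple[tuple[int, int, int, float, float], ...]
    dihedrals: tuple[tuple[int, int, int, int, str, tuple], ...]
    central_dihedral: tuple[int, int, int, int]
    group_pairs: tuple[tuple[tuple[int, ...], tuple[int, ...], float], ...] = ()

    def __post_init__(self):
        n = len(self.atoms)
        if [a.index for a in self.atoms] != list(range(n)):
            raise ValidationError("atom indices must be unique and contiguous from 0")
        seen = set()
        for i, j, _, _ in self.bonds:
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValidationError(f"duplicate bond {key}")
            seen.add(key)
        for term in self.bonds + self.angles:
            for idx in term[: len(term) - 2]:
                if not (0 <= idx < n):
                    raise ValidationError(f"bonded-term index {idx} out of range")
        quads = {d[:4] for d in self.dihedrals}
        if tuple(self.central_dihedral) not in quads:
            raise ValidationError("central_dihedral must appear in the dihedral list")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])


@dataclass
class AzobenzeneModel:
    """A topology plus a current coordinate set (nm)."""

    topology: Topology
    coordinates: np.ndarray

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (self.topology.n_atoms, 3):
            raise ValidationError(
                f"coordinate shape {self.coordinates.shape} does not match "
                f"{self.topology.n_atoms} atoms"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValidationError("coordinates must be finite")

    def with_coordinates(self, coords: np.ndarray) -> "AzobenzeneModel":
        return AzobenzeneModel(self.topology, np.array(coords, dtype=float))


def wrap_angle(angle_deg):
    """Wrap an angle (deg) into (-180, 180]."""
    a = -((-np.asarray(angle_deg, dtype=float) + 180.0) % 360.0 - 180.0)
    return a


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed dihedral (deg) in (-180, 180], IUPAC convention.

    180 deg = trans (anti-periplanar), 0 deg = cis (syn-periplanar).  Raises
    :class:`DegenerateGeometryError` when three consecutive points are
    collinear and the torsion is undefined.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 * max(np.linalg.norm(b1) * b2n, 1e-300) or \
       np.linalg.norm(n2) < 1e-10 * max(np.linalg.norm(b3) * b2n, 1e-300):
        raise DegenerateGeometryError("collinear points: dihedral undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n2, n1), b2 / b2n))
    phi = np.degrees(np.arctan2(y, x))
    return float(wrap_angle(phi))


def _hexagon(center, u, v, radius=R0_RING):
    """Six sites of a regular hexagon in the plane spanned by unit vectors u, v."""
    pts = []
    for k in range(6):
        a = np.radians(60.0 * k)
        pts.append(center + radius * (np.cos(a) * u + np.sin(a) * v))
    return pts


def build_azobenzene(variant: str = "minimal", barrier: float = DIHEDRAL_BARRIER) -> AzobenzeneModel:
    """Build the toy azobenzene in its planar trans geometry.

    ``minimal``: 4 atoms (C, N, N, C), 3 bonds, 2 angles, 1 dihedral.
    ``phenyl``: the minimal core plus two rigid 6-site rings bonded to the
    terminal carbons (16 atoms) and a single repulsive ring-ring term.
    """
    if barrier <= 0:
        raise ValidationError("dihedral barrier must be > 0")
    theta = np.radians(THETA0_CNN)
    n1 = np.array([0.0, 0.0, 0.0])
    n2 = np.array([R0_NN, 0.0, 0.0])
    c0 = n1 + R0_CN * np.array([np.cos(theta), np.sin(theta), 0.0])
    c3 = n2 + R0_CN * np.array([-np.cos(theta), -np.sin(theta), 0.0])

    atoms = [
        AtomSpec(0, "C1", MASS_C),
        AtomSpec(1, "N1", MASS_N),
        AtomSpec(2, "N2", MASS_N),
        AtomSpec(3, "C2", MASS_C),
    ]
    bonds = [
        (0, 1, BOND_K, R0_CN),
        (1, 2, BOND_K, R0_NN),
        (2, 3, BOND_K, R0_CN),
    ]
    angles = [
        (0, 1, 2, ANGLE_K, THETA0_CNN),
        (1, 2, 3, ANGLE_K, THETA0_CNN),
    ]
    dihedrals = [(0, 1, 2, 3, "cos2", (float(barrier),))]
    coords = [c0, n1, n2, c3]
    group_pairs: list = []

    if variant == "minimal":
        pass
    elif variant == "phenyl":
        # Each ring: regular hexagon whose site 0 (ipso) is bonded to a core
        # terminal carbon; all 15 intra-ring pairwise distances are restrained,
        # which makes the 6-site body rigid in 3-D.
        theta_att = np.radians(THETA0_RING_ATT)
        for core_c, core_n in ((0, 1), (3, 2)):
            d_n = coords[core_n] - coords[core_c]
            d_n = d_n / np.linalg.norm(d_n)
            p = np.cross([0.0, 0.0, 1.0], d_n)
            w = np.cos(theta_att) * d_n + np.sin(theta_att) * p
            v = np.array([0.0, 0.0, 1.0])
            ipso = coords[core_c] + R0_C_RING * w
            center = ipso + R0_RING * w
            # hexagon with site 0 at the ipso position
            ring = _hexagon(center, -w, v)
            base = len(atoms)
            for s, p in enumerate(ring):
                atoms.append(AtomSpec(base + s, f"R{s}", MASS_CH))
                coords.append(p)
            ring_idx = list(range(base, base + 6))
            # rigid body: restrain every intra-ring pair at its hexagon distance
            for a in range(6):
                for b in range(a + 1, 6):
                    d0 = float(np.linalg.norm(ring[a] - ring[b]))
                    bonds.append((ring_idx[a], ring_idx[b], BOND_K / 2.0, d0))
            bonds.append((core_c, ring_idx[0], BOND_K, R0_C_RING))
            angles.append((core_n, core_c, ring_idx[0], ANGLE_K, THETA0_RING_ATT))
        group_pairs.append((tuple(range(4, 10)), tuple(range(10, 16)), RING_C12))
    else:
        raise ValidationError(f"unknown variant {variant!r} (use 'minimal' or 'phenyl')")

    topo = Topology(
        atoms=tuple(atoms),
        bonds=tuple(bonds),
        angles=tuple(angles),
        dihedrals=tuple(dihedrals),
        central_dihedral=(0, 1, 2, 3),
        group_pairs=tuple(group_pairs),
    )
    return AzobenzeneModel(topo, np.array(coords))


class _CompiledFF:
    """Topology flattened into index/parameter arrays for fast evaluation.

    Pair/angle force contributions are scattered onto atoms with precomputed
    incidence matrices so the hot loop is two small matmuls instead of
    ``np.add.at`` calls.
    """

    def __init__(self, topo: Topology):
        n = topo.n_atoms
        self.masses = topo.masses
        b = topo.bonds
        self.bi = np.array([t[0] for t in b], dtype=int)
        self.bj = np.array([t[1] for t in b], dtype=int)
        self.bk = np.array([t[2] for t in b])
        self.br0 = np.array([t[3] for t in b])
        self.Sb = np.zeros((n, len(b)))
        for col, (i, j, _, _) in enumerate(b):
            self.Sb[i, col] += 1.0
            self.Sb[j, col] -= 1.0
        a = topo.angles
        self.ai = np.array([t[0] for t in a], dtype=int)
        self.aj = np.array([t[1] for t in a], dtype=int)
        self.ak = np.array([t[2] for t in a], dtype=int)
        self.aka = np.array([t[3] for t in a])
        self.at0 = np.radians(np.array([t[4] for t in a]))
        # columns 0..na-1 carry the -dV/dtheta*gi rows, na..2na-1 the gk rows;
        # the vertex j receives minus both contributions
        self.Sa = np.zeros((n, 2 * len(a)))
        for col, (i, j, k, _, _) in enumerate(a):
            self.Sa[i, col] += 1.0
            self.Sa[j, col] -= 1.0
            self.Sa[k, col + len(a)] += 1.0
            self.Sa[j, col + len(a)] -= 1.0
        self.dihedrals = [
            (t[0], t[1], t[2], t[3], t[4], t[5]) for t in topo.dihedrals
        ]
        self.group_pairs = [
            (np.array(ga, dtype=int), np.array(gb, dtype=int), c12)
            for ga, gb, c12 in topo.group_pairs
        ]


_FF_CACHE: dict[int, _CompiledFF] = {}


def _compiled(topo: Topology) -> _CompiledFF:
    key = id(topo)
    ff = _FF_CACHE.get(key)
    if ff is None:
        ff = _FF_CACHE[key] = _CompiledFF(topo)
    return ff


def _dihedral_and_grad(c, quad):
    """phi (rad, signed) and d(phi)/d(coords) for the four atoms of ``quad``.

    Gradient rows are returned in quad order.  Standard analytic form via the
    two plane normals, in scalar arithmetic (hot path); validated against
    central finite differences in tests.
    """
    i, j, k, l = quad
    px, py, pz = c[i]
    qx, qy, qz = c[j]
    rx, ry, rz = c[k]
    sx, sy, sz = c[l]
    b1x, b1y, b1z = qx - px, qy - py, qz - pz
    b2x, b2y, b2z = rx - qx, ry - qy, rz - qz
    b3x, b3y, b3z = sx - rx, sy - ry, sz - rz
    n1x = b1y * b2z - b1z * b2y
    n1y = b1z * b2x - b1x * b2z
    n1z = b1x * b2y - b1y * b2x
    n2x = b2y * b3z - b2z * b3y
    n2y = b2z * b3x - b2x * b3z
    n2z = b2x * b3y - b2y * b3x
    n1sq = n1x * n1x + n1y * n1y + n1z * n1z
    n2sq = n2x * n2x + n2y * n2y + n2z * n2z
    b2sq = b2x * b2x + b2y * b2y + b2z * b2z
    if n1sq < 1e-20 or n2sq < 1e-20 or b2sq < 1e-24:
        raise DegenerateGeometryError("collinear points: dihedral undefined")
    b2n = math.sqrt(b2sq)
    x = n1x * n2x + n1y * n2y + n1z * n2z
    cx = n1y * n2z - n1z * n2y
    cy = n1z * n2x - n1x * n2z
    cz = n1x * n2y - n1y * n2x
    y = -(cx * b2x + cy * b2y + cz * b2z) / b2n
    phi = math.atan2(y, x)
    fi = b2n / n1sq
    fl = -b2n / n2sq
    gi = np.array((fi * n1x, fi * n1y, fi * n1z))
    gl = np.array((fl * n2x, fl * n2y, fl * n2z))
    s = (b1x * b2x + b1y * b2y + b1z * b2z) / b2sq
    t = (b3x * b2x + b3y * b2y + b3z * b2z) / b2sq
    gj = -(1.0 + s) * gi + t * gl
    gk = -(gi + gj + gl)
    return phi, (gi, gj, gk, gl)


def _energy_forces(topo: Topology, coords: np.ndarray, check: bool = True):
    """Total energy (kJ/mol) and per-atom forces (kJ/mol/nm) of all terms."""
    if check:
        c = np.asarray(coords, dtype=float)
        if c.shape != (topo.n_atoms, 3):
            raise ValidationError(
                f"coordinate shape {c.shape} does not match {topo.n_atoms} atoms"
            )
        if not np.all(np.isfinite(c)):
            raise ValidationError("coordinates must be finite")
    else:
        c = coords
    ff = _compiled(topo)
    energy = 0.0
    forces = np.zeros_like(c)

    if ff.bi.size:
        d = c[ff.bi] - c[ff.bj]
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        dr = r - ff.br0
        energy += float(np.dot(0.5 * ff.bk * dr, dr))
        fpair = (-(ff.bk * dr) / r)[:, None] * d
        forces += ff.Sb @ fpair

    if ff.ai.size:
        u = c[ff.ai] - c[ff.aj]
        v = c[ff.ak] - c[ff.aj]
        un = np.sqrt(np.einsum("ij,ij->i", u, u))
        vn = np.sqrt(np.einsum("ij,ij->i", v, v))
        uh = u / un[:, None]
        vh = v / vn[:, None]
        cos_t = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
        theta = np.arccos(cos_t)
        sin_t = np.maximum(np.sqrt(1.0 - cos_t * cos_t), 1e-8)
        dth = theta - ff.at0
        energy += float(np.dot(0.5 * ff.aka * dth, dth))
        dVdt = ff.aka * dth
        gi = (cos_t[:, None] * uh - vh) / (un * sin_t)[:, None]
        gk = (cos_t[:, None] * vh - uh) / (vn * sin_t)[:, None]
        rows = np.concatenate([-dVdt[:, None] * gi, -dVdt[:, None] * gk], axis=0)
        forces += ff.Sa @ rows

    for (i, j, k, l, form, params) in ff.dihedrals:
        phi, grads = _dihedral_and_grad(c, (i, j, k, l))
        if form == "cos2":
            (barrier,) = params
            energy += 0.5 * barrier * (1.0 - np.cos(2.0 * phi))
            dVdphi = barrier * np.sin(2.0 * phi)
        else:
            raise ValidationError(f"unknown dihedral form {form!r}")
        for idx, g in zip((i, j, k, l), grads):
            forces[idx] -= dVdphi * g

    for ga, gb, c12 in ff.group_pairs:
        ma = ff.masses[ga]
        mb = ff.masses[gb]
        ca = ma @ c[ga] / ma.sum()
        cb = mb @ c[gb] / mb.sum()
        d = ca - cb
        r = float(np.linalg.norm(d))
        r = max(r, 1e-6)
        energy += c12 / r**12
        dVdr = -12.0 * c12 / r**13
        g = dVdr * d / r
        forces[ga] -= np.outer(ma / ma.sum(), g)
        forces[gb] += np.outer(mb / mb.sum(), g)

    return energy, forces


def potential_energy(topo: Topology, coords) -> float:
    """Ground-state potential energy (kJ/mol): bonds + angles + dihedrals (+ ring repulsion)."""
    return _energy_forces(topo, coords)[0]


def forces(topo: Topology, coords) -> np.ndarray:
    """Analytic forces, -grad of :func:`potential_energy` (kJ/mol/nm)."""
    return _energy_forces(topo, coords)[1]


def minimize(model: AzobenzeneModel, max_steps: int = 2000, f_tol: float = 1e-4,
             step0: float = 1e-5) -> AzobenzeneModel:
    """Steepest-descent minimization with backtracking; returns a relaxed model.

    ``f_tol`` is the convergence threshold on the max force component
    (kJ/mol/nm); ``step0`` the initial step size in nm^2 mol/kJ.
    """
    c = model.coordinates.copy()
    topo = model.topology
    e, f = _energy_forces(topo, c)
    step = step0
    for _ in range(max_steps):
        fmax = float(np.max(np.abs(f)))
        if fmax < f_tol:
            break
        trial = c + step * f
        e_t, f_t = _energy_forces(topo, trial)
        if e_t < e:
            c, e, f = trial, e_t, f_t
            step *= 1.2
        else:
            step *= 0.5
            if step < 1e-16:
                break
    return model.with_coordinates(c)
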