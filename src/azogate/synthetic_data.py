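"""Synthetic inputs for every pipeline stage.

The toy LBD scaffold is a *geometric test fixture*, not a protein model: each
order parameter involves a disjoint set of residues, so the generator places
each residue cluster in its own region of space and realizes every requested
centre-of-mass distance exactly (to floating-point round-off).  Trajectories
with planted step events, correlated series pairs and labelled docking-pose
sets are built on top of it.  Every generator is a pure function of its spec
and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .pose_filter import DockedPose, SiteSpec
from .structure_io import ATOMIC_MASSES, Atom, Structure
from .switch_dynamics import Trajectory
from .traj_metrics import (MetricConfig, OrderParameterSeries,
                           azobenzene_pocket_distance, clamshell_distance,
                           gate_distance, helix_distance)

#: toy helix residue ranges used by the scaffold (an arbitrary convention of
#: this fixture; real systems must configure their own ranges)
HELIX_H_RANGE = (721, 728)
HELIX_B_RANGE = (741, 748)
#: residue range serving as "domain 1" for dimer projection on the scaffold
DOMAIN1_RANGE = (400, 460)

_BACKBONE = (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"))


@dataclass(frozen=True)
class ScaffoldSpec:
    """Requested order-parameter values (nm) for the toy LBD scaffold."""

    clamshell_nm: float = 0.70
    gate_nm: float = 0.55
    pocket_nm: float = 0.45
    helix_nm: float = 2.00
    linker_nm: float = 2.50
    include_ligand: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("clamshell_nm", "gate_nm", "pocket_nm", "helix_nm", "linker_nm"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(
                    f"geometrically inconsistent spec: {name} = {v} (must be > 0)")


@dataclass(frozen=True)
class EventSpec:
    """A planted step in one named order-parameter series.

    The controlled unit (single residue, or the helix-H rod for the helix
    series) jumps along the inter-COM axis at ``event_frame`` so the series
    steps from ``baseline`` to ``post_event``; isotropic Gaussian noise of
    width ``sigma`` (nm) is then added to *all* coordinates of every frame.
    """

    series: str
    baseline: float
    event_frame: int
    post_event: float
    sigma: float = 0.0
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.event_frame < self.n_frames):
            raise ValidationError("event_frame must lie in [0, n_frames)")
        if self.sigma < 0:
            raise ValidationError("noise sigma must be >= 0")
        if self.baseline <= 0 or self.post_event <= 0:
            raise ValidationError("series values must be > 0")


def _cluster(atoms, center, rng, spread=0.06):
    """Place an atom cluster with its mass-weighted COM exactly at ``center``.

    ``atoms`` is a list of (name, element); offsets are a deterministic jitter
    of scale ``spread`` nm, recentred so the weighted mean is exact.
    """
    center = np.asarray(center, dtype=float)
    n = len(atoms)
    masses = np.array([ATOMIC_MASSES[el] for _, el in atoms])
    if n == 1:
        return [center]
    off = rng.uniform(-spread, spread, size=(n, 3))
    off -= (masses @ off / masses.sum())[None, :]
    return [center + o for o in off]


def _rod(residues, center, rng, axis=np.array([1.0, 0.0, 0.0]), pitch=0.15):
    """Backbone-only residue rod whose overall backbone COM is exactly ``center``."""
    out = []
    n = len(residues)
    centers = [center + (i - (n - 1) / 2) * pitch * axis for i in range(n)]
    # per-residue identical composition and exact per-residue COMs keep the
    # overall backbone COM at `center`
    for res, c in zip(residues, centers):
        coords = _cluster(list(_BACKBONE), c, rng, spread=0.04)
        out.append((res, list(_BACKBONE), coords))
    return out


def make_toy_lbd(spec: ScaffoldSpec = ScaffoldSpec()) -> Structure:
    """Build the toy LBD scaffold realizing every requested order parameter.

    The structure carries (author-numbered) pseudo-residues 402/686 (gate),
    451/651 (clamshell), 403-405/707/711/712 (pocket), 632 (linker),
    485/705/654/655 (docking anchors), two helix rods and, optionally, an
    azobenzene-like HETATM ligand.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    pocket_center = np.zeros(3)
    gate_anchor = np.array([0.0, -1.6, 0.0])
    clam_anchor = np.array([-1.8, 0.9, 0.0])
    helix_anchor = np.array([1.8, 1.6, 0.0])
    linker_pos = np.array([0.6, 2.6, 0.4])

    placements = []  # (res_number, res_name, chain, [(name, element)], [coords], record)

    def add(res_number, res_name, atoms, coords, chain="A", record="ATOM"):
        placements.append((res_number, res_name, chain, atoms, coords, record))

    # pocket: six CA/CB clusters at +-0.3 nm along each axis; equal
    # composition makes the union COM exactly the pocket centre
    pocket_names = {403: "SER", 404: "PRO", 405: "TYR",
                    707: "THR", 711: "TYR", 712: "ILE"}
    offsets = [(0.3, 0, 0), (-0.3, 0, 0), (0, 0.3, 0),
               (0, -0.3, 0), (0, 0, 0.3), (0, 0, -0.3)]
    for (res, rname), off in zip(sorted(pocket_names.items()), offsets):
        atoms = [("CA", "C"), ("CB", "C")]
        add(res, rname, atoms, _cluster(atoms, pocket_center + np.array(off, float), rng))

    if spec.include_ligand:
        atoms = [("C1", "C"), ("N1", "N"), ("N2", "N"), ("C2", "C")]
        lig_com = pocket_center + np.array([spec.pocket_nm, 0.0, 0.0])
        add(1, "AZO", atoms, _cluster(atoms, lig_com, rng), chain="L", record="HETATM")

    # gate pair: E402 carboxylate COM at the anchor, T686 hydroxyl at
    # anchor + gate_nm along +y; extra CA atoms sit off-axis and do not enter
    # the functional-group COMs
    acid_atoms = [("CD", "C"), ("OE1", "O"), ("OE2", "O")]
    acid_coords = _cluster(acid_atoms, gate_anchor, rng, spread=0.05)
    add(402, "GLU", acid_atoms + [("CA", "C")],
        acid_coords + [gate_anchor + np.array([0.25, -0.1, 0.0])])
    t686_og1 = gate_anchor + np.array([0.0, spec.gate_nm, 0.0])
    add(686, "THR", [("OG1", "O"), ("CA", "C")],
        [t686_og1, t686_og1 + np.array([0.2, 0.1, 0.0])])

    # clamshell pair: whole-residue COMs clamshell_nm apart along z
    for res, rname, centre in (
            (451, "GLY", clam_anchor),
            (651, "SER", clam_anchor + np.array([0.0, 0.0, spec.clamshell_nm]))):
        atoms = list(_BACKBONE)
        add(res, rname, atoms, _cluster(atoms, centre, rng))

    # helix rods H and B, backbone COMs helix_nm apart along z
    for (lo, hi), centre in ((HELIX_H_RANGE, helix_anchor),
                             (HELIX_B_RANGE, helix_anchor + np.array([0.0, 0.0, spec.helix_nm]))):
        for res, atoms, coords in _rod(list(range(lo, hi + 1)), centre, rng):
            add(res, "ALA", atoms, coords)

    # linker residue (chain-B partner is created by make_toy_dimer)
    add(632, "PRO", list(_BACKBONE), _cluster(list(_BACKBONE), linker_pos, rng))

    # docking anchors near the pocket
    anchor_defs = [
        (485, "ARG", [("CA", "C"), ("NE", "N"), ("NH1", "N"), ("NH2", "N")],
         np.array([0.55, 0.55, 0.0])),
        (705, "GLU", [("CA", "C"), ("CD", "C"), ("OE1", "O"), ("OE2", "O")],
         np.array([-0.55, 0.55, 0.0])),
        (654, "SER", list(_BACKBONE), np.array([0.55, -0.55, 0.0])),
        (655, "THR", list(_BACKBONE), np.array([-0.55, -0.55, 0.0])),
    ]
    for res, rname, atoms, centre in anchor_defs:
        add(res, rname, atoms, _cluster(atoms, centre, rng, spread=0.05))

    atoms_out = []
    serial = 1
    for res_number, res_name, chain, atom_defs, coords, record in placements:
        for (name, element), xyz in zip(atom_defs, coords):
            atoms_out.append(Atom(serial, name, res_name, chain, res_number,
                                  element, ATOMIC_MASSES[element],
                                  tuple(np.asarray(xyz, float)), record))
            serial += 1
    return Structure(atoms_out)


def make_toy_dimer(spec: ScaffoldSpec = ScaffoldSpec()) -> Structure:
    """Two copies of the scaffold as chains A and B.

    Chain B is the chain-A scaffold rotated 180 deg about z and translated so
    the P632-P632 linker distance is exactly ``spec.linker_nm``.
    """
    mono = make_toy_lbd(spec)
    rot = np.diag([-1.0, -1.0, 1.0])  # proper rotation about z
    coords = mono.coordinates
    linker_idx = [i for i, a in enumerate(mono.atoms) if a.res_number == 632]
    m = mono.masses[linker_idx]
    linker_com = m @ coords[linker_idx] / m.sum()
    rotated = coords @ rot.T
    linker_com_b = m @ rotated[linker_idx] / m.sum()
    shift = (linker_com + np.array([0.0, spec.linker_nm, 0.0])) - linker_com_b
    atoms = list(mono.atoms)
    serial = len(atoms) + 1
    for a, xyz in zip(mono.atoms, rotated + shift):
        atoms.append(Atom(serial, a.name, a.res_name, "B", a.res_number,
                          a.element, a.mass, tuple(xyz), a.record))
        serial += 1
    return Structure(atoms)


#: series name -> (metric fn, moving unit selector, static-reference COM fn)
def _series_registry(structure: Structure, cfg: MetricConfig):
    def residue_idx(res, chain=None):
        return [i for i, a in enumerate(structure.atoms)
                if a.res_number == res and (chain is None or a.chain == chain)]

    def com(idx, coords):
        m = structure.masses[idx]
        return m @ coords[idx] / m.sum()

    lig_idx = [i for i, a in enumerate(structure.atoms) if a.res_name == cfg.ligand_res_name]
    helixH_idx = [i for i, a in enumerate(structure.atoms)
                  if HELIX_H_RANGE[0] <= a.res_number <= HELIX_H_RANGE[1]]
    acid_idx = [i for i, a in enumerate(structure.atoms)
                if a.res_number == 402 and a.name in cfg.acid_atoms]
    pocket_idx = [i for i, a in enumerate(structure.atoms)
                  if a.res_number in cfg.pocket_residues]
    hx_cfg = MetricConfig(helixH_range=HELIX_H_RANGE, helixB_range=HELIX_B_RANGE)

    return {
        "clamshell": {
            "moving": residue_idx(651),
            "static_com": lambda c: com(residue_idx(451), c),
            "moving_com": lambda c: com(residue_idx(651), c),
            "metric": lambda frame: clamshell_distance(structure, frame),
        },
        "gate": {
            "moving": residue_idx(686),
            "static_com": lambda c: com(acid_idx, c),
            "moving_com": lambda c: com(
                [i for i in residue_idx(686)
                 if structure.atoms[i].name in cfg.hydroxyl_atoms], c),
            "metric": lambda frame: gate_distance(structure, frame),
        },
        "pocket": {
            "moving": lig_idx,
            "static_com": lambda c: com(pocket_idx, c),
            "moving_com": lambda c: com(lig_idx, c),
            "metric": lambda frame: azobenzene_pocket_distance(structure, frame),
        },
        "helix": {
            "moving": helixH_idx,
            "static_com": lambda c: _backbone_com(structure, c, HELIX_B_RANGE),
            "moving_com": lambda c: _backbone_com(structure, c, HELIX_H_RANGE),
            "metric": lambda frame: helix_distance(structure, frame, hx_cfg),
        },
    }


def _backbone_com(structure, coords, res_range):
    idx = [i for i, a in enumerate(structure.atoms)
           if res_range[0] <= a.res_number <= res_range[1]
           and a.name in ("N", "CA", "C", "O")]
    m = structure.masses[idx]
    return m @ coords[idx] / m.sum()


def make_event_trajectory(structure: Structure, events,
                          cfg: MetricConfig = MetricConfig(),
                          frame_spacing_ps: float = 1.0) -> Trajectory:
    """Frames in which each event's controlled unit jumps along the inter-COM
    axis at its event frame (baseline -> post-event value), plus isotropic
    Gaussian coordinate noise.

    All events must agree on ``n_frames``; two events controlling the same
    unit conflict.  Deterministic given the first event's seed.
    """
    events = list(events)
    if not events:
        raise ValidationError("at least one event spec required")
    n_frames = events[0].n_frames
    if any(e.n_frames != n_frames for e in events):
        raise ValidationError("all events must agree on n_frames")
    registry = _series_registry(structure, cfg)
    moving_sets = []
    for e in events:
        if e.series not in registry:
            raise ValidationError(
                f"unknown series {e.series!r}; known: {sorted(registry)}")
        unit = frozenset(registry[e.series]["moving"])
        if not unit:
            raise ValidationError(f"series {e.series!r}: controlled unit absent")
        for other in moving_sets:
            if unit & other:
                raise ValidationError(
                    "conflicting events: two events control the same residue")
        moving_sets.append(unit)

    base = structure.coordinates
    rng = np.random.default_rng(events[0].seed)

    # per-event displacement vectors for baseline and post-event values
    shifts = []
    for e in events:
        reg = registry[e.series]
        static_com = reg["static_com"](base)
        moving_com = reg["moving_com"](base)
        axis = moving_com - static_com
        norm = np.linalg.norm(axis)
        if norm < 1e-9:
            raise ValidationError(f"series {e.series!r}: degenerate axis")
        axis = axis / norm
        idx = list(registry[e.series]["moving"])
        pre = (e.baseline - norm) * axis
        post = (e.post_event - norm) * axis
        shifts.append((idx, pre, post, e.event_frame))

    frames = np.empty((n_frames, len(base), 3))
    for f in range(n_frames):
        coords = base.copy()
        for idx, pre, post, ev in shifts:
            coords[idx] += post if f >= ev else pre
        frames[f] = coords
    sigma = events[0].sigma
    if any(e.sigma != sigma for e in events):
        raise ValidationError("all events must agree on the noise sigma")
    if sigma > 0:
        frames += rng.normal(0.0, sigma, size=frames.shape)
    times = np.arange(n_frames) * frame_spacing_ps
    zeros = np.zeros(n_frames)
    return Trajectory(times, frames, zeros, zeros.copy())


def make_correlated_series(rho: float, n: int, seed: int = 0,
                           names=("clamshell", "linker")) -> tuple[OrderParameterSeries, OrderParameterSeries]:
    """Bivariate-normal series pair with population correlation ``rho``.

    Values are mapped to plausible nm scales (affine, correlation-preserving).
    ``rho = +-1`` produces an exactly affine pair.
    """
    if not (-1.0 <= rho <= 1.0):
        raise ValidationError("rho must lie in [-1, 1]")
    if n < 3:
        raise ValidationError("n must be >= 3")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    if abs(rho) == 1.0:
        y = np.copysign(1.0, rho) * x
    else:
        y = rho * x + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    t = np.arange(n, dtype=float)
    a = OrderParameterSeries(names[0], t, 0.80 + 0.15 * x)
    b = OrderParameterSeries(names[1], t, 2.50 + 0.30 * y)
    return a, b


def make_pose_set(n_accept: int, n_reject_hbond: int, n_reject_site: int,
                  receptor: Structure, seed: int = 0,
                  site: SiteSpec | None = None):
    """Labelled docking poses that satisfy / violate exactly one criterion each.

    Returns ``(poses, labels)`` where labels are dicts with keys ``rank``,
    ``label`` in {accept, reject-hbond, reject-site} and ``reason``.  All
    constructions keep a >= 0.02 nm margin around the 0.35 nm contact cutoff
    so PDB-precision round-trips cannot flip a verdict.
    """
    for n in (n_accept, n_reject_hbond, n_reject_site):
        if n < 0:
            raise ValidationError("pose counts must be >= 0")
    site = site or SiteSpec(residues=(403, 404, 405, 707, 711, 712))
    rng = np.random.default_rng(seed)

    def atom_xyz(res, name):
        for a in receptor.atoms:
            if a.res_number == res and a.name == name:
                return np.array(a.coord)
        raise ValidationError(f"receptor lacks anchor atom {res}/{name}")

    idx = [i for i, a in enumerate(receptor.atoms) if a.res_number in site.residues]
    m = receptor.masses[idx]
    site_com = m @ receptor.coordinates[idx] / m.sum()
    nh1 = atom_xyz(485, "NH1")
    oe1 = atom_xyz(705, "OE1")

    poses, labels = [], []

    def jitter(scale=0.01):
        return rng.uniform(-scale, scale, size=3)

    rank = 1
    for _ in range(n_accept):
        # polar O at 0.30 nm (+-0.01) from R485 NH1: clearly inside the
        # cutoff; companion carbons keep the COM near the anchor (inside site)
        direction = nh1 - site_com
        direction /= np.linalg.norm(direction)
        o_pos = nh1 - (0.30 + rng.uniform(-0.01, 0.01)) * direction
        atoms = [("O1", "O", tuple(o_pos)),
                 ("C1", "C", tuple(o_pos - 0.12 * direction + jitter())),
                 ("C2", "C", tuple(o_pos - 0.24 * direction + jitter()))]
        poses.append(DockedPose(atoms, float(rng.uniform(-11, -6)), rank))
        labels.append({"rank": rank, "label": "accept", "reason": "-"})
        rank += 1

    for _ in range(n_reject_hbond):
        # near the site COM: far (>= 0.37 nm by construction) from every
        # anchor polar atom, which all sit ~0.78 nm from the site centre
        centre = site_com + np.array([0.0, 0.0, 0.25]) + jitter(0.03)
        atoms = [("O1", "O", tuple(centre + jitter(0.02))),
                 ("C1", "C", tuple(centre + np.array([0.12, 0, 0]) + jitter(0.02))),
                 ("N1", "N", tuple(centre + np.array([-0.12, 0, 0]) + jitter(0.02)))]
        poses.append(DockedPose(atoms, float(rng.uniform(-11, -6)), rank))
        labels.append({"rank": rank, "label": "reject-hbond",
                       "reason": "no-anchor-hbond"})
        rank += 1

    for _ in range(n_reject_site):
        # an elongated pose: one polar O still contacts E705 OE1, but a heavy
        # tail drags the COM far outside the site radius
        direction = oe1 - site_com
        direction /= np.linalg.norm(direction)
        o_pos = oe1 + (0.30 + rng.uniform(-0.01, 0.01)) * direction
        tail = o_pos + 4.0 * direction
        atoms = [("O1", "O", tuple(o_pos)),
                 ("S1", "S", tuple(tail + jitter(0.02))),
                 ("S2", "S", tuple(tail + np.array([0.15, 0, 0]) + jitter(0.02)))]
        poses.append(DockedPose(atoms, float(rng.uniform(-11, -6)), rank))
        labels.append({"rank": rank, "label": "reject-site",
                       "reason": "outside-site"})
        rank += 1

    return poses, labels
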