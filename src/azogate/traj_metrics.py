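"""Order parameters, state classifiers, dimer projection and correlations.

These are the observables used to characterise the ligand-binding-domain
(LBD) response to ligand photo-isomerization:

* clamshell distance — G451/S651 centre-of-mass separation, a proxy for LBD
  opening (~0.7 nm bound/closed, ~1.1 nm opening);
* gate distance — separation of the E402 carboxylate and T686 hydroxyl
  centres of mass, tracking the interdomain hydrogen bond that separates the
  two ligand poses (~0.55 nm closed, ~0.8 nm open);
* azobenzene-pocket distance — ligand azo moiety vs. the pocket defined by
  S403, P404, Y405, T707, Y711, I712 (position 1 below ~0.6 nm, intermediate
  ~0.75 nm, position 2 ~1.05 nm);
* helix H - helix B distance (residue ranges are system-specific and must be
  configured);
* P632-P632 linker distance of a dimer projected onto a monomer trajectory —
  a proxy for ion-channel opening.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (ConfigurationError, DegenerateGeometryError,
                     EmptySelectionError, MissingResidueError, ValidationError)
from .structure_io import Selection, Structure, select

GATE_RESIDUE_ACID = 402   # glutamate supplying the carboxylate
GATE_RESIDUE_HYDROXYL = 686  # threonine supplying the hydroxyl
CLAMSHELL_RESIDUES = (451, 651)


@dataclass
class OrderParameterSeries:
    """A named per-frame scalar series (nm for distances)."""

    name: str
    times: np.ndarray
    values: np.ndarray
    states: list | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValidationError("times and values must have equal length")
        if self.states is not None and len(self.states) != len(self.values):
            raise ValidationError("states must match series length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("series times must be strictly increasing")

    def __len__(self):
        return len(self.values)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation mapping mobile onto reference coordinates."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self):
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        if self.rotation.shape != (3, 3) or abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValidationError("rotation must be a proper orthogonal 3x3 matrix")
        if self.rmsd < 0:
            raise ValidationError("rmsd must be >= 0")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class MetricConfig:
    """Thresholds, residue definitions and atom subsets for the metrics.

    ``gate_threshold`` (0.65 nm) is the midpoint of the closed (0.55 nm) and
    open (0.8 nm) gate populations; ``pose_bounds`` (0.60, 0.90 nm) bracket
    the intermediate (~0.75 nm) and position-2 (~1.05 nm) pose readings.
    Helix ranges have no defensible default and must be configured.
    """

    gate_threshold: float = 0.65
    pose_bounds: tuple[float, float] = (0.60, 0.90)
    pocket_residues: tuple[int, ...] = (403, 404, 405, 707, 711, 712)
    helixH_range: tuple[int, int] | None = None
    helixB_range: tuple[int, int] | None = None
    hbond_cutoff: float = 0.35
    acid_atoms: tuple[str, ...] = ("CD", "OE1", "OE2")
    hydroxyl_atoms: tuple[str, ...] = ("OG1", "HG1")
    azo_atom_names: tuple[str, ...] | None = None  # None: all ligand atoms
    ligand_res_name: str = "AZO"

    def __post_init__(self):
        lo, hi = self.pose_bounds
        if not (0 < lo < hi):
            raise ValidationError("pose bounds must satisfy 0 < lower < upper")
        if self.gate_threshold <= 0 or self.hbond_cutoff <= 0:
            raise ValidationError("thresholds must be positive")


def center_of_mass(sel: Selection, frame: np.ndarray | None = None) -> np.ndarray:
    """Mass-weighted mean position (nm) of a non-empty selection."""
    if len(sel) == 0:
        raise EmptySelectionError("center of mass of an empty selection")
    m = sel.masses()
    return m @ sel.coordinates(frame) / m.sum()


def _residue_selection(structure: Structure, res: int, atom_names=None,
                       chain=None, metric: str = "metric") -> Selection:
    try:
        return select(structure, chain=chain, residue_numbers=[res],
                      atom_names=atom_names)
    except EmptySelectionError:
        raise MissingResidueError(
            f"{metric}: residue {res}"
            + (f" atoms {list(atom_names)}" if atom_names else "")
            + " missing from structure")


def _frame_distance(structure, frame, sel_a, sel_b) -> float:
    return float(np.linalg.norm(center_of_mass(sel_a, frame)
                                - center_of_mass(sel_b, frame)))


def clamshell_distance(structure: Structure, frame: np.ndarray | None = None,
                       cfg: MetricConfig = MetricConfig()) -> float:
    """|COM(residue 451) - COM(residue 651)| in nm — LBD opening proxy."""
    a = _residue_selection(structure, CLAMSHELL_RESIDUES[0], metric="clamshell")
    b = _residue_selection(structure, CLAMSHELL_RESIDUES[1], metric="clamshell")
    return _frame_distance(structure, frame, a, b)


def gate_distance(structure: Structure, frame: np.ndarray | None = None,
                  cfg: MetricConfig = MetricConfig()) -> float:
    """COM separation of the E402 carboxylate and the T686 hydroxyl (nm).

    The hydroxyl selection tolerates a missing HG1 (heavy-atom structures).
    """
    acid = _residue_selection(structure, GATE_RESIDUE_ACID, cfg.acid_atoms,
                              metric="gate")
    try:
        hydroxyl = select(structure, residue_numbers=[GATE_RESIDUE_HYDROXYL],
                          atom_names=cfg.hydroxyl_atoms)
    except EmptySelectionError:
        raise MissingResidueError(
            f"gate: residue {GATE_RESIDUE_HYDROXYL} atoms "
            f"{list(cfg.hydroxyl_atoms)} missing from structure")
    return _frame_distance(structure, frame, acid, hydroxyl)


def gate_state(d: float, cfg: MetricConfig = MetricConfig()) -> str:
    """'closed' iff d < gate_threshold, else 'open' (boundary -> open)."""
    if d < 0:
        raise ValidationError("distance must be >= 0")
    return "closed" if d < cfg.gate_threshold else "open"


def azobenzene_pocket_distance(structure: Structure,
                               frame: np.ndarray | None = None,
                               azo: Selection | None = None,
                               cfg: MetricConfig = MetricConfig()) -> float:
    """|COM(azo moiety) - COM(union of the six pocket residues)| in nm."""
    if azo is None:
        try:
            azo = select(structure, residue_numbers=None, atom_names=cfg.azo_atom_names)
            idx = tuple(i for i in azo.indices
                        if structure.atoms[i].res_name == cfg.ligand_res_name)
            if not idx:
                raise EmptySelectionError("no ligand atoms")
            azo = Selection(structure, idx, label="azo")
        except EmptySelectionError:
            raise MissingResidueError(
                f"pocket metric: ligand residue {cfg.ligand_res_name!r} missing")
    pocket_idx: list[int] = []
    for res in cfg.pocket_residues:
        sel = _residue_selection(structure, res, metric="pocket")
        pocket_idx.extend(sel.indices)
    pocket = Selection(structure, tuple(pocket_idx), label="pocket")
    return _frame_distance(structure, frame, azo, pocket)


def pose_state(d: float, cfg: MetricConfig = MetricConfig()) -> str:
    """position1 / intermediate / position2 by the configured distance bands."""
    if d < 0:
        raise ValidationError("distance must be >= 0")
    lo, hi = cfg.pose_bounds
    if d < lo:
        return "position1"
    if d < hi:
        return "intermediate"
    return "position2"


def helix_distance(structure: Structure, frame: np.ndarray | None = None,
                   cfg: MetricConfig = MetricConfig()) -> float:
    """Backbone COM separation of the configured helix H and helix B ranges (nm)."""
    from .structure_io import BACKBONE_ATOMS

    if cfg.helixH_range is None or cfg.helixB_range is None:
        raise ConfigurationError(
            "helix H / helix B residue ranges are not configured; they are "
            "system-specific and have no default")
    sels = []
    for lo, hi in (cfg.helixH_range, cfg.helixB_range):
        try:
            sels.append(select(structure, residue_numbers=range(lo, hi + 1),
                               atom_names=BACKBONE_ATOMS))
        except EmptySelectionError:
            raise MissingResidueError(
                f"helix metric: no backbone atoms in residue range {lo}-{hi}")
    return _frame_distance(structure, frame, sels[0], sels[1])


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None) -> RigidTransform:
    """Least-squares optimal proper rotation + translation (Kabsch, via SVD).

    Maps ``mobile`` onto ``reference``; reflections are excluded by flipping
    the sign of the smallest singular vector when det < 0.  ``rmsd`` is the
    post-fit root-mean-square deviation (weighted if weights are given).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape:
        raise ValidationError("mobile and reference atom counts differ")
    if P.ndim != 2 or P.shape[0] < 3:
        raise ValidationError("superposition needs >= 3 atoms")
    w = np.ones(len(P)) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    pc = w @ P / wsum
    qc = w @ Q / wsum
    P0 = P - pc
    Q0 = Q - qc
    H = (w[:, None] * P0).T @ Q0
    U, S, Vt = np.linalg.svd(H)
    # degenerate (e.g. collinear) point sets leave the rotation underdetermined
    if S[1] < 1e-12 * max(S[0], 1e-300):
        raise DegenerateGeometryError("reference geometry is (near-)collinear")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    moved = P0 @ R.T
    rmsd = float(np.sqrt(np.sum(w[:, None] * (moved - Q0) ** 2) / wsum))
    return RigidTransform(R, qc - R @ pc, rmsd)


def project_dimer(monomer_traj, reference_dimer: Structure,
                  domain1_range: tuple[int, int], monomer_structure: Structure,
                  linker_residue: int = 632,
                  chain_a: str | None = None, chain_b: str | None = None,
                  name: str = "linker") -> OrderParameterSeries:
    """Per-frame P632-P632 distance of the reference dimer projected onto a monomer.

    For every trajectory frame the reference dimer's chain-A domain 1 (backbone
    atoms in ``domain1_range``) is superposed onto the monomer's domain 1; the
    resulting transform carries chain B along, and the series reports
    |COM(linker residue, monomer frame) - COM(linker residue, transformed
    chain B)| — the ion-channel opening proxy.
    """
    from .structure_io import BACKBONE_ATOMS

    chains = [ch for ch in reference_dimer.chains()
              if any(a.chain == ch and a.res_number == linker_residue
                     for a in reference_dimer.atoms)]
    if len(chains) < 2 and (chain_a is None or chain_b is None):
        raise ValidationError(
            "reference dimer must contain two chains carrying the linker residue")
    chain_a = chain_a or chains[0]
    chain_b = chain_b or chains[1]
    lo, hi = domain1_range
    dom_rng = range(lo, hi + 1)

    def dom_sel(struct, chain):
        try:
            return select(struct, chain=chain, residue_numbers=dom_rng,
                          atom_names=BACKBONE_ATOMS)
        except EmptySelectionError:
            raise MissingResidueError(
                f"dimer projection: no domain-1 backbone atoms {lo}-{hi} "
                f"in chain {chain!r}")

    ref_dom_a = dom_sel(reference_dimer, chain_a)
    mono_dom = dom_sel(monomer_structure, None)
    if len(ref_dom_a) != len(mono_dom):
        raise ValidationError(
            "domain-1 atom counts differ between reference chain A and monomer")
    try:
        ref_linker_b = select(reference_dimer, chain=chain_b,
                              residue_numbers=[linker_residue])
    except EmptySelectionError:
        raise MissingResidueError(
            f"dimer projection: linker residue {linker_residue} missing in "
            f"chain {chain_b!r}")
    mono_linker = _residue_selection(monomer_structure, linker_residue,
                                     metric="dimer projection")

    ref_dom_coords = ref_dom_a.coordinates()
    ref_b_coords = ref_linker_b.coordinates()
    m_b = ref_linker_b.masses()
    m_mono = mono_linker.masses()
    values = []
    for frame in monomer_traj.frames:
        tr = kabsch_superpose(ref_dom_coords, mono_dom.coordinates(frame))
        com_b = m_b @ tr.apply(ref_b_coords) / m_b.sum()
        com_mono = m_mono @ mono_linker.coordinates(frame) / m_mono.sum()
        values.append(float(np.linalg.norm(com_mono - com_b)))
    return OrderParameterSeries(name, monomer_traj.times, np.array(values))


def order_parameter_series(structure: Structure, traj, name: str,
                           cfg: MetricConfig = MetricConfig(),
                           classify: bool = True) -> OrderParameterSeries:
    """Vectorized per-frame series for one named metric over a trajectory.

    ``name`` is one of clamshell / gate / pocket / helix.  Equivalent to
    calling the scalar metric on every frame (asserted in tests) but computed
    as one COM-difference norm over the whole frame stack.
    """
    frames = np.asarray(traj.frames)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValidationError("trajectory has no frames")

    def group(sel: Selection):
        idx = list(sel.indices)
        m = structure.masses[idx]
        return idx, m / m.sum()

    classifier = None
    if name == "clamshell":
        a = _residue_selection(structure, CLAMSHELL_RESIDUES[0], metric=name)
        b = _residue_selection(structure, CLAMSHELL_RESIDUES[1], metric=name)
    elif name == "gate":
        a = _residue_selection(structure, GATE_RESIDUE_ACID, cfg.acid_atoms,
                               metric=name)
        try:
            b = select(structure, residue_numbers=[GATE_RESIDUE_HYDROXYL],
                       atom_names=cfg.hydroxyl_atoms)
        except EmptySelectionError:
            raise MissingResidueError(
                f"gate: residue {GATE_RESIDUE_HYDROXYL} atoms "
                f"{list(cfg.hydroxyl_atoms)} missing from structure")
        if classify:
            classifier = lambda d: gate_state(d, cfg)
    elif name == "pocket":
        lig = [i for i, at in enumerate(structure.atoms)
               if at.res_name == cfg.ligand_res_name]
        if not lig:
            raise MissingResidueError(
                f"pocket metric: ligand residue {cfg.ligand_res_name!r} missing")
        a = Selection(structure, tuple(lig), "azo")
        pocket_idx: list[int] = []
        for res in cfg.pocket_residues:
            pocket_idx.extend(
                _residue_selection(structure, res, metric=name).indices)
        b = Selection(structure, tuple(pocket_idx), "pocket")
        if classify:
            classifier = lambda d: pose_state(d, cfg)
    elif name == "helix":
        from .structure_io import BACKBONE_ATOMS

        if cfg.helixH_range is None or cfg.helixB_range is None:
            raise ConfigurationError("helix ranges are not configured")
        a = select(structure, residue_numbers=range(cfg.helixH_range[0],
                                                    cfg.helixH_range[1] + 1),
                   atom_names=BACKBONE_ATOMS)
        b = select(structure, residue_numbers=range(cfg.helixB_range[0],
                                                    cfg.helixB_range[1] + 1),
                   atom_names=BACKBONE_ATOMS)
    else:
        raise ValidationError(f"unknown metric {name!r}")

    ia, wa = group(a)
    ib, wb = group(b)
    delta = np.einsum("a,fax->fx", wa, frames[:, ia, :]) \
        - np.einsum("b,fbx->fx", wb, frames[:, ib, :])
    values = np.linalg.norm(delta, axis=1)
    states = [classifier(v) for v in values] if classifier else None
    return OrderParameterSeries(name, traj.times, values, states)


def pearson_r2(a: OrderParameterSeries, b: OrderParameterSeries) -> float:
    """Squared Pearson product-moment correlation of two paired series."""
    if len(a) != len(b):
        raise ValidationError("series lengths differ")
    if len(a) < 3:
        raise ValidationError("correlation needs at least 3 points")
    if np.ptp(a.values) == 0 or np.ptp(b.values) == 0:
        raise ValidationError("correlation undefined for a constant series")
    r, _ = stats.pearsonr(a.values, b.values)
    return float(r * r)


def detect_transitions(series: OrderParameterSeries, classifier,
                       min_dwell: int = 10) -> list[tuple[int, str, str]]:
    """Debounced state changes: (frame, from_state, to_state), ordered by frame.

    A change is reported only when the new state persists for at least
    ``min_dwell`` consecutive frames, which suppresses single-frame noise
    spikes; the macroscopic transitions of interest dwell far longer.
    """
    if min_dwell < 1:
        raise ValidationError("min_dwell must be >= 1")
    if len(series) == 0:
        raise ValidationError("empty series")
    states = [classifier(v) for v in series.values]
    out = []
    current = states[0]
    n = len(states)
    i = 1
    while i < n:
        s = states[i]
        if s == current:
            i += 1
            continue
        run = 1
        while i + run < n and states[i + run] == s:
            run += 1
        if run >= min_dwell:
            out.append((i, current, s))
            current = s
        i += run
    return out
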