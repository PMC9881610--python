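"""Monte-Carlo docking in the FragMap field.

Each run places the ligand at random inside a sphere around the pocket
center, greedily minimizes the LGFE, samples with Metropolis MC at fixed
temperature, then anneals the temperature linearly to zero, keeping the
lowest-LGFE pose seen. Runs are repeated in independent blocks until the
two lowest run minima agree within a convergence tolerance or a run cap is
reached.

Intramolecular strain is not modeled by default; an optional
``intramolecular_energy(coords) -> kcal/mol`` callback can be added to the
MC energy for ligands where it matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .grids import KB_KCAL, FragMapSet
from .ligands import AtomClassAssignment, Conformer, IonizationPair, Ligand, Torsion, rotatable_bonds
from .scoring import GFEBreakdown, PoseScorer, WeightVector, atomic_gfes


@dataclass
class MoveAmplitudes:
    """Maximum per-move perturbations; uniform within the amplitude."""

    translation: float = 1.0  # Å
    rotation: float = 0.25  # rad
    torsion: float = 0.5  # rad


@dataclass
class DockProtocol:
    """Full docking protocol parameters.

    Defaults mirror the production setup: 10 Å placement radius, 10,000
    greedy minimization moves, 10,000 Metropolis steps at 300 K, 40,000
    annealing steps from 300 K to 0 K, five independent blocks of up to 50
    runs each, convergence when the two lowest run minima agree within
    0.5 kcal/mol, hard cap of 250 runs.
    """

    pocket_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    placement_radius: float = 10.0
    n_min_steps: int = 10_000
    n_mc_steps: int = 10_000
    T_mc: float = 300.0
    n_anneal_steps: int = 40_000
    T_anneal_start: float = 300.0
    T_anneal_end: float = 0.0
    n_independent: int = 5
    runs_per_block: int = 50
    convergence_tol: float = 0.5
    max_runs: int = 250
    amplitudes: MoveAmplitudes = field(default_factory=MoveAmplitudes)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.pocket_center = np.asarray(self.pocket_center, dtype=float).reshape(3)
        if self.placement_radius <= 0:
            raise ValueError("placement_radius must be > 0")
        for name in ("n_min_steps", "n_mc_steps", "n_anneal_steps", "n_independent",
                     "runs_per_block", "max_runs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")
        if self.T_anneal_end > self.T_anneal_start:
            raise ValueError("T_anneal_end must not exceed T_anneal_start")


@dataclass
class DockResult:
    """Outcome of a multi-run dock: global-best pose and diagnostics."""

    best_conformer: Conformer
    best_lgfe: float
    breakdown: GFEBreakdown
    site_label: str
    runs_executed: int
    converged: bool
    run_minima: list[float] = field(default_factory=list)


def random_rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation via a random unit quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def random_placement(lig: Ligand, protocol: DockProtocol, rng: np.random.Generator) -> Conformer:
    """Place the ligand with centroid uniform in the placement sphere and a
    uniform random rigid orientation; internal geometry is untouched."""
    coords = lig.coords
    centroid = coords.mean(axis=0)
    # uniform point in sphere: direction x cbrt(u) scaling
    direction = rng.normal(size=3)
    norm = np.linalg.norm(direction)
    direction = direction / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
    r = protocol.placement_radius * rng.random() ** (1.0 / 3.0)
    target = protocol.pocket_center + r * direction
    rot = random_rotation_matrix(rng)
    new = (coords - centroid) @ rot.T + target
    return Conformer(lig, new)


def apply_torsion(coords: np.ndarray, torsion: Torsion, angle: float) -> np.ndarray:
    """Rotate the movable side of a torsion about its j→k bond axis."""
    new = coords.copy()
    pj, pk = coords[torsion.j], coords[torsion.k]
    axis = pk - pj
    rot = _axis_rotation(axis, angle)
    movable = sorted(torsion.movable - {torsion.k})
    if movable:
        new[movable] = (coords[movable] - pk) @ rot.T + pk
    return new


def propose_move(
    coords: np.ndarray,
    torsions: Sequence[Torsion],
    amplitudes: MoveAmplitudes,
    rng: np.random.Generator,
) -> np.ndarray:
    """One MC move: rigid translation, rigid rotation, or torsion rotation.

    The move type is chosen uniformly among the available kinds (torsions
    only when rotatable bonds exist); the perturbation magnitude is uniform
    within the amplitude. Rigid moves preserve all interatomic distances.
    """
    n_kinds = 3 if torsions else 2
    kind = rng.integers(n_kinds)
    if kind == 0:  # translate
        shift = rng.uniform(-amplitudes.translation, amplitudes.translation, size=3)
        return coords + shift
    if kind == 1:  # rotate about centroid
        angle = rng.uniform(-amplitudes.rotation, amplitudes.rotation)
        axis = rng.normal(size=3)
        while np.linalg.norm(axis) == 0:
            axis = rng.normal(size=3)
        rot = _axis_rotation(axis, angle)
        centroid = coords.mean(axis=0)
        return (coords - centroid) @ rot.T + centroid
    t = torsions[rng.integers(len(torsions))]
    angle = rng.uniform(-amplitudes.torsion, amplitudes.torsion)
    return apply_torsion(coords, t, angle)


def metropolis(delta_e: float, T: float, rng: np.random.Generator) -> bool:
    """Metropolis criterion: accept downhill always; uphill with
    probability exp(-ΔE / kB T); at T = 0 only downhill moves pass."""
    if T < 0:
        raise ValueError("temperature must be >= 0")
    if delta_e <= 0:
        return True
    if T == 0:
        return False
    return rng.random() < np.exp(-delta_e / (KB_KCAL * T))


def anneal_run(
    lig: Ligand,
    maps: FragMapSet,
    assignment: AtomClassAssignment,
    w: WeightVector | None,
    protocol: DockProtocol,
    rng: np.random.Generator,
    intramolecular_energy: Callable[[np.ndarray], float] | None = None,
) -> tuple[Conformer, float]:
    """One docking run: placement → greedy minimization → fixed-T MC →
    simulated annealing; returns the lowest-LGFE pose seen.

    Greedy minimization accepts only LGFE-lowering moves, standing in for
    a force-field pre-minimization; the optional intramolecular-energy
    callback is added to the MC energy (the returned score is LGFE only).
    """
    torsions = rotatable_bonds(lig)
    scorer = PoseScorer(assignment, maps, w)

    def energy(c: np.ndarray) -> tuple[float, float]:
        s = scorer.score(c)
        e = s + (intramolecular_energy(c) if intramolecular_energy else 0.0)
        return e, s

    conf = random_placement(lig, protocol, rng)
    coords = conf.coords
    e_cur, lgfe_cur = energy(coords)
    best_coords, best_lgfe = coords.copy(), lgfe_cur

    def track(c: np.ndarray, s: float) -> None:
        nonlocal best_coords, best_lgfe
        if s < best_lgfe:
            best_coords, best_lgfe = c.copy(), s

    for _ in range(protocol.n_min_steps):
        cand = propose_move(coords, torsions, protocol.amplitudes, rng)
        e_new, lgfe_new = energy(cand)
        if e_new < e_cur:
            coords, e_cur, lgfe_cur = cand, e_new, lgfe_new
            track(coords, lgfe_cur)

    for _ in range(protocol.n_mc_steps):
        cand = propose_move(coords, torsions, protocol.amplitudes, rng)
        e_new, lgfe_new = energy(cand)
        if metropolis(e_new - e_cur, protocol.T_mc, rng):
            coords, e_cur, lgfe_cur = cand, e_new, lgfe_new
            track(coords, lgfe_cur)

    n = protocol.n_anneal_steps
    for step in range(n):
        frac = step / max(n - 1, 1)
        T = protocol.T_anneal_start + frac * (protocol.T_anneal_end - protocol.T_anneal_start)
        cand = propose_move(coords, torsions, protocol.amplitudes, rng)
        e_new, lgfe_new = energy(cand)
        if metropolis(e_new - e_cur, T, rng):
            coords, e_cur, lgfe_cur = cand, e_new, lgfe_new
            track(coords, lgfe_cur)

    return Conformer(lig, best_coords), best_lgfe


def dock(
    lig: Ligand,
    maps: FragMapSet,
    assignment: AtomClassAssignment,
    protocol: DockProtocol,
    w: WeightVector | None = None,
    site_label: str = "S1",
    intramolecular_energy: Callable[[np.ndarray], float] | None = None,
) -> DockResult:
    """Multi-run dock with the block/convergence protocol.

    Executes up to ``n_independent`` blocks of up to ``runs_per_block``
    runs (each block on its own reproducible RNG substream); after each
    run, convergence is declared when the two lowest run minima agree
    within ``convergence_tol``. Stops unconditionally at ``max_runs``.
    The result is the global minimum over all runs.
    """
    run_minima: list[float] = []
    best_conf: Conformer | None = None
    best_lgfe = np.inf
    runs_executed = 0
    converged = False

    for block in range(protocol.n_independent):
        rng = np.random.default_rng([protocol.rng_seed, block])
        for _ in range(protocol.runs_per_block):
            if runs_executed >= protocol.max_runs or converged:
                break
            conf, run_lgfe = anneal_run(
                lig, maps, assignment, w, protocol, rng, intramolecular_energy
            )
            runs_executed += 1
            run_minima.append(run_lgfe)
            if run_lgfe < best_lgfe:
                best_conf, best_lgfe = conf, run_lgfe
            if len(run_minima) >= 2:
                lo = sorted(run_minima)[:2]
                if lo[1] - lo[0] <= protocol.convergence_tol:
                    converged = True
        if converged:
            break

    if best_conf is None:  # zero-run protocol: score the input pose in place
        best_conf = Conformer.from_ligand(lig)
        best_lgfe = atomic_gfes(best_conf, assignment, maps, w).total
    breakdown = atomic_gfes(best_conf, assignment, maps, w)
    return DockResult(
        best_conformer=best_conf,
        best_lgfe=best_lgfe,
        breakdown=breakdown,
        site_label=site_label,
        runs_executed=runs_executed,
        converged=converged,
        run_minima=run_minima,
    )


def dock_pair(
    pair: IonizationPair,
    maps: FragMapSet,
    assignments: dict[str, AtomClassAssignment],
    protocol: DockProtocol,
    w: WeightVector | None = None,
    site_label: str = "S1",
) -> dict[str, DockResult]:
    """Dock both protomers of an ionizable compound; keys 'neutral'/'charged'."""
    return {
        "neutral": dock(pair.neutral, maps, assignments["neutral"], protocol, w, site_label),
        "charged": dock(
            pair.charged, maps, assignments["charged"],
            replace(protocol, rng_seed=protocol.rng_seed + 1), w, site_label,
        ),
    }
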