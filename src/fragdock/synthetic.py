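"""Synthetic fixtures with known ground truth.

Every stage of the stack is testable without external data: FragMaps are
sums of negative Gaussian wells on a capped baseline, ligands are
procedurally built chains with known atom-class composition, and affinity
tables are generated from a known true weight vector with Gaussian noise
in pIC50 space. The generator emulates the *shape* of the real inputs
(volumetric GFE maps, SDF ligands, affinity tables), not hERG pharmacology
or realistic chemotypes — the scoring, docking and reweighting machinery
never inspects chemistry beyond class labels and coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bml import AtomicGFETable
from .grids import DEFAULT_GFE_CAP, DEFAULT_MAP_TYPES, FragMapGrid, FragMapSet
from .ligands import Atom, AtomClassAssignment, Ligand
from .scoring import lgfe_to_pic50


@dataclass
class GaussianWell:
    """One attractive basin: value depth·exp(-|r-center|²/(2 width²))."""

    center: tuple[float, float, float]
    depth: float  # kcal/mol, <= 0
    width: float  # Å

    def __post_init__(self) -> None:
        if self.depth > 0:
            raise ValueError("well depth must be <= 0")
        if self.width <= 0:
            raise ValueError("well width must be > 0")


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic fixtures.

    Defaults: a 21³ grid at 1 Å spacing centered on the origin; one well
    per FragMap type (depth -6 kcal/mol, width 2.5 Å) at distinct offsets;
    50 ligands of 4-10 heavy atoms; true weights spread across the
    optimizer bounds; pIC50 noise σ = 0.3 log units.
    """

    dims: tuple[int, int, int] = (21, 21, 21)
    spacing: float = 1.0
    gfe_cap: float = DEFAULT_GFE_CAP
    wells: dict[str, list[GaussianWell]] = field(default_factory=lambda: {
        "GENN": [GaussianWell((0.0, 0.0, 0.0), -6.0, 2.5)],
        "GEND": [GaussianWell((4.0, 0.0, 0.0), -6.0, 2.5)],
        "GENA": [GaussianWell((-4.0, 0.0, 0.0), -6.0, 2.5)],
        "MAMN": [GaussianWell((0.0, 4.0, 0.0), -6.0, 2.5)],
        "ACEO": [GaussianWell((0.0, -4.0, 0.0), -6.0, 2.5)],
    })
    n_ligands: int = 50
    size_range: tuple[int, int] = (4, 10)
    true_weights: dict[str, float] = field(default_factory=lambda: {
        "GENN": 0.8, "GEND": 1.5, "GENA": 0.6, "MAMN": 1.2, "ACEO": 0.4,
    })
    noise_sigma: float = 0.3
    descriptor_coefficients: dict[str, float] = field(default_factory=lambda: {
        "logP": 0.4, "logS": -0.3, "TPSA": 0.01, "MW": 0.002, "vdW_volume": 0.001,
    })
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        lo, hi = self.size_range
        if lo < 1 or hi < lo:
            raise ValueError("size_range must satisfy 1 <= lo <= hi")

    @property
    def origin(self) -> np.ndarray:
        return -(np.array(self.dims) - 1) / 2.0 * self.spacing


# ---------------------------------------------------------------------------
# FragMaps
# ---------------------------------------------------------------------------

def _well_grid(spec: SyntheticSpec, wells: Sequence[GaussianWell]) -> np.ndarray:
    origin = spec.origin
    axes = [origin[a] + spec.spacing * np.arange(spec.dims[a]) for a in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    vals = np.full(spec.dims, spec.gfe_cap, dtype=float)
    hi = origin + (np.array(spec.dims) - 1) * spec.spacing
    for well in wells:
        c = np.asarray(well.center, dtype=float)
        if np.any(c < origin) or np.any(c > hi):
            raise ValueError(f"well center {tuple(c)} lies outside the grid bounds")
        r2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
        vals += well.depth * np.exp(-r2 / (2.0 * well.width**2))
    return vals


def make_fragmaps(spec: SyntheticSpec) -> FragMapSet:
    """Gaussian-well FragMaps: cap baseline plus summed negative wells.

    Wells only subtract from the baseline, so the favorable side is never
    capped; values are clipped at ``gfe_cap`` per the grid rules.
    """
    grids = {}
    for map_type, wells in spec.wells.items():
        grids[map_type] = FragMapGrid(
            map_type=map_type,
            origin=spec.origin,
            spacing=np.full(3, spec.spacing),
            values=_well_grid(spec, wells),
            gfe_cap=spec.gfe_cap,
        )
    return FragMapSet(grids)


def single_well_map(
    map_type: str = "GENN",
    center=(0.0, 0.0, 0.0),
    depth: float = -6.0,
    width: float = 2.5,
    dims: tuple[int, int, int] = (21, 21, 21),
    spacing: float = 1.0,
    gfe_cap: float = DEFAULT_GFE_CAP,
) -> FragMapSet:
    """Convenience: a FragMapSet holding one single-Gaussian-well map."""
    spec = SyntheticSpec(
        dims=dims, spacing=spacing, gfe_cap=gfe_cap,
        wells={map_type: [GaussianWell(tuple(center), depth, width)]},
    )
    return make_fragmaps(spec)


# ---------------------------------------------------------------------------
# Ligands
# ---------------------------------------------------------------------------

#: label → (element, formal charge, hydrogens) for chain building; interior
#: and terminal variants keep valences chemically sane.
_LABEL_ATOMS = {
    "GENN": {"interior": ("C", 0, 2), "terminal": ("C", 0, 3)},
    "GEND": {"interior": ("N", 0, 1), "terminal": ("O", 0, 1)},
    "GENA": {"interior": ("O", 0, 0), "terminal": ("N", 0, 0)},
    "MAMN": {"interior": ("N", 1, 2), "terminal": ("N", 1, 3)},
    "ACEO": {"terminal": ("O", -1, 0), "interior": ("O", -1, 0)},
}

_BOND_DX = 1.3
_BOND_DY = 0.75  # zig-zag; bond length = sqrt(1.3² + 0.75²) = 1.5 Å


def build_chain_ligand(name: str, labels: Sequence[str]) -> tuple[Ligand, AtomClassAssignment]:
    """Build a heavy-atom zig-zag chain whose classification is ``labels``.

    Atom k sits at (1.3k, ±0.75, 0) so every bond is 1.5 Å. Charged and
    acceptor labels are only chemically sensible at some positions; the
    table picks an interior or terminal variant accordingly, and the
    returned assignment is the by-construction ground truth.
    """
    if not labels:
        raise ValueError("need at least one atom label")
    atoms = []
    n = len(labels)
    for k, label in enumerate(labels):
        pos_kind = "terminal" if (k == 0 or k == n - 1) else "interior"
        element, charge, n_h = _LABEL_ATOMS[label][pos_kind]
        coords = np.array([_BOND_DX * k, _BOND_DY * (k % 2), 0.0])
        atoms.append(Atom(element=element, formal_charge=charge, coords=coords, n_hydrogens=n_h))
    bonds = [(k, k + 1, 1) for k in range(n - 1)]
    lig = Ligand(name=name, atoms=atoms, bonds=bonds)
    return lig, AtomClassAssignment(list(labels))


def make_ligand_set(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> list[tuple[Ligand, AtomClassAssignment]]:
    """Procedural ligand set with known class composition.

    Each ligand is a chain of 4-10 heavy atoms: a carbon backbone with a
    random sprinkling of donor / acceptor / charged positions, so the
    per-type GFE features vary across the set.
    """
    rng = rng or np.random.default_rng(spec.rng_seed)
    out = []
    lo, hi = spec.size_range
    label_pool = list(spec.wells) or list(DEFAULT_MAP_TYPES)
    for i in range(spec.n_ligands):
        n = int(rng.integers(lo, hi + 1))
        labels = ["GENN" if "GENN" in label_pool else label_pool[0]] * n
        # decorate 0-3 random positions with non-apolar types
        n_hetero = int(rng.integers(0, min(3, n) + 1))
        hetero_types = [t for t in label_pool if t != "GENN"]
        if hetero_types:
            for pos in rng.choice(n, size=n_hetero, replace=False):
                labels[pos] = hetero_types[int(rng.integers(len(hetero_types)))]
        lig, assignment = build_chain_ligand(f"syn{i:03d}", labels)
        out.append((lig, assignment))
    return out


# ---------------------------------------------------------------------------
# BML dataset
# ---------------------------------------------------------------------------

def make_bml_dataset(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[AtomicGFETable, dict[str, float]]:
    """Synthetic atomic-GFE table with known true weights.

    Features g_i[t] are drawn uniform[-5, 0] on a per-ligand random
    sparsity pattern (each type present with probability 0.7, at least one
    per ligand); experimental pIC50 is the true-weight prediction plus
    Gaussian noise of σ = ``noise_sigma`` log units. Returns the table and
    the generating weights for recovery tests.
    """
    rng = rng or np.random.default_rng(spec.rng_seed)
    if spec.n_ligands == 0:
        raise ValueError("empty table: n_ligands must be >= 1")
    types = list(spec.true_weights)
    n_t = len(types)
    g = np.zeros((spec.n_ligands, n_t))
    for i in range(spec.n_ligands):
        occupied = rng.random(n_t) < 0.7
        if not occupied.any():
            occupied[rng.integers(n_t)] = True
        g[i, occupied] = rng.uniform(-5.0, 0.0, size=int(occupied.sum()))
    w_star = np.array([spec.true_weights[t] for t in types])
    exp = lgfe_to_pic50(g @ w_star) + rng.normal(0.0, spec.noise_sigma, size=spec.n_ligands)
    table = AtomicGFETable(
        ligand_ids=[f"syn{i:03d}" for i in range(spec.n_ligands)],
        map_types=types,
        g=g,
        exp_pic50=exp,
    )
    return table, dict(spec.true_weights)


# ---------------------------------------------------------------------------
# Descriptors / two-signal affinity study
# ---------------------------------------------------------------------------

def make_descriptor_table(
    ids: Sequence[str], rng: np.random.Generator
) -> pd.DataFrame:
    """Random but plausibly scaled physicochemical descriptors per compound."""
    n = len(ids)
    return pd.DataFrame(
        {
            "compound": list(ids),
            "logP": rng.normal(2.5, 1.5, n),
            "logS": rng.normal(-4.0, 1.0, n),
            "TPSA": rng.uniform(20.0, 140.0, n),
            "MW": rng.uniform(200.0, 550.0, n),
            "vdW_volume": rng.uniform(150.0, 500.0, n),
        }
    )


def two_signal_affinities(
    structure_pic50: np.ndarray,
    descriptors: pd.DataFrame,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    alpha: float = 0.5,
    beta: float = 0.5,
) -> np.ndarray:
    """Affinities carrying both a descriptor and a structure signal.

    exp = α·(descriptor linear signal) + β·(structure pIC50) + N(0, σ);
    by construction a consensus model using both sources outranks either
    single-source model.
    """
    coef = spec.descriptor_coefficients
    desc_signal = sum(
        coef[c] * descriptors[c].to_numpy(dtype=float) for c in coef
    )
    noise = rng.normal(0.0, spec.noise_sigma, size=len(descriptors))
    return alpha * desc_signal + beta * np.asarray(structure_pic50, float) + noise
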