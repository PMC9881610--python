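"""Molecular data model, SDF ingestion, atom classification, rotatable bonds.

Ligands are held as explicit molecular graphs (elements, formal charges,
hydrogen counts, bonds, 3D coordinates). Atom classification assigns each
heavy atom to one FragMap type — apolar carbon (GENN), H-bond donor (GEND),
H-bond acceptor (GENA), charged nitrogen (MAMN) or charged-group oxygen
(ACEO) — with precedence charged > donor > acceptor > apolar. The default
rule table is a documented approximation of the generic apolar-scale
classification scheme used with cosolvent-derived maps; users can load a
replacement table from YAML.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class Atom:
    element: str
    formal_charge: int = 0
    aromatic: bool = False
    coords: np.ndarray = field(default_factory=lambda: np.zeros(3))
    n_hydrogens: int = 0  # implicit+explicit H attached (donor detection)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(3)


@dataclass
class Ligand:
    """A small molecule: graph + one set of 3D coordinates.

    ``ionization_state`` distinguishes the neutral and charged protomers of
    ionizable compounds, which are supplied as explicit separate structures.
    """

    name: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, int]]  # (i, j, order)
    ionization_state: str = "neutral"

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) indexes outside {n} atoms")
        if not all(np.all(np.isfinite(a.coords)) for a in self.atoms):
            raise ValueError("atom coordinates must be finite")
        if n > 1 and len(self._components()) > 1:
            warnings.warn(f"ligand {self.name!r}: molecular graph is disconnected")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a.element != "H" for a in self.atoms])

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.atoms]
        for i, j, _ in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def _components(self) -> list[set[int]]:
        adj = self.adjacency()
        seen: set[int] = set()
        comps = []
        for start in range(self.n_atoms):
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            while stack:
                v = stack.pop()
                for w in adj[v]:
                    if w not in comp:
                        comp.add(w)
                        stack.append(w)
            seen |= comp
            comps.append(comp)
        return comps

    def with_coords(self, coords: np.ndarray) -> "Ligand":
        coords = np.asarray(coords, dtype=float)
        atoms = [replace(a, coords=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return Ligand(self.name, atoms, list(self.bonds), self.ionization_state)


@dataclass
class Conformer:
    """One pose of a parent ligand: same atoms, alternative coordinates."""

    parent: Ligand
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.parent.n_atoms, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match parent "
                f"({self.parent.n_atoms} atoms)"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("conformer coordinates must be finite")

    @classmethod
    def from_ligand(cls, lig: Ligand) -> "Conformer":
        return cls(lig, lig.coords)

    def centroid(self, heavy_only: bool = True) -> np.ndarray:
        mask = self.parent.heavy_mask if heavy_only else np.ones(len(self.coords), bool)
        return self.coords[mask].mean(axis=0)


@dataclass
class AtomClassAssignment:
    """Per-atom FragMap-type labels; hydrogens are always UNCLASSIFIED."""

    labels: list[str]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("empty assignment")

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, i: int) -> str:
        return self.labels[i]


@dataclass
class IonizationPair:
    """Neutral and charged protomers of an ionizable compound plus its pKa."""

    neutral: Ligand
    charged: Ligand
    pKa: float
    kind: str  # "acid" or "base"

    def __post_init__(self) -> None:
        if self.kind not in ("acid", "base"):
            raise ValueError(f"kind must be 'acid' or 'base', got {self.kind!r}")
        if not np.isfinite(self.pKa):
            raise ValueError("pKa must be finite")
        n_heavy = int(self.neutral.heavy_mask.sum())
        if n_heavy != int(self.charged.heavy_mask.sum()):
            raise ValueError("neutral and charged states must share the heavy-atom scaffold")


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

#: Default rule table. Each rule: match conditions on element / charge sign /
#: hydrogen count; first match wins. Precedence: charged > donor > acceptor
#: > apolar.
DEFAULT_CLASSIFICATION_RULES: list[dict] = [
    {"label": "MAMN", "element": ["N"], "charge": "+"},
    {"label": "ACEO", "element": ["O"], "charge": "-"},
    {"label": "ACEO", "element": ["O"], "charged_group": "-"},
    {"label": "GEND", "element": ["N", "O"], "min_hydrogens": 1},
    {"label": "GENA", "element": ["N", "O"]},
    {"label": "GENN", "element": ["C"]},
]


@dataclass
class ClassificationScheme:
    """Ordered first-match-wins rule table mapping atom environment to label."""

    rules: list[dict] = field(default_factory=lambda: list(DEFAULT_CLASSIFICATION_RULES))

    @classmethod
    def from_yaml(cls, path) -> "ClassificationScheme":
        data = yaml.safe_load(Path(path).read_text())
        return cls(rules=list(data["rules"]))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump({"rules": self.rules}, sort_keys=False))


def _rule_matches(rule: dict, lig: Ligand, i: int) -> bool:
    atom = lig.atoms[i]
    if "element" in rule and atom.element not in rule["element"]:
        return False
    if "charge" in rule:
        want = rule["charge"]
        if want == "+" and atom.formal_charge <= 0:
            return False
        if want == "-" and atom.formal_charge >= 0:
            return False
        if want == "0" and atom.formal_charge != 0:
            return False
    if "charged_group" in rule:
        # resonance partner of a charged same-element atom: the atom must be
        # double-bonded to a shared neighbor that also bears the charged atom
        # (e.g. the carbonyl oxygen of a carboxylate); single-bonded chain
        # neighbors do not qualify
        sign = 1 if rule["charged_group"] == "+" else -1
        orders = {}
        for a, b, o in lig.bonds:
            orders[(a, b)] = o
            orders[(b, a)] = o
        found = False
        for nb in lig.neighbors(i):
            if orders.get((i, nb), 1) < 2:
                continue
            for nb2 in lig.neighbors(nb):
                a2 = lig.atoms[nb2]
                if nb2 != i and a2.element == atom.element and a2.formal_charge * sign > 0:
                    found = True
        if not found:
            return False
    if "min_hydrogens" in rule and atom.n_hydrogens < rule["min_hydrogens"]:
        return False
    if "aromatic" in rule and atom.aromatic != bool(rule["aromatic"]):
        return False
    return True


def classify_atoms(lig: Ligand, scheme: ClassificationScheme | None = None) -> AtomClassAssignment:
    """Assign each heavy atom a FragMap-type label; hydrogens get UNCLASSIFIED.

    Pure function of the molecular graph and formal charges — coordinates
    never enter. Heavy atoms matching no rule (unknown elements under the
    default table) are labeled UNCLASSIFIED with a warning.
    """
    scheme = scheme or ClassificationScheme()
    labels = []
    for i, atom in enumerate(lig.atoms):
        if atom.element == "H":
            labels.append(UNCLASSIFIED)
            continue
        for rule in scheme.rules:
            if _rule_matches(rule, lig, i):
                labels.append(rule["label"])
                break
        else:
            warnings.warn(
                f"ligand {lig.name!r}: atom {i} ({atom.element}) matches no "
                f"classification rule; labeled UNCLASSIFIED"
            )
            labels.append(UNCLASSIFIED)
    return AtomClassAssignment(labels)


# ---------------------------------------------------------------------------
# Rotatable bonds
# ---------------------------------------------------------------------------

@dataclass
class Torsion:
    """A rotatable bond j-k with flanking atoms i, l and the movable atom set.

    Rotating the torsion moves every atom in ``movable`` (the side containing
    ``k``) about the j→k axis.
    """

    i: int
    j: int
    k: int
    l: int
    movable: frozenset[int]


def _bond_in_ring(lig: Ligand, bi: int, bj: int) -> bool:
    # a bond is in a ring iff its endpoints stay connected with it removed
    adj = lig.adjacency()
    seen = {bi}
    stack = [bi]
    while stack:
        v = stack.pop()
        for w in adj[v]:
            if (v, w) in ((bi, bj), (bj, bi)):
                continue
            if w == bj:
                return True
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return False


def _side_atoms(lig: Ligand, root: int, blocked: int) -> frozenset[int]:
    """Atoms reachable from ``root`` without passing through ``blocked``."""
    adj = lig.adjacency()
    seen = {root}
    stack = [root]
    while stack:
        v = stack.pop()
        for w in adj[v]:
            if w == blocked or w in seen:
                continue
            seen.add(w)
            stack.append(w)
    return frozenset(seen)


def rotatable_bonds(lig: Ligand) -> list[Torsion]:
    """Detect rotatable torsions: single acyclic bonds between non-terminal
    heavy atoms.

    A bond qualifies when it is order 1, not in a ring, and both endpoints
    are heavy atoms with at least two heavy neighbors (terminal methyls,
    hydroxyls etc. are excluded — rotating them never changes heavy-atom
    positions).
    """
    heavy = lig.heavy_mask
    adj = lig.adjacency()

    def n_heavy_neighbors(i: int) -> int:
        return sum(1 for w in adj[i] if heavy[w])

    torsions = []
    for bi, bj, order in lig.bonds:
        if order != 1 or not (heavy[bi] and heavy[bj]):
            continue
        if n_heavy_neighbors(bi) < 2 or n_heavy_neighbors(bj) < 2:
            continue
        if _bond_in_ring(lig, bi, bj):
            continue
        i_fl = next(w for w in adj[bi] if w != bj and heavy[w])
        l_fl = next(w for w in adj[bj] if w != bi and heavy[w])
        movable = _side_atoms(lig, bj, blocked=bi)
        torsions.append(Torsion(i=i_fl, j=bi, k=bj, l=l_fl, movable=movable))
    return torsions


# ---------------------------------------------------------------------------
# SDF I/O (rdkit-backed)
# ---------------------------------------------------------------------------

def _rdkit_to_ligand(mol, name: str | None = None) -> Ligand:
    from rdkit import Chem

    conf = mol.GetConformer()
    atoms = []
    for a in mol.GetAtoms():
        pos = conf.GetAtomPosition(a.GetIdx())
        atoms.append(
            Atom(
                element=a.GetSymbol(),
                formal_charge=a.GetFormalCharge(),
                aromatic=a.GetIsAromatic(),
                coords=np.array([pos.x, pos.y, pos.z]),
                n_hydrogens=a.GetTotalNumHs(includeNeighbors=True),
            )
        )
    order_map = {Chem.BondType.SINGLE: 1, Chem.BondType.DOUBLE: 2, Chem.BondType.TRIPLE: 3,
                 Chem.BondType.AROMATIC: 1}
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order_map.get(b.GetBondType(), 1))
        for b in mol.GetBonds()
    ]
    if name is None:
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else "unnamed"
    return Ligand(name=name, atoms=atoms, bonds=bonds)


def ligand_to_rdkit(lig: Ligand):
    """Build an rdkit RWMol (with conformer) from a Ligand."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    mol = Chem.RWMol()
    for a in lig.atoms:
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(a.formal_charge)
        ra.SetNoImplicit(True)
        ra.SetNumExplicitHs(a.n_hydrogens)
        mol.AddAtom(ra)
    order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
    for i, j, order in lig.bonds:
        mol.AddBond(i, j, order_map.get(order, Chem.BondType.SINGLE))
    conf = Chem.Conformer(lig.n_atoms)
    for i, a in enumerate(lig.atoms):
        conf.SetAtomPosition(i, Point3D(*[float(v) for v in a.coords]))
    m = mol.GetMol()
    m.AddConformer(conf)
    m.SetProp("_Name", lig.name)
    Chem.SanitizeMol(m, catchErrors=True)
    return m


def read_sdf(path) -> list[Ligand]:
    """Read a V2000/V3000 SDF into Ligands.

    Records that rdkit cannot parse are skipped with a logged reason; an
    SDF yielding zero parsable records is an error.
    """
    from rdkit import Chem

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    ligands = []
    for idx, mol in enumerate(supplier):
        if mol is None:
            logger.warning("%s: record %d unparsable, skipped", path, idx)
            continue
        try:
            Chem.SanitizeMol(
                mol,
                Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES,
                catchErrors=False,
            )
            ligands.append(_rdkit_to_ligand(mol))
        except Exception as exc:  # noqa: BLE001 — degraded-input contract
            logger.warning("%s: record %d failed sanity checks (%s), skipped", path, idx, exc)
    if not ligands:
        raise ValueError(f"{path}: no parsable SDF records")
    return ligands


def write_sdf(ligands: Iterable[Ligand], path, properties: dict[str, dict] | None = None) -> None:
    """Write ligands to SDF; optional per-ligand tag dict keyed by name."""
    from rdkit import Chem

    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for lig in ligands:
            mol = ligand_to_rdkit(lig)
            for key, val in (properties or {}).get(lig.name, {}).items():
                mol.SetProp(key, str(val))
            writer.write(mol)
    finally:
        writer.close()
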