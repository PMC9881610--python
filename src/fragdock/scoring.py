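"""LGFE scoring: atomic GFE lookups, weighting, HH mixing, pIC50 conversion.

The ligand grid free energy (LGFE) of a pose is the sum over classified
heavy atoms of the GFE of the voxel each atom occupies in the FragMap of
its type, scaled by a per-map-type weight. The score is exactly linear in
the weight vector, which the weight-optimization fast path exploits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .grids import KB_KCAL, FragMapSet, gfe_at_many
from .ligands import UNCLASSIFIED, AtomClassAssignment, Conformer

#: ln(10) * kB * 300 K — converts kcal/mol to pIC50 log units.
PIC50_PER_KCAL = math.log(10.0) * KB_KCAL * 300.0


class WeightVector(dict):
    """Per-FragMap-type multiplicative weights; missing types default to 1.

    After Bayesian reweighting the entries are expected to lie inside the
    optimizer's flat-bottom bounds.
    """

    def __init__(self, weights: Mapping[str, float] | None = None):
        super().__init__()
        for k, v in (weights or {}).items():
            v = float(v)
            if v < 0:
                raise ValueError(f"weight for {k!r} must be >= 0, got {v}")
            self[k] = v

    def __missing__(self, key: str) -> float:
        return 1.0

    def get(self, key, default=None):  # keep defaulting behavior for .get too
        return super().get(key, 1.0 if default is None else default)

    def scaled(self, alpha: float) -> "WeightVector":
        return WeightVector({k: alpha * v for k, v in self.items()})

    @classmethod
    def ones(cls, map_types: Sequence[str]) -> "WeightVector":
        return cls({t: 1.0 for t in map_types})

    def as_array(self, map_types: Sequence[str]) -> np.ndarray:
        return np.array([self[t] for t in map_types])


@dataclass
class GFEBreakdown:
    """Per-atom GFE contributions (kcal/mol); total is their exact sum."""

    per_atom: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.per_atom = np.asarray(self.per_atom, dtype=float)

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())

    def group_sums(self, groups: Mapping[str, Sequence[int]]) -> dict[str, float]:
        """Sum atomic GFEs over user-defined atom index sets (moieties)."""
        return {name: float(self.per_atom[list(idx)].sum()) for name, idx in groups.items()}

    def by_map_type(self) -> dict[str, float]:
        """Weighted GFE attributed to each FragMap type."""
        out: dict[str, float] = {}
        for v, lab in zip(self.per_atom, self.labels):
            if lab != UNCLASSIFIED:
                out[lab] = out.get(lab, 0.0) + float(v)
        return out


def atomic_gfes(
    conf: Conformer,
    assignment: AtomClassAssignment,
    maps: FragMapSet,
    w: WeightVector | None = None,
) -> GFEBreakdown:
    """Per-atom GFE scores for a pose.

    Each classified atom contributes ``w[label] * gfe_at(maps[label], xyz)``;
    UNCLASSIFIED atoms (hydrogens, unknown elements) contribute zero. Labels
    with no corresponding grid contribute zero with a warning.
    """
    if len(assignment) != conf.parent.n_atoms:
        raise ValueError("assignment length does not match conformer's parent")
    w = w if w is not None else WeightVector()
    per_atom = np.zeros(conf.parent.n_atoms)
    labels = list(assignment.labels)
    missing: set[str] = set()
    for label in set(labels) - {UNCLASSIFIED}:
        idx = [i for i, lab in enumerate(labels) if lab == label]
        if label not in maps:
            missing.add(label)
            continue
        per_atom[idx] = w[label] * gfe_at_many(maps[label], conf.coords[idx])
    if missing:
        warnings.warn(f"no FragMap for labels {sorted(missing)}; contributions set to 0")
    return GFEBreakdown(per_atom=per_atom, labels=labels)


def lgfe(
    conf: Conformer,
    assignment: AtomClassAssignment,
    maps: FragMapSet,
    w: WeightVector | None = None,
) -> float:
    """Ligand grid free energy: exact sum of the atomic GFE scores, kcal/mol."""
    return atomic_gfes(conf, assignment, maps, w).total


class PoseScorer:
    """Precompiled LGFE evaluator for repeated scoring of one ligand.

    Groups atom indices by label and caches grid arrays so the docking hot
    loop avoids per-call set arithmetic. Produces values identical to
    :func:`lgfe`.
    """

    def __init__(self, assignment: AtomClassAssignment, maps: FragMapSet, w: WeightVector | None = None):
        w = w if w is not None else WeightVector()
        self._groups = []
        labels = list(assignment.labels)
        for label in sorted(set(labels) - {UNCLASSIFIED}):
            if label not in maps:
                continue
            idx = np.array([i for i, lab in enumerate(labels) if lab == label])
            g = maps[label]
            self._groups.append(
                (idx, g.values, g.origin, 1.0 / g.spacing, np.array(g.dims), g.gfe_cap, w[label])
            )

    def score(self, coords: np.ndarray) -> float:
        total = 0.0
        for idx, values, origin, inv_sp, dims, cap, weight in self._groups:
            pts = coords[idx]
            vi = np.floor((pts - origin) * inv_sp + 0.5).astype(int)
            inside = np.all((vi >= 0) & (vi < dims), axis=1)
            s = cap * float((~inside).sum())
            if inside.any():
                ii = vi[inside]
                s += float(values[ii[:, 0], ii[:, 1], ii[:, 2]].sum())
            total += weight * s
        return total


def charged_fraction(pKa: float, pH: float, kind: str) -> float:
    """Henderson–Hasselbalch fraction of the charged protomer at a given pH."""
    if kind == "base":
        return 1.0 / (1.0 + 10.0 ** (pH - pKa))
    if kind == "acid":
        return 1.0 / (1.0 + 10.0 ** (pKa - pH))
    raise ValueError(f"kind must be 'acid' or 'base', got {kind!r}")


def hh_weighted_lgfe(
    lgfe_neutral: float,
    lgfe_charged: float,
    pKa: float,
    pH: float = 7.4,
    kind: str = "base",
) -> float:
    """Ionization-state-weighted LGFE via the Henderson–Hasselbalch equation.

    Linearly mixes the two state scores by the population fractions at the
    given pH (default 7.4, physiological). The result is a convex
    combination, always between the two inputs.
    """
    if not (np.isfinite(lgfe_neutral) and np.isfinite(lgfe_charged) and np.isfinite(pKa)):
        raise ValueError("inputs must be finite")
    f = charged_fraction(pKa, pH, kind)
    return f * lgfe_charged + (1.0 - f) * lgfe_neutral


def lgfe_to_pic50(
    lgfe_value,
    mode: str = "thermodynamic",
    a: float | None = None,
    b: float | None = None,
):
    """Convert an LGFE score (kcal/mol) to a predicted pIC50.

    ``thermodynamic`` applies the ΔG↔pIC50 relation at 300 K
    (pIC50 = -LGFE / (ln 10 · kB · 300 K), denominator ≈ 1.3727 kcal/mol);
    ``affine`` applies a user-calibrated linear map a·(-LGFE)+b, fit on a
    training set. Accepts scalars or arrays.
    """
    neg = -np.asarray(lgfe_value, dtype=float)
    if mode == "thermodynamic":
        out = neg / PIC50_PER_KCAL
    elif mode == "affine":
        if a is None or b is None:
            raise ValueError("affine mode requires a and b")
        out = a * neg + b
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(out) if np.isscalar(lgfe_value) else out
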