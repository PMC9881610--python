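"""Bayesian-ML reweighting of FragMap contributions by MCSA.

Because LGFE is exactly linear in the per-map-type weights, a fixed set of
docked poses reduces to a table ``g[i, t]`` — the unweighted GFE of ligand
i attributed to map type t — and the weighted score is just ``g @ w``. The
optimizer runs a Markov-chain Monte Carlo simulated-annealing walk over w,
maximizing the correlation (or rank) metric against experimental pIC50,
with a flat-bottom penalty that is zero inside the weight bounds and
harmonically large outside. Final model quality is then re-measured by
redocking every compound under the optimized weights, since reweighting
can move the optimal poses themselves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .docking import DockProtocol, dock
from .grids import FragMapSet
from .ligands import AtomClassAssignment, Ligand
from .scoring import WeightVector, lgfe_to_pic50

logger = logging.getLogger(__name__)


@dataclass
class AtomicGFETable:
    """Unweighted per-map-type GFE sums from fixed docked poses.

    ``g[i, t]`` holds the sum of atomic GFEs of ligand i over atoms labeled
    with map type t, at unit weight, so ``LGFE_i(w) = sum_t w[t] * g[i, t]``
    reproduces the pose score exactly.
    """

    ligand_ids: list[str]
    map_types: list[str]
    g: np.ndarray  # (n_ligands, n_types)
    exp_pic50: np.ndarray

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        self.exp_pic50 = np.asarray(self.exp_pic50, dtype=float).ravel()
        n, t = self.g.shape
        if n != len(self.ligand_ids) or t != len(self.map_types):
            raise ValueError("g shape inconsistent with ids/map_types")
        if n != len(self.exp_pic50):
            raise ValueError("exp_pic50 length mismatch")
        if n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return len(self.ligand_ids)

    def lgfe(self, w: WeightVector) -> np.ndarray:
        return self.g @ w.as_array(self.map_types)

    def predicted_pic50(self, w: WeightVector) -> np.ndarray:
        return lgfe_to_pic50(self.lgfe(w))

    @classmethod
    def from_dock_results(cls, results: dict[str, "object"], exp_pic50: dict[str, float],
                          map_types: Sequence[str]) -> "AtomicGFETable":
        """Build the table from DockResults keyed by ligand id.

        Results must come from unit-weight docking so the per-type sums are
        the unweighted features.
        """
        ids = sorted(results)
        g = np.zeros((len(ids), len(map_types)))
        for row, lid in enumerate(ids):
            by_type = results[lid].breakdown.by_map_type()
            for col, t in enumerate(map_types):
                g[row, col] = by_type.get(t, 0.0)
        y = np.array([exp_pic50[lid] for lid in ids])
        return cls(ligand_ids=ids, map_types=list(map_types), g=g, exp_pic50=y)

    def to_csv(self, path) -> None:
        rows = []
        for i, lid in enumerate(self.ligand_ids):
            for j, t in enumerate(self.map_types):
                rows.append({"ligand": lid, "map_type": t, "gfe_sum": self.g[i, j],
                             "exp_pic50": self.exp_pic50[i]})
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AtomicGFETable":
        df = pd.read_csv(path)
        ids = list(dict.fromkeys(df["ligand"]))
        types = list(dict.fromkeys(df["map_type"]))
        g = (
            df.pivot(index="ligand", columns="map_type", values="gfe_sum")
            .loc[ids, types]
            .to_numpy()
        )
        y = df.drop_duplicates("ligand").set_index("ligand").loc[ids, "exp_pic50"].to_numpy()
        return cls(ligand_ids=[str(x) for x in ids], map_types=[str(t) for t in types],
                   g=g, exp_pic50=y)


@dataclass
class BMLConfig:
    """MCSA optimizer settings.

    The flat-bottom force constant (5000 kcal/mol) and the weight bounds
    [0.05, 2.0] are the production values; chain length, proposal width and
    the geometric effective-temperature schedule are package defaults.
    """

    k_flat: float = 5000.0
    lower: float = 0.05
    upper: float = 2.0
    target_metric: str = "pearson_r"  # or "percent_correct"
    n_mcsa_steps: int = 50_000
    T_start: float = 1.0
    T_end: float = 1e-4
    proposal_width: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.lower >= self.upper:
            raise ValueError("lower bound must be below upper bound")
        if self.k_flat < 0:
            raise ValueError("k_flat must be >= 0")
        if self.target_metric not in ("pearson_r", "percent_correct"):
            raise ValueError(f"unknown target metric {self.target_metric!r}")


def flat_bottom_penalty(w: WeightVector, cfg: BMLConfig) -> float:
    """Quadratic penalty outside [lower, upper], zero inside (per weight)."""
    total = 0.0
    for v in w.values():
        if v > cfg.upper:
            total += cfg.k_flat * (v - cfg.upper) ** 2
        elif v < cfg.lower:
            total += cfg.k_flat * (cfg.lower - v) ** 2
    return total


def _metric_value(pred: np.ndarray, exp: np.ndarray, which: str, quiet: bool = False) -> float:
    if which == "pearson_r":
        if quiet:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return _metrics.pearson_r(pred, exp)
        return _metrics.pearson_r(pred, exp)
    return _metrics.percent_correct(pred, exp)


def bml_objective(w: WeightVector, table: AtomicGFETable, cfg: BMLConfig) -> float:
    """Loss = -(target metric of predicted vs experimental pIC50) + penalty."""
    if cfg.target_metric == "pearson_r" and table.n < 3:
        raise ValueError("pearson_r objective needs at least 3 ligands")
    pred = table.predicted_pic50(w)
    return -_metric_value(pred, table.exp_pic50, cfg.target_metric) + flat_bottom_penalty(w, cfg)


def mcsa_optimize(table: AtomicGFETable, cfg: BMLConfig | None = None) -> WeightVector:
    """Optimize FragMap weights by Markov-chain MC simulated annealing.

    Starts from unit weights; each step perturbs one randomly chosen weight
    uniformly within the proposal width and applies the Metropolis
    criterion on the loss under a geometrically decaying effective
    temperature. Returns the best-loss weights observed during the chain.
    """
    cfg = cfg or BMLConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    types = table.map_types
    nT = len(types)
    w_arr = np.ones(nT)
    y = table.exp_pic50
    g = table.g

    def loss_of(arr: np.ndarray) -> float:
        pred = lgfe_to_pic50(g @ arr)
        pen = 0.0
        over = arr - cfg.upper
        under = cfg.lower - arr
        pen += cfg.k_flat * float((over[over > 0] ** 2).sum())
        pen += cfg.k_flat * float((under[under > 0] ** 2).sum())
        return -_metric_value(pred, y, cfg.target_metric, quiet=True) + pen

    cur = loss_of(w_arr)
    best_arr, best_loss = w_arr.copy(), cur
    n = cfg.n_mcsa_steps
    if n > 0:
        decay = (cfg.T_end / cfg.T_start) ** (1.0 / max(n - 1, 1))
    T = cfg.T_start
    for _ in range(n):
        k = rng.integers(nT)
        cand = w_arr.copy()
        cand[k] += rng.uniform(-cfg.proposal_width, cfg.proposal_width)
        new = loss_of(cand)
        d = new - cur
        if d <= 0 or rng.random() < np.exp(-d / T):
            w_arr, cur = cand, new
            if cur < best_loss:
                best_arr, best_loss = w_arr.copy(), cur
        T *= decay

    out = WeightVector({t: max(v, 0.0) for t, v in zip(types, best_arr)})
    viol = [t for t in types if not (cfg.lower - 1e-9 <= out[t] <= cfg.upper + 1e-9)]
    if viol:
        logger.warning("optimized weights outside [%g, %g] for types %s",
                       cfg.lower, cfg.upper, viol)
    return out


@dataclass
class RedockReport:
    """Redock-and-re-evaluate outcome: final metrics plus pose-shift diagnostics."""

    metrics: _metrics.MetricsReport
    predicted_pic50: dict[str, float]
    lgfe: dict[str, float]
    pose_shift: dict[str, float]  # centroid displacement vs reference poses, Å
    failures: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "metrics": self.metrics.to_dict(),
            "predicted_pic50": self.predicted_pic50,
            "lgfe": self.lgfe,
            "pose_shift": self.pose_shift,
            "failures": self.failures,
        }


def redock_evaluate(
    w: WeightVector,
    ligands: dict[str, Ligand],
    assignments: dict[str, AtomClassAssignment],
    maps: FragMapSet,
    protocol: DockProtocol,
    experimental: dict[str, float],
    reference_poses: dict[str, np.ndarray] | None = None,
) -> RedockReport:
    """Redock every compound under the optimized weights and evaluate.

    Large centroid shifts relative to the original (unit-weight) poses are
    an overfitting sentinel: weights that only look good because they moved
    every pose are suspect.
    """
    preds: dict[str, float] = {}
    lgfes: dict[str, float] = {}
    shifts: dict[str, float] = {}
    failures: list[str] = []
    for lid in sorted(ligands):
        try:
            res = dock(ligands[lid], maps, assignments[lid], protocol, w)
        except Exception as exc:  # noqa: BLE001 — per-ligand skip contract
            logger.warning("redock failed for %s: %s", lid, exc)
            failures.append(lid)
            continue
        lgfes[lid] = res.best_lgfe
        preds[lid] = lgfe_to_pic50(res.best_lgfe)
        if reference_poses and lid in reference_poses:
            ref_centroid = reference_poses[lid].mean(axis=0)
            shifts[lid] = float(
                np.linalg.norm(res.best_conformer.coords.mean(axis=0) - ref_centroid)
            )
    ids = sorted(preds)
    report = _metrics.evaluate(
        np.array([preds[i] for i in ids]), np.array([experimental[i] for i in ids])
    )
    return RedockReport(metrics=report, predicted_pic50=preds, lgfe=lgfes,
                        pose_shift=shifts, failures=failures)


def save_weights(w: WeightVector, path) -> None:
    import yaml

    Path(path).write_text(yaml.safe_dump({k: float(v) for k, v in w.items()}, sort_keys=True))


def load_weights(path) -> WeightVector:
    import yaml

    return WeightVector(yaml.safe_load(Path(path).read_text()))
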