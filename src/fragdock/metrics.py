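"""Rank-ordering and error metrics: MUE, Pearson R, predictive index, percent correct.

PI weights each ordered pair by the experimental affinity difference, so
getting the big gaps right matters more than the close calls; PC averages,
over every compound taken as the reference ligand, the fraction of other
compounds whose relative order is predicted correctly. PI is 0 for random
predictions; PC concentrates at 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np


def _check_pair(pred, exp, min_len: int = 1) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float).ravel()
    exp = np.asarray(exp, dtype=float).ravel()
    if len(pred) != len(exp):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(exp)} experimental")
    if len(pred) < min_len:
        raise ValueError(f"need at least {min_len} values, got {len(pred)}")
    return pred, exp


def mue(pred, exp) -> float:
    """Mean unsigned error between predicted and experimental values."""
    pred, exp = _check_pair(pred, exp, min_len=1)
    return float(np.mean(np.abs(pred - exp)))


def pearson_r(pred, exp) -> float:
    """Pearson product-moment correlation in [-1, 1].

    Zero-variance input returns 0 with a warning rather than NaN, so
    optimizer objectives built on R stay finite for degenerate weights.
    """
    pred, exp = _check_pair(pred, exp, min_len=3)
    if np.std(pred) == 0 or np.std(exp) == 0:
        warnings.warn("zero-variance input to pearson_r; returning 0")
        return 0.0
    return float(np.corrcoef(pred, exp)[0, 1])


def predictive_index(pred, exp) -> float:
    """Experimental-difference-weighted pairwise rank concordance in [-1, 1].

    PI = sum_{i<j} w_ij c_ij / sum_{i<j} w_ij with w_ij = |exp_j - exp_i|;
    c_ij = +1 when the predicted difference has the same sign as the
    experimental one, -1 when opposite, 0 when the prediction ties. Pairs
    with equal experimental values carry zero weight; all-equal experimental
    input leaves PI undefined.
    """
    pred, exp = _check_pair(pred, exp, min_len=2)
    de = exp[None, :] - exp[:, None]
    dp = pred[None, :] - pred[:, None]
    iu = np.triu_indices(len(pred), k=1)
    w = np.abs(de[iu])
    c = np.sign(de[iu]) * np.sign(dp[iu])
    denom = w.sum()
    if denom == 0:
        raise ValueError("predictive index undefined: all experimental values equal")
    return float((w * c).sum() / denom)


def percent_correct(pred, exp, ties: str = "strict") -> float:
    """Mean per-reference fraction of correctly rank-ordered compounds, in [0, 1].

    For each reference compound i, PC_i is the fraction of the other n-1
    compounds whose predicted order relative to i matches the experimental
    order; PC is the average of PC_i over all references. Under the default
    strict convention a tie in either vector counts as incorrect;
    ``ties="half"`` gives half credit for prediction ties. Random
    predictions give PC near 0.5.
    """
    if ties not in ("strict", "half"):
        raise ValueError(f"ties must be 'strict' or 'half', got {ties!r}")
    pred, exp = _check_pair(pred, exp, min_len=2)
    n = len(pred)
    de = np.sign(exp[None, :] - exp[:, None])
    dp = np.sign(pred[None, :] - pred[:, None])
    off = ~np.eye(n, dtype=bool)
    correct = (de == dp) & (de != 0)
    score = correct.astype(float)
    if ties == "half":
        score[(dp == 0) & (de != 0) & off] = 0.5
    per_ref = score.sum(axis=1) / (n - 1)
    return float(per_ref.mean())


@dataclass
class MetricsReport:
    """Bundle of the four evaluation metrics for one model/dataset pairing."""

    mue: float
    r: float
    pi: float
    pc: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate(pred, exp, ties: str = "strict") -> MetricsReport:
    """Compute MUE, Pearson R, PI and PC for one prediction vector."""
    pred, exp = _check_pair(pred, exp, min_len=2)
    r = pearson_r(pred, exp) if len(pred) >= 3 else 0.0
    try:
        pi = predictive_index(pred, exp)
    except ValueError:
        pi = float("nan")
    return MetricsReport(
        mue=mue(pred, exp),
        r=r,
        pi=pi,
        pc=percent_correct(pred, exp, ties=ties),
        n=len(pred),
    )
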