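"""Physicochemical property model (PPM) and consensus affinity modeling.

The PPM is an ordinary-least-squares multiple linear regression of
experimental pIC50 on five descriptors: logP, logS, TPSA (Å²), MW (g/mol)
and van der Waals volume (Å³). The consensus model adds the structure-based
predicted pIC50 (from LGFE, in any of its neutral / charged / HH-weighted
variants) as a sixth regressor and refits jointly; a simple
average-of-models combination is available as an alternative.

Descriptors are consumed from an input table; any callable provider with
the same schema can be plugged in, but no particular descriptor algorithm
is assumed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DESCRIPTOR_COLUMNS = ["logP", "logS", "TPSA", "MW", "vdW_volume"]


class CollinearityError(ValueError):
    """Raised when the design matrix is rank-deficient; names the columns."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"collinear or constant feature columns: {self.columns}")


@dataclass
class MLRModel:
    """Fitted OLS regression: ordered features, coefficients, intercept."""

    features: list[str]
    coefficients: np.ndarray
    intercept: float
    r2_train: float = float("nan")

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float).ravel()
        if len(self.coefficients) != len(self.features):
            raise ValueError("coefficient count must equal feature count")

    def to_dict(self) -> dict:
        return {
            "features": self.features,
            "coefficients": self.coefficients.tolist(),
            "intercept": float(self.intercept),
            "r2_train": float(self.r2_train),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLRModel":
        return cls(
            features=list(d["features"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            r2_train=float(d.get("r2_train", float("nan"))),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "MLRModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _find_collinear(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns (incl. intercept interplay) lying in the span of the others."""
    bad = []
    design = np.column_stack([np.ones(len(X)), X])
    full_rank = np.linalg.matrix_rank(design)
    if full_rank == design.shape[1]:
        return bad
    for j, name in enumerate(names):
        others = np.delete(design, j + 1, axis=1)
        col = design[:, j + 1]
        coef, *_ = np.linalg.lstsq(others, col, rcond=None)
        resid = col - others @ coef
        if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(col)):
            bad.append(name)
    return bad


def fit_mlr(X: pd.DataFrame | np.ndarray, y, feature_names: Sequence[str] | None = None) -> MLRModel:
    """Ordinary least squares with intercept; deterministic.

    Requires n > p + 1 observations, no missing values, and a full-rank
    design; rank deficiency raises :class:`CollinearityError` naming the
    offending columns.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(Xa.shape[1])]
    y = np.asarray(y, dtype=float).ravel()
    n, p = Xa.shape
    if len(y) != n:
        raise ValueError("X and y length mismatch")
    if not (np.all(np.isfinite(Xa)) and np.all(np.isfinite(y))):
        raise ValueError("missing or non-finite values in the fit data")
    if n <= p + 1:
        raise ValueError(f"need more than p+1={p + 1} observations, got {n}")
    bad = _find_collinear(Xa, feature_names)
    if bad:
        raise CollinearityError(bad)
    design = np.column_stack([np.ones(n), Xa])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else float("nan")
    return MLRModel(
        features=list(feature_names),
        coefficients=beta[1:],
        intercept=float(beta[0]),
        r2_train=r2,
    )


def predict(model: MLRModel, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """intercept + X @ coefficients; feature names must match the model."""
    if isinstance(X, pd.DataFrame):
        if list(X.columns) != model.features:
            raise ValueError(
                f"feature mismatch: model expects {model.features}, got {list(X.columns)}"
            )
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.atleast_2d(np.asarray(X, dtype=float))
    if Xa.shape[1] != len(model.features):
        raise ValueError(
            f"feature mismatch: model has {len(model.features)} features, X has {Xa.shape[1]}"
        )
    return model.intercept + Xa @ model.coefficients


def build_feature_matrix(
    descriptors: pd.DataFrame,
    silcs_pic50: Mapping[str, float] | pd.Series | None = None,
    mode: str = "ppm_only",
    silcs_column: str = "silcs_pic50",
) -> pd.DataFrame:
    """Assemble the regression design from descriptors and docking scores.

    ``descriptors`` must be indexed by compound id (or carry a ``compound``
    column) with the five descriptor columns. ``ppm_only`` returns them as
    is; ``consensus`` appends the structure-based predicted pIC50 as the
    last column. Compounds missing from either source are an error.
    """
    if mode not in ("ppm_only", "consensus"):
        raise ValueError(f"mode must be 'ppm_only' or 'consensus', got {mode!r}")
    df = descriptors.copy()
    if "compound" in df.columns:
        df = df.set_index("compound")
    missing_cols = [c for c in DESCRIPTOR_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"descriptor table missing columns: {missing_cols}")
    out = df[DESCRIPTOR_COLUMNS].astype(float)
    if out.isna().any().any():
        bad = out.index[out.isna().any(axis=1)].tolist()
        raise ValueError(f"missing descriptor values for compounds: {bad}")
    if mode == "consensus":
        if silcs_pic50 is None:
            raise ValueError("consensus mode requires structure-based predictions")
        s = pd.Series(dict(silcs_pic50)) if not isinstance(silcs_pic50, pd.Series) else silcs_pic50
        absent = sorted(set(out.index) - set(s.index))
        if absent:
            raise ValueError(f"compounds missing structure-based predictions: {absent}")
        out[silcs_column] = s.reindex(out.index).astype(float)
    return out


def consensus_average(ppm_pred: np.ndarray, silcs_pred: np.ndarray) -> np.ndarray:
    """Alternative consensus: unweighted mean of the two model predictions."""
    return 0.5 * (np.asarray(ppm_pred, float) + np.asarray(silcs_pred, float))
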