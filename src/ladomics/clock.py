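"""Linear epigenetic-clock application with passage correction.

A clock is a sparse linear model over CpG beta values whose score is
mapped to years through the standard piecewise log-linear age transform
anchored at ``adult_age`` (20 by default):

    age(score) = (1 + adult_age) * exp(score) - 1     for score < 0
               = (1 + adult_age) * score + adult_age  for score >= 0

The transform is continuous and monotone, with both branches meeting at
score 0 where age equals ``adult_age``.

Cultured fibroblasts accumulate mitotic age with passaging; the passage
factor

    rho = passage * 3.32 * log10(harvested / seeded)

estimates cumulative population doublings (3.32 ~ 1/log10(2), so each
harvest/seed doubling contributes one unit per passage).  How rho should
*correct* an age estimate is an open modelling choice; this package
reports rho alongside the raw delta-age and offers least-squares
residualization of delta-age on rho as an explicit, clearly labelled
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "ClockModel",
    "EpigeneticClock",
    "apply_clock",
    "transform_age",
    "inverse_transform_age",
    "passage_factor",
    "age_acceleration",
]


def transform_age(score: float | np.ndarray, adult_age: float = 20.0):
    """Piecewise log-linear map from clock score to years."""
    score = np.asarray(score, dtype=float)
    young = (1 + adult_age) * np.exp(score) - 1
    old = (1 + adult_age) * score + adult_age
    out = np.where(score < 0, young, old)
    return float(out) if out.ndim == 0 else out


def inverse_transform_age(age: float | np.ndarray, adult_age: float = 20.0):
    """Inverse of :func:`transform_age` (years back to clock score)."""
    age = np.asarray(age, dtype=float)
    young = np.log(np.maximum(age + 1, 1e-12) / (1 + adult_age))
    old = (age - adult_age) / (1 + adult_age)
    out = np.where(age < adult_age, young, old)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ClockModel:
    """Sparse linear age predictor over CpG probes."""

    intercept: float
    weights: Mapping[str, float]
    adult_age: float = 20.0

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("clock must carry >= 1 weight")
        if len(set(self.weights)) != len(self.weights):
            raise ValueError("duplicate probe ids in clock weights")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.weights)

    def to_files(self, weights_tsv: str | Path, config_yaml: str | Path) -> None:
        pd.Series(dict(self.weights), name="weight").rename_axis("probe_id").to_csv(
            weights_tsv, sep="\t"
        )
        Path(config_yaml).write_text(
            yaml.safe_dump(
                {"intercept": float(self.intercept),
                 "adult_age": float(self.adult_age)}
            )
        )

    @classmethod
    def from_files(cls, weights_tsv: str | Path, config_yaml: str | Path) -> "ClockModel":
        w = pd.read_csv(weights_tsv, sep="\t", index_col="probe_id")["weight"]
        cfg = yaml.safe_load(Path(config_yaml).read_text())
        return cls(
            intercept=float(cfg["intercept"]),
            weights=w.to_dict(),
            adult_age=float(cfg.get("adult_age", 20.0)),
        )


class EpigeneticClock(BaseEstimator, RegressorMixin):
    """Pre-trained linear clock as an sklearn-style predictor.

    The coefficients come from the supplied :class:`ClockModel`; there is
    no training step (``fit`` only validates probe availability).
    ``predict(X)`` with ``X`` a samples x probes DataFrame returns DNAm
    ages in years.
    """

    def __init__(self, model: ClockModel, missing_policy: str = "error"):
        self.model = model
        self.missing_policy = missing_policy

    def fit(self, X: pd.DataFrame, y=None):
        self._check_probes(X)
        self.n_features_in_ = X.shape[1]
        return self

    def _check_probes(self, X: pd.DataFrame) -> list[str]:
        missing = [p for p in self.model.probe_ids if p not in X.columns]
        if missing and self.missing_policy == "error":
            raise ValueError(
                f"{len(missing)} clock probes missing from the matrix: "
                f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
            )
        return missing

    def score_samples(self, X: pd.DataFrame) -> np.ndarray:
        """Linear clock score (intercept + weighted beta sum) per sample."""
        if self.missing_policy not in ("error", "mean_impute"):
            raise ValueError("missing_policy must be 'error' or 'mean_impute'")
        missing = self._check_probes(X)
        w = pd.Series(dict(self.model.weights))
        cols = X.reindex(columns=w.index)
        if missing:
            # cohort-mean imputation keeps the score defined for every sample
            cols = cols.apply(lambda c: c.fillna(c.mean()) if c.notna().any() else c.fillna(0.5))
        vals = cols.to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            vals = np.where(np.isfinite(vals), vals, 0.5)
        return self.model.intercept + vals @ w.to_numpy()

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return transform_age(self.score_samples(X), self.model.adult_age)


def apply_clock(
    beta_column: pd.Series,
    clock: ClockModel,
    missing_policy: str = "error",
) -> dict[str, float]:
    """Clock score and DNAm age for a single sample's probe column."""
    X = beta_column.to_frame().T
    est = EpigeneticClock(clock, missing_policy=missing_policy)
    score = float(est.score_samples(X)[0])
    return {"linear_score": score, "dnam_age": transform_age(score, clock.adult_age)}


def passage_factor(passage: int, harvested: float, seeded: float) -> float:
    """Cumulative population doublings: passage * 3.32 * log10(h/s)."""
    if harvested <= 0 or seeded <= 0:
        raise ValueError("cell counts must be positive")
    if passage < 0:
        raise ValueError("passage must be >= 0")
    return float(passage * 3.32 * np.log10(harvested / seeded))


def age_acceleration(
    estimates: pd.DataFrame,
    subgroups: Sequence[str] | pd.Series,
    adjust_rho: bool = False,
) -> pd.DataFrame:
    """Median delta-age per subgroup, optionally rho-residualized.

    ``estimates`` carries ``dnam_age`` and ``chronological_age`` (and
    ``rho`` when ``adjust_rho``); ``subgroups`` labels each row.  The
    adjusted column residualizes delta-age against rho by least squares
    across *all* samples before taking subgroup medians.
    """
    est = estimates.copy()
    est["delta_age"] = est["dnam_age"] - est["chronological_age"]
    labels = pd.Series(np.asarray(subgroups), index=est.index, name="subgroup")
    if labels.isna().any():
        raise ValueError("every sample needs a subgroup label")
    if adjust_rho:
        if "rho" not in est.columns:
            raise ValueError("rho column required for adjustment")
        rho = est["rho"].to_numpy(dtype=float)
        delta = est["delta_age"].to_numpy(dtype=float)
        slope, icpt = np.polyfit(rho, delta, 1) if np.ptp(rho) > 0 else (0.0, delta.mean())
        est["delta_age_adjusted"] = delta - (slope * rho + icpt)
    rows = []
    for name, sub in est.groupby(labels, sort=True):
        if sub.empty:
            raise ValueError(f"subgroup {name!r} has no samples")
        row = {
            "subgroup": name,
            "n": len(sub),
            "median_delta_age": float(sub["delta_age"].median()),
        }
        if adjust_rho:
            row["median_delta_age_adjusted"] = float(sub["delta_age_adjusted"].median())
        rows.append(row)
    return pd.DataFrame(rows).set_index("subgroup")
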