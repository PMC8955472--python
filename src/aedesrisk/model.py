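"""Leave-one-year-out L1-penalized logistic regression ensemble.

Establishment probability is modeled with LASSO logistic regression: the
L1 penalty shrinks coefficients and sets the least informative of the 79
(mostly correlated) candidate predictors exactly to zero, performing
selection while fitting.  ``C`` is scikit-learn's inverse penalty
strength — smaller ``C`` means stronger penalization; the reference
setting is ``C = 0.1`` (performance was insensitive within [0.01, 1]).

Rather than random folds, the training data are grouped by year: one
member model per training year, each fit on all the *other* years.  This
yields more diverse members and lets each be validated on its own left-out
year without temporal leakage.  The ensemble prediction is the mean of the
member probabilities; its uncertainty is their (population) standard
deviation.  A feature's importance is reported as its *frequency* — the
fraction of members giving it a nonzero coefficient — plus the coefficient
sign.

Each member normalizes features by min-max bounds fit on its own training
subset (a global-bounds switch exists for sensitivity checks); the
intercept is never penalized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .features import (
    NormalizationBounds,
    apply_normalizer,
    build_feature_catalog,
    fit_normalizer,
)

__all__ = [
    "EnsembleConfig",
    "MemberModel",
    "EnsembleModel",
    "ModelError",
    "fit_member",
    "fit_ensemble",
    "ensemble_predict",
    "feature_frequency",
    "save_ensemble",
    "load_ensemble",
]

SOLVER = "saga"  # supports L1 and leaves the intercept unpenalized
SOLVER_TOL = 1e-8
SOLVER_MAX_ITER = 200_000


class ModelError(ValueError):
    """Invalid training data or configuration (single-class subsets, ...)."""


@dataclass(frozen=True)
class EnsembleConfig:
    """Hyperparameters of the leave-one-year-out ensemble."""

    C: float = 0.1
    train_years: tuple[int, ...] = ()
    coefficient_tolerance: float = 1e-6
    global_normalization: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ModelError(f"C must be positive, got {self.C}")
        if self.train_years and len(self.train_years) < 2:
            raise ModelError("need at least 2 training years for a leave-one-year-out ensemble")


@dataclass(frozen=True)
class MemberModel:
    """One member: LASSO logistic fit with one training year left out."""

    left_out_year: int
    coefficients: np.ndarray  # logit units per normalized feature unit
    intercept: float
    normalization: NormalizationBounds
    feature_names: tuple[str, ...]

    def predict_proba(self, vectors: pd.DataFrame) -> np.ndarray:
        if tuple(vectors.columns) != self.feature_names:
            raise ModelError("feature columns do not match the member's catalog order")
        xn = apply_normalizer(self.normalization, vectors).to_numpy()
        z = self.intercept + xn @ self.coefficients
        return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class EnsembleModel:
    """All member models plus the configuration they were fit with."""

    members: tuple[MemberModel, ...]
    config: EnsembleConfig

    @property
    def feature_names(self) -> tuple[str, ...]:
        return self.members[0].feature_names


def _check_xy(X: pd.DataFrame, y: np.ndarray, context: str) -> None:
    if len(X) != len(y):
        raise ModelError(f"{context}: X and y lengths differ")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ModelError(f"{context}: training data contains a single class ({classes})")


def fit_member(
    X: pd.DataFrame,
    y: Sequence[bool] | np.ndarray,
    left_out_year: int,
    config: EnsembleConfig,
    bounds: NormalizationBounds | None = None,
) -> MemberModel:
    """Fit one L1-penalized member on its training subset.

    Features are min-max normalized by ``bounds`` (fit on ``X`` itself when
    not supplied, the per-member default).  The solver maximizes the
    L1-penalized log-likelihood at strength ``1/C`` with an unpenalized
    intercept; the fit is deterministic given data and config.
    """
    y = np.asarray(y, dtype=int)
    _check_xy(X, y, f"member leaving out {left_out_year}")
    if bounds is None:
        bounds = fit_normalizer(X)
    xn = apply_normalizer(bounds, X).to_numpy()
    clf = LogisticRegression(
        l1_ratio=1.0,  # pure L1 (LASSO)
        C=config.C,
        solver=SOLVER,
        tol=SOLVER_TOL,
        max_iter=SOLVER_MAX_ITER,
        random_state=config.rng_seed,
    )
    clf.fit(xn, y)
    return MemberModel(
        left_out_year=int(left_out_year),
        coefficients=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        normalization=bounds,
        feature_names=tuple(X.columns),
    )


def fit_ensemble(
    X: pd.DataFrame,
    y: Sequence[bool] | np.ndarray,
    years: Sequence[int],
    config: EnsembleConfig,
) -> EnsembleModel:
    """Fit one member per training year, each on all the other years.

    Parameters
    ----------
    X, y, years
        Row-aligned feature matrix, binary labels, and the year of each row.
    config
        Training years default to the distinct years present in ``years``.
    """
    years = np.asarray(years, dtype=int)
    y = np.asarray(y, dtype=int)
    train_years = config.train_years or tuple(sorted(np.unique(years)))
    missing = set(train_years) - set(np.unique(years))
    if missing:
        raise ModelError(f"train years absent from data: {sorted(missing)}")
    if len(train_years) < 2:
        raise ModelError("need at least 2 training years")

    global_bounds = fit_normalizer(X) if config.global_normalization else None
    members = []
    for left_out in train_years:
        mask = (years != left_out) & np.isin(years, train_years)
        sub_x, sub_y = X[mask], y[mask]
        if len(np.unique(sub_y)) < 2:
            raise ModelError(
                f"training subset leaving out {left_out} contains a single class"
            )
        members.append(fit_member(sub_x, sub_y, left_out, config, bounds=global_bounds))
    return EnsembleModel(members=tuple(members), config=config)


def ensemble_predict(
    ensemble: EnsembleModel, vectors: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ensemble mean, population SD, and per-member probabilities.

    Returns ``(mean, sd, member_probs)`` with ``member_probs`` of shape
    (n_members, n_rows).  SD uses the population convention (divide by the
    member count).
    """
    probs = np.vstack([m.predict_proba(vectors) for m in ensemble.members])
    return probs.mean(axis=0), probs.std(axis=0, ddof=0), probs


def feature_frequency(
    ensemble: EnsembleModel, tolerance: float | None = None
) -> pd.DataFrame:
    """Selection frequency, sign and mean coefficient per feature.

    Frequency is the fraction of members whose coefficient magnitude
    exceeds ``tolerance`` (default: the config's); sign is "+" or "-" when
    all nonzero coefficients agree, "mixed" otherwise, "" for never
    selected.  Sorted by frequency, then |mean coefficient|, descending.
    """
    tol = ensemble.config.coefficient_tolerance if tolerance is None else tolerance
    coefs = np.vstack([m.coefficients for m in ensemble.members])
    nonzero = np.abs(coefs) > tol
    freq = nonzero.mean(axis=0)
    mean_coef = coefs.mean(axis=0)
    signs = []
    for j in range(coefs.shape[1]):
        active = coefs[nonzero[:, j], j]
        if len(active) == 0:
            signs.append("")
        elif (active > 0).all():
            signs.append("+")
        elif (active < 0).all():
            signs.append("-")
        else:
            signs.append("mixed")
    report = pd.DataFrame(
        {
            "feature": list(ensemble.feature_names),
            "frequency": freq,
            "sign": signs,
            "mean_coef": mean_coef,
        }
    )
    report["_abs"] = report["mean_coef"].abs()
    report = (
        report.sort_values(["frequency", "_abs"], ascending=False, kind="mergesort")
        .drop(columns="_abs")
        .reset_index(drop=True)
    )
    return report


def save_ensemble(ensemble: EnsembleModel, path: str | Path) -> None:
    """Serialize to JSON (coefficients, intercepts, bounds, solver metadata)."""
    payload = {
        "config": {
            "C": ensemble.config.C,
            "train_years": [int(y) for y in ensemble.config.train_years],
            "coefficient_tolerance": ensemble.config.coefficient_tolerance,
            "global_normalization": ensemble.config.global_normalization,
            "rng_seed": ensemble.config.rng_seed,
        },
        "solver": {"name": SOLVER, "tol": SOLVER_TOL, "max_iter": SOLVER_MAX_ITER},
        "feature_names": list(ensemble.feature_names),
        "members": [
            {
                "left_out_year": m.left_out_year,
                "coefficients": [float(v) for v in m.coefficients],
                "intercept": m.intercept,
                "normalization": m.normalization.to_dict(),
            }
            for m in ensemble.members
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_ensemble(path: str | Path) -> EnsembleModel:
    payload = json.loads(Path(path).read_text())
    cfg = EnsembleConfig(
        C=payload["config"]["C"],
        train_years=tuple(payload["config"]["train_years"]),
        coefficient_tolerance=payload["config"]["coefficient_tolerance"],
        global_normalization=payload["config"]["global_normalization"],
        rng_seed=payload["config"]["rng_seed"],
    )
    names = tuple(payload["feature_names"])
    members = tuple(
        MemberModel(
            left_out_year=m["left_out_year"],
            coefficients=np.array(m["coefficients"], float),
            intercept=m["intercept"],
            normalization=NormalizationBounds.from_dict(m["normalization"]),
            feature_names=names,
        )
        for m in payload["members"]
    )
    return EnsembleModel(members=members, config=cfg)
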