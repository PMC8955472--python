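"""AUC-based assessment of the establishment ensemble.

Two protocols mirror how the reference analysis was validated:

* *Cross-validation*: each member's probability is scored on the data of
  its own left-out training year.  Years with too few established cells
  (fewer than ``min_established``, default 5) are excluded — an AUC over a
  handful of positives is noise — and the mean/SD is reported over the
  evaluable members only.
* *Test assessment*: for each held-out year, every member is scored, their
  AUC mean/SD reported, and additionally the AUC of the ensemble-mean
  prediction (average the member probabilities first, then compute one
  AUC).

AUC is the rank-based (Mann-Whitney) estimate: the probability that a
randomly chosen established cell receives a higher score than a randomly
chosen non-established cell, with tied scores given half credit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .model import EnsembleModel, ensemble_predict

__all__ = ["EvaluationError", "EvaluationReport", "auc", "crossval_assess", "test_assess"]

MIN_ESTABLISHED_DEFAULT = 5


class EvaluationError(ValueError):
    """Assessment impossible (single-class data, no evaluable member)."""


def auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Rank-based AUC with half credit for ties.

    Equals (concordant pairs + 0.5 * tied pairs) / (positives * negatives).
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise EvaluationError("AUC needs both established and non-established cells")
    return float(roc_auc_score(labels, scores))


@dataclass
class EvaluationReport:
    """Cross-validation and per-test-year AUCs of an ensemble."""

    cv_member_aucs: dict[int, float] = field(default_factory=dict)
    cv_excluded_years: list[int] = field(default_factory=list)
    cv_mean: float | None = None
    cv_sd: float | None = None
    test_member_aucs: dict[int, list[float]] = field(default_factory=dict)
    test_member_mean: dict[int, float] = field(default_factory=dict)
    test_member_sd: dict[int, float] = field(default_factory=dict)
    test_ensemble_auc: dict[int, float] = field(default_factory=dict)
    test_skipped_years: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Two-row table: member AUC mean (sd) and ensemble AUC, per column."""
        cols: dict[str, list] = {}
        if self.cv_mean is not None:
            cols["cross_validation"] = [f"{self.cv_mean:.3f} ({self.cv_sd:.3f})", ""]
        for year in sorted(self.test_ensemble_auc):
            cols[str(year)] = [
                f"{self.test_member_mean[year]:.3f} ({self.test_member_sd[year]:.3f})",
                f"{self.test_ensemble_auc[year]:.3f}",
            ]
        return pd.DataFrame(cols, index=["member AUC mean (sd)", "ensemble AUC"])


def crossval_assess(
    ensemble: EnsembleModel,
    X: pd.DataFrame,
    y: Sequence[bool],
    years: Sequence[int],
    min_established: int = MIN_ESTABLISHED_DEFAULT,
) -> EvaluationReport:
    """Score each member on its own left-out year.

    A year is evaluable iff it has at least ``min_established`` established
    cells and at least one non-established cell; mean/SD (population) are
    over evaluable members only.
    """
    y = np.asarray(y, dtype=int)
    years = np.asarray(years, dtype=int)
    report = EvaluationReport()
    for member in ensemble.members:
        mask = years == member.left_out_year
        sub_y = y[mask]
        if sub_y.sum() < min_established or (sub_y == 0).sum() < 1:
            report.cv_excluded_years.append(member.left_out_year)
            continue
        scores = member.predict_proba(X[mask])
        report.cv_member_aucs[member.left_out_year] = auc(scores, sub_y)
    if not report.cv_member_aucs:
        raise EvaluationError(
            f"no member has an evaluable left-out year "
            f"(min_established={min_established})"
        )
    vals = np.array(list(report.cv_member_aucs.values()))
    report.cv_mean = float(vals.mean())
    report.cv_sd = float(vals.std(ddof=0))
    return report


def test_assess(
    ensemble: EnsembleModel,
    X: pd.DataFrame,
    y: Sequence[bool],
    years: Sequence[int],
    report: EvaluationReport | None = None,
) -> EvaluationReport:
    """Per-test-year member AUCs and the AUC of the ensemble-mean prediction.

    Years whose labels are single-class are flagged in
    ``test_skipped_years`` rather than scored.
    """
    y = np.asarray(y, dtype=int)
    years = np.asarray(years, dtype=int)
    report = report if report is not None else EvaluationReport()
    for year in sorted(np.unique(years)):
        mask = years == year
        sub_y = y[mask]
        if len(np.unique(sub_y)) < 2:
            report.test_skipped_years.append(int(year))
            continue
        mean_pred, _, member_probs = ensemble_predict(ensemble, X[mask])
        member_aucs = [auc(p, sub_y) for p in member_probs]
        report.test_member_aucs[int(year)] = member_aucs
        report.test_member_mean[int(year)] = float(np.mean(member_aucs))
        report.test_member_sd[int(year)] = float(np.std(member_aucs, ddof=0))
        report.test_ensemble_auc[int(year)] = auc(mean_pred, sub_y)
    return report
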