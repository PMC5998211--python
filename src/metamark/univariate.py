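"""Per-marker ROC curves, AUCs, direction calls and box-plot summaries.

AUC is the Mann-Whitney probability that a random case value exceeds a
random control value, ties counted one half (midrank convention).  The
positive class is always the case group and AUCs are reported unflipped,
so a marker decreased in cases shows AUC < 0.5; direction is carried
separately by the Low/High call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import ClassDegeneracyError
from .table import CASE, FeatureTable, ProcessedTable


@dataclass
class RocCurve:
    """ROC points from (0,0) to (1,1), nondecreasing in both coordinates."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    positive_class: str = CASE


@dataclass
class DirectionCall:
    marker: str
    control_level: str  # "Low" or "High"
    case_level: str
    tied: bool = False


@dataclass
class MarkerRecord:
    marker: str
    auc: float
    curve: RocCurve
    direction: DirectionCall
    control_summary: np.ndarray  # five-number summary (min, q1, median, q3, max)
    case_summary: np.ndarray


def _split(values, groups) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    case_mask = np.asarray(groups, dtype=object) == CASE
    cases, controls = values[case_mask], values[~case_mask]
    if len(cases) == 0 or len(controls) == 0:
        raise ClassDegeneracyError("both case and control values are required")
    return cases, controls


def auc(values, groups) -> float:
    """Mann-Whitney AUC of case-vs-control, ties counting one half."""
    cases, controls = _split(values, groups)
    ranks = rankdata(np.concatenate([cases, controls]))
    u = ranks[: len(cases)].sum() - len(cases) * (len(cases) + 1) / 2
    return float(u / (len(cases) * len(controls)))


def roc_curve(values, groups) -> RocCurve:
    """Threshold-sweep ROC, one point per distinct value plus endpoints.

    A sample is called positive when its value is >= the threshold; the
    trapezoidal area under the returned points equals :func:`auc` to
    floating tolerance (ties traced as diagonal segments).
    """
    cases, controls = _split(values, groups)
    thresholds = np.unique(np.concatenate([cases, controls]))[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for thr in thresholds:
        tpr.append(np.mean(cases >= thr))
        fpr.append(np.mean(controls >= thr))
    tpr.append(1.0)
    fpr.append(1.0)
    fpr_arr, tpr_arr = np.asarray(fpr), np.asarray(tpr)
    area = float(np.trapezoid(tpr_arr, fpr_arr))
    return RocCurve(fpr=fpr_arr, tpr=tpr_arr, auc=area)


def direction_call(values, groups, marker: str = "") -> DirectionCall:
    """Which class sits High: the one with the larger mean value.

    Intended for batch-normalized (pre-pareto) data where group means are
    interpretable.  Exactly equal means yield a withheld (tied) call.
    """
    cases, controls = _split(values, groups)
    case_mean, control_mean = cases.mean(), controls.mean()
    if case_mean == control_mean:
        return DirectionCall(marker, "tied", "tied", tied=True)
    if case_mean > control_mean:
        return DirectionCall(marker, "Low", "High")
    return DirectionCall(marker, "High", "Low")


def _five_number(values: np.ndarray) -> np.ndarray:
    return np.quantile(values, [0.0, 0.25, 0.5, 0.75, 1.0])


def univariate_report(table: FeatureTable | ProcessedTable) -> list[MarkerRecord]:
    """One record per marker: AUC, ROC curve, direction call and per-class
    five-number summaries, sorted by AUC descending.

    For a :class:`ProcessedTable` carrying a pre-pareto snapshot, direction
    calls and box-plot summaries use that snapshot (pareto centering makes
    raw means uninterpretable); AUC is invariant to the choice.
    """
    scored = np.asarray(table.intensities, dtype=float)
    summarised = scored
    if isinstance(table, ProcessedTable) and table.unscaled is not None:
        summarised = table.unscaled
    case_mask = table.is_case()
    records = []
    for j, name in enumerate(table.markers):
        col_auc = scored[:, j]
        col_sum = summarised[:, j]
        records.append(
            MarkerRecord(
                marker=name,
                auc=auc(col_auc, table.groups),
                curve=roc_curve(col_auc, table.groups),
                direction=direction_call(col_sum, table.groups, name),
                control_summary=_five_number(col_sum[~case_mask]),
                case_summary=_five_number(col_sum[case_mask]),
            )
        )
    records.sort(key=lambda r: (-r.auc, r.marker))
    return records


def report_frame(records: list[MarkerRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "marker": r.marker,
            "auc": r.auc,
            "control_level": r.direction.control_level,
            "case_level": r.direction.case_level,
        }
        for i, q in enumerate(("q1", "q2", "q3", "q4", "q5"), 0):
            row[f"ctrl_{q}"] = r.control_summary[i]
            row[f"case_{q}"] = r.case_summary[i]
        rows.append(row)
    return pd.DataFrame(rows)
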