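"""Monte Carlo cross-validation around random-forest backward selection.

Each of N iterations draws a random (by default stratified) train/test
split, fits pareto centering/scaling constants on the training rows only,
runs SBS on the training data, refits a forest on the selected subset and
scores the held-out samples with its case-class probability.  Batch
normalization and the log transform are applied to the full table up
front: batch structure is a property of acquisition, not of the
classifier, and the log is elementwise, so neither leaks test labels.

Aggregates: per-marker rank frequency (fraction of iterations selected),
a VIP-like mean importance score (forest importances rescaled so the
ever-selected panel has mean square 1), direction calls on the pre-pareto
data, the test-AUC distribution, and the composite (vertically averaged)
ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, MetamarkError
from .preprocess import PreprocessConfig, batch_normalize, log_transform, pareto_apply, pareto_fit
from .selection import SBSConfig, rf_oob, sbs
from .table import CASE, FeatureTable, ProcessedTable
from .univariate import DirectionCall, RocCurve, auc, direction_call, roc_curve

_ROC_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class MCCVConfig:
    n_iterations: int = 50
    train_fraction: float = 0.7
    stratified: bool = True
    base_seed: int = 0
    sbs: SBSConfig = field(default_factory=SBSConfig)

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ConfigurationError(f"n_iterations must be >= 1, got {self.n_iterations}")
        if not 0 < self.train_fraction < 1:
            raise ConfigurationError(
                f"train_fraction must be in (0, 1), got {self.train_fraction}"
            )


@dataclass
class IterationResult:
    train_idx: np.ndarray
    test_idx: np.ndarray
    selected_markers: list[str]
    importance: dict[str, float]
    test_scores: np.ndarray
    roc: RocCurve
    auc: float


@dataclass
class MCCVResult:
    markers: list[str]
    groups: np.ndarray
    unscaled: np.ndarray  # batch-normalized + logged matrix (pre-pareto)
    iterations: list[IterationResult]
    config: MCCVConfig

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    @property
    def test_aucs(self) -> np.ndarray:
        return np.array([it.auc for it in self.iterations])


def _split_sizes(n: int, fraction: float) -> int:
    return int(round(n * fraction))


def _draw_split(groups: np.ndarray, config: MCCVConfig, rng: np.random.Generator):
    n = len(groups)
    if config.stratified:
        train = []
        for label in sorted(set(groups)):
            idx = np.flatnonzero(groups == label)
            n_train = _split_sizes(len(idx), config.train_fraction)
            if n_train < 2 or len(idx) - n_train < 2:
                raise ConfigurationError(
                    f"split leaves fewer than 2 '{label}' samples on one side "
                    f"({n_train} train of {len(idx)})"
                )
            train.extend(rng.permutation(idx)[:n_train])
        train_idx = np.sort(np.asarray(train))
    else:
        n_train = _split_sizes(n, config.train_fraction)
        train_idx = np.sort(rng.permutation(n)[:n_train])
    mask = np.zeros(n, dtype=bool)
    mask[train_idx] = True
    return train_idx, np.flatnonzero(~mask)


def _subtable(table, rows: np.ndarray, values: np.ndarray) -> FeatureTable:
    return FeatureTable(
        sample_ids=[table.sample_ids[i] for i in rows],
        groups=table.groups[rows],
        batches=table.batches[rows],
        markers=list(table.markers),
        intensities=values,
    )


def mccv_run(
    table: FeatureTable | ProcessedTable,
    config: MCCVConfig | None = None,
    preprocess_config: PreprocessConfig | None = None,
    fixed_markers: list[str] | None = None,
) -> MCCVResult:
    """Run N iterations of split -> (pareto on train) -> SBS -> test ROC.

    ``table`` is the raw feature table; batch normalization and the log
    transform (as configured) are applied once before splitting, pareto
    scaling is refitted inside every split.  A :class:`ProcessedTable`
    that already includes pareto scaling is rejected, since its scaling
    constants would leak test rows.  With ``fixed_markers`` the SBS step
    is skipped and the given panel is validated in every iteration.
    Deterministic given ``base_seed`` (iteration i uses seed
    ``base_seed + i``).
    """
    config = config or MCCVConfig()
    pp = preprocess_config or PreprocessConfig()
    if isinstance(table, ProcessedTable):
        if "pareto" in table.steps:
            raise ConfigurationError(
                "table is already pareto-scaled; pass the raw table so "
                "scaling can be fitted on training rows only"
            )
        base = table.table
    else:
        base = table
        if pp.apply_batch_norm:
            base = batch_normalize(base)
        if pp.apply_log:
            base = log_transform(base, pp)
    base.require_two_classes()
    M = base.intensities
    groups = base.groups

    iterations: list[IterationResult] = []
    for i in range(config.n_iterations):
        seed = config.base_seed + i
        rng = np.random.default_rng(seed)
        train_idx, test_idx = _draw_split(groups, config, rng)
        stats = pareto_fit(M[train_idx])
        train_tab = _subtable(base, train_idx, pareto_apply(M[train_idx], stats))
        X_test = pareto_apply(M[test_idx], stats)

        if fixed_markers is None:
            trace = sbs(train_tab, replace(config.sbs, seed=config.sbs.seed + seed))
            selected = trace.selected_markers
        else:
            selected = list(fixed_markers)
        fit = rf_oob(train_tab, selected, config.sbs, seed=seed)
        forest = fit["forest"]
        cols = [base.markers.index(m) for m in selected]
        case_col = list(forest.classes_).index(1)
        scores = forest.predict_proba(X_test[:, cols])[:, case_col]
        test_groups = groups[test_idx]
        iterations.append(
            IterationResult(
                train_idx=train_idx,
                test_idx=test_idx,
                selected_markers=selected,
                importance=fit["importance"],
                test_scores=scores,
                roc=roc_curve(scores, test_groups),
                auc=auc(scores, test_groups),
            )
        )
    return MCCVResult(
        markers=list(base.markers),
        groups=groups,
        unscaled=M.copy(),
        iterations=iterations,
        config=config,
    )


def rank_frequency(result: MCCVResult) -> dict[str, float]:
    """Fraction of iterations in which each marker was selected."""
    counts = dict.fromkeys(result.markers, 0)
    for it in result.iterations:
        for m in it.selected_markers:
            counts[m] += 1
    n = result.n_iterations
    return {m: c / n for m, c in counts.items()}


def importance_scores(result: MCCVResult) -> dict[str, float]:
    """VIP-like score: mean refit-forest importance over the iterations in
    which a marker was selected, rescaled so the mean square over all
    ever-selected markers equals 1.  Never-selected markers score 0."""
    sums = dict.fromkeys(result.markers, 0.0)
    counts = dict.fromkeys(result.markers, 0)
    for it in result.iterations:
        for m in it.selected_markers:
            sums[m] += it.importance[m]
            counts[m] += 1
    raw = {m: (sums[m] / counts[m] if counts[m] else 0.0) for m in result.markers}
    selected_vals = np.array([v for m, v in raw.items() if counts[m]])
    if len(selected_vals) == 0:
        return raw
    ms = float(np.mean(selected_vals**2))
    scale = 1.0 / np.sqrt(ms) if ms > 0 else 1.0
    return {m: v * scale for m, v in raw.items()}


def direction_calls(result: MCCVResult) -> dict[str, DirectionCall]:
    """Low/High calls per marker on the pre-pareto matrix."""
    return {
        m: direction_call(result.unscaled[:, j], result.groups, m)
        for j, m in enumerate(result.markers)
    }


def composite_roc(result: MCCVResult) -> RocCurve:
    """Vertical averaging: mean TPR over iterations on a fixed 101-point
    FPR grid.  Per-grid-point standard deviations are recoverable via
    :func:`composite_roc_frame`."""
    curves = [it.roc for it in result.iterations if it.roc is not None]
    if not curves:
        raise MetamarkError("no valid ROC curves to average")
    tprs = np.vstack([np.interp(_ROC_GRID, c.fpr, c.tpr) for c in curves])
    mean_tpr = tprs.mean(axis=0)
    mean_tpr[0], mean_tpr[-1] = 0.0, 1.0
    area = float(np.trapezoid(mean_tpr, _ROC_GRID))
    return RocCurve(fpr=_ROC_GRID.copy(), tpr=mean_tpr, auc=area, positive_class=CASE)


def composite_roc_frame(result: MCCVResult) -> pd.DataFrame:
    curves = [it.roc for it in result.iterations]
    tprs = np.vstack([np.interp(_ROC_GRID, c.fpr, c.tpr) for c in curves])
    mean_tpr = tprs.mean(axis=0)
    mean_tpr[0], mean_tpr[-1] = 0.0, 1.0
    return pd.DataFrame(
        {"fpr": _ROC_GRID, "mean_tpr": mean_tpr, "sd_tpr": tprs.std(axis=0, ddof=0)}
    )


def marker_table(result: MCCVResult, min_rank_freq: float = 0.5) -> pd.DataFrame:
    """Summary of markers selected in at least ``min_rank_freq`` of the
    iterations: rank frequency, importance score and Low/High direction,
    sorted by rank frequency then importance descending."""
    freqs = rank_frequency(result)
    scores = importance_scores(result)
    dirs = direction_calls(result)
    rows = [
        {
            "marker": m,
            "rank_freq": freqs[m],
            "importance": scores[m],
            "control_level": dirs[m].control_level,
            "case_level": dirs[m].case_level,
        }
        for m in result.markers
        if freqs[m] >= min_rank_freq and freqs[m] > 0
    ]
    df = pd.DataFrame(rows, columns=["marker", "rank_freq", "importance", "control_level", "case_level"])
    if len(df):
        df = df.sort_values(
            ["rank_freq", "importance", "marker"], ascending=[False, False, True], kind="stable"
        ).reset_index(drop=True)
    return df
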