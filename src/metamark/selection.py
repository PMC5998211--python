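"""Sequential backward selection (SBS) driven by random-forest OOB error.

Starting from the full marker panel, each round grows a forest on the
surviving markers, records its out-of-bag misclassification rate and
per-marker importances, and drops the least important fraction (at least
one marker) until ``min_subset`` markers remain.  The selected subset is
the surviving set at the round minimizing OOB error; with the one-SE rule
enabled, the smallest subset whose error is within one binomial standard
error of the minimum wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.ensemble._forest import _generate_unsampled_indices, _get_n_samples_bootstrap

from .exceptions import ClassDegeneracyError, ConfigurationError
from .table import CASE, FeatureTable, ProcessedTable

_IMPORTANCE_TYPES = ("impurity", "permutation")


@dataclass
class SBSConfig:
    """Knobs of the elimination schedule and the underlying forest.

    The elimination fraction, subset floor, tree count, importance type
    and one-standard-error tie rule are deliberately configuration, not
    constants.  ``importance_type``: "impurity" (mean decrease in node
    impurity, the forest's native ranking; default, fast) or "permutation"
    (OOB permutation importance, slower).
    """

    n_trees: int = 500
    elimination_fraction: float = 0.2
    min_subset: int = 2
    importance_type: str = "impurity"
    one_se_rule: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.elimination_fraction < 1:
            raise ConfigurationError(
                f"elimination_fraction must be in (0, 1), got {self.elimination_fraction}"
            )
        if self.min_subset < 1:
            raise ConfigurationError(f"min_subset must be >= 1, got {self.min_subset}")
        if self.n_trees < 1:
            raise ConfigurationError(f"n_trees must be >= 1, got {self.n_trees}")
        if self.importance_type not in _IMPORTANCE_TYPES:
            raise ConfigurationError(
                f"importance_type must be one of {_IMPORTANCE_TYPES}, got "
                f"{self.importance_type!r}"
            )


@dataclass
class SBSRound:
    markers: list[str]
    oob_error: float
    oob_se: float
    importance: dict[str, float]
    dropped: list[str] = field(default_factory=list)


@dataclass
class SBSTrace:
    rounds: list[SBSRound]
    best_round: int
    selected_markers: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "round": range(len(self.rounds)),
                "n_markers": [len(r.markers) for r in self.rounds],
                "oob_error": [r.oob_error for r in self.rounds],
                "oob_se": [r.oob_se for r in self.rounds],
                "dropped_markers": [";".join(r.dropped) for r in self.rounds],
            }
        )


def _as_xy(table: FeatureTable | ProcessedTable, markers: list[str] | None):
    names = list(table.markers)
    if markers is None:
        idx = np.arange(len(names))
        markers = names
    else:
        idx = np.array([names.index(m) for m in markers])
    X = np.asarray(table.intensities, dtype=float)[:, idx]
    y = (np.asarray(table.groups, dtype=object) == CASE).astype(int)
    if y.all() or not y.any():
        raise ClassDegeneracyError("random forest requires both classes")
    return X, y, list(markers)


def _fit_forest(X: np.ndarray, y: np.ndarray, config: SBSConfig, seed: int):
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return forest


def _oob_permutation_importance(
    forest: RandomForestClassifier, X: np.ndarray, y: np.ndarray, seed: int
) -> np.ndarray:
    """Per-feature OOB permutation importance: mean over trees of the
    increase in OOB error when the feature is permuted within the tree's
    out-of-bag rows."""
    rng = np.random.default_rng(seed)
    n, p = X.shape
    n_boot = _get_n_samples_bootstrap(n, forest.max_samples, None)
    deltas = np.zeros(p)
    for tree in forest.estimators_:
        oob = _generate_unsampled_indices(tree.random_state, n, n_boot, None)
        if len(oob) == 0:
            continue
        X_oob, y_oob = X[oob], y[oob]
        base = np.mean(tree.predict(X_oob) != y_oob)
        for j in range(p):
            perm = X_oob.copy()
            perm[:, j] = rng.permutation(perm[:, j])
            deltas[j] += np.mean(tree.predict(perm) != y_oob) - base
    return deltas / len(forest.estimators_)


def rf_oob(
    table: FeatureTable | ProcessedTable,
    markers: list[str] | None = None,
    config: SBSConfig | None = None,
    *,
    seed: int | None = None,
) -> dict:
    """OOB misclassification rate and per-marker importances of a forest
    grown on the given marker subset.  Deterministic given the seed."""
    config = config or SBSConfig()
    seed = config.seed if seed is None else seed
    X, y, markers = _as_xy(table, markers)
    forest = _fit_forest(X, y, config, seed)
    error = 1.0 - float(forest.oob_score_)
    if config.importance_type == "permutation":
        imp = _oob_permutation_importance(forest, X, y, seed)
    else:
        imp = forest.feature_importances_
    return {
        "oob_error": error,
        "oob_se": math.sqrt(max(error * (1 - error), 0.0) / len(y)),
        "importance": dict(zip(markers, map(float, imp))),
        "forest": forest,
    }


def _next_size(n: int, fraction: float, floor: int) -> int:
    keep = math.ceil(n * (1 - fraction))
    return max(floor, min(keep, n - 1))


def sbs(
    table: FeatureTable | ProcessedTable,
    config: SBSConfig | None = None,
) -> SBSTrace:
    """Backward elimination over the marker panel.

    Importances are recomputed each round on the surviving set.  Round
    sizes follow ``n -> max(min_subset, ceil(n * (1 - fraction)))`` (drop
    at least one marker per round).  Within a round, ties in importance
    are broken by marker name so the trace is deterministic.
    """
    config = config or SBSConfig()
    surviving = list(table.markers)
    if len(surviving) < config.min_subset:
        raise ConfigurationError(
            f"table has {len(surviving)} markers, fewer than min_subset "
            f"{config.min_subset}"
        )
    rounds: list[SBSRound] = []
    round_idx = 0
    while True:
        res = rf_oob(table, surviving, config, seed=config.seed + round_idx)
        record = SBSRound(
            markers=list(surviving),
            oob_error=res["oob_error"],
            oob_se=res["oob_se"],
            importance=res["importance"],
        )
        rounds.append(record)
        if len(surviving) <= config.min_subset:
            break
        target = _next_size(len(surviving), config.elimination_fraction, config.min_subset)
        order = sorted(surviving, key=lambda m: (res["importance"][m], m))
        drop = set(order[: len(surviving) - target])
        record.dropped = [m for m in surviving if m in drop]
        surviving = [m for m in surviving if m not in drop]
        round_idx += 1

    errors = np.array([r.oob_error for r in rounds])
    best = int(np.argmin(errors))
    if config.one_se_rule:
        cutoff = errors[best] + rounds[best].oob_se
        # smallest surviving subset within one SE of the minimum
        candidates = [i for i, r in enumerate(rounds) if r.oob_error <= cutoff]
        best = max(candidates, key=lambda i: (-len(rounds[i].markers), i))
    return SBSTrace(rounds=rounds, best_round=best, selected_markers=list(rounds[best].markers))


def with_seed(config: SBSConfig, seed: int) -> SBSConfig:
    return replace(config, seed=seed)
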