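"""Synthetic two-class cohort generator.

Generates feature tables with the statistical structure the downstream
analysis assumes: log-normal intensities, an additive case/control effect
on the log scale for a chosen subset of "informative" markers, purely
multiplicative per-batch per-marker scale factors, and Gaussian
log-intensity noise.  Everything is deterministic given the seed, and the
identities and signed effects of the planted markers are recoverable so
that marker-recovery performance can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ConfigurationError
from .table import CASE, CONTROL, FeatureTable

_UP_FRACTION = 0.7  # planted effects: ~70% elevated in cases, rest decreased


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    ``effect_log2fc`` may be ``None`` (signed magnitudes drawn uniformly
    from ``effect_magnitude_range``, with ``ceil(0.7 * n_informative)``
    positive), a scalar applied to every informative marker, or an explicit
    sequence of ``n_informative`` signed log2 fold changes.
    """

    n_case: int = 15
    n_control: int = 21
    n_markers: int = 232
    n_informative: int = 10
    n_batches: int = 2
    effect_log2fc: float | Sequence[float] | None = None
    effect_magnitude_range: tuple[float, float] = (1.0, 2.0)
    baseline_log_mean: float | Sequence[float] = 8.0
    noise_sd: float = 0.5
    batch_scale_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_case", "n_control", "n_markers", "n_batches"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_informative < 0:
            raise ConfigurationError(f"n_informative must be >= 0, got {self.n_informative}")
        if self.n_informative > self.n_markers:
            raise ConfigurationError(
                f"n_informative ({self.n_informative}) exceeds n_markers ({self.n_markers})"
            )
        if not self.noise_sd > 0:
            raise ConfigurationError(f"noise_sd must be > 0, got {self.noise_sd}")
        lo, hi = self.batch_scale_range
        if not (0 < lo <= hi):
            raise ConfigurationError(f"batch_scale_range must be positive, got {self.batch_scale_range}")
        if self.effect_log2fc is not None and not np.isscalar(self.effect_log2fc):
            if len(self.effect_log2fc) != self.n_informative:
                raise ConfigurationError(
                    f"effect_log2fc has {len(self.effect_log2fc)} entries, "
                    f"expected n_informative = {self.n_informative}"
                )


@dataclass
class CohortPlan:
    """Deterministic layout shared by :func:`generate_cohort` and
    :func:`planted_markers`: marker names, informative subset with signed
    effects, per-marker baselines and per-batch scale factors."""

    marker_names: list[str]
    informative: dict[str, float]  # marker name -> signed log2 fold change
    baselines: np.ndarray  # (p,) natural-log means
    batch_factors: np.ndarray  # (n_batches, p) multiplicative factors
    batch_names: list[str] = field(default_factory=list)


def _plan(config: SyntheticConfig) -> CohortPlan:
    rng = np.random.default_rng(config.seed)
    p = config.n_markers
    width = max(3, len(str(p)))
    names = [f"marker_{i + 1:0{width}d}" for i in range(p)]

    idx = rng.choice(p, size=config.n_informative, replace=False) if config.n_informative else np.array([], dtype=int)
    if config.effect_log2fc is None:
        lo, hi = config.effect_magnitude_range
        mags = rng.uniform(lo, hi, size=config.n_informative)
        n_up = math.ceil(_UP_FRACTION * config.n_informative)
        signs = np.where(np.arange(config.n_informative) < n_up, 1.0, -1.0)
        effects = mags * signs
    elif np.isscalar(config.effect_log2fc):
        effects = np.full(config.n_informative, float(config.effect_log2fc))
    else:
        effects = np.asarray(config.effect_log2fc, dtype=float)

    if np.isscalar(config.baseline_log_mean):
        baselines = np.full(p, float(config.baseline_log_mean))
    else:
        baselines = np.asarray(config.baseline_log_mean, dtype=float)
        if baselines.shape != (p,):
            raise ConfigurationError(
                f"baseline_log_mean must be scalar or length n_markers ({p})"
            )

    lo, hi = config.batch_scale_range
    # log-uniform draw keeps the factor distribution symmetric around 1
    # when the range is (1/k, k)
    factors = np.exp(rng.uniform(np.log(lo), np.log(hi), size=(config.n_batches, p)))
    batch_names = [f"batch_{b + 1}" for b in range(config.n_batches)]
    informative = {names[i]: float(e) for i, e in zip(idx, effects)}
    return CohortPlan(names, informative, baselines, factors, batch_names)


def planted_markers(config: SyntheticConfig) -> dict[str, float]:
    """Names and signed log2 effects of the informative markers.

    The returned dict has exactly ``n_informative`` entries and its keys
    are a subset of the marker names produced by :func:`generate_cohort`
    with the same config.
    """
    return dict(_plan(config).informative)


def generate_cohort(config: SyntheticConfig, *, return_plan: bool = False):
    """Draw a synthetic cohort.

    Intensities are ``exp(baseline + group effect + log batch factor +
    N(0, noise_sd))``; the group effect ``log(2) * effect_log2fc`` is added
    to case samples of informative markers only.  Batches are assigned
    round-robin over the sample index so batch is not confounded with
    class.  Bit-identical output for identical config.

    Returns the :class:`~metamark.table.FeatureTable`, and with
    ``return_plan=True`` also the :class:`CohortPlan` (for tests that need
    the applied batch factors or baselines).
    """
    plan = _plan(config)
    # independent stream for the noise so planted identities do not shift
    # when cohort sizes change
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_case + config.n_control
    p = config.n_markers

    log_x = np.tile(plan.baselines, (n, 1))
    case_mask = np.zeros(n, dtype=bool)
    case_mask[: config.n_case] = True
    for name, lfc in plan.informative.items():
        j = plan.marker_names.index(name)
        log_x[case_mask, j] += math.log(2.0) * lfc

    batch_idx = np.arange(n) % config.n_batches
    log_x += np.log(plan.batch_factors)[batch_idx, :]
    log_x += rng.normal(0.0, config.noise_sd, size=(n, p))

    sample_ids = [f"case_{i + 1:02d}" for i in range(config.n_case)] + [
        f"control_{i + 1:02d}" for i in range(config.n_control)
    ]
    groups = np.array([CASE] * config.n_case + [CONTROL] * config.n_control, dtype=object)
    batches = np.array([plan.batch_names[b] for b in batch_idx], dtype=object)
    table = FeatureTable(
        sample_ids=sample_ids,
        groups=groups,
        batches=batches,
        markers=plan.marker_names,
        intensities=np.exp(log_x),
    )
    return (table, plan) if return_plan else table
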