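"""Preprocessing: batch RMS normalization, log transform, pareto scaling.

The three steps are applied in the fixed order batch_normalize ->
log_transform -> pareto_scale.  Batch normalization divides each marker
within each batch by the root-mean-square of that marker's values in that
batch, so every batch-marker block has RMS 1 afterwards and any purely
multiplicative per-batch distortion cancels.  Pareto scaling mean-centers
each column and divides by the square root of its sample standard
deviation (n-1 denominator), a compromise between no scaling and
unit-variance scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    ConfigurationError,
    DegenerateScaleError,
    DomainError,
    InsufficientDataError,
)
from .table import FeatureTable, ProcessedTable

_LOG_BASES = {"10": 10.0, "e": math.e, "2": 2.0}


@dataclass
class PreprocessConfig:
    log_base: str | float = 10
    log_offset: float = 0.0
    apply_batch_norm: bool = True
    apply_log: bool = True
    apply_pareto: bool = True

    def __post_init__(self) -> None:
        key = str(self.log_base).lower()
        if key not in _LOG_BASES:
            raise ConfigurationError(f"log_base must be one of 10, e, 2; got {self.log_base!r}")
        self.log_base = key
        if self.log_offset < 0:
            raise ConfigurationError(f"log_offset must be >= 0, got {self.log_offset}")

    @property
    def base_value(self) -> float:
        return _LOG_BASES[str(self.log_base)]


def batch_rms(table: FeatureTable) -> dict[str, np.ndarray]:
    """Per-batch, per-marker root-mean-square of the intensities."""
    out: dict[str, np.ndarray] = {}
    for batch in sorted(set(table.batches)):
        rows = table.intensities[table.batches == batch]
        out[batch] = np.sqrt(np.mean(rows**2, axis=0))
    return out


def batch_normalize(table: FeatureTable) -> FeatureTable:
    """Divide each marker in each batch by that block's RMS.

    After the call the RMS of every marker within every batch is exactly 1.
    Raises :class:`DegenerateScaleError` for an all-zero batch-marker block.
    """
    values = table.intensities.copy()
    for batch, rms in batch_rms(table).items():
        zero = rms == 0
        if zero.any():
            j = int(np.argmax(zero))
            raise DegenerateScaleError(
                f"marker '{table.markers[j]}' is all zero within batch '{batch}'"
            )
        mask = table.batches == batch
        values[mask] = values[mask] / rms
    return table.with_intensities(values)


def log_transform(table: FeatureTable, config: PreprocessConfig | None = None) -> FeatureTable:
    """Elementwise log of (value + offset) in the configured base."""
    config = config or PreprocessConfig()
    shifted = table.intensities + config.log_offset
    if (shifted <= 0).any():
        i, j = map(int, np.argwhere(shifted <= 0)[0])
        raise DomainError(
            f"log of nonpositive value for sample '{table.sample_ids[i]}', "
            f"marker '{table.markers[j]}' (value {table.intensities[i, j]}, "
            f"offset {config.log_offset})"
        )
    return table.with_intensities(np.log(shifted) / math.log(config.base_value))


def pareto_fit(values: np.ndarray) -> dict[str, np.ndarray]:
    """Centering/scaling constants for pareto scaling, fitted column-wise.

    Returned dict holds per-column ``mean``, ``scale`` (sqrt of the sample
    standard deviation; 1 for zero-variance columns) and a ``zero_variance``
    flag.  Kept separate from :func:`pareto_apply` so cross-validation can
    fit on training rows only.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        raise InsufficientDataError(
            f"pareto scaling needs >= 2 samples, got {values.shape[0]}"
        )
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    zero = sd == 0
    scale = np.where(zero, 1.0, np.sqrt(sd))
    return {"mean": mean, "scale": scale, "zero_variance": zero}


def pareto_apply(values: np.ndarray, stats: dict[str, np.ndarray]) -> np.ndarray:
    """Apply fitted pareto constants; zero-variance columns map to zero."""
    out = (np.asarray(values, dtype=float) - stats["mean"]) / stats["scale"]
    out[:, stats["zero_variance"]] = 0.0
    return out


def pareto_scale(table: FeatureTable) -> ProcessedTable:
    """Mean-center each column and divide by sqrt(sample sd).

    Zero-variance columns become all-zero and are flagged in the result's
    constants rather than dropped, so marker indices stay stable.
    """
    stats = pareto_fit(table.intensities)
    scaled = table.with_intensities(pareto_apply(table.intensities, stats))
    return ProcessedTable(
        table=scaled,
        steps=["pareto"],
        constants={"pareto": stats},
        unscaled=table.intensities.copy(),
    )


def preprocess(table: FeatureTable, config: PreprocessConfig | None = None) -> ProcessedTable:
    """Run the enabled steps in the fixed order batch norm -> log -> pareto."""
    config = config or PreprocessConfig()
    steps: list[str] = []
    constants: dict = {}
    current = table
    if config.apply_batch_norm:
        constants["batch_rms"] = batch_rms(table)
        current = batch_normalize(current)
        steps.append("batch_norm")
    if config.apply_log:
        current = log_transform(current, config)
        steps.append("log")
    unscaled = current.intensities.copy()
    if config.apply_pareto:
        stats = pareto_fit(current.intensities)
        constants["pareto"] = stats
        current = current.with_intensities(pareto_apply(current.intensities, stats))
        steps.append("pareto")
    return ProcessedTable(table=current, steps=steps, constants=constants, unscaled=unscaled)
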