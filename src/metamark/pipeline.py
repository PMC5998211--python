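"""End-to-end runner: simulation/input -> preprocessing -> PLS-DA/VIP ->
univariate ROC -> SBS -> MCCV -> CSV reports plus a reproducibility
manifest."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import sklearn
import yaml

from . import __version__
from .exceptions import ConfigurationError
from .mccv import MCCVConfig, composite_roc_frame, marker_table, mccv_run
from .plsda import fit_plsda, vip_report
from .preprocess import PreprocessConfig, preprocess
from .selection import SBSConfig, sbs
from .synthetic import SyntheticConfig, generate_cohort, planted_markers
from .table import FeatureTable, read_feature_table, write_feature_table
from .univariate import report_frame, univariate_report

log = logging.getLogger("metamark")

# fixed fan-out offsets: adding a stage never perturbs another stage's stream
SEED_OFFSET_SBS = 1000
SEED_OFFSET_MCCV = 2000

_FLOAT_FMT = "%.17g"


@dataclass
class RunConfig:
    input_path: str | None = None
    synthetic: bool = False
    synthetic_config: SyntheticConfig = field(default_factory=SyntheticConfig)
    preprocess_config: PreprocessConfig = field(default_factory=PreprocessConfig)
    n_components: int = 3
    vip_threshold: float = 2.0
    sbs_config: SBSConfig = field(default_factory=SBSConfig)
    mccv_config: MCCVConfig = field(default_factory=MCCVConfig)
    rank_freq_threshold: float = 0.5
    out_dir: str = "metamark_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if bool(self.input_path) == bool(self.synthetic):
            raise ConfigurationError(
                "exactly one of input_path / synthetic must be set"
            )


def config_from_mapping(raw: dict) -> RunConfig:
    """Build a RunConfig from a (YAML-loaded) nested mapping."""
    raw = dict(raw or {})
    kwargs: dict = {}
    for key in ("input_path", "synthetic", "n_components", "vip_threshold",
                "rank_freq_threshold", "out_dir", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    if "synthetic_config" in raw:
        kwargs["synthetic_config"] = SyntheticConfig(**raw["synthetic_config"])
    if "preprocess" in raw:
        kwargs["preprocess_config"] = PreprocessConfig(**raw["preprocess"])
    sbs_kwargs = raw.get("sbs", {})
    if sbs_kwargs:
        kwargs["sbs_config"] = SBSConfig(**sbs_kwargs)
    if "mccv" in raw:
        mc = dict(raw["mccv"])
        mc["sbs"] = SBSConfig(**mc.pop("sbs", sbs_kwargs))
        kwargs["mccv_config"] = MCCVConfig(**mc)
    return RunConfig(**kwargs)


def _manifest(config: RunConfig) -> dict:
    return {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "seed_offsets": {"sbs": SEED_OFFSET_SBS, "mccv": SEED_OFFSET_MCCV},
        "versions": {
            "metamark": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }


def load_input(config: RunConfig) -> FeatureTable:
    if config.synthetic:
        syn = dataclasses.replace(config.synthetic_config, seed=config.seed)
        log.info("simulating cohort: %d markers, seed %d", syn.n_markers, config.seed)
        return generate_cohort(syn)
    log.info("reading feature table from %s", config.input_path)
    return read_feature_table(config.input_path)


def run_full_analysis(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle into the output directory.

    Returns a mapping of artifact name -> written path.  Numeric CSVs are
    written with full float precision so identical config + seed yields
    byte-identical files.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    table = load_input(config)
    sbs_cfg = dataclasses.replace(config.sbs_config, seed=config.seed + SEED_OFFSET_SBS)
    mccv_cfg = dataclasses.replace(
        config.mccv_config,
        base_seed=config.seed + SEED_OFFSET_MCCV,
        sbs=dataclasses.replace(config.sbs_config, seed=0),
    )

    processed = preprocess(table, config.preprocess_config)
    paths["processed_table"] = out / "processed_table.csv"
    write_feature_table(processed, paths["processed_table"])
    _write_sidecar(processed, out / "processed_table.meta.yaml")

    log.info("fitting PLS-DA with %d components", config.n_components)
    model = fit_plsda(processed, config.n_components)
    report = vip_report(model)
    paths["vip_report"] = out / "vip_report.csv"
    report.to_frame().to_csv(paths["vip_report"], index=False, float_format=_FLOAT_FMT)

    log.info("univariate ROC analysis of %d markers", processed.n_markers)
    records = univariate_report(processed)
    paths["univariate_report"] = out / "univariate_report.csv"
    report_frame(records).to_csv(paths["univariate_report"], index=False, float_format=_FLOAT_FMT)

    log.info("sequential backward selection (%d trees)", sbs_cfg.n_trees)
    trace = sbs(processed, sbs_cfg)
    paths["sbs_trace"] = out / "sbs_trace.csv"
    trace.to_frame().to_csv(paths["sbs_trace"], index=False, float_format=_FLOAT_FMT)
    paths["selected_markers"] = out / "selected_markers.txt"
    paths["selected_markers"].write_text("\n".join(trace.selected_markers) + "\n")

    log.info("MCCV: %d iterations", mccv_cfg.n_iterations)
    result = mccv_run(table, mccv_cfg, config.preprocess_config)
    paths["mccv_markers"] = out / "mccv_markers.csv"
    marker_table(result, config.rank_freq_threshold).to_csv(
        paths["mccv_markers"], index=False, float_format=_FLOAT_FMT
    )
    paths["composite_roc"] = out / "composite_roc.csv"
    composite_roc_frame(result).to_csv(paths["composite_roc"], index=False, float_format=_FLOAT_FMT)
    paths["auc_distribution"] = out / "auc_distribution.csv"
    pd.DataFrame({"auc": result.test_aucs}).to_csv(
        paths["auc_distribution"], index=False, float_format=_FLOAT_FMT
    )

    manifest = _manifest(config)
    if config.synthetic:
        manifest["planted_markers"] = planted_markers(
            dataclasses.replace(config.synthetic_config, seed=config.seed)
        )
    paths["manifest"] = out / "manifest.yaml"
    paths["manifest"].write_text(yaml.safe_dump(manifest, sort_keys=True))
    log.info("wrote %d artifacts to %s", len(paths), out)
    return paths


def _write_sidecar(processed, path: Path) -> None:
    meta: dict = {"steps": list(processed.steps)}
    pareto = processed.constants.get("pareto")
    if pareto is not None:
        meta["pareto_mean"] = [float(v) for v in pareto["mean"]]
        meta["pareto_scale"] = [float(v) for v in pareto["scale"]]
        meta["zero_variance_markers"] = [
            m for m, z in zip(processed.markers, pareto["zero_variance"]) if z
        ]
    rms = processed.constants.get("batch_rms")
    if rms is not None:
        meta["batch_rms"] = {b: [float(v) for v in vals] for b, vals in rms.items()}
    path.write_text(yaml.safe_dump(meta, sort_keys=True))
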