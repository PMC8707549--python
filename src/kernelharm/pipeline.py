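"""End-to-end experiment: simulate -> train -> convert -> extract -> CCC -> AUC.

Two phases on disjoint synthetic cohorts.  The *development* cohort trains
the two converters (slice pairs in both directions) and provides the RMSE
quality check; the *validation* cohort — simulated with slightly different
kernel parameters, emulating a second scanner — is where feature
reproducibility (CCC) and mixed-group label prediction (AUC) are measured.
All randomness derives from a single master seed, and a rerun with the same
config reproduces every output byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .simcohort import (
    Cohort,
    KernelProfile,
    PhantomSpec,
    generate_cohort,
)
from .converter import (
    ConverterConfig,
    TrainedConverter,
    convert_volume,
    rmse,
    rmse_reduction,
    train_converter,
)
from .radfeat import ExtractorConfig, FeatureTable, extract_table, feature_groups
from .reproducibility import CCCReport, ccc_table, grouped_ccc
from .stattests import wilcoxon_signed_rank
from .egfr import (
    AUCReport,
    assign_mixed,
    auc_distribution,
    build_groups_from_tables,
)

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment",
            "write_report", "clinical_scale_config"]


def _seed_for(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one full experiment."""

    seed: int = 0
    # cohorts
    n_dev: int = 16
    n_val: int = 60
    prevalence: float = 114.0 / 223.0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    # development-scanner kernels
    dev_smooth: KernelProfile = KernelProfile("smooth", -0.7, 0.20, 5.0)
    dev_sharp: KernelProfile = KernelProfile("sharp", 1.0, 0.25, 40.0)
    # validation-scanner kernels (second-scanner analog: shifted cutoff/noise)
    val_smooth: KernelProfile = KernelProfile("smooth", -0.7, 0.18, 6.0)
    val_sharp: KernelProfile = KernelProfile("sharp", 1.0, 0.27, 45.0)
    # converter (desk-scale training defaults; architecture is configurable)
    n_layers: int = 4
    channels: int = 16
    learning_rate: float = 1e-3
    n_epochs: int = 20
    batch_size: int = 8
    train_fraction: float = 14.0 / 32.0  # fraction of dev patients used to train
    holdout_fraction: float = 0.25
    # analysis
    extractor: ExtractorConfig = field(default_factory=ExtractorConfig)
    ccc_threshold: float = 0.85
    top_k: int = 3

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def clinical_scale_config(seed: int = 0) -> ExperimentConfig:
    """Cohort sizes of a full two-phase evaluation (development 32, validation 223)."""
    return ExperimentConfig(seed=seed, n_dev=32, n_val=223)


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    ccc_reports: dict  # comparison name -> CCCReport
    grouped: dict  # comparison name -> grouped-mean DataFrame
    ccc_comparisons: dict  # signed-rank results between CCC distributions
    auc_report: AUCReport
    rmse_check: dict  # mean rmse reduction (%) per direction
    training: dict  # per-direction initial/final held-out losses
    provenance: dict

    def summary(self) -> dict:
        out = {
            "provenance": self.provenance,
            "rmse_check": self.rmse_check,
            "training": self.training,
            "ccc": {k: r.summary() for k, r in self.ccc_reports.items()},
            "ccc_comparisons": self.ccc_comparisons,
            "auc": self.auc_report.summary(),
        }
        return out


def _slice_pairs(cohort: Cohort, direction: str, record_indices) -> list:
    """(source, target) axial slice pairs from the given records."""
    pairs = []
    for i in record_indices:
        rec = cohort.records[i]
        for z in range(rec.truth.values.shape[2]):
            smo = rec.smooth_image[:, :, z]
            shp = rec.sharp_image[:, :, z]
            if direction == "to_smooth":
                pairs.append((shp, smo))
            else:
                pairs.append((smo, shp))
    return pairs


def train_direction(
    cohort: Cohort, direction: str, config: ExperimentConfig
) -> TrainedConverter:
    """Train one converter direction on the development cohort's slices."""
    n_train = max(1, int(round(config.train_fraction * len(cohort))))
    cc = ConverterConfig(
        direction=direction,
        n_layers=config.n_layers,
        channels=config.channels,
        learning_rate=config.learning_rate,
        n_epochs=config.n_epochs,
        batch_size=config.batch_size,
        seed=_seed_for(config.seed, f"train-{direction}"),
    )
    pairs = _slice_pairs(cohort, direction, range(n_train))
    return train_converter(pairs, cc, holdout_fraction=config.holdout_fraction)


def _rmse_check(cohort: Cohort, model: TrainedConverter, direction: str,
                record_indices) -> float:
    """Mean RMSE reduction (%) over held-out development records."""
    reductions = []
    for i in record_indices:
        rec = cohort.records[i]
        if direction == "to_smooth":
            src, tgt = rec.sharp_image, rec.smooth_image
        else:
            src, tgt = rec.smooth_image, rec.sharp_image
        conv = convert_volume(model, src)
        reductions.append(rmse_reduction(src, conv, tgt))
    return float(np.mean(reductions))


def run_experiment(config: ExperimentConfig | None = None) -> ExperimentReport:
    config = config or ExperimentConfig()

    # ---- development phase: train converters, RMSE quality check ----
    dev = generate_cohort(
        config.n_dev, config.prevalence, config.phantom,
        smooth=config.dev_smooth, sharp=config.dev_sharp,
        seed=_seed_for(config.seed, "dev-cohort"), id_prefix="D",
    )
    to_smooth = train_direction(dev, "to_smooth", config)
    to_sharp = train_direction(dev, "to_sharp", config)

    n_train = max(1, int(round(config.train_fraction * len(dev))))
    held_records = range(n_train, len(dev))
    rmse_check = {
        "to_smooth_mean_reduction_pct": _rmse_check(dev, to_smooth, "to_smooth", held_records),
        "to_sharp_mean_reduction_pct": _rmse_check(dev, to_sharp, "to_sharp", held_records),
    }
    training = {
        d.config.direction: {
            "initial_test_loss": d.initial_test_loss,
            "final_test_loss": d.training_log[-1]["test_loss"],
            "n_epochs": len(d.training_log),
        }
        for d in (to_smooth, to_sharp)
    }

    # ---- validation phase: disjoint cohort, different scanner analog ----
    val = generate_cohort(
        config.n_val, config.prevalence, config.phantom,
        smooth=config.val_smooth, sharp=config.val_sharp,
        seed=_seed_for(config.seed, "val-cohort"), id_prefix="V",
    )
    vols = {"ori_smo": {}, "ori_shp": {}, "conv_smo": {}, "conv_shp": {}}
    masks = {}
    for rec in val.records:
        masks[rec.id] = rec.mask.values
        vols["ori_smo"][rec.id] = rec.smooth_image
        vols["ori_shp"][rec.id] = rec.sharp_image
        vols["conv_smo"][rec.id] = convert_volume(to_smooth, rec.sharp_image)
        vols["conv_shp"][rec.id] = convert_volume(to_sharp, rec.smooth_image)

    tables = {
        key: extract_table(v, masks, config.extractor, setting=key)
        for key, v in vols.items()
    }

    comparisons = {
        "ori_smo_vs_ori_shp": ("ori_smo", "ori_shp"),
        "ori_smo_vs_conv_smo": ("ori_smo", "conv_smo"),
        "ori_shp_vs_conv_shp": ("ori_shp", "conv_shp"),
    }
    ccc_reports: dict[str, CCCReport] = {}
    grouped = {}
    for name, (a, b) in comparisons.items():
        rep = ccc_table(tables[a], tables[b], comparison=name,
                        threshold=config.ccc_threshold)
        ccc_reports[name] = rep
        grouped[name] = grouped_ccc(rep, feature_groups())

    # paired signed-rank between CCC distributions across features
    base = ccc_reports["ori_smo_vs_ori_shp"].values()
    ccc_comparisons = {}
    for name in ("ori_smo_vs_conv_smo", "ori_shp_vs_conv_shp"):
        other = ccc_reports[name].values()
        ok = np.isfinite(base) & np.isfinite(other)
        res = wilcoxon_signed_rank(other[ok].to_numpy(), base[ok].to_numpy(),
                                   mode="approx")
        ccc_comparisons[name] = {"W": res.W, "Z": abs(res.Z), "p": res.p,
                                 "n": res.n_effective}

    # ---- mixed groups and univariate AUC ----
    assignment = assign_mixed(val, _seed_for(config.seed, "mixed-assignment"))
    groups = build_groups_from_tables(
        assignment, tables["ori_smo"], tables["ori_shp"],
        tables["conv_smo"], tables["conv_shp"],
    )
    labels = {rec.id: rec.label for rec in val.records}
    auc_report = auc_distribution(groups, labels, ccc_reports=ccc_reports,
                                  top_k=config.top_k)

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "n_dev": config.n_dev,
        "n_val": config.n_val,
    }
    return ExperimentReport(
        config=config,
        ccc_reports=ccc_reports,
        grouped=grouped,
        ccc_comparisons=ccc_comparisons,
        auc_report=auc_report,
        rmse_check=rmse_check,
        training=training,
        provenance=provenance,
    )


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not serializable: {type(o)}")


def write_report(report: ExperimentReport, out_dir: str | Path) -> Path:
    """Persist the report as CSV tables plus a summary JSON.

    Deterministic: no timestamps, sorted keys, fixed float formatting via
    repr, so two runs from one config are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, rep in report.ccc_reports.items():
        rep.to_frame().to_csv(out / f"ccc_{name}.csv")
        report.grouped[name].to_csv(out / f"ccc_grouped_{name}.csv")
    report.auc_report.per_feature.to_csv(out / "auc_per_feature.csv",
                                         index_label="feature")
    report.auc_report.top_features.to_csv(out / "top_features.csv",
                                          index_label="feature")
    summary_path = out / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(report.summary(), fh, indent=2, sort_keys=True,
                  default=_json_default)
        fh.write("\n")
    return summary_path
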