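"""Mixed-kernel group construction and univariate AUC label prediction.

Emulates a multi-center situation: each patient is randomly assigned one of
the two kernel renderings ("ori_mix"), then two harmonized variants are
built — "conv_mix_smo" converts the sharp-arm patients to smooth, and
"conv_mix_shp" converts the smooth-arm patients to sharp — so the three
groups contain the same patients and features and differ only in which
rows went through the converter.  Each feature is scored as a univariate
classifier of the binary label by the rank-based AUC (normalized
Mann-Whitney U with midrank tie handling), orientation-corrected to
max(A, 1 - A) so direction-agnostic screening never reports below 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .converter import TrainedConverter, convert_volume
from .radfeat import ExtractorConfig, FeatureTable, extract_all
from .simcohort import Cohort
from .stattests import wilcoxon_signed_rank

__all__ = [
    "MixedAssignment",
    "GroupedFeatureTables",
    "AUCReport",
    "assign_mixed",
    "build_groups",
    "univariate_auc",
    "auc_distribution",
]

GROUP_KEYS = ("ori_mix", "conv_mix_smo", "conv_mix_shp")


@dataclass
class MixedAssignment:
    arms: dict  # patient id -> "smooth" | "sharp"
    seed: int

    @property
    def counts(self) -> dict:
        vals = list(self.arms.values())
        return {"smooth": vals.count("smooth"), "sharp": vals.count("sharp")}


def assign_mixed(cohort: Cohort, seed: int) -> MixedAssignment:
    """Randomly split patients into near-equal smooth/sharp arms.

    A uniform random permutation is halved; with odd n the sharp arm gets
    the extra patient (223 -> 111 smooth / 112 sharp).  Deterministic for a
    given seed.
    """
    if len(cohort) < 2:
        raise ValueError("cohort needs >= 2 patients")
    ids = [r.id for r in cohort.records]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_smooth = len(ids) // 2
    arms = {}
    for rank, idx in enumerate(perm):
        arms[ids[idx]] = "smooth" if rank < n_smooth else "sharp"
    return MixedAssignment(arms=arms, seed=seed)


@dataclass
class GroupedFeatureTables:
    tables: dict  # key in GROUP_KEYS -> FeatureTable
    assignment: MixedAssignment

    def __post_init__(self) -> None:
        pats = None
        feats = None
        for key in GROUP_KEYS:
            t = self.tables[key]
            if pats is None:
                pats, feats = t.patients, t.features
            elif t.patients != pats or t.features != feats:
                raise ValueError("group tables must share patients and features")


def build_groups(
    cohort: Cohort,
    assignment: MixedAssignment,
    to_smooth: TrainedConverter,
    to_sharp: TrainedConverter,
    config: ExtractorConfig | None = None,
) -> GroupedFeatureTables:
    """Extract the three mixed-group feature tables from one assignment."""
    if to_smooth.config.direction != "to_smooth":
        raise ValueError("to_smooth converter has wrong direction")
    if to_sharp.config.direction != "to_sharp":
        raise ValueError("to_sharp converter has wrong direction")
    config = config or ExtractorConfig()

    rows: dict[str, dict[str, pd.Series]] = {k: {} for k in GROUP_KEYS}
    for rec in cohort.records:
        arm = assignment.arms[rec.id]
        ori = rec.smooth_image if arm == "smooth" else rec.sharp_image
        if arm == "smooth":
            mix_smo = rec.smooth_image  # kept as-is
            mix_shp = convert_volume(to_sharp, rec.smooth_image)
        else:
            mix_smo = convert_volume(to_smooth, rec.sharp_image)
            mix_shp = rec.sharp_image
        for key, vol in (("ori_mix", ori), ("conv_mix_smo", mix_smo),
                         ("conv_mix_shp", mix_shp)):
            fv = extract_all(vol, rec.mask.values, config, image_id=rec.id,
                             setting=key)
            rows[key][rec.id] = fv.as_series()

    tables = {}
    for key in GROUP_KEYS:
        df = pd.DataFrame(rows[key]).T
        df.index.name = "id"
        tables[key] = FeatureTable(data=df, setting=key)
    return GroupedFeatureTables(tables=tables, assignment=assignment)


def build_groups_from_tables(
    assignment: MixedAssignment,
    ori_smo: FeatureTable,
    ori_shp: FeatureTable,
    conv_smo: FeatureTable,
    conv_shp: FeatureTable,
) -> GroupedFeatureTables:
    """Assemble mixed-group tables by row selection from per-setting tables.

    Because extraction is deterministic, picking each patient's row from the
    already-extracted table of their assigned setting gives exactly the same
    values as re-extracting the mixed volumes (``build_groups``), at no
    extraction cost.
    """
    pats = ori_smo.patients
    source_for = {
        "ori_mix": {"smooth": ori_smo, "sharp": ori_shp},
        "conv_mix_smo": {"smooth": ori_smo, "sharp": conv_smo},
        "conv_mix_shp": {"smooth": conv_shp, "sharp": ori_shp},
    }
    tables = {}
    for key, src in source_for.items():
        rows = {p: src[assignment.arms[p]].data.loc[p] for p in pats}
        df = pd.DataFrame(rows).T
        df.index.name = "id"
        tables[key] = FeatureTable(data=df, setting=key)
    return GroupedFeatureTables(tables=tables, assignment=assignment)


def univariate_auc(values, labels, orientation_correct: bool = True) -> float:
    """Rank-based AUC of one feature as a classifier of a binary label.

    AUC = U / (n1 * n0) with midrank tie handling; with
    ``orientation_correct`` the result is max(A, 1 - A).
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be equal-length 1D")
    if len(values) < 4:
        raise ValueError("need at least 4 patients")
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(values)
    u = float(ranks[labels == 1].sum()) - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n0)
    return float(max(auc, 1.0 - auc)) if orientation_correct else float(auc)


@dataclass
class AUCReport:
    per_feature: pd.DataFrame  # features x groups, orientation-corrected AUC
    medians: dict  # group -> median AUC
    mads: dict  # group -> median absolute deviation
    comparisons: dict  # group -> {"Z": ..., "p": ..., "W": ...} vs ori_mix
    top_features: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary(self) -> dict:
        return {
            "medians": self.medians,
            "mads": self.mads,
            "comparisons": self.comparisons,
        }


def _mad(v: np.ndarray) -> float:
    return float(np.median(np.abs(v - np.median(v))))


def auc_distribution(
    tables: GroupedFeatureTables,
    labels: dict,
    ccc_reports: dict | None = None,
    top_k: int = 3,
    orientation_correct: bool = True,
) -> AUCReport:
    """Per-feature AUC for each mixed group plus paired comparisons.

    ``labels`` maps patient id -> {0,1}.  Each converted group's AUC vector
    is compared against ori_mix with the two-tailed signed-rank test across
    features (Z and p reported).  When ``ccc_reports`` (comparison name ->
    CCCReport) is given, the top-k table joins each high-AUC feature's three
    CCC comparisons with its three group AUCs.
    """
    pats = tables.tables["ori_mix"].patients
    missing = [p for p in pats if p not in labels]
    if missing:
        raise ValueError(f"labels missing for patients: {missing[:5]}")
    y = np.array([labels[p] for p in pats], dtype=int)

    per = {}
    for key in GROUP_KEYS:
        df = tables.tables[key].data
        aucs = {}
        for feat in df.columns:
            x = df[feat].to_numpy(dtype=float)
            ok = np.isfinite(x)
            if ok.sum() < 4 or len(set(y[ok])) < 2:
                aucs[feat] = np.nan
                continue
            aucs[feat] = univariate_auc(x[ok], y[ok], orientation_correct)
        per[key] = pd.Series(aucs)
    per_df = pd.DataFrame(per)

    defined = per_df.dropna()
    medians = {k: float(np.median(defined[k])) for k in GROUP_KEYS}
    mads = {k: _mad(defined[k].to_numpy()) for k in GROUP_KEYS}

    comparisons = {}
    for key in ("conv_mix_smo", "conv_mix_shp"):
        res = wilcoxon_signed_rank(
            defined[key].to_numpy(), defined["ori_mix"].to_numpy(), mode="approx"
        )
        comparisons[key] = {
            "Z": abs(res.Z),
            "p": res.p,
            "W": res.W,
            "no_difference": res.no_difference,
        }

    top = defined.sort_values("conv_mix_smo", ascending=False).head(top_k)
    cols = {f"auc_{k}": top[k] for k in GROUP_KEYS}
    if ccc_reports:
        for comp_name, rep in ccc_reports.items():
            vals = rep.values()
            cols[f"ccc_{comp_name}"] = vals.reindex(top.index)
    top_df = pd.DataFrame(cols)

    return AUCReport(
        per_feature=per_df,
        medians=medians,
        mads=mads,
        comparisons=comparisons,
        top_features=top_df,
    )
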