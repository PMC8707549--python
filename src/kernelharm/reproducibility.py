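"""Feature reproducibility between kernel settings via Lin's CCC.

Lin's concordance correlation coefficient,

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2),

measures agreement between paired measurements: it is 1 only for perfect
identity and, unlike Pearson's r, is penalized by location or scale shifts.
Moments are population (1/n) moments, matching Lin's original estimator —
a choice that changes values at small n and is therefore fixed here.

A feature whose denominator is zero (both vectors constant and equal)
carries an undefined flag and is excluded from summaries, with the count
of contributing pairs recorded per feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .radfeat import FeatureTable, feature_groups

__all__ = ["CCCEntry", "CCCReport", "ccc", "ccc_table", "fraction_high", "grouped_ccc"]


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient of two paired vectors.

    Returns NaN (undefined) when the denominator is zero.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    mx, my = x.mean(), y.mean()
    sx2 = float(np.mean((x - mx) ** 2))  # population moments
    sy2 = float(np.mean((y - my) ** 2))
    sxy = float(np.mean((x - mx) * (y - my)))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        return float("nan")
    return float(2.0 * sxy / denom)


@dataclass
class CCCEntry:
    feature_name: str
    value: float  # NaN when undefined
    n: int

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.value))


@dataclass
class CCCReport:
    comparison: str
    entries: list = field(default_factory=list)
    threshold: float = 0.85

    def _defined(self) -> np.ndarray:
        return np.array([e.value for e in self.entries if e.defined])

    @property
    def n_defined(self) -> int:
        return len(self._defined())

    @property
    def mean(self) -> float:
        return float(self._defined().mean())

    @property
    def sd(self) -> float:
        return float(self._defined().std())

    @property
    def median(self) -> float:
        return float(np.median(self._defined()))

    @property
    def fraction_high(self) -> float:
        return fraction_high(self, self.threshold)

    def values(self) -> pd.Series:
        return pd.Series(
            {e.feature_name: e.value for e in self.entries}, dtype=float
        )

    def summary(self) -> dict:
        return {
            "comparison": self.comparison,
            "mean": self.mean,
            "sd": self.sd,
            "median": self.median,
            "fraction_above_threshold": self.fraction_high,
            "threshold": self.threshold,
            "n_features": len(self.entries),
            "n_defined": self.n_defined,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": [e.feature_name for e in self.entries],
                "ccc": [e.value for e in self.entries],
                "n": [e.n for e in self.entries],
            }
        ).set_index("feature")


def ccc_table(
    a: FeatureTable,
    b: FeatureTable,
    comparison: str = "",
    threshold: float = 0.85,
) -> CCCReport:
    """Per-feature CCC between two feature tables aligned by patient id.

    Patients with an undefined (NaN) value in either table are dropped per
    feature; the number of contributing pairs is recorded in each entry.
    """
    shared_feats = [f for f in a.features if f in set(b.features)]
    if not shared_feats:
        raise ValueError("tables share no features")
    shared_pats = [p for p in a.patients if p in set(b.patients)]
    if len(shared_pats) < 3:
        raise ValueError("tables share fewer than 3 patients")
    da = a.data.loc[shared_pats, shared_feats]
    db = b.data.loc[shared_pats, shared_feats]

    name = comparison or f"{a.setting} vs {b.setting}"
    entries = []
    for feat in shared_feats:
        x = da[feat].to_numpy(dtype=float)
        y = db[feat].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        n = int(ok.sum())
        if n < 3:
            entries.append(CCCEntry(feat, float("nan"), n))
            continue
        entries.append(CCCEntry(feat, ccc(x[ok], y[ok]), n))
    return CCCReport(comparison=name, entries=entries, threshold=threshold)


def fraction_high(report: CCCReport, threshold: float = 0.85) -> float:
    """Fraction of defined entries with CCC strictly above the threshold."""
    vals = np.array([e.value for e in report.entries if e.defined])
    if len(vals) == 0:
        raise ValueError("no defined CCC entries")
    return float((vals > threshold).mean())


def grouped_ccc(report: CCCReport, grouping: dict | None = None) -> pd.DataFrame:
    """Mean defined CCC per feature group, ordered by group id.

    ``grouping`` maps feature name -> group id; defaults to the registry's
    23-group mapping.  An ungrouped reported feature is an error.
    """
    grouping = grouping or feature_groups()
    rows: dict[int, list[float]] = {}
    for e in report.entries:
        if e.feature_name not in grouping:
            raise ValueError(f"feature without group: {e.feature_name}")
        if e.defined:
            rows.setdefault(grouping[e.feature_name], []).append(e.value)
    out = pd.DataFrame(
        {
            "group": sorted(rows),
            "mean_ccc": [float(np.mean(rows[g])) for g in sorted(rows)],
            "n_features": [len(rows[g]) for g in sorted(rows)],
        }
    ).set_index("group")
    out.attrs["comparison"] = report.comparison
    return out
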