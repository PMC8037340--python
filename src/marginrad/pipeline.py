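"""Assembly of the full 76-feature margin vector, cohort normalization and
two-rater reproducibility.

Canonical feature order: 7 three-dimensional shape features, 63 LoG
histogram features (statistic-major, scale-minor), 3 two-dimensional
shape features, 3 fractal features — 76 in total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import fractal as _fractal
from . import loghist as _loghist
from . import shape2d as _shape2d
from . import shape3d as _shape3d
from .io import ImageVolume, ROIMask

__all__ = [
    "FeatureVector",
    "ExtractionError",
    "CATEGORY_COUNTS",
    "canonical_feature_names",
    "feature_category",
    "extract_all",
    "MinMaxNormalizer",
    "minmax_normalize",
    "icc_two_rater",
    "reproducibility_report",
]

CATEGORY_COUNTS = {"shape3d": 7, "log": 63, "shape2d": 3, "fractal": 3}

_SHAPE3D_NAMES = (
    "shape3d.volume", "shape3d.surface_area", "shape3d.sv_ratio",
    "shape3d.sphericity", "shape3d.compactness", "shape3d.convexity",
    "shape3d.max_diameter",
)
_SHAPE2D_NAMES = ("shape2d.roundness_factor", "shape2d.eccentricity", "shape2d.solidity")
_FRACTAL_NAMES = ("fractal.dimension", "fractal.lacunarity", "fractal.fsd_blanket")


def canonical_feature_names() -> list[str]:
    """The 76 feature names in canonical order."""
    log_names = [
        f"log.{stat}_{label}"
        for stat in _loghist.STAT_NAMES
        for label in _loghist.VERSION_LABELS
    ]
    return list(_SHAPE3D_NAMES) + log_names + list(_SHAPE2D_NAMES) + list(_FRACTAL_NAMES)


def feature_category(name: str) -> str:
    return name.split(".", 1)[0]


class ExtractionError(RuntimeError):
    """Strict-mode extraction failure; carries the per-extractor errors."""

    def __init__(self, errors: dict[str, Exception]):
        self.errors = errors
        detail = "; ".join(f"{k}: {v}" for k, v in errors.items())
        super().__init__(f"feature extraction failed in {sorted(errors)} ({detail})")


@dataclass(frozen=True)
class FeatureVector:
    """The 76 named margin characteristics of one subject."""

    values: dict[str, float]
    degenerate: dict[str, bool] = field(default_factory=dict)
    subject_id: str | None = None

    def __post_init__(self):
        expected = canonical_feature_names()
        if list(self.values) != expected:
            raise ValueError("feature vector must carry the 76 canonical names in order")

    @property
    def categories(self) -> dict[str, str]:
        return {name: feature_category(name) for name in self.values}

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {k: 0 for k in CATEGORY_COUNTS}
        for name in self.values:
            counts[feature_category(name)] += 1
        return counts

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.subject_id)


def extract_all(
    volume: ImageVolume,
    mask: ROIMask,
    subject_id: str | None = None,
    strict: bool = True,
) -> FeatureVector:
    """Run all four extractors and assemble the 76-feature vector.

    In strict mode any extractor error aborts with an
    :class:`ExtractionError` listing the offending extractors; in lenient
    mode failed features are emitted as NaN with their degeneracy flag set.
    """
    if volume.shape != mask.shape:
        raise ValueError(f"volume shape {volume.shape} != mask shape {mask.shape}")
    values: dict[str, float] = {}
    flags: dict[str, bool] = {}
    errors: dict[str, Exception] = {}

    try:
        values.update(_shape3d.compute_shape3d(mask).as_dict())
    except Exception as exc:  # noqa: BLE001 - collected and re-raised in strict mode
        errors["shape3d"] = exc
    try:
        log_vals, log_flags = _loghist.compute_log_histogram(volume, mask)
        values.update(log_vals)
        for label, flag in log_flags.items():
            for stat in _loghist.STAT_NAMES:
                flags[f"log.{stat}_{label}"] = flag
    except Exception as exc:  # noqa: BLE001
        errors["log"] = exc
    try:
        values.update(_shape2d.compute_shape2d(mask).as_dict())
    except Exception as exc:  # noqa: BLE001
        errors["shape2d"] = exc
    try:
        ff = _fractal.compute_fractal(volume, mask)
        values.update(ff.as_dict())
        flags["fractal.fsd_blanket"] = ff.degenerate_fsd
    except Exception as exc:  # noqa: BLE001
        errors["fractal"] = exc

    if errors and strict:
        raise ExtractionError(errors)
    ordered = {name: values.get(name, float("nan")) for name in canonical_feature_names()}
    return FeatureVector(values=ordered, degenerate=flags, subject_id=subject_id)


class MinMaxNormalizer(BaseEstimator, TransformerMixin):
    """Per-column min-max normalization to [0, 1] over a cohort table.

    Stores the training (min, max) per column so held-out subjects can be
    transformed with training parameters; held-out values may then fall
    outside [0, 1], which is permitted.  Constant columns map to 0 with a
    warning.

    Parameters
    ----------
    columns : list of str, optional
        Columns to normalize; ``None`` means every numeric column.
    """

    def __init__(self, columns: list[str] | None = None):
        self.columns = columns

    def fit(self, X: pd.DataFrame, y=None) -> "MinMaxNormalizer":
        if len(X) < 2:
            raise ValueError("need at least 2 subjects to fit normalization")
        cols = self.columns if self.columns is not None else list(
            X.select_dtypes(include=[np.number]).columns
        )
        self.columns_ = list(cols)
        self.data_min_ = X[self.columns_].min(axis=0).to_numpy(dtype=float)
        self.data_max_ = X[self.columns_].max(axis=0).to_numpy(dtype=float)
        constant = self.data_max_ - self.data_min_ == 0
        if constant.any():
            names = [c for c, flag in zip(self.columns_, constant) if flag]
            warnings.warn(f"constant columns map to 0 under min-max scaling: {names}")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        span = self.data_max_ - self.data_min_
        safe = np.where(span == 0, 1.0, span)
        vals = (X[self.columns_].to_numpy(dtype=float) - self.data_min_) / safe
        vals[:, span == 0] = 0.0
        out[self.columns_] = vals
        return out


def minmax_normalize(
    cohort: pd.DataFrame, feature_columns: list[str] | None = None
) -> tuple[pd.DataFrame, MinMaxNormalizer]:
    """Fit-and-transform convenience wrapper around :class:`MinMaxNormalizer`."""
    norm = MinMaxNormalizer(columns=feature_columns).fit(cohort)
    return norm.transform(cohort), norm


def icc_two_rater(measurements: np.ndarray) -> float:
    """Two-way random-effects, absolute-agreement, single-rater ICC(2,1).

    ``measurements`` is an (n_subjects, 2) matrix of the same quantity
    scored by two raters.  Computed from the standard two-way ANOVA
    decomposition:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    m = np.asarray(measurements, dtype=np.float64)
    if m.ndim != 2 or m.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) matrix, got {m.shape}")
    n, k = m.shape
    if n < 5:
        raise ValueError(f"need >= 5 subjects, got {n}")
    if not np.all(np.isfinite(m)):
        raise ValueError("measurements must be finite")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_total = ((m - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total == 0:
        raise ValueError("ICC undefined: zero total variance")
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


_ICC_BANDS = (("excellent", 0.8), ("good", 0.6), ("poor", -np.inf))


def _icc_band(icc: float) -> str:
    for name, lo in _ICC_BANDS:
        if icc >= lo:
            return name
    return "poor"


def reproducibility_report(
    cohort_a: pd.DataFrame,
    cohort_b: pd.DataFrame,
    feature_columns: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature two-rater ICC with per-category summaries.

    The two tables must carry the same subjects (same order) and features.
    Band labels follow the reproducibility convention: ICC >= 0.8
    excellent, 0.6-0.799 good, < 0.6 poor.  Returns
    ``(per_feature, per_category)`` tables.
    """
    if feature_columns is None:
        feature_columns = [c for c in cohort_a.columns if c in set(canonical_feature_names())]
        if not feature_columns:
            feature_columns = list(cohort_a.select_dtypes(include=[np.number]).columns)
    if len(cohort_a) != len(cohort_b):
        raise ValueError("paired cohorts must have the same number of subjects")
    missing = [c for c in feature_columns if c not in cohort_b.columns]
    if missing:
        raise ValueError(f"features missing from second cohort: {missing}")

    rows = []
    for feat in feature_columns:
        m = np.column_stack([cohort_a[feat].to_numpy(), cohort_b[feat].to_numpy()])
        icc = icc_two_rater(m)
        rows.append({"feature": feat, "category": feature_category(feat),
                     "icc": icc, "band": _icc_band(icc)})
    per_feature = pd.DataFrame(rows).set_index("feature")

    summaries = []
    for cat, grp in per_feature.groupby("category"):
        summaries.append({
            "category": cat,
            "n_features": len(grp),
            "icc_min": grp["icc"].min(),
            "icc_max": grp["icc"].max(),
            "n_excellent": int((grp["band"] == "excellent").sum()),
            "n_good": int((grp["band"] == "good").sum()),
            "n_poor": int((grp["band"] == "poor").sum()),
        })
    per_category = pd.DataFrame(summaries).set_index("category")
    return per_feature, per_category
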