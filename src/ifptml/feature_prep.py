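"""Feature filtering and standardisation.

Two-step selection: (1) drop columns whose sample variance is below a
threshold (default 0.01); (2) greedily drop the later member of every
column pair with |Pearson r| above a threshold (default 0.97), scanning in
registry order so the outcome is deterministic.  Standardisation is a plain
z-score (population std), fitted once and reapplied verbatim to new rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import StandardScaler

from .pt_engine import FeatureMatrix


class DegenerateMatrixError(ValueError):
    pass


@dataclass
class FilterReport:
    dropped_by_variance: list[str] = field(default_factory=list)
    dropped_by_correlation: list[tuple[str, str, float]] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    thresholds: dict[str, float] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "dropped_by_variance": self.dropped_by_variance,
                "dropped_by_correlation": [
                    [k, d, r] for k, d, r in self.dropped_by_correlation
                ],
                "retained": self.retained,
                "thresholds": self.thresholds,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(payload)
        return payload


def _as_frame(fm) -> pd.DataFrame:
    return fm.df if isinstance(fm, FeatureMatrix) else fm


def _wrap_like(fm, df: pd.DataFrame):
    if isinstance(fm, FeatureMatrix):
        return FeatureMatrix(
            df, {c: fm.provenance.get(c, "?") for c in df.columns},
            fm.fallback_flags,
        )
    return df


class VarianceFilter(BaseEstimator, TransformerMixin):
    """Drop columns with sample variance (ddof=1) strictly below threshold.

    No column is special-cased: f_ref survives iff its variance clears the
    bar like any other column.
    """

    def __init__(self, threshold: float = 0.01):
        self.threshold = threshold

    def fit(self, fm, y=None) -> "VarianceFilter":
        df = _as_frame(fm)
        if not np.isfinite(df.to_numpy()).all():
            raise DegenerateMatrixError("non-finite entries before filtering")
        var = df.var(ddof=1)
        keep = var >= self.threshold
        if not keep.any():
            raise DegenerateMatrixError("variance filter removed every column")
        self.retained_ = [c for c in df.columns if keep[c]]
        self.report_ = FilterReport(
            dropped_by_variance=[c for c in df.columns if not keep[c]],
            retained=list(self.retained_),
            thresholds={"variance": self.threshold},
        )
        return self

    def transform(self, fm):
        df = _as_frame(fm)
        return _wrap_like(fm, df[self.retained_].copy())


class CorrelationFilter(BaseEstimator, TransformerMixin):
    """Greedy de-duplication of near-collinear columns.

    Columns are scanned in their registry order; a column is dropped the
    first time its |Pearson r| with an already-kept column exceeds
    ``r_max``; survivors take part in all later comparisons.
    """

    def __init__(self, r_max: float = 0.97):
        self.r_max = r_max

    def fit(self, fm, y=None) -> "CorrelationFilter":
        df = _as_frame(fm)
        cols = list(df.columns)
        corr = np.corrcoef(df.to_numpy(float), rowvar=False)
        corr = np.atleast_2d(corr)
        kept_idx: list[int] = []
        dropped: list[tuple[str, str, float]] = []
        for j in range(len(cols)):
            clash = None
            for i in kept_idx:
                r = corr[i, j]
                if np.isfinite(r) and abs(r) > self.r_max:
                    clash = (cols[i], cols[j], float(r))
                    break
            if clash is None:
                kept_idx.append(j)
            else:
                dropped.append(clash)
        if not kept_idx:
            raise DegenerateMatrixError("correlation filter removed every column")
        self.retained_ = [cols[j] for j in kept_idx]
        self.report_ = FilterReport(
            dropped_by_correlation=dropped,
            retained=list(self.retained_),
            thresholds={"r_max": self.r_max},
        )
        return self

    def transform(self, fm):
        df = _as_frame(fm)
        return _wrap_like(fm, df[self.retained_].copy())


class FeatureScaler(BaseEstimator, TransformerMixin):
    """Column-wise z-score wrapper keeping DataFrame structure."""

    def __init__(self):
        self._scaler = StandardScaler()

    def fit(self, fm, y=None) -> "FeatureScaler":
        df = _as_frame(fm)
        self.columns_ = list(df.columns)
        self._scaler.fit(df.to_numpy(float))
        if np.any(self._scaler.scale_ == 0):
            bad = [c for c, s in zip(self.columns_, self._scaler.scale_) if s == 0]
            raise DegenerateMatrixError(f"zero-scale column(s): {bad}")
        self.means_ = pd.Series(self._scaler.mean_, index=self.columns_)
        self.scales_ = pd.Series(self._scaler.scale_, index=self.columns_)
        return self

    def transform(self, fm):
        df = _as_frame(fm)
        if list(df.columns) != self.columns_:
            raise DegenerateMatrixError("column mismatch in FeatureScaler")
        out = pd.DataFrame(
            self._scaler.transform(df.to_numpy(float)),
            index=df.index, columns=self.columns_,
        )
        return _wrap_like(fm, out)


def variance_filter(fm, threshold: float = 0.01):
    """Functional form: returns (filtered matrix, FilterReport)."""
    f = VarianceFilter(threshold).fit(fm)
    return f.transform(fm), f.report_


def correlation_filter(fm, r_max: float = 0.97):
    f = CorrelationFilter(r_max).fit(fm)
    return f.transform(fm), f.report_


def standardize(fm, params: FeatureScaler | None = None):
    """Fit-or-apply z-scoring; returns (scaled matrix, fitted scaler)."""
    scaler = params if params is not None else FeatureScaler().fit(fm)
    return scaler.transform(fm), scaler
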