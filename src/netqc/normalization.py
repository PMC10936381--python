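"""Per-sample feature normalization through percentile Winsorization.

Staining intensity features extracted from different tissue cores routinely
live on shifted, stretched scales (fixation and antibody-binding variation).
Winsorization clamps each feature into [P_low, P_high] — by default the 10th
and 90th percentiles of that feature *within that core* — and, by default,
rescales affinely so that P_low maps to 0 and P_high to 1. Anchoring each
core to its own percentiles removes any positive-slope affine difference
between cores exactly, which is what aligns their feature spaces; disabling
the rescale gives textbook Winsorization (pure clamping).

Percentiles use linear interpolation between order statistics (numpy's
default), a convention that matters for small samples and is therefore fixed
and documented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .errors import ValidationError
from .io_tables import FeatureTable


@dataclass(frozen=True)
class WinsorSpec:
    """Winsorization parameters: percentile ranks, rescale and grouping flags."""

    p_low: float = 10.0
    p_high: float = 90.0
    rescale: bool = True
    per_sample: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.p_low < self.p_high <= 100):
            raise ValidationError(
                f"need 0 <= p_low < p_high <= 100, got ({self.p_low}, {self.p_high})"
            )


def winsorize(values: np.ndarray, spec: WinsorSpec = WinsorSpec()) -> np.ndarray:
    """Clamp values into their [p_low, p_high] percentile band, optionally rescale.

    Missing values (NaN) pass through unchanged and are ignored when the
    percentiles are computed. A constant feature (P_low == P_high) maps every
    non-missing value to 0 with a warning.
    """
    arr = np.asarray(values, dtype=float)
    out = arr.copy()
    mask = np.isfinite(arr)
    if mask.sum() < 2:
        raise ValidationError("winsorize needs at least 2 non-missing values")
    lo, hi = np.percentile(arr[mask], [spec.p_low, spec.p_high], method="linear")
    if hi == lo:
        warnings.warn("constant feature: all winsorized values set to 0", stacklevel=2)
        out[mask] = 0.0
        return out
    clamped = np.clip(arr[mask], lo, hi)
    out[mask] = (clamped - lo) / (hi - lo) if spec.rescale else clamped
    return out


def normalize_feature_table(table: FeatureTable, spec: WinsorSpec = WinsorSpec()) -> FeatureTable:
    """Winsorize every feature column, per sample group when ``spec.per_sample``.

    Shape and row order are preserved. A sample group with fewer than 2 rows
    is passed through unchanged with a warning.
    """
    df = table.data.copy()
    if spec.per_sample:
        groups = [idx.to_numpy() for _, idx in df.groupby("sample", sort=False).groups.items()]
    else:
        groups = [df.index.to_numpy()]
    for rows in groups:
        if len(rows) < 2:
            warnings.warn(
                f"sample group with {len(rows)} row(s) passed through un-normalized",
                stacklevel=2,
            )
            continue
        for name in table.feature_names:
            df.loc[rows, name] = winsorize(df.loc[rows, name].to_numpy(), spec)
    return FeatureTable(data=df, feature_names=table.feature_names)


def alignment_report(before: FeatureTable, after: FeatureTable) -> pd.DataFrame:
    """Two-sample Kolmogorov-Smirnov divergence per feature, before vs after.

    Both tables must contain exactly two sample groups. Returns a frame
    indexed by feature with columns ``ks_before``, ``ks_after`` and
    ``improved`` (did the statistic decrease); the fraction of improved
    features is stored in ``DataFrame.attrs["fraction_improved"]``.
    """
    for name, table in (("before", before), ("after", after)):
        if len(table.sample_ids) != 2:
            raise ValidationError(
                f"alignment report needs exactly 2 sample groups, {name} table has "
                f"{len(table.sample_ids)}"
            )
    if before.feature_names != after.feature_names:
        raise ValidationError("before/after tables must share feature columns")

    def _ks(table: FeatureTable, feature: str) -> float:
        s1, s2 = table.sample_ids
        g = table.data.groupby("sample", sort=False)[feature]
        a = g.get_group(s1).dropna().to_numpy()
        b = g.get_group(s2).dropna().to_numpy()
        if len(a) == 0 or len(b) == 0:
            return np.nan
        return float(ks_2samp(a, b).statistic)

    rows = []
    for feature in before.feature_names:
        ks_b = _ks(before, feature)
        ks_a = _ks(after, feature)
        rows.append({"feature": feature, "ks_before": ks_b, "ks_after": ks_a,
                     "improved": bool(ks_a < ks_b)})
    report = pd.DataFrame(rows).set_index("feature")
    report.attrs["fraction_improved"] = float(report["improved"].mean()) if len(report) else np.nan
    return report


def textbook_spec(spec: WinsorSpec = WinsorSpec()) -> WinsorSpec:
    """The same spec with rescaling off (pure clamping Winsorization)."""
    return replace(spec, rescale=False)
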