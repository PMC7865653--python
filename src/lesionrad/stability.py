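"""Inter-reader feature stability and lesion-size confounding.

Features are kept for analysis only when the two readers' per-patient
values agree: intraclass correlation coefficient (two-way random-effects
model, absolute agreement, single measurement — ICC(2,1)) at or above a
threshold, 0.8 by default.  Retained features are additionally screened for
a lesion-size effect by comparing patients whose largest lesion is below
vs at/above 2 cm with the Wilcoxon-Mann-Whitney test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .univariate import wilcoxon_mw

__all__ = ["icc", "stability_filter", "size_effect_screen", "StabilityReport"]


def icc(ratings: np.ndarray, form: str = "icc2") -> float:
    """Intraclass correlation from the two-way ANOVA mean squares.

    Parameters
    ----------
    ratings : (n_subjects, n_raters) array
    form : 'icc2' (two-way random effects, absolute agreement, single
        measurement; the default) or 'icc3' (two-way mixed, consistency).

    The mean squares are computed directly from the crossed layout (no
    model-fitting routine).  Returns NaN when the total variance is zero
    (agreement undefined).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("ratings must be subjects x raters with >= 2 raters")
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if not np.isfinite(x).all():
        raise ValueError("ratings must be finite")
    grand = x.mean()
    if np.allclose(x, grand):
        return float("nan")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = (resid**2).sum() / ((n - 1) * (k - 1))
    if form == "icc2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "icc3":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC form {form!r}")
    if denom == 0:
        return float("nan")
    return float((msr - mse) / denom)


@dataclass
class StabilityReport:
    """Per-feature ICCs, the retained (stable) set, and screen outcomes."""

    icc_values: pd.Series
    threshold: float
    retained: list[str]
    form: str = "icc2"
    size_effect_p: pd.Series | None = None
    size_flagged: list[str] = field(default_factory=list)

    @property
    def stable_flags(self) -> pd.Series:
        return self.icc_values >= self.threshold

    @property
    def retained_icc_median(self) -> float:
        return float(self.icc_values[self.retained].median())

    @property
    def retained_icc_range(self) -> tuple[float, float]:
        vals = self.icc_values[self.retained]
        return float(vals.min()), float(vals.max())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"icc": self.icc_values})
        df["stable"] = self.stable_flags
        if self.size_effect_p is not None:
            df["size_effect_p"] = self.size_effect_p
        return df


def stability_filter(
    features_r1: pd.DataFrame,
    features_r2: pd.DataFrame,
    threshold: float = 0.8,
    form: str = "icc2",
) -> StabilityReport:
    """Retain features whose two-reader ICC is at least ``threshold``.

    Both tables must be patients x features with identical columns; rows
    are aligned on the patient index.  Features whose ICC is undefined
    (zero variance) are not retained.
    """
    if set(features_r1.columns) != set(features_r2.columns):
        raise ValueError("the two readers must provide the same features")
    common = features_r1.index.intersection(features_r2.index)
    r1 = features_r1.loc[common]
    r2 = features_r2.loc[common, r1.columns]
    iccs = {}
    for name in r1.columns:
        pair = np.column_stack([r1[name].to_numpy(), r2[name].to_numpy()])
        ok = np.isfinite(pair).all(axis=1)
        iccs[name] = icc(pair[ok], form=form) if ok.sum() >= 3 else float("nan")
    icc_s = pd.Series(iccs)
    retained = [name for name, v in icc_s.items() if np.isfinite(v) and v >= threshold]
    return StabilityReport(icc_values=icc_s, threshold=threshold, retained=retained, form=form)


def size_effect_screen(
    features: pd.DataFrame,
    max_diameter_mm: pd.Series,
    cut_mm: float = 20.0,
    alpha: float = 0.05,
) -> pd.Series:
    """Wilcoxon p per feature between small-lesion and large-lesion patients.

    Groups are patients whose largest lesion equivalent diameter is below
    ``cut_mm`` vs at/above it.  Returns NaN for every feature (with a
    warning) when either group has fewer than 2 patients.
    """
    import warnings

    sizes = max_diameter_mm.loc[features.index]
    small = features.index[sizes < cut_mm]
    large = features.index[sizes >= cut_mm]
    if len(small) < 2 or len(large) < 2:
        warnings.warn(
            "size-effect screen skipped: a size group has fewer than 2 patients",
            stacklevel=2,
        )
        return pd.Series(float("nan"), index=features.columns)
    out = {}
    for name in features.columns:
        a = features.loc[small, name].dropna().to_numpy()
        b = features.loc[large, name].dropna().to_numpy()
        out[name] = wilcoxon_mw(a, b).p_value if len(a) and len(b) else float("nan")
    return pd.Series(out)


def attach_size_screen(
    report: StabilityReport,
    features: pd.DataFrame,
    max_diameter_mm: pd.Series,
    cut_mm: float = 20.0,
    alpha: float = 0.05,
) -> StabilityReport:
    """Run the size screen on the retained features and record flags."""
    p = size_effect_screen(features[report.retained], max_diameter_mm, cut_mm=cut_mm)
    report.size_effect_p = p
    report.size_flagged = [name for name, v in p.items() if np.isfinite(v) and v <= alpha]
    return report
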