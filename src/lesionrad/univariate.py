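"""Per-feature two-group testing and ROC characterization.

Each feature is compared between classes with the Wilcoxon-Mann-Whitney
test (exact by enumeration at small sample sizes, normal approximation with
tie correction otherwise), characterized by its empirical ROC curve with a
Youden-index cut-off and the associated sensitivity / specificity /
predictive values / accuracy, and the p-values are adjusted across features
by the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MannWhitneyResult",
    "wilcoxon_mw",
    "RocSummary",
    "roc_with_youden",
    "fdr_adjust",
    "univariate_table",
    "EXACT_MAX_N",
]

# full enumeration of group assignments is used up to this combined n;
# beyond it the normal approximation with midrank tie correction applies
EXACT_MAX_N = 12


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # U statistic of the first group (midrank convention)
    p_value: float
    exact: bool


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def wilcoxon_mw(group_a: np.ndarray, group_b: np.ndarray) -> MannWhitneyResult:
    """Two-sided Wilcoxon-Mann-Whitney test with midrank tie handling.

    For combined samples of at most ``EXACT_MAX_N`` the two-sided p-value is
    computed by full enumeration of all group assignments (valid under
    ties); larger samples use the normal approximation with tie-corrected
    variance and continuity correction.  If every value is tied across both
    groups, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs at least one value")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    u_obs = _u_statistic(ranks[:n_a], n_a)
    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(u=u_obs, p_value=1.0, exact=True)
    n = n_a + n_b
    if n <= EXACT_MAX_N:
        center = n_a * n_b / 2.0
        dev_obs = abs(u_obs - center)
        count = 0
        total = 0
        idx = np.arange(n)
        for comb in combinations(idx, n_a):
            u = _u_statistic(ranks[list(comb)], n_a)
            total += 1
            if abs(u - center) >= dev_obs - 1e-12:
                count += 1
        return MannWhitneyResult(u=u_obs, p_value=count / total, exact=True)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(u=float(res.statistic), p_value=float(res.pvalue), exact=False)


@dataclass
class RocSummary:
    """ROC characterization of one feature at its Youden-optimal cut-off."""

    feature: str
    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    p_value: float = float("nan")
    p_adjusted: float = float("nan")
    orientation: str = "high"  # 'high': larger values called positive
    significant: bool = False

    def as_row(self) -> dict:
        return {
            "feature": self.feature,
            "auc": self.auc,
            "auc_ci_low": self.auc_ci[0],
            "auc_ci_high": self.auc_ci[1],
            "cutoff": self.cutoff,
            "sen": self.sensitivity,
            "spec": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "acc": self.accuracy,
            "p_value": self.p_value,
            "p_adjusted": self.p_adjusted,
            "orientation": self.orientation,
            "significant": self.significant,
        }


def _delong_auc_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from the placement values."""
    m, n = len(pos), len(neg)
    # midrank placements
    v10 = np.empty(m)
    v01 = np.empty(n)
    for i, x in enumerate(pos):
        v10[i] = (np.sum(x > neg) + 0.5 * np.sum(x == neg)) / n
    for j, y in enumerate(neg):
        v01[j] = (np.sum(pos > y) + 0.5 * np.sum(pos == y)) / m
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_with_youden(
    values: np.ndarray,
    labels: np.ndarray,
    feature: str = "",
    ci_method: str = "delong",
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> RocSummary:
    """Empirical ROC with Youden-index cut-off and 95% AUC CI.

    The ROC is oriented so AUC >= 0.5 (the orientation — whether high or
    low values are called positive — is recorded).  The cut-off is the
    observed value maximizing J = SEN + SPEC - 1; among ties the threshold
    with the higher specificity wins.  Positivity is ``value >= cutoff``
    under 'high' orientation (``value <= cutoff`` under 'low').
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("need both classes present, labels coded 0/1")
    pos, neg = x[y == 1], x[y == 0]
    auc_raw, _ = _delong_auc_variance(pos, neg)
    orientation = "high"
    xo = x
    if auc_raw < 0.5:
        orientation = "low"
        xo = -x
        pos, neg = -pos, -neg
    auc, var = _delong_auc_variance(pos, neg)
    if ci_method == "delong":
        z = stats.norm.ppf(0.975)
        half = z * np.sqrt(var)
        ci = (max(0.0, auc - half), min(1.0, auc + half))
    elif ci_method == "bootstrap":
        rng = rng or np.random.default_rng(0)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            pb = rng.choice(pos, size=len(pos), replace=True)
            nb = rng.choice(neg, size=len(neg), replace=True)
            reps[b], _ = _delong_auc_variance(pb, nb)
        ci = (float(np.quantile(reps, 0.025)), float(np.quantile(reps, 0.975)))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    # Youden scan over all observed thresholds (oriented values)
    best = None
    for t in np.unique(xo):
        pred = xo >= t
        tp = int(np.sum(pred & (y == 1)))
        fn = int(np.sum(~pred & (y == 1)))
        tn = int(np.sum(~pred & (y == 0)))
        fp = int(np.sum(pred & (y == 0)))
        sen = tp / (tp + fn)
        spec = tn / (tn + fp)
        j = sen + spec - 1.0
        key = (j, spec)
        if best is None or key > best[0]:
            best = (key, t, tp, fn, tn, fp, sen, spec)
    _, t, tp, fn, tn, fp, sen, spec = best
    ppv = tp / (tp + fp) if (tp + fp) else float("nan")
    npv = tn / (tn + fn) if (tn + fn) else float("nan")
    acc = (tp + tn) / len(y)
    cutoff = float(t if orientation == "high" else -t)
    return RocSummary(
        feature=feature,
        auc=auc,
        auc_ci=ci,
        cutoff=cutoff,
        sensitivity=sen,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        accuracy=acc,
        orientation=orientation,
    )


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def univariate_table(
    features: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.05,
    ci_method: str = "delong",
) -> pd.DataFrame:
    """Per-feature ROC summary table with raw and BH-adjusted p-values.

    One row per feature: AUC (95% CI), Youden cut-off, SEN/SPEC/PPV/NPV/ACC
    at the cut-off, Wilcoxon-Mann-Whitney p, FDR-adjusted p and the
    significance flag (adjusted p < alpha).
    """
    y = labels.loc[features.index].to_numpy(dtype=int)
    rows: list[RocSummary] = []
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        ok = np.isfinite(x)
        summ = roc_with_youden(x[ok], y[ok], feature=name, ci_method=ci_method)
        summ.p_value = wilcoxon_mw(x[ok][y[ok] == 1], x[ok][y[ok] == 0]).p_value
        rows.append(summ)
    padj = fdr_adjust([r.p_value for r in rows])
    for r, pa in zip(rows, padj):
        r.p_adjusted = float(pa)
        r.significant = bool(pa < alpha)
    return pd.DataFrame([r.as_row() for r in rows]).set_index("feature")
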