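"""Empirical ROC analysis, Youden-optimal cut-offs and diagnostic metrics.

The AUC is computed as the Mann-Whitney pairwise-concordance probability
(ties half-weighted), identical to the trapezoidal area under the empirical
ROC curve.  Its standard error uses the Hanley-McNeil rank-based formula by
default, with DeLong's structural-component estimator as an option; the 95%
confidence interval is Wald, clipped to [0, 1].

Screening direction is fixed: a higher index value indicates disease, and a
record is classified positive when ``score >= cutoff``.  Candidate cut-offs
are the midpoints between consecutive distinct observed values, plus -inf
and +inf sentinels; the optimum maximises the Youden index
J = sensitivity + specificity - 1.  When several candidates tie on J, the
one with the higher sensitivity wins (screening favours sensitivity), then
the lower cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from metscreen.indices import INDEX_NAMES

__all__ = [
    "auc_mann_whitney",
    "roc_curve_points",
    "diagnostic_metrics",
    "metrics_from_rates",
    "youden_optimal_cutpoint",
    "run_roc_battery",
    "accuracy_band",
    "CutpointResult",
    "DiagnosticMetrics",
]


def _check_two_classes(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC analysis requires both classes present")
    return n_pos, n_neg


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if np.any(np.isnan(scores)):
        raise ValueError("scores contain NaN; drop missing values first")
    return scores, labels


def auc_mann_whitney(
    scores, labels, se_method: str = "hanley"
) -> tuple[float, float, tuple[float, float]]:
    """AUC with standard error and 95% CI.

    Parameters
    ----------
    scores
        Index values; higher means more disease-like.
    labels
        Boolean disease status.
    se_method
        ``"hanley"`` (default) or ``"delong"``.

    Returns
    -------
    (auc, se, (ci_lo, ci_hi))
    """
    scores, labels = _as_arrays(scores, labels)
    n_pos, n_neg = _check_two_classes(labels)
    ranks = rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    if se_method == "hanley":
        q1 = auc / (2.0 - auc)
        q2 = 2.0 * auc**2 / (1.0 + auc)
        var = (
            auc * (1.0 - auc)
            + (n_pos - 1) * (q1 - auc**2)
            + (n_neg - 1) * (q2 - auc**2)
        ) / (n_pos * n_neg)
        se = float(np.sqrt(max(var, 0.0)))
    elif se_method == "delong":
        pos = scores[labels]
        neg = scores[~labels]
        # placement values via midranks of the pooled sample
        all_ranks = rankdata(np.concatenate([pos, neg]))
        pos_ranks = rankdata(pos)
        neg_ranks = rankdata(neg)
        v10 = (all_ranks[:n_pos] - pos_ranks) / n_neg
        v01 = 1.0 - (all_ranks[n_pos:] - neg_ranks) / n_pos
        s10 = np.var(v10, ddof=1) if n_pos > 1 else 0.0
        s01 = np.var(v01, ddof=1) if n_neg > 1 else 0.0
        se = float(np.sqrt(s10 / n_pos + s01 / n_neg))
    else:
        raise ValueError(f"unknown se_method {se_method!r}")

    lo = max(0.0, auc - 1.96 * se)
    hi = min(1.0, auc + 1.96 * se)
    return float(auc), se, (lo, hi)


def roc_curve_points(scores, labels) -> pd.DataFrame:
    """The empirical ROC curve as a table of operating points.

    One row per candidate cut-off (descending, with +/-inf sentinels) with
    ``cutoff, sens, spec``.  Sensitivity and the false-positive rate are
    non-decreasing as the cut-off decreases; the curve runs from (0, 0) to
    (1, 1) in ROC space.
    """
    scores, labels = _as_arrays(scores, labels)
    n_pos, n_neg = _check_two_classes(labels)
    cutoffs = candidate_cutoffs(scores)[::-1]  # descending
    pos_sorted = np.sort(scores[labels])
    neg_sorted = np.sort(scores[~labels])
    tp = n_pos - np.searchsorted(pos_sorted, cutoffs, side="left")
    fp = n_neg - np.searchsorted(neg_sorted, cutoffs, side="left")
    return pd.DataFrame(
        {
            "cutoff": cutoffs,
            "sens": tp / n_pos,
            "spec": 1.0 - fp / n_neg,
        }
    )


def candidate_cutoffs(scores) -> np.ndarray:
    """Ascending candidate thresholds: -inf, inter-value midpoints, +inf."""
    distinct = np.unique(np.asarray(scores, float))
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate([[-np.inf], mids, [np.inf]])


@dataclass
class DiagnosticMetrics:
    """2x2-table screening metrics at a fixed cut-off.

    Ratios whose denominator is an empty cell are ``None`` (undefined),
    never silent NaN.
    """

    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None
    lr_pos: float | None
    lr_neg: float | None
    youden_j: float


def diagnostic_metrics(scores, labels, cutoff: float) -> DiagnosticMetrics:
    """Evaluate the rule ``score >= cutoff -> predicted positive``."""
    scores, labels = _as_arrays(scores, labels)
    n_pos, n_neg = _check_two_classes(labels)
    predicted = scores >= cutoff
    tp = int((predicted & labels).sum())
    fp = int((predicted & ~labels).sum())
    fn = n_pos - tp
    tn = n_neg - fp
    sens = tp / n_pos
    spec = tn / n_neg
    return DiagnosticMetrics(
        sensitivity=sens,
        specificity=spec,
        ppv=tp / (tp + fp) if tp + fp > 0 else None,
        npv=tn / (tn + fn) if tn + fn > 0 else None,
        lr_pos=sens / (1.0 - spec) if spec < 1.0 else None,
        lr_neg=(1.0 - sens) / spec if spec > 0.0 else None,
        youden_j=sens + spec - 1.0,
    )


def metrics_from_rates(sens: float, spec: float) -> dict[str, float | None]:
    """Youden J and likelihood ratios from sensitivity and specificity alone.

    Useful for re-deriving the arithmetic identities of a published
    diagnostic table row without the underlying scores.
    """
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    return {
        "youden_j": sens + spec - 1.0,
        "lr_pos": sens / (1.0 - spec) if spec < 1.0 else None,
        "lr_neg": (1.0 - sens) / spec if spec > 0.0 else None,
    }


def accuracy_band(auc: float) -> str:
    """Discriminative-accuracy band: >0.9 high, 0.7-0.9 moderate,
    >0.5-0.7 low, otherwise chance."""
    if auc > 0.9:
        return "high"
    if auc >= 0.7:
        return "moderate"
    if auc > 0.5:
        return "low"
    return "chance"


@dataclass
class CutpointResult:
    """Per-index, per-stratum ROC summary row."""

    index_name: str
    sex_stratum: str
    auc: float
    auc_se: float
    auc_ci95: tuple[float, float]
    optimal_cutoff: float
    youden_j: float
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None
    lr_pos: float | None
    lr_neg: float | None
    accuracy_band: str

    def as_row(self) -> dict:
        d = asdict(self)
        lo, hi = d.pop("auc_ci95")
        d["auc_ci_lo"] = lo
        d["auc_ci_hi"] = hi
        return d


def youden_optimal_cutpoint(
    scores,
    labels,
    index_name: str = "",
    sex_stratum: str = "",
    se_method: str = "hanley",
) -> CutpointResult:
    """Find the cut-off maximising J = sensitivity + specificity - 1."""
    scores, labels = _as_arrays(scores, labels)
    n_pos, n_neg = _check_two_classes(labels)

    cutoffs = candidate_cutoffs(scores)
    pos_sorted = np.sort(scores[labels])
    neg_sorted = np.sort(scores[~labels])
    sens = (n_pos - np.searchsorted(pos_sorted, cutoffs, side="left")) / n_pos
    spec = np.searchsorted(neg_sorted, cutoffs, side="left") / n_neg
    j = sens + spec - 1.0

    best = j == j.max()
    best &= sens == sens[best].max()
    idx = np.flatnonzero(best)[0]  # cutoffs ascending -> first = lowest
    cutoff = float(cutoffs[idx])

    auc, se, ci = auc_mann_whitney(scores, labels, se_method=se_method)
    m = diagnostic_metrics(scores, labels, cutoff)
    return CutpointResult(
        index_name=index_name,
        sex_stratum=sex_stratum,
        auc=auc,
        auc_se=se,
        auc_ci95=ci,
        optimal_cutoff=cutoff,
        youden_j=m.youden_j,
        sensitivity=m.sensitivity,
        specificity=m.specificity,
        ppv=m.ppv,
        npv=m.npv,
        lr_pos=m.lr_pos,
        lr_neg=m.lr_neg,
        accuracy_band=accuracy_band(auc),
    )


def run_roc_battery(
    cohort: pd.DataFrame,
    panels: pd.DataFrame,
    mets_flags: pd.Series,
    index_names: tuple[str, ...] = INDEX_NAMES,
) -> pd.DataFrame:
    """ROC battery: one row per index per sex, ranked by AUC within sex.

    Records with a missing value for an index are excluded from that index's
    curve only (``n_missing`` column).  A stratum where the analysis cannot
    run (no records, or a single outcome class) yields an error row with NaN
    statistics and the reason in ``error``.
    """
    if not cohort.index.equals(panels.index) or not cohort.index.equals(mets_flags.index):
        raise ValueError("cohort, panels and mets flags must be aligned by record id")
    rows = []
    for sex in ("male", "female"):
        mask = (cohort["sex"] == sex).to_numpy()
        labels_all = mets_flags.to_numpy(bool)[mask]
        for name in index_names:
            values = panels[name].to_numpy(float)[mask]
            keep = ~np.isnan(values)
            n_missing = int((~keep).sum())
            try:
                res = youden_optimal_cutpoint(
                    values[keep], labels_all[keep], index_name=name, sex_stratum=sex
                )
                row = res.as_row()
                row.update(n=int(keep.sum()), n_missing=n_missing, error="")
            except ValueError as err:
                row = {
                    "index_name": name,
                    "sex_stratum": sex,
                    "n": int(keep.sum()),
                    "n_missing": n_missing,
                    "error": str(err),
                }
            rows.append(row)
    table = pd.DataFrame(rows)
    table["auc_rank"] = table.groupby("sex_stratum")["auc"].rank(
        ascending=False, method="min"
    )
    return table
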