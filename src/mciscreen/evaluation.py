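"""Screening-style evaluation: confusion metrics, cutoff sweeps, ROC/AUC.

A predicted probability is classified positive when it is >= the cutoff.
Undefined ratios (0/0) are reported as NaN, never silently substituted with
zero.  The AUC is the Mann-Whitney rank statistic (ties at midrank), which
equals the trapezoidal area under the empirical ROC curve; its confidence
interval comes from a stratified bootstrap by default, with the DeLong
closed form available as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

DEFAULT_CUTOFFS = (0.3, 0.4, 0.5, 0.6)


@dataclass(frozen=True)
class CutoffMetrics:
    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f1: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class RocResult:
    points: np.ndarray  # (1 - specificity, sensitivity) pairs, ordered
    auc: float
    ci_low: float
    ci_high: float


def _ratio(num: int, den: int) -> float:
    return num / den if den else math.nan


def _check(probs, labels) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels)
    if p.size == 0:
        raise ValueError("empty input")
    if p.shape != y.shape:
        raise ValueError("probs and labels must have the same length")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return p, y.astype(int)


def confusion_at_cutoff(probs, labels, cutoff: float) -> CutoffMetrics:
    """Counts and screening metrics classifying positive at prob >= cutoff."""
    p, y = _check(probs, labels)
    pred = p >= cutoff
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    f1 = f1_from_ppv_sensitivity(ppv, sens)
    return CutoffMetrics(cutoff, tp, fp, tn, fn, sens, spec, ppv, npv, f1)


def f1_from_ppv_sensitivity(ppv: float, sensitivity: float) -> float:
    """Harmonic mean of PPV (precision) and sensitivity (recall)."""
    if math.isnan(ppv) or math.isnan(sensitivity):
        return math.nan
    if ppv + sensitivity == 0:
        return math.nan
    return 2 * ppv * sensitivity / (ppv + sensitivity)


def cutoff_sweep(
    probs, labels, cutoffs: Sequence[float] = DEFAULT_CUTOFFS
) -> pd.DataFrame:
    """One metrics row per cutoff (the operating-point table of a screening test)."""
    rows = []
    for c in cutoffs:
        m = confusion_at_cutoff(probs, labels, c)
        rows.append(
            {
                "cutoff": c, "sensitivity": m.sensitivity, "specificity": m.specificity,
                "ppv": m.ppv, "npv": m.npv, "f1": m.f1,
                "tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn,
            }
        )
    return pd.DataFrame(rows)


def _delong_ci(p: np.ndarray, y: np.ndarray, alpha: float) -> tuple[float, float]:
    # DeLong variance of the Mann-Whitney AUC via placement values
    pos, neg = p[y == 1], p[y == 0]
    m, n = len(pos), len(neg)
    v10 = np.array([(np.sum(x > neg) + 0.5 * np.sum(x == neg)) / n for x in pos])
    v01 = np.array([(np.sum(pos > x) + 0.5 * np.sum(pos == x)) / m for x in neg])
    auc = v10.mean()
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(var)
    return max(0.0, auc - half), min(1.0, auc + half)


def roc_auc(
    probs,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
    ci_method: str = "bootstrap",
    alpha: float = 0.05,
) -> RocResult:
    """Empirical ROC points and Mann-Whitney AUC with a confidence interval.

    ``ci_method="bootstrap"`` resamples positives and negatives separately
    (class-stratified, ``n_boot`` replicates, percentile interval);
    ``"delong"`` uses the asymptotic closed form.
    """
    p, y = _check(probs, labels)
    if y.min() == y.max():
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, _ = roc_curve(y, p)
    auc = float(roc_auc_score(y, p))
    if ci_method == "delong":
        lo, hi = _delong_ci(p, y, alpha)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos, neg = p[y == 1], p[y == 0]
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            bp = rng.choice(pos, size=len(pos), replace=True)
            bn = rng.choice(neg, size=len(neg), replace=True)
            bl = np.concatenate([np.ones(len(bp), dtype=int), np.zeros(len(bn), dtype=int)])
            aucs[b] = roc_auc_score(bl, np.concatenate([bp, bn]))
        lo, hi = (
            float(np.quantile(aucs, alpha / 2)),
            float(np.quantile(aucs, 1 - alpha / 2)),
        )
    else:
        raise ValueError(f"unknown ci_method: {ci_method!r}")
    return RocResult(points=np.column_stack([fpr, tpr]), auc=auc, ci_low=lo, ci_high=hi)


def ppv_npv_at_prevalence(
    sensitivity: float, specificity: float, prevalence: float
) -> tuple[float, float]:
    """Bayes-rule predictive values of a test applied at a given prevalence.

    PPV rises and NPV falls as prevalence increases for any fixed
    sensitivity/specificity; degenerate denominators yield NaN.
    """
    for name, v in (
        ("sensitivity", sensitivity), ("specificity", specificity), ("prevalence", prevalence)
    ):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    ppv_den = sensitivity * prevalence + (1 - specificity) * (1 - prevalence)
    npv_den = specificity * (1 - prevalence) + (1 - sensitivity) * prevalence
    ppv = sensitivity * prevalence / ppv_den if ppv_den > 0 else math.nan
    npv = specificity * (1 - prevalence) / npv_den if npv_den > 0 else math.nan
    return ppv, npv


def plot_roc(results: dict[str, RocResult], path=None):
    """Overlay ROC curves for several cohorts (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, r in results.items():
        ax.plot(r.points[:, 0], r.points[:, 1],
                label=f"{name}: AUC = {r.auc:.3f} ({r.ci_low:.3f}, {r.ci_high:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
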