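"""Statistical evaluation of frame classification and onset calling.

Implements the full evaluation protocol: confusion-matrix metrics
(positive class = after-onset), ROC/AUC, percentile-bootstrap confidence
intervals (default 1000 replicates, 95%), a two-tailed two-proportion
z-test, a two-sided Wilcoxon matched-pairs signed-rank test (exact
sign-flip enumeration for small samples), Pearson correlation, and
majority aggregation of multiple raters with a seeded fair-coin
tie-break.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve, roc_auc_score

__all__ = [
    "EvalConfig",
    "EvalReport",
    "confusion_metrics",
    "roc_auc",
    "bootstrap_ci",
    "two_proportion_ztest",
    "wilcoxon_signed_rank",
    "pearson_corr",
    "aggregate_raters",
    "evaluate_frames",
]


@dataclass
class EvalConfig:
    n_bootstrap: int = 1000
    ci_level: float = 95.0
    seed: int = 0

    def __post_init__(self):
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not 0 < self.ci_level < 100:
            raise ValueError("ci_level must be in (0, 100)")


@dataclass
class EvalReport:
    """Aggregated frame-level and onset-level evaluation results."""

    n_frames: int = 0
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    accuracy: float = np.nan
    sensitivity: float = np.nan
    specificity: float = np.nan
    auc: float = np.nan
    ci: dict = field(default_factory=dict)  # metric -> (lo, hi)
    tests: dict = field(default_factory=dict)  # name -> {"stat":..,"p":..}
    pearson_rho: float = np.nan
    time_discrepancies_s: dict = field(default_factory=dict)  # id -> seconds

    def to_dict(self) -> dict:
        return asdict(self)


def _binary(a):
    arr = np.asarray(a)
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return arr.astype(int)


def confusion_metrics(pred_labels, true_labels) -> EvalReport:
    """Confusion counts plus accuracy / sensitivity / specificity
    (positive class = after-onset = 1)."""
    pred = _binary(pred_labels)
    true = _binary(true_labels)
    if pred.shape != true.shape:
        raise ValueError("prediction and truth lengths differ")
    tp = int(np.sum((pred == 1) & (true == 1)))
    fp = int(np.sum((pred == 1) & (true == 0)))
    tn = int(np.sum((pred == 0) & (true == 0)))
    fn = int(np.sum((pred == 0) & (true == 1)))
    n = pred.size

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)")
            return float("nan")
        return num / den

    return EvalReport(
        n_frames=n,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=ratio(tp + tn, n, "accuracy"),
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
    )


def roc_auc(scores, true_labels):
    """ROC curve (threshold sweep over the after-onset probability) and
    AUC (Mann–Whitney concordance, ties counted 1/2)."""
    true = _binary(true_labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(true)) < 2:
        raise ValueError("ROC needs both classes in the truth labels")
    fpr, tpr, thresholds = _sk_roc_curve(true, scores)
    auc = float(roc_auc_score(true, scores))
    return np.column_stack([fpr, tpr]), auc


def bootstrap_ci(values, cfg: EvalConfig | None = None, statistic=np.mean):
    """Percentile bootstrap confidence interval for ``statistic`` over
    the item vector (resampled with replacement, B replicates)."""
    cfg = cfg or EvalConfig()
    arr = np.asarray(values)
    if arr.size == 0:
        raise ValueError("bootstrap_ci needs at least one item")
    rng = np.random.default_rng(cfg.seed)
    idx = rng.integers(0, arr.size, size=(cfg.n_bootstrap, arr.size))
    reps = np.apply_along_axis(statistic, 1, arr[idx])
    alpha = (100.0 - cfg.ci_level) / 2.0
    lo, hi = np.percentile(reps, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int):
    """Two-tailed z-test of two population proportions with pooled
    variance: z = (p1-p2)/sqrt(p(1-p)(1/n1+1/n2))."""
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1 or not 0 <= x <= n:
            raise ValueError("need 0 <= successes <= trials, trials >= 1")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn("pooled proportion is degenerate; z undefined")
        return float("nan"), float("nan")
    z = (p1 - p2) / np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def wilcoxon_signed_rank(differences, exact_max_n: int = 15):
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped; absolute differences are ranked with
    mid-ranks for ties; the reported statistic is W = min(W+, W-).  The
    p-value is computed by exact enumeration of all 2^n sign
    assignments for n <= exact_max_n, otherwise by the normal
    approximation with tie correction.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= exact_max_n:
        # all 2^n sign assignments of the rank vector
        signs = ((np.arange(1 << n)[:, None] >> np.arange(n)) & 1).astype(float)
        wplus_all = signs @ ranks
        wmin_all = np.minimum(wplus_all, ranks.sum() - wplus_all)
        p = float(np.mean(wmin_all <= w + 1e-12))
    else:
        mean = n * (n + 1) / 4.0
        tie_counts = np.unique(ranks, return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
            tie_counts**3 - tie_counts
        ) / 48.0
        z = (w_plus - mean) / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return w, min(p, 1.0)


def pearson_corr(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need two equal-length series of length >= 2")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson correlation undefined for constant series")
    return float(stats.pearsonr(x, y).statistic)


def aggregate_raters(label_matrix, seed: int = 0) -> np.ndarray:
    """Per-frame majority vote over raters (rows); exact ties are
    resolved by a seeded fair coin."""
    mat = np.asarray(label_matrix)
    if mat.ndim != 2:
        raise ValueError("label matrix must be raters x frames")
    mat = _binary(mat)
    votes = mat.sum(axis=0)
    n_raters = mat.shape[0]
    out = (2 * votes > n_raters).astype(int)
    ties = np.flatnonzero(2 * votes == n_raters)
    if ties.size:
        rng = np.random.default_rng(seed)
        out[ties] = rng.integers(0, 2, size=ties.size)
    return out


def evaluate_frames(
    scores, pred_labels, true_labels, cfg: EvalConfig | None = None
) -> EvalReport:
    """Full frame-level report: confusion metrics, AUC, and percentile
    bootstrap CIs (resampling frames) for each metric."""
    cfg = cfg or EvalConfig()
    report = confusion_metrics(pred_labels, true_labels)
    scores = np.asarray(scores, dtype=float)
    pred = _binary(pred_labels)
    true = _binary(true_labels)
    if len(np.unique(true)) == 2:
        _, report.auc = roc_auc(scores, true)
    rng = np.random.default_rng(cfg.seed)
    n = true.size
    reps = {"accuracy": [], "sensitivity": [], "specificity": [], "auc": []}
    for _ in range(cfg.n_bootstrap):
        idx = rng.integers(0, n, size=n)
        p, t, s = pred[idx], true[idx], scores[idx]
        reps["accuracy"].append(np.mean(p == t))
        pos, neg = t == 1, t == 0
        reps["sensitivity"].append(np.mean(p[pos] == 1) if pos.any() else np.nan)
        reps["specificity"].append(np.mean(p[neg] == 0) if neg.any() else np.nan)
        reps["auc"].append(
            roc_auc_score(t, s) if 0 < t.sum() < n else np.nan
        )
    alpha = (100.0 - cfg.ci_level) / 2.0
    for name, vals in reps.items():
        vals = np.asarray(vals, float)
        vals = vals[np.isfinite(vals)]
        if vals.size:
            lo, hi = np.percentile(vals, [alpha, 100.0 - alpha])
            report.ci[name] = (float(lo), float(hi))
    point = {
        "accuracy": report.accuracy,
        "sensitivity": report.sensitivity,
        "specificity": report.specificity,
        "auc": report.auc,
    }
    for name, (lo, hi) in report.ci.items():
        if np.isfinite(point[name]) and not lo <= point[name] <= hi:
            warnings.warn(
                f"percentile CI for {name} does not cover the point estimate"
            )
    return report
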