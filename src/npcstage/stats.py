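"""Classification metrics and the study's statistical test battery.

Covers: exact (Clopper-Pearson) binomial confidence intervals;
accuracy / macro-averaged sensitivity and specificity from a 4x4
confusion table; one-vs-rest micro / macro ROC-AUC; DeLong's test for
correlated AUCs; McNemar's test for paired accuracies; the Wilcoxon
matched-pairs signed-rank test; the Mann-Whitney U test; and Pearson's
chi-square test for contingency tables.  Scipy / scikit-learn /
statsmodels provide the standard machinery; DeLong's structural-
component covariance is implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

__all__ = [
    "BinomialCI",
    "ConfusionTable",
    "TestResult",
    "clopper_pearson",
    "confusion_table",
    "acc_sen_spe",
    "group_accuracy",
    "roc_auc_ovr",
    "delong_test",
    "mcnemar_test",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "chi_square_test",
]

N_STAGES = 4


@dataclass(frozen=True)
class BinomialCI:
    successes: int
    trials: int
    level: float
    lower: float
    upper: float

    @property
    def proportion(self) -> float:
        return self.successes / self.trials


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: int
    df: int | None = None


def clopper_pearson(k: int, n: int, level: float = 0.95) -> BinomialCI:
    """Exact binomial CI from beta quantiles; lower=0 at k=0, upper=1 at k=n."""
    if not (0 <= k <= n) or n <= 0:
        raise ValueError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    if not (0 < level < 1):
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return BinomialCI(successes=k, trials=n, level=level, lower=lower, upper=upper)


@dataclass(frozen=True)
class ConfusionTable:
    """4x4 stage confusion counts; rows true stage, columns predicted."""

    counts: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.counts, dtype=int)
        if arr.shape != (N_STAGES, N_STAGES) or (arr < 0).any():
            raise ValueError("confusion table must be 4x4 nonnegative counts")
        object.__setattr__(self, "counts", arr)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_table(true_stages, pred_stages) -> ConfusionTable:
    counts = np.zeros((N_STAGES, N_STAGES), dtype=int)
    for t, p in zip(true_stages, pred_stages):
        counts[int(t) - 1, int(p) - 1] += 1
    return ConfusionTable(counts)


def acc_sen_spe(table: ConfusionTable, level: float = 0.95) -> dict:
    """Accuracy with Clopper-Pearson CI; macro one-vs-rest SEN and SPE.

    Stages absent from the cohort are dropped from the macro averages
    (with a warning), since their recall is undefined.
    """
    c = table.counts
    total = table.total
    if total == 0:
        raise ValueError("empty confusion table")
    correct = int(np.trace(c))
    acc_ci = clopper_pearson(correct, total, level)
    sens, spes = [], []
    for s in range(N_STAGES):
        tp = c[s, s]
        fn = c[s].sum() - tp
        fp = c[:, s].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn == 0:
            warnings.warn(f"stage T{s + 1} absent; excluded from macro averages")
            continue
        sens.append(tp / (tp + fn))
        spes.append(tn / (tn + fp))
    return {
        "acc": correct / total,
        "acc_ci": acc_ci,
        "sen": float(np.mean(sens)),
        "spe": float(np.mean(spes)),
        "n": total,
    }


def group_accuracy(table: ConfusionTable, stages: tuple[int, ...]) -> BinomialCI:
    """Exact-stage accuracy restricted to the given true stages.

    E.g. ``stages=(1, 2)`` gives the early-stage accuracy: correctly
    staged early cases over all early cases.
    """
    rows = [s - 1 for s in stages]
    correct = int(sum(table.counts[r, r] for r in rows))
    n = int(table.counts[rows].sum())
    return clopper_pearson(correct, n)


def _one_hot(labels: np.ndarray) -> np.ndarray:
    out = np.zeros((len(labels), N_STAGES))
    out[np.arange(len(labels)), labels - 1] = 1.0
    return out


def roc_auc_ovr(stage_probs: np.ndarray, labels, average: str = "micro") -> float:
    """One-vs-rest multiclass AUC.

    micro: AUC over the flattened indicator/score pairs; macro:
    unweighted mean of the four per-stage AUCs (every stage must occur).
    """
    probs = np.asarray(stage_probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    if probs.ndim != 2 or probs.shape[1] != N_STAGES:
        raise ValueError(f"stage_probs must be n x {N_STAGES}")
    if average == "micro":
        onehot = _one_hot(y)
        return float(roc_auc_score(onehot.ravel(), probs.ravel()))
    if average == "macro":
        present = np.unique(y)
        if len(present) < 2:
            raise ValueError("macro AUC needs at least two classes present")
        if len(present) < N_STAGES:
            raise ValueError(f"macro AUC needs all stages present, got {present.tolist()}")
        onehot = _one_hot(y)
        return float(np.mean([roc_auc_score(onehot[:, s], probs[:, s])
                              for s in range(N_STAGES)]))
    raise ValueError(f"unknown average {average!r}")


# ---------------------------------------------------------------------
# DeLong test for correlated AUCs
# ---------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def delong_components(scores: np.ndarray, labels: np.ndarray):
    """Structural components (V10, V01) and the AUC of one score vector."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m < 2 or n < 2:
        raise ValueError("DeLong needs at least 2 cases per class")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n                 # per positive case
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m           # per negative case
    return auc, v10, v01


def delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    """DeLong variance of a single AUC."""
    auc, v10, v01 = delong_components(scores, labels)
    m, n = len(v10), len(v01)
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


def delong_test(scores_a, scores_b, binary_labels) -> TestResult:
    """Two-sided test for the difference of two correlated AUCs.

    Both score vectors must be computed on the same cases; the
    structural-component covariance accounts for the pairing.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(binary_labels, dtype=int)
    if not (len(sa) == len(sb) == len(y)):
        raise ValueError("scores and labels must be paired on the same cases")
    auc_a, v10_a, v01_a = delong_components(sa, y)
    auc_b, v10_b, v01_b = delong_components(sb, y)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        z = diff / np.sqrt(var)
    p = 1.0 if not np.isfinite(z) and diff == 0 else 2.0 * sps.norm.sf(abs(z))
    if diff == 0:
        z, p = 0.0, 1.0
    return TestResult(statistic=float(z), p_value=float(min(p, 1.0)),
                      method="DeLong", n=len(y))


# ---------------------------------------------------------------------
# Paired / unpaired nonparametric tests
# ---------------------------------------------------------------------

_MCNEMAR_EXACT_MAX = 25


def mcnemar_test(correct_a, correct_b) -> TestResult:
    """McNemar's test on paired boolean outcomes.

    Exact binomial on the discordant pairs when they number < 25,
    continuity-corrected chi-square otherwise; p = 1 when there are no
    discordant pairs.
    """
    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("outcome vectors must be paired")
    n01 = int((~a & b).sum())
    n10 = int((a & ~b).sum())
    nd = n01 + n10
    if nd == 0:
        return TestResult(statistic=0.0, p_value=1.0, method="McNemar exact", n=len(a))
    if nd < _MCNEMAR_EXACT_MAX:
        p = float(min(1.0, 2.0 * sps.binom.cdf(min(n01, n10), nd, 0.5)))
        return TestResult(statistic=float(min(n01, n10)), p_value=p,
                          method="McNemar exact", n=len(a))
    stat = (abs(n01 - n10) - 1) ** 2 / nd
    p = float(sps.chi2.sf(stat, df=1))
    return TestResult(statistic=float(stat), p_value=p, method="McNemar chi2", n=len(a), df=1)


_WILCOXON_EXACT_MAX = 25


def wilcoxon_signed_rank(x, y) -> TestResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped; exact null enumeration for n <= 25
    without ties in |differences|, tie-corrected normal approximation
    otherwise.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("samples must be paired")
    d = xa - ya
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult(statistic=0.0, p_value=1.0, method="Wilcoxon", n=0)
    if n < 5:
        warnings.warn("fewer than 5 nonzero differences; p-value is coarse")
    ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= _WILCOXON_EXACT_MAX and not ties) else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.wilcoxon(d, alternative="two-sided", method=method, correction=False)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method=f"Wilcoxon {method}", n=n)


_MWU_EXACT_MAX = 8


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test on independent samples.

    Exact enumeration when the smaller sample has <= 8 observations and
    there are no cross-sample ties, tie-corrected normal approximation
    otherwise.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) == 0 or len(ya) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([xa, ya])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(xa), len(ya)) <= _MWU_EXACT_MAX and not ties) else "asymptotic"
    res = sps.mannwhitneyu(xa, ya, alternative="two-sided", method=method)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method=f"Mann-Whitney {method}", n=len(xa) + len(ya))


def chi_square_test(table) -> TestResult:
    """Pearson chi-square on an r x c contingency table, no continuity correction."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or (arr < 0).any():
        raise ValueError("table must be a nonnegative 2D array of counts")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("table has a zero marginal")
    stat, p, dof, expected = sps.chi2_contingency(arr, correction=False)
    if (expected <= 0).any():
        raise ValueError("expected counts must be positive")
    return TestResult(statistic=float(stat), p_value=float(p), method="chi-square",
                      n=int(arr.sum()), df=int(dof))
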