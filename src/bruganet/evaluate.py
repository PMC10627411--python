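"""Cross-validation machinery and diagnostic statistics.

Covers the independent-validation scheme (leave-one-out around 7-fold
ensembles, with a stored blindness certificate) and the statistics used
to report a binary diagnostic test: Youden's J threshold, confusion
counts and the derived sensitivity/specificity/PPV/NPV/accuracy, the
Mann–Whitney AUC with tie handling, DeLong structural-components
confidence intervals, and two-sided χ²/Fisher comparisons of
proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .model import DenseNoiseClassifier, FoldEnsembleClassifier

__all__ = [
    "ConfusionCounts",
    "ROCResult",
    "CVResult",
    "kfold_ensemble",
    "loocv",
    "youden_threshold",
    "confusion_counts",
    "binary_metrics",
    "roc_auc",
    "delong_interval",
    "compare_proportions",
    "ttest_groups",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FN/FP/TN of a binary diagnostic decision."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class ROCResult:
    """ROC curve with AUC point estimate and (optional) DeLong interval."""

    auc: float
    curve: np.ndarray              # (k, 2) array of (fpr, tpr)
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None


@dataclass
class CVResult:
    """Outcome of leave-one-out validation over fold ensembles."""

    scores: np.ndarray             # held-out mean ŷ per patient
    score_sds: np.ndarray          # member spread per patient
    labels: np.ndarray
    threshold: float
    youden_j: float
    confusion: ConfusionCounts
    roc: ROCResult
    blindness_certificate: list[bool] = field(default_factory=list)

    @property
    def blind(self) -> bool:
        """True iff no patient ever appeared in their own training data."""
        return all(self.blindness_certificate)


# ---------------------------------------------------------------------------
# cross-validation

def kfold_ensemble(X, y, k: int = 7,
                   estimator: DenseNoiseClassifier | None = None,
                   seed=None) -> FoldEnsembleClassifier:
    """Train the k-member stratified fold ensemble on (X, y)."""
    ens = FoldEnsembleClassifier(estimator=estimator, n_folds=k,
                                 random_state=seed)
    return ens.fit(np.asarray(X, dtype=float), np.asarray(y))


def loocv(X, y, k: int = 7, estimator: DenseNoiseClassifier | None = None,
          seed: int = 0, threshold: float | str = "youden") -> CVResult:
    """Leave-one-out validation: each patient is scored by a k-fold
    ensemble trained on the other n−1 patients.

    The per-patient fold seed derives deterministically from
    ``(seed, patient index)``.  A blindness certificate records, for
    every patient, that they were absent from every member's training
    split.  Global metrics are computed from the n held-out mean scores:
    the decision threshold is the Youden cut on those scores unless a
    fixed numeric threshold is given.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < 10:
        raise ValueError("leave-one-out needs at least 10 patients")
    scores = np.empty(n)
    sds = np.empty(n)
    certificate: list[bool] = []
    for i in range(n):
        rest = np.delete(np.arange(n), i)
        fold_seed = int(np.random.default_rng(
            np.random.SeedSequence((seed, i))).integers(2**31 - 1))
        try:
            ens = kfold_ensemble(X[rest], y[rest], k=k, estimator=estimator,
                                 seed=fold_seed)
        except ValueError as exc:
            raise ValueError(f"patient index {i}: {exc}") from exc
        mean_i, sd_i = ens.predict_score(X[i:i + 1], return_sd=True)
        scores[i], sds[i] = float(mean_i[0]), float(sd_i[0])
        # member training rows index into `rest`, which excludes i
        certificate.append(
            all(i not in rest[tr] for tr in ens.train_indices_))
    if threshold == "youden":
        thr, j = youden_threshold(scores, y)
    else:
        thr = float(threshold)
        j = np.nan
    conf = confusion_counts(scores, y, thr)
    roc = delong_interval(scores, y)
    return CVResult(scores=scores, score_sds=sds, labels=y, threshold=thr,
                    youden_j=j, confusion=conf, roc=roc,
                    blindness_certificate=certificate)


# ---------------------------------------------------------------------------
# thresholding and confusion metrics

def youden_threshold(scores, labels) -> tuple[float, float]:
    """The score cut maximizing Youden's J = sensitivity + specificity − 1.

    Decisions use ``score >= threshold``.  Candidate cuts are midpoints
    between adjacent distinct scores (plus one cut below the minimum),
    so the returned threshold sits halfway between the score groups it
    separates.  Returns ``(threshold, J)``; a degenerate all-equal score
    vector yields J = 0 with the common score as threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    if len(uniq) == 1:
        warnings.warn("all scores identical; Youden J degenerate at 0",
                      stacklevel=2)
        return float(uniq[0]), 0.0
    cuts = np.concatenate(([uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0))
    pos = labels == np.max(labels)
    n_pos, n_neg = pos.sum(), (~pos).sum()
    best_j, best_cut = -np.inf, cuts[0]
    for c in cuts:
        pred = scores >= c
        sens = (pred & pos).sum() / n_pos
        spec = (~pred & ~pos).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_cut = j, c
    return float(best_cut), float(best_j)


def confusion_counts(scores, labels, threshold: float) -> ConfusionCounts:
    """Tally the 2×2 table with ``score >= threshold`` called positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(scores) != len(labels):
        raise ValueError("scores and labels must align")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(tp=int((pred & pos).sum()),
                           fn=int((~pred & pos).sum()),
                           fp=int((pred & ~pos).sum()),
                           tn=int((~pred & ~pos).sum()))


def binary_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, PPV, NPV and accuracy from counts.

    A metric whose denominator is zero is reported as NaN (undefined),
    never as 0.
    """
    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    return {
        "sensitivity": ratio(c.tp, c.tp + c.fn),
        "specificity": ratio(c.tn, c.tn + c.fp),
        "ppv": ratio(c.tp, c.tp + c.fp),
        "npv": ratio(c.tn, c.tn + c.fn),
        "accuracy": ratio(c.tp + c.tn, c.n),
    }


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong

def _split_scores(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("both classes must be present")
    pos = scores[labels == classes[1]]
    neg = scores[labels == classes[0]]
    return pos, neg


def mann_whitney_auc(scores, labels) -> float:
    """AUC as the Mann–Whitney probability P(s⁺ > s⁻) + ½ P(s⁺ = s⁻),
    computed via midranks so ties count one half."""
    pos, neg = _split_scores(scores, labels)
    m, n = len(pos), len(neg)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    return float((ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n))


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve by threshold sweep plus the Mann–Whitney AUC."""
    pos, neg = _split_scores(scores, labels)
    auc = mann_whitney_auc(scores, labels)
    labels01 = (np.asarray(labels) == np.unique(labels)[1]).astype(int)
    fpr, tpr, _ = _sk_roc_curve(labels01, np.asarray(scores, dtype=float))
    return ROCResult(auc=auc, curve=np.column_stack([fpr, tpr]))


def delong_interval(scores, labels, level: float = 0.95) -> ROCResult:
    """AUC with DeLong structural-components variance and a
    normal-approximation confidence interval clipped to [0, 1].

    The structural component of a positive is the fraction of negatives
    it outranks (ties half), and symmetrically for negatives; the AUC
    variance is var(V10)/m + var(V01)/n.
    """
    pos, neg = _split_scores(scores, labels)
    m, n = len(pos), len(neg)
    if m < 2 or n < 2:
        raise ValueError("need at least 2 observations per class")
    # midrank formulation (handles ties, O((m+n) log(m+n)))
    allv = np.concatenate([pos, neg])
    r_all = stats.rankdata(allv)
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    auc = float(v10.mean())
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    se = float(np.sqrt(var))
    if se == 0:
        warnings.warn("degenerate DeLong variance (all comparisons tied)",
                      stacklevel=2)
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo, hi = max(auc - z * se, 0.0), min(auc + z * se, 1.0)
    roc = roc_auc(scores, labels)
    return ROCResult(auc=auc, curve=roc.curve, se=se, ci_low=lo, ci_high=hi)


# ---------------------------------------------------------------------------
# proportion comparisons and cohort descriptors

def compare_proportions(c1: tuple[int, int], c2: tuple[int, int],
                        method: str = "chi2") -> float:
    """Two-sided p-value comparing two binomial proportions.

    ``chi2`` is the Pearson χ² test on the 2×2 table without continuity
    correction; ``fisher`` is the exact hypergeometric test with
    two-tail doubling (p = min(1, 2·min(lower tail, upper tail))).
    """
    s1, n1 = c1
    s2, n2 = c2
    if n1 <= 0 or n2 <= 0 or not (0 <= s1 <= n1 and 0 <= s2 <= n2):
        raise ValueError("invalid proportion counts")
    table = np.array([[s1, n1 - s1], [s2, n2 - s2]])
    if method == "chi2":
        if table.sum() == 0:
            raise ValueError("empty table")
        res = stats.chi2_contingency(table, correction=False)
        return float(res[1])
    if method == "fisher":
        M, K, N = n1 + n2, s1 + s2, n1  # population, successes, draws
        hg = stats.hypergeom(M, K, N)
        lower = hg.cdf(s1)
        upper = hg.sf(s1 - 1)
        return float(min(1.0, 2.0 * min(lower, upper)))
    raise ValueError(f"unknown method {method!r}")


def ttest_groups(a, b, equal_var: bool = False) -> tuple[float, float]:
    """Two-sided Student/Welch t-test for continuous cohort descriptors.
    Returns ``(statistic, p)``."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                          equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)
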