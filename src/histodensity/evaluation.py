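"""ROC/AUC evaluation with class-stratified percentile bootstrap.

The AUC is the Mann-Whitney concordance probability (ties counted 1/2).
Confidence intervals resample patients with replacement *within* each
outcome class, so every bootstrap replicate preserves the case/control
counts, and read the interval off percentiles of the replicate AUCs.  Two
independent ROC curves (different patients) are compared with the bootstrap
difference test: the observed AUC difference standardised by the bootstrap
standard deviation of the difference, referred to the standard normal law —
the unpaired scheme used by the pROC R package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_auc_score, roc_curve


@dataclass
class RocReport:
    """AUC with optional percentile-bootstrap CI for one stratum."""

    auc: float
    stratum: str = ""
    ci_low: float | None = None
    ci_high: float | None = None
    level: float | None = None
    n_bootstrap: int = 0
    seed: int | None = None
    roc_points: np.ndarray | None = field(default=None, repr=False)
    replicates: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        out = {"auc": self.auc, "stratum": self.stratum,
               "ci_low": self.ci_low, "ci_high": self.ci_high,
               "level": self.level, "n_bootstrap": self.n_bootstrap,
               "seed": self.seed}
        if self.replicates is not None:
            out["replicate_mean"] = float(np.mean(self.replicates))
            out["replicate_sd"] = float(np.std(self.replicates))
        return out


@dataclass
class AucComparison:
    """Unpaired bootstrap comparison of two AUCs."""

    auc_a: float
    auc_b: float
    statistic: float
    p_value: float
    n_bootstrap: int
    seed: int | None = None

    def to_dict(self) -> dict:
        return {"auc_a": self.auc_a, "auc_b": self.auc_b,
                "statistic": self.statistic, "p_value": self.p_value,
                "n_bootstrap": self.n_bootstrap, "seed": self.seed}


def _check_binary(truth: np.ndarray) -> None:
    classes = np.unique(truth)
    if not np.isin(classes, (0, 1)).all() or len(classes) < 2:
        raise ValueError("truth must contain both classes coded 0/1")


def roc_auc(scores, truth, stratum: str = "") -> RocReport:
    """Empirical ROC curve and AUC (no confidence interval)."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    _check_binary(truth)
    fpr, tpr, _ = roc_curve(truth, scores)
    return RocReport(auc=float(roc_auc_score(truth, scores)), stratum=stratum,
                     roc_points=np.column_stack([fpr, tpr]))


def _bootstrap_aucs(scores: np.ndarray, truth: np.ndarray, n_bootstrap: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Vectorised class-stratified bootstrap replicate AUCs."""
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    n1, n0 = len(pos), len(neg)
    pos_rs = pos[rng.integers(0, n1, (n_bootstrap, n1))]
    neg_rs = neg[rng.integers(0, n0, (n_bootstrap, n0))]
    combined = np.concatenate([pos_rs, neg_rs], axis=1)
    ranks = rankdata(combined, axis=1, method="average")
    rank_sum_pos = ranks[:, :n1].sum(axis=1)
    return (rank_sum_pos - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def bootstrap_auc_ci(scores, truth, n_bootstrap: int = 2000,
                     level: float = 0.95, seed: int = 0,
                     stratum: str = "") -> RocReport:
    """AUC with class-stratified percentile-bootstrap confidence interval."""
    if n_bootstrap < 100:
        raise ValueError("n_bootstrap must be >= 100")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    _check_binary(truth)
    rng = np.random.default_rng(seed)
    reps = _bootstrap_aucs(scores, truth, n_bootstrap, rng)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(reps, [100.0 * alpha, 100.0 * (1.0 - alpha)])
    report = roc_auc(scores, truth, stratum=stratum)
    report.ci_low, report.ci_high = float(lo), float(hi)
    report.level = level
    report.n_bootstrap = n_bootstrap
    report.seed = seed
    report.replicates = reps
    return report


def compare_auc_bootstrap(scores_a, truth_a, scores_b, truth_b,
                          n_bootstrap: int = 2000, seed: int = 0) -> AucComparison:
    """Bootstrap test for a difference between two independent AUCs.

    Per replicate both datasets are resampled class-stratified and the AUC
    difference recorded; the statistic is D = (AUC_a - AUC_b) / sd(bootstrap
    differences) with a two-sided normal p-value.
    """
    if n_bootstrap < 100:
        raise ValueError("n_bootstrap must be >= 100")
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    truth_a = np.asarray(truth_a)
    truth_b = np.asarray(truth_b)
    _check_binary(truth_a)
    _check_binary(truth_b)
    auc_a = float(roc_auc_score(truth_a, scores_a))
    auc_b = float(roc_auc_score(truth_b, scores_b))
    rng = np.random.default_rng(seed)
    reps_a = _bootstrap_aucs(scores_a, truth_a, n_bootstrap, rng)
    reps_b = _bootstrap_aucs(scores_b, truth_b, n_bootstrap, rng)
    sd = float(np.std(reps_a - reps_b, ddof=1))
    diff = auc_a - auc_b
    if sd == 0.0:
        statistic = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0.0 else 0.0
    else:
        statistic = diff / sd
        p = float(2.0 * norm.sf(abs(statistic)))
    return AucComparison(auc_a=auc_a, auc_b=auc_b, statistic=float(statistic),
                         p_value=p, n_bootstrap=n_bootstrap, seed=seed)
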