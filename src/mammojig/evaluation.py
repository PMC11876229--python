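"""Metric and statistics suite for the classification study.

Covers ROC/AUC (Mann–Whitney convention: ties count one half), the
Youden operating point J = max(sensitivity + specificity − 1), subgroup
metrics per radiological finding and breast density (with the
normal-true-negative-rate substituting for AUC in the lesion-free
group), vertically averaged mean ROC curves over repeated trials,
patient-grouped repeated k-fold split plans, and the trial-level t-test
comparing AUCs between arms.

Threshold convention, used consistently: predict positive when
``score >= cutoff``; candidate cutoffs are the distinct observed scores
plus +inf, and ties on J are broken toward the smallest cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "SplitPlan", "EvalReport", "MetricError", "roc_auc", "youden_cutoff",
    "subgroup_report", "mean_roc_curve", "grouped_kfold",
    "compare_auc_ttest", "evaluate_run",
]


class MetricError(ValueError):
    """A metric's preconditions (e.g. both classes present) are violated."""


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) != {0, 1}:
        raise MetricError("both classes must be present")
    return labels


def roc_auc(scores, labels) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """ROC points at every distinct threshold and the AUC.

    The AUC equals the Mann–Whitney probability
    ``P(score+ > score−) + 0.5 P(tie)`` (trapezoidal area under the
    tie-aware ROC). Returns ``((fpr, tpr), auc)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_classes(labels)
    fpr, tpr, _ = _sk_roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return (fpr, tpr), auc


def youden_cutoff(scores, labels) -> tuple[float, float, float, float]:
    """Operating point maximizing J = sensitivity + specificity − 1.

    Scans the distinct observed scores plus +inf as cutoffs (predict
    positive at ``score >= cutoff``), breaking ties toward the smallest
    cutoff. Returns ``(cutoff, J, sensitivity, specificity)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_classes(labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    cands = np.concatenate([np.unique(scores), [np.inf]])
    # sens(c) = P(pos >= c), spec(c) = P(neg < c)
    sens = (pos[None, :] >= cands[:, None]).mean(axis=1)
    spec = (neg[None, :] < cands[:, None]).mean(axis=1)
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax takes the first (= smallest cutoff) on ties
    return float(cands[best]), float(j[best]), float(sens[best]), float(spec[best])


def subgroup_report(score_table: pd.DataFrame, cutoff: float) -> dict:
    """Per-finding and per-density metrics of one score table.

    Lesion findings get an AUC over the images with that finding (cancer
    vs not); the normal group, which has no positives by definition,
    gets the normal-TNR: the fraction of normal images scored below the
    cutoff. A subgroup missing a class reports ``nan`` rather than
    aborting.
    """
    out: dict = {"per_finding_auc": {}, "per_density_auc": {}, "normal_tnr": np.nan}
    for finding in ("mass", "calcification", "distortion"):
        sub = score_table[score_table.finding == finding]
        try:
            _, auc = roc_auc(sub.score, sub.label)
        except MetricError:
            auc = np.nan
        out["per_finding_auc"][finding] = auc
    normals = score_table[score_table.finding == "normal"]
    if len(normals):
        out["normal_tnr"] = float((normals.score < cutoff).mean())
    for density in ("DB", "Not-DB"):
        sub = score_table[score_table.density == density]
        try:
            _, auc = roc_auc(sub.score, sub.label)
        except MetricError:
            auc = np.nan
        out["per_density_auc"][density] = auc
    return out


#: Fixed 101-point FPR grid for vertical ROC averaging.
FPR_GRID = np.linspace(0.0, 1.0, 101)


def mean_roc_curve(per_trial_rocs) -> tuple[np.ndarray, np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Vertical averaging of trial ROC curves.

    Each trial's ``(fpr, tpr)`` polyline is linearly interpolated onto
    the fixed grid; the mean and the min/max envelope per grid point are
    returned as ``(grid, mean_tpr, (lo, hi))``.
    """
    curves = list(per_trial_rocs)
    if not curves:
        raise MetricError("no ROC curves to average")
    interp = []
    for fpr, tpr in curves:
        fpr = np.asarray(fpr, dtype=float)
        tpr = np.asarray(tpr, dtype=float)
        if fpr[0] > 0.0:
            fpr, tpr = np.r_[0.0, fpr], np.r_[0.0, tpr]
        if fpr[-1] < 1.0:
            fpr, tpr = np.r_[fpr, 1.0], np.r_[tpr, 1.0]
        interp.append(np.interp(FPR_GRID, fpr, tpr))
    arr = np.vstack(interp)
    return FPR_GRID.copy(), arr.mean(axis=0), (arr.min(axis=0), arr.max(axis=0))


@dataclass
class SplitPlan:
    """Patient-grouped fold assignments for repeated k-fold CV."""

    k: int
    trials: int
    assignment: dict[tuple[int, str], int]
    seed: int = 0

    def fold_of(self, trial: int, patient_id: str) -> int:
        return self.assignment[(trial, patient_id)]

    def patients_in_fold(self, trial: int, fold: int) -> set[str]:
        return {p for (t, p), f in self.assignment.items()
                if t == trial and f == fold}

    def patients(self, trial: int = 0) -> set[str]:
        return {p for (t, p) in self.assignment if t == trial}


def grouped_kfold(patient_ids, k: int = 5, trials: int = 10, seed: int = 0
                  ) -> SplitPlan:
    """Per trial: shuffle the distinct patients with a trial-specific
    seed and deal them round-robin into ``k`` folds, so folds are sized
    within one patient of equal and no patient ever spans folds."""
    distinct: list[str] = []
    seen = set()
    for p in patient_ids:
        if p not in seen:
            seen.add(p)
            distinct.append(p)
    if len(distinct) < k:
        raise ValueError(f"need at least {k} distinct patients, got {len(distinct)}")
    assignment: dict[tuple[int, str], int] = {}
    for trial in range(trials):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, trial])
        order = rng.permutation(len(distinct))
        for pos, idx in enumerate(order):
            assignment[(trial, distinct[idx])] = pos % k
    return SplitPlan(k=k, trials=trials, assignment=assignment, seed=seed)


def compare_auc_ttest(trial_aucs_a, trial_aucs_b, paired: bool = True
                      ) -> tuple[float, float]:
    """Two-sided t-test on per-trial AUCs of two arms.

    Paired by default (arms share the trial split seeds, so trials are
    matched observations); ``paired=False`` falls back to the two-sample
    equal-variance test. Degenerate paired cases: all differences zero
    → ``(0, 1)``; zero variance with nonzero mean → ``p = 0`` in the
    limit.
    """
    a = np.asarray(trial_aucs_a, dtype=float)
    b = np.asarray(trial_aucs_b, dtype=float)
    if paired and len(a) != len(b):
        raise ValueError("paired test requires equal-length vectors")
    if min(len(a), len(b)) < 2:
        raise ValueError("need at least 2 trials")
    if paired:
        d = a - b
        if np.allclose(d.std(ddof=1), 0.0):
            if np.allclose(d.mean(), 0.0):
                return 0.0, 1.0
            return float(np.sign(d.mean()) * np.inf), 0.0
        t, p = stats.ttest_rel(a, b)
    else:
        t, p = stats.ttest_ind(a, b)
    return float(t), float(p)


@dataclass
class EvalReport:
    """Aggregated study metrics with trial-level 95% confidence intervals."""

    auc: float
    sensitivity: float
    specificity: float
    cutoff: float
    normal_tnr: float
    per_finding_auc: dict[str, float]
    per_density_auc: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    mean_roc: tuple[np.ndarray, np.ndarray]
    trial_aucs: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        def clean(x):
            if isinstance(x, dict):
                return {k: clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [clean(v) for v in x]
            if isinstance(x, float) and np.isnan(x):
                return None  # undefined subgroup -> JSON null
            return x

        return clean({
            "auc": self.auc, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "cutoff": self.cutoff,
            "normal_tnr": self.normal_tnr,
            "per_finding_auc": self.per_finding_auc,
            "per_density_auc": self.per_density_auc,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "trial_aucs": list(self.trial_aucs),
            "mean_roc": {"fpr": self.mean_roc[0].tolist(),
                         "tpr": self.mean_roc[1].tolist()},
        })


def _ci95(values: np.ndarray) -> tuple[float, float]:
    """Normal-approximation CI over trial means: mean ± 1.96·SE."""
    values = np.asarray(values, dtype=float)
    m = values.mean()
    if len(values) < 2:
        return (float(m), float(m))
    se = values.std(ddof=1) / np.sqrt(len(values))
    return (float(m - 1.96 * se), float(m + 1.96 * se))


def evaluate_run(score_table: pd.DataFrame) -> EvalReport:
    """Full study evaluation of one arm's score table.

    Per trial: AUC, Youden operating point, sensitivity/specificity at
    that cutoff, normal-TNR and subgroup AUCs; reported values are means
    over trials with mean ± 1.96·SE confidence intervals, plus the
    vertically averaged ROC curve.
    """
    required = {"trial", "score", "label", "finding", "density"}
    missing = required - set(score_table.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    per_trial: dict[str, list[float]] = {
        "auc": [], "sensitivity": [], "specificity": [], "cutoff": [],
        "normal_tnr": [], "mass": [], "calcification": [], "distortion": [],
        "DB": [], "Not-DB": [],
    }
    rocs = []
    for _, sub in score_table.groupby("trial"):
        (fpr, tpr), auc = roc_auc(sub.score, sub.label)
        rocs.append((fpr, tpr))
        cutoff, _, sens, spec = youden_cutoff(sub.score, sub.label)
        groups = subgroup_report(sub, cutoff)
        per_trial["auc"].append(auc)
        per_trial["sensitivity"].append(sens)
        per_trial["specificity"].append(spec)
        per_trial["cutoff"].append(cutoff)
        per_trial["normal_tnr"].append(groups["normal_tnr"])
        for f, v in groups["per_finding_auc"].items():
            per_trial[f].append(v)
        for d, v in groups["per_density_auc"].items():
            per_trial[d].append(v)
    grid, mean_tpr, _ = mean_roc_curve(rocs)
    mean = {
        k: float(np.nanmean(v)) if len(v) and not np.all(np.isnan(v)) else float("nan")
        for k, v in per_trial.items()
    }
    ci = {k: _ci95(np.asarray(v)[~np.isnan(v)]) for k, v in per_trial.items()
          if len(v) and not np.all(np.isnan(v))}
    return EvalReport(
        auc=mean["auc"], sensitivity=mean["sensitivity"],
        specificity=mean["specificity"], cutoff=mean["cutoff"],
        normal_tnr=mean["normal_tnr"],
        per_finding_auc={f: mean[f] for f in ("mass", "calcification", "distortion")},
        per_density_auc={d: mean[d] for d in ("DB", "Not-DB")},
        ci95=ci, mean_roc=(grid, mean_tpr),
        trial_aucs=per_trial["auc"],
    )
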