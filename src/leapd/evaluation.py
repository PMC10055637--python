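"""Statistical evaluation of the fitted index.

Implements the full battery used to judge an EEG cognition index:
age-controlled Spearman partial correlations, comparison of two
dependent (overlapping) correlations, ROC/AUC, classification metrics
with a rank-sum group separation test, linear vs quadratic regression
with a likelihood-ratio test, leave-one-out and repeated k-fold
cross-validation, label-shuffling randomization tests, robustness
sweeps over electrode count and data truncation, and classical Welch
band-power baselines (delta 1-4, theta 4-8, alpha 8-13, beta 13-30,
gamma 31-100 Hz, plus the alpha/theta log-spectral ratio).

Hyperparameter search and electrode selection always happen inside the
training fold; held-out subjects contribute nothing to the model that
scores them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

import statsmodels.api as sm

from .io import Dataset
from .preprocess import normalize_unit_power, notch_line
from .training import (
    IMPAIRED,
    NORMAL,
    FeatureCache,
    TrainingSettings,
    assign_groups,
    fit_leapd,
    score_rows,
)

__all__ = [
    "CVScheme",
    "EvaluationReport",
    "CVResult",
    "spearman_partial",
    "compare_dependent_correlations",
    "roc_auc",
    "classification_metrics",
    "regression_linear_quadratic",
    "cross_validate",
    "randomization_test",
    "robustness_sweep",
    "spectral_baselines",
    "BANDS",
]

log = logging.getLogger("leapd")

BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (31.0, 100.0),
}


# ---------------------------------------------------------------------------
# correlation statistics
# ---------------------------------------------------------------------------

def spearman_partial(x, y, covariate) -> tuple[float, float]:
    """Spearman rank partial correlation of x and y controlling a covariate.

    All three vectors are rank-transformed (mid-ranks for ties), then the
    first-order partial Pearson correlation

        rho = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))

    is computed; the p value uses the t approximation with n - 3 degrees
    of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(covariate, float)
    n = x.size
    if not (x.size == y.size == z.size):
        raise ValueError("vectors must have equal length")
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("x and y must be non-constant")
    if np.ptp(z) == 0:
        raise ValueError("covariate must be non-constant")
    rx, ry, rz = (stats.rankdata(v) for v in (x, y, z))
    C = np.corrcoef(np.vstack([rx, ry, rz]))
    r_xy, r_xz, r_yz = C[0, 1], C[0, 2], C[1, 2]
    denom = np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    if denom == 0:
        raise ValueError("covariate is perfectly rank-correlated with x or y")
    rho = float(np.clip((r_xy - r_xz * r_yz) / denom, -1.0, 1.0))
    df = n - 3
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1 - rho**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return rho, p


def compare_dependent_correlations(x1, x2, y) -> float:
    """z statistic for r(x1, y) vs r(x2, y) with overlapping samples.

    Meng-Rosenthal-Rubin construction: Fisher-transform both
    correlations and scale their difference by a factor that accounts
    for the correlation between the two predictors.  A negative z means
    x1 correlates less strongly with y than x2 does.
    """
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    y = np.asarray(y, float)
    n = y.size
    if not (x1.size == x2.size == n):
        raise ValueError("vectors must have equal length")
    if n < 10:
        raise ValueError("need at least 10 observations")
    r1 = float(np.corrcoef(x1, y)[0, 1])
    r2 = float(np.corrcoef(x2, y)[0, 1])
    r12 = float(np.corrcoef(x1, x2)[0, 1])
    if any(abs(r) >= 1.0 for r in (r1, r2)):
        raise ValueError("degenerate (|r| = 1) correlation")
    if r1 == r2:
        return 0.0
    rbar2 = (r1**2 + r2**2) / 2.0
    f = min((1.0 - r12) / (2.0 * (1.0 - rbar2)), 1.0)
    h = (1.0 - f * rbar2) / (1.0 - rbar2)
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    return float((z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - r12) * h)))


# ---------------------------------------------------------------------------
# classification statistics
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """AUC = P(score_pos > score_neg) + 0.5 P(tie), plus the ROC curve.

    ``labels`` are truthy for the positive class.  The AUC is computed
    from mid-ranks (exactly the pairwise probability); curve points are
    (FPR, TPR) at every distinct threshold.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    order = np.argsort(-scores, kind="stable")
    tps = np.cumsum(labels[order])
    fps = np.cumsum(~labels[order])
    keep = np.r_[np.flatnonzero(np.diff(scores[order]) != 0), len(scores) - 1]
    curve = pd.DataFrame({
        "threshold": scores[order][keep],
        "fpr": fps[keep] / n_neg,
        "tpr": tps[keep] / n_pos,
    })
    return float(auc), curve


def classification_metrics(predicted, truth, scores) -> dict:
    """Confusion table, percent metrics and the rank-sum separation test.

    Sensitivity is the detection rate of the impaired class.  The
    rank-sum test compares the continuous scores between the two truth
    groups (exact for small samples without ties, normal approximation
    with tie correction otherwise).
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    scores = np.asarray(scores, float)
    if not (predicted.size == truth.size == scores.size):
        raise ValueError("length mismatch")
    t_imp = truth == IMPAIRED
    p_imp = predicted == IMPAIRED
    if t_imp.all() or not t_imp.any():
        raise ValueError("both classes must be present in the truth labels")
    tp = int(np.sum(p_imp & t_imp))
    fn = int(np.sum(~p_imp & t_imp))
    tn = int(np.sum(~p_imp & ~t_imp))
    fp = int(np.sum(p_imp & ~t_imp))
    res = stats.mannwhitneyu(
        scores[~t_imp], scores[t_imp], alternative="two-sided", method="auto"
    )
    return {
        "confusion": np.array([[tp, fn], [fp, tn]]),
        "accuracy": 100.0 * (tp + tn) / truth.size,
        "sensitivity": 100.0 * tp / (tp + fn),
        "specificity": 100.0 * tn / (tn + fp),
        "ranksum_p": float(res.pvalue),
    }


def regression_linear_quadratic(index, score):
    """OLS fits of score ~ index and score ~ index + index^2, with LR test.

    Returns the two fitted models and the chi-square (1 df) p value of
    the likelihood-ratio test for the added quadratic term.
    """
    index = np.asarray(index, float)
    score = np.asarray(score, float)
    if index.size != score.size or index.size < 4:
        raise ValueError("need equal-length vectors with n >= 4")
    if np.ptp(index) == 0:
        raise ValueError("degenerate design: constant index")
    X1 = sm.add_constant(index)
    X2 = sm.add_constant(np.column_stack([index, index**2]))
    fit1 = sm.OLS(score, X1).fit()
    fit2 = sm.OLS(score, X2).fit()
    lr = 2.0 * (fit2.llf - fit1.llf)
    lr_p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    return fit1, fit2, lr_p


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVScheme:
    kind: str = "loocv"  # or "kfold"
    k: int = 5
    repeats: int = 1
    shuffle_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("loocv", "kfold"):
            raise ValueError(f"unknown scheme {self.kind!r}")
        if self.kind == "kfold" and self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class EvaluationReport:
    rho: float
    rho_p: float
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    confusion: np.ndarray
    ranksum_p: float
    r2_linear: float
    r2_quadratic: float
    lr_p: float
    indices: pd.DataFrame

    METRICS = ("rho", "auc", "accuracy", "sensitivity", "specificity",
               "r2_linear", "r2_quadratic")

    def metric_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in self.METRICS}


@dataclass
class CVResult:
    """Per-repeat reports plus mean +- sd aggregation across repeats."""

    reports: list[EvaluationReport]

    @property
    def report(self) -> EvaluationReport:
        return self.reports[0]

    @property
    def mean(self) -> dict[str, float]:
        return {
            m: float(np.mean([r.metric_dict()[m] for r in self.reports]))
            for m in EvaluationReport.METRICS
        }

    @property
    def sd(self) -> dict[str, float]:
        return {
            m: float(np.std([r.metric_dict()[m] for r in self.reports], ddof=0))
            for m in EvaluationReport.METRICS
        }


def evaluate_indices(
    df: pd.DataFrame, threshold: float = 0.5
) -> EvaluationReport:
    """Build the full report from a per-subject index table.

    ``df`` needs columns id, index, score, age, truth (normal/impaired).
    Classification: index > threshold -> normal.
    """
    idx = df["index"].to_numpy()
    rho, rho_p = spearman_partial(idx, df["score"], df["age"])
    auc, _ = roc_auc(idx, (df["truth"] == NORMAL).to_numpy())
    predicted = np.where(idx > threshold, NORMAL, IMPAIRED)
    cm = classification_metrics(predicted, df["truth"].to_numpy(), idx)
    fit1, fit2, lr_p = regression_linear_quadratic(idx, df["score"])
    return EvaluationReport(
        rho=rho, rho_p=rho_p, auc=auc,
        accuracy=cm["accuracy"], sensitivity=cm["sensitivity"],
        specificity=cm["specificity"], confusion=cm["confusion"],
        ranksum_p=cm["ranksum_p"],
        r2_linear=float(fit1.rsquared), r2_quadratic=float(fit2.rsquared),
        lr_p=lr_p, indices=df,
    )


def _stratified_folds(
    labels: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Disjoint, label-stratified folds covering all rows."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for lab in np.unique(labels):
        rows = np.flatnonzero(labels == lab)
        rng.shuffle(rows)
        for j, r in enumerate(rows):
            folds[j % k].append(int(r))
    return [np.sort(np.array(f)) for f in folds]


def _truth_groups(ds: Dataset, score_name, rule, cutoff) -> dict[str, str]:
    return assign_groups(ds.subjects, score_name, rule=rule, cutoff=cutoff)


def cross_validate(
    ds: Dataset,
    settings: TrainingSettings | None = None,
    scheme: CVScheme = CVScheme("loocv"),
    score_name: str = "moca",
    rule: str = "fixed_cutoff",
    cutoff: float = 26.0,
    cache: FeatureCache | None = None,
    balanced: bool = False,
) -> CVResult:
    """Cross-validated out-of-fold evaluation of the whole pipeline.

    Every fold refits the model — grid search, electrode selection and
    subspaces — on its training subjects only, then scores the held-out
    subjects.  Group assignment under ``median_cut`` uses the training
    fold's median.  ``balanced`` subsamples the majority class (seeded)
    to equal group sizes before splitting.
    """
    settings = settings or TrainingSettings()
    if cache is None:
        cache = FeatureCache(
            ds, max_order=max(g[1] for g in settings.grid),
            line_freq=settings.line_freq,
        )
    truth = _truth_groups(ds, score_name, rule, cutoff)
    subj = {s.id: s for s in ds.subjects}
    ids = list(cache.ids)
    rng = np.random.default_rng(scheme.shuffle_seed)
    if balanced:
        by_class = {
            lab: [i for i in ids if truth[i] == lab] for lab in (NORMAL, IMPAIRED)
        }
        m = min(len(v) for v in by_class.values())
        kept = []
        for lab, members in sorted(by_class.items()):
            members = list(members)
            rng.shuffle(members)
            kept += members[:m]
        ids = [i for i in ids if i in set(kept)]
    labels = np.array([truth[i] == NORMAL for i in ids])
    row_of = {i: r for r, i in enumerate(cache.ids)}

    reports = []
    n_repeats = 1 if scheme.kind == "loocv" else scheme.repeats
    for rep in range(n_repeats):
        if scheme.kind == "loocv":
            folds = [np.array([r]) for r in range(len(ids))]
        else:
            folds = _stratified_folds(labels, scheme.k, rng)
        out_index = np.full(len(ids), np.nan)
        for fold in folds:
            if fold.size == 0:
                continue
            test_ids = [ids[r] for r in fold]
            train_ids = [i for i in ids if i not in set(test_ids)]
            train_subjects = [subj[i] for i in train_ids]
            fold_groups = assign_groups(
                train_subjects, score_name, rule=rule, cutoff=cutoff
            )
            model = fit_leapd(
                ds, fold_groups, score_name=score_name, settings=settings,
                cache=cache, subset=train_ids,
            )
            test_rows_cache = np.array([row_of[i] for i in test_ids])
            out_index[fold] = score_rows(model, cache, test_rows_cache)
        df = pd.DataFrame({
            "id": ids,
            "index": out_index,
            "score": [subj[i].scores[score_name] for i in ids],
            "age": [subj[i].age for i in ids],
            "group": [subj[i].group for i in ids],
            "truth": [truth[i] for i in ids],
        })
        reports.append(evaluate_indices(df, threshold=settings.threshold))
    return CVResult(reports=reports)


def randomization_test(
    ds: Dataset,
    settings: TrainingSettings | None = None,
    scheme: CVScheme = CVScheme("loocv"),
    n_shuffles: int = 1,
    seed: int = 0,
    score_name: str = "moca",
    rule: str = "fixed_cutoff",
    cutoff: float = 26.0,
    cache: FeatureCache | None = None,
) -> pd.DataFrame:
    """Label-shuffling null: permute scores, rerun the entire pipeline.

    Recordings stay fixed; the cognitive score column is permuted among
    subjects, and the whole cross-validated pipeline — including
    hyperparameter search and electrode selection — reruns on the
    shuffled labels.  Returns one row (rho, auc, accuracy) per shuffle.
    """
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle")
    settings = settings or TrainingSettings()
    if cache is None:
        cache = FeatureCache(
            ds, max_order=max(g[1] for g in settings.grid),
            line_freq=settings.line_freq,
        )
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_shuffles):
        perm = rng.permutation(len(ds.subjects))
        orig = [sub.scores[score_name] for sub in ds.subjects]
        shuffled_subjects = [
            dc_replace(sub, scores={**sub.scores, score_name: orig[perm[j]]})
            for j, sub in enumerate(ds.subjects)
        ]
        ds_shuf = Dataset(subjects=shuffled_subjects, recordings=ds.recordings)
        res = cross_validate(
            ds_shuf, settings=settings, scheme=scheme, score_name=score_name,
            rule=rule, cutoff=cutoff, cache=cache,
        )
        rows.append({
            "shuffle": s, "rho": res.mean["rho"], "auc": res.mean["auc"],
            "accuracy": res.mean["accuracy"],
        })
    return pd.DataFrame(rows)


def robustness_sweep(
    ds: Dataset,
    settings: TrainingSettings | None = None,
    axis: str = "fraction",
    values=(0.1, 0.4, 1.0),
    scheme: CVScheme = CVScheme("loocv"),
    score_name: str = "moca",
    rule: str = "fixed_cutoff",
    cutoff: float = 26.0,
) -> pd.DataFrame:
    """Performance vs electrode count or vs retained data fraction.

    ``fraction`` truncates every recording to its leading fraction
    before the whole pipeline (conditioning, encoding, training); the
    returned table includes the mean retained EEG seconds.
    """
    settings = settings or TrainingSettings()
    max_order = max(g[1] for g in settings.grid)
    rows = []
    if axis == "n_electrodes":
        n_ch = len(ds.channel_labels)
        if any(v < 1 or v > n_ch for v in values):
            raise ValueError(f"electrode counts must lie in 1..{n_ch}")
        cache = FeatureCache(ds, max_order=max_order,
                             line_freq=settings.line_freq)
        for v in values:
            res = cross_validate(
                ds, settings=dc_replace(settings, n_electrodes=int(v)),
                scheme=scheme, score_name=score_name, rule=rule, cutoff=cutoff,
                cache=cache,
            )
            rows.append({"value": v, **_sweep_metrics(res)})
    elif axis == "fraction":
        if any(not (0.0 < v <= 1.0) for v in values):
            raise ValueError("fractions must lie in (0, 1]")
        durations = np.array([r.duration for r in ds.recordings.values()])
        for v in values:
            cache = FeatureCache(ds, max_order=max_order,
                                 line_freq=settings.line_freq, fraction=v)
            res = cross_validate(
                ds, settings=settings, scheme=scheme, score_name=score_name,
                rule=rule, cutoff=cutoff, cache=cache,
            )
            rows.append({
                "value": v, **_sweep_metrics(res),
                "mean_seconds": float(np.mean(durations) * v),
            })
    else:
        raise ValueError(f"unknown sweep axis {axis!r}")
    return pd.DataFrame(rows)


def _sweep_metrics(res: CVResult) -> dict:
    m = res.mean
    return {"rho": m["rho"], "auc": m["auc"], "accuracy": m["accuracy"]}


# ---------------------------------------------------------------------------
# classical spectral baselines
# ---------------------------------------------------------------------------

def _welch_psd(x, fs):
    """Welch PSD with 2-s Hann segments at 50% overlap."""
    nperseg = min(int(2 * fs), len(x))
    return sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2)


def band_powers(x, fs) -> dict[str, float]:
    """Relative Welch power per canonical band for one channel."""
    f, p = _welch_psd(x, fs)
    total = np.trapezoid(p[(f >= 1.0) & (f <= 100.0)],
                         f[(f >= 1.0) & (f <= 100.0)])
    out = {}
    for name, (lo, hi) in BANDS.items():
        m = (f >= lo) & (f <= hi)
        out[name] = float(np.trapezoid(p[m], f[m]) / total) if total > 0 else 0.0
    out["alpha_theta_ratio"] = float(
        np.log(out["alpha"]) - np.log(out["theta"])
    ) if out["alpha"] > 0 and out["theta"] > 0 else np.nan
    return out


def spectral_baselines(
    ds: Dataset,
    score_name: str = "moca",
    rule: str = "fixed_cutoff",
    cutoff: float = 26.0,
    line_freq: float | None = 60.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-channel classical features and their association with cognition.

    For every channel: relative delta/theta/alpha/beta/gamma Welch power
    and the alpha/theta log-spectral ratio; each feature's age-controlled
    Spearman correlation with the score, and its AUC for the cognitive
    group labels (high feature value treated as the normal-class
    direction).  Returns (summary table, per-subject feature table).
    """
    truth = _truth_groups(ds, score_name, rule, cutoff)
    feats = []
    for s in ds.subjects:
        rec = ds.recordings[s.id]
        for ch in rec.channel_labels:
            x = rec.channel(ch)
            if line_freq is not None:
                x = notch_line(x, rec.sample_rate, line_freq)
            x = normalize_unit_power(x)
            bp = band_powers(x, rec.sample_rate)
            feats.append({"id": s.id, "channel": ch, "score": s.scores[score_name],
                          "age": s.age, "truth": truth[s.id], **bp})
    fdf = pd.DataFrame(feats)
    rows = []
    feature_names = list(BANDS) + ["alpha_theta_ratio"]
    for ch, sub in fdf.groupby("channel", sort=False):
        for name in feature_names:
            vals = sub[name].to_numpy()
            if np.ptp(vals[np.isfinite(vals)]) == 0:
                continue
            rho, p = spearman_partial(vals, sub["score"], sub["age"])
            auc, _ = roc_auc(vals, (sub["truth"] == NORMAL).to_numpy())
            rows.append({"channel": ch, "feature": name, "rho": rho,
                         "rho_p": p, "auc": auc})
    return pd.DataFrame(rows), fdf
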