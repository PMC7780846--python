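"""Downstream cohort statistics.

Effect sizes and group tests on summary statistics, prediction-score /
cognitive-score correlations, the three-condition partial-mediation model
with a permutation null, misclassification-by-puberty chi-square analyses,
per-stratum accuracy, ROI-volume baseline classifiers under the same
subject-level CV protocol as the deep model, and the DeLong test for
correlated ROC curves.

Sex is coded girl = 1, boy = 0 throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

from .metrics import MetricsReport, compute_metrics
from .types import Atlas

__all__ = [
    "GroupSummary",
    "MediationResult",
    "summarize",
    "cohens_d",
    "two_sample_t",
    "score_correlations",
    "partial_mediation",
    "chi2_test",
    "agreement_groups",
    "misclassification_chi2",
    "per_stratum_accuracy",
    "roi_volume_features",
    "baseline_classifiers",
    "delong_test",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean and SD of one group on a continuous measure."""

    n: int
    mean: float
    sd: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("SD must be non-negative")


def summarize(x: np.ndarray, name: str = "") -> GroupSummary:
    x = np.asarray(x, dtype=np.float64)
    return GroupSummary(n=len(x), mean=float(x.mean()), sd=float(x.std(ddof=1)), name=name)


def _pooled_sd(a: GroupSummary, b: GroupSummary) -> float:
    if a.sd <= 0 or b.sd <= 0:
        raise ValueError("pooled SD requires positive group SDs")
    num = (a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2
    return float(np.sqrt(num / (a.n + b.n - 2)))


def cohens_d(a: GroupSummary, b: GroupSummary) -> float:
    """Absolute standardized mean difference with (n-1)-weighted pooled SD."""
    return abs(b.mean - a.mean) / _pooled_sd(a, b)


def two_sample_t(a: GroupSummary, b: GroupSummary) -> tuple[float, float]:
    """Pooled-variance two-sample t-test from group summaries; two-sided p."""
    sp = _pooled_sd(a, b)
    t = (a.mean - b.mean) / (sp * np.sqrt(1.0 / a.n + 1.0 / b.n))
    dof = a.n + b.n - 2
    p = 2.0 * sps.t.sf(abs(t), dof)
    return float(t), float(p)


def score_correlations(scores: np.ndarray, tests: pd.DataFrame) -> pd.DataFrame:
    """Pearson R (and two-sided p) of the prediction score with each test column."""
    scores = np.asarray(scores, dtype=np.float64)
    if len(scores) != len(tests):
        raise ValueError("scores and test table misaligned")
    if len(scores) <= 3:
        raise ValueError("need more than 3 subjects for a correlation test")
    rows = []
    for col in tests.columns:
        x = tests[col].to_numpy(dtype=np.float64)
        if np.ptp(x) == 0 or np.ptp(scores) == 0:
            raise ValueError(f"correlation undefined: column {col!r} or scores constant")
        r, p = sps.pearsonr(scores, x)
        rows.append({"test": col, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# partial mediation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MediationResult:
    """Outcome of the three-condition partial-mediation analysis.

    Condition 1: sex associates with the mediator. Condition 2: the
    mediator associates with the prediction score controlling for sex.
    Condition 3: the sex-score correlation drops when the mediator is
    added; its statistic is |r(sex, S)| - |partial r(sex, S | mediator)|
    with a permutation p-value (mediator column permuted).
    """

    condition1_p: float
    condition2_p: float
    condition3_p: float
    statistic: float
    n_permutations: int
    seed: int
    verdict: bool


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (x - x.mean()) / sd


def _mediation_stat(zx: np.ndarray, zy: np.ndarray, zm: np.ndarray) -> float:
    """|r(x, y)| minus |partial r(x, y | m)| on standardized columns."""
    n = len(zx)
    r_xy = float(zx @ zy) / n
    r_xm = float(zx @ zm) / n
    r_ym = float(zy @ zm) / n
    denom = np.sqrt((1.0 - r_xm**2) * (1.0 - r_ym**2))
    partial = (r_xy - r_xm * r_ym) / denom if denom > 0 else 0.0
    return abs(r_xy) - abs(partial)


def partial_mediation(
    sex: np.ndarray,
    scores: np.ndarray,
    mediator: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> MediationResult:
    """Three-condition partial mediation of the sex -> prediction-score link.

    The condition-3 permutation statistic and scheme (permute the mediator
    column, count permuted statistics at least as large as the observed
    one, add-one correction) are this package's construction; only the
    number of permutations follows the published protocol.
    """
    sex = np.asarray(sex, dtype=np.float64)
    scores = np.asarray(scores, dtype=np.float64)
    mediator = np.asarray(mediator, dtype=np.float64)
    if not (len(sex) == len(scores) == len(mediator)):
        raise ValueError("inputs misaligned")
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    if np.ptp(mediator) == 0:
        raise ValueError("mediator is constant")

    # condition 1: sex ~ mediator (point-biserial correlation test)
    _, p1 = sps.pearsonr(sex, mediator)

    # condition 2: mediator coefficient in S ~ sex + mediator
    x = np.column_stack([np.ones(len(sex)), sex, mediator])
    beta, _, _, _ = np.linalg.lstsq(x, scores, rcond=None)
    resid = scores - x @ beta
    dof = len(sex) - 3
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(x.T @ x)
    se_m = np.sqrt(sigma2 * xtx_inv[2, 2])
    t_m = beta[2] / se_m if se_m > 0 else 0.0
    p2 = 2.0 * sps.t.sf(abs(t_m), dof)

    # condition 3: drop in |r(sex, S)| when partialling out the mediator
    zx, zy, zm = _standardize(sex), _standardize(scores), _standardize(mediator)
    observed = _mediation_stat(zx, zy, zm)
    rng = np.random.default_rng(seed)
    n = len(zx)
    r_xy = abs(float(zx @ zy) / n)
    count = 0
    chunk = 2048
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perm = np.argsort(rng.random((b, n)), axis=1)
        zm_p = zm[perm]  # (b, n)
        r_xm = zm_p @ zx / n
        r_ym = zm_p @ zy / n
        denom = np.sqrt((1.0 - r_xm**2) * (1.0 - r_ym**2))
        partial = np.where(denom > 0, ((zx @ zy) / n - r_xm * r_ym) / np.where(denom > 0, denom, 1.0), 0.0)
        stat = r_xy - np.abs(partial)
        count += int((stat >= observed).sum())
        done += b
    p3 = (1.0 + count) / (1.0 + n_perm)

    return MediationResult(
        condition1_p=float(p1),
        condition2_p=float(p2),
        condition3_p=float(p3),
        statistic=float(observed),
        n_permutations=n_perm,
        seed=seed,
        verdict=bool(p1 < alpha and p2 < alpha and p3 < alpha),
    )


# ---------------------------------------------------------------------------
# misclassification by puberty
# ---------------------------------------------------------------------------


def chi2_test(table: np.ndarray) -> tuple[float, float, int]:
    """Pearson chi-square on a complete contingency table, no Yates correction."""
    table = np.asarray(table, dtype=np.float64)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need a contingency table with at least 2 rows and columns")
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if (expected == 0).any():
        raise ValueError("table has an empty margin")
    chi2 = float(((table - expected) ** 2 / expected).sum())
    dof = (table.shape[0] - 1) * (table.shape[1] - 1)
    p = float(sps.chi2.sf(chi2, dof))
    return chi2, p, dof


def _pool_sparse_levels(table: np.ndarray, levels: list) -> tuple[np.ndarray, list]:
    """Merge adjacent ordinal levels until every expected cell is >= 1."""
    table = table.astype(np.float64)
    while table.shape[0] > 2:
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        if expected.min() >= 1.0:
            break
        row = int(expected.min(axis=1).argmin())
        merge_into = row - 1 if row > 0 else row + 1
        warnings.warn(
            f"pooling sparse level {levels[row]} into {levels[merge_into]}", stacklevel=3
        )
        table[merge_into] += table[row]
        table = np.delete(table, row, axis=0)
        levels = levels[:row] + levels[row + 1 :]
    return table, levels


def agreement_groups(
    prediction_runs: list[pd.DataFrame], records: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split subjects by agreement across repeated CV runs.

    Subjects classified correctly in every run form the always-correct
    group; those misclassified in every run the always-wrong group.
    Subjects with mixed outcomes belong to neither.  Returns the two
    groups as cohort-record subsets.
    """
    if not prediction_runs:
        raise ValueError("need at least one prediction run")
    correct = None
    wrong = None
    for pred in prediction_runs:
        c = pred.set_index("subject_id")["correct"].astype(bool)
        correct = c if correct is None else (correct & c)
        wrong = ~c if wrong is None else (wrong & ~c)
    always_correct = records[records["subject_id"].map(correct).fillna(False)]
    always_wrong = records[records["subject_id"].map(wrong).fillna(False)]
    return always_correct, always_wrong


def misclassification_chi2(
    always_correct: pd.DataFrame,
    always_wrong: pd.DataFrame,
    variable: str = "pds_level",
) -> dict[str, dict]:
    """Chi-square of variable level x (always-correct vs always-wrong), per sex.

    The two groups come from agreement across repeated CV runs: subjects
    classified correctly in every run versus incorrectly in every run.
    Adjacent ordinal levels with expected counts below 1 are pooled.
    """
    out: dict[str, dict] = {}
    for sex_value, sex_name in ((1, "girls"), (0, "boys")):
        correct = always_correct.loc[always_correct["sex"] == sex_value, variable]
        wrong = always_wrong.loc[always_wrong["sex"] == sex_value, variable]
        levels = sorted(set(correct) | set(wrong))
        if len(levels) < 2 or len(correct) == 0 or len(wrong) == 0:
            out[sex_name] = {"chi2": np.nan, "p": np.nan, "dof": 0, "levels": levels}
            continue
        table = np.array(
            [[(correct == lv).sum(), (wrong == lv).sum()] for lv in levels],
            dtype=np.float64,
        )
        table, levels = _pool_sparse_levels(table, levels)
        chi2, p, dof = chi2_test(table)
        out[sex_name] = {"chi2": chi2, "p": p, "dof": dof, "levels": levels, "table": table}
    return out


def per_stratum_accuracy(
    predictions: pd.DataFrame,
    stratum: str = "pds_level",
    min_per_sex: int = 10,
) -> pd.DataFrame:
    """Accuracy within each stratum of a covariate (e.g. PDS level).

    A stratum is reported only when both sexes reach ``min_per_sex``
    subjects; predictions must carry ``sex``, ``correct`` and the stratum
    column.
    """
    rows = []
    for level, grp in predictions.groupby(stratum):
        n_g = int((grp["sex"] == 1).sum())
        n_b = int((grp["sex"] == 0).sum())
        if min(n_g, n_b) < min_per_sex:
            continue
        rows.append(
            {
                "stratum": level,
                "n_girls": n_g,
                "n_boys": n_b,
                "n": len(grp),
                "accuracy": float(grp["correct"].mean()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ROI-volume baselines and DeLong comparison
# ---------------------------------------------------------------------------


def roi_volume_features(volumes: np.ndarray, atlas: Atlas | np.ndarray) -> pd.DataFrame:
    """Tabular per-subject ROI summaries: mean intensity and voxel count per label."""
    labels = atlas.labels if isinstance(atlas, Atlas) else np.asarray(atlas)
    volumes = np.asarray(volumes)
    flat = volumes.reshape(len(volumes), -1)
    lab_flat = labels.ravel()
    cols = {}
    for lab in (int(v) for v in np.unique(labels) if v != 0):
        mask = lab_flat == lab
        cols[f"roi{lab}_mean"] = flat[:, mask].mean(axis=1)
        cols[f"roi{lab}_nvox"] = np.full(len(volumes), float(mask.sum()))
    return pd.DataFrame(cols)


_BASELINES = {
    "logistic_regression": lambda seed: make_pipeline(
        StandardScaler(), LogisticRegression(max_iter=1000, random_state=seed)
    ),
    "svm": lambda seed: make_pipeline(
        StandardScaler(),
        CalibratedClassifierCV(SVC(random_state=seed), ensemble=False),
    ),
    "random_forest": lambda seed: RandomForestClassifier(
        n_estimators=200, random_state=seed
    ),
}


def baseline_classifiers(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    seed: int = 0,
    methods: tuple[str, ...] = ("logistic_regression", "svm", "random_forest"),
) -> dict[str, tuple[np.ndarray, MetricsReport]]:
    """Standard classifiers on tabular ROI features under subject-level CV.

    Returns out-of-fold positive-class probabilities and the pooled metrics
    per method, using the same stratified seeded folds for every method so
    DeLong comparisons stay paired.  Constant feature columns are dropped.
    """
    x = features.to_numpy(dtype=np.float64) if isinstance(features, pd.DataFrame) else np.asarray(features, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if len(x) != len(y):
        raise ValueError("features and labels misaligned")
    keep = np.ptp(x, axis=0) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant feature column(s)", stacklevel=2)
        x = x[:, keep]
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(splitter.split(x, y))
    out: dict[str, tuple[np.ndarray, MetricsReport]] = {}
    for name in methods:
        scores = np.empty(len(y), dtype=np.float64)
        for train_idx, test_idx in folds:
            clf = _BASELINES[name](seed)
            clf.fit(x[train_idx], y[train_idx])
            proba = clf.predict_proba(x[test_idx])
            scores[test_idx] = proba[:, list(clf.classes_).index(1)]
        out[name] = (scores, compute_metrics(scores, y))
    return out


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """DeLong test for the AUC difference of two correlated ROC curves.

    Uses the structural-components estimator: per-positive and
    per-negative placement values give unbiased AUC estimates and an
    empirical covariance for the paired difference.  Returns (z, two-sided
    p); identical score vectors give z = 0, p = 1.
    """
    labels = np.asarray(labels).astype(int)
    pos = labels == 1
    neg = labels == 0
    if not pos.any() or not neg.any():
        raise ValueError("DeLong test undefined: need both classes")
    v10 = []
    v01 = []
    aucs = []
    for s in (np.asarray(scores_a, float), np.asarray(scores_b, float)):
        sp, sn = s[pos], s[neg]
        cmp = (sp[:, None] > sn[None, :]).astype(np.float64)
        cmp += 0.5 * (sp[:, None] == sn[None, :])
        v10.append(cmp.mean(axis=1))
        v01.append(cmp.mean(axis=0))
        aucs.append(float(cmp.mean()))
    m, n = int(pos.sum()), int(neg.sum())
    d10 = v10[0] - v10[1]
    d01 = v01[0] - v01[1]
    var = 0.0
    if m > 1:
        var += d10.var(ddof=1) / m
    if n > 1:
        var += d01.var(ddof=1) / n
    delta = aucs[0] - aucs[1]
    if var <= 0:
        z = 0.0
        p = 1.0 if delta == 0 else 0.0
    else:
        z = delta / np.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)
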