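"""Confounder screening of predictors and confounder-free saliency mapping.

After the network is trained on the full cohort, each learned predictor
P_j is screened with an ordinary-least-squares GLM

    P_j = b0 + b1 * S + b2 * z_pds + b3 * z_age + b4 * z_ses

fit across all subjects.  A predictor whose fit shows a significant
association (p <= alpha, deliberately uncorrected to stay sensitive) with
any of the three demographic covariates is considered confounded.
Saliency maps are the absolute input gradient of the pre-sigmoid score;
"confounder-free" maps stop gradient flow through the confounded
predictors, "confounded" maps through the clean ones.  Each per-subject
map is min-max scaled before cohort averaging, because raw gradient
magnitudes are only comparable within one map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import SexNet
from .types import BrainVolume, Atlas

__all__ = [
    "SaliencyMap",
    "ScreenResult",
    "screen_predictors",
    "compute_saliency",
    "saliency_maps",
    "cohort_pattern",
    "roi_statistics",
    "threshold_pattern",
]

CONFOUNDERS = ("pds", "age", "ses")


@dataclass(frozen=True)
class SaliencyMap:
    """Voxel-wise importance field on the model's input grid, scaled to [0, 1]."""

    data: np.ndarray
    subject_id: str | None = None
    scaled: bool = True


@dataclass(frozen=True)
class ScreenResult:
    """Per-predictor GLM coefficients, confounder p-values and flags.

    ``beta`` has one row per predictor with columns (intercept, S, z_pds,
    z_age, z_ses); ``pvalues`` the two-sided t-test p-values for the three
    confounder coefficients in the order ``CONFOUNDERS``; ``attribution``
    the confounder achieving each predictor's minimum p-value.
    """

    beta: np.ndarray
    pvalues: np.ndarray
    confounded: np.ndarray
    attribution: np.ndarray
    alpha: float

    @property
    def n_predictors(self) -> int:
        return len(self.confounded)

    @property
    def free_mask(self) -> np.ndarray:
        return ~self.confounded

    @property
    def confounded_mask(self) -> np.ndarray:
        return self.confounded.copy()

    def mask_for(self, confounder: str) -> np.ndarray:
        if confounder not in CONFOUNDERS:
            raise ValueError(f"unknown confounder {confounder!r}; expected {CONFOUNDERS}")
        return self.confounded & (self.attribution == confounder)

    def to_frame(self) -> pd.DataFrame:
        cols = {"beta_intercept": self.beta[:, 0], "beta_score": self.beta[:, 1]}
        for i, name in enumerate(CONFOUNDERS):
            cols[f"beta_z_{name}"] = self.beta[:, 2 + i]
        for i, name in enumerate(CONFOUNDERS):
            cols[f"p_{name}"] = self.pvalues[:, i]
        cols["confounded"] = self.confounded
        cols["attribution"] = np.where(self.confounded, self.attribution, "")
        df = pd.DataFrame(cols)
        df.index.name = "predictor"
        return df


def screen_predictors(
    p_matrix: np.ndarray,
    scores: np.ndarray,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
) -> ScreenResult:
    """OLS screen of every predictor against score and confounder covariates.

    ``covariates`` must carry ``z_pds``, ``z_age``, ``z_ses`` columns
    aligned with the rows of ``p_matrix``.  All predictors are fit at once
    (shared design matrix), and each confounder coefficient gets a
    two-sided t-test with n - 5 degrees of freedom.
    """
    p_matrix = np.asarray(p_matrix, dtype=np.float64)
    scores = np.asarray(scores, dtype=np.float64)
    n, m = p_matrix.shape
    if len(scores) != n or len(covariates) != n:
        raise ValueError("predictor matrix, scores and covariates misaligned")
    if n <= 5:
        raise ValueError("need more than 5 subjects to fit the 5-coefficient GLM")
    cols = [np.ones(n), scores]
    names = ["intercept", "score"]
    for name in CONFOUNDERS:
        cols.append(covariates[f"z_{name}"].to_numpy(dtype=np.float64))
        names.append(f"z_{name}")
    x = np.column_stack(cols)
    for j, name in enumerate(names[1:], start=1):
        if np.ptp(x[:, j]) == 0:
            raise np.linalg.LinAlgError(f"degenerate design: column {name!r} is constant")
    xtx = x.T @ x
    if np.linalg.matrix_rank(xtx) < x.shape[1]:
        raise np.linalg.LinAlgError("degenerate design: collinear covariates")
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ x.T @ p_matrix  # (5, M)
    resid = p_matrix - x @ beta
    dof = n - x.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))  # (5, M)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)  # (5, M)
    conf_p = pvals[2:5].T  # (M, 3) in CONFOUNDERS order
    confounded = conf_p.min(axis=1) <= alpha
    attribution = np.array([CONFOUNDERS[i] for i in conf_p.argmin(axis=1)])
    return ScreenResult(
        beta=beta.T,
        pvalues=conf_p,
        confounded=confounded,
        attribution=attribution,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# saliency
# ---------------------------------------------------------------------------


def _minmax(maps: np.ndarray) -> np.ndarray:
    """Scale each map to [0, 1]; constant maps become all zeros."""
    flat = maps.reshape(len(maps), -1)
    lo = flat.min(axis=1)[:, None, None, None]
    hi = flat.max(axis=1)[:, None, None, None]
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(span > 0, (maps - lo) / np.where(span > 0, span, 1.0), 0.0)
    return out.astype(np.float32)


def saliency_maps(
    model: SexNet,
    volumes: np.ndarray,
    predictor_mask: np.ndarray | None = None,
    batch: int = 64,
    scale: bool = True,
) -> np.ndarray:
    """Per-subject saliency: |d score / d voxel| averaged over hemisphere copies.

    The flipped copy's gradient is mirrored back before averaging so both
    contributions live in native orientation.  With ``scale`` each map is
    min-max normalized.
    """
    volumes = np.asarray(volumes, dtype=np.float32)
    if volumes.ndim == 3:
        volumes = volumes[None]
    if predictor_mask is not None and not np.asarray(predictor_mask).any():
        raise ValueError("predictor mask is empty")
    g_native = model.input_gradient(volumes, predictor_mask, batch=batch)
    flipped = np.flip(volumes, axis=1).copy()
    g_flipped = model.input_gradient(flipped, predictor_mask, batch=batch)
    sal = 0.5 * (np.abs(g_native) + np.abs(np.flip(g_flipped, axis=1)))
    return _minmax(sal) if scale else sal


def compute_saliency(
    model: SexNet,
    v: BrainVolume | np.ndarray,
    predictor_mask: np.ndarray | None = None,
    subject_id: str | None = None,
) -> SaliencyMap:
    """Saliency map for one volume (gradient restricted to masked predictors)."""
    data = v.data if isinstance(v, BrainVolume) else np.asarray(v)
    sal = saliency_maps(model, data[None], predictor_mask)[0]
    return SaliencyMap(data=sal, subject_id=subject_id)


def cohort_pattern(
    model: SexNet,
    volumes: np.ndarray,
    screen: ScreenResult,
    mode: str = "confounder_free",
    confounder: str | None = None,
    batch: int = 64,
) -> SaliencyMap:
    """Cohort-average saliency pattern restricted to clean or confounded predictors.

    ``confounder_free`` masks gradient flow to the unflagged predictors;
    ``confounded`` to the flagged ones (optionally only those attributed to
    one named confounder).  The pattern is the voxel-wise mean of the
    per-subject min-max-scaled maps.
    """
    if mode == "confounder_free":
        mask = screen.free_mask
        if not mask.any():
            raise ValueError(
                "all predictors are flagged as confounded; no confounder-free "
                "saliency can be computed (consider more predictors or a stricter alpha)"
            )
    elif mode == "confounded":
        mask = screen.mask_for(confounder) if confounder else screen.confounded_mask
        if not mask.any():
            raise ValueError("no predictor is flagged for the requested confounder")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    maps = saliency_maps(model, volumes, mask, batch=batch)
    return SaliencyMap(data=maps.mean(axis=0).astype(np.float32))


def roi_statistics(
    maps: np.ndarray,
    atlas: Atlas | np.ndarray,
    sex: np.ndarray,
) -> pd.DataFrame:
    """Per-ROI mean saliency with girl-vs-boy t-tests, Bonferroni corrected.

    Rows are ordered by cohort-mean saliency (most salient ROI first);
    ROIs with no voxels are excluded with a warning.
    """
    labels = atlas.labels if isinstance(atlas, Atlas) else np.asarray(atlas)
    maps = np.asarray(maps)
    sex = np.asarray(sex).astype(int)
    if maps.ndim == 3:
        maps = maps[None]
    if maps.shape[1:] != labels.shape:
        raise ValueError("saliency maps and atlas are on different grids")
    if min((sex == 1).sum(), (sex == 0).sum()) < 2:
        raise ValueError("need at least 2 subjects per sex")
    if isinstance(atlas, Atlas) and atlas.regions:
        roi_labels = atlas.roi_labels
    else:
        roi_labels = [int(v) for v in np.unique(labels) if v != 0]
    rows = []
    flat = maps.reshape(len(maps), -1)
    lab_flat = labels.ravel()
    for lab in roi_labels:
        mask = lab_flat == lab
        if not mask.any():
            warnings.warn(f"ROI {lab} has no voxels; excluded", stacklevel=2)
            continue
        per_subj = flat[:, mask].mean(axis=1)
        girls, boys = per_subj[sex == 1], per_subj[sex == 0]
        if np.ptp(per_subj) == 0:
            tstat, praw = 0.0, 1.0
        else:
            tstat, praw = stats.ttest_ind(girls, boys, equal_var=True)
        rows.append(
            {
                "roi": lab,
                "n_voxels": int(mask.sum()),
                "mean_saliency": float(per_subj.mean()),
                "mean_girls": float(girls.mean()),
                "mean_boys": float(boys.mean()),
                "t": float(tstat),
                "p_raw": float(praw),
            }
        )
    table = pd.DataFrame(rows)
    n_roi = len(table)
    table["p_bonferroni"] = np.minimum(1.0, table["p_raw"] * n_roi)
    table = table.sort_values("mean_saliency", ascending=False, ignore_index=True)
    table.insert(0, "rank", np.arange(1, n_roi + 1))
    return table


def threshold_pattern(pattern: SaliencyMap | np.ndarray, tau: float = 0.1) -> np.ndarray:
    """Binary mask of voxels whose scaled saliency exceeds ``tau``."""
    data = pattern.data if isinstance(pattern, SaliencyMap) else np.asarray(pattern)
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    if data.min() < 0 or data.max() > 1:
        raise ValueError("pattern must be scaled to [0, 1] before thresholding")
    return data > tau
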