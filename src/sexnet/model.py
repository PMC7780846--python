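"""The extractor+classifier network, training, and subject-level cross-validation.

The model maps a registered volume to M continuous predictor variables P
(the extractor: stacked 3x3x3 conv blocks with 2x pooling, then a sparse
linear readout of the flattened feature map) and reduces P to a prediction
score S through fully connected layers with a sigmoid output; S is the
probability that the volume belongs to a girl.

Evaluation follows a subject-level k-fold protocol: each subject's two
hemisphere copies (native + mirrored) stay in the same fold, training
folds are balanced by rigid-augmented oversampling, the held-out fold is
never augmented, and the subject's score is the average of its two
hemisphere scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .metrics import MetricsReport, compute_metrics
from .prep import balance_augment, mirror
from .types import HemispherePair, SyntheticCohort

__all__ = [
    "ModelConfig",
    "PredictionRecord",
    "SexNet",
    "train",
    "fit_full",
    "crossvalidate",
    "repeated_crossvalidate",
    "extract_predictors",
    "compute_metrics",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    ``conv_channels`` gives the output channels of each conv block (each
    block halves the grid); ``n_predictors`` is M, the width of the
    extractor output; ``hidden`` the widths of the classifier's hidden
    dense layers.  ``l1_predictor`` applies an L1 penalty to the predictor
    readout weights, encouraging each predictor to attend to a compact
    spatial support (which is what makes the per-predictor confounder
    screen informative).  ``target_per_class`` is the per-class training
    count after balanced augmentation; None balances to the larger class.
    """

    grid: int = 16
    conv_channels: tuple[int, ...] = (8,)
    predictor_mode: str = "local"
    predictor_channels: int = 1
    n_predictors: int = 16
    hidden: tuple[int, ...] = (16,)
    lr: float = 3e-3
    epochs: int = 10
    batch_size: int = 32
    l1_predictor: float = 1e-4
    target_per_class: int | None = None
    max_shift: float = 1.0
    max_rot: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.predictor_mode not in ("local", "dense"):
            raise ValueError("predictor_mode must be 'local' or 'dense'")
        if self.n_predictors < 1 or self.predictor_channels < 1:
            raise ValueError("need at least one predictor variable")
        if len(self.conv_channels) < 1 or len(self.hidden) < 0:
            raise ValueError("need at least one conv block")
        if self.grid % (2 ** len(self.conv_channels)) != 0:
            raise ValueError(
                f"grid {self.grid} not divisible by 2^{len(self.conv_channels)} "
                "(each conv block halves the grid)"
            )


@dataclass(frozen=True)
class PredictionRecord:
    """One subject's cross-validated prediction."""

    subject_id: str
    score: float  # S = mean of the two hemisphere scores, in [0, 1]
    fold: int
    score_native: float
    score_flipped: float


class SexNet:
    """Extractor (volume -> M predictors) + classifier (predictors -> score)."""

    def __init__(self, cfg: ModelConfig) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        layers: list[nn.Layer] = []
        c_in = 1
        edge = cfg.grid
        for c_out in cfg.conv_channels:
            layers += [nn.Conv3d(c_in, c_out, rng), nn.ReLU(), nn.AvgPool3d()]
            c_in = c_out
            edge //= 2
        if cfg.predictor_mode == "local":
            self.predictor_layer = nn.PointwiseConv3d(c_in, cfg.predictor_channels, rng)
            layers += [self.predictor_layer, nn.Flatten()]
            self.m = cfg.predictor_channels * edge**3
        else:
            flat = c_in * edge**3
            self.predictor_layer = nn.Linear(flat, cfg.n_predictors, rng)
            layers += [nn.Flatten(), self.predictor_layer]
            self.m = cfg.n_predictors
        self.extractor = nn.Sequential(layers)

        clf: list[nn.Layer] = []
        d = self.m
        for h in cfg.hidden:
            clf += [nn.Linear(d, h, rng), nn.ReLU()]
            d = h
        clf += [nn.Linear(d, 1, rng)]
        self.classifier = nn.Sequential(clf)

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Volumes (n, G, G, G) -> (predictor matrix (n, M), logits (n,))."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1] != self.cfg.grid or x.shape[1:] != (self.cfg.grid,) * 3:
            raise ValueError(f"expected {(self.cfg.grid,) * 3} volumes, got {x.shape[1:]}")
        p = self.extractor.forward(x[:, None])
        logit = self.classifier.forward(p)[:, 0]
        return p, logit

    def backward(
        self,
        dlogit: np.ndarray,
        predictor_mask: np.ndarray | None = None,
        need_input_grad: bool = False,
    ) -> np.ndarray | None:
        """Backprop a gradient on the logits; optionally stop gradient flow
        through predictors outside ``predictor_mask`` (boolean, length M)."""
        dp = self.classifier.backward(dlogit[:, None], need_input_grad=True)
        if predictor_mask is not None:
            mask = np.asarray(predictor_mask, dtype=bool)
            if mask.shape != (self.m,):
                raise ValueError("predictor mask must have length M")
            if not mask.any():
                raise ValueError("predictor mask is empty")
            dp = dp * mask[None, :]
        dx = self.extractor.backward(dp, need_input_grad=need_input_grad)
        if dx is None:
            return None
        return dx[:, 0]

    def zero_grad(self) -> None:
        self.extractor.zero_grad()
        self.classifier.zero_grad()

    @property
    def params(self) -> list[np.ndarray]:
        return self.extractor.params + self.classifier.params

    @property
    def grads(self) -> list[np.ndarray]:
        return self.extractor.grads + self.classifier.grads

    # -- inference ----------------------------------------------------------

    def predict_logit(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        out = np.empty(len(x), dtype=np.float64)
        for lo in range(0, len(x), batch):
            _, logit = self.forward(x[lo : lo + batch])
            out[lo : lo + batch] = logit
        return out

    def predict_proba(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        return _sigmoid(self.predict_logit(x, batch=batch))

    def input_gradient(
        self,
        x: np.ndarray,
        predictor_mask: np.ndarray | None = None,
        batch: int = 64,
    ) -> np.ndarray:
        """d(logit)/d(voxel) for each volume, optionally predictor-masked."""
        x = np.asarray(x, dtype=np.float32)
        single = x.ndim == 3
        if single:
            x = x[None]
        out = np.empty_like(x, dtype=np.float32)
        for lo in range(0, len(x), batch):
            xb = x[lo : lo + batch]
            self.forward(xb)
            self.zero_grad()
            dx = self.backward(
                np.ones(len(xb), dtype=np.float32),
                predictor_mask=predictor_mask,
                need_input_grad=True,
            )
            self.zero_grad()
            out[lo : lo + batch] = dx
        return out[0] if single else out


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(z, dtype=np.float64)))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def train(
    model: SexNet,
    x: np.ndarray,
    y: np.ndarray,
    cfg: ModelConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[float]:
    """Train end-to-end on (volumes, binary labels); returns per-epoch BCE loss."""
    cfg = cfg or model.cfg
    rng = rng or np.random.default_rng(cfg.seed + 1)
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)
    if len(x) != len(y):
        raise ValueError("data and labels misaligned")
    opt = nn.Adam(model.params, model.grads, lr=cfg.lr)
    pred_w = model.predictor_layer.w
    pred_gw = model.predictor_layer.grads[0]
    history: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x))
        total = 0.0
        for lo in range(0, len(x), cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            _, logit = model.forward(xb)
            # BCE with logits: mean(softplus(logit) - y * logit)
            loss = float(np.mean(np.logaddexp(0.0, logit) - yb * logit))
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            total += loss * len(idx)
            dlogit = ((_sigmoid(logit) - yb) / len(idx)).astype(np.float32)
            model.zero_grad()
            model.backward(dlogit, need_input_grad=False)
            if cfg.l1_predictor > 0:
                pred_gw += cfg.l1_predictor * np.sign(pred_w)
            opt.step()
        history.append(total / len(x))
    return history


def _training_items(
    cohort: SyntheticCohort, subject_idx: np.ndarray
) -> list[tuple[np.ndarray, int]]:
    items: list[tuple[np.ndarray, int]] = []
    labels = cohort.records["sex"].to_numpy()
    for i in subject_idx:
        vol = cohort.volumes[i]
        items.append((vol, int(labels[i])))
        items.append((mirror(vol).copy(), int(labels[i])))
    return items


def _balanced_training_arrays(
    cohort: SyntheticCohort,
    subject_idx: np.ndarray,
    cfg: ModelConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    items = _training_items(cohort, subject_idx)
    counts: dict[int, int] = {}
    for _, lab in items:
        counts[lab] = counts.get(lab, 0) + 1
    target = cfg.target_per_class or max(counts.values())
    items = balance_augment(items, target, rng, cfg.max_shift, cfg.max_rot)
    x = np.stack([v for v, _ in items]).astype(np.float32)
    y = np.array([lab for _, lab in items], dtype=np.float32)
    return x, y


def fit_full(cohort: SyntheticCohort, cfg: ModelConfig) -> SexNet:
    """Retrain on the entire cohort (used before saliency mapping)."""
    rng = np.random.default_rng(cfg.seed + 10_000)
    x, y = _balanced_training_arrays(cohort, np.arange(cohort.n), cfg, rng)
    model = SexNet(cfg)
    train(model, x, y, cfg, rng=np.random.default_rng(cfg.seed + 20_000))
    return model


def _stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded subject-level fold assignment, stratified by class."""
    fold = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        fold[idx] = np.arange(len(idx)) % k
    return fold


def subject_scores(model: SexNet, volumes: np.ndarray) -> pd.DataFrame:
    """Score volumes and their mirrors; S is the per-subject hemisphere average."""
    s_native = model.predict_proba(volumes)
    s_flipped = model.predict_proba(np.flip(volumes, axis=1).copy())
    return pd.DataFrame(
        {
            "score_native": s_native,
            "score_flipped": s_flipped,
            "score": (s_native + s_flipped) / 2.0,
        }
    )


def crossvalidate(
    cohort: SyntheticCohort,
    k: int = 5,
    cfg: ModelConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, MetricsReport]:
    """Subject-level k-fold cross-validation.

    Every subject lands in exactly one test fold; its two hemisphere
    copies always travel together.  Training folds are balanced-augmented;
    the test fold is scored un-augmented.  Returns the per-subject
    prediction table (one S per subject, from the model that never saw it)
    and the pooled metrics over all folds.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    cfg = cfg or ModelConfig(grid=cohort.grid)
    labels = cohort.records["sex"].to_numpy()
    rng = np.random.default_rng(seed)
    fold = _stratified_folds(labels, k, rng)

    rows = []
    for f in range(k):
        test_idx = np.flatnonzero(fold == f)
        train_idx = np.flatnonzero(fold != f)
        fold_cfg = replace(cfg, seed=cfg.seed + 101 * f)
        fold_rng = np.random.default_rng(seed + 7919 * (f + 1))
        x, y = _balanced_training_arrays(cohort, train_idx, fold_cfg, fold_rng)
        model = SexNet(fold_cfg)
        train(model, x, y, fold_cfg, rng=np.random.default_rng(seed + 104_729 * (f + 1)))
        scored = subject_scores(model, cohort.volumes[test_idx])
        scored.insert(0, "subject_id", cohort.records["subject_id"].to_numpy()[test_idx])
        scored.insert(1, "sex", labels[test_idx])
        scored.insert(2, "fold", f)
        rows.append(scored)

    pred = pd.concat(rows, ignore_index=True)
    assert pred["subject_id"].is_unique, "subject leaked across test folds"
    assert len(pred) == cohort.n, "test folds do not partition the cohort"
    pred["pred"] = (pred["score"] > 0.5).astype(int)
    pred["correct"] = (pred["pred"] == pred["sex"]).astype(int)
    report = compute_metrics(pred["score"].to_numpy(), pred["sex"].to_numpy())
    return pred, report


def repeated_crossvalidate(
    cohort: SyntheticCohort,
    runs: int = 5,
    k: int = 5,
    cfg: ModelConfig | None = None,
    seed: int = 0,
) -> tuple[list[pd.DataFrame], list[MetricsReport]]:
    """Repeat k-fold cross-validation with fresh random fold splits.

    Used both for the stability estimate (SD of balanced accuracy across
    runs) and for the always-correct / always-wrong grouping of the
    misclassification-by-puberty analysis.
    """
    preds, reports = [], []
    for r in range(runs):
        p, rep = crossvalidate(cohort, k=k, cfg=cfg, seed=seed + 1_000_003 * r)
        preds.append(p)
        reports.append(rep)
    return preds, reports


def extract_predictors(model: SexNet, pair: HemispherePair) -> np.ndarray:
    """Predictor rows (2, M) for a subject's two hemisphere copies."""
    x = np.stack([pair.native_right.data, pair.flipped_left.data])
    p, _ = model.forward(x)
    return p


def cohort_predictors(model: SexNet, volumes: np.ndarray, batch: int = 64) -> np.ndarray:
    """Per-subject predictors averaged over the two hemisphere copies (n, M)."""
    volumes = np.asarray(volumes, dtype=np.float32)
    out = np.empty((len(volumes), model.m), dtype=np.float64)
    flipped = np.flip(volumes, axis=1).copy()
    for lo in range(0, len(volumes), batch):
        p_n, _ = model.forward(volumes[lo : lo + batch])
        p_f, _ = model.forward(flipped[lo : lo + batch])
        out[lo : lo + batch] = (p_n + p_f) / 2.0
    return out
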