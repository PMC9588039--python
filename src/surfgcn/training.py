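"""Training machinery: score normalization, augmentation, the composite loss,
nested cross-validation with ensembling, and evaluation statistics.

The loss is L_all = MSE + lambda1 * reg - lambda2 * corr, where reg is the l2
norm of the trainable filter and fully connected weights and corr is the
Pearson correlation between batch predictions and targets.  The correlation
term counteracts the regression-to-the-mean shrinkage an MSE-only objective
induces: higher correlation lowers the loss.

Model selection follows a nested scheme: an outer loop of six folds provides
held-out test sets; within each outer training set an inner loop of five
folds trains five models (each early-stopped on its inner validation fold),
whose predictions are averaged into the fold's ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.stats
from scipy.spatial.transform import Rotation
from statsmodels.stats.multitest import multipletests

from .datasets import PreparedDataset
from .model import Model, ModelConfig, build_model

__all__ = [
    "TrainConfig",
    "hcp_preset",
    "FoldSplit",
    "LossValue",
    "PredictionMetrics",
    "quantile_normalize",
    "augment",
    "compute_loss",
    "loss_prediction_gradient",
    "make_nested_splits",
    "Adam",
    "train_model",
    "train_fold",
    "ensemble_predict",
    "evaluate",
    "benjamini_hochberg",
    "compare_models",
    "run_nested_cv",
]


@dataclass
class TrainConfig:
    """Optimization and augmentation settings (defaults follow the larger,
    pediatric-cohort configuration; :func:`hcp_preset` gives the adult one)."""

    batch_size: int = 32
    max_epochs: int = 100
    learning_rate: float = 5e-4
    lr_decay: float = 0.99
    lr_decay_every: int = 10
    lambda1: float = 1e-4
    lambda2: float = 1e-4
    p_a: float = 0.5
    rotation_limit_deg: float = 20.0
    noise_sigma: float = 0.02
    patience: int = 5
    center_features: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_a <= 1.0:
            raise ValueError("p_a must lie in [0, 1]")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        for name in ("batch_size", "max_epochs", "learning_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def hcp_preset(**overrides) -> TrainConfig:
    """Adult-cohort preset: batch 50, lambda1 = 5e-4, 80 epochs."""
    cfg = TrainConfig(batch_size=50, lambda1=5e-4, max_epochs=80)
    return replace(cfg, **overrides)


@dataclass
class FoldSplit:
    """Nested fold assignment: outer test folds + per-outer-fold inner folds."""

    outer_folds: list[np.ndarray]  # index arrays into the subject list
    inner_folds: dict[int, list[np.ndarray]]
    seed: int

    @property
    def outer_k(self) -> int:
        return len(self.outer_folds)

    def outer_train(self, fold: int) -> np.ndarray:
        return np.concatenate(
            [f for i, f in enumerate(self.outer_folds) if i != fold]
        )

    def outer_assignment(self) -> dict[int, int]:
        return {int(s): i for i, f in enumerate(self.outer_folds) for s in f}


@dataclass
class LossValue:
    total: float
    mse_term: float
    reg_term: float
    corr_term: float


@dataclass
class PredictionMetrics:
    mse: float
    pearson_r: float
    r_ci: tuple[float, float]  # Fisher-z 95% confidence interval for R
    prediction_interval: tuple[float, float]  # 95% PI for a new observation
    n: int
    fold: int | None = None


# ---------------------------------------------------------------------------
# Score normalization
# ---------------------------------------------------------------------------


def quantile_normalize(
    scores, mode: str = "deterministic", seed: int | None = None
) -> np.ndarray:
    """Gaussian-rank transform of raw trait scores.

    Scores are ranked from low to high (ties broken by stable input order) and
    replaced by standard-normal values in the same order.  ``deterministic``
    uses the normal quantiles at (i + 0.5)/n; ``sampled`` replaces ranks with
    the sorted order statistics of n seeded standard-normal draws (the
    historically common variant — seed-dependent, hence not the default).
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if n < 2:
        raise ValueError("need at least 2 scores to quantile normalize")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    order = np.argsort(scores, kind="stable")
    if mode == "deterministic":
        gauss = scipy.stats.norm.ppf((np.arange(n) + 0.5) / n)
    elif mode == "sampled":
        rng = np.random.default_rng(seed)
        gauss = np.sort(rng.standard_normal(n))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = np.empty(n)
    out[order] = gauss
    return out


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------


def augment(coords: np.ndarray, config: TrainConfig,
            rng: np.random.Generator) -> np.ndarray:
    """Randomly rotate and jitter raw (m, 3) coordinates with probability p_a.

    Rotation: three independent Euler angles uniform in +-rotation_limit_deg,
    about the centroid of the active structure set.  Noise: i.i.d. Gaussian
    with the configured sigma, per coordinate.  Must run *before* min-max
    normalization.
    """
    coords = np.asarray(coords, dtype=float)
    if rng.random() >= config.p_a:
        return coords
    angles = rng.uniform(-config.rotation_limit_deg, config.rotation_limit_deg, 3)
    rot = Rotation.from_euler("xyz", angles, degrees=True).as_matrix()
    centroid = coords.mean(axis=0)
    out = (coords - centroid) @ rot.T + centroid
    if config.noise_sigma > 0:
        out = out + rng.normal(0.0, config.noise_sigma, size=out.shape)
    return out


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


def _pearson_guarded(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation, defined as 0 when either vector has no variance."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def compute_loss(
    y_p, y_t, weights=None, lambda1: float = 1e-4, lambda2: float = 1e-4
) -> LossValue:
    """Composite loss: MSE + lambda1 * reg - lambda2 * corr.

    ``weights`` is an iterable of trainable weight arrays entering the l2 term
    (filter coefficients and FC weights; batch-norm parameters and biases are
    excluded).
    """
    y_p = np.asarray(y_p, float)
    y_t = np.asarray(y_t, float)
    if y_p.shape != y_t.shape:
        raise ValueError("prediction/target length mismatch")
    if y_p.size < 1:
        raise ValueError("need at least one observation")
    mse = float(np.mean((y_p - y_t) ** 2))
    reg = float(sum(np.sum(w**2) for w in weights)) if weights is not None else 0.0
    corr = _pearson_guarded(y_p, y_t)
    total = mse + lambda1 * reg - lambda2 * corr
    return LossValue(total=total, mse_term=mse, reg_term=reg, corr_term=corr)


def loss_prediction_gradient(y_p, y_t, lambda2: float) -> np.ndarray:
    """d(MSE - lambda2 * corr)/d y_p; the reg term is handled as weight decay."""
    y_p = np.asarray(y_p, float)
    y_t = np.asarray(y_t, float)
    n = y_p.shape[0]
    grad = 2.0 * (y_p - y_t) / n
    sp, st = y_p.std(), y_t.std()
    if lambda2 != 0.0 and sp > 0.0 and st > 0.0:
        dp = y_p - y_p.mean()
        dt = y_t - y_t.mean()
        corr = float((dp * dt).mean() / (sp * st))
        dcorr = dt / (n * sp * st) - corr * dp / (n * sp**2)
        grad = grad - lambda2 * dcorr
    return grad


# ---------------------------------------------------------------------------
# Nested splits
# ---------------------------------------------------------------------------


def _even_partition(indices: np.ndarray, k: int) -> list[np.ndarray]:
    """Split into k folds as evenly as possible; remainders to the lowest folds."""
    n = indices.shape[0]
    base, rem = divmod(n, k)
    folds = []
    pos = 0
    for i in range(k):
        size = base + (1 if i < rem else 0)
        folds.append(indices[pos : pos + size])
        pos += size
    return folds


def make_nested_splits(
    subject_ids, outer_k: int = 6, inner_k: int = 5, seed: int = 0
) -> FoldSplit:
    """Seeded uniform shuffle partitioned into outer folds; each outer training
    set is shuffled and partitioned again into inner folds."""
    n = len(subject_ids)
    if n < outer_k:
        raise ValueError(f"need at least {outer_k} subjects, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    outer = _even_partition(perm, outer_k)
    inner: dict[int, list[np.ndarray]] = {}
    for i in range(outer_k):
        train = np.concatenate([f for j, f in enumerate(outer) if j != i])
        inner[i] = _even_partition(rng.permutation(train), inner_k)
    return FoldSplit(outer_folds=outer, inner_folds=inner, seed=seed)


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------


class Adam:
    """Adam with a stepwise-decayed learning rate (decay^floor(t/every))."""

    def __init__(self, model: Model, config: TrainConfig,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.config = config
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        grads = model.gradients()
        self.m = {k: np.zeros_like(g) for k, g in grads.items()}
        self.v = {k: np.zeros_like(g) for k, g in grads.items()}
        self.t = 0

    @property
    def lr(self) -> float:
        decay_steps = self.t // self.config.lr_decay_every
        return self.config.learning_rate * self.config.lr_decay**decay_steps

    def step(self) -> None:
        self.t += 1
        lr = self.lr
        params = self.model.parameters()
        for k, g in self.model.gradients().items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Training loops
# ---------------------------------------------------------------------------


def _predict(model: Model, dataset: PreparedDataset, indices,
             batch_size: int = 64) -> np.ndarray:
    model.eval_mode()
    preds = []
    indices = np.asarray(indices)
    for s in range(0, indices.shape[0], batch_size):
        batch = dataset.padded_features(indices[s : s + batch_size])
        preds.append(model.forward(batch))
    return np.concatenate(preds) if preds else np.empty(0)


def train_model(
    dataset: PreparedDataset,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    model_config: ModelConfig,
    train_config: TrainConfig,
    model: Model | None = None,
) -> tuple[Model, list[dict]]:
    """Train one network with Adam, augmentation, and early stopping.

    Stops when the validation MSE has not improved for ``patience`` consecutive
    epochs and restores the best-validation parameters.  Returns the model and
    per-epoch logs (train loss components, validation MSE, learning rate).
    """
    train_idx = np.asarray(train_idx)
    val_idx = np.asarray(val_idx)
    if train_idx.size == 0 or val_idx.size == 0:
        raise ValueError("empty training or validation fold")
    if model is None:
        checksum = dataset.template.checksum()
        model = build_model(model_config, dataset.hierarchy, checksum)
    if train_config.center_features:
        # training-fold mean feature map, subtracted from every input (the
        # mean-image-subtraction of classic CNN pipelines); stored on the
        # model so held-out prediction applies the same offset
        mean_map = np.zeros_like(model.input_offset)
        for i in train_idx:
            mean_map += model.hierarchy.pad_features(dataset.features(int(i)))
        model.input_offset[...] = mean_map / train_idx.size
    rng = np.random.default_rng(train_config.seed)
    optimizer = Adam(model, train_config)
    targets = dataset.normalized_scores

    best_val = np.inf
    best_state = model.state_dict()
    stall = 0
    logs: list[dict] = []
    for epoch in range(train_config.max_epochs):
        model.train_mode()
        order = rng.permutation(train_idx)
        epoch_losses = []
        for s in range(0, order.shape[0], train_config.batch_size):
            idx = order[s : s + train_config.batch_size]
            coords = [
                augment(dataset.raw_coords[i], train_config, rng) for i in idx
            ]
            x = dataset.padded_features(idx, coords_override=coords)
            y_t = targets[idx]
            y_p = model.forward(x)
            loss = compute_loss(
                y_p, y_t, model.weight_arrays(),
                train_config.lambda1, train_config.lambda2,
            )
            model.zero_grad()
            model.backward(loss_prediction_gradient(y_p, y_t, train_config.lambda2))
            if train_config.lambda1 != 0.0:
                # l2 penalty gradient on filter/FC weights only
                grads = model.gradients()
                params = model.parameters()
                weight_ids = {id(w) for w in model.weight_arrays()}
                for k in grads:
                    if id(params[k]) in weight_ids:
                        grads[k] += 2.0 * train_config.lambda1 * params[k]
            if train_config.learning_rate > 0:
                optimizer.step()
            epoch_losses.append(loss.total)

        val_pred = _predict(model, dataset, val_idx)
        val_mse = float(np.mean((val_pred - targets[val_idx]) ** 2))
        logs.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "val_mse": val_mse,
                "lr": optimizer.lr,
            }
        )
        if val_mse < best_val - 1e-12:
            best_val = val_mse
            best_state = model.state_dict()
            stall = 0
        else:
            stall += 1
            if stall >= train_config.patience:
                break
    model.load_state_dict(best_state)
    model.eval_mode()
    model.clear_caches()
    return model, logs


def train_fold(
    dataset: PreparedDataset,
    split: FoldSplit,
    outer_fold: int,
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> tuple[list[Model], list[list[dict]]]:
    """Train the five inner-fold member models of one outer fold."""
    inner = split.inner_folds[outer_fold]
    models: list[Model] = []
    logs: list[list[dict]] = []
    for j, val_idx in enumerate(inner):
        train_idx = np.concatenate([f for i, f in enumerate(inner) if i != j])
        if val_idx.size == 0 or train_idx.size == 0:
            raise ValueError(f"empty inner fold {j} of outer fold {outer_fold}")
        cfg = replace(train_config, seed=train_config.seed + 1000 * outer_fold + j)
        mcfg = replace(model_config, seed=model_config.seed + 1000 * outer_fold + j)
        model, log = train_model(dataset, train_idx, val_idx, mcfg, cfg)
        models.append(model)
        logs.append(log)
    return models, logs


def ensemble_predict(models: list[Model], dataset: PreparedDataset,
                     indices) -> np.ndarray:
    """Arithmetic mean of the member models' evaluation-mode predictions."""
    if not models:
        raise ValueError("empty model ensemble")
    first = models[0]
    for m in models[1:]:
        # members differ only in their initialization seed
        if (
            replace(m.config, seed=0) != replace(first.config, seed=0)
            or m.template_checksum != first.template_checksum
        ):
            raise ValueError("ensemble members disagree on config or template")
    preds = np.stack([_predict(m, dataset, indices) for m in models])
    for m in models:
        m.clear_caches()
    return preds.mean(axis=0)


# ---------------------------------------------------------------------------
# Evaluation statistics
# ---------------------------------------------------------------------------


def evaluate(y_p, y_t, fold: int | None = None) -> PredictionMetrics:
    """MSE, Pearson R with Fisher-z 95% CI, and a 95% prediction interval.

    The prediction interval comes from the simple linear regression of targets
    on predictions, evaluated at the mean prediction (the interval a new
    observation would fall into with 95% probability).
    """
    y_p = np.asarray(y_p, float)
    y_t = np.asarray(y_t, float)
    n = y_p.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations")
    if y_p.std() == 0.0:
        raise ValueError("predictions have zero variance; R undefined")
    mse = float(np.mean((y_p - y_t) ** 2))
    r = float(scipy.stats.pearsonr(y_p, y_t).statistic)

    if n > 3 and abs(r) < 1.0:
        z = np.arctanh(r)
        half = 1.959963984540054 / np.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    else:
        ci = (r, r)

    slope, intercept = np.polyfit(y_p, y_t, 1)
    resid = y_t - (slope * y_p + intercept)
    dof = n - 2
    s = float(np.sqrt(np.sum(resid**2) / dof))
    tcrit = float(scipy.stats.t.ppf(0.975, dof))
    x0 = y_p.mean()
    sx2 = np.sum((y_p - x0) ** 2)
    half_pi = tcrit * s * np.sqrt(1.0 + 1.0 / n + 0.0 / max(sx2, 1e-300))
    center = slope * x0 + intercept
    pi = (float(center - half_pi), float(center + half_pi))
    return PredictionMetrics(
        mse=mse, pearson_r=r, r_ci=ci, prediction_interval=pi, n=n, fold=fold
    )


def benjamini_hochberg(p_values, alpha: float = 0.05) -> np.ndarray:
    """Step-up false-discovery-rate adjustment of raw p-values."""
    _, adjusted, _, _ = multipletests(np.asarray(p_values, float), alpha=alpha,
                                      method="fdr_bh")
    return adjusted


def compare_models(per_fold_r: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]],
                   alpha: float = 0.05) -> dict[tuple[str, str], dict]:
    """Paired t-tests across folds per input-mode pair, BH-FDR adjusted.

    ``per_fold_r`` maps (mode_a, mode_b) to the two paired per-fold R vectors.
    Returns per pair: t statistic, raw p, adjusted p, significance flag.
    """
    pairs = list(per_fold_r)
    raw_p = []
    stats = []
    for pair in pairs:
        a, b = (np.asarray(v, float) for v in per_fold_r[pair])
        if a.shape != b.shape or a.size < 2:
            raise ValueError(f"comparison {pair} needs >= 2 paired observations")
        if np.allclose(a, b):
            t_stat, p = 0.0, 1.0
        else:
            res = scipy.stats.ttest_rel(a, b)
            t_stat, p = float(res.statistic), float(res.pvalue)
        stats.append(t_stat)
        raw_p.append(p)
    adj = benjamini_hochberg(raw_p, alpha=alpha)
    return {
        pair: {
            "t": stats[i],
            "p_raw": raw_p[i],
            "p_adjusted": float(adj[i]),
            "significant": bool(adj[i] < alpha),
        }
        for i, pair in enumerate(pairs)
    }


# ---------------------------------------------------------------------------
# Full nested-CV pipeline
# ---------------------------------------------------------------------------


def run_nested_cv(
    dataset: PreparedDataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
    outer_k: int = 6,
    inner_k: int = 5,
    seed: int = 0,
) -> dict:
    """Run the whole nested cross-validation: per outer fold, train the five
    inner models, ensemble them, and evaluate on the held-out outer test set.

    Returns per-fold models, predictions, and metrics, plus pooled metrics
    over all held-out predictions.
    """
    split = make_nested_splits(dataset.subject_ids, outer_k, inner_k, seed)
    fold_results = []
    all_pred = np.empty(dataset.n_subjects)
    targets = dataset.normalized_scores
    for k in range(outer_k):
        models, logs = train_fold(dataset, split, k, model_config, train_config)
        test_idx = split.outer_folds[k]
        preds = ensemble_predict(models, dataset, test_idx)
        all_pred[test_idx] = preds
        metrics = evaluate(preds, targets[test_idx], fold=k)
        fold_results.append(
            {
                "fold": k,
                "models": models,
                "logs": logs,
                "test_indices": test_idx,
                "predictions": preds,
                "metrics": metrics,
            }
        )
    pooled = evaluate(all_pred, targets)
    return {
        "split": split,
        "folds": fold_results,
        "pooled_predictions": all_pred,
        "pooled_metrics": pooled,
    }
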