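"""Subject-wise cross-validated training, final full-data training, metrics.

The protocol: subjects (never individual segments) are split into k folds;
in each fold 20% of the subjects are held out and divided between a
validation set (loss monitored every epoch, no model selection) and a test
set, while the remaining 80% train the network.  After the epoch loop, train
and validation sets are pooled and the parameters are optimized for exactly
one more epoch before test metrics are computed at the 0.5 probability
threshold.  A final model is trained on the entire dataset without splits;
its fitted predictions on the training data are the substrate of the
revision stage.

The loss is class-weighted cross-entropy with weights 1 / n_class, and the
optimizer is averaged stochastic gradient descent (ASGD: plain SGD steps
with a slowly decaying step size and Polyak-Ruppert tail averaging that
activates after ``t0`` steps).

Metrics: sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision
TP/(TP+FP), and balanced accuracy (sensitivity + specificity) / 2, with
"artifact" the positive class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import SegmentDataset
from .errors import ConfigError, TrainingError
from .network import ArchSpec, CNNModel, build_model, softmax

__all__ = [
    "FoldPlan",
    "TrainConfig",
    "MetricsReport",
    "make_folds",
    "class_weights",
    "weighted_cross_entropy",
    "ASGD",
    "train_cv",
    "train_final",
    "evaluate",
    "metrics_from_counts",
]

POSITIVE = "artifact"
NEGATIVE = "nonartifact"


# ---------------------------------------------------------------------------
# configuration and fold plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    Defaults are the full-scale values (batch 64, learning rate 1e-4, 70
    cross-validation epochs, 100 final epochs); experiments on small
    synthetic datasets shrink ``epochs_*``/``batch_size`` and raise the
    learning rate to match their reduced number of gradient updates.
    """

    batch_size: int = 64
    learning_rate: float = 1e-4
    epochs_cv: int = 70
    epochs_final: int = 100
    threshold: float = 0.5
    seed: int = 0
    # ASGD constants (conventional defaults)
    asgd_lambd: float = 1e-4
    asgd_alpha: float = 0.75
    asgd_t0: float = 1e6
    # predict with the Polyak-Ruppert averaged iterate instead of the live
    # parameters; pointless unless asgd_t0 is small enough for the averaging
    # to activate within the run
    use_averaged_weights: bool = False

    def __post_init__(self):
        if self.batch_size <= 0 or self.learning_rate <= 0:
            raise ConfigError("batch size and learning rate must be positive")
        if self.epochs_cv <= 0 or self.epochs_final <= 0:
            raise ConfigError("epoch counts must be positive")
        if not 0 < self.threshold < 1:
            raise ConfigError("threshold must be in (0, 1)")


@dataclass(frozen=True)
class FoldPlan:
    """Per-fold subject lists; holdouts partition the subjects."""

    k: int
    folds: tuple[dict, ...]  # each {"train": [...], "val": [...], "test": [...]}
    seed: int

    def validate(self) -> None:
        all_holdout: list[str] = []
        for fold in self.folds:
            tr, va, te = set(fold["train"]), set(fold["val"]), set(fold["test"])
            if tr & va or tr & te or va & te:
                raise ConfigError("train/validation/test subjects overlap within a fold")
            all_holdout.extend(sorted(va | te))
        if len(all_holdout) != len(set(all_holdout)):
            raise ConfigError("a subject is held out in more than one fold")


def make_folds(subject_ids, k: int = 5, seed: int = 0) -> FoldPlan:
    """Build a subject-wise k-fold plan.

    Subjects are shuffled once, divided into k holdout groups; each fold's
    group is split evenly between test and validation (test takes the extra
    subject in odd groups; a singleton group becomes test only) and the
    remaining ~80% of subjects train.
    """
    subjects = sorted(set(map(str, subject_ids)))
    if len(subjects) < k:
        raise ConfigError(f"{len(subjects)} subjects cannot form {k} folds")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, k, 0xF07D]))
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    groups = [order[i::k] for i in range(k)]
    folds = []
    for i, group in enumerate(groups):
        shuffled = [group[j] for j in rng.permutation(len(group))]
        test = shuffled[0::2]
        val = shuffled[1::2]
        train = [s for s in order if s not in group]
        folds.append({"train": sorted(train), "val": sorted(val), "test": sorted(test)})
    plan = FoldPlan(k=k, folds=tuple(folds), seed=seed)
    plan.validate()
    return plan


# ---------------------------------------------------------------------------
# loss and metrics
# ---------------------------------------------------------------------------

def class_weights(labels) -> dict[str, float]:
    """Inverse-frequency class weights: weight(c) = 1 / count(c)."""
    labels = pd.Series(labels)
    counts = labels.value_counts().to_dict()
    for cls in (POSITIVE, NEGATIVE):
        if counts.get(cls, 0) == 0:
            raise ConfigError(f"class {cls!r} has no examples; cannot weight")
    return {cls: 1.0 / n for cls, n in counts.items()}


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))

def weighted_cross_entropy(
    logits: np.ndarray, y: np.ndarray, weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Class-weighted cross-entropy and its gradient w.r.t. the logits.

    ``y`` holds class indices (0 = nonartifact, 1 = artifact), ``weights``
    the per-class weights.  The loss is the weighted mean of per-example
    negative log-likelihoods (normalized by the sum of applied weights, so
    equal weights reduce exactly to the unweighted mean).
    """
    logp = _log_softmax(logits.astype(np.float64))
    n = logits.shape[0]
    w = weights[y]
    wsum = w.sum()
    loss = float(-(w * logp[np.arange(n), y]).sum() / wsum)
    p = np.exp(logp)
    grad = p
    grad[np.arange(n), y] -= 1.0
    grad *= (w / wsum)[:, None]
    return loss, grad.astype(np.float32)


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and derived scores; artifact is the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int
    sensitivity: float
    specificity: float
    precision: float
    bacc: float

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def metrics_from_counts(tp: int, fn: int, fp: int, tn: int) -> MetricsReport:
    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
            return float("nan")
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    prec = ratio(tp, tp + fp, "precision")
    return MetricsReport(
        tp=tp, fn=fn, fp=fp, tn=tn,
        sensitivity=sens, specificity=spec, precision=prec,
        bacc=(sens + spec) / 2.0,
    )


def metrics_from_probabilities(
    y_true: np.ndarray, p_artifact: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """Metrics at a probability threshold; prediction is artifact iff
    ``p_artifact >= threshold``."""
    y_true = np.asarray(y_true).astype(int)
    pred = (np.asarray(p_artifact) >= threshold).astype(int)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    return metrics_from_counts(tp, fn, fp, tn)


def evaluate(
    model: CNNModel, tensors: np.ndarray, labels, threshold: float = 0.5
) -> MetricsReport:
    """Evaluate a model on labelled tensors at the given threshold."""
    y = _label_indices(labels)
    p = model.predict_proba(tensors)[:, 1]
    return metrics_from_probabilities(y, p, threshold)


def _label_indices(labels) -> np.ndarray:
    arr = np.asarray(list(labels))
    bad = set(arr) - {POSITIVE, NEGATIVE}
    if bad:
        raise ConfigError(f"unknown labels {sorted(bad)}")
    return (arr == POSITIVE).astype(int)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class ASGD:
    """Averaged stochastic gradient descent.

    Each step applies a decayed-step-size SGD update with decoupled
    ell-2 decay ``lambd``, anneals the step size as
    ``lr / (1 + lambd * lr * t) ** alpha``, and maintains a tail average of
    the iterates that activates after ``t0`` steps.  The live (non-averaged)
    parameters are what the model predicts with, matching common usage where
    the module's own weights are read out after training.
    """

    def __init__(self, params: list[np.ndarray], lr: float,
                 lambd: float = 1e-4, alpha: float = 0.75, t0: float = 1e6):
        self.params = params
        self.lr = lr
        self.lambd = lambd
        self.alpha = alpha
        self.t0 = t0
        self.step_count = 0
        self.eta = lr
        self.mu = 1.0
        self.ax = [p.copy() for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.step_count += 1
        eta = np.float32(self.eta)
        decay = np.float32(1.0 - self.lambd * self.eta)
        for p, g, ax in zip(self.params, grads, self.ax):
            p *= decay
            p -= eta * g
            if self.mu != 1.0:
                ax += self.mu * (p - ax)
            else:
                ax[:] = p
        self.eta = self.lr / (1.0 + self.lambd * self.lr * self.step_count) ** self.alpha
        self.mu = 1.0 / max(1.0, self.step_count - self.t0)

    def swap_in_average(self) -> None:
        """Copy the averaged iterates into the live parameters (used for
        prediction when a config opts into tail averaging)."""
        for p, ax in zip(self.params, self.ax):
            p[:] = ax


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------

def _mean_loss(model: CNNModel, tensors, y, weights, batch_size) -> float:
    total, wtot = 0.0, 0.0
    for i in range(0, len(y), batch_size):
        logits = model.logits(tensors[i : i + batch_size])
        logp = _log_softmax(logits.astype(np.float64))
        w = weights[y[i : i + batch_size]]
        total += -(w * logp[np.arange(len(w)), y[i : i + batch_size]]).sum()
        wtot += w.sum()
    return float(total / wtot)


def _run_epochs(
    model: CNNModel,
    tensors: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    cfg: TrainConfig,
    epochs: int,
    rng: np.random.Generator,
    optimizer: ASGD | None = None,
    val: tuple[np.ndarray, np.ndarray] | None = None,
    context: str = "",
) -> tuple[ASGD, list[dict]]:
    """Mini-batch training for a number of epochs; batches reshuffled per epoch."""
    if optimizer is None:
        optimizer = ASGD(model.parameters(), cfg.learning_rate,
                         cfg.asgd_lambd, cfg.asgd_alpha, cfg.asgd_t0)
    history = []
    n = len(y)
    for epoch in range(1, epochs + 1):
        order = rng.permutation(n)
        epoch_loss, epoch_w = 0.0, 0.0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            logits = model.logits(tensors[idx], train=True)
            loss, dlogits = weighted_cross_entropy(logits, y[idx], weights)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at {context} epoch {epoch}")
            model.backward(dlogits)
            optimizer.step(model.gradients())
            wbatch = weights[y[idx]].sum()
            epoch_loss += loss * wbatch
            epoch_w += wbatch
        record = {"epoch": epoch, "train_loss": epoch_loss / epoch_w}
        if val is not None and len(val[1]):
            record["val_loss"] = _mean_loss(model, val[0], val[1], weights, cfg.batch_size)
        history.append(record)
    return optimizer, history


@dataclass
class FoldResult:
    fold: int
    history: pd.DataFrame          # epoch, train_loss, val_loss
    metrics: MetricsReport
    predictions: pd.DataFrame      # segment_id, label, p_artifact


@dataclass
class CVResult:
    folds: list[FoldResult]
    summary: pd.DataFrame          # metric, mean, sd (as proportions)

    @property
    def pooled_metrics(self) -> MetricsReport:
        """Metrics over all folds' pooled test predictions (threshold 0.5)."""
        preds = pd.concat([f.predictions for f in self.folds], ignore_index=True)
        return metrics_from_probabilities(
            (preds["label"] == POSITIVE).astype(int).to_numpy(),
            preds["p_artifact"].to_numpy(),
        )


def train_cv(
    ds: SegmentDataset,
    plan: FoldPlan,
    cfg: TrainConfig,
    arch: ArchSpec | None = None,
) -> CVResult:
    """Subject-wise cross-validation: per-fold training with loss curves, one
    pooled train+validation epoch, then test metrics at threshold 0.5."""
    arch = arch or ArchSpec()
    subjects = ds.segments["subject_id"].astype(str).to_numpy()
    y_all = _label_indices(ds.segments["label"])
    results = []
    for fi, fold in enumerate(plan.folds):
        tr = np.isin(subjects, fold["train"])
        va = np.isin(subjects, fold["val"])
        te = np.isin(subjects, fold["test"])
        w = _weights_vector(y_all[tr])
        model = build_model(arch, seed=_fold_seed(cfg.seed, fi))
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, fi, 0x7A1]))
        opt, history = _run_epochs(
            model, ds.tensors[tr], y_all[tr], w, cfg, cfg.epochs_cv, rng,
            val=(ds.tensors[va], y_all[va]), context=f"fold {fi}",
        )
        # pooled extra epoch on train + validation with the latest parameters
        pool = tr | va
        _run_epochs(model, ds.tensors[pool], y_all[pool], _weights_vector(y_all[pool]),
                    cfg, 1, rng, optimizer=opt, context=f"fold {fi} pooled")
        p_test = model.predict_proba(ds.tensors[te])[:, 1]
        preds = ds.segments.loc[te, ["segment_id", "label"]].copy()
        preds["p_artifact"] = p_test.astype(np.float64)
        metrics = metrics_from_probabilities(y_all[te], p_test, cfg.threshold)
        results.append(FoldResult(fi, pd.DataFrame(history), metrics, preds.reset_index(drop=True)))
    summary = _summarize([r.metrics for r in results])
    return CVResult(results, summary)


def _weights_vector(y: np.ndarray) -> np.ndarray:
    counts = np.bincount(y, minlength=2)
    if (counts == 0).any():
        raise ConfigError("both classes must be present in the training set")
    return 1.0 / counts


def _fold_seed(seed: int, fold: int) -> int:
    return (seed * 31 + fold * 7919 + 17) & 0x7FFFFFFF


def _summarize(reports: list[MetricsReport]) -> pd.DataFrame:
    rows = []
    for name in ("sensitivity", "specificity", "precision", "bacc"):
        vals = np.array([getattr(r, name) for r in reports], float)
        rows.append({"metric": name,
                     "mean": float(np.nanmean(vals)),
                     "sd": float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0})
    return pd.DataFrame(rows)


def train_final(
    ds: SegmentDataset,
    cfg: TrainConfig,
    arch: ArchSpec | None = None,
) -> tuple[CNNModel, pd.DataFrame]:
    """Train on the entire dataset without splits; return the model and its
    fitted predictions on every segment (the revision substrate).

    The prediction table has columns ``segment_id, recording_id, subject_id,
    onset_s, label, p_artifact`` and round-trips through :mod:`eegannot.io`.
    """
    y = _label_indices(ds.segments["label"])
    w = _weights_vector(y)
    model = build_model(arch or ArchSpec(), seed=cfg.seed)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 0xF17A]))
    opt, history = _run_epochs(model, ds.tensors, y, w, cfg, cfg.epochs_final, rng,
                               context="final")
    if cfg.use_averaged_weights:
        opt.swap_in_average()
    preds = ds.segments[["segment_id", "recording_id", "subject_id", "onset_s", "label"]].copy()
    preds["p_artifact"] = model.predict_proba(ds.tensors)[:, 1].astype(np.float64)
    model.history = pd.DataFrame(history)
    return model, preds
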