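"""Training recipes, distillation loop, grid search and evaluation metrics.

Model selection follows validation accuracy (VA): after every epoch the
network is evaluated on a held-out validation split (10% of the training
set by default, patient-disjoint and class-stratified), and the checkpoint
with maximal VA is kept, ties resolved towards the earliest epoch.
Balanced accuracies on the validation and test splits (VAB, TAB) are the
mean per-class recall, i.e. the mean of the diagonal of the row-normalised
confusion matrix; they are reported but never optimised.

Distillation trains the student together with one projection head per
associated tap pair against the combined loss of
:mod:`sonodistill.distillation`; the teacher runs in evaluation mode on the
same augmented batch and receives no gradient.  With beta = 0 and
lambda = 1 the distillation loop reduces exactly to supervised training.

All loops are deterministic given their ``numpy.random.Generator`` and run
single-threaded on CPU.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .architectures import Network, get_feature_taps
from .augmentation import AugmentationConfig, augment
from .distillation import DistillationConfig, ProjectionHead, batch_ce_loss_grad, batch_kd_loss_grad
from .nn import Adam, AdaptiveAvgPool2d
from .synthetic import ImageSample, samples_to_arrays

__all__ = [
    "TrainRecipe",
    "GridSpec",
    "ConfusionMatrix",
    "Checkpoint",
    "TrainingDivergedError",
    "split_validation",
    "train",
    "distill",
    "grid_search",
    "evaluate",
    "report_improvement",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class TrainRecipe:
    """Optimizer settings for one training run.

    The exponential schedule multiplies both the learning rate and the
    weight decay by ``schedule_rate`` every ``schedule_every_n_steps``
    optimisation steps (the recipe used for the teacher models); students
    default to a fixed learning rate of 1e-3, batch size 16, Adam.
    """

    optimizer: str = "adam"
    lr: float = 1e-3
    weight_decay: float = 0.0
    batch_size: int = 16
    epochs: int = 50
    schedule: str = "fixed"  # "fixed" | "exponential"
    schedule_every_n_steps: int = 100
    schedule_rate: float = 0.9
    early_stop_patience: int | None = 10

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")
        if self.lr <= 0 or self.weight_decay < 0:
            raise ValueError("lr must be positive, weight_decay non-negative")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size must be >= 1 and epochs >= 0")
        if self.schedule not in ("fixed", "exponential"):
            raise ValueError("schedule must be 'fixed' or 'exponential'")


#: The exponential-decay recipe used to train teacher networks.
TEACHER_RECIPE = TrainRecipe(
    lr=1e-4, weight_decay=5e-5, schedule="exponential", schedule_every_n_steps=100, schedule_rate=0.9
)


@dataclass(frozen=True)
class GridSpec:
    """The hyperparameter grid searched for distillation runs."""

    lam: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 10))
    tau: tuple[float, ...] = tuple(float(i) for i in range(1, 11))
    beta: tuple[float, ...] = (1.0, 5.0, 10.0, 100.0, 200.0, 400.0, 800.0)
    weight_decay: tuple[float, ...] = (5e-5, 5e-6, 1e-5, 1e-6, 1e-7, 1e-8)
    lr: tuple[float, ...] = (0.01, 0.001, 0.0001, 0.00005)

    @property
    def cardinality(self) -> int:
        return (
            len(self.lam) * len(self.tau) * len(self.beta) * len(self.weight_decay) * len(self.lr)
        )

    def enumerate(self):
        """Deterministic full-factorial enumeration (lam, tau, beta, wd, lr)."""
        yield from itertools.product(self.lam, self.tau, self.beta, self.weight_decay, self.lr)

    def sample(self, budget: int, rng: np.random.Generator):
        """Uniform sample without replacement of ``budget`` grid points."""
        total = self.cardinality
        if budget >= total:
            return list(self.enumerate())
        idx = sorted(rng.choice(total, size=budget, replace=False))
        sizes = [len(self.tau) * len(self.beta) * len(self.weight_decay) * len(self.lr),
                 len(self.beta) * len(self.weight_decay) * len(self.lr),
                 len(self.weight_decay) * len(self.lr),
                 len(self.lr)]
        axes = (self.lam, self.tau, self.beta, self.weight_decay, self.lr)
        out = []
        for flat in idx:
            coords = []
            rem = int(flat)
            for s in sizes:
                coords.append(rem // s)
                rem %= s
            coords.append(rem)
            out.append(tuple(axis[c] for axis, c in zip(axes, coords)))
        return out


class ConfusionMatrix:
    """K x K prediction counts; rows are ground truth, columns predictions."""

    def __init__(self, counts: np.ndarray) -> None:
        counts = np.asarray(counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype(int)

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray, k: int) -> "ConfusionMatrix":
        counts = np.zeros((k, k), dtype=int)
        np.add.at(counts, (np.asarray(y_true, dtype=int), np.asarray(y_pred, dtype=int)), 1)
        return cls(counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def accuracy(self) -> float:
        if self.total == 0:
            return float("nan")
        return float(np.trace(self.counts) / self.total)

    def balanced_accuracy(self) -> float:
        """Mean of the diagonal of the row-normalised matrix; empty classes
        (zero row sum) are excluded with a warning."""
        row_sums = self.counts.sum(axis=1)
        present = row_sums > 0
        if not present.any():
            return float("nan")
        if not present.all():
            warnings.warn(
                f"{(~present).sum()} class(es) have no evaluated samples and are "
                "excluded from the balanced accuracy",
                stacklevel=2,
            )
        recalls = np.diag(self.counts)[present] / row_sums[present]
        return float(recalls.mean())


@dataclass
class Checkpoint:
    """Best-by-VA snapshot of a training run."""

    state: list
    projection_states: list | None
    epoch: int
    validation_accuracy: float
    validation_balanced_accuracy: float
    config: dict
    history: pd.DataFrame


def split_validation(
    samples: list[ImageSample], fraction: float = 0.1, rng: np.random.Generator | None = None
) -> tuple[list[ImageSample], list[ImageSample]]:
    """Partition training samples into train/validation parts.

    Class-stratified and patient-disjoint: whole patients move to the
    validation side until each class's target count (fraction of its
    images) is met as closely as possible.  A class whose images all come
    from fewer than two patients falls back to image-level stratification
    with a warning.
    """
    if not samples:
        raise ValueError("cannot split an empty manifest")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly in (0, 1)")
    rng = rng if rng is not None else np.random.default_rng()
    val_idx: set[int] = set()
    labels = sorted({s.label for s in samples})
    for label in labels:
        cls_idx = [i for i, s in enumerate(samples) if s.label == label]
        target = int(round(fraction * len(cls_idx)))
        if target == 0:
            continue
        by_patient: dict[str, list[int]] = {}
        for i in cls_idx:
            by_patient.setdefault(samples[i].patient_id, []).append(i)
        if len(by_patient) < 2:
            warnings.warn(
                f"class {label} has fewer than two patients; falling back to "
                "image-level stratification for the validation split",
                stacklevel=2,
            )
            picked = rng.choice(len(cls_idx), size=target, replace=False)
            val_idx.update(cls_idx[int(i)] for i in picked)
            continue
        patients = sorted(by_patient)
        order = rng.permutation(len(patients))
        taken = 0
        for pi in order:
            if taken >= target:
                break
            group = by_patient[patients[int(pi)]]
            # never move the whole class to validation
            if taken + len(group) >= len(cls_idx):
                continue
            # do not overshoot the target by more than we currently
            # undershoot it (but always provide some validation data)
            if taken > 0 and abs(taken + len(group) - target) > target - taken:
                continue
            val_idx.update(group)
            taken += len(group)
    train_part = [s for i, s in enumerate(samples) if i not in val_idx]
    val_part = [s for i, s in enumerate(samples) if i in val_idx]
    return train_part, val_part


def evaluate(
    network: Network, samples: list[ImageSample], batch_size: int = 64
) -> tuple[float, float, ConfusionMatrix]:
    """Accuracy, balanced accuracy and the confusion matrix on a labelled
    set (evaluation mode, no augmentation)."""
    if not samples:
        raise ValueError("cannot evaluate on an empty set")
    x, y = samples_to_arrays(samples)
    x = _match_channels(x, network.input_channels)
    preds = network.predict(x, batch_size=batch_size)
    cm = ConfusionMatrix.from_predictions(y, preds, network.num_classes)
    return cm.accuracy(), cm.balanced_accuracy(), cm


def report_improvement(distilled_tab: float, baseline_tab: float) -> float:
    """Signed difference of balanced test accuracies, in percentage points
    (positive means the distilled student improved on its baseline)."""
    return float(distilled_tab - baseline_tab)


def _match_channels(x: np.ndarray, channels: int) -> np.ndarray:
    """Replicate grayscale input across channels for multi-channel nets."""
    if x.shape[1] == channels:
        return x
    if x.shape[1] == 1:
        return np.repeat(x, channels, axis=1)
    raise ValueError(f"cannot adapt {x.shape[1]}-channel input to {channels} channels")


def _augmented_batch(
    x: np.ndarray, idx: np.ndarray, aug: AugmentationConfig | None, rng: np.random.Generator
) -> np.ndarray:
    xb = x[idx]
    if aug is None:
        return xb
    out = np.empty_like(xb)
    for i in range(xb.shape[0]):
        out[i, 0] = augment(xb[i, 0], aug, rng)
    return out


def _run_training(
    student: Network,
    recipe: TrainRecipe,
    train_samples: list[ImageSample],
    val_samples: list[ImageSample],
    augmentation: AugmentationConfig | None,
    rng: np.random.Generator,
    *,
    teacher: Network | None = None,
    config: DistillationConfig | None = None,
) -> Checkpoint:
    """Shared epoch loop for supervised training and distillation."""
    distilling = teacher is not None and config is not None
    x_tr, y_tr = samples_to_arrays(train_samples)
    x_tr = _match_channels(x_tr, student.input_channels)
    n = len(train_samples)
    if n == 0:
        raise ValueError("empty training set")

    projections: list[ProjectionHead] = []
    assoc: list[tuple[int, int]] = []  # (teacher depth, student depth)
    params = list(student.parameters())
    use_features = distilling and config.beta > 0.0
    if use_features:
        t_taps = get_feature_taps(teacher, config.n_tiers)
        s_taps = get_feature_taps(student, config.n_tiers)
        if len(t_taps) != len(s_taps):
            raise ValueError("teacher and student tap counts differ")
        for tt, st in zip(t_taps, s_taps):
            proj = ProjectionHead(st.channels, tt.channels, rng=rng)
            projections.append(proj)
            params.extend(proj.parameters())
            assoc.append((tt.depth, st.depth))

    opt = Adam(
        params,
        lr=recipe.lr,
        weight_decay=recipe.weight_decay,
        schedule=recipe.schedule,
        every_n_steps=recipe.schedule_every_n_steps,
        rate=recipe.schedule_rate,
    )

    def validate() -> tuple[float, float]:
        if not val_samples:
            return float("nan"), float("nan")
        va, vab, _ = evaluate(student, val_samples)
        return va, vab

    best_state = student.state()
    best_proj = [p.seq.state() for p in projections] if projections else None
    best_va, best_vab, best_epoch = -np.inf, float("nan"), 0
    history_rows = []
    since_best = 0

    for epoch in range(1, recipe.epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, recipe.batch_size):
            idx = order[start : start + recipe.batch_size]
            xb = _augmented_batch(x_tr, idx, augmentation, rng)
            yb = y_tr[idx]
            opt.zero_grad()
            if not distilling:
                logits = student.forward(xb, train=True)
                loss, dlogits = batch_ce_loss_grad(logits, yb)
                student.backward(dlogits)
            else:
                loss, dlogits, tap_grads = _distill_batch(
                    teacher, student, projections, assoc, xb, yb, config
                )
                student.backward(dlogits, tap_grads)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, step {n_batches + 1} "
                    f"(lr={opt.lr:g}); reduce the learning rate"
                )
            opt.step()
            epoch_loss += loss
            n_batches += 1
        va, vab = validate()
        history_rows.append(
            {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1), "va": va, "vab": vab}
        )
        if np.isfinite(va) and va > best_va:
            best_va, best_vab, best_epoch = va, vab, epoch
            best_state = student.state()
            best_proj = [p.seq.state() for p in projections] if projections else None
            since_best = 0
        else:
            since_best += 1
            if recipe.early_stop_patience is not None and since_best >= recipe.early_stop_patience:
                break

    if best_va == -np.inf:  # zero epochs or no validation set
        best_va, best_vab = validate()
        best_epoch = len(history_rows)
        best_state = student.state()
    student.load_state(best_state)
    cfg_snapshot: dict = {"recipe": recipe.__dict__.copy()}
    if distilling:
        cfg_snapshot["distillation"] = {
            "lambda": config.lam,
            "tau": config.tau,
            "beta": config.beta,
            "n_tiers": config.n_tiers,
        }
    return Checkpoint(
        state=best_state,
        projection_states=best_proj,
        epoch=best_epoch,
        validation_accuracy=float(best_va),
        validation_balanced_accuracy=float(best_vab),
        config=cfg_snapshot,
        history=pd.DataFrame(history_rows),
    )


def _distill_batch(
    teacher: Network,
    student: Network,
    projections: list[ProjectionHead],
    assoc: list[tuple[int, int]],
    xb: np.ndarray,
    yb: np.ndarray,
    config: DistillationConfig,
):
    """Forward/backward of the combined loss on one batch.

    Returns (loss, dL/d student logits, {student tap depth: dL/d tap}).
    The teacher runs in evaluation mode on the same augmented batch and is
    never back-propagated through.
    """
    xt = _match_channels(xb, teacher.input_channels)
    t_depths = [d for d, _ in assoc]
    s_depths = [d for _, d in assoc]
    if assoc:
        t_logits, t_feats = teacher.forward(xt, train=False, tap_depths=t_depths)
    else:
        t_logits = teacher.forward(xt, train=False)
        t_feats = {}
    if assoc:
        s_logits, s_feats = student.forward(xb, train=True, tap_depths=s_depths)
    else:
        s_logits = student.forward(xb, train=True)
        s_feats = {}

    loss, dlogits = batch_kd_loss_grad(s_logits, t_logits, yb, config.lam, config.tau)

    tap_grads: dict[int, np.ndarray] = {}
    for (t_depth, s_depth), proj in zip(assoc, projections):
        t_map = t_feats[t_depth]
        s_map = s_feats[s_depth]
        size = (min(t_map.shape[2], s_map.shape[2]), min(t_map.shape[3], s_map.shape[3]))
        t_pool = AdaptiveAvgPool2d(size)
        s_pool = AdaptiveAvgPool2d(size)
        t_al = t_pool.forward(t_map)  # constant: no teacher gradient
        s_pooled = s_pool.forward(s_map, train=True)
        s_al = proj.forward(s_pooled, train=True)
        diff = s_al - t_al
        mse = float(np.mean(diff**2))
        loss += config.beta * mse
        d_s_al = config.beta * 2.0 * diff / diff.size
        d_s_pooled = proj.backward(d_s_al)
        g = s_pool.backward(d_s_pooled)
        tap_grads[s_depth] = tap_grads.get(s_depth, 0.0) + g
    return loss, dlogits, tap_grads


def train(
    network: Network,
    recipe: TrainRecipe,
    train_samples: list[ImageSample],
    val_samples: list[ImageSample],
    augmentation: AugmentationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Checkpoint:
    """Supervised training; returns the best-by-VA checkpoint (the network
    is left loaded with the selected weights)."""
    rng = rng if rng is not None else np.random.default_rng()
    return _run_training(network, recipe, train_samples, val_samples, augmentation, rng)


def distill(
    teacher: Network,
    student: Network,
    config: DistillationConfig,
    recipe: TrainRecipe,
    train_samples: list[ImageSample],
    val_samples: list[ImageSample],
    augmentation: AugmentationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Checkpoint:
    """Distil ``teacher`` into ``student`` with the combined loss.

    Projection heads (one per tap pair) are created and trained jointly
    with the student but excluded from the returned inference model.  With
    beta = 0 and lambda = 1 the trajectory is identical to :func:`train`
    under the same seed.
    """
    rng = rng if rng is not None else np.random.default_rng()
    return _run_training(
        student, recipe, train_samples, val_samples, augmentation, rng,
        teacher=teacher, config=config,
    )


def grid_search(
    grid: GridSpec,
    budget: int,
    objective,
    rng: np.random.Generator | None = None,
) -> tuple[DistillationConfig, TrainRecipe, pd.DataFrame]:
    """Budgeted hyperparameter search maximising validation accuracy.

    ``objective(config, recipe) -> float`` evaluates one grid point (VA of
    the distilled student).  With ``budget`` >= the grid cardinality the
    full factorial is enumerated; otherwise a seeded uniform sample
    without replacement is evaluated.  Returns the argmax configuration
    (ties -> first encountered in enumeration order) and a report table of
    every evaluated point.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if grid.cardinality == 0:
        raise ValueError("empty grid")
    rng = rng if rng is not None else np.random.default_rng()
    points = grid.sample(budget, rng)
    rows = []
    best = None
    for lam, tau, beta, wd, lr in points:
        config = DistillationConfig(lam=lam, tau=tau, beta=beta)
        recipe = replace(TrainRecipe(), lr=lr, weight_decay=wd)
        va = float(objective(config, recipe))
        rows.append(
            {"lambda": lam, "tau": tau, "beta": beta, "weight_decay": wd, "lr": lr, "va": va}
        )
        if best is None or va > best[0]:
            best = (va, config, recipe)
    report = pd.DataFrame(rows)
    return best[1], best[2], report
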