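"""Combined response- and feature-based knowledge-distillation loss.

The total objective optimised by the student is

    L = L_KD + beta * L_FMD
    L_KD = lambda * L_SL + (1 - lambda) * L_logits
    L_SL = H(softmax(a_s), y_r)                      (cross-entropy)
    L_logits = tau^2 * KL(softmax(a_t/tau) || softmax(a_s/tau))
    L_FMD = sum over associated tap pairs of MSE(aligned maps)

where a_t / a_s are teacher / student logits, y_r the ground-truth label
and tau the softening temperature.  The teacher distribution is the first
(KL target) argument, so gradients drive the student towards the teacher;
the teacher itself receives no gradient.

Feature alignment: both maps are adaptive-average-pooled to the
element-wise minimum of their spatial sizes, then the student map is passed
through a trainable projection (1x1, 3x3, 1x1 convolution stack with ReLU
between, output channels equal to the teacher tap's channels).  Projections
train jointly with the student and are discarded at inference.

MSE is the per-element mean, which keeps the beta grid scale-stable across
tap sizes and tier counts.  Setting beta = 0 recovers plain logit
distillation (BasicKD); beta = 0 with lambda = 1 is ordinary supervised
training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_softmax, softmax

from .nn import AdaptiveAvgPool2d, Conv2d, ReLU, Sequential

__all__ = [
    "DistillationConfig",
    "LogitPair",
    "ProjectionHead",
    "softened_probs",
    "loss_logits",
    "loss_sl",
    "loss_kd",
    "align_maps",
    "loss_fmd",
    "total_loss",
]


@dataclass(frozen=True)
class DistillationConfig:
    """Hyperparameters of the combined loss and the tap association.

    lam: weight of the supervised cross-entropy term, in (0, 1].
    tau: softening temperature, >= 1.
    beta: weight of the feature-map term, >= 0 (0 disables it: BasicKD).
    n_tiers: number of associated tap pairs (2, 3 or 4).
    """

    lam: float = 0.5
    tau: float = 4.0
    beta: float = 10.0
    n_tiers: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.lam <= 1.0:
            raise ValueError("lambda must lie in (0, 1]")
        if self.tau < 1.0:
            raise ValueError("tau must be >= 1")
        if self.beta < 0.0:
            raise ValueError("beta must be >= 0")
        if self.n_tiers not in (2, 3, 4):
            raise ValueError("n_tiers must be 2, 3 or 4")


@dataclass
class LogitPair:
    """Teacher and student logits for one sample, plus the true label."""

    teacher_logits: np.ndarray
    student_logits: np.ndarray
    label: int

    def __post_init__(self) -> None:
        self.teacher_logits = np.asarray(self.teacher_logits, dtype=float)
        self.student_logits = np.asarray(self.student_logits, dtype=float)
        if self.teacher_logits.shape != self.student_logits.shape:
            raise ValueError("teacher and student logit vectors differ in length")
        if not (np.all(np.isfinite(self.teacher_logits)) and np.all(np.isfinite(self.student_logits))):
            raise ValueError("logits must be finite")
        if not 0 <= self.label < self.teacher_logits.shape[-1]:
            raise ValueError("label out of range")


def softened_probs(logits: np.ndarray, tau: float) -> np.ndarray:
    """softmax(logits / tau); tau > 1 flattens the distribution."""
    if tau <= 0:
        raise ValueError("temperature must be positive")
    logits = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(logits)):
        raise ValueError("logits must be finite")
    return softmax(logits / tau, axis=-1)


def loss_logits(pair: LogitPair, tau: float) -> float:
    """tau^2 * KL(teacher softened || student softened), >= 0.

    Invariant to adding a common constant to either logit vector; zero iff
    the softened distributions coincide.
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    p = softened_probs(pair.teacher_logits, tau)
    log_q = log_softmax(pair.student_logits / tau, axis=-1)
    log_p = log_softmax(pair.teacher_logits / tau, axis=-1)
    return float(tau * tau * np.sum(p * (log_p - log_q)))


def loss_sl(student_logits: np.ndarray, label: int) -> float:
    """Supervised cross-entropy at unit temperature: -log softmax(a_s)[y]."""
    student_logits = np.asarray(student_logits, dtype=float)
    if not 0 <= label < student_logits.shape[-1]:
        raise ValueError(f"label {label} out of range for K={student_logits.shape[-1]}")
    return float(-log_softmax(student_logits, axis=-1)[..., label])


def loss_kd(pair: LogitPair, lam: float, tau: float) -> float:
    """lambda * L_SL + (1 - lambda) * L_logits."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    return lam * loss_sl(pair.student_logits, pair.label) + (1.0 - lam) * loss_logits(pair, tau)


class ProjectionHead:
    """Trainable 1x1 -> 3x3 -> 1x1 convolution stack on student features.

    Maps a student tap (``in_channels``) into the associated teacher tap's
    channel space (``out_channels``); the middle width equals the output
    width.  ReLU between the convolutions, none after the last.  Used only
    during distillation and discarded at inference.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        mid_channels: int | None = None,
        *,
        rng: np.random.Generator | None = None,
    ) -> None:
        mid = out_channels if mid_channels is None else mid_channels
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_channels = in_channels
        self.mid_channels = mid
        self.out_channels = out_channels
        last = Conv2d(mid, out_channels, 1, rng=rng)
        # zero-initialised output conv: the projected map starts at zero, so
        # the feature loss perturbs the student only once the projection has
        # adapted to the teacher's scale (stabilises early distillation)
        last.weight.value[...] = 0.0
        self.seq = Sequential(
            [
                Conv2d(in_channels, mid, 1, rng=rng),
                ReLU(),
                Conv2d(mid, mid, 3, rng=rng),
                ReLU(),
                last,
            ]
        )

    def parameters(self):
        return self.seq.parameters()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.seq.forward(np.asarray(x, dtype=float), train=train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.seq.backward(dy)

    __call__ = forward


def _common_size(t_map: np.ndarray, s_map: np.ndarray) -> tuple[int, int]:
    return (min(t_map.shape[-2], s_map.shape[-2]), min(t_map.shape[-1], s_map.shape[-1]))


def align_maps(
    teacher_map: np.ndarray,
    student_map: np.ndarray,
    projection: ProjectionHead | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pool both maps to their common (minimum) spatial size and project
    the student map into the teacher's channel space.

    Accepts 3-D (C, H, W) or batched 4-D maps; returns arrays of identical
    shape.  ``projection=None`` is allowed only when the channel counts
    already agree.
    """
    t = np.asarray(teacher_map, dtype=float)
    s = np.asarray(student_map, dtype=float)
    squeeze = False
    if t.ndim == 3 and s.ndim == 3:
        t, s = t[None], s[None]
        squeeze = True
    if t.ndim != 4 or s.ndim != 4:
        raise ValueError("feature maps must be (C,H,W) or (N,C,H,W)")
    if min(t.shape[1:]) == 0 or min(s.shape[1:]) == 0:
        raise ValueError("cannot align a zero-sized feature map")
    size = _common_size(t, s)
    pool = AdaptiveAvgPool2d(size)
    t_al = pool.forward(t)
    s_al = AdaptiveAvgPool2d(size).forward(s)
    if projection is not None:
        s_al = projection(s_al)
    if t_al.shape != s_al.shape:
        raise ValueError(
            f"aligned shapes differ: teacher {t_al.shape} vs student {s_al.shape}; "
            "projection output channels must equal teacher channels"
        )
    if squeeze:
        return t_al[0], s_al[0]
    return t_al, s_al


def loss_fmd(aligned_pairs) -> float:
    """Sum over associated pairs of per-element mean squared differences."""
    pairs = list(aligned_pairs)
    if not 2 <= len(pairs) <= 4:
        raise ValueError("expected between 2 and 4 aligned pairs")
    total = 0.0
    for t, s in pairs:
        t = np.asarray(t, dtype=float)
        s = np.asarray(s, dtype=float)
        if t.shape != s.shape:
            raise ValueError(f"aligned pair shapes differ: {t.shape} vs {s.shape}")
        total += float(np.mean((t - s) ** 2))
    return total


def total_loss(pair: LogitPair, aligned_pairs, config: DistillationConfig) -> float:
    """L = L_KD + beta * L_FMD (beta = 0 skips the feature term entirely)."""
    value = loss_kd(pair, config.lam, config.tau)
    if config.beta > 0.0:
        value += config.beta * loss_fmd(aligned_pairs)
    return value


# ---------------------------------------------------------------------------
# Batched losses with analytic gradients, used by the training loop.
# ---------------------------------------------------------------------------


def batch_ce_loss_grad(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over a batch and its gradient w.r.t. the logits."""
    n, k = logits.shape
    logp = log_softmax(logits, axis=1)
    loss = -float(np.mean(logp[np.arange(n), labels]))
    grad = softmax(logits, axis=1)
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def batch_kd_loss_grad(
    student_logits: np.ndarray,
    teacher_logits: np.ndarray,
    labels: np.ndarray,
    lam: float,
    tau: float,
) -> tuple[float, np.ndarray]:
    """Mean L_KD over a batch and its gradient w.r.t. the student logits.

    The teacher logits are constants.  d(tau^2 KL)/d a_s = tau (q - p) with
    p, q the softened teacher/student distributions.
    """
    n, k = student_logits.shape
    ce, dce = batch_ce_loss_grad(student_logits, labels)
    p = softmax(teacher_logits / tau, axis=1)
    log_p = log_softmax(teacher_logits / tau, axis=1)
    log_q = log_softmax(student_logits / tau, axis=1)
    kl = float(tau * tau * np.mean(np.sum(p * (log_p - log_q), axis=1)))
    q = softmax(student_logits / tau, axis=1)
    dkl = tau * (q - p) / n
    return lam * ce + (1.0 - lam) * kl, lam * dce + (1.0 - lam) * dkl
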