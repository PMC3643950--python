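"""Generation of internal processing constraints by gradient learning.

The belief-to-belief connection strengths are learned from input patterns
representing past social contexts.  Training follows the generalized delta
rule in batch mode: each pattern is presented, the network settles
synchronously, and the error between the visible-unit activations and the
28-bit target pattern (the input itself — auto-association) is evaluated
on a late window of settling cycles (cycles 7-9 by default).  Gradients
are obtained by backpropagation through the unrolled settling, including
through the activation carry-over that chains successive patterns, and one
weight update is applied per epoch.  The paired inter-valence links stay
fixed at their inhibitory strength throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inputs import PatternSet
from .network import DEFAULT_GAIN, EPS, WeightSet, external_term, ClampedInput, activation_fn

__all__ = [
    "TrainingConfig",
    "TrainingTrace",
    "TrainingDiverged",
    "pattern_error",
    "epoch_forward",
    "gradient",
    "train",
]


class TrainingDiverged(RuntimeError):
    """Raised when the epoch error becomes non-finite during training."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"training diverged at epoch {epoch}")


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of constraint learning.

    Defaults follow the study conditions where stated (200 epochs, clamp
    0.50 during training, error on settling cycles 7-9); the learning rate,
    momentum and error measure are standard delta-rule choices.
    """

    n_epochs: int = 200
    lr: float = 1e-5
    momentum: float = 0.5
    error_cycles: tuple = (7, 8, 9)
    clamp: float = 0.50
    error_measure: str = "cross_entropy"  # or "sse"
    n_cycles: int = 9
    kappa: float = 0.1
    rest: float = 0.5
    gain: float = DEFAULT_GAIN
    seed: int = 0

    def __post_init__(self):
        if self.lr < 0:
            raise ValueError("learning rate must be >= 0")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        if self.error_measure not in ("sse", "cross_entropy"):
            raise ValueError(f"unknown error measure {self.error_measure!r}")
        if any(c < 1 or c > self.n_cycles for c in self.error_cycles):
            raise ValueError("error cycles must lie within 1..n_cycles")


@dataclass
class TrainingTrace:
    """Per-epoch total error and the resulting weights."""

    errors: np.ndarray
    weights: WeightSet


def pattern_error(
    trajectory,
    target,
    error_cycles=(7, 8, 9),
    measure: str = "sse",
    n_visible: int | None = None,
) -> float:
    """Total discrepancy between visible activations and the binary target
    over the listed settling cycles.  Hidden units contribute nothing.

    ``trajectory`` is a sequence of ActivationState (cycle 1 first) or of
    plain activation vectors; ``target`` is the 2*n_beliefs binary vector.
    """
    target = np.asarray(target, dtype=float)
    nv = target.size if n_visible is None else n_visible
    if max(error_cycles) > len(trajectory):
        raise ValueError(
            f"error cycle {max(error_cycles)} out of range for a "
            f"{len(trajectory)}-cycle trajectory"
        )
    total = 0.0
    for c in error_cycles:
        state = trajectory[c - 1]
        a = getattr(state, "activations", state)[:nv]
        if measure == "sse":
            total += float(np.sum((a - target) ** 2))
        elif measure == "cross_entropy":
            total += float(
                -np.sum(target * np.log(a) + (1 - target) * np.log(1 - a))
            )
        else:
            raise ValueError(f"unknown error measure {measure!r}")
    return total


def epoch_forward(weights: WeightSet, patterns: PatternSet, config: TrainingConfig):
    """One forward pass over the pattern set in presentation order with
    carry-over chaining.  Returns (total error, per-pattern activation
    history) where each history is the list [init, a_1, ..., a_n_cycles].
    """
    t = weights.topology
    nv = t.n_visible
    histories = []
    total_error = 0.0
    prev_final = None
    for pat in patterns.patterns:
        if prev_final is None:
            a = np.full(t.n_units, config.rest)
        else:
            a = config.rest + config.kappa * (prev_final - config.rest)
        ext = external_term(t, ClampedInput(pat, config.clamp))
        hist = [a]
        for _ in range(config.n_cycles):
            a = activation_fn(weights.w @ a + weights.bias + ext, gain=config.gain)
            hist.append(a)
        histories.append(hist)
        total_error += pattern_error(
            hist[1:], pat, config.error_cycles, config.error_measure, n_visible=nv
        )
        prev_final = a
    return total_error, histories


def gradient(weights: WeightSet, patterns: PatternSet, config: TrainingConfig):
    """Batch gradient of the total epoch error with respect to the weight
    matrix and biases, by backpropagation through time.

    The backward pass runs through every settling cycle of every pattern
    and through the carry-over links between successive patterns, so the
    gradient is exact for the chained forward pass.  Entries on masked-out
    and fixed (inter-valence) connections are zero.

    Returns ``(grad_w, grad_bias, total_error)``.
    """
    if len(patterns) == 0:
        raise ValueError("pattern set is empty")
    t = weights.topology
    nv = t.n_visible
    total_error, histories = epoch_forward(weights, patterns, config)

    grad_w = np.zeros_like(weights.w)
    grad_b = np.zeros_like(weights.bias)
    # gradient flowing into the *final* activation of the previous pattern
    g_carry = np.zeros(t.n_units)

    for p in range(len(patterns) - 1, -1, -1):
        pat = patterns.patterns[p].astype(float)
        hist = histories[p]
        # dE/da at the last cycle: carry-over into the next pattern
        g_a = g_carry.copy()
        for c in range(config.n_cycles, 0, -1):
            a = hist[c]
            if c in config.error_cycles:
                if config.error_measure == "sse":
                    g_a[:nv] += 2.0 * (a[:nv] - pat)
                else:  # cross-entropy
                    g_a[:nv] += (a[:nv] - pat) / (a[:nv] * (1 - a[:nv]))
            # through the logistic (zero where the clip is active)
            live = (a > EPS) & (a < 1.0 - EPS)
            g_net = g_a * config.gain * a * (1.0 - a) * live
            a_prev = hist[c - 1]
            grad_w += np.outer(g_net, a_prev)
            grad_b += g_net
            g_a = weights.w.T @ g_net
        # g_a now holds dE/d(init state); the init state depends on the
        # previous pattern's final activation through the carry-over
        g_carry = config.kappa * g_a

    grad_w[~t.trainable_mask] = 0.0
    return grad_w, grad_b, total_error


def train(
    weights: WeightSet, patterns: PatternSet, config: TrainingConfig
) -> tuple[WeightSet, TrainingTrace]:
    """Batch training for ``config.n_epochs`` epochs.

    Patterns are presented in fixed order within each epoch (the carry-over
    chain), gradients accumulated over the whole epoch, and a single
    delta-rule update (with optional momentum) applied at epoch end.  The
    fixed inter-valence links and the connectivity mask are preserved
    exactly.
    """
    w = weights.copy()
    errors = np.empty(config.n_epochs)
    vel_w = np.zeros_like(w.w)
    vel_b = np.zeros_like(w.bias)
    for epoch in range(config.n_epochs):
        gw, gb, err = gradient(w, patterns, config)
        if not np.isfinite(err):
            raise TrainingDiverged(epoch)
        errors[epoch] = err
        vel_w = config.momentum * vel_w - config.lr * gw
        vel_b = config.momentum * vel_b - config.lr * gb
        w.w += vel_w
        w.bias += vel_b
        # structural guarantees (vel is already masked via the gradient,
        # but enforce exactly)
        w.w[~w.topology.mask] = 0.0
        w.w[w.topology.fixed_mask] = w.inter_valence
    return w, TrainingTrace(errors, w)
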