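"""Paired-valence auto-associator: topology, activation, settling dynamics.

The intention system is a recurrent auto-associator over 14 beliefs, each
split into two processing units — one for the positive valence ("intend")
and one for the negative valence ("not intend").  Within each valence bank
the belief units are fully inter-connected; across banks the only
visible-visible links are the paired inter-valence connections (belief *i*
positive <-> belief *i* negative), which carry a fixed inhibitory weight.
Each valence bank additionally projects to and from its own bank of hidden
units.  External social context enters as a binary input pattern scaled by
a clamp strength and added to the net input of the visible units (soft
clamping).  Units update synchronously; the model settles for a fixed
number of cycles and the state at the final recorded cycle is read out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "EPS",
    "DEFAULT_GAIN",
    "NetworkTopology",
    "WeightSet",
    "ActivationState",
    "ClampedInput",
    "make_topology",
    "init_weights",
    "amplifier_init",
    "activation_fn",
    "net_input",
    "settle",
    "carryover_state",
    "save_weights",
    "load_weights",
]

#: activations are restricted to the open interval (0, 1); numerically they
#: are clipped to [EPS, 1 - EPS]
EPS = 1e-6

#: fixed inhibitory weight on every paired inter-valence connection
INTER_VALENCE_WEIGHT = -0.20

#: default logistic gain (the "modified" logistic: a steepened squashing
#: that lets a clamped external input drive units decisively off rest)
DEFAULT_GAIN = 5.0


@dataclass(frozen=True)
class NetworkTopology:
    """Unit layout and connectivity mask of the intention network.

    Unit ordering: intend bank (``0 .. n_beliefs-1``), not-intend bank
    (``n_beliefs .. 2*n_beliefs-1``), hidden bank A (attached to the intend
    bank), hidden bank B (attached to the not-intend bank).
    """

    n_beliefs: int
    n_hidden_per_bank: int
    #: ``mask[i, j]`` is True when a directed connection j -> i exists
    mask: np.ndarray = field(repr=False)
    #: True on the paired inter-valence links (fixed, not trainable)
    fixed_mask: np.ndarray = field(repr=False)

    @property
    def n_units(self) -> int:
        return 2 * self.n_beliefs + 2 * self.n_hidden_per_bank

    @property
    def n_visible(self) -> int:
        return 2 * self.n_beliefs

    @property
    def intend(self) -> slice:
        return slice(0, self.n_beliefs)

    @property
    def not_intend(self) -> slice:
        return slice(self.n_beliefs, 2 * self.n_beliefs)

    @property
    def hidden_a(self) -> slice:
        v = 2 * self.n_beliefs
        return slice(v, v + self.n_hidden_per_bank)

    @property
    def hidden_b(self) -> slice:
        v = 2 * self.n_beliefs
        return slice(v + self.n_hidden_per_bank, v + 2 * self.n_hidden_per_bank)

    @property
    def trainable_mask(self) -> np.ndarray:
        return self.mask & ~self.fixed_mask


def make_topology(n_beliefs: int = 14, n_hidden_per_bank: int = 10) -> NetworkTopology:
    """Build the paired-valence connectivity pattern.

    Within-bank visible units are fully connected (no self-connections);
    between banks only the paired inter-valence links exist; each hidden
    bank connects bidirectionally to every unit of its own visible bank and
    to nothing else.

    Parameters
    ----------
    n_beliefs
        Number of beliefs; each contributes one unit per valence bank.
    n_hidden_per_bank
        Hidden units attached to each visible bank.
    """
    if n_beliefs < 1:
        raise ValueError(f"n_beliefs must be >= 1, got {n_beliefs}")
    if n_hidden_per_bank < 0:
        raise ValueError(f"n_hidden_per_bank must be >= 0, got {n_hidden_per_bank}")

    nb, nh = n_beliefs, n_hidden_per_bank
    n = 2 * nb + 2 * nh
    mask = np.zeros((n, n), dtype=bool)
    fixed = np.zeros((n, n), dtype=bool)

    intend = np.arange(nb)
    notint = np.arange(nb, 2 * nb)
    hid_a = np.arange(2 * nb, 2 * nb + nh)
    hid_b = np.arange(2 * nb + nh, n)

    # full intra-bank connectivity among visible units of the same valence
    mask[np.ix_(intend, intend)] = True
    mask[np.ix_(notint, notint)] = True
    # paired inter-valence links, both directions, fixed
    mask[intend, notint] = True
    mask[notint, intend] = True
    fixed[intend, notint] = True
    fixed[notint, intend] = True
    # hidden banks attach only to their own visible bank, bidirectionally
    mask[np.ix_(hid_a, intend)] = True
    mask[np.ix_(intend, hid_a)] = True
    mask[np.ix_(hid_b, notint)] = True
    mask[np.ix_(notint, hid_b)] = True
    # no self-connections
    np.fill_diagonal(mask, False)

    mask.flags.writeable = False
    fixed.flags.writeable = False
    return NetworkTopology(nb, nh, mask, fixed)


@dataclass
class WeightSet:
    """Connection strengths and biases over a :class:`NetworkTopology`.

    ``w[i, j]`` is the strength of the directed connection j -> i; entries
    outside the connectivity mask are structurally zero.  The paired
    inter-valence links carry a fixed inhibitory strength and are excluded
    from training.  The bias is a trainable weight from a constant-1 unit.
    """

    topology: NetworkTopology
    w: np.ndarray
    bias: np.ndarray
    inter_valence: float = INTER_VALENCE_WEIGHT

    def validate(self) -> None:
        t = self.topology
        if self.w.shape != (t.n_units, t.n_units):
            raise ValueError("weight matrix shape does not match topology")
        if self.bias.shape != (t.n_units,):
            raise ValueError("bias vector length does not match topology")
        if not np.all(np.isfinite(self.w)) or not np.all(np.isfinite(self.bias)):
            raise ValueError("non-finite weight or bias")
        if np.any(self.w[~t.mask] != 0.0):
            raise ValueError("nonzero weight outside connectivity mask")
        if not np.allclose(self.w[t.fixed_mask], self.inter_valence):
            raise ValueError("inter-valence link deviates from its fixed strength")

    def copy(self) -> "WeightSet":
        return WeightSet(self.topology, self.w.copy(), self.bias.copy(), self.inter_valence)


def init_weights(
    topology: NetworkTopology,
    seed: int,
    scale: float = 0.1,
    inter_valence: float = INTER_VALENCE_WEIGHT,
) -> WeightSet:
    """Draw trainable weights i.i.d. uniform on [-scale, scale]; set the
    paired inter-valence links to their fixed strength."""
    if scale < 0:
        raise ValueError(f"scale must be >= 0, got {scale}")
    rng = np.random.default_rng(seed)
    n = topology.n_units
    w = np.zeros((n, n))
    tm = topology.trainable_mask
    w[tm] = rng.uniform(-scale, scale, size=int(tm.sum()))
    w[topology.fixed_mask] = inter_valence
    bias = rng.uniform(-scale, scale, size=n)
    return WeightSet(topology, w, bias, inter_valence)


@dataclass(frozen=True)
class ActivationState:
    """Per-unit activations, each in (0, 1), at a given settling cycle."""

    activations: np.ndarray
    cycle: int = 0

    def __post_init__(self):
        a = np.asarray(self.activations, dtype=float)
        if np.any(a < EPS - 1e-15) or np.any(a > 1 - EPS + 1e-15):
            raise ValueError("activations must lie in [EPS, 1 - EPS]")
        object.__setattr__(self, "activations", a)


@dataclass(frozen=True)
class ClampedInput:
    """A 2*n_beliefs binary external pattern plus its clamp strength.

    The first half addresses the intend bank, the second half the
    not-intend bank; patterns produced by the generators satisfy
    ``external[n_beliefs + i] == 1 - external[i]``.  Hidden units receive
    no external input.
    """

    external: np.ndarray
    clamp: float

    def __post_init__(self):
        x = np.asarray(self.external, dtype=float)
        if not np.all(np.isin(x, (0.0, 1.0))):
            raise ValueError("external pattern must be binary")
        if not 0.0 <= self.clamp <= 1.0:
            raise ValueError(f"clamp must be in [0, 1], got {self.clamp}")
        object.__setattr__(self, "external", x)

    @property
    def is_complemented(self) -> bool:
        half = self.external.size // 2
        return bool(np.all(self.external[half:] == 1 - self.external[:half]))


def activation_fn(net, gain: float = 1.0, eps: float = EPS):
    """Logistic squashing with configurable gain, clipped to [eps, 1-eps].

    The clipping keeps activations inside the open unit interval as the
    model requires.
    """
    if gain <= 0:
        raise ValueError(f"gain must be > 0, got {gain}")
    out = expit(gain * np.asarray(net, dtype=float))
    return np.clip(out, eps, 1.0 - eps)


def external_term(topology: NetworkTopology, inp: ClampedInput) -> np.ndarray:
    """Additive external contribution c*x_j for visible units, 0 for hidden."""
    if inp.external.size != topology.n_visible:
        raise ValueError(
            f"external pattern length {inp.external.size} != "
            f"{topology.n_visible} visible units"
        )
    ext = np.zeros(topology.n_units)
    ext[: topology.n_visible] = inp.clamp * inp.external
    return ext


def net_input(state: ActivationState, weights: WeightSet, inp: ClampedInput) -> np.ndarray:
    """Net input per unit: weighted sum of presynaptic activations, plus
    bias, plus the clamped external term on visible units."""
    t = weights.topology
    a = state.activations
    if a.size != t.n_units:
        raise ValueError(f"state has {a.size} units, topology has {t.n_units}")
    return weights.w @ a + weights.bias + external_term(t, inp)


def settle(
    weights: WeightSet,
    inp: ClampedInput,
    n_cycles: int = 9,
    init_state: ActivationState | None = None,
    gain: float = DEFAULT_GAIN,
) -> list[ActivationState]:
    """Synchronous settling: every cycle computes all net inputs from the
    previous cycle's activations and squashes them simultaneously.

    Returns the trajectory, one :class:`ActivationState` per cycle
    ``1 .. n_cycles``.
    """
    if n_cycles < 1:
        raise ValueError(f"n_cycles must be >= 1, got {n_cycles}")
    t = weights.topology
    if init_state is None:
        init_state = ActivationState(np.full(t.n_units, 0.5), cycle=0)
    a = init_state.activations
    ext = external_term(t, inp)
    traj: list[ActivationState] = []
    for cycle in range(1, n_cycles + 1):
        a = activation_fn(weights.w @ a + weights.bias + ext, gain=gain)
        traj.append(ActivationState(a, cycle=cycle))
    return traj


def amplifier_init(
    topology: NetworkTopology,
    seed: int,
    beta: float = 2.0,
    noise: float = 0.05,
    clamp: float = 0.5,
    rest: float = 0.5,
    inter_valence: float = INTER_VALENCE_WEIGHT,
) -> WeightSet:
    """Tied autoencoder-style starting weights for constraint learning.

    Each hidden bank is initialized as a linear reconstructor of its own
    visible bank: the visible-to-hidden weights hold ``n_hidden`` rows of an
    orthonormal basis of the bank (the uniform prevalence direction is
    always included, since overall belief prevalence is the dominant
    statistic of any input set) and the hidden-to-visible weights are the
    transpose scaled by ``beta``.  Biases center every unit at the resting
    activation, with the visible biases additionally offset by ``-clamp/2``
    so a clamped binary input drives units symmetrically around rest.
    Small uniform noise on all trainable weights breaks symmetry.

    This gives settling an initial signal-amplifying operating point, which
    plain gradient descent then reshapes toward the statistics of the
    training patterns.
    """
    rng = np.random.default_rng(seed)
    nb, nh = topology.n_beliefs, topology.n_hidden_per_bank
    n = topology.n_units
    w = np.zeros((n, n))
    b = np.zeros(n)
    if nh > 0:
        # orthonormal basis whose first direction is the uniform vector
        basis = np.concatenate(
            [np.ones((1, nb)) / np.sqrt(nb), rng.normal(size=(nb - 1, nb))]
        )
        q, _ = np.linalg.qr(basis.T)
        # fix sign so the first column is the +uniform direction
        if q[0, 0] < 0:
            q = -q
        proj = q[:, :nh].T  # nh x nb, rows orthonormal, row 0 = uniform
        for vis, hid in ((topology.intend, topology.hidden_a),
                         (topology.not_intend, topology.hidden_b)):
            w[hid, vis] = proj
            w[vis, hid] = beta * proj.T
    w[topology.fixed_mask] = inter_valence
    rest_vec = np.full(n, rest)
    b[:] = -(w @ rest_vec)
    b[: topology.n_visible] -= clamp / 2.0
    tm = topology.trainable_mask
    w[tm] += rng.uniform(-noise, noise, size=int(tm.sum()))
    w[~topology.mask] = 0.0
    w[topology.fixed_mask] = inter_valence
    return WeightSet(topology, w, b, inter_valence)


def save_weights(weights: WeightSet, path) -> None:
    """Serialize a WeightSet to JSON (exact round-trip via float repr).

    The file records the unit-index map alongside the matrices so the
    layout is self-describing.
    """
    import json

    t = weights.topology
    payload = {
        "n_beliefs": t.n_beliefs,
        "n_hidden_per_bank": t.n_hidden_per_bank,
        "unit_index_map": {
            "intend": [t.intend.start, t.intend.stop],
            "not_intend": [t.not_intend.start, t.not_intend.stop],
            "hidden_a": [t.hidden_a.start, t.hidden_a.stop],
            "hidden_b": [t.hidden_b.start, t.hidden_b.stop],
        },
        "inter_valence": weights.inter_valence,
        "w": weights.w.tolist(),
        "bias": weights.bias.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_weights(path) -> WeightSet:
    """Load a WeightSet written by :func:`save_weights`."""
    import json

    with open(path) as fh:
        payload = json.load(fh)
    topo = make_topology(payload["n_beliefs"], payload["n_hidden_per_bank"])
    ws = WeightSet(
        topo,
        np.asarray(payload["w"], dtype=float),
        np.asarray(payload["bias"], dtype=float),
        float(payload["inter_valence"]),
    )
    ws.validate()
    return ws


def carryover_state(
    prev_final: ActivationState | None,
    kappa: float = 0.1,
    rest: float = 0.5,
    n_units: int | None = None,
) -> ActivationState:
    """Initial state for the next pattern: resting level plus a small
    portion of the previous pattern's final activations.

    ``init = rest + kappa * (prev_final - rest)``; with no previous pattern
    the state is uniform at the resting level.
    """
    if not 0.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must be in [0, 1], got {kappa}")
    if not 0.0 < rest < 1.0:
        raise ValueError(f"rest must be in (0, 1), got {rest}")
    if prev_final is None:
        if n_units is None:
            raise ValueError("n_units required when there is no previous state")
        return ActivationState(np.full(n_units, rest), cycle=0)
    a = rest + kappa * (prev_final.activations - rest)
    return ActivationState(a, cycle=0)
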