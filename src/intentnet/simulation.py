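"""Simulation experiments: factorial input-set x clamp conditions and the
single-pass per-respondent run.

A *condition* fixes a trained weight set, an input-pattern source and a
clamp level.  Each condition comprises independent runs (a run is the
analog of one person): a run presents 50 input patterns for 10 epochs
(500 exposures), settling the network for 9 cycles per pattern with
activation carry-over chained across exposures, and records the cycle-9
state of every exposure.  Learning is always off during simulation.
Summaries report the mean activation of each visible valence bank over
all exposures and the spread of the per-run means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inputs import PatternSet, bernoulli_set, sample_run_patterns
from .network import DEFAULT_GAIN, ClampedInput, WeightSet, activation_fn, external_term

__all__ = [
    "SimulationDesign",
    "RunRecord",
    "run_condition",
    "bank_summary",
    "run_single_pass",
    "records_to_frame",
    "trajectory_to_frame",
]


@dataclass(frozen=True)
class SimulationDesign:
    """One condition of a simulation experiment.

    ``source`` is either a float p in [0, 1] — a probabilistic condition
    where a fresh Bernoulli(p) set is generated for every run — or a
    :class:`PatternSet` from which each run samples without replacement.
    """

    source: object
    clamp: float
    label: str = ""
    n_runs: int = 30
    n_epochs_per_run: int = 10
    n_patterns_per_run: int = 50
    n_cycles: int = 9
    record_cycle: int = 9
    kappa: float = 0.1
    rest: float = 0.5
    gain: float = DEFAULT_GAIN
    seed: int = 0

    def __post_init__(self):
        if self.record_cycle > self.n_cycles:
            raise ValueError("record cycle beyond the settling horizon")
        if isinstance(self.source, float) and not 0.0 <= self.source <= 1.0:
            raise ValueError("probabilistic source must be a probability")


@dataclass
class RunRecord:
    """Cycle-9 activations for every exposure of one run.

    ``states`` has shape (n_epochs * n_patterns, n_units); rows follow
    presentation order.  ``pattern_index`` and ``epoch`` identify each
    exposure.
    """

    run: int
    states: np.ndarray
    pattern_index: np.ndarray
    epoch: np.ndarray


def _run_patterns(design: SimulationDesign, rng, topology_n_beliefs: int) -> PatternSet:
    if isinstance(design.source, PatternSet):
        return sample_run_patterns(
            design.source, design.n_patterns_per_run, rng
        )
    p = float(design.source)
    return bernoulli_set(
        p,
        design.n_patterns_per_run,
        int(rng.integers(2**31)),
        n_beliefs=topology_n_beliefs,
    )


def run_condition(weights: WeightSet, design: SimulationDesign) -> list[RunRecord]:
    """Execute all runs of one condition with learning off.

    Carry-over chains across the exposures within a run and resets to the
    resting state between runs.  Per-run randomness derives reproducibly
    from the design's master seed.
    """
    t = weights.topology
    master = np.random.default_rng(design.seed)
    records: list[RunRecord] = []
    n_expo = design.n_epochs_per_run * design.n_patterns_per_run
    for run in range(design.n_runs):
        rng = np.random.default_rng(master.integers(2**31))
        pats = _run_patterns(design, rng, t.n_beliefs)
        states = np.empty((n_expo, t.n_units))
        pidx = np.empty(n_expo, dtype=int)
        eidx = np.empty(n_expo, dtype=int)
        a = np.full(t.n_units, design.rest)
        first = True
        k = 0
        for epoch in range(design.n_epochs_per_run):
            for j, pat in enumerate(pats.patterns):
                if first:
                    first = False
                else:
                    a = design.rest + design.kappa * (a - design.rest)
                ext = external_term(t, ClampedInput(pat, design.clamp))
                rec = None
                for cyc in range(1, design.n_cycles + 1):
                    a = activation_fn(
                        weights.w @ a + weights.bias + ext, gain=design.gain
                    )
                    if cyc == design.record_cycle:
                        rec = a
                states[k] = rec
                pidx[k] = j
                eidx[k] = epoch
                k += 1
        records.append(RunRecord(run, states, pidx, eidx))
    return records


def bank_summary(records: list[RunRecord], topology) -> pd.DataFrame:
    """Mean bank activation over all exposures and runs, with the standard
    deviation of the per-run means (population form, divisor n_runs).

    Returns a frame with one row per visible bank: columns ``bank``,
    ``mean``, ``sd``, ``n_runs``, ``n_exposures``.
    """
    if not records:
        raise ValueError("no run records")
    rows = []
    for bank, sl in (("intend", topology.intend), ("not_intend", topology.not_intend)):
        run_means = np.array([r.states[:, sl].mean() for r in records])
        rows.append(
            {
                "bank": bank,
                "mean": float(run_means.mean()),
                "sd": float(run_means.std(ddof=0)),
                "n_runs": len(records),
                "n_exposures": sum(r.states.shape[0] for r in records),
            }
        )
    return pd.DataFrame(rows)


def run_single_pass(
    weights: WeightSet,
    patterns: PatternSet,
    clamp: float,
    n_cycles: int = 9,
    record_cycle: int = 9,
    kappa: float = 0.1,
    rest: float = 0.5,
    gain: float = DEFAULT_GAIN,
) -> np.ndarray:
    """Present every pattern once, in order, with carry-over chaining and
    learning off; return the recorded-cycle state per pattern
    (shape: n_patterns x n_units)."""
    if len(patterns) == 0:
        raise ValueError("pattern set is empty")
    t = weights.topology
    out = np.empty((len(patterns), t.n_units))
    a = np.full(t.n_units, rest)
    first = True
    for i, pat in enumerate(patterns.patterns):
        if first:
            first = False
        else:
            a = rest + kappa * (a - rest)
        ext = external_term(t, ClampedInput(pat, clamp))
        rec = None
        for cyc in range(1, n_cycles + 1):
            a = activation_fn(weights.w @ a + weights.bias + ext, gain=gain)
            if cyc == record_cycle:
                rec = a
        out[i] = rec
    return out


def trajectory_to_frame(trajectory, run: int = 0, pattern_index: int = 0) -> pd.DataFrame:
    """Long-format export of a settling trajectory: one row per
    (cycle, unit); columns run, pattern_index, cycle, unit_index,
    activation."""
    rows = []
    for state in trajectory:
        a = getattr(state, "activations", state)
        cycle = getattr(state, "cycle", None)
        for j, v in enumerate(np.asarray(a)):
            rows.append({"run": run, "pattern_index": pattern_index,
                         "cycle": cycle, "unit_index": j, "activation": float(v)})
    return pd.DataFrame(rows)


def records_to_frame(records: list[RunRecord], condition: str = "") -> pd.DataFrame:
    """Long-format export: one row per (run, exposure, unit)."""
    frames = []
    for r in records:
        n_expo, n_units = r.states.shape
        frames.append(
            pd.DataFrame(
                {
                    "condition": condition,
                    "run": r.run,
                    "epoch": np.repeat(r.epoch, n_units),
                    "pattern_index": np.repeat(r.pattern_index, n_units),
                    "unit_index": np.tile(np.arange(n_units), n_expo),
                    "activation": r.states.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
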