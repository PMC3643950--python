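"""Canned experiment designs: the three simulation studies end to end.

Each function derives every source of randomness reproducibly from a
single master seed: weight initialization, training patterns, synthetic
survey generation, and per-run pattern sampling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .analysis import (
    crosstab,
    dummy_regression,
    exact_point_probability,
    freeman_halton_p,
    group_stats,
    score_states,
)
from .inputs import (
    SurveyGeneratorSpec,
    bernoulli_set,
    surveys_to_patternset,
    synth_survey,
)
from .learning import TrainingConfig, train
from .network import amplifier_init, make_topology
from .simulation import SimulationDesign, bank_summary, run_condition, run_single_pass

__all__ = [
    "train_probabilistic_weights",
    "train_group_weights",
    "simulation_one",
    "simulation_two",
    "simulation_three",
]


def _subseeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(2**31, size=n)]


def train_probabilistic_weights(seed: int, p: float = 0.25, n_patterns: int = 50,
                                config: TrainingConfig | None = None):
    """Learn internal constraints from a Bernoulli(p) input set (the
    "leaning against" context; p=0.25 is the canonical not-intend bias)."""
    s_init, s_pat = _subseeds(seed, 2)
    topo = make_topology()
    cfg = config or TrainingConfig()
    w0 = amplifier_init(topo, seed=s_init, clamp=cfg.clamp)
    pats = bernoulli_set(p, n_patterns, seed=s_pat)
    w, trace = train(w0, pats, cfg)
    return w, pats, trace


def train_group_weights(seed: int, group: str = "F10V",
                        config: TrainingConfig | None = None):
    """Learn internal constraints from a synthetic belief survey calibrated
    to one surveyed group; returns (weights, pattern set, responses, trace).
    """
    s_init, s_survey, s_transform = _subseeds(seed, 3)
    topo = make_topology()
    cfg = config or TrainingConfig()
    spec = SurveyGeneratorSpec.for_group(group, seed=s_survey)
    responses = synth_survey(spec)
    pats = surveys_to_patternset(responses, seed=s_transform, label=f"synth-{group}")
    w0 = amplifier_init(topo, seed=s_init, clamp=cfg.clamp)
    w, trace = train(w0, pats, cfg)
    return w, pats, responses, trace


def simulation_one(seed: int = 0, n_runs: int = 30,
                   clamps=(0.5, 0.1)) -> pd.DataFrame:
    """Input set (P25/P50/P75) x clamp factorial on the P25-trained weights."""
    s_train, s_cond = _subseeds(seed, 2)
    w, _, _ = train_probabilistic_weights(s_train)
    rng = np.random.default_rng(s_cond)
    rows = []
    for clamp in clamps:
        for p in (0.25, 0.50, 0.75):
            design = SimulationDesign(
                source=p, clamp=clamp, label=f"P{int(p * 100)}",
                n_runs=n_runs, seed=int(rng.integers(2**31)),
            )
            summary = bank_summary(run_condition(w, design), w.topology)
            for _, r in summary.iterrows():
                rows.append({"condition": design.label, "clamp": clamp, **r})
    return pd.DataFrame(rows)


def simulation_two(seed: int = 0, n_runs: int = 30,
                   clamps=(0.5, 0.1)) -> pd.DataFrame:
    """Synthetic-survey conditions (F10V/F12V/F12NV) plus P50/P75 on the
    synthetic-F10V-trained weights."""
    s_train, s_cond, *s_groups = _subseeds(seed, 5)
    w, _, _, _ = train_group_weights(s_train, "F10V")
    sources = []
    for grp, sg in zip(("F10V", "F12V", "F12NV"), s_groups):
        spec = SurveyGeneratorSpec.for_group(grp, seed=sg)
        ps = surveys_to_patternset(synth_survey(spec), seed=sg + 1,
                                   label=f"synth-{grp}")
        sources.append((f"synth-{grp}", ps))
    sources += [("P50", 0.50), ("P75", 0.75)]
    rng = np.random.default_rng(s_cond)
    rows = []
    for clamp in clamps:
        for label, src in sources:
            design = SimulationDesign(
                source=src, clamp=clamp, label=label,
                n_runs=n_runs, seed=int(rng.integers(2**31)),
            )
            summary = bank_summary(run_condition(w, design), w.topology)
            for _, r in summary.iterrows():
                rows.append({"condition": label, "clamp": clamp, **r})
    return pd.DataFrame(rows)


def simulation_three(seed: int = 0, clamp: float = 0.5) -> dict:
    """Single-pass run over the synthetic F10V respondents: one settled
    state, intention score and category per respondent, compared against
    the generated empirical-intention item."""
    s_train = _subseeds(seed, 1)[0]
    w, pats, responses, _ = train_group_weights(s_train, "F10V")
    states = run_single_pass(w, pats, clamp=clamp)
    results = score_states(states, w.topology)
    scores = np.array([r.score for r in results])
    model_cats = np.array([r.category for r in results])
    emp_cats = np.array([r.intention for r in responses])

    ct = crosstab(model_cats, emp_cats)
    try:
        tail_p = freeman_halton_p(ct, mode="enumerate", guard_limit=500_000)
        tail_mode = "enumerate"
    except ValueError:
        tail_p = freeman_halton_p(ct, mode="montecarlo", n_mc=200_000, seed=seed)
        tail_mode = "montecarlo"
    reg = dummy_regression(scores, emp_cats)
    stats = {
        "n": int(scores.size),
        "score_mean": float(scores.mean()),
        "score_sd": float(scores.std(ddof=1)),
        "score_range": [float(scores.min()), float(scores.max())],
        "point_probability": exact_point_probability(ct),
        "freeman_halton_p": float(tail_p),
        "freeman_halton_mode": tail_mode,
        "group_stats": group_stats(scores, emp_cats).to_dict(orient="records"),
        "regression": {
            "params": {k: float(v) for k, v in reg.params.items()},
            "se": {k: float(v) for k, v in reg.bse.items()},
            "adj_r_squared": reg.adj_r_squared,
            "f_statistic": reg.f_statistic,
            "df": [reg.df_model, reg.df_resid],
        },
    }
    return {
        "stats": stats,
        "scores": pd.DataFrame({
            "score": scores,
            "model_category": model_cats,
            "empirical_category": emp_cats,
        }),
        "crosstab": ct,
        "weights": w,
    }
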