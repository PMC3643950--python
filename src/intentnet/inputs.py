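"""Input-pattern construction: probabilistic sets, the survey-scale
transform, run-level sampling, and the synthetic belief-survey generator.

Input patterns are binary vectors of length ``2 * n_beliefs``: the first
half drives the intend bank and the second half is the bitwise complement
driving the not-intend bank.  Probabilistic sets (P25/P50/P75) draw each
positive-valence bit independently with a fixed probability.  Empirical-style
sets come from belief surveys: 14 items on an integer -8..8 scale, mapped to
bits by sign (zeros resolved by a fair coin).  Because the original school
survey is not public, a seeded synthetic generator emulates its structure,
calibrated so the mean positive-valence fraction matches a chosen target
(0.29 / 0.36 / 0.42 for the three surveyed groups).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PatternSet",
    "SurveyResponse",
    "SurveyGeneratorSpec",
    "bernoulli_set",
    "survey_to_pattern",
    "surveys_to_patternset",
    "synth_survey",
    "sample_run_patterns",
    "calibrated_positivity",
    "GROUP_MEAN_POSITIVITY",
    "read_survey_csv",
    "write_survey_csv",
    "read_patternset_csv",
    "write_patternset_csv",
]

#: printed mean positive-valence fractions of the three empirical groups
#: (female 10th-grade virgins, 12th-grade virgins, 12th-grade non-virgins)
GROUP_MEAN_POSITIVITY = {"F10V": 0.29, "F12V": 0.36, "F12NV": 0.42}

#: group sizes of the empirical subsamples the generator stands in for
GROUP_SIZES = {"F10V": 105, "F12V": 66, "F12NV": 73}

N_BELIEFS = 14

# Heterogeneous relative-positivity profile over the 14 beliefs (9 outcome
# beliefs, then 5 normative beliefs).  Qualitative shape only: hedonic /
# relational outcomes lean positive, health-risk outcomes strongly negative,
# referents mildly negative.  Scaled by `calibrated_positivity` to hit a
# target mean; never used unscaled.
_BASE_PROFILE = np.array(
    [0.80, 0.45, 0.85, 0.75, 0.06, 0.10, 0.30, 0.05, 0.25,
     0.20, 0.55, 0.50, 0.30, 0.35]
)


@dataclass(frozen=True)
class PatternSet:
    """An ordered collection of binary input patterns.

    ``patterns`` has shape (n_patterns, 2*n_beliefs); every row satisfies
    the bitwise-complement invariant when produced by the generators here.
    """

    patterns: np.ndarray
    label: str = ""
    seed: int | None = None

    def __post_init__(self):
        p = np.asarray(self.patterns, dtype=np.int8)
        if p.ndim != 2 or p.shape[1] % 2:
            raise ValueError("patterns must be 2-D with an even number of columns")
        if not np.all(np.isin(p, (0, 1))):
            raise ValueError("patterns must be binary")
        object.__setattr__(self, "patterns", p)

    def __len__(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_beliefs(self) -> int:
        return self.patterns.shape[1] // 2

    def complement_holds(self) -> bool:
        h = self.n_beliefs
        return bool(np.all(self.patterns[:, h:] == 1 - self.patterns[:, :h]))


@dataclass(frozen=True)
class SurveyResponse:
    """One respondent: 14 belief items in [-8, 8] and an optional 4-level
    intention rating (1 = NO!, 2 = no, 3 = yes, 4 = YES!)."""

    beliefs: tuple
    intention: int | None = None

    def __post_init__(self):
        b = tuple(int(v) for v in self.beliefs)
        if any(v < -8 or v > 8 for v in b):
            raise ValueError("belief values must be integers in [-8, 8]")
        if self.intention is not None and self.intention not in (1, 2, 3, 4):
            raise ValueError("intention must be in {1, 2, 3, 4}")
        object.__setattr__(self, "beliefs", b)


def bernoulli_set(
    p: float, n_patterns: int, seed: int, n_beliefs: int = N_BELIEFS, label: str = ""
) -> PatternSet:
    """Probabilistic input set: each positive-valence bit is an independent
    Bernoulli(p) draw; the second half is the bitwise complement."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    pos = (rng.random((n_patterns, n_beliefs)) < p).astype(np.int8)
    pats = np.hstack([pos, 1 - pos])
    return PatternSet(pats, label=label or f"P{int(round(p * 100))}", seed=seed)


def survey_to_pattern(response: SurveyResponse, rng) -> np.ndarray:
    """Map a -8..8 belief vector to a binary pattern, preserving valence
    but not magnitude.

    Positive values map to bit 1, negative to 0, and zeros are resolved by
    a fair coin; the negative-valence half is the logical complement.

    ``rng`` may be an integer seed or a ``numpy.random.Generator``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    b = np.asarray(response.beliefs)
    pos = np.where(b > 0, 1, 0).astype(np.int8)
    zeros = b == 0
    if zeros.any():
        pos[zeros] = (rng.random(int(zeros.sum())) < 0.5).astype(np.int8)
    return np.concatenate([pos, 1 - pos])


def surveys_to_patternset(
    responses, seed: int, label: str = ""
) -> PatternSet:
    """Apply the valence transform to a collection of survey responses."""
    rng = np.random.default_rng(seed)
    pats = np.array([survey_to_pattern(r, rng) for r in responses])
    return PatternSet(pats, label=label, seed=seed)


def calibrated_positivity(
    target_mean: float, zero_prob: float = 0.1, profile: np.ndarray | None = None
) -> np.ndarray:
    """Per-belief positivity probabilities with a heterogeneous profile,
    scaled so the expected positive-bit fraction equals ``target_mean``.

    A belief is zero with probability ``zero_prob`` (then a fair coin sets
    its bit), otherwise positive with the per-belief probability q_i, so the
    expected positive-bit fraction is ``(1 - zero_prob) * mean(q) +
    zero_prob / 2``; the profile is rescaled (with clipping at [0.01, 0.99]
    compensated iteratively) so this equals the target.
    """
    if profile is None:
        profile = _BASE_PROFILE
    q_target = (target_mean - 0.5 * zero_prob) / (1.0 - zero_prob)
    if not 0.0 < q_target < 1.0:
        raise ValueError(f"target mean {target_mean} infeasible with zero_prob {zero_prob}")
    q = profile.astype(float).copy()
    for _ in range(100):
        q *= q_target / q.mean()
        q = np.clip(q, 0.01, 0.99)
        if abs(q.mean() - q_target) < 1e-12:
            break
        # distribute the residual over entries with slack
        free = (q > 0.011) & (q < 0.989)
        if not free.any():
            break
        q[free] += (q_target - q.mean()) * q.size / free.sum()
        q = np.clip(q, 0.01, 0.99)
    return q


@dataclass(frozen=True)
class SurveyGeneratorSpec:
    """Configuration of the synthetic belief-survey generator.

    Belief signs are independent across items: zero with ``zero_prob``,
    otherwise positive with the per-belief probability; magnitudes are drawn
    from ``magnitude_probs`` over 1..8.  The 4-level intention item follows
    a cumulative-logit link on the respondent's realized mean positivity
    (fraction of positive beliefs, counting zeros as half).
    """

    positivity: np.ndarray
    n_respondents: int
    seed: int
    zero_prob: float = 0.1
    magnitude_probs: np.ndarray = field(
        default_factory=lambda: np.full(8, 1.0 / 8.0)
    )
    intention_slope: float = 8.0
    intention_thresholds: tuple = (2.24, 3.84, 6.92)

    def __post_init__(self):
        q = np.asarray(self.positivity, dtype=float)
        if np.any(q < 0) or np.any(q > 1):
            raise ValueError("positivity probabilities must be in [0, 1]")
        m = np.asarray(self.magnitude_probs, dtype=float)
        if m.size != 8 or np.any(m < 0) or not np.isclose(m.sum(), 1.0):
            raise ValueError("magnitude_probs must be 8 probabilities summing to 1")
        if not 0.0 <= self.zero_prob <= 1.0:
            raise ValueError("zero_prob must be in [0, 1]")
        object.__setattr__(self, "positivity", q)
        object.__setattr__(self, "magnitude_probs", m)

    @classmethod
    def for_group(
        cls, group: str, n_respondents: int | None = None, seed: int = 0, **kw
    ) -> "SurveyGeneratorSpec":
        """Spec calibrated to one of the surveyed groups (F10V/F12V/F12NV)."""
        target = GROUP_MEAN_POSITIVITY[group]
        zero_prob = kw.pop("zero_prob", 0.1)
        q = calibrated_positivity(target, zero_prob=zero_prob)
        if n_respondents is None:
            n_respondents = GROUP_SIZES[group]
        return cls(q, n_respondents, seed, zero_prob=zero_prob, **kw)


def _intention_category(rng, mean_positivity: float, slope: float, thresholds) -> int:
    # cumulative-logit: P(Y <= k) = sigmoid(tau_k - slope * pi)
    cum = 1.0 / (1.0 + np.exp(-(np.asarray(thresholds) - slope * mean_positivity)))
    u = rng.random()
    return int(np.searchsorted(cum, u) + 1)


def synth_survey(spec: SurveyGeneratorSpec) -> list[SurveyResponse]:
    """Generate a seeded synthetic belief survey per the spec."""
    rng = np.random.default_rng(spec.seed)
    n_items = spec.positivity.size
    out: list[SurveyResponse] = []
    for _ in range(spec.n_respondents):
        is_zero = rng.random(n_items) < spec.zero_prob
        sign = np.where(rng.random(n_items) < spec.positivity, 1, -1)
        mag = rng.choice(np.arange(1, 9), size=n_items, p=spec.magnitude_probs)
        beliefs = np.where(is_zero, 0, sign * mag)
        pi = (np.sum(beliefs > 0) + 0.5 * np.sum(beliefs == 0)) / n_items
        cat = _intention_category(
            rng, pi, spec.intention_slope, spec.intention_thresholds
        )
        out.append(SurveyResponse(tuple(int(v) for v in beliefs), cat))
    return out


def sample_run_patterns(pattern_set: PatternSet, n: int, seed) -> PatternSet:
    """Draw ``n`` distinct patterns (without replacement) in random order —
    the per-run sampling used with empirical-style input sets."""
    if n > len(pattern_set):
        raise ValueError(
            f"cannot sample {n} patterns without replacement from a set of "
            f"{len(pattern_set)}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(len(pattern_set), size=n, replace=False)
    return PatternSet(
        pattern_set.patterns[idx],
        label=pattern_set.label,
        seed=pattern_set.seed,
    )


# ---------------------------------------------------------------------------
# file formats

_BELIEF_COLS = [f"belief_{i}" for i in range(1, N_BELIEFS + 1)]


def write_survey_csv(responses, path) -> None:
    rows = []
    for r in responses:
        row = dict(zip(_BELIEF_COLS, r.beliefs))
        if r.intention is not None:
            row["intention"] = r.intention
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_survey_csv(path) -> list[SurveyResponse]:
    df = pd.read_csv(path)
    missing = [c for c in _BELIEF_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"survey file missing belief columns: {missing}")
    has_int = "intention" in df.columns
    out = []
    for _, row in df.iterrows():
        beliefs = tuple(int(row[c]) for c in _BELIEF_COLS)
        intention = int(row["intention"]) if has_int else None
        out.append(SurveyResponse(beliefs, intention))
    return out


def write_patternset_csv(pattern_set: PatternSet, path) -> None:
    h = pattern_set.n_beliefs
    cols = [f"pos_{i}" for i in range(1, h + 1)] + [f"neg_{i}" for i in range(1, h + 1)]
    pd.DataFrame(pattern_set.patterns, columns=cols).to_csv(path, index=False)


def read_patternset_csv(path, label: str = "") -> PatternSet:
    df = pd.read_csv(path)
    return PatternSet(df.to_numpy(dtype=np.int8), label=label)
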