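# Methods

## The model

`intentnet` implements behavioral intention as the settled state of a
parallel constraint-satisfaction network. Fourteen beliefs about a health
behavior (nine outcome beliefs, five normative beliefs) are each split
into two processing units: one carries the positive valence of the belief
("intend"), the other the negative valence ("not intend"). The 28 visible
units form two valence banks of 14. Connectivity is:

- full directed connectivity among the visible units **within** each
  valence bank (no self-connections);
- between banks, only the paired inter-valence links (belief *i* positive
  <-> belief *i* negative), fixed at an inhibitory strength of -0.20 and
  excluded from learning;
- a bank of 10 hidden units attached bidirectionally to each visible bank
  (hidden A <-> intend, hidden B <-> not-intend), no hidden-hidden links;
- a trainable bias on every unit (a weight from a constant-1 unit).

With the default sizes the network has 48 units.

Units take activations in the open interval (0, 1) (clipped numerically to
[1e-6, 1-1e-6]) and update **synchronously**: at each cycle every unit's
net input is computed from the previous cycle's activations, then all
units are squashed at once through a logistic with gain *g*,

    a_j(t+1) = sigma( g * [ sum_k w_jk a_k(t) + b_j + c * x_j ] ),

where `c` is the clamp strength and `x_j` the external input bit (visible
units only; hidden units receive no external input). The network settles
for 9 cycles and the cycle-9 state is the readout. A small portion
`kappa` of the final activations carries over into the initial state of
the next pattern, `init = rest + kappa * (final - rest)` with `rest = 0.5`
(the logistic of zero net input); the chain resets between runs.

### The "modified" logistic and its gain

The activation function is a standard logistic with a configurable gain
plus range clipping; the gain is the package's reading of the otherwise
unspecified "modification". The default is **g = 5**. The choice matters:
a 0.50-clamped input bit shifts a unit's net input by 0.5, which at unit
gain moves the activation by at most ~0.12 per cycle — far too little for
an external context ever to dominate the settled state. At g = 5 the same
input drives a centered unit to ~0.92/0.08, and the strong-clamp
conditions then track the external input statistics the way the reference
behavior requires. The gain was calibrated once against that qualitative
pattern and applies uniformly to training and simulation.

### External inputs

Input patterns are binary vectors of length 28: 14 positive-valence bits
and their bitwise complement. They enter the net input additively as
`c * x_j` (soft clamping); hard clamping is not used. Clamp levels 0.10
("weak") and 0.50 ("strong") are the two study conditions; 0.50 is also
used during training.

## Learning the internal constraints

Connection strengths among the beliefs are learned by the generalized
delta rule in batch mode for **200 epochs**: each epoch presents the
pattern set in fixed order (carry-over chained across patterns), the error
between the visible activations and the 28-bit pattern itself
(auto-association) is evaluated on **settling cycles 7-9**, gradients are
accumulated over the epoch, and one update is applied at epoch end.
Gradients come from backpropagation through the unrolled settling,
including through the carry-over links between successive patterns, so
they are exact for the chained forward pass (verified against central
finite differences to < 1e-4 relative error). Hidden units receive no
targets; masked-out and fixed inter-valence connections receive no
updates.

Defaults: learning rate 1e-5, momentum 0.5, cross-entropy error. Both the
rate and the error measure were chosen because the summed batch gradient
over 50 patterns x 3 cycles x 28 units is large: rates of the order 0.01+
saturate the network within a few epochs, and sum-squared error (also
available as `error_measure="sse"`) stalls in a marginal-statistics
solution. These are exposed on `TrainingConfig`.

### Initialization: the amplifier operating point

Training starts from `amplifier_init`, not from small uniform noise. Each
hidden bank is initialized as a tied linear reconstructor of its own
visible bank: the visible-to-hidden weights hold 10 rows of an orthonormal
basis of the 14-dimensional bank, the hidden-to-visible weights are the
transpose scaled by beta = 2, and biases center every unit at rest (visible
biases offset by -c/2 so a clamped binary bit drives its unit
symmetrically around rest). The uniform direction is always included in
the basis because overall belief prevalence is the dominant statistic of
any input set; leaving it to chance makes the reachable reconstruction
quality seed-dependent. Small uniform noise (±0.05) on all trainable
weights breaks symmetry.

The reason is structural. A unit's own external bit is its only reliable
information source under statistically unstructured input sets: no
self-connections exist, the paired link is fixed, and intra-bank weights
carry no signal when bits are independent. Signal amplification must
therefore run through the hidden bank (a rank-10 bottleneck), and 200
batch updates of gradient descent from random small weights reliably find
the marginal-statistics solution instead of the amplifying one. Started
at the amplifier operating point, training reshapes the weights toward the
statistics of the training set — producing exactly the learned negative
bias that the weak-clamp conditions are designed to reveal — while
retaining the input-tracking regime under strong clamping.

`init_weights` (plain uniform) is kept for small-network oracle work and
for experimentation.

## The simulation experiments

A *condition* is a trained weight set x an input source x a clamp level.
Each run (the analog of one person) presents 50 patterns for 10 epochs
(500 exposures) with carry-over chained within the run and reset between
runs; the cycle-9 state of every exposure is recorded; learning is off.
Probabilistic sources (P25/P50/P75: each positive bit i.i.d. Bernoulli(p))
generate a fresh 50-pattern set per run; survey-derived sources sample 50
respondents without replacement per run. Condition summaries report the
mean bank activation over all exposures and the standard deviation of the
per-run means with divisor n (population form).

The canned designs (`intentnet.experiments`):

1. **Probabilistic contexts.** Weights trained on a 50-pattern P25 set;
   conditions P25/P50/P75 x clamp {0.50, 0.10}.
2. **Survey contexts.** Weights trained on the synthetic 10th-grade-virgin
   survey (105 respondents); conditions: the three synthetic group sets
   plus P50 and P75, x clamp {0.50, 0.10}.
3. **Per-respondent prediction.** The same weights, single pass over the
   105 patterns at clamp 0.50: one settled state per respondent, scored as
   mean(intend) - mean(not-intend) in (-1, 1), binned at cut-points
   (-1,-0.5] -> 1, (-0.5,0] -> 2, (0,0.5] -> 3, (0.5,1) -> 4, and compared
   to the generated intention item by cross-tabulation (exact conditional
   test), per-category means, and dummy-coded OLS.

The acceptance tests run conditions at 10 runs instead of 30; with 500
exposures per run the condition means are stable to ~0.01, so the
qualitative and ±0.10 quantitative checks do not need the full 30.

## The synthetic belief survey

The original adolescent survey is not public, so a seeded generator
emulates its structure: 14 belief items on an integer -8..8 scale with a
zero midpoint, and a 4-level intention item. Per item, a respondent is
zero with probability 0.1, otherwise positive with a per-belief
probability q_i and magnitude uniform on 1..8. The q_i follow a fixed
heterogeneous profile (hedonic/relational outcome beliefs lean positive,
health-risk beliefs strongly negative, referent beliefs mildly negative)
rescaled so the expected positive-bit fraction — (1-z)·mean(q) + z/2,
counting the fair-coin resolution of zeros — hits the documented group
means exactly: 0.29 (10th-grade virgins), 0.36 (12th-grade virgins), 0.42
(12th-grade non-virgins). The intention item follows a cumulative-logit
link on the respondent's realized mean positivity, P(Y<=k) =
sigma(tau_k - s·pi) with slope s = 8 and thresholds (2.24, 3.84, 6.92),
set so that a group at mean positivity 0.29 answers roughly
(0.48, 0.34, 0.17, 0.01) across NO!/no/yes/YES! — matching the heavily
"no"-leaning distribution documented for that group.

What the generator does **not** emulate: item nonresponse, within-
respondent correlation across items beyond the shared positivity profile,
magnitude-valence dependence, survey weights, and the longitudinal
design. Consequently the per-respondent analysis (experiment 3) checks
the direction and ordering of the score-intention association, not the
original point estimates, which depend on the real belief covariance.

## The survey-to-pattern transform

Belief values map to bits by sign: positive -> 1, negative -> 0, zero ->
fair coin; the negative-valence half is the logical complement. Magnitude
is discarded. The transform is seeded; zeros make it stochastic.

## Exact contingency-table inference

For an R x C table with both margins fixed, the point probability is the
multivariate hypergeometric mass

    P(T) = (prod_i R_i!)(prod_j C_j!) / (N! prod_ij n_ij!),

accumulated in log space via log-gamma. The two-sided test value
(Freeman-Halton, the R x C generalization of Fisher's exact test) is the
sum of P over all margin-consistent tables with P(T) <= P(observed); ties
at the observed probability (within 1e-9 in log space) count toward the
tail. Enumeration is exhaustive with a guard limit (default 2e6 tables);
beyond it a Monte-Carlo mode estimates the same tail by sampling tables
with fixed margins through random permutation pairing. Both the point
mass and the tail sum are reported side by side: for the reference 4x4
table the tail sum (4.355e-4) is the published quantity, and the point
mass (3.38e-6) is orders of magnitude smaller.

## Numerical and design notes

- Activations clip at [1e-6, 1-1e-6]; the backward pass treats clipped
  units as having zero local derivative.
- Carry-over proportion kappa = 0.1 by default ("a small portion"),
  applied during both training and simulation; resting activation 0.5.
- Bidirectional visible<->hidden links are two independent directed
  weights (tied only at initialization, free to diverge in training).
- A score of exactly 0 falls in category 2; exactly -0.5 in category 1.
  +1 and -1 are unreachable with activations in the open unit interval.
- Dummy-coded OLS uses homoskedastic standard errors; the intercept equals
  the reference-category mean and coefficients equal group-mean contrasts
  (the one-way ANOVA identity, tested exactly).
- All randomness flows through `numpy.random.default_rng` seeds; every
  experiment derives sub-seeds reproducibly from one master seed.

## Known limitations

- The gain, learning rate and initialization define a working regime
  calibrated to the reference behavior; far outside it (e.g. unit gain, or
  rates above ~1e-3) training lands in marginal-statistics solutions.
- The rank-10 hidden bottleneck cannot amplify 4 of the 14 dimensions per
  bank, so strong-clamp tracking of extreme input sets saturates slightly
  below the external prediction (e.g. P75 intend mean ~0.70, not 0.75).
- Enumeration cost grows combinatorially with the margins; tables much
  larger than the reference one need the Monte-Carlo mode.
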