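# Methods

## The task and the model

`refgame` models multi-round pictorial reference games of the kind used to
study ad-hoc implicature (Frank & Goodman 2012; Degen & Franke 2016; Franke &
Degen 2016; Mayn & Demberg 2023): on each trial a comprehender sees three
referents, each a shape (circle, square, triangle) in a color (red, green,
blue), receives a single-feature message drawn from a restricted bank of four
(circle, triangle, red, green — blue and square are inexpressible), and picks
the referent the speaker intended.  Critical trials are *simple* (two literal
matches, only one of which lacks an alternative in-bank message; first-order
reasoning suffices) or *complex* (both matches have alternatives, only one of
which is contextually ambiguous; second-order reasoning is required).  With
the default bank and the 3×3 feature space there are exactly 8 simple and 8
complex message/referent patterns, which the package enumerates exhaustively.

The core model is a resource-rational performance account: a comprehender can
execute three deterministic interpretation strategies —

* **A** (literal): accept any referent matching the message;
* **B** (first-order): accept a matching referent only if no other bank
  message matches it;
* **C** (second-order): accept a matching referent only if every other
  matching bank message is contextually ambiguous —

and arbitrates between them with production-utility reinforcement learning in
the style of ACT-R's conflict-resolution mechanism.  A strategy *solves* a
trial when it accepts exactly one referent.  Strategy A runs first on every
trial as an automatic check.  On failure, the model penalizes the failed
strategy's start production and enters a selection cycle: the noisy-argmax of
the three utilities (independent logistic noise, scale `s = 0.6`) proposes a
strategy; an episodic memory check asks whether it already ran this trial; a
remembered repeat is penalized again (disengagement) and selection repeats; a
forgotten repeat is simply re-executed.  The cycle ends when a strategy
solves the trial or the internally perceived time — a pulse clock whose
pulses lengthen geometrically — exceeds the participant's persistence
threshold, at which point the model guesses: uniformly between the last
attempt's two candidates if it found exactly two, otherwise uniformly over
the literal matches.  Non-matching referents are never chosen.

Utility learning is the ACT-R temporal-difference rule: a reward event of
signed magnitude `m` at time `now` moves every production fired in the
current cycle by `U += lr * ((m - (now - t_fired)) - U)` with `lr = 0.2`.
Successes pay `+5`, failures `-F_NEG`.  Only the three strategy start
productions carry learned utilities (initial values `5.0, -2.5, -5.0` for A,
B, C).  Two parameters vary across individuals: the strength of negative
feedback `F_NEG` (0.5–10) and the persistence threshold (24–33 pulses).
These are the only individual-difference parameters; everything else is a
fixed constant of the model.

Two readings of the reward-crediting rule are implemented
(`credit_initial_pass`).  Under the default, the automatic first pass of A
fires the learnable start production, so A's utility is restored by the many
unambiguous fillers it solves and must be argued down afresh on every
critical trial — this is what makes low `F_NEG` a trap: the comprehender must
repeat and re-penalize the failing literal strategy several times per trial
before an alternative can win a selection.  The alternative reading (no
learnable production on the automatic pass) makes A's utility decay
monotonically over the experiment; it produces steeper adaptation but loses
the sustained guessing behaviour, and is retained as a configuration option.

## Timing model

Strategy execution time is the sum of lognormally jittered elementary steps
(attention shift 0.142 s, feature comparison 0.04 s, initiation 0.12 s, motor
response 0.335 s; `sdlog = 0.15`).  Iterating the message bank uses memory
retrieval (0.35 s, success probability 0.8 per message) and falls back to
visual scanning (0.70 s per message) for the rest of the attempt after the
first retrieval failure.  These constants are calibrated — once, by script —
so that mean execution times on randomly ordered critical trials are ≈1.0 s
(A), ≈3.5 s (B) and ≈4.0 s (C), the strategy-level means the model is built
around; the test suite pins them to ±0.25 s.  Fidelity to declarative-memory
dynamics is deliberately minimal (no base-level learning or spreading
activation): memory here is incidental to the resource-rational argument.

The selection cycle costs 0.1 s of production firings plus a 2.6 s episodic
memory-check episode per pass, with check reliability 0.65.  The large check
latency stands in for everything the disengagement impasse involves beyond
two production firings — near-threshold retrievals are slow, and the delay
also absorbs unmodelled processes such as trial-and-error reassembly of a
strategy.  Check failures re-execute the proposed strategy in full, which is
what produces the observed chains of one to four literal-strategy attempts
ending in a guess.

The pulse clock uses `pulse_start = 0.08 s` and multiplier 1.1 with no pulse
noise, so persistence thresholds 24–33 correspond to give-up times of about
7.1–17.8 s — room for two to four strategy attempts.  The persistence clock
can fire *mid-attempt*: the interrupted scan keeps the per-referent decisions
it completed (they are stored as the scan progresses), so an interrupted
attempt that had already isolated a unique referent still answers with it,
while anything less falls back to the guessing policy.  Without mid-attempt
interruption, high-persistence agents complete a second-order evaluation on
the *second* impasse of a trial from the very first trials, which
contradicts the observed chance-level early complex accuracy.

## Population simulation

Cohorts draw `F_NEG` and persistence from independent truncated normal
distributions (persistence is drawn continuously and rounded to the integer
lattice); because the fitted centers sit near the lower bounds, these behave
like half-normals there.  Two fitted presets ship with the package: the
population fit to the 66-trial no-feedback task of Mayn & Demberg
(μ_F = 1.04, σ_F = 4.74, μ_P = 24.56, σ_P = 6.86) and the fit to the
36-trial with-feedback variant (9.13, 4.67, 27.50, 6.66).  Grid mode iterates
the fixed 20 × 10 lattice (20 F_NEG values from 0.50 to 10.00, persistence
24–33) with a configurable number of replicates; 25 replicates per cell give
the canonical 5000-run survey.

The 66-trial design's published condition counts (12 simple + 12 complex +
35 unambiguous + 9 fully ambiguous) sum to 68; the literal 68-trial build is
the default and a `strict_66` flag drops two unambiguous fillers.  Fully
ambiguous fillers repeat a feature combination (two indistinguishable
matching referents), and are the only trials exempt from the
distinct-referent invariant.  Trial order and referent order are randomized
per participant and seed.  Trial-order quartiles are defined over the full
interleaved design, with summaries then restricted to critical trials.

## RSA baselines

The comparison models are heterogeneous Rational Speech Act mixtures.  The
listener hierarchy uses uniform referent priors (salience is out of scope):
L0 is uniform over literal matches; S1 softmaxes (inverse temperature α) the
literal listener's success probability over true messages; L1 and L2 invert
the speaker one level down by proportional Bayes.  An optional softmax at
the responding listener is available behind a flag but off by default — the
proportional posterior is the form under which the classic two-thirds/
one-third simple-trial prediction holds.  Referents with no true bank
message receive zero speaker likelihood.  As α → ∞ each listener's
maximally probable referents coincide with the corresponding strategy's
accepted set wherever that strategy solves the trial.

The two population models are a fixed three-type mixture (each participant
literal, first-order or second-order for the whole experiment) and a
flexible variant with separate type weights per experiment quarter.  Both
integrate a participant-level α over a population Gamma(shape, scale) by
32-node Gauss–Legendre quadrature on its quantiles, and perturb predicted
response probabilities with uniform response noise `p' = (1-ε)p + ε/3`.  The
exact form of "noise around the predicted probability" is underdetermined;
a truncated-normal smoothing variant is implemented alongside the default
uniform mixing, isolated behind one function.

## Fitting and model comparison

The adaptive model has no closed-form likelihood, so fitting is
simulation-based: the lattice is simulated once into a grid table of
response-role probabilities by condition × trial-order quartile (add-one
smoothing over replicate counts), and a participant's likelihood under
hyper-parameters (μ_F, σ_F, μ_P, σ_P) is the truncated-normal-weighted
mixture over cells of the product of cell probabilities over their trials.
F_NEG cells receive their bin's truncated-normal mass (edges midway between
lattice values); persistence cells receive the rounding mass of the
continuous truncated normal.  Quartile binning, rather than per-trial-index
probabilities, keeps grid variance manageable.

Sampling uses an affine-invariant ensemble sampler (differential-evolution
moves) under uniform priors on all free hyper-parameters, initialized near
the maximum of a coarse 384-point profile search; an empty dataset therefore
returns the prior.  Restricted variants pin σ_P (fixed persistence), σ_F
(fixed F_NEG), or both at a negligible 0.05.  Pointwise log-likelihood
contributions for cross-validation are sequential one-step-ahead predictive
log-probabilities within each participant; they sum exactly to the
participant's marginal log-likelihood, and the total is invariant to
participant order and to trial order within quartile bins.  Whether the
cross-validation unit should be the trial or the participant is genuinely
open; trial-level is the default and participant-level totals are a sum away.
Model comparison is PSIS-LOO expected log predictive density via arviz, with
models whose Pareto-k diagnostics exceed 0.7 reported but flagged
unreliable.

Numerical notes: likelihood mixtures are computed with log-sum-exp
throughout; the RSA response table exploits that L0 and L1 are α-free under
the proportional posterior, so only L2 is tabulated per quadrature node;
timed-out guesses trigger no utility update (the model has no internal
success signal for them) — whether they should is unknown and exposed as
`reward_guess`.

## What the synthetic data does and does not emulate

The generators reproduce the statistical structure the fitting machinery
needs: per-participant accuracies spreading from chance to ceiling and
clustering by condition, adaptation across trial order driven by utility
learning, and multimodal correct-response-time mixtures of fast strategy
solutions and slow timeout guesses.  They do not emulate perceptual or motor
noise beyond lognormal step jitter, fatigue or practice speed-up (production
compilation is deliberately absent), implicit-negation responding, salience
effects, or any dependence of behaviour on on-screen feedback (rewards are
internal; the 36-trial task's feedback manipulation is not modelled).  RSA
datasets carry placeholder response times, flagged in their provenance,
because the mixture baselines predict choices only.  Passing tests therefore
demonstrate internal consistency of the modelling pipeline and recovery of
known ground truth — not that the model family captures every aspect of
human data.

## Problem sizes

Default analysis sizes are chosen to be statistically meaningful at
interactive cost: cohort statistics use 228 participants per cohort averaged
over five seeded replicates; the corner analysis of the parameter lattice
uses 500 runs per corner; hyper-parameter recovery uses twenty 60-participant
cohorts on the 36-trial design against a 10-replicate grid; model recovery
uses twenty 50-participant replications.  The full 25-replicate 5000-run
survey grid is available through `refgame grid`.

## Known limitations

* With the published learning constants, no calibration of the free loop
  latencies jointly reproduces all eight cohort statistics of the reference
  simulation.  The shipped calibration matches the complex-condition means
  and quartiles, first-quartile simple accuracy, and both guess-pathway
  shares, but **underestimates the late-experiment surge in simple-trial
  accuracy** (and hence the simple-condition mean, ≈73% vs ≈82%).  The surge
  requires low-F_NEG agents to keep executing the first-order strategy at a
  high rate late in the task while early complex accuracy stays at chance
  and a third of correct answers still come from literal-chain guesses; in
  this architecture those demands pull the same loop constants in opposite
  directions.
* Because give-up times are bounded below by ≈7 s, timeout guesses are
  *slower* than strategy solutions here, so mean correct response times come
  out slightly slower on complex than simple trials — the opposite ordering
  from a regime in which guesses are fast.  Correct-RT distributions are
  still strongly multimodal.
* The grid likelihood conditions on quartile-binned response-role
  frequencies only; it cannot exploit response times or attempt traces.
* Persistence is weakly identified near the top of its range (behaviour
  saturates once two strategies fit in the budget), which widens μ_P
  posteriors.
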