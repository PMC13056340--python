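"""The adaptive comprehender: strategy selection, utility learning, guessing.

One simulated participant carries three production utilities, one per
interpretation strategy.  On every trial the literal strategy A runs first as
an automatic check.  Failures trigger a selection cycle: the strategy with the
highest utility after logistic noise is proposed; a memory check decides
whether it has already been attempted this trial, in which case the proposal
is penalized (disengagement) and selection repeats — unless the memory check
fails, in which case the already-attempted strategy is simply re-executed.
The cycle ends when some strategy solves the trial or the internally perceived
time (a geometrically slowing pulse clock) exceeds the participant's
persistence threshold, at which point the model guesses among the candidates
left by the last attempt.

Utility learning follows the ACT-R production-utility rule, a
temporal-difference variant: a reward event of signed magnitude ``m`` at time
``now`` updates every production that fired at time ``t`` in the current cycle
by ``U += lr * ((m - (now - t)) - U)``.  Successes pay ``+F_pos``, failures
``-F_NEG``.  Only the strategy start productions carry learned utilities;
every attempt (including the automatic first pass of A) fires its start
production, so A's utility is continually restored by the many unambiguous
fillers it solves, and must be penalized down afresh on each critical trial
before an alternative strategy can win selection.
"""

from __future__ import annotations

import dataclasses
import math
import random
from dataclasses import dataclass, field
from typing import Sequence

from .strategies import (
    DEFAULT_TIMING,
    STRATEGIES,
    Strategy,
    StrategyOutcome,
    TimingParams,
    run_strategy,
)
from .task_model import DEFAULT_BANK, ExperimentDesign, Message, Trial


@dataclass(frozen=True)
class AgentParams:
    """Individual parameters of one simulated participant.

    ``f_neg`` (strength of negative feedback, grid range 0.5–10) and
    ``persistence`` (pulse-count threshold, grid range 24–33) are the two
    individually varying parameters; everything else is a fixed constant of
    the model.
    """

    f_neg: float
    persistence: int
    f_pos: float = 5.0
    learning_rate: float = 0.2
    utility_noise_s: float = 0.6
    initial_utilities: tuple[float, float, float] = (5.0, -2.5, -5.0)
    timing: TimingParams = DEFAULT_TIMING
    pulse_start: float = 0.08  #: seconds, duration of the first pulse
    pulse_multiplier: float = 1.1  #: each pulse is this much longer than the last
    select_latency: float = 0.1  #: production cost of one selection-loop pass
    #: latency of the episodic memory check "have I tried this strategy?".
    #: Near-threshold retrievals are slow, so this dominates the loop cost.
    memcheck_latency: float = 2.6
    #: success probability of that episodic check; on failure the proposed
    #: strategy is re-executed in full even if it already ran this trial,
    #: which is what produces chains of repeated literal-strategy attempts.
    p_remember: float = 0.65
    reward_guess: bool = False  #: whether a timed-out guess triggers any reward
    #: whether the automatic first pass of A fires the learnable initiation
    #: production (True) or only a non-learnable automatic check (False)
    credit_initial_pass: bool = True
    #: if True, the disengagement penalty is discounted from the moment the
    #: penalized strategy's attempt started (real-time recency weighting), so
    #: re-penalization grows harsher as the trial drags on; if False the
    #: penalty applies at zero offset
    recency_discount: bool = False
    scan_order: str = "fixed"  #: "fixed" (left-to-right) or "random"

    def __post_init__(self) -> None:
        if self.f_neg <= 0:
            raise ValueError("f_neg must be positive")
        if self.persistence < 1 or self.persistence != int(self.persistence):
            raise ValueError("persistence must be a positive integer")
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")
        if self.utility_noise_s < 0:
            raise ValueError("utility_noise_s must be >= 0")

    def to_config(self) -> dict:
        """A plain-dict (YAML/JSON-ready) view of all agent parameters."""
        d = dataclasses.asdict(self)
        d["initial_utilities"] = list(self.initial_utilities)
        return d

    @classmethod
    def from_config(cls, config: dict) -> "AgentParams":
        d = dict(config)
        if isinstance(d.get("timing"), dict):
            d["timing"] = TimingParams(**d["timing"])
        if "initial_utilities" in d:
            d["initial_utilities"] = tuple(d["initial_utilities"])
        return cls(**d)


@dataclass
class UtilityState:
    """Per-participant learning state carried across trials."""

    utilities: dict[Strategy, float]
    fired: list[tuple[Strategy, float]] = field(default_factory=list)
    attempted: set[Strategy] = field(default_factory=set)

    @classmethod
    def fresh(cls, params: AgentParams) -> "UtilityState":
        return cls(utilities=dict(zip(STRATEGIES, params.initial_utilities)))

    def begin_trial(self) -> None:
        self.fired.clear()
        self.attempted.clear()


@dataclass
class TrialResult:
    """Observable (and trace-level) outcome of one trial."""

    trial_index: int
    condition: str
    attempts: list[tuple[str, float, bool]]  #: (strategy, duration, solved)
    response_index: int
    response_role: str
    correct: bool
    rt: float
    guessed: bool

    @property
    def n_attempts(self) -> int:
        return len(self.attempts)

    @property
    def strategies_tried(self) -> str:
        return ",".join(a[0] for a in self.attempts)


def noisy_select(
    utilities: dict[Strategy, float] | Sequence[float],
    noise_s: float,
    rng: random.Random,
) -> Strategy:
    """Argmax of utility plus independent logistic noise of scale ``noise_s``."""
    if not isinstance(utilities, dict):
        utilities = dict(zip(STRATEGIES, utilities))
    best, best_u = None, -math.inf
    for strat, u in utilities.items():
        if noise_s > 0:
            p = rng.random()
            u = u + noise_s * math.log(p / (1.0 - p))
        if u > best_u:
            best, best_u = strat, u
    return best


def update_utilities(
    state: UtilityState,
    signed_magnitude: float,
    now: float,
    learning_rate: float,
) -> None:
    """Apply a reward event to every production fired in the current cycle.

    The effective (discounted) reward for a production fired at ``t`` is the
    signed magnitude minus the temporal offset ``now - t``; utilities move a
    fraction ``learning_rate`` of the way toward it.  Clears the cycle's
    firing record.
    """
    if not state.fired:
        raise ValueError("no productions fired in the current cycle")
    for strat, t in state.fired:
        reward = signed_magnitude - (now - t)
        u = state.utilities[strat]
        state.utilities[strat] = u + learning_rate * (reward - u)
    state.fired.clear()


def pulses_elapsed(
    seconds: float, pulse_start: float = 0.1, pulse_multiplier: float = 1.1
) -> int:
    """Completed pulses of the internal clock after ``seconds`` of real time.

    Pulse ``n`` lasts ``pulse_start * pulse_multiplier**(n-1)`` seconds, so the
    perceived passage of time slows down as a trial drags on.
    """
    if seconds < 0:
        raise ValueError("seconds must be >= 0")
    if pulse_multiplier == 1.0:
        return int(seconds / pulse_start)
    # cumulative time of n pulses: pulse_start * (m^n - 1) / (m - 1)
    x = seconds * (pulse_multiplier - 1.0) / pulse_start + 1.0
    return max(0, int(math.log(x) / math.log(pulse_multiplier) + 1e-12))


def seconds_for_pulses(
    n: int, pulse_start: float = 0.1, pulse_multiplier: float = 1.1
) -> float:
    """Real time at which the ``n``-th pulse completes (inverse of pulses_elapsed)."""
    if pulse_multiplier == 1.0:
        return n * pulse_start
    return pulse_start * (pulse_multiplier**n - 1.0) / (pulse_multiplier - 1.0)


def guess(
    trial: Trial, last_outcome: StrategyOutcome | None, rng: random.Random
) -> int:
    """Timed-out response: the last attempt's two candidates if it found exactly
    two, otherwise any literally-matching referent, uniformly at random."""
    matches = trial.literal_matches()
    if not matches:
        raise ValueError("trial has no literal match")
    if last_outcome is not None and len(last_outcome.accepted) == 2:
        return rng.choice(sorted(last_outcome.accepted))
    return rng.choice(matches)


def _scan_order(params: AgentParams, rng: random.Random) -> Sequence[int]:
    if params.scan_order == "random":
        order = [0, 1, 2]
        rng.shuffle(order)
        return order
    return (0, 1, 2)


def run_trial(
    state: UtilityState,
    params: AgentParams,
    trial: Trial,
    rng: random.Random,
    trial_index: int = 0,
    bank: Sequence[Message] = DEFAULT_BANK,
) -> TrialResult:
    """Run one trial, mutating ``state`` (utilities persist across trials)."""
    state.begin_trial()
    clock = 0.0
    attempts: list[tuple[str, float, bool]] = []
    last: StrategyOutcome | None = None
    timing = params.timing

    def jitter(base: float) -> float:
        if timing.noise_sd > 0 and base > 0:
            return rng.lognormvariate(math.log(base), timing.noise_sd)
        return base

    def timed_out() -> bool:
        return (
            pulses_elapsed(clock, params.pulse_start, params.pulse_multiplier)
            >= params.persistence
        )

    def respond(index: int, guessed: bool) -> TrialResult:
        role = trial.role_of(index)
        return TrialResult(
            trial_index=trial_index,
            condition=trial.condition,
            attempts=attempts,
            response_index=index,
            response_role=role,
            correct=role == "target",
            rt=clock,
            guessed=guessed,
        )

    budget = seconds_for_pulses(
        params.persistence, params.pulse_start, params.pulse_multiplier
    )
    strategy = Strategy.A
    initial = True
    attempt_start: dict[Strategy, float] = {}
    while True:
        t_fire = clock
        attempt_start[strategy] = t_fire
        outcome = run_strategy(
            strategy,
            trial,
            bank,
            timing,
            rng,
            _scan_order(params, rng),
            deadline=budget - t_fire,
        )
        clock += outcome.duration
        attempts.append((strategy.value, outcome.duration, outcome.solved))
        if outcome.interrupted:
            # the persistence threshold fired mid-scan; decisions completed
            # before the interruption are retained: a unique accepted referent
            # is still a reasoned response, otherwise the model guesses
            clock += jitter(timing.t_motor)
            if len(outcome.accepted) == 1:
                return respond(next(iter(outcome.accepted)), guessed=False)
            pool = outcome if len(outcome.accepted) == 2 else last
            return respond(guess(trial, pool, rng), guessed=True)
        state.attempted.add(strategy)
        last = outcome

        # the strategy's initiation production fired at attempt onset; the
        # reward event at attempt end credits/penalizes it with the temporal
        # discount.  The automatic first pass of A only fires the learnable
        # initiation production if credit_initial_pass is set.
        if not initial or params.credit_initial_pass:
            state.fired.append((strategy, t_fire))
        initial = False
        if outcome.solved:
            if state.fired:
                update_utilities(state, params.f_pos, clock, params.learning_rate)
            return respond(next(iter(outcome.accepted)), guessed=False)
        if state.fired:
            update_utilities(state, -params.f_neg, clock, params.learning_rate)

        # selection / disengagement cycle
        while True:
            if timed_out():
                clock += jitter(timing.t_motor)
                return respond(guess(trial, last, rng), guessed=True)
            proposal = noisy_select(state.utilities, params.utility_noise_s, rng)
            clock += jitter(params.select_latency)  # selection productions
            clock += jitter(params.memcheck_latency)  # memory: tried already?
            if proposal in state.attempted and rng.random() < params.p_remember:
                # remembered the failed attempt: penalize and re-select
                t0 = attempt_start[proposal] if params.recency_discount else clock
                state.fired.append((proposal, t0))
                update_utilities(state, -params.f_neg, clock, params.learning_rate)
            else:
                strategy = proposal
                break


def run_experiment(
    params: AgentParams,
    design: ExperimentDesign,
    rng: random.Random | int | None = None,
) -> list[TrialResult]:
    """Run one participant through a full design with persistent utilities."""
    if not isinstance(rng, random.Random):
        rng = random.Random(rng)
    state = UtilityState.fresh(params)
    return [
        run_trial(state, params, trial, rng, trial_index=i)
        for i, trial in enumerate(design.trials)
    ]
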