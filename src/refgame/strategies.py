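"""The three interpretation strategies and their execution-time model.

Each strategy is a deterministic accept/reject predicate applied to each
referent in turn (left to right), corresponding to increasingly sophisticated
comprehension:

* **A** (literal): accept any referent that literally matches the message.
* **B** (first-order): accept a matching referent only if no *other* bank
  message matches it — a literal speaker would most likely have used the
  observed message for such a referent.
* **C** (second-order): accept a matching referent only if every other bank
  message matching it is contextually ambiguous (matches some other referent
  on the display) — a pragmatic speaker would have preferred the unambiguous
  alternative otherwise.

A strategy *solves* a trial when it accepts exactly one referent.  Execution
duration is stochastic: each elementary step (attention shift, feature
comparison, memory retrieval or visual scan of a bank message, motor response)
takes a lognormally jittered latency, and iteration over the message bank uses
memory retrieval while it keeps succeeding, falling back to visual scanning
for the rest of the attempt after the first retrieval failure.
"""

from __future__ import annotations

import enum
import math
import random
from dataclasses import dataclass
from typing import Sequence

from .task_model import (
    DEFAULT_BANK,
    Message,
    Referent,
    Trial,
    alternative_messages,
    literal_match,
)


class Strategy(str, enum.Enum):
    A = "A"
    B = "B"
    C = "C"

    @property
    def description(self) -> str:
        return {
            "A": "literal: find matches",
            "B": "first-order: find matches w/o other matching messages",
            "C": "second-order: find matches w/o other unambiguous messages",
        }[self.value]


STRATEGIES = (Strategy.A, Strategy.B, Strategy.C)


@dataclass(frozen=True)
class TimingParams:
    """Per-step latency constants (seconds) for strategy execution.

    Defaults are calibrated so that mean execution durations on randomly
    ordered critical trials are ~1.0 s (A), ~3.5 s (B) and ~4.0 s (C),
    the strategy-level means the adaptive model is built around.
    """

    t_init: float = 0.12  #: strategy-initiation production
    t_attend: float = 0.142  #: attention shift to (and encoding of) a referent
    t_compare: float = 0.04  #: a single feature comparison
    t_retrieve: float = 0.35  #: successful memory retrieval of a bank message
    t_scan: float = 0.70  #: visual re-scan of a bank message after retrieval failure
    t_motor: float = 0.335  #: response preparation and keypress
    p_retrieve: float = 0.8  #: per-message retrieval success probability
    noise_sd: float = 0.15  #: lognormal jitter (sdlog) applied to every step

    def __post_init__(self) -> None:
        for name in (
            "t_init",
            "t_attend",
            "t_compare",
            "t_retrieve",
            "t_scan",
            "t_motor",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.p_retrieve <= 1.0:
            raise ValueError("p_retrieve must be in [0, 1]")


DEFAULT_TIMING = TimingParams()


@dataclass
class StrategyOutcome:
    """Result of one strategy attempt on a trial.

    ``interrupted`` marks an attempt cut short by the persistence clock; its
    ``accepted`` set then holds the decisions for the referents that were
    fully evaluated before the interruption, and ``solved`` is always False
    (the scan did not run to completion).
    """

    strategy: Strategy
    accepted: frozenset[int]  #: referent positions accepted by the predicate
    solved: bool
    duration: float  #: seconds from initiation to (attempted) keypress
    interrupted: bool = False

    def __post_init__(self) -> None:
        if self.interrupted:
            if self.solved:
                raise ValueError("an interrupted attempt cannot be solved")
        elif self.solved != (len(self.accepted) == 1):
            raise ValueError("solved must hold iff exactly one referent accepted")


def accept_literal(message: Message, referent: Referent) -> bool:
    """Strategy A predicate: match(M, R)."""
    return literal_match(message, referent)


def accept_first_order(
    message: Message, referent: Referent, bank: Sequence[Message] = DEFAULT_BANK
) -> bool:
    """Strategy B predicate: match(M, R) and no other bank message matches R."""
    return literal_match(message, referent) and not alternative_messages(
        message, referent, bank
    )


def accept_second_order(
    message: Message,
    referent: Referent,
    trial: Trial,
    bank: Sequence[Message] = DEFAULT_BANK,
) -> bool:
    """Strategy C predicate: match(M, R), and every other bank message matching
    R also matches at least one other referent on the display."""
    if not literal_match(message, referent):
        return False
    others = list(trial.referents)
    others.remove(referent)  # drop one copy only, in case of duplicated referents
    for m in alternative_messages(message, referent, bank):
        if not any(literal_match(m, r) for r in others):
            return False
    return True


def accepts(
    strategy: Strategy,
    message: Message,
    referent: Referent,
    trial: Trial,
    bank: Sequence[Message] = DEFAULT_BANK,
) -> bool:
    if strategy is Strategy.A:
        return accept_literal(message, referent)
    if strategy is Strategy.B:
        return accept_first_order(message, referent, bank)
    return accept_second_order(message, referent, trial, bank)


class _Clock:
    """Accumulates lognormally jittered step latencies."""

    def __init__(self, timing: TimingParams, rng: random.Random):
        self.timing = timing
        self.rng = rng
        self.elapsed = 0.0

    def step(self, base: float) -> None:
        if base <= 0:
            return
        sd = self.timing.noise_sd
        if sd > 0:
            self.elapsed += self.rng.lognormvariate(math.log(base), sd)
        else:
            self.elapsed += base


def run_strategy(
    strategy: Strategy,
    trial: Trial,
    bank: Sequence[Message] = DEFAULT_BANK,
    timing: TimingParams = DEFAULT_TIMING,
    rng: random.Random | None = None,
    scan_order: Sequence[int] = (0, 1, 2),
    deadline: float | None = None,
) -> StrategyOutcome:
    """Execute one strategy attempt, returning the accepted set and its duration.

    Acceptance is deterministic (the predicates above); only the duration is
    stochastic.  Referents are scanned in ``scan_order`` (left-to-right by
    default).  For strategies B and C the iteration over alternative bank
    messages starts in memory-retrieval mode and degrades to visual scanning
    after the first retrieval failure; because referents carry only two
    features, the iteration stops once the referent's single possible
    alternative message has been found and evaluated.

    If ``deadline`` is given and the accumulated duration crosses it, the
    attempt is abandoned mid-scan: per-referent decisions completed so far are
    kept (they were stored as the scan progressed) but the attempt counts as
    interrupted, not solved.
    """
    rng = rng if rng is not None else random.Random()
    clock = _Clock(timing, rng)
    message = trial.message
    clock.step(timing.t_init)

    retrieval_mode = True

    def message_access() -> None:
        nonlocal retrieval_mode
        if retrieval_mode and rng.random() < timing.p_retrieve:
            clock.step(timing.t_retrieve)
        else:
            retrieval_mode = False
            clock.step(timing.t_scan)

    accepted: set[int] = set()
    interrupted = False
    for pos in scan_order:
        if deadline is not None and clock.elapsed >= deadline:
            interrupted = True
            break
        referent = trial.referents[pos]
        clock.step(timing.t_attend)
        clock.step(timing.t_compare)
        if not literal_match(message, referent):
            continue
        if strategy is Strategy.A:
            if deadline is not None and clock.elapsed > deadline:
                interrupted = True  # gave up mid-evaluation: decision discarded
                break
            accepted.add(pos)
            continue

        ok = True
        for alt in bank:
            if alt == message:
                continue
            message_access()
            clock.step(timing.t_compare)
            if not literal_match(alt, referent):
                continue
            # found the referent's (unique) alternative message
            if strategy is Strategy.B:
                ok = False
            else:  # Strategy C: is the alternative contextually ambiguous?
                ambiguous = False
                for other_pos in scan_order:
                    if other_pos == pos:
                        continue
                    clock.step(timing.t_attend)
                    clock.step(timing.t_compare)
                    if literal_match(alt, trial.referents[other_pos]):
                        ambiguous = True
                        break
                if not ambiguous:
                    ok = False
            break  # two-feature referents have at most one alternative message
        if deadline is not None and clock.elapsed > deadline:
            # gave up mid-evaluation: this referent's decision is discarded
            interrupted = True
            break
        if ok:
            accepted.add(pos)

    if not interrupted:
        clock.step(timing.t_motor)
    duration = clock.elapsed
    if interrupted and deadline is not None:
        duration = min(duration, deadline)
    return StrategyOutcome(
        strategy=strategy,
        accepted=frozenset(accepted),
        solved=not interrupted and len(accepted) == 1,
        duration=duration,
        interrupted=interrupted,
    )


def sample_durations(
    strategy: Strategy,
    n: int,
    timing: TimingParams = DEFAULT_TIMING,
    seed: int | None = None,
    bank: Sequence[Message] = DEFAULT_BANK,
) -> list[float]:
    """Draw *n* execution durations on randomly ordered critical trials.

    Used for timing calibration: scenarios are drawn uniformly from the
    canonical simple and complex scenarios with shuffled referent order.
    """
    from .task_model import enumerate_critical_scenarios

    rng = random.Random(seed)
    scenarios = enumerate_critical_scenarios(bank)
    out = []
    for _ in range(n):
        s = rng.choice(scenarios)
        trial = s.trial()
        order = [0, 1, 2]
        rng.shuffle(order)
        trial = trial.reordered(order)
        out.append(run_strategy(strategy, trial, bank, timing, rng).duration)
    return out
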