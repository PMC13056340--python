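"""Reference-game world: referents, messages, trial classification, experiment designs.

The games modelled here follow the two-feature design used in multi-round
reference-game studies (Frank & Goodman 2012; Degen & Franke 2016; Mayn &
Demberg 2023): three candidate referents, each a combination of a shape
(circle, square, triangle) and a color (red, green, blue), and a single-feature
message drawn from a restricted bank of four messages.  With the default bank
the color blue and the shape square can never be expressed.

Critical trials come in two flavours:

* **simple** — two referents literally match the message but only one of them
  lacks an alternative in-bank message; first-order reasoning about a literal
  speaker suffices to pick it out.
* **complex** — both matching referents have an alternative in-bank message,
  but only one of those alternatives is contextually ambiguous; identifying
  that referent requires second-order reasoning about a pragmatic speaker.

Everything else is either *unambiguous* (exactly one literal match) or
*ambiguous* (no uniquely pragmatically-favoured referent).
"""

from __future__ import annotations

import functools
import itertools
import random
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import pandas as pd

SHAPES = ("circle", "square", "triangle")
COLORS = ("red", "green", "blue")

CONDITIONS = ("unambiguous", "simple", "complex", "ambiguous")

TARGET = "target"
COMPETITOR = "competitor"
DISTRACTOR = "distractor"


class Referent(NamedTuple):
    """A two-feature referent (one shape, one color)."""

    shape: str
    color: str

    def feature(self, dimension: str) -> str:
        return self.shape if dimension == "shape" else self.color

    @property
    def code(self) -> str:
        return f"{self.shape}-{self.color}"

    @classmethod
    def from_code(cls, code: str) -> "Referent":
        shape, color = code.split("-")
        if shape not in SHAPES or color not in COLORS:
            raise ValueError(f"bad referent code {code!r}")
        return cls(shape, color)


class Message(NamedTuple):
    """A single-feature message (one value on one dimension)."""

    dimension: str
    value: str

    @classmethod
    def of(cls, value: str) -> "Message":
        if value in SHAPES:
            return cls("shape", value)
        if value in COLORS:
            return cls("color", value)
        raise ValueError(f"unknown feature value {value!r}")


#: The standard four-message bank: blue and square are inexpressible.
DEFAULT_BANK: tuple[Message, ...] = (
    Message.of("circle"),
    Message.of("triangle"),
    Message.of("red"),
    Message.of("green"),
)

ALL_REFERENTS: tuple[Referent, ...] = tuple(
    Referent(s, c) for s in SHAPES for c in COLORS
)


@dataclass(frozen=True)
class MessageBank:
    """An ordered, duplicate-free bank of messages available to the speaker."""

    messages: tuple[Message, ...] = DEFAULT_BANK

    def __post_init__(self) -> None:
        if len(set(self.messages)) != len(self.messages):
            raise ValueError("message bank must not contain duplicates")

    def __iter__(self):
        return iter(self.messages)

    def __len__(self) -> int:
        return len(self.messages)

    def __contains__(self, message: Message) -> bool:
        return message in self.messages

    def expressible_values(self) -> set[str]:
        return {m.value for m in self.messages}


def literal_match(message: Message, referent: Referent) -> bool:
    """True iff the referent's value on the message's dimension equals the message."""
    return referent.feature(message.dimension) == message.value


def matching_messages(referent: Referent, bank: Sequence[Message]) -> list[Message]:
    """All bank messages that literally match *referent*."""
    return [m for m in bank if literal_match(m, referent)]


def alternative_messages(
    message: Message, referent: Referent, bank: Sequence[Message]
) -> list[Message]:
    """In-bank messages other than *message* that match *referent*."""
    return [m for m in bank if m != message and literal_match(m, referent)]


@dataclass(frozen=True)
class Trial:
    """One game round: a message plus an ordered triple of referents with roles.

    ``roles`` maps each referent position (0..2) to target/competitor/distractor.
    ``allow_duplicates`` is set only for fully-ambiguous filler trials, which may
    repeat a feature combination.
    """

    message: Message
    referents: tuple[Referent, Referent, Referent]
    condition: str
    roles: tuple[str, str, str]
    allow_duplicates: bool = False

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if len(self.referents) != 3:
            raise ValueError("a trial has exactly three referents")
        if not self.allow_duplicates and len(set(self.referents)) != 3:
            raise ValueError("referents must be pairwise distinct")
        if not any(literal_match(self.message, r) for r in self.referents):
            raise ValueError("message must literally match at least one referent")

    @property
    def target_index(self) -> int:
        return self.roles.index(TARGET)

    def literal_matches(self) -> list[int]:
        return [
            i for i, r in enumerate(self.referents) if literal_match(self.message, r)
        ]

    def role_of(self, index: int) -> str:
        return self.roles[index]

    def reordered(self, order: Sequence[int]) -> "Trial":
        refs = tuple(self.referents[i] for i in order)
        roles = tuple(self.roles[i] for i in order)
        return replace(self, referents=refs, roles=roles)


class InvalidTrialError(ValueError):
    """Raised when a message/referent combination does not form a valid trial."""


def classify_trial(
    message: Message,
    referents: Sequence[Referent],
    bank: Sequence[Message] = DEFAULT_BANK,
) -> tuple[str, tuple[str, str, str]]:
    """Classify a message/referent-triple into a condition and assign roles.

    Returns ``(condition, roles)`` where roles is aligned with referent order.

    The taxonomy follows the standard multi-round reference-game conditions:
    exactly one literal match is *unambiguous*; two matches where exactly one
    matching referent has no alternative in-bank message is *simple* (that
    referent is the target); two matches where both have alternatives and
    exactly one alternative is contextually ambiguous is *complex* (the
    referent with the ambiguous alternative is the target); everything else
    with two or more matches is *ambiguous*.
    """
    referents = tuple(referents)
    matches = [i for i, r in enumerate(referents) if literal_match(message, r)]
    if not matches:
        raise InvalidTrialError("message matches no referent")

    roles = [DISTRACTOR, DISTRACTOR, DISTRACTOR]
    if len(matches) == 1:
        roles[matches[0]] = TARGET
        return "unambiguous", tuple(roles)

    if len(matches) == 2:
        i, j = matches
        alts = {k: alternative_messages(message, referents[k], bank) for k in (i, j)}
        no_alt = [k for k in (i, j) if not alts[k]]
        if len(no_alt) == 1:
            tgt = no_alt[0]
            cmp_ = j if tgt == i else i
            roles[tgt], roles[cmp_] = TARGET, COMPETITOR
            return "simple", tuple(roles)
        if len(no_alt) == 0:
            # both have alternatives: complex iff exactly one alternative is
            # itself ambiguous in context (matches some other referent)
            ambiguous_alt = []
            for k in (i, j):
                others = [r for idx, r in enumerate(referents) if idx != k]
                if any(
                    any(literal_match(m, r) for r in others) for m in alts[k]
                ):
                    ambiguous_alt.append(k)
            if len(ambiguous_alt) == 1:
                tgt = ambiguous_alt[0]
                cmp_ = j if tgt == i else i
                roles[tgt], roles[cmp_] = TARGET, COMPETITOR
                return "complex", tuple(roles)

    # >=2 matches without a uniquely pragmatically-favoured referent
    first, second = matches[0], matches[1]
    roles[first], roles[second] = TARGET, COMPETITOR
    return "ambiguous", tuple(roles)


def make_trial(
    message: Message,
    referents: Sequence[Referent],
    bank: Sequence[Message] = DEFAULT_BANK,
    allow_duplicates: bool = False,
) -> Trial:
    condition, roles = classify_trial(message, referents, bank)
    return Trial(
        message=message,
        referents=tuple(referents),
        condition=condition,
        roles=roles,
        allow_duplicates=allow_duplicates,
    )


@dataclass(frozen=True)
class Scenario:
    """A canonical critical scenario: (message, target, competitor) pattern.

    The distractor is a presentation variable; ``distractor`` holds the
    canonical choice (the valid distractor with the fewest in-bank matching
    messages) and ``valid_distractors`` all referents that realize the pattern.
    """

    message: Message
    target: Referent
    competitor: Referent
    condition: str
    distractor: Referent
    valid_distractors: tuple[Referent, ...]

    def trial(self, distractor: Referent | None = None) -> Trial:
        d = distractor if distractor is not None else self.distractor
        return make_trial(self.message, (self.target, self.competitor, d))


def _scenario_distractors(
    message: Message,
    target: Referent,
    competitor: Referent,
    condition: str,
    bank: Sequence[Message],
) -> list[Referent]:
    """Distractors that realize the canonical simple/complex pattern.

    A valid distractor must not match the message, and must leave the trial
    solvable by second-order reasoning with the intended target: in simple
    trials it must not match the competitor's alternative message (which has
    to stay contextually unambiguous), in complex trials it must match the
    target's alternative (making it ambiguous) but not the competitor's.
    """
    t_alts = alternative_messages(message, target, bank)
    c_alts = alternative_messages(message, competitor, bank)
    out = []
    for d in ALL_REFERENTS:
        if d in (target, competitor) or literal_match(message, d):
            continue
        if not matching_messages(d, bank):
            continue  # every referent must be expressible by some bank message
        if condition == "simple":
            if any(literal_match(m, d) for m in c_alts):
                continue
        else:  # complex
            if not all(literal_match(m, d) for m in t_alts):
                continue
            if any(literal_match(m, d) for m in c_alts):
                continue
        cond, roles = classify_trial(message, (target, competitor, d), bank)
        if cond == condition and roles[0] == TARGET:
            out.append(d)
    return out


def enumerate_critical_scenarios(
    bank: Sequence[Message] = DEFAULT_BANK,
) -> list[Scenario]:
    return list(_enumerate_critical_scenarios(tuple(bank)))


@functools.lru_cache(maxsize=None)
def _enumerate_critical_scenarios(bank: tuple[Message, ...]) -> tuple[Scenario, ...]:
    """Exhaustively enumerate the canonical critical scenarios for *bank*.

    Scenario identity is the (message, target, competitor) pattern; referent
    order and the distractor are treated as presentation variables.  With the
    default bank this yields exactly 8 simple and 8 complex scenarios.

    (The public wrapper above returns a fresh list; enumeration is memoized
    per bank.)
    """
    scenarios: list[Scenario] = []
    seen: set[tuple] = set()
    for message in bank:
        for target, competitor in itertools.permutations(ALL_REFERENTS, 2):
            if not (
                literal_match(message, target)
                and literal_match(message, competitor)
            ):
                continue
            t_alts = alternative_messages(message, target, bank)
            c_alts = alternative_messages(message, competitor, bank)
            if not t_alts and c_alts:
                condition = "simple"
            elif t_alts and c_alts:
                condition = "complex"
            else:
                continue
            key = (message, target, competitor, condition)
            if key in seen:
                continue
            valid = _scenario_distractors(message, target, competitor, condition, bank)
            if not valid:
                continue
            # canonical distractor: fewest in-bank messages, then feature order
            canon = min(
                valid,
                key=lambda d: (
                    len(matching_messages(d, bank)),
                    ALL_REFERENTS.index(d),
                ),
            )
            seen.add(key)
            scenarios.append(
                Scenario(
                    message=message,
                    target=target,
                    competitor=competitor,
                    condition=condition,
                    distractor=canon,
                    valid_distractors=tuple(valid),
                )
            )
    return tuple(scenarios)


def enumerate_unambiguous_scenarios(
    bank: Sequence[Message] = DEFAULT_BANK,
) -> list[tuple[Message, tuple[Referent, Referent, Referent]]]:
    return list(_enumerate_unambiguous(tuple(bank)))


@functools.lru_cache(maxsize=None)
def _enumerate_unambiguous(bank: tuple[Message, ...]):
    """All (message, distinct referent triple) combinations with exactly one literal match.

    Referent order inside the triple is ignored (triples are returned in
    canonical feature order).
    """
    out = []
    for message in bank:
        for triple in itertools.combinations(ALL_REFERENTS, 3):
            n = sum(literal_match(message, r) for r in triple)
            if n == 1:
                out.append((message, triple))
    return tuple(out)


@dataclass(frozen=True)
class ExperimentDesign:
    """An ordered list of trials plus the metadata needed to regenerate it."""

    design_id: str
    trials: tuple[Trial, ...]
    seed: int
    meta: Mapping[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    def condition_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.trials:
            counts[t.condition] = counts.get(t.condition, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.trials):
            rows.append(
                {
                    "trial_index": i,
                    "condition": t.condition,
                    "message_dim": t.message.dimension,
                    "message_val": t.message.value,
                    "ref1": t.referents[0].code,
                    "ref2": t.referents[1].code,
                    "ref3": t.referents[2].code,
                    "role1": t.roles[0],
                    "role2": t.roles[1],
                    "role3": t.roles[2],
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, design_id: str = "custom", seed: int = 0
    ) -> "ExperimentDesign":
        trials = []
        for _, row in frame.sort_values("trial_index").iterrows():
            refs = tuple(
                Referent.from_code(row[c]) for c in ("ref1", "ref2", "ref3")
            )
            trials.append(
                Trial(
                    message=Message.of(row["message_val"]),
                    referents=refs,
                    condition=row["condition"],
                    roles=(row["role1"], row["role2"], row["role3"]),
                    allow_duplicates=len(set(refs)) < 3,
                )
            )
        return cls(design_id=design_id, trials=tuple(trials), seed=seed)

    def to_config(self) -> dict:
        return {
            "design_id": self.design_id,
            "seed": self.seed,
            "meta": dict(self.meta),
            "trials": self.to_frame().to_dict(orient="records"),
        }

    @classmethod
    def from_config(cls, config: Mapping) -> "ExperimentDesign":
        design = cls.from_frame(
            pd.DataFrame(config["trials"]),
            design_id=config["design_id"],
            seed=config["seed"],
        )
        return replace(design, meta=dict(config.get("meta", {})))


def _unique_message_for(
    referent: Referent, trial_refs: Sequence[Referent], bank: Sequence[Message]
) -> Message | None:
    """An in-bank message matching *referent* and nothing else on the display."""
    for m in matching_messages(referent, bank):
        others = [r for r in trial_refs if r != referent]
        if not any(literal_match(m, r) for r in others):
            return m
    return None


def _all_unique_trials(bank: Sequence[Message]) -> list[Trial]:
    """Unambiguous trials in which all six feature values are distinct."""
    trials = []
    color_perms = list(itertools.permutations(COLORS))
    for k, colors in enumerate(color_perms):
        refs = tuple(Referent(s, c) for s, c in zip(SHAPES, colors))
        # rotate the targeted referent across trials for variety
        for target in refs:
            msgs = matching_messages(target, bank)
            if msgs:
                message = msgs[k % len(msgs)]
                trials.append(make_trial(message, refs, bank))
                break
    return trials


def _ambiguous_filler(
    rng: random.Random, bank: Sequence[Message]
) -> Trial:
    """A fully-ambiguous filler: two identical matching referents plus a non-match."""
    while True:
        message = rng.choice(list(bank))
        candidates = [r for r in ALL_REFERENTS if literal_match(message, r)]
        ref = rng.choice(candidates)
        non = [r for r in ALL_REFERENTS if not literal_match(message, r)]
        distractor = rng.choice(non)
        condition, roles = classify_trial(message, (ref, ref, distractor), bank)
        if condition == "ambiguous":
            return Trial(
                message=message,
                referents=(ref, ref, distractor),
                condition=condition,
                roles=roles,
                allow_duplicates=True,
            )


def build_design(
    design_id: str,
    seed: int,
    bank: Sequence[Message] = DEFAULT_BANK,
    strict_66: bool = False,
) -> ExperimentDesign:
    """Build a randomized experiment design.

    ``d36``: 8 simple + 8 complex + 20 unambiguous fillers (4 all-features-unique,
    8 reusing simple displays with the target moved to the former competitor (4)
    or distractor (4), and 8 reusing complex displays with the target moved to
    the former competitor).

    ``d66``: 12 simple + 12 complex + 35 unambiguous + 9 fully-ambiguous
    fillers.  These published counts sum to 68 trials; the literal 68-trial
    build is the default, and ``strict_66=True`` drops two unambiguous fillers
    to honour the nominal 66-trial length.

    Trial order and within-trial referent order are randomized per seed;
    identical seeds give identical designs.
    """
    if design_id not in ("d36", "d66"):
        raise ValueError(f"unknown design_id {design_id!r}")
    rng = random.Random(seed)
    scenarios = enumerate_critical_scenarios(bank)
    simple = [s for s in scenarios if s.condition == "simple"]
    complex_ = [s for s in scenarios if s.condition == "complex"]

    trials: list[Trial] = []
    if design_id == "d36":
        trials += [s.trial() for s in simple]
        trials += [s.trial() for s in complex_]
        trials += _all_unique_trials(bank)[:4]
        # unambiguous re-targets of the simple displays
        for k, s in enumerate(simple):
            base = s.trial()
            new_target = s.competitor if k < 4 else base.referents[2]
            msg = _unique_message_for(new_target, base.referents, bank)
            if msg is None:  # fall back to the competitor re-target
                msg = _unique_message_for(s.competitor, base.referents, bank)
            trials.append(make_trial(msg, base.referents, bank))
        # unambiguous re-targets of the complex displays (target = competitor)
        for s in complex_:
            base = s.trial()
            msg = _unique_message_for(s.competitor, base.referents, bank)
            trials.append(make_trial(msg, base.referents, bank))
    else:
        reps_s = simple + simple[:4]
        reps_c = complex_ + complex_[:4]
        trials += [s.trial() for s in reps_s]
        trials += [s.trial() for s in reps_c]
        n_unamb = 33 if strict_66 else 35
        pool = enumerate_unambiguous_scenarios(bank)
        for message, triple in rng.sample(pool, n_unamb):
            trials.append(make_trial(message, triple, bank))
        for _ in range(9):
            trials.append(_ambiguous_filler(rng, bank))

    # per-seed randomization of referent order within trials, then trial order
    randomized = []
    for t in trials:
        order = [0, 1, 2]
        rng.shuffle(order)
        randomized.append(t.reordered(order))
    rng.shuffle(randomized)
    counts = {}
    for t in randomized:
        counts[t.condition] = counts.get(t.condition, 0) + 1
    return ExperimentDesign(
        design_id=design_id,
        trials=tuple(randomized),
        seed=seed,
        meta={"total": len(randomized), **counts},
    )
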