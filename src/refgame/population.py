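"""Cohort simulation: sampling participants from hyper-distributions and
computing the summary statistics the adaptive model is evaluated on.

A simulated population is described by independent truncated normal
distributions over the two individual-difference parameters: the strength of
negative feedback ``F_NEG`` on [0.5, 10] and the persistence threshold on the
integer grid {24..33}.  Persistence is drawn from the continuous truncated
normal and rounded to the lattice.  Because the fitted centers sit near the
lower bounds, the truncated distributions behave like half-normals there.

``simulate_cohort`` either samples ``n`` participants from a hyper-distribution
or, in grid mode, iterates the fixed 20x10 parameter lattice with a given
number of replicates per cell (the survey design: 20 F_NEG values between 0.50
and 10.00, 10 persistence values between 24 and 33, 25 replicates = 5000
simulated participants).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .agent import AgentParams, run_experiment
from .task_model import ExperimentDesign, build_design

F_BOUNDS = (0.5, 10.0)
P_BOUNDS = (24, 33)

#: the survey lattice: 20 F_NEG values x 10 persistence values
F_GRID = tuple(np.round(np.linspace(0.5, 10.0, 20), 2))
P_GRID = tuple(range(24, 34))


@dataclass(frozen=True)
class HyperParams:
    """Centers and spreads of the population distributions of F_NEG and persistence."""

    mu_f: float
    sigma_f: float
    mu_p: float
    sigma_p: float

    def __post_init__(self) -> None:
        if self.sigma_f <= 0 or self.sigma_p <= 0:
            raise ValueError("sigmas must be positive")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.mu_f, self.sigma_f, self.mu_p, self.sigma_p)


#: population fit reported for the 66-trial multi-round game of
#: Mayn & Demberg (no trial feedback): low F_NEG center, low persistence center
MD_COHORT = HyperParams(mu_f=1.04, sigma_f=4.74, mu_p=24.56, sigma_p=6.86)
#: population fit reported for the 36-trial task variant with trial feedback
FEEDBACK_COHORT = HyperParams(mu_f=9.13, sigma_f=4.67, mu_p=27.50, sigma_p=6.66)

PRESETS: Mapping[str, HyperParams] = {
    "md-cohort": MD_COHORT,
    "feedback-cohort": FEEDBACK_COHORT,
}


def _truncnorm(mu: float, sigma: float, lo: float, hi: float):
    return stats.truncnorm((lo - mu) / sigma, (hi - mu) / sigma, loc=mu, scale=sigma)


def sample_participants(
    hyper: HyperParams,
    n: int,
    rng: np.random.Generator | int | None = None,
    **agent_overrides,
) -> list[AgentParams]:
    """Draw ``n`` independent participants from the hyper-distribution.

    F_NEG is a truncated normal on [0.5, 10]; persistence is a truncated
    normal on [24, 33] rounded to the integer lattice.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    f = _truncnorm(hyper.mu_f, hyper.sigma_f, *F_BOUNDS).rvs(size=n, random_state=rng)
    p = _truncnorm(hyper.mu_p, hyper.sigma_p, *P_BOUNDS).rvs(size=n, random_state=rng)
    p = np.clip(np.round(p), P_BOUNDS[0], P_BOUNDS[1]).astype(int)
    return [
        AgentParams(f_neg=float(fi), persistence=int(pi), **agent_overrides)
        for fi, pi in zip(f, p)
    ]


def grid_participants(reps: int = 25, **agent_overrides) -> list[AgentParams]:
    """The fixed survey lattice, ``reps`` replicates per cell (row-major order)."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    return [
        AgentParams(f_neg=float(f), persistence=int(p), **agent_overrides)
        for f in F_GRID
        for p in P_GRID
        for _ in range(reps)
    ]


@dataclass
class CohortSummary:
    """Aggregate statistics of a cohort simulation."""

    by_participant: pd.DataFrame  #: one row per participant x condition
    accuracy_by_condition: dict[str, float]
    accuracy_by_condition_quartile: dict[tuple[str, int], float]
    rt_quantiles: dict[str, dict[float, float]]  #: correct responses, by condition
    guess_share: dict[str, float]  #: correct responses from short literal-chain guesses
    n_participants: int

    @classmethod
    def empty(cls) -> "CohortSummary":
        return cls(pd.DataFrame(), {}, {}, {}, {}, 0)


RESULT_COLUMNS = [
    "participant_id",
    "f_neg",
    "persistence",
    "trial_index",
    "condition",
    "n_attempts",
    "strategies_tried",
    "response_role",
    "correct",
    "rt_s",
    "guessed",
    "seed",
]


def _participant_frame(
    pid: int, params: AgentParams, results, seed: int
) -> list[dict]:
    rows = []
    for tr in results:
        rows.append(
            {
                "participant_id": pid,
                "f_neg": params.f_neg,
                "persistence": params.persistence,
                "trial_index": tr.trial_index,
                "condition": tr.condition,
                "n_attempts": tr.n_attempts,
                "strategies_tried": tr.strategies_tried,
                "response_role": tr.response_role,
                "correct": bool(tr.correct),
                "rt_s": tr.rt,
                "guessed": bool(tr.guessed),
                "seed": seed,
            }
        )
    return rows


def is_literal_chain_guess(strategies_tried: str, guessed: bool, max_len: int = 4) -> bool:
    """True for a timed-out guess preceded only by 1..max_len literal-strategy attempts."""
    if not guessed:
        return False
    chain = strategies_tried.split(",") if strategies_tried else []
    return 1 <= len(chain) <= max_len and set(chain) == {"A"}


def guess_share(raw: pd.DataFrame, condition: str) -> float:
    """Among correct responses in *condition*, the fraction arising from
    chains of one to four literal-strategy attempts followed by a guess."""
    sub = raw[(raw["condition"] == condition) & raw["correct"]]
    if len(sub) == 0:
        return float("nan")
    flags = [
        is_literal_chain_guess(s, g)
        for s, g in zip(sub["strategies_tried"], sub["guessed"])
    ]
    return float(np.mean(flags))


def summarize(raw: pd.DataFrame, n_quartiles: int = 4) -> CohortSummary:
    """Compute the cohort summary from a raw trial-level results table."""
    if len(raw) == 0:
        return CohortSummary.empty()
    raw = raw.copy()
    n_trials = raw.groupby("participant_id")["trial_index"].transform("count")
    raw["quartile"] = np.minimum(
        n_quartiles - 1, raw["trial_index"] * n_quartiles // n_trials
    )

    by_p = (
        raw.groupby(["participant_id", "f_neg", "persistence", "condition"])["correct"]
        .mean()
        .rename("accuracy")
        .reset_index()
    )
    acc = raw.groupby("condition")["correct"].mean().to_dict()
    accq = (
        raw[raw["condition"].isin(["simple", "complex"])]
        .groupby(["condition", "quartile"])["correct"]
        .mean()
        .to_dict()
    )
    rtq = {}
    for cond, sub in raw[raw["correct"]].groupby("condition"):
        qs = sub["rt_s"].quantile([0.1, 0.25, 0.5, 0.75, 0.9])
        rtq[cond] = {float(q): float(v) for q, v in qs.items()}
    shares = {c: guess_share(raw, c) for c in ("simple", "complex")}
    return CohortSummary(
        by_participant=by_p,
        accuracy_by_condition={k: float(v) for k, v in acc.items()},
        accuracy_by_condition_quartile={k: float(v) for k, v in accq.items()},
        rt_quantiles=rtq,
        guess_share=shares,
        n_participants=raw["participant_id"].nunique(),
    )


def simulate_cohort(
    hyper: HyperParams | None = None,
    n: int = 228,
    design: str | ExperimentDesign = "d66",
    rng: np.random.Generator | int | None = None,
    grid: bool = False,
    reps: int = 25,
    fresh_design_per_participant: bool = True,
    **agent_overrides,
) -> tuple[CohortSummary, pd.DataFrame]:
    """Simulate a cohort and return its summary plus the raw results table.

    In sampled mode (default), ``n`` participants are drawn from ``hyper``.
    In grid mode the fixed 20x10 lattice is iterated with ``reps`` replicates
    per cell and ``hyper``/``n`` are ignored.  Each participant receives a
    per-participant randomization of the design (trial order and referent
    order), as in the experiments being modelled.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if grid:
        participants = grid_participants(reps, **agent_overrides)
    else:
        if hyper is None:
            raise ValueError("hyper is required in sampled mode")
        if n == 0:
            return CohortSummary.empty(), pd.DataFrame(columns=RESULT_COLUMNS)
        participants = sample_participants(hyper, n, rng, **agent_overrides)

    design_id = design if isinstance(design, str) else None
    rows: list[dict] = []
    for pid, params in enumerate(participants):
        seed = int(rng.integers(0, 2**31 - 1))
        if design_id is not None and fresh_design_per_participant:
            d = build_design(design_id, seed=seed)
        elif design_id is not None:
            d = build_design(design_id, seed=0)
        else:
            d = design
        results = run_experiment(params, d, rng=random.Random(seed ^ 0x5EED))
        rows.extend(_participant_frame(pid, params, results, seed))
    raw = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return summarize(raw), raw
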