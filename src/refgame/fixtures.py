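"""Synthetic trial-level datasets with known ground truth, and their I/O.

Datasets emulate what a human reference-game experiment actually yields: one
row per participant and trial with the condition, the message, the three
referents, the chosen referent's role, correctness and a response time.
Model-internal columns (attempt traces, utilities) are deliberately absent so
that fitting code cannot peek at the generating process.

Files are CSV with a JSON provenance sidecar (``<name>.provenance.json``)
recording the generator, its parameters and the seed — enough to regenerate
the file exactly.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .population import HyperParams, simulate_cohort
from .rsa import RSAMixtureParams, sample_responses
from .task_model import CONDITIONS, build_design

DATA_COLUMNS = [
    "participant_id",
    "trial_index",
    "condition",
    "message_val",
    "ref1",
    "ref2",
    "ref3",
    "response_role",
    "correct",
    "rt_s",
]

ROLES = ("target", "competitor", "distractor")


class DatasetError(ValueError):
    """Raised when a trial-level dataset fails validation."""


@dataclass
class Dataset:
    """A validated trial-level response table plus its provenance."""

    frame: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_frame(self.frame)
        if not self.provenance:
            raise DatasetError("provenance block is required")

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Dataset)
            and self.frame.reset_index(drop=True).equals(
                other.frame.reset_index(drop=True)
            )
            and self.provenance == other.provenance
        )


def validate_frame(frame: pd.DataFrame) -> None:
    """Check the dataset contract, raising DatasetError with specifics."""
    missing = [c for c in DATA_COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetError(f"missing columns: {missing}")
    bad_cond = set(frame["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise DatasetError(f"malformed condition labels: {sorted(bad_cond)}")
    bad_role = set(frame["response_role"]) - set(ROLES)
    if bad_role:
        raise DatasetError(f"malformed response roles: {sorted(bad_role)}")
    nonpos = frame.index[frame["rt_s"] <= 0].tolist()
    if nonpos:
        raise DatasetError(f"non-positive rt_s at rows {nonpos[:5]}")
    dup = frame.duplicated(subset=["participant_id", "trial_index"])
    if dup.any():
        raise DatasetError(
            f"duplicate participant/trial rows at {frame.index[dup][:5].tolist()}"
        )


def _design_columns(design, results) -> list[dict]:
    rows = []
    for tr in results:
        trial = design.trials[tr.trial_index]
        rows.append(
            {
                "trial_index": tr.trial_index,
                "condition": tr.condition,
                "message_val": trial.message.value,
                "ref1": trial.referents[0].code,
                "ref2": trial.referents[1].code,
                "ref3": trial.referents[2].code,
                "response_role": tr.response_role,
                "correct": bool(tr.correct),
                "rt_s": float(tr.rt),
            }
        )
    return rows


def generate_adaptive_dataset(
    hyper: HyperParams,
    n: int = 228,
    design: str = "d66",
    rng: int | np.random.Generator | None = 0,
    **agent_overrides,
) -> Dataset:
    """Simulate a cohort of adaptive agents and keep only the observables."""
    seed = int(rng) if isinstance(rng, (int, np.integer)) else None
    _, raw = simulate_cohort(
        hyper, n=n, design=design, rng=rng, **agent_overrides
    )
    frame = raw[
        [
            "participant_id",
            "trial_index",
            "condition",
            "response_role",
            "correct",
            "rt_s",
        ]
    ].copy()
    # re-attach the stimulus columns by rebuilding each participant's design
    stim = []
    for pid, sub in raw.groupby("participant_id"):
        d = build_design(design, seed=int(sub["seed"].iloc[0]))
        for ti in sub["trial_index"]:
            t = d.trials[ti]
            stim.append(
                {
                    "participant_id": pid,
                    "trial_index": ti,
                    "message_val": t.message.value,
                    "ref1": t.referents[0].code,
                    "ref2": t.referents[1].code,
                    "ref3": t.referents[2].code,
                }
            )
    frame = frame.merge(pd.DataFrame(stim), on=["participant_id", "trial_index"])
    frame = frame[DATA_COLUMNS]
    prov = {
        "generator": "adaptive",
        "design": design,
        "n": n,
        "hyper": dataclasses.asdict(hyper),
        "agent_overrides": {k: repr(v) for k, v in agent_overrides.items()},
        "seed": seed,
    }
    return Dataset(frame=frame, provenance=prov)


def generate_rsa_dataset(
    params: RSAMixtureParams,
    n: int = 228,
    design: str = "d66",
    rng: int | np.random.Generator | None = 0,
    noise_model: str = "mix",
) -> Dataset:
    """Sample responses from the heterogeneous RSA mixture.

    Each participant draws a listener type (per experiment, or per quarter in
    the flexible variant) and an alpha from the population Gamma.  Response
    times are filled from a condition-level lognormal placeholder — the RSA
    baselines predict no response times — and are marked non-substantive in
    the provenance.
    """
    seed = int(rng) if isinstance(rng, (int, np.integer)) else None
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    rt_means = {"unambiguous": 1.2, "simple": 3.2, "complex": 3.6, "ambiguous": 3.0}
    rows = []
    for pid in range(n):
        d = build_design(design, seed=int(gen.integers(0, 2**31 - 1)))
        alpha = float(gen.gamma(params.a_alpha, params.b_alpha))
        n_trials = len(d.trials)
        if params.flexible:
            types = [
                int(gen.choice(3, p=params.weights_for_quarter(q))) for q in range(4)
            ]
        else:
            level = int(gen.choice(3, p=params.weights_for_quarter(0)))
        for ti, trial in enumerate(d.trials):
            if params.flexible:
                q = min(3, ti * 4 // n_trials)
                level = types[q]
            pos = sample_responses(params, trial, level, alpha, gen, noise_model)
            role = trial.roles[pos]
            rt = float(gen.lognormal(np.log(rt_means[trial.condition]), 0.4))
            rows.append(
                {
                    "participant_id": pid,
                    "trial_index": ti,
                    "condition": trial.condition,
                    "message_val": trial.message.value,
                    "ref1": trial.referents[0].code,
                    "ref2": trial.referents[1].code,
                    "ref3": trial.referents[2].code,
                    "response_role": role,
                    "correct": role == "target",
                    "rt_s": rt,
                }
            )
    prov = {
        "generator": "rsa",
        "design": design,
        "n": n,
        "params": {
            "weights": np.asarray(params.weights).tolist(),
            "a_alpha": params.a_alpha,
            "b_alpha": params.b_alpha,
            "sigma_noise": params.sigma_noise,
            "noise_model": noise_model,
        },
        "seed": seed,
        "rt_note": "response times are synthetic placeholders; the mixture "
        "models predict choices only",
    }
    return Dataset(frame=pd.DataFrame(rows, columns=DATA_COLUMNS), provenance=prov)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".provenance.json")


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write the CSV and its JSON provenance sidecar."""
    path = Path(path)
    # %.17g round-trips every double exactly through the CSV
    dataset.frame.to_csv(path, index=False, float_format="%.17g")
    with open(_sidecar(path), "w") as fh:
        json.dump(dataset.provenance, fh, indent=2, sort_keys=True)


def read_dataset(path: str | Path) -> Dataset:
    """Read and validate a dataset written by :func:`write_dataset`."""
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"no such file: {path}")
    frame = pd.read_csv(path, float_precision="round_trip")
    side = _sidecar(path)
    if side.exists():
        with open(side) as fh:
            provenance = json.load(fh)
    else:
        provenance = {"generator": "unknown", "source": str(path)}
    return Dataset(frame=frame, provenance=provenance)
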