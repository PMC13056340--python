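import numpy as np
import pytest
from scipy import stats

from refgame.agent import AgentParams, run_experiment
from refgame.inference import build_grid
from refgame.population import MD_COHORT
from refgame.task_model import build_design, enumerate_critical_scenarios


@pytest.fixture(scope="session")
def scenarios():
    return enumerate_critical_scenarios()


@pytest.fixture(scope="session")
def d36_design():
    return build_design("d36", seed=11)


@pytest.fixture(scope="session")
def d66_design():
    return build_design("d66", seed=11)


@pytest.fixture(scope="session")
def d36_grid():
    """Simulation grid on the 36-trial design, 10 replicates per lattice cell."""
    return build_grid("d36", reps=10, rng=7)


def run_md_cohort(seed: int, n: int = 228):
    """One cohort draw from the published hyper-distribution on the 66-trial task.

    Returns a list of (f_neg, persistence, trial results, n_trials) tuples.
    """
    rng = np.random.default_rng(seed)
    h = MD_COHORT
    f = stats.truncnorm.rvs(
        (0.5 - h.mu_f) / h.sigma_f,
        (10 - h.mu_f) / h.sigma_f,
        loc=h.mu_f,
        scale=h.sigma_f,
        size=n,
        random_state=rng,
    )
    p = stats.truncnorm.rvs(
        (24 - h.mu_p) / h.sigma_p,
        (33 - h.mu_p) / h.sigma_p,
        loc=h.mu_p,
        scale=h.sigma_p,
        size=n,
        random_state=rng,
    )
    p = np.clip(np.round(p), 24, 33).astype(int)
    out = []
    for i, (fi, pi) in enumerate(zip(f, p)):
        design = build_design("d66", seed=seed * 100000 + i)
        res = run_experiment(
            AgentParams(f_neg=float(fi), persistence=int(pi)),
            design,
            rng=seed * 31337 + i,
        )
        out.append((float(fi), int(pi), res, len(design.trials)))
    return out


def cohort_stats(cohorts):
    """Accuracy by condition/quartile, guess shares, and correct-RT means."""
    acc = {"simple": [], "complex": []}
    quart = {(c, q): [] for c in acc for q in (0, 3)}
    guess = {"simple": [0, 0], "complex": [0, 0]}
    rt = {"simple": [], "complex": []}
    for cohort in cohorts:
        for _, _, res, n_trials in cohort:
            for tr in res:
                if tr.condition not in acc:
                    continue
                acc[tr.condition].append(tr.correct)
                q = min(3, tr.trial_index * 4 // n_trials)
                if (tr.condition, q) in quart:
                    quart[(tr.condition, q)].append(tr.correct)
                if tr.correct:
                    rt[tr.condition].append(tr.rt)
                    guess[tr.condition][1] += 1
                    chain = [a[0] for a in tr.attempts]
                    if tr.guessed and set(chain) == {"A"} and 1 <= len(chain) <= 4:
                        guess[tr.condition][0] += 1
    out = {c: 100 * np.mean(v) for c, v in acc.items()}
    for (c, q), v in quart.items():
        out[f"{c}_q{q + 1}"] = 100 * np.mean(v)
    for c, (a, b) in guess.items():
        out[f"guess_{c}"] = 100 * a / b
    for c, v in rt.items():
        out[f"rt_{c}"] = float(np.mean(v))
    return out


@pytest.fixture(scope="session")
def md_cohorts():
    """Five seeded cohort draws of 228 simulated participants each."""
    return [run_md_cohort(seed) for seed in (11, 22, 33, 44, 55)]
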