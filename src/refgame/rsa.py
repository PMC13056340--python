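"""Rational Speech Act listener hierarchy and heterogeneous mixture baselines.

The recursion stack follows the standard reference-game formulation:

* ``L0`` — literal listener: uniform over referents that literally match the
  message (uniform referent prior; salience priors are out of scope).
* ``S0`` — literal speaker: uniform over the bank messages that are true of
  the referent.
* ``S1`` — pragmatic speaker: softmax (inverse temperature ``alpha``) over
  true messages of the literal listener's success probability.
* ``L1`` / ``L2`` — pragmatic listeners: Bayes inversion of the speaker one
  level down under a uniform prior.  The posterior is proportional by
  default; an optional softmax at the responding listener level is provided
  behind a flag.

Two population mixture models serve as comparison baselines: a three-type
mixture in which each participant is a literal, first-order, or second-order
comprehender for the whole experiment (fixed weights), and a flexible variant
in which the type weights are free to differ in each quarter of the
experiment.  Both marginalize a participant-level ``alpha`` drawn from a
Gamma population distribution (Gauss-Legendre quadrature over its quantiles)
and perturb the predicted response probabilities with uniform response noise.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .task_model import (
    DEFAULT_BANK,
    Message,
    Referent,
    Trial,
    literal_match,
    matching_messages,
)

ListenerLevel = Literal[0, 1, 2]


@dataclass(frozen=True)
class RSAMixtureParams:
    """Parameters of the heterogeneous RSA population models.

    ``weights`` is a 3-simplex over listener types (L0, L1, L2); the flexible
    variant carries one simplex per experiment quarter (shape (4, 3)).
    ``a_alpha``/``b_alpha`` are the shape and scale of the population Gamma
    over the softmax inverse temperature; ``sigma_noise`` scales the uniform
    response noise ``p' = (1 - eps) p + eps/3``.
    """

    weights: tuple  #: (3,) or (4, 3) of nonnegative weights summing to 1
    a_alpha: float = 2.0
    b_alpha: float = 1.0
    sigma_noise: float = 0.1

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim not in (1, 2) or w.shape[-1] != 3:
            raise ValueError("weights must have trailing dimension 3")
        if np.any(w < 0) or not np.allclose(w.sum(axis=-1), 1.0, atol=1e-8):
            raise ValueError("weights must be a simplex (per quarter)")
        if self.a_alpha <= 0 or self.b_alpha <= 0 or self.sigma_noise <= 0:
            raise ValueError("a_alpha, b_alpha, sigma_noise must be positive")

    @property
    def flexible(self) -> bool:
        return np.asarray(self.weights).ndim == 2

    def weights_for_quarter(self, quarter: int) -> np.ndarray:
        w = np.asarray(self.weights, dtype=float)
        return w[quarter] if w.ndim == 2 else w


def literal_listener(message: Message, trial: Trial) -> np.ndarray:
    """Uniform distribution over the trial's literally matching referents."""
    mask = np.array(
        [literal_match(message, r) for r in trial.referents], dtype=float
    )
    if mask.sum() == 0:
        raise ValueError("message matches no referent")
    return mask / mask.sum()


def speaker(
    level: int,
    referent: Referent,
    trial: Trial,
    bank: Sequence[Message] = DEFAULT_BANK,
    alpha: float = 1.0,
) -> dict[Message, float]:
    """Speaker distribution over bank messages for a given referent.

    Level 0 is the literal speaker (uniform over true messages); level 1
    softmaxes the literal listener's probability of recovering the referent.
    """
    msgs = matching_messages(referent, bank)
    if not msgs:
        raise ValueError(f"referent {referent.code} has no true bank message")
    if level == 0:
        p = np.full(len(msgs), 1.0 / len(msgs))
    elif level == 1:
        utils = np.array(
            [literal_listener(m, trial)[trial.referents.index(referent)] for m in msgs]
        )
        z = alpha * utils
        z -= z.max()
        p = np.exp(z)
        p /= p.sum()
    else:
        raise ValueError("speaker level must be 0 or 1")
    return dict(zip(msgs, p))


def listener(
    level: ListenerLevel,
    message: Message,
    trial: Trial,
    bank: Sequence[Message] = DEFAULT_BANK,
    alpha: float = 1.0,
    listener_softmax: bool = False,
) -> np.ndarray:
    """Listener distribution over the trial's three referents.

    Level 0 is the literal listener.  Level ``k >= 1`` inverts the level
    ``k-1`` speaker under a uniform referent prior; with
    ``listener_softmax=True`` an additional softmax with ``alpha`` is applied
    to the posterior at the responding level (the default is the plain
    proportional posterior).
    """
    if level == 0:
        return literal_listener(message, trial)
    lik = np.zeros(3)
    for i, r in enumerate(trial.referents):
        if not matching_messages(r, bank):
            continue  # inexpressible referent: the speaker never produces it
        s = speaker(level - 1, r, trial, bank, alpha)
        lik[i] = s.get(message, 0.0)
    if lik.sum() == 0:
        raise ValueError("message has zero likelihood under every referent")
    post = lik / lik.sum()
    if listener_softmax:
        z = alpha * post
        z -= z.max()
        post = np.exp(z)
        post /= post.sum()
    return post


def response_probability(
    p: np.ndarray, sigma_noise: float, model: str = "mix"
) -> np.ndarray:
    """Perturb a predicted response distribution with response noise.

    ``mix`` (default): ``p' = (1 - eps) p + eps/3`` with ``eps =
    min(sigma_noise, 1)``.  ``truncnorm``: each probability is the mean of a
    normal centred on it with sd ``sigma_noise`` truncated to [0, 1],
    renormalized — a smoother alternative kept for comparison.
    """
    p = np.asarray(p, dtype=float)
    if model == "mix":
        eps = min(float(sigma_noise), 1.0)
        return (1.0 - eps) * p + eps / len(p)
    if model == "truncnorm":
        lo, hi = (0.0 - p) / sigma_noise, (1.0 - p) / sigma_noise
        m = stats.truncnorm.mean(lo, hi, loc=p, scale=sigma_noise)
        return m / m.sum()
    raise ValueError(f"unknown noise model {model!r}")


# role order used throughout the tabular pipeline
ROLE_ORDER = ("target", "competitor", "distractor")


@functools.lru_cache(maxsize=None)
def _condition_role_probs(
    condition: str, level: int, alpha: float, bank: tuple[Message, ...]
) -> np.ndarray:
    """P(respond role) for a canonical trial of *condition* under listener *level*.

    The canonical critical scenarios are structurally identical within a
    condition up to relabeling, so the role distribution depends only on
    (condition, level, alpha).  Unambiguous trials give a point mass on the
    target; fully ambiguous fillers split the literal matches evenly.
    """
    from .task_model import enumerate_critical_scenarios

    if condition in ("simple", "complex"):
        sc = [
            s for s in enumerate_critical_scenarios(bank) if s.condition == condition
        ][0]
        trial = sc.trial()
        dist = listener(level, trial.message, trial, bank, alpha)
        out = np.zeros(3)
        for pos, role in enumerate(trial.roles):
            out[ROLE_ORDER.index(role)] += dist[pos]
        return out
    if condition == "unambiguous":
        return np.array([1.0, 0.0, 0.0])
    if condition == "ambiguous":
        # two indistinguishable matching referents labelled target/competitor
        return np.array([0.5, 0.5, 0.0])
    raise ValueError(f"unknown condition {condition!r}")


def _alpha_quadrature(a: float, b: float, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre quadrature over the Gamma(a, scale=b) quantile function."""
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    q = (x + 1.0) / 2.0  # nodes in (0, 1)
    alphas = stats.gamma.ppf(q, a, scale=b)
    weights = w / 2.0
    return alphas, weights


def mixture_loglik(
    dataset: pd.DataFrame,
    params: RSAMixtureParams,
    flexible: bool | None = None,
    n_nodes: int = 32,
    noise_model: str = "mix",
) -> np.ndarray:
    """Pointwise (per-trial) log-likelihood of a dataset under a mixture model.

    Rows must carry ``participant_id``, ``condition``, ``response_role`` and a
    ``quartile`` column (added from trial order if absent).  The participant's
    listener type (per experiment in the fixed model, per quarter in the
    flexible model) and alpha are latent; the likelihood marginalizes the
    type(s) and integrates alpha by quadrature.  Pointwise contributions are
    the sequential one-step-ahead predictive log-probabilities within each
    participant, so they sum exactly to the participant's marginal
    log-likelihood.

    Returns an array aligned with the dataset rows.
    """
    if flexible is None:
        flexible = params.flexible
    df = dataset.copy()
    if "quartile" not in df.columns:
        n_trials = df.groupby("participant_id")["trial_index"].transform("count")
        df["quartile"] = np.minimum(3, df["trial_index"] * 4 // n_trials)

    alphas, a_w = _alpha_quadrature(params.a_alpha, params.b_alpha, n_nodes)
    bank = DEFAULT_BANK

    # response probability lookup table: (condition, level, alpha) -> roles.
    # L0 and L1 are alpha-free under the proportional posterior (the literal
    # speaker carries no softmax), so only L2 varies across nodes.
    conds = sorted(set(df["condition"]))
    table = np.zeros((len(conds), 3, len(alphas), 3))
    for c, cond in enumerate(conds):
        for li in range(3):
            if li < 2:
                pr = response_probability(
                    _condition_role_probs(cond, li, 1.0, bank),
                    params.sigma_noise,
                    noise_model,
                )
                table[c, li, :, :] = pr[None, :]
            else:
                for ai, alpha in enumerate(alphas):
                    table[c, li, ai] = response_probability(
                        _condition_role_probs(cond, li, float(alpha), bank),
                        params.sigma_noise,
                        noise_model,
                    )

    cond_codes = df["condition"].map({c: i for i, c in enumerate(conds)}).to_numpy()
    role_codes = df["response_role"].map(
        {r: i for i, r in enumerate(ROLE_ORDER)}
    ).to_numpy()
    # (n, 3, A): probability of the observed response under each latent state
    p_row = table[cond_codes][np.arange(len(df))[:, None, None],
                              np.arange(3)[None, :, None],
                              np.arange(len(alphas))[None, None, :],
                              role_codes[:, None, None]]
    with np.errstate(divide="ignore"):
        logp_row = np.log(p_row)
        log_aw = np.log(a_w)

    out = np.zeros(len(df))
    pos = df.index.get_indexer
    for pid, idx in df.groupby("participant_id").groups.items():
        idx = np.asarray(idx)
        sub = df.loc[idx]
        order = np.argsort(sub["trial_index"].to_numpy(), kind="stable")
        idx = idx[order]
        rows = pos(idx)
        lp = logp_row[rows]  # (T, 3, A)
        T = len(rows)
        if not flexible:
            logw = np.log(np.maximum(params.weights_for_quarter(0), 1e-300))
            base = logw[None, :, None] + log_aw[None, None, :]
            cum = np.concatenate(
                [np.zeros((1, 3, len(alphas))), np.cumsum(lp, axis=0)], axis=0
            )
            evid = logsumexp(base + cum, axis=(1, 2))  # (T+1,)
            out[rows] = np.diff(evid)
        else:
            quart = df.loc[idx, "quartile"].to_numpy(dtype=int)
            carry = log_aw.copy()  # (A,) log evidence so far, per alpha
            t = 0
            while t < T:
                q = quart[t]
                end = t
                while end < T and quart[end] == q:
                    end += 1
                logw = np.log(
                    np.maximum(params.weights_for_quarter(int(q)), 1e-300)
                )
                lpq = lp[t:end]  # (Tq, 3, A)
                cum = np.concatenate(
                    [np.zeros((1, 3, len(alphas))), np.cumsum(lpq, axis=0)],
                    axis=0,
                )
                state = logw[None, :, None] + carry[None, None, :] + cum
                evid = logsumexp(state, axis=(1, 2))
                out[rows[t:end]] = np.diff(evid)
                carry = logsumexp(
                    logw[:, None] + carry[None, :] + cum[-1], axis=0
                )
                t = end
    return out


def sample_responses(
    params: RSAMixtureParams,
    trial: Trial,
    level: int,
    alpha: float,
    rng: np.random.Generator,
    noise_model: str = "mix",
) -> int:
    """Sample a referent position from the noise-perturbed listener distribution."""
    dist = listener(level, trial.message, trial, DEFAULT_BANK, alpha)
    dist = response_probability(dist, params.sigma_noise, noise_model)
    return int(rng.choice(3, p=dist / dist.sum()))
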