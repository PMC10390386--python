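"""Bayesian hidden-Markov change-point filter for binary reversal learning.

The generative model has a binary hidden "preferred side" ``z_t`` that flips
between trials with an unknown probability ``a ~ Beta(alpha_a, beta_a)``, and
a binary observation ``x_t`` (the rewarded side) that matches ``z_t`` with an
unknown probability ``p`` drawn from a Beta(alpha_p, beta_p) prior truncated
to (0.5, 1].  Because both ``a`` and ``p`` are integrated out analytically,
the filtering distribution over hidden-state *histories* admits exact
sufficient statistics per history: the reversal count ``r``, the match count
``m`` and a truncation-correction term ``c``.  A sequential Monte Carlo
filter over these statistics approximates the (exponentially large) sum over
histories; :func:`exact_posterior` evaluates the same sum by enumeration for
small ``t`` and serves as the reference implementation.

Per-trial outputs are the posterior over the current hidden state, the
one-step-ahead predictive for the observation, the probability that the
hidden state differs from the subject's choice (``state change probability``)
and the binary entropy of that probability (``state entropy``, in bits).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betainc, betaln

__all__ = [
    "HMMParams",
    "ParticleSet",
    "TrialEstimates",
    "c0_correction",
    "init_particles",
    "predict_next",
    "filter_step",
    "run_filter",
    "state_change_probability",
    "binary_entropy",
    "exact_posterior",
    "estimates_to_tsv",
    "read_estimates_tsv",
]


@dataclass(frozen=True)
class HMMParams:
    """Shape parameters of the two conjugate priors.

    ``alpha_p, beta_p`` parameterize the truncated beta prior on the reward
    probability of the preferred side; ``alpha_a, beta_a`` the beta prior on
    the per-transition reversal probability.
    """

    alpha_p: float
    beta_p: float
    alpha_a: float
    beta_a: float

    def __post_init__(self) -> None:
        for name in ("alpha_p", "beta_p", "alpha_a", "beta_a"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive and finite, got {v!r}")


@dataclass
class ParticleSet:
    """Weighted sample of hidden-state histories, compressed to sufficient stats.

    Each particle carries its current hidden state ``z``, reversal count ``r``,
    match count ``m`` (trials where the observation equalled the hidden state)
    and the truncation correction ``c``.  ``t`` is the number of observations
    absorbed so far; at ``t == 0`` the particles represent the empty history
    and ``z`` is unset (-1).
    """

    params: HMMParams
    z: np.ndarray
    r: np.ndarray
    m: np.ndarray
    c: np.ndarray
    log_w: np.ndarray
    t: int = 0

    @property
    def n_particles(self) -> int:
        return self.z.shape[0]

    @property
    def weights(self) -> np.ndarray:
        w = np.exp(self.log_w - self.log_w.max())
        return w / w.sum()


@dataclass(frozen=True)
class TrialEstimates:
    """Posterior and predictive summaries for one trial."""

    trial: int
    posterior_z0: float
    posterior_z1: float
    predictive_x0: float
    predictive_x1: float
    state_change_probability: float = math.nan
    state_entropy: float = math.nan


def c0_correction(params: HMMParams) -> float:
    """Initial truncation-correction term of the filter recursion.

    ``c_0 = 0.5**(a+b) / (B(a,b) - B(0.5; a,b))`` with ``B`` the (non
    regularized) beta and incomplete beta functions.  Evaluated in log space
    so large shape parameters do not overflow.
    """
    a, b = params.alpha_p, params.beta_p
    # 1 - I_{0.5}(a, b) == I_{0.5}(b, a): mass of Beta(a,b) above 0.5.
    upper_mass = betainc(b, a, 0.5)
    if upper_mass <= 0.0:
        raise FloatingPointError(
            "prior mass of p above 0.5 underflows; truncated prior is degenerate"
        )
    log_c0 = (a + b) * math.log(0.5) - betaln(a, b) - math.log(upper_mass)
    return math.exp(log_c0)


def init_particles(params: HMMParams, n_particles: int) -> ParticleSet:
    """Uniform-weight particles representing the empty history."""
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    n = int(n_particles)
    c0 = c0_correction(params)
    return ParticleSet(
        params=params,
        z=np.full(n, -1, dtype=np.int64),
        r=np.zeros(n, dtype=np.int64),
        m=np.zeros(n, dtype=np.int64),
        c=np.full(n, c0, dtype=np.float64),
        log_w=np.full(n, -math.log(n), dtype=np.float64),
        t=0,
    )


def binary_entropy(q) -> float | np.ndarray:
    """Binary Shannon entropy in bits, with the 0*log(0) := 0 convention."""
    q = np.asarray(q, dtype=np.float64)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("probability outside [0, 1]")
    out = np.zeros_like(q)
    interior = (q > 0) & (q < 1)
    qi = q[interior]
    out[interior] = -(qi * np.log2(qi) + (1 - qi) * np.log2(1 - qi))
    return float(out) if out.ndim == 0 else out


def state_change_probability(posterior_z0: float, posterior_z1: float, y_t) -> float:
    """P(hidden state != choice | observations); NaN for a missed choice."""
    if y_t is None:
        return math.nan
    y_val = float(y_t)
    if math.isnan(y_val) or y_val < 0:
        return math.nan
    return posterior_z1 if int(y_val) == 0 else posterior_z0


def _branch(particles: ParticleSet):
    """Expand each particle over the two candidate hidden states.

    Returns per-branch arrays (stay first, flip second; at t == 0 the two
    branches are z=0 and z=1) of candidate z, transition and observation
    probabilities, and the branch prior weights w * p_trans.
    """
    p = particles.params
    t = particles.t
    n = particles.n_particles
    if t == 0:
        z_new = np.concatenate([np.zeros(n, np.int64), np.ones(n, np.int64)])
        p_trans = np.full(2 * n, 0.5)
    else:
        denom = p.alpha_a + p.beta_a + t - 1
        p_flip = (p.alpha_a + particles.r) / denom
        z_stay = particles.z
        z_new = np.concatenate([z_stay, 1 - z_stay])
        p_trans = np.concatenate([1.0 - p_flip, p_flip])
    m2 = np.tile(particles.m, 2)
    c2 = np.tile(particles.c, 2)
    denom_obs = p.alpha_p + p.beta_p + t
    # P(x_{t+1} = z_{t+1} | history)
    p_match = (p.alpha_p + m2 + c2) / denom_obs
    return z_new, p_trans, m2, c2, p_match


def predict_next(particles: ParticleSet) -> tuple[float, float]:
    """One-step-ahead predictive P(x=0), P(x=1) before the feedback arrives."""
    z_new, p_trans, _, _, p_match = _branch(particles)
    w2 = np.tile(particles.weights, 2) * p_trans
    p_x1 = float(np.sum(w2 * np.where(z_new == 1, p_match, 1.0 - p_match)))
    return 1.0 - p_x1, p_x1


def _systematic_indices(weights: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions)


def filter_step(
    particles: ParticleSet,
    x_t: int,
    rng: np.random.Generator,
    resampler: str = "systematic",
) -> tuple[ParticleSet, TrialEstimates]:
    """Absorb one observation: branch, condition, resample.

    The predictive is computed from the pre-observation branch weights; the
    posterior over the new hidden state from the conditioned weights.
    """
    if x_t not in (0, 1):
        raise ValueError(f"observation must be 0 or 1, got {x_t!r}")
    p = particles.params
    t = particles.t
    n = particles.n_particles

    z_new, p_trans, m2, c2, p_match = _branch(particles)
    w2 = np.tile(particles.weights, 2) * p_trans
    p_x1 = float(np.sum(w2 * np.where(z_new == 1, p_match, 1.0 - p_match)))

    match = z_new == x_t
    p_obs = np.where(match, p_match, 1.0 - p_match)
    with np.errstate(divide="ignore"):
        log_w2 = np.log(w2) + np.log(p_obs)
    if not np.any(np.isfinite(log_w2)):
        raise FloatingPointError("all branch probabilities vanished")
    log_w2 -= log_w2.max()
    w2_post = np.exp(log_w2)
    w2_post /= w2_post.sum()

    posterior_z1 = float(np.sum(w2_post[z_new == 1]))

    # Sufficient-statistic updates (exact compression of the history).
    if t == 0:
        r_new = np.zeros(2 * n, dtype=np.int64)
    else:
        r_new = np.tile(particles.r, 2) + (z_new != np.tile(particles.z, 2))
    m_new = m2 + match
    denom_obs = p.alpha_p + p.beta_p + t
    c_new = np.where(
        match,
        0.5 * denom_obs * c2 / (p.alpha_p + m2 + c2),
        0.5 * denom_obs * c2 / (p.beta_p + t - m2 - c2),
    )

    if resampler == "systematic":
        idx = _systematic_indices(w2_post, n, rng)
    elif resampler == "multinomial":
        idx = rng.choice(2 * n, size=n, p=w2_post)
    else:
        raise ValueError(f"unknown resampler {resampler!r}")

    new_set = ParticleSet(
        params=p,
        z=z_new[idx],
        r=r_new[idx],
        m=m_new[idx],
        c=c_new[idx],
        log_w=np.full(n, -math.log(n)),
        t=t + 1,
    )
    est = TrialEstimates(
        trial=t + 1,
        posterior_z0=1.0 - posterior_z1,
        posterior_z1=posterior_z1,
        predictive_x0=1.0 - p_x1,
        predictive_x1=p_x1,
    )
    return new_set, est


def run_filter(
    params: HMMParams,
    x: np.ndarray,
    y: np.ndarray | None = None,
    n_particles: int = 10_000,
    seed: int | np.random.Generator = 0,
    resampler: str = "systematic",
) -> pd.DataFrame:
    """Filter a full observation sequence.

    Parameters
    ----------
    x : observed rewarded sides, shape (T,), values in {0, 1}.
    y : optional choices, shape (T,); -1 (or None) marks missed trials, for
        which state change probability and entropy propagate as NaN.

    Returns a frame with one row per trial: posterior, predictive, state
    change probability and state entropy (bits).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(x, dtype=np.int64)
    particles = init_particles(params, n_particles)
    rows = []
    for t, x_t in enumerate(x):
        particles, est = filter_step(particles, int(x_t), rng, resampler=resampler)
        q = math.nan
        if y is not None:
            q = state_change_probability(est.posterior_z0, est.posterior_z1, y[t])
        h = binary_entropy(q) if not math.isnan(q) else math.nan
        rows.append(
            {
                "trial": t + 1,
                "posterior_z0": est.posterior_z0,
                "posterior_z1": est.posterior_z1,
                "predictive_x0": est.predictive_x0,
                "predictive_x1": est.predictive_x1,
                "state_change_probability": q,
                "state_entropy": h,
            }
        )
    return pd.DataFrame(rows)


def _sequence_stats(params: HMMParams, zs: tuple[int, ...], xs) -> float:
    """Log joint probability of one complete (z, x) trajectory.

    Straightforward trial-by-trial evaluation used only by the enumeration
    oracle; intentionally independent of the vectorized filter code path.
    """
    a_p, b_p = params.alpha_p, params.beta_p
    a_a, b_a = params.alpha_a, params.beta_a
    c = c0_correction(params)
    m = 0
    r = 0
    log_p = 0.0
    for t0 in range(len(zs)):  # t0 = number of trials already absorbed
        z, x_obs = zs[t0], xs[t0]
        if t0 == 0:
            p_trans = 0.5
        else:
            p_flip = (a_a + r) / (a_a + b_a + t0 - 1)
            p_trans = p_flip if z != zs[t0 - 1] else 1.0 - p_flip
            r += int(z != zs[t0 - 1])
        if z == x_obs:
            p_obs = (a_p + m + c) / (a_p + b_p + t0)
            c = 0.5 * (a_p + b_p + t0) * c / (a_p + m + c)
            m += 1
        else:
            p_obs = (b_p + t0 - m - c) / (a_p + b_p + t0)
            c = 0.5 * (a_p + b_p + t0) * c / (b_p + t0 - m - c)
        if p_trans <= 0 or p_obs <= 0:
            return -math.inf
        log_p += math.log(p_trans) + math.log(p_obs)
    return log_p


def exact_posterior(params: HMMParams, x) -> pd.DataFrame:
    """Exact filtering by enumeration of all 2^t hidden-state histories.

    Oracle for the particle filter; limited to t <= 14.  Returns per-trial
    posterior over the current hidden state and the one-step predictive.
    """
    x = [int(v) for v in np.asarray(x)]
    t_max = len(x)
    if t_max > 14:
        raise ValueError("exact enumeration limited to t <= 14")
    rows = []
    for t in range(1, t_max + 1):
        xs = x[:t]
        joint_z1 = 0.0
        total = 0.0
        # predictive: marginal of x_t under both candidate values
        pred = {0: 0.0, 1: 0.0}
        for zs in itertools.product((0, 1), repeat=t):
            lp = _sequence_stats(params, zs, xs)
            pr = math.exp(lp) if lp > -math.inf else 0.0
            total += pr
            if zs[-1] == 1:
                joint_z1 += pr
            for x_last in (0, 1):
                lp_alt = _sequence_stats(params, zs, xs[:-1] + [x_last])
                pred[x_last] += math.exp(lp_alt) if lp_alt > -math.inf else 0.0
        pred_total = pred[0] + pred[1]
        rows.append(
            {
                "trial": t,
                "posterior_z0": 1.0 - joint_z1 / total,
                "posterior_z1": joint_z1 / total,
                "predictive_x0": pred[0] / pred_total,
                "predictive_x1": pred[1] / pred_total,
                "log_evidence": math.log(total),
            }
        )
    return pd.DataFrame(rows)


ESTIMATE_COLUMNS = [
    "trial",
    "posterior_z0",
    "posterior_z1",
    "state_change_probability",
    "state_entropy",
    "predictive_x1",
]


def estimates_to_tsv(estimates: pd.DataFrame, path) -> None:
    estimates.loc[:, ESTIMATE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_estimates_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
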