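"""Choice models, likelihoods, multistart MLE and model comparison.

Three candidate models of trial-by-trial choice are supported, all sharing a
softmax decision rule over per-side values:

``hmm``             five parameters (alpha_p, beta_p, alpha_a, beta_a, beta);
                    values are the change-point filter's one-step predictive
                    reward probabilities.
``rescorla_wagner`` two parameters (alpha, beta); values are delta-rule
                    Q-values initialized at 0.5.
``no_reversal``     two parameters (alpha_p + beta_p, beta); values follow
                    the closed-form beta-Bernoulli predictive with a
                    hyperbolically decaying learning rate.

Sessions are scored by the negative log-likelihood of the responded choices;
missed trials contribute no likelihood term but their feedback still advances
the observer state.  Fitting minimizes the NLL with SLSQP from multiple
random starts inside box bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .hmm import HMMParams, filter_step, init_particles, predict_next
from .task import MISSING, SessionRecord, TaskConfig, generate_session

__all__ = [
    "MODELS",
    "FitSpec",
    "FitResult",
    "softmax_choice",
    "rw_update",
    "no_reversal_step",
    "no_reversal_predictive",
    "session_nll",
    "fit_mle",
    "model_recovery",
    "generative_check",
    "fit_results_to_tsv",
]

P_FLOOR = 1e-12  # probability floor inside log to guard the NLL

_PARAM_NAMES = {
    "hmm": ("alpha_p", "beta_p", "alpha_a", "beta_a", "beta"),
    "rescorla_wagner": ("alpha", "beta"),
    "no_reversal": ("alpha_sum", "beta"),
}
_DEFAULT_BOUNDS = {
    "hmm": ((1e-3, 1e3),) * 4 + ((0.0, 1e3),),
    "rescorla_wagner": ((0.0, 1.0), (0.0, 1e3)),
    "no_reversal": ((1e-3, 1e3), (0.0, 1e3)),
}
MODELS = tuple(_PARAM_NAMES)


def softmax_choice(values: np.ndarray, beta: float) -> np.ndarray:
    """Softmax choice probabilities; overflow-safe via max subtraction."""
    if beta < 0:
        raise ValueError("inverse temperature must be non-negative")
    u = beta * np.asarray(values, dtype=float)
    u = u - u.max()
    e = np.exp(u)
    return e / e.sum()


def rw_update(q: np.ndarray, y: int, reward: int, alpha: float) -> np.ndarray:
    """Delta-rule update of the chosen side's value only."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("learning rate must be in [0, 1]")
    q = np.array(q, dtype=float)
    q[y] = q[y] + alpha * (reward - q[y])
    return q


def no_reversal_step(p_x1: float, x_t: int, alpha_sum: float, t: int) -> float:
    """One step of the closed-form no-switching predictive recursion."""
    return p_x1 + (x_t - p_x1) / (alpha_sum + t)


def no_reversal_predictive(alpha_sum: float, x) -> np.ndarray:
    """P(x_t = 1 | x_{1:t-1}) for every trial, starting symmetrically at 0.5."""
    if alpha_sum <= 0:
        raise ValueError("alpha_sum must be positive")
    x = np.asarray(x, dtype=float)
    out = np.empty(x.shape[0])
    p = 0.5
    for t in range(x.shape[0]):
        out[t] = p
        p = no_reversal_step(p, x[t], alpha_sum, t + 1)
    return out


def _predictive_values(model: str, theta, session: SessionRecord,
                       n_particles: int, seed: int) -> np.ndarray:
    """Per-trial per-side values entering the softmax, shape (T, 2).

    For all models the value of side s at trial t is the model's predicted
    probability that the reward is on side s (Q-values play that role for the
    delta-rule model), computed before the trial's feedback.
    """
    x = session.x
    y = session.y
    n = session.n_trials
    values = np.empty((n, 2))
    if model == "hmm":
        a_p, b_p, a_a, b_a, _ = theta
        params = HMMParams(a_p, b_p, a_a, b_a)
        rng = np.random.default_rng(seed)
        particles = init_particles(params, n_particles)
        for t in range(n):
            values[t] = predict_next(particles)
            particles, _ = filter_step(particles, int(x[t]), rng)
    elif model == "rescorla_wagner":
        alpha, _ = theta
        rewarded = session.binary_reward
        q = np.array([0.5, 0.5])
        for t in range(n):
            values[t] = q
            if y[t] != MISSING:
                q = rw_update(q, int(y[t]), int(rewarded[t]), alpha)
    elif model == "no_reversal":
        alpha_sum, _ = theta
        p1 = no_reversal_predictive(alpha_sum, x)
        values[:, 1] = p1
        values[:, 0] = 1.0 - p1
    else:
        raise ValueError(f"unknown model {model!r}")
    return values


def session_nll(
    model: str,
    theta,
    session: SessionRecord,
    n_particles: int = 1000,
    seed: int = 0,
    p_floor: float = P_FLOOR,
) -> float:
    """Negative log-likelihood of the responded choices under ``model``."""
    resp = session.responded
    if resp.sum() < 1:
        raise ValueError("session has no responded trials")
    beta = theta[-1]
    values = _predictive_values(model, theta, session, n_particles, seed)
    nll = 0.0
    for t in np.flatnonzero(resp):
        probs = softmax_choice(values[t], beta)
        nll -= np.log(max(probs[int(session.y[t])], p_floor))
    return float(nll)


@dataclass(frozen=True)
class FitSpec:
    model: str
    bounds: tuple = None
    n_starts: int = 10
    seed: int = 0
    n_particles: int = 1000
    p_floor: float = P_FLOOR

    def __post_init__(self) -> None:
        if self.model not in _PARAM_NAMES:
            raise ValueError(f"unknown model {self.model!r}")
        if self.bounds is None:
            object.__setattr__(self, "bounds", _DEFAULT_BOUNDS[self.model])


@dataclass
class FitResult:
    model: str
    theta: np.ndarray
    param_names: tuple[str, ...]
    nll: float
    aic: float
    bic: float
    n_obs: int
    converged: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.theta)

    def as_dict(self) -> dict:
        d = {"model": self.model, "k": self.k, "nll": self.nll,
             "aic": self.aic, "bic": self.bic, "n_obs": self.n_obs}
        d.update(dict(zip(self.param_names, self.theta)))
        return d


def _draw_start(rng: np.random.Generator, model: str, bounds) -> np.ndarray:
    """Random start: uniform for rates, log-uniform for shapes and beta."""
    theta = np.empty(len(bounds))
    for i, (lo, hi) in enumerate(bounds):
        name = _PARAM_NAMES[model][i]
        if name == "alpha":
            theta[i] = rng.uniform(lo, hi)
        else:
            lo_eff = max(lo, 1e-2)
            theta[i] = np.exp(rng.uniform(np.log(lo_eff), np.log(max(hi, lo_eff * 10))))
    return theta


def fit_mle(spec: FitSpec, session: SessionRecord) -> FitResult:
    """Best-of-``n_starts`` constrained SLSQP minimization of the session NLL.

    A fixed particle-filter seed is reused across objective evaluations so
    the objective is deterministic for the optimizer.
    """
    rng = np.random.default_rng(spec.seed)
    pf_seed = int(rng.integers(2**31 - 1))

    def objective(theta):
        try:
            return session_nll(spec.model, theta, session,
                               n_particles=spec.n_particles, seed=pf_seed,
                               p_floor=spec.p_floor)
        except (FloatingPointError, ValueError):
            return 1e10

    best = None
    converged = []
    for _ in range(spec.n_starts):
        x0 = _draw_start(rng, spec.model, spec.bounds)
        res = optimize.minimize(objective, x0, method="SLSQP", bounds=spec.bounds,
                                options={"maxiter": 200, "ftol": 1e-6})
        converged.append(bool(res.success))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e10:
        raise RuntimeError("no optimization start converged")

    n_obs = int(session.responded.sum())
    k = len(spec.bounds)
    nll = float(best.fun)
    return FitResult(
        model=spec.model,
        theta=np.asarray(best.x),
        param_names=_PARAM_NAMES[spec.model],
        nll=nll,
        aic=2.0 * k + 2.0 * nll,
        bic=k * np.log(n_obs) + 2.0 * nll,
        n_obs=n_obs,
        converged=converged,
    )


def model_recovery(
    config: TaskConfig,
    param_pool: dict[str, np.ndarray],
    n_sessions: int,
    seed: int = 0,
    fit_models: tuple[str, ...] | None = None,
    n_starts: int = 4,
    n_particles: int = 500,
    agent_particles: int = 1000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate data with each model and refit candidates; AIC/BIC table.

    ``param_pool`` maps model name -> array of parameter vectors (rows); each
    simulated dataset draws one vector from its generator's pool.  Returns the
    per-dataset long table and paired-comparison summary (paired t-tests on
    AIC between fitting models on the same datasets).
    """
    from .agents import build_agent

    if not param_pool:
        raise ValueError("empty parameter pool")
    rng = np.random.default_rng(seed)
    rows = []
    for gen_model, pool in param_pool.items():
        pool = np.atleast_2d(np.asarray(pool, dtype=float))
        candidates = fit_models if fit_models is not None else tuple(param_pool)
        for i in range(n_sessions):
            theta = pool[rng.integers(pool.shape[0])]
            agent = build_agent(gen_model, theta, n_particles=agent_particles,
                                seed=int(rng.integers(2**31 - 1)))
            session = generate_session(config, agent, int(rng.integers(2**31 - 1)))
            for fit_model in candidates:
                spec = FitSpec(fit_model, n_starts=n_starts,
                               seed=int(rng.integers(2**31 - 1)),
                               n_particles=n_particles)
                try:
                    fr = fit_mle(spec, session)
                except RuntimeError as exc:  # recorded, not fatal
                    rows.append({"gen_model": gen_model, "dataset": i,
                                 "fit_model": fit_model, "error": str(exc)})
                    continue
                rows.append({"gen_model": gen_model, "dataset": i,
                             "fit_model": fit_model, "nll": fr.nll,
                             "aic": fr.aic, "bic": fr.bic, "error": ""})
    table = pd.DataFrame(rows)
    comparisons = []
    ok = table[table["error"] == ""] if "error" in table else table
    for gen_model in ok["gen_model"].unique():
        sub = ok[ok["gen_model"] == gen_model]
        fitted = sorted(sub["fit_model"].unique())
        for a in fitted:
            for b in fitted:
                if a >= b:
                    continue
                merged = sub[sub["fit_model"] == a].merge(
                    sub[sub["fit_model"] == b], on="dataset", suffixes=("_a", "_b"))
                if len(merged) < 2:
                    continue
                tt = stats.ttest_rel(merged["aic_a"], merged["aic_b"])
                comparisons.append({
                    "gen_model": gen_model, "fit_a": a, "fit_b": b,
                    "mean_aic_a": merged["aic_a"].mean(),
                    "mean_aic_b": merged["aic_b"].mean(),
                    "t": tt.statistic, "p": tt.pvalue,
                })
    return table, pd.DataFrame(comparisons)


def generative_check(
    fitted: list[FitResult] | list[tuple[str, np.ndarray]],
    config: TaskConfig,
    n_reps: int = 10,
    seed: int = 0,
    window=range(-2, 4),
    agent_particles: int = 1000,
):
    """Simulate ``n_reps`` sessions per fitted parameter vector.

    Returns (summaries frame, reversal-aligned curves frame or None).  Each
    simulated session is treated as a different simulated participant.
    """
    from .agents import build_agent
    from .task import reversal_aligned_curves, summarize_behavior

    rng = np.random.default_rng(seed)
    entries = [(f.model, f.theta) if isinstance(f, FitResult) else f for f in fitted]
    rows, sessions = [], []
    for j, (model, theta) in enumerate(entries):
        for rep in range(n_reps):
            agent = build_agent(model, theta, n_particles=agent_particles,
                                seed=int(rng.integers(2**31 - 1)))
            s = generate_session(config, agent, int(rng.integers(2**31 - 1)))
            sessions.append((model, s))
            summ = summarize_behavior(s)
            rows.append({"model": model, "fit_index": j, "rep": rep,
                         "preferred_pct": summ.preferred_pct,
                         "rewarded_pct": summ.rewarded_pct,
                         "switch_pct": summ.switch_pct})
    summaries = pd.DataFrame(rows)
    curves = None
    if sessions:
        curve_rows = []
        for model in {m for m, _ in sessions}:
            subset = [s for m, s in sessions if m == model]
            try:
                c = reversal_aligned_curves(subset, window)
            except ValueError:
                continue
            c.insert(0, "model", model)
            curve_rows.append(c)
        if curve_rows:
            curves = pd.concat(curve_rows, ignore_index=True)
    return summaries, curves


def fit_results_to_tsv(results: list[FitResult], path, session_ids=None) -> None:
    rows = []
    for i, fr in enumerate(results):
        d = fr.as_dict()
        d["session"] = session_ids[i] if session_ids is not None else i
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
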