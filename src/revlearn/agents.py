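"""Choice agents that drive the task simulator.

All agents share the interface used by :func:`revlearn.task.generate_session`:
``reset()``, ``choose(rng) -> side`` and ``observe(y, x, rewarded)``.  Choice
probabilities come from the shared softmax rule applied to each model's
per-side values (predictive reward probabilities, or Q-values for the
delta-rule learner).
"""

from __future__ import annotations

import numpy as np

from .fitting import no_reversal_step, rw_update, softmax_choice
from .hmm import HMMParams, filter_step, init_particles, predict_next

__all__ = ["RWAgent", "NoReversalAgent", "BayesAgent", "build_agent"]


class RWAgent:
    """Delta-rule learner with softmax choice; Q starts at (0.5, 0.5)."""

    def __init__(self, alpha: float, beta: float):
        self.alpha = float(alpha)
        self.beta = float(beta)
        self.q = np.array([0.5, 0.5])

    def reset(self) -> None:
        self.q = np.array([0.5, 0.5])

    def choose(self, rng: np.random.Generator) -> int:
        probs = softmax_choice(self.q, self.beta)
        return int(rng.random() < probs[1])

    def observe(self, y: int, x: int, rewarded: int) -> None:
        self.q = rw_update(self.q, y, rewarded, self.alpha)


class NoReversalAgent:
    """Beta-Bernoulli tracker with no switching; hyperbolically decaying updates."""

    def __init__(self, alpha_sum: float, beta: float):
        self.alpha_sum = float(alpha_sum)
        self.beta = float(beta)
        self.p_x1 = 0.5
        self.t = 0

    def reset(self) -> None:
        self.p_x1 = 0.5
        self.t = 0

    def choose(self, rng: np.random.Generator) -> int:
        probs = softmax_choice(np.array([1.0 - self.p_x1, self.p_x1]), self.beta)
        return int(rng.random() < probs[1])

    def observe(self, y: int, x: int, rewarded: int) -> None:
        self.t += 1
        self.p_x1 = no_reversal_step(self.p_x1, x, self.alpha_sum, self.t)


class BayesAgent:
    """Online particle-filter observer with softmax choice on predictive probabilities.

    The filter sees every feedback (the rewarded side is revealed whether or
    not the choice was correct), matching the task's full-information display.
    """

    def __init__(
        self,
        params: HMMParams,
        beta: float,
        n_particles: int = 2000,
        seed: int = 0,
    ):
        self.params = params
        self.beta = float(beta)
        self.n_particles = int(n_particles)
        self.seed = int(seed)
        self.reset()

    def reset(self) -> None:
        self._rng = np.random.default_rng(self.seed)
        self.particles = init_particles(self.params, self.n_particles)

    def choose(self, rng: np.random.Generator) -> int:
        p_x0, p_x1 = predict_next(self.particles)
        probs = softmax_choice(np.array([p_x0, p_x1]), self.beta)
        return int(rng.random() < probs[1])

    def observe(self, y: int, x: int, rewarded: int) -> None:
        self.particles, _ = filter_step(self.particles, x, self._rng)


def build_agent(model: str, theta, n_particles: int = 2000, seed: int = 0):
    """Instantiate the agent matching a fitted model's parameter vector."""
    theta = np.asarray(theta, dtype=float)
    if model == "hmm":
        a_p, b_p, a_a, b_a, beta = theta
        return BayesAgent(HMMParams(a_p, b_p, a_a, b_a), beta, n_particles=n_particles, seed=seed)
    if model == "rescorla_wagner":
        return RWAgent(*theta)
    if model == "no_reversal":
        return NoReversalAgent(*theta)
    raise ValueError(f"unknown model {model!r}")
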