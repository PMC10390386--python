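import numpy as np
import pandas as pd
import pytest

from revlearn import preprocess, pupilgen, task
from revlearn.agents import build_agent
from revlearn.hmm import HMMParams, run_filter


@pytest.fixture(scope="session")
def default_params():
    return HMMParams(1.0, 1.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def exp2a_session():
    agent = build_agent("hmm", [1.0, 1.0, 1.0, 30.0, 10.0], n_particles=500, seed=11)
    return task.generate_session(task.EXP2A, agent, seed=42)


def make_cohort_table(
    n_participants=6,
    n_trials=50,
    b_feedback=0.0,
    b_changeprob=0.0,
    b_entropy=0.0,
    noise_sd=0.02,
    seed=0,
    filter_particles=800,
):
    """Full-chain synthetic cohort: sessions -> filter -> pupil -> epochs table.

    Returns the long epochs table joined with per-trial predictors, ready for
    the statistics module.

    Effect weights must stay within the 3-SD outlier envelope of the noise
    floor (stationary AR sd is noise_sd / sqrt(1 - 0.97^2) ~ 4 * noise_sd):
    larger evoked peaks get clipped by the outlier-deletion rule, which
    saturates the injected linear relationship.  Keep |b| <= ~8 * noise_sd.
    """
    rng = np.random.default_rng(seed)
    cfg = task.TaskConfig(n_trials=n_trials, p_reward=0.85,
                          reversal_rule=task.ReversalRule("stochastic", h=0.06))
    params = HMMParams(1.0, 1.0, 1.0, 30.0)
    spec = pupilgen.PupilGenSpec(
        b_feedback=b_feedback, b_changeprob=b_changeprob, b_entropy=b_entropy,
        noise_sd=noise_sd, blink_rate=0.05,
    )
    frames = []
    for p in range(n_participants):
        agent = build_agent("hmm", [1.0, 1.0, 1.0, 30.0, 8.0],
                            n_particles=400, seed=int(rng.integers(2**31 - 1)))
        session = task.generate_session(cfg, agent, int(rng.integers(2**31 - 1)))
        est = run_filter(params, session.x, session.y,
                         n_particles=filter_particles,
                         seed=int(rng.integers(2**31 - 1)))
        rec = pupilgen.generate_recording(spec, session, est,
                                          seed=int(rng.integers(2**31 - 1)))
        cleaned = preprocess.clean_series(rec)
        epochs = preprocess.epoch_and_baseline(cleaned, rec.events)
        epochs.insert(0, "participant", f"p{p:02d}")
        merged = epochs.merge(
            rec.events[["trial", "feedback_sign", "state_change_probability",
                        "state_entropy"]],
            on="trial",
        )
        frames.append(merged)
    table = pd.concat(frames, ignore_index=True)
    table["negative"] = (table["feedback_sign"] < 0).astype(float)
    return table.dropna(subset=["state_change_probability"]).reset_index(drop=True)
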