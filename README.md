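# revlearn

Analysis toolkit for probabilistic reversal-learning experiments with
pupillometry. The package covers the full synthetic-study loop:

- **`revlearn.task`** — binary-choice reversal-learning sessions under three
  reward contingencies (0.75/0.25, 0.85/0.15, 0.65/0.35) with either
  response-contingent (8 consecutive preferred choices) or stochastic
  (0.06/trial) reversals; behavioral summaries and reversal-aligned curves.
- **`revlearn.hmm`** — Bayesian hidden-Markov change-point filter with
  analytically integrated beta priors (truncated prior on the reward
  probability, beta prior on the switch rate). A sequential Monte Carlo
  filter over exact sufficient statistics produces per-trial hidden-state
  posteriors, one-step predictives, state change probability, and state
  entropy (bits); an exact enumeration oracle validates it.
- **`revlearn.fitting`** — softmax choice models (change-point filter,
  Rescorla–Wagner, no-reversal beta-Bernoulli), session likelihoods,
  multistart SLSQP maximum-likelihood fitting, AIC/BIC, model recovery and
  generative checks.
- **`revlearn.pupilgen`** — synthetic 250 Hz two-eye pupil recordings with
  feedback-locked evoked responses driven by known effect weights, AR(1)
  noise, blinks and injectable artifacts.
- **`revlearn.preprocess`** — cleaning chain (eye averaging, blink deletion,
  3-SD outlier removal with 40 ms padding, 50 Hz resampling, linear
  interpolation, Savitzky–Golay smoothing), feedback-locked −1…+6 s epochs
  (350 bins), baseline correction, participant exclusion rule.
- **`revlearn.stats`** / **`revlearn.lmm`** — mass-univariate per-bin
  random-intercept mixed models (fast profiled-ML implementation,
  cross-validated against statsmodels), likelihood-ratio tests, cluster-based
  permutation correction, dual-basis (linear + entropy) and
  dichotomized-interaction analyses.
- **`revlearn.study`** / **`revlearn.cli`** — end-to-end orchestration with
  per-stage seed substreams and a provenance manifest.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` contains the long-running end-to-end calibration
checks (several minutes); the rest of the suite finishes in well under a
minute.

## CLI

```sh
revlearn simulate --condition exp2a --model hmm --theta 1,1,1,30,10 --seed 1 --out session.tsv
revlearn filter session.tsv --theta 1,1,1,30 --out estimates.tsv
revlearn fit session.tsv --model rescorla_wagner
revlearn pupilgen session.tsv estimates.tsv --b-feedback 0.1 \
    --samples-out samples.tsv --events-out events.tsv
revlearn preprocess samples.tsv events.tsv --out epochs.csv
revlearn stats epochs.csv --predictor state_change_probability \
    --n-perm 500 --bins-out bins.csv --clusters-out clusters.json
revlearn recover --condition exp1 --n-sessions 10 --out recovery.csv
revlearn run-study study.yaml --out run/
```

`run-study` consumes a YAML file mirroring `revlearn.study.StudyConfig`
(condition, cohort size, agent model/parameters, pupil generator weights,
statistics settings, master seed) and writes sessions, fits, filter
estimates, raw pupil TSVs, epoch tables, per-bin statistics and a manifest
into the output directory; completed stages are skipped on rerun.

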