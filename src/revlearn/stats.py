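"""Mass-univariate per-bin mixed models with cluster-based permutation correction.

For each time bin a random-intercept (participant) linear mixed model is fit
by ML with the pre-feedback baseline as nuisance covariate; predictors of
interest are tested with a likelihood-ratio test against the nested model
without them.  Multiple comparisons across bins are controlled by a
cluster-length permutation scheme: the predictor of interest is shuffled
across trials within participant, the whole bin series is refit, lengths of
consecutive significant runs are pooled over permutations, and observed
clusters survive only if strictly longer than the 95th percentile of that
null distribution.

Also provides the two-basis-function analysis (identity and binary-entropy
transforms of state change probability entered jointly) and the
dichotomized-interaction analysis (slope difference below/above 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .hmm import binary_entropy
from .lmm import lrt_series

__all__ = [
    "BinSeriesResult",
    "ClusterResult",
    "fit_bin_series",
    "cluster_permutation",
    "dual_basis_model",
    "dichotomized_interaction",
    "clusters_from_mask",
    "reversal_contrast_table",
]


@dataclass
class BinSeriesResult:
    """Per-bin LRT series for one predictor set."""

    bins: pd.DataFrame  # bin, lrt, p, significant, coef_<col>...
    df: int
    alpha: float


@dataclass
class ClusterResult:
    bins: pd.DataFrame
    clusters: list  # [(start_bin, length), ...] of observed significant runs
    null_cluster_lengths: np.ndarray
    threshold: float
    surviving: list
    n_perm: int
    alpha: float

    def to_json_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_perm": self.n_perm,
            "threshold": self.threshold,
            "clusters": [{"start": int(s), "length": int(l)} for s, l in self.clusters],
            "surviving": [{"start": int(s), "length": int(l)} for s, l in self.surviving],
        }


def reversal_contrast_table(
    table: pd.DataFrame,
    reversal_trials: dict[str, np.ndarray],
    n_around: int = 2,
) -> pd.DataFrame:
    """Subset epochs to the trials flanking reversals and code the contrast.

    Keeps, per participant, the last ``n_around`` trials before and the first
    ``n_around`` trials after each reversal (``reversal_trials`` maps
    participant -> 1-based trial indices at which the hidden side changed)
    and adds a ``post_reversal`` 0/1 column for use as predictor of interest.
    """
    frames = []
    for pid, revs in reversal_trials.items():
        sub = table[table["participant"] == pid]
        pre, post = set(), set()
        for t0 in np.asarray(revs, dtype=int):
            pre.update(range(t0 - n_around, t0))
            post.update(range(t0, t0 + n_around))
        pre -= post  # a trial both after one reversal and before the next counts as post
        picked = sub[sub["trial"].isin(pre | post)].copy()
        picked["post_reversal"] = picked["trial"].isin(post).astype(float)
        frames.append(picked)
    if not frames:
        raise ValueError("no reversal trials to contrast")
    return pd.concat(frames, ignore_index=True)


def clusters_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """Runs of consecutive True values as (start, length) pairs."""
    mask = np.asarray(mask, dtype=bool)
    padded = np.concatenate([[False], mask, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


@dataclass
class _Pivot:
    """Epoch table reshaped to (trial-rows x bins) with per-trial metadata."""

    Y: np.ndarray  # (n_rows, B)
    meta: pd.DataFrame  # one row per (participant, trial); baseline + predictors
    group_idx: np.ndarray  # participant codes per row
    bin_values: np.ndarray
    participant_rows: dict = field(default_factory=dict)  # code -> row indices


_REQUIRED = ("participant", "trial", "bin", "value", "baseline")


def _pivot(table: pd.DataFrame, columns: list[str]) -> _Pivot:
    for col in _REQUIRED:
        if col not in table.columns:
            raise ValueError(f"epochs table lacks required column {col!r}")
    df = table.sort_values(["participant", "trial", "bin"], kind="mergesort")
    bin_values = np.sort(df["bin"].unique())
    n_bins = bin_values.shape[0]
    meta_cols = ["participant", "trial", "baseline"] + [
        c for c in columns if c in df.columns and c != "baseline"
    ]
    meta = df.groupby(["participant", "trial"], sort=True).first().reset_index()
    meta = meta[[c for c in meta_cols if c in meta.columns]]
    n_rows = len(meta)
    if len(df) != n_rows * n_bins:
        raise ValueError("epochs table is not complete: every trial needs every bin")
    Y = df["value"].to_numpy(float).reshape(n_rows, n_bins)
    codes = pd.Categorical(meta["participant"]).codes.astype(np.int64)
    rows_by_part = {c: np.flatnonzero(codes == c) for c in np.unique(codes)}
    return _Pivot(Y=Y, meta=meta, group_idx=codes, bin_values=bin_values,
                  participant_rows=rows_by_part)


def _design(piv: _Pivot, columns: list[str],
            override: dict[str, np.ndarray] | None = None) -> np.ndarray:
    cols = [np.ones(len(piv.meta)), piv.meta["baseline"].to_numpy(float)]
    for c in columns:
        if override and c in override:
            cols.append(override[c])
        else:
            cols.append(piv.meta[c].to_numpy(float))
    return np.column_stack(cols)


def _lrt_frame(piv: _Pivot, full_cols: list[str], test_cols: list[str],
               alpha: float, override=None) -> tuple[pd.DataFrame, int]:
    X_full = _design(piv, full_cols, override)
    reduced_cols = [c for c in full_cols if c not in test_cols]
    X_red = _design(piv, reduced_cols, override)
    df = X_full.shape[1] - X_red.shape[1]
    if df < 1:
        raise ValueError("test columns must appear in the full model")
    lrt, beta_full = lrt_series(X_full, X_red, piv.Y, piv.group_idx)
    p = chi2.sf(lrt, df)
    frame = pd.DataFrame({"bin": piv.bin_values, "lrt": lrt, "p": p,
                          "significant": p < alpha})
    for j, c in enumerate(full_cols):
        frame[f"coef_{c}"] = beta_full[2 + j]
    return frame, df


def fit_bin_series(
    table: pd.DataFrame,
    predictors: list[str],
    test: list[str] | None = None,
    alpha: float = 0.05,
) -> BinSeriesResult:
    """Per-bin LRT of ``test`` predictors (default: all of ``predictors``).

    The full model is ``value ~ baseline + predictors + (1 | participant)``;
    the reduced model drops only the tested columns.
    """
    test = list(predictors) if test is None else list(test)
    for c in predictors:
        col = table[c].to_numpy(float)
        if np.nanstd(col) == 0:
            raise ValueError(f"predictor {c!r} is constant; model is degenerate")
    piv = _pivot(table, predictors)
    frame, df = _lrt_frame(piv, list(predictors), test, alpha)
    return BinSeriesResult(bins=frame, df=df, alpha=alpha)


def _permute_within(piv: _Pivot, rng: np.random.Generator) -> np.ndarray:
    """Row permutation shuffling trials within each participant."""
    perm = np.arange(len(piv.meta))
    for rows in piv.participant_rows.values():
        perm[rows] = rows[rng.permutation(rows.shape[0])]
    return perm


def _run_permutation(
    piv: _Pivot,
    full_cols: list[str],
    test_cols: list[str],
    permuted_cols: list[str],
    derive,
    n_perm: int,
    alpha: float,
    rng: np.random.Generator,
    cluster_stat: str,
) -> ClusterResult:
    """Shared permutation engine.

    ``derive(values_dict)`` maps the permuted base column values to the
    override dict for the design (identity for plain predictors; recomputes
    derived basis columns otherwise).
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    observed, df = _lrt_frame(piv, full_cols, test_cols, alpha)
    obs_clusters = clusters_from_mask(observed["significant"].to_numpy())

    base_values = {c: piv.meta[c].to_numpy(float) for c in permuted_cols}
    null_lengths: list[int] = []
    per_perm_max: list[int] = []
    for _ in range(n_perm):
        perm = _permute_within(piv, rng)
        permuted = {c: v[perm] for c, v in base_values.items()}
        override = derive(permuted)
        frame, _ = _lrt_frame(piv, full_cols, test_cols, alpha, override=override)
        lengths = [l for _, l in clusters_from_mask(frame["significant"].to_numpy())]
        null_lengths.extend(lengths)
        per_perm_max.append(max(lengths) if lengths else 0)

    if cluster_stat == "pooled":
        pool = np.asarray(null_lengths, dtype=float)
    elif cluster_stat == "max":
        pool = np.asarray(per_perm_max, dtype=float)
    else:
        raise ValueError(f"unknown cluster_stat {cluster_stat!r}")
    threshold = float(np.percentile(pool, 95)) if pool.size else 0.0
    surviving = [(s, l) for s, l in obs_clusters if l > threshold]
    return ClusterResult(
        bins=observed, clusters=obs_clusters,
        null_cluster_lengths=pool, threshold=threshold,
        surviving=surviving, n_perm=n_perm, alpha=alpha,
    )


def cluster_permutation(
    table: pd.DataFrame,
    predictors: list[str],
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    cluster_stat: str = "pooled",
) -> ClusterResult:
    """Cluster-corrected test of ``predictors`` (jointly) against the baseline-only model."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for c in predictors:
        if np.nanstd(table[c].to_numpy(float)) == 0:
            raise ValueError(f"predictor {c!r} is constant")
    piv = _pivot(table, predictors)
    return _run_permutation(
        piv, list(predictors), list(predictors), list(predictors),
        derive=lambda v: v, n_perm=n_perm, alpha=alpha, rng=rng,
        cluster_stat=cluster_stat,
    )


def dual_basis_model(
    table: pd.DataFrame,
    q_col: str = "state_change_probability",
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    cluster_stat: str = "pooled",
) -> dict[str, ClusterResult]:
    """Joint linear + entropy basis model of state change probability.

    The full model carries both the identity basis (q) and the binary-entropy
    basis H(q); each is tested by dropping it alone, with its own permutation
    correction.  Permutations shuffle q within participant and recompute both
    bases, preserving their deterministic coupling.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = table[q_col].to_numpy(float)
    if np.nanstd(q) == 0:
        raise ValueError("state change probability is constant; bases are collinear")
    work = table.copy()
    work["phi_linear"] = work[q_col]
    work["phi_entropy"] = binary_entropy(np.clip(work[q_col].to_numpy(float), 0, 1))
    piv = _pivot(work, ["phi_linear", "phi_entropy"])

    def derive(vals):
        qp = vals["phi_linear"]
        return {"phi_linear": qp, "phi_entropy": binary_entropy(np.clip(qp, 0, 1))}

    out = {}
    for name, test in (("linear", ["phi_linear"]), ("entropy", ["phi_entropy"])):
        out[name] = _run_permutation(
            piv, ["phi_linear", "phi_entropy"], test, ["phi_linear"],
            derive=derive, n_perm=n_perm, alpha=alpha, rng=rng,
            cluster_stat=cluster_stat,
        )
    return out


def dichotomized_interaction(
    table: pd.DataFrame,
    q_col: str = "state_change_probability",
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    cluster_stat: str = "pooled",
) -> ClusterResult:
    """Interaction of state change probability with the above-0.5 indicator.

    Tests whether the slope of q on pupil response differs below vs. above
    0.5 (the signature of an entropy-like, sign-flipping effect).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = table[q_col].to_numpy(float)
    above = (q > 0.5).astype(float)
    if np.nanstd(above) == 0:
        raise ValueError("all trials on one side of 0.5; interaction undefined")
    work = table.copy()
    work["q_lin"] = q
    work["q_above"] = above
    work["q_inter"] = q * above
    piv = _pivot(work, ["q_lin", "q_above", "q_inter"])

    def derive(vals):
        qp = vals["q_lin"]
        ab = (qp > 0.5).astype(float)
        return {"q_lin": qp, "q_above": ab, "q_inter": qp * ab}

    return _run_permutation(
        piv, ["q_lin", "q_above", "q_inter"], ["q_inter"], ["q_lin"],
        derive=derive, n_perm=n_perm, alpha=alpha, rng=rng,
        cluster_stat=cluster_stat,
    )
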