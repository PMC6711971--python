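"""Per-feature differential testing for the crossover/crossback study.

Three model families share one engine:

* **Transition models** (long-RNA elements, RPKM): within one study arm, a
  random-intercept linear mixed model per feature over a pair of consecutive
  visits (baseline->crossover = T1, crossover->crossback = T2).  The slope is
  the coefficient of the later-visit indicator, adjusted for the nine study
  covariates, with the intercept varying by subject.
* **Condition models** (small RNAs, RPM): the same mixed model but pooling
  all visits of an arm into high-DBP vs background conditions, treating a
  subject's visits as replicates of their condition.
* **IBD-vs-control models**: ordinary least squares of expression on cohort
  (control = 1, so a positive slope means higher expression in controls),
  repeated over random draws of one sample per subject to absorb replicate
  visits, then Benjamini-Hochberg adjusted.

Significance for the mixed models uses a permutation empirical P-value:
within each subject, the visit (or condition) assignment of that subject's
observations is permuted — realised by permuting the subject's responses
across the subject's design rows, which keeps the design fixed and makes
the test exact under within-subject exchangeability — the full model is
refit, and p = (1 + #{|slope*| >= |slope_obs|}) / (B + 1).  When the design
admits fewer within-subject permutations than B, the test enumerates the
full permutation group instead.

Default thresholds follow the study: a call requires the empirical P below
0.05 and an absolute slope exceeding 10 RPKM (long RNAs) or 5 RPM (small
RNAs), both inequalities strict on the slope.
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._lmm import RandomInterceptWorkspace
from .study_io import ARMS, COVARIATE_COLUMNS, ExpressionMatrix, StudyIOError

logger = logging.getLogger(__name__)

TRANSITION_VISITS = {"T1": ("baseline", "crossover"), "T2": ("crossover", "crossback")}

MIN_INPUT_READS = 50_000
HIGH_SMALL_MEDIAN = 50.0


@dataclass
class ModelSpec:
    """Configuration for one differential run.

    ``n_resamples`` (B) counts permutations for the empirical P-value;
    ``resampling_mode`` chooses between per-feature permutations and one
    null-slope pool shared by every feature of the run.  ``slope_threshold``
    is in matrix units (10 RPKM for long REs, 5 RPM for small RNAs).
    """

    covariates: list[str] = field(default_factory=lambda: list(COVARIATE_COLUMNS))
    grouping: str = "subject_id"
    n_resamples: int = 1000
    resampling_mode: str = "per_feature"
    alpha: float = 0.05
    slope_threshold: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_resamples < 19:
            raise ValueError("n_resamples must be >= 19")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.resampling_mode not in ("per_feature", "pooled_null"):
            raise ValueError(f"unknown resampling_mode {self.resampling_mode!r}")


def small_rna_spec(**overrides) -> ModelSpec:
    """ModelSpec preset with the small-RNA 5 RPM slope threshold."""
    overrides.setdefault("slope_threshold", 5.0)
    return ModelSpec(**overrides)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def design_matrix(samples: pd.DataFrame, indicator: np.ndarray,
                  covariates: list[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + group indicator + covariate columns (batch -> dummies)."""
    cols = [np.ones(len(samples)), np.asarray(indicator, dtype=float)]
    names = ["intercept", "indicator"]
    for cov in covariates:
        if cov not in samples.columns:
            raise StudyIOError(f"covariate {cov!r} missing from sample sheet")
        col = samples[cov]
        if cov == "batch" or col.dtype == object:
            dummies = pd.get_dummies(col.astype(str), prefix=cov, drop_first=True)
            for name in dummies.columns:
                cols.append(dummies[name].to_numpy(dtype=float))
                names.append(name)
        else:
            vals = pd.to_numeric(col)
            if vals.isna().any():
                raise StudyIOError(f"covariate {cov!r} contains NA in modelled samples")
            cols.append(vals.to_numpy(dtype=float))
            names.append(cov)
    X = np.column_stack(cols)
    # drop constant covariate columns (e.g. single-level batch) but never
    # the intercept or the indicator
    keep = [i for i in range(X.shape[1]) if i < 2 or np.ptp(X[:, i]) > 0]
    return X[:, keep], [names[i] for i in keep]


def _subject_positions(samples: pd.DataFrame, grouping: str):
    codes, uniques = pd.factorize(samples[grouping])
    positions = [np.flatnonzero(codes == g) for g in range(len(uniques))]
    return codes, positions


def _stage_seed(seed: int, *tokens: str) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        [int(seed)] + [zlib.crc32(t.encode()) for t in tokens]
    )


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

def _exact_permutation_indices(positions, n_obs: int, cap: int):
    """The full group of within-subject sample permutations as index arrays,
    if it has at most ``cap + 1`` elements; otherwise None.

    The identity is excluded from the returned null set, so the add-one
    estimator reproduces the exact permutation P-value.
    """
    per_subject = []
    total = 1
    for pos in positions:
        perms = list(itertools.permutations(range(len(pos))))
        per_subject.append(perms)
        total *= len(perms)
        if total > cap + 1:
            return None
    out = []
    for combo in itertools.product(*per_subject):
        idx = np.arange(n_obs)
        for pos, perm in zip(positions, combo):
            idx[pos] = pos[list(perm)]
        if not np.array_equal(idx, np.arange(n_obs)):
            out.append(idx)
    return out


def _permute_within_subjects(values: np.ndarray, positions, rng) -> np.ndarray:
    """Permute entries of ``values`` within each subject's positions."""
    out = values.copy()
    for pos in positions:
        if len(pos) > 1:
            out[pos] = out[pos][rng.permutation(len(pos))]
    return out


def empirical_pvalue(observed_slopes: np.ndarray, null_abs_slopes,
                     mode: str = "per_feature") -> np.ndarray:
    """Add-one permutation P-values.

    ``null_abs_slopes`` is a list of per-feature |slope*| arrays in
    ``per_feature`` mode, or a single shared pool in ``pooled_null`` mode.
    Never returns 0: p in [1/(B+1), 1].
    """
    observed = np.abs(np.asarray(observed_slopes, dtype=float))
    if mode == "pooled_null":
        pool = np.sort(np.abs(np.asarray(null_abs_slopes, dtype=float)))
        n_ge = len(pool) - np.searchsorted(pool, observed, side="left")
        return (1.0 + n_ge) / (len(pool) + 1.0)
    out = np.empty(len(observed))
    for i, null in enumerate(null_abs_slopes):
        null = np.abs(np.asarray(null, dtype=float))
        out[i] = (1.0 + np.sum(null >= observed[i])) / (len(null) + 1.0)
    return out


def call_significance(slope, p, spec: ModelSpec) -> np.ndarray:
    """up / down / ns calls; slope threshold strict, p threshold strict."""
    slope = np.atleast_1d(np.asarray(slope, dtype=float))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    call = np.full(slope.shape, "ns", dtype=object)
    sig = p < spec.alpha
    call[sig & (slope > spec.slope_threshold)] = "up"
    call[sig & (slope < -spec.slope_threshold)] = "down"
    return call


# ---------------------------------------------------------------------------
# mixed-model drivers
# ---------------------------------------------------------------------------

def _check_single_arm(samples: pd.DataFrame) -> str:
    arms = set(samples["arm"])
    if len(arms) != 1 or not arms <= set(ARMS):
        raise StudyIOError(f"expected samples from exactly one arm, got {sorted(arms)}")
    return arms.pop()


def fit_transition_lmem(matrix: ExpressionMatrix, samples: pd.DataFrame,
                        transition: str, spec: ModelSpec) -> pd.DataFrame:
    """Mixed-model slopes for one visit transition in one arm.

    Returns one row per feature with the visit slope (later minus earlier
    visit, in matrix units), estimated variance components and the fit
    method (``reml`` or a flagged fallback).
    """
    if transition not in TRANSITION_VISITS:
        raise StudyIOError(f"unknown transition {transition!r}")
    _check_single_arm(samples)
    earlier, later = TRANSITION_VISITS[transition]
    sub = samples[samples["visit"].isin([earlier, later])].reset_index(drop=True)
    by_subject = sub.groupby("subject_id")["visit"].nunique()
    if (by_subject == 2).sum() < 4:
        raise StudyIOError(
            f"transition {transition}: need >= 4 subjects observed at both visits"
        )
    indicator = (sub["visit"] == later).to_numpy(dtype=float)
    X, names = design_matrix(sub, indicator, spec.covariates)
    codes, positions = _subject_positions(sub, spec.grouping)
    ws = RandomInterceptWorkspace(codes, len(positions))
    values = matrix.data[sub["sample_id"]].to_numpy(dtype=float)
    rows = []
    for i, fid in enumerate(matrix.feature_ids):
        fit = ws.fit(values[i], X)
        rows.append((fid, transition, fit.beta[1], fit.sigma2_subject,
                     fit.sigma2_resid, fit.method))
    return pd.DataFrame(rows, columns=["feature_id", "transition", "slope",
                                       "sigma2_subject", "sigma2_resid", "method"])


def _permutation_run(matrix: ExpressionMatrix, sub: pd.DataFrame,
                     indicator: np.ndarray, spec: ModelSpec,
                     stage: str, label: str) -> pd.DataFrame:
    """Observed fits + within-subject permutation null + calls."""
    X, _ = design_matrix(sub, indicator, spec.covariates)
    codes, positions = _subject_positions(sub, spec.grouping)
    ws = RandomInterceptWorkspace(codes, len(positions))
    values = matrix.data[sub["sample_id"]].to_numpy(dtype=float)
    n_features = values.shape[0]

    slopes = np.empty(n_features)
    methods = []
    for i in range(n_features):
        fit = ws.fit(values[i], X)
        slopes[i] = fit.beta[1]
        methods.append(fit.method)

    n_obs = len(sub)
    exact = _exact_permutation_indices(positions, n_obs, spec.n_resamples)
    if exact is not None:
        logger.warning(
            "%s: only %d within-subject permutations; exact test replaces "
            "B=%d random draws", stage, len(exact) + 1, spec.n_resamples)

    constant = np.array([m == "constant" for m in methods])
    identity = np.arange(n_obs)

    def null_slopes_for(i: int, index_sets) -> np.ndarray:
        out = np.empty(len(index_sets))
        for b, idx in enumerate(index_sets):
            out[b] = ws.fit(values[i][idx], X).beta[1]
        return out

    if spec.resampling_mode == "pooled_null":
        rng = np.random.default_rng(_stage_seed(spec.seed, stage, "pool"))
        pool = np.empty(spec.n_resamples)
        if exact is not None:
            index_sets = [exact[b % len(exact)] for b in range(spec.n_resamples)]
        else:
            index_sets = [_permute_within_subjects(identity, positions, rng)
                          for _ in range(spec.n_resamples)]
        live = np.flatnonzero(~constant)
        if len(live) == 0:
            pvals = np.ones(n_features)
        else:
            for b, idx in enumerate(index_sets):
                i = live[b % len(live)]
                pool[b] = ws.fit(values[i][idx], X).beta[1]
            pvals = empirical_pvalue(slopes, np.abs(pool), mode="pooled_null")
    else:
        pvals = np.empty(n_features)
        for i, fid in enumerate(matrix.feature_ids):
            if constant[i]:
                pvals[i] = 1.0
                continue
            if exact is not None:
                index_sets = exact
            else:
                rng = np.random.default_rng(_stage_seed(spec.seed, stage, str(fid)))
                index_sets = [_permute_within_subjects(identity, positions, rng)
                              for _ in range(spec.n_resamples)]
            null = null_slopes_for(i, index_sets)
            pvals[i] = empirical_pvalue(slopes[[i]], [np.abs(null)])[0]
    pvals[constant] = 1.0

    calls = call_significance(slopes, pvals, spec)
    result = pd.DataFrame({
        "feature_id": matrix.feature_ids,
        "transition": label,
        "slope": slopes,
        "empirical_p": pvals,
        "call": calls,
        "method": methods,
    })
    n_perm = len(exact) if exact is not None else spec.n_resamples
    result.attrs["n_perm"] = n_perm
    logger.info("%s: %d features, %d up / %d down (B=%d, mode=%s)",
                stage, n_features, (calls == "up").sum(), (calls == "down").sum(),
                n_perm, spec.resampling_mode)
    return result


def run_transition(matrix: ExpressionMatrix, samples: pd.DataFrame,
                   transition: str, spec: ModelSpec) -> pd.DataFrame:
    """Full transition analysis: slopes, empirical P-values and calls."""
    if transition not in TRANSITION_VISITS:
        raise StudyIOError(f"unknown transition {transition!r}")
    arm = _check_single_arm(samples)
    earlier, later = TRANSITION_VISITS[transition]
    sub = samples[samples["visit"].isin([earlier, later])].reset_index(drop=True)
    by_subject = sub.groupby("subject_id")["visit"].nunique()
    if (by_subject == 2).sum() < 4:
        raise StudyIOError(
            f"transition {transition}: need >= 4 subjects observed at both visits"
        )
    indicator = (sub["visit"] == later).to_numpy(dtype=float)
    return _permutation_run(matrix, sub, indicator, spec,
                            stage=f"{arm}:{transition}", label=transition)


def fit_condition_lmem(matrix: ExpressionMatrix, samples: pd.DataFrame,
                       spec: ModelSpec) -> pd.DataFrame:
    """Condition (high-DBP vs background) analysis pooling all visits of an
    arm; a subject's visits act as replicates of their condition."""
    arm = _check_single_arm(samples)
    sub = samples.reset_index(drop=True)
    conditions = set(sub["condition"])
    if len(conditions) < 2:
        raise StudyIOError(f"arm {arm}: only one condition present, cannot contrast")
    indicator = (sub["condition"] == "high_dbp").to_numpy(dtype=float)
    return _permutation_run(matrix, sub, indicator, spec,
                            stage=f"{arm}:condition", label="condition")


run_condition = fit_condition_lmem


# ---------------------------------------------------------------------------
# small-RNA filters
# ---------------------------------------------------------------------------

def filter_small_libraries(samples: pd.DataFrame,
                           min_reads: int = MIN_INPUT_READS) -> pd.DataFrame:
    """Retain libraries with at least ``min_reads`` input reads (default
    50,000, inclusive at the boundary)."""
    if "input_reads" not in samples.columns:
        raise StudyIOError("sample sheet has no input_reads column")
    reads = pd.to_numeric(samples["input_reads"], errors="coerce")
    if reads.isna().any():
        bad = samples.loc[reads.isna(), "sample_id"].iloc[0]
        raise StudyIOError(f"sample {bad!r}: missing input_reads")
    kept = samples[reads >= min_reads]
    logger.info("read-depth filter (>= %d): %d of %d libraries retained",
                min_reads, len(kept), len(samples))
    return kept


def highly_expressed_small(matrix: ExpressionMatrix,
                           median_threshold: float = HIGH_SMALL_MEDIAN) -> pd.Index:
    """Features whose median RPM across all samples strictly exceeds the
    threshold (default 50)."""
    medians = matrix.data.median(axis=1)
    return matrix.feature_ids[medians > median_threshold]


def small_family_summary(features, families: pd.Series) -> pd.Series:
    """Counts per small-RNA family (piRNA, miRNA, tRF, ...) for a feature set."""
    return families.reindex(features).fillna("unknown").value_counts()


# ---------------------------------------------------------------------------
# IBD vs control
# ---------------------------------------------------------------------------

def _ols_group_test(Y: np.ndarray, X: np.ndarray, group_col: int = 1):
    """Vectorised OLS of every feature on X; t-test on the group column."""
    n, p = X.shape
    XtX = X.T @ X
    XtX_inv = np.linalg.pinv(XtX)
    beta = XtX_inv @ (X.T @ Y.T)          # p x F
    resid = Y.T - X @ beta
    dof = n - np.linalg.matrix_rank(X)
    s2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(s2 * XtX_inv[group_col, group_col], 1e-300))
    t = beta[group_col] / se
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    return beta[group_col], pvals


def ibd_linear_model(control_matrix: ExpressionMatrix, control_samples: pd.DataFrame,
                     ibd_matrix: ExpressionMatrix, ibd_samples: pd.DataFrame,
                     covariates: list[str] | None = None, B: int = 100,
                     seed: int = 0, alpha: float = 0.05,
                     slope_threshold: float = 10.0) -> pd.DataFrame:
    """Compare one study visit of the IBD arm against an external control
    cohort.

    Per resample, one sample is drawn per IBD subject (absorbing replicate
    visits), and each feature is fit by OLS of expression on cohort with the
    control group coded 1 — a positive slope means higher expression in
    controls.  Median slope and median P across resamples are reported,
    with Benjamini-Hochberg adjustment across features.
    """
    if not control_matrix.feature_ids.equals(ibd_matrix.feature_ids):
        raise StudyIOError("control and IBD matrices must share feature ids")
    covariates = covariates or []
    groups = [np.flatnonzero((ibd_samples["subject_id"] == s).to_numpy())
              for s in ibd_samples["subject_id"].unique()]
    empty = [i for i, g in enumerate(groups) if len(g) == 0]
    if empty:
        logger.warning("dropping %d subjects with no samples at this visit", len(empty))
    groups = [g for g in groups if len(g)]
    if not groups:
        raise StudyIOError("no IBD samples at this visit")
    replicated = any(len(g) > 1 for g in groups)
    B_eff = B if replicated else 1
    rng = np.random.default_rng(_stage_seed(seed, "ibd"))

    ctrl_vals = control_matrix.data[control_samples["sample_id"]].to_numpy(dtype=float)
    ibd_vals = ibd_matrix.data[ibd_samples["sample_id"].to_numpy()].to_numpy(dtype=float)
    n_features = ctrl_vals.shape[0]

    slopes = np.empty((B_eff, n_features))
    pvals = np.empty((B_eff, n_features))
    for b in range(B_eff):
        picks = np.array([g[rng.integers(len(g))] for g in groups])
        frame = pd.concat(
            [control_samples, ibd_samples.iloc[picks]], ignore_index=True)
        group = np.r_[np.ones(len(control_samples)), np.zeros(len(picks))]
        X, _ = design_matrix(frame, group, covariates)
        Y = np.hstack([ctrl_vals, ibd_vals[:, picks]])
        slopes[b], pvals[b] = _ols_group_test(Y, X)

    med_slope = np.median(slopes, axis=0)
    med_p = np.median(pvals, axis=0)
    bh = bh_adjust(med_p)
    call = np.full(n_features, "ns", dtype=object)
    sig = bh < alpha
    call[sig & (med_slope > slope_threshold)] = "up"
    call[sig & (med_slope < -slope_threshold)] = "down"
    out = pd.DataFrame({
        "feature_id": control_matrix.feature_ids,
        "transition": "visit_vs_control",
        "slope": med_slope,
        "p_raw": med_p,
        "bh_p": bh,
        "call": call,
    })
    out.attrs["n_resamples"] = B_eff
    return out


def consensus_two_of_three(results_b1: pd.DataFrame, results_h: pd.DataFrame,
                           results_b2: pd.DataFrame) -> pd.DataFrame:
    """Features called in the same direction in >= 2 of the 3 visit-vs-control
    comparisons; a conflicting third call is retained but flagged."""
    calls = pd.DataFrame({
        "B1": results_b1.set_index("feature_id")["call"],
        "H": results_h.set_index("feature_id")["call"],
        "B2": results_b2.set_index("feature_id")["call"],
    })
    ups = (calls == "up").sum(axis=1)
    downs = (calls == "down").sum(axis=1)
    direction = np.where(ups >= 2, "up", np.where(downs >= 2, "down", "ns"))
    keep = direction != "ns"
    out = pd.DataFrame({
        "feature_id": calls.index[keep],
        "direction": direction[keep],
        "n_support": np.maximum(ups, downs)[keep].astype(int),
        "conflict": ((ups > 0) & (downs > 0))[keep].to_numpy(),
    }).reset_index(drop=True)
    n_conflict = int(out["conflict"].sum())
    if n_conflict:
        logger.warning("%d consensus REs carry a conflicting third call", n_conflict)
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_adjust")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out
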