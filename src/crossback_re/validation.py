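"""Self-validation studies: planted-truth simulations exercised end to end.

Each function simulates a study with :mod:`crossback_re.synthetic_data`,
runs the corresponding analysis stage and returns summary measures of how
well the known truth is recovered (type-I error under the null, slope bias,
pattern-classification accuracy, planted repeat-enrichment detection).
They are consumed by the acceptance test-suite and by the repository's
acceptance script; problem sizes default to what a single CPU handles in a
few minutes.
"""

from __future__ import annotations

import pandas as pd

from . import diff_expression as de
from . import patterns as pt
from . import repeat_enrichment as renr
from . import synthetic_data as sd

__all__ = [
    "null_calibration",
    "slope_recovery",
    "pattern_recovery",
    "planted_repeat_enrichment",
]


def _one_arm_design(n_subjects: int, seed: int) -> pd.DataFrame:
    design = sd.generate_design(sd.StudyDesignSpec(
        n_subjects_arm_bhb=n_subjects, n_subjects_arm_hbh=0,
        p_missing_visit=0.0, p_replicate_visit=0.0, seed=seed))
    return design


def null_calibration(seed: int, n_features: int = 500, n_subjects: int = 20,
                     B: int = 200, alpha: float = 0.05) -> dict:
    """Type-I error of the permutation empirical P under a planted null.

    All features are null; the rejection rate at ``alpha`` (on the P-value
    alone, ignoring the slope threshold) should match ``alpha``.
    """
    design = _one_arm_design(n_subjects, seed)
    noise = sd.NoiseSpec(subject_intercept_sd=10.0, residual_sd=5.0)
    matrix, _ = sd.generate_long_matrix(design, n_features, {}, noise,
                                        seed=seed + 1)
    spec = de.ModelSpec(n_resamples=B, alpha=alpha, seed=seed + 2)
    res = de.run_transition(matrix, design, "T1", spec)
    rate = float((res["empirical_p"] < alpha).mean())
    return {"rejection_rate": rate, "alpha": alpha, "n_features": n_features,
            "pvalues": res["empirical_p"].to_numpy()}


def slope_recovery(seed: int, deltas=(10.0, 20.0, 40.0),
                   n_features: int = 200, n_subjects: int = 20,
                   residual_sd: float = 5.0) -> dict:
    """Mean mixed-model slope for planted acute effects of known size."""
    design = _one_arm_design(n_subjects, seed)
    noise = sd.NoiseSpec(subject_intercept_sd=10.0, residual_sd=residual_sd)
    spec = de.ModelSpec(n_resamples=19, seed=seed)
    out = {}
    for k, delta in enumerate(deltas):
        matrix, truth = sd.generate_long_matrix(
            design, n_features, {"acute_up": 1.0}, noise,
            seed=seed + 10 + k, effect_size=float(delta))
        fits = de.fit_transition_lmem(matrix, design, "T1", spec)
        out[float(delta)] = float(fits["slope"].mean())
    return {"mean_slopes": out, "n_features": n_features}


def pattern_recovery(seed: int, effect_size: float = 30.0,
                     n_planted_per_class: int = 12, n_null: int = 24,
                     n_subjects: int = 20, B: int = 500) -> dict:
    """Fraction of planted features assigned their true response class."""
    planted_classes = [c for c in pt.RESPONSE_CLASSES if c != "none"]
    n_features = n_planted_per_class * len(planted_classes) + n_null
    fractions = {c: n_planted_per_class / n_features for c in planted_classes}
    design = _one_arm_design(n_subjects, seed)
    noise = sd.NoiseSpec(subject_intercept_sd=10.0, residual_sd=5.0)
    matrix, truth = sd.generate_long_matrix(
        design, n_features, fractions, noise, seed=seed + 20,
        effect_size=effect_size)
    spec = de.ModelSpec(n_resamples=B, seed=seed + 21)
    res_t1 = de.run_transition(matrix, design, "T1", spec)
    res_t2 = de.run_transition(matrix, design, "T2", spec)
    calls = pt.classify_patterns(res_t1, res_t2).merge(truth, on="feature_id")
    planted = calls[calls["response_class_y"] != "none"]
    accuracy = float(
        (planted["response_class_x"] == planted["response_class_y"]).mean())
    correct = planted["response_class_x"] == planted["response_class_y"]
    per_class = correct.groupby(planted["response_class_y"]).mean()
    return {"accuracy": accuracy, "n_planted": len(planted),
            "per_class": per_class.to_dict()}


def planted_repeat_enrichment(seed: int, n_repeat_res: int = 10,
                              n_steady: int = 15, n_low: int = 15,
                              n_subjects_per_arm: int = 16) -> dict:
    """A repeat group expressed only under high DBP: enrichment should be
    flagged at every high-DBP visit but not at the DBP-naive baseline of the
    background-first arm."""
    design = sd.generate_design(sd.StudyDesignSpec(
        n_subjects_arm_bhb=n_subjects_per_arm,
        n_subjects_arm_hbh=n_subjects_per_arm,
        p_missing_visit=0.0, p_replicate_visit=0.0, seed=seed))
    n = n_repeat_res + n_steady + n_low
    ids = [f"re_{i:06d}" for i in range(n)]
    annotation = pd.DataFrame({
        "re_id": ids,
        "re_class": "orphan",
        "repeat_names": [["(TTTC)n"]] * n_repeat_res
        + [["GA-rich"]] * (n_steady + n_low),
    }).set_index("re_id", drop=False)
    cond = {ids[i]: 40.0 for i in range(n_repeat_res)}
    noise = sd.NoiseSpec(subject_intercept_sd=0.0, residual_sd=2.0)
    matrix, _ = sd.generate_long_matrix(
        design, n, {}, noise, seed=seed + 30, baseline_range=(10.0, 10.0),
        condition_deltas=cond)
    steady = ids[n_repeat_res:n_repeat_res + n_steady]
    matrix.data.loc[steady] += 25.0  # constitutively expressed background
    res = renr.enrichment_by_visit(matrix, design, annotation)
    res = res.set_index(["arm", "visit", "repeat_name"])
    high_visits = [("B1HB2", "crossover"), ("H1BH2", "baseline"),
                   ("H1BH2", "crossback")]
    high = {f"{arm}:{visit}": res.loc[(arm, visit, "(TTTC)n")]
            for arm, visit in high_visits}
    naive = res.loc[("B1HB2", "baseline", "(TTTC)n")]
    return {
        "high_enriched": all(r["direction"] == "enriched" and r["p_hyper"] < 0.05
                             for r in high.values()),
        "naive_not_enriched": naive["direction"] != "enriched",
        "high_delta_ratios": {k: float(r["delta_ratio"]) for k, r in high.items()},
        "high_p": {k: float(r["p_hyper"]) for k, r in high.items()},
        "naive_delta_ratio": float(naive["delta_ratio"]),
    }
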