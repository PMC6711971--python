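"""Delta-ratio statistic and hypergeometric testing vs exact enumeration."""

import math

import numpy as np
import pandas as pd
import pytest

from crossback_re import repeat_enrichment as renr
from crossback_re import synthetic_data as sd
from crossback_re.study_io import ExpressionMatrix, StudyIOError


def exact_hypergeom_tail(R, A, R_expressed, A_expressed, direction):
    """Exact tail probability by summing the probability mass directly."""
    total = 0
    denom = math.comb(A, A_expressed)
    ks = range(R_expressed, min(R, A_expressed) + 1) if direction == "enriched" \
        else range(0, R_expressed + 1)
    for k in ks:
        if A_expressed - k <= A - R:
            total += math.comb(R, k) * math.comb(A - R, A_expressed - k)
    return total / denom


class TestDeltaRatio:
    def test_worked_example(self):
        assert renr.delta_ratio(10, 100, 5, 20) == pytest.approx(0.15)

    def test_no_threshold_is_identity_zero(self):
        assert renr.delta_ratio(7, 31, 7, 31) == 0.0

    def test_depletion_sign(self):
        assert renr.delta_ratio(50, 100, 0, 30) == pytest.approx(-0.5)

    def test_no_expressed_universe_rejected(self):
        with pytest.raises(StudyIOError, match="A_expressed"):
            renr.delta_ratio(5, 10, 0, 0)

    def test_antisymmetric_under_complementing_an_even_split(self):
        """When the expressed set is half the universe, swapping 'expressed'
        for its complement flips the sign exactly."""
        for R, A, Re in [(12, 40, 9), (5, 10, 4), (20, 60, 3)]:
            Ae = A // 2
            d1 = renr.delta_ratio(R, A, Re, Ae)
            d2 = renr.delta_ratio(R, A, R - Re, A - Ae)
            assert d1 + d2 == pytest.approx(0.0, abs=1e-12)


class TestHypergeomTest:
    def test_enrichment_worked_example(self):
        # A=10, R=5, A_expressed=4, all four expressed from R
        p = renr.hypergeom_test(5, 10, 4, 4, "enriched")
        assert p == pytest.approx(5 / 210, abs=1e-12)

    def test_depletion_worked_example(self):
        p = renr.hypergeom_test(5, 10, 0, 4, "depleted")
        assert p == pytest.approx(5 / 210, abs=1e-12)

    def test_degenerate_full_draw(self):
        assert renr.hypergeom_test(5, 10, 5, 10, "enriched") == pytest.approx(1.0)

    def test_none_direction_is_one(self):
        assert renr.hypergeom_test(5, 10, 2, 4, "none") == 1.0

    def test_matches_exact_enumeration_sampled_configs(self, rng):
        """Spot-check both tails against direct mass summation."""
        for _ in range(300):
            A = int(rng.integers(1, 26))
            R = int(rng.integers(0, A + 1))
            Ae = int(rng.integers(1, A + 1))
            Re = int(rng.integers(max(0, Ae - (A - R)), min(R, Ae) + 1))
            for direction in ("enriched", "depleted"):
                expected = exact_hypergeom_tail(R, A, Re, Ae, direction)
                assert renr.hypergeom_test(R, A, Re, Ae, direction) == \
                    pytest.approx(expected, abs=1e-12)


class TestExpressedFilter:
    def _matrix(self):
        frame = pd.DataFrame({
            "s1": [30.0, 0.0, 25.0, 10.0],
            "s2": [30.0, 0.0, 25.0, 40.0],
            "s3": [30.0, 0.0, 25.0, 80.0],
        }, index=["steady", "silent", "boundary", "mixed"])
        return ExpressionMatrix(frame, "RPKM")

    def test_median_threshold_inclusive(self):
        kept = renr.expressed_filter(self._matrix(), ["s1", "s2", "s3"])
        assert list(kept) == ["steady", "boundary", "mixed"]

    def test_all_zero_not_expressed(self):
        kept = renr.expressed_filter(self._matrix(), ["s1", "s2", "s3"])
        assert "silent" not in kept

    def test_empty_sample_set_rejected(self):
        with pytest.raises(StudyIOError, match="empty sample set"):
            renr.expressed_filter(self._matrix(), [])

    def test_counts_monotone_in_threshold(self, rng):
        frame = pd.DataFrame(rng.uniform(0, 60, (50, 6)),
                             index=[f"f{i}" for i in range(50)],
                             columns=[f"s{i}" for i in range(6)])
        matrix = ExpressionMatrix(frame, "RPKM")
        sizes = [len(renr.expressed_filter(matrix, frame.columns, t))
                 for t in (0, 10, 20, 30, 40, 50)]
        assert sizes == sorted(sizes, reverse=True)


def _annotation(repeats_per_feature):
    rows = []
    for i, reps in enumerate(repeats_per_feature):
        rows.append({"re_id": f"re_{i:06d}", "re_class": "orphan",
                     "repeat_names": reps})
    return pd.DataFrame(rows).set_index("re_id", drop=False)


class TestEnrichmentByVisit:
    def test_planted_high_condition_enrichment(self, full_design):
        """A repeat group expressed only under high DBP is enriched at
        high-DBP visits and not at the naive baseline visit."""
        n = 40
        reps = [["(TTTC)n"] if i < 10 else ["GA-rich"] for i in range(n)]
        annotation = _annotation(reps)
        noise = sd.NoiseSpec(subject_intercept_sd=0.0, residual_sd=2.0)
        cond = {f"re_{i:06d}": 40.0 for i in range(10)}
        matrix, _ = sd.generate_long_matrix(
            full_design, n, {}, noise, seed=13, baseline_range=(10.0, 10.0),
            condition_deltas=cond)
        # 15 GA-rich REs are constitutively expressed; the rest stay low
        steady = [f"re_{i:06d}" for i in range(10, 25)]
        matrix.data.loc[steady] += 25.0
        res = renr.enrichment_by_visit(matrix, full_design, annotation)
        res = res.set_index(["arm", "visit", "repeat_name"])
        for arm, visit in [("B1HB2", "crossover"), ("H1BH2", "baseline"),
                           ("H1BH2", "crossback")]:
            high = res.loc[(arm, visit, "(TTTC)n")]
            assert high["direction"] == "enriched"
            assert high["p_hyper"] < 0.05
        naive = res.loc[("B1HB2", "baseline", "(TTTC)n")]
        assert naive["direction"] != "enriched"

    def test_uniform_expression_no_signal(self, full_design):
        annotation = _annotation([["GA-rich"] if i % 2 else ["(TTTC)n"]
                                  for i in range(20)])
        noise = sd.NoiseSpec(subject_intercept_sd=0.0, residual_sd=1.0)
        matrix, _ = sd.generate_long_matrix(full_design, 20, {}, noise, seed=14,
                                            baseline_range=(60.0, 60.0))
        res = renr.enrichment_by_visit(matrix, full_design, annotation)
        assert (res["bh_p"] > 0.05).all()

    def test_stratified_run_emits_class_rows(self, full_design):
        annotation = _annotation([["GA-rich"]] * 10)
        annotation.loc[annotation.index[:5], "re_class"] = "intronic"
        noise = sd.NoiseSpec(subject_intercept_sd=0.0, residual_sd=1.0)
        matrix, _ = sd.generate_long_matrix(full_design, 10, {}, noise, seed=15)
        res = renr.enrichment_by_visit(matrix, full_design, annotation,
                                       stratify_class=True)
        assert set(res["re_class"]) == {"intronic", "orphan"}

    def test_non_repeat_res_outside_universe(self, full_design):
        annotation = _annotation([["GA-rich"]] * 5 + [[]] * 15)
        noise = sd.NoiseSpec(subject_intercept_sd=0.0, residual_sd=1.0)
        matrix, _ = sd.generate_long_matrix(full_design, 20, {}, noise, seed=16)
        res = renr.enrichment_by_visit(matrix, full_design, annotation)
        assert (res["A"] == 5).all()


class TestDifferentialRepeatCounts:
    def _calls(self, classes):
        return pd.DataFrame({
            "feature_id": [f"re_{i:06d}" for i in range(len(classes))],
            "response_class": classes,
        })

    def test_no_differential_res_empty(self):
        annotation = _annotation([["GA-rich"]] * 3)
        out = renr.differential_repeat_counts(self._calls(["none"] * 3),
                                              annotation)
        assert out.empty

    def test_multi_repeat_re_counted_once_per_repeat(self):
        annotation = _annotation([["GA-rich", "(TTTC)n"]])
        out = renr.differential_repeat_counts(self._calls(["acute_down"]),
                                              annotation)
        assert len(out) == 2 and (out["n"] == 1).all()

    def test_planted_class_recovered_in_cell(self):
        annotation = _annotation([["(AATGGAATGG)n"]] * 4)
        out = renr.differential_repeat_counts(
            self._calls(["acute_down", "acute_down", "none", "recovery_up"]),
            annotation)
        cell = out[(out["repeat_name"] == "(AATGGAATGG)n")
                   & (out["response_class"] == "acute_down")]
        assert cell["n"].iloc[0] == 2
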