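"""Differential testing: permutation P-values, calls, IBD model, BH."""

import itertools

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from crossback_re import diff_expression as de
from crossback_re import synthetic_data as sd
from crossback_re.study_io import ExpressionMatrix, StudyIOError


def spec(**kw):
    kw.setdefault("n_resamples", 99)
    kw.setdefault("seed", 0)
    return de.ModelSpec(**kw)


class TestEmpiricalPvalue:
    def test_minimum_attainable_p(self):
        p = de.empirical_pvalue([50.0], [np.zeros(999)])
        assert p[0] == pytest.approx(1 / 1000)

    def test_counting_formula(self):
        # B=4 permutations, 2 null slopes at least as extreme -> (1+2)/5
        p = de.empirical_pvalue([3.0], [np.array([1.0, 5.0, -4.0, 2.0])])
        assert p[0] == pytest.approx(3 / 5)

    def test_pooled_mode_shares_the_null(self):
        pool = np.array([1.0, 2.0, 3.0, 4.0])
        p = de.empirical_pvalue([2.5, 10.0], pool, mode="pooled_null")
        assert p[0] == pytest.approx((1 + 2) / 5)
        assert p[1] == pytest.approx(1 / 5)

    def test_never_zero_and_bounded(self, rng):
        obs = rng.normal(size=50)
        nulls = [rng.normal(size=200) for _ in range(50)]
        p = de.empirical_pvalue(obs, nulls)
        assert (p >= 1 / 201).all() and (p <= 1.0).all()


class TestCallSignificance:
    long_spec = spec(slope_threshold=10.0, alpha=0.05)
    small_spec = spec(slope_threshold=5.0, alpha=0.05)

    @pytest.mark.parametrize("slope,p,model,expected", [
        (15.0, 0.01, "long", "up"),
        (9.9, 0.001, "long", "ns"),      # threshold strict: must exceed 10
        (10.0, 0.001, "long", "ns"),
        (-12.0, 0.04, "long", "down"),
        (-6.0, 0.04, "small", "down"),
        (-6.0, 0.05, "small", "ns"),     # alpha strict
        (4.0, 0.001, "small", "ns"),
    ])
    def test_threshold_conventions(self, slope, p, model, expected):
        s = self.long_spec if model == "long" else self.small_spec
        assert de.call_significance(slope, p, s)[0] == expected


class TestTransitionAnalysis:
    def _matrix(self, design, n, fractions, sigma_u=5.0, sigma_e=5.0, seed=1,
                effect=30.0):
        noise = sd.NoiseSpec(subject_intercept_sd=sigma_u, residual_sd=sigma_e)
        return sd.generate_long_matrix(design, n, fractions, noise, seed=seed,
                                       effect_size=effect)

    def test_noiseless_slope_recovery(self, bhb_design):
        matrix, truth = self._matrix(bhb_design, 5, {"acute_up": 0.4},
                                     sigma_u=0.0, sigma_e=0.0)
        res = de.fit_transition_lmem(matrix, bhb_design, "T1", spec())
        merged = res.merge(truth, on="feature_id")
        planted = merged[merged["response_class"] == "acute_up"]
        assert np.allclose(planted["slope"], 30.0, atol=1e-6)

    def test_planted_effect_called_up(self, bhb_design):
        matrix, truth = self._matrix(bhb_design, 30, {"acute_up": 0.3},
                                     sigma_e=2.0)
        res = de.run_transition(matrix, bhb_design, "T1", spec(seed=5))
        merged = res.merge(truth, on="feature_id")
        planted = merged[merged["response_class"] == "acute_up"]
        assert (planted["call"] == "up").all()

    def test_confounded_covariate_biases_without_adjustment(self, bhb_design):
        """A technical covariate aligned with visit biases the slope unless
        it is in the model."""
        confounded = bhb_design.copy()
        gen = np.random.default_rng(17)
        # amplification efficiency drops at crossover but varies by sample,
        # so visit and covariate are correlated yet separable
        confounded["amplification_efficiency"] = np.round(
            np.where(confounded["visit"] == "crossover", 0.5, 0.8)
            + gen.normal(0, 0.1, len(confounded)), 4)
        noise = sd.NoiseSpec(subject_intercept_sd=0.0, residual_sd=1.0,
                             covariate_effects={"amplification_efficiency": 50.0})
        matrix, _ = sd.generate_long_matrix(confounded, 30, {}, noise, seed=3)
        adjusted = de.fit_transition_lmem(
            matrix, confounded, "T1", spec(covariates=["amplification_efficiency"]))
        unadjusted = de.fit_transition_lmem(
            matrix, confounded, "T1", spec(covariates=[]))
        assert abs(adjusted["slope"].mean()) < 2.0
        # bias equals coefficient x covariate shift = 50 x (0.5 - 0.8) = -15
        assert unadjusted["slope"].mean() == pytest.approx(-15.0, abs=3.0)

    def test_permutations_preserve_subject_sample_counts(self, bhb_design):
        from crossback_re.diff_expression import (_permute_within_subjects,
                                                  _subject_positions)

        sub = bhb_design[bhb_design["visit"].isin(["baseline", "crossover"])]
        sub = sub.reset_index(drop=True)
        indicator = (sub["visit"] == "crossover").to_numpy(float)
        _, positions = _subject_positions(sub, "subject_id")
        rng = np.random.default_rng(0)
        for _ in range(20):
            perm = _permute_within_subjects(indicator, positions, rng)
            for pos in positions:
                assert sorted(perm[pos]) == sorted(indicator[pos])

    def test_exact_test_when_few_arrangements(self):
        """6 paired subjects -> 2^6 = 64 arrangements < B, exact test used."""
        design = sd.generate_design(sd.StudyDesignSpec(6, 0, 0.0, 0.0, seed=2))
        noise = sd.NoiseSpec(subject_intercept_sd=0.0, residual_sd=3.0)
        matrix, _ = sd.generate_long_matrix(design, 3, {}, noise, seed=2)
        res = de.run_transition(matrix, design, "T1",
                                spec(n_resamples=500, covariates=[]))
        assert res.attrs["n_perm"] == 63  # observed arrangement excluded
        assert (res["empirical_p"] >= 1 / 64).all()

    def test_single_arm_enforced(self, full_design):
        matrix, _ = self._matrix(full_design, 2, {})
        with pytest.raises(StudyIOError, match="one arm"):
            de.run_transition(matrix, full_design, "T1", spec())

    def test_too_few_paired_subjects_rejected(self):
        design = sd.generate_design(sd.StudyDesignSpec(3, 0, 0.0, 0.0, seed=4))
        matrix, _ = self._matrix(design, 2, {})
        with pytest.raises(StudyIOError, match=">= 4 subjects"):
            de.run_transition(matrix, design, "T1", spec())


class TestConditionAnalysis:
    def test_planted_condition_effect_recovered(self, full_design):
        noise = sd.NoiseSpec(subject_intercept_sd=3.0, residual_sd=1.0)
        matrix, truth, _ = sd.generate_small_matrix(
            full_design, 20, {"condition_up": 0.5}, noise, seed=6,
            effect_size=10.0)
        arm = full_design[full_design["arm"] == "H1BH2"]
        res = de.fit_condition_lmem(matrix, arm, de.small_rna_spec(
            n_resamples=99, seed=7))
        merged = res.merge(truth, on="feature_id")
        planted = merged[merged["response_class"] == "condition_up"]
        assert planted["slope"].mean() == pytest.approx(10.0, abs=1.0)
        assert (planted["call"] == "up").mean() > 0.9

    def test_single_condition_rejected(self, full_design):
        arm = full_design[(full_design["arm"] == "B1HB2")
                          & (full_design["visit"] == "baseline")]
        matrix, _, _ = sd.generate_small_matrix(full_design, 3, {},
                                                sd.NoiseSpec(), seed=8)
        with pytest.raises(StudyIOError, match="one condition"):
            de.fit_condition_lmem(matrix, arm, de.small_rna_spec(
                n_resamples=19, seed=1))


class TestSmallFilters:
    def _sheet(self, reads):
        return pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(len(reads))],
            "input_reads": reads,
        })

    @pytest.mark.parametrize("reads,kept", [(49_999, 0), (50_000, 1), (50_001, 1)])
    def test_library_threshold_boundary(self, reads, kept):
        assert len(de.filter_small_libraries(self._sheet([reads]))) == kept

    def test_missing_reads_error(self):
        sheet = self._sheet([60_000, None])
        with pytest.raises(StudyIOError, match="missing input_reads"):
            de.filter_small_libraries(sheet)

    def test_median_threshold_strictly_exceeding(self):
        frame = pd.DataFrame({
            "a": [50.0, 51.0, 100.0], "b": [50.0, 51.0, 100.0],
            "c": [50.0, 51.0, 100.0],
        }, index=["at_50", "just_above", "high"])
        matrix = ExpressionMatrix(frame, "RPM")
        kept = de.highly_expressed_small(matrix)
        assert list(kept) == ["just_above", "high"]

    def test_family_summary_counts(self):
        families = pd.Series({"mir1": "miRNA", "pir1": "piRNA", "pir2": "piRNA"})
        counts = de.small_family_summary(["pir1", "pir2", "novel1"], families)
        assert counts["piRNA"] == 2 and counts["unknown"] == 1

    def test_planted_set_recovered_exactly(self, rng):
        n_high, n_low = 156, 244
        frame = pd.DataFrame(
            np.vstack([rng.uniform(60, 200, (n_high, 10)),
                       rng.uniform(0, 40, (n_low, 10))]),
            index=[f"f{i}" for i in range(n_high + n_low)],
            columns=[f"s{i}" for i in range(10)])
        kept = de.highly_expressed_small(ExpressionMatrix(frame, "RPM"))
        assert list(kept) == [f"f{i}" for i in range(n_high)]


class TestIBDModel:
    def _cohorts(self, rng, n_features=30, shift=0.0, replicates=False):
        n_ctrl, n_ibd = 20, 12
        base = rng.uniform(40, 120, n_features)
        ctrl = base[:, None] + shift + rng.normal(0, 5, (n_features, n_ctrl))
        ctrl_samples = pd.DataFrame({
            "sample_id": [f"c{i}" for i in range(n_ctrl)],
            "subject_id": [f"c{i}" for i in range(n_ctrl)],
        })
        reps = 2 if replicates else 1
        ibd = np.repeat(base[:, None], n_ibd * reps, axis=1) \
            + rng.normal(0, 5, (n_features, n_ibd * reps))
        ibd_samples = pd.DataFrame({
            "sample_id": [f"i{i}_{r}" for i in range(n_ibd) for r in range(reps)],
            "subject_id": [f"i{i}" for i in range(n_ibd) for r in range(reps)],
        })
        ids = [f"re{i}" for i in range(n_features)]
        return (ExpressionMatrix(pd.DataFrame(ctrl.clip(min=0), index=ids,
                                              columns=ctrl_samples["sample_id"]), "RPKM"),
                ctrl_samples,
                ExpressionMatrix(pd.DataFrame(ibd.clip(min=0), index=ids,
                                              columns=ibd_samples["sample_id"]), "RPKM"),
                ibd_samples)

    def test_no_replicates_collapses_to_single_ols(self, rng):
        cm, cs, im, isamp = self._cohorts(rng)
        a = de.ibd_linear_model(cm, cs, im, isamp, B=50, seed=1)
        b = de.ibd_linear_model(cm, cs, im, isamp, B=5, seed=99)
        pd.testing.assert_frame_equal(a, b)
        assert a.attrs["n_resamples"] == 1

    def test_planted_control_enrichment_detected(self, rng):
        cm, cs, im, isamp = self._cohorts(rng, shift=25.0, replicates=True)
        res = de.ibd_linear_model(cm, cs, im, isamp, B=25, seed=2)
        assert (res["slope"] > 0).all()
        assert (res["call"] == "up").mean() > 0.9

    def test_null_bh_controls_discoveries(self, rng):
        cm, cs, im, isamp = self._cohorts(rng, n_features=300, replicates=True)
        res = de.ibd_linear_model(cm, cs, im, isamp, B=10, seed=3)
        # null: essentially nothing should pass BH at 5%
        assert (res["call"] != "ns").mean() <= 0.01


class TestConsensus:
    @staticmethod
    def _results(calls):
        return [pd.DataFrame({"feature_id": ["f"], "call": [c]}) for c in calls]

    def test_agrees_with_hand_enumerated_oracle(self):
        """All 27 call triples against the 2-of-3 same-direction rule."""
        for triple in itertools.product(["up", "down", "ns"], repeat=3):
            out = de.consensus_two_of_three(*self._results(triple))
            ups, downs = triple.count("up"), triple.count("down")
            if ups >= 2:
                assert list(out["direction"]) == ["up"]
                assert out["conflict"].iloc[0] == (downs > 0)
            elif downs >= 2:
                assert list(out["direction"]) == ["down"]
                assert out["conflict"].iloc[0] == (ups > 0)
            else:
                assert out.empty

    def test_support_counts(self):
        out = de.consensus_two_of_three(*self._results(("up", "up", "up")))
        assert out["n_support"].iloc[0] == 3


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(de.bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert de.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_stay_one(self):
        assert (de.bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_matches_statsmodels_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(de.bh_adjust(p), ref, atol=1e-12)

    def test_adjusted_at_least_raw_and_capped(self, rng):
        p = rng.uniform(size=100)
        adj = de.bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            de.bh_adjust([0.1, np.nan])
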