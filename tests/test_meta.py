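"""Unit and property tests for the odds-ratio pooling machinery."""

import math

import numpy as np
import pytest

from hlalink.meta import (
    EffectEstimate,
    StudyRecord,
    cochran_q,
    effect_estimate,
    forest_data,
    pool,
    pool_fixed,
    read_study_table,
    sensitivity,
    tau_squared,
    write_study_table,
)

from _meta_oracle import oracle_pool
from conftest import random_study_set


def est(log_or, var):
    return EffectEstimate(log_or=log_or, variance=var)


class TestEffectEstimate:
    @pytest.mark.parametrize(
        "cells, expected_or, expected_var",
        [
            ((10, 10, 10, 10), 1.0, 0.4),
            ((20, 80, 10, 90), 2.25, 1 / 20 + 1 / 80 + 1 / 10 + 1 / 90),
            # zero cell: Haldane-Anscombe 0.5 on all four cells of this study
            ((0, 30, 5, 25), (0.5 * 25.5) / (30.5 * 5.5), 1 / 0.5 + 1 / 30.5 + 1 / 5.5 + 1 / 25.5),
        ],
    )
    def test_log_or_and_woolf_variance(self, cells, expected_or, expected_var):
        a, b, c, d = cells
        e = effect_estimate(StudyRecord("s", a=a, b=b, c=c, d=d))
        assert math.exp(e.log_or) == pytest.approx(expected_or, rel=1e-12)
        assert e.variance == pytest.approx(expected_var, rel=1e-12)
        assert e.weight == pytest.approx(1 / e.variance)

    def test_degenerate_studies_rejected(self):
        with pytest.raises(ValueError, match="zero cases"):
            StudyRecord("s", a=0, b=0, c=5, d=5)
        with pytest.raises(ValueError, match="zero controls"):
            StudyRecord("s", a=5, b=5, c=0, d=0)
        with pytest.raises(ValueError, match="negative|>= 0"):
            StudyRecord("s", a=-1, b=5, c=5, d=5)

    def test_correction_only_applied_on_zero_cells(self):
        no_zero = effect_estimate(StudyRecord("s", a=3, b=7, c=4, d=6), zero_cell_correction=0.5)
        assert math.exp(no_zero.log_or) == pytest.approx((3 * 6) / (7 * 4))


class TestPooling:
    def test_single_study_pools_to_itself(self):
        r = pool_fixed([est(math.log(2.25), 0.17)])
        assert r.pooled_or == pytest.approx(2.25)
        assert r.k == 1 and r.model == "fixed"
        assert r.ci_low == pytest.approx(math.exp(math.log(2.25) - 1.96 * 0.17 ** 0.5))

    def test_equal_weights_average_and_halve_variance(self):
        r = pool_fixed([est(0.1, 0.2), est(0.1, 0.2)])
        assert math.log(r.pooled_or) == pytest.approx(0.1)
        # pooled SE = sqrt(0.1); CI half-width = 1.96*sqrt(0.1) on log scale
        assert math.log(r.ci_high / r.pooled_or) == pytest.approx(1.96 * 0.1 ** 0.5)

    def test_symmetric_pair_pools_to_geometric_mean(self):
        r = pool_fixed([est(0.0, 1.0), est(math.log(4), 1.0)])
        assert r.pooled_or == pytest.approx(2.0)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            pool_fixed([])
        with pytest.raises(ValueError):
            pool([])


class TestHeterogeneity:
    def test_identical_estimates_have_zero_q(self):
        q, q_p = cochran_q([est(0.3, 0.5)] * 4)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert q_p == pytest.approx(1.0)

    def test_hand_computed_q(self):
        # w=1 each, fixed mean 1: Q = (0-1)^2 + (2-1)^2 = 2
        q, q_p = cochran_q([est(0.0, 1.0), est(2.0, 1.0)])
        assert q == pytest.approx(2.0)
        from scipy.stats import chi2

        assert q_p == pytest.approx(float(chi2.sf(2.0, 1)))

    def test_single_study_convention(self):
        assert cochran_q([est(0.5, 0.2)]) == (0.0, 1.0)

    def test_tau_squared_hand_value_and_clipping(self):
        pair = [est(0.0, 1.0), est(2.0, 1.0)]
        tau2, raw = tau_squared(pair, q=2.0)
        assert raw == pytest.approx(1.0)  # (2-1)/(2 - 2/2)
        assert tau2 == pytest.approx(1.0)
        tau2, raw = tau_squared(pair, q=0.2)
        assert raw < 0 and tau2 == 0.0

    def test_tau_squared_near_zero_for_homogeneous_simulation(self):
        from hlalink.simulate import StudySimSpec, gen_studies

        spec = StudySimSpec(
            n_studies=8,
            cases_sizes=(5000,) * 8,
            controls_sizes=(5000,) * 8,
            true_or=1.5,
            between_study_sd=0.0,
            seed=7,
        )
        ests = [effect_estimate(s) for s in gen_studies(spec)]
        q, _ = cochran_q(ests)
        tau2, _ = tau_squared(ests, q)
        assert tau2 < 0.01


class TestModelSelection:
    def test_homogeneous_studies_select_fixed(self):
        studies = [StudyRecord(f"s{i}", a=40, b=60, c=30, d=70) for i in range(5)]
        r = pool(studies)
        assert r.model == "fixed" and r.tau2 == 0.0
        assert r.q == pytest.approx(0.0, abs=1e-12)

    def test_heterogeneous_pair_selects_random_with_wider_ci(self):
        studies = [
            StudyRecord("a", a=80, b=20, c=20, d=80),
            StudyRecord("b", a=20, b=80, c=80, d=20),
        ]
        r = pool(studies)
        assert r.model == "random"
        ests = [effect_estimate(s) for s in studies]
        fixed = pool_fixed(ests)
        assert (r.ci_high / r.ci_low) > (fixed.ci_high / fixed.ci_low)

    def test_study_order_is_irrelevant(self):
        rng = np.random.default_rng(3)
        studies = random_study_set(rng)
        shuffled = list(studies)
        rng.shuffle(shuffled)
        a, b = pool(studies), pool(shuffled)
        assert a.model == b.model and a.k == b.k
        for key in ("pooled_or", "ci_low", "ci_high", "q", "q_p", "tau2"):
            assert getattr(a, key) == pytest.approx(getattr(b, key), rel=1e-12)

    def test_fixed_pooled_se_bounded_by_smallest_variance(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            ests = [effect_estimate(s) for s in random_study_set(rng)]
            r = pool_fixed(ests)
            se2 = (math.log(r.ci_high / r.pooled_or) / 1.96) ** 2
            assert se2 <= min(e.variance for e in ests) + 1e-12


class TestSensitivity:
    def test_identical_studies_leave_one_out_is_invariant(self):
        studies = [StudyRecord(f"s{i}", a=40, b=60, c=30, d=70) for i in range(4)]
        full = pool(studies)
        results = sensitivity(studies)
        assert len(results) == 4
        assert [r.excluded_label for r in results] == [s.label for s in studies]
        for r in results:
            assert r.result.pooled_or == pytest.approx(full.pooled_or)
            assert r.result.k == 3

    def test_excluding_outlier_moves_pooled_or_toward_remaining(self):
        base = StudyRecord("base", a=30, b=70, c=30, d=70)  # OR 1
        outlier = StudyRecord("out", a=80, b=20, c=20, d=80)  # OR 16
        results = sensitivity([base, StudyRecord("base2", a=30, b=70, c=30, d=70), outlier])
        without_outlier = next(r for r in results if r.excluded_label == "out")
        with_outlier = next(r for r in results if r.excluded_label == "base")
        assert without_outlier.result.pooled_or == pytest.approx(1.0)
        assert with_outlier.result.pooled_or > 1.5

    def test_requires_two_studies(self):
        with pytest.raises(ValueError):
            sensitivity([StudyRecord("s", a=1, b=1, c=1, d=1)])


class TestAgainstIndependentImplementations:
    def test_matches_brute_force_oracle_on_random_sets(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            studies = random_study_set(rng)
            mine = pool(studies)
            ref = oracle_pool([(s.a, s.b, s.c, s.d) for s in studies])
            assert mine.model == ref["model"]
            for key in ("pooled_or", "ci_low", "ci_high", "q", "q_p", "tau2"):
                assert getattr(mine, key) == pytest.approx(ref[key], abs=1e-9)

    def test_matches_statsmodels_dl_estimates(self):
        """Cross-check effect/tau2 against statsmodels' DL meta-analysis."""
        from statsmodels.stats.meta_analysis import combine_effects

        rng = np.random.default_rng(5)
        studies = random_study_set(rng)
        ests = [effect_estimate(s) for s in studies]
        res = combine_effects(
            np.array([e.log_or for e in ests]),
            np.array([e.variance for e in ests]),
            method_re="dl",
        )
        q, _ = cochran_q(ests)
        tau2, raw = tau_squared(ests, q)
        assert tau2 == pytest.approx(max(0.0, float(res.tau2)), abs=1e-10)
        fixed = pool_fixed(ests)
        assert math.log(fixed.pooled_or) == pytest.approx(float(res.mean_effect_fe), abs=1e-10)


class TestStudyTableIO:
    def test_round_trip_and_comments(self, tmp_path):
        studies = [
            StudyRecord("alpha", a=10, b=20, c=30, d=40, population="Caucasian", typing_method="serology"),
            StudyRecord("beta", a=5, b=6, c=7, d=8, population="Asian", typing_method="molecular"),
        ]
        path = tmp_path / "studies.tsv"
        write_study_table(studies, path, header_comment="round trip")
        assert read_study_table(path) == studies

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "label\tpopulation\ttyping_method\tcases_pos\tcases_neg\tcontrols_pos\tcontrols_neg\n"
            "x\tp\tm\t1\t2\tnope\t4\n"
        )
        with pytest.raises(ValueError, match="bad.tsv:2"):
            read_study_table(path)

    def test_forest_weights_sum_to_100(self):
        rng = np.random.default_rng(8)
        rows = forest_data(random_study_set(rng))
        assert sum(r["weight_percent"] for r in rows) == pytest.approx(100.0)
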