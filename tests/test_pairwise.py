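"""Study-level odds ratios, MH/DL pooling, and Egger's test.

Closed-form examples are checked against hand computations; the
DerSimonian-Laird and Egger results are additionally frozen against
R's metafor (rma(method="DL"), regtest(model="lm", predictor="sei"),
rma.mh) on two fixed table sets.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ironnma import (
    CollinearityError,
    EffectEstimate,
    InsufficientStudiesError,
    StudyArm,
    UninformativeStudyError,
    ValidationError,
    egger_test,
    forest_funnel_export,
    pool_dl_random,
    pool_mh_fixed,
    study_log_or,
)


def tables_to_estimates(a, b, c, d):
    out = []
    for i in range(len(a)):
        t = StudyArm(f"S{i}", "iron_sucrose_ge400", a[i], a[i] + b[i])
        ctrl = StudyArm(f"S{i}", "oral_iron", c[i], c[i] + d[i])
        out.append(study_log_or(t, ctrl))
    return out


def est(sid, y, se):
    return EffectEstimate(sid, y, se, False, (1, 1, 1, 1))


# Two fixed 2x2 table sets; expected values computed with metafor 4.8-0.
METAFOR_HOMOGENEOUS = dict(
    a=[12, 8, 30, 5, 22, 14, 9, 40],
    b=[88, 42, 70, 45, 178, 86, 41, 160],
    c=[20, 12, 25, 9, 35, 20, 15, 55],
    d=[80, 38, 75, 41, 165, 80, 35, 145],
    pooled=-0.389828421847,
    tau2=0.0,
    Q=5.283187757914,
    i2_pct=0.0,
    mh_or=0.677072120560,
    mh_se=0.124563001957,
    egger_t=-0.778675967347,
    egger_df=6,
    egger_p=0.465761345971,
    egger_intercept=-0.876272575666,
)
METAFOR_HETEROGENEOUS = dict(
    a=[5, 40, 12, 28, 7, 33],
    b=[95, 60, 88, 72, 93, 67],
    c=[20, 22, 30, 15, 25, 18],
    d=[80, 78, 70, 85, 75, 82],
    pooled=-0.248528366158,
    tau2=1.213900136501,
    Q=46.844631900809,
    i2_pct=89.326418423807,
    ci=(-1.185715127634, 0.688658395319),
    egger_t=-3.183552424500,
    egger_df=4,
    egger_p=0.033421477939,
    egger_intercept=-14.462594762903,
    egger_intercept_se=4.542910822389,
)


class TestStudyLogOr:
    def test_identical_arms_give_null_effect(self):
        t = StudyArm("S1", "iron_sucrose_ge400", 10, 100)
        c = StudyArm("S1", "oral_iron", 10, 100)
        e = study_log_or(t, c)
        assert e.y == 0.0
        assert e.odds_ratio == 1.0
        assert not e.corrected

    def test_cross_product_closed_form(self):
        t = StudyArm("S1", "iron_sucrose_ge400", 10, 100)
        c = StudyArm("S1", "oral_iron", 20, 100)
        e = study_log_or(t, c)
        assert e.odds_ratio == pytest.approx(4 / 9, rel=1e-12)
        assert e.se == pytest.approx(
            math.sqrt(1 / 10 + 1 / 90 + 1 / 20 + 1 / 80), rel=1e-12
        )

    def test_continuity_correction_on_zero_cell(self):
        t = StudyArm("S1", "iron_sucrose_ge400", 0, 50)
        c = StudyArm("S1", "oral_iron", 5, 50)
        e = study_log_or(t, c)
        assert e.corrected
        assert e.cells == (0, 50, 5, 45)
        assert e.y == pytest.approx(math.log(0.5 * 45.5 / (50.5 * 5.5)), rel=1e-12)
        assert e.se == pytest.approx(
            math.sqrt(1 / 0.5 + 1 / 50.5 + 1 / 5.5 + 1 / 45.5), rel=1e-12
        )

    @pytest.mark.parametrize("et, ec", [(0, 0), (50, 50)])
    def test_double_zero_and_double_full_are_uninformative(self, et, ec):
        t = StudyArm("S1", "iron_sucrose_ge400", et, 50)
        c = StudyArm("S1", "oral_iron", ec, 50)
        with pytest.raises(UninformativeStudyError):
            study_log_or(t, c)

    def test_arms_must_share_study(self):
        with pytest.raises(ValidationError):
            study_log_or(
                StudyArm("S1", "iron_sucrose_ge400", 1, 10),
                StudyArm("S2", "oral_iron", 1, 10),
            )


class TestMantelHaenszel:
    def test_single_study_is_identity(self):
        ests = tables_to_estimates([10], [90], [20], [80])
        assert pool_mh_fixed(ests).pooled_or == pytest.approx(4 / 9, rel=1e-12)

    def test_pooling_equal_odds_ratios(self):
        ests = tables_to_estimates([10, 5], [90, 45], [20, 10], [80, 40])
        assert pool_mh_fixed(ests).pooled_or == pytest.approx(4 / 9, rel=1e-12)

    def test_weight_sum_oracle(self):
        # (10/100 vs 20/100) and (30/100 vs 15/100): (4 + 12.75) / (9 + 5.25)
        ests = tables_to_estimates([10, 30], [90, 70], [20, 15], [80, 85])
        assert pool_mh_fixed(ests).pooled_or == pytest.approx(16.75 / 14.25, rel=1e-12)

    def test_frozen_metafor_values(self):
        m = METAFOR_HOMOGENEOUS
        res = pool_mh_fixed(tables_to_estimates(m["a"], m["b"], m["c"], m["d"]))
        assert res.pooled_or == pytest.approx(m["mh_or"], rel=1e-8)
        rbg_se = (res.ci95[1] - res.pooled_log_or) / 1.959963984540054
        assert rbg_se == pytest.approx(m["mh_se"], rel=1e-8)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.integers(1, 40), st.integers(1, 40), st.integers(1, 40), st.integers(1, 40)
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_pooled_or_between_study_extremes(self, cells):
        ests = [
            EffectEstimate(
                f"S{i}",
                math.log(a * d / (b * c)),
                math.sqrt(1 / a + 1 / b + 1 / c + 1 / d),
                False,
                (a, b, c, d),
            )
            for i, (a, b, c, d) in enumerate(cells)
        ]
        res = pool_mh_fixed(ests)
        ors = [e.odds_ratio for e in ests]
        assert min(ors) - 1e-12 <= res.pooled_or <= max(ors) + 1e-12


class TestDerSimonianLaird:
    def test_equal_estimates_collapse(self):
        ests = [est(f"S{i}", 0.4, 0.2) for i in range(5)]
        res = pool_dl_random(ests)
        assert res.Q == pytest.approx(0.0, abs=1e-12)
        assert res.tau_squared == 0.0
        assert res.i_squared == 0.0
        assert res.pooled_log_or == pytest.approx(0.4, rel=1e-12)

    def test_hand_computed_heterogeneity(self):
        # y = {0, 0.5}, se = {0.2, 0.2}: Q = 3.125, C = 25, tau2 = 0.085
        res = pool_dl_random([est("S1", 0.0, 0.2), est("S2", 0.5, 0.2)])
        assert res.Q == pytest.approx(3.125, rel=1e-12)
        assert res.df == 1
        assert res.tau_squared == pytest.approx(0.085, rel=1e-12)
        assert res.i_squared == pytest.approx(0.68, rel=1e-12)

    def test_truncation_reduces_to_fixed_effect(self):
        ests = [est("S1", 0.0, 0.5), est("S2", 0.01, 0.5)]
        res = pool_dl_random(ests)
        assert res.tau_squared == 0.0
        w = 1 / 0.25
        assert res.pooled_log_or == pytest.approx((0.0 + 0.01) * w / (2 * w), rel=1e-12)
        assert res.ci95[1] - res.ci95[0] == pytest.approx(
            2 * 1.959963984540054 / math.sqrt(2 * w), rel=1e-12
        )

    def test_single_estimate_degenerates(self):
        res = pool_dl_random([est("S1", 0.3, 0.1)])
        assert res.pooled_log_or == pytest.approx(0.3)
        assert res.tau_squared == 0.0
        assert res.k == 1

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValidationError):
            pool_dl_random([est("S1", 0.1, 0.0), est("S2", 0.2, 0.1)])

    @pytest.mark.parametrize("m", [METAFOR_HOMOGENEOUS, METAFOR_HETEROGENEOUS])
    def test_frozen_metafor_values(self, m):
        res = pool_dl_random(tables_to_estimates(m["a"], m["b"], m["c"], m["d"]))
        assert res.pooled_log_or == pytest.approx(m["pooled"], rel=1e-8)
        assert res.tau_squared == pytest.approx(m["tau2"], abs=1e-8)
        assert res.Q == pytest.approx(m["Q"], rel=1e-8)
        assert 100 * res.i_squared == pytest.approx(m["i2_pct"], abs=1e-6)
        if "ci" in m:
            assert res.ci95 == pytest.approx(m["ci"], rel=1e-8)


class TestEgger:
    def test_too_few_studies(self):
        with pytest.raises(InsufficientStudiesError):
            egger_test([est("S1", 0.1, 0.2), est("S2", 0.2, 0.2)])

    def test_collinear_design(self):
        with pytest.raises(CollinearityError):
            egger_test([est(f"S{i}", 0.1 * i, 0.25) for i in range(5)])

    def test_mirror_symmetric_estimates_have_null_intercept(self):
        # pairs symmetric about a common mean with matched standard errors
        ests = []
        for i, se in enumerate([0.1, 0.2, 0.3, 0.4]):
            ests.append(est(f"P{i}", 0.5 + se, se))
            ests.append(est(f"M{i}", 0.5 - se, se))
        res = egger_test(ests)
        assert res.intercept == pytest.approx(0.0, abs=1e-10)
        assert abs(res.t) < 1e-8

    def test_matches_independent_least_squares(self):
        # planted intercept 1.5, one perturbed point; oracle = lstsq solve
        se = np.array([0.1, 0.15, 0.2, 0.3, 0.4, 0.5])
        y = 1.5 * se + 0.2
        y[3] += 0.37
        ests = [est(f"S{i}", y[i], se[i]) for i in range(6)]
        res = egger_test(ests)
        design = np.column_stack([np.ones(6), 1.0 / se])
        z = y / se
        coef, *_ = np.linalg.lstsq(design, z, rcond=None)
        resid = z - design @ coef
        cov = np.linalg.inv(design.T @ design) * (resid @ resid) / (6 - 2)
        assert res.intercept == pytest.approx(coef[0], abs=1e-10)
        assert res.slope == pytest.approx(coef[1], abs=1e-10)
        assert res.intercept_se == pytest.approx(math.sqrt(cov[0, 0]), abs=1e-10)

    @pytest.mark.parametrize("m", [METAFOR_HOMOGENEOUS, METAFOR_HETEROGENEOUS])
    def test_frozen_metafor_values(self, m):
        res = egger_test(tables_to_estimates(m["a"], m["b"], m["c"], m["d"]))
        assert res.t == pytest.approx(m["egger_t"], rel=1e-8)
        assert res.df == m["egger_df"]
        assert res.p == pytest.approx(m["egger_p"], rel=1e-8)
        assert res.intercept == pytest.approx(m["egger_intercept"], rel=1e-8)
        if "egger_intercept_se" in m:
            assert res.intercept_se == pytest.approx(m["egger_intercept_se"], rel=1e-8)


class TestForestFunnelExport:
    def test_single_study_full_weight(self):
        ests = [est("S1", 0.2, 0.1)]
        forest, funnel = forest_funnel_export(ests, pool_dl_random(ests))
        assert forest["weight_pct"].iloc[0] == pytest.approx(100.0, abs=1e-9)
        assert funnel["se"].iloc[0] == 0.1

    def test_equal_variance_studies_split_evenly(self):
        ests = [est("S1", 0.0, 0.2), est("S2", 0.5, 0.2)]
        forest, _ = forest_funnel_export(ests, pool_mh_fixed_like(ests))
        assert forest["weight_pct"].tolist() == pytest.approx([50.0, 50.0], abs=1e-9)

    def test_weights_match_renormalization_oracle(self):
        rng = np.random.default_rng(3)
        ses = rng.uniform(0.05, 0.6, 19)
        ests = [est(f"S{i}", float(rng.normal()), float(s)) for i, s in enumerate(ses)]
        pooled = pool_dl_random(ests)
        forest, _ = forest_funnel_export(ests, pooled)
        w = 1.0 / (ses**2 + pooled.tau_squared)
        np.testing.assert_allclose(
            forest["weight_pct"].to_numpy(), 100 * w / w.sum(), rtol=1e-12
        )
        assert forest["weight_pct"].sum() == pytest.approx(100.0, abs=0.1)


def pool_mh_fixed_like(ests):
    """Fixed-effect pooled result (tau2 = 0) for weight checks on
    synthetic estimates that carry no meaningful 2x2 cells."""
    from ironnma import PooledResult

    return PooledResult("mantel_haenszel_fixed", 0.0, (0.0, 0.0), 0.0, 1, 0.0, 0.0, len(ests))
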