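"""MR estimators, sensitivity statistics, instrument processing, gating."""
import math

import numpy as np
import pytest

from ptmr.mr import (
    MendelianRandomization,
    MrGateError,
    clump,
    ivw,
    mr_egger,
    replicate,
    run_mr,
    select_instruments,
    steiger,
    wald_ratio,
    MrResult,
)
from ptmr.synth import simulate_ld, simulate_mr_set
from ptmr.tiering import TierRecord
from ptmr.types import Instrument, LdMatrix

from conftest import (
    make_instruments,
    make_snp,
    wls_through_origin_oracle,
    wls_with_intercept_oracle,
)


class TestSelectInstruments:
    def test_primary_threshold(self):
        snps = [make_snp("a", beta=0.3, se=0.3 / 6.1), make_snp("b", beta=0.2, se=0.2 / 5.3)]
        kept = select_instruments(snps)  # p ~ 1e-9 and ~1e-7
        assert [s.snp_id for s in kept] == ["a"]

    def test_fallback_engaged_when_primary_empty(self):
        snps = [make_snp("a", beta=0.2, se=0.2 / 5.3), make_snp("b", beta=0.2, se=0.2 / 4.75)]
        kept = select_instruments(snps)  # p ~1e-7 and ~2e-6, both < 5e-6
        assert [s.snp_id for s in kept] == ["a", "b"]

    def test_nothing_passes_gives_empty_list(self):
        kept = select_instruments([make_snp("a", beta=0.05, se=0.02)])  # p ~ 0.012
        assert kept == []


class TestClump:
    def test_correlated_pair_keeps_best(self):
        ld = LdMatrix(["a", "b"], [[1.0, 0.95], [0.95, 1.0]])
        snps = [make_snp("a", beta=0.64, se=0.1, pos=1000),
                make_snp("b", beta=0.57, se=0.1, pos=2000)]
        kept = clump(snps, ld)
        assert [s.snp_id for s in kept] == ["a"]

    def test_independent_pair_both_kept(self):
        r = 0.0005**0.5
        ld = LdMatrix(["a", "b"], [[1.0, r], [r, 1.0]])
        snps = [make_snp("a", beta=0.64, se=0.1, pos=1000),
                make_snp("b", beta=0.57, se=0.1, pos=2000)]
        assert len(clump(snps, ld)) == 2

    def test_greedy_chain(self):
        # A-B r2=0.5, B-C r2=0.5, A-C r2=0; p(A)<p(B)<p(C) -> keep A and C
        r = math.sqrt(0.5)
        ld = LdMatrix(["A", "B", "C"], [[1, r, 0], [r, 1, r], [0, r, 1]])
        snps = [make_snp("A", beta=0.70, se=0.1, pos=1000),
                make_snp("B", beta=0.65, se=0.1, pos=2000),
                make_snp("C", beta=0.60, se=0.1, pos=3000)]
        kept = clump(snps, ld, r2=0.1)
        assert [s.snp_id for s in kept] == ["A", "C"]

    def test_distance_window_respected(self):
        ld = LdMatrix(["a", "b"], [[1.0, 0.95], [0.95, 1.0]])
        snps = [make_snp("a", beta=0.64, se=0.1, pos=1000),
                make_snp("b", beta=0.57, se=0.1, pos=1000 + 10_001 * 1000)]
        assert len(clump(snps, ld)) == 2  # outside the 10 Mb window


class TestWaldRatio:
    def test_unit_exposure(self):
        (i,) = make_instruments([1.0], [0.2], se_out=0.05)
        res = wald_ratio(i)
        assert res.beta == pytest.approx(0.2)
        assert res.se == pytest.approx(0.05)
        assert res.method == "wald_ratio"

    def test_negative_exposure_by_hand(self):
        (i,) = make_instruments([-0.5], [0.1], se_out=0.05)
        res = wald_ratio(i)
        assert res.beta == pytest.approx(-0.2)
        assert res.se == pytest.approx(0.1)

    def test_zero_exposure_rejected(self):
        (i,) = make_instruments([0.0], [0.1])
        with pytest.raises(ValueError):
            wald_ratio(i)

    def test_or_and_ci_consistency(self):
        (i,) = make_instruments([0.4], [0.08], se_out=0.02)
        res = wald_ratio(i)
        assert res.or_ == pytest.approx(math.exp(res.beta), rel=1e-10)
        assert res.ci_low == pytest.approx(math.exp(res.beta - 1.96 * res.se), rel=1e-10)
        assert res.ci_high == pytest.approx(math.exp(res.beta + 1.96 * res.se), rel=1e-10)


class TestIvw:
    def test_identical_instruments_recover_common_ratio(self):
        insts = make_instruments([0.5, 0.5], [0.1, 0.1])
        res = ivw(insts)
        assert res.beta == pytest.approx(0.2)
        assert res.q_stat == pytest.approx(0.0, abs=1e-12)
        assert res.q_df == 1

    def test_matches_wls_through_origin_oracle(self, rng):
        for _ in range(10):
            k = int(rng.integers(3, 12))
            bx = rng.normal(0.3, 0.1, k)
            by = 0.15 * bx + rng.normal(0, 0.01, k)
            se_out = rng.uniform(0.01, 0.05, k)
            insts = [Instrument(f"iv{i}", bx[i], 0.01, by[i], se_out[i]) for i in range(k)]
            res = ivw(insts)
            beta_o, se_o = wls_through_origin_oracle(bx, by, se_out)
            assert res.beta == pytest.approx(beta_o, abs=1e-10)
            # fixed-effect se before dispersion inflation
            infl = max(1.0, math.sqrt(res.q_stat / res.q_df))
            assert res.se == pytest.approx(se_o * infl, abs=1e-10)

    def test_single_instrument_equals_wald_ratio(self):
        insts = make_instruments([0.37], [0.081], se_out=0.013)
        res_w = wald_ratio(insts[0])
        res_i = ivw(insts, allow_single=True)
        assert res_i.beta == pytest.approx(res_w.beta, abs=1e-15)
        assert res_i.se == pytest.approx(res_w.se, abs=1e-15)

    def test_recovers_true_effect(self):
        insts, truth = simulate_mr_set(k=10, alpha=0.2, pleiotropy_sd=0.0, seed=77)
        res = ivw(insts)
        assert abs(res.beta - 0.2) < 3 * res.se

    def test_sign_equivariance(self):
        insts, _ = simulate_mr_set(k=6, alpha=0.15, seed=2)
        res = ivw(insts)
        neg = [Instrument(i.snp_id, i.beta_exp, i.se_exp, -i.beta_out, i.se_out) for i in insts]
        res_n = ivw(neg)
        assert res_n.beta == pytest.approx(-res.beta, abs=1e-12)
        assert res_n.or_ == pytest.approx(1.0 / res.or_, rel=1e-10)


class TestMrEgger:
    def test_points_on_line_through_origin(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        insts = make_instruments(bx, 0.3 * bx)
        res = mr_egger(insts)
        assert res.beta == pytest.approx(0.3, abs=1e-10)
        assert res.egger_intercept == pytest.approx(0.0, abs=1e-12)

    def test_pure_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        insts = make_instruments(bx, np.full(4, 0.1))
        res = mr_egger(insts)
        assert res.beta == pytest.approx(0.0, abs=1e-12)
        assert res.egger_intercept == pytest.approx(0.1, abs=1e-12)

    def test_matches_generic_weighted_regression_oracle(self, rng):
        for _ in range(5):
            k = 5
            bx = np.abs(rng.normal(0.3, 0.1, k))
            by = 0.05 + 0.2 * bx + rng.normal(0, 0.02, k)
            se_out = rng.uniform(0.01, 0.05, k)
            insts = [Instrument(f"iv{i}", bx[i], 0.01, by[i], se_out[i]) for i in range(k)]
            res = mr_egger(insts)
            inter_o, slope_o, _ = wls_with_intercept_oracle(bx, by, se_out)
            assert res.beta == pytest.approx(slope_o, abs=1e-10)
            assert res.egger_intercept == pytest.approx(inter_o, abs=1e-10)

    def test_exposure_orientation_invariance(self):
        bx = np.array([0.2, -0.3, 0.4])
        by = 0.1 * bx + np.array([0.01, -0.02, 0.015])
        insts = make_instruments(bx, by)
        flipped = make_instruments(-bx, -by)
        a, b = mr_egger(insts), mr_egger(flipped)
        assert a.beta == pytest.approx(b.beta, abs=1e-12)
        assert a.egger_intercept == pytest.approx(b.egger_intercept, abs=1e-12)

    def test_too_few_instruments_rejected(self):
        with pytest.raises(ValueError):
            mr_egger(make_instruments([0.1, 0.2], [0.01, 0.02]))


class TestSteiger:
    def test_dominant_exposure_direction(self):
        insts = make_instruments([0.3], [0.03], n_exp=10_000, n_out=10_000)
        insts[0].beta_exp, insts[0].se_exp = 0.3, 0.01   # z=30
        insts[0].beta_out, insts[0].se_out = 0.03, 0.01  # z=3
        direction, p = steiger(insts)
        assert direction is True
        assert p < 1e-10

    def test_symmetric_gives_p_one(self):
        i = Instrument("iv", 0.05, 0.01, 0.05, 0.01, n_exp=5_000, n_out=5_000)
        direction, p = steiger([i])
        assert direction is False  # strict inequality on equal r2
        assert p == pytest.approx(1.0)

    def test_hand_computed_r2(self):
        i = Instrument("iv", 0.10, 0.01, 0.02, 0.01, n_exp=1_000, n_out=1_000)
        # z_exp=10 -> r2=100/1098; z_out=2 -> r2=4/1002
        direction, p = steiger([i])
        assert direction is True
        assert 100 / 1098 == pytest.approx(0.0911, abs=1e-4)
        assert 4 / 1002 == pytest.approx(0.0040, abs=1e-4)

    def test_missing_sample_size_rejected(self):
        with pytest.raises(ValueError):
            steiger(make_instruments([0.1], [0.01]))


class TestModelInterface:
    def test_auto_routes_single_to_wald(self):
        insts, _ = simulate_mr_set(k=1, alpha=0.1, seed=1)
        assert MendelianRandomization(insts).fit().method == "wald_ratio"

    def test_auto_routes_many_to_ivw_with_egger(self):
        insts, _ = simulate_mr_set(k=5, alpha=0.1, seed=1)
        res = MendelianRandomization(insts).fit()
        assert res.method == "ivw"
        assert res.q_df == 4
        assert res.egger_intercept is not None

    def test_empty_set_not_estimable(self):
        res = MendelianRandomization([]).fit()
        assert res.status == "not-estimable"
        assert res.beta is None

    def test_summary_renders(self):
        insts, _ = simulate_mr_set(k=4, alpha=0.2, seed=9)
        text = MendelianRandomization(insts, "PEX14", "overall").fit().summary()
        assert "PEX14" in text and "OR" in text and "Cochran" in text


class TestRunMrGating:
    def _tier(self, tier, consistent=True):
        return TierRecord(feature_id="F", outcome="o", score=5, tier=tier,
                          direction_consistent=consistent)

    def _locus(self, k):
        ld = simulate_ld(k, 0.0)
        exp = [make_snp(s, beta=0.2, se=0.02, pos=1_000 * (i + 1), n=10_000)
               for i, s in enumerate(ld.snp_ids)]
        out = [make_snp(s, beta=0.04, se=0.005, pos=1_000 * (i + 1), n=100_000)
               for i, s in enumerate(ld.snp_ids)]
        return exp, out, ld

    def test_single_instrument_routes_to_wald(self):
        exp, out, ld = self._locus(1)
        res = run_mr(self._tier("Strong"), exp, out, ld)
        assert res.method == "wald_ratio"

    def test_five_instruments_route_to_ivw(self):
        exp, out, ld = self._locus(5)
        res = run_mr(self._tier("Moderate"), exp, out, ld)
        assert res.method == "ivw"
        assert res.q_df == 4

    @pytest.mark.parametrize("tier,consistent", [("Weak", True), ("None", True), ("Strong", False)])
    def test_ineligible_features_refused(self, tier, consistent):
        exp, out, ld = self._locus(2)
        with pytest.raises(MrGateError):
            run_mr(self._tier(tier, consistent), exp, out, ld)

    def test_no_instrument_status(self):
        ld = simulate_ld(2, 0.0)
        exp = [make_snp(s, beta=0.01, se=0.02, pos=1_000 * (i + 1), n=10_000)
               for i, s in enumerate(ld.snp_ids)]
        res = run_mr(self._tier("Strong"), exp, [], ld)
        assert res.status == "no-instrument"


class TestReplicate:
    def _res(self, beta, p):
        return MrResult(beta=beta, se=0.1, pvalue=p, or_=math.exp(beta))

    def test_significant_same_sign_replicates(self):
        assert replicate(self._res(0.18, 0.016), [self._res(0.2, 0.001)]) == "replicated"

    def test_opposite_signs_fail(self):
        assert replicate(self._res(0.18, 0.016), [self._res(-0.2, 0.001)]) == "not-replicated"

    def test_same_sign_insignificant_is_trend(self):
        assert replicate(self._res(-0.17, 0.038), [self._res(-0.174, 0.129)]) == "trend"
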