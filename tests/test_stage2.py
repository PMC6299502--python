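import math

import pytest
from hypothesis import given, settings, strategies as st

from cessmiss import (
    ArmCounts,
    ImputationError,
    SensitivityParams,
    allocate_missing_urine,
    impute_arm,
    impute_stage1,
    impute_stage2,
    split_imputed_urine_outcomes,
    split_urine_availability,
)

from conftest import OR_GRID


@pytest.fixture
def tx1(quit_win):
    return quit_win.arm("Tx1")


class TestSplitUrineAvailability:
    def test_trial_arm_under_mar(self, tx1):
        # Tx1 under OR1 = 1 has n21 = 47*65/259 ~ 11.80 imputed abstainers,
        # split by the observed 44:21 provided:missing odds.
        s1 = impute_stage1(tx1, 1.0)
        assert s1.n21 == pytest.approx(47 * 65 / 259, abs=1e-9)
        u_imp, v_imp = split_urine_availability(s1, tx1, lam=1.0)
        assert u_imp == pytest.approx(s1.n21 * 44 / 65, abs=1e-9)
        assert u_imp == pytest.approx(7.9846, abs=1e-3)
        assert v_imp == pytest.approx(3.8108, abs=1e-3)

    def test_halved_provision_odds(self, tx1):
        s1 = impute_stage1(tx1, 1.0)
        u_imp, _ = split_urine_availability(s1, tx1, lam=0.5)
        assert u_imp == pytest.approx(s1.n21 * 22 / 43, abs=1e-9)
        assert u_imp == pytest.approx(6.0348, abs=1e-3)

    def test_empty_stage1_pool_gives_zero(self, tx1):
        s1 = impute_stage1(tx1, math.inf)  # n21 = 0
        assert split_urine_availability(s1, tx1, lam=1.0) == (0.0, 0.0)

    def test_no_observed_pattern_is_an_error(self):
        # No self-reported abstainer has any urine record at all: nothing
        # anchors the availability odds for a nonempty imputed pool.
        from cessmiss.stage1 import Stage1Result

        arm = ArmCounts("B", 30, 0, 20, 10, 0.0, 0.0, 0.0)
        s1 = Stage1Result(
            n21=5.0, n22=5.0, pi=0.5, sr_abstinent_total=5.0, sr_failure_total=25.0
        )
        with pytest.raises(ImputationError):
            split_urine_availability(s1, arm, lam=1.0)


class TestSplitImputedUrineOutcomes:
    def test_trial_arm_under_eta_one(self):
        f11_imp, f12_imp = split_imputed_urine_outcomes(7.988, 38, 6, eta=1.0)
        assert f11_imp == pytest.approx(7.988 * 38 / 44, abs=1e-9)
        assert f11_imp == pytest.approx(6.899, abs=1e-3)
        assert f12_imp == pytest.approx(1.089, abs=1e-3)

    def test_doubled_verification_odds(self):
        f11_imp, _ = split_imputed_urine_outcomes(10, 5, 5, eta=2.0)
        assert f11_imp == pytest.approx(10 * 2 / 3, abs=1e-9)

    def test_nothing_to_split(self):
        assert split_imputed_urine_outcomes(0.0, 38, 6, eta=1.0) == (0.0, 0.0)

    def test_no_observed_outcomes_is_an_error(self):
        with pytest.raises(ImputationError):
            split_imputed_urine_outcomes(5.0, 0, 0, eta=1.0)


class TestAllocateMissingUrine:
    def test_trial_arm_mar_cell(self):
        f21, f22, pi_prime = allocate_missing_urine(
            44.899, 7.089, 24.812, or2=1.0
        )
        assert pi_prime == pytest.approx(0.13636, abs=1e-4)
        assert f22 == pytest.approx(3.384, abs=1e-3)
        assert f21 == pytest.approx(21.428, abs=1e-3)

    def test_infinite_or2_is_the_naive_failure_allocation(self):
        f21, f22, pi_prime = allocate_missing_urine(40, 7, 25.0, or2=math.inf)
        assert f21 == 0.0 and f22 == 25.0 and pi_prime == 1.0

    def test_empty_pool(self):
        f21, f22, _ = allocate_missing_urine(40, 7, 0.0, or2=1.0)
        assert f21 == f22 == 0.0

    def test_degenerate_cells(self):
        with pytest.raises(ImputationError):
            allocate_missing_urine(0, 0, 5.0, or2=1.0)
        # observed zero failure odds beat OR2 = +inf
        f21, f22, _ = allocate_missing_urine(40, 0, 5.0, or2=math.inf)
        assert f21 == 5.0 and f22 == 0.0


class TestImputeStage2:
    def test_composition_on_trial_arm(self, tx1):
        params = SensitivityParams(or1=1.0, or2=1.0)
        s1 = impute_stage1(tx1, params.or1)
        s2 = impute_stage2(tx1, s1, params)
        assert s2.verified_abstinent_total == pytest.approx(66.33, abs=0.01)
        assert s2.verified_failure_total == pytest.approx(306 - 66.33, abs=0.01)

    def test_missing_equals_smoking_at_both_stages(self, tx1):
        params = SensitivityParams(or1=math.inf, or2=math.inf)
        ia = impute_arm(tx1, params)
        assert ia.verified_abstinent_total == pytest.approx(38.0, abs=1e-12)

    @pytest.mark.parametrize("or1", OR_GRID)
    @pytest.mark.parametrize("or2", OR_GRID)
    def test_arm_without_missing_is_invariant(self, no_missing_arm, or1, or2):
        params = SensitivityParams(or1=or1, or2=or2)
        ia = impute_arm(no_missing_arm, params)
        assert ia.verified_abstinent_total == pytest.approx(
            no_missing_arm.urine_abstinent, abs=1e-12
        )

    def test_conservation_chain_on_fixture(self, quit_win):
        params = SensitivityParams(or1=2.0, or2=3.0, lam=0.7, eta=1.4)
        for arm in quit_win.arms:
            s1 = impute_stage1(arm, params.or1)
            s2 = impute_stage2(arm, s1, params)
            assert s2.u_imp + s2.v_imp == pytest.approx(s1.n21, abs=1e-9)
            assert s2.f11_imp + s2.f12_imp == pytest.approx(s2.u_imp, abs=1e-9)
            assert s2.f21 + s2.f22 == pytest.approx(s2.v_total, abs=1e-9)
            assert (
                s2.verified_abstinent_total + s2.verified_failure_total
                == pytest.approx(arm.n_total, abs=1e-9)
            )
            for fld in ("u_imp", "v_imp", "f11_imp", "f12_imp", "f21", "f22"):
                assert getattr(s2, fld) >= 0

    def test_or2_identity_reconstruction(self, quit_win):
        for arm in quit_win.arms:
            for or2 in (1.0, 2.5, 7.0):
                params = SensitivityParams(or1=1.5, or2=or2)
                s1 = impute_stage1(arm, params.or1)
                s2 = impute_stage2(arm, s1, params)
                reconstructed = (s2.f22 / s2.f21) / (s2.f12_dot / s2.f11_dot)
                assert reconstructed == pytest.approx(or2, abs=1e-9 * max(1, or2))

    def test_verified_total_non_increasing_in_both_ors(self, quit_win):
        for arm in quit_win.arms:
            for or1 in OR_GRID:
                totals = [
                    impute_arm(arm, SensitivityParams(or1=or1, or2=or2))
                    .verified_abstinent_total
                    for or2 in OR_GRID
                ]
                assert all(a >= b - 1e-12 for a, b in zip(totals, totals[1:]))
            for or2 in OR_GRID:
                totals = [
                    impute_arm(arm, SensitivityParams(or1=or1, or2=or2))
                    .verified_abstinent_total
                    for or1 in OR_GRID
                ]
                assert all(a >= b - 1e-12 for a, b in zip(totals, totals[1:]))

    @pytest.mark.parametrize("lam, eta", [(0.25, 1.0), (1.0, 4.0), (2.0, 0.5)])
    def test_lambda_eta_irrelevant_when_stage1_pool_empty(
        self, quit_win, lam, eta
    ):
        """When OR1 = +inf no abstainers are imputed, so the stage-2 result
        cannot depend on lambda or eta."""
        for arm in quit_win.arms:
            base = impute_arm(arm, SensitivityParams(or1=math.inf, or2=2.0))
            alt = impute_arm(
                arm, SensitivityParams(or1=math.inf, or2=2.0, lam=lam, eta=eta)
            )
            assert alt.stage2 == base.stage2


@settings(max_examples=150, derandomize=True)
@given(
    n11=st.integers(1, 300),
    n12=st.integers(1, 300),
    n2dot=st.integers(0, 200),
    f11=st.integers(1, 150),
    f12=st.integers(1, 50),
    or1=st.floats(0.1, 50, allow_nan=False),
    or2=st.floats(0.1, 50, allow_nan=False),
    lam=st.floats(0.1, 10, allow_nan=False),
    eta=st.floats(0.1, 10, allow_nan=False),
)
def test_conservation_chain_property(n11, n12, n2dot, f11, f12, or1, or2, lam, eta):
    """The imputed quantities always close the accounting chain, for any
    admissible observed table and scenario."""
    f11 = min(f11, n11)
    f12 = min(f12, n11 - f11)
    arm = ArmCounts(
        "A", n11 + n12 + n2dot, n11, n12, n2dot, float(f11), float(f12),
        float(n11 - f11 - f12),
    )
    params = SensitivityParams(or1=or1, or2=or2, lam=lam, eta=eta)
    s1 = impute_stage1(arm, or1)
    s2 = impute_stage2(arm, s1, params)
    assert s2.u_imp + s2.v_imp == pytest.approx(s1.n21, abs=1e-9)
    assert s2.f11_imp + s2.f12_imp == pytest.approx(s2.u_imp, abs=1e-9)
    assert s2.f21 + s2.f22 == pytest.approx(s2.v_total, abs=1e-9)
    assert s2.verified_abstinent_total <= arm.n_total + 1e-9
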