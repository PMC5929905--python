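import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ascnet.bounds import (
    AdditiveSignalSpec,
    Direction,
    additive_bounds,
    additive_bounds_batch,
    additive_direction_feasible,
    common_bounds_batch,
    common_signal_bounds,
    extremal_specs,
    forward_correlation,
    uncorrelated_predicted_correlation,
)
from _oracle import additive_oracle, common_oracle

REF = dict(rho=0.58, var_ax=1.0, var_ay=1.0, var_bx=1.44, var_by=1.44)
ORTHOGONAL_COMMON = (0.58 + 0.44) / 1.44  # shared latent, orthogonal to both nodes


def random_instances(n, seed=7):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        rho = rng.uniform(-0.9, 0.9)
        vax, vay = rng.uniform(0.5, 2.0, 2)
        vbx = vax * rng.uniform(0.7, 1.4) ** 2
        vby = vay * rng.uniform(0.7, 1.4) ** 2
        out.append((rho, vax, vay, vbx, vby))
    return out


class TestDirectionFeasibility:
    @pytest.mark.parametrize("var_a,var_b,var_n,expected", [
        (1.0, 1.44, 0.44, True),    # boundary of a 20% SD increase
        (1.0, 1.0, 0.01, False),    # no variance change admits no addition
        (1.0, 0.5, 0.5, True),      # decrease direction
    ])
    def test_examples(self, var_a, var_b, var_n, expected):
        assert additive_direction_feasible(var_a, var_b, var_n) is expected


class TestForwardCorrelation:
    def test_zero_scales_leave_correlation_unchanged(self):
        spec = AdditiveSignalSpec(0, 0, 0, 0, 0, 0, 0)
        assert forward_correlation(0.58, 1, 1, spec) == pytest.approx(0.58)

    def test_orthogonal_common_signal_hand_expansion(self):
        s = np.sqrt(0.44)
        spec = AdditiveSignalSpec(s, s, 0, 0, 0, 0, 1)
        assert forward_correlation(0.58, 1, 1, spec) == pytest.approx(
            ORTHOGONAL_COMMON, abs=1e-12)

    def test_uncorrelated_spec_matches_closed_form(self):
        s = np.sqrt(0.44)
        spec = AdditiveSignalSpec(s, s, 0, 0, 0, 0, 0)
        assert forward_correlation(0.58, 1, 1, spec) == pytest.approx(
            uncorrelated_predicted_correlation(0.58, 1.2, 1.2), abs=1e-12)

    def test_non_psd_spec_is_rejected(self):
        spec = AdditiveSignalSpec(0.5, 0.5, 0.9, 0.9, 0.9, -0.9, 0.9)
        with pytest.raises(ValueError, match="PSD"):
            forward_correlation(0.0, 1, 1, spec)


class TestUncorrelatedPrediction:
    def test_reference_value(self):
        r = uncorrelated_predicted_correlation(0.58, 1.2, 1.2)
        assert r == pytest.approx(0.58 / 1.44, abs=1e-12)
        assert round(r, 2) == 0.40

    @pytest.mark.parametrize("rho", [-0.7, 0.0, 0.31])
    def test_unit_ratios_are_identity(self, rho):
        assert uncorrelated_predicted_correlation(rho, 1, 1) == pytest.approx(rho)

    def test_simulation_agreement(self, rng):
        n = 200_000
        z = rng.normal(size=(n, 2))
        z[:, 1] = 0.58 * z[:, 0] + np.sqrt(1 - 0.58 ** 2) * z[:, 1]
        noisy = z + np.sqrt(0.44) * rng.normal(size=(n, 2))
        emp = np.corrcoef(noisy[:, 0], noisy[:, 1])[0, 1]
        assert emp == pytest.approx(
            uncorrelated_predicted_correlation(0.58, 1.2, 1.2), abs=0.005)


class TestIntervals:
    def test_collapse_with_no_variance_change(self):
        for fn in (common_signal_bounds, additive_bounds):
            iv = fn(0.58, 1, 1, 1, 1)
            assert iv.lo == iv.hi == 0.58
            assert iv.argmin_spec.scale_xn == iv.argmin_spec.scale_yn == 0.0

    def test_reference_common_interval(self):
        iv = common_signal_bounds(**{k: REF[k] for k in
                                     ("var_ax", "var_ay", "var_bx", "var_by")},
                                  rho_a=REF["rho"])
        # the orthogonal shared latent is feasible, so the max is at least
        # its value; it is in fact the interval minimum
        assert iv.hi >= ORTHOGONAL_COMMON - 1e-9
        assert iv.lo == pytest.approx(ORTHOGONAL_COMMON, abs=1e-6)
        olo, ohi = common_oracle(REF["rho"], 1, 1, 1.44, 1.44)
        assert iv.lo == pytest.approx(olo, abs=1e-3)
        assert iv.hi == pytest.approx(ohi, abs=1e-3)

    def test_reference_additive_interval_reaches_full_synchrony(self):
        iv = additive_bounds(0.58, 1, 1, 1.44, 1.44)
        # a feasible pair of additions makes the two state-B signals equal
        assert iv.hi == pytest.approx(1.0, abs=1e-6)
        assert iv.lo < 0

    @pytest.mark.parametrize("inst", random_instances(12))
    def test_nesting_and_roundtrip(self, inst):
        rho, vax, vay, vbx, vby = inst
        ia = additive_bounds(rho, vax, vay, vbx, vby)
        up = uncorrelated_predicted_correlation(
            rho, np.sqrt(vbx / vax), np.sqrt(vby / vay))
        assert ia.lo <= up + 1e-6 and ia.hi >= up - 1e-6
        try:
            ic = common_signal_bounds(rho, vax, vay, vbx, vby)
        except ValueError:
            ic = None
        if ic is not None:
            assert ia.lo <= ic.lo + 1e-6
            assert ia.hi >= ic.hi - 1e-6
            assert forward_correlation(rho, vax, vay, ic.argmin_spec) == \
                pytest.approx(ic.lo, abs=1e-6)
            assert forward_correlation(rho, vax, vay, ic.argmax_spec) == \
                pytest.approx(ic.hi, abs=1e-6)
        assert forward_correlation(rho, vax, vay, ia.argmin_spec) == \
            pytest.approx(ia.lo, abs=1e-6)
        assert forward_correlation(rho, vax, vay, ia.argmax_spec) == \
            pytest.approx(ia.hi, abs=1e-6)
        assert -1 <= ia.lo <= ia.hi <= 1

    def test_sign_equivariance(self):
        for rho, vax, vay, vbx, vby in random_instances(5, seed=3):
            rho = abs(rho)
            pos = additive_bounds(rho, vax, vay, vbx, vby)
            neg = additive_bounds(-rho, vax, vay, vbx, vby)
            assert neg.lo == pytest.approx(-pos.hi, abs=1e-7)
            assert neg.hi == pytest.approx(-pos.lo, abs=1e-7)

    def test_monotone_widening(self):
        """Enlarging the variance change in either node never shrinks the
        additive interval (tested on a nested grid of SD ratios)."""
        prev = None
        for ratio in (1.05, 1.15, 1.25, 1.35):
            iv = additive_bounds(0.5, 1, 1, ratio ** 2, ratio ** 2)
            if prev is not None:
                assert iv.lo <= prev.lo + 1e-7
                assert iv.hi >= prev.hi - 1e-7
            prev = iv

    def test_extremal_specs_preserve_class_and_directions(self):
        ic = common_signal_bounds(0.58, 1, 1, 1.44, 1.44)
        lo_spec, hi_spec = extremal_specs(ic)
        assert lo_spec.rho_xn_yn == pytest.approx(1.0, abs=1e-9)
        assert hi_spec.rho_xn_yn == pytest.approx(1.0, abs=1e-9)
        assert lo_spec.direction_x is Direction.added_in_B
        iv_dec = additive_bounds(0.58, 1, 1, 0.8, 0.8)
        assert iv_dec.argmax_spec.direction_x is Direction.added_in_A

    def test_batch_matches_scalar(self):
        insts = random_instances(8, seed=42)
        arr = np.array(insts)
        alo, ahi = additive_bounds_batch(arr[:, 0], arr[:, 1], arr[:, 2],
                                         arr[:, 3], arr[:, 4])
        clo, chi = common_bounds_batch(arr[:, 0], arr[:, 1], arr[:, 2],
                                       arr[:, 3], arr[:, 4])
        for i, (rho, vax, vay, vbx, vby) in enumerate(insts):
            ia = additive_bounds(rho, vax, vay, vbx, vby)
            assert alo[i] == pytest.approx(ia.lo, abs=2e-3)
            assert ahi[i] == pytest.approx(ia.hi, abs=2e-3)
            try:
                ic = common_signal_bounds(rho, vax, vay, vbx, vby)
            except ValueError:
                assert np.isnan(clo[i])
                continue
            assert clo[i] == pytest.approx(ic.lo, abs=2e-3)
            assert chi[i] == pytest.approx(ic.hi, abs=2e-3)


class TestOracleEquivalence:
    @pytest.mark.parametrize("inst", random_instances(10, seed=99))
    def test_solver_matches_brute_force(self, inst):
        rho, vax, vay, vbx, vby = inst
        ia = additive_bounds(rho, vax, vay, vbx, vby)
        olo, ohi = additive_oracle(rho, vax, vay, vbx, vby)
        assert ia.lo == pytest.approx(olo, abs=1e-3)
        assert ia.hi == pytest.approx(ohi, abs=1e-3)
        oclo, ochi = common_oracle(rho, vax, vay, vbx, vby)
        try:
            ic = common_signal_bounds(rho, vax, vay, vbx, vby)
        except ValueError:
            assert np.isnan(oclo)
            return
        assert ic.lo == pytest.approx(oclo, abs=1e-3)
        assert ic.hi == pytest.approx(ochi, abs=1e-3)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    rho=st.floats(-0.85, 0.85),
    vax=st.floats(0.5, 2.0),
    vay=st.floats(0.5, 2.0),
    rx=st.floats(0.75, 1.35),
    ry=st.floats(0.75, 1.35),
)
def test_interval_invariants_property(rho, vax, vay, rx, ry):
    """For any feasible input the additive interval is a valid interval in
    [-1, 1] containing the uncorrelated point, and its extremal specs
    forward-evaluate onto the endpoints."""
    vbx, vby = vax * rx ** 2, vay * ry ** 2
    iv = additive_bounds(rho, vax, vay, vbx, vby)
    assert -1 <= iv.lo <= iv.hi <= 1
    up = uncorrelated_predicted_correlation(rho, rx, ry)
    assert iv.lo - 1e-6 <= up <= iv.hi + 1e-6
    assert forward_correlation(rho, vax, vay, iv.argmax_spec) == \
        pytest.approx(iv.hi, abs=1e-6)
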