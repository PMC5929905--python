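import numpy as np
import pytest

from ascnet.bounds import common_signal_bounds
from ascnet.covariance import TwoStateSummary, estimate_state_covariance
from ascnet.inference import (
    CLASS_IDS,
    McConfig,
    class_test,
    correlation_change_test,
    null_distribution,
    sample_true_covariances,
)
from ascnet.simulate import Injection, ScenarioSpec, generate_state
from conftest import make_summary

ORTHOGONAL_COMMON = (0.58 + 0.44) / 1.44


class TestCovarianceSampling:
    def test_fixed_seed_is_deterministic(self):
        s = make_summary(0.58, 0.40)
        cfg = McConfig(n_iterations=200, seed=5)
        d1 = sample_true_covariances(s, cfg)
        d2 = sample_true_covariances(s, cfg)
        np.testing.assert_array_equal(d1.rho_a, d2.rho_a)
        np.testing.assert_array_equal(d1.var_bx, d2.var_bx)

    def test_large_dof_concentrates_on_observed(self):
        s = make_summary(0.58, 0.40, dof=1e6, n=2_000_000)
        d = sample_true_covariances(s, McConfig(n_iterations=500, seed=1))
        assert np.all(np.abs(d.rho_a - 0.58) < 0.01)

    def test_posterior_roughly_centred(self):
        s = make_summary(0.58, 0.40, dof=100)
        d = sample_true_covariances(s, McConfig(n_iterations=2000, seed=2))
        assert d.rho_a.mean() == pytest.approx(0.58, abs=0.05)
        assert d.var_ax.mean() == pytest.approx(1.0, rel=0.1)

    def test_low_dof_is_an_error(self):
        s = make_summary(0.5, 0.5, dof=3)
        with pytest.raises(ValueError, match="dof"):
            sample_true_covariances(s, McConfig(n_iterations=200, seed=0))


class TestNullDistributions:
    def test_uncorrelated_degenerates_at_large_dof(self):
        s = make_summary(0.58, 0.40, dof=1e6, n=2_000_000)
        lo, hi = null_distribution(s, "uncorrelated", McConfig(n_iterations=400, seed=3))
        assert lo.mean() == pytest.approx(0.58 / 1.44, abs=0.01)
        assert hi.mean() == pytest.approx(0.58 / 1.44, abs=0.01)
        assert lo.std() < 0.01

    def test_zero_variance_change_centres_on_rho_a(self):
        """In the large-dof limit the posterior collapses onto the observed
        covariances and every class interval collapses onto rho_A. The
        approach is slow for the optimized classes (the admissible added
        scale shrinks like the fourth root of 1/dof), so centring is checked
        jointly with its monotone tightening in dof."""
        off = {}
        for dof, n in ((2e3, 4000), (5e5, 1_000_000)):
            s = make_summary(0.5, 0.5, var_b=1.0, dof=dof, n=n)
            for cid in CLASS_IDS:
                lo, hi = null_distribution(s, cid,
                                           McConfig(n_iterations=400, seed=4))
                off[cid, dof] = max(abs(lo.mean() - 0.5), abs(hi.mean() - 0.5))
        assert off["uncorrelated", 5e5] < 0.01
        for cid in CLASS_IDS:
            assert off[cid, 5e5] < 0.08
            assert off[cid, 5e5] < off[cid, 2e3] + 1e-6

    def test_common_max_tracks_deterministic_bound(self):
        s = make_summary(0.58, ORTHOGONAL_COMMON, dof=5e5, n=1_000_000)
        lo, hi = null_distribution(s, "common", McConfig(n_iterations=300, seed=5))
        iv = common_signal_bounds(0.58, 1, 1, 1.44, 1.44)
        assert lo.mean() == pytest.approx(iv.lo, abs=0.01)
        assert hi.mean() == pytest.approx(iv.hi, abs=0.01)


class TestClassTest:
    def test_no_change_keeps_all_classes(self):
        s = make_summary(0.5, 0.5, var_b=1.0, dof=200)
        for cid in CLASS_IDS:
            assert not class_test(s, cid, McConfig(n_iterations=400, seed=6)).rejected

    def test_change_outside_additive_bounds_rejects_everything(self):
        # strong decorrelation with no variance change cannot be additive
        s = make_summary(0.9, 0.0, var_b=1.0, dof=2000, n=4000)
        cfg = McConfig(n_iterations=400, seed=7)
        for cid in CLASS_IDS:
            assert class_test(s, cid, cfg).rejected

    def test_decision_nesting(self):
        """Whenever the general additive class is rejected, both subclasses
        are rejected too (same posterior draw set)."""
        rng = np.random.default_rng(8)
        for _ in range(6):
            rho_a = rng.uniform(-0.8, 0.8)
            rho_b = rng.uniform(-0.95, 0.95)
            var_b = rng.uniform(0.8, 1.5)
            s = make_summary(rho_a, rho_b, var_b=var_b, dof=500, n=1000)
            cfg = McConfig(n_iterations=300, seed=int(rng.integers(1 << 20)))
            res = {cid: class_test(s, cid, cfg) for cid in CLASS_IDS}
            if res["additive"].rejected:
                assert res["common"].rejected
                assert res["uncorrelated"].rejected

    def test_infeasible_class_is_rejected_outright(self):
        # one node strongly down, the other up, high correlation: no shared
        # latent can produce this variance pattern
        s = make_summary(0.9, 0.85, dof=300, n=500)
        s = TwoStateSummary(
            state_a=s.state_a,
            state_b=type(s.state_b)(var_x=1.6, var_y=0.3, cov_xy=0.85 * np.sqrt(1.6 * 0.3),
                                    n_timepoints=500, dof_eff=300),
            pair_labels=s.pair_labels)
        res = class_test(s, "common", McConfig(n_iterations=300, seed=9))
        if res.n_rejected_draws >= 300:
            assert res.rejected


class TestConservativeness:
    @pytest.mark.parametrize("class_id,targets,relation", [
        ("uncorrelated", ("x", "y"), 0.0),
        ("uncorrelated", ("x",), 0.0),  # one-sided noise increase
        ("common", ("x", "y"), 0.0),    # orthogonal shared latent
        ("common", ("x", "y"), 0.4),    # shared latent aligned with existing
    ])
    def test_rejection_rate_at_most_nominal(self, class_id, targets, relation):
        """Data generated by an (arbitrary, not extremal) member of a class
        should be rejected at no more than the nominal rate."""
        base = np.array([[1.0, 0.5], [0.5, 1.0]])
        reps, rejections = 24, 0
        for r in range(reps):
            spec = ScenarioSpec(
                n_nodes=2, base_covariance=base, node_labels=("x", "y"),
                n_timepoints=1000, seed=5000 + r,
                injections=(Injection(targets=targets, class_id=class_id,
                                      variance_increase=0.3, relation=relation),))
            sa = generate_state(spec, "A")
            sb = generate_state(spec, "B")
            summ = TwoStateSummary(
                state_a=estimate_state_covariance(sa, ("x", "y"), dof_eff=999),
                state_b=estimate_state_covariance(sb, ("x", "y"), dof_eff=999),
                pair_labels=("x", "y"))
            cfg = McConfig(n_iterations=250, seed=r)
            rejections += class_test(summ, class_id, cfg).rejected
        # nominal 5% with binomial slack at 24 reps
        assert rejections / reps <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)


class TestCorrelationChangeTest:
    def test_identical_states_give_p_near_one(self):
        assert correlation_change_test(make_summary(0.58, 0.58, var_b=1.0)) \
            == pytest.approx(1.0, abs=1e-9)

    def test_large_change_is_overwhelming(self):
        p = correlation_change_test(make_summary(0.9, 0.0, var_b=1.0, dof=200))
        assert p < 1e-10

    def test_degenerate_correlation_raises(self):
        with pytest.raises(ValueError):
            correlation_change_test(make_summary(1.0, 0.5))

    def test_type_one_error_calibration(self, rng):
        """Null replicates (same correlation both states) should reject at
        the nominal 5% rate within binomial error."""
        reps, dof, rho = 1000, 200, 0.4
        hits = 0
        for _ in range(reps):
            # sample correlations directly from the Wishart model
            def sample_r():
                g = rng.normal(size=(dof, 2))
                g[:, 1] = rho * g[:, 0] + np.sqrt(1 - rho ** 2) * g[:, 1]
                return np.corrcoef(g[:, 0], g[:, 1])[0, 1]
            s = make_summary(sample_r(), sample_r(), var_b=1.0, dof=dof, n=dof)
            hits += correlation_change_test(s) < 0.05
        rate = hits / reps
        assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / reps)
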