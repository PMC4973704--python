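"""Moment estimation of the heterogeneity and inconsistency variances."""

import warnings

import numpy as np
import pytest

import netmoments as nm
from netmoments import IdentifiabilityError
from netmoments.network import build_design_matrices, pcd_matrix
from netmoments.simulation import _LayoutTemplate, LAYOUTS

from conftest import ab_study, dl_tau_squared, random_network, two_arm_network


def _ri(data):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return nm.fit_full_model(data)


class TestTauBeta:
    def test_hand_example(self, two_ab_network):
        qd = nm.decompose_q(two_ab_network)
        assert nm.estimate_tau_beta(qd) == pytest.approx(1.0, abs=1e-12)

    def test_exact_null_fit_gives_zero(self):
        # two AB studies with v = 1: Q = (y2-y1)^2 / 2 = 1 = df exactly
        net = two_arm_network([0.0, np.sqrt(2.0)], [1.0, 1.0])
        qd = nm.decompose_q(net)
        assert nm.estimate_tau_beta(qd) == pytest.approx(0.0, abs=1e-12)

    def test_no_replication_raises(self):
        net = nm.Network([ab_study("1", 0.0, 1.0, "AB"), ab_study("2", 0.5, 1.0, "AC")])
        with pytest.raises(IdentifiabilityError, match="replication"):
            nm.estimate_tau_beta(nm.decompose_q(net))
        with pytest.raises(IdentifiabilityError):
            nm.fit_full_model(net)

    def test_matches_dersimonian_laird(self):
        rng = np.random.default_rng(31)
        y = rng.normal(0, 0.8, size=7)
        v = rng.uniform(0.05, 0.5, size=7)
        fit = _ri(two_arm_network(y, v))
        untrunc, trunc = dl_tau_squared(y, v)
        assert fit.tau_beta_sq_untrunc == pytest.approx(untrunc, rel=1e-12)
        assert fit.tau_beta_sq == pytest.approx(trunc, rel=1e-12)


class TestTauOmega:
    def test_null_case(self):
        qd = nm.QDecomposition(
            q_net=11.0,
            q_het_by_design={},
            k_by_design={},
            df_het=0,
            df_net=11,
            tr_bp1=2.0,
            tr_bp2=3.0,
        )
        assert nm.estimate_tau_omega(qd, 0.0) == pytest.approx(0.0)

    def test_single_design_inestimable(self):
        net = two_arm_network([0.0, 1.0, 0.5], [1.0, 1.0, 1.0])
        qd = nm.decompose_q(net)
        with pytest.raises(IdentifiabilityError, match="not estimable"):
            nm.estimate_tau_omega(qd, 0.1)
        with pytest.warns(UserWarning, match="tau_omega"):
            fit = nm.fit_full_model(net)
        assert "omega_inestimable" in fit.flags
        assert fit.tau_omega_sq == 0.0

    def test_untruncated_beta_substituted(self):
        # dataset where both untruncated estimates are negative
        template = _LayoutTemplate(LAYOUTS["run1"])
        dm = template.simulate(np.random.default_rng(1), 0.0, 0.0)
        fit = nm.fit_full_model(dm)
        assert fit.tau_beta_sq_untrunc < 0.0
        qd = fit.qdecomp
        expected = (
            qd.q_net - qd.df_net - fit.tau_beta_sq_untrunc * qd.tr_bp1
        ) / qd.tr_bp2
        assert fit.tau_omega_sq_untrunc == pytest.approx(expected, rel=1e-12)
        assert {"truncated_beta", "truncated_omega"} <= fit.flags
        assert fit.tau_beta_sq == 0.0 and fit.tau_omega_sq == 0.0


class TestConsistencyModel:
    def test_qnet_estimator_and_collapse_flag(self):
        # exactly consistent and homogeneous data: Q_net = 0 < df_net
        rng = np.random.default_rng(41)
        net = random_network(rng)
        dm = build_design_matrices(net)
        delta = rng.normal(size=dm.c)
        consistent = nm.Network(
            [
                nm.Study(s.id, s.design, (dm.X @ delta)[sl], s.S)
                for s, sl in zip(net.studies, dm.study_rows)
            ]
        )
        fit = nm.fit_consistency_model(consistent)
        assert fit.model == "RC"
        assert fit.tau_beta_sq_untrunc < 0.0
        assert fit.tau_beta_sq == 0.0
        assert "collapsed_to_cc" in fit.flags

    def test_het_variant_matches_first_equation(self, two_ab_network):
        fit = nm.fit_consistency_model(two_ab_network, method="het")
        qd = nm.decompose_q(two_ab_network)
        assert fit.tau_beta_sq_untrunc == pytest.approx(nm.estimate_tau_beta(qd))
        with pytest.raises(ValueError):
            nm.fit_consistency_model(two_ab_network, method="bogus")

    def test_single_design_rc_equals_dl(self):
        # one design: Q_net = Q_het, tr(BP1) = K, so RC == RI == classical DL
        rng = np.random.default_rng(43)
        y = rng.normal(0, 0.6, size=6)
        v = rng.uniform(0.1, 0.6, size=6)
        net = two_arm_network(y, v)
        rc = nm.fit_consistency_model(net)
        untrunc, _ = dl_tau_squared(y, v)
        assert rc.tau_beta_sq_untrunc == pytest.approx(untrunc, rel=1e-12)

    def test_rc_more_precise_than_ri_under_consistency(self):
        """Attributing the inconsistency SS to heterogeneity shrinks the MC
        spread of the heterogeneity estimate when consistency truly holds."""
        template = _LayoutTemplate(LAYOUTS["run1"])
        rng = np.random.default_rng(45)
        ri_est, rc_est = [], []
        for _ in range(400):
            dm = template.simulate(rng, 0.0, 0.0)
            ri_est.append(nm.fit_full_model(dm).tau_beta_sq)
            rc_est.append(nm.fit_consistency_model(dm).tau_beta_sq)
        assert np.std(rc_est) < np.std(ri_est)


class TestCommonEffectModel:
    def test_variances_zero(self, two_ab_network):
        fit = nm.fit_common_effect_model(two_ab_network)
        assert fit.model == "CC"
        assert fit.tau_beta_sq == 0.0 and fit.tau_omega_sq == 0.0

    def test_inverse_variance_weighting(self):
        y = np.array([0.2, 0.8, -0.1])
        v = np.array([0.5, 0.25, 1.0])
        net = two_arm_network(y, v)
        gls = nm.gls_estimate(net, nm.fit_common_effect_model(net))
        w = 1.0 / v
        assert gls.delta_hat[0] == pytest.approx(np.sum(w * y) / w.sum(), rel=1e-12)
        assert gls.cov[0, 0] == pytest.approx(1.0 / w.sum(), rel=1e-12)


class TestLoopInconsistency:
    @pytest.fixture
    def network_and_dm(self):
        cfg = nm.SimulationConfig(
            layout="run1", tau_beta_sq=0.1, tau_omega_sq=0.1, seed=13
        )
        net = nm.simulate_dataset(cfg)
        return net, build_design_matrices(net)

    def test_full_p2_reproduces_full_model(self, network_and_dm):
        net, dm = network_and_dm
        full = nm.fit_full_model(net)
        loop = nm.fit_loop_inconsistency(dm, dm.P2)
        assert loop.tau_beta_sq_untrunc == pytest.approx(full.tau_beta_sq_untrunc)
        assert loop.tau_omega_sq_untrunc == pytest.approx(full.tau_omega_sq_untrunc)

    def test_zero_p2_is_degenerate(self, network_and_dm):
        _, dm = network_and_dm
        with pytest.warns(UserWarning):
            fit = nm.fit_loop_inconsistency(dm, np.zeros_like(dm.P2))
        assert "omega_inestimable" in fit.flags

    def test_zeroing_one_design_reduces_trbp2(self, network_and_dm):
        _, dm = network_and_dm
        p2 = dm.P2.copy()
        g = dm.groups[0]
        p2[g.rows, :] = 0.0
        p2[:, g.rows] = 0.0
        loop = nm.fit_loop_inconsistency(dm, p2)
        full = nm.fit_full_model(dm)
        assert loop.qdecomp.tr_bp2 < full.qdecomp.tr_bp2

    def test_invalid_overrides_rejected(self, network_and_dm):
        _, dm = network_and_dm
        bad_entries = dm.P2 * 0.6  # entries not in {0, 1/2, 1}
        with pytest.raises(ValueError, match="entries"):
            nm.fit_loop_inconsistency(dm, bad_entries)
        cross = np.ones_like(dm.P2)  # nonzero across designs
        with pytest.raises(ValueError, match="different designs"):
            nm.fit_loop_inconsistency(dm, cross)
        asym = dm.P2.copy()
        asym[0, 1] = 0.0
        with pytest.raises(ValueError, match="symmetric"):
            nm.fit_loop_inconsistency(dm, asym)

    def test_inconsistency_ratio(self, network_and_dm):
        net, _ = network_and_dm
        fit = nm.fit_full_model(net)
        if fit.tau_beta_sq > 0:
            assert fit.inconsistency_ratio == pytest.approx(
                fit.tau_omega_sq / fit.tau_beta_sq
            )


class TestScaleConsistency:
    def test_estimates_match_brute_force_rederivation(self):
        """Both estimating equations recomputed with raw dense algebra on a
        3-study toy, at two scalings of the within-study covariances."""
        d_ab = nm.canonicalize_design("AB")
        d_abc = nm.canonicalize_design("ABC")
        base = [
            nm.Study("1", d_ab, [0.3], [[0.2]]),
            nm.Study("2", d_ab, [-0.4], [[0.3]]),
            nm.Study("3", d_abc, [0.1, 0.6], 0.25 * pcd_matrix(2)),
        ]
        for scale in (1.0, 3.7):
            studies = [
                nm.Study(s.id, s.design, s.y, scale * s.S) for s in base
            ]
            net = nm.Network(studies)
            dm = build_design_matrices(net)
            fit = _ri(net)
            # independent re-derivation with dense numpy only
            W = np.linalg.inv(dm.S)
            H = dm.X @ np.linalg.solve(dm.X.T @ W @ dm.X, dm.X.T @ W)
            r = dm.y - H @ dm.y
            qnet = r @ W @ r
            B = W - W @ H
            tr1, tr2 = np.sum(B * dm.P1), np.sum(B * dm.P2)
            # design AB has the only replication; ABC is saturated
            sl = slice(0, 2)
            w = np.diag(W)[sl]
            ybar = np.sum(w * dm.y[sl]) / w.sum()
            qhet = np.sum(w * (dm.y[sl] - ybar) ** 2)
            kd = w.sum() - (w**2).sum() / w.sum()
            tb = (qhet - 1) / kd
            tw = (qnet - (4 - 2) - tb * tr1) / tr2
            assert fit.tau_beta_sq_untrunc == pytest.approx(tb, rel=1e-10)
            assert fit.tau_omega_sq_untrunc == pytest.approx(tw, rel=1e-10)
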