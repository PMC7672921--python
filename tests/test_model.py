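"""Unit tests for the GLS variance/precision core."""

import numpy as np
import pytest

import swdesign as sw
from swdesign.model import ClusterState

from conftest import (
    dense_treatment_variance,
    exchangeable_cluster_information,
    random_general_design,
    random_identifiable_design,
)


def scen(K=2, M=4, rho=0.05, tau=0.2, sigma2=1.0, degree=1):
    return sw.Scenario(K=K, M=M, rho=rho, tau=tau, sigma2=sigma2, degree=degree)


class TestScenario:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(K=3),  # odd
            dict(K=0),
            dict(M=0),
            dict(rho=1.0),
            dict(rho=-0.1),
            dict(tau=0.0),
            dict(tau=1.5),
            dict(sigma2=0.0),
            dict(degree=-1),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(K=2, M=4, rho=0.05, tau=0.2, sigma2=1.0, degree=1)
        base.update(kwargs)
        with pytest.raises(sw.InvalidDesignError):
            sw.Scenario(**base)

    def test_parameter_count(self):
        assert scen(degree=6).p == 8


class TestCorrelationBlock:
    def test_entries_follow_exponential_decay(self):
        sc = scen(rho=0.2, tau=0.3)
        R = sw.correlation_block(sc, [0.25, 0.5, 1.0])
        assert np.allclose(np.diag(R), 1.0)
        assert R[0, 1] == pytest.approx(0.2 * 0.3**0.25)
        # two individuals at either end of the trial: rho * tau
        assert R[0, 2] == pytest.approx(0.2 * 0.3**0.75)
        R2 = sw.correlation_block(sc, [1e-9, 1.0])
        assert R2[0, 1] == pytest.approx(0.2 * 0.3)

    def test_same_time_limit_is_rho(self):
        # correlation approaches rho (its upper bound) as the gap shrinks
        sc = scen(rho=0.1, tau=0.5)
        R = sw.correlation_block(sc, [0.5, 0.5 + 1e-12])
        assert R[0, 1] == pytest.approx(0.1, rel=1e-9)
        assert np.all(R[~np.eye(2, dtype=bool)] <= 0.1 + 1e-15)

    def test_exchangeable_at_tau_one(self):
        sc = scen(rho=0.15, tau=1.0)
        R = sw.correlation_block(sc, [0.1, 0.4, 0.9])
        off = R[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.15)

    def test_non_increasing_times_rejected(self):
        with pytest.raises(sw.InvalidDesignError):
            sw.correlation_block(scen(), [0.5, 0.5])
        with pytest.raises(sw.InvalidDesignError):
            sw.correlation_block(scen(), [0.5, 0.25])

    def test_positive_definite(self, rng):
        sc = scen(rho=0.8, tau=0.04)
        t = np.sort(rng.choice(np.arange(1, 101), size=30, replace=False)) / 100
        w = np.linalg.eigvalsh(sw.correlation_block(sc, t))
        assert w.min() > 0


class TestDesignMatrix:
    def test_intercept_plus_indicator(self):
        sc = scen(K=2, M=2, degree=0)
        d = sw.Design([2, 3], np.ones((2, 2), bool))
        Z = sw.design_matrix(sc, d)
        assert np.allclose(Z[0], [[1, 0], [1, 1]])

    def test_never_crossing_cluster_has_zero_treatment_column(self):
        sc = scen(K=2, M=3, degree=1)
        d = sw.Design([4, 1], np.ones((2, 3), bool))
        Z = sw.design_matrix(sc, d)
        assert np.all(Z[0][:, -1] == 0)
        assert np.all(Z[1][:, -1] == 1)

    def test_slot_at_crossover_is_treated(self):
        # H(0) = 1: the participant presenting exactly at cross-over is treated
        sc = scen(K=2, M=3, degree=0)
        d = sw.Design([2, 3], np.ones((2, 3), bool))
        Z = sw.design_matrix(sc, d)
        assert list(Z[0][:, -1]) == [0, 1, 1]

    def test_rows_only_for_recruited_slots(self):
        sc = scen(K=2, M=4, degree=0)
        rec = np.array([[1, 0, 1, 0], [0, 1, 0, 1]], bool)
        d = sw.Design([3, 3], rec)
        Z = sw.design_matrix(sc, d)
        assert Z[0].shape == (2, 2) and Z[1].shape == (2, 2)


class TestTreatmentVariance:
    def test_hand_computed_two_cluster_case(self):
        # one participant per cluster, one treated: Z'Z = [[2,1],[1,1]],
        # so Var(theta_hat) = 2 * sigma2
        for sigma2 in (1.0, 2.5):
            sc = sw.Scenario(K=2, M=1, rho=0.05, tau=0.2, sigma2=sigma2, degree=0)
            d = sw.Design([1, 2], np.ones((2, 1), bool))
            assert sw.treatment_variance(sc, d) == pytest.approx(2 * sigma2)
            assert sw.treatment_precision(sc, d) == pytest.approx(0.5)

    def test_independence_limit_matches_ols(self, rng):
        sc = scen(K=4, M=6, rho=0.0, tau=0.5, sigma2=1.7, degree=2)
        d = random_identifiable_design(rng, sc)
        Z = np.vstack(sw.design_matrix(sc, d))
        ols = sc.sigma2 * np.linalg.inv(Z.T @ Z)[-1, -1]
        assert sw.treatment_variance(sc, d) == pytest.approx(ols, rel=1e-10)

    def test_matches_dense_oracle(self, rng):
        for _ in range(10):
            sc = scen(
                K=int(rng.choice([2, 4])),
                M=int(rng.integers(3, 10)),
                rho=float(rng.choice([0.05, 0.25])),
                tau=float(rng.choice([0.2, 1.0])),
                sigma2=float(rng.uniform(0.5, 2.0)),
                degree=int(rng.integers(0, 3)),
            )
            d = random_identifiable_design(rng, sc)
            assert sw.treatment_variance(sc, d) == pytest.approx(
                dense_treatment_variance(sc, d), rel=1e-8
            )

    def test_basis_invariance(self, rng):
        # any invertible reparameterisation of the polynomial block leaves
        # the treatment variance unchanged
        sc = scen(K=4, M=8, rho=0.1, tau=0.5, degree=3)
        d = random_identifiable_design(rng, sc)
        ref = sw.treatment_variance(sc, d)
        for _ in range(3):
            T = rng.normal(size=(sc.degree + 1, sc.degree + 1))
            T += np.eye(sc.degree + 1) * 3
            assert dense_treatment_variance(sc, d, poly_mix=T) == pytest.approx(
                ref, rel=1e-9
            )

    def test_reversal_gives_identical_variance(self, rng):
        sc = scen(K=4, M=7, rho=0.2, tau=0.3, degree=2)
        d = random_identifiable_design(rng, sc)
        v1 = sw.treatment_variance(sc, d)
        v2 = sw.treatment_variance(sc, sw.reverse_design(d))
        assert v2 == pytest.approx(v1, rel=1e-10)

    def test_all_one_condition_raises_identifiability(self):
        sc = scen(K=2, M=3, degree=0)
        d = sw.Design([4, 4], np.ones((2, 3), bool))  # never crosses
        with pytest.raises(sw.IdentifiabilityError, match="control"):
            sw.treatment_variance(sc, d)

    def test_time_collinear_with_intercept_raises(self):
        sc = sw.Scenario(K=2, M=1, rho=0.05, tau=0.2, degree=1)
        d = sw.Design([1, 2], np.ones((2, 1), bool))
        with pytest.raises(sw.IdentifiabilityError):
            sw.treatment_variance(sc, d)

    def test_too_few_participants_raises(self):
        sc = scen(K=2, M=3, degree=3)  # p = 5
        d = sw.Design([2, 3], np.eye(2, 3, dtype=bool))
        with pytest.raises(sw.IdentifiabilityError):
            sw.treatment_variance(sc, d)

    def test_empty_design_raises(self):
        sc = scen(K=2, M=3)
        d = sw.Design([2, 3], np.zeros((2, 3), bool))
        with pytest.raises(sw.InvalidDesignError):
            sw.treatment_variance(sc, d)


class TestExchangeableClosedForm:
    def test_cluster_information_matches_closed_form(self, rng):
        sc = scen(K=4, M=8, rho=0.3, tau=1.0, sigma2=1.4, degree=2)
        d = random_identifiable_design(rng, sc)
        states = [
            ClusterState(sc, int(d.crossover[k]), d.recruit[k]) for k in range(d.K)
        ]
        for k, st in enumerate(states):
            if st.m == 0:
                continue
            W_ref = exchangeable_cluster_information(sc, d, k)
            assert np.allclose(st.W, W_ref, rtol=1e-10, atol=1e-12)


class TestClusterStateUpdates:
    def test_remove_then_readd_recovers_information(self, rng):
        sc = scen(K=2, M=8, rho=0.2, tau=0.4, degree=2)
        st = ClusterState(sc, 4, np.ones(8, bool))
        W0 = st.W.copy()
        st.apply_remove(5)
        st.apply_add(5)
        assert np.allclose(st.W, W0, atol=1e-10)

    def test_adjust_information_matches_rebuild(self, rng):
        for _ in range(25):
            M = int(rng.integers(3, 12))
            sc = scen(K=2, M=M, rho=float(rng.uniform(0, 0.5)), tau=float(rng.uniform(0.04, 1.0)), degree=int(rng.integers(0, 3)))
            row = rng.random(M) < 0.7
            if row.sum() < 2:
                continue
            c = int(rng.integers(1, M + 2))
            st = ClusterState(sc, c, row)
            slots = list(st.slots)
            s_rm = int(rng.choice(slots))
            W_dd = sw.adjust_information(st, s_rm, "remove")
            row2 = row.copy()
            row2[s_rm - 1] = False
            assert np.allclose(W_dd, ClusterState(sc, c, row2).W, atol=1e-10)
            unrec = [s for s in range(1, M + 1) if not row[s - 1]]
            if unrec:
                s_ad = int(rng.choice(unrec))
                W_up = sw.adjust_information(st, s_ad, "add")
                row3 = row.copy()
                row3[s_ad - 1] = True
                assert np.allclose(W_up, ClusterState(sc, c, row3).W, atol=1e-10)

    def test_removal_shrinks_information_in_psd_order(self, rng):
        sc = scen(K=2, M=10, rho=0.3, tau=0.5, degree=2)
        st = ClusterState(sc, 5, np.ones(10, bool))
        W_less = st.info_without(4)
        assert np.all(np.linalg.eigvalsh(st.W - W_less) > -1e-12)

    def test_invalid_slot_operations_raise(self):
        sc = scen(K=2, M=4, degree=0)
        st = ClusterState(sc, 2, np.array([1, 0, 1, 0], bool))
        with pytest.raises(sw.InvalidDesignError):
            st.apply_remove(2)  # not recruited
        with pytest.raises(sw.InvalidDesignError):
            st.apply_add(1)  # already recruited
        with pytest.raises(ValueError):
            sw.adjust_information(st, 1, "toggle")


class TestPrecisionAfterChanges:
    def test_empty_change_list_is_identity(self, rng):
        sc = scen(K=4, M=6, degree=1)
        d = random_identifiable_design(rng, sc)
        assert sw.precision_after_changes(sc, d, []) == pytest.approx(
            sw.treatment_precision(sc, d), rel=1e-12
        )

    def test_single_removal_matches_recompute(self, rng):
        sc = scen(K=4, M=6, rho=0.1, tau=0.3, degree=1)
        for _ in range(10):
            d = random_identifiable_design(rng, sc)
            recruited = np.argwhere(d.recruit)
            k, s = recruited[rng.integers(len(recruited))]
            d2 = d.copy()
            d2.recruit[k, s] = False
            try:
                expected = sw.treatment_precision(sc, d2)
            except sw.IdentifiabilityError:
                continue
            got = sw.precision_after_changes(sc, d, [(int(k) + 1, int(s) + 1, "remove")])
            assert got == pytest.approx(expected, rel=1e-9)

    def test_mirror_pair_removal_preserves_symmetry(self, rng):
        sc = scen(K=4, M=6, rho=0.1, tau=0.5, degree=1)
        d = random_identifiable_design(rng, sc, symmetric=True)
        recruited = np.argwhere(d.recruit[: d.K // 2])
        k, s = recruited[rng.integers(len(recruited))]
        mk, ms = d.K - 1 - int(k), d.M - 1 - int(s)
        d2 = d.copy()
        d2.recruit[k, s] = False
        d2.recruit[mk, ms] = False
        assert sw.is_symmetric(d2)
        try:
            expected = sw.treatment_precision(sc, d2)
        except sw.IdentifiabilityError:
            return
        got = sw.precision_after_changes(
            sc, d, [(int(k) + 1, int(s) + 1, "remove"), (mk + 1, ms + 1, "remove")]
        )
        assert got == pytest.approx(expected, rel=1e-9)

    def test_conflicting_changes_rejected(self, rng):
        sc = scen(K=2, M=4, degree=0)
        d = sw.Design([2, 4], np.ones((2, 4), bool))
        with pytest.raises(sw.InvalidDesignError):
            sw.precision_after_changes(sc, d, [(1, 2, "remove"), (1, 2, "remove")])


class TestReversalMatrix:
    def test_mirrored_cluster_information_via_linear_map(self, rng):
        for _ in range(5):
            M = int(rng.integers(2, 9))
            sc = scen(K=2, M=M, rho=0.1, tau=0.3, degree=int(rng.integers(0, 4)))
            c = int(rng.integers(1, M + 2))
            row = rng.random(M) < 0.7
            if row.sum() == 0:
                continue
            st = ClusterState(sc, c, row)
            st_m = ClusterState(sc, M + 2 - c, row[::-1].copy())
            S = sw.reversal_matrix(sc)
            assert np.allclose(st_m.W, S @ st.W @ S.T, rtol=1e-9, atol=1e-12)
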