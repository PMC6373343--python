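"""Streaming (SEMA) state: ingest, rank-one updates, online E/M steps,
sweeps, warm start, checkpointing, and exact equivalence with batch EM."""

import json

import numpy as np
import pytest

from semastream.em import BatchData, e_step, m_step
from semastream.model import DataPoint, ModelParameters
from semastream.sema import (
    GlobalState,
    IndividualSummary,
    init_warm_start,
    process_data_point,
    sherman_morrison_update,
    sweep,
)

from conftest import batch_to_points, random_batch, random_params


def _blank_state(p, r, params=None):
    params = params or ModelParameters(np.zeros(p), np.eye(r), 1.0)
    return GlobalState(p, r, params)


class TestShermanMorrison:
    def test_scalar_case(self):
        out = sherman_morrison_update(np.array([[0.25]]), np.array([2.0]))
        assert out[0, 0] == pytest.approx(1.0 / 8.0, rel=1e-14)

    def test_matches_direct_inversion(self):
        inv = np.linalg.inv(np.diag([2.0, 2.0]))
        out = sherman_morrison_update(inv, np.array([1.0, 1.0]))
        expected = np.linalg.inv(np.array([[3.0, 1.0], [1.0, 3.0]]))
        assert np.allclose(out, expected, atol=1e-12)

    def test_zero_vector_is_identity_operation(self, rng):
        A = rng.normal(size=(3, 3))
        inv = np.linalg.inv(A @ A.T + np.eye(3))
        assert np.allclose(sherman_morrison_update(inv, np.zeros(3)), inv)

    def test_degenerate_denominator_raises(self):
        with pytest.raises(np.linalg.LinAlgError, match="degenerate"):
            sherman_morrison_update(np.array([[-1.0]]), np.array([1.0]))

    def test_repeated_updates_track_true_inverse(self, rng):
        X0 = rng.normal(size=(6, 4))
        M = X0.T @ X0
        inv = np.linalg.inv(M)
        for _ in range(50):
            x = rng.normal(size=4)
            M += np.outer(x, x)
            inv = sherman_morrison_update(inv, x)
        assert np.allclose(inv, np.linalg.inv(M), atol=1e-8)


class TestIngest:
    def test_first_point_accumulators(self):
        state = _blank_state(1, 1)
        state.ingest(DataPoint("a", 3.0, np.array([1.0]), np.array([1.0])))
        assert state.n == 1 and state.J == 1
        assert state.XtX[0, 0] == 1.0 and state.xy[0] == 3.0
        ind = state.individuals["a"]
        assert ind.ZtZ[0, 0] == 1.0 and ind.Zty[0] == 3.0 and ind.yty == 9.0

    def test_accumulators_equal_from_scratch_products(self, rng):
        X = rng.normal(size=(100, 3))
        Z = rng.normal(size=(100, 2))
        y = rng.normal(size=100)
        state = _blank_state(3, 2)
        for i in range(100):
            state.ingest(DataPoint("only", y[i], X[i], Z[i]))
        ind = state.individuals["only"]
        assert np.allclose(ind.ZtZ, Z.T @ Z, atol=1e-10)
        assert np.allclose(ind.XtZ, X.T @ Z, atol=1e-10)
        assert np.allclose(ind.Zty, Z.T @ y, atol=1e-10)
        assert np.allclose(ind.XtX, X.T @ X, atol=1e-10)
        assert np.allclose(ind.Xty, X.T @ y, atol=1e-10)
        assert ind.yty == pytest.approx(y @ y, rel=1e-12)
        assert np.allclose(state.XtX, X.T @ X, atol=1e-10)

    def test_permutation_insensitive(self, rng):
        pts = [
            DataPoint(int(g), float(y), x, z)
            for g, y, x, z in zip(
                rng.integers(0, 3, 30),
                rng.normal(size=30),
                rng.normal(size=(30, 2)),
                rng.normal(size=(30, 1)),
            )
        ]
        s1, s2 = _blank_state(2, 1), _blank_state(2, 1)
        for pt in pts:
            s1.ingest(pt)
        order = rng.permutation(30)
        for k in order:
            s2.ingest(pts[k])
        assert np.allclose(s1.XtX, s2.XtX, atol=1e-10)
        for g in s1.individuals:
            assert np.allclose(
                s1.individuals[g].XtZ, s2.individuals[g].XtZ, atol=1e-10
            )

    def test_nonfinite_record_rejected_stream_continues(self):
        state = _blank_state(1, 1)
        with pytest.warns(UserWarning, match="non-finite"):
            state.ingest(DataPoint("a", np.nan, np.ones(1), np.ones(1)))
        assert state.n == 0
        state.ingest(DataPoint("a", 1.0, np.ones(1), np.ones(1)))
        assert state.n == 1


class TestOnlineEStep:
    def test_prior_only_individual(self):
        params = ModelParameters(np.zeros(2), np.diag([2.0, 0.5]), 3.0)
        state = _blank_state(2, 2, params)
        state.individuals["ghost"] = IndividualSummary(2, 2)
        state.J = 1
        state.e_step_individual("ghost")
        ind = state.individuals["ghost"]
        assert np.allclose(ind.b_hat, 0.0)
        assert np.allclose(ind.contrib_t1, 0.0)
        # T2j = sigma2 * (sigma2 Phi^-1)^-1 = Phi
        assert np.allclose(ind.contrib_T2, params.phi, atol=1e-9)
        assert ind.contrib_t3 == pytest.approx(0.0, abs=1e-12)

    def test_matches_offline_posterior_and_contributions(self, rng):
        from semastream.em import random_effects_posterior

        params = random_params(rng, p=3, r=2)
        X = rng.normal(size=(9, 3))
        Z = rng.normal(size=(9, 2))
        y = rng.normal(size=9)
        state = _blank_state(3, 2, params)
        for i in range(9):
            state.ingest(DataPoint("j", y[i], X[i], Z[i]))
        state.e_step_individual("j")
        ind = state.individuals["j"]
        post = random_effects_posterior(params, X, Z, y)
        assert np.allclose(ind.b_hat, post.b_hat, atol=1e-10)
        assert np.allclose(ind.C, post.C, atol=1e-8)
        # contributions against the raw-row definitions
        t1j = X.T @ Z @ post.b_hat
        T2j = np.outer(post.b_hat, post.b_hat) + params.sigma2 * post.C_inv
        u = y - X @ params.beta - Z @ post.b_hat
        t3j = u @ u + params.sigma2 * np.trace(post.C_inv @ Z.T @ Z)
        assert np.allclose(ind.contrib_t1, t1j, atol=1e-10)
        assert np.allclose(ind.contrib_T2, T2j, atol=1e-10)
        assert ind.contrib_t3 == pytest.approx(t3j, rel=1e-8)

    def test_residual_expansion_equals_raw_rss(self, rng):
        # the cross-product expansion of u'u must equal the direct residual
        # sum of squares from raw rows
        params = random_params(rng, p=4, r=2)
        X = rng.normal(size=(20, 4))
        Z = rng.normal(size=(20, 2))
        y = rng.normal(size=20)
        state = _blank_state(4, 2, params)
        for i in range(20):
            state.ingest(DataPoint("j", y[i], X[i], Z[i]))
        state.e_step_individual("j")
        ind = state.individuals["j"]
        u = y - X @ params.beta - Z @ ind.b_hat
        raw = float(u @ u) + params.sigma2 * np.trace(ind.C_inv @ (Z.T @ Z))
        assert ind.contrib_t3 == pytest.approx(raw, rel=1e-8)

    def test_idempotent_at_fixed_parameters(self, rng):
        data, params = random_batch(rng, J=4)
        state = _blank_state(data.p, data.r, params)
        for pt in batch_to_points(data):
            state.ingest(pt)
        for g in list(state.individuals):
            state.e_step_individual(g)
        t1, T2, t3 = state.t1.copy(), state.T2.copy(), state.t3
        for g in list(state.individuals):
            state.e_step_individual(g)
        assert np.allclose(state.t1, t1, atol=1e-12)
        assert np.allclose(state.T2, T2, atol=1e-12)
        assert state.t3 == pytest.approx(t3, rel=1e-14)


class TestOnlineOfflineEquivalence:
    def test_cdss_identical_at_frozen_parameters(self, rng):
        # all data arrived, parameters frozen: online totals == batch E-step
        data, params = random_batch(rng, J=6, n_j=5, p=3, r=2)
        state = _blank_state(data.p, data.r, params)
        for pt in batch_to_points(data):
            state.ingest(pt)
        for g in list(state.individuals):
            state.e_step_individual(g)
        cdss, _ = e_step(params, data)
        assert np.allclose(state.t1, cdss.t1, atol=1e-9)
        assert np.allclose(state.T2, cdss.T2, atol=1e-9)
        assert state.t3 == pytest.approx(cdss.t3, rel=1e-10)

    def test_m_step_matches_offline(self, rng):
        data, params = random_batch(rng, J=6)
        state = _blank_state(data.p, data.r, params)
        for pt in batch_to_points(data):
            state.ingest(pt)
        for g in list(state.individuals):
            state.e_step_individual(g)
        state.XtX_inv = np.linalg.inv(state.XtX)
        state.m_step()
        cdss, _ = e_step(params, data)
        offline = m_step(cdss, state.XtX, state.xy, data.n, data.J)
        assert np.allclose(state.params.beta, offline.beta, atol=1e-8)
        assert np.allclose(state.params.phi, offline.phi, atol=1e-10)
        assert state.params.sigma2 == pytest.approx(offline.sigma2, rel=1e-10)


class TestOnlineMStep:
    def test_beta_arithmetic(self):
        state = _blank_state(1, 1)
        state.n, state.J = 100, 2
        state.XtX_inv = np.array([[0.01]])
        state.xy = np.array([250.0])
        state.t1 = np.array([50.0])
        state.T2 = np.array([[100.0]])
        state.t3 = 500.0
        state.m_step()
        assert state.params.beta[0] == pytest.approx(2.0)
        assert state.params.phi[0, 0] == pytest.approx(50.0)
        assert state.params.sigma2 == pytest.approx(5.0)

    def test_phi_recovers_scaled_t2(self):
        phi0 = np.array([[2.0, 0.3], [0.3, 1.0]])
        state = _blank_state(1, 2)
        state.n, state.J = 10, 5
        state.XtX_inv = np.eye(1)
        state.xy = np.zeros(1)
        state.T2 = 5 * phi0
        state.t3 = 10.0
        state.m_step()
        assert np.allclose(state.params.phi, phi0)

    def test_negative_t3_signals_corruption(self):
        state = _blank_state(1, 1)
        state.n, state.J = 5, 1
        state.XtX_inv = np.eye(1)
        state.t3 = -1.0
        with pytest.raises(ValueError, match="inconsistent"):
            state.m_step()


class TestProcessDataPoint:
    def _warm_state(self, rng, J=6):
        data, params = random_batch(rng, J=J, n_j=5, p=3, r=2)
        return init_warm_start(batch_to_points(data)), data

    def test_unseen_individual_predicted_at_population_mean(self, rng):
        state, _ = self._warm_state(rng)
        x = rng.normal(size=3)
        pt = DataPoint("brand-new", 0.0, x, rng.normal(size=2))
        beta_before = state.params.beta.copy()
        pred, state = process_data_point(state, pt)
        assert pred == pytest.approx(float(x @ beta_before), abs=1e-12)

    def test_locality_of_update(self, rng):
        state, _ = self._warm_state(rng)
        n_before = state.n
        others = {
            g: (ind.contrib_t1.copy(), ind.n_j)
            for g, ind in state.individuals.items()
            if g != 0
        }
        pt = DataPoint(0, 1.0, rng.normal(size=3), rng.normal(size=2))
        _, state = process_data_point(state, pt)
        assert state.n == n_before + 1
        for g, (t1, n_j) in others.items():
            assert state.individuals[g].n_j == n_j
            assert np.array_equal(state.individuals[g].contrib_t1, t1)

    def test_cdss_totals_track_contributions(self, rng):
        state, _ = self._warm_state(rng)
        for _ in range(50):
            pt = DataPoint(
                int(rng.integers(0, 8)), float(rng.normal()),
                rng.normal(size=3), rng.normal(size=2),
            )
            _, state = process_data_point(state, pt)
        assert state.cdss_reconstruction_gap() < 1e-9


class TestWarmStart:
    def test_degenerate_stream_equals_batch_em(self, rng):
        from semastream.em import fit_em

        data, _ = random_batch(rng, J=6)
        state = init_warm_start(batch_to_points(data))
        params, _ = fit_em(data)
        assert np.allclose(state.params.beta, params.beta, atol=1e-12)
        assert np.allclose(state.params.phi, params.phi, atol=1e-12)
        assert state.cdss_reconstruction_gap() < 1e-12
        assert np.allclose(
            state.XtX_inv @ state.XtX, np.eye(data.p), atol=1e-8
        )

    def test_rank_deficient_training_raises(self):
        pts = [
            DataPoint(0, 1.0, np.array([1.0, 1.0]), np.ones(1))
            for _ in range(20)
        ]
        with pytest.raises(np.linalg.LinAlgError, match="larger warm-up"):
            init_warm_start(pts)

    def test_tolerance_insensitivity(self, rng):
        data, _ = random_batch(rng, J=30, n_j=10, p=2, r=1)
        pts = batch_to_points(data)
        loose = init_warm_start(pts, tol=1e-4)
        tight = init_warm_start(pts, tol=1e-9, max_iter=20_000)
        assert loose.params.max_abs_diff(tight.params) < 1e-3


class TestSweep:
    def test_sweep_converges_to_em_fixed_point(self, rng):
        data, _ = random_batch(rng, J=8, n_j=6)
        state = init_warm_start(batch_to_points(data))
        prev = state.params.copy()
        for _ in range(5000):
            state.sweep()
            delta = state.params.max_abs_diff(prev)
            prev = state.params.copy()
            if delta < 1e-9:
                break
        state.sweep()
        assert state.params.max_abs_diff(prev) < 1e-8

    def test_sweep_restores_reconstruction_invariant(self, rng):
        data, _ = random_batch(rng, J=6)
        state = init_warm_start(batch_to_points(data))
        for _ in range(30):
            pt = DataPoint(
                int(rng.integers(0, 6)), float(rng.normal()),
                rng.normal(size=3), rng.normal(size=2),
            )
            state.process(pt)
        state = sweep(state)
        assert state.cdss_reconstruction_gap() < 1e-9

    def test_sweeps_help_when_individuals_never_return(self):
        # burst-ordered arrivals: each individual's rows are contiguous, so
        # without sweeps early contributions go stale
        import semastream as ss

        errs_sema, errs_su = [], []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            J, per = 150, 40
            b = rng.normal(0.0, np.sqrt(8.0), size=J)
            pts = []
            for j in range(J):
                X = np.column_stack([np.ones(per), rng.standard_normal(per)])
                y = X @ np.array([5.0, 1.0]) + b[j] + rng.normal(0, 1, per)
                pts += [DataPoint(j, y[i], X[i], np.ones(1)) for i in range(per)]
            for method, errs in (("sema", errs_sema), ("sema_update", errs_su)):
                log, traj = ss.prequential_run(
                    method, pts, train_n=400, sweep_every=500
                )
                errs.append(abs(traj[-1]["phi"][0, 0] - 8.0))
        assert np.mean(errs_su) <= np.mean(errs_sema) * 1.1


class TestCheckpoint:
    def test_round_trip_is_exact(self, rng):
        data, _ = random_batch(rng, J=5)
        state = init_warm_start(batch_to_points(data))
        snap = json.loads(json.dumps(state.to_checkpoint()))
        restored = GlobalState.from_checkpoint(snap)
        assert restored.n == state.n and restored.J == state.J
        assert np.array_equal(restored.XtX, state.XtX)
        assert np.array_equal(restored.params.beta, state.params.beta)
        for g, ind in state.individuals.items():
            assert np.array_equal(restored.individuals[g].XtZ, ind.XtZ)
        # continued processing agrees exactly
        pt = DataPoint(0, 0.7, rng.normal(size=3), rng.normal(size=2))
        p1 = state.process(pt)
        p2 = restored.process(pt)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_version_mismatch_refused(self, rng):
        data, _ = random_batch(rng, J=3)
        state = init_warm_start(batch_to_points(data))
        snap = state.to_checkpoint()
        snap["version"] = 99
        with pytest.raises(ValueError, match="version"):
            GlobalState.from_checkpoint(snap)


class TestMemoryContract:
    def test_state_size_grows_with_J_not_n(self, rng):
        # same individuals, twice the data: identical structure sizes
        params = random_params(rng, p=2, r=1)

        def run(n):
            state = _blank_state(2, 1, params)
            for i in range(n):
                state.ingest(
                    DataPoint(i % 10, float(rng.normal()),
                              rng.normal(size=2), rng.normal(size=1))
                )
            return state

        s1, s2 = run(200), run(400)
        assert len(s1.individuals) == len(s2.individuals) == 10
        c1, c2 = s1.to_checkpoint(), s2.to_checkpoint()
        assert len(json.dumps(c1)) == pytest.approx(len(json.dumps(c2)), rel=0.2)
        # the per-individual map is the only growing structure
        assert set(c1) == set(c2)
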