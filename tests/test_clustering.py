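"""Alternating multi-scale clustering: block-update oracles, monotone
descent, simplex weights, indicator validity, and planted-label recovery."""

import numpy as np
import pytest

from spadom.clustering import (
    ClusteringState,
    _clustering_costs,
    fit,
    init_state,
    objective,
    update_assignments,
    update_centers,
    update_common,
    update_mappings,
    update_specific,
    update_weights,
)
from spadom.mgae import MultiScaleEmbeddings
from spadom.metrics import ari
from spadom.simulate import make_embedding_fixture


def random_instance(seed, N=12, M=2, dims=(6, 5), C=3, dc=4, ds=3,
                    beta=0.1, lam=1.0, delta=None):
    rng = np.random.default_rng(seed)
    H = MultiScaleEmbeddings([rng.normal(size=(N, d)) for d in dims])
    state = init_state(H, C, dc=dc, ds=ds, beta=beta, lam=lam, delta=delta,
                       seed=seed)
    return H, state


def brute_force_objective(state, H):
    """Scalar-loop evaluation of every term of the objective."""
    val = 0.0
    for m, Hm in enumerate(H.per_scale):
        R = Hm - state.Hc.T @ state.Wmaps[m] - state.Hs[m].T @ state.Pmaps[m]
        val += sum(R[i, j] ** 2 for i in range(R.shape[0]) for j in range(R.shape[1]))
    val += state.beta * np.sum(state.Hc**2)
    for h in state.Hs:
        val += state.beta * np.sum(h**2)
    reps = state.Hs + [state.Hc]
    for a, Rr, V in zip(state.alpha, reps, state.centers):
        val += a * np.sum((Rr - V @ state.U) ** 2)
    for V in state.centers:
        G = V.T @ V - np.eye(state.C)
        val += state.lam * np.sum(G**2)
    for a in state.alpha:
        if a > 0:
            val += state.delta * a * np.log(a)
    return val


class TestInitAndObjective:
    def test_init_contract(self):
        H, state = random_instance(0)
        M = H.n_scales
        np.testing.assert_allclose(state.alpha, 1.0 / (M + 1))
        assert np.isfinite(state.trace[0])
        assert np.all(state.U.sum(axis=0) == 1)

    def test_init_deterministic(self):
        _, s1 = random_instance(5)
        _, s2 = random_instance(5)
        np.testing.assert_array_equal(s1.U, s2.U)

    def test_too_many_clusters_rejected(self):
        rng = np.random.default_rng(0)
        H = MultiScaleEmbeddings([rng.normal(size=(4, 3))])
        with pytest.raises(ValueError):
            init_state(H, C=5)

    def test_objective_matches_brute_force(self):
        for seed in range(5):
            H, state = random_instance(seed)
            np.testing.assert_allclose(objective(state, H),
                                       brute_force_objective(state, H), rtol=1e-9)

    def test_zeroed_terms_closed_form(self):
        # H^m = Hc^T Wm exactly, Hs = 0, V columns = the points they cluster,
        # orthonormal V, uniform alpha
        rng = np.random.default_rng(3)
        dc, ds, C, N = 3, 2, 3, 3
        Hc = rng.normal(size=(dc, N))
        Wm = rng.normal(size=(dc, 4))
        H = MultiScaleEmbeddings([Hc.T @ Wm])
        U = np.eye(C)
        Vc = Hc.copy()  # common centers hit their points exactly
        q, _ = np.linalg.qr(rng.normal(size=(ds, C)))  # used only via lam=0
        state = ClusteringState(
            Hc=Hc, Hs=[np.zeros((ds, N))], Wmaps=[Wm], Pmaps=[np.zeros((ds, 4))],
            centers=[np.zeros((ds, C)), Vc], U=U,
            alpha=np.full(2, 0.5), beta=0.7, lam=0.0, delta=1.3, C=C,
        )
        expected = 0.7 * np.sum(Hc**2) + 1.3 * 2 * 0.5 * np.log(0.5)
        np.testing.assert_allclose(objective(state, H), expected, rtol=1e-12)

    def test_lambda_linearity(self):
        H, state = random_instance(7)
        pen = sum(np.sum((V.T @ V - np.eye(state.C)) ** 2) for V in state.centers)
        v1 = objective(state, H)
        state.lam *= 2.0
        v2 = objective(state, H)
        np.testing.assert_allclose(v2 - v1, pen * (state.lam / 2), rtol=1e-8)


class TestMappingUpdates:
    def test_exact_fit_recovery(self):
        rng = np.random.default_rng(0)
        dc, N, dm = 4, 10, 6
        Hc = rng.normal(size=(dc, N))
        Wstar = rng.normal(size=(dc, dm))
        H = MultiScaleEmbeddings([Hc.T @ Wstar])
        _, state = random_instance(0, N=N, M=1, dims=(dm,), dc=dc, ds=3)
        state.Hc = Hc
        state.Hs = [np.zeros_like(state.Hs[0])]
        state.Pmaps = [np.zeros_like(state.Pmaps[0])]
        update_mappings(state, H)
        np.testing.assert_allclose(state.Wmaps[0], Wstar, atol=1e-5)

    def test_residual_never_increases(self):
        for seed in range(5):
            H, state = random_instance(seed)

            def resid():
                return sum(
                    np.linalg.norm(Hm - state.Hc.T @ state.Wmaps[m]
                                   - state.Hs[m].T @ state.Pmaps[m]) ** 2
                    for m, Hm in enumerate(H.per_scale)
                )

            before = resid()
            update_mappings(state, H)
            assert resid() <= before + 1e-8 * max(before, 1.0)

    def test_matches_pseudoinverse_oracle(self):
        H, state = random_instance(4, N=5, M=1, dims=(4,), dc=3, ds=2, C=2)
        Hm = H.per_scale[0]
        target = Hm - state.Hs[0].T @ state.Pmaps[0]
        oracle = np.linalg.pinv(state.Hc.T) @ target  # exact normal equations
        update_mappings(state, H)
        np.testing.assert_allclose(state.Wmaps[0], oracle, rtol=1e-6, atol=1e-6)


class TestRepresentationUpdates:
    def test_huge_beta_shrinks_common_to_zero(self):
        H, state = random_instance(1)
        state.beta = 1e12
        update_common(state, H)
        assert np.max(np.abs(state.Hc)) < 1e-6

    def test_stationarity_of_linear_solve(self):
        H, state = random_instance(2)
        update_common(state, H)
        Hc1 = state.Hc.copy()
        update_common(state, H)
        np.testing.assert_allclose(state.Hc, Hc1, atol=1e-8)
        update_specific(state, H)
        Hs1 = [h.copy() for h in state.Hs]
        update_specific(state, H)
        for a, b in zip(state.Hs, Hs1):
            np.testing.assert_allclose(a, b, atol=1e-8)

    def test_matches_normal_equations_oracle(self):
        H, state = random_instance(6)
        M = H.n_scales
        dc = state.Hc.shape[0]
        A = (state.beta + state.alpha[-1]) * np.eye(dc)
        B = state.alpha[-1] * state.centers[-1] @ state.U
        for m, Hm in enumerate(H.per_scale):
            A += state.Wmaps[m] @ state.Wmaps[m].T
            B += state.Wmaps[m] @ (Hm - state.Hs[m].T @ state.Pmaps[m]).T
        oracle = np.linalg.solve(A, B)
        update_common(state, H)
        np.testing.assert_allclose(state.Hc, oracle, rtol=1e-6, atol=1e-8)
        ds = state.Hs[0].shape[0]
        oracles = []
        for m, Hm in enumerate(H.per_scale):
            Am = state.Pmaps[m] @ state.Pmaps[m].T + (state.beta + state.alpha[m]) * np.eye(ds)
            Bm = state.Pmaps[m] @ (Hm - state.Hc.T @ state.Wmaps[m]).T \
                + state.alpha[m] * state.centers[m] @ state.U
            oracles.append(np.linalg.solve(Am, Bm))
        update_specific(state, H)
        for m in range(M):
            np.testing.assert_allclose(state.Hs[m], oracles[m], rtol=1e-6, atol=1e-8)


class TestCenterUpdates:
    def test_lambda_zero_gives_cluster_means(self):
        H, state = random_instance(3)
        state.lam = 0.0
        update_centers(state, H)
        labels = state.labels
        reps = state.Hs + [state.Hc]
        for R, V in zip(reps, state.centers):
            for c in range(state.C):
                idx = np.flatnonzero(labels == c)
                if idx.size:
                    np.testing.assert_allclose(V[:, c], R[:, idx].mean(axis=1),
                                               atol=1e-6)

    def test_large_lambda_drives_orthonormality(self):
        H, state = random_instance(4, N=20, dc=6, ds=5)
        state.lam = 1e9
        update_centers(state, H, max_steps=500)
        for V in state.centers:
            np.testing.assert_allclose(V.T @ V, np.eye(state.C), atol=1e-3)

    def test_descent_beats_lambda_zero_initializer(self):
        for seed in range(5):
            H, state = random_instance(seed, lam=2.0)
            U, lam = state.U, state.lam
            counts = U.sum(axis=1)
            reps = [h.copy() for h in state.Hs] + [state.Hc.copy()]
            alphas = state.alpha.copy()
            update_centers(state, H, max_steps=300)
            for m, (R, V) in enumerate(zip(reps, state.centers)):
                V0 = R @ U.T @ np.linalg.inv(np.diag(counts) + 1e-8 * np.eye(state.C))

                def f(V_):
                    return alphas[m] * np.linalg.norm(R - V_ @ U) ** 2 \
                        + lam * np.linalg.norm(V_.T @ V_ - np.eye(state.C)) ** 2

                assert f(V) <= f(V0) + 1e-10
                # independent slow gradient descent oracle from the same start
                Vg, fg = V0.copy(), f(V0)
                step = 1e-3
                for _ in range(3000):
                    G = Vg.T @ Vg - np.eye(state.C)
                    grad = 2 * alphas[m] * (Vg @ U - R) @ U.T + 4 * lam * Vg @ G
                    cand = Vg - step * grad
                    fc = f(cand)
                    if fc <= fg:
                        Vg, fg = cand, fc
                    else:
                        step *= 0.5
                        if step < 1e-12:
                            break
                assert f(V) <= fg + 1e-4 * max(abs(fg), 1.0)


class TestAssignments:
    def test_zero_cost_point_assigned_to_its_center(self):
        H, state = random_instance(0, N=6, C=3)
        j = 2
        for m in range(len(state.Hs)):
            state.Hs[m][:, j] = state.centers[m][:, 2]
        state.Hc[:, j] = state.centers[-1][:, 2]
        update_assignments(state, H)
        assert state.labels[j] == 2

    def test_tie_broken_to_lowest_index(self):
        H, state = random_instance(1, N=5, C=4)
        # make clusters 0 and 3 identical -> every spot equidistant to both
        for V in state.centers:
            V[:, 3] = V[:, 0]
        update_assignments(state, H)
        assert not np.any(state.labels == 3)

    def test_matches_per_column_enumeration(self):
        for seed in range(5):
            H, state = random_instance(seed, N=4, M=2, dims=(3, 3), C=3, dc=2, ds=2)
            update_assignments(state, H)
            reps = state.Hs + [state.Hc]
            for j in range(4):
                costs = []
                for c in range(3):
                    v = sum(a * np.sum((R[:, j] - V[:, c]) ** 2)
                            for a, R, V in zip(state.alpha, reps, state.centers))
                    costs.append(v)
                assert state.labels[j] == int(np.argmin(costs))
            assert np.all(state.U.sum(axis=0) == 1)


class TestWeights:
    def test_equal_costs_give_uniform_weights(self):
        H, state = random_instance(0)
        # force equal costs by zeroing representations and centers
        for m in range(len(state.Hs)):
            state.Hs[m][:] = 0.0
            state.centers[m][:] = 0.0
        state.Hc[:] = 0.0
        state.centers[-1][:] = 0.0
        update_weights(state, H)
        np.testing.assert_allclose(state.alpha, 1.0 / (len(state.Hs) + 1))

    def test_high_temperature_limit(self):
        H, state = random_instance(2)
        state.delta = 1e9
        update_weights(state, H)
        np.testing.assert_allclose(state.alpha, 1.0 / state.alpha.size, atol=1e-3)

    def test_matches_simplex_grid_search(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            costs = rng.uniform(0.1, 3.0, size=3)
            delta = float(rng.uniform(0.5, 2.0))
            z = -costs / delta
            z -= z.max()
            softmax = np.exp(z) / np.exp(z).sum()

            def val(a):
                a = np.asarray(a)
                ent = np.sum(np.where(a > 0, a * np.log(np.where(a > 0, a, 1)), 0))
                return float(a @ costs + delta * ent)

            # exhaustive grid over the simplex at resolution 1e-3 (vectorised)
            grid = np.arange(0.0, 1.0 + 1e-9, 1e-3)
            a0, a1 = np.meshgrid(grid, grid, indexing="ij")
            a2 = 1.0 - a0 - a1
            ok = a2 >= -1e-12
            A = np.stack([a0[ok], a1[ok], np.maximum(a2[ok], 0.0)], axis=1)
            ent = np.sum(np.where(A > 0, A * np.log(np.where(A > 0, A, 1)), 0), axis=1)
            vals = A @ costs + delta * ent
            best_i = int(np.argmin(vals))
            np.testing.assert_allclose(softmax, A[best_i], atol=2e-3)
            assert val(softmax) <= vals[best_i] + 1e-9

    def test_simplex_conservation(self):
        for seed in range(10):
            H, state = random_instance(seed)
            update_weights(state, H)
            assert np.all(state.alpha > 0)
            assert abs(state.alpha.sum() - 1.0) < 1e-12

    def test_nonpositive_delta_rejected(self):
        H, state = random_instance(0)
        state.delta = 0.0
        with pytest.raises(ValueError):
            update_weights(state, H)


class TestMonotoneDescent:
    def test_every_block_never_increases_objective(self):
        blocks = [update_mappings, update_common, update_specific,
                  update_centers, update_assignments, update_weights]
        rng = np.random.default_rng(0)
        for trial in range(50):
            H, state = random_instance(trial, N=int(rng.integers(8, 16)),
                                       C=int(rng.integers(2, 4)))
            val = objective(state, H)
            for block in blocks:
                block(state, H)
                new = objective(state, H)
                assert new <= val + 1e-8 * abs(val) + 1e-12, block.__name__
                val = new


class TestFit:
    def test_separable_blobs_recovered_exactly(self):
        emb, labels = make_embedding_fixture(N=200, M=2, C=3, sep=5.0,
                                             spread=1.0, dims=(8, 6), seed=0)
        res = fit(emb, C=3, dc=6, ds=4, seed=0)
        assert ari(labels, res.labels) == 1.0

    def test_trace_non_increasing(self):
        emb, _ = make_embedding_fixture(N=80, M=2, C=3, sep=3.0, spread=1.0,
                                        dims=(6, 5), seed=1)
        res = fit(emb, C=3, dc=5, ds=3, seed=1, max_iter=30)
        t = np.asarray(res.objective_trace)
        assert np.all(np.diff(t) <= 1e-8 * np.abs(t[:-1]) + 1e-12)

    def test_max_iter_zero_returns_initialization(self):
        emb, _ = make_embedding_fixture(N=40, M=2, C=3, sep=4.0, spread=1.0,
                                        dims=(5, 4), seed=2)
        res0 = fit(emb, C=3, dc=4, ds=3, seed=3, max_iter=0)
        state = init_state(emb, 3, dc=4, ds=3, seed=3)
        np.testing.assert_array_equal(res0.labels, state.labels)
        assert res0.n_iter == 0

    def test_alpha_returned_on_simplex(self):
        emb, _ = make_embedding_fixture(N=60, M=2, C=3, sep=4.0, spread=1.0,
                                        dims=(6, 4), seed=4)
        res = fit(emb, C=3, dc=4, ds=3, seed=4, max_iter=20)
        assert np.all(res.alpha > 0) and abs(res.alpha.sum() - 1) < 1e-12
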