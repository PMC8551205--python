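"""Screening and the penalized embedding-regression solvers.

The coordinate-descent solutions are checked against closed forms
(orthonormal designs), a generic smooth optimizer on the split-variable
reformulation of the L1 term, and the stationarity (KKT) conditions of the
stated objectives.
"""

import numpy as np
import pytest
from scipy.optimize import minimize

from keser import (
    EmbeddingRegression,
    EmbeddingSet,
    IntegrativeEmbeddingRegression,
    Vocabulary,
    screen,
)
from keser.regression import default_lambda2_grid, fit_integrative, fit_single_site, tune_single_site
from keser import synthetic


def orthonormal_problem(p=5, d=16, seed=0):
    """Target + p candidates whose normalized vectors are orthonormal."""
    rng = np.random.default_rng(seed)
    X = np.linalg.qr(rng.standard_normal((d, p)))[0].T
    u = rng.standard_normal(d)
    u /= np.linalg.norm(u)
    vocab = Vocabulary(tuple(f"PheCode:{i}" for i in range(p + 1)))
    emb = EmbeddingSet(vocab, np.vstack([u, X]))
    return EmbeddingRegression(emb, "PheCode:0")


def random_problem(p, d=30, seed=0):
    rng = np.random.default_rng(seed)
    V = rng.standard_normal((p + 1, d))
    vocab = Vocabulary(tuple(f"PheCode:{i}" for i in range(p + 1)))
    emb = EmbeddingSet(vocab, V)
    return EmbeddingRegression(emb, "PheCode:0")


def oracle_minimize(model, lam1, lam2):
    """Generic optimizer on the split b = b+ - b- smooth reformulation."""
    p = len(model.candidates)
    r, G, w = model.r, model.G, model.weights

    def f(x):
        bp, bm = x[:p], x[p:]
        b = bp - bm
        return (
            1 - 2 * b @ r + b @ G @ b + lam1 * np.sum(w * (bp + bm)) + lam2 * np.sum(b**2)
        )

    best = None
    for s in range(3):
        x0 = np.abs(np.random.default_rng(s).standard_normal(2 * p)) * 0.1
        res = minimize(f, x0, method="L-BFGS-B", bounds=[(0, None)] * 2 * p,
                       options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    return best.fun


class TestSingleSiteSolver:
    def test_unpenalized_orthonormal_equals_cosines(self):
        model = orthonormal_problem()
        res = model.fit(0.0, 0.0)
        assert np.allclose(res.params_array, model.r, atol=1e-10)

    @pytest.mark.parametrize("lam1,lam2", [(0.02, 0.0), (0.0, 0.7), (0.05, 0.3), (0.3, 1.0)])
    def test_orthonormal_closed_form(self, lam1, lam2):
        model = orthonormal_problem(seed=3)
        res = model.fit(lam1, lam2)
        r = model.r
        closed = np.sign(r) * np.maximum(np.abs(r) - lam1 / (2 * np.abs(r)), 0) / (1 + lam2)
        assert np.allclose(res.params_array, closed, atol=1e-8)

    def test_large_lam1_zeroes_everything(self):
        model = random_problem(6, seed=1)
        res = model.fit(model.lambda1_max * 1.0001, 0.1)
        assert res.n_selected == 0
        res2 = model.fit(model.lambda1_max * 0.99, 0.1)
        assert res2.n_selected >= 1  # threshold is sharp

    @pytest.mark.parametrize("p,seed", [(3, 0), (5, 1), (8, 2), (8, 3)])
    def test_matches_generic_optimizer(self, p, seed):
        model = random_problem(p, seed=seed)
        lam1, lam2 = 0.05, 0.2
        res = model.fit(lam1, lam2)
        oracle = oracle_minimize(model, lam1, lam2)
        assert res.objective <= oracle + 1e-6
        assert abs(res.objective - oracle) <= 1e-6

    @pytest.mark.parametrize("seed", range(4))
    def test_kkt_residual_small(self, seed):
        model = random_problem(7, seed=seed)
        for lam1, lam2 in [(0.01, 0.0), (0.1, 0.5), (0.0, 0.0)]:
            res = model.fit(lam1, lam2)
            assert res.kkt_residual() <= 1e-6

    def test_objective_below_zero_vector_and_sweepwise_decrease(self):
        model = random_problem(6, seed=5)
        lam1, lam2 = 0.05, 0.1
        res = model.fit(lam1, lam2)
        assert res.objective <= model.objective(np.zeros(6), lam1, lam2)
        # monotone decrease across sweeps: run sweep-by-sweep via max_iter
        prev = np.inf
        for sweeps in range(1, 6):
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                obj = model.fit(lam1, lam2, max_iter=sweeps).objective
            assert obj <= prev + 1e-12
            prev = obj

    def test_support_monotone_in_lam1_orthonormal(self):
        model = orthonormal_problem(seed=7)
        sizes = [model.fit(l1, 0.2).n_selected for l1 in np.linspace(0, model.lambda1_max, 12)]
        assert sizes == sorted(sizes, reverse=True)

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            random_problem(3).fit(-1.0, 0.0)


class TestScreening:
    def test_brute_force_equivalence_small_fixture(self):
        emb, truth = synthetic.simulate_ggm_embeddings(p=20, d=400, n_neighbors=3, seed=4)
        tgt = truth.vocab.codes[0]
        s = screen(emb, tgt, alpha=0.05, n_null=150, seed=1)
        rho = s.rho["PheCode-PheCode"]
        U = emb.rows_normalized()
        ti = emb.vocab.index(tgt)
        expect = {
            c
            for j, c in enumerate(emb.vocab.codes)
            if c != tgt and U[j] @ U[ti] >= rho
        }
        assert set(s.candidates) == expect

    def test_alpha_zero_uses_null_maximum(self, toy_embeddings):
        from keser.evaluate import make_pair_type

        s = screen(toy_embeddings, "PheCode:000", alpha=0.0, n_null=20, seed=2)
        for c in s.candidates:
            rho = s.rho[make_pair_type("PheCode:000", c)]
            assert s.cosines[c] >= rho

    def test_target_never_candidate_and_absent_target_errors(self, toy_embeddings):
        s = screen(toy_embeddings, "PheCode:000", alpha=None)
        assert "PheCode:000" not in s.candidates
        with pytest.raises(ValueError):
            screen(toy_embeddings, "PheCode:xxx")


class TestTuning:
    def test_grid_of_one_returns_that_point(self):
        model = random_problem(4, seed=6)
        emb = model.embeddings
        res = model.fit_tuned(emb, lam1_grid=[0.07], lam2_grid=[0.3])
        assert (res.lam1, res.lam2) == (0.07, 0.3)

    def test_matches_exhaustive_grid_scan(self):
        model = random_problem(5, seed=8)
        valid = random_problem(5, seed=9).embeddings  # independent validation draw
        lam1s, lam2s = [0.02, 0.1, 0.4], [0.01, 1.0]
        res = model.fit_tuned(valid, lam1_grid=lam1s, lam2_grid=lam2s)
        # brute-force scan with the same tolerance-based tie-break
        from keser.regression import _tuning_better
        _, r_v, G_v = model.validation_quantities(valid)
        best = None
        for l2 in sorted(lam2s):
            for l1 in sorted(lam1s, reverse=True):
                fit = model.fit(l1, l2)
                b = fit.params_array
                loss = float(1 - 2 * b @ r_v + b @ G_v @ b)
                key = (loss, fit.n_selected, l2)
                if best is None or _tuning_better(key, best[0]):
                    best = (key, (l1, l2))
        assert (res.lam1, res.lam2) == best[1]

    def test_functional_wrapper_route(self):
        emb_t, truth = synthetic.simulate_ggm_embeddings(p=15, d=300, n_neighbors=2, seed=11)
        emb_v, _ = synthetic.simulate_ggm_embeddings(p=15, d=300, seed=12, spec=truth.ggm)
        res = tune_single_site(emb_t, emb_v, truth.vocab.codes[0])
        assert res.converged and res.validation_loss is not None


class TestIntegrative:
    def test_single_site_reduction(self):
        """With one site the group penalty reduces algebraically to the
        adaptive-lasso + ridge form; both solvers must agree."""
        model = random_problem(6, seed=13)
        integ = IntegrativeEmbeddingRegression([model.embeddings], "PheCode:0")
        for lam1, lam2 in [(0.02, 0.0), (0.08, 0.4), (0.0, 0.0)]:
            a = model.fit(lam1, lam2).params_array
            b = integ.fit(lam1, lam2).params_sites[0]
            assert np.allclose(a, b, atol=1e-6)

    def test_group_kkt_threshold_zeroes_all(self):
        train, _, truth = synthetic.simulate_multisite_embeddings(p=20, d=200, n_neighbors=3, seed=3)
        tgt = truth.vocab.codes[0]
        im = IntegrativeEmbeddingRegression(train, tgt)
        res = im.fit(im.lambda1_max * 1.0001, 0.1)
        assert len(res.support) == 0
        res2 = im.fit(im.lambda1_max * 0.99, 0.1)
        assert len(res2.support) >= 1

    def test_group_structure_respected(self):
        train, valid, truth = synthetic.simulate_multisite_embeddings(p=20, d=300, n_neighbors=3, seed=5)
        tgt = truth.vocab.codes[2]
        im = IntegrativeEmbeddingRegression(train, tgt)
        res = im.fit(im.lambda1_max * 0.2, 0.1)
        df = res.params
        for c in df.index:
            norm = np.abs(df.loc[c]).sum()
            assert (c in res.support) == (norm != 0)

    @pytest.mark.parametrize("seed", range(3))
    def test_integrative_kkt(self, seed):
        train, _, truth = synthetic.simulate_multisite_embeddings(p=15, d=250, n_neighbors=2, seed=seed)
        tgt = truth.vocab.codes[0]
        im = IntegrativeEmbeddingRegression(train, tgt)
        res = im.fit(im.lambda1_max * 0.1, 0.3)
        assert res.kkt_residual() <= 1e-6

    def test_matches_generic_optimizer_two_sites(self):
        train, _, truth = synthetic.simulate_multisite_embeddings(p=6, d=60, n_neighbors=2, seed=7)
        tgt = truth.vocab.codes[0]
        im = IntegrativeEmbeddingRegression(train, tgt)
        lam1, lam2 = 0.05, 0.2
        res = im.fit(lam1, lam2)

        sizes = [r.size for r in im.r_sites]
        def f(x):
            bs, off = [], 0
            for s in sizes:
                bs.append(x[off : off + s])
                off += s
            return im.objective(bs, lam1, lam2)

        x0 = np.concatenate(res.params_sites)
        ref = minimize(f, np.zeros_like(x0), method="Powell", options={"maxiter": 200000, "xtol": 1e-12, "ftol": 1e-14})
        assert res.objective <= ref.fun + 1e-6

    def test_structural_zeros_outside_site_screen(self):
        train, _, truth = synthetic.simulate_multisite_embeddings(
            p=20, d=300, n_neighbors=3, seed=9, site_vocab_fraction=0.8
        )
        shared = [c for c in truth.vocab.codes if all(c in e.vocab for e in train)]
        tgt = shared[0]
        screens = [screen(e, tgt, alpha=None) for e in train]
        res = fit_integrative(train, screens, 0.05, 0.1)
        df = res.params
        for m, e in enumerate(train):
            col = df[res.model.site_names[m]]
            for c in df.index:
                if c not in screens[m].candidates:
                    assert col[c] == 0.0

    def test_wrapper_and_summary(self):
        emb_t, truth = synthetic.simulate_ggm_embeddings(p=12, d=200, n_neighbors=2, seed=15)
        tgt = truth.vocab.codes[0]
        s = screen(emb_t, tgt, alpha=None)
        res = fit_single_site(emb_t, s, 0.05, 0.1)
        text = res.summary()
        assert tgt in text and "lam1" in text
        ires = fit_integrative([emb_t], [s], 0.05, 0.1)
        assert tgt in ires.summary()


def test_default_lambda2_grid_shape():
    g = default_lambda2_grid()
    assert len(g) == 5 and g[0] == pytest.approx(1e-4) and g[-1] == pytest.approx(1.0)
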