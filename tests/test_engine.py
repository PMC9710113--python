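"""Per-target lambda-sweep scoring, dropout accumulation, score matrix."""

import dataclasses

import numpy as np
import pytest

import srgs
from srgs.engine import (RawScoreVector, SRGSConfig, dropout_iteration,
                         lambda_grid, minmax_normalize, score_target,
                         srgs_infer, tune_p)
from srgs.io import ExpressionMatrix


class TestConfig:
    def test_defaults_match_standard_protocol(self):
        cfg = SRGSConfig()
        assert cfg.K == 1 and cfg.iter == 10
        assert (cfg.lam_min, cfg.lam_max, cfg.lam_step) == (0.01, 0.99, 0.01)

    @pytest.mark.parametrize("kw", [
        {"lam_min": 0.0}, {"lam_max": 1.0}, {"lam_min": 0.6, "lam_max": 0.5},
        {"lam_step": 0.0}, {"K": 0}, {"iter": 0},
        {"dropout": True, "p": 1.5},
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            SRGSConfig(**kw)


class TestLambdaGrid:
    @pytest.mark.parametrize("lo, hi, step, n", [
        (0.01, 0.99, 0.01, 99),
        (0.5, 0.99, 0.01, 50),
        (0.3, 0.3, 0.1, 1),
    ])
    def test_grid_length(self, lo, hi, step, n):
        grid = lambda_grid(SRGSConfig(lam_min=lo, lam_max=hi, lam_step=step))
        assert len(grid) == n
        assert grid[0] == pytest.approx(lo)
        np.testing.assert_allclose(np.diff(grid), step)

    def test_endpoints_inclusive(self):
        grid = lambda_grid(SRGSConfig())
        assert grid[-1] == pytest.approx(0.99)


class TestMinMax:
    @pytest.mark.parametrize("v, expected", [
        ([99.0, 0.0], [1.0, 0.0]),
        ([5.0, 5.0, 5.0], [0.0, 0.0, 0.0]),
        ([2.0, 6.0, 4.0], [0.0, 1.0, 0.5]),
    ])
    def test_examples(self, v, expected):
        np.testing.assert_allclose(minmax_normalize(np.array(v)), expected)

    def test_accepts_raw_score_vector(self):
        v = RawScoreVector(counts=np.array([0.0, 3.0]))
        np.testing.assert_allclose(minmax_normalize(v), [0.0, 1.0])


def closed_form_two_candidate_counts(X, y, cfg):
    """Oracle for d=2: gene 1 counted where lam*z1 > z2, gene 2 never.

    z1 > z2 > 0 are the covariance magnitudes after standardization;
    when both survive the threshold |A| = d and the increment is gated.
    """
    data = srgs.standardize(X, y, scale=cfg.scale)
    z = np.abs(data.X.T @ data.y)
    assert z[0] > z[1] > 0
    grid = lambda_grid(cfg)
    c1 = int(np.sum(grid * z[0] > z[1]))
    return np.array([float(c1), 0.0])


class TestScoreTarget:
    def test_two_candidate_closed_form(self, rng):
        X = rng.normal(size=(40, 2))
        y = X[:, 0] * 1.0 + X[:, 1] * 0.4 + 0.2 * rng.normal(size=40)
        cfg = SRGSConfig()
        expected = closed_form_two_candidate_counts(X, y, cfg)
        got = score_target(X, y, cfg).counts
        np.testing.assert_array_equal(got, expected)

    def test_equal_covariances_always_gated(self):
        # three identical candidate columns: |A| = d at every lambda
        y = np.array([1.0, -1.0, 2.0, -2.0, 0.5, -0.5])
        X = np.column_stack([y, y, y])
        counts = score_target(X, y, SRGSConfig()).counts
        np.testing.assert_array_equal(counts, np.zeros(3))

    def test_orthogonal_response_all_zero(self):
        X = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]])
        y = np.array([1.0, -1.0, -1.0, 1.0])
        counts = score_target(X, y, SRGSConfig()).counts
        np.testing.assert_array_equal(counts, np.zeros(2))

    def test_constant_response_warns_and_zeroes(self, rng, caplog):
        X = rng.normal(size=(10, 3))
        with caplog.at_level("WARNING", logger="srgs.engine"):
            counts = score_target(X, np.ones(10), SRGSConfig()).counts
        np.testing.assert_array_equal(counts, np.zeros(3))
        assert any("constant" in r.message for r in caplog.records)

    def test_count_bound(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        counts = score_target(X, y, SRGSConfig()).counts
        assert np.all(counts <= 99)

    def test_k2_path_agrees_with_gate_semantics(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        counts = score_target(X, y, SRGSConfig(K=2)).counts
        assert counts.shape == (4,) and np.all(counts >= 0)
        assert np.all(counts <= 99)


class TestDropoutIteration:
    def test_p1_reproduces_plain_scoring(self, rng):
        X = rng.normal(size=(25, 6))
        y = rng.normal(size=25)
        cfg = SRGSConfig(dropout=True, p=1.0)
        plain = score_target(X, y, cfg).counts
        masked = dropout_iteration(X, y, cfg, iteration_seed=7).counts
        np.testing.assert_array_equal(plain, masked)

    def test_same_seed_identical(self, rng):
        X = rng.normal(size=(25, 6))
        y = rng.normal(size=25)
        cfg = SRGSConfig(dropout=True, p=0.5)
        a = dropout_iteration(X, y, cfg, iteration_seed=3).counts
        b = dropout_iteration(X, y, cfg, iteration_seed=3).counts
        np.testing.assert_array_equal(a, b)

    def test_mask_law_binomial_concentration(self, rng, monkeypatch):
        # capture the masked matrix handed to the scorer and check the
        # zeroed fraction against Bernoulli(1-p) concentration
        M, d, p = 100, 10, 0.5
        X = np.abs(rng.normal(size=(M, d))) + 0.5   # all entries nonzero
        y = rng.normal(size=M)
        seen = {}

        def capture(X_cand, y_target, cfg, target_id=None):
            seen["X"] = X_cand
            return RawScoreVector(counts=np.zeros(X_cand.shape[1]))

        import srgs.engine as eng
        monkeypatch.setattr(eng, "score_target", capture)
        dropout_iteration(X, y, SRGSConfig(dropout=True, p=p),
                          iteration_seed=42)
        frac = np.mean(seen["X"] == 0.0)
        sd = np.sqrt(p * (1 - p) / (M * d))
        assert abs(frac - (1 - p)) < 3 * sd

    def test_response_never_masked(self, rng, monkeypatch):
        X = np.abs(rng.normal(size=(50, 4))) + 0.5
        y = np.abs(rng.normal(size=50)) + 0.5
        seen = {}

        def capture(X_cand, y_target, cfg, target_id=None):
            seen["y"] = y_target
            return RawScoreVector(counts=np.zeros(X_cand.shape[1]))

        import srgs.engine as eng
        monkeypatch.setattr(eng, "score_target", capture)
        dropout_iteration(X, y, SRGSConfig(dropout=True, p=0.2),
                          iteration_seed=1)
        assert np.all(seen["y"] > 0)
        assert sorted(seen["y"]) == sorted(y)


def three_gene_matrix(rng, M=50):
    g1 = rng.normal(size=M)
    g2 = rng.normal(size=M)
    g3 = 2 * g1 + 0.05 * rng.normal(size=M)
    return ExpressionMatrix(np.column_stack([g1, g2, g3]),
                            [f"s{i}" for i in range(M)], ["g1", "g2", "g3"])


class TestInfer:
    def test_planted_driver_scores_one_other_zero(self, rng):
        expr = three_gene_matrix(rng)
        S = srgs_infer(expr, SRGSConfig())
        i3, i1, i2 = 2, 0, 1
        assert S.S[i3, i1] == 1.0
        assert S.S[i3, i2] == 0.0

    def test_entries_in_unit_interval_diagonal_zero(self, rng):
        expr = ExpressionMatrix(rng.normal(size=(20, 6)),
                                [f"s{i}" for i in range(20)],
                                [f"g{j}" for j in range(6)])
        S = srgs_infer(expr, SRGSConfig())
        assert np.all(S.S >= 0) and np.all(S.S <= 1)
        np.testing.assert_array_equal(np.diag(S.S), 0)

    def test_dropout_noop_matches_deterministic(self, rng):
        expr = three_gene_matrix(rng, M=30)
        S_off = srgs_infer(expr, SRGSConfig())
        S_on = srgs_infer(expr, SRGSConfig(dropout=True, p=1.0, iter=1, seed=5))
        np.testing.assert_allclose(S_on.S, S_off.S, atol=1e-12)

    def test_worker_invariance_bitwise(self, rng):
        expr = ExpressionMatrix(rng.normal(size=(15, 5)),
                                [f"s{i}" for i in range(15)],
                                [f"g{j}" for j in range(5)])
        cfg = SRGSConfig(dropout=True, p=0.7, iter=3, seed=11)
        S1 = srgs_infer(expr, dataclasses.replace(cfg, n_workers=1))
        S2 = srgs_infer(expr, dataclasses.replace(cfg, n_workers=2))
        np.testing.assert_array_equal(S1.S, S2.S)

    def test_seed_determinism(self, rng):
        expr = three_gene_matrix(rng, M=20)
        cfg = SRGSConfig(dropout=True, p=0.6, iter=2, seed=9)
        np.testing.assert_array_equal(srgs_infer(expr, cfg).S,
                                      srgs_infer(expr, cfg).S)

    def test_duplicate_gene_ids_rejected(self, rng):
        expr = three_gene_matrix(rng, M=10)
        expr.gene_ids = ["g1", "g1", "g3"]
        with pytest.raises(ValueError, match="duplicat"):
            srgs_infer(expr, SRGSConfig())

    def test_too_few_genes_rejected(self, rng):
        expr = ExpressionMatrix(rng.normal(size=(10, 2)),
                                [f"s{i}" for i in range(10)], ["a", "b"])
        with pytest.raises(ValueError, match="3 genes"):
            srgs_infer(expr, SRGSConfig())


class TestTuneP:
    def test_singleton_grid_matches_deterministic_run(self, rng):
        net = srgs.random_network(6, 0.3, seed=4)
        ts = srgs.simulate_timeseries(net, n_series=60, seed=5)
        expr = srgs.sample_cells(ts, 30, seed=6)
        cfg = SRGSConfig(seed=2)
        best_p, profile = tune_p(expr, net, cfg, p_grid=[1.0], repeats=1)
        assert best_p == 1.0
        det = srgs.auroc_aupr(
            srgs.scores_to_edges(srgs_infer(expr, dataclasses.replace(
                cfg, dropout=True, p=1.0))), net).auroc
        assert profile[1.0] == pytest.approx(det, abs=1e-12)

    def test_tie_breaks_toward_smaller_p(self, rng, monkeypatch):
        import srgs.evaluate as ev
        from srgs.evaluate import EvalResult

        monkeypatch.setattr(ev, "auroc_aupr",
                            lambda edges, truth: EvalResult(0.7, 0.1, 1, 1))
        net = srgs.random_network(4, 0.3, seed=0)
        expr = ExpressionMatrix(rng.normal(size=(8, 4)),
                                [f"s{i}" for i in range(8)],
                                list(net.gene_ids))
        best_p, profile = tune_p(expr, net, SRGSConfig(seed=0),
                                 p_grid=[0.4, 0.8], repeats=1)
        assert best_p == 0.4 and profile == {0.4: 0.7, 0.8: 0.7}
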