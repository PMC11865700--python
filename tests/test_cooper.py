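"""Cooperative alternation: initialization, iteration, convergence."""

import numpy as np
import pytest

from coopernet.cooper import (
    CooperConfig,
    convergence_check,
    extract_coefficients,
    fit_cooper,
    shared_selection,
)
from coopernet.cox_core import SurvivalDataset
from coopernet.fwcoxnet import PenaltyConfig
from coopernet.simulators import BlockSpec, HighDimConfig, gen_highdim_dataset


def small_competing_dataset(seed=0, n=150, p=12) -> SurvivalDataset:
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    b1 = np.zeros(p)
    b2 = np.zeros(p)
    b1[0] = b2[0] = 1.0       # one shared effect
    b1[1] = 0.8               # one cause-1-only effect
    t1 = -np.log(rng.uniform(size=n)) / (0.2 * np.exp(X @ b1))
    t2 = -np.log(rng.uniform(size=n)) / (0.2 * np.exp(X @ b2))
    c = -np.log(rng.uniform(size=n)) / 0.15
    stacked = np.column_stack([c, t1, t2])
    status = np.argmin(stacked, axis=1)
    return SurvivalDataset(time=stacked[np.arange(n), status], status=status, X=X)


SMALL_CFG = PenaltyConfig(alpha=1.0, nfolds=4, n_lambda=25)


class TestConvergenceCheck:
    def test_identical_vectors_converged(self):
        h = [(np.ones(3), np.zeros(3)), (np.ones(3), np.zeros(3))]
        assert convergence_check(h, 1e-12)

    def test_boundary_norm_equal_epsilon_is_not_converged(self):
        h = [(np.zeros(3), np.zeros(3)), (np.array([0.1, 0, 0]), np.zeros(3))]
        assert not convergence_check(h, 0.1)

    def test_matches_independent_norm(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=4), rng.normal(size=4)
            c, d = rng.normal(size=4), rng.normal(size=4)
            eps = float(rng.uniform(0.5, 3.0))
            expected = (np.sqrt(np.sum((c - a) ** 2)) < eps
                        and np.sqrt(np.sum((d - b) ** 2)) < eps)
            assert convergence_check([(a, b), (c, d)], eps) == expected

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            convergence_check([(np.zeros(3), np.zeros(2)), (np.zeros(4), np.zeros(2))], 1.0)

    def test_requires_two_entries(self):
        with pytest.raises(ValueError):
            convergence_check([(np.zeros(2), np.zeros(2))], 1.0)


class TestFitCooper:
    def test_mt_zero_collapses_to_initial_fits(self):
        ds = small_competing_dataset()
        fit = fit_cooper(ds, CooperConfig(mt_max_iter=0, penalty=SMALL_CFG, seed=1))
        assert np.array_equal(fit.fit_cause1.beta, fit.initial_fit_cause1.beta)
        assert np.array_equal(fit.fit_cause2.beta, fit.initial_fit_cause2.beta)
        assert fit.n_iterations_run == 0 and len(fit.history) == 1

    def test_history_starts_at_initial_coefficients(self):
        ds = small_competing_dataset(seed=3)
        fit = fit_cooper(ds, CooperConfig(mt_max_iter=2, penalty=SMALL_CFG, seed=4))
        assert np.array_equal(fit.history[0][0], fit.initial_fit_cause1.beta)
        assert np.array_equal(fit.history[0][1], fit.initial_fit_cause2.beta)
        assert len(fit.history) == fit.n_iterations_run + 1

    def test_missing_cause_raises_with_cause_name(self):
        ds = small_competing_dataset()
        ds.status[ds.status == 2] = 0
        with pytest.raises(ValueError, match="cause 2"):
            fit_cooper(ds, CooperConfig(penalty=SMALL_CFG))

    def test_deterministic_replay(self):
        ds = small_competing_dataset(seed=5)
        cfg = CooperConfig(mt_max_iter=2, penalty=SMALL_CFG, seed=11)
        a = fit_cooper(ds, cfg)
        b = fit_cooper(ds, cfg)
        assert np.array_equal(a.fit_cause1.beta, b.fit_cause1.beta)
        assert np.array_equal(a.fit_cause2.beta, b.fit_cause2.beta)
        for (x1, x2), (y1, y2) in zip(a.history, b.history):
            assert np.array_equal(x1, y1) and np.array_equal(x2, y2)

    def test_all_zero_initials_collapse_to_plain_fits(self):
        # a lambda path that never releases any coefficient: every fit stays
        # null, so the exchanged score vectors are all-zero and iterations
        # reproduce the initial (null) fits
        ds = small_competing_dataset(seed=6)
        cfg = PenaltyConfig(alpha=1.0, nfolds=4,
                            lambda_path=np.array([50.0, 40.0, 30.0]))
        fit = fit_cooper(ds, CooperConfig(mt_max_iter=2, penalty=cfg, seed=2))
        assert np.all(fit.initial_fit_cause1.beta == 0.0)
        assert np.all(fit.fit_cause1.beta == 0.0)
        assert np.all(fit.fit_cause2.beta == 0.0)
        assert fit.converged  # null fits do not move


class TestExtractCoefficients:
    def test_unknown_cause_raises(self):
        ds = small_competing_dataset()
        fit = fit_cooper(ds, CooperConfig(mt_max_iter=0, penalty=SMALL_CFG))
        with pytest.raises(ValueError, match="cause"):
            extract_coefficients(fit, 3)

    def test_initial_equals_final_when_no_iterations(self):
        ds = small_competing_dataset()
        fit = fit_cooper(ds, CooperConfig(mt_max_iter=0, penalty=SMALL_CFG))
        assert extract_coefficients(fit, 1, True) == extract_coefficients(fit, 1, False)

    def test_sparse_map_contains_only_nonzeros(self):
        ds = small_competing_dataset(seed=7)
        fit = fit_cooper(ds, CooperConfig(mt_max_iter=1, penalty=SMALL_CFG, seed=3))
        coefs = extract_coefficients(fit, 1)
        assert all(v != 0.0 for v in coefs.values())
        assert set(coefs) <= set(ds.feature_names)

    def test_shared_selection_is_intersection(self):
        ds = small_competing_dataset(seed=8)
        fit = fit_cooper(ds, CooperConfig(mt_max_iter=1, penalty=SMALL_CFG, seed=3))
        s1 = set(extract_coefficients(fit, 1))
        s2 = set(extract_coefficients(fit, 2))
        assert set(shared_selection(fit)) == s1 & s2


class TestCooperOnStructuredData:
    """Scaled-down shared-effect recovery (block-structured competing risks)."""

    def test_shared_block_drives_selection(self):
        blocks = [BlockSpec("B1", 20, 0.3, [0.8] * 2, [0.8] * 2),
                  BlockSpec("B2", 20, 0.3)]
        cfg = HighDimConfig(n=250, blocks=blocks, n_uncorrelated_noise=20,
                            seed=123)
        sim = gen_highdim_dataset(cfg)
        fit = fit_cooper(sim.data, CooperConfig(
            mt_max_iter=2, penalty=PenaltyConfig(alpha=1.0, nfolds=5, n_lambda=40),
            seed=123))
        shared = shared_selection(fit)
        assert any(name.startswith("B1_") for name in shared)
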