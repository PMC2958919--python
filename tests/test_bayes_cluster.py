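import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import betaln
from sklearn.metrics import adjusted_rand_score

from aflpdelim.bayes_cluster import (
    BayesConfig,
    estimate_lnP,
    evanno_delta_k,
    fit_structure_model,
    pairwise_admixture,
    run_lnp_table,
)
from aflpdelim.io_formats import AFLPMatrix
from aflpdelim.synthetic_data import PopModel, simulate_aflp


def _matrix(values):
    values = np.asarray(values, dtype=np.int8)
    return AFLPMatrix([f"s{i}" for i in range(values.shape[0])],
                      [f"l{j}" for j in range(values.shape[1])], values)


def brute_force_log_marginal(values: np.ndarray, K: int) -> float:
    """Exact log P(X) of the no-admixture phenotype model by summation over
    all K^n cluster assignments with conjugate Beta integrals per marker."""
    n, L = values.shape
    obs = values >= 0
    total = -np.inf
    for assign in itertools.product(range(K), repeat=n):
        z = np.array(assign)
        lp = -n * np.log(K)
        for k in range(K):
            sub = values[z == k]
            sobs = sub >= 0
            n1 = ((sub == 1) & sobs).sum(axis=0)
            n0 = ((sub == 0) & sobs).sum(axis=0)
            lp += float((betaln(1 + n1, 1 + n0) - betaln(1, 1)).sum())
        total = np.logaddexp(total, lp)
    return float(total)


class TestEvidence:
    def test_estimate_hand_cases(self):
        assert estimate_lnP([5.0]) == 5.0
        assert estimate_lnP([0.0, 2.0]) == pytest.approx(0.5)
        assert estimate_lnP([3.0, 3.0, 3.0]) == 3.0

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            estimate_lnP([])

    def test_k1_matches_exact_conjugate_marginal(self):
        rng = np.random.default_rng(3)
        values = rng.integers(0, 2, (3, 4)).astype(np.int8)
        m = _matrix(values)
        n1 = values.sum(axis=0)
        n0 = 3 - n1
        exact = float((betaln(1 + n1, 1 + n0) - betaln(1, 1)).sum())
        cfg = BayesConfig(K=1, iterations=20_000, burn_in=2_000, thin=2,
                          runs=1, seed=1)
        _, trace, _ = fit_structure_model(m, cfg)
        assert abs(trace.lnp - exact) < 0.5

    def test_k2_matches_brute_force_marginal(self):
        rng = np.random.default_rng(8)
        values = rng.integers(0, 2, (4, 4)).astype(np.int8)
        values[0, 1] = -1  # missing cells are skipped in the likelihood
        exact = brute_force_log_marginal(values, K=2)
        cfg = BayesConfig(K=2, iterations=30_000, burn_in=3_000, thin=2,
                          runs=3, seed=2)
        _, trace, _ = fit_structure_model(_matrix(values), cfg)
        assert abs(trace.lnp - exact) < 0.5


class TestEvannoDeltaK:
    def test_linear_lnp_gives_zero(self):
        tab = {k: [-10.0 - 2 * k, -12.0 - 2 * k] for k in range(1, 5)}
        res = evanno_delta_k(tab)
        interior = res.table.dropna(subset=["delta_k"])
        assert (interior["delta_k"] == 0).all()

    def test_two_run_hand_table(self):
        # run-wise |L(3) - 2 L(2) + L(1)| = 5.5 in both runs; sd(L(2)) = sqrt(2)
        res = evanno_delta_k({1: [-10, -12], 2: [-4, -6], 3: [-3.5, -5.5]})
        dk2 = res.table.set_index("K").loc[2, "delta_k"]
        assert dk2 == pytest.approx(5.5 / np.sqrt(2.0), abs=1e-4)
        assert res.best_k == 2

    def test_zero_sd_flagged_and_excluded(self):
        res = evanno_delta_k({1: [-9, -10], 2: [-5, -5], 3: [-4, -4.5], 4: [-3, -4]})
        assert 2 in res.flagged
        assert res.best_k == 3

    def test_input_validation(self):
        with pytest.raises(ValueError, match="3 consecutive"):
            evanno_delta_k({1: [-1, -2], 2: [-1, -2]})
        with pytest.raises(ValueError, match="2 runs"):
            evanno_delta_k(pd.DataFrame({1: [-1.0], 2: [-1.0], 3: [-1.0]}))
        with pytest.raises(ValueError, match="consecutive"):
            evanno_delta_k({1: [-1, -2], 3: [-1, -2], 5: [-1, -2]})


class TestRecovery:
    def test_no_admixture_recovers_pure_populations(self):
        m, meta, truth = simulate_aflp(
            PopModel(K=2, L=200, F=0.5, n_per_pop=25, seed=5))
        cfg = BayesConfig(K=2, iterations=3_000, burn_in=500, thin=5,
                          runs=2, seed=2)
        _, _, part = fit_structure_model(m, cfg)
        assert adjusted_rand_score(truth.labels, part.labels) == 1.0

    def test_admixture_recovers_f1_hybrids(self, two_pop_hybrid_aflp):
        m, meta, truth = two_pop_hybrid_aflp
        cfg = BayesConfig(K=2, admixture=True, iterations=3_000, burn_in=500,
                          thin=5, runs=2, seed=3)
        ancestry, trace, part = fit_structure_model(m, cfg)
        hybrids = truth.q.max(axis=1) == 0.5
        assert np.all(np.abs(ancestry.q[hybrids] - 0.5) < 0.1)
        assert ancestry.q[~hybrids].max(axis=1).min() > 0.9

    def test_recessive_diploid_emission_recovers(self):
        m, meta, truth = simulate_aflp(
            PopModel(K=2, L=200, F=0.6, n_per_pop=15, seed=6))
        cfg = BayesConfig(K=2, iterations=2_000, burn_in=400, thin=5, runs=1,
                          emission="recessive-diploid", seed=4)
        _, _, part = fit_structure_model(m, cfg)
        assert adjusted_rand_score(truth.labels, part.labels) == 1.0

    def test_ancestry_rows_sum_to_one(self, two_pop_hybrid_aflp):
        m, _, _ = two_pop_hybrid_aflp
        cfg = BayesConfig.scaled_down(K=2, admixture=True, runs=1, seed=1,
                                      iterations=2_000, burn_in=400)
        ancestry, _, _ = fit_structure_model(m, cfg)
        assert np.allclose(ancestry.q.sum(axis=1), 1.0, atol=1e-9)


class TestPriorSampling:
    def test_zero_markers_reproduce_dirichlet_prior_moments(self):
        # with no data the admixture sampler must target Dirichlet(alpha):
        # mean 1/K and Var(q_k) = (K-1) / (K^2 (K alpha + 1))
        n, K, alpha = 12, 3, 0.7
        m = AFLPMatrix([f"s{i}" for i in range(n)], [],
                       np.zeros((n, 0), dtype=np.int8))
        cfg = BayesConfig(K=K, admixture=True, alpha=alpha, iterations=20_000,
                          burn_in=2_000, thin=4, runs=1, collect_q=True, seed=9)
        from aflpdelim import bayes_cluster as bc

        _, tr, _ = bc._chain(m.values.astype(np.int64), cfg,
                             np.random.default_rng(9))
        q_samples = tr.q_samples
        assert q_samples is not None
        flat = q_samples.reshape(-1, K)
        var_exp = (K - 1) / (K ** 2 * (K * alpha + 1))
        assert abs(flat.mean() - 1.0 / K) < 0.01
        assert abs(flat.var(axis=0).mean() - var_exp) < 0.15 * var_exp


class TestPairwiseAdmixture:
    def test_pure_populations_have_full_own_ancestry(self):
        m, meta, truth = simulate_aflp(
            PopModel(K=2, L=300, F=0.6, n_per_pop=12, seed=8))
        cfg = BayesConfig(K=2, admixture=True, iterations=3_000, burn_in=500,
                          thin=5, runs=2, seed=5)
        ancestry, report = pairwise_admixture(m, meta, "sp1", "sp2", cfg)
        assert report["own_cluster_ancestry"].min() >= 0.95

    def test_f1_hybrid_detected(self, two_pop_hybrid_aflp):
        m, meta, truth = two_pop_hybrid_aflp
        cfg = BayesConfig(K=2, admixture=True, iterations=3_000, burn_in=500,
                          thin=5, runs=2, seed=6)
        ancestry, report = pairwise_admixture(m, meta, "sp1", "sp2", cfg)
        hybrids = report["specimen_id"].str.startswith("sp1_2")  # hybrids got sp1 ids
        hyb = report.loc[report["specimen_id"].isin(
            [i for i, h in zip(m.specimen_ids, truth.q.max(axis=1) == 0.5) if h])]
        assert np.all(np.abs(hyb["own_cluster_ancestry"] - 0.5) < 0.1)
        others = report.loc[~report["specimen_id"].isin(hyb["specimen_id"])]
        assert others["own_cluster_ancestry"].min() >= 0.9

    def test_absent_species_rejected(self, two_pop_hybrid_aflp):
        m, meta, _ = two_pop_hybrid_aflp
        with pytest.raises(ValueError, match="absent"):
            pairwise_admixture(m, meta, "sp1", "nosuch",
                               BayesConfig.scaled_down(K=2, admixture=True, runs=1))

    def test_wrong_k_rejected(self, two_pop_hybrid_aflp):
        m, meta, _ = two_pop_hybrid_aflp
        with pytest.raises(ValueError, match="K = 2"):
            pairwise_admixture(m, meta, "sp1", "sp2",
                               BayesConfig(K=3, admixture=True))


class TestConfig:
    def test_invariants(self):
        with pytest.raises(ValueError):
            BayesConfig(K=0)
        with pytest.raises(ValueError):
            BayesConfig(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            BayesConfig(emission="diploid-codominant")

    def test_lnp_table_shape_and_determinism(self):
        m, _, _ = simulate_aflp(PopModel(K=2, L=60, F=0.5, n_per_pop=8, seed=3))
        cfg = BayesConfig(iterations=600, burn_in=100, thin=5, runs=2, seed=11)
        t1 = run_lnp_table(m, [1, 2, 3], cfg)
        t2 = run_lnp_table(m, [1, 2, 3], cfg)
        assert t1.shape == (2, 3)
        assert t1.equals(t2)
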