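"""Sampler contracts, harmonic means, Bayes factors, and the
enumerated partition space."""

import numpy as np
import pytest
from scipy.optimize import minimize

from traitcorr.bayesfactor import (best_of_replicates, bf_band,
                                   bf_from_odds_ratio, harmonic_mean_loglik,
                                   log_bayes_factor, prior_odds_model_space,
                                   visit_odds_bf)
from traitcorr.ctmc import TreeLikelihood, dual_tip_partials
from traitcorr.mcmc import McmcSettings, PosteriorSample, _MODELS, mcmc_run, rj_mcmc_run
from traitcorr.partitions import (bell_number, canonical_partition,
                                  count_model_space, is_independent_partition,
                                  iter_partitions, partition_string)
from traitcorr.phylo import TreeSample, parse_newick
from traitcorr.simulate import simulate_dual_pair, simulate_yule_tree
from traitcorr.ctmc import DependentRates

SMALL = McmcSettings(iterations=1000, burn_in=100, thinning=10, seed=3)


@pytest.fixture(scope="module")
def tiny_dataset():
    tree = simulate_yule_tree(12, 1.0, seed=5).rescale(3.0)
    rates = DependentRates(q12=5, q13=0.5, q21=1, q24=10, q31=1, q34=5, q42=1, q43=1)
    hab, morph = simulate_dual_pair(tree, rates, root=0, seed=8)
    return tree, dual_tip_partials(hab, morph)


class TestMcmcContracts:
    def test_retained_sample_count(self, tiny_dataset):
        tree, data = tiny_dataset
        run = mcmc_run("dependent", tree, data, SMALL)
        assert run.n_samples == 90
        assert run.rates.shape == (90, 8)
        lo, hi = SMALL.rate_prior_bounds
        assert run.rates.min() >= lo and run.rates.max() <= hi

    def test_same_seed_identical_runs(self, tiny_dataset):
        tree, data = tiny_dataset
        a = mcmc_run("independent", tree, data, SMALL)
        b = mcmc_run("independent", tree, data, SMALL)
        assert np.array_equal(a.lnl, b.lnl)
        assert np.array_equal(a.rates, b.rates)
        c = mcmc_run("independent", tree, data, SMALL.with_seed(4))
        assert not np.array_equal(a.lnl, c.lnl)

    def test_settings_invariants_enforced(self):
        with pytest.raises(ValueError):
            McmcSettings(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            McmcSettings(thinning=0)
        with pytest.raises(ValueError):
            McmcSettings(rate_prior_bounds=(5, 2))

    def test_empty_data_rejected(self, tiny_dataset):
        tree, _ = tiny_dataset
        with pytest.raises(ValueError):
            mcmc_run("dependent", tree, {}, SMALL)

    def test_tree_sample_uniform_sampling(self, tiny_dataset):
        tree, data = tiny_dataset
        trees = TreeSample([tree, tree.rescale(1.5)])
        s = McmcSettings(iterations=2000, burn_in=200, thinning=10, seed=1,
                         tree_sampling="uniform")
        run = mcmc_run("dependent", trees, data, s)
        assert set(np.unique(run.tree_indices)) == {0, 1}

    def test_restricted_nested_in_dependent(self, tiny_dataset):
        tree, data = tiny_dataset
        ev = TreeLikelihood(tree, data, 4)
        # the restricted parameterisation maps into the dependent one
        rng = np.random.default_rng(0)
        for _ in range(5):
            theta = rng.uniform(0, 10, 7)
            q_r = _MODELS["restricted"][1](theta)
            expanded = np.array([theta[0], theta[0], theta[1], theta[2],
                                 theta[3], theta[4], theta[5], theta[6]])
            q_d = _MODELS["dependent"][1](expanded)
            assert np.allclose(q_r, q_d)
        # hence the maximised restricted likelihood cannot exceed the full one

        def neg(model):
            names, build_q, _ = _MODELS[model]
            best = -np.inf
            for s in range(3):
                x0 = np.random.default_rng(s).uniform(0.5, 8, len(names))
                r = minimize(lambda x: -ev.loglik(build_q(np.clip(x, 1e-6, 100))),
                             x0, method="Nelder-Mead", options={"maxiter": 1500})
                best = max(best, -r.fun)
            return best
        assert neg("restricted") <= neg("dependent") + 1e-6


class TestRjMcmc:
    def test_determinism_and_flags(self, tiny_dataset):
        tree, data = tiny_dataset
        a = rj_mcmc_run(tree, data, SMALL)
        b = rj_mcmc_run(tree, data, SMALL)
        assert np.array_equal(a.lnl, b.lnl)
        assert a.partitions == b.partitions
        assert a.visits_independent == b.visits_independent
        assert a.visits_independent <= a.n_samples
        for part, flag in zip(a.partitions, a.is_independent):
            assert is_independent_partition(part) == flag

    def test_strong_dependence_rarely_visits_independent(self):
        tree = simulate_yule_tree(64, 1.0, seed=3).rescale(4.0)
        rates = DependentRates(q12=5, q13=0.5, q21=1, q24=10, q31=1,
                               q34=5, q42=1, q43=1)
        hab, morph = simulate_dual_pair(tree, rates, root=0, seed=11)
        s = McmcSettings(iterations=12000, burn_in=2000, thinning=5, seed=5)
        run = rj_mcmc_run(tree, dual_tip_partials(hab, morph), s)
        assert run.visits_independent / run.n_samples < 0.5

    def test_trace_serialisation(self, tiny_dataset, tmp_path):
        tree, data = tiny_dataset
        run = rj_mcmc_run(tree, data, SMALL)
        path = tmp_path / "trace.tsv"
        run.to_tsv(path)
        header = path.read_text().splitlines()[0].split("\t")
        assert header[:2] == ["sample", "lnl"]
        assert "partition" in header and "is_independent" in header


class TestPartitions:
    def test_bell_numbers_match_enumeration(self):
        for n in range(1, 9):
            assert sum(1 for _ in iter_partitions(n)) == bell_number(n)

    def test_model_space_counts(self):
        total, indep = count_model_space(False)
        assert total == bell_number(8) == 4140
        assert indep == bell_number(4) == 15
        assert prior_odds_model_space(False) == pytest.approx(275.0)

    def test_zero_class_model_space(self):
        total, indep = count_model_space(True)
        assert total == bell_number(9) == 21147   # sum_k C(8,k) Bell(8-k)
        assert indep == bell_number(5) == 52
        assert prior_odds_model_space(True) == pytest.approx((21147 - 52) / 52)

    def test_canonical_and_string_forms(self):
        a = canonical_partition([3, 3, 7, 7, 3, -1, 9, 9])
        assert a == (0, 0, 2, 2, 0, -1, 6, 6)
        s = partition_string(a)
        assert s.startswith("Z{q34}") or "Z{q34}" in s
        assert "{q12,q13,q31}" in s

    def test_independence_is_structural(self):
        # the four forced pairs merged into one class per trait-direction
        indep = [0, 1, 2, 1, 3, 0, 3, 2]  # q12=q34, q13=q24, q21=q43, q31=q42
        assert is_independent_partition(indep)
        dep = [0, 1, 2, 1, 3, 0, 3, 4]
        assert not is_independent_partition(dep)
        assert is_independent_partition([-1] * 8)


class TestHarmonicMeanAndBf:
    def test_constant_samples(self):
        assert harmonic_mean_loglik([-3.7] * 50) == pytest.approx(-3.7, abs=1e-12)

    def test_two_point_hand_computation(self):
        got = harmonic_mean_loglik([np.log(1.0), np.log(3.0)])
        assert got == pytest.approx(np.log(1.5), abs=1e-12)

    def test_permutation_invariance_and_direct_formula(self):
        rng = np.random.default_rng(1)
        lnl = rng.normal(-40, 2, 100)
        direct = np.log(len(lnl) / np.sum(1.0 / np.exp(lnl + 40))) - 40
        assert harmonic_mean_loglik(lnl) == pytest.approx(direct, abs=1e-12)
        assert harmonic_mean_loglik(np.flip(lnl)) == pytest.approx(
            harmonic_mean_loglik(lnl), abs=1e-14)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            harmonic_mean_loglik([])

    def test_bf_definition_and_bands(self):
        res = log_bayes_factor(-10.0, -10.0)
        assert res.bf == 0.0 and res.band == "none"
        assert bf_band(3.0) == "positive" and bf_band(6.0) == "strong"
        assert bf_band(-4.0) == "none"
        with pytest.raises(ValueError):
            log_bayes_factor(np.inf, -1.0)

    def test_best_of_replicates_max_and_tie_rule(self):
        def fake(hm, seed):
            return PosteriorSample(model="dependent", lnl=np.full(10, hm),
                                   rates=np.zeros((10, 8)),
                                   rate_names=("q",) * 8, settings=SMALL,
                                   seed=seed, acceptance_rate=0.2)
        runs = [fake(-43.94, 1), fake(-43.65, 2), fake(-44.10, 3)]
        assert best_of_replicates(runs).seed == 2
        assert best_of_replicates([runs[0]]) is runs[0]
        tied = [fake(-10.0, 2), fake(-10.0, 1)]
        assert best_of_replicates(tied).seed == 1
        with pytest.raises(ValueError):
            best_of_replicates([])


class TestVisitOdds:
    @staticmethod
    def rj_stub(total, vi):
        flags = np.zeros(total, dtype=bool)
        flags[:vi] = True
        return PosteriorSample(model="rj", lnl=np.zeros(total),
                               rates=np.zeros((total, 8)), rate_names=("q",) * 8,
                               settings=SMALL, seed=0, acceptance_rate=0.2,
                               partitions=[()] * total, is_independent=flags)

    def test_posterior_odds_from_counts(self):
        s = visit_odds_bf(self.rj_stub(20000, 4), prior_odds=275.0)
        assert s.posterior_odds == pytest.approx(4999.0)
        assert s.odds_ratio == pytest.approx(4999.0 / 275.0)
        assert s.bf == pytest.approx(bf_from_odds_ratio(4999.0 / 275.0))

    def test_na_propagation_when_no_independent_visits(self):
        s = visit_odds_bf(self.rj_stub(20000, 0), prior_odds=275.0)
        assert s.not_applicable
        assert s.posterior_odds is None and s.bf is None

    def test_unit_odds_ratio_is_zero_evidence(self):
        assert bf_from_odds_ratio(1.0) == 0.0
        with pytest.raises(ValueError):
            bf_from_odds_ratio(0.0)
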