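"""Adaptive-testing engine: selection rules, stopping, cohort simulation."""

import numpy as np
import pytest

from epdscat import (
    CATConfig,
    ItemBank,
    LatentModel,
    QuadratureGrid,
    check_termination,
    eap_score,
    run_cat_for_patient,
    select_next_item,
    simulate_cohort,
)
from epdscat.grm import information_trace_profile, response_loglik
from epdscat.score import TraitEstimate

from conftest import item_matrix


def three_item_bank():
    slopes = np.array([[1.2], [2.5], [0.8]])
    d = np.array([[1.0, -0.5, -2.0], [0.5, -1.0, -2.5], [2.0, 0.0, -1.5]])
    return ItemBank(slopes, d, [0, 0, 0], si_item=2)


class TestSelection:
    def test_tie_breaks_to_lowest_index(self):
        slopes = np.array([[1.5], [1.5]])
        d = np.array([[0.5, -0.5, -1.5], [0.5, -0.5, -1.5]])
        bank = ItemBank(slopes, d, [0, 0], si_item=1)
        assert select_next_item(bank, [0, 1], rule="MI", theta=[0.0]) == 0
        assert select_next_item(bank, [1, 0], rule="MI", theta=[0.0]) == 0

    def test_dominating_item_wins_under_every_rule(self):
        # same thresholds, much larger slope -> uniformly more information
        slopes = np.array([[1.0], [3.0], [1.2]])
        d = np.array([[0.5, -0.5, -1.5]] * 3)
        bank = ItemBank(slopes, d, [0, 0, 0], si_item=2)
        latent = LatentModel(1)
        grid = QuadratureGrid.build(latent)
        assert select_next_item(bank, [0, 1, 2], rule="MI", theta=[0.0]) == 1
        assert select_next_item(bank, [0, 1, 2], rule="trace", theta=[-1.0]) == 1
        post = np.full(grid.n_nodes, 1.0 / grid.n_nodes)
        assert select_next_item(bank, [0, 1, 2], rule="MPWI", posterior=post, grid=grid) == 1

    def test_mpwi_matches_fine_grid_integration(self):
        bank = three_item_bank()
        latent = LatentModel(1)
        grid = QuadratureGrid.build(latent)
        # observe item 1 = category 2; posterior over theta
        pattern = np.array([-1, 2, -1])
        ll = response_loglik(bank, pattern, grid.nodes)
        post = np.exp(ll) * grid.weights
        post /= post.sum()
        choice = select_next_item(bank, [0, 2], rule="MPWI", posterior=post, grid=grid)

        # brute-force oracle on a dense grid
        t = np.linspace(-8, 8, 20001)[:, None]
        dense_post = np.exp(response_loglik(bank, pattern, t)) * np.exp(-0.5 * t[:, 0] ** 2)
        dense_post /= dense_post.sum()
        info = information_trace_profile(bank, t)
        scores = dense_post @ info
        oracle = [0, 2][int(np.argmax(scores[[0, 2]]))]
        assert choice == oracle

    def test_empty_available_raises(self):
        with pytest.raises(ValueError):
            select_next_item(three_item_bank(), [], rule="MI", theta=[0.0])


class TestTermination:
    def _traj(self, *vals):
        return [TraitEstimate(np.array([v]), np.array([0.5]), i + 1) for i, v in enumerate(vals)]

    def test_small_change_stops(self):
        cfg = CATConfig(termination_delta=0.05)
        assert check_termination(self._traj(0.30, 0.27), cfg, 10)

    def test_large_change_continues(self):
        cfg = CATConfig(termination_delta=0.05)
        assert not check_termination(self._traj(0.5, 0.6), cfg, 10)

    def test_bank_exhaustion_stops(self):
        cfg = CATConfig(termination_delta=0.001)
        traj = self._traj(*np.linspace(0, 2, 10))
        assert check_termination(traj, cfg, 10)

    def test_min_items_respected(self):
        cfg = CATConfig(termination_delta=0.5, min_items=4)
        assert not check_termination(self._traj(0.1, 0.1), cfg, 10)
        assert check_termination(self._traj(0.1, 0.1, 0.1, 0.1), cfg, 10)


class TestCohortSimulation:
    def test_infinite_delta_administers_exactly_min_items(self, bank1, latent1, cohort1):
        X = item_matrix(cohort1)[:100]
        for m in (2, 3):
            cfg = CATConfig(termination_delta=np.inf, min_items=m)
            results, _ = simulate_cohort(X, bank1, latent1, cfg)
            assert all(r.n_administered == m for r in results)

    def test_full_length_reproduces_full_test_eap(self, bank1, latent1, grid1, cohort1):
        X = item_matrix(cohort1)[:40]
        cfg = CATConfig(min_items=10, max_items=10, shrinkage_correction=False)
        results, _ = simulate_cohort(X, bank1, latent1, cfg)
        for row, res in zip(X, results):
            full = eap_score(bank1, latent1, row, grid1)
            assert res.final_estimate.theta_hat[0] == pytest.approx(full.theta_hat[0], abs=1e-10)
            assert res.final_estimate.posterior_sd[0] == pytest.approx(
                full.posterior_sd[0], abs=1e-10
            )

    def test_no_repeats_and_responses_faithful(self, bank1, latent1, cohort1):
        X = item_matrix(cohort1)[:200]
        results, _ = simulate_cohort(X, bank1, latent1)
        for row, res in zip(X, results):
            assert len(set(res.administered)) == res.n_administered
            assert res.responses_seen == [int(row[i]) for i in res.administered]
            assert len(res.trajectory) == res.n_administered
            assert 0 <= res.expected_total <= 30

    def test_monotone_burden_in_delta(self, bank1, latent1, cohort1):
        X = item_matrix(cohort1)[:100]
        counts = {}
        for delta in (0.1, 0.05, 0.025):
            res, _ = simulate_cohort(X, bank1, latent1, CATConfig(termination_delta=delta))
            counts[delta] = np.array([r.n_administered for r in res])
        assert np.all(counts[0.05] >= counts[0.1])
        assert np.all(counts[0.025] >= counts[0.05])

    def test_identical_records_get_identical_results(self, bank1, latent1):
        row = np.array([1, 0, 2, 1, 0, 1, 0, 0, 1, 0])
        X = np.tile(row, (5, 1))
        results, _ = simulate_cohort(X, bank1, latent1)
        first = results[0]
        for r in results[1:]:
            assert r.administered == first.administered
            assert r.expected_total == pytest.approx(first.expected_total)

    def test_order_independence(self, bank1, latent1, cohort1):
        X = item_matrix(cohort1)[:60]
        perm = np.random.default_rng(1).permutation(60)
        res_a, _ = simulate_cohort(X, bank1, latent1, CATConfig(shrinkage_correction=False))
        res_b, _ = simulate_cohort(X[perm], bank1, latent1, CATConfig(shrinkage_correction=False))
        for i, j in enumerate(perm):
            assert res_b[i].administered == res_a[j].administered
            assert res_b[i].expected_total == pytest.approx(res_a[j].expected_total)

    def test_si_force_administration(self, bank1, latent1, cohort1):
        X = item_matrix(cohort1)[:100]
        cfg = CATConfig(si_always_administered=True)
        results, _ = simulate_cohort(X, bank1, latent1, cfg)
        assert all(bank1.si_item in r.administered for r in results)
        plain, _ = simulate_cohort(X, bank1, latent1)
        assert not all(bank1.si_item in r.administered for r in plain)

    def test_single_patient_api_matches_engine(self, bank1, latent1, cohort1):
        X = item_matrix(cohort1)[:10]
        cohort_res, _ = simulate_cohort(
            X, bank1, latent1, CATConfig(shrinkage_correction=False)
        )
        for row, ref in zip(X, cohort_res):
            solo = run_cat_for_patient(row, bank1, latent1)
            assert solo.administered == ref.administered
            assert solo.expected_total == pytest.approx(ref.expected_total)

    def test_incomplete_record_rejected(self, bank1, latent1):
        rec = np.array([1.0, np.nan, 0, 1, 0, 1, 0, 0, 1, 0])
        with pytest.raises(ValueError, match="incomplete"):
            run_cat_for_patient(rec, bank1, latent1)

    def test_multidimensional_trace_rule_runs(self):
        from epdscat import CohortSpec, generate_cohort, generate_item_bank
        from epdscat.synth import default_corr

        bank = generate_item_bank(3, seed=2)
        corr = default_corr(3)
        spec = CohortSpec(n=150, dimension=3, seed=2)
        X = item_matrix(generate_cohort(spec, bank))
        results, summary = simulate_cohort(X, bank, LatentModel(3, corr))
        assert summary.min_items >= 2
        assert all(len(set(r.administered)) == r.n_administered for r in results)
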