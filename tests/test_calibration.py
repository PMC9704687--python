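"""Fixed-parameter EM calibration: E-step, M-step, weights, full driver."""

import numpy as np
import pytest
from scipy.optimize import minimize

from scorelink import (
    GRMItem,
    ResponseMatrix,
    ThetaGrid,
    e_step,
    fixed_parameter_calibrate,
    m_step_item,
    marginal_loglik,
    update_latent_weights,
    category_prob,
    make_linking_fixture,
    development_population,
)
from scorelink.calibrate import (
    AnchoringError,
    CalibrationConfig,
    LinkageError,
    collapse_empty_categories,
    expected_item_loglik,
)
from scorelink.grm import MISSING


class TestEStep:
    def test_flat_likelihood_returns_prior(self, grid49):
        item = GRMItem("flat", 1e-6, (0.0,))
        resp = ResponseMatrix(np.array([[1]]), ("flat",))
        post, _ = e_step(resp, [item], grid49)
        np.testing.assert_allclose(post[0], grid49.weights, atol=1e-7)

    def test_single_grid_point_gets_all_mass(self):
        grid = ThetaGrid(np.array([0.3]), np.array([1.0]))
        item = GRMItem("i", 2.0, (0.0,))
        resp = ResponseMatrix(np.array([[1], [0]]), ("i",))
        post, _ = e_step(resp, [item], grid)
        np.testing.assert_allclose(post, 1.0)

    def test_toy_posteriors_match_hand_bayes(self, toy_responses):
        resp, items = toy_responses
        grid = ThetaGrid(np.array([-1.0, 0.0, 1.0]), np.array([0.25, 0.5, 0.25]))
        post, counts = e_step(resp, items, grid)
        # independent enumeration: likelihood x prior, normalized, plain loops
        for i in range(3):
            lik = []
            for q, th in enumerate(grid.points):
                p = 1.0
                for j, it in enumerate(items):
                    p *= category_prob(it, th)[resp.values[i, j]]
                lik.append(p * grid.weights[q])
            lik = np.array(lik) / np.sum(lik)
            np.testing.assert_allclose(post[i], lik, atol=1e-12)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_expected_counts_sum_to_observed(self, bsi_8a, grid49, rng):
        vals = np.array(
            [[int(rng.integers(0, it.n_categories)) for it in bsi_8a] for _ in range(40)]
        )
        vals[:7, 2] = MISSING
        resp = ResponseMatrix(vals, tuple(it.item_id for it in bsi_8a))
        _, counts = e_step(resp, bsi_8a, grid49)
        for j, it in enumerate(bsi_8a):
            n_obs = int(np.sum(vals[:, j] != MISSING))
            assert counts[it.item_id].sum() == pytest.approx(n_obs, abs=1e-8)


class TestMStep:
    def test_stationary_at_generating_parameters(self, grid49):
        start = GRMItem("g", 2.0, (-0.5, 0.8))
        # expected counts generated exactly from the model at the start values
        counts = 1000.0 * grid49.weights[None, :] * category_prob(start, grid49.points).T
        out = m_step_item(counts, grid49, start)
        assert out.slope == pytest.approx(2.0, abs=2e-3)
        np.testing.assert_allclose(out.thresholds, (-0.5, 0.8), atol=2e-3)

    def test_recovers_from_distant_start(self, grid49):
        truth = GRMItem("g", 2.0, (0.0, 1.0))
        counts = 5000.0 * grid49.weights[None, :] * category_prob(truth, grid49.points).T
        start = GRMItem("g", 1.0, (-1.0, 0.2))
        out = m_step_item(counts, grid49, start)
        assert out.slope == pytest.approx(2.0, abs=0.01)
        np.testing.assert_allclose(out.thresholds, (0.0, 1.0), atol=0.01)

    def test_monotone_ascent_on_real_counts(self, bsi_8a, grid49, rng):
        vals = np.array(
            [[int(rng.integers(0, it.n_categories)) for it in bsi_8a] for _ in range(60)]
        )
        resp = ResponseMatrix(vals, tuple(it.item_id for it in bsi_8a))
        _, counts = e_step(resp, bsi_8a, grid49)
        start = bsi_8a[3].replace(slope=1.0, thresholds=(-0.5, 0.0, 0.5, 1.0))
        out = m_step_item(counts["BSI_D4"], grid49, start)
        assert expected_item_loglik(out, counts["BSI_D4"], grid49) >= expected_item_loglik(
            start, counts["BSI_D4"], grid49
        )
        assert np.all(np.diff(out.thresholds) > 0)

    def test_fixed_item_rejected(self, grid49):
        item = GRMItem("a", 1.0, (0.0,), fixed=True)
        with pytest.raises(ValueError, match="fixed"):
            m_step_item(np.ones((2, 49)), grid49, item)


class TestWeightUpdate:
    def test_single_row(self):
        grid = ThetaGrid(np.array([-1.0, 1.0]), np.array([0.5, 0.5]))
        got = update_latent_weights(np.array([[0.2, 0.8]]), grid)
        np.testing.assert_allclose(got.weights, [0.2, 0.8])

    def test_two_person_average(self):
        grid = ThetaGrid(np.array([-1.0, 1.0]), np.array([0.5, 0.5]))
        got = update_latent_weights(np.array([[1.0, 0.0], [0.0, 1.0]]), grid)
        np.testing.assert_allclose(got.weights, [0.5, 0.5])

    def test_random_table_column_means(self, rng):
        grid = ThetaGrid.equally_spaced(21, -4, 4)
        raw = rng.random((50, 21))
        post = raw / raw.sum(axis=1, keepdims=True)
        got = update_latent_weights(post, grid)
        np.testing.assert_allclose(got.weights, post.mean(axis=0), atol=1e-12)

    def test_empty_table_rejected(self, grid49):
        with pytest.raises(ValueError):
            update_latent_weights(np.empty((0, 49)), grid49)


class TestCalibrate:
    def test_anchor_only_dataset_updates_weights_only(self, anchors, rng):
        thetas = rng.normal(size=150)
        from scorelink import simulate_responses

        resp = simulate_responses(thetas, anchors, seed=5)
        res = fixed_parameter_calibrate(resp, anchors)
        assert res.items == anchors  # byte-identical anchors, nothing estimated
        assert not np.allclose(res.latent_weights.weights, ThetaGrid.equally_spaced().weights)

    def test_no_fixed_items_is_anchoring_error(self, bsi_8a):
        resp = ResponseMatrix(np.zeros((5, 6), dtype=int), tuple(i.item_id for i in bsi_8a))
        with pytest.raises(AnchoringError):
            fixed_parameter_calibrate(resp, bsi_8a)

    def test_disjoint_administration_is_linkage_error(self):
        items = [GRMItem("a", 1.0, (0.0,), fixed=True), GRMItem("f", 1.0, (0.0,))]
        vals = np.array([[0, MISSING], [1, MISSING], [MISSING, 1], [MISSING, 0]])
        resp = ResponseMatrix(vals, ("a", "f"))
        with pytest.raises(LinkageError):
            fixed_parameter_calibrate(resp, items)

    def test_determinism(self):
        fx = make_linking_fixture(spec=development_population(seed=7, n_persons=150))
        cfg = CalibrationConfig(max_cycles=25, compute_se=False)
        r1 = fixed_parameter_calibrate(fx.responses, fx.items, config=cfg)
        r2 = fixed_parameter_calibrate(fx.responses, fx.items, config=cfg)
        assert r1.items == r2.items
        np.testing.assert_array_equal(r1.loglik_trace, r2.loglik_trace)
        np.testing.assert_array_equal(r1.latent_weights.weights, r2.latent_weights.weights)

    def test_em_monotone_and_anchors_immutable(self):
        fx = make_linking_fixture(spec=development_population(seed=11, n_persons=250))
        res = fixed_parameter_calibrate(
            fx.responses, fx.items, config=CalibrationConfig(max_cycles=60, compute_se=False)
        )
        assert np.all(np.diff(res.loglik_trace) >= -1e-6)
        fitted = {it.item_id: it for it in res.items}
        for it in fx.anchor_items:
            assert fitted[it.item_id] == it

    def test_all_missing_persons_dropped(self, anchors):
        from scorelink import simulate_responses

        resp = simulate_responses(np.zeros(10), anchors, seed=3)
        vals = np.array(resp.values)
        vals[4] = MISSING
        resp = ResponseMatrix(vals, resp.item_ids)
        res = fixed_parameter_calibrate(resp, anchors)
        assert res.n_persons_dropped == 1
        assert res.n_persons_used == 9

    def test_agrees_with_direct_mml_oracle(self):
        """EM solution matches an independent direct optimization of the
        marginal likelihood (no EM, scipy on the raw objective)."""
        items = [
            GRMItem("anchor", 1.8, (-0.8, 0.6), fixed=True),
            GRMItem("free1", 1.3, (-0.4, 0.9)),
            GRMItem("free2", 2.2, (0.1, 1.2)),
        ]
        fx = make_linking_fixture(
            anchor_items=[items[0]],
            legacy_items=items[1:],
            spec=development_population(seed=3, n_persons=300),
        )
        grid = ThetaGrid.equally_spaced(31, -4, 4)
        cfg = CalibrationConfig(update_weights=False, compute_se=False, max_cycles=400)
        em = fixed_parameter_calibrate(fx.responses, fx.items, grid, cfg)

        def unpack(x):
            out = []
            for i in range(2):
                a = np.exp(x[3 * i])
                b1 = x[3 * i + 1]
                b2 = b1 + np.exp(x[3 * i + 2])
                out.append(items[i + 1].replace(slope=a, thresholds=(b1, b2)))
            return [items[0]] + out

        def neg_ll(x):
            return -marginal_loglik(fx.responses, unpack(x), grid)

        x0 = np.array([np.log(1.3), -0.4, np.log(1.3), np.log(2.2), 0.1, np.log(1.1)])
        direct = minimize(neg_ll, x0, method="Nelder-Mead",
                          options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000})
        ref = unpack(direct.x)
        for em_it, ref_it in zip(em.free_items, ref[1:]):
            assert em_it.slope == pytest.approx(ref_it.slope, abs=0.05)
            np.testing.assert_allclose(em_it.thresholds, ref_it.thresholds, atol=0.05)


class TestCollapse:
    def test_empty_category_merged_and_mapped(self):
        item = GRMItem("f", 2.0, (0.0, 1.0, 2.0))  # K=4, category 3 never endorsed
        vals = np.array([[0], [1], [2], [2], [1]])
        resp = ResponseMatrix(vals, ("f",))
        with pytest.warns(UserWarning, match="collapsed"):
            new_resp, new_items, maps = collapse_empty_categories(resp, [item])
        assert maps["f"] == {0: 0, 1: 1, 2: 2, 3: 2}
        assert new_items[0].n_categories == 3
        np.testing.assert_array_equal(new_resp.values, vals)

    def test_full_data_untouched(self, bsi_8a):
        # every category of every item endorsed at least once -> no recode
        vals = np.vstack([np.tile(np.arange(5), (6, 1)).T, np.zeros((1, 6), dtype=int)])
        resp = ResponseMatrix(vals.astype(int), tuple(i.item_id for i in bsi_8a))
        new_resp, new_items, maps = collapse_empty_categories(resp, bsi_8a)
        assert maps == {}
        assert new_items == list(bsi_8a)
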