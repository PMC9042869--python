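import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plvcpm.cpm import (
    CpmModel,
    PredictiveNetwork,
    ScaleParams,
    StrengthFeatures,
    apply_edge_standardization,
    edge_score_correlations,
    equivalent_scale_params,
    features_from_strengths,
    fit_edge_standardization,
    fit_svr,
    network_strength,
    predict_scores,
    select_edges,
    standardize_scores,
    strength_matrix,
    unstandardize_scores,
)

# Printed training-distribution parameters used for the exact worked values.
TRAIN_PARAMS = ScaleParams("BDI", mean=9.5207, sd=10.5064, range_max=63.0)


class TestScoreStandardization:
    def test_printed_z_at_zero(self):
        # z(BDI=0) with mean 9.5207, SD 10.5064 -> -0.9062 (printed rounding)
        z = standardize_scores(0.0, TRAIN_PARAMS)
        assert z == pytest.approx(-0.9062, abs=5e-5)

    def test_centering_and_unit_scale(self):
        assert standardize_scores(TRAIN_PARAMS.mean, TRAIN_PARAMS) == pytest.approx(0.0)
        assert standardize_scores(
            TRAIN_PARAMS.mean + TRAIN_PARAMS.sd, TRAIN_PARAMS
        ) == pytest.approx(1.0)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            ScaleParams("BDI", 5.0, 0.0, 63.0)

    @given(st.floats(0, 63))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_inverse(self, raw):
        z = standardize_scores(raw, TRAIN_PARAMS)
        assert unstandardize_scores(z, TRAIN_PARAMS) == pytest.approx(raw, abs=1e-10)


class TestEquivalentScaleParams:
    def test_mean_rescaled(self):
        eq = equivalent_scale_params(TRAIN_PARAMS, 52.0, scale="HDRS")
        assert eq.mean == pytest.approx(9.5207 * 52 / 63)
        assert eq.mean == pytest.approx(7.8583, abs=1e-4)

    def test_sd_rescaled(self):
        eq = equivalent_scale_params(TRAIN_PARAMS, 52.0)
        assert eq.sd == pytest.approx(10.5064 * 52 / 63)
        assert eq.sd == pytest.approx(8.6720, abs=1e-4)

    def test_identity_at_same_range(self):
        eq = equivalent_scale_params(TRAIN_PARAMS, 63.0)
        assert eq.mean == TRAIN_PARAMS.mean and eq.sd == TRAIN_PARAMS.sd

    def test_z_at_scale_floor_preserved(self):
        # z(HDRS=0) under equivalent params equals z(BDI=0) under source params
        eq = equivalent_scale_params(TRAIN_PARAMS, 52.0, scale="HDRS")
        assert standardize_scores(0.0, eq) == pytest.approx(
            standardize_scores(0.0, TRAIN_PARAMS), abs=1e-12
        )

    def test_nonpositive_range(self):
        with pytest.raises(ValueError):
            equivalent_scale_params(TRAIN_PARAMS, 0.0)


class TestEdgeStandardization:
    def test_two_point_case(self):
        std = fit_edge_standardization(np.array([[0.2], [0.4]]))
        assert std.means[0] == pytest.approx(0.3)
        assert std.sds[0] == pytest.approx(np.std([0.2, 0.4], ddof=1))

    def test_degenerate_edge_flagged(self):
        std = fit_edge_standardization(np.array([[0.5, 0.1], [0.5, 0.2], [0.5, 0.3]]))
        assert std.degenerate[0] and not std.degenerate[1]

    def test_self_standardization(self, rng):
        x = rng.random((10, 6))
        std = fit_edge_standardization(x)
        z = apply_edge_standardization(x, std)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_frozen_application_hand_case(self):
        # 3 subjects x 2 edges, verified against direct arithmetic
        x = np.array([[0.1, 0.5], [0.2, 0.5], [0.6, 0.8]])
        std = fit_edge_standardization(x)
        new = np.array([0.3, 0.6])
        z = apply_edge_standardization(new, std)
        expected = (new - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        np.testing.assert_allclose(z, expected)

    def test_mean_vector_maps_to_zero(self, rng):
        x = rng.random((8, 5))
        std = fit_edge_standardization(x)
        np.testing.assert_allclose(
            apply_edge_standardization(x.mean(axis=0), std), 0.0, atol=1e-12
        )

    def test_degenerate_maps_to_zero(self):
        std = fit_edge_standardization(np.array([[0.5], [0.5]]))
        assert apply_edge_standardization(np.array([0.9]), std)[0] == 0.0

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            fit_edge_standardization(np.array([[0.2, 0.3]]))

    def test_dimension_mismatch(self):
        std = fit_edge_standardization(np.random.default_rng(0).random((4, 3)))
        with pytest.raises(ValueError):
            apply_edge_standardization(np.zeros(5), std)


class TestSelectEdges:
    def test_planted_strong_edge_selected(self, rng):
        n, m = 100, 50
        z_scores = rng.normal(size=n)
        edges = rng.normal(size=(n, m))
        edges[:, 7] = 0.9 * z_scores + np.sqrt(1 - 0.81) * rng.normal(size=n)
        net = select_edges(edges, z_scores, q=0.01)
        assert 7 in net.pos_edges

    def test_negated_scores_swap_tails(self, rng):
        n, m = 80, 40
        z = rng.normal(size=n)
        edges = rng.normal(size=(n, m))
        edges[:, 3] += 1.5 * z
        edges[:, 9] -= 1.5 * z
        net = select_edges(edges, z, q=0.01)
        flipped = select_edges(edges, -z, q=0.01)
        assert net.pos_edges == flipped.neg_edges
        assert net.neg_edges == flipped.pos_edges

    def test_constant_scores_rejected(self, rng):
        with pytest.raises(ValueError):
            select_edges(rng.random((10, 5)), np.ones(10))

    def test_constant_edge_never_selected(self, rng):
        n = 50
        z = rng.normal(size=n)
        edges = rng.normal(size=(n, 5))
        edges[:, 2] = 0.7
        net = select_edges(edges, z, q=0.5)
        assert 2 not in net.pos_edges | net.neg_edges

    def test_affine_edge_rescaling_invariance(self, rng):
        n = 60
        z = rng.normal(size=n)
        edges = rng.normal(size=(n, 20))
        edges[:, 4] += 2 * z
        net1 = select_edges(edges, z, q=0.01)
        scaled = edges.copy()
        scaled[:, 4] = 5.0 * scaled[:, 4] + 3.0
        net2 = select_edges(scaled, z, q=0.01)
        assert net1 == net2

    def test_partial_selection_removes_covariate_driven_edge(self, rng):
        n = 200
        cov = rng.normal(size=n)
        z = 0.8 * cov + 0.2 * rng.normal(size=n)
        edges = rng.normal(size=(n, 30))
        edges[:, 0] = cov + 0.1 * rng.normal(size=n)  # edge driven by covariate only
        plain = select_edges(edges, z, q=0.01)
        partial = select_edges(edges, z, q=0.01, covariates=cov)
        assert 0 in plain.pos_edges
        assert 0 not in partial.pos_edges | partial.neg_edges

    def test_too_few_subjects(self, rng):
        with pytest.raises(ValueError):
            select_edges(rng.random((3, 5)), rng.normal(size=3))


class TestStrengthFeatures:
    def test_single_pos_edge(self):
        net = PredictiveNetwork(pos_edges={1})
        z = np.array([0.0, 2.0, -1.0])
        sf = network_strength(z, net)
        assert (sf.pos_strength, sf.neg_strength, sf.summed_index) == (2.0, 0.0, 2.0)

    def test_arithmetic(self):
        net = PredictiveNetwork(pos_edges={0, 1}, neg_edges={2})
        sf = network_strength(np.array([1.5, 0.5, 1.0]), net)
        assert sf.pos_strength == 2.0
        assert sf.neg_strength == 1.0
        assert sf.summed_index == 1.0

    def test_empty_network(self):
        sf = network_strength(np.array([1.0, 2.0]), PredictiveNetwork())
        assert (sf.pos_strength, sf.neg_strength, sf.summed_index) == (0.0, 0.0, 0.0)

    def test_index_out_of_range(self):
        with pytest.raises(ValueError):
            network_strength(np.zeros(3), PredictiveNetwork(pos_edges={10}))

    @given(
        pos=st.floats(-100, 100, allow_nan=False),
        neg=st.floats(-100, 100, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_summed_index_identity(self, pos, neg):
        sf = StrengthFeatures(pos_strength=pos, neg_strength=neg)
        assert sf.summed_index == pos - neg

    def test_strength_matrix_matches_scalar_version(self, rng):
        net = PredictiveNetwork(pos_edges={0, 3}, neg_edges={5})
        z = rng.normal(size=(4, 8))
        s = strength_matrix(z, net)
        for i in range(4):
            sf = network_strength(z[i], net)
            assert s[i, 0] == pytest.approx(sf.pos_strength)
            assert s[i, 1] == pytest.approx(sf.neg_strength)


class TestSvr:
    def test_linear_realizable(self, rng):
        x = rng.normal(size=(30, 1))
        y = 2.0 * x[:, 0]
        reg = fit_svr(x, y, kernel="linear", C=100.0, epsilon=0.01)
        pred = reg.predict(x)
        assert np.max(np.abs(pred - y)) < 0.02

    def test_determinism(self, rng):
        x = rng.normal(size=(25, 2))
        y = rng.normal(size=25)
        p1 = fit_svr(x, y).predict(x)
        p2 = fit_svr(x, y).predict(x)
        np.testing.assert_array_equal(p1, p2)

    def test_monotone_relation_high_r(self, rng):
        x = rng.normal(size=(100, 1))
        y = 1.3 * x[:, 0] + 0.01 * rng.normal(size=100)
        pred = fit_svr(x, y).predict(x)
        assert np.corrcoef(pred, y)[0, 1] > 0.9

    def test_degenerate_features_rejected(self):
        with pytest.raises(ValueError):
            fit_svr(np.ones((10, 1)), np.arange(10.0))

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            fit_svr(np.arange(4.0)[:, None], np.arange(4.0))

    def test_json_roundtrip_preserves_predictions(self, rng):
        from plvcpm.cpm import FrozenSVR

        x = rng.normal(size=(40, 2))
        y = rng.normal(size=40)
        reg = fit_svr(x, y, kernel="rbf", C=2.0, epsilon=0.05)
        clone = FrozenSVR.from_dict(reg.to_dict())
        np.testing.assert_allclose(clone.predict(x), reg.predict(x))


class TestFeatureModes:
    def test_modes(self):
        s = np.array([[3.0, 1.0]])
        assert features_from_strengths(s, "pos")[0, 0] == 3.0
        assert features_from_strengths(s, "neg")[0, 0] == 1.0
        assert features_from_strengths(s, "combined")[0, 0] == 2.0
        np.testing.assert_array_equal(features_from_strengths(s, "both"), s)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            features_from_strengths(np.zeros((1, 2)), "weird")


def _toy_model(rng, n_regions=10):
    from plvcpm._edges import n_edges

    m = n_edges(n_regions)
    train = rng.random((20, m))
    z = rng.normal(size=20)
    train[:, 0] = 0.3 + 0.1 * z  # plant a clean edge
    std = fit_edge_standardization(train)
    net = PredictiveNetwork(pos_edges={0})
    zed = apply_edge_standardization(train, std)
    feats = features_from_strengths(strength_matrix(zed, net), "combined")
    reg = fit_svr(feats, z)
    return (
        CpmModel(
            scale_params=TRAIN_PARAMS,
            edge_std=std,
            network=net,
            regressor=reg,
            feature_mode="combined",
        ),
        train,
        z,
    )


class TestCpmModel:
    def test_training_subject_consistency(self, rng):
        model, train, z = _toy_model(rng)
        from plvcpm._edges import unvectorize

        conn = unvectorize(train[0], 10)
        single = predict_scores(model, conn)
        batch = model.predict_z(train)[0]
        assert single == pytest.approx(batch)

    def test_identical_connectomes_identical_predictions(self, rng):
        model, train, _ = _toy_model(rng)
        a = model.predict_z(train[3])
        b = model.predict_z(train[3].copy())
        np.testing.assert_array_equal(a, b)

    def test_wrong_shape_rejected(self, rng):
        model, _, _ = _toy_model(rng)
        with pytest.raises(ValueError):
            predict_scores(model, np.zeros((7, 7)))

    def test_json_roundtrip(self, rng, tmp_path):
        model, train, _ = _toy_model(rng)
        path = tmp_path / "model.json"
        model.save(path)
        clone = CpmModel.load(path)
        np.testing.assert_allclose(clone.predict_z(train), model.predict_z(train))
        assert clone.network == model.network
        assert clone.scale_params == model.scale_params
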