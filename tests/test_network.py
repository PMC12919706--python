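"""Encoder, token projection, positional encoding, attention, Bayesian head."""

import numpy as np
import pytest

from gridreg import (GridRegModel, GriddedDisplacementField, NetworkConfig,
                     cross_attention, make_control_grid, parameter_count,
                     positional_encoding, sample_transform)
from gridreg.network import (AttentionParams, BayesianGridOutput,
                             bayesian_head, create_weights, decode, encode,
                             grid_positional_encoding, load_checkpoint,
                             project_tokens, save_checkpoint)
from gridreg._tensor import Tensor

CFG64 = NetworkConfig(dtype="float64")


@pytest.fixture(scope="module")
def volumes():
    rng = np.random.default_rng(0)
    return rng.random((32, 32, 32)), rng.random((32, 32, 32))


@pytest.fixture(scope="module")
def weights():
    return create_weights(CFG64, rng=np.random.default_rng(3))


class TestEncoder:
    def test_channel_doubling_and_spatial_halving(self, volumes, weights):
        pyr = encode(volumes[0], volumes[1], CFG64, weights)
        chans = [lv.shape[1] for lv in pyr.levels]
        sizes = [lv.shape[2] for lv in pyr.levels]
        assert chans == [16, 32, 64, 128, 256]
        assert sizes == [16, 8, 4, 2, 1]

    def test_deterministic_for_fixed_seed(self, volumes):
        w1 = create_weights(CFG64, rng=np.random.default_rng(11))
        w2 = create_weights(CFG64, rng=np.random.default_rng(11))
        p1 = encode(volumes[0], volumes[1], CFG64, w1)
        p2 = encode(volumes[0], volumes[1], CFG64, w2)
        for a, b in zip(p1.levels, p2.levels):
            np.testing.assert_array_equal(a.data, b.data)

    def test_too_small_volume_rejected(self, weights):
        small = np.zeros((16, 16, 16))
        with pytest.raises(ValueError, match="too small"):
            encode(small, small, CFG64, weights)


class TestProjectTokens:
    def test_token_count_fixed_across_levels(self, volumes, weights):
        pyr = encode(volumes[0], volumes[1], CFG64, weights)
        for l, lv in enumerate(pyr.levels):
            toks = project_tokens(lv, CFG64, weights, l)
            assert toks.shape == (1, CFG64.np_tokens, CFG64.proj_channels)

    def test_zero_features_give_finite_bias_tokens(self, weights):
        zeros = Tensor(np.zeros((1, 16, 16, 16, 16)))
        toks = project_tokens(zeros, CFG64, weights, 0)
        assert np.all(np.isfinite(toks.data))


class TestPositionalEncoding:
    def test_cache_hit_equals_recompute(self):
        grid = make_control_grid((32, 32, 32), (8, 8, 8))
        a = grid_positional_encoding(grid, 66)
        b = grid_positional_encoding(grid, 66)
        c = positional_encoding(grid.normalized_coords(), 66)
        assert a is b
        np.testing.assert_array_equal(a, c)

    @pytest.mark.parametrize("g", [5, 8, 10, 15])
    def test_rows_injective_per_grid(self, g):
        grid = make_control_grid((32, 32, 32), (g, g, g))
        pe = positional_encoding(grid.normalized_coords(), 66)
        assert len(np.unique(pe.round(12), axis=0)) == g ** 3

    def test_origin_row_is_sin0_cos1_pattern(self):
        pe = positional_encoding(np.zeros((1, 3)), 6)
        np.testing.assert_allclose(pe[0], [0, 1, 0, 1, 0, 1], atol=1e-15)

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            positional_encoding(np.zeros((2, 3)), 64)


def brute_force_attention(q, tokens, params):
    """Per-head loop with explicit slicing and softmax."""
    H, d = params.heads, params.head_dim
    Q = q @ params.WQ.data
    K = tokens @ params.WK.data
    V = tokens @ params.WV.data
    outs = []
    for h in range(H):
        Qh = Q[:, h * d:(h + 1) * d]
        Kh = K[:, h * d:(h + 1) * d]
        Vh = V[:, h * d:(h + 1) * d]
        logits = Qh @ Kh.T / np.sqrt(d)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        A = e / e.sum(axis=1, keepdims=True)
        outs.append(A @ Vh)
    return np.concatenate(outs, axis=1) @ params.WO.data


def small_attention_params(rng, Cpe=12, Cin=10, H=2, d=4, Cout=6):
    return AttentionParams(
        WQ=Tensor(rng.normal(size=(Cpe, H * d))),
        WK=Tensor(rng.normal(size=(Cin, H * d))),
        WV=Tensor(rng.normal(size=(Cin, H * d))),
        WO=Tensor(rng.normal(size=(H * d, Cout))),
        heads=H, head_dim=d)


class TestCrossAttention:
    def test_matches_per_head_loop_oracle(self, rng):
        params = small_attention_params(rng)
        q = rng.normal(size=(8, 12))
        toks = rng.normal(size=(27, 10))
        out = cross_attention(Tensor(q), Tensor(toks), params)
        np.testing.assert_allclose(out.data,
                                   brute_force_attention(q, toks, params),
                                   atol=1e-6)

    def test_single_token_softmax_degenerates(self, rng):
        params = small_attention_params(rng)
        q = rng.normal(size=(5, 12))
        tok = rng.normal(size=(1, 10))
        out = cross_attention(Tensor(q), Tensor(tok), params)
        np.testing.assert_allclose(out.data,
                                   brute_force_attention(q, tok, params),
                                   atol=1e-8)

    def test_token_permutation_invariance(self, rng):
        params = small_attention_params(rng)
        q = rng.normal(size=(6, 12))
        toks = rng.normal(size=(20, 10))
        perm = rng.permutation(20)
        out1 = cross_attention(Tensor(q), Tensor(toks), params)
        out2 = cross_attention(Tensor(q), Tensor(toks[perm]), params)
        np.testing.assert_allclose(out1.data, out2.data, atol=1e-10)

    def test_locality_mask_errors_when_query_isolated(self, rng):
        params = small_attention_params(rng)
        q = rng.normal(size=(2, 12))
        toks = rng.normal(size=(4, 10))
        qc = np.array([[0.0, 0, 0], [1.0, 1, 1]])
        tc = np.full((4, 3), 0.05)
        with pytest.raises(ValueError, match="local_radius"):
            cross_attention(Tensor(q), Tensor(toks), params,
                            local_radius=0.2, query_coords=qc,
                            token_coords=tc)

    def test_locality_restricts_to_neighbors(self, rng):
        """With a tight radius, far tokens get (numerically) zero weight."""
        params = small_attention_params(rng)
        q = rng.normal(size=(1, 12))
        toks = rng.normal(size=(5, 10))
        qc = np.zeros((1, 3))
        tc = np.array([[0.01, 0, 0], [0.05, 0, 0], [0.9, 0, 0],
                       [0.95, 0, 0], [0.99, 0, 0]])
        near_only = cross_attention(Tensor(q), Tensor(toks), params,
                                    local_radius=0.2, query_coords=qc,
                                    token_coords=tc)
        near_tokens_only = cross_attention(Tensor(q), Tensor(toks[:2]),
                                           params)
        np.testing.assert_allclose(near_only.data, near_tokens_only.data,
                                   atol=1e-8)


class TestDecodeAndHead:
    @pytest.mark.parametrize("g", [5, 8, 10, 15])
    def test_one_weight_set_serves_every_grid(self, volumes, weights, g):
        pyr = encode(volumes[0], volumes[1], CFG64, weights)
        grid = make_control_grid((32, 32, 32), (g, g, g))
        mu, eta = bayesian_head(decode(pyr, grid, CFG64, weights),
                                weights, CFG64, grid)
        assert mu.shape == (1, 3, g, g, g)
        assert eta.shape == (1, 3, g, g, g)

    def test_parameter_count_independent_of_grid(self, volumes, weights):
        # all grids share the same weight dict; the count is structural
        counts = set()
        for g in (5, 15):
            grid = make_control_grid((32, 32, 32), (g, g, g))
            pyr = encode(volumes[0], volumes[1], CFG64, weights)
            decode(pyr, grid, CFG64, weights)
            counts.add(parameter_count(weights))
        assert len(counts) == 1

    def test_gradient_reaches_every_parameter(self, volumes):
        cfg = NetworkConfig(dtype="float64", proj_spatial=(4, 4, 4))
        w = create_weights(cfg, rng=np.random.default_rng(5))
        rng = np.random.default_rng(0)
        f, m = rng.random((32, 32, 32)), rng.random((32, 32, 32))
        grid = make_control_grid((32, 32, 32), (5, 5, 5))
        pyr = encode(f, m, cfg, w)
        mu, eta = bayesian_head(decode(pyr, grid, cfg, w), w, cfg, grid)
        loss = (mu * mu).sum() + (eta * eta).sum()
        loss.backward()
        dead = [k for k, p in w.items()
                if p.grad is None or not np.any(p.grad)]
        assert dead == []

    def test_no_projector_mode_forward(self, volumes):
        cfg = NetworkConfig(dtype="float64", use_projector=False)
        w = create_weights(cfg, rng=np.random.default_rng(5))
        pyr = encode(volumes[0], volumes[1], cfg, w)
        grid = make_control_grid((32, 32, 32), (5, 5, 5))
        feats = decode(pyr, grid, cfg, w)
        assert feats.shape == (1, 125, cfg.out_channels)
        assert np.all(np.isfinite(feats.data))


class TestBayesianHead:
    def test_softplus_values(self):
        assert np.logaddexp(0, 0.0) == pytest.approx(np.log(2))
        grid = make_control_grid((16, 16, 16), (3, 3, 3))
        mean = GriddedDisplacementField(grid=grid,
                                        vectors=np.zeros((3, 3, 3, 3)))
        out = BayesianGridOutput(mean=mean,
                                 raw_var=np.full((3, 3, 3, 3), -20.0),
                                 var=np.logaddexp(0, np.full((3, 3, 3, 3),
                                                             -20.0)))
        assert np.all(out.var > 0)
        assert out.var.max() < 1e-8

    def test_variance_positive_for_random_features(self, volumes, weights):
        pyr = encode(volumes[0], volumes[1], CFG64, weights)
        grid = make_control_grid((32, 32, 32), (5, 5, 5))
        _, eta = bayesian_head(decode(pyr, grid, CFG64, weights),
                               weights, CFG64, grid)
        var = np.logaddexp(0, eta.data)
        assert np.all(var > 0) and np.all(np.isfinite(var))


class TestSampling:
    def _output(self, var_value):
        grid = make_control_grid((16, 16, 16), (3, 3, 3))
        mean = GriddedDisplacementField(
            grid=grid, vectors=np.random.default_rng(1).normal(
                size=(3, 3, 3, 3)))
        v = np.full((3, 3, 3, 3), var_value)
        return BayesianGridOutput(mean=mean, raw_var=np.log(v), var=v)

    def test_vanishing_variance_returns_mean(self):
        out = self._output(1e-30)
        for s in sample_transform(out, 3, seed=0):
            np.testing.assert_allclose(s.vectors, out.mean.vectors,
                                       atol=1e-12)

    def test_seeded_reproducibility(self):
        out = self._output(0.5)
        a = sample_transform(out, 4, seed=9)
        b = sample_transform(out, 4, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.vectors, y.vectors)

    def test_monte_carlo_moments(self):
        grid = make_control_grid((16, 16, 16), (2, 2, 2))
        mean = GriddedDisplacementField(grid=grid,
                                        vectors=np.zeros((3, 2, 2, 2)))
        out = BayesianGridOutput(mean=mean, raw_var=np.zeros((3, 2, 2, 2)),
                                 var=np.ones((3, 2, 2, 2)))
        S = 10_000
        draws = np.array([s.vectors[0, 0, 0, 0]
                          for s in sample_transform(out, S, seed=2)])
        assert abs(draws.mean()) < 4 / np.sqrt(S)
        assert abs(draws.var() - 1.0) < 0.1


class TestCheckpoint:
    def test_roundtrip_preserves_weights_and_config(self, tmp_path):
        cfg = NetworkConfig(base_channels=4, proj_spatial=(2, 2, 2),
                            num_layers=2)
        model = GridRegModel(cfg)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model, extra={"note": 1})
        loaded, extra = load_checkpoint(path)
        assert extra == {"note": 1}
        assert loaded.cfg == cfg
        for k in model.weights:
            np.testing.assert_array_equal(loaded.weights[k].data,
                                          model.weights[k].data)
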