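"""The sparse-grid registration network.

Architecture, in forward order:

1. **Encoder** — the fixed and moving volumes are concatenated as a
   2-channel input and passed through ``num_layers`` blocks of
   (3D conv, ReLU, stride-2 downsampling); channels start at
   ``base_channels`` and double per level.
2. **Skip projection** — each pyramid level is adaptively average-pooled to
   ``proj_spatial``, mapped to ``proj_channels`` by a 1x1x1 convolution, and
   flattened into Np tokens; a fixed sinusoidal encoding of the token-center
   coordinates is added so tokens retain spatial identity.
3. **Cross-attention decoder** — control points are queries. Their
   positional encodings (cached per grid size) seed a per-query feature
   stream that is residually refined bottom-to-top: at each level the
   projected tokens are concatenated with a per-token decoder stream, and
   multi-head attention (queries from the query stream, keys/values from the
   tokens) adds its output back into the query stream. All projection
   matrices are sized by channel counts only, so the same weights serve any
   control-grid resolution — the basis of grid-adaptive training.
4. **Bayesian head** — two linear heads map the final per-query features to
   a displacement mean and a raw variance; ``sigma^2 = softplus(eta)`` keeps
   the variance positive. Training draws Monte Carlo displacement samples by
   the reparameterization trick; inference uses the mean field only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np

from ._tensor import Tensor, as_tensor, concatenate, conv3d, axis_linear3
from .grid_geometry import (ControlGrid, DenseDisplacementField,
                            GriddedDisplacementField, ImageVolume,
                            make_control_grid)
from .field_interpolation import UpsamplerConfig, upsample_tensor

__all__ = [
    "NetworkConfig", "FeaturePyramid", "AttentionParams",
    "BayesianGridOutput", "GridRegModel", "create_weights",
    "positional_encoding", "cross_attention", "encode", "project_tokens",
    "decode", "bayesian_head", "sample_transform", "forward",
    "parameter_count", "save_checkpoint", "load_checkpoint",
]


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``pe_channels`` must be divisible by 6 (three axes x sin/cos bands).
    ``grid_sizes`` is the candidate set sampled during adaptive training.
    """

    base_channels: int = 16
    num_layers: int = 5
    proj_channels: int = 32
    proj_spatial: tuple = (8, 8, 8)
    pe_channels: int = 66
    heads: int = 4
    head_dim: int = 16
    decoder_channels: int = 32
    out_channels: int = 64
    grid_sizes: tuple = ((5, 5, 5), (8, 8, 8), (10, 10, 10), (15, 15, 15))
    use_projector: bool = True
    use_bayesian: bool = True
    local_radius: float | None = None
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.num_layers < 2:
            raise ValueError("need at least two encoder layers")
        if self.pe_channels % 6 != 0:
            raise ValueError("pe_channels must be divisible by 6")
        for v in (self.base_channels, self.proj_channels, self.heads,
                  self.head_dim, self.decoder_channels, self.out_channels):
            if v < 1:
                raise ValueError("all channel counts must be positive")

    @property
    def np_tokens(self) -> int:
        pw, ph, pd = self.proj_spatial
        return pw * ph * pd

    @property
    def encoder_channels(self) -> list:
        return [self.base_channels * 2 ** l for l in range(self.num_layers)]

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["proj_spatial"] = list(self.proj_spatial)
        d["grid_sizes"] = [list(g) for g in self.grid_sizes]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["proj_spatial"] = tuple(d.get("proj_spatial", (8, 8, 8)))
        d["grid_sizes"] = tuple(tuple(g) for g in d.get(
            "grid_sizes", ((5, 5, 5), (8, 8, 8), (10, 10, 10), (15, 15, 15))))
        return cls(**d)


@dataclass
class FeaturePyramid:
    """Encoder feature maps, one per level, shapes (B, C_l, W_l, H_l, D_l)."""

    levels: list


@dataclass
class AttentionParams:
    """Projection matrices of one cross-attention block."""

    WQ: Tensor
    WK: Tensor
    WV: Tensor
    WO: Tensor
    heads: int
    head_dim: int


@dataclass
class BayesianGridOutput:
    """Mean and variance displacement fields on the control grid."""

    mean: GriddedDisplacementField
    raw_var: np.ndarray
    var: np.ndarray

    def __post_init__(self):
        if np.any(self.var <= 0):
            raise ValueError("variances must be strictly positive")


# ---------------------------------------------------------------------------
# Weight creation
# ---------------------------------------------------------------------------

def _fan_in_uniform(rng, shape, fan_in, dtype):
    """He fan-in uniform (gain sqrt(2), for ReLU nets without norm layers)."""
    if len(shape) == 1:            # biases start at zero
        return Tensor(np.zeros(shape, dtype=dtype), requires_grad=True)
    bound = np.sqrt(6.0 / fan_in)
    return Tensor(rng.uniform(-bound, bound, size=shape).astype(dtype),
                  requires_grad=True)


def create_weights(cfg: NetworkConfig, rng=None) -> dict:
    """Initialize all trainable tensors (fan-in uniform, single seed)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    dt = np.dtype(cfg.dtype)
    w: dict[str, Tensor] = {}
    chans = [2] + cfg.encoder_channels
    for l in range(cfg.num_layers):
        cin, cout = chans[l], chans[l + 1]
        w[f"enc{l}_w"] = _fan_in_uniform(rng, (cout, cin, 3, 3, 3),
                                         cin * 27, dt)
        w[f"enc{l}_b"] = _fan_in_uniform(rng, (cout,), cin * 27, dt)
    hd = cfg.heads * cfg.head_dim
    kv_in = cfg.proj_channels + cfg.decoder_channels
    if cfg.use_projector:
        for l in range(cfg.num_layers):
            cl = cfg.encoder_channels[l]
            w[f"proj{l}_w"] = _fan_in_uniform(rng, (cl, cfg.proj_channels),
                                              cl, dt)
            w[f"proj{l}_b"] = _fan_in_uniform(rng, (cfg.proj_channels,),
                                              cl, dt)
            if l > 0:      # token stream feeds the next level up only
                w[f"tok{l}_w"] = _fan_in_uniform(
                    rng, (kv_in, cfg.decoder_channels), kv_in, dt)
                w[f"tok{l}_b"] = _fan_in_uniform(
                    rng, (cfg.decoder_channels,), kv_in, dt)
        att_levels = range(cfg.num_layers)
    else:
        cl = cfg.encoder_channels[-1]
        w["noproj_w"] = _fan_in_uniform(rng, (cl, kv_in), cl, dt)
        w["noproj_b"] = _fan_in_uniform(rng, (kv_in,), cl, dt)
        att_levels = range(1)
    for l in att_levels:
        w[f"att{l}_wq"] = _fan_in_uniform(rng, (cfg.pe_channels, hd),
                                          cfg.pe_channels, dt)
        w[f"att{l}_wk"] = _fan_in_uniform(rng, (kv_in, hd), kv_in, dt)
        w[f"att{l}_wv"] = _fan_in_uniform(rng, (kv_in, hd), kv_in, dt)
        w[f"att{l}_wo"] = _fan_in_uniform(rng, (hd, cfg.pe_channels), hd, dt)
    w["head_w"] = _fan_in_uniform(rng, (cfg.pe_channels, cfg.out_channels),
                                  cfg.pe_channels, dt)
    w["head_b"] = _fan_in_uniform(rng, (cfg.out_channels,),
                                  cfg.pe_channels, dt)
    w["mu_w"] = _fan_in_uniform(rng, (cfg.out_channels, 3),
                                cfg.out_channels, dt)
    w["mu_b"] = _fan_in_uniform(rng, (3,), cfg.out_channels, dt)
    if cfg.use_bayesian:
        w["eta_w"] = _fan_in_uniform(rng, (cfg.out_channels, 3),
                                     cfg.out_channels, dt)
        w["eta_b"] = _fan_in_uniform(rng, (3,), cfg.out_channels, dt)
    return w


def parameter_count(weights: dict) -> int:
    return int(sum(p.size for p in weights.values()))


# ---------------------------------------------------------------------------
# Positional encoding (cached)
# ---------------------------------------------------------------------------

_PE_CACHE: dict = {}


def positional_encoding(coords: np.ndarray, Cpe: int) -> np.ndarray:
    """Fixed 3D sinusoidal encoding of normalized coordinates.

    ``coords`` is (G, 3) in [0, 1]; each axis gets ``Cpe/6`` frequency bands
    (angular frequencies pi * 2^k) with sin and cos phases. Deterministic,
    non-learned, hence reusable at any grid size.
    """
    if Cpe % 6 != 0:
        raise ValueError("Cpe must be divisible by 6")
    coords = np.asarray(coords, dtype=float)
    bands = Cpe // 6
    freqs = np.pi * (2.0 ** np.arange(bands))
    parts = []
    for axis in range(3):
        ang = coords[:, axis:axis + 1] * freqs[None, :]
        parts.append(np.sin(ang))
        parts.append(np.cos(ang))
    return np.concatenate(parts, axis=1)


def grid_positional_encoding(grid: ControlGrid, Cpe: int) -> np.ndarray:
    """Cached encoding of a control grid's normalized coordinates.

    Normalized control coordinates depend only on the per-axis point count,
    so the cache key is (grid size, Cpe).
    """
    key = (tuple(grid.size), Cpe)
    if key not in _PE_CACHE:
        _PE_CACHE[key] = positional_encoding(grid.normalized_coords(), Cpe)
    return _PE_CACHE[key]


def _padded_pe(coords: np.ndarray, channels: int) -> np.ndarray:
    """Sinusoidal encoding zero-padded to an arbitrary channel count."""
    usable = 6 * (channels // 6)
    out = np.zeros((coords.shape[0], channels))
    if usable:
        out[:, :usable] = positional_encoding(coords, usable)
    return out


def _token_centers(proj_spatial) -> np.ndarray:
    axes = [(np.arange(p) + 0.5) / p for p in proj_spatial]
    xs, ys, zs = np.meshgrid(*axes, indexing="ij")
    return np.stack([xs.ravel(), ys.ravel(), zs.ravel()], axis=1)


# ---------------------------------------------------------------------------
# Forward components
# ---------------------------------------------------------------------------

def _pool_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Adaptive average pooling stencil along one axis."""
    w = np.zeros((n_out, n_in))
    for i in range(n_out):
        a = int(np.floor(i * n_in / n_out))
        b = int(np.ceil((i + 1) * n_in / n_out))
        b = max(b, a + 1)
        w[i, a:b] = 1.0 / (b - a)
    return w


def encode(fixed, moving, cfg: NetworkConfig, weights: dict) -> FeaturePyramid:
    """Run the conv encoder on a (possibly batched) fixed/moving pair."""
    fa = fixed.data if isinstance(fixed, ImageVolume) else np.asarray(fixed)
    ma = moving.data if isinstance(moving, ImageVolume) else np.asarray(moving)
    if fa.shape != ma.shape:
        raise ValueError("fixed and moving must share a shape")
    if fa.ndim == 3:
        x = np.stack([fa, ma])[None]           # (1, 2, W, H, D)
    else:                                      # (B, W, H, D) batched
        x = np.stack([fa, ma], axis=1)
    if min(x.shape[2:]) < 2 ** cfg.num_layers:
        raise ValueError(
            f"volume of shape {x.shape[2:]} too small for "
            f"{cfg.num_layers} stride-2 layers")
    h = Tensor(x.astype(cfg.dtype))
    levels = []
    for l in range(cfg.num_layers):
        h = conv3d(h, weights[f"enc{l}_w"], weights[f"enc{l}_b"],
                   stride=2, padding=1).relu()
        levels.append(h)
    return FeaturePyramid(levels=levels)


def project_tokens(level_features, cfg: NetworkConfig, weights: dict,
                   level: int):
    """Pool one pyramid level to Np tokens with positional information.

    Returns a Tensor of shape (B, Np, Cp): adaptive average pooling to
    ``proj_spatial``, a per-token linear map (1x1x1 conv), then the
    sinusoidal encoding of token centers added on the feature axis.
    """
    feats = as_tensor(level_features)
    pw, ph, pd = cfg.proj_spatial
    shp = feats.shape[-3:]
    pooled = axis_linear3(feats, _pool_matrix(shp[0], pw),
                          _pool_matrix(shp[1], ph),
                          _pool_matrix(shp[2], pd))
    # (B, C, pw, ph, pd) -> (B, Np, C)
    B, C = pooled.shape[0], pooled.shape[1]
    toks = pooled.reshape(B, C, cfg.np_tokens).transpose(0, 2, 1)
    toks = toks @ weights[f"proj{level}_w"] + weights[f"proj{level}_b"]
    pe = _padded_pe(_token_centers(cfg.proj_spatial),
                    cfg.proj_channels).astype(cfg.dtype)
    return toks + Tensor(pe[None])


def cross_attention(queries, tokens, params: AttentionParams,
                    local_radius: float | None = None,
                    query_coords: np.ndarray | None = None,
                    token_coords: np.ndarray | None = None):
    """Multi-head cross-attention of control-point queries over tokens.

    ``queries``: (..., G, Cpe); ``tokens``: (..., Np, Cin). Softmax is
    applied row-wise over the tokens, so every attention row is a
    distribution. With ``local_radius`` set, tokens farther than the radius
    (Euclidean, normalized coordinates) from a query are masked out before
    the softmax; a query with no token in range is an error.
    """
    q = as_tensor(queries) @ params.WQ
    k = as_tensor(tokens) @ params.WK
    v = as_tensor(tokens) @ params.WV
    H, d = params.heads, params.head_dim
    G, Np = q.shape[-2], k.shape[-2]

    def split_heads(t, n):
        lead = t.shape[:-2]
        t = t.reshape(*lead, n, H, d)
        axes = tuple(range(len(lead))) + (t.ndim - 2, t.ndim - 3, t.ndim - 1)
        return t.transpose(axes)               # (..., H, n, d)

    qh = split_heads(q, G)
    kh = split_heads(k, Np)
    vh = split_heads(v, Np)
    mask_bias = None
    if local_radius is not None:
        if query_coords is None or token_coords is None:
            raise ValueError("locality masking needs query and token coords")
        dist = np.linalg.norm(query_coords[:, None, :]
                              - token_coords[None, :, :], axis=-1)
        mask = dist > local_radius
        if np.any(mask.all(axis=1)):
            raise ValueError("a query has no tokens within local_radius")
        mask_bias = np.where(mask, -1e30, 0.0).astype(qh.data.dtype)
    from ._tensor import scaled_dot_softmax
    att = scaled_dot_softmax(qh, kh, 1.0 / np.sqrt(d),
                             mask_bias)         # (..., H, G, Np)
    out = att @ vh                             # (..., H, G, d)
    lead = tuple(range(out.ndim - 3))
    out = out.transpose(*lead, out.ndim - 2, out.ndim - 3, out.ndim - 1)
    out = out.reshape(*out.shape[:-2], H * d)
    return out @ params.WO


def _attention_params(weights: dict, cfg: NetworkConfig,
                      level: int) -> AttentionParams:
    return AttentionParams(WQ=weights[f"att{level}_wq"],
                           WK=weights[f"att{level}_wk"],
                           WV=weights[f"att{level}_wv"],
                           WO=weights[f"att{level}_wo"],
                           heads=cfg.heads, head_dim=cfg.head_dim)


def decode(pyramid: FeaturePyramid, grid: ControlGrid, cfg: NetworkConfig,
           weights: dict):
    """Aggregate pyramid tokens into per-control-point features.

    Returns a Tensor (B, G, Cout). The query stream starts as the cached
    positional encoding of the control grid and accumulates each level's
    attention output (bottom level first); the token stream concatenates the
    level's projected tokens with a linear map of the previous level's
    token state.
    """
    B = pyramid.levels[0].shape[0]
    pe = grid_positional_encoding(grid, cfg.pe_channels).astype(cfg.dtype)
    qfeat = Tensor(np.broadcast_to(pe[None], (B,) + pe.shape).copy())
    qc = grid.normalized_coords()
    tc = _token_centers(cfg.proj_spatial)

    if not cfg.use_projector:
        bott = pyramid.levels[-1]
        Bc, C = bott.shape[0], bott.shape[1]
        npix = int(np.prod(bott.shape[2:]))
        toks = bott.reshape(Bc, C, npix).transpose(0, 2, 1)
        toks = toks @ weights["noproj_w"] + weights["noproj_b"]
        btc = _token_centers(bott.shape[2:])
        out = cross_attention(qfeat, toks, _attention_params(weights, cfg, 0),
                              cfg.local_radius, qc, btc)
        qfeat = qfeat + out
    else:
        dstate = None
        for l in reversed(range(cfg.num_layers)):     # bottom -> top
            toks = project_tokens(pyramid.levels[l], cfg, weights, l)
            if dstate is None:
                dstate = Tensor(np.zeros(
                    (B, cfg.np_tokens, cfg.decoder_channels),
                    dtype=cfg.dtype))
            cat = concatenate([toks, dstate], axis=2)
            out = cross_attention(qfeat, cat,
                                  _attention_params(weights, cfg, l),
                                  cfg.local_radius, qc, tc)
            qfeat = qfeat + out
            if l > 0:
                dstate = (cat @ weights[f"tok{l}_w"]
                          + weights[f"tok{l}_b"]).relu()
    return (qfeat @ weights["head_w"] + weights["head_b"]).relu()


def bayesian_head(grid_features, weights: dict, cfg: NetworkConfig,
                  grid: ControlGrid):
    """Map decoder features to (mu, eta) tensors of shape (B, 3, gw, gh, gd)."""
    feats = as_tensor(grid_features)
    B = feats.shape[0]
    gw, gh, gd = grid.size
    mu = feats @ weights["mu_w"] + weights["mu_b"]
    mu = mu.transpose(0, 2, 1).reshape(B, 3, gw, gh, gd)
    if cfg.use_bayesian:
        eta = feats @ weights["eta_w"] + weights["eta_b"]
        eta = eta.transpose(0, 2, 1).reshape(B, 3, gw, gh, gd)
    else:
        eta = None
    return mu, eta


def sample_transform(out: BayesianGridOutput, S: int,
                     seed: int = 0) -> list:
    """Draw S reparameterized displacement samples mu + sigma * eps."""
    if S < 1:
        raise ValueError("S must be >= 1")
    rng = np.random.default_rng(seed)
    sig = np.sqrt(out.var)
    fields = []
    for _ in range(S):
        eps = rng.standard_normal(out.mean.vectors.shape)
        fields.append(GriddedDisplacementField(
            grid=out.mean.grid, vectors=out.mean.vectors + sig * eps))
    return fields


def forward(fixed, moving, grid_size, cfg: NetworkConfig, weights: dict,
            inference: bool = True,
            upsampler: UpsamplerConfig | None = None):
    """Full single-pair pass: encode, decode, head, upsample the mean.

    Returns ``(BayesianGridOutput, DenseDisplacementField)``. In inference
    mode (and in this functional API generally) no sampling occurs; use
    :func:`sample_transform` on the output for Monte Carlo draws.
    """
    upsampler = upsampler or UpsamplerConfig()
    fa = fixed.data if isinstance(fixed, ImageVolume) else np.asarray(fixed)
    grid = make_control_grid(fa.shape, grid_size)
    pyr = encode(fixed, moving, cfg, weights)
    feats = decode(pyr, grid, cfg, weights)
    mu_t, eta_t = bayesian_head(feats, weights, cfg, grid)
    mu = mu_t.data[0].astype(float)
    if eta_t is not None:
        eta = eta_t.data[0].astype(float)
        var = np.logaddexp(0.0, eta)           # softplus
    else:
        eta = np.full_like(mu, -np.inf)
        var = np.full_like(mu, 1e-12)
    gdf = GriddedDisplacementField(grid=grid, vectors=mu)
    out = BayesianGridOutput(
        mean=gdf, raw_var=eta,
        var=np.maximum(var, np.finfo(float).tiny))
    dense = upsample_tensor(Tensor(mu), grid, fa.shape, upsampler)
    return out, DenseDisplacementField(vectors=dense.data)


# ---------------------------------------------------------------------------
# Model wrapper and checkpointing
# ---------------------------------------------------------------------------

class GridRegModel:
    """Configuration + weights, with convenience forward/training hooks."""

    def __init__(self, cfg: NetworkConfig, weights: dict | None = None):
        self.cfg = cfg
        self.weights = weights if weights is not None else create_weights(cfg)

    def parameters(self) -> list:
        return [self.weights[k] for k in sorted(self.weights)]

    def parameter_count(self) -> int:
        return parameter_count(self.weights)

    def forward_batch(self, fixed_batch: np.ndarray, moving_batch: np.ndarray,
                      grid: ControlGrid):
        """Batched training pass returning (mu, eta) Tensors."""
        pyr = encode(fixed_batch, moving_batch, self.cfg, self.weights)
        feats = decode(pyr, grid, self.cfg, self.weights)
        return bayesian_head(feats, self.weights, self.cfg, grid)

    def register_pair(self, fixed, moving, grid_size,
                      upsampler: UpsamplerConfig | None = None):
        return forward(fixed, moving, grid_size, self.cfg, self.weights,
                       inference=True, upsampler=upsampler)


def save_checkpoint(path, model: GridRegModel, extra: dict | None = None):
    """Single-archive checkpoint: weights + full config (+ extras)."""
    arrays = {k: v.data for k, v in model.weights.items()}
    meta = {"config": model.cfg.to_dict(), "extra": extra or {}}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple:
    """Load a checkpoint; returns (GridRegModel, extra dict)."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
        cfg = NetworkConfig.from_dict(meta["config"])
        weights = {k: Tensor(z[k].copy(), requires_grad=True)
                   for k in z.files if k != "__meta__"}
    return GridRegModel(cfg, weights), meta.get("extra", {})
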