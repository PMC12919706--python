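"""Independent per-head attention oracle shared by the test modules."""

import numpy as np

from gridreg.network import AttentionParams
from gridreg._tensor import Tensor


def params_for(rng, Cpe, Cin, H, d, Cout):
    return AttentionParams(
        WQ=Tensor(rng.normal(size=(Cpe, H * d))),
        WK=Tensor(rng.normal(size=(Cin, H * d))),
        WV=Tensor(rng.normal(size=(Cin, H * d))),
        WO=Tensor(rng.normal(size=(H * d, Cout))),
        heads=H, head_dim=d)


def brute_force(q, tokens, params):
    """Explicit per-head slicing, softmax loop; returns (output, A list)."""
    H, d = params.heads, params.head_dim
    Q = q @ params.WQ.data
    K = tokens @ params.WK.data
    V = tokens @ params.WV.data
    outs, mats = [], []
    for h in range(H):
        Qh = Q[:, h * d:(h + 1) * d]
        Kh = K[:, h * d:(h + 1) * d]
        Vh = V[:, h * d:(h + 1) * d]
        logits = Qh @ Kh.T / np.sqrt(d)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        A = e / e.sum(axis=1, keepdims=True)
        mats.append(A)
        outs.append(A @ Vh)
    return np.concatenate(outs, axis=1) @ params.WO.data, mats
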