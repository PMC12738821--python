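"""Six-layer Vision-Transformer encoder in numpy.

The encoder follows the printed formulation exactly: patch + position
embedding with a CLS token, per-head scaled-dot-product attention
softmax(QK^T/sqrt(dk))V, a GELU MLP with expansion ratio 4, and *post-norm*
residual wiring

    X_l   = LayerNorm(X_{l-1} + DropPath(Attn(X_{l-1})))
    X_l+1 = LayerNorm(X_l     + DropPath(MLP(X_l)))

with classification read out from the CLS token,
y = softmax(head(LayerNorm(X^L_0))). The head is either a single linear map
or a B-spline Kolmogorov-Arnold stage (see :mod:`leafvit.kan`).

All forward passes return caches consumed by matching backward passes, so
training needs no autodiff framework and repeated runs are bit-identical.
"""

from __future__ import annotations

import functools
import io
import json
import zipfile
from typing import Any

import numpy as np

_einsum = functools.partial(np.einsum, optimize=True)

from . import kan as kan_mod
from . import routing_attention as routing
from .config import ModelConfig
from .layers import (
    drop_path_mask,
    dropout_mask,
    layer_norm,
    layer_norm_backward,
    linear,
    linear_backward,
    gelu,
    gelu_grad,
    softmax,
)

CHECKPOINT_VERSION = 1

__all__ = [
    "init_params",
    "embed_patches",
    "multi_head_attention",
    "mlp_block",
    "encoder_layer",
    "classify_head",
    "profile_model",
    "ViTClassifier",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# parameters


def _param_shapes(config: ModelConfig) -> dict[str, tuple[int, ...]]:
    p, C, d = config.patch_size, config.channels, config.embed_dim
    h, dk = config.num_heads, config.head_dim
    N = config.num_patches
    hidden = config.mlp_ratio * d
    shapes: dict[str, tuple[int, ...]] = {
        "embed/E": (p * p * C, d),
        "embed/cls": (d,),
        "embed/pos": (N + 1, d),
    }
    for i in range(config.num_layers):
        pre = f"layer{i}"
        shapes[f"{pre}/attn/Wq"] = (h, d, dk)
        shapes[f"{pre}/attn/Wk"] = (h, d, dk)
        shapes[f"{pre}/attn/Wv"] = (h, d, dk)
        shapes[f"{pre}/attn/Wo"] = (d, d)
        if config.attention_mode == "routed":
            shapes[f"{pre}/attn/lce"] = (d, config.lce_kernel, config.lce_kernel)
        shapes[f"{pre}/ln1/gamma"] = (d,)
        shapes[f"{pre}/ln1/beta"] = (d,)
        shapes[f"{pre}/mlp/W1"] = (d, hidden)
        shapes[f"{pre}/mlp/b1"] = (hidden,)
        shapes[f"{pre}/mlp/W2"] = (hidden, d)
        shapes[f"{pre}/mlp/b2"] = (d,)
        shapes[f"{pre}/ln2/gamma"] = (d,)
        shapes[f"{pre}/ln2/beta"] = (d,)
    shapes["head/ln/gamma"] = (d,)
    shapes["head/ln/beta"] = (d,)
    if config.head_type == "linear":
        shapes["head/W"] = (d, config.num_classes)
    else:
        shapes["head/kan_coeffs"] = (config.num_classes, d, config.kan_num_basis)
    return shapes


def init_params(config: ModelConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Seeded normal(0, 0.02) weights; LayerNorm gains 1, shifts/biases 0.

    The local-context-enhancement depthwise kernel starts at zero so a fresh
    routed model is exactly its attention-only counterpart.
    """
    params: dict[str, np.ndarray] = {}
    for name, shape in _param_shapes(config).items():
        if name.endswith("gamma"):
            params[name] = np.ones(shape)
        elif name.endswith(("beta", "b1", "b2")) or name.endswith("/lce"):
            params[name] = np.zeros(shape)
        else:
            params[name] = rng.normal(0.0, 0.02, size=shape)
    return params


# ---------------------------------------------------------------------------
# patch embedding


def extract_patches(image: np.ndarray, patch_size: int) -> np.ndarray:
    """Flatten raster-ordered p x p patches of one H x W x C image."""
    H, W = image.shape[:2]
    C = 1 if image.ndim == 2 else image.shape[2]
    p = patch_size
    if H % p or W % p:
        raise ValueError(f"patch size {p} does not partition a {H}x{W} image")
    img = image.reshape(H, W, C)
    # (H/p, p, W/p, p, C) -> (H/p, W/p, p, p, C) -> (N, p*p*C)
    patches = img.reshape(H // p, p, W // p, p, C).transpose(0, 2, 1, 3, 4)
    return patches.reshape(-1, p * p * C)


def embed_patches(
    image: np.ndarray,
    config: ModelConfig,
    E: np.ndarray,
    Epos: np.ndarray,
    Xclass: np.ndarray,
) -> np.ndarray:
    """z0 = [Xclass; Xp1 E; ...; XpN E] + Epos for a single image."""
    patches = extract_patches(image, config.patch_size)
    N, flat = patches.shape
    if E.shape[0] != flat:
        raise ValueError(f"projection matrix expects {E.shape[0]} inputs, got {flat}")
    if Epos.shape != (N + 1, E.shape[1]):
        raise ValueError(
            f"position encoding must be {(N + 1, E.shape[1])}, got {Epos.shape}"
        )
    tokens = np.empty((N + 1, E.shape[1]))
    tokens[0] = Xclass
    tokens[1:] = patches @ E
    return tokens + Epos


# ---------------------------------------------------------------------------
# dense multi-head attention


def _dense_attn_forward(x, Wq, Wk, Wv, Wo):
    """x: (B, T, d); per-head scaled dot-product attention, concat, project."""
    dk = Wq.shape[-1]
    Q = _einsum("btd,hdk->bhtk", x, Wq)
    K = _einsum("btd,hdk->bhtk", x, Wk)
    V = _einsum("btd,hdk->bhtk", x, Wv)
    scores = _einsum("bhqk,bhtk->bhqt", Q, K) / float(np.sqrt(dk))
    A = softmax(scores, axis=-1)
    heads = _einsum("bhqt,bhtk->bhqk", A, V)
    B, h, T, _ = heads.shape
    concat = heads.transpose(0, 2, 1, 3).reshape(B, T, h * dk)
    out = concat @ Wo
    cache = (x, Wq, Wk, Wv, Wo, Q, K, V, A, concat)
    return out, cache


def _softmax_backward(dA, A):
    return A * (dA - np.sum(dA * A, axis=-1, keepdims=True))


def _dense_attn_backward(dout, cache):
    x, Wq, Wk, Wv, Wo, Q, K, V, A, concat = cache
    B, T, d = x.shape
    h, _, dk = Wq.shape
    dWo = concat.reshape(-1, d).T @ dout.reshape(-1, d)
    dconcat = dout @ Wo.T
    dheads = dconcat.reshape(B, T, h, dk).transpose(0, 2, 1, 3)
    dA = _einsum("bhqk,bhtk->bhqt", dheads, V)
    dV = _einsum("bhqt,bhqk->bhtk", A, dheads)
    dscores = _softmax_backward(dA, A) / float(np.sqrt(dk))
    dQ = _einsum("bhqt,bhtk->bhqk", dscores, K)
    dK = _einsum("bhqt,bhqk->bhtk", dscores, Q)
    dx = (
        _einsum("bhtk,hdk->btd", dQ, Wq)
        + _einsum("bhtk,hdk->btd", dK, Wk)
        + _einsum("bhtk,hdk->btd", dV, Wv)
    )
    dWq = _einsum("btd,bhtk->hdk", x, dQ)
    dWk = _einsum("btd,bhtk->hdk", x, dK)
    dWv = _einsum("btd,bhtk->hdk", x, dV)
    return dx, {"Wq": dWq, "Wk": dWk, "Wv": dWv, "Wo": dWo}


def multi_head_attention(
    x: np.ndarray,
    params: dict[str, np.ndarray],
    config: ModelConfig,
) -> np.ndarray:
    """Dense attention for one (N+1) x d token sequence.

    ``params`` holds per-head ``Wq``/``Wk``/``Wv`` of shape (h, d, dk) and the
    output projection ``Wo`` of shape (d, d).
    """
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite attention input")
    if config.embed_dim % config.num_heads:
        raise ValueError("num_heads must divide embed_dim")
    out, _ = _dense_attn_forward(
        x[None], params["Wq"], params["Wk"], params["Wv"], params["Wo"]
    )
    return out[0]


# ---------------------------------------------------------------------------
# MLP block


def _mlp_forward(x, W1, b1, W2, b2):
    pre, c1 = linear(x, W1, b1)
    act = gelu(pre)
    out, c2 = linear(act, W2, b2)
    return out, (pre, c1, c2)


def _mlp_backward(dout, cache):
    pre, c1, c2 = cache
    dact, dW2, db2 = linear_backward(dout, c2)
    dpre = dact * gelu_grad(pre)
    dx, dW1, db1 = linear_backward(dpre, c1)
    return dx, {"W1": dW1, "b1": db1, "W2": dW2, "b2": db2}


def mlp_block(x: np.ndarray, params: dict[str, np.ndarray]) -> np.ndarray:
    """GELU(x W1 + b1) W2 + b2 applied row-wise (exact erf GELU)."""
    if x.shape[-1] != params["W1"].shape[0]:
        raise ValueError("token width does not match W1")
    out, _ = _mlp_forward(x, params["W1"], params["b1"], params["W2"], params["b2"])
    return out


# ---------------------------------------------------------------------------
# encoder layer


def _attn_dispatch_forward(x, layer_params, config):
    if config.attention_mode == "dense":
        out, cache = _dense_attn_forward(
            x, layer_params["Wq"], layer_params["Wk"], layer_params["Wv"],
            layer_params["Wo"],
        )
        return out, ("dense", cache)
    out, cache = routing.biformer_attention_forward(x, layer_params, config)
    return out, ("routed", cache)


def _attn_dispatch_backward(dout, dispatch_cache):
    mode, cache = dispatch_cache
    if mode == "dense":
        return _dense_attn_backward(dout, cache)
    return routing.biformer_attention_backward(dout, cache)


def _encoder_layer_forward(x, layer_params, config, training, rng):
    B = x.shape[0]
    rate = config.drop_path_rate if training else 0.0
    a, acache = _attn_dispatch_forward(x, layer_params, config)
    mask1 = drop_path_mask(B, rate, rng).astype(x.dtype) if training else 1.0
    x1, ln1c = layer_norm(x + mask1 * a, layer_params["ln1/gamma"], layer_params["ln1/beta"])
    m, mcache = _mlp_forward(
        x1, layer_params["mlp/W1"], layer_params["mlp/b1"],
        layer_params["mlp/W2"], layer_params["mlp/b2"],
    )
    mask2 = drop_path_mask(B, rate, rng).astype(x.dtype) if training else 1.0
    x2, ln2c = layer_norm(x1 + mask2 * m, layer_params["ln2/gamma"], layer_params["ln2/beta"])
    return x2, (acache, mask1, ln1c, mcache, mask2, ln2c)


def _encoder_layer_backward(dout, cache):
    acache, mask1, ln1c, mcache, mask2, ln2c = cache
    grads: dict[str, np.ndarray] = {}
    dr2, g2, b2 = layer_norm_backward(dout, ln2c)
    grads["ln2/gamma"], grads["ln2/beta"] = g2, b2
    dm = dr2 * mask2
    dx1_mlp, mlp_grads = _mlp_backward(dm, mcache)
    for k, v in mlp_grads.items():
        grads[f"mlp/{k}"] = v
    dx1 = dr2 + dx1_mlp
    dr1, g1, b1 = layer_norm_backward(dx1, ln1c)
    grads["ln1/gamma"], grads["ln1/beta"] = g1, b1
    da = dr1 * mask1
    dx_attn, attn_grads = _attn_dispatch_backward(da, acache)
    for k, v in attn_grads.items():
        grads[f"attn/{k}"] = v
    dx = dr1 + dx_attn
    return dx, grads


def encoder_layer(
    x: np.ndarray,
    attn_params: dict[str, np.ndarray],
    mlp_params: dict[str, np.ndarray],
    config: ModelConfig,
    *,
    training: bool = False,
    rng: np.random.Generator | None = None,
    ln_params: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """One post-norm encoder layer applied to a single token sequence.

    LayerNorm gains/shifts default to identity when ``ln_params`` is omitted.
    """
    if training and rng is None:
        raise ValueError("training mode requires an rng for DropPath")
    d = x.shape[-1]
    lp = dict(attn_params)
    lp.update({f"mlp/{k}": v for k, v in mlp_params.items()})
    ln = ln_params or {}
    lp["ln1/gamma"] = ln.get("ln1/gamma", np.ones(d))
    lp["ln1/beta"] = ln.get("ln1/beta", np.zeros(d))
    lp["ln2/gamma"] = ln.get("ln2/gamma", np.ones(d))
    lp["ln2/beta"] = ln.get("ln2/beta", np.zeros(d))
    out, _ = _encoder_layer_forward(
        x[None], lp, config, training, rng if rng is not None else np.random.default_rng(0)
    )
    return out[0]


# ---------------------------------------------------------------------------
# classification head


def classify_head(x: np.ndarray, head) -> np.ndarray:
    """y = softmax(head(LayerNorm(CLS))) for a final-layer token sequence.

    ``head`` is either a (d, num_classes) weight matrix or a
    :class:`leafvit.kan.KANHead`.
    """
    cls = x[0]
    d = cls.shape[0]
    u, _ = layer_norm(cls, np.ones(d), np.zeros(d))
    if isinstance(head, kan_mod.KANHead):
        logits = head.forward(u[None])[0][0]
    else:
        logits = u @ head
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite classification logits")
    return softmax(logits)


# ---------------------------------------------------------------------------
# full model


class ViTClassifier:
    """Patch-embedding ViT with dense or bi-level routed attention.

    ``forward`` computes logits for a batch of H x W x C images in [0, 1];
    ``backward`` returns the gradient of any scalar loss given d(loss)/d(logits).
    """

    def __init__(
        self,
        config: ModelConfig,
        params: dict[str, np.ndarray] | None = None,
        rng: np.random.Generator | None = None,
        dtype: np.dtype = np.float64,
    ):
        self.config = config
        self.dtype = np.dtype(dtype)
        if params is None:
            params = init_params(config, rng or np.random.default_rng(0))
        if self.dtype != np.float64:
            # encoder body runs in the reduced precision; the head (and its
            # spline machinery) stays double so probabilities are exact
            params = {
                k: (v if k.startswith("head/") else v.astype(self.dtype))
                for k, v in params.items()
            }
        self.params = params
        if config.head_type == "kan":
            knots = kan_mod.uniform_clamped_knots(
                config.kan_num_basis, config.kan_degree,
                -config.kan_domain, config.kan_domain,
            )
            self.kan_head = kan_mod.KANHead(knots, params["head/kan_coeffs"])
        else:
            self.kan_head = None
        self._cache: Any = None

    # -- forward -----------------------------------------------------------

    def _embed_batch(self, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cfg = self.config
        images = np.asarray(images, dtype=self.dtype)
        B = images.shape[0]
        patches = np.stack(
            [extract_patches(img, cfg.patch_size) for img in images]
        )  # (B, N, p*p*C)
        proj = patches @ self.params["embed/E"]
        tokens = np.empty((B, cfg.num_patches + 1, cfg.embed_dim), dtype=self.dtype)
        tokens[:, 0] = self.params["embed/cls"]
        tokens[:, 1:] = proj
        tokens = tokens + self.params["embed/pos"]
        return tokens, patches

    def forward(
        self,
        images: np.ndarray,
        *,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        cfg = self.config
        if training and rng is None:
            raise ValueError("training mode requires an rng")
        x, patches = self._embed_batch(images)
        layer_caches = []
        for i in range(cfg.num_layers):
            lp = self._layer_params(i)
            x, cache = _encoder_layer_forward(x, lp, cfg, training, rng)
            layer_caches.append(cache)
        cls = x[:, 0]
        u, lnc = layer_norm(cls, self.params["head/ln/gamma"], self.params["head/ln/beta"])
        if training and cfg.dropout_rate > 0:
            dmask = dropout_mask(u.shape, cfg.dropout_rate, rng)
        else:
            dmask = 1.0
        ud = u * dmask
        if self.kan_head is not None:
            self.kan_head.coeffs = self.params["head/kan_coeffs"]
            logits, head_cache = self.kan_head.forward(ud)
        else:
            logits = ud @ self.params["head/W"]
            head_cache = ud
        self._cache = (patches, layer_caches, lnc, dmask, head_cache)
        return logits

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, len(images), batch_size):
            out.append(softmax(self.forward(images[i : i + batch_size]), axis=-1))
        return np.concatenate(out, axis=0)

    # -- backward ----------------------------------------------------------

    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        cfg = self.config
        patches, layer_caches, lnc, dmask, head_cache = self._cache
        grads: dict[str, np.ndarray] = {}
        if self.kan_head is not None:
            dud, dcoeffs = self.kan_head.backward(dlogits, head_cache)
            grads["head/kan_coeffs"] = dcoeffs
        else:
            ud = head_cache
            grads["head/W"] = ud.T @ dlogits
            dud = dlogits @ self.params["head/W"].T
        du = dud * dmask
        dcls, dg, db = layer_norm_backward(du, lnc)
        grads["head/ln/gamma"], grads["head/ln/beta"] = dg, db
        B = dcls.shape[0]
        dx = np.zeros((B, cfg.num_patches + 1, cfg.embed_dim), dtype=self.dtype)
        dx[:, 0] = dcls
        for i in reversed(range(cfg.num_layers)):
            dx, lgrads = _encoder_layer_backward(dx, layer_caches[i])
            for k, v in lgrads.items():
                grads[f"layer{i}/{k}"] = v
        grads["embed/pos"] = dx.sum(axis=0)
        grads["embed/cls"] = dx[:, 0].sum(axis=0)
        dproj = dx[:, 1:]
        grads["embed/E"] = _einsum("bnf,bnd->fd", patches, dproj)
        return grads

    def _layer_params(self, i: int) -> dict[str, np.ndarray]:
        pre = f"layer{i}/"
        out = {}
        for k, v in self.params.items():
            if k.startswith(pre):
                key = k[len(pre):]
                if key.startswith("attn/"):
                    key = key[len("attn/"):]
                out[key] = v
        return out


# ---------------------------------------------------------------------------
# profiling


def profile_model(config: ModelConfig) -> dict[str, int]:
    """Learnable-parameter count and a forward-pass FLOP estimate.

    Counting convention: one multiply-accumulate = 2 FLOPs; only matrix
    products, attention contractions and the depthwise convolution are
    counted (normalisations, softmaxes and activations are omitted).
    """
    shapes = _param_shapes(config)
    param_count = int(sum(int(np.prod(s)) for s in shapes.values()))

    p, C, d = config.patch_size, config.channels, config.embed_dim
    N = config.num_patches
    T = N + 1
    dk = config.head_dim
    h = config.num_heads
    hidden = config.mlp_ratio * d
    flops = 2 * N * (p * p * C) * d  # patch projection
    per_layer = 0
    per_layer += 3 * 2 * T * d * d  # Q, K, V projections (all heads)
    if config.attention_mode == "dense":
        per_layer += 2 * 2 * h * T * T * dk  # scores + weighted sum
    else:
        S2 = config.region_grid**2
        tr = N // S2
        kv = config.routing_k * tr
        per_layer += 2 * h * S2 * S2 * dk  # region adjacency Qr Kr^T
        per_layer += 2 * 2 * h * N * kv * dk  # routed scores + weighted sum
        per_layer += 2 * 2 * h * T * dk  # CLS dense row
        per_layer += 2 * N * d * config.lce_kernel**2  # depthwise LCE
    per_layer += 2 * T * d * d  # output projection
    per_layer += 2 * 2 * T * d * hidden  # MLP
    flops += config.num_layers * per_layer
    if config.head_type == "linear":
        flops += 2 * d * config.num_classes
    else:
        flops += 2 * d * config.num_classes * config.kan_num_basis
    return {"param_count": param_count, "flop_estimate": int(flops)}


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path: str, config: ModelConfig, params: dict[str, np.ndarray],
                    meta: dict[str, Any] | None = None) -> None:
    """Single-file zip archive: config JSON + named float64 weight arrays."""
    with zipfile.ZipFile(path, "w") as zf:
        header = {
            "version": CHECKPOINT_VERSION,
            "config": config.to_dict(),
            "meta": meta or {},
            "weights": sorted(params),
        }
        zf.writestr("header.json", json.dumps(header))
        for name, arr in params.items():
            buf = io.BytesIO()
            np.save(buf, arr)
            zf.writestr(f"weights/{name}.npy", buf.getvalue())


def load_checkpoint(path: str) -> tuple[ModelConfig, dict[str, np.ndarray], dict[str, Any]]:
    with zipfile.ZipFile(path) as zf:
        header = json.loads(zf.read("header.json"))
        if header.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {header.get('version')}")
        config = ModelConfig.from_dict(header["config"])
        params = {}
        for name in header["weights"]:
            params[name] = np.load(io.BytesIO(zf.read(f"weights/{name}.npy")))
    return config, params, header.get("meta", {})
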