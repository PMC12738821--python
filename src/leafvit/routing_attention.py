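"""Bi-level routing sparse attention with local context enhancement.

The mechanism prunes token-to-token attention in two stages. The H x W token
grid is cut into S x S non-overlapping regions; region-level query/key
summaries (arithmetic means) build an adjacency matrix A_r = Q_r K_r^T whose
row-wise top-k indices I_r say which k regions each region may attend to.
Token-level attention then runs only over the gathered keys/values of those
routed regions, and a depthwise ("deep") convolution of the value grid is
added as a local context enhancement term:

    O = Attention(Q, K_g, V_g) + LCE(V)

At k = S^2 with a zero LCE kernel the construction collapses exactly to
dense attention over all H*W tokens, which is the main correctness oracle.

Ties in the top-k routing are broken toward the lower region index so the
routing index is platform-independent. Routing is per-head by default
(region summaries are taken after the per-head Q/K projection); set
``share_routing`` to average the adjacency over heads and share one index.

The CLS token of a ViT sequence does not live on the grid: in
``biformer_layer`` the CLS token attends densely over the full sequence,
and the CLS key/value is appended to every region's gathered set so patch
tokens always keep one global route. This preserves the CLS-based
classification readout and makes k = S^2 with zero LCE coincide exactly
with dense attention over the whole sequence.
"""

from __future__ import annotations

import functools

import numpy as np

from .layers import softmax

# contraction-order-optimised einsum hits BLAS kernels on the hot paths
_einsum = functools.partial(np.einsum, optimize=True)

__all__ = [
    "partition_regions",
    "unpartition_regions",
    "project_qkv",
    "route_regions",
    "gather_kv",
    "routed_attention",
    "biformer_layer",
    "depthwise_conv2d",
]


# ---------------------------------------------------------------------------
# region partition


def _region_permutation(H: int, W: int, S: int) -> np.ndarray:
    """Flat-index permutation: position j in region-major order -> raster index."""
    rh, rw = H // S, W // S
    idx = np.arange(H * W).reshape(H, W)
    # (S, rh, S, rw) -> (S, S, rh, rw): regions in raster order, raster within
    return idx.reshape(S, rh, S, rw).transpose(0, 2, 1, 3).reshape(-1)


def partition_regions(feature_map: np.ndarray, S: int) -> np.ndarray:
    """Reshape an H x W x C map into (S^2, HW/S^2, C) contiguous region blocks."""
    H, W, C = feature_map.shape
    if H % S or W % S:
        raise ValueError(f"S={S} does not partition a {H}x{W} grid")
    perm = _region_permutation(H, W, S)
    flat = feature_map.reshape(H * W, C)
    return flat[perm].reshape(S * S, (H * W) // (S * S), C)


def unpartition_regions(regions: np.ndarray, H: int, W: int) -> np.ndarray:
    """Inverse of :func:`partition_regions`."""
    nR, t, C = regions.shape
    S = int(round(np.sqrt(nR)))
    if S * S != nR or S * S * t != H * W:
        raise ValueError("region array inconsistent with the stated grid")
    perm = _region_permutation(H, W, S)
    flat = np.empty((H * W, C), dtype=regions.dtype)
    flat[perm] = regions.reshape(H * W, C)
    return flat.reshape(H, W, C)


# ---------------------------------------------------------------------------
# projections, routing, gathering


def project_qkv(Xr: np.ndarray, Wq: np.ndarray, Wk: np.ndarray, Wv: np.ndarray):
    """Q = Xr Wq, K = Xr Wk, V = Xr Wv with the region layout preserved."""
    if Xr.shape[-1] != Wq.shape[0]:
        raise ValueError("projection width does not match token width")
    return Xr @ Wq, Xr @ Wk, Xr @ Wv


def topk_rows(Ar: np.ndarray, k: int) -> np.ndarray:
    """Row-wise top-k indices of Ar, descending score, ties to lower index."""
    nR = Ar.shape[-1]
    if not 1 <= k <= nR:
        raise ValueError(f"routing_k must lie in [1, {nR}]")
    # stable argsort of -Ar keeps the lower index first among equal scores
    return np.argsort(-Ar, axis=-1, kind="stable")[..., :k]


def route_regions(Q: np.ndarray, K: np.ndarray, k: int) -> np.ndarray:
    """Region-level routing index I_r from per-region token queries/keys.

    Q, K: (S^2, tokens_per_region, dk). Region summaries are arithmetic means
    over each region's tokens; A_r = Q_r K_r^T; rows are pruned to their k
    largest entries.
    """
    Qr = Q.mean(axis=1)
    Kr = K.mean(axis=1)
    Ar = Qr @ Kr.T
    return topk_rows(Ar, k)


def gather_kv(K: np.ndarray, V: np.ndarray, Ir: np.ndarray):
    """Concatenate each region's routed keys/values in I_r row order."""
    nR = K.shape[0]
    if Ir.min() < 0 or Ir.max() >= nR:
        raise IndexError("routing index out of range")
    nr, k = Ir.shape
    t, C = K.shape[1], K.shape[2]
    Kg = K[Ir].reshape(nr, k * t, C)
    Vg = V[Ir].reshape(nr, k * t, C)
    return Kg, Vg


# ---------------------------------------------------------------------------
# depthwise convolution (LCE)


def depthwise_conv2d(grid: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Per-channel 'same' cross-correlation of a (..., H, W, C) value grid.

    ``kernel`` has shape (C, kh, kw): one kernel per channel, no
    cross-channel mixing, zero padding.
    """
    C, kh, kw = kernel.shape
    if grid.shape[-1] != C:
        raise ValueError("kernel channels do not match the grid")
    ph, pw = kh // 2, kw // 2
    pad = [(0, 0)] * (grid.ndim - 3) + [(ph, kh - 1 - ph), (pw, kw - 1 - pw), (0, 0)]
    padded = np.pad(grid, pad)
    win = np.lib.stride_tricks.sliding_window_view(padded, (kh, kw), axis=(-3, -2))
    # win: (..., H, W, C, kh, kw)
    return _einsum("...cij,cij->...c", win, kernel)


def _depthwise_conv2d_backward(dout: np.ndarray, grid: np.ndarray, kernel: np.ndarray):
    C, kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    pad = [(0, 0)] * (grid.ndim - 3) + [(ph, kh - 1 - ph), (pw, kw - 1 - pw), (0, 0)]
    padded = np.pad(grid, pad)
    win = np.lib.stride_tricks.sliding_window_view(padded, (kh, kw), axis=(-3, -2))
    dkernel = _einsum("...cij,...c->cij", win, dout)
    # gradient to the input: correlate dout with the flipped kernel
    dpad = [(0, 0)] * (grid.ndim - 3) + [(kh - 1 - ph, ph), (kw - 1 - pw, pw), (0, 0)]
    dout_p = np.pad(dout, dpad)
    dwin = np.lib.stride_tricks.sliding_window_view(dout_p, (kh, kw), axis=(-3, -2))
    dgrid = _einsum("...cij,cij->...c", dwin, kernel[:, ::-1, ::-1])
    return dgrid, dkernel


# ---------------------------------------------------------------------------
# routed attention on one feature map (single projection, no heads)


def routed_attention(
    Q: np.ndarray,
    Kg: np.ndarray,
    Vg: np.ndarray,
    V: np.ndarray,
    lce_kernel: np.ndarray | None,
    grid_shape: tuple[int, int],
) -> np.ndarray:
    """O = Attention(Q, K_g, V_g) + LCE(V) in region layout.

    Q and V are (S^2, t, C) region arrays; Kg/Vg are the gathered
    (S^2, k*t, C) arrays; the LCE depthwise convolution acts on V arranged
    back on its ``grid_shape`` grid.
    """
    if not (np.all(np.isfinite(Q)) and np.all(np.isfinite(Kg))):
        raise FloatingPointError("non-finite routed-attention input")
    dk = Q.shape[-1]
    scores = _einsum("rqc,rkc->rqk", Q, Kg) / float(np.sqrt(dk))
    A = softmax(scores, axis=-1)
    out = _einsum("rqk,rkc->rqc", A, Vg)
    if lce_kernel is not None:
        H, W = grid_shape
        vgrid = unpartition_regions(V, H, W)
        lce = depthwise_conv2d(vgrid, lce_kernel)
        out = out + partition_regions(lce, int(round(np.sqrt(Q.shape[0]))))
    return out


# ---------------------------------------------------------------------------
# batched multi-head BiFormer attention (used inside encoder layers)


def biformer_attention_forward(x: np.ndarray, params: dict, config):
    """Routed multi-head attention over a (B, N+1, d) token batch.

    Patch tokens attend over their routed regions; the CLS token (row 0)
    attends densely over the full sequence. Heads are concatenated and
    projected by Wo, mirroring the dense path.
    """
    Wq, Wk, Wv, Wo = params["Wq"], params["Wk"], params["Wv"], params["Wo"]
    lce_kernel = params["lce"]
    B, T, d = x.shape
    g = config.grid_size
    S = config.region_grid
    kroute = config.routing_k
    h, _, dk = Wq.shape
    nR = S * S
    t = (g * g) // nR

    Q = _einsum("btd,hdk->bhtk", x, Wq)
    K = _einsum("btd,hdk->bhtk", x, Wk)
    V = _einsum("btd,hdk->bhtk", x, Wv)

    perm = _region_permutation(g, g, S)
    inv_perm = np.empty_like(perm)
    inv_perm[perm] = np.arange(perm.size)

    # (B, h, nR, t, dk) region-major views of the patch tokens
    Qp = Q[:, :, 1:, :][:, :, perm, :].reshape(B, h, nR, t, dk)
    Kp = K[:, :, 1:, :][:, :, perm, :].reshape(B, h, nR, t, dk)
    Vp = V[:, :, 1:, :][:, :, perm, :].reshape(B, h, nR, t, dk)

    Qr = Qp.mean(axis=3)
    Kr = Kp.mean(axis=3)
    Ar = _einsum("bhrk,bhsk->bhrs", Qr, Kr)
    if config.share_routing:
        Ar = np.broadcast_to(Ar.mean(axis=1, keepdims=True), Ar.shape)
    Ir = topk_rows(Ar, kroute)  # (B, h, nR, k)

    bidx = np.arange(B)[:, None, None, None]
    hidx = np.arange(h)[None, :, None, None]
    Kg = Kp[bidx, hidx, Ir].reshape(B, h, nR, kroute * t, dk)
    Vg = Vp[bidx, hidx, Ir].reshape(B, h, nR, kroute * t, dk)
    # the CLS key/value joins every region's gathered set, so patch tokens
    # keep a global summary route and k = S^2 recovers dense attention
    cls_k = np.broadcast_to(K[:, :, None, 0:1, :], (B, h, nR, 1, dk))
    cls_v = np.broadcast_to(V[:, :, None, 0:1, :], (B, h, nR, 1, dk))
    Kg = np.concatenate([cls_k, Kg], axis=3)
    Vg = np.concatenate([cls_v, Vg], axis=3)

    scores = _einsum("bhrqk,bhrmk->bhrqm", Qp, Kg) / float(np.sqrt(dk))
    A = softmax(scores, axis=-1)
    Op = _einsum("bhrqm,bhrmk->bhrqk", A, Vg)  # (B, h, nR, t, dk)

    # local context enhancement on the value grid (all heads at once)
    vgrid = Vp.reshape(B, h, nR * t, dk)[:, :, inv_perm, :].reshape(B, h, g, g, dk)
    ker = lce_kernel.reshape(h, dk, *lce_kernel.shape[1:])
    lce = _einsum(
        "bhyxcij,hcij->bhyxc",
        _lce_windows(vgrid, ker.shape[-2:]),
        ker,
    )
    patch_out = Op.reshape(B, h, nR * t, dk)[:, :, inv_perm, :]
    patch_out = patch_out + lce.reshape(B, h, g * g, dk)

    # CLS row: dense attention over every token
    q_cls = Q[:, :, 0, :]
    s_cls = _einsum("bhk,bhtk->bht", q_cls, K) / float(np.sqrt(dk))
    A_cls = softmax(s_cls, axis=-1)
    o_cls = _einsum("bht,bhtk->bhk", A_cls, V)

    heads = np.concatenate([o_cls[:, :, None, :], patch_out], axis=2)  # (B,h,T,dk)
    concat = heads.transpose(0, 2, 1, 3).reshape(B, T, h * dk)
    out = concat @ Wo
    cache = (
        x, Wq, Wk, Wv, Wo, lce_kernel, Q, K, V, Qp, Kp, Vp, Ir, Kg, Vg, A,
        A_cls, vgrid, concat, perm, inv_perm, (B, T, d, g, S, h, dk, nR, t, kroute),
    )
    return out, cache


def _lce_windows(vgrid: np.ndarray, kshape: tuple[int, int]) -> np.ndarray:
    kh, kw = kshape
    ph, pw = kh // 2, kw // 2
    pad = [(0, 0), (0, 0), (ph, kh - 1 - ph), (pw, kw - 1 - pw), (0, 0)]
    padded = np.pad(vgrid, pad)
    return np.lib.stride_tricks.sliding_window_view(padded, (kh, kw), axis=(2, 3))


def biformer_attention_backward(dout: np.ndarray, cache):
    (x, Wq, Wk, Wv, Wo, lce_kernel, Q, K, V, Qp, Kp, Vp, Ir, Kg, Vg, A,
     A_cls, vgrid, concat, perm, inv_perm, dims) = cache
    B, T, d, g, S, h, dk, nR, t, kroute = dims

    dWo = concat.reshape(-1, d).T @ dout.reshape(-1, d)
    dconcat = dout @ Wo.T
    dheads = dconcat.reshape(B, T, h, dk).transpose(0, 2, 1, 3)
    do_cls = dheads[:, :, 0, :]
    dpatch = dheads[:, :, 1:, :]  # (B, h, N, dk) raster order

    # -- LCE branch
    ker = lce_kernel.reshape(h, dk, *lce_kernel.shape[1:])
    dlce_grid = dpatch.reshape(B, h, g, g, dk)
    kh, kw = ker.shape[-2:]
    win = _lce_windows(vgrid, (kh, kw))
    dker = _einsum("bhyxcij,bhyxc->hcij", win, dlce_grid)
    ph, pw = kh // 2, kw // 2
    pad = [(0, 0), (0, 0), (kh - 1 - ph, ph), (kw - 1 - pw, pw), (0, 0)]
    dwin = np.lib.stride_tricks.sliding_window_view(
        np.pad(dlce_grid, pad), (kh, kw), axis=(2, 3)
    )
    dvgrid = _einsum("bhyxcij,hcij->bhyxc", dwin, ker[:, :, ::-1, ::-1])
    dVp = dvgrid.reshape(B, h, g * g, dk)[:, :, perm, :].reshape(B, h, nR, t, dk)

    # -- routed attention branch
    dOp = dpatch[:, :, perm, :].reshape(B, h, nR, t, dk)
    dA = _einsum("bhrqk,bhrmk->bhrqm", dOp, Vg)
    dVg = _einsum("bhrqm,bhrqk->bhrmk", A, dOp)
    dscores = A * (dA - np.sum(dA * A, axis=-1, keepdims=True))
    dscores /= float(np.sqrt(dk))
    dQp = _einsum("bhrqm,bhrmk->bhrqk", dscores, Kg)
    dKg = _einsum("bhrqm,bhrqk->bhrmk", dscores, Qp)

    bidx = np.arange(B)[:, None, None, None]
    hidx = np.arange(h)[None, :, None, None]
    dK_cls_route = dKg[:, :, :, 0, :].sum(axis=2)
    dV_cls_route = dVg[:, :, :, 0, :].sum(axis=2)
    dKp = np.zeros_like(Kp)
    np.add.at(dKp, (bidx, hidx, Ir), dKg[:, :, :, 1:, :].reshape(B, h, nR, kroute, t, dk))
    np.add.at(dVp, (bidx, hidx, Ir), dVg[:, :, :, 1:, :].reshape(B, h, nR, kroute, t, dk))

    # -- CLS dense branch
    dA_cls = _einsum("bhk,bhtk->bht", do_cls, V)
    dV_cls = _einsum("bht,bhk->bhtk", A_cls, do_cls)
    ds_cls = A_cls * (dA_cls - np.sum(dA_cls * A_cls, axis=-1, keepdims=True))
    ds_cls /= float(np.sqrt(dk))
    dq_cls = _einsum("bht,bhtk->bhk", ds_cls, K)
    dK_cls = _einsum("bht,bhk->bhtk", ds_cls, Q[:, :, 0, :])

    # -- assemble token-level gradients
    dQ = np.zeros_like(Q)
    dK = np.zeros_like(K)
    dV = np.zeros_like(V)
    dQ[:, :, 0, :] = dq_cls
    dK += dK_cls
    dV += dV_cls
    dK[:, :, 0, :] += dK_cls_route
    dV[:, :, 0, :] += dV_cls_route
    dQ[:, :, 1:, :] += dQp.reshape(B, h, nR * t, dk)[:, :, inv_perm, :]
    dK[:, :, 1:, :] += dKp.reshape(B, h, nR * t, dk)[:, :, inv_perm, :]
    dV[:, :, 1:, :] += dVp.reshape(B, h, nR * t, dk)[:, :, inv_perm, :]

    dx = (
        _einsum("bhtk,hdk->btd", dQ, Wq)
        + _einsum("bhtk,hdk->btd", dK, Wk)
        + _einsum("bhtk,hdk->btd", dV, Wv)
    )
    grads = {
        "Wq": _einsum("btd,bhtk->hdk", x, dQ),
        "Wk": _einsum("btd,bhtk->hdk", x, dK),
        "Wv": _einsum("btd,bhtk->hdk", x, dV),
        "Wo": dWo,
        "lce": dker.reshape(lce_kernel.shape),
    }
    return dx, grads


def biformer_layer(x: np.ndarray, params: dict, config) -> np.ndarray:
    """Routed attention sublayer for one (N+1) x d token sequence.

    Drop-in replacement for :func:`leafvit.core_vit.multi_head_attention`;
    the caller wires the result into the post-norm residual slot.
    """
    if x.shape[0] != config.num_patches + 1:
        raise ValueError("sequence length does not match the configured grid")
    out, _ = biformer_attention_forward(x[None], params, config)
    return out[0]
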