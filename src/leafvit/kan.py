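"""Kolmogorov-Arnold layers with B-spline learnable univariate functions.

Every edge (input j -> unit i) of a layer carries its own univariate
function f_{i,j}(x) = sum_k c_{i,j,k} B_k(x; t) on a knot vector t shared by
the whole layer (the parameter-sharing the formulation allows); unit outputs
are plain sums z_i = sum_j f_{i,j}(x_j). A curvature regulariser
lambda * sum_{functions} integral (f'')^2 dx discourages wiggly splines, and
an adaptive-width diagnostic m_new = floor(m_init * ||grad|| / alpha)
suggests a hidden width from observed gradient magnitudes.

B-spline bases are evaluated by the Cox-de Boor recursion on clamped uniform
knots; inputs are clamped to the knot domain (the head input is LayerNorm-ed,
so a [-3, 3] domain covers ~99.7% of it). Derivatives use the standard
knot-difference operator, which also yields an exact piecewise-polynomial
Gram matrix for the curvature penalty via Gauss-Legendre quadrature.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KnotVector",
    "SplineFunction",
    "KANLayer",
    "KANHead",
    "KANNetwork",
    "uniform_clamped_knots",
    "bspline_basis",
    "bspline_basis_matrix",
    "bspline_derivative_matrix",
    "second_derivative_gram",
    "kan_forward",
    "smoothness_penalty",
    "adapt_width",
]


# ---------------------------------------------------------------------------
# knot vectors and basis evaluation


@dataclass(frozen=True)
class KnotVector:
    """Nondecreasing knot sequence defining K = len(t) - degree - 1 bases."""

    t: tuple[float, ...]
    degree: int = 3

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        if np.any(np.diff(t) < 0):
            raise ValueError("knots must be nondecreasing")
        if len(t) < 2 * (self.degree + 1):
            raise ValueError("knot vector too short for the stated degree")

    @property
    def num_basis(self) -> int:
        return len(self.t) - self.degree - 1

    @property
    def domain(self) -> tuple[float, float]:
        p = self.degree
        return (self.t[p], self.t[len(self.t) - p - 1])

    def array(self) -> np.ndarray:
        return np.asarray(self.t, dtype=float)


def uniform_clamped_knots(K: int, degree: int = 3, a: float = -3.0, b: float = 3.0) -> KnotVector:
    """Clamped knots: a and b repeated degree+1 times, interior uniform."""
    if K < degree + 1:
        raise ValueError("need at least degree+1 basis functions")
    interior = np.linspace(a, b, K - degree + 1)[1:-1]
    t = np.concatenate([[a] * (degree + 1), interior, [b] * (degree + 1)])
    return KnotVector(tuple(t), degree)


def _basis_matrix_raw(x: np.ndarray, t: np.ndarray, degree: int) -> np.ndarray:
    """Cox-de Boor recursion; returns (..., len(t)-degree-1) basis values.

    Half-open interval convention with the right domain endpoint folded into
    the last nonempty interval, so partition of unity holds on the closed
    domain. 0/0 terms in the recursion are taken as 0.
    """
    x = np.asarray(x, dtype=float)
    n0 = len(t) - 1
    B = np.zeros(x.shape + (n0,))
    for k in range(n0):
        B[..., k] = (x >= t[k]) & (x < t[k + 1])
    nonempty = np.nonzero(np.diff(t) > 0)[0]
    if nonempty.size:
        last = nonempty[-1]
        B[..., last] = np.where(
            (x >= t[last]) & (x <= t[last + 1]), 1.0, B[..., last]
        )
    for p in range(1, degree + 1):
        nb = len(t) - p - 1
        newB = np.zeros(x.shape + (nb,))
        for k in range(nb):
            d1 = t[k + p] - t[k]
            d2 = t[k + p + 1] - t[k + 1]
            term = 0.0
            if d1 > 0:
                term = (x - t[k]) / d1 * B[..., k]
            if d2 > 0:
                term = term + (t[k + p + 1] - x) / d2 * B[..., k + 1]
            newB[..., k] = term
        B = newB
    return B


def bspline_basis_matrix(x: np.ndarray, knots: KnotVector) -> np.ndarray:
    """Basis values B_k(x) for clamped-to-domain inputs; shape (..., K)."""
    a, b = knots.domain
    xc = np.clip(x, a, b)
    return _basis_matrix_raw(xc, knots.array(), knots.degree)


def bspline_basis(x: float, knots: KnotVector, K: int | None = None) -> np.ndarray:
    """K basis values at a scalar x (Cox-de Boor; nonnegative, <= degree+1 nonzero)."""
    vals = bspline_basis_matrix(np.asarray(x, dtype=float), knots)
    if K is not None and K != knots.num_basis:
        raise ValueError(f"knot vector defines {knots.num_basis} bases, not {K}")
    return vals


def _derivative_operator(t: np.ndarray, degree: int) -> tuple[np.ndarray, np.ndarray]:
    """Matrix D with (Dc) the degree-1-lower coefficients of f'; new knots."""
    K = len(t) - degree - 1
    D = np.zeros((K - 1, K))
    for k in range(K - 1):
        dt = t[k + degree + 1] - t[k + 1]
        if dt > 0:
            D[k, k] = -degree / dt
            D[k, k + 1] = degree / dt
    return D, t[1:-1]


def bspline_derivative_matrix(x: np.ndarray, knots: KnotVector, order: int = 1) -> np.ndarray:
    """d^order/dx^order of each basis function at x; zero outside the domain
    (inputs are clamped, so the function is constant there)."""
    t = knots.array()
    degree = knots.degree
    if order > degree:
        return np.zeros(np.shape(x) + (knots.num_basis,))
    D = np.eye(knots.num_basis)
    for _ in range(order):
        Dstep, t = _derivative_operator(t, degree)
        degree -= 1
        D = Dstep @ D
    a, b = knots.domain
    inside = (np.asarray(x) >= a) & (np.asarray(x) <= b)
    low = _basis_matrix_raw(np.clip(x, a, b), t, degree)
    return np.where(inside[..., None], low @ D, 0.0)


def _mass_matrix(t: np.ndarray, degree: int) -> np.ndarray:
    """Gram matrix integral B_m B_n dx by per-interval Gauss-Legendre
    quadrature, exact for the piecewise degree-2p integrand."""
    K = len(t) - degree - 1
    npts = degree + 1
    nodes, weights = np.polynomial.legendre.leggauss(npts)
    M = np.zeros((K, K))
    for i in range(len(t) - 1):
        lo, hi = t[i], t[i + 1]
        if hi <= lo:
            continue
        xm = 0.5 * (hi + lo) + 0.5 * (hi - lo) * nodes
        w = 0.5 * (hi - lo) * weights
        Bv = _basis_matrix_raw(xm, t, degree)
        M += np.einsum("q,qm,qn->mn", w, Bv, Bv)
    return M


def second_derivative_gram(knots: KnotVector) -> np.ndarray:
    """G with c^T G c = integral (f'')^2 dx for f = sum_k c_k B_k."""
    t = knots.array()
    degree = knots.degree
    if degree < 2:
        return np.zeros((knots.num_basis, knots.num_basis))
    D = np.eye(knots.num_basis)
    for _ in range(2):
        Dstep, t = _derivative_operator(t, degree)
        degree -= 1
        D = Dstep @ D
    M = _mass_matrix(t, degree)
    return D.T @ M @ D


def greville_abscissae(knots: KnotVector) -> np.ndarray:
    """Knot averages; as coefficients they reproduce f(x) = x on the domain."""
    t = knots.array()
    p = knots.degree
    return np.array([t[k + 1 : k + p + 1].mean() for k in range(knots.num_basis)])


# ---------------------------------------------------------------------------
# univariate spline functions


@dataclass
class SplineFunction:
    """One univariate KAN function f(x) = sum_k c_k B_k(x; t)."""

    knots: KnotVector
    coeffs: np.ndarray

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (self.knots.num_basis,):
            raise ValueError(
                f"expected {self.knots.num_basis} coefficients, got {self.coeffs.shape}"
            )

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return bspline_basis_matrix(x, self.knots) @ self.coeffs

    def curvature(self) -> float:
        """integral (f'')^2 dx over the knot domain."""
        G = second_derivative_gram(self.knots)
        return float(self.coeffs @ G @ self.coeffs)

    def to_json(self) -> str:
        return json.dumps(
            {
                "knots": list(self.knots.t),
                "degree": self.knots.degree,
                "coeffs": self.coeffs.tolist(),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "SplineFunction":
        d = json.loads(s)
        return cls(KnotVector(tuple(d["knots"]), d["degree"]), np.asarray(d["coeffs"]))


# ---------------------------------------------------------------------------
# layers and networks


class KANLayer:
    """n -> m layer: z_i = sum_j f_{i,j}(x_j), coefficients (m, n, K)."""

    def __init__(self, knots: KnotVector, coeffs: np.ndarray):
        coeffs = np.asarray(coeffs, dtype=float)
        if coeffs.ndim != 3 or coeffs.shape[2] != knots.num_basis:
            raise ValueError("coefficients must have shape (out_dim, in_dim, K)")
        self.knots = knots
        self.coeffs = coeffs

    @property
    def in_dim(self) -> int:
        return self.coeffs.shape[1]

    @property
    def out_dim(self) -> int:
        return self.coeffs.shape[0]

    def forward(self, x: np.ndarray):
        """x: (B, n) -> (B, m); returns (output, cache)."""
        if x.shape[-1] != self.in_dim:
            raise ValueError(f"expected {self.in_dim} inputs, got {x.shape[-1]}")
        basis = bspline_basis_matrix(x, self.knots)  # (B, n, K)
        out = np.einsum("bjk,ijk->bi", basis, self.coeffs)
        return out, (x, basis)

    def backward(self, dout: np.ndarray, cache):
        """Gradients of a scalar loss: returns (dx, dcoeffs)."""
        x, basis = cache
        dcoeffs = np.einsum("bi,bjk->ijk", dout, basis)
        dbasis_x = bspline_derivative_matrix(x, self.knots)  # (B, n, K)
        fprime = np.einsum("ijk,bjk->bij", self.coeffs, dbasis_x)
        dx = np.einsum("bi,bij->bj", dout, fprime)
        return dx, dcoeffs

    def curvature(self) -> float:
        G = second_derivative_gram(self.knots)
        return float(np.einsum("ijk,kl,ijl->", self.coeffs, G, self.coeffs))

    def curvature_grad(self) -> np.ndarray:
        G = second_derivative_gram(self.knots)
        return 2.0 * np.einsum("kl,ijl->ijk", G, self.coeffs)

    def functions(self):
        for i in range(self.out_dim):
            for j in range(self.in_dim):
                yield SplineFunction(self.knots, self.coeffs[i, j])


# the classification head is a single KAN stage d -> num_classes
KANHead = KANLayer


@dataclass
class KANNetwork:
    """Stack of KAN layers ending in one scalar per class.

    ``lam`` weighs the curvature penalty; ``alpha`` is the width-adaptation
    constant of the between-trainings diagnostic.
    """

    layers: list[KANLayer] = field(default_factory=list)
    lam: float = 0.1
    alpha: float = 1.0

    def forward(self, x: np.ndarray):
        caches = []
        for i, layer in enumerate(self.layers):
            if i > 0:
                # deeper-layer inputs are clamped to the shared knot domain
                a, b = layer.knots.domain
                x = np.clip(x, a, b)
            x, c = layer.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, dout: np.ndarray, caches):
        dcoeffs = []
        for layer, cache in zip(reversed(self.layers), reversed(caches)):
            dout, dc = layer.backward(dout, cache)
            dcoeffs.append(dc)
        return dout, list(reversed(dcoeffs))


def kan_forward(x: np.ndarray, net: KANNetwork | KANLayer) -> np.ndarray:
    """Evaluate a KAN on a single n-vector (or a (B, n) batch)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None]
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite KAN input")
    out, _ = net.forward(x)
    return out[0] if single else out


def smoothness_penalty(net: KANNetwork | KANLayer, lam: float | None = None) -> float:
    """lambda * sum over univariate functions of integral (f'')^2 dx."""
    if isinstance(net, KANLayer):
        layers, lam = [net], (0.1 if lam is None else lam)
    else:
        layers, lam = net.layers, (net.lam if lam is None else lam)
    total = 0.0
    for layer in layers:
        if layer.knots.degree < 2:
            warnings.warn(
                "curvature penalty undefined for degree < 2; counted as 0",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        total += layer.curvature()
    return lam * total


def adapt_width(m_init: int, grad_norm: float, alpha: float) -> int:
    """Suggested hidden width floor(m_init * ||grad|| / alpha), at least 1.

    A diagnostic reported between trainings, never applied mid-training.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if grad_norm < 0:
        raise ValueError("grad_norm must be nonnegative")
    return max(1, int(np.floor(m_init * grad_norm / alpha)))
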