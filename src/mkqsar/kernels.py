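"""Convex-combination (multiple) kernels for epsilon-SVR.

Three base kernels:

* linear      K_L(x, z)   = x.z
* RBF         K_RBF(x, z) = exp(-||x - z||^2 / (2 sigma^2))
* polynomial  K_P(x, z)   = (x.z)^q,  homogeneous, q in {1, 2, 3}

and their convex mixtures

    K = a * K_RBF + b * K_P + (1 - a - b) * K_L,   a, b >= 0,  a + b <= 1.

A convex combination of Mercer kernels is again a Mercer kernel (non-negative
sums of PSD Gram matrices stay PSD), so every valid mixture yields a valid
SVR kernel; :func:`check_psd` provides the numerical verification.

Families: ``single`` is pure RBF (a=1), ``double`` is RBF + polynomial
(b = 1 - a), ``triple`` adds the linear kernel with weight 1 - a - b.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "KernelSpec",
    "k_linear",
    "k_rbf",
    "k_poly",
    "k_mixture",
    "gram_matrix",
    "cross_gram",
    "check_psd",
]

_FAMILIES = ("single", "double", "triple")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus parameters (sigma, q) and mixture weights (a, b).

    The linear weight is implicit: 1 - a - b.  Family fixes the weights:
    ``single`` forces a=1, b=0; ``double`` forces b = 1 - a.
    """

    family: str = "single"
    sigma: float = 1.0
    q: int = 2
    a: float = 1.0
    b: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.q not in (1, 2, 3):
            raise ValueError(f"polynomial order q must be 1, 2 or 3, got {self.q}")
        a, b = self.a, self.b
        if self.family == "single":
            if not (a == 1.0 and b == 0.0):
                raise ValueError("single-kernel spec requires a=1, b=0")
        elif self.family == "double":
            if not (0.0 <= a <= 1.0) or abs(b - (1.0 - a)) > 1e-12:
                raise ValueError("double-kernel spec requires 0<=a<=1 and b=1-a")
        else:
            if a < 0 or b < 0 or a + b > 1.0 + 1e-12:
                raise ValueError("triple-kernel spec requires a,b>=0 and a+b<=1")

    @property
    def weights(self) -> tuple[float, float, float]:
        """(RBF, polynomial, linear) mixture weights."""
        return (self.a, self.b, max(0.0, 1.0 - self.a - self.b))


def _pair(x, z) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    if x.shape != z.shape:
        raise ValueError(f"length mismatch: {x.size} vs {z.size}")
    return x, z


def k_linear(x, z) -> float:
    """Inner product x.z."""
    x, z = _pair(x, z)
    return float(x @ z)


def k_rbf(x, z, sigma: float) -> float:
    """Gaussian kernel exp(-||x-z||^2 / (2 sigma^2)); value in (0, 1]."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    x, z = _pair(x, z)
    return float(np.exp(-np.sum((x - z) ** 2) / (2.0 * sigma**2)))


def k_poly(x, z, q: int) -> float:
    """Homogeneous polynomial kernel (x.z)^q, q in {1, 2, 3}."""
    if q not in (1, 2, 3):
        raise ValueError(f"polynomial order q must be 1, 2 or 3, got {q}")
    x, z = _pair(x, z)
    return float((x @ z) ** q)


def k_mixture(x, z, spec: KernelSpec) -> float:
    """Convex mixture a*K_RBF + b*K_P + (1-a-b)*K_L under the given spec."""
    wa, wb, wl = spec.weights
    out = 0.0
    if wa:
        out += wa * k_rbf(x, z, spec.sigma)
    if wb:
        out += wb * k_poly(x, z, spec.q)
    if wl:
        out += wl * k_linear(x, z)
    return float(out)


def cross_gram(X, Z, spec: KernelSpec) -> np.ndarray:
    """Kernel matrix K[i, j] = k(X_i, Z_j) under the given spec (vectorized)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if X.shape[1] != Z.shape[1]:
        raise ValueError(f"feature mismatch: {X.shape[1]} vs {Z.shape[1]}")
    wa, wb, wl = spec.weights
    G = np.zeros((X.shape[0], Z.shape[0]))
    if wa:
        G += wa * np.exp(-cdist(X, Z, "sqeuclidean") / (2.0 * spec.sigma**2))
    if wb or wl:
        ip = X @ Z.T
        if wb:
            G += wb * ip**spec.q
        if wl:
            G += wl * ip
    return G


def gram_matrix(X, spec: KernelSpec) -> np.ndarray:
    """Symmetric Gram matrix of the sample rows of X (symmetrized exactly)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty sample matrix")
    G = cross_gram(X, X, spec)
    return (G + G.T) / 2.0


def check_psd(G: np.ndarray, tol: float = 1e-8) -> bool:
    """True iff the smallest eigenvalue of symmetric G is >= -tol_abs.

    ``tol`` is relative to the largest eigenvalue magnitude (with an absolute
    floor of ``tol`` itself for near-zero matrices).
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("Gram matrix must be square")
    if not np.allclose(G, G.T, atol=1e-10, rtol=0.0):
        raise ValueError("Gram matrix must be symmetric")
    eig = np.linalg.eigvalsh((G + G.T) / 2.0)
    scale = max(1.0, float(np.abs(eig).max()))
    return bool(eig.min() >= -tol * scale)
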