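"""Epsilon-SVR fitted through its dual, over an arbitrary kernel.

The primal problem is

    min_{w, b, xi}  1/2 ||w||^2 + (C/l) sum_i (xi_i + xi_i^*)
    s.t.            |y_i - (w.phi(x_i) + b)| <= eps + slack

and the dual solved here, in the beta_i = alpha_i - alpha_i^* coefficients,

    min  1/2 beta' K beta + eps sum|beta| - y' beta
    s.t. sum beta = 0,  |beta_i| <= C/l,

with K the Gram matrix of the chosen kernel.  Note the box bound is C/l
(the primal penalty is written C/l per slack): a ``box_scaling="absolute"``
flag switches to the plain C bound used by most SVM libraries.

The solver is sequential minimal optimization: the dual is expressed in 2l
non-negative multipliers (alpha, alpha*), and at each step the most
KKT-violating pair (first-order working-set selection) is optimized exactly
along the equality-preserving direction.  Fitting is deterministic.

The fitted function (the decision function of the dual) is

    f(x) = sum_i beta_i K(x_i, x) + b

with the bias b recovered from the KKT conditions: the mean of
y_i - sum_j beta_j K(x_j, x_i) -/+ eps over free support vectors, or the
midpoint of the feasible bias interval when no multiplier is free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .kernels import KernelSpec, cross_gram, gram_matrix

__all__ = ["SvrHyperParams", "SvrModel", "SvrConvergenceError", "fit_svr", "predict",
           "kkt_report", "save_model", "load_model"]

SUPPORT_TOL = 1e-8


class SvrConvergenceError(RuntimeError):
    """SMO failed to reach the KKT tolerance within the pass budget."""

    def __init__(self, violation: float, passes: int):
        self.violation = violation
        self.passes = passes
        super().__init__(
            f"SMO did not converge: KKT violation {violation:.3e} after {passes} passes"
        )


@dataclass(frozen=True)
class SvrHyperParams:
    """Tube half-width epsilon, penalty C and training size l.

    The effective per-coefficient box bound is C/l (``per_sample``) or C
    (``absolute``).
    """

    epsilon: float
    c: float
    l: int = 0
    box_scaling: str = "per_sample"

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.c <= 0:
            raise ValueError("C must be positive")
        if self.box_scaling not in ("per_sample", "absolute"):
            raise ValueError(f"unknown box_scaling {self.box_scaling!r}")

    def box_bound(self, l: int) -> float:
        return self.c / l if self.box_scaling == "per_sample" else self.c


@dataclass
class Standardizer:
    """Per-feature center/scale learned on training data."""

    mean: np.ndarray
    scale: np.ndarray
    enabled: bool = True

    @classmethod
    def fit(cls, X: np.ndarray, enabled: bool = True) -> "Standardizer":
        if not enabled:
            p = X.shape[1]
            return cls(np.zeros(p), np.ones(p), enabled=False)
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0  # constant features pass through centred
        return cls(mean, scale, enabled=True)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale


@dataclass
class SvrModel:
    """Fitted epsilon-SVR: dual coefficients, bias, kernel and bookkeeping."""

    dual_coefficients: np.ndarray  # beta_i = alpha_i - alpha_i*
    bias: float
    support_indices: np.ndarray
    training_inputs: np.ndarray  # standardized
    standardizer: Standardizer
    kernel: KernelSpec
    hyper: SvrHyperParams
    dual_objective: float
    kkt_violation: float = 0.0

    def predict(self, X_new) -> np.ndarray:
        return predict(self, X_new)


@njit(cache=True)
def _smo_loop(K, y, eps, box, tol, max_passes):  # pragma: no cover - compiled
    l = y.size
    n2 = 2 * l
    # z = (alpha, alpha*), sign s = +1 for alpha, -1 for alpha*; beta = alpha - alpha*
    z = np.zeros(n2)
    s = np.empty(n2)
    grad = np.empty(n2)  # gradient of 1/2 z'Qz + p'z, Q_pq = s_p s_q K, p_p = eps - s_p y
    for i in range(l):
        s[i] = 1.0
        s[i + l] = -1.0
        grad[i] = eps - y[i]
        grad[i + l] = eps + y[i]
    violation = np.inf
    converged = False
    for _ in range(max_passes):
        # first-order working-set selection: i maximizes -s*grad over the up
        # set, j minimizes it over the low set
        m = -np.inf
        M = np.inf
        i = -1
        j = -1
        for p in range(n2):
            g = -s[p] * grad[p]
            in_up = (s[p] > 0.0 and z[p] < box - 1e-14) or (s[p] < 0.0 and z[p] > 1e-14)
            in_low = (s[p] > 0.0 and z[p] > 1e-14) or (s[p] < 0.0 and z[p] < box - 1e-14)
            if in_up and g > m:
                m = g
                i = p
            if in_low and g < M:
                M = g
                j = p
        if i < 0 or j < 0:
            violation = 0.0
            converged = True
            break
        violation = m - M
        if violation < tol:
            converged = True
            break
        ii = i % l
        jj = j % l
        a = K[ii, ii] + K[jj, jj] - 2.0 * K[ii, jj]
        if a < 1e-12:
            a = 1e-12
        t = violation / a
        # clip so both coordinates stay inside [0, box]
        cap_i = box - z[i] if s[i] > 0.0 else z[i]
        cap_j = z[j] if s[j] > 0.0 else box - z[j]
        if t > cap_i:
            t = cap_i
        if t > cap_j:
            t = cap_j
        z[i] += s[i] * t
        z[j] -= s[j] * t
        for p in range(n2):
            grad[p] += t * s[p] * (K[p % l, ii] - K[p % l, jj])
    return z, grad, violation, converged


def _smo(K: np.ndarray, y: np.ndarray, eps: float, box: float,
         tol: float = 1e-6, max_passes: int = 200_000) -> tuple[np.ndarray, float, float]:
    """Solve the 2l-variable dual by maximal-violating-pair SMO.

    Returns (beta, bias, final KKT violation).  Raises
    :class:`SvrConvergenceError` if the violation is still above tol after
    ``max_passes`` pair updates.
    """
    l = y.size
    z, grad, violation, converged = _smo_loop(
        np.ascontiguousarray(K), np.ascontiguousarray(y, dtype=np.float64),
        float(eps), float(box), float(tol), int(max_passes),
    )
    if not converged:
        raise SvrConvergenceError(float(violation), max_passes)
    s = np.concatenate([np.ones(l), -np.ones(l)])
    beta = z[:l] - z[l:]
    # bias from free multipliers (KKT: b = -s_p * grad_p there), else midpoint
    free = (z > SUPPORT_TOL * max(box, 1.0)) & (z < box - SUPPORT_TOL * max(box, 1.0))
    neg_s_grad = -s * grad
    if free.any():
        b = float(neg_s_grad[free].mean())
    else:
        up = ((s > 0) & (z < box - 1e-14)) | ((s < 0) & (z > 1e-14))
        low = ((s > 0) & (z > 1e-14)) | ((s < 0) & (z < box - 1e-14))
        hi = neg_s_grad[up].max() if up.any() else 0.0
        lo = neg_s_grad[low].min() if low.any() else 0.0
        b = float((hi + lo) / 2.0)
    return beta, b, float(max(violation, 0.0))


def dual_objective_value(K: np.ndarray, y: np.ndarray, eps: float, beta: np.ndarray) -> float:
    """Minimized dual objective 1/2 b'Kb + eps*sum|b| - y'b at the given beta."""
    return float(0.5 * beta @ K @ beta + eps * np.abs(beta).sum() - y @ beta)


def fit_svr(X, y, spec: KernelSpec, hyper: SvrHyperParams, *,
            standardize: bool = True, tol: float = 1e-6,
            max_passes: int = 200_000) -> SvrModel:
    """Fit epsilon-SVR on (X, y) with the given kernel and hyperparameters.

    Features are z-scored with training statistics before kernel evaluation
    unless ``standardize=False``; sigma is then interpreted on the
    standardized scale.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    l = y.size
    if X.shape[0] != l:
        raise ValueError(f"{X.shape[0]} rows of X for {l} responses")
    if l < 2:
        raise ValueError("need at least 2 training samples")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")

    std = Standardizer.fit(X, enabled=standardize)
    Xs = std.transform(X)
    K = gram_matrix(Xs, spec)
    eig_min = float(np.linalg.eigvalsh(K).min())
    if eig_min < -1e-6 * max(1.0, float(np.abs(K).max())):
        raise ValueError(
            f"Gram matrix is not positive semidefinite (min eigenvalue {eig_min:.3e}); "
            "revise the kernel spec"
        )
    box = hyper.box_bound(l)
    beta, bias, violation = _smo(K, y, hyper.epsilon, box, tol=tol, max_passes=max_passes)
    support = np.where(np.abs(beta) > SUPPORT_TOL)[0]
    return SvrModel(
        dual_coefficients=beta,
        bias=bias,
        support_indices=support,
        training_inputs=Xs,
        standardizer=std,
        kernel=spec,
        hyper=SvrHyperParams(hyper.epsilon, hyper.c, l, hyper.box_scaling),
        dual_objective=dual_objective_value(K, y, hyper.epsilon, beta),
        kkt_violation=violation,
    )


def predict(model: SvrModel, X_new) -> np.ndarray:
    """Evaluate f(x) = sum_i beta_i K(x_i, x) + b on new compounds."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.training_inputs.shape[1]:
        raise ValueError(
            f"feature-count mismatch: model has {model.training_inputs.shape[1]}, "
            f"input has {X_new.shape[1]}"
        )
    Xs = model.standardizer.transform(X_new)
    Kx = cross_gram(Xs, model.training_inputs, model.kernel)
    return Kx @ model.dual_coefficients + model.bias


@dataclass
class KktReport:
    """Per-sample KKT diagnostics of a fitted model on its training data."""

    residuals: np.ndarray
    beta: np.ndarray
    box: float
    epsilon: float
    tol: float
    inside_violations: list = field(default_factory=list)
    free_violations: list = field(default_factory=list)
    bound_violations: list = field(default_factory=list)

    @property
    def n_violations(self) -> int:
        return len(self.inside_violations) + len(self.free_violations) + len(self.bound_violations)

    @property
    def converged(self) -> bool:
        return self.n_violations == 0


def kkt_report(model: SvrModel, X, y, tol: float = 1e-4) -> KktReport:
    """Check the optimality conditions sample by sample.

    * beta_i = 0        ->  |r_i| <= eps + tol (inside the tube)
    * 0 < |beta_i| < C/l ->  |r_i| = eps +- tol (on the tube boundary)
    * |beta_i| = C/l     ->  |r_i| >= eps - tol (outside or on the tube)

    with r_i = y_i - f(x_i).
    """
    y = np.asarray(y, dtype=float).ravel()
    r = y - predict(model, X)
    beta = model.dual_coefficients
    box = model.hyper.box_bound(y.size)
    rep = KktReport(residuals=r, beta=beta, box=box, epsilon=model.hyper.epsilon, tol=tol)
    eps = model.hyper.epsilon
    for i in range(y.size):
        bi, ri = abs(beta[i]), abs(r[i])
        if bi <= SUPPORT_TOL:
            if ri > eps + tol:
                rep.inside_violations.append((i, float(r[i])))
        elif bi >= box - SUPPORT_TOL * max(box, 1.0):
            if ri < eps - tol:
                rep.bound_violations.append((i, float(r[i])))
        else:
            if abs(ri - eps) > tol:
                rep.free_violations.append((i, float(r[i])))
    return rep


_SCHEMA_VERSION = 1


def save_model(model: SvrModel, path: str | Path) -> None:
    """Serialize a fitted model to diffable JSON."""
    payload = {
        "schema_version": _SCHEMA_VERSION,
        "kernel": {"family": model.kernel.family, "sigma": model.kernel.sigma,
                   "q": model.kernel.q, "a": model.kernel.a, "b": model.kernel.b},
        "hyper": {"epsilon": model.hyper.epsilon, "c": model.hyper.c,
                  "l": model.hyper.l, "box_scaling": model.hyper.box_scaling},
        "dual_coefficients": model.dual_coefficients.tolist(),
        "bias": model.bias,
        "support_indices": model.support_indices.tolist(),
        "training_inputs": model.training_inputs.tolist(),
        "standardizer": {"mean": model.standardizer.mean.tolist(),
                         "scale": model.standardizer.scale.tolist(),
                         "enabled": model.standardizer.enabled},
        "dual_objective": model.dual_objective,
        "kkt_violation": model.kkt_violation,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> SvrModel:
    """Load a model serialized by :func:`save_model`."""
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != _SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema in {path}")
    std = payload["standardizer"]
    return SvrModel(
        dual_coefficients=np.array(payload["dual_coefficients"]),
        bias=float(payload["bias"]),
        support_indices=np.array(payload["support_indices"], dtype=int),
        training_inputs=np.array(payload["training_inputs"]),
        standardizer=Standardizer(np.array(std["mean"]), np.array(std["scale"]),
                                  enabled=bool(std["enabled"])),
        kernel=KernelSpec(**payload["kernel"]),
        hyper=SvrHyperParams(**payload["hyper"]),
        dual_objective=float(payload["dual_objective"]),
        kkt_violation=float(payload["kkt_violation"]),
    )
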