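"""Model validation statistics for QSAR regression.

Implements the usual internal and external validation suite: coefficient of
determination R^2 (1 - SSres/SStot), RMSE, MAE, Lin's concordance
correlation coefficient (CCC), the external predictivity coefficients
Q2_F1 / Q2_F2, a seeded 4:1 random train/test split, and k-fold
cross-validated mean R^2 (R2cv).

Conventions
-----------
* R^2 defaults to 1 - SSres/SStot with the mean of the evaluated observed
  series; a squared-Pearson variant is available because published QSAR
  tables do not always say which convention they use.
* RMSE is sqrt(mean squared error); :func:`mse` is exposed alongside since
  some published "RMSE" magnitudes are consistent with the un-rooted MSE.
* CCC uses population (1/n) moments, per Lin's original definition; a
  sample-moment (1/(n-1)) variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "PairedSeries",
    "MetricsReport",
    "r_squared",
    "rmse",
    "mse",
    "mae",
    "ccc",
    "q2_external",
    "split_4_to_1",
    "kfold_r2cv",
    "metrics_report",
]


@dataclass
class PairedSeries:
    """Aligned observed / predicted response vectors."""

    observed: np.ndarray
    predicted: np.ndarray

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float).ravel()
        self.predicted = np.asarray(self.predicted, dtype=float).ravel()
        if self.observed.size == 0:
            raise ValueError("empty series")
        if self.observed.shape != self.predicted.shape:
            raise ValueError(
                f"length mismatch: {self.observed.size} observed vs "
                f"{self.predicted.size} predicted"
            )
        if not (np.isfinite(self.observed).all() and np.isfinite(self.predicted).all()):
            raise ValueError("series must be finite")

    @property
    def n(self) -> int:
        return self.observed.size


def _as_pair(p, predicted=None) -> PairedSeries:
    if isinstance(p, PairedSeries):
        return p
    return PairedSeries(np.asarray(p), np.asarray(predicted))


def r_squared(p, predicted=None, *, convention: Literal["ss", "pearson2"] = "ss") -> float:
    """Coefficient of determination.

    ``ss`` (default): 1 - sum((y - yhat)^2) / sum((y - ybar)^2), with ybar the
    mean of the evaluated observed series; defined as 0 when the observed
    series is constant.  ``pearson2``: squared Pearson correlation.
    """
    pair = _as_pair(p, predicted)
    y, yhat = pair.observed, pair.predicted
    if convention == "pearson2":
        sy, syh = y.std(), yhat.std()
        if sy == 0 or syh == 0:
            return 0.0
        return float(np.corrcoef(y, yhat)[0, 1] ** 2)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0
    return float(1.0 - np.sum((y - yhat) ** 2) / ss_tot)


def rmse(p, predicted=None) -> float:
    """Root mean squared error."""
    pair = _as_pair(p, predicted)
    return float(np.sqrt(np.mean((pair.observed - pair.predicted) ** 2)))


def mse(p, predicted=None) -> float:
    """Mean squared error (the un-rooted companion of :func:`rmse`)."""
    pair = _as_pair(p, predicted)
    return float(np.mean((pair.observed - pair.predicted) ** 2))


def mae(p, predicted=None) -> float:
    """Mean absolute error."""
    pair = _as_pair(p, predicted)
    return float(np.mean(np.abs(pair.observed - pair.predicted)))


def ccc(p, predicted=None, *, moments: Literal["population", "sample"] = "population") -> float:
    """Lin's concordance correlation coefficient.

    2*s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2) with population (1/n) moments
    by default.  Conventions for degenerate input: 1 if both series are
    constant and equal, 0 if either series is constant otherwise.
    """
    pair = _as_pair(p, predicted)
    y, yhat = pair.observed, pair.predicted
    ddof = 0 if moments == "population" else 1
    sy2 = float(y.var(ddof=ddof))
    syh2 = float(yhat.var(ddof=ddof))
    if sy2 == 0.0 and syh2 == 0.0:
        return 1.0 if y[0] == yhat[0] else 0.0
    if sy2 == 0.0 or syh2 == 0.0:
        return 0.0
    n = pair.n
    cov = float(np.sum((y - y.mean()) * (yhat - yhat.mean())) / (n - ddof))
    return float(2.0 * cov / (sy2 + syh2 + (y.mean() - yhat.mean()) ** 2))


def q2_external(p, training_mean: float, variant: Literal["F1", "F2"] = "F1",
                predicted=None) -> float:
    """External predictivity coefficient Q2_F1 or Q2_F2.

    F1 references the training-set mean in the denominator,
    F2 the mean of the evaluated (test) series itself:

        Q2_F1 = 1 - sum((y - yhat)^2) / sum((y - ybar_train)^2)
        Q2_F2 = 1 - sum((y - yhat)^2) / sum((y - ybar_test)^2)
    """
    pair = _as_pair(p, predicted)
    y, yhat = pair.observed, pair.predicted
    ref = float(training_mean) if variant == "F1" else float(y.mean())
    denom = float(np.sum((y - ref) ** 2))
    if denom == 0.0:
        raise ZeroDivisionError("zero denominator in external Q2")
    return float(1.0 - np.sum((y - yhat) ** 2) / denom)


def split_4_to_1(ids: Sequence, seed: int) -> tuple[list, list]:
    """Random 4:1 train/test partition of the given ids.

    Test size is ceil(n/5), sampled without replacement; deterministic for a
    given seed.  For the 57-compound table this gives 45 train / 12 test.
    """
    ids = list(ids)
    n = len(ids)
    if n < 5:
        raise ValueError(f"need at least 5 ids for a 4:1 split, got {n}")
    n_test = -(-n // 5)  # ceil(n/5)
    rng = np.random.default_rng(seed)
    test_pos = set(rng.choice(n, size=n_test, replace=False).tolist())
    train = [ids[i] for i in range(n) if i not in test_pos]
    test = [ids[i] for i in range(n) if i in test_pos]
    return train, test


def kfold_r2cv(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    fit: Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]],
    seed: int,
) -> float:
    """Mean held-out R^2 over a seeded even k-fold partition.

    ``fit(X_train, y_train)`` must return a predictor ``X -> yhat``.  Folds
    differ in size by at most one; assignment is a seeded shuffle.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    scores = []
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        if mask.sum() < 2:
            raise ValueError("training fold too small to fit")
        predictor = fit(X[mask], y[mask])
        scores.append(r_squared(y[fold], predictor(X[fold])))
    return float(np.mean(scores))


@dataclass
class MetricsReport:
    """Bundle of the validation statistics for one observed/predicted series."""

    r2: float
    rmse: float
    mse: float
    mae: float
    ccc: float
    q2_f1: float
    q2_f2: float
    n: int
    reference_mean: float

    def as_dict(self) -> dict[str, float]:
        return {
            "r2": self.r2, "rmse": self.rmse, "mse": self.mse, "mae": self.mae,
            "ccc": self.ccc, "q2_f1": self.q2_f1, "q2_f2": self.q2_f2,
            "n": self.n, "reference_mean": self.reference_mean,
        }


def metrics_report(p, training_mean: float | None = None, predicted=None) -> MetricsReport:
    """Compute the full statistics suite for one paired series.

    ``training_mean`` is the reference mean used by Q2_F1; it defaults to the
    mean of the evaluated observed series (in which case F1 == F2).
    """
    pair = _as_pair(p, predicted)
    ref = float(pair.observed.mean()) if training_mean is None else float(training_mean)
    return MetricsReport(
        r2=r_squared(pair),
        rmse=rmse(pair),
        mse=mse(pair),
        mae=mae(pair),
        ccc=ccc(pair),
        q2_f1=q2_external(pair, ref, "F1"),
        q2_f2=q2_external(pair, ref, "F2"),
        n=pair.n,
        reference_mean=ref,
    )
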