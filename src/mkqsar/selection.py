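"""Heuristic forward descriptor selection (CODESSA/BMLR-style).

Reproduces the classic heuristic-method pipeline used to pick a small
multilinear QSAR model out of a large descriptor pool:

1. **Preprocessing** drops descriptors that are missing for any compound,
   have negligible variance, or are collinear with a better descriptor
   (pairwise |Pearson r| above a cut; the member less correlated with the
   response is removed).
2. **Forward expansion** keeps every one-descriptor model passing the
   F-statistic (> 1), R^2 and Student-t gates, then grows each retained
   model by one descriptor at a time (candidates too correlated with an
   already-included descriptor are skipped), keeping a beam of the best
   models per size and stopping a branch when its F-statistic no longer
   improves.
3. **Size choice** stops where adding a descriptor no longer improves R^2
   by a configurable increment.

All ordinary least-squares fits include an intercept by default (the
published descriptor table prints slopes only; a flag drops the intercept).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .descriptors import DescriptorMatrix

__all__ = [
    "SelectionConfig",
    "MlrModel",
    "SelectionResult",
    "preprocess_descriptors",
    "fit_mlr",
    "forward_select",
    "choose_model_size",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds of the heuristic selection.

    r_collinear
        pairwise |Pearson r| above which two descriptors are considered
        collinear during preprocessing (published convention: 0.8).
    var_min
        minimum column variance (computed on z-scored columns, so this is a
        relative floor).
    r2_min, t_min
        gates on one-descriptor models: R^2 and min |t|-value.
    r_dup
        max |r| allowed between a candidate and any already-included
        descriptor during expansion.
    beam_width
        models kept per size during the forward search.
    max_size / delta_r2_stop
        largest model grown, and the R^2 increment below which
        :func:`choose_model_size` stops.
    """

    r_collinear: float = 0.8
    var_min: float = 1e-10
    r2_min: float = 0.01
    t_min: float = 1.5
    r_dup: float = 0.8
    beam_width: int = 10
    max_size: int = 12
    delta_r2_stop: float = 0.02
    intercept: bool = True


@dataclass
class MlrModel:
    """One multilinear regression model over a named descriptor subset."""

    descriptor_names: list[str]
    coefficients: np.ndarray
    intercept: float
    r2: float
    s2: float
    f_stat: float
    t_values: np.ndarray

    @property
    def size(self) -> int:
        return len(self.descriptor_names)

    def predict(self, m: DescriptorMatrix) -> np.ndarray:
        X = m.subset(self.descriptor_names).values
        return X @ self.coefficients + self.intercept


@dataclass
class SelectionResult:
    """Best model per size plus the preprocessing removal report."""

    models_by_size: dict[int, MlrModel]
    removed_descriptors: list[tuple[str, str]] = field(default_factory=list)
    chosen_size: int = 0


def _corr_with(y: np.ndarray, col: np.ndarray) -> float:
    sy, sc = y.std(), col.std()
    if sy == 0 or sc == 0:
        return 0.0
    return float(np.corrcoef(y, col)[0, 1])


def preprocess_descriptors(
    m: DescriptorMatrix, y, cfg: SelectionConfig = SelectionConfig()
) -> tuple[DescriptorMatrix, list[tuple[str, str]]]:
    """Drop unusable descriptor columns; report every removal with its rule.

    Removal rules, applied in order: ``missing`` (any NaN), ``low-variance``
    (variance of the z-scored column below ``var_min``, i.e. essentially
    constant), ``collinear`` (pair with |r| > ``r_collinear``; the member
    with smaller |corr with y| goes, ties broken by column order).
    """
    y = np.asarray(y, dtype=float).ravel()
    if m.n_compounds < 2:
        raise ValueError("need at least 2 compounds")
    if y.size != m.n_compounds:
        raise ValueError(f"{y.size} responses for {m.n_compounds} compounds")

    removed: list[tuple[str, str]] = []
    keep: list[str] = []
    for j, name in enumerate(m.col_names):
        col = m.values[:, j]
        if np.isnan(col).any():
            removed.append((name, "missing"))
            continue
        # variance gate relative to the column's own magnitude, so "small
        # variation" means small compared to the values, not in raw units
        v = col.var()
        if v <= 0 or (v / max(np.abs(col).max() ** 2, 1e-300)) < cfg.var_min:
            removed.append((name, "low-variance"))
            continue
        keep.append(name)

    # collinearity pass on survivors
    sub = m.subset(keep)
    n_keep = len(keep)
    if n_keep:
        R = np.corrcoef(sub.values, rowvar=False).reshape(n_keep, n_keep)
        ycorr = np.array([abs(_corr_with(y, sub.values[:, j])) for j in range(n_keep)])
        dropped = np.zeros(n_keep, dtype=bool)
        for a in range(n_keep):
            if dropped[a]:
                continue
            for b in range(a + 1, n_keep):
                if dropped[b]:
                    continue
                if abs(R[a, b]) > cfg.r_collinear:
                    # drop the one less correlated with the response; on a
                    # tie the later column goes
                    loser = a if ycorr[a] < ycorr[b] else b
                    dropped[loser] = True
                    removed.append((keep[loser], "collinear"))
                    if loser == a:
                        break
        keep = [keep[j] for j in range(n_keep) if not dropped[j]]

    if not keep:
        raise ValueError(
            "preprocessing removed every descriptor; relax var_min/r_collinear"
        )
    return m.subset(keep), removed


def fit_mlr(m: DescriptorMatrix, y, *, intercept: bool = True) -> MlrModel:
    """Ordinary least squares of y on the descriptor columns of ``m``.

    Returns slopes, intercept, R^2 = 1 - SSres/SStot, residual variance s^2,
    the overall F statistic and per-slope t values.  A constant response
    (SStot = 0) yields R^2 = 0 and F = 0 by convention.
    """
    y = np.asarray(y, dtype=float).ravel()
    n, k = m.n_compounds, m.n_descriptors
    if m.has_missing:
        raise ValueError("descriptor matrix contains missing values")
    if n <= k + (1 if intercept else 0):
        raise ValueError(f"need more than {k + 1} compounds to fit {k} descriptors")
    X = np.column_stack([m.values, np.ones(n)]) if intercept else m.values
    ncol = X.shape[1]
    rank = np.linalg.matrix_rank(X)
    if rank < ncol:
        raise ValueError(f"rank-deficient design over descriptors {m.col_names}")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    resid = y - fitted
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    dof = n - ncol
    s2 = ss_res / dof if dof > 0 else 0.0
    if ss_tot == 0.0:
        r2, f_stat = 0.0, 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
        denom = (1.0 - r2) / (n - k - 1)
        f_stat = float((r2 / k) / denom) if denom > 0 else np.inf
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * s2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_all = np.where(se > 0, coef / se, 0.0)
    slopes = coef[:k] if intercept else coef
    b0 = float(coef[k]) if intercept else 0.0
    return MlrModel(
        descriptor_names=list(m.col_names),
        coefficients=np.asarray(slopes),
        intercept=b0,
        r2=float(r2),
        s2=float(s2),
        f_stat=float(f_stat),
        t_values=np.asarray(t_all[:k]),
    )


def _try_fit(m: DescriptorMatrix, names: list[str], y, intercept: bool) -> MlrModel | None:
    try:
        return fit_mlr(m.subset(names), y, intercept=intercept)
    except ValueError:
        return None


def forward_select(
    m: DescriptorMatrix, y, cfg: SelectionConfig = SelectionConfig()
) -> SelectionResult:
    """Beam forward search for the best multilinear model at each size.

    Size-1 models must pass F > 1, R^2 > ``r2_min`` and |t| >= ``t_min``;
    retained models are expanded one descriptor at a time (skipping
    candidates with |r| >= ``r_dup`` to an included descriptor), a branch
    stopping once its F statistic no longer increases.  R^2 ties in beam
    pruning are broken by lexicographic descriptor-name order.
    """
    y = np.asarray(y, dtype=float).ravel()
    names = list(m.col_names)
    p = len(names)
    R = np.corrcoef(m.values, rowvar=False).reshape(p, p) if p > 1 else np.ones((1, 1))
    col_idx = {nm: j for j, nm in enumerate(names)}

    seeds: list[MlrModel] = []
    gate_log = []
    for nm in names:
        model = _try_fit(m, [nm], y, cfg.intercept)
        if model is None:
            continue
        ok = (
            model.f_stat > 1.0
            and model.r2 > cfg.r2_min
            and np.all(np.abs(model.t_values) >= cfg.t_min)
        )
        gate_log.append((nm, model.r2, model.f_stat, float(np.abs(model.t_values).min())))
        if ok:
            seeds.append(model)
    if not seeds:
        stats = ", ".join(f"{nm}: r2={r2:.3f} F={f:.2f} min|t|={t:.2f}" for nm, r2, f, t in gate_log[:10])
        raise ValueError(f"no single-descriptor model passes the gates ({stats} ...)")

    def beam_key(mod: MlrModel):
        return (-mod.r2, tuple(sorted(mod.descriptor_names)))

    beam = sorted(seeds, key=beam_key)[: cfg.beam_width]
    models_by_size: dict[int, MlrModel] = {1: beam[0]}

    for size in range(2, cfg.max_size + 1):
        children: dict[tuple, MlrModel] = {}
        for parent in beam:
            in_idx = [col_idx[nm] for nm in parent.descriptor_names]
            for nm in names:
                if nm in parent.descriptor_names:
                    continue
                j = col_idx[nm]
                if max(abs(R[j, i]) for i in in_idx) >= cfg.r_dup:
                    continue
                child = _try_fit(m, parent.descriptor_names + [nm], y, cfg.intercept)
                if child is None:
                    continue
                if child.f_stat <= parent.f_stat:
                    continue  # branch stops: normalized F no longer improves
                key = tuple(sorted(child.descriptor_names))
                if key not in children or child.r2 > children[key].r2:
                    children[key] = child
        if not children:
            break
        beam = sorted(children.values(), key=beam_key)[: cfg.beam_width]
        models_by_size[size] = beam[0]

    result = SelectionResult(models_by_size=models_by_size)
    result.chosen_size = choose_model_size(result, cfg)
    return result


def choose_model_size(result: SelectionResult, cfg: SelectionConfig = SelectionConfig()) -> int:
    """Smallest size s with r2(s+1) - r2(s) < ``delta_r2_stop``, else the largest."""
    sizes = sorted(result.models_by_size)
    if not sizes:
        raise ValueError("empty selection result")
    for s in sizes:
        if s + 1 in result.models_by_size:
            gain = result.models_by_size[s + 1].r2 - result.models_by_size[s].r2
            if gain < cfg.delta_r2_stop:
                return s
        else:
            return s
    return sizes[-1]
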