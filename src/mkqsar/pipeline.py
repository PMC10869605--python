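"""End-to-end modelling pipeline: select descriptors, tune, fit, score.

The workflow mirrors the published study design: the descriptor subset is
chosen by heuristic forward selection over all compounds (descriptor
identity only — model coefficients never see the test set), the data are
split 4:1 into training and test compounds, the multilinear model is
refitted on the training set, and the SVR hyperparameters are tuned by PSO
with cross-validated RMSE on the training set only.  Both models are then
scored on the held-out compounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .descriptors import DescriptorMatrix
from .metrics import r_squared, rmse, split_4_to_1
from .pso import PsoConfig, SearchSpace, cv_rmse_objective, decode_position, optimize
from .selection import SelectionConfig, fit_mlr, forward_select, preprocess_descriptors
from .svr import SvrModel, fit_svr, predict
from .synthetic import make_paper_like

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Held-out comparison of the linear model and the tuned SVR."""

    selected: list[str]
    r2_linear_train: float
    r2_linear_test: float
    r2_svr_train: float
    r2_svr_test: float
    rmse_svr_test: float
    best_position: np.ndarray
    cv_rmse: float
    svr_model: SvrModel

    @property
    def svr_beats_linear(self) -> bool:
        return self.r2_svr_test > self.r2_linear_test


def run_pipeline(
    m: DescriptorMatrix,
    y: np.ndarray,
    seed: int,
    *,
    family: str = "triple",
    n_descriptors: int = 8,
    selection_cfg: SelectionConfig | None = None,
    pso_cfg: PsoConfig | None = None,
    folds: int = 5,
) -> PipelineResult:
    """Select descriptors, split 4:1, fit linear and PSO-tuned SVR, score both."""
    y = np.asarray(y, dtype=float).ravel()
    sel_cfg = selection_cfg or SelectionConfig(max_size=n_descriptors)
    clean, _ = preprocess_descriptors(m, y, sel_cfg)
    result = forward_select(clean, y, sel_cfg)
    top_size = max(result.models_by_size)
    names = result.models_by_size[top_size].descriptor_names

    train_idx, test_idx = split_4_to_1(list(range(len(y))), seed)
    sub = m.subset(names)
    Xtr, Xte = sub.values[train_idx], sub.values[test_idx]
    ytr, yte = y[train_idx], y[test_idx]

    # linear model refitted on training compounds only
    dtr = DescriptorMatrix(Xtr, [str(i) for i in train_idx], names)
    lin = fit_mlr(dtr, ytr, intercept=sel_cfg.intercept)
    lin_tr = lin.predict(dtr)
    lin_te = Xte @ lin.coefficients + lin.intercept

    space = SearchSpace(family)
    cfg = pso_cfg or PsoConfig(swarm_size=12, iter_max=30, stall_patience=10, seed=seed)
    if cfg.seed != seed:
        cfg = PsoConfig(**{**cfg.__dict__, "seed": seed})
    objective = cv_rmse_objective(Xtr, ytr, space, folds=folds, seed=seed)
    best_x, best_fit, _ = optimize(objective, space, cfg)
    hyper, spec = decode_position(best_x, space)
    model = fit_svr(Xtr, ytr, spec, hyper)

    return PipelineResult(
        selected=names,
        r2_linear_train=r_squared(ytr, lin_tr),
        r2_linear_test=r_squared(yte, lin_te),
        r2_svr_train=r_squared(ytr, predict(model, Xtr)),
        r2_svr_test=r_squared(yte, predict(model, Xte)),
        rmse_svr_test=rmse(yte, predict(model, Xte)),
        best_position=best_x,
        cv_rmse=best_fit,
        svr_model=model,
    )


def paper_like_comparison(seed: int, **kwargs) -> PipelineResult:
    """Run the pipeline on one study-scale synthetic dataset."""
    m, y, _ = make_paper_like(seed)
    return run_pipeline(m, y, seed, **kwargs)
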