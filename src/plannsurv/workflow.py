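"""End-to-end orchestration: split-sample protocol, cross-validated
hyper-parameter tuning of the discrete-time network on the Integrated
Brier Score, and side-by-side evaluation of Cox-family and network
models on a held-out test set.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import cox as cox_mod
from . import metrics as metrics_mod
from .discretize import IntervalGrid, SurvivalDataset, to_long_test, to_long_train
from .metrics import EvaluationReport
from .plann import PlannConfig, PlannModel, build_plann, hazards_to_survival, predict_hazards, train

__all__ = ["TuningGrid", "split_sample", "tune_plann", "compare_models"]


@dataclass
class TuningGrid:
    """Candidate hyper-parameter lists for the grid search (network) and
    the LASSO penalty; the tuning criterion is the cross-validated IBS
    (minimized)."""

    activation: tuple[str, ...] = ("sigmoid",)
    node_size: tuple[int, ...] = (8,)
    dropout_rate: tuple[float, ...] = (0.1,)
    learning_rate: tuple[float, ...] = (0.2,)
    momentum: tuple[float, ...] = (0.9,)
    event_class_weight: tuple[float, ...] = (1.0,)
    n_epochs: int = 30
    batch_size: int | str = 256
    lambda_grid: tuple[float, ...] = ()
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("activation", "node_size", "dropout_rate", "learning_rate",
                     "momentum", "event_class_weight"):
            if not getattr(self, name):
                raise ValueError(f"empty candidate list for {name}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")

    def configs(self, n_hidden_layers: int = 1):
        for act, h, dr, lr, mom, ecw in itertools.product(
            self.activation, self.node_size, self.dropout_rate,
            self.learning_rate, self.momentum, self.event_class_weight,
        ):
            yield PlannConfig(
                n_hidden_layers=n_hidden_layers, node_size=h, activation=act,
                dropout_rate=dr, learning_rate=lr, momentum=mom,
                event_class_weight=ecw, n_epochs=self.n_epochs,
                batch_size=self.batch_size, seed=self.seed,
            )


def split_sample(
    data: SurvivalDataset,
    train_frac: float = 2.0 / 3.0,
    seed: int = 0,
) -> tuple[SurvivalDataset, SurvivalDataset]:
    """Random complementary train/test split stratified by event status
    (the split-sample protocol: 2/3 training, 1/3 test by default)."""
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must be in (0, 1)")
    idx = np.arange(data.n)
    try:
        tr, te = train_test_split(
            idx, train_size=train_frac, stratify=data.event, random_state=seed
        )
    except ValueError as exc:
        raise ValueError("a stratum is too small to split") from exc
    return data.subset(np.sort(tr)), data.subset(np.sort(te))


def _plann_ibs_on(
    model: PlannModel,
    test: SurvivalDataset,
    grid: IntervalGrid,
    censoring: metrics_mod.CensoringEstimate,
) -> tuple[float, dict[float, float]]:
    long_te = to_long_test(test, grid)
    surv = hazards_to_survival(predict_hazards(model, long_te))
    times = np.asarray(grid.boundaries[1:])
    curve = metrics_mod.prediction_error_curve(surv, test, times, censoring)
    return metrics_mod.integrated_brier(curve, t_hor=grid.upper), curve


def tune_plann(
    train_data: SurvivalDataset,
    grid: TuningGrid,
    interval_grid: IntervalGrid,
    n_hidden_layers: int = 1,
) -> tuple[PlannConfig, pd.DataFrame]:
    """Grid search by k-fold cross-validation on the training set.

    Each configuration's score is the mean fold IBS: the network is
    trained on the other folds and evaluated on the held-out fold, with
    the censoring distribution estimated on the training folds (no
    leakage).  Ties favour the simpler model (smaller node size, then
    lower dropout)."""
    skf = StratifiedKFold(n_splits=grid.n_folds, shuffle=True, random_state=grid.seed)
    folds = list(skf.split(np.zeros(train_data.n), train_data.event))
    rows = []
    for config in grid.configs(n_hidden_layers):
        fold_scores = []
        failed = False
        for tr_idx, va_idx in folds:
            tr = train_data.subset(tr_idx)
            va = train_data.subset(va_idx)
            try:
                model = build_plann(config, len(train_data.covariate_names), interval_grid.k)
                train(model, to_long_train(tr, interval_grid))
                censoring = metrics_mod.reverse_km(tr)
                ibs, _ = _plann_ibs_on(model, va, interval_grid, censoring)
            except (RuntimeError, ValueError) as exc:
                warnings.warn(f"config {config} failed in a fold: {exc}", stacklevel=2)
                failed = True
                break
            fold_scores.append(ibs)
        rows.append(
            {
                "activation": config.activation,
                "node_size": config.node_size,
                "dropout_rate": config.dropout_rate,
                "learning_rate": config.learning_rate,
                "momentum": config.momentum,
                "event_class_weight": config.event_class_weight,
                "cv_ibs": np.nan if failed else float(np.mean(fold_scores)),
                "config": config,
            }
        )
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["cv_ibs"])
    if valid.empty:
        raise RuntimeError("every configuration failed during cross-validation")
    best = valid.sort_values(
        ["cv_ibs", "node_size", "dropout_rate"], kind="stable"
    ).iloc[0]
    return best["config"], table.drop(columns="config")


def _evaluate_cox(
    name: str,
    fit: cox_mod.CoxFit,
    test: SurvivalDataset,
    times: np.ndarray,
    t_hor: float,
    censoring: metrics_mod.CensoringEstimate,
) -> EvaluationReport:
    surv = cox_mod.predict_cox_survival(fit, test.covariates, times)
    curve = metrics_mod.prediction_error_curve(surv, test, times, censoring)
    ibs = metrics_mod.integrated_brier(curve, t_hor=t_hor)
    cidx = metrics_mod.concordance_index(fit.prognostic_index(test.covariates), test)
    return EvaluationReport(model=name, ibs=ibs, brier_by_time=curve,
                            t_hor=t_hor, n_test=test.n, c_index=cidx)


def compare_models(
    train_data: SurvivalDataset,
    test_data: SurvivalDataset,
    interval_grid: IntervalGrid,
    models: tuple[str, ...] = ("cox_all", "cox_backward", "cox_lasso", "plann_1h", "plann_2h"),
    plann_configs: dict[str, PlannConfig] | None = None,
    lambda_grid: tuple[float, ...] = (0.5, 2.0, 8.0, 32.0),
    seed: int = 0,
    external_models: dict | None = None,
) -> dict[str, EvaluationReport]:
    """Fit the requested models on the training set and evaluate all of
    them on the test set.

    Every model gets a prediction-error curve at the interval boundaries
    and its IBS; the C-index is reported only for models with a scalar
    risk ordering (the Cox prognostic index) and deliberately omitted for
    the discrete-hazard networks.  ``external_models`` may supply already
    fitted objects exposing ``predict_survival_matrix(test, times)`` (and
    optionally ``risk_score(test)``), e.g. a random survival forest
    adapter.
    """
    times = np.asarray(interval_grid.boundaries[1:])
    t_hor = interval_grid.upper
    censoring = metrics_mod.reverse_km(train_data)
    reports: dict[str, EvaluationReport] = {}
    p = len(train_data.covariate_names)
    default_cfg = PlannConfig(node_size=16, dropout_rate=0.1, learning_rate=0.2,
                              momentum=0.9, n_epochs=30, seed=seed)
    for name in models:
        if name == "cox_all":
            fit = cox_mod.fit_cox(train_data)
            reports[name] = _evaluate_cox(name, fit, test_data, times, t_hor, censoring)
        elif name == "cox_backward":
            fit = cox_mod.backward_eliminate(train_data)
            reports[name] = _evaluate_cox(name, fit, test_data, times, t_hor, censoring)
        elif name == "cox_lasso":
            lam, _ = cox_mod.select_lambda(train_data, lambda_grid, seed=seed)
            fit = cox_mod.fit_cox_lasso(train_data, lam)
            reports[name] = _evaluate_cox(name, fit, test_data, times, t_hor, censoring)
        elif name in ("plann_1h", "plann_2h"):
            layers = 1 if name == "plann_1h" else 2
            cfg = (plann_configs or {}).get(name, replace(default_cfg, n_hidden_layers=layers))
            model = build_plann(cfg, p, interval_grid.k)
            train(model, to_long_train(train_data, interval_grid))
            ibs, curve = _plann_ibs_on(model, test_data, interval_grid, censoring)
            reports[name] = EvaluationReport(model=name, ibs=ibs, brier_by_time=curve,
                                             t_hor=t_hor, n_test=test_data.n, c_index=None)
        else:
            raise ValueError(f"unknown model {name!r}")
    for name, obj in (external_models or {}).items():
        surv = np.asarray(obj.predict_survival_matrix(test_data, times), dtype=float)
        curve = metrics_mod.prediction_error_curve(surv, test_data, times, censoring)
        ibs = metrics_mod.integrated_brier(curve, t_hor=t_hor)
        cidx = None
        if hasattr(obj, "risk_score"):
            cidx = metrics_mod.concordance_index(obj.risk_score(test_data), test_data)
        reports[name] = EvaluationReport(model=name, ibs=ibs, brier_by_time=curve,
                                         t_hor=t_hor, n_test=test_data.n, c_index=cidx)
    return reports
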