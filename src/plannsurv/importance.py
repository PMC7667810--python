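"""Connection-weight relative importance for trained networks.

Garson's algorithm partitions the absolute connection weights of a
1-hidden-layer network to attribute a share of the output signal to each
input; the extension chains the same partition through a second hidden
layer.  The result is sign-blind: it ranks inputs by importance but says
nothing about the direction of their effect.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .plann import PlannModel

__all__ = [
    "garson_1h",
    "garson_2h",
    "relative_importance",
    "aggregate_importance",
    "rank_importance",
]

TIME_GROUP = "time"


def _names(model: PlannModel, n_inputs: int) -> list[str]:
    if model.feature_names is not None and len(model.feature_names) == n_inputs:
        return list(model.feature_names)
    return [f"input_{i}" for i in range(n_inputs)]


def _normalize(imp: np.ndarray, names: list[str]) -> pd.Series:
    total = imp.sum()
    if total <= 0:
        raise ValueError("all connection weights are zero; importance undefined")
    s = pd.Series(imp / total, index=names, name="importance")
    return s.sort_values(ascending=False, kind="stable")


def garson_1h(model: PlannModel) -> pd.Series:
    """Relative importance for a 1-hidden-layer network.

    For input i, hidden node j with input-hidden weights ``w_ij`` and
    hidden-output weights ``v_j`` (biases excluded): ``c_ij = |w_ij| /
    sum_i' |w_i'j| * |v_j|``; importances are ``sum_j c_ij`` normalized to
    total 1.
    """
    if model.config.n_hidden_layers != 1:
        raise ValueError("model has 2 hidden layers; use garson_2h")
    W = np.abs(model.weights[0][0])  # (n_in, h)
    v = np.abs(model.weights[1][0]).ravel()  # (h,)
    colsum = W.sum(axis=0)
    share = np.divide(W, colsum, out=np.zeros_like(W), where=colsum > 0)
    imp = share @ v
    return _normalize(imp, _names(model, W.shape[0]))


def garson_2h(model: PlannModel) -> pd.Series:
    """Extension of the partition to 2 hidden layers: the absolute-weight
    share is chained through both layers, ``c_ijl = (|w_ij|/sum_i'|w_i'j|)
    * (|u_jl|/sum_j'|u_j'l|) * |v_l|``, then summed over (j, l) and
    normalized."""
    if model.config.n_hidden_layers != 2:
        raise ValueError("model has 1 hidden layer; use garson_1h")
    W = np.abs(model.weights[0][0])  # (n_in, h1)
    U = np.abs(model.weights[1][0])  # (h1, h2)
    v = np.abs(model.weights[2][0]).ravel()  # (h2,)
    w_col = W.sum(axis=0)
    A = np.divide(W, w_col, out=np.zeros_like(W), where=w_col > 0)
    u_col = U.sum(axis=0)
    B = np.divide(U, u_col, out=np.zeros_like(U), where=u_col > 0)
    imp = A @ (B @ v)
    return _normalize(imp, _names(model, W.shape[0]))


def relative_importance(model: PlannModel) -> pd.Series:
    """Dispatch on the model depth."""
    if model.config.n_hidden_layers == 1:
        return garson_1h(model)
    return garson_2h(model)


def aggregate_importance(
    ri: pd.Series,
    group_map: Mapping[str, str],
    time_group: str = TIME_GROUP,
) -> pd.Series:
    """Sum per-level importances within each parent variable.

    Interval-indicator inputs (``interval_*``) are pooled into a single
    ``time`` entry so the time contribution can be reported separately
    from the covariates; the grand total is preserved.
    """
    parents = []
    for feat in ri.index:
        if feat in group_map:
            parents.append(group_map[feat])
        elif feat.startswith("interval_") or feat == "interval_midpoint":
            parents.append(time_group)
        else:
            raise KeyError(f"feature {feat!r} missing from group_map")
    agg = ri.groupby(pd.Index(parents, name="variable")).sum()
    return agg.sort_values(ascending=False, kind="stable").rename("importance")


def rank_importance(ri: pd.Series, top_n: int) -> list[tuple[str, float]]:
    """Top-n features by importance, descending; exact ties broken
    alphabetically for reproducible reports."""
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    order = sorted(ri.items(), key=lambda kv: (-kv[1], kv[0]))
    return order[:top_n]


def importance_report(
    ri: pd.Series,
    group_map: Mapping[str, str],
    path=None,
    time_path=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-table report: per-variable importance (time pooled) and the
    per-interval time contributions; optionally written as CSV."""
    agg = aggregate_importance(ri, group_map)
    variables = agg.reset_index().rename(columns={"index": "variable"})
    time_rows = ri[[f for f in ri.index if f.startswith("interval_")]]
    time_rows = time_rows.sort_index(key=lambda ix: [int(s.split("_")[1]) for s in ix])
    times = time_rows.reset_index().rename(columns={"index": "interval"})
    if path is not None:
        variables.to_csv(path, index=False)
    if time_path is not None:
        times.to_csv(time_path, index=False)
    return variables, times
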