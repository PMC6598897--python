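"""Posterior-predictive trajectories and Bayesian model averaging.

Trajectory means are computed per retained draw on the percentile scale,
each draw is mapped back through the inverse percentile transform, and
pointwise summaries (mean and a central credible interval, default 95%)
are taken over the back-transformed draws.  Because the inverse transform
is nonlinear, trajectories that are linear on the percentile scale are
generally nonlinear on the raw scale.

Model averaging treats the averaged posterior predictive as the
weight-proportional mixture of the per-model draw sets: the mixture mean
is the weighted sum of component means and interval endpoints are
weighted quantiles over the pooled draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import ConfigurationError, ValidationError
from ..transform import ECDFTransform
from .fit import PosteriorDraws


@dataclass
class PredictionSet:
    """Per (subject, time, marker) posterior predictive summaries.

    ``table`` has columns ``subject_id, time_years, marker, mean, lo, hi``;
    ``draws`` keeps the raw-scale draw matrix (n_points, S) aligned with
    the table rows, with per-draw mixture weights in ``draw_weights``
    (uniform for a single model).
    """

    table: pd.DataFrame
    draws: np.ndarray
    draw_weights: np.ndarray
    level: float = 0.95
    scale: str = "raw"

    def __post_init__(self) -> None:
        bad = (self.table["lo"] > self.table["mean"]) | (self.table["mean"] > self.table["hi"])
        if bad.any():
            raise ValidationError("credible bounds must satisfy lo <= mean <= hi")

    @property
    def widths(self) -> np.ndarray:
        """Credible-interval widths, the inverse weights of the WES metric."""
        return (self.table["hi"] - self.table["lo"]).to_numpy()

    def to_csv(self, path) -> None:
        out = self.table.rename(columns={"lo": "lo95", "hi": "hi95"})
        out.to_csv(path, index=False)


def _weighted_quantile(draws: np.ndarray, weights: np.ndarray, q: float) -> np.ndarray:
    """Row-wise weighted quantile of (n_points, S) draws."""
    order = np.argsort(draws, axis=1)
    sorted_draws = np.take_along_axis(draws, order, axis=1)
    w = weights[order]
    cw = np.cumsum(w, axis=1)
    cw = cw / cw[:, -1:]
    idx = np.argmax(cw >= q, axis=1)
    return sorted_draws[np.arange(len(draws)), idx]


def _summarize(
    grid: pd.DataFrame, draws: np.ndarray, weights: np.ndarray, level: float, scale: str
) -> PredictionSet:
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    w = weights / weights.sum()
    mean = draws @ w
    lo = _weighted_quantile(draws, w, lo_q)
    hi = _weighted_quantile(draws, w, hi_q)
    table = grid.copy()
    table["mean"] = mean
    table["lo"] = np.minimum(lo, mean)
    table["hi"] = np.maximum(hi, mean)
    return PredictionSet(table=table, draws=draws, draw_weights=w, level=level, scale=scale)


def predict_trajectories(
    draws: PosteriorDraws,
    transform: ECDFTransform | None,
    subjects,
    times,
    level: float = 0.95,
    include_noise: bool = False,
) -> PredictionSet:
    """Posterior predictive trajectories for fitted subjects on a time grid.

    ``subjects`` must all have appeared in the fitted data (their random
    effects were sampled); for a new subject, refit with its baseline
    included, per the training-split rule.  ``times`` is either a single
    grid applied to every subject or a mapping subject -> times.  With a
    transform the summaries are on the raw scale, otherwise on the
    percentile scale.  ``include_noise`` adds residual noise to each draw
    (posterior-predictive rather than mean-trajectory intervals).
    """
    pos = {s: i for i, s in enumerate(draws.design.subjects)}
    unknown = [s for s in subjects if str(s) not in pos]
    if unknown:
        raise ConfigurationError(
            f"subjects {unknown[:5]} were not in the fitted data; refit with their "
            "baseline visits included in the training set"
        )
    if isinstance(times, dict):
        time_of = {str(s): np.asarray(times[s], dtype=float) for s in subjects}
    else:
        grid_times = np.asarray(times, dtype=float)
        time_of = {str(s): grid_times for s in subjects}

    markers = draws.design.markers
    rows = []
    for s in subjects:
        for t in time_of[str(s)]:
            for k, m in enumerate(markers):
                rows.append((str(s), float(t), m, pos[str(s)], k))
    grid = pd.DataFrame(rows, columns=["subject_id", "time_years", "marker", "_i", "_k"])

    mu = draws.conditional_mean(
        grid["_i"].to_numpy(), grid["time_years"].to_numpy(), grid["_k"].to_numpy()
    )  # (S, G)
    if include_noise:
        rng = np.random.default_rng(draws.config.seed + 97)
        mu = mu + rng.standard_normal(mu.shape) * draws.sigma[:, grid["_k"].to_numpy()]
    out = mu.T  # (G, S)

    scale = "percentile"
    if transform is not None:
        out = np.clip(out, 0.0, 1.0)
        raw = np.empty_like(out)
        for k, m in enumerate(markers):
            mask = grid["_k"].to_numpy() == k
            raw[mask] = transform.from_percentile(m, out[mask].ravel()).reshape(mask.sum(), -1)
        out = raw
        scale = "raw"

    weights = np.full(out.shape[1], 1.0 / out.shape[1])
    return _summarize(grid.drop(columns=["_i", "_k"]), out, weights, level, scale)


def model_average(prediction_sets: list[PredictionSet], weights) -> PredictionSet:
    """Pool per-model posterior predictive draws with simplex weights.

    All models must supply draws on identical (subject, time, marker)
    grids.  A weight of zero removes a model; weights (1, 0) reproduce the
    first model's predictions exactly.
    """
    from .criteria import ModelWeights

    if isinstance(weights, ModelWeights):
        w = np.asarray(weights.weights, dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
    if len(w) != len(prediction_sets):
        raise ConfigurationError("one weight per model is required")
    if (w < 0).any() or not np.isclose(w.sum(), 1.0):
        raise ValidationError("weights must be non-negative and sum to 1")
    grids = [
        ps.table[["subject_id", "time_years", "marker"]].reset_index(drop=True)
        for ps in prediction_sets
    ]
    for g in grids[1:]:
        if not g.equals(grids[0]):
            raise ConfigurationError("models supply different prediction grids")
    levels = {ps.level for ps in prediction_sets}
    scales = {ps.scale for ps in prediction_sets}
    if len(levels) > 1 or len(scales) > 1:
        raise ConfigurationError("prediction sets differ in level or scale")

    keep = [i for i, wi in enumerate(w) if wi > 0]
    pooled = np.concatenate([prediction_sets[i].draws for i in keep], axis=1)
    pooled_w = np.concatenate(
        [
            np.full(prediction_sets[i].draws.shape[1], w[i] / prediction_sets[i].draws.shape[1])
            for i in keep
        ]
    )
    return _summarize(grids[0], pooled, pooled_w, levels.pop(), scales.pop())
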