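"""Information criteria and Bayesian-model-averaging weights.

Model comparison uses the widely applicable information criterion (WAIC)
and the PSIS-smoothed leave-one-out information criterion (LOOIC); lower
values are preferred.  Exact posterior model probabilities require
marginal likelihoods that are intractable for these hierarchical models,
so the default averaging weights are pseudo-BMA weights — a softmax over
PSIS-LOO expected log pointwise predictive densities — with stacking of
predictive distributions and equal weights available as alternatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

from ..errors import ConfigurationError, ValidationError
from .fit import PosteriorDraws

_LOG_2PI = np.log(2.0 * np.pi)


def pointwise_log_likelihood(draws: PosteriorDraws) -> np.ndarray:
    """Conditional log-likelihood of every fitted observation under every draw.

    Shape (S, N); Gaussian density at the draw's subject-specific mean
    with the draw's residual scale.
    """
    design = draws.design
    mu = draws.conditional_mean(design.subj_idx, design.t, design.marker_idx)  # (S, N)
    sig = draws.sigma[:, design.marker_idx]  # (S, N)
    resid = design.y[None, :] - mu
    return -0.5 * (_LOG_2PI + 2.0 * np.log(sig) + (resid / sig) ** 2)


def compute_waic(draws: PosteriorDraws, log_lik: np.ndarray | None = None) -> float:
    """WAIC = -2 (lppd - p_waic); lower is better.

    ``p_waic`` is the summed posterior variance of the pointwise
    log-likelihood.  Requires at least 2 draws.
    """
    ll = pointwise_log_likelihood(draws) if log_lik is None else np.asarray(log_lik)
    if ll.shape[0] < 2:
        raise ValidationError("WAIC requires at least 2 posterior draws")
    S = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(S)))
    p_waic = float(np.sum(np.var(ll, axis=0, ddof=1)))
    return -2.0 * (lppd - p_waic)


def _psis_elpd(ll: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise PSIS-LOO elpd and Pareto-k diagnostics from (S, N) log-lik."""
    import arviz as az

    if np.allclose(ll, ll[0]):  # degenerate posterior: weights are exactly uniform
        S = ll.shape[0]
        return logsumexp(ll, axis=0) - np.log(S), np.zeros(ll.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lw, k = az.psislw(ll.T * -1.0)  # arviz expects (..., n_samples)
    lw = np.asarray(lw)
    elpd = logsumexp(lw + ll.T, axis=1)
    return elpd, np.asarray(k)


def compute_looic(
    draws: PosteriorDraws, log_lik: np.ndarray | None = None, return_pointwise: bool = False
):
    """PSIS-LOO estimate of -2 * elpd with Pareto-k diagnostics.

    Returns the scalar LOOIC, or ``(looic, pointwise_elpd, pareto_k)``
    when ``return_pointwise`` is set.
    """
    ll = pointwise_log_likelihood(draws) if log_lik is None else np.asarray(log_lik)
    if ll.shape[0] < 2:
        raise ValidationError("LOOIC requires at least 2 posterior draws")
    elpd, k = _psis_elpd(ll)
    looic = float(-2.0 * np.sum(elpd))
    if return_pointwise:
        return looic, elpd, k
    return looic


@dataclass
class ModelWeights:
    """Simplex weights over a set of fitted models."""

    names: tuple[str, ...]
    weights: np.ndarray
    method: str

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValidationError("model weights must be non-negative and sum to 1")
        self.weights = w

    def as_dict(self) -> dict[str, float]:
        return {n: float(w) for n, w in zip(self.names, self.weights)}


def _observation_keys(draws: PosteriorDraws):
    d = draws.design
    subs = np.asarray(d.subjects)[d.subj_idx]
    mks = np.asarray(d.markers)[d.marker_idx]
    return list(zip(subs, d.t.tolist(), mks))


def compute_model_weights(
    models: dict[str, PosteriorDraws] | list[PosteriorDraws],
    method: str = "pseudo-bma",
    elpd_pointwise: dict[str, np.ndarray] | None = None,
) -> ModelWeights:
    """Simplex weights over >= 2 models fitted to the same observations.

    ``pseudo-bma``: softmax over total PSIS-LOO elpd.  ``stacking``:
    maximizes the pooled log predictive density of the weighted mixture.
    ``equal``: uniform.  Pointwise elpd values may be supplied directly
    (keyed like ``models``) to skip recomputation.
    """
    if isinstance(models, dict):
        names = tuple(models)
        model_list = list(models.values())
    else:
        names = tuple(m.spec.family for m in models)
        model_list = list(models)
    if len(model_list) < 2:
        raise ConfigurationError("model averaging requires at least 2 models")

    keys0 = _observation_keys(model_list[0])
    for m in model_list[1:]:
        if _observation_keys(m) != keys0:
            raise ConfigurationError("models were fitted to different observation sets")

    if method == "equal":
        w = np.full(len(model_list), 1.0 / len(model_list))
        return ModelWeights(names, w, method)

    if elpd_pointwise is not None:
        elpds = [np.asarray(elpd_pointwise[n]) for n in names]
    else:
        elpds = []
        for m in model_list:
            _, e, _ = compute_looic(m, return_pointwise=True)
            elpds.append(e)
    E = np.stack(elpds)  # (n_models, N)

    if method == "pseudo-bma":
        w = softmax(E.sum(axis=1))
        return ModelWeights(names, w, method)
    if method == "stacking":
        M = E.shape[0]

        def neg_score(x):
            w = softmax(x)
            return -float(np.sum(logsumexp(E.T + np.log(w)[None, :], axis=1)))

        res = minimize(neg_score, np.zeros(M), method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 5000})
        w = softmax(res.x)
        return ModelWeights(names, w, method)
    raise ConfigurationError(f"unknown weighting method {method!r}")
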