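"""Posterior container and the top-level model-fitting entry point."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from ..data import LongitudinalDataset
from ..errors import ConfigurationError, ValidationError
from ..transform import ECDFTransform, dataset_to_percentiles
from .design import Design, build_design
from .sampler import run_chain
from .spec import MCMCConfig, ModelSpec


@dataclass
class PosteriorDraws:
    """Retained MCMC draws for one fitted model.

    Random effects are stored standardized (``z``) together with the scale
    matrix diagonal (``v_sd``) and correlation Cholesky factor (``L``);
    the random effects are reconstructed as ``alpha = V L z`` per draw.
    Shapes: S retained draws, p markers, d covariate columns, n subjects,
    r random-effect dimensions (2p with random slopes).
    """

    spec: ModelSpec
    config: MCMCConfig
    design: Design
    beta: np.ndarray          # (S, p, d)
    sigma: np.ndarray         # (S, p)
    v_sd: np.ndarray          # (S, r)
    L: np.ndarray             # (S, r, r)
    z: np.ndarray             # (S, n, r)
    chain: np.ndarray         # (S,)
    iteration: np.ndarray     # (S,)
    gamma: np.ndarray | None = None        # (S, p), LTJMM
    delta: np.ndarray | None = None        # (S, n), LTJMM
    sigma_delta: np.ndarray | None = None  # (S,), LTJMM
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    @property
    def n_random_dims(self) -> int:
        return self.v_sd.shape[1]

    def random_effects(self) -> np.ndarray:
        """alpha = V L z, shape (S, n, r)."""
        W = self.v_sd[:, :, None] * self.L  # (S, r, r)
        return np.einsum("srq,snq->snr", W, self.z)

    def omega(self) -> np.ndarray:
        """Correlation matrices Omega = L L', shape (S, r, r)."""
        return np.einsum("sij,skj->sik", self.L, self.L)

    def D(self) -> np.ndarray:
        """Random-effect covariance D = V Omega V, shape (S, r, r)."""
        return self.v_sd[:, :, None] * self.omega() * self.v_sd[:, None, :]

    def validate(self) -> None:
        """Positivity / triangularity invariants of every retained draw."""
        if not (self.sigma > 0).all():
            raise ValidationError("non-positive sigma_k draw")
        if not (self.v_sd > 0).all():
            raise ValidationError("non-positive diagonal of V")
        r = self.L.shape[-1]
        upper = np.triu_indices(r, k=1)
        if not np.allclose(self.L[:, upper[0], upper[1]], 0.0):
            raise ValidationError("L has non-zero entries above the diagonal")
        diag = self.L[:, np.arange(r), np.arange(r)]
        if not (diag > 0).all():
            raise ValidationError("L has non-positive diagonal entries")
        row_norms = np.linalg.norm(self.L, axis=2)
        if not np.allclose(row_norms, 1.0, atol=1e-6):
            raise ValidationError("rows of L are not unit-norm")
        if self.gamma is not None and not (self.gamma > 0).all():
            raise ValidationError("non-positive gamma_k draw")
        if self.sigma_delta is not None and not (self.sigma_delta > 0).all():
            raise ValidationError("non-positive sigma_delta draw")

    def conditional_mean(self, subj_idx, t, marker_idx) -> np.ndarray:
        """Model mean on the percentile scale, per draw: shape (S, len(t))."""
        subj_idx = np.asarray(subj_idx)
        marker_idx = np.asarray(marker_idx)
        t = np.asarray(t, dtype=float)
        p = len(self.design.markers)
        X = self.design.subject_X[subj_idx]                       # (G, d)
        mu = np.einsum("sgd,gd->sg", self.beta[:, marker_idx, :], X)
        alpha = self.random_effects()                              # (S, n, r)
        mu = mu + alpha[:, subj_idx, marker_idx]
        if self.n_random_dims == 2 * p:
            mu = mu + alpha[:, subj_idx, p + marker_idx] * t[None, :]
        if self.gamma is not None:
            mu = mu + self.gamma[:, marker_idx] * (t[None, :] + self.delta[:, subj_idx])
        return mu

    # -- persistence ----------------------------------------------------

    def save(self, directory) -> None:
        import pathlib

        path = pathlib.Path(directory)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {
            "beta": self.beta, "sigma": self.sigma, "v_sd": self.v_sd, "L": self.L,
            "z": self.z, "chain": self.chain, "iteration": self.iteration,
            "y": self.design.y, "t": self.design.t, "subj_idx": self.design.subj_idx,
            "marker_idx": self.design.marker_idx, "X": self.design.X,
            "subject_X": self.design.subject_X,
        }
        if self.gamma is not None:
            arrays.update(gamma=self.gamma, delta=self.delta, sigma_delta=self.sigma_delta)
        np.savez(path / "draws.npz", **arrays)
        manifest = {
            "spec": {
                "family": self.spec.family,
                "markers": list(self.spec.markers),
                "covariates": list(self.spec.covariates),
                "include_random_slope": self.spec.include_random_slope,
            },
            "config": {
                "iterations": self.config.iterations, "warmup": self.config.warmup,
                "chains": self.config.chains, "thin": self.config.thin, "seed": self.config.seed,
            },
            "x_cols": self.design.x_cols,
            "subjects": self.design.subjects,
            "markers": self.design.markers,
            "diagnostics": {k: (float(v) if np.isscalar(v) else v) for k, v in self.diagnostics.items()},
            "versions": _versions(),
        }
        with open(path / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, directory) -> "PosteriorDraws":
        import pathlib

        path = pathlib.Path(directory)
        with open(path / "manifest.json", encoding="utf-8") as fh:
            manifest = json.load(fh)
        arrs = np.load(path / "draws.npz")
        spec = ModelSpec(
            family=manifest["spec"]["family"],
            markers=tuple(manifest["spec"]["markers"]),
            covariates=tuple(manifest["spec"]["covariates"]),
            include_random_slope=manifest["spec"]["include_random_slope"],
        )
        config = MCMCConfig(**manifest["config"])
        design = Design(
            y=arrs["y"], t=arrs["t"], subj_idx=arrs["subj_idx"], marker_idx=arrs["marker_idx"],
            X=arrs["X"], x_cols=manifest["x_cols"], subjects=manifest["subjects"],
            markers=manifest["markers"], subject_X=arrs["subject_X"],
        )
        return cls(
            spec=spec, config=config, design=design,
            beta=arrs["beta"], sigma=arrs["sigma"], v_sd=arrs["v_sd"], L=arrs["L"], z=arrs["z"],
            chain=arrs["chain"], iteration=arrs["iteration"],
            gamma=arrs.get("gamma"), delta=arrs.get("delta"), sigma_delta=arrs.get("sigma_delta"),
            diagnostics=manifest["diagnostics"],
        )


def _versions() -> dict:
    import numpy, pandas, scipy
    import adprogress

    return {
        "adprogress": adprogress.__version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }


def _split_rhat(per_chain: np.ndarray) -> float:
    """Split-Rhat of a (chains, draws) array of one scalar parameter."""
    import arviz as az

    c, s = per_chain.shape
    half = s // 2
    if half < 2:
        return float("nan")
    split = np.concatenate([per_chain[:, :half], per_chain[:, half : 2 * half]], axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(split))


def _diagnostics(chain_ids: np.ndarray, beta: np.ndarray, sigma: np.ndarray, threshold: float) -> dict:
    chains = np.unique(chain_ids)
    rhats = []
    scalars = [beta[:, k, j] for k in range(beta.shape[1]) for j in range(beta.shape[2])]
    scalars += [sigma[:, k] for k in range(sigma.shape[1])]
    for x in scalars:
        per_chain = np.stack([x[chain_ids == c] for c in chains])
        rhats.append(_split_rhat(per_chain))
    rhats = np.asarray(rhats)
    max_rhat = float(np.nanmax(rhats)) if np.isfinite(rhats).any() else float("nan")
    flagged = bool(np.isfinite(max_rhat) and max_rhat > threshold)
    return {"max_rhat": max_rhat, "converged": not flagged, "rhat_threshold": threshold}


def _slice_design(design: Design, k: int) -> Design:
    rows = np.flatnonzero(design.marker_idx == k)
    return Design(
        y=design.y[rows], t=design.t[rows], subj_idx=design.subj_idx[rows],
        marker_idx=np.zeros(len(rows), dtype=np.int64), X=design.X[rows],
        x_cols=design.x_cols, subjects=design.subjects, markers=[design.markers[k]],
        subject_X=design.subject_X,
    )


def fit_model(
    spec: ModelSpec,
    train_dataset: LongitudinalDataset,
    mcmc_config: MCMCConfig,
    transform: ECDFTransform | None = None,
) -> PosteriorDraws:
    """Fit one model family by MCMC and return the retained posterior draws.

    The dataset must carry percentile-scale responses; pass ``transform``
    to convert raw values first.  Requires at least two subjects with two
    or more visits so random slopes are identifiable.
    """
    if transform is not None:
        train_dataset = dataset_to_percentiles(train_dataset, transform)
    design = build_design(train_dataset, spec)

    visits = train_dataset.observations.groupby("subject_id")["time_years"].nunique()
    if (visits >= 2).sum() < 2:
        raise ConfigurationError("need at least 2 subjects with >= 2 visits to fit random slopes")

    p = design.n_markers
    slope = spec.include_random_slope
    if spec.family in ("JMM", "LTJMM"):
        chains_out = [
            run_chain(design, spec.family, mcmc_config, (mcmc_config.seed, c), with_slope=slope)
            for c in range(mcmc_config.chains)
        ]
        beta = np.concatenate([co["beta"] for co in chains_out])
        sigma = np.concatenate([co["sigma"] for co in chains_out])
        v_sd = np.concatenate([co["v"] for co in chains_out])
        L = np.concatenate([co["L"] for co in chains_out])
        z = np.concatenate([co["z"] for co in chains_out])
        iteration = np.concatenate([co["iteration"] for co in chains_out])
        chain_ids = np.concatenate(
            [np.full(len(co["beta"]), c) for c, co in enumerate(chains_out)]
        )
        gamma = delta = sigma_delta = None
        if spec.family == "LTJMM":
            gamma = np.concatenate([co["gamma"] for co in chains_out])
            delta = np.concatenate([co["delta"] for co in chains_out])
            sigma_delta = np.concatenate([co["sigma_delta"] for co in chains_out])
    else:  # IMM: independent per-marker fits assembled block-diagonally
        per_marker = []
        for k in range(p):
            sub = _slice_design(design, k)
            outs = [
                run_chain(sub, "JMM", mcmc_config, (mcmc_config.seed, c, k), with_slope=slope)
                for c in range(mcmc_config.chains)
            ]
            per_marker.append(
                {key: np.concatenate([o[key] for o in outs]) for key in outs[0]}
            )
        S = len(per_marker[0]["beta"])
        n, d = design.n_subjects, design.X.shape[1]
        r = 2 * p if slope else p
        beta = np.stack([pm["beta"][:, 0, :] for pm in per_marker], axis=1)
        sigma = np.stack([pm["sigma"][:, 0] for pm in per_marker], axis=1)
        v_sd = np.empty((S, r))
        L = np.zeros((S, r, r))
        L[:, np.arange(r), np.arange(r)] = 1.0
        z = np.zeros((S, n, r))
        for k, pm in enumerate(per_marker):
            v_sd[:, k] = pm["v"][:, 0]
            z[:, :, k] = pm["z"][:, :, 0]
            if slope:
                v_sd[:, p + k] = pm["v"][:, 1]
                z[:, :, p + k] = pm["z"][:, :, 1]
                L[:, p + k, k] = pm["L"][:, 1, 0]
                L[:, p + k, p + k] = pm["L"][:, 1, 1]
        iteration = per_marker[0]["iteration"]
        draws_per_chain = mcmc_config.retained_per_chain
        chain_ids = np.repeat(np.arange(mcmc_config.chains), draws_per_chain)
        gamma = delta = sigma_delta = None

    diagnostics = _diagnostics(chain_ids, beta, sigma, mcmc_config.rhat_threshold)
    if not diagnostics["converged"]:
        warnings.warn(
            f"fit flagged: max split-Rhat {diagnostics['max_rhat']:.3f} exceeds "
            f"{mcmc_config.rhat_threshold}",
            stacklevel=2,
        )
    draws = PosteriorDraws(
        spec=spec, config=mcmc_config, design=design,
        beta=beta, sigma=sigma, v_sd=v_sd, L=L, z=z,
        chain=chain_ids, iteration=iteration,
        gamma=gamma, delta=delta, sigma_delta=sigma_delta,
        diagnostics=diagnostics,
    )
    draws.validate()
    return draws
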