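"""Synthetic multi-marker longitudinal cohorts with known ground truth.

Emulates the structure of a multi-cohort Alzheimer's observational study:
a panel of correlated cognitive/functional and imaging markers observed at
scheduled visits over 0-5 years, three-class visit diagnoses driven by an
anchor assessment (CDRSB), per-marker intermittent missingness and
monotone attrition.  Trajectories are simulated natively on the percentile
scale from the same mixed-effects families the longitudinal stage fits
(so parameter recovery is directly checkable) and mapped to plausible raw
scales through monotone marker-specific links.

What it does not emulate: practice effects, measurement floors/ceilings
beyond simple clipping, informative (outcome-dependent) dropout, or the
empirical marginal distributions of any real cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DX_LABELS, LongitudinalDataset
from .errors import ConfigurationError, ValidationError

#: Default marker panel: eight cognitive/functional plus four imaging measures.
DEFAULT_MARKERS = (
    "ADAS13",
    "CDRSB",
    "MMSE",
    "MOCA",
    "RAVLT_immediate",
    "EcogPtTotal",
    "EcogSPTotal",
    "FAQ",
    "FDG",
    "Hippocampus_ICV",
    "Ventricles_ICV",
    "Entorhinal",
)

#: Raw-scale links: (low, high, direction); direction +1 means larger raw
#: values indicate worse disease, -1 the reverse.  raw = low + (high-low)*q
#: for +1 and high - (high-low)*q for -1, with q the clipped percentile.
DEFAULT_MARKER_LINKS = {
    "ADAS13": (0.0, 85.0, +1),
    "CDRSB": (0.0, 18.0, +1),
    "MMSE": (0.0, 30.0, -1),
    "MOCA": (0.0, 30.0, -1),
    "RAVLT_immediate": (0.0, 75.0, -1),
    "EcogPtTotal": (1.0, 4.0, +1),
    "EcogSPTotal": (1.0, 4.0, +1),
    "FAQ": (0.0, 30.0, +1),
    "FDG": (0.6, 1.6, -1),
    "Hippocampus_ICV": (0.2, 0.8, -1),
    "Ventricles_ICV": (0.01, 0.06, +1),
    "Entorhinal": (2000.0, 4500.0, -1),
}


def default_omega(p: int, load_int: float = 0.6, load_slope: float = 0.4) -> np.ndarray:
    """One-factor correlation structure over the 2p random-effect dims.

    Intercepts share pairwise correlation ``load_int``, slopes
    ``load_slope``; positive-definiteness is guaranteed by construction.
    """
    lam = np.concatenate([np.full(p, np.sqrt(load_int)), np.full(p, np.sqrt(load_slope))])
    omega = np.outer(lam, lam)
    np.fill_diagonal(omega, 1.0)
    return omega


@dataclass
class CohortConfig:
    """Ground-truth parameters and sampling plan for one synthetic cohort.

    Fixed effects apply to the design (intercept, age_bl, sex[male],
    apoe4[carrier]) exactly as the model stage encodes it; ``beta`` is
    (p, 4).  Scales are on the percentile scale.
    """

    n_subjects: int = 200
    markers: tuple[str, ...] = DEFAULT_MARKERS
    visit_times: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0)
    family: str = "JMM"
    beta: np.ndarray | None = None          # (p, 4); defaults built in __post_init__
    v_diag: np.ndarray | None = None        # (2p,) random-effect SDs
    omega: np.ndarray | None = None         # (2p, 2p) correlation matrix
    sigma: np.ndarray | None = None         # (p,) residual SDs
    gamma: np.ndarray | None = None         # (p,) positive shifted-time slopes (LTJMM)
    sigma_delta: float = 0.5                # latent-shift SD (LTJMM)
    anchor_marker: str = "CDRSB"
    dx_thresholds: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)
    dx_on_noisy: bool = False
    mcar_rate: float = 0.10
    dropout_hazard: float = 0.12            # annual exponential attrition rate
    emit_scale: str = "raw"                 # "raw" or "percentile"
    age_mean: float = 73.5
    age_sd: float = 7.0
    p_female: float = 0.449
    p_apoe4: float = 0.46
    educ_mean: float = 16.0
    educ_sd: float = 2.6
    with_amyloid: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        p = len(self.markers)
        if len(set(self.markers)) != p or p == 0:
            raise ConfigurationError("markers must be a non-empty list of unique names")
        if self.family not in ("IMM", "JMM", "LTJMM"):
            raise ConfigurationError(f"unknown family {self.family!r}")
        if self.anchor_marker not in self.markers:
            raise ConfigurationError("anchor marker must be in the panel")
        if self.beta is None:
            b0 = np.linspace(0.05, 0.15, p)
            self.beta = np.column_stack(
                [b0, np.full(p, 0.004), np.full(p, 0.02), np.full(p, 0.06)]
            )
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (p, 4):
            raise ConfigurationError("beta must have shape (p, 4)")
        if self.v_diag is None:
            self.v_diag = np.concatenate([np.full(p, 0.15), np.full(p, 0.05)])
        self.v_diag = np.asarray(self.v_diag, dtype=float)
        if self.omega is None:
            if self.family == "JMM":
                self.omega = default_omega(p)
            else:
                # IMM: no cross-marker correlation by definition; LTJMM:
                # cross-marker correlation is carried by the shared shift
                self.omega = np.eye(2 * p)
        self.omega = np.asarray(self.omega, dtype=float)
        if self.sigma is None:
            self.sigma = np.full(p, 0.07)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.family == "LTJMM" and self.gamma is None:
            # progression rate along long-term disease time, large enough
            # that a latent shift of O(sigma_delta) visibly offsets markers
            self.gamma = np.full(p, 0.2)
        if self.gamma is not None:
            self.gamma = np.asarray(self.gamma, dtype=float)
            if (self.gamma <= 0).any():
                raise ConfigurationError("gamma must be positive")
        if (self.v_diag < 0).any() or (self.sigma < 0).any():
            raise ConfigurationError("scales must be non-negative")
        if not np.allclose(self.omega, self.omega.T) or not np.allclose(np.diag(self.omega), 1.0):
            raise ConfigurationError("omega must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(self.omega).min() <= 1e-10:
            raise ConfigurationError("omega must be positive-definite")
        if not (0 <= self.mcar_rate <= 1):
            raise ConfigurationError("mcar_rate must be in [0, 1]")
        if self.emit_scale not in ("raw", "percentile"):
            raise ConfigurationError("emit_scale must be 'raw' or 'percentile'")


@dataclass
class CohortTruth:
    """Realized ground truth: parameters, random effects, noiseless paths."""

    config: CohortConfig
    alpha: np.ndarray                 # (n, 2p) realized random effects
    delta: np.ndarray                 # (n,) latent shifts (zeros unless LTJMM)
    latent: pd.DataFrame              # subject_id, time_years, marker, eta (noiseless percentile)
    subjects: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        cfg = self.config
        payload = {
            "config": {
                "n_subjects": cfg.n_subjects,
                "markers": list(cfg.markers),
                "visit_times": list(cfg.visit_times),
                "family": cfg.family,
                "beta": cfg.beta.tolist(),
                "v_diag": cfg.v_diag.tolist(),
                "omega": cfg.omega.tolist(),
                "sigma": cfg.sigma.tolist(),
                "gamma": None if cfg.gamma is None else cfg.gamma.tolist(),
                "sigma_delta": cfg.sigma_delta,
                "seed": cfg.seed,
            },
            "alpha": self.alpha.tolist(),
            "delta": self.delta.tolist(),
            "subjects": self.subjects,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)


def _raw_link(marker: str, q: np.ndarray) -> np.ndarray:
    lo, hi, direction = DEFAULT_MARKER_LINKS.get(marker, (0.0, 1.0, +1))
    q = np.clip(q, 0.0, 1.0)
    return lo + (hi - lo) * q if direction > 0 else hi - (hi - lo) * q


def generate_cohort(config: CohortConfig) -> tuple[LongitudinalDataset, CohortTruth]:
    """Simulate covariates, random effects and marker observations.

    Fully deterministic given ``config.seed``.  Returns the complete
    (pre-missingness, pre-diagnosis) dataset and the realized truth.
    """
    p = len(config.markers)
    n = config.n_subjects
    rng = np.random.default_rng([config.seed, 0])
    subjects = [f"S{i:04d}" for i in range(n)]

    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 55.0, 92.0)
    sex = np.where(rng.uniform(size=n) < config.p_female, "female", "male")
    apoe = np.where(rng.uniform(size=n) < config.p_apoe4, "carrier", "non-carrier")
    educ = np.clip(rng.normal(config.educ_mean, config.educ_sd, n), 8.0, 20.0).round(1)
    marital = rng.choice(
        ["married", "widowed", "divorced", "never-married"], size=n, p=[0.75, 0.10, 0.10, 0.05]
    )

    X = np.column_stack(
        [np.ones(n), age, (sex == "male").astype(float), (apoe == "carrier").astype(float)]
    )
    fixed = X @ config.beta.T  # (n, p)

    # Cholesky factor of D = V Omega V is V @ chol(Omega); valid even when
    # some scales are exactly zero (no random effect in that dimension)
    chol = config.v_diag[:, None] * np.linalg.cholesky(config.omega)
    alpha = rng.standard_normal((n, 2 * p)) @ chol.T
    if config.family == "LTJMM":
        delta = rng.normal(0.0, config.sigma_delta, n)
        gamma = config.gamma
    else:
        delta = np.zeros(n)
        gamma = np.zeros(p)

    times = np.asarray(config.visit_times, dtype=float)
    recs, lat = [], []
    for i, sid in enumerate(subjects):
        for t in times:
            eta_row = (
                fixed[i]
                + gamma * (t + delta[i])
                + alpha[i, :p]
                + alpha[i, p:] * t
            )
            noise = rng.normal(0.0, config.sigma)
            y_pct = eta_row + noise
            for k, m in enumerate(config.markers):
                lat.append((sid, t, m, eta_row[k]))
                if config.emit_scale == "raw":
                    value = float(_raw_link(m, np.array([y_pct[k]]))[0])
                else:
                    value = float(y_pct[k])
                recs.append((sid, t, m, value))

    obs = pd.DataFrame(recs, columns=["subject_id", "time_years", "marker", "value"])
    latent = pd.DataFrame(lat, columns=["subject_id", "time_years", "marker", "eta"])

    cov = pd.DataFrame(
        {
            "subject_id": subjects,
            "age_bl": age,
            "sex": sex,
            "apoe4": apoe,
            "educ_years": educ,
            "marital": marital,
        }
    )
    if config.with_amyloid:
        # disease-linked amyloid measures (anchor intercept drives pathology)
        anchor_k = list(config.markers).index(config.anchor_marker)
        stage = fixed[:, anchor_k] + alpha[:, anchor_k] + gamma[anchor_k] * delta
        cov["amyloid_suvr"] = np.round(1.00 + 0.45 * stage + rng.normal(0, 0.08, n), 3)
        cov["amyloid_csf"] = np.round(1250.0 - 900.0 * stage + rng.normal(0, 120.0, n), 1)
    dataset = LongitudinalDataset(obs, cov, marker_panel=list(config.markers))
    truth = CohortTruth(config=config, alpha=alpha, delta=delta, latent=latent, subjects=subjects)
    return dataset, truth


def assign_diagnoses(
    dataset: LongitudinalDataset,
    truth: CohortTruth,
    thresholds: tuple[float, float] | None = None,
    use_noisy: bool | None = None,
) -> LongitudinalDataset:
    """Per-visit CN/MCI/Dementia labels by thresholding the anchor marker.

    The anchor's percentile-scale value (noiseless by default) is cut at
    two strictly increasing thresholds; labels are monotone in the anchor
    value.  Baseline diagnosis is written into the covariate table.
    """
    cfg = truth.config
    thr = thresholds if thresholds is not None else cfg.dx_thresholds
    if not (thr[0] < thr[1]):
        raise ValidationError("diagnosis thresholds must be strictly increasing")
    use_noisy = cfg.dx_on_noisy if use_noisy is None else use_noisy

    anchor = cfg.anchor_marker
    if use_noisy:
        src = dataset.observations
        rows = src[src["marker"] == anchor][["subject_id", "time_years", "value"]].copy()
        lo, hi, direction = DEFAULT_MARKER_LINKS.get(anchor, (0.0, 1.0, +1))
        q = (rows["value"] - lo) / (hi - lo)
        rows["score"] = q if direction > 0 else 1.0 - q
    else:
        rows = truth.latent[truth.latent["marker"] == anchor][
            ["subject_id", "time_years", "eta"]
        ].rename(columns={"eta": "score"})

    labels = np.select(
        [rows["score"] < thr[0], rows["score"] < thr[1]], [DX_LABELS[0], DX_LABELS[1]], DX_LABELS[2]
    )
    dx = pd.DataFrame(
        {"subject_id": rows["subject_id"], "time_years": rows["time_years"], "dx": labels}
    ).reset_index(drop=True)

    cov = dataset.covariates.copy()
    base = dx.sort_values("time_years").groupby("subject_id").first()["dx"]
    cov["dx_bl"] = cov["subject_id"].map(base)
    return LongitudinalDataset(
        dataset.observations, cov, dx, marker_panel=list(dataset.marker_panel)
    )


def apply_missingness(
    dataset: LongitudinalDataset,
    mcar_rate: float | None = None,
    dropout_hazard: float | None = None,
    seed: int | None = None,
    config: CohortConfig | None = None,
) -> LongitudinalDataset:
    """Per-marker MCAR masking plus monotone (exponential-time) dropout.

    A subject's dropout time is exponential with the configured annual
    hazard; visits strictly after it vanish entirely (observations and
    diagnosis records), but baseline visits are never dropped.  MCAR then
    removes individual marker observations.  Deterministic given the seed.
    """
    if config is not None:
        mcar_rate = config.mcar_rate if mcar_rate is None else mcar_rate
        dropout_hazard = config.dropout_hazard if dropout_hazard is None else dropout_hazard
        seed = config.seed if seed is None else seed
    mcar_rate = mcar_rate or 0.0
    dropout_hazard = dropout_hazard or 0.0
    if not (0 <= mcar_rate <= 1) or dropout_hazard < 0:
        raise ValidationError("rates must be non-negative (mcar in [0, 1])")
    rng = np.random.default_rng([seed or 0, 1])

    obs = dataset.observations.copy()
    dx = dataset.diagnoses.copy()
    subjects = dataset.subjects
    base = dataset.baseline_times()

    if dropout_hazard > 0:
        tdrop = rng.exponential(1.0 / dropout_hazard, size=len(subjects))
        drop_of = dict(zip(subjects, tdrop))
        keep = (
            obs["time_years"].to_numpy()
            <= np.array([drop_of[s] for s in obs["subject_id"]])
        ) | (obs["time_years"].to_numpy() == base.reindex(obs["subject_id"]).to_numpy())
        obs = obs[keep]
        if len(dx):
            keep_dx = (
                dx["time_years"].to_numpy()
                <= np.array([drop_of[s] for s in dx["subject_id"]])
            ) | (dx["time_years"].to_numpy() == base.reindex(dx["subject_id"]).to_numpy())
            dx = dx[keep_dx]

    if mcar_rate > 0:
        keep_obs = rng.uniform(size=len(obs)) >= mcar_rate
        obs = obs[keep_obs]

    return LongitudinalDataset(obs, dataset.covariates, dx, marker_panel=list(dataset.marker_panel))


def simulate_cohort(config: CohortConfig) -> tuple[LongitudinalDataset, CohortTruth]:
    """generate -> assign diagnoses -> apply missingness, all from one seed."""
    dataset, truth = generate_cohort(config)
    dataset = assign_diagnoses(dataset, truth)
    dataset = apply_missingness(dataset, config=config)
    return dataset, truth
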