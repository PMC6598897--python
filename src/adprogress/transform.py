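"""Weighted empirical-CDF percentile transform.

Heterogeneous markers (cognitive scores, functional scales, volumetrics)
are placed on a common [0, 1] percentile scale before model fitting, and
model predictions are mapped back to each marker's raw scale afterwards.
Each training observation is weighted by the inverse of the proportion of
its diagnosis category among that marker's training observations, so that
under-represented disease stages contribute equally to the reference
distribution.

Conventions
-----------
* Forward direction: weighted proportion of reference values <= query
  (right-continuous), clamped to [eps, 1 - eps] with eps defaulting to
  1/(2n) so percentiles stay inside the open unit interval.
* Inverse direction: piecewise-linear interpolation between the reference
  order statistics at their (clamped) cumulative weights, so the round
  trip from_percentile(to_percentile(v)) == v holds exactly on every
  distinct training value.
* Ties in reference values collapse to a single step with summed weight.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DX_LABELS, LongitudinalDataset
from .errors import DegenerateTransformError, ValidationError


@dataclass
class _MarkerECDF:
    values: np.ndarray   # distinct reference values, strictly increasing
    weights: np.ndarray  # summed per distinct value; sums to 1
    eps: float

    def _knots(self) -> tuple[np.ndarray, np.ndarray]:
        """Clamped cumulative-weight knots, strictly increasing.

        Both directions share these knots so the round trip is exact on
        every reference value even when a clamp bites at the extremes.
        """
        pk = np.clip(np.cumsum(self.weights), self.eps, 1.0 - self.eps)
        for j in range(1, len(pk)):
            if pk[j] <= pk[j - 1]:
                pk[j] = np.nextafter(pk[j - 1], 1.0)
        return pk, self.values

    def forward(self, v: np.ndarray) -> np.ndarray:
        pk, vk = self._knots()
        idx = np.searchsorted(vk, v, side="right")
        padded = np.concatenate([[self.eps], pk])
        return padded[idx]

    def inverse(self, p: np.ndarray) -> np.ndarray:
        pk, vk = self._knots()
        return np.interp(p, pk, vk)


@dataclass
class ECDFTransform:
    """Per-marker weighted empirical CDF and its interpolated inverse.

    ``directions`` optionally records, per marker, whether larger raw
    values indicate worse disease (+1) or better (-1); it is metadata for
    reporting and does not alter the transform.
    """

    marker_ecdfs: dict[str, _MarkerECDF]
    weight_by: str = "visit"
    directions: dict[str, int] | None = None
    categories: tuple[str, ...] = field(default_factory=lambda: tuple(DX_LABELS))

    @property
    def markers(self) -> list[str]:
        return list(self.marker_ecdfs)

    def _ecdf(self, marker: str) -> _MarkerECDF:
        try:
            return self.marker_ecdfs[marker]
        except KeyError:
            raise KeyError(f"transform was not fitted for marker {marker!r}") from None

    def to_percentile(self, marker: str, value):
        """Weighted ECDF of ``value`` under marker's reference distribution."""
        v = np.asarray(value, dtype=float)
        if not np.isfinite(v).all():
            raise ValidationError("to_percentile requires finite values")
        out = self._ecdf(marker).forward(np.atleast_1d(v))
        return float(out[0]) if np.isscalar(value) or v.ndim == 0 else out

    def from_percentile(self, marker: str, p):
        """Weighted-quantile inverse with linear interpolation."""
        q = np.asarray(p, dtype=float)
        if ((q < 0) | (q > 1)).any() or not np.isfinite(q).all():
            raise ValidationError("percentiles must lie in [0, 1]")
        out = self._ecdf(marker).inverse(np.atleast_1d(q))
        return float(out[0]) if np.isscalar(p) or q.ndim == 0 else out

    # -- serialization -------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "weight_by": self.weight_by,
            "categories": list(self.categories),
            "directions": self.directions,
            "markers": {
                m: {"values": e.values.tolist(), "weights": e.weights.tolist(), "eps": e.eps}
                for m, e in self.marker_ecdfs.items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ECDFTransform":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        ecdfs = {
            m: _MarkerECDF(np.asarray(d["values"]), np.asarray(d["weights"]), d["eps"])
            for m, d in payload["markers"].items()
        }
        return cls(
            ecdfs,
            weight_by=payload["weight_by"],
            directions=payload["directions"],
            categories=tuple(payload["categories"]),
        )


def fit_weighted_ecdf(
    frame: pd.DataFrame,
    eps: float | None = None,
    categories: tuple[str, ...] = tuple(DX_LABELS),
    weight_by: str = "visit",
    directions: dict[str, int] | None = None,
) -> ECDFTransform:
    """Fit the per-marker weighted ECDF transform.

    Parameters
    ----------
    frame
        Long table with columns ``marker``, ``value``, ``category`` — one
        row per training observation with its diagnosis category.
    eps
        Clamp distance from exact 0/1; defaults per marker to ``1/(2n)``.
    categories
        Allowed category labels; anything else raises.

    Each observation's weight is ``1 / (fraction of that marker's
    observations in the observation's category)``, normalized to sum to 1
    per marker.  Transforms of different markers are independent.
    """
    for col in ("marker", "value", "category"):
        if col not in frame.columns:
            raise ValidationError(f"fit frame is missing column {col!r}")
    bad = ~frame["category"].isin(categories)
    if bad.any():
        raise ValidationError(
            f"unknown category {frame.loc[bad, 'category'].iloc[0]!r}; expected {categories}"
        )

    ecdfs: dict[str, _MarkerECDF] = {}
    for marker, grp in frame.groupby("marker", sort=True):
        vals = np.asarray(grp["value"], dtype=float)
        if not np.isfinite(vals).all():
            raise ValidationError(f"non-finite training values for marker {marker!r}")
        if len(np.unique(vals)) < 2:
            raise DegenerateTransformError(
                f"marker {marker!r} has fewer than 2 distinct training values"
            )
        props = grp["category"].value_counts(normalize=True)
        w = 1.0 / props.reindex(grp["category"]).to_numpy()
        w = w / w.sum()
        order = np.argsort(vals, kind="stable")
        vs, ws = vals[order], w[order]
        uniq, start = np.unique(vs, return_index=True)
        summed = np.add.reduceat(ws, start)
        e = 1.0 / (2 * len(vals)) if eps is None else eps
        ecdfs[str(marker)] = _MarkerECDF(uniq, summed, e)
    return ECDFTransform(ecdfs, weight_by=weight_by, directions=directions, categories=tuple(categories))


def fit_transform_from_dataset(
    dataset: LongitudinalDataset,
    weight_by: str = "visit",
    eps: float | None = None,
) -> ECDFTransform:
    """Fit the transform from a dataset, weighting by diagnosis category.

    ``weight_by="visit"`` attaches to each observation the diagnosis at the
    same visit (falling back to the most recent prior diagnosis when a
    visit lacks a record); ``weight_by="baseline"`` uses the baseline
    diagnosis from the covariate table throughout.
    """
    obs = dataset.observations
    if weight_by == "baseline":
        cat = obs.merge(
            dataset.covariates[["subject_id", "dx_bl"]], on="subject_id", how="left"
        )["dx_bl"]
    elif weight_by == "visit":
        dx = dataset.diagnoses.sort_values("time_years", kind="stable")
        obs_sorted = obs.reset_index().sort_values("time_years", kind="stable")
        merged = pd.merge_asof(
            obs_sorted,
            dx.rename(columns={"time_years": "dx_time"}),
            left_on="time_years",
            right_on="dx_time",
            by="subject_id",
            direction="backward",
        )
        merged = merged.sort_values("index")
        cat = merged["dx"].reset_index(drop=True)
        obs = merged[["subject_id", "time_years", "marker", "value"]].reset_index(drop=True)
    else:
        raise ValidationError(f"unknown weight_by {weight_by!r}")
    if cat.isna().any():
        raise ValidationError("some observations have no diagnosis category to weight by")
    frame = pd.DataFrame(
        {"marker": obs["marker"].to_numpy(), "value": obs["value"].to_numpy(), "category": cat.to_numpy()}
    )
    return fit_weighted_ecdf(frame, eps=eps, weight_by=weight_by)


def dataset_to_percentiles(dataset: LongitudinalDataset, transform: ECDFTransform) -> LongitudinalDataset:
    """Return a copy of the dataset with values mapped to percentiles."""
    obs = dataset.observations.copy()
    for marker in obs["marker"].unique():
        mask = obs["marker"] == marker
        obs.loc[mask, "value"] = transform.to_percentile(marker, obs.loc[mask, "value"].to_numpy())
    return LongitudinalDataset(
        obs, dataset.covariates, dataset.diagnoses, marker_panel=list(dataset.marker_panel)
    )
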