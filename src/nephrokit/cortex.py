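"""Renal cortex volumetry from tomographic slices and the sub-cohort
estimating equation.

Whole-kidney and cortex volumes are simple slice summations
(area x slice spacing, no end-cap correction — the acquisition protocol
specifies exactly that).  The sub-cohort equation is an ordinary
least-squares linear predictor of the tomographically measured cortex
volume from clinically available features (ultrasound axes, sex, eGFR,
birth weight, body weight, ...); the feature set is configurable and no
automatic variable selection is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SliceMeasurement",
    "UltrasoundAxes",
    "VolumeResult",
    "CortexVolumeModel",
    "volume_from_slices",
    "fit_cortex_volume_model",
    "predict_cortex_volume",
    "slices_from_mask",
]

#: Tomographic acquisition parameters carried as metadata only.
ACQUISITION_METADATA = {
    "sequence": "2D Turbo FLASH",
    "TR_ms": "1570",
    "TE_ms": "2.74",
    "TI_ms": "1000",
    "flip_angle_deg": "15",
    "fat_sat": "off",
}


@dataclass(frozen=True)
class SliceMeasurement:
    """Cross-sectional areas of one axial slice, cm^2, with its spacing, cm.

    ``spacing_cm`` is the reconstruction interval (slice thickness when
    contiguous).
    """

    slice_index: int
    kidney_area_cm2: float
    cortex_area_cm2: float
    spacing_cm: float

    def __post_init__(self) -> None:
        if self.spacing_cm <= 0:
            raise ValueError(f"slice spacing must be positive, got {self.spacing_cm}")
        if self.kidney_area_cm2 < 0:
            raise ValueError("kidney area must be >= 0")
        if not 0 <= self.cortex_area_cm2 <= self.kidney_area_cm2:
            raise ValueError(
                f"slice {self.slice_index}: cortex area "
                f"{self.cortex_area_cm2} must lie in [0, kidney area "
                f"{self.kidney_area_cm2}]"
            )


@dataclass(frozen=True)
class UltrasoundAxes:
    """Kidney axes from ultrasound, cm: major (a), minor (b), transverse (c)."""

    major_axis_cm: float
    minor_axis_cm: float
    transverse_axis_cm: float
    side: str = "left"

    def __post_init__(self) -> None:
        for name in ("major_axis_cm", "minor_axis_cm", "transverse_axis_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")


@dataclass(frozen=True)
class VolumeResult:
    whole_kidney_cm3: float
    cortex_cm3: float


def volume_from_slices(slices: Sequence[SliceMeasurement]) -> VolumeResult:
    """Slice-summation volumes: V = sum(area x spacing) for organ and cortex."""
    if not slices:
        raise ValueError("need at least one slice")
    whole = sum(s.kidney_area_cm2 * s.spacing_cm for s in slices)
    cortex = sum(s.cortex_area_cm2 * s.spacing_cm for s in slices)
    return VolumeResult(whole_kidney_cm3=whole, cortex_cm3=cortex)


@dataclass
class CortexVolumeModel:
    """Fitted linear predictor of the cortex volume (cm^3).

    ``coefficients`` maps feature names (plus ``"intercept"``) to weights;
    ``stderr`` carries the matching standard errors.  The statsmodels
    results object is retained on models fitted in-session (``_results``)
    and powers prediction intervals; models restored from JSON predict
    point values only.
    """

    feature_names: list[str]
    coefficients: dict[str, float]
    stderr: dict[str, float]
    n_obs: int
    resid_std: float
    r_squared: float
    _results: object | None = None

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "coefficients": dict(self.coefficients),
            "stderr": dict(self.stderr),
            "n_obs": self.n_obs,
            "resid_std": self.resid_std,
            "r_squared": self.r_squared,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CortexVolumeModel":
        return cls(
            feature_names=list(d["feature_names"]),
            coefficients=dict(d["coefficients"]),
            stderr=dict(d["stderr"]),
            n_obs=int(d["n_obs"]),
            resid_std=float(d["resid_std"]),
            r_squared=float(d["r_squared"]),
        )


class CollinearityError(ValueError):
    """Design matrix is rank deficient; names the offending columns."""


def _design(features: pd.DataFrame, feature_names: Sequence[str]) -> pd.DataFrame:
    import statsmodels.api as sm

    missing = [c for c in feature_names if c not in features.columns]
    if missing:
        raise KeyError(f"missing feature columns: {missing}")
    X = features.loc[:, list(feature_names)].astype(float)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing values in feature columns: {bad}")
    return sm.add_constant(X, prepend=True, has_constant="raise")


def fit_cortex_volume_model(
    features: pd.DataFrame,
    cortex_volumes_cm3: Sequence[float],
    feature_names: Sequence[str] | None = None,
) -> CortexVolumeModel:
    """Fit the sub-cohort estimating equation by OLS with an intercept."""
    import statsmodels.api as sm

    y = np.asarray(cortex_volumes_cm3, dtype=float)
    if feature_names is None:
        feature_names = list(features.columns)
    if len(y) != len(features):
        raise ValueError("features and volumes must have equal length")
    if len(y) < len(feature_names) + 2:
        raise ValueError(
            f"need at least {len(feature_names) + 2} observations for "
            f"{len(feature_names)} features"
        )
    X = _design(features, feature_names)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify columns that add no rank
        culprits = []
        cols = X.to_numpy()
        base_rank = 0
        kept = np.empty((cols.shape[0], 0))
        for j, name in enumerate(X.columns):
            cand = np.column_stack([kept, cols[:, j]])
            if np.linalg.matrix_rank(cand) > base_rank:
                kept = cand
                base_rank += 1
            else:
                culprits.append(str(name))
        raise CollinearityError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {culprits}"
        )
    res = sm.OLS(y, X).fit()
    names = ["intercept"] + [str(c) for c in X.columns[1:]]
    return CortexVolumeModel(
        feature_names=[str(c) for c in feature_names],
        coefficients=dict(zip(names, res.params.tolist())),
        stderr=dict(zip(names, res.bse.tolist())),
        n_obs=int(res.nobs),
        resid_std=float(np.sqrt(res.scale)),
        r_squared=float(res.rsquared),
        _results=res,
    )


def predict_cortex_volume(
    model: CortexVolumeModel, features: Mapping[str, float]
) -> tuple[float, bool]:
    """Apply the estimating equation to one feature row.

    Returns ``(volume_cm3, floored)``; a negative linear prediction is
    floored at 0 with the flag set.
    """
    missing = [c for c in model.feature_names if c not in features]
    if missing:
        raise KeyError(f"missing features: {missing}")
    pred = model.coefficients["intercept"] + sum(
        model.coefficients[c] * float(features[c]) for c in model.feature_names
    )
    if pred < 0:
        return 0.0, True
    return pred, False


def prediction_interval(
    model: CortexVolumeModel, features: Mapping[str, float], alpha: float = 0.05
) -> tuple[float, float]:
    """95% (by default) prediction interval; needs an in-session fit."""
    import statsmodels.api as sm  # noqa: F401

    if model._results is None:
        raise ValueError("prediction intervals need a model fitted in-session")
    row = pd.DataFrame(
        [[1.0] + [float(features[c]) for c in model.feature_names]],
        columns=["const"] + model.feature_names,
    )
    frame = model._results.get_prediction(row).summary_frame(alpha=alpha)
    return float(frame["obs_ci_lower"].iloc[0]), float(frame["obs_ci_upper"].iloc[0])


def slices_from_mask(path: str) -> list[SliceMeasurement]:
    """Per-slice areas from a 3-D label volume (0 background, 1 kidney
    parenchyma, 2 cortex); voxel dimensions are read from the header.

    The last array axis is taken as the slice axis.  Areas are voxel counts
    times in-plane voxel area; the CSV area tables remain the canonical
    input path.
    """
    import nibabel as nib

    img = nib.load(path)
    data = np.asarray(img.dataobj)
    dx, dy, dz = img.header.get_zooms()[:3]  # mm
    voxel_area_cm2 = (dx / 10.0) * (dy / 10.0)
    spacing_cm = dz / 10.0
    slices = []
    for k in range(data.shape[2]):
        plane = data[:, :, k]
        kidney = int((plane >= 1).sum())
        cortex = int((plane == 2).sum())
        if kidney == 0:
            continue
        slices.append(
            SliceMeasurement(
                slice_index=k,
                kidney_area_cm2=kidney * voxel_area_cm2,
                cortex_area_cm2=cortex * voxel_area_cm2,
                spacing_cm=spacing_cm,
            )
        )
    if not slices:
        raise ValueError(f"no labelled voxels found in {path}")
    return slices
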