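"""Chart-based colour calibration.

Photographs taken under uncontrolled lighting carry a colour cast.  When
each photograph includes a colour chart with known nominal sRGB patch
values, the cast can be estimated and removed before any colour is
measured.  The model here is a single 3x3 linear map acting on *linearised*
RGB (sRGB transfer function decoded): the simplest physically motivated
description of an illumination change.  There is no offset term, so black
stays black, and out-of-gamut results are clipped, never renormalised, so
neutral patches stay neutral.

The transform is fitted by ordinary least squares over the chart patches
and reported with its root-mean-square patch residual in linear RGB units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .colour_core import RGBImage, decode_srgb, encode_srgb

__all__ = [
    "ChartMeasurement",
    "CalibrationTransform",
    "fit_calibration",
    "apply_calibration",
    "read_chart_csv",
    "write_transform_json",
    "read_transform_json",
]

_MIN_PATCHES = 3


@dataclass(frozen=True)
class ChartMeasurement:
    """One chart patch: what the camera recorded vs. the nominal sRGB value."""

    patch_id: str
    observed_rgb: tuple[float, float, float]
    reference_rgb: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name in ("observed_rgb", "reference_rgb"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or v.min() < 0 or v.max() > 255:
                raise ValueError(f"{name} must be 3 values in [0, 255], got {v.tolist()}")


@dataclass(frozen=True)
class CalibrationTransform:
    """A 3x3 linear correction applied in linearised RGB."""

    matrix: np.ndarray
    fit_residual: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"matrix must be 3x3, got shape {m.shape}")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("calibration matrix must be invertible")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "CalibrationTransform":
        return cls(matrix=np.eye(3), fit_residual=0.0)


def _linearise(rgb8: np.ndarray) -> np.ndarray:
    return decode_srgb(np.asarray(rgb8, dtype=float) / 255.0)


def fit_calibration(measurements: Sequence[ChartMeasurement]) -> CalibrationTransform:
    """Least-squares 3x3 map from linearised observed RGB to linearised reference RGB.

    Requires at least 3 patches whose linearised observed values span all
    three channels; 4 or more (including neutrals) is recommended.  Raises
    ``ValueError("underdetermined calibration")`` otherwise.
    """
    measurements = list(measurements)
    ids = [m.patch_id for m in measurements]
    if len(set(ids)) != len(ids):
        raise ValueError("patch_ids must be unique")
    if len(measurements) < _MIN_PATCHES:
        raise ValueError(
            f"underdetermined calibration: {len(measurements)} patches, need >= {_MIN_PATCHES}"
        )
    obs = _linearise(np.array([m.observed_rgb for m in measurements]))
    ref = _linearise(np.array([m.reference_rgb for m in measurements]))
    if np.linalg.matrix_rank(obs, tol=1e-10) < 3:
        raise ValueError("underdetermined calibration: observed patches are rank deficient")
    # obs @ M.T ~= ref  =>  per-row correction  corrected = M @ observed
    mt, *_ = np.linalg.lstsq(obs, ref, rcond=None)
    matrix = mt.T
    residual = float(np.sqrt(np.mean((obs @ mt - ref) ** 2)))
    return CalibrationTransform(matrix=matrix, fit_residual=residual)


def apply_calibration(image: RGBImage | np.ndarray, t: CalibrationTransform) -> RGBImage:
    """Correct an image: decode sRGB, apply the matrix per pixel, clip, re-encode."""
    px = image.pixels if isinstance(image, RGBImage) else np.asarray(image)
    linear = _linearise(px)
    corrected = np.clip(linear @ t.matrix.T, 0.0, 1.0)
    out = np.clip(np.rint(encode_srgb(corrected) * 255.0), 0, 255).astype(np.uint8)
    return RGBImage(pixels=out)


# ---------------------------------------------------------------------------
# Chart and transform I/O
# ---------------------------------------------------------------------------

_CHART_COLUMNS = ["patch_id", "obs_r", "obs_g", "obs_b", "ref_r", "ref_g", "ref_b"]


def read_chart_csv(path: str | Path) -> list[ChartMeasurement]:
    """Read chart measurements from a CSV with columns
    patch_id, obs_r, obs_g, obs_b, ref_r, ref_g, ref_b."""
    df = pd.read_csv(path)
    missing = [c for c in _CHART_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"chart file {path} is missing columns: {missing}")
    return [
        ChartMeasurement(
            patch_id=str(row.patch_id),
            observed_rgb=(row.obs_r, row.obs_g, row.obs_b),
            reference_rgb=(row.ref_r, row.ref_g, row.ref_b),
        )
        for row in df.itertuples()
    ]


def write_chart_csv(measurements: Iterable[ChartMeasurement], path: str | Path) -> None:
    rows = [
        {
            "patch_id": m.patch_id,
            "obs_r": m.observed_rgb[0],
            "obs_g": m.observed_rgb[1],
            "obs_b": m.observed_rgb[2],
            "ref_r": m.reference_rgb[0],
            "ref_g": m.reference_rgb[1],
            "ref_b": m.reference_rgb[2],
        }
        for m in measurements
    ]
    pd.DataFrame(rows, columns=_CHART_COLUMNS).to_csv(path, index=False)


def write_transform_json(t: CalibrationTransform, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"matrix": t.matrix.tolist(), "fit_residual": t.fit_residual}, indent=2)
    )


def read_transform_json(path: str | Path) -> CalibrationTransform:
    payload = json.loads(Path(path).read_text())
    return CalibrationTransform(
        matrix=np.asarray(payload["matrix"], dtype=float),
        fit_residual=float(payload["fit_residual"]),
    )
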