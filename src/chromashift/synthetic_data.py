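"""Synthetic study fixtures with known ground truth.

No raw photographs or phenotype records accompany the study this package
reimplements, so every test input is generated here with its ground truth
recorded:

* fish-on-background images — an elliptical "fish" of known mean Lab colour
  with optional mottling, plus the matching binary mask, with the exact
  post-quantisation region mean recorded by an independent per-pixel loop;
* colour-chart fixtures — 24 nominal sRGB patches pushed through a known
  linear cast, for calibration-recovery tests;
* phenotype shift tables — per-individual colour-shift records with the
  structure of the two experimental designs (social context: 2 lines x
  {control n=8, single n=9, group n=9} per line; infection: 80 fish, 40 per
  line, half infected), simulated from an explicit linear mixed-effects
  model y = X beta + u_individual + eps.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .calibration import ChartMeasurement
from .colour_core import (
    ColourAttributes,
    RGBImage,
    decode_srgb,
    encode_srgb,
    hue_chroma,
    lab_to_srgb8,
)
from .shift_assembly import INTERVALS, TIME_POINTS_H

__all__ = [
    "COLORCHECKER_SRGB",
    "FishImageSpec",
    "ExperimentDesign",
    "EffectModel",
    "social_design",
    "infection_design",
    "generate_fish_image",
    "generate_chart_fixture",
    "random_cast",
    "design_matrix",
    "generate_shift_dataset",
    "generate_attribute_trajectories",
]

# ---------------------------------------------------------------------------
# Colour chart
# ---------------------------------------------------------------------------

#: Nominal sRGB values of the classic 24-patch colour-rendition chart.
COLORCHECKER_SRGB: dict[str, tuple[int, int, int]] = {
    "dark_skin": (115, 82, 68),
    "light_skin": (194, 150, 130),
    "blue_sky": (98, 122, 157),
    "foliage": (87, 108, 67),
    "blue_flower": (133, 128, 177),
    "bluish_green": (103, 189, 170),
    "orange": (214, 126, 44),
    "purplish_blue": (80, 91, 166),
    "moderate_red": (193, 90, 99),
    "purple": (94, 60, 108),
    "yellow_green": (157, 188, 64),
    "orange_yellow": (224, 163, 46),
    "blue": (56, 61, 150),
    "green": (70, 148, 73),
    "red": (175, 54, 60),
    "yellow": (231, 199, 31),
    "magenta": (187, 86, 149),
    "cyan": (8, 133, 161),
    "white_95": (243, 243, 242),
    "neutral_8": (200, 200, 200),
    "neutral_65": (160, 160, 160),
    "neutral_5": (122, 122, 121),
    "neutral_35": (85, 85, 85),
    "black_2": (52, 52, 52),
}


def random_cast(seed: int, strength: float = 0.15) -> np.ndarray:
    """Draw a well-conditioned near-identity 3x3 colour cast.

    Diagonal channel gains in [1 - strength, 1 + strength] plus small
    cross-channel leakage; the result emulates a mild illumination change.
    """
    rng = np.random.default_rng(seed)
    ref_linear = decode_srgb(np.array(list(COLORCHECKER_SRGB.values()), float) / 255.0)
    for _ in range(1000):
        m = np.diag(rng.uniform(1.0 - strength, 1.0 + strength, size=3))
        m += rng.uniform(-strength / 3.0, strength / 3.0, size=(3, 3)) * (1 - np.eye(3))
        cast_chart = ref_linear @ m.T
        # a cast that clips chart patches at the gamut boundary is not
        # invertible from the chart and does not model a mild illumination
        # change; redraw until the chart stays in gamut
        if np.linalg.cond(m) < 1e3 and cast_chart.min() >= 0 and cast_chart.max() <= 1:
            return m
    raise ValueError("could not draw a gamut-preserving cast; use a smaller strength")


def generate_chart_fixture(
    cast_matrix: np.ndarray | None = None, quantise: bool = True
) -> list[ChartMeasurement]:
    """Synthesise chart measurements: observed = cast applied to reference.

    The cast acts in linearised RGB; the observed values are re-encoded and,
    by default, quantised to 8 bits as a camera would record them
    (``quantise=False`` keeps them continuous, the noiseless limit).
    ``None`` means no cast (observed equals reference exactly).
    """
    ref = np.array(list(COLORCHECKER_SRGB.values()), dtype=float)
    if cast_matrix is None:
        obs = ref.copy()
    else:
        cast = np.asarray(cast_matrix, dtype=float)
        if cast.shape != (3, 3):
            raise ValueError(f"cast must be 3x3, got {cast.shape}")
        if abs(np.linalg.det(cast)) < 1e-8:
            raise ValueError("singular cast matrix")
        linear = decode_srgb(ref / 255.0) @ cast.T
        obs = encode_srgb(np.clip(linear, 0.0, 1.0)) * 255.0
        if quantise:
            obs = np.rint(obs)
    return [
        ChartMeasurement(patch_id=name, observed_rgb=tuple(o), reference_rgb=tuple(r))
        for name, o, r in zip(COLORCHECKER_SRGB, obs, ref)
    ]


# ---------------------------------------------------------------------------
# Fish images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FishImageSpec:
    """Recipe for one synthetic fish photograph and its mask.

    The fish is an ellipse of base colour ``base_lab`` with optional
    mottling: independent zero-mean Gaussian Lab perturbations of standard
    deviation ``mottle_amplitude`` per channel, emulating the mottled grey
    melanin pattern of the killifish at the coarsest level.
    """

    size: tuple[int, int] = (128, 128)  # (height, width)
    centre: tuple[float, float] = (64.0, 64.0)  # (row, col)
    axes: tuple[float, float] = (28.0, 52.0)  # (semi-height, semi-width)
    base_lab: tuple[float, float, float] = (55.0, 2.0, 8.0)
    mottle_amplitude: float = 3.0
    background_rgb: tuple[int, int, int] = (30, 60, 90)
    seed: int = 0


# Pure-scalar reference conversion used for ground truth.  Kept deliberately
# independent of the vectorised path in colour_core so generated fixtures can
# arbitrate between the two.
_M = (
    (0.4124, 0.3576, 0.1805),
    (0.2126, 0.7152, 0.0722),
    (0.0193, 0.1192, 0.9505),
)
_WHITE = tuple(sum(row) for row in _M)
_D = 6.0 / 29.0


def _ref_decode(c: float) -> float:
    c /= 255.0
    return c / 12.92 if c <= 0.04045 else ((c + 0.055) / 1.055) ** 2.4


def _ref_f(t: float) -> float:
    return t ** (1.0 / 3.0) if t > _D**3 else t / (3.0 * _D * _D) + 4.0 / 29.0


def _reference_pixel_lab(r: int, g: int, b: int) -> tuple[float, float, float]:
    rl, gl, bl = _ref_decode(r), _ref_decode(g), _ref_decode(b)
    fx = _ref_f((_M[0][0] * rl + _M[0][1] * gl + _M[0][2] * bl) / _WHITE[0])
    fy = _ref_f((_M[1][0] * rl + _M[1][1] * gl + _M[1][2] * bl) / _WHITE[1])
    fz = _ref_f((_M[2][0] * rl + _M[2][1] * gl + _M[2][2] * bl) / _WHITE[2])
    return 116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)


def generate_fish_image(
    spec: FishImageSpec,
) -> tuple[RGBImage, np.ndarray, ColourAttributes]:
    """Render one fish photograph, its mask, and the exact region-mean truth.

    Returns ``(image, mask_image, truth)`` where ``mask_image`` is an 8-bit
    array (255 inside the fish ellipse, 0 outside) and ``truth`` is the mean
    Lab (plus hue/chroma) of the *rendered 8-bit* pixels, computed by an
    independent per-pixel scalar loop — not the pre-quantisation target.
    """
    h, w = spec.size
    cy, cx = spec.centre
    ay, ax = spec.axes
    if ay <= 0 or ax <= 0:
        raise ValueError("ellipse axes must be positive")
    if cy - ay < 0 or cy + ay > h - 1 or cx - ax < 0 or cx + ax > w - 1:
        raise ValueError(
            f"fish ellipse (centre {spec.centre}, axes {spec.axes}) "
            f"extends outside the {h}x{w} image"
        )
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0:h, 0:w]
    inside = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0

    pixels = np.empty((h, w, 3), dtype=np.uint8)
    pixels[:, :] = np.asarray(spec.background_rgb, dtype=np.uint8)
    n_in = int(inside.sum())
    lab = np.asarray(spec.base_lab, dtype=float) + spec.mottle_amplitude * rng.standard_normal(
        (n_in, 3)
    )
    lab[:, 0] = np.clip(lab[:, 0], 0.0, 100.0)
    pixels[inside] = lab_to_srgb8(lab)

    mask_image = np.where(inside, 255, 0).astype(np.uint8)

    total = [0.0, 0.0, 0.0]
    for r, g, b in pixels[inside]:
        L, a, bb = _reference_pixel_lab(int(r), int(g), int(b))
        total[0] += L
        total[1] += a
        total[2] += bb
    mean_l, mean_a, mean_b = (t / n_in for t in total)
    hue, chroma = hue_chroma(mean_a, mean_b)
    truth = ColourAttributes(L=mean_l, a=mean_a, b=mean_b, h=hue, C=chroma)
    return RGBImage(pixels=pixels), mask_image, truth


# ---------------------------------------------------------------------------
# Experimental designs
# ---------------------------------------------------------------------------

LINES = ("DAN", "R")


@dataclass(frozen=True)
class ExperimentDesign:
    """One of the two study designs, expanded to fish x treatment series.

    ``series`` has one row per (individual, treatment) combination; in the
    social design each of the 18 test fish appears under both the single and
    the group context (sharing its random intercept), alongside 16 controls,
    for 52 series from 34 unique fish.  The infection design has 80 fish,
    each in exactly one series.  Every series is photographed at 0/24/48 h.
    """

    experiment: str
    series: pd.DataFrame = field(repr=False)
    time_points: tuple[int, ...] = TIME_POINTS_H

    @property
    def n_units(self) -> int:
        """Number of fish x treatment series."""
        return len(self.series)

    @property
    def n_individuals(self) -> int:
        return self.series["individual_id"].nunique()

    @property
    def treatment_levels(self) -> tuple[str, ...]:
        order = {"social": ("control", "single", "group"), "infection": ("control", "infected")}
        return order[self.experiment]


def social_design() -> ExperimentDesign:
    """Social-context design: per line 8 controls plus 9 test fish measured
    under both the single-fish and the group context (52 series, 34 fish)."""
    rows = []
    for line in LINES:
        for i in range(1, 9):
            rows.append((f"{line}-C{i:02d}", line, "control"))
        for i in range(1, 10):
            rows.append((f"{line}-T{i:02d}", line, "single"))
            rows.append((f"{line}-T{i:02d}", line, "group"))
    series = pd.DataFrame(rows, columns=["individual_id", "line", "treatment"])
    return ExperimentDesign(experiment="social", series=series)


def infection_design() -> ExperimentDesign:
    """Infection design: 40 fish per line, 20 infected and 20 uninfected controls."""
    rows = []
    for line in LINES:
        for i in range(1, 21):
            rows.append((f"{line}-U{i:02d}", line, "control"))
        for i in range(1, 21):
            rows.append((f"{line}-I{i:02d}", line, "infected"))
    series = pd.DataFrame(rows, columns=["individual_id", "line", "treatment"])
    return ExperimentDesign(experiment="infection", series=series)


# ---------------------------------------------------------------------------
# Effect model and shift simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectModel:
    """Generating linear mixed-effects model for one colour attribute.

    ``effects`` maps encoded design columns to coefficients; keys use
    treatment-contrast names with the control level and the DAN line as
    references, e.g. ``"line[R]"``, ``"treatment[infected]"``, ``"time"``
    (continuous interval-end hour) or ``"time[24-48]"`` (categorical),
    and interactions joined by ``:`` such as ``"line[R]:treatment[infected]"``.
    Unknown keys are rejected at simulation time.  Defaults give effect
    magnitudes of the order seen in this kind of repeated-measures colour
    data: a treatment effect of a few L* units, an individual random
    intercept smaller than the residual scatter.
    """

    intercept: float = 0.0
    effects: Mapping[str, float] = field(default_factory=dict)
    sd_individual: float = 2.0
    sd_residual: float = 4.0

    def __post_init__(self) -> None:
        if self.sd_individual < 0 or self.sd_residual < 0:
            raise ValueError("standard deviations must be non-negative")


def _interval_end_hour(interval: str) -> int:
    return INTERVALS[interval][1]


def design_matrix(
    rows: pd.DataFrame,
    effect_names: tuple[str, ...],
    treatment_levels: tuple[str, ...],
    time_coding: str = "continuous",
) -> np.ndarray:
    """Encode covariate rows into the columns named by ``effect_names``.

    Treatment-contrast encoding: indicator columns for every non-reference
    level of ``line`` (reference DAN) and ``treatment`` (first of
    ``treatment_levels``); ``time`` is the interval-end hour when
    ``time_coding="continuous"``, or indicator columns ``interval[...]``
    (reference 0-24, columns named ``time[...]``) when categorical.
    Interaction columns are products of their parts.
    """
    base: dict[str, np.ndarray] = {}
    base["line[R]"] = (rows["line"] == "R").to_numpy(dtype=float)
    for level in treatment_levels[1:]:
        base[f"treatment[{level}]"] = (rows["treatment"] == level).to_numpy(dtype=float)
    if time_coding == "continuous":
        base["time"] = rows["interval"].map(_interval_end_hour).to_numpy(dtype=float)
    elif time_coding == "categorical":
        for label in list(INTERVALS)[1:]:
            base[f"time[{label}]"] = (rows["interval"] == label).to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown time_coding {time_coding!r}")

    cols = []
    for name in effect_names:
        parts = name.split(":")
        try:
            col = np.prod([base[p] for p in parts], axis=0)
        except KeyError as exc:
            raise ValueError(f"unknown effect term {name!r} (component {exc})") from exc
        cols.append(col)
    if not cols:
        return np.empty((len(rows), 0))
    return np.column_stack(cols)


def _expanded_rows(design: ExperimentDesign) -> pd.DataFrame:
    """One covariate row per series x interval."""
    reps = []
    for interval in INTERVALS:
        block = design.series.copy()
        block["interval"] = interval
        reps.append(block)
    return pd.concat(reps, ignore_index=True).sort_values(
        ["individual_id", "treatment", "interval"], ignore_index=True
    )


def generate_shift_dataset(
    design: ExperimentDesign,
    model: EffectModel,
    seed: int,
    attribute: str = "L",
    time_coding: str = "continuous",
) -> pd.DataFrame:
    """Simulate the long-format shift table directly from the LMM.

    One record per series x interval (three intervals per series):
    ``delta = intercept + X beta + u_individual + eps`` with
    ``u ~ N(0, sd_individual^2)`` drawn once per unique fish and
    ``eps ~ N(0, sd_residual^2)`` independent per record.  Deterministic
    given ``seed``.
    """
    rng = np.random.default_rng(seed)
    rows = _expanded_rows(design)
    names = tuple(model.effects)
    X = design_matrix(rows, names, design.treatment_levels, time_coding)
    beta = np.array([model.effects[n] for n in names], dtype=float)

    individuals = np.sort(design.series["individual_id"].unique())
    u = dict(zip(individuals, model.sd_individual * rng.standard_normal(len(individuals))))
    eps = model.sd_residual * rng.standard_normal(len(rows))

    delta = (
        model.intercept
        + (X @ beta if len(names) else 0.0)
        + rows["individual_id"].map(u).to_numpy()
        + eps
    )
    out = rows.copy()
    out["attribute"] = attribute
    out["delta"] = delta
    return out[["individual_id", "line", "treatment", "interval", "attribute", "delta"]]


def generate_attribute_trajectories(
    design: ExperimentDesign,
    model: EffectModel,
    seed: int,
    attribute: str = "L",
    baseline: float = 50.0,
    time_coding: str = "continuous",
) -> pd.DataFrame:
    """Simulate raw attribute values at 0/24/48 h instead of shifts.

    The value at 0 h is ``baseline``; each 24 h increment follows the same
    LMM as :func:`generate_shift_dataset` evaluated at its own interval
    (0-24 then 24-48).  Differencing the result with
    :func:`shift_assembly.compute_shifts` recovers additive shifts, which
    exercises the alternative measurement-then-difference pathway.

    Returns an attribute-record table (columns ``individual_id, line,
    treatment, time_h`` and the five attribute columns, with the
    non-simulated attributes held at neutral constants).
    """
    rng = np.random.default_rng(seed)
    names = tuple(model.effects)
    individuals = np.sort(design.series["individual_id"].unique())
    u = dict(zip(individuals, model.sd_individual * rng.standard_normal(len(individuals))))

    inc_rows = []
    for interval in ("0-24", "24-48"):
        block = design.series.copy()
        block["interval"] = interval
        inc_rows.append(block)
    inc = pd.concat(inc_rows, ignore_index=True)
    X = design_matrix(inc, names, design.treatment_levels, time_coding)
    beta = np.array([model.effects[n] for n in names], dtype=float)
    inc["increment"] = (
        model.intercept
        + (X @ beta if len(names) else 0.0)
        + inc["individual_id"].map(u).to_numpy()
        + model.sd_residual * rng.standard_normal(len(inc))
    )

    records = []
    neutral = {"L": 50.0, "a": 0.0, "b": 0.0, "h": 0.0, "C": 0.0}
    for (ind, line, treat), grp in inc.groupby(["individual_id", "line", "treatment"]):
        d = grp.set_index("interval")["increment"]
        values = {0: baseline, 24: baseline + d["0-24"], 48: baseline + d["0-24"] + d["24-48"]}
        for t, v in values.items():
            row = dict(individual_id=ind, line=line, treatment=treat, time_h=t, **neutral)
            row[attribute] = v
            records.append(row)
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Full image-experiment fixture (images + masks + manifest on disk)
# ---------------------------------------------------------------------------


def simulate_image_experiment(
    design: ExperimentDesign,
    out_dir,
    seed: int,
    image_size: tuple[int, int] = (128, 128),
    treatment_lightness_per_day: float = 2.0,
    individual_sd: float = 1.5,
    mottle_amplitude: float = 2.0,
) -> "pd.DataFrame":
    """Render one photograph + mask per series x time point and write a manifest.

    Fish lightness starts near L* = 55 and, for non-control treatments,
    rises by ``treatment_lightness_per_day`` per 24 h; each fish carries a
    persistent Gaussian offset of standard deviation ``individual_sd`` (the
    random intercept made visible in the images).  Images, masks, the
    manifest CSV and a per-photograph ground-truth CSV are written under
    ``out_dir``; the manifest DataFrame is returned.
    """
    import imageio.v3 as iio
    from pathlib import Path

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    h, w = image_size
    geometry = dict(
        size=(h, w),
        centre=(h / 2.0, w / 2.0),
        axes=(h * 0.22, w * 0.40),
    )
    individuals = np.sort(design.series["individual_id"].unique())
    offsets = dict(zip(individuals, individual_sd * rng.standard_normal(len(individuals))))

    manifest_rows, truth_rows = [], []
    for rec in design.series.itertuples():
        for t in design.time_points:
            bump = 0.0 if rec.treatment == "control" else treatment_lightness_per_day * t / 24.0
            base_l = 55.0 + offsets[rec.individual_id] + bump
            spec = FishImageSpec(
                base_lab=(base_l, 2.0, 8.0),
                mottle_amplitude=mottle_amplitude,
                seed=int(rng.integers(0, 2**31 - 1)),
                **geometry,
            )
            image, mask, truth = generate_fish_image(spec)
            stem = f"{rec.individual_id}_{rec.treatment}_{t:02d}h"
            img_path, mask_path = f"images/{stem}.png", f"images/{stem}_mask.png"
            iio.imwrite(out / img_path, image.pixels)
            iio.imwrite(out / mask_path, mask)
            manifest_rows.append(
                dict(
                    individual_id=rec.individual_id,
                    line=rec.line,
                    treatment=rec.treatment,
                    time_h=t,
                    image=img_path,
                    mask=mask_path,
                )
            )
            truth_rows.append(
                dict(
                    individual_id=rec.individual_id,
                    treatment=rec.treatment,
                    time_h=t,
                    L=truth.L,
                    a=truth.a,
                    b=truth.b,
                    h=truth.h,
                    C=truth.C,
                )
            )
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out / "truth.csv", index=False)
    return manifest
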