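"""Assembly of per-individual colour shifts across time points.

Each fish is photographed at 0, 24 and 48 h; the models operate on the
before-after change of each colour attribute over the three intervals
0-24, 0-48 and 24-48 h.  This module turns a table of per-photograph
attribute records into the long-format shift table the inference stage
consumes.

Sign convention: delta = later value minus earlier value, so a positive
lightness shift means the fish got lighter.  Hue is an angle, so its delta
is the signed shortest angular difference, in (-180, 180] degrees, which
avoids spurious +-360 jumps when a hue trajectory crosses 0.

Individuals (more precisely, fish x treatment series: a test fish measured
under two social contexts contributes two series) missing any of the three
time points are dropped from the output with a logged warning; duplicated
(individual, treatment, time) rows are an error.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = ["TIME_POINTS_H", "INTERVALS", "hue_difference", "compute_shifts"]

logger = logging.getLogger(__name__)

TIME_POINTS_H = (0, 24, 48)
#: interval label -> (earlier time, later time)
INTERVALS = {"0-24": (0, 24), "0-48": (0, 48), "24-48": (24, 48)}

#: attributes that are modelled downstream (a and b feed hue/chroma only)
DEFAULT_ATTRIBUTES = ("L", "h", "C")

_SERIES_KEYS = ["individual_id", "line", "treatment"]


def hue_difference(h_earlier: float | np.ndarray, h_later: float | np.ndarray) -> np.ndarray:
    """Signed shortest angular difference later - earlier, in (-180, 180] degrees."""
    d = (np.asarray(h_later, dtype=float) - np.asarray(h_earlier, dtype=float)) % 360.0
    return np.where(d > 180.0, d - 360.0, d)


def compute_shifts(
    records: pd.DataFrame, attributes: tuple[str, ...] = DEFAULT_ATTRIBUTES
) -> pd.DataFrame:
    """Difference attribute records over the standard intervals.

    Parameters
    ----------
    records
        One row per photograph with columns ``individual_id``, ``line``,
        ``treatment``, ``time_h`` and one column per attribute (at least
        those in ``attributes``).
    attributes
        Attribute columns to difference.  ``h`` uses the shortest-angle
        rule; all others are plain subtraction.

    Returns
    -------
    Long table with columns ``individual_id, line, treatment, interval,
    attribute, delta`` — one row per complete series x interval x attribute.
    """
    required = _SERIES_KEYS + ["time_h"] + list(attributes)
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ValueError(f"attribute table is missing columns: {missing}")

    dup = records.duplicated(subset=_SERIES_KEYS + ["time_h"])
    if dup.any():
        offender = records[dup].iloc[0][_SERIES_KEYS + ["time_h"]].tolist()
        raise ValueError(f"duplicate (individual, treatment, time) record: {offender}")

    bad_time = set(records["time_h"]) - set(TIME_POINTS_H)
    if bad_time:
        raise ValueError(f"unexpected time points {sorted(bad_time)}; expected {TIME_POINTS_H}")

    out_rows: list[dict] = []
    n_dropped = 0
    for keys, grp in records.groupby(_SERIES_KEYS, sort=True):
        times = set(grp["time_h"])
        if times != set(TIME_POINTS_H):
            n_dropped += 1
            logger.warning(
                "dropping incomplete series %s: has time points %s", keys, sorted(times)
            )
            continue
        by_time = grp.set_index("time_h")
        for label, (t0, t1) in INTERVALS.items():
            for attr in attributes:
                earlier = float(by_time.loc[t0, attr])
                later = float(by_time.loc[t1, attr])
                if attr == "h":
                    delta = float(hue_difference(earlier, later))
                else:
                    delta = later - earlier
                out_rows.append(
                    dict(
                        individual_id=keys[0],
                        line=keys[1],
                        treatment=keys[2],
                        interval=label,
                        attribute=attr,
                        delta=delta,
                    )
                )
    if n_dropped:
        logger.warning("dropped %d incomplete series", n_dropped)
    return pd.DataFrame(
        out_rows,
        columns=["individual_id", "line", "treatment", "interval", "attribute", "delta"],
    )
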