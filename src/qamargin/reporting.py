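"""Numerical QAM summaries: percentiles, traffic-light classes, substrata.

The margin distribution is reported numerically as min / 25th / 50th /
75th percentile / max, as relative class fractions in the traffic-light
scheme (orange x < 0 mm, yellow 0 <= x < 5 mm, green x >= 5 mm), and as a
histogram of 1 mm substrata centred on integer millimetres.  Class
fractions and percentiles are always computed over the included voxels
only; subcapsular-excluded voxels change the denominator, they are never
counted as margin 0.

Next to the raw-precision percentiles the summary carries a substrata
distance summary, i.e. the same five order statistics computed after
rounding each margin to the nearest substrata centre.  On 1 mm grids the
raw margins are square roots of integers, so the substrata summary is what
a whole-millimetre report of the distribution looks like.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_model import AllExcludedError
from .qam_core import MarginDistribution

__all__ = [
    "TrafficLightClass",
    "ORANGE",
    "YELLOW",
    "GREEN",
    "classify",
    "QAMSummary",
    "summarize",
    "write_summary",
    "format_summary_table",
    "write_distances",
    "DEFAULT_CLASS_LOW",
    "DEFAULT_CLASS_HIGH",
    "DEFAULT_BIN_WIDTH",
]

DEFAULT_CLASS_LOW = 0.0
DEFAULT_CLASS_HIGH = 5.0
DEFAULT_BIN_WIDTH = 1.0


@dataclass(frozen=True)
class TrafficLightClass:
    """One of the three margin classes; intervals partition the real line."""

    label: str
    interval: str


ORANGE = TrafficLightClass("orange", "x < low")
YELLOW = TrafficLightClass("yellow", "low <= x < high")
GREEN = TrafficLightClass("green", "x >= high")


def classify(
    margin: float,
    low: float = DEFAULT_CLASS_LOW,
    high: float = DEFAULT_CLASS_HIGH,
) -> TrafficLightClass:
    """Traffic-light class of one margin: orange below ``low``, yellow in
    ``[low, high)``, green at or above ``high``."""
    if not low < high:
        raise ValueError(f"class bounds must satisfy low < high, got {low}, {high}")
    if margin < low:
        return ORANGE
    if margin < high:
        return YELLOW
    return GREEN


@dataclass(frozen=True)
class QAMSummary:
    """Numerical record of one margin distribution."""

    n_included: int
    n_excluded: int
    min_mm: float
    p25_mm: float
    median_mm: float
    p75_mm: float
    max_mm: float
    #: (min, p25, median, p75, max) of the margins rounded to substrata centres
    substrata_mm: tuple[float, float, float, float, float]
    #: percentages over included voxels, keys "orange"/"yellow"/"green"
    class_fractions: dict
    #: ordered (bin centre mm, percentage) pairs, contiguous, width bin_width
    bins: tuple
    class_low: float = DEFAULT_CLASS_LOW
    class_high: float = DEFAULT_CLASS_HIGH
    bin_width: float = DEFAULT_BIN_WIDTH
    zero_set: str = "surface"

    def to_dict(self) -> dict:
        return {
            "n_included": self.n_included,
            "n_excluded": self.n_excluded,
            "min_mm": round(self.min_mm, 2),
            "p25_mm": round(self.p25_mm, 2),
            "median_mm": round(self.median_mm, 2),
            "p75_mm": round(self.p75_mm, 2),
            "max_mm": round(self.max_mm, 2),
            "substrata_mm": {
                k: round(v, 2)
                for k, v in zip(("min", "p25", "median", "p75", "max"), self.substrata_mm)
            },
            "class_fractions_pct": {k: v for k, v in self.class_fractions.items()},
            "bins": [{"center_mm": c, "pct": p} for c, p in self.bins],
            "class_low_mm": self.class_low,
            "class_high_mm": self.class_high,
            "bin_width_mm": self.bin_width,
            "zero_set": self.zero_set,
        }


def _bin_centers(margins: np.ndarray, bin_width: float) -> np.ndarray:
    """Index of the substrata bin [k*w - w/2, k*w + w/2) holding each margin."""
    return np.floor(margins / bin_width + 0.5).astype(np.int64)


def _percentiles(margins: np.ndarray, method: str) -> np.ndarray:
    if method == "linear":
        return np.percentile(margins, (25, 50, 75))
    if method == "nearest":
        return np.percentile(margins, (25, 50, 75), method="closest_observation")
    raise ValueError(f"unknown percentile method {method!r}")


def summarize(
    dist: MarginDistribution,
    low: float = DEFAULT_CLASS_LOW,
    high: float = DEFAULT_CLASS_HIGH,
    bin_width: float = DEFAULT_BIN_WIDTH,
    percentile_method: str = "linear",
) -> QAMSummary:
    """Summary statistics, class fractions and substrata histogram.

    Percentiles use linear interpolation between closest ranks by default
    (``percentile_method="nearest"`` selects the closest observation
    instead).  Class fractions are computed from the raw margins, never
    from histogram bins.
    """
    m = np.asarray(dist.margins, dtype=float)
    if m.size == 0:
        raise AllExcludedError("margin distribution is empty; nothing to summarize")
    if not low < high:
        raise ValueError(f"class bounds must satisfy low < high, got {low}, {high}")
    n = m.size
    q25, q50, q75 = _percentiles(m, percentile_method)
    frac = {
        "orange": round(float(100.0 * (m < low).sum() / n), 2),
        "yellow": round(float(100.0 * ((m >= low) & (m < high)).sum() / n), 2),
        "green": round(float(100.0 * (m >= high).sum() / n), 2),
    }
    k = _bin_centers(m, bin_width)
    k_all = np.arange(k.min(), k.max() + 1)
    counts = np.bincount(k - k.min(), minlength=k_all.size)
    bins = tuple(
        (float(c * bin_width), round(float(100.0 * cnt / n), 2))
        for c, cnt in zip(k_all, counts)
    )
    rounded = k.astype(float) * bin_width
    sub = (
        float(rounded.min()),
        *(float(x) for x in _percentiles(rounded, percentile_method)),
        float(rounded.max()),
    )
    return QAMSummary(
        n_included=int(n),
        n_excluded=dist.n_excluded,
        min_mm=float(m.min()),
        p25_mm=float(q25),
        median_mm=float(q50),
        p75_mm=float(q75),
        max_mm=float(m.max()),
        substrata_mm=sub,
        class_fractions=frac,
        bins=bins,
        class_low=low,
        class_high=high,
        bin_width=bin_width,
        zero_set=dist.zero_set,
    )


def format_summary_table(summary: QAMSummary, case_id: str = "") -> str:
    """Human-readable two-column table mirroring the numerical report."""
    lo, hi = summary.class_low, summary.class_high
    rows = [
        ("Case ID", case_id or "-", "", ""),
        ("Euclidean distance (mm)", "", "Tumor surface covered", ""),
        ("Min", f"{summary.min_mm:.2f}", f"x < {lo:g}",
         f"{summary.class_fractions['orange']:.2f}%"),
        ("25th percentile", f"{summary.p25_mm:.2f}",
         f"{lo:g} <= x < {hi:g}", f"{summary.class_fractions['yellow']:.2f}%"),
        ("Median", f"{summary.median_mm:.2f}", f"x >= {hi:g}",
         f"{summary.class_fractions['green']:.2f}%"),
        ("75th percentile", f"{summary.p75_mm:.2f}", "", ""),
        ("Max", f"{summary.max_mm:.2f}", "", ""),
        ("Included voxels", str(summary.n_included), "Excluded voxels",
         str(summary.n_excluded)),
    ]
    widths = [max(len(r[i]) for r in rows) for i in range(4)]
    return "\n".join(
        "  ".join(col.ljust(w) for col, w in zip(row, widths)).rstrip()
        for row in rows
    )


def write_summary(summary: QAMSummary, path, case_id: str = "") -> Path:
    """Write the summary as JSON; a plain-text table goes next to it.

    The JSON file is the machine-readable record; the sibling ``.txt``
    holds the human-readable table.
    """
    path = Path(path)
    try:
        with open(path, "w") as fh:
            json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        txt = path.with_suffix(".txt") if path.suffix else Path(str(path) + ".txt")
        txt.write_text(format_summary_table(summary, case_id) + "\n")
    except IsADirectoryError:
        raise
    except OSError:
        raise
    return path


def write_distances(dist: MarginDistribution, path) -> Path:
    """CSV of per-voxel margins: one row per tumor surface voxel.

    Included voxels carry their signed margin in mm; subcapsular-excluded
    voxels are flagged and carry no margin value.
    """
    path = Path(path)
    lines = ["i,j,k,margin_mm,excluded"]
    for (i, j, k), m in zip(dist.included.indices, dist.margins):
        lines.append(f"{i},{j},{k},{m:.6g},0")
    for i, j, k in np.asarray(dist.excluded, dtype=np.int64).reshape(-1, 3):
        lines.append(f"{i},{j},{k},,1")
    path.write_text("\n".join(lines) + "\n")
    return path
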