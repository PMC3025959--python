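"""Spot-level two-color array parsing, background, and expression calls.

The input is a feature-extraction-style tab-delimited table, one row per
spot, with per-channel foreground/background, a control class and a
manual flag — a strict subset mapping of GenePix-results conventions:

    Slide  Block  Row  Column  ID  ControlClass  F_red  B_red
    F_green  B_green  Flag

Background noise is estimated from printed negative-control (NC) spots:
a gene is called expressed in a channel when its foreground exceeds
median(NC) + 2·SD(NC) for that channel.  Spot filtering before
normalization uses a stricter control-based threshold (90th percentile
of empty/NC intensities + 2·SD) that must be exceeded in BOTH channels.
Flagged spots never enter any statistic.  Local background is reported
(median of the surrounding regions) but not subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median

import numpy as np
import pandas as pd

__all__ = [
    "MANDATORY_COLUMNS",
    "QCThresholds",
    "read_spot_table",
    "write_spot_table",
    "local_background",
    "expression_threshold",
    "is_expressed",
    "present_across",
    "filter_spots",
]

MANDATORY_COLUMNS = (
    "Slide", "Block", "Row", "Column", "ID", "ControlClass",
    "F_red", "B_red", "F_green", "B_green", "Flag",
)
CONTROL_CLASSES = ("probe", "negative", "empty", "positive")
CHANNELS = ("red", "green")


@dataclass(frozen=True)
class QCThresholds:
    """Per-channel thresholds derived from a slide's control spots.

    ``expression_threshold[ch]`` = median(NC) + 2·SD(NC);
    ``filter_threshold[ch]`` = P90(empty+NC) + 2·SD(empty+NC).
    SD is the sample (n−1) standard deviation.
    """

    nc_median: dict
    nc_sd: dict
    expression_threshold: dict
    filter_threshold: dict


class SpotTableError(ValueError):
    pass


def read_spot_table(path) -> pd.DataFrame:
    """Read and validate a spot table; malformed rows are reported with
    their (1-based, header-inclusive) line numbers."""
    df = pd.read_csv(path, sep="\t", dtype={"Slide": str, "ID": str})
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SpotTableError(f"missing mandatory column(s): {', '.join(missing)}")
    return _validate_spot_table(df)


def _validate_spot_table(df: pd.DataFrame) -> pd.DataFrame:
    bad_lines = []
    intensity_cols = ["F_red", "B_red", "F_green", "B_green"]
    for col in intensity_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0)
        bad_lines.extend((df.index[bad] + 2).tolist())  # +2: header + 1-basing
        df[col] = vals
    bad_cc = ~df["ControlClass"].isin(CONTROL_CLASSES)
    bad_lines.extend((df.index[bad_cc] + 2).tolist())
    bad_flag = ~df["Flag"].isin(["ok", "manual_flag"])
    bad_lines.extend((df.index[bad_flag] + 2).tolist())
    if bad_lines:
        raise SpotTableError(
            f"malformed rows at line(s): {sorted(set(bad_lines))}"
        )
    return df


def write_spot_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def local_background(neighborhood) -> float:
    """Median of the 1-4 available surrounding-region intensities."""
    vals = [float(v) for v in neighborhood]
    if not vals:
        raise ValueError("no surrounding regions available")
    if not 1 <= len(vals) <= 4:
        raise ValueError("expected 1-4 surrounding regions")
    return float(median(vals))


def _unflagged(df: pd.DataFrame) -> pd.DataFrame:
    return df[df["Flag"] == "ok"]


def expression_threshold(slide: pd.DataFrame, sd_multiplier: float = 2.0,
                         filter_percentile: float = 90.0) -> QCThresholds:
    """Control-derived thresholds for one slide.

    Needs at least 2 unflagged negative-control spots per channel (the SD
    is undefined otherwise).
    """
    ok = _unflagged(slide)
    nc = ok[ok["ControlClass"] == "negative"]
    if len(nc) < 2:
        raise ValueError("need >= 2 unflagged negative-control spots")
    ctrl = ok[ok["ControlClass"].isin(["negative", "empty"])]
    nc_median, nc_sd, expr, filt = {}, {}, {}, {}
    for ch in CHANNELS:
        col = f"F_{ch}"
        m = float(nc[col].median())
        s = float(nc[col].std(ddof=1))
        nc_median[ch], nc_sd[ch] = m, s
        expr[ch] = m + sd_multiplier * s
        cvals = ctrl[col].to_numpy(dtype=float)
        filt[ch] = float(
            np.percentile(cvals, filter_percentile) + sd_multiplier * np.std(cvals, ddof=1)
        )
    return QCThresholds(nc_median, nc_sd, expr, filt)


def is_expressed(fg: float, thresholds: QCThresholds, channel: str) -> bool:
    """Strict exceedance of the channel's expression threshold."""
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    return float(fg) > thresholds.expression_threshold[channel]


def present_across(calls, k: int = 5, n: int = 6) -> bool:
    """True iff at least k of the n per-hybridization calls are positive."""
    calls = list(calls)
    if len(calls) != n:
        raise ValueError(f"expected {n} calls, got {len(calls)}")
    return sum(bool(c) for c in calls) >= k


def filter_spots(slide: pd.DataFrame, thresholds: QCThresholds | None = None) -> pd.DataFrame:
    """Retain unflagged probe spots above the filter threshold in BOTH
    channels."""
    if thresholds is None:
        thresholds = expression_threshold(slide)
    ok = _unflagged(slide)
    probes = ok[ok["ControlClass"] == "probe"]
    keep = (probes["F_red"] > thresholds.filter_threshold["red"]) & (
        probes["F_green"] > thresholds.filter_threshold["green"]
    )
    return probes[keep]


def expression_calls(slide: pd.DataFrame, thresholds: QCThresholds | None = None,
                     combine: str = "per_channel") -> pd.DataFrame:
    """Per-spot expressed/not calls for unflagged probe spots.

    ``combine``: 'per_channel' returns both channels; 'union' /
    'intersection' collapse them into a single boolean.
    """
    if thresholds is None:
        thresholds = expression_threshold(slide)
    ok = _unflagged(slide)
    probes = ok[ok["ControlClass"] == "probe"].copy()
    red = probes["F_red"] > thresholds.expression_threshold["red"]
    green = probes["F_green"] > thresholds.expression_threshold["green"]
    probes["expressed_red"] = red
    probes["expressed_green"] = green
    if combine == "union":
        probes["expressed"] = red | green
    elif combine == "intersection":
        probes["expressed"] = red & green
    elif combine != "per_channel":
        raise ValueError(f"unknown combine mode {combine!r}")
    return probes
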