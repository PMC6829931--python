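"""Per-trial feature extraction from seat-pressure sequences.

Five scalar features summarise one motion trial:

* ``ASV`` — average sensor value, the per-trial mean of the summed frame
  pressure ``SSV(t) = sum_i p_i(t)``:  ``ASV = (1/T) * sum_t SSV(t)``.
* ``SD_LatCOP`` / ``SD_LonCOP`` — standard deviations of the lateral and
  longitudinal centre of pressure, the pressure-weighted mean sensor
  coordinates ``LatCOP(t) = sum_i x_i p_i(t) / SSV(t)`` (columns) and
  ``LonCOP(t) = sum_i y_i p_i(t) / SSV(t)`` (rows).
* ``SD_LRratio`` / ``SD_FBratio`` — standard deviations of the left/right
  and front/back half-pressure ratios.

The COP and ratio series are undefined for frames whose total pressure (or
a ratio denominator) is zero; such frames are flagged invalid and excluded
from the standard deviations, while ``ASV`` always averages over all ``T``
frames.

``axis_mode`` controls which grid axis the half-ratios split. In
``"semantic"`` mode (default) ``LRratio`` splits the lateral axis (columns)
and ``FBratio`` the longitudinal axis (rows), so each ratio matches its
name. ``"literal"`` mode swaps the axes, reproducing a formula variant in
which the LR ratio is written over longitudinal halves and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pressure import PressureSequence

__all__ = [
    "FEATURE_NAMES",
    "FrameSeries",
    "FeatureVector",
    "ssv_series",
    "asv",
    "cop_series",
    "ratio_series",
    "frame_series",
    "extract_features",
    "feature_table",
]

FEATURE_NAMES = ("asv", "sd_lat_cop", "sd_lon_cop", "sd_lr_ratio", "sd_fb_ratio")


@dataclass
class FrameSeries:
    """Per-frame series underlying the five features.

    Invalid frames hold ``nan`` in the COP/ratio series and ``False`` in
    ``valid``.
    """

    ssv: np.ndarray
    lat_cop: np.ndarray
    lon_cop: np.ndarray
    lr_ratio: np.ndarray
    fb_ratio: np.ndarray
    valid: np.ndarray


@dataclass
class FeatureVector:
    """The five per-trial classification features."""

    asv: float
    sd_lat_cop: float
    sd_lon_cop: float
    sd_lr_ratio: float
    sd_fb_ratio: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.asv, self.sd_lat_cop, self.sd_lon_cop, self.sd_lr_ratio, self.sd_fb_ratio]
        )


def ssv_series(seq: PressureSequence) -> np.ndarray:
    """Sum of sensor values per frame, ``SSV(t)``."""
    return seq.frames.sum(axis=(1, 2))


def asv(seq: PressureSequence) -> float:
    """Average sensor value over the trial, ``ASV = sum_t SSV(t) / T``."""
    return float(ssv_series(seq).mean())


def cop_series(seq: PressureSequence) -> tuple[np.ndarray, np.ndarray]:
    """Lateral and longitudinal centre-of-pressure series.

    ``LatCOP(t)`` is the pressure-weighted mean column (1-based), and
    ``LonCOP(t)`` the weighted mean row. Frames with zero total pressure
    yield ``nan`` (flagged, not raised).
    """
    x = np.arange(1, seq.n_cols + 1, dtype=float)
    y = np.arange(1, seq.n_rows + 1, dtype=float)
    ssv = ssv_series(seq)
    with np.errstate(invalid="ignore", divide="ignore"):
        lat = seq.frames.sum(axis=1) @ x / ssv
        lon = seq.frames.sum(axis=2) @ y / ssv
    lat[ssv == 0] = np.nan
    lon[ssv == 0] = np.nan
    return lat, lon


def _half_sums(frames: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
    n = frames.shape[axis]
    if n % 2:
        raise ValueError(f"grid axis of length {n} cannot be split into halves")
    lo = frames.take(range(n // 2), axis=axis).sum(axis=(1, 2))
    hi = frames.take(range(n // 2, n), axis=axis).sum(axis=(1, 2))
    return lo, hi


def ratio_series(
    seq: PressureSequence,
    axis_mode: str = "semantic",
    flip_lateral: bool = False,
    flip_longitudinal: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Left/right and front/back half-pressure ratio series.

    The left half is columns ``1..n/2`` and the front half rows ``1..n/2``
    (flip with ``flip_lateral`` / ``flip_longitudinal`` if the mat was
    mounted the other way round). Frames with a zero denominator half
    yield ``nan``.
    """
    if axis_mode not in ("semantic", "literal"):
        raise ValueError(f"unknown axis_mode {axis_mode!r}")
    left, right = _half_sums(seq.frames, axis=2)  # column halves (lateral)
    front, back = _half_sums(seq.frames, axis=1)  # row halves (longitudinal)
    if flip_lateral:
        left, right = right, left
    if flip_longitudinal:
        front, back = back, front
    if axis_mode == "semantic":
        lr_num, lr_den = left, right
        fb_num, fb_den = front, back
    else:  # literal: LR over longitudinal halves, FB over lateral halves
        lr_num, lr_den = front, back
        fb_num, fb_den = left, right
    with np.errstate(invalid="ignore", divide="ignore"):
        lr = np.where(lr_den > 0, lr_num / lr_den, np.nan)
        fb = np.where(fb_den > 0, fb_num / fb_den, np.nan)
    return lr, fb


def frame_series(seq: PressureSequence, axis_mode: str = "semantic") -> FrameSeries:
    """Compute all per-frame series and the combined validity mask."""
    ssv = ssv_series(seq)
    lat, lon = cop_series(seq)
    lr, fb = ratio_series(seq, axis_mode=axis_mode)
    valid = (ssv > 0) & ~np.isnan(lr) & ~np.isnan(fb)
    return FrameSeries(ssv=ssv, lat_cop=lat, lon_cop=lon, lr_ratio=lr, fb_ratio=fb, valid=valid)


def extract_features(
    seq: PressureSequence, axis_mode: str = "semantic", ddof: int = 1
) -> FeatureVector:
    """Assemble the five-feature vector for one trial.

    ``ASV`` averages over all frames; the four standard deviations are
    sample SDs (``ddof=1``) over valid frames only. Raises ``ValueError``
    (naming the trial) if fewer than two frames are valid.
    """
    series = frame_series(seq, axis_mode=axis_mode)
    n_valid = int(series.valid.sum())
    if n_valid < 2:
        raise ValueError(
            f"trial {seq.meta.as_dict()}: only {n_valid} valid frame(s); "
            "need at least 2 for standard deviations"
        )
    v = series.valid
    return FeatureVector(
        asv=float(series.ssv.mean()),
        sd_lat_cop=float(np.std(series.lat_cop[v], ddof=ddof)),
        sd_lon_cop=float(np.std(series.lon_cop[v], ddof=ddof)),
        sd_lr_ratio=float(np.std(series.lr_ratio[v], ddof=ddof)),
        sd_fb_ratio=float(np.std(series.fb_ratio[v], ddof=ddof)),
    )


def feature_table(
    trials: Iterable[PressureSequence] | Sequence[PressureSequence],
    axis_mode: str = "semantic",
) -> pd.DataFrame:
    """Extract features for a collection of trials into a tidy table.

    Columns: ``subject, task, side, label`` plus the five feature columns.
    """
    records = []
    for seq in trials:
        fv = extract_features(seq, axis_mode=axis_mode)
        rec = seq.meta.as_dict()
        rec.update(zip(FEATURE_NAMES, fv.as_array()))
        records.append(rec)
    if not records:
        raise ValueError("no trials given")
    return pd.DataFrame.from_records(records)
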