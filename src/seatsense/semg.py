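"""Surface-EMG preprocessing and RMS summaries for the trunk muscles.

Nine trunk muscles are monitored during seated reaching: left/right rectus
abdominis (LRA, RRA), left/right obliquus externus abdominis (LOEA, ROEA),
left/right thoracic erector spinae (LTES, RTES), left/right lumbar erector
spinae (LLES, RLES) and the descending trapezius (DT) of the moving arm.
Recordings are digitised at 2 kHz.

The preprocessing chain, applied per channel in order:

1. baseline correction (mean subtraction),
2. 20–200 Hz band-pass (4th-order Butterworth, zero-phase),
3. 50 Hz mains notch (4th-order Butterworth band-stop, 48–52 Hz, zero-phase),
4. full-wave rectification,
5. amplitude normalisation (default: per-channel trial maximum).

Zero-phase (forward-backward) filtering avoids phase distortion in the
amplitude envelope; the effective filter order is therefore doubled.

The RMS of the processed signal over a whole motion trial indexes the
activation level of each muscle; Ave-RMS averages trial RMS values across
subjects per muscle, movement and body side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "MUSCLES",
    "EMGRecording",
    "bandpass_notch",
    "preprocess_emg",
    "rms",
    "rms_table",
    "ave_rms",
]

#: The nine monitored trunk muscles.
MUSCLES = ("LRA", "RRA", "LOEA", "ROEA", "LTES", "RTES", "LLES", "RLES", "DT")


@dataclass
class EMGRecording:
    """Multichannel sEMG recording of one motion trial.

    ``data`` has one column per muscle (mV); all channels share the sample
    rate. ``meta`` carries subject / side / movement label.
    """

    data: pd.DataFrame
    sample_rate: float = 2000.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.data) == 0:
            raise ValueError("empty EMG recording")

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.data)


def bandpass_notch(
    x: np.ndarray,
    sample_rate: float,
    band: tuple[float, float] = (20.0, 200.0),
    notch: tuple[float, float] = (48.0, 52.0),
    order: int = 4,
) -> np.ndarray:
    """Linear part of the chain: zero-phase band-pass then band-stop notch."""
    if sample_rate < 2 * band[1]:
        raise ValueError(
            f"sample rate {sample_rate} Hz too low for a {band[1]} Hz band edge"
        )
    sos_bp = sps.butter(order, band, btype="bandpass", fs=sample_rate, output="sos")
    sos_bs = sps.butter(order, notch, btype="bandstop", fs=sample_rate, output="sos")
    y = sps.sosfiltfilt(sos_bp, np.asarray(x, dtype=float))
    return sps.sosfiltfilt(sos_bs, y)


def preprocess_emg(
    rec: EMGRecording,
    band: tuple[float, float] = (20.0, 200.0),
    notch: tuple[float, float] = (48.0, 52.0),
    order: int = 4,
    normalize: str = "max",
) -> EMGRecording:
    """Run the full preprocessing chain on every channel.

    ``normalize="max"`` divides each rectified channel by its trial maximum
    (output in [0, 1]); ``normalize="none"`` skips the division. An
    all-zero channel is left at zero rather than divided by zero.
    """
    if normalize not in ("max", "none"):
        raise ValueError(f"unknown normalization {normalize!r}")
    out = {}
    for ch in rec.data.columns:
        x = rec.data[ch].to_numpy(dtype=float)
        if x.size == 0:
            raise ValueError(f"channel {ch} is empty")
        x = x - x.mean()  # baseline correction
        y = np.abs(bandpass_notch(x, rec.sample_rate, band, notch, order))
        if normalize == "max":
            peak = y.max()
            if peak > 0:
                y = y / peak
        out[ch] = y
    return EMGRecording(pd.DataFrame(out), sample_rate=rec.sample_rate, meta=dict(rec.meta))


def rms(x: Sequence[float] | np.ndarray) -> float:
    """Root mean square of a signal over the whole trial segment."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("rms of an empty signal")
    return float(np.sqrt(np.mean(x**2)))


def rms_table(recordings: Iterable[EMGRecording]) -> pd.DataFrame:
    """Tidy table of per-trial, per-channel RMS values.

    Rows carry the recording metadata (subject, side, movement, ...) plus
    ``channel`` and ``rms``.
    """
    records = []
    for rec in recordings:
        for ch in rec.data.columns:
            row = dict(rec.meta)
            row["channel"] = ch
            row["rms"] = rms(rec.data[ch].to_numpy())
            records.append(row)
    if not records:
        raise ValueError("no recordings given")
    return pd.DataFrame.from_records(records)


def ave_rms(
    table: pd.DataFrame,
    by: Sequence[str] = ("channel", "movement", "side"),
    subject_col: str = "subject",
    value_col: str = "rms",
) -> pd.DataFrame:
    """Average RMS across subjects per cell of ``by``.

    Trial RMS values are first averaged within subject (one value per
    subject per cell), then the across-subject mean and SD are reported.
    With a single subject the SD is 0 by convention. Cells absent from the
    input are simply missing from the output (flagged by absence, never an
    error).
    """
    by = list(by)
    per_subject = (
        table.groupby(by + [subject_col], sort=True)[value_col].mean().reset_index()
    )
    g = per_subject.groupby(by, sort=True)[value_col]
    out = g.agg(ave_rms="mean", sd=lambda v: v.std(ddof=1), n_subjects="count")
    out["sd"] = out["sd"].fillna(0.0)
    return out.reset_index()
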