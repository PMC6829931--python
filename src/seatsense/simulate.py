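"""Synthetic seated-pressure and sEMG trial generator.

The clinical recordings behind this system are not publicly deposited, so
this module generates labelled trials with the statistical structure the
detection method assumes, for end-to-end testing and benchmarking.

Seat-pressure model
-------------------
The seated pressure map is two bell-shaped peaks under the ischial
tuberosities plus a broad anterior thigh band, on the 32 x 32 grid
(front = row 1, left = column 1). During a reach the whole distribution
sways along a smooth out-and-back envelope ``e(t) = sin^2(pi t / (T-1))``;
compensation patterns add label-specific displacement or load asymmetry on
top, scaled by ``m(t) = e(t)/mean(e)`` so that the *trial-mean* applied
shift equals the configured effect size:

* ``NC``   — mild task-dependent sway only (back-and-forth reaches sway
  mostly longitudinally, side-to-side mostly laterally);
* ``TLF``  — trunk lean-forward: the distribution shifts toward the front
  rows by ``tlf_forward_shift`` rows on average;
* ``TR``   — trunk rotation: a lateral shift of ``tr_lateral_shift``
  columns toward the contralateral side plus loading of one ischial peak
  and unloading of the other (``tr_load_asymmetry``);
* ``SE``   — shoulder elevation: a small ipsilateral lateral shift
  (``se_ipsilateral_shift``) with extra loading of the ipsilateral peak
  (``se_amp_asymmetry``).

Per-subject anatomy (peak positions, overall load, effect magnitude) and
per-trial execution (sway amplitude, effect magnitude, reach direction)
are randomised, then multiplicative and additive sensor noise is applied
and values clipped at zero. All randomness flows from one root seed; the
same seed regenerates a dataset bit-for-bit, and a trial's random draws do
not depend on its label, so zeroing all effect sizes makes a compensation
trial identical to its NC counterpart.

sEMG model
----------
Companion recordings are band-limited (20–200 Hz) noise carriers modulated
by the reach envelope on 9 trunk-muscle channels. On the affected side the
channels associated with the trial's compensation pattern (TLF -> rectus
abdominis / obliquus externus / thoracic erector spinae, TR -> lumbar
erector spinae, SE -> descending trapezius) are scaled up by
``semg_affected_gain``, emulating the elevated affected-side activation
the pressure-based detector is cross-checked against.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .pressure import LABELS, SIDES, TASKS, PressureSequence, TrialMeta, write_pressure_ascii
from .semg import MUSCLES, EMGRecording

__all__ = [
    "SimulationParams",
    "SubjectProfile",
    "SimulatedDataset",
    "make_subject_profiles",
    "simulate_trial",
    "simulate_dataset",
    "simulate_semg",
    "write_dataset",
]

#: Affected-side muscle groups whose activation a pattern elevates.
PATTERN_MUSCLES: Mapping[str, tuple[str, ...]] = {
    "TLF": ("LRA", "RRA", "LOEA", "ROEA", "LTES", "RTES"),
    "TR": ("LLES", "RLES"),
    "SE": ("DT",),
}


@dataclass
class SimulationParams:
    """All knobs of the generator; defaults are the study conditions.

    Units: rows/columns are sensor pitches (~15 mm on the physical mat),
    amplitudes are arbitrary device units, durations seconds.
    """

    # grid & timing
    n_rows: int = 32
    n_cols: int = 32
    sample_rate: float = 50.0
    duration: float = 3.0  # one self-paced reach, out and back

    # baseline seated posture (ischial peaks toward the seat back)
    peak_row: float = 22.0
    peak_cols: tuple[float, float] = (12.5, 20.5)  # left, right ischial peak
    peak_sigma: float = 2.6
    peak_amp: float = 45.0
    thigh_row: float = 7.0
    thigh_sigma_row: float = 3.0
    thigh_sigma_col: float = 6.0
    thigh_amp: float = 12.0

    # NC sway amplitude (lateral cols, longitudinal rows) per task
    sway_amp: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "back-and-forth": (0.2, 0.7),
            "side-to-side": (0.6, 0.2),
            "up-and-down": (0.25, 0.25),
        }
    )

    # compensation effect sizes (trial-mean displacement / relative load)
    tlf_forward_shift: float = 3.0  # rows
    tr_lateral_shift: float = 2.5  # columns
    tr_load_asymmetry: float = 0.3
    se_ipsilateral_shift: float = 0.6  # columns
    se_amp_asymmetry: float = 0.25

    # sensor noise
    mult_noise_sd: float = 0.08
    add_noise_sd: float = 0.3

    # inter-subject / inter-trial variability (lognormal sigmas unless noted)
    subject_center_sd: float = 1.0  # rows/cols, normal
    subject_amp_sd: float = 0.15
    subject_effect_sd: float = 0.15
    trial_effect_sd: float = 0.10
    trial_sway_sd: float = 0.15

    # experimental design
    n_subjects: int = 8
    reps: int = 30
    tasks: tuple[str, ...] = TASKS
    task_pattern: Mapping[str, str] = field(
        default_factory=lambda: {
            "back-and-forth": "TLF",
            "side-to-side": "TR",
            "up-and-down": "SE",
        }
    )

    # companion sEMG
    semg_sample_rate: float = 2000.0
    semg_affected_gain: float = 1.5
    semg_rest_level: float = 0.15

    seed: int = 42

    def validate(self) -> None:
        for name in (
            "mult_noise_sd",
            "add_noise_sd",
            "subject_center_sd",
            "subject_amp_sd",
            "subject_effect_sd",
            "trial_effect_sd",
            "trial_sway_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.reps < 1 or self.n_subjects < 1:
            raise ValueError("need at least 1 subject and 1 repetition")
        if self.duration * self.sample_rate < 2:
            raise ValueError("trial too short for at least 2 frames")
        # generous headroom for shifts: peaks must stay on-grid (tested at
        # twice the mean shift, the envelope peak of m(t))
        margin = 1.0
        max_lat = 2 * max(self.tr_lateral_shift, self.se_ipsilateral_shift) + 3 * self.subject_center_sd + 2
        max_lon = 2 * self.tlf_forward_shift + 3 * self.subject_center_sd + 2
        if self.peak_cols[0] - max_lat < margin or self.peak_cols[1] + max_lat > self.n_cols - margin:
            raise ValueError("lateral shift would push an ischial peak off-grid")
        if self.peak_row - max_lon < margin or self.peak_row > self.n_rows - margin:
            raise ValueError("forward shift would push the pressure peaks off-grid")


@dataclass
class SubjectProfile:
    """Per-subject anatomy and severity drawn once per subject."""

    subject: str
    d_row: float
    d_col: float
    amp_scale: float
    effect_scale: float
    side_sign: int  # +1: affected side is the right, -1: the left


@dataclass
class SimulatedDataset:
    """Labelled synthetic trials plus full provenance."""

    trials: list[PressureSequence]
    params: SimulationParams
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def manifest(self) -> dict:
        p = asdict(self.params)
        p["sway_amp"] = dict(p["sway_amp"])
        p["task_pattern"] = dict(p["task_pattern"])
        return {
            "seed": self.seed,
            "n_trials": len(self.trials),
            "params": p,
            "trials": [t.meta.as_dict() for t in self.trials],
        }


def make_subject_profiles(params: SimulationParams) -> list[SubjectProfile]:
    profiles = []
    for s in range(params.n_subjects):
        rng = np.random.default_rng([params.seed, 1000 + s])
        profiles.append(
            SubjectProfile(
                subject=f"S{s + 1:02d}",
                d_row=rng.normal(0, params.subject_center_sd),
                d_col=rng.normal(0, params.subject_center_sd),
                amp_scale=float(np.exp(rng.normal(0, params.subject_amp_sd))),
                effect_scale=float(np.exp(rng.normal(0, params.subject_effect_sd))),
                side_sign=1 if rng.random() < 0.5 else -1,
            )
        )
    return profiles


def _envelope(T: int) -> np.ndarray:
    if T == 1:
        return np.ones(1)
    t = np.arange(T)
    return np.sin(np.pi * t / (T - 1)) ** 2


def simulate_trial(
    label: str,
    profile: SubjectProfile,
    params: SimulationParams,
    trial_seed: Sequence[int],
    task: str = "up-and-down",
    side: str = "affected",
) -> PressureSequence:
    """Generate one labelled pressure trial.

    ``trial_seed`` is a sequence of integers mixed with the root seed so
    every trial has its own reproducible stream. The stream is consumed
    identically for every label, so labels differ only through the
    deterministic effect terms.
    """
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}")
    params.validate()
    rng = np.random.default_rng([params.seed, *map(int, trial_seed)])
    T = int(round(params.duration * params.sample_rate))
    e = _envelope(T)
    m = e / e.mean()

    # per-trial execution randomness (same draws regardless of label)
    sway_scale = np.exp(rng.normal(0, params.trial_sway_sd, size=2))
    sway_sign = rng.choice([-1.0, 1.0], size=2)
    effect_jitter = float(np.exp(rng.normal(0, params.trial_effect_sd)))

    a_lat, a_lon = params.sway_amp[task]
    dx = sway_sign[0] * a_lat * sway_scale[0] * e
    dy = -sway_sign[1] * a_lon * sway_scale[1] * e  # forward = toward row 1
    amp_l = np.ones(T)
    amp_r = np.ones(T)

    s = profile.effect_scale * effect_jitter
    sign = profile.side_sign  # +1 -> affected right side
    if label == "TLF":
        dy = dy - params.tlf_forward_shift * s * m
    elif label == "TR":
        # rotation swings the trunk toward the contralateral side
        dx = dx - sign * params.tr_lateral_shift * s * m
        amp_l = amp_l * (1 + sign * params.tr_load_asymmetry * s * m / 2)
        amp_r = amp_r * (1 - sign * params.tr_load_asymmetry * s * m / 2)
    elif label == "SE":
        # elevation effort presses down through the ipsilateral ischium:
        # the lateral shift and the load asymmetry reinforce each other
        dx = dx + sign * params.se_ipsilateral_shift * s * m
        amp_l = amp_l * (1 - sign * params.se_amp_asymmetry * s * m / 2)
        amp_r = amp_r * (1 + sign * params.se_amp_asymmetry * s * m / 2)

    rows = np.arange(1, params.n_rows + 1, dtype=float)
    cols = np.arange(1, params.n_cols + 1, dtype=float)
    base_amp = params.peak_amp * profile.amp_scale
    cy = params.peak_row + profile.d_row + dy  # (T,)
    row_gauss = np.exp(-((rows[None, :] - cy[:, None]) ** 2) / (2 * params.peak_sigma**2))
    frames = np.zeros((T, params.n_rows, params.n_cols))
    for cx0, amp_t in (
        (params.peak_cols[0], amp_l),
        (params.peak_cols[1], amp_r),
    ):
        cx = cx0 + profile.d_col + dx
        col_gauss = np.exp(-((cols[None, :] - cx[:, None]) ** 2) / (2 * params.peak_sigma**2))
        frames += (base_amp * amp_t)[:, None, None] * row_gauss[:, :, None] * col_gauss[:, None, :]
    # anterior thigh band
    cy_band = params.thigh_row + profile.d_row + dy
    band_row = np.exp(-((rows[None, :] - cy_band[:, None]) ** 2) / (2 * params.thigh_sigma_row**2))
    cx_band = (params.peak_cols[0] + params.peak_cols[1]) / 2 + profile.d_col + dx
    band_col = np.exp(-((cols[None, :] - cx_band[:, None]) ** 2) / (2 * params.thigh_sigma_col**2))
    frames += (params.thigh_amp * profile.amp_scale) * band_row[:, :, None] * band_col[:, None, :]

    if params.mult_noise_sd > 0:
        frames = frames * (1 + rng.normal(0, params.mult_noise_sd, size=frames.shape))
    if params.add_noise_sd > 0:
        frames = frames + rng.normal(0, params.add_noise_sd, size=frames.shape)
    frames = np.clip(frames, 0.0, None)

    meta = TrialMeta(subject=profile.subject, task=task, side=side, label=label)
    return PressureSequence(frames, sample_rate=params.sample_rate, meta=meta)


def simulate_dataset(params: SimulationParams | None = None) -> SimulatedDataset:
    """Generate the full labelled design.

    ``n_subjects x 2 sides x len(tasks) x reps`` trials; healthy-side
    trials are labelled NC, affected-side trials carry the dominant
    compensation pattern of their task (``task_pattern``).
    """
    params = params or SimulationParams()
    params.validate()
    profiles = make_subject_profiles(params)
    trials: list[PressureSequence] = []
    for si, profile in enumerate(profiles):
        counter = 0
        for side in SIDES:
            for task in params.tasks:
                label_pool = "NC" if side == "healthy" else params.task_pattern[task]
                for rep in range(params.reps):
                    seq = simulate_trial(
                        label_pool,
                        profile,
                        params,
                        trial_seed=(2000 + si, counter),
                        task=task,
                        side=side,
                    )
                    trials.append(seq)
                    counter += 1
    return SimulatedDataset(trials, params, params.seed)


def simulate_semg(
    label: str,
    side: str,
    params: SimulationParams,
    trial_seed: Sequence[int],
    duration: float | None = None,
) -> EMGRecording:
    """Generate one companion 9-channel sEMG trial.

    Channels are 20–200 Hz noise carriers scaled by ``rest + envelope``;
    on the affected side the muscles of the trial's compensation pattern
    get an extra ``semg_affected_gain``.
    """
    rng = np.random.default_rng([params.seed, 7, *map(int, trial_seed)])
    fs = params.semg_sample_rate
    n = int(round((duration or params.duration) * fs))
    e = _envelope(n)
    sos = sps.butter(4, (20.0, 200.0), btype="bandpass", fs=fs, output="sos")
    gains = {ch: 1.0 for ch in MUSCLES}
    if side == "affected" and label in PATTERN_MUSCLES:
        for ch in PATTERN_MUSCLES[label]:
            gains[ch] = params.semg_affected_gain
    data = {}
    for ch in MUSCLES:
        carrier = sps.sosfiltfilt(sos, rng.standard_normal(n))
        data[ch] = gains[ch] * (params.semg_rest_level + e) * carrier
    meta = {"label": label, "side": side, "movement": label if label != "NC" else "NC"}
    return EMGRecording(pd.DataFrame(data), sample_rate=fs, meta=meta)


def write_dataset(ds: SimulatedDataset, outdir: str | Path, decimals: int = 3) -> Path:
    """Write every trial in the plain-text dialect plus a manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = ds.manifest()
    for i, seq in enumerate(ds.trials):
        m = seq.meta
        fname = f"trial_{i:04d}_{m.subject}_{m.task}_{m.side}_{m.label}.txt"
        write_pressure_ascii(seq, outdir / fname, decimals=decimals)
        manifest["trials"][i]["file"] = fname
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir / "manifest.json"
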