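"""Prediction-instance construction from denoised recordings.

Each instance summarises the 70 minutes preceding an emission time t_end by
two overlapping one-hour windows — window A covers [t_end−70, t_end−10) min,
window B covers [t_end−60, t_end) min, sharing 50 min (3000 samples).  From
each window and each of 7 channels (HR, RR, SBP, DBP, MAP, SpO2 and the
derived pulse pressure PP = SBP − DBP) an 11-vector of statistics is
extracted, giving 77 dimensions per window and 2 × 77 = 154 per instance.
Targets
are the {min, max, mean} of future one-hour windows at horizons +1/+2/+3 h
(the +h window is [t_end+(h−1)·60, t_end+h·60)); instances are emitted every
10 minutes.

The 11 features per channel, in fixed order, are {min, max, mean, median,
standard deviation, variance, energy} of the window signal and {min, max,
mean, standard deviation} of its first difference (energy = sum of squared
samples; standard deviations are population, ddof=0).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WINDOW_SAMPLES = 3600           # one hour at 1 Hz
OVERLAP_SAMPLES = 3000          # 50 min shared between the two windows
SPAN_MIN = 70                   # total history per instance, minutes
STEP_MIN = 10                   # emission period, minutes

#: channels featurized, in fixed order (pp derived as sbp − dbp)
FEATURE_CHANNELS = ("hr", "rr", "sbp", "dbp", "map", "spo2", "pp")

#: target vitals and statistics
TARGET_VITALS = ("hr", "sbp", "spo2", "rr", "pp")
TARGET_STATS = ("min", "max", "mean")
DEFAULT_HORIZONS = (1, 2, 3)

FEATURE_NAMES = (
    "min", "max", "mean", "median", "sd", "var", "energy",
    "d_min", "d_max", "d_mean", "d_sd",
)
N_FEATURES_PER_CHANNEL = len(FEATURE_NAMES)                       # 11
N_FEATURES_PER_WINDOW = N_FEATURES_PER_CHANNEL * len(FEATURE_CHANNELS)  # 77
N_FEATURES = 2 * N_FEATURES_PER_WINDOW                            # 154


def extract_channel_features(window) -> np.ndarray:
    """The 11 statistical features of one channel over one 1-h window."""
    x = np.asarray(window, dtype=float)
    if x.shape != (WINDOW_SAMPLES,):
        raise ValueError(
            f"window must have exactly {WINDOW_SAMPLES} samples, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains non-finite values")
    d = np.diff(x)
    sd = float(np.std(x))
    return np.array([
        x.min(), x.max(), x.mean(), float(np.median(x)),
        sd, sd * sd, float(np.dot(x, x)),
        d.min(), d.max(), d.mean(), float(np.std(d)),
    ])


def feature_vector_names() -> list[str]:
    """Names of the entries of x, in order: window A then B, channel-major."""
    return [f"{win}_{ch}_{f}"
            for win in ("A", "B")
            for ch in FEATURE_CHANNELS
            for f in FEATURE_NAMES]


@dataclass
class PredictionInstance:
    """One emission: 154-dim (2 × 77) feature vector plus future targets."""

    patient_id: str
    t_end: int  # minute index at the end of the 70-min feature span
    x: np.ndarray
    targets: dict[tuple[str, str, int], float]  # (vital, stat, horizon) -> value
    quality: bool = True

    def __post_init__(self) -> None:
        if self.x.shape != (N_FEATURES,):
            raise ValueError(f"x must be {N_FEATURES}-dimensional")


def _channel_series(recording) -> dict[str, np.ndarray]:
    series = dict(recording.channels)
    series["pp"] = recording.pulse_pressure()
    return series


def build_instance(recording, t_end: int,
                   horizons=DEFAULT_HORIZONS) -> PredictionInstance:
    """Build the instance emitted at minute ``t_end`` of a denoised recording.

    Targets are included for every requested horizon whose full one-hour
    window lies inside the recording; at least the feature span must fit.
    """
    n_min = int(recording.n_samples // 60)
    if t_end < SPAN_MIN:
        raise ValueError(f"t_end={t_end} min leaves no room for the 70-min span")
    if t_end > n_min:
        raise ValueError(f"t_end={t_end} min beyond recording end ({n_min} min)")
    series = _channel_series(recording)

    def window(lo_min: int, hi_min: int, ch: str) -> np.ndarray:
        return series[ch][lo_min * 60:hi_min * 60]

    blocks = []
    for lo, hi in ((t_end - 70, t_end - 10), (t_end - 60, t_end)):
        for ch in FEATURE_CHANNELS:
            blocks.append(extract_channel_features(window(lo, hi, ch)))
    x = np.concatenate(blocks)

    targets: dict[tuple[str, str, int], float] = {}
    for h in horizons:
        lo, hi = t_end + (h - 1) * 60, t_end + h * 60
        if hi > n_min:
            continue
        for vital in TARGET_VITALS:
            w = window(lo, hi, vital)
            targets[(vital, "min", h)] = float(w.min())
            targets[(vital, "max", h)] = float(w.max())
            targets[(vital, "mean", h)] = float(w.mean())

    span_ok = bool(recording.quality[(t_end - 70) * 60:t_end * 60].all())
    return PredictionInstance(
        patient_id=recording.patient_id, t_end=t_end, x=x,
        targets=targets, quality=span_ok)


def enumerate_instances(recording, step_min: int = STEP_MIN,
                        horizons=DEFAULT_HORIZONS) -> list[PredictionInstance]:
    """All instances of a recording: t_end ∈ {70, 70+step, …} minutes, emitted
    while at least one requested horizon's target window still fits."""
    if step_min < 1:
        raise ValueError("step_min must be >= 1")
    horizons = tuple(sorted(set(horizons)))
    if not horizons:
        raise ValueError("need at least one horizon")
    n_min = int(recording.n_samples // 60)
    h_min = horizons[0]
    last_t_end = n_min - h_min * 60  # nearest horizon must fit
    out = []
    for t_end in range(SPAN_MIN, last_t_end + 1, step_min):
        out.append(build_instance(recording, t_end, horizons=horizons))
    if not out:
        warnings.warn(
            f"recording of {n_min} min too short for span {SPAN_MIN} min + "
            f"horizon {h_min} h; no instances emitted", stacklevel=2)
    return out


def instances_to_frame(instances: list[PredictionInstance]) -> pd.DataFrame:
    """Wide table: id, t_end, x_000…x_153, then one column per target."""
    names = feature_vector_names()
    rows = []
    for inst in instances:
        row = {"patient_id": inst.patient_id, "t_end": inst.t_end,
               "quality": inst.quality}
        for j, v in enumerate(inst.x):
            row[f"x_{j:03d}"] = v
        for (vital, stat, h), v in inst.targets.items():
            row[f"y_{vital}_{stat}_h{h}"] = v
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["feature_names"] = names
    return df


def frame_to_instances(df: pd.DataFrame) -> list[PredictionInstance]:
    xcols = [c for c in df.columns if c.startswith("x_")]
    ycols = [c for c in df.columns if c.startswith("y_")]
    out = []
    for _, row in df.iterrows():
        targets = {}
        for c in ycols:
            if pd.notna(row[c]):
                _, vital, stat, h = c.split("_")
                targets[(vital, stat, int(h[1:]))] = float(row[c])
        out.append(PredictionInstance(
            patient_id=str(row["patient_id"]), t_end=int(row["t_end"]),
            x=row[xcols].to_numpy(float), targets=targets,
            quality=bool(row.get("quality", True))))
    return out
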