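"""Early-warning-score (EWS) component scoring of vital-sign values.

An EWS assigns each vital sign a component score 0–3 against hospital
threshold bands; the bands shipped here follow the Ziekenhuis Oost-Limburg
(ZOL) convention and are hot-swappable — any hospital's table can be loaded
from a yaml file of the same shape.  Rather than scoring instantaneous
samples, the per-minute stream scores the {min, max, mean, median} of each
denoised one-minute segment, giving a high-rate (every minute) EWS component
estimate per vital sign.

Printed bands like "101–110" are closed intervals on the vital's resolution
grid (1 unit for HR/RR/SBP/SpO2, 0.1 °C for temperature); continuous inputs
are rounded to that grid before lookup, which makes the table total over the
reals.  Where a printed boundary belongs to two bands (SBP 180) the
lower-score band is listed first and wins.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .conditioning import SEGMENT_SAMPLES, FilterSpec, denoise_recording

logger = logging.getLogger(__name__)

#: recording channel name → threshold-table vital name
SCOREABLE = {"hr": "HR", "rr": "RR", "sbp": "SBP", "spo2": "SpO2"}

STATISTICS = ("min", "max", "mean", "median")


@dataclass(frozen=True)
class Band:
    lo: float  # -inf for an open lower end
    hi: float  # +inf for an open upper end
    score: int


@dataclass
class VitalBands:
    name: str
    unit: str
    resolution: float
    bands: list[Band]
    unused: bool = False

    def validate(self) -> None:
        if not self.bands:
            raise ValueError(f"{self.name}: empty band list")
        for b in self.bands:
            if not 0 <= b.score <= 3:
                raise ValueError(f"{self.name}: score {b.score} outside 0–3")
        # coverage of the rounded grid: every grid value in a wide range must
        # match at least one band (overlap at a shared printed boundary is ok)
        ordered = sorted(self.bands, key=lambda b: b.lo)
        if not math.isinf(ordered[0].lo) or not math.isinf(ordered[-1].hi):
            raise ValueError(f"{self.name}: bands must cover the whole line")
        for a, b in zip(ordered, ordered[1:]):
            if b.lo > a.hi + self.resolution * 1.0001:
                raise ValueError(
                    f"{self.name}: gap between bands ending {a.hi} and "
                    f"starting {b.lo}")


class EwsTable:
    """Ordered threshold bands mapping each vital to a component score 0–3."""

    def __init__(self, vitals: dict[str, VitalBands]):
        self.vitals = vitals
        for vb in vitals.values():
            vb.validate()

    def __contains__(self, vital: str) -> bool:
        return vital in self.vitals

    def score(self, vital: str, value: float) -> int:
        return score_component(vital, value, self)

    @classmethod
    def from_yaml(cls, path=None) -> "EwsTable":
        """Load a threshold table; default is the packaged ZOL table."""
        if path is None:
            text = (resources.files("vitalcast.data") / "zol_ews.yaml").read_text()
        else:
            with open(path) as fh:
                text = fh.read()
        raw = yaml.safe_load(text)
        vitals = {}
        for name, spec in raw["vitals"].items():
            bands = [
                Band(
                    lo=-math.inf if b["lo"] is None else float(b["lo"]),
                    hi=math.inf if b["hi"] is None else float(b["hi"]),
                    score=int(b["score"]),
                )
                for b in spec["bands"]
            ]
            vitals[name] = VitalBands(
                name=name,
                unit=str(spec.get("unit", "")),
                resolution=float(spec.get("resolution", 1)),
                bands=bands,
                unused=bool(spec.get("unused", False)),
            )
        return cls(vitals)


def load_zol_table() -> EwsTable:
    return EwsTable.from_yaml()


def score_component(vital: str, value: float, table: EwsTable) -> int:
    """Score one vital-sign value: round to the vital's resolution, then match
    the first band containing the rounded value."""
    if vital not in table.vitals:
        raise KeyError(f"vital {vital!r} not in threshold table")
    if not np.isfinite(value):
        raise ValueError(f"non-finite value {value!r} cannot be scored")
    vb = table.vitals[vital]
    res = vb.resolution
    # half-up rounding to the resolution grid (50.5 -> 51, not banker's 50)
    v = round(math.floor(float(value) / res + 0.5) * res, 10)
    for b in vb.bands:
        if b.lo <= v <= b.hi:
            return b.score
    raise AssertionError(
        f"{vital}: rounded value {v} matched no band (table not total)")


def segment_statistics(segment) -> dict[str, float]:
    """Exact {min, max, mean, median} of a (partial) one-minute segment."""
    x = np.asarray(segment, dtype=float)
    if x.size == 0:
        raise ValueError("empty segment")
    if x.size > SEGMENT_SAMPLES:
        raise ValueError(f"segment longer than {SEGMENT_SAMPLES} samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("segment contains non-finite values")
    return {
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
    }


@dataclass
class MinuteScore:
    """Per-minute segment statistics and their EWS component scores."""

    segment_index: int
    stats: dict[str, dict[str, float]]   # channel -> statistic -> value
    scores: dict[str, dict[str, int]]    # channel -> statistic -> score 0–3
    quality: bool


def minute_ews_stream(recording, table: EwsTable | None = None,
                      spec: FilterSpec | None = None,
                      predenoised: bool = False) -> list[MinuteScore]:
    """High-rate EWS stream: denoise per minute, compute segment statistics,
    score each statistic independently for every scoreable channel.

    One :class:`MinuteScore` per complete 60-sample segment; quality is False
    for segments overlapping flagged samples.
    """
    if table is None:
        table = load_zol_table()
    if not np.isclose(recording.rate_hz, 1.0):
        raise ValueError("expected a 1 Hz recording")
    n = recording.n_samples
    if n < SEGMENT_SAMPLES:
        warnings.warn("recording shorter than one minute; no scores emitted",
                      stacklevel=2)
        return []
    rec = recording if predenoised else denoise_recording(recording, spec)
    n_seg = n // SEGMENT_SAMPLES
    out: list[MinuteScore] = []
    for s in range(n_seg):
        lo, hi = s * SEGMENT_SAMPLES, (s + 1) * SEGMENT_SAMPLES
        stats: dict[str, dict[str, float]] = {}
        scores: dict[str, dict[str, int]] = {}
        for ch, vital in SCOREABLE.items():
            st = segment_statistics(rec.channels[ch][lo:hi])
            stats[ch] = st
            scores[ch] = {k: score_component(vital, v, table)
                          for k, v in st.items()}
        out.append(MinuteScore(
            segment_index=s,
            stats=stats,
            scores=scores,
            quality=bool(rec.quality[lo:hi].all()),
        ))
    return out


def minute_scores_to_frame(scores: list[MinuteScore]) -> pd.DataFrame:
    """Long-format table: segment_index, channel, stat, value, score, quality."""
    rows = []
    for ms in scores:
        for ch in ms.stats:
            for stat in STATISTICS:
                rows.append({
                    "segment_index": ms.segment_index,
                    "channel": ch,
                    "stat": stat,
                    "value": ms.stats[ch][stat],
                    "score": ms.scores[ch][stat],
                    "quality": ms.quality,
                })
    return pd.DataFrame(rows)


def moving_median_score(recording, table: EwsTable | None = None,
                        channel: str = "hr", window_s: int = 60,
                        spec: FilterSpec | None = None) -> np.ndarray:
    """Score the median of a one-minute window sliding one sample at a time.

    The denoised channel's rolling median is scored at every window position;
    output length is N − window + 1.  Compared to the per-segment median this
    variant smooths over segment boundaries (and can miss brief score
    excursions — the price of the heavier smoothing).
    """
    if table is None:
        table = load_zol_table()
    if channel not in SCOREABLE:
        raise ValueError(f"channel {channel!r} has no EWS thresholds")
    n = recording.n_samples
    if n < window_s:
        return np.empty(0, dtype=int)
    rec = denoise_recording(recording, spec)
    x = pd.Series(rec.channels[channel])
    med = x.rolling(window_s).median().to_numpy()[window_s - 1:]
    vital = SCOREABLE[channel]
    return np.array([score_component(vital, v, table) for v in med], dtype=int)
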