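"""Synthetic cohorts of continuously monitored vital signs.

Real general-ward recordings of the kind this pipeline analyses (wearable,
1 Hz, multichannel) are not publicly deposited, so every downstream stage is
exercised on seeded synthetic patients instead.  Each channel is driven by a
slow mean-reverting (Ornstein–Uhlenbeck) latent trend, on top of which white
measurement noise and short motion-artefact bursts are added.  Blood-pressure
channels are generated coupled — diastolic plus a strictly positive pulse
pressure — so systolic > diastolic holds at every sample of the clean series
and mean arterial pressure follows the standard MAP = DBP + (SBP − DBP)/3.

Three ward profiles are shipped: ``cardiology`` (long stays, moderate
variability), ``postsurgical`` (similar but a single day), and ``dialysis``
(short ~4 h sessions with a within-session systolic drift emulating the more
dynamic haemodialysis behaviour).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical channel order used throughout the package
CHANNELS = ("hr", "rr", "sbp", "dbp", "map", "spo2")

#: channels that are generated from independent latent processes
#: (sbp and map are derived from dbp + pulse pressure)
_LATENT_CHANNELS = ("hr", "rr", "dbp", "pp", "spo2")

#: physiologic admissibility ranges for profile baselines
_BASELINE_RANGES = {
    "hr": (30.0, 200.0),
    "rr": (4.0, 50.0),
    "sbp": (60.0, 220.0),
    "spo2": (70.0, 100.0),
}

CSV_COLUMNS = (
    "timestamp_s",
    "hr_bpm",
    "rr_bpm",
    "sbp_mmhg",
    "dbp_mmhg",
    "map_mmhg",
    "spo2_pct",
)

_COL_OF_CHANNEL = {
    "hr": "hr_bpm",
    "rr": "rr_bpm",
    "sbp": "sbp_mmhg",
    "dbp": "dbp_mmhg",
    "map": "map_mmhg",
    "spo2": "spo2_pct",
}


@dataclass(frozen=True)
class ProfileSpec:
    """Generative parameters for one synthetic patient recording.

    Per-channel parameters are keyed by ``hr, rr, sbp, dbp, spo2`` for
    baselines and by the latent channels ``hr, rr, dbp, pp, spo2`` for trend
    amplitudes and noise (pulse pressure pp = sbp − dbp is the second
    blood-pressure degree of freedom).
    """

    name: str
    duration_min: int
    baseline: dict[str, float]
    trend_timescale_s: float
    trend_amplitude: dict[str, float]
    noise_sd: dict[str, float]
    artefact_rate_per_hour: float
    artefact_amplitude: dict[str, float]
    seed: int = 0
    sbp_drift_per_session: float = 0.0  # mmHg over the whole recording

    def __post_init__(self) -> None:
        if self.name not in ("cardiology", "postsurgical", "dialysis"):
            raise ValueError(f"unknown profile name {self.name!r}")
        if self.duration_min < 1:
            raise ValueError("duration_min must be at least one minute")
        for d in (self.trend_amplitude, self.noise_sd, self.artefact_amplitude):
            if any(v < 0 for v in d.values()):
                raise ValueError("amplitudes and noise scales must be >= 0")
        if self.artefact_rate_per_hour < 0:
            raise ValueError("artefact_rate_per_hour must be >= 0")
        for ch, (lo, hi) in _BASELINE_RANGES.items():
            v = self.baseline[ch]
            if not lo <= v <= hi:
                raise ValueError(f"baseline {ch}={v} outside physiologic [{lo}, {hi}]")
        if self.baseline["dbp"] >= self.baseline["sbp"]:
            raise ValueError("baseline DBP must be below baseline SBP")


@dataclass
class VitalRecording:
    """One patient's multichannel 1 Hz vital-sign series."""

    patient_id: str
    profile: str
    rate_hz: float
    channels: dict[str, np.ndarray]
    quality: np.ndarray  # per-sample boolean, False where flagged
    start_s: float = 0.0

    @property
    def n_samples(self) -> int:
        return len(self.quality)

    @property
    def duration_min(self) -> float:
        return self.n_samples / self.rate_hz / 60.0

    def pulse_pressure(self) -> np.ndarray:
        return self.channels["sbp"] - self.channels["dbp"]

    def to_frame(self) -> pd.DataFrame:
        t = self.start_s + np.arange(self.n_samples) / self.rate_hz
        data = {"timestamp_s": t}
        for ch in CHANNELS:
            data[_COL_OF_CHANNEL[ch]] = self.channels[ch]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, patient_id: str | None = None,
                 profile: str = "cardiology") -> "VitalRecording":
        df = pd.read_csv(path)
        t = df["timestamp_s"].to_numpy(float)
        rate = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 1.0
        channels = {ch: df[_COL_OF_CHANNEL[ch]].to_numpy(float) for ch in CHANNELS}
        quality = np.isfinite(np.column_stack(list(channels.values()))).all(axis=1)
        return cls(
            patient_id=patient_id or str(path),
            profile=profile,
            rate_hz=float(round(rate, 6)),
            channels=channels,
            quality=quality,
            start_s=float(t[0]) if len(t) else 0.0,
        )


@dataclass
class SyntheticGroundTruth:
    """Noise-free latent truth emitted alongside a synthetic recording."""

    clean: dict[str, np.ndarray]
    artefact_mask: np.ndarray
    latent_state: dict[str, np.ndarray]

    def to_csv(self, path) -> None:
        n = len(self.artefact_mask)
        data = {"timestamp_s": np.arange(n, dtype=float)}
        for ch in CHANNELS:
            data[_COL_OF_CHANNEL[ch] + "_clean"] = self.clean[ch]
        data["artefact"] = self.artefact_mask.astype(int)
        pd.DataFrame(data).to_csv(path, index=False)


def _default_profile_params(name: str) -> dict:
    """Per-ward defaults: baselines near the cohort averages reported for the
    study wards (e.g. SBP ≈ 124 mmHg, RR ≈ 14 BPM), amplitudes spanning the
    adjacent scoring bands so EWS components other than 0 actually occur."""
    base = dict(
        baseline={"hr": 75.0, "rr": 14.0, "sbp": 124.0, "dbp": 72.0, "spo2": 97.0},
        trend_timescale_s=3 * 3600.0,
        trend_amplitude={"hr": 9.0, "rr": 2.5, "dbp": 6.0, "pp": 5.0, "spo2": 1.2},
        noise_sd={"hr": 1.5, "rr": 0.7, "dbp": 1.5, "pp": 1.2, "spo2": 0.4},
        artefact_rate_per_hour=4.0,
        artefact_amplitude={"hr": 25.0, "rr": 8.0, "dbp": 15.0, "pp": 10.0, "spo2": 6.0},
    )
    if name == "cardiology":
        return dict(base, duration_min=23 * 60)
    if name == "postsurgical":
        return dict(base, duration_min=23 * 60)
    if name == "dialysis":
        out = dict(base, duration_min=4 * 60, sbp_drift_per_session=-12.0)
        out["trend_timescale_s"] = 3600.0  # more dynamic within-session behaviour
        return out
    raise ValueError(f"unknown profile name {name!r}")


def make_profile(name: str, duration_min: int | None = None, seed: int = 0,
                 **overrides) -> ProfileSpec:
    """Construct a :class:`ProfileSpec` with the ward's default parameters."""
    params = _default_profile_params(name)
    if duration_min is not None:
        params["duration_min"] = duration_min
    params.update(overrides)
    return ProfileSpec(name=name, seed=seed, **params)


def _ou_path(rng: np.random.Generator, n: int, tau_s: float) -> np.ndarray:
    """Stationary unit-variance Ornstein–Uhlenbeck path sampled at 1 Hz.

    Exact AR(1) discretisation x[i] = ρ·x[i−1] + √(1−ρ²)·ε[i], ρ = e^(−1/τ),
    started from the stationary law; evaluated with an IIR filter so long
    recordings stay cheap.
    """
    from scipy.signal import lfilter

    rho = float(np.exp(-1.0 / tau_s))
    innov_sd = float(np.sqrt(1.0 - rho**2))
    eps = rng.standard_normal(n)
    x0 = eps[0]
    if n == 1:
        return np.array([x0])
    rest, _ = lfilter([innov_sd], [1.0, -rho], eps[1:], zi=[rho * x0])
    return np.concatenate(([x0], rest))


def _artefact_bursts(rng: np.random.Generator, n: int, rate_per_hour: float
                     ) -> tuple[np.ndarray, list[tuple[int, int, float]]]:
    """Poisson-count motion-artefact bursts of 5–30 s, uniform random sign."""
    mask = np.zeros(n, dtype=bool)
    bursts: list[tuple[int, int, float]] = []
    hours = n / 3600.0
    count = rng.poisson(rate_per_hour * hours)
    for _ in range(count):
        start = int(rng.integers(0, n))
        dur = int(rng.integers(5, 31))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        stop = min(start + dur, n)
        mask[start:stop] = True
        bursts.append((start, stop, sign))
    return mask, bursts


def generate_recording(profile: ProfileSpec
                       ) -> tuple[VitalRecording, SyntheticGroundTruth]:
    """Generate one synthetic patient recording with its ground truth.

    The clean series is baseline + trend_amplitude × OU(t) per latent channel;
    SBP = DBP + PP with PP floored at 10 mmHg, MAP = DBP + PP/3, SpO2 capped
    at 100 %.  The emitted series adds white noise and signed artefact bursts
    on the masked samples.  Identical spec (including seed) gives bit-identical
    output.
    """
    n = profile.duration_min * 60
    if n < 60:
        raise ValueError(
            f"duration {profile.duration_min} min too short for one 1-min segment")
    root = np.random.SeedSequence(profile.seed)
    streams = {ch: np.random.default_rng(s)
               for ch, s in zip(_LATENT_CHANNELS, root.spawn(len(_LATENT_CHANNELS)))}
    rng_art = np.random.default_rng(root.spawn(1)[0])

    latent = {ch: _ou_path(streams[ch], n, profile.trend_timescale_s)
              for ch in _LATENT_CHANNELS}

    base, amp = profile.baseline, profile.trend_amplitude
    clean: dict[str, np.ndarray] = {}
    clean["hr"] = base["hr"] + amp["hr"] * latent["hr"]
    clean["rr"] = np.maximum(base["rr"] + amp["rr"] * latent["rr"], 4.0)
    dbp = base["dbp"] + amp["dbp"] * latent["dbp"]
    pp0 = base["sbp"] - base["dbp"]
    pp = np.maximum(pp0 + amp["pp"] * latent["pp"], 10.0)
    if profile.sbp_drift_per_session:
        pp = np.maximum(
            pp + profile.sbp_drift_per_session * np.arange(n) / max(n - 1, 1), 10.0)
    clean["dbp"] = dbp
    clean["sbp"] = dbp + pp
    clean["map"] = dbp + pp / 3.0
    clean["spo2"] = np.minimum(base["spo2"] + amp["spo2"] * latent["spo2"], 100.0)

    mask, bursts = _artefact_bursts(rng_art, n, profile.artefact_rate_per_hour)
    noisy: dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        latent_ch = {"sbp": "pp", "map": "pp"}.get(ch, ch)
        sd = profile.noise_sd[latent_ch]
        noise = sd * streams[latent_ch].standard_normal(n) if sd > 0 else 0.0
        x = clean[ch] + noise
        a = profile.artefact_amplitude[latent_ch]
        for start, stop, sign in bursts:
            x[start:stop] = x[start:stop] + sign * a
        noisy[ch] = x

    rec = VitalRecording(
        patient_id=f"{profile.name}-{profile.seed:06d}",
        profile=profile.name,
        rate_hz=1.0,
        channels=noisy,
        quality=np.ones(n, dtype=bool),
    )
    truth = SyntheticGroundTruth(clean=clean, artefact_mask=mask, latent_state=latent)
    return rec, truth


def generate_cohort(profiles: list[ProfileSpec]) -> list[VitalRecording]:
    """Generate one recording per spec; warns on duplicate seeds."""
    if not profiles:
        raise ValueError("profiles list must be nonempty")
    seeds = [p.seed for p in profiles]
    if len(set(seeds)) != len(seeds):
        warnings.warn("duplicate seeds across patients; recordings will repeat",
                      stacklevel=2)
    recs = []
    for i, p in enumerate(profiles):
        rec, _ = generate_recording(p)
        rec.patient_id = f"{p.name}-{i:03d}-s{p.seed}"
        recs.append(rec)
    return recs


def generate_learnable_cohort(
    n_patients: int = 10,
    snr: float = 5.0,
    seed: int = 0,
    duration_min: int = 360,
    trend_timescale_s: float = 3 * 3600.0,
) -> list[tuple[VitalRecording, SyntheticGroundTruth]]:
    """Cohort with forecastable structure for exercising the predictor.

    Each channel follows a slow OU trend with correlation time ≥ 2 h (default
    3 h), so the next hour's window statistics are smooth deterministic
    functions of the preceding 70 min plus observation noise of standard
    deviation trend_amplitude / snr.  No artefact bursts are injected: the
    skill comparison against the persistence baseline is then a property of
    the dynamics, not of artefact handling.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    if snr <= 0:
        raise ValueError("snr must be > 0")
    if trend_timescale_s < 2 * 3600.0:
        raise ValueError("trend correlation time must be >= 2 h for learnability")
    params = _default_profile_params("cardiology")
    out = []
    root = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_patients)]
    for i, s in enumerate(child_seeds):
        spec = ProfileSpec(
            name="cardiology",
            duration_min=duration_min,
            baseline=params["baseline"],
            trend_timescale_s=trend_timescale_s,
            trend_amplitude=params["trend_amplitude"],
            noise_sd={ch: params["trend_amplitude"][ch] / snr
                      for ch in _LATENT_CHANNELS},
            artefact_rate_per_hour=0.0,
            artefact_amplitude={ch: 0.0 for ch in _LATENT_CHANNELS},
            seed=s,
        )
        rec, truth = generate_recording(spec)
        rec.patient_id = f"learnable-{i:03d}"
        out.append((rec, truth))
    return out
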