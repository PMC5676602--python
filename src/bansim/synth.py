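"""Synthetic multi-athlete session generator with ground-truth labels.

Everything the framework consumes is generated here so the whole test
suite runs offline: per-athlete ECG traces with exactly known R-peak
times, 1 Hz telemetry packets (heart rate, GPS position on the pitch,
covered distance, minutes played) and 1/min ambient readings.

ECG synthesis uses a fixed sum-of-Gaussians beat template (P, Q, R, S, T
bumps) placed at beat times integrated from a piecewise-constant heart-rate
profile — the R times are therefore known analytically, which is the whole
point: detection quality can be scored against exact ground truth.  A
dynamical-system morphology model is deliberately out of scope.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .ecg import ECGSignal, write_ecg_csv

__all__ = [
    "HRSegment",
    "AnomalyInjection",
    "SessionSpec",
    "TelemetryPacket",
    "AmbientReading",
    "GeneratorError",
    "generate_ecg",
    "inject_anomaly",
    "generate_session",
    "write_session",
]

DEFAULT_SAMPLING_RATE = 250.0  # Hz — desk-scale, comfortably above the 0.5–40 Hz band

#: (amplitude mV, offset s relative to R, width s) of the template bumps
_BEAT_TEMPLATE = (
    ("P", 0.15, -0.20, 0.040),
    ("Q", -0.20, -0.040, 0.015),
    ("R", 1.20, 0.0, 0.020),
    ("S", -0.25, 0.040, 0.015),
    ("T", 0.35, 0.25, 0.070),
)

AnomalyType = Literal["tachycardia", "bradycardia", "flatline"]

#: default override heart rates for injected episodes, beats/min
ANOMALY_HR = {"tachycardia": 230.0, "bradycardia": 35.0}


class GeneratorError(ValueError):
    """Invalid generator specification."""


@dataclass(frozen=True)
class HRSegment:
    """One piece of a piecewise-constant heart-rate profile."""

    start: float  # seconds
    hr: float     # beats/min

    def __post_init__(self) -> None:
        if self.hr <= 0:
            raise GeneratorError(f"non-positive heart rate {self.hr}")


@dataclass(frozen=True)
class AnomalyInjection:
    """An episode overriding the HR profile of one athlete."""

    athlete: int
    start: float
    duration: float
    kind: AnomalyType
    hr: float | None = None  # override rate; defaults per kind

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise GeneratorError("injection duration must be positive")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class NoiseSpec:
    baseline_amp: float = 0.05   # mV, sinusoidal wander
    baseline_freq: float = 0.3   # Hz
    powerline_amp: float = 0.02  # mV at 50 Hz
    powerline_freq: float = 50.0
    white_sd: float = 0.01       # mV

    @classmethod
    def zero(cls) -> "NoiseSpec":
        return cls(baseline_amp=0.0, powerline_amp=0.0, white_sd=0.0)


@dataclass
class SessionSpec:
    """A full synthetic monitoring session."""

    n_athletes: int = 11
    duration: float = 60.0
    hr_profile: tuple[HRSegment, ...] = (HRSegment(0.0, 75.0),)
    injections: tuple[AnomalyInjection, ...] = ()
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_athletes < 1:
            raise GeneratorError("n_athletes must be >= 1")
        if self.duration <= 0:
            raise GeneratorError("duration must be positive")
        for inj in self.injections:
            if inj.start < 0 or inj.end > self.duration:
                raise GeneratorError(f"injection outside session: {inj}")
            if not 0 <= inj.athlete < self.n_athletes:
                raise GeneratorError(f"injection names unknown athlete {inj.athlete}")


def _profile_hr(profile: Sequence[HRSegment], t: float) -> float:
    hr = profile[0].hr
    for seg in profile:
        if t >= seg.start:
            hr = seg.hr
        else:
            break
    return hr


#: lead-in before the first R peak so the full P-QRS-T template fits the record
BEAT_START_OFFSET_S = 0.3


def _beat_times(
    profile: Sequence[HRSegment],
    duration: float,
    flatline: Sequence[tuple[float, float]] = (),
) -> np.ndarray:
    """Integrate the piecewise-constant HR profile into beat times."""
    times = []
    t = BEAT_START_OFFSET_S
    while t < duration:
        if not any(lo <= t < hi for lo, hi in flatline):
            times.append(t)
        t += 60.0 / _profile_hr(profile, t)
    return np.array(times)


def generate_ecg(
    hr_profile: Sequence[HRSegment] | float,
    duration: float,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    amplitude_scale: float = 1.0,
    flatline_windows: Sequence[tuple[float, float]] = (),
) -> tuple[ECGSignal, np.ndarray]:
    """Synthesize one ECG trace; returns (signal, ground-truth R times).

    Beats are placed by integrating the heart-rate profile; each beat adds
    the five-bump Gaussian template, with the non-R bump offsets/widths
    compressed when the local RR interval is short so fast rhythms stay
    morphologically plausible.  Noise is an additive sinusoidal baseline
    wander, a powerline tone and white Gaussian noise; ``seed`` fixes the
    white-noise realization exactly.
    """
    if duration <= 0:
        raise GeneratorError("duration must be positive")
    if isinstance(hr_profile, (int, float)):
        hr_profile = (HRSegment(0.0, float(hr_profile)),)
    if not hr_profile:
        raise GeneratorError("empty HR profile")
    noise = noise if noise is not None else NoiseSpec.zero()

    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    x = np.zeros(n)
    r_times = _beat_times(hr_profile, duration, flatline_windows)

    for i, rt in enumerate(r_times):
        rr = r_times[i + 1] - rt if i + 1 < len(r_times) else 60.0 / _profile_hr(hr_profile, rt)
        squeeze = float(np.clip(rr / 0.8, 0.3, 1.0))
        for _, amp, offset, width in _BEAT_TEMPLATE:
            off = offset * squeeze if offset != 0.0 else 0.0
            w = width * squeeze if offset != 0.0 else width
            center = rt + off
            lo = max(0, int((center - 5 * w) * sampling_rate))
            hi = min(n, int((center + 5 * w) * sampling_rate) + 1)
            if hi > lo:
                x[lo:hi] += amplitude_scale * amp * np.exp(
                    -((t[lo:hi] - center) ** 2) / (2 * w * w)
                )

    rng = np.random.default_rng(seed)
    if noise.baseline_amp:
        x += noise.baseline_amp * np.sin(2 * np.pi * noise.baseline_freq * t)
    if noise.powerline_amp:
        x += noise.powerline_amp * np.sin(2 * np.pi * noise.powerline_freq * t)
    if noise.white_sd:
        x += rng.normal(0.0, noise.white_sd, size=n)

    signal = ECGSignal(samples=x[:, None], sampling_rate=sampling_rate)
    return signal, r_times


def inject_anomaly(
    spec_injections: Sequence[AnomalyInjection],
    hr_profile: Sequence[HRSegment],
    duration: float,
) -> tuple[tuple[HRSegment, ...], list[tuple[float, float]], np.ndarray]:
    """Fold injections into an HR profile and build the per-second labels.

    Returns (modified profile, flatline windows, label track) where the
    label track holds one string per whole second ("normal" or the anomaly
    kind).  Overlapping injections are rejected.
    """
    injections = sorted(spec_injections, key=lambda i: i.start)
    for a, b in zip(injections, injections[1:]):
        if b.start < a.end:
            raise GeneratorError(f"overlapping injections at {b.start}")
    labels = np.array(["normal"] * int(math.ceil(duration)), dtype=object)
    segments = list(hr_profile)
    flatline: list[tuple[float, float]] = []
    for inj in injections:
        if inj.kind == "flatline":
            flatline.append((inj.start, inj.end))
        else:
            hr = inj.hr if inj.hr is not None else ANOMALY_HR[inj.kind]
            resume = _profile_hr(hr_profile, inj.end)
            # base segments starting inside the episode are overridden by it
            segments = [s for s in segments if not (inj.start <= s.start < inj.end)]
            segments.append(HRSegment(inj.start, hr))
            segments.append(HRSegment(inj.end, resume))
        lo, hi = int(inj.start), int(math.ceil(inj.end))
        labels[lo:min(hi, labels.size)] = inj.kind
    segments.sort(key=lambda s: s.start)
    return tuple(segments), flatline, labels


@dataclass(frozen=True)
class TelemetryPacket:
    """The 1 Hz data package each athlete's wearable sends to the staff."""

    athlete_id: str
    timestamp: int       # seconds since session start
    heart_rate: int      # beats/min
    lat: float
    lon: float
    distance_m: float    # cumulative, non-decreasing
    minutes_played: int

    def to_json(self) -> str:
        return json.dumps({
            "athlete_id": self.athlete_id, "timestamp": self.timestamp,
            "heart_rate": self.heart_rate, "lat": round(self.lat, 7),
            "lon": round(self.lon, 7), "distance_m": round(self.distance_m, 2),
            "minutes_played": self.minutes_played,
        }, sort_keys=True)


@dataclass(frozen=True)
class AmbientReading:
    """Per-minute environmental sensor reading."""

    timestamp: int
    ground_temp_c: float
    wind_speed_ms: float
    wind_temp_c: float
    humidity_pct: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.humidity_pct <= 100.0:
            raise GeneratorError("humidity must be within [0, 100]%")


@dataclass
class Session:
    """All generated streams of one synthetic session."""

    spec: SessionSpec
    ecg: list[ECGSignal]
    r_times: list[np.ndarray]
    labels: list[np.ndarray]
    packets: list[TelemetryPacket]
    ambient: list[AmbientReading]


# football pitch dimensions, meters
_PITCH_X, _PITCH_Y = 105.0, 68.0
# reference corner of the pitch (lat/lon); 1 deg lat ~ 111320 m
_LAT0, _LON0 = 38.385, -0.513


def _gps_walk(rng: np.random.Generator, n_seconds: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smooth random walk confined to the pitch; returns (lat, lon, distance)."""
    pos = np.array([_PITCH_X / 2, _PITCH_Y / 2])
    vel = np.zeros(2)
    xs = np.empty((n_seconds, 2))
    dist = np.empty(n_seconds)
    total = 0.0
    for s in range(n_seconds):
        vel = 0.8 * vel + rng.normal(0.0, 1.2, size=2)
        speed = float(np.hypot(*vel))
        if speed > 8.0:  # cap at a sprint
            vel *= 8.0 / speed
        new = np.clip(pos + vel, [0.0, 0.0], [_PITCH_X, _PITCH_Y])
        total += float(np.hypot(*(new - pos)))
        pos = new
        xs[s] = pos
        dist[s] = total
    lat = _LAT0 + xs[:, 1] / 111320.0
    lon = _LON0 + xs[:, 0] / (111320.0 * math.cos(math.radians(_LAT0)))
    return lat, lon, dist


def generate_session(spec: SessionSpec) -> Session:
    """Generate all per-athlete and ambient streams of a session.

    Exactly one packet per athlete per second (timestamps 0..duration-1)
    and one ambient reading per started minute; fully reproducible under
    ``spec.seed``.
    """
    n_seconds = int(spec.duration)
    ecg: list[ECGSignal] = []
    r_times: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    packets: list[TelemetryPacket] = []

    for a in range(spec.n_athletes):
        own = tuple(i for i in spec.injections if i.athlete == a)
        profile, flatline, lab = inject_anomaly(own, spec.hr_profile, spec.duration)
        sig, rt = generate_ecg(
            profile, spec.duration, spec.sampling_rate, spec.noise,
            seed=spec.seed * 10007 + a, flatline_windows=flatline,
        )
        ecg.append(sig)
        r_times.append(rt)
        labels.append(lab)

        rng = np.random.default_rng(spec.seed * 20011 + a)
        lat, lon, dist = _gps_walk(rng, n_seconds)
        for s in range(n_seconds):
            flat = any(lo <= s < hi for lo, hi in flatline)
            hr = 0 if flat else int(round(_profile_hr(profile, float(s))))
            packets.append(TelemetryPacket(
                athlete_id=f"a{a + 1}", timestamp=s, heart_rate=hr,
                lat=float(lat[s]), lon=float(lon[s]), distance_m=float(dist[s]),
                minutes_played=s // 60,
            ))

    rng = np.random.default_rng(spec.seed * 30013 + 1)
    ambient = [
        AmbientReading(
            timestamp=60 * m,
            ground_temp_c=round(24.0 + float(rng.normal(0, 1.5)), 2),
            wind_speed_ms=round(abs(float(rng.normal(2.0, 1.0))), 2),
            wind_temp_c=round(21.0 + float(rng.normal(0, 1.5)), 2),
            humidity_pct=round(float(np.clip(rng.normal(55.0, 8.0), 0.0, 100.0)), 2),
        )
        for m in range(math.ceil(spec.duration / 60.0))
    ]
    return Session(spec=spec, ecg=ecg, r_times=r_times, labels=labels,
                   packets=packets, ambient=ambient)


def write_session(session: Session, out_dir: str | Path) -> Path:
    """Write a session to disk: ECG CSVs, packets as JSON-lines, ambient as
    CSV, and ground-truth labels as JSON."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for a, (sig, rt, lab) in enumerate(zip(session.ecg, session.r_times, session.labels)):
        write_ecg_csv(sig, out / f"ecg_a{a + 1}.csv")
        (out / f"labels_a{a + 1}.json").write_text(json.dumps({
            "r_times": [round(float(x), 6) for x in rt],
            "per_second": list(lab),
        }, sort_keys=True))
    with (out / "packets.jsonl").open("w") as fh:
        for p in session.packets:
            fh.write(p.to_json() + "\n")
    pd.DataFrame([vars(r) for r in session.ambient]).to_csv(
        out / "ambient.csv", index=False
    )
    return out
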