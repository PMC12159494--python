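"""Ground-truthed synthetic CBV movie generator.

Emulates resting-state Power Doppler acquisitions at the statistical
level the analysis assumes: per-region baseline intensities, white +
1/f temporal noise per pixel, quasi-sinusoidal travelling waves in the
vasomotion band (0.08–0.15 Hz, 0.1–0.8 mm/s), static localised CBV
events, sustained oscillation trains, and stimulation-evoked plateau
responses.  Every injected event is registered in a
:class:`GroundTruthLog` so downstream stages can be scored against the
truth.

Composition model: events modulate the baseline multiplicatively
(``movie *= 1 + m``) because Power Doppler intensity is proportional to
CBV and relative change is the analysed quantity.  The wave carrier is
a raised cosine, i.e. a nonnegative modulation, so injected events are
CBV *increases*, matching the positive-peak detector.  Spatial
footprints are Gaussian bumps hard-truncated at 3σ, so outside the 3σ
union of footprints the movie equals the baseline exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .core import AcquisitionSpec, BandSpec, Movie, WAVE_BAND
from .atlas import RoiAtlas, build_atlas, CORTEX_NAMES
from .patterns import PatternLabel

__all__ = [
    "WaveSpec",
    "StimulusProtocol",
    "GroundTruthEvent",
    "GroundTruthLog",
    "NoiseSpec",
    "simulate_baseline",
    "inject_travelling_wave",
    "inject_static_event",
    "inject_oscillation_train",
    "simulate_cohort",
    "simulate_event_scan",
    "simulate_pattern_scan",
    "simulate_stim_session",
    "fitted_wave",
    "pattern_path",
    "carrier_band_gain",
    "predicted_noise_sd",
]

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WaveSpec:
    """One travelling-wave injection.

    The Gaussian bump centre advances along ``path`` (a polyline of
    ``(row, col)`` waypoints) at ``speed`` mm/s while carrying a raised
    cosine at ``freq`` Hz with peak relative amplitude
    ``amplitude_pct`` % of baseline.
    """

    path: tuple[tuple[float, float], ...]
    speed: float  # mm/s
    freq: float  # Hz
    amplitude_pct: float
    width_mm: float = 0.6  # Gaussian footprint sigma
    t_onset: int = 0  # frame index
    n_cycles: float = 1.0
    pattern: PatternLabel | None = None
    #: fraction of the active window during which the centre moves
    #: (clamped at the path ends outside it); (0, 1) = always moving
    motion_window: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.speed <= 0 or self.freq <= 0 or self.amplitude_pct <= 0:
            raise ValueError("speed, freq and amplitude_pct must be positive")
        if self.width_mm <= 0 or self.n_cycles <= 0:
            raise ValueError("width_mm and n_cycles must be positive")
        if len(self.path) < 1:
            raise ValueError("path needs at least one waypoint")
        m0, m1 = self.motion_window
        if not (0.0 <= m0 < m1 <= 1.0):
            raise ValueError("motion_window must satisfy 0 <= start < end <= 1")

    def duration_s(self) -> float:
        return self.n_cycles / self.freq

    def duration_frames(self, dt: float) -> int:
        return max(2, int(round(self.duration_s() / dt)))


@dataclass(frozen=True)
class StimulusProtocol:
    """Block-design visual stimulation protocol.

    Defaults: a 30-s initial rest in the dark, then 4 blocks of 30 s of
    3 Hz black/white flicker, separated by 45-s rest periods.
    """

    initial_rest: float = 30.0
    n_blocks: int = 4
    stim_dur: float = 30.0
    rest_between: float = 45.0
    flicker_hz: float = 3.0

    def __post_init__(self) -> None:
        if min(self.initial_rest, self.stim_dur, self.rest_between) <= 0:
            raise ValueError("all protocol durations must be positive")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")

    @property
    def total_duration_s(self) -> float:
        return (
            self.initial_rest
            + self.n_blocks * self.stim_dur
            + (self.n_blocks - 1) * self.rest_between
        )

    def stim_epochs(self, dt: float) -> list[tuple[int, int]]:
        """Frame ranges ``[start, end)`` of each stimulation block."""
        epochs = []
        t = self.initial_rest
        for _ in range(self.n_blocks):
            epochs.append((int(round(t / dt)), int(round((t + self.stim_dur) / dt))))
            t += self.stim_dur + self.rest_between
        return epochs

    def baseline_frames(self, dt: float) -> tuple[int, int]:
        """Frame range of the initial pre-stimulus rest period."""
        return (0, int(round(self.initial_rest / dt)))


@dataclass
class GroundTruthEvent:
    """Registry entry for one injected event."""

    event_id: int
    kind: str  # "wave" | "static" | "train" | "stim"
    pattern: str | None
    t_onset: int
    t_end: int  # inclusive last active frame
    amplitude_pct: float
    freq: float | None
    speed_mm_s: float | None
    width_mm: float
    centroid_track: list[tuple[int, float, float]]  # (frame, row, col)
    path_length_px: float
    dynamic: bool
    peak_z: float | None = None  # predicted detector z at the event peak

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruthLog:
    """Simulator-side registry of all injected events in one movie."""

    events: list[GroundTruthEvent] = field(default_factory=list)
    seed: int | None = None

    def append(self, event: GroundTruthEvent) -> None:
        self.events.append(event)

    def next_id(self) -> int:
        return len(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def of_kind(self, *kinds: str) -> list[GroundTruthEvent]:
        return [e for e in self.events if e.kind in kinds]

    def to_json(self, path) -> None:
        payload = {"seed": self.seed, "events": [e.to_dict() for e in self.events]}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruthLog":
        with open(path) as fh:
            payload = json.load(fh)
        log = cls(seed=payload.get("seed"))
        for d in payload["events"]:
            d["centroid_track"] = [tuple(c) for c in d["centroid_track"]]
            log.append(GroundTruthEvent(**d))
        return log


@dataclass(frozen=True)
class NoiseSpec:
    """Temporal noise model: white + spectrally shaped 1/f^exponent."""

    white_sd: float = 1.0
    pink_sd: float = 0.8
    pink_exponent: float = 1.0

    def __post_init__(self) -> None:
        for v in (self.white_sd, self.pink_sd, self.pink_exponent):
            if not np.isfinite(v):
                raise ValueError("noise parameters must be finite")
        if self.white_sd < 0 or self.pink_sd < 0:
            raise ValueError("noise sds must be >= 0")


#: Default per-region baseline Power Doppler intensity (arbitrary units).
DEFAULT_BASELINES = {
    "background": 40.0,
    "RetroGrCtx_B": 100.0,
    "RetroGrCtx_A": 100.0,
    "RetroDysCtx": 100.0,
    "SecVisCtx": 100.0,
    "PrimVisCtx": 100.0,
    "SuperiorColl": 90.0,
    "Hippocampus": 90.0,
    "DorsalMidbrain": 80.0,
    "VentralMidbrain": 70.0,
}


# ---------------------------------------------------------------------------
# baseline + noise
# ---------------------------------------------------------------------------


def baseline_map(atlas: RoiAtlas, baselines: dict[str, float] | None = None) -> np.ndarray:
    """Per-pixel baseline intensity from the per-region table."""
    table = dict(DEFAULT_BASELINES)
    if baselines:
        table.update(baselines)
    out = np.full(atlas.shape, table["background"], dtype=np.float32)
    for rid in atlas.all_ids():
        out[atlas.labels == rid] = table[atlas.names[rid]]
    return out


def _pink_shaping(n_frames: int, dt: float, exponent: float) -> np.ndarray:
    """rfft-domain amplitude shaping for unit-variance 1/f^exponent noise."""
    freqs = np.fft.rfftfreq(n_frames, d=dt)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    # normalise so the time-domain variance of shaped white noise is 1
    # var = (sum over one-sided bins with multiplicity) * sigma_in^2 / n
    mult = np.full_like(shape, 2.0)
    mult[0] = 1.0
    if n_frames % 2 == 0:
        mult[-1] = 1.0
    var = float(np.sum(mult * shape**2)) / n_frames
    return (shape / math.sqrt(var)).astype(np.float32)


def predicted_noise_sd(noise: NoiseSpec, n_frames: int, dt: float) -> float:
    """Noise sd as the first-difference MAD estimator will see it.

    The detector estimates the noise sd from temporal first differences,
    which fully captures white noise but discounts the temporally
    correlated 1/f component.  This returns the expected estimate,
    sqrt(white² + pink² · r) with r = var(diff(pink))/2 from the shaped
    spectrum, and is used to predict per-event detector z-scores.
    """
    if noise.pink_sd == 0:
        return noise.white_sd
    shape = _pink_shaping(n_frames, dt, noise.pink_exponent).astype(np.float64)
    freqs = np.fft.rfftfreq(n_frames, d=dt)
    mult = np.full_like(shape, 2.0)
    mult[0] = 1.0
    if n_frames % 2 == 0:
        mult[-1] = 1.0
    # var of first differences of a process with one-sided spectrum S:
    # sum S(f) * 2(1 - cos(2 pi f dt))
    diff_var = float(
        np.sum(mult * shape**2 * 2.0 * (1.0 - np.cos(2 * np.pi * freqs * dt)))
        / n_frames
    )
    r = diff_var / 2.0
    return math.sqrt(noise.white_sd**2 + noise.pink_sd**2 * r)


def simulate_baseline(
    atlas: RoiAtlas,
    spec: AcquisitionSpec,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    baselines: dict[str, float] | None = None,
) -> Movie:
    """Per-region constant baseline plus per-pixel white + 1/f noise.

    Identical ``seed`` and configuration give a bit-identical movie.
    """
    if atlas.shape != (spec.height, spec.width):
        raise ValueError("atlas grid does not match acquisition spec")
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    base = baseline_map(atlas, baselines)
    data = np.repeat(base[:, :, None], spec.n_frames, axis=2)
    if noise.white_sd > 0:
        data += rng.standard_normal(spec.shape, dtype=np.float32) * np.float32(
            noise.white_sd
        )
    if noise.pink_sd > 0:
        shape = _pink_shaping(spec.n_frames, spec.dt, noise.pink_exponent)
        white = rng.standard_normal(spec.shape, dtype=np.float32)
        spec_f = np.fft.rfft(white, axis=2)
        spec_f *= shape[None, None, :]
        pink = np.fft.irfft(spec_f, n=spec.n_frames, axis=2).astype(np.float32)
        data += pink * np.float32(noise.pink_sd)
        del white, spec_f, pink
    np.maximum(data, np.float32(1e-6), out=data)
    return Movie(data, spec)


# ---------------------------------------------------------------------------
# event injection
# ---------------------------------------------------------------------------


def _polyline_arclength(path: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _point_at(path: np.ndarray, cum: np.ndarray, s: float) -> np.ndarray:
    """Point at arclength ``s`` along the polyline (clamped at the ends)."""
    if s <= 0 or len(path) == 1:
        return path[0]
    if s >= cum[-1]:
        return path[-1]
    i = int(np.searchsorted(cum, s, side="right")) - 1
    seg_len = cum[i + 1] - cum[i]
    f = (s - cum[i]) / seg_len
    return path[i] + f * (path[i + 1] - path[i])


def _raised_cosine(frames: np.ndarray, t_onset: int, freq: float, dt: float) -> np.ndarray:
    """Nonnegative carrier: 0.5 (1 - cos(2 pi f t)) within the active window."""
    t = (frames - t_onset) * dt
    return 0.5 * (1.0 - np.cos(2 * np.pi * freq * t))


def _apply_bump(
    data: np.ndarray,
    centre: np.ndarray,
    sigma_px: float,
    peak_rel: float,
    frame: int,
) -> None:
    """Multiply one frame by ``1 + peak_rel * G`` (G truncated at 3 sigma)."""
    h, w = data.shape[:2]
    r3 = 3.0 * sigma_px
    r0 = max(0, int(math.floor(centre[0] - r3)))
    r1 = min(h, int(math.ceil(centre[0] + r3)) + 1)
    c0 = max(0, int(math.floor(centre[1] - r3)))
    c1 = min(w, int(math.ceil(centre[1] + r3)) + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1, dtype=np.float32)[:, None] - np.float32(centre[0])
    cc = np.arange(c0, c1, dtype=np.float32)[None, :] - np.float32(centre[1])
    d2 = rr**2 + cc**2
    g = np.exp(-d2 / np.float32(2.0 * sigma_px**2))
    g[d2 > r3**2] = 0.0
    data[r0:r1, c0:c1, frame] *= 1.0 + np.float32(peak_rel) * g


def carrier_band_gain(
    wave: WaveSpec, dt: float, band: BandSpec = WAVE_BAND
) -> float:
    """Peak gain of the wave carrier through the detector's band filter.

    A short raised-cosine train is broadband, so its band-filtered peak
    is well below the injected amplitude; this measures the actual
    attenuation by filtering the carrier waveform itself.
    """
    from .preproc import _bandpass_series  # local import to avoid cycle

    dur = wave.duration_frames(dt)
    pad = max(64, 4 * dur)
    series = np.zeros(dur + 2 * pad)
    frames = np.arange(pad, pad + dur)
    series[pad : pad + dur] = _raised_cosine(frames, pad, wave.freq, dt)
    filt = _bandpass_series(series, dt, band)
    return float(np.max(np.abs(filt)))


def inject_travelling_wave(
    movie: Movie,
    atlas: RoiAtlas,
    wave: WaveSpec,
    ground_truth: GroundTruthLog,
    noise: NoiseSpec | None = None,
    baselines: dict[str, float] | None = None,
    band: BandSpec = WAVE_BAND,
) -> Movie:
    """Inject one travelling wave in place and register its ground truth.

    The predicted detector z of the event (``peak_z``) combines the
    injected relative amplitude, the local baseline, the band-filter
    gain of the carrier, and the first-difference noise-sd estimate.
    """
    spec = movie.spec
    path = np.asarray(wave.path, dtype=float)
    if np.any(path[:, 0] < 0) or np.any(path[:, 0] >= spec.height) or np.any(
        path[:, 1] < 0
    ) or np.any(path[:, 1] >= spec.width):
        raise ValueError("path waypoints must lie inside the image")
    dur = wave.duration_frames(spec.dt)
    if wave.t_onset < 0 or wave.t_onset + dur > spec.n_frames:
        raise ValueError("wave active window does not fit in the movie")

    cum = _polyline_arclength(path)
    v_px = wave.speed * spec.dt / spec.pixel_mm  # px per frame
    sigma_px = wave.width_mm / spec.pixel_mm
    frames = np.arange(wave.t_onset, wave.t_onset + dur)
    w = _raised_cosine(frames, wave.t_onset, wave.freq, spec.dt)

    m0, m1 = wave.motion_window
    k0 = m0 * dur
    track: list[tuple[int, float, float]] = []
    centres = np.empty((dur, 2))
    for k, t in enumerate(frames):
        k_move = min(max(k - k0, 0.0), (m1 - m0) * dur)
        c = _point_at(path, cum, v_px * k_move)
        centres[k] = c
        track.append((int(t), float(c[0]), float(c[1])))
        if w[k] > 0:
            _apply_bump(movie.data, c, sigma_px, wave.amplitude_pct / 100.0 * w[k], t)

    path_len = float(np.sum(np.linalg.norm(np.diff(centres, axis=0), axis=1)))
    peak_z = None
    if noise is not None:
        base = baseline_map(atlas, baselines)
        mid = centres[dur // 2]
        b_local = float(base[int(round(mid[0])), int(round(mid[1]))])
        sd = predicted_noise_sd(noise, spec.n_frames, spec.dt)
        if sd > 0:
            gain = carrier_band_gain(wave, spec.dt, band)
            peak_z = wave.amplitude_pct / 100.0 * b_local * gain / sd
    ground_truth.append(
        GroundTruthEvent(
            event_id=ground_truth.next_id(),
            kind="wave",
            pattern=wave.pattern.name if wave.pattern else None,
            t_onset=int(wave.t_onset),
            t_end=int(frames[-1]),
            amplitude_pct=wave.amplitude_pct,
            freq=wave.freq,
            speed_mm_s=wave.speed,
            width_mm=wave.width_mm,
            centroid_track=track,
            path_length_px=path_len,
            dynamic=True,
            peak_z=peak_z,
        )
    )
    return movie


def inject_static_event(
    movie: Movie,
    atlas: RoiAtlas,
    centre: tuple[float, float],
    amplitude_pct: float,
    duration_frames: int,
    width_mm: float,
    t_onset: int,
    ground_truth: GroundTruthLog,
    noise: NoiseSpec | None = None,
    baselines: dict[str, float] | None = None,
    band: BandSpec = WAVE_BAND,
) -> Movie:
    """Inject a non-travelling CBV increase: same bump, zero displacement."""
    spec = movie.spec
    if amplitude_pct <= 0 or width_mm <= 0:
        raise ValueError("amplitude_pct and width_mm must be positive")
    if duration_frames < 2:
        raise ValueError("duration_frames must be >= 2")
    if not (0 <= centre[0] < spec.height and 0 <= centre[1] < spec.width):
        raise ValueError("centre must lie inside the image")
    if t_onset < 0 or t_onset + duration_frames > spec.n_frames:
        raise ValueError("event window does not fit in the movie")

    sigma_px = width_mm / spec.pixel_mm
    c = np.asarray(centre, dtype=float)
    frames = np.arange(t_onset, t_onset + duration_frames)
    freq_eq = 1.0 / (duration_frames * spec.dt)  # single raised-cosine cycle
    w = _raised_cosine(frames, t_onset, freq_eq, spec.dt)
    track = []
    for k, t in enumerate(frames):
        track.append((int(t), float(c[0]), float(c[1])))
        if w[k] > 0:
            _apply_bump(movie.data, c, sigma_px, amplitude_pct / 100.0 * w[k], t)

    peak_z = None
    if noise is not None:
        base = baseline_map(atlas, baselines)
        b_local = float(base[int(round(c[0])), int(round(c[1]))])
        sd = predicted_noise_sd(noise, spec.n_frames, spec.dt)
        if sd > 0:
            eq = WaveSpec(
                path=((float(c[0]), float(c[1])),),
                speed=1e-6 + 1.0,
                freq=freq_eq,
                amplitude_pct=amplitude_pct,
                width_mm=width_mm,
                t_onset=t_onset,
                n_cycles=1.0,
            )
            gain = carrier_band_gain(eq, spec.dt, band)
            peak_z = amplitude_pct / 100.0 * b_local * gain / sd
    ground_truth.append(
        GroundTruthEvent(
            event_id=ground_truth.next_id(),
            kind="static",
            pattern=PatternLabel.UNCLASSIFIED_STATIC.name,
            t_onset=int(t_onset),
            t_end=int(frames[-1]),
            amplitude_pct=amplitude_pct,
            freq=None,
            speed_mm_s=None,
            width_mm=width_mm,
            centroid_track=track,
            path_length_px=0.0,
            dynamic=False,
            peak_z=peak_z,
        )
    )
    return movie


def inject_oscillation_train(
    movie: Movie,
    centres: Sequence[tuple[float, float]],
    amplitude_pct: float,
    freq: float,
    n_cycles: float,
    t_onset: int,
    width_mm: float,
    node_delay_s: float,
    ground_truth: GroundTruthLog,
    pattern: PatternLabel | None = None,
) -> Movie:
    """Sustained quasi-sinusoidal train on a chain of oscillation nodes.

    Each node is a stationary Gaussian bump carrying the same raised
    cosine train; node ``k`` is delayed by ``k * node_delay_s``, giving
    a slow travelling phase gradient along the chain (the mesoscale
    appearance of a propagating vasomotor wave).
    """
    spec = movie.spec
    if amplitude_pct <= 0 or freq <= 0 or n_cycles <= 0:
        raise ValueError("amplitude, freq and n_cycles must be positive")
    sigma_px = width_mm / spec.pixel_mm
    dur = max(2, int(round(n_cycles / freq / spec.dt)))
    delay_f = node_delay_s / spec.dt
    total_end = t_onset + dur + int(math.ceil(delay_f * (len(centres) - 1)))
    if t_onset < 0 or total_end > spec.n_frames:
        raise ValueError("train window does not fit in the movie")

    track = []
    for k, centre in enumerate(centres):
        onset_k = t_onset + delay_f * k
        f0 = int(math.ceil(onset_k))
        f1 = int(math.floor(onset_k + dur - 1))
        frames = np.arange(f0, f1 + 1)
        t_rel = (frames - onset_k) * spec.dt
        w = 0.5 * (1.0 - np.cos(2 * np.pi * freq * t_rel))
        c = np.asarray(centre, dtype=float)
        track.append((int(round(onset_k)), float(c[0]), float(c[1])))
        for w_k, t in zip(w, frames):
            if w_k > 0:
                _apply_bump(movie.data, c, sigma_px, amplitude_pct / 100.0 * w_k, t)

    pts = np.asarray([(r, c) for _, r, c in track])
    path_len = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))) if len(pts) > 1 else 0.0
    ground_truth.append(
        GroundTruthEvent(
            event_id=ground_truth.next_id(),
            kind="train",
            pattern=pattern.name if pattern else None,
            t_onset=int(t_onset),
            t_end=int(total_end - 1),
            amplitude_pct=amplitude_pct,
            freq=freq,
            speed_mm_s=(
                float(np.linalg.norm(pts[1] - pts[0]) * spec.pixel_mm / node_delay_s)
                if len(pts) > 1 and node_delay_s > 0
                else None
            ),
            width_mm=width_mm,
            centroid_track=track,
            path_length_px=path_len,
            dynamic=len(pts) > 1,
        )
    )
    return movie


# ---------------------------------------------------------------------------
# pattern path templates
# ---------------------------------------------------------------------------


def _mask_centroid(mask: np.ndarray) -> tuple[float, float]:
    rr, cc = np.nonzero(mask)
    return float(rr.mean()), float(cc.mean())


def _cortex_row(atlas: RoiAtlas) -> float:
    return _mask_centroid(atlas.tissue_mask("cortex"))[0]


def pattern_path(
    atlas: RoiAtlas, pattern: PatternLabel, hemi: str = "right"
) -> tuple[tuple[float, float], ...]:
    """Waypoints realising one of the six trajectory patterns.

    Medio-temporal runs from the midline cortex toward the lateral
    (temporal) cortex of ``hemi``; subcortical patterns connect the
    cortical ribbon with the hippocampus or the dorsal midbrain.
    """
    row = _cortex_row(atlas)
    mid = atlas.midline_col

    def ctx_point(name: str, h: str) -> tuple[float, float]:
        r, c = _mask_centroid(atlas.mask(name, h))
        return (row, c)

    medial = (row, mid + (6.0 if hemi == "right" else -6.0))
    temporal = ctx_point("PrimVisCtx", hemi)
    ctx_mid = ctx_point("SecVisCtx", hemi)
    hippo = _mask_centroid(atlas.mask("Hippocampus", hemi))
    midbrain = _mask_centroid(atlas.mask("DorsalMidbrain", hemi))

    if pattern is PatternLabel.MEDIO_TEMPORAL:
        return (medial, temporal)
    if pattern is PatternLabel.TEMPORO_MEDIAL:
        return (temporal, medial)
    if pattern is PatternLabel.TRANSHEMISPHERIC:
        other = "left" if hemi == "right" else "right"
        return (ctx_point("SecVisCtx", other), ctx_point("SecVisCtx", hemi))
    if pattern is PatternLabel.CORTICO_HIPPOCAMPAL:
        return (ctx_mid, hippo)
    if pattern is PatternLabel.HIPPOCAMPO_CORTICAL:
        return (hippo, ctx_mid)
    if pattern is PatternLabel.CORTICO_SUBCORTICAL:
        return (ctx_mid, midbrain)
    raise ValueError(f"no path template for {pattern}")


TRAVELLING_PATTERNS = (
    PatternLabel.MEDIO_TEMPORAL,
    PatternLabel.TEMPORO_MEDIAL,
    PatternLabel.TRANSHEMISPHERIC,
    PatternLabel.CORTICO_SUBCORTICAL,
    PatternLabel.CORTICO_HIPPOCAMPAL,
    PatternLabel.HIPPOCAMPO_CORTICAL,
)


def fitted_wave(
    atlas: RoiAtlas,
    spec: AcquisitionSpec,
    pattern: PatternLabel,
    hemi: str,
    freq: float,
    amplitude_pct: float,
    t_onset: int,
    width_mm: float = 0.9,
) -> WaveSpec:
    """Wave whose speed makes one carrier cycle traverse its full path.

    The motion is centred on the carrier peak (30–70 % of the active
    window), with a brief dwell at each path end while the carrier is
    still above detection threshold, so both trajectory endpoints are
    visible to a z>5 detector; the speed is set so that interval covers
    the full path, staying in the physiological 0.1–0.8 mm/s range for
    the atlas's templates at desk-scale grids.
    """
    path = pattern_path(atlas, pattern, hemi)
    arc_px = float(
        np.sum(np.linalg.norm(np.diff(np.asarray(path), axis=0), axis=1))
    )
    motion = (0.30, 0.70)
    speed = arc_px * spec.pixel_mm * freq / (motion[1] - motion[0])
    return WaveSpec(
        path=path,
        speed=speed,
        freq=freq,
        amplitude_pct=amplitude_pct,
        width_mm=width_mm,
        t_onset=t_onset,
        n_cycles=1.0,
        pattern=pattern,
        motion_window=motion,
    )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

#: Arm definitions.  The VEH-like arm carries sparse, low-amplitude
#: cortical medio-temporal / temporo-medial waves only.  The LPS-like
#: arm adds sustained high-amplitude quasi-periodic oscillation trains
#: on a chain of cortical nodes (phase-lagged, i.e. slowly travelling)
#: plus occasional waves of all six patterns.
ARM_DEFAULTS = {
    "VEH": dict(
        wave_rate_per_min=0.3,
        static_rate_per_min=0.3,
        amplitude_range=(8.0, 15.0),
        patterns=(PatternLabel.MEDIO_TEMPORAL, PatternLabel.TEMPORO_MEDIAL),
        trains=False,
    ),
    "LPS": dict(
        wave_rate_per_min=0.8,
        static_rate_per_min=0.5,
        amplitude_range=(20.0, 35.0),
        patterns=TRAVELLING_PATTERNS,
        trains=True,
        train_amplitude_range=(50.0, 70.0),
        train_width_mm=1.2,
        train_cycles=8.0,
        train_gap_s=(4.0, 12.0),
        node_delay_s=2.0,
        n_nodes_per_hemi=4,
    ),
}


def _cortex_node_chain(atlas: RoiAtlas, n_nodes: int, hemi: str) -> list[tuple[float, float]]:
    """Evenly spaced oscillation-node centres along the cortical ribbon."""
    row = _cortex_row(atlas)
    mid = atlas.midline_col
    lateral = _mask_centroid(atlas.mask("PrimVisCtx", hemi))[1]
    start = mid + (4.0 if hemi == "right" else -4.0)
    cols = np.linspace(start, lateral, n_nodes)
    return [(row, float(c)) for c in cols]


def _poisson_onsets(
    rng: np.random.Generator, rate_per_min: float, spec: AcquisitionSpec, margin: int
) -> list[int]:
    n = rng.poisson(rate_per_min * spec.duration_s / 60.0)
    hi = spec.n_frames - margin
    if hi <= 0:
        return []
    return sorted(int(v) for v in rng.integers(0, hi, size=n))


def simulate_scan(
    arm: str,
    atlas: RoiAtlas,
    spec: AcquisitionSpec,
    seed: int,
    noise: NoiseSpec | None = None,
    overrides: dict | None = None,
) -> tuple[Movie, GroundTruthLog]:
    """Simulate one resting-state scan of the given arm."""
    if arm not in ARM_DEFAULTS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {sorted(ARM_DEFAULTS)}")
    cfg = dict(ARM_DEFAULTS[arm])
    if overrides:
        cfg.update(overrides)
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    movie = simulate_baseline(atlas, spec, noise, seed=int(rng.integers(2**31)))
    gt = GroundTruthLog(seed=seed)

    if cfg.get("trains"):
        # sustained quasi-periodic trains, homotopic in both hemispheres
        chains = {
            h: _cortex_node_chain(atlas, cfg["n_nodes_per_hemi"], h)
            for h in ("left", "right")
        }
        t = int(rng.integers(0, 20))
        while True:
            freq = float(rng.uniform(0.10, 0.15))
            amp = float(rng.uniform(*cfg["train_amplitude_range"]))
            cycles = cfg["train_cycles"]
            dur = int(round(cycles / freq / spec.dt))
            tail = int(math.ceil(cfg["node_delay_s"] / spec.dt)) * (
                cfg["n_nodes_per_hemi"] - 1
            )
            if t + dur + tail >= spec.n_frames:
                break
            for h in ("left", "right"):
                inject_oscillation_train(
                    movie,
                    chains[h],
                    amplitude_pct=amp,
                    freq=freq,
                    n_cycles=cycles,
                    t_onset=t,
                    width_mm=cfg["train_width_mm"],
                    node_delay_s=cfg["node_delay_s"],
                    ground_truth=gt,
                    pattern=PatternLabel.MEDIO_TEMPORAL,
                )
            gap = rng.uniform(*cfg["train_gap_s"])
            t += dur + tail + int(round(gap / spec.dt))

    margin = int(round((2.0 / 0.08) / spec.dt)) + 4  # longest wave window
    for onset in _poisson_onsets(rng, cfg["wave_rate_per_min"], spec, margin):
        pattern = cfg["patterns"][int(rng.integers(len(cfg["patterns"])))]
        hemi = "right" if rng.random() < 0.5 else "left"
        wave = fitted_wave(
            atlas,
            spec,
            pattern,
            hemi,
            freq=float(rng.uniform(0.09, 0.14)),
            amplitude_pct=float(rng.uniform(*cfg["amplitude_range"])),
            t_onset=onset,
            width_mm=float(rng.uniform(0.7, 1.0)),
        )
        inject_travelling_wave(movie, atlas, wave, gt, noise=noise)

    for onset in _poisson_onsets(rng, cfg["static_rate_per_min"], spec, 40):
        name = CORTEX_NAMES[int(rng.integers(len(CORTEX_NAMES)))]
        hemi = "right" if rng.random() < 0.5 else "left"
        centre = _mask_centroid(atlas.mask(name, hemi))
        inject_static_event(
            movie,
            atlas,
            centre,
            amplitude_pct=float(rng.uniform(*cfg["amplitude_range"])),
            duration_frames=int(rng.integers(15, 30)),
            width_mm=float(rng.uniform(0.5, 0.8)),
            t_onset=onset,
            ground_truth=gt,
            noise=noise,
        )
    return movie, gt


def simulate_cohort(
    arm: str,
    n_scans: int,
    spec: AcquisitionSpec,
    seed: int,
    atlas: RoiAtlas | None = None,
    noise: NoiseSpec | None = None,
    overrides: dict | None = None,
) -> list[tuple[Movie, GroundTruthLog]]:
    """Simulate ``n_scans`` independent scans of one arm.

    Per-scan seeds are drawn from ``seed`` so scans differ in event
    timing while sharing the arm's statistics.
    """
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    atlas = atlas or build_atlas(spec)
    rng = np.random.default_rng(seed)
    scan_seeds = rng.integers(0, 2**31, size=n_scans)
    return [
        simulate_scan(arm, atlas, spec, int(s), noise=noise, overrides=overrides)
        for s in scan_seeds
    ]


def _cortical_run_path(
    atlas: RoiAtlas,
    spec: AcquisitionSpec,
    length_px: float,
    rng: np.random.Generator,
) -> tuple[tuple[tuple[float, float], tuple[float, float]], PatternLabel]:
    """Straight path of the given length along the cortical ribbon.

    Start column and direction are random within the image; the
    implied pattern is medio-temporal / temporo-medial (or
    trans-hemispheric when the run crosses the midline).
    """
    row = _cortex_row(atlas)
    mid = atlas.midline_col
    w = atlas.shape[1]
    margin = 6.0
    if length_px > w - 2 * margin:
        raise ValueError("path longer than the cortical ribbon")
    c0 = float(rng.uniform(margin, w - margin - length_px))
    c1 = c0 + length_px
    if rng.random() < 0.5:
        c0, c1 = c1, c0  # reverse direction
    crosses = (min(c0, c1) < mid) and (max(c0, c1) > mid)
    if crosses:
        pattern = PatternLabel.TRANSHEMISPHERIC
    else:
        hemi_sign = 1.0 if min(c0, c1) >= mid else -1.0
        outward = (c1 - c0) * hemi_sign > 0
        pattern = PatternLabel.MEDIO_TEMPORAL if outward else PatternLabel.TEMPORO_MEDIAL
    return ((row, c0), (row, c1)), pattern


def simulate_event_scan(
    spec: AcquisitionSpec,
    atlas: RoiAtlas,
    seed: int,
    n_waves: int = 8,
    n_static: int = 4,
    amplitude_range: tuple[float, float] = (12.0, 45.0),
    speed_range: tuple[float, float] = (0.2, 0.8),
    freq_range: tuple[float, float] = (0.09, 0.13),
    noise: NoiseSpec | None = None,
) -> tuple[Movie, GroundTruthLog]:
    """Detector-recovery scan: well-separated single-cycle waves + static events.

    Events are laid out in disjoint time slots so that each injected
    event corresponds to at most one detected event, which makes the
    per-event recovery and dynamic/static bookkeeping unambiguous.
    Waves run along the cortical ribbon with path length matched to one
    carrier cycle (``v / f``), so the bump travels for its entire
    active window.
    """
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    movie = simulate_baseline(atlas, spec, noise, seed=int(rng.integers(2**31)))
    gt = GroundTruthLog(seed=seed)

    n_events = n_waves + n_static
    slot = spec.n_frames // n_events
    kinds = ["wave"] * n_waves + ["static"] * n_static
    rng.shuffle(kinds)
    max_dur = int(round(1.0 / freq_range[0] / spec.dt)) + 2
    for i, kind in enumerate(kinds):
        lo = i * slot + 4
        hi = (i + 1) * slot - max_dur - 4
        if hi <= lo:
            raise ValueError("record too short for the requested number of events")
        onset = int(rng.integers(lo, hi))
        if kind == "wave":
            # the one-cycle journey (v / f) must fit on the cortical
            # ribbon: cap the speed for small grids and floor the
            # carrier frequency for fast waves
            max_len_mm = (spec.width - 13) * spec.pixel_mm
            v_hi = min(speed_range[1], freq_range[1] * max_len_mm)
            speed = float(rng.uniform(speed_range[0], max(v_hi, speed_range[0])))
            f_lo = max(freq_range[0], speed / max_len_mm)
            freq = float(rng.uniform(f_lo, max(freq_range[1], f_lo)))
            length_px = speed / freq / spec.pixel_mm
            path, pattern = _cortical_run_path(atlas, spec, length_px, rng)
            wave = WaveSpec(
                path=path,
                speed=speed,
                freq=freq,
                amplitude_pct=float(rng.uniform(*amplitude_range)),
                width_mm=float(rng.uniform(0.5, 0.8)),
                t_onset=onset,
                n_cycles=1.0,
                pattern=pattern,
            )
            inject_travelling_wave(movie, atlas, wave, gt, noise=noise)
        else:
            name = CORTEX_NAMES[int(rng.integers(len(CORTEX_NAMES)))]
            hemi = "right" if rng.random() < 0.5 else "left"
            centre = _mask_centroid(atlas.mask(name, hemi))
            inject_static_event(
                movie,
                atlas,
                centre,
                amplitude_pct=float(rng.uniform(*amplitude_range)),
                duration_frames=int(rng.integers(18, 30)),
                width_mm=float(rng.uniform(0.5, 0.8)),
                t_onset=onset,
                ground_truth=gt,
                noise=noise,
            )
    return movie, gt


def simulate_pattern_scan(
    spec: AcquisitionSpec,
    atlas: RoiAtlas,
    seed: int,
    patterns: Sequence[PatternLabel] = TRAVELLING_PATTERNS,
    n_static: int = 2,
    amplitude_pct: float = 36.0,
    width_mm: float = 0.9,
    noise: NoiseSpec | None = None,
) -> tuple[Movie, GroundTruthLog]:
    """Trajectory-taxonomy scan: one fitted wave per requested pattern.

    Waves traverse their full pattern path in one carrier cycle and use
    a wide footprint so the detected event's occupancy spans both
    tissues of subcortical trajectories; static events are appended for
    the unclassified class.
    """
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    movie = simulate_baseline(atlas, spec, noise, seed=int(rng.integers(2**31)))
    gt = GroundTruthLog(seed=seed)

    n_events = len(patterns) + n_static
    slot = spec.n_frames // n_events
    max_dur = int(round(1.0 / 0.09 / spec.dt)) + 2
    kinds: list = list(patterns) + ["static"] * n_static
    for i, kind in enumerate(kinds):
        lo, hi = i * slot + 4, (i + 1) * slot - max_dur - 4
        if hi <= lo:
            raise ValueError("record too short for the requested patterns")
        onset = int(rng.integers(lo, hi))
        hemi = "right" if rng.random() < 0.5 else "left"
        if kind == "static":
            name = CORTEX_NAMES[int(rng.integers(len(CORTEX_NAMES)))]
            centre = _mask_centroid(atlas.mask(name, hemi))
            inject_static_event(
                movie, atlas, centre,
                amplitude_pct=amplitude_pct,
                duration_frames=int(rng.integers(18, 30)),
                width_mm=width_mm, t_onset=onset,
                ground_truth=gt, noise=noise,
            )
        else:
            wave = fitted_wave(
                atlas, spec, kind, hemi,
                freq=float(rng.uniform(0.10, 0.13)),
                amplitude_pct=amplitude_pct,
                t_onset=onset,
                width_mm=width_mm,
            )
            inject_travelling_wave(movie, atlas, wave, gt, noise=noise)
    return movie, gt


# ---------------------------------------------------------------------------
# stimulation sessions
# ---------------------------------------------------------------------------


def simulate_stim_session(
    atlas: RoiAtlas,
    spec: AcquisitionSpec,
    protocol: StimulusProtocol,
    response: dict,
    seed: int = 0,
    noise: NoiseSpec | None = None,
    waves: Sequence[WaveSpec] = (),
) -> tuple[Movie, GroundTruthLog]:
    """Stimulation session: plateau responses in target ROIs per block.

    ``response`` keys: ``regions`` (iterable of region names or ids),
    ``amplitude_pct``, ``rise_s``, ``fall_s``.  The response follows
    first-order rise/decay kinetics toward the plateau during each
    stimulation block (a boxcar convolved with an exponential kernel);
    ``rise_s = 0`` gives an ideal plateau.  Optional ``waves`` are
    superimposed to emulate oscillations persisting during stimulation.
    """
    if protocol.total_duration_s > spec.duration_s + 1e-9:
        raise ValueError(
            f"protocol ({protocol.total_duration_s} s) exceeds the movie "
            f"duration ({spec.duration_s} s)"
        )
    regions: list[int] = []
    for r in response["regions"]:
        if isinstance(r, str):
            regions.extend(atlas.ids_for(r))
        else:
            if r not in atlas.names:
                raise ValueError(f"region id {r} not in atlas")
            regions.append(int(r))
    amp = float(response["amplitude_pct"])
    rise = float(response.get("rise_s", 1.5))
    fall = float(response.get("fall_s", 2.0))

    noise = noise or NoiseSpec()
    movie = simulate_baseline(atlas, spec, noise, seed=seed)
    gt = GroundTruthLog(seed=seed)

    stim_on = np.zeros(spec.n_frames, dtype=bool)
    for s, e in protocol.stim_epochs(spec.dt):
        stim_on[s:e] = True
    r_t = np.zeros(spec.n_frames)
    level = 0.0
    for t in range(spec.n_frames):
        target = amp if stim_on[t] else 0.0
        tau = rise if stim_on[t] else fall
        if tau <= 0:
            level = target
        else:
            level += (target - level) * (1.0 - math.exp(-spec.dt / tau))
        r_t[t] = level

    target_mask = np.isin(atlas.labels, regions)
    movie.data[target_mask, :] *= (1.0 + r_t / 100.0).astype(np.float32)[None, :]

    for s, e in protocol.stim_epochs(spec.dt):
        cen = _mask_centroid(target_mask)
        gt.append(
            GroundTruthEvent(
                event_id=gt.next_id(),
                kind="stim",
                pattern=None,
                t_onset=int(s),
                t_end=int(e - 1),
                amplitude_pct=amp,
                freq=None,
                speed_mm_s=None,
                width_mm=0.0,
                centroid_track=[(int(s), cen[0], cen[1])],
                path_length_px=0.0,
                dynamic=False,
            )
        )
    for wave in waves:
        inject_travelling_wave(movie, atlas, wave, gt, noise=noise)
    return movie, gt
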