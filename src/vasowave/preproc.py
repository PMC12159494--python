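"""Temporal preprocessing: band-pass filtering, relative CBV change,
ROI time-course extraction and artifact-free window selection.

Filtering is a 4th-order Butterworth applied forward-backward
(zero-phase) per pixel with reflect padding, so it is linear, causes no
spatial mixing, and commutes with ROI averaging to numerical tolerance.

Note on the wide resting-state band (0.0008–0.2 Hz): on a 20-min record
the low cut is at/below 1/duration, so the high-pass part removes
little beyond the mean; it is implemented as stated for fidelity to the
analysis constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import BandSpec, Movie
from .atlas import RoiAtlas

__all__ = [
    "bandpass_movie",
    "bandpass_series",
    "percent_change",
    "roi_timecourses",
    "artifact_free_window",
    "RoiTimecourses",
]

_FILTER_ORDER = 4


def _design_sos(dt: float, band: BandSpec) -> np.ndarray:
    band.validate_for(dt)
    nyq = 0.5 / dt
    if band.high >= nyq * (1 - 1e-9):
        # band reaches Nyquist: pure high-pass
        return signal.butter(_FILTER_ORDER, band.low / nyq, btype="highpass", output="sos")
    if band.low <= 0:
        return signal.butter(_FILTER_ORDER, band.high / nyq, btype="lowpass", output="sos")
    return signal.butter(
        _FILTER_ORDER, [band.low / nyq, band.high / nyq], btype="bandpass", output="sos"
    )


def _bandpass_series(x: np.ndarray, dt: float, band: BandSpec) -> np.ndarray:
    """Zero-phase band-pass along the last axis."""
    sos = _design_sos(dt, band)
    n = x.shape[-1]
    if n <= 6 * (2 * _FILTER_ORDER + 1):
        raise ValueError(
            f"record too short for filtering: {n} frames (need > {6 * (2 * _FILTER_ORDER + 1)})"
        )
    return signal.sosfiltfilt(sos, x, axis=-1)


def bandpass_series(x: np.ndarray, dt: float, band: BandSpec) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass of 1-D/2-D series."""
    return _bandpass_series(np.asarray(x, dtype=float), dt, band)


def bandpass_movie(movie: Movie, band: BandSpec) -> Movie:
    """Apply the zero-phase temporal band-pass to every pixel.

    For ``band.low > 0`` the per-pixel mean of the output is ~0.  The
    filter acts on the time axis only — no spatial mixing.
    """
    out = _bandpass_series(movie.data.astype(np.float64, copy=False), movie.spec.dt, band)
    return Movie(out.astype(np.float32), movie.spec)


def percent_change(movie: Movie, baseline: tuple[int, int] | None = None) -> Movie:
    """Relative CBV change in % of baseline, per pixel.

    ``baseline`` is a frame range ``(start, stop)`` (e.g. a pre-stimulus
    rest period); ``None`` uses the whole-series mean.  Output is
    ``100 * (data - b) / b``.
    """
    if baseline is None:
        b = movie.data.mean(axis=2)
    else:
        s, e = baseline
        if not (0 <= s < e <= movie.n_frames):
            raise ValueError(f"baseline frame range {baseline} invalid for {movie.n_frames} frames")
        b = movie.data[:, :, s:e].mean(axis=2)
    bad = b <= 0
    if np.any(bad):
        r, c = np.argwhere(bad)[0]
        raise ValueError(f"non-positive baseline at pixel ({r}, {c})")
    out = 100.0 * (movie.data / b[:, :, None] - 1.0)
    return Movie(out.astype(np.float32), movie.spec)


@dataclass
class RoiTimecourses:
    """Per-ROI mean intensity time series."""

    series: dict[int, np.ndarray]  # roi id -> (n_frames,)
    names: dict[int, str]
    dt: float
    hemisphere: dict[int, str] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.series.values())))

    def ids(self) -> list[int]:
        return sorted(self.series)

    def as_matrix(self) -> np.ndarray:
        """(n_rois, n_frames) matrix in id order."""
        return np.vstack([self.series[i] for i in self.ids()])

    def label(self, rid: int) -> str:
        hemi = self.hemisphere.get(rid)
        return f"{self.names[rid]}_{hemi[0].upper()}" if hemi else self.names[rid]

    def to_frame(self):
        import pandas as pd

        n = self.n_frames
        data = {"frame": np.arange(n), "time_s": np.arange(n) * self.dt}
        for rid in self.ids():
            data[self.label(rid)] = self.series[rid]
        return pd.DataFrame(data)


def roi_timecourses(
    movie: Movie, atlas: RoiAtlas, roi_ids: list[int] | None = None
) -> RoiTimecourses:
    """Per-frame unweighted mean over each ROI's pixels."""
    if atlas.shape != movie.shape[:2]:
        raise ValueError("atlas grid does not match the movie")
    ids = roi_ids if roi_ids is not None else atlas.all_ids()
    series: dict[int, np.ndarray] = {}
    for rid in ids:
        if rid not in atlas.names:
            raise KeyError(f"roi id {rid} not in atlas")
        mask = atlas.labels == rid
        if not mask.any():
            raise ValueError(f"roi {atlas.names[rid]} ({rid}) is empty")
        series[rid] = movie.data[mask, :].mean(axis=0).astype(np.float64)
    return RoiTimecourses(
        series=series,
        names={i: atlas.names[i] for i in ids},
        dt=movie.spec.dt,
        hemisphere={i: atlas.hemisphere[i] for i in ids},
    )


def artifact_free_window(
    series: np.ndarray,
    dt: float,
    spike_threshold: float = 5.0,
    min_duration_s: float = 120.0,
) -> tuple[int, int]:
    """Earliest maximal-length contiguous window free of motion spikes.

    A sample is a spike when it exceeds ``median + spike_threshold *
    robust sd`` (robust sd = 1.4826·MAD).  Returns ``(start, end)``
    frame indices (end exclusive); raises if no clean window reaches
    ``min_duration_s``.
    """
    x = np.asarray(series, dtype=float)
    min_frames = int(round(min_duration_s / dt))
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if len(x) < min_frames:
        raise ValueError(
            f"series shorter ({len(x)} frames) than the minimum window ({min_frames})"
        )
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    robust_sd = 1.4826 * mad
    clean = x <= med + spike_threshold * robust_sd

    best: tuple[int, int] | None = None
    start = None
    for i, ok in enumerate(np.append(clean, False)):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            if best is None or (i - start) > (best[1] - best[0]):
                best = (start, i)
            start = None
    if best is None or (best[1] - best[0]) < min_frames:
        raise ValueError(
            f"no artifact-free window of at least {min_duration_s} s found"
        )
    return best
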