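"""Spatiotemporal CBV-increase event detection and quantification.

The detector works on the vasomotion-band-filtered movie: per-pixel
robust z-scoring against a first-difference noise estimate, light
spatial smoothing, thresholding at z > 5, spatiotemporal connected
components (8-neighbour in space, frame-adjacent in time when the
footprints overlap by at least one pixel), and a minimum single-frame
footprint of 15 px.  Merged components holding two clearly separated
z-maxima (saddle below 50 % of the lower peak) are split by
marker-based watershed.

An event's propagation distance is the sum of its frame-to-frame
z-weighted centroid displacements; events travelling more than 5 px
are classified dynamic, the rest static.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from .core import AcquisitionSpec, BandSpec, Movie, WAVE_BAND

__all__ = [
    "DetectorConfig",
    "EventRecord",
    "robust_zscore",
    "smooth_z",
    "detect_events",
    "event_features",
    "classify_dynamic",
    "summarize_scan",
    "train_speed",
]


@dataclass(frozen=True)
class DetectorConfig:
    z_threshold: float = 5.0
    min_size_px: int = 15
    smoothing_sigma_px: float = 0.5
    dynamic_threshold_px: float = 5.0
    band: BandSpec = WAVE_BAND
    min_peak_amplitude_pct: float = 0.0  # optional ΔCBV% gate, disabled by default
    split_events: bool = True

    def __post_init__(self) -> None:
        if min(self.z_threshold, self.min_size_px, self.smoothing_sigma_px,
               self.dynamic_threshold_px) <= 0:
            raise ValueError("detector thresholds must be positive")


@dataclass
class EventRecord:
    """One detected spatiotemporal CBV peak."""

    event_id: int
    t_start: int
    t_end: int  # inclusive
    footprints: dict[int, np.ndarray]  # frame -> (n_px, 2) int array of (row, col)
    seed: tuple[int, int, int]  # (row, col, frame) of the peak z
    peak_z: float
    # features (filled by event_features)
    centroid_track: np.ndarray | None = None  # (n_frames_active, 2)
    propagation_px: float | None = None
    propagation_mm: float | None = None
    peak_amplitude_pct: float | None = None
    duration_s: float | None = None
    delay_map: dict[tuple[int, int], float] | None = None  # pixel -> seconds
    speed_mm_s: float | None = None
    speed_undefined: bool = False
    dynamic: bool | None = None

    @property
    def frames(self) -> list[int]:
        return sorted(self.footprints)

    @property
    def n_px_union(self) -> int:
        return len(self.union_pixels())

    def union_pixels(self) -> set[tuple[int, int]]:
        px: set[tuple[int, int]] = set()
        for fp in self.footprints.values():
            px.update(map(tuple, fp))
        return px

    def max_frame_size(self) -> int:
        return max(len(fp) for fp in self.footprints.values())

    def delay_image(self, shape: tuple[int, int]) -> np.ndarray:
        """Delay map as a full image (NaN outside the union footprint)."""
        img = np.full(shape, np.nan, dtype=np.float32)
        for (r, c), d in (self.delay_map or {}).items():
            img[r, c] = d
        return img


def robust_zscore(
    movie_band: Movie, noise_source: Movie | np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel robust z-scoring of the band-filtered movie.

    The noise sd per pixel is estimated from temporal first differences
    (insensitive to the slow in-band waves themselves):
    ``sd = 1.4826 · MAD(diff) / sqrt(2)``.  For band-limited data the
    differences of neighbouring frames are strongly correlated and the
    estimate would shrink ~5-fold, so the pipeline passes the *raw*
    movie as ``noise_source``; without one the band movie itself is
    used (appropriate for broadband input).

    Returns ``(z, sd_map)``.  Zero-variance pixels get an
    epsilon-floored sd with a warning.
    """
    src = noise_source.data if isinstance(noise_source, Movie) else noise_source
    if src is None:
        src = movie_band.data
    if src.shape != movie_band.shape:
        raise ValueError("noise source shape does not match the movie")
    d = np.diff(src.astype(np.float32), axis=2)
    med = np.median(d, axis=2, keepdims=True)
    mad = np.median(np.abs(d - med), axis=2)
    sd = (mad * (1.4826 / np.sqrt(2.0))).astype(np.float32)
    del d, med, mad
    eps = np.float32(max(float(np.abs(movie_band.data).max()), 1.0) * 1e-9)
    n_floor = int(np.count_nonzero(sd < eps))
    if n_floor:
        warnings.warn(
            f"{n_floor} zero-variance pixels: noise sd floored at {eps:.3g}",
            RuntimeWarning,
            stacklevel=2,
        )
        sd = np.maximum(sd, eps)
    z = movie_band.data / sd[:, :, None]
    return z.astype(np.float32), sd


# spatiotemporal connectivity: 8-neighbour in space within a frame,
# same-pixel adjacency across consecutive frames (equivalent to linking
# frame-wise components that overlap by >= 1 px)
_STRUCTURE = np.zeros((3, 3, 3), dtype=bool)
_STRUCTURE[:, :, 1] = True
_STRUCTURE[1, 1, 0] = _STRUCTURE[1, 1, 2] = True


def _component_events(
    labels: np.ndarray, z_s: np.ndarray, config: DetectorConfig, n_labels: int
) -> list[EventRecord]:
    objects = ndimage.find_objects(labels)
    events: list[EventRecord] = []
    for lab in range(1, n_labels + 1):
        sl = objects[lab - 1]
        if sl is None:
            continue
        sub = labels[sl] == lab
        rr, cc, tt = np.nonzero(sub)
        r0, c0, t0 = sl[0].start, sl[1].start, sl[2].start
        frames: dict[int, list[tuple[int, int]]] = {}
        for r, c, t in zip(rr + r0, cc + c0, tt + t0):
            frames.setdefault(int(t), []).append((int(r), int(c)))
        if max(len(v) for v in frames.values()) < config.min_size_px:
            continue
        zvals = z_s[sl][sub]
        k = int(np.argmax(zvals))
        seed = (int(rr[k] + r0), int(cc[k] + c0), int(tt[k] + t0))
        events.append(
            EventRecord(
                event_id=-1,
                t_start=min(frames),
                t_end=max(frames),
                footprints={t: np.array(v, dtype=np.int32) for t, v in frames.items()},
                seed=seed,
                peak_z=float(zvals[k]),
            )
        )
    return events


def _split_component(
    mask: np.ndarray, z_sub: np.ndarray, saddle_frac: float = 0.5
) -> np.ndarray:
    """Watershed split of one component when it holds well-separated peaks.

    Candidate markers are local z-maxima inside the component; two
    watershed basins are merged back when the best saddle between them
    reaches ``saddle_frac`` of the lower peak.  Returns a label image
    over ``mask`` (0 outside).
    """
    peaks = (ndimage.maximum_filter(z_sub, size=3, mode="constant") == z_sub) & mask
    markers, n_marks = ndimage.label(peaks, structure=np.ones((3, 3, 3), dtype=bool))
    if n_marks <= 1:
        return mask.astype(np.int32)
    seg = watershed(-z_sub, markers=markers, mask=mask)
    peak_val = ndimage.maximum(z_sub, labels=seg, index=np.arange(1, n_marks + 1))

    # saddle between adjacent basins: max z over voxels bordering both
    parent = list(range(n_marks + 1))
    root_peak = [0.0] + [float(v) for v in peak_val]

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    saddles: dict[tuple[int, int], float] = {}
    for axis in range(3):
        a = np.take(seg, range(seg.shape[axis] - 1), axis=axis)
        b = np.take(seg, range(1, seg.shape[axis]), axis=axis)
        za = np.take(z_sub, range(seg.shape[axis] - 1), axis=axis)
        zb = np.take(z_sub, range(1, seg.shape[axis]), axis=axis)
        touch = (a > 0) & (b > 0) & (a != b)
        for la, lb, va, vb in zip(a[touch], b[touch], za[touch], zb[touch]):
            key = (min(la, lb), max(la, lb))
            v = min(va, vb)  # conservative boundary height
            if v > saddles.get(key, -np.inf):
                saddles[key] = v
    # merge highest saddles first, tracking each root's combined peak, so a
    # shallow bridge basin cannot chain two genuine peaks together
    for (la, lb), s in sorted(saddles.items(), key=lambda kv: -kv[1]):
        ra, rb = find(int(la)), find(int(lb))
        if ra == rb:
            continue
        if s >= saddle_frac * min(root_peak[ra], root_peak[rb]):
            parent[rb] = ra
            root_peak[ra] = max(root_peak[ra], root_peak[rb])
    out = np.zeros_like(seg)
    relabel: dict[int, int] = {}
    nz = seg > 0
    roots = np.array([find(int(v)) for v in seg[nz]])
    for i, root in enumerate(np.unique(roots), start=1):
        relabel[int(root)] = i
    out[nz] = [relabel[int(r)] for r in roots]
    return out


def smooth_z(z: np.ndarray, config: DetectorConfig = DetectorConfig()) -> np.ndarray:
    """Per-frame spatial Gaussian smoothing of the z movie (no temporal mixing)."""
    return ndimage.gaussian_filter(
        z, sigma=(config.smoothing_sigma_px, config.smoothing_sigma_px, 0.0)
    )


def detect_events(
    z: np.ndarray,
    config: DetectorConfig = DetectorConfig(),
    z_smoothed: np.ndarray | None = None,
) -> list[EventRecord]:
    """Detect spatiotemporal CBV-increase events in a z-scored movie.

    Pipeline: spatial Gaussian smoothing (σ = ``smoothing_sigma_px``) →
    threshold at ``z_threshold`` → spatiotemporal connected components →
    discard components whose largest single-frame footprint is below
    ``min_size_px`` → optional watershed splitting of merged peaks.
    An empty result list is valid.  ``z_smoothed`` may be supplied to
    reuse a precomputed :func:`smooth_z` result.
    """
    if not np.all(np.isfinite(z)):
        raise ValueError("z movie contains non-finite values")
    z_s = z_smoothed if z_smoothed is not None else smooth_z(z, config)
    mask = z_s > config.z_threshold
    labels, n_labels = ndimage.label(mask, structure=_STRUCTURE)
    events = _component_events(labels, z_s, config, n_labels)

    if config.split_events and events:
        split: list[EventRecord] = []
        for ev in events:
            frames = ev.frames
            rows = [p[0] for fp in ev.footprints.values() for p in fp]
            cols = [p[1] for fp in ev.footprints.values() for p in fp]
            sl = (
                slice(min(rows), max(rows) + 1),
                slice(min(cols), max(cols) + 1),
                slice(frames[0], frames[-1] + 1),
            )
            sub_mask = np.zeros(
                (sl[0].stop - sl[0].start, sl[1].stop - sl[1].start, sl[2].stop - sl[2].start),
                dtype=bool,
            )
            for t, fp in ev.footprints.items():
                sub_mask[fp[:, 0] - sl[0].start, fp[:, 1] - sl[1].start, t - sl[2].start] = True
            seg = _split_component(sub_mask, z_s[sl])
            n_parts = int(seg.max())
            if n_parts <= 1:
                split.append(ev)
                continue
            parts = _component_events(
                np.where(seg > 0, seg, 0), z_s[sl], config, n_parts
            )
            for p in parts:
                p.t_start += sl[2].start
                p.t_end += sl[2].start
                p.footprints = {
                    t + sl[2].start: fp + np.array([sl[0].start, sl[1].start], dtype=np.int32)
                    for t, fp in p.footprints.items()
                }
                p.seed = (p.seed[0] + sl[0].start, p.seed[1] + sl[1].start, p.seed[2] + sl[2].start)
                split.append(p)
        events = split

    events.sort(key=lambda e: (e.t_start, e.seed))
    for i, ev in enumerate(events):
        ev.event_id = i
    return events


def event_features(
    event: EventRecord,
    movie_pct: Movie,
    z: np.ndarray,
    spec: AcquisitionSpec,
) -> EventRecord:
    """Complete an event record with its quantitative features.

    centroid_track: per-frame z-weighted centroid of that frame's
    footprint (pass the smoothed z for stable weighting), denoised by a
    3-point boxcar on interior points (endpoints kept, so straight
    tracks are unchanged); propagation: sum of consecutive centroid
    displacements; peak_amplitude_pct: max ΔCBV% inside the footprint;
    delay map: each union-footprint pixel's time of maximal z relative
    to ``t_start``; speed: propagation_mm / duration_s (0 and flagged
    for single-frame events).
    """
    frames = event.frames
    track = np.empty((len(frames), 2))
    peak_amp = -np.inf
    for i, t in enumerate(frames):
        fp = event.footprints[t]
        wz = np.maximum(z[fp[:, 0], fp[:, 1], t].astype(np.float64), 0.0)
        if wz.sum() <= 0:
            wz = np.ones(len(fp))
        track[i] = (fp * wz[:, None]).sum(axis=0) / wz.sum()
        amps = movie_pct.data[fp[:, 0], fp[:, 1], t]
        peak_amp = max(peak_amp, float(amps.max()))

    if len(track) > 2:  # interior boxcar: kills frame-to-frame jitter only
        smoothed = track.copy()
        smoothed[1:-1] = (track[:-2] + track[1:-1] + track[2:]) / 3.0
        track = smoothed
    prop_px = float(np.sum(np.linalg.norm(np.diff(track, axis=0), axis=1)))
    event.centroid_track = track
    event.propagation_px = prop_px
    event.propagation_mm = prop_px * spec.pixel_mm
    event.peak_amplitude_pct = peak_amp
    event.duration_s = (event.t_end - event.t_start) * spec.dt

    delay: dict[tuple[int, int], float] = {}
    for px in event.union_pixels():
        best_t, best_z = None, -np.inf
        for t in frames:
            fp = event.footprints[t]
            hit = (fp[:, 0] == px[0]) & (fp[:, 1] == px[1])
            if hit.any():
                v = float(z[px[0], px[1], t])
                if v > best_z:
                    best_z, best_t = v, t
        delay[px] = (best_t - event.t_start) * spec.dt
    event.delay_map = delay

    if event.duration_s > 0:
        event.speed_mm_s = event.propagation_mm / event.duration_s
        event.speed_undefined = False
    else:
        event.speed_mm_s = 0.0
        event.speed_undefined = True
    return event


def classify_dynamic(event: EventRecord, config: DetectorConfig = DetectorConfig()) -> bool:
    """Dynamic/travelling iff the centroid path exceeds the 5-px rule."""
    if event.propagation_px is None:
        raise ValueError("event features not computed")
    event.dynamic = bool(event.propagation_px > config.dynamic_threshold_px)
    return event.dynamic


def train_speed(events: list[EventRecord], spec: AcquisitionSpec) -> float:
    """Propagation speed of a quasi-periodic wave train (mm/s).

    A sustained vasomotor wave appears as one detected event per
    carrier cycle; the bump's position advances between cycles.  This
    regresses the events' mean centroid positions (projected on the
    overall displacement axis) onto their peak times — robust to the
    carrier-shape and band-filter biases that affect a single event's
    propagation/duration ratio.  With a single event it falls back to
    that event's ``speed_mm_s``.
    """
    if not events:
        raise ValueError("no events")
    for ev in events:
        if ev.centroid_track is None:
            raise ValueError("event features not computed")
    evs = sorted(events, key=lambda e: e.seed[2])
    if len(evs) == 1:
        return float(evs[0].speed_mm_s or 0.0)
    pos = np.array([e.centroid_track.mean(axis=0) for e in evs])
    t = np.array([e.seed[2] for e in evs], dtype=float) * spec.dt
    axis = pos[-1] - pos[0]
    norm = np.linalg.norm(axis)
    if norm == 0 or np.ptp(t) == 0:
        return 0.0
    x = pos @ (axis / norm) * spec.pixel_mm
    tc = t - t.mean()
    return float((tc @ (x - x.mean())) / (tc @ tc))


def summarize_scan(
    events: list[EventRecord], config: DetectorConfig = DetectorConfig()
) -> dict:
    """Per-scan summary: % dynamic and feature means over dynamic events."""
    for ev in events:
        if ev.dynamic is None:
            classify_dynamic(ev, config)
    n = len(events)
    dyn = [e for e in events if e.dynamic]
    out = {
        "n_events": n,
        "n_dynamic": len(dyn),
        "pct_dynamic": 100.0 * len(dyn) / n if n else float("nan"),
        "undefined": n == 0,
    }
    if dyn:
        out["mean_amplitude_pct"] = float(np.mean([e.peak_amplitude_pct for e in dyn]))
        out["mean_propagation_mm"] = float(np.mean([e.propagation_mm for e in dyn]))
        out["mean_speed_mm_s"] = float(
            np.mean([e.speed_mm_s for e in dyn if not e.speed_undefined])
        )
    else:
        out["mean_amplitude_pct"] = float("nan")
        out["mean_propagation_mm"] = float("nan")
        out["mean_speed_mm_s"] = float("nan")
    return out
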