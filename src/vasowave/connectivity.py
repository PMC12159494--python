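"""Static and dynamic functional connectivity.

Static FC is the Pearson correlation between ROI-mean time courses
(band-passed 0.0008–0.2 Hz upstream), Fisher-Z transformed for group
differencing.  Dynamic seed-based FC correlates a seed-ROI mean with
every pixel inside a sliding window (default 15 frames × 0.4 s = 6 s,
step 1 frame) and aggregates r over a target ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Movie
from .atlas import RoiAtlas
from .preproc import RoiTimecourses

__all__ = ["FcMatrix", "DynamicFcTrace", "static_fc", "fc_difference", "dynamic_seed_fc"]

_R_CLIP = 1.0 - 1e-7


@dataclass
class FcMatrix:
    """Symmetric ROI–ROI Pearson correlation matrix with Fisher-Z copy."""

    roi_ids: list[int]
    labels: list[str]
    r: np.ndarray
    z: np.ndarray

    def pair(self, i: int, j: int) -> tuple[float, float]:
        a, b = self.roi_ids.index(i), self.roi_ids.index(j)
        return float(self.r[a, b]), float(self.z[a, b])

    def to_frame(self):
        import pandas as pd

        rows = []
        for a in range(len(self.roi_ids)):
            for b in range(a + 1, len(self.roi_ids)):
                rows.append(
                    {
                        "roi_a": self.labels[a],
                        "roi_b": self.labels[b],
                        "r": self.r[a, b],
                        "z": self.z[a, b],
                    }
                )
        return pd.DataFrame(rows)


def static_fc(timecourses: RoiTimecourses) -> FcMatrix:
    """Pearson r for every ROI pair; z = atanh(r) with r clipped to ±(1−1e−7)."""
    ids = timecourses.ids()
    mat = timecourses.as_matrix()
    sds = mat.std(axis=1)
    for rid, sd in zip(ids, sds):
        if sd == 0:
            raise ValueError(
                f"zero-variance series for ROI {timecourses.label(rid)}"
            )
    r = np.corrcoef(mat)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    z = np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))
    return FcMatrix(
        roi_ids=ids,
        labels=[timecourses.label(i) for i in ids],
        r=r,
        z=z,
    )


def fc_difference(
    group_a: list[FcMatrix], group_b: list[FcMatrix]
) -> tuple[np.ndarray, np.ndarray]:
    """Element-wise mean-z difference between two groups of FC matrices.

    Returns ``(dz, dr)`` where ``dz = mean(z_a) − mean(z_b)`` and
    ``dr = tanh(mean z_a) − tanh(mean z_b)`` (back-transformed).
    """
    if not group_a or not group_b:
        raise ValueError("each group needs at least one FC matrix")
    ref = group_a[0].roi_ids
    for fc in group_a + group_b:
        if fc.roi_ids != ref:
            raise ValueError("FC matrices cover different ROI sets")
    za = np.mean([fc.z for fc in group_a], axis=0)
    zb = np.mean([fc.z for fc in group_b], axis=0)
    dz = za - zb
    dr = np.tanh(za) - np.tanh(zb)
    np.fill_diagonal(dz, 0.0)
    np.fill_diagonal(dr, 0.0)
    return dz, dr


@dataclass
class DynamicFcTrace:
    """Sliding-window seed connectivity aggregated over a target ROI."""

    times: np.ndarray  # window-centre seconds
    values: np.ndarray  # mean r over the target ROI per window
    window_frames: int
    step_frames: int
    dt: float

    @property
    def window_s(self) -> float:
        return self.window_frames * self.dt

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_s": self.times, "r": self.values})


def dynamic_seed_fc(
    movie: Movie,
    atlas: RoiAtlas,
    seed_roi: int | str,
    target_roi: int | str,
    window_frames: int = 15,
    step: int = 1,
    aggregate_z: bool = False,
) -> DynamicFcTrace:
    """Sliding-window Pearson r between the seed-ROI mean and target pixels.

    The movie should be band-passed to the vasomotion band upstream.
    Per window, r is computed between the seed mean and each pixel of
    the target ROI and averaged (over r by default; over z with
    ``aggregate_z``).  Window timestamps are window centres.
    """
    if window_frames < 3:
        raise ValueError("window_frames must be >= 3")
    n = movie.n_frames
    if window_frames > n:
        raise ValueError(f"window ({window_frames}) longer than record ({n})")
    seed_mask = atlas.mask(seed_roi) if not isinstance(seed_roi, int) else atlas.labels == seed_roi
    target_mask = (
        atlas.mask(target_roi) if not isinstance(target_roi, int) else atlas.labels == target_roi
    )
    if not seed_mask.any() or not target_mask.any():
        raise ValueError("seed or target ROI is empty")

    seed = movie.data[seed_mask, :].mean(axis=0).astype(np.float64)
    pix = movie.data[target_mask, :].astype(np.float64)  # (n_px, n_frames)

    starts = np.arange(0, n - window_frames + 1, step)
    values = np.empty(len(starts))
    for k, s in enumerate(starts):
        sw = seed[s : s + window_frames]
        pw = pix[:, s : s + window_frames]
        sw = sw - sw.mean()
        pw = pw - pw.mean(axis=1, keepdims=True)
        denom = np.sqrt((sw**2).sum()) * np.sqrt((pw**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (pw @ sw) / denom
        r = np.clip(np.nan_to_num(r), -1.0, 1.0)
        if aggregate_z:
            values[k] = float(np.tanh(np.mean(np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP)))))
        else:
            values[k] = float(r.mean())
    times = (starts + (window_frames - 1) / 2.0) * movie.spec.dt
    return DynamicFcTrace(
        times=times,
        values=values,
        window_frames=window_frames,
        step_frames=step,
        dt=movie.spec.dt,
    )
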