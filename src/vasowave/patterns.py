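"""Travelling-wave trajectory taxonomy.

Detected events are grouped descriptively (SVD-reduced binarised delay
maps → k-means into 4 spatial clusters, each subclustered by
horizontal/vertical propagation direction) and, independently, labelled
by an explicit rule on atlas occupancy and delay slopes into six
trajectory classes: medio-temporal, temporo-medial, trans-hemispheric,
cortico-subcortical, cortico-hippocampal and hippocampo-cortical, with
everything else (static or undefined propagation) left unclassified.
The clustering reproduces the descriptive grouping of the source
analysis; the rule-based labeller makes the semantic naming of the
subclusters reproducible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .atlas import RoiAtlas
from .events import EventRecord

__all__ = [
    "PatternLabel",
    "ClusterConfig",
    "build_delay_features",
    "cluster_patterns",
    "label_patterns",
    "pattern_frequencies",
]


class PatternLabel(enum.Enum):
    """Trajectory classes of travelling CBV waves."""

    MEDIO_TEMPORAL = "medio_temporal"
    TEMPORO_MEDIAL = "temporo_medial"
    TRANSHEMISPHERIC = "transhemispheric"
    CORTICO_SUBCORTICAL = "cortico_subcortical"
    CORTICO_HIPPOCAMPAL = "cortico_hippocampal"
    HIPPOCAMPO_CORTICAL = "hippocampo_cortical"
    UNCLASSIFIED_STATIC = "unclassified_static"


TRAVELLING_LABELS = tuple(l for l in PatternLabel if l is not PatternLabel.UNCLASSIFIED_STATIC)

#: label swaps under time reversal of the movie
TIME_REVERSAL_SWAP = {
    PatternLabel.MEDIO_TEMPORAL: PatternLabel.TEMPORO_MEDIAL,
    PatternLabel.TEMPORO_MEDIAL: PatternLabel.MEDIO_TEMPORAL,
    PatternLabel.CORTICO_HIPPOCAMPAL: PatternLabel.HIPPOCAMPO_CORTICAL,
    PatternLabel.HIPPOCAMPO_CORTICAL: PatternLabel.CORTICO_HIPPOCAMPAL,
    PatternLabel.TRANSHEMISPHERIC: PatternLabel.TRANSHEMISPHERIC,
    PatternLabel.CORTICO_SUBCORTICAL: PatternLabel.CORTICO_SUBCORTICAL,
    PatternLabel.UNCLASSIFIED_STATIC: PatternLabel.UNCLASSIFIED_STATIC,
}


@dataclass(frozen=True)
class ClusterConfig:
    svd_components: int = 3000  # capped at matrix rank
    k_spatial: int = 4
    kmeans_restarts: int = 10
    seed: int = 0
    min_area_px: int = 5

    def __post_init__(self) -> None:
        if self.k_spatial < 2:
            raise ValueError("k_spatial must be >= 2")
        if self.svd_components < self.k_spatial:
            raise ValueError("svd_components must be >= k_spatial")


def _lsq_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y on x (0 for degenerate spreads)."""
    if len(x) < 2 or np.ptp(x) == 0:
        return 0.0
    xc = x - x.mean()
    return float((xc @ (y - y.mean())) / (xc @ xc))


def build_delay_features(
    events: list[EventRecord],
    image_shape: tuple[int, int],
    min_area_px: int = 5,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Binary occupancy matrix and direction vectors from event delay maps.

    Per kept event (union footprint area > ``min_area_px``): a flattened
    binary occupancy row of its delay map, and a direction vector of
    (horizontal, vertical) delay slopes — the column-profile and
    row-profile of the delay map each reduced to a signed least-squares
    slope.  Returns ``(binary, directions, kept_indices)``.
    """
    binary_rows, dir_rows, kept = [], [], []
    for i, ev in enumerate(events):
        if ev.delay_map is None:
            raise ValueError(f"event {ev.event_id} has no delay map")
        px = list(ev.delay_map)
        if len(px) <= min_area_px:
            continue
        occ = np.zeros(image_shape, dtype=np.float32)
        rows = np.array([p[0] for p in px])
        cols = np.array([p[1] for p in px])
        delays = np.array([ev.delay_map[p] for p in px])
        occ[rows, cols] = 1.0

        # horizontal delay profile (mean per column) -> slope vs column
        col_ids = np.unique(cols)
        col_prof = np.array([delays[cols == c].mean() for c in col_ids])
        h_slope = _lsq_slope(col_ids.astype(float), col_prof)
        row_ids = np.unique(rows)
        row_prof = np.array([delays[rows == r].mean() for r in row_ids])
        v_slope = _lsq_slope(row_ids.astype(float), row_prof)

        binary_rows.append(occ.ravel())
        dir_rows.append((h_slope, v_slope))
        kept.append(i)
    if not binary_rows:
        return (
            np.zeros((0, image_shape[0] * image_shape[1]), dtype=np.float32),
            np.zeros((0, 2)),
            [],
        )
    return np.vstack(binary_rows), np.asarray(dir_rows), kept


def cluster_patterns(
    binary: np.ndarray,
    directions: np.ndarray,
    config: ClusterConfig = ClusterConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Spatial k-means on SVD scores, then directional subclustering.

    Binary occupancy rows are SVD-reduced to ``min(svd_components,
    rank)`` scores and k-means clustered into ``k_spatial`` spatial
    groups (location only); each spatial cluster is then split in two
    by k-means on the (horizontal, vertical) delay-slope vectors.
    Deterministic given ``config.seed``.
    """
    n = binary.shape[0]
    if n < config.k_spatial:
        raise ValueError(f"{n} events < k_spatial={config.k_spatial}")
    if directions.shape[0] != n:
        raise ValueError("binary and direction matrices disagree on event count")

    u, s, _ = np.linalg.svd(binary, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if len(s) else 0
    k = max(1, min(config.svd_components, rank))
    scores = u[:, :k] * s[:k]

    km = KMeans(
        n_clusters=config.k_spatial,
        n_init=config.kmeans_restarts,
        random_state=config.seed,
    )
    spatial = km.fit_predict(scores)

    sub = np.zeros(n, dtype=int)
    for c in range(config.k_spatial):
        idx = np.nonzero(spatial == c)[0]
        if len(idx) < 2 or np.allclose(directions[idx], directions[idx][0]):
            continue
        km2 = KMeans(n_clusters=2, n_init=config.kmeans_restarts,
                     random_state=config.seed + 1 + c)
        sub[idx] = km2.fit_predict(directions[idx])
    return spatial, sub


def _occupancy(ev: EventRecord, atlas: RoiAtlas) -> dict[str, float]:
    px = list(ev.delay_map)
    tissues = []
    for r, c in px:
        rid = int(atlas.labels[r, c])
        tissues.append(atlas.tissue(rid) if rid else "background")
    n = len(px)
    return {t: tissues.count(t) / n for t in ("cortex", "hippocampus", "subcortex", "background")}


def _tissue_delay(ev: EventRecord, atlas: RoiAtlas, tissue: str) -> float:
    vals = [
        d
        for (r, c), d in ev.delay_map.items()
        if atlas.labels[r, c] and atlas.tissue(int(atlas.labels[r, c])) == tissue
    ]
    return float(np.mean(vals)) if vals else float("nan")


def _majority_tissue(tissues: list[str]) -> str | None:
    """Most frequent non-background tissue of a pixel set."""
    counts: dict[str, int] = {}
    for t in tissues:
        if t != "background":
            counts[t] = counts.get(t, 0) + 1
    return max(counts, key=counts.get) if counts else None


def label_patterns(
    events: list[EventRecord],
    atlas: RoiAtlas,
    dt: float,
    min_occupancy: float = 0.15,
    quartile: float = 0.25,
) -> list[PatternLabel]:
    """Rule-based trajectory labels from atlas occupancy and delay order.

    Dynamic events are labelled by where they start and end: the
    majority tissues of the earliest and latest delay quartiles.

    * cortex → hippocampus (or reverse) → CORTICO_HIPPOCAMPAL /
      HIPPOCAMPO_CORTICAL;
    * cortex ↔ other subcortex (either direction) →
      CORTICO_SUBCORTICAL;
    * within-cortex events spanning both hemispheres with a
      cross-midline delay ordering → TRANSHEMISPHERIC;
    * within-cortex events with a mediolateral delay slope (regressed
      on distance from the midline) → MEDIO_TEMPORAL (outward) /
      TEMPORO_MEDIAL (inward);
    * everything else, and all static events → UNCLASSIFIED_STATIC.

    Directional calls require the delay ordering or slope to explain
    at least one frame period across the event (the rule margin).
    """
    if not atlas.hemisphere:
        raise ValueError("atlas lacks hemisphere information")
    mid = atlas.midline_col
    labels: list[PatternLabel] = []
    for ev in events:
        if ev.delay_map is None or ev.dynamic is None:
            raise ValueError("events must have features and dynamic flags")
        if not ev.dynamic:
            labels.append(PatternLabel.UNCLASSIFIED_STATIC)
            continue
        occ = _occupancy(ev, atlas)
        px = list(ev.delay_map)
        delays = np.array([ev.delay_map[p] for p in px])
        cols = np.array([p[1] for p in px], dtype=float)

        order = np.argsort(delays)
        k = max(1, int(round(quartile * len(px))))

        def tissue_of(indices) -> str | None:
            ts = []
            for i in indices:
                r, c = px[i]
                rid = int(atlas.labels[r, c])
                ts.append(atlas.tissue(rid) if rid else "background")
            return _majority_tissue(ts)

        start_t = tissue_of(order[:k])
        end_t = tissue_of(order[-k:])
        span_ok = delays[order[-k:]].mean() - delays[order[:k]].mean() >= dt

        if span_ok and start_t and end_t and start_t != end_t:
            pair = {start_t, end_t}
            if pair == {"cortex", "hippocampus"}:
                labels.append(
                    PatternLabel.CORTICO_HIPPOCAMPAL
                    if start_t == "cortex"
                    else PatternLabel.HIPPOCAMPO_CORTICAL
                )
                continue
            if pair == {"cortex", "subcortex"}:
                labels.append(PatternLabel.CORTICO_SUBCORTICAL)
                continue
        if occ["cortex"] >= 0.5:
            left = cols < mid
            right = cols > mid
            if left.mean() >= 0.2 and right.mean() >= 0.2:
                if abs(delays[left].mean() - delays[right].mean()) >= dt:
                    labels.append(PatternLabel.TRANSHEMISPHERIC)
                    continue
            # distance from midline, increasing = toward temporal cortex
            dist = np.abs(cols - mid)
            slope = _lsq_slope(dist, delays)
            if abs(slope) * np.ptp(dist) >= dt:
                labels.append(
                    PatternLabel.MEDIO_TEMPORAL if slope > 0 else PatternLabel.TEMPORO_MEDIAL
                )
                continue
        labels.append(PatternLabel.UNCLASSIFIED_STATIC)
    return labels


def pattern_frequencies(
    labels_per_scan: dict[str, list[PatternLabel]],
):
    """Per-scan pattern proportions, with and without the unclassified class.

    Returns a pandas DataFrame with one row per (scan, label):
    ``pct`` over all events and ``pct_excl_unclassified`` renormalised
    over the six travelling classes (NaN when a scan has no travelling
    events).  Scans with zero events yield flagged empty rows.
    """
    import pandas as pd

    rows = []
    for scan, labels in labels_per_scan.items():
        n = len(labels)
        n_travel = sum(1 for l in labels if l is not PatternLabel.UNCLASSIFIED_STATIC)
        for lab in PatternLabel:
            cnt = sum(1 for l in labels if l is lab)
            rows.append(
                {
                    "scan": scan,
                    "label": lab.value,
                    "count": cnt,
                    "pct": 100.0 * cnt / n if n else float("nan"),
                    "pct_excl_unclassified": (
                        100.0 * cnt / n_travel
                        if n_travel and lab is not PatternLabel.UNCLASSIFIED_STATIC
                        else (float("nan"))
                    ),
                    "empty_scan": n == 0,
                }
            )
    return pd.DataFrame(rows)
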