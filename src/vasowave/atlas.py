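"""Schematic bilateral ROI atlas for the −6 mm bregma coronal plane.

The atlas is deliberately geometric rather than anatomically registered:
only the topology matters for wave-pattern labelling — a cortical ribbon
at the top with its five ROIs ordered medial→temporal, hippocampal and
midbrain territories below it, and two hemispheres mirrored about the
midline column.

Region names follow the standard rat-atlas ROIs of this plane:
primary/secondary visual cortices, retrosplenial dysgranular cortex,
retrosplenial granular cortex parts A and B, the superficial superior
colliculus, plus hippocampus and dorsal/ventral midbrain territories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AcquisitionSpec

__all__ = ["RoiAtlas", "build_atlas", "REGION_NAMES", "CORTEX_NAMES"]

#: Medial→temporal order of the cortical ribbon ROIs.
CORTEX_NAMES = (
    "RetroGrCtx_B",
    "RetroGrCtx_A",
    "RetroDysCtx",
    "SecVisCtx",
    "PrimVisCtx",
)

#: All nine named regions and their coarse tissue class.
REGION_TISSUE = {
    "RetroGrCtx_B": "cortex",
    "RetroGrCtx_A": "cortex",
    "RetroDysCtx": "cortex",
    "SecVisCtx": "cortex",
    "PrimVisCtx": "cortex",
    "SuperiorColl": "subcortex",
    "Hippocampus": "hippocampus",
    "DorsalMidbrain": "subcortex",
    "VentralMidbrain": "subcortex",
}

REGION_NAMES = tuple(REGION_TISSUE)


@dataclass
class RoiAtlas:
    """Integer ROI label map plus id→name and id→hemisphere tables.

    Label 0 is background.  Bilateral regions carry two ids sharing the
    same name, one per hemisphere.
    """

    labels: np.ndarray
    names: dict[int, str]
    hemisphere: dict[int, str]
    _name_index: dict[tuple[str, str], int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be a 2-D integer map")
        present = set(np.unique(self.labels)) - {0}
        missing = set(self.names) - present
        if missing:
            raise ValueError(f"named ids absent from the label map: {sorted(missing)}")
        stray = present - set(self.names)
        if stray:
            raise ValueError(f"label map contains unnamed ids: {sorted(stray)}")
        for i in self.names:
            if self.hemisphere.get(i) not in ("left", "right"):
                raise ValueError(f"id {i} lacks a left/right hemisphere assignment")
        self._name_index = {
            (self.names[i], self.hemisphere[i]): i for i in self.names
        }

    # -- lookups ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def midline_col(self) -> float:
        """Column coordinate of the inter-hemispheric midline."""
        return (self.labels.shape[1] - 1) / 2.0

    def ids_for(self, name: str) -> list[int]:
        ids = [i for i, n in self.names.items() if n == name]
        if not ids:
            raise KeyError(f"unknown region name {name!r}")
        return sorted(ids)

    def id_of(self, name: str, hemi: str) -> int:
        try:
            return self._name_index[(name, hemi)]
        except KeyError:
            raise KeyError(f"no region {name!r} in hemisphere {hemi!r}") from None

    def mask(self, roi: int | str, hemi: str | None = None) -> np.ndarray:
        """Boolean mask of one ROI id, or of a named region (both sides)."""
        if isinstance(roi, str):
            ids = [self.id_of(roi, hemi)] if hemi else self.ids_for(roi)
        else:
            ids = [roi]
        return np.isin(self.labels, ids)

    def tissue(self, roi_id: int) -> str:
        return REGION_TISSUE[self.names[roi_id]]

    def tissue_mask(self, tissue: str) -> np.ndarray:
        ids = [i for i in self.names if self.tissue(i) == tissue]
        return np.isin(self.labels, ids)

    def all_ids(self) -> list[int]:
        return sorted(self.names)


def _band_cols(half_width: int, fractions: np.ndarray) -> list[tuple[int, int]]:
    """Split ``half_width`` columns into contiguous bands by fraction."""
    edges = np.round(np.cumsum(np.concatenate([[0.0], fractions])) * half_width)
    return [(int(edges[i]), int(edges[i + 1])) for i in range(len(fractions))]


def build_atlas(spec: AcquisitionSpec) -> RoiAtlas:
    """Build the schematic bilateral atlas on the grid of ``spec``.

    Raises a sizing error if the grid is too small (< 64 px a side) to
    place every region with a usable footprint (each ≥ 15 px).
    """
    h, w = spec.height, spec.width
    if h < 64 or w < 64:
        raise ValueError(f"grid {h}x{w} too small to place all ROIs (need >= 64x64)")

    labels = np.zeros((h, w), dtype=np.int32)
    names: dict[int, str] = {}
    hemisphere: dict[int, str] = {}

    def region_id(index: int, hemi: str) -> int:
        rid = 2 * index + (1 if hemi == "left" else 2)
        names[rid] = REGION_NAMES[index]
        hemisphere[rid] = hemi
        return rid

    half = w // 2
    odd = w % 2  # odd width: the centre column stays background
    # distance-from-midline coordinate per hemisphere, 0 at the midline edge
    rows = {
        "margin": (0, round(0.08 * h)),
        "cortex": (round(0.08 * h), round(0.30 * h)),
        "upper_sub": (round(0.30 * h), round(0.55 * h)),
        "dorsal_mb": (round(0.55 * h), round(0.75 * h)),
        "ventral_mb": (round(0.75 * h), round(0.95 * h)),
    }

    usable = round(0.95 * half)  # leave a lateral background margin
    cortex_fracs = np.array([0.14, 0.14, 0.20, 0.24, 0.28])
    cortex_bands = _band_cols(usable, cortex_fracs)

    def paint(r0: int, r1: int, d0: int, d1: int, index: int) -> None:
        """Fill rows [r0, r1) at midline distance [d0, d1) in both hemispheres."""
        for hemi in ("left", "right"):
            rid = region_id(index, hemi)
            if hemi == "left":
                c0, c1 = half - d1, half - d0
            else:
                c0, c1 = half + odd + d0, half + odd + d1
            labels[r0:r1, c0:c1] = rid

    r0, r1 = rows["cortex"]
    for k, (d0, d1) in enumerate(cortex_bands):
        paint(r0, r1, d0, d1, k)

    r0, r1 = rows["upper_sub"]
    paint(r0, r1, 0, round(0.30 * usable), REGION_NAMES.index("SuperiorColl"))
    paint(r0, r1, round(0.35 * usable), round(0.90 * usable),
          REGION_NAMES.index("Hippocampus"))

    r0, r1 = rows["dorsal_mb"]
    paint(r0, r1, 0, round(0.85 * usable), REGION_NAMES.index("DorsalMidbrain"))
    r0, r1 = rows["ventral_mb"]
    paint(r0, r1, 0, round(0.85 * usable), REGION_NAMES.index("VentralMidbrain"))

    atlas = RoiAtlas(labels, names, hemisphere)
    for rid in atlas.all_ids():
        n_px = int(np.count_nonzero(labels == rid))
        if n_px < 15:
            raise ValueError(
                f"grid {h}x{w} too small: region {atlas.names[rid]} "
                f"({atlas.hemisphere[rid]}) has only {n_px} px"
            )
    return atlas
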