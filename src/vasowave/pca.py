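"""Group-mean-covariance PCA: oscillatory haemodynamic modes.

Each acquisition is band-passed (0.0008–0.2 Hz), centred by its global
(all-pixel, all-frame) mean and scaled by its global standard deviation
— one scalar per acquisition, preserving the relative spatial amplitude
structure — then flattened to pixels × time.  The spatial (pixel ×
pixel) covariance matrices of all acquisitions in a group are averaged;
eigenvectors of the mean covariance, sorted by descending eigenvalue,
are the group's spatial modes.  Temporal signatures are obtained by
projecting each acquisition onto the modes, and their amplitude spectra
are averaged across acquisitions.

Retention rule: eigenvalues above ``eigenvalue_min`` (default 0.1),
capped at ``n_display`` (default 10) components.  Explained fractions
are per-component eigenvalue over the total eigenvalue sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BandSpec, Movie, WIDE_BAND
from .preproc import bandpass_movie
from .spectral import Spectrum, amplitude_spectrum

__all__ = [
    "PcaConfig",
    "PcaModes",
    "preprocess_for_pca",
    "group_mean_covariance",
    "eigenmodes",
    "project_and_spectra",
    "reconstruct",
]


@dataclass(frozen=True)
class PcaConfig:
    eigenvalue_min: float = 0.1
    n_display: int = 10
    band: BandSpec = WIDE_BAND

    def __post_init__(self) -> None:
        if self.eigenvalue_min < 0:
            raise ValueError("eigenvalue_min must be >= 0")
        if self.n_display < 1:
            raise ValueError("n_display must be >= 1")


@dataclass
class PcaModes:
    """Spatial/temporal/spectral signature of the retained components."""

    eigenvalues: np.ndarray  # all eigenvalues, descending
    maps: np.ndarray  # (n_retained, height, width), orthonormal
    explained: np.ndarray  # per-component fraction of total variance (all)
    image_shape: tuple[int, int]
    n_retained: int
    projections: list[np.ndarray] = field(default_factory=list)  # per acquisition (k, T)
    spectra: list[Spectrum] = field(default_factory=list)  # group-mean per component

    @property
    def cumulative_explained(self) -> np.ndarray:
        return np.cumsum(self.explained)

    def explained_at(self, k: int) -> float:
        """Cumulative explained-variance fraction of the first k components."""
        return float(self.cumulative_explained[min(k, len(self.explained)) - 1])

    def flat_maps(self) -> np.ndarray:
        return self.maps.reshape(self.n_retained, -1)


def preprocess_for_pca(
    movies: list[Movie], band: BandSpec = WIDE_BAND
) -> list[np.ndarray]:
    """Band-pass, globally centre/scale, and flatten each acquisition.

    Output arrays are (pixels × time) with global mean 0 and global sd 1.
    Scaling an input movie leaves the output unchanged.
    """
    if not movies:
        raise ValueError("no acquisitions given")
    shape = movies[0].shape[:2]
    out = []
    for m in movies:
        if m.shape[:2] != shape:
            raise ValueError(
                f"acquisition grids differ: {m.shape[:2]} vs {shape}"
            )
        scale = float(np.abs(m.data).max())
        x = bandpass_movie(m, band).data.astype(np.float64)
        x -= x.mean()
        sd = x.std()
        # guard against numerically-constant input (filter round-off only)
        if sd <= 1e-9 * max(scale, 1.0):
            raise ValueError("acquisition has zero variance after filtering")
        x /= sd
        out.append(x.reshape(-1, m.n_frames))
    return out


def group_mean_covariance(preprocessed: list[np.ndarray]) -> np.ndarray:
    """Mean over acquisitions of the spatial (pixel × pixel) covariance."""
    if not preprocessed:
        raise ValueError("no acquisitions given")
    cov = None
    for x in preprocessed:
        if x.shape[1] < 2:
            raise ValueError("need at least 2 frames per acquisition")
        xc = x - x.mean(axis=1, keepdims=True)
        c = (xc @ xc.T) / (x.shape[1] - 1)
        cov = c if cov is None else cov + c
    return cov / len(preprocessed)


def eigenmodes(
    cov: np.ndarray, config: PcaConfig = PcaConfig(), image_shape: tuple[int, int] | None = None
) -> PcaModes:
    """Eigen-decomposition of the group-mean covariance.

    Components with eigenvalues above ``eigenvalue_min`` are retained,
    capped at ``n_display``.  Each eigenvector is oriented so its
    maximum-absolute element is positive, and reshaped to the image
    grid when ``image_shape`` is given.
    """
    cov = np.asarray(cov, dtype=np.float64)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError(f"covariance must be square, got {cov.shape}")
    if not np.allclose(cov, cov.T, atol=1e-8 * max(1.0, float(np.abs(cov).max()))):
        raise ValueError("covariance matrix is not symmetric")
    n_px = cov.shape[0]
    if image_shape is None:
        image_shape = (1, n_px)
    if image_shape[0] * image_shape[1] != n_px:
        raise ValueError("image_shape inconsistent with covariance size")

    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.maximum(vals[order], 0.0)
    vecs = vecs[:, order]
    total = vals.sum()
    explained = vals / total if total > 0 else np.zeros_like(vals)

    n_retained = int(np.sum(vals > config.eigenvalue_min))
    n_retained = max(1, min(n_retained, config.n_display))
    maps = vecs[:, :n_retained].T.copy()
    for i in range(n_retained):
        j = int(np.argmax(np.abs(maps[i])))
        if maps[i, j] < 0:
            maps[i] *= -1.0
    return PcaModes(
        eigenvalues=vals,
        maps=maps.reshape(n_retained, *image_shape),
        explained=explained,
        image_shape=image_shape,
        n_retained=n_retained,
    )


def project_and_spectra(
    preprocessed: list[np.ndarray], modes: PcaModes, dt: float
) -> PcaModes:
    """Temporal projections per acquisition + group-mean amplitude spectra.

    ``projection_k(t) = eigenvector_k · frame_t``.  Spectra of each
    component's projection are averaged across acquisitions.
    """
    w = modes.flat_maps()
    projections = []
    per_comp_amp: list[list[np.ndarray]] = [[] for _ in range(modes.n_retained)]
    freqs = None
    for x in preprocessed:
        if x.shape[0] != w.shape[1]:
            raise ValueError("acquisition pixel count does not match the modes")
        proj = w @ x  # (k, T)
        projections.append(proj)
        for k in range(modes.n_retained):
            s = amplitude_spectrum(proj[k], dt)
            per_comp_amp[k].append(s.amplitude)
            freqs = s.freqs
    modes.projections = projections
    modes.spectra = [
        Spectrum(freqs, np.mean(amps, axis=0)) for amps in per_comp_amp
    ]
    return modes


def reconstruct(
    x: np.ndarray, modes: PcaModes, k: int
) -> tuple[np.ndarray, float]:
    """Rank-``k`` reconstruction of one preprocessed acquisition.

    Sums map_i × projection_i(t) for i ≤ k, reshaped to movie form.
    Returns the reconstruction and the residual variance fraction
    (relative to the per-pixel-centred input).
    """
    if k > modes.n_retained:
        raise ValueError(f"k={k} exceeds the {modes.n_retained} retained components")
    w = modes.flat_maps()[:k]  # (k, pixels)
    proj = w @ x
    recon = w.T @ proj  # (pixels, T)
    xc = x - x.mean(axis=1, keepdims=True)
    denom = float((xc**2).sum())
    resid = float(((x - recon) ** 2).sum()) / denom if denom > 0 else 0.0
    return recon.reshape(*modes.image_shape, x.shape[1]), resid
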