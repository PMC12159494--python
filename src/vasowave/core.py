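"""Core containers shared by every stage of the pipeline.

A CBV movie is a ``(height, width, n_frames)`` array of Power Doppler
intensity, which is directly proportional to cerebral blood volume.  The
acquisition grid is fixed by the imaging system: one pixel is 100 μm and
one frame is 0.4 s unless stated otherwise.

Coordinate convention used throughout the package: 0-based, row-major,
origin at the top-left of the image; "medial" means toward the midline
column of the atlas, "temporal" means away from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionSpec", "BandSpec", "Movie"]


@dataclass(frozen=True)
class AcquisitionSpec:
    """Geometry and timing of one acquisition.

    Parameters
    ----------
    height, width:
        Image size in pixels.
    n_frames:
        Number of frames in the movie.
    dt:
        Frame period in seconds (0.4 s for the fUS system emulated here).
    pixel_mm:
        Pixel pitch in millimetres (0.1 mm).
    """

    height: int
    width: int
    n_frames: int
    dt: float = 0.4
    pixel_mm: float = 0.1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.pixel_mm <= 0:
            raise ValueError(f"pixel_mm must be positive, got {self.pixel_mm}")
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")
        if self.height < 1 or self.width < 1:
            raise ValueError("height and width must be positive")

    @property
    def duration_s(self) -> float:
        """Total record length in seconds."""
        return self.n_frames * self.dt

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.dt

    @property
    def nyquist(self) -> float:
        return 0.5 / self.dt

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.height, self.width, self.n_frames)

    @classmethod
    def resting_default(cls, height: int = 128, width: int = 128) -> "AcquisitionSpec":
        """20-minute resting-state acquisition: 3000 frames at 0.4 s."""
        return cls(height=height, width=width, n_frames=3000)


@dataclass(frozen=True)
class BandSpec:
    """A temporal frequency band ``[low, high]`` in Hz.

    ``low`` may be 0 (pure low-pass).  ``high`` must not exceed the
    Nyquist frequency of the movie the band is applied to; that check is
    deferred to :func:`vasowave.preproc.bandpass_movie` because the band
    alone does not know the frame period.
    """

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.low) and np.isfinite(self.high)):
            raise ValueError("band edges must be finite")
        if self.low < 0:
            raise ValueError(f"band low must be >= 0, got {self.low}")
        if self.low >= self.high:
            raise ValueError(f"band low must be < high, got [{self.low}, {self.high}]")

    def validate_for(self, dt: float) -> None:
        nyq = 0.5 / dt
        if self.high > nyq + 1e-12:
            raise ValueError(
                f"band high {self.high} Hz exceeds Nyquist {nyq} Hz for dt={dt}"
            )


#: Wide resting-state band used before functional-connectivity and PCA stages.
WIDE_BAND = BandSpec(0.0008, 0.2)
#: Vasomotion band: the frequency range of the ~0.1 Hz oscillations.
WAVE_BAND = BandSpec(0.08, 0.15)


@dataclass
class Movie:
    """A CBV movie: nonnegative intensity on a ``(row, col, frame)`` grid."""

    data: np.ndarray
    spec: AcquisitionSpec = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"movie data must be 3-D, got shape {self.data.shape}")
        if self.data.shape != self.spec.shape:
            raise ValueError(
                f"movie shape {self.data.shape} does not match spec {self.spec.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "Movie":
        return Movie(self.data.copy(), self.spec)

    def times(self) -> np.ndarray:
        """Frame timestamps in seconds."""
        return np.arange(self.n_frames) * self.spec.dt
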