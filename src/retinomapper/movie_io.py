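"""Movie stacks: TIFF + JSON sidecar I/O and spatiotemporal binning.

Pixel convention: origin top-left, row-major, y increasing downward.
Raw movies hold 12-bit data in a 16-bit container; binning SUMS 4x2x2
(t, y, x) blocks, so a full-scale 12-bit movie bins to 16*4095 = 65520,
which is why the binned container is 16-bit.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .stimulus_model import SCHEMA_VERSION, ScreenGeometry, StimulusSpec

__all__ = ["RawMovie", "BinnedMovie", "read_movie", "write_movie", "bin_movie",
           "MovieFormatError"]

logger = logging.getLogger(__name__)

MAX_12BIT = 4095
BIN_T, BIN_Y, BIN_X = 4, 2, 2


class MovieFormatError(ValueError):
    """Raised for malformed movie files or sidecars."""


@dataclass
class RawMovie:
    """Acquired image time series, shape (H, W, T), 12-bit values."""

    data: np.ndarray
    frame_rate_hz: float = 30.0
    stimulus: StimulusSpec | None = None
    geometry: ScreenGeometry | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise MovieFormatError(f"movie data must be HxWxT, got {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise MovieFormatError("movie data must be an integer dtype")
        if self.data.min() < 0 or self.data.max() > MAX_12BIT:
            raise MovieFormatError(
                f"12-bit violation: values outside [0, {MAX_12BIT}] "
                f"(found min={self.data.min()}, max={self.data.max()})"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]


@dataclass
class BinnedMovie:
    """Movie after 4x (temporal) and 2x2 (spatial) sum-binning."""

    data: np.ndarray
    frame_rate_hz: float = 7.5
    bin_factors: tuple[int, int, int] = (BIN_T, BIN_Y, BIN_X)
    stimulus: StimulusSpec | None = None
    geometry: ScreenGeometry | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise MovieFormatError(f"movie data must be HxWxT, got {self.data.shape}")
        if self.data.min() < 0 or self.data.max() > np.iinfo(np.uint16).max:
            raise MovieFormatError("binned values outside 16-bit range")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_movie(movie: RawMovie | BinnedMovie, path: str | Path) -> None:
    """Write a movie as a multi-page 16-bit TIFF plus JSON sidecar."""
    path = Path(path)
    pages = np.moveaxis(movie.data.astype(np.uint16), 2, 0)  # T first for TIFF pages
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "kind": "binned" if isinstance(movie, BinnedMovie) else "raw",
        "frame_rate_hz": movie.frame_rate_hz,
        "n_frames": movie.n_frames,
        "height": movie.data.shape[0],
        "width": movie.data.shape[1],
        "stimulus": movie.stimulus.to_dict() if movie.stimulus else None,
        "geometry": movie.geometry.to_dict() if movie.geometry else None,
        "meta": movie.meta,
    }
    if isinstance(movie, BinnedMovie):
        sidecar["bin_factors"] = list(movie.bin_factors)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_movie(path: str | Path) -> RawMovie | BinnedMovie:
    """Read a TIFF movie and its sidecar; validates the 12-bit contract for raw."""
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise MovieFormatError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    data = np.moveaxis(pages, 0, 2)
    if data.shape[2] != sidecar["n_frames"]:
        raise MovieFormatError(
            f"sidecar frame count {sidecar['n_frames']} != TIFF page count "
            f"{data.shape[2]}"
        )
    stimulus = (StimulusSpec.from_dict(sidecar["stimulus"])
                if sidecar.get("stimulus") else None)
    geometry = (ScreenGeometry.from_dict(sidecar["geometry"])
                if sidecar.get("geometry") else None)
    common = dict(frame_rate_hz=sidecar["frame_rate_hz"], stimulus=stimulus,
                  geometry=geometry, meta=sidecar.get("meta", {}))
    if sidecar.get("kind") == "binned":
        return BinnedMovie(data=data,
                           bin_factors=tuple(sidecar.get("bin_factors", (4, 2, 2))),
                           **common)
    return RawMovie(data=data, **common)


def bin_movie(raw: RawMovie) -> BinnedMovie:
    """Sum-bin 4x temporally and 2x2 spatially.

    Output values are exact block sums (never clipped): 16 samples of at
    most 4095 sum to at most 65520, inside the 16-bit range.  Odd spatial
    dimensions are rejected; a temporal remainder is dropped with a warning.
    """
    h, w, t = raw.data.shape
    if h % BIN_Y or w % BIN_X:
        raise MovieFormatError(f"spatial dims must be even for 2x2 binning, got {h}x{w}")
    t_used = (t // BIN_T) * BIN_T
    if t_used == 0:
        raise MovieFormatError(f"movie too short to bin: {t} frames < {BIN_T}")
    if t_used != t:
        warnings.warn(f"dropping {t - t_used} trailing frames not filling a "
                      f"temporal bin of {BIN_T}", stacklevel=2)
    d = raw.data[:, :, :t_used].astype(np.uint32)
    d = d.reshape(h // BIN_Y, BIN_Y, w // BIN_X, BIN_X, t_used // BIN_T, BIN_T)
    summed = d.sum(axis=(1, 3, 5))
    assert summed.max(initial=0) <= np.iinfo(np.uint16).max  # 16*4095 = 65520
    return BinnedMovie(
        data=summed.astype(np.uint16),
        frame_rate_hz=raw.frame_rate_hz / BIN_T,
        bin_factors=(BIN_T, BIN_Y, BIN_X),
        stimulus=raw.stimulus,
        geometry=raw.geometry,
        meta=dict(raw.meta),
    )
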