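"""Shared containers and small utilities used across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Compartment labels used throughout the pipeline.
COMPARTMENTS = ("cytoplasm", "nucleus", "trans-nuclear")


@dataclass
class ImageStack:
    """Time-ordered stack of 2D fluorescence frames.

    Attributes
    ----------
    frames : ndarray, shape (T, H, W)
        Pixel intensities in camera counts (float while synthetic, cast to
        uint16 on disk).
    pixel_size_nm : float
        Lateral pixel size, nm per pixel.
    frame_interval_ms : float
        Time between frame starts, ms.
    channel : str
        Detection channel label, e.g. ``"green"`` or ``"red"``.
    t_start_ms : float
        Acquisition start time relative to illumination onset, ms.
    """

    frames: np.ndarray
    pixel_size_nm: float = 80.0
    frame_interval_ms: float = 5.0
    channel: str = "green"
    t_start_ms: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.pixel_size_nm <= 0 or self.frame_interval_ms <= 0:
            raise ValueError("pixel size and frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def times_ms(self) -> np.ndarray:
        """Frame acquisition times (ms) relative to illumination onset."""
        return self.t_start_ms + np.arange(self.n_frames) * self.frame_interval_ms

    def save(self, path) -> None:
        """Write as multi-page 16-bit TIFF (values clipped to uint16)."""
        import tifffile

        data = np.clip(np.rint(self.frames), 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, data, photometric="minisblack", metadata={
            "pixel_size_nm": self.pixel_size_nm,
            "frame_interval_ms": self.frame_interval_ms,
            "channel": self.channel,
        })

    @classmethod
    def load(cls, path, pixel_size_nm: float = 80.0,
             frame_interval_ms: float = 5.0, channel: str = "green") -> "ImageStack":
        import tifffile

        return cls(tifffile.imread(path).astype(float), pixel_size_nm,
                   frame_interval_ms, channel)


def check_positive(**kwargs) -> None:
    """Raise ValueError when any named value is not strictly positive."""
    for name, value in kwargs.items():
        if not np.all(np.asarray(value, dtype=float) > 0):
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


#: IUPAC nucleotide codes mapped to the set of bases they match.
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def iupac_regex(pattern: str) -> str:
    """Translate an IUPAC nucleotide pattern into a plain regex."""
    pattern = pattern.upper()
    parts = []
    for c in pattern:
        if c not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC symbol {c!r} in pattern {pattern!r}")
        bases = IUPAC_CODES[c]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


def rng_from_seed(seed) -> np.random.Generator:
    """A Generator from an int seed, an existing Generator, or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
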