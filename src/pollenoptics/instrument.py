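"""Data model of a four-channel elastic light-scattering particle counter.

The instrument is an airflow cytometer: single particles cross a laser
beam and the light each one scatters is recorded by four photodiodes at
fixed scattering angles (15°, 60°, 125° and 160°).  Every 10-second
frame, each channel reports a histogram of particle counts over 19
scattered-intensity bins.

The near-forward channel (channel 1) is essentially insensitive to the
refractive index of irregular particles, so its intensity maps to an
optical diameter through a power law ``F = a · d**b``; its 19 intensity
bins double as size bins spanning 5–100 µm.  The three side/back
channels ("speciation channels") respond to shape, surface texture and
absorbance and feed the optical-signature stage.

The true bin placement and calibration constants of any particular
instrument are proprietary; the default here uses geometrically spaced
bins and a quadratic (geometric-optics) power law, both overridable
through :class:`InstrumentConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

N_CHANNELS = 4
N_BINS = 19
SCATTERING_ANGLES = (15.0, 60.0, 125.0, 160.0)


@dataclass(frozen=True)
class PowerLawCalibration:
    """Power-law link ``F = scale · d**exponent`` between scattered
    intensity ``F`` (arbitrary units) and optical diameter ``d`` (µm).

    ``exponent > 0`` so the map is strictly increasing and invertible.
    The default exponent 2 is the geometric-optics scaling of the
    scattering cross-section with particle size.
    """

    scale: float = 1.0
    exponent: float = 2.0

    def __post_init__(self) -> None:
        if not (self.scale > 0 and np.isfinite(self.scale)):
            raise ValueError(f"calibration scale must be positive, got {self.scale}")
        if not (self.exponent > 0 and np.isfinite(self.exponent)):
            raise ValueError(f"calibration exponent must be positive, got {self.exponent}")

    def intensity(self, diameter):
        """Scattered intensity for a diameter in µm (scalar or array)."""
        d = np.asarray(diameter, dtype=float)
        if np.any(d <= 0):
            raise ValueError("diameter must be positive")
        out = self.scale * d**self.exponent
        return float(out) if out.ndim == 0 else out

    def diameter(self, intensity):
        """Optical diameter in µm for a scattered intensity (scalar or array)."""
        f = np.asarray(intensity, dtype=float)
        if np.any(f <= 0):
            raise ValueError("intensity must be positive")
        out = (f / self.scale) ** (1.0 / self.exponent)
        return float(out) if out.ndim == 0 else out


def intensity_to_diameter(intensity, calibration: PowerLawCalibration):
    """Invert the sizing power law: ``d = (F / a)**(1/b)``.

    Raises ``ValueError`` for non-positive intensities.
    """
    return calibration.diameter(intensity)


@dataclass(frozen=True)
class InstrumentConfig:
    """Static description of one instrument: channels, bins, calibration.

    ``size_range`` is the (d_min, d_max) sizing span in µm of channel 1;
    the channel-1 intensity-bin edges are the images of geometrically
    spaced diameters under the calibration, so the intensity range maps
    exactly onto the size range.  Channels 2–4 reuse the same intensity
    edge layout.  ``flow_rate`` (L/min) is carried as metadata only.
    """

    n_bins: int = N_BINS
    size_range: tuple[float, float] = (5.0, 100.0)
    scattering_angles: tuple[float, float, float, float] = SCATTERING_ANGLES
    frame_period: float = 10.0
    flow_rate: float = 10.0
    calibration: PowerLawCalibration = field(default_factory=PowerLawCalibration)

    def __post_init__(self) -> None:
        if self.n_bins != N_BINS:
            raise ValueError(f"the instrument has {N_BINS} intensity bins, got {self.n_bins}")
        if tuple(self.scattering_angles) != SCATTERING_ANGLES:
            raise ValueError(f"scattering angles are fixed to {SCATTERING_ANGLES}")
        lo, hi = self.size_range
        if not (0 < lo < hi):
            raise ValueError(f"invalid size range {self.size_range}")
        if self.frame_period <= 0:
            raise ValueError("frame_period must be positive")

    @property
    def diameter_edges(self) -> np.ndarray:
        """Geometrically spaced diameter-bin edges (length n_bins+1, µm)."""
        lo, hi = self.size_range
        return np.geomspace(lo, hi, self.n_bins + 1)

    @property
    def intensity_edges(self) -> np.ndarray:
        """Channel-1 intensity-bin edges: images of the diameter edges."""
        return self.calibration.intensity(self.diameter_edges)

    @property
    def bin_edges(self) -> np.ndarray:
        """Per-channel intensity edges, shape (4, n_bins+1); all channels
        share the channel-1 layout."""
        return np.tile(self.intensity_edges, (N_CHANNELS, 1))

    @classmethod
    def from_dict(cls, d: dict) -> "InstrumentConfig":
        inst = d.get("instrument", d)
        calib = inst.get("calibration", {})
        kwargs: dict = {}
        if "n_bins" in inst:
            kwargs["n_bins"] = int(inst["n_bins"])
        if "size_range" in inst:
            kwargs["size_range"] = tuple(float(x) for x in inst["size_range"])
        if "angles" in inst:
            kwargs["scattering_angles"] = tuple(float(x) for x in inst["angles"])
        if calib:
            kwargs["calibration"] = PowerLawCalibration(
                scale=float(calib.get("a", 1.0)), exponent=float(calib.get("b", 2.0))
            )
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "InstrumentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def make_bin_edges(cfg: InstrumentConfig) -> np.ndarray:
    """Per-channel intensity-bin edges, shape (4, n_bins+1)."""
    return cfg.bin_edges


def bin_intensities(values, edges) -> tuple[np.ndarray, int, int]:
    """Histogram intensities into half-open bins ``[e_i, e_{i+1})``.

    The last bin is closed at the top edge.  Returns ``(counts,
    n_underflow, n_overflow)``; out-of-range values are tallied, never
    silently dropped.
    """
    v = np.asarray(values, dtype=float)
    edges = np.asarray(edges, dtype=float)
    n_bins = len(edges) - 1
    idx = np.searchsorted(edges, v, side="right") - 1
    idx[v == edges[-1]] = n_bins - 1  # top edge belongs to the last bin
    under = int(np.count_nonzero(v < edges[0]))
    over = int(np.count_nonzero(v > edges[-1]))
    ok = (idx >= 0) & (idx < n_bins)
    counts = np.bincount(idx[ok], minlength=n_bins).astype(np.int64)
    return counts, under, over


@dataclass(frozen=True)
class Frame:
    """One acquisition frame: a timestamp plus 4 × 19 particle counts
    (channel-major)."""

    timestamp: float
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (N_CHANNELS, N_BINS):
            raise ValueError(f"counts must have shape {(N_CHANNELS, N_BINS)}, got {c.shape}")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(c.dtype, np.integer):
            if not np.allclose(c, np.round(c)):
                raise ValueError("counts must be integers")
            c = np.round(c).astype(np.int64)
        object.__setattr__(self, "counts", np.ascontiguousarray(c, dtype=np.int64))

    def flatten(self) -> np.ndarray:
        """Channel-major flat vector of length 76."""
        return self.counts.reshape(-1)

    def channel_histogram(self, channel: int, cfg: InstrumentConfig) -> "ChannelHistogram":
        if channel not in (1, 2, 3, 4):
            raise ValueError("channel must be in 1..4")
        return ChannelHistogram(
            channel=channel,
            bin_edges=cfg.bin_edges[channel - 1],
            counts=self.counts[channel - 1],
        )

    def __add__(self, other: "Frame") -> "Frame":
        return Frame(timestamp=self.timestamp, counts=self.counts + other.counts)

    def __eq__(self, other) -> bool:  # dataclass eq fails on arrays
        if not isinstance(other, Frame):
            return NotImplemented
        return self.timestamp == other.timestamp and np.array_equal(self.counts, other.counts)


@dataclass(frozen=True)
class ChannelHistogram:
    """Counts of one channel over its 19 intensity bins."""

    channel: int
    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.bin_edges, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        if len(e) != len(c) + 1:
            raise ValueError("bin_edges must be one longer than counts")
        if np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "bin_edges", e)
        object.__setattr__(self, "counts", c)

    @property
    def bin_centers(self) -> np.ndarray:
        """Geometric bin centres."""
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    def total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class SizeDistribution:
    """Particle counts over diameter bins (µm), in number or volume form.

    The volume form weights each bin by the volume ``(π/6)·d_c³`` of a
    sphere at the bin's geometric-centre diameter ``d_c``; it emphasises
    large particles and aggregates.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    mode: str = "number"

    def __post_init__(self) -> None:
        e = np.asarray(self.bin_edges, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        if len(e) != len(c) + 1:
            raise ValueError("bin_edges must be one longer than counts")
        if np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.mode not in ("number", "volume"):
            raise ValueError("mode must be 'number' or 'volume'")
        object.__setattr__(self, "bin_edges", e)
        object.__setattr__(self, "counts", c)

    @property
    def bin_centers(self) -> np.ndarray:
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])

    def total(self) -> float:
        return float(self.counts.sum())

    def to_volume(self) -> "SizeDistribution":
        if self.mode == "volume":
            return self
        w = (np.pi / 6.0) * self.bin_centers**3
        return SizeDistribution(self.bin_edges, self.counts * w, mode="volume")

    def to_number(self) -> "SizeDistribution":
        if self.mode == "number":
            return self
        w = (np.pi / 6.0) * self.bin_centers**3
        return SizeDistribution(self.bin_edges, self.counts / w, mode="number")

    def modal_bin(self) -> int:
        return int(np.argmax(self.counts))

    def modal_diameter(self) -> float:
        """Geometric-centre diameter of the fullest bin."""
        return float(self.bin_centers[self.modal_bin()])

    def __add__(self, other: "SizeDistribution") -> "SizeDistribution":
        if self.mode != other.mode or not np.allclose(self.bin_edges, other.bin_edges):
            raise ValueError("can only add distributions on the same bins and mode")
        return SizeDistribution(self.bin_edges, self.counts + other.counts, self.mode)


def frame_to_size_distribution(frame: Frame, cfg: InstrumentConfig) -> SizeDistribution:
    """Map channel-1 counts bin-for-bin onto diameter bins (number mode).

    The mapping is bijective because the channel-1 intensity edges are
    the calibrated images of the diameter edges, so the total count is
    conserved exactly.
    """
    return SizeDistribution(cfg.diameter_edges, frame.counts[0].astype(float), mode="number")


def sum_frames(frames: Sequence[Frame]) -> Frame:
    """Element-wise sum of frames (timestamp taken from the first)."""
    if len(frames) == 0:
        raise ValueError("cannot sum zero frames")
    total = np.zeros((N_CHANNELS, N_BINS), dtype=np.int64)
    for f in frames:
        total += f.counts
    return Frame(timestamp=frames[0].timestamp, counts=total)
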