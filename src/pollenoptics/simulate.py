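"""Synthetic measurement sessions for the four-channel pollen counter.

Laboratory sessions release one aerosol type (a pollen taxon, droplets,
carbonaceous soot, or mineral dust) in front of the inlet and record
10-s frames for 30–50 minutes.  This module emulates that protocol:

* grain diameters are lognormal around a species' median diameter
  (dry pollen is near-monodisperse, default geometric SD 1.08);
* the *measured* channel-1 intensity is the power-law image of the
  diameter times multiplicative lognormal sizing noise (default σ_log
  0.20, i.e. ≈10 % optical-diameter uncertainty at exponent 2 — optical
  sizing of irregular particles is orientation- and shape-dependent, so
  the per-species intensity histograms are several bins wide even for
  near-monodisperse grains);
* channels 2–4 see the measured channel-1 intensity scaled by a
  species/aerosol-dependent gain triple (g2, g3, g4) times their own
  multiplicative lognormal noise (default σ_log 0.15) — optically
  transparent droplets scatter strongly forward and weakly at side and
  back angles, strongly absorbing carbonaceous particles are dim on all
  speciation channels, minerals and semi-transparent pollen sit between;
* per-frame particle counts are Poisson;
* contamination adds ambient particles, pollen aggregates (diameter
  multiplied by a fixed factor) and debris, and a configurable fraction
  of frames are grossly contaminated "outlier" frames.

Every session carries its ground truth (per-frame inlier flags and true
particle diameters) so downstream stages can be tested against it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .instrument import (
    Frame,
    InstrumentConfig,
    N_BINS,
    N_CHANNELS,
    bin_intensities,
)

#: default multiplicative speciation-channel noise (sigma of log intensity)
DEFAULT_NOISE_SIGMA = 0.15

#: default channel-1 optical sizing dispersion (sigma of log intensity);
#: 0.20 at calibration exponent 2 is a ~10 % optical-diameter uncertainty
DEFAULT_SIZING_SIGMA = 0.20

#: gains given to ambient-air background particles (dull mineral-like)
_AMBIENT_GAINS = (0.40, 0.20, 0.14)


def as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass(frozen=True)
class SpeciesProfile:
    """Synthetic ground truth for one aerosol class.

    ``median_diameter`` (µm) and ``gsd`` (geometric standard deviation)
    parameterise the lognormal grain-size law; ``gains`` are the
    relative channel-2..4 intensity gains; ``mean_rate`` is the expected
    particle count per 10-s frame.
    """

    name: str
    median_diameter: float
    gsd: float = 1.08
    gains: tuple[float, float, float] = (0.6, 0.3, 0.2)
    aerosol_class: str = "pollen"
    mean_rate: float = 10.0

    def __post_init__(self) -> None:
        if not (5.0 <= self.median_diameter <= 100.0):
            raise ValueError(f"median_diameter must lie in the 5–100 µm sizing range, got {self.median_diameter}")
        if self.gsd < 1.0:
            raise ValueError("gsd must be >= 1")
        if len(self.gains) != 3 or any(g <= 0 for g in self.gains):
            raise ValueError("gains must be three positive numbers")
        if self.aerosol_class not in ("pollen", "droplet", "carbonaceous", "mineral"):
            raise ValueError(f"unknown aerosol class {self.aerosol_class!r}")
        if self.mean_rate < 0:
            raise ValueError("mean_rate must be non-negative")


@dataclass(frozen=True)
class ContaminationModel:
    """Contamination mixed into clean sessions.

    ``ambient_fraction`` of frames also carry ambient-air background
    particles around ``ambient_diameter``; each grain is an aggregate
    (diameter × ``aggregate_factor``) with probability
    ``aggregate_fraction`` or storage debris with probability
    ``debris_fraction``; ``outlier_frame_fraction`` of frames are
    grossly contaminated (aggregates and debris dominate) and are
    flagged as ground-truth outliers.
    """

    ambient_fraction: float = 0.30
    ambient_diameter: float = 7.0
    aggregate_fraction: float = 0.08
    aggregate_factor: float = 1.6
    debris_fraction: float = 0.02
    outlier_frame_fraction: float = 0.10

    def __post_init__(self) -> None:
        for name in ("ambient_fraction", "aggregate_fraction", "debris_fraction", "outlier_frame_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.aggregate_factor <= 1.0:
            raise ValueError("aggregate_factor must be > 1")
        if self.ambient_diameter <= 0:
            raise ValueError("ambient_diameter must be positive")

    @classmethod
    def none(cls) -> "ContaminationModel":
        """A perfectly clean session."""
        return cls(ambient_fraction=0.0, aggregate_fraction=0.0, debris_fraction=0.0, outlier_frame_fraction=0.0)

    def corrupted(self) -> "ContaminationModel":
        """The mixture used for grossly contaminated outlier frames."""
        return replace(
            self,
            ambient_fraction=1.0,
            aggregate_fraction=max(self.aggregate_fraction, 0.5),
            debris_fraction=max(self.debris_fraction, 0.3),
        )


@dataclass
class Session:
    """One simulated measurement session of a single aerosol class.

    ``inlier`` flags (True = clean frame) and ``true_diameters`` are
    ground truth for test oracles only; the analysis pipeline never
    reads them.
    """

    species: str
    frames: list[Frame]
    inlier: np.ndarray
    true_diameters: list[np.ndarray]

    def __post_init__(self) -> None:
        if not (len(self.frames) == len(self.inlier) == len(self.true_diameters)):
            raise ValueError("ground truth must align 1:1 with frames")


# ---------------------------------------------------------------------------
# Species registry
# ---------------------------------------------------------------------------

# (median diameter µm, (g2, g3, g4), mean particles per frame)
# Diameters are the supplier values for each taxon (midpoint of a range);
# per-frame rates are total grains / number of frames from the same
# laboratory sessions.  Gain triples are fixed, documented stand-ins
# encoding the qualitative optics: pollen semi-transparent, each taxon
# with its own triple (hazel and oak deliberately close — they are known
# to be optically confusable).
_POLLEN_TABLE: dict[str, tuple[float, tuple[float, float, float], float]] = {
    "Alnus glutinosa": (28.0, (0.62, 0.30, 0.21), 12.0),
    "Anthoxanthum odoratum": (39.0, (0.48, 0.36, 0.27), 40.9),
    "Ambrosia artemisiifolia": (19.5, (0.70, 0.24, 0.16), 7.5),
    "Betula pendula": (28.0, (0.58, 0.27, 0.23), 8.6),
    "Corylus avellana": (29.0, (0.55, 0.33, 0.19), 5.8),
    "Cupressus sempervirens": (30.0, (0.80, 0.42, 0.30), 20.6),
    "Festuca pratensis": (45.0, (0.44, 0.22, 0.33), 26.6),
    "Fraxinus excelsior": (29.0, (0.66, 0.45, 0.28), 12.4),
    "Olea euopaea": (25.0, (0.75, 0.35, 0.25), 5.4),
    "Parietaria officinalis": (14.0, (0.50, 0.40, 0.30), 17.2),
    "Platanus acerifolia": (22.0, (0.85, 0.28, 0.35), 3.2),
    "Quercus robur": (36.0, (0.54, 0.32, 0.20), 17.5),
}

# Non-pollen aerosol classes: transparent droplets (bright forward, very
# dim side/back), strongly absorbing carbonaceous particles (dim on all
# speciation channels), and two mineral dusts with intermediate,
# class-specific gains.
_NON_POLLEN_TABLE: dict[str, tuple[float, float, tuple[float, float, float], str, float]] = {
    # name: (median d, gsd, gains, class, rate)
    # diameters/low gains keep every class's speciation-channel modes
    # inside the shared intensity range (an instrument-design constraint:
    # a channel that cannot see its target particles is mis-specified)
    "droplet": (22.0, 1.30, (1.50, 0.14, 0.12), "droplet", 25.0),
    "carbonaceous": (16.0, 1.40, (0.30, 0.24, 0.20), "carbonaceous", 25.0),
    "saharan_dust": (18.0, 1.50, (0.35, 0.20, 0.16), "mineral", 20.0),
    "concrete_dust": (40.0, 1.35, (0.90, 0.55, 0.45), "mineral", 15.0),
}

POLLEN_SPECIES = tuple(_POLLEN_TABLE)
NON_POLLEN_CLASSES = tuple(_NON_POLLEN_TABLE)


def builtin_profiles() -> dict[str, SpeciesProfile]:
    """Registry of the 12 study pollen taxa plus 4 non-pollen classes."""
    registry: dict[str, SpeciesProfile] = {}
    for name, (d, gains, rate) in _POLLEN_TABLE.items():
        registry[name] = SpeciesProfile(
            name=name, median_diameter=d, gains=gains, aerosol_class="pollen", mean_rate=rate
        )
    for name, (d, gsd, gains, cls, rate) in _NON_POLLEN_TABLE.items():
        registry[name] = SpeciesProfile(
            name=name, median_diameter=d, gsd=gsd, gains=gains, aerosol_class=cls, mean_rate=rate
        )
    return registry


# ---------------------------------------------------------------------------
# Frame / session simulation
# ---------------------------------------------------------------------------


def _draw_particles(
    profile: SpeciesProfile,
    contamination: ContaminationModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Diameters (µm) and per-particle gain triples for one frame."""
    n = rng.poisson(profile.mean_rate)
    d = rng.lognormal(np.log(profile.median_diameter), np.log(profile.gsd), size=n)
    gains = np.tile(profile.gains, (n, 1))

    if contamination.aggregate_fraction > 0 and n:
        agg = rng.random(n) < contamination.aggregate_fraction
        d[agg] *= contamination.aggregate_factor
    if contamination.debris_fraction > 0 and n:
        deb = rng.random(n) < contamination.debris_fraction
        m = int(deb.sum())
        if m:
            d[deb] = np.exp(rng.uniform(np.log(5.0), np.log(60.0), size=m))
            gains[deb] = rng.uniform(0.1, 0.9, size=(m, 3))
    if contamination.ambient_fraction > 0 and rng.random() < contamination.ambient_fraction:
        m = rng.poisson(0.3 * profile.mean_rate + 1.0)
        if m:
            da = rng.lognormal(np.log(contamination.ambient_diameter), np.log(1.4), size=m)
            d = np.concatenate([d, da])
            gains = np.vstack([gains, np.tile(_AMBIENT_GAINS, (m, 1))])
    return d, gains


def _particles_to_frame(
    diameters: np.ndarray,
    gains: np.ndarray,
    cfg: InstrumentConfig,
    rng: np.random.Generator,
    noise_sigma: float,
    sizing_sigma: float,
    timestamp: float,
) -> Frame:
    counts = np.zeros((N_CHANNELS, N_BINS), dtype=np.int64)
    edges = cfg.bin_edges
    if len(diameters):
        f1 = np.atleast_1d(cfg.calibration.intensity(np.asarray(diameters, dtype=float)))
        if sizing_sigma > 0:
            f1 = f1 * np.exp(rng.normal(0.0, sizing_sigma, size=len(f1)))
        counts[0], _, _ = bin_intensities(f1, edges[0])
        for c in range(1, N_CHANNELS):
            noise = (
                np.exp(rng.normal(0.0, noise_sigma, size=len(f1))) if noise_sigma > 0 else 1.0
            )
            fc = gains[:, c - 1] * f1 * noise
            counts[c], _, _ = bin_intensities(fc, edges[c])
    return Frame(timestamp=timestamp, counts=counts)


def simulate_frame(
    profile: SpeciesProfile,
    contamination: ContaminationModel,
    cfg: InstrumentConfig,
    rng,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    sizing_sigma: float = DEFAULT_SIZING_SIGMA,
    timestamp: float = 0.0,
) -> Frame:
    """Simulate one 10-s frame of a single-aerosol release."""
    frame, _ = simulate_frame_with_truth(
        profile, contamination, cfg, rng, noise_sigma, sizing_sigma, timestamp
    )
    return frame


def simulate_frame_with_truth(
    profile: SpeciesProfile,
    contamination: ContaminationModel,
    cfg: InstrumentConfig,
    rng,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    sizing_sigma: float = DEFAULT_SIZING_SIGMA,
    timestamp: float = 0.0,
) -> tuple[Frame, np.ndarray]:
    """As :func:`simulate_frame`, also returning the true diameters."""
    rng = as_rng(rng)
    d, gains = _draw_particles(profile, contamination, rng)
    frame = _particles_to_frame(d, gains, cfg, rng, noise_sigma, sizing_sigma, timestamp)
    return frame, d


def simulate_session(
    profile: SpeciesProfile,
    contamination: ContaminationModel,
    n_frames: int,
    cfg: InstrumentConfig,
    rng,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    sizing_sigma: float = DEFAULT_SIZING_SIGMA,
) -> Session:
    """Simulate an ordered session of ``n_frames`` 10-s frames.

    With probability ``outlier_frame_fraction`` a frame is drawn from
    the grossly contaminated mixture and flagged as a ground-truth
    outlier.  Fully reproducible under a fixed seed.
    """
    rng = as_rng(rng)
    frames: list[Frame] = []
    inlier = np.ones(n_frames, dtype=bool)
    diameters: list[np.ndarray] = []
    corrupted = contamination.corrupted()
    for i in range(n_frames):
        is_outlier = rng.random() < contamination.outlier_frame_fraction
        mix = corrupted if is_outlier else contamination
        frame, d = simulate_frame_with_truth(
            profile, mix, cfg, rng, noise_sigma, sizing_sigma, timestamp=i * cfg.frame_period
        )
        frames.append(frame)
        inlier[i] = not is_outlier
        diameters.append(d)
    return Session(species=profile.name, frames=frames, inlier=inlier, true_diameters=diameters)


def simulate_sessions(
    species: Sequence[str],
    contamination: ContaminationModel,
    cfg: InstrumentConfig,
    rng,
    n_frames_range: tuple[int, int] = (180, 300),
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    sizing_sigma: float = DEFAULT_SIZING_SIGMA,
    profiles: Mapping[str, SpeciesProfile] | None = None,
) -> dict[str, Session]:
    """One session per listed species, with session lengths drawn from
    ``n_frames_range`` (the 30–50 min laboratory protocol)."""
    rng = as_rng(rng)
    registry = builtin_profiles() if profiles is None else dict(profiles)
    lo, hi = n_frames_range
    if not (0 < lo <= hi):
        raise ValueError(f"invalid n_frames_range {n_frames_range}")
    sessions: dict[str, Session] = {}
    for name in species:
        if name not in registry:
            raise KeyError(f"unknown species profile {name!r}")
        n_frames = int(rng.integers(lo, hi + 1))
        sessions[name] = simulate_session(
            registry[name], contamination, n_frames, cfg, rng, noise_sigma, sizing_sigma
        )
    return sessions
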