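"""Speciation indices and six-element optical signatures.

For particles counted with intensity ``F1`` on the sizing channel, the
speciation index of channel c asks: what intensity ``F_c`` on that
channel corresponds to the *same number concentration*?  Formally the
channel-c intensity distribution is inverted at the channel-1 level,

    dN/dF1 (F1) = dN/dFc (Fc),      S_c = F1 / F_c,  c = 2, 3, 4.

If channel c sees a pure gain g of the channel-1 intensity, then
S_c = 1/g; transparent droplets (tiny side/back gains) therefore get
large S3, S4 while absorbing soot pushes all three indices up, so the
indices encode shape, surface and absorbance contrasts that the sizing
channel cannot see.  The optical signature is the 6-vector
``(S2, S3, S4, S2/S3, S2/S4, S3/S4)`` used as classifier features.

Numerics.  Scattered intensities span decades, so all interpolation is
done on log axes.  The matched quantity is the number concentration per
logarithmic intensity interval, dN/dlnF = F·dN/dF: a pure channel gain
translates that curve horizontally in log intensity without distorting
it, which makes the index exactly gain-covariant on the geometric bin
grid (and, with geometric bins, matching dN/dlnF is the same as
matching counts per bin).  Zero-count bins are bridged by the log-log
line between their populated neighbours.  The inversion scans crossings
from low intensity and keeps the first; inversions falling outside the
recorded intensity range are errors, never extrapolations — an
extrapolated index would fabricate optical contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .instrument import ChannelHistogram, Frame, InstrumentConfig


class SpeciationError(ValueError):
    """Base class for failed index computations."""


class NoSignalError(SpeciationError):
    """Raised when a channel has too little signal to interpolate."""


class InversionRangeError(SpeciationError):
    """Raised when the channel-1 level cannot be matched on the target
    channel within its recorded intensity range."""


@dataclass(frozen=True)
class DensityCurve:
    """Sampled intensity distribution dN/dF of one channel.

    ``support`` holds the geometric bin centres (strictly increasing),
    ``density`` the counts divided by bin width.
    """

    support: np.ndarray
    density: np.ndarray
    channel: int = 0

    def __post_init__(self) -> None:
        s = np.asarray(self.support, dtype=float)
        d = np.asarray(self.density, dtype=float)
        if len(s) != len(d):
            raise ValueError("support and density must have equal length")
        if np.any(np.diff(s) <= 0) or np.any(s <= 0):
            raise ValueError("support must be positive and strictly increasing")
        if np.any(d < 0):
            raise ValueError("density must be non-negative")
        object.__setattr__(self, "support", s)
        object.__setattr__(self, "density", d)


def histogram_to_density(h: ChannelHistogram) -> DensityCurve:
    """Counts / bin width, sampled at the geometric bin centres."""
    return DensityCurve(support=h.bin_centers, density=h.counts / h.widths, channel=h.channel)


def _log_nodes(curve: DensityCurve) -> tuple[np.ndarray, np.ndarray]:
    """Log-log nodes of the dN/dlnF polyline through populated bins."""
    pos = curve.density > 0
    if pos.sum() < 2:
        raise NoSignalError(
            f"channel {curve.channel}: needs at least two populated bins to interpolate"
        )
    u = np.log(curve.support[pos])
    w = np.log(curve.density[pos] * curve.support[pos])  # log dN/dlnF
    return u, w


def _eval_polyline(u: np.ndarray, w: np.ndarray, uq: float, max_extension: float) -> float:
    """Evaluate the polyline at ``uq``.

    Outside the node span the end value is extended as a constant for at
    most ``max_extension`` in log intensity (a bin lower bound carries
    its own bin's concentration level; extrapolating end-segment slopes
    would invent levels the curve never reached).
    """
    if uq < u[0] - max_extension or uq > u[-1] + max_extension:
        raise InversionRangeError(
            f"query log-intensity {uq:.3f} outside interpolable range "
            f"[{u[0] - max_extension:.3f}, {u[-1] + max_extension:.3f}]"
        )
    if uq <= u[0]:
        return float(w[0])
    if uq >= u[-1]:
        return float(w[-1])
    i = int(np.searchsorted(u, uq, side="right") - 1)
    t = (uq - u[i]) / (u[i + 1] - u[i])
    return float(w[i] + t * (w[i + 1] - w[i]))


@dataclass(frozen=True)
class InversionResult:
    """One solved index: the matched intensity, the index value, and how
    many crossings the level had (more than one ⇒ ambiguous density)."""

    s: float
    f_c: float
    n_crossings: int


def invert_density(
    d1: DensityCurve, dc: DensityCurve, f1: float, warn_multiple: bool = True
) -> InversionResult:
    """Solve ``dN/dFc(Fc) = dN/dF1(F1)`` for ``Fc``; return ``S = F1/Fc``.

    The channel-1 level is evaluated at ``f1`` (a channel-1 bin lower
    bound, so it may sit up to one bin below the first populated centre;
    end segments are extended by at most one segment length).  The
    channel-c polyline is then scanned from low intensity and the first
    crossing is kept.
    """
    if f1 <= 0:
        raise SpeciationError("F1 must be positive")
    u1, w1 = _log_nodes(d1)
    uc, wc = _log_nodes(dc)
    uq = np.log(f1)

    # allow F1 (a bin lower bound) slightly outside the centre-node span
    max_ext = float(np.diff(u1).max())
    target = _eval_polyline(u1, w1, uq, max_extension=max_ext)

    # a level exactly at the curve's extremum is a valid (boundary) match
    tol = 1e-9 * max(1.0, abs(target))
    if target > wc.max() + tol or target < wc.min() - tol:
        raise InversionRangeError(
            f"channel-{dc.channel} curve never reaches the channel-1 level "
            f"(target log dN/dlnF {target:.3f} outside [{wc.min():.3f}, {wc.max():.3f}])"
        )
    target = float(np.clip(target, wc.min(), wc.max()))

    crossings: list[float] = []
    for i in range(len(uc) - 1):
        w_lo, w_hi = wc[i], wc[i + 1]
        if (w_lo - target) * (w_hi - target) > 0:
            continue
        if w_hi == w_lo:  # flat segment at the level: take its left end
            crossings.append(uc[i])
        else:
            t = (target - w_lo) / (w_hi - w_lo)
            crossings.append(uc[i] + t * (uc[i + 1] - uc[i]))
    # collapse node-duplicate crossings (a node shared by two segments)
    unique: list[float] = []
    for c in crossings:
        if not unique or not np.isclose(c, unique[-1], atol=1e-12):
            unique.append(c)
    if not unique:
        raise InversionRangeError(f"no crossing found on channel {dc.channel}")
    if len(unique) > 1 and warn_multiple:
        warnings.warn(
            f"channel {dc.channel}: {len(unique)} crossings for the channel-1 level; "
            "keeping the first (lowest intensity)"
        )
    f_c = float(np.exp(unique[0]))
    return InversionResult(s=float(f1 / f_c), f_c=f_c, n_crossings=len(unique))


def speciation_index(d1: DensityCurve, dc: DensityCurve, f1: float) -> float:
    """The speciation index ``S_c = F1 / F_c`` (see :func:`invert_density`)."""
    return invert_density(d1, dc, f1).s


@dataclass(frozen=True)
class OpticalSignature:
    """The 6-element optical signature and its provenance.

    When ``valid`` is False the failing channels are recorded and the
    affected entries are NaN.
    """

    s2: float
    s3: float
    s4: float
    s2_over_s3: float
    s2_over_s4: float
    s3_over_s4: float
    f1: float = np.nan
    valid: bool = True
    failed_channels: tuple[int, ...] = ()

    def as_vector(self) -> np.ndarray:
        """(S2, S3, S4, S2/S3, S2/S4, S3/S4)."""
        return np.array(
            [self.s2, self.s3, self.s4, self.s2_over_s3, self.s2_over_s4, self.s3_over_s4]
        )


SIGNATURE_COLUMNS = ("S2", "S3", "S4", "S2_over_S3", "S2_over_S4", "S3_over_S4")


def _modal_f1(h1: ChannelHistogram) -> float:
    """F1 policy ``modal``: lower bound of the modal channel-1 bin."""
    if h1.counts.sum() == 0:
        raise NoSignalError("channel 1 is empty")
    return float(h1.bin_edges[int(np.argmax(h1.counts))])


def _flank_f1(h1: ChannelHistogram) -> float:
    """F1 policy ``flank``: lower bound of the first bin reaching half
    the modal count.

    The matched level then sits on the rising flank of the channel-1
    curve, around half-maximum.  Matching at the modal bin instead puts
    the level at the channel-1 peak height, which sampling noise on the
    other channels' peaks routinely renders unreachable; the flank level
    is crossed by any channel whose (gain-shifted) peak reaches half the
    channel-1 peak.
    """
    if h1.counts.sum() == 0:
        raise NoSignalError("channel 1 is empty")
    half = 0.5 * h1.counts.max()
    b = int(np.argmax(h1.counts >= half))
    return float(h1.bin_edges[b])


_F1_POLICIES = {"modal": _modal_f1, "flank": _flank_f1}


def optical_signature(
    histograms,
    f1: float | None = None,
    f1_policy: str = "flank",
) -> OpticalSignature:
    """Signature of one frame (or cumulative frame) of four histograms.

    ``histograms`` is a sequence of the four :class:`ChannelHistogram`
    (channels 1..4 in order).  ``f1`` overrides the F1 policy
    (``flank``, the default, or ``modal`` — both take the lower bound of
    a populated channel-1 bin).  Invalid channels mark the signature
    invalid instead of raising.
    """
    if len(histograms) != 4:
        raise ValueError("need all four channel histograms")
    h1 = histograms[0]
    if f1 is None:
        if f1_policy not in _F1_POLICIES:
            raise ValueError(f"unknown F1 policy {f1_policy!r}")
        f1 = _F1_POLICIES[f1_policy](h1)

    d1 = histogram_to_density(h1)
    s = {}
    failed: list[int] = []
    for c in (2, 3, 4):
        try:
            dc = histogram_to_density(histograms[c - 1])
            s[c] = invert_density(d1, dc, f1, warn_multiple=False).s
        except SpeciationError:
            s[c] = np.nan
            failed.append(c)
    return OpticalSignature(
        s2=s[2], s3=s[3], s4=s[4],
        s2_over_s3=s[2] / s[3], s2_over_s4=s[2] / s[4], s3_over_s4=s[3] / s[4],
        f1=float(f1), valid=not failed, failed_channels=tuple(failed),
    )


def signature_from_frame(
    frame: Frame, cfg: InstrumentConfig, f1: float | None = None, f1_policy: str = "flank"
) -> OpticalSignature:
    hists = [frame.channel_histogram(c, cfg) for c in (1, 2, 3, 4)]
    return optical_signature(hists, f1=f1, f1_policy=f1_policy)


def signatures_per_bin(frame: Frame, cfg: InstrumentConfig) -> list[OpticalSignature]:
    """One signature per populated channel-1 bin (the "all-bins" F1
    policy, for feature enrichment); invalid ones come back flagged."""
    hists = [frame.channel_histogram(c, cfg) for c in (1, 2, 3, 4)]
    out = []
    for b in np.nonzero(hists[0].counts)[0]:
        f1 = float(hists[0].bin_edges[b])
        out.append(optical_signature(hists, f1=f1))
    return out
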