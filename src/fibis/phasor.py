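"""Phasor transform of TCSPC decays, calibration, and lifetime inversion.

The phasor approach maps each pixel's photon arrival-time histogram onto a
pair of Fourier coordinates at the laser repetition frequency,

    g = sum_k h_k cos(n w t_k) / sum_k h_k,
    s = sum_k h_k sin(n w t_k) / sum_k h_k,

with ``t_k`` the bin centers, ``n`` the harmonic (1 throughout) and
``w = 2 pi * rep_rate`` the angular repetition frequency.  A
mono-exponential decay of lifetime tau sits on the universal semicircle at

    g = 1 / (1 + (w tau)^2),   s = w tau / (1 + (w tau)^2),

and mixtures of decays sit at the photon-weighted mean of their component
phasors, i.e. inside the semicircle along chords.  Instrument response is
removed by a single global complex factor obtained from a reference
fluorophore of known lifetime (Coumarin 6, tau = 2.5 ns, in the workflow
this package mirrors).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .io import DataError, PhasorBundle, TCSPCStack


class UndefinedPhasorError(ValueError):
    """Raised for a histogram with zero total photons."""


class CalibrationError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class PhasorPoint:
    """A single (g, s) phasor coordinate."""

    g: float
    s: float

    @property
    def modulation(self) -> float:
        return math.hypot(self.g, self.s)

    @property
    def phase_rad(self) -> float:
        return math.atan2(self.s, self.g)

    def as_complex(self) -> complex:
        return complex(self.g, self.s)


@dataclasses.dataclass
class CalibrationReference:
    """A reference acquisition of known single-exponential lifetime."""

    known_lifetime_ns: float
    measured: PhasorPoint
    rep_rate_hz: float

    def __post_init__(self) -> None:
        if self.known_lifetime_ns <= 0:
            raise ValueError("known_lifetime_ns must be positive")


def angular_frequency_per_ns(rep_rate_hz: float, harmonic: int = 1) -> float:
    """n * 2 pi * rep_rate, expressed in rad/ns."""
    return 2.0 * math.pi * rep_rate_hz * 1e-9 * harmonic


def bin_centers_ns(t_bins: int, period_ns: float) -> np.ndarray:
    """Centers of ``t_bins`` uniform bins covering [0, period_ns)."""
    return (np.arange(t_bins) + 0.5) * (period_ns / t_bins)


def decay_to_phasor(
    histogram: np.ndarray, period_ns: float, harmonic: int = 1
) -> PhasorPoint:
    """First-harmonic phasor of one arrival-time histogram.

    ``histogram`` holds (expected or observed) photon counts in ``T`` uniform
    bins covering one laser period.
    """
    h = np.asarray(histogram, dtype=float)
    if h.ndim != 1 or h.size < 8:
        raise ValueError("histogram must be 1-D with at least 8 bins")
    if np.any(h < 0):
        raise DataError("histogram holds negative counts")
    total = h.sum()
    if total <= 0:
        raise UndefinedPhasorError("histogram has zero total counts")
    t = bin_centers_ns(h.size, period_ns)
    w = 2.0 * math.pi / period_ns * harmonic  # rad/ns at harmonic n
    g = float(np.dot(h, np.cos(w * t)) / total)
    s = float(np.dot(h, np.sin(w * t)) / total)
    return PhasorPoint(g, s)


def field_phasor(stack: TCSPCStack, harmonic: int = 1) -> PhasorBundle:
    """Per-pixel phasor transform of a stack's accumulated decay.

    Pixels with zero photons are marked invalid (NaN phasor), not errors.
    """
    if stack.decay is None:
        raise ValueError("stack carries no decay histogram")
    decay = stack.decay.astype(float)
    T = stack.t_bins
    t = bin_centers_ns(T, stack.period_ns)
    w = 2.0 * math.pi / stack.period_ns * harmonic
    total = decay.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = decay @ np.cos(w * t) / total
        s = decay @ np.sin(w * t) / total
    empty = total <= 0
    g[empty] = np.nan
    s[empty] = np.nan
    return PhasorBundle(
        g=g,
        s=s,
        intensity=total,
        rep_rate_hz=stack.rep_rate_hz,
        harmonic=harmonic,
        calibrated=False,
    )


def single_exp_phasor(
    tau_ns: float, rep_rate_hz: float, harmonic: int = 1
) -> PhasorPoint:
    """Closed-form phasor of a mono-exponential decay (universal semicircle)."""
    if tau_ns < 0:
        raise ValueError("lifetime must be nonnegative")
    wt = angular_frequency_per_ns(rep_rate_hz, harmonic) * tau_ns
    d = 1.0 + wt * wt
    return PhasorPoint(1.0 / d, wt / d)


def calibration_factor(ref: CalibrationReference, harmonic: int = 1) -> complex:
    """Global complex factor mapping the measured reference onto its true phasor."""
    expected = single_exp_phasor(ref.known_lifetime_ns, ref.rep_rate_hz, harmonic)
    z_meas = ref.measured.as_complex()
    if abs(z_meas) == 0:
        raise CalibrationError("measured reference phasor has zero modulation")
    return expected.as_complex() / z_meas


def calibrate(bundle: PhasorBundle, ref: CalibrationReference) -> PhasorBundle:
    """Apply the global complex calibration factor to every pixel.

    Phasors are treated as complex numbers z = g + i s and multiplied by
    c = z_expected / z_measured; self-calibrating the reference's own bundle
    therefore maps its mean phasor exactly onto the known-lifetime phasor.
    """
    c = calibration_factor(ref, bundle.harmonic)
    z = (bundle.g + 1j * bundle.s) * c
    return PhasorBundle(
        g=z.real,
        s=z.imag,
        intensity=bundle.intensity,
        rep_rate_hz=bundle.rep_rate_hz,
        harmonic=bundle.harmonic,
        calibrated=True,
        reference_lifetime_ns=ref.known_lifetime_ns,
    )


def mean_phasor(bundle: PhasorBundle) -> PhasorPoint:
    """Intensity-weighted mean phasor over the bundle's valid pixels."""
    m = bundle.valid
    if not m.any():
        raise UndefinedPhasorError("bundle has no valid pixels")
    w = bundle.intensity[m].astype(float)
    return PhasorPoint(
        float(np.average(bundle.g[m], weights=w)),
        float(np.average(bundle.s[m], weights=w)),
    )


def phase_lifetime(p: PhasorPoint, rep_rate_hz: float, harmonic: int = 1) -> float:
    """Phase lifetime tau_phi = tan(phi) / w in ns; requires g > 0."""
    if p.g <= 0:
        raise ValueError("phase lifetime undefined for g <= 0")
    return (p.s / p.g) / angular_frequency_per_ns(rep_rate_hz, harmonic)


def modulation_lifetime(
    p: PhasorPoint, rep_rate_hz: float, harmonic: int = 1, tol: float = 1e-9
) -> float:
    """Modulation lifetime tau_M = (1/w) sqrt(1/M^2 - 1) in ns."""
    m = p.modulation
    if m <= 0 or m > 1.0 + tol:
        raise ValueError(f"modulation {m} outside (0, 1]")
    m = min(m, 1.0)
    return math.sqrt(max(1.0 / (m * m) - 1.0, 0.0)) / angular_frequency_per_ns(
        rep_rate_hz, harmonic
    )
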