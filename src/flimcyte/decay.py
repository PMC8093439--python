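"""TCSPC decay-model primitives shared by the simulator and the fitters.

A fluorophore excited by a pulsed laser with repetition period ``T`` emits
photons whose arrival-time density within one period is the *wrapped*
(periodic) exponential

    p(t) = sum_k exp(-(t + k*T)/tau) = exp(-t/tau) / (1 - exp(-T/tau)),

i.e. photons from incompletely decayed previous pulses pile up at the start
of the window.  The detected histogram is this curve circularly convolved
with the instrument response function (IRF) and sampled at the TCSPC bin
centers, plus a flat dark-count offset.

All curves here use *amplitude* weighting: a bi-exponential mixture
``alpha1 * exp(-t/tau1) + alpha2 * exp(-t/tau2)`` has component amplitudes
(not photon fractions) ``alpha1, alpha2`` with ``alpha1 + alpha2 = 1`` —
the convention of standard FLIM fitting software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IRF",
    "default_irf",
    "bin_centers",
    "periodic_exponential",
    "convolve_irf",
    "biexp_shape",
    "mono_shape",
]

#: Laser repetition period in ns for a standard 80 MHz Ti:Sapphire source.
DEFAULT_PERIOD_NS = 12.5
#: TCSPC histogram length.
DEFAULT_N_BINS = 256


@dataclass(frozen=True)
class IRF:
    """Measured instrument response function.

    Parameters
    ----------
    histogram:
        Non-negative counts (or density) per TCSPC bin; normalized to unit
        sum on construction so that convolution with it preserves total
        photon counts.
    bin_width:
        Width of one TCSPC bin in ns.
    """

    histogram: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        h = np.asarray(self.histogram, dtype=float)
        if h.ndim != 1 or h.size == 0:
            raise ValueError("IRF histogram must be a non-empty 1-D vector")
        if not np.all(np.isfinite(h)) or np.any(h < 0):
            raise ValueError("IRF histogram must be finite and non-negative")
        total = h.sum()
        if total <= 0:
            raise ValueError("IRF histogram must have positive total weight")
        object.__setattr__(self, "histogram", h / total)
        if not self.bin_width > 0:
            raise ValueError("IRF bin_width must be positive")

    @property
    def n_bins(self) -> int:
        return self.histogram.size


def default_irf(
    n_bins: int = DEFAULT_N_BINS,
    period: float = DEFAULT_PERIOD_NS,
    fwhm: float = 0.2,
    center: float = 1.0,
) -> IRF:
    """Gaussian IRF (0.2 ns FWHM, centered at 1.0 ns), truncated to the
    measurement window and renormalized — a conventional stand-in for a
    second-harmonic-generation IRF measurement."""
    t = bin_centers(n_bins, period)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    h = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    return IRF(histogram=h, bin_width=period / n_bins)


def bin_centers(n_bins: int, period: float) -> np.ndarray:
    """Arrival-time bin centers (ns) for ``n_bins`` bins over one period."""
    dt = period / n_bins
    return (np.arange(n_bins) + 0.5) * dt


def periodic_exponential(tau: float, n_bins: int, period: float) -> np.ndarray:
    """Wrapped exponential ``exp(-t/tau)/(1 - exp(-T/tau))`` at bin centers.

    The underlying (un-wrapped) exponential has unit amplitude at t=0, so
    mixtures of these curves carry amplitude weights directly.
    """
    if not tau > 0:
        raise ValueError("lifetime tau must be positive")
    t = bin_centers(n_bins, period)
    return np.exp(-t / tau) / -np.expm1(-period / tau)


def convolve_irf(curve: np.ndarray, irf: IRF) -> np.ndarray:
    """Circular convolution of a periodic decay curve with the IRF.

    Both live on the same bin grid; the convolution wraps around the laser
    period, matching the physics of a periodically re-excited sample.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.shape != irf.histogram.shape:
        raise ValueError("curve and IRF must share the same bin grid")
    n = curve.size
    return np.fft.irfft(np.fft.rfft(curve) * np.fft.rfft(irf.histogram), n)


def biexp_shape(
    tau1: float,
    tau2: float,
    alpha1: float,
    irf: IRF,
    n_bins: int,
    period: float,
) -> np.ndarray:
    """IRF-convolved periodic bi-exponential, normalized to unit sum.

    Multiply by an expected photon count to obtain the expected decay part
    of a TCSPC histogram.
    """
    if not 0.0 <= alpha1 <= 1.0:
        raise ValueError("alpha1 must lie in [0, 1]")
    curve = alpha1 * periodic_exponential(tau1, n_bins, period)
    if alpha1 < 1.0:
        curve = curve + (1.0 - alpha1) * periodic_exponential(tau2, n_bins, period)
    shape = convolve_irf(curve, irf)
    shape = np.clip(shape, 0.0, None)
    return shape / shape.sum()


def mono_shape(tau: float, irf: IRF, n_bins: int, period: float) -> np.ndarray:
    """IRF-convolved periodic mono-exponential, normalized to unit sum."""
    shape = convolve_irf(periodic_exponential(tau, n_bins, period), irf)
    shape = np.clip(shape, 0.0, None)
    return shape / shape.sum()
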