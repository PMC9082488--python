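"""Core spectral data types and arithmetic for J-difference-edited MRS.

This module defines the in-memory carriers used throughout the package —
time-domain FIDs and frequency-domain spectra with acquisition metadata —
together with the parametric forward model that synthesizes edited
multiplet responses, FFT/apodization, and the MEGA subtraction / HERMES
Hadamard recombination arithmetic.

Conventions
-----------
* The ppm axis is *descending* (standard NMR display order), referenced to
  water at ``center_ppm`` (default 4.68 ppm).
* A resonance at chemical shift ``p`` ppm evolves in the rotating frame at
  ``f = (p - center_ppm) * transmitter_frequency`` Hz, i.e. signals
  downfield of water have positive offset frequency.
* Time axis: ``t_k = k / spectral_width`` seconds for sample ``k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Sequence, Union

import numpy as np

__all__ = [
    "AcquisitionParams",
    "SpectralLine",
    "Multiplet",
    "Fid",
    "Spectrum",
    "ppm_axis",
    "hz_to_ppm",
    "ppm_to_hz",
    "synth_fid",
    "to_spectrum",
    "hadamard_combine",
    "mega_difference",
    "HERMES_LABELS",
    "MEGA_LABELS",
]

HERMES_LABELS = ("A", "B", "C", "D")
MEGA_LABELS = ("ON", "OFF")


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition metadata for one scan.

    Defaults reproduce the reference protocol: TR 2,000 ms, 256 transients,
    spectral width 2.5 kHz, 2,048 complex points (16-step phase cycling is
    metadata only and is not simulated).
    """

    transmitter_frequency: float = 127.7  # MHz (3 T)
    center_ppm: float = 4.68  # carrier on water
    spectral_width: float = 2500.0  # Hz
    n_points: int = 2048
    te: float = 80.0  # ms
    tr: float = 2000.0  # ms
    n_transients: int = 256
    sequence_tag: str = "HERMES80"  # HERMES80 | MEGA120
    editing_frequencies: tuple = (1.9, 4.56)  # ppm

    def __post_init__(self) -> None:
        if self.spectral_width <= 0:
            raise ValueError("spectral_width must be positive")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.sequence_tag not in ("HERMES80", "MEGA120"):
            raise ValueError(f"unknown sequence_tag {self.sequence_tag!r}")

    @property
    def dwell_time(self) -> float:
        """Sampling interval in seconds (1 / spectral_width)."""
        return 1.0 / self.spectral_width

    def time_axis(self, n: int | None = None) -> np.ndarray:
        """Time of each sample in seconds."""
        n = self.n_points if n is None else n
        return np.arange(n) / self.spectral_width

    @property
    def sub_experiment_labels(self) -> tuple:
        return HERMES_LABELS if self.sequence_tag == "HERMES80" else MEGA_LABELS


@dataclass(frozen=True)
class SpectralLine:
    """A single resonance line: position, magnitude, and phase.

    The per-line phase encodes J-evolution/editing behavior (e.g. the
    mixed-phase co-edited aspartyl lines at short TE); amplitudes are
    non-negative by construction with sign carried in the phase.
    """

    offset_ppm: float
    amplitude: float
    phase_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0 (encode sign via phase)")


@dataclass(frozen=True)
class Multiplet:
    """A named group of lines sharing Lorentzian/Gaussian decay."""

    name: str
    lines: tuple  # of SpectralLine
    t2_ms: float = 200.0
    gaussian_hz: float = 8.0

    def __post_init__(self) -> None:
        if self.t2_ms <= 0:
            raise ValueError("t2_ms must be positive")
        if self.gaussian_hz < 0:
            raise ValueError("gaussian_hz must be >= 0")


@dataclass
class Fid:
    """Complex time-domain signal plus acquisition metadata."""

    samples: np.ndarray
    acq: AcquisitionParams
    label: str = ""  # A|B|C|D|ON|OFF|WATER|DIFF...

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")

    def copy(self) -> "Fid":
        return Fid(self.samples.copy(), self.acq, self.label)


@dataclass
class Spectrum:
    """Complex frequency-domain signal on a descending ppm axis."""

    intensities: np.ndarray
    ppm_axis: np.ndarray
    acq: AcquisitionParams

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=complex)
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=float)
        if len(self.intensities) != len(self.ppm_axis):
            raise ValueError("intensities and ppm_axis must have equal length")
        d = np.diff(self.ppm_axis)
        if not (np.all(d < 0) or np.all(d > 0)):
            raise ValueError("ppm axis must be strictly monotone")

    def slice_ppm(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of axis points with lo <= ppm <= hi."""
        return (self.ppm_axis >= lo) & (self.ppm_axis <= hi)


def hz_to_ppm(f_hz: np.ndarray | float, acq: AcquisitionParams):
    """Offset frequency in Hz -> chemical shift in ppm."""
    return acq.center_ppm + np.asarray(f_hz, dtype=float) / acq.transmitter_frequency


def ppm_to_hz(p: np.ndarray | float, acq: AcquisitionParams):
    """Chemical shift in ppm -> offset frequency in Hz."""
    return (np.asarray(p, dtype=float) - acq.center_ppm) * acq.transmitter_frequency


def ppm_axis(acq: AcquisitionParams, n: int) -> np.ndarray:
    """Descending ppm axis of ``n`` points spanning the spectral width.

    The axis runs from ``center + sw/(2 nu0)`` down to ``center - sw/(2 nu0)``
    inclusive, so its width in Hz equals the spectral width and the midpoint
    equals ``center_ppm`` for odd ``n``.  (FFT bin centers differ from these
    labels by at most one bin width; at the 32K grids used for fitting the
    difference is < 0.001 ppm and is absorbed by the fitted shift terms.)
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    half = acq.spectral_width / (2.0 * acq.transmitter_frequency)
    return np.linspace(acq.center_ppm + half, acq.center_ppm - half, n)


def synth_fid(
    multiplets: Sequence[Multiplet],
    concentrations: Mapping[str, float],
    acq: AcquisitionParams,
    label: str = "",
) -> Fid:
    """Parametric forward model: sum of damped complex exponentials.

    ``s(t) = sum_m c_m sum_l a_l e^{i phi_l} e^{i 2 pi f_l t}
             e^{-t/T2_m} e^{-(g_m t)^2}``

    with ``f_l = (offset_l - center_ppm) * nu0``.  Every multiplet name must
    have an entry in ``concentrations``.
    """
    t = acq.time_axis()
    out = np.zeros(acq.n_points, dtype=complex)
    for m in multiplets:
        try:
            c = concentrations[m.name]
        except KeyError:
            raise KeyError(f"missing concentration for multiplet {m.name!r}")
        if c == 0 or not m.lines:
            continue
        decay = np.exp(-t / (m.t2_ms / 1000.0)) * np.exp(-((m.gaussian_hz * t) ** 2))
        acc = np.zeros(acq.n_points, dtype=complex)
        for ln in m.lines:
            f = (ln.offset_ppm - acq.center_ppm) * acq.transmitter_frequency
            acc += ln.amplitude * np.exp(
                1j * (np.deg2rad(ln.phase_deg) + 2.0 * np.pi * f * t)
            )
        out += c * acc * decay
    return Fid(out, acq, label)


def to_spectrum(fid: Fid, zerofill_to: int = 32768, lb_hz: float = 3.0) -> Spectrum:
    """Apodize, zero-fill and Fourier transform an FID.

    Applies exponential line broadening ``exp(-pi * lb_hz * t)`` (adding
    ``lb_hz`` to every Lorentzian FWHM), zero-fills to ``zerofill_to``
    points, then FFTs.  Output intensities are ordered along the descending
    ppm axis.
    """
    n = len(fid.samples)
    if zerofill_to < n:
        raise ValueError("zerofill_to must be >= number of FID points")
    if lb_hz < 0:
        raise ValueError("lb_hz must be >= 0")
    t = fid.acq.time_axis(n)
    s = fid.samples * np.exp(-np.pi * lb_hz * t)
    if zerofill_to > n:
        s = np.concatenate([s, np.zeros(zerofill_to - n, dtype=complex)])
    spec = np.fft.fftshift(np.fft.fft(s))
    # ascending frequency -> ascending ppm; flip to descending ppm display
    spec = spec[::-1]
    axis = ppm_axis(fid.acq, zerofill_to)
    return Spectrum(spec, axis, fid.acq)


def _check_matched(items: Sequence[Union[Fid, Spectrum]]) -> None:
    first = items[0]
    n0 = len(first.samples) if isinstance(first, Fid) else len(first.intensities)
    for it in items[1:]:
        n = len(it.samples) if isinstance(it, Fid) else len(it.intensities)
        if type(it) is not type(first):
            raise TypeError("cannot mix Fid and Spectrum inputs")
        if n != n0:
            raise ValueError("mismatched lengths between sub-experiments")
        if (
            it.acq.spectral_width != first.acq.spectral_width
            or it.acq.n_points != first.acq.n_points
            or it.acq.transmitter_frequency != first.acq.transmitter_frequency
        ):
            raise ValueError("mismatched acquisition parameters")


def _combine(items: Sequence[Union[Fid, Spectrum]], coeffs: Sequence[float]):
    _check_matched(list(items))
    first = items[0]
    if isinstance(first, Fid):
        out = np.zeros_like(first.samples)
        for it, c in zip(items, coeffs):
            out = out + c * it.samples
        return Fid(out, first.acq, "DIFF")
    out = np.zeros_like(first.intensities)
    for it, c in zip(items, coeffs):
        out = out + c * it.intensities
    return Spectrum(out, first.ppm_axis, first.acq)


# Hadamard sign patterns over sub-experiments (A, B, C, D) where
# A = (GABA-ON, GSH-ON), B = (GABA-ON, GSH-OFF),
# C = (GABA-OFF, GSH-ON), D = (GABA-OFF, GSH-OFF).
_HADAMARD_SIGNS = {
    "GSH": (1.0, -1.0, 1.0, -1.0),
    "GABA": (1.0, 1.0, -1.0, -1.0),
}


def hadamard_combine(
    quartet: Mapping[str, Union[Fid, Spectrum]], target: str
) -> Union[Fid, Spectrum]:
    """HERMES Hadamard recombination for the requested target.

    ``GSH: (A - B + C - D)/4``; ``GABA: (A + B - C - D)/4``.  Dividing by
    the number of summed sub-spectra keeps amplitudes per-average
    comparable between HERMES and MEGA-PRESS (any consistent convention
    cancels in water-scaled ratios).
    """
    if target not in _HADAMARD_SIGNS:
        raise ValueError(f"unknown Hadamard target {target!r}")
    missing = [k for k in HERMES_LABELS if k not in quartet]
    if missing:
        raise ValueError(f"missing sub-experiments: {missing}")
    signs = _HADAMARD_SIGNS[target]
    items = [quartet[k] for k in HERMES_LABELS]
    return _combine(items, [s / 4.0 for s in signs])


def mega_difference(
    on: Union[Fid, Spectrum], off: Union[Fid, Spectrum]
) -> Union[Fid, Spectrum]:
    """MEGA-PRESS difference ``(ON - OFF)/2`` (normalization consistent
    with :func:`hadamard_combine`)."""
    return _combine([on, off], [0.5, -0.5])
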