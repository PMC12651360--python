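"""Spectral preprocessing: Burg AR models, PSD grids, resonance features.

The pipeline turns a raw velocity-vs-time record into the fixed 2623-point
power spectral density on 0-5000 Hz that every calibration model consumes:

    detect_onset -> extract_segment -> burg_ar -> ar_psd -> find_resonances

The AR coefficient convention used throughout is

    x[n] + a_1 x[n-1] + ... + a_p x[n-p] = e[n],

i.e. the polynomial ``A(z) = 1 + sum_k a_k z^-k`` whitens the signal; the
one-sided PSD is ``P(f) = (2 sigma^2 / fs) / |A(e^{-i 2 pi f / fs})|^2``.
Burg's recursion minimizes the summed forward+backward prediction error and
yields reflection coefficients in [-1, 1], hence a minimum-phase model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .synthgen import VibrationRecord

__all__ = [
    "SigprocError",
    "NoOnsetError",
    "SegmentBoundsError",
    "DegenerateSignalError",
    "InsufficientPeaksError",
    "ARModel",
    "Spectrum",
    "ResonanceSet",
    "CorrelationProfile",
    "detect_onset",
    "extract_segment",
    "burg_ar",
    "ar_psd",
    "find_resonances",
    "elasticity_index",
    "correlation_profile",
]

DEFAULT_AR_ORDER = 400
DEFAULT_N_POINTS = 2623
DEFAULT_F_MAX = 5000.0


class SigprocError(ValueError):
    """Domain error raised by the signal-processing stage."""


class NoOnsetError(SigprocError):
    """No excitation onset found in the record."""


class SegmentBoundsError(SigprocError):
    """Requested segment extends beyond the record (no implicit padding)."""


class DegenerateSignalError(SigprocError):
    """Constant (zero-variance) segment cannot support an AR fit."""


class InsufficientPeaksError(SigprocError):
    """Fewer qualifying spectral peaks than requested."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ARModel:
    """Burg-estimated autoregressive model.

    ``coefficients`` are a_1..a_p in the convention
    ``x[n] + sum_k a_k x[n-k] = e[n]``; ``noise_variance`` is the final
    prediction-error power sigma^2.
    """

    order: int
    coefficients: np.ndarray
    noise_variance: float
    sampling_rate: float

    def __post_init__(self) -> None:
        if len(self.coefficients) != self.order:
            raise SigprocError("coefficient count must equal order")
        if self.noise_variance < 0:
            raise SigprocError("noise_variance must be >= 0")


@dataclass(frozen=True)
class Spectrum:
    """Power spectral density on a uniform frequency grid."""

    frequencies: np.ndarray
    power: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        f, p = np.asarray(self.frequencies), np.asarray(self.power)
        if f.shape != p.shape or f.ndim != 1:
            raise SigprocError("frequencies and power must be 1-D, same length")
        if np.any(np.diff(f) <= 0):
            raise SigprocError("frequency grid must be strictly increasing")
        step = np.diff(f)
        if step.size and not np.allclose(step, step[0], rtol=1e-6):
            raise SigprocError("frequency grid must be uniform")
        if np.any(p < 0):
            raise SigprocError("power must be non-negative")

    def __len__(self) -> int:
        return len(self.frequencies)


@dataclass(frozen=True)
class ResonanceSet:
    """First two resonant frequencies and peak powers, optional EI."""

    f1: float
    f2: float
    peak_powers: tuple[float, float]
    elasticity_index: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.f1 < self.f2):
            raise SigprocError("need 0 < f1 < f2")
        if any(p <= 0 for p in self.peak_powers):
            raise SigprocError("peak powers must be positive")


@dataclass(frozen=True)
class CorrelationProfile:
    """Per-frequency-bin Pearson correlation between PSD power and firmness."""

    frequencies: np.ndarray
    r: np.ndarray
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.frequencies) != len(self.r):
            raise SigprocError("grid/r length mismatch")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise SigprocError("|r| must be <= 1")
        if self.degenerate is None:
            object.__setattr__(self, "degenerate",
                               np.zeros(len(self.r), dtype=bool))


# --------------------------------------------------------------------------
# segmentation
# --------------------------------------------------------------------------


def detect_onset(
    record: VibrationRecord,
    noise_window: float = 0.5,
    k: float = 5.0,
    m: int = 10,
) -> int:
    """First index where |x| exceeds k*sd(noise) for m consecutive samples.

    The noise sd is estimated from the first ``noise_window`` seconds, which
    must precede any excitation.  A zero noise sd (digitally silent record)
    is replaced by a tiny epsilon so any nonzero excursion still triggers.
    """
    x = np.asarray(record.samples, dtype=float)
    n_noise = int(round(noise_window * record.sampling_rate))
    if n_noise < 1 or n_noise >= len(x):
        raise SigprocError("record shorter than noise_window")
    sd = float(np.std(x[:n_noise]))
    if sd == 0.0:
        sd = np.finfo(float).tiny
    above = np.abs(x) > k * sd
    if m <= 1:
        idx = np.flatnonzero(above)
        if idx.size:
            return int(idx[0])
        raise NoOnsetError("no threshold crossing found")
    # find the first run of >= m consecutive True
    run = np.convolve(above.astype(int), np.ones(m, dtype=int), mode="valid")
    starts = np.flatnonzero(run == m)
    if starts.size:
        return int(starts[0])
    raise NoOnsetError("no threshold crossing found")


def extract_segment(
    record: VibrationRecord,
    onset: int,
    pre: float = 1.5,
    post: float = 1.5,
) -> np.ndarray:
    """Contiguous slice spanning ``pre`` s before to ``post`` s after onset."""
    fs = record.sampling_rate
    n_pre = int(round(pre * fs))
    length = int(round((pre + post) * fs))
    start = onset - n_pre
    stop = start + length
    if start < 0 or stop > len(record.samples):
        raise SegmentBoundsError(
            f"segment [{start}, {stop}) outside record of length "
            f"{len(record.samples)}"
        )
    return np.asarray(record.samples[start:stop], dtype=float)


# --------------------------------------------------------------------------
# Burg AR estimation
# --------------------------------------------------------------------------


def burg_ar(
    segment: np.ndarray,
    order: int,
    sampling_rate: float = 312500.0,
) -> ARModel:
    """Fit an AR(order) model by Burg's maximum-entropy recursion.

    Vectorized O(N*p).  Reflection coefficients are guaranteed in [-1, 1],
    so the model is minimum-phase; ``noise_variance`` is the final
    forward/backward prediction-error power.
    """
    x = np.asarray(segment, dtype=float)
    if x.ndim != 1:
        raise SigprocError("segment must be 1-D")
    if order < 1 or order >= len(x):
        raise SigprocError("need 1 <= order < len(segment)")
    if np.ptp(x) == 0.0:
        raise DegenerateSignalError("constant segment")

    a = np.zeros(0)
    E = float(np.mean(x * x))
    f = x.copy()      # forward prediction errors
    b = x.copy()      # backward prediction errors
    for _ in range(order):
        ff = f[1:]
        bb = b[:-1]
        den = float(ff @ ff + bb @ bb)
        if den == 0.0:
            k = 0.0
        else:
            k = -2.0 * float(ff @ bb) / den
        k = float(np.clip(k, -1.0, 1.0))
        # Levinson update of the coefficient vector
        a = np.concatenate([a, [0.0]])
        a = a + k * np.concatenate([a[-2::-1], [1.0]])
        f = ff + k * bb
        b = bb + k * ff
        E *= max(1.0 - k * k, 0.0)
    return ARModel(order=order, coefficients=a, noise_variance=E,
                   sampling_rate=float(sampling_rate))


def ar_psd(
    model: ARModel,
    f_max: float = DEFAULT_F_MAX,
    n_points: int = DEFAULT_N_POINTS,
    source_id: str = "",
) -> Spectrum:
    """Evaluate the one-sided AR PSD on the inclusive grid [0, f_max].

    ``P(f) = (2 sigma^2 / fs) / |A(e^{-i 2 pi f / fs})|^2`` on
    ``linspace(0, f_max, n_points)`` -- with defaults, 2623 points spanning
    0-5000 Hz (grid step 5000/2622 ~= 1.907 Hz).
    """
    fs = model.sampling_rate
    if f_max > fs / 2 + 1e-9:
        raise SigprocError("f_max exceeds Nyquist frequency")
    if n_points < 2:
        raise SigprocError("need n_points >= 2")
    freqs = np.linspace(0.0, f_max, n_points)
    poly = np.concatenate([[1.0], model.coefficients])
    w = 2.0 * np.pi * freqs / fs
    # A(e^{-iw}) evaluated for all grid points at once
    A = np.exp(-1j * np.outer(w, np.arange(len(poly)))) @ poly
    power = (2.0 * model.noise_variance / fs) / np.abs(A) ** 2
    return Spectrum(frequencies=freqs, power=power, source_id=source_id)


# --------------------------------------------------------------------------
# resonance features
# --------------------------------------------------------------------------


def find_resonances(
    spectrum: Spectrum,
    n_peaks: int = 2,
    min_freq: float = 200.0,
    prominence_fraction: float = 0.05,
    mass: float | None = None,
) -> ResonanceSet:
    """Locate the first resonant frequencies of a PSD.

    Returns the ``n_peaks`` lowest-frequency local maxima above ``min_freq``
    whose prominence exceeds ``prominence_fraction`` of the global maximum
    (ties broken toward lower frequency by construction).  With ``mass``
    given, the elasticity index f2^2 * m is attached.
    """
    p = spectrum.power
    prominence = prominence_fraction * float(np.max(p))
    peaks, _ = _sig.find_peaks(p, prominence=prominence)
    peaks = peaks[spectrum.frequencies[peaks] >= min_freq]
    if len(peaks) < n_peaks:
        raise InsufficientPeaksError(
            f"found {len(peaks)} qualifying peaks, need {n_peaks}"
        )
    sel = peaks[:n_peaks]
    f1, f2 = (float(spectrum.frequencies[i]) for i in sel[:2])
    powers = (float(p[sel[0]]), float(p[sel[1]]))
    ei = elasticity_index(f2, mass) if mass is not None else None
    return ResonanceSet(f1=f1, f2=f2, peak_powers=powers, elasticity_index=ei)


def elasticity_index(f2: float, mass: float) -> float:
    """Classical stiffness surrogate EI = f2^2 * m (Hz^2 kg)."""
    if f2 <= 0 or mass <= 0:
        raise SigprocError("f2 and mass must be positive")
    return f2 * f2 * mass


def correlation_profile(
    spectra: list[Spectrum],
    firmness: np.ndarray,
) -> CorrelationProfile:
    """Per-bin Pearson correlation between PSD power and firmness.

    Bins with zero power variance across samples (or constant firmness) get
    r = 0 and are flagged in ``degenerate``.
    """
    if len(spectra) != len(firmness) or len(spectra) < 3:
        raise SigprocError("need matching spectra/firmness lists, n >= 3")
    grid = spectra[0].frequencies
    for s in spectra[1:]:
        if len(s) != len(grid) or not np.allclose(s.frequencies, grid):
            raise SigprocError("spectra must share a common frequency grid")
    P = np.stack([s.power for s in spectra])          # (n, bins)
    y = np.asarray(firmness, dtype=float)
    Pc = P - P.mean(axis=0)
    yc = y - y.mean()
    sp = np.sqrt((Pc * Pc).sum(axis=0))
    sy = float(np.sqrt(yc @ yc))
    # numerical zero variance: constant bins leave O(eps) rounding residue
    scale = np.sqrt((P * P).sum(axis=0))
    degenerate = (sp <= 1e-10 * scale) | (sy <= 1e-10 * abs(y).max())
    denom = np.where(degenerate, 1.0, sp * sy)
    r = (Pc * yc[:, None]).sum(axis=0) / denom
    r = np.where(degenerate, 0.0, np.clip(r, -1.0, 1.0))
    return CorrelationProfile(frequencies=grid, r=r, degenerate=degenerate)
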