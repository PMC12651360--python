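"""Synthetic acoustic-vibration data generator.

Emulates the noncontact measurement chain (air-jet excitation + laser Doppler
vibrometer) with a damped multi-mode oscillator model, so the downstream
spectral and calibration code can be exercised without hardware.  A record is

* a pre-excitation stretch of zero-mean sensor noise,
* followed, from the excitation onset, by a sum of exponentially decaying
  sinusoids (the fruit's resonant modes) whose frequencies shift with
  firmness in a cultivar-specific way,
* plus a stationary band-limited stochastic component centred near 3 kHz whose
  power grows affinely with firmness (tissue-elasticity surrogate),
* plus additive measurement noise.

Cultivar profiles anchor the first two resonances at the cultivar's mean
firmness and encode a deliberately non-monotonic pooled relation between the
first resonance and firmness across cultivars: the firmest default cultivar
("dongxue") has the *lowest* first resonance, so pooled f1-firmness
correlation is weak/negative while within-cultivar relations are positive.

Also provides toy puncture force-displacement curves whose initial slope is
the firmness ground truth, mirroring how reference firmness is measured with
a texture analyzer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as _sig
from scipy import stats as _stats

__all__ = [
    "SynthError",
    "CultivarProfile",
    "SyntheticConfig",
    "VibrationRecord",
    "ForceCurve",
    "DEFAULT_PROFILES",
    "default_profiles",
    "new_cultivar_profile",
    "simulate_signal",
    "simulate_dataset",
    "simulate_force_curve",
]


class SynthError(ValueError):
    """Domain error raised by the synthetic generator."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CultivarProfile:
    """Cultivar-specific vibro-mechanical parameters.

    Resonance frequencies are affine in firmness: the k-th mode frequency at
    firmness F is ``f_k(F) = f_k_at_mean + slope_k * (F - mean_firmness)``.
    ``highband_slope`` sets the power (variance, arbitrary velocity units^2)
    of the band-limited component as ``highband_slope * F`` -- increasing and
    affine in firmness.

    ``freq_scatter_sd`` (Hz) and ``amp_scatter_sd`` (log units) describe the
    fruit-to-fruit biological scatter of resonance position and mode
    amplitude around the population relation: real fruit of equal firmness
    differ in size, shape and internal structure, so resonance frequency is
    an imperfect firmness proxy and peak amplitude is essentially
    uninformative.  The scatter is drawn per fruit (shared by its
    replicates) by the dataset simulator; direct single-signal simulation
    uses the population relation exactly.
    """

    name: str
    f1_at_mean: float
    f2_at_mean: float
    mean_firmness: float
    f1_slope: float
    f2_slope: float
    damping_ratios: tuple[float, ...] = (0.012, 0.012)
    mode_amplitudes: tuple[float, ...] = (1.0, 0.8)
    highband_center: float = 3000.0
    highband_slope: float = 5.0e-3
    firmness_range: tuple[float, float] = (0.5, 9.0)
    mass_range: tuple[float, float] = (0.15, 0.30)
    freq_scatter_sd: float = 30.0
    amp_scatter_sd: float = 0.25

    def __post_init__(self) -> None:
        lo, hi = self.firmness_range
        if not (0.0 < lo < hi):
            raise SynthError("firmness_range must satisfy 0 < min < max")
        if self.f2_slope <= 0:
            raise SynthError("f2_slope must be positive")
        if len(self.damping_ratios) != len(self.mode_amplitudes):
            raise SynthError("damping_ratios and mode_amplitudes lengths differ")
        if not all(0.0 < z < 1.0 for z in self.damping_ratios):
            raise SynthError("damping ratios must lie in (0, 1)")
        for F in (lo, hi):
            fr = self.mode_frequencies(F)
            if np.any(fr <= 0.0) or np.any(np.diff(fr) <= 0) or fr[-1] >= 5000.0:
                raise SynthError(
                    f"{self.name}: need 0 < f1 < ... < 5000 Hz over the "
                    f"firmness range, got {np.round(fr, 1)} at F={F}"
                )

    @property
    def n_modes(self) -> int:
        return len(self.mode_amplitudes)

    def mode_frequencies(self, firmness: float) -> np.ndarray:
        """Resonance frequencies (Hz) of all modes at the given firmness."""
        dF = firmness - self.mean_firmness
        return np.array(
            [self.f1_at_mean + self.f1_slope * dF,
             self.f2_at_mean + self.f2_slope * dF][: self.n_modes]
        )

    def highband_power(self, firmness: float) -> float:
        """Variance of the band-limited component at the given firmness."""
        return self.highband_slope * firmness


@dataclass(frozen=True)
class SyntheticConfig:
    """Acquisition-chain parameters for the simulator.

    Defaults mirror the measurement protocol (312.5 kHz sampling, a window
    of 1.5 s either side of the onset, three excitations per fruit).  For
    desk-scale experiments a reduced sampling rate (e.g. 12.5 kHz) preserves
    the 0-5 kHz band of interest while keeping AR fits cheap.
    """

    sampling_rate: float = 312500.0
    pre_window: float = 1.5
    post_window: float = 1.5
    excitation_rise: float = 0.004
    noise_sd: float = 0.05
    n_modes: int = 2
    replicates_per_fruit: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise SynthError("sampling_rate must be positive")
        if self.pre_window < 0 or self.post_window < 0:
            raise SynthError("windows must be non-negative")
        if self.replicates_per_fruit < 1:
            raise SynthError("replicates_per_fruit must be >= 1")
        if self.n_modes < 2:
            raise SynthError("n_modes must be >= 2")


@dataclass(frozen=True)
class VibrationRecord:
    """A single-excitation velocity-vs-time record with its labels."""

    fruit_id: str
    replicate_id: str
    cultivar: str
    firmness: float
    mass: float
    sampling_rate: float
    onset_index: int
    samples: np.ndarray

    def __post_init__(self) -> None:
        if not (0 <= self.onset_index < len(self.samples)):
            raise SynthError("onset_index out of bounds")
        if not np.all(np.isfinite(self.samples)):
            raise SynthError("samples must be finite")
        if self.sampling_rate <= 0:
            raise SynthError("sampling_rate must be positive")


@dataclass(frozen=True)
class ForceCurve:
    """Puncture force-displacement curve (displacement mm, force N)."""

    displacement: np.ndarray
    force: np.ndarray

    def __post_init__(self) -> None:
        d, f = np.asarray(self.displacement), np.asarray(self.force)
        if d.shape != f.shape:
            raise SynthError("displacement and force lengths differ")
        if d[0] != 0.0 or np.any(np.diff(d) <= 0) or d[-1] > 15.0 + 1e-9:
            raise SynthError("displacement must start at 0, strictly increase, max 15 mm")
        if not np.all(np.isfinite(f)):
            raise SynthError("force must be finite")


# --------------------------------------------------------------------------
# default cultivar profiles
# --------------------------------------------------------------------------

# Resonance anchors sit at the printed cultivar mean firmness; the firmest
# profile gets a negative f1 slope so the pooled f1-firmness relation is
# non-monotonic while within-cultivar slopes stay interpretable.
def default_profiles() -> dict[str, CultivarProfile]:
    """The three default cultivar profiles (fresh copies)."""
    return {
        "hujing": CultivarProfile(
            name="hujing",
            f1_at_mean=841.7, f2_at_mean=1293.2, mean_firmness=2.01,
            f1_slope=5.0, f2_slope=6.0,
            firmness_range=(0.87, 5.08),
        ),
        "jinqiuhong": CultivarProfile(
            name="jinqiuhong",
            f1_at_mean=900.3, f2_at_mean=1401.9, mean_firmness=4.63,
            f1_slope=5.0, f2_slope=6.0,
            firmness_range=(1.26, 8.92),
        ),
        "dongxue": CultivarProfile(
            name="dongxue",
            f1_at_mean=665.7, f2_at_mean=1403.8, mean_firmness=6.07,
            f1_slope=-4.0, f2_slope=5.0,
            firmness_range=(2.22, 8.29),
        ),
    }


DEFAULT_PROFILES: dict[str, CultivarProfile] = default_profiles()


def new_cultivar_profile() -> CultivarProfile:
    """A soft, early-season cultivar with a shifted resonance-firmness map.

    Used for transfer-learning experiments: firmness statistics follow a
    soft white-peach population (mean 1.79 N/mm, range 0.45-4.47 N/mm) and
    both the resonance anchors and slopes differ from every default profile,
    so a model calibrated on the three default cultivars extrapolates poorly
    until fine-tuned.
    """
    return CultivarProfile(
        name="baifeng",
        f1_at_mean=760.0, f2_at_mean=1210.0, mean_firmness=1.79,
        f1_slope=45.0, f2_slope=55.0,
        damping_ratios=(0.014, 0.014),
        mode_amplitudes=(0.9, 0.75),
        highband_slope=8.0e-3,
        firmness_range=(0.45, 4.47),
        mass_range=(0.12, 0.25),
    )


# --------------------------------------------------------------------------
# signal simulation
# --------------------------------------------------------------------------


def simulate_signal(
    profile: CultivarProfile,
    firmness: float,
    mass: float,
    config: SyntheticConfig,
    seed: int,
    amplitude_scale: float = 1.0,
    highband_factor: float = 1.0,
    freq_offsets: Sequence[float] | None = None,
    mode_amp_factors: Sequence[float] | None = None,
    noise_scale: float = 1.0,
) -> VibrationRecord:
    """Simulate one excitation of one fruit.

    Deterministic given ``seed``.  The post-onset deterministic part is

        sum_k  A_k * exp(-2*pi*f_k*zeta_k*t) * sin(2*pi*f_k*sqrt(1-zeta_k^2)*t)

    multiplied by a rise envelope ``1 - exp(-t/excitation_rise)`` (identity
    when ``excitation_rise == 0``), with mode frequencies f_k taken from the
    profile at the given firmness.  The band-limited component is white noise
    shaped by a second-order resonator at ``highband_center`` and scaled to
    variance ``highband_slope * firmness`` (omitted when the slope is 0).
    """
    lo, hi = profile.firmness_range
    if not (lo <= firmness <= hi):
        raise SynthError(
            f"firmness {firmness} outside {profile.name} range [{lo}, {hi}]"
        )
    if mass <= 0:
        raise SynthError("mass must be positive")

    fs = config.sampling_rate
    n_total = int(round((config.pre_window + config.post_window) * fs))
    onset = int(round(config.pre_window * fs))
    n_post = n_total - onset

    rng = np.random.default_rng(seed)
    x = np.zeros(n_total)

    # deterministic damped multi-mode response
    t = np.arange(n_post) / fs
    freqs = profile.mode_frequencies(firmness)
    if freq_offsets is not None:
        freqs = freqs + np.asarray(freq_offsets, dtype=float)
    amps = np.asarray(profile.mode_amplitudes, dtype=float)
    if mode_amp_factors is not None:
        amps = amps * np.asarray(mode_amp_factors, dtype=float)
    resp = np.zeros(n_post)
    for A, f, z in zip(amps, freqs, profile.damping_ratios):
        fd = f * np.sqrt(1.0 - z * z)
        resp += A * np.exp(-2.0 * np.pi * f * z * t) * np.sin(2.0 * np.pi * fd * t)
    if config.excitation_rise > 0:
        resp *= 1.0 - np.exp(-t / config.excitation_rise)
    x[onset:] += amplitude_scale * resp

    # draw order is fixed so records are reproducible bit-for-bit:
    # (1) broadband sensor noise, (2) high-band innovation noise
    if config.noise_sd > 0:
        x += rng.normal(0.0, noise_scale * config.noise_sd, n_total)

    # the band-limited component exists only inside the sampled bandwidth;
    # a steep band-pass keeps the injected information localized in
    # frequency instead of leaking through shallow resonator skirts
    if profile.highband_slope > 0 and profile.highband_center < 0.95 * fs / 2:
        w = rng.standard_normal(n_post)
        half_width = 100.0
        b, a = _sig.butter(
            2,
            [profile.highband_center - half_width,
             profile.highband_center + half_width],
            btype="bandpass", fs=fs)
        band = _sig.lfilter(b, a, w)
        sd = band.std()
        if sd > 0:
            band *= np.sqrt(highband_factor * profile.highband_power(firmness)) / sd
        x[onset:] += amplitude_scale * band

    return VibrationRecord(
        fruit_id="single",
        replicate_id="r0",
        cultivar=profile.name,
        firmness=float(firmness),
        mass=float(mass),
        sampling_rate=fs,
        onset_index=onset,
        samples=x,
    )


def _truncnorm_draw(rng: np.random.Generator, mean: float, sd: float,
                    lo: float, hi: float, size: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return _stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_dataset(
    profiles: Sequence[CultivarProfile],
    n_per_cultivar: Sequence[int],
    config: SyntheticConfig,
    seed: int,
) -> list[VibrationRecord]:
    """Simulate a multi-cultivar dataset of fruit, with replicates.

    Per cultivar, fruit firmness is drawn from a normal centred at the
    profile mean with sd = range/4, truncated to the firmness range; mass is
    uniform over the profile's mass range.  Each fruit also carries a
    lognormal multiplier on its high-band power (biological scatter of the
    tissue response, sigma 0.25 in log space) so the pooled firmness /
    high-band-power correlation is strong but imperfect rather than
    deterministic.  Per-fruit biological scatter is further applied to
    the resonance frequencies (normal, sd ``profile.freq_scatter_sd``) and
    mode amplitudes (lognormal, sigma ``profile.amp_scatter_sd``), so
    resonance position is an informative but imperfect firmness proxy and
    peak amplitude is essentially uninformative, as in real fruit.
    Replicates of one fruit share firmness/mass/modal parameters and the
    per-fruit scatter but get independent noise and a small amplitude
    jitter (the repeat-excitation variability of a real rig).
    """
    profiles = list(profiles)
    if len(profiles) == 0:
        raise SynthError("need at least one cultivar profile")
    if len(n_per_cultivar) != len(profiles):
        raise SynthError("n_per_cultivar length must match profiles")
    if any(n < 1 for n in n_per_cultivar):
        raise SynthError("counts must be >= 1")

    rng = np.random.default_rng(seed)
    records: list[VibrationRecord] = []
    for profile, n in zip(profiles, n_per_cultivar):
        lo, hi = profile.firmness_range
        sd = (hi - lo) / 4.0
        firmness = _truncnorm_draw(rng, profile.mean_firmness, sd, lo, hi, n)
        mass = rng.uniform(*profile.mass_range, size=n)
        hb_factor = rng.lognormal(0.0, 0.25, size=n)
        noise_fact = rng.lognormal(0.0, 0.3, size=n)
        n_modes = profile.n_modes
        freq_off = rng.normal(0.0, profile.freq_scatter_sd, size=(n, n_modes))
        amp_fact = rng.lognormal(0.0, profile.amp_scatter_sd,
                                 size=(n, n_modes))
        for i in range(n):
            fruit_id = f"{profile.name}-{i:04d}"
            for r in range(config.replicates_per_fruit):
                jitter = float(np.clip(rng.normal(1.0, 0.05), 0.7, 1.3))
                rec_seed = int(rng.integers(0, 2**31 - 1))
                rec = simulate_signal(
                    profile, float(firmness[i]), float(mass[i]), config,
                    seed=rec_seed, amplitude_scale=jitter,
                    highband_factor=float(hb_factor[i]),
                    freq_offsets=freq_off[i], mode_amp_factors=amp_fact[i],
                    noise_scale=float(noise_fact[i]),
                )
                records.append(replace(rec, fruit_id=fruit_id, replicate_id=f"r{r}"))
    return records


# --------------------------------------------------------------------------
# puncture curves
# --------------------------------------------------------------------------


def simulate_force_curve(
    firmness: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    max_depth: float = 15.0,
    step: float = 0.05,
    yield_depth: float = 4.0,
) -> ForceCurve:
    """Toy puncture force-displacement curve with initial slope = firmness.

    Exactly linear (slope = firmness, N/mm) up to ``yield_depth`` mm, then a
    smooth softening toward a plateau -- the qualitative shape of a flesh
    puncture test.  Gaussian noise of sd ``noise_sd`` (N) is added pointwise.
    """
    if firmness <= 0:
        raise SynthError("firmness must be positive")
    d = np.arange(0.0, max_depth + step / 2, step)
    f = np.where(
        d <= yield_depth,
        firmness * d,
        firmness * yield_depth
        + firmness * 1.5 * (1.0 - np.exp(-(d - yield_depth) / 1.5)),
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, f.shape)
    return ForceCurve(displacement=d, force=f)
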