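"""Model-ready dataset assembly.

Covers the calibration bookkeeping around the spectra: reference firmness
from puncture curves (mean initial slope of three force-displacement
curves), pointwise-mean aggregation of replicate spectra, stratified
7:1:2 train/validation/test splitting with largest-remainder rounding, and
per-frequency-bin standardization fitted on the training partition only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .sigproc import (DEFAULT_F_MAX, DEFAULT_N_POINTS, Spectrum, ar_psd,
                      burg_ar)
from .synthgen import ForceCurve, VibrationRecord

__all__ = [
    "DatasetError",
    "Sample",
    "DatasetSplit",
    "Standardizer",
    "firmness_from_force_curves",
    "aggregate_replicates",
    "samples_from_records",
    "largest_remainder",
    "split_dataset",
    "fit_standardizer",
    "apply_standardizer",
    "design_matrix",
]


class DatasetError(ValueError):
    """Domain error raised by dataset assembly."""


@dataclass(frozen=True)
class Sample:
    """One fruit: aggregated spectrum plus labels."""

    fruit_id: str
    cultivar: str
    spectrum: Spectrum
    firmness: float
    mass: float

    def __post_init__(self) -> None:
        if self.firmness <= 0:
            raise DatasetError("firmness must be positive")
        if self.spectrum is None:
            raise DatasetError("spectrum is required")


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/validation/test id lists."""

    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        parts = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(p) for p in parts)
        if len(set().union(*parts)) != total:
            raise DatasetError("partitions must be pairwise disjoint")

    @property
    def all_ids(self) -> set[str]:
        return set(self.train_ids) | set(self.val_ids) | set(self.test_ids)


# --------------------------------------------------------------------------
# reference firmness
# --------------------------------------------------------------------------


def _initial_slope(curve: ForceCurve, fit_depth: float) -> float:
    mask = curve.displacement <= fit_depth + 1e-12
    if mask.sum() < 2 or curve.displacement[-1] < fit_depth:
        raise DatasetError(f"curve does not reach fit depth {fit_depth} mm")
    d = curve.displacement[mask]
    f = curve.force[mask]
    slope, _ = np.polyfit(d, f, deg=1)
    return float(slope)


def firmness_from_force_curves(
    curves: Sequence[ForceCurve],
    fit_depth: float = 2.0,
) -> float:
    """Reference firmness: mean least-squares initial slope of three curves.

    Each puncture curve is fitted with a straight line over displacement in
    [0, fit_depth] mm; the mean slope over the three measurement points is
    the fruit's firmness (N/mm).
    """
    if len(curves) < 3:
        raise DatasetError("need three force-displacement curves")
    return float(np.mean([_initial_slope(c, fit_depth) for c in curves]))


# --------------------------------------------------------------------------
# replicate aggregation and spectra
# --------------------------------------------------------------------------


def aggregate_replicates(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise mean power over replicate spectra (common grid required)."""
    if len(spectra) < 1:
        raise DatasetError("need at least one spectrum")
    grid = spectra[0].frequencies
    for s in spectra[1:]:
        if len(s) != len(grid) or not np.allclose(s.frequencies, grid):
            raise DatasetError("replicate spectra must share a frequency grid")
    power = np.mean([s.power for s in spectra], axis=0)
    source = "+".join(s.source_id for s in spectra if s.source_id)
    return Spectrum(frequencies=grid, power=power, source_id=source)


def samples_from_records(
    records: Sequence[VibrationRecord],
    ar_order: int,
    n_points: int = DEFAULT_N_POINTS,
    f_max: float = DEFAULT_F_MAX,
) -> list[Sample]:
    """Group replicate records by fruit and build one aggregated Sample each.

    Each record is reduced to its post-onset AR/Burg PSD (the stored onset is
    trusted; onset detection is available separately) and replicate spectra
    are averaged pointwise.
    """
    by_fruit: dict[str, list[VibrationRecord]] = {}
    for rec in records:
        by_fruit.setdefault(rec.fruit_id, []).append(rec)
    samples = []
    for fruit_id, recs in by_fruit.items():
        spectra = []
        for rec in recs:
            seg = np.asarray(rec.samples, dtype=float)
            model = burg_ar(seg, ar_order, sampling_rate=rec.sampling_rate)
            spectra.append(ar_psd(model, f_max=f_max, n_points=n_points,
                                  source_id=f"{fruit_id}/{rec.replicate_id}"))
        spec = aggregate_replicates(spectra)
        r0 = recs[0]
        samples.append(Sample(fruit_id=fruit_id, cultivar=r0.cultivar,
                              spectrum=spec, firmness=r0.firmness,
                              mass=r0.mass))
    return samples


# --------------------------------------------------------------------------
# splitting
# --------------------------------------------------------------------------


def largest_remainder(n: int, ratios: Sequence[float]) -> list[int]:
    """Integer partition sizes by largest-remainder rounding.

    Quotas ``n * r_j / sum(r)`` are floored; leftover units go to the
    largest fractional remainders, ties broken toward earlier partitions.
    """
    ratios = np.asarray(ratios, dtype=float)
    if np.any(ratios < 0) or ratios.sum() == 0:
        raise DatasetError("ratios must be non-negative, not all zero")
    quota = n * ratios / ratios.sum()
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    short = n - counts.sum()
    order = np.lexsort((np.arange(len(ratios)), -remainder))
    for j in order[:short]:
        counts[j] += 1
    return counts.tolist()


def split_dataset(
    samples: Sequence[Sample],
    ratios: Sequence[float] = (7, 1, 2),
    seed: int = 0,
    stratify: bool = True,
) -> DatasetSplit:
    """Stratified (by cultivar) shuffled split with largest-remainder sizes.

    Global partition sizes follow largest-remainder rounding of the ratios
    over the full sample count; within each stratum, per-stratum
    largest-remainder allocations are reconciled to those global totals by a
    deterministic greedy pass (moving single samples between partitions in
    the stratum where the rounding distortion is largest), so the split is
    simultaneously stratified and exactly sized.
    """
    if len(ratios) != 3:
        raise DatasetError("ratios must have three entries (train, val, test)")
    ids = [s.fruit_id for s in samples]
    if len(set(ids)) != len(ids):
        raise DatasetError("duplicate fruit ids")
    n = len(samples)
    if n == 0:
        raise DatasetError("no samples to split")

    strata: dict[str, list[str]] = {}
    for s in samples:
        key = s.cultivar if stratify else "all"
        strata.setdefault(key, []).append(s.fruit_id)
    names = sorted(strata)
    if any(len(strata[k]) == 0 for k in names):
        raise DatasetError("empty stratum")

    targets = np.array(largest_remainder(n, ratios))
    ratios = np.asarray(ratios, dtype=float)
    counts = np.array([largest_remainder(len(strata[k]), ratios)
                       for k in names])              # (strata, 3)
    ideal = np.array([[len(strata[k]) * r / ratios.sum() for r in ratios]
                      for k in names])

    # greedy reconciliation toward the global largest-remainder totals
    col = counts.sum(axis=0)
    while not np.array_equal(col, targets):
        j_over = int(np.argmax(col - targets))
        j_under = int(np.argmin(col - targets))
        gain = (counts[:, j_over] - ideal[:, j_over]) + \
               (ideal[:, j_under] - counts[:, j_under])
        gain = np.where(counts[:, j_over] > 0, gain, -np.inf)
        h = int(np.argmax(gain))
        counts[h, j_over] -= 1
        counts[h, j_under] += 1
        col = counts.sum(axis=0)

    rng = np.random.default_rng(seed)
    parts: list[list[str]] = [[], [], []]
    for hi, key in enumerate(names):
        stratum_ids = sorted(strata[key])
        rng.shuffle(stratum_ids)
        c = counts[hi]
        parts[0] += stratum_ids[: c[0]]
        parts[1] += stratum_ids[c[0]: c[0] + c[1]]
        parts[2] += stratum_ids[c[0] + c[1]:]
    split = DatasetSplit(tuple(parts[0]), tuple(parts[1]), tuple(parts[2]))
    assert split.all_ids == set(ids)
    return split


# --------------------------------------------------------------------------
# standardization
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Standardizer:
    """Per-bin affine transform learned from the training partition.

    ``mode='raw'`` standardizes the PSD power directly; ``mode='log10'``
    takes log10 first (the CNN input convention -- PSD dynamic range spans
    orders of magnitude).  Bins with zero training variance get sd replaced
    by 1 and are flagged.
    """

    mean: np.ndarray
    sd: np.ndarray
    degenerate: np.ndarray
    mode: Literal["raw", "log10"] = "raw"

    def transform(self, power: np.ndarray) -> np.ndarray:
        x = np.asarray(power, dtype=float)
        if x.shape[-1] != len(self.mean):
            raise DatasetError("length mismatch with fitted standardizer")
        if self.mode == "log10":
            x = np.log10(x)
        z = (x - self.mean) / self.sd
        if self.degenerate.any():
            z[..., self.degenerate] = 0.0
        return z

    def inverse(self, z: np.ndarray) -> np.ndarray:
        x = np.asarray(z, dtype=float) * self.sd + self.mean
        if self.mode == "log10":
            x = 10.0 ** x
        return x


def fit_standardizer(
    train: Sequence[Sample],
    mode: Literal["raw", "log10"] = "raw",
) -> Standardizer:
    """Fit per-bin mean/sd on the training samples only (leakage guard)."""
    if len(train) < 2:
        raise DatasetError("need at least two training samples")
    X = np.stack([s.spectrum.power for s in train])
    if mode == "log10":
        X = np.log10(X)
    elif mode != "raw":
        raise DatasetError(f"unknown standardizer mode {mode!r}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    # numerical zero variance (constant bins leave O(eps) rounding residue)
    degenerate = sd <= 1e-12 * (np.abs(mean) + np.finfo(float).tiny)
    sd = np.where(degenerate, 1.0, sd)
    return Standardizer(mean=mean, sd=sd, degenerate=degenerate, mode=mode)


def apply_standardizer(std: Standardizer, spectrum: Spectrum) -> np.ndarray:
    """Standardize one spectrum into a model-input vector."""
    return std.transform(spectrum.power)


def design_matrix(
    samples: Sequence[Sample],
    std: Standardizer,
) -> tuple[np.ndarray, np.ndarray]:
    """(X, y): standardized spectra rows and firmness targets."""
    X = np.stack([apply_standardizer(std, s.spectrum) for s in samples])
    y = np.array([s.firmness for s in samples])
    return X, y
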