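"""HDF5 / CSV / JSON persistence for records, spectra and splits.

Layout of the signal bundle: one HDF5 group per fruit carrying firmness,
mass and cultivar attributes; one dataset per replicate record with the
sampling rate and onset index as attributes.  Spectra bundles store the
frequency grid once plus one PSD dataset per fruit.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .dataset import DatasetSplit, Sample
from .sigproc import Spectrum
from .synthgen import VibrationRecord

__all__ = [
    "write_records_h5", "read_records_h5",
    "write_samples_h5", "read_samples_h5",
    "sample_table", "write_split_json", "read_split_json",
]


def write_records_h5(path: str | Path, records: Sequence[VibrationRecord]) -> None:
    with h5py.File(path, "w") as f:
        for rec in records:
            grp = f.require_group(rec.fruit_id)
            grp.attrs["cultivar"] = rec.cultivar
            grp.attrs["firmness"] = rec.firmness
            grp.attrs["mass"] = rec.mass
            ds = grp.create_dataset(rec.replicate_id, data=rec.samples)
            ds.attrs["sampling_rate"] = rec.sampling_rate
            ds.attrs["onset_index"] = rec.onset_index


def read_records_h5(path: str | Path) -> list[VibrationRecord]:
    records = []
    with h5py.File(path, "r") as f:
        for fruit_id in sorted(f):
            grp = f[fruit_id]
            for rep_id in sorted(grp):
                ds = grp[rep_id]
                records.append(VibrationRecord(
                    fruit_id=fruit_id, replicate_id=rep_id,
                    cultivar=str(grp.attrs["cultivar"]),
                    firmness=float(grp.attrs["firmness"]),
                    mass=float(grp.attrs["mass"]),
                    sampling_rate=float(ds.attrs["sampling_rate"]),
                    onset_index=int(ds.attrs["onset_index"]),
                    samples=ds[...],
                ))
    return records


def write_samples_h5(path: str | Path, samples: Sequence[Sample]) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("frequencies", data=samples[0].spectrum.frequencies)
        for s in samples:
            grp = f.require_group(s.fruit_id)
            grp.attrs["cultivar"] = s.cultivar
            grp.attrs["firmness"] = s.firmness
            grp.attrs["mass"] = s.mass
            grp.create_dataset("psd", data=s.spectrum.power)


def read_samples_h5(path: str | Path) -> list[Sample]:
    samples = []
    with h5py.File(path, "r") as f:
        freqs = f["frequencies"][...]
        for fruit_id in sorted(k for k in f if k != "frequencies"):
            grp = f[fruit_id]
            samples.append(Sample(
                fruit_id=fruit_id, cultivar=str(grp.attrs["cultivar"]),
                spectrum=Spectrum(frequencies=freqs, power=grp["psd"][...],
                                  source_id=fruit_id),
                firmness=float(grp.attrs["firmness"]),
                mass=float(grp.attrs["mass"]),
            ))
    return samples


def sample_table(samples: Sequence[Sample]) -> pd.DataFrame:
    return pd.DataFrame([{
        "fruit_id": s.fruit_id, "cultivar": s.cultivar,
        "firmness": s.firmness, "mass": s.mass,
    } for s in samples])


def write_split_json(path: str | Path, split: DatasetSplit, seed: int,
                     ratios: Sequence[float]) -> None:
    Path(path).write_text(json.dumps({
        "seed": seed, "ratios": list(ratios),
        "train": list(split.train_ids), "val": list(split.val_ids),
        "test": list(split.test_ids)}, indent=1))


def read_split_json(path: str | Path) -> DatasetSplit:
    d = json.loads(Path(path).read_text())
    return DatasetSplit(tuple(d["train"]), tuple(d["val"]), tuple(d["test"]))
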