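"""Shared fixtures.

The expensive artifacts (the full three-cultivar synthetic dataset, its
spectra, and trained networks) are session-scoped so the whole suite pays
for them once.  All seeds are fixed.
"""

from __future__ import annotations

import numpy as np
import pytest

from vibrofirm import baselines, dataset, isnet1d, synthgen

REDUCED_FS = 12500.0          # keeps the 0-5 kHz band; desk-scale AR fits
REDUCED_AR_ORDER = 50
DATASET_SEED = 7
N_PER_CULTIVAR = (128, 167, 176)


@pytest.fixture(scope="session")
def reduced_config() -> synthgen.SyntheticConfig:
    return synthgen.SyntheticConfig(sampling_rate=REDUCED_FS)


@pytest.fixture(scope="session")
def profiles() -> dict[str, synthgen.CultivarProfile]:
    return synthgen.default_profiles()


@pytest.fixture(scope="session")
def full_records(reduced_config, profiles):
    return synthgen.simulate_dataset(
        list(profiles.values()), N_PER_CULTIVAR, reduced_config,
        seed=DATASET_SEED,
    )


@pytest.fixture(scope="session")
def full_samples(full_records):
    return dataset.samples_from_records(full_records,
                                        ar_order=REDUCED_AR_ORDER)


@pytest.fixture(scope="session")
def pipeline_parts(full_samples):
    """Split + standardizers + design matrices for all three partitions."""
    split = dataset.split_dataset(full_samples, (7, 1, 2), seed=DATASET_SEED)
    by_id = {s.fruit_id: s for s in full_samples}
    parts = {k: [by_id[i] for i in ids] for k, ids in
             (("train", split.train_ids), ("val", split.val_ids),
              ("test", split.test_ids))}
    std_raw = dataset.fit_standardizer(parts["train"], "raw")
    std_log = dataset.fit_standardizer(parts["train"], "log10")
    out = {"split": split, "parts": parts, "std_raw": std_raw,
           "std_log": std_log, "samples": full_samples}
    for mode, std in (("raw", std_raw), ("log", std_log)):
        for k in parts:
            out[f"{mode}_{k}"] = dataset.design_matrix(parts[k], std)
    return out


def _train_isnet(pipeline_parts, seed: int):
    Xtr, ytr = pipeline_parts["log_train"]
    Xva, yva = pipeline_parts["log_val"]
    cfg = isnet1d.TrainConfig(max_epochs=60, early_stopping_patience=15,
                              seed=seed)
    net = isnet1d.build_isnet(isnet1d.ISNetConfig(), seed=seed)
    return isnet1d.train(net, Xtr, ytr, Xva, yva, cfg)


@pytest.fixture(scope="session")
def trained_isnet(pipeline_parts):
    """One trained network, shared by the saliency and transfer tests."""
    trained, _ = _train_isnet(pipeline_parts, seed=3)
    return trained


@pytest.fixture(scope="session")
def isnet_seed_runs(pipeline_parts, trained_isnet):
    """Test-set predictions for three training seeds (reuses the shared net)."""
    runs = {3: trained_isnet}
    for seed in (4, 5):
        runs[seed], _ = _train_isnet(pipeline_parts, seed=seed)
    return runs


@pytest.fixture(scope="session")
def plsr_fit(pipeline_parts):
    Xtr, ytr = pipeline_parts["raw_train"]
    Xva, yva = pipeline_parts["raw_val"]
    n_lv = baselines.select_latent_variables(Xtr, ytr, Xva, yva, max_lv=60)
    return baselines.fit_plsr(Xtr, ytr, n_lv)
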