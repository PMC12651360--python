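"""Model evaluation, comparison arithmetic, and the pipeline orchestrator.

Metrics follow the standard chemometric conventions:

    RMSE = sqrt( (1/n) sum (y_i - yhat_i)^2 )
    R^2  = 1 - sum (y_i - yhat_i)^2 / sum (y_i - ybar)^2
    RPD  = SD / RMSE

where SD is the *sample* standard deviation (n-1 denominator) of the
measured values.  With the population SD (n denominator) instead, the exact
identity RPD = 1 / sqrt(1 - R^2) holds whenever both are computed on the
same partition; reported RPDs use the sample convention.

Relative model comparison uses (candidate - baseline) / baseline * 100 on
the printed scale, rounded to two decimals.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "EvaluationError",
    "MetricsReport",
    "ComparisonReport",
    "RunConfig",
    "metrics",
    "relative_change",
    "compare",
    "run_pipeline",
]

log = logging.getLogger("vibrofirm")


class EvaluationError(ValueError):
    """Domain error raised by the evaluation stage."""


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricsReport:
    """R^2 / RMSE / RPD for one dataset partition."""

    label: str
    n: int
    r2: float
    rmse: float
    sd: float
    rpd: float
    mean: float
    degenerate: bool = False

    def rounded(self, ndigits: int = 4) -> dict:
        out = dataclasses.asdict(self)
        for k in ("r2", "rmse", "sd", "rpd", "mean"):
            v = out[k]
            out[k] = round(v, ndigits) if np.isfinite(v) else v
        return out


def metrics(y, yhat, label: str = "", sd_ddof: int = 1) -> MetricsReport:
    """Compute R^2, RMSE and RPD for one partition.

    ``sd_ddof=1`` (default) uses the sample standard deviation in RPD;
    ``sd_ddof=0`` the population convention, under which
    RPD == 1/sqrt(1 - R^2) exactly.  A constant reference vector yields a
    degenerate report (R^2/RPD undefined -> NaN); a perfect fit yields
    RMSE = 0 and RPD = inf with the degenerate flag set.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape or y.size < 2:
        raise EvaluationError("need equal-length y/yhat with n >= 2")
    n = y.size
    resid = y - yhat
    rmse = float(np.sqrt(np.mean(resid**2)))
    ybar = float(np.mean(y))
    ss_tot = float(np.sum((y - ybar) ** 2))
    sd = float(np.std(y, ddof=sd_ddof))
    if ss_tot == 0.0:
        return MetricsReport(label=label, n=n, r2=np.nan, rmse=rmse, sd=sd,
                             rpd=np.nan, mean=ybar, degenerate=True)
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    if rmse == 0.0:
        return MetricsReport(label=label, n=n, r2=r2, rmse=0.0, sd=sd,
                             rpd=np.inf, mean=ybar, degenerate=True)
    return MetricsReport(label=label, n=n, r2=r2, rmse=rmse, sd=sd,
                         rpd=sd / rmse, mean=ybar)


def relative_change(baseline: float, candidate: float) -> float:
    """(candidate - baseline) / baseline * 100, rounded to 2 decimals."""
    if baseline == 0:
        raise EvaluationError("baseline must be nonzero")
    return round((candidate - baseline) / baseline * 100.0, 2)


@dataclass(frozen=True)
class ComparisonReport:
    """Relative change of one metric between two models."""

    metric: str
    baseline: float
    candidate: float
    change_pct: float
    higher_is_better: bool

    @property
    def improved(self) -> bool:
        return (self.change_pct > 0) == self.higher_is_better


def compare(metric: str, baseline: float, candidate: float,
            higher_is_better: bool = True) -> ComparisonReport:
    return ComparisonReport(
        metric=metric, baseline=baseline, candidate=candidate,
        change_pct=relative_change(baseline, candidate),
        higher_is_better=higher_is_better,
    )


# --------------------------------------------------------------------------
# pipeline orchestration
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end pipeline configuration, YAML round-trippable.

    ``n_per_cultivar`` follows the default cultivar profile order
    (hujing, jinqiuhong, dongxue).  The reduced sampling rate keeps the AR
    stage desk-scale while preserving the 0-5 kHz analysis band.
    """

    seed: int = 7
    n_per_cultivar: tuple[int, ...] = (128, 167, 176)
    sampling_rate: float = 12500.0
    ar_order: int = 50
    replicates_per_fruit: int = 3
    split_ratios: tuple[int, int, int] = (7, 1, 2)
    max_lv: int = 60
    svr_budget: int = 40
    nn_max_epochs: int = 80
    nn_patience: int = 15
    out_dir: str = "run"

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("n_per_cultivar", "split_ratios"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _hash_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a, dtype=np.float64).tobytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Simulate, preprocess, split, fit all three models, evaluate, explain.

    Writes a metrics CSV (model x partition x R^2/RMSE/RPD), a comparison
    report, split manifest, training history and saliency maps under
    ``out_dir``; returns everything as a dict as well.  All randomness
    descends from ``config.seed``.
    """
    from . import baselines, dataset, interpret, isnet1d, synthgen

    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
             for s in root.spawn(5)]
    log.info("pipeline start: seed=%d -> stage seeds %s", config.seed, seeds)

    profiles = list(synthgen.default_profiles().values())
    syn_cfg = synthgen.SyntheticConfig(
        sampling_rate=config.sampling_rate,
        replicates_per_fruit=config.replicates_per_fruit,
    )
    records = synthgen.simulate_dataset(profiles, config.n_per_cultivar,
                                        syn_cfg, seed=seeds[0])
    log.info("simulated %d records (%d fruits)", len(records),
             sum(config.n_per_cultivar))

    samples = dataset.samples_from_records(records, ar_order=config.ar_order)
    spectra_hash = _hash_array(np.stack([s.spectrum.power for s in samples]))
    log.info("spectra computed: hash %s", spectra_hash)

    split = dataset.split_dataset(samples, ratios=config.split_ratios,
                                  seed=seeds[1])
    by_id = {s.fruit_id: s for s in samples}
    parts = {k: [by_id[i] for i in ids] for k, ids in
             (("train", split.train_ids), ("val", split.val_ids),
              ("test", split.test_ids))}
    (out / "split.json").write_text(json.dumps({
        "seed": seeds[1], "ratios": list(config.split_ratios),
        "train": list(split.train_ids), "val": list(split.val_ids),
        "test": list(split.test_ids)}, indent=1))

    std_raw = dataset.fit_standardizer(parts["train"], mode="raw")
    std_log = dataset.fit_standardizer(parts["train"], mode="log10")
    XY = {m: {k: dataset.design_matrix(parts[k], std)
              for k in parts}
          for m, std in (("raw", std_raw), ("log", std_log))}

    results: dict = {"config": dataclasses.asdict(config),
                     "spectra_hash": spectra_hash, "metrics": {}}
    rows = []

    def record_metrics(model_name, part, rep):
        results["metrics"].setdefault(model_name, {})[part] = rep.rounded()
        rows.append({"model": model_name, "partition": part,
                     "n": rep.n, "R2": round(rep.r2, 4),
                     "RMSE": round(rep.rmse, 4), "RPD": round(rep.rpd, 4)})

    # --- PLSR ------------------------------------------------------------
    (Xtr, ytr), (Xva, yva), (Xte, yte) = (XY["raw"][k] for k in
                                          ("train", "val", "test"))
    n_lv = baselines.select_latent_variables(Xtr, ytr, Xva, yva,
                                             max_lv=config.max_lv)
    pls = baselines.fit_plsr(Xtr, ytr, n_lv)
    log.info("PLSR: %d latent variables", n_lv)
    results["plsr_n_latent"] = n_lv
    for part, (X, y) in (("train", (Xtr, ytr)), ("val", (Xva, yva)),
                         ("test", (Xte, yte))):
        record_metrics("PLSR", part, metrics(y, pls.predict(X), label=part))

    # --- PCA + SVR -------------------------------------------------------
    basis = baselines.fit_pca_95(Xtr)
    Ztr, Zva, Zte = (basis.transform(X) for X in (Xtr, Xva, Xte))
    search = baselines.bayes_opt_svr((Ztr, ytr), (Zva, yva),
                                     budget=config.svr_budget, seed=seeds[2])
    best = search.best_config
    svr = baselines.fit_svr(Ztr, ytr, **best)
    log.info("SVR: retained %d PCs, best %s (val RMSE %.4f)",
             basis.retained, best, search.best_score)
    results["pca_retained"] = basis.retained
    results["svr_best"] = {k: (v if isinstance(v, str) else float(v))
                           for k, v in best.items()}
    for part, (Z, y) in (("train", (Ztr, ytr)), ("val", (Zva, yva)),
                         ("test", (Zte, yte))):
        record_metrics("SVR", part, metrics(y, svr.predict(Z), label=part))

    # --- ISNet-1D --------------------------------------------------------
    (Ltr, _), (Lva, _), (Lte, _) = (XY["log"][k] for k in
                                    ("train", "val", "test"))
    net_cfg = isnet1d.ISNetConfig()
    train_cfg = isnet1d.TrainConfig(max_epochs=config.nn_max_epochs,
                                    early_stopping_patience=config.nn_patience,
                                    seed=seeds[3])
    net = isnet1d.build_isnet(net_cfg, seed=seeds[3])
    trained, history = isnet1d.train(net, Ltr, ytr, Lva, yva, train_cfg,
                                     isnet_config=net_cfg)
    log.info("ISNet-1D: best epoch %d / %d recorded", trained.best_epoch,
             len(history.val_loss))
    pd.DataFrame({"epoch": np.arange(1, len(history.train_loss) + 1),
                  "train_loss": history.train_loss,
                  "val_loss": history.val_loss}).to_csv(
        out / "isnet_history.csv", index=False)
    for part, (X, y) in (("train", (Ltr, ytr)), ("val", (Lva, yva)),
                         ("test", (Lte, yte))):
        record_metrics("ISNet-1D", part,
                       metrics(y, isnet1d.predict(trained, X), label=part))

    # --- comparison report ----------------------------------------------
    m = results["metrics"]
    comparisons = [
        compare("test R2", m["SVR"]["test"]["r2"],
                m["ISNet-1D"]["test"]["r2"], higher_is_better=True),
        compare("test RMSE", m["SVR"]["test"]["rmse"],
                m["ISNet-1D"]["test"]["rmse"], higher_is_better=False),
        compare("test RPD", m["SVR"]["test"]["rpd"],
                m["ISNet-1D"]["test"]["rpd"], higher_is_better=True),
    ]
    results["comparison"] = [dataclasses.asdict(c) for c in comparisons]

    # --- saliency for a few test samples ---------------------------------
    grid = samples[0].spectrum.frequencies
    sal_rows = {}
    for s in parts["test"][:3]:
        x = dataset.apply_standardizer(std_log, s.spectrum)
        sal = interpret.grad_cam_1d(trained, x, source_id=s.fruit_id)
        sal_rows[s.fruit_id] = sal.values
    pd.DataFrame({"frequency_hz": grid, **sal_rows}).to_csv(
        out / "saliency.csv", index=False)

    table = pd.DataFrame(rows)
    table.to_csv(out / "metrics.csv", index=False)
    (out / "results.json").write_text(json.dumps(results, indent=1,
                                                 default=float))
    log.info("pipeline done: artifacts in %s", out)
    results["_artifacts"] = {"out_dir": str(out), "samples": samples,
                             "split": split, "standardizer_log": std_log,
                             "standardizer_raw": std_raw, "trained": trained,
                             "pls": pls, "svr": svr, "grid": grid}
    return results
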