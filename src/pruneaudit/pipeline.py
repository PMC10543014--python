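"""Orchestration: generate -> train population -> prune sweep -> analysis.

One call runs the whole audit under a single base seed and writes every
artifact (dataset, AP table, significance sweep, forgettability curves,
pair statistics + regression, PIE report) plus a manifest with the config
hash, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import forget, pies, synth
from .classifier import DEFAULT_GRID, train_population
from .metrics import APTable, build_ap_table, mean_ap, welch_t_test
from .prune import SparsityGrid

__all__ = ["ExperimentConfig", "run_experiment", "significance_sweep"]

log = logging.getLogger("pruneaudit")


@dataclass
class ExperimentConfig:
    """Everything one audit run needs; all randomness flows from ``seed``."""

    # synthetic-data scenario; the defaults are the reference study
    # conditions: a 150x head-to-tail prevalence span, rare classes given
    # weak feature signal, and the five rarest classes made to visually
    # resemble one head class each (see docs/methods.md)
    C: int = 20
    N: int = 5000
    D: int = 64
    head_prevalence: float = 0.3
    tail_prevalence: float = 0.002
    cooccur_pairs: list = field(default_factory=list)
    noise_sd: float = 1.0
    head_signal: float = 2.5
    tail_signal: float = 0.35
    n_resembling: int = 5  # rarest classes whose prototypes mimic a head class
    resemblance: float = 0.85  # cosine between a mimicking prototype and its partner
    # model / population
    hidden_units: int = 256
    epochs: int = 10
    learning_rate: float = 3.0
    weight_decay: float = 0.0
    R: int = 10
    grid: list = field(default_factory=lambda: list(DEFAULT_GRID))
    # analysis
    pie_fraction: float = 0.05
    comparator_k: float = 0.9
    alpha: float = 0.001
    drop: float = 0.20
    seed: int = 0

    def __post_init__(self):
        SparsityGrid(self.grid)  # validates
        if self.R < 2:
            raise ValueError("R must be >= 2")
        if len(self.grid) > 1 and float(self.comparator_k) not in [float(g) for g in self.grid]:
            raise ValueError(f"comparator_k={self.comparator_k} not in grid")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def content_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def significance_sweep(table: APTable, alpha: float = 0.001) -> dict:
    """First sparsity with a significant *drop* in mean AP vs. k=0.

    For each k > 0, Welch's t-test compares the per-run mean APs at k=0 and
    at k across the population; the first k with p < alpha and a lower mean
    is reported (None if no such k). A significant increase never counts.
    No multiplicity correction is applied across the grid comparisons.
    """
    grid = table.grid.values
    base = np.array([mean_ap(table, i, 0.0) for i in range(table.n_runs)])
    per_k = []
    first = None
    for k in grid[1:]:
        at_k = np.array([mean_ap(table, i, k) for i in range(table.n_runs)])
        t, p, df = welch_t_test(base, at_k)
        dropped = at_k.mean() < base.mean()
        per_k.append(
            {"k": float(k), "t": t, "p": p, "df": df,
             "mean_ap": float(at_k.mean()), "dropped": bool(dropped)}
        )
        if first is None and p < alpha and dropped:
            first = float(k)
    return {
        "alpha": float(alpha),
        "mean_ap_at_0": float(base.mean()),
        "per_k": per_k,
        "first_significant_k": first,
    }


def run_experiment(cfg: ExperimentConfig, out_dir) -> dict:
    """Run the full audit and write artifacts under ``out_dir``.

    Returns a bundle dict with the in-memory results. On a stage failure,
    artifacts written so far are preserved and the manifest records the
    failure point.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.content_hash(),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "stages": {},
        "artifact_hashes": {},
    }
    bundle: dict = {"config": cfg}

    def _finish_stage(name, *paths):
        manifest["stages"][name] = "ok"
        for p in paths:
            manifest["artifact_hashes"][p.name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        _write_manifest()

    def _write_manifest():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    stage = "generate"
    try:
        structure = synth.sample_class_structure(
            cfg.C, cfg.head_prevalence, cfg.tail_prevalence, cfg.cooccur_pairs,
            seed=cfg.seed, head_signal=cfg.head_signal, tail_signal=cfg.tail_signal,
        )
        overlap = [
            (cfg.C - 1 - j, j, cfg.resemblance)
            for j in range(min(cfg.n_resembling, cfg.C // 2))
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            ds = synth.generate_dataset(
                structure, cfg.N, cfg.D, cfg.noise_sd, seed=cfg.seed,
                prototype_overlap=overlap,
            )
        synth.save_dataset(ds, out / "dataset.npz", out / "dataset.json")
        bundle["dataset"] = ds
        bundle["structure"] = structure
        _finish_stage(stage, out / "dataset.json")
        log.info("generated dataset N=%d C=%d", ds.n_samples, ds.n_classes)

        stage = "train_population"
        pop = train_population(
            ds, R=cfg.R, grid=cfg.grid, base_seed=cfg.seed,
            hidden_units=cfg.hidden_units, epochs=cfg.epochs,
            learning_rate=cfg.learning_rate, weight_decay=cfg.weight_decay,
        )
        bundle["population"] = pop
        manifest["stages"][stage] = "ok"
        manifest["run_seeds"] = pop.seeds
        _write_manifest()

        stage = "ap_table"
        _, y_test = ds.subset("test")
        table = build_ap_table(pop, y_test)
        table.to_frame().to_csv(out / "ap_table.csv", index=False)
        bundle["ap_table"] = table
        _finish_stage(stage, out / "ap_table.csv")

        stage = "significance_sweep"
        sweep = significance_sweep(table, alpha=cfg.alpha) if len(cfg.grid) > 1 else {
            "alpha": cfg.alpha, "per_k": [], "first_significant_k": None,
            "mean_ap_at_0": float(np.mean([mean_ap(table, i, 0.0) for i in range(table.n_runs)])),
        }
        (out / "significance.json").write_text(json.dumps(sweep, indent=2))
        bundle["significance"] = sweep
        _finish_stage(stage, out / "significance.json")

        stage = "forgettability"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            curves = forget.forgettability_curves(table)
        rows = [
            {"class": name, "sparsity": k, "value": v}
            for name, curve in curves.items()
            for k, v in zip(curve.grid.values, curve.values)
        ]
        pd.DataFrame(rows).to_csv(out / "curves.csv", index=False)
        bundle["curves"] = curves
        _finish_stage(stage, out / "curves.csv")

        stage = "pair_stats"
        pairs = forget.build_pair_stats(curves, y_test, ds.class_names)
        pd.DataFrame(
            [
                {"class_a": p.class_a, "class_b": p.class_b, "fcd": p.fcd,
                 "log_freq_diff": p.log_freq_diff, "iou": p.iou}
                for p in pairs
            ]
        ).to_csv(out / "pairs.csv", index=False)
        bundle["pairs"] = pairs
        if len(pairs) >= 5:
            fit = forget.fit_fcd_regression(pairs)
            (out / "regression.json").write_text(json.dumps(fit.as_dict(), indent=2))
            bundle["regression"] = fit
            _finish_stage(stage, out / "pairs.csv", out / "regression.json")
        else:
            manifest["stages"][stage] = "skipped: fewer than 5 defined pairs"
            _write_manifest()

        stage = "pies"
        if len(cfg.grid) > 1 and float(cfg.comparator_k) in [float(g) for g in cfg.grid]:
            report = pies.build_pie_report(
                pop, y_test, comparator_k=cfg.comparator_k, fraction=cfg.pie_fraction
            )
            pd.DataFrame(
                {
                    "image_id": np.arange(len(report.per_image_corr)),
                    "correlation": report.per_image_corr,
                    "is_pie": report.pie_mask.astype(int),
                }
            ).to_csv(out / "pie_report.csv", index=False)
            (out / "pie_summary.json").write_text(
                json.dumps(
                    {
                        "threshold": report.threshold,
                        "comparator_sparsity": report.comparator_sparsity,
                        "fraction": report.fraction,
                        "n_pies": int(report.pie_mask.sum()),
                        "class_ratio": {
                            n: (None if np.isnan(r) else float(r))
                            for n, r in zip(ds.class_names, report.class_ratio)
                        },
                        "count_ratio": {
                            d: (None if np.isnan(r) else float(r))
                            for d, r in report.count_ratio.items()
                        },
                    },
                    indent=2,
                )
            )
            bundle["pie_report"] = report
            _finish_stage(stage, out / "pie_report.csv", out / "pie_summary.json")
        else:
            manifest["stages"][stage] = (
                f"skipped: comparator sparsity {cfg.comparator_k} not in grid"
            )
            _write_manifest()
            log.info("PIE stage skipped: no comparator sparsity in grid")
    except Exception as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        _write_manifest()
        raise

    return bundle
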