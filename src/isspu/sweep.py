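"""Reproducible imbalance-sweep harness.

Runs ISS and baseline classifiers over a grid of minority:majority ratios
(a:b from 1:99 up to 50:50) with repeated seeded trials on a synthetic
scene, records OA, per-class F1, minority F1 and the disagreement measures
per trial, and summarises mean ± std curves per method and ratio.  All
randomness flows from the single config seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ensemble import (
    SampleSet,
    SimulatorConfig,
    derive_seed,
    fit_aio_baseline,
    fit_iss,
    fit_one_vs_rest_baseline,
)
from .metrics import confusion_matrix, evaluate_confusion
from .synthetic import (
    ImbalanceDesign,
    SyntheticScene,
    generate_scene,
    sample_training_sets,
    smote_balance,
)

logger = logging.getLogger("isspu")

KNOWN_METHODS = ("iss", "aio-gbt", "aio-rf", "aio-mlp", "aio-svm",
                 "one-vs-rest", "smote-gbt", "smote-rf", "smote-mlp",
                 "smote-svm")


@dataclass
class SweepConfig:
    """Everything one sweep needs; serialisable to/from YAML."""

    ratios: list[tuple[int, int]] = field(
        default_factory=lambda: [(2, 98), (10, 90), (50, 50)])
    trials: int = 10
    methods: tuple[str, ...] = ("iss", "aio-gbt")
    J: int = 10
    per_majority: int = 1000
    test_size: int = 5000
    seed: int = 0
    scene: dict = field(default_factory=lambda: {
        "n_classes": 6, "size": (128, 128), "spatial_scale": 8.0,
        "spectral_separability": 3.0, "n_bands": 3})
    minority_class: int = 0
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        unknown = set(self.methods) - set(KNOWN_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}; "
                             f"choose from {KNOWN_METHODS}")
        for a, b in self.ratios:
            ImbalanceDesign(a=a, b=b, per_majority=self.per_majority,
                            minority_class=self.minority_class)

    @classmethod
    def from_yaml(cls, path) -> "SweepConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "ratios" in raw:
            raw["ratios"] = [tuple(r) for r in raw["ratios"]]
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        if "simulator" in raw:
            raw["simulator"] = SimulatorConfig(**raw["simulator"])
        if "scene" in raw and "size" in raw["scene"]:
            raw["scene"]["size"] = tuple(raw["scene"]["size"])
        return cls(**raw)


def _fit_method(method: str, train: SampleSet, pool: np.ndarray,
                config: SweepConfig, seed: int):
    if method == "iss":
        return fit_iss(train, pool, J=config.J, config=config.simulator,
                       seed=seed)
    if method.startswith("aio-"):
        return fit_aio_baseline(train, backend=method[4:],
                                config=config.simulator, seed=seed)
    if method == "one-vs-rest":
        return fit_one_vs_rest_baseline(train, config=config.simulator,
                                        seed=seed)
    if method.startswith("smote-"):
        balanced = smote_balance(train, k=5, seed=seed)
        return fit_aio_baseline(balanced, backend=method[6:],
                                config=config.simulator, seed=seed)
    raise ValueError(f"unknown method {method!r}")


def run_trial(method: str, scene: SyntheticScene, ratio: tuple[int, int],
              trial: int, config: SweepConfig) -> dict:
    """One (method, ratio, trial) evaluation; returns a result record."""
    a, b = ratio
    seed = derive_seed(config.seed, a, b, trial)
    design = ImbalanceDesign(a=a, b=b, minority_class=config.minority_class,
                             per_majority=config.per_majority,
                             test_size=config.test_size, seed=seed)
    train, test = sample_training_sets(scene, design)
    pool, _ = scene.pixel_table()
    model = _fit_method(method, train, pool, config, seed)
    pred = model.predict(test.X)
    cm = confusion_matrix(test.y, pred, train.classes)
    rep = evaluate_confusion(cm, minority=config.minority_class)
    return {
        "method": method, "a": a, "b": b, "trial": trial, "seed": seed,
        "oa": rep.oa, "minority_f1": rep.f1[config.minority_class],
        "qd": rep.qd, "ad": rep.ad,
        "minority_qd": rep.minority_qd, "minority_ad": rep.minority_ad,
        "f1_json": json.dumps({str(k): v for k, v in rep.f1.items()}),
        "error": "",
    }


def run_sweep(config: SweepConfig,
              scene: SyntheticScene | None = None) -> pd.DataFrame:
    """Full sweep: one row per (method, ratio, trial); failures recorded.

    The scene is generated once from the config seed (or supplied) and
    shared across all trials; per-trial randomness covers the sampling
    draws and model fits.
    """
    if scene is None:
        scene = generate_scene(seed=derive_seed(config.seed, 999),
                               **config.scene)
    rows = []
    for a, b in config.ratios:
        for method in config.methods:
            for trial in range(config.trials):
                try:
                    rows.append(run_trial(method, scene, (a, b), trial,
                                          config))
                except Exception as exc:   # record, never drop silently
                    logger.exception("trial failed: %s a:b=%d:%d trial=%d",
                                     method, a, b, trial)
                    rows.append({"method": method, "a": a, "b": b,
                                 "trial": trial, "seed": -1,
                                 "oa": np.nan, "minority_f1": np.nan,
                                 "qd": np.nan, "ad": np.nan,
                                 "minority_qd": np.nan,
                                 "minority_ad": np.nan, "f1_json": "{}",
                                 "error": f"{type(exc).__name__}: {exc}"})
    df = pd.DataFrame(rows)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "results.csv", index=False)
    return df


def summarize(results: pd.DataFrame, out_dir: str | None = None,
              plot: bool = False) -> pd.DataFrame:
    """Per-(method, ratio) mean/std curves plus box-plot statistics."""
    if results.empty:
        raise ValueError("empty results table")
    if results.duplicated(["method", "a", "b", "trial"]).any():
        raise ValueError("results table mixes several sweep configurations "
                         "(duplicate method/ratio/trial rows)")
    ok = results[results["error"] == ""] if "error" in results else results
    rows = []
    for (method, a, b), grp in ok.groupby(["method", "a", "b"], sort=True):
        rec = {"method": method, "a": a, "b": b, "n_trials": len(grp)}
        for col in ("oa", "minority_f1", "qd", "ad", "minority_qd",
                    "minority_ad"):
            v = grp[col].to_numpy(dtype=float)
            finite = v[np.isfinite(v)]
            rec[f"{col}_mean"] = float(finite.mean()) if finite.size \
                else float("nan")
            rec[f"{col}_std"] = float(finite.std(ddof=1)) \
                if finite.size > 1 else 0.0
        q1, med, q3 = np.nanpercentile(grp["minority_f1"], [25, 50, 75])
        rec.update({"minority_f1_q1": q1, "minority_f1_median": med,
                    "minority_f1_q3": q3})
        rows.append(rec)
    summary = pd.DataFrame(rows)
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "summary.csv", index=False)
        if plot:
            _plot_curves(summary, out)
    return summary


def _plot_curves(summary: pd.DataFrame, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for col, title in (("oa_mean", "Overall accuracy (%)"),
                       ("minority_f1_mean", "Minority-class F1")):
        fig, ax = plt.subplots(figsize=(6, 4))
        for method, grp in summary.groupby("method"):
            grp = grp.sort_values("a")
            ax.errorbar(grp["a"], grp[col],
                        yerr=grp[col.replace("_mean", "_std")],
                        marker="o", capsize=3, label=method)
        ax.set_xlabel("minority share a (of a:b)")
        ax.set_ylabel(title)
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / f"{col}.png", dpi=120)
        plt.close(fig)
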