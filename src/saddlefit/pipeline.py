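"""End-to-end run orchestration.

``run_pipeline`` executes simulate → segment → extract → balance → select →
evaluate → stats, writing every stage's artifact plus the verbatim config
snapshot into the output directory. Re-running with the same config
reproduces all outputs (every stochastic stage is re-seeded
deterministically from the one root seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from saddlefit import simulator
from saddlefit.dataset import LabeledDataset, smote_balance
from saddlefit.features import FeatureTable, build_feature_table, normalize_columns
from saddlefit.modeling import SaddleHeightModel
from saddlefit.preprocess import segment_recording
from saddlefit import stats as sstats

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated configuration of one full pipeline run."""

    seed: int = 0
    n_subjects: int = 16
    n_cycles: int = 30
    models: tuple[str, ...] = ("svm", "knn", "nb", "dt")
    selection_model: str = "knn"
    leakage_mode: str = "paper"
    normalize: bool = True
    smote: bool = True
    k_neighbors: int = 5
    folds: int = 5
    sfs_tol: float = 1e-4
    max_features: int | None = 20
    tune: bool = False
    tune_budget: int = 30
    simulation: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.leakage_mode not in ("paper", "strict"):
            raise ValueError("leakage_mode must be 'paper' or 'strict'")
        unknown = set(self.models) - {"svm", "knn", "nb", "dt"}
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["models"] = list(d["models"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)


def simulate_stage(config: RunConfig, out: Path) -> list[simulator.KinematicRecording]:
    sim_cfg = simulator.SimulationConfig(
        n_cycles=config.n_cycles, seed=config.seed, **config.simulation)
    cohort = simulator.generate_cohort(config.n_subjects, sim_cfg)
    sim_dir = out / "sim"
    for rec in cohort:
        simulator.write_recording(rec, sim_dir)
    return cohort


def segment_stage(cohort, out: Path):
    all_cycles, rows = [], []
    for rec in cohort:
        cycles, excluded = segment_recording(rec)
        all_cycles.extend(cycles)
        for c in cycles:
            rows.append({"subject_id": rec.subject_id, "level": rec.label,
                         "cycle_ordinal": c.cycle_ordinal, "kept": True,
                         "reason": ""})
        for e in excluded:
            rows.append({"subject_id": rec.subject_id, "level": rec.label,
                         "cycle_ordinal": -1, "kept": False,
                         "reason": e["reason"]})
    pd.DataFrame(rows).to_csv(out / "cycles.csv", index=False)
    return all_cycles


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run every stage and write artifacts under ``out_dir``; returns it.

    Artifacts: ``config.yaml``, ``sim/``, ``cycles.csv``, ``features.csv``,
    ``balanced.csv``, ``selected.yaml``, ``report.json``, ``report.csv``,
    ``stats.json``.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    log.info("stage simulate: %d subjects x 3 levels x %d cycles",
             config.n_subjects, config.n_cycles)
    cohort = simulate_stage(config, out)

    log.info("stage segment")
    cycles = segment_stage(cohort, out)

    log.info("stage extract: %d cycles", len(cycles))
    table = build_feature_table(cycles)
    table.to_csv(out / "features.csv")

    log.info("stage balance (SMOTE, k=%d)", config.k_neighbors)
    normed = normalize_columns(table)
    pd.Series({k: float(v) for k, v in normed.scales.items()}).to_frame("scale") \
        .rename_axis("feature").to_csv(out / "scales.csv")
    data = LabeledDataset.from_feature_table(normed)
    if config.smote:
        data = smote_balance(data, k_neighbors=config.k_neighbors,
                             seed=config.seed)
    data.to_csv(out / "balanced.csv")

    log.info("stage select (forward SFS, %s wrapper)", config.selection_model)
    model = SaddleHeightModel(table)
    results = model.fit(
        models=config.models, selection_model=config.selection_model,
        folds=config.folds, tol=config.sfs_tol,
        max_features=config.max_features, leakage_mode=config.leakage_mode,
        tune=config.tune, budget=config.tune_budget,
        k_neighbors=config.k_neighbors, seed=config.seed, smote=config.smote)

    (out / "selected.yaml").write_text(yaml.safe_dump({
        "selected": results.selection.selected,
        "trace": [float(t) for t in results.selection.trace],
        "stop_reason": results.selection.stop_reason,
    }, sort_keys=False))
    results.report.to_json(out / "report.json")
    results.report.summary_frame().to_csv(out / "report.csv")

    log.info("stage stats")
    subset = results.selection.selected or list(table.X.columns)
    stats_out: dict = {"features": {}}
    for feat in subset:
        cond = sstats.build_condition_table(table, feat)
        fr = sstats.friedman_test(cond)
        entry = {"friedman_chi2": fr.statistic, "friedman_p": fr.pvalue,
                 "degenerate": fr.degenerate, "pairwise": []}
        if fr.pvalue < sstats.ALPHA and len(cond) >= 5:
            for pw in sstats.wilcoxon_posthoc_bonferroni(cond):
                entry["pairwise"].append(dataclasses.asdict(pw))
        stats_out["features"][feat] = entry
    normed_sub = normalize_columns(table).X[subset]
    corr = sstats.pearson_categorize(normed_sub)
    stats_out["correlation"] = {
        "r": corr.r.round(6).to_dict(),
        "categories": corr.categories.to_dict(),
    }
    (out / "stats.json").write_text(json.dumps(stats_out, indent=2))
    (out / "summary.txt").write_text(results.summary() + "\n")
    log.info("pipeline complete: %s", out)
    return out
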