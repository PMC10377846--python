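"""End-to-end study orchestration.

Generate or load a table, preprocess it, split it into demographic
groups, compare a classifier roster per group (seven metrics + mean
rank), run the swarm feature selection over several seeded repetitions,
and write the summary artifacts: metric tables, per-run masks,
selection frequencies, and the reduction/improvement accounting.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocessing, synthetic
from .classifiers import KNNSpec, PresetSpec, SubspaceEnsembleSpec
from .evaluation import CVConfig, cross_validate, tune_knn
from .fs import FitnessWeights, SwarmConfig, run_bpso, save_result
from .metrics import METRIC_FIELDS, mean_rank
from .table import LabeledTable, read_csv, write_csv

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "selection_frequency",
    "improvement_summary",
    "relative_accuracy_change",
    "default_roster",
]


def improvement_summary(acc_before: float, n_before: int,
                        acc_after: float, n_after: int) -> tuple:
    """Feature-reduction % and accuracy gain in percentage points.

    Returns ``(100*(n_before-n_after)/n_before, 100*(acc_after-acc_before))``.
    """
    if n_before == 0:
        raise ValueError("n_before must be positive")
    if n_after > n_before:
        raise ValueError("n_after cannot exceed n_before")
    for a in (acc_before, acc_after):
        if not 0.0 <= a <= 1.0:
            raise ValueError("accuracies must lie in [0, 1]")
    reduction = 100.0 * (n_before - n_after) / n_before
    improvement = 100.0 * (acc_after - acc_before)
    return reduction, improvement


def relative_accuracy_change(acc_before: float, acc_after: float) -> float:
    """Relative change in % (distinct from the percentage-point gain)."""
    if acc_before == 0:
        raise ValueError("acc_before must be positive")
    return 100.0 * (acc_after - acc_before) / acc_before


def selection_frequency(masks) -> np.ndarray:
    """Per-feature count of masks with the bit set.

    All masks must share one feature universe (equal lengths); align
    group-specific masks to the universe before calling.
    """
    masks = [np.asarray(m, dtype=bool) for m in masks]
    if not masks:
        raise ValueError("need at least one mask")
    n = masks[0].size
    if any(m.size != n for m in masks):
        raise ValueError("masks must share a common feature universe")
    return np.sum(masks, axis=0).astype(int)


def align_mask(mask, group_names, universe_names) -> np.ndarray:
    """Embed a group-level mask into the full feature universe.

    Features absent from the group schema count as not selected.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size != len(group_names):
        raise ValueError("mask length must match group feature names")
    out = np.zeros(len(universe_names), dtype=bool)
    pos = {name: i for i, name in enumerate(universe_names)}
    for name, bit in zip(group_names, mask):
        out[pos[name]] = bit
    return out


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------

def default_roster(seed: int = 0) -> dict:
    """Name -> classifier spec for the comparison stage."""
    return {
        "DT": PresetSpec("DT"),
        "LDA": PresetSpec("LDA"),
        "LR": PresetSpec("LR"),
        "NB": PresetSpec("NB"),
        "SVM": PresetSpec("SVM"),
        "kNN": KNNSpec(n_neighbors=10, distance="euclidean",
                       weighting="equal", standardize=True),
        "Ensemble": SubspaceEnsembleSpec(n_learners=30, subspace_dim=16, seed=seed),
    }


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one study run."""

    data_path: str = None                 # CSV path; None -> synthetic
    generator: synthetic.GeneratorConfig = None
    groups: tuple = ("none", "race", "sex", "age")
    runs: int = 10
    swarm: SwarmConfig = field(default_factory=SwarmConfig)
    weights: FitnessWeights = field(default_factory=FitnessWeights)
    cv: CVConfig = field(default_factory=CVConfig)
    tune_budget: int = 40
    out_dir: str = "results/experiment"
    seed: int = 0

    def __post_init__(self):
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        for g in self.groups:
            if g not in ("none", "race", "sex", "age"):
                raise ValueError(f"unknown group {g!r}")

    def config_hash(self) -> str:
        payload = json.dumps(_jsonable(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ----------------------------------------------------------------------
# stages
# ----------------------------------------------------------------------

def _load_table(config: ExperimentConfig) -> LabeledTable:
    if config.data_path is not None:
        return read_csv(config.data_path)
    gen = config.generator
    if gen is None:
        rng = np.random.default_rng(config.seed)
        gen = synthetic.GeneratorConfig(
            planted_features=(4, 7, 21, 25, 28),
            effect_sizes=(1.0, 1.2, 1.5, 0.8, 1.0),
            missing_rate=0.02,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    return synthetic.generate_dataset(synthetic.default_schema(), gen)


def _group_tables(table: LabeledTable, group: str) -> dict:
    if group == "none":
        return {"all": table}
    spec = preprocessing.GroupSpec(group_variable=group)
    return preprocessing.split_groups(table, spec)


def compare_classifiers(table: LabeledTable, roster: dict, cv: CVConfig) -> pd.DataFrame:
    """Seven-metric table with a mean-rank column, one classifier per row."""
    rows = {}
    for name, spec in roster.items():
        report = cross_validate(table, spec, cv)
        rows[name] = [getattr(report, m) for m in METRIC_FIELDS]
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(METRIC_FIELDS))
    frame["mean_rank"] = mean_rank(frame[list(METRIC_FIELDS)].to_numpy())
    return frame


def run_feature_selection(table: LabeledTable, classifier_spec, config: ExperimentConfig,
                          seeds) -> list:
    """One swarm run per seed; returns the list of FSResult."""
    results = []
    for s in seeds:
        swarm = SwarmConfig(
            n_particles=config.swarm.n_particles,
            n_iterations=config.swarm.n_iterations,
            inertia=config.swarm.inertia,
            c1=config.swarm.c1,
            c2=config.swarm.c2,
            velocity_clamp=config.swarm.velocity_clamp,
            tf_id=config.swarm.tf_id,
            polarity=config.swarm.polarity,
            seed=int(s),
        )
        results.append(run_bpso(table, swarm, classifier_spec, config.weights, config.cv))
    return results


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute the full pipeline; writes artifacts and returns a summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(config.seed)

    raw = _load_table(config)
    write_csv(raw, out / "data_raw.csv")
    clean, norm_params = preprocessing.preprocess(raw)
    norm_params.to_json(out / "normalization.json")

    universe = clean.column_names
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_samples": clean.n_samples,
        "n_features": clean.n_features,
        "groups": {},
    }
    summary = {"groups": {}, "manifest": manifest}
    all_masks_aligned = []

    for group in config.groups:
        for label, table in _group_tables(clean, group).items():
            gname = label if group == "none" else f"{group}_{label}"
            gdir = out / gname
            gdir.mkdir(exist_ok=True)
            gseed = int(master.integers(0, 2**31 - 1))

            roster = default_roster(seed=gseed)
            # ensemble subspace cannot exceed the group's feature count
            if roster["Ensemble"].subspace_dim > table.n_features:
                roster["Ensemble"] = SubspaceEnsembleSpec(
                    n_learners=30, subspace_dim=table.n_features, seed=gseed
                )
            cv = CVConfig(config.cv.k, config.cv.stratified, gseed)
            tuned = tune_knn(table, budget=config.tune_budget, cv=cv, seed=gseed)
            roster["kNN*"] = tuned
            metrics_frame = compare_classifiers(table, roster, cv)
            metrics_frame.to_csv(gdir / "classifier_metrics.csv")

            acc_before = metrics_frame.loc["kNN*", "accuracy"]
            run_seeds = [int(master.integers(0, 2**31 - 1)) for _ in range(config.runs)]
            results = run_feature_selection(table, tuned, config, run_seeds)
            best = min(results, key=lambda r: (r.fitness.value, r.fitness.n_selected))
            for i, res in enumerate(results):
                save_result(res, gdir, table.column_names, prefix=f"run{i:02d}")
            save_result(best, gdir, table.column_names, prefix="best")

            aligned = [align_mask(r.mask, table.column_names, universe) for r in results]
            all_masks_aligned.extend(aligned)
            freq = selection_frequency(aligned)
            pd.DataFrame({"feature": universe, "count": freq}).to_csv(
                gdir / "selection_frequency.csv", index=False
            )

            accs = [r.accuracy for r in results]
            reduction, improvement = improvement_summary(
                acc_before, table.n_features, best.accuracy, best.fitness.n_selected
            )
            ginfo = {
                "n_samples": table.n_samples,
                "n_features": table.n_features,
                "group_seed": gseed,
                "run_seeds": run_seeds,
                "tuned_knn": _jsonable(tuned),
                "accuracy_before": float(acc_before),
                "best_accuracy": float(best.accuracy),
                "best_n_selected": int(best.fitness.n_selected),
                "mean_accuracy": float(np.mean(accs)),
                "std_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
                "feature_reduction_pct": reduction,
                "accuracy_improvement_pp": improvement,
            }
            manifest["groups"][gname] = ginfo
            summary["groups"][gname] = ginfo

    freq_all = selection_frequency(all_masks_aligned)
    pd.DataFrame({"feature": universe, "count": freq_all}).to_csv(
        out / "selection_frequency_all.csv", index=False
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    rows = []
    for gname, info in manifest["groups"].items():
        rows.append(
            {
                "dataset": gname,
                "accuracy_before": info["accuracy_before"],
                "n_features_before": info["n_features"],
                "accuracy_after": info["best_accuracy"],
                "n_features_after": info["best_n_selected"],
                "feature_reduction_pct": info["feature_reduction_pct"],
                "accuracy_improvement_pp": info["accuracy_improvement_pp"],
            }
        )
    pd.DataFrame(rows).to_csv(out / "improvement_summary.csv", index=False)
    return summary
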