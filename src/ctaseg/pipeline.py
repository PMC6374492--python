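"""Experiment orchestration: cohorts, training runs, ablations, reports.

`run_experiment` drives one feature-set experiment end to end — phantom
cohort generation, preprocessing, training on the training split only,
prediction and two-level evaluation on the held-out split — writing tabular
reports and logs under an output directory.  `run_ablation` repeats this for
the three input-feature configurations (CTA alone, CTA + hemispheric
comparison, + NCCT) on a shared test cohort.  `table2_check` recomputes the
published region-contingency metrics from printed counts and verifies them
after 2-decimal rounding.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .cnn import CHANNEL_SETS, NetworkConfig, TrainingConfig
from .evaluation import (
    RegionContingency,
    combined_dsc,
    metrics_from_contingency,
    round_half_up,
)
from .grid import ConfigurationError, ParameterError
from .model import LesionSegmentationModel
from .phantom import PhantomSpec, generate_cohort, write_cohort
from .preprocessing import PreprocessConfig, preprocess_case

logger = logging.getLogger(__name__)


def derive_seed(master: int, label: str) -> int:
    """Stable sub-seed below 2^31 for a named pipeline stage."""
    digest = hashlib.sha256(f"{master}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything one experiment needs; defaults are the desk-scale cohort."""

    n_train_positive: int = 4
    n_train_negative: int = 4
    n_test_positive: int = 4
    n_test_negative: int = 4
    base_spec: PhantomSpec = field(default_factory=PhantomSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    network: NetworkConfig | None = None
    training: TrainingConfig = field(default_factory=TrainingConfig)
    feature_set: str = "cta+flip"
    threshold: float = 0.5
    output_dir: str | None = None
    seed: int = 0
    save_cohort: bool = False

    def __post_init__(self):
        if self.feature_set not in CHANNEL_SETS:
            raise ConfigurationError(f"unknown feature_set {self.feature_set!r}")
        net = self.resolved_network()
        if net.n_input_channels != len(CHANNEL_SETS[self.feature_set]):
            raise ConfigurationError(
                f"feature_set {self.feature_set!r} needs "
                f"{len(CHANNEL_SETS[self.feature_set])} input channels, "
                f"network has {net.n_input_channels}"
            )

    def resolved_network(self) -> NetworkConfig:
        if self.network is not None:
            return self.network
        return NetworkConfig(n_input_channels=len(CHANNEL_SETS[self.feature_set]))


def build_cohorts(config: ExperimentConfig):
    """Deterministic, ID-disjoint train/test phantom cohorts."""
    train = generate_cohort(
        config.n_train_positive, config.n_train_negative, config.base_spec,
        seed=derive_seed(config.seed, "train-cohort"),
    )
    test = generate_cohort(
        config.n_test_positive, config.n_test_negative, config.base_spec,
        seed=derive_seed(config.seed, "test-cohort"),
    )
    train = [replace(c, case_id=f"train-{c.case_id}") for c in train]
    test = [replace(c, case_id=f"test-{c.case_id}") for c in test]
    return train, test


def _preprocess_all(cases, config: ExperimentConfig, channels):
    out = []
    for case in cases:
        t0 = time.perf_counter()
        out.append(preprocess_case(case, config.preprocess, channels=channels))
        logger.info("preprocessed %s in %.2fs", case.case_id, time.perf_counter() - t0)
    return out


def run_experiment(config: ExperimentConfig) -> dict:
    """One feature-set experiment end to end; returns the report bundle.

    The bundle holds the fitted results object, the evaluation report, the
    train/test case IDs and (when ``output_dir`` is set) the paths of the
    emitted report files.  Identical config and seed reproduce identical
    reports.
    """
    channels = CHANNEL_SETS[config.feature_set]
    stage = "generate"
    try:
        train_cases, test_cases = build_cohorts(config)
        stage = "preprocess"
        ptrain = _preprocess_all(train_cases, config, channels)
        ptest = _preprocess_all(test_cases, config, channels)
        stage = "train"
        model = LesionSegmentationModel(
            ptrain, config.feature_set, config.resolved_network(),
            replace(config.training, seed=derive_seed(config.seed, "training")),
        )
        results = model.fit()
        stage = "evaluate"
        report = results.evaluate(ptest, threshold=config.threshold)
    except Exception as err:  # noqa: BLE001 - annotate failing stage and re-raise
        raise RuntimeError(f"experiment failed at stage {stage!r}: {err}") from err

    bundle = {
        "config": config,
        "results": results,
        "report": report,
        "train_ids": [c.case_id for c in ptrain],
        "test_ids": [c.case_id for c in ptest],
        "files": {},
    }
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = bundle["files"]
        files["per_case"] = str(out / "per_case.tsv")
        report.per_case.to_csv(files["per_case"], sep="\t", index=False, float_format="%.6f")
        files["summary"] = str(out / "summary.txt")
        Path(files["summary"]).write_text(report.summary() + "\n" + results.summary() + "\n")
        files["loss_trace"] = str(out / "loss_trace.tsv")
        Path(files["loss_trace"]).write_text(results.loss_trace.to_text())
        files["metrics"] = str(out / "metrics.json")
        rm = report.region_metrics
        Path(files["metrics"]).write_text(json.dumps({
            "feature_set": config.feature_set,
            "region_sensitivity": rm["sensitivity"],
            "region_specificity": rm["specificity"],
            "region_dsc": rm["dsc"],
            "combined_dsc": report.combined_dsc,
            "voxel": report.pooled_voxel,
            "voxel_auc": report.pooled_auc,
            "train_ids": bundle["train_ids"],
            "test_ids": bundle["test_ids"],
        }, indent=2, sort_keys=True, allow_nan=True))
        files["model"] = str(out / "model.npz")
        results.net.save(files["model"])
        if config.save_cohort:
            write_cohort(train_cases + test_cases, out / "cohort")
    return bundle


def run_ablation(
    config: ExperimentConfig,
    feature_sets: tuple[str, ...] = ("cta", "cta+flip", "cta+flip+ncct"),
    seeds: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Train one model per feature set on a shared cohort; compare metrics.

    All feature sets share the same phantom cohorts, preprocessing,
    thresholds and test cases.  With multiple seeds, each feature set is
    trained once per seed and per-run rows are returned (callers can take
    medians across seeds).
    """
    union_channels = tuple(
        dict.fromkeys(ch for fs in feature_sets for ch in CHANNEL_SETS[fs])
    )
    train_cases, test_cases = build_cohorts(config)
    ptrain = _preprocess_all(train_cases, config, union_channels)
    ptest = _preprocess_all(test_cases, config, union_channels)
    if seeds is None:
        seeds = (derive_seed(config.seed, "training"),)

    rows = []
    for fs in feature_sets:
        net_cfg = (
            config.network
            if config.network is not None and config.network.n_input_channels == len(CHANNEL_SETS[fs])
            else NetworkConfig(
                **{**(config.network.__dict__ if config.network else NetworkConfig().__dict__),
                   "n_input_channels": len(CHANNEL_SETS[fs])}
            )
        )
        for seed in seeds:
            model = LesionSegmentationModel(
                ptrain, fs, net_cfg, replace(config.training, seed=seed)
            )
            results = model.fit()
            report = results.evaluate(ptest, threshold=config.threshold)
            rm = report.region_metrics
            rows.append({
                "feature_set": fs,
                "seed": seed,
                "region_sensitivity": rm["sensitivity"],
                "region_specificity": rm["specificity"],
                "region_dsc": rm["dsc"],
                "combined_dsc": report.combined_dsc,
                "voxel_sensitivity": report.pooled_voxel["sensitivity"],
                "voxel_specificity": report.pooled_voxel["specificity"],
                "voxel_dsc": report.pooled_voxel["dsc"],
                "voxel_auc": report.pooled_auc,
                "final_loss": results.final_loss,
            })
            logger.info(
                "ablation %s seed %d: region spec %.3f, voxel AUC %.3f",
                fs, seed, rm["specificity"], report.pooled_auc,
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# published-counts verification
# ---------------------------------------------------------------------------

class CountsParseError(ParameterError):
    """The region-counts file is malformed; the message names the line."""


def packaged_table2_path() -> Path:
    return Path(resources.files("ctaseg.data") / "table2_counts.csv")


def load_region_counts(path=None) -> pd.DataFrame:
    """Read a region-counts CSV (feature_set, tn, tp, fn, fp, fp_group_b, printed metrics)."""
    p = Path(path) if path is not None else packaged_table2_path()
    text = p.read_text().strip().splitlines()
    if not text:
        raise CountsParseError(f"{p}: line 1: file is empty")
    header = [h.strip() for h in text[0].split(",")]
    required = {"feature_set", "tn", "tp", "fn", "fp", "fp_group_b",
                "dsc", "sensitivity", "specificity", "combined_dsc"}
    missing = required - set(header)
    if missing:
        raise CountsParseError(f"{p}: line 1: missing columns {sorted(missing)}")
    rows = []
    for lineno, line in enumerate(text[1:], start=2):
        parts = [x.strip() for x in line.split(",")]
        if len(parts) != len(header):
            raise CountsParseError(f"{p}: line {lineno}: expected {len(header)} fields, got {len(parts)}")
        row = dict(zip(header, parts))
        try:
            for k in required - {"feature_set"}:
                row[k] = float(row[k])
        except ValueError as err:
            raise CountsParseError(f"{p}: line {lineno}: {err}") from err
        rows.append(row)
    return pd.DataFrame(rows)


def table2_check(path=None) -> pd.DataFrame:
    """Recompute every printed metric from the printed counts; compare at 2 dp.

    Returns one row per (feature set, metric) with the printed value, the
    recomputed value and a pass flag.
    """
    df = load_region_counts(path)
    rows = []
    for _, r in df.iterrows():
        cont = RegionContingency(tn=int(r.tn), tp=int(r.tp), fn=int(r.fn), fp=int(r.fp))
        computed = metrics_from_contingency(cont)
        computed["combined_dsc_2dp"] = round_half_up(combined_dsc(cont, int(r.fp_group_b)))
        for metric in ("sensitivity", "specificity", "dsc", "combined_dsc"):
            got = computed[f"{metric}_2dp"]
            rows.append({
                "feature_set": r.feature_set,
                "metric": metric,
                "printed": float(r[metric]),
                "recomputed": got,
                "pass": bool(abs(got - float(r[metric])) < 1e-9),
            })
    return pd.DataFrame(rows)
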