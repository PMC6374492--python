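"""Model/Results interface for lesion segmentation experiments.

`LesionSegmentationModel` is constructed from preprocessed training cases and
the architecture/recipe configurations; `fit()` optimizes the network and
returns a `LesionSegmentationResults` holding the trained network and loss
trace, with `predict()` for probability maps and `evaluate()` producing a
two-level evaluation report (voxel metrics/ROC plus ASPECTS-region
contingency, scores and volumetry) with a `summary()` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cnn import (
    CHANNEL_SETS,
    LossTrace,
    MultiScalePatchNet,
    NetworkConfig,
    SampleableCase,
    TrainingConfig,
    build_network,
    predict as _predict,
    train as _train,
)
from .evaluation import (
    RegionContingency,
    aspects_score,
    combined_dsc,
    largest_component_volume,
    metrics_from_contingency,
    region_contingency,
    region_positivity,
    roc_curve,
    threshold_map,
    voxel_metrics,
)
from .grid import ConfigurationError
from .preprocessing import PreprocessedCase


class LesionSegmentationModel:
    """Patch-based 3D CNN lesion segmentation, built from preprocessed cases.

    Parameters
    ----------
    train_cases : list of PreprocessedCase
        Conditioned training cases; each must carry every channel of the
        chosen feature set.
    feature_set : {"cta", "cta+flip", "cta+flip+ncct"}
        Input channels: CTA alone, plus the hemispheric comparison volume,
        plus NCCT.
    network_config, training_config : optional
        Architecture and recipe; defaults are the desk-scale configuration.
    """

    def __init__(
        self,
        train_cases: list[PreprocessedCase],
        feature_set: str = "cta+flip",
        network_config: NetworkConfig | None = None,
        training_config: TrainingConfig | None = None,
    ):
        if feature_set not in CHANNEL_SETS:
            raise ConfigurationError(
                f"feature_set must be one of {sorted(CHANNEL_SETS)}, got {feature_set!r}"
            )
        self.feature_set = feature_set
        self.channel_names = CHANNEL_SETS[feature_set]
        if network_config is None:
            network_config = NetworkConfig(n_input_channels=len(self.channel_names))
        if network_config.n_input_channels != len(self.channel_names):
            raise ConfigurationError(
                f"feature set {feature_set!r} has {len(self.channel_names)} channels but "
                f"the network expects {network_config.n_input_channels}"
            )
        self.network_config = network_config
        self.training_config = training_config or TrainingConfig()
        self.train_cases = list(train_cases)
        self.train_ids = [c.case_id for c in self.train_cases]

    def fit(self, seed: int | None = None) -> "LesionSegmentationResults":
        """Train the network; ``seed`` overrides the configured training seed."""
        cfg = self.training_config if seed is None else replace(self.training_config, seed=seed)
        net = build_network(self.network_config, seed=cfg.seed)
        sampleable = [
            SampleableCase.from_preprocessed(c, self.channel_names, self.network_config)
            for c in self.train_cases
        ]
        trace = _train(net, sampleable, cfg)
        return LesionSegmentationResults(self, net, trace, cfg)


@dataclass
class EvaluationReport:
    """Two-level evaluation of one trained model on a test cohort."""

    feature_set: str
    threshold: float
    per_case: pd.DataFrame
    contingency_a: RegionContingency
    fp_group_b: int
    region_metrics: dict
    combined_dsc: float
    pooled_voxel: dict
    pooled_auc: float

    def summary(self) -> str:
        rm = self.region_metrics
        lines = [
            f"Feature set: {self.feature_set}   threshold: {self.threshold}",
            "",
            "Region-level (ASPECTS regions, pooled over cases)",
            f"  TN={self.contingency_a.tn} TP={self.contingency_a.tp} "
            f"FN={self.contingency_a.fn} FP={self.contingency_a.fp} "
            f"FP(group B)={self.fp_group_b}",
            f"  sensitivity={rm['sensitivity_2dp']:.2f} specificity={rm['specificity_2dp']:.2f} "
            f"DSC={rm['dsc_2dp']:.2f} DSC(A+B)={self.combined_dsc:.2f}",
            "",
            "Voxel-level (pooled over in-mask voxels)",
            f"  sensitivity={self.pooled_voxel['sensitivity']:.2f} "
            f"specificity={self.pooled_voxel['specificity']:.2f} "
            f"DSC={self.pooled_voxel['dsc']:.2f} AUC={self.pooled_auc:.2f}",
            "",
            self.per_case.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)


class LesionSegmentationResults:
    """Trained network plus its loss trace; prediction and evaluation hang here."""

    def __init__(
        self,
        model: LesionSegmentationModel,
        net: MultiScalePatchNet,
        loss_trace: LossTrace,
        training_config: TrainingConfig,
    ):
        self.model = model
        self.net = net
        self.loss_trace = loss_trace
        self.training_config = training_config

    @property
    def final_loss(self) -> float:
        return float(self.loss_trace.losses[-1])

    def predict(self, case: PreprocessedCase):
        """Probability map for one preprocessed case."""
        channels = [case.channels[name] for name in self.model.channel_names]
        return _predict(self.net, channels, case.brain_mask)

    def evaluate(self, test_cases: list[PreprocessedCase], threshold: float = 0.5) -> EvaluationReport:
        """Voxel- and region-level evaluation against the ground-truth masks."""
        rows = []
        cont_a = RegionContingency()
        fp_b = 0
        probs, truths = [], []
        for case in test_cases:
            pmap = self.predict(case)
            pred = threshold_map(pmap, threshold)
            vm = voxel_metrics(pred, case.lesion_mask, case.brain_mask, threshold)
            pred_regions = region_positivity(pred, case.atlas)
            truth_regions = region_positivity(case.lesion_mask, case.atlas)
            cont = region_contingency(pred_regions, truth_regions)
            if case.group == "A":
                cont_a = cont_a + cont
            else:
                fp_b += cont.fp
            m = case.brain_mask.as_bool()
            probs.append(pmap.values[m])
            truths.append(case.lesion_mask.values[m].astype(bool))
            rows.append(
                {
                    "case_id": case.case_id,
                    "group": case.group,
                    "voxel_sensitivity": vm.sensitivity,
                    "voxel_specificity": vm.specificity,
                    "voxel_dsc": vm.dsc,
                    "aspects_pred": aspects_score(pred_regions),
                    "aspects_truth": aspects_score(truth_regions),
                    "volume_pred_cm3": largest_component_volume(pred),
                    "volume_truth_cm3": largest_component_volume(case.lesion_mask),
                }
            )
        per_case = pd.DataFrame(rows)
        rm = metrics_from_contingency(cont_a)
        cdsc = combined_dsc(cont_a, fp_b)

        p_all = np.concatenate(probs)
        t_all = np.concatenate(truths)
        pos = p_all >= threshold
        tp = int(np.sum(pos & t_all))
        fp = int(np.sum(pos & ~t_all))
        fn = int(np.sum(~pos & t_all))
        tn = int(np.sum(~pos & ~t_all))
        pooled_voxel = {
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp else float("nan"),
            "dsc": 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan"),
        }
        if t_all.any() and not t_all.all():
            # pooled ROC over all test voxels, via the evaluation-module sweep
            from .grid import BinaryMask, ImageVolume, ProbabilityMap

            flat = ImageVolume(p_all.reshape(-1, 1, 1))
            mask1 = BinaryMask.from_array(np.ones_like(p_all, dtype=np.uint8).reshape(-1, 1, 1), flat)
            truth1 = BinaryMask.from_array(t_all.astype(np.uint8).reshape(-1, 1, 1), flat)
            pooled_auc = roc_curve(ProbabilityMap(flat, mask1), truth1, mask1).auc
        else:
            pooled_auc = float("nan")
        return EvaluationReport(
            feature_set=self.model.feature_set,
            threshold=threshold,
            per_case=per_case,
            contingency_a=cont_a,
            fp_group_b=fp_b,
            region_metrics=rm,
            combined_dsc=cdsc,
            pooled_voxel=pooled_voxel,
            pooled_auc=pooled_auc,
        )

    def summary(self) -> str:
        cfg, tcfg = self.model.network_config, self.training_config
        lines = [
            "LesionSegmentationResults",
            f"  feature set:      {self.model.feature_set} ({cfg.n_input_channels} channels)",
            f"  architecture:     {cfg.n_layers} weighted layers, filters {cfg.filters}, "
            f"{cfg.n_pathways} pathway(s), output patch {cfg.output_patch}^3",
            f"  parameters:       {self.net.n_parameters()}",
            f"  training:         {tcfg.n_epochs} epochs x {tcfg.subepochs_per_epoch} sub-epochs, "
            f"batch {tcfg.batch_size}, lr0 {tcfg.initial_lr}, seed {tcfg.seed}",
            f"  final loss:       {self.final_loss:.4f}",
            f"  training cases:   {', '.join(self.model.train_ids)}",
        ]
        return "\n".join(lines)
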