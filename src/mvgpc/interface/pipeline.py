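"""Pipeline driver: configuration, map thresholding, end-to-end run.

``run_pipeline`` chains simulation (optional), feature extraction,
within-group classification for every (group, contrast), second-level
group statistics, between-group classification for every (group pair,
condition), and discriminating-map thresholding.  Every stage logs its
parameters; completed stage outputs are persisted before the next stage
starts, so a failing stage preserves earlier results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mvgpc._version import __version__
from mvgpc.confounds import covariates_for, intercept_only
from mvgpc.errors import InvalidParameterError, PipelineStageError
from mvgpc.evaluation import (
    CvConfig,
    lopo_between_group,
    loso_within_group,
)
from mvgpc.first_level import FeatureMatrix, extract_features, variance_mask
from mvgpc.gpc import KernelOptions, gpc_train, weight_map
from mvgpc.group_stats import second_level_report
from mvgpc.interface import io
from mvgpc.synthetic_data import CONDITIONS, GroupSpec, generate_cohort

log = logging.getLogger("mvgpc")


class EmptyMapWarning(UserWarning):
    """Thresholding an all-zero weight map."""


def threshold_map(weights: np.ndarray, fraction: float) -> np.ndarray:
    """Keep voxels whose |weight| reaches ``fraction`` of the maximum.

    Surviving voxels keep their signed value (positive = class-1
    evidence, negative = class-2); all others are zeroed.  Ties at the
    cutoff are retained, so ``fraction=1.0`` keeps exactly the voxels
    tied at the maximum magnitude.
    """
    if not 0.0 < fraction <= 1.0:
        raise InvalidParameterError("fraction must be in (0, 1]")
    weights = np.asarray(weights, dtype=float)
    max_abs = np.abs(weights).max()
    if max_abs == 0.0:
        warnings.warn("weight map is all zero", EmptyMapWarning)
        return np.zeros_like(weights)
    out = weights.copy()
    out[np.abs(weights) < fraction * max_abs] = 0.0
    return out


#: Default graded group structure: separability of the happy patterns
#: from the neutral pattern decreases HC > UD > BD.
DEFAULT_GROUPS = {
    "HC": {"intense_happy": 1.0, "mild_happy": 0.8, "neutral": 0.6},
    "UD": {"intense_happy": 0.6, "mild_happy": 0.3, "neutral": 0.6},
    "BD": {"intense_happy": 0.35, "mild_happy": 0.2, "neutral": 0.6},
}


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs; round-trips through YAML."""

    out_dir: str | None = None
    input_dir: str | None = None  # load a saved cohort instead of simulating
    seed: int = 0
    n_subjects: int = 18
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    group_amplitudes: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GROUPS.items()})
    pattern_overlap: float = 0.0
    subject_variability: float = 0.5
    noise_sd: float = 1.0
    contrasts: tuple = (("intense_happy", "neutral"), ("mild_happy", "neutral"))
    residualize_mode: str = "train_only"
    kernel_amplitude: float | str = 1.0
    kernel_bias: float = 0.0
    kernel_normalize: bool = True
    n_permutations: int = 1000
    alpha: float = 0.05
    map_threshold: float = 0.3

    def __post_init__(self):
        if not 0.0 < self.map_threshold <= 1.0:
            raise InvalidParameterError("map_threshold must be in (0, 1]")
        self.grid_shape = tuple(self.grid_shape)
        self.contrasts = tuple(tuple(c) for c in self.contrasts)

    def kernel_options(self) -> KernelOptions:
        return KernelOptions(
            amplitude=self.kernel_amplitude,
            bias=self.kernel_bias,
            normalize=self.kernel_normalize,
        )

    def cv_config(self, seed_offset: int = 0) -> CvConfig:
        return CvConfig(
            kernel=self.kernel_options(),
            residualize_mode=self.residualize_mode,
            n_permutations=self.n_permutations,
            seed=self.seed + seed_offset,
        )

    def to_yaml(self) -> str:
        data = asdict(self)
        data["grid_shape"] = list(self.grid_shape)
        data["contrasts"] = [list(c) for c in self.contrasts]
        return yaml.safe_dump(data, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls(**yaml.safe_load(text))

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def group_specs(config: PipelineConfig) -> list[GroupSpec]:
    return [
        GroupSpec.for_label(
            label,
            n_subjects=config.n_subjects,
            pattern_amplitude=dict(amps),
            pattern_overlap=config.pattern_overlap,
            subject_variability=config.subject_variability,
            noise_sd=config.noise_sd,
        )
        for label, amps in config.group_amplitudes.items()
    ]


@dataclass
class ResultsBundle:
    """All pipeline outputs plus provenance."""

    within: pd.DataFrame
    between: pd.DataFrame
    predictions: pd.DataFrame
    anova: pd.DataFrame
    posthoc: pd.DataFrame
    weight_maps: dict[str, np.ndarray]
    thresholded_maps: dict[str, np.ndarray]
    provenance: dict

    TABLES = ("within", "between", "predictions", "anova", "posthoc")

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in self.TABLES:
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        maps_dir = out / "maps"
        maps_dir.mkdir(exist_ok=True)
        for name, vol in self.weight_maps.items():
            io.save_volume(maps_dir / f"{name}_weights.nii.gz", vol)
        for name, vol in self.thresholded_maps.items():
            io.save_volume(maps_dir / f"{name}_thresholded.nii.gz", vol)
        (out / "bundle.json").write_text(json.dumps(self.provenance, indent=2))


def load_bundle(out_dir) -> dict:
    """Reload the persisted tables and provenance without recomputation."""
    out = Path(out_dir)
    bundle = {name: pd.read_csv(out / f"{name}.csv") for name in ResultsBundle.TABLES}
    bundle["provenance"] = json.loads((out / "bundle.json").read_text())
    return bundle


def _within_table(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": r.group,
                "contrast": f"{r.contrast[0]}_vs_{r.contrast[1]}",
                "accuracy": r.accuracy,
                "tp_rate": r.tp_rate,
                "tn_rate": r.tn_rate,
                "p_value": r.p_value,
            }
            for r in results
        ]
    )


def _between_table(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_pair": f"{r.group_pair[0]}_vs_{r.group_pair[1]}",
                "condition": r.condition,
                "accuracy": r.accuracy,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "p_value": r.p_value,
            }
            for r in results
        ]
    )


def _predictions_table(results) -> pd.DataFrame:
    rows = []
    for r in results:
        for p in r.predictions:
            rows.append(
                {
                    "group": getattr(r, "group", "_".join(getattr(r, "group_pair", ()))),
                    "contrast": p.contrast,
                    "subject_id": p.subject_id,
                    "condition": p.condition,
                    "probability_class1": p.probability_class1,
                    "fold_index": p.fold_index,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> ResultsBundle:
    """Execute every stage; see the module docstring for the sequence."""
    out = Path(config.out_dir) if config.out_dir else None
    provenance = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": yaml.safe_load(config.to_yaml()),
    }

    stage = "simulate"
    try:
        if config.input_dir:
            records = io.load_cohort(config.input_dir)
        else:
            records = generate_cohort(
                group_specs(config), grid_shape=config.grid_shape, seed=config.seed
            )
        log.info("stage=%s seed=%d n_records=%d", stage, config.seed, len(records))

        stage = "features"
        mask = variance_mask(records)
        by_group: dict[str, FeatureMatrix] = {}
        for label in dict.fromkeys(r.group for r in records):
            grp_records = [r for r in records if r.group == label]
            by_group[label] = extract_features(grp_records, mask)
        cov_table = pd.DataFrame(
            [
                {
                    "subject_id": r.subject_id,
                    "medication_load": r.medication_load,
                    "substance_history": r.substance_history,
                }
            for r in records
            ]
        )
        log.info("stage=%s n_voxels=%d", stage, int(mask.sum()))

        stage = "within_group"
        within_results = []
        trained_models = {}
        for gi, (label, feats) in enumerate(by_group.items()):
            # covariates apply to patient groups; HC gets intercept-only
            if label == "HC":
                cov = None
            else:
                cov = covariates_for(feats, cov_table)
            for ci, contrast in enumerate(config.contrasts):
                res = loso_within_group(
                    feats,
                    contrast=contrast,
                    covariates=cov,
                    config=config.cv_config(seed_offset=10 * gi + ci),
                )
                within_results.append(res)
                keep = feats.rows["condition"].isin(contrast).to_numpy()
                sub = feats.subset(np.flatnonzero(keep))
                y = np.where(sub.rows["condition"] == contrast[0], 1.0, -1.0)
                model = gpc_train(sub.values, y, config.kernel_options())
                trained_models[f"{label}_{contrast[0]}_vs_{contrast[1]}"] = (model, sub)
        within = _within_table(within_results)
        if out:
            out.mkdir(parents=True, exist_ok=True)
            within.to_csv(out / "within.csv", index=False)

        stage = "second_level"
        anova_frames, posthoc_frames = [], []
        for contrast in config.contrasts:
            group_results = [r for r in within_results if r.contrast == contrast]
            report = second_level_report(group_results, alpha=config.alpha)
            af, pf = report.to_frames()
            af.insert(0, "contrast", f"{contrast[0]}_vs_{contrast[1]}")
            pf.insert(0, "contrast", f"{contrast[0]}_vs_{contrast[1]}")
            anova_frames.append(af)
            posthoc_frames.append(pf)
        anova = pd.concat(anova_frames, ignore_index=True)
        posthoc = pd.concat(posthoc_frames, ignore_index=True)
        if out:
            anova.to_csv(out / "anova.csv", index=False)
            posthoc.to_csv(out / "posthoc.csv", index=False)

        stage = "between_group"
        between_results = []
        labels = list(by_group)
        for pi, (la, lb) in enumerate(combinations(labels, 2)):
            for ci, condition in enumerate(CONDITIONS):
                between_results.append(
                    lopo_between_group(
                        by_group[la],
                        by_group[lb],
                        condition=condition,
                        config=config.cv_config(seed_offset=100 + 10 * pi + ci),
                    )
                )
        between = _between_table(between_results)
        if out:
            between.to_csv(out / "between.csv", index=False)

        stage = "maps"
        weight_maps, thresholded = {}, {}
        for name, (model, sub) in trained_models.items():
            vol = weight_map(model, sub)
            weight_maps[name] = vol
            thresholded[name] = threshold_map(vol, config.map_threshold)
    except Exception as exc:  # noqa: BLE001 - re-tag with the failing stage
        if isinstance(exc, PipelineStageError):
            raise
        raise PipelineStageError(stage, str(exc)) from exc

    predictions = _predictions_table(within_results + between_results)
    bundle = ResultsBundle(
        within=within,
        between=between,
        predictions=predictions,
        anova=anova,
        posthoc=posthoc,
        weight_maps=weight_maps,
        thresholded_maps=thresholded,
        provenance=provenance,
    )
    if out:
        bundle.save(out)
    return bundle
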