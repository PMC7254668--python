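"""End-to-end pipeline: simulate -> segment -> standardize -> extract ->
train -> evaluate.

`run_pipeline` drives the whole chain on a synthetic cohort (or a
pre-extracted feature table) and returns the trained model plus training
(cross-validation) and test evaluation reports.  Histogram standardization
is learned per phase position on the training exams only, then applied to
every exam, so no test information leaks into the intensity scale.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import PHASE_NAMES, DCESeries, TumorMask
from .evaluation import EvalReport, evaluate_scores
from .features import TextureConfig, extract_lesion_features
from .modeling import (
    LABEL_COLUMN,
    SPLIT_COLUMN,
    ModelingConfig,
    TrainedModel,
    split_cohort,
    train_rfe_rf,
)
from .phantom import PhantomLesion, PhantomParams, generate_cohort
from .segmentation import SegmentationConfig, segment_exam
from .standardization import (
    StandardizationConfig,
    StandardizationMap,
    apply_standardization,
    learn_standard_scale,
    otsu_foreground,
)

log = logging.getLogger("deltarad")


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs, YAML-serializable.

    Defaults equal the published chain parameters: MRMR top 80%,
    elastic-net importance > 0.1, SMOTE K=5 with 3:1 minority weighting,
    1000 trees, 5 CV folds, Gabor bandwidth 1.414 at 0/90 degrees.
    """

    n_lesions: int = 278
    pcr_fraction: float = 74.0 / 278.0
    train_fraction: float = 0.8
    variant: int = 1
    seed: int = 0
    use_truth_masks: bool = False
    phantom: PhantomParams = field(default_factory=PhantomParams)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    standardization: StandardizationConfig = field(default_factory=StandardizationConfig)
    texture: TextureConfig = field(default_factory=TextureConfig)
    modeling: ModelingConfig = field(default_factory=ModelingConfig)

    def __post_init__(self) -> None:
        # propagate the master seed to every stochastic stage
        ss = np.random.SeedSequence(self.seed)
        s = [int(x % (2**31)) for x in ss.generate_state(4)]
        self.phantom = dataclasses.replace(self.phantom, seed=s[0])
        self.segmentation = dataclasses.replace(self.segmentation, random_state=s[1])
        self.texture = dataclasses.replace(self.texture, random_state=s[2])
        self.modeling = dataclasses.replace(self.modeling, seed=s[3])

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, sub in (
            ("phantom", PhantomParams),
            ("segmentation", SegmentationConfig),
            ("standardization", StandardizationConfig),
            ("texture", TextureConfig),
            ("modeling", ModelingConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                d = kwargs[key]
                for k, v in d.items():
                    if isinstance(v, list):
                        d[k] = tuple(v)
                kwargs[key] = sub(**d)
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """Artifacts of one end-to-end run."""

    table: pd.DataFrame
    model: TrainedModel
    train_report: EvalReport     #: pooled out-of-fold cross-validation scores
    test_report: EvalReport
    manifest: dict


def segment_cohort(
    lesions: list[PhantomLesion], config: SegmentationConfig
) -> list[tuple[TumorMask, TumorMask]]:
    """Grow volumetric masks for every lesion's two exams."""
    out = []
    for lesion in lesions:
        m_pre = segment_exam(lesion.pre_exam, lesion.seed_slice_pre, config)
        m_post = segment_exam(lesion.post_exam, lesion.seed_slice_post, config)
        out.append((m_pre, m_post))
    return out


def learn_phase_standardization(
    exams: list[DCESeries], config: StandardizationConfig
) -> dict[str, StandardizationMap]:
    """One standardization map per phase position, learned across exams."""
    maps = {}
    for k, phase in enumerate(PHASE_NAMES):
        vols = [e.phases[k] for e in exams]
        maps[phase] = learn_standard_scale(vols, config)
    return maps


def standardize_exam(
    series: DCESeries, maps: dict[str, StandardizationMap]
) -> DCESeries:
    fg = otsu_foreground(series.phases[0])
    phases = np.stack(
        [
            apply_standardization(series.phases[k], maps[phase], foreground=fg)
            for k, phase in enumerate(PHASE_NAMES)
        ]
    )
    return DCESeries(phases, spacing=series.spacing, exam_timing=series.exam_timing)


def extract_cohort_features(
    lesions: list[PhantomLesion],
    masks: list[tuple[TumorMask, TumorMask]],
    maps: dict[str, StandardizationMap],
    texture: TextureConfig,
) -> pd.DataFrame:
    rows = {}
    for lesion, (m_pre, m_post) in zip(lesions, masks):
        pre = standardize_exam(lesion.pre_exam, maps)
        post = standardize_exam(lesion.post_exam, maps)
        rows[lesion.lesion_id] = extract_lesion_features(
            pre, post, m_pre, m_post, texture
        )
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "lesion_id"
    return table


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Execute the full pipeline and return model plus evaluation reports."""
    timers = {}

    def _stage(name):
        timers[name] = time.perf_counter()
        log.info("stage %s started", name)

    def _done(name):
        timers[name] = time.perf_counter() - timers[name]
        log.info("stage %s finished in %.1fs", name, timers[name])

    _stage("simulate")
    lesions, clinical = generate_cohort(
        config.n_lesions, config.pcr_fraction, config.phantom
    )
    _done("simulate")

    _stage("split")
    clinical = split_cohort(clinical, config.train_fraction, seed=config.seed)
    _done("split")

    _stage("segment")
    if config.use_truth_masks:
        masks = [(l.truth_mask_pre, l.truth_mask_post) for l in lesions]
    else:
        masks = segment_cohort(lesions, config.segmentation)
    _done("segment")

    _stage("standardize")
    train_ids = set(clinical.index[clinical[SPLIT_COLUMN] == "train"])
    train_exams = [
        exam
        for lesion in lesions
        if lesion.lesion_id in train_ids
        for exam in (lesion.pre_exam, lesion.post_exam)
    ]
    maps = learn_phase_standardization(train_exams, config.standardization)
    _done("standardize")

    _stage("extract")
    features = extract_cohort_features(lesions, masks, maps, config.texture)
    _done("extract")

    table = features.join(clinical)

    _stage("train")
    model = train_rfe_rf(table, variant=config.variant, config=config.modeling)
    _done("train")

    _stage("evaluate")
    cv = model.cv_predictions
    cv_labels = pd.Series(
        np.where(cv["y"] == 1, "pCR", "no-pCR"), index=cv.index
    )
    train_report = evaluate_scores(cv["score"], cv_labels, model.threshold)

    test_rows = table[table[SPLIT_COLUMN] == "test"]
    test_scores = model.predict_scores(test_rows)
    test_report = evaluate_scores(
        test_scores, test_rows[LABEL_COLUMN], model.threshold
    )
    _done("evaluate")

    cfg_dict = config.to_dict()
    manifest = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": config.seed,
        "stage_seconds": {k: round(v, 2) for k, v in timers.items()},
        "n_train": int((table[SPLIT_COLUMN] == "train").sum()),
        "n_test": int((table[SPLIT_COLUMN] == "test").sum()),
    }

    result = PipelineResult(
        table=table,
        model=model,
        train_report=train_report,
        test_report=test_report,
        manifest=manifest,
    )
    if out_dir is not None:
        persist_result(result, out_dir)
    return result


def persist_result(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(out / "features.csv")
    with open(out / "report.json", "w") as fh:
        json.dump(
            {
                "train": result.train_report.to_dict(),
                "test": result.test_report.to_dict(),
                "selected_features": result.model.features,
                "importances": result.model.importances.to_dict(),
                "best_size": result.model.best_size,
                "cv_auc": result.model.cv_auc,
                "manifest": result.manifest,
            },
            fh,
            indent=2,
            default=str,
        )
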