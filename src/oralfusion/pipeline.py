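"""End-to-end orchestration: generate -> preprocess -> quantify -> reduce ->
fuse -> classify -> validate -> report.

``run_pipeline`` produces one report with three analysis blocks (raman-only,
velscope-only, fused), each holding — per classifier — the resubstitution
confusion matrix with its four metrics, and LOOCV / stratified k-fold error
rates.  The report is a plain dict of JSON-serializable values with a
provenance block (config hash, seeds, package version) and no timestamps, so
identical configurations yield byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import StageError
from .evaluation import CvConfig, confusion, kfold_cv, loocv, performance, resubstitution
from .models import (
    FeatureMatrix,
    feature_matrix_from_frame,
    fit_discriminant,
    fit_pca,
    fuse_features,
    transform_pca,
)
from .raman import PreprocessConfig, preprocess_cohort
from .reference import REPORTED_CONFUSIONS
from .synthetic import Cohort, CohortSpec, generate_cohort, save_cohort
from .velscope import quantify_cohort

__all__ = ["PipelineConfig", "run_pipeline", "make_fixtures"]

_CLASSIFIER_NAMES = {"linear": "pca_lda", "quadratic": "pca_qda"}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one full analysis."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    channel_mode: str = "green"
    n_components: int = 2
    classifiers: tuple[str, ...] = ("linear", "quadratic")
    kfold_k: int = 10
    cv_seed: int = 0
    paper_mode: bool = False
    group_by_patient: bool = False
    output_dir: str | None = None

    def to_json(self) -> dict:
        def _plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: _plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [_plain(v) for v in obj]
            return obj

        return _plain(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_json(), sort_keys=True).encode()
        ).hexdigest()


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage={name}: {exc}") from exc


def build_feature_matrices(cohort: Cohort, config: PipelineConfig) -> dict[str, FeatureMatrix]:
    """Per-modality sample-level feature matrices, aligned on sample ids."""
    raman_df = _stage("preprocess", preprocess_cohort, cohort.spectra, config.preprocess)
    vel_df = _stage("quantify", quantify_cohort, cohort.images, config.channel_mode)
    raman_fm = feature_matrix_from_frame(raman_df, modality="raman")
    vel_fm = feature_matrix_from_frame(
        vel_df, ["norm_intensity", "norm_heterogeneity"], modality="velscope"
    )
    if raman_fm.sample_ids != vel_fm.sample_ids:
        order = [vel_fm.sample_ids.index(s) for s in raman_fm.sample_ids]
        vel_fm = vel_fm.subset(np.asarray(order))
    return {"raman": raman_fm, "velscope": vel_fm}


def _analysis_block(dataset, config: PipelineConfig, kind: str) -> dict:
    cv_cfg = CvConfig(
        classifier=kind,
        n_components=config.n_components,
        paper_mode=config.paper_mode,
        group_by_patient=config.group_by_patient,
    )
    resub = resubstitution(dataset, cv_cfg)
    cm = confusion(resub.y_true, resub.y_pred, positive_class="tumor")
    metrics = performance(cm)
    loo = loocv(dataset, cv_cfg)
    kf = kfold_cv(dataset, config.kfold_k, config.cv_seed, cv_cfg)
    return {
        "confusion": cm.as_dict(),
        "metrics": {
            "accuracy": metrics.accuracy,
            "sensitivity": metrics.sensitivity,
            "specificity": metrics.specificity,
            "error_rate": metrics.error_rate,
        },
        "cv": {
            "loocv_error_rate": loo.error_rate,
            "kfold_error_rate": kf.error_rate,
            "kfold_k": config.kfold_k,
            "cv_seed": config.cv_seed,
            "paper_mode": config.paper_mode,
        },
    }


def run_pipeline(config: PipelineConfig = PipelineConfig()) -> dict:
    """Run all three analyses and return the report dict.

    When ``config.output_dir`` is set, the feature tables (CSV), fitted
    full-data models (JSON), and the report (JSON) are written there.
    """
    cohort = _stage("simulate", generate_cohort, config.cohort)
    fms = build_feature_matrices(cohort, config)
    mods: dict[str, object] = {
        "raman": fms["raman"],
        "velscope": fms["velscope"],
        "fused": [fms["raman"], fms["velscope"]],
    }
    report: dict = {
        "provenance": {
            "package_version": __version__,
            "config": config.to_json(),
            "config_sha256": config.digest(),
            "cohort_seed": config.cohort.seed,
            "cv_seed": config.cv_seed,
            "cohort_digest": cohort.digest(),
        },
        "n_samples": int(fms["raman"].n_samples),
        "analyses": {},
    }
    for name, dataset in mods.items():
        block = {}
        for kind in config.classifiers:
            block[_CLASSIFIER_NAMES[kind]] = _stage(
                f"classify[{name},{kind}]", _analysis_block, dataset, config, kind
            )
        report["analyses"][name] = block

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, fm in fms.items():
            df = pd.DataFrame(fm.values, index=fm.sample_ids)
            df.insert(0, "tissue_class", fm.labels)
            df.to_csv(out / f"features_{name}.csv")
        for name, fm in fms.items():
            k = min(config.n_components, fm.n_samples - 1, fm.n_features)
            pca = fit_pca(fm, k)
            (out / f"pca_{name}.json").write_text(json.dumps(pca.to_json(), indent=1))
        scores = {
            name: transform_pca(
                fit_pca(fm, min(config.n_components, fm.n_samples - 1, fm.n_features)), fm
            )
            for name, fm in fms.items()
        }
        fused_scores = fuse_features(scores["raman"], scores["velscope"])
        for kind in config.classifiers:
            clf = fit_discriminant(fused_scores, kind=kind)
            (out / f"discriminant_fused_{kind}.json").write_text(
                json.dumps(clf.to_json(), indent=1)
            )
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def make_fixtures(seed: int = 0, outdir: str | Path = "fixtures") -> Path:
    """Write a small 4-patient cohort plus the reference confusion counts.

    The bundle contains 40 raw spectrum CSVs (4 patients x 2 classes x 5
    replicates), 4 PNG images with their ROI JSON, the manifest, and
    ``reference_confusions.json`` for metric regression tests.
    """
    outdir = Path(outdir)
    spec = CohortSpec(n_patients=4, replicates_per_sample=5, seed=seed)
    cohort = generate_cohort(spec)
    save_cohort(cohort, outdir)
    reference = {
        f"{modality}/{kind}": counts
        for (modality, kind), counts in REPORTED_CONFUSIONS.items()
    }
    (outdir / "reference_confusions.json").write_text(json.dumps(reference, indent=1))
    return outdir
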