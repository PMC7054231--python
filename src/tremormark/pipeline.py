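"""End-to-end analysis orchestration.

``run_full_analysis`` executes load → preprocess/features → cohort stats →
feature selection → GPR prediction with permutation testing, and writes a
provenance-stamped report (every table regenerable from manifest + config).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .features import FeatureConfig, cohort_feature_table
from .io import PatientRecord, load_cohort
from .prediction import ImprovementGPR, GPRPredictionResults
from .preprocess import EnvelopeConfig, FilterConfig
from .stats import (
    build_ir_table,
    paired_change_table,
    select_predictive_features,
    spearman_cocorrelation,
)

__all__ = ["AnalysisConfig", "Report", "run_full_analysis", "analyze_patients"]

logger = logging.getLogger(__name__)

#: Fallback predictors when no feature passes selection on a weak cohort.
FALLBACK_FEATURES = ["PeakFPSD", "wRMS", "MNP"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Full configuration of the analysis; defaults match the module docs."""

    features: FeatureConfig = field(default_factory=FeatureConfig)
    alpha: float = 0.05
    correction: "str | None" = None
    kernel: str = "rbf"
    standardize: bool = True
    n_restarts: int = 1
    n_permutations: int = 1000
    loocv_method: str = "per_fold"
    #: at most this many selected features (by |R|) enter the GP model
    max_model_features: int = 3
    seed: int = 42

    def to_dict(self) -> dict:
        out = asdict(self)
        return _tuples_to_lists(out)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        data = dict(data)
        feat = data.pop("features", {})
        if isinstance(feat, dict):
            filt = feat.pop("filter", {})
            env = feat.pop("envelope", {})
            feat = {k: _list_to_tuple(v) for k, v in feat.items()}
            feature_cfg = FeatureConfig(
                filter=FilterConfig(**{k: _list_to_tuple(v) for k, v in filt.items()}),
                envelope=EnvelopeConfig(**env),
                **feat,
            )
        else:
            feature_cfg = feat
        return cls(features=feature_cfg, **data)

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: "str | Path") -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class Report:
    """All analysis outputs plus run metadata."""

    feature_table: pd.DataFrame
    ir_table: pd.DataFrame
    paired_table: pd.DataFrame
    cocorrelation_R: pd.DataFrame
    cocorrelation_P: pd.DataFrame
    cocorrelation_thresholded: pd.DataFrame
    selected_features: pd.DataFrame
    used_fallback: bool
    prediction: GPRPredictionResults
    config: AnalysisConfig
    metadata: dict

    def write(self, out_dir: "str | Path") -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.feature_table.to_csv(out_dir / "feature_table.csv", index=False)
        self.ir_table.to_csv(out_dir / "ir_table.csv")
        self.paired_table.to_csv(out_dir / "paired_change_table.csv")
        self.cocorrelation_R.to_csv(out_dir / "cocorrelation_R.csv")
        self.cocorrelation_P.to_csv(out_dir / "cocorrelation_P.csv")
        self.cocorrelation_thresholded.to_csv(
            out_dir / "cocorrelation_R_thresholded.csv"
        )
        self.selected_features.to_csv(out_dir / "selected_features.csv", index=False)
        self.prediction.to_frame().to_csv(
            out_dir / "prediction_scatter.csv", index=False
        )
        payload = {
            "prediction": self.prediction.to_dict(),
            "used_fallback_features": self.used_fallback,
            "metadata": self.metadata,
            "config": self.config.to_dict(),
        }
        with open(out_dir / "prediction_result.json", "w") as fh:
            json.dump(payload, fh, indent=2)
        return out_dir


def analyze_patients(
    patients: Sequence[PatientRecord],
    config: "AnalysisConfig | None" = None,
    feature_table: "pd.DataFrame | None" = None,
) -> Report:
    """Run the analysis stages on in-memory patients.

    ``feature_table`` may be supplied to skip re-extraction (it must match
    the cohort). Stage order: features → improvement rates → paired change
    table → co-correlation of significantly changed features → selection of
    outcome-associated features → LOOCV-GPR with permutation test.
    """
    config = config or AnalysisConfig()
    stage = "features"
    try:
        if feature_table is None:
            feature_table = cohort_feature_table(patients, config.features)
        stage = "cohort_stats"
        ir_table = build_ir_table(feature_table, patients)
        paired = paired_change_table(
            feature_table, patients, correction=config.correction
        )
        significant = [
            name
            for name in paired.index
            if name not in ("UPDRS_III", "UPDRS_t") and paired.loc[name, "p"] < config.alpha
        ]
        cols = [f"IR_{name}" for name in significant]
        if len(significant) >= 2:
            r_df, p_df, thr = spearman_cocorrelation(
                ir_table, columns=cols, alpha=config.alpha
            )
        else:
            r_df = p_df = thr = pd.DataFrame()
        selected = select_predictive_features(ir_table, alpha=config.alpha)
        used_fallback = False
        if selected.empty:
            logger.warning(
                "no feature passed selection at alpha=%.3g; "
                "falling back to the canonical trio %s",
                config.alpha,
                FALLBACK_FEATURES,
            )
            used_fallback = True
            # the fallback trio is filtered by the same completeness rule as
            # regular selection so complete-case deletion cannot gut the model
            names = [
                f
                for f in FALLBACK_FEATURES
                if ir_table[f"IR_{f}"].notna().mean() >= 0.8
            ] or ["wRMS", "MNP"]
        else:
            # selection is sorted by |R| descending; a handful of predictors
            # is all a GP at this cohort size can support
            names = list(selected["feature"].head(config.max_model_features))
        stage = "prediction"
        model = ImprovementGPR.from_ir_table(
            ir_table,
            names,
            kernel=config.kernel,
            standardize=config.standardize,
            n_restarts=config.n_restarts,
        )
        results = model.fit(seed=config.seed, method=config.loocv_method)
        results.permutation_test(n_permutations=config.n_permutations)
    except Exception as exc:
        raise RuntimeError(f"analysis failed in stage {stage!r}: {exc}") from exc

    from importlib.metadata import version as _dist_version

    try:
        pkg_version = _dist_version("tremormark")
    except Exception:  # pragma: no cover
        pkg_version = "unknown"
    metadata = {
        "software_version": pkg_version,
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_patients": len(patients),
        "significant_features": significant,
        "selected_features": names,
    }
    return Report(
        feature_table=feature_table,
        ir_table=ir_table,
        paired_table=paired,
        cocorrelation_R=r_df,
        cocorrelation_P=p_df,
        cocorrelation_thresholded=thr,
        selected_features=selected,
        used_fallback=used_fallback,
        prediction=results,
        config=config,
        metadata=metadata,
    )


def run_full_analysis(
    manifest_path: "str | Path",
    config: "AnalysisConfig | None" = None,
    out_dir: "str | Path | None" = None,
) -> Report:
    """Load a cohort manifest, run every stage, optionally write the report."""
    config = config or AnalysisConfig()
    patients = load_cohort(manifest_path)
    report = analyze_patients(patients, config)
    report.metadata["manifest"] = str(manifest_path)
    if out_dir is not None:
        report.write(out_dir)
    return report


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_tuples_to_lists(v) for v in obj]
    return obj


def _list_to_tuple(v):
    return tuple(v) if isinstance(v, list) else v
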