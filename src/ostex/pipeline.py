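"""End-to-end orchestration: extract -> screen -> match -> score.

Stages:

1. **Extract** texture features per subject, region and timepoint (rater 1
   masks), and duplicate-rater feature tables for the reproducibility
   subset.
2. **Screen** the feature registry on inter-observer ICC/RMSCV in both
   regions.
3. **Build the cohort**: progression labels from the minJSW trajectory,
   eligibility exclusions, optimal 1:1 propensity matching of cases to the
   control pool.
4. **Score**: six repeated-LASSO composite-score models
   (tibial/femoral/combined x initial/change) with odds ratios per SD,
   c-statistics and the p < 0.008 significance gate.

Works on an in-memory :class:`~ostex.synthetic.SyntheticStudy` or on a
study directory with a ``manifest.csv`` (see :mod:`ostex.synthetic`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .image_roi import GrayImage, InputError, ROIMask, Slice, SliceSeries, read_image, read_mask
from .reproducibility import (
    ICC_MIN_DEFAULT,
    RMSCV_MAX_DEFAULT,
    ReproducibilityReport,
    assess_reproducibility,
    screen_registry,
)
from .score import AssociationResult, run_association_suite
from .synthetic import SyntheticStudy
from .texture import DEFAULT_REGISTRY, TextureConfig, build_feature_table, feature_table_to_tidy, series_feature_vectors

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisSettings:
    """Screening and modelling knobs for one analysis run."""

    icc_min: float = ICC_MIN_DEFAULT
    rmscv_max: float = RMSCV_MAX_DEFAULT
    n_iter: int = 100
    n_folds: int = 10
    n_lambda: int = 100
    base_seed: int = 0


def features_from_series(
    series_map: Mapping[tuple[str, str], SliceSeries],
    config: TextureConfig = TextureConfig(),
) -> pd.DataFrame:
    """Feature table from (subject_id, timepoint) -> SliceSeries."""
    vectors: dict[tuple[str, str, str], dict[str, float]] = {}
    for (sid, tp_name), series in series_map.items():
        for region, feats in series_feature_vectors(series, config).items():
            vectors[(sid, region, tp_name)] = feats
    return build_feature_table(vectors, registry=config.registry)


def extract_study_features(
    study: SyntheticStudy, config: TextureConfig = TextureConfig()
) -> pd.DataFrame:
    """Rater-1 feature table for every subject and timepoint of a study."""
    series_map = {
        (sid, tp_name): series
        for sid, subj in study.subjects.items()
        for tp_name, series in subj.series.items()
    }
    return features_from_series(series_map, config)


def duplicate_ratings(
    study: SyntheticStudy,
    config: TextureConfig = TextureConfig(),
    timepoint: str = "initial",
) -> dict[tuple[str, str], np.ndarray]:
    """(feature, region) -> n_subjects x 2 rating table for the duplicate set."""
    dup = study.duplicate_subject_ids()
    if len(dup) < 3:
        raise InputError("need >= 3 duplicate-rater subjects for reproducibility")
    r1 = features_from_series(
        {(sid, timepoint): study.subjects[sid].series[timepoint] for sid in dup}, config
    )
    r2 = features_from_series(
        {(sid, timepoint): study.subjects[sid].rater2_series[timepoint] for sid in dup}, config
    )
    ratings: dict[tuple[str, str], np.ndarray] = {}
    for region in ("medial_tibia", "medial_femur"):
        a = r1[(r1.region == region) & (r1.timepoint == timepoint)].set_index("subject_id")
        b = r2[(r2.region == region) & (r2.timepoint == timepoint)].set_index("subject_id")
        for feat in config.registry:
            ratings[(feat, region)] = np.column_stack(
                [a.loc[dup, feat].to_numpy(), b.loc[dup, feat].to_numpy()]
            )
    return ratings


def load_study_features(
    study_dir: str | Path, config: TextureConfig = TextureConfig(), rater: str = "1"
) -> pd.DataFrame:
    """Feature table from an on-disk study directory's manifest."""
    series_map = load_series_map(study_dir, rater=rater)
    return features_from_series(series_map, config)


def load_series_map(
    study_dir: str | Path, rater: str = "1", subjects: Sequence[str] | None = None
) -> dict[tuple[str, str], SliceSeries]:
    root = Path(study_dir)
    manifest = pd.read_csv(root / "manifest.csv", dtype={"rater": str})
    manifest = manifest[manifest.rater == rater]
    if subjects is not None:
        manifest = manifest[manifest.subject_id.isin(set(subjects))]
    series_map: dict[tuple[str, str], SliceSeries] = {}
    for (sid, tp_name), grp in manifest.groupby(["subject_id", "timepoint"]):
        slices = []
        for k, sl_grp in grp.groupby("slice_index"):
            image = GrayImage(read_image(root / sl_grp.image_path.iloc[0]))
            masks = {
                row.region: ROIMask(read_mask(root / row.mask_path), row.region)
                for row in sl_grp.itertuples(index=False)
            }
            slices.append(Slice(image=image, masks=masks))
        series_map[(str(sid), str(tp_name))] = SliceSeries(
            slices, subject_id=str(sid), timepoint=str(tp_name)
        )
    return series_map


def duplicate_ratings_from_dir(
    study_dir: str | Path, config: TextureConfig = TextureConfig(), timepoint: str = "initial"
) -> dict[tuple[str, str], np.ndarray]:
    root = Path(study_dir)
    manifest = pd.read_csv(root / "manifest.csv", dtype={"rater": str})
    dup = sorted(manifest.loc[manifest.rater == "2", "subject_id"].unique())
    if len(dup) < 3:
        raise InputError("study has < 3 duplicate-rater subjects")
    tables = {}
    for rater in ("1", "2"):
        smap = {
            k: v for k, v in load_series_map(root, rater=rater, subjects=dup).items()
            if k[1] == timepoint
        }
        tables[rater] = features_from_series(smap, config)
    ratings: dict[tuple[str, str], np.ndarray] = {}
    for region in ("medial_tibia", "medial_femur"):
        a = tables["1"][tables["1"].region == region].set_index("subject_id")
        b = tables["2"][tables["2"].region == region].set_index("subject_id")
        for feat in config.registry:
            ratings[(feat, region)] = np.column_stack(
                [a.loc[dup, feat].to_numpy(), b.loc[dup, feat].to_numpy()]
            )
    return ratings


@dataclass
class PipelineResult:
    """Everything one analysis run produces."""

    feature_table: pd.DataFrame
    reproducibility: ReproducibilityReport
    retained_features: list[str]
    matched: cohort_mod.MatchedCohort
    exclusion_log: pd.DataFrame
    balance: pd.Series
    results: list[AssociationResult]
    results_table: pd.DataFrame

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.feature_table.to_csv(out / "features_wide.csv", index=False)
        feature_table_to_tidy(self.feature_table).to_csv(out / "features_tidy.csv", index=False)
        self.reproducibility.to_csv(out / "reproducibility.csv")
        self.matched.pairs.to_csv(out / "matching_audit.csv", index=False)
        self.exclusion_log.to_csv(out / "exclusions.csv", index=False)
        self.balance.rename_axis("covariate").to_frame().to_csv(out / "balance.csv")
        self.results_table.to_csv(out / "results.csv", index=False)
        return out


def build_matched_cohort(
    cohort_df: pd.DataFrame,
) -> tuple[cohort_mod.MatchedCohort, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Label, screen and match a cohort table.

    Returns (matched cohort, cases, controls, exclusion log).
    """
    df = cohort_df.copy()
    df["subject_id"] = df.subject_id.astype(str)
    eligible, excl_log = cohort_mod.apply_exclusions(df)
    status = [
        cohort_mod.classify_progression(r.minjsw_36m, r.minjsw_72m)
        for r in eligible.itertuples(index=False)
    ]
    eligible = eligible.assign(status=status)
    cases = eligible[eligible.status == "case"].reset_index(drop=True)
    controls = eligible[eligible.status == "control"].reset_index(drop=True)
    if len(cases) == 0:
        raise InputError("no eligible cases in cohort")
    matched = cohort_mod.propensity_match(cases, controls)
    return matched, cases, controls, excl_log


def analyze(
    feature_table: pd.DataFrame,
    cohort_df: pd.DataFrame,
    ratings: Mapping[tuple[str, str], np.ndarray],
    *,
    registry: Sequence[str] = DEFAULT_REGISTRY,
    settings: AnalysisSettings = AnalysisSettings(),
) -> PipelineResult:
    """Screen, match and model an extracted study."""
    report = assess_reproducibility(
        ratings, icc_min=settings.icc_min, rmscv_max=settings.rmscv_max
    )
    retained = screen_registry(report, [f for f in registry])
    logger.info("reproducibility screen retained %d/%d features", len(retained), len(registry))

    matched, cases, controls, excl_log = build_matched_cohort(cohort_df)
    balance = cohort_mod.standardized_mean_differences(cases, controls, matched)
    labels = matched.labels()

    results, results_table = run_association_suite(
        feature_table, labels, retained,
        n_iter=settings.n_iter, n_folds=settings.n_folds,
        n_lambda=settings.n_lambda, base_seed=settings.base_seed,
    )
    return PipelineResult(
        feature_table=feature_table,
        reproducibility=report,
        retained_features=retained,
        matched=matched,
        exclusion_log=excl_log,
        balance=balance,
        results=results,
        results_table=results_table,
    )


def run_study(
    study: SyntheticStudy,
    *,
    config: TextureConfig = TextureConfig(),
    settings: AnalysisSettings = AnalysisSettings(),
) -> PipelineResult:
    """Full pipeline on an in-memory synthetic study."""
    features = extract_study_features(study, config)
    ratings = duplicate_ratings(study, config)
    return analyze(features, study.cohort, ratings, registry=config.registry,
                   settings=settings)
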