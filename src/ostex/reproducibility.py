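"""Inter-observer reproducibility screening of texture features.

Duplicate ROI analyses by two independent analysts yield, per feature and
region, an n-subjects x 2 rating table.  Agreement is summarized by the
two-way random-effects, absolute-agreement, single-measures intraclass
correlation ICC(A,1) and by the root-mean-square average coefficient of
variation (RMSCV).  A feature enters modelling only if ICC >= 0.8 and
RMSCV <= 10% in BOTH regions — failing either threshold in either region
excludes it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .image_roi import InputError

logger = logging.getLogger(__name__)

ICC_MIN_DEFAULT = 0.8
RMSCV_MAX_DEFAULT = 10.0


def _as_ratings(ratings: np.ndarray) -> np.ndarray:
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[1] != 2:
        raise InputError(f"ratings must be n x 2 (subjects x analysts), got {r.shape}")
    if r.shape[0] < 3:
        raise InputError("need >= 3 subjects for reproducibility metrics")
    if not np.all(np.isfinite(r)):
        raise InputError("ratings contain missing/non-finite cells")
    return r


def icc_single_absolute(ratings: np.ndarray) -> float:
    """ICC(A,1): two-way random effects, absolute agreement, single measures.

    Computed from explicit two-way ANOVA mean squares with k raters and n
    subjects::

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    Absolute agreement penalizes systematic rater offsets: a constant shift
    between analysts lowers the ICC even when rankings agree perfectly.
    """
    r = _as_ratings(ratings)
    n, k = r.shape
    grand = r.mean()
    row_means = r.mean(axis=1)
    col_means = r.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((r - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err + (k / n) * (ms_cols - ms_err)
    if denom <= 0:
        raise InputError("ICC undefined: zero total variance in ratings")
    return float((ms_rows - ms_err) / denom)


def rmscv(ratings: np.ndarray, *, eps_rel: float = 1e-8) -> float:
    """Root-mean-square average coefficient of variation, in percent.

    Per subject, CV = SD(two ratings) / |mean(two ratings)| using the
    sample (n-1) SD, so for two ratings a and b, SD = |a - b| / sqrt(2).
    RMSCV = 100 * sqrt(mean CV^2).  Subjects whose |mean| falls below
    ``eps_rel`` times the feature scale (largest |rating|) are excluded
    (CV is ill-defined near zero, e.g. for sign-crossing skewness values);
    if all subjects are excluded the metric is undefined.
    """
    r = _as_ratings(ratings)
    means = r.mean(axis=1)
    sds = np.abs(r[:, 0] - r[:, 1]) / np.sqrt(2.0)
    scale = np.max(np.abs(r))
    keep = np.abs(means) >= eps_rel * max(scale, np.finfo(float).tiny)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("rmscv: excluded %d subject(s) with near-zero mean rating", n_dropped)
    if not keep.any():
        raise InputError("RMSCV undefined: all subjects have near-zero mean ratings")
    cv = sds[keep] / np.abs(means[keep])
    return float(100.0 * np.sqrt(np.mean(cv**2)))


@dataclass
class ReproducibilityReport:
    """Per feature x region agreement metrics with retain/drop verdicts."""

    table: pd.DataFrame  # columns: feature, region, icc, rmscv_percent, retained
    icc_min: float = ICC_MIN_DEFAULT
    rmscv_max: float = RMSCV_MAX_DEFAULT

    def retained_features(self, registry_order: Sequence[str] | None = None) -> list[str]:
        kept = set(self.table.groupby("feature")["retained"].all().loc[lambda s: s].index)
        if registry_order is None:
            registry_order = list(dict.fromkeys(self.table.feature))
        return [f for f in registry_order if f in kept]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def assess_reproducibility(
    ratings_by_feature_region: Mapping[tuple[str, str], np.ndarray],
    *,
    icc_min: float = ICC_MIN_DEFAULT,
    rmscv_max: float = RMSCV_MAX_DEFAULT,
) -> ReproducibilityReport:
    """Compute ICC and RMSCV per (feature, region) and apply the screen.

    A (feature, region) cell passes iff ICC >= ``icc_min`` AND
    RMSCV <= ``rmscv_max`` (exclusion is strictly "ICC < 0.8 or
    RMSCV > 10%", so boundary values are retained).  An undefined metric
    auto-fails the cell.
    """
    rows = []
    for (feature, region), ratings in ratings_by_feature_region.items():
        try:
            icc = icc_single_absolute(ratings)
        except InputError as exc:
            logger.warning("ICC undefined for %s/%s: %s", feature, region, exc)
            icc = np.nan
        try:
            cv = rmscv(ratings)
        except InputError as exc:
            logger.warning("RMSCV undefined for %s/%s: %s", feature, region, exc)
            cv = np.nan
        ok = bool(np.isfinite(icc) and np.isfinite(cv) and icc >= icc_min and cv <= rmscv_max)
        rows.append(
            {"feature": feature, "region": region, "icc": icc,
             "rmscv_percent": cv, "retained": ok}
        )
    report = ReproducibilityReport(pd.DataFrame(rows), icc_min=icc_min, rmscv_max=rmscv_max)
    return report


def screen_registry(
    report: ReproducibilityReport,
    registry: Sequence[str],
    *,
    required_regions: Sequence[str] = ("medial_tibia", "medial_femur"),
) -> list[str]:
    """Registry features passing the screen in every required region."""
    covered = set(map(tuple, report.table[["feature", "region"]].itertuples(index=False)))
    for feature in registry:
        for region in required_regions:
            if (feature, region) not in covered:
                raise InputError(
                    f"reproducibility report missing ({feature}, {region})"
                )
    retained = [
        f for f in registry
        if all(
            report.table.loc[
                (report.table.feature == f) & (report.table.region == r), "retained"
            ].item()
            for r in required_regions
        )
    ]
    dropped = [f for f in registry if f not in retained]
    if dropped:
        logger.info("screened out %d feature(s): %s", len(dropped), ", ".join(dropped))
    if not retained:
        raise InputError("reproducibility screen retained no features; aborting")
    return retained
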