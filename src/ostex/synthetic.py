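"""Synthetic trabecular-texture studies for end-to-end pipeline testing.

Real study data (coronal FISP MRIs of the knee) cannot be redistributed,
so this module fabricates complete studies with known ground truth:

* **Images** — thresholded Gaussian random fields.  White noise is smoothed
  at a correlation length ``ell`` (pixels), thresholded at a quantile to a
  binary trabecular pattern, then blurred and corrupted with Rician noise
  as in magnitude MRI.  ``ell`` is the single "spatial organisation" knob:
  large ``ell`` gives coarse, organised plates (low GLCM entropy, long
  runs); small ``ell`` gives fine, disorganised texture.  Progressors are
  emulated by drawing their (follow-up) ``ell`` smaller than controls'.
* **ROIs** — rectangular bands of ~1 cm equivalent depth above and below a
  synthetic joint line (medial femur above, medial tibia below), plus
  morphologically jittered duplicate-rater masks for reproducibility runs.
* **Covariates** — age, sex, BMI and minJSW trajectories drawn from the
  study population's published distributions (age ~64 y, BMI ~31 kg/m^2,
  initial minJSW ~3.8 mm; minJSW change N(-1.29, 0.63) mm in progressors,
  N(0, 0.44) in controls), with Kellgren-Lawrence and OARSI JSN grades at
  the observed frequencies.

Everything is deterministic given (parameters, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_roi import GrayImage, ROIMask, Slice, SliceSeries, write_image_png, write_mask_png

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TextureParams:
    """Generative texture settings for one study."""

    correlation_length: float = 4.0  # px; control-group baseline ell
    trabecular_threshold: float = 0.5  # field quantile kept as "bone"
    noise_sigma: float = 40.0  # Rician channel SD, scanner units
    blur_sigma: float = 0.6  # px, point-spread blur after thresholding
    image_size: int = 256  # px (desk-scale stand-in for 1024)
    slice_count: int = 5
    roi_depth_px: int = 21  # ~1 cm at 256 px across a 12 cm field of view
    joint_gap_px: int = 6
    roi_margin_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be > 0")
        if not 0.0 < self.trabecular_threshold < 1.0:
            raise ValueError("trabecular_threshold must be in (0, 1)")
        if self.slice_count < 1:
            raise ValueError("slice_count must be >= 1")


@dataclass(frozen=True)
class CohortParams:
    """Cohort-level generative settings (defaults follow the published
    participant table of the emulated study)."""

    n_cases: int = 61
    n_controls_pool: int = 122  # pool for matching incl. reserves
    age_mean: float = 64.5
    age_sd: float = 8.0
    bmi_mean: float = 31.2
    bmi_sd: float = 4.7
    female_fraction: float = 0.42  # 51 of 122
    minjsw_mean: float = 3.8
    minjsw_sd: float = 1.2
    case_change_mean: float = -1.29
    case_change_sd: float = 0.63
    control_change_mean: float = 0.0
    control_change_sd: float = 0.44
    # texture effect sizes, in correlation-length units
    ell_group_delta: float = 0.15  # cases' initial ell deficit vs controls
    ell_change_delta: float = 0.25  # additional follow-up ell loss in cases
    ell_between_sd: float = 0.25  # between-subject ell spread
    ell_drift_sd: float = 0.05  # within-subject follow-up ell noise
    rater_jitter_px: float = 1.0  # duplicate-analyst ROI boundary jitter
    n_duplicate: int = 23  # subjects analysed in duplicate
    followup_missing_fraction: float = 0.0
    strict_labels: bool = True  # resample minJSW change until it matches group
    seed: int = 0

    def zero_effect(self) -> "CohortParams":
        """Same cohort with no texture difference between groups."""
        return replace(self, ell_group_delta=0.0, ell_change_delta=0.0)

    def strong_effect(self) -> "CohortParams":
        """Group follow-up ell separation of 4x the between-subject SD."""
        return replace(self, ell_group_delta=0.25, ell_change_delta=1.0)


# Kellgren-Lawrence 0..3 and OARSI medial JSN 0..2 frequencies pooled over
# the emulated study's cases and controls (KL-4 knees are excluded upstream).
KL_PROBS = np.array([15, 20, 45, 42], dtype=float) / 122.0
JSN_MEDIAL_PROBS = np.array([40, 40, 42], dtype=float) / 122.0
JSN_LATERAL_PROBS = np.array([118, 4, 0], dtype=float) / 122.0

PROGRESSION_THRESHOLD_MM = 0.7


def make_trabecular_field(
    size: int, ell: float, threshold: float, rng: np.random.Generator
) -> np.ndarray:
    """Binary trabecular pattern: smoothed white noise above its quantile."""
    noise = rng.standard_normal((size, size))
    smooth = ndimage.gaussian_filter(noise, sigma=ell)
    cut = np.quantile(smooth, threshold)
    return (smooth >= cut).astype(float)


def _rician(image: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma <= 0:
        return image
    n1 = rng.normal(0.0, sigma, image.shape)
    n2 = rng.normal(0.0, sigma, image.shape)
    return np.sqrt((image + n1) ** 2 + n2**2)


def make_roi_masks(params: TextureParams) -> dict[str, np.ndarray]:
    """Rectangular femoral (above) and tibial (below) bands at the joint line."""
    size = params.image_size
    mid = size // 2
    half_gap = params.joint_gap_px // 2
    margin = int(round(params.roi_margin_frac * size))
    femur = np.zeros((size, size), dtype=bool)
    tibia = np.zeros((size, size), dtype=bool)
    femur[mid - half_gap - params.roi_depth_px : mid - half_gap, margin : size - margin] = True
    tibia[mid + half_gap : mid + half_gap + params.roi_depth_px, margin : size - margin] = True
    return {"medial_femur": femur, "medial_tibia": tibia}


def make_trabecular_slice(
    params: TextureParams, seed: int | np.random.Generator, *, ell: float | None = None
) -> tuple[GrayImage, dict[str, ROIMask]]:
    """One synthetic coronal slice with its two subchondral-band ROIs."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ell = params.correlation_length if ell is None else ell
    pattern = make_trabecular_field(params.image_size, ell, params.trabecular_threshold, rng)
    img = 200.0 + 800.0 * pattern
    if params.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=params.blur_sigma)
    img = _rician(img, params.noise_sigma, rng)
    masks = {
        label: ROIMask(m, label) for label, m in make_roi_masks(params).items()
    }
    return GrayImage(img), masks


def jitter_mask(mask: np.ndarray, jitter_px: float, rng: np.random.Generator) -> np.ndarray:
    """Duplicate-analyst ROI: translate the boundary and grow/shrink by one.

    ``jitter_px`` scales a random integer translation; with probability 1/2
    the mask is additionally eroded or dilated one step.  ``jitter_px = 0``
    returns the mask unchanged.
    """
    if jitter_px <= 0:
        return mask.copy()
    shift = np.round(rng.normal(0.0, jitter_px, size=2)).astype(int)
    out = np.roll(mask, shift, axis=(0, 1))
    if rng.random() < 0.5:
        op = ndimage.binary_erosion if rng.random() < 0.5 else ndimage.binary_dilation
        candidate = op(out)
        if candidate.sum() >= ROIMask.MIN_PIXELS:
            out = candidate
    return out


@dataclass
class SyntheticSubject:
    record: dict
    series: dict[str, SliceSeries]  # timepoint -> series (rater 1)
    rater2_series: dict[str, SliceSeries] = field(default_factory=dict)
    truth: dict[str, float] = field(default_factory=dict)  # timepoint -> ell


def _draw_change(
    group: str, cp: CohortParams, rng: np.random.Generator
) -> float:
    """minJSW change (72m - 36m, mm) consistent with the assigned group."""
    if group == "case":
        mu, sd, ok = cp.case_change_mean, cp.case_change_sd, lambda d: d <= -PROGRESSION_THRESHOLD_MM
    else:
        mu, sd, ok = cp.control_change_mean, cp.control_change_sd, lambda d: d > -PROGRESSION_THRESHOLD_MM
    for _ in range(1000):
        d = rng.normal(mu, sd)
        if not cp.strict_labels or ok(d):
            return float(d)
    raise RuntimeError("could not draw a group-consistent minJSW change")


def draw_covariates(
    group: str,
    cohort_params: CohortParams,
    rng: np.random.Generator,
    *,
    subject_id: str = "S000",
) -> dict:
    """One subject's cohort-table row (no images).

    Cases and controls share the same covariate distributions — as in the
    emulated study, where matching makes the groups near-identical on age,
    sex, BMI and initial minJSW — and differ only in the minJSW trajectory.
    """
    if group not in ("case", "control"):
        raise ValueError(f"group must be 'case' or 'control', got {group!r}")
    cp = cohort_params
    minjsw_36 = float(np.clip(rng.normal(cp.minjsw_mean, cp.minjsw_sd), 0.9, None))
    change = _draw_change(group, cp, rng)
    kl = int(rng.choice(4, p=KL_PROBS))
    jsn_med = int(rng.choice(3, p=JSN_MEDIAL_PROBS))
    jsn_lat = min(int(rng.choice(3, p=JSN_LATERAL_PROBS)), jsn_med)
    return {
        "subject_id": subject_id,
        "group": group,
        "age": float(np.clip(rng.normal(cp.age_mean, cp.age_sd), 45.0, 85.0)),
        "sex": "F" if rng.random() < cp.female_fraction else "M",
        "bmi": float(np.clip(rng.normal(cp.bmi_mean, cp.bmi_sd), 18.0, 50.0)),
        "kl_grade_36m": kl,
        "oarsi_jsn_medial_36m": jsn_med,
        "oarsi_jsn_lateral_36m": jsn_lat,
        "minjsw_36m": minjsw_36,
        "minjsw_72m": float(max(minjsw_36 + change, 0.0)),
    }


def make_subject(
    group: str,
    cohort_params: CohortParams,
    texture_params: TextureParams,
    seed: int | np.random.Generator,
    *,
    subject_id: str = "S000",
    duplicate_rater: bool = False,
    with_followup: bool = True,
) -> SyntheticSubject:
    """Covariates, two-timepoint slice series and optional duplicate masks."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cp, tp = cohort_params, texture_params
    record = draw_covariates(group, cp, rng, subject_id=subject_id)

    is_case = group == "case"
    ell_base = tp.correlation_length - (cp.ell_group_delta if is_case else 0.0)
    ell_init = max(ell_base + rng.normal(0.0, cp.ell_between_sd), 1.0)
    ell_fu = max(
        ell_init - (cp.ell_change_delta if is_case else 0.0)
        + rng.normal(0.0, cp.ell_drift_sd),
        1.0,
    )

    timepoints = {"initial": ell_init}
    if with_followup:
        timepoints["followup"] = ell_fu
    series: dict[str, SliceSeries] = {}
    rater2: dict[str, SliceSeries] = {}
    truth: dict[str, float] = {}
    for tp_name, ell in timepoints.items():
        slices, slices2 = [], []
        for _ in range(tp.slice_count):
            image, masks = make_trabecular_slice(tp, rng, ell=ell)
            slices.append(Slice(image=image, masks=masks))
            if duplicate_rater:
                masks2 = {
                    label: ROIMask(jitter_mask(m.mask, cp.rater_jitter_px, rng), label)
                    for label, m in masks.items()
                }
                slices2.append(Slice(image=image, masks=masks2))
        series[tp_name] = SliceSeries(slices, subject_id=subject_id, timepoint=tp_name)
        if duplicate_rater:
            rater2[tp_name] = SliceSeries(slices2, subject_id=subject_id, timepoint=tp_name)
        truth[tp_name] = ell
    return SyntheticSubject(record=record, series=series, rater2_series=rater2, truth=truth)


@dataclass
class SyntheticStudy:
    """A complete in-memory study: cohort table, image series, ground truth."""

    cohort: pd.DataFrame
    subjects: dict[str, SyntheticSubject]
    cohort_params: CohortParams
    texture_params: TextureParams

    @property
    def truth(self) -> pd.DataFrame:
        rows = [
            {"subject_id": sid, "timepoint": tp_name, "ell": ell,
             "group": subj.record["group"]}
            for sid, subj in self.subjects.items()
            for tp_name, ell in subj.truth.items()
        ]
        return pd.DataFrame(rows)

    def duplicate_subject_ids(self) -> list[str]:
        return [sid for sid, s in self.subjects.items() if s.rater2_series]


def make_study(
    cohort_params: CohortParams = CohortParams(),
    texture_params: TextureParams = TextureParams(),
) -> SyntheticStudy:
    """Generate the full study: cases, control pool, duplicates, truth."""
    cp = cohort_params
    root = np.random.default_rng(cp.seed)
    n_total = cp.n_cases + cp.n_controls_pool
    dup_ids = set(root.choice(n_total, size=min(cp.n_duplicate, n_total), replace=False))
    subject_seeds = root.integers(0, 2**31 - 1, size=n_total)

    subjects: dict[str, SyntheticSubject] = {}
    records = []
    for i in range(n_total):
        group = "case" if i < cp.n_cases else "control"
        sid = f"S{i:04d}"
        missing_fu = root.random() < cp.followup_missing_fraction
        subj = make_subject(
            group, cp, texture_params, int(subject_seeds[i]), subject_id=sid,
            duplicate_rater=(i in dup_ids), with_followup=not missing_fu,
        )
        subjects[sid] = subj
        records.append(subj.record)
    cohort = pd.DataFrame(records)
    return SyntheticStudy(cohort=cohort, subjects=subjects,
                          cohort_params=cp, texture_params=texture_params)


def write_study(study: SyntheticStudy, out_dir: str | Path) -> Path:
    """Write a study directory: manifest.csv, cohort.csv, truth.csv, images/.

    The manifest has one row per (subject, timepoint, slice, region, rater)
    with image and mask paths, and is consumed directly by the extraction
    pipeline/CLI.
    """
    import yaml

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for sid, subj in study.subjects.items():
        for rater, series_map in (("1", subj.series), ("2", subj.rater2_series)):
            for tp_name, series in series_map.items():
                for k, sl in enumerate(series.slices):
                    img_path = out / "images" / f"{sid}_{tp_name}_{k}.png"
                    if rater == "1":  # raters share images, differ in masks
                        write_image_png(img_path, sl.image.pixels)
                    for region, roi in sl.masks.items():
                        mask_path = out / "masks" / f"{sid}_{tp_name}_{k}_{region}_r{rater}.png"
                        write_mask_png(mask_path, roi.mask)
                        manifest_rows.append({
                            "subject_id": sid, "timepoint": tp_name, "slice_index": k,
                            "region": region, "rater": rater,
                            "image_path": str(img_path.relative_to(out)),
                            "mask_path": str(mask_path.relative_to(out)),
                        })
    pd.DataFrame(manifest_rows).sort_values(
        ["subject_id", "rater", "timepoint", "slice_index", "region"]
    ).to_csv(out / "manifest.csv", index=False)
    study.cohort.to_csv(out / "cohort.csv", index=False)
    study.truth.to_csv(out / "truth.csv", index=False)
    with open(out / "generation_config.yaml", "w") as fh:
        yaml.safe_dump(
            {"cohort_params": asdict(study.cohort_params),
             "texture_params": asdict(study.texture_params)},
            fh, sort_keys=True,
        )
    return out
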