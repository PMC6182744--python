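"""Texture features for subchondral bone ROIs.

Four feature classes are computed per ROI per slice:

* grey-level histogram — moments of the in-mask intensity distribution;
* absolute gradient — moments of the central-difference gradient magnitude
  on the 4-bit quantized ROI (interior pixels only);
* run-length matrix (RLM) — maximal same-level runs on the 6-bit ROI,
  in the horizontal, vertical, 45 and 135 degree directions;
* grey-level co-occurrence matrix (GLCM) — symmetric pair counts on the
  6-bit ROI for 4 directions x 5 offsets (20 configurations).

RLM features are averaged over the 4 directions and GLCM features over the
20 direction-offset configurations within each slice; per-slice values are
then averaged over the (five) central slices to give one summary value per
participant, region and timepoint.  Pixel pairs and runs never cross mask
gaps: both members of a pair, and every pixel of a run, must be in-mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .image_roi import GrayImage, InputError, QuantizedROI, ROIMask, SliceSeries, quantize

logger = logging.getLogger(__name__)

# direction angle (degrees) -> (row step, col step) for a unit offset;
# rows grow downward, so 45 deg points up-right.
DIRECTION_STEPS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}

HISTOGRAM_FEATURES = ("mean", "variance", "skewness", "kurtosis")
GRADIENT_FEATURES = ("gr_mean", "gr_variance", "gr_skewness", "gr_kurtosis", "gr_nonzeros")
RLM_FEATURES = (
    "short_run_emphasis",
    "long_run_emphasis",
    "grey_level_nonuniformity",
    "run_length_nonuniformity",
    "fraction_in_runs",
)
GLCM_FEATURES = (
    "asm",
    "contrast",
    "correlation",
    "sum_of_squares",
    "inverse_difference_moment",
    "sum_average",
    "sum_entropy",
    "entropy",
    "difference_entropy",
)
ALL_FEATURES = HISTOGRAM_FEATURES + GRADIENT_FEATURES + RLM_FEATURES + GLCM_FEATURES

# Default 19-name registry: full histogram/gradient/RLM classes plus the
# five most widely reported GLCM features; covers every feature named in
# the study's results tables (mean, variance, Gr. mean, Gr. variance,
# contrast, ASM, entropy).
DEFAULT_GLCM_REGISTRY = ("asm", "contrast", "correlation", "inverse_difference_moment", "entropy")
DEFAULT_REGISTRY = HISTOGRAM_FEATURES + GRADIENT_FEATURES + RLM_FEATURES + DEFAULT_GLCM_REGISTRY

#: Features named in the study's association tables; always retained in a
#: custom registry.
MANDATORY_FEATURES = ("mean", "variance", "gr_mean", "gr_variance", "contrast", "asm", "entropy")


@dataclass(frozen=True)
class TextureConfig:
    """Settings controlling quantization and feature accumulation."""

    bits_gradient: int = 4
    bits_cooccurrence: int = 6
    offsets: tuple[int, ...] = (1, 2, 3, 4, 5)
    directions: tuple[int, ...] = (0, 45, 90, 135)
    registry: tuple[str, ...] = DEFAULT_REGISTRY
    glcm_log_base: float = np.e
    histogram_normalize: str = "minmax"  # or "none"
    quantize_normalization: str = "minmax"  # or "sigma"

    def __post_init__(self) -> None:
        unknown = set(self.registry) - set(ALL_FEATURES)
        if unknown:
            raise ValueError(f"unknown registry features: {sorted(unknown)}")
        missing = set(MANDATORY_FEATURES) - set(self.registry)
        if missing:
            raise ValueError(f"registry must include mandatory features: {sorted(missing)}")
        for d in self.directions:
            if d not in DIRECTION_STEPS:
                raise ValueError(f"unsupported direction {d}")
        if any(o < 1 for o in self.offsets):
            raise ValueError("offsets must be >= 1")


# ---------------------------------------------------------------------------
# Histogram features


def distribution_moments(values: np.ndarray) -> tuple[dict[str, float], bool]:
    """Population moments: mean, variance, skewness (m3/s^3), excess kurtosis.

    Returns the moment dict and a degenerate flag (zero variance, where
    skewness and kurtosis are reported as 0).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise InputError("need >= 2 pixels for histogram features")
    mu = x.mean()
    d = x - mu
    var = float(np.mean(d**2))
    if var == 0.0:
        return {"mean": float(mu), "variance": 0.0, "skewness": 0.0, "kurtosis": 0.0}, True
    sd = np.sqrt(var)
    skew = float(np.mean(d**3) / sd**3)
    kurt = float(np.mean(d**4) / var**2 - 3.0)
    return {"mean": float(mu), "variance": var, "skewness": skew, "kurtosis": kurt}, False


def histogram_features(
    image: GrayImage | np.ndarray,
    mask: ROIMask | np.ndarray,
    *,
    normalize: str = "minmax",
) -> tuple[dict[str, float], bool]:
    """Histogram moments of the raw in-mask intensities.

    With ``normalize="minmax"`` (default) intensities are first mapped
    linearly onto [0, 1] within the ROI, making mean and variance invariant
    to scanner gain; ``"none"`` uses raw units.
    """
    px = image.pixels if isinstance(image, GrayImage) else np.asarray(image, dtype=float)
    m = mask.mask if isinstance(mask, ROIMask) else np.asarray(mask).astype(bool)
    values = px[m]
    if normalize == "minmax":
        lo, hi = values.min(), values.max()
        values = (values - lo) / (hi - lo) if hi > lo else np.zeros_like(values)
    elif normalize != "none":
        raise ValueError(f"unknown histogram normalization {normalize!r}")
    return distribution_moments(values)


# ---------------------------------------------------------------------------
# Gradient features


def gradient_features(
    image: GrayImage | np.ndarray,
    mask: ROIMask | np.ndarray,
    *,
    bits: int = 4,
    quantize_normalization: str = "minmax",
) -> tuple[dict[str, float], bool]:
    """Moments of the gradient-magnitude field on the quantized ROI.

    Central differences on the 4-neighbourhood: for each interior pixel
    (all four neighbours in-mask)
    ``G = sqrt((I[i+1,j]-I[i-1,j])**2 + (I[i,j+1]-I[i,j-1])**2)``.
    Features are the population moments of G over interior pixels plus the
    fraction of interior pixels with G > 0.
    """
    q = quantize(image, mask, bits, normalization=quantize_normalization)
    m = q.mask
    interior = m.copy()
    interior[[0, -1], :] = False
    interior[:, [0, -1]] = False
    interior[1:-1, 1:-1] &= m[:-2, 1:-1] & m[2:, 1:-1] & m[1:-1, :-2] & m[1:-1, 2:]
    if not interior.any():
        raise InputError("ROI too thin for gradient (no interior pixels)")
    g = q.grid.astype(float)
    dr = np.zeros_like(g)
    dc = np.zeros_like(g)
    dr[1:-1, :] = g[2:, :] - g[:-2, :]
    dc[:, 1:-1] = g[:, 2:] - g[:, :-2]
    grad = np.sqrt(dr**2 + dc**2)[interior]
    if grad.size < 2:
        raise InputError("ROI too thin for gradient (single interior pixel)")
    moments, degenerate = distribution_moments(grad)
    feats = {
        "gr_mean": moments["mean"],
        "gr_variance": moments["variance"],
        "gr_skewness": moments["skewness"],
        "gr_kurtosis": moments["kurtosis"],
        "gr_nonzeros": float(np.mean(grad > 0)),
    }
    return feats, degenerate or q.degenerate


# ---------------------------------------------------------------------------
# GLCM


@dataclass(frozen=True)
class GLCMatrix:
    """Symmetric co-occurrence matrix for one (direction, offset)."""

    counts: np.ndarray
    direction: int
    offset: int

    @property
    def n_pairs(self) -> int:
        # each unordered pair is accumulated once in each orientation
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise InputError("GLCM has no valid pairs")
        return self.counts / total


def _pair_indices(
    grid: np.ndarray, mask: np.ndarray, direction: int, offset: int
) -> tuple[np.ndarray, np.ndarray]:
    """Grey levels (i, j) of all in-mask ordered pairs along one step."""
    dr, dc = DIRECTION_STEPS[direction]
    dr, dc = dr * offset, dc * offset
    h, w = mask.shape
    r0s, r0e = max(0, -dr), min(h, h - dr)
    c0s, c0e = max(0, -dc), min(w, w - dc)
    base = mask[r0s:r0e, c0s:c0e]
    shifted = mask[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
    valid = base & shifted
    i = grid[r0s:r0e, c0s:c0e][valid]
    j = grid[r0s + dr : r0e + dr, c0s + dc : c0e + dc][valid]
    return i, j


def compute_glcm(qroi: QuantizedROI, direction: int, offset: int) -> GLCMatrix:
    """Symmetric GLCM: each valid ordered pair counted in both orientations."""
    if direction not in DIRECTION_STEPS:
        raise ValueError(f"unsupported direction {direction}")
    if offset < 1:
        raise ValueError("offset must be >= 1")
    L = qroi.n_levels
    i, j = _pair_indices(qroi.grid, qroi.mask, direction, offset)
    if i.size:
        one = np.bincount((i - 1) * L + (j - 1), minlength=L * L).reshape(L, L)
        counts = one + one.T  # symmetric accumulation
    else:
        counts = np.zeros((L, L), dtype=np.int64)
    return GLCMatrix(counts=counts, direction=direction, offset=offset)


class _GLCMWorkspace:
    """Cached index grids and aggregation matrices for an L-level GLCM."""

    _cache: dict[int, "_GLCMWorkspace"] = {}

    def __init__(self, L: int) -> None:
        idx = np.arange(1, L + 1, dtype=float)
        ii, jj = np.meshgrid(idx, idx, indexing="ij")
        self.idx = idx
        self.contrast_w = (ii - jj) ** 2
        self.idm_w = 1.0 / (1.0 + (ii - jj) ** 2)
        # 0/1 aggregation maps: cell (i,j) -> i+j bucket and |i-j| bucket
        sum_idx = (ii + jj - 2).astype(int).ravel()  # 0 .. 2L-2
        diff_idx = np.abs(ii - jj).astype(int).ravel()  # 0 .. L-1
        self.sum_map = np.zeros((L * L, 2 * L - 1))
        self.sum_map[np.arange(L * L), sum_idx] = 1.0
        self.diff_map = np.zeros((L * L, L))
        self.diff_map[np.arange(L * L), diff_idx] = 1.0
        self.sum_values = np.arange(2, 2 * L + 1, dtype=float)

    @classmethod
    def get(cls, L: int) -> "_GLCMWorkspace":
        if L not in cls._cache:
            cls._cache[L] = cls(L)
        return cls._cache[L]


def _xlogx(p: np.ndarray, log_base: float) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    if log_base != np.e:
        out /= np.log(log_base)
    return out


def glcm_features_stack(
    probabilities: np.ndarray, *, log_base: float = np.e
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Haralick features for a stack of normalized GLCMs, shape (B, L, L).

    Returns per-feature arrays of length B and a boolean array flagging
    configurations with degenerate correlation (zero marginal variance,
    reported as 0).
    """
    P = np.asarray(probabilities, dtype=float)
    if P.ndim == 2:
        P = P[None]
    B, L, _ = P.shape
    ws = _GLCMWorkspace.get(L)
    idx = ws.idx

    asm = np.einsum("bij,bij->b", P, P)
    contrast = np.einsum("bij,ij->b", P, ws.contrast_w)
    idm = np.einsum("bij,ij->b", P, ws.idm_w)
    px = P.sum(axis=2)
    py = P.sum(axis=1)
    mux = px @ idx
    muy = py @ idx
    varx = px @ idx**2 - mux**2
    vary = py @ idx**2 - muy**2
    cov = np.einsum("bij,i,j->b", P, idx, idx) - mux * muy
    denom = np.sqrt(np.clip(varx, 0, None) * np.clip(vary, 0, None))
    degenerate = denom <= 0
    correlation = np.where(degenerate, 0.0, cov / np.where(degenerate, 1.0, denom))
    sum_of_squares = ((idx[None, :] - mux[:, None]) ** 2 * px).sum(axis=1)

    flat = P.reshape(B, L * L)
    p_sum = flat @ ws.sum_map  # (B, 2L-1), buckets i+j = 2 .. 2L
    p_diff = flat @ ws.diff_map  # (B, L), buckets |i-j| = 0 .. L-1
    sum_average = p_sum @ ws.sum_values
    sum_entropy = -_xlogx(p_sum, log_base).sum(axis=1)
    entropy = -_xlogx(flat, log_base).sum(axis=1)
    difference_entropy = -_xlogx(p_diff, log_base).sum(axis=1)

    feats = {
        "asm": asm,
        "contrast": contrast,
        "correlation": correlation,
        "sum_of_squares": sum_of_squares,
        "inverse_difference_moment": idm,
        "sum_average": sum_average,
        "sum_entropy": sum_entropy,
        "entropy": entropy,
        "difference_entropy": difference_entropy,
    }
    return feats, degenerate


def glcm_features(glcm: GLCMatrix, *, log_base: float = np.e) -> dict[str, float]:
    """Haralick features of one normalized GLCM."""
    feats, _ = glcm_features_stack(glcm.probabilities[None], log_base=log_base)
    return {k: float(v[0]) for k, v in feats.items()}


# ---------------------------------------------------------------------------
# RLM


@dataclass(frozen=True)
class RunLengthMatrix:
    """Counts p(i, r) of maximal runs of level i with length r, one direction."""

    counts: np.ndarray  # (n_levels, max_run_length); column r-1 holds length r
    direction: int
    n_pixels: int

    @property
    def total_runs(self) -> int:
        return int(self.counts.sum())


def _lines_along(grid: np.ndarray, direction: int) -> list[np.ndarray]:
    """Collinear scan lines of the level grid (0 = out of mask)."""
    if direction == 0:
        return list(grid)
    if direction == 90:
        return list(grid.T)
    if direction == 45:
        g = grid[::-1]  # 45 deg runs are diagonals of the vertically flipped grid
    elif direction == 135:
        g = grid[::-1, ::-1]
    else:
        raise ValueError(f"unsupported direction {direction}")
    h, w = g.shape
    return [np.diagonal(g, off) for off in range(-(h - 1), w)]


def _runs_in_line(line: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(levels, lengths) of maximal nonzero runs in a 1-D level array."""
    x = np.asarray(line)
    if x.size == 0:
        return np.empty(0, int), np.empty(0, int)
    change = np.nonzero(np.diff(x))[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [x.size]))
    levels = x[starts]
    keep = levels > 0
    return levels[keep].astype(int), (ends - starts)[keep].astype(int)


def compute_rlm(qroi: QuantizedROI, direction: int) -> RunLengthMatrix:
    """Run-length matrix along one direction; mask gaps terminate runs."""
    rows, cols = np.nonzero(qroi.mask)
    grid = qroi.grid[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]
    lines = _lines_along(grid, direction)
    # join all scan lines with 0 separators so runs never bridge lines,
    # then extract every run in one pass
    sep = np.zeros(1, dtype=grid.dtype)
    joined = np.concatenate([part for line in lines for part in (line, sep)])
    lv, ln = _runs_in_line(joined)
    L = qroi.n_levels
    rmax = int(ln.max())
    counts = np.bincount((lv - 1) * rmax + (ln - 1), minlength=L * rmax).reshape(L, rmax)
    return RunLengthMatrix(counts=counts, direction=direction, n_pixels=int(qroi.mask.sum()))


def rlm_features(rlm: RunLengthMatrix) -> dict[str, float]:
    """Galloway run-length features of one direction's matrix."""
    p = rlm.counts.astype(float)
    C = p.sum()
    if C < 1:
        raise InputError("RLM has no runs")
    r = np.arange(1, p.shape[1] + 1, dtype=float)
    by_length = p.sum(axis=0)
    by_level = p.sum(axis=1)
    return {
        "short_run_emphasis": float((by_length / r**2).sum() / C),
        "long_run_emphasis": float((by_length * r**2).sum() / C),
        "grey_level_nonuniformity": float((by_level**2).sum() / C),
        "run_length_nonuniformity": float((by_length**2).sum() / C),
        "fraction_in_runs": float(C / rlm.n_pixels),
    }


# ---------------------------------------------------------------------------
# Aggregation


def aggregate_feature(values: Sequence[float]) -> float:
    """Unweighted mean over the valid direction/offset configurations."""
    vals = [v for v in values if v is not None and np.isfinite(v)]
    if not vals:
        raise InputError("no valid configuration values to aggregate")
    return float(np.mean(vals))


def aggregate_slices(per_slice: Sequence[Mapping[str, float]]) -> tuple[dict[str, float], bool]:
    """Per-feature unweighted mean over slices.

    Features missing on some slices are averaged over the slices that have
    them; the returned flag is True when every feature was present on every
    slice.
    """
    if not per_slice:
        raise InputError("no slices to aggregate")
    names: list[str] = []
    for d in per_slice:
        for k in d:
            if k not in names:
                names.append(k)
    out: dict[str, float] = {}
    complete = True
    for name in names:
        vals = [d[name] for d in per_slice if name in d and np.isfinite(d[name])]
        if len(vals) < len(per_slice):
            complete = False
        if vals:
            out[name] = float(np.mean(vals))
    return out, complete


# ---------------------------------------------------------------------------
# Per-ROI and per-series drivers


def roi_feature_vector(
    image: GrayImage | np.ndarray,
    mask: ROIMask | np.ndarray,
    config: TextureConfig = TextureConfig(),
) -> dict[str, float]:
    """All registry features for one ROI on one slice."""
    feats: dict[str, float] = {}
    hist, _ = histogram_features(image, mask, normalize=config.histogram_normalize)
    feats.update(hist)
    grad, _ = gradient_features(
        image, mask, bits=config.bits_gradient,
        quantize_normalization=config.quantize_normalization,
    )
    feats.update(grad)

    q = quantize(image, mask, config.bits_cooccurrence,
                 normalization=config.quantize_normalization)

    # RLM: feature per direction, then unweighted mean over directions
    rlm_per_dir = [rlm_features(compute_rlm(q, d)) for d in config.directions]
    for name in RLM_FEATURES:
        feats[name] = aggregate_feature([d[name] for d in rlm_per_dir])

    # GLCM: one matrix per (direction, offset); configurations with no valid
    # pairs are skipped and excluded from the average
    stacks = []
    for d in config.directions:
        for off in config.offsets:
            i, j = _pair_indices(q.grid, q.mask, d, off)
            L = q.n_levels
            if i.size == 0:
                logger.info("GLCM config (dir=%d, offset=%d) has no valid pairs; skipped", d, off)
                continue
            one = np.bincount((i - 1) * L + (j - 1), minlength=L * L).reshape(L, L)
            sym = (one + one.T).astype(float)
            stacks.append(sym / sym.sum())
    if not stacks:
        raise InputError("no GLCM configuration has valid pairs")
    glcm_stack, _ = glcm_features_stack(np.stack(stacks), log_base=config.glcm_log_base)
    for name in GLCM_FEATURES:
        feats[name] = aggregate_feature(glcm_stack[name])

    return {k: feats[k] for k in config.registry}


def series_feature_vectors(
    series: SliceSeries, config: TextureConfig = TextureConfig()
) -> dict[str, dict[str, float]]:
    """Slice-averaged feature vector per region for one knee/timepoint."""
    out: dict[str, dict[str, float]] = {}
    for region in series.regions:
        per_slice = [
            roi_feature_vector(s.image, s.masks[region], config) for s in series.slices
        ]
        agg, complete = aggregate_slices(per_slice)
        if not complete:
            logger.warning("incomplete features for region %s", region)
        out[region] = agg
    return out


# ---------------------------------------------------------------------------
# Feature table


REGION_PREFIX = {"medial_tibia": "T_", "medial_femur": "F_"}
TIMEPOINTS = ("initial", "followup")


def build_feature_table(
    series_features,
    registry: Sequence[str] = DEFAULT_REGISTRY,
) -> pd.DataFrame:
    """Wide feature table from per-(subject, region, timepoint) vectors.

    ``series_features`` is a mapping (or iterable of pairs) from
    ``(subject_id, region, timepoint)`` to a feature dict, with timepoint in
    {"initial", "followup"}.  Every subject must have an initial-timepoint
    row for each region it appears in.  ``change_<feature>`` columns
    (followup - initial) are added for subjects with both timepoints.
    """
    items = series_features.items() if hasattr(series_features, "items") else series_features
    rows = []
    seen: set[tuple[str, str, str]] = set()
    for (subject, region, timepoint), feats in items:
        key = (str(subject), region, timepoint)
        if key in seen:
            raise InputError(f"duplicate feature-table key {key}")
        seen.add(key)
        if timepoint not in TIMEPOINTS:
            raise InputError(f"unknown timepoint {timepoint!r}")
        row = {"subject_id": str(subject), "region": region, "timepoint": timepoint}
        row.update({f: feats[f] for f in registry if f in feats})
        rows.append(row)
    table = pd.DataFrame(rows)
    for subject, region in (
        table.loc[table.timepoint == "followup", ["subject_id", "region"]].itertuples(index=False)
    ):
        has_initial = (
            (table.subject_id == subject)
            & (table.region == region)
            & (table.timepoint == "initial")
        ).any()
        if not has_initial:
            raise InputError(f"subject {subject} region {region} has followup but no initial")
    feature_cols = [c for c in table.columns if c in registry]
    wide = table.set_index(["subject_id", "region", "timepoint"])[feature_cols].sort_index()

    initial = wide.xs("initial", level="timepoint")
    try:
        followup = wide.xs("followup", level="timepoint")
    except KeyError:
        followup = initial.iloc[0:0]
    change = (followup - initial.reindex(followup.index)).dropna()
    change.columns = [f"change_{c}" for c in change.columns]

    out = wide.reset_index()
    change_reset = change.reset_index()
    change_reset["timepoint"] = "followup"
    out = out.merge(change_reset, on=["subject_id", "region", "timepoint"], how="left")
    return out


def analysis_matrix(
    feature_table: pd.DataFrame,
    region: str,
    timebase: str,
    registry: Sequence[str] = DEFAULT_REGISTRY,
) -> pd.DataFrame:
    """Subject-by-feature matrix for one (region, timebase) analysis.

    ``region`` is "tibial", "femoral" or "combined"; ``timebase`` is
    "initial" or "change".  Combined matrices concatenate tibial and
    femoral columns with T_/F_ prefixes.  Subjects missing the required
    data are dropped.
    """
    if timebase not in ("initial", "change"):
        raise ValueError(f"timebase must be 'initial' or 'change', got {timebase!r}")
    region_map = {"tibial": "medial_tibia", "femoral": "medial_femur"}
    if region == "combined":
        t = analysis_matrix(feature_table, "tibial", timebase, registry)
        f = analysis_matrix(feature_table, "femoral", timebase, registry)
        t.columns = [f"T_{c}" for c in t.columns]
        f.columns = [f"F_{c}" for c in f.columns]
        return t.join(f, how="inner")
    if region not in region_map:
        raise ValueError(f"unknown region {region!r}")
    label = region_map[region]
    if timebase == "initial":
        sub = feature_table[
            (feature_table.region == label) & (feature_table.timepoint == "initial")
        ]
        cols = [c for c in registry if c in sub.columns]
        return sub.set_index("subject_id")[cols].dropna()
    sub = feature_table[
        (feature_table.region == label) & (feature_table.timepoint == "followup")
    ]
    cols = [f"change_{c}" for c in registry if f"change_{c}" in sub.columns]
    return sub.set_index("subject_id")[cols].dropna()


def feature_table_to_tidy(feature_table: pd.DataFrame) -> pd.DataFrame:
    """Long (subject_id, region, timepoint, feature, value) view."""
    id_cols = ["subject_id", "region", "timepoint"]
    value_cols = [c for c in feature_table.columns if c not in id_cols]
    tidy = feature_table.melt(
        id_vars=id_cols, value_vars=value_cols, var_name="feature", value_name="value"
    )
    return tidy.dropna(subset=["value"]).reset_index(drop=True)
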