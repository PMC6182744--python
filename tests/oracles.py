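"""Independent brute-force oracles for texture features.

Everything here is written as plain loops and direct summation, on purpose:
these functions define expected values for the vectorized implementations
and must stay naive.
"""

import math

import numpy as np

STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_counts_oracle(grid, mask, direction, offset, n_levels):
    """Exhaustive enumeration of symmetric co-occurrence pairs."""
    dr, dc = STEPS[direction]
    dr, dc = dr * offset, dc * offset
    h, w = grid.shape
    counts = np.zeros((n_levels, n_levels), dtype=int)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                i, j = grid[r, c], grid[r2, c2]
                counts[i - 1, j - 1] += 1
                counts[j - 1, i - 1] += 1
    return counts


def haralick_oracle(P):
    """Direct-summation Haralick features of one normalized GLCM."""
    L = P.shape[0]
    asm = contrast = idm = entropy = 0.0
    mux = muy = 0.0
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    for i in range(L):
        mux += (i + 1) * px[i]
        muy += (i + 1) * py[i]
    sigx = math.sqrt(sum((i + 1 - mux) ** 2 * px[i] for i in range(L)))
    sigy = math.sqrt(sum((j + 1 - muy) ** 2 * py[j] for j in range(L)))
    corr_num = 0.0
    sos = 0.0
    p_sum = np.zeros(2 * L - 1)
    p_diff = np.zeros(L)
    for i in range(L):
        for j in range(L):
            p = P[i, j]
            asm += p * p
            contrast += (i - j) ** 2 * p
            idm += p / (1 + (i - j) ** 2)
            if p > 0:
                entropy -= p * math.log(p)
            corr_num += (i + 1 - mux) * (j + 1 - muy) * p
            sos += (i + 1 - mux) ** 2 * p
            p_sum[i + j] += p
            p_diff[abs(i - j)] += p
    sum_average = sum((k + 2) * p_sum[k] for k in range(2 * L - 1))
    sum_entropy = -sum(p * math.log(p) for p in p_sum if p > 0)
    difference_entropy = -sum(p * math.log(p) for p in p_diff if p > 0)
    correlation = 0.0 if sigx * sigy == 0 else corr_num / (sigx * sigy)
    return {
        "asm": asm,
        "contrast": contrast,
        "correlation": correlation,
        "sum_of_squares": sos,
        "inverse_difference_moment": idm,
        "sum_average": sum_average,
        "sum_entropy": sum_entropy,
        "entropy": entropy,
        "difference_entropy": difference_entropy,
    }


def rlm_runs_oracle(grid, mask, direction):
    """Scan-line run enumeration; mask gaps split runs.

    Returns a list of (level, length) maximal runs.
    """
    dr, dc = STEPS[direction]
    h, w = grid.shape
    starts = []
    for r in range(h):
        for c in range(w):
            rp, cp = r - dr, c - dc  # previous cell along the direction
            if not (0 <= rp < h and 0 <= cp < w):
                starts.append((r, c))
    runs = []
    for r0, c0 in starts:
        r, c = r0, c0
        cur_level, cur_len = None, 0
        while 0 <= r < h and 0 <= c < w:
            lvl = grid[r, c] if mask[r, c] else None
            if lvl is not None and lvl == cur_level:
                cur_len += 1
            else:
                if cur_level is not None:
                    runs.append((cur_level, cur_len))
                cur_level, cur_len = lvl, 1 if lvl is not None else 0
            r, c = r + dr, c + dc
        if cur_level is not None:
            runs.append((cur_level, cur_len))
    return runs


def rlm_features_oracle(runs, n_pixels):
    C = len(runs)
    sre = sum(1.0 / (ln**2) for _, ln in runs) / C
    lre = sum(float(ln**2) for _, ln in runs) / C
    by_level = {}
    by_len = {}
    for lvl, ln in runs:
        by_level[lvl] = by_level.get(lvl, 0) + 1
        by_len[ln] = by_len.get(ln, 0) + 1
    glnu = sum(v**2 for v in by_level.values()) / C
    rlnu = sum(v**2 for v in by_len.values()) / C
    return {
        "short_run_emphasis": sre,
        "long_run_emphasis": lre,
        "grey_level_nonuniformity": glnu,
        "run_length_nonuniformity": rlnu,
        "fraction_in_runs": C / n_pixels,
    }


def gradient_oracle(levels_grid, mask):
    """Per-pixel central-difference gradient moments on interior pixels."""
    h, w = mask.shape
    grads = []
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            if (mask[r, c] and mask[r - 1, c] and mask[r + 1, c]
                    and mask[r, c - 1] and mask[r, c + 1]):
                gy = float(levels_grid[r + 1, c]) - float(levels_grid[r - 1, c])
                gx = float(levels_grid[r, c + 1]) - float(levels_grid[r, c - 1])
                grads.append(math.sqrt(gx * gx + gy * gy))
    return grads


def moments_oracle(values):
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    if var == 0:
        return {"mean": mean, "variance": 0.0, "skewness": 0.0, "kurtosis": 0.0}
    sd = math.sqrt(var)
    skew = sum((v - mean) ** 3 for v in values) / n / sd**3
    kurt = sum((v - mean) ** 4 for v in values) / n / var**2 - 3.0
    return {"mean": mean, "variance": var, "skewness": skew, "kurtosis": kurt}


def quantize_oracle(value, lo, hi, n_levels):
    """Equal-width binning with closed top edge, levels 1..n_levels."""
    if hi <= lo:
        return 1
    level = int((value - lo) / (hi - lo) * n_levels) + 1
    return min(level, n_levels)
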