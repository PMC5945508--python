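"""Independent brute-force oracles used only by the tests.

Each oracle is a deliberately naive re-derivation of a quantity the
package computes: exhaustive pair enumeration for the co-occurrence
matrix, full line extraction with run-length encoding for the
run-length matrix, explicit-loop central moments, a textbook two-way
sum-of-squares decomposition for the repeated-measures ANOVA, and a
pointwise Chebyshev distance transform for the background shell.  They
share no code with the implementation paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_glcm(levels: np.ndarray, mask: np.ndarray, bins: int, offset) -> np.ndarray:
    """Symmetrized co-occurrence counts for one direction by scanning all voxels."""
    counts = np.zeros((bins, bins), dtype=np.int64)
    nx, ny, nz = levels.shape
    dx, dy, dz = offset
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                qx, qy, qz = x + dx, y + dy, z + dz
                if not (0 <= qx < nx and 0 <= qy < ny and 0 <= qz < nz):
                    continue
                if mask[x, y, z] and mask[qx, qy, qz]:
                    a, b = levels[x, y, z] - 1, levels[qx, qy, qz] - 1
                    counts[a, b] += 1
                    counts[b, a] += 1
    return counts


def brute_glrlm(levels: np.ndarray, mask: np.ndarray, bins: int, offset) -> dict:
    """Run counts {(level, length): n} for one direction.

    Extracts every maximal grid line along the direction, materializes
    its level sequence with ``None`` at out-of-mask voxels, and
    run-length encodes it.
    """
    nx, ny, nz = levels.shape
    dx, dy, dz = offset
    starts = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                px, py, pz = x - dx, y - dy, z - dz
                if not (0 <= px < nx and 0 <= py < ny and 0 <= pz < nz):
                    starts.append((x, y, z))
    tally: dict = {}
    for sx, sy, sz in starts:
        sequence = []
        x, y, z = sx, sy, sz
        while 0 <= x < nx and 0 <= y < ny and 0 <= z < nz:
            sequence.append(int(levels[x, y, z]) if mask[x, y, z] else None)
            x, y, z = x + dx, y + dy, z + dz
        for value, group in itertools.groupby(sequence):
            if value is None:
                continue
            length = sum(1 for _ in group)
            tally[(value, length)] = tally.get((value, length), 0) + 1
    return tally


def glrlm_dict(counts_3d: np.ndarray, direction_index: int) -> dict:
    """Convert one direction of a packed run-length array to {(level, length): n}."""
    out = {}
    mat = counts_3d[direction_index]
    for i, j in zip(*np.nonzero(mat)):
        out[(int(i) + 1, int(j) + 1)] = int(mat[i, j])
    return out


def central_moment(values, order: int) -> float:
    values = [float(v) for v in values]
    mean = sum(values) / len(values)
    return sum((v - mean) ** order for v in values) / len(values)


def moment_skewness(values) -> float:
    return central_moment(values, 3) / central_moment(values, 2) ** 1.5


def moment_kurtosis(values) -> float:
    return central_moment(values, 4) / central_moment(values, 2) ** 2


def rm_anova_ss(matrix: np.ndarray):
    """Textbook two-way (subject x condition) decomposition by explicit loops.

    Returns (F, df1, df2, ss_subjects, ss_conditions, ss_error).
    """
    x = np.asarray(matrix, dtype=float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    row_means = [x[i, :].sum() / k for i in range(n)]
    col_means = [x[:, j].sum() / n for j in range(k)]
    ss_subj = sum(k * (rm - grand) ** 2 for rm in row_means)
    ss_cond = sum(n * (cm - grand) ** 2 for cm in col_means)
    ss_err = sum(
        (x[i, j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    f = (ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
    return f, k - 1, (n - 1) * (k - 1), ss_subj, ss_cond, ss_err


def paired_t_p(a, b) -> float:
    """Two-sided paired t-test p by the direct formula."""
    from scipy.stats import t as t_dist

    d = [ai - bi for ai, bi in zip(a, b)]
    n = len(d)
    mean = sum(d) / n
    var = sum((di - mean) ** 2 for di in d) / (n - 1)
    t = mean / math.sqrt(var / n)
    return 2.0 * float(t_dist.sf(abs(t), n - 1))


def pearson_direct(x, y) -> float:
    """Product-moment r by the definitional formula."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    den = math.sqrt(
        sum((xi - mx) ** 2 for xi in x) * sum((yi - my) ** 2 for yi in y)
    )
    return num / den


def chebyshev_shell(core: np.ndarray, gap: int, thickness: int) -> np.ndarray:
    """Voxels at Chebyshev distance in (gap, gap + thickness] from the core."""
    core_points = np.argwhere(core)
    shell = np.zeros_like(core, dtype=bool)
    for p in np.ndindex(core.shape):
        d = min(
            max(abs(int(p[0]) - int(c[0])), abs(int(p[1]) - int(c[1])),
                abs(int(p[2]) - int(c[2])))
            for c in core_points
        )
        if gap < d <= gap + thickness:
            shell[p] = True
    return shell


def sphere_count(shape, spacing, center_mm, radius_mm) -> int:
    """Voxel centers within radius_mm of center_mm, counted one by one."""
    count = 0
    for p in np.ndindex(tuple(shape)):
        d2 = sum(((pi * si) - ci) ** 2 for pi, si, ci in zip(p, spacing, center_mm))
        if d2 <= radius_mm**2:
            count += 1
    return count
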