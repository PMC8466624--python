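"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: a quadratic-space
affine-gap DP for alignment scores, a brute-force axis-angle rotation-grid
search for superposition RMSD, and direct summation for Neq.
"""

import math

import numpy as np
from Bio.Align import substitution_matrices
from scipy.spatial.transform import Rotation


def gotoh_score(a: str, b: str, matrix_name="BLOSUM62",
                open_=10.0, ext=0.5) -> float:
    """Optimal global affine-gap alignment score; a gap of length k costs
    open_ + (k-1)*ext, end gaps penalized identically."""
    M = substitution_matrices.load(matrix_name)
    n, m = len(a), len(b)
    NEG = -1e9
    Mm = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    Mm[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -open_ - (i - 1) * ext
    for j in range(1, m + 1):
        Iy[0, j] = -open_ - (j - 1) * ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = M[a[i - 1], b[j - 1]]
            Mm[i, j] = max(Mm[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(Mm[i - 1, j] - open_, Ix[i - 1, j] - ext,
                           Iy[i - 1, j] - open_)
            Iy[i, j] = max(Mm[i, j - 1] - open_, Iy[i, j - 1] - ext,
                           Ix[i, j - 1] - open_)
    return float(max(Mm[n, m], Ix[n, m], Iy[n, m]))


def _fibonacci_axes(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = np.pi * (3 - np.sqrt(5)) * i
    z = 1 - 2 * (i + 0.5) / n
    r = np.sqrt(1 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def grid_search_rmsd(x: np.ndarray, y: np.ndarray, n_axes: int = 1500) -> float:
    """Minimum RMSD over a dense rotation grid (axis-angle: Fibonacci-sphere
    axes x 1-degree angle steps) after centroid removal."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    axes = _fibonacci_axes(n_axes)
    best = np.inf
    for ang in np.radians(np.arange(0.0, 360.0, 1.0)):
        R = Rotation.from_rotvec(axes * ang).as_matrix()
        xr = np.einsum("nij,kj->nki", R, xc)
        d = xr - yc[None]
        rmsd = np.sqrt((d ** 2).sum(-1).mean(-1)).min()
        if rmsd < best:
            best = float(rmsd)
    return best


def neq_direct(counts) -> float:
    """Neq from raw letter counts by direct summation."""
    total = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            f = c / total
            h -= f * math.log(f)
    return math.exp(h)


def total_variation(p, q) -> float:
    """TV distance via the maximizing event S = {x : p_x > q_x}."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    s = p > q
    return float(p[s].sum() - q[s].sum())
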