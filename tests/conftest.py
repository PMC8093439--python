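import numpy as np
import pytest

import flimcyte as fc


@pytest.fixture(scope="session")
def irf():
    return fc.default_irf()


@pytest.fixture(scope="session")
def small_scene():
    """Five-cell tumor scene on a 96x96 field (cheap, shared read-only)."""
    preset = fc.make_preset("tumor", n_cells=5, field_size=(96, 96), seed=7)
    stack, gt, irf = fc.render_scene(preset)
    return preset, stack, gt, irf


def brute_force_reconstruct(marker: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Oracle: repeat {dilate by 3x3; intersect with mask} until fixed point."""
    from scipy.ndimage import binary_dilation

    marker = np.asarray(marker, dtype=bool) & np.asarray(mask, dtype=bool)
    struct = np.ones((3, 3), dtype=bool)
    while True:
        grown = binary_dilation(marker, structure=struct) & mask
        if np.array_equal(grown, marker):
            return marker
        marker = grown


def brute_force_bin(data: np.ndarray, kernel: int) -> np.ndarray:
    """Oracle: nested-loop neighborhood histogram sums with edge truncation."""
    ny, nx, nt = data.shape
    half = kernel // 2
    out = np.zeros((ny, nx, nt), dtype=np.int64)
    for y in range(ny):
        for x in range(nx):
            for dy in range(-half, half + 1):
                for dx in range(-half, half + 1):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < ny and 0 <= xx < nx:
                        out[y, x] += data[yy, xx]
    return out


def exact_mannwhitney_p(a, b) -> tuple:
    """Oracle: two-sided exact Mann-Whitney p by full enumeration of
    all C(n1+n2, n1) group assignments of the pooled (tie-free) values."""
    from itertools import combinations

    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)

    def u_stat(group_a, group_b):
        return sum(1.0 for x in group_a for y in group_b if x > y) + sum(
            0.5 for x in group_a for y in group_b if x == y
        )

    u_obs = u_stat(a, b)
    mean_u = n1 * len(b) / 2.0
    dev_obs = abs(u_obs - mean_u)
    count = total = 0
    idx = range(len(pooled))
    for comb in combinations(idx, n1):
        in_a = set(comb)
        ga = [pooled[i] for i in in_a]
        gb = [pooled[i] for i in idx if i not in in_a]
        if abs(u_stat(ga, gb) - mean_u) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return u_obs, count / total
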