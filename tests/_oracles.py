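"""Independent brute-force oracles used by the tests.

Deliberately simple and slow: explicit per-slice flood fill and loop-based
sums of squares, sharing no code with the package implementations.
"""

from collections import deque

import numpy as np


def brute_force_calcium_scores(data, spacing, threshold=130.0, min_area_mm2=1.0,
                               exclusion=None):
    """Slice-wise 8-connected flood fill + Agatston weight table.

    Returns ``(agatston_total, volume_mm3, n_lesions)``.
    """
    nx, ny, nz = data.shape
    voxel_area = spacing[0] * spacing[1]
    factor = spacing[2] / 3.0
    agatston = 0.0
    n_vox = 0
    n_lesions = 0
    for k in range(nz):
        visited = np.zeros((nx, ny), dtype=bool)
        for i in range(nx):
            for j in range(ny):
                if visited[i, j]:
                    continue
                if data[i, j, k] < threshold:
                    continue
                if exclusion is not None and exclusion[i, j, k]:
                    continue
                # flood fill one component
                comp = []
                queue = deque([(i, j)])
                visited[i, j] = True
                while queue:
                    a, b = queue.popleft()
                    comp.append((a, b))
                    for da in (-1, 0, 1):
                        for db in (-1, 0, 1):
                            if da == 0 and db == 0:
                                continue
                            x, y = a + da, b + db
                            if not (0 <= x < nx and 0 <= y < ny):
                                continue
                            if visited[x, y] or data[x, y, k] < threshold:
                                continue
                            if exclusion is not None and exclusion[x, y, k]:
                                continue
                            visited[x, y] = True
                            queue.append((x, y))
                area = len(comp) * voxel_area
                if area < min_area_mm2:
                    continue
                peak = max(data[a, b, k] for a, b in comp)
                if peak >= 400:
                    w = 4
                elif peak >= 300:
                    w = 3
                elif peak >= 200:
                    w = 2
                else:
                    w = 1
                agatston += area * w * factor
                n_vox += len(comp)
                n_lesions += 1
    return agatston, n_vox * voxel_area * spacing[2], n_lesions


def anova_icc3(table):
    """ICC(3,1) by explicit loop-based two-way ANOVA sums of squares."""
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    grand = table.sum() / (n * k)
    ss_rows = 0.0
    for i in range(n):
        ss_rows += k * (table[i].mean() - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        ss_cols += n * (table[:, j].mean() - grand) ** 2
    ss_tot = 0.0
    for i in range(n):
        for j in range(k):
            ss_tot += (table[i, j] - grand) ** 2
    ms_rows = ss_rows / (n - 1)
    ms_err = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)


def spearman_rank_formula(a, b):
    """Spearman rho via 1 - 6*sum(d^2)/(n(n^2-1)); assumes no ties."""
    a = np.asarray(a)
    b = np.asarray(b)
    ra = np.empty(len(a))
    rb = np.empty(len(b))
    ra[np.argsort(a)] = np.arange(1, len(a) + 1)
    rb[np.argsort(b)] = np.arange(1, len(b) + 1)
    d2 = ((ra - rb) ** 2).sum()
    n = len(a)
    return 1.0 - 6.0 * d2 / (n * (n ** 2 - 1))
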