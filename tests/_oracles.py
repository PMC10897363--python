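"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: patch labelling is a
hand-rolled breadth-first flood fill, the access buffer is an O(n^2)
all-pairs distance computation, and the OLS line comes straight from the
closed-form normal equations.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def flood_fill_labels(binary: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """BFS connected-component labels of 1-cells (0 = background)."""
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    nr, nc = binary.shape
    labels = np.zeros(binary.shape, dtype=np.int32)
    next_id = 0
    for r in range(nr):
        for c in range(nc):
            if binary[r, c] != 1 or labels[r, c] != 0:
                continue
            next_id += 1
            q = deque([(r, c)])
            labels[r, c] = next_id
            while q:
                rr, cc = q.popleft()
                for dr, dc in steps:
                    r2, c2 = rr + dr, cc + dc
                    if (0 <= r2 < nr and 0 <= c2 < nc
                            and binary[r2, c2] == 1 and labels[r2, c2] == 0):
                        labels[r2, c2] = next_id
                        q.append((r2, c2))
    return labels


def brute_force_access_flags(
    filtered: np.ndarray,
    cell_size: float,
    radius_m: float,
    min_area_m2: float,
) -> np.ndarray:
    """All-pairs distance version of the buffer-access flag.

    For every cell, count filtered-natural cells whose centre lies within
    ``radius_m`` of the cell centre and compare the summed area against
    the minimum.
    """
    nr, nc = filtered.shape
    nat = np.argwhere(filtered == 1).astype(np.float64)
    flags = np.zeros((nr, nc), dtype=np.uint8)
    if len(nat) == 0:
        return flags
    rows = np.arange(nr, dtype=np.float64)
    cols = np.arange(nc, dtype=np.float64)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    centers = np.stack([rr.ravel(), cc.ravel()], axis=1)
    d2 = (
        (centers[:, None, 0] - nat[None, :, 0]) ** 2
        + (centers[:, None, 1] - nat[None, :, 1]) ** 2
    ) * cell_size**2
    counts = (d2 <= radius_m**2 + 1e-6).sum(axis=1)
    area = counts * cell_size**2
    return (area >= min_area_m2).astype(np.uint8).reshape(nr, nc)


def normal_equation_line(x: np.ndarray, y: np.ndarray):
    """Closed-form simple-regression fit: slope, intercept, r2, rmse."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - intercept - slope * x
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(ss_res / n))
    return intercept, slope, r2, rmse
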