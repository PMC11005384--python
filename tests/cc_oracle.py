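"""Independent brute-force oracles shared by the test modules.

These deliberately avoid the library code paths they check: connected
components by pure-Python BFS flood fill, and per-voxel statistics by
explicit loops.
"""

from __future__ import annotations

from collections import deque
from itertools import product

import numpy as np


def neighbor_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    offs = []
    for d in product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        order = sum(abs(x) for x in d)
        if connectivity == 6 and order > 1:
            continue
        if connectivity == 18 and order > 2:
            continue
        offs.append(d)
    return offs


def flood_fill_components(binary: np.ndarray, connectivity: int
                          ) -> list[set[tuple[int, int, int]]]:
    """All connected components of a 3D boolean array, as voxel-index sets."""
    offs = neighbor_offsets(connectivity)
    seen = np.zeros(binary.shape, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(binary)):
        if seen[start]:
            continue
        comp = set()
        q = deque([start])
        seen[start] = True
        while q:
            v = q.popleft()
            comp.add(v)
            for d in offs:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if (0 <= w[0] < binary.shape[0] and 0 <= w[1] < binary.shape[1]
                        and 0 <= w[2] < binary.shape[2]
                        and binary[w] and not seen[w]):
                    seen[w] = True
                    q.append(w)
        comps.append(comp)
    return comps


def loop_mean_sd(volumes: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel sample mean and SD (ddof=1) by explicit scalar loops."""
    shape = volumes[0].shape
    n = len(volumes)
    mean = np.zeros(shape)
    sd = np.zeros(shape)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                xs = [v[i, j, k] for v in volumes]
                m = sum(xs) / n
                mean[i, j, k] = m
                sd[i, j, k] = (sum((x - m) ** 2 for x in xs) / (n - 1)) ** 0.5
    return mean, sd


def pairwise_u(x, y) -> float:
    """Mann-Whitney U for x by exhaustive pair counting (ties count 1/2)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u
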