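"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized/FFT code paths: explicit
Python loops and breadth-first search only.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def loop_mean_vector(amp, phase) -> complex:
    """|M_raw| ingredient computed with an explicit per-sample loop."""
    acc = 0j
    n = 0
    for a, p in zip(amp.tolist(), phase.tolist()):
        acc += a * complex(np.cos(p), np.sin(p))
        n += 1
    return acc / n


def loop_lagged_length(amp, phase, lag: int) -> float:
    """Surrogate mean-vector length for one circular lag, by explicit loop."""
    n = len(amp)
    acc = 0j
    for t in range(n):
        a = amp[(t + lag) % n]
        acc += a * complex(np.cos(phase[t]), np.sin(phase[t]))
    return abs(acc / n)


def bfs_clusters(t_map: np.ndarray, threshold: float, connectivity: int = 4):
    """Connected components of equal-sign supra-threshold cells via BFS.

    Returns a list of (frozenset of (i, j), signed mass) tuples.
    """
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    n_i, n_j = t_map.shape
    seen = np.zeros(t_map.shape, dtype=bool)
    out = []
    for i0 in range(n_i):
        for j0 in range(n_j):
            if seen[i0, j0] or abs(t_map[i0, j0]) <= threshold:
                continue
            sign = np.sign(t_map[i0, j0])
            cells = set()
            queue = deque([(i0, j0)])
            seen[i0, j0] = True
            while queue:
                i, j = queue.popleft()
                cells.add((i, j))
                for di, dj in steps:
                    ni, nj = i + di, j + dj
                    if (
                        0 <= ni < n_i
                        and 0 <= nj < n_j
                        and not seen[ni, nj]
                        and abs(t_map[ni, nj]) > threshold
                        and np.sign(t_map[ni, nj]) == sign
                    ):
                        seen[ni, nj] = True
                        queue.append((ni, nj))
            mass = float(sum(t_map[c] for c in cells))
            out.append((frozenset(cells), mass))
    return out
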