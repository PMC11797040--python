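"""Independent brute-force re-derivation of the two-pass block clustering.

Deliberately written against the prose definition, with numpy distance
matrices and explicit boundary sets, sharing no code with the library
implementation it cross-checks. Operates on bare (x, y) pairs.
"""

from __future__ import annotations

import numpy as np


def brute_force_cluster(xy: list[tuple[float, float]], threshold: float
                        ) -> list[list[int]]:
    """Cluster (x, y) points; returns index groups into the sorted order.

    Pass 1: a boundary falls between consecutive sorted points whenever
    their Euclidean distance is at least ``threshold`` (the current point
    is always compared against the last point of the open cluster, which
    by construction is its predecessor). Pass 2: within each run, every
    interior strict local extremum in y is cut out as a singleton.
    """
    if not xy:
        return []
    order = sorted(range(len(xy)), key=lambda i: (xy[i][0], xy[i][1]))
    pts = np.array([xy[i] for i in order], dtype=float)
    n = len(pts)

    # full distance matrix, then consecutive-pair boundaries
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    boundaries = {0, n}
    for i in range(1, n):
        if dist[i - 1, i] >= threshold:
            boundaries.add(i)

    # pass 2: exhaustively mark interior extrema within each pass-1 run
    cuts = sorted(boundaries)
    for lo, hi in zip(cuts, cuts[1:]):
        ys = pts[lo:hi, 1]
        for j in range(1, len(ys) - 1):
            both_above = ys[j - 1] > ys[j] and ys[j + 1] > ys[j]
            both_below = ys[j - 1] < ys[j] and ys[j + 1] < ys[j]
            if both_above or both_below:
                boundaries.add(lo + j)      # cut before the extremum
                boundaries.add(lo + j + 1)  # and after it

    cuts = sorted(boundaries)
    return [
        [order[i] for i in range(lo, hi)] for lo, hi in zip(cuts, cuts[1:])
    ]
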