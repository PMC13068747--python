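"""Open-begin-end asymmetric dynamic time warping.

The aligner matches a query trajectory against a reference trajectory
with the asymmetric step set {(1,0), (1,1), (1,2)} in (query, reference)
increments: every query frame is matched exactly once, while the
reference may stall or be skipped one frame at a time. Open begin/end
means the path may enter and leave the reference anywhere at no cost,
which makes the distance robust to imprecise stroke segmentation —
mis-annotated lead-in and retraction frames of the reference are simply
ignored.

The cumulative cost (the sum of local Euclidean costs along the optimal
path) grows with gesture duration, so pair-level distances are reported
per frame: cumulative cost divided by the total frame count of the two
gestures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

#: reference-index decrement of each admissible step, in tie-break
#: preference order: diagonal, vertical-repeat, skip
_STEP_DELTAS = (1, 0, 2)


def local_cost(frame_a: np.ndarray, frame_b: np.ndarray) -> float:
    """Euclidean distance between two per-frame coordinate vectors."""
    return float(np.linalg.norm(np.asarray(frame_a) - np.asarray(frame_b)))


@dataclass(frozen=True)
class AlignmentResult:
    """Optimal open-begin-end alignment of a query onto a reference.

    ``path`` is an ``(n, 2)`` array of 0-based (query, reference) index
    pairs; query indices increase by exactly 1 per row. ``j_start`` and
    ``j_end`` are the reference indices where the path enters and exits.
    """

    cumulative_cost: float
    path: np.ndarray
    n: int
    m: int
    j_start: int
    j_end: int

    @property
    def normalized(self) -> float:
        return normalized_distance(self.cumulative_cost, self.n, self.m)


def normalized_distance(cumulative_cost: float, n: int, m: int) -> float:
    """Per-frame distance: cumulative cost over the total frame count."""
    if cumulative_cost < 0:
        raise ValueError("cumulative cost must be nonnegative")
    return cumulative_cost / (n + m)


def dtw_open_begin_end(
    query: np.ndarray, reference: np.ndarray
) -> AlignmentResult:
    """Align ``query`` (n, d) onto ``reference`` (m, d).

    Dynamic program: ``D[i, j] = c[i, j] + min(D[i-1, j], D[i-1, j-1],
    D[i-1, j-2])`` with ``D[0, j] = c[0, j]`` for every j (open begin) and
    the result the minimum of the last row (open end). Ties are broken
    deterministically: smallest exit index, then backtracking preference
    diagonal > vertical-repeat > skip.
    """
    query = np.atleast_2d(np.asarray(query, dtype=float))
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    n, m = query.shape[0], reference.shape[0]
    if n < 2 or m < 2:
        raise ValueError(
            f"both series need >= 2 frames (got {n} and {m}); pad first"
        )
    if query.shape[1] != reference.shape[1]:
        raise ValueError("query and reference dimensionality differ")
    cost = cdist(query, reference)  # (n, m) local Euclidean costs

    acc = np.empty_like(cost)
    acc[0] = cost[0]  # open begin: free entry anywhere
    choice = np.zeros((n, m), dtype=np.int8)
    inf = np.inf
    prev_pad = np.empty(m + 2)
    for i in range(1, n):
        prev_pad[2:] = acc[i - 1]
        prev_pad[:2] = inf
        # candidate predecessors for column j: j-1 (diag), j (repeat), j-2 (skip)
        cand = np.stack((prev_pad[1:-1], prev_pad[2:], prev_pad[:-2]))
        best = np.argmin(cand, axis=0)  # first minimum -> preference order
        acc[i] = cost[i] + cand[best, np.arange(m)]
        choice[i] = best

    j_end = int(np.argmin(acc[-1]))  # first minimum -> smallest j_end
    path = np.empty((n, 2), dtype=np.intp)
    j = j_end
    for i in range(n - 1, -1, -1):
        path[i] = (i, j)
        if i > 0:
            j -= _STEP_DELTAS[choice[i, j]]
    return AlignmentResult(
        cumulative_cost=float(acc[-1, j_end]),
        path=path,
        n=n,
        m=m,
        j_start=int(path[0, 1]),
        j_end=j_end,
    )
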