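"""Piecewise-linear time-series segmentation (bottom-up and SWAB).

SWAB (Sliding Window And Bottom-up) keeps a buffer of recent samples, runs
bottom-up segmentation inside it, emits the leftmost finished segment, and
slides on.  With a buffer spanning the whole series it reduces exactly to
bottom-up segmentation, which is the oracle the tests use.

Segments are half-open index intervals ``[start, end)``; the cost of a
segment is the sum of squared residuals (SSE) of its least-squares line.
Costs are evaluated in O(1) from prefix sums.
"""

from __future__ import annotations

import numpy as np

__all__ = ["segment_cost", "bottom_up", "swab"]


class _CostTable:
    """O(1) linear-fit SSE over any index interval, via prefix sums."""

    def __init__(self, y: np.ndarray):
        y = np.asarray(y, dtype=float)
        x = np.arange(len(y), dtype=float)
        z = np.zeros(1)
        self._cx = np.concatenate([z, np.cumsum(x)])
        self._cxx = np.concatenate([z, np.cumsum(x * x)])
        self._cy = np.concatenate([z, np.cumsum(y)])
        self._cyy = np.concatenate([z, np.cumsum(y * y)])
        self._cxy = np.concatenate([z, np.cumsum(x * y)])

    def sse(self, i: int, j: int) -> float:
        """SSE of the least-squares line over ``y[i:j]``."""
        n = j - i
        if n <= 2:
            return 0.0
        sx = self._cx[j] - self._cx[i]
        sy = self._cy[j] - self._cy[i]
        sxx = self._cxx[j] - self._cxx[i] - sx * sx / n
        syy = self._cyy[j] - self._cyy[i] - sy * sy / n
        sxy = self._cxy[j] - self._cxy[i] - sx * sy / n
        if sxx <= 0:
            return max(syy, 0.0)
        return max(syy - sxy * sxy / sxx, 0.0)


def segment_cost(y: np.ndarray, start: int, end: int) -> float:
    """Least-squares line SSE of ``y[start:end]`` (reference implementation)."""
    return _CostTable(np.asarray(y, dtype=float)).sse(start, end)


def bottom_up(y: np.ndarray, max_error: float, initial_seg: int = 2) -> list[tuple[int, int]]:
    """Bottom-up merge of fine segments under a per-segment SSE cap.

    Starts from contiguous segments of ``initial_seg`` samples and greedily
    merges the adjacent pair whose merged SSE is smallest, while that SSE
    stays below ``max_error``.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n == 0:
        raise ValueError("cannot segment an empty series")
    if max_error < 0:
        raise ValueError(f"max_error must be >= 0, got {max_error}")
    bounds = list(range(0, n, initial_seg)) + [n]
    bounds = sorted(set(bounds))
    if len(bounds) < 2:
        return [(0, n)]
    table = _CostTable(y)

    segs = [(bounds[k], bounds[k + 1]) for k in range(len(bounds) - 1)]
    merge_cost = [
        table.sse(segs[k][0], segs[k + 1][1]) for k in range(len(segs) - 1)
    ]
    while merge_cost:
        k = int(np.argmin(merge_cost))
        if merge_cost[k] >= max_error:
            break
        segs[k] = (segs[k][0], segs[k + 1][1])
        del segs[k + 1]
        del merge_cost[k]
        if k > 0:
            merge_cost[k - 1] = table.sse(segs[k - 1][0], segs[k][1])
        if k < len(segs) - 1:
            merge_cost[k] = table.sse(segs[k][0], segs[k + 1][1])
    return segs


def swab(
    y: np.ndarray,
    max_error: float,
    buffer_size: int | None = None,
    initial_seg: int = 2,
) -> list[tuple[int, int]]:
    """Online-style segmentation: bottom-up inside a sliding buffer.

    ``buffer_size`` defaults to roughly six nominal segments' worth of
    samples (n/6, at least 20).  A buffer covering the whole series makes
    the output identical to :func:`bottom_up`.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n == 0:
        raise ValueError("cannot segment an empty series")
    if buffer_size is None:
        buffer_size = max(20, n // 6)
    buffer_size = min(buffer_size, n)

    out: list[tuple[int, int]] = []
    lo = 0
    hi = min(n, buffer_size)
    while True:
        segs = bottom_up(y[lo:hi], max_error, initial_seg=initial_seg)
        if hi >= n:
            out.extend((s + lo, e + lo) for s, e in segs)
            break
        if len(segs) == 1:
            # buffer is one segment: grow it so the left boundary can settle
            hi = min(n, hi + buffer_size // 2)
            continue
        s, e = segs[0]
        out.append((s + lo, e + lo))
        lo += e
        hi = min(n, lo + buffer_size)
    return out
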