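"""Fisher–Jenks natural-breaks classification.

The natural-breaks problem: partition a set of 1-D values into ``k``
contiguous classes minimising the total within-class sum of squared
deviations (SSD). Fisher's dynamic program solves it exactly in
O(k·n²) after sorting; this module implements that DP from scratch
(numba-compiled kernel) because the break placement is the backbone of
every sensitivity classification in the pipeline and must be exact and
deterministic.

Intervals are left-open/right-closed: a value exactly on a break goes to
the lower class. On grids larger than ``MAX_EXACT_CELLS`` valid cells the
breaks are computed on a seeded random subsample (documented in the run
report); below that threshold they are exact.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numba import njit

from .grid import GridLayer

__all__ = ["BreakSet", "compute_breaks", "classify_with_breaks", "MAX_EXACT_CELLS"]

log = logging.getLogger(__name__)

MAX_EXACT_CELLS = 10_000


@dataclass(frozen=True)
class BreakSet:
    """k-class natural-breaks result: k-1 strictly increasing upper bounds."""

    k: int
    breaks: tuple[float, ...]
    data_min: float
    data_max: float

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if len(self.breaks) != self.k - 1:
            raise ValueError("need exactly k-1 breaks")
        if any(b2 <= b1 for b1, b2 in zip(self.breaks, self.breaks[1:])):
            raise ValueError("breaks must be strictly increasing")


@njit(cache=True)
def _fisher_jenks_dp(v, w, k):  # pragma: no cover - exercised via compute_breaks
    """DP over *distinct* sorted values ``v`` with multiplicities ``w``.

    Returns the start index (into v) of classes 2..k plus the optimal total
    within-class SSD. Working on distinct values keeps breaks strictly
    increasing under heavy ties and shrinks the O(k·n²) table.
    """
    n = v.shape[0]
    s = np.zeros(n + 1)
    s2 = np.zeros(n + 1)
    sw = np.zeros(n + 1)
    for i in range(n):
        s[i + 1] = s[i] + w[i] * v[i]
        s2[i + 1] = s2[i] + w[i] * v[i] * v[i]
        sw[i + 1] = sw[i] + w[i]

    D = np.full((k + 1, n + 1), np.inf)
    B = np.zeros((k + 1, n + 1), np.int64)
    D[0, 0] = 0.0
    for j in range(1, k + 1):
        for i in range(j, n + 1):
            best = np.inf
            arg = j - 1
            for m in range(j - 1, i):
                prev = D[j - 1, m]
                if prev == np.inf:
                    continue
                seg = s2[i] - s2[m] - (s[i] - s[m]) ** 2 / (sw[i] - sw[m])
                cost = prev + seg
                if cost < best:
                    best = cost
                    arg = m
            D[j, i] = best
            B[j, i] = arg
    starts = np.zeros(k - 1, np.int64)
    i = n
    for j in range(k, 1, -1):
        i = B[j, i]
        starts[j - 2] = i
    return starts, D[k, n]


def _dp_breaks(values: np.ndarray, counts: np.ndarray, k: int) -> tuple[tuple[float, ...], float]:
    starts, ssd = _fisher_jenks_dp(values, counts.astype(np.float64), k)
    # break value = last distinct value of the lower class ((lo, hi] intervals)
    breaks = tuple(float(values[s - 1]) for s in starts)
    return breaks, float(ssd)


def compute_breaks(
    values,
    k: int,
    *,
    max_cells: int = MAX_EXACT_CELLS,
    seed: int | None = None,
) -> BreakSet:
    """Optimal k-class natural breaks of ``values``.

    Parameters
    ----------
    values : array-like of finite numbers
    k : target class count (>= 2)
    max_cells : subsample size above which a seeded sample is classified
        instead of the full vector
    seed : seed for the subsample draw (ignored when n <= max_cells)

    If the data has fewer distinct values than classes, the class count
    collapses to the number of distinct values with a warning instead of
    failing — plateaus and constant rasters must not crash the pipeline.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0 or not np.all(np.isfinite(v)):
        raise ValueError("values must be non-empty and finite")
    if k < 2:
        raise ValueError("k must be >= 2")

    if v.size > max_cells:
        rng = np.random.default_rng(seed)
        sample = rng.choice(v, size=max_cells, replace=False)
        # keep the true extremes so the outer intervals cover the data
        sample = np.concatenate([sample, [v.min(), v.max()]])
        log.info("jenks: subsampled %d of %d values (seed=%s)", max_cells, v.size, seed)
        v = sample

    distinct, counts = np.unique(v, return_counts=True)
    if distinct.size < k:
        warnings.warn(
            f"only {distinct.size} distinct values for k={k}; "
            f"collapsing to {max(distinct.size, 1)} classes",
            stacklevel=2,
        )
        k = int(distinct.size)
        if k == 1:
            return BreakSet(1, (), float(distinct[0]), float(distinct[-1]))

    breaks, ssd = _dp_breaks(distinct, counts, k)
    gvf = 1.0 - ssd / max(np.sum((v - v.mean()) ** 2), np.finfo(float).tiny)
    log.info("jenks: k=%d ssd=%.6g gvf=%.4f", k, ssd, gvf)
    return BreakSet(k, breaks, float(distinct[0]), float(distinct[-1]))


def classify_with_breaks(
    layer: GridLayer, breaks: BreakSet, ascending: bool = True
) -> GridLayer:
    """Assign every valid cell an integer class 1..k from a BreakSet.

    ``ascending=True`` maps larger values to larger codes; ``False``
    reverses the coding, for factors where a high raw value means LOW
    sensitivity. Intervals are (lo, hi]: boundary values take the lower
    class.
    """
    vals = layer.values.astype(float)
    edges = np.asarray(breaks.breaks, dtype=float)
    # side="left": v == break stays in the lower class
    codes = np.searchsorted(edges, vals, side="left") + 1
    if not ascending:
        codes = breaks.k + 1 - codes
    out = np.where(layer.mask, int(layer.nodata), codes)
    return layer.with_values(out.astype(np.int64), nodata=int(layer.nodata))


# ---------------------------------------------------------------------------
# Break persistence (CSV) so classifications are reproducible across runs
# ---------------------------------------------------------------------------

def save_breaks(table: dict[str, BreakSet], path: str | Path) -> None:
    lines = ["factor,k,breaks"]
    for name, bs in table.items():
        lines.append(f"{name},{bs.k},{';'.join(repr(b) for b in bs.breaks)}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_breaks(path: str | Path) -> dict[str, BreakSet]:
    out: dict[str, BreakSet] = {}
    for line in Path(path).read_text().splitlines()[1:]:
        name, k, brk = line.split(",")
        breaks = tuple(float(b) for b in brk.split(";") if b)
        lo = breaks[0] if breaks else 0.0
        hi = breaks[-1] if breaks else 0.0
        out[name] = BreakSet(int(k), breaks, lo, hi)
    return out
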