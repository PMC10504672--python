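"""Exact penalized least-squares segmentation of per-bin values.

The objective is the classical piecewise-constant fit

    sum of squared residuals + penalty * (number of breakpoints)

solved exactly with an O(n^2) dynamic program.  The penalty is
``gamma * sigma^2`` where ``sigma^2`` is a robust noise estimate from the
scaled median absolute first difference, so ``gamma`` is unitless and the
standard default (gamma = 100) works across value scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ValueSegment:
    start_index: int   # inclusive bin index
    end_index: int     # exclusive bin index
    mean: float

    @property
    def n_bins(self) -> int:
        return self.end_index - self.start_index


def estimate_noise_variance(values: np.ndarray) -> float:
    """Robust residual variance from first differences.

    MAD of successive differences, Gaussian-consistent, divided by 2
    because a difference of two independent values doubles the variance.
    A small floor keeps the per-breakpoint penalty strictly positive on
    noiseless input.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        return 1e-12
    diffs = np.diff(values)
    mad = np.median(np.abs(diffs - np.median(diffs)))
    sigma = 1.4826 * mad / np.sqrt(2.0)
    return max(float(sigma * sigma), 1e-12)


def segment_values(
    values,
    gamma: float = 100.0,
    sigma2: float | None = None,
) -> list[ValueSegment]:
    """Optimal piecewise-constant segmentation of an ordered series.

    Parameters
    ----------
    values
        Per-bin values ordered along a chromosome.
    gamma
        Penalty per breakpoint in units of the noise variance.
    sigma2
        Noise variance; estimated from the data when omitted.

    Returns the exact optimum of SSE + gamma*sigma2*(#breakpoints),
    found by dynamic programming.  Empty input yields no segments.
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    if n == 0:
        return []
    if sigma2 is None:
        sigma2 = estimate_noise_variance(y)
    penalty = float(gamma) * float(sigma2)

    # prefix sums for O(1) segment SSE:  sse(i, j) over bins i..j-1
    s1 = np.concatenate(([0.0], np.cumsum(y)))
    s2 = np.concatenate(([0.0], np.cumsum(y * y)))

    best = np.empty(n + 1)
    back = np.zeros(n + 1, dtype=np.int64)
    best[0] = -penalty  # first segment carries no breakpoint
    idx = np.arange(n + 1)
    for j in range(1, n + 1):
        i = idx[:j]
        length = j - i
        seg_sum = s1[j] - s1[i]
        sse = (s2[j] - s2[i]) - seg_sum * seg_sum / length
        cost = best[:j] + sse + penalty
        k = int(np.argmin(cost))
        best[j] = cost[k]
        back[j] = k

    bounds = [n]
    j = n
    while j > 0:
        j = int(back[j])
        bounds.append(j)
    bounds.reverse()

    segments = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        segments.append(ValueSegment(a, b, float(y[a:b].mean())))
    return segments


def fine_map_boundaries(
    coarse_segments: list[tuple[int, int]],
    fine_segments: list[tuple[int, int]],
    max_shift: int | None = None,
) -> list[tuple[int, int]]:
    """Snap coarse segment boundaries (bp) to fine-segment boundaries.

    Each boundary between coarse segments moves to the nearest boundary
    of the fine segmentation, so breakpoints gain the fine grid's
    resolution.  ``max_shift`` limits how far a boundary may move
    (default: half the longest coarse segment, so snapping can never
    erase a segment); boundaries with no fine boundary in range stay put.
    """
    if not coarse_segments or not fine_segments:
        return list(coarse_segments)
    fine_bounds = np.unique(
        np.concatenate([[fs for fs, _ in fine_segments], [fe for _, fe in fine_segments]])
    )
    if max_shift is None:
        max_shift = max(1, min(e - s for s, e in coarse_segments) // 2)
    bounds = [coarse_segments[0][0]] + [e for _, e in coarse_segments]
    snapped = []
    for i, b in enumerate(bounds):
        j = int(np.argmin(np.abs(fine_bounds - b)))
        nearest = int(fine_bounds[j])
        snapped.append(nearest if abs(nearest - b) <= max_shift else b)
    # enforce strictly increasing boundaries
    for i in range(1, len(snapped)):
        if snapped[i] <= snapped[i - 1]:
            snapped[i] = max(bounds[i], snapped[i - 1] + 1)
    return [(s, e) for s, e in zip(snapped[:-1], snapped[1:]) if e > s]
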