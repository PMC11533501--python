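"""Photobleaching step counting for single-molecule copy-number estimates.

Counts discrete downward intensity steps in a trace, each step one
fluorophore bleaching, so the step count estimates the number of tagged
protein copies in an assembly.

The detector is a recursive binary segmentation with Welch's unequal
variance t-test: within each segment every admissible split point is
scored, the strongest split is kept if significant at level ``alpha``
(Bonferroni-corrected over the candidate splits in that segment), and
the two halves are recursed. A merge pass then removes any changepoint
whose flanking segments do not differ significantly at ``alpha``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class StepFit:
    """Piecewise-constant fit of an intensity trace."""

    changepoint_times: np.ndarray  # s, strictly increasing
    changepoint_indices: np.ndarray  # first frame of each new segment
    levels: np.ndarray  # one per segment
    n_down_steps: int
    n_up_steps: int
    fitted: np.ndarray  # same length as the trace


def _welch_best_split(y: np.ndarray, min_seg: int):
    """Best split of a segment by Welch t; returns (index, p_bonferroni).

    Vectorized over all candidate splits via cumulative sums.
    """
    n = len(y)
    if n < 2 * min_seg:
        return None, 1.0
    cs = np.cumsum(y)
    cs2 = np.cumsum(y * y)
    k = np.arange(min_seg, n - min_seg + 1)  # left part = y[:k]
    n1 = k.astype(float)
    n2 = n - n1
    m1 = cs[k - 1] / n1
    m2 = (cs[-1] - cs[k - 1]) / n2
    ss1 = cs2[k - 1] - n1 * m1**2
    ss2 = (cs2[-1] - cs2[k - 1]) - n2 * m2**2
    v1 = ss1 / np.maximum(n1 - 1, 1)
    v2 = ss2 / np.maximum(n2 - 1, 1)
    se2 = v1 / n1 + v2 / n2
    se2 = np.maximum(se2, 1e-300)
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / np.maximum(
        (v1 / n1) ** 2 / np.maximum(n1 - 1, 1) + (v2 / n2) ** 2 / np.maximum(n2 - 1, 1),
        1e-300,
    )
    best = int(np.argmax(np.abs(t)))
    # (near-)zero-variance halves: a noiseless step is a certain detection
    # (the Welch df underflows there); a perfectly flat segment has no step
    if not np.isfinite(t[best]) or abs(t[best]) > 1e8 or df[best] <= 0:
        if abs(m1[best] - m2[best]) > 0:
            return int(k[best]), 0.0
        return None, 1.0
    p = 2.0 * stats.t.sf(abs(t[best]), df[best])
    return int(k[best]), min(1.0, p * len(k))


def _segment(y: np.ndarray, start: int, alpha: float, min_seg: int, cps: list):
    idx, p = _welch_best_split(y, min_seg)
    if idx is None or p >= alpha:
        return
    cps.append(start + idx)
    _segment(y[:idx], start, alpha, min_seg, cps)
    _segment(y[idx:], start + idx, alpha, min_seg, cps)


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.var(a) == 0 and np.var(b) == 0:
        return 0.0 if np.mean(a) != np.mean(b) else 1.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def detect_steps(
    trace: pd.DataFrame, alpha: float = 0.01, min_segment_frames: int = 5
) -> StepFit:
    """Fit a piecewise-constant model and count bleaching (downward) steps.

    ``trace`` needs columns ``time_s`` and ``intensity`` on a uniform
    grid. Raises ValueError for traces shorter than
    ``2 * min_segment_frames``. Upward transitions are counted
    separately and excluded from ``n_down_steps``.
    """
    y = np.asarray(trace["intensity"], dtype=float)
    t = np.asarray(trace["time_s"], dtype=float)
    if len(y) < 2 * min_segment_frames:
        raise ValueError("trace too short for step detection")
    if not np.all(np.isfinite(y)):
        raise ValueError("trace contains non-finite values")

    cps: list[int] = []
    _segment(y, 0, alpha, min_segment_frames, cps)
    cps = sorted(cps)

    # merge pass: drop the least significant changepoint until all remain
    # significant between their flanking segments
    while cps:
        bounds = [0] + cps + [len(y)]
        pvals = []
        for i in range(1, len(bounds) - 1):
            a = y[bounds[i - 1] : bounds[i]]
            b = y[bounds[i] : bounds[i + 1]]
            pvals.append(_welch_p(a, b))
        worst = int(np.argmax(pvals))
        if pvals[worst] < alpha:
            break
        del cps[worst]

    bounds = [0] + cps + [len(y)]
    levels = np.array([y[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])
    fitted = np.concatenate(
        [np.full(b - a, lv) for a, b, lv in zip(bounds[:-1], bounds[1:], levels)]
    )
    diffs = np.diff(levels)
    return StepFit(
        changepoint_times=t[np.asarray(cps, dtype=int)] if cps else np.empty(0),
        changepoint_indices=np.asarray(cps, dtype=int),
        levels=levels,
        n_down_steps=int(np.sum(diffs < 0)),
        n_up_steps=int(np.sum(diffs > 0)),
        fitted=fitted,
    )


def copy_number_histogram(fits: Iterable[StepFit]) -> dict[int, int]:
    """Histogram of downward step counts across traces.

    The values sum to the number of traces supplied.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("need at least one StepFit")
    return dict(sorted(Counter(f.n_down_steps for f in fits).items()))
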