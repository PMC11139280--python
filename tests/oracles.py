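"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they are checked against:
extrema detection is re-derived from the topographic-prominence definition by
exhaustive scanning, and rank-sum p-values by enumerating every group
assignment.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_force_extrema(y: np.ndarray, min_prominence: float, min_separation: int) -> list[int]:
    """All maxima of y surviving prominence and separation, by exhaustive scan.

    Procedure: enumerate every local maximum (plateau midpoints); thin by
    minimum separation in order of decreasing height (a kept peak removes all
    lower peaks closer than the separation); then keep survivors whose
    topographic prominence — height above the higher of the two lowest points
    separating the peak from higher terrain on each side — reaches the
    threshold.  Minima of y are maxima of -y.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)

    peaks = []
    i = 1
    while i < n - 1:
        if y[i - 1] < y[i]:
            j = i
            while j < n - 1 and y[j + 1] == y[i]:
                j += 1
            if j < n - 1 and y[j + 1] < y[i]:
                peaks.append((i + j) // 2)
            i = j + 1
        else:
            i += 1

    order = sorted(peaks, key=lambda p: (-y[p], p))
    removed: set[int] = set()
    for p in order:
        if p in removed:
            continue
        for q in peaks:
            if q != p and q not in removed and abs(q - p) < min_separation:
                if (y[q], -q) < (y[p], -p):
                    removed.add(q)
    survivors = [p for p in peaks if p not in removed]

    out = []
    for p in survivors:
        higher_left = [k for k in range(p) if y[k] > y[p]]
        lo = max(higher_left) + 1 if higher_left else 0
        left_min = y[lo : p + 1].min()
        higher_right = [k for k in range(p + 1, n) if y[k] > y[p]]
        hi = min(higher_right) if higher_right else n
        right_min = y[p:hi].min()
        if y[p] - max(left_min, right_min) >= min_prominence:
            out.append(p)
    return out


def exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum p-value by enumerating all group assignments.

    Returns (rank sum of group a, exact two-sided p).  Assumes no ties.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    obs = ranks[: len(a)].sum()
    n1 = len(a)
    mu = n1 * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for combo in combinations(range(len(pooled)), n1):
        r = ranks[list(combo)].sum()
        total += 1
        if abs(r - mu) >= abs(obs - mu) - 1e-12:
            count += 1
    return float(obs), count / total


def hand_kappa(pairs: list[tuple[str, str]]) -> tuple[float, float]:
    """(raw agreement, Cohen's kappa) from explicit contingency arithmetic."""
    n = len(pairs)
    cats = sorted({t for p in pairs for t in p})
    p_o = sum(a == b for a, b in pairs) / n
    p_e = 0.0
    for c in cats:
        row = sum(a == c for a, _ in pairs) / n
        col = sum(b == c for _, b in pairs) / n
        p_e += row * col
    return p_o, (p_o - p_e) / (1 - p_e)
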