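"""Independent brute-force reference implementations used only by tests."""

from __future__ import annotations

import re
from itertools import combinations

import numpy as np
from scipy import stats


def brute_force_peaks(
    counts: np.ndarray,
    bg_window: int,
    pval_cut: float,
    merge_gap: int,
    min_width: int,
) -> list[tuple[int, int, int]]:
    """Position-by-position exceedance -> gap merge -> width filter.

    Plain Python scan; returns (start, end, summit) triples.
    """
    counts = np.asarray(counts)
    n = len(counts)
    if n == 0 or counts.sum() == 0:
        return []
    global_mean = float(np.mean(counts))
    half = bg_window // 2
    lam = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        window_mean = sum(int(c) for c in counts[lo:hi]) / (hi - lo)
        lam[i] = max(global_mean, window_mean)
    thresholds = stats.poisson.isf(pval_cut, lam)
    seeds = [i for i in range(n) if counts[i] > thresholds[i]]
    if not seeds:
        return []
    blocks = [[seeds[0], seeds[0] + 1]]
    for s in seeds[1:]:
        if s - blocks[-1][1] <= merge_gap:
            blocks[-1][1] = s + 1
        else:
            blocks.append([s, s + 1])
    peaks = []
    for start, end in blocks:
        if end - start < min_width:
            continue
        best = start
        for i in range(start, end):
            if counts[i] > counts[best]:
                best = i
        peaks.append((start, end, best))
    return peaks


def regex_t_runs(seq: str, min_len: int) -> list[tuple[int, int]]:
    return [
        (m.start(), m.end() - m.start())
        for m in re.finditer(r"T+", seq.upper())
        if m.end() - m.start() >= min_len
    ]


def enumerate_mwu(x, y) -> tuple[float, float]:
    """U and exact two-tailed p by full enumeration of group assignments."""
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    n, m = len(x), len(y)

    def u_of(xs, ys):
        return sum(
            1.0 if a > b else (0.5 if a == b else 0.0) for a in xs for b in ys
        )

    u_obs = u_of(x, y)
    mean_u = n * m / 2.0
    d_obs = abs(u_obs - mean_u)
    total = extreme = 0
    for comb in combinations(range(n + m), n):
        chosen = set(comb)
        xs = [pooled[i] for i in range(n + m) if i in chosen]
        ys = [pooled[i] for i in range(n + m) if i not in chosen]
        total += 1
        if abs(u_of(xs, ys) - mean_u) >= d_obs - 1e-9:
            extreme += 1
    return u_obs, extreme / total


def reference_bh(p: list[float]) -> list[float]:
    """Quadratic-time BH step-up."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [0.0] * n
    for rank_pos, idx in enumerate(order, start=1):
        q[idx] = min(1.0, p[idx] * n / rank_pos)
    # enforce monotonicity from the largest p downward
    for rank_pos in range(n - 2, -1, -1):
        q[order[rank_pos]] = min(q[order[rank_pos]], q[order[rank_pos + 1]])
    return q
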