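"""Independent brute-force oracles used by the test suite.

Everything here is written as plain O(n^2) enumeration, deliberately sharing
no code with the package implementation it checks.
"""

from __future__ import annotations

import math

EPS = 1e-9


def bf_window_min(times, values, t, window):
    """Min value with time in [t - window, t); None when empty."""
    best = None
    for tj, vj in zip(times, values):
        if t - window - EPS <= tj < t:
            if best is None or vj < best:
                best = vj
    return best


def bf_trigger(times, values, i):
    """Which KDIGO criterion fires at index i (None / abs / rel / both)."""
    t, v = times[i], values[i]
    m48 = bf_window_min(times, values, t, 48.0)
    base = bf_window_min(times, values, t, 168.0)
    abs_f = m48 is not None and (v - m48) >= 0.3 - EPS
    rel_f = base is not None and v >= 1.5 * base - EPS
    if abs_f and rel_f:
        return "both"
    if abs_f:
        return "absolute_rise_48h"
    if rel_f:
        return "relative_rise_baseline"
    return None


def bf_stage(value, baseline):
    ratio = value / baseline
    if ratio >= 3.0 - EPS or value >= 4.0 - EPS:
        return 3
    if ratio >= 2.0 - EPS:
        return 2
    return 1


def bf_detect(times, values):
    """Brute-force first-AKI detection: dict or None."""
    n = len(times)
    for i in range(1, n):
        crit = bf_trigger(times, values, i)
        if crit is None:
            continue
        base = bf_window_min(times, values, times[i], 168.0)
        stage = bf_stage(values[i], base) if base is not None else (
            3 if values[i] >= 4.0 - EPS else 1
        )
        sustained = i + 1 < n and bf_trigger(times, values, i + 1) is not None
        return {
            "onset_time": times[i],
            "criterion": crit,
            "stage": stage,
            "sustained": sustained,
        }
    return None


def bf_auc(scores, labels):
    """All-pairs concordance with ties counted half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def bf_locf(obs_times, obs_values, t):
    """Latest value at or before t by linear scan; NaN when none."""
    best_t, best_v = None, math.nan
    for tj, vj in zip(obs_times, obs_values):
        if tj <= t and (best_t is None or tj >= best_t):
            best_t, best_v = tj, vj
    return best_v
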