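"""Independent brute-force oracles used by the tests.

These are deliberately naive re-derivations — direct products over risk
sets, dense grid searches — kept separate from the package so that the
implementation and its check never share code paths.
"""

from __future__ import annotations

import math
from typing import List, Sequence, Tuple

import numpy as np


def brute_force_km(
    times: Sequence[float], events: Sequence[bool]
) -> List[Tuple[float, float]]:
    """(time, S(time)) at each distinct observed time, by direct product.

    S(t) = prod over distinct event times u <= t of (1 - d(u)/n(u)), with
    n(u) counting all subjects whose observed time is >= u (events before
    censorings at ties).
    """
    times = list(times)
    events = list(events)
    out = []
    for t in sorted(set(times)):
        s = 1.0
        for u in sorted(set(times)):
            if u > t:
                break
            d = sum(1 for ti, ei in zip(times, events) if ti == u and ei)
            n = sum(1 for ti in times if ti >= u)
            if d > 0:
                s *= 1.0 - d / n
        out.append((t, s))
    return out


def efron_loglik(
    beta: float,
    times: Sequence[float],
    events: Sequence[bool],
    x: Sequence[float],
) -> float:
    """Efron-tie Cox log partial likelihood, written with explicit loops."""
    ll = 0.0
    for t in sorted({ti for ti, ei in zip(times, events) if ei}):
        dead = [i for i, (ti, ei) in enumerate(zip(times, events))
                if ti == t and ei]
        risk = [i for i, ti in enumerate(times) if ti >= t]
        d = len(dead)
        s_r = sum(math.exp(beta * x[i]) for i in risk)
        s_d = sum(math.exp(beta * x[i]) for i in dead)
        ll += sum(beta * x[i] for i in dead)
        for k in range(d):
            ll -= math.log(s_r - (k / d) * s_d)
    return ll


def grid_search_log_hr(
    times: Sequence[float],
    events: Sequence[bool],
    x: Sequence[float],
    lo: float = -5.0,
    hi: float = 5.0,
) -> float:
    """Argmax of the Efron partial likelihood by dense grid + refinement."""
    grid = np.linspace(lo, hi, 2001)
    vals = [efron_loglik(b, times, events, x) for b in grid]
    best = int(np.argmax(vals))
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, len(grid) - 1)]
    # golden-section refinement on the bracket
    phi = (math.sqrt(5) - 1) / 2
    c, d = b - phi * (b - a), a + phi * (b - a)
    for _ in range(80):
        if efron_loglik(c, times, events, x) > efron_loglik(d, times, events, x):
            b, d = d, c
            c = b - phi * (b - a)
        else:
            a, c = c, d
            d = a + phi * (b - a)
    return (a + b) / 2
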