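"""Independent brute-force reference implementations.

Everything here is written with naive loops and no reuse of the package
internals, so it can serve as an oracle for exact-equivalence tests on
small fixtures.
"""

from __future__ import annotations

from itertools import combinations, combinations_with_replacement, product
from math import hypot, isnan

import numpy as np


def naive_rd(beak_xy: list[tuple[float, float] | None], height_mean: float):
    """Per-frame relative displacement; None where undefined."""
    out = [None]
    for t in range(1, len(beak_xy)):
        a, b = beak_xy[t - 1], beak_xy[t]
        if a is None or b is None:
            out.append(None)
        else:
            out.append(hypot(b[0] - a[0], b[1] - a[1]) / height_mean)
    return out


def naive_delta(rd: list, start: int, baseline: int, post: int):
    """(delta_mean, delta_max) or None if the window is unusable."""
    b_lo, b_hi = start - baseline + 1, start
    p_lo, p_hi = start, start + post - 1
    if b_lo < 0 or p_hi >= len(rd):
        return None
    base = [rd[t] for t in range(b_lo, b_hi + 1)]
    posts = [rd[t] for t in range(p_lo, p_hi + 1)]
    if any(v is None or (isinstance(v, float) and isnan(v)) for v in base + posts):
        return None
    d_mean = sum(posts) / len(posts) - sum(base) / len(base)
    d_max = max(posts) - max(base)
    return d_mean, d_max


def naive_eligible(rd: list, baseline: int, post: int) -> list[int]:
    """Frames whose full window is inside the bout with rd defined."""
    return [t for t in range(len(rd)) if naive_delta(rd, t, baseline, post) is not None]


def naive_exhaustive_null(per_male: list[tuple[list[float], int]]) -> list[float]:
    """Grand means of every unordered with-replacement draw per male."""
    male_mean_sets = []
    for values, n_draw in per_male:
        means = [
            sum(values[i] for i in combo) / n_draw
            for combo in combinations_with_replacement(range(len(values)), n_draw)
        ]
        male_mean_sets.append(means)
    return [sum(m) / len(m) for m in product(*male_mean_sets)]


def naive_permutation_p(proportions: list[float], n_owner: int) -> float:
    """Two-sided exhaustive label-permutation p for the mean difference."""
    n = len(proportions)

    def diff(owner_idx):
        owners = [proportions[i] for i in owner_idx]
        subs = [proportions[i] for i in range(n) if i not in owner_idx]
        return sum(owners) / len(owners) - sum(subs) / len(subs)

    observed = abs(diff(set(range(n_owner))))
    hits = 0
    total = 0
    for combo in combinations(range(n), n_owner):
        total += 1
        if abs(diff(set(combo))) >= observed - 1e-12:
            hits += 1
    return hits / total


def expected_pulse_delta_mean(
    magnitude: float,
    latency_range: tuple[int, int],
    duration: int,
    post: int,
    probability: float = 1.0,
    jitter_sd: float = 0.0,
) -> float:
    """Expected injected Δ_mean by direct enumeration of pulse placement.

    For each equally likely latency the pulse occupies frames
    ``latency … latency + duration − 1`` relative to the element start;
    the baseline never contains pulse frames (latency ≥ 1).  With no
    jitter each pulse frame landing in the post window ``0 … post − 1``
    adds exactly ``magnitude/post`` to the post mean.

    With positional jitter of per-axis standard deviation ``jitter_sd``
    (in body heights), the frame-to-frame displacement noise has
    per-axis sd ``s = jitter_sd * sqrt(2)``.  A pulse frame's
    displacement is the magnitude of the pulse step plus a 2-D Gaussian
    — Rice distributed with location ``magnitude`` and scale ``s`` —
    and it *replaces* that frame's pure-noise displacement (Rayleigh
    mean ``s * sqrt(pi/2)``), so each pulse frame contributes the
    difference of those two expectations.
    """
    from scipy.stats import rice

    lo, hi = latency_range
    s = jitter_sd * np.sqrt(2.0)
    if s > 0:
        per_frame = rice.mean(b=magnitude / s, scale=s) - s * np.sqrt(np.pi / 2.0)
    else:
        per_frame = magnitude
    total = 0.0
    for lat in range(lo, hi + 1):
        in_post = sum(1 for k in range(lat, lat + duration) if 0 <= k <= post - 1)
        total += in_post * per_frame / post
    return probability * total / (hi - lo + 1)
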