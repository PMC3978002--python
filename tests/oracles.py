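"""Independent, loop-based reference implementations.

These are deliberately naive translations of the detection rules — plain
Python loops over samples, no numpy vector tricks, no code shared with the
package — used only to cross-check the production implementations.
"""

from __future__ import annotations

import math


def reference_demean(xs: list[float]) -> list[float]:
    m = sum(xs) / len(xs)
    return [x - m for x in xs]


def reference_agw(
    acc_v: list[float], acc_ap: list[float], ratio: float = 1.5
) -> tuple[bool, bool]:
    """Half-window asymmetry screen, sample-by-sample."""
    v = reference_demean(list(acc_v))
    ap = reference_demean(list(acc_ap))
    mid = len(v) // 2

    def exceeds(high: float, low: float) -> bool:
        if low <= 0:
            return high > 0
        return high > ratio * low

    max1 = max(v[:mid])
    max2 = max(v[mid:])
    agw_v = exceeds(max(max1, max2), min(max1, max2))

    min1 = abs(min(ap[:mid]))
    min2 = abs(min(ap[mid:]))
    agw_ap = exceeds(max(min1, min2), min(min1, min2))
    return agw_v, agw_ap


def reference_spaced_maxima(xs: list[float], min_separation: int) -> list[int]:
    """Strict local maxima, then greedy removal of lower peaks within
    ``min_separation`` samples of a kept higher peak (highest first)."""
    candidates = [
        i for i in range(1, len(xs) - 1) if xs[i - 1] < xs[i] and xs[i] > xs[i + 1]
    ]
    keep: list[int] = []
    removed = set()
    for i in sorted(candidates, key=lambda i: xs[i], reverse=True):
        if i in removed:
            continue
        keep.append(i)
        for j in candidates:
            if j != i and abs(j - i) < min_separation:
                removed.add(j)
    return sorted(keep)


def reference_sw_channel(
    xs: list[float], sample_rate: float, ratio: float = 1.8
) -> bool:
    """Highest-vs-third-following-peak test, loop-based."""
    sep = max(1, round(sample_rate / 3.0))
    peaks = reference_spaced_maxima(list(xs), sep)
    if not peaks:
        return False
    heights = [xs[i] for i in peaks]
    best = 0
    for k in range(len(heights)):
        if heights[k] > heights[best]:
            best = k
    following = heights[best + 1 :]
    if len(following) < 3:
        return False
    p3 = following[2]
    if p3 <= 0:
        return False
    return heights[best] / p3 > ratio


def reference_prominence(xs: list[float], i: int) -> float:
    """Topographic prominence of a local maximum, by walking outward to the
    nearest higher ground on each side and taking the higher of the two
    intervening valleys."""
    left_min = xs[i]
    j = i - 1
    while j >= 0 and xs[j] <= xs[i]:
        left_min = min(left_min, xs[j])
        j -= 1
    right_min = xs[i]
    j = i + 1
    while j < len(xs) and xs[j] <= xs[i]:
        right_min = min(right_min, xs[j])
        j += 1
    return xs[i] - max(left_min, right_min)


def reference_response_cycles(
    response: list[float], sample_rate: float, min_amplitude: float
) -> int:
    """Count maxima of a template response by +to- sign changes of the
    first difference, with the same separation and prominence rules."""
    diffs = [response[i + 1] - response[i] for i in range(len(response) - 1)]
    maxima = [
        i + 1
        for i in range(len(diffs) - 1)
        if diffs[i] > 0 and diffs[i + 1] < 0
    ]
    top = max(response) if response else 0.0
    floor = max(0.1 * top, min_amplitude)
    sep = max(1, round(sample_rate / 3.0))
    # separation first (keep higher peaks), then the prominence floor
    spaced: list[int] = []
    removed = set()
    for i in sorted(maxima, key=lambda i: response[i], reverse=True):
        if i in removed:
            continue
        spaced.append(i)
        for j in maxima:
            if j != i and abs(j - i) < sep:
                removed.add(j)
    kept = [i for i in spaced if reference_prominence(response, i) >= floor]
    return len(kept)


def reference_odds_ratio(a: float, b: float, c: float, d: float):
    """Closed-form 2x2 odds ratio with Woolf CI, spreadsheet-style."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(or_) - 1.96 * se)
    hi = math.exp(math.log(or_) + 1.96 * se)
    return or_, (lo, hi)
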