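"""Independent brute-force reference implementations used only by tests.

These are deliberately naive (plain Python loops, explicit formulas) and
share no code with the package; they exist so the vectorised implementations
can be checked against something written straight from the definitions.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Sequence


def naive_apen(x: Sequence[float], m: int = 2, r_coef: float = 0.2) -> float:
    """Approximate entropy via the definition: triple loop, no vectorisation.

    Chebyshev distance, self-matches included, r = r_coef * sample sd,
    ApEn = Phi^m - Phi^{m+1}; constant input returns 0.
    """
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1))
    r = r_coef * sd
    if r == 0.0:
        return 0.0

    def phi(mm: int) -> float:
        n_vec = n - mm + 1
        vecs = [x[i:i + mm] for i in range(n_vec)]
        total = 0.0
        for i in range(n_vec):
            count = 0
            for j in range(n_vec):
                d = max(abs(a - b) for a, b in zip(vecs[i], vecs[j]))
                if d <= r:
                    count += 1
            total += math.log(count / n_vec)
        return total / n_vec

    return phi(m) - phi(m + 1)


def entropy_bits(labels: Sequence[str]) -> float:
    n = len(labels)
    return -sum(
        (c / n) * math.log2(c / n) for c in Counter(labels).values()
    )


def gain_ratio(
    xs: Sequence[float], ys: Sequence[str], threshold: float
) -> float:
    """Gain ratio of the binary split x <= threshold, from the formulas."""
    left = [y for x, y in zip(xs, ys) if x <= threshold]
    right = [y for x, y in zip(xs, ys) if x > threshold]
    n = len(ys)
    if not left or not right:
        return float("-inf")
    gain = (
        entropy_bits(ys)
        - (len(left) / n) * entropy_bits(left)
        - (len(right) / n) * entropy_bits(right)
    )
    pl = len(left) / n
    split_info = -(pl * math.log2(pl) + (1 - pl) * math.log2(1 - pl))
    return gain / split_info


def best_split_exhaustive(
    columns: dict[str, Sequence[float]],
    ys: Sequence[str],
    min_leaf: int = 2,
) -> tuple[float, str, float] | None:
    """Exhaustive search over every (feature, midpoint threshold) candidate.

    Returns (gain_ratio, feature, threshold) of the best positive-gain
    split, preferring earlier feature names and lower thresholds on ties,
    or None when no candidate has positive information gain.
    """
    best = None
    n = len(ys)
    for name in sorted(columns):
        xs = list(columns[name])
        values = sorted(set(xs))
        for a, b in zip(values, values[1:]):
            t = (a + b) / 2.0
            n_left = sum(1 for x in xs if x <= t)
            if n_left < min_leaf or n - n_left < min_leaf:
                continue
            # positive information gain required
            left = [y for x, y in zip(xs, ys) if x <= t]
            right = [y for x, y in zip(xs, ys) if x > t]
            gain = (
                entropy_bits(ys)
                - (len(left) / n) * entropy_bits(left)
                - (len(right) / n) * entropy_bits(right)
            )
            if gain <= 1e-12:
                continue
            gr = gain_ratio(xs, ys, t)
            if best is None or gr > best[0] + 1e-12:
                best = (gr, name, t)
    return best


#: The classic 14-row two-class weather fixture with numeric encodings
#: (outlook: sunny=0, overcast=1, rain=2; windy: false=0, true=1).
WEATHER_COLUMNS = {
    "humidity": [85, 90, 86, 96, 80, 70, 65, 95, 70, 80, 70, 90, 75, 91],
    "outlook": [0, 0, 1, 2, 2, 2, 1, 0, 0, 2, 0, 1, 1, 2],
    "temperature": [85, 80, 83, 70, 68, 65, 64, 72, 69, 75, 75, 72, 81, 71],
    "windy": [0, 1, 0, 0, 0, 1, 1, 0, 0, 0, 1, 1, 0, 1],
}
WEATHER_PLAY = [
    "no", "no", "yes", "yes", "yes", "no", "yes",
    "no", "yes", "yes", "yes", "yes", "yes", "no",
]
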