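"""Brute-force single-pass reference implementations used only by tests.

Each oracle walks the label sequence once with explicit Python loops and
no shared code with the package, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np


def rle_oracle(labels) -> list[tuple[str, int, int]]:
    """(state, start, length) runs by explicit scan."""
    runs = []
    labels = list(labels)
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        runs.append((str(labels[i]), i, j - i))
        i = j
    return runs


def transition_oracle(labels, a: str, b: str) -> int:
    count = 0
    labels = list(labels)
    for i in range(len(labels) - 1):
        if labels[i] == a and labels[i + 1] == b:
            count += 1
    return count


def bout_metrics_oracle(labels, state: str, epoch_s: float = 5.0):
    durations = [r[2] * epoch_s for r in rle_oracle(labels) if r[0] == state]
    if not durations:
        return 0, float("nan")
    return len(durations), sum(durations) / len(durations)


def interbout_oracle(labels, state: str, epoch_s: float = 5.0) -> float:
    """Mean gap between successive runs of `state` (no window/phase
    restriction; valid when the whole sequence sits inside one phase)."""
    runs = [r for r in rle_oracle(labels) if r[0] == state]
    if len(runs) < 2:
        return float("nan")
    gaps = []
    for (_, s1, n1), (_, s2, _) in zip(runs[:-1], runs[1:]):
        gaps.append((s2 - (s1 + n1)) * epoch_s)
    return sum(gaps) / len(gaps)


def percent_oracle(labels, state: str) -> float:
    labels = list(labels)
    return 100.0 * sum(1 for lab in labels if lab == state) / len(labels)


def anova_f_oracle(g1, g2) -> float:
    """Two-group one-way ANOVA F by the sums-of-squares definition."""
    g1, g2 = np.asarray(g1, float), np.asarray(g2, float)
    n1, n2 = len(g1), len(g2)
    grand = np.concatenate([g1, g2]).mean()
    ss_between = n1 * (g1.mean() - grand) ** 2 + n2 * (g2.mean() - grand) ** 2
    ss_within = ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
    if ss_within == 0:
        return float("inf") if ss_between > 0 else 0.0
    return (ss_between / 1.0) / (ss_within / (n1 + n2 - 2))


def r2_two_predictors(y, x1, x2) -> float:
    """Multiple R^2 of y on (x1, x2) with intercept, via the correlation
    matrix closed form."""
    r_y1 = np.corrcoef(y, x1)[0, 1]
    r_y2 = np.corrcoef(y, x2)[0, 1]
    r_12 = np.corrcoef(x1, x2)[0, 1]
    return (r_y1**2 + r_y2**2 - 2 * r_y1 * r_y2 * r_12) / (1 - r_12**2)
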