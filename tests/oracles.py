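"""Independent brute-force oracles used only by the test suite.

These deliberately use naive explicit loops over the defining formulas so
they share no code path with the package implementations they check.
"""
from __future__ import annotations

import math

import numpy as np


def itc_loop(coeffs: np.ndarray) -> np.ndarray:
    """Naive per-trial loop ITC over a (trials, ch, f, t) coefficient tensor."""
    n_trials, n_ch, n_f, n_t = coeffs.shape
    out = np.zeros((n_ch, n_f, n_t))
    for c in range(n_ch):
        for f in range(n_f):
            for t in range(n_t):
                acc = 0.0 + 0.0j
                count = 0
                for i in range(n_trials):
                    z = coeffs[i, c, f, t]
                    m = abs(z)
                    if m > 0:
                        acc += z / m
                        count += 1
                out[c, f, t] = abs(acc) / count if count else 0.0
    return out


def ersp_loop(coeffs: np.ndarray, times: np.ndarray, valid: np.ndarray,
              baseline_window: tuple[float, float],
              sampling_rate: float) -> np.ndarray:
    """Naive per-trial loop ERSP (dB vs. mean baseline power)."""
    n_trials, n_ch, n_f, n_t = coeffs.shape
    eps = 0.25 / sampling_rate
    base_idx = [t for t in range(n_t)
                if baseline_window[0] - eps <= times[t]
                <= baseline_window[1] + eps]
    out = np.zeros((n_ch, n_f, n_t))
    for c in range(n_ch):
        for f in range(n_f):
            power = np.zeros(n_t)
            for t in range(n_t):
                s = 0.0
                for i in range(n_trials):
                    s += abs(coeffs[i, c, f, t]) ** 2
                power[t] = s / n_trials
            use = [t for t in base_idx if valid[f, t]]
            baseline = sum(power[t] for t in use) / len(use)
            for t in range(n_t):
                out[c, f, t] = 10.0 * math.log10(power[t] / baseline)
    return out


def rm_anova_2way_loop(values: dict) -> dict:
    """Brute-force SS decomposition for a balanced two-way within design.

    ``values`` maps (subject, a_level, b_level) -> value.  Returns per-effect
    (F, df1, df2) using explicit loops over the cell-mean formulas.
    """
    subjects = sorted({k[0] for k in values})
    la = sorted({k[1] for k in values})
    lb = sorted({k[2] for k in values})
    n, a, b = len(subjects), len(la), len(lb)
    grand = sum(values.values()) / (n * a * b)

    def mean_s(s):
        return sum(values[(s, x, y)] for x in la for y in lb) / (a * b)

    def mean_a(x):
        return sum(values[(s, x, y)] for s in subjects for y in lb) / (n * b)

    def mean_b(y):
        return sum(values[(s, x, y)] for s in subjects for x in la) / (n * a)

    def mean_ab(x, y):
        return sum(values[(s, x, y)] for s in subjects) / n

    def mean_as(x, s):
        return sum(values[(s, x, y)] for y in lb) / b

    def mean_bs(y, s):
        return sum(values[(s, x, y)] for x in la) / a

    ss_a = n * b * sum((mean_a(x) - grand) ** 2 for x in la)
    ss_b = n * a * sum((mean_b(y) - grand) ** 2 for y in lb)
    ss_ab = n * sum((mean_ab(x, y) - mean_a(x) - mean_b(y) + grand) ** 2
                    for x in la for y in lb)
    ss_as = b * sum((mean_as(x, s) - mean_a(x) - mean_s(s) + grand) ** 2
                    for x in la for s in subjects)
    ss_bs = a * sum((mean_bs(y, s) - mean_b(y) - mean_s(s) + grand) ** 2
                    for y in lb for s in subjects)
    ss_res = sum((values[(s, x, y)] - mean_ab(x, y) - mean_as(x, s)
                  - mean_bs(y, s) + mean_a(x) + mean_b(y) + mean_s(s)
                  - grand) ** 2
                 for s in subjects for x in la for y in lb)

    def f_of(ss_eff, df_eff, ss_err, df_err):
        return (ss_eff / df_eff) / (ss_err / df_err)

    return {
        "a": (f_of(ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
              a - 1, (a - 1) * (n - 1)),
        "b": (f_of(ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
              b - 1, (b - 1) * (n - 1)),
        "ab": (f_of(ss_ab, (a - 1) * (b - 1), ss_res,
                    (a - 1) * (b - 1) * (n - 1)),
               (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1)),
    }


def rm_anova_1way_loop(values: dict) -> tuple[float, int, int]:
    """Brute-force one-way within-subject F; values[(subject, level)]."""
    subjects = sorted({k[0] for k in values})
    levels = sorted({k[1] for k in values})
    n, b = len(subjects), len(levels)
    grand = sum(values.values()) / (n * b)
    mean_l = {l: sum(values[(s, l)] for s in subjects) / n for l in levels}
    mean_s = {s: sum(values[(s, l)] for l in levels) / b for s in subjects}
    ss_b = n * sum((mean_l[l] - grand) ** 2 for l in levels)
    ss_err = sum((values[(s, l)] - mean_l[l] - mean_s[s] + grand) ** 2
                 for s in subjects for l in levels)
    F = (ss_b / (b - 1)) / (ss_err / ((b - 1) * (n - 1)))
    return F, b - 1, (b - 1) * (n - 1)


def paired_t_loop(x, y) -> tuple[float, float]:
    """Textbook paired t and two-sided p via the t survival function."""
    from scipy.stats import t as tdist

    d = [a - b for a, b in zip(x, y)]
    n = len(d)
    mean = sum(d) / n
    var = sum((v - mean) ** 2 for v in d) / (n - 1)
    t = mean / math.sqrt(var / n)
    return t, 2 * tdist.sf(abs(t), n - 1)


def rayleigh_p(phases: np.ndarray) -> float:
    """Rayleigh uniformity test p-value (with small-sample correction)."""
    n = len(phases)
    r = abs(np.exp(1j * phases).mean())
    z = n * r ** 2
    return math.exp(-z) * (1 + (2 * z - z ** 2) / (4 * n)
                           - (24 * z - 132 * z ** 2 + 76 * z ** 3 - 9 * z ** 4)
                           / (288 * n ** 2))
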