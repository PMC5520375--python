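"""Independent reference implementations used only to check the package.

Each oracle is deliberately written from first principles (plain loops,
exact rational arithmetic where possible) and shares no code with the
implementation under test.
"""

from __future__ import annotations

import math
from math import comb

import numpy as np


def sw_affine_oracle(a: str, b: str, matrix, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Brute-force Gotoh dynamic program for local alignment with affine gaps.

    A gap of length k costs ``gap_open + k * gap_extend``. Returns the
    optimal local score (zero floor).
    """
    neg = float("-inf")
    open_cost = gap_open + gap_extend
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]  # best ending in a match column
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in sequence a
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in sequence b
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_cost, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - open_cost, F[i - 1][j] - gap_extend)
            diag = max(H[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1])
            H[i][j] = max(0.0, diag + matrix[a[i - 1], b[j - 1]])
            best = max(best, H[i][j], E[i][j], F[i][j])
    return best


def fisher_right_enum(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail Fisher p by exhaustive enumeration with exact integers."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if n == 0:
        return 1.0
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    denom = comb(n, col1)
    numer = sum(comb(row1, x) * comb(n - row1, col1 - x) for x in range(max(a, lo), hi + 1))
    return numer / denom


def bh_stepup_direct(p_values) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up written from the definition."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        candidate = min(p[idx] * m / rank_from_top, 1.0)
        running_min = min(running_min, candidate)
        adj[idx] = running_min
    return adj


def harmonic_grid_fit(t, y, period: float = 24.0, phase_step: float = 0.01):
    """Grid-search harmonic fit: scan peak phase, solve trend+amplitude by LS.

    For each candidate phase the model ``b0 + b1*t + A*cos(w*(t - phi))`` is
    linear in ``(b0, b1, A)``; the phase minimising the residual sum of
    squares wins. Returns (phase, amplitude).
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    w = 2.0 * np.pi / period
    best = (np.inf, np.nan, np.nan)
    for phi in np.arange(0.0, period, phase_step):
        X = np.column_stack([np.ones_like(t), t, np.cos(w * (t - phi))])
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        if rss < best[0]:
            best = (rss, phi, beta[2])
    _, phi, amp = best
    if amp < 0:  # equivalent solution half a period away
        phi = (phi + period / 2.0) % period
        amp = -amp
    return phi, amp


def circ_corr_direct(phases_a, phases_b, period: float = 24.0) -> float:
    """Direct loop evaluation of the angular correlation coefficient."""
    a = [2.0 * math.pi * p / period for p in phases_a]
    b = [2.0 * math.pi * p / period for p in phases_b]
    n = len(a)
    abar = math.atan2(sum(math.sin(x) for x in a) / n, sum(math.cos(x) for x in a) / n)
    bbar = math.atan2(sum(math.sin(x) for x in b) / n, sum(math.cos(x) for x in b) / n)
    num = sum(math.sin(a[i] - abar) * math.sin(b[i] - bbar) for i in range(n))
    den_a = sum(math.sin(x - abar) ** 2 for x in a)
    den_b = sum(math.sin(x - bbar) ** 2 for x in b)
    return num / math.sqrt(den_a * den_b)


#: Published central Savitzky-Golay coefficients for window 5, degree 2.
SG_5_2_COEFFS = np.array([-3.0, 12.0, 17.0, 12.0, -3.0]) / 35.0
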