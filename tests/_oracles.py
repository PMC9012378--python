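"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle is deliberately naive (exact integer arithmetic, explicit
double loops, exhaustive pair counting) and shares no code with the
library paths it checks.
"""

from __future__ import annotations

import math

import numpy as np

MISSING = -1


def hwe_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE p-value by full enumeration with integer weights.

    The conditional probability of h heterozygotes given the allele
    counts is proportional to the integer 2^h * multinomial(n; r, h, c);
    summing exact integers makes the <=-observed comparison exact.
    """
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    rare = min(n_a, 2 * n - n_a)
    hets = list(range(rare % 2, rare + 1, 2)) or [0]

    def weight(h: int) -> int:
        r = (rare - h) // 2
        c = n - h - r
        return (2 ** h) * math.factorial(n) // (
            math.factorial(r) * math.factorial(h) * math.factorial(c)
        )

    ws = {h: weight(h) for h in hets}
    w_obs = ws[n_ab]
    return sum(w for w in ws.values() if w <= w_obs) / sum(ws.values())


def auroc_pair_counting(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUROC by exhaustive case-control pair comparison."""
    cases = [s for l, s in zip(labels, scores) if l == 1]
    controls = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for c in cases:
        for k in controls:
            if c > k:
                total += 1.0
            elif c == k:
                total += 0.5
    return total / (len(cases) * len(controls))


def prs_double_loop(dosages: np.ndarray, weights: np.ndarray, mode: str) -> np.ndarray:
    """Naive per-sample PRS: sum mode mean-imputes, average mode skips.

    ``dosages`` is an integer matrix with MISSING sentinels; ``weights``
    the per-variant log-odds.
    """
    n, m = dosages.shape
    col_mean = np.empty(m)
    for j in range(m):
        obs = [dosages[i, j] for i in range(n) if dosages[i, j] != MISSING]
        col_mean[j] = sum(obs) / len(obs)
    out = np.empty(n)
    for i in range(n):
        acc = 0.0
        n_obs = 0
        for j in range(m):
            g = dosages[i, j]
            if g == MISSING:
                if mode == "sum":
                    acc += weights[j] * col_mean[j]
                continue
            acc += weights[j] * g
            n_obs += 1
        out[i] = acc if mode == "sum" else acc / (2 * n_obs)
    return out


def cross_product_or(a: int, b: int, c: int, d: int) -> float:
    """2x2 odds ratio: exposed cases a, exposed controls b, ref cases c, ref controls d."""
    return (a * d) / (b * c)


def pearson_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook squared Pearson correlation, written out longhand."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    cov = ((x - mx) * (y - my)).sum()
    return float(cov * cov / (((x - mx) ** 2).sum() * ((y - my) ** 2).sum()))
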