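"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately written the slow, obvious way (loops, direct
textbook formulas, scipy's generic contingency-table routine) and never calls
into the package, so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def ras_oracle(a: float, b: float) -> float:
    return a / (a + b)


def raf_oracle(a: float, b: float, k: float) -> float:
    return a / (a + k * b)


def normalize_oracle(x: float, hi: float, lo: float) -> float:
    return min(max((x - lo) / (hi - lo), 0.0), 1.0)


def k_oracle(pairs) -> float:
    total = 0.0
    for a, b in pairs:
        total += a / b
    return total / len(pairs)


def bh_oracle(p_values, q: float) -> list[bool]:
    """Benjamini-Hochberg step-up, run literally from the definition."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    k_max = 0
    for rank, i in enumerate(order, start=1):
        if p_values[i] <= rank * q / m:
            k_max = rank
    flags = [False] * m
    for rank, i in enumerate(order, start=1):
        if rank <= k_max:
            flags[i] = True
    return flags


def hwe_oracle(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    n = n_aa + n_ab + n_bb
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1 - p
    expected = [n * p * p, n * 2 * p * q, n * q * q]
    chi2 = sum((o - e) ** 2 / e for o, e in zip((n_aa, n_ab, n_bb), expected))
    return chi2, stats.chi2.sf(chi2, 1)


def pearson_chi2_oracle(table) -> tuple[float, float]:
    """Pearson chi-square via scipy's generic routine, no continuity correction."""
    res = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(res.statistic), float(res.pvalue)


def allele_table(case, control) -> np.ndarray:
    """Collapse genotype triples to the 2x2 allele-count table."""
    (caa, cab, cbb), (uaa, uab, ubb) = case, control
    return np.array([[2 * caa + cab, cab + 2 * cbb],
                     [2 * uaa + uab, uab + 2 * ubb]], dtype=float)


def woolf_ci_oracle(a, b, c, d, z: float = 1.96) -> tuple[float, float, float]:
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = (1 / a + 1 / b + 1 / c + 1 / d) ** 0.5
    return or_, np.exp(np.log(or_) - z * se), np.exp(np.log(or_) + z * se)


def trend_oracle(case, control, scores=(0, 1, 2)) -> float:
    """Cochran-Armitage trend chi-square as N times the squared Pearson
    correlation between case status (0/1) and genotype score over individuals,
    evaluated in exact rational arithmetic."""
    from fractions import Fraction

    sx = sxx = sy = sxy = 0
    n = 0
    for s, r, m in zip(scores, case, control):
        s, r, m = int(s), int(r), int(m)
        n += r + m
        sx += s * (r + m)
        sxx += s * s * (r + m)
        sy += r
        sxy += s * r
    num = Fraction(n * sxy - sx * sy) ** 2
    den = Fraction((n * sxx - sx * sx) * (n * sy - sy * sy))
    return float(n * num / den)


def rank_combine_oracle(records) -> list[str]:
    """Brute-force combined ordering: sort tuples of
    (rank_sum, -mean |RAF diff|, snp_id) with average ranks per gender."""
    def avg_ranks(values):
        order = sorted(range(len(values)), key=lambda i: values[i])
        ranks = [0.0] * len(values)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
                j += 1
            mean_rank = (i + j) / 2 + 1
            for t in range(i, j + 1):
                ranks[order[t]] = mean_rank
            i = j + 1
        return ranks

    rf = avg_ranks([r["p_female"] for r in records])
    rm = avg_ranks([r["p_male"] for r in records])
    keys = []
    for i, r in enumerate(records):
        diff = (abs(r["raf_diff_female"]) + abs(r["raf_diff_male"])) / 2
        keys.append((rf[i] + rm[i], -diff, r["snp_id"]))
    return [records[i]["snp_id"] for i in sorted(range(len(records)),
                                                 key=lambda i: keys[i])]
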