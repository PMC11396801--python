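"""Independent brute-force re-implementations used as oracles.

Deliberately naive: explicit Python loops and textbook formulas only, sharing
no code path with the package.  Each function recomputes a statistic from
first principles so the vectorized implementations can be checked to 1e-9.
"""

from __future__ import annotations

import math
from statistics import mean, stdev


def sample_sd(xs) -> float:
    return stdev(xs)


def genorm_m_single_pass(ct_rows: dict[str, list[float]], log_ratio=True) -> dict[str, float]:
    """M_j = mean over k != j of SD_s(log2 Q_j/Q_k); Q rows given directly."""
    genes = list(ct_rows)
    out = {}
    for j in genes:
        sds = []
        for k in genes:
            if k == j:
                continue
            if log_ratio:
                diffs = [
                    math.log2(a) - math.log2(b)
                    for a, b in zip(ct_rows[j], ct_rows[k])
                ]
            else:
                diffs = [a - b for a, b in zip(ct_rows[j], ct_rows[k])]
            sds.append(sample_sd(diffs))
        out[j] = mean(sds)
    return out


def genorm_exclusion_rounds(q_rows: dict[str, list[float]]):
    """Full stepwise geNorm: per-round M dict and the exclusion order."""
    remaining = dict(q_rows)
    rounds = []
    excluded = []
    while len(remaining) > 2:
        m = genorm_m_single_pass(remaining)
        rounds.append(m)
        worst_val = max(m.values())
        worst = max(sorted(g for g, v in m.items() if v == worst_val))
        excluded.append(worst)
        del remaining[worst]
    rounds.append(genorm_m_single_pass(remaining))
    return rounds, excluded


def genorm_v_curve(q_rows: dict[str, list[float]], order: list[str]) -> list[tuple[int, float]]:
    """V(n/n+1) from geometric-mean normalization factors, by enumeration."""
    n_samples = len(next(iter(q_rows.values())))

    def nf(n):
        # geometric mean over the n most stable genes, per sample
        vals = []
        for s in range(n_samples):
            prod = 1.0
            for g in order[:n]:
                prod *= q_rows[g][s]
            vals.append(prod ** (1.0 / n))
        return vals

    curve = []
    for n in range(2, len(order)):
        a, b = nf(n), nf(n + 1)
        ratios = [math.log2(x / y) for x, y in zip(a, b)]
        curve.append((n, sample_sd(ratios)))
    return curve


def delta_ct_scores(ct_rows: dict[str, list[float]]) -> dict[str, float]:
    """Mean over partners of SD of pairwise Ct differences."""
    return genorm_m_single_pass(ct_rows, log_ratio=False)


def bestkeeper_stats(ct_rows: dict[str, list[float]]) -> dict[str, tuple[float, float]]:
    """Per gene: (sample SD, CV% = 100*SD/mean)."""
    out = {}
    for g, xs in ct_rows.items():
        sd = sample_sd(xs)
        out[g] = (sd, 100.0 * sd / mean(xs))
    return out


def geometric_mean_ranks(rank_rows: dict[str, list[float]]) -> dict[str, float]:
    """Product-and-root composite rank per gene."""
    out = {}
    for g, ranks in rank_rows.items():
        prod = 1.0
        for r in ranks:
            prod *= r
        out[g] = prod ** (1.0 / len(ranks))
    return out


def pearson_r(xs, ys) -> float:
    mx, my = mean(xs), mean(ys)
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    den = math.sqrt(sum((x - mx) ** 2 for x in xs) * sum((y - my) ** 2 for y in ys))
    return num / den


def welch_t_p(a, b) -> float:
    """Two-sided Welch t-test p-value via the t-distribution CDF."""
    from scipy.stats import t as tdist  # distribution lookup only

    na, nb = len(a), len(b)
    va, vb = stdev(a) ** 2, stdev(b) ** 2
    se2 = va / na + vb / nb
    tstat = (mean(a) - mean(b)) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2.0 * tdist.sf(abs(tstat), df)
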