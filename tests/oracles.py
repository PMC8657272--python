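"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is written from the definitions, deliberately avoiding the
package's own implementations and vectorized shortcuts.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import binom


def bh_stepup(pvals):
    """Direct BH step-up: q_i = min over j>=rank(i) of p_(j) * m / j."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running_min = float("inf")
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        q[i] = min(running_min, 1.0)
    return q


def conditional_binomial_p(counts_a, counts_b):
    """Two-sided conditional binomial test (equal library sizes)."""
    sa = int(round(sum(counts_a)))
    sb = int(round(sum(counts_b)))
    s = sa + sb
    if s == 0:
        return 1.0
    prop = len(counts_a) / (len(counts_a) + len(counts_b))
    probs = binom.pmf(np.arange(s + 1), s, prop)
    p_obs = probs[sa]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-10)].sum() / probs.sum()))


def tmm_by_hand(counts, lib_sizes, trim_m=0.30, trim_a=0.05):
    """Step-by-step TMM over a small matrix (features x samples), plain Python.

    Reference sample: upper-quartile CPM closest to the mean upper quartile.
    Per sample: M/A over doubly-positive features, double-sided trimming by
    rank, inverse-variance-weighted mean of surviving M, 2**f, then rescale to
    geometric mean one.
    """
    counts = [list(map(float, row)) for row in counts]
    n_feat = len(counts)
    n_samp = len(counts[0])
    lib = list(map(float, lib_sizes))
    uq = []
    for j in range(n_samp):
        col = sorted(counts[i][j] / lib[j] for i in range(n_feat))
        uq.append(float(np.quantile(col, 0.75)))
    mean_uq = sum(uq) / n_samp
    ref = min(range(n_samp), key=lambda j: (abs(uq[j] - mean_uq), j))

    def rank_avg(values):
        order = sorted(range(len(values)), key=lambda i: values[i])
        ranks = [0.0] * len(values)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    log_f = [0.0] * n_samp
    for j in range(n_samp):
        if j == ref:
            continue
        ms, as_, ws = [], [], []
        for i in range(n_feat):
            o, r = counts[i][j], counts[i][ref]
            if o > 0 and r > 0:
                ms.append(math.log2((o / lib[j]) / (r / lib[ref])))
                as_.append(0.5 * math.log2((o / lib[j]) * (r / lib[ref])))
                v = (lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r)
                ws.append(1.0 / v)
        if not ms or max(abs(m) for m in ms) < 1e-6:
            continue
        n = len(ms)
        lo_m = math.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rm = rank_avg(ms)
        ra = rank_avg(as_)
        num = den = 0.0
        for i in range(n):
            if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
                num += ms[i] * ws[i]
                den += ws[i]
        if den > 0:
            log_f[j] = num / den
    factors = [2.0 ** f for f in log_f]
    gm = math.exp(sum(math.log(f) for f in factors) / n_samp)
    return [f / gm for f in factors]


def running_sum_es(ranking, gene_set):
    """Unweighted enrichment score by literal running-sum enumeration."""
    hits = [g in gene_set for g in ranking]
    k = sum(hits)
    n = len(ranking)
    from fractions import Fraction

    inc = Fraction(1, k)
    dec = Fraction(1, n - k)
    cur = Fraction(0)
    hi = lo = Fraction(0)
    for h in hits:
        cur += inc if h else -dec
        hi = max(hi, cur)
        lo = min(lo, cur)
    # equal-magnitude deviations break toward the positive extremum
    best = hi if hi >= -lo else lo
    return best.numerator / best.denominator


def logrank_by_hand(times, events, high):
    """O/E/variance tabulation over distinct event times, plain loops."""
    rows = sorted(zip(times, events, high))
    event_times = sorted({t for t, e, _ in rows if e == 1})
    o1 = e1 = o2 = e2 = var = 0.0
    for et in event_times:
        n1 = sum(1 for t, _e, h in rows if t >= et and h)
        n2 = sum(1 for t, _e, h in rows if t >= et and not h)
        n = n1 + n2
        d1 = sum(1 for t, e, h in rows if t == et and e == 1 and h)
        d2 = sum(1 for t, e, h in rows if t == et and e == 1 and not h)
        d = d1 + d2
        o1 += d1
        o2 += d2
        e1 += d * n1 / n
        e2 += d * n2 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    chisq = (o1 - e1) ** 2 / var if var > 0 else 0.0
    hr = (o1 / e1) / (o2 / e2) if e1 > 0 and e2 > 0 and o2 > 0 else float("nan")
    return o1, o2, e1, e2, var, chisq, hr


def enumerate_utr_nucleotides(blocks, strand):
    """Genomic position of every UTR nucleotide in transcript (5'->3') order.

    ``blocks`` must already be in transcript order (ascending genomic start
    for plus strand, descending for minus).
    """
    positions = []
    for s, e in blocks:
        if strand == "+":
            positions.extend(range(s, e))
        else:
            positions.extend(range(e - 1, s - 1, -1))
    return positions


def intervals_from_positions(chrom, positions):
    """Collapse an ordered nucleotide walk into (chrom, start, end) intervals."""
    out = []
    run = [positions[0], positions[0]]
    direction = 0
    for p in positions[1:]:
        step = p - run[1]
        if step in (-1, 1) and (direction in (0, step)):
            run[1] = p
            direction = step
        else:
            out.append(run)
            run = [p, p]
            direction = 0
    out.append(run)
    return [(chrom, min(a, b), max(a, b) + 1) for a, b in out]
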