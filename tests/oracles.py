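"""Independent reference implementations used only by the tests.

These deliberately re-derive results through a different route than the
package (distance rules instead of interval construction, explicit
enumeration instead of closed forms) so they can serve as oracles.
"""

from __future__ import annotations

from math import comb

import numpy as np

# precedence used by the brute-force scanner; must match the documented
# ordering, not the package internals
_PREC = {"EXON": 1, "INTRON": 2, "P250": 3, "P1K": 4, "P5K": 5, "FLANK": 6,
         "IGR": 7}
_BY_RANK = {v: k for k, v in _PREC.items()}


def brute_force_labels(models, chrom, length):
    """Per-base labels on one chromosome from strand-aware distance rules.

    For every position and gene: exon membership wins, then intron
    (inside the mRNA span but not an exon), then the upstream distance u
    from the TSS mapped to P250 (1..250), P1K (251..1000), P5K
    (1001..5000), then any position within 10 kb of the mRNA span.  The
    lowest precedence rank across genes wins.
    """
    pos = np.arange(1, length + 1)
    rank = np.full(length, _PREC["IGR"], dtype=np.int8)
    for m in models.values():
        if m.chrom != chrom:
            continue
        in_span = (pos >= m.mrna_start) & (pos <= m.mrna_end)
        in_exon = np.zeros(length, dtype=bool)
        for s, e in m.exons:
            in_exon |= (pos >= s) & (pos <= e)
        u = (m.tss - pos) if m.strand == "+" else (pos - m.tss)
        near = (pos >= m.mrna_start - 10000) & (pos <= m.mrna_end + 10000)
        g_rank = np.full(length, _PREC["IGR"], dtype=np.int8)
        g_rank[near & ~in_span] = _PREC["FLANK"]
        g_rank[(u >= 1001) & (u <= 5000)] = np.minimum(
            g_rank[(u >= 1001) & (u <= 5000)], _PREC["P5K"]
        )
        g_rank[(u >= 251) & (u <= 1000)] = np.minimum(
            g_rank[(u >= 251) & (u <= 1000)], _PREC["P1K"]
        )
        g_rank[(u >= 1) & (u <= 250)] = np.minimum(
            g_rank[(u >= 1) & (u <= 250)], _PREC["P250"]
        )
        g_rank[in_span & ~in_exon] = _PREC["INTRON"]
        g_rank[in_exon] = _PREC["EXON"]
        rank = np.minimum(rank, g_rank)
    return np.array([_BY_RANK[int(r)] for r in rank], dtype=object)


def hypergeom_tail_enumerated(k, n_universe, set_size, study_size):
    """P(overlap >= k) by explicit enumeration over all outcomes."""
    total = comb(n_universe, study_size)
    acc = 0
    for x in range(k, min(set_size, study_size) + 1):
        acc += comb(set_size, x) * comb(n_universe - set_size, study_size - x)
    return acc / total


def brute_force_es(stats_desc, member_flags, weight=1.0):
    """Running-sum enrichment score computed step by step."""
    n = len(stats_desc)
    m = sum(member_flags)
    if m == 0 or m == n:
        return 0.0
    from math import fsum

    denom = fsum(abs(s) ** weight for s, h in zip(stats_desc, member_flags) if h)
    best, run = 0.0, 0.0
    for s, h in zip(stats_desc, member_flags):
        if h:
            run += (abs(s) ** weight) / denom if denom > 0 else 1.0 / m
        else:
            run -= 1.0 / (n - m)
        if abs(run) > abs(best):
            best = run
    return best


def bh_by_hand(pvals):
    """Benjamini-Hochberg step-up, written the long way."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    q = [0.0] * n
    prev = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        val = min(prev, pvals[i] * n / (rank_idx + 1))
        q[i] = val
        prev = val
    return q
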