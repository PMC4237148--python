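"""Independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

import itertools
import math

import numpy as np


def wc_theta_longhand(dosage_by_pop):
    """Scalar longhand Weir-Cockerham (1984) variance components for one locus.

    ``dosage_by_pop`` is a list of per-population dosage lists.
    Returns (a, b, c).
    """
    r = len(dosage_by_pop)
    n = [len(d) for d in dosage_by_pop]
    p = [sum(d) / (2 * len(d)) for d in dosage_by_pop]
    h = [sum(1 for x in d if x == 1) / len(d) for d in dosage_by_pop]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni * ni for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def manhattan_matrix_bruteforce(dosage, codes, n_pops):
    """Mean pairwise Manhattan distance by exhaustive pair enumeration."""
    out = np.zeros((n_pops, n_pops))
    for i in range(n_pops):
        for j in range(n_pops):
            rows_i = np.flatnonzero(codes == i)
            rows_j = np.flatnonzero(codes == j)
            dists = []
            for a in rows_i:
                for b in rows_j:
                    if i == j and b <= a:
                        continue
                    dists.append(np.abs(dosage[a] - dosage[b]).sum())
            out[i, j] = np.mean(dists) if dists else np.nan
    return out


def poisson_binomial_tail_enum(probs, k):
    """P(X >= k) by exhaustive enumeration over all 2^L outcomes (L <= ~15)."""
    total = 0.0
    L = len(probs)
    for bits in itertools.product([0, 1], repeat=L):
        if sum(bits) >= k:
            pr = 1.0
            for b, p in zip(bits, probs):
                pr *= p if b else (1 - p)
            total += pr
    return total


def fisher_two_tailed_enum(k, n, K, N):
    """Two-tailed Fisher p by hypergeometric enumeration.

    Table [[k, n-k], [K-k, N-n-(K-k)]] with the candidate column drawn
    from N balls of which K carry the term; sums P(X = i) over all i
    whose point probability does not exceed that of the observed table.
    """
    def pmf(i):
        return (
            math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
        )

    lo = max(0, n - (N - K))
    hi = min(n, K)
    p_obs = pmf(k)
    return sum(pmf(i) for i in range(lo, hi + 1) if pmf(i) <= p_obs * (1 + 1e-9))


def interval_links_bruteforce(loci, genes, window):
    """O(L*G) SNP-to-gene linkage by explicit gap computation.

    Gap = number of bases strictly between the SNP and the gene span
    (0 when the SNP touches or lies inside the span); linked iff
    gap <= window.
    """
    links = {}
    for lr in loci.itertuples():
        hit = set()
        for gr in genes.itertuples():
            if gr.contig != lr.contig:
                continue
            if lr.pos < gr.start:
                gap = gr.start - lr.pos - 1
            elif lr.pos > gr.end:
                gap = lr.pos - gr.end - 1
            else:
                gap = 0
            if gap <= window:
                hit.add(gr.gene)
        links[lr.id] = hit
    return links


def mann_whitney_u_enum(x, y):
    """Exact two-sided Mann-Whitney p by enumeration over label assignments."""
    m, n = len(x), len(y)
    combined = list(x) + list(y)
    obs_u = sum(1 for xi in x for yj in y if xi > yj) + 0.5 * sum(
        1 for xi in x for yj in y if xi == yj
    )
    us = []
    for subset in itertools.combinations(range(m + n), m):
        xs = [combined[i] for i in subset]
        ys = [combined[i] for i in range(m + n) if i not in subset]
        u = sum(1 for xi in xs for yj in ys if xi > yj) + 0.5 * sum(
            1 for xi in xs for yj in ys if xi == yj
        )
        us.append(u)
    us = np.array(us)
    lower = (us <= obs_u + 1e-12).mean()
    upper = (us >= obs_u - 1e-12).mean()
    return min(1.0, 2 * min(lower, upper))
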