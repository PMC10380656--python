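"""Shared hand-built fixtures and brute-force oracles for the test suite."""

import itertools
import math

import numpy as np

from svaexo.core_io import GenomicInterval, TranscriptModel


def make_transcript(
    transcript_id="TX1",
    chrom="chr1",
    strand="+",
    exons=((100, 300), (400, 600), (700, 900)),
    cds=(200, 800),
    biotype="protein_coding",
    gene_id=None,
):
    """Hand-built toy transcript; cds=None makes it non-coding."""
    return TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id or f"G_{transcript_id}",
        gene_name=f"g_{transcript_id}",
        strand=strand,
        exons=tuple(GenomicInterval(chrom, a, b, strand) for a, b in exons),
        cds_span=GenomicInterval(chrom, *cds, strand) if cds else None,
        biotype=biotype,
    )


def fisher_enumeration(table):
    """Two-sided Fisher exact p by explicit enumeration of all tables with
    the observed margins (no hypergeometric shortcuts)."""
    (a, b), (c, d) = table
    n, r1, c1 = a + b + c + d, a + b, a + c

    def prob(k):
        return (
            math.comb(r1, k)
            * math.comb(n - r1, c1 - k)
            / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for k in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        pk = prob(k)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


def rank_sum_enumeration(a, b):
    """Exact two-sided rank-sum p by enumerating every group assignment of
    the pooled (untied) sample: fraction of assignments whose U statistic
    deviates from its null mean at least as much as observed."""
    pooled = sorted(a) + sorted(b)
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    na, nb = len(a), len(b)
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}

    def u_of(group):
        r = sum(ranks[v] for v in group)
        return r - na * (na + 1) / 2

    mu = na * nb / 2
    dev_obs = abs(u_of(a) - mu)
    hits = total = 0
    for combo in itertools.combinations(pooled, na):
        total += 1
        if abs(u_of(combo) - mu) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def bh_step_up(pvalues):
    """Hand Benjamini-Hochberg: sort, p(i)*m/i, running minimum from the top."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = min(running, 1.0)
    return adjusted


def assert_replicate_rate(successes, reps, claimed_rate, alpha=0.05):
    """Check a 'holds in >= claimed_rate of replicates' claim with a proper
    one-sided binomial test: fail only when the observed success count is
    significantly below the claimed rate (a hard cut at the claimed rate
    would reject a process exactly at that rate half the time)."""
    from scipy.stats import binom

    tail = binom.cdf(successes, reps, claimed_rate)
    assert tail >= alpha, (
        f"{successes}/{reps} successes is significantly below the claimed "
        f"{claimed_rate:.0%} rate (one-sided binomial tail {tail:.4f})"
    )


def studentized_range_sf_quadrature(q, k, df):
    """P(Q > q) for the studentized range by direct numerical integration
    (independent of scipy.stats.studentized_range)."""
    from scipy import integrate
    from scipy.stats import chi2, norm

    def inner(s):
        def f(z):
            return norm.pdf(z) * (norm.cdf(z) - norm.cdf(z - q * s)) ** (k - 1)

        val, _ = integrate.quad(f, -7, 7, limit=80, epsabs=1e-8)
        return k * val

    def outer(x):
        # x = chi2_df value; s = sqrt(x / df)
        return chi2.pdf(x, df) * inner(np.sqrt(x / df))

    cdf, _ = integrate.quad(
        outer, 1e-9, chi2.ppf(1 - 1e-9, df), limit=60, epsabs=1e-7
    )
    return 1.0 - cdf
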