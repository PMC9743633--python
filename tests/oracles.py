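"""Brute-force oracles, independent of the library code they check.

Everything here is written the slow, obviously-correct way: exact rational
hypergeometric enumeration, exhaustive rank assignments, per-element scans.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def fisher_enum(a: int, b: int, c: int, d: int,
                alternative: str = "two-sided") -> float:
    """Fisher exact p by full hypergeometric enumeration in exact rationals."""
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)

    def prob(k: int) -> Fraction:
        return Fraction(comb(r1, k) * comb(n - r1, c1 - k), comb(n, c1))

    p_obs = prob(a)
    if alternative == "greater":
        total = sum(prob(k) for k in range(a, hi + 1))
    elif alternative == "less":
        total = sum(prob(k) for k in range(lo, a + 1))
    else:
        total = sum(p for k in range(lo, hi + 1)
                    if (p := prob(k)) <= p_obs * (1 + Fraction(1, 10**7)))
    return float(min(total, Fraction(1)))


def chi2_stat_closed_form(a: int, b: int, c: int, d: int) -> float:
    """Uncorrected Pearson statistic via N(ad-bc)^2 / product of margins."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    return n * (a * d - b * c) ** 2 / denom


def ranksum_enum(x, y, alternative: str = "two-sided") -> float:
    """Exact Mann-Whitney p by enumerating every rank assignment.

    Assumes no ties. Two-sided p is 2 * min(P(U <= u), P(U >= u)) capped
    at 1, matching the exact-method convention.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    assert len(np.unique(pooled)) == nx + ny, "oracle requires no ties"
    ranks = np.argsort(np.argsort(pooled)) + 1
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    us = []
    for idx in combinations(range(nx + ny), nx):
        r = sum(i + 1 for i in idx)
        us.append(r - nx * (nx + 1) / 2)
    us = np.asarray(us, float)
    p_ge = np.mean(us >= u_obs)
    p_le = np.mean(us <= u_obs)
    if alternative == "greater":
        return float(p_ge)
    if alternative == "less":
        return float(p_le)
    return float(min(1.0, 2 * min(p_ge, p_le)))


def ranksum_perm(x, y, rng: np.random.Generator, n_perm: int = 100_000) -> float:
    """Monte-Carlo permutation p (two-sided, midrank statistic) for tied data."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx = len(x)
    pooled = np.concatenate([x, y])
    from scipy.stats import rankdata
    ranks = rankdata(pooled)
    obs = ranks[:nx].sum()
    mean = nx * (len(pooled) + 1) / 2
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(ranks)
        if abs(perm[:nx].sum() - mean) >= abs(obs - mean) - 1e-9:
            count += 1
    return count / n_perm


def classify_brute(cohort, genes, tags):
    """Per-copy ancestry labels by a literal scan over every tag SNP.

    Returns {(sample, gene_id, chrom, copy): (label, n_matching,
    somatic_count)}; samples with no observed tag genotype at a gene are
    absent, mirroring the exclusion contract.
    """
    out = {}
    for gene in genes:
        gene_tags = []
        for t in tags:
            if t.chrom != gene.chrom or not (gene.start <= t.pos < gene.end):
                continue
            for j, s in enumerate(cohort.sites):
                if (s.chrom, s.pos) == (t.chrom, t.pos):
                    if t.archaic_allele == s.ref:
                        gene_tags.append((j, 0))
                    elif t.archaic_allele == s.alt:
                        gene_tags.append((j, 1))
        if not gene_tags:
            continue
        span = [j for j, s in enumerate(cohort.sites)
                if s.chrom == gene.chrom and gene.start <= s.pos < gene.end]
        for i, sample in enumerate(cohort.samples):
            observed = any(cohort.genotypes[i, j, copy] >= 0
                           for j, _ in gene_tags for copy in (0, 1))
            if not observed:
                continue
            for copy in (0, 1):
                n_match = sum(1 for j, code in gene_tags
                              if cohort.genotypes[i, j, copy] == code)
                som = sum(1 for j in span if cohort.somatic_flags[i, j, copy])
                label = "neanderthal" if n_match >= 1 else "modern"
                out[(sample, gene.gene_id, gene.chrom, copy)] = (label, n_match, som)
    return out


def carriers_brute(cohort, tags, genes):
    """{(gene_id, chrom): (n_carrier, n_total)} by per-sample scanning."""
    out = {}
    for gene in genes:
        gene_tags = []
        for t in tags:
            if t.chrom != gene.chrom or not (gene.start <= t.pos < gene.end):
                continue
            for j, s in enumerate(cohort.sites):
                if (s.chrom, s.pos) == (t.chrom, t.pos):
                    code = 0 if t.archaic_allele == s.ref else (
                        1 if t.archaic_allele == s.alt else None)
                    if code is not None:
                        gene_tags.append((j, code))
        if not gene_tags:
            continue
        n_total = n_carrier = 0
        for i in range(cohort.n_samples):
            alleles = [cohort.genotypes[i, j, copy]
                       for j, _ in gene_tags for copy in (0, 1)]
            if all(a < 0 for a in alleles):
                continue
            n_total += 1
            if any(cohort.genotypes[i, j, copy] == code
                   for j, code in gene_tags for copy in (0, 1)):
                n_carrier += 1
        out[(gene.gene_id, gene.chrom)] = (n_carrier, n_total)
    return out


def intersect_brute(sites, genes):
    """O(n*m) interval assignment: {gene: sorted site indices}."""
    out = {}
    for gene in genes:
        out[gene] = sorted(i for i, s in enumerate(sites)
                           if s.chrom == gene.chrom
                           and gene.start <= s.pos < gene.end)
    return out
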