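"""Per-gene haplotype classification and somatic-mutation enrichment.

A phased haplotype copy at a gene is called Neanderthal-introgressed when it
carries the archaic allele at one or more tag SNPs inside the gene span; a
copy with tag genotypes observed but no archaic allele is modern. Somatic
mutations are attached to the copy that carries them, a per-gene 2x2 table of
(has somatic) x (Neanderthal/modern) copies feeds a two-sided Fisher exact
test with Bonferroni correction, and a per-individual somatic mutation ratio
contrasts the mutation rate on the two haplotype classes.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats
from .core_io import MISSING, GeneModel, PhasedCohort, assign_sites_to_genes
from .tag_snps import TagSNP

logger = logging.getLogger(__name__)

__all__ = [
    "classify_copies",
    "build_gene_contingency",
    "test_gene_enrichment",
    "somatic_mutation_ratios",
    "cohort_rate_comparison",
    "somatic_site_table",
]

#: minimum Neanderthal haplotypes at a gene for the enrichment test
MIN_NEA_HAPLOTYPES = 5

CALL_COLUMNS = ["sample", "gene_id", "chrom", "copy", "label", "n_tag_sites",
                "n_matching", "somatic_count", "has_somatic", "gene_length"]


def _tag_codes_for_gene(cohort: PhasedCohort, gene: GeneModel,
                        tags: Sequence[TagSNP],
                        site_idx: Mapping[tuple[str, int], int]) -> tuple[list[int], list[int]]:
    """Cohort site indices of the gene's tag SNPs and the genotype code
    (0=ref, 1=alt) that corresponds to the archaic allele at each."""
    idxs: list[int] = []
    codes: list[int] = []
    for t in tags:
        if t.chrom != gene.chrom or not (gene.start <= t.pos < gene.end):
            continue
        j = site_idx.get((t.chrom, t.pos))
        if j is None:
            continue
        site = cohort.sites[j]
        if t.archaic_allele == site.ref:
            code = 0
        elif t.archaic_allele == site.alt:
            code = 1
        else:
            logger.warning("tag archaic allele %s at %s:%d matches neither cohort "
                           "allele; tag ignored", t.archaic_allele, t.chrom, t.pos + 1)
            continue
        idxs.append(j)
        codes.append(code)
    return idxs, codes


def classify_copies(cohort: PhasedCohort, genes: Iterable[GeneModel],
                    tags: Sequence[TagSNP]) -> tuple[pd.DataFrame, set[tuple[str, str]]]:
    """Label every (sample, gene, copy) as Neanderthal or modern.

    A copy is Neanderthal iff it carries the archaic allele at >= 1 tag site
    within the gene span; with tag sites observed but zero archaic matches it
    is modern. Samples whose genotypes are missing at every tag site of a
    gene are excluded for that gene (absence of evidence). Genes with no tag
    site present in the cohort are returned in the second element (the
    unclassifiable set, keyed (gene_id, chrom)) and their calls — emitted
    with ``n_tag_sites = 0`` and label modern — must not enter enrichment
    testing. ``somatic_count`` tallies somatic flags on the copy across all
    cohort sites inside the gene span.
    """
    site_idx = cohort.site_index()
    gene_sites = assign_sites_to_genes(cohort.sites, genes)
    rows: list[tuple] = []
    unclassifiable: set[tuple[str, str]] = set()
    for gene, span_sites in gene_sites.items():
        tag_idx, codes = _tag_codes_for_gene(cohort, gene, tags, site_idx)
        span = np.asarray(span_sites, dtype=int)
        som = (cohort.somatic_flags[:, span, :].sum(axis=1)
               if span.size else np.zeros((cohort.n_samples, 2), dtype=int))
        if not tag_idx:
            unclassifiable.add(gene.key)
            for i, sample in enumerate(cohort.samples):
                for copy in (0, 1):
                    sc = int(som[i, copy])
                    rows.append((sample, gene.gene_id, gene.chrom, copy, "modern",
                                 0, 0, sc, sc > 0, gene.length))
            continue
        g = cohort.genotypes[:, tag_idx, :]            # (n_samples, k, 2)
        codes_arr = np.asarray(codes, dtype=np.int8)[None, :, None]
        observed = (g != MISSING).sum(axis=1)          # (n_samples, 2)
        matching = ((g == codes_arr) & (g != MISSING)).sum(axis=1)
        for i, sample in enumerate(cohort.samples):
            if observed[i].sum() == 0:
                continue  # no evidence at this gene for this sample
            for copy in (0, 1):
                n_obs = int(observed[i, copy])
                n_match = int(matching[i, copy])
                label = "neanderthal" if n_match >= 1 else "modern"
                sc = int(som[i, copy])
                rows.append((sample, gene.gene_id, gene.chrom, copy, label,
                             n_obs, n_match, sc, sc > 0, gene.length))
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return calls.sort_values(["chrom", "gene_id", "sample", "copy"],
                             ignore_index=True), unclassifiable


def build_gene_contingency(calls: pd.DataFrame) -> tuple[int, int, int, int]:
    """Collapse one gene's calls to (a, b, c, d).

    a/b = Neanderthal copies with/without somatic mutations, c/d likewise for
    modern copies. The unit is the haplotype copy with a binary has-somatic
    indicator: a copy with three somatic mutations still contributes one.
    """
    if calls["gene_id"].nunique() > 1 or calls["chrom"].nunique() > 1:
        raise ValueError("build_gene_contingency expects calls for exactly one gene")
    nea = calls["label"] == "neanderthal"
    som = calls["has_somatic"].astype(bool)
    a = int((nea & som).sum())
    b = int((nea & ~som).sum())
    c = int((~nea & som).sum())
    d = int((~nea & ~som).sum())
    return a, b, c, d


def test_gene_enrichment(calls: pd.DataFrame,
                         min_nea_haplotypes: int = MIN_NEA_HAPLOTYPES,
                         unclassifiable: set[tuple[str, str]] | None = None
                         ) -> pd.DataFrame:
    """Per-gene Fisher exact test of somatic presence vs haplotype ancestry.

    Genes with fewer than ``min_nea_haplotypes`` Neanderthal copies (or in
    the unclassifiable set) are excluded before testing; the Bonferroni
    divisor is the number of genes actually tested. Direction is
    ``"neanderthal"`` when the somatic proportion is higher on introgressed
    copies, ``"modern"`` when lower, ``"none"`` when equal.
    """
    unclassifiable = unclassifiable or set()
    rows = []
    for (gene_id, chrom), sub in calls.groupby(["gene_id", "chrom"], sort=True):
        if (gene_id, chrom) in unclassifiable or (sub["n_tag_sites"] == 0).all():
            continue
        a, b, c, d = build_gene_contingency(sub)
        if a + b < min_nea_haplotypes:
            continue
        res = stats.fisher_exact_2x2(a, b, c, d, alternative="two-sided")
        prop_nea = a / (a + b) if a + b else float("nan")
        prop_mod = c / (c + d) if c + d else float("nan")
        if np.isnan(prop_mod) or prop_nea == prop_mod:
            direction = "none"
        else:
            direction = "neanderthal" if prop_nea > prop_mod else "modern"
        rows.append((gene_id, chrom, a, b, c, d, prop_nea, prop_mod,
                     res.statistic, res.p, direction))
    out = pd.DataFrame(rows, columns=["gene_id", "chrom", "a", "b", "c", "d",
                                      "prop_nea", "prop_mod", "odds_ratio",
                                      "p", "direction"])
    if out.empty:
        logger.warning("no gene passed the >=%d Neanderthal-haplotype filter",
                       min_nea_haplotypes)
        out["p_adj"] = pd.Series(dtype=float)
        return out
    out["p_adj"] = stats.bonferroni(out["p"].to_numpy())
    return out.sort_values("p", ignore_index=True)


def somatic_mutation_ratios(calls: pd.DataFrame,
                            restrict_to_genes: set[tuple[str, str]] | None = None
                            ) -> pd.DataFrame:
    """Per-individual somatic mutation ratio across introgressed genes.

    The ratio is (somatic mutations on the sample's Neanderthal copies over
    their summed gene-span length) divided by the same rate on its modern
    copies. By default genes are restricted to those with at least one
    Neanderthal copy anywhere in the cohort. Samples for which the ratio is
    undefined (no Neanderthal length, no modern length, or zero modern
    mutations) carry NaN and are excluded from summaries.
    """
    calls = calls[calls["n_tag_sites"] > 0]
    if restrict_to_genes is None:
        nea_genes = calls.loc[calls["label"] == "neanderthal", ["gene_id", "chrom"]]
        restrict_to_genes = set(map(tuple, nea_genes.drop_duplicates().to_numpy()))
    if len(calls):
        keep = [(g, c) in restrict_to_genes
                for g, c in zip(calls["gene_id"], calls["chrom"])]
        calls = calls[np.asarray(keep, dtype=bool)]
    rows = []
    for sample, sub in calls.groupby("sample", sort=True):
        nea = sub[sub["label"] == "neanderthal"]
        mod = sub[sub["label"] == "modern"]
        m_nea = int(nea["somatic_count"].sum())
        l_nea = int(nea["gene_length"].sum())
        m_mod = int(mod["somatic_count"].sum())
        l_mod = int(mod["gene_length"].sum())
        rate_nea = m_nea / l_nea * 1e6 if l_nea else float("nan")
        rate_mod = m_mod / l_mod * 1e6 if l_mod else float("nan")
        if l_nea > 0 and l_mod > 0 and m_mod > 0:
            ratio = (m_nea / l_nea) / (m_mod / l_mod)
        else:
            ratio = float("nan")
            logger.info("sample %s: somatic mutation ratio undefined "
                        "(L_nea=%d, L_mod=%d, m_mod=%d)", sample, l_nea, l_mod, m_mod)
        log10_ratio = np.log10(ratio) if ratio and not np.isnan(ratio) else float("nan")
        rows.append((sample, m_nea, l_nea, m_mod, l_mod, rate_nea, rate_mod,
                     ratio, log10_ratio))
    return pd.DataFrame(rows, columns=["sample", "m_nea", "L_nea", "m_mod",
                                       "L_mod", "rate_nea_perMb", "rate_mod_perMb",
                                       "ratio", "log10_ratio"])


def cohort_rate_comparison(ratios: pd.DataFrame, alternative: str = "greater",
                           paired: bool = False) -> dict:
    """Compare per-Mb somatic rates on Neanderthal vs modern haplotypes.

    By default an unpaired one-sided Wilcoxon rank-sum test of whether the
    Neanderthal-haplotype rates exceed the modern-haplotype rates, treating
    the two per-sample rate vectors as independent samples; ``paired=True``
    switches to the Wilcoxon signed-rank test on the per-sample rate pairs.
    """
    sub = ratios.dropna(subset=["rate_nea_perMb", "rate_mod_perMb"])
    nea = sub["rate_nea_perMb"].to_numpy()
    mod = sub["rate_mod_perMb"].to_numpy()
    if len(nea) < 2:
        raise ValueError("need >= 2 samples with defined rates in each class")
    test = (stats.signed_rank(nea, mod, alternative=alternative) if paired
            else stats.rank_sum(nea, mod, alternative=alternative))
    return {
        "n_samples": int(len(sub)),
        "median_rate_nea_perMb": float(np.median(nea)),
        "median_rate_mod_perMb": float(np.median(mod)),
        "test": test,
    }


def somatic_site_table(cohort: PhasedCohort, genes: Iterable[GeneModel],
                       calls: pd.DataFrame) -> pd.DataFrame:
    """One row per somatic mutation: which gene and haplotype copy carries it.

    The copy's ancestry label is joined from ``calls``; mutations in genes or
    samples without a call (unclassifiable gene, all-missing sample) are
    dropped.
    """
    gene_sites = assign_sites_to_genes(cohort.sites, genes)
    rows = []
    for gene, span_sites in gene_sites.items():
        for j in span_sites:
            site = cohort.sites[j]
            hit_samples, hit_copies = np.nonzero(cohort.somatic_flags[:, j, :])
            for i, copy in zip(hit_samples, hit_copies):
                rows.append((cohort.samples[i], gene.gene_id, gene.chrom,
                             site.chrom, site.pos, site.ref, site.alt, int(copy)))
    muts = pd.DataFrame(rows, columns=["sample", "gene_id", "gene_chrom", "chrom",
                                       "pos", "ref", "alt", "copy"])
    labels = calls[["sample", "gene_id", "chrom", "copy", "label"]].rename(
        columns={"chrom": "gene_chrom"})
    return muts.merge(labels, on=["sample", "gene_id", "gene_chrom", "copy"],
                      how="inner")
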