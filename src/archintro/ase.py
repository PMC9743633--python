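"""Allele-specific expression (ASE) of archaic alleles.

Input is an allele-count table (ASEReadCounter-style: one row per sample per
heterozygous site with ref/alt read counts). Each site's Neanderthal-read
fraction is the proportion of reads carrying the archaic allele; fractions
are averaged (unweighted) across a sample's heterozygous tag sites within a
gene, genes with too few heterozygous observations cohort-wide are dropped,
and group comparisons use the Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import stats
from .core_io import GeneModel, PhasedCohort, Site, assign_sites_to_genes
from .tag_snps import TagSNP

logger = logging.getLogger(__name__)

__all__ = ["read_ase_table", "annotate_archaic_allele", "nea_read_fraction",
           "aggregate_gene_ase", "compare_enrichment_groups", "tumor_vs_normal"]

MIN_DEPTH = 10
MIN_HET_SITES_PER_GENE = 5

_ASE_ALIASES = {
    "sample": ("sample", "sample_id"),
    "chrom": ("chrom", "contig", "chr"),
    "pos": ("pos", "position"),
    "ref": ("ref", "refAllele"),
    "alt": ("alt", "altAllele"),
    "refCount": ("refCount", "ref_count"),
    "altCount": ("altCount", "alt_count"),
}


def read_ase_table(path: str | Path, tissue: str | None = None) -> pd.DataFrame:
    """Read an allele-count TSV (GATK ASEReadCounter column names accepted).

    Positions in the file are 1-based and are converted to the internal
    0-based convention. A ``tissue`` column is kept if present, else filled
    from the ``tissue`` argument.
    """
    df = pd.read_csv(path, sep="\t")
    rename = {}
    for logical, aliases in _ASE_ALIASES.items():
        found = next((a for a in aliases if a in df.columns), None)
        if found is None:
            raise ValueError(f"ASE table {path} is missing a '{logical}' column")
        rename[found] = logical
    df = df.rename(columns=rename)
    df["pos"] = df["pos"].astype(int) - 1
    if "tissue" not in df.columns:
        df["tissue"] = tissue if tissue is not None else "unknown"
    keep = ["sample", "chrom", "pos", "ref", "alt", "refCount", "altCount", "tissue"]
    return df[keep]


def annotate_archaic_allele(ase: pd.DataFrame, tags: Sequence[TagSNP]) -> pd.DataFrame:
    """Keep rows at tag-SNP sites and record which observed allele is archaic.

    The archaic allele is matched by base identity against the row's ref/alt
    alleles; rows at non-tag sites, or where neither allele is the archaic
    base, are dropped.
    """
    tag_allele = {(t.chrom, t.pos): t.archaic_allele for t in tags}
    keys = list(zip(ase["chrom"], ase["pos"]))
    archaic = [tag_allele.get(k) for k in keys]
    out = ase.assign(archaic_allele=archaic).dropna(subset=["archaic_allele"])
    is_ref = out["archaic_allele"] == out["ref"]
    is_alt = out["archaic_allele"] == out["alt"]
    out = out[is_ref | is_alt].copy()
    out["nea_allele"] = np.where(out["archaic_allele"] == out["ref"], "ref", "alt")
    return out.reset_index(drop=True)


def nea_read_fraction(ref_count: int, alt_count: int, nea_allele: str) -> float:
    """Fraction of reads supporting the archaic allele at one site."""
    total = ref_count + alt_count
    if total <= 0:
        raise ValueError("site has zero reads")
    nea = ref_count if nea_allele == "ref" else alt_count
    return nea / total


def aggregate_gene_ase(ase: pd.DataFrame, genes: Iterable[GeneModel],
                       min_depth: int = MIN_DEPTH,
                       min_het_sites_per_gene: int = MIN_HET_SITES_PER_GENE,
                       cohort: PhasedCohort | None = None
                       ) -> tuple[pd.DataFrame, set[tuple[str, str]]]:
    """Per-(sample, gene, tissue) mean archaic-read fraction.

    ``ase`` must already carry ``nea_allele`` (see
    :func:`annotate_archaic_allele`). Sites below ``min_depth`` total reads
    are removed first. When a phased ``cohort`` is given, rows are restricted
    to sites heterozygous in that sample's germline (the count table is
    otherwise trusted to contain het sites only). Genes whose heterozygous
    observations, summed across samples, number fewer than
    ``min_het_sites_per_gene`` are dropped from the analysis set. Returns the
    per-gene table and the retained gene-key set.
    """
    df = ase.copy()
    df["total"] = df["refCount"] + df["altCount"]
    df = df[df["total"] >= min_depth]
    if cohort is not None and len(df):
        idx = cohort.site_index()
        sample_pos = {s: i for i, s in enumerate(cohort.samples)}
        het = []
        for sample, chrom, pos in zip(df["sample"], df["chrom"], df["pos"]):
            i = sample_pos.get(sample)
            j = idx.get((chrom, pos))
            if i is None or j is None:
                het.append(False)
                continue
            g = cohort.genotypes[i, j]
            het.append(g[0] != g[1] and g[0] >= 0 and g[1] >= 0)
        df = df[np.asarray(het, dtype=bool)]
    if df.empty:
        return (pd.DataFrame(columns=["sample", "gene_id", "chrom", "tissue",
                                      "nea_fraction", "n_sites"]), set())
    nea_count = np.where(df["nea_allele"] == "ref", df["refCount"], df["altCount"])
    df = df.assign(site_fraction=nea_count / df["total"])
    sites = [Site(c, p, r, a) for c, p, r, a in
             zip(df["chrom"], df["pos"], df["ref"], df["alt"])]
    site_rows: dict[int, list[int]] = {}
    unique_sites = list({s: None for s in sites})
    row_of_site = {s: k for k, s in enumerate(unique_sites)}
    mapping = assign_sites_to_genes(unique_sites, genes)
    rows = []
    site_keys = np.array([row_of_site[s] for s in sites])
    for gene, site_idx in mapping.items():
        if not site_idx:
            continue
        mask = np.isin(site_keys, site_idx)
        sub = df[mask]
        if sub.empty:
            continue
        for (sample, tissue), grp in sub.groupby(["sample", "tissue"], sort=True):
            rows.append((sample, gene.gene_id, gene.chrom, tissue,
                         float(grp["site_fraction"].mean()), int(len(grp))))
    gene_ase = pd.DataFrame(rows, columns=["sample", "gene_id", "chrom", "tissue",
                                           "nea_fraction", "n_sites"])
    het_per_gene = gene_ase.groupby(["gene_id", "chrom"])["n_sites"].sum()
    retained = {k for k, n in het_per_gene.items() if n >= min_het_sites_per_gene}
    if len(gene_ase):
        keep = [(g, c) in retained
                for g, c in zip(gene_ase["gene_id"], gene_ase["chrom"])]
        gene_ase = gene_ase[np.asarray(keep, dtype=bool)].reset_index(drop=True)
    return gene_ase, retained


def compare_enrichment_groups(gene_ase: pd.DataFrame,
                              enriched_genes: set[tuple[str, str]],
                              excluded_genes: set[tuple[str, str]] | None = None
                              ) -> dict:
    """Archaic-read fractions in somatic-enriched vs non-enriched genes.

    Groups the per-(sample, gene) fractions by whether the gene showed a
    somatic-mutation enrichment on Neanderthal haplotypes; ``excluded_genes``
    (e.g. genes enriched on the modern haplotype) belong to neither group.
    Reports medians, IQRs and a two-sided rank-sum p; an empty group yields
    a missing p with a warning.
    """
    excluded_genes = excluded_genes or set()
    keys = list(zip(gene_ase["gene_id"], gene_ase["chrom"]))
    in_enriched = np.array([k in enriched_genes for k in keys])
    in_excluded = np.array([k in excluded_genes for k in keys])
    frac = gene_ase["nea_fraction"].to_numpy()
    enr = frac[in_enriched & ~in_excluded]
    rest = frac[~in_enriched & ~in_excluded]

    def _summ(v: np.ndarray) -> dict:
        if v.size == 0:
            return {"n": 0, "median": float("nan"), "iqr": float("nan")}
        q1, q3 = np.percentile(v, [25, 75])
        return {"n": int(v.size), "median": float(np.median(v)), "iqr": float(q3 - q1)}

    result = {"enriched": _summ(enr), "other": _summ(rest), "test": None}
    if enr.size == 0 or rest.size == 0:
        logger.warning("a comparison group is empty (enriched n=%d, other n=%d); "
                       "no test performed", enr.size, rest.size)
        return result
    result["test"] = stats.rank_sum(enr, rest, alternative="two-sided")
    return result


def tumor_vs_normal(gene_ase_tumor: pd.DataFrame, gene_ase_normal: pd.DataFrame,
                    min_per_group: int = 3) -> pd.DataFrame:
    """Per-gene rank-sum test of archaic-read fraction, tumor vs normal.

    Only genes present in both cohorts are tested (shared-gene rule), and
    only when each cohort contributes at least ``min_per_group`` samples.
    Direction records whether tumor expression is biased toward or away from
    the archaic allele relative to normal. Bonferroni over tested genes.
    """
    rows = []
    t_groups = dict(iter(gene_ase_tumor.groupby(["gene_id", "chrom"], sort=True)))
    n_groups = dict(iter(gene_ase_normal.groupby(["gene_id", "chrom"], sort=True)))
    for key in sorted(set(t_groups) & set(n_groups)):
        tv = t_groups[key]["nea_fraction"].to_numpy()
        nv = n_groups[key]["nea_fraction"].to_numpy()
        if len(tv) < min_per_group or len(nv) < min_per_group:
            continue
        res = stats.rank_sum(tv, nv, alternative="two-sided")
        med_t, med_n = float(np.median(tv)), float(np.median(nv))
        direction = ("toward_nea" if med_t > med_n
                     else "away_from_nea" if med_t < med_n else "none")
        rows.append((key[0], key[1], len(tv), len(nv), med_t, med_n,
                     res.p, direction))
    out = pd.DataFrame(rows, columns=["gene_id", "chrom", "n_tumor", "n_normal",
                                      "median_tumor", "median_normal", "p",
                                      "direction"])
    if out.empty:
        out["p_adj"] = pd.Series(dtype=float)
        return out
    out["p_adj"] = stats.bonferroni(out["p"].to_numpy())
    return out.sort_values("p", ignore_index=True)
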