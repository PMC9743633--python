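"""Case-control comparison of per-gene archaic-carrier proportions.

A sample is a carrier at a gene when it has at least one archaic allele at
any tag SNP overlapping the gene (phase-free — either chromosome counts).
Per gene, a 2x2 table of carrier status x cohort feeds a Pearson chi-square
test (Yates continuity correction on by default, both variants reported)
with Bonferroni correction over the shared tested genes.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import stats
from .core_io import MISSING, GeneModel, PhasedCohort
from .haplotype_analysis import _tag_codes_for_gene
from .core_io import assign_sites_to_genes
from .tag_snps import TagSNP

logger = logging.getLogger(__name__)

__all__ = ["call_carriers", "test_proportions", "shared_tag_sites"]


def shared_tag_sites(cohort_a: PhasedCohort, cohort_b: PhasedCohort,
                     tags: Sequence[TagSNP]) -> list[TagSNP]:
    """Tag SNPs genotyped in both cohorts (matched on chrom, pos)."""
    a = set(cohort_a.site_index())
    b = set(cohort_b.site_index())
    return [t for t in tags if (t.chrom, t.pos) in a and (t.chrom, t.pos) in b]


def call_carriers(cohort: PhasedCohort, tags: Sequence[TagSNP],
                  genes: Iterable[GeneModel], label: str = "cohort"
                  ) -> pd.DataFrame:
    """Per-gene carrier counts for one cohort.

    Carrier status is defined for samples with >= 1 observed tag genotype at
    the gene; genes with no tag site in the cohort's data are omitted.
    Returns one row per gene: gene_id, chrom, n_carrier, n_total, cohort.
    """
    site_idx = cohort.site_index()
    rows = []
    for gene in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
        tag_idx, codes = _tag_codes_for_gene(cohort, gene, tags, site_idx)
        if not tag_idx:
            continue
        g = cohort.genotypes[:, tag_idx, :]             # (n_samples, k, 2)
        codes_arr = np.asarray(codes, dtype=np.int8)[None, :, None]
        observed = (g != MISSING).any(axis=(1, 2))
        carrier = ((g == codes_arr) & (g != MISSING)).any(axis=(1, 2))
        n_total = int(observed.sum())
        n_carrier = int((carrier & observed).sum())
        rows.append((gene.gene_id, gene.chrom, n_carrier, n_total, label))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "n_carrier",
                                       "n_total", "cohort"])


def test_proportions(cases: pd.DataFrame, controls: pd.DataFrame,
                     continuity: bool = True) -> pd.DataFrame:
    """Per-gene chi-square test of carrier proportion, cases vs controls.

    Only genes present in both tables are tested. The reported ``chi2``/``p``
    follow the ``continuity`` flag; the other variant is carried alongside
    (``chi2_uncorrected``/``p_uncorrected`` or ``chi2_yates``/``p_yates``)
    since the correction is the only difference between the two conventions.
    Genes where a margin is zero (carrier status fixed across both cohorts)
    are reported untested (NaN p) and excluded from the Bonferroni family.
    """
    merged = cases.merge(controls, on=["gene_id", "chrom"],
                         suffixes=("_case", "_ctrl"))
    rows = []
    for r in merged.itertuples(index=False):
        a = r.n_carrier_case
        b = r.n_total_case - r.n_carrier_case
        c = r.n_carrier_ctrl
        d = r.n_total_ctrl - r.n_carrier_ctrl
        main = stats.chi2_2x2(a, b, c, d, continuity=continuity)
        other = stats.chi2_2x2(a, b, c, d, continuity=not continuity)
        prop_case = a / r.n_total_case if r.n_total_case else float("nan")
        prop_ctrl = c / r.n_total_ctrl if r.n_total_ctrl else float("nan")
        if main.degenerate or prop_case == prop_ctrl:
            direction = "none"
        else:
            direction = "enriched" if prop_case > prop_ctrl else "depleted"
        rows.append((r.gene_id, r.chrom, a, r.n_total_case, c, r.n_total_ctrl,
                     prop_case, prop_ctrl, main.statistic, main.p,
                     other.statistic, other.p, direction, main.degenerate))
    alt_suffix = "_uncorrected" if continuity else "_yates"
    out = pd.DataFrame(rows, columns=[
        "gene_id", "chrom", "n_case_carrier", "n_case", "n_ctrl_carrier",
        "n_ctrl", "prop_case", "prop_ctrl", "chi2", "p",
        f"chi2{alt_suffix}", f"p{alt_suffix}", "direction", "untested"])
    tested = ~out["untested"]
    out["p_adj"] = np.nan
    if tested.any():
        out.loc[tested, "p_adj"] = stats.bonferroni(
            out.loc[tested, "p"].to_numpy())
    n_untested = int((~tested).sum())
    if n_untested:
        logger.info("%d gene(s) untested (degenerate margin)", n_untested)
    return out.sort_values(["p"], na_position="last", ignore_index=True)
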