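"""Gene-expression comparison between archaic-allele carriers and non-carriers.

Raw gene x sample counts are scaled to counts per million (CPM), samples are
grouped by whether they carry at least one archaic allele at a gene's tag
SNPs, and per-gene group differences are assessed with a two-sided Wilcoxon
rank-sum test. No dispersion modelling: this mirrors a minimal CPM workflow.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import stats
from .core_io import MISSING, GeneModel, PhasedCohort
from .haplotype_analysis import classify_copies
from .tag_snps import TagSNP

logger = logging.getLogger(__name__)

__all__ = ["read_counts_matrix", "cpm", "ancestry_groups", "compare_expression",
           "significance_band"]


def read_counts_matrix(path: str | Path) -> pd.DataFrame:
    """Read a featureCounts-style TSV: first column gene id, one column per
    sample, non-negative integer counts."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"negative counts in {path}")
    return df


def cpm(counts: pd.DataFrame, log2: bool = False) -> pd.DataFrame:
    """Counts-per-million scaling: entry / column sum x 1e6.

    Raises when a sample's library size is zero, naming the sample.
    ``log2`` returns log2(CPM + 1) for plotting.
    """
    lib = counts.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    out = counts.div(lib, axis=1) * 1e6
    return np.log2(out + 1) if log2 else out


def ancestry_groups(cohort: PhasedCohort, genes: Iterable[GeneModel],
                    tags: Sequence[TagSNP]) -> pd.DataFrame:
    """Per (sample, gene) diploid ancestry label.

    A sample has Neanderthal ancestry at a gene iff either haplotype copy
    carries >= 1 archaic allele at the gene's tag sites; with tag genotypes
    observed but no archaic allele it is modern. Samples with no observed
    tag genotype at a gene, and genes without tag sites, are absent from the
    table (unassigned).
    """
    calls, unclassifiable = classify_copies(cohort, genes, tags)
    calls = calls[calls["n_tag_sites"] > 0]
    rows = []
    for (sample, gene_id, chrom), sub in calls.groupby(
            ["sample", "gene_id", "chrom"], sort=True):
        label = ("neanderthal" if (sub["label"] == "neanderthal").any()
                 else "modern")
        rows.append((sample, gene_id, chrom, label))
    return pd.DataFrame(rows, columns=["sample", "gene_id", "chrom", "label"])


def significance_band(p: float) -> str:
    """Figure-style annotation: ns / * / ** / *** at 0.05 / 0.01 / 0.001."""
    if np.isnan(p):
        return "na"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def compare_expression(values: pd.Series, groups: pd.Series,
                       min_group: int = 2) -> dict:
    """Compare one gene's CPM values between ancestry groups.

    ``values`` maps sample -> CPM; ``groups`` maps sample -> label
    ('neanderthal'/'modern'). Reports group sizes and medians always; the
    two-sided rank-sum p only when both groups have at least ``min_group``
    samples (smaller carrier groups are reported descriptively).
    """
    joined = pd.DataFrame({"value": values, "label": groups}).dropna()
    nea = joined.loc[joined["label"] == "neanderthal", "value"].to_numpy()
    mod = joined.loc[joined["label"] == "modern", "value"].to_numpy()
    out = {
        "n_nea": int(nea.size),
        "n_mod": int(mod.size),
        "median_nea": float(np.median(nea)) if nea.size else float("nan"),
        "median_mod": float(np.median(mod)) if mod.size else float("nan"),
        "test": None,
        "band": "na",
    }
    if nea.size >= min_group and mod.size >= min_group:
        res = stats.rank_sum(nea, mod, alternative="two-sided")
        out["test"] = res
        out["band"] = significance_band(res.p)
    else:
        logger.info("expression comparison reported descriptively "
                    "(n_nea=%d, n_mod=%d)", nea.size, mod.size)
    return out
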