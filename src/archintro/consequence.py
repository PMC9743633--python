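"""Consequence-severity classification of somatic mutations.

Somatic mutations are classified by a VEP-style annotation table into
disruptive (IMPACT = HIGH) and non-disruptive (MODERATE, LOW, MODIFIER), and
per gene a 2x2 table of (disruptive / non-disruptive) x (Neanderthal copy /
modern copy) mutations feeds a two-sided Fisher exact test with Bonferroni
correction. VEP itself is never run here: its tab-delimited output is parsed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .core_io import Site

logger = logging.getLogger(__name__)

__all__ = ["ConsequenceRecord", "parse_vep_table", "test_consequence_enrichment",
           "IMPACT_SEVERITY"]

IMPACT_SEVERITY = {"HIGH": 3, "MODERATE": 2, "LOW": 1, "MODIFIER": 0}


@dataclass(frozen=True)
class ConsequenceRecord:
    site: Site
    gene_id: str
    impact: str
    consequence_term: str

    def __post_init__(self) -> None:
        if self.impact not in IMPACT_SEVERITY:
            raise ValueError(f"unknown IMPACT class {self.impact!r}")

    @property
    def disruptive(self) -> bool:
        return self.impact == "HIGH"


def parse_vep_table(path) -> pd.DataFrame:
    """Parse standard VEP tab-delimited output into one row per (variant, gene).

    Expected columns: Uploaded_variation, Location (``chrom:pos``, 1-based),
    Gene, Consequence, IMPACT. Duplicate (variant, gene) rows keep the most
    severe impact (HIGH > MODERATE > LOW > MODIFIER). Unknown IMPACT strings
    raise, naming the value. Returned positions are 0-based. An already
    loaded DataFrame with the same columns is accepted in place of a path.
    """
    df = path.copy() if isinstance(path, pd.DataFrame) else pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    required = ["Uploaded_variation", "Location", "Gene", "Consequence", "IMPACT"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"VEP table {path} is missing columns: {missing}")
    unknown = set(df["IMPACT"].unique()) - set(IMPACT_SEVERITY)
    if unknown:
        raise ValueError(f"unknown IMPACT value(s) in {path}: {sorted(unknown)}")
    loc = df["Location"].astype(str).str.split(":", expand=True)
    df = df.assign(
        chrom=loc[0],
        pos=loc[1].str.split("-").str[0].astype(int) - 1,
        severity=df["IMPACT"].map(IMPACT_SEVERITY),
    )
    df = (df.sort_values("severity", ascending=False)
            .drop_duplicates(["Uploaded_variation", "Gene"], keep="first"))
    out = df.rename(columns={"Uploaded_variation": "variant_id", "Gene": "gene_id",
                             "Consequence": "consequence_term", "IMPACT": "impact"})
    cols = ["variant_id", "chrom", "pos", "gene_id", "consequence_term", "impact"]
    return out[cols].sort_values(["chrom", "pos", "gene_id"], ignore_index=True)


def test_consequence_enrichment(somatic: pd.DataFrame, vep: pd.DataFrame,
                                genes: set[tuple[str, str]] | None = None
                                ) -> pd.DataFrame:
    """Per-gene Fisher test of disruptive-mutation proportion by ancestry.

    ``somatic`` is the per-mutation table from
    :func:`archintro.haplotype_analysis.somatic_site_table` (one row per
    somatic mutation with its haplotype label); ``vep`` is the parsed
    annotation table. Each mutation contributes to exactly one cell of its
    gene's 2x2 table: (disruptive?, on Neanderthal copy?). Mutations with no
    annotation for their gene are counted as MODIFIER (non-disruptive) and
    logged. ``genes`` restricts the tested universe, e.g. to the genes found
    somatic-enriched on Neanderthal haplotypes; genes with zero somatic
    mutations are skipped with a log entry.
    """
    if genes is not None and len(somatic):
        keep = [(g, c) in genes
                for g, c in zip(somatic["gene_id"], somatic["gene_chrom"])]
        somatic = somatic[np.asarray(keep, dtype=bool)]
    ann = vep[["chrom", "pos", "gene_id", "impact"]]
    merged = somatic.merge(ann, on=["chrom", "pos", "gene_id"], how="left")
    n_unannotated = int(merged["impact"].isna().sum())
    if n_unannotated:
        logger.info("%d somatic mutations without a consequence record; "
                    "counted as MODIFIER", n_unannotated)
    merged["impact"] = merged["impact"].fillna("MODIFIER")
    merged["disruptive"] = merged["impact"] == "HIGH"
    rows = []
    for (gene_id, chrom), sub in merged.groupby(["gene_id", "gene_chrom"], sort=True):
        if sub.empty:
            continue
        nea = sub["label"] == "neanderthal"
        dis = sub["disruptive"]
        a = int((dis & nea).sum())
        b = int((~dis & nea).sum())
        c = int((dis & ~nea).sum())
        d = int((~dis & ~nea).sum())
        res = stats.fisher_exact_2x2(a, b, c, d, alternative="two-sided")
        rows.append((gene_id, chrom, a, b, c, d, res.p))
    out = pd.DataFrame(rows, columns=["gene_id", "chrom", "high_nea", "other_nea",
                                      "high_mod", "other_mod", "p"])
    if genes is not None:
        skipped = genes - set(zip(out["gene_id"], out["chrom"]))
        for g in sorted(skipped):
            logger.info("gene %s has no somatic mutations; skipped", g)
    if out.empty:
        out["p_adj"] = pd.Series(dtype=float)
        return out
    out["p_adj"] = stats.bonferroni(out["p"].to_numpy())
    return out.sort_values("p", ignore_index=True)
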