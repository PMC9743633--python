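"""Readers, writers and interval plumbing shared by every pipeline stage.

Coordinates are 0-based half-open internally; VCF and BED files are read and
written with their native conventions (1-based VCF POS, half-open BED).
Sites are restricted to biallelic SNPs; everything else is dropped with a
logged count, mirroring upstream biallelic-SNV extraction.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

BASES = frozenset("ACGT")
SEX_CHROMS = frozenset({"X", "Y", "chrX", "chrY"})

MISSING = -1  # genotype code for an uncalled allele


@dataclass(frozen=True)
class Site:
    """A biallelic SNP. ``pos`` is 0-based; VCF POS is ``pos + 1``."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt or self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"not a biallelic SNP: {self.chrom}:{self.pos + 1} "
                             f"{self.ref}>{self.alt}")


@dataclass(frozen=True)
class GeneModel:
    """A gene collapsed to a single span: union of all isoform transcripts.

    ``start``/``end`` are 0-based half-open. Genes are identified by
    (gene_id, chrom) so a duplicated symbol on two chromosomes yields two
    distinct models.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    n_isoforms: int = 1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty gene span for {self.gene_id}: "
                             f"[{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_id, self.chrom)


@dataclass
class PhasedCohort:
    """Phased genotypes for samples x sites with per-copy somatic flags.

    ``genotypes`` has shape (n_samples, n_sites, 2) with 0 = ref allele,
    1 = alt allele, -1 = missing; axis 2 indexes the two haplotype copies in
    VCF GT order. ``somatic_flags`` marks, per copy, sites where the carried
    alt allele is a somatic mutation.
    """

    samples: list[str]
    sites: list[Site]
    genotypes: np.ndarray
    somatic_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        expected = (len(self.samples), len(self.sites), 2)
        if self.genotypes.shape != expected:
            raise ValueError(f"genotypes shape {self.genotypes.shape} != {expected}")
        if self.somatic_flags is None:
            self.somatic_flags = np.zeros(expected, dtype=bool)
        self.somatic_flags = np.asarray(self.somatic_flags, dtype=bool)
        if self.somatic_flags.shape != expected:
            raise ValueError("somatic_flags shape mismatch")
        if np.any(self.somatic_flags & (self.genotypes != 1)):
            raise ValueError("somatic flag set on a copy that does not carry the alt allele")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_index(self) -> dict[tuple[str, int], int]:
        return {(s.chrom, s.pos): i for i, s in enumerate(self.sites)}


# ---------------------------------------------------------------------------
# gene tables

_GENE_COL_ALIASES = {
    "name": ("name2", "name", "gene", "gene_name", "geneName"),
    "chrom": ("chrom", "chr", "chromosome"),
    "txStart": ("txStart", "txstart", "start"),
    "txEnd": ("txEnd", "txend", "end"),
}


def read_gene_table(path: str | Path) -> set[GeneModel]:
    """Read a RefSeq-style isoform table and collapse isoforms per gene.

    One row per isoform; the gene span is min(txStart)..max(txEnd) over all
    isoforms sharing (gene name, chrom). Rows on unplaced contigs are kept
    verbatim. Raises on a missing required column or on any row with
    txStart >= txEnd (all offending rows listed).
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    cols: dict[str, str] = {}
    for logical, aliases in _GENE_COL_ALIASES.items():
        found = next((a for a in aliases if a in df.columns), None)
        if found is None:
            raise ValueError(f"gene table {path} is missing a '{logical}' column "
                             f"(accepted names: {aliases})")
        cols[logical] = found
    bad = df[df[cols["txStart"]] >= df[cols["txEnd"]]]
    if len(bad):
        raise ValueError("gene table rows with txStart >= txEnd: "
                         + ", ".join(str(i) for i in bad.index.tolist()))
    grouped = df.groupby([cols["name"], cols["chrom"]], sort=True).agg(
        start=(cols["txStart"], "min"),
        end=(cols["txEnd"], "max"),
        n_isoforms=(cols["txStart"], "size"),
    )
    return {
        GeneModel(gene_id=str(name), chrom=str(chrom), start=int(r.start),
                  end=int(r.end), n_isoforms=int(r.n_isoforms))
        for (name, chrom), r in grouped.iterrows()
    }


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
    df = pd.DataFrame({
        "name": [g.gene_id for g in rows],
        "chrom": [g.chrom for g in rows],
        "strand": ["+"] * len(rows),
        "txStart": [g.start for g in rows],
        "txEnd": [g.end for g in rows],
    })
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phased VCF

def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_phased_vcf(path: str | Path,
                    somatic_info_key: str = "SOMATIC",
                    somatic_format_key: str = "SM",
                    autosomes_only: bool = True) -> PhasedCohort:
    """Load a phased multi-sample VCF into a :class:`PhasedCohort`.

    All genotypes must be phased ('|'); the first unphased call raises an
    error naming the sample and site. Non-biallelic or non-SNP records are
    dropped with a logged count. Somatic provenance is taken from a
    per-sample FORMAT field (``SM``, values like ``0|1``) when present,
    otherwise from a site-level INFO flag (``SOMATIC``), in which case every
    alt-carrying copy at the site is flagged.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    sites: list[Site] = []
    gt_rows: list[list[tuple[int, int]]] = []
    som_rows: list[list[tuple[bool, bool]]] = []
    n_dropped = 0
    for rec in vf:
        if autosomes_only and rec.chrom in SEX_CHROMS:
            n_dropped += 1
            continue
        alts = rec.alts or ()
        if (len(alts) != 1 or rec.ref not in BASES or alts[0] not in BASES):
            n_dropped += 1
            logger.warning("dropping non-biallelic-SNP site %s:%d", rec.chrom, rec.pos)
            continue
        info_somatic = somatic_info_key in rec.info
        row_gt: list[tuple[int, int]] = []
        row_som: list[tuple[bool, bool]] = []
        for sample in samples:
            call = rec.samples[sample]
            gt = call.get("GT")
            if gt is None or all(a is None for a in gt):
                row_gt.append((MISSING, MISSING))
                row_som.append((False, False))
                continue
            if len(gt) != 2:
                raise ValueError(f"non-diploid GT for {sample} at {rec.chrom}:{rec.pos}")
            if not call.phased:
                raise ValueError(f"unphased genotype for sample {sample} at "
                                 f"{rec.chrom}:{rec.pos}; phase the VCF first")
            pair = tuple(MISSING if a is None else int(a) for a in gt)
            sm = call.get(somatic_format_key) if somatic_format_key in rec.format else None
            if sm is not None:
                sm_str = sm if isinstance(sm, str) else "|".join(map(str, sm))
                flags = tuple(tok == "1" for tok in sm_str.split("|"))
                if len(flags) != 2:
                    raise ValueError(f"malformed {somatic_format_key} field {sm_str!r}")
            elif info_somatic:
                flags = tuple(a == 1 for a in pair)
            else:
                flags = (False, False)
            row_gt.append(pair)  # type: ignore[arg-type]
            row_som.append(flags)  # type: ignore[arg-type]
        sites.append(Site(rec.chrom, rec.pos - 1, rec.ref, alts[0]))
        gt_rows.append(row_gt)
        som_rows.append(row_som)
    if n_dropped:
        logger.info("read_phased_vcf: dropped %d non-biallelic-SNP/sex-chrom sites", n_dropped)
    n_sites = len(sites)
    genotypes = np.full((len(samples), n_sites, 2), MISSING, dtype=np.int8)
    somatic = np.zeros((len(samples), n_sites, 2), dtype=bool)
    for j in range(n_sites):
        for i in range(len(samples)):
            genotypes[i, j] = gt_rows[j][i]
            somatic[i, j] = som_rows[j][i]
    return PhasedCohort(samples=samples, sites=sites, genotypes=genotypes,
                        somatic_flags=somatic)


def write_phased_vcf(cohort: PhasedCohort, path: str | Path) -> None:
    """Write a cohort as VCF 4.2 with phased GT and a per-copy SM somatic field.

    Output is deterministic (no timestamps) and round-trips bit-exactly
    through :func:`read_phased_vcf`.
    """
    contigs = sorted({s.chrom for s in cohort.sites})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=archintro\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype">\n')
        fh.write('##FORMAT=<ID=SM,Number=1,Type=String,'
                 'Description="Per-haplotype somatic flag, phased as GT">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(cohort.samples) + "\n")
        order = sorted(range(cohort.n_sites),
                       key=lambda j: (cohort.sites[j].chrom, cohort.sites[j].pos))
        for j in order:
            s = cohort.sites[j]
            cells = []
            for i in range(cohort.n_samples):
                a0, a1 = cohort.genotypes[i, j]
                gt = "|".join("." if a == MISSING else str(int(a)) for a in (a0, a1))
                f0, f1 = cohort.somatic_flags[i, j]
                cells.append(f"{gt}:{int(f0)}|{int(f1)}")
            fh.write(f"{s.chrom}\t{s.pos + 1}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t.\t"
                     "GT:SM\t" + "\t".join(cells) + "\n")


def merge_somatic_vcfs(cohort: PhasedCohort,
                       somatic_paths: Mapping[str, str | Path]) -> PhasedCohort:
    """Attach per-patient somatic SNVs to an already-phased cohort.

    Somatic records are matched on (chrom, pos, ref, alt). A mutation is
    assigned to the single haplotype copy of its patient that carries the alt
    allele; records whose patient carries zero or two alt copies cannot be
    placed on one copy and are logged and skipped, as are non-SNV records.
    Returns a new cohort; the input is not modified.
    """
    idx = cohort.site_index()
    sample_pos = {s: i for i, s in enumerate(cohort.samples)}
    flags = cohort.somatic_flags.copy()
    n_skipped = 0
    for sample, path in somatic_paths.items():
        if sample not in sample_pos:
            raise KeyError(f"somatic VCF given for unknown sample {sample!r}")
        i = sample_pos[sample]
        vf = pysam.VariantFile(str(path))
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1 or rec.ref not in BASES or alts[0] not in BASES:
                n_skipped += 1
                logger.warning("skipping non-SNV somatic record %s:%d for %s",
                               rec.chrom, rec.pos, sample)
                continue
            j = idx.get((rec.chrom, rec.pos - 1))
            if j is None or cohort.sites[j].ref != rec.ref or cohort.sites[j].alt != alts[0]:
                n_skipped += 1
                continue
            alt_copies = np.flatnonzero(cohort.genotypes[i, j] == 1)
            if len(alt_copies) != 1:
                n_skipped += 1
                logger.warning("somatic site %s:%d for %s has %d alt copies; cannot "
                               "assign to one haplotype", rec.chrom, rec.pos, sample,
                               len(alt_copies))
                continue
            flags[i, j, alt_copies[0]] = True
    if n_skipped:
        logger.info("merge_somatic_vcfs: %d somatic records skipped", n_skipped)
    return PhasedCohort(samples=list(cohort.samples), sites=list(cohort.sites),
                        genotypes=cohort.genotypes.copy(), somatic_flags=flags)


# ---------------------------------------------------------------------------
# interval assignment

def assign_sites_to_genes(sites: Sequence[Site],
                          genes: Iterable[GeneModel]) -> dict[GeneModel, list[int]]:
    """Map every gene to the (sorted) indices of sites inside its span.

    A site at position p belongs to gene g iff chromosomes match and
    g.start <= p < g.end; overlapping genes each receive the site, and genes
    with no sites map to an empty list.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {s.chrom for s in sites}:
        idx = np.array([i for i, s in enumerate(sites) if s.chrom == chrom])
        pos = np.array([sites[i].pos for i in idx])
        order = np.argsort(pos, kind="stable")
        by_chrom[chrom] = (pos[order], idx[order])
    out: dict[GeneModel, list[int]] = {}
    for gene in genes:
        if gene.chrom not in by_chrom:
            out[gene] = []
            continue
        pos, idx = by_chrom[gene.chrom]
        lo = np.searchsorted(pos, gene.start, side="left")
        hi = np.searchsorted(pos, gene.end, side="left")
        out[gene] = sorted(int(i) for i in idx[lo:hi])
    return out
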