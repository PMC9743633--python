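"""Curation of archaic tag SNPs.

A tag SNP marks an introgressed haplotype: its archaic allele matches an
archaic reference genome (Neanderthal by default) and is rare or absent in an
unadmixed outgroup panel. Tag sets are read and written as BED 4+3
(chrom, start, end, name, modern_allele, archaic_allele[, outgroup_freq
[, matched_labels]]).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .core_io import BASES, Site

logger = logging.getLogger(__name__)

__all__ = ["TagSNP", "read_tag_bed", "write_tag_bed", "filter_tag_snps",
           "archaic_specificity", "outgroup_frequency_from_vcf"]


@dataclass
class TagSNP:
    """One putative archaic site.

    ``site`` carries the modern allele as REF and the archaic allele as ALT
    when built from a tag BED; when matched against a cohort VCF the archaic
    allele is compared by base identity, not by REF/ALT role.
    ``archaic_match`` maps archaic-reference labels (e.g. ``"neanderthal"``,
    ``"denisovan"``) to whether the allele matches that genome.
    """

    site: Site
    archaic_allele: str
    modern_allele: str
    outgroup_freq: float | None = None
    archaic_match: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.archaic_allele not in BASES or self.modern_allele not in BASES:
            raise ValueError("tag alleles must be single bases in ACGT")
        if self.archaic_allele == self.modern_allele:
            raise ValueError("archaic and modern alleles must differ")
        if self.archaic_allele not in (self.site.ref, self.site.alt):
            raise ValueError("archaic allele must be one of the site alleles")
        if self.outgroup_freq is not None and not 0 <= self.outgroup_freq <= 1:
            raise ValueError(f"outgroup_freq {self.outgroup_freq} outside [0, 1]")

    @property
    def chrom(self) -> str:
        return self.site.chrom

    @property
    def pos(self) -> int:
        return self.site.pos


def _open_text(path: str | Path):
    path = str(path)
    return gzip.open(path, "rt") if path.endswith(".gz") else open(path)


def read_tag_bed(path: str | Path) -> list[TagSNP]:
    """Read tag SNPs from BED 4+3 (0-based half-open single-base intervals).

    Optional column 7 is the archaic-allele frequency in the outgroup panel;
    optional column 8 is a comma-separated list of archaic references the
    allele matches (``.`` for none recorded).
    """
    tags: list[TagSNP] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: tag BED needs >= 6 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end - start != 1:
                raise ValueError(f"{path}:{lineno}: tag SNP interval must span 1 bp")
            modern, archaic = parts[4], parts[5]
            freq = None
            if len(parts) > 6 and parts[6] not in (".", ""):
                freq = float(parts[6])
            matches: dict[str, bool] = {}
            if len(parts) > 7 and parts[7] not in (".", ""):
                matches = {label: True for label in parts[7].split(",")}
            tags.append(TagSNP(site=Site(chrom, start, modern, archaic),
                               archaic_allele=archaic, modern_allele=modern,
                               outgroup_freq=freq, archaic_match=matches))
    return tags


def write_tag_bed(tags: Iterable[TagSNP], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in sorted(tags, key=lambda t: (t.chrom, t.pos, t.archaic_allele)):
            freq = "." if t.outgroup_freq is None else f"{t.outgroup_freq:.6g}"
            labels = ",".join(sorted(k for k, v in t.archaic_match.items() if v)) or "."
            fh.write(f"{t.chrom}\t{t.pos}\t{t.pos + 1}\ttag_{t.chrom}_{t.pos}\t"
                     f"{t.modern_allele}\t{t.archaic_allele}\t{freq}\t{labels}\n")


def filter_tag_snps(candidates: Sequence[TagSNP],
                    require_match: str | None = "neanderthal",
                    max_outgroup_freq: float = 0.01) -> list[TagSNP]:
    """Retain tag SNPs matching the requested archaic reference and rare in
    the outgroup.

    A candidate survives iff ``archaic_match[require_match]`` is true (skipped
    when ``require_match`` is None) and ``outgroup_freq <= max_outgroup_freq``.
    Candidates without an outgroup frequency raise unless the frequency filter
    is disabled (``max_outgroup_freq >= 1``). Output is sorted by (chrom, pos)
    and deduplicated on (chrom, pos, archaic allele).
    """
    retained: list[TagSNP] = []
    for t in candidates:
        if require_match is not None and not t.archaic_match.get(require_match, False):
            continue
        if max_outgroup_freq < 1:
            if t.outgroup_freq is None:
                raise ValueError(f"tag at {t.chrom}:{t.pos} lacks an outgroup "
                                 "frequency; disable the filter with "
                                 "max_outgroup_freq=1 or supply frequencies")
            if t.outgroup_freq > max_outgroup_freq:
                continue
        retained.append(t)
    seen: set[tuple[str, int, str]] = set()
    out: list[TagSNP] = []
    for t in sorted(retained, key=lambda t: (t.chrom, t.pos, t.archaic_allele)):
        key = (t.chrom, t.pos, t.archaic_allele)
        if key not in seen:
            seen.add(key)
            out.append(t)
    return out


def archaic_specificity(tag: TagSNP, other_label: str = "denisovan",
                        primary_label: str = "neanderthal") -> str:
    """Classify a tag allele as specific to the primary archaic reference.

    Returns ``"specific"`` when the allele matches the primary genome but not
    the other, ``"shared"`` when it matches both, and ``"unknown"`` when the
    other reference was never queried for this tag.
    """
    if other_label not in tag.archaic_match:
        return "unknown"
    primary = tag.archaic_match.get(primary_label, False)
    other = tag.archaic_match[other_label]
    if primary and not other:
        return "specific"
    if primary and other:
        return "shared"
    return "unknown" if not primary else "shared"


def outgroup_frequency_from_vcf(tags: Sequence[TagSNP],
                                panel_vcf: str | Path) -> list[TagSNP]:
    """Fill ``outgroup_freq`` from a genotype panel VCF.

    The frequency is the archaic-allele count over 2 x called samples at the
    matching (chrom, pos); tags absent from the panel get frequency 0.0
    (the allele was never observed in the outgroup).
    """
    vf = pysam.VariantFile(str(panel_vcf))
    counts: dict[tuple[str, int], tuple[dict[str, int], int]] = {}
    for rec in vf:
        allele_counts: dict[str, int] = {}
        n_called = 0
        alleles = (rec.ref,) + (rec.alts or ())
        for sample in rec.samples.values():
            gt = sample.get("GT") or ()
            for a in gt:
                if a is None:
                    continue
                n_called += 1
                base = alleles[a]
                allele_counts[base] = allele_counts.get(base, 0) + 1
        counts[(rec.chrom, rec.pos - 1)] = (allele_counts, n_called)
    out: list[TagSNP] = []
    for t in tags:
        rec = counts.get((t.chrom, t.pos))
        if rec is None:
            freq = 0.0
        else:
            allele_counts, n_called = rec
            freq = (allele_counts.get(t.archaic_allele, 0) / n_called
                    if n_called else 0.0)
        out.append(TagSNP(site=t.site, archaic_allele=t.archaic_allele,
                          modern_allele=t.modern_allele, outgroup_freq=freq,
                          archaic_match=dict(t.archaic_match)))
    return out
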