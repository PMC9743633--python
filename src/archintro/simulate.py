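"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator plants, gene by gene, the effects the analysis is meant to
detect: haplotype copies are introgressed with a set frequency (all tag SNPs
of a gene flip together on a copy, matching the gene-scoped unit of
analysis), somatic mutations arrive as a Poisson process along each copy
with an optional rate multiplier on introgressed copies, allele-specific
reads at heterozygous tag sites are binomial with an optional shift of the
archaic-allele probability away from 0.5 in tumor, expression counts are
gamma-Poisson (negative binomial) with an optional multiplicative carrier
effect, and the case cohort's carrier frequency can differ from the
control's. Truth tables record every planted effect. A fixed seed makes all
outputs byte-identical. No coalescent realism: linkage across genes,
recombination and demography are deliberately not modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import GeneModel, PhasedCohort, Site, write_gene_table, write_phased_vcf
from .tag_snps import TagSNP, write_tag_bed

logger = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "SimulatedData", "simulate_cohort",
           "write_outputs", "truth_report"]

_BASES = np.array(list("ACGT"))

_CONSEQUENCE_TERM = {"HIGH": "stop_gained", "MODERATE": "missense_variant",
                     "LOW": "synonymous_variant", "MODIFIER": "intron_variant"}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a liver-cancer-like desk-scale study: ~1 somatic
    mutation per Mb per haplotype copy, 4 tag SNPs per 50 kb gene, a
    per-haplotype introgression frequency of 0.15, and read depth 30 at ASE
    sites. ``*_planted_genes = None`` applies the corresponding effect size
    to every gene (the null configuration leaves every effect at its neutral
    value anyway); a tuple of gene ids plants the effect in that subset only.
    """

    seed: int = 0
    n_case: int = 100
    n_control: int = 100
    n_normal: int = 50
    n_genes: int = 200
    gene_length_bp: int = 50_000
    gene_spacing_bp: int = 10_000
    tags_per_gene: int = 4
    intro_freq: float = 0.15
    somatic_rate_modern: float = 1e-6
    rate_multiplier_rho: float = 1.0
    planted_enriched_genes: tuple[str, ...] | None = None
    ase_depth: int = 30
    ase_shift_delta: float = 0.0
    ase_planted_genes: tuple[str, ...] | None = None
    expr_baseline: float = 100.0
    expr_effect: float = 1.0
    expr_planted_genes: tuple[str, ...] | None = None
    expr_dispersion: float = 10.0
    case_control_freq_delta: float = 0.0
    cc_planted_genes: tuple[str, ...] | None = None
    consequence_probs: Mapping[str, float] = field(
        default_factory=lambda: {"HIGH": 0.1, "MODERATE": 0.5, "LOW": 0.4})
    coding_fraction: float = 0.3
    chrom: str = "chr1"

    def validate(self) -> None:
        if not 0 <= self.intro_freq <= 1:
            raise ValueError("intro_freq must lie in [0, 1]")
        if not 0 <= self.intro_freq + self.case_control_freq_delta <= 1:
            raise ValueError("case carrier frequency outside [0, 1]")
        if self.somatic_rate_modern < 0 or self.rate_multiplier_rho < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= 0.5 + self.ase_shift_delta <= 1:
            raise ValueError("ase_shift_delta pushes the read probability outside [0, 1]")
        if not 0 <= self.coding_fraction <= 1:
            raise ValueError("coding_fraction must lie in [0, 1]")
        if any(p < 0 for p in self.consequence_probs.values()):
            raise ValueError("consequence probabilities must be non-negative")
        planted_somatic = (self.rate_multiplier_rho != 1.0
                           or self.planted_enriched_genes)
        if self.intro_freq == 0 and planted_somatic:
            raise ValueError("infeasible: somatic enrichment planted with "
                             "intro_freq = 0 (no introgressed copies exist)")


@dataclass
class SimulatedData:
    """Everything one synthetic study produces, in memory."""

    config: SimulationConfig
    genes: list[GeneModel]
    tags: list[TagSNP]
    case: PhasedCohort
    control: PhasedCohort
    normal: PhasedCohort
    ase_tumor: pd.DataFrame
    ase_normal: pd.DataFrame
    vep: pd.DataFrame
    counts_tumor: pd.DataFrame
    counts_normal: pd.DataFrame
    truth: pd.DataFrame
    somatic_by_sample: dict[str, list[Site]]


def _planted_set(genes: Sequence[str], subset: tuple[str, ...] | None,
                 active: bool) -> set[str]:
    if not active:
        return set()
    return set(genes) if subset is None else set(subset)


def _simulate_haplotypes(rng: np.random.Generator, n_samples: int,
                         n_genes: int, freqs: np.ndarray) -> np.ndarray:
    """(n_samples, n_genes, 2) boolean: is the copy introgressed."""
    return rng.random((n_samples, n_genes, 2)) < freqs[None, :, None]


def simulate_cohort(config: SimulationConfig) -> SimulatedData:
    """Generate one synthetic study under ``config`` (seed-deterministic)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    cfg = config
    gene_ids = [f"G{i:04d}" for i in range(cfg.n_genes)]

    # gene models laid head to tail along one autosome
    genes: list[GeneModel] = []
    cursor = 1000
    for gid in gene_ids:
        genes.append(GeneModel(gid, cfg.chrom, cursor, cursor + cfg.gene_length_bp))
        cursor += cfg.gene_length_bp + cfg.gene_spacing_bp

    # tag SNPs: modern allele is the cohort REF, archaic allele the ALT
    tag_sites: list[Site] = []
    tags: list[TagSNP] = []
    tag_gene_of: list[int] = []
    for gi, gene in enumerate(genes):
        pos = np.sort(rng.choice(gene.length, size=cfg.tags_per_gene,
                                 replace=False)) + gene.start
        for p in pos:
            modern, archaic = rng.choice(4, size=2, replace=False)
            site = Site(cfg.chrom, int(p), str(_BASES[modern]), str(_BASES[archaic]))
            tag_sites.append(site)
            tags.append(TagSNP(site=site, archaic_allele=site.alt,
                               modern_allele=site.ref, outgroup_freq=0.0,
                               archaic_match={"neanderthal": True}))
            tag_gene_of.append(gi)

    planted_somatic = _planted_set(gene_ids, cfg.planted_enriched_genes,
                                   cfg.rate_multiplier_rho != 1.0)
    planted_ase = _planted_set(gene_ids, cfg.ase_planted_genes,
                               cfg.ase_shift_delta != 0.0)
    planted_expr = _planted_set(gene_ids, cfg.expr_planted_genes,
                                cfg.expr_effect != 1.0)
    planted_cc = _planted_set(gene_ids, cfg.cc_planted_genes,
                              cfg.case_control_freq_delta != 0.0)

    freq_control = np.full(cfg.n_genes, cfg.intro_freq)
    freq_case = np.array([cfg.intro_freq + (cfg.case_control_freq_delta
                                            if g in planted_cc else 0.0)
                          for g in gene_ids])
    rho = np.array([cfg.rate_multiplier_rho if g in planted_somatic else 1.0
                    for g in gene_ids])

    case_samples = [f"case{i:04d}" for i in range(cfg.n_case)]
    control_samples = [f"ctrl{i:04d}" for i in range(cfg.n_control)]
    normal_samples = [f"norm{i:04d}" for i in range(cfg.n_normal)]

    nea_case = _simulate_haplotypes(rng, cfg.n_case, cfg.n_genes, freq_case)
    nea_control = _simulate_haplotypes(rng, cfg.n_control, cfg.n_genes, freq_control)
    nea_normal = _simulate_haplotypes(rng, cfg.n_normal, cfg.n_genes, freq_control)

    def _tag_genotypes(nea: np.ndarray) -> np.ndarray:
        # archaic allele (code 1) at every tag site of an introgressed copy
        return nea[:, np.asarray(tag_gene_of), :].astype(np.int8)

    # somatic mutations on the case cohort
    used_positions = {s.pos for s in tag_sites}
    somatic_sites: list[Site] = []
    somatic_carrier: list[tuple[int, int]] = []   # (sample index, copy)
    somatic_gene_of: list[int] = []
    for gi, gene in enumerate(genes):
        lam_mod = cfg.somatic_rate_modern * gene.length
        lam = np.where(nea_case[:, gi, :], lam_mod * rho[gi], lam_mod)
        counts = rng.poisson(lam)
        for si, copy in zip(*np.nonzero(counts)):
            for _ in range(counts[si, copy]):
                while True:
                    p = int(rng.integers(gene.start, gene.end))
                    if p not in used_positions:
                        used_positions.add(p)
                        break
                ref, alt = rng.choice(4, size=2, replace=False)
                somatic_sites.append(Site(cfg.chrom, p, str(_BASES[ref]),
                                          str(_BASES[alt])))
                somatic_carrier.append((int(si), int(copy)))
                somatic_gene_of.append(gi)

    # assemble the case cohort: tag sites + somatic sites, position-sorted
    all_sites = tag_sites + somatic_sites
    order = np.argsort([s.pos for s in all_sites], kind="stable")
    n_sites = len(all_sites)
    genotypes = np.zeros((cfg.n_case, n_sites, 2), dtype=np.int8)
    somatic_flags = np.zeros((cfg.n_case, n_sites, 2), dtype=bool)
    genotypes[:, :len(tag_sites), :] = _tag_genotypes(nea_case)
    for k, (si, copy) in enumerate(somatic_carrier):
        j = len(tag_sites) + k
        genotypes[si, j, copy] = 1
        somatic_flags[si, j, copy] = True
    case = PhasedCohort(samples=case_samples,
                        sites=[all_sites[j] for j in order],
                        genotypes=genotypes[:, order, :],
                        somatic_flags=somatic_flags[:, order, :])

    control = PhasedCohort(samples=control_samples, sites=list(tag_sites),
                           genotypes=_tag_genotypes(nea_control))
    normal = PhasedCohort(samples=normal_samples, sites=list(tag_sites),
                          genotypes=_tag_genotypes(nea_normal))

    somatic_by_sample: dict[str, list[Site]] = {s: [] for s in case_samples}
    for site, (si, _copy) in zip(somatic_sites, somatic_carrier):
        somatic_by_sample[case_samples[si]].append(site)

    # VEP-style annotation of the somatic variants
    impact_labels = list(cfg.consequence_probs)
    impact_p = np.array([cfg.consequence_probs[k] for k in impact_labels], float)
    impact_p = impact_p / impact_p.sum()
    vep_rows = []
    for site, gi in zip(somatic_sites, somatic_gene_of):
        gene = genes[gi]
        margin = gene.length * (1 - cfg.coding_fraction) / 2
        in_coding = gene.start + margin <= site.pos < gene.end - margin
        impact = (str(rng.choice(impact_labels, p=impact_p)) if in_coding
                  else "MODIFIER")
        vep_rows.append((f"{site.chrom}_{site.pos + 1}_{site.ref}/{site.alt}",
                         f"{site.chrom}:{site.pos + 1}", gene.gene_id,
                         _CONSEQUENCE_TERM[impact], impact))
    vep = pd.DataFrame(vep_rows, columns=["Uploaded_variation", "Location",
                                          "Gene", "Consequence", "IMPACT"])
    vep = vep.sort_values(["Location", "Gene"], ignore_index=True)

    # ASE read counts at heterozygous tag sites (archaic allele is ALT)
    def _ase_table(nea: np.ndarray, samples: list[str], tissue: str) -> pd.DataFrame:
        rows = []
        shift = cfg.ase_shift_delta if tissue == "tumor" else 0.0
        for gi, gene in enumerate(genes):
            p_nea = 0.5 + (shift if gene.gene_id in planted_ase else 0.0)
            het = nea[:, gi, 0] != nea[:, gi, 1]
            het_idx = np.nonzero(het)[0]
            gene_tag_idx = [k for k, gg in enumerate(tag_gene_of) if gg == gi]
            for si in het_idx:
                for k in gene_tag_idx:
                    site = tag_sites[k]
                    nea_reads = int(rng.binomial(cfg.ase_depth, p_nea))
                    rows.append((samples[si], site.chrom, site.pos, site.ref,
                                 site.alt, cfg.ase_depth - nea_reads, nea_reads,
                                 tissue))
        return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref", "alt",
                                           "refCount", "altCount", "tissue"])

    ase_tumor = _ase_table(nea_case, case_samples, "tumor")
    ase_normal = _ase_table(nea_normal, normal_samples, "normal")

    # expression counts: gamma-Poisson with a multiplicative carrier effect
    def _counts(nea: np.ndarray, samples: list[str]) -> pd.DataFrame:
        lib = rng.lognormal(mean=0.0, sigma=0.2, size=len(samples))
        carrier = nea.any(axis=2)                     # (n_samples, n_genes)
        effect = np.array([cfg.expr_effect if g in planted_expr else 1.0
                           for g in gene_ids])
        mu = cfg.expr_baseline * lib[:, None] * np.where(carrier, effect, 1.0)
        shape = cfg.expr_dispersion
        lam = rng.gamma(shape, mu / shape)
        counts = rng.poisson(lam)                     # (n_samples, n_genes)
        return pd.DataFrame(counts.T, index=pd.Index(gene_ids, name="gene_id"),
                            columns=samples)

    counts_tumor = _counts(nea_case, case_samples)
    counts_normal = _counts(nea_normal, normal_samples)

    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "chrom": cfg.chrom,
        "start": [g.start for g in genes],
        "end": [g.end for g in genes],
        "intro_freq_case": freq_case,
        "intro_freq_control": freq_control,
        "rho": rho,
        "ase_delta": [cfg.ase_shift_delta if g in planted_ase else 0.0
                      for g in gene_ids],
        "expr_effect": [cfg.expr_effect if g in planted_expr else 1.0
                        for g in gene_ids],
        "somatic_planted": [g in planted_somatic for g in gene_ids],
        "ase_planted": [g in planted_ase for g in gene_ids],
        "expr_planted": [g in planted_expr for g in gene_ids],
        "cc_planted": [g in planted_cc for g in gene_ids],
        "n_nea_copies_case": nea_case.sum(axis=(0, 2)),
    })

    return SimulatedData(config=cfg, genes=genes, tags=tags, case=case,
                         control=control, normal=normal, ase_tumor=ase_tumor,
                         ase_normal=ase_normal, vep=vep,
                         counts_tumor=counts_tumor, counts_normal=counts_normal,
                         truth=truth, somatic_by_sample=somatic_by_sample)


def _write_somatic_vcf(sites: list[Site], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=archintro-simulate\n")
        for chrom in sorted({s.chrom for s in sites}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(sites, key=lambda s: (s.chrom, s.pos)):
            fh.write(f"{s.chrom}\t{s.pos + 1}\t.\t{s.ref}\t{s.alt}\t.\tPASS\tSOMATIC\n")


def _ase_to_tsv(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    out["pos"] = out["pos"] + 1   # files carry 1-based positions
    out.to_csv(path, sep="\t", index=False)


def write_outputs(data: SimulatedData, outdir: str | Path) -> dict[str, Path]:
    """Emit every file the pipeline consumes; byte-identical under one seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "case_vcf": outdir / "case_phased.vcf",
        "control_vcf": outdir / "control_phased.vcf",
        "normal_vcf": outdir / "normal_phased.vcf",
        "tags_bed": outdir / "tags.bed",
        "genes_tsv": outdir / "genes.tsv",
        "vep_tsv": outdir / "vep.tsv",
        "ase_tumor_tsv": outdir / "ase_tumor.tsv",
        "ase_normal_tsv": outdir / "ase_normal.tsv",
        "counts_tumor_tsv": outdir / "counts_tumor.tsv",
        "counts_normal_tsv": outdir / "counts_normal.tsv",
        "truth_tsv": outdir / "truth.tsv",
    }
    write_phased_vcf(data.case, paths["case_vcf"])
    write_phased_vcf(data.control, paths["control_vcf"])
    write_phased_vcf(data.normal, paths["normal_vcf"])
    write_tag_bed(data.tags, paths["tags_bed"])
    write_gene_table(data.genes, paths["genes_tsv"])
    data.vep.to_csv(paths["vep_tsv"], sep="\t", index=False)
    _ase_to_tsv(data.ase_tumor, paths["ase_tumor_tsv"])
    _ase_to_tsv(data.ase_normal, paths["ase_normal_tsv"])
    data.counts_tumor.to_csv(paths["counts_tumor_tsv"], sep="\t")
    data.counts_normal.to_csv(paths["counts_normal_tsv"], sep="\t")
    data.truth.to_csv(paths["truth_tsv"], sep="\t", index=False)
    somdir = outdir / "somatic"
    somdir.mkdir(exist_ok=True)
    for sample, sites in sorted(data.somatic_by_sample.items()):
        p = somdir / f"{sample}.vcf"
        _write_somatic_vcf(sites, p)
        paths[f"somatic/{sample}"] = p
    return paths


def truth_report(truth: pd.DataFrame, results: Mapping[str, pd.DataFrame],
                 alpha: float = 0.05, use_adjusted: bool = False) -> pd.DataFrame:
    """Recovery metrics per analysis: sensitivity and false-discovery
    proportion of planted genes at threshold ``alpha``.

    ``results`` maps an analysis name ('somatic_enrichment',
    'ase_tumor_vs_normal', 'cohort_comparison') to its per-gene result table
    (must carry gene_id and p/p_adj columns). Result genes must be a subset
    of the truth universe.
    """
    planted_col = {"somatic_enrichment": "somatic_planted",
                   "ase_tumor_vs_normal": "ase_planted",
                   "cohort_comparison": "cc_planted"}
    universe = set(truth["gene_id"])
    rows = []
    for analysis, res in results.items():
        if analysis not in planted_col:
            raise KeyError(f"unknown analysis {analysis!r}")
        extra = set(res["gene_id"]) - universe
        if extra:
            raise ValueError(f"{analysis}: result genes outside the truth "
                             f"universe: {sorted(extra)[:5]}")
        pcol = "p_adj" if use_adjusted else "p"
        detected = set(res.loc[res[pcol] < alpha, "gene_id"])
        planted = set(truth.loc[truth[planted_col[analysis]], "gene_id"])
        n_planted = len(planted)
        sens = (len(detected & planted) / n_planted) if n_planted else float("nan")
        fdp = (len(detected - planted) / len(detected)) if detected else float("nan")
        rows.append((analysis, n_planted, len(detected), sens, fdp))
    return pd.DataFrame(rows, columns=["analysis", "n_planted", "n_detected",
                                       "sensitivity", "fdp"])
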