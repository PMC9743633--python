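"""Gene tables, phased VCF round trips, and interval assignment."""

import numpy as np
import pandas as pd
import pytest

from archintro import (GeneModel, PhasedCohort, Site, assign_sites_to_genes,
                       merge_somatic_vcfs, read_gene_table, read_phased_vcf,
                       write_phased_vcf)
from conftest import write_vcf
from oracles import intersect_brute


def _gene_table(tmp_path, rows):
    df = pd.DataFrame(rows, columns=["name", "chrom", "strand", "txStart", "txEnd"])
    path = tmp_path / "genes.tsv"
    df.to_csv(path, sep="\t", index=False)
    return path


class TestGeneTable:
    def test_isoform_union(self, tmp_path):
        path = _gene_table(tmp_path, [("geneA", "chr1", "+", 100, 200),
                                      ("geneA", "chr1", "+", 150, 300)])
        (g,) = read_gene_table(path)
        assert (g.start, g.end, g.n_isoforms) == (100, 300, 2)

    def test_single_isoform_identity(self, tmp_path):
        path = _gene_table(tmp_path, [("geneB", "chr2", "-", 10, 20)])
        (g,) = read_gene_table(path)
        assert (g.gene_id, g.chrom, g.start, g.end) == ("geneB", "chr2", 10, 20)

    def test_duplicated_symbol_on_two_chromosomes_keyed_separately(self, tmp_path):
        path = _gene_table(tmp_path, [("dup", "chr1", "+", 0, 10),
                                      ("dup", "chr1", "+", 5, 12),
                                      ("dup", "chr2", "+", 100, 110),
                                      ("solo", "chr1", "+", 50, 60),
                                      ("dup", "chr2", "+", 90, 105)])
        genes = read_gene_table(path)
        assert {g.key for g in genes} == {("dup", "chr1"), ("dup", "chr2"),
                                          ("solo", "chr1")}
        by_key = {g.key: g for g in genes}
        assert (by_key[("dup", "chr2")].start, by_key[("dup", "chr2")].end) == (90, 110)

    def test_union_is_idempotent(self, tmp_path):
        from archintro.core_io import write_gene_table
        path = _gene_table(tmp_path, [("geneA", "chr1", "+", 100, 200),
                                      ("geneA", "chr1", "+", 150, 300),
                                      ("geneC", "chr2", "+", 5, 9)])
        genes = read_gene_table(path)
        again = tmp_path / "again.tsv"
        write_gene_table(genes, again)
        spans = {(g.gene_id, g.chrom, g.start, g.end) for g in genes}
        assert {(g.gene_id, g.chrom, g.start, g.end)
                for g in read_gene_table(again)} == spans

    def test_missing_column_raises(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"name": ["x"], "chrom": ["chr1"]}).to_csv(path, sep="\t",
                                                                index=False)
        with pytest.raises(ValueError, match="txStart"):
            read_gene_table(path)

    def test_inverted_span_names_offending_row(self, tmp_path):
        path = _gene_table(tmp_path, [("ok", "chr1", "+", 0, 10),
                                      ("bad", "chr1", "+", 30, 20)])
        with pytest.raises(ValueError, match="1"):
            read_gene_table(path)


class TestPhasedVcf:
    def test_gt_decoding_and_coordinate_shift(self, tmp_path):
        path = write_vcf(tmp_path / "a.vcf",
                         "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
                         "chr1\t101\t.\tA\tG\t.\tPASS\t.\tGT\t0|1\n")
        cohort = read_phased_vcf(path)
        assert cohort.sites == [Site("chr1", 100, "A", "G")]
        assert list(cohort.genotypes[0, 0]) == [0, 1]  # copy0=A(ref), copy1=G(alt)

    def test_multiallelic_and_non_snp_sites_dropped(self, tmp_path):
        body = ("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
                "chr1\t10\t.\tA\tG\t.\tPASS\t.\tGT\t0|1\t0|0\t1|1\n"
                "chr1\t20\t.\tA\tG,T\t.\tPASS\t.\tGT\t0|1\t0|2\t0|0\n"
                "chr1\t30\t.\tC\tT\t.\tPASS\t.\tGT\t0|0\t0|1\t0|0\n"
                "chr1\t40\t.\tG\tA\t.\tPASS\t.\tGT\t1|0\t0|0\t0|0\n")
        cohort = read_phased_vcf(write_vcf(tmp_path / "m.vcf", body))
        assert cohort.n_sites == 3
        assert [s.pos for s in cohort.sites] == [9, 29, 39]

    def test_unphased_genotype_names_sample_and_site(self, tmp_path):
        body = ("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
                "chr1\t10\t.\tA\tG\t.\tPASS\t.\tGT\t0|1\t0/1\n")
        with pytest.raises(ValueError, match="S2.*chr1:10"):
            read_phased_vcf(write_vcf(tmp_path / "u.vcf", body))

    def test_sex_chromosome_sites_excluded_by_default(self, tmp_path):
        body = ("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
                "chr1\t10\t.\tA\tG\t.\tPASS\t.\tGT\t0|1\n"
                "chrX\t10\t.\tA\tG\t.\tPASS\t.\tGT\t0|1\n")
        path = write_vcf(tmp_path / "x.vcf", body)
        assert read_phased_vcf(path).n_sites == 1
        assert read_phased_vcf(path, autosomes_only=False).n_sites == 2

    def test_round_trip_preserves_everything(self, tmp_path, small_sim):
        out = tmp_path / "rt.vcf"
        write_phased_vcf(small_sim.case, out)
        back = read_phased_vcf(out)
        assert back.samples == small_sim.case.samples
        assert back.sites == small_sim.case.sites
        assert np.array_equal(back.genotypes, small_sim.case.genotypes)
        assert np.array_equal(back.somatic_flags, small_sim.case.somatic_flags)
        # and writing again is byte-identical
        out2 = tmp_path / "rt2.vcf"
        write_phased_vcf(back, out2)
        assert out.read_bytes() == out2.read_bytes()

    def test_info_somatic_flag_marks_alt_carrying_copies(self, tmp_path):
        body = ("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
                "chr1\t10\t.\tA\tG\t.\tPASS\tSOMATIC\tGT\t0|1\t0|0\n")
        cohort = read_phased_vcf(write_vcf(tmp_path / "s.vcf", body))
        assert cohort.somatic_flags[0, 0, 1] and not cohort.somatic_flags[0, 0, 0]
        assert not cohort.somatic_flags[1, 0].any()

    def test_merge_somatic_vcfs_assigns_single_alt_copy(self, tmp_path):
        body = ("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
                "chr1\t10\t.\tA\tG\t.\tPASS\t.\tGT\t1|0\t0|0\n"
                "chr1\t20\t.\tC\tT\t.\tPASS\t.\tGT\t0|0\t1|1\n")
        cohort = read_phased_vcf(write_vcf(tmp_path / "g.vcf", body))
        som = tmp_path / "s1_somatic.vcf"
        som.write_text("##fileformat=VCFv4.2\n##contig=<ID=chr1>\n"
                       "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
                       "chr1\t10\t.\tA\tG\t.\tPASS\t.\n")
        merged = merge_somatic_vcfs(cohort, {"S1": som})
        assert merged.somatic_flags[0, 0, 0]
        assert merged.somatic_flags.sum() == 1
        assert not cohort.somatic_flags.any()  # input untouched


class TestSiteAssignment:
    def test_start_inclusive_end_exclusive(self):
        gene = GeneModel("g", "chr1", 100, 300)
        sites = [Site("chr1", 100, "A", "G"), Site("chr1", 300, "A", "G")]
        mapping = assign_sites_to_genes(sites, {gene})
        assert mapping[gene] == [0]

    def test_matches_brute_force_on_random_overlapping_genes(self, rng):
        for _ in range(20):
            n_sites = int(rng.integers(1, 50))
            positions = rng.choice(1000, size=n_sites, replace=False)
            sites = [Site(rng.choice(["chr1", "chr2"]), int(p), "A", "C")
                     for p in positions]
            genes = set()
            for k in range(3):
                start = int(rng.integers(0, 900))
                genes.add(GeneModel(f"g{k}", str(rng.choice(["chr1", "chr2"])),
                                    start, start + int(rng.integers(10, 400))))
            got = assign_sites_to_genes(sites, genes)
            expected = intersect_brute(sites, genes)
            assert {g: got[g] for g in genes} == expected

    def test_gene_without_sites_maps_to_empty_list(self):
        gene = GeneModel("empty", "chr9", 0, 10)
        assert assign_sites_to_genes([Site("chr1", 5, "A", "G")], {gene}) == {gene: []}


class TestCohortInvariants:
    def test_somatic_flag_requires_alt_allele(self):
        with pytest.raises(ValueError, match="somatic flag"):
            PhasedCohort(samples=["s"], sites=[Site("chr1", 0, "A", "G")],
                         genotypes=np.zeros((1, 1, 2), dtype=np.int8),
                         somatic_flags=np.ones((1, 1, 2), dtype=bool))
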