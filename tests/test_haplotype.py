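"""Haplotype classification, gene contingencies, and the somatic ratio."""

import numpy as np
import pandas as pd
import pytest

from archintro import (GeneModel, PhasedCohort, Site, TagSNP,
                       build_gene_contingency, classify_copies,
                       cohort_rate_comparison, somatic_mutation_ratios)
from archintro.haplotype_analysis import test_gene_enrichment as gene_enrichment
from oracles import classify_brute, fisher_enum


def random_cohort(rng, n_samples=8, n_sites=30, missing_rate=0.1):
    """A cohort with arbitrary genotypes (not gene-block introgression) so
    classification has to work site by site."""
    positions = np.sort(rng.choice(1000, size=n_sites, replace=False))
    sites = [Site("chr1", int(p), "A", "G") for p in positions]
    genotypes = rng.integers(0, 2, size=(n_samples, n_sites, 2)).astype(np.int8)
    genotypes[rng.random(genotypes.shape) < missing_rate] = -1
    somatic = (genotypes == 1) & (rng.random(genotypes.shape) < 0.3)
    samples = [f"s{i}" for i in range(n_samples)]
    return PhasedCohort(samples=samples, sites=sites, genotypes=genotypes,
                        somatic_flags=somatic)


def tags_for(cohort, rng, fraction=0.5):
    tags = []
    for s in cohort.sites:
        if rng.random() < fraction:
            archaic = s.alt if rng.random() < 0.8 else s.ref
            modern = s.ref if archaic == s.alt else s.alt
            tags.append(TagSNP(site=s, archaic_allele=archaic, modern_allele=modern,
                               outgroup_freq=0.0,
                               archaic_match={"neanderthal": True}))
    return tags


GENES = {GeneModel("gA", "chr1", 0, 400), GeneModel("gB", "chr1", 300, 700),
         GeneModel("gC", "chr1", 650, 1000), GeneModel("gD", "chr2", 0, 500)}


class TestClassification:
    def test_one_matching_allele_suffices_for_neanderthal_label(self, rng):
        # 4 tag sites; copy 1 carries the archaic allele at exactly one
        sites = [Site("chr1", p, "A", "G") for p in (10, 20, 30, 40)]
        gt = np.zeros((1, 4, 2), dtype=np.int8)
        gt[0, 2, 1] = 1
        cohort = PhasedCohort(samples=["s0"], sites=sites, genotypes=gt)
        tags = [TagSNP(site=s, archaic_allele="G", modern_allele="A",
                       archaic_match={"neanderthal": True}) for s in sites]
        calls, _ = classify_copies(cohort, {GeneModel("g", "chr1", 0, 100)}, tags)
        by_copy = calls.set_index("copy")["label"]
        assert by_copy[0] == "modern" and by_copy[1] == "neanderthal"
        assert calls.set_index("copy")["n_matching"][1] == 1

    def test_matches_brute_force_scan_on_random_cohorts(self, rng):
        for _ in range(10):
            cohort = random_cohort(rng)
            tags = tags_for(cohort, rng)
            calls, _ = classify_copies(cohort, GENES, tags)
            expected = classify_brute(cohort, GENES, tags)
            got = {(r.sample, r.gene_id, r.chrom, r.copy):
                   (r.label, r.n_matching, r.somatic_count)
                   for r in calls.itertuples() if r.n_tag_sites > 0 or True}
            got = {k: v for k, v in got.items()
                   if (k[1], k[2]) in {(g.gene_id, g.chrom) for g in GENES
                                       if any(t.chrom == g.chrom
                                              and g.start <= t.pos < g.end
                                              for t in tags)}}
            assert got == expected

    def test_label_conservation_per_gene(self, rng):
        cohort = random_cohort(rng, n_samples=12)
        tags = tags_for(cohort, rng)
        calls, _ = classify_copies(cohort, GENES, tags)
        for _, sub in calls[calls.n_tag_sites > 0].groupby(["gene_id", "chrom"]):
            n_samples_with_data = sub["sample"].nunique()
            assert len(sub) == 2 * n_samples_with_data
            assert set(sub["label"]) <= {"neanderthal", "modern"}

    def test_gene_without_tag_sites_flagged_unclassifiable(self, rng):
        cohort = random_cohort(rng)
        tags = []  # no tags at all
        calls, unclassifiable = classify_copies(cohort, GENES, tags)
        assert unclassifiable == {g.key for g in GENES}
        assert (calls["label"] == "modern").all()
        assert (calls["n_tag_sites"] == 0).all()
        assert gene_enrichment(calls, unclassifiable=unclassifiable).empty


class TestContingency:
    def test_tallying_uses_binary_has_somatic(self):
        rows = ([("s%d" % i, "g", "chr1", 0, "neanderthal", 2, 1, 3 if i == 0 else 0,
                  i == 0, 100) for i in range(4)]
                + [("t%d" % i, "g", "chr1", 1, "modern", 2, 0, 1 if i < 2 else 0,
                    i < 2, 100) for i in range(6)])
        calls = pd.DataFrame(rows, columns=["sample", "gene_id", "chrom", "copy",
                                            "label", "n_tag_sites", "n_matching",
                                            "somatic_count", "has_somatic",
                                            "gene_length"])
        assert build_gene_contingency(calls) == (1, 3, 2, 4)

    def test_no_neanderthal_copies_degenerate_table(self):
        calls = pd.DataFrame([("s", "g", "chr1", 0, "modern", 1, 0, 1, True, 50),
                              ("s", "g", "chr1", 1, "modern", 1, 0, 0, False, 50)],
                             columns=["sample", "gene_id", "chrom", "copy", "label",
                                      "n_tag_sites", "n_matching", "somatic_count",
                                      "has_somatic", "gene_length"])
        assert build_gene_contingency(calls) == (0, 0, 1, 1)

    def test_random_fixture_equals_brute_tally(self, rng):
        cohort = random_cohort(rng, n_samples=10)
        tags = tags_for(cohort, rng)
        calls, _ = classify_copies(cohort, GENES, tags)
        for _, sub in calls[calls.n_tag_sites > 0].groupby(["gene_id", "chrom"]):
            a, b, c, d = build_gene_contingency(sub)
            nea = sub[sub.label == "neanderthal"]
            mod = sub[sub.label == "modern"]
            assert (a, b) == (int(nea.has_somatic.sum()), int((~nea.has_somatic).sum()))
            assert (c, d) == (int(mod.has_somatic.sum()), int((~mod.has_somatic).sum()))
            assert a + b + c + d == len(sub)


def _calls_for_table(a, b, c, d, gene="g"):
    rows = []
    for i in range(a + b):
        rows.append((f"n{i}", gene, "chr1", 0, "neanderthal", 1, 1,
                     int(i < a), i < a, 1000))
    for i in range(c + d):
        rows.append((f"m{i}", gene, "chr1", 1, "modern", 1, 0,
                     int(i < c), i < c, 1000))
    return pd.DataFrame(rows, columns=["sample", "gene_id", "chrom", "copy",
                                       "label", "n_tag_sites", "n_matching",
                                       "somatic_count", "has_somatic",
                                       "gene_length"])


class TestEnrichment:
    def test_gene_below_min_neanderthal_haplotypes_excluded(self):
        res4 = gene_enrichment(_calls_for_table(2, 2, 2, 8))
        res5 = gene_enrichment(_calls_for_table(2, 3, 2, 8))
        assert res4.empty and len(res5) == 1

    def test_identical_proportions_give_p_one_direction_none(self):
        res = gene_enrichment(_calls_for_table(5, 5, 5, 5))
        assert res.loc[0, "p"] == pytest.approx(1.0)
        assert res.loc[0, "direction"] == "none"

    def test_p_matches_hypergeometric_enumeration(self):
        res = gene_enrichment(_calls_for_table(8, 2, 2, 8))
        assert res.loc[0, "p"] == pytest.approx(fisher_enum(8, 2, 2, 8), rel=1e-9)
        assert res.loc[0, "direction"] == "neanderthal"

    def test_bonferroni_divisor_is_number_of_tested_genes(self):
        calls = pd.concat([_calls_for_table(8, 2, 2, 8, "g1"),
                           _calls_for_table(5, 5, 5, 5, "g2"),
                           _calls_for_table(1, 2, 2, 8, "g3")])  # g3 excluded
        res = gene_enrichment(calls)
        assert len(res) == 2
        assert res.set_index("gene_id").loc["g1", "p_adj"] == pytest.approx(
            min(1.0, 2 * fisher_enum(8, 2, 2, 8)))


class TestMutationRatio:
    def test_three_gene_hand_computation(self):
        # one sample; gene spans 1000, 2000, 3000 bp
        rows = [
            ("s", "g1", "chr1", 0, "neanderthal", 1, 1, 2, True, 1000),
            ("s", "g1", "chr1", 1, "modern", 1, 0, 1, True, 1000),
            ("s", "g2", "chr1", 0, "modern", 1, 0, 0, False, 2000),
            ("s", "g2", "chr1", 1, "neanderthal", 1, 1, 1, True, 2000),
            ("s", "g3", "chr1", 0, "modern", 1, 0, 2, True, 3000),
            ("s", "g3", "chr1", 1, "modern", 1, 0, 0, False, 3000),
        ]
        calls = pd.DataFrame(rows, columns=["sample", "gene_id", "chrom", "copy",
                                            "label", "n_tag_sites", "n_matching",
                                            "somatic_count", "has_somatic",
                                            "gene_length"])
        out = somatic_mutation_ratios(calls)
        r = out.iloc[0]
        # only g1 and g2 have an introgressed copy in the cohort, so g3 is
        # outside the introgressed-gene universe entirely.
        # by hand: m_nea = 2+1 = 3 over L_nea = 1000+2000 = 3000
        #          m_mod = 1+0 = 1 over L_mod = 1000+2000 = 3000
        assert (r.m_nea, r.L_nea, r.m_mod, r.L_mod) == (3, 3000, 1, 3000)
        assert r.ratio == pytest.approx((3 / 3000) / (1 / 3000))
        assert r.rate_nea_perMb == pytest.approx(1000.0)

    def test_zero_numerator_gives_ratio_zero(self):
        calls = _calls_for_table(0, 5, 3, 2)
        out = somatic_mutation_ratios(calls)
        # samples here have only one copy each; nea-only samples have no
        # modern length -> undefined; modern-only samples have no nea length
        assert out["ratio"].isna().all()

    def test_sample_without_neanderthal_copies_excluded_from_summaries(self):
        rows = [("s", "g1", "chr1", 0, "modern", 1, 0, 1, True, 1000),
                ("s", "g1", "chr1", 1, "modern", 1, 0, 0, False, 1000),
                ("t", "g1", "chr1", 0, "neanderthal", 1, 1, 1, True, 1000),
                ("t", "g1", "chr1", 1, "modern", 1, 0, 1, True, 1000)]
        calls = pd.DataFrame(rows, columns=["sample", "gene_id", "chrom", "copy",
                                            "label", "n_tag_sites", "n_matching",
                                            "somatic_count", "has_somatic",
                                            "gene_length"])
        out = somatic_mutation_ratios(calls).set_index("sample")
        assert np.isnan(out.loc["s", "ratio"])
        assert out.loc["t", "ratio"] == pytest.approx(1.0)

    def test_restriction_to_cohort_introgressed_genes(self):
        # g2 has no neanderthal copy anywhere -> its mutations never count
        rows = [("s", "g1", "chr1", 0, "neanderthal", 1, 1, 1, True, 1000),
                ("s", "g1", "chr1", 1, "modern", 1, 0, 1, True, 1000),
                ("s", "g2", "chr1", 0, "modern", 1, 0, 5, True, 1000),
                ("s", "g2", "chr1", 1, "modern", 1, 0, 5, True, 1000)]
        calls = pd.DataFrame(rows, columns=["sample", "gene_id", "chrom", "copy",
                                            "label", "n_tag_sites", "n_matching",
                                            "somatic_count", "has_somatic",
                                            "gene_length"])
        r = somatic_mutation_ratios(calls).iloc[0]
        assert (r.m_nea, r.m_mod) == (1, 1)


class TestRateComparison:
    def test_clear_excess_detected_one_sided(self):
        df = pd.DataFrame({"rate_nea_perMb": np.linspace(1.9, 2.1, 10),
                           "rate_mod_perMb": np.linspace(0.9, 1.1, 10)})
        out = cohort_rate_comparison(df, alternative="greater")
        assert out["test"].p < 0.05
        assert out["median_rate_nea_perMb"] > out["median_rate_mod_perMb"]

    def test_identical_rates_are_null(self):
        df = pd.DataFrame({"rate_nea_perMb": [1.0] * 10,
                           "rate_mod_perMb": [1.0] * 10})
        out = cohort_rate_comparison(df, alternative="greater")
        assert out["test"].p >= 0.5

    def test_paired_variant_available(self):
        df = pd.DataFrame({"rate_nea_perMb": [2.0, 2.1, 2.2, 1.9, 2.3],
                           "rate_mod_perMb": [1.0, 1.1, 1.2, 0.9, 1.3]})
        out = cohort_rate_comparison(df, alternative="greater", paired=True)
        assert out["test"].method == "signed-rank"
        assert out["test"].p < 0.05
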