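"""Post-processing: stats report, gene/case-control/inheritance filters, merge."""

import itertools

import numpy as np
import pytest

from varprio import (
    ConfigurationError,
    GeneList,
    Pedigree,
    PedigreeEntry,
    VPOL,
    ValidationError,
    filter_by_genes,
    filter_case_control,
    filter_inheritance,
    merge_vpols,
    stats,
)
from varprio.postprocess import nearest_rank_threshold

from conftest import make_record, make_variant

PROBAND, FATHER, MOTHER = "P", "FA", "MO"
TRIO_SAMPLES = [PROBAND, FATHER, MOTHER]


def trio_pedigree(father_affected=False):
    return Pedigree([
        PedigreeEntry("F0", PROBAND, FATHER, MOTHER, "1", "affected"),
        PedigreeEntry("F0", FATHER, "0", "0", "1",
                      "affected" if father_affected else "unaffected"),
        PedigreeEntry("F0", MOTHER, "0", "0", "2", "unaffected"),
    ])


def trio_vpol(codes, genes=None):
    """One record per (proband, father, mother) encoded-genotype combination."""
    records = []
    for i, (p, f, m) in enumerate(codes):
        gene = genes[i] if genes else f"G{i}"
        records.append(make_record(
            variant=make_variant(pos=i + 1, **{"Gene.refGene": gene}),
            raw=1, normalized=1.0,
            genotypes={PROBAND: p, FATHER: f, MOTHER: m},
        ))
    return VPOL(records=records, samples=list(TRIO_SAMPLES))


class TestStats:
    def test_nearest_rank_threshold_on_four_scores(self):
        # frozen from the nearest-rank definition: ceil(0.75*4) = 3rd smallest
        assert nearest_rank_threshold([1.0, 0.8, 0.5, 0.1], 75) == 0.8

    def test_report_lists_genes_of_carriers_above_threshold(self):
        records = [
            make_record(variant=make_variant(pos=1, **{"Gene.refGene": "HAAO"}),
                        raw=4, normalized=1.0, genotypes={"S1": "2", "S2": "0"}),
            make_record(variant=make_variant(pos=2, **{"Gene.refGene": "TTN"}),
                        raw=2, normalized=0.5, genotypes={"S1": "1", "S2": "1"}),
        ]
        report = stats(VPOL(records=records, samples=["S1", "S2"]), percentile=75)
        assert report.threshold == 1.0
        assert report.genes_by_sample == {"S1": ["HAAO"], "S2": []}
        assert report.carrier_counts == {"S1": 2, "S2": 1}

    def test_empty_vpol_yields_empty_report(self):
        report = stats(VPOL(records=[], samples=["S1"]))
        assert report.n_records == 0 and report.threshold is None
        assert report.genes_by_sample == {"S1": []}

    def test_sample_without_carried_variants_reports_no_genes(self):
        vpol = trio_vpol([("0", ".", "0")])
        report = stats(vpol)
        assert report.genes_by_sample[PROBAND] == []

    def test_percentile_outside_range_rejected(self):
        with pytest.raises(ConfigurationError):
            stats(trio_vpol([("1", "0", "0")]), percentile=0)


class TestGeneFilter:
    def test_full_gene_list_is_identity(self):
        vpol = trio_vpol([("1", "0", "0"), ("1", "1", "0")])
        genes = GeneList.from_iterable(["G0", "G1"])
        out = filter_by_genes(vpol, genes)
        assert [r.variant.site_id for r in out.records] == \
            [r.variant.site_id for r in vpol.records]
        assert [r.rank for r in out.records] == [1, 2]

    def test_multi_gene_cell_split_on_semicolon_and_comma(self):
        vpol = trio_vpol([("1", "0", "0")], genes=["NCR1;NCR2"])
        out = filter_by_genes(vpol, GeneList.from_iterable(["NCR2"]))
        assert len(out.records) == 1
        out2 = filter_by_genes(vpol, GeneList.from_iterable(["NCR3"]))
        assert len(out2.records) == 0

    def test_absent_gene_field_is_configuration_error(self):
        vpol = trio_vpol([("1", "0", "0")])
        with pytest.raises(ConfigurationError):
            filter_by_genes(vpol, GeneList.from_iterable(["G0"]), gene_field="Symbol")

    def test_single_gene_on_demo_table_returns_one_record(self, demo_tsv):
        from varprio import read_annotated_tsv
        variants, _, _ = read_annotated_tsv(demo_tsv)
        records = [make_record(variant=v) for v in variants]
        vpol = VPOL(records=records, samples=[])
        out = filter_by_genes(vpol, GeneList.from_iterable(["HAAO"]))
        assert len(out.records) == 1
        assert out.records[0].variant.annotations["Gene.refGene"] == "HAAO"


class TestCaseControl:
    CODES = ("0", "1", "2", ".")

    def test_truth_table_over_all_case_control_code_pairs(self):
        pedigree = Pedigree([
            PedigreeEntry("F", "CASE", "0", "0", "1", "affected"),
            PedigreeEntry("F", "CTRL", "0", "0", "1", "unaffected"),
        ])
        for case, ctrl in itertools.product(self.CODES, repeat=2):
            vpol = VPOL(
                records=[make_record(variant=make_variant(pos=1, **{"Gene.refGene": "G"}),
                                     genotypes={"CASE": case, "CTRL": ctrl})],
                samples=["CASE", "CTRL"],
            )
            kept = len(filter_case_control(vpol, pedigree).records) == 1
            # independent predicate: a carrying case, no carrying control;
            # "." never counts as carrying
            expected = case in "12" and ctrl not in "12"
            assert kept == expected, (case, ctrl)

    def test_no_affected_samples_is_configuration_error(self):
        pedigree = Pedigree([PedigreeEntry("F", "S", "0", "0", "1", "unaffected")])
        vpol = VPOL(records=[], samples=["S"])
        with pytest.raises(ConfigurationError):
            filter_case_control(vpol, pedigree)


def enumerate_trio_codes():
    return list(itertools.product("012.", repeat=3))


# independent truth tables, hand-written from the model definitions
def dn_expected(p, f, m):
    return p in "12" and f == "0" and m == "0"


def ar_expected(p, f, m):
    return p == "2" and f == "1" and m == "1"


def ad_expected(p, affected, unaffected):
    return p == "1" and affected == "1" and unaffected == "0"


class TestInheritance:
    def test_dn_ar_match_the_64_combination_truth_table(self):
        codes = enumerate_trio_codes()
        vpol = trio_vpol(codes)
        pedigree = trio_pedigree()
        for model, expected in (("DN", dn_expected), ("AR", ar_expected)):
            kept = {r.variant.pos for r in
                    filter_inheritance(vpol, pedigree, model).records}
            want = {i + 1 for i, (p, f, m) in enumerate(codes) if expected(p, f, m)}
            assert kept == want, model

    def test_ad_matches_truth_table_with_affected_father(self):
        codes = enumerate_trio_codes()
        vpol = trio_vpol(codes)
        pedigree = trio_pedigree(father_affected=True)
        kept = {r.variant.pos for r in
                filter_inheritance(vpol, pedigree, "AD").records}
        want = {i + 1 for i, (p, f, m) in enumerate(codes) if ad_expected(p, f, m)}
        assert kept == want

    def test_ad_without_a_single_affected_parent_is_an_error(self):
        vpol = trio_vpol([("1", "1", "0")])
        with pytest.raises(ConfigurationError):
            filter_inheritance(vpol, trio_pedigree(), "AD")

    def test_dn_ad_ar_are_pairwise_disjoint_on_clean_trios(self):
        clean = [c for c in enumerate_trio_codes() if "." not in c]
        assert len(clean) == 27
        for p, f, m in clean:
            hits = [dn_expected(p, f, m), ar_expected(p, f, m),
                    ad_expected(p, f, m) or ad_expected(p, m, f)]
            assert sum(hits) <= 1, (p, f, m)

    def test_incomplete_trio_is_configuration_error(self):
        vpol = trio_vpol([("1", "0", "0")])
        pedigree = Pedigree([
            PedigreeEntry("F0", PROBAND, "0", MOTHER, "1", "affected"),
            PedigreeEntry("F0", MOTHER, "0", "0", "2", "unaffected"),
        ])
        with pytest.raises(ConfigurationError):
            filter_inheritance(vpol, pedigree, "DN")

    def test_ch_agrees_with_bruteforce_pair_search(self):
        rng = np.random.default_rng(14)
        pedigree = trio_pedigree()
        for _ in range(200):
            n_genes = int(rng.integers(1, 4))
            codes, genes = [], []
            for g in range(n_genes):
                for _ in range(int(rng.integers(1, 5))):
                    codes.append(tuple(str(rng.choice(list("012.")))
                                       for _ in range(3)))
                    gene = f"CG{g}"
                    if rng.random() < 0.2:  # occasional multi-gene cell
                        gene += f";CG{int(rng.integers(n_genes))}"
                    genes.append(gene)
            vpol = trio_vpol(codes, genes=genes)
            kept = {r.variant.pos for r in
                    filter_inheritance(vpol, pedigree, "CH").records}

            # brute force over ordered pairs of records sharing a gene
            def pat(c):
                return c[0] == "1" and c[1] in "12" and c[2] == "0"

            def mat(c):
                return c[0] == "1" and c[2] in "12" and c[1] == "0"

            def gene_set(cell):
                return {g for part in cell.split(";") for g in part.split(",")}

            want = set()
            for i, ci in enumerate(codes):
                for j, cj in enumerate(codes):
                    if i == j:
                        continue
                    if gene_set(genes[i]) & gene_set(genes[j]) and pat(ci) and mat(cj):
                        want.add(i + 1)
                        want.add(j + 1)
            assert kept == want

    def test_filters_are_idempotent_and_preserve_scores(self):
        codes = enumerate_trio_codes()
        vpol = trio_vpol(codes)
        pedigree = trio_pedigree()
        once = filter_inheritance(vpol, pedigree, "DN")
        twice = filter_inheritance(once, pedigree, "DN")
        assert [r.variant.site_id for r in twice.records] == \
            [r.variant.site_id for r in once.records]
        assert all(r.raw_score == 1 and r.normalized_score == 1.0
                   for r in once.records)


class TestMerge:
    def _vpol(self, sample, raws, s_max=None):
        s_max = s_max or (max(raws) if raws else 0)
        records = [
            make_record(variant=make_variant(pos=i + 1, **{"Gene.refGene": "G"}),
                        raw=r, normalized=(r / s_max if s_max > 0 else 0.0),
                        genotypes={sample: "1"})
            for i, r in enumerate(raws)
        ]
        return VPOL(records=records, samples=[sample])

    def test_merge_of_one_vpol_is_identity_up_to_ranks(self):
        vpol = self._vpol("S1", [4, 2])
        merged = merge_vpols([vpol])
        assert [r.variant.site_id for r in merged.records] == \
            [r.variant.site_id for r in vpol.records]
        assert [r.raw_score for r in merged.records] == [4, 2]

    def test_absent_sites_fill_reference_and_scores_renormalize(self):
        a = self._vpol("S1", [4, 2])
        b = VPOL(records=[make_record(
            variant=make_variant(pos=9, **{"Gene.refGene": "G"}),
            raw=8, normalized=1.0, genotypes={"S2": "2"})], samples=["S2"])
        merged = merge_vpols([a, b])
        assert merged.samples == ["S1", "S2"]
        top = merged.records[0]
        assert top.raw_score == 8 and top.normalized_score == 1.0
        assert top.encoded_genotypes == {"S1": "0", "S2": "2"}
        # the site unique to `a` renormalizes against the merged maximum
        assert merged.records[1].normalized_score == 0.5

    def test_shared_sample_name_rejected(self):
        with pytest.raises(ValidationError):
            merge_vpols([self._vpol("S1", [1]), self._vpol("S1", [1])])

    def test_conflicting_raw_scores_rejected_naming_the_site(self):
        a = self._vpol("S1", [4])
        b = self._vpol("S2", [5])
        with pytest.raises(ValidationError, match="site"):
            merge_vpols([a, b])

    def test_merge_is_order_insensitive(self):
        a = self._vpol("S1", [4, 2])
        b = self._vpol("S2", [4, 2])
        ab = merge_vpols([a, b])
        ba = merge_vpols([b, a])
        assert [r.variant.site_id for r in ab.records] == \
            [r.variant.site_id for r in ba.records]
        assert [r.encoded_genotypes for r in ab.records] == \
            [r.encoded_genotypes for r in ba.records]
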