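"""Cohort I/O, interval overlap annotation and event-rate summaries."""

import numpy as np
import pandas as pd
import pytest

from subgofa import (
    CohortError,
    GeneTrack,
    Region,
    SampleRecord,
    annotate_sample,
    event_frequency_summary,
    read_cohort,
    read_gene2go,
    restrict_term_set,
)

from conftest import make_toy_dag


@pytest.fixture
def toy_track():
    return GeneTrack(pd.DataFrame(
        [("chr1", 300, 400, "g1"), ("chr1", 450, 600, "g2"), ("chr2", 100, 200, "g3")],
        columns=["chrom", "start", "end", "symbol"],
    ))


def write(path, text):
    path.write_text(text)
    return path


class TestReadCohort:
    def test_readback_counts(self, tmp_path):
        pheno = write(tmp_path / "p.tsv",
                      "sample_id\tlabel\tsex\tage\n"
                      "s1\tcase\tF\t61\ns2\tcase\tM\t70\ns3\tctrl\tF\t66\n")
        regions = write(tmp_path / "r.bed",
                        "chr1\t100\t500\ts1\nchr2\t0\t100\ts1\n"
                        "chr1\t10\t20\ts2\nchr1\t30\t40\ts2\nchr3\t5\t6\ts3\n")
        cohort = read_cohort(regions, pheno)
        assert [len(r.regions) for r in cohort] == [2, 2, 1]
        assert cohort[0].label == "case" and cohort[2].label == "ctrl"

    def test_sample_without_regions_kept(self, tmp_path):
        pheno = write(tmp_path / "p.tsv",
                      "sample_id\tlabel\tsex\tage\ns1\tcase\tF\t61\ns2\tctrl\tM\t70\n")
        regions = write(tmp_path / "r.bed", "chr1\t100\t500\ts1\n")
        cohort = read_cohort(regions, pheno)
        assert cohort[1].regions == []

    def test_bad_coordinates_name_the_line(self, tmp_path):
        pheno = write(tmp_path / "p.tsv", "sample_id\tlabel\tsex\tage\ns1\tcase\tF\t61\n")
        regions = write(tmp_path / "r.bed", "chr1\t100\t500\ts1\nchr1\t700\t600\ts1\n")
        with pytest.raises(CohortError, match="line 2"):
            read_cohort(regions, pheno)

    def test_unknown_sample_in_regions(self, tmp_path):
        pheno = write(tmp_path / "p.tsv", "sample_id\tlabel\tsex\tage\ns1\tcase\tF\t61\n")
        regions = write(tmp_path / "r.bed", "chr1\t100\t500\tsX\n")
        with pytest.raises(CohortError, match="sX"):
            read_cohort(regions, pheno)

    def test_unknown_label_rejected(self, tmp_path):
        pheno = write(tmp_path / "p.tsv", "sample_id\tlabel\tsex\tage\ns1\tpatient\tF\t61\n")
        regions = write(tmp_path / "r.bed", "chr1\t100\t500\ts1\n")
        with pytest.raises(CohortError, match="patient"):
            read_cohort(regions, pheno)

    def test_one_based_conversion(self, tmp_path):
        pheno = write(tmp_path / "p.tsv", "sample_id\tlabel\tsex\tage\ns1\tcase\tF\t61\n")
        regions = write(tmp_path / "r.bed", "chr1\t101\t500\ts1\n")
        cohort = read_cohort(regions, pheno, one_based=True)
        assert cohort[0].regions[0].start == 100


class TestAnnotateSample:
    def _record(self, regions):
        return SampleRecord(sample_id="s", label="case", regions=regions)

    def test_contained_gene_collected(self, toy_track):
        dag = make_toy_dag()
        rec = annotate_sample(self._record([Region("chr1", 100, 500)]),
                              toy_track, {"g1": {"c"}}, dag)
        assert "c" in rec.term_set and "g1" in rec.genes

    def test_boundary_straddling_gene_included(self, toy_track):
        dag = make_toy_dag()
        rec = annotate_sample(self._record([Region("chr1", 100, 500)]),
                              toy_track, {"g2": {"e"}}, dag)
        assert rec.genes == {"g1", "g2"}  # g2 overlaps [450,500) by 50 bp
        assert rec.term_set == {"e"}

    def test_no_regions_empty_sets(self, toy_track):
        dag = make_toy_dag()
        rec = annotate_sample(self._record([]), toy_track, {"g1": {"c"}}, dag)
        assert rec.term_set == frozenset() and rec.genes == frozenset()

    def test_order_independence(self, toy_track):
        dag = make_toy_dag()
        regions = [Region("chr1", 100, 500), Region("chr2", 50, 150)]
        g2go = {"g1": {"c"}, "g2": {"d"}, "g3": {"e"}}
        fwd = annotate_sample(self._record(regions), toy_track, g2go, dag)
        rev = annotate_sample(self._record(regions[::-1]), toy_track, g2go, dag)
        assert fwd.term_set == rev.term_set and fwd.genes == rev.genes

    def test_union_over_single_region_subsamples(self, toy_track):
        dag = make_toy_dag()
        regions = [Region("chr1", 100, 500), Region("chr2", 50, 150)]
        g2go = {"g1": {"c"}, "g2": {"d"}, "g3": {"e"}}
        whole = annotate_sample(self._record(regions), toy_track, g2go, dag)
        parts = [annotate_sample(self._record([r]), toy_track, g2go, dag)
                 for r in regions]
        assert whole.term_set == frozenset().union(*(p.term_set for p in parts))


class TestRestrictAndSummaries:
    def test_restrict_term_set(self, toy_dag):
        sub_a = toy_dag.subgo("a")
        assert restrict_term_set({"c", "e"}, sub_a) == {"c"}
        assert restrict_term_set({"e", "b"}, sub_a) == frozenset()
        assert restrict_term_set({"c", "e"}, toy_dag.subgo("r")) == {"c", "e"}

    def test_event_rate_normalisation(self):
        cohort = [
            SampleRecord("s1", "case", regions=[Region("chr1", 0, 10), Region("chr1", 20, 30)]),
            SampleRecord("s2", "ctrl", regions=[Region("chr2", 0, 10)]),
        ]
        table = event_frequency_summary(cohort, {"chr1": 1_000_000_000, "chr2": 500_000_000})
        assert table.loc["chr1", "case"] == pytest.approx(2.0)
        assert table.loc["chr2", "ctrl"] == pytest.approx(2.0)
        assert table.loc["chr2", "case"] == 0.0

    def test_missing_chromosome_length_is_error(self):
        cohort = [SampleRecord("s1", "case", regions=[Region("chrX", 0, 10)])]
        with pytest.raises(CohortError, match="chrX"):
            event_frequency_summary(cohort, {"chr1": 1_000_000_000})

    def test_empty_cohort_all_zero(self):
        table = event_frequency_summary([], {"chr1": 1_000_000_000})
        assert (table.values == 0).all()


class TestGene2GoReader:
    def test_two_column_tsv(self, tmp_path):
        path = write(tmp_path / "map.tsv", "g1\tc\ng1\td\ng2\te\n")
        assert read_gene2go(path) == {"g1": {"c", "d"}, "g2": {"e"}}

    def test_gaf_with_not_qualifier(self, tmp_path):
        cols = ["DB", "ID1", "SYM", "", "GO:0000004", "REF", "IEA",
                "", "P", "", "", "protein", "taxon:9606", "20200101", "DB", "", ""]
        lines = ["!gaf-version: 2.1"]
        row = cols.copy(); row[2] = "g1"
        lines.append("\t".join(row))
        row2 = cols.copy(); row2[2] = "g2"; row2[3] = "NOT"; row2[4] = "GO:0000005"
        lines.append("\t".join(row2))
        path = write(tmp_path / "map.gaf", "\n".join(lines) + "\n")
        assert read_gene2go(path) == {"g1": {"GO:0000004"}}

    def test_unknown_terms_dropped_against_dag(self, tmp_path, toy_dag):
        path = write(tmp_path / "map.tsv", "g1\tc\ng1\tnope\ng2\tnope\n")
        assert read_gene2go(path, toy_dag) == {"g1": {"c"}}
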