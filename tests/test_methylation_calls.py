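"""Call-table ingestion and methylation aggregation."""

import numpy as np
import pandas as pd
import pytest

from rlmeth import (
    AnalysisError,
    InputError,
    STUDY_MOTIFS,
    compare_conditions,
    genome_base_methylation,
    motif_methylation,
    read_calls,
    scan,
    site_fraction,
    window_profile,
)
from rlmeth.methylation_calls import MethylationTable, windows_to_bedgraph
from rlmeth.synthetic_data import make_genome

from conftest import make_table

GANTC, GATC, GGCGCC = STUDY_MOTIFS


class TestReadCalls:
    def test_simple_tsv_round_trip(self, toy_assembly, tmp_path):
        path = tmp_path / "calls.tsv"
        path.write_text(
            "replicon\tposition\tstrand\tbase\tmod_type\tcoverage\tmodified\n"
            "chr\t10\t+\tA\t6mA\t20\t15\n"
        )
        table = read_calls(path, toy_assembly, "simple_tsv", condition="x")
        assert len(table) == 1
        row = table.sites.iloc[0]
        assert site_fraction(row.coverage, row.modified) == pytest.approx(75.0)

    def test_modified_exceeding_coverage_dropped(self, toy_assembly,
                                                 tmp_path, caplog):
        path = tmp_path / "calls.tsv"
        path.write_text(
            "replicon\tposition\tstrand\tbase\tmod_type\tcoverage\tmodified\n"
            "chr\t10\t+\tA\t6mA\t20\t21\n"
            "chr\t11\t+\tA\t6mA\t20\t5\n"
        )
        with caplog.at_level("WARNING"):
            table = read_calls(path, toy_assembly, "simple_tsv")
        assert len(table) == 1
        assert "rejected 1" in caplog.text

    def test_unknown_replicon_dropped(self, toy_assembly, tmp_path):
        path = tmp_path / "calls.tsv"
        path.write_text(
            "replicon\tposition\tstrand\tbase\tmod_type\tcoverage\tmodified\n"
            "mystery\t10\t+\tA\t6mA\t20\t5\n"
        )
        assert len(read_calls(path, toy_assembly, "simple_tsv")) == 0

    def test_malformed_line_reported_with_number(self, toy_assembly,
                                                 tmp_path):
        path = tmp_path / "calls.tsv"
        path.write_text(
            "replicon\tposition\tstrand\tbase\tmod_type\tcoverage\tmodified\n"
            "chr\tten\t+\tA\t6mA\t20\t5\n"
        )
        with pytest.raises(InputError, match="line 2"):
            read_calls(path, toy_assembly, "simple_tsv")

    def test_bedmethyl_modified_from_percent(self, toy_assembly, tmp_path):
        path = tmp_path / "calls.bed"
        path.write_text("chr\t10\t11\t6mA\t0\t+\t10\t11\t0,0,0\t10\t50\n")
        table = read_calls(path, toy_assembly, "bedmethyl")
        assert table.sites.iloc[0].modified == 5
        assert table.sites.iloc[0].base == "A"

    def test_unknown_dialect_rejected(self, toy_assembly, tmp_path):
        path = tmp_path / "calls.tsv"
        path.write_text("x\n")
        with pytest.raises(InputError, match="dialect"):
            read_calls(path, toy_assembly, "parquet")


class TestSiteFraction:
    @pytest.mark.parametrize("coverage,modified,expected", [
        (10, 10, 100.0),
        (10, 0, 0.0),
        (5, 2, 40.0),  # exactly at the default threshold: included
    ])
    def test_included(self, coverage, modified, expected):
        assert site_fraction(coverage, modified) == pytest.approx(expected)

    @pytest.mark.parametrize("coverage,modified", [(0, 0), (4, 2)])
    def test_under_threshold_excluded(self, coverage, modified):
        assert site_fraction(coverage, modified, min_coverage=5) is None


class TestGenomeBaseMethylation:
    def test_unweighted_mean_across_sites(self, toy_assembly):
        # one site at 0% with huge coverage, one at 100% with tiny coverage
        table = make_table("t", [
            ("chr", 1, "+", "A", "6mA", 1000, 0),
            ("chr", 9, "+", "A", "6mA", 10, 10),
        ])
        out = genome_base_methylation(table, toy_assembly, "A")
        genome = out[out.replicon == "genome"].iloc[0]
        assert genome.mean_percent == pytest.approx(50.0)
        assert genome.n_sites == 2

    def test_no_sites_is_signaled(self, toy_assembly):
        table = make_table("t", [("chr", 1, "+", "A", "6mA", 2, 1)])
        with pytest.raises(AnalysisError):
            genome_base_methylation(table, toy_assembly, "C")

    def test_binomial_sampling_recovers_mean(self, toy_assembly, rng):
        # per-site fractions Binomial(30, 0.75)/30 concentrate at 75
        n = 20_000
        rows = [("chr", i % 1000, "+", "A", "6mA", 30,
                 int(rng.binomial(30, 0.75))) for i in range(n)]
        df = pd.DataFrame(rows, columns=["replicon", "position", "strand",
                                         "base", "mod_type", "coverage",
                                         "modified"])
        table = MethylationTable("t", df)
        out = genome_base_methylation(table, toy_assembly, "A")
        genome = out[out.replicon == "genome"].iloc[0]
        assert genome.mean_percent == pytest.approx(75.0, abs=1.0)

    def test_threshold_irrelevant_at_uniform_coverage(self, toy_assembly,
                                                      uniform_table):
        lo = genome_base_methylation(uniform_table, toy_assembly, "A",
                                     min_coverage=1)
        hi = genome_base_methylation(uniform_table, toy_assembly, "A",
                                     min_coverage=10)
        pd.testing.assert_frame_equal(lo, hi)


class TestWindowProfile:
    def test_uniform_sites_give_uniform_windows(self, toy_assembly,
                                                uniform_table):
        prof = window_profile(uniform_table, toy_assembly, "A",
                              width=100, step=50)
        filled = prof.dropna(subset=["percent_methylated"])
        assert filled.percent_methylated.to_numpy() == pytest.approx(50.0)

    def test_window_count_tiling(self, toy_assembly, uniform_table):
        prof = window_profile(uniform_table, toy_assembly, "A",
                              width=500, step=500)
        chrom = prof[prof.replicon == "chr"]
        assert len(chrom) == 2  # toy chr is 1000 bp
        assert list(chrom.window_end) == [500, 1000]

    def test_empty_windows_emitted_with_zero_sites(self, toy_assembly):
        table = make_table("t", [("chr", 5, "+", "A", "6mA", 10, 5)])
        prof = window_profile(table, toy_assembly, "A", width=100, step=100)
        chrom = prof[prof.replicon == "chr"]
        assert chrom.iloc[0].n_sites == 1
        assert (chrom.iloc[1:].n_sites == 0).all()
        assert chrom.iloc[1:].percent_methylated.isna().all()

    def test_matches_brute_force_recomputation(self, rng):
        asm = make_genome({"chr": 30_000}, 61.0, seed=2)
        n = 3000
        pos = np.sort(rng.choice(30_000, size=n, replace=False))
        cov = rng.poisson(30, size=n) + 1
        mod = rng.binomial(cov, 0.5)
        df = pd.DataFrame({"replicon": "chr", "position": pos, "strand": "+",
                           "base": "A", "mod_type": "6mA", "coverage": cov,
                           "modified": mod})
        table = MethylationTable("t", df)
        prof = window_profile(table, asm, "A", width=5000, step=1000,
                              min_coverage=5)
        frac = 100.0 * mod / cov
        ok = cov >= 5
        for row in prof.itertuples(index=False):
            in_win = ok & (pos >= row.window_start) & (pos < row.window_end)
            assert row.n_sites == int(in_win.sum())
            if row.n_sites:
                assert row.percent_methylated == pytest.approx(
                    float(frac[in_win].mean()))

    def test_aggregation_linearity(self, toy_assembly, rng):
        """Genome mean equals the site-weighted mean of tiling windows."""
        rows = [("chr", int(p), "+", "A", "6mA", 20, int(rng.binomial(20, .4)))
                for p in rng.choice(1000, size=300, replace=False)]
        table = make_table("t", rows)
        gbm = genome_base_methylation(table, toy_assembly, "A")
        overall = float(gbm[gbm.replicon == "genome"].mean_percent.iloc[0])
        prof = window_profile(table, toy_assembly, "A", width=100, step=100)
        chrom = prof[(prof.replicon == "chr") & (prof.n_sites > 0)]
        weighted = float((chrom.percent_methylated * chrom.n_sites).sum()
                         / chrom.n_sites.sum())
        assert weighted == pytest.approx(overall)

    def test_bedgraph_skips_empty_windows(self, toy_assembly, tmp_path):
        table = make_table("t", [("chr", 5, "+", "A", "6mA", 10, 5)])
        prof = window_profile(table, toy_assembly, "A", width=100, step=100)
        out = tmp_path / "w.bedgraph"
        windows_to_bedgraph(prof, out)
        lines = out.read_text().strip().split("\n")
        assert lines == ["chr\t0\t100\t50.00"]


class TestMotifMethylation:
    def test_palindromic_strands_are_two_observations(self, toy_assembly):
        # toy chr starts with GATC at 0: + strand C at 3, - strand C at 0
        table = make_table("t", [
            ("chr", 3, "+", "C", "4mC", 10, 10),
            ("chr", 0, "-", "C", "4mC", 10, 0),
        ])
        occs = [o for o in scan(toy_assembly, GATC) if o.start == 0]
        out = motif_methylation(table, occs, toy_assembly)
        genome = out[(out.motif == "GATC") & (out.replicon == "genome")]
        assert genome.iloc[0].n_sites_used == 2
        assert genome.iloc[0].mean_percent == pytest.approx(50.0)

    def test_low_coverage_observations_excluded(self, toy_assembly):
        table = make_table("t", [
            ("chr", 3, "+", "C", "4mC", 3, 3),
            ("chr", 0, "-", "C", "4mC", 2, 0),
            ("chr", 7, "+", "C", "4mC", 10, 10),  # second GATC locus
            ("chr", 4, "-", "C", "4mC", 10, 10),
        ])
        occs = [o for o in scan(toy_assembly, GATC) if o.start in (0, 4)]
        out = motif_methylation(table, occs, toy_assembly)
        genome = out[(out.motif == "GATC") & (out.replicon == "genome")]
        assert genome.iloc[0].n_sites_used == 2

    def test_missing_mod_type_signaled(self, toy_assembly):
        table = make_table("t", [("chr", 3, "+", "A", "6mA", 10, 10)])
        occs = scan(toy_assembly, GATC)
        with pytest.raises(AnalysisError, match="4mC"):
            motif_methylation(table, occs, toy_assembly)

    def test_background_attached_from_genome_average(self, toy_assembly,
                                                     uniform_table):
        occs = scan(toy_assembly, GATC)
        out = motif_methylation(uniform_table, occs, toy_assembly)
        assert out.background_percent.to_numpy() == pytest.approx(50.0)

    def test_covering_motif_equals_genome_average(self, toy_assembly,
                                                  uniform_table):
        """A motif whose sites cover all C bases reproduces the C average.

        On the toy chromosome (GATCGATCAA repeats) the GATC modified
        sites are exactly the C calls on both strands.
        """
        occs = [o for o in scan(toy_assembly, GATC) if o.replicon == "chr"]
        out = motif_methylation(uniform_table, occs, toy_assembly)
        row = out[(out.motif == "GATC") & (out.replicon == "genome")].iloc[0]
        c_avg = genome_base_methylation(uniform_table, toy_assembly, "C")
        expected = float(
            c_avg[c_avg.replicon == "genome"].mean_percent.iloc[0])
        c_total = int(c_avg[c_avg.replicon == "genome"].n_sites.iloc[0])
        assert row.mean_percent == pytest.approx(expected)
        assert row.n_sites_used == c_total


class TestCompareConditions:
    def summaries(self, toy_assembly, mods_a, mods_b):
        occs = [o for o in scan(toy_assembly, GATC) if o.start == 0]
        tables = {}
        for cond, (m_plus, m_minus) in (("a", mods_a), ("b", mods_b)):
            tables[cond] = make_table(cond, [
                ("chr", 3, "+", "C", "4mC", 10, m_plus),
                ("chr", 0, "-", "C", "4mC", 10, m_minus),
            ])
        return {cond: motif_methylation(t, occs, toy_assembly)
                for cond, t in tables.items()}

    def test_identical_conditions_zero_difference(self, toy_assembly):
        out = compare_conditions(self.summaries(toy_assembly, (5, 5), (5, 5)))
        assert out.difference.dropna().to_numpy() == pytest.approx(0.0)
        assert out.pooled_difference.dropna().to_numpy() == pytest.approx(0.0)

    def test_planted_difference_recovered(self, toy_assembly):
        out = compare_conditions(
            self.summaries(toy_assembly, (10, 10), (4, 4)))
        genome = out[out.replicon == "genome"]
        assert genome.difference.iloc[0] == pytest.approx(60.0)

    def test_single_condition_rejected(self, toy_assembly):
        with pytest.raises(AnalysisError, match=">= 2"):
            compare_conditions({"only": pd.DataFrame()})
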