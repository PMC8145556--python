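import numpy as np
import pandas as pd
import pytest

from isoqc import typing as typ
from isoqc import simulate_benchmark as sb
from isoqc.qc_engine import MetricThreshold, ThresholdSet


class TestSimulateGenome:
    def test_gc_concentrates_on_target(self):
        g = sb.simulate_genome(200_000, 0.30, 100, 1000, seed=1)
        gc = sum(b in "GC" for b in g.seq) / len(g.seq)
        assert gc == pytest.approx(0.30, abs=0.01)

    def test_deterministic_per_seed(self):
        a = sb.simulate_genome(20_000, 0.5, 10, 1000, seed=3)
        b = sb.simulate_genome(20_000, 0.5, 10, 1000, seed=3)
        assert a.seq == b.seq

    def test_infeasible_layout_error(self):
        with pytest.raises(ValueError):
            sb.simulate_genome(5_000, 0.5, 10, 1000, seed=1)

    def test_gene_layout_non_overlapping(self):
        g = sb.simulate_genome(20_000, 0.5, 10, 1000, seed=4)
        for (_, s1, e1), (_, s2, _) in zip(g.core_genes, g.core_genes[1:]):
            assert e1 <= s2


class TestSimulateRelative:
    @pytest.mark.parametrize("target_ad", [0, 2, 4, 6, 7, 10])
    def test_allele_distance_recovered_exactly(self, target_ad):
        g = sb.simulate_genome(40_000, 0.5, 20, 1000, seed=5)
        for seed in range(20):
            rel = sb.simulate_relative(g, target_ad, seed=seed)
            scheme = sb.core_scheme_from_taxa([g, rel])
            ad = typ.allele_distance(
                sb.allele_profile(g, scheme), sb.allele_profile(rel, scheme)
            )
            assert ad == target_ad

    def test_categories_follow_distance(self):
        g = sb.simulate_genome(40_000, 0.5, 20, 1000, seed=6)
        for ad, expected in [(0, "close"), (4, "intermediate"), (7, "distant")]:
            rel = sb.simulate_relative(g, ad, seed=1)
            scheme = sb.core_scheme_from_taxa([g, rel])
            d = typ.allele_distance(
                sb.allele_profile(g, scheme), sb.allele_profile(rel, scheme)
            )
            same_st = d == 0
            assert typ.categorize_relatedness(same_st, d) == expected

    def test_non_gene_sequence_untouched(self):
        g = sb.simulate_genome(40_000, 0.5, 20, 1000, seed=7)
        rel = sb.simulate_relative(g, 5, seed=2)
        _, _, end_last = g.core_genes[-1]
        assert g.seq[end_last:] == rel.seq[end_last:]


class TestSimulateReads:
    def test_base_total_matches_coverage(self):
        g = sb.simulate_genome(100_000, 0.5, 10, 1000, seed=8)
        reads = sb.simulate_reads(g, coverage=50, seed=1)
        assert reads.n_bases == pytest.approx(5_000_000, abs=300)

    def test_zero_error_reads_are_exact_substrings(self):
        from isoqc._kmers import revcomp

        g = sb.simulate_genome(20_000, 0.5, 10, 1000, seed=9)
        reads = sb.simulate_reads(g, coverage=1, error_rate=0.0, seed=2)
        both = g.seq + "#" + revcomp(g.seq)
        for rec in list(reads)[:50]:
            assert rec.seq in both

    def test_quality_mixture_mean_error_matches(self):
        g = sb.simulate_genome(50_000, 0.5, 10, 1000, seed=10)
        reads = sb.simulate_reads(g, coverage=20, error_rate=0.01, seed=3)
        implied = np.mean(10 ** (-reads.quals.astype(float) / 10))
        assert implied == pytest.approx(0.01, rel=0.05)

    def test_plasmid_read_share_follows_copy_number(self):
        g = sb.simulate_genome(30_000, 0.5, 10, 1000, seed=11)
        sb.add_plasmid(g, length=1500, copy_number=10, label="D d1", seed=12)
        reads = sb.simulate_reads(g, coverage=20, seed=4)
        # 15 kb effective plasmid vs 30 kb chromosome -> 1/3 of bases
        expected = 45_000 * 20 / 150
        assert len(reads) == pytest.approx(expected, rel=0.01)

    def test_deterministic(self):
        g = sb.simulate_genome(20_000, 0.5, 10, 1000, seed=13)
        a = sb.simulate_reads(g, coverage=5, seed=5)
        b = sb.simulate_reads(g, coverage=5, seed=5)
        assert np.array_equal(a.codes, b.codes)
        assert np.array_equal(a.quals, b.quals)


class TestMixReads:
    @pytest.fixture(scope="class")
    def pools(self):
        g1 = sb.simulate_genome(20_000, 0.4, 10, 1000, seed=14)
        g2 = sb.simulate_genome(20_000, 0.6, 10, 1000, seed=15)
        return (
            sb.simulate_reads(g1, coverage=20, seed=6),
            sb.simulate_reads(g2, coverage=20, seed=7),
        )

    def test_contaminant_count_exact(self):
        from isoqc.seqio import ReadSet

        subject = ReadSet(
            np.zeros((5000, 50), dtype=np.uint8), np.full((5000, 50), 40, np.uint8)
        )
        contaminant = ReadSet(
            np.ones((5000, 50), dtype=np.uint8), np.full((5000, 50), 40, np.uint8)
        )
        mix = sb.mix_reads(subject, contaminant, 0.2, total_reads=1000, seed=1)
        assert len(mix) == 1000
        assert int((mix.codes[:, 0] == 1).sum()) == 200  # floor(0.2 * 1000)

    def test_zero_ratio_identity(self, pools):
        s, _ = pools
        mix = sb.mix_reads(s, s, 0.0, total_reads=500, seed=2)
        assert len(mix) == 500

    def test_insufficient_reads_error(self, pools):
        s, c = pools
        with pytest.raises(ValueError):
            sb.mix_reads(s, c, 0.5, total_reads=10 * len(s), seed=3)


class TestPseudoAssemble:
    @pytest.fixture(scope="class")
    def subject(self):
        return sb.simulate_genome(40_000, 0.5, 20, 1000, seed=16)

    def test_self_sample_tiles_genome_exactly(self, subject):
        spec = sb.MixtureSpec(subject, None, 0.0, "self", coverage=50, seed=1)
        contigs = sb.pseudo_assemble(spec)
        assert "".join(c.seq for c in contigs) == subject.seq

    def test_low_ratio_contaminant_absent(self, subject):
        rel = sb.simulate_relative(subject, 10, seed=3)
        # 5% of 50x = 2.5x effective coverage, below the 10x inclusion bar
        spec = sb.MixtureSpec(subject, rel, 0.05, "intragenus", coverage=50, seed=2)
        contigs = sb.pseudo_assemble(spec)
        assert not any(c.id.startswith("contam") for c in contigs)

    def test_high_ratio_contaminant_present(self, subject):
        rel = sb.simulate_relative(subject, 10, seed=3)
        spec = sb.MixtureSpec(subject, rel, 0.30, "intragenus", coverage=50, seed=2)
        contigs = sb.pseudo_assemble(spec)
        extra = [c for c in contigs if c.id.startswith("contam")]
        assert len(extra) == 10  # one divergent gene copy per changed allele

    def test_intergenus_contaminant_contributes_whole_genome(self, subject):
        other = sb.simulate_genome(40_000, 0.6, 20, 1000, seed=17, genus="Genus9")
        spec = sb.MixtureSpec(subject, other, 0.30, "intergenus", coverage=50, seed=4)
        contigs = sb.pseudo_assemble(spec)
        contam_len = sum(len(c.seq) for c in contigs if c.id.startswith("contam"))
        assert contam_len == len(other.seq)

    def test_cuts_avoid_core_genes(self, subject):
        spec = sb.MixtureSpec(subject, None, 0.0, "self", coverage=50, seed=5)
        contigs = sb.pseudo_assemble(spec)
        text = "#".join(c.seq for c in contigs)
        for i in range(len(subject.core_genes)):
            assert subject.gene_seq(i) in text

    def test_plasmids_emitted_once(self, subject):
        host = sb.simulate_genome(30_000, 0.5, 10, 1000, seed=18)
        sb.add_plasmid(host, length=2000, copy_number=10, label="D d1", seed=19)
        spec = sb.MixtureSpec(host, None, 0.0, "self", coverage=50, seed=6)
        contigs = sb.pseudo_assemble(spec)
        plasmid_contigs = [c for c in contigs if host.plasmids[0].seq == c.seq]
        assert len(plasmid_contigs) == 1


class TestRunPanel:
    @pytest.fixture(scope="class")
    def tiny_cfg(self):
        return sb.PanelConfig(
            n_genera=2,
            genome_length=20_000,
            n_core_genes=10,
            gene_len=1000,
            gc_targets=(0.40, 0.60),
            ratios=(0.10, 0.30),
            replicates=1,
        )

    def test_row_combinatorics(self, tiny_cfg):
        table = sb.run_panel(tiny_cfg, seed=2, metrics=["gc_percent"])
        # per genus: 1 self + 2 ratios x (1 other genus + 3 distances)
        expected = 2 * (1 + 2 * (1 + 3))
        assert len(table) == expected
        assert (table["kind"] == "self").sum() == 2

    def test_deterministic_per_seed(self, tiny_cfg):
        a = sb.run_panel(tiny_cfg, seed=3, metrics=["gc_percent", "n_contigs"])
        b = sb.run_panel(tiny_cfg, seed=3, metrics=["gc_percent", "n_contigs"])
        pd.testing.assert_frame_equal(a, b)

    def test_truth_columns_present(self, tiny_cfg):
        table = sb.run_panel(tiny_cfg, seed=4, metrics=["gc_percent"])
        assert {"kind", "relatedness", "ratio", "contaminated"} <= set(table.columns)
        assert (~table.loc[table["kind"] == "self", "contaminated"]).all()


class TestSensitivityTable:
    def make_table(self):
        return pd.DataFrame(
            {
                "species": ["S s1"] * 4,
                "genus": ["S"] * 4,
                "kind": ["self", "intergenus", "intragenus", "intragenus"],
                "relatedness": [None, None, "distant", "close"],
                "ratio": [0.0, 0.2, 0.2, 0.2],
                "contaminated": [False, True, True, True],
                "read_purity": [0.99, 0.80, 0.99, 0.99],
            }
        )

    def test_flagging_metric_sensitivity_and_specificity(self):
        table = self.make_table()
        # a threshold set whose purity cut flags everything (cut above 1.0)
        ts = ThresholdSet(rank_override={})
        ts.add("all", MetricThreshold("species_purity", low=1.01, critical=True))
        sens = sb.sensitivity_table(table, ts)
        assert sens.loc["read_purity", "intergenus:S"] == 1.0
        assert sens.loc["read_purity", "specificity"] == 0.0

    def test_standard_purity_cut(self):
        table = self.make_table()
        ts = ThresholdSet(rank_override={})
        ts.add("all", MetricThreshold("species_purity", low=0.95, critical=True))
        sens = sb.sensitivity_table(table, ts)
        assert sens.loc["read_purity", "intergenus:S"] == 1.0
        assert sens.loc["read_purity", "intragenus:distant"] == 0.0
        assert sens.loc["read_purity", "specificity"] == 1.0


class TestThresholdCohort:
    def test_cohort_bands_cover_the_founder(self):
        taxon = sb.simulate_genome(40_000, 0.45, 20, 1000, seed=20)
        ts = sb.derive_panel_thresholds([taxon], n_per_species=100, seed=21)
        spec = sb.MixtureSpec(taxon, None, 0.0, "self", coverage=50, seed=22)
        from isoqc.assembly_metrics import assembly_stats

        stats = assembly_stats(sb.pseudo_assemble(spec))
        for metric, value in [
            ("assembly_length", stats.total_length),
            ("gc_percent", stats.gc_percent),
            ("n_contigs", stats.n_contigs),
        ]:
            th = ts.lookup(metric, taxon.species, taxon.genus)
            assert th.low <= value <= th.high, metric
        n50_th = ts.lookup("n50", taxon.species, taxon.genus)
        assert stats.n50 >= n50_th.low
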