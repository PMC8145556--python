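import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from isoqc import qc_engine as qc
from isoqc import seqio
from isoqc.seqio import SequenceRecord
from isoqc.simulate_benchmark import simulate_genome, simulate_reads


class TestDeriveSpeciesThresholds:
    def make_table(self, values, species="Salmonella enterica", genus="Salmonella"):
        return pd.DataFrame(
            {"species": species, "genus": genus, "metric_x": values}
        )

    def test_identical_values_degenerate_range(self):
        out = qc.derive_species_thresholds(self.make_table([7.0] * 100))
        row = out.iloc[0]
        assert (row["low"], row["high"]) == (7.0, 7.0)

    def test_linear_interpolation_quantiles(self):
        out = qc.derive_species_thresholds(self.make_table(list(range(1, 101))))
        row = out.iloc[0]
        # numpy linear-interpolation oracle on 1..100
        assert row["low"] == pytest.approx(5.95)
        assert row["high"] == pytest.approx(95.05)

    def test_species_below_min_n_omitted(self):
        out = qc.derive_species_thresholds(self.make_table([1.0] * 99), min_n=100)
        assert out.empty

    def test_empty_table_error(self):
        with pytest.raises(ValueError):
            qc.derive_species_thresholds(pd.DataFrame())


class TestDeriveGenusThresholds:
    def test_single_species_identity(self):
        ranges = pd.DataFrame(
            [{"species": "s1", "genus": "g", "metric": "m", "low": 4.5, "high": 5.0}]
        )
        out = qc.derive_genus_thresholds(ranges)
        assert out.iloc[0]["low"] == 4.5 and out.iloc[0]["high"] == 5.0

    def test_min_low_max_high_rule(self):
        ranges = pd.DataFrame(
            [
                {"species": "s1", "genus": "g", "metric": "m", "low": 4.5, "high": 5.0},
                {"species": "s2", "genus": "g", "metric": "m", "low": 4.7, "high": 5.3},
            ]
        )
        out = qc.derive_genus_thresholds(ranges)
        assert out.iloc[0]["low"] == 4.5 and out.iloc[0]["high"] == 5.3

    @given(
        st.lists(
            st.tuples(st.floats(0, 50), st.floats(50, 100)), min_size=1, max_size=6
        )
    )
    def test_genus_range_contains_every_species_range(self, spans):
        ranges = pd.DataFrame(
            [
                {"species": f"s{i}", "genus": "g", "metric": "m", "low": lo, "high": hi}
                for i, (lo, hi) in enumerate(spans)
            ]
        )
        out = qc.derive_genus_thresholds(ranges).iloc[0]
        for lo, hi in spans:
            assert out["low"] <= lo and hi <= out["high"]


class TestBundledThresholds:
    def test_bundled_table_loads(self):
        ts = qc.ThresholdSet.bundled()
        th = ts.lookup("assembly_length", "Salmonella enterica")
        assert (th.low, th.high) == (4_500_000, 5_100_000)
        assert th.critical

    def test_contig_count_warn_for_e_coli(self):
        ts = qc.ThresholdSet.bundled()
        th = ts.lookup("n_contigs", "Escherichia coli")
        assert qc.evaluate_metric(700, th) == qc.WARN

    def test_short_salmonella_assembly_fails(self):
        ts = qc.ThresholdSet.bundled()
        th = ts.lookup("assembly_length", "Salmonella enterica")
        assert qc.evaluate_metric(3_000_000, th) == qc.FAIL

    def test_lookup_fallback_species_genus_global(self):
        ts = qc.ThresholdSet.bundled()
        # Campylobacter thresholds sit at genus rank
        th = ts.lookup("gc_percent", "Campylobacter jejuni", "Campylobacter")
        assert th is not None and th.low == pytest.approx(26.4)
        assert ts.lookup("q30_fraction", "Unknown species", "Unknowngenus").low == 0.90
        assert ts.lookup("n50", "Unknown species", "Unknowngenus") is None

    def test_campylobacter_rank_override(self):
        ts = qc.ThresholdSet.bundled()
        assert ts.classification_rank("Campylobacter") == "genus"
        assert ts.classification_rank("Salmonella") == "species"


class TestEvaluateMetric:
    def test_missing_value_not_assessed(self):
        th = qc.MetricThreshold("m", low=0, high=1, critical=True)
        assert qc.evaluate_metric(None, th) == qc.NOT_ASSESSED
        assert qc.evaluate_metric(0.5, None) == qc.NOT_ASSESSED

    def test_warn_band_inside_fail_band(self):
        th = qc.MetricThreshold("m", low=0, high=10, warn_low=2, warn_high=8, critical=True)
        assert qc.evaluate_metric(5, th) == qc.PASS
        assert qc.evaluate_metric(1, th) == qc.WARN
        assert qc.evaluate_metric(11, th) == qc.FAIL

    def test_warn_only_metric_never_fails(self):
        th = qc.MetricThreshold("m", low=0, high=10, critical=False)
        assert qc.evaluate_metric(50, th) == qc.WARN

    def test_invalid_warn_band_rejected(self):
        with pytest.raises(ValueError):
            qc.MetricThreshold("m", low=5, high=10, warn_low=1)


class TestCombinedTaxonomyStatus:
    @pytest.mark.parametrize(
        "read_f,contig_f,expected",
        [
            (0.80, 0.82, qc.FAIL),
            (0.89, 0.99, qc.WARN),  # plasmid bias pattern: reads low, contigs fine
            (0.99, 0.99, qc.PASS),
            (0.99, 0.80, qc.WARN),
            (None, 0.99, qc.PASS),  # single assessed value decides alone
            (0.80, None, qc.FAIL),
            (None, None, qc.NOT_ASSESSED),
        ],
    )
    def test_rule(self, read_f, contig_f, expected):
        assert qc.combined_taxonomy_status(read_f, contig_f) == expected


class TestQcVerdict:
    def test_all_pass(self):
        statuses = {m: qc.PASS for m in qc.CRITICAL_METRICS | qc.WARN_METRICS}
        assert qc.qc_verdict(statuses) == "pass"

    def test_warn_only_metric_yields_warning(self):
        statuses = {m: qc.PASS for m in qc.CRITICAL_METRICS}
        statuses["n50"] = qc.WARN
        assert qc.qc_verdict(statuses) == "warning"

    def test_critical_fail_yields_fail(self):
        statuses = {m: qc.PASS for m in qc.CRITICAL_METRICS | qc.WARN_METRICS}
        statuses["snv_contaminated"] = qc.FAIL
        assert qc.qc_verdict(statuses) == "fail"

    def test_not_assessed_ignored(self):
        statuses = {"q30_fraction": qc.NOT_ASSESSED, "n50": qc.PASS}
        assert qc.qc_verdict(statuses) == "pass"

    @given(st.data())
    def test_monotone_under_degradation(self, data):
        """Worsening one metric's status never improves the verdict."""
        order = {qc.PASS: 0, qc.WARN: 1, qc.FAIL: 2}
        rank = {"pass": 0, "warning": 1, "fail": 2}
        metrics = sorted(qc.CRITICAL_METRICS | qc.WARN_METRICS)
        statuses = {
            m: data.draw(st.sampled_from([qc.PASS, qc.WARN, qc.FAIL]), label=m)
            for m in metrics
        }
        target = data.draw(st.sampled_from(metrics), label="degraded")
        before = qc.qc_verdict(statuses)
        worse = dict(statuses)
        worse[target] = qc.FAIL if statuses[target] == qc.WARN else qc.WARN if statuses[target] == qc.PASS else qc.FAIL
        assert order[worse[target]] >= order[statuses[target]]
        assert rank[qc.qc_verdict(worse)] >= rank[before]


@pytest.fixture()
def report():
    return {
        "pipeline": {
            "assembly": {"result": {"n50": 50_000}, "time": "t"},
            "classification": {"result": {"fraction": 0.99}, "time": "t"},
        },
        "sample": {
            "name": "s1",
            "summary": {"n50": 50_000},
            "assessment": {"statuses": {"n50": "pass"}, "verdict": "pass"},
        },
    }


class TestReportValidationAndFiltering:
    def test_valid_report_passes(self, report):
        assert qc.validate_report(report) == []

    def test_missing_sample_summary_violation(self, report):
        del report["sample"]["summary"]
        violations = qc.validate_report(report)
        assert any("summary" in v for v in violations)

    def test_filter_prunes_omitted_branch(self, report):
        schema = {
            "properties": {
                "pipeline": {"properties": {"assembly": {}}},
                "sample": {},
            }
        }
        pruned = qc.filter_report(report, schema)
        assert "classification" not in pruned["pipeline"]
        assert pruned["sample"] == report["sample"]

    def test_identity_filter_is_identity(self, report):
        assert qc.filter_report(report, {}) == report

    def test_filtering_idempotent(self, report):
        schema = {"properties": {"pipeline": {"properties": {"assembly": {}}}, "sample": {}}}
        once = qc.filter_report(report, schema)
        twice = qc.filter_report(once, schema)
        assert once == twice

    def test_pruned_report_still_validates_core(self, report):
        schema = {"properties": {"pipeline": {}, "sample": {}}}
        assert qc.validate_report(qc.filter_report(report, schema)) == []


class TestRunBatch:
    @pytest.fixture()
    def batch(self, tmp_path):
        genome = simulate_genome(20_000, 0.5, 5, 1000, seed=1)
        reads = simulate_reads(genome, coverage=10, seed=2).to_records()
        rows = []
        for name in ("good1", "good2"):
            fq = tmp_path / f"{name}.fastq"
            fa = tmp_path / f"{name}.fasta"
            seqio.write_sequences(reads, fq, "fastq")
            seqio.write_sequences([SequenceRecord("c1", genome.seq)], fa, "fasta")
            rows.append(seqio.SampleRow(name, str(fq), None, str(fa)))
        # unassemblable: every contig below the length filter
        bad_fa = tmp_path / "bad.fasta"
        seqio.write_sequences([SequenceRecord("c1", "ACGT" * 50)], bad_fa, "fasta")
        rows.append(seqio.SampleRow("bad", None, None, str(bad_fa)))
        return seqio.SampleSheet(rows), tmp_path

    def test_failed_sample_recorded_batch_continues(self, batch):
        sheet, tmp_path = batch
        config = qc.QCConfig(expected_genome_length=20_000)
        reports, failed = qc.run_batch(sheet, config, tmp_path / "out")
        assert sorted(reports) == ["good1", "good2"]
        assert len(failed) == 1
        assert failed[0].sample == "bad"
        assert failed[0].reason == "no assembly"
        assert (tmp_path / "out" / "summary.tsv").exists()
        assert (tmp_path / "out" / "summary.html").exists()

    def test_all_good_batch_empty_failed_list(self, batch):
        sheet, _ = batch
        sheet = seqio.SampleSheet(sheet.rows[:2])
        _, failed = qc.run_batch(sheet, qc.QCConfig(expected_genome_length=20_000))
        assert failed == []

    def test_rerun_reuses_cached_reports(self, batch, monkeypatch):
        sheet, tmp_path = batch
        config = qc.QCConfig(expected_genome_length=20_000)
        first, _ = qc.run_batch(sheet, config, tmp_path / "out")

        calls = {"n": 0}
        real = qc.process_sample

        def counting(row, cfg):
            calls["n"] += 1
            return real(row, cfg)

        monkeypatch.setattr(qc, "process_sample", counting)
        second, failed = qc.run_batch(sheet, config, tmp_path / "out")
        # the two good samples come from cache; only the failed one reruns
        assert calls["n"] == 1
        assert {k: v["sample"]["summary"] for k, v in second.items()} == {
            k: v["sample"]["summary"] for k, v in first.items()
        }

    def test_report_two_branch_structure(self, batch):
        sheet, tmp_path = batch
        config = qc.QCConfig(expected_genome_length=20_000)
        reports, _ = qc.run_batch(sheet, config)
        for report in reports.values():
            assert set(report) == {"pipeline", "sample"}
            assert qc.validate_report(report) == []
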