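"""Threshold derivation, the pass/warning/fail decision engine and reporting.

Thresholds are per-taxon metric ranges carrying a criticality flag. Critical
metrics (Q30 fraction, coverage depth, assembly length, the combined
read+contig taxonomy status, SNV contamination) fail a sample when out of
range; the remaining metrics (contig count, N50, GC, MLST duplication,
core-gene completeness/duplication, duplication ratio) only warn. Threshold
lookup resolves species, then genus, then species-agnostic defaults; taxa
without thresholds simply skip the taxon-specific checks.

Species-specific ranges are derived as empirical 5%/95% quantiles (linear
interpolation) over all samples of a species, for species with at least 100
samples; a genus range is the union of its species ranges (minimum of lows,
maximum of highs).

Reports are two-branch JSON: "pipeline" holds unaltered per-module results,
"sample" the run configuration, summary metrics and their assessment. A
filtering schema prunes branches by omission; a validation schema checks
the mandatory core structure. Batch execution records per-sample module
failures with a reason and completes over the surviving samples.
"""

from __future__ import annotations

import copy
import hashlib
import importlib.resources
import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from . import assembly_metrics as am
from . import read_metrics as rm
from . import seqio
from . import snv_contamination as snv
from . import taxonomy as tax
from . import typing as typ

PASS, WARN, FAIL, NOT_ASSESSED = "pass", "warn", "fail", "not-assessed"

CRITICAL_METRICS = {
    "q30_fraction",
    "coverage_depth",
    "assembly_length",
    "combined_taxonomy",
    "snv_contaminated",
}
WARN_METRICS = {
    "n_contigs",
    "n50",
    "gc_percent",
    "mlst_duplicated",
    "unique_core_fraction",
    "duplicated_core_count",
    "duplication_ratio",
}


@dataclass
class MetricThreshold:
    metric: str
    low: Optional[float] = None
    high: Optional[float] = None
    warn_low: Optional[float] = None  # defaults to low (no warn band)
    warn_high: Optional[float] = None
    critical: bool = False

    def __post_init__(self):
        if self.warn_low is None:
            self.warn_low = self.low
        if self.warn_high is None:
            self.warn_high = self.high
        if (
            self.low is not None
            and self.high is not None
            and self.low > self.high
        ):
            raise ValueError(f"{self.metric}: low > high")
        if self.warn_low is not None and self.low is not None and self.warn_low < self.low:
            raise ValueError(f"{self.metric}: warn range outside fail range")
        if self.warn_high is not None and self.high is not None and self.warn_high > self.high:
            raise ValueError(f"{self.metric}: warn range outside fail range")


@dataclass
class ThresholdSet:
    """Per-taxon metric thresholds with species -> genus -> global fallback."""

    entries: dict[tuple[str, str], MetricThreshold] = field(default_factory=dict)
    rank_override: dict[str, str] = field(default_factory=lambda: {"Campylobacter": "genus"})

    def add(self, taxon: str, threshold: MetricThreshold) -> None:
        self.entries[(taxon, threshold.metric)] = threshold

    def lookup(self, metric: str, species: Optional[str] = None, genus: Optional[str] = None) -> Optional[MetricThreshold]:
        for taxon in (species, genus, "all"):
            if taxon is not None and (taxon, metric) in self.entries:
                return self.entries[(taxon, metric)]
        return None

    def classification_rank(self, genus: Optional[str]) -> str:
        """Purity-check rank; genus for taxa with indistinct species boundaries."""
        return self.rank_override.get(genus or "", "species")

    def expected_length(self, species: Optional[str] = None, genus: Optional[str] = None) -> Optional[float]:
        th = self.lookup("assembly_length", species, genus)
        if th is None or th.low is None or th.high is None:
            return None
        return (th.low + th.high) / 2

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "ThresholdSet":
        ts = cls()
        for _, row in df.iterrows():
            def num(col):
                val = row.get(col)
                if val is None or (isinstance(val, float) and math.isnan(val)) or val == "":
                    return None
                return float(val)

            ts.add(
                str(row["taxon"]),
                MetricThreshold(
                    metric=str(row["metric"]),
                    low=num("low"),
                    high=num("high"),
                    warn_low=num("warn_low") if "warn_low" in df.columns else None,
                    warn_high=num("warn_high") if "warn_high" in df.columns else None,
                    critical=str(row.get("criticality", "warn")) == "critical",
                ),
            )
        return ts

    @classmethod
    def from_tsv(cls, path) -> "ThresholdSet":
        return cls.from_table(pd.read_csv(path, sep="\t"))

    @classmethod
    def bundled(cls) -> "ThresholdSet":
        """The packaged default thresholds for the four reference genera."""
        ref = importlib.resources.files("isoqc").joinpath("data/thresholds.tsv")
        with importlib.resources.as_file(ref) as path:
            return cls.from_tsv(path)


# ---------------------------------------------------------------------------
# Threshold derivation
# ---------------------------------------------------------------------------

def derive_species_thresholds(
    metric_table: pd.DataFrame,
    metrics: Optional[list[str]] = None,
    min_n: int = 100,
    q: tuple[float, float] = (0.05, 0.95),
) -> pd.DataFrame:
    """Per-species empirical quantile ranges for each metric.

    ``metric_table`` has one row per sample with columns ``species``,
    ``genus`` (optional) and metric values. Species with fewer than
    ``min_n`` samples are omitted. Quantiles use linear interpolation.
    Returns a table (species, genus, metric, low, high, n).
    """
    if metric_table.empty:
        raise ValueError("empty metric table")
    if metrics is None:
        skip = {"sample", "species", "genus"}
        metrics = [c for c in metric_table.columns if c not in skip]
    out = []
    for species, group in metric_table.groupby("species", sort=True):
        if len(group) < min_n:
            continue
        genus = group["genus"].iloc[0] if "genus" in group.columns else species.split()[0]
        for metric in metrics:
            vals = group[metric].dropna().to_numpy(dtype=float)
            if not len(vals):
                continue
            low, high = np.quantile(vals, q, method="linear")
            out.append(
                {
                    "species": species,
                    "genus": genus,
                    "metric": metric,
                    "low": float(low),
                    "high": float(high),
                    "n": len(group),
                }
            )
    return pd.DataFrame(out)


def derive_genus_thresholds(species_ranges: pd.DataFrame) -> pd.DataFrame:
    """Genus-wide interval per metric: min of species lows, max of highs."""
    if species_ranges.empty:
        return pd.DataFrame(columns=["genus", "metric", "low", "high"])
    return (
        species_ranges.groupby(["genus", "metric"], sort=True)
        .agg(low=("low", "min"), high=("high", "max"))
        .reset_index()
    )


# ---------------------------------------------------------------------------
# Decision rules
# ---------------------------------------------------------------------------

def evaluate_metric(value: Optional[float], threshold: Optional[MetricThreshold]) -> str:
    """Status of one metric value against its resolved threshold.

    Critical metrics fail outside the fail range and warn when inside it but
    outside the (optional) warn band; warn-only metrics warn when out of
    range. Missing values or missing thresholds are not assessed.
    """
    if value is None or threshold is None:
        return NOT_ASSESSED
    if isinstance(value, float) and math.isnan(value):
        return NOT_ASSESSED
    out_fail = (threshold.low is not None and value < threshold.low) or (
        threshold.high is not None and value > threshold.high
    )
    if threshold.critical:
        if out_fail:
            return FAIL
        out_warn = (threshold.warn_low is not None and value < threshold.warn_low) or (
            threshold.warn_high is not None and value > threshold.warn_high
        )
        return WARN if out_warn else PASS
    return WARN if out_fail else PASS


def combined_taxonomy_status(
    read_fraction: Optional[float],
    contig_fraction: Optional[float],
    purity_threshold: float = 0.95,
) -> str:
    """Combine read- and contig-level purity into one status.

    Fail only when both fractions fall below the threshold; exactly one low
    fraction warns (e.g. read-level plasmid bias); a single assessed value
    decides alone.
    """
    assessed = [f for f in (read_fraction, contig_fraction) if f is not None]
    if not assessed:
        return NOT_ASSESSED
    n_low = sum(1 for f in assessed if f < purity_threshold)
    if n_low == len(assessed):
        return FAIL
    return WARN if n_low else PASS


def qc_verdict(statuses: dict[str, str]) -> str:
    """Aggregate per-metric statuses into a sample verdict.

    Fail iff any critical metric fails; warning iff no critical failure but
    at least one warning (or an out-of-range warn-only metric); else pass.
    """
    if any(
        status == FAIL and metric in CRITICAL_METRICS
        for metric, status in statuses.items()
    ):
        return "fail"
    if any(status in (WARN, FAIL) for status in statuses.values()):
        return "warning"
    return "pass"


# ---------------------------------------------------------------------------
# Report assembly, validation, filtering
# ---------------------------------------------------------------------------

VALIDATION_SCHEMA = {
    "type": "object",
    "required": ["pipeline", "sample"],
    "properties": {
        "pipeline": {"type": "object"},
        "sample": {
            "type": "object",
            "required": ["name", "summary", "assessment"],
            "properties": {
                "summary": {"type": "object"},
                "assessment": {
                    "type": "object",
                    "required": ["statuses", "verdict"],
                },
            },
        },
    },
}

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "number": (int, float),
    "boolean": bool,
}


def validate_report(report: dict, schema: Optional[dict] = None, _path: str = "$") -> list[str]:
    """Structural validation; returns a list of violations (empty = ok)."""
    schema = VALIDATION_SCHEMA if schema is None else schema
    violations: list[str] = []
    expected = schema.get("type")
    if expected and not isinstance(report, _TYPES[expected]):
        return [f"{_path}: expected {expected}, got {type(report).__name__}"]
    if isinstance(report, dict):
        for key in schema.get("required", []):
            if key not in report:
                violations.append(f"{_path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in report:
                violations.extend(validate_report(report[key], sub, f"{_path}.{key}"))
    return violations


def filter_report(report: dict, filter_schema: dict) -> dict:
    """Prune branches absent from the filter schema.

    A schema node with ``properties`` keeps only the listed keys (recursing
    into each); a node without ``properties`` keeps its subtree verbatim, so
    the empty schema is the identity. Filtering is idempotent.
    """
    props = filter_schema.get("properties")
    if props is None or not isinstance(report, dict):
        return copy.deepcopy(report)
    return {
        key: filter_report(report[key], sub if isinstance(sub, dict) else {})
        for key, sub in props.items()
        if key in report
    }


def assemble_report(
    sample_name: str,
    module_results: dict,
    metric_values: dict[str, Optional[float]],
    statuses: dict[str, str],
    verdict: str,
    metadata: Optional[dict] = None,
    failure_reasons: Optional[dict[str, str]] = None,
) -> dict:
    """Build the two-branch report dict for one sample."""
    return {
        "pipeline": {
            module: {"result": result, "time": time.strftime("%Y-%m-%dT%H:%M:%S")}
            for module, result in module_results.items()
        },
        "sample": {
            "name": sample_name,
            "config": dict(metadata or {}),
            "summary": dict(metric_values),
            "assessment": {"statuses": dict(statuses), "verdict": verdict},
            "failure_reasons": dict(failure_reasons or {}),
            "version": __version__,
        },
    }


# ---------------------------------------------------------------------------
# Batch execution
# ---------------------------------------------------------------------------

@dataclass
class QCConfig:
    """Everything the per-sample pipeline needs besides the input files."""

    thresholds: ThresholdSet = field(default_factory=ThresholdSet.bundled)
    min_contig_len: int = 500
    purity_threshold: float = 0.95
    expected_genome_length: float = 5_000_000
    taxonomy_index: Optional[tax.KmerIndex] = None
    mlst_scheme: Optional[typ.Scheme] = None
    core_scheme: Optional[typ.Scheme] = None
    references: Optional[dict[str, str]] = None  # label -> genome sequence
    snv_min_depth: int = 10
    snv_min_minor_reads: int = 2
    snv_min_minor_fraction: float = 0.05
    snv_cutoff: int = 3
    snv_min_base_quality: int = 20
    species: Optional[str] = None  # expected taxon; overrides classification
    genus: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "QCConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        if "thresholds_tsv" in raw:
            cfg.thresholds = ThresholdSet.from_tsv(raw.pop("thresholds_tsv"))
        for key, val in raw.items():
            if hasattr(cfg, key):
                setattr(cfg, key, val)
        return cfg


@dataclass
class ModuleFailure:
    sample: str
    module: str
    reason: str


def _input_checksum(row: seqio.SampleRow) -> str:
    h = hashlib.md5()
    for path in (row.fq1, row.fq2, row.assembly):
        if path and Path(path).exists():
            h.update(Path(path).read_bytes())
        h.update(b"|")
    return h.hexdigest()


def process_sample(
    row: seqio.SampleRow, config: QCConfig
) -> tuple[Optional[dict], Optional[ModuleFailure]]:
    """Run every applicable metric module for one sample and assemble its report.

    Returns (report, None) on success or (None, failure) when a required
    module fails (e.g. nothing assembles); metrics whose inputs are missing
    are reported not-assessed rather than failing the sample.
    """
    modules: dict = {}
    values: dict[str, Optional[float]] = {}
    reads = None
    contigs = None

    if row.fq1:
        try:
            records = seqio.read_sequences(row.fq1, "fastq")
            if row.fq2:
                records += seqio.read_sequences(row.fq2, "fastq")
            reads = records
        except (OSError, ValueError) as exc:
            return None, ModuleFailure(row.sample, "reads", str(exc))
    if row.assembly:
        try:
            contigs = seqio.read_sequences(row.assembly, "fasta")
        except (OSError, ValueError) as exc:
            return None, ModuleFailure(row.sample, "assembly", str(exc))

    stats = None
    if contigs is not None:
        stats = am.assembly_stats(contigs, config.min_contig_len)
        if stats is None:
            return None, ModuleFailure(row.sample, "assembly", "no assembly")
        values["assembly_length"] = stats.total_length
        values["n_contigs"] = stats.n_contigs
        values["n50"] = stats.n50
        values["gc_percent"] = stats.gc_percent
        modules["assembly"] = {
            "total_length": stats.total_length,
            "n_contigs": stats.n_contigs,
            "n50": stats.n50,
            "gc_percent": stats.gc_percent,
        }

    species, genus = config.species, config.genus
    read_fraction = contig_fraction = None
    if config.taxonomy_index is not None:
        rank = config.thresholds.classification_rank(genus)
        if reads is not None:
            res = tax.majority_fraction_reads(reads, config.taxonomy_index, rank)
            if res is not None:
                read_fraction = res.fraction
                if species is None and rank == "species":
                    species = res.majority_taxon
                    genus = genus or config.taxonomy_index.genus_of(species)
                modules["classification_reads"] = {
                    "majority_taxon": res.majority_taxon,
                    "fraction": res.fraction,
                    "rank": rank,
                }
        if contigs is not None:
            res = tax.majority_fraction_contigs(contigs, config.taxonomy_index, rank)
            if res is not None:
                contig_fraction = res.fraction
                modules["classification_contigs"] = {
                    "majority_taxon": res.majority_taxon,
                    "fraction": res.fraction,
                    "rank": rank,
                }
    values["read_purity"] = read_fraction
    values["contig_purity"] = contig_fraction

    if reads is not None:
        denom = stats.total_length if stats else (
            config.thresholds.expected_length(species, genus)
            or config.expected_genome_length
        )
        rstats = rm.compute_read_stats(reads, int(denom))
        values["q30_fraction"] = rstats.q30_fraction
        values["coverage_depth"] = rstats.est_coverage
        modules["read_qc"] = {
            "n_reads": rstats.n_reads,
            "n_bases": rstats.n_bases,
            "q30_fraction": rstats.q30_fraction,
            "est_coverage": rstats.est_coverage,
        }

    if contigs is not None and config.mlst_scheme is not None:
        calls = typ.call_alleles(contigs, config.mlst_scheme)
        st = typ.sequence_type(calls, config.mlst_scheme)
        dup_count, _ = typ.duplicated_alleles(calls)
        values["mlst_duplicated"] = dup_count
        modules["mlst"] = {"st": st, "duplicated_loci": dup_count}

    if contigs is not None and config.core_scheme is not None:
        core = typ.core_gene_assessment(contigs, config.core_scheme)
        values["unique_core_fraction"] = core["unique_fraction"]
        values["duplicated_core_count"] = core["duplicated_count"]
        modules["core_genes"] = core

    if reads is not None and config.core_scheme is not None:
        call = snv.detect_contamination(
            reads,
            config.core_scheme,
            min_depth=config.snv_min_depth,
            min_minor_reads=config.snv_min_minor_reads,
            min_minor_fraction=config.snv_min_minor_fraction,
            snv_cutoff=config.snv_cutoff,
            min_base_quality=config.snv_min_base_quality,
        )
        values["snv_contaminated"] = int(call.contaminated)
        modules["snv_contamination"] = {
            "n_snvs": call.n_contaminating_snvs,
            "multiallelic_loci": call.multiallelic_loci,
            "contaminated": call.contaminated,
            "est_contamination_percent": call.est_contamination_percent,
        }

    if contigs is not None and config.references:
        sketches = [
            am.sketch([seq], label=label) for label, seq in config.references.items()
        ]
        asm_sketch = am.sketch([c.seq for c in contigs])
        label, dist = am.select_reference(asm_sketch, sketches)
        aln = am.map_contigs(contigs, config.references[label])
        dup = am.duplication_ratio(aln)
        values["duplication_ratio"] = dup
        modules["reference"] = {
            "reference": label,
            "mash_distance": dist,
            "duplication_ratio": dup,
            "genome_fraction": am.genome_fraction(aln),
        }

    statuses: dict[str, str] = {}
    for metric, value in values.items():
        if metric in ("read_purity", "contig_purity"):
            continue
        statuses[metric] = evaluate_metric(
            value, config.thresholds.lookup(metric, species, genus)
        )
    purity_th = config.thresholds.lookup("species_purity", species, genus)
    statuses["combined_taxonomy"] = combined_taxonomy_status(
        read_fraction,
        contig_fraction,
        purity_th.low if purity_th and purity_th.low else config.purity_threshold,
    )
    verdict = qc_verdict(statuses)
    report = assemble_report(
        row.sample,
        modules,
        values,
        statuses,
        verdict,
        metadata={"species": species, "genus": genus},
    )
    return report, None


def run_batch(
    samplesheet: seqio.SampleSheet,
    config: Optional[QCConfig] = None,
    outdir=None,
) -> tuple[dict[str, dict], list[ModuleFailure]]:
    """Process every sample of a sheet, tracking failed samples.

    Per-sample module failures are recorded with a reason and the batch
    continues over the surviving samples. With ``outdir`` given, per-sample
    JSON reports are written and cached by input checksum so a rerun after
    fixing a failed sample reuses prior results; an aggregate ``summary.tsv``
    and a color-coded ``summary.html`` are emitted.
    """
    config = config or QCConfig()
    outdir = Path(outdir) if outdir else None
    cache_dir = None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        cache_dir = outdir / "cache"
        cache_dir.mkdir(exist_ok=True)
    reports: dict[str, dict] = {}
    failed: list[ModuleFailure] = []
    for row in samplesheet.rows:
        cache_path = None
        if cache_dir:
            cache_path = cache_dir / f"{row.sample}.{_input_checksum(row)}.json"
            if cache_path.exists():
                reports[row.sample] = seqio.read_report_json(cache_path)
                continue
        report, failure = process_sample(row, config)
        if failure is not None:
            failed.append(failure)
            continue
        reports[row.sample] = report
        if cache_path:
            seqio.write_report_json(report, cache_path)
        if outdir:
            seqio.write_report_json(report, outdir / f"{row.sample}.json")
    if outdir:
        write_summary_tsv(reports, failed, outdir / "summary.tsv")
        write_html_summary(reports, failed, outdir / "summary.html")
    return reports, failed


SUMMARY_METRICS = [
    "q30_fraction",
    "coverage_depth",
    "assembly_length",
    "n_contigs",
    "n50",
    "gc_percent",
    "read_purity",
    "contig_purity",
    "mlst_duplicated",
    "unique_core_fraction",
    "duplicated_core_count",
    "duplication_ratio",
    "snv_contaminated",
]


def write_summary_tsv(reports: dict[str, dict], failed: list[ModuleFailure], path) -> None:
    rows = []
    for name, report in reports.items():
        summary = report["sample"]["summary"]
        row = {"sample": name, "verdict": report["sample"]["assessment"]["verdict"]}
        for metric in SUMMARY_METRICS:
            row[metric] = summary.get(metric)
        rows.append(row)
    for failure in failed:
        rows.append({"sample": failure.sample, "verdict": f"failed: {failure.reason}"})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_STATUS_COLORS = {PASS: "#b6e3b6", WARN: "#ffd47f", FAIL: "#f4a1a1", NOT_ASSESSED: "#e0e0e0"}


def write_html_summary(reports: dict[str, dict], failed: list[ModuleFailure], path) -> None:
    """Static traffic-light table: one row per sample, colored per metric."""
    metrics = [m for m in SUMMARY_METRICS if m not in ("read_purity", "contig_purity")]
    head = "".join(f"<th>{m}</th>" for m in ["sample", "verdict", "combined_taxonomy"] + metrics)
    body = []
    for name, report in reports.items():
        s = report["sample"]
        statuses = s["assessment"]["statuses"]
        verdict = s["assessment"]["verdict"]
        vcolor = {"pass": "#b6e3b6", "warning": "#ffd47f", "fail": "#f4a1a1"}[verdict]
        cells = [f"<td>{name}</td>", f'<td style="background:{vcolor}">{verdict}</td>']
        combo = statuses.get("combined_taxonomy", NOT_ASSESSED)
        cells.append(f'<td style="background:{_STATUS_COLORS[combo]}">{combo}</td>')
        for metric in metrics:
            status = statuses.get(metric, NOT_ASSESSED)
            value = s["summary"].get(metric)
            text = "" if value is None else (f"{value:.4g}" if isinstance(value, float) else str(value))
            cells.append(f'<td style="background:{_STATUS_COLORS[status]}">{text}</td>')
        body.append("<tr>" + "".join(cells) + "</tr>")
    for failure in failed:
        body.append(
            f'<tr><td>{failure.sample}</td><td style="background:#f4a1a1">'
            f"failed: {failure.module}: {failure.reason}</td></tr>"
        )
    html = (
        "<html><head><meta charset='utf-8'><style>table{border-collapse:collapse}"
        "td,th{border:1px solid #999;padding:4px;font-family:sans-serif;font-size:12px}"
        "</style></head><body><table><tr>" + head + "</tr>" + "".join(body)
        + "</table></body></html>"
    )
    Path(path).write_text(html)
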