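"""File input/output: FASTA/FASTQ, sample sheets, scheme directories, report JSON.

This is the only module that touches the filesystem. Sequences are normalized
on input: lowercase is uppercased and any character outside {A,C,G,T,N} is
mapped to N. FASTQ quality encoding is fixed to Phred+33 (modern Illumina);
there is no auto-detection. Files ending in ``.gz`` are decompressed
transparently.
"""

from __future__ import annotations

import gzip
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._kmers import decode, encode
from .typing import Scheme

_VALID = set("ACGTN")
_NORMALIZE = str.maketrans(
    {chr(c): "N" for c in range(256) if chr(c).upper() not in _VALID}
)


class ParseError(ValueError):
    """Malformed sequence file; carries the approximate 1-based line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        suffix = f" (around line {line})" if line is not None else ""
        super().__init__(message + suffix)


def normalize_seq(seq: str) -> str:
    """Uppercase and map any non-ACGTN character to N."""
    return seq.upper().translate(_NORMALIZE)


@dataclass
class SequenceRecord:
    """One named nucleotide sequence with optional per-base Phred scores."""

    id: str
    seq: str
    quals: Optional[list[int]] = None

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.quals is not None and len(self.quals) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: sequence and quality lengths differ "
                f"({len(self.seq)} vs {len(self.quals)})"
            )

    def __len__(self) -> int:
        return len(self.seq)


class ReadSet:
    """Matrix-backed container for equal-length reads.

    Stores base codes and Phred scores as (n_reads, read_len) uint8 arrays so
    the classifiers and pileup can operate vectorized. Iteration yields
    plain :class:`SequenceRecord` objects.
    """

    def __init__(self, codes: np.ndarray, quals: np.ndarray, ids: Optional[list[str]] = None):
        if codes.shape != quals.shape:
            raise ValueError("codes and quals shapes differ")
        self.codes = codes
        self.quals = quals
        self._ids = ids

    @property
    def ids(self) -> list[str]:
        if self._ids is None:
            self._ids = [f"read_{i}" for i in range(len(self))]
        return self._ids

    def __len__(self) -> int:
        return self.codes.shape[0]

    @property
    def read_len(self) -> int:
        return self.codes.shape[1]

    @property
    def n_bases(self) -> int:
        return int(self.codes.size)

    def subset(self, index: np.ndarray) -> "ReadSet":
        ids = [self.ids[i] for i in index] if self._ids is not None else None
        return ReadSet(self.codes[index], self.quals[index], ids)

    def __iter__(self) -> Iterator[SequenceRecord]:
        for i in range(len(self)):
            yield SequenceRecord(
                self.ids[i], decode(self.codes[i]), self.quals[i].tolist()
            )

    def to_records(self) -> list[SequenceRecord]:
        return list(self)

    @classmethod
    def from_records(cls, records: Iterable[SequenceRecord]) -> "ReadSet":
        records = list(records)
        if not records:
            return cls(np.empty((0, 0), np.uint8), np.empty((0, 0), np.uint8), [])
        length = len(records[0].seq)
        codes = np.empty((len(records), length), dtype=np.uint8)
        quals = np.zeros((len(records), length), dtype=np.uint8)
        for i, rec in enumerate(records):
            if len(rec.seq) != length:
                raise ValueError("ReadSet requires equal-length reads")
            codes[i] = encode(rec.seq)
            if rec.quals is not None:
                quals[i] = rec.quals
        return cls(codes, quals, [r.id for r in records])


def as_read_set(reads) -> ReadSet:
    return reads if isinstance(reads, ReadSet) else ReadSet.from_records(reads)


def _open_text(path, mode: str = "rt"):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_sequences(path, format: Optional[str] = None) -> list[SequenceRecord]:
    """Read all records from a FASTA or FASTQ file, in file order.

    ``format`` is inferred from the file name when omitted. FASTQ qualities
    are decoded as Phred+33. Malformed records raise :class:`ParseError`
    naming the approximate line.
    """
    path = os.fspath(path)
    if format is None:
        stem = path[:-3] if path.endswith(".gz") else path
        ext = Path(stem).suffix.lower()
        format = "fastq" if ext in {".fastq", ".fq"} else "fasta"
    if format not in {"fasta", "fastq"}:
        raise ValueError(f"unsupported format {format!r}")

    records: list[SequenceRecord] = []
    seen: set[str] = set()

    def check_id(name: str, line: int):
        rec_id = name.split()[0] if name.split() else name
        if rec_id in seen:
            raise ParseError(f"duplicate record id {rec_id!r}", line)
        seen.add(rec_id)
        return rec_id

    with _open_text(path) as fh:
        if format == "fasta":
            for i, (title, seq) in enumerate(SimpleFastaParser(fh)):
                rec_id = check_id(title, 2 * i + 1)
                if not seq:
                    raise ParseError(f"record {rec_id!r} has no sequence", 2 * i + 1)
                records.append(SequenceRecord(rec_id, normalize_seq(seq)))
        else:
            it = FastqGeneralIterator(fh)
            i = 0
            while True:
                try:
                    title, seq, qual = next(it)
                except StopIteration:
                    break
                except ValueError as exc:
                    raise ParseError(str(exc), 4 * i + 1) from exc
                rec_id = check_id(title, 4 * i + 1)
                if len(seq) != len(qual):
                    raise ParseError(
                        f"record {rec_id!r}: sequence/quality length mismatch",
                        4 * i + 1,
                    )
                quals = [ord(c) - 33 for c in qual]
                if any(q < 0 for q in quals):
                    raise ParseError(
                        f"record {rec_id!r}: quality character below Phred+33 range",
                        4 * i + 4,
                    )
                records.append(SequenceRecord(rec_id, normalize_seq(seq), quals))
                i += 1
    return records


def write_sequences(records: Iterable[SequenceRecord], path, format: Optional[str] = None) -> None:
    path = os.fspath(path)
    if format is None:
        stem = path[:-3] if path.endswith(".gz") else path
        ext = Path(stem).suffix.lower()
        format = "fastq" if ext in {".fastq", ".fq"} else "fasta"
    with _open_text(path, "wt") as fh:
        if format == "fasta":
            for rec in records:
                fh.write(f">{rec.id}\n")
                for i in range(0, len(rec.seq), 80):
                    fh.write(rec.seq[i : i + 80] + "\n")
        elif format == "fastq":
            for rec in records:
                if rec.quals is None:
                    raise ValueError(f"record {rec.id!r} has no qualities for FASTQ")
                qual = "".join(chr(q + 33) for q in rec.quals)
                fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")
        else:
            raise ValueError(f"unsupported format {format!r}")


# ---------------------------------------------------------------------------
# Sample sheets
# ---------------------------------------------------------------------------

@dataclass
class SampleRow:
    sample: str
    fq1: Optional[str] = None
    fq2: Optional[str] = None
    assembly: Optional[str] = None


@dataclass
class SampleSheet:
    rows: list[SampleRow]
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)


def read_samplesheet(path) -> SampleSheet:
    """Read and validate a TSV sample sheet (header ``sample fq1 fq2 assembly``).

    Relative paths are resolved against the sheet's directory. Duplicate
    sample names are an error; files that do not exist are collected into
    the returned sheet's ``warnings`` rather than being fatal.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample" not in df.columns:
        raise ValueError("sample sheet must have a 'sample' column")
    base = path.parent
    rows: list[SampleRow] = []
    warnings: list[str] = []
    seen: set[str] = set()
    for _, r in df.iterrows():
        name = r["sample"].strip()
        if not name:
            raise ValueError("empty sample name in sample sheet")
        if name in seen:
            raise ValueError(f"duplicate sample name {name!r}")
        seen.add(name)

        def resolve(col: str) -> Optional[str]:
            val = str(r.get(col, "") or "").strip()
            if not val:
                return None
            p = Path(val)
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                warnings.append(f"sample {name!r}: {col} file not found: {p}")
            return str(p)

        row = SampleRow(name, resolve("fq1"), resolve("fq2"), resolve("assembly"))
        if row.fq1 is None and row.assembly is None:
            raise ValueError(f"sample {name!r}: needs at least reads or an assembly")
        rows.append(row)
    return SampleSheet(rows, warnings)


def write_samplesheet(sheet: SampleSheet, path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample": r.sample,
                "fq1": r.fq1 or "",
                "fq2": r.fq2 or "",
                "assembly": r.assembly or "",
            }
            for r in sheet.rows
        ]
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Report JSON
# ---------------------------------------------------------------------------

REPORT_BRANCHES = ("pipeline", "sample")


def write_report_json(report: dict, path) -> None:
    """Write a two-branch QC report; the top level must be exactly
    ``{"pipeline": ..., "sample": ...}``."""
    if set(report) != set(REPORT_BRANCHES):
        raise ValueError(
            f"report top level must have exactly the branches {REPORT_BRANCHES}, "
            f"got {sorted(report)}"
        )
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")


def read_report_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Scheme directories
# ---------------------------------------------------------------------------

def read_scheme(directory, scheme_kind: str = "mlst") -> Scheme:
    """Load a typing scheme from a directory of per-locus FASTA files.

    Each ``<locus>.fasta`` holds that locus' alleles with ids ``<locus>_<n>``.
    An optional ``profiles.tsv`` (header ``ST<TAB>locus1...locusN``) maps
    sequence types to allele numbers, PubMLST-style.
    """
    directory = Path(directory)
    loci: list[str] = []
    alleles: dict[str, dict[str, str]] = {}
    for fasta in sorted(directory.glob("*.fasta")) + sorted(directory.glob("*.fa")):
        locus = fasta.stem
        loci.append(locus)
        alleles[locus] = {}
        for rec in read_sequences(fasta, "fasta"):
            rec_id = rec.id if rec.id.startswith(locus) else f"{locus}_{rec.id}"
            alleles[locus][rec_id] = rec.seq
    profiles = None
    prof_path = directory / "profiles.tsv"
    if prof_path.exists():
        tab = pd.read_csv(prof_path, sep="\t", dtype=str)
        st_col = tab.columns[0]
        profiles = {
            str(row[st_col]): tuple(
                f"{locus}_{row[locus]}" for locus in tab.columns[1:]
            )
            for _, row in tab.iterrows()
        }
    return Scheme(loci=loci, alleles=alleles, profiles=profiles, scheme_kind=scheme_kind)


def write_scheme(scheme: Scheme, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for locus in scheme.loci:
        write_sequences(
            [SequenceRecord(aid, seq) for aid, seq in scheme.alleles[locus].items()],
            directory / f"{locus}.fasta",
            "fasta",
        )
    if scheme.profiles:
        with open(directory / "profiles.tsv", "w") as fh:
            fh.write("ST\t" + "\t".join(scheme.loci) + "\n")
            for st, profile in scheme.profiles.items():
                numbers = [aid.rsplit("_", 1)[1] for aid in profile]
                fh.write(st + "\t" + "\t".join(numbers) + "\n")
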