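"""Read-level quality metrics: Q30 base fraction, yields, estimated coverage.

Metrics are computed on the input reads as given (no trimming). The coverage
denominator is the assembly length when the sample has one, otherwise a
user-supplied expected genome length. An optional quality mask replaces
bases below a Phred cutoff with N for downstream k-mer use only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import ReadSet, as_read_set


@dataclass
class ReadStats:
    n_reads: int
    n_bases: int
    q30_fraction: float
    est_coverage: float


def compute_read_stats(reads, genome_length: int) -> ReadStats:
    """Q30 fraction and estimated depth for a read set.

    ``q30_fraction`` is the share of bases with Phred >= 30;
    ``est_coverage`` is total bases over ``genome_length``.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if isinstance(reads, ReadSet):
        n_reads = len(reads)
        n_bases = reads.n_bases
        if n_reads == 0:
            raise ValueError("no reads given")
        q30 = float(np.mean(reads.quals >= 30))
    else:
        reads = list(reads)
        if not reads:
            raise ValueError("no reads given")
        n_reads = len(reads)
        n_bases = 0
        n_q30 = 0
        for rec in reads:
            if rec.quals is None:
                raise ValueError(f"read {rec.id!r} has no quality scores")
            n_bases += len(rec.seq)
            n_q30 += sum(q >= 30 for q in rec.quals)
        q30 = n_q30 / n_bases
    return ReadStats(
        n_reads=n_reads,
        n_bases=n_bases,
        q30_fraction=q30,
        est_coverage=n_bases / genome_length,
    )


def mask_low_quality(reads, min_qual: int = 5) -> ReadSet:
    """Return a copy of the reads with bases below ``min_qual`` masked to N.

    Intended for downstream k-mer work (classification, baiting); quality
    metrics are always computed on the unmasked input.
    """
    rs = as_read_set(reads)
    codes = rs.codes.copy()
    codes[rs.quals < min_qual] = 4
    return ReadSet(codes, rs.quals.copy(), list(rs.ids))
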