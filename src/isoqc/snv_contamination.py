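"""Read-level intragenus/intergenus contamination detection via core-gene SNVs.

Reads are baited to the core-gene locus they share the most k-mers with,
placed on the locus reference by their best exact-k-mer anchor (ungapped;
indel-bearing reads lose their anchor and are dropped), and piled up per
site. A site is a contaminating SNV when, at sufficient depth, a second
base is supported by enough independent reads at a non-trivial fraction.
Bases below a Phred cutoff are excluded from the pileup: with realistic
Illumina quality mixtures the residual error rate after this filter is low
enough that sequencing errors essentially never co-occur at one site, which
is what gives the detector its specificity on pure samples.

A locus is multi-allelic when it carries two or more SNV sites, the
signature of a second allele from a contaminant. The sample-level call
flags contamination when the genome-wide SNV count reaches the cutoff or
any locus is multi-allelic. The contaminant fraction is estimated as the
median minor-base fraction over SNV sites: in a haploid two-strain mixture
the minor fraction at a divergent site estimates the contaminant read share
directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from ._kmers import CodeTable, encode, kmer_codes, kmer_codes_matrix
from .seqio import ReadSet, as_read_set
from .typing import Scheme


@dataclass
class SitePileup:
    locus: str
    position: int  # 0-based on the locus reference
    base_counts: tuple[int, int, int, int]  # A, C, G, T

    @property
    def depth(self) -> int:
        return sum(self.base_counts)


@dataclass
class ContaminationCall:
    n_contaminating_snvs: int
    multiallelic_loci: int
    contaminated: bool
    est_contamination_percent: Optional[float]  # None = not assessed


def _locus_reference(scheme: Scheme, locus: str) -> str:
    """First allele of the locus serves as the pileup reference."""
    return next(iter(scheme.alleles[locus].values()))


def _unique_kmer_table(seq: str, k: int) -> CodeTable:
    """Forward k-mers occurring exactly once in ``seq`` -> their position."""
    kmers, pos = kmer_codes(encode(seq), k, canonical=False)
    order = np.argsort(kmers, kind="stable")
    sk, sp = kmers[order], pos[order]
    uniq = np.ones(len(sk), dtype=bool)
    dup = sk[1:] == sk[:-1]
    uniq[1:][dup] = False
    uniq[:-1][dup] = False
    return CodeTable(sk[uniq], sp[uniq])


def _scheme_kmer_table(scheme: Scheme, k: int) -> tuple[CodeTable, list[str]]:
    """Both-strand k-mers of all alleles -> locus id; ambiguous k-mers dropped."""
    loci = list(scheme.loci)
    chunks = []
    for lid, locus in enumerate(loci):
        for seq in scheme.alleles[locus].values():
            codes = encode(seq)
            fwd, _ = kmer_codes(codes, k, canonical=False)
            rc, _ = kmer_codes(
                np.where(codes < 4, 3 - codes, 4).astype(np.uint8)[::-1],
                k,
                canonical=False,
            )
            kmers = np.concatenate([fwd, rc])
            chunks.append(
                np.stack([kmers, np.full(len(kmers), lid, dtype=np.int64)], axis=1)
            )
    pairs = np.unique(np.concatenate(chunks), axis=0)
    kmer_col, lid_col = pairs[:, 0], pairs[:, 1]
    first = np.concatenate([[True], np.diff(kmer_col) != 0])
    counts = np.diff(np.concatenate([np.nonzero(first)[0], [len(kmer_col)]]))
    keep = first.copy()
    keep[np.nonzero(first)[0][counts > 1]] = False
    return CodeTable(kmer_col[keep], lid_col[keep]), loci


def bait_reads(reads, core_scheme: Scheme, k: int = 31, stride: int = 4) -> dict[str, ReadSet]:
    """Group reads by the locus they share the most k-mers with.

    Reads sharing no k-mer with any locus are dropped; a chimeric read goes
    to its single best locus. ``stride`` thins each read's k-mer windows
    before counting (plenty remain for the per-read vote).
    """
    rs = as_read_set(reads)
    if len(rs) == 0 or rs.read_len < k:
        return {}
    table, loci = _scheme_kmer_table(core_scheme, k)
    kmer_mat = kmer_codes_matrix(rs.codes, k, canonical=False, stride=stride)
    hits = table.lookup(kmer_mat)
    hits[kmer_mat < 0] = -1
    n_reads, n_win = hits.shape
    rows = np.repeat(np.arange(n_reads), n_win)
    flat = hits.ravel()
    mask = flat >= 0
    counts = np.bincount(
        rows[mask] * len(loci) + flat[mask], minlength=n_reads * len(loci)
    ).reshape(n_reads, len(loci))
    totals = counts.sum(axis=1)
    best = counts.argmax(axis=1)
    out: dict[str, ReadSet] = {}
    for lid, locus in enumerate(loci):
        idx = np.nonzero((totals > 0) & (best == lid))[0]
        if len(idx):
            out[locus] = rs.subset(idx)
    return out


def _pileup_counts(
    locus_sequence: str,
    reads: ReadSet,
    k: int,
    min_base_quality: int,
    stride: int = 2,
) -> np.ndarray:
    """(4, L) base-count matrix from best-anchor ungapped read placement."""
    L = len(locus_sequence)
    counts = np.zeros((4, L), dtype=np.int32)
    if len(reads) == 0 or reads.read_len < k:
        return counts
    table = _unique_kmer_table(locus_sequence, k)
    read_len = reads.read_len
    span = np.arange(read_len)
    big = np.iinfo(np.int64).max
    rc_codes = np.where(reads.codes < 4, 3 - reads.codes, 4).astype(np.uint8)[:, ::-1]
    for codes_mat, quals_mat in (
        (reads.codes, reads.quals),
        (rc_codes, reads.quals[:, ::-1]),
    ):
        kmer_mat = kmer_codes_matrix(codes_mat, k, canonical=False, stride=stride)
        rpos = table.lookup(kmer_mat)
        rpos[kmer_mat < 0] = -1
        hit = rpos >= 0
        any_hit = hit.any(axis=1)
        if not any_hit.any():
            continue
        qpos = (np.arange(kmer_mat.shape[1]) * stride)[None, :]
        diag = rpos - qpos
        dmin = np.where(hit, diag, big).min(axis=1)
        dmax = np.where(hit, diag, -big).max(axis=1)
        offsets = dmin.copy()
        ambiguous = np.nonzero(any_hit & (dmin != dmax))[0]
        for i in ambiguous:  # rare: anchors on several diagonals -> take the mode
            vals, cnts = np.unique(diag[i][hit[i]], return_counts=True)
            offsets[i] = vals[np.argmax(cnts)]
        rows = np.nonzero(any_hit)[0]
        pos = offsets[rows, None] + span[None, :]
        seg = codes_mat[rows]
        qseg = quals_mat[rows]
        valid = (pos >= 0) & (pos < L) & (seg < 4) & (qseg >= min_base_quality)
        counts += np.bincount(
            seg[valid].astype(np.int64) * L + pos[valid], minlength=4 * L
        ).reshape(4, L).astype(np.int32)
    return counts


def pileup(
    locus_sequence: str,
    baited_reads,
    k: int = 31,
    min_base_quality: int = 20,
    locus: str = "",
) -> list[SitePileup]:
    """Per-site base counts for one locus; one entry per covered site.

    Each read is placed at the offset supported by most of its exact k-mer
    matches against the locus (forward or reverse-complemented); reads with
    no anchor are dropped. Bases with Phred < ``min_base_quality`` do not
    enter the counts. Zero baited reads yield an empty pileup.
    """
    counts = _pileup_counts(
        locus_sequence, as_read_set(baited_reads), k, min_base_quality
    )
    covered = np.nonzero(counts.sum(axis=0))[0]
    return [
        SitePileup(locus, int(p), tuple(int(c) for c in counts[:, p]))
        for p in covered
    ]


def _snv_sites_from_counts(
    counts: np.ndarray,
    locus: str,
    min_depth: int,
    min_minor_reads: int,
    min_minor_fraction: float,
) -> list[SitePileup]:
    depth = counts.sum(axis=0)
    part = np.sort(counts, axis=0)
    minor = part[-2]
    qual = (
        (depth >= min_depth)
        & (minor >= min_minor_reads)
        & (minor >= min_minor_fraction * depth)
    )
    return [
        SitePileup(locus, int(p), tuple(int(c) for c in counts[:, p]))
        for p in np.nonzero(qual)[0]
    ]


def contaminating_snvs(
    pileups: Union[dict[str, list[SitePileup]], list[SitePileup]],
    min_depth: int = 10,
    min_minor_reads: int = 2,
    min_minor_fraction: float = 0.05,
) -> tuple[int, list[SitePileup]]:
    """Count contaminating SNV sites across pileups.

    A site qualifies when depth >= ``min_depth`` and at least two distinct
    bases are each supported by >= ``min_minor_reads`` reads, with the minor
    (second-most-supported) base at >= ``min_minor_fraction`` of the depth.
    """
    if isinstance(pileups, dict):
        flat = [s for sites in pileups.values() for s in sites]
    else:
        flat = list(pileups)
    snvs = []
    for site in flat:
        depth = site.depth
        if depth < min_depth:
            continue
        top2 = sorted(site.base_counts, reverse=True)[:2]
        if top2[1] >= min_minor_reads and top2[1] >= min_minor_fraction * depth:
            snvs.append(site)
    return len(snvs), snvs


def count_multiallelic_loci(snv_sites: list[SitePileup], min_sites: int = 2) -> int:
    """Loci carrying >= ``min_sites`` SNV sites (a distinct second allele)."""
    per_locus: dict[str, int] = {}
    for s in snv_sites:
        per_locus[s.locus] = per_locus.get(s.locus, 0) + 1
    return sum(1 for n in per_locus.values() if n >= min_sites)


def contamination_call(
    snv_count: int,
    multiallelic_loci: int,
    snv_cutoff: int = 3,
    snv_sites: Optional[list[SitePileup]] = None,
) -> ContaminationCall:
    """Sample-level contamination verdict and contaminant-fraction estimate.

    Contaminated iff ``snv_count >= snv_cutoff`` or any locus is
    multi-allelic. The estimate (median minor-base fraction over SNV sites,
    as a percentage) is not assessed when there are no SNV sites.
    """
    contaminated = snv_count >= snv_cutoff or multiallelic_loci >= 1
    est = None
    if snv_count > 0 and snv_sites:
        minor_fracs = [
            sorted(s.base_counts, reverse=True)[1] / s.depth for s in snv_sites
        ]
        est = float(np.clip(100.0 * float(np.median(minor_fracs)), 0.0, 100.0))
    return ContaminationCall(
        n_contaminating_snvs=snv_count,
        multiallelic_loci=multiallelic_loci,
        contaminated=contaminated,
        est_contamination_percent=est,
    )


def detect_contamination(
    reads,
    core_scheme: Scheme,
    k: int = 31,
    min_depth: int = 10,
    min_minor_reads: int = 2,
    min_minor_fraction: float = 0.05,
    snv_cutoff: int = 3,
    min_base_quality: int = 20,
) -> ContaminationCall:
    """Bait, pile up and call contamination in one step."""
    baited = bait_reads(reads, core_scheme, k)
    all_sites: list[SitePileup] = []
    for locus, locus_reads in baited.items():
        ref = _locus_reference(core_scheme, locus)
        counts = _pileup_counts(ref, locus_reads, k, min_base_quality)
        all_sites.extend(
            _snv_sites_from_counts(
                counts, locus, min_depth, min_minor_reads, min_minor_fraction
            )
        )
    n_snvs = len(all_sites)
    return contamination_call(
        n_snvs, count_multiallelic_loci(all_sites), snv_cutoff, all_sites
    )
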