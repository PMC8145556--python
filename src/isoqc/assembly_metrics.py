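"""Assembly statistics, sketch-based reference selection and contig mapping.

The sketch machinery is a MinHash bottom-s sketch over canonical 21-mers
hashed with splitmix64, with the standard Jaccard-to-distance transform
d = -ln(2j/(1+j))/k. Contig mapping is exact unique-k-mer anchoring merged
into colinear blocks (no gapped alignment), sufficient for low-divergence
assemblies; the duplication ratio follows its verbal definition, aligned
bases divided by reference bases covered at least once.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._kmers import CodeTable, encode, kmer_codes, splitmix64


@dataclass
class AssemblyStats:
    n_contigs: int
    total_length: int
    n50: int
    gc_percent: float
    max_contig: int = 0


def assembly_stats(contigs, min_contig_len: int = 500) -> Optional[AssemblyStats]:
    """Contig count, total length, N50 and GC% after a minimum-length filter.

    Returns None ("no assembly") when no contig survives the filter, which
    drives the failed-sample logic rather than raising.
    """
    kept = [c for c in contigs if len(c.seq) >= min_contig_len]
    if not kept:
        return None
    lengths = np.sort(np.array([len(c.seq) for c in kept]))[::-1]
    total = int(lengths.sum())
    cum = np.cumsum(lengths)
    n50 = int(lengths[np.searchsorted(cum, total / 2)])
    gc = at = 0
    for c in kept:
        codes = encode(c.seq)
        gc += int(np.sum((codes == 1) | (codes == 2)))
        at += int(np.sum((codes == 0) | (codes == 3)))
    gc_percent = 100.0 * gc / (gc + at) if gc + at else 0.0
    return AssemblyStats(
        n_contigs=len(kept),
        total_length=total,
        n50=n50,
        gc_percent=gc_percent,
        max_contig=int(lengths[0]),
    )


# ---------------------------------------------------------------------------
# MinHash sketches and reference selection
# ---------------------------------------------------------------------------

@dataclass
class Sketch:
    label: str
    k: int
    s: int
    hashes: np.ndarray  # sorted uint64, bottom-s
    empty: bool = False


@dataclass
class SketchIndex:
    k: int = 21
    s: int = 1000
    sketches: dict[str, Sketch] = field(default_factory=dict)

    def add(self, label: str, seqs) -> Sketch:
        sk = sketch(seqs, k=self.k, s=self.s, label=label)
        self.sketches[label] = sk
        return sk


def sketch(seqs, k: int = 21, s: int = 1000, label: str = "") -> Sketch:
    """Bottom-s sketch of canonical k-mer hashes over a set of sequences."""
    all_hashes = []
    for rec in seqs:
        seq = rec.seq if hasattr(rec, "seq") else rec
        codes = encode(seq)
        kmers, _ = kmer_codes(codes, k)
        if len(kmers):
            all_hashes.append(splitmix64(kmers.astype(np.uint64)))
    if not all_hashes:
        return Sketch(label, k, s, np.empty(0, dtype=np.uint64), empty=True)
    h = np.unique(np.concatenate(all_hashes))
    return Sketch(label, k, s, h[:s])


def mash_distance(j: float, k: int) -> float:
    """Jaccard-to-distance transform; j=0 maps to the maximal distance 1.0."""
    if j <= 0:
        return 1.0
    return min(1.0, -math.log(2 * j / (1 + j)) / k)


def sketch_jaccard(a: Sketch, b: Sketch) -> float:
    """Jaccard estimate on the merged bottom-s sketch (Mash's estimator)."""
    s = min(a.s, b.s)
    merged = np.unique(np.concatenate([a.hashes, b.hashes]))[:s]
    shared = np.intersect1d(a.hashes, b.hashes, assume_unique=True)
    inter = np.isin(merged, shared, assume_unique=True).sum()
    return float(inter) / len(merged) if len(merged) else 0.0


def select_reference(assembly_sketch: Sketch, reference_sketches: list[Sketch]) -> tuple[str, float]:
    """Closest reference by mash distance; ties broken by lexicographic label."""
    if assembly_sketch.empty or len(assembly_sketch.hashes) == 0:
        raise ValueError("assembly sketch is empty")
    if not reference_sketches:
        raise ValueError("no reference sketches given")
    best: Optional[tuple[float, str]] = None
    for ref in reference_sketches:
        d = mash_distance(sketch_jaccard(assembly_sketch, ref), assembly_sketch.k)
        key = (d, ref.label)
        if best is None or key < best:
            best = key
    return best[1], best[0]


# ---------------------------------------------------------------------------
# Contig-to-reference mapping and duplication ratio
# ---------------------------------------------------------------------------

@dataclass
class ReferenceAlignment:
    ref_length: int
    blocks: list[tuple[str, int, int]]  # (contig id, ref_start, ref_end)
    covered: np.ndarray  # per-base coverage multiplicity over the reference

    @property
    def aligned_bases(self) -> int:
        return sum(end - start for _, start, end in self.blocks)


def _anchor_blocks(diag_pos: dict[int, list[int]], k: int, min_block: int) -> list[tuple[int, int]]:
    """Merge per-diagonal anchor positions into maximal runs -> ref intervals."""
    blocks = []
    for positions in diag_pos.values():
        positions.sort()
        run_start = prev = positions[0]
        for p in positions[1:]:
            if p == prev + 1:
                prev = p
                continue
            if prev + k - run_start >= min_block:
                blocks.append((run_start, prev + k))
            run_start = prev = p
        if prev + k - run_start >= min_block:
            blocks.append((run_start, prev + k))
    return blocks


def map_contigs(contigs, reference: str, k: int = 31, min_block: int = 200) -> ReferenceAlignment:
    """Place contigs on a reference via maximal exact unique-k-mer anchor runs.

    Only k-mers occurring exactly once in the reference anchor; consecutive
    anchors on one diagonal merge into blocks of at least ``min_block`` bases,
    reported in reference coordinates. A contig may yield several blocks;
    unmappable contigs contribute none.
    """
    ref_codes = encode(reference)
    ref_kmers, ref_pos = kmer_codes(ref_codes, k, canonical=False)
    # keep forward k-mers unique in the reference
    order = np.argsort(ref_kmers, kind="stable")
    sk, sp = ref_kmers[order], ref_pos[order]
    uniq_mask = np.ones(len(sk), dtype=bool)
    dup = sk[1:] == sk[:-1]
    uniq_mask[1:][dup] = False
    uniq_mask[:-1][dup] = False
    table = CodeTable(sk[uniq_mask], sp[uniq_mask])

    blocks: list[tuple[str, int, int]] = []
    covered = np.zeros(len(reference) + 1, dtype=np.int32)
    for rec in contigs:
        codes = encode(rec.seq)
        for oriented in (codes, _revcomp_codes(codes)):
            kmers, qpos = kmer_codes(oriented, k, canonical=False)
            if not len(kmers):
                continue
            rpos = table.lookup(kmers)
            hit = rpos >= 0
            if not hit.any():
                continue
            diag_pos: dict[int, list[int]] = {}
            for q, r in zip(qpos[hit], rpos[hit]):
                diag_pos.setdefault(int(r - q), []).append(int(r))
            for start, end in _anchor_blocks(diag_pos, k, min_block):
                blocks.append((rec.id, start, end))
                covered[start] += 1
                covered[end] -= 1
    covered = np.cumsum(covered[:-1])
    return ReferenceAlignment(len(reference), blocks, covered)


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return np.where(codes < 4, 3 - codes, np.uint8(4)).astype(np.uint8)[::-1]


def duplication_ratio(aln: ReferenceAlignment) -> Optional[float]:
    """Aligned assembly bases over reference bases covered at least once.

    >= 1 whenever anything aligned; None ("not assessed") when nothing did.
    """
    covered_once = int(np.count_nonzero(aln.covered))
    if covered_once == 0:
        return None
    return aln.aligned_bases / covered_once


def genome_fraction(aln: ReferenceAlignment, ref_length: Optional[int] = None) -> float:
    """Share of the reference covered by at least one block."""
    ref_length = ref_length or aln.ref_length
    return int(np.count_nonzero(aln.covered)) / ref_length
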