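"""Sequence typing: MLST allele calling, allele distances, core-gene schemes.

A :class:`Scheme` serves three roles: classical 7-gene MLST (with an ST
profile table), cgMLST-like core-gene schemes, and the core-gene set used
for completeness/duplication assessment. Allele calling is exact full-length
substring matching on both strands; scheme building tolerates up to 10%
divergence through anchored extension. Both are deliberate, deterministic
simplifications suited to low-divergence assemblies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from ._kmers import revcomp


@dataclass
class Scheme:
    """Per-locus allele sequences, optionally with an ST profile table.

    ``alleles[locus]`` maps allele id (``<locus>_<n>``) to its sequence;
    ``profiles`` maps an ST label to the tuple of allele ids across ``loci``.
    """

    loci: list[str]
    alleles: dict[str, dict[str, str]]
    profiles: Optional[dict[str, tuple[str, ...]]] = None
    scheme_kind: str = "mlst"

    def __post_init__(self):
        for locus in self.loci:
            seqs = list(self.alleles.get(locus, {}).values())
            if len(set(seqs)) != len(seqs):
                raise ValueError(f"locus {locus!r}: duplicate allele sequences")
        if self.profiles:
            for st, profile in self.profiles.items():
                if len(profile) != len(self.loci):
                    raise ValueError(f"profile {st!r}: wrong number of loci")
                for locus, aid in zip(self.loci, profile):
                    if aid not in self.alleles.get(locus, {}):
                        raise ValueError(f"profile {st!r}: unknown allele {aid!r}")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def total_length(self) -> int:
        return sum(
            len(next(iter(a.values()))) for a in self.alleles.values() if a
        )


@dataclass
class AlleleCalls:
    """Alleles found per locus; ``calls[locus]`` may be empty or hold >1 id."""

    calls: dict[str, set[str]]

    def profile(self) -> dict[str, Optional[str]]:
        """Profile vector for distance computation: the single called allele
        per locus, or None where the locus is missing or ambiguous."""
        return {
            locus: next(iter(ids)) if len(ids) == 1 else None
            for locus, ids in self.calls.items()
        }


@dataclass
class RelatednessCall:
    AD: int
    same_st: bool
    category: str = field(init=False)

    def __post_init__(self):
        self.category = categorize_relatedness(self.same_st, self.AD)


def _assembly_text(contigs) -> str:
    """Concatenated both-strand search text with separators that break matches."""
    fwd = "#".join(c.seq for c in contigs)
    return fwd + "#" + revcomp(fwd)


def call_alleles(contigs, scheme: Scheme) -> AlleleCalls:
    """Exact full-length substring match of every allele against the contigs.

    Both strands are searched; every matching allele id is recorded per
    locus. Absent loci yield empty sets.
    """
    text = _assembly_text(contigs)
    calls: dict[str, set[str]] = {}
    for locus in scheme.loci:
        found = {
            aid for aid, seq in scheme.alleles[locus].items() if seq in text
        }
        calls[locus] = found
    return AlleleCalls(calls)


def sequence_type(calls: AlleleCalls, scheme: Scheme) -> str:
    """Return the ST whose profile matches, or "unknown".

    An ST is assigned only when every locus has exactly one called allele
    and the resulting tuple matches a profile row.
    """
    if not scheme.profiles:
        return "unknown"
    profile = []
    for locus in scheme.loci:
        ids = calls.calls.get(locus, set())
        if len(ids) != 1:
            return "unknown"
        profile.append(next(iter(ids)))
    profile = tuple(profile)
    for st, row in scheme.profiles.items():
        if row == profile:
            return st
    return "unknown"


def duplicated_alleles(calls: AlleleCalls) -> tuple[int, bool]:
    """Count loci with >=2 distinct alleles; contaminated iff count >= 1."""
    count = sum(1 for ids in calls.calls.values() if len(ids) >= 2)
    return count, count >= 1


def allele_distance(profile_a: dict[str, Optional[str]], profile_b: dict[str, Optional[str]]) -> int:
    """Hamming distance over loci non-missing in both profiles."""
    shared = [
        locus
        for locus in profile_a
        if locus in profile_b
        and profile_a[locus] is not None
        and profile_b[locus] is not None
    ]
    if not shared:
        raise ValueError("no comparable loci between profiles")
    return sum(1 for locus in shared if profile_a[locus] != profile_b[locus])


def categorize_relatedness(same_st: bool, ad: int) -> str:
    """Relatedness bins: close (same ST, AD 0), intermediate (1-6 AD),
    distant (AD >= 7).

    AD 1 and the AD-0-but-different-ST corner both fall into the
    intermediate bin, the nearest defined category.
    """
    if ad < 0:
        raise ValueError("allele distance must be >= 0")
    if same_st and ad == 0:
        return "close"
    if ad >= 7:
        return "distant"
    return "intermediate"


# ---------------------------------------------------------------------------
# Core-gene scheme construction (cgMLST-like)
# ---------------------------------------------------------------------------

def _find_occurrences(gene: str, genome: str, min_identity: float, anchor_k: int = 21) -> list[tuple[int, str]]:
    """Locate full-length near-exact copies of ``gene`` in ``genome``.

    Exact matches are found by substring search; otherwise k-mer seeds from
    the gene anchor candidate windows which are accepted at >= ``min_identity``
    ungapped identity. Returns (start, observed_sequence) per occurrence,
    forward strand of ``genome`` only (callers add the reverse strand).
    """
    hits: dict[int, str] = {}
    start = genome.find(gene)
    while start != -1:
        hits[start] = gene
        start = genome.find(gene, start + 1)
    glen = len(gene)
    if glen >= anchor_k:
        # seed every 100 bp along the gene; each seed proposes one window
        for off in range(0, glen - anchor_k + 1, 100):
            seed = gene[off : off + anchor_k]
            pos = genome.find(seed)
            while pos != -1:
                cand = pos - off
                if 0 <= cand <= len(genome) - glen and cand not in hits:
                    window = genome[cand : cand + glen]
                    ident = sum(a == b for a, b in zip(window, gene)) / glen
                    if ident >= min_identity:
                        hits[cand] = window
                pos = genome.find(seed, pos + 1)
    return sorted(hits.items())


def find_gene_copies(gene: str, genome: str, min_identity: float = 0.90) -> list[str]:
    """Observed sequences of all full-length copies of ``gene`` in ``genome``
    (both strands, >= ``min_identity`` ungapped identity)."""
    out = [seq for _, seq in _find_occurrences(gene, genome, min_identity)]
    rc = revcomp(genome)
    out += [revcomp(seq) for _, seq in _find_occurrences(gene, rc, min_identity)]
    return out


def build_core_scheme(
    reference_genes: dict[str, str],
    genomes: list[str],
    min_presence: float = 0.95,
    min_identity: float = 0.90,
) -> Scheme:
    """Construct a core-gene scheme from reference genes and a genome set.

    A locus is retained iff its gene is found exactly once (full length, at
    >= ``min_identity`` identity) in at least ``min_presence`` of the genomes.
    Distinct observed sequences become numbered alleles in order of first
    appearance. Deterministic for a fixed input ordering; the retained locus
    set does not depend on genome order.
    """
    if not reference_genes:
        raise ValueError("no reference genes given")
    if len(genomes) < 2:
        raise ValueError("need at least two genomes to build a core scheme")
    loci: list[str] = []
    alleles: dict[str, dict[str, str]] = {}
    for name, gene in reference_genes.items():
        per_genome = [find_gene_copies(gene, g, min_identity) for g in genomes]
        n_single = sum(1 for copies in per_genome if len(copies) == 1)
        if n_single / len(genomes) < min_presence:
            continue
        loci.append(name)
        seen: dict[str, str] = {}
        for copies in per_genome:
            if len(copies) == 1 and copies[0] not in seen:
                seen[copies[0]] = f"{name}_{len(seen) + 1}"
        alleles[name] = {aid: seq for seq, aid in seen.items()}
    if not loci:
        raise ValueError("no loci retained for the core scheme")
    return Scheme(loci=loci, alleles=alleles, profiles=None, scheme_kind="core")


def core_gene_assessment(contigs, core_scheme: Scheme) -> dict:
    """Completeness and duplication against a core-gene scheme.

    ``unique_fraction`` is the percentage of loci found exactly once;
    ``duplicated_count`` counts loci with >=2 distinct alleles or >=2
    placements of the same allele. A contamination warning is raised only
    when more than one locus is duplicated.
    """
    text = _assembly_text(contigs)
    unique = 0
    duplicated = 0
    for locus in core_scheme.loci:
        placements = 0
        distinct = 0
        for seq in core_scheme.alleles[locus].values():
            # each genomic copy hits once: forward copies in the forward text,
            # reverse-strand copies in the mirrored text (palindromes aside)
            n = 0
            start = text.find(seq)
            while start != -1:
                n += 1
                start = text.find(seq, start + 1)
            if n:
                distinct += 1
                placements += n
        if placements == 1:
            unique += 1
        if distinct >= 2 or placements >= 2:
            duplicated += 1
    total = core_scheme.n_loci
    return {
        "unique_fraction": 100.0 * unique / total if total else 0.0,
        "duplicated_count": duplicated,
        "contamination_warning": duplicated > 1,
    }
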