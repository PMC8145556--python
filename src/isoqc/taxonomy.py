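"""K-mer taxonomic classification of reads and contigs.

The index maps canonical k-mers to taxonomy nodes with an LCA rule: a k-mer
seen in exactly one species maps to that species; in several species of one
genus, to the genus; across genera it is uninformative (root) and ignored.
Each read (or contig) is classified by majority vote over its k-mer hits.
Species purity is the fraction of classified units assigned to the majority
species; at genus rank species hits roll up to their genus and genus-level
hits count directly. Contigs are weighted by their length, so a multi-copy
plasmid contributes once, which is what makes the contig-level fraction
robust against the read-level plasmid bias.

Unclassified units are excluded from the fraction's denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._kmers import CodeTable, encode, kmer_codes, kmer_codes_matrix
from .seqio import as_read_set

ROOT = -2  # k-mer shared across genera: uninformative
UNCLASSIFIED = -1


@dataclass
class KmerIndex:
    k: int
    table: CodeTable  # canonical k-mer code -> node id
    species: list[str]  # node ids 0..n_species-1
    genera: list[str]  # node ids n_species..n_species+n_genera-1
    species_genus: np.ndarray  # species id -> genus id (offset into genera)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def genus_of(self, species_label: str) -> str:
        return self.genera[int(self.species_genus[self.species.index(species_label)])]


@dataclass
class MajorityResult:
    rank: str
    majority_taxon: str
    fraction: float
    unclassified_fraction: float
    fractions: dict[str, float]


def build_index(labeled_genomes: list[tuple[str, str]], taxonomy: dict[str, tuple[str, str]], k: int = 21) -> KmerIndex:
    """Build the classification index from (label, sequence) genomes.

    ``taxonomy`` maps each genome label to its (species, genus). K-mers
    occurring in several species of one genus map to the genus node; across
    genera they map to root and never vote.
    """
    species: list[str] = []
    genera: list[str] = []
    sp_genus: list[int] = []
    for label, _ in labeled_genomes:
        if label not in taxonomy:
            raise ValueError(f"genome {label!r} missing from the taxonomy table")
    sp_of_label: dict[str, int] = {}
    for label, _ in labeled_genomes:
        sp, gen = taxonomy[label]
        if sp not in species:
            species.append(sp)
            if gen not in genera:
                genera.append(gen)
            sp_genus.append(genera.index(gen))
        sp_of_label[label] = species.index(sp)

    chunks = []
    for label, seq in labeled_genomes:
        codes = encode(seq if isinstance(seq, str) else seq.seq)
        # index both strands so reads can be queried with one forward pass
        fwd, _ = kmer_codes(codes, k, canonical=False)
        rc, _ = kmer_codes(
            np.where(codes < 4, 3 - codes, 4).astype(np.uint8)[::-1], k, canonical=False
        )
        kmers = np.concatenate([fwd, rc])
        sid = sp_of_label[label]
        chunks.append(np.stack([kmers, np.full(len(kmers), sid, dtype=np.int64)], axis=1))
    pairs = np.unique(np.concatenate(chunks), axis=0)
    kmer_col, sp_col = pairs[:, 0], pairs[:, 1]
    # group consecutive runs of equal k-mer
    boundary = np.nonzero(np.diff(kmer_col))[0] + 1
    starts = np.concatenate([[0], boundary])
    ends = np.concatenate([boundary, [len(kmer_col)]])
    uniq_kmers = kmer_col[starts]
    sp_genus_arr = np.array(sp_genus, dtype=np.int64)
    n_sp = len(species)
    nodes = np.empty(len(starts), dtype=np.int64)
    single = (ends - starts) == 1
    nodes[single] = sp_col[starts[single]]
    for i in np.nonzero(~single)[0]:
        members = sp_col[starts[i] : ends[i]]
        gens = np.unique(sp_genus_arr[members])
        nodes[i] = n_sp + gens[0] if len(gens) == 1 else ROOT
    keep = nodes != ROOT
    return KmerIndex(
        k=k,
        table=CodeTable(uniq_kmers[keep], nodes[keep]),
        species=species,
        genera=genera,
        species_genus=sp_genus_arr,
    )


def _vote_counts(node_hits: np.ndarray, index: KmerIndex, rank: str) -> np.ndarray:
    """Per-taxon vote counts at the requested rank for one unit's node hits."""
    n_sp = index.n_species
    if rank == "species":
        taxa = node_hits[(node_hits >= 0) & (node_hits < n_sp)]
        return np.bincount(taxa, minlength=n_sp)
    # genus rank: species hits roll up; genus-node hits count directly
    counts = np.zeros(len(index.genera), dtype=np.int64)
    sp_hits = node_hits[(node_hits >= 0) & (node_hits < n_sp)]
    np.add.at(counts, index.species_genus[sp_hits], 1)
    gen_hits = node_hits[node_hits >= n_sp] - n_sp
    np.add.at(counts, gen_hits, 1)
    return counts


def classify_unit(seq, index: KmerIndex, rank: str = "species") -> Optional[str]:
    """Majority-vote taxon of one sequence, or None when no k-mer hits.

    At species rank a tie between species of one genus resolves to their
    genus (reported as the genus label); ties across genera are unresolved
    (None).
    """
    s = seq.seq if hasattr(seq, "seq") else seq
    kmers, _ = kmer_codes(encode(s), index.k, canonical=False)
    if not len(kmers):
        return None
    nodes = index.table.lookup(kmers)
    nodes = nodes[nodes != UNCLASSIFIED]
    if not len(nodes):
        return None
    counts = _vote_counts(nodes, index, rank)
    if counts.sum() == 0:
        # species rank with only genus-level hits: fall back to genus vote
        if rank == "species":
            gcounts = _vote_counts(nodes, index, "genus")
            if gcounts.sum():
                best = np.nonzero(gcounts == gcounts.max())[0]
                return index.genera[best[0]] if len(best) == 1 else None
        return None
    best = np.nonzero(counts == counts.max())[0]
    labels = index.species if rank == "species" else index.genera
    if len(best) == 1:
        return labels[best[0]]
    if rank == "species":
        gens = np.unique(index.species_genus[best])
        if len(gens) == 1:
            return index.genera[gens[0]]
    return None


def _classify_matrix(kmer_mat: np.ndarray, index: KmerIndex, rank: str) -> np.ndarray:
    """Majority taxon id per row of a k-mer matrix; -1 = unclassified."""
    n_units, n_win = kmer_mat.shape
    nodes = index.table.lookup(kmer_mat.ravel()).reshape(n_units, n_win)
    nodes[kmer_mat < 0] = UNCLASSIFIED
    n_sp = index.n_species
    n_gen = len(index.genera)
    n_taxa = n_sp if rank == "species" else n_gen
    rows = np.repeat(np.arange(n_units), n_win)
    flat = nodes.ravel()
    if rank == "species":
        mask = (flat >= 0) & (flat < n_sp)
        taxa = flat[mask]
    else:
        mask = flat >= 0
        taxa = flat[mask].copy()
        sp = taxa < n_sp
        taxa[sp] = index.species_genus[taxa[sp]]
        taxa[~sp] -= n_sp
    counts = np.bincount(
        rows[mask] * n_taxa + taxa, minlength=n_units * n_taxa
    ).reshape(n_units, n_taxa)
    totals = counts.sum(axis=1)
    winners = counts.argmax(axis=1)
    # ties or zero hits -> unclassified at this rank
    top = counts[np.arange(n_units), winners]
    tied = (counts == top[:, None]).sum(axis=1) > 1
    out = winners.astype(np.int64)
    out[(totals == 0) | tied] = UNCLASSIFIED
    return out


def majority_fraction_reads(
    reads, index: KmerIndex, rank: str = "species", stride: int = 4
) -> Optional[MajorityResult]:
    """Majority-taxon fraction over classified reads (each read weighs 1).

    ``stride`` subsamples each read's k-mer windows before voting (a
    minimizer-style thinning; dozens of windows per read remain, so the
    per-read majority is unchanged in practice). Returns None ("not
    assessed") when no read could be classified.
    """
    rs = as_read_set(reads)
    if rs.read_len < index.k or len(rs) == 0:
        return None
    kmer_mat = kmer_codes_matrix(rs.codes, index.k, canonical=False, stride=stride)
    assign = _classify_matrix(kmer_mat, index, rank)
    labels = index.species if rank == "species" else index.genera
    classified = assign[assign >= 0]
    n_total = len(assign)
    if not len(classified):
        return None
    counts = np.bincount(classified, minlength=len(labels))
    fracs = counts / counts.sum()
    best = int(np.argmax(counts))
    return MajorityResult(
        rank=rank,
        majority_taxon=labels[best],
        fraction=float(fracs[best]),
        unclassified_fraction=float((n_total - len(classified)) / n_total),
        fractions={labels[i]: float(fracs[i]) for i in range(len(labels)) if counts[i]},
    )


def majority_fraction_contigs(contigs, index: KmerIndex, rank: str = "species") -> Optional[MajorityResult]:
    """Length-weighted majority fraction over classified contigs.

    Each contig is classified once by best hit (so multi-copy plasmids count
    once) and weighted by its length; the fraction is over classified length.
    """
    contigs = list(contigs)
    labels = index.species if rank == "species" else index.genera
    weights = np.zeros(len(labels))
    unclassified_len = 0
    total_len = 0
    for rec in contigs:
        total_len += len(rec.seq)
        taxon = classify_unit(rec, index, rank)
        if taxon is None or taxon not in labels:
            # species-rank contigs resolved only to genus are not species votes
            unclassified_len += len(rec.seq)
            continue
        weights[labels.index(taxon)] += len(rec.seq)
    if weights.sum() == 0:
        return None
    fracs = weights / weights.sum()
    best = int(np.argmax(weights))
    return MajorityResult(
        rank=rank,
        majority_taxon=labels[best],
        fraction=float(fracs[best]),
        unclassified_fraction=unclassified_len / total_len if total_len else 0.0,
        fractions={labels[i]: float(fracs[i]) for i in range(len(labels)) if weights[i]},
    )
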