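"""Synthetic genomes, reads, contaminated mixtures and the benchmark harness.

The generator emulates the study conditions of an in-silico contamination
experiment: clonal bacterial chromosomes with designated core genes,
relatives constructed at an exact target core-gene allele distance (close =
identical profile, intermediate = a few changed alleles, distant = many),
high-copy plasmids with discordant taxonomic labels, substitution-error
short reads at a set depth, read mixtures at defined contaminant ratios,
and a truth-aware pseudo-assembler that mimics how a real assembler treats
contaminant reads: below a minimum effective depth they vanish, above it
they form separate contigs (whole-genome contigs for intergenus
contaminants, divergent gene copies for intragenus ones).

Read qualities are drawn from a two-point mixture (Q40 bulk plus a Q10
tail) whose implied mean error equals the requested error rate, and each
base's substitution probability follows its own quality — the property
quality-aware downstream steps rely on. Reads carry no indels; no in-scope
metric is indel-sensitive.

Everything is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._kmers import decode, encode
from .seqio import ReadSet, SequenceRecord
from . import assembly_metrics as am
from . import qc_engine as qc
from . import read_metrics as rm
from . import snv_contamination as snv
from . import taxonomy as tax
from . import typing as typ


@dataclass
class Plasmid:
    name: str
    seq: str
    copy_number: int
    label: str  # taxon label used when indexing (may be discordant)


@dataclass
class SyntheticTaxon:
    genus: str
    species: str
    strain: str
    seq: str
    gc_target: float
    core_genes: list[tuple[str, int, int]]  # (name, start, end), non-overlapping
    plasmids: list[Plasmid] = field(default_factory=list)

    @property
    def label(self) -> str:
        return f"{self.species}|{self.strain}"

    def gene_seq(self, index: int) -> str:
        _, start, end = self.core_genes[index]
        return self.seq[start:end]

    def gene_profile(self) -> dict[str, str]:
        """Locus name -> observed sequence, the taxon's exact allele profile."""
        return {name: self.seq[s:e] for name, s, e in self.core_genes}


@dataclass
class MixtureSpec:
    subject: SyntheticTaxon
    contaminant: Optional[SyntheticTaxon]
    ratio: float  # contaminant read share in [0, 1)
    kind: str  # self | intragenus | intergenus
    coverage: float = 50.0
    read_len: int = 150
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.kind == "self" and self.ratio != 0:
            raise ValueError("self samples have ratio 0")
        if self.kind != "self" and self.contaminant is None:
            raise ValueError("contaminated mixtures need a contaminant")


def simulate_genome(
    length: int = 200_000,
    gc_target: float = 0.5,
    n_core_genes: int = 100,
    gene_len: int = 1000,
    seed: int = 0,
    genus: str = "Genus1",
    species: Optional[str] = None,
    strain: str = "ref",
) -> SyntheticTaxon:
    """I.i.d.-base genome at a GC target with evenly spaced core genes.

    Gene i occupies ``[i*spacing, i*spacing + gene_len)`` with
    ``spacing = length // n_core_genes``; the layout must fit.
    """
    spacing = length // n_core_genes
    if spacing < gene_len:
        raise ValueError("genome too short for the requested gene layout")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_target) / 2, gc_target / 2, gc_target / 2, (1 - gc_target) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    genes = [
        (f"gene{i + 1:04d}", i * spacing, i * spacing + gene_len)
        for i in range(n_core_genes)
    ]
    return SyntheticTaxon(
        genus=genus,
        species=species or f"{genus} sp1",
        strain=strain,
        seq=decode(codes),
        gc_target=gc_target,
        core_genes=genes,
    )


def add_plasmid(
    taxon: SyntheticTaxon,
    length: int = 5000,
    copy_number: int = 10,
    label: str = "plasmid_donor",
    seed: int = 0,
    name: Optional[str] = None,
) -> Plasmid:
    """Attach a random plasmid (possibly with a discordant taxon label)."""
    rng = np.random.default_rng(seed)
    gc = taxon.gc_target
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = decode(rng.choice(4, size=length, p=p).astype(np.uint8))
    plasmid = Plasmid(name or f"p{len(taxon.plasmids) + 1}", seq, copy_number, label)
    taxon.plasmids.append(plasmid)
    return plasmid


def simulate_relative(
    taxon: SyntheticTaxon,
    target_ad: int,
    subs_per_allele: int = 3,
    seed: int = 0,
    strain: Optional[str] = None,
) -> SyntheticTaxon:
    """Relative at an exact core-gene allele distance.

    Exactly ``target_ad`` core genes receive ``subs_per_allele``
    substitutions each (changing their allele); everything else is
    untouched, so the measured allele distance recovers ``target_ad``.
    """
    if target_ad > len(taxon.core_genes):
        raise ValueError("target allele distance exceeds the number of core genes")
    rng = np.random.default_rng(seed)
    codes = encode(taxon.seq).copy()
    changed = rng.choice(len(taxon.core_genes), size=target_ad, replace=False)
    for gi in np.sort(changed):
        _, start, end = taxon.core_genes[gi]
        positions = start + rng.choice(end - start, size=subs_per_allele, replace=False)
        codes[positions] = (codes[positions] + rng.integers(1, 4, size=subs_per_allele)) % 4
    return SyntheticTaxon(
        genus=taxon.genus,
        species=taxon.species,
        strain=strain or f"{taxon.strain}_ad{target_ad}_s{seed}",
        seq=decode(codes),
        gc_target=taxon.gc_target,
        core_genes=list(taxon.core_genes),
        plasmids=list(taxon.plasmids),
    )


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

_Q_HIGH, _Q_LOW = 40, 10
_P_HIGH, _P_LOW = 10 ** (-_Q_HIGH / 10), 10 ** (-_Q_LOW / 10)


def _reads_from_source(
    codes: np.ndarray, n_reads: int, read_len: int, error_rate: float, rng
) -> tuple[np.ndarray, np.ndarray]:
    if n_reads <= 0:
        return (
            np.empty((0, read_len), np.uint8),
            np.empty((0, read_len), np.uint8),
        )
    starts = rng.integers(0, len(codes) - read_len + 1, size=n_reads)
    mat = codes[starts[:, None] + np.arange(read_len)[None, :]].copy()
    # reverse-complement roughly half the reads (both strands sequenced)
    flip = rng.random(n_reads) < 0.5
    mat[flip] = np.where(mat[flip] < 4, 3 - mat[flip], 4)[:, ::-1]
    if error_rate <= 0:
        quals = np.full(mat.shape, _Q_HIGH, dtype=np.uint8)
        return mat, quals
    w_low = float(np.clip((error_rate - _P_HIGH) / (_P_LOW - _P_HIGH), 0.0, 1.0))
    low = rng.random(mat.shape) < w_low
    quals = np.where(low, _Q_LOW, _Q_HIGH).astype(np.uint8)
    p_err = np.where(low, _P_LOW, _P_HIGH)
    err = rng.random(mat.shape) < p_err
    n_err = int(err.sum())
    if n_err:
        mat[err] = (mat[err] + rng.integers(1, 4, size=n_err)) % 4
    return mat, quals


def simulate_reads(
    taxon: SyntheticTaxon,
    coverage: float = 50.0,
    read_len: int = 150,
    error_rate: float = 0.01,
    paired: bool = True,
    seed: int = 0,
) -> ReadSet:
    """Uniform-start substitution-error reads at the requested depth.

    Chromosomal bases total ``coverage * len(genome)`` up to one read;
    plasmids are sampled at ``copy_number`` times the chromosomal rate.
    ``paired`` only rounds the read count to full pairs (mates are
    interleaved); no metric depends on insert structure.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    sources = [(encode(taxon.seq), 1.0)]
    for plasmid in taxon.plasmids:
        sources.append((encode(plasmid.seq), float(plasmid.copy_number)))
    mats, quals = [], []
    for codes, copy_number in sources:
        n = int(round(coverage * copy_number * len(codes) / read_len))
        if paired:
            n -= n % 2
        m, q = _reads_from_source(codes, n, read_len, error_rate, rng)
        mats.append(m)
        quals.append(q)
    return ReadSet(np.concatenate(mats), np.concatenate(quals))


def mix_reads(
    subject_reads: ReadSet,
    contaminant_reads: ReadSet,
    r: float,
    total_reads: Optional[int] = None,
    seed: int = 0,
) -> ReadSet:
    """Deterministic contaminated mixture: ``floor(r*total)`` contaminant
    reads, the rest subject, shuffled."""
    total = total_reads if total_reads is not None else len(subject_reads)
    n_cont = int(r * total)
    n_subj = total - n_cont
    if n_subj > len(subject_reads) or n_cont > len(contaminant_reads):
        raise ValueError("not enough reads on one side of the mixture")
    rng = np.random.default_rng(seed)
    si = rng.choice(len(subject_reads), size=n_subj, replace=False)
    ci = rng.choice(len(contaminant_reads), size=n_cont, replace=False)
    codes = np.concatenate([subject_reads.codes[si], contaminant_reads.codes[ci]])
    quals = np.concatenate([subject_reads.quals[si], contaminant_reads.quals[ci]])
    order = rng.permutation(total)
    return ReadSet(codes[order], quals[order])


def simulate_mixture_reads(spec: MixtureSpec) -> ReadSet:
    """Reads for a mixture spec: subject at ``(1-r)`` and contaminant at
    ``r`` of the total depth, shuffled together."""
    rng = np.random.default_rng(spec.seed)
    s_seed, c_seed, m_seed = (int(x) for x in rng.integers(0, 2**31, size=3))
    subject = simulate_reads(
        spec.subject, spec.coverage * (1 - spec.ratio), spec.read_len,
        spec.error_rate, seed=s_seed,
    )
    if spec.ratio <= 0 or spec.contaminant is None:
        return subject
    contaminant = simulate_reads(
        spec.contaminant, spec.coverage * spec.ratio, spec.read_len,
        spec.error_rate, seed=c_seed,
    )
    total = len(subject) + len(contaminant)
    codes = np.concatenate([subject.codes, contaminant.codes])
    quals = np.concatenate([subject.quals, contaminant.quals])
    order = np.random.default_rng(m_seed).permutation(total)
    return ReadSet(codes[order], quals[order])


# ---------------------------------------------------------------------------
# Pseudo-assembly
# ---------------------------------------------------------------------------

def _fragment(
    seq: str,
    n: int,
    rng,
    sigma: float = 0.7,
    keep_intact: Optional[list[tuple[str, int, int]]] = None,
) -> list[str]:
    """Cut a sequence into n contiguous fragments with log-normal sizes.

    With ``keep_intact`` given (gene intervals), internal cut points are
    snapped to the nearest intergenic position: real assemblers break
    contigs at repeats and coverage dips, not inside well-covered genes.
    """
    if n <= 1 or len(seq) < 2 * n:
        return [seq]
    weights = rng.lognormal(0.0, sigma, size=n)
    sizes = np.maximum(1, np.floor(weights / weights.sum() * len(seq)).astype(int))
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    bounds[-1] = len(seq)
    if keep_intact:
        intervals = sorted((s, e) for _, s, e in keep_intact)
        starts = np.array([s for s, _ in intervals])
        ends = np.array([e for _, e in intervals])
        for i in range(1, n):
            b = bounds[i]
            j = np.searchsorted(ends, b, side="right")
            if j < len(starts) and starts[j] < b < ends[j]:
                bounds[i] = starts[j] if b - starts[j] <= ends[j] - b else ends[j]
        bounds = np.unique(bounds)
    return [
        seq[bounds[i] : bounds[i + 1]]
        for i in range(len(bounds) - 1)
        if bounds[i + 1] > bounds[i]
    ]


def divergent_genes(subject: SyntheticTaxon, relative: SyntheticTaxon) -> list[int]:
    """Indices of core genes whose sequences differ between the two strains."""
    return [
        i
        for i in range(len(subject.core_genes))
        if subject.gene_seq(i) != relative.gene_seq(i)
    ]


def pseudo_assemble(
    spec: MixtureSpec,
    min_assembly_depth: float = 10.0,
    frag_n: int = 40,
    seed: Optional[int] = None,
    frag_sigma: float = 0.7,
) -> list[SequenceRecord]:
    """Truth-aware stand-in for a de-novo assembler.

    The subject chromosome is emitted as ``frag_n`` log-normal-sized
    fragments and each plasmid once. Contaminant material appears only when
    its effective depth (total coverage x ratio) reaches
    ``min_assembly_depth``: intergenus contaminants then contribute their
    own fragmented chromosome, intragenus ones only their divergent gene
    copies as extra short contigs (which is what drives duplicated alleles
    and duplicated core genes). Self samples tile the genome exactly.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    contigs = [
        SequenceRecord(f"{spec.subject.strain}_ctg{i + 1}", frag)
        for i, frag in enumerate(
            _fragment(spec.subject.seq, frag_n, rng, frag_sigma, spec.subject.core_genes)
        )
    ]
    for plasmid in spec.subject.plasmids:
        contigs.append(SequenceRecord(f"{spec.subject.strain}_{plasmid.name}", plasmid.seq))
    eff = spec.coverage * spec.ratio
    if spec.contaminant is not None and eff >= min_assembly_depth:
        if spec.kind == "intergenus":
            for i, frag in enumerate(
                _fragment(
                    spec.contaminant.seq, frag_n, rng, frag_sigma,
                    spec.contaminant.core_genes,
                )
            ):
                contigs.append(SequenceRecord(f"contam_ctg{i + 1}", frag))
            for plasmid in spec.contaminant.plasmids:
                contigs.append(SequenceRecord(f"contam_{plasmid.name}", plasmid.seq))
        else:  # intragenus: divergent gene copies assemble separately
            for gi in divergent_genes(spec.subject, spec.contaminant):
                name = spec.subject.core_genes[gi][0]
                contigs.append(
                    SequenceRecord(f"contam_{name}", spec.contaminant.gene_seq(gi))
                )
    return contigs


# ---------------------------------------------------------------------------
# Schemes and taxonomy index from a synthetic panel
# ---------------------------------------------------------------------------

def _scheme_from_profiles(
    loci: list[str],
    profiles: list[dict[str, str]],
    kind: str,
    with_profiles: bool,
) -> typ.Scheme:
    alleles: dict[str, dict[str, str]] = {locus: {} for locus in loci}
    id_of: dict[tuple[str, str], str] = {}
    for prof in profiles:
        for locus in loci:
            seq = prof[locus]
            if (locus, seq) not in id_of:
                aid = f"{locus}_{len(alleles[locus]) + 1}"
                alleles[locus][aid] = seq
                id_of[(locus, seq)] = aid
    st_table = None
    if with_profiles:
        st_table = {}
        seen: dict[tuple[str, ...], str] = {}
        for prof in profiles:
            key = tuple(id_of[(locus, prof[locus])] for locus in loci)
            if key not in seen:
                seen[key] = f"ST{len(seen) + 1}"
                st_table[seen[key]] = key
    return typ.Scheme(loci=loci, alleles=alleles, profiles=st_table, scheme_kind=kind)


def mlst_scheme_from_taxa(taxa: Sequence[SyntheticTaxon], n_loci: int = 7) -> typ.Scheme:
    """Classical 7-gene scheme over the first core genes of the given strains,
    with an ST profile table (one ST per distinct profile)."""
    loci = [taxa[0].core_genes[i][0] for i in range(n_loci)]
    profiles = [{locus: t.gene_profile()[locus] for locus in loci} for t in taxa]
    return _scheme_from_profiles(loci, profiles, "mlst", with_profiles=True)


def core_scheme_from_taxa(taxa: Sequence[SyntheticTaxon]) -> typ.Scheme:
    """Core-gene (cgMLST-like) scheme over all designated core genes."""
    loci = [name for name, _, _ in taxa[0].core_genes]
    profiles = [t.gene_profile() for t in taxa]
    return _scheme_from_profiles(loci, profiles, "core", with_profiles=False)


def panel_taxonomy_index(taxa: Sequence[SyntheticTaxon], k: int = 21) -> tax.KmerIndex:
    """Classification index over the panel's reference genomes (plasmids are
    indexed under their own, possibly discordant, labels)."""
    genomes: list[tuple[str, str]] = []
    taxonomy: dict[str, tuple[str, str]] = {}
    for t in taxa:
        genomes.append((t.label, t.seq))
        taxonomy[t.label] = (t.species, t.genus)
        for plasmid in t.plasmids:
            label = f"{t.label}|{plasmid.name}"
            genomes.append((label, plasmid.seq))
            taxonomy[label] = (plasmid.label, plasmid.label.split()[0])
    return tax.build_index(genomes, taxonomy, k=k)


def allele_profile(taxon: SyntheticTaxon, scheme: typ.Scheme) -> dict[str, Optional[str]]:
    """The strain's profile vector against a scheme (by exact allele lookup)."""
    prof: dict[str, Optional[str]] = {}
    genes = taxon.gene_profile()
    for locus in scheme.loci:
        seq = genes.get(locus)
        match = None
        for aid, allele in scheme.alleles[locus].items():
            if allele == seq:
                match = aid
                break
        prof[locus] = match
    return prof


# ---------------------------------------------------------------------------
# Threshold cohort
# ---------------------------------------------------------------------------

def simulate_strain_metrics(
    taxon: SyntheticTaxon,
    seed: int,
    sub_rate: float = 0.005,
    gc_jitter_sd: float = 0.003,
    length_cv: float = 0.02,
    frag_n: int = 40,
    frag_n_sigma: float = 0.3,
    frag_sigma: float = 0.7,
    min_contig_len: int = 500,
) -> dict:
    """Assembly metrics of one synthetic population strain.

    Population strains carry genome-wide substitutions, a strain-level GC
    drift, gene gain/loss-scale length variation and library-to-library
    fragmentation variability — the between-isolate dispersion real QC
    threshold cohorts are built from, which dwarfs single-sample assembly
    noise.
    """
    rng = np.random.default_rng(seed)
    codes = encode(taxon.seq).copy()
    n_sub = rng.poisson(sub_rate * len(codes))
    if n_sub:
        pos = rng.choice(len(codes), size=min(n_sub, len(codes)), replace=False)
        codes[pos] = (codes[pos] + rng.integers(1, 4, size=len(pos))) % 4
    delta = rng.normal(0.0, gc_jitter_sd)
    n_flip = int(abs(delta) * len(codes))
    if n_flip:
        if delta > 0:  # AT -> GC
            cand = np.nonzero((codes == 0) | (codes == 3))[0]
            new = rng.integers(1, 3, size=min(n_flip, len(cand)))
        else:  # GC -> AT
            cand = np.nonzero((codes == 1) | (codes == 2))[0]
            new = np.array([0, 3])[rng.integers(0, 2, size=min(n_flip, len(cand)))]
        pos = rng.choice(cand, size=len(new), replace=False)
        codes[pos] = new
    f = rng.normal(1.0, length_cv)
    target_len = max(1000, int(f * len(codes)))
    if target_len < len(codes):
        codes = codes[:target_len]
    elif target_len > len(codes):
        gc = taxon.gc_target
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        extra = rng.choice(4, size=target_len - len(codes), p=p).astype(np.uint8)
        codes = np.concatenate([codes, extra])
    n = max(5, int(round(frag_n * rng.lognormal(0.0, frag_n_sigma))))
    seq = decode(codes)
    contigs = [
        SequenceRecord(f"s{seed}_c{i}", frag)
        for i, frag in enumerate(_fragment(seq, n, rng, frag_sigma))
    ]
    stats = am.assembly_stats(contigs, min_contig_len)
    return {
        "species": taxon.species,
        "genus": taxon.genus,
        "assembly_length": stats.total_length,
        "n_contigs": stats.n_contigs,
        "n50": stats.n50,
        "gc_percent": stats.gc_percent,
    }


def simulate_threshold_cohort(
    taxa: Sequence[SyntheticTaxon], n_per_species: int = 100, seed: int = 0, **kwargs
) -> pd.DataFrame:
    """Metric table of pure population strains for threshold derivation."""
    rng = np.random.default_rng(seed)
    rows = []
    for taxon in taxa:
        seeds = rng.integers(0, 2**31, size=n_per_species)
        rows.extend(simulate_strain_metrics(taxon, int(s), **kwargs) for s in seeds)
    return pd.DataFrame(rows)


def derive_panel_thresholds(
    taxa: Sequence[SyntheticTaxon],
    n_per_species: int = 100,
    seed: int = 0,
    min_n: int = 100,
    **kwargs,
) -> qc.ThresholdSet:
    """Quantile thresholds for the panel species plus species-agnostic rules.

    Assembly length, contig count, N50 and GC ranges come from the simulated
    pure cohort (5%/95% quantiles per species, widened to the genus where a
    genus has several species); purity, MLST-duplication, core-duplication
    and SNV rules are species-agnostic defaults.
    """
    cohort = simulate_threshold_cohort(taxa, n_per_species, seed, **kwargs)
    ranges = qc.derive_species_thresholds(cohort, min_n=min_n)
    ts = qc.ThresholdSet(rank_override={})
    for _, row in ranges.iterrows():
        metric = row["metric"]
        if metric == "n50":
            th = qc.MetricThreshold(metric, low=row["low"])  # minimum only
        elif metric == "assembly_length":
            th = qc.MetricThreshold(metric, low=row["low"], high=row["high"], critical=True)
        else:
            th = qc.MetricThreshold(metric, low=row["low"], high=row["high"])
        ts.add(row["species"], th)
    for genus_row in qc.derive_genus_thresholds(ranges).itertuples():
        metric = genus_row.metric
        if metric == "n50":
            th = qc.MetricThreshold(metric, low=genus_row.low)
        elif metric == "assembly_length":
            th = qc.MetricThreshold(metric, low=genus_row.low, high=genus_row.high, critical=True)
        else:
            th = qc.MetricThreshold(metric, low=genus_row.low, high=genus_row.high)
        ts.add(genus_row.genus, th)
    ts.add("all", qc.MetricThreshold("species_purity", low=0.95, critical=True))
    ts.add("all", qc.MetricThreshold("q30_fraction", low=0.90, critical=True))
    ts.add("all", qc.MetricThreshold("mlst_duplicated", high=0))
    ts.add("all", qc.MetricThreshold("duplicated_core_count", high=1))
    ts.add("all", qc.MetricThreshold("snv_contaminated", high=0, critical=True))
    return ts


# ---------------------------------------------------------------------------
# Panel and sensitivity tables
# ---------------------------------------------------------------------------

@dataclass
class PanelConfig:
    """The default benchmark conditions.

    Four genera at distinct GC targets, contaminated pairwise (intergenus)
    and by same-species relatives at close/intermediate/distant allele
    distance (intragenus), at 10/20/30% contaminant read share, 50x depth,
    1% sequencing error, two replicates per cell, plus one self sample per
    genus and replicate.
    """

    n_genera: int = 4
    genome_length: int = 200_000
    n_core_genes: int = 100
    gene_len: int = 1000
    gc_targets: tuple[float, ...] = (0.35, 0.45, 0.55, 0.65)
    coverage: float = 50.0
    read_len: int = 150
    error_rate: float = 0.01
    ratios: tuple[float, ...] = (0.10, 0.20, 0.30)
    distances: dict = field(
        default_factory=lambda: {"close": 0, "intermediate": 4, "distant": 10}
    )
    subs_per_allele: int = 3
    replicates: int = 2
    frag_n: int = 40
    min_assembly_depth: float = 10.0
    mlst_loci: int = 7

    def make_taxa(self, seed: int = 1) -> list[SyntheticTaxon]:
        """The panel's founder genomes (seeds ``seed .. seed+n_genera-1``)."""
        return [
            simulate_genome(
                self.genome_length,
                self.gc_targets[i % len(self.gc_targets)],
                self.n_core_genes,
                self.gene_len,
                seed=seed + i,
                genus=f"Genus{i + 1}",
                species=f"Genus{i + 1} sp1",
            )
            for i in range(self.n_genera)
        ]


_READ_METRICS = {"read_purity", "q30_fraction", "coverage_depth", "snv_contaminated"}
_ASSEMBLY_METRICS = {
    "assembly_length", "n_contigs", "n50", "gc_percent", "contig_purity",
    "mlst_duplicated", "unique_core_fraction", "duplicated_core_count",
    "duplication_ratio",
}
ALL_PANEL_METRICS = sorted(_READ_METRICS | _ASSEMBLY_METRICS)


def _measure_sample(
    spec: MixtureSpec,
    cfg: PanelConfig,
    index: Optional[tax.KmerIndex],
    mlst: Optional[typ.Scheme],
    core: Optional[typ.Scheme],
    metrics: set[str],
    snv_params: Optional[dict] = None,
) -> dict:
    row: dict = {}
    if metrics & _READ_METRICS:
        reads = simulate_mixture_reads(spec)
        if "read_purity" in metrics and index is not None:
            res = tax.majority_fraction_reads(reads, index, "species")
            row["read_purity"] = res.fraction if res else None
        if "q30_fraction" in metrics or "coverage_depth" in metrics:
            stats = rm.compute_read_stats(reads, len(spec.subject.seq))
            row["q30_fraction"] = stats.q30_fraction
            row["coverage_depth"] = stats.est_coverage
        if "snv_contaminated" in metrics and core is not None:
            call = snv.detect_contamination(reads, core, **(snv_params or {}))
            row["snv_contaminated"] = int(call.contaminated)
            row["n_snvs"] = call.n_contaminating_snvs
            row["est_contamination_percent"] = call.est_contamination_percent
    if metrics & _ASSEMBLY_METRICS:
        contigs = pseudo_assemble(spec, cfg.min_assembly_depth, cfg.frag_n)
        stats = am.assembly_stats(contigs)
        if stats is not None:
            row["assembly_length"] = stats.total_length
            row["n_contigs"] = stats.n_contigs
            row["n50"] = stats.n50
            row["gc_percent"] = stats.gc_percent
        if "contig_purity" in metrics and index is not None:
            res = tax.majority_fraction_contigs(contigs, index, "species")
            row["contig_purity"] = res.fraction if res else None
        if "mlst_duplicated" in metrics and mlst is not None:
            calls = typ.call_alleles(contigs, mlst)
            row["mlst_duplicated"] = typ.duplicated_alleles(calls)[0]
        if ("unique_core_fraction" in metrics or "duplicated_core_count" in metrics) and core is not None:
            core_res = typ.core_gene_assessment(contigs, core)
            row["unique_core_fraction"] = core_res["unique_fraction"]
            row["duplicated_core_count"] = core_res["duplicated_count"]
        if "duplication_ratio" in metrics:
            aln = am.map_contigs(contigs, spec.subject.seq)
            row["duplication_ratio"] = am.duplication_ratio(aln)
    return row


def run_panel(
    cfg: Optional[PanelConfig] = None,
    seed: int = 1,
    metrics: Optional[Sequence[str]] = None,
    kinds: tuple[str, ...] = ("self", "intergenus", "intragenus"),
) -> pd.DataFrame:
    """Simulate the benchmark panel and measure every requested metric.

    One row per simulated sample with truth columns (``kind``,
    ``relatedness``, ``ratio``, ``contaminated``) carried through. Fully
    deterministic per seed. ``metrics`` defaults to all panel metrics;
    restricting it skips the corresponding simulation work.
    """
    cfg = cfg or PanelConfig()
    wanted = set(metrics) if metrics is not None else set(ALL_PANEL_METRICS)
    taxa = cfg.make_taxa(seed)
    index = panel_taxonomy_index(taxa) if {"read_purity", "contig_purity"} & wanted else None
    want_mlst = "mlst_duplicated" in wanted
    want_core = bool(
        {"snv_contaminated", "unique_core_fraction", "duplicated_core_count"} & wanted
    )
    rng = np.random.default_rng(seed + 10_000)
    rows = []

    def record(spec: MixtureSpec, subject: SyntheticTaxon, relatedness: Optional[str], rep: int):
        row = {
            "sample": f"{subject.species}|{spec.kind}|{relatedness or '-'}|r{spec.ratio:.2f}|rep{rep}",
            "species": subject.species,
            "genus": subject.genus,
            "kind": spec.kind,
            "relatedness": relatedness,
            "ratio": spec.ratio,
            "replicate": rep,
            "contaminated": spec.kind != "self",
        }
        row.update(_measure_sample(spec, cfg, index, mlst, core, wanted))
        rows.append(row)

    for si, subject in enumerate(taxa):
        relatives = {
            name: simulate_relative(
                subject, ad, cfg.subs_per_allele,
                seed=int(rng.integers(0, 2**31)),
            )
            for name, ad in cfg.distances.items()
        }
        # schemes are species specific (as MLST/cgMLST databases are) and
        # comprehensive: they know the subject's and its relatives' alleles
        scheme_taxa = [subject] + list(relatives.values())
        mlst = mlst_scheme_from_taxa(scheme_taxa, cfg.mlst_loci) if want_mlst else None
        core = core_scheme_from_taxa(scheme_taxa) if want_core else None
        for rep in range(cfg.replicates):
            if "self" in kinds:
                spec = MixtureSpec(
                    subject, None, 0.0, "self", cfg.coverage, cfg.read_len,
                    cfg.error_rate, seed=int(rng.integers(0, 2**31)),
                )
                record(spec, subject, None, rep)
            for ratio in cfg.ratios:
                if "intergenus" in kinds:
                    for cj, contaminant in enumerate(taxa):
                        if cj == si:
                            continue
                        spec = MixtureSpec(
                            subject, contaminant, ratio, "intergenus",
                            cfg.coverage, cfg.read_len, cfg.error_rate,
                            seed=int(rng.integers(0, 2**31)),
                        )
                        record(spec, subject, None, rep)
                if "intragenus" in kinds:
                    for name, relative in relatives.items():
                        spec = MixtureSpec(
                            subject, relative, ratio, "intragenus",
                            cfg.coverage, cfg.read_len, cfg.error_rate,
                            seed=int(rng.integers(0, 2**31)),
                        )
                        record(spec, subject, name, rep)
    return pd.DataFrame(rows)


def flag_contamination(table: pd.DataFrame, thresholds: qc.ThresholdSet) -> pd.DataFrame:
    """Per-metric contamination flags (True = metric claims contamination).

    Purity flags below 0.95; threshold metrics flag outside their resolved
    per-species range; MLST flags on any duplicated locus; core genes on
    more than one duplicated locus; the SNV detector on its own call.
    """
    out = pd.DataFrame(index=table.index)
    for metric in ("read_purity", "contig_purity"):
        if metric in table.columns:
            th = thresholds.lookup("species_purity")
            cut = th.low if th and th.low else 0.95
            out[metric] = table[metric].astype(float) < cut
    for metric in ("assembly_length", "n_contigs", "n50", "gc_percent", "duplication_ratio"):
        if metric in table.columns:
            flags = []
            for _, row in table.iterrows():
                th = thresholds.lookup(metric, row["species"], row["genus"])
                status = qc.evaluate_metric(row[metric], th)
                flags.append(status in (qc.WARN, qc.FAIL))
            out[metric] = flags
    if "mlst_duplicated" in table.columns:
        out["mlst_duplicated"] = table["mlst_duplicated"].fillna(0) >= 1
    if "duplicated_core_count" in table.columns:
        out["duplicated_core_count"] = table["duplicated_core_count"].fillna(0) > 1
    if "unique_core_fraction" in table.columns:
        flags = []
        for _, row in table.iterrows():
            th = thresholds.lookup("unique_core_fraction", row["species"], row["genus"])
            low = th.low if th and th.low is not None else 95.0
            flags.append(float(row["unique_core_fraction"]) < low)
        out["unique_core_fraction"] = flags
    if "snv_contaminated" in table.columns:
        out["snv_contaminated"] = table["snv_contaminated"].fillna(0) >= 1
    return out


def sensitivity_table(
    table: pd.DataFrame,
    thresholds: qc.ThresholdSet,
    grouping: str = "auto",
) -> pd.DataFrame:
    """Per-metric sensitivity by group, plus specificity on self samples.

    Intergenus rows group by subject genus, intragenus rows by relatedness
    (averaging over ratios and contaminants, as the benchmark tables do);
    self rows yield a specificity column ``1 - false-positive rate``.
    Rows are metrics; empty groups are NaN (not assessed).
    """
    flags = flag_contamination(table, thresholds)
    metrics = list(flags.columns)
    result: dict[str, dict[str, float]] = {m: {} for m in metrics}
    inter = table["kind"] == "intergenus"
    intra = table["kind"] == "intragenus"
    selfs = table["kind"] == "self"
    for metric in metrics:
        ok = flags[metric].notna() & table[metric].notna() if metric in table.columns else flags[metric].notna()
        if grouping in ("auto", "intergenus"):
            for genus, idx in table[inter & ok].groupby("genus").groups.items():
                result[metric][f"intergenus:{genus}"] = float(flags[metric][idx].mean())
        if grouping in ("auto", "intragenus"):
            for rel, idx in table[intra & ok].groupby("relatedness").groups.items():
                result[metric][f"intragenus:{rel}"] = float(flags[metric][idx].mean())
        if selfs.any():
            sel = selfs & ok
            if sel.any():
                result[metric]["specificity"] = float(1.0 - flags[metric][sel].mean())
    return pd.DataFrame(result).T
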