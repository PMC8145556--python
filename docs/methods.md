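# Methods

`isoqc` re-creates, as a self-contained library and CLI, the core of an
assembly-based QC pipeline for bacterial isolate sequencing: a suite of
read-, assembly-, taxonomy-, typing- and SNV-based metrics; species-specific
threshold derivation; an automated pass/warning/fail decision with
structured two-branch JSON reporting; and an in-silico contamination
simulator with a benchmark harness. This note records the models,
parameters and design choices, and what the synthetic benchmark does and
does not demonstrate about real data.

## Metric suite

**Read metrics.** Q30 fraction is the share of bases with Phred >= 30;
estimated depth is total bases over a genome length. The denominator is the
sample's assembly length when an assembly exists, else an expected genome
length (the midpoint of the taxon's assembly-length threshold band, falling
back to a configured default). Metrics are computed on the input reads as
given; no trimming is performed. An optional mask replaces bases below Q5
with N for downstream k-mer use only.

**Assembly metrics.** Contigs below `min_contig_len` (default 500 bp, the
common convention) are excluded everywhere. N50 is the largest contig
length L such that contigs of length >= L hold at least half the filtered
assembly; GC% is computed over non-N bases. An assembly with no surviving
contig yields an explicit "no assembly" state that feeds the
failed-sample logic rather than an exception.

**Reference selection.** Genomes are sketched with bottom-s MinHash
(s = 1000) over canonical 21-mers hashed with the splitmix64 finalizer of
the 2-bit-packed k-mer — fixed so sketches are bit-reproducible across
platforms. The Jaccard estimate j on the merged bottom-s sketch converts to
a distance d = -ln(2j/(1+j))/k; j = 0 reports the maximal distance 1.0, and
ties break lexicographically by reference label.

**Contig mapping and duplication ratio.** Contigs are placed on the
selected reference by maximal runs of exactly matching k-mers (k = 31) that
occur uniquely in the reference, merged per diagonal into blocks of at
least 200 bp; both orientations are tried; there is no gapped alignment.
This is a deliberate simplification adequate for low-divergence assemblies;
it under-places highly divergent contigs, which for the QC use case is the
conservative direction. The duplication ratio is aligned assembly bases
divided by reference bases covered at least once — the verbal definition of
"parts of the reference covered by two or more contigs", which differs
subtly from QUAST's internal formula; all tests use constructed cases and
threshold bands, not QUAST parity. Coordinates are 0-based, half-open.

**Taxonomic classification.** A k-mer index (k = 21) over labeled reference
genomes applies an LCA rule: k-mers private to one species map to the
species, k-mers shared across species of one genus map to the genus, k-mers
shared across genera are uninformative and dropped. Both strands are
indexed so reads are queried with a single forward pass. Each read votes
with its k-mer hits (windows subsampled 4-fold, a minimizer-style thinning
that leaves ~30 voting windows per 150 bp read); each contig is classified
once by best hit and weighted by its length. The species-purity metric is
the majority-taxon share of *classified* units; unclassified units are
reported separately and excluded from the denominator (no abundance
re-estimation). Contig-level weighting by length is what neutralizes
multi-copy plasmids: a 10-copy plasmid inflates its read share
copy-number-fold but appears once in the assembly. The purity rank defaults
to species with a per-genus override to genus for genera with indistinct
species boundaries (the bundled default applies this to *Campylobacter*).

**Typing.** MLST allele calling is exact full-length substring matching of
every allele against both strands of the assembly; all matches per locus
are recorded. An ST is assigned only when every locus has exactly one
allele and the tuple matches a profile row. The duplicated-allele
contamination rule flags a sample when at least one locus carries two
distinct alleles. Allele distance is the Hamming distance over loci
non-missing in both profiles; relatedness bins are close (same ST, AD 0),
intermediate (AD 1–6) and distant (AD >= 7). The published bin definition
leaves AD 1 unassigned and is ambiguous about whether "distant" means
exactly 7; we assign AD 1 (and the AD-0-with-different-ST corner) to the
nearest bin, intermediate, and read distant as >= 7.

**Core-gene scheme construction.** A locus from a reference gene set is
retained when the gene is found exactly once — full length, at >= 90%
ungapped identity via exact-seed anchoring — in at least `min_presence`
(default 0.95) of the input genomes; distinct observed sequences become
numbered alleles. The 0.95 presence bound and single-copy requirement
mirror common cgMLST practice. There is no BLAST dependency; anchored
exact/near-exact matching is deterministic and sufficient for
low-divergence genomes, at the cost of missing highly diverged or
rearranged gene copies.

**Core-gene assessment.** Completeness is the percentage of scheme loci
found exactly once; a locus is duplicated when it has two distinct alleles
or two placements. A contamination warning requires more than one
duplicated locus — single duplicated genes occur in clean data.

**SNV-based contamination detection.** Reads are baited to the core-gene
locus sharing the most 31-mers, placed ungapped at their best exact-anchor
offset on the locus reference (the scheme's first allele), and piled up
per site. Reads bearing indels lose their anchors and are dropped — a
documented limitation; none of the in-scope metrics is indel-sensitive. A
site is a contaminating SNV when depth >= 10 and a second base is supported
by >= 2 reads at >= 5% of the depth. Bases below Phred 20 are excluded from
the pileup. This quality filter is load-bearing: at 50x depth and a 1%
mean error rate, raw errors co-occur often enough (expected ~λ³/6 per site
and alternative base, summed over ~10⁵ scheme sites) to produce hundreds of
spurious SNV sites per pure sample; restricting to high-quality bases drops
the residual error to ~10⁻⁴ and the expected spurious count to ~0, which is
what gives the detector its specificity while leaving true minor alleles
(present at the mixing ratio) untouched. A locus with >= 2 SNV sites is
multi-allelic (the signature of a second allele). A sample is called
contaminated when the genome-wide SNV count reaches 3 or any locus is
multi-allelic; all cutoffs are configurable. The contaminant fraction is
estimated as the median minor-base fraction over SNV sites — in a haploid
two-strain mixture the minor fraction at a divergent site estimates the
contaminant read share directly, and on the synthetic panel this estimator
recovers the mixing ratio to within a few percentage points.

## Threshold derivation and decision rules

Species-specific ranges are empirical 5%/95% quantiles (linear
interpolation, so derived thresholds are reproducible) over all samples of
a species, computed only for species with at least 100 samples; a genus
range takes the minimum of its species' lows and the maximum of their
highs. Threshold lookup resolves species, then genus, then species-agnostic
defaults; taxa without thresholds simply skip those checks.

The bundled `data/thresholds.tsv` carries the default ranges for
*Salmonella enterica*, *Listeria monocytogenes*, *Escherichia coli* and
*Campylobacter* spp. (assembly length, contig count, GC, N50, duplication
ratio, coverage, core-gene completeness) plus species-agnostic rules
(purity > 0.95, at most one duplicated core gene, no duplicated MLST
allele, SNV status negative). The Q30 bound (fraction >= 0.90) is a package
default chosen for modern Illumina output, where Q30 fractions below 0.9
indicate a problematic run.

Critical metrics — Q30 fraction, coverage depth, assembly length, the
combined taxonomy status and the SNV contamination status — fail a sample
when out of range; contig count, N50, GC, MLST duplication, core-gene
completeness/duplication and duplication ratio only warn. The combined
taxonomy status fails only when *both* read- and contig-level purity fall
below the cut, warns when exactly one does (the read-level plasmid-bias
pattern), and a single assessed value decides alone. Warn bands for
critical metrics are supported (`warn_low`/`warn_high` nested inside the
fail range) but default to the fail range, collapsing the two tiers; the
published decision rules mention a warning tier without defining it, so the
default keeps the defined behavior and leaves the band as configuration.
The verdict is fail iff any critical metric fails, warning iff anything
warns, else pass — by construction monotone: worsening a metric can never
improve the verdict.

Reports are two-branch JSON: `pipeline` holds unaltered per-module results
with timestamps, `sample` the configuration, summary metrics, per-metric
statuses and verdict. Validation and filtering use a small structural
schema dialect (`type`/`required`/`properties`): the filter keeps exactly
the keys a schema node lists and keeps subtrees verbatim where a node lists
none, so the empty schema is the identity and filtering is idempotent.
Batch execution records per-sample module failures (e.g. "no assembly")
with a reason, continues over surviving samples, caches per-sample reports
keyed by an input-content checksum so reruns after fixing a failed sample
reuse prior results, and emits an aggregate TSV plus a static traffic-light
HTML table.

## The synthetic panel

The generator defines the study conditions the benchmark and the
acceptance checks run under; its defaults are fixed.

* **Genomes**: four "genera", i.i.d.-base chromosomes of 200 kb at GC
  targets 35/45/55/65% (distinct, as real genera differ), with 100
  designated non-overlapping core genes of 1 kb on a 2 kb spacing; the
  first seven double as the MLST loci. Tests use the same design at 40 kb /
  20 genes to keep the suite fast; the measured sensitivities are
  scale-robust because they depend on ratios and allele distances, not
  genome size.
* **Relatives**: a relative at target allele distance d receives exactly 3
  substitutions in each of d randomly chosen core genes and is untouched
  elsewhere, so the measured allele distance recovers d exactly. A close
  relative (d = 0) is genomically identical — the hardest case, and the
  reason every metric is blind to close contamination on this panel.
* **Reads**: uniform start positions, 150 bp, 50x; plasmids are sampled at
  copy-number-fold the chromosomal rate. Per-base qualities are drawn from
  a two-point mixture (Q40 bulk, Q10 tail) whose weights make the implied
  mean error equal the requested error rate (default 1%), and each base's
  substitution probability follows its own quality — the realistic
  quality–error coupling that quality-aware pileup filtering relies on.
  There are no indels and no quality-by-cycle structure.
* **Mixtures**: a contaminated sample takes floor(r x total) contaminant
  reads, the rest subject; ratios 10/20/30%.
* **Pseudo-assembly**: a truth-aware stand-in for a de-novo assembler. The
  subject chromosome is emitted as 40 log-normal-sized fragments with cut
  points snapped to intergenic positions (assemblers break at repeats and
  coverage dips, not inside well-covered single-copy genes); plasmids are
  emitted once. Contaminant material appears only when its effective depth
  (total coverage x ratio) reaches 10x — below that, contaminant reads
  vanish into the subject's consensus; above it, intergenus contaminants
  contribute their own fragmented chromosome and intragenus contaminants
  their divergent gene copies as extra short contigs, which is what drives
  duplicated MLST alleles and duplicated core genes. The 10x bar is our
  mechanistic encoding of observed assembler behavior at small mixing
  ratios; benchmark cells that depend on assembly behavior are therefore
  properties of this model, not reproductions of any particular assembler.
* **Threshold cohort**: quantile thresholds for the panel species are
  derived from 100 simulated *population strains* per species. A population
  strain carries genome-wide substitutions (0.5%), a strain-level GC drift
  (sd 0.3 GC points), gene gain/loss-scale length variation (cv 2%) and
  library-to-library fragmentation variability — the between-isolate
  dispersion real threshold cohorts are built from, which dwarfs
  single-sample assembly noise. This matters statistically: bands derived
  from replicates with the *same* noise as the evaluated sample would
  exclude ~10% of clean samples by construction. Because the cohort is
  centered on the founder strain, the founder's own samples sit mid-band,
  and the GC/length perturbations of a same-species contaminant (a few
  hundred substituted bases, a few kb of extra gene copies) are an order of
  magnitude smaller than the band width.
* **Schemes** are species-specific and comprehensive, as real MLST/cgMLST
  databases are: each genus' scheme holds the subject's and its relatives'
  alleles, never another genus'.

### What the panel does and does not show

The panel reproduces the *structure* of the published sensitivity tables:
read-level purity catches every intergenus contamination at >= 10% mixing;
assembly-derived metrics (contig count, assembly length, contig purity)
catch intergenus contamination only once the contaminant assembles
(ratios >= 20% at 50x); GC, read purity and duplicated MLST alleles are
blind to intermediate/close intragenus contamination; the core-gene SNV
detector catches every distant intragenus contamination and stays negative
on pure samples.

It does not emulate: cross-genus homology (random genomes share no genes,
so the SNV detector and core-gene metrics cannot see intergenus
contamination here, whereas universal-gene schemes give real ConFindr-style
detectors intergenus sensitivity); real genome structure (repeats, mobile
elements, compositional skew); assembler artifacts beyond the 10x
inclusion rule; or close relatives that differ outside the typing scheme.
Passing the benchmark therefore validates the metric implementations and
the decision logic under controlled truth, not field performance on real
sequencing runs.

## Problem sizes

The default benchmark (acceptance script) runs the full conditions above:
72 intergenus samples for the read-purity check, 24 samples per intragenus
cell, 400 cohort strains for threshold derivation — about six minutes on
one CPU. The pytest suite runs the same design at 40 kb genomes with 20
core genes (~1 minute) plus property tests; the SNV specificity sweep uses
100 pure 20 kb samples at full 50x depth.
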