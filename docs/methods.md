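# Methods

This note documents the models, defaults and design choices behind
`radmarkers`, and what the simulation-based validation does and does not
demonstrate.

## The discovery problem

Marker panels for non-model, genetically depleted species must be built
from low-coverage sequence with no reference genome. Two library designs
are modelled. In RAD-seq, a restriction digest (EagI, recognition
`CGGCCG`, cut after the first base) anchors short fragments at cut
sites; asymmetric paired-end sequencing reads 40 bases from the cut
(the *unitag*) and 80 bases from a randomly sheared end 300–800 bp away.
Because every copy of a locus yields the identical unitag, exact-match
clustering of forward reads groups read pairs by locus without any
reference, and the paired reverse reads of each cluster tile the
adjacent 220–800 bp for local assembly. In the shotgun design, long
reads (mean 348 bp) from two individuals are pooled into a combined de
novo assembly that is then used as the calling reference.

## Simulator (`simdata`)

The genome is laid out locus-by-locus: each planted site carries
`insert_max + 50` bases of unique flank on both sides, so the two RAD
loci of a cut (one per direction) never interfere. After assembly of the
full sequence, chance occurrences of the recognition sequence are
scrubbed by flipping one base to A/T (the site is all-G/C, so this can
never create a new occurrence); digesting the reference therefore
returns exactly the planted sites, which is what makes digest-recall
testable.

Genotypes. Each variant site draws per-individual genotypes from
Hardy–Weinberg class probabilities `((1-p)^2, h', p^2)` with
`h' = 2p(1-p)`. Two genotype patterns are reserved for explicitly
planted features and rejected when drawn for ordinary variants: the
singleton-heterozygote pattern (that is what a planted private allele
is) and the all-heterozygote pattern (the signature of a planted
duplicated locus). So that the *conditional* per-individual
heterozygosity still equals the configured target (default 0.057), `h'`
is calibrated by bisection on the closed-form conditional expectation;
for 8 individuals and target 0.057 the calibrated per-site value is
0.081. Consequences worth knowing: ordinary variants never appear as
singletons, and private-allele counts on error-free calls equal the
planted `n_private_per_individual` exactly.

Duplicated segments copy a whole locus block verbatim with exactly one
substitution per cut direction, placed in the well-covered core. Both
copies share the unitag, so their reads collapse into one cluster at
twice the depth — mechanically reproducing how co-amplifying paralogs
produce loci at which every individual appears heterozygous. Duplicated
loci carry no ordinary variants (real co-amplifying loci in such panels
are monomorphic), which also keeps paralog read dilution out of the
genotype-recovery measurement.

Coverage is parameterized as target per-base depth over the reverse-read
span (`insert_max − insert_min + 80` = 580 bp at defaults); the read
count per tag per individual is `depth × span / 80` (default per-base
depth 12.9, matching the contig coverage such libraries typically
yield). Note the distinction from *cluster* depth: a per-base depth of
30 corresponds to ~218 read pairs in the unitag cluster.

Reads are emitted already oriented on the locus strand
(upstream-direction loci are represented reverse-complemented), because
the minimal assembler and mappers are deliberately single-strand. Base
qualities are constant Phred 30, dropped to 10 at injected error
positions; the RAD caller uses counts, not qualities. Shotgun read
lengths follow a normal(348, 60) truncated to [100, 800] — the mean is
the design value, the spread chosen to give the long right tail such
instruments produce. Replicate PCR genotypes fail with `fail_rate`,
drop one allele of a heterozygote with `ado_rate`, and add a spurious
allele to any post-dropout homozygote with `fa_rate` (defaults 0.1 /
0.2 / 0.01, the regime such validation panels report).

What the simulator does **not** emulate: PCR duplicates, indel
sequencing errors on the RAD path, base-quality miscalibration,
strand-of-origin ambiguity, GC-coverage bias, and CpG depletion of
recognition sites. Passing tests therefore demonstrate algorithmic
correctness under clean library geometry, not robustness to every
artifact of real libraries.

## Assembly (`radassembly`)

Unitag clustering is exact-match; sequencing errors fall out of clusters
and are absorbed by the 5x–500x depth window (defaults from the unitag
coverage range such pipelines use). Each cluster is assembled by a
single-k de Bruijn walk (k = 31): greedy maximal paths seeded from the
highest-count k-mer, extending through forks along the strictly-majority
edge with a lexicographic tie-break. A heterozygous site inside a locus
therefore yields a contig carrying one allele (the variation is
recovered at the calling stage); a collapsed paralog's fixed difference
likewise survives as a single base in the contig, which is essential for
the fixed-heterozygosity screen to see it. There is no bubble popping,
scaffolding or error correction. Contigs shorter than 150 bp are
dropped (the observed floor of such assemblies). Under the default
300–800 bp insert range the unitag k-mers form a disconnected 40 bp
island, so the "locus contig" flag falls to the longest retained path.

Assemblies with mean depth outside [0.25x, 4x] the sample's median are
removed as under-covered or repetitive; the factor-2 depth of two-copy
paralogs deliberately survives this window. The mini-reference is the
sample maximizing contig count (ties: total bases, then smallest id).

## Mapping and calling (`aligncall`)

RAD mode places 80 bp reads by exact 20-mer seeds and ungapped
full-length extension, accepting ≤4 mismatches with a unique best hit
(ties are discarded as ambiguous). Shotgun mode seeds the same way and
extends with a banded edit-distance alignment (edlib) so gaps are
observed; insertions and deletions are recorded against the
left-anchoring base. No indel realignment is performed, so an indel
whose edge bases match its context may be reported as adjacent
sub-events.

The threshold caller needs ≥5 reads (below that the genotype is
missing); an alternate fraction exactly at the threshold calls
heterozygous — alternate evidence *at* the nominal rate counts. Sites
with a recurrent third allele are flagged tri-allelic and excluded from
assay design. Indels are modelled only on the shotgun path (the RAD
mapper is ungapped by construction).

## Marker filtering and statistics

`assaydesign.filter_assayable` applies the transparent surrogate for a
proprietary designability score: bi-allelic, ±60 bp free of other
polymorphism (indels and tri-allelic residues included), ≥30 bp to both
contig ends, one SNP per contig (highest quality, ties leftmost). A
`design_score` equal to the fraction of rules passed is emitted for
report compatibility. Multiplex grouping is a plain ≤40 split in input
order; primer-mass chemistry is out of scope.

Percentages in reports are *truncated* at the printed precision (the
convention of published marker tables, where 18.876% prints as 18.8%);
ts/tv ratios are rounded to two decimals. The ADO estimator conditions
on heterozygous consensuses; entries whose repeated dropouts disguise
them as homozygotes leave the denominator, so the estimate sits slightly
below truth (exact expectation 0.1956 at rate 0.2 with 4 replicates and
no failures, 0.186 with 10% failures) — a property of consensus-based
estimation itself, visible in `examples/05_replicate_qc.py`. SNP density
is reported as SNPs per base of the contig set screened, to two
significant figures.

## Validation scale and numerics

The end-to-end validation study uses 8 individuals, 100 planted sites
(200 RAD loci, 10 of them duplicated), per-base depth 30 and error-free
reads over a 250 kb genome — the smallest configuration at which every
stage (clustering, paralog collapse, mini-reference mapping, threshold
calling, private-allele counting) operates in its intended regime; it
completes in well under a minute. Locus recovery is scored as the
flagged contig being an exact substring of one of the sample's true
haplotype sequences: under uniform shearing the span endpoints are
stochastic, so exactness is judged over the assembled span while any
internal mis-assembly fails the test. Monte-Carlo checks of the
expected-site-count formula use 200 random 100 kb genomes per GC value
and a 3-standard-error band.

Degenerate inputs: an empty truth set yields empty read streams with a
warning; zero-depth positions are missing genotypes; an all-missing
replicate entry is missing rather than no-consensus; `n50` and the
summary operations reject empty inputs explicitly rather than returning
sentinel values.
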