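# radmarkers

De novo discovery of SNP and microsatellite markers for species with no
reference genome and very low genetic diversity, from two complementary
sequencing designs:

* **RAD-seq**: short paired-end reads (40 x 80 bp) anchored at the cut
  sites of a restriction enzyme (EagI, `CGGCCG` by default). Loci are
  clustered by their *unitag* (the unique single-end sequence at the
  cut), locally assembled per sample with a minimal de Bruijn walker,
  and genotyped against the best sample's contig set used as a
  "mini-reference".
* **shotgun**: long single-end reads (mean 348 bp) from a couple of
  individuals, pooled into one combined assembly and genotyped with
  quality-gated SNP/indel calls.

The package is aimed at conservation-genomics workflows where a marker
panel (a multiplexed genotyping assay plus microsatellite primers) must
be designed from low-coverage data, and where genotypes are validated by
replicate PCR. It is a library first (`import radmarkers`), with short
narrative scripts under `examples/` and a thin `radmarkers` CLI.

## The statistics at the core

* **Threshold genotype model** — at a site with `ref + alt = d >= 5`
  reads and alternate fraction `f = alt/d`: `f < t` calls the homozygous
  reference, `f > 1 - t` the homozygous alternate, anything in between a
  heterozygote; default `t = 0.075`.
* **Surrogate site quality** — `Q = min(60, -10 log10 P(X >= alt))` with
  `X ~ Binomial(d, e)`, `e = 0.01`; shotgun substitutions require
  `Q >= 20`, indels `Q >= 50`.
* **Assay-design filter** — a marker is assayable when bi-allelic, free
  of other polymorphism within ±60 bp, ≥30 bp from both contig ends, and
  the only selected SNP on its contig; multiplexes hold ≤40 markers.
* **Paralog screen** — a locus where every genotyped individual is
  heterozygous is flagged as two co-amplifying monomorphic loci and split
  in two for population bookkeeping.
* **Replicate QC** — consensus alleles are those seen in ≥2 PCR
  replicates; allelic dropout (ADO) is a positive amplification of a het
  consensus showing one consensus allele, a false allele (FA) any
  amplification showing a non-consensus allele.
* **SSR scan** — maximal perfect tandem runs of 1–4 bp motifs under
  canonical motif naming (lexicographic minimum over rotations and the
  reverse complement); a run with ≥3 repeats and ≥30 clean flanking bases
  per side is a *potentially amplifiable locus* (PAL).

Everything is exercised end-to-end on a truth-linked simulator
(`radmarkers.simdata`) that plants enzyme sites, a low-heterozygosity
SNP spectrum (target mean Ho ≈ 0.057), individual-private alleles,
duplicated segments (the fixed-heterozygosity mechanism), and
microsatellites, then emits barcoded RAD pairs, shotgun reads, and
replicate genotypes with injected ADO/FA events.

## Worked example

`python examples/02_rad_pipeline.py` simulates 8 barcoded individuals
over 12 planted cut sites (24 RAD loci, 2 of them duplicated) and runs
the full RAD pipeline:

```
mini-reference sample : sample2
contigs               : 25 (13,759 bp, N50 573, range 280-580)
variant sites called  : 20
assayable markers     : 14 in 1 plex(es)
fixed-het (paralog)   : 4 loci
private alleles       : {'sample1': 1, 'sample2': 1, ..., 'sample8': 1}
locus recovery        : 192/192
genotype concordance  : 256/256
```

The sample with the most assembled contigs becomes the mini-reference;
20 variant sites are called of which 14 survive the assay-design rules;
the 4 fixed-heterozygote loci are exactly the two planted duplicated
segments (each contributes one locus per cut direction); with error-free
reads, every planted locus is reconstructed as an exact haplotype
substring and every genotype call matches the planted truth. The other
examples cover digest prediction, the shotgun path, SSR/PAL
classification, replicate QC, and panel summary statistics.

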