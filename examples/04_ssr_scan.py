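"""Microsatellite detection and PAL classification on one contig.

Shows canonical motif naming (TG/GT/CA/AC are all class AC), compound
annotation of nearby runs, and the two-threshold PAL / primer-candidate
flags.
"""

from radmarkers.ssr import classify_compound, classify_pal, find_ssrs

flank = ("AACCGGTTACGT" * 5)[:40]          # repeat-free filler
contig = flank + "TG" * 6 + "AGC" + "AT" * 4 + flank + "CAGT" * 5 + flank

loci = find_ssrs(contig, {1: 8, 2: 3, 3: 3, 4: 3})
classify_compound(loci, max_gap=10)
for locus in loci:
    classify_pal(locus, contig)

print(f"{'span':>12}  {'motif':<6}{'class':<7}{'reps':<6}"
      f"{'compound':<10}{'pal':<5}{'primer'}")
for locus in loci:
    print(f"{locus.start:>5}-{locus.end:<6} {locus.motif:<6}"
          f"{locus.ssr_class:<7}{locus.repeats:<6}"
          f"{str(locus.compound):<10}{str(locus.pal):<5}"
          f"{locus.primer_candidate}")
print()
print("The TG run is reported under its canonical motif AC; it and the AT")
print("run sit 3 bp apart so both are compound. PAL needs >=3 repeats and")
print("30 clean flanking bases on each side; primer candidates need >=4")
print("repeats, so the (ACTG)5 run qualifies while a 3-repeat run would not.")
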