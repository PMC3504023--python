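"""VCF 4.2 output of called sites and round-trip reading.

Writing serializes our own :class:`~radmarkers.aligncall.SiteCall`
records (one record per variant site, GT and DP per sample, 1-based
coordinates per the VCF standard); reading goes through cyvcf2 and
reconstructs the retained fields."""

from __future__ import annotations

import os

from cyvcf2 import VCF

from .aligncall import HET, HOM_ALT, HOM_REF, MISSING, SiteCall

_GT_TO_VCF = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
_VCF_TO_GT = {v: k for k, v in _GT_TO_VCF.items()}


def write_vcf(calls: list[SiteCall], contigs: dict[str, str], path: str,
              samples: list[str] | None = None) -> int:
    """Write calls as VCF 4.2 with contig headers; returns record count."""
    if samples is None:
        samples = sorted({s for c in calls for s in c.genotypes})
    unknown = {c.contig for c in calls} - set(contigs)
    if unknown:
        raise ValueError(f"calls reference unknown contigs: {sorted(unknown)[:3]}")
    lines = ["##fileformat=VCFv4.2", "##source=radmarkers"]
    for cid in sorted(contigs):
        lines.append(f"##contig=<ID={cid},length={len(contigs[cid])}>")
    lines.append('##INFO=<ID=INDEL,Number=0,Type=Flag,Description="Indel site">')
    lines.append('##INFO=<ID=TRIALLELIC,Number=0,Type=Flag,Description="Third allele observed">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    n = 0
    for c in sorted(calls, key=lambda x: (x.contig, x.pos)):
        info_flags = []
        if c.is_indel:
            info_flags.append("INDEL")
        if c.tri_allelic:
            info_flags.append("TRIALLELIC")
        info = ";".join(info_flags) or "."
        fields = [
            c.contig, str(c.pos + 1), ".", c.ref, c.alt,
            f"{c.quality:.4g}", "PASS", info, "GT:DP",
        ]
        for s in samples:
            gt = _GT_TO_VCF[c.genotypes.get(s, MISSING)]
            rc, ac = c.counts.get(s, (0, 0))
            fields.append(f"{gt}:{rc + ac}")
        lines.append("\t".join(fields))
        n += 1
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return n


def read_vcf(path: str) -> tuple[list[SiteCall], dict[str, int], list[str]]:
    """Read a VCF written by :func:`write_vcf`.

    Returns (calls, contig lengths, samples). Malformed records raise a
    ValueError carrying the 1-based record index.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    reader = VCF(path)
    samples = list(reader.samples)
    contig_lengths = {}
    for raw in reader.raw_header.splitlines():
        if raw.startswith("##contig="):
            body = raw.split("<", 1)[1].rstrip(">")
            kv = dict(item.split("=", 1) for item in body.split(","))
            contig_lengths[kv["ID"]] = int(kv["length"])
    calls: list[SiteCall] = []
    for i, rec in enumerate(reader, start=1):
        try:
            alt = rec.ALT[0] if rec.ALT else rec.REF
            genotypes = {}
            counts = {}
            depths = rec.format("DP")
            for j, s in enumerate(samples):
                gt_str = _gt_string(rec.genotypes[j])
                genotypes[s] = _VCF_TO_GT[gt_str]
                dp = int(depths[j][0]) if depths is not None else 0
                # REF/ALT split is not stored; keep the depth on the called
                # allele side so DP round-trips
                if genotypes[s] == HOM_ALT:
                    counts[s] = (0, dp)
                elif genotypes[s] == HET:
                    counts[s] = (dp - dp // 2, dp // 2)
                else:
                    counts[s] = (dp, 0)
            calls.append(SiteCall(
                contig=rec.CHROM, pos=rec.POS - 1, ref=rec.REF, alt=alt,
                genotypes=genotypes, counts=counts,
                quality=float(rec.QUAL) if rec.QUAL is not None else 0.0,
                is_indel=rec.INFO.get("INDEL") is not None,
                tri_allelic=rec.INFO.get("TRIALLELIC") is not None,
            ))
        except (KeyError, IndexError, TypeError) as exc:
            raise ValueError(f"malformed VCF record #{i} in {path}: {exc}") from exc
    return calls, contig_lengths, samples


def _gt_string(gt_entry) -> str:
    # cyvcf2 genotype entries are [allele0, allele1, phased]
    a, b = gt_entry[0], gt_entry[1]
    if a < 0 or b < 0:
        return "./."
    return f"{min(a, b)}/{max(a, b)}"
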