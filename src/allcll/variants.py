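"""Pileup-based SNV/indel calling over driver targets and VAF-tier filtering.

The caller is a reference implementation: its role is to make the filter
tiers and the end-to-end pipeline testable on the ~1500x capture data the
panel produces, and externally produced VCFs can be fed straight into
:func:`apply_vaf_filters`. The tiers follow the analysis rules: variants
below 2% VAF are filtered out; 2-3% are called but flagged low-confidence
(reproducibility across runs is only guaranteed at >= 3%); >= 3% pass.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .reference import ReferenceBundle


@dataclass
class VariantConfig:
    min_base_q: int = 20
    min_mapq: int = 20
    min_depth: int = 100
    min_alt_reads: int = 5
    vaf_cutoff: float = 0.02
    high_confidence_vaf: float = 0.03


@dataclass
class VariantCall:
    chrom: str
    pos: int                 # 1-based, VCF export convention
    ref: str
    alt: str
    depth: int
    alt_count: int
    gene: str
    filters: set[str] = field(default_factory=set)
    status: str = "pass"     # pass | low_confidence | filtered

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0


def pileup_call(alignments, reference: Mapping[str, str], bundle: ReferenceBundle,
                config: VariantConfig | None = None) -> list[VariantCall]:
    """Per-position allele counts from quality-filtered bases over driver
    targets; SNVs and simple CIGAR indels with alt_count >= min_alt_reads.

    ``reference`` maps contig name to genomic sequence (dict, pyfaidx.Fasta,
    or anything sliceable by name).
    """
    config = config or VariantConfig()
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
            records = [r for r in fh if not r.is_unmapped]
    else:
        records = list(alignments)
    targets = bundle.targets_by_role("driver")
    in_target = {}
    for t in targets:
        in_target.setdefault(t.chrom, []).append(t)

    depth: dict[tuple[str, int], int] = defaultdict(int)
    alt_counts: dict[tuple[str, int, str, str], int] = defaultdict(int)

    for rec in records:
        chrom = rec.reference_name
        if chrom not in in_target:
            continue
        if rec.is_duplicate or rec.mapping_quality < config.min_mapq:
            continue
        if not any(t.start < rec.reference_end and rec.reference_start < t.end
                   for t in in_target[chrom]):
            continue  # on a driver chromosome but off-target (e.g. backbone)
        seq = rec.query_sequence
        quals = rec.query_qualities
        ref_seq = reference[chrom]
        q, r = 0, rec.reference_start
        for op, length in rec.cigartuples or []:
            if op in (0, 7, 8):  # aligned
                for i in range(length):
                    if quals[q + i] < config.min_base_q:
                        continue
                    pos = r + i
                    depth[(chrom, pos)] += 1
                    base = seq[q + i]
                    refb = str(ref_seq[pos]).upper()
                    if base != refb:
                        alt_counts[(chrom, pos, refb, base)] += 1
                q += length
                r += length
            elif op == 1:  # insertion anchored at previous ref base
                anchor = r - 1
                refb = str(ref_seq[anchor]).upper()
                ins = seq[q:q + length]
                alt_counts[(chrom, anchor, refb, refb + ins)] += 1
                q += length
            elif op == 2:  # deletion anchored at previous ref base
                anchor = r - 1
                refb = str(ref_seq[anchor]).upper()
                deleted = str(ref_seq[anchor + 1:anchor + 1 + length]).upper()
                alt_counts[(chrom, anchor, refb + deleted, refb)] += 1
                r += length
            elif op in (3,):  # N
                r += length
            elif op in (4,):  # soft clip
                q += length

    def gene_for(chrom: str, pos: int) -> str | None:
        for t in in_target.get(chrom, []):
            if t.start <= pos < t.end:
                return t.label
        return None

    calls: list[VariantCall] = []
    for (chrom, pos, ref, alt), count in sorted(alt_counts.items()):
        if count < config.min_alt_reads:
            continue
        gene = gene_for(chrom, pos)
        if gene is None:
            continue
        d = depth[(chrom, pos)]
        if d == 0:
            continue
        call = VariantCall(chrom=chrom, pos=pos + 1, ref=ref, alt=alt,
                           depth=d, alt_count=min(count, d), gene=gene)
        if d < config.min_depth:
            call.filters.add("low_depth")
        calls.append(call)
    return apply_vaf_filters(calls, config)


def apply_vaf_filters(calls: Iterable[VariantCall],
                      config: VariantConfig | None = None) -> list[VariantCall]:
    """VAF tiers: < 2% filtered (below_vaf_cutoff), 2-3% low-confidence,
    >= 3% pass; low_depth always forces filtered status."""
    config = config or VariantConfig()
    out = []
    for call in calls:
        call.filters.discard("below_vaf_cutoff")
        call.filters.discard("low_confidence_vaf")
        if call.vaf < config.vaf_cutoff:
            call.filters.add("below_vaf_cutoff")
        elif call.vaf < config.high_confidence_vaf:
            call.filters.add("low_confidence_vaf")
        if "below_vaf_cutoff" in call.filters or "low_depth" in call.filters:
            call.status = "filtered"
        elif "low_confidence_vaf" in call.filters:
            call.status = "low_confidence"
        else:
            call.status = "pass"
        out.append(call)
    return out


_FILTER_CODES = {"below_vaf_cutoff": "vafCutoff", "low_confidence_vaf": "lowConf",
                 "low_depth": "lowDepth", "strand_bias": "strandBias"}


def write_vcf(calls: Sequence[VariantCall], path: str | Path,
              contig_lengths: Mapping[str, int] | None = None) -> None:
    """Minimal VCF 4.2 with FILTER tiers and INFO VAF/ALTC/GENE fields."""
    lines = ["##fileformat=VCFv4.2",
             '##FILTER=<ID=vafCutoff,Description="VAF below 2% analysis cutoff">',
             '##FILTER=<ID=lowConf,Description="VAF in the 2-3% low-confidence tier">',
             '##FILTER=<ID=lowDepth,Description="Qualifying depth below threshold">',
             '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">',
             '##INFO=<ID=ALTC,Number=1,Type=Integer,Description="Alternate read count">',
             '##INFO=<ID=DP,Number=1,Type=Integer,Description="Qualifying depth">',
             '##INFO=<ID=GENE,Number=1,Type=String,Description="Driver target label">']
    for chrom in sorted(contig_lengths or {}):
        lines.append(f"##contig=<ID={chrom},length={contig_lengths[chrom]}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for c in sorted(calls, key=lambda c: (c.chrom, c.pos, c.alt)):
        filt = ";".join(sorted(_FILTER_CODES[f] for f in c.filters)) or "PASS"
        info = f"VAF={c.vaf:.4f};ALTC={c.alt_count};DP={c.depth};GENE={c.gene}"
        lines.append(f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\t{filt}\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path, default_gene: str = "") -> list[VariantCall]:
    """Read calls from a plain-text VCF (the filter-only input path)."""
    calls = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        chrom, pos, _id, ref, alt = fields[0], int(fields[1]), fields[2], fields[3], fields[4]
        info = dict(kv.split("=", 1) for kv in fields[7].split(";") if "=" in kv)
        depth = int(info.get("DP", 0))
        altc = int(info.get("ALTC", round(float(info.get("VAF", 0)) * depth)))
        calls.append(VariantCall(chrom=chrom, pos=pos, ref=ref, alt=alt,
                                 depth=depth, alt_count=altc,
                                 gene=info.get("GENE", default_gene)))
    return calls


def variant_table(calls: Sequence[VariantCall]) -> pd.DataFrame:
    rows = [{
        "chrom": c.chrom, "pos": c.pos, "ref": c.ref, "alt": c.alt,
        "gene": c.gene, "depth": c.depth, "alt_count": c.alt_count,
        "vaf": f"{c.vaf:.4f}", "status": c.status,
        "filters": ";".join(sorted(c.filters)),
    } for c in sorted(calls, key=lambda c: (c.chrom, c.pos, c.alt))]
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gene",
                                       "depth", "alt_count", "vaf", "status", "filters"])
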