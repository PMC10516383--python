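"""IGLV3-21 light-chain analysis and R110 determination.

The IGLV3-21ᴿ¹¹⁰ lesion is a point mutation creating an arginine at IMGT
position 110 of the lambda V-J junction, enabling autonomous B-cell receptor
signalling; it is prognostically adverse and travels with CLL subset #2. The
position-110 codon is carried in the reference bundle as an annotated codon
offset on IGLV3-21 alleles (range-validated at load time; the germline
residue at that offset is reported alongside every call) rather than computed
by full IMGT numbering.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotate import AnnotationConfig, AnnotationError, GeneAssignment, assign_v_gene
from .reference import ReferenceBundle
from .simulate import translate

R110_STATUSES = ("positive", "negative", "indeterminate", "not_IGLV3-21", "no_rearrangement")


@dataclass
class R110Result:
    status: str                      # one of R110_STATUSES
    iglv_allele: str | None = None
    identity_pct: float | None = None
    position110_codon: str | None = None
    position110_aa: str | None = None
    r110: bool | None = None
    supporting_reads: int = 0

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "iglv_allele": self.iglv_allele,
            "identity_pct": self.identity_pct,
            "position110_codon": self.position110_codon,
            "position110_aa": self.position110_aa,
            "r110": self.r110,
            "supporting_reads": self.supporting_reads,
        }


def call_iglv_allele(sequence: str, bundle: ReferenceBundle,
                     config: AnnotationConfig | None = None) -> GeneAssignment:
    """Best-identity IGL V allele (IGLV3-21 alleles compete against the other
    IGLV genes in the bundle, which act as rejectors)."""
    return assign_v_gene(sequence, bundle, "IGL", config)


def detect_r110(sequence: str, v_assign: GeneAssignment, bundle: ReferenceBundle,
                per_base_support: list[int] | None = None,
                min_codon_support: int = 10) -> R110Result:
    """Translate the IMGT position-110 codon of an assembled IGLV3-21
    rearrangement.

    A codon that maps into an alignment gap, is truncated, or is covered by
    fewer than ``min_codon_support`` reads yields "indeterminate" — never a
    false negative.
    """
    seg = bundle.segments[v_assign.segment_name]
    if not seg.name.startswith("IGLV3-21"):
        return R110Result(status="not_IGLV3-21", iglv_allele=seg.name,
                          identity_pct=v_assign.identity_pct)
    if seg.aux_codon is None:
        raise AnnotationError(f"{seg.name}: no annotated position-110 codon in bundle")
    q = v_assign.map_segment_offset(seg.aux_codon)
    q2 = v_assign.map_segment_offset(seg.aux_codon + 2)
    if q is None or q2 != q + 2 or q + 3 > len(sequence):
        return R110Result(status="indeterminate", iglv_allele=seg.name,
                          identity_pct=v_assign.identity_pct)
    support = 1
    if per_base_support is not None:
        if q + 3 > len(per_base_support):
            return R110Result(status="indeterminate", iglv_allele=seg.name,
                              identity_pct=v_assign.identity_pct)
        support = min(per_base_support[q:q + 3])
        if support < min_codon_support:
            return R110Result(status="indeterminate", iglv_allele=seg.name,
                              identity_pct=v_assign.identity_pct,
                              supporting_reads=support)
    codon = sequence[q:q + 3]
    aa = translate(codon)
    return R110Result(status="positive" if aa == "R" else "negative",
                      iglv_allele=seg.name, identity_pct=v_assign.identity_pct,
                      position110_codon=codon, position110_aa=aa,
                      r110=(aa == "R"), supporting_reads=support)


def analyze_light_chain(candidates, bundle: ReferenceBundle,
                        config: AnnotationConfig | None = None,
                        min_codon_support: int = 10) -> R110Result:
    """R110 status from the top-ranked IGL candidate (or absence thereof)."""
    igl = [c for c in candidates if c.locus == "IGL"]
    if not igl:
        return R110Result(status="no_rearrangement")
    top = igl[0]
    try:
        v_assign = call_iglv_allele(top.sequence, bundle, config)
    except AnnotationError:
        return R110Result(status="no_rearrangement")
    return detect_r110(top.sequence, v_assign, bundle,
                       per_base_support=top.per_base_support,
                       min_codon_support=min_codon_support)
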