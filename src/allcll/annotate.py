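"""Germline gene assignment, SHM status, CDR3 and productivity.

Percent identity to the germline V gene is the clinical SHM readout: >= 98%
identity is "unmutated" (adverse prognosis), < 98% "mutated", and the
97.00-97.99% band is flagged as borderline. Identity is computed over aligned
germline-V columns only (matches + mismatches + gap columns, one column per
inserted/deleted base) and rounded half-up to two decimals before the cutoff
is applied, which makes the borderline band well-defined.

The V-gene 3' boundary is taken as the end of the germline allele mapped
through a local affine alignment: the aligned span is extended base by
base to the query 5' start and to the allele 3' end. When the rearrangement
trimmed the V 3' end, a few untemplated junction bases may be attributed to V
— an inherent ambiguity of junction analysis shared by all annotators.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from Bio import Align

from .reference import ReferenceBundle, revcomp
from .simulate import translate


class AnnotationError(ValueError):
    pass


@dataclass
class AnnotationConfig:
    match: int = 1
    mismatch: int = -2
    gap_open: int = -7     # gap of length k scores -(6 + k)
    gap_extend: int = -1
    min_v_identity: float = 60.0
    min_j_identity: float = 60.0
    min_j_span: int = 20
    d_min_length: int = 5
    d_min_identity: float = 80.0


@dataclass
class GeneAssignment:
    segment_name: str
    alignment: list[tuple[int, int, int]]  # (query offset, segment offset, length)
    matches: int
    mismatches: int
    insertions: int
    deletions: int
    identity_pct: float
    score: float = 0.0

    @property
    def gapped_columns(self) -> int:
        return self.insertions + self.deletions

    @property
    def query_start(self) -> int:
        return self.alignment[0][0]

    @property
    def query_end(self) -> int:
        q, _t, ln = self.alignment[-1]
        return q + ln

    @property
    def segment_start(self) -> int:
        return self.alignment[0][1]

    @property
    def segment_end(self) -> int:
        _q, t, ln = self.alignment[-1]
        return t + ln

    def map_segment_offset(self, offset: int) -> int | None:
        """Query position of a segment-local offset; None if gapped/outside."""
        for q, t, ln in self.alignment:
            if t <= offset < t + ln:
                return q + (offset - t)
        return None


@dataclass(frozen=True)
class SHMStatus:
    identity_pct: float
    status: str          # "mutated" | "unmutated"
    borderline: bool


@dataclass(frozen=True)
class CDR3:
    nt_sequence: str     # between (exclusive of) the anchor codons
    aa_sequence: str
    junction_aa: str     # Cys-104 .. Trp/Phe-118 inclusive
    frame_offset: int


@dataclass
class AnnotatedRearrangement:
    sequence: str
    locus: str
    v: GeneAssignment
    d: GeneAssignment | None
    j: GeneAssignment
    shm: SHMStatus
    cdr3: CDR3 | None
    junction_nt: str
    productive: bool
    failure_reason: str | None  # out_of_frame | stop_codon | missing_anchor
    candidate: object | None = None
    subset_id: str | None = None


def round2(value: float) -> float:
    return float(Decimal(repr(float(value))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _make_aligner(config: AnnotationConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    # Local mode lets a trimmed allele 5'/3' end dangle over junction bases;
    # the explicit boundary extensions in _evaluate then pin the evaluated
    # span to the query start (V) and the allele ends.
    aligner.mode = "local"
    aligner.match_score = config.match
    aligner.mismatch_score = config.mismatch
    aligner.open_gap_score = config.gap_open
    aligner.extend_gap_score = config.gap_extend
    return aligner


def _evaluate(allele: str, query: str, aligner: Align.PairwiseAligner,
              extend_left: bool, extend_right: bool) -> GeneAssignment | None:
    alignments = aligner.align(allele, query)
    aln = alignments[0]
    t_blocks, q_blocks = (list(map(tuple, b)) for b in aln.aligned)
    if not t_blocks:
        return None
    blocks = [(q[0], t[0], t[1] - t[0]) for t, q in zip(t_blocks, q_blocks)]
    if extend_left:
        q0, t0, _ = blocks[0]
        k = min(q0, t0)
        if k:
            blocks.insert(0, (q0 - k, t0 - k, k))
    if extend_right:
        q, t, ln = blocks[-1]
        k = min(len(allele) - (t + ln), len(query) - (q + ln))
        if k:
            blocks.append((q + ln, t + ln, k))
    # merge contiguous blocks
    merged: list[tuple[int, int, int]] = []
    for q, t, ln in blocks:
        if merged and merged[-1][0] + merged[-1][2] == q and merged[-1][1] + merged[-1][2] == t:
            pq, pt, pl = merged[-1]
            merged[-1] = (pq, pt, pl + ln)
        else:
            merged.append((q, t, ln))
    matches = mismatches = insertions = deletions = 0
    for (q, t, ln), nxt in zip(merged, merged[1:] + [None]):
        for i in range(ln):
            if query[q + i] == allele[t + i]:
                matches += 1
            else:
                mismatches += 1
        if nxt is not None:
            insertions += nxt[0] - (q + ln)   # query bases opposite gaps
            deletions += nxt[1] - (t + ln)    # allele bases opposite gaps
    span = matches + mismatches + insertions + deletions
    if span == 0:
        return None
    identity = round2(100.0 * matches / span)
    return GeneAssignment("", merged, matches, mismatches, insertions, deletions,
                          identity, score=float(aln.score))


def _allele_key(ga: GeneAssignment):
    """Allele selection order: alignment score first (identity alone is
    degenerate — a wrong allele can produce a short 100%-identity core under
    ends-free alignment), then identity, fewest gapped columns, name."""
    return (-ga.score, -ga.identity_pct, ga.gapped_columns, ga.segment_name)


def assign_v_gene(sequence: str, bundle: ReferenceBundle, locus: str,
                  config: AnnotationConfig | None = None) -> GeneAssignment:
    """Best-identity germline V allele for an assembled rearrangement.

    Ties go to fewest gapped columns, then lexicographic allele name.
    """
    config = config or AnnotationConfig()
    if len(sequence) < 100:
        raise AnnotationError(f"sequence too short for V assignment ({len(sequence)} nt)")
    aligner = _make_aligner(config)
    best: GeneAssignment | None = None
    for seg in bundle.segments_by_class(locus, "V"):
        ga = _evaluate(seg.sequence, sequence, aligner, extend_left=True, extend_right=True)
        if ga is None:
            continue
        ga.segment_name = seg.name
        if best is None or _allele_key(ga) < _allele_key(best):
            best = ga
    if best is None or best.identity_pct < config.min_v_identity:
        raise AnnotationError(f"no V assignment for locus {locus}")
    return best


def assign_j_gene(sequence: str, bundle: ReferenceBundle, locus: str,
                  config: AnnotationConfig | None = None) -> GeneAssignment:
    """Best-identity germline J allele, anchored at the sequence 3' end."""
    config = config or AnnotationConfig()
    aligner = _make_aligner(config)
    best: GeneAssignment | None = None
    for seg in bundle.segments_by_class(locus, "J"):
        ga = _evaluate(seg.sequence, sequence, aligner, extend_left=False, extend_right=True)
        if ga is None:
            continue
        if ga.matches + ga.mismatches + ga.gapped_columns < config.min_j_span:
            continue
        ga.segment_name = seg.name
        if best is None or _allele_key(ga) < _allele_key(best):
            best = ga
    if best is None or best.identity_pct < config.min_j_identity:
        raise AnnotationError(f"no J assignment for locus {locus}")
    return best


def assign_d_gene(junction_nt: str, bundle: ReferenceBundle,
                  config: AnnotationConfig | None = None) -> GeneAssignment | None:
    """Best ungapped local D match within the junction, both orientations.

    Reported only for matches of >= 5 nt at >= 80% identity; ties go to the
    longer match, then allele name. None is a valid outcome.
    """
    config = config or AnnotationConfig()
    best = None
    best_key = None
    for seg in bundle.segments_by_class("IGH", "D") + bundle.segments_by_class("IGL", "D"):
        for oriented, orient_rank in ((seg.sequence, 0), (revcomp(seg.sequence), 1)):
            hit = _best_ungapped(junction_nt, oriented, config.d_min_length,
                                 config.d_min_identity / 100.0)
            if hit is None:
                continue
            qstart, dstart, length, matches = hit
            key = (-matches, -length, seg.name, orient_rank)
            if best_key is None or key < best_key:
                best_key = key
                identity = round2(100.0 * matches / length)
                best = GeneAssignment(seg.name, [(qstart, dstart, length)],
                                      matches, length - matches, 0, 0, identity)
    return best


def _best_ungapped(junction: str, d: str, min_len: int, min_ident: float):
    """Best-scoring ungapped window (match +1 / mismatch -1) over all
    diagonals, subject to length and identity floors."""
    best = None
    best_key = None
    for shift in range(-(len(d) - 1), len(junction)):
        lo = max(0, shift)
        hi = min(len(junction), shift + len(d))
        score = 0
        start = lo
        for i in range(lo, hi):
            s = 1 if junction[i] == d[i - shift] else -1
            if score <= 0:
                score, start = s, i
            else:
                score += s
            length = i - start + 1
            # score = matches - mismatches, length = matches + mismatches
            m = (length + score) // 2
            if length >= min_len and m / length >= min_ident:
                key = (-m, -length)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (start, start - shift, length, m)
    return best


def classify_shm(identity_pct: float) -> SHMStatus:
    """98% cutoff: >= 98.00 unmutated, < 98.00 mutated; 97.00-97.99 borderline."""
    if not 0.0 <= identity_pct <= 100.0:
        raise AnnotationError(f"identity out of range: {identity_pct}")
    ident = round2(identity_pct)
    return SHMStatus(identity_pct=ident,
                     status="unmutated" if ident >= 98.00 else "mutated",
                     borderline=97.00 <= ident <= 97.99)


def extract_cdr3(sequence: str, v_assign: GeneAssignment, j_assign: GeneAssignment,
                 bundle: ReferenceBundle) -> tuple[CDR3 | None, str | None]:
    """Anchor-to-anchor junction (Cys-104 .. Trp/Phe-118) and the enclosed CDR3.

    Returns (cdr3, failure_reason); an out-of-frame junction still yields the
    nucleotide CDR3 (productivity is judged separately), whereas a missing or
    mutated anchor yields (None, "missing_anchor").
    """
    vseg = bundle.segments[v_assign.segment_name]
    jseg = bundle.segments[j_assign.segment_name]
    vq = v_assign.map_segment_offset(vseg.anchor_codon)
    jq = j_assign.map_segment_offset(jseg.anchor_codon)
    if vq is None or jq is None or jq + 3 > len(sequence) or jq <= vq:
        return None, "missing_anchor"
    if v_assign.map_segment_offset(vseg.anchor_codon + 2) != vq + 2 or \
       j_assign.map_segment_offset(jseg.anchor_codon + 2) != jq + 2:
        return None, "missing_anchor"
    v_aa = translate(sequence[vq:vq + 3])
    j_aa = translate(sequence[jq:jq + 3])
    if v_aa != "C" or j_aa not in ("W", "F"):
        return None, "missing_anchor"
    junction_nt = sequence[vq: jq + 3]
    junction_aa = translate(junction_nt)
    frame_start = v_assign.query_start - v_assign.segment_start
    cdr3 = CDR3(nt_sequence=sequence[vq + 3: jq],
                aa_sequence=junction_aa[1:-1] if len(junction_nt) % 3 == 0 else
                translate(sequence[vq + 3: jq]),
                junction_aa=junction_aa,
                frame_offset=(vq - frame_start) % 3)
    return cdr3, None


def check_productivity(sequence: str, v_assign: GeneAssignment,
                       j_assign: GeneAssignment, bundle: ReferenceBundle
                       ) -> tuple[bool, str | None]:
    """Productive iff the junction preserves the V reading frame into J, both
    anchors are intact, and the V-through-J translation is stop-free."""
    cdr3, reason = extract_cdr3(sequence, v_assign, j_assign, bundle)
    if reason is not None:
        return False, reason
    vseg = bundle.segments[v_assign.segment_name]
    vq = v_assign.map_segment_offset(vseg.anchor_codon)
    jq = j_assign.map_segment_offset(bundle.segments[j_assign.segment_name].anchor_codon)
    if (jq - vq) % 3 != 0:
        return False, "out_of_frame"
    frame_start = max(0, v_assign.query_start - v_assign.segment_start)
    coding = sequence[frame_start: j_assign.query_end]
    if "*" in translate(coding):
        return False, "stop_codon"
    return True, None


def annotate_sequence(sequence: str, bundle: ReferenceBundle, locus: str,
                      candidate: object | None = None,
                      config: AnnotationConfig | None = None) -> AnnotatedRearrangement:
    """Full annotation of one assembled rearrangement."""
    config = config or AnnotationConfig()
    v = assign_v_gene(sequence, bundle, locus, config)
    j = assign_j_gene(sequence, bundle, locus, config)
    junction_nt = sequence[v.query_end: j.query_start]
    d = None
    if locus == "IGH" and junction_nt:
        d = assign_d_gene(junction_nt, bundle, config)
    shm = classify_shm(v.identity_pct)
    cdr3, cdr3_reason = extract_cdr3(sequence, v, j, bundle)
    productive, reason = check_productivity(sequence, v, j, bundle)
    return AnnotatedRearrangement(
        sequence=sequence, locus=locus, v=v, d=d, j=j, shm=shm, cdr3=cdr3,
        junction_nt=junction_nt, productive=productive,
        failure_reason=reason if not productive else None,
        candidate=candidate)


def airr_table(annotations: list[AnnotatedRearrangement]) -> pd.DataFrame:
    """AIRR-style rearrangement table, one row per annotated candidate."""
    rows = []
    for i, ann in enumerate(annotations, start=1):
        rows.append({
            "sequence_id": f"candidate_{i}",
            "locus": ann.locus,
            "v_call": ann.v.segment_name,
            "d_call": ann.d.segment_name if ann.d else "",
            "j_call": ann.j.segment_name,
            "junction_aa": ann.cdr3.junction_aa if ann.cdr3 else "",
            "cdr3_aa": ann.cdr3.aa_sequence if ann.cdr3 else "",
            "v_identity": f"{ann.shm.identity_pct:.2f}",
            "shm_status": ann.shm.status,
            "borderline": ann.shm.borderline,
            "productive": ann.productive,
            "failure_reason": ann.failure_reason or "",
            "subset_id": ann.subset_id or "",
            "sequence": ann.sequence,
        })
    return pd.DataFrame(rows)
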