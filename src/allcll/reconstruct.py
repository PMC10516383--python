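"""V(D)J rearrangement reconstruction from soft-clipped capture reads.

Capture panels tile both sides of the rearrangement junction at high depth,
so the junction shows up as deep stacks of soft-clipped reads anchored on the
germline V and J segments. The pipeline here is:

    soft-clip harvest -> breakpoint clustering -> two-sided consensus ->
    overlap join -> ranked candidates

The assembled sequence is germline V up to the V breakpoint (read consensus
where covered, so SHM within V is captured), the junction consensus from
clipped bases, and germline J from the J breakpoint.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .reference import ReferenceBundle, revcomp

_BASE_PRIORITY = "ACGT"  # tie-break order for equal majority counts


@dataclass
class ReconstructionConfig:
    min_clip: int = 10
    min_mapq: int = 20
    window: int = 5
    min_support: int = 3
    min_overlap: int = 20
    max_mismatch_rate: float = 0.05


@dataclass(frozen=True)
class JunctionEvidence:
    anchor_segment: str
    breakpoint: int          # segment-local, reading orientation
    clip_side: str           # "left" | "right" in reading orientation
    clipped_sequence: str    # reading orientation
    read_name: str
    mapq: int


@dataclass
class JunctionCluster:
    anchor_segment: str
    clip_side: str
    breakpoint: int          # modal offset; ties -> smallest
    members: list[JunctionEvidence]

    @property
    def support(self) -> int:
        return len(self.members)

    @property
    def mean_mapq(self) -> float:
        return float(np.mean([m.mapq for m in self.members]))


@dataclass
class RearrangementCandidate:
    locus: str
    sequence: str
    v_cluster: JunctionCluster
    j_cluster: JunctionCluster
    support: int
    score: float
    per_base_support: list[int]
    tie_positions: list[int] = field(default_factory=list)

    @property
    def v_segment(self) -> str:
        return self.v_cluster.anchor_segment

    @property
    def j_segment(self) -> str:
        return self.j_cluster.anchor_segment


@dataclass
class ReconstructionResult:
    candidates: list[RearrangementCandidate]
    n_evidence: int
    n_clusters: int
    unjoined_clusters: list[tuple[str, str, int, int]]  # (segment, side, breakpoint, support)
    skipped_contigs: Counter = field(default_factory=Counter)

    @property
    def top(self) -> RearrangementCandidate | None:
        return self.candidates[0] if self.candidates else None


def _load_alignments(alignments) -> list[pysam.AlignedSegment]:
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
            return [r for r in fh if not r.is_unmapped]
    return list(alignments)


def collect_junction_evidence(alignments, bundle: ReferenceBundle,
                              config: ReconstructionConfig | None = None,
                              skipped: Counter | None = None) -> list[JunctionEvidence]:
    """Harvest soft-clips >= min_clip from reads over ig-role targets.

    Clip coordinates are converted to segment-local offsets in reading
    orientation; for minus-strand segments the clip side flips and the clipped
    bases are reverse-complemented.
    """
    config = config or ReconstructionConfig()
    ig_targets = bundle.targets_by_role("ig")
    known_chroms = {s.chrom for s in bundle.segments.values()}
    evidence: list[JunctionEvidence] = []
    for rec in _load_alignments(alignments):
        if rec.is_unmapped or rec.mapping_quality < config.min_mapq:
            continue
        chrom = rec.reference_name
        if chrom not in known_chroms:
            if skipped is not None:
                skipped[chrom] += 1
            continue
        if not any(t.chrom == chrom and rec.reference_start < t.end and rec.reference_end > t.start
                   for t in ig_targets):
            continue
        cigar = rec.cigartuples or []
        seq = rec.query_sequence
        # left clip: genomic coordinate of junction = reference_start
        if cigar and cigar[0][0] == 4 and cigar[0][1] >= config.min_clip:
            clip = seq[:cigar[0][1]]
            ev = _to_segment_local(bundle, chrom, rec.reference_start, "left", clip,
                                   rec.query_name, rec.mapping_quality)
            if ev is not None:
                evidence.append(ev)
        if cigar and cigar[-1][0] == 4 and cigar[-1][1] >= config.min_clip:
            clip = seq[len(seq) - cigar[-1][1]:]
            ev = _to_segment_local(bundle, chrom, rec.reference_end, "right", clip,
                                   rec.query_name, rec.mapping_quality)
            if ev is not None:
                evidence.append(ev)
    return evidence


def _to_segment_local(bundle: ReferenceBundle, chrom: str, gpos: int,
                      genomic_side: str, clip: str, read_name: str,
                      mapq: int) -> JunctionEvidence | None:
    seg = bundle.segment_at(chrom, gpos)
    if seg is None:
        return None
    if seg.strand == "+":
        local = gpos - seg.start
        side = genomic_side
        clipped = clip
    else:
        local = seg.end - gpos
        side = "right" if genomic_side == "left" else "left"
        clipped = revcomp(clip)
    if not 0 <= local <= len(seg.sequence):
        return None
    return JunctionEvidence(seg.name, local, side, clipped, read_name, mapq)


def cluster_junctions(evidence: Iterable[JunctionEvidence],
                      config: ReconstructionConfig | None = None) -> list[JunctionCluster]:
    """Single-linkage clustering of breakpoints within ``window`` per
    (segment, side); clusters below ``min_support`` are discarded. The modal
    breakpoint is the most frequent offset, ties to the smallest."""
    config = config or ReconstructionConfig()
    groups: dict[tuple[str, str], list[JunctionEvidence]] = defaultdict(list)
    for ev in evidence:
        groups[(ev.anchor_segment, ev.clip_side)].append(ev)
    clusters: list[JunctionCluster] = []
    for (segment, side), items in sorted(groups.items()):
        items.sort(key=lambda e: (e.breakpoint, e.read_name))
        chain: list[JunctionEvidence] = []
        for ev in items:
            if chain and ev.breakpoint - chain[-1].breakpoint > config.window:
                clusters.extend(_finalize(segment, side, chain, config))
                chain = []
            chain.append(ev)
        clusters.extend(_finalize(segment, side, chain, config))
    return clusters


def _finalize(segment: str, side: str, chain: list[JunctionEvidence],
              config: ReconstructionConfig) -> list[JunctionCluster]:
    if len(chain) < config.min_support:
        return []
    counts = Counter(e.breakpoint for e in chain)
    modal = min(counts, key=lambda b: (-counts[b], b))
    return [JunctionCluster(segment, side, modal, chain)]


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _vote(counts: Counter, fallback: str | None, ties: list[int], pos: int) -> str:
    if not counts:
        return fallback if fallback is not None else "N"
    best = max(counts.values())
    winners = sorted((b for b, c in counts.items() if c == best),
                     key=_BASE_PRIORITY.index)
    if len(winners) > 1:
        ties.append(pos)
    return winners[0]


def assemble_candidate(v_cluster: JunctionCluster, j_cluster: JunctionCluster,
                       alignments, bundle: ReferenceBundle,
                       config: ReconstructionConfig | None = None
                       ) -> RearrangementCandidate | None:
    """Join the V-side and J-side consensi into a full rearranged sequence.

    Returns None when the two consensi cannot be joined with an overlap of at
    least ``min_overlap`` at a mismatch rate <= ``max_mismatch_rate``.
    """
    config = config or ReconstructionConfig()
    vseg = bundle.segments[v_cluster.anchor_segment]
    jseg = bundle.segments[j_cluster.anchor_segment]
    if vseg.locus != jseg.locus:
        return None
    if v_cluster.clip_side != "right" or j_cluster.clip_side != "left":
        return None
    records = _load_alignments(alignments)
    bv, bj = v_cluster.breakpoint, j_cluster.breakpoint

    # V body votes from aligned read bases (captures SHM); germline fallback.
    v_counts: list[Counter] = [Counter() for _ in range(bv)]
    j_body_support = [0] * (len(jseg.sequence) - bj)
    for rec in records:
        if rec.is_unmapped or rec.mapping_quality < config.min_mapq:
            continue
        if rec.reference_name == vseg.chrom and rec.reference_start < vseg.end and rec.reference_end > vseg.start:
            seq = rec.query_sequence
            for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
                if vseg.strand == "+":
                    if vseg.start <= rpos < vseg.start + bv:
                        v_counts[rpos - vseg.start][seq[qpos]] += 1
                elif vseg.end - bv <= rpos < vseg.end:
                    v_counts[vseg.end - 1 - rpos][revcomp(seq[qpos])] += 1
        if rec.reference_name == jseg.chrom and rec.reference_start < jseg.end and rec.reference_end > jseg.start:
            for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
                if jseg.strand == "+" and jseg.start + bj <= rpos < jseg.end:
                    j_body_support[rpos - jseg.start - bj] += 1
                elif jseg.strand == "-" and jseg.start <= rpos < jseg.end - bj:
                    j_body_support[jseg.end - 1 - rpos - bj] += 1

    ties: list[int] = []
    # clip votes, column-aligned at the modal breakpoints
    right_cols: dict[int, Counter] = defaultdict(Counter)
    for ev in v_cluster.members:
        shift = ev.breakpoint - bv
        for i, base in enumerate(ev.clipped_sequence):
            col = shift + i
            if col < 0:
                if 0 <= bv + col < bv:
                    v_counts[bv + col][base] += 1
            else:
                right_cols[col][base] += 1
    left_cols: dict[int, Counter] = defaultdict(Counter)
    for ev in j_cluster.members:
        c = len(ev.clipped_sequence)
        for i, base in enumerate(ev.clipped_sequence):
            rel = (i - c) + (ev.breakpoint - bj)
            if rel < 0:
                left_cols[rel][base] += 1
            # rel >= 0 would vote into the J body; germline is used there

    v_body = "".join(_vote(v_counts[p], vseg.sequence[p], ties, p) for p in range(bv))
    n_right = 0
    while n_right in right_cols:
        n_right += 1
    right_ext = "".join(_vote(right_cols[c], None, ties, bv + c) for c in range(n_right))
    n_left = 0
    while -(n_left + 1) in left_cols:
        n_left += 1
    left_ext = "".join(_vote(left_cols[c - n_left], None, ties, c) for c in range(n_left))

    ev_seq = v_body + right_ext
    ej_seq = left_ext + jseg.sequence[bj:]
    ev_support = [sum(c.values()) for c in v_counts] + \
                 [sum(right_cols[c].values()) for c in range(n_right)]
    ej_support = [sum(left_cols[c - n_left].values()) for c in range(n_left)] + j_body_support

    offset = _best_placement(ev_seq, ej_seq, config.min_overlap, config.max_mismatch_rate)
    if offset is None:
        return None
    # The assembly ends at the J 3' end (= end of EJ); V-side clip consensus
    # extending past it (downstream germline flank) is discarded.
    sequence = ev_seq[:offset] + ej_seq
    support_vec = list(ev_support[:offset])
    for i in range(len(ej_seq)):
        base = ev_support[offset + i] if offset + i < len(ev_support) else 0
        support_vec.append(base + ej_support[i])

    support = min(v_cluster.support, j_cluster.support)
    mean_mapq = float(np.mean([m.mapq for m in v_cluster.members + j_cluster.members]))
    score = candidate_score(support, len(sequence), mean_mapq)
    return RearrangementCandidate(
        locus=vseg.locus, sequence=sequence, v_cluster=v_cluster,
        j_cluster=j_cluster, support=support, score=score,
        per_base_support=support_vec, tie_positions=sorted(set(ties)))


def _best_placement(left: str, right: str, min_overlap: int,
                    max_mismatch_rate: float) -> int | None:
    """Offset of ``right`` within/after ``left`` maximizing the overlap, with
    Hamming mismatch fraction <= max_mismatch_rate over the overlapping
    window. ``right`` may be contained in ``left`` or extend past its end.
    Ties (equal overlap) go to the smaller mismatch count, then the smaller
    offset."""
    l_arr = np.frombuffer(left.encode(), dtype=np.uint8)
    r_arr = np.frombuffer(right.encode(), dtype=np.uint8)
    best: tuple[int, int, int] | None = None  # (-overlap, mismatches, offset)
    for offset in range(0, len(left) - min_overlap + 1):
        ov = min(len(left) - offset, len(right))
        mismatches = int(np.count_nonzero(l_arr[offset:offset + ov] != r_arr[:ov]))
        if mismatches / ov > max_mismatch_rate:
            continue
        key = (-ov, mismatches, offset)
        if best is None or key < best:
            best = key
    return best[2] if best else None


def candidate_score(support: int, length: int, mean_mapq: float) -> float:
    """support x log2(1 + assembled length) x mean_mapq / 60."""
    return support * math.log2(1 + length) * mean_mapq / 60.0


def rank_candidates(candidates: Sequence[RearrangementCandidate]
                    ) -> list[RearrangementCandidate]:
    """Descending by score; ties lexicographic by (V name, J name). The top
    candidate is the reported clonal rearrangement."""
    return sorted(candidates, key=lambda c: (-c.score, c.v_segment, c.j_segment))


def reconstruct(alignments, bundle: ReferenceBundle,
                config: ReconstructionConfig | None = None,
                locus: str | None = None) -> ReconstructionResult:
    """Full pipeline: evidence -> clusters -> assembled, ranked candidates."""
    config = config or ReconstructionConfig()
    records = _load_alignments(alignments)
    skipped: Counter = Counter()
    evidence = collect_junction_evidence(records, bundle, config, skipped)
    clusters = cluster_junctions(evidence, config)

    v_clusters = [c for c in clusters
                  if bundle.segments[c.anchor_segment].segment_class == "V"
                  and c.clip_side == "right"]
    j_clusters = [c for c in clusters
                  if bundle.segments[c.anchor_segment].segment_class == "J"
                  and c.clip_side == "left"]
    if locus is not None:
        v_clusters = [c for c in v_clusters if bundle.segments[c.anchor_segment].locus == locus]
        j_clusters = [c for c in j_clusters if bundle.segments[c.anchor_segment].locus == locus]

    candidates = []
    joined: set[int] = set()
    for vc in v_clusters:
        for jc in j_clusters:
            if bundle.segments[vc.anchor_segment].locus != bundle.segments[jc.anchor_segment].locus:
                continue
            cand = assemble_candidate(vc, jc, records, bundle, config)
            if cand is not None:
                candidates.append(cand)
                joined.add(id(vc))
                joined.add(id(jc))
    unjoined = [(c.anchor_segment, c.clip_side, c.breakpoint, c.support)
                for c in v_clusters + j_clusters if id(c) not in joined]
    return ReconstructionResult(
        candidates=rank_candidates(candidates),
        n_evidence=len(evidence), n_clusters=len(clusters),
        unjoined_clusters=sorted(unjoined), skipped_contigs=skipped)


def candidates_to_fasta(candidates: Sequence[RearrangementCandidate], path: str | Path) -> None:
    with open(path, "w") as fa:
        for i, c in enumerate(candidates, start=1):
            fa.write(f">candidate_{i} locus={c.locus} v={c.v_segment} j={c.j_segment} "
                     f"support={c.support} score={c.score:.3f}\n{c.sequence}\n")
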