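"""Junction-evidence harvesting, clustering and assembly."""

import pysam
import pytest

from allcll.reconstruct import (JunctionEvidence, ReconstructionConfig,
                                candidate_score, cluster_junctions,
                                collect_junction_evidence, rank_candidates,
                                reconstruct)
from allcll.simulate import (ReadSimConfig, RearrangementConfig,
                             simulate_reads, simulate_rearrangement,
                             simulate_panel_reads)
from conftest import make_mini_bundle
from oracles import brute_force_clusters, revcomp_oracle


def _record(header, chrom, pos, cigar, seq, name="r1", mapq=60):
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.reference_id = list(header.references).index(chrom)
    rec.reference_start = pos
    rec.mapping_quality = mapq
    rec.cigartuples = cigar
    rec.query_sequence = seq
    rec.query_qualities = pysam.qualitystring_to_array("?" * len(seq))
    return rec


def test_fully_aligned_read_yields_no_evidence():
    b = make_mini_bundle()
    header = pysam.AlignmentHeader.from_references(["chrT"], [1000])
    rec = _record(header, "chrT", 110, [(0, 60)], b.segments["IGHV9-1*01"].sequence[10:70])
    assert collect_junction_evidence([rec], b) == []


def test_left_clip_on_plus_strand_j():
    """40-nt left soft-clip at J offset 7 -> one (J, 7, left) evidence item."""
    b = make_mini_bundle()
    header = pysam.AlignmentHeader.from_references(["chrT"], [1000])
    j = b.segments["IGHJ9*01"]
    clip = "ACGT" * 10
    aligned = j.sequence[7:]
    rec = _record(header, "chrT", j.start + 7, [(4, 40), (0, len(aligned))], clip + aligned)
    evidence = collect_junction_evidence([rec], b)
    assert len(evidence) == 1
    ev = evidence[0]
    assert (ev.anchor_segment, ev.breakpoint, ev.clip_side) == ("IGHJ9*01", 7, "left")
    assert ev.clipped_sequence == clip


def test_minus_strand_j_gives_identical_evidence_after_flip():
    """The same biological junction read against the minus-strand genomic
    representation of the J maps to identical reading-orientation evidence."""
    b = make_mini_bundle(j_strand="-")
    header = pysam.AlignmentHeader.from_references(["chrT"], [1000])
    j = b.segments["IGHJ9*01"]
    clip = "ACGT" * 10
    aligned_reading = j.sequence[7:]
    # genomic record: reverse-complemented, clip on the genomic right end
    genomic_seq = revcomp_oracle(clip + aligned_reading)
    rec = _record(header, "chrT", j.end - 7 - len(aligned_reading),
                  [(0, len(aligned_reading)), (4, 40)], genomic_seq)
    evidence = collect_junction_evidence([rec], b)
    assert len(evidence) == 1
    ev = evidence[0]
    assert (ev.anchor_segment, ev.breakpoint, ev.clip_side) == ("IGHJ9*01", 7, "left")
    assert ev.clipped_sequence == clip


def test_short_clip_and_low_mapq_are_ignored():
    b = make_mini_bundle()
    header = pysam.AlignmentHeader.from_references(["chrT"], [1000])
    j = b.segments["IGHJ9*01"]
    aligned = j.sequence[7:]
    short = _record(header, "chrT", j.start + 7, [(4, 5), (0, len(aligned))],
                    "ACGTA" + aligned)
    lowq = _record(header, "chrT", j.start + 7, [(4, 40), (0, len(aligned))],
                   "ACGT" * 10 + aligned, mapq=5)
    assert collect_junction_evidence([short, lowq], b) == []


@pytest.mark.parametrize("offsets,window,expected", [
    ([100, 100, 101, 100, 250], 5, [(100, 4)]),
    ([], 5, []),
    ([100, 104], 5, []),          # below min_support=3
    ([100, 104, 102, 200, 201, 200], 3, [(100, 3), (200, 3)]),
])
def test_clustering_matches_brute_force(offsets, window, expected):
    cfg = ReconstructionConfig(window=window, min_support=3)
    evidence = [JunctionEvidence("IGHV9-1*01", off, "right", "ACGTACGTACGT", f"r{i}", 60)
                for i, off in enumerate(offsets)]
    clusters = cluster_junctions(evidence, cfg)
    got = sorted((c.breakpoint, c.support) for c in clusters)
    assert got == expected
    assert got == brute_force_clusters(offsets, window, 3)


def test_no_soft_clips_means_no_candidates(bundle, genome):
    rs = simulate_panel_reads(bundle, genome, base_depth=50, seed=1)
    result = reconstruct(rs.records, bundle)
    assert result.candidates == [] and result.n_evidence == 0


@pytest.mark.parametrize("seed", range(15))
def test_exact_recovery_error_free(bundle, genome, seed):
    t = simulate_rearrangement(
        bundle, "IGH", RearrangementConfig(shm_target_identity=0.96), seed=seed)
    rs = simulate_reads(t, bundle, genome, ReadSimConfig(depth=35), seed=1000 + seed)
    top = reconstruct(rs.records, bundle).top
    assert top is not None
    assert top.sequence == t.truth_sequence
    assert len(top.per_base_support) == len(top.sequence)
    assert min(top.per_base_support) >= 1


def test_shm_mutations_present_in_assembly(bundle, genome):
    cfg = RearrangementConfig(v_name="IGHV3-21*01", shm_target_identity=0.98)
    t = simulate_rearrangement(bundle, "IGH", cfg, seed=4)
    assert len(t.truth_mutations) == 6
    rs = simulate_reads(t, bundle, genome, ReadSimConfig(depth=100), seed=5)
    top = reconstruct(rs.records, bundle).top
    for off, _ref, alt in t.truth_mutations:
        assert top.sequence[off] == alt


def test_robust_recovery_with_sequencing_errors(bundle, genome):
    close = 0
    n = 20
    for seed in range(n):
        t = simulate_rearrangement(
            bundle, "IGH", RearrangementConfig(shm_target_identity=0.95), seed=300 + seed)
        rs = simulate_reads(t, bundle, genome,
                            ReadSimConfig(depth=100, error_rate=0.002), seed=400 + seed)
        top = reconstruct(rs.records, bundle).top
        if top is not None and len(top.sequence) == len(t.truth_sequence):
            diff = sum(a != b for a, b in zip(top.sequence, t.truth_sequence))
            close += diff <= 1
    assert close >= round(0.95 * n)


def test_score_spot_check():
    assert candidate_score(10, 511, 60.0) == pytest.approx(90.0)


def test_score_monotone_in_support():
    for s in range(1, 50):
        assert candidate_score(s + 1, 400, 55.0) > candidate_score(s, 400, 55.0)


def test_ranking_tie_break_is_lexicographic(bundle, genome):
    t = simulate_rearrangement(bundle, "IGH", RearrangementConfig(), seed=8)
    rs = simulate_reads(t, bundle, genome, ReadSimConfig(depth=40), seed=9)
    result = reconstruct(rs.records, bundle)
    cands = result.candidates
    # duplicate the top candidate under a lexicographically smaller V name
    import copy
    clone = copy.deepcopy(cands[0])
    clone.v_cluster.anchor_segment = "IGHA0-0*01"
    ranked = rank_candidates([cands[0], clone])
    assert ranked[0].v_segment == "IGHA0-0*01"
    # higher support dominates
    boosted = copy.deepcopy(cands[0])
    boosted.score = cands[0].score * 2
    assert rank_candidates([cands[0], boosted])[0] is boosted
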