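"""Gene assignment, percent identity, SHM classification, CDR3, productivity."""

import numpy as np
import pytest

from allcll.annotate import (AnnotationError, annotate_sequence, assign_d_gene,
                             assign_j_gene, assign_v_gene, check_productivity,
                             classify_shm, extract_cdr3, round2)
from allcll.simulate import RearrangementConfig, simulate_rearrangement
from oracles import gotoh_identity, translate_oracle


def _rearranged(bundle, identity=1.0, seed=0, **kw):
    cfg = RearrangementConfig(shm_target_identity=identity, **kw)
    return simulate_rearrangement(bundle, "IGH", cfg, seed=seed)


def test_exact_germline_v_scores_100(bundle):
    t = _rearranged(bundle, identity=1.0, seed=1, v_name="IGHV3-21*01")
    v = assign_v_gene(t.truth_sequence, bundle, "IGH")
    assert v.segment_name == "IGHV3-21*01"
    assert v.identity_pct == 100.00
    assert v.query_start == 0 and v.segment_start == 0


def test_six_mutations_over_300nt_give_9800(bundle):
    t = _rearranged(bundle, identity=0.98, seed=2, v_name="IGHV3-21*01")
    assert len(t.truth_mutations) == 6 and t.v_portion_len == 300
    v = assign_v_gene(t.truth_sequence, bundle, "IGH")
    assert v.identity_pct == 98.00
    assert v.mismatches == 6


def test_equal_scores_tie_break_to_smaller_name(bundle):
    """Identical alleles under two names: the lexicographically smaller wins."""
    import copy
    b = copy.deepcopy(bundle)
    seg = b.segments["IGHV3-21*01"]
    twin = copy.deepcopy(seg)
    object.__setattr__(twin, "name", "IGHV3-21*09")
    b.segments["IGHV3-21*09"] = twin
    t = _rearranged(bundle, identity=0.99, seed=3, v_name="IGHV3-21*01")
    v = assign_v_gene(t.truth_sequence, b, "IGH")
    assert v.segment_name == "IGHV3-21*01"


def test_j_trim_shifts_alignment_start(bundle):
    j = bundle.segments["IGHJ4*02"]
    v = bundle.segments["IGHV1-2*01"]
    # junction chosen so its last base cannot extend the J alignment by chance
    junction = "CCCCCC" if j.sequence[4] != "C" else "GGGGGG"
    seq = v.sequence + junction + j.sequence[5:]
    ja = assign_j_gene(seq, bundle, "IGH")
    assert ja.segment_name == "IGHJ4*02"
    assert ja.segment_start == 5
    assert ja.identity_pct == 100.00


def test_no_j_match_is_error(bundle):
    rng = np.random.default_rng(42)
    v = bundle.segments["IGHV1-2*01"]
    seq = v.sequence + "".join(rng.choice(list("ACGT"), size=60))
    with pytest.raises(AnnotationError, match="no J assignment"):
        assign_j_gene(seq, bundle, "IGH")


def test_d_exact_core_is_reported(bundle):
    d = bundle.segments["IGHD6-19*01"]  # 12 nt
    junction = "CC" + d.sequence + "GG"
    hit = assign_d_gene(junction, bundle)
    assert hit is not None
    assert hit.segment_name == "IGHD6-19*01"
    assert hit.matches >= 12 and hit.identity_pct == 100.00


def test_short_junction_yields_no_d(bundle):
    assert assign_d_gene("ACGT", bundle) is None


def test_d_tie_goes_to_longer_match(bundle):
    d8 = bundle.segments["IGHD3-10*01"].sequence[:8]
    d6 = bundle.segments["IGHD2-2*01"].sequence[:6]
    hit = assign_d_gene(d8 + "AA" + d6, bundle)
    assert hit is not None and hit.matches >= 8
    assert hit.segment_name == "IGHD3-10*01"


@pytest.mark.parametrize("identity,status,borderline", [
    (98.00, "unmutated", False),
    (97.50, "mutated", True),
    (100.00, "unmutated", False),
    (97.994, "mutated", True),   # rounds half-up to 97.99
    (97.995, "unmutated", False),  # rounds half-up to 98.00
])
def test_shm_classification_boundaries(identity, status, borderline):
    s = classify_shm(identity)
    assert (s.status, s.borderline) == (status, borderline)


def test_shm_classification_consistent_over_grid():
    """unmutated <=> identity >= 98.00 over a 10,001-point grid of [0, 100]."""
    for i in range(10_001):
        ident = i / 100.0
        s = classify_shm(ident)
        assert (s.status == "unmutated") == (round2(ident) >= 98.00)
        assert s.borderline == (97.00 <= round2(ident) <= 97.99)
    with pytest.raises(AnnotationError):
        classify_shm(100.5)


def test_cdr3_matches_truth_translation(bundle):
    t = _rearranged(bundle, identity=1.0, seed=5)
    ann = annotate_sequence(t.truth_sequence, bundle, "IGH")
    v = bundle.segments[t.v_name]
    j = bundle.segments[t.j_name]
    vq = v.anchor_codon
    jq = t.junction_end + (j.anchor_codon - t.j_trim)
    expected = translate_oracle(t.truth_sequence[vq:jq + 3])
    assert ann.cdr3 is not None
    assert ann.cdr3.junction_aa == expected
    assert expected[0] == "C" and expected[-1] in "WF"
    assert len(ann.cdr3.junction_aa) == len(ann.cdr3.aa_sequence) + 2
    assert len(ann.cdr3.nt_sequence) == 3 * len(ann.cdr3.aa_sequence)


def test_mutated_cys_anchor_fails_with_missing_anchor(bundle):
    t = _rearranged(bundle, identity=1.0, seed=6)
    v = bundle.segments[t.v_name]
    a = v.anchor_codon
    assert t.truth_sequence[a:a + 3] == "TGT"
    seq = t.truth_sequence[:a] + "TAT" + t.truth_sequence[a + 3:]  # C -> Y
    va = assign_v_gene(seq, bundle, "IGH")
    ja = assign_j_gene(seq, bundle, "IGH")
    cdr3, reason = extract_cdr3(seq, va, ja, bundle)
    assert cdr3 is None and reason == "missing_anchor"
    ok, why = check_productivity(seq, va, ja, bundle)
    assert not ok and why == "missing_anchor"


def test_one_nt_junction_insertion_is_out_of_frame(bundle):
    t = _rearranged(bundle, identity=1.0, seed=7)
    cut = t.junction_start + max(1, t.junction_len // 2)
    seq = t.truth_sequence[:cut] + "A" + t.truth_sequence[cut:]
    va = assign_v_gene(seq, bundle, "IGH")
    ja = assign_j_gene(seq, bundle, "IGH")
    ok, why = check_productivity(seq, va, ja, bundle)
    assert not ok and why == "out_of_frame"
    cdr3, reason = extract_cdr3(seq, va, ja, bundle)
    assert reason is None and cdr3 is not None  # nt CDR3 still reported


def test_stop_codon_in_fr3_detected(bundle):
    t = _rearranged(bundle, identity=1.0, seed=8)
    v = bundle.segments[t.v_name]
    fr3_codon = (v.region_bounds["FR3"][0] // 3) * 3 + 3
    seq = t.truth_sequence[:fr3_codon] + "TAG" + t.truth_sequence[fr3_codon + 3:]
    va = assign_v_gene(seq, bundle, "IGH")
    ja = assign_j_gene(seq, bundle, "IGH")
    ok, why = check_productivity(seq, va, ja, bundle)
    assert not ok and why == "stop_codon"


def test_identity_agrees_with_dp_oracle(bundle):
    """Spot version of the oracle-equivalence property (full 200-pair run in
    the acceptance suite)."""
    rng = np.random.default_rng(0)
    alleles = bundle.segments_by_class("IGH", "V")
    for trial in range(30):
        seg = alleles[int(rng.integers(len(alleles)))]
        seq = list(seg.sequence)
        n_mut = int(rng.integers(0, 31))
        for pos in rng.choice(len(seq), size=n_mut, replace=False):
            seq[pos] = str(rng.choice([b for b in "ACGT" if b != seq[pos]]))
        mutated = "".join(seq)
        va = assign_v_gene(mutated + "ACGTACGTACGT", bundle, "IGH")
        oracle = round2(gotoh_identity(seg.sequence, mutated))
        assert va.segment_name == seg.name
        assert va.identity_pct == pytest.approx(oracle, abs=0.005)
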