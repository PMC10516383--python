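import pytest
from hypothesis import HealthCheck, settings

from allcll.reference import GeneSegment, PanelTarget, ReferenceBundle
from allcll.simulate import synthetic_reference

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def world():
    """The default synthetic reference world: (bundle, genome)."""
    return synthetic_reference(0)


@pytest.fixture(scope="session")
def bundle(world):
    return world[0]


@pytest.fixture(scope="session")
def genome(world):
    return world[1]


def make_mini_bundle(j_strand: str = "+") -> ReferenceBundle:
    """A tiny hand-built bundle: one V, one D, one J on one contig."""
    v_seq = ("ATGGCC" * 12 + "TGT" + "GCAGAA")  # 81 nt, Cys anchor at 72
    d_seq = "GGTACGTAGCTA"
    j_seq = "ACGTACGTA" + "TGG" + "GGCACCACTGTC"  # Trp anchor at 9
    segs = {
        "IGHV9-1*01": GeneSegment("IGHV9-1*01", "IGH", "V", "chrT", 100, 100 + len(v_seq),
                                  "+", v_seq,
                                  {"FR1": (0, 18), "CDR1": (18, 27), "FR2": (27, 45),
                                   "CDR2": (45, 54), "FR3": (54, 72)}, 72),
        "IGHD9-9*01": GeneSegment("IGHD9-9*01", "IGH", "D", "chrT", 300, 300 + len(d_seq),
                                  "+", d_seq),
    }
    if j_strand == "+":
        segs["IGHJ9*01"] = GeneSegment("IGHJ9*01", "IGH", "J", "chrT", 500, 500 + len(j_seq),
                                       "+", j_seq, None, 9)
    else:
        segs["IGHJ9*01"] = GeneSegment("IGHJ9*01", "IGH", "J", "chrT", 500, 500 + len(j_seq),
                                       "-", j_seq, None, 9)
    targets = [PanelTarget("chrT", 0, 700, "ig_all", "ig")]
    return ReferenceBundle(segments=segs, targets=targets, cna_regions={})
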