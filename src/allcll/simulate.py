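"""Seeded capture-NGS simulator: the test bed for the whole workflow.

The simulator emits *pre-aligned* SAM records: reads that span a V(D)J
junction are written as reference-aligned records soft-clipped at the
breakpoint, with the clipped bases taken from the rearranged (non-reference)
side — mimicking what a short-read aligner produces on capture data without
requiring an external aligner. Identical seed + parameters give byte-identical
output.

Read geometry defaults to 2x300 bp paired ends; per-base errors are
substitutions at a constant rate with flat Q30 qualities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam
from Bio.Seq import Seq

from .reference import (
    CNA_REGIONS,
    GeneSegment,
    PanelTarget,
    ReferenceBundle,
    ReferenceError,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}


class SimulationError(RuntimeError):
    def __init__(self, message: str, attempts: int | None = None):
        super().__init__(message)
        self.attempts = attempts


def translate(nt: str) -> str:
    """Translate in frame 0, dropping any trailing partial codon."""
    usable = len(nt) - len(nt) % 3
    return str(Seq(nt[:usable]).translate())


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n random non-stop codons."""
    out = []
    while len(out) < n:
        codon = "".join(rng.choice(["A", "C", "G", "T"], size=3))
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(["A", "C", "G", "T"], size=n)) if n else ""


def _random_seq_no_stop_triplets(rng: np.random.Generator, n: int) -> str:
    """Random sequence with no stop triplet at any offset (synthetic D
    segments, so forced-productive junctions are satisfiable in any frame)."""
    while True:
        seq = _random_seq(rng, n)
        if not any(seq[i:i + 3] in _STOPS for i in range(n - 2)):
            return seq


# ---------------------------------------------------------------------------
# Synthetic reference world
# ---------------------------------------------------------------------------

def synthetic_reference(seed: int = 0) -> tuple[ReferenceBundle, dict[str, str]]:
    """Build a synthetic germline bundle plus its genome.

    Segments are synthetic sequences with realistic lengths (V 300-309 nt in
    frame 0 with a Cys anchor at the FR3 end, D 12-27 nt, J 48 nt with a
    Trp/Phe anchor), not IMGT-licensed sequences. IGLV3-21*04/*02 carry an
    annotated IMGT position-110 codon (germline GGG = Gly) near their 3' end;
    *02 differs from *04 at two diagnostic positions. All segments are placed
    on the plus strand.
    """
    rng = np.random.default_rng(seed)
    segments: dict[str, GeneSegment] = {}
    targets: list[PanelTarget] = []
    genome: dict[str, str] = {}

    v_bounds = {"FR1": (0, 75), "CDR1": (75, 99), "FR2": (99, 150),
                "CDR2": (150, 174), "FR3": (174, 288)}

    def make_v(extra_codons: int, aux: bool) -> tuple[str, int, int | None]:
        seq = _random_codons(rng, 96)
        seq += "TGT"  # Cys anchor at offset 288
        seq += _random_codons(rng, extra_codons)
        aux_off = None
        if aux:
            # IMGT position 110 = 6 codons after Cys-104
            aux_off = 288 + 18
            seq = seq[:aux_off] + "GGG" + seq[aux_off + 3:]
        return seq, 288, aux_off

    def make_j(anchor_codon_nt: str) -> tuple[str, int]:
        seq = _random_seq(rng, 9) + anchor_codon_nt + _random_codons(rng, 12)
        return seq, 9

    def place(chrom: str, cursor: int, name: str, locus: str, cls: str, seq: str,
              bounds=None, anchor=None, aux=None, gap: int = 400) -> int:
        start = cursor + gap
        end = start + len(seq)
        segments[name] = GeneSegment(name, locus, cls, chrom, start, end, "+",
                                     seq, bounds, anchor, aux)
        targets.append(PanelTarget(chrom, max(0, start - 150), end + 150,
                                   f"ig_{name}", "ig"))
        return end

    # IGH on chr14
    cur = 100
    for name in ("IGHV1-2*01", "IGHV3-21*01", "IGHV3-23*01", "IGHV4-34*01"):
        seq, anchor, _ = make_v(extra_codons=3, aux=False)  # 300 nt
        cur = place("chr14", cur, name, "IGH", "V", seq, dict(v_bounds), anchor)
    for name, length in (("IGHD2-2*01", 27), ("IGHD3-10*01", 20), ("IGHD6-19*01", 12)):
        cur = place("chr14", cur, name, "IGH", "D", _random_seq_no_stop_triplets(rng, length))
    for name in ("IGHJ4*02", "IGHJ6*02"):
        seq, anchor = make_j("TGG")
        cur = place("chr14", cur, name, "IGH", "J", seq, None, anchor)
    genome_len_chr14 = cur + 1000

    # IGL on chr22; *02 derived from *04 at two diagnostic positions
    cur = 100
    seq04, anchor, aux = make_v(extra_codons=7, aux=True)
    cur = place("chr22", cur, "IGLV3-21*04", "IGL", "V", seq04, dict(v_bounds), anchor, aux)
    seq02 = list(seq04)
    for off, base in ((51, "A"), (153, "T")):
        seq02[off] = base if seq04[off] != base else ("C" if base != "C" else "G")
    seq02 = "".join(seq02)
    assert translate(seq02).find("*") < 0
    cur = place("chr22", cur, "IGLV3-21*02", "IGL", "V", seq02, dict(v_bounds), anchor, aux)
    seq140, anchor140, _ = make_v(extra_codons=4, aux=False)
    cur = place("chr22", cur, "IGLV1-40*01", "IGL", "V", seq140, dict(v_bounds), anchor140)
    for name in ("IGLJ2*01", "IGLJ3*02"):
        seq, anchor = make_j("TTC")
        cur = place("chr22", cur, name, "IGL", "J", seq, None, anchor)
    genome_len_chr22 = cur + 1000

    # CNA backbone + neutral backbone + driver targets. Capture panels tile
    # the recurrent CNA regions densely with probe-sized targets; the median
    # log2 ratio over ~200 targets resolves clonal fractions down to ~0.3 at
    # the default thresholds.
    backbone_plan = [("chr17", "del17p"), ("chr11", "del11q"),
                     ("chr13", "del13q"), ("chr12", "tri12"), ("chr2", None)]
    contig_cursor: dict[str, int] = {}
    n_per_region = {None: 200}
    for chrom, region in backbone_plan:
        cur = 500
        n = n_per_region.get(region, 200)
        for i in range(n):
            label = f"{region or 'neutral'}_t{i + 1:03d}"
            targets.append(PanelTarget(chrom, cur, cur + 120, label, "cna_backbone", region))
            cur += 120 + 180
        contig_cursor[chrom] = cur
    drivers = [("TP53", "chr17"), ("ATM", "chr11"), ("SF3B1", "chr2"),
               ("NOTCH1", "chr9"), ("BTK", "chrX")]
    for gene, chrom in drivers:
        cur = contig_cursor.get(chrom, 500)
        targets.append(PanelTarget(chrom, cur + 300, cur + 800, gene, "driver"))
        contig_cursor[chrom] = cur + 800

    cna_regions = {r: {t.label for t in targets if t.cna_region == r} for r in CNA_REGIONS}
    bundle = ReferenceBundle(segments=segments, targets=targets, cna_regions=cna_regions)

    # genome: random background with segments written in at their intervals
    lengths = {"chr14": genome_len_chr14, "chr22": genome_len_chr22}
    for t in targets:
        lengths[t.chrom] = max(lengths.get(t.chrom, 0), t.end + 1000)
    for chrom in sorted(lengths):
        genome[chrom] = _random_seq(rng, lengths[chrom])
    for s in segments.values():
        g = genome[s.chrom]
        genome[s.chrom] = g[:s.start] + s.sequence + g[s.end:]
    return bundle, genome


# ---------------------------------------------------------------------------
# Rearrangement truth model
# ---------------------------------------------------------------------------

@dataclass
class RearrangementConfig:
    v_name: str | None = None
    d_name: str | None = None
    j_name: str | None = None
    v_trim_range: tuple[int, int] = (0, 0)
    d_trim_range: tuple[int, int] = (0, 4)
    j_trim_range: tuple[int, int] = (0, 6)
    n_length_range: tuple[int, int] = (0, 10)
    shm_target_identity: float = 1.0
    force_productive: bool = True
    forced_v_mutations: tuple[tuple[int, str], ...] = ()
    max_attempts: int = 50


@dataclass
class SimulatedRearrangement:
    locus: str
    v_name: str
    d_name: str | None
    j_name: str
    v_trim: int
    d_trim_left: int
    d_trim_right: int
    j_trim: int
    n1: str
    n2: str
    shm_target_identity: float
    truth_sequence: str
    truth_mutations: list[tuple[int, str, str]]
    productive_truth: bool
    seed: int
    v_portion_len: int  # junction starts here in truth coordinates
    junction_len: int

    @property
    def junction_start(self) -> int:
        return self.v_portion_len

    @property
    def junction_end(self) -> int:
        return self.v_portion_len + self.junction_len

    @property
    def truth_identity(self) -> float:
        """Germline identity of the V portion implied by the applied mutations."""
        return 1.0 - len(self.truth_mutations) / self.v_portion_len

    def reconstruct(self, bundle: ReferenceBundle) -> str:
        """Rebuild the truth sequence from the recorded fields (invariant)."""
        v = bundle.segments[self.v_name].sequence
        j = bundle.segments[self.j_name].sequence
        v_part = list(v[: len(v) - self.v_trim])
        for off, _ref, alt in self.truth_mutations:
            v_part[off] = alt
        d_core = ""
        if self.d_name is not None:
            d = bundle.segments[self.d_name].sequence
            d_core = d[self.d_trim_left: len(d) - self.d_trim_right]
        return "".join(v_part) + self.n1 + d_core + self.n2 + j[self.j_trim:]


def simulate_rearrangement(bundle: ReferenceBundle, locus: str,
                           config: RearrangementConfig | None = None,
                           seed: int = 0) -> SimulatedRearrangement:
    """Recombine germline segments into a hypermutated rearrangement truth.

    Trimming never removes an anchor codon; SHM substitutions fall only within
    the V portion, uniformly at random, at the closest achievable count with
    identity >= ``shm_target_identity``. With ``force_productive`` the junction
    is padded to preserve the reading frame and mutation draws are retried
    until translation is stop-free with intact anchors.
    """
    config = config or RearrangementConfig()
    rng = np.random.default_rng(seed)

    def pick(cls: str, name: str | None) -> GeneSegment | None:
        options = bundle.segments_by_class(locus, cls)
        if name is not None:
            return bundle.segments[name]
        if not options:
            return None
        return options[int(rng.integers(0, len(options)))]

    v = pick("V", config.v_name)
    j = pick("J", config.j_name)
    if v is None or j is None:
        raise SimulationError(f"locus {locus}: bundle lacks a V or J segment")
    d = pick("D", config.d_name) if locus == "IGH" or config.d_name else None

    for attempt in range(1, config.max_attempts + 1):
        if attempt > 1:  # a fresh draw can escape an unproductive combination
            v = pick("V", config.v_name)
            j = pick("J", config.j_name)
            d = pick("D", config.d_name) if locus == "IGH" or config.d_name else None
        v_trim = int(rng.integers(config.v_trim_range[0], config.v_trim_range[1] + 1))
        v_trim = min(v_trim, len(v.sequence) - (v.anchor_codon + 3))
        j_trim = int(rng.integers(config.j_trim_range[0], config.j_trim_range[1] + 1))
        j_trim = min(j_trim, j.anchor_codon)
        dl = dr = 0
        d_core = ""
        if d is not None:
            dl = int(rng.integers(config.d_trim_range[0], config.d_trim_range[1] + 1))
            dr = int(rng.integers(config.d_trim_range[0], config.d_trim_range[1] + 1))
            if dl + dr >= len(d.sequence):
                dl = dr = 0
            d_core = d.sequence[dl: len(d.sequence) - dr]
        n1 = _random_seq(rng, int(rng.integers(config.n_length_range[0], config.n_length_range[1] + 1)))
        n2 = _random_seq(rng, int(rng.integers(config.n_length_range[0], config.n_length_range[1] + 1)))

        v_portion_len = len(v.sequence) - v_trim
        if config.force_productive:
            span = (v_portion_len + len(n1) + len(d_core) + len(n2)
                    + (j.anchor_codon - j_trim)) - v.anchor_codon
            n2 += _random_seq(rng, (3 - span % 3) % 3)

        forced = {off: alt for off, alt in config.forced_v_mutations}
        for off in forced:
            if not 0 <= off < v_portion_len:
                raise SimulationError(f"forced mutation offset {off} outside V portion")
        n_mut = int(np.floor((1.0 - config.shm_target_identity) * v_portion_len + 1e-9))
        free = [i for i in range(v_portion_len) if i not in forced]
        positions = sorted(rng.choice(len(free), size=min(n_mut, len(free)), replace=False))
        mutations: list[tuple[int, str, str]] = []
        v_part = list(v.sequence[:v_portion_len])
        for idx in positions:
            off = free[idx]
            ref = v_part[off]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            v_part[off] = alt
            mutations.append((off, ref, alt))
        for off in sorted(forced):
            ref = v_part[off]
            if forced[off] == ref:
                raise SimulationError(f"forced mutation at {off} equals germline base")
            v_part[off] = forced[off]
            mutations.append((off, ref, forced[off]))
        mutations.sort()

        truth = "".join(v_part) + n1 + d_core + n2 + j.sequence[j_trim:]
        junction_len = len(n1) + len(d_core) + len(n2)
        v_anchor_aa = translate(truth[v.anchor_codon: v.anchor_codon + 3])
        jq = v_portion_len + junction_len + (j.anchor_codon - j_trim)
        j_anchor_aa = translate(truth[jq: jq + 3])
        in_frame = (jq - v.anchor_codon) % 3 == 0
        stop_free = "*" not in translate(truth)
        productive = in_frame and stop_free and v_anchor_aa == "C" and j_anchor_aa in "WF"
        if config.force_productive and not productive:
            continue
        return SimulatedRearrangement(
            locus=locus, v_name=v.name, d_name=d.name if d else None, j_name=j.name,
            v_trim=v_trim, d_trim_left=dl, d_trim_right=dr, j_trim=j_trim,
            n1=n1, n2=n2, shm_target_identity=config.shm_target_identity,
            truth_sequence=truth, truth_mutations=mutations,
            productive_truth=productive, seed=seed,
            v_portion_len=v_portion_len, junction_len=junction_len)
    raise SimulationError(
        f"could not satisfy productivity in {config.max_attempts} attempts",
        attempts=config.max_attempts)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadSimConfig:
    read_len: int = 300
    frag_mean: float = 500.0
    frag_sd: float = 50.0
    error_rate: float = 0.0
    depth: float = 100.0
    flank: int = 400
    base_quality: int = 30
    min_anchor: int = 20


@dataclass
class SimReadSet:
    header: pysam.AlignmentHeader
    records: list[pysam.AlignedSegment]
    truth: dict
    seed: int

    def write_sam(self, path: str | Path) -> None:
        with pysam.AlignmentFile(str(path), "w", header=self.header) as out:
            for rec in sorted(self.records, key=lambda r: (r.reference_id, r.reference_start, r.query_name, r.flag)):
                out.write(rec)

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fq:
            for rec in self.records:
                seq = rec.query_sequence
                qual = "".join(chr(q + 33) for q in rec.query_qualities)
                if rec.is_reverse:
                    seq = str(Seq(seq).reverse_complement())
                    qual = qual[::-1]
                fq.write(f"@{rec.query_name}/{2 if rec.is_read2 else 1}\n{seq}\n+\n{qual}\n")

    def extend(self, other: "SimReadSet") -> None:
        self.records.extend(other.records)
        for key, val in other.truth.items():
            self.truth.setdefault(key, val)


def make_header(bundle: ReferenceBundle, genome: Mapping[str, str] | None = None) -> pysam.AlignmentHeader:
    if genome is not None:
        names = sorted(genome)
        lengths = [len(genome[n]) for n in names]
    else:
        cl = bundle.contig_lengths()
        names = sorted(cl)
        lengths = [cl[n] for n in names]
    return pysam.AlignmentHeader.from_references(names, lengths)


def _make_record(header: pysam.AlignmentHeader, name: str, chrom: str, pos: int,
                 cigar: list[tuple[int, int]], seq: str, mapq: int, qual: int,
                 flag: int) -> pysam.AlignedSegment:
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.flag = flag
    rec.reference_id = list(header.references).index(chrom)
    rec.reference_start = pos
    rec.mapping_quality = mapq
    rec.cigartuples = cigar
    rec.query_sequence = seq
    rec.query_qualities = pysam.qualitystring_to_array(chr(qual + 33) * len(seq))
    return rec


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = bytes([choices[int(rng.integers(0, 3))]])
    return arr.tobytes().decode()


def simulate_reads(truth: SimulatedRearrangement, bundle: ReferenceBundle,
                   genome: Mapping[str, str], config: ReadSimConfig | None = None,
                   seed: int = 0) -> SimReadSet:
    """Paired capture reads over a rearranged molecule, pre-aligned.

    The template molecule is upstream germline flank + rearranged sequence +
    downstream germline flank. A read's alignable portion on the V side (flank
    + mutated V body, contiguous with the genome) or the J side determines its
    anchor; the rest of the read is emitted as a soft clip at the junction
    breakpoint. Reads whose longest alignable portion is below ``min_anchor``
    are dropped (an aligner would leave them unmapped).
    """
    config = config or ReadSimConfig()
    if config.depth <= 0:
        raise SimulationError("depth must be > 0")
    if config.read_len > config.frag_mean + 4 * config.frag_sd:
        raise SimulationError("read_len exceeds plausible fragment length")
    rng = np.random.default_rng(seed)
    v = bundle.segments[truth.v_name]
    j = bundle.segments[truth.j_name]
    if v.strand != "+" or j.strand != "+":
        raise SimulationError("read simulation requires plus-strand segments")

    flank = config.flank
    flank_up = genome[v.chrom][max(0, v.start - flank): v.start]
    flank_down = genome[j.chrom][j.end: j.end + flank]
    molecule = flank_up + truth.truth_sequence + flank_down
    a = len(flank_up)
    v_end_mol = a + truth.junction_start       # alignable V side: [0, v_end_mol)
    j_start_mol = a + truth.junction_end       # alignable J side: [j_start_mol, len)
    v_gstart = v.start - a                     # genomic pos of molecule position 0
    j_gstart = j.start + truth.j_trim          # genomic pos of molecule position j_start_mol

    header = make_header(bundle, genome)
    rl = config.read_len
    # interior coverage = n_frag * covered_span / n_start_positions; solve for
    # n_frag so that the plateau over the molecule interior hits `depth`
    covered_span = min(config.frag_mean, 2 * rl)
    n_starts = max(1.0, len(molecule) - config.frag_mean + 1)
    n_frag = int(rng.poisson(config.depth * n_starts / covered_span))
    records: list[pysam.AlignedSegment] = []

    def map_read(s: int, e: int):
        left = max(0, min(e, v_end_mol) - s)
        right = max(0, e - max(s, j_start_mol))
        if left >= right and left >= config.min_anchor:
            pos = v_gstart + s
            cigar = [(0, left)]
            if e - s > left:
                cigar.append((4, e - s - left))
            return v.chrom, pos, cigar
        if right >= config.min_anchor:
            clip = e - s - right
            pos = j_gstart + max(0, s - j_start_mol)
            cigar = ([(4, clip)] if clip else []) + [(0, right)]
            return j.chrom, pos, cigar
        return None

    for i in range(n_frag):
        fl = int(np.clip(rng.normal(config.frag_mean, config.frag_sd), rl, len(molecule)))
        start = int(rng.integers(0, len(molecule) - fl + 1))
        name = f"sim{seed}_{i:06d}"
        ends = [(start, start + min(rl, fl), False),
                (start + fl - min(rl, fl), start + fl, True)]
        mapped = []
        for s, e, rev in ends:
            m = map_read(s, e)
            if m is None:
                mapped.append(None)
                continue
            chrom, pos, cigar = m
            seq = _apply_errors(rng, molecule[s:e], config.error_rate)
            mapped.append((chrom, pos, cigar, seq, rev))
        for k, m in enumerate(mapped):
            if m is None:
                continue
            chrom, pos, cigar, seq, rev = m
            flag = 0x1 | (0x40 if k == 0 else 0x80)
            if rev:
                flag |= 0x10
            mate = mapped[1 - k]
            rec = _make_record(header, name, chrom, pos, cigar, seq, 60,
                               config.base_quality, flag)
            if mate is not None:
                rec.flag |= 0x2 | (0x20 if mate[4] else 0)
                rec.next_reference_id = list(header.references).index(mate[0])
                rec.next_reference_start = mate[1]
            else:
                rec.flag |= 0x8
            records.append(rec)

    return SimReadSet(header=header, records=records,
                      truth={"rearrangement": truth}, seed=seed)


def simulate_panel_reads(bundle: ReferenceBundle, genome: Mapping[str, str],
                         base_depth: float = 200.0,
                         lesions: Mapping[str, float] | None = None,
                         noise_cv: float = 0.0, seed: int = 0,
                         read_len: int = 150,
                         roles: Sequence[str] = ("driver", "cna_backbone"),
                         base_quality: int = 30,
                         error_rate: float = 0.0) -> SimReadSet:
    """Fully-aligned reads over panel targets with CNA-scaled depths."""
    rng = np.random.default_rng(seed)
    header = make_header(bundle, genome)
    multipliers = cna_multipliers(lesions or {})
    records: list[pysam.AlignedSegment] = []
    i = 0
    for t in sorted(bundle.targets, key=lambda t: (t.chrom, t.start, t.label)):
        if t.role not in roles:
            continue
        mult = multipliers.get(t.cna_region, 1.0) if t.cna_region else 1.0
        depth = base_depth * mult
        if noise_cv > 0:
            sigma = np.sqrt(np.log1p(noise_cv ** 2))
            depth *= rng.lognormal(-sigma ** 2 / 2, sigma)
        n_reads = int(rng.poisson(depth * t.length / read_len))
        glen = len(genome[t.chrom])
        lo = max(0, t.start - read_len // 2)
        hi = min(glen - read_len, t.end - read_len // 2)
        for _ in range(n_reads):
            pos = int(rng.integers(lo, hi + 1))
            seq = _apply_errors(rng, genome[t.chrom][pos:pos + read_len], error_rate)
            records.append(_make_record(header, f"pnl{seed}_{i:07d}", t.chrom, pos,
                                        [(0, read_len)], seq, 60, base_quality, 0))
            i += 1
    return SimReadSet(header=header, records=records, truth={"lesions": dict(lesions or {})}, seed=seed)


# ---------------------------------------------------------------------------
# CNA depth profiles
# ---------------------------------------------------------------------------

def cna_multipliers(lesions: Mapping[str, float]) -> dict[str, float]:
    """Expected depth multiplier per region: 1 - f/2 for deletions (one copy
    lost in a fraction f of cells), 1 + f/2 for trisomy 12."""
    out = {}
    for region, f in lesions.items():
        if region not in CNA_REGIONS:
            raise ReferenceError(f"unknown CNA region {region!r}")
        if not 0.0 <= f <= 1.0:
            raise ReferenceError(f"clonal fraction for {region} outside [0,1]: {f}")
        out[region] = 1.0 + f / 2.0 if region == "tri12" else 1.0 - f / 2.0
    return out


def simulate_cna_profile(bundle: ReferenceBundle, lesions: Mapping[str, float],
                         base_depth: float = 1500.0, noise_cv: float = 0.0,
                         seed: int = 0) -> dict[str, float]:
    """Per-target mean depths under a lesion profile with multiplicative noise
    of the given coefficient of variation (lognormal, mean 1)."""
    rng = np.random.default_rng(seed)
    multipliers = cna_multipliers(lesions)
    sigma = np.sqrt(np.log1p(noise_cv ** 2)) if noise_cv > 0 else 0.0
    depths: dict[str, float] = {}
    for t in sorted(bundle.targets, key=lambda t: (t.chrom, t.start, t.label)):
        if t.role not in ("cna_backbone", "driver"):
            continue
        mult = multipliers.get(t.cna_region, 1.0) if t.cna_region else 1.0
        noise = rng.lognormal(-sigma ** 2 / 2, sigma) if sigma > 0 else 1.0
        depths[t.label] = base_depth * mult * noise
    return depths


# ---------------------------------------------------------------------------
# Variant spiking
# ---------------------------------------------------------------------------

def _ref_to_query(rec: pysam.AlignedSegment, pos: int, span: int = 1) -> int | None:
    """Query index of reference position ``pos`` if pos..pos+span-1 fall inside
    a single aligned (M) run of the read; else None."""
    q = 0
    r = rec.reference_start
    for op, length in rec.cigartuples:
        if op in (0, 7, 8):  # M/=/X
            if r <= pos and pos + span <= r + length:
                return q + (pos - r)
            q += length
            r += length
        elif op in (1, 4):  # I/S
            q += length
        elif op in (2, 3):  # D/N
            r += length
    return None


def _normalize_allele(ref: str, alt: str) -> tuple[str, str]:
    if alt.startswith("+"):
        return ref, ref + alt[1:]
    if alt.startswith("-"):
        return ref + alt[1:], ref
    return ref, alt


def spike_variant(read_set: SimReadSet, chrom: str, pos: int, ref: str, alt: str,
                  vaf: float, seed: int = 0,
                  genome: Mapping[str, str] | None = None) -> SimReadSet:
    """Spike a SNV or simple indel into overlapping reads at probability ``vaf``.

    ``pos`` is 0-based. ``alt`` may be VCF-style or '+SEQ' (insertion after
    pos) / '-SEQ' (deletion of SEQ after pos). Modifies the read set in place
    and records the realized alternate fraction in its truth block.
    """
    if not 0 < vaf <= 1:
        raise SimulationError(f"vaf outside (0,1]: {vaf}")
    ref, alt = _normalize_allele(ref, alt)
    if genome is not None and genome[chrom][pos:pos + len(ref)] != ref:
        raise SimulationError(
            f"ref mismatch at {chrom}:{pos}: expected {ref}, reference has "
            f"{genome[chrom][pos:pos + len(ref)]}")
    rng = np.random.default_rng(seed)
    realized = covered = 0
    for rec in read_set.records:
        if rec.reference_name != chrom:
            continue
        qidx = _ref_to_query(rec, pos, span=len(ref))
        if qidx is None:
            continue
        covered += 1
        if rng.random() >= vaf:
            continue
        realized += 1
        _apply_allele(rec, pos, qidx, ref, alt)
    read_set.truth.setdefault("spikes", []).append({
        "chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "vaf": vaf,
        "covered": covered, "realized": realized,
        "realized_fraction": realized / covered if covered else 0.0,
    })
    return read_set


def _apply_allele(rec: pysam.AlignedSegment, pos: int, qidx: int, ref: str, alt: str) -> None:
    seq = rec.query_sequence
    qual = list(rec.query_qualities)
    if len(ref) == len(alt) == 1:
        seq = seq[:qidx] + alt + seq[qidx + 1:]
        rec.query_sequence = seq
        rec.query_qualities = qual
        return
    cigar = list(rec.cigartuples)
    if len(alt) > len(ref):  # insertion after pos
        ins = alt[len(ref):]
        cut = qidx + 1
        seq = seq[:cut] + ins + seq[cut:]
        qual = qual[:cut] + [qual[qidx]] * len(ins) + qual[cut:]
        rec.cigartuples = _split_cigar(cigar, cut, (1, len(ins)))
    else:  # deletion of ref[1:] after pos
        ndel = len(ref) - len(alt)
        cut = qidx + 1
        seq = seq[:cut] + seq[cut + ndel:]
        qual = qual[:cut] + qual[cut + ndel:]
        rec.cigartuples = _excise_cigar(cigar, cut, ndel)
    rec.query_sequence = seq
    rec.query_qualities = qual


def _split_cigar(cigar, qcut: int, new_op: tuple[int, int]):
    """Insert ``new_op`` at query offset ``qcut`` (splitting the M run there)."""
    out = []
    q = 0
    inserted = False
    for op, length in cigar:
        consumes_q = op in (0, 1, 4, 7, 8)
        if not inserted and consumes_q and q <= qcut <= q + length:
            head = qcut - q
            if head:
                out.append((op, head))
            out.append(new_op)
            if length - head:
                out.append((op, length - head))
            inserted = True
        else:
            out.append((op, length))
        if consumes_q:
            q += length
    return out


def _excise_cigar(cigar, qcut: int, ndel: int):
    """Replace ``ndel`` query bases at offset ``qcut`` with a deletion op."""
    out = []
    q = 0
    for op, length in cigar:
        consumes_q = op in (0, 1, 4, 7, 8)
        if consumes_q and q <= qcut and qcut + ndel <= q + length:
            head = qcut - q
            if head:
                out.append((op, head))
            out.append((2, ndel))
            if length - head - ndel:
                out.append((op, length - head - ndel))
        else:
            out.append((op, length))
        if consumes_q:
            q += length
    return out
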