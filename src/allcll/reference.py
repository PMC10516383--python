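"""Germline IG reference bundle: gene segments, panel targets, CNA regions.

All coordinates are 0-based half-open internally. Segment sequences are stored
in reading orientation (coding strand, 5'->3'); minus-strand segments are
reverse-complemented once at load time so every downstream alignment is
strand-free.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from Bio import SeqIO
from Bio.Seq import Seq

LOCI = ("IGH", "IGL", "IGK")
SEGMENT_CLASSES = ("V", "D", "J")
CNA_REGIONS = ("del17p", "del11q", "del13q", "tri12")
V_REGIONS = ("FR1", "CDR1", "FR2", "CDR2", "FR3")

_VALID_BASES = set("ACGTN")


class ReferenceError(ValueError):
    """Raised when a reference bundle violates its contract."""


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GeneSegment:
    """One germline V, D or J allele in reading orientation.

    ``region_bounds`` (V only) maps FR1/CDR1/FR2/CDR2/FR3 to half-open offsets
    within ``sequence``. ``anchor_codon`` is the offset of the conserved
    Cys-104 (V) or Trp/Phe-118 (J) codon; ``aux_codon`` optionally marks a
    second annotated codon (used for the IMGT position-110 codon of IGLV3-21
    alleles, whose mutation to arginine is the R110 lesion).
    """

    name: str
    locus: str
    segment_class: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    region_bounds: dict[str, tuple[int, int]] | None = None
    anchor_codon: int | None = None
    aux_codon: int | None = None

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise ReferenceError(f"{self.name}: unknown locus {self.locus!r}")
        if self.segment_class not in SEGMENT_CLASSES:
            raise ReferenceError(f"{self.name}: unknown class {self.segment_class!r}")
        if self.strand not in "+-":
            raise ReferenceError(f"{self.name}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ReferenceError(f"{self.name}: bad interval [{self.start},{self.end})")
        if self.end - self.start != len(self.sequence):
            raise ReferenceError(f"{self.name}: interval length != sequence length")
        if set(self.sequence) - _VALID_BASES:
            raise ReferenceError(f"{self.name}: sequence contains non-ACGTN characters")
        if self.segment_class == "D":
            if self.anchor_codon is not None:
                raise ReferenceError(f"{self.name}: D segments carry no anchor codon")
        else:
            if self.anchor_codon is None:
                raise ReferenceError(f"{self.name}: {self.segment_class} segment needs an anchor codon")
            if not 0 <= self.anchor_codon <= len(self.sequence) - 3:
                raise ReferenceError(f"{self.name}: anchor codon outside sequence")
        if self.aux_codon is not None and not 0 <= self.aux_codon <= len(self.sequence) - 3:
            raise ReferenceError(f"{self.name}: aux codon outside sequence")
        if self.region_bounds is not None:
            prev_end = 0
            for region in V_REGIONS:
                if region not in self.region_bounds:
                    raise ReferenceError(f"{self.name}: missing region {region}")
                s, e = self.region_bounds[region]
                if not (0 <= s < e <= len(self.sequence)):
                    raise ReferenceError(f"{self.name}: region {region} out of range")
                if s < prev_end:
                    raise ReferenceError(f"{self.name}: region {region} overlaps/descends")
                prev_end = e
            if self.segment_class == "V" and self.anchor_codon is not None:
                if self.anchor_codon < self.region_bounds["FR3"][1]:
                    raise ReferenceError(f"{self.name}: V anchor lies before FR3 end")

    @property
    def gene(self) -> str:
        """Allele-agnostic gene name ('IGHV3-21*01' -> 'IGHV3-21')."""
        return self.name.split("*")[0]


@dataclass(frozen=True)
class PanelTarget:
    chrom: str
    start: int
    end: int
    label: str
    role: str  # "ig" | "driver" | "cna_backbone"
    cna_region: str | None = None

    def __post_init__(self) -> None:
        if not self.label:
            raise ReferenceError("panel target with empty label")
        if self.start >= self.end:
            raise ReferenceError(f"target {self.label}: zero/negative length")
        if self.role not in ("ig", "driver", "cna_backbone"):
            raise ReferenceError(f"target {self.label}: unknown role {self.role!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReferenceBundle:
    segments: dict[str, GeneSegment]
    targets: list[PanelTarget]
    cna_regions: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = {t.label for t in self.targets}
        for region, members in self.cna_regions.items():
            if region not in CNA_REGIONS:
                raise ReferenceError(f"unknown CNA region {region!r}")
            missing = members - labels
            if missing:
                raise ReferenceError(f"CNA region {region}: unknown targets {sorted(missing)}")
        by_chrom: dict[str, list[PanelTarget]] = {}
        for t in self.targets:
            if t.role == "cna_backbone":
                by_chrom.setdefault(t.chrom, []).append(t)
        for chrom, ts in by_chrom.items():
            ts = sorted(ts, key=lambda t: t.start)
            for a, b in zip(ts, ts[1:]):
                if b.start < a.end:
                    raise ReferenceError(f"overlapping backbone targets on {chrom}: {a.label}/{b.label}")
        present = {(s.locus, s.segment_class) for s in self.segments.values()}
        for locus in {s.locus for s in self.segments.values()}:
            for cls in ("V", "J"):
                if (locus, cls) not in present:
                    raise ReferenceError(f"locus {locus}: no {cls} segment in bundle")

    # -- lookups -------------------------------------------------------------

    def segments_by_class(self, locus: str, cls: str) -> list[GeneSegment]:
        """Segments of one locus and class, lexicographic by name (the
        deterministic order used for all downstream tie-breaking)."""
        return sorted(
            (s for s in self.segments.values() if s.locus == locus and s.segment_class == cls),
            key=lambda s: s.name,
        )

    def loci(self) -> list[str]:
        return sorted({s.locus for s in self.segments.values()})

    def segment_at(self, chrom: str, pos: int) -> GeneSegment | None:
        for s in self.segments.values():
            if s.chrom == chrom and s.start <= pos <= s.end:
                return s
        return None

    def targets_by_role(self, role: str) -> list[PanelTarget]:
        return [t for t in self.targets if t.role == role]

    def target_map(self) -> dict[str, PanelTarget]:
        return {t.label: t for t in self.targets}

    def contig_lengths(self, pad: int = 1000) -> dict[str, int]:
        lengths: dict[str, int] = {}
        for s in self.segments.values():
            lengths[s.chrom] = max(lengths.get(s.chrom, 0), s.end + pad)
        for t in self.targets:
            lengths[t.chrom] = max(lengths.get(t.chrom, 0), t.end + pad)
        return lengths

    def checksum(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.segments):
            s = self.segments[name]
            h.update(f"{name}|{s.chrom}:{s.start}-{s.end}{s.strand}|{s.sequence}".encode())
        for t in sorted(self.targets, key=lambda t: (t.chrom, t.start, t.label)):
            h.update(f"{t.chrom}:{t.start}-{t.end}|{t.label}|{t.role}|{t.cna_region}".encode())
        return h.hexdigest()[:16]


# -- serialization ------------------------------------------------------------

_TSV_COLUMNS = [
    "name", "locus", "class", "chrom", "start", "end", "strand",
    "region_bounds", "anchor_codon", "aux_codon",
]


def _parse_bounds(text: str) -> dict[str, tuple[int, int]] | None:
    if not text or text == ".":
        return None
    offsets = [int(x) for x in text.split(",")]
    if len(offsets) != 6:
        raise ReferenceError(f"region_bounds needs 6 comma-separated offsets, got {text!r}")
    return {r: (offsets[i], offsets[i + 1]) for i, r in enumerate(V_REGIONS)}


def _format_bounds(bounds: dict[str, tuple[int, int]] | None) -> str:
    if bounds is None:
        return "."
    offsets = [bounds["FR1"][0]] + [bounds[r][1] for r in V_REGIONS]
    return ",".join(str(x) for x in offsets)


def load_reference_bundle(fasta_path: str | Path, annotation_path: str | Path,
                          bed_path: str | Path) -> ReferenceBundle:
    """Load and validate a germline bundle from FASTA + annotation TSV + BED.

    FASTA records hold segment sequences in genomic orientation; minus-strand
    segments are reverse-complemented here into reading orientation. The BED
    carries label (col 4) and role (col 5); backbone targets encode their CNA
    region as ``cna:<region>``.
    """
    sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    rows: dict[str, dict[str, str]] = {}
    with open(annotation_path) as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t")
        missing_cols = set(_TSV_COLUMNS) - set(reader.fieldnames or [])
        if missing_cols:
            raise ReferenceError(f"annotation TSV missing columns: {sorted(missing_cols)}")
        for row in reader:
            rows[row["name"]] = row

    segments: dict[str, GeneSegment] = {}
    for name, seq in sequences.items():
        if name not in rows:
            raise ReferenceError(f"FASTA record {name!r} has no annotation row")
        row = rows[name]
        strand = row["strand"]
        stored = revcomp(seq) if strand == "-" else seq
        segments[name] = GeneSegment(
            name=name,
            locus=row["locus"],
            segment_class=row["class"],
            chrom=row["chrom"],
            start=int(row["start"]),
            end=int(row["end"]),
            strand=strand,
            sequence=stored,
            region_bounds=_parse_bounds(row["region_bounds"]),
            anchor_codon=None if row["anchor_codon"] in ("", ".") else int(row["anchor_codon"]),
            aux_codon=None if row.get("aux_codon", ".") in ("", ".") else int(row["aux_codon"]),
        )
    for name in rows:
        if name not in segments:
            raise ReferenceError(f"annotation row {name!r} has no FASTA record")

    targets, cna_regions = _load_bed(bed_path)
    return ReferenceBundle(segments=segments, targets=targets, cna_regions=cna_regions)


def _load_bed(bed_path: str | Path) -> tuple[list[PanelTarget], dict[str, set[str]]]:
    targets: list[PanelTarget] = []
    cna_regions: dict[str, set[str]] = {}
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ReferenceError(f"{bed_path}: malformed BED line {lineno}: {line!r}")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ReferenceError(f"{bed_path}: malformed BED line {lineno}: {line!r}") from exc
            label = fields[3] if len(fields) > 3 else f"target_{lineno}"
            role_field = fields[4] if len(fields) > 4 else "driver"
            cna_region = None
            if role_field.startswith("cna:"):
                role, cna_region = "cna_backbone", role_field.split(":", 1)[1]
            elif role_field == "cna_backbone":
                role = "cna_backbone"
            else:
                role = role_field
            targets.append(PanelTarget(chrom, start, end, label, role, cna_region))
            if cna_region is not None and cna_region in CNA_REGIONS:
                cna_regions.setdefault(cna_region, set()).add(label)
    return targets, cna_regions


def write_reference_bundle(bundle: ReferenceBundle, fasta_path: str | Path,
                           annotation_path: str | Path, bed_path: str | Path) -> None:
    """Inverse of :func:`load_reference_bundle` (round-trip safe)."""
    with open(fasta_path, "w") as fa:
        for name in sorted(bundle.segments):
            s = bundle.segments[name]
            genomic = revcomp(s.sequence) if s.strand == "-" else s.sequence
            fa.write(f">{name}\n{genomic}\n")
    with open(annotation_path, "w") as tsv:
        tsv.write("\t".join(_TSV_COLUMNS) + "\n")
        for name in sorted(bundle.segments):
            s = bundle.segments[name]
            tsv.write("\t".join([
                s.name, s.locus, s.segment_class, s.chrom, str(s.start), str(s.end),
                s.strand, _format_bounds(s.region_bounds),
                "." if s.anchor_codon is None else str(s.anchor_codon),
                "." if s.aux_codon is None else str(s.aux_codon),
            ]) + "\n")
    with open(bed_path, "w") as bed:
        for t in sorted(bundle.targets, key=lambda t: (t.chrom, t.start, t.label)):
            role = f"cna:{t.cna_region}" if t.cna_region else t.role
            bed.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.label}\t{role}\n")
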