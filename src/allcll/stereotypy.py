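"""Stereotyped B-cell receptor subset assignment.

Roughly one third of CLL clones carry quasi-identical ("stereotyped") B-cell
receptors; membership in the major subsets (e.g. CLL#2, IGHV3-21-associated)
is prognostic. Assignment here is resource-driven: a definitions TSV gives,
per subset, the allowed V genes, the exact CDR3 amino-acid length, a
position-indexed motif and a mismatch budget. Canonical definitions are a
user-supplied resource; the table bundled with this package contains clearly
labelled synthetic test definitions only.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .annotate import AnnotatedRearrangement


class SubsetDefinitionError(ValueError):
    pass


@dataclass(frozen=True)
class SubsetDefinition:
    subset_id: str
    allowed_v_genes: frozenset[str]   # allele-agnostic gene names
    cdr3_length_aa: int
    motif: tuple[frozenset[str], ...]  # per-position allowed residue sets
    max_mismatches: int

    def __post_init__(self) -> None:
        if len(self.motif) != self.cdr3_length_aa:
            raise SubsetDefinitionError(
                f"{self.subset_id}: motif length {len(self.motif)} != "
                f"cdr3_length_aa {self.cdr3_length_aa}")
        if self.max_mismatches >= self.cdr3_length_aa:
            raise SubsetDefinitionError(
                f"{self.subset_id}: max_mismatches must be < CDR3 length")
        if not self.allowed_v_genes:
            raise SubsetDefinitionError(f"{self.subset_id}: empty V gene set")


@dataclass(frozen=True)
class SubsetAssignment:
    subset_id: str              # "CLL#2" etc., or "unassigned"
    mismatches: int | None
    matched_definition: SubsetDefinition | None


_AA = set("ACDEFGHIKLMNPQRSTVWY")


def parse_motif(text: str) -> tuple[frozenset[str], ...]:
    """Parse a motif string: single residues, '.'/'X' wildcards, and bracketed
    alternatives like '[ILV]'."""
    positions: list[frozenset[str]] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            end = text.find("]", i)
            if end < 0:
                raise SubsetDefinitionError(f"unterminated bracket in motif {text!r}")
            allowed = set(text[i + 1:end])
            if not allowed <= _AA:
                raise SubsetDefinitionError(f"bad residues in motif set {text[i:end + 1]!r}")
            positions.append(frozenset(allowed))
            i = end + 1
        elif ch in (".", "X"):
            positions.append(frozenset(_AA))
            i += 1
        elif ch in _AA:
            positions.append(frozenset(ch))
            i += 1
        else:
            raise SubsetDefinitionError(f"bad motif character {ch!r} in {text!r}")
    return tuple(positions)


def load_subset_definitions(path: str | Path) -> tuple[list[SubsetDefinition], str]:
    """Load a definitions TSV; returns (definitions, resource version string).

    The version is taken from a ``# version: ...`` comment line and is echoed
    into reports. Malformed definitions raise at load time, not at assignment.
    """
    definitions: list[SubsetDefinition] = []
    version = "unversioned"
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                if "version" in line:
                    version = line.split(":", 1)[1].strip()
                continue
            if not line:
                continue
            if header is None:
                header = line.split("\t")
                continue
            row = dict(zip(header, line.split("\t")))
            definitions.append(SubsetDefinition(
                subset_id=row["subset_id"],
                allowed_v_genes=frozenset(row["v_genes"].split(",")),
                cdr3_length_aa=int(row["cdr3_length_aa"]),
                motif=parse_motif(row["motif"]),
                max_mismatches=int(row["max_mismatches"]),
            ))
    return definitions, version


def bundled_definitions() -> tuple[list[SubsetDefinition], str]:
    """The synthetic test definitions shipped with the package."""
    with resources.as_file(resources.files("allcll").joinpath("data/subsets.synthetic.tsv")) as p:
        return load_subset_definitions(p)


def assign_subset(annotated: AnnotatedRearrangement,
                  definitions: list[SubsetDefinition]) -> SubsetAssignment:
    """Assign a rearrangement to the best-matching stereotyped subset.

    The CDR3-length and V-gene gates are necessary conditions; among
    definitions passing both, the fewest positionwise motif mismatches wins
    (ties lexicographic by subset id); above the definition's mismatch budget
    the rearrangement stays unassigned. Non-productive rearrangements and
    those without a CDR3 are always unassigned.
    """
    if not annotated.productive or annotated.cdr3 is None:
        return SubsetAssignment("unassigned", None, None)
    cdr3 = annotated.cdr3.aa_sequence
    v_gene = annotated.v.segment_name.split("*")[0]
    best: tuple[int, str, SubsetDefinition] | None = None
    for d in sorted(definitions, key=lambda d: d.subset_id):
        if len(cdr3) != d.cdr3_length_aa or v_gene not in d.allowed_v_genes:
            continue
        mismatches = sum(aa not in allowed for aa, allowed in zip(cdr3, d.motif))
        if mismatches > d.max_mismatches:
            continue
        if best is None or (mismatches, d.subset_id) < (best[0], best[1]):
            best = (mismatches, d.subset_id, d)
    if best is None:
        return SubsetAssignment("unassigned", None, None)
    return SubsetAssignment(best[1], best[0], best[2])
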