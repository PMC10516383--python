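"""Coverage-based calling of the four recurrent CLL copy-number alterations.

del(17p), del(11q), del(13q) and trisomy 12 are called from per-target mean
depths via the standard log2-ratio formulation: depths are divided by a
panel-of-normals median (when normals are given), median-centred on the
backbone targets and log2-transformed. A coverage-uniformity QC gate — the
interquartile range of backbone log2 ratios after removing each region's own
median shift, so genuine lesions do not read as noise — withholds all calls
on non-uniform samples. The clonal fraction of a lesion follows from the expected ratio of
a heterozygous deletion (1 - f/2) or a trisomy (1 + f/2):

    deletions:  f = 2 * (1 - 2**median_log2)
    trisomy 12: f = 2 * (2**median_log2 - 1)

clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .reference import CNA_REGIONS, PanelTarget, ReferenceBundle, ReferenceError

# direction gate: trisomy 12 can only be a gain, the dels only deletions
_REGION_DIRECTION = {"del17p": "deletion", "del11q": "deletion",
                     "del13q": "deletion", "tri12": "gain"}


@dataclass
class CNAConfig:
    del_threshold: float = -0.2
    gain_threshold: float = 0.15
    min_targets: int = 3
    uniformity_threshold: float = 0.5   # IQR of backbone log2 ratios
    min_mapq: int = 20


@dataclass
class CoverageProfile:
    sample_id: str
    depths: dict[str, float]  # target label -> mean depth

    def validate(self, bundle: ReferenceBundle) -> None:
        needed = set().union(*bundle.cna_regions.values()) if bundle.cna_regions else set()
        missing = needed - set(self.depths)
        if missing:
            raise ReferenceError(f"{self.sample_id}: missing CNA targets {sorted(missing)}")
        bad = [k for k, v in self.depths.items() if v < 0]
        if bad:
            raise ReferenceError(f"{self.sample_id}: negative depths at {bad}")


@dataclass
class NormalizedProfile:
    sample_id: str
    log2_ratios: dict[str, float]       # backbone targets only
    mode: str                            # "median_center" | "panel_of_normals"
    uniformity_metric: float             # IQR of backbone log2 ratios
    qc_pass: bool
    masked_targets: list[str] = field(default_factory=list)


@dataclass
class CNACall:
    region: str
    state: str                # deletion | gain | neutral | uncallable
    median_log2: float | None
    n_targets: int
    clonal_fraction_est: float | None


@dataclass
class CNAResult:
    qc_pass: bool
    uniformity_metric: float
    calls: list[CNACall]


def compute_depths(alignments, bundle: ReferenceBundle, sample_id: str = "sample",
                   config: CNAConfig | None = None) -> CoverageProfile:
    """Per-target mean depth = aligned bases overlapping the target / target
    length; duplicate-flagged and low-mapq reads are excluded."""
    config = config or CNAConfig()
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
            records = [r for r in fh if not r.is_unmapped]
    else:
        records = list(alignments)
    targets = [t for t in bundle.targets if t.role in ("cna_backbone", "driver")]
    bases = {t.label: 0 for t in targets}
    by_chrom: dict[str, list] = {}
    for t in targets:
        by_chrom.setdefault(t.chrom, []).append(t)
    # sorted interval arrays per chromosome so each read only touches the
    # targets it can overlap (panels carry hundreds of backbone probes)
    index: dict[str, tuple[np.ndarray, list[PanelTarget]]] = {}
    for chrom, ts in by_chrom.items():
        ts.sort(key=lambda t: t.start)
        index[chrom] = (np.array([t.start for t in ts]), ts)
    max_len = max((t.length for t in targets), default=0)
    for rec in records:
        if rec.is_unmapped or rec.is_duplicate or rec.mapping_quality < config.min_mapq:
            continue
        entry = index.get(rec.reference_name)
        if entry is None:
            continue
        starts, ts = entry
        lo = int(np.searchsorted(starts, rec.reference_start - max_len))
        for t in ts[lo:]:
            if t.start >= rec.reference_end:
                break
            overlap = min(rec.reference_end, t.end) - max(rec.reference_start, t.start)
            if overlap > 0:
                bases[t.label] += overlap
    depths = {t.label: bases[t.label] / t.length for t in targets}
    return CoverageProfile(sample_id=sample_id, depths=depths)


def load_depth_table(path: str | Path, sample_id: str | None = None) -> CoverageProfile:
    df = pd.read_csv(path, sep="\t", comment="#")
    return CoverageProfile(sample_id=sample_id or Path(path).stem,
                           depths=dict(zip(df["target"], df["depth"].astype(float))))


def write_depth_table(profile: CoverageProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("target\tdepth\n")
        for label in sorted(profile.depths):
            fh.write(f"{label}\t{profile.depths[label]:.6g}\n")


def _backbone_labels(bundle: ReferenceBundle) -> list[str]:
    return sorted(t.label for t in bundle.targets if t.role == "cna_backbone")


def normalize(profile: CoverageProfile, bundle: ReferenceBundle,
              normals: Sequence[CoverageProfile] | None = None,
              config: CNAConfig | None = None) -> NormalizedProfile:
    """Panel-of-normals (or self median-centred) log2 ratios over backbone
    targets, with the uniformity QC metric.

    Targets whose normal-panel median depth is zero are masked and counted.
    For a lesion-free sample the median backbone log2 ratio is 0 by
    construction; lesioned regions are excluded from the centring estimate.
    """
    config = config or CNAConfig()
    profile.validate(bundle)
    backbone = _backbone_labels(bundle)
    masked: list[str] = []
    ratios: dict[str, float] = {}
    for label in backbone:
        depth = profile.depths.get(label, 0.0)
        if normals:
            norm_depths = [n.depths[label] for n in normals]
            med = float(np.median(norm_depths))
            if med <= 0:
                masked.append(label)
                continue
            ratios[label] = depth / med
        else:
            ratios[label] = depth
    # Robust two-pass centering: a clonal lesion spanning a fifth of the
    # backbone drags the plain global median, eroding the margin to the
    # calling thresholds. First centre on the median of per-region medians,
    # then re-centre on the pooled targets of regions that look neutral.
    region_of = {t.label: (t.cna_region or "neutral") for t in bundle.targets
                 if t.role == "cna_backbone"}
    groups: dict[str, list[float]] = {}
    for label, v in ratios.items():
        groups.setdefault(region_of.get(label, "neutral"), []).append(v)
    group_medians = {g: float(np.median(vs)) for g, vs in groups.items()}
    c0 = float(np.median(list(group_medians.values())))
    if c0 <= 0:
        raise ReferenceError(f"{profile.sample_id}: non-positive median backbone coverage")
    neutral_pool = [v for g, vs in groups.items() for v in vs
                    if abs(np.log2(group_medians[g] / c0)) < 0.1]
    center = float(np.median(neutral_pool)) if neutral_pool else c0
    log2 = {k: float(np.log2(v / center)) if v > 0 else float("-inf")
            for k, v in ratios.items()}
    # Uniformity: IQR of backbone log2 ratios after subtracting each CNA
    # region's own median, so a genuine clonal lesion (a coherent shift of a
    # whole region) does not masquerade as poor coverage uniformity.
    by_region: dict[str, list[float]] = {}
    for label, v in log2.items():
        if np.isfinite(v):
            by_region.setdefault(region_of.get(label, "neutral"), []).append(v)
    residuals = []
    for vals in by_region.values():
        med = float(np.median(vals))
        residuals.extend(v - med for v in vals)
    q75, q25 = np.percentile(residuals, [75, 25])
    iqr = float(q75 - q25)
    return NormalizedProfile(
        sample_id=profile.sample_id, log2_ratios=log2,
        mode="panel_of_normals" if normals else "median_center",
        uniformity_metric=iqr, qc_pass=iqr <= config.uniformity_threshold,
        masked_targets=masked)


def call_cnas(norm: NormalizedProfile, bundle: ReferenceBundle,
              config: CNAConfig | None = None) -> CNAResult:
    """Per-region calls from the median backbone log2 ratio.

    A sample failing the uniformity gate yields no calls (QC-failed marker
    only). Regions with fewer than ``min_targets`` unmasked targets are
    "uncallable". The direction gate keeps trisomy 12 gain-only and the
    deletions deletion-only.
    """
    config = config or CNAConfig()
    if not norm.qc_pass:
        return CNAResult(qc_pass=False, uniformity_metric=norm.uniformity_metric, calls=[])
    calls: list[CNACall] = []
    for region in CNA_REGIONS:
        labels = sorted(bundle.cna_regions.get(region, ()))
        values = [norm.log2_ratios[l] for l in labels
                  if l in norm.log2_ratios and np.isfinite(norm.log2_ratios[l])]
        if len(values) < config.min_targets:
            calls.append(CNACall(region, "uncallable", None, len(values), None))
            continue
        med = float(np.median(values))
        direction = _REGION_DIRECTION[region]
        state = "neutral"
        frac = None
        if direction == "deletion" and med <= config.del_threshold:
            state = "deletion"
            frac = float(np.clip(2.0 * (1.0 - 2.0 ** med), 0.0, 1.0))
        elif direction == "gain" and med >= config.gain_threshold:
            state = "gain"
            frac = float(np.clip(2.0 * (2.0 ** med - 1.0), 0.0, 1.0))
        calls.append(CNACall(region, state, med, len(values), frac))
    return CNAResult(qc_pass=True, uniformity_metric=norm.uniformity_metric, calls=calls)


def cna_table(result: CNAResult) -> pd.DataFrame:
    rows = [{
        "region": c.region, "state": c.state,
        "median_log2": "" if c.median_log2 is None else f"{c.median_log2:.4f}",
        "n_targets": c.n_targets,
        "clonal_fraction": "" if c.clonal_fraction_est is None else f"{c.clonal_fraction_est:.3f}",
    } for c in result.calls]
    return pd.DataFrame(rows, columns=["region", "state", "median_log2", "n_targets", "clonal_fraction"])
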