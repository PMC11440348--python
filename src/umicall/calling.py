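"""Hotspot quantification, single-molecule positivity, LOD and secondary
variant screening.

Allele frequencies are computed over error-corrected consensus reads — i.e.
over original molecules, not raw reads — so amplification bias cancels.  A
sample is ctDNA-positive for its tracked hotspot as soon as one consensus
read carries the mutant base.  The per-sample limit of detection is the VAF
of a single mutant molecule among the consensus depth at the hotspot,
100/depth percent (depth 5,180 gives 0.02%).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

from .consensus import ConsensusRead, consensus_pileup
from .panel import HotspotMutation, PanelDefinition, annotate_variant

DEFAULT_SECONDARY_AF = 0.01

Pileup = dict[int, dict[str, int]]


@dataclass
class HotspotResult:
    """Mutant/total consensus counts for one tracked hotspot in one sample."""

    sample_id: str
    hotspot_id: str
    mutant_consensus_count: int
    total_consensus_depth: int
    evaluable: bool = True

    @property
    def vaf(self) -> Optional[float]:
        if not self.evaluable or self.total_consensus_depth == 0:
            return None
        return self.mutant_consensus_count / self.total_consensus_depth

    @property
    def is_positive(self) -> bool:
        return self.evaluable and self.mutant_consensus_count >= 1

    @property
    def lod_percent(self) -> Optional[float]:
        if not self.evaluable or self.total_consensus_depth == 0:
            return None
        return compute_lod(self.total_consensus_depth)

    @property
    def lod_fraction(self) -> Optional[float]:
        """Unrounded single-molecule detection floor as a fraction."""
        if not self.evaluable or self.total_consensus_depth == 0:
            return None
        return 1.0 / self.total_consensus_depth


class ReviewStatus(str, enum.Enum):
    candidate = "candidate"
    confirmed = "confirmed"
    rejected = "rejected"


@dataclass
class SecondaryVariant:
    """A non-tracked, nonsynonymous variant above the screening threshold."""

    sample_id: str
    assay_id: str
    pos: int  # 0-based
    ref_base: str
    alt_base: str
    af: float
    alt_count: int
    depth: int
    protein_change: Optional[str]
    review_status: ReviewStatus = ReviewStatus.candidate


def compute_lod(consensus_depth: int) -> float:
    """Limit of detection for a locus with ``consensus_depth`` UMI families,
    as a percentage rounded half-up to two decimals.

    One mutant molecule among N families is the smallest detectable signal,
    so LOD = 100/N percent; N = 5,180 gives 0.02%.
    """
    if consensus_depth < 1:
        raise ValueError("consensus depth must be >= 1")
    exact = Decimal(100) / Decimal(consensus_depth)
    return float(exact.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def quantify_hotspot(pileup: Pileup, hotspot: HotspotMutation,
                     sample_id: str) -> HotspotResult:
    """Count mutant and total consensus reads at the hotspot position."""
    if hotspot.pos not in pileup:
        raise ValueError(
            f"hotspot {hotspot.hotspot_id} at {hotspot.chrom}:{hotspot.pos + 1} "
            f"not covered by pileup")
    counts = pileup[hotspot.pos]
    depth = sum(counts.values())
    mutant = counts.get(hotspot.alt_base, 0)
    if depth == 0:
        return HotspotResult(sample_id, hotspot.hotspot_id, 0, 0, evaluable=False)
    return HotspotResult(sample_id, hotspot.hotspot_id, mutant, depth)


def screen_secondary_variants(
    pileup: Pileup,
    assay_id: str,
    panel: PanelDefinition,
    sample_id: str,
    tracked_hotspots: Iterable[str] = (),
    secondary_af_threshold: float = DEFAULT_SECONDARY_AF,
) -> list[SecondaryVariant]:
    """Scan every target position for non-reference bases at or above the
    AF threshold; keep only nonsynonymous, non-tracked SNVs (candidates for
    manual review)."""
    assay = panel.assay(assay_id)
    tracked_keys = set()
    for hid in tracked_hotspots:
        h = panel.hotspot(hid)
        tracked_keys.add((h.chrom, h.pos, h.alt_base))
    out: list[SecondaryVariant] = []
    for pos in sorted(pileup):
        counts = pileup[pos]
        depth = sum(counts.values())
        if depth == 0:
            continue
        ref = assay.reference_insert[pos - assay.target_start]
        for alt, cnt in counts.items():
            if alt == ref or cnt == 0:
                continue
            af = cnt / depth
            if af < secondary_af_threshold:
                continue
            if (assay.chrom, pos, alt) in tracked_keys:
                continue
            cons = annotate_variant(assay, pos, ref, alt)
            if not cons.is_nonsynonymous:
                continue
            out.append(SecondaryVariant(
                sample_id, assay_id, pos, ref, alt, af, cnt, depth,
                cons.protein_change))
    return out


@dataclass
class SampleCall:
    """Per-sample calling output: one result per tracked hotspot plus the
    panel-wide secondary screen."""

    sample_id: str
    hotspot_results: list[HotspotResult]
    secondary_variants: list[SecondaryVariant]
    consensus_depth_by_assay: dict[str, int] = field(default_factory=dict)


def call_sample(consensus_reads: Iterable[ConsensusRead],
                panel: PanelDefinition,
                tracked_hotspots: list[str],
                sample_id: str,
                secondary_af_threshold: float = DEFAULT_SECONDARY_AF) -> SampleCall:
    """Quantify each tracked hotspot and screen all assays for secondary
    variants, from one sample's consensus reads.

    The tracked hotspots (the diagnostic tumor mutations of this patient) are
    an input; they are validated against the panel before any computation.
    """
    if not tracked_hotspots:
        raise ValueError("tracked_hotspots must be non-empty")
    for hid in tracked_hotspots:
        try:
            panel.hotspot(hid)
        except KeyError:
            raise ValueError(f"tracked hotspot {hid!r} not in panel {panel.name}")

    by_assay: dict[str, list[ConsensusRead]] = {}
    for c in consensus_reads:
        by_assay.setdefault(c.assay_id, []).append(c)

    pileups = {
        aid: consensus_pileup(reads, panel.assay(aid))
        for aid, reads in by_assay.items()
    }

    results = []
    for hid in tracked_hotspots:
        h = panel.hotspot(hid)
        assay = panel.assay_for_hotspot(hid)
        pileup = pileups.get(assay.assay_id)
        if pileup is None:
            results.append(HotspotResult(sample_id, hid, 0, 0, evaluable=False))
        else:
            results.append(quantify_hotspot(pileup, h, sample_id))

    secondary: list[SecondaryVariant] = []
    for aid, pileup in pileups.items():
        secondary.extend(screen_secondary_variants(
            pileup, aid, panel, sample_id, tracked_hotspots,
            secondary_af_threshold))

    depths = {aid: len(reads) for aid, reads in by_assay.items()}
    return SampleCall(sample_id, results, secondary, depths)
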