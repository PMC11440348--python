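"""UMI family grouping and error-corrected consensus building.

Reads sharing a (target region, UMI) key are presumed copies of one original
molecule.  A consensus read is emitted only for families with at least
``min_family_size`` raw reads (default 3); at each position the consensus base
is the one reaching the majority threshold among covering members, else N.
Errors introduced after the first copy are voted away; errors on the first
copy penetrate the consensus — exactly the distinction the simulator's two
error tiers encode.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal, Optional

from .panel import PanelAssay
from .reads import TaggedRead

DEFAULT_MIN_FAMILY_SIZE = 3
DEFAULT_MAJORITY_THRESHOLD = 0.6


@dataclass
class UmiFamily:
    assay_id: str
    umi: str
    member_reads: list[str]  # inserts, plus-strand, anchored at target_start

    @property
    def size(self) -> int:
        return len(self.member_reads)


@dataclass
class ConsensusRead:
    assay_id: str
    umi: str
    family_size: int
    sequence: str  # target-region length; N where unresolved


def group_families(tagged: Iterable[TaggedRead],
                   collapse_mode: Literal["exact", "hamming1"] = "exact"
                   ) -> list[UmiFamily]:
    """Group tagged reads into UMI families.

    ``exact``: one family per distinct (assay_id, umi).  ``hamming1``: after
    exact grouping, each family is greedily absorbed into a strictly larger
    family of the same assay whose UMI differs by exactly one base (largest
    target wins, ties broken lexicographically by UMI), treating small
    families as UMI-sequencing-error satellites of big ones.
    """
    buckets: dict[tuple[str, str], list[str]] = defaultdict(list)
    for t in tagged:
        buckets[(t.assay_id, t.umi)].append(t.insert)
    families = [UmiFamily(aid, umi, reads) for (aid, umi), reads in buckets.items()]
    if collapse_mode == "exact":
        return families
    if collapse_mode != "hamming1":
        raise ValueError(f"unknown collapse_mode {collapse_mode!r}")

    merged: list[UmiFamily] = []
    by_assay: dict[str, list[UmiFamily]] = defaultdict(list)
    for f in families:
        by_assay[f.assay_id].append(f)
    for aid, fams in by_assay.items():
        # order: largest first, then UMI; absorb smaller into earlier-ranked
        fams.sort(key=lambda f: (-f.size, f.umi))
        alive: list[UmiFamily] = []
        for f in fams:
            target = None
            for g in alive:
                if g.size > f.size and _hamming1(g.umi, f.umi):
                    target = g
                    break
            if target is None:
                # equal-size candidates: lexicographically smaller UMI absorbs
                for g in alive:
                    if g.size == f.size and g.umi < f.umi and _hamming1(g.umi, f.umi):
                        target = g
                        break
            if target is not None:
                target.member_reads.extend(f.member_reads)
            else:
                alive.append(f)
        merged.extend(alive)
    return merged


def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    return sum(x != y for x, y in zip(a, b)) == 1


def build_consensus(family: UmiFamily,
                    min_family_size: int = DEFAULT_MIN_FAMILY_SIZE,
                    majority_threshold: float = DEFAULT_MAJORITY_THRESHOLD,
                    target_length: Optional[int] = None
                    ) -> Optional[ConsensusRead]:
    """Per-position majority consensus of one family, or None (rejected) if
    the family is below ``min_family_size``.

    A member shorter than the target covers only its prefix; uncovered
    positions reduce the denominator at that position.  The consensus base
    must reach ``majority_threshold`` of covering members (ties and
    sub-threshold pluralities give N; frequency exactly at threshold is
    called).
    """
    if not family.member_reads:
        raise ValueError("empty family")
    if family.size < min_family_size:
        return None
    if target_length is None:
        target_length = max(len(m) for m in family.member_reads)
    out = []
    for pos in range(target_length):
        counts = Counter(m[pos] for m in family.member_reads if pos < len(m))
        counts.pop("N", None)
        depth = sum(counts.values())
        if depth == 0:
            out.append("N")
            continue
        base, cnt = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
        top = [b for b, c in counts.items() if c == cnt]
        if len(top) > 1 or cnt / depth < majority_threshold:
            out.append("N")
        else:
            out.append(base)
    return ConsensusRead(family.assay_id, family.umi, family.size, "".join(out))


def build_all_consensus(families: Iterable[UmiFamily],
                        min_family_size: int = DEFAULT_MIN_FAMILY_SIZE,
                        majority_threshold: float = DEFAULT_MAJORITY_THRESHOLD,
                        target_length_by_assay: Optional[dict[str, int]] = None
                        ) -> tuple[list[ConsensusRead], int]:
    """Consensus for every eligible family; returns (reads, n_rejected)."""
    out: list[ConsensusRead] = []
    rejected = 0
    for fam in families:
        tl = (target_length_by_assay or {}).get(fam.assay_id)
        cons = build_consensus(fam, min_family_size, majority_threshold, tl)
        if cons is None:
            rejected += 1
        else:
            out.append(cons)
    return out, rejected


def consensus_pileup(consensus_reads: Iterable[ConsensusRead],
                     assay: PanelAssay) -> dict[int, dict[str, int]]:
    """Per-target-position base counts (A/C/G/T; N excluded) over consensus
    reads of one assay.  Keys are 0-based genomic positions."""
    reads = list(consensus_reads)
    for c in reads:
        if c.assay_id != assay.assay_id:
            raise ValueError(
                f"consensus read from assay {c.assay_id} in pileup for "
                f"{assay.assay_id}")
    pile: dict[int, dict[str, int]] = {
        assay.target_start + i: {"A": 0, "C": 0, "G": 0, "T": 0}
        for i in range(assay.target_length)
    }
    for c in reads:
        for i, base in enumerate(c.sequence):
            if base in "ACGT" and i < assay.target_length:
                pile[assay.target_start + i][base] += 1
    return pile
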