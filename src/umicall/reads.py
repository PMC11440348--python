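"""UMI extraction and primer-anchored assay assignment.

For fixed-layout amplicon reads, matching the read prefix against each assay's
forward primer (Hamming distance, substitution-only error model) identifies
the locus without a genome aligner.  Off-target or damaged reads land in the
rejection tallies of :class:`ReadQcTally` rather than being silently dropped.
Reads are single-end, forward orientation; no reverse-complement rescue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pysam

from .panel import PanelDefinition


@dataclass
class TaggedRead:
    read_id: str
    assay_id: str
    umi: str
    insert: str  # plus-strand orientation, starts at the assay target_start
    n_mismatches_primer: int


@dataclass
class ReadQcTally:
    total_reads: int = 0
    assigned_reads: int = 0
    rejected_short: int = 0
    rejected_no_primer: int = 0
    rejected_ambiguous: int = 0

    @property
    def rejected(self) -> int:
        return self.rejected_short + self.rejected_no_primer + self.rejected_ambiguous

    def check(self) -> None:
        assert self.total_reads == self.assigned_reads + self.rejected, \
            "read tally conservation violated"

    def as_dict(self) -> dict[str, int]:
        return {
            "total_reads": self.total_reads,
            "assigned_reads": self.assigned_reads,
            "rejected_short": self.rejected_short,
            "rejected_no_primer": self.rejected_no_primer,
            "rejected_ambiguous": self.rejected_ambiguous,
        }


REJECT_SHORT = "rejected_short"
REJECT_NO_PRIMER = "rejected_no_primer"
REJECT_AMBIGUOUS = "rejected_ambiguous"


def extract_umi(sequence: str, umi_length: int,
                min_primer_length: int = 15) -> Optional[tuple[str, str]]:
    """Split off the leading UMI; None if the read is too short to contain a
    UMI plus a minimal primer."""
    if len(sequence) < umi_length + min_primer_length:
        return None
    return sequence[:umi_length], sequence[umi_length:]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def assign_assay(remainder: str, panel: PanelDefinition,
                 max_primer_mismatches: int = 2
                 ) -> tuple[str, str, int] | str:
    """Assign a post-UMI read remainder to the unique assay whose forward
    primer matches its prefix within ``max_primer_mismatches`` substitutions.

    Returns ``(assay_id, insert, n_mismatches)`` or a rejection code.  The
    insert is truncated at the known target length (equivalently, at the
    reverse-primer read-through).
    """
    if not remainder:
        return REJECT_NO_PRIMER
    best: list[tuple[int, str]] = []
    for assay in panel.assays:
        primer = assay.forward_primer
        if len(remainder) < len(primer):
            continue
        d = _hamming(remainder[: len(primer)], primer)
        if d <= max_primer_mismatches:
            best.append((d, assay.assay_id))
    if not best:
        return REJECT_NO_PRIMER
    best.sort()
    if len(best) > 1 and best[0][0] == best[1][0]:
        return REJECT_AMBIGUOUS
    d, assay_id = best[0]
    assay = panel.assay(assay_id)
    insert = remainder[len(assay.forward_primer):][: assay.target_length]
    return assay_id, insert, d


def tag_reads(records: Iterable[tuple[str, str]], panel: PanelDefinition,
              umi_length: int = 12, max_primer_mismatches: int = 2,
              tally: Optional[ReadQcTally] = None) -> Iterator[TaggedRead]:
    """Apply extract_umi then assign_assay to (read_id, sequence) pairs.

    Yields TaggedReads; rejections are tallied, never raised.  Pass a tally
    to collect QC counters (its conservation identity holds on every run).
    """
    if tally is None:
        tally = ReadQcTally()
    min_primer = min(len(a.forward_primer) for a in panel.assays)
    for read_id, seq in records:
        tally.total_reads += 1
        split = extract_umi(seq, umi_length, min_primer_length=min_primer)
        if split is None:
            tally.rejected_short += 1
            continue
        umi, remainder = split
        res = assign_assay(remainder, panel, max_primer_mismatches)
        if res == REJECT_NO_PRIMER:
            tally.rejected_no_primer += 1
            continue
        if res == REJECT_AMBIGUOUS:
            tally.rejected_ambiguous += 1
            continue
        assay_id, insert, d = res
        tally.assigned_reads += 1
        yield TaggedRead(read_id, assay_id, umi, insert, d)


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """(read_id, sequence) pairs from a FASTQ/FASTQ.gz file."""
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield entry.name, entry.sequence


def process_fastq(path: str | Path, panel: PanelDefinition,
                  umi_length: int = 12, max_primer_mismatches: int = 2
                  ) -> tuple[list[TaggedRead], ReadQcTally]:
    """Tag every read of a FASTQ file; returns the tagged reads and QC tally."""
    tally = ReadQcTally()
    tagged = list(tag_reads(iter_fastq(path), panel, umi_length,
                            max_primer_mismatches, tally))
    tally.check()
    return tagged, tally
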