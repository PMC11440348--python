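"""Targeted amplicon panel model.

A panel is a small set of short PCR amplicons (an assay each), a catalogue of
hotspot single-nucleotide variants the assays cover, and design constraints on
amplicon size.  Intervals are 0-based half-open internally; the panel file and
all human-readable output use 1-based coordinates.  ``reference_insert`` is
always stored in genomic plus-strand orientation; assays on minus-strand genes
(ALK, HRAS) carry ``strand='-'`` and are translated from the reverse
complement.
"""

from __future__ import annotations

import enum
from pathlib import Path
from typing import Optional

import yaml
from Bio.Seq import Seq
from pydantic import BaseModel, Field, field_validator

VALID_BASES = frozenset("ACGT")


class PanelError(ValueError):
    """Raised when a panel file cannot be parsed or violates an invariant."""


class MutationCategory(str, enum.Enum):
    neuroblastoma_hotspot = "neuroblastoma_hotspot"
    tki_resistance = "tki_resistance"


class HotspotMutation(BaseModel):
    """One catalogued hotspot SNV, e.g. ALK p.R1275Q."""

    hotspot_id: str
    gene: str
    chrom: str
    pos: int = Field(ge=0, description="0-based genomic position")
    ref_base: str
    alt_base: str
    protein_change: str
    category: MutationCategory

    @field_validator("ref_base", "alt_base")
    @classmethod
    def _single_base(cls, v: str) -> str:
        if len(v) != 1 or v not in VALID_BASES:
            raise ValueError(f"expected a single A/C/G/T base, got {v!r}")
        return v

    def model_post_init(self, __context) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError(
                f"hotspot {self.hotspot_id}: ref and alt base are both {self.ref_base}"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt_base)


class PanelAssay(BaseModel):
    """One amplicon assay: primers flanking a target insert.

    ``coding_frame_offset`` is the number of bases of a partial codon at the
    start of the insert *in coding orientation* (None for non-coding targets);
    ``first_codon_number`` is the amino-acid number of the first complete codon,
    giving p.-notation its residue numbers.
    """

    assay_id: str
    chrom: str
    amplicon_start: int = Field(ge=0)
    amplicon_end: int
    target_start: int
    target_end: int
    forward_primer: str
    reverse_primer: str
    reference_insert: str
    strand: str = "+"
    coding_frame_offset: Optional[int] = Field(default=None, ge=0, le=2)
    first_codon_number: Optional[int] = None
    covered_mutations: list[str] = Field(default_factory=list)
    annealing_temp_c: Optional[float] = None  # inert metadata, never validated

    @field_validator("forward_primer", "reverse_primer", "reference_insert")
    @classmethod
    def _dna(cls, v: str) -> str:
        v = v.upper()
        if not set(v) <= VALID_BASES:
            raise ValueError(f"non-ACGT characters in sequence {v!r}")
        return v

    @field_validator("strand")
    @classmethod
    def _strand(cls, v: str) -> str:
        if v not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        return v

    def model_post_init(self, __context) -> None:
        aid = self.assay_id
        if not (self.amplicon_start <= self.target_start
                <= self.target_end <= self.amplicon_end):
            raise ValueError(f"assay {aid}: target interval not nested in amplicon")
        if len(self.reference_insert) != self.target_end - self.target_start:
            raise ValueError(
                f"assay {aid}: reference_insert length "
                f"{len(self.reference_insert)} != target interval "
                f"{self.target_end - self.target_start}"
            )

    @property
    def amplicon_length(self) -> int:
        return self.amplicon_end - self.amplicon_start

    @property
    def target_length(self) -> int:
        return self.target_end - self.target_start

    @property
    def is_coding(self) -> bool:
        return self.coding_frame_offset is not None

    def contains(self, pos: int) -> bool:
        """Whether 0-based genomic ``pos`` lies in the target interval."""
        return self.target_start <= pos < self.target_end


class ConsequenceRecord(BaseModel):
    """Coding consequence of a candidate SNV within one assay."""

    protein_change: Optional[str]
    is_nonsynonymous: bool
    consequence: str  # "missense" | "synonymous" | "nonsense" | "non-coding" | "partial-codon"


class Violation(BaseModel):
    """One panel design-rule violation (returned, never raised)."""

    kind: str
    subject: str
    message: str


class PanelDefinition(BaseModel):
    name: str
    assays: list[PanelAssay]
    hotspots: list[HotspotMutation]
    min_amplicon_bp: int = 75
    max_amplicon_bp: int = 105
    notes: str = ""

    def model_post_init(self, __context) -> None:
        ids = [a.assay_id for a in self.assays]
        if len(set(ids)) != len(ids):
            raise ValueError(f"panel {self.name}: duplicate assay_ids")
        hids = [h.hotspot_id for h in self.hotspots]
        if len(set(hids)) != len(hids):
            raise ValueError(f"panel {self.name}: duplicate hotspot ids")
        keys = [h.key for h in self.hotspots]
        if len(set(keys)) != len(keys):
            raise ValueError(f"panel {self.name}: duplicate (chrom,pos,alt) hotspots")
        seen: dict[str, str] = {}
        for a in self.assays:
            for hid in a.covered_mutations:
                if hid in seen:
                    raise ValueError(
                        f"hotspot {hid} covered by both {seen[hid]} and {a.assay_id}"
                    )
                seen[hid] = a.assay_id
        by_id = {h.hotspot_id: h for h in self.hotspots}
        for a in self.assays:
            for hid in a.covered_mutations:
                h = by_id.get(hid)
                if h is None:
                    raise ValueError(f"assay {a.assay_id} covers unknown hotspot {hid}")
                if h.chrom != a.chrom or not a.contains(h.pos):
                    raise ValueError(
                        f"hotspot {hid} at {h.chrom}:{h.pos + 1} lies outside the "
                        f"target region of assay {a.assay_id}"
                    )
        for h in self.hotspots:
            if h.hotspot_id not in seen:
                raise ValueError(f"hotspot {h.hotspot_id} not covered by any assay")

    # -- lookups -----------------------------------------------------------
    def assay(self, assay_id: str) -> PanelAssay:
        for a in self.assays:
            if a.assay_id == assay_id:
                return a
        raise KeyError(assay_id)

    def hotspot(self, hotspot_id: str) -> HotspotMutation:
        for h in self.hotspots:
            if h.hotspot_id == hotspot_id:
                return h
        raise KeyError(hotspot_id)

    def assay_for_hotspot(self, hotspot_id: str) -> PanelAssay:
        for a in self.assays:
            if hotspot_id in a.covered_mutations:
                return a
        raise KeyError(hotspot_id)

    @property
    def total_target_bp(self) -> int:
        return sum(a.target_length for a in self.assays)


# ---------------------------------------------------------------------------
# Panel file I/O (YAML schema; 1-based inclusive coordinates in the file)
# ---------------------------------------------------------------------------

def load_panel(path: str | Path) -> PanelDefinition:
    """Parse and validate a panel file.

    Raises :class:`PanelError` naming the offending field, assay or hotspot on
    any parse failure or invariant violation.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise PanelError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(doc, dict) or "panel" not in doc:
        raise PanelError(f"{path}: missing top-level 'panel' section")
    meta = doc["panel"]
    try:
        assays = [
            PanelAssay(
                assay_id=a["assay_id"],
                chrom=a["chrom"],
                amplicon_start=int(a["amplicon_start"]) - 1,
                amplicon_end=int(a["amplicon_end"]),
                target_start=int(a["target_start"]) - 1,
                target_end=int(a["target_end"]),
                forward_primer=a["forward_primer"],
                reverse_primer=a["reverse_primer"],
                reference_insert=a["reference_insert"],
                strand=a.get("strand", "+"),
                coding_frame_offset=a.get("coding_frame_offset"),
                first_codon_number=a.get("first_codon_number"),
                covered_mutations=list(a.get("covered_mutations", [])),
                annealing_temp_c=a.get("annealing_temp_c"),
            )
            for a in doc.get("assays", [])
        ]
        hotspots = [
            HotspotMutation(
                hotspot_id=h["hotspot_id"],
                gene=h["gene"],
                chrom=h["chrom"],
                pos=int(h["pos"]) - 1,
                ref_base=h["ref_base"],
                alt_base=h["alt_base"],
                protein_change=h["protein_change"],
                category=h["category"],
            )
            for h in doc.get("hotspots", [])
        ]
        panel = PanelDefinition(
            name=meta["name"],
            assays=assays,
            hotspots=hotspots,
            min_amplicon_bp=meta.get("min_amplicon_bp", 75),
            max_amplicon_bp=meta.get("max_amplicon_bp", 105),
            notes=meta.get("notes", ""),
        )
    except (KeyError, ValueError) as exc:
        raise PanelError(f"{path}: {exc}") from exc
    bad = [v for v in validate_panel(panel) if v.kind == "ref_base_mismatch"]
    if bad:
        raise PanelError(f"{path}: {bad[0].message}")
    return panel


def write_panel(panel: PanelDefinition, path: str | Path) -> None:
    """Serialize a panel back to the YAML schema (round-trips with load_panel)."""
    doc = {
        "panel": {
            "name": panel.name,
            "min_amplicon_bp": panel.min_amplicon_bp,
            "max_amplicon_bp": panel.max_amplicon_bp,
            "notes": panel.notes,
        },
        "assays": [
            {
                "assay_id": a.assay_id,
                "chrom": a.chrom,
                "amplicon_start": a.amplicon_start + 1,
                "amplicon_end": a.amplicon_end,
                "target_start": a.target_start + 1,
                "target_end": a.target_end,
                "forward_primer": a.forward_primer,
                "reverse_primer": a.reverse_primer,
                "reference_insert": a.reference_insert,
                "strand": a.strand,
                "coding_frame_offset": a.coding_frame_offset,
                "first_codon_number": a.first_codon_number,
                "covered_mutations": list(a.covered_mutations),
                "annealing_temp_c": a.annealing_temp_c,
            }
            for a in panel.assays
        ],
        "hotspots": [
            {
                "hotspot_id": h.hotspot_id,
                "gene": h.gene,
                "chrom": h.chrom,
                "pos": h.pos + 1,
                "ref_base": h.ref_base,
                "alt_base": h.alt_base,
                "protein_change": h.protein_change,
                "category": h.category.value,
            }
            for h in panel.hotspots
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def validate_panel(panel: PanelDefinition) -> list[Violation]:
    """Check design rules; returns violations instead of raising.

    Empty iff every amplicon length lies within the design constraints and
    every covered hotspot's ref_base matches the reference insert.
    """
    out: list[Violation] = []
    for a in panel.assays:
        n = a.amplicon_length
        if not (panel.min_amplicon_bp <= n <= panel.max_amplicon_bp):
            out.append(Violation(
                kind="amplicon_size",
                subject=a.assay_id,
                message=(f"assay {a.assay_id}: amplicon length {n} outside "
                         f"[{panel.min_amplicon_bp}, {panel.max_amplicon_bp}]"),
            ))
    for a in panel.assays:
        for hid in a.covered_mutations:
            h = panel.hotspot(hid)
            ref = a.reference_insert[h.pos - a.target_start]
            if ref != h.ref_base:
                out.append(Violation(
                    kind="ref_base_mismatch",
                    subject=hid,
                    message=(f"hotspot {hid}: ref_base {h.ref_base} but reference "
                             f"insert of {a.assay_id} has {ref} at "
                             f"{h.chrom}:{h.pos + 1}"),
                ))
    return out


# ---------------------------------------------------------------------------
# Coding-consequence annotation
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def annotate_variant(assay: PanelAssay, pos: int, ref_base: str,
                     alt_base: str) -> ConsequenceRecord:
    """Coding consequence of a single-base substitution at 0-based ``pos``.

    Translates the reference and alternate codons under the standard genetic
    code, honouring the assay strand.  Non-coding assays yield a "non-coding"
    record; a variant whose codon is only partially inside the insert yields
    "partial-codon" (never called nonsynonymous).
    """
    if not assay.contains(pos):
        raise ValueError(
            f"position {assay.chrom}:{pos + 1} outside target region of "
            f"assay {assay.assay_id}"
        )
    offset = pos - assay.target_start
    if assay.reference_insert[offset] != ref_base:
        raise ValueError(
            f"ref base {ref_base} does not match reference insert "
            f"({assay.reference_insert[offset]}) at {assay.chrom}:{pos + 1}"
        )
    if not assay.is_coding:
        return ConsequenceRecord(protein_change=None, is_nonsynonymous=False,
                                 consequence="non-coding")

    if assay.strand == "+":
        coding = assay.reference_insert
        cidx = offset
        alt_coding_base = alt_base
    else:
        coding = str(Seq(assay.reference_insert).reverse_complement())
        cidx = assay.target_length - 1 - offset
        alt_coding_base = alt_base.translate(_COMPLEMENT)

    skip = assay.coding_frame_offset or 0
    if cidx < skip:
        return ConsequenceRecord(protein_change=None, is_nonsynonymous=False,
                                 consequence="partial-codon")
    codon_idx, within = divmod(cidx - skip, 3)
    start = skip + 3 * codon_idx
    if start + 3 > len(coding):
        return ConsequenceRecord(protein_change=None, is_nonsynonymous=False,
                                 consequence="partial-codon")
    ref_codon = coding[start:start + 3]
    alt_codon = ref_codon[:within] + alt_coding_base + ref_codon[within + 1:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    residue = (assay.first_codon_number or 1) + codon_idx
    if ref_aa == alt_aa:
        return ConsequenceRecord(
            protein_change=f"p.{ref_aa}{residue}{alt_aa}",
            is_nonsynonymous=False, consequence="synonymous")
    consequence = "nonsense" if alt_aa == "*" else "missense"
    return ConsequenceRecord(
        protein_change=f"p.{ref_aa}{residue}{alt_aa}",
        is_nonsynonymous=True, consequence=consequence)


def bundled_panel_path(name: str) -> Path:
    """Path of a panel file shipped with the package ('nb_alk' or 'hras_q61')."""
    p = Path(__file__).parent / "data" / f"{name}_panel.yaml"
    if not p.exists():
        raise FileNotFoundError(p)
    return p
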