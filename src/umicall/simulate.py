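"""Synthetic UMI-tagged amplicon reads with ground truth.

Emulates a two-step barcoded-PCR (SiMSen-seq style) library: every original
cfDNA molecule receives a random UMI, is assigned mutant/wild-type status per
hotspot by a Bernoulli draw at the true VAF, and is then "amplified" into a
UMI family of reads.  Errors come in two tiers:

* **early** errors strike the molecule's first copy once, so every read of the
  family inherits them — UMI consensus cannot remove these;
* **late** errors strike each read independently (later PCR cycles and the
  sequencer) — these are what consensus building suppresses.

Each read is laid out 5'→3' as ``[UMI][forward primer][insert][revcomp of
reverse primer]``, truncated at ``read_length``.  All randomness flows from a
single seed; output is byte-identical across runs.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .panel import PanelAssay, PanelDefinition

BASES = np.frombuffer(b"ACGT", dtype="S1")
_IDX = {b: i for i, b in enumerate("ACGT")}


class FamilySizeDistribution(BaseModel):
    """Named distribution of reads per UMI family, truncated at >= 1.

    ``negative_binomial`` uses (mean, dispersion): dispersion is the shape
    parameter n of numpy's negative_binomial, p = n / (n + mean).  ``fixed``
    emits exactly ``mean`` reads per molecule.
    """

    name: str = "negative_binomial"
    mean: float = 8.0
    dispersion: float = 2.0

    @model_validator(mode="after")
    def _check(self):
        if self.name not in ("negative_binomial", "fixed"):
            raise ValueError(f"unknown family size distribution {self.name!r}")
        if self.mean < 1:
            raise ValueError("family size mean must be >= 1")
        return self

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.name == "fixed":
            return np.full(n, int(round(self.mean)), dtype=np.int64)
        p = self.dispersion / (self.dispersion + self.mean)
        out = rng.negative_binomial(self.dispersion, p, size=n)
        # truncation at >=1: redraw zeros
        while True:
            zeros = out == 0
            if not zeros.any():
                return out
            out[zeros] = rng.negative_binomial(self.dispersion, p, size=int(zeros.sum()))


class SimulationParams(BaseModel):
    molecules_per_assay: int = Field(ge=1)
    vaf_by_hotspot: dict[str, float] = Field(default_factory=dict)
    umi_length: int = Field(default=12, ge=6)
    family_size_distribution: FamilySizeDistribution = Field(
        default_factory=FamilySizeDistribution)
    early_error_rate: float = Field(default=0.0, ge=0.0, lt=1.0)
    late_error_rate: float = Field(default=0.0, ge=0.0, lt=1.0)
    read_length: int = 150
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        for hid, v in self.vaf_by_hotspot.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"VAF for {hid} outside [0, 1]: {v}")
        return self


@dataclass
class MoleculeRecord:
    """Ground truth for one original cfDNA molecule."""

    assay_id: str
    umi: str
    mutant_hotspots: list[str]
    early_errors: list[tuple[int, str]]  # (insert offset, substituted base)
    n_reads: int


@dataclass
class TruthManifest:
    """Per-molecule ground truth of one simulated sample."""

    sample_id: str
    molecules: dict[str, list[MoleculeRecord]] = field(default_factory=dict)

    def reads_per_assay(self, assay_id: str) -> int:
        return sum(m.n_reads for m in self.molecules.get(assay_id, []))

    def mutant_molecules(self, hotspot_id: str) -> int:
        return sum(
            1 for recs in self.molecules.values() for m in recs
            if hotspot_id in m.mutant_hotspots
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("assay_id\tumi\tmutant_hotspots\tearly_errors\tn_reads\n")
            for recs in self.molecules.values():
                for m in recs:
                    errs = ",".join(f"{o}:{b}" for o, b in m.early_errors)
                    fh.write(f"{m.assay_id}\t{m.umi}\t"
                             f"{','.join(m.mutant_hotspots)}\t{errs}\t{m.n_reads}\n")


@dataclass
class FastqRecord:
    read_id: str
    sequence: str
    quality: str

    def format(self) -> str:
        return f"@{self.read_id}\n{self.sequence}\n+\n{self.quality}\n"


def _random_substitution(rng: np.random.Generator, base: str) -> str:
    """A uniformly random base different from ``base``."""
    alternatives = "ACGT".replace(base, "")
    return alternatives[rng.integers(3)]


def _apply_late_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0.0:
        return seq
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    positions = rng.choice(len(seq), size=k, replace=False)
    chars = list(seq)
    for p in sorted(positions):
        chars[p] = _random_substitution(rng, chars[p])
    return "".join(chars)


def _check_read_length(panel: PanelDefinition, params: SimulationParams) -> None:
    for a in panel.assays:
        need = params.umi_length + len(a.forward_primer) + a.target_length
        if params.read_length < need:
            raise ValueError(
                f"read_length {params.read_length} too short for assay "
                f"{a.assay_id} layout (needs >= {need})"
            )


def _molecule_insert(assay: PanelAssay, mutant_hotspots: list[str],
                     panel: PanelDefinition,
                     early_errors: list[tuple[int, str]]) -> str:
    ins = list(assay.reference_insert)
    for hid in mutant_hotspots:
        h = panel.hotspot(hid)
        ins[h.pos - assay.target_start] = h.alt_base
    for off, base in early_errors:
        ins[off] = base
    return "".join(ins)


def simulate_sample(panel: PanelDefinition, params: SimulationParams,
                    sample_id: str = "sample") -> tuple[list[FastqRecord], TruthManifest]:
    """Simulate one sample across all panel assays.

    Returns FASTQ records (constant placeholder base quality) and the
    molecule-level :class:`TruthManifest`.  Deterministic given
    ``params.seed``.
    """
    for hid in params.vaf_by_hotspot:
        panel.hotspot(hid)  # KeyError -> unknown hotspot
    _check_read_length(panel, params)

    rng = np.random.default_rng(params.seed)
    manifest = TruthManifest(sample_id=sample_id)
    reads: list[FastqRecord] = []

    for assay in panel.assays:
        n = params.molecules_per_assay
        hotspot_ids = [hid for hid in assay.covered_mutations
                       if params.vaf_by_hotspot.get(hid, 0.0) > 0.0]
        # per-molecule draws, vectorised
        umi_mat = rng.integers(0, 4, size=(n, params.umi_length))
        umis = ["".join("ACGT"[b] for b in row) for row in umi_mat]
        mutant = {
            hid: rng.random(n) < params.vaf_by_hotspot[hid] for hid in hotspot_ids
        }
        sizes = params.family_size_distribution.sample(rng, n)
        ins_len = assay.target_length
        n_early = (rng.binomial(ins_len, params.early_error_rate, size=n)
                   if params.early_error_rate > 0 else np.zeros(n, dtype=int))

        records = []
        for i in range(n):
            muts = [hid for hid in hotspot_ids if mutant[hid][i]]
            early: list[tuple[int, str]] = []
            if n_early[i]:
                offs = rng.choice(ins_len, size=int(n_early[i]), replace=False)
                for off in sorted(int(o) for o in offs):
                    ref = assay.reference_insert[off]
                    early.append((off, _random_substitution(rng, ref)))
            rec = MoleculeRecord(assay.assay_id, umis[i], muts, early,
                                 int(sizes[i]))
            records.append(rec)
            insert = _molecule_insert(assay, muts, panel, early)
            template = (rec.umi + assay.forward_primer + insert
                        + _revcomp(assay.reverse_primer))[: params.read_length]
            qual = "I" * len(template)
            if params.late_error_rate > 0:
                for j in range(rec.n_reads):
                    seq = _apply_late_errors(rng, template, params.late_error_rate)
                    reads.append(FastqRecord(
                        f"{sample_id}.{assay.assay_id}.m{i}.r{j}", seq, qual))
            else:
                for j in range(rec.n_reads):
                    reads.append(FastqRecord(
                        f"{sample_id}.{assay.assay_id}.m{i}.r{j}", template, qual))
        manifest.molecules[assay.assay_id] = records

    return reads, manifest


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def write_fastq(reads: Iterable[FastqRecord], path: str | Path) -> None:
    """Write standard 4-line FASTQ; gzip if the path ends in .gz."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for r in reads:
            fh.write(r.format())


def simulate_timecourse(
    panel: PanelDefinition,
    schedule: list[tuple[Date, SimulationParams]],
    master_seed: Optional[int] = None,
    sample_prefix: str = "s",
) -> list[tuple[str, Date, list[FastqRecord], TruthManifest]]:
    """Simulate a longitudinal series of samples, one per schedule entry.

    Dates must be strictly increasing.  Each sample's seed is derived
    deterministically from ``master_seed`` (default: the first entry's seed)
    and the sample index.
    """
    if not schedule:
        return []
    dates = [d for d, _ in schedule]
    for a, b in zip(dates, dates[1:]):
        if b <= a:
            raise ValueError(f"schedule dates not strictly increasing: {a} !< {b}")
    if master_seed is None:
        master_seed = schedule[0][1].seed
    out = []
    for idx, (date, params) in enumerate(schedule):
        sub_seed = int(np.random.SeedSequence(
            entropy=master_seed, spawn_key=(idx,)).generate_state(1)[0] % (2**31))
        p = params.model_copy(update={"seed": sub_seed})
        sample_id = f"{sample_prefix}{idx:02d}"
        reads, manifest = simulate_sample(panel, p, sample_id=sample_id)
        out.append((sample_id, date, reads, manifest))
    return out
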