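"""VCF 4.2 serialization of per-sample calls (pysam-backed).

Positions are 1-based in the file (0-based internally); contig headers come
from the panel.  One record per called variant: tracked hotspots with at
least one mutant consensus read, and secondary-screen candidates.
"""

from __future__ import annotations

from pathlib import Path

import pysam

from .calling import SampleCall
from .panel import PanelDefinition

_INFO_LINES = [
    ('MC', '1', 'Integer', 'Mutant consensus read (molecule) count'),
    ('DP', '1', 'Integer', 'Total consensus depth at the position'),
    ('VAF_PCT', '1', 'Float', 'Variant allele frequency, percent of consensus reads'),
    ('LOD_PCT', '1', 'Float', 'Per-sample limit of detection, percent (100/DP)'),
    ('PCHANGE', '1', 'String', 'Protein change (HGVS p. notation)'),
    ('HOTSPOT', '1', 'String', 'Catalogued hotspot id (tracked variants)'),
    ('VARCLASS', '1', 'String', 'tracked_hotspot or secondary_candidate'),
]


def _build_header(panel: PanelDefinition, sample_id: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    contigs = {}
    for a in panel.assays:
        contigs[a.chrom] = max(contigs.get(a.chrom, 0), a.amplicon_end + 1000)
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    for name, number, vtype, desc in _INFO_LINES:
        header.info.add(name, number, vtype, desc)
    header.add_meta('umicall_sample', sample_id)
    header.add_meta('umicall_panel', panel.name)
    return header


def write_vcf(call: SampleCall, panel: PanelDefinition,
              path: str | Path) -> None:
    """Write one sample's called variants as a sites-only VCF 4.2 file."""
    header = _build_header(panel, call.sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        records = []
        for r in call.hotspot_results:
            if not r.is_positive:
                continue
            h = panel.hotspot(r.hotspot_id)
            records.append((
                h.chrom, h.pos, h.ref_base, h.alt_base,
                dict(MC=r.mutant_consensus_count, DP=r.total_consensus_depth,
                     VAF_PCT=round(100.0 * r.vaf, 4), LOD_PCT=r.lod_percent,
                     PCHANGE=h.protein_change, HOTSPOT=h.hotspot_id,
                     VARCLASS='tracked_hotspot'),
            ))
        for v in call.secondary_variants:
            assay = panel.assay(v.assay_id)
            records.append((
                assay.chrom, v.pos, v.ref_base, v.alt_base,
                dict(MC=v.alt_count, DP=v.depth,
                     VAF_PCT=round(100.0 * v.af, 4),
                     PCHANGE=v.protein_change or '.',
                     VARCLASS='secondary_candidate'),
            ))
        records.sort(key=lambda r: (r[0], r[1], r[3]))
        for chrom, pos, ref, alt, info in records:
            rec = vcf.new_record(contig=chrom, start=pos, stop=pos + 1,
                                 alleles=(ref, alt))
            for k, val in info.items():
                rec.info[k] = val
            vcf.write(rec)


def read_vcf(path: str | Path) -> list[dict]:
    """Parse a VCF written by :func:`write_vcf` back to plain records."""
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            out.append({
                'chrom': rec.chrom,
                'pos': rec.start,  # back to 0-based
                'ref': rec.ref,
                'alt': rec.alts[0],
                'mutant_count': rec.info['MC'],
                'depth': rec.info['DP'],
                'vaf_pct': float(rec.info['VAF_PCT']),
                'lod_pct': (float(rec.info['LOD_PCT'])
                            if 'LOD_PCT' in rec.info else None),
                'protein_change': rec.info.get('PCHANGE'),
                'varclass': rec.info.get('VARCLASS'),
            })
    return out
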