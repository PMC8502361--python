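"""File formats: phased VCF 4.2 (pysam), and the TSV dialects used by the
pipeline.

TSV columns, documented once here:

* barcode table:   barcode, chrom, pos, allele (REF/ALT base), snp_index
* plasma counts:   chrom, pos, ref_count, alt_count
* genetic map:     chrom, pos, cM
* block stats:     block_id, chrom, start, end, n_snps, length_bp
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import pysam

from .genetic_map import GeneticMap
from .types import (
    BarcodeObservationTable,
    Diplotype,
    PhaseBlock,
    PlasmaCounts,
    SNPMarker,
    SnpPanel,
)


# ---------------------------------------------------------------------------
# VCF

def write_parents_vcf(
    path: str | Path,
    panel: SnpPanel,
    mother: Diplotype,
    father: Diplotype,
    phase_set: int = 1,
) -> None:
    """Write both parents as a phased VCF 4.2 with GT (pipe separator for
    phased samples) and PS phase-set tags."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">')
    header.add_line('##INFO=<ID=PATHO,Number=0,Type=Flag,Description="Pathogenic variant site">')
    header.contigs.add(panel.chrom)
    header.add_sample(mother.sample_id)
    header.add_sample(father.sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i, m in enumerate(panel.markers):
            rec = vcf.new_record(
                contig=m.chrom, start=m.pos - 1, stop=m.pos,
                alleles=(m.ref_allele, m.alt_allele),
            )
            if m.is_pathogenic:
                rec.info["PATHO"] = True
            for dip, sample in ((mother, mother.sample_id), (father, father.sample_id)):
                rec.samples[sample]["GT"] = (int(dip.hap1[i]), int(dip.hap2[i]))
                rec.samples[sample].phased = dip.phased
                if dip.phased:
                    rec.samples[sample]["PS"] = phase_set
            vcf.write(rec)


def read_parents_vcf(path: str | Path) -> tuple[SnpPanel, Diplotype, Diplotype]:
    """Read a two-sample VCF back into a panel and two diplotypes.

    Phasing is taken from the GT separator; the PATHO info flag marks
    pathogenic sites.  The first sample is the mother, the second the
    father.
    """
    markers: list[SNPMarker] = []
    gts: dict[str, list[tuple[int, int]]] = {}
    phased: dict[str, bool] = {}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 2:
            raise ValueError("expected exactly two samples (mother, father)")
        for s in samples:
            gts[s] = []
            phased[s] = True
        for rec in vcf:
            markers.append(
                SNPMarker(rec.chrom, rec.pos, rec.ref, rec.alts[0],
                          is_pathogenic="PATHO" in rec.info)
            )
            for s in samples:
                call = rec.samples[s]
                g = call["GT"]
                gts[s].append((g[0], g[1]))
                phased[s] = phased[s] and bool(call.phased)
    panel = SnpPanel(markers)
    dips = []
    for s in samples:
        arr = np.array(gts[s], dtype=np.int8)
        dip = Diplotype(s, arr[:, 0], arr[:, 1], phased=phased[s])
        patho = [i for i in panel.pathogenic_indices if dip.is_het(i)]
        if phased[s] and patho:
            i = patho[0]
            dip.pathogenic_hap = 1 if dip.hap1[i] == 1 else 2
        dips.append(dip)
    return panel, dips[0], dips[1]


# ---------------------------------------------------------------------------
# TSV dialects

def write_barcode_table(path: str | Path, obs: BarcodeObservationTable, panel: SnpPanel) -> None:
    df = pd.DataFrame(
        {
            "barcode": obs.barcode,
            "chrom": panel.chrom,
            "pos": panel.positions[obs.snp_index],
            "allele": [
                panel[i].alt_allele if a == 1 else panel[i].ref_allele
                for i, a in zip(obs.snp_index, obs.allele)
            ],
            "snp_index": obs.snp_index,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_barcode_table(path: str | Path, panel: SnpPanel) -> BarcodeObservationTable:
    df = pd.read_csv(path, sep="\t")
    snp_index = df["snp_index"].to_numpy(dtype=np.int64) if "snp_index" in df else np.array(
        [panel.index_of(p) for p in df["pos"]], dtype=np.int64
    )
    allele = np.array(
        [1 if a == panel[i].alt_allele else 0 for i, a in zip(snp_index, df["allele"])],
        dtype=np.int8,
    )
    return BarcodeObservationTable(df["barcode"].to_numpy(dtype=np.int64), snp_index, allele)


def write_plasma_counts(path: str | Path, counts: PlasmaCounts, panel: SnpPanel) -> None:
    pd.DataFrame(
        {
            "chrom": panel.chrom,
            "pos": panel.positions,
            "ref_count": counts.ref_count,
            "alt_count": counts.alt_count,
        }
    ).to_csv(path, sep="\t", index=False)


def read_plasma_counts(path: str | Path, panel: SnpPanel) -> PlasmaCounts:
    df = pd.read_csv(path, sep="\t")
    by_pos = {int(p): (int(r), int(a)) for p, r, a in zip(df["pos"], df["ref_count"], df["alt_count"])}
    ref = np.array([by_pos.get(int(p), (0, 0))[0] for p in panel.positions], dtype=np.int64)
    alt = np.array([by_pos.get(int(p), (0, 0))[1] for p in panel.positions], dtype=np.int64)
    return PlasmaCounts(ref, alt)


def write_genetic_map(path: str | Path, gmap: GeneticMap, chrom: str) -> None:
    pd.DataFrame({"chrom": chrom, "pos": gmap.bp.astype(np.int64), "cM": gmap.cm}).to_csv(
        path, sep="\t", index=False
    )


def read_genetic_map(path: str | Path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    return GeneticMap(df["pos"].to_numpy(), df["cM"].to_numpy())


def write_block_stats(path: str | Path, blocks: list[PhaseBlock]) -> None:
    pd.DataFrame(
        {
            "block_id": [b.block_id for b in blocks],
            "chrom": [b.chrom for b in blocks],
            "start": [b.start for b in blocks],
            "end": [b.end for b in blocks],
            "n_snps": [b.n_snps for b in blocks],
            "length_bp": [b.length for b in blocks],
        }
    ).to_csv(path, sep="\t", index=False)


def write_phased_vcf(
    path: str | Path,
    panel: SnpPanel,
    blocks: list[PhaseBlock],
    sample_id: str,
    genotypes: Optional[Diplotype] = None,
) -> None:
    """Write one parent's assembled phase blocks as a phased VCF with PS
    set to each block's start position; unphased het sites fall back to
    '/' genotypes from ``genotypes``."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">')
    header.contigs.add(panel.chrom)
    header.add_sample(sample_id)
    in_block: dict[int, tuple[int, int]] = {}  # snp index -> (hap1 allele, block start)
    for b in blocks:
        for s, a1 in zip(b.snp_indices, b.hap1_alleles):
            in_block[int(s)] = (int(a1), b.start)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i, m in enumerate(panel.markers):
            rec = vcf.new_record(contig=m.chrom, start=m.pos - 1, stop=m.pos,
                                 alleles=(m.ref_allele, m.alt_allele))
            call = rec.samples[sample_id]
            if i in in_block:
                a1, ps = in_block[i]
                call["GT"] = (a1, 1 - a1)
                call.phased = True
                call["PS"] = ps
            elif genotypes is not None:
                call["GT"] = (int(genotypes.hap1[i]), int(genotypes.hap2[i]))
                call.phased = False
            else:
                call["GT"] = (None, None)
            vcf.write(rec)
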