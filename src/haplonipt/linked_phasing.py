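"""Phase-block assembly from barcode-allele co-occurrence.

Short fragments sharing a partition barcode are treated as coming from the
same long molecule, so the alleles they show at two heterozygous sites are
evidence for the relative phase of those sites: both-alt or both-ref
observations support the alt alleles being on the same haplotype (cis),
mixed observations the opposite (trans).  Blocks are assembled greedily
left to right, linked by overlapping SNPs, and finally anchored at the
pathogenic variant to label the pathogenic (P) and normal (N) haplotypes.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Optional

import numpy as np

from .types import (
    ALT,
    BarcodeObservationTable,
    Diplotype,
    HaplotypePair,
    MISSING,
    PhaseBlock,
    PhaseBlockStats,
    REF,
    SnpPanel,
)

logger = logging.getLogger(__name__)

#: ignore SNP pairs further apart than this when accumulating evidence;
#: molecules rarely link sites beyond a few molecule lengths
DEFAULT_MAX_PAIR_DIST = 500_000


def build_allele_barcode_graph(
    obs: BarcodeObservationTable,
    het_indices: Iterable[int],
    panel: Optional[SnpPanel] = None,
    max_pair_dist: Optional[int] = DEFAULT_MAX_PAIR_DIST,
) -> dict[tuple[int, int], tuple[int, int]]:
    """Pairwise phasing evidence between heterozygous sites.

    Returns ``{(i, j): (cis_support, trans_support)}`` for i < j, where
    cis counts barcodes observing equal alleles at the two sites and trans
    barcodes observing opposite alleles.  Within one barcode, conflicting
    observations at the same SNP are resolved by majority (ties dropped).
    ``max_pair_dist`` (bp, needs ``panel``) limits pairing range; pass
    ``None`` for all pairs.
    """
    if len(obs) == 0:
        raise ValueError("empty observation table")
    het = set(int(i) for i in het_indices)
    positions = panel.positions if panel is not None else None

    # per barcode: consensus allele per het SNP
    by_barcode: dict[int, dict[int, list[int]]] = defaultdict(lambda: defaultdict(list))
    for bc, si, al in zip(obs.barcode, obs.snp_index, obs.allele):
        if int(si) in het:
            by_barcode[int(bc)][int(si)].append(int(al))

    evidence: dict[tuple[int, int], list[int]] = defaultdict(lambda: [0, 0])
    for snp_alleles in by_barcode.values():
        consensus = {}
        for si, alleles in snp_alleles.items():
            n_alt = sum(alleles)
            n_ref = len(alleles) - n_alt
            if n_alt != n_ref:
                consensus[si] = ALT if n_alt > n_ref else REF
        sites = sorted(consensus)
        for a in range(len(sites)):
            for b in range(a + 1, len(sites)):
                i, j = sites[a], sites[b]
                if (
                    max_pair_dist is not None
                    and positions is not None
                    and positions[j] - positions[i] > max_pair_dist
                ):
                    break
                if consensus[i] == consensus[j]:
                    evidence[(i, j)][0] += 1
                else:
                    evidence[(i, j)][1] += 1
    return {k: (v[0], v[1]) for k, v in evidence.items()}


def assemble_phase_blocks(
    evidence: dict[tuple[int, int], tuple[int, int]],
    het_indices: Iterable[int],
    panel: SnpPanel,
    min_support: int = 2,
    min_margin: int = 2,
) -> list[PhaseBlock]:
    """Greedy left-to-right 2-coloring of het sites into phase blocks.

    A site joins the current block when its net evidence against the
    already-phased members (|cis-weighted - trans-weighted|) reaches
    ``min_margin`` with total support >= ``min_support``; otherwise it
    starts a new block.  Orientation (+1: alt on haplotype 1) is the one
    maximising agreement; a tie defers to the nearest upstream phased SNP,
    then defaults to +1.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    order = sorted(int(i) for i in het_indices)
    blocks: list[PhaseBlock] = []
    cur: list[int] = []  # member snp indices
    cur_phase: dict[int, int] = {}  # snp -> +1 (alt on hap1) / -1
    cur_support: dict[int, int] = {}

    def flush() -> None:
        if not cur:
            return
        idx = np.array(cur, dtype=np.int64)
        hap1 = np.array([ALT if cur_phase[i] > 0 else REF for i in cur], dtype=np.int8)
        blocks.append(
            PhaseBlock(
                block_id=len(blocks),
                chrom=panel.chrom,
                start=int(panel.positions[idx[0]]),
                end=int(panel.positions[idx[-1]]),
                snp_indices=idx,
                positions=panel.positions[idx].copy(),
                hap1_alleles=hap1,
                hap2_alleles=(1 - hap1).astype(np.int8),
                support=np.array([cur_support[i] for i in cur], dtype=np.int64),
            )
        )

    for j in order:
        if not cur:
            cur = [j]
            cur_phase = {j: +1}
            cur_support = {j: 0}
            continue
        net = 0  # >0: same orientation as block's hap1 coloring
        total = 0
        nearest = None  # evidence sign vs nearest upstream phased member
        for i in reversed(cur):
            pair = evidence.get((i, j)) or evidence.get((j, i))
            if pair is None:
                continue
            cis, trans = pair
            contrib = cur_phase[i] * (cis - trans)
            net += contrib
            total += cis + trans
            if nearest is None and contrib != 0:
                nearest = 1 if contrib > 0 else -1
        if total >= min_support and abs(net) >= min_margin and net != 0:
            orient = 1 if net > 0 else -1
        elif total >= min_support and min_margin == 0 and net == 0 and nearest is not None:
            orient = nearest  # tie: defer to the nearest upstream phased SNP
        else:
            orient = None
        if orient is None:
            flush()
            cur = [j]
            cur_phase = {j: +1}
            cur_support = {j: 0}
        else:
            cur.append(j)
            cur_phase[j] = orient
            cur_support[j] = total
    flush()
    return blocks


def merge_blocks_by_overlap(
    blocks_a: list[PhaseBlock],
    blocks_b: list[PhaseBlock],
    min_shared_snps: int = 2,
) -> list[PhaseBlock]:
    """Link blocks from two assemblies via their overlapping phased SNPs.

    Blocks sharing at least ``min_shared_snps`` het SNPs are merged when
    the shared sites vote a consistent relative orientation (majority);
    an exact 50:50 split leaves the blocks unmerged with a warning.
    Returns a consolidated, non-overlapping block list.
    """
    # union-find over all blocks, with a relative orientation per member
    blocks = list(blocks_a) + list(blocks_b)
    parent = list(range(len(blocks)))
    orient = [1] * len(blocks)  # orientation relative to the component root

    def find(x: int) -> tuple[int, int]:
        o = 1
        while parent[x] != x:
            o *= orient[x]
            x = parent[x]
        return x, o

    site_alleles = []
    for b in blocks:
        site_alleles.append({int(s): int(a) for s, a in zip(b.snp_indices, b.hap1_alleles)})

    for ia in range(len(blocks)):
        for ib in range(ia + 1, len(blocks)):
            shared = site_alleles[ia].keys() & site_alleles[ib].keys()
            if len(shared) < min_shared_snps:
                continue
            same = sum(1 for s in shared if site_alleles[ia][s] == site_alleles[ib][s])
            diff = len(shared) - same
            if same == diff:
                logger.warning(
                    "blocks %d/%d share %d SNPs with contradictory orientation; not merged",
                    blocks[ia].block_id, blocks[ib].block_id, len(shared),
                )
                continue
            rel = 1 if same > diff else -1
            ra, oa = find(ia)
            rb, ob = find(ib)
            if ra != rb:
                parent[rb] = ra
                orient[rb] = oa * rel * ob

    merged: dict[int, dict[int, tuple[int, int]]] = defaultdict(dict)  # root -> snp -> (allele, support)
    chrom = blocks[0].chrom if blocks else ""
    for i, b in enumerate(blocks):
        root, o = find(i)
        for s, a, sup in zip(b.snp_indices, b.hap1_alleles, b.support):
            allele = int(a) if o > 0 else 1 - int(a)
            prev = merged[root].get(int(s))
            if prev is None or sup > prev[1]:
                merged[root][int(s)] = (allele, int(sup))

    pos_of: dict[int, int] = {}
    for b in blocks:
        for s, p in zip(b.snp_indices, b.positions):
            pos_of[int(s)] = int(p)

    out: list[PhaseBlock] = []
    for root in sorted(merged, key=lambda r: min(merged[r])):
        sites = sorted(merged[root])
        idx = np.array(sites, dtype=np.int64)
        hap1 = np.array([merged[root][s][0] for s in sites], dtype=np.int8)
        sup = np.array([merged[root][s][1] for s in sites], dtype=np.int64)
        out.append(
            PhaseBlock(
                block_id=len(out),
                chrom=chrom,
                start=pos_of[sites[0]],
                end=pos_of[sites[-1]],
                snp_indices=idx,
                positions=np.array([pos_of[s] for s in sites], dtype=np.int64),
                hap1_alleles=hap1,
                hap2_alleles=(1 - hap1).astype(np.int8),
                support=sup,
            )
        )
    return out


def anchor_pathogenic_variant(
    blocks: list[PhaseBlock],
    panel: SnpPanel,
    variant_pos: int,
    parent_id: str,
    diplotype_hom_fill: Optional[Diplotype] = None,
) -> HaplotypePair:
    """Label the P (pathogenic) and N (normal) haplotypes of one parent.

    The block containing the pathogenic site determines the assignment:
    the haplotype carrying the alternate (disease) allele there becomes P.
    If no block covers the site, phasing failed for this parent and
    ``covered`` is False — downstream analysis is skipped, as for real
    samples whose anchoring block misses the variant.  Homozygous sites can
    be filled in from an (unphased) genotype source via
    ``diplotype_hom_fill``.
    """
    vi = panel.index_of(variant_pos)
    n = len(panel)
    p_allele = np.full(n, MISSING, dtype=np.int8)
    n_allele = np.full(n, MISSING, dtype=np.int8)

    anchor = None
    for b in blocks:
        # a singleton block carries no linkage: it cannot anchor
        if b.n_snps >= 2 and vi in set(int(s) for s in b.snp_indices):
            anchor = b
            break
    covered = anchor is not None
    if covered:
        member = {int(s): k for k, s in enumerate(anchor.snp_indices)}
        k = member[vi]
        if anchor.hap1_alleles[k] == anchor.hap2_alleles[k]:
            raise ValueError("pathogenic site is homozygous; carrier parents must be het")
        # P = the haplotype carrying the alt (variant) allele at the anchor site
        p_is_hap1 = anchor.hap1_alleles[k] == ALT
        for s, a1, a2 in zip(anchor.snp_indices, anchor.hap1_alleles, anchor.hap2_alleles):
            p_allele[int(s)] = a1 if p_is_hap1 else a2
            n_allele[int(s)] = a2 if p_is_hap1 else a1
    if diplotype_hom_fill is not None:
        hom = ~diplotype_hom_fill.het_mask
        p_allele[hom] = diplotype_hom_fill.hap1[hom]
        n_allele[hom] = diplotype_hom_fill.hap1[hom]
    return HaplotypePair(parent_id, p_allele, n_allele, covered)


def haplotype_pair_from_diplotype(dip: Diplotype, parent_id: str) -> HaplotypePair:
    """P/N haplotypes straight from a phased diplotype with a known
    pathogenic haplotype (the phased-VCF bypass)."""
    if not dip.phased or dip.pathogenic_hap is None:
        raise ValueError("need a phased diplotype with pathogenic_hap set")
    p = dip.hap(dip.pathogenic_hap).copy()
    nn = dip.hap(3 - dip.pathogenic_hap).copy()
    return HaplotypePair(parent_id, p, nn, covered=True)


def phase_block_stats(
    blocks: list[PhaseBlock],
    gene_interval: Optional[tuple[int, int]] = None,
) -> PhaseBlockStats:
    """N50 / longest-block statistics, plus the SNP count of the block
    spanning the gene interval (0 if none does)."""
    if not blocks:
        raise ValueError("no blocks")
    lengths = sorted((b.length for b in blocks), reverse=True)
    total = sum(lengths)
    acc = 0
    n50 = lengths[0]
    for L in lengths:
        acc += L
        if acc >= total / 2:
            n50 = L
            break
    anchor_snps = 0
    if gene_interval is not None:
        for b in blocks:
            if b.spans(*gene_interval):
                anchor_snps = max(anchor_snps, b.n_snps)
    return PhaseBlockStats(
        n50_length=n50,
        longest_block=lengths[0],
        total_blocks=len(blocks),
        snps_in_anchor_block=anchor_snps,
    )


def phase_parent(
    obs: BarcodeObservationTable,
    genotypes: Diplotype,
    panel: SnpPanel,
    variant_pos: int,
    parent_id: str,
    min_support: int = 2,
    min_margin: int = 2,
    max_pair_dist: Optional[int] = DEFAULT_MAX_PAIR_DIST,
) -> tuple[HaplotypePair, list[PhaseBlock]]:
    """Convenience wrapper: evidence graph -> blocks -> anchored P/N pair."""
    het = np.flatnonzero(genotypes.het_mask)
    evidence = build_allele_barcode_graph(obs, het, panel, max_pair_dist)
    blocks = assemble_phase_blocks(evidence, het, panel, min_support, min_margin)
    pair = anchor_pathogenic_variant(blocks, panel, variant_pos, parent_id, genotypes)
    return pair, blocks
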