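"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates what a targeted linked-read NIPD assay observes:

* phased parental diplotypes over a ~2 Mb capture region with a
  heterozygous pathogenic variant per carrier parent;
* high-molecular-weight molecules (exponential lengths with a 50 kb floor)
  sheared into barcoded allele observations, several molecules sharing a
  gel-bead barcode;
* a fetal genome drawn from the parental haplotypes with genetic-map
  driven recombination (Haldane map function);
* maternal plasma allele counts as a (1-f) maternal : f fetal mixture
  with sequencing error, Poisson depth per SNP.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .genetic_map import GeneticMap, recombination_fraction
from .types import (
    ALT,
    BarcodeObservationTable,
    Diplotype,
    PlasmaCounts,
    REF,
    SimTruth,
    SNPMarker,
    SnpPanel,
)

_BASES = np.array(list("ACGT"))

#: default minimum HMW molecule length (bp); linked-read library preparation
#: requires molecules of at least this size
MIN_MOLECULE_LEN = 50_000

#: probability that a molecule covering a SNP yields an observation there
#: (linked reads cover each molecule sparsely)
SNP_OBSERVATION_RATE = 0.5


@dataclass
class PathogenicSpec:
    """Placement of one parent's pathogenic variant: position and which
    haplotype (1 or 2) carries it."""

    pos: int
    hap: int = 1


def simulate_parental_diplotypes(
    n_snps: int = 300,
    region_length: int = 2_000_000,
    het_rate: float = 0.6,
    pathogenic_spec: Optional[dict[str, PathogenicSpec]] = None,
    seed: int = 0,
    chrom: str = "chr11",
    region_start: int = 4_000_000,
) -> tuple[SnpPanel, Diplotype, Diplotype]:
    """Draw a SNP panel and phased mother/father diplotypes.

    Each parent is heterozygous (carrier) at its own pathogenic site and
    homozygous reference there in the other parent.  ``het_rate`` is the
    per-site probability that a parent is heterozygous; homozygous sites
    are hom-ref or hom-alt with equal probability.
    """
    if n_snps < 2:
        raise ValueError("need at least 2 SNPs")
    if not 0.0 < het_rate <= 1.0:
        raise ValueError("het_rate must be in (0, 1]")
    pathogenic_spec = pathogenic_spec or {}
    for parent, spec in pathogenic_spec.items():
        if parent not in ("mother", "father"):
            raise ValueError(f"unknown parent {parent!r} in pathogenic_spec")
        if not region_start <= spec.pos < region_start + region_length:
            raise ValueError(f"pathogenic position {spec.pos} outside the region")
        if spec.hap not in (1, 2):
            raise ValueError("pathogenic hap must be 1 or 2")

    rng = np.random.default_rng(seed)
    patho_pos = sorted({s.pos for s in pathogenic_spec.values()})
    n_random = n_snps - len(patho_pos)
    if n_random < 0:
        raise ValueError("more pathogenic sites than SNPs")
    taken = set(patho_pos)
    pos = []
    while len(pos) < n_random:
        cand = int(rng.integers(region_start, region_start + region_length))
        if cand not in taken:
            taken.add(cand)
            pos.append(cand)
    positions = np.array(sorted(taken), dtype=np.int64)
    patho_set = set(patho_pos)

    markers = []
    for p in positions:
        ref, alt = rng.choice(4, size=2, replace=False)
        markers.append(
            SNPMarker(chrom, int(p), str(_BASES[ref]), str(_BASES[alt]), is_pathogenic=int(p) in patho_set)
        )
    panel = SnpPanel(markers)

    def draw_parent(sample_id: str) -> Diplotype:
        het = rng.random(n_snps) < het_rate
        hom_allele = rng.integers(0, 2, size=n_snps).astype(np.int8)
        alt_on_hap1 = rng.random(n_snps) < 0.5
        hap1 = np.where(het, np.where(alt_on_hap1, ALT, REF), hom_allele).astype(np.int8)
        hap2 = np.where(het, np.where(alt_on_hap1, REF, ALT), hom_allele).astype(np.int8)
        return Diplotype(sample_id, hap1, hap2, phased=True)

    mother = draw_parent("mother")
    father = draw_parent("father")

    # force the configured carrier genotypes at the pathogenic sites
    for parent_name, dip, other in (("mother", mother, father), ("father", father, mother)):
        spec = pathogenic_spec.get(parent_name)
        if spec is None:
            continue
        i = panel.index_of(spec.pos)
        dip.hap(spec.hap)[i] = ALT
        dip.hap(3 - spec.hap)[i] = REF
        dip.pathogenic_hap = spec.hap
        # a site pathogenic only in this parent: other parent hom-ref there,
        # unless both parents share the same variant position
        other_spec = pathogenic_spec.get("mother" if parent_name == "father" else "father")
        if other_spec is None or other_spec.pos != spec.pos:
            other.hap1[i] = REF
            other.hap2[i] = REF
    return panel, mother, father


def simulate_linked_reads(
    diplotype: Diplotype,
    panel: SnpPanel,
    molecule_len_mean: int = 100_000,
    molecules_per_partition: int = 10,
    target_depth: float = 100.0,
    error_rate: float = 0.001,
    min_molecule_len: int = MIN_MOLECULE_LEN,
    seed: int = 0,
) -> BarcodeObservationTable:
    """Shear one parent's haplotypes into barcoded allele observations.

    Molecule lengths are exponential with mean ``molecule_len_mean``,
    truncated below at ``min_molecule_len`` (by memorylessness this is a
    shifted exponential).  Each molecule copies one haplotype; every SNP it
    covers is observed with probability :data:`SNP_OBSERVATION_RATE` so the
    mean per-SNP observation count is approximately ``target_depth``.
    Barcodes are shared by ``molecules_per_partition`` molecules, emulating
    gel-bead partitions.
    """
    if molecule_len_mean <= 0:
        raise ValueError("molecule_len_mean must be positive")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    region_start = int(panel.positions[0])
    region_end = int(panel.positions[-1])
    region_len = region_end - region_start + 1
    # mean truncated length: floor + exponential mean (memoryless excess)
    mean_len = min_molecule_len + molecule_len_mean
    span = region_len + mean_len  # molecules may start upstream of the first SNP
    n_molecules = int(round(target_depth * span / (mean_len * SNP_OBSERVATION_RATE)))
    if n_molecules == 0:
        warnings.warn("region too small: no molecules generated")
        empty = np.array([], dtype=np.int64)
        return BarcodeObservationTable(empty, empty, empty.astype(np.int8), empty)

    starts = rng.integers(region_start - mean_len, region_end + 1, size=n_molecules)
    lengths = min_molecule_len + rng.exponential(molecule_len_mean, size=n_molecules)
    ends = starts + lengths.astype(np.int64)
    hap_choice = rng.integers(1, 3, size=n_molecules)  # 1 or 2
    barcodes = rng.permutation(n_molecules) // molecules_per_partition

    bc_out, snp_out, allele_out, mol_out = [], [], [], []
    pos = panel.positions
    for m in range(n_molecules):
        lo = np.searchsorted(pos, starts[m], side="left")
        hi = np.searchsorted(pos, ends[m], side="right")
        if hi <= lo:
            continue
        covered = np.arange(lo, hi)
        keep = rng.random(len(covered)) < SNP_OBSERVATION_RATE
        covered = covered[keep]
        if len(covered) == 0:
            continue
        hap = diplotype.hap(int(hap_choice[m]))
        alleles = hap[covered].copy()
        if error_rate > 0:
            flip = rng.random(len(covered)) < error_rate
            alleles = np.where(flip, 1 - alleles, alleles)
        bc_out.append(np.full(len(covered), barcodes[m], dtype=np.int64))
        snp_out.append(covered.astype(np.int64))
        allele_out.append(alleles.astype(np.int8))
        mol_out.append(np.full(len(covered), m, dtype=np.int64))

    if not bc_out:
        warnings.warn("no SNP observations generated")
        empty = np.array([], dtype=np.int64)
        return BarcodeObservationTable(empty, empty, empty.astype(np.int8), empty)
    return BarcodeObservationTable(
        np.concatenate(bc_out),
        np.concatenate(snp_out),
        np.concatenate(allele_out),
        np.concatenate(mol_out),
    )


def simulate_fetal_genome(
    mother: Diplotype,
    father: Diplotype,
    panel: SnpPanel,
    genetic_map: Optional[GeneticMap] = None,
    recombination: bool = True,
    true_ff: float = 0.132,
    seed: int = 0,
    map_function: str = "haldane",
) -> SimTruth:
    """Draw the fetal inheritance vector from the parental haplotypes.

    For each parent the initial haplotype is uniform; between adjacent SNPs
    a crossover occurs with the map-derived recombination fraction.
    """
    if not (mother.phased and father.phased):
        raise ValueError("parental diplotypes must be phased")
    rng = np.random.default_rng(seed)
    n = len(panel)
    if genetic_map is None:
        genetic_map = GeneticMap.uniform(int(panel.positions[0]), int(panel.positions[-1]))
    if recombination:
        d_cm = genetic_map.distances_cm(panel.positions)
        r = recombination_fraction(d_cm, map_function)
    else:
        r = np.zeros(n - 1)

    crossovers: list[tuple[str, int]] = []
    haps = {}
    for parent in ("mat", "pat"):
        h = np.empty(n, dtype=np.int8)
        h[0] = rng.integers(1, 3)
        xo = rng.random(n - 1) < r
        for i in range(1, n):
            h[i] = (3 - h[i - 1]) if xo[i - 1] else h[i - 1]
            if xo[i - 1]:
                crossovers.append((parent, i - 1))
        haps[parent] = h
    return SimTruth(haps["mat"], haps["pat"], crossovers, true_ff, seed)


def simulate_plasma_counts(
    mother: Diplotype,
    father: Diplotype,
    sim_truth: SimTruth,
    panel: SnpPanel,
    depth_mean: float = 200.0,
    error_rate: float = 0.005,
    seed: int = 0,
) -> PlasmaCounts:
    """Draw maternal-plasma allele counts for every panel SNP.

    Depth is Poisson per SNP.  Each read originates from the mother with
    probability 1-f (her two alleles equally likely) or from the fetus with
    probability f (its two alleles equally likely), then is mis-read with
    probability ``error_rate``.  Counts are drawn binomially from the exact
    per-read alt probability, which is distributionally identical to
    simulating reads one by one.
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    f = sim_truth.true_ff
    rng = np.random.default_rng(seed)
    fet_mat, fet_pat = sim_truth.fetal_alleles(mother, father)
    mat_alt_dose = (mother.hap1 + mother.hap2) / 2.0
    fet_alt_dose = (fet_mat + fet_pat) / 2.0
    p_alt = (1.0 - f) * mat_alt_dose + f * fet_alt_dose
    p_alt = p_alt * (1.0 - error_rate) + (1.0 - p_alt) * error_rate
    depth = rng.poisson(depth_mean, size=len(panel))
    alt = rng.binomial(depth, p_alt)
    return PlasmaCounts(ref_count=depth - alt, alt_count=alt)


def expected_plasma_alt_fraction(
    mother_gt: tuple[int, int],
    fetal_gt: tuple[int, int],
    ff: float,
    error_rate: float = 0.0,
) -> float:
    """Closed-form expected alt-allele fraction of the cfDNA mixture at one
    SNP; the independent check for the count generator."""
    m = (mother_gt[0] + mother_gt[1]) / 2.0
    c = (fetal_gt[0] + fetal_gt[1]) / 2.0
    p = (1.0 - ff) * m + ff * c
    return p * (1.0 - error_rate) + (1.0 - p) * error_rate
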