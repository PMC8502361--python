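"""Core domain types shared across the pipeline.

Alleles are encoded as small integers throughout: ``0`` for the reference
allele, ``1`` for the alternate allele, ``-1`` for missing/unphased.  The
pathogenic variant is always modelled as a biallelic marker whose alternate
allele is the disease allele (large deletions such as the Southeast-Asian
alpha-thalassemia deletion are represented abstractly the same way).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

REF = 0
ALT = 1
MISSING = -1


@dataclass(frozen=True)
class SNPMarker:
    """A biallelic SNP site on the capture panel."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    is_pathogenic: bool = False

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt allele identical at {self.chrom}:{self.pos}")


class SnpPanel:
    """An ordered panel of SNP markers over one target region.

    Positions must be strictly increasing.  Provides O(1) lookup from
    position to panel index.
    """

    def __init__(self, markers: Sequence[SNPMarker]):
        if len(markers) < 1:
            raise ValueError("panel needs at least one marker")
        pos = np.array([m.pos for m in markers], dtype=np.int64)
        if np.any(np.diff(pos) <= 0):
            raise ValueError("marker positions must be strictly increasing")
        chroms = {m.chrom for m in markers}
        if len(chroms) != 1:
            raise ValueError("a panel spans a single chromosome")
        self.markers = list(markers)
        self.positions = pos
        self.chrom = markers[0].chrom
        self._index = {int(p): i for i, p in enumerate(pos)}

    def __len__(self) -> int:
        return len(self.markers)

    def __getitem__(self, i: int) -> SNPMarker:
        return self.markers[i]

    def index_of(self, pos: int) -> int:
        return self._index[int(pos)]

    @property
    def pathogenic_indices(self) -> list[int]:
        return [i for i, m in enumerate(self.markers) if m.is_pathogenic]


@dataclass
class Diplotype:
    """Phased (or unphased) genotypes of one individual over a panel.

    ``hap1`` / ``hap2`` hold the 0/1 allele carried by each haplotype at
    every panel site.  For unphased data the ordering within a site is
    arbitrary and ``phased`` is False.  ``pathogenic_hap`` names the
    haplotype (1 or 2) carrying the pathogenic variant, when known.
    """

    sample_id: str
    hap1: np.ndarray
    hap2: np.ndarray
    phased: bool = True
    pathogenic_hap: Optional[int] = None

    def __post_init__(self) -> None:
        self.hap1 = np.asarray(self.hap1, dtype=np.int8)
        self.hap2 = np.asarray(self.hap2, dtype=np.int8)
        if self.hap1.shape != self.hap2.shape:
            raise ValueError("haplotype arrays differ in length")
        if self.pathogenic_hap not in (None, 1, 2):
            raise ValueError("pathogenic_hap must be 1, 2 or None")

    def __len__(self) -> int:
        return len(self.hap1)

    def genotype(self, i: int) -> tuple[int, int]:
        return int(self.hap1[i]), int(self.hap2[i])

    def is_het(self, i: int) -> bool:
        return self.hap1[i] != self.hap2[i]

    @property
    def het_mask(self) -> np.ndarray:
        return self.hap1 != self.hap2

    def hap(self, index: int) -> np.ndarray:
        if index == 1:
            return self.hap1
        if index == 2:
            return self.hap2
        raise ValueError("haplotype index must be 1 or 2")


@dataclass
class SimTruth:
    """Ground truth of a simulated pregnancy.

    ``fetal_mat_hap`` / ``fetal_pat_hap`` give, per panel SNP, which
    parental haplotype (1 or 2) the fetus inherited; the indices change
    only at the recorded crossovers.
    """

    fetal_mat_hap: np.ndarray
    fetal_pat_hap: np.ndarray
    crossovers: list[tuple[str, int]]  # (parent, interval index i: between SNP i and i+1)
    true_ff: float
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 < self.true_ff < 1.0:
            raise ValueError("fetal fraction must lie in (0, 1)")

    def fetal_alleles(self, mother: Diplotype, father: Diplotype) -> tuple[np.ndarray, np.ndarray]:
        """Return the fetus's (maternal allele, paternal allele) per SNP."""
        idx = np.arange(len(self.fetal_mat_hap))
        mat = np.where(self.fetal_mat_hap == 1, mother.hap1, mother.hap2)[idx]
        pat = np.where(self.fetal_pat_hap == 1, father.hap1, father.hap2)[idx]
        return mat, pat


@dataclass
class BarcodeObservationTable:
    """Allele-level linked-read observations.

    One record per (barcode, SNP) allele observation.  ``molecule_id`` is
    simulation truth retained for testing only; real data would not carry it.
    """

    barcode: np.ndarray  # int barcode ids
    snp_index: np.ndarray  # panel indices
    allele: np.ndarray  # 0/1
    molecule_id: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.barcode)

    def to_dataframe(self, panel: Optional[SnpPanel] = None):
        import pandas as pd

        d = {"barcode": self.barcode, "snp_index": self.snp_index, "allele": self.allele}
        if panel is not None:
            d["chrom"] = [panel.chrom] * len(self.snp_index)
            d["pos"] = panel.positions[self.snp_index]
        if self.molecule_id is not None:
            d["molecule_id"] = self.molecule_id
        return pd.DataFrame(d)


@dataclass
class PlasmaCounts:
    """Per-SNP allele depths observed in maternal plasma cfDNA."""

    ref_count: np.ndarray
    alt_count: np.ndarray
    ff: Optional[float] = None  # estimated fetal fraction, set later

    def __post_init__(self) -> None:
        self.ref_count = np.asarray(self.ref_count, dtype=np.int64)
        self.alt_count = np.asarray(self.alt_count, dtype=np.int64)
        if np.any(self.ref_count < 0) or np.any(self.alt_count < 0):
            raise ValueError("negative read counts")

    @property
    def depth(self) -> np.ndarray:
        return self.ref_count + self.alt_count

    def __len__(self) -> int:
        return len(self.ref_count)


@dataclass
class PhaseBlock:
    """A maximal set of het SNPs jointly phased from barcode evidence."""

    block_id: int
    chrom: str
    start: int  # 1-based inclusive
    end: int
    snp_indices: np.ndarray
    positions: np.ndarray  # bp position of each member SNP
    hap1_alleles: np.ndarray  # allele on haplotype 1 at each member SNP
    hap2_alleles: np.ndarray
    support: np.ndarray  # per member SNP: concordant barcode count

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def spans(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end


@dataclass
class HaplotypePair:
    """Per-parent pathogenic (P) and normal (N) haplotypes.

    ``p_allele`` / ``n_allele`` give the 0/1 allele on each haplotype per
    panel SNP, ``MISSING`` at het sites outside the anchoring block.
    ``covered`` is True only if the anchoring block spans the pathogenic
    site — otherwise phasing failed for this parent.
    """

    parent_id: str
    p_allele: np.ndarray
    n_allele: np.ndarray
    covered: bool

    def __len__(self) -> int:
        return len(self.p_allele)

    @property
    def phased_mask(self) -> np.ndarray:
        return (self.p_allele != MISSING) & (self.n_allele != MISSING)


@dataclass
class PhaseBlockStats:
    n50_length: int
    longest_block: int
    total_blocks: int
    snps_in_anchor_block: int


class Category(str, enum.Enum):
    """Informative-SNP classification from the two parental genotypes."""

    MAT_INFORMATIVE = "MAT_INFORMATIVE"  # mother het, father hom
    PAT_INFORMATIVE = "PAT_INFORMATIVE"  # father het, mother hom
    UNINFORMATIVE = "UNINFORMATIVE"


class MatSubtype(str, enum.Enum):
    """For maternal-informative SNPs: which maternal haplotype the father's
    homozygous allele matches."""

    FATHER_HOM_P = "FATHER_HOM_P"
    FATHER_HOM_N = "FATHER_HOM_N"


@dataclass
class InformativeSNP:
    snp_index: int
    category: Category
    subtype: Optional[MatSubtype] = None
    p_hap_allele: int = MISSING  # allele on the analysed parent's P haplotype


class State(str, enum.Enum):
    """Hidden state: which parental haplotype the fetus inherited."""

    P = "P"
    N = "N"


@dataclass
class HaplotypePath:
    """Viterbi-decoded fetal inheritance path for one parent."""

    parent: str  # "mat" or "pat"
    snp_positions: np.ndarray
    states: np.ndarray  # bool array, True = P
    log_likelihood: float
    segments: list[tuple[State, int, int]] = field(default_factory=list)  # (state, start pos, end pos)

    def __post_init__(self) -> None:
        if not self.segments and len(self.states):
            self.segments = path_segments(self.snp_positions, self.states)


def path_segments(positions: np.ndarray, states: np.ndarray) -> list[tuple[State, int, int]]:
    """Collapse a per-SNP state vector into maximal constant-state runs."""
    segs: list[tuple[State, int, int]] = []
    if len(states) == 0:
        return segs
    start = 0
    for i in range(1, len(states)):
        if states[i] != states[start]:
            segs.append((State.P if states[start] else State.N, int(positions[start]), int(positions[i - 1])))
            start = i
    segs.append((State.P if states[start] else State.N, int(positions[start]), int(positions[-1])))
    return segs


@dataclass
class FetalCall:
    """Per-parent fetal allele call at the pathogenic site."""

    parent: str
    allele: str  # "P", "N" or "NO_CALL"
    cs: Optional[float] = None
    reason: str = ""


class GenotypeCategory(str, enum.Enum):
    AFFECTED = "AFFECTED"
    CARRIER = "CARRIER"
    NORMAL = "NORMAL"
    PARTIAL = "PARTIAL"
    NO_CALL = "NO_CALL"


@dataclass
class CSResult:
    cs: float
    replicates: int
    threshold: float
    decision: str  # "CALL" | "NO_CALL"
    seed: int


@dataclass
class FamilyReport:
    family_id: str
    gene: str
    mat_call: FetalCall
    pat_call: FetalCall
    genotype_category: GenotypeCategory
    ff: float
    n_mat_informative: int
    n_pat_informative: int
    concordant_with_truth: Optional[bool] = None
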