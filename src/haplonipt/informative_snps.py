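"""Informative-SNP classification, fetal-fraction estimation and
haplotype-resolved plasma counts.

A SNP heterozygous in the mother and homozygous in the father is
informative for maternal inheritance (the paternal contribution to plasma
is fixed there); the mirror-image configuration is informative for
paternal inheritance.  Paternal-informative sites also power the fetal
fraction estimate: the allele the mother lacks appears in plasma only via
the fetus, at fraction f/2 when the fetus inherited it.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np

from .types import (
    Category,
    Diplotype,
    HaplotypePair,
    InformativeSNP,
    MatSubtype,
    MISSING,
    PlasmaCounts,
)

logger = logging.getLogger(__name__)


def classify_informative_snps(mother: Diplotype, father: Diplotype) -> list[InformativeSNP]:
    """Classify every panel SNP by the parental genotype configuration.

    Mother het + father hom -> maternal-informative; father het + mother
    hom -> paternal-informative; everything else (double-het, double-hom,
    missing) is uninformative.
    """
    if len(mother) != len(father):
        raise ValueError("parental diplotypes cover different panels")
    out: list[InformativeSNP] = []
    for i in range(len(mother)):
        m_het = mother.is_het(i)
        f_het = father.is_het(i)
        if MISSING in mother.genotype(i) or MISSING in father.genotype(i):
            logger.warning("missing genotype at panel index %d; uninformative", i)
            cat = Category.UNINFORMATIVE
        elif m_het and not f_het:
            cat = Category.MAT_INFORMATIVE
        elif f_het and not m_het:
            cat = Category.PAT_INFORMATIVE
        else:
            cat = Category.UNINFORMATIVE
        out.append(InformativeSNP(i, cat))
    return out


def annotate_with_haplotypes(
    informative: list[InformativeSNP],
    mother: Diplotype,
    father: Diplotype,
    mat_pair: HaplotypePair,
    pat_pair: HaplotypePair,
) -> list[InformativeSNP]:
    """Attach the P-haplotype allele (and, for maternal-informative SNPs,
    the father-hom subtype) from the anchored haplotype pairs.

    SNPs whose analysed parent is not phased at that site (outside the
    anchoring block, or a failed parent) are demoted to uninformative and
    counted in the log.
    """
    dropped = 0
    out: list[InformativeSNP] = []
    for s in informative:
        i = s.snp_index
        if s.category == Category.MAT_INFORMATIVE:
            if not mat_pair.covered or mat_pair.p_allele[i] == MISSING:
                dropped += 1
                out.append(InformativeSNP(i, Category.UNINFORMATIVE))
                continue
            p_al = int(mat_pair.p_allele[i])
            father_allele = father.hap1[i]  # father hom
            subtype = MatSubtype.FATHER_HOM_P if father_allele == p_al else MatSubtype.FATHER_HOM_N
            out.append(InformativeSNP(i, s.category, subtype, p_al))
        elif s.category == Category.PAT_INFORMATIVE:
            if not pat_pair.covered or pat_pair.p_allele[i] == MISSING:
                dropped += 1
                out.append(InformativeSNP(i, Category.UNINFORMATIVE))
                continue
            out.append(InformativeSNP(i, s.category, None, int(pat_pair.p_allele[i])))
        else:
            out.append(s)
    if dropped:
        logger.info("%d informative SNPs outside covered phase blocks dropped", dropped)
    return out


def _otsu_threshold(q: np.ndarray) -> float:
    """Threshold separating the background (fetus did not inherit the
    paternal-specific allele) and signal modes of the q distribution, by
    maximising between-class variance over candidate splits."""
    qs = np.sort(q)
    best_t, best_v = qs[0], -1.0
    for k in range(1, len(qs)):
        lo, hi = qs[:k], qs[k:]
        w = k * (len(qs) - k)
        v = w * (hi.mean() - lo.mean()) ** 2
        if v > best_v:
            best_v = v
            best_t = 0.5 * (qs[k - 1] + qs[k])
    return float(best_t)


def estimate_fetal_fraction(
    counts: PlasmaCounts,
    mother: Diplotype,
    father: Diplotype,
    informative: Optional[list[InformativeSNP]] = None,
    min_depth: int = 50,
    max_q: float = 0.4,
    estimator: str = "median",
) -> float:
    """Estimate the fetal fraction from paternal-specific allele fractions.

    At each paternal-informative SNP (mother hom, father het) the fraction
    q of plasma reads carrying the allele absent from the mother is ~f/2
    when the fetus inherited that paternal allele and ~0 otherwise.  Sites
    with q above ``max_q`` (likely genotyping errors) or depth below
    ``min_depth`` are excluded; the two modes are separated with an
    Otsu-style split and f = 2 x median (or mean) of the signal mode.
    """
    if informative is None:
        informative = classify_informative_snps(mother, father)
    depth = counts.depth
    qs = []
    for s in informative:
        if s.category != Category.PAT_INFORMATIVE:
            continue
        i = s.snp_index
        if depth[i] < min_depth:
            continue
        mom_allele = int(mother.hap1[i])  # mother hom here
        specific = counts.alt_count[i] if mom_allele == 0 else counts.ref_count[i]
        q = specific / depth[i]
        if q <= max_q:
            qs.append(q)
    if not qs:
        raise ValueError(
            "no qualifying paternal-specific SNPs; supply the fetal fraction manually (--ff)"
        )
    q = np.asarray(qs)
    if q.max() <= 0:
        raise ValueError("all paternal-specific allele fractions are zero: no fetal signal")
    t = _otsu_threshold(q) if len(q) > 1 else 0.0
    signal = q[q > t]
    if len(signal) == 0:
        signal = q
    if estimator == "median":
        ff = 2.0 * float(np.median(signal))
    elif estimator == "mean":
        ff = 2.0 * float(np.mean(signal))
    else:
        raise ValueError("estimator must be 'median' or 'mean'")
    ff = min(max(ff, 1e-6), 1.0 - 1e-6)
    if ff <= 1e-6:
        raise ValueError("fetal fraction estimate is zero: no fetal signal")
    return ff


def extract_haplotype_counts(
    counts: PlasmaCounts,
    informative: list[InformativeSNP],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Relabel plasma ref/alt counts as P-hap / N-hap counts.

    Returns ``(snp_indices, p_counts, n_counts, n_excluded)`` over the
    informative SNPs with an assigned P-haplotype allele; SNPs outside
    covered blocks (``p_hap_allele`` missing) are excluded and counted.
    """
    idx, p_out, n_out = [], [], []
    excluded = 0
    for s in informative:
        if s.category == Category.UNINFORMATIVE:
            continue
        if s.p_hap_allele == MISSING:
            excluded += 1
            continue
        i = s.snp_index
        if s.p_hap_allele == 1:
            p, n = counts.alt_count[i], counts.ref_count[i]
        else:
            p, n = counts.ref_count[i], counts.alt_count[i]
        idx.append(i)
        p_out.append(int(p))
        n_out.append(int(n))
    if excluded:
        logger.info("%d informative SNPs excluded (outside covered phase blocks)", excluded)
    return (
        np.array(idx, dtype=np.int64),
        np.array(p_out, dtype=np.int64),
        np.array(n_out, dtype=np.int64),
        excluded,
    )
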