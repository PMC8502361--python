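"""Two-state HMM over informative SNPs: relative haplotype dosage decoding.

For each parent separately, the hidden state at an informative SNP is
which of that parent's haplotypes — pathogenic (P) or normal (N) — the
fetus inherited.  Emissions are binomial draws of P-haplotype allele reads
out of the SNP's plasma depth, with success probability given by the
closed-form cfDNA mixture fractions; transitions between adjacent SNPs
are recombination fractions from the genetic map (Haldane by default).
Decoding is exact maximum-probability Viterbi; the fetal allele at the
pathogenic site is then called from the segment structure of the path.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.stats import binom

from .genetic_map import GeneticMap, recombination_fraction
from .types import (
    Category,
    FetalCall,
    HaplotypePath,
    InformativeSNP,
    MatSubtype,
    State,
    path_segments,
)

#: baseline fraction at which an allele absent from both mother and the
#: transmitted paternal haplotype is still observed (sequencing error)
DEFAULT_EPSILON = 0.005


def expected_allele_fraction(
    state: State,
    category: Category,
    subtype: Optional[MatSubtype],
    ff: float,
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """Expected plasma fraction of the P-haplotype allele at one SNP.

    Maternal-informative (mother het, father hom):
      father hom for the maternal P allele: P -> (1+f)/2, N -> 1/2
      father hom for the maternal N allele: P -> 1/2,     N -> (1-f)/2
    Paternal-informative (father het, mother hom):
      mother lacks the paternal P allele:   P -> f/2,     N -> ~0
      mother carries the paternal P allele: P -> ~1,      N -> 1 - f/2
    Fractions are clamped to [epsilon, 1-epsilon] so sequencing error
    keeps every emission possible.
    """
    if not 0.0 < ff < 1.0:
        raise ValueError("fetal fraction must lie in (0, 1)")
    f = ff
    if category == Category.MAT_INFORMATIVE:
        if subtype is None:
            raise ValueError("maternal-informative SNPs need a subtype")
        if subtype == MatSubtype.FATHER_HOM_P:
            frac = (1.0 + f) / 2.0 if state == State.P else 0.5
        else:
            frac = 0.5 if state == State.P else (1.0 - f) / 2.0
    elif category == Category.PAT_INFORMATIVE:
        if subtype is None or subtype == "MOTHER_LACKS_P":
            # canonical case: mother homozygous for the N-type allele
            frac = f / 2.0 if state == State.P else 0.0
        else:
            frac = 1.0 if state == State.P else 1.0 - f / 2.0
    else:
        raise ValueError("uninformative SNPs have no emission model")
    return float(min(max(frac, epsilon), 1.0 - epsilon))


def pat_subtype_of(p_hap_allele: int, mother_hom_allele: int) -> str:
    """Which paternal-informative sub-case applies at a SNP: does the
    mother's homozygous allele match the father's P allele?"""
    return "MOTHER_HAS_P" if mother_hom_allele == p_hap_allele else "MOTHER_LACKS_P"


def emission_logprob(p_count: int, n_count: int, expected_p_fraction: float) -> float:
    """Binomial log-probability of the observed P/N read split.

    A SNP with zero depth carries no information and contributes 0.
    """
    if p_count < 0 or n_count < 0:
        raise ValueError("negative counts")
    depth = p_count + n_count
    if depth == 0:
        return 0.0
    if not 0.0 < expected_p_fraction < 1.0:
        raise ValueError("expected fraction must lie strictly in (0, 1)")
    return float(binom.logpmf(p_count, depth, expected_p_fraction))


def _emission_matrix(
    p_counts: np.ndarray,
    n_counts: np.ndarray,
    fractions_P: np.ndarray,
    fractions_N: np.ndarray,
) -> np.ndarray:
    """(n, 2) log-emission matrix, columns ordered [P, N]."""
    depth = p_counts + n_counts
    logB = np.zeros((len(p_counts), 2))
    nz = depth > 0
    logB[nz, 0] = binom.logpmf(p_counts[nz], depth[nz], fractions_P[nz])
    logB[nz, 1] = binom.logpmf(p_counts[nz], depth[nz], fractions_N[nz])
    return logB


def expected_fraction_arrays(
    informative: list[InformativeSNP],
    mother_hom_alleles: Optional[np.ndarray],
    ff: float,
    parent: str,
    epsilon: float = DEFAULT_EPSILON,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP expected P-allele fractions for both states, restricted to
    the SNPs informative for ``parent`` ('mat' or 'pat').

    Returns ``(snp_indices, frac_if_P, frac_if_N)``.  For paternal
    decoding, ``mother_hom_alleles`` supplies the mother's homozygous
    allele per panel SNP to resolve the sub-case.
    """
    want = Category.MAT_INFORMATIVE if parent == "mat" else Category.PAT_INFORMATIVE
    idx, fP, fN = [], [], []
    for s in informative:
        if s.category != want or s.p_hap_allele < 0:
            continue
        if parent == "mat":
            subtype = s.subtype
            fP.append(expected_allele_fraction(State.P, want, subtype, ff, epsilon))
            fN.append(expected_allele_fraction(State.N, want, subtype, ff, epsilon))
        else:
            sub = pat_subtype_of(s.p_hap_allele, int(mother_hom_alleles[s.snp_index]))
            fP.append(expected_allele_fraction(State.P, want, sub, ff, epsilon))
            fN.append(expected_allele_fraction(State.N, want, sub, ff, epsilon))
        idx.append(s.snp_index)
    return np.array(idx, dtype=np.int64), np.array(fP), np.array(fN)


def viterbi_decode(
    positions: np.ndarray,
    p_counts: np.ndarray,
    n_counts: np.ndarray,
    fractions_P: np.ndarray,
    fractions_N: np.ndarray,
    genetic_map: GeneticMap,
    parent: str = "mat",
    map_function: str = "haldane",
) -> HaplotypePath:
    """Maximum-probability inheritance path over one parent's informative
    SNPs (log-space Viterbi, uniform initial state, ties broken toward the
    stay/no-switch predecessor)."""
    n = len(positions)
    if n == 0:
        raise ValueError("no informative SNPs to decode")
    logB = _emission_matrix(np.asarray(p_counts), np.asarray(n_counts),
                            np.asarray(fractions_P), np.asarray(fractions_N))
    r = recombination_fraction(genetic_map.distances_cm(np.asarray(positions)), map_function)
    log_stay = np.log1p(-r)
    log_switch = np.log(r)

    delta = np.log(0.5) + logB[0]
    ptr = np.zeros((n, 2), dtype=np.int8)
    for t in range(1, n):
        for s in range(2):
            stay = delta[s] + log_stay[t - 1]
            switch = delta[1 - s] + log_switch[t - 1]
            # tie -> prefer the stay predecessor
            if switch > stay:
                ptr[t, s] = 1 - s
                new = switch
            else:
                ptr[t, s] = s
                new = stay
            if s == 0:
                d0 = new + logB[t, 0]
            else:
                d1 = new + logB[t, 1]
        delta = np.array([d0, d1])

    last = int(np.argmax(delta))  # argmax prefers P (index 0) on exact ties
    ll = float(delta[last])
    states_idx = np.empty(n, dtype=np.int8)
    states_idx[-1] = last
    for t in range(n - 1, 0, -1):
        states_idx[t - 1] = ptr[t, states_idx[t]]
    states = states_idx == 0  # True = P
    return HaplotypePath(parent=parent, snp_positions=np.asarray(positions),
                         states=states, log_likelihood=ll)


def path_loglik(
    states: np.ndarray,
    p_counts: np.ndarray,
    n_counts: np.ndarray,
    fractions_P: np.ndarray,
    fractions_N: np.ndarray,
    genetic_map: GeneticMap,
    positions: np.ndarray,
    map_function: str = "haldane",
) -> float:
    """Log-probability of one explicit state path (True = P); used by the
    exhaustive-enumeration cross-check of the Viterbi decoder."""
    logB = _emission_matrix(np.asarray(p_counts), np.asarray(n_counts),
                            np.asarray(fractions_P), np.asarray(fractions_N))
    r = recombination_fraction(genetic_map.distances_cm(np.asarray(positions)), map_function)
    states = np.asarray(states, dtype=bool)
    col = np.where(states, 0, 1)
    ll = np.log(0.5) + logB[np.arange(len(states)), col].sum()
    switch = states[1:] != states[:-1]
    ll += np.sum(np.where(switch, np.log(r), np.log1p(-r)))
    return float(ll)


def call_fetal_allele(
    path: HaplotypePath,
    gene_interval: tuple[int, int],
) -> FetalCall:
    """Fetal allele at the pathogenic site from the decoded path.

    A segment "spans the gene" when its bp interval (first to last member
    SNP) fully contains the gene interval.  One segment spanning the gene
    gives that segment's state; a haplotype switch inside the gene, or no
    segment spanning it, gives a no-call.
    """
    if len(path.states) == 0:
        return FetalCall(path.parent, "NO_CALL", reason="no informative SNPs")
    g_start, g_end = gene_interval
    span_start, span_end = int(path.snp_positions[0]), int(path.snp_positions[-1])
    if g_end < span_start or g_start > span_end:
        return FetalCall(path.parent, "NO_CALL", reason="gene not covered by informative SNPs")
    spanning = [seg for seg in path.segments if seg[1] <= g_start and g_end <= seg[2]]
    if len(spanning) == 1:
        return FetalCall(path.parent, spanning[0][0].value,
                         reason=f"{len(path.segments)} segment(s); one spans the gene")
    if g_start < span_start or g_end > span_end:
        return FetalCall(path.parent, "NO_CALL", reason="gene only partially covered")
    # a boundary between segments falls inside (or across) the gene interval
    return FetalCall(path.parent, "NO_CALL", reason="haplotype block boundary inside gene")
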