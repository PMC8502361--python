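"""Simulation experiments that characterise the pipeline's operating
behaviour: decoder exactness, end-to-end allele recovery, fetal-fraction
estimator bias, confidence-score calibration and recombination handling.

These are the package's own benchmark battery; the test suite and the
reproduction script both run them at documented problem sizes.
"""

from __future__ import annotations

import itertools
from typing import Optional

import numpy as np
from scipy.stats import binom

from . import confidence as conf
from . import informative_snps as isnp
from . import rhdo_hmm as hmm
from . import simdata
from .genetic_map import GeneticMap, recombination_fraction
from .types import (
    ALT,
    Category,
    Diplotype,
    InformativeSNP,
    MatSubtype,
    PlasmaCounts,
    REF,
    SNPMarker,
    SnpPanel,
    State,
)


def exhaustive_best_loglik(
    positions: np.ndarray,
    p_counts: np.ndarray,
    n_counts: np.ndarray,
    fractions_P: np.ndarray,
    fractions_N: np.ndarray,
    genetic_map: GeneticMap,
) -> float:
    """Maximum path log-likelihood by enumerating all 2^n state paths
    (vectorised); the independent oracle for the Viterbi decoder."""
    n = len(positions)
    depth = p_counts + n_counts
    logB = np.zeros((n, 2))
    nz = depth > 0
    logB[nz, 0] = binom.logpmf(p_counts[nz], depth[nz], fractions_P[nz])
    logB[nz, 1] = binom.logpmf(p_counts[nz], depth[nz], fractions_N[nz])
    r = recombination_fraction(genetic_map.distances_cm(positions))
    paths = np.array(list(itertools.product([0, 1], repeat=n)))  # 0 = P
    ll = np.log(0.5) + logB[np.arange(n), paths].sum(axis=1)
    if n > 1:
        switch = paths[:, 1:] != paths[:, :-1]
        ll += np.where(switch, np.log(r), np.log1p(-r)).sum(axis=1)
    return float(ll.max())


def viterbi_exhaustive_agreement(n_instances: int = 100, max_snps: int = 12,
                                 seed: int = 0) -> float:
    """Fraction of random small instances on which Viterbi attains the
    exhaustively enumerated maximum path likelihood."""
    rng = np.random.default_rng(seed)
    gm = GeneticMap.uniform(0, 1_000_000, 1.0)
    hits = 0
    for _ in range(n_instances):
        n = int(rng.integers(1, max_snps + 1))
        pos = np.sort(rng.choice(np.arange(1, 1_000_000), size=n, replace=False))
        depth = rng.integers(0, 60, size=n)
        fP = rng.uniform(0.05, 0.95, size=n)
        fN = rng.uniform(0.05, 0.95, size=n)
        pc = rng.binomial(depth, 0.5)
        path = hmm.viterbi_decode(pos, pc, depth - pc, fP, fN, gm)
        best = exhaustive_best_loglik(pos, pc, depth - pc, fP, fN, gm)
        if abs(best - path.log_likelihood) <= 1e-9:
            hits += 1
    return hits / n_instances


def _constructed_family(
    n_mat: int,
    n_pat: int,
    region_start: int = 4_000_000,
    region_end: int = 6_000_000,
) -> tuple[SnpPanel, Diplotype, Diplotype]:
    """Parents with exactly ``n_mat`` maternal- and ``n_pat``
    paternal-informative SNPs, alternating along an evenly spaced panel;
    each parent's pathogenic variant sits mid-region on haplotype 1."""
    n = n_mat + n_pat
    positions = np.linspace(region_start, region_end, n).astype(np.int64)
    mid = n // 2
    markers = [
        SNPMarker("chr11", int(p), "A", "G", is_pathogenic=(i in (mid, mid + 1)))
        for i, p in enumerate(positions)
    ]
    panel = SnpPanel(markers)
    mom1 = np.zeros(n, np.int8)
    mom2 = np.zeros(n, np.int8)
    dad1 = np.zeros(n, np.int8)
    dad2 = np.zeros(n, np.int8)
    # alternate maternal/paternal-informative sites, then trim to the
    # requested counts
    take_mat = np.arange(n) % 2 == 0
    if take_mat.sum() > n_mat:
        take_mat[np.flatnonzero(take_mat)[n_mat:]] = False
    elif take_mat.sum() < n_mat:
        need = n_mat - int(take_mat.sum())
        take_mat[np.flatnonzero(~take_mat)[:need]] = True
    # maternal-informative: mother het, father hom-ref; paternal-informative
    # the mirror image.  The het parent's alt allele alternates between its
    # two haplotypes, as real variation would distribute it.
    mat_sites = np.flatnonzero(take_mat)
    pat_sites = np.flatnonzero(~take_mat)
    mom1[mat_sites[::2]] = ALT
    mom2[mat_sites[1::2]] = ALT
    dad1[pat_sites[::2]] = ALT
    dad2[pat_sites[1::2]] = ALT
    # pathogenic sites must be het in their own carrier
    mid_sites = (mid, mid + 1)
    mom1[mid_sites[0]], mom2[mid_sites[0]] = ALT, REF
    dad1[mid_sites[0]], dad2[mid_sites[0]] = REF, REF
    dad1[mid_sites[1]], dad2[mid_sites[1]] = ALT, REF
    mom1[mid_sites[1]], mom2[mid_sites[1]] = REF, REF
    mother = Diplotype("mother", mom1, mom2, phased=True, pathogenic_hap=1)
    father = Diplotype("father", dad1, dad2, phased=True, pathogenic_hap=1)
    return panel, mother, father


def end_to_end_recovery(
    n_sims: int = 200,
    ff: float = 0.10,
    depth: float = 200.0,
    n_informative: int = 100,
    seed: int = 0,
    error_rate: float = 0.001,
    estimate_ff: bool = True,
) -> float:
    """Fraction of per-parent fetal-allele calls matching the simulation
    truth: constructed parents with ``n_informative`` informative SNPs per
    parent, no recombination, plasma at ``depth`` reads/SNP."""
    panel, mother, father = _constructed_family(n_informative, n_informative)
    gene = (int(panel.positions[0] + 0.45 * (panel.positions[-1] - panel.positions[0])),
            int(panel.positions[0] + 0.55 * (panel.positions[-1] - panel.positions[0])))
    gm = GeneticMap.uniform(int(panel.positions[0]), int(panel.positions[-1]))
    informative = isnp.classify_informative_snps(mother, father)
    # phased-truth bypass: P = haplotype 1 for both parents
    from .linked_phasing import haplotype_pair_from_diplotype

    mat_pair = haplotype_pair_from_diplotype(mother, "mother")
    pat_pair = haplotype_pair_from_diplotype(father, "father")
    informative = isnp.annotate_with_haplotypes(informative, mother, father, mat_pair, pat_pair)

    correct = total = 0
    for k in range(n_sims):
        truth = simdata.simulate_fetal_genome(
            mother, father, panel, gm, recombination=False, true_ff=ff, seed=seed * 1_000_003 + k)
        counts = simdata.simulate_plasma_counts(
            mother, father, truth, panel, depth_mean=depth, error_rate=error_rate,
            seed=seed * 2_000_003 + k)
        if estimate_ff:
            try:
                est = isnp.estimate_fetal_fraction(counts, mother, father, informative)
            except ValueError:
                est = ff
        else:
            est = ff
        idx, pc, nc, _ = isnp.extract_haplotype_counts(counts, informative)
        pos_in_idx = {int(i): j for j, i in enumerate(idx)}
        for parent, hap_vec in (("mat", truth.fetal_mat_hap), ("pat", truth.fetal_pat_hap)):
            sel, fP, fN = hmm.expected_fraction_arrays(informative, mother.hap1, est, parent)
            take = np.array([pos_in_idx[int(i)] for i in sel])
            path = hmm.viterbi_decode(panel.positions[sel], pc[take], nc[take], fP, fN, gm, parent)
            call = hmm.call_fetal_allele(path, gene)
            true_allele = State.P.value if hap_vec[0] == 1 else State.N.value
            total += 1
            if call.allele == true_allele:
                correct += 1
    return correct / total


def ff_estimator_bias(
    n_seeds: int = 50,
    depth: float = 400.0,
    n_snps: int = 300,
    true_ff: float = 0.132,
    error_rate: float = 0.001,
    seed: int = 0,
) -> float:
    """Signed bias (mean estimate minus truth) of the fetal-fraction
    estimator over repeated simulated pregnancies."""
    panel, mother, father = _constructed_family(n_snps // 2, n_snps)
    informative = isnp.classify_informative_snps(mother, father)
    gm = GeneticMap.uniform(int(panel.positions[0]), int(panel.positions[-1]))
    ests = []
    for k in range(n_seeds):
        truth = simdata.simulate_fetal_genome(
            mother, father, panel, gm, recombination=False, true_ff=true_ff,
            seed=seed * 1_000_003 + k)
        counts = simdata.simulate_plasma_counts(
            mother, father, truth, panel, depth_mean=depth, error_rate=error_rate,
            seed=seed * 2_000_003 + k)
        ests.append(isnp.estimate_fetal_fraction(counts, mother, father, informative))
    return float(np.mean(ests) - true_ff)


def cs_calibration(
    n_cases: int = 500,
    replicates: int = 1000,
    threshold: float = conf.DEFAULT_THRESHOLD,
    seed: int = 0,
) -> tuple[float, int, int]:
    """Empirical error rate among high-confidence calls.

    Each case draws an operating point (fetal fraction, depth, number of
    maternal-informative SNPs), simulates plasma counts under a random
    true inheritance state (no recombination), decodes and calls, then
    computes the CS.  Returns ``(error_rate_among_cs_ge_threshold,
    n_high_cs_calls, n_called)``.
    """
    rng = np.random.default_rng(seed)
    gm = GeneticMap.uniform(0, 2_000_000, 1.0)
    errors = high = called = 0
    for _ in range(n_cases):
        n = int(rng.choice([30, 60, 120]))
        depth_mean = float(rng.choice([50, 100, 200]))
        ff = float(rng.uniform(0.03, 0.20))
        positions = np.sort(rng.choice(np.arange(100_000, 1_900_000), n, replace=False))
        gene = (900_000, 1_100_000)
        # maternal-informative emissions, random father-hom subtype per SNP
        sub_p = rng.random(n) < 0.5
        fP = np.where(sub_p, (1 + ff) / 2, 0.5)
        fN = np.where(sub_p, 0.5, (1 - ff) / 2)
        true_state = State.P if rng.random() < 0.5 else State.N
        frac = fP if true_state == State.P else fN
        depths = rng.poisson(depth_mean, size=n)
        pc = rng.binomial(depths, frac)
        path = hmm.viterbi_decode(positions, pc, depths - pc, fP, fN, gm)
        call = hmm.call_fetal_allele(path, gene)
        if call.allele == "NO_CALL":
            continue
        called += 1
        cs = conf.confidence_score(
            n, depths, ff, call.allele, positions, fP, fN, gm, gene, "mat",
            replicates=replicates, threshold=threshold,
            seed=int(rng.integers(2**31)))
        if cs.cs >= threshold:
            high += 1
            if call.allele != true_state.value:
                errors += 1
    return (errors / high if high else 0.0), high, called


def crossover_case(inside_gene: bool) -> tuple[str, int]:
    """Deterministic recombination scenario.

    Twenty maternal-informative SNPs with counts strongly supporting state
    P on the left and state N on the right of a crossover placed either
    inside the gene interval (between its two flanking informative SNPs)
    or downstream of the gene.  Returns ``(call allele, n_segments)``.
    """
    n = 20
    positions = np.linspace(100_000, 2_000_000, n).astype(np.int64)
    gene = (900_000, 1_100_000)  # between SNPs 8 and 10
    ff = 0.15
    fP, fN = np.full(n, (1 + ff) / 2), np.full(n, 0.5)
    switch_at = 9 if inside_gene else 15  # first SNP emitting under N
    depth = np.full(n, 300)
    pc = np.empty(n, dtype=np.int64)
    pc[:switch_at] = np.round(depth[:switch_at] * (1 + ff) / 2).astype(np.int64)
    pc[switch_at:] = depth[switch_at:] // 2
    gm = GeneticMap.uniform(0, 2_100_000, 1.0)
    path = hmm.viterbi_decode(positions, pc, depth - pc, fP, fN, gm)
    call = hmm.call_fetal_allele(path, gene)
    return call.allele, len(path.segments)
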