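"""Monte-Carlo confidence score (CS) and the no-call decision.

The CS quantifies the probability that the pipeline's fetal-allele call is
correct given the experiment's operating point: fetal fraction, per-SNP
plasma depth and the number of parental informative SNPs.  Replicate
datasets are simulated under the called state from the binomial emission
model, each replicate is re-decoded (Viterbi) and re-called with the same
rules, and the CS is the fraction of replicates reproducing the call.
Calls with CS below the threshold (default 0.99) become no-calls.

The replicate decoders run as one vectorised Viterbi over all replicates
simultaneously, which is exactly equivalent to decoding them one by one.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom

from .genetic_map import GeneticMap, recombination_fraction
from .types import CSResult, FetalCall, HaplotypePath, State, path_segments

DEFAULT_THRESHOLD = 0.99
DEFAULT_REPLICATES = 1000


def _batch_viterbi(
    p_counts: np.ndarray,  # (R, n)
    depths: np.ndarray,  # (R, n)
    fractions_P: np.ndarray,  # (n,)
    fractions_N: np.ndarray,
    r: np.ndarray,  # (n-1,) recombination fractions
) -> np.ndarray:
    """Decode R replicate count vectors at once; returns (R, n) bool states
    (True = P).  Tie-breaking matches the scalar decoder: prefer the stay
    predecessor, prefer state P at the final argmax."""
    R, n = p_counts.shape
    logB = np.empty((R, n, 2))
    logB[:, :, 0] = binom.logpmf(p_counts, depths, fractions_P[None, :])
    logB[:, :, 1] = binom.logpmf(p_counts, depths, fractions_N[None, :])
    logB[depths == 0] = 0.0

    log_stay = np.log1p(-r)
    log_switch = np.log(r)
    delta = np.log(0.5) + logB[:, 0, :]  # (R, 2)
    ptr = np.zeros((R, n, 2), dtype=np.int8)
    for t in range(1, n):
        stay = delta + log_stay[t - 1]  # predecessor = same state
        switch = delta[:, ::-1] + log_switch[t - 1]  # predecessor = other state
        take_switch = switch > stay  # strict: ties prefer stay
        ptr[:, t, 0] = np.where(take_switch[:, 0], 1, 0)
        ptr[:, t, 1] = np.where(take_switch[:, 1], 0, 1)
        delta = np.maximum(stay, switch) + logB[:, t, :]

    states = np.empty((R, n), dtype=np.int8)
    states[:, -1] = np.where(delta[:, 0] >= delta[:, 1], 0, 1)
    rows = np.arange(R)
    for t in range(n - 1, 0, -1):
        states[:, t - 1] = ptr[rows, t, states[:, t]]
    return states == 0


def _call_from_states(
    states: np.ndarray,
    positions: np.ndarray,
    gene_interval: tuple[int, int],
    parent: str,
) -> str:
    from .rhdo_hmm import call_fetal_allele

    path = HaplotypePath(parent=parent, snp_positions=positions, states=states,
                         log_likelihood=0.0)
    return call_fetal_allele(path, gene_interval).allele


def batch_call(
    states: np.ndarray,  # (R, n) bool, True = P
    positions: np.ndarray,
    gene_interval: tuple[int, int],
) -> np.ndarray:
    """Vectorised genotype-call rule over replicate state paths.

    A segment spans the gene iff the states are constant from the last SNP
    at or before the gene start through the first SNP at or after the gene
    end; this is equivalent to the segment-based rule applied per path
    (verified against :func:`rhdo_hmm.call_fetal_allele` in the tests).
    """
    R, n = states.shape
    g0, g1 = gene_interval
    out = np.full(R, "NO_CALL", dtype=object)
    if g0 < positions[0] or g1 > positions[-1]:
        return out
    i0 = int(np.searchsorted(positions, g0, side="right") - 1)
    i1 = int(np.searchsorted(positions, g1, side="left"))
    block = states[:, i0:i1 + 1]
    out[block.all(axis=1)] = State.P.value
    out[(~block).all(axis=1)] = State.N.value
    return out


def confidence_score(
    n_informative: int,
    depth_profile: np.ndarray,
    ff: float,
    called_state: str,
    positions: np.ndarray,
    fractions_P: np.ndarray,
    fractions_N: np.ndarray,
    genetic_map: GeneticMap,
    gene_interval: tuple[int, int],
    parent: str = "mat",
    replicates: int = DEFAULT_REPLICATES,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = 0,
    map_function: str = "haldane",
) -> CSResult:
    """Simulated probability of reproducing the called fetal allele.

    Replicate depths are resampled with replacement from the observed
    per-SNP ``depth_profile`` (preserving depth heterogeneity); P-allele
    counts are then binomial at the expected fraction of the called state.
    Each replicate is Viterbi-decoded and passed through the genotype-call
    rules; CS is the fraction of replicates whose call equals
    ``called_state``.
    """
    if ff <= 0 or ff >= 1:
        raise ValueError("fetal fraction must lie in (0, 1)")
    if replicates < 100:
        raise ValueError("need at least 100 replicates")
    if called_state not in (State.P.value, State.N.value):
        raise ValueError("called_state must be 'P' or 'N'")
    if n_informative != len(positions):
        raise ValueError("n_informative does not match the SNP positions")
    rng = np.random.default_rng(seed)
    n = n_informative
    depth_profile = np.asarray(depth_profile, dtype=np.int64)
    frac = fractions_P if called_state == State.P.value else fractions_N

    depths = rng.choice(depth_profile, size=(replicates, n), replace=True)
    p_counts = rng.binomial(depths, frac[None, :])
    r = recombination_fraction(genetic_map.distances_cm(np.asarray(positions)), map_function)
    states = _batch_viterbi(p_counts, depths, fractions_P, fractions_N, r)

    positions = np.asarray(positions)
    calls = batch_call(states, positions, gene_interval)
    cs = float(np.mean(calls == called_state))
    return CSResult(cs=cs, replicates=replicates, threshold=threshold,
                    decision=apply_no_call(cs, threshold), seed=seed)


def apply_no_call(cs: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """No-call iff the confidence score is strictly below the threshold
    (a CS exactly at the threshold remains callable)."""
    if not 0.0 <= cs <= 1.0:
        raise ValueError("cs must lie in [0, 1]")
    return "NO_CALL" if cs < threshold else "CALL"


def attach_confidence(
    call: FetalCall,
    cs_result: CSResult,
) -> FetalCall:
    """Fold a CS into a fetal call: the allele is retained only when the
    call rules produced one and the CS clears the threshold."""
    call.cs = cs_result.cs
    if call.allele != "NO_CALL" and cs_result.decision == "NO_CALL":
        call.allele = "NO_CALL"
        call.reason = f"CS below threshold ({cs_result.cs:.4f} < {cs_result.threshold})"
    return call
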