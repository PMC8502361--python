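"""Genetic-map positions and recombination fractions.

A :class:`GeneticMap` interpolates centimorgan positions piecewise-linearly
in base pairs between its anchors; queries outside the anchored range are
clamped to the nearest anchor (zero extra genetic distance beyond the ends).
Genetic distance is converted to a recombination fraction with a map
function: Haldane (no crossover interference, the default) or Kosambi.
"""

from __future__ import annotations

import numpy as np

#: floor on the recombination fraction, preventing -inf log-transitions
#: between co-located SNPs
R_MIN = 1e-8


class GeneticMap:
    """Piecewise-linear bp -> cM map."""

    def __init__(self, bp: np.ndarray, cm: np.ndarray):
        bp = np.asarray(bp, dtype=np.float64)
        cm = np.asarray(cm, dtype=np.float64)
        if len(bp) != len(cm) or len(bp) < 2:
            raise ValueError("need >= 2 (bp, cM) anchor pairs")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("anchor bp positions must be strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise ValueError("cM positions must be non-decreasing")
        self.bp = bp
        self.cm = cm

    @classmethod
    def uniform(cls, start_bp: int, end_bp: int, cm_per_mb: float = 1.0) -> "GeneticMap":
        """A constant-rate map over a region (default 1 cM/Mb)."""
        span_cm = (end_bp - start_bp) / 1e6 * cm_per_mb
        return cls(np.array([start_bp, end_bp]), np.array([0.0, span_cm]))

    def cm_at(self, pos) -> np.ndarray:
        """Interpolated cM position; clamped outside the anchor range."""
        return np.interp(np.asarray(pos, dtype=np.float64), self.bp, self.cm)

    def distances_cm(self, positions: np.ndarray) -> np.ndarray:
        """Genetic distances between consecutive positions (length n-1)."""
        return np.diff(self.cm_at(positions))


def recombination_fraction(d_cm, map_function: str = "haldane") -> np.ndarray:
    """Map genetic distance (cM) to a recombination fraction.

    Haldane: r = (1 - exp(-2 d/100)) / 2; Kosambi: r = tanh(2 d/100) / 2.
    The result is floored at :data:`R_MIN` and capped at 0.5.
    """
    d = np.asarray(d_cm, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    m = d / 100.0  # Morgans
    if map_function == "haldane":
        r = 0.5 * (1.0 - np.exp(-2.0 * m))
    elif map_function == "kosambi":
        r = 0.5 * np.tanh(2.0 * m)
    else:
        raise ValueError(f"unknown map function: {map_function!r}")
    return np.clip(r, R_MIN, 0.5)


def transition_matrix(d_cm: float, map_function: str = "haldane") -> np.ndarray:
    """2x2 HMM transition matrix between the two inheritance states.

    Off-diagonal entries are the recombination fraction for the genetic
    distance ``d_cm`` between adjacent SNPs; rows sum to one.
    """
    r = float(recombination_fraction(d_cm, map_function))
    return np.array([[1.0 - r, r], [r, 1.0 - r]])
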