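"""Distance between simulated and measured cell populations.

The total distance is the maximum over the two cell lines of the two-sample
Kolmogorov-Smirnov distance on protein abundances, plus an additive penalty
mu * |m1 - m2| / (m1 + m2) on the difference in mean mRNA between the two
*simulated* lines.  qPCR shows near-equal mRNA levels in the two cell
lines, so any simulated between-line mRNA difference is penalised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .model import PopulationSample

__all__ = ["DistanceBreakdown", "ks_distance", "mrna_penalty",
           "total_distance"]


@dataclass(frozen=True)
class DistanceBreakdown:
    """Per-component decomposition; total == max(ks terms) + penalty."""

    ks_reference: float
    ks_regulated: float
    penalty: float
    mu: float

    @property
    def total(self) -> float:
        return max(self.ks_reference, self.ks_regulated) + self.penalty

    def to_json(self) -> str:
        return json.dumps({
            "ks_ref": self.ks_reference, "ks_reg": self.ks_regulated,
            "penalty": self.penalty, "total": self.total, "mu": self.mu,
        })


def ks_distance(sample_a, sample_b) -> float:
    """sup_x |ECDF_a(x) - ECDF_b(x)| over the pooled sample points.

    ECDFs are right-continuous (P(X <= x)); both one-sided gaps are taken
    at every pooled breakpoint, which is exact for step functions and
    handles ties across samples.  Symmetric in its arguments.
    """
    a = np.sort(np.asarray(sample_a, dtype=float).ravel())
    b = np.sort(np.asarray(sample_b, dtype=float).ravel())
    if a.size == 0 or b.size == 0:
        raise ValueError("KS distance requires two non-empty samples")
    pooled = np.concatenate([a, b])
    fa = np.searchsorted(a, pooled, side="right") / a.size
    fb = np.searchsorted(b, pooled, side="right") / b.size
    return float(np.max(np.abs(fa - fb)))


def mrna_penalty(avg_m1: float, avg_m2: float, mu: float) -> float:
    """Relative mRNA-difference penalty mu * |m1 - m2| / (m1 + m2)."""
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if avg_m1 < 0 or avg_m2 < 0:
        raise ValueError("mean mRNA levels must be >= 0")
    if avg_m1 + avg_m2 == 0:
        raise ValueError("mRNA penalty undefined when both means are zero")
    return mu * abs(avg_m1 - avg_m2) / (avg_m1 + avg_m2)


def total_distance(sim_ref: PopulationSample, sim_reg: PopulationSample,
                   data_ref: PopulationSample, data_reg: PopulationSample,
                   mu: float = 0.0) -> DistanceBreakdown:
    """Combine the per-line KS distances with the simulated-mRNA penalty."""
    ks_ref = ks_distance(sim_ref.protein, data_ref.protein)
    ks_reg = ks_distance(sim_reg.protein, data_reg.protein)
    if mu > 0:
        if sim_ref.mrna is None or sim_reg.mrna is None:
            raise ValueError(
                "mu > 0 requires simulated samples to carry mRNA values")
        penalty = mrna_penalty(float(sim_ref.mrna.mean()),
                               float(sim_reg.mrna.mean()), mu)
    else:
        penalty = 0.0
    return DistanceBreakdown(ks_reference=ks_ref, ks_regulated=ks_reg,
                             penalty=penalty, mu=mu)
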