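"""Synthetic inputs: gamma-emulated intensity fixtures and model-generated
validation datasets.

Two kinds of fixture stand in for data that cannot be downloaded:

* ``GAMMA_EMULATION`` draws per-cell intensities from the gamma fits
  reported for the two cell lines (MCF7: shape 9.05, scale 5.43e5, n=122;
  BE: shape 2.44, scale 5.19e6, n=400), reproducing the published means,
  CVs and sample sizes.

* ``MODEL_GENERATED`` simulates a reference population of 150 cells from
  known base rates and a regulated population of 300 cells in which exactly
  one reaction rate is changed by a large factor while the remaining rates
  receive a small multiplicative jitter — ground-truth datasets for
  validating the model-selection machinery.  Generating rates may be given
  before normalisation (d_m != 1); they are rescaled internally, which
  leaves the stationary law untouched.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .model import (CellLine, M0, PopulationSample, RateParameters,
                    SimulationConfig, simulate_population)
from .stats import CtRecord

__all__ = ["FixtureKind", "RegulatedReaction", "FixtureSpec",
           "REFERENCE_GAMMA", "REGULATED_GAMMA", "VALIDATION_RATES",
           "generate_gamma_fixture", "generate_validation_dataset",
           "generate_ct_fixture"]

# reported gamma fits: (shape, scale, n)
REFERENCE_GAMMA = (9.05, 5.43e5, 122)
REGULATED_GAMMA = (2.44, 5.19e6, 400)

# Base rates for validation datasets, given before normalisation (d_m = 2)
# to exercise the rescaling path.  Normalised: k1=4, k2=1.5e7, k3=12 --
# protein mean 5e6 a.u. with CV ~0.48 (reference line), i.e. the regime of
# the measured single-cell distributions, with protein turnover much faster
# than mRNA turnover as expected for basal p53.
VALIDATION_RATES: Dict[str, float] = {
    "k1": 8.0, "k2": 3.0e7, "k3": 24.0, "d_m": 2.0,
}


class FixtureKind(enum.Enum):
    GAMMA_EMULATION = "gamma"
    MODEL_GENERATED = "model"


class RegulatedReaction(enum.Enum):
    NONE = "none"
    TRANSCRIPTION = "transcription"
    TRANSLATION = "translation"
    PROTEIN_DEGRADATION = "protein_degradation"


@dataclass(frozen=True)
class FixtureSpec:
    """Full description of a synthetic dataset; bit-reproducible from
    (spec, seed)."""

    kind: FixtureKind = FixtureKind.GAMMA_EMULATION
    n_ref: int = REFERENCE_GAMMA[2]
    n_reg: int = REGULATED_GAMMA[2]
    gamma_ref: Tuple[float, float] = REFERENCE_GAMMA[:2]
    gamma_reg: Tuple[float, float] = REGULATED_GAMMA[:2]
    rates: Optional[Dict[str, float]] = None
    regulated_reaction: RegulatedReaction = RegulatedReaction.NONE
    regulation_magnitude: float = 8.0
    jitter: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_ref < 1 or self.n_reg < 1:
            raise ValueError("sample sizes must be >= 1")
        if self.regulation_magnitude <= 0:
            raise ValueError("regulation magnitude must be > 0")
        if not (0 <= self.jitter < 0.5):
            raise ValueError("jitter must lie in [0, 0.5)")
        if (self.regulated_reaction is RegulatedReaction.NONE
                and self.regulation_magnitude != 1.0
                and self.kind is FixtureKind.MODEL_GENERATED):
            raise ValueError(
                "regulated_reaction NONE requires regulation_magnitude == 1")


def validation_spec(reaction: RegulatedReaction,
                    magnitude: float = 8.0, jitter: float = 0.05,
                    n_ref: int = 150, n_reg: int = 300,
                    seed: int = 0) -> FixtureSpec:
    """Convenience constructor for the model-generated validation protocol."""
    return FixtureSpec(kind=FixtureKind.MODEL_GENERATED, n_ref=n_ref,
                       n_reg=n_reg, rates=dict(VALIDATION_RATES),
                       regulated_reaction=reaction,
                       regulation_magnitude=magnitude if reaction is not
                       RegulatedReaction.NONE else 1.0,
                       jitter=jitter, seed=seed)


def generate_gamma_fixture(spec: FixtureSpec
                           ) -> Tuple[PopulationSample, PopulationSample]:
    """Draw the two cell-line intensity samples from the reported gamma fits."""
    if spec.kind is not FixtureKind.GAMMA_EMULATION:
        raise ValueError("spec.kind must be GAMMA_EMULATION")
    rng = np.random.default_rng(spec.seed)
    ref = rng.gamma(spec.gamma_ref[0], spec.gamma_ref[1], spec.n_ref)
    reg = rng.gamma(spec.gamma_reg[0], spec.gamma_reg[1], spec.n_reg)
    return PopulationSample(protein=ref), PopulationSample(protein=reg)


def _normalised(raw: Dict[str, float]) -> RateParameters:
    d_m = float(raw.get("d_m", 1.0))
    if d_m <= 0:
        raise ValueError("d_m must be > 0")
    return RateParameters(k1=raw["k1"] / d_m, k2=raw["k2"] / d_m,
                          k3=raw["k3"] / d_m)


def generate_validation_dataset(spec: FixtureSpec,
                                cfg: Optional[SimulationConfig] = None
                                ) -> Tuple[PopulationSample, PopulationSample]:
    """Simulate ground-truth reference and regulated populations.

    The regulated line applies ``regulation_magnitude`` to exactly one
    reaction (transcription and translation rates are multiplied; protein
    degradation is divided, so a magnitude of 2.5 reads "2.5 times
    slower") and an independent uniform jitter in [1-j, 1+j] to every
    other rate.  Both samples keep their mRNA values.
    """
    if spec.kind is not FixtureKind.MODEL_GENERATED:
        raise ValueError("spec.kind must be MODEL_GENERATED")
    raw = dict(spec.rates or VALIDATION_RATES)
    base = _normalised(raw)
    if cfg is None:
        cfg = SimulationConfig(dt=0.05, t_end=30.0, method="exact")
    rng = np.random.default_rng(spec.seed)
    seeds = rng.integers(2 ** 31, size=2)

    jit = {name: float(rng.uniform(1 - spec.jitter, 1 + spec.jitter))
           for name in ("k1", "k2", "k3")}
    reac = spec.regulated_reaction
    reg_rates = {
        "k1": base.k1 * jit["k1"], "k2": base.k2 * jit["k2"],
        "k3": base.k3 * jit["k3"],
    }
    if reac is RegulatedReaction.TRANSCRIPTION:
        reg_rates["k1"] = base.k1 * spec.regulation_magnitude
    elif reac is RegulatedReaction.TRANSLATION:
        reg_rates["k2"] = base.k2 * spec.regulation_magnitude
    elif reac is RegulatedReaction.PROTEIN_DEGRADATION:
        reg_rates["k3"] = base.k3 / spec.regulation_magnitude

    ref = simulate_population(base, M0, CellLine.REFERENCE, spec.n_ref, cfg,
                              seed=int(seeds[0]))
    reg = simulate_population(RateParameters(**reg_rates), M0,
                              CellLine.REFERENCE, spec.n_reg, cfg,
                              seed=int(seeds[1]))
    return ref, reg


def generate_ct_fixture(relative_levels: Dict[str, float], seed: int = 0,
                        noise_sd: float = 0.0,
                        ct_housekeeping: float = 20.0,
                        ct_reference_target: float = 25.0
                        ) -> List[CtRecord]:
    """Construct C_T records whose comparative-CT analysis recovers the
    requested per-sample relative levels (exactly at zero cycle noise).

    The first entry of ``relative_levels`` is the reference sample and
    should map to 1.
    """
    if not relative_levels:
        raise ValueError("no samples requested")
    if any(v <= 0 for v in relative_levels.values()):
        raise ValueError("relative levels must be > 0")
    rng = np.random.default_rng(seed)
    records = []
    for name, ratio in relative_levels.items():
        ct_t = ct_reference_target - np.log2(ratio)
        if noise_sd > 0:
            ct_t += rng.normal(0, noise_sd)
        records.append(CtRecord(sample=name, ct_target=float(ct_t),
                                ct_housekeeping=ct_housekeeping))
    return records
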