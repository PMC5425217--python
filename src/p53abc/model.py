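"""Two-stage stochastic gene-expression model of basal p53 abundance.

The kinetic scheme has two species (mRNA and protein) and four first-order
reactions: transcription (rate ``k1``), translation (``k2`` per mRNA), mRNA
degradation (rate 1 -- the normaliser, so time is measured in mean mRNA
lifetimes) and protein degradation (``k3``, or ``k3 * p`` in the nonlinear
feedback variant, giving an effective degradation propensity ``k3 * p^2``).

Two cell lines share all rates except a single regulatory scale factor:
``s1`` multiplies transcription in the regulated line (model I), ``s2``
divides protein degradation (model II; ``s2 = 2.5`` reads "degradation 2.5
times slower").  Model 0 applies neither, model III applies both.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from . import _kernels

__all__ = [
    "RateParameters", "ModelVariant", "CellLine", "PopulationSample",
    "SimulationConfig", "Moments", "M0", "MI", "MII", "MIII",
    "effective_rates", "steady_state_moments", "simulate_population",
    "simulate_gillespie", "IntegrationError",
]


class IntegrationError(RuntimeError):
    """Raised when a trajectory leaves the finite domain or exceeds caps."""


@dataclass(frozen=True)
class RateParameters:
    """Normalised kinetic rates plus the regulatory scale factors.

    All rates are per unit time with the mean mRNA lifetime as the time
    unit; ``d_m`` is therefore pinned to 1 and construction rejects any
    other value.
    """

    k1: float
    k2: float
    k3: float
    s1: float = 1.0
    s2: float = 1.0
    d_m: float = 1.0

    def __post_init__(self):
        for name in ("k1", "k2", "k3", "s1", "s2"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if self.d_m != 1.0:
            raise ValueError(
                "d_m is the normaliser and must equal 1; rescale the other "
                "rates by the mRNA degradation rate instead")


@dataclass(frozen=True)
class ModelVariant:
    """A candidate regulatory hypothesis.

    ``id`` selects which scale factors act on the regulated cell line;
    ``nonlinear_degradation`` switches protein decay from k3*p to k3*p^2
    (feedback-like degradation).
    """

    id: str
    nonlinear_degradation: bool = False

    _IDS = ("M0", "MI", "MII", "MIII")

    def __post_init__(self):
        if self.id not in self._IDS:
            raise ValueError(f"model id must be one of {self._IDS}")

    @property
    def uses_s1(self) -> bool:
        return self.id in ("MI", "MIII")

    @property
    def uses_s2(self) -> bool:
        return self.id in ("MII", "MIII")

    @property
    def parameter_names(self) -> tuple:
        names = ["k1", "k2", "k3"]
        if self.uses_s1:
            names.append("s1")
        if self.uses_s2:
            names.append("s2")
        return tuple(names)


M0 = ModelVariant("M0")
MI = ModelVariant("MI")
MII = ModelVariant("MII")
MIII = ModelVariant("MIII")


class CellLine(enum.Enum):
    """REFERENCE maps to MCF7, REGULATED to BE; scale factors apply only to
    the regulated line."""

    REFERENCE = "reference"
    REGULATED = "regulated"


@dataclass
class PopulationSample:
    """Per-cell abundances for one cell line (simulated or measured)."""

    protein: np.ndarray
    mrna: Optional[np.ndarray] = None

    def __post_init__(self):
        self.protein = np.asarray(self.protein, dtype=float)
        if self.protein.ndim != 1 or self.protein.size == 0:
            raise ValueError("protein must be a non-empty 1-d array")
        if np.any(~np.isfinite(self.protein)) or np.any(self.protein < 0):
            raise ValueError("protein abundances must be finite and >= 0")
        if self.mrna is not None:
            self.mrna = np.asarray(self.mrna, dtype=float)
            if self.mrna.shape != self.protein.shape:
                raise ValueError("mrna must match protein in length")
            if np.any(~np.isfinite(self.mrna)) or np.any(self.mrna < 0):
                raise ValueError("mRNA abundances must be finite and >= 0")

    @property
    def n(self) -> int:
        return self.protein.size

    def to_frame(self):
        import pandas as pd

        d = {"cell_id": np.arange(self.n), "protein": self.protein}
        if self.mrna is not None:
            d["mrna"] = self.mrna
        return pd.DataFrame(d)


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical settings for population simulation.

    ``t_end`` is a lower bound on the horizon: for the linear model the run
    is automatically extended so that the protein (relaxation time 1/k3)
    has decayed its initial displacement from the stationary mean down to
    less than e^-10 of that mean -- at least ``10 / k3_eff``, more when the
    fixed initial condition starts far above the stationary level.
    ``method`` selects plain Euler-Maruyama ("euler") or the exponential
    linear-propagator variant ("exact"), see _kernels.
    """

    dt: float = 0.01
    t_end: float = 30.0
    protein_init: float = 4e6
    mrna_init: float = 100.0
    seed: Optional[int] = None
    method: str = "euler"
    max_ssa_events: int = 50_000_000

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.t_end < 10:
            raise ValueError("t_end must be >= 10 mRNA lifetimes")
        if self.protein_init < 0 or self.mrna_init < 0:
            raise ValueError("initial conditions must be >= 0")
        if self.method not in ("euler", "exact"):
            raise ValueError("method must be 'euler' or 'exact'")

    def horizon(self, k3_eff: float, rel_displacement: float = 0.0) -> float:
        return max(self.t_end,
                   (10.0 + np.log1p(rel_displacement)) / k3_eff)


def effective_rates(params: RateParameters, variant: ModelVariant,
                    line: CellLine) -> RateParameters:
    """Rates actually driving a given cell line under a given model.

    The reference line always uses the base rates; the regulated line gets
    ``k1 * s1`` (models I, III) and/or ``k3 / s2`` (models II, III).
    Model 0 leaves the regulated line untouched.
    """
    if line is CellLine.REFERENCE or variant.id == "M0":
        return replace(params, s1=1.0, s2=1.0)
    k1 = params.k1 * params.s1 if variant.uses_s1 else params.k1
    k3 = params.k3 / params.s2 if variant.uses_s2 else params.k3
    return RateParameters(k1=k1, k2=params.k2, k3=k3)


@dataclass(frozen=True)
class Moments:
    mean_m: float
    var_m: float
    mean_p: float
    var_p: float

    @property
    def cv_p(self) -> float:
        return float(np.sqrt(self.var_p) / self.mean_p)


def steady_state_moments(params: RateParameters, variant: ModelVariant = M0,
                         line: CellLine = CellLine.REFERENCE) -> Moments:
    """Closed-form stationary moments of the linear two-stage model.

    mRNA is Poisson (mean = variance = k1); the protein mean is k1*k2/k3 and
    its variance carries the translational amplification term
    ``var_p = mean_p * (1 + k2 / (1 + k3))``.  Serves as the analytic oracle
    for both stochastic simulators.
    """
    if variant.nonlinear_degradation:
        raise ValueError("closed-form moments exist only for the linear model")
    r = effective_rates(params, variant, line)
    mean_m = r.k1
    mean_p = r.k1 * r.k2 / r.k3
    var_p = mean_p * (1.0 + r.k2 / (1.0 + r.k3))
    return Moments(mean_m=mean_m, var_m=mean_m, mean_p=mean_p, var_p=var_p)


# Stiffness threshold for plain EM: substep so that k3_eff * h <= this.
_EM_STABILITY = 0.1


def _linear_horizon(r: RateParameters, cfg: SimulationConfig) -> float:
    mean_p = r.k1 * r.k2 / r.k3
    rel = abs(cfg.protein_init - mean_p) / mean_p
    return cfg.horizon(r.k3, rel)


def _resolve_seed(cfg: SimulationConfig, seed):
    if seed is None:
        seed = cfg.seed
    if seed is None:
        seed = np.random.SeedSequence().generate_state(1)[0]
    return int(seed) & 0x7FFFFFFF


def simulate_population(params: RateParameters, variant: ModelVariant,
                        line: CellLine, n: int, cfg: SimulationConfig,
                        seed: Optional[int] = None) -> PopulationSample:
    """Simulate n cells to the stationary horizon; returns final (m, p).

    Chemical-Langevin SDE integrated with the configured scheme from the
    fixed initial conditions.  Deterministic given a seed (taken from
    ``seed`` or ``cfg.seed``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    r = effective_rates(params, variant, line)
    t_end = cfg.t_end if variant.nonlinear_degradation \
        else _linear_horizon(r, cfg)
    n_steps = int(np.ceil(t_end / cfg.dt))
    sd = _resolve_seed(cfg, seed)
    if cfg.method == "exact":
        if variant.nonlinear_degradation:
            raise ValueError("method='exact' supports the linear model only")
        m, p = _kernels.exponential_em(
            r.k1, r.k2, r.k3, n, cfg.mrna_init, cfg.protein_init,
            cfg.dt, n_steps, sd)
    else:
        stiff = r.k3 * cfg.dt
        if variant.nonlinear_degradation:
            stiff = r.k3 * cfg.protein_init * cfg.dt
        substeps = max(1, int(np.ceil(stiff / _EM_STABILITY)))
        m, p = _kernels.euler_maruyama(
            r.k1, r.k2, r.k3, n, cfg.mrna_init, cfg.protein_init,
            cfg.dt, n_steps, substeps, variant.nonlinear_degradation, sd)
    if not (np.all(np.isfinite(m)) and np.all(np.isfinite(p))):
        raise IntegrationError(
            f"non-finite state integrating k1={r.k1:g} k2={r.k2:g} "
            f"k3={r.k3:g} dt={cfg.dt:g}")
    return PopulationSample(protein=p, mrna=m)


def simulate_gillespie(params: RateParameters, variant: ModelVariant,
                       line: CellLine, n: int, cfg: SimulationConfig,
                       seed: Optional[int] = None) -> PopulationSample:
    """Exact SSA oracle for small copy-number regimes (same contract)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    r = effective_rates(params, variant, line)
    t_end = cfg.t_end if variant.nonlinear_degradation \
        else _linear_horizon(r, cfg)
    sd = _resolve_seed(cfg, seed)
    mom = None
    if not variant.nonlinear_degradation:
        mom = steady_state_moments(r)
        expected = t_end * (r.k1 + mom.mean_m * (1 + r.k2) + r.k3 * mom.mean_p)
        if expected * n > cfg.max_ssa_events:
            raise IntegrationError(
                f"expected SSA event count {expected * n:.3g} exceeds cap "
                f"{cfg.max_ssa_events:g}; use the SDE simulator instead")
    m, p, ok = _kernels.gillespie(
        r.k1, r.k2, r.k3, n, round(cfg.mrna_init), round(cfg.protein_init),
        t_end, variant.nonlinear_degradation, cfg.max_ssa_events, sd)
    if not ok:
        raise IntegrationError("SSA event cap exceeded mid-run")
    return PopulationSample(protein=p, mrna=m)


# ---------------------------------------------------------------------------
# flat key-value (de)serialisation of parameter + simulation settings

def config_to_dict(params: RateParameters, variant: ModelVariant,
                   cfg: SimulationConfig) -> dict:
    return {
        "k1": params.k1, "k2": params.k2, "k3": params.k3,
        "s1": params.s1, "s2": params.s2,
        "model": variant.id, "nonlinear": variant.nonlinear_degradation,
        "dt": cfg.dt, "t_end": cfg.t_end,
        "protein_init": cfg.protein_init, "mrna_init": cfg.mrna_init,
        "seed": cfg.seed,
    }


def config_from_dict(d: dict):
    params = RateParameters(
        k1=float(d["k1"]), k2=float(d["k2"]), k3=float(d["k3"]),
        s1=float(d.get("s1", 1.0)), s2=float(d.get("s2", 1.0)))
    variant = ModelVariant(d.get("model", "M0"),
                           nonlinear_degradation=bool(d.get("nonlinear", False)))
    cfg = SimulationConfig(
        dt=float(d.get("dt", 0.01)), t_end=float(d.get("t_end", 30.0)),
        protein_init=float(d.get("protein_init", 4e6)),
        mrna_init=float(d.get("mrna_init", 100.0)),
        seed=None if d.get("seed") is None else int(d["seed"]),
        method=d.get("method", "euler"))
    return params, variant, cfg


def save_config(path, params, variant, cfg):
    d = config_to_dict(params, variant, cfg)
    text = str(path)
    if text.endswith((".yml", ".yaml")):
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
    else:
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


def load_config(path):
    text = str(path)
    if text.endswith((".yml", ".yaml")):
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            d = json.load(fh)
    return config_from_dict(d)
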