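"""ABC-SMC parameter inference and model selection.

Likelihood-free Bayesian comparison of the candidate regulatory models
(transcription- vs degradation-based control, optionally neither or both).
A weighted particle population over (model, parameters) is propagated
through a schedule of decreasing distance thresholds; each threshold is the
two-sample KS critical value at an increasing significance level alpha_i,
ending at alpha_f = 0.5.  Per-model evidence is the weighted fraction of
accepted particles carrying that model.

The particle transition (model resampling with a stay probability,
component-wise uniform parameter kernel, importance weights of the form
prior / kernel-smoothed previous population) follows the standard SMC
model-selection construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from scipy.special import gammainc

from .distance import DistanceBreakdown, ks_distance, mrna_penalty
from .model import (CellLine, ModelVariant, PopulationSample, RateParameters,
                    SimulationConfig, effective_rates, simulate_population,
                    steady_state_moments)

__all__ = [
    "PriorInterval", "PriorSpec", "ThresholdSchedule", "Particle",
    "SMCPopulation", "ks_critical_value", "sample_prior", "perturb_particle",
    "importance_weight", "run_abc_smc", "evidence", "posterior_summary",
    "AbundanceRegulationABC", "ABCSMCResults", "SMCStallError",
]

log = logging.getLogger("p53abc")


class SMCStallError(RuntimeError):
    """Threshold schedule too aggressive for the data/model combination."""


# ---------------------------------------------------------------------------
# priors

@dataclass(frozen=True)
class PriorInterval:
    """Uniform (or log-uniform) prior range for one rate parameter."""

    low: float
    high: float
    log: bool = False

    def __post_init__(self):
        if not (0 < self.low < self.high):
            raise ValueError("prior bounds must satisfy 0 < low < high")

    def sample(self, rng: np.random.Generator) -> float:
        if self.log:
            return float(np.exp(rng.uniform(np.log(self.low),
                                            np.log(self.high))))
        return float(rng.uniform(self.low, self.high))

    def pdf(self, x: float) -> float:
        if not (self.low <= x <= self.high):
            return 0.0
        if self.log:
            return 1.0 / (x * (np.log(self.high) - np.log(self.low)))
        return 1.0 / (self.high - self.low)

    def transform(self, x: float) -> float:
        """Map to the space in which the perturbation kernel is uniform."""
        return math.log(x) if self.log else x

    def untransform(self, y: float) -> float:
        return math.exp(y) if self.log else y


@dataclass(frozen=True)
class PriorSpec:
    """Per-parameter priors; each model uses its active subset.

    Defaults are the broad empirical-study ranges: they let the reference
    line reach protein means of ~5e6 a.u. with single-digit-to-tens mRNA
    counts, and allow fast protein turnover (k3 >> 1), which the reported
    gamma shapes require under degradation-based regulation.
    """

    k1: PriorInterval = PriorInterval(1.0, 20.0)
    k2: PriorInterval = PriorInterval(1e4, 1e9, log=True)
    k3: PriorInterval = PriorInterval(0.5, 50.0)
    s1: PriorInterval = PriorInterval(0.1, 10.0)
    s2: PriorInterval = PriorInterval(0.1, 10.0)

    def interval(self, name: str) -> PriorInterval:
        return getattr(self, name)

    def sample_theta(self, variant: ModelVariant,
                     rng: np.random.Generator) -> np.ndarray:
        return np.array([self.interval(p).sample(rng)
                         for p in variant.parameter_names])

    def density(self, variant: ModelVariant, theta: np.ndarray) -> float:
        d = 1.0
        for name, x in zip(variant.parameter_names, theta):
            d *= self.interval(name).pdf(float(x))
        return d

    def contains(self, variant: ModelVariant, theta: np.ndarray) -> bool:
        return all(self.interval(n).low <= x <= self.interval(n).high
                   for n, x in zip(variant.parameter_names, theta))


# ---------------------------------------------------------------------------
# thresholds

def ks_critical_value(alpha: float, n1: int, n2: int) -> float:
    """Asymptotic two-sample KS critical value c(alpha)*sqrt((n1+n2)/(n1*n2)).

    c(alpha) = sqrt(-ln(alpha/2) / 2); strictly decreasing in alpha and in
    both sample sizes.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    c = math.sqrt(-math.log(alpha / 2.0) / 2.0)
    return c * math.sqrt((n1 + n2) / (n1 * n2))


# Entry rungs at tiny alpha keep the first-iteration (prior-predictive)
# acceptance workable on one CPU; the final significance level is 0.5.
DEFAULT_ALPHAS = (1e-9, 1e-6, 1e-4, 0.001, 0.005, 0.01, 0.05, 0.1, 0.2,
                  0.3, 0.4, 0.5)


@dataclass(frozen=True)
class ThresholdSchedule:
    """Increasing KS significance levels ending at alpha_f = 0.5."""

    alphas: Tuple[float, ...] = DEFAULT_ALPHAS

    def __post_init__(self):
        a = tuple(float(x) for x in self.alphas)
        object.__setattr__(self, "alphas", a)
        if len(a) == 0 or any(x2 <= x1 for x1, x2 in zip(a, a[1:])):
            raise ValueError("alphas must be strictly increasing")
        if a[-1] != 0.5:
            raise ValueError("the final significance level must be 0.5")

    def epsilons(self, n_ref: int, n_reg: int) -> np.ndarray:
        return np.array([ks_critical_value(a, n_ref, n_reg)
                         for a in self.alphas])

    def __len__(self):
        return len(self.alphas)


# ---------------------------------------------------------------------------
# particles and populations

@dataclass
class Particle:
    model_id: str
    theta: np.ndarray
    weight: float = 1.0
    distance: Optional[DistanceBreakdown] = None


@dataclass
class SMCPopulation:
    """One accepted, weighted particle population (a single SMC iteration)."""

    particles: List[Particle]
    iteration: int
    alpha: float
    epsilon: float
    n_proposed: int
    model_ids: Tuple[str, ...]

    def __post_init__(self):
        w = np.array([p.weight for p in self.particles])
        if w.size == 0 or np.any(w < 0):
            raise ValueError("population needs particles with weights >= 0")

    @property
    def n(self) -> int:
        return len(self.particles)

    @property
    def acceptance_rate(self) -> float:
        return self.n / self.n_proposed if self.n_proposed else float("nan")

    def normalise(self):
        w = np.array([p.weight for p in self.particles])
        total = w.sum()
        if total <= 0:
            raise ZeroDivisionError("all particle weights vanished")
        for p in self.particles:
            p.weight /= total

    @property
    def evidence(self) -> Dict[str, float]:
        ev = {m: 0.0 for m in self.model_ids}
        for p in self.particles:
            ev[p.model_id] += p.weight
        return ev

    def subset(self, model_id: str) -> Tuple[np.ndarray, np.ndarray]:
        """(thetas, weights) of the particles carrying ``model_id``."""
        rows = [p for p in self.particles if p.model_id == model_id]
        if not rows:
            return np.empty((0, 0)), np.empty(0)
        return (np.array([p.theta for p in rows]),
                np.array([p.weight for p in rows]))


def evidence(population: SMCPopulation) -> Dict[str, float]:
    """Weighted per-model fraction of the population (sums to 1)."""
    ev = population.evidence
    total = sum(ev.values())
    return {m: v / total for m, v in ev.items()}


def _weighted_quantile(x, w, q):
    order = np.argsort(x)
    x, w = np.asarray(x)[order], np.asarray(w)[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return np.interp(q, cw, x)


def posterior_summary(population: SMCPopulation, variant: ModelVariant,
                      ci: float = 0.95) -> pd.DataFrame:
    """Weighted posterior mean, sd and central credible interval."""
    thetas, w = population.subset(variant.id)
    if thetas.size == 0:
        raise ValueError(f"no particles of model {variant.id} in population")
    w = w / w.sum()
    lo, hi = (1 - ci) / 2, 1 - (1 - ci) / 2
    rows = {}
    for j, name in enumerate(variant.parameter_names):
        x = thetas[:, j]
        mean = float(np.sum(w * x))
        sd = float(np.sqrt(np.sum(w * (x - mean) ** 2)))
        qlo, qhi = _weighted_quantile(x, w, [lo, hi])
        rows[name] = {"mean": mean, "sd": sd,
                      f"ci{100 * lo:g}": float(qlo),
                      f"ci{100 * hi:g}": float(qhi)}
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# proposal machinery

def sample_prior(prior: PriorSpec, models: Sequence[ModelVariant],
                 model_prior: np.ndarray, rng: np.random.Generator) -> Particle:
    """Draw (model, theta) from the model prior and the parameter priors."""
    idx = rng.choice(len(models), p=model_prior)
    variant = models[idx]
    return Particle(model_id=variant.id,
                    theta=prior.sample_theta(variant, rng))


def _kernel_halfwidths(prior: PriorSpec, variant: ModelVariant,
                       thetas: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Per-component kernel half-width: ``scale`` times half the range of
    the previous population (transformed space for log-uniform
    components).  ``scale`` trades exploration against acceptance rate and
    is corrected for by the importance weights either way."""
    h = np.empty(thetas.shape[1])
    for j, name in enumerate(variant.parameter_names):
        iv = prior.interval(name)
        t = np.array([iv.transform(x) for x in thetas[:, j]])
        h[j] = scale * 0.5 * (t.max() - t.min())
    return h


def perturb_particle(theta: np.ndarray, variant: ModelVariant,
                     prior: PriorSpec, halfwidths: np.ndarray,
                     rng: np.random.Generator,
                     max_tries: int = 1000) -> np.ndarray:
    """Component-wise uniform perturbation, rejected back into the prior box."""
    names = variant.parameter_names
    for _ in range(max_tries):
        out = np.empty_like(theta)
        for j, name in enumerate(names):
            iv = prior.interval(name)
            y = iv.transform(float(theta[j]))
            if halfwidths[j] > 0:
                y += rng.uniform(-halfwidths[j], halfwidths[j])
            out[j] = iv.untransform(y)
        if prior.contains(variant, out):
            return out
    raise RuntimeError("perturbation failed to re-enter the prior support")


def _kernel_density(prior: PriorSpec, variant: ModelVariant,
                    theta: np.ndarray, thetas_prev: np.ndarray,
                    w_prev: np.ndarray, halfwidths: np.ndarray) -> float:
    """Mixture density sum_j w_j K(theta | theta_j) of the uniform kernel."""
    names = variant.parameter_names
    t = np.array([prior.interval(n).transform(float(x))
                  for n, x in zip(names, theta)])
    tp = np.column_stack([
        [prior.interval(n).transform(float(x)) for x in thetas_prev[:, j]]
        for j, n in enumerate(names)])
    inside = np.ones(len(tp), dtype=bool)
    dens = 1.0
    for j in range(len(names)):
        if halfwidths[j] > 0:
            inside &= np.abs(tp[:, j] - t[j]) <= halfwidths[j] * (1 + 1e-12)
            dens /= 2.0 * halfwidths[j]
    # log-uniform components carry the Jacobian of the log map
    jac = 1.0
    for n, x in zip(names, theta):
        if prior.interval(n).log:
            jac /= float(x)
    return float(np.sum(w_prev[inside])) * dens * jac


def importance_weight(particle: Particle, variant: ModelVariant,
                      prior: PriorSpec, model_prior_prob: float,
                      transition_mass: float, thetas_prev: np.ndarray,
                      w_prev: np.ndarray, halfwidths: np.ndarray) -> float:
    """prior(model, theta) / [model-transition mass * kernel mixture]."""
    num = model_prior_prob * prior.density(variant, particle.theta)
    den = transition_mass * _kernel_density(
        prior, variant, particle.theta, thetas_prev, w_prev, halfwidths)
    if den <= 0:
        raise ZeroDivisionError(
            "degenerate importance-weight denominator (empty kernel support)")
    return num / den


# ---------------------------------------------------------------------------
# analytic pre-screen (lazy early rejection)

def _surrogate_ks(params: RateParameters, data_sorted: np.ndarray) -> float:
    """KS of the gamma moment-surrogate of the stationary protein law
    against a sorted data sample.

    The linear two-stage model's stationary protein distribution is
    gamma-like at translation rates >> 1; matching its first two moments
    gives a surrogate whose KS to the data tracks the simulated KS to
    within a couple of percent.  Used only to skip simulating proposals
    that are bound to miss by a wide margin.
    """
    mom = steady_state_moments(params)
    shape = mom.mean_p ** 2 / mom.var_p
    f = gammainc(shape, data_sorted * (mom.mean_p / mom.var_p))
    n = data_sorted.size
    i = np.arange(1, n + 1)
    return float(max(np.max(i / n - f), np.max(f - (i - 1) / n)))


# ---------------------------------------------------------------------------
# main SMC loop

def run_abc_smc(models: Sequence[ModelVariant], prior: PriorSpec,
                data_ref: PopulationSample, data_reg: PopulationSample,
                schedule: ThresholdSchedule = ThresholdSchedule(),
                mu: float = 0.0, n_particles: int = 3000,
                cfg: SimulationConfig = SimulationConfig(),
                seed: Optional[int] = None,
                model_prior: Optional[Sequence[float]] = None,
                stay_prob: float = 0.75,
                min_acceptance: float = 1e-4,
                max_proposals: int = 1_000_000,
                on_stall: str = "raise",
                prescreen_margin: Optional[float] = 0.1,
                kernel_scale: float = 1.0) -> List[SMCPopulation]:
    """Run the full ABC-SMC model-selection loop.

    Per iteration t, proposals are drawn (from the prior at t=1, otherwise
    by resampling and perturbing the previous population), both cell lines
    are simulated at the data sample sizes, and the proposal is accepted if
    the total distance is <= eps_t, until ``n_particles`` acceptances.

    ``on_stall`` controls behaviour when an iteration cannot reach the
    particle count within the proposal budget / acceptance floor: "raise"
    aborts with :class:`SMCStallError`; "stop" concludes the run and
    returns the populations completed so far (the tightest threshold the
    data supports).

    ``prescreen_margin`` enables lazy early rejection: a proposal whose
    moment-surrogate KS (see :func:`_surrogate_ks`) already exceeds
    ``eps + margin`` for either line is rejected without simulating.  The
    margin is far larger than the surrogate's error, so the accepted
    distribution is unaffected; set to None to disable (always disabled
    for nonlinear-degradation variants, which have no closed-form
    surrogate).
    """
    if on_stall not in ("raise", "stop"):
        raise ValueError("on_stall must be 'raise' or 'stop'")
    models = list(models)
    ids = tuple(m.id for m in models)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate model ids")
    by_id = {m.id: m for m in models}
    if model_prior is None:
        model_prior = np.full(len(models), 1.0 / len(models))
    else:
        model_prior = np.asarray(model_prior, dtype=float)
        if len(model_prior) != len(models) or not np.isclose(model_prior.sum(), 1):
            raise ValueError("model_prior must sum to 1 over the models")

    rng = np.random.default_rng(seed)
    epsilons = schedule.epsilons(data_ref.n, data_reg.n)
    populations: List[SMCPopulation] = []

    ref_sorted = np.sort(data_ref.protein)
    reg_sorted = np.sort(data_reg.protein)

    def simulate_pair(variant, theta, eps):
        params = _theta_to_params(variant, theta)
        screen = prescreen_margin is not None and \
            not variant.nonlinear_degradation
        if screen:
            p_ref = effective_rates(params, variant, CellLine.REFERENCE)
            if _surrogate_ks(p_ref, ref_sorted) > eps + prescreen_margin:
                return None
            p_reg = effective_rates(params, variant, CellLine.REGULATED)
            if _surrogate_ks(p_reg, reg_sorted) > eps + prescreen_margin:
                return None
        s_ref = simulate_population(params, variant, CellLine.REFERENCE,
                                    data_ref.n, cfg,
                                    seed=int(rng.integers(2 ** 31)))
        ks_ref = ks_distance(s_ref.protein, data_ref.protein)
        if ks_ref > eps:  # total >= ks_ref: cheap early rejection
            return None
        s_reg = simulate_population(params, variant, CellLine.REGULATED,
                                    data_reg.n, cfg,
                                    seed=int(rng.integers(2 ** 31)))
        ks_reg = ks_distance(s_reg.protein, data_reg.protein)
        pen = (mrna_penalty(float(s_ref.mrna.mean()),
                            float(s_reg.mrna.mean()), mu) if mu > 0 else 0.0)
        d = DistanceBreakdown(ks_reference=ks_ref, ks_regulated=ks_reg,
                              penalty=pen, mu=mu)
        return d if d.total <= eps else None

    for t, (alpha, eps) in enumerate(zip(schedule.alphas, epsilons), start=1):
        accepted: List[Particle] = []
        proposed = 0
        if populations:
            prev = populations[-1]
            prev_ev = evidence(prev)
            alive = [m for m in ids if prev_ev[m] > 0]
            marginal = np.array([prev_ev[m] for m in alive])
            marginal /= marginal.sum()
            cache = {}
            for m in alive:
                thetas_m, w_m = prev.subset(m)
                w_m = w_m / w_m.sum()
                cache[m] = (thetas_m, w_m,
                            _kernel_halfwidths(prior, by_id[m], thetas_m,
                                               kernel_scale))

            def transition_mass(m_new):
                # sum_m' P(m') T(m' -> m_new) over alive source models
                tot = 0.0
                for i, m_src in enumerate(alive):
                    if m_src == m_new:
                        tot += marginal[i] * (stay_prob if len(alive) > 1 else 1.0)
                    else:
                        tot += marginal[i] * (1 - stay_prob) / (len(alive) - 1)
                return tot

        while len(accepted) < n_particles:
            if proposed >= max_proposals or (
                    proposed >= 20_000 and
                    len(accepted) / proposed < min_acceptance):
                msg = (f"iteration {t} (alpha={alpha}, eps={eps:.4f}) stalled: "
                       f"{len(accepted)}/{proposed} accepted")
                if on_stall == "raise":
                    raise SMCStallError(msg)
                log.warning("%s; concluding at the previous threshold", msg)
                return populations
            proposed += 1
            if not populations:
                part = sample_prior(prior, models, model_prior, rng)
                d = simulate_pair(by_id[part.model_id], part.theta, eps)
                if d is None:
                    continue
                part.distance = d
                part.weight = 1.0
                accepted.append(part)
            else:
                i0 = rng.choice(len(alive), p=marginal)
                if len(alive) > 1 and rng.random() >= stay_prob:
                    others = [m for m in alive if m != alive[i0]]
                    m_new = others[rng.integers(len(others))]
                else:
                    m_new = alive[i0]
                variant = by_id[m_new]
                thetas_m, w_m, hw = cache[m_new]
                src = thetas_m[rng.choice(len(w_m), p=w_m)]
                theta = perturb_particle(src, variant, prior, hw, rng)
                d = simulate_pair(variant, theta, eps)
                if d is None:
                    continue
                part = Particle(model_id=m_new, theta=theta, distance=d)
                mp = float(model_prior[ids.index(m_new)])
                part.weight = importance_weight(
                    part, variant, prior, mp, transition_mass(m_new),
                    thetas_m, w_m, hw)
                accepted.append(part)

        pop = SMCPopulation(particles=accepted, iteration=t, alpha=alpha,
                            epsilon=float(eps), n_proposed=proposed,
                            model_ids=ids)
        pop.normalise()
        populations.append(pop)
        ev = evidence(pop)
        log.info("iter %d alpha=%.3g eps=%.4f proposals=%d acc=%.3g "
                 "evidence=%s", t, alpha, eps, proposed,
                 pop.acceptance_rate,
                 {m: round(v, 3) for m, v in ev.items()})
    return populations


def _theta_to_params(variant: ModelVariant, theta: np.ndarray) -> RateParameters:
    kw = dict(zip(variant.parameter_names, (float(x) for x in theta)))
    return RateParameters(**kw)


# ---------------------------------------------------------------------------
# statsmodels-style front end

class AbundanceRegulationABC:
    """Model-selection analysis of two single-cell abundance samples.

    Parameters
    ----------
    data_ref, data_reg : PopulationSample
        Measured (or emulated) per-cell protein abundances for the
        reference (MCF7-like) and regulated (BE-like) cell line.
    models : sequence of ModelVariant
        Candidate regulatory hypotheses, default (MI, MII).
    priors : PriorSpec
    schedule : ThresholdSchedule
    mu : float
        Weight of the mRNA-difference penalty.
    n_particles : int
        Accepted particles per SMC iteration (3000 in the full study).
    sim_config : SimulationConfig

    Examples
    --------
    >>> mdl = AbundanceRegulationABC(ref, reg, mu=0.1, n_particles=500)
    >>> res = mdl.fit(seed=1)
    >>> print(res.summary())
    """

    def __init__(self, data_ref: PopulationSample, data_reg: PopulationSample,
                 models: Sequence[ModelVariant] = (ModelVariant("MI"),
                                                   ModelVariant("MII")),
                 priors: Optional[PriorSpec] = None,
                 schedule: Optional[ThresholdSchedule] = None,
                 mu: float = 0.0, n_particles: int = 3000,
                 sim_config: Optional[SimulationConfig] = None,
                 model_prior: Optional[Sequence[float]] = None,
                 stay_prob: float = 0.75, min_acceptance: float = 1e-4,
                 max_proposals: int = 1_000_000, on_stall: str = "raise",
                 prescreen_margin: float = 0.1, kernel_scale: float = 1.0):
        self.data_ref = data_ref
        self.data_reg = data_reg
        self.models = list(models)
        self.priors = priors or PriorSpec()
        self.schedule = schedule or ThresholdSchedule()
        self.mu = mu
        self.n_particles = n_particles
        self.sim_config = sim_config or SimulationConfig()
        self.model_prior = model_prior
        self.stay_prob = stay_prob
        self.min_acceptance = min_acceptance
        self.max_proposals = max_proposals
        self.on_stall = on_stall
        self.prescreen_margin = prescreen_margin
        self.kernel_scale = kernel_scale

    @classmethod
    def from_csv(cls, path_ref, path_reg, **kwargs):
        from .io import read_intensity_csv

        return cls(read_intensity_csv(path_ref), read_intensity_csv(path_reg),
                   **kwargs)

    def fit(self, seed: Optional[int] = None,
            n_particles: Optional[int] = None) -> "ABCSMCResults":
        pops = run_abc_smc(
            self.models, self.priors, self.data_ref, self.data_reg,
            schedule=self.schedule, mu=self.mu,
            n_particles=n_particles or self.n_particles,
            cfg=self.sim_config, seed=seed, model_prior=self.model_prior,
            stay_prob=self.stay_prob, min_acceptance=self.min_acceptance,
            max_proposals=self.max_proposals, on_stall=self.on_stall,
            prescreen_margin=self.prescreen_margin,
            kernel_scale=self.kernel_scale)
        if not pops:
            raise SMCStallError("no iteration completed; loosen the schedule")
        return ABCSMCResults(self, pops)


class ABCSMCResults:
    """Fitted ABC-SMC run: evidence trajectory, posteriors, diagnostics."""

    def __init__(self, model: AbundanceRegulationABC,
                 populations: List[SMCPopulation]):
        self.model = model
        self.populations = populations

    @property
    def final(self) -> SMCPopulation:
        return self.populations[-1]

    @property
    def completed_schedule(self) -> bool:
        return len(self.populations) == len(self.model.schedule)

    @property
    def evidence_trajectory(self) -> pd.DataFrame:
        rows = []
        for pop in self.populations:
            r = {"iteration": pop.iteration, "alpha": pop.alpha,
                 "epsilon": pop.epsilon,
                 "acceptance_rate": pop.acceptance_rate}
            r.update(evidence(pop))
            rows.append(r)
        return pd.DataFrame(rows).set_index("iteration")

    @property
    def best_model(self) -> ModelVariant:
        ev = evidence(self.final)
        best = max(ev, key=ev.get)
        return next(m for m in self.model.models if m.id == best)

    def posterior_summary(self, variant: Optional[ModelVariant] = None,
                          ci: float = 0.95) -> pd.DataFrame:
        return posterior_summary(self.final, variant or self.best_model, ci)

    def summary(self) -> str:
        ev = evidence(self.final)
        lines = [
            "ABC-SMC model selection of basal expression regulation",
            "=" * 56,
            f"cell-line samples: n_ref={self.model.data_ref.n}, "
            f"n_reg={self.model.data_reg.n}",
            f"particles per iteration: {self.final.n};  mu = {self.model.mu}",
            f"iterations completed: {len(self.populations)}/"
            f"{len(self.model.schedule)} "
            f"(final alpha={self.final.alpha:g}, eps={self.final.epsilon:.4f})",
            "",
            "model evidence (final population):",
        ]
        for m, v in ev.items():
            lines.append(f"    {m:5s} {v:8.4f}")
        best = self.best_model
        lines += ["", f"posterior summary ({best.id}):",
                  self.posterior_summary(best).to_string(
                      float_format=lambda v: f"{v:.4g}")]
        return "\n".join(lines)

    def particles_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.final.particles:
            r = {"model": p.model_id, "weight": p.weight,
                 "distance": p.distance.total if p.distance else np.nan}
            variant = next(m for m in self.model.models if m.id == p.model_id)
            r.update(dict(zip(variant.parameter_names, p.theta)))
            rows.append(r)
        return pd.DataFrame(rows)

    def plot_evidence(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        traj = self.evidence_trajectory
        for m in (m.id for m in self.model.models):
            ax.plot(traj.index, traj[m], marker="o", label=m)
        ax.set_xlabel("SMC iteration")
        ax.set_ylabel("model evidence")
        ax.set_ylim(-0.02, 1.02)
        ax.legend()
        return ax
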