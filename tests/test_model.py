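"""Kinetic model: effective rates, analytic moments, SDE and SSA simulators."""

import numpy as np
import pytest

import p53abc as pa
from p53abc.model import config_from_dict, config_to_dict, load_config, \
    save_config


class TestRateParameters:
    def test_rejects_nonunit_mrna_degradation(self):
        with pytest.raises(ValueError, match="d_m"):
            pa.RateParameters(k1=1, k2=1, k3=1, d_m=2.0)

    @pytest.mark.parametrize("bad", [dict(k1=0), dict(k2=-1), dict(k3=0),
                                     dict(s1=0), dict(s2=-2)])
    def test_rejects_nonpositive_rates(self, bad):
        kw = dict(k1=1.0, k2=1.0, k3=1.0)
        kw.update(bad)
        with pytest.raises(ValueError):
            pa.RateParameters(**kw)


class TestEffectiveRates:
    def test_degradation_slowdown_divides_k3(self):
        p = pa.RateParameters(k1=10, k2=1, k3=0.5, s2=2.5)
        eff = pa.effective_rates(p, pa.MII, pa.CellLine.REGULATED)
        assert eff.k3 == pytest.approx(0.2)
        assert eff.k1 == 10

    def test_transcription_scaling_multiplies_k1(self):
        p = pa.RateParameters(k1=10, k2=1, k3=1, s1=3)
        eff = pa.effective_rates(p, pa.MI, pa.CellLine.REGULATED)
        assert eff.k1 == pytest.approx(30)
        assert eff.k3 == 1

    def test_null_model_is_identity_on_regulated_line(self):
        p = pa.RateParameters(k1=7, k2=2, k3=0.3, s1=5, s2=5)
        eff = pa.effective_rates(p, pa.M0, pa.CellLine.REGULATED)
        assert (eff.k1, eff.k2, eff.k3) == (7, 2, 0.3)

    def test_reference_line_never_scaled(self):
        p = pa.RateParameters(k1=7, k2=2, k3=0.3, s1=5, s2=5)
        for variant in (pa.MI, pa.MII, pa.MIII):
            eff = pa.effective_rates(p, variant, pa.CellLine.REFERENCE)
            assert (eff.k1, eff.k2, eff.k3) == (7, 2, 0.3)

    def test_combined_model_applies_both_factors(self):
        p = pa.RateParameters(k1=10, k2=1, k3=0.5, s1=2, s2=2.5)
        eff = pa.effective_rates(p, pa.MIII, pa.CellLine.REGULATED)
        assert (eff.k1, eff.k3) == (pytest.approx(20), pytest.approx(0.2))


class TestSteadyStateMoments:
    def test_closed_form_example(self):
        mom = pa.steady_state_moments(pa.RateParameters(k1=100, k2=10, k3=0.1))
        assert mom.mean_m == pytest.approx(100)
        assert mom.var_m == pytest.approx(100)
        assert mom.mean_p == pytest.approx(10000)
        assert mom.var_p / mom.mean_p == pytest.approx(1 + 10 / 1.1)

    def test_unit_rates(self):
        mom = pa.steady_state_moments(pa.RateParameters(k1=1, k2=1, k3=1))
        assert mom.mean_p == pytest.approx(1)
        assert mom.var_p == pytest.approx(1.5)

    def test_slowdown_scales_protein_mean_linearly(self):
        p = pa.RateParameters(k1=5, k2=2, k3=1, s2=2)
        ref = pa.steady_state_moments(p, pa.MII, pa.CellLine.REFERENCE)
        reg = pa.steady_state_moments(p, pa.MII, pa.CellLine.REGULATED)
        assert reg.mean_p == pytest.approx(2 * ref.mean_p)

    def test_nonlinear_variant_unsupported(self):
        nl = pa.ModelVariant("MII", nonlinear_degradation=True)
        with pytest.raises(ValueError, match="linear"):
            pa.steady_state_moments(pa.RateParameters(k1=1, k2=1, k3=1), nl)


# parameter grid spanning slow/fast protein turnover and burst sizes
MOMENT_GRID = [
    dict(k1=100, k2=10, k3=0.1),
    dict(k1=20, k2=100, k3=0.5),
    dict(k1=5, k2=1000, k3=1.0),
    dict(k1=10, k2=50, k3=2.0),
    dict(k1=3, k2=5000, k3=10.0),
]


class TestSDESimulator:
    @pytest.mark.parametrize("method", ["euler", "exact"])
    @pytest.mark.parametrize("kw", MOMENT_GRID,
                             ids=lambda kw: f"k3={kw['k3']}")
    def test_moments_match_closed_form(self, kw, method):
        """Population mean/variance agree with the analytic oracle (3 SE)."""
        p = pa.RateParameters(**kw)
        mom = pa.steady_state_moments(p)
        n = 1500
        cfg = pa.SimulationConfig(dt=0.02 if method == "euler" else 0.05,
                                  t_end=30, method=method)
        seed = int(kw["k3"] * 1000) + (1 if method == "exact" else 0)
        s = pa.simulate_population(p, pa.M0, pa.CellLine.REFERENCE, n, cfg,
                                   seed=seed)
        se_mean_p = np.sqrt(mom.var_p / n)
        assert s.protein.mean() == pytest.approx(mom.mean_p,
                                                 abs=3 * se_mean_p)
        se_mean_m = np.sqrt(mom.var_m / n)
        assert s.mrna.mean() == pytest.approx(mom.mean_m, abs=3 * se_mean_m)
        # variance SE via the fourth-moment formula, gamma-like kurtosis
        kurt = 3 + 6 / (mom.mean_p ** 2 / mom.var_p)
        se_var = mom.var_p * np.sqrt((kurt - 1) / n)
        assert s.protein.var() == pytest.approx(mom.var_p, abs=3.5 * se_var)

    def test_same_seed_reproduces_sample(self):
        p = pa.RateParameters(k1=100, k2=10, k3=0.1)
        cfg = pa.SimulationConfig(dt=0.05, t_end=30)
        a = pa.simulate_population(p, pa.M0, pa.CellLine.REFERENCE, 50, cfg,
                                   seed=7)
        b = pa.simulate_population(p, pa.M0, pa.CellLine.REFERENCE, 50, cfg,
                                   seed=7)
        np.testing.assert_array_equal(a.protein, b.protein)
        np.testing.assert_array_equal(a.mrna, b.mrna)

    def test_low_transcription_limit_clamps_near_zero(self):
        p = pa.RateParameters(k1=1e-3, k2=1, k3=1)
        cfg = pa.SimulationConfig(dt=0.01, t_end=30, mrna_init=0,
                                  protein_init=0)
        s = pa.simulate_population(p, pa.M0, pa.CellLine.REFERENCE, 4000, cfg,
                                   seed=3)
        assert np.all(s.mrna >= 0)
        assert s.mrna.mean() == pytest.approx(1e-3, abs=5e-3)
        assert np.median(s.mrna) == 0

    def test_regulated_line_scaling_property(self):
        """Under MII, multiplying s2 by c multiplies the stationary protein
        mean by c."""
        base = pa.RateParameters(k1=20, k2=100, k3=0.5, s2=2.0)
        cfg = pa.SimulationConfig(dt=0.05, t_end=60, method="exact")
        means = []
        for c, seed in ((1.0, 11), (3.0, 12)):
            p = pa.RateParameters(k1=20, k2=100, k3=0.5, s2=2.0 * c)
            s = pa.simulate_population(p, pa.MII, pa.CellLine.REGULATED,
                                       2000, cfg, seed=seed)
            means.append(s.protein.mean())
        assert means[1] / means[0] == pytest.approx(3.0, rel=0.1)

    def test_nonlinear_degradation_supported_by_euler_only(self):
        nl = pa.ModelVariant("MII", nonlinear_degradation=True)
        p = pa.RateParameters(k1=5, k2=5, k3=0.01, s2=2)
        cfg = pa.SimulationConfig(dt=0.01, t_end=10.0, mrna_init=5,
                                  protein_init=50)
        s = pa.simulate_population(p, nl, pa.CellLine.REFERENCE, 200, cfg,
                                   seed=5)
        assert np.all(s.protein >= 0)
        with pytest.raises(ValueError, match="exact"):
            pa.simulate_population(
                p, nl, pa.CellLine.REFERENCE, 10,
                pa.SimulationConfig(dt=0.01, t_end=10.0, method="exact"),
                seed=5)


class TestGillespie:
    def test_moments_match_closed_form(self, small_sim_config):
        p = pa.RateParameters(k1=5, k2=2, k3=0.5)
        mom = pa.steady_state_moments(p)
        n = 2000
        s = pa.simulate_gillespie(p, pa.M0, pa.CellLine.REFERENCE, n,
                                  small_sim_config, seed=9)
        assert s.protein.mean() == pytest.approx(
            mom.mean_p, abs=3 * np.sqrt(mom.var_p / n))
        kurt = 3 + 6 / (mom.mean_p ** 2 / mom.var_p)
        se_var = mom.var_p * np.sqrt((kurt - 1) / n)
        assert s.protein.var() == pytest.approx(mom.var_p, abs=3.5 * se_var)

    def test_reproducible_endpoint(self, small_sim_config):
        p = pa.RateParameters(k1=5, k2=2, k3=0.5)
        a = pa.simulate_gillespie(p, pa.M0, pa.CellLine.REFERENCE, 1,
                                  small_sim_config, seed=13)
        b = pa.simulate_gillespie(p, pa.M0, pa.CellLine.REFERENCE, 1,
                                  small_sim_config, seed=13)
        assert a.protein[0] == b.protein[0] and a.mrna[0] == b.mrna[0]

    def test_event_cap_guard(self):
        p = pa.RateParameters(k1=100, k2=1000, k3=0.1)
        cfg = pa.SimulationConfig(dt=0.01, t_end=30, max_ssa_events=10_000)
        with pytest.raises(pa.model.IntegrationError, match="cap"):
            pa.simulate_gillespie(p, pa.M0, pa.CellLine.REFERENCE, 100, cfg)

    def test_sde_and_ssa_distributions_indistinguishable(self):
        """Two-sample KS between SSA and SDE protein populations stays below
        the alpha=0.01 critical value at moderate copy numbers."""
        from scipy.stats import ks_2samp

        p = pa.RateParameters(k1=100, k2=10, k3=0.5)
        cfg_ssa = pa.SimulationConfig(dt=0.01, t_end=30)
        cfg_sde = pa.SimulationConfig(dt=0.01, t_end=30)
        n = 500
        ssa = pa.simulate_gillespie(p, pa.M0, pa.CellLine.REFERENCE, n,
                                    cfg_ssa, seed=21)
        sde = pa.simulate_population(p, pa.M0, pa.CellLine.REFERENCE, n,
                                     cfg_sde, seed=22)
        d = pa.ks_distance(ssa.protein, sde.protein)
        crit = pa.ks_critical_value(0.01, n, n)
        assert d < crit
        # agreement also holds under the independent scipy statistic
        assert ks_2samp(ssa.protein, sde.protein).pvalue > 0.01


class TestConfigRoundTrip:
    @pytest.mark.parametrize("ext", ["json", "yaml"])
    def test_save_load_round_trip(self, tmp_path, ext):
        p = pa.RateParameters(k1=3, k2=4e5, k3=2.5, s1=1.5, s2=3.0)
        cfg = pa.SimulationConfig(dt=0.02, t_end=40, seed=99)
        path = tmp_path / f"run.{ext}"
        save_config(path, p, pa.MIII, cfg)
        p2, v2, cfg2 = load_config(path)
        assert p2 == p
        assert v2.id == "MIII"
        assert cfg2.dt == 0.02 and cfg2.t_end == 40 and cfg2.seed == 99

    def test_flat_keys(self):
        d = config_to_dict(pa.RateParameters(k1=1, k2=2, k3=3),
                           pa.MII, pa.SimulationConfig())
        assert set(d) == {"k1", "k2", "k3", "s1", "s2", "model", "nonlinear",
                          "dt", "t_end", "protein_init", "mrna_init", "seed"}
        p, v, cfg = config_from_dict(d)
        assert v.id == "MII" and p.k3 == 3


class TestPopulationSample:
    def test_rejects_negative_and_mismatched(self):
        with pytest.raises(ValueError):
            pa.PopulationSample(protein=np.array([1.0, -2.0]))
        with pytest.raises(ValueError, match="length"):
            pa.PopulationSample(protein=np.array([1.0, 2.0]),
                                mrna=np.array([1.0]))

    def test_n_and_frame(self):
        s = pa.PopulationSample(protein=np.array([1.0, 2.0, 3.0]),
                                mrna=np.array([1.0, 1.0, 2.0]))
        assert s.n == 3
        df = s.to_frame()
        assert list(df.columns) == ["cell_id", "protein", "mrna"]
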