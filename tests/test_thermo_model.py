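"""Forward-model layers: occupancy oracle, layer contracts, composition."""

import numpy as np
import pytest
from conftest import brute_force_occupancy, make_sitemap

from thermoexpr.io_formats import TFProfileTable
from thermoexpr.synthetic_data import build_model
from thermoexpr.thermo_model import (
    ModelConfig,
    ParameterSet,
    TFRoleTable,
    ThermoModel,
    activation_efficiency,
    apply_coactivation_quenching,
    compute_occupancy,
    enhancer_competition,
    eve_roles,
    free_parameter_names,
    promoter_activity,
)

TWO_TF = TFRoleTable(roles={"A": "activator", "Q": "quencher"})


def two_tf_params(**overrides):
    base = {
        "K_A": 0.05, "K_Q": 0.05, "Ea_A": 0.5, "Eq_Q": 0.8,
        "qrange_Q": 100.0, "M_max": 100.0, "theta": 2.0, "scale": 2.0,
        "basal": 1.0,
    }
    base.update(overrides)
    return ParameterSet(base)


class TestParameterSpace:
    def test_eve_configuration_exposes_32_free_parameters(self):
        names = free_parameter_names(eve_roles())
        assert len(names) == 32
        assert len(set(names)) == 32

    def test_minimal_configuration_parameter_count(self):
        # 2 K + 1 Ea + 1 Eq + 1 qrange + 4 promoter constants
        assert len(free_parameter_names(TWO_TF)) == 9


class TestOccupancy:
    def test_zero_concentration_means_zero_occupancy(self):
        smap = make_sitemap([("A", 0, 8, 1.0), ("Q", 20, 28, 1.0)])
        f = compute_occupancy(smap, {"A": 0.0, "Q": 0.0}, two_tf_params(), TWO_TF)
        assert np.all(f == 0.0)

    def test_isolated_site_saturates_monotonically(self):
        smap = make_sitemap([("A", 0, 8, 1.0)])
        last = -1.0
        for conc in [1, 10, 100, 1000, 1e5]:
            f = compute_occupancy(smap, {"A": conc, "Q": 0.0},
                                  two_tf_params(), TWO_TF)[0]
            assert f > last
            last = f
        assert last == pytest.approx(1.0, abs=1e-3)

    def test_unknown_tf_in_sitemap_rejected(self):
        smap = make_sitemap([("Zld", 0, 8, 1.0)])
        with pytest.raises(ValueError, match="unknown TF"):
            compute_occupancy(smap, {"Zld": 1.0}, two_tf_params(), TWO_TF)

    @pytest.mark.parametrize("trial", range(20))
    def test_dp_matches_exhaustive_enumeration(self, trial):
        """Interval-DP occupancy equals the 2^n partition function, with
        overlapping sites and a cooperative pair, to 1e-9."""
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(2, 13))
        roles = TFRoleTable(roles={"B": "activator", "O": "activator"},
                            cooperative=("B",))
        starts = np.sort(rng.integers(0, 120, size=n))
        lengths = rng.integers(5, 12, size=n)
        tfs = rng.choice(["B", "O"], size=n)
        specs, intervals = [], []
        for i in range(n):
            s, e = int(starts[i]), int(starts[i] + lengths[i])
            specs.append((tfs[i], s, e, float(rng.uniform(0.3, 1.0))))
            intervals.append((s, e))
        # unique (start, tf) keys for SiteMap ids
        if len({(sp[0], sp[1]) for sp in specs}) < n:
            specs = [(tf, s + 200 * k, e + 200 * k, sc)
                     for k, (tf, s, e, sc) in enumerate(specs)]
            intervals = [(sp[1], sp[2]) for sp in specs]
        smap = make_sitemap(specs, locus_length=5000)
        conc = {"B": float(rng.uniform(10, 120)), "O": float(rng.uniform(10, 120))}
        params = ParameterSet({
            "K_B": 0.05, "K_O": 0.04, "Ea_B": 0.5, "Ea_O": 0.5,
            "coop_B_strength": float(rng.uniform(1, 6)),
            "coop_B_range": float(rng.uniform(10, 80)),
            "M_max": 100.0, "theta": 2.0, "scale": 2.0, "basal": 1.0,
        })
        f = compute_occupancy(smap, conc, params, roles)
        ordered = smap.sites  # SiteMap order
        weights = [params[f"K_{s.tf_name}"] * s.norm_score * conc[s.tf_name]
                   for s in ordered]
        expect = brute_force_occupancy(
            [(s.start, s.end) for s in ordered],
            [s.tf_name for s in ordered], weights,
            coop_tf="B", coop_strength=params["coop_B_strength"],
            coop_range=params["coop_B_range"],
        )
        assert np.allclose(f, expect, atol=1e-9)

    def test_cooperativity_raises_pair_occupancy(self):
        roles = TFRoleTable(roles={"B": "activator"}, cooperative=("B",))
        smap = make_sitemap([("B", 0, 8, 1.0), ("B", 20, 28, 1.0)])
        conc = {"B": 10.0}

        def occ(strength):
            params = ParameterSet({
                "K_B": 0.05, "Ea_B": 0.5,
                "coop_B_strength": strength, "coop_B_range": 50.0,
                "M_max": 100.0, "theta": 2.0, "scale": 2.0, "basal": 1.0,
            })
            return compute_occupancy(smap, conc, params, roles)

        assert np.all(occ(5.0) > occ(1.0))


class TestCoactivationQuenching:
    def test_identity_when_nothing_in_range(self):
        smap = make_sitemap([("A", 0, 8, 1.0), ("Q", 300, 308, 1.0)])
        params = two_tf_params(qrange_Q=50.0)
        f = compute_occupancy(smap, {"A": 50, "Q": 50}, params, TWO_TF)
        F = apply_coactivation_quenching(f, smap, TWO_TF, params)
        a_idx = [i for i, s in enumerate(smap.sites) if s.tf_name == "A"][0]
        assert F[a_idx] == pytest.approx(f[a_idx])

    def test_single_quencher_multiplicative_kernel(self):
        smap = make_sitemap([("A", 0, 8, 1.0), ("Q", 40, 48, 1.0)])
        params = two_tf_params()
        f = compute_occupancy(smap, {"A": 50, "Q": 50}, params, TWO_TF)
        F = apply_coactivation_quenching(f, smap, TWO_TF, params)
        idx = {s.tf_name: i for i, s in enumerate(smap.sites)}
        q = f[idx["Q"]]
        assert F[idx["A"]] == pytest.approx(f[idx["A"]] * (1 - 0.8 * q), abs=1e-12)
        assert F[idx["Q"]] == 0.0
        # monotone decreasing in quencher occupancy and efficiency
        f2 = compute_occupancy(smap, {"A": 50, "Q": 200}, params, TWO_TF)
        F2 = apply_coactivation_quenching(f2, smap, TWO_TF, params)
        assert F2[idx["A"]] < F[idx["A"]]
        F3 = apply_coactivation_quenching(f, smap, TWO_TF, two_tf_params(Eq_Q=0.95))
        assert F3[idx["A"]] < F[idx["A"]]

    def test_quenching_only_reduces(self):
        smap = make_sitemap([("A", 0, 8, 1.0), ("Q", 30, 38, 1.0),
                             ("Q", 60, 68, 1.0)])
        params = two_tf_params()
        f = compute_occupancy(smap, {"A": 80, "Q": 80}, params, TWO_TF)
        F = apply_coactivation_quenching(f, smap, TWO_TF, params)
        for i, s in enumerate(smap.sites):
            if s.tf_name == "A":
                assert 0.0 <= F[i] <= f[i]

    def test_coactivated_site_switches_to_activator_channel(self, eve_scenario):
        """A bound Hb site near a saturated Bcd site appears in the
        activator channel of F."""
        roles = eve_roles()
        smap = make_sitemap([("Bcd", 0, 7, 1.0), ("Hb", 40, 48, 1.0)])
        params = ParameterSet(dict(eve_scenario.true_params))
        conc = {tf: 0.0 for tf in roles.tf_names}
        conc.update({"Bcd": 1e5, "Hb": 60.0})
        f = compute_occupancy(smap, conc, params, roles)
        F = apply_coactivation_quenching(f, smap, roles, params)
        idx = {s.tf_name: i for i, s in enumerate(smap.sites)}
        hb, bcd = idx["Hb"], idx["Bcd"]
        assert f[hb] > 0
        # bound Bcd with Eco=0.9 converts that share of bound Hb to activation
        assert F[hb] == pytest.approx(f[hb] * 0.9 * f[bcd], rel=1e-9)
        # with coactivation disabled Hb contributes nothing to the channel
        off = params.replace(Eco_Bcd_Hb=0.0, Eco_Cad_Hb=0.0)
        F_off = apply_coactivation_quenching(f_off := compute_occupancy(
            smap, conc, off, roles), smap, roles, off)
        assert F_off[hb] == 0.0

    def test_f_equals_F_with_null_quenching_and_coactivation(self, eve_scenario):
        model = build_model(eve_scenario)
        params = eve_scenario.true_params.replace(
            **{f"Eq_{tf}": 0.0 for tf in eve_roles().quenchers},
            Eco_Bcd_Hb=0.0, Eco_Cad_Hb=0.0)
        conc = {tf: eve_scenario.profiles.concentrations[tf][5]
                for tf in eve_scenario.profiles.tf_names}
        layers = model.layers(params, conc)
        act = set(eve_roles().activators)
        for i, s in enumerate(model.sitemap.sites):
            if s.tf_name in act:
                assert layers["F"][i] == pytest.approx(layers["f"][i], abs=1e-12)


class TestActivationEfficiency:
    def test_null_efficacy_gives_zero(self):
        smap = make_sitemap([("A", 0, 8, 1.0), ("A", 30, 38, 0.7)])
        params = two_tf_params(Ea_A=0.0)
        F = np.array([0.5, 0.3])
        assert np.all(activation_efficiency(F, smap, params, TWO_TF) == 0.0)

    def test_linearity_in_efficacy(self):
        smap = make_sitemap([("A", 0, 8, 1.0), ("Q", 40, 48, 1.0)])
        F = np.array([0.5, 0.2])
        fe1 = activation_efficiency(F, smap, two_tf_params(Ea_A=0.4), TWO_TF)
        fe2 = activation_efficiency(F, smap, two_tf_params(Ea_A=0.8), TWO_TF)
        assert np.allclose(fe2, 2 * fe1)

    def test_three_site_hand_product(self):
        smap = make_sitemap([("A", 0, 8, 1.0), ("A", 30, 38, 1.0),
                             ("Q", 60, 68, 1.0)])
        F = np.array([0.5, 0.25, 0.4])
        fe = activation_efficiency(F, smap, two_tf_params(Ea_A=0.6), TWO_TF)
        assert np.allclose(fe, [0.5 * 0.6, 0.25 * 0.6, 0.0])


class TestEnhancerCompetition:
    def test_single_window_common_proportionality(self):
        smap = make_sitemap([("A", 0, 8, 1.0), ("A", 50, 58, 1.0)],
                            locus_length=400)
        FE = np.array([0.4, 0.2])
        RT = enhancer_competition(FE, smap, alpha=1000.0, params=two_tf_params(),
                                  roles=TWO_TF)
        # one window: every site keeps the same realized fraction
        factor = 1.0 / (1.0 + FE.sum())
        assert np.allclose(RT, FE * factor)
        assert RT[0] / RT[1] == pytest.approx(FE[0] / FE[1])

    def test_two_identical_windows_share_equally(self):
        # window width 100: sites at 10/60 in window 0, 110/160 in window 1
        smap = make_sitemap([("A", 10, 18, 1.0), ("A", 60, 68, 1.0),
                             ("A", 110, 118, 1.0), ("A", 160, 168, 1.0)],
                            locus_length=200)
        FE = np.array([0.3, 0.1, 0.3, 0.1])
        RT = enhancer_competition(FE, smap, alpha=100.0, params=two_tf_params(),
                                  roles=TWO_TF)
        assert RT[:2].sum() == pytest.approx(RT[2:].sum())
        assert RT.sum() <= FE.sum() + 1e-12

    def test_total_rt_never_exceeds_total_feaa(self):
        rng = np.random.default_rng(3)
        smap = make_sitemap([("A", int(s), int(s) + 8, 1.0)
                             for s in range(0, 390, 30)], locus_length=400)
        for _ in range(20):
            FE = rng.uniform(0, 1, size=len(smap))
            RT = enhancer_competition(FE, smap, alpha=90.0,
                                      params=two_tf_params(), roles=TWO_TF)
            assert RT.sum() <= FE.sum() + 1e-12
            assert np.all(RT >= 0)


class TestPromoterActivity:
    def test_no_activation_gives_basal_level(self):
        params = two_tf_params(theta=5.0, scale=3.0, basal=1.5)
        m = promoter_activity(np.zeros(4), params)
        assert m == pytest.approx(1.5 + 100.0 * np.exp(-15.0))
        assert m == pytest.approx(params["basal"], abs=1e-4)

    def test_saturation_at_high_rt(self):
        params = two_tf_params(theta=2.0, scale=2.0, basal=1.0)
        assert promoter_activity(np.array([50.0]), params) == pytest.approx(101.0)

    def test_monotone_in_total_barrier_reduction(self):
        params = two_tf_params()
        rng = np.random.default_rng(5)
        for _ in range(100):
            x = rng.uniform(0, 5)
            m0 = promoter_activity(np.array([x]), params)
            m1 = promoter_activity(np.array([x + 1e-4]), params)
            assert m1 >= m0 - 1e-12


class TestPredictExpression:
    def test_no_activators_gives_flat_basal_profile(self, eve_scenario):
        model = build_model(eve_scenario)
        prof = eve_scenario.profiles
        dead = TFProfileTable(prof.nu_grid, {
            tf: (np.zeros_like(v) if tf in eve_roles().activators else v)
            for tf, v in prof.concentrations.items()
        })
        pred = model.predict(eve_scenario.true_params, dead)
        p = eve_scenario.true_params
        floor = p["basal"] + p["M_max"] * np.exp(-p["scale"] * p["theta"])
        assert np.allclose(pred.values, floor, atol=1e-9)

    def test_two_site_three_nuclei_hand_composition(self):
        """Full composition agrees with the closed form for two
        non-overlapping sites (activator + in-range quencher)."""
        smap = make_sitemap([("A", 0, 8, 1.0), ("Q", 40, 48, 0.5)])
        params = two_tf_params()
        nu = np.array([1.0, 2.0, 3.0])
        prof = TFProfileTable(nu, {"A": np.array([0.0, 40.0, 400.0]),
                                   "Q": np.array([10.0, 20.0, 0.0])})
        model = ThermoModel(smap, TWO_TF, ModelConfig(alpha=1000.0))
        pred = model.predict(params, prof)
        for v in range(3):
            wa = 0.05 * 1.0 * prof.concentrations["A"][v]
            wq = 0.05 * 0.5 * prof.concentrations["Q"][v]
            z = 1 + wa + wq + wa * wq
            fa = wa * (1 + wq) / z
            fq = wq * (1 + wa) / z
            F = fa * (1 - 0.8 * fq)
            fe = F * 0.5
            rt = fe / (1.0 + fe)  # single window, capacity kappa = 1
            m = 1.0 + 100.0 * np.exp(-2.0 * max(2.0 - rt, 0.0))
            assert pred.values[v] == pytest.approx(m, abs=1e-12)

    def test_self_consistency_at_true_parameters(self, minimal_scenario,
                                                 minimal_fitter):
        pred = minimal_fitter.predict(minimal_scenario.true_params)
        assert np.allclose(pred.values, minimal_scenario.expression_true.values,
                           atol=1e-9)

    def test_invariant_under_site_order_permutation(self, eve_scenario):
        from thermoexpr.pwm_annotation import SiteMap

        model = build_model(eve_scenario)
        rng = np.random.default_rng(0)
        shuffled = list(model.sitemap.sites)
        rng.shuffle(shuffled)
        model2 = ThermoModel(SiteMap(tuple(shuffled), eve_scenario.locus),
                             eve_scenario.roles, eve_scenario.model_config)
        a = model.predict(eve_scenario.true_params, eve_scenario.profiles)
        b = model2.predict(eve_scenario.true_params, eve_scenario.profiles)
        assert np.array_equal(a.values, b.values)


class TestModelMonotonicity:
    """Concentration monotonicity of the full prediction."""

    def _check(self, scenario, tf, factor, sign, coactivation_off=True):
        model = build_model(scenario)
        params = scenario.true_params
        if coactivation_off:
            params = params.replace(Eco_Bcd_Hb=0.0, Eco_Cad_Hb=0.0)
        prof = scenario.profiles
        base = model.predict(params, prof).values
        bumped = TFProfileTable(prof.nu_grid, {
            t: (v * factor if t == tf else v)
            for t, v in prof.concentrations.items()
        })
        new = model.predict(params, bumped).values
        if sign > 0:
            assert np.all(new >= base - 1e-9)
        else:
            assert np.all(new <= base + 1e-9)

    @pytest.mark.parametrize("tf", ["Bcd", "Cad", "Dst"])
    def test_activators_never_decrease_expression(self, eve_scenario, tf):
        self._check(eve_scenario, tf, 1.5, +1)

    @pytest.mark.parametrize("tf", ["Hb", "Gt", "Kr", "Kni", "Tll"])
    def test_quenchers_never_increase_expression(self, eve_scenario, tf):
        self._check(eve_scenario, tf, 1.5, -1)

    @pytest.mark.parametrize("tf", ["Gt", "Kr", "Kni", "Tll"])
    def test_non_coactivated_quenchers_monotone_with_coactivation_on(
            self, eve_scenario, tf):
        self._check(eve_scenario, tf, 1.5, -1, coactivation_off=False)
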