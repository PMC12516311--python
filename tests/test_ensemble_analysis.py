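"""Ensemble site summaries, functional clusters, alpha sweep."""

import numpy as np
import pytest
from conftest import make_sitemap

from thermoexpr.annealing_fit import AnnealingConfig, FitResult, rms_cost
from thermoexpr.compat_filters import FilterConfig
from thermoexpr.ensemble_analysis import (
    aggregate_site_weights,
    alpha_sweep,
    identify_functional_clusters,
    weighted_site_frequency,
)
from thermoexpr.io_formats import TFProfileTable
from thermoexpr.synthetic_data import make_fitter
from thermoexpr.thermo_model import ParameterSet, ThermoModel, eve_roles


def _true_fits(scenario, fitter, n=3, jitter=0.02):
    """Small perturbations of the ground truth, evaluated forward."""
    rng = np.random.default_rng(5)
    fits = []
    for k in range(n):
        factors = np.exp(rng.normal(0, jitter, size=len(scenario.true_params)))
        params = ParameterSet({name: v * f for (name, v), f in
                               zip(scenario.true_params.items(), factors)})
        pred = fitter.predict(params)
        fits.append(FitResult(params=params, rms=rms_cost(scenario.expression, pred),
                              predicted=pred, seed=k, filter1_pass=True,
                              filter2_pass=True))
    return fits


class TestAggregateSiteWeights:
    def test_quoted_weighting_rule_arithmetic(self):
        """Site A contributes 0.6 in both of two fits (count 2); site B 0.9
        in one (count 1): raw(A)=1.2*2/2=1.2, raw(B)=0.9*1/2=0.45."""
        scores, counts = aggregate_site_weights([
            {"A": 0.6, "B": 0.9},
            {"A": 0.6},
        ])
        assert counts == {"A": 2, "B": 1}
        assert scores["A"] == pytest.approx(1.0)       # 1.2 normalized
        assert scores["B"] == pytest.approx(0.45 / 1.2)
        assert scores["A"] > scores["B"]

    def test_single_active_site_scores_one(self):
        scores, _ = aggregate_site_weights([{"only": 0.123}])
        assert scores == {"only": 1.0}

    def test_scale_invariance(self):
        per_fit = [{"A": 0.2, "B": 0.5}, {"B": 0.1}]
        s1, _ = aggregate_site_weights(per_fit)
        s2, _ = aggregate_site_weights(
            [{k: 7.0 * v for k, v in d.items()} for d in per_fit])
        for k in s1:
            assert s1[k] == pytest.approx(s2[k])


class TestWeightedSiteFrequency:
    def test_permutation_invariance(self, minimal_scenario, minimal_fitter):
        fits = _true_fits(minimal_scenario, minimal_fitter, n=4)
        a = weighted_site_frequency(fits, minimal_fitter.model,
                                    minimal_scenario.profiles, 40.5)
        b = weighted_site_frequency(fits[::-1], minimal_fitter.model,
                                    minimal_scenario.profiles, 40.5)
        assert a.table.equals(b.table)

    def test_top_score_is_one_and_scores_in_unit_interval(
            self, minimal_scenario, minimal_fitter):
        fits = _true_fits(minimal_scenario, minimal_fitter)
        summary = weighted_site_frequency(fits, minimal_fitter.model,
                                          minimal_scenario.profiles, 40.5)
        scores = summary.table.score.to_numpy()
        assert scores.max() == pytest.approx(1.0)
        assert np.all((scores >= 0) & (scores <= 1 + 1e-12))

    def test_empty_ensemble_rejected(self, minimal_fitter, minimal_scenario):
        with pytest.raises(ValueError, match="empty"):
            weighted_site_frequency([], minimal_fitter.model,
                                    minimal_scenario.profiles, 40.5)


class TestFunctionalClusters:
    @staticmethod
    def _toy_model_and_fit(extra_sites=(), conc_overrides=None):
        """An isolated coactivated-Hb center with optional neighbours."""
        roles = eve_roles()
        sites = [("Hb", 0, 8, 1.0)] + list(extra_sites)
        smap = make_sitemap(sites, locus_length=2000, offset=1000)
        model = ThermoModel(smap, roles)
        params = ParameterSet({
            "K_Bcd": 0.05, "K_Cad": 0.05, "K_Dst": 0.05, "K_Hb": 0.05,
            "K_Gt": 0.05, "K_Kr": 0.05, "K_Kni": 0.05, "K_Tll": 0.05,
            "Ea_Bcd": 0.5, "Ea_Cad": 0.5, "Ea_Dst": 0.5, "Ea_Hb_coact": 0.8,
            "Eq_Hb": 0.8, "Eq_Gt": 0.8, "Eq_Kr": 0.8, "Eq_Kni": 0.8,
            "Eq_Tll": 0.8,
            "Eco_Bcd_Hb": 0.9, "Eco_Cad_Hb": 0.5,
            "coop_Bcd_strength": 2.0, "coop_Bcd_range": 60.0,
            "qrange_Hb": 150.0, "qrange_Gt": 150.0, "qrange_Kr": 150.0,
            "qrange_Kni": 150.0, "qrange_Tll": 150.0,
            "corange_Bcd_Hb": 150.0, "corange_Cad_Hb": 150.0,
            "M_max": 100.0, "theta": 1.0, "scale": 2.0, "basal": 1.0,
        })
        conc = {tf: 0.0 for tf in roles.tf_names}
        conc.update({"Hb": 60.0, "Bcd": 80.0, "Kr": 50.0})
        if conc_overrides:
            conc.update(conc_overrides)
        nu = np.array([40.5])
        profiles = TFProfileTable(nu, {tf: np.array([c])
                                       for tf, c in conc.items()})
        fit = FitResult(params=params, rms=0.0,
                        predicted=model.predict(params, profiles), seed=0)
        return model, profiles, fit

    def test_isolated_activator_forms_singleton_cluster(self):
        model, profiles, fit = self._toy_model_and_fit(
            extra_sites=[("Bcd", -700, -693, 1.0)],  # coactivator out of range
            conc_overrides={"Kr": 0.0})
        # Hb needs an in-range coactivator to be active at all; give it one
        model, profiles, fit = self._toy_model_and_fit(
            extra_sites=[("Bcd", -40, -33, 1.0)], conc_overrides={"Kr": 0.0})
        clusters = identify_functional_clusters(fit, model, profiles, 40.5)
        hb = [c for c in clusters if c.center_tf == "Hb"]
        assert len(hb) == 1
        roles = {r for _, r, _ in hb[0].members}
        assert roles == {"coactivator"}

    def test_planted_geometry_recovered(self):
        """Activator (coactivated Hb) at x with a quencher at x+60 and a
        coactivator at x-40, interaction range 150."""
        model, profiles, fit = self._toy_model_and_fit(
            extra_sites=[("Kr", 60, 68, 1.0), ("Bcd", -40, -33, 1.0)])
        clusters = identify_functional_clusters(fit, model, profiles, 40.5,
                                                interaction_range=150.0)
        center = [c for c in clusters if c.center_tf == "Hb"][0]
        members = {(m[1], m[2]) for m in center.members}
        assert ("quencher", 60) in members
        assert ("coactivator", -40) in members

    def test_coactivated_center_has_both_roles(self):
        model, profiles, fit = self._toy_model_and_fit(
            extra_sites=[("Kr", 60, 68, 1.0), ("Bcd", -40, -33, 1.0)])
        clusters = identify_functional_clusters(fit, model, profiles, 40.5)
        center = [c for c in clusters if c.center_tf == "Hb"][0]
        roles = {m[1] for m in center.members}
        assert roles == {"quencher", "coactivator"}

    def test_members_within_interaction_range(self, eve_scenario, eve_fitter):
        fits = _true_fits(eve_scenario, eve_fitter, n=1)
        clusters = identify_functional_clusters(
            fits[0], eve_fitter.model, eve_scenario.profiles, 40.5,
            interaction_range=150.0)
        sites = {s.site_id: s for s in eve_fitter.model.sitemap.sites}
        assert clusters, "expected at least one functional cluster"
        for c in clusters:
            for sid, _, _ in c.members:
                gap = sites[c.center].gap_to(sites[sid])
                assert gap <= 150.0

    def test_ranks_are_a_permutation(self, eve_scenario, eve_fitter):
        fits = _true_fits(eve_scenario, eve_fitter, n=1)
        clusters = identify_functional_clusters(
            fits[0], eve_fitter.model, eve_scenario.profiles, 40.5)
        assert sorted(c.rank for c in clusters) == list(
            range(1, len(clusters) + 1))


class TestAlphaSweep:
    def test_four_window_sizes_keyed_by_alpha(self, eve_scenario, eve_fitter):
        base = _true_fits(eve_scenario, eve_fitter, n=3)
        cfg = AnnealingConfig(max_evaluations=100, seed=0)
        fcfg = FilterConfig(rms_threshold=1e9,
                            reference_region=eve_scenario.reference_region,
                            reference_nu=eve_scenario.reference_nu)
        out = alpha_sweep([300, 500, 800, 1000],
                          lambda a: make_fitter(eve_scenario, alpha=a),
                          eve_scenario.prior_range, cfg, fcfg, n_fits=0,
                          refit=False, base_fits=base)
        assert sorted(out) == [300.0, 500.0, 800.0, 1000.0]
        for res in out.values():
            assert len(res["site_summary"].table) > 0

    def test_singleton_sweep_matches_plain_evaluation(self, eve_scenario,
                                                      eve_fitter):
        base = _true_fits(eve_scenario, eve_fitter, n=2)
        cfg = AnnealingConfig(max_evaluations=100, seed=0)
        fcfg = FilterConfig(rms_threshold=1e9,
                            reference_region=eve_scenario.reference_region,
                            reference_nu=eve_scenario.reference_nu)
        out = alpha_sweep([eve_scenario.model_config.alpha],
                          lambda a: make_fitter(eve_scenario, alpha=a),
                          eve_scenario.prior_range, cfg, fcfg, n_fits=0,
                          refit=False, base_fits=base)
        res = out[eve_scenario.model_config.alpha]
        direct = weighted_site_frequency(base, eve_fitter.model,
                                         eve_scenario.profiles,
                                         eve_scenario.reference_nu)
        assert res["site_summary"].table.site_id.tolist() == \
            direct.table.site_id.tolist()

    def test_quenching_mass_trend_with_window_size(self, eve_scenario):
        """Larger competition windows recruit more quenching into the
        functional clusters at the stripe peak."""
        masses = []
        for alpha in (300, 1000):
            fitter = make_fitter(eve_scenario, alpha=alpha)
            fits = _true_fits(eve_scenario, fitter, n=1)
            clusters = identify_functional_clusters(
                fits[0], fitter.model, eve_scenario.profiles, 40.5)
            n_quench = sum(
                sum(1 for _, role, _ in c.members if role == "quencher")
                for c in clusters)
            masses.append(n_quench)
        assert masses[1] >= masses[0]
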