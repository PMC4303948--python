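import numpy as np
import pytest

from gapcircuit.regions import BindingSite
from gapcircuit.thermo import (Configuration, ThermoParams,
                               activation_brute_force, activation_dp,
                               config_weight, site_strength)

from conftest import monotone_thermo_instance, random_thermo_instance


def simple_params(**kw):
    defaults = dict(
        target_gene="g",
        t_row={"act": 3.0, "rep": -5.0},
        affinity={"act": 0.01, "rep": 0.01},
        cooperativity={"act": 5.0, "rep": 1.0},
        repression_range={"act": 0.0, "rep": 50.0},
        coop_range=50.0,
        q_btm=0.1,
    )
    defaults.update(kw)
    return ThermoParams(**defaults)


def site(tf, start, length=8, llr=0.0):
    return BindingSite(tf, start, start + length, "+", "A" * length, llr)


class TestSiteStrength:
    def test_strongest_site_measured_affinity(self):
        # published affinity constant for the hb strongest site
        params = simple_params(affinity={"act": 0.005731, "rep": 0.01})
        q = site_strength(site("act", 0, llr=2.0), params, 100.0,
                          llr_max=2.0)
        assert q == pytest.approx(0.5731)

    def test_zero_concentration_gives_zero(self):
        assert site_strength(site("act", 0), simple_params(), 0.0,
                             0.0) == 0.0

    def test_log_odds_deficit_discount(self):
        q_max = site_strength(site("act", 0, llr=1.0), simple_params(),
                              50.0, llr_max=1.0)
        q_half = site_strength(site("act", 0, llr=1.0 - np.log(2)),
                               simple_params(), 50.0, llr_max=1.0)
        assert q_half == pytest.approx(q_max / 2)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            site_strength(site("act", 0), simple_params(), -1.0, 0.0)


class TestConfigWeight:
    def test_empty_configuration_normalisation(self):
        w, q = config_weight(Configuration(frozenset()), [],
                             simple_params(), {}, {})
        assert (w, q) == (1.0, 0.1)

    def test_single_activator_products(self):
        params = simple_params(affinity={"act": 0.01, "rep": 0.01})
        sites = [site("act", 0, llr=0.0)]
        conc = {"act": 200.0}   # q = 0.01*200 = 2
        w, q = config_weight(Configuration(frozenset({0})), sites,
                             params, conc, {"act": 0.0})
        assert w == pytest.approx(2.0)
        assert q == pytest.approx(0.1 * 3.0)

    def test_homotypic_cooperativity_bonus(self):
        params = simple_params()
        sites = [site("act", 0), site("act", 18)]  # 10 bp edge gap
        conc = {"act": 100.0}   # q = 1 each
        w, _ = config_weight(Configuration(frozenset({0, 1})), sites,
                             params, conc, {"act": 0.0})
        assert w == pytest.approx(1.0 * 1.0 * 5.0)

    def test_overlapping_bound_sites_rejected(self):
        sites = [site("act", 0), site("act", 4)]
        with pytest.raises(ValueError, match="overlap"):
            config_weight(Configuration(frozenset({0, 1})), sites,
                          simple_params(), {"act": 1.0}, {"act": 0.0})


class TestBruteForceClosedForms:
    def test_no_sites_basal_level(self):
        params = simple_params(q_btm=0.25)
        e = activation_brute_force([], params, {}, {})
        assert e == pytest.approx(0.25 / 1.25)

    def test_single_activator_two_configurations(self):
        params = simple_params(q_btm=0.1)
        conc = {"act": 150.0}   # q = 1.5
        e = activation_brute_force([site("act", 0)], params, conc,
                                   {"act": 0.0})
        q, t, qb = 1.5, 3.0, 0.1
        expected = (qb + q * qb * t) / (qb + q * qb * t + 1 + q)
        assert e == pytest.approx(expected, rel=1e-12)

    def test_strong_repressor_quenches_nearby_activator(self):
        conc = {"act": 150.0, "rep": 100.0}
        sites = [site("act", 0), site("rep", 20)]
        weak = simple_params(t_row={"act": 3.0, "rep": -1e-9})
        strong = simple_params(t_row={"act": 3.0, "rep": -1e6})
        e_no = activation_brute_force(sites, weak, conc,
                                      {"act": 0.0, "rep": 0.0})
        e_rep = activation_brute_force(sites, strong, conc,
                                       {"act": 0.0, "rep": 0.0})
        assert e_rep < e_no

    def test_enumeration_cap(self):
        sites = [site("act", 30 * j) for j in range(16)]
        with pytest.raises(ValueError, match="cap"):
            activation_brute_force(sites, simple_params(),
                                   {"act": 1.0}, {"act": 0.0})


class TestDpEquivalence:
    def test_dp_matches_enumeration_on_random_instances(self, rng):
        for _ in range(60):
            sites, params, conc, llr_max = random_thermo_instance(rng)
            e_bf = activation_brute_force(sites, params, conc, llr_max)
            e_dp = activation_dp(sites, params, conc, llr_max)
            assert 0.0 <= e_dp <= 1.0
            assert e_dp == pytest.approx(e_bf, rel=1e-10)

    def test_independent_binding_product_form(self, rng):
        # omega = 1 everywhere and d_R = 0 decouple non-overlapping
        # sites; E then has a closed product form.
        tfs = ["a", "r", "n"]
        params = ThermoParams(
            "g", {"a": 4.0, "r": -6.0, "n": 0.0},
            affinity={t: 0.01 for t in tfs},
            cooperativity={t: 1.0 for t in tfs},
            repression_range={t: 0.0 for t in tfs},
            q_btm=0.2)
        sites = [site(tfs[int(rng.integers(0, 3))], 20 * j,
                      llr=float(rng.uniform(-1, 0)))
                 for j in range(8)]
        conc = {t: float(rng.uniform(10, 150)) for t in tfs}
        llr_max = {t: 0.0 for t in tfs}
        z_on = z_off = 1.0
        for s in sites:
            q = 0.01 * conc[s.tf_name] * np.exp(s.llr)
            t_val = params.t_row[s.tf_name]
            if t_val > 0:
                z_on *= 1 + q * t_val
                z_off *= 1 + q
            elif t_val < 0:
                z_on *= 1 + q + q * abs(t_val)
                z_off *= 1 + q + q * abs(t_val)
            else:
                z_on *= 1 + q
                z_off *= 1 + q
        expected = 0.2 * z_on / (0.2 * z_on + z_off)
        e_dp = activation_dp(sites, params, conc, llr_max)
        assert e_dp == pytest.approx(expected, rel=1e-10)

    def test_zero_strength_site_is_neutral(self, rng):
        sites, params, conc, llr_max = random_thermo_instance(rng, 6)
        dead = BindingSite("tf0", 500, 508, "+", "A" * 8, -1e3)
        e_with = activation_dp(sites + [dead], params, conc, llr_max)
        e_without = activation_dp(sites, params, conc, llr_max)
        assert e_with == pytest.approx(e_without, rel=1e-12)

    def test_many_sites_fast_and_bounded(self):
        import time
        rng = np.random.default_rng(5)
        params = simple_params()
        sites = []
        pos = 0
        for _ in range(200):
            pos += int(rng.integers(9, 25))
            tf = "act" if rng.random() < 0.5 else "rep"
            sites.append(site(tf, pos))
        conc = {"act": 80.0, "rep": 60.0}
        t0 = time.time()
        e = activation_dp(sites, params, conc, {"act": 0.0, "rep": 0.0})
        assert time.time() - t0 < 1.0
        assert 0.0 <= e <= 1.0


class TestMonotonicity:
    def test_activator_monotonicity_on_arbitrary_instances(self, rng):
        # raising any activator's T never lowers E, whatever the layout
        for _ in range(25):
            sites, params, conc, llr_max = random_thermo_instance(rng, 8)
            e0 = activation_dp(sites, params, conc, llr_max)
            for tf, t_val in params.t_row.items():
                if t_val <= 0:
                    continue
                bumped = {**params.t_row, tf: t_val * 1.5}
                p2 = ThermoParams(
                    "g", bumped, params.affinity, params.cooperativity,
                    params.repression_range, params.coop_range,
                    params.q_btm)
                assert activation_dp(sites, p2, conc,
                                     llr_max) >= e0 - 1e-12

    def test_repressor_monotonicity_without_interference(self, rng):
        # a lone repressor quenching local activators can only lower E
        for _ in range(25):
            sites, params, conc, llr_max = monotone_thermo_instance(rng)
            e0 = activation_dp(sites, params, conc, llr_max)
            bumped = {**params.t_row,
                      "rep": params.t_row["rep"] * 2.0}
            p2 = ThermoParams(
                "g", bumped, params.affinity, params.cooperativity,
                params.repression_range, params.coop_range,
                params.q_btm)
            assert activation_dp(sites, p2, conc, llr_max) <= e0 + 1e-12
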