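import numpy as np
import pandas as pd
import pytest

from gapcircuit.data import ExpressionDataset
from gapcircuit.experiments import (classify_topology, ranked_removal_curve,
                                    regulatory_weight, simulate_mutant,
                                    simulate_reporter, site_weight_report,
                                    weight_vs_llr_correlation)
from gapcircuit.fit import CircuitModel
from gapcircuit.params import ParameterVector
from gapcircuit.regions import BindingSite


@pytest.fixture(scope="module")
def weight_report(toy):
    return site_weight_report(toy.model, toy.truth, toy.dataset)


class TestRegulatoryWeight:
    def test_zero_strength_site_has_zero_weight(self, toy):
        gene = "gA"
        region = toy.regions[gene]
        dead = BindingSite("M1", 560, 568, "+", "A" * 8, -1e3)
        regions = dict(toy.regions)
        regions[gene] = region.with_sites(region.sites + [dead])
        model = CircuitModel(regions, toy.config, toy.model.grid,
                             toy.external, toy.model.llr_max)
        w = regulatory_weight(model, toy.truth, toy.dataset, gene, dead)
        assert w == pytest.approx(0.0, abs=1e-9)

    def test_unknown_site_rejected(self, toy):
        ghost = BindingSite("M1", 0, 8, "+", "A" * 8, 0.0)
        with pytest.raises(ValueError, match="not in region"):
            regulatory_weight(toy.model, toy.truth, toy.dataset, "gA",
                              ghost)

    def test_report_covers_all_sites_with_cre_flags(self, toy,
                                                    weight_report):
        n_sites = sum(len(r.sites) for r in toy.regions.values())
        assert len(weight_report) == n_sites
        assert weight_report["inside_cre"].all()   # CREs tile the toy
        assert (weight_report["w_r"] <= 1.0).all()

    def test_input_gradient_sites_dominate_anterior_gene(
            self, weight_report):
        # gA is driven by the planted external-gradient sites
        sub = weight_report[weight_report["gene"] == "gA"]
        top = sub.loc[sub["w_r"].abs().idxmax()]
        assert top["tf"] in ("M1", "M2")


class TestRankedRemoval:
    def test_curve_shape_and_degradation(self, toy, weight_report):
        curve = ranked_removal_curve(toy.model, toy.truth, toy.dataset,
                                     report=weight_report)
        n_sites = len(weight_report)
        assert len(curve) == n_sites + 1
        assert curve.loc[0, "relative_rss"] == 1.0
        assert curve["n_removed"].tolist() == list(range(n_sites + 1))
        # stripping every site leaves only basal activation
        assert curve.loc[n_sites, "relative_rss"] > 1.0

    def test_removing_all_activator_sites_degrades_fit(self, toy):
        excluded = frozenset(
            (g, s) for g, region in toy.regions.items()
            for s in region.sites
            if toy.truth.thermo_params(g).role(s.tf_name) == 1)
        rss_ref = toy.model.rss(toy.truth, toy.dataset)
        rss_mut = toy.model.rss(toy.truth, toy.dataset,
                                exclude_sites=excluded)
        assert rss_mut / rss_ref > 1.0


class TestMutant:
    def test_knocked_out_gene_silenced(self, toy):
        traj = simulate_mutant(toy.model, toy.truth, "gA")
        for cls in toy.model.grid.class_labels:
            assert np.allclose(traj.u[cls][0], 0.0)
            assert np.allclose(traj.v[cls][0], 0.0)

    def test_repressive_edge_releases_target(self, toy):
        # gA quenches gB: removing gA must raise gB where gA was high
        wild = toy.model.trajectory(toy.truth)
        mut = simulate_mutant(toy.model, toy.truth, "gA")
        last = toy.model.grid.class_labels[-1]
        assert mut.v[last][1].sum() > wild.v[last][1].sum()

    def test_knockout_without_outgoing_edges_leaves_rest_untouched(
            self, toy):
        # silence gA's regulatory output first (T column to zero);
        # then its knockout cannot change gB at all
        vec = toy.truth.pack().copy()
        pv = ParameterVector.unpack(vec, toy.config)
        pv.t_matrix[:, 0] = 0.0
        # also disable quenching: a neutral site inside an effective
        # repressor's neighborhood would otherwise still compete
        pv.repression_range[:] = 0.0
        wild = toy.model.trajectory(pv)
        mut = simulate_mutant(toy.model, pv, "gA")
        # the neutral (1 + q) binding factor of the silenced TF cancels
        # from the occupancy ratio, so gA is unchanged up to rounding
        for cls in toy.model.grid.class_labels:
            assert np.allclose(wild.v[cls][1], mut.v[cls][1],
                               rtol=1e-10)
            assert np.allclose(wild.u[cls][1], mut.u[cls][1],
                               rtol=1e-10)

    def test_no_knockout_path_reproduces_wild_type_bitwise(self, toy):
        wild = toy.model.trajectory(toy.truth)
        again = toy.model.trajectory(toy.truth, knockouts=())
        for cls in toy.model.grid.class_labels:
            assert np.array_equal(wild.v[cls], again.v[cls])

    def test_unknown_gene_rejected(self, toy):
        with pytest.raises(KeyError):
            simulate_mutant(toy.model, toy.truth, "nope")


def all_inputs_for_reporter(toy):
    wild = toy.model.trajectory(toy.truth).to_dataset()
    merged = pd.concat([wild.data, toy.external.data],
                       ignore_index=True)
    return ExpressionDataset(merged, wild.class_times)


class TestReporter:
    def test_whole_region_cre_with_external_only_inputs(self, toy):
        # a reporter whose CRE spans the full region and whose parent
        # has no feedback sites reproduces the endogenous simulation
        from gapcircuit.dynamics import CompiledCircuit
        from gapcircuit.regions import RegulatoryRegion

        region = toy.regions["gA"]
        m_sites = [s for s in region.sites if s.tf_name == "M1"]
        solo = RegulatoryRegion("solo", region.sequence, 0, m_sites,
                                cres={"all": (0, len(region.sequence))})
        model = CircuitModel({"solo": solo},
                             _solo_config(toy), toy.model.grid,
                             toy.external, toy.model.llr_max)
        pv = _solo_params(toy)
        endo = model.trajectory(pv)
        rep = simulate_reporter(model, pv, "solo", "all", toy.external)
        last = toy.model.grid.class_labels[-1]
        assert np.allclose(rep.v[last][0], endo.v[last][0], rtol=1e-12)

    def test_empty_cre_gives_basal_only_solution(self, toy):
        region = toy.regions["gA"]
        cres = dict(region.cres)
        cres["nothing"] = (590, 591)
        toy.regions["gA"].cres.update(cres)
        inputs = all_inputs_for_reporter(toy)
        rep = simulate_reporter(toy.model, toy.truth, "gA", "nothing",
                                inputs)
        # basal activation is flat: so is the reporter profile
        last = toy.model.grid.class_labels[-1]
        prof = rep.v[last][0]
        assert np.allclose(prof, prof[0], rtol=1e-9)

    def test_gradient_cre_peaks_in_the_anterior(self, toy):
        # gA's proximal CRE carries the anterior-gradient input sites
        inputs = all_inputs_for_reporter(toy)
        rep = simulate_reporter(toy.model, toy.truth, "gA", "prox",
                                inputs)
        last = toy.model.grid.class_labels[-1]
        prof = rep.v[last][0]
        assert int(np.argmax(prof)) <= 2


def _solo_config(toy):
    from gapcircuit.params import CircuitConfig
    return CircuitConfig(genes=["solo"], tfs=["M1"],
                         synthesis={"solo": (20.0, 0.1)},
                         diffusion={"solo": (0.05, 0.05, 0.1, 0.1)})


def _solo_params(toy):
    cfg = _solo_config(toy)
    return ParameterVector(
        config=cfg, t_matrix=np.array([[60.0]]), q_btm=np.array([0.08]),
        affinity=np.array([0.004]), cooperativity=np.array([1.5]),
        repression_range=np.array([100.0]), delay=np.array([2.0]),
        decay_u=np.array([0.14]), decay_v=np.array([0.06]))


class TestTopology:
    def make_pv(self, toy, t):
        pv = ParameterVector.unpack(toy.truth.pack().copy(), toy.config)
        pv.t_matrix = np.asarray(t, float)
        return pv

    def test_single_all_positive_network(self, toy):
        pv = self.make_pv(toy, np.ones((2, 3)))
        summary = classify_topology([pv])
        assert (summary["n_positive"] == 1).all()
        assert (summary["n_negative"] == 0).all()
        assert (summary["consensus"] == "activation").all()

    def test_counts_sum_to_network_count_without_zeros(self, toy):
        fits = [self.make_pv(toy, np.full((2, 3), v))
                for v in [1.0, -2.0, 3.0]]
        summary = classify_topology(fits)
        assert ((summary["n_positive"] + summary["n_negative"])
                == 3).all()

    def test_zeros_count_in_neither_category(self, toy):
        pv = self.make_pv(toy, np.zeros((2, 3)))
        summary = classify_topology([pv])
        assert (summary["n_positive"] == 0).all()
        assert (summary["n_negative"] == 0).all()


class TestWeightScoreCorrelation:
    def frame(self, w, llr):
        return pd.DataFrame({"w_r": w, "llr": llr})

    def test_perfect_and_anti_monotone(self):
        w = np.array([0.1, 0.2, 0.5, 0.9])
        rho, r = weight_vs_llr_correlation(self.frame(w, w))
        assert rho == pytest.approx(1.0)
        assert r == pytest.approx(1.0)
        rho, _ = weight_vs_llr_correlation(self.frame(w, -w))
        assert rho == pytest.approx(-1.0)

    def test_independent_inputs_weakly_correlated(self, rng):
        w = rng.normal(size=500)
        s = rng.normal(size=500)
        rho, r = weight_vs_llr_correlation(self.frame(w, s))
        assert abs(rho) < 0.15

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            weight_vs_llr_correlation(self.frame(np.ones(5),
                                                 np.arange(5.0)))


class TestExclusionPathsAgree:
    def test_masked_scan_equals_region_rebuild(self, toy):
        # dropping a site via the exclusion mask must equal simulating
        # a region constructed without that site
        gene = "gA"
        site = toy.regions[gene].sites[0]
        masked = toy.model.rss(toy.truth, toy.dataset,
                               exclude_sites=frozenset({(gene, site)}))
        regions = dict(toy.regions)
        regions[gene] = regions[gene].without_site(site)
        rebuilt = CircuitModel(regions, toy.config, toy.model.grid,
                               toy.external, toy.model.llr_max)
        assert rebuilt.rss(toy.truth, toy.dataset) == pytest.approx(
            masked, rel=1e-12)
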