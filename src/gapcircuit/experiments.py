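"""In-silico perturbation experiments on a fitted circuit.

Site-level: the regulatory weight of a binding site,
w_r = (RSS_ref - RSS_mut) / RSS_ref, where RSS_mut is recomputed with
that single site excluded and all parameters frozen; ranked cumulative
site removal; correlation of regulatory weights with PWM scores.
Gene-level: null mutants (synthesis rates of the mutated gene set to
zero, optionally with mutant TF input profiles) and reporter constructs
(activation computed from the sites of one CRE only, no feedback of the
reporter into the TF fields).  Network-level: sign classification of
the fitted T-matrix entries over a collection of fits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionDataset
from .dynamics import CompiledCircuit, Trajectory
from .fit import CircuitModel
from .params import CircuitConfig, ParameterVector
from .regions import BindingSite

__all__ = [
    "regulatory_weight", "site_weight_report", "ranked_removal_curve",
    "simulate_mutant", "simulate_reporter", "classify_topology",
    "weight_vs_llr_correlation", "HIGH_IMPACT_THRESHOLD",
]

#: sites with |w_r| above this are called high-impact.
HIGH_IMPACT_THRESHOLD = 0.005


def regulatory_weight(model: CircuitModel, pv: ParameterVector,
                      data: ExpressionDataset, gene: str,
                      site: BindingSite,
                      rss_ref: float | None = None) -> float:
    """w_r = (RSS_ref - RSS_mut)/RSS_ref for one site, parameters frozen.

    Reported exactly as defined: w_r is positive when excluding the
    site *lowers* the RSS, so a site the model output depends on gets a
    negative value; ranking and impact thresholds therefore use |w_r|.
    A zero-strength site has w_r = 0, and w_r <= 1 always.
    """
    if site not in model.regions[gene].sites:
        raise ValueError(f"site {site} not in region {gene}")
    if rss_ref is None:
        rss_ref = model.rss(pv, data)
    rss_mut = model.rss(pv, data,
                        exclude_sites=frozenset({(gene, site)}))
    return (rss_ref - rss_mut) / rss_ref


def site_weight_report(model: CircuitModel, pv: ParameterVector,
                       data: ExpressionDataset) -> pd.DataFrame:
    """Regulatory weight of every annotated site in every region.

    Columns: gene, tf, start, end, strand, llr, w_r, inside_cre.
    """
    rss_ref = model.rss(pv, data)
    rows = []
    for gene, region in model.regions.items():
        for site in region.sites:
            w_r = regulatory_weight(model, pv, data, gene, site, rss_ref)
            inside = any(site.overlaps(a, b)
                         for a, b in region.cres.values())
            rows.append({
                "gene": gene, "tf": site.tf_name, "start": site.start,
                "end": site.end, "strand": site.strand, "llr": site.llr,
                "w_r": w_r, "inside_cre": inside,
            })
    return pd.DataFrame(rows)


def ranked_removal_curve(model: CircuitModel, pv: ParameterVector,
                         data: ExpressionDataset,
                         report: pd.DataFrame | None = None
                         ) -> pd.DataFrame:
    """Relative RSS after cumulative removal of sites ranked by |w_r|.

    Sites are removed in order of increasing |w_r| (least impactful
    first); row n holds RSS(first n sites removed)/RSS_ref, starting at
    exactly 1 for n = 0.  The curve length is site count + 1.
    """
    if report is None:
        report = site_weight_report(model, pv, data)
    report = report.assign(abs_w=report["w_r"].abs()) \
                   .sort_values("abs_w", kind="stable")
    rss_ref = model.rss(pv, data)
    sites_by_gene = {g: {(s.start, s.end, s.tf_name, s.strand): s
                         for s in region.sites}
                     for g, region in model.regions.items()}
    removed: set = set()
    rows = [{"n_removed": 0, "relative_rss": 1.0}]
    for _, rec in report.iterrows():
        site = sites_by_gene[rec["gene"]][
            (rec["start"], rec["end"], rec["tf"], rec["strand"])]
        removed.add((rec["gene"], site))
        rss_mut = model.rss(pv, data, exclude_sites=frozenset(removed))
        rows.append({"n_removed": len(removed),
                     "relative_rss": rss_mut / rss_ref})
    return pd.DataFrame(rows)


def simulate_mutant(model: CircuitModel, pv: ParameterVector, gene: str,
                    mutant_inputs: ExpressionDataset | None = None
                    ) -> Trajectory:
    """Null mutant: R_u = R_v = 0 for ``gene``; otherwise identical.

    ``mutant_inputs``, when given, replaces the external TF profiles
    (concentration profiles measured in mutant embryos).
    """
    if gene not in model.config.genes:
        raise KeyError(f"unknown gene {gene!r}")
    override = None
    if mutant_inputs is not None:
        override = CompiledCircuit(model.regions, model.config.tfs,
                                   mutant_inputs, model.grid,
                                   model.llr_max)
    return model.trajectory(pv, knockouts=(gene,),
                            external_override=override)


def simulate_reporter(model: CircuitModel, pv: ParameterVector,
                      gene: str, cre_name: str,
                      inputs: ExpressionDataset) -> Trajectory:
    """Reporter construct driven by the sites of one CRE.

    The reporter obeys the same synthesis/diffusion/decay equations as
    its parent gene, but its activation is computed from the sites
    overlapping the named CRE only, and its own product does not feed
    back: *all* regulator concentrations, including the gap genes', are
    taken from ``inputs`` (typically measured data or a wild-type
    simulation exported with ``Trajectory.to_dataset``).
    """
    region = model.regions[gene]
    from .regions import restrict_sites_to_cre
    sites = restrict_sites_to_cre(region, cre_name)
    reporter = f"{gene}::{cre_name}"
    rep_region = region.with_sites(sites)
    rep_region.gene = reporter
    cfg = model.config
    rep_config = CircuitConfig(
        genes=[reporter], tfs=list(cfg.tfs),
        synthesis={reporter: cfg.synthesis[gene]},
        diffusion={reporter: cfg.diffusion[gene]},
        coop_range=cfg.coop_range, bounds=dict(cfg.bounds))
    gi = cfg.genes.index(gene)
    rep_pv = ParameterVector(
        config=rep_config,
        t_matrix=pv.t_matrix[gi:gi + 1],
        q_btm=pv.q_btm[gi:gi + 1],
        affinity=pv.affinity,
        cooperativity=pv.cooperativity,
        repression_range=pv.repression_range[gi:gi + 1],
        delay=pv.delay[gi:gi + 1],
        decay_u=pv.decay_u[gi:gi + 1],
        decay_v=pv.decay_v[gi:gi + 1])
    compiled = CompiledCircuit({reporter: rep_region}, rep_config.tfs,
                               inputs, model.grid, model.llr_max)
    return compiled.run(rep_pv.all_thermo(), rep_pv.all_kinetics())


def classify_topology(fits: list[ParameterVector]) -> pd.DataFrame:
    """Sign classification of T entries over a collection of networks.

    Returns per (gene, tf): counts of positive (activation) and
    negative (repression) entries — zeros count in neither category —
    and the majority consensus.
    """
    if not fits:
        raise ValueError("need at least one fitted network")
    cfg = fits[0].config
    rows = []
    for gi, g in enumerate(cfg.genes):
        for ti, tf in enumerate(cfg.tfs):
            values = np.array([pv.t_matrix[gi, ti] for pv in fits])
            n_pos = int((values > 0).sum())
            n_neg = int((values < 0).sum())
            consensus = ("activation" if n_pos > n_neg else
                         "repression" if n_neg > n_pos else "tie")
            rows.append({"gene": g, "tf": tf, "n_positive": n_pos,
                         "n_negative": n_neg, "consensus": consensus})
    return pd.DataFrame(rows)


def weight_vs_llr_correlation(report: pd.DataFrame
                              ) -> tuple[float, float]:
    """(Spearman rho, Pearson r) between site w_r and PWM score."""
    if len(report) < 3:
        raise ValueError("need >= 3 sites")
    w = report["w_r"].to_numpy(dtype=float)
    s = report["llr"].to_numpy(dtype=float)
    if np.ptp(w) == 0 or np.ptp(s) == 0:
        raise ValueError("degenerate (constant) inputs")
    rho = stats.spearmanr(w, s).statistic
    r = stats.pearsonr(w, s).statistic
    return float(rho), float(r)
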