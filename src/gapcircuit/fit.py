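"""Model fitting: combined objective, differential evolution, validation.

The central object is :class:`GapGeneCircuit`, a scikit-learn-style
estimator: ``fit`` minimises the combined error (RSS + 5e4*wPGP +
1e-3*Penalty) over the free parameter vector by differential evolution,
``predict`` returns the trajectory at the fitted parameters and
``score`` the negative root-mean-square residual.  Cross-validation and
the label-shuffled negative control reuse the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import differential_evolution, minimize
from sklearn.base import BaseEstimator

from .data import ExpressionDataset
from .dynamics import CompiledCircuit, SimulationGrid, Trajectory
from .objective import (DEFAULT_WEIGHTS, PatternIndex, rms, rss,
                        score_report)
from .params import (CircuitConfig, ParameterVector, from_search_space,
                     to_search_space)
from .regions import RegulatoryRegion, restrict_sites_to_cre

__all__ = [
    "CircuitModel", "GapGeneCircuit", "FitResult", "fit_de",
    "crossvalidate", "make_negative_control", "flag_degenerate_affinities",
    "minimize_de", "partition_indices",
]

#: K below this for every site of a TF marks a degenerate fit
#: (the TF is effectively switched off).
DEGENERATE_K = 1.0e-4


class CircuitModel:
    """Regions + configuration + inputs, ready to simulate at any params.

    Bundles everything that stays fixed while the free vector varies:
    the regulatory regions with their predicted sites, the gene/TF
    layout, the nucleus/time grid, the external TF input profiles and
    the per-TF maximum log-odds scores.  Compiled circuits are cached
    per site-modification key, so repeated evaluation (fitting, site
    knockouts) stays cheap.
    """

    def __init__(self, regions: dict[str, RegulatoryRegion],
                 config: CircuitConfig, grid: SimulationGrid,
                 external_inputs: ExpressionDataset,
                 llr_max: dict[str, float],
                 initial_v: dict[str, np.ndarray] | None = None,
                 weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
                 wpgp_normalization: str = "printed"):
        self.regions = regions
        self.config = config
        self.grid = grid
        self.external_inputs = external_inputs
        self.llr_max = dict(llr_max)
        self.initial_v = initial_v
        self.weights = weights
        self.wpgp_normalization = wpgp_normalization
        self._cache: dict = {}

    def compiled(self, exclude_sites: frozenset = frozenset(),
                 cre: tuple[str, str] | None = None) -> CompiledCircuit:
        """Compiled circuit with optional site exclusions.

        ``exclude_sites`` holds (gene, BindingSite) pairs to drop;
        ``cre = (gene, cre_name)`` restricts that gene's sites to the
        named CRE.
        """
        key = (exclude_sites, cre)
        if key not in self._cache:
            regions = {}
            for g, region in self.regions.items():
                sites = list(region.sites)
                if cre is not None and cre[0] == g:
                    sites = restrict_sites_to_cre(region, cre[1])
                sites = [s for s in sites
                         if (g, s) not in exclude_sites]
                regions[g] = region.with_sites(sites)
            self._cache[key] = CompiledCircuit(
                regions, self.config.tfs, self.external_inputs,
                self.grid, self.llr_max)
        return self._cache[key]

    def trajectory(self, pv: ParameterVector,
                   knockouts: tuple[str, ...] = (),
                   exclude_sites: frozenset = frozenset(),
                   cre: tuple[str, str] | None = None,
                   external_override: CompiledCircuit | None = None
                   ) -> Trajectory:
        return self.compiled(exclude_sites, cre).run(
            pv.all_thermo(), pv.all_kinetics(), initial_v=self.initial_v,
            knockouts=knockouts, external_override=external_override)

    def rss(self, pv: ParameterVector, data: ExpressionDataset,
            **mods) -> float:
        return rss(self.trajectory(pv, **mods), data)

    def scores(self, pv: ParameterVector,
               data: ExpressionDataset) -> dict[str, float]:
        return score_report(self.trajectory(pv), data, pv.t_matrix,
                            self.weights, self.wpgp_normalization)

    def objective(self, data: ExpressionDataset):
        """Closure vector -> combined error (large-finite on blow-up)."""
        compiled = self.compiled()
        index = PatternIndex(data, self.config.genes)
        w0, w1, w2 = self.weights

        def fun(vector: np.ndarray) -> float:
            pv = ParameterVector.unpack(vector, self.config)
            try:
                traj = compiled.run(pv.all_thermo(), pv.all_kinetics(),
                                    initial_v=self.initial_v)
                rss_v, wpgp_v = index.scores(traj,
                                             self.wpgp_normalization)
                t = pv.t_matrix
                return w0 * rss_v + w1 * wpgp_v + w2 * float((t * t).sum())
            except (RuntimeError, ValueError):
                return 1.0e15
        return fun


@dataclass
class FitResult:
    """Outcome of one differential-evolution fit."""

    params: ParameterVector
    error: float
    rss: float
    rms: float
    wpgp: float
    penalty: float
    seed: int | None
    n_evaluations: int
    converged: bool
    degenerate_tfs: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "vector": self.params.pack().tolist(),
            "error": self.error, "rss": self.rss, "rms": self.rms,
            "wpgp": self.wpgp, "penalty": self.penalty, "seed": self.seed,
            "n_evaluations": self.n_evaluations,
            "converged": self.converged,
            "degenerate_tfs": self.degenerate_tfs,
        }


def flag_degenerate_affinities(pv: ParameterVector,
                               threshold: float = DEGENERATE_K
                               ) -> list[str]:
    """TFs whose affinity constant K fell below the plausibility floor.

    Fits where several TFs end up with K < 1e-4 have effectively
    switched those regulators off and are discarded from downstream
    analysis.
    """
    return [tf for tf, k in zip(pv.config.tfs, pv.affinity)
            if k < threshold]


def minimize_de(fun, bounds, seed=None, maxiter: int = 150,
                popsize: int = 7, mutation=(0.5, 1.0),
                recombination: float = 0.9, init: str = "sobol",
                polish: bool = True):
    """Bounded global minimisation by differential evolution.

    rand/1/bin with immediate updating and optional L-BFGS-B polish of
    the best member; deterministic for a fixed seed.  Returns the scipy
    result object.
    """
    return differential_evolution(
        fun, bounds, strategy="rand1bin", maxiter=maxiter,
        popsize=popsize, mutation=mutation, recombination=recombination,
        tol=0.0, seed=seed, init=init, polish=polish,
        updating="immediate")


def partition_indices(d: int, k: int, seed=None) -> list[np.ndarray]:
    """Random partition of range(d) into k near-equal disjoint subsets."""
    if k > d:
        raise ValueError(f"k={k} exceeds D={d}")
    rng = np.random.default_rng(seed)
    return np.array_split(rng.permutation(d), k)


class GapGeneCircuit(BaseEstimator):
    """Sequence-based gap-gene circuit as a scikit-learn estimator.

    Parameters
    ----------
    model : CircuitModel
        The frozen circuit (regions, grid, inputs).
    bounds : (lo, hi) arrays, optional
        Free-vector bounds; default from the model's config blocks.
    seed : int, optional
        Differential-evolution RNG seed (same seed -> same fit).
    maxiter, popsize, mutation, recombination, init :
        Passed to scipy's differential evolution (rand/1/bin strategy;
        population size is ``popsize * n_free``).

    Attributes
    ----------
    params_ : ParameterVector
        Best-found parameters after :meth:`fit`.
    result_ : FitResult
        Scores, evaluation count and degeneracy flags.
    """

    def __init__(self, model: CircuitModel, bounds=None, seed=None,
                 maxiter: int = 150, popsize: int = 7,
                 mutation=(0.5, 1.0), recombination: float = 0.9,
                 init: str = "sobol", polish: bool = True,
                 polish_maxfun: int = 5000):
        self.model = model
        self.bounds = bounds
        self.seed = seed
        self.maxiter = maxiter
        self.popsize = popsize
        self.mutation = mutation
        self.recombination = recombination
        self.init = init
        self.polish = polish
        self.polish_maxfun = polish_maxfun

    def fit(self, data: ExpressionDataset, y=None) -> "GapGeneCircuit":
        cfg = self.model.config
        lo, hi = self.bounds if self.bounds is not None \
            else cfg.vector_bounds()
        slo = to_search_space(cfg, np.asarray(lo, float))
        shi = to_search_space(cfg, np.asarray(hi, float))
        fun = self.model.objective(data)

        def fun_search(y_vec: np.ndarray) -> float:
            return fun(from_search_space(cfg, y_vec))

        res = minimize_de(
            fun_search, list(zip(slo, shi)), seed=self.seed,
            maxiter=self.maxiter, popsize=self.popsize,
            mutation=self.mutation, recombination=self.recombination,
            init=self.init, polish=False)
        x_best, f_best, nfev = res.x, res.fun, int(res.nfev)
        if self.polish:
            # bounded local refinement of the best member, with a hard
            # evaluation cap so the total budget stays predictable
            local = minimize(
                fun_search, x_best, method="L-BFGS-B",
                bounds=list(zip(slo, shi)),
                options={"maxfun": self.polish_maxfun})
            nfev += int(local.nfev)
            if local.fun < f_best:
                x_best, f_best = local.x, local.fun
        best = from_search_space(cfg, x_best)
        pv = ParameterVector.unpack(best, cfg)
        scores = self.model.scores(pv, data)
        self.params_ = pv
        self.vector_ = best.copy()
        self.result_ = FitResult(
            params=pv, error=scores["Error"], rss=scores["RSS"],
            rms=scores["rms"], wpgp=scores["wPGP"],
            penalty=scores["Penalty"], seed=self.seed,
            n_evaluations=nfev, converged=bool(res.success),
            degenerate_tfs=flag_degenerate_affinities(pv))
        return self

    def predict(self, data=None) -> Trajectory:
        """Trajectory at the fitted parameters."""
        self._check_fitted()
        return self.model.trajectory(self.params_)

    def score(self, data: ExpressionDataset, y=None) -> float:
        """Negative rms residual (higher is better)."""
        self._check_fitted()
        value = self.model.rss(self.params_, data)
        return -rms(value, data.D)

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise AttributeError("estimator is not fitted; call fit first")


def fit_de(model: CircuitModel, data: ExpressionDataset, bounds=None,
           seed: int | None = None, maxiter: int = 40,
           popsize: int = 6, polish_maxfun: int = 5000) -> FitResult:
    """Functional wrapper: one DE fit, returning the FitResult."""
    est = GapGeneCircuit(model, bounds=bounds, seed=seed,
                         maxiter=maxiter, popsize=popsize,
                         polish_maxfun=polish_maxfun)
    est.fit(data)
    return est.result_


def crossvalidate(model: CircuitModel, data: ExpressionDataset, k: int = 4,
                  seed: int | None = None, maxiter: int = 40,
                  popsize: int = 6) -> list[dict]:
    """k-fold cross-validation of the fitting procedure.

    The observations are partitioned randomly into k near-equal subsets;
    the model is fitted to k-1 of them and scored by rms on the held-out
    subset, each subset being left out exactly once.
    """
    folds = partition_indices(data.D, k, seed)
    out = []
    for j, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(data.D), test_idx)
        train = data.subset(np.sort(train_idx))
        test = data.subset(np.sort(test_idx))
        result = fit_de(model, train, seed=None if seed is None
                        else seed + j, maxiter=maxiter, popsize=popsize)
        test_rss = model.rss(result.params, test)
        out.append({
            "fold": j,
            "train_result": result,
            "test_rms": rms(test_rss, test.D),
        })
    return out


def make_negative_control(data: ExpressionDataset,
                          pairs: list[tuple[str, str]] | None = None
                          ) -> ExpressionDataset:
    """Shuffle target patterns with respect to the regulatory regions.

    Default pairing swaps hb with kni and Kr with gt (or, for a two-gene
    circuit, the two genes); TF input profiles are untouched.  Applying
    the shuffle twice restores the original dataset.
    """
    if pairs is None:
        genes = set(data.genes)
        if {"hb", "kni", "Kr", "gt"} <= genes:
            pairs = [("hb", "kni"), ("Kr", "gt")]
        elif len(data.genes) == 2:
            pairs = [tuple(data.genes)]
        else:
            raise ValueError(
                "cannot infer swap pairs; pass them explicitly")
    return data.swap_genes(pairs)
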