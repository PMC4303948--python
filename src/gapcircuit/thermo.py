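"""Thermodynamic promoter-occupancy layer.

The probability that the basal transcriptional machinery (BTM) is
recruited to a target gene's promoter is computed from the partition
function over all binding configurations of the predicted sites in its
regulatory region:

    E = sum_sigma W(sigma) Q(sigma) / (sum_sigma W(sigma) Q(sigma)
                                       + sum_sigma W(sigma))

where a configuration ``sigma`` is a non-overlapping subset of bound
sites together with an effective/neutral flag per bound repressor.  The
statistical weight of a configuration is

    W(sigma) = prod_bound q(S_i)
             * prod_{adjacent same-TF bound pairs within d_coop} omega
             * prod_{effective repressors} beta_R

with site strength ``q(S) = K(S_max) * v_TF * exp[LLR(S) - LLR(S_max)]``,
and the BTM interaction weight is ``Q(sigma) = q_btm * prod_bound-activators
T^ab``.  Signed T entries encode the regulatory mode: positive values act
as activator weights (alpha), negative magnitudes as repressor strengths
(beta) under the short-range quenching mechanism — an *effective*
repressor makes all DNA within ``d_R`` bp of its midpoint inaccessible to
any other binding and rescales the configuration weight by beta.

Two evaluators are provided: an exact enumeration
(:func:`activation_brute_force`, exponential, serves as oracle) and a
polynomial dynamic program (:func:`activation_dp`) over sites sorted by
position, whose exactness rests on midpoints of non-overlapping sites
being ordered, so compatibility with the most recent bound site implies
compatibility with all earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .regions import BindingSite

__all__ = [
    "ThermoParams", "Configuration", "site_strength", "config_weight",
    "activation_brute_force", "activation_dp",
]

#: |T| below this is "no interaction": the TF binds neutrally.
NEUTRAL_T = 0.0


@dataclass
class ThermoParams:
    """Thermodynamic parameters for one target gene.

    ``t_row`` maps each regulator to its signed T^ab entry; ``affinity``
    is K(S_max) per TF; ``cooperativity`` the homotypic omega per TF;
    ``repression_range`` the quenching radius d_R (bp) per TF;
    ``coop_range`` the maximum edge-to-edge distance for the homotypic
    cooperativity bonus; ``q_btm`` the basal machinery constant.
    """

    target_gene: str
    t_row: dict[str, float]
    affinity: dict[str, float]
    cooperativity: dict[str, float] = field(default_factory=dict)
    repression_range: dict[str, float] = field(default_factory=dict)
    coop_range: float = 50.0
    q_btm: float = 0.1

    def __post_init__(self) -> None:
        if self.q_btm <= 0:
            raise ValueError("q_btm must be positive")
        for tf, k in self.affinity.items():
            if k <= 0:
                raise ValueError(f"affinity K for {tf} must be positive")
        for tf, w in self.cooperativity.items():
            if w < 0:
                raise ValueError(f"cooperativity for {tf} must be >= 0")

    def role(self, tf: str) -> int:
        """+1 activator, -1 repressor, 0 neutral (T == 0)."""
        t = self.t_row.get(tf, 0.0)
        if t > NEUTRAL_T:
            return 1
        if t < -NEUTRAL_T:
            return -1
        return 0

    def omega(self, tf: str) -> float:
        return self.cooperativity.get(tf, 1.0)

    def d_rep(self, tf: str) -> float:
        return self.repression_range.get(tf, 0.0)


@dataclass(frozen=True)
class Configuration:
    """A binding configuration: bound site indices + effective repressors."""

    bound: frozenset[int]
    effective: frozenset[int] = frozenset()


def site_strength(site: BindingSite, params: ThermoParams, v_tf: float,
                  llr_max: float) -> float:
    """Strength q(S) = K(S_max) * v_TF * exp[LLR(S) - LLR(S_max)].

    The strongest possible site of the TF at concentration v binds with
    weight K*v; weaker sites are discounted exponentially in their
    log-odds deficit.
    """
    if v_tf < 0:
        raise ValueError("negative TF concentration")
    k = params.affinity[site.tf_name]
    return k * v_tf * float(np.exp(site.llr - llr_max))


def _site_q(sites: list[BindingSite], params: ThermoParams,
            concentrations: dict[str, float],
            llr_max: dict[str, float]) -> np.ndarray:
    return np.array([
        site_strength(s, params, concentrations[s.tf_name],
                      llr_max[s.tf_name])
        for s in sites
    ])


def _check_config(config: Configuration, sites: list[BindingSite],
                  params: ThermoParams) -> None:
    bound = sorted(config.bound)
    for i in config.effective:
        if i not in config.bound:
            raise ValueError("effective site not bound")
        if params.role(sites[i].tf_name) != -1:
            raise ValueError("effective site is not a repressor")
    for a, b in zip(bound, bound[1:]):
        if sites[a].overlaps(sites[b].start, sites[b].end):
            raise ValueError("bound sites overlap")
    for r in config.effective:
        d_r = params.d_rep(sites[r].tf_name)
        for j in config.bound:
            if j != r and abs(sites[j].midpoint
                              - sites[r].midpoint) <= d_r:
                raise ValueError("bound site within repression range")


def config_weight(config: Configuration, sites: list[BindingSite],
                  params: ThermoParams, concentrations: dict[str, float],
                  llr_max: dict[str, float]) -> tuple[float, float]:
    """Statistical weights (W, Q) of a single configuration.

    The empty configuration has W = 1 and Q = q_btm.  Bound repressors
    (effective or neutral) contribute nothing to Q.
    """
    _check_config(config, sites, params)
    q = _site_q(sites, params, concentrations, llr_max)
    bound = sorted(config.bound, key=lambda i: sites[i].start)
    w = 1.0
    big_q = params.q_btm
    for i in bound:
        w *= q[i]
        if i in config.effective:
            w *= abs(params.t_row[sites[i].tf_name])
        elif params.role(sites[i].tf_name) == 1:
            big_q *= params.t_row[sites[i].tf_name]
    for a, b in zip(bound, bound[1:]):
        if (sites[a].tf_name == sites[b].tf_name
                and sites[b].start - sites[a].end <= params.coop_range):
            w *= params.omega(sites[a].tf_name)
    return w, big_q


def _valid_subset(idx: tuple[int, ...], sites: list[BindingSite]) -> bool:
    for a, b in zip(idx, idx[1:]):
        if sites[a].overlaps(sites[b].start, sites[b].end):
            return False
    return True


def activation_brute_force(sites: list[BindingSite], params: ThermoParams,
                           concentrations: dict[str, float],
                           llr_max: dict[str, float],
                           max_sites: int = 15) -> float:
    """Exact activation probability by full configuration enumeration.

    Enumerates every non-overlapping bound subset and every assignment of
    effective flags to its repressors; exponential cost, refused above
    ``max_sites``.  Serves as the oracle for :func:`activation_dp`.
    """
    n = len(sites)
    if n > max_sites:
        raise ValueError(f"{n} sites exceeds enumeration cap {max_sites}")
    order = sorted(range(n), key=lambda i: sites[i].start)
    num = params.q_btm   # empty configuration: W=1, Q=q_btm
    den = 1.0
    for mask in range(1, 1 << n):
        idx = tuple(i for i in order if mask >> i & 1)
        if not _valid_subset(idx, sites):
            continue
        reps = [i for i in idx if params.role(sites[i].tf_name) == -1]
        for flags in product((False, True), repeat=len(reps)):
            eff = frozenset(r for r, f in zip(reps, flags) if f)
            config = Configuration(frozenset(idx), eff)
            try:
                _check_config(config, sites, params)
            except ValueError:
                continue
            w, big_q = config_weight(config, sites, params, concentrations,
                                     llr_max)
            num += w * big_q
            den += w
    return num / (num + den)


def activation_dp(sites: list[BindingSite], params: ThermoParams,
                  concentrations: dict[str, float],
                  llr_max: dict[str, float]) -> float:
    """Activation probability via the exact O(n^2) dynamic program.

    Sites are sorted by start; the DP state is the most recent bound site
    and whether it binds as an effective repressor.  Two partition sums
    are accumulated: Z_off (plain W) and Z_on (W times the product of
    activator T factors), giving
    ``E = q_btm*Z_on / (q_btm*Z_on + Z_off)``.
    """
    order = sorted(range(len(sites)), key=lambda i: sites[i].start)
    ss = [sites[i] for i in order]
    n = len(ss)
    if n == 0:
        return params.q_btm / (1.0 + params.q_btm)
    q = _site_q(ss, params, concentrations, llr_max)
    role = np.array([params.role(s.tf_name) for s in ss])
    beta = np.array([abs(params.t_row.get(s.tf_name, 0.0)) for s in ss])
    tval = np.array([params.t_row.get(s.tf_name, 0.0) for s in ss])
    d_r = np.array([params.d_rep(s.tf_name) for s in ss])
    mid = np.array([s.midpoint for s in ss])

    # dp[j][f]: sum of weights of partial configurations whose last bound
    # site is j with flag f (f=1: effective repressor).
    dp_off = np.zeros((n, 2))
    dp_on = np.zeros((n, 2))
    for j in range(n):
        flags_j = (0, 1) if role[j] == -1 else (0,)
        for fj in flags_j:
            w_off = q[j] * (beta[j] if fj else 1.0)
            w_on = w_off * (tval[j] if (role[j] == 1 and not fj) else 1.0)
            acc_off = 1.0   # predecessor = empty configuration
            acc_on = 1.0
            for k in range(j):
                if ss[k].overlaps(ss[j].start, ss[j].end):
                    continue
                coop = 1.0
                if (ss[k].tf_name == ss[j].tf_name
                        and ss[j].start - ss[k].end <= params.coop_range):
                    coop = params.omega(ss[j].tf_name)
                for fk in (0, 1):
                    if fk == 1 and role[k] != -1:
                        continue
                    if fk == 1 and mid[j] - mid[k] <= d_r[k]:
                        continue
                    if fj == 1 and mid[j] - mid[k] <= d_r[j]:
                        continue
                    acc_off += coop * dp_off[k, fk]
                    acc_on += coop * dp_on[k, fk]
            dp_off[j, fj] = w_off * acc_off
            dp_on[j, fj] = w_on * acc_on
    z_off = 1.0 + dp_off.sum()
    z_on = 1.0 + dp_on.sum()
    num = params.q_btm * z_on
    return num / (num + z_off)
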