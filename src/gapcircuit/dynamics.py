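"""Delay reaction-diffusion dynamics of gap mRNA and protein.

For each target gene ``a`` in nucleus ``i``:

    du_i/dt = R_u * E_i(t) + D_u(n) * [(u_{i-1}-u_i) + (u_{i+1}-u_i)]
              - lambda_u * u_i
    dv_i/dt = R_v * u_i(t - tau_v) + D_v(n) * [...] - lambda_v * v_i

where E is the thermodynamic activation probability recomputed at every
integration step from the current TF fields (gap proteins feed back;
maternal/terminal inputs are interpolated from data), n is the cleavage
cycle, and tau_v the protein-synthesis delay.  The simulated period
spans cleavage cycle 13 and cycle 14A (8 classes of 6.5 min); the
nucleus row doubles at the cycle boundary, daughters inheriting the
mother's concentrations.  Integration is fixed-step explicit Euler with
a history buffer for the delay term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .data import ExpressionDataset
from .regions import RegulatoryRegion
from .thermo import ThermoParams

__all__ = [
    "KineticParams", "SimulationGrid", "Trajectory", "CompiledCircuit",
    "simulate", "interpolate_inputs", "decay_from_halflife",
]


def decay_from_halflife(halflife: float) -> float:
    """Decay rate lambda = ln 2 / half-life (minutes)."""
    if halflife <= 0:
        raise ValueError("half-life must be positive")
    return float(np.log(2.0) / halflife)


@dataclass
class KineticParams:
    """Per-gene kinetic constants of the RD equations.

    ``diffusion_u``/``diffusion_v`` map the cleavage-cycle number (13 or
    14) to the diffusion coefficient for that cycle.
    """

    synthesis_u: float
    synthesis_v: float
    diffusion_u: dict[int, float]
    diffusion_v: dict[int, float]
    decay_u: float
    decay_v: float
    delay_v: float = 0.0

    def __post_init__(self) -> None:
        if min(self.synthesis_u, self.synthesis_v, self.decay_u,
               self.decay_v, self.delay_v) < 0:
            raise ValueError("rates and delays must be non-negative")


@dataclass
class SimulationGrid:
    """Nucleus/time discretisation over cycles 13 and 14A.

    Cycle 14A is divided into ``n_classes_c14`` temporal classes of
    ``class_duration`` (6.5 min) each; output snapshots are taken at the
    midpoint of cycle 13 and of every class.  ``dt`` is the Euler step.
    """

    n_nuclei_c13: int = 29
    cycle13_duration: float = 16.0
    class_duration: float = 6.5
    n_classes_c14: int = 8
    dt: float = 0.0625
    mitosis_blackout: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_nuclei_c13 < 1 or self.n_classes_c14 < 1:
            raise ValueError("grid sizes must be positive")

    @classmethod
    def from_c14_duration(cls, duration: float,
                          class_duration: float = 6.5,
                          **kw) -> "SimulationGrid":
        """Grid with cycle 14A of the given length split into 6.5-min
        classes (52 min -> 8 classes)."""
        n = int(round(duration / class_duration))
        return cls(n_classes_c14=n, class_duration=class_duration, **kw)

    @property
    def n_nuclei_c14(self) -> int:
        return 2 * self.n_nuclei_c13

    @property
    def class_labels(self) -> list[str]:
        return ["c13"] + [f"T{k}" for k in
                          range(1, self.n_classes_c14 + 1)]

    @property
    def class_times(self) -> dict[str, float]:
        times = {"c13": 0.5 * self.cycle13_duration}
        for k in range(1, self.n_classes_c14 + 1):
            times[f"T{k}"] = (self.cycle13_duration
                              + (k - 0.5) * self.class_duration)
        return times

    @property
    def steps_c13(self) -> int:
        return max(int(round(self.cycle13_duration / self.dt)), 1)

    @property
    def steps_c14(self) -> int:
        dur = self.n_classes_c14 * self.class_duration
        return max(int(round(dur / self.dt)), 1)

    def nuclei_of(self, time_class: str) -> int:
        return self.n_nuclei_c13 if time_class == "c13" \
            else self.n_nuclei_c14


@dataclass
class Trajectory:
    """Simulated mRNA (u) and protein (v) snapshots per time class.

    ``u[cls]`` and ``v[cls]`` have shape (n_genes, n_nuclei_of_class).
    """

    genes: list[str]
    grid: SimulationGrid
    u: dict[str, np.ndarray] = field(default_factory=dict)
    v: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in self.grid.class_labels:
            if cls not in self.v:
                continue
            for gi, g in enumerate(self.genes):
                vv = self.v[cls][gi]
                uu = self.u[cls][gi]
                for i in range(len(vv)):
                    rows.append((g, cls, i, uu[i], vv[i]))
        return pd.DataFrame(rows,
                            columns=["gene", "time_class", "nucleus",
                                     "u", "v"])

    def to_dataset(self) -> ExpressionDataset:
        """Protein profiles as an ExpressionDataset (e.g. reporter input)."""
        df = self.to_frame().rename(columns={"v": "conc"})
        df = df[["gene", "time_class", "nucleus", "conc"]]
        df["conc"] = df["conc"].clip(lower=0.0)
        return ExpressionDataset(df, self.grid.class_times)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def interpolate_inputs(dataset: ExpressionDataset, t: float,
                       n_nuclei: int | None = None
                       ) -> dict[str, np.ndarray]:
    """Per-TF nucleus profiles at time ``t`` (minutes).

    Piecewise-linear in time between class midpoints, constant beyond the
    first/last class.  Classes with half the target nucleus count are
    upsampled by duplicating each mother value.
    """
    if not dataset.class_times:
        raise ValueError("dataset lacks class_times")
    out: dict[str, np.ndarray] = {}
    classes = dataset.classes
    times = np.array([dataset.class_times[c] for c in classes])
    for tf in dataset.genes:
        mats = []
        for c in classes:
            prof = dataset.profile(tf, c)
            mats.append(prof)
        n_max = n_nuclei or max(len(m) for m in mats)
        stack = np.empty((len(classes), n_max))
        for j, m in enumerate(mats):
            if len(m) == n_max:
                stack[j] = m
            elif 2 * len(m) == n_max:
                stack[j] = np.repeat(m, 2)
            else:
                raise ValueError(
                    f"class {classes[j]} has {len(m)} nuclei; expected "
                    f"{n_max} or {n_max // 2}")
        tc = min(max(t, times[0]), times[-1])
        j1 = int(np.searchsorted(times, tc, side="left"))
        if j1 == 0 or times[j1] == tc:
            out[tf] = stack[j1].copy()
        else:
            w = (tc - times[j1 - 1]) / (times[j1] - times[j1 - 1])
            out[tf] = (1 - w) * stack[j1 - 1] + w * stack[j1]
    return out


def _interp_steps(times: np.ndarray, values: np.ndarray,
                  t_query: np.ndarray) -> np.ndarray:
    """Linear time interpolation of (n_classes, n_nuc) onto t_query."""
    tq = np.clip(t_query, times[0], times[-1])
    idx = np.searchsorted(times, tq, side="right")
    idx = np.clip(idx, 1, len(times) - 1)
    t0, t1 = times[idx - 1], times[idx]
    w = np.where(t1 > t0, (tq - t0) / np.where(t1 > t0, t1 - t0, 1.0), 0.0)
    return ((1 - w)[:, None] * values[idx - 1]
            + w[:, None] * values[idx])


class CompiledCircuit:
    """A circuit frozen for repeated simulation (fitting inner loop).

    Pre-computes flat site arrays, TF source mapping and per-step
    external-input fields once; :meth:`run` then only refreshes the
    parameter-dependent arrays and calls the jitted kernel.
    """

    def __init__(self, regions: dict[str, RegulatoryRegion],
                 tfs: list[str], external_inputs: ExpressionDataset,
                 grid: SimulationGrid, llr_max: dict[str, float]):
        self.genes = list(regions)
        self.regions = regions
        self.tfs = list(tfs)
        self.grid = grid
        self.llr_max = dict(llr_max)

        ext_tfs = [t for t in self.tfs if t not in self.genes]
        self.external_tfs = ext_tfs
        tf_index = {t: i for i, t in enumerate(self.tfs)}
        gene_index = {g: i for i, g in enumerate(self.genes)}
        self.tf_src_type = np.array(
            [0 if t in ext_tfs else 1 for t in self.tfs], dtype=np.int64)
        self.tf_src_idx = np.array(
            [ext_tfs.index(t) if t in ext_tfs else gene_index[t]
             for t in self.tfs], dtype=np.int64)

        offs = [0]
        s_tf, s_start, s_end, s_mid, s_rel = [], [], [], [], []
        self.site_lists = {}
        for g in self.genes:
            sites = sorted(regions[g].sites, key=lambda s: s.start)
            self.site_lists[g] = sites
            for s in sites:
                if s.tf_name not in tf_index:
                    raise ValueError(
                        f"site TF {s.tf_name} not among regulators {tfs}")
                s_tf.append(tf_index[s.tf_name])
                s_start.append(float(s.start))
                s_end.append(float(s.end))
                s_mid.append(s.midpoint)
                s_rel.append(np.exp(s.llr - llr_max[s.tf_name]))
            offs.append(len(s_tf))
        self.site_off = np.array(offs, dtype=np.int64)
        self.s_tf = np.array(s_tf, dtype=np.int64)
        self.s_start = np.array(s_start)
        self.s_end = np.array(s_end)
        self.s_mid = np.array(s_mid)
        self.s_rel = np.array(s_rel)

        # external input fields per integration step, per phase
        missing = [t for t in ext_tfs if t not in external_inputs.genes] \
            if ext_tfs else []
        if missing:
            raise ValueError(f"no input profiles for external TFs {missing}")
        self._build_external(external_inputs)

    def _build_external(self, external_inputs: ExpressionDataset) -> None:
        grid = self.grid
        n13, n14 = grid.n_nuclei_c13, grid.n_nuclei_c14
        s13, s14 = grid.steps_c13, grid.steps_c14
        t13 = np.arange(s13 + 1) * grid.dt
        t14 = grid.cycle13_duration + np.arange(s14 + 1) * grid.dt
        self.ext13 = np.zeros((max(len(self.external_tfs), 1), s13 + 1, n13))
        self.ext14 = np.zeros((max(len(self.external_tfs), 1), s14 + 1, n14))
        if not self.external_tfs:
            return
        classes = external_inputs.classes
        times = np.array([external_inputs.class_times[c] for c in classes])
        for e, tf in enumerate(self.external_tfs):
            stack = np.empty((len(classes), n14))
            for j, c in enumerate(classes):
                prof = external_inputs.profile(tf, c)
                if len(prof) == n14:
                    stack[j] = prof
                elif len(prof) == n13:
                    stack[j] = np.repeat(prof, 2)
                else:
                    raise ValueError(
                        f"profile {tf}/{c} has {len(prof)} nuclei, grid "
                        f"expects {n13} or {n14}")
            v14 = _interp_steps(times, stack, t14)
            v13full = _interp_steps(times, stack, t13)
            self.ext14[e] = v14
            # mother-nucleus field: average of the two daughter columns
            self.ext13[e] = 0.5 * (v13full[:, 0::2] + v13full[:, 1::2])

    # -- parameter-dependent arrays ------------------------------------

    def _thermo_arrays(self, thermo: dict[str, ThermoParams]):
        n_sites = len(self.s_tf)
        qcoef = np.zeros(n_sites)
        tval = np.zeros(n_sites)
        role = np.zeros(n_sites, dtype=np.int64)
        beta = np.zeros(n_sites)
        omega = np.ones(n_sites)
        drep = np.zeros(n_sites)
        coop_range = np.zeros(len(self.genes))
        q_btm = np.zeros(len(self.genes))
        for gi, g in enumerate(self.genes):
            tp = thermo[g]
            coop_range[gi] = tp.coop_range
            q_btm[gi] = tp.q_btm
            j0, j1 = self.site_off[gi], self.site_off[gi + 1]
            for j in range(j0, j1):
                tf = self.tfs[self.s_tf[j]]
                qcoef[j] = tp.affinity[tf] * self.s_rel[j]
                t = tp.t_row.get(tf, 0.0)
                tval[j] = t
                role[j] = tp.role(tf)
                beta[j] = abs(t)
                omega[j] = tp.omega(tf)
                drep[j] = tp.d_rep(tf)
        return (qcoef, tval, role, beta, omega, drep, coop_range, q_btm)

    def activation(self, thermo: dict[str, ThermoParams],
                   concentrations: dict[str, np.ndarray]) -> np.ndarray:
        """E per (gene, nucleus) at fixed TF concentration profiles."""
        (qcoef, tval, role, beta, omega, drep, coop_range,
         q_btm) = self._thermo_arrays(thermo)
        n_nuc = len(next(iter(concentrations.values())))
        conc = np.zeros((len(self.tfs), n_nuc))
        for t, tf in enumerate(self.tfs):
            conc[t] = concentrations[tf]
        return _kernel.activation_profile_core(
            n_nuc, self.site_off, self.s_tf, self.s_start, self.s_end,
            self.s_mid, qcoef, tval, role, beta, omega, drep, coop_range,
            q_btm, conc)

    def run(self, thermo: dict[str, ThermoParams],
            kinetics: dict[str, KineticParams],
            initial_v: dict[str, np.ndarray] | None = None,
            initial_u: dict[str, np.ndarray] | None = None,
            knockouts: tuple[str, ...] = (),
            external_override: "CompiledCircuit | None" = None
            ) -> Trajectory:
        grid = self.grid
        n13 = grid.n_nuclei_c13
        n_genes = len(self.genes)
        (qcoef, tval, role, beta, omega, drep, coop_range,
         q_btm) = self._thermo_arrays(thermo)
        r_u = np.array([kinetics[g].synthesis_u for g in self.genes])
        r_v = np.array([kinetics[g].synthesis_v for g in self.genes])
        for g in knockouts:
            if g not in self.genes:
                raise KeyError(f"unknown gene {g!r}")
            gi = self.genes.index(g)
            r_u[gi] = 0.0
            r_v[gi] = 0.0
        du13 = np.array([kinetics[g].diffusion_u[13] for g in self.genes])
        du14 = np.array([kinetics[g].diffusion_u[14] for g in self.genes])
        dv13 = np.array([kinetics[g].diffusion_v[13] for g in self.genes])
        dv14 = np.array([kinetics[g].diffusion_v[14] for g in self.genes])
        lam_u = np.array([kinetics[g].decay_u for g in self.genes])
        lam_v = np.array([kinetics[g].decay_v for g in self.genes])
        dec_u = np.exp(-lam_u * grid.dt)
        dec_v = np.exp(-lam_v * grid.dt)
        phi_u = np.where(lam_u > 0, (1.0 - dec_u) / np.where(
            lam_u > 0, lam_u, 1.0), grid.dt)
        phi_v = np.where(lam_v > 0, (1.0 - dec_v) / np.where(
            lam_v > 0, lam_v, 1.0), grid.dt)
        lag = np.array([kinetics[g].delay_v / grid.dt
                        for g in self.genes], dtype=float)
        u0 = np.zeros((n_genes, n13))
        v0 = np.zeros((n_genes, n13))
        for gi, g in enumerate(self.genes):
            if initial_u and g in initial_u:
                u0[gi] = np.asarray(initial_u[g], dtype=float)
            if initial_v and g in initial_v:
                v0[gi] = np.asarray(initial_v[g], dtype=float)

        ct = grid.class_times
        out13 = np.array([int(round(ct["c13"] / grid.dt))], dtype=np.int64)
        out14 = np.array(
            [int(round((ct[c] - grid.cycle13_duration) / grid.dt))
             for c in grid.class_labels[1:]], dtype=np.int64)
        blackout = int(round(grid.mitosis_blackout / grid.dt))
        src = external_override or self
        rec13u, rec13v, rec14u, rec14v, status = _kernel.simulate_core(
            n13, grid.steps_c13, grid.steps_c14, grid.dt,
            self.site_off, self.s_tf, self.s_start, self.s_end, self.s_mid,
            qcoef, tval, role, beta, omega, drep, coop_range, q_btm,
            self.tf_src_type, self.tf_src_idx,
            r_u, r_v, du13, du14, dv13, dv14, dec_u, phi_u, dec_v, phi_v,
            lag, src.ext13, src.ext14, u0, v0, out13, out14, blackout)
        if status != 0:
            raise RuntimeError(
                "integration became non-finite; reduce dt or check "
                "parameter magnitudes")
        traj = Trajectory(self.genes, grid)
        traj.u["c13"] = rec13u[0]
        traj.v["c13"] = rec13v[0]
        for k, c in enumerate(grid.class_labels[1:]):
            traj.u[c] = rec14u[k]
            traj.v[c] = rec14v[k]
        return traj


def simulate(regions: dict[str, RegulatoryRegion],
             thermo_params: dict[str, ThermoParams],
             kinetic_params: dict[str, KineticParams],
             external_inputs: ExpressionDataset,
             grid: SimulationGrid,
             llr_max: dict[str, float],
             initial_v: dict[str, np.ndarray] | None = None,
             initial_u: dict[str, np.ndarray] | None = None) -> Trajectory:
    """One-shot simulation (compiles the circuit, then runs it once).

    The regulator list is taken from the union of the thermo T rows.
    """
    tfs = sorted({tf for tp in thermo_params.values() for tf in tp.t_row})
    compiled = CompiledCircuit(regions, tfs, external_inputs, grid, llr_max)
    return compiled.run(thermo_params, kinetic_params, initial_v, initial_u)
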