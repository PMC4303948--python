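"""Synthetic fixtures: PWMs, regions with planted sites, gradients,
and a fully specified toy circuit with known ground-truth parameters.

Everything the other modules consume can be generated here without any
external download: motif matrices with controllable information
content, regulatory sequences with consensus words planted at known
positions, smooth anterior-posterior concentration profiles with
multiplicative (concentration-proportional) noise, and a two-gene toy
circuit whose data are forward-simulated from known parameters — the
substrate for parameter-recovery and negative-control benchmarks.

The toy circuit drives two gap-like genes with two spatially distinct
external inputs — an anterior exponential gradient (M1, Bcd-like) and a
posterior sigmoid (M2, Tll/Cad-like) — plus one gap-gene feedback TF
(gA, which autoactivates and quenches gB).  M1 activates gA and M2
quenches it; M2 activates gB while gA and M1 quench it, producing
complementary anterior/posterior domains over 20 nuclei and 5 time
classes.  Two inputs with different axis shapes keep the sensitivity
columns of the regulatory parameters linearly separable, which is what
makes per-entry identifiability (and hence sign recovery) possible at
this scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ExpressionDataset
from .dynamics import SimulationGrid, Trajectory
from .fit import CircuitModel
from .motifs import PWM
from .params import CircuitConfig, ParameterVector
from .regions import BindingSite, RegulatoryRegion, scan_sequence

__all__ = [
    "GradientShape", "FixtureSpec", "synth_pwm", "synth_region",
    "synth_gradients", "synth_ground_truth", "ToyGroundTruth",
    "write_fixture", "load_fixture",
]

_BASES = np.array(list("ACGT"))


@dataclass
class GradientShape:
    """Analytic A-P profile: exponential, sigmoid or gaussian bump.

    ``location``/``scale`` are in fractions of the axis, ``amplitude``
    in fluorescence units.
    """

    kind: str = "exponential"
    location: float = 0.0
    scale: float = 0.3
    amplitude: float = 200.0

    def profile(self, x: np.ndarray) -> np.ndarray:
        if self.kind == "exponential":
            return self.amplitude * np.exp(-(x - self.location)
                                           / self.scale)
        if self.kind == "sigmoid":
            return self.amplitude / (1.0 + np.exp(-(x - self.location)
                                                  / self.scale))
        if self.kind == "bump":
            return self.amplitude * np.exp(
                -0.5 * ((x - self.location) / self.scale) ** 2)
        raise ValueError(f"unknown gradient kind {self.kind!r}")


@dataclass
class FixtureSpec:
    """Study conditions of the synthetic fixtures.

    Defaults are the toy scale used throughout: 2 target genes, 3
    regulators, 20 cycle-14 nuclei, 5 time classes (c13 + T1..T4) and
    5% multiplicative noise, small enough for the brute-force
    thermodynamic oracle and desk-scale fits.
    """

    seed: int = 0
    n_nuclei: int = 20
    n_time_classes: int = 5
    noise_cv: float = 0.05
    r_max: float = 255.0
    gradients: dict[str, GradientShape] = field(default_factory=lambda: {
        "M1": GradientShape("exponential", 0.0, 0.2, 220.0),
        "M2": GradientShape("sigmoid", 0.6, 0.12, 180.0),
    })

    def grid(self, dt: float = 0.0625) -> SimulationGrid:
        return SimulationGrid(
            n_nuclei_c13=self.n_nuclei // 2,
            n_classes_c14=self.n_time_classes - 1, dt=dt)


def synth_pwm(seed: int, length: int = 8,
              information_content: float = 1.8,
              tf_name: str = "TF") -> PWM:
    """Random PWM with controllable peakiness; consensus recoverable.

    ``information_content`` (0..2 bits/position) sets how dominant the
    consensus base is; at the maximum the matrix is near-deterministic
    and the planted consensus word attains the maximum score.
    """
    if length < 4:
        raise ValueError("PWM length must be >= 4")
    rng = np.random.default_rng(seed)
    ic = float(np.clip(information_content, 0.0, 2.0))
    p_cons = 0.25 + 0.75 * (ic / 2.0) ** 0.7
    counts = np.full((length, 4), (1.0 - p_cons) / 3.0 * 100.0)
    cons = rng.integers(0, 4, size=length)
    counts[np.arange(length), cons] = p_cons * 100.0
    return PWM.from_counts(tf_name, counts, pseudocount=1.0)


def synth_pwm_counts(seed: int, length: int = 8,
                     information_content: float = 1.8) -> np.ndarray:
    """The count matrix underlying :func:`synth_pwm` (for serialisation)."""
    rng = np.random.default_rng(seed)
    ic = float(np.clip(information_content, 0.0, 2.0))
    p_cons = 0.25 + 0.75 * (ic / 2.0) ** 0.7
    counts = np.full((length, 4), (1.0 - p_cons) / 3.0 * 100.0)
    cons = rng.integers(0, 4, size=length)
    counts[np.arange(length), cons] = p_cons * 100.0
    return counts


def synth_region(seed: int, length: int,
                 planted: list[tuple[PWM, int]], gc: float = 0.5,
                 ensure_exact: bool = True, max_redraws: int = 50
                 ) -> tuple[str, list[BindingSite]]:
    """Background sequence with consensus words planted at stated positions.

    Returns the sequence and the truth set of sites.  With
    ``ensure_exact`` the background is redrawn (deterministically) until
    scanning each planted PWM at its consensus score recovers exactly
    the truth set, so scanner round-trips are reproducible.
    """
    for pwm, pos in planted:
        if pos < 0 or pos + pwm.length > length:
            raise ValueError("planted site outside region")
    spans = sorted((pos, pos + pwm.length) for pwm, pos in planted)
    for (a0, b0), (a1, b1) in zip(spans, spans[1:]):
        if a1 < b0:
            raise ValueError("overlapping planted sites")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    for attempt in range(max_redraws):
        rng = np.random.default_rng((seed, attempt))
        seq = rng.choice(_BASES, size=length, p=p)
        truth: list[BindingSite] = []
        for pwm, pos in planted:
            word = pwm.consensus
            seq[pos:pos + pwm.length] = list(word)
            truth.append(BindingSite(pwm.tf_name, pos, pos + pwm.length,
                                     "+", word, pwm.max_score))
        sequence = "".join(seq)
        truth.sort(key=lambda s: s.start)
        if not ensure_exact:
            return sequence, truth
        ok = True
        for pwm in {id(pw): pw for pw, _ in planted}.values():
            hits = scan_sequence(pwm, sequence,
                                 threshold=pwm.max_score - 1e-9)
            want = [(s.start, s.end) for s in truth
                    if s.tf_name == pwm.tf_name]
            got = [(s.start, s.end) for s in hits]
            if got != want:
                ok = False
                break
        if ok:
            return sequence, truth
    raise RuntimeError("could not build an exact planted region; "
                       "lower GC or shorten the region")


def synth_gradients(spec: FixtureSpec,
                    noise: bool = True) -> ExpressionDataset:
    """Per-TF nucleus x time-class profiles with multiplicative noise.

    Profiles are constant in time (maternal-style inputs); the c13 class
    lives on the mother grid (half the nuclei), cycle-14 classes on the
    full grid.  Noise is multiplicative Gaussian with coefficient of
    variation ``spec.noise_cv`` — measurement error grows roughly
    linearly with the mean, as in quantitative imaging data — and the
    result is clipped to [0, r_max].
    """
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid()
    rows = []
    for tf, shape in spec.gradients.items():
        for cls in grid.class_labels:
            n = grid.nuclei_of(cls)
            x = (np.arange(n) + 0.5) / n
            prof = shape.profile(x)
            if noise and spec.noise_cv > 0:
                prof = prof * (1.0 + spec.noise_cv
                               * rng.standard_normal(n))
            prof = np.clip(prof, 0.0, spec.r_max)
            rows += [(tf, cls, i, prof[i]) for i in range(n)]
    df = pd.DataFrame(rows, columns=["gene", "time_class", "nucleus",
                                     "conc"])
    return ExpressionDataset(df, grid.class_times)


@dataclass
class ToyGroundTruth:
    """A complete synthetic study: circuit, truth parameters and data."""

    spec: FixtureSpec
    pwms: dict[str, PWM]
    regions: dict[str, RegulatoryRegion]
    config: CircuitConfig
    truth: ParameterVector
    model: CircuitModel
    external: ExpressionDataset
    trajectory: Trajectory          # noiseless forward simulation
    dataset: ExpressionDataset      # noisy target observations


def _toy_regions(spec: FixtureSpec,
                 pwms: dict[str, PWM]) -> dict[str, RegulatoryRegion]:
    length = 600
    # Repressor sites are interleaved with activator sites (short-range
    # quenching only acts on binding within d_R of the repressor), and
    # each region carries one same-TF pair within the cooperativity
    # range so omega is exercised.
    layout = {
        "gA": [("M1", 30), ("M1", 68), ("gA", 120), ("M2", 150),
               ("gA", 220), ("M2", 250), ("M1", 310)],
        "gB": [("M2", 60), ("M2", 98), ("gA", 140), ("M2", 200),
               ("gA", 240), ("M1", 300), ("gA", 340)],
    }
    regions = {}
    for k, (gene, plan) in enumerate(layout.items()):
        seq, truth = synth_region(spec.seed * 101 + k, length,
                                  [(pwms[tf], pos) for tf, pos in plan])
        regions[gene] = RegulatoryRegion(
            gene, seq, tss_offset=length, sites=truth,
            accessibility=[(0, length)],
            cres={"prox": (0, 300), "dist": (300, length)})
    return regions


def synth_ground_truth(spec: FixtureSpec | None = None) -> ToyGroundTruth:
    """Forward-simulate the two-gene toy circuit at known parameters.

    Returns the circuit model, the true parameter vector, the noiseless
    trajectory and a noisy protein dataset in the format the fitter
    consumes.  Same spec (same seed) -> identical outputs.
    """
    spec = spec or FixtureSpec()
    pwms = {tf: synth_pwm(spec.seed * 17 + j, 8, 1.8, tf)
            for j, tf in enumerate(["gA", "M1", "M2"])}
    regions = _toy_regions(spec, pwms)
    config = CircuitConfig(
        genes=["gA", "gB"], tfs=["gA", "M1", "M2"],
        synthesis={"gA": (20.0, 0.1), "gB": (20.0, 0.1)},
        diffusion={"gA": (0.05, 0.05, 0.1, 0.1),
                   "gB": (0.05, 0.05, 0.1, 0.1)})
    # Responsive (non-saturated) regime: site strengths q of order
    # 0.1-1, so the anterior input M1 activates gA while the posterior
    # input M2 quenches it, and vice versa for gB; gA autoactivates and
    # quenches gB across the boundary.
    ln2 = np.log(2.0)
    truth = ParameterVector(
        config=config,
        t_matrix=np.array([[15.0, 60.0, -250.0],
                           [-60.0, -40.0, 50.0]]),
        q_btm=np.array([0.08, 0.1]),
        affinity=np.array([0.008, 0.004, 0.008]),
        cooperativity=np.array([2.0, 1.5, 1.3]),
        repression_range=np.array([100.0, 100.0]),
        delay=np.array([2.0, 3.0]),
        decay_u=np.array([ln2 / 5.0, ln2 / 5.0]),
        decay_v=np.array([ln2 / 12.0, ln2 / 12.0]),
    )
    grid = spec.grid()
    external = synth_gradients(spec, noise=False)
    llr_max = {tf: pwms[tf].max_score for tf in pwms}
    model = CircuitModel(regions, config, grid, external, llr_max)
    traj = model.trajectory(truth)

    rng = np.random.default_rng(spec.seed + 7_777)
    rows = []
    for cls in grid.class_labels:
        for gi, g in enumerate(config.genes):
            v = traj.v[cls][gi]
            noisy = v * (1.0 + spec.noise_cv
                         * rng.standard_normal(len(v)))
            noisy = np.clip(noisy, 0.0, spec.r_max)
            rows += [(g, cls, i, noisy[i]) for i in range(len(v))]
    dataset = ExpressionDataset(
        pd.DataFrame(rows, columns=["gene", "time_class", "nucleus",
                                    "conc"]),
        grid.class_times)
    return ToyGroundTruth(spec, pwms, regions, config, truth, model,
                          external, traj, dataset)


# ---------------------------------------------------------------------------
# Fixture directory round trip (plain-text formats only)


def write_fixture(toy: ToyGroundTruth, directory) -> None:
    """Serialise a toy study to FASTA/PWM/BED/TSV/JSON files.

    The directory is self-contained: regions as FASTA, motif count
    matrices in the 4-column text format, site truth sets plus
    accessibility and CRE intervals as BED, input/target profiles as
    tidy TSV and the configuration + true parameter vector as JSON.
    """
    import json
    from pathlib import Path

    from .motifs import write_pwm
    from .regions import sites_to_bed6

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for j, (tf, pwm) in enumerate(toy.pwms.items()):
        counts = synth_pwm_counts(toy.spec.seed * 17 + j, pwm.length)
        write_pwm(counts, tf, d / f"pwm_{tf}.txt")
    with open(d / "regions.fasta", "w") as fh:
        for gene, region in toy.regions.items():
            fh.write(f">{gene}\n{region.sequence}\n")
    for gene, region in toy.regions.items():
        sites_to_bed6(region.sites, gene).to_csv(
            d / f"sites_{gene}.bed", sep="\t", header=False, index=False)
        pd.DataFrame([(gene, a, b) for a, b in region.accessibility]) \
            .to_csv(d / f"accessibility_{gene}.bed", sep="\t",
                    header=False, index=False)
        pd.DataFrame([(gene, a, b, name)
                      for name, (a, b) in region.cres.items()]) \
            .to_csv(d / f"cres_{gene}.bed", sep="\t", header=False,
                    index=False)
    toy.external.to_tsv(d / "external_inputs.tsv")
    toy.dataset.to_tsv(d / "dataset.tsv")
    toy.trajectory.to_tsv(d / "trajectory_truth.tsv")
    grid = toy.model.grid
    meta = {
        "spec": {
            "seed": toy.spec.seed, "n_nuclei": toy.spec.n_nuclei,
            "n_time_classes": toy.spec.n_time_classes,
            "noise_cv": toy.spec.noise_cv, "r_max": toy.spec.r_max,
        },
        "genes": toy.config.genes,
        "tfs": toy.config.tfs,
        "synthesis": toy.config.synthesis,
        "diffusion": toy.config.diffusion,
        "coop_range": toy.config.coop_range,
        "grid": {
            "n_nuclei_c13": grid.n_nuclei_c13,
            "cycle13_duration": grid.cycle13_duration,
            "class_duration": grid.class_duration,
            "n_classes_c14": grid.n_classes_c14,
            "dt": grid.dt,
        },
        "tss_offset": {g: r.tss_offset for g, r in toy.regions.items()},
        "truth_vector": toy.truth.pack().tolist(),
    }
    (d / "circuit.json").write_text(json.dumps(meta, indent=1))


def load_fixture(directory) -> ToyGroundTruth:
    """Rebuild a toy study from a fixture directory (see write_fixture)."""
    import json
    from pathlib import Path

    from .motifs import read_pwm
    from .regions import read_bed_intervals, read_fasta_sequence

    d = Path(directory)
    meta = json.loads((d / "circuit.json").read_text())
    spec = FixtureSpec(**meta["spec"])
    pwms = {tf: read_pwm(d / f"pwm_{tf}.txt") for tf in meta["tfs"]}
    regions = {}
    for gene in meta["genes"]:
        seq = read_fasta_sequence(d / "regions.fasta", gene)
        bed = read_bed_intervals(d / f"sites_{gene}.bed")
        sites = [BindingSite(r["name"], r["start"], r["end"], r["strand"],
                             seq[r["start"]:r["end"]], float(r["score"]))
                 for _, r in bed.iterrows()]
        acc_bed = read_bed_intervals(d / f"accessibility_{gene}.bed")
        acc = list(zip(acc_bed["start"], acc_bed["end"]))
        cre_bed = read_bed_intervals(d / f"cres_{gene}.bed")
        cres = {r["name"]: (r["start"], r["end"])
                for _, r in cre_bed.iterrows()}
        regions[gene] = RegulatoryRegion(
            gene, seq, meta["tss_offset"][gene], sites, acc, cres)
    config = CircuitConfig(
        genes=meta["genes"], tfs=meta["tfs"],
        synthesis={g: tuple(v) for g, v in meta["synthesis"].items()},
        diffusion={g: tuple(v) for g, v in meta["diffusion"].items()},
        coop_range=meta["coop_range"])
    grid = SimulationGrid(**meta["grid"])
    external = ExpressionDataset.from_tsv(d / "external_inputs.tsv")
    dataset = ExpressionDataset.from_tsv(d / "dataset.tsv")
    truth = ParameterVector.unpack(
        np.asarray(meta["truth_vector"]), config)
    llr_max = {tf: pwm.max_score for tf, pwm in pwms.items()}
    model = CircuitModel(regions, config, grid, external, llr_max)
    traj_df = pd.read_csv(d / "trajectory_truth.tsv", sep="\t")
    traj = Trajectory(config.genes, grid)
    for cls, grp in traj_df.groupby("time_class"):
        n = grid.nuclei_of(cls)
        u = np.zeros((len(config.genes), n))
        v = np.zeros((len(config.genes), n))
        for gi, g in enumerate(config.genes):
            sub = grp[grp["gene"] == g].sort_values("nucleus")
            u[gi] = sub["u"].to_numpy()
            v[gi] = sub["v"].to_numpy()
        traj.u[cls] = u
        traj.v[cls] = v
    return ToyGroundTruth(spec, pwms, regions, config, truth, model,
                          external, traj, dataset)
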