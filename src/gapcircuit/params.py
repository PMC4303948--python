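"""The free-parameter vector of the circuit and its packing.

For the default configuration (4 gap genes regulated by 8 TFs) the free
vector has 68 entries: 32 T-matrix elements, 4 basal machinery constants
(q_btm per gene), 8 binding affinities K, 8 homotypic cooperativities
omega, 4 short-range repression radii d_R (one per target gene,
broadcast to all its repressors), 4 protein-synthesis delays tau_v and
8 decay rates (lambda_u, lambda_v per gene).  Synthesis rates and
diffusion coefficients are fixed and never enter the vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import KineticParams
from .thermo import ThermoParams

__all__ = ["CircuitConfig", "ParameterVector", "default_bounds"]

#: Per-block [low, high] defaults.  T and K ranges are guided by the
#: magnitudes of published representative fits; decay bounds correspond
#: to half-lives between 1 and 100 minutes.
DEFAULT_BOUNDS = {
    "t_matrix": (-1.0e4, 1.0e4),
    "q_btm": (1.0e-3, 10.0),
    "affinity": (1.0e-5, 0.1),
    "cooperativity": (1.0, 5.0),
    "repression_range": (50.0, 250.0),
    "delay": (0.0, 10.0),
    "decay": (np.log(2.0) / 100.0, np.log(2.0) / 1.0),
}

GAP_GENES = ["hb", "Kr", "gt", "kni"]
EXTERNAL_TFS = ["bcd", "cad", "tll", "hkb"]


@dataclass
class CircuitConfig:
    """Gene/TF layout plus the fixed (non-optimised) constants.

    ``tfs`` lists every regulator; those not in ``genes`` are external
    inputs read from data.  ``synthesis`` maps gene -> (R_u, R_v) and
    ``diffusion`` maps gene -> (Du13, Du14, Dv13, Dv14); both blocks are
    held fixed during optimisation.
    """

    genes: list[str] = field(default_factory=lambda: list(GAP_GENES))
    tfs: list[str] = field(
        default_factory=lambda: list(GAP_GENES) + list(EXTERNAL_TFS))
    synthesis: dict[str, tuple[float, float]] = field(default_factory=dict)
    diffusion: dict[str, tuple[float, float, float, float]] = field(
        default_factory=dict)
    coop_range: float = 50.0
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.tfs)) != len(self.tfs):
            raise ValueError("duplicate TF names")
        for g in self.genes:
            self.synthesis.setdefault(g, (20.0, 0.1))
            self.diffusion.setdefault(g, (0.05, 0.05, 0.1, 0.1))
        merged = dict(DEFAULT_BOUNDS)
        merged.update(self.bounds)
        self.bounds = merged

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_tfs(self) -> int:
        return len(self.tfs)

    @property
    def external_tfs(self) -> list[str]:
        return [t for t in self.tfs if t not in self.genes]

    @property
    def block_sizes(self) -> dict[str, int]:
        g, t = self.n_genes, self.n_tfs
        return {
            "t_matrix": g * t,
            "q_btm": g,
            "affinity": t,
            "cooperativity": t,
            "repression_range": g,
            "delay": g,
            "decay": 2 * g,
        }

    @property
    def n_free(self) -> int:
        return sum(self.block_sizes.values())

    def vector_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for block, size in self.block_sizes.items():
            a, b = self.bounds[block]
            lo += [a] * size
            hi += [b] * size
        return np.array(lo), np.array(hi)

    def parameter_names(self) -> list[str]:
        names = [f"T[{g},{t}]" for g in self.genes for t in self.tfs]
        names += [f"q_btm[{g}]" for g in self.genes]
        names += [f"K[{t}]" for t in self.tfs]
        names += [f"omega[{t}]" for t in self.tfs]
        names += [f"d_R[{g}]" for g in self.genes]
        names += [f"tau_v[{g}]" for g in self.genes]
        names += [f"lambda_u[{g}]" for g in self.genes]
        names += [f"lambda_v[{g}]" for g in self.genes]
        return names


@dataclass
class ParameterVector:
    """The free parameters, structured by block."""

    config: CircuitConfig
    t_matrix: np.ndarray          # (n_genes, n_tfs)
    q_btm: np.ndarray             # (n_genes,)
    affinity: np.ndarray          # (n_tfs,)
    cooperativity: np.ndarray     # (n_tfs,)
    repression_range: np.ndarray  # (n_genes,)
    delay: np.ndarray             # (n_genes,)
    decay_u: np.ndarray           # (n_genes,)
    decay_v: np.ndarray           # (n_genes,)

    def __post_init__(self) -> None:
        g, t = self.config.n_genes, self.config.n_tfs
        self.t_matrix = np.asarray(self.t_matrix, float).reshape(g, t)
        for name, size in [("q_btm", g), ("affinity", t),
                           ("cooperativity", t), ("repression_range", g),
                           ("delay", g), ("decay_u", g), ("decay_v", g)]:
            arr = np.asarray(getattr(self, name), float).reshape(size)
            setattr(self, name, arr)

    def pack(self) -> np.ndarray:
        """Flatten to the free vector (lossless; fixed blocks excluded)."""
        return np.concatenate([
            self.t_matrix.ravel(), self.q_btm, self.affinity,
            self.cooperativity, self.repression_range, self.delay,
            np.concatenate([self.decay_u, self.decay_v]),
        ])

    @classmethod
    def unpack(cls, vector: np.ndarray,
               config: CircuitConfig) -> "ParameterVector":
        vector = np.asarray(vector, float)
        if vector.shape != (config.n_free,):
            raise ValueError(
                f"vector length {vector.shape} != {config.n_free} free "
                "parameters")
        g, t = config.n_genes, config.n_tfs
        pos = 0

        def take(n):
            nonlocal pos
            out = vector[pos:pos + n]
            pos += n
            return out

        return cls(
            config=config,
            t_matrix=take(g * t).reshape(g, t),
            q_btm=take(g),
            affinity=take(t),
            cooperativity=take(t),
            repression_range=take(g),
            delay=take(g),
            decay_u=take(g),
            decay_v=take(g),
        )

    # -- views consumed by the thermo / dynamics layers ----------------

    def thermo_params(self, gene: str) -> ThermoParams:
        cfg = self.config
        gi = cfg.genes.index(gene)
        return ThermoParams(
            target_gene=gene,
            t_row={tf: float(self.t_matrix[gi, ti])
                   for ti, tf in enumerate(cfg.tfs)},
            affinity={tf: float(self.affinity[ti])
                      for ti, tf in enumerate(cfg.tfs)},
            cooperativity={tf: float(self.cooperativity[ti])
                           for ti, tf in enumerate(cfg.tfs)},
            repression_range={tf: float(self.repression_range[gi])
                              for tf in cfg.tfs},
            coop_range=cfg.coop_range,
            q_btm=float(self.q_btm[gi]),
        )

    def kinetic_params(self, gene: str) -> KineticParams:
        cfg = self.config
        gi = cfg.genes.index(gene)
        r_u, r_v = cfg.synthesis[gene]
        du13, du14, dv13, dv14 = cfg.diffusion[gene]
        return KineticParams(
            synthesis_u=r_u, synthesis_v=r_v,
            diffusion_u={13: du13, 14: du14},
            diffusion_v={13: dv13, 14: dv14},
            decay_u=float(self.decay_u[gi]),
            decay_v=float(self.decay_v[gi]),
            delay_v=float(self.delay[gi]),
        )

    def all_thermo(self) -> dict[str, ThermoParams]:
        return {g: self.thermo_params(g) for g in self.config.genes}

    def all_kinetics(self) -> dict[str, KineticParams]:
        return {g: self.kinetic_params(g) for g in self.config.genes}


def default_bounds(config: CircuitConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-entry (low, high) bound arrays for the free vector."""
    return config.vector_bounds()


# ---------------------------------------------------------------------------
# Optimiser search-space transform.
#
# Scale parameters (K, q_btm, decay rates) span several decades and the
# signed T entries act through products q*T that saturate for large
# magnitudes, so uniform sampling of the natural ranges concentrates all
# trial points in the saturated regime.  The optimiser therefore works
# in a transformed space: log10 for strictly positive scale blocks and a
# sign-preserving symlog for T; the model always sees natural units.

SEARCH_TRANSFORMS = {
    "t_matrix": "symlog",
    "q_btm": "log",
    "affinity": "log",
    "decay": "log",
}


def _block_slices(config: CircuitConfig) -> dict[str, slice]:
    out = {}
    pos = 0
    for block, size in config.block_sizes.items():
        out[block] = slice(pos, pos + size)
        pos += size
    return out


def _symlog(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.log10(1.0 + np.abs(x))


def _symexp(y: np.ndarray) -> np.ndarray:
    return np.sign(y) * (10.0 ** np.abs(y) - 1.0)


def to_search_space(config: CircuitConfig,
                    vector: np.ndarray) -> np.ndarray:
    """Natural-unit free vector -> optimiser coordinates (monotone)."""
    out = np.asarray(vector, float).copy()
    for block, sl in _block_slices(config).items():
        kind = SEARCH_TRANSFORMS.get(block)
        if kind == "log":
            out[sl] = np.log10(out[sl])
        elif kind == "symlog":
            out[sl] = _symlog(out[sl])
    return out


def from_search_space(config: CircuitConfig,
                      vector: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_search_space`."""
    out = np.asarray(vector, float).copy()
    for block, sl in _block_slices(config).items():
        kind = SEARCH_TRANSFORMS.get(block)
        if kind == "log":
            out[sl] = 10.0 ** out[sl]
        elif kind == "symlog":
            out[sl] = _symexp(out[sl])
    return out
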