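"""Goodness-of-fit machinery: RSS, rms, wPGP, T-penalty, combined error.

The combined objective used for fitting is

    Error = RSS + 5e4 * wPGP + 1e-3 * Penalty

where RSS is the residual sum of squares over all observed
(gene, nucleus, time) triples, wPGP the weighted Pattern Generating
Potential (direction-aware fit score, 0 = perfect), and
Penalty = sum (T^ab)^2 limits the growth of the regulatory parameters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import ExpressionDataset

__all__ = [
    "rss", "rms", "wpgp", "t_penalty", "combined_error", "sqrt_transform",
    "DEFAULT_WEIGHTS", "residuals", "score_report",
]

#: (RSS, wPGP, Penalty) weights of the combined error.
DEFAULT_WEIGHTS = (1.0, 5.0e4, 1.0e-3)


def _model_frame(model) -> pd.DataFrame:
    """Accept a Trajectory or a tidy frame with a ``v`` column."""
    if isinstance(model, pd.DataFrame):
        return model
    return model.to_frame()


def _aligned(model, data: ExpressionDataset) -> pd.DataFrame:
    frame = _model_frame(model)
    merged = data.data.merge(frame[["gene", "time_class", "nucleus", "v"]],
                             on=["gene", "time_class", "nucleus"],
                             how="left")
    if merged["v"].isna().any():
        bad = merged[merged["v"].isna()].iloc[0]
        raise ValueError(
            "no model value for observation "
            f"({bad['gene']}, {bad['time_class']}, {bad['nucleus']})")
    return merged


def residuals(model, data: ExpressionDataset,
              transform: bool = False) -> np.ndarray:
    """Residual vector model - data over the observed triples.

    With ``transform`` the variance-stabilising square root is applied to
    both model and data first (exactly once; used by the identifiability
    analysis where the measurement error grows with the mean).
    """
    merged = _aligned(model, data)
    v = merged["v"].to_numpy(dtype=float)
    r = merged["conc"].to_numpy(dtype=float)
    if transform:
        v, r = sqrt_transform(np.clip(v, 0.0, None)), sqrt_transform(r)
    return v - r


def rss(model, data: ExpressionDataset) -> float:
    """Residual sum of squared differences over all observations."""
    res = residuals(model, data)
    return float(res @ res)


def rms(rss_value: float, d: int) -> float:
    """Root mean square residual, sqrt(RSS / D)."""
    if d <= 0:
        raise ValueError("D must be positive")
    return float(np.sqrt(rss_value / d))


def wpgp(predicted: np.ndarray, observed: np.ndarray, r_max: float,
         normalization: str = "printed") -> float:
    """Weighted Pattern Generating Potential of one spatial pattern.

    wPGP = 0.5 + 0.5*(penalty - reward) with
    reward  = sum r_i * min(r_i, p_i) / sum r_i^2,
    penalty = sum (r_max - r_i) * |p_i - r_i| / norm,

    where ``norm`` is [sum (r_max - r_i)]^2 as printed in the source
    formula (``normalization="printed"``) or sum (r_max - r_i) * r_max
    (``normalization="rmax"``), an alternative scaling that bounds the
    penalty by 1.  0 is a perfect fit.
    """
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(observed, dtype=float)
    if p.shape != r.shape:
        raise ValueError("pattern shapes differ")
    if (p < 0).any() or (r < 0).any():
        raise ValueError("patterns must be non-negative")
    sum_rr = float(r @ r)
    if sum_rr == 0.0:
        raise ValueError("all-zero reference pattern: reward undefined")
    reward = float(r @ np.minimum(r, p)) / sum_rr
    slack = r_max - r
    if normalization == "printed":
        norm = float(slack.sum()) ** 2
    elif normalization == "rmax":
        norm = float(slack.sum()) * r_max
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    penalty = float(slack @ np.abs(p - r)) / norm if norm > 0 else 0.0
    return 0.5 + 0.5 * (penalty - reward)


def wpgp_dataset(model, data: ExpressionDataset,
                 normalization: str = "printed") -> float:
    """wPGP per (gene, time class) spatial pattern, averaged over patterns.

    Patterns whose reference is all-zero are skipped.
    """
    merged = _aligned(model, data)
    r_max = data.r_max
    scores = []
    for _, grp in merged.groupby(["gene", "time_class"], sort=False):
        r = grp["conc"].to_numpy(dtype=float)
        if (r == 0).all():
            continue
        p = np.clip(grp["v"].to_numpy(dtype=float), 0.0, None)
        scores.append(wpgp(p, r, r_max, normalization))
    if not scores:
        raise ValueError("no scorable patterns (all references zero)")
    return float(np.mean(scores))


def t_penalty(t_matrix: np.ndarray) -> float:
    """Sum of squares of all T-matrix entries."""
    t = np.asarray(t_matrix, dtype=float)
    return float((t * t).sum())


def combined_error(rss_value: float, wpgp_value: float, penalty_value: float,
                   weights: tuple[float, float, float] = DEFAULT_WEIGHTS
                   ) -> float:
    """Error = w0*RSS + w1*wPGP + w2*Penalty (defaults 1, 5e4, 1e-3)."""
    parts = (rss_value, wpgp_value, penalty_value)
    if not all(np.isfinite(parts)):
        raise ValueError("non-finite objective component")
    return float(sum(w * x for w, x in zip(weights, parts)))


def sqrt_transform(values: np.ndarray) -> np.ndarray:
    """Variance-stabilising elementwise square root (apply exactly once)."""
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative input to sqrt transform")
    return np.sqrt(arr)


class PatternIndex:
    """Pre-resolved observation -> trajectory addressing for fast scoring.

    Groups the dataset once by (gene, time class); repeated evaluation
    of RSS/wPGP against trajectories (the fitting inner loop) then runs
    on plain arrays.  Scores agree with :func:`rss`/:func:`wpgp_dataset`
    exactly.
    """

    def __init__(self, data: ExpressionDataset, genes: list[str]):
        self.r_max = data.r_max
        self.D = data.D
        self.groups = []
        gene_index = {g: i for i, g in enumerate(genes)}
        for (gene, cls), grp in data.data.groupby(
                ["gene", "time_class"], sort=False):
            if gene not in gene_index:
                raise ValueError(f"dataset gene {gene} not in model")
            self.groups.append((
                gene_index[gene], cls,
                grp["nucleus"].to_numpy(dtype=np.intp),
                grp["conc"].to_numpy(dtype=float),
            ))

    def scores(self, traj, normalization: str = "printed"
               ) -> tuple[float, float]:
        """(RSS, wPGP) of a trajectory against the indexed dataset."""
        total = 0.0
        wpgp_values = []
        for gi, cls, nuc, r in self.groups:
            p = traj.v[cls][gi][nuc]
            res = p - r
            total += float(res @ res)
            if (r > 0).any():
                wpgp_values.append(
                    wpgp(np.clip(p, 0.0, None), r, self.r_max,
                         normalization))
        if not wpgp_values:
            raise ValueError("no scorable patterns (all references zero)")
        return total, float(np.mean(wpgp_values))


def score_report(model, data: ExpressionDataset, t_matrix: np.ndarray,
                 weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
                 normalization: str = "printed") -> dict[str, float]:
    """All fit scores of a trajectory against a dataset, as a dict."""
    rss_value = rss(model, data)
    wpgp_value = wpgp_dataset(model, data, normalization)
    pen = t_penalty(t_matrix)
    return {
        "RSS": rss_value,
        "rms": rms(rss_value, data.D),
        "wPGP": wpgp_value,
        "Penalty": pen,
        "Error": combined_error(rss_value, wpgp_value, pen, weights),
    }
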