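"""Spatiotemporal expression data: (gene, time class, nucleus) records.

Emulates quantitative protein-profile databases for the blastoderm:
concentrations on a row of nuclei along the anterior-posterior axis,
observed at discrete time classes (one class in cleavage cycle 13,
classes T1..T8 in cycle 14A).  The nucleus grid may differ between
classes (nuclei double at the 13 -> 14A transition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionDataset"]

COLUMNS = ["gene", "time_class", "nucleus", "conc"]


@dataclass
class ExpressionDataset:
    """Tidy table of expression observations plus the class -> time map.

    ``data`` has columns gene, time_class, nucleus, conc; ``class_times``
    maps each time-class label to minutes from the start of cycle 13.
    """

    data: pd.DataFrame
    class_times: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        if len(self.data) == 0:
            raise ValueError("empty dataset")
        conc = self.data["conc"].to_numpy()
        if not np.isfinite(conc).all() or (conc < 0).any():
            raise ValueError("concentrations must be finite and >= 0")
        self.data = self.data.reset_index(drop=True)

    @property
    def D(self) -> int:
        """Number of observations."""
        return len(self.data)

    @property
    def r_max(self) -> float:
        """Maximum observed concentration."""
        return float(self.data["conc"].max())

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    @property
    def classes(self) -> list[str]:
        cls = list(self.data["time_class"].unique())
        if self.class_times:
            cls.sort(key=lambda c: self.class_times.get(c, np.inf))
        return cls

    def profile(self, gene: str, time_class: str) -> np.ndarray:
        """Concentrations over the nucleus grid of one class, in order."""
        sel = self.data[(self.data["gene"] == gene)
                        & (self.data["time_class"] == time_class)]
        sel = sel.sort_values("nucleus")
        return sel["conc"].to_numpy()

    def subset(self, row_index: np.ndarray) -> "ExpressionDataset":
        """Dataset restricted to the given row positions."""
        return ExpressionDataset(self.data.iloc[row_index].copy(),
                                 dict(self.class_times))

    def swap_genes(self, pairs: list[tuple[str, str]]) -> "ExpressionDataset":
        """Relabel target patterns pairwise (negative-control shuffle)."""
        mapping: dict[str, str] = {}
        for a, b in pairs:
            mapping[a], mapping[b] = b, a
        present = set(self.data["gene"].unique())
        absent = set(mapping) - present
        if absent:
            raise ValueError(f"genes {sorted(absent)} not in dataset")
        df = self.data.copy()
        df["gene"] = df["gene"].map(lambda g: mapping.get(g, g))
        return ExpressionDataset(df, dict(self.class_times))

    def to_tsv(self, path) -> None:
        df = self.data.copy()
        df["time_min"] = df["time_class"].map(self.class_times)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ExpressionDataset":
        df = pd.read_csv(path, sep="\t")
        times: dict[str, float] = {}
        if "time_min" in df.columns:
            times = (df.drop_duplicates("time_class")
                     .set_index("time_class")["time_min"].to_dict())
            df = df.drop(columns=["time_min"])
        return cls(df, times)
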