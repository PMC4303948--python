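"""Position weight matrices and log-odds binding-site scanning.

A PWM stores per-position log-odds weights for the four nucleotides.
Matrices are read from a small plain-text format (``>TFNAME`` header
followed by one whitespace-delimited A C G T row per motif position,
holding counts or frequencies) and converted to log-odds with a
pseudocount against a background nucleotide distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["PWM", "read_pwm", "write_pwm", "llr_score"]

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Log-odds scoring matrix for one transcription factor.

    Attributes
    ----------
    tf_name : str
        Factor identifier (e.g. ``"bcd"``).
    matrix : ndarray, shape (length, 4)
        Log-odds weights, columns ordered A, C, G, T.
    background : ndarray, shape (4,)
        Background nucleotide probabilities (sums to 1).
    threshold : float
        Log-odds cutoff used by :func:`~gapcircuit.regions.scan_sequence`.
    """

    tf_name: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    threshold: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (length, 4)")
        if self.matrix.shape[0] < 1:
            raise ValueError("zero-length PWM")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        """Score of the consensus word (best base at every position)."""
        return float(self.matrix.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    @classmethod
    def from_counts(cls, tf_name: str, counts: np.ndarray,
                    background: np.ndarray | None = None,
                    pseudocount: float = 1.0,
                    threshold: float = 0.0) -> "PWM":
        """Build a log-odds PWM from a count (or frequency) matrix.

        Each cell gets ``pseudocount`` added; rows are normalised and the
        log-ratio against the background taken.
        """
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("count matrix must have 4 columns (A,C,G,T)")
        if counts.shape[0] < 1:
            raise ValueError("empty count matrix")
        if (counts < 0).any():
            raise ValueError("negative counts")
        bg = (np.full(4, 0.25) if background is None
              else np.asarray(background, dtype=float))
        freq = counts + pseudocount
        freq = freq / freq.sum(axis=1, keepdims=True)
        matrix = np.log(freq / bg)
        return cls(tf_name, matrix, bg, threshold)


def llr_score(pwm: PWM, word: str) -> float:
    """Log-odds score of ``word``: per-position sum of matrix entries.

    Raises ``ValueError`` for a word of the wrong length; an ambiguous
    base raises ``ValueError`` as well (callers scanning genomic sequence
    skip such windows with a warning).
    """
    if len(word) != pwm.length:
        raise ValueError(
            f"word length {len(word)} != PWM length {pwm.length}")
    try:
        idx = [_BASE_INDEX[b] for b in word.upper()]
    except KeyError as exc:
        raise ValueError(f"ambiguous base {exc} in word {word!r}") from exc
    return float(pwm.matrix[np.arange(pwm.length), idx].sum())


def read_pwm(path: str | Path, background: np.ndarray | None = None,
             pseudocount: float = 1.0, threshold: float = 0.0,
             as_counts: bool = True) -> PWM:
    """Read one PWM from a ``>NAME`` + 4-column matrix text file.

    With ``as_counts`` (default) the rows are treated as counts or
    frequencies and converted to log-odds via :meth:`PWM.from_counts`;
    otherwise rows are taken as ready-made log-odds weights.
    """
    path = Path(path)
    name = None
    rows: list[list[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            name = line[1:].split()[0]
            continue
        fields = line.split()
        if len(fields) != 4:
            raise ValueError(
                f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
        rows.append([float(x) for x in fields])
    if name is None:
        raise ValueError(f"{path}: missing '>TFNAME' header")
    if not rows:
        raise ValueError(f"{path}: zero-length matrix")
    arr = np.asarray(rows)
    if as_counts:
        return PWM.from_counts(name, arr, background, pseudocount, threshold)
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    return PWM(name, arr, bg, threshold)


def write_pwm(pwm_counts: np.ndarray, tf_name: str, path: str | Path) -> None:
    """Write a count/frequency matrix in the 4-column text format."""
    lines = [f">{tf_name}"]
    for row in np.asarray(pwm_counts):
        lines.append(" ".join(f"{x:.6g}" for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


def scan_words(pwm: PWM, sequence: str):
    """Yield ``(start, strand, word, llr)`` for every window on both strands.

    Windows containing ambiguous bases are skipped with a warning.
    """
    seq = sequence.upper()
    L = pwm.length
    warned = False
    for start in range(len(seq) - L + 1):
        word = seq[start:start + L]
        for strand, w in (("+", word), ("-", reverse_complement(word))):
            try:
                score = llr_score(pwm, w)
            except ValueError:
                if not warned:
                    warnings.warn(
                        f"skipping windows with ambiguous bases for "
                        f"{pwm.tf_name}", stacklevel=2)
                    warned = True
                continue
            yield start, strand, w, score
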