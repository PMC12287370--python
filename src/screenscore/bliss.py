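"""Bliss independence scoring of drug-combination viability surfaces.

Bliss independence treats the two drugs as statistically independent
killers: with fractional inhibitions f_a and f_b, the expected combined
inhibition is f_a + f_b − f_a·f_b. The synergy score of a surface is the
mean observed-minus-expected excess, in percentage points, over the cells
where both drugs are present. Inhibition fractions are clipped to [0, 1]
before entering the formula — it is a probability identity.

Classification bounds: score < −10 antagonistic, −10..10 (inclusive)
additive, > 10 synergistic.

Two designs are supported: the full dose grid (monotherapies as row 0 /
column 0) and the diagonal 1:1 fixed-molar design, where both drugs share
one concentration series and only the matrix diagonal is measured. The
diagonal scorer evaluates the measured cells directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import DomainError, InputError

Call = Literal["antagonistic", "additive", "synergistic"]

ANTAGONISM_BOUND = -10.0
SYNERGY_BOUND = 10.0


@dataclass
class CombinationMatrix:
    """Full dose-grid viability surface.

    ``doses_a`` (rows) and ``doses_b`` (columns) are ascending nM series
    each prepended with 0, so row 0 and column 0 hold the monotherapies and
    cell [0, 0] is the untreated well, renormalized to exactly 100%.
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    viability: np.ndarray  # percent, shape (len(doses_a), len(doses_b))

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.doses_a[0] != 0 or self.doses_b[0] != 0:
            raise InputError("dose axes must start with the 0-dose monotherapy row/column")
        if self.viability.shape != (self.doses_a.size, self.doses_b.size):
            raise InputError("viability matrix shape does not match dose axes")
        if not np.all(np.isfinite(self.viability)):
            raise InputError("viability must be finite")
        if self.doses_a.size < 2 or self.doses_b.size < 2:
            raise InputError("need at least one combination cell")
        self.viability[0, 0] = 100.0  # untreated anchor defines the f=0 baseline


@dataclass
class DiagonalCombination:
    """1:1 fixed-molar design: both monotherapies and the combination are
    dosed along the same concentration series."""

    concentrations: np.ndarray  # nM, shared series
    mono_a: np.ndarray  # viability %
    mono_b: np.ndarray
    combo: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.mono_a = np.asarray(self.mono_a, dtype=float)
        self.mono_b = np.asarray(self.mono_b, dtype=float)
        self.combo = np.asarray(self.combo, dtype=float)
        n = self.concentrations.size
        if not (self.mono_a.size == self.mono_b.size == self.combo.size == n):
            raise InputError("diagonal series must all have equal length")


@dataclass(frozen=True)
class BlissResult:
    excess: np.ndarray  # percentage points, matrix or vector
    score: float  # mean excess over combination cells
    call: Call
    n_cells: int


def _inhibition(viability: np.ndarray) -> np.ndarray:
    return np.clip((100.0 - viability) / 100.0, 0.0, 1.0)


def classify_bliss(score: float) -> Call:
    """Classify a mean Bliss excess with the −10 / +10 bounds (boundaries
    inclusive to additive)."""
    if not np.isfinite(score):
        raise DomainError(f"score must be finite, got {score!r}")
    if score < ANTAGONISM_BOUND:
        return "antagonistic"
    if score > SYNERGY_BOUND:
        return "synergistic"
    return "additive"


def bliss_matrix(m: CombinationMatrix) -> BlissResult:
    """Score a full dose-response matrix against Bliss independence."""
    f = _inhibition(m.viability)
    f_a = f[:, 0][:, None]  # monotherapy A down column 0
    f_b = f[0, :][None, :]  # monotherapy B along row 0
    expected = f_a + f_b - f_a * f_b
    excess = (f - expected) * 100.0
    combo = (m.doses_a[:, None] > 0) & (m.doses_b[None, :] > 0)
    score = float(excess[combo].mean())
    return BlissResult(excess=excess, score=score, call=classify_bliss(score), n_cells=int(combo.sum()))


def bliss_diagonal(d: DiagonalCombination) -> BlissResult:
    """Score the measured diagonal cells of a 1:1 combination directly."""
    f_a = _inhibition(d.mono_a)
    f_b = _inhibition(d.mono_b)
    f_c = _inhibition(d.combo)
    expected = f_a + f_b - f_a * f_b
    excess = (f_c - expected) * 100.0
    dosed = d.concentrations > 0
    if not dosed.any():
        raise InputError("diagonal series has no dosed concentration")
    score = float(excess[dosed].mean())
    return BlissResult(excess=excess, score=score, call=classify_bliss(score), n_cells=int(dosed.sum()))
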