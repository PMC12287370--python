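"""Deterministic transforms for flow-cytometry median fluorescence intensities.

Raw marker MFIs carry instrument background; the standard corrections
before plotting are (i) subtract the matched isotype-control signal,
(ii) log10-transform when values are shown on absolute scale, or
(iii) express them relative to the vehicle (DMSO) control, which is set to
exactly zero by linear subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError


@dataclass(frozen=True)
class MFIRecord:
    marker: str
    raw_mfi: float
    isotype_mfi: float
    dmso_reference_mfi: float | None = None


def noise_correct(raw, isotype):
    """Isotype-subtracted MFI; may legitimately be <= 0 (use
    :func:`is_flagged` to detect)."""
    return np.asarray(raw, dtype=float) - np.asarray(isotype, dtype=float) if np.ndim(raw) else float(raw) - float(isotype)


def is_flagged(corrected) -> bool | np.ndarray:
    """True where the corrected signal is at or below zero."""
    return np.asarray(corrected) <= 0 if np.ndim(corrected) else corrected <= 0


def log10_mfi(corrected, floor: float = 1.0):
    """log10 of the corrected MFI, floored at ``floor`` AU (> 0)."""
    if not floor > 0:
        raise DomainError("floor must be positive")
    return np.log10(np.maximum(corrected, floor))


def relative_to_dmso(corrected_drug, corrected_dmso):
    """Drug-treated minus DMSO-treated corrected MFI: the vehicle control
    maps to exactly zero, decreases below it are negative."""
    return np.asarray(corrected_drug, dtype=float) - np.asarray(corrected_dmso, dtype=float) if np.ndim(corrected_drug) else float(corrected_drug) - float(corrected_dmso)
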