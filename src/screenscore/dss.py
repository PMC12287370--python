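"""Modified DSS3 drug-sensitivity scoring.

The drug sensitivity score (DSS) summarizes a fitted dose-response curve as
a normalized area under the inhibition curve on the log10-dose axis, scaled
to [0, 100]; higher means more sensitive. The variant implemented here is
the DSS3 family member with the division by log10 of the curve's upper
asymptote omitted, and with the activity window running from 100% down to a
viability floor t_v (default 10%):

    y(x)  = 100 - v(x)                      inhibition, %
    AUC   = integral over [x_min, x_max] of clip(y(x), 0, 100 - t_v) dx
    DSS   = 100 * AUC / ((100 - t_v) * (x_max - x_min))

Geometrically the integrand is the region between the fitted curve and the
100% line, clipped to the t_v..100% viability band, taken over the full
tested log-dose window. This realizes both stated score properties: a flat
100%-viability curve scores 0 and a complete-kill curve scores 100.
Negative inhibition (viability above 100%) contributes zero area, never
negative area, so the score is floored at 0.

A literal dose-window truncation variant — multiply by the fraction of the
window before viability first reaches t_v — is available behind
``apply_window_factor`` and labelled in ``metric_label``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .dose_response import LogisticFit
from .errors import DomainError


@dataclass(frozen=True)
class DSSConfig:
    """Scoring configuration.

    viability_floor:
        t_v, the viability level (%) closing the activity window; the
        inhibition integrand is capped at ``100 - viability_floor``.
    apply_window_factor:
        Multiply the score by (x_stop - x_min)/(x_max - x_min), the literal
        responsive-dose-window rescaling. Off by default.
    quadrature_tol:
        Absolute tolerance passed to the adaptive quadrature.
    """

    viability_floor: float = 10.0
    apply_window_factor: bool = False
    quadrature_tol: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 < self.viability_floor < 100.0:
            raise DomainError("viability_floor must lie strictly between 0 and 100")

    @property
    def inhibition_cap(self) -> float:
        return 100.0 - self.viability_floor


@dataclass(frozen=True)
class DSSResult:
    sample_id: str
    treatment_id: str
    dss: float
    auc: float  # %·log10(nM)
    x_stop: float  # log10(nM) where viability first reaches the floor
    metric_label: str


def _crossing(fit: LogisticFit, level: float) -> float | None:
    """log10 dose where the fitted curve crosses ``level`` %, if identifiable."""
    lo, hi = sorted((fit.top, fit.bottom))
    if fit.hill <= 0 or not (lo < level < hi):
        return None
    ratio = (fit.top - level) / (level - fit.bottom)
    return fit.log10_ic50 + np.log10(ratio) / fit.hill


def dss_score(
    fit: LogisticFit,
    config: DSSConfig | None = None,
    sample_id: str = "",
    treatment_id: str = "",
) -> DSSResult:
    """Score one fitted curve over its tested log10-dose window."""
    config = config or DSSConfig()
    if not fit.x_max > fit.x_min:
        raise DomainError("fit window is empty: x_max must exceed x_min")
    cap = config.inhibition_cap

    def integrand(x: float) -> float:
        y = 100.0 - fit(x)
        return min(max(y, 0.0), cap)

    # the clipped integrand has kinks where v crosses 100% and the floor;
    # hand those breakpoints to the quadrature
    points = [
        c
        for level in (100.0, config.viability_floor)
        if (c := _crossing(fit, level)) is not None and fit.x_min < c < fit.x_max
    ]
    auc, _ = quad(
        integrand,
        fit.x_min,
        fit.x_max,
        points=sorted(points) or None,
        epsabs=config.quadrature_tol,
        limit=200,
    )
    width = fit.x_max - fit.x_min
    dss = 100.0 * auc / (cap * width)

    # x_stop: first log-dose where viability is at or below the floor
    if fit(fit.x_min) <= config.viability_floor:
        x_stop = fit.x_min
    elif fit(fit.x_max) > config.viability_floor:
        x_stop = fit.x_max
    else:
        c = _crossing(fit, config.viability_floor)
        x_stop = float(c) if c is not None else fit.x_max

    label = "DSS3m"
    if config.apply_window_factor:
        dss *= (x_stop - fit.x_min) / width
        label = "DSS3m:windowed"
    dss = float(np.clip(dss, 0.0, 100.0))
    return DSSResult(
        sample_id=sample_id,
        treatment_id=treatment_id,
        dss=dss,
        auc=float(auc),
        x_stop=float(x_stop),
        metric_label=label,
    )


@dataclass(frozen=True)
class ScoredFit:
    """One independent experiment's fitted curve for a (sample, treatment)."""

    sample_id: str
    treatment_id: str
    experiment: str
    fit: LogisticFit


@dataclass
class DSSTable:
    """Per-experiment scores plus mean/SD across independent experiments.

    ``scores`` has one row per (sample, treatment, experiment); ``summary``
    one row per (sample, treatment) with ``dss_mean``, ``dss_sd`` (NaN when
    only a single experiment contributes) and ``n_experiments``.
    """

    scores: pd.DataFrame
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        if self.scores.empty:
            self.summary = pd.DataFrame(
                columns=["sample_id", "treatment_id", "dss_mean", "dss_sd", "n_experiments"]
            )
            return
        self.summary = (
            self.scores.groupby(["sample_id", "treatment_id"], sort=True)["dss"]
            .agg(dss_mean="mean", dss_sd=lambda v: v.std(ddof=1), n_experiments="size")
            .reset_index()
        )


def dss_table(fits: list[ScoredFit], config: DSSConfig | None = None) -> DSSTable:
    """Score a collection of fits; combinations are scored exactly like
    singles, using the shared 1:1 series concentration as the dose axis."""
    rows = []
    for sf in fits:
        res = dss_score(sf.fit, config, sample_id=sf.sample_id, treatment_id=sf.treatment_id)
        rows.append(
            {
                "sample_id": sf.sample_id,
                "treatment_id": sf.treatment_id,
                "experiment": sf.experiment,
                "dss": res.dss,
                "auc": res.auc,
                "x_stop": res.x_stop,
            }
        )
    return DSSTable(pd.DataFrame(rows, columns=["sample_id", "treatment_id", "experiment", "dss", "auc", "x_stop"]))
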