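"""Four-parameter logistic dose-response fitting on the log10-dose axis.

The model is the standard monotone-decreasing viability curve

    v(x) = bottom + (top - bottom) / (1 + 10^(hill * (x - log10_ic50)))

with x = log10(concentration in nM). ``hill >= 0`` enforces a monotone
non-increasing kill curve, the shape the downstream sensitivity score
assumes. Fitting is deterministic: bounded least squares started from a
fixed coarse grid of (log10_ic50, hill) candidates, best residual wins.
A series that defeats the optimizer falls back to a flat curve at the mean
viability with ``converged=False`` — a screen must never abort on one bad
well series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import DomainError, InputError

DEFAULT_BOUNDS = {
    "viability": (0.0, 120.0),  # bottom/top range; viability occasionally tops 100%
    "hill": (0.0, 10.0),
    "log10_ic50_margin": 2.0,  # allowed overhang beyond the tested log-range
}

_ORDER_PENALTY = 1e3  # soft enforcement of bottom <= top in the residual


@dataclass(frozen=True)
class DoseSeries:
    """One treatment's normalized viability along its concentration series."""

    concentrations: tuple[float, ...]  # nM, strictly ascending
    viability: tuple[float, ...]  # percent of control
    sample_id: str = ""
    treatment_id: str = ""

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        viab = np.asarray(self.viability, dtype=float)
        if conc.size != viab.size:
            raise InputError("concentrations and viability must have equal length")
        if conc.size < 2:
            raise InputError("need at least 2 dose points to fit")
        if np.any(np.diff(conc) <= 0):
            raise InputError("concentrations must be strictly ascending")
        if np.any(conc <= 0):
            raise InputError("concentrations must be positive (nM)")
        if not np.all(np.isfinite(viab)):
            raise InputError("viability values must be finite")

    @property
    def log10_conc(self) -> np.ndarray:
        return np.log10(np.asarray(self.concentrations, dtype=float))


@dataclass(frozen=True)
class LogisticFit:
    """Fitted logistic curve plus the tested log10-dose window it covers."""

    top: float
    bottom: float
    log10_ic50: float
    hill: float
    rss: float
    converged: bool
    x_min: float
    x_max: float

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        """Viability (%) at log10 concentration ``x``."""
        return logistic(x, self.top, self.bottom, self.log10_ic50, self.hill)


def logistic(
    x: np.ndarray | float, top: float, bottom: float, log10_ic50: float, hill: float
) -> np.ndarray | float:
    """Evaluate the 4-parameter logistic viability curve at log10 dose ``x``."""
    z = hill * (np.asarray(x, dtype=float) - log10_ic50)
    # 10^z overflows for extreme z; the curve saturates there anyway
    z = np.clip(z, -300.0, 300.0)
    out = bottom + (top - bottom) / (1.0 + np.power(10.0, z))
    return float(out) if np.ndim(x) == 0 else out


def fit_logistic(series: DoseSeries, bounds: dict | None = None) -> LogisticFit:
    """Least-squares fit of the logistic curve to one dose series.

    The optimizer is restarted from a 5x5 grid over (log10_ic50, hill);
    a flat-mean candidate always competes, so the returned fit's residual
    never exceeds the flat fallback's. Deterministic (no randomness).
    """
    cfg = dict(DEFAULT_BOUNDS)
    if bounds:
        cfg.update(bounds)
    v_lo, v_hi = cfg["viability"]
    h_lo, h_hi = cfg["hill"]

    x = series.log10_conc
    v = np.asarray(series.viability, dtype=float)
    x_min, x_max = float(x[0]), float(x[-1])
    c_lo = x_min - cfg["log10_ic50_margin"]
    c_hi = x_max + cfg["log10_ic50_margin"]

    flat_level = float(np.clip(np.mean(v), v_lo, v_hi))
    flat = LogisticFit(
        top=flat_level,
        bottom=flat_level,
        log10_ic50=0.5 * (x_min + x_max),
        hill=0.0,
        rss=float(np.sum((v - flat_level) ** 2)),
        converged=True,
        x_min=x_min,
        x_max=x_max,
    )

    def residuals(p: np.ndarray) -> np.ndarray:
        top, bottom, c, h = p
        r = logistic(x, top, bottom, c, h) - v
        return np.append(r, _ORDER_PENALTY * max(bottom - top, 0.0))

    lb = np.array([v_lo, v_lo, c_lo, max(h_lo, 0.0)])
    ub = np.array([v_hi, v_hi, c_hi, h_hi])
    top0 = float(np.clip(np.max(v), v_lo, v_hi))
    bottom0 = float(np.clip(np.min(v), v_lo, v_hi))

    best: LogisticFit | None = None
    c_grid = np.linspace(x_min - 0.5, x_max + 0.5, 5)
    h_grid = np.array([0.25, 0.5, 1.0, 2.0, 4.0])
    h_grid = np.clip(h_grid, h_lo + 1e-6, h_hi)
    for c0 in c_grid:
        for h0 in h_grid:
            p0 = np.clip(np.array([top0, bottom0, c0, h0]), lb, ub)
            try:
                sol = least_squares(residuals, p0, bounds=(lb, ub), method="trf")
            except Exception:
                continue
            top, bottom, c, h = sol.x
            bottom = min(bottom, top)  # trim residual-penalty leakage
            rss = float(np.sum((logistic(x, top, bottom, c, h) - v) ** 2))
            if best is None or rss < best.rss:
                best = LogisticFit(
                    top=float(top),
                    bottom=float(bottom),
                    log10_ic50=float(c),
                    hill=float(h),
                    rss=rss,
                    converged=True,
                    x_min=x_min,
                    x_max=x_max,
                )
    if best is None:
        # optimizer never produced a candidate: degenerate fallback, flagged
        return LogisticFit(
            top=flat.top,
            bottom=flat.bottom,
            log10_ic50=flat.log10_ic50,
            hill=0.0,
            rss=flat.rss,
            converged=False,
            x_min=x_min,
            x_max=x_max,
        )
    return best if best.rss <= flat.rss else flat


def fit_normalized_table(normalized) -> dict[tuple[str, str], LogisticFit]:
    """Fit every (sample, treatment) series of a control-normalized table.

    ``normalized`` is the frame produced by
    :func:`screenscore.screen_io.normalize_viability` (possibly concatenated
    over samples). Returns a mapping keyed by (sample_id, treatment_id).
    """
    fits: dict[tuple[str, str], LogisticFit] = {}
    for (sample_id, treatment_id), grp in normalized.groupby(
        ["sample_id", "treatment_id"], sort=True
    ):
        grp = grp.sort_values("concentration_nM")
        series = DoseSeries(
            tuple(grp["concentration_nM"]),
            tuple(grp["viability_pct"]),
            sample_id=sample_id,
            treatment_id=treatment_id,
        )
        fits[(sample_id, treatment_id)] = fit_logistic(series)
    return fits


def predict_viability(fit: LogisticFit, concentration: float) -> float:
    """Closed-form viability (%) at ``concentration`` (nM, > 0)."""
    if not concentration > 0:
        raise DomainError(f"concentration must be positive, got {concentration!r}")
    return float(fit(np.log10(concentration)))
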