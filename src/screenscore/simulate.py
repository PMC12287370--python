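"""Synthetic screen, combination-surface and count-matrix generators.

Every consumer module in the package is exercised against data whose ground
truth is known by construction: logistic viability curves rendered back
into raw plate luminescence (so control normalization is tested end to
end), Bliss-independent or synergy-injected combination surfaces, and
negative-binomial transcript counts with spiked fold changes.

The defaults emulate the screening design the package targets: a library
of 93 single agents and 87 fixed-ratio 1:1 combinations, each dosed at five
log-spaced concentrations (1–10,000 nM), viability read out against
in-plate vehicle and full-kill controls, and two biological replicates per
condition for transcript counts. Noise defaults — additive Gaussian
viability noise of 5% (truncated so signals stay non-negative) and
negative-binomial dispersion 0.05 — are chosen to resemble triplicate
CellTiter-Glo scatter and bulk RNA-seq overdispersion, and are all
configurable.

All generators are pure functions of (ground truth, seed): identical seeds
give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bliss import CombinationMatrix, DiagonalCombination
from .diff_transcription import CountMatrix
from .dose_response import logistic
from .errors import ValidationError
from .screen_io import ScreenTable, Treatment, TreatmentLibrary

DEFAULT_SERIES = (1.0, 10.0, 100.0, 1000.0, 10000.0)  # nM, 5-point log-spaced

TARGET_POOL = (
    "BCL2", "BCL2L1", "HDAC1", "HDAC2", "HDAC6", "PSMB5", "PSMB1", "PIK3CD",
    "BTK", "MTOR", "JAK1", "JAK2", "SYK", "CDK9", "MCL1", "XPO1", "EZH2",
    "BRD4", "PARP1", "AURKB",
)


@dataclass(frozen=True)
class LogisticParams:
    """Admissible ground-truth curve parameters (viability %, log10 nM)."""

    top: float = 100.0
    bottom: float = 0.0
    log10_ic50: float = 2.0
    hill: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.bottom <= self.top <= 120.0):
            raise ValidationError("require 0 <= bottom <= top <= 120")
        if not 0.0 <= self.hill <= 10.0:
            raise ValidationError("require 0 <= hill <= 10")


@dataclass(frozen=True)
class NoiseModel:
    """Viability noise: additive Gaussian (% points) plus multiplicative CV."""

    additive_sd: float = 5.0
    multiplicative_cv: float = 0.0


@dataclass
class ScreenGroundTruth:
    """True curves and noise for one simulated screen.

    ``params`` maps (sample_id, treatment_id) to the true logistic curve.
    Raw signals are rendered as pos + v/100 · (neg − pos), so that control
    normalization inverts the construction exactly at zero noise.
    """

    params: dict[tuple[str, str], LogisticParams]
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    n_replicates: int = 3
    neg_mean: float = 10000.0
    pos_mean: float = 500.0
    n_control_wells: int = 16


def simulate_screen(truth: ScreenGroundTruth, library: TreatmentLibrary) -> ScreenTable:
    """Render ground-truth curves into a raw long-format screen table."""
    rng = np.random.default_rng(truth.seed)
    span = truth.neg_mean - truth.pos_mean
    if span <= 0:
        raise ValidationError("neg_mean must exceed pos_mean")
    rows: list[dict] = []
    samples = sorted({s for s, _ in truth.params})
    for sample in samples:
        for role, mean in (("neg_ctrl", truth.neg_mean), ("pos_ctrl", truth.pos_mean)):
            for rep in range(1, truth.n_control_wells + 1):
                sig = mean * (1.0 + truth.noise.multiplicative_cv * rng.standard_normal())
                sig += truth.noise.additive_sd / 100.0 * span * rng.standard_normal()
                rows.append(
                    {
                        "sample_id": sample,
                        "treatment_id": "",
                        "treatment_type": "",
                        "concentration_nM": np.nan,
                        "replicate": rep,
                        "signal": max(sig, 0.0),
                        "well_role": role,
                    }
                )
        for (s, treatment_id), p in truth.params.items():
            if s != sample:
                continue
            treatment = library[treatment_id]
            x = np.log10(treatment.concentration_series)
            true_v = logistic(x, p.top, p.bottom, p.log10_ic50, p.hill)
            for rep in range(1, truth.n_replicates + 1):
                v = true_v * (
                    1.0 + truth.noise.multiplicative_cv * rng.standard_normal(x.size)
                ) + truth.noise.additive_sd * rng.standard_normal(x.size)
                signal = np.maximum(truth.pos_mean + v / 100.0 * span, 0.0)
                for conc, sig in zip(treatment.concentration_series, signal):
                    rows.append(
                        {
                            "sample_id": sample,
                            "treatment_id": treatment_id,
                            "treatment_type": treatment.treatment_type,
                            "concentration_nM": conc,
                            "replicate": rep,
                            "signal": float(sig),
                            "well_role": "compound",
                        }
                    )
    return ScreenTable(pd.DataFrame(rows))


def random_ground_truth(
    library: TreatmentLibrary,
    samples: list[str],
    seed: int = 0,
    noise: NoiseModel | None = None,
    n_replicates: int = 3,
    potent_targets: set[str] | None = None,
) -> ScreenGroundTruth:
    """Draw admissible random curves for every (sample, treatment) pair.

    When ``potent_targets`` is given, treatments annotated to any of those
    targets are drawn potent (low IC50, complete kill) and all others weak —
    the construction behind rank-recovery checks on target addiction.
    """
    rng = np.random.default_rng(seed)
    params: dict[tuple[str, str], LogisticParams] = {}
    for sample in samples:
        for t in library:
            x = np.log10(t.concentration_series)
            if potent_targets is not None:
                if t.targets & potent_targets:
                    p = LogisticParams(
                        top=100.0,
                        bottom=float(rng.uniform(0.0, 5.0)),
                        log10_ic50=float(rng.uniform(x[0] + 0.3, x[0] + 1.2)),
                        hill=float(rng.uniform(1.0, 2.0)),
                    )
                else:
                    p = LogisticParams(
                        top=100.0,
                        bottom=float(rng.uniform(60.0, 90.0)),
                        log10_ic50=float(rng.uniform(x[-1] - 1.0, x[-1])),
                        hill=float(rng.uniform(0.5, 1.5)),
                    )
            else:
                p = LogisticParams(
                    top=float(rng.uniform(90.0, 110.0)),
                    bottom=float(rng.uniform(0.0, 30.0)),
                    log10_ic50=float(rng.uniform(x[0] + 1.0, x[-1] - 1.0)),
                    hill=float(rng.uniform(0.8, 2.0)),
                )
            params[(sample, t.treatment_id)] = p
    return ScreenGroundTruth(
        params=params,
        noise=noise or NoiseModel(),
        seed=int(rng.integers(2**31 - 1)),
        n_replicates=n_replicates,
    )


@dataclass
class CombinationGroundTruth:
    """True monotherapy curves, injected Bliss excess and grid for one pair.

    ``injected_excess`` is added to the Bliss-independent combined
    inhibition *before* clipping to [0, 1]; on unsaturated interior cells
    the scorer recovers it exactly (×100, in percentage points).
    """

    mono_a: LogisticParams
    mono_b: LogisticParams
    doses_a: tuple[float, ...] = DEFAULT_SERIES
    doses_b: tuple[float, ...] = DEFAULT_SERIES
    injected_excess: float = 0.0
    noise_sd: float = 0.0  # viability % points, Gaussian, on every measured cell
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.injected_excess) > 1.0:
            raise ValidationError("|injected_excess| must be <= 1 (inhibition fraction)")


def simulate_combination(
    truth: CombinationGroundTruth,
) -> tuple[CombinationMatrix, DiagonalCombination]:
    """Render a full matrix and the matching 1:1 diagonal design."""
    rng = np.random.default_rng(truth.seed)

    def mono_inhibition(p: LogisticParams, doses: np.ndarray) -> np.ndarray:
        f = np.zeros_like(doses)
        pos = doses > 0
        v = logistic(np.log10(doses[pos]), p.top, p.bottom, p.log10_ic50, p.hill)
        f[pos] = np.clip((100.0 - v) / 100.0, 0.0, 1.0)
        return f

    da = np.concatenate([[0.0], np.asarray(truth.doses_a, dtype=float)])
    db = np.concatenate([[0.0], np.asarray(truth.doses_b, dtype=float)])
    f_a = mono_inhibition(truth.mono_a, da)
    f_b = mono_inhibition(truth.mono_b, db)
    f = f_a[:, None] + f_b[None, :] - f_a[:, None] * f_b[None, :]
    combo_cells = (da[:, None] > 0) & (db[None, :] > 0)
    f = np.where(combo_cells, np.clip(f + truth.injected_excess, 0.0, 1.0), f)
    viability = 100.0 * (1.0 - f)
    if truth.noise_sd > 0:
        noise = truth.noise_sd * rng.standard_normal(viability.shape)
        noise[0, 0] = 0.0  # untreated anchor stays exact
        viability = viability + noise
    matrix = CombinationMatrix(doses_a=da, doses_b=db, viability=viability.copy())

    # diagonal design shares the A-series for both drugs
    series = np.asarray(truth.doses_a, dtype=float)
    fa = mono_inhibition(truth.mono_a, series)
    fb = mono_inhibition(truth.mono_b, series)
    fc = np.clip(fa + fb - fa * fb + truth.injected_excess, 0.0, 1.0)
    mono_a_v = 100.0 * (1.0 - fa)
    mono_b_v = 100.0 * (1.0 - fb)
    combo_v = 100.0 * (1.0 - fc)
    if truth.noise_sd > 0:
        mono_a_v = mono_a_v + truth.noise_sd * rng.standard_normal(series.size)
        mono_b_v = mono_b_v + truth.noise_sd * rng.standard_normal(series.size)
        combo_v = combo_v + truth.noise_sd * rng.standard_normal(series.size)
    diagonal = DiagonalCombination(
        concentrations=series, mono_a=mono_a_v, mono_b=mono_b_v, combo=combo_v
    )
    return matrix, diagonal


@dataclass
class CountGroundTruth:
    """Negative-binomial transcript counts with spiked fold changes.

    Baseline means are log-normal across transcripts; ``spiked`` transcripts
    get ``fold_change`` applied to the resistant condition (and a fixed
    well-expressed baseline mean, so the spike is detectable by design).
    """

    n_transcripts: int = 5000
    baseline_log_mean: float = np.log(100.0)
    baseline_log_sd: float = 1.0
    dispersion: float = 0.05
    n_spiked: int = 25
    fold_change: float = 8.0
    spiked_baseline_mean: float = 200.0
    n_replicates: int = 2
    line: str = "SIMLINE"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")
        if self.fold_change <= 0:
            raise ValidationError("fold_change must be positive")
        if self.n_spiked > self.n_transcripts:
            raise ValidationError("spiked set must be a subset of transcripts")


def simulate_counts(truth: CountGroundTruth) -> tuple[CountMatrix, set[str]]:
    """Sample the count matrix; returns it with the spiked transcript ids."""
    rng = np.random.default_rng(truth.seed)
    ids = np.array([f"T{i:05d}" for i in range(truth.n_transcripts)])
    means = np.exp(
        truth.baseline_log_mean + truth.baseline_log_sd * rng.standard_normal(truth.n_transcripts)
    )
    spiked_idx = rng.choice(truth.n_transcripts, size=truth.n_spiked, replace=False)
    means[spiked_idx] = truth.spiked_baseline_mean
    fc = np.ones(truth.n_transcripts)
    # spikes go both directions, alternating up/down
    fc[spiked_idx] = np.where(
        np.arange(truth.n_spiked) % 2 == 0, truth.fold_change, 1.0 / truth.fold_change
    )

    def nb(mean: np.ndarray) -> np.ndarray:
        n = 1.0 / truth.dispersion  # NB size so that var = mean + dispersion·mean^2
        p = n / (n + mean)
        return rng.negative_binomial(n, p)

    data = {}
    for rep in range(1, truth.n_replicates + 1):
        data[f"{truth.line}_parental_{rep}"] = nb(means)
    for rep in range(1, truth.n_replicates + 1):
        data[f"{truth.line}_resistant_{rep}"] = nb(means * fc)
    counts = pd.DataFrame(data, index=pd.Index(ids, name="transcript_id"))
    return CountMatrix(counts), set(ids[spiked_idx])


def default_library(
    n_singles: int = 93,
    n_combinations: int = 87,
    series: tuple[float, ...] = DEFAULT_SERIES,
    seed: int = 0,
) -> TreatmentLibrary:
    """A deterministic stand-in drug library mirroring the screening design:
    93 single agents and 87 1:1 combinations over a 5-point series, with
    protein-target annotations drawn from a fixed pool."""
    rng = np.random.default_rng(seed)
    singles = []
    for i in range(n_singles):
        n_targets = int(rng.integers(1, 3))
        targets = set(rng.choice(TARGET_POOL, size=n_targets, replace=False))
        singles.append(
            Treatment(
                treatment_id=f"drug{i + 1:03d}",
                treatment_type="single",
                components=[f"drug{i + 1:03d}"],
                concentration_series=list(series),
                targets=targets,
            )
        )
    combos = []
    for j in range(n_combinations):
        a, b = rng.choice(n_singles, size=2, replace=False)
        sa, sb = singles[int(a)], singles[int(b)]
        combos.append(
            Treatment(
                treatment_id=f"{sa.treatment_id}+{sb.treatment_id}#{j + 1}",
                treatment_type="combination",
                components=[sa.treatment_id, sb.treatment_id],
                concentration_series=list(series),
                targets=sa.targets | sb.targets,
            )
        )
    return TreatmentLibrary.from_treatments(singles + combos)
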