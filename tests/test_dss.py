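import numpy as np
import pandas as pd
import pytest

import screenscore as ss
from screenscore.errors import DomainError

# Dense-trapezoid value for the reference curve (top=100, bottom=0,
# log10_ic50=2, hill=1) on x in [0, 4] with a 10% floor, computed on a
# 10,001-point grid independently of the quadrature path.
REFERENCE_DSS = 53.801677


def flat_fit(level: float) -> ss.LogisticFit:
    return ss.LogisticFit(level, level, 2.0, 0.0, 0.0, True, 0.0, 4.0)


def trapezoid_dss(fit: ss.LogisticFit, floor: float = 10.0, n: int = 10001) -> float:
    """Independent dense-grid oracle for the score."""
    x = np.linspace(fit.x_min, fit.x_max, n)
    y = np.clip(100.0 - np.asarray(fit(x)), 0.0, 100.0 - floor)
    return 100.0 * np.trapezoid(y, x) / ((100.0 - floor) * (fit.x_max - fit.x_min))


class TestDSSScore:
    def test_flat_full_viability_scores_zero(self):
        assert ss.dss_score(flat_fit(100.0)).dss == 0.0

    def test_flat_complete_kill_scores_hundred(self):
        assert ss.dss_score(flat_fit(0.0)).dss == pytest.approx(100.0, abs=1e-9)

    def test_reference_curve_matches_frozen_oracle(self, reference_fit):
        assert ss.dss_score(reference_fit).dss == pytest.approx(REFERENCE_DSS, abs=1e-3)

    def test_quadrature_agrees_with_trapezoid_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = ss.LogisticParams(
                top=float(rng.uniform(80, 115)),
                bottom=float(rng.uniform(0, 70)),
                log10_ic50=float(rng.uniform(-1, 5)),
                hill=float(rng.uniform(0, 6)),
            )
            fit = ss.LogisticFit(p.top, p.bottom, p.log10_ic50, p.hill, 0.0, True, 0.0, 4.0)
            assert ss.dss_score(fit).dss == pytest.approx(trapezoid_dss(fit), abs=1e-3)

    def test_score_bounded(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            fit = ss.LogisticFit(
                float(rng.uniform(0, 120)), 0.0,
                float(rng.uniform(-2, 6)), float(rng.uniform(0, 10)),
                0.0, True, 0.0, 4.0,
            )
            assert 0.0 <= ss.dss_score(fit).dss <= 100.0

    def test_monotone_in_potency_and_efficacy(self):
        """Lower IC50 (more potent) or lower bottom (deeper kill) never
        decreases the score."""
        rng = np.random.default_rng(9)
        for _ in range(200):
            c = float(rng.uniform(0, 4))
            bottom = float(rng.uniform(0, 60))
            hill = float(rng.uniform(0.3, 4))
            base = ss.dss_score(ss.LogisticFit(100, bottom, c, hill, 0, True, 0, 4)).dss
            potent = ss.dss_score(
                ss.LogisticFit(100, bottom, c - rng.uniform(0.1, 1.0), hill, 0, True, 0, 4)
            ).dss
            deeper = ss.dss_score(
                ss.LogisticFit(100, bottom * rng.uniform(0, 0.9), c, hill, 0, True, 0, 4)
            ).dss
            assert potent >= base - 1e-9
            assert deeper >= base - 1e-9

    def test_equal_log_width_windows_score_equally(self):
        """Identical curve shapes over different tested ranges of the same
        log-width get the same score (drug-specific series stay comparable)."""
        a = ss.LogisticFit(100, 0, 2.0, 1.0, 0, True, 0.0, 4.0)
        shift = -1.0  # e.g. a 0.1-1000 nM series
        b = ss.LogisticFit(100, 0, 2.0 + shift, 1.0, 0, True, 0.0 + shift, 4.0 + shift)
        assert ss.dss_score(a).dss == pytest.approx(ss.dss_score(b).dss, abs=1e-9)

    def test_viability_above_hundred_contributes_nothing(self):
        stimulated = flat_fit(115.0)
        assert ss.dss_score(stimulated).dss == 0.0

    def test_window_factor_variant_labelled_and_smaller(self, reference_fit):
        plain = ss.dss_score(reference_fit)
        windowed = ss.dss_score(reference_fit, ss.DSSConfig(apply_window_factor=True))
        assert windowed.metric_label == "DSS3m:windowed"
        assert windowed.dss <= plain.dss
        # x_stop = log-dose where viability hits 10%: 2 + log10(90/10)
        assert plain.x_stop == pytest.approx(2.0 + np.log10(9.0))

    def test_empty_window_rejected(self):
        bad = ss.LogisticFit(100, 0, 2, 1, 0, True, 4.0, 4.0)
        with pytest.raises(DomainError):
            ss.dss_score(bad)

    def test_invalid_floor_rejected(self):
        with pytest.raises(DomainError):
            ss.DSSConfig(viability_floor=0.0)


class TestDSSTable:
    def test_mean_and_sd_across_experiments(self):
        # two flat fits engineered to score 60 and 70
        fits = [
            ss.ScoredFit("S1", "T1", "exp1", flat_fit(100 - 0.6 * 90)),
            ss.ScoredFit("S1", "T1", "exp2", flat_fit(100 - 0.7 * 90)),
        ]
        table = ss.dss_table(fits)
        row = table.summary.iloc[0]
        assert row["dss_mean"] == pytest.approx(65.0, abs=1e-6)
        assert row["dss_sd"] == pytest.approx(np.std([60, 70], ddof=1), abs=1e-6)
        assert row["n_experiments"] == 2

    def test_single_experiment_has_undefined_sd(self):
        table = ss.dss_table([ss.ScoredFit("S1", "T1", "exp1", flat_fit(50.0))])
        assert pd.isna(table.summary["dss_sd"].iloc[0])

    def test_empty_input_gives_empty_table(self):
        table = ss.dss_table([])
        assert table.scores.empty and table.summary.empty

    def test_more_potent_drug_scores_higher(self):
        """A drug generated 10x more potent at equal efficacy outranks the weaker one."""
        lib = ss.TreatmentLibrary.from_treatments(
            [
                ss.Treatment("A", "single", ["A"], [1, 10, 100, 1000, 10000]),
                ss.Treatment("B", "single", ["B"], [1, 10, 100, 1000, 10000]),
            ]
        )
        truth = ss.ScreenGroundTruth(
            params={
                ("S1", "A"): ss.LogisticParams(100, 0, 1.5, 1.0),
                ("S1", "B"): ss.LogisticParams(100, 0, 2.5, 1.0),
            },
            noise=ss.NoiseModel(additive_sd=0.0),
            seed=0,
        )
        screen = ss.simulate_screen(truth, lib)
        nv = ss.normalize_viability(screen, "S1")
        fits = []
        for tid in ("A", "B"):
            sub = nv[nv["treatment_id"] == tid].sort_values("concentration_nM")
            fits.append(
                ss.ScoredFit(
                    "S1", tid, "exp1",
                    ss.fit_logistic(
                        ss.DoseSeries(
                            tuple(sub["concentration_nM"]), tuple(sub["viability_pct"])
                        )
                    ),
                )
            )
        summary = ss.dss_table(fits).summary.set_index("treatment_id")
        assert summary.loc["A", "dss_mean"] > summary.loc["B", "dss_mean"]
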