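"""Reading, validation and control-normalization of viability screen tables.

A screen table is a long-format record of one CellTiter-Glo-style plate run:
one row per well, tagged as a compound well, a negative control (vehicle,
0.1% DMSO) or a positive control (100 µM benzethonium chloride, full kill).
Raw luminescence is converted to percent viability with a linear rescaling
anchored at the two control means:

    viability% = 100 * (signal - mean_pos) / (mean_neg - mean_pos)

so the vehicle control maps to 100% and the full-kill control to 0%.
Viability is deliberately *not* clipped to [0, 100] here: values slightly
outside the range are legitimate measurement noise, and downstream formulas
clip only where they require it.

Concentrations are stored in nM throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import (
    DegenerateControlsError,
    InputError,
    ParseError,
    SchemaError,
    ValidationError,
)

SCREEN_COLUMNS = (
    "sample_id",
    "treatment_id",
    "treatment_type",
    "concentration_nM",
    "replicate",
    "signal",
    "well_role",
)

WELL_ROLES = ("compound", "neg_ctrl", "pos_ctrl")


@dataclass
class ScreenTable:
    """Validated long-format screen table.

    ``data`` holds one row per well with the columns in :data:`SCREEN_COLUMNS`.
    Control rows may leave the treatment fields blank.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SCREEN_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"screen table missing column(s): {', '.join(missing)}")
        _validate_screen(self.data)

    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample_id"].unique())

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        sub = self.data[self.data["sample_id"] == sample_id]
        if sub.empty:
            raise InputError(f"sample {sample_id!r} not present in screen table")
        return sub


def _validate_screen(df: pd.DataFrame) -> None:
    bad_roles = set(df["well_role"].unique()) - set(WELL_ROLES)
    if bad_roles:
        raise ValidationError(f"unknown well_role values: {sorted(bad_roles)}")
    if (df["signal"] < 0).any():
        raise ValidationError("negative luminescence signal")
    for sample_id, grp in df.groupby("sample_id"):
        roles = set(grp["well_role"])
        if "neg_ctrl" not in roles or "pos_ctrl" not in roles:
            raise ValidationError(
                f"sample {sample_id!r} lacks a negative and/or positive control well"
            )
    compound = df[df["well_role"] == "compound"]
    if (compound["concentration_nM"] <= 0).any():
        raise ValidationError("compound wells must have concentration > 0")


def read_screen_table(path: str | Path, sep: str | None = None) -> ScreenTable:
    """Read a CSV/TSV screen table, case-insensitively matching headers.

    Parameters
    ----------
    path:
        File with columns ``sample_id, treatment_id, treatment_type,
        concentration_nM, replicate, signal, well_role`` (any capitalization).
    sep:
        Field separator; inferred from the extension when ``None``
        (``.tsv`` → tab, otherwise comma).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    raw.columns = [c.strip().lower() for c in raw.columns]
    missing = [c for c in SCREEN_COLUMNS if c.lower() not in raw.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    raw = raw.rename(columns={"concentration_nm": "concentration_nM"})

    df = raw.loc[:, list(SCREEN_COLUMNS)].copy()
    for col in ("concentration_nM", "signal"):
        parsed = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
        bad = parsed.isna() & (df[col] != "")
        if bad.any():
            # +2: header line plus 1-based numbering
            lines = [str(i + 2) for i in df.index[bad]]
            raise ParseError(
                f"{path.name}: non-numeric {col} at line(s) {', '.join(lines)}"
            )
        df[col] = parsed
    df["replicate"] = pd.to_numeric(df["replicate"].replace("", "0"), errors="coerce")
    if df["replicate"].isna().any():
        lines = [str(i + 2) for i in df.index[df["replicate"].isna()]]
        raise ParseError(f"{path.name}: non-numeric replicate at line(s) {', '.join(lines)}")
    df["replicate"] = df["replicate"].astype(int)
    df["signal"] = df["signal"].astype(float)
    return ScreenTable(df)


def write_screen_table(table: ScreenTable, path: str | Path, sep: str | None = None) -> None:
    """Write a screen table; numeric fields round-trip to full precision."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    table.data.to_csv(path, sep=sep, index=False, float_format="%.17g")


def normalize_viability(
    table: ScreenTable,
    sample_id: str,
    control_stat: Literal["mean", "median"] = "mean",
) -> pd.DataFrame:
    """Normalize one sample's compound wells to its own plate controls.

    Each well is normalized individually against the sample's control
    summary (arithmetic mean by default), then replicates are averaged per
    (treatment, concentration). Returns a frame with columns ``sample_id,
    treatment_id, concentration_nM, viability_pct, n_replicates,
    viability_sd`` (``viability_sd`` is NaN for a single replicate).

    Raises
    ------
    DegenerateControlsError
        If the negative-control summary does not exceed the positive-control
        summary, which signals assay failure.
    """
    sub = table.for_sample(sample_id)
    stat = np.mean if control_stat == "mean" else np.median
    neg = stat(sub.loc[sub["well_role"] == "neg_ctrl", "signal"].to_numpy())
    pos = stat(sub.loc[sub["well_role"] == "pos_ctrl", "signal"].to_numpy())
    if neg <= pos:
        raise DegenerateControlsError(
            f"sample {sample_id!r}: negative-control signal ({neg:g}) does not exceed "
            f"positive-control signal ({pos:g})"
        )
    compound = sub[sub["well_role"] == "compound"].copy()
    if compound.empty:
        import warnings

        warnings.warn(f"sample {sample_id!r} has no compound wells", stacklevel=2)
        return pd.DataFrame(
            columns=[
                "sample_id",
                "treatment_id",
                "concentration_nM",
                "viability_pct",
                "n_replicates",
                "viability_sd",
            ]
        )
    compound["viability_pct"] = 100.0 * (compound["signal"] - pos) / (neg - pos)
    grouped = (
        compound.groupby(["treatment_id", "concentration_nM"], sort=True)["viability_pct"]
        .agg(viability_pct="mean", n_replicates="size", viability_sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    grouped.insert(0, "sample_id", sample_id)
    return grouped


@dataclass
class Treatment:
    """One library entry: a single agent or fixed-ratio combination."""

    treatment_id: str
    treatment_type: Literal["single", "combination"]
    components: list[str]
    concentration_series: list[float]
    targets: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        series = list(self.concentration_series)
        if not series:
            raise ValidationError(f"{self.treatment_id}: empty concentration series")
        if any(b <= a for a, b in zip(series, series[1:])):
            raise ValidationError(
                f"{self.treatment_id}: concentration series must be strictly ascending"
            )
        if self.treatment_type == "combination" and len(self.components) < 2:
            raise ValidationError(
                f"{self.treatment_id}: combination must list >= 2 component drugs"
            )


@dataclass
class TreatmentLibrary:
    """Mapping treatment_id -> :class:`Treatment`."""

    treatments: dict[str, Treatment]

    def __iter__(self) -> Iterable[Treatment]:
        return iter(self.treatments.values())

    def __len__(self) -> int:
        return len(self.treatments)

    def __getitem__(self, treatment_id: str) -> Treatment:
        return self.treatments[treatment_id]

    @classmethod
    def from_treatments(cls, treatments: Iterable[Treatment]) -> "TreatmentLibrary":
        out: dict[str, Treatment] = {}
        for t in treatments:
            if t.treatment_id in out:
                raise ValidationError(f"duplicate treatment_id {t.treatment_id!r}")
            out[t.treatment_id] = t
        return cls(out)


def read_treatment_library(path: str | Path) -> TreatmentLibrary:
    """Read a TSV annotation table of treatments.

    Expected columns: ``treatment_id, type, components, targets, series``;
    ``components``, ``targets`` and ``series`` are semicolon-separated.
    An empty ``targets`` field is allowed (the treatment is then simply
    excluded from target-addiction scoring).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    required = ["treatment_id", "type", "components", "targets", "series"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s): {', '.join(missing)}")
    treatments = []
    for i, row in df.iterrows():
        try:
            series = [float(s) for s in row["series"].split(";") if s.strip()]
        except ValueError as exc:
            raise ParseError(f"{path.name}: bad series at line {i + 2}: {exc}") from exc
        treatments.append(
            Treatment(
                treatment_id=row["treatment_id"].strip(),
                treatment_type=row["type"].strip(),  # type: ignore[arg-type]
                components=[c.strip() for c in row["components"].split(";") if c.strip()],
                concentration_series=series,
                targets={t.strip() for t in row["targets"].split(";") if t.strip()},
            )
        )
    return TreatmentLibrary.from_treatments(treatments)


def write_treatment_library(library: TreatmentLibrary, path: str | Path) -> None:
    rows = [
        {
            "treatment_id": t.treatment_id,
            "type": t.treatment_type,
            "components": ";".join(t.components),
            "targets": ";".join(sorted(t.targets)),
            "series": ";".join(f"{c:g}" for c in t.concentration_series),
        }
        for t in library
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
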