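"""Threshold-based differential-transcription filter on paired count data.

For each cell-line model (a parental / drug-resistant pair profiled with
two biological replicates each), replicate raw counts are averaged to one
value per condition and three per-transcript statistics are computed:

    CPM   counts per million: count / condition library sum × 10^6
    MC    mean of counts between the parental and resistant condition
    L2FC  log2(resistant + 1) − log2(parental + 1)   (+1 pseudocount)

A transcript is flagged *altered* iff CPM > 0.5 (in at least one of the two
conditions, by default), MC ≥ 10 and |L2FC| > 2 — strict/non-strict
inequalities exactly as written. This is a plain filter: no dispersion
modelling, no p-values. Lines are analyzed separately; the per-line altered
sets are then compared with exact Venn arithmetic.

Config switches cover the two genuinely ambiguous readings: whether the
CPM clause must hold in one or both conditions, and whether replicates are
averaged before computing CPM or CPM is computed per replicate and then
averaged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import DomainError, InputError, SchemaError

STATES = ("parental", "resistant")


@dataclass
class CountMatrix:
    """Transcript × sample count matrix.

    ``counts`` is indexed by transcript id; column names encode
    ``{line}_{state}_{replicate}``, e.g. ``KARPAS1718_parental_1``.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise InputError("counts must be non-negative")
        meta = []
        for col in self.counts.columns:
            parts = str(col).rsplit("_", 2)
            if len(parts) != 3 or parts[1] not in STATES:
                raise SchemaError(
                    f"column {col!r} does not encode line_state_replicate "
                    f"with state in {STATES}"
                )
            meta.append({"column": col, "line": parts[0], "state": parts[1], "replicate": parts[2]})
        self.samples = pd.DataFrame(meta)

    @property
    def lines(self) -> list[str]:
        return sorted(self.samples["line"].unique())

    def condition_columns(self, line: str, state: str) -> list[str]:
        sel = self.samples[(self.samples["line"] == line) & (self.samples["state"] == state)]
        return sel["column"].tolist()


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a TSV count matrix: first column transcript_id, remaining column
    headers encoding ``line_state_replicate``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(df)


def cpm(counts: np.ndarray | pd.Series, library_sum: float) -> np.ndarray | pd.Series:
    """Counts per million: count / library_sum × 10^6."""
    if not library_sum > 0:
        raise DomainError(f"library_sum must be positive, got {library_sum!r}")
    return counts / library_sum * 1e6


def mean_counts(parental, resistant):
    """Mean of counts between the paired conditions."""
    return (parental + resistant) / 2.0


def log2_fc(parental, resistant):
    """log2 fold change of resistant over parental with a +1 pseudocount."""
    return np.log2(np.asarray(resistant, dtype=float) + 1.0) - np.log2(
        np.asarray(parental, dtype=float) + 1.0
    )


@dataclass(frozen=True)
class FilterThresholds:
    """The three filter clauses and the two ambiguity switches."""

    cpm_min: float = 0.5  # strict: CPM > cpm_min
    mc_min: float = 10.0  # non-strict: MC >= mc_min
    l2fc_min: float = 2.0  # strict: |L2FC| > l2fc_min
    cpm_mode: Literal["any", "both"] = "any"
    replicate_mode: Literal["average_counts", "per_replicate_cpm"] = "average_counts"


@dataclass
class DiffResult:
    """Per-transcript statistics for one line plus the altered id set."""

    line: str
    table: pd.DataFrame  # transcript_id, cpm_parental, cpm_resistant, mc, l2fc, altered

    @property
    def altered_ids(self) -> set[str]:
        return set(self.table.loc[self.table["altered"], "transcript_id"])


def altered_transcripts(
    m: CountMatrix, line: str, thresholds: FilterThresholds | None = None
) -> DiffResult:
    """Apply the CPM/MC/L2FC filter to one line's parental/resistant pair."""
    th = thresholds or FilterThresholds()
    cols = {state: m.condition_columns(line, state) for state in STATES}
    for state, cc in cols.items():
        if not cc:
            raise InputError(f"line {line!r} has no {state} samples")

    mean_cond = {state: m.counts[cols[state]].mean(axis=1) for state in STATES}

    if th.replicate_mode == "average_counts":
        cpm_cond = {
            state: cpm(mean_cond[state], float(mean_cond[state].sum())) for state in STATES
        }
    else:  # CPM per replicate against that replicate's library, then averaged
        cpm_cond = {
            state: pd.concat(
                [cpm(m.counts[c], float(m.counts[c].sum())) for c in cols[state]], axis=1
            ).mean(axis=1)
            for state in STATES
        }

    mc = mean_counts(mean_cond["parental"], mean_cond["resistant"])
    l2 = pd.Series(
        log2_fc(mean_cond["parental"].to_numpy(), mean_cond["resistant"].to_numpy()),
        index=m.counts.index,
    )
    if th.cpm_mode == "any":
        cpm_pass = np.maximum(cpm_cond["parental"], cpm_cond["resistant"]) > th.cpm_min
    else:
        cpm_pass = (cpm_cond["parental"] > th.cpm_min) & (cpm_cond["resistant"] > th.cpm_min)
    altered = cpm_pass & (mc >= th.mc_min) & (l2.abs() > th.l2fc_min)

    table = pd.DataFrame(
        {
            "transcript_id": m.counts.index.astype(str),
            "cpm_parental": cpm_cond["parental"].to_numpy(),
            "cpm_resistant": cpm_cond["resistant"].to_numpy(),
            "mc": mc.to_numpy(),
            "l2fc": l2.to_numpy(),
            "altered": altered.to_numpy(),
        }
    ).reset_index(drop=True)
    return DiffResult(line=line, table=table)


@dataclass(frozen=True)
class VennSummary:
    only_a: int
    only_b: int
    both: int

    @property
    def union(self) -> int:
        return self.only_a + self.only_b + self.both


def venn(set_a: Iterable[str], set_b: Iterable[str]) -> VennSummary:
    """Exact two-set overlap counts."""
    a, b = set(set_a), set(set_b)
    both = len(a & b)
    return VennSummary(only_a=len(a) - both, only_b=len(b) - both, both=both)
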