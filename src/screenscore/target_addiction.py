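"""Target addiction scoring: deconvolving drug sensitivity into protein targets.

The target addiction score (TAS) of a protein target is the arithmetic mean
of the drug sensitivity scores of every screened treatment — single agents
and combinations alike — annotated to that target. It quantifies how
functionally dependent a sample is on the target: if every drug hitting a
protein kills the cells, the cells are addicted to that protein. Higher TAS
means higher functional importance.

Combinations contribute their combined (union) target set, each target
receiving the combination's one DSS value once. Treatments without a
measured score are excluded from the mean, never imputed; targets with no
scored annotated treatment are absent from the table rather than zero.
"""

from __future__ import annotations

import pandas as pd

from .dss import DSSTable
from .errors import DomainError, InputError
from .screen_io import TreatmentLibrary


def compute_tas(
    dss: DSSTable | pd.DataFrame, library: TreatmentLibrary, sample_id: str
) -> pd.DataFrame:
    """Per-target addiction scores for one sample.

    Parameters
    ----------
    dss:
        A :class:`~screenscore.dss.DSSTable` (its experiment-mean summary is
        used) or a frame with columns ``sample_id, treatment_id, dss_mean``.
    library:
        Treatment annotations supplying each treatment's target set.
    sample_id:
        Sample to score; must appear in ``dss``.

    Returns
    -------
    DataFrame with one row per target: ``target, tas, n_treatments,
    treatment_ids`` (semicolon-joined contributors), sorted by target name.
    """
    summary = dss.summary if isinstance(dss, DSSTable) else dss
    mine = summary[summary["sample_id"] == sample_id]
    if mine.empty:
        raise InputError(f"sample {sample_id!r} has no scored treatments")
    scores = dict(zip(mine["treatment_id"], mine["dss_mean"]))

    per_target: dict[str, list[str]] = {}
    for treatment in library:
        if treatment.treatment_id not in scores:
            continue  # unmeasured: excluded, not imputed
        for target in treatment.targets:
            per_target.setdefault(target, []).append(treatment.treatment_id)

    rows = [
        {
            "target": target,
            "tas": sum(scores[t] for t in tids) / len(tids),
            "n_treatments": len(tids),
            "treatment_ids": ";".join(sorted(tids)),
        }
        for target, tids in per_target.items()
    ]
    return (
        pd.DataFrame(rows, columns=["target", "tas", "n_treatments", "treatment_ids"])
        .sort_values("target", ignore_index=True)
    )


def rank_targets(tas: pd.DataFrame, top_k: int) -> list[str]:
    """Targets ordered by TAS descending; ties broken by name ascending."""
    if top_k < 1:
        raise DomainError("top_k must be >= 1")
    if tas.empty:
        raise InputError("empty TAS table")
    ordered = tas.sort_values(["tas", "target"], ascending=[False, True])
    return ordered["target"].head(top_k).tolist()
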