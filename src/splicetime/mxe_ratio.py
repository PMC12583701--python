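"""Mutually exclusive exon (MXE) usage and RT-qPCR relative quantification.

The archetype is Snap25 exon 5a/5b: two exons of which mature transcripts
carry exactly one.  From isoform counts, the inclusion level of the b-form
is psi_b = b / (a + b); transcripts containing neither exon are excluded
from the denominator.  The developmental isoform switch is the timepoint at
which psi_b crosses 0.5 and the b-form becomes the dominant isoform.

qPCR support implements the 2^-ddCt method: target Ct normalised to an
endogenous-control gene, then to a calibrator sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CtRecord",
    "mxe_psi",
    "delta_psi",
    "majority_switch_interval",
    "ddct_fold_change",
]

MAJORITY_THRESHOLD = 0.5


@dataclass(frozen=True)
class CtRecord:
    """One qPCR well: threshold cycles for target and reference gene."""

    sample: str
    target: str  # e.g. "5a", "5b", "total"
    ct_target: Optional[float]
    ct_reference: Optional[float]
    replicate: int = 1

    def __post_init__(self) -> None:
        for ct in (self.ct_target, self.ct_reference):
            if ct is not None and ct <= 0:
                raise ValueError(f"{self.sample}: Ct must be positive, got {ct}")


def mxe_psi(count_a: int, count_b: int) -> float:
    """Inclusion level of the b isoform among the two mutually exclusive
    forms; NaN when neither isoform was observed."""
    if count_a < 0 or count_b < 0:
        raise ValueError("isoform counts must be non-negative")
    total = count_a + count_b
    if total == 0:
        return float("nan")
    return count_b / total


def delta_psi(
    psi_b: Sequence[float], reference_index: int = 0
) -> tuple[list[float], Optional[int]]:
    """Change in psi_b relative to a reference timepoint, plus the majority
    switch point.

    Returns ``(delta, switch_index)`` where ``switch_index`` is the first
    timepoint at which psi_b exceeds 0.5 after having been at or below it
    (the b-form becomes dominant), or None if no crossing occurs.
    """
    psi = [float(p) for p in psi_b]
    if not (0 <= reference_index < len(psi)) or math.isnan(psi[reference_index]):
        raise ValueError("reference timepoint absent or missing")
    ref = psi[reference_index]
    delta = [p - ref if not math.isnan(p) else float("nan") for p in psi]
    return delta, majority_switch_interval(psi)


def majority_switch_interval(psi_b: Sequence[float]) -> Optional[int]:
    """Index of the first observed timepoint where psi_b > 0.5 following an
    observed timepoint with psi_b <= 0.5; None without such a crossing."""
    below_seen = False
    for i, p in enumerate(psi_b):
        if math.isnan(p):
            continue
        if p > MAJORITY_THRESHOLD:
            if below_seen:
                return i
        else:
            below_seen = True
    return None


def ddct_fold_change(
    records: Sequence[CtRecord], calibrator: str
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method, per (sample, target).

    Replicate Cts are averaged before differencing.  dCt = Ct_target -
    Ct_reference per sample; ddCt = dCt_sample - dCt_calibrator; fold =
    2^-ddCt (so the calibrator's fold change is exactly 1).  Samples with a
    missing reference or target Ct are dropped with a reason.
    """
    df = pd.DataFrame(
        {
            "sample": r.sample,
            "target": r.target,
            "ct_target": r.ct_target,
            "ct_reference": r.ct_reference,
        }
        for r in records
    )
    if df.empty:
        raise ValueError("no Ct records")
    mean = df.groupby(["sample", "target"], sort=False).mean(numeric_only=True)
    mean["dct"] = mean["ct_target"] - mean["ct_reference"]
    rows = []
    for (sample, target), row in mean.iterrows():
        if np.isnan(row["dct"]):
            rows.append(
                {"sample": sample, "target": target, "fold_change": np.nan,
                 "ddct": np.nan, "dropped_reason": "missing_ct"}
            )
            continue
        if (calibrator, target) not in mean.index:
            raise ValueError(f"calibrator {calibrator!r} absent for target {target!r}")
        cal_dct = mean.loc[(calibrator, target), "dct"]
        if np.isnan(cal_dct):
            raise ValueError(f"calibrator {calibrator!r} has missing Ct for {target!r}")
        ddct = row["dct"] - cal_dct
        rows.append(
            {"sample": sample, "target": target, "fold_change": 2.0 ** (-ddct),
             "ddct": ddct, "dropped_reason": None}
        )
    return pd.DataFrame(rows)
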