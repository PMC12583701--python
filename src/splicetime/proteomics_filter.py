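"""Interactome comparative filter from IP-MS abundance ratios.

Defines nuclear-import-dependent interaction partners: proteins whose
co-precipitated abundance under import blockade plus stimulation drops
relative to stimulation alone.  A protein is kept when

    ratio = abundance(blocked + stimulated) / abundance(stimulated) <= cutoff

with cutoff 0.78 by default (non-strict inequality; a ``strict`` toggle
gives ``<``).  No multiple-testing layer is applied here: the downstream
cross-referencing consumes the ratio-filtered name list as-is.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["abundance_ratio", "filter_interactors", "DEFAULT_CUTOFF"]

DEFAULT_CUTOFF = 0.78


def abundance_ratio(
    table: pd.DataFrame,
    numerator: str,
    denominator: str,
    protein_col: str = "protein",
) -> pd.DataFrame:
    """Per-protein abundance ratio and log2 ratio between two conditions.

    ``table`` has one row per protein with abundance columns per condition;
    missing or non-positive denominators propagate a missing ratio.
    """
    for col in (protein_col, numerator, denominator):
        if col not in table.columns:
            raise ValueError(f"abundance table missing column {col!r}")
    num = pd.to_numeric(table[numerator], errors="coerce")
    den = pd.to_numeric(table[denominator], errors="coerce")
    if (num.dropna() < 0).any() or (den.dropna() < 0).any():
        raise ValueError("abundances must be non-negative")
    ratio = num / den.where(den > 0)
    return pd.DataFrame(
        {
            "protein": table[protein_col].astype(str),
            "ratio": ratio,
            "log2_ratio": np.log2(ratio.where(ratio > 0)),
        }
    )


def filter_interactors(
    ratios: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
    strict: bool = False,
) -> tuple[list[str], pd.DataFrame]:
    """Keep proteins whose ratio falls at or below the cutoff.

    Returns ``(kept_names, dropped)`` where ``dropped`` records proteins
    removed for a missing ratio.  The filter is monotone in ``cutoff``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    missing = ratios["ratio"].isna()
    dropped = ratios.loc[missing, ["protein"]].assign(reason="missing_ratio")
    r = ratios.loc[~missing]
    keep = r["ratio"] < cutoff if strict else r["ratio"] <= cutoff
    return r.loc[keep, "protein"].tolist(), dropped.reset_index(drop=True)
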