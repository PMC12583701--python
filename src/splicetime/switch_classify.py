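"""Compare control vs perturbed switch calls and assign splicing-timing
categories.

Each exon with a testable trajectory in both conditions is assigned exactly
one of four categories relative to control:

* ``Early``    -- the perturbed switch precedes the control switch (or the
                  control never switches while the perturbed condition does);
* ``Late``     -- the perturbed switch follows the control switch, including
                  the case where it never arrives within the observation
                  window (index treated as +inf);
* ``Reversed`` -- both conditions switch but in opposite directions;
* ``Unaffected`` -- neither switches, or both switch at the same timepoint
                  in the same direction.

Exons that are untestable (under-covered or degenerate) in either condition
are *excluded*, not folded into Unaffected, so category denominators stay
honest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .psi_core import SwitchCall

__all__ = [
    "CATEGORIES",
    "CategorySummary",
    "classify_exon",
    "categorize_all",
    "category_summary",
]

CATEGORIES = ("Early", "Late", "Reversed", "Unaffected")

CATEGORY_COLUMNS = [
    "exon_id",
    "control_switch",
    "treatment_switch",
    "control_direction",
    "treatment_direction",
    "category",
    "n_reversals_control",
    "n_reversals_treatment",
    "excluded",
    "excluded_reason",
]


def classify_exon(control: SwitchCall, treatment: SwitchCall) -> str:
    """Assign a timing category from a matched pair of switch calls.

    Only the first reversal of each series is compared; multiple reversals
    are retained on the calls for downstream flagging.
    """
    if control.exon_id != treatment.exon_id:
        raise ValueError(
            f"mismatched exon ids: {control.exon_id!r} vs {treatment.exon_id!r}"
        )
    if not control.switched and not treatment.switched:
        return "Unaffected"
    if control.switched and not treatment.switched:
        # switch deferred beyond the observation window
        return "Late"
    if treatment.switched and not control.switched:
        return "Early"
    if control.direction != treatment.direction:
        return "Reversed"
    if treatment.switch_index < control.switch_index:
        return "Early"
    if treatment.switch_index > control.switch_index:
        return "Late"
    return "Unaffected"


def categorize_all(
    control_calls: Mapping[str, Union[SwitchCall, str]],
    treatment_calls: Mapping[str, Union[SwitchCall, str]],
) -> pd.DataFrame:
    """Outer-join switch calls from both conditions into a category table.

    Values may be :class:`SwitchCall` objects or strings naming an exclusion
    reason (e.g. ``"untestable"``) for exons dropped in that condition.
    Exons present on only one side are excluded with reason
    ``missing_in_<condition>``.
    """
    rows = []
    for exon_id in sorted(set(control_calls) | set(treatment_calls)):
        ctrl = control_calls.get(exon_id)
        trt = treatment_calls.get(exon_id)
        reason = None
        if ctrl is None:
            reason = "missing_in_control"
        elif trt is None:
            reason = "missing_in_treatment"
        elif isinstance(ctrl, str):
            reason = f"control:{ctrl}"
        elif isinstance(trt, str):
            reason = f"treatment:{trt}"
        if reason is not None:
            rows.append(
                {
                    "exon_id": exon_id,
                    "control_switch": None,
                    "treatment_switch": None,
                    "control_direction": None,
                    "treatment_direction": None,
                    "category": None,
                    "n_reversals_control": None,
                    "n_reversals_treatment": None,
                    "excluded": True,
                    "excluded_reason": reason,
                }
            )
            continue
        rows.append(
            {
                "exon_id": exon_id,
                "control_switch": ctrl.switch_index,
                "treatment_switch": trt.switch_index,
                "control_direction": ctrl.direction,
                "treatment_direction": trt.direction,
                "category": classify_exon(ctrl, trt),
                "n_reversals_control": ctrl.n_reversals,
                "n_reversals_treatment": trt.n_reversals,
                "excluded": False,
                "excluded_reason": None,
            }
        )
    return pd.DataFrame(rows, columns=CATEGORY_COLUMNS)


@dataclass(frozen=True)
class CategorySummary:
    total: int
    included: int
    excluded: int
    early: int
    late: int
    reversed: int
    unaffected: int

    @property
    def altered(self) -> int:
        """Exons with any timing change: Early + Late + Reversed."""
        return self.early + self.late + self.reversed

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "included": self.included,
            "excluded": self.excluded,
            "Early": self.early,
            "Late": self.late,
            "Reversed": self.reversed,
            "Unaffected": self.unaffected,
            "altered": self.altered,
        }


def category_summary(table: pd.DataFrame) -> CategorySummary:
    """Totals and per-category counts for a category table."""
    if len(table) == 0:
        return CategorySummary(0, 0, 0, 0, 0, 0, 0)
    excluded = int(table["excluded"].sum())
    counts = table.loc[~table["excluded"], "category"].value_counts()
    return CategorySummary(
        total=len(table),
        included=len(table) - excluded,
        excluded=excluded,
        early=int(counts.get("Early", 0)),
        late=int(counts.get("Late", 0)),
        reversed=int(counts.get("Reversed", 0)),
        unaffected=int(counts.get("Unaffected", 0)),
    )
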