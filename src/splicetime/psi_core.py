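"""Percent-spliced-in (PSI) trajectories and switching-time calls.

A cassette exon's inclusion over development is summarised per timepoint as
PSI, the length-normalised fraction of junction reads supporting the
inclusion isoform.  Across an ordered series of timepoints the trajectory is
z-scored into a *relative inclusion rate*,

    z_t = (PSI_t - PSI_mu) / PSI_sigma,

where PSI_mu / PSI_sigma are the trajectory's own mean and (population)
standard deviation.  The *switching time* of an exon is the first timepoint
at which the sign of the relative inclusion series reverses -- the
developmental moment at which splice-site preference flips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "JunctionCounts",
    "PsiTrajectory",
    "RelativeInclusionSeries",
    "SwitchCall",
    "UntestableTrajectoryError",
    "compute_psi",
    "replicate_psi",
    "relative_inclusion",
    "switching_time",
    "call_switch",
]

DEFAULT_MIN_TOTAL_READS = 10
DEFAULT_SIGMA_TOL = 1e-8
DEFAULT_ZERO_TOL = 1e-8
#: Minimum PSI amplitude (max - min) for a trajectory to be considered
#: testable; below this the series is pure noise after z-scoring.
DEFAULT_MIN_PSI_RANGE = 0.05


class UntestableTrajectoryError(ValueError):
    """Raised when a trajectory has fewer than two informative timepoints."""


@dataclass(frozen=True)
class JunctionCounts:
    """Per-replicate inclusion/skipping junction counts for one exon cell.

    A *cell* is one (exon, condition, timepoint) combination.  Replicates
    where the count is unavailable (rMATS ``NA``) are ``None``.
    """

    exon_id: str
    timepoint: str
    condition: str
    inclusion: tuple[Optional[int], ...]
    skipping: tuple[Optional[int], ...]
    inc_form_len: int
    skip_form_len: int

    def __post_init__(self) -> None:
        if len(self.inclusion) != len(self.skipping) or len(self.inclusion) == 0:
            raise ValueError(
                f"{self.exon_id}: inclusion/skipping replicate lists must have "
                f"equal non-zero length"
            )
        for counts in (self.inclusion, self.skipping):
            for c in counts:
                if c is not None and c < 0:
                    raise ValueError(f"{self.exon_id}: negative junction count {c}")
        if self.inc_form_len <= 0 or self.skip_form_len <= 0:
            raise ValueError(f"{self.exon_id}: effective form lengths must be > 0")


@dataclass(frozen=True)
class PsiTrajectory:
    """Replicate-averaged PSI across ordered timepoints for one condition."""

    exon_id: str
    condition: str
    timepoints: tuple[str, ...]
    psi: tuple[float, ...]  # NaN marks a missing cell
    n_informative: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.timepoints) == len(self.psi) == len(self.n_informative)):
            raise ValueError(f"{self.exon_id}: trajectory field lengths differ")
        for p in self.psi:
            if not math.isnan(p) and not (0.0 <= p <= 1.0):
                raise ValueError(f"{self.exon_id}: PSI {p} outside [0, 1]")

    @property
    def n_observed(self) -> int:
        return sum(0 if math.isnan(p) else 1 for p in self.psi)

    @property
    def psi_range(self) -> float:
        obs = [p for p in self.psi if not math.isnan(p)]
        return (max(obs) - min(obs)) if obs else float("nan")


@dataclass(frozen=True)
class RelativeInclusionSeries:
    """Trajectory z-scores: (PSI_t - PSI_mu) / PSI_sigma per timepoint."""

    exon_id: str
    condition: str
    timepoints: tuple[str, ...]
    z: tuple[float, ...]  # NaN propagated from missing PSI cells
    mu: float
    sigma: float
    degenerate: bool


@dataclass(frozen=True)
class SwitchCall:
    """Switching-time verdict for one exon in one condition.

    ``switch_index`` is the ordinal timepoint index (into ``signs``) at which
    the reversed sign first holds, or ``None`` when the series never reverses.
    ``direction`` is the sign after the first reversal: ``"up"`` for a
    negative-to-positive flip, ``"down"`` for the converse.
    """

    exon_id: str
    condition: str
    switch_index: Optional[int]
    direction: str  # "up" | "down" | "none"
    n_reversals: int
    signs: tuple[str, ...] = field(default=())  # per timepoint: "-", "0", "+", "."

    def __post_init__(self) -> None:
        switched = self.switch_index is not None
        if switched != (self.direction != "none") or switched != (self.n_reversals > 0):
            raise ValueError(
                f"{self.exon_id}: inconsistent switch call "
                f"(index={self.switch_index}, direction={self.direction}, "
                f"n_reversals={self.n_reversals})"
            )

    @property
    def switched(self) -> bool:
        return self.switch_index is not None


def replicate_psi(inc: int, skip: int, inc_form_len: int, skip_form_len: int) -> float:
    """Length-normalised PSI for a single replicate.

    psi = (I / lI) / (I / lI + S / lS), the rMATS effective-length convention.
    """
    if inc < 0 or skip < 0:
        raise ValueError("negative junction counts")
    if inc_form_len <= 0 or skip_form_len <= 0:
        raise ValueError("form lengths must be positive")
    inc_norm = inc / inc_form_len
    skip_norm = skip / skip_form_len
    total = inc_norm + skip_norm
    if total == 0:
        return float("nan")
    return inc_norm / total


def compute_psi(
    counts: JunctionCounts, min_total_reads: int = DEFAULT_MIN_TOTAL_READS
) -> tuple[float, int]:
    """Replicate-averaged PSI for one cell.

    Replicates with ``inclusion + skipping < min_total_reads`` (or zero
    coverage, or a missing count) are uninformative and dropped.  Returns
    ``(psi, n_informative)`` with psi ``NaN`` when no replicate is informative.
    """
    if min_total_reads < 0:
        raise ValueError("min_total_reads must be >= 0")
    values = []
    for inc, skip in zip(counts.inclusion, counts.skipping):
        if inc is None or skip is None:
            continue
        total = inc + skip
        if total == 0 or total < min_total_reads:
            continue
        values.append(
            replicate_psi(inc, skip, counts.inc_form_len, counts.skip_form_len)
        )
    if not values:
        return float("nan"), 0
    return float(np.mean(values)), len(values)


def relative_inclusion(
    traj: PsiTrajectory,
    sigma_tol: float = DEFAULT_SIGMA_TOL,
    min_psi_range: float = 0.0,
    ddof: int = 0,
) -> RelativeInclusionSeries:
    """Z-score a PSI trajectory into the relative inclusion rate.

    ``sigma`` is the population SD by default (``ddof=0``); set ``ddof=1``
    for the sample SD.  Trajectories with ``sigma < sigma_tol`` or PSI
    amplitude below ``min_psi_range`` are *degenerate*: all observed z are 0
    and no switch can be called from them.

    Raises :class:`UntestableTrajectoryError` for trajectories with fewer
    than two observed timepoints; such exons are excluded downstream.
    """
    psi = np.asarray(traj.psi, dtype=float)
    observed = ~np.isnan(psi)
    if observed.sum() < 2:
        raise UntestableTrajectoryError(
            f"{traj.exon_id}/{traj.condition}: fewer than 2 informative timepoints"
        )
    mu = float(psi[observed].mean())
    sigma = float(psi[observed].std(ddof=ddof))
    amplitude = float(psi[observed].max() - psi[observed].min())
    degenerate = sigma < sigma_tol or amplitude < min_psi_range
    z = np.full_like(psi, np.nan)
    if degenerate:
        z[observed] = 0.0
    else:
        z[observed] = (psi[observed] - mu) / sigma
    return RelativeInclusionSeries(
        exon_id=traj.exon_id,
        condition=traj.condition,
        timepoints=traj.timepoints,
        z=tuple(float(v) for v in z),
        mu=mu,
        sigma=sigma,
        degenerate=degenerate,
    )


def _sign_symbols(z: Sequence[float], zero_tol: float) -> tuple[str, ...]:
    out = []
    for v in z:
        if math.isnan(v):
            out.append(".")
        elif abs(v) < zero_tol:
            out.append("0")
        else:
            out.append("+" if v > 0 else "-")
    return tuple(out)


def switching_time(
    series: RelativeInclusionSeries, zero_tol: float = DEFAULT_ZERO_TOL
) -> SwitchCall:
    """Call the switching time of a relative inclusion series.

    The switching time is the first timepoint whose (non-zero) sign is
    opposite to the last non-zero sign seen before it.  Zeros (|z| below
    ``zero_tol``) inherit the most recent non-zero sign, so a trajectory
    passing through 0 does not register a double reversal; missing
    timepoints are skipped, so a reversal is only ever called between two
    observed signs.  Degenerate series never switch.
    """
    signs = _sign_symbols(series.z, zero_tol)
    switch_index: Optional[int] = None
    direction = "none"
    n_reversals = 0
    if not series.degenerate:
        last = 0  # last non-zero sign seen, 0 = none yet
        for i, s in enumerate(signs):
            if s in (".", "0"):
                continue  # zeros inherit `last`; missing skipped
            cur = 1 if s == "+" else -1
            if last != 0 and cur != last:
                n_reversals += 1
                if switch_index is None:
                    switch_index = i
                    direction = "up" if cur > 0 else "down"
            last = cur
    return SwitchCall(
        exon_id=series.exon_id,
        condition=series.condition,
        switch_index=switch_index,
        direction=direction,
        n_reversals=n_reversals,
        signs=signs,
    )


def call_switch(
    traj: PsiTrajectory,
    sigma_tol: float = DEFAULT_SIGMA_TOL,
    zero_tol: float = DEFAULT_ZERO_TOL,
    min_psi_range: float = DEFAULT_MIN_PSI_RANGE,
    ddof: int = 0,
) -> SwitchCall:
    """Convenience: z-score a trajectory and call its switching time."""
    series = relative_inclusion(
        traj, sigma_tol=sigma_tol, min_psi_range=min_psi_range, ddof=ddof
    )
    return switching_time(series, zero_tol=zero_tol)
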