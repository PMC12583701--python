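"""PSI computation, relative-inclusion z-scoring and switch-time calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicetime.psi_core import (
    JunctionCounts,
    PsiTrajectory,
    RelativeInclusionSeries,
    SwitchCall,
    UntestableTrajectoryError,
    compute_psi,
    relative_inclusion,
    replicate_psi,
    switching_time,
)

TPS = ("DIV0", "DIV3", "DIV5", "DIV10")


def make_counts(inc, skip, li=100, ls=100):
    return JunctionCounts(
        exon_id="e1",
        timepoint="DIV0",
        condition="control",
        inclusion=tuple(inc),
        skipping=tuple(skip),
        inc_form_len=li,
        skip_form_len=ls,
    )


def make_series(z, degenerate=False):
    zs = tuple(float(v) for v in z)
    obs = [v for v in zs if not math.isnan(v)]
    return RelativeInclusionSeries(
        exon_id="e1",
        condition="control",
        timepoints=TPS[: len(zs)],
        z=zs,
        mu=float(np.mean(obs)) if obs else float("nan"),
        sigma=float(np.std(obs)) if obs else 0.0,
        degenerate=degenerate,
    )


class TestComputePsi:
    @pytest.mark.parametrize(
        "inc,skip,li,ls,expected,n_inf",
        [
            ([0], [50], 100, 100, 0.0, 1),  # no inclusion reads
            ([30], [10], 150, 50, 0.5, 1),  # length normalisation: (0.2)/(0.2+0.2)
            ([10, 0], [10, 0], 100, 100, 0.5, 1),  # zero-coverage replicate dropped
        ],
    )
    def test_examples(self, inc, skip, li, ls, expected, n_inf):
        psi, n = compute_psi(make_counts(inc, skip, li, ls), min_total_reads=1)
        assert psi == pytest.approx(expected)
        assert n == n_inf

    def test_low_coverage_replicates_are_uninformative(self):
        psi, n = compute_psi(make_counts([5, 50], [4, 50]), min_total_reads=10)
        assert n == 1 and psi == pytest.approx(0.5)
        psi, n = compute_psi(make_counts([5], [4]), min_total_reads=10)
        assert math.isnan(psi) and n == 0

    def test_missing_replicates_skipped(self):
        psi, n = compute_psi(make_counts([30, None], [30, None]), min_total_reads=1)
        assert n == 1 and psi == pytest.approx(0.5)

    def test_input_errors(self):
        with pytest.raises(ValueError):
            make_counts([-1], [5])
        with pytest.raises(ValueError):
            make_counts([1], [5], li=0)
        with pytest.raises(ValueError):
            compute_psi(make_counts([1], [1]), min_total_reads=-1)

    @given(
        inc=st.integers(0, 1000),
        skip=st.integers(0, 1000),
        li=st.integers(1, 500),
        ls=st.integers(1, 500),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_swap_symmetry(self, inc, skip, li, ls):
        """PSI lies in [0,1] and swapping inclusion<->skipping maps psi to 1-psi."""
        if inc + skip == 0:
            return
        p = replicate_psi(inc, skip, li, ls)
        q = replicate_psi(skip, inc, ls, li)
        assert 0.0 <= p <= 1.0
        assert p + q == pytest.approx(1.0)


class TestRelativeInclusion:
    def test_constant_trajectory_is_degenerate(self):
        traj = PsiTrajectory("e1", "control", TPS, (0.2, 0.2, 0.2, 0.2), (3,) * 4)
        series = relative_inclusion(traj)
        assert series.degenerate
        assert series.z == (0.0, 0.0, 0.0, 0.0)

    def test_step_trajectory_hand_values(self):
        traj = PsiTrajectory("e1", "control", TPS, (0.0, 0.0, 1.0, 1.0), (3,) * 4)
        series = relative_inclusion(traj)
        assert series.mu == pytest.approx(0.5)
        assert series.sigma == pytest.approx(0.5)  # population SD
        assert series.z == pytest.approx((-1.0, -1.0, 1.0, 1.0))

    def test_sample_sd_toggle(self):
        traj = PsiTrajectory("e1", "control", TPS, (0.0, 0.0, 1.0, 1.0), (3,) * 4)
        series = relative_inclusion(traj, ddof=1)
        assert series.sigma == pytest.approx(np.std([0, 0, 1, 1], ddof=1))

    def test_under_observed_trajectory_rejected(self):
        nan = float("nan")
        traj = PsiTrajectory("e1", "control", TPS, (0.5, nan, nan, nan), (3, 0, 0, 0))
        with pytest.raises(UntestableTrajectoryError):
            relative_inclusion(traj)

    def test_missing_timepoints_propagate(self):
        nan = float("nan")
        traj = PsiTrajectory("e1", "control", TPS, (0.0, nan, 1.0, 1.0), (3, 0, 3, 3))
        series = relative_inclusion(traj)
        assert math.isnan(series.z[1])
        observed = [series.z[0], series.z[2], series.z[3]]
        assert np.mean(observed) == pytest.approx(0.0, abs=1e-9)

    def test_amplitude_filter_marks_degenerate(self):
        traj = PsiTrajectory("e1", "control", TPS, (0.50, 0.51, 0.50, 0.52), (3,) * 4)
        assert not relative_inclusion(traj).degenerate
        assert relative_inclusion(traj, min_psi_range=0.05).degenerate

    @given(
        psi=st.lists(
            st.floats(0.0, 1.0, allow_nan=False), min_size=2, max_size=8
        )
    )
    @settings(max_examples=300, deadline=None)
    def test_normalization_identity(self, psi):
        """Non-degenerate series: mean(z)=0 and population SD(z)=1 to 1e-9."""
        traj = PsiTrajectory(
            "e1", "control", tuple(f"T{i}" for i in range(len(psi))),
            tuple(psi), (3,) * len(psi),
        )
        series = relative_inclusion(traj)
        if series.degenerate:
            return
        z = np.asarray(series.z)
        assert abs(z.mean()) < 1e-9
        assert abs(z.std() - 1.0) < 1e-9


def brute_force_switch(signs):
    """Literal reference scan: forward-fill zeros with the last non-zero
    sign, then the switch is the first position whose own non-zero sign is
    opposite to the filled sign before it."""
    filled = []
    prev = 0
    for s in signs:
        prev = s if s != 0 else prev
        filled.append(prev)
    reversals = [
        i
        for i in range(1, len(signs))
        if signs[i] != 0 and filled[i - 1] != 0 and signs[i] == -filled[i - 1]
    ]
    if not reversals:
        return None, "none", 0
    first = reversals[0]
    return first, ("up" if signs[first] > 0 else "down"), len(reversals)


class TestSwitchingTime:
    @pytest.mark.parametrize(
        "z,index,direction,n_rev",
        [
            ((-1, -1, 1, 1), 2, "up", 1),  # DIV5 up-switch
            ((1, 1, 1, 1), None, "none", 0),  # constant sign never switches
            ((-1, 1, -1, 1), 1, "up", 3),  # oscillation: first reversal wins
            ((1, 1, -1, -1), 2, "down", 1),
            ((-1, 0, 1, 1), 2, "up", 1),  # zero inherits the minus sign
            ((-1, 0, -1, 1), 3, "up", 1),  # no double reversal through zero
        ],
    )
    def test_examples(self, z, index, direction, n_rev):
        call = switching_time(make_series(z))
        assert (call.switch_index, call.direction, call.n_reversals) == (
            index,
            direction,
            n_rev,
        )

    def test_degenerate_series_never_switches(self):
        call = switching_time(make_series([0, 0, 0, 0], degenerate=True))
        assert not call.switched and call.n_reversals == 0

    def test_missing_timepoints_bridge_reversals(self):
        nan = float("nan")
        call = switching_time(make_series([-1.0, nan, 1.0, 1.0]))
        assert call.switch_index == 2 and call.direction == "up"

    def test_exhaustive_sign_sequences_match_brute_force(self):
        """All 3^4 sign sequences agree with the literal reference scan."""
        from itertools import product

        for signs in product((-1, 0, 1), repeat=4):
            call = switching_time(make_series([float(s) for s in signs]))
            idx, direction, n_rev = brute_force_switch(signs)
            assert (call.switch_index, call.direction, call.n_reversals) == (
                idx,
                direction,
                n_rev,
            ), signs

    @given(st.lists(st.sampled_from([-1, 0, 1]), min_size=2, max_size=10))
    @settings(max_examples=500, deadline=None)
    def test_property_matches_brute_force(self, signs):
        call = switching_time(make_series([float(s) for s in signs]))
        assert (call.switch_index, call.direction, call.n_reversals) == (
            brute_force_switch(signs)
        )

    @given(st.integers(0, 4), st.sampled_from([-1, 1]))
    @settings(max_examples=50, deadline=None)
    def test_monotone_trajectories_have_at_most_one_reversal(self, cut, start):
        signs = [start] * cut + [-start] * (4 - cut)
        call = switching_time(make_series([float(s) for s in signs]))
        assert call.n_reversals <= 1

    def test_call_invariants_enforced(self):
        with pytest.raises(ValueError):
            SwitchCall("e1", "control", None, "up", 1)
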