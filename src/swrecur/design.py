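"""Stepped-wedge trial geometry.

A stepped-wedge cluster randomized trial (SWCRT) starts with every cluster in
the control condition; one cluster switches to the intervention at each step
(``s = m``), so the switch times are equally spaced over the step period
``(t_S, t_E)``.  Subjects enter an open cohort at random times and may be
observed under both conditions.  This module encodes the switch schedule, the
entry-time sampler and the subject-level distances to the switch on the
total-time and gap-time scales.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EntryPolicy",
    "DesignSpec",
    "SwitchSchedule",
    "build_switch_schedule",
    "draw_entry_time",
    "switch_distance",
    "gap_switch_distance",
]


class EntryPolicy(enum.Enum):
    """How trial entry interacts with the follow-up period.

    ``NO_FOLLOWUP``
        No follow-up period (``F = 0``); entry is uniform over the step
        period, scaled by the concentration coefficient ``E``.
    ``ENTRY_UNTIL_TF``
        Follow-up period present and entry allowed until its end ``t_F``.
    ``ENTRY_UNTIL_TE``
        Follow-up period present but entry closes at the end of the last
        step period ``t_E``.
    """

    NO_FOLLOWUP = "no_followup"
    ENTRY_UNTIL_TF = "entry_until_tf"
    ENTRY_UNTIL_TE = "entry_until_te"


@dataclass(frozen=True)
class DesignSpec:
    """Geometry of one stepped-wedge trial.

    Parameters
    ----------
    m : int
        Number of clusters; equal to the number of steps (one cluster
        switches per step).
    t_S, t_E : float
        Trial start and end of the last step period, in days.
    E : float
        Entry-concentration coefficient (>= 1).  ``E = 1`` gives uniform
        entry over the whole window; larger values concentrate entry at the
        start of the trial.
    F : float
        Follow-up coefficient in units of the inter-switch distance
        ``W_d``; the trial runs until ``t_F = t_E + W_d * F``.
    entry_policy : EntryPolicy
        Entry window policy; must be ``NO_FOLLOWUP`` exactly when ``F = 0``.
    N : int
        Total number of subjects; must equal ``m * n_per_cluster``.
    n_per_cluster : int
        Subjects per cluster.
    """

    m: int
    t_S: float
    t_E: float
    E: float = 1.0
    F: float = 0.0
    entry_policy: EntryPolicy = EntryPolicy.NO_FOLLOWUP
    N: int = 2000
    n_per_cluster: int | None = None

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError(f"need at least 2 clusters, got m={self.m}")
        if not self.t_E > self.t_S:
            raise ValueError(f"t_E={self.t_E} must exceed t_S={self.t_S}")
        if self.E < 1:
            raise ValueError(f"entry coefficient E must be >= 1, got {self.E}")
        if self.F < 0:
            raise ValueError(f"follow-up coefficient F must be >= 0, got {self.F}")
        if self.n_per_cluster is None:
            n, rem = divmod(self.N, self.m)
            if rem:
                raise ValueError(
                    f"N={self.N} does not divide evenly over m={self.m} clusters"
                )
            object.__setattr__(self, "n_per_cluster", n)
        elif self.N != self.m * self.n_per_cluster:
            raise ValueError(
                f"N={self.N} != m*n_per_cluster={self.m * self.n_per_cluster}"
            )
        if (self.F == 0) != (self.entry_policy is EntryPolicy.NO_FOLLOWUP):
            raise ValueError(
                "entry_policy must be NO_FOLLOWUP exactly when F == 0 "
                f"(got F={self.F}, policy={self.entry_policy})"
            )


@dataclass(frozen=True)
class SwitchSchedule:
    """Realized switch times for one design.

    Attributes
    ----------
    W : ndarray
        Switch times ``W_i = t_S + i * W_d`` for clusters ``i = 1..m``.
    W_d : float
        Inter-switch distance ``(t_E - t_S) / (m + 1)``, kept at full
        floating precision.
    t_F : float
        End of the trial, ``t_E + W_d * F``.
    """

    W: np.ndarray
    W_d: float
    t_F: float


def build_switch_schedule(spec: DesignSpec) -> SwitchSchedule:
    """Compute the equally spaced switch times and trial end for ``spec``."""
    W_d = (spec.t_E - spec.t_S) / (spec.m + 1)
    W = spec.t_S + W_d * np.arange(1, spec.m + 1, dtype=float)
    t_F = spec.t_E + W_d * spec.F
    return SwitchSchedule(W=W, W_d=W_d, t_F=t_F)


def _entry_window_end(spec: DesignSpec, schedule: SwitchSchedule) -> float:
    if spec.entry_policy is EntryPolicy.ENTRY_UNTIL_TF:
        return schedule.t_F
    return spec.t_E


def draw_entry_time(
    spec: DesignSpec,
    schedule: SwitchSchedule,
    rng: np.random.Generator,
    size: int | None = None,
) -> float | np.ndarray:
    """Draw open-cohort entry times ``d = t_S + (t_end - t_S) * e / E``.

    ``e ~ U(0, 1)`` and ``t_end`` is ``t_F`` under ``ENTRY_UNTIL_TF`` and
    ``t_E`` otherwise, so entry lies in ``[t_S, t_S + (t_end - t_S)/E)``:
    ``E = 1`` is uniform over the whole window and ``E > 1`` concentrates
    entry at the start of the trial.
    """
    t_end = _entry_window_end(spec, schedule)
    e = rng.uniform(size=size)
    return spec.t_S + (t_end - spec.t_S) * e / spec.E


def switch_distance(W_i, d):
    """Distance from trial entry to the switch, ``w_ij = max(W_i - d, 0)``."""
    return np.maximum(np.asarray(W_i, dtype=float) - d, 0.0)


def gap_switch_distance(W_i, d, T_prev=None, k: int = 1):
    """Distance to the switch on the gap-time scale.

    For the first recurrence (``k = 1``) the gap clock starts at entry ``d``;
    for later recurrences it starts at the previous event time ``T_prev``:

    ``w_ijk = max(W_i - d, 0)``        for ``k = 1``
    ``w_ijk = max(W_i - T_prev, 0)``   for ``k >= 2``
    """
    if k < 1:
        raise ValueError(f"recurrence index k must be >= 1, got {k}")
    if k == 1:
        return switch_distance(W_i, d)
    if T_prev is None:
        raise ValueError("T_prev is required for k >= 2")
    return np.maximum(np.asarray(W_i, dtype=float) - T_prev, 0.0)
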