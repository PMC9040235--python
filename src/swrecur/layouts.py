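"""Counting-process layouts for the three extended Cox models.

Observed subject paths are converted into (start, stop] risk intervals with
a single binary time-dependent intervention indicator ``z`` that is constant
within each interval (intervals are split at the cluster's switch time).

* AG (Andersen-Gill): one continuous at-risk spell from entry to end of
  follow-up, common baseline hazard for all recurrences.
* PWP-TT (total time): same total-time axis with delayed entry; the subject
  is at risk for recurrence ``k`` only between the (k-1)th event and the
  kth, stratified by ``k``.
* PWP-GT (gap time): the clock restarts at each event; risk intervals run
  from 0 to the gap length, stratified by ``k``.

The total-time axis for AG and PWP-TT is *time since trial entry* (each
subject's clock is zeroed at its entry ``d_ij``), so the intervention
indicator switches at the subject-specific distance ``w_ij = max(W_i - d,
0)``.  This is the scale on which the indicator is defined (``z = 1`` for
``t >= w_ij``) and the only total-time scale that remains informative under
cluster stratification: on the calendar scale all subjects in a cluster
share one switch time, making the indicator deterministic given stratum and
time, so every risk set would be condition-homogeneous.

Either layout may additionally stratify by cluster (separate baseline hazard
per cluster).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import SwitchBasis, TrialData

__all__ = [
    "ModelKind",
    "LayoutPolicy",
    "INTERVAL_COLUMNS",
    "build_layout",
    "build_ag",
    "build_pwp_tt",
    "build_pwp_gt",
    "total_time_by_condition",
    "export_intervals",
    "import_intervals",
]

INTERVAL_COLUMNS = [
    "subject",
    "cluster",
    "event_index",
    "stratum",
    "start",
    "stop",
    "status",
    "z",
]

# stratum code = event_index * _STRATUM_BASE + cluster keeps integer labels
# unique for any realistic cluster count
_STRATUM_BASE = 100_000


class ModelKind(enum.Enum):
    AG = "ag"
    PWP_TT = "pwp-tt"
    PWP_GT = "pwp-gt"


@dataclass(frozen=True)
class LayoutPolicy:
    """Analysis layout: which model, and how baselines/switches are handled.

    ``switch_basis`` only affects the gap-time layout: under ``ENTRY`` (the
    default, matching the generator's default) the indicator switches at
    gap time ``w_ij``; under ``RECURRENCE`` at ``w_ijk = max(W_i -
    T_{k-1}, 0)``.  The total-time layouts switch at ``w_ij`` either way.
    """

    model: ModelKind
    stratify_by_cluster: bool = True
    switch_basis: SwitchBasis = SwitchBasis.ENTRY


def _segments(data: TrialData):
    """Per-subject calendar segments between consecutive clock origins.

    Returns flat arrays (subject, cluster, k, origin, stop, status, W) with
    one row per observed event plus one censored tail per subject whose
    follow-up extends past the last event.
    """
    obs = data.observed
    n_obs = data.n_observed
    N = len(data)
    d = data.d

    # origins for recurrence k = 1..3 are (d, T1, T2)
    origins = np.column_stack([d, obs[:, 0], obs[:, 1]])
    valid = np.arange(3)[None, :] < n_obs[:, None]
    subj_idx, k_idx = np.nonzero(valid)

    last_origin = np.where(n_obs > 0, obs[np.arange(N), np.maximum(n_obs - 1, 0)], d)
    has_tail = data.censor_time > last_origin

    subj = np.concatenate([subj_idx, np.nonzero(has_tail)[0]])
    k = np.concatenate([k_idx + 1, n_obs[has_tail] + 1])
    origin = np.concatenate([origins[subj_idx, k_idx], last_origin[has_tail]])
    stop = np.concatenate([obs[subj_idx, k_idx], data.censor_time[has_tail]])
    status = np.concatenate(
        [np.ones(subj_idx.size, dtype=int), np.zeros(int(has_tail.sum()), dtype=int)]
    )
    order = np.lexsort((k, subj))
    return subj[order], k[order], origin[order], stop[order], status[order]


def _split_at_switch(start, stop, status, switch_pt, carry):
    """Split (start, stop] rows at an interior switch point.

    ``carry`` is a dict of equal-length arrays carried through the split.
    Rows with ``start < switch_pt < stop`` become a control part
    (start, switch_pt] with status 0 and an intervention part
    (switch_pt, stop] holding the original status; otherwise ``z = 1`` iff
    ``start >= switch_pt``.
    """
    interior = (start < switch_pt) & (switch_pt < stop)
    z_whole = (start >= switch_pt).astype(int)

    def cat(a, b):
        return np.concatenate([a, b])

    pre = interior
    out = {
        "start": cat(start, start[pre]),
        "stop": cat(np.where(pre, stop, stop), switch_pt[pre]),
        "status": cat(status, np.zeros(int(pre.sum()), dtype=int)),
        "z": cat(np.where(pre, 1, z_whole), np.zeros(int(pre.sum()), dtype=int)),
    }
    # the original row of a split pair becomes the post-switch part
    out["start"] = out["start"].astype(float).copy()
    out["start"][: start.size][pre] = switch_pt[pre]
    for name, arr in carry.items():
        out[name] = cat(arr, arr[pre])
    return out


def _finalize(parts, policy: LayoutPolicy, pwp: bool) -> pd.DataFrame:
    start, stop = parts["start"], parts["stop"]
    keep = stop > start
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} zero-length risk interval(s) at boundary ties",
            stacklevel=3,
        )
    k = parts["k"]
    cluster = parts["cluster"]
    if pwp:
        stratum = k * (_STRATUM_BASE if policy.stratify_by_cluster else 1)
        if policy.stratify_by_cluster:
            stratum = stratum + cluster
    else:
        stratum = cluster if policy.stratify_by_cluster else np.zeros_like(cluster)
    df = pd.DataFrame(
        {
            "subject": parts["subject"][keep],
            "cluster": cluster[keep],
            "event_index": k[keep],
            "stratum": np.asarray(stratum)[keep],
            "start": start[keep],
            "stop": stop[keep],
            "status": parts["status"][keep],
            "z": parts["z"][keep],
        }
    )
    return df.reset_index(drop=True)


def _total_time_layout(data: TrialData, policy: LayoutPolicy, pwp: bool) -> pd.DataFrame:
    if len(data) == 0:
        raise ValueError("no subjects to lay out")
    subj, k, origin, stop, status = _segments(data)
    d = data.d[subj]
    # time-since-entry scale: switch at w_ij = W_i - d (clamped by split logic)
    parts = _split_at_switch(
        origin - d,
        stop - d,
        status,
        data.W[subj] - d,
        carry={
            "subject": data.subject_id[subj],
            "cluster": data.cluster_id[subj],
            "k": k,
        },
    )
    return _finalize(parts, policy, pwp=pwp)


def build_ag(data: TrialData, policy: LayoutPolicy | None = None) -> pd.DataFrame:
    """Andersen-Gill layout: total-time scale, continuous at-risk spell."""
    policy = policy or LayoutPolicy(ModelKind.AG)
    if policy.model is not ModelKind.AG:
        raise ValueError(f"policy.model must be AG, got {policy.model}")
    return _total_time_layout(data, policy, pwp=False)


def build_pwp_tt(data: TrialData, policy: LayoutPolicy | None = None) -> pd.DataFrame:
    """PWP total-time layout: delayed entry within total time, stratified by k."""
    policy = policy or LayoutPolicy(ModelKind.PWP_TT)
    if policy.model is not ModelKind.PWP_TT:
        raise ValueError(f"policy.model must be PWP_TT, got {policy.model}")
    return _total_time_layout(data, policy, pwp=True)


def build_pwp_gt(data: TrialData, policy: LayoutPolicy | None = None) -> pd.DataFrame:
    """PWP gap-time layout: per-recurrence clock reset, stratified by k."""
    policy = policy or LayoutPolicy(ModelKind.PWP_GT)
    if policy.model is not ModelKind.PWP_GT:
        raise ValueError(f"policy.model must be PWP_GT, got {policy.model}")
    if len(data) == 0:
        raise ValueError("no subjects to lay out")
    subj, k, origin, stop, status = _segments(data)
    gap = stop - origin
    # gap-scale switch point (clamped by the split logic: <= 0 means fully
    # post-switch, >= gap fully pre-switch)
    if policy.switch_basis is SwitchBasis.ENTRY:
        w = data.W[subj] - data.d[subj]
    else:
        w = data.W[subj] - origin
    parts = _split_at_switch(
        np.zeros_like(gap),
        gap,
        status,
        w,
        carry={
            "subject": data.subject_id[subj],
            "cluster": data.cluster_id[subj],
            "k": k,
        },
    )
    return _finalize(parts, policy, pwp=True)


_BUILDERS = {
    ModelKind.AG: build_ag,
    ModelKind.PWP_TT: build_pwp_tt,
    ModelKind.PWP_GT: build_pwp_gt,
}


def build_layout(data: TrialData, policy: LayoutPolicy) -> pd.DataFrame:
    """Dispatch to the builder for ``policy.model``."""
    return _BUILDERS[policy.model](data, policy)


def total_time_by_condition(intervals: pd.DataFrame):
    """Person-time under control and intervention, and their ratio.

    Expects an AG layout (each subject's follow-up counted once).  Returns
    ``(control_time, intervention_time, ratio)`` with ``ratio = inf`` when
    no intervention time was accrued.
    """
    lengths = intervals["stop"] - intervals["start"]
    control = float(lengths[intervals["z"] == 0].sum())
    interv = float(lengths[intervals["z"] == 1].sum())
    ratio = control / interv if interv > 0 else float("inf")
    return control, interv, ratio


def export_intervals(intervals: pd.DataFrame, path_or_buf, sep: str = "\t") -> None:
    intervals.loc[:, INTERVAL_COLUMNS].to_csv(path_or_buf, sep=sep, index=False)


def import_intervals(path_or_buf, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path_or_buf, sep=sep)
    missing = set(INTERVAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"interval table missing columns: {sorted(missing)}")
    return df.loc[:, INTERVAL_COLUMNS]
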