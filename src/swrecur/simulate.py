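"""Recurrent-event generation for stepped-wedge trials.

Events are generated by inverse-transform sampling from a piecewise hazard
that switches from the control to the intervention rate at the cluster's
switch time.  Four generation models are supported:

``POISSON``
    Exponential inter-arrival times with constant hazard ``lambda``; the
    three latent total-time durations are iid draws from entry, sorted.
``MIXED_POISSON``
    As ``POISSON`` with an extra subject-level normal random effect on the
    log-hazard (inter-individual variability).
``WEIBULL_CONSTANT``
    Sequential Weibull gap times with one (scale, shape) pair shared by all
    three recurrences; the gap clock restarts at each event.
``WEIBULL_CHANGE``
    As above but the first recurrence has its own (scale, shape), while the
    second and third share another pair.

A Weibull terminal event (e.g. death) censors the recurrent-event process
mid-trial; administrative censoring applies at the end of the trial, and at
most three recurrences are generated per subject.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import (
    DesignSpec,
    SwitchSchedule,
    build_switch_schedule,
    draw_entry_time,
    switch_distance,
)

__all__ = [
    "GenModel",
    "TerminalParam",
    "CensorCause",
    "EventGenConfig",
    "SubjectPath",
    "TrialData",
    "invert_exponential_switch",
    "invert_weibull_switch",
    "generate_subject_poisson",
    "generate_subject_weibull",
    "draw_terminal_time",
    "apply_observation_scheme",
    "simulate_trial",
]

MAX_EVENTS = 3


class GenModel(enum.Enum):
    POISSON = "poisson"
    MIXED_POISSON = "mixed_poisson"
    WEIBULL_CONSTANT = "weibull_constant"
    WEIBULL_CHANGE = "weibull_change"


class TerminalParam(enum.Enum):
    """Parameterization of the terminal-event Weibull.

    ``CUM_HAZ_POW``
        Survival ``S(t) = exp{-(lambda_c * t)^nu_c}`` (default): the scale
        enters like a rate, matching the recurrent-event hazard form, and
        yields a plausible terminal-event fraction over a one-year trial.
    ``SCALE_DENOM``
        Survival ``S(t) = exp{-(t / lambda_c)^nu_c}`` (scale in the
        denominator, the textbook density form).
    ``CUM_HAZ_LIN``
        Cumulative hazard ``lambda_c * t^nu_c``.
    """

    CUM_HAZ_POW = "cum_haz_pow"
    SCALE_DENOM = "scale_denom"
    CUM_HAZ_LIN = "cum_haz_lin"


class CensorCause(enum.IntEnum):
    ADMIN_END = 0
    TERMINAL = 1
    THIRD_EVENT = 2


class SwitchBasis(enum.Enum):
    """Clock origin for the distance to the intervention switch.

    ``ENTRY`` (default)
        The switch distance is ``w_ij = max(W_i - d, 0)`` on every segment's
        own clock: the Weibull gap thresholds and the gap-scale analysis
        split both sit at ``w_ij``.  This basis reproduces the published
        operating characteristics of the study the parameters come from.
    ``RECURRENCE``
        The switch distance is re-measured from each gap's origin,
        ``w_ijk = max(W_i - T_{k-1}, 0)``, which keeps the intervention
        switch calendar-aligned at ``W_i`` for every recurrence.
    """

    ENTRY = "entry"
    RECURRENCE = "recurrence"


@dataclass(frozen=True)
class EventGenConfig:
    """Hazard parameters for one generation model.

    ``lambda_k``/``nu_k`` are per-recurrence Weibull scale (units
    1/days^nu) and shape parameters; for the exponential models all shapes
    are 1 and a single rate is used.  ``sigma2_cluster`` and
    ``sigma2_subject`` are the variances of the normal random effects on the
    log hazard at the cluster and subject level.  ``beta_t`` is the true
    intervention log-hazard-ratio and ``lp_offset`` a fixed extra linear
    predictor (0 in all study settings).  ``lambda_c``/``nu_c`` parameterize
    the terminal-event Weibull per ``terminal_parameterization``.

    ``sigma2_subject`` carries the study's printed subject-heterogeneity
    parameter (0.3455); with ``subject_effect_is_sd`` (the default) that
    value is used as the standard deviation of ``tau_j``, matching the
    source's verbal description, and the variance reading is available by
    clearing the flag.  ``switch_basis`` selects how the distance to the
    switch is measured for the second and third recurrences (see
    :class:`SwitchBasis`).
    """

    model: GenModel
    lambda_k: tuple[float, float, float]
    nu_k: tuple[float, float, float] = (1.0, 1.0, 1.0)
    sigma2_cluster: float = 0.0
    sigma2_subject: float = 0.0
    beta_t: float = 0.0
    lp_offset: float = 0.0
    lambda_c: float = 0.003674
    nu_c: float = 1.7191
    terminal_parameterization: TerminalParam = TerminalParam.CUM_HAZ_POW
    subject_effect_is_sd: bool = True
    switch_basis: SwitchBasis = SwitchBasis.ENTRY
    max_events: int = MAX_EVENTS

    def __post_init__(self) -> None:
        if len(self.lambda_k) != 3 or len(self.nu_k) != 3:
            raise ValueError("lambda_k and nu_k must each have 3 entries")
        if any(l <= 0 for l in self.lambda_k) or any(n <= 0 for n in self.nu_k):
            raise ValueError("all lambda_k and nu_k must be positive")
        if self.lambda_c <= 0 or self.nu_c <= 0:
            raise ValueError("terminal-event parameters must be positive")
        if self.sigma2_cluster < 0 or self.sigma2_subject < 0:
            raise ValueError("random-effect variances must be non-negative")
        if self.max_events != MAX_EVENTS:
            raise ValueError(f"max_events is fixed at {MAX_EVENTS}")
        if self.model in (GenModel.POISSON, GenModel.MIXED_POISSON):
            if any(n != 1.0 for n in self.nu_k):
                raise ValueError("exponential models require nu_k == 1")
            if len(set(self.lambda_k)) != 1:
                raise ValueError("exponential models use a single rate")
        if self.model is GenModel.POISSON and self.sigma2_subject != 0:
            raise ValueError("POISSON has no subject random effect")
        if self.model is GenModel.MIXED_POISSON and self.sigma2_subject <= 0:
            raise ValueError("MIXED_POISSON requires sigma2_subject > 0")
        if self.model is GenModel.WEIBULL_CONSTANT:
            if len(set(self.lambda_k)) != 1 or len(set(self.nu_k)) != 1:
                raise ValueError("WEIBULL_CONSTANT requires common (lambda, nu)")
        if self.model is GenModel.WEIBULL_CHANGE:
            if self.lambda_k[1] != self.lambda_k[2] or self.nu_k[1] != self.nu_k[2]:
                raise ValueError(
                    "WEIBULL_CHANGE requires lambda_2 == lambda_3, nu_2 == nu_3"
                )

    @property
    def subject_sd(self) -> float:
        """Standard deviation of the subject random effect tau_j."""
        if self.subject_effect_is_sd:
            return self.sigma2_subject
        return float(np.sqrt(self.sigma2_subject))

    # -- study-setting constructors (parameters fitted to the motivating
    #    palliative-care trial's hospitalisation and death times) ----------
    @classmethod
    def poisson(cls, beta_t: float = 0.0, lam: float = 0.003281, **kw) -> "EventGenConfig":
        return cls(GenModel.POISSON, (lam,) * 3, beta_t=beta_t, **kw)

    @classmethod
    def mixed_poisson(
        cls,
        beta_t: float = 0.0,
        lam: float = 0.003281,
        sigma2_subject: float = 0.3455,
        **kw,
    ) -> "EventGenConfig":
        return cls(
            GenModel.MIXED_POISSON,
            (lam,) * 3,
            beta_t=beta_t,
            sigma2_subject=sigma2_subject,
            **kw,
        )

    @classmethod
    def weibull_constant(
        cls, beta_t: float = 0.0, lam: float = 0.004703, nu: float = 1.1219, **kw
    ) -> "EventGenConfig":
        return cls(GenModel.WEIBULL_CONSTANT, (lam,) * 3, (nu,) * 3, beta_t=beta_t, **kw)

    @classmethod
    def weibull_change(
        cls,
        beta_t: float = 0.0,
        lam1: float = 0.003599,
        lam23: float = 0.009910,
        nu1: float = 1.5122,
        nu23: float = 0.9108,
        **kw,
    ) -> "EventGenConfig":
        return cls(
            GenModel.WEIBULL_CHANGE,
            (lam1, lam23, lam23),
            (nu1, nu23, nu23),
            beta_t=beta_t,
            **kw,
        )

    def with_(self, **kw) -> "EventGenConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class SubjectPath:
    """One subject's latent and observed event history (calendar time)."""

    cluster_id: int
    subject_id: int
    d: float
    tau_i: float
    tau_j: float
    latent_times: tuple[float, ...]
    terminal_time: float
    observed_events: tuple[float, ...]
    censor_time: float
    censor_cause: CensorCause


@dataclass
class TrialData:
    """Columnar container for one simulated trial.

    Arrays are aligned per subject; ``latent`` and ``observed`` hold the
    (up to) three calendar event times, with NaN padding for unobserved
    slots in ``observed``.
    """

    design: DesignSpec
    schedule: SwitchSchedule
    cluster_id: np.ndarray
    subject_id: np.ndarray
    d: np.ndarray
    tau_i: np.ndarray
    tau_j: np.ndarray
    W: np.ndarray  # per-subject switch time of own cluster
    latent: np.ndarray  # (N, 3) calendar latent event times
    terminal: np.ndarray  # (N,) calendar terminal-event time
    n_observed: np.ndarray  # (N,) int, 0..3
    censor_time: np.ndarray
    censor_cause: np.ndarray  # (N,) int (CensorCause values)

    @property
    def trial_end(self) -> float:
        return self.schedule.t_F

    @property
    def observed(self) -> np.ndarray:
        """(N, 3) observed event times with NaN beyond ``n_observed``."""
        obs = self.latent.copy()
        obs[np.arange(3) >= self.n_observed[:, None]] = np.nan
        return obs

    def __len__(self) -> int:
        return self.d.size

    def __iter__(self):
        obs = self.observed
        for i in range(len(self)):
            k = int(self.n_observed[i])
            yield SubjectPath(
                cluster_id=int(self.cluster_id[i]),
                subject_id=int(self.subject_id[i]),
                d=float(self.d[i]),
                tau_i=float(self.tau_i[i]),
                tau_j=float(self.tau_j[i]),
                latent_times=tuple(self.latent[i]),
                terminal_time=float(self.terminal[i]),
                observed_events=tuple(obs[i, :k]),
                censor_time=float(self.censor_time[i]),
                censor_cause=CensorCause(int(self.censor_cause[i])),
            )

    # -- long-format export / import --------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per observed event plus one censoring row."""
        rows = []
        obs = self.observed
        for i in range(len(self)):
            base = dict(
                cluster=int(self.cluster_id[i]),
                subject=int(self.subject_id[i]),
                entry_time=float(self.d[i]),
            )
            for k in range(int(self.n_observed[i])):
                rows.append(
                    base
                    | dict(
                        event_index=k + 1,
                        calendar_time=float(obs[i, k]),
                        status=1,
                        terminal_flag=0,
                    )
                )
            # three observed events end follow-up at the third event itself;
            # only earlier exits get an explicit censoring record
            if self.censor_cause[i] != CensorCause.THIRD_EVENT:
                rows.append(
                    base
                    | dict(
                        event_index=int(self.n_observed[i]) + 1,
                        calendar_time=float(self.censor_time[i]),
                        status=0,
                        terminal_flag=int(
                            self.censor_cause[i] == CensorCause.TERMINAL
                        ),
                    )
                )
        return pd.DataFrame(
            rows,
            columns=[
                "cluster",
                "subject",
                "entry_time",
                "event_index",
                "calendar_time",
                "status",
                "terminal_flag",
            ],
        )

    def export(self, path_or_buf, sep: str = "\t") -> None:
        self.to_frame().to_csv(path_or_buf, sep=sep, index=False)


def import_records(path_or_buf, design: DesignSpec, sep: str = "\t") -> TrialData:
    """Re-import a long-format event-history table written by ``export``.

    Latent times and random effects are not recoverable from observed
    records; the returned object carries NaN for them but supports all
    layout building and fitting.
    """
    df = pd.read_csv(path_or_buf, sep=sep)
    schedule = build_switch_schedule(design)
    groups = df.groupby("subject", sort=True)
    n = groups.ngroups
    cluster = np.empty(n, dtype=int)
    subject = np.empty(n, dtype=int)
    d = np.empty(n)
    latent = np.full((n, 3), np.nan)
    n_obs = np.zeros(n, dtype=int)
    censor_time = np.empty(n)
    cause = np.empty(n, dtype=int)
    for i, (sid, g) in enumerate(groups):
        subject[i] = sid
        cluster[i] = g["cluster"].iloc[0]
        d[i] = g["entry_time"].iloc[0]
        ev = g.loc[g["status"] == 1, "calendar_time"].to_numpy()
        ev = np.sort(ev)[:3]
        n_obs[i] = ev.size
        latent[i, : ev.size] = ev
        cens = g.loc[g["status"] == 0]
        if len(cens):
            censor_time[i] = cens["calendar_time"].iloc[0]
            cause[i] = (
                CensorCause.TERMINAL
                if cens["terminal_flag"].iloc[0]
                else CensorCause.ADMIN_END
            )
        else:  # three events observed: follow-up ends at the third event
            censor_time[i] = ev[-1]
            cause[i] = CensorCause.THIRD_EVENT
    return TrialData(
        design=design,
        schedule=schedule,
        cluster_id=cluster,
        subject_id=subject,
        d=d,
        tau_i=np.full(n, np.nan),
        tau_j=np.full(n, np.nan),
        W=schedule.W[cluster - 1],
        latent=latent,
        terminal=np.full(n, np.nan),
        n_observed=n_obs,
        censor_time=censor_time,
        censor_cause=cause,
    )


# ---------------------------------------------------------------------------
# inverse-transform samplers with the piecewise (control -> intervention)
# hazard switch
# ---------------------------------------------------------------------------

def _check_u(u) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("uniform draws must lie strictly inside (0, 1)")
    return u


def invert_exponential_switch(u, rate0, rate1, w):
    """Invert the piecewise-exponential cumulative hazard at ``-log(u)``.

    The hazard is ``rate0`` for the first ``w`` time units (control) and
    ``rate1`` thereafter (intervention):

    ``T* = -log(u)/rate0``                                if ``-log(u) < rate0*w``
    ``T* = (-log(u) - rate0*w + rate1*w)/rate1``          otherwise
    """
    u = _check_u(u)
    neg = -np.log(u)
    rate0 = np.asarray(rate0, dtype=float)
    rate1 = np.asarray(rate1, dtype=float)
    w = np.asarray(w, dtype=float)
    pre = neg < rate0 * w
    return np.where(pre, neg / rate0, (neg - rate0 * w + rate1 * w) / rate1)


def invert_weibull_switch(u, lam, nu, eta, beta_t, w):
    """Invert the piecewise-Weibull cumulative hazard at ``-log(u)``.

    The baseline hazard is ``lam * nu * t^(nu-1)`` scaled by ``eta =
    exp(beta'x + tau_i)`` before the switch (gap distance ``w``) and by an
    extra ``exp(beta_t)`` after it:

    ``T* = (-log(u)/(lam*eta))^(1/nu)``                   if ``-log(u) < lam*eta*w^nu``
    ``T* = ((-log(u) - lam*eta*w^nu + lam*e^bt*eta*w^nu) / (lam*e^bt*eta))^(1/nu)``
                                                          otherwise
    """
    u = _check_u(u)
    neg = -np.log(u)
    lam = np.asarray(lam, dtype=float)
    eta = np.asarray(eta, dtype=float)
    w = np.asarray(w, dtype=float)
    scale0 = lam * eta
    scale1 = scale0 * np.exp(beta_t)
    wnu = w**nu
    pre = neg < scale0 * wnu
    inner = np.where(pre, neg / scale0, (neg - scale0 * wnu + scale1 * wnu) / scale1)
    return inner ** (1.0 / nu)


def generate_subject_poisson(config, d, W_i, tau_i, tau_j, rng):
    """Three latent calendar event times under the (mixed-)Poisson model.

    Three iid uniforms are inverted through the piecewise-exponential
    transform with the common total-time switch distance ``w_ij``; the
    resulting durations are sorted ascending so calendar times increase.
    """
    rate0 = config.lambda_k[0] * np.exp(config.lp_offset + tau_i + tau_j)
    rate1 = rate0 * np.exp(config.beta_t)
    w = switch_distance(W_i, d)
    u = rng.uniform(size=3)
    durations = np.sort(invert_exponential_switch(u, rate0, rate1, w))
    return d + durations


def generate_subject_weibull(config, d, W_i, tau_i, rng):
    """Three latent calendar event times under the Weibull gap-time models.

    Gaps are drawn sequentially with per-recurrence (lambda_k, nu_k).  Under
    the default ENTRY switch basis every gap's hazard switches at the
    entry-measured distance ``w_ij``; under RECURRENCE the distance is
    re-measured from the gap's own origin (the previous event).
    """
    eta = np.exp(config.lp_offset + tau_i)
    times = np.empty(3)
    origin = d
    w_entry = max(W_i - d, 0.0)
    for k in range(3):
        if config.switch_basis is SwitchBasis.ENTRY:
            w = w_entry
        else:
            w = max(W_i - origin, 0.0)
        u = rng.uniform()
        gap = invert_weibull_switch(
            u, config.lambda_k[k], config.nu_k[k], eta, config.beta_t, w
        )
        origin = origin + float(gap)
        times[k] = origin
    return times


def terminal_survival(config: EventGenConfig, t):
    """Analytic survival function of the terminal-event duration."""
    t = np.asarray(t, dtype=float)
    if config.terminal_parameterization is TerminalParam.CUM_HAZ_POW:
        return np.exp(-((config.lambda_c * t) ** config.nu_c))
    if config.terminal_parameterization is TerminalParam.SCALE_DENOM:
        return np.exp(-((t / config.lambda_c) ** config.nu_c))
    return np.exp(-config.lambda_c * t**config.nu_c)


def _terminal_durations(config: EventGenConfig, u: np.ndarray) -> np.ndarray:
    neg = -np.log(u)
    if config.terminal_parameterization is TerminalParam.CUM_HAZ_POW:
        return neg ** (1.0 / config.nu_c) / config.lambda_c
    if config.terminal_parameterization is TerminalParam.SCALE_DENOM:
        return config.lambda_c * neg ** (1.0 / config.nu_c)
    return (neg / config.lambda_c) ** (1.0 / config.nu_c)


def draw_terminal_time(config, d, rng, size=None):
    """Calendar terminal-event time ``C = d + C*`` (independent of events)."""
    u = rng.uniform(size=size)
    return d + _terminal_durations(config, np.asarray(u, dtype=float))


def apply_observation_scheme(latent, terminal, censor_out, cause_out, trial_end):
    """Vectorized observation scheme (in-place outputs).

    The observation horizon is ``H = min(C, trial_end)``; latent events at
    or before H are observed (at most three).  A subject with all three
    events observed ends follow-up at the third event; otherwise follow-up
    is censored at H, by the terminal event if it precedes the trial end and
    administratively otherwise.  Returns the per-subject observed count.
    """
    horizon = np.minimum(terminal, trial_end)
    n_obs = (latent <= horizon[:, None]).sum(axis=1)
    third = n_obs == 3
    censor_out[:] = np.where(third, latent[:, 2], horizon)
    cause_out[:] = np.where(
        third,
        CensorCause.THIRD_EVENT,
        np.where(terminal < trial_end, CensorCause.TERMINAL, CensorCause.ADMIN_END),
    )
    return n_obs


def observe_path(path: SubjectPath, trial_end: float) -> SubjectPath:
    """Single-subject observation scheme (object form of the vectorized rule)."""
    latent = np.asarray(path.latent_times)[None, :]
    terminal = np.asarray([path.terminal_time])
    censor = np.empty(1)
    cause = np.empty(1, dtype=int)
    n_obs = apply_observation_scheme(latent, terminal, censor, cause, trial_end)
    k = int(n_obs[0])
    return replace(
        path,
        observed_events=tuple(path.latent_times[:k]),
        censor_time=float(censor[0]),
        censor_cause=CensorCause(int(cause[0])),
    )


def simulate_trial(
    design: DesignSpec, config: EventGenConfig, seed
) -> TrialData:
    """Simulate one complete stepped-wedge trial.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``/Generator.
    Cluster random effects are drawn once per cluster, subject effects once
    per subject (mixed-Poisson only); the result is deterministic given the
    seed.
    """
    rng = np.random.default_rng(seed)
    schedule = build_switch_schedule(design)
    m, n = design.m, design.n_per_cluster
    N = design.N

    cluster = np.repeat(np.arange(1, m + 1), n)
    subject = np.arange(1, N + 1)
    sd_c = float(np.sqrt(config.sigma2_cluster))
    tau_i_cluster = rng.normal(0.0, sd_c, size=m) if sd_c > 0 else np.zeros(m)
    tau_i = tau_i_cluster[cluster - 1]

    d = np.asarray(draw_entry_time(design, schedule, rng, size=N))
    W = schedule.W[cluster - 1]

    exponential = config.model in (GenModel.POISSON, GenModel.MIXED_POISSON)
    if config.model is GenModel.MIXED_POISSON:
        tau_j = rng.normal(0.0, config.subject_sd, size=N)
    else:
        tau_j = np.zeros(N)

    if exponential:
        rate0 = config.lambda_k[0] * np.exp(config.lp_offset + tau_i + tau_j)
        rate1 = rate0 * np.exp(config.beta_t)
        w = switch_distance(W, d)
        u = rng.uniform(size=(N, 3))
        durations = invert_exponential_switch(
            u, rate0[:, None], rate1[:, None], w[:, None]
        )
        latent = d[:, None] + np.sort(durations, axis=1)
    else:
        eta = np.exp(config.lp_offset + tau_i)
        latent = np.empty((N, 3))
        origin = d.copy()
        w_entry = switch_distance(W, d)
        for k in range(3):
            if config.switch_basis is SwitchBasis.ENTRY:
                w = w_entry
            else:
                w = np.maximum(W - origin, 0.0)
            u = rng.uniform(size=N)
            gap = invert_weibull_switch(
                u, config.lambda_k[k], config.nu_k[k], eta, config.beta_t, w
            )
            origin = origin + gap
            latent[:, k] = origin

    terminal = np.asarray(draw_terminal_time(config, d, rng, size=N))
    censor_time = np.empty(N)
    cause = np.empty(N, dtype=int)
    n_obs = apply_observation_scheme(latent, terminal, censor_time, cause, schedule.t_F)

    return TrialData(
        design=design,
        schedule=schedule,
        cluster_id=cluster,
        subject_id=subject,
        d=d,
        tau_i=tau_i,
        tau_j=tau_j,
        W=W,
        latent=latent,
        terminal=terminal,
        n_observed=n_obs,
        censor_time=censor_time,
        censor_cause=cause,
    )
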