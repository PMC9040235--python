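import numpy as np
import pytest

from swrecur import (
    CensorCause,
    DesignSpec,
    EventGenConfig,
    TrialData,
    build_switch_schedule,
)


@pytest.fixture
def reference_design() -> DesignSpec:
    """The study's reference geometry: 5 clusters, 360-day step period."""
    return DesignSpec(m=5, t_S=0.0, t_E=360.0, N=2000)


@pytest.fixture
def small_design() -> DesignSpec:
    return DesignSpec(m=5, t_S=0.0, t_E=360.0, N=250)


def make_trial(design, subjects):
    """Build a TrialData from explicit subject tuples.

    Each subject is (cluster_id, d, events, censor_time, cause); latent
    slots beyond the observed events are padded past the trial end.
    """
    schedule = build_switch_schedule(design)
    n = len(subjects)
    cluster = np.array([s[0] for s in subjects])
    d = np.array([float(s[1]) for s in subjects])
    latent = np.full((n, 3), schedule.t_F + 1e6)
    n_obs = np.zeros(n, dtype=int)
    censor = np.array([float(s[3]) for s in subjects])
    cause = np.array([int(s[4]) for s in subjects])
    for i, (_, _, events, _, _) in enumerate(subjects):
        events = list(events)
        n_obs[i] = len(events)
        latent[i, : len(events)] = events
    return TrialData(
        design=design,
        schedule=schedule,
        cluster_id=cluster,
        subject_id=np.arange(1, n + 1),
        d=d,
        tau_i=np.zeros(n),
        tau_j=np.zeros(n),
        W=schedule.W[cluster - 1],
        latent=latent,
        terminal=np.where(cause == CensorCause.TERMINAL, censor, schedule.t_F + 1e6),
        n_observed=n_obs,
        censor_time=censor,
        censor_cause=cause,
    )


@pytest.fixture
def worked_path(reference_design):
    """One subject in cluster 1 (W=60): entry 40, events at 50 and 100,
    follow-up ends at 120."""
    return make_trial(
        reference_design, [(1, 40.0, (50.0, 100.0), 120.0, CensorCause.TERMINAL)]
    )


@pytest.fixture
def poisson_config() -> EventGenConfig:
    return EventGenConfig.poisson(beta_t=-0.264)
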