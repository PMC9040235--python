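"""Stratified Cox partial likelihood for a single binary time-dependent
covariate on counting-process intervals.

The engine exploits that the intervention indicator takes only the values
0/1: the Breslow risk-set sum at an event time ``t`` in stratum ``g`` is
``S0(t) = n0(t) + exp(beta) * n1(t)`` where ``n0``/``n1`` count at-risk
intervals (``start < t <= stop``) by covariate value.  The counts are
precomputed once by binary search, after which every Newton step is O(events)
and the fit of a 2000-subject trial takes milliseconds.

Variances: the model-based SE is the inverse observed information at the
maximum; the robust SE is the subject-clustered sandwich built from summed
score residuals, the standard choice for recurrent-event Cox models where
within-subject event times are correlated.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FailureReason",
    "FitResult",
    "partial_loglik",
    "fit",
    "wald_ci",
]

Z975 = 1.96
SCORE_TOL = 1e-9
STEP_TOL = 1e-10
MAX_ITER = 50
# monotone likelihoods push the estimate off to infinity while the score
# decays to zero, so a converged fit beyond this bound is flagged as
# separation (|log HR| = 15 is a hazard ratio above 3e6)
BETA_BOUND = 15.0


class FailureReason(enum.Enum):
    NONE = "none"
    SEPARATION = "separation"
    NO_EVENTS = "no_events"
    NO_VARIATION = "no_variation"
    MAX_ITER = "max_iter"


@dataclass(frozen=True)
class FitResult:
    beta_hat: float
    se_model: float
    se_robust: float
    hr: float
    ci_low: float
    ci_high: float
    loglik: float
    n_events: int
    iterations: int
    converged: bool
    failure_reason: FailureReason = FailureReason.NONE

    def to_row(self) -> dict:
        return {
            "beta_hat": self.beta_hat,
            "se_model": self.se_model,
            "se_robust": self.se_robust,
            "hr": self.hr,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "loglik": self.loglik,
            "n_events": self.n_events,
            "iterations": self.iterations,
            "converged": self.converged,
            "failure_reason": self.failure_reason.value,
        }


def wald_ci(beta_hat: float, se: float, z: float = Z975):
    """95% Wald confidence interval on the hazard-ratio scale."""
    if se <= 0:
        raise ValueError(f"standard error must be positive, got {se}")
    return float(np.exp(beta_hat - z * se)), float(np.exp(beta_hat + z * se))


class _PartialLikelihood:
    """Precomputed event-level risk counts for one interval table."""

    def __init__(self, intervals: pd.DataFrame):
        start = intervals["start"].to_numpy(dtype=float)
        stop = intervals["stop"].to_numpy(dtype=float)
        status = intervals["status"].to_numpy(dtype=int)
        z = intervals["z"].to_numpy(dtype=int)
        stratum = intervals["stratum"].to_numpy()
        if np.any(start >= stop):
            raise ValueError("intervals must satisfy start < stop")
        if not np.isin(z, (0, 1)).all() or not np.isin(status, (0, 1)).all():
            raise ValueError("z and status must be 0/1")

        self.start, self.stop, self.status, self.z = start, stop, status, z
        self.n_events = int(status.sum())
        self.subject = intervals["subject"].to_numpy()

        # per-event: covariate value and at-risk counts by covariate group
        ev_z: list[np.ndarray] = []
        ev_n0: list[np.ndarray] = []
        ev_n1: list[np.ndarray] = []
        ev_row: list[np.ndarray] = []  # interval row index of the event
        # per-stratum descriptors for the residual pass
        self._strata: list[dict] = []

        _, inv = np.unique(stratum, return_inverse=True)
        order = np.argsort(inv, kind="stable")
        bounds = np.searchsorted(inv[order], np.arange(inv.max() + 1 if inv.size else 0))
        bounds = np.append(bounds, inv.size)
        for g in range(len(bounds) - 1):
            rows = order[bounds[g] : bounds[g + 1]]
            s, e, st, zz = start[rows], stop[rows], status[rows], z[rows]
            ev = st == 1
            t_e = e[ev]
            if t_e.size == 0:
                self._strata.append(None)
                continue
            starts_by = [np.sort(s[zz == v]) for v in (0, 1)]
            stops_by = [np.sort(e[zz == v]) for v in (0, 1)]
            # at risk at t: start < t and stop >= t
            n0 = np.searchsorted(starts_by[0], t_e, side="left") - np.searchsorted(
                stops_by[0], t_e, side="left"
            )
            n1 = np.searchsorted(starts_by[1], t_e, side="left") - np.searchsorted(
                stops_by[1], t_e, side="left"
            )
            ev_z.append(zz[ev])
            ev_n0.append(n0.astype(float))
            ev_n1.append(n1.astype(float))
            ev_row.append(rows[ev])
            t_order = np.argsort(t_e, kind="stable")
            self._strata.append(
                {
                    "rows": rows,
                    "t_sorted": t_e[t_order],
                    "ev_pos": np.arange(t_e.size)[t_order],  # into stratum events
                    "offset": sum(a.size for a in ev_z[:-1]),
                }
            )
        if ev_z:
            self.ev_z = np.concatenate(ev_z).astype(float)
            self.ev_n0 = np.concatenate(ev_n0)
            self.ev_n1 = np.concatenate(ev_n1)
            self.ev_row = np.concatenate(ev_row)
        else:
            self.ev_z = self.ev_n0 = self.ev_n1 = np.empty(0)
            self.ev_row = np.empty(0, dtype=int)

    def loglik_score_info(self, beta: float):
        eb = np.exp(beta)
        s0 = self.ev_n0 + eb * self.ev_n1
        zbar = eb * self.ev_n1 / s0
        loglik = float(np.sum(self.ev_z * beta - np.log(s0)))
        score = float(np.sum(self.ev_z - zbar))
        info = float(np.sum(zbar * (1.0 - zbar)))
        return loglik, score, info

    def robust_variance(self, beta: float, info: float) -> float:
        """Subject-clustered sandwich variance at ``beta``."""
        eb = np.exp(beta)
        s0 = self.ev_n0 + eb * self.ev_n1
        zbar = eb * self.ev_n1 / s0
        a = 1.0 / s0  # per-event 1/S0
        b = zbar / s0  # per-event zbar/S0

        resid = np.zeros(self.start.size)
        # event-side term: z_event - zbar(t_event)
        resid[self.ev_row] += self.ev_z - zbar
        # expected-side term: sum over events while at risk
        for g, desc in enumerate(self._strata):
            if desc is None:
                continue
            rows = desc["rows"]
            off = desc["offset"]
            t_sorted = desc["t_sorted"]
            a_g = a[off : off + t_sorted.size][desc["ev_pos"]]
            b_g = b[off : off + t_sorted.size][desc["ev_pos"]]
            prefA = np.concatenate([[0.0], np.cumsum(a_g)])
            prefB = np.concatenate([[0.0], np.cumsum(b_g)])
            lo = np.searchsorted(t_sorted, self.start[rows], side="right")
            hi = np.searchsorted(t_sorted, self.stop[rows], side="right")
            sumA = prefA[hi] - prefA[lo]
            sumB = prefB[hi] - prefB[lo]
            zr = self.z[rows]
            resid[rows] -= np.exp(beta * zr) * (zr * sumA - sumB)

        _, subj_inv = np.unique(self.subject, return_inverse=True)
        u_subject = np.bincount(subj_inv, weights=resid)
        return float(np.sum(u_subject**2)) / info**2


def partial_loglik(intervals: pd.DataFrame, beta: float):
    """Breslow partial log-likelihood, score and information at ``beta``.

    Each event at time ``t`` in stratum ``g`` contributes
    ``z_event * beta - log(sum_{risk set} exp(z * beta))`` with risk set
    ``{start < t <= stop}`` within the stratum.
    """
    pl = _PartialLikelihood(intervals)
    if pl.n_events == 0:
        raise ValueError("no events in interval table")
    return pl.loglik_score_info(beta)


def _failed(reason: FailureReason, n_events: int, loglik: float = np.nan) -> FitResult:
    return FitResult(
        beta_hat=np.nan,
        se_model=np.nan,
        se_robust=np.nan,
        hr=np.nan,
        ci_low=np.nan,
        ci_high=np.nan,
        loglik=loglik,
        n_events=n_events,
        iterations=0,
        converged=False,
        failure_reason=reason,
    )


def fit(intervals: pd.DataFrame, ci_se: str = "model") -> FitResult:
    """Newton-Raphson fit of the single intervention coefficient.

    Starts from ``beta = 0`` with step-halving; convergence requires the
    score magnitude below 1e-9 or a step below 1e-10.  Failure modes:
    ``NO_EVENTS`` (no status=1 rows), ``NO_VARIATION`` (the covariate does
    not vary within any informative risk set, including the degenerate
    one-subject-per-stratum case), ``SEPARATION`` (monotone likelihood) and
    ``MAX_ITER``.

    Both the model-based SE (inverse information) and the subject-clustered
    robust sandwich SE are returned.  ``ci_se`` selects which one feeds the
    95% Wald interval: ``"model"`` (default; the interval behind the
    coverage probabilities this package reproduces) or ``"robust"``.
    """
    if ci_se not in ("model", "robust"):
        raise ValueError(f"ci_se must be 'model' or 'robust', got {ci_se!r}")
    pl = _PartialLikelihood(intervals)
    if pl.n_events == 0:
        return _failed(FailureReason.NO_EVENTS, 0)

    beta = 0.0
    loglik, score, info = pl.loglik_score_info(beta)
    if info <= 0.0:
        return _failed(FailureReason.NO_VARIATION, pl.n_events, loglik)

    iterations = 0
    converged = False
    for iterations in range(1, MAX_ITER + 1):
        if abs(score) < SCORE_TOL:
            converged = True
            break
        step = score / info
        new_beta = beta + step
        new_ll, new_score, new_info = pl.loglik_score_info(new_beta)
        halvings = 0
        while new_ll < loglik and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = pl.loglik_score_info(new_beta)
            halvings += 1
        if abs(new_beta) > BETA_BOUND and new_ll >= loglik:
            return _failed(FailureReason.SEPARATION, pl.n_events, new_ll)
        delta = new_beta - beta
        beta, loglik, score, info = new_beta, new_ll, new_score, new_info
        if info <= 0.0:
            return _failed(FailureReason.NO_VARIATION, pl.n_events, loglik)
        if abs(delta) < STEP_TOL:
            converged = True
            break
    if not converged and abs(score) >= SCORE_TOL:
        return _failed(FailureReason.MAX_ITER, pl.n_events, loglik)
    if abs(beta) > BETA_BOUND:
        return _failed(FailureReason.SEPARATION, pl.n_events, loglik)

    se_model = float(1.0 / np.sqrt(info))
    se_robust = float(np.sqrt(pl.robust_variance(beta, info)))
    ci_low, ci_high = wald_ci(beta, se_model if ci_se == "model" else se_robust)
    return FitResult(
        beta_hat=float(beta),
        se_model=se_model,
        se_robust=se_robust,
        hr=float(np.exp(beta)),
        ci_low=ci_low,
        ci_high=ci_high,
        loglik=float(loglik),
        n_events=pl.n_events,
        iterations=iterations,
        converged=True,
        failure_reason=FailureReason.NONE,
    )
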