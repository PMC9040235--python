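"""Replicated simulation-plus-fit experiments and their summaries.

A scenario couples one trial design with one event-generation configuration
and a set of analysis layouts (AG / PWP-TT / PWP-GT, with or without cluster
stratification).  ``run_scenario`` simulates R independent trials, fits every
layout to each, and ``summarize`` reduces the per-replicate estimates to the
Monte-Carlo operating characteristics:

* bias = mean(beta_hat) - beta_t  (positive = effect underestimated for a
  protective beta_t < 0),
* MSE = bias^2 + Var(beta_hat)  (population variance over replicates),
* CP = fraction of replicates whose 95% robust-SE Wald interval for the
  hazard ratio contains exp(beta_t).

``preset_scenarios`` builds the full factorial of the six study scenarios
(number of steps, cluster heterogeneity, follow-up period x entry policy,
entry concentration) around the reference setting t_S=0, t_E=360 days,
N=2000, m=5, sigma^2=0, E=1, F=0.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .cox import fit
from .design import DesignSpec, EntryPolicy
from .layouts import LayoutPolicy, ModelKind, build_ag, build_layout, total_time_by_condition
from .simulate import (
    CensorCause,
    EventGenConfig,
    GenModel,
    SwitchBasis,
    TerminalParam,
    simulate_trial,
)

__all__ = [
    "ScenarioSpec",
    "ScenarioSummary",
    "default_layouts",
    "run_scenario",
    "summarize",
    "preset_scenarios",
    "reference_scenario",
    "scenario_to_yaml",
    "scenario_from_yaml",
    "run_manifest",
]

BETA_EFFECT = -0.264  # ln(4.3 / 5.6): fitted hospitalisation-rate ratio
REFERENCE_DESIGN = dict(m=5, t_S=0.0, t_E=360.0, N=2000)

RESULT_COLUMNS = [
    "replicate",
    "model",
    "stratified",
    "beta_hat",
    "se_model",
    "se_robust",
    "hr",
    "ci_low",
    "ci_high",
    "loglik",
    "n_events",
    "iterations",
    "converged",
    "failure_reason",
    "mean_events",
    "terminal_prop",
    "ctrl_int_ratio",
]


def default_layouts(stratify_by_cluster: bool = True) -> list[LayoutPolicy]:
    return [LayoutPolicy(kind, stratify_by_cluster) for kind in ModelKind]


@dataclass(frozen=True)
class ScenarioSpec:
    design: DesignSpec
    event_config: EventGenConfig
    layouts: tuple[LayoutPolicy, ...] = field(
        default_factory=lambda: tuple(default_layouts())
    )
    replications: int = 1000
    root_seed: int = 0
    scenario_id: str = "scenario"

    def __post_init__(self) -> None:
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if not self.layouts:
            raise ValueError("at least one layout policy is required")
        object.__setattr__(self, "layouts", tuple(self.layouts))

    def with_(self, **kw) -> "ScenarioSpec":
        return replace(self, **kw)


@dataclass(frozen=True)
class ScenarioSummary:
    """Per-(model, stratified) operating characteristics of one scenario."""

    table: pd.DataFrame
    beta_true: float
    scenario_id: str


def _diagnostics(data) -> dict:
    ag = build_ag(data, LayoutPolicy(ModelKind.AG, True))
    _, _, ratio = total_time_by_condition(ag)
    return {
        "mean_events": float(data.n_observed.mean()),
        "terminal_prop": float(
            (data.censor_cause == CensorCause.TERMINAL).mean()
        ),
        "ctrl_int_ratio": ratio,
    }


def run_scenario(spec: ScenarioSpec, progress: bool = False) -> pd.DataFrame:
    """Simulate and fit ``spec.replications`` independent trials.

    Per-replicate seeds are spawned from ``root_seed`` so replicates are
    independent and the whole table is deterministic given the spec.  Fit
    failures are recorded as flagged rows, never raised.
    """
    children = np.random.SeedSequence(spec.root_seed).spawn(spec.replications)
    rows = []
    for r, child in enumerate(children, start=1):
        data = simulate_trial(spec.design, spec.event_config, child)
        diag = _diagnostics(data)
        for policy in spec.layouts:
            intervals = build_layout(data, policy)
            res = fit(intervals)
            rows.append(
                {
                    "replicate": r,
                    "model": policy.model.value,
                    "stratified": policy.stratify_by_cluster,
                }
                | res.to_row()
                | diag
            )
        if progress and r % 50 == 0:
            print(f"[{spec.scenario_id}] replicate {r}/{spec.replications}")
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def summarize(results: pd.DataFrame, beta_true: float, scenario_id: str = "") -> ScenarioSummary:
    """Reduce a per-replicate table to bias / MSE / CP per analysis cell.

    Only converged replicates enter the moments and coverage; their count is
    reported alongside so non-convergence is visible.  A cell with no
    converged replicate is reported with NaN characteristics.
    """
    hr_true = float(np.exp(beta_true))
    out = []
    for (model, strat), g in results.groupby(["model", "stratified"], sort=True):
        conv = g[g["converged"].astype(bool)]
        row = {
            "model": model,
            "stratified": strat,
            "R": len(g),
            "n_converged": len(conv),
        }
        if len(conv):
            beta = conv["beta_hat"].to_numpy()
            bias = float(beta.mean() - beta_true)
            var = float(beta.var(ddof=0))
            row |= {
                "bias": bias,
                "mse": bias**2 + var,
                "cp": float(
                    ((conv["ci_low"] <= hr_true) & (hr_true <= conv["ci_high"])).mean()
                ),
                "mean_beta": float(beta.mean()),
                "var_beta": var,
            }
        else:
            row |= {k: float("nan") for k in ("bias", "mse", "cp", "mean_beta", "var_beta")}
        for diag in ("mean_events", "terminal_prop", "ctrl_int_ratio"):
            row[diag] = float(g.drop_duplicates("replicate")[diag].mean())
        out.append(row)
    table = pd.DataFrame(out)
    return ScenarioSummary(table=table, beta_true=beta_true, scenario_id=scenario_id)


# ---------------------------------------------------------------------------
# preset scenario library
# ---------------------------------------------------------------------------

_EVENT_FACTORIES = {
    "poisson": EventGenConfig.poisson,
    "mixed_poisson": EventGenConfig.mixed_poisson,
    "weibull_constant": EventGenConfig.weibull_constant,
    "weibull_change": EventGenConfig.weibull_change,
}


def _design(m=5, E=1.0, F=0.0, policy=EntryPolicy.NO_FOLLOWUP, N=2000) -> DesignSpec:
    return DesignSpec(
        m=m,
        t_S=REFERENCE_DESIGN["t_S"],
        t_E=REFERENCE_DESIGN["t_E"],
        E=E,
        F=F,
        entry_policy=policy,
        N=N,
    )


def reference_scenario(
    gen: str = "poisson",
    beta_t: float = BETA_EFFECT,
    replications: int = 1000,
    root_seed: int = 0,
    stratify: bool = True,
) -> ScenarioSpec:
    """The reference setting: m=5, N=2000, sigma^2=0, E=1, F=0."""
    return ScenarioSpec(
        design=_design(),
        event_config=_EVENT_FACTORIES[gen](beta_t=beta_t),
        layouts=tuple(default_layouts(stratify)),
        replications=replications,
        root_seed=root_seed,
        scenario_id=f"reference_{gen}_bt{beta_t:g}",
    )


def preset_scenarios(replications: int = 1000, root_seed: int = 0) -> dict[str, ScenarioSpec]:
    """Full factorial library of the six study scenarios.

    Every cell crosses the four event-generation models with both true
    effects (-0.264, 0).  Scenario II additionally toggles cluster
    stratification; Scenario III allows entry until the end of follow-up
    while IV and VI close entry at the end of the last step period.
    """
    specs: dict[str, ScenarioSpec] = {}
    betas = (BETA_EFFECT, 0.0)

    def add(scn, design, gen, beta_t, stratify=True, extra=""):
        key = f"{scn}{extra}_{gen}_bt{beta_t:g}" + ("" if stratify else "_nostrat")
        specs[key] = ScenarioSpec(
            design=design,
            event_config=_EVENT_FACTORIES[gen](beta_t=beta_t),
            layouts=tuple(default_layouts(stratify)),
            replications=replications,
            root_seed=root_seed,
            scenario_id=key,
        )

    for gen in _EVENT_FACTORIES:
        for beta_t in betas:
            # Scenario I: number of steps (= clusters)
            for m in (2, 4, 5, 8, 10, 20):
                add("I", _design(m=m), gen, beta_t, extra=f"_m{m}")
            # Scenario II: cluster heterogeneity, both stratification policies
            for s2 in (0.25, 0.5, 1.0):
                for stratify in (True, False):
                    design = _design()
                    cfg = _EVENT_FACTORIES[gen](beta_t=beta_t).with_(sigma2_cluster=s2)
                    key = f"II_s2{s2:g}_{gen}_bt{beta_t:g}" + (
                        "" if stratify else "_nostrat"
                    )
                    specs[key] = ScenarioSpec(
                        design=design,
                        event_config=cfg,
                        layouts=tuple(default_layouts(stratify)),
                        replications=replications,
                        root_seed=root_seed,
                        scenario_id=key,
                    )
            # Scenario III: follow-up period, entry allowed until t_F
            for F in (1, 2, 3, 4):
                add(
                    "III",
                    _design(F=F, policy=EntryPolicy.ENTRY_UNTIL_TF),
                    gen,
                    beta_t,
                    extra=f"_F{F}",
                )
            # Scenario IV: follow-up period, entry closes at t_E
            for F in (1, 2, 3, 4):
                add(
                    "IV",
                    _design(F=F, policy=EntryPolicy.ENTRY_UNTIL_TE),
                    gen,
                    beta_t,
                    extra=f"_F{F}",
                )
            # Scenario V: entry concentrated early
            for E in (1.5, 2, 4, 6):
                add("V", _design(E=E), gen, beta_t, extra=f"_E{E:g}")
            # Scenario VI: E x F grid, entry closes at t_E
            for E in (1.5, 2, 4, 6):
                for F in (1, 2, 3, 4):
                    add(
                        "VI",
                        _design(E=E, F=F, policy=EntryPolicy.ENTRY_UNTIL_TE),
                        gen,
                        beta_t,
                        extra=f"_E{E:g}_F{F}",
                    )
    return specs


# ---------------------------------------------------------------------------
# config serialization and run manifest
# ---------------------------------------------------------------------------

def scenario_to_yaml(spec: ScenarioSpec) -> str:
    doc = {
        "scenario_id": spec.scenario_id,
        "replications": spec.replications,
        "root_seed": spec.root_seed,
        "design": {
            "m": spec.design.m,
            "t_S": spec.design.t_S,
            "t_E": spec.design.t_E,
            "E": spec.design.E,
            "F": spec.design.F,
            "entry_policy": spec.design.entry_policy.value,
            "N": spec.design.N,
            "n_per_cluster": spec.design.n_per_cluster,
        },
        "event_config": {
            "model": spec.event_config.model.value,
            "lambda_k": list(spec.event_config.lambda_k),
            "nu_k": list(spec.event_config.nu_k),
            "sigma2_cluster": spec.event_config.sigma2_cluster,
            "sigma2_subject": spec.event_config.sigma2_subject,
            "beta_t": spec.event_config.beta_t,
            "lp_offset": spec.event_config.lp_offset,
            "lambda_c": spec.event_config.lambda_c,
            "nu_c": spec.event_config.nu_c,
            "terminal_parameterization": spec.event_config.terminal_parameterization.value,
            "subject_effect_is_sd": spec.event_config.subject_effect_is_sd,
            "switch_basis": spec.event_config.switch_basis.value,
        },
        "layouts": [
            {
                "model": p.model.value,
                "stratify_by_cluster": p.stratify_by_cluster,
                "switch_basis": p.switch_basis.value,
            }
            for p in spec.layouts
        ],
    }
    return yaml.safe_dump(doc, sort_keys=True)


def scenario_from_yaml(text: str) -> ScenarioSpec:
    doc = yaml.safe_load(text)
    d = doc["design"]
    design = DesignSpec(
        m=d["m"],
        t_S=d["t_S"],
        t_E=d["t_E"],
        E=d.get("E", 1.0),
        F=d.get("F", 0.0),
        entry_policy=EntryPolicy(d.get("entry_policy", "no_followup")),
        N=d["N"],
        n_per_cluster=d.get("n_per_cluster"),
    )
    c = doc["event_config"]
    config = EventGenConfig(
        model=GenModel(c["model"]),
        lambda_k=tuple(c["lambda_k"]),
        nu_k=tuple(c.get("nu_k", (1.0, 1.0, 1.0))),
        sigma2_cluster=c.get("sigma2_cluster", 0.0),
        sigma2_subject=c.get("sigma2_subject", 0.0),
        beta_t=c.get("beta_t", 0.0),
        lp_offset=c.get("lp_offset", 0.0),
        lambda_c=c.get("lambda_c", 0.003674),
        nu_c=c.get("nu_c", 1.7191),
        terminal_parameterization=TerminalParam(
            c.get("terminal_parameterization", "cum_haz_pow")
        ),
        subject_effect_is_sd=c.get("subject_effect_is_sd", True),
        switch_basis=SwitchBasis(c.get("switch_basis", "entry")),
    )
    layouts = tuple(
        LayoutPolicy(
            ModelKind(p["model"]),
            p.get("stratify_by_cluster", True),
            SwitchBasis(p.get("switch_basis", "entry")),
        )
        for p in doc.get("layouts", [])
    ) or tuple(default_layouts())
    return ScenarioSpec(
        design=design,
        event_config=config,
        layouts=layouts,
        replications=doc.get("replications", 1000),
        root_seed=doc.get("root_seed", 0),
        scenario_id=doc.get("scenario_id", "scenario"),
    )


def run_manifest(spec: ScenarioSpec) -> dict:
    """Reproducibility record: seed, config hash and software version."""
    from . import __version__

    cfg = scenario_to_yaml(spec)
    return {
        "scenario_id": spec.scenario_id,
        "root_seed": spec.root_seed,
        "replications": spec.replications,
        "config_sha256": hashlib.sha256(cfg.encode()).hexdigest(),
        "swrecur_version": __version__,
    }


def write_manifest(spec: ScenarioSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(run_manifest(spec), fh, indent=2)
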