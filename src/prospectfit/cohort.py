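"""Synthetic participant cohorts with group x drug x domain structure.

The study design crossed two groups (healthy controls, pathological
gamblers) with two drug sessions (placebo, sulpiride — a D2/D3 antagonist)
and two outcome domains (gains, losses).  This module draws per-participant
prospect-theory parameters around per-cell medians, builds softmax choice
agents from them, and runs the staircase task to produce certainty-
equivalent tables with known ground truth — so every downstream stage
(estimation, recovery, statistics) is testable without any external data.

Parameters are drawn log-normally: they are strictly positive and the
field's summary statistic is the median, which the log-normal preserves as
its location.  A shared per-participant random effect on the log scale
induces the placebo–sulpiride correlation (test–retest reliability knob).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import Domain, Gamble, PTParams, WeightingForm
from .staircase import Agent, run_session

__all__ = [
    "STUDY_MEDIANS",
    "CohortSpec",
    "sample_cohort",
    "make_choice_model",
    "simulate_ce_table",
]

GROUPS = ("control", "gambler")
DRUGS = ("placebo", "sulpiride")
DOMAINS = ("gain", "loss")
PARAM_NAMES = ("alpha", "delta", "gamma")

# Published per-cell medians of (alpha, delta, gamma), used as the default
# generating values of the synthetic population.
STUDY_MEDIANS: dict[tuple[str, str, str], dict[str, float]] = {
    ("control", "placebo", "gain"): {"alpha": 0.74, "delta": 0.99, "gamma": 0.55},
    ("control", "sulpiride", "gain"): {"alpha": 0.80, "delta": 0.93, "gamma": 0.66},
    ("control", "placebo", "loss"): {"alpha": 1.02, "delta": 1.08, "gamma": 0.97},
    ("control", "sulpiride", "loss"): {"alpha": 1.28, "delta": 0.83, "gamma": 1.06},
    ("gambler", "placebo", "gain"): {"alpha": 0.80, "delta": 0.90, "gamma": 0.64},
    ("gambler", "sulpiride", "gain"): {"alpha": 1.16, "delta": 0.68, "gamma": 0.89},
    ("gambler", "placebo", "loss"): {"alpha": 1.92, "delta": 0.42, "gamma": 0.88},
    ("gambler", "sulpiride", "loss"): {"alpha": 1.36, "delta": 0.78, "gamma": 0.72},
}


@dataclass
class CohortSpec:
    """Generating distribution of a synthetic cohort.

    ``medians`` maps (group, drug, domain) -> {alpha, delta, gamma} cell
    medians; ``log_sd`` is the log-scale dispersion common to all parameters
    (0.5 reproduces interquartile ranges of roughly 0.7x the median, in line
    with the study's parameter tables); ``within_subject_corr`` is the
    correlation of log-parameters between a participant's two drug sessions;
    ``temperature`` scales softmax choice noise in utility units (0 =
    deterministic agent; the default 10 produces certainty-equivalent noise
    of a few euros and occasional control-trial failures).
    """

    n_controls: int = 21
    n_gamblers: int = 16
    medians: dict[tuple[str, str, str], dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in STUDY_MEDIANS.items()}
    )
    log_sd: float = 0.5
    within_subject_corr: float = 0.5
    temperature: float = 10.0
    weighting_form: WeightingForm = "lattimore"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 1 or self.n_gamblers < 1:
            raise ValueError("need at least one participant per group")
        if not (0 <= self.within_subject_corr <= 1):
            raise ValueError("within_subject_corr must be in [0, 1]")
        if self.log_sd < 0 or self.temperature < 0:
            raise ValueError("log_sd and temperature must be >= 0")
        for key, cell in self.medians.items():
            for name in PARAM_NAMES:
                if not cell[name] > 0:
                    raise ValueError(f"median {name} for {key} must be > 0")

    @classmethod
    def pure_gamma_shift(
        cls,
        gamma_placebo: float = 0.58,
        gamma_sulpiride: float = 0.69,
        alpha: float = 0.85,
        delta: float = 0.95,
        gamma_loss: float = 0.95,
        **kwargs,
    ) -> "CohortSpec":
        """Cohort whose only drug effect is a gamma shift in the gain domain.

        Defaults place the across-participant gain-domain gamma medians at
        0.58 (placebo) and 0.69 (sulpiride) with every other median equal
        across drugs, isolating the distortion effect of interest.
        """
        medians = {}
        for group in GROUPS:
            for drug in DRUGS:
                g_gain = gamma_placebo if drug == "placebo" else gamma_sulpiride
                medians[(group, drug, "gain")] = {
                    "alpha": alpha, "delta": delta, "gamma": g_gain,
                }
                medians[(group, drug, "loss")] = {
                    "alpha": alpha, "delta": delta, "gamma": gamma_loss,
                }
        return cls(medians=medians, **kwargs)


def sample_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw true per-participant parameters for every drug x domain cell.

    Returns a long DataFrame with one row per participant x drug x domain
    and columns participant_id, group, drug_order, drug, domain, alpha,
    delta, gamma, w26 (the implied weight at p = 2/6).  Drug order is
    counterbalanced within group.  Reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    r = spec.within_subject_corr
    rows = []
    pid = 0
    for group, n in (("control", spec.n_controls), ("gambler", spec.n_gamblers)):
        for i in range(n):
            pid += 1
            participant = f"{group[0]}{pid:03d}"
            order = "placebo_first" if i % 2 == 0 else "sulpiride_first"
            # shared random effect per (domain, parameter), common to drugs
            z_subj = rng.standard_normal((len(DOMAINS), len(PARAM_NAMES)))
            for drug in DRUGS:
                z_cell = rng.standard_normal((len(DOMAINS), len(PARAM_NAMES)))
                z = np.sqrt(r) * z_subj + np.sqrt(1.0 - r) * z_cell
                for d, domain in enumerate(DOMAINS):
                    cell = spec.medians[(group, drug, domain)]
                    vals = {
                        name: cell[name] * np.exp(spec.log_sd * z[d, j])
                        for j, name in enumerate(PARAM_NAMES)
                    }
                    params = PTParams(
                        alpha=vals["alpha"],
                        delta=vals["delta"],
                        gamma=vals["gamma"],
                        w26=float(np.clip(
                            _w26_of(vals, spec.weighting_form), 1e-9, 1 - 1e-9)),
                        weighting_form=spec.weighting_form,
                    )
                    rows.append(
                        {
                            "participant_id": participant,
                            "group": group,
                            "drug_order": order,
                            "drug": drug,
                            "domain": domain,
                            "alpha": params.alpha,
                            "delta": params.delta,
                            "gamma": params.gamma,
                            "w26": params.w26,
                        }
                    )
    return pd.DataFrame(rows)


def _w26_of(vals: dict[str, float], form: WeightingForm) -> float:
    from .model import weighting_function

    return float(weighting_function(2.0 / 6.0, vals["delta"], vals["gamma"], form))


def make_choice_model(
    params: PTParams,
    temperature: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Agent:
    """Softmax prospect-theory agent over (signed sure amount, gamble).

    Utilities follow the reflected power-value / weighted-probability model;
    the gamble is chosen with probability ``sigmoid((U_gamble - U_sure) /
    temperature)``.  At temperature 0 the choice is the deterministic argmax
    with ties broken toward the sure option.
    """
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    if rng is None:
        rng = np.random.default_rng()

    def agent(sure_amount: float, gamble: Gamble) -> str:
        w = params.weight(gamble.p_float)
        u_gamble = w * (gamble.x**params.alpha - gamble.y**params.alpha) + gamble.y**params.alpha
        u_sure = abs(sure_amount) ** params.alpha
        if gamble.domain == "loss":
            u_gamble, u_sure = -u_gamble, -u_sure
        diff = u_gamble - u_sure
        if temperature == 0:
            return "gamble" if diff > 0 else "sure"
        p_gamble = expit(diff / temperature)
        return "gamble" if rng.random() < p_gamble else "sure"

    return agent


def simulate_ce_table(
    cohort: pd.DataFrame,
    temperature: float = 0.0,
    seed: int = 0,
    weighting_form: WeightingForm = "lattimore",
    control_eps: float = 0.05,
    max_repeats: int = 3,
    return_trials: bool = False,
):
    """Run the staircase task for every participant x drug in a cohort.

    Produces the signed CE table (participant_id, group, drug_order, drug,
    domain, gamble_index, ce) consumed by the estimation stage; optionally
    also the full trial log.  Block order follows each participant's
    counterbalancing; per-participant RNG streams are derived from ``seed``
    so sessions are individually reproducible.
    """
    root = np.random.SeedSequence(seed)
    ce_rows = []
    all_trials = []
    keys = cohort[["participant_id", "drug"]].drop_duplicates()
    streams = {
        (row.participant_id, row.drug): np.random.default_rng(child)
        for row, child in zip(
            keys.itertuples(index=False), root.spawn(len(keys))
        )
    }
    for (participant, drug), sub in cohort.groupby(["participant_id", "drug"], sort=True):
        rng = streams[(participant, drug)]
        group = sub["group"].iloc[0]
        order = sub["drug_order"].iloc[0]
        agents: dict[Domain, Agent] = {}
        for domain in DOMAINS:
            row = sub[sub["domain"] == domain].iloc[0]
            params = PTParams(
                alpha=row["alpha"],
                delta=row["delta"],
                gamma=row["gamma"],
                w26=float(np.clip(row["w26"], 1e-9, 1 - 1e-9)),
                weighting_form=weighting_form,
            )
            agents[domain] = make_choice_model(params, temperature, rng)
        block_order = ("gain", "loss") if order == "placebo_first" else ("loss", "gain")
        results, trials = run_session(
            agents,
            rng,
            participant_id=participant,
            drug=drug,
            block_order=block_order,
            control_eps=control_eps,
            max_repeats=max_repeats,
        )
        all_trials.extend(trials)
        for res in results:
            ce_rows.append(
                {
                    "participant_id": participant,
                    "group": group,
                    "drug_order": order,
                    "drug": drug,
                    "domain": res.domain,
                    "gamble_index": res.gamble_index,
                    "ce": res.ce,
                }
            )
    ce_table = pd.DataFrame(ce_rows).sort_values(
        ["participant_id", "drug", "domain", "gamble_index"], ignore_index=True
    )
    if return_trials:
        return ce_table, all_trials
    return ce_table
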