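"""Simulation of the certainty-equivalent elicitation task.

Each gamble is played as a *series*: six bisection trials that home in on
the sure amount subjectively equivalent to the gamble, followed by two
control trials slightly above and below the estimated certainty equivalent
(CE).  A full session presents the 10-gamble menu in a gain block and a
loss block (order counterbalanced, gambles shuffled within block), for a
minimum of 10 x 8 x 2 = 160 trials.

The bisection bracket logic runs on *signed* money: for losses the sure
amounts are negative, and "higher signed value" is always the more
attractive sure option, so a single bound-update rule covers both domains
(gamble chosen -> the offer was too unattractive -> raise the lower bound;
sure chosen -> lower the upper bound).

An *agent* is any callable ``agent(sure_amount, gamble) -> "sure"|"gamble"``
taking the signed sure amount.  Deterministic prospect-theory agents are
monotone in the offer, so the true indifference point stays inside the
bracket at every step and the final midpoint is within half the terminal
bracket width of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .model import Domain, Gamble, gamble_menu

Agent = Callable[[float, Gamble], str]

__all__ = [
    "TrialRecord",
    "StaircaseResult",
    "SeriesFlaggedError",
    "initial_sure_amount",
    "run_series",
    "run_session",
    "N_BISECTION_STEPS",
    "TRIALS_PER_SERIES",
]

N_BISECTION_STEPS = 6
N_CONTROL_TRIALS = 2
TRIALS_PER_SERIES = N_BISECTION_STEPS + N_CONTROL_TRIALS


@dataclass
class TrialRecord:
    """One choice between a signed sure amount and a fixed gamble."""

    participant_id: str
    drug: str
    domain: Domain
    gamble_index: int
    series_repeat: int
    trial_number: int  # 1-6 staircase, 7-8 control
    sure_amount: float  # signed euros
    choice: str  # "sure" | "gamble"
    is_control: bool


@dataclass
class StaircaseResult:
    """Outcome of one (possibly repeated) series for a single gamble."""

    gamble_index: int
    domain: Domain
    ce: float  # signed euros
    trials: list[TrialRecord] = field(default_factory=list)
    n_repeats: int = 0
    flagged: bool = False

    @property
    def ce_magnitude(self) -> float:
        return abs(self.ce)


class SeriesFlaggedError(RuntimeError):
    """Raised when a series keeps failing its control trials past max_repeats.

    Carries the last completed result so callers can keep it flagged rather
    than lose the data.
    """

    def __init__(self, result: StaircaseResult):
        super().__init__(
            f"series for gamble {result.gamble_index} ({result.domain}) failed "
            f"control trials {result.n_repeats + 1} times"
        )
        self.result = result


def initial_sure_amount(gamble: Gamble) -> float:
    """First sure offer: the gamble's expected value (magnitude)."""
    return gamble.expected_value()


def _signed_bounds(gamble: Gamble) -> tuple[float, float]:
    # signed interval of possible CEs: [y, x] for gains, [-x, -y] for losses
    if gamble.domain == "gain":
        return gamble.y, gamble.x
    return -gamble.x, -gamble.y


def _run_one_staircase(
    agent: Agent,
    gamble: Gamble,
    participant_id: str,
    drug: str,
    series_repeat: int,
    n_steps: int,
) -> tuple[float, float, float, list[TrialRecord]]:
    """One pass of the bisection; returns (ce, lo, hi, trials), all signed."""
    lo, hi = _signed_bounds(gamble)
    offer = gamble.sign * initial_sure_amount(gamble)
    trials: list[TrialRecord] = []
    for t in range(1, n_steps + 1):
        choice = agent(offer, gamble)
        if choice not in ("sure", "gamble"):
            raise ValueError(f"agent returned {choice!r}")
        trials.append(
            TrialRecord(
                participant_id=participant_id,
                drug=drug,
                domain=gamble.domain,
                gamble_index=gamble.index,
                series_repeat=series_repeat,
                trial_number=t,
                sure_amount=offer,
                choice=choice,
                is_control=False,
            )
        )
        # gamble chosen: sure offer too low (signed) -> raise lower bound
        if choice == "gamble":
            lo = offer
        else:
            hi = offer
        offer = 0.5 * (lo + hi)
    ce = 0.5 * (lo + hi)
    return ce, lo, hi, trials


def run_series(
    agent: Agent,
    gamble: Gamble,
    n_steps: int = N_BISECTION_STEPS,
    control_eps: float = 0.05,
    max_repeats: int = 3,
    participant_id: str = "sim",
    drug: str = "placebo",
) -> StaircaseResult:
    """Run one series (staircase + two control trials), repeating on failure.

    The control trials offer the estimated CE nudged up and down by
    ``control_eps * |CE|``.  A control response counts as inconsistent only
    when it contradicts the terminal bisection bracket — an offer at or above
    the bracket must be taken sure, one at or below it must be gambled;
    offers inside the bracket cannot be judged, since the participant's
    indifference point is only localized to the bracket.  Under this rule a
    deterministic monotone agent always passes, so repeats reflect genuine
    choice inconsistency.  After ``max_repeats`` failed repeats the series is
    flagged via :class:`SeriesFlaggedError` carrying the last result.
    """
    all_trials: list[TrialRecord] = []
    for attempt in range(max_repeats + 1):
        ce, lo, hi, trials = _run_one_staircase(
            agent, gamble, participant_id, drug, attempt, n_steps
        )
        all_trials.extend(trials)
        consistent = True
        offsets = (control_eps * abs(ce), -control_eps * abs(ce))
        for k, off in enumerate(offsets):
            offer = ce + off
            choice = agent(offer, gamble)
            trials_rec = TrialRecord(
                participant_id=participant_id,
                drug=drug,
                domain=gamble.domain,
                gamble_index=gamble.index,
                series_repeat=attempt,
                trial_number=n_steps + 1 + k,
                sure_amount=offer,
                choice=choice,
                is_control=True,
            )
            all_trials.append(trials_rec)
            if offer >= hi and choice != "sure":
                consistent = False
            elif offer <= lo and choice != "gamble":
                consistent = False
        if consistent:
            return StaircaseResult(
                gamble_index=gamble.index,
                domain=gamble.domain,
                ce=ce,
                trials=all_trials,
                n_repeats=attempt,
            )
    result = StaircaseResult(
        gamble_index=gamble.index,
        domain=gamble.domain,
        ce=ce,
        trials=all_trials,
        n_repeats=max_repeats,
        flagged=True,
    )
    raise SeriesFlaggedError(result)


def run_session(
    agents: dict[Domain, Agent],
    seed: int | np.random.Generator,
    participant_id: str = "sim",
    drug: str = "placebo",
    block_order: Sequence[Domain] = ("gain", "loss"),
    control_eps: float = 0.05,
    max_repeats: int = 3,
) -> tuple[list[StaircaseResult], list[TrialRecord]]:
    """Simulate a full session: both domain blocks, shuffled gamble order.

    ``agents`` maps each domain to its choice model (parameters may differ
    between gains and losses).  With no repeated series the session contains
    exactly 160 trials and yields 20 CEs.  Flagged series are kept (with
    ``flagged=True``) rather than dropped.
    """
    rng = np.random.default_rng(seed)
    results: list[StaircaseResult] = []
    trials: list[TrialRecord] = []
    for domain in block_order:
        menu = gamble_menu(domain)
        order = rng.permutation(len(menu))
        for idx in order:
            gamble = menu[idx]
            try:
                res = run_series(
                    agents[domain],
                    gamble,
                    control_eps=control_eps,
                    max_repeats=max_repeats,
                    participant_id=participant_id,
                    drug=drug,
                )
            except SeriesFlaggedError as err:
                res = err.result
            results.append(res)
            trials.extend(res.trials)
    return results, trials
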