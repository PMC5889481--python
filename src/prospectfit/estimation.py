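"""Two-step semi-parametric prospect-theory estimation from CE tables.

For each participant x drug x domain cell the task yields 10 certainty
equivalents (CEs), one per menu gamble.  Estimation proceeds in two steps:

1. The six gambles with p = 2/6 (indices 2-7) share a single decision
   weight w(2/6), so their CEs identify the value curvature ``alpha`` and
   ``w(2/6)`` jointly by nonlinear least squares on the CE scale,
   ``CE_i ~ [w26*(x_i^a - y_i^a) + y_i^a]^(1/a)``.
2. The four zero-floor gambles (indices 1, 8, 9, 10) then give
   *nonparametric* weights at p = 1/6, 3/6, 4/6, 5/6 by direct inversion,
   ``w(p) = (CE/x)^alpha``.

A two-parameter weighting function (Lattimore or Prelec) is finally fitted
by least squares to the five (p, w) points.  Both nonlinear fits are run
from many random starting values (uniform on [0,5] for alpha, delta, gamma
and [0,1] for w26) and the solution with the smallest squared residual norm
("resnorm") is kept; a canonical neutral start (alpha=1, w26=1/3,
delta=gamma=1) is always tried first so noiseless data re-estimates to a
bit-stable fixed point.

Loss-domain cells are estimated on CE magnitudes with the same machinery
(reflection); exclusion rules (probability-monotonicity violations and
alpha outliers) operate on the assembled parameter table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import WeightingForm, gamble_menu, weight_from_ce, weighting_function

__all__ = [
    "PTEstimate",
    "EstimationError",
    "STEP1_INDICES",
    "STEP2_INDICES",
    "estimate_step1",
    "estimate_step2",
    "fit_weighting",
    "estimate_participant",
    "check_monotonicity",
    "check_alpha_outlier",
    "estimate_table",
]

STEP1_INDICES = (2, 3, 4, 5, 6, 7)  # the p = 2/6 gambles
STEP2_INDICES = (1, 8, 9, 10)  # zero-floor gambles at p = 1/6, 3/6, 4/6, 5/6

# Optimizer bounds mirror the random-start ranges; tolerances are tight so
# that noiseless self-consistency holds to ~1e-8.
ALPHA_BOUNDS = (1e-6, 5.0)
W_BOUNDS = (1e-6, 1.0 - 1e-6)
DG_BOUNDS = (1e-6, 5.0)
_LSQ_KW = dict(method="trf", ftol=1e-12, xtol=1e-12, gtol=1e-12)

_MENU = {g.index: g for g in gamble_menu("gain")}
_STEP2_P = {1: 1.0 / 6.0, 8: 3.0 / 6.0, 9: 4.0 / 6.0, 10: 5.0 / 6.0}
WEIGHT_COLS = {1: "w16", 8: "w36", 9: "w46", 10: "w56"}


class EstimationError(RuntimeError):
    """Raised when a fit cannot be performed (bad input or no convergence)."""


@dataclass
class PTEstimate:
    """Fitted parameters for one participant x drug x domain cell."""

    alpha: float
    w26: float
    nonparam_weights: dict[float, float]  # p -> w(p) for p in {1,3,4,5}/6
    delta: float
    gamma: float
    weighting_form: WeightingForm
    resnorm_step1: float
    resnorm_step2: float
    n_restarts_used: int = 0


def _as_magnitudes(ce_table: Mapping[int, float]) -> dict[int, float]:
    return {int(k): abs(float(v)) for k, v in ce_table.items()}


def _step1_predict(alpha: float, w26: float, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    u = w26 * (xs**alpha - ys**alpha) + ys**alpha
    return u ** (1.0 / alpha)


def estimate_step1(
    ce_table: Mapping[int, float],
    fix_alpha: bool = False,
    start: tuple[float, float] = (1.0, 1.0 / 3.0),
) -> tuple[float, float, float]:
    """Fit (alpha, w26) to the six p = 2/6 CEs from one starting point.

    Residuals are in CE (euro) units.  With ``fix_alpha`` the value function
    is pinned linear (alpha = 1) and only w26 is fitted.  Returns
    (alpha, w26, resnorm) where resnorm is the squared residual norm.
    """
    ces = _as_magnitudes(ce_table)
    missing = [i for i in STEP1_INDICES if i not in ces]
    if missing:
        raise EstimationError(f"step 1 needs CEs for gambles {STEP1_INDICES}; missing {missing}")
    xs = np.array([_MENU[i].x for i in STEP1_INDICES])
    ys = np.array([_MENU[i].y for i in STEP1_INDICES])
    obs = np.array([ces[i] for i in STEP1_INDICES])

    a0 = min(max(start[0], ALPHA_BOUNDS[0]), ALPHA_BOUNDS[1])
    w0 = min(max(start[1], W_BOUNDS[0]), W_BOUNDS[1])
    if fix_alpha:
        res = least_squares(
            lambda th: _step1_predict(1.0, th[0], xs, ys) - obs,
            x0=[w0], bounds=([W_BOUNDS[0]], [W_BOUNDS[1]]), **_LSQ_KW,
        )
        alpha, w26 = 1.0, float(res.x[0])
    else:
        res = least_squares(
            lambda th: _step1_predict(th[0], th[1], xs, ys) - obs,
            x0=[a0, w0],
            bounds=([ALPHA_BOUNDS[0], W_BOUNDS[0]], [ALPHA_BOUNDS[1], W_BOUNDS[1]]),
            **_LSQ_KW,
        )
        alpha, w26 = float(res.x[0]), float(res.x[1])
    if not res.success:
        raise EstimationError(f"step-1 optimizer failed: {res.message}")
    return alpha, w26, float(2.0 * res.cost)


def estimate_step2(ce_table: Mapping[int, float], alpha: float) -> dict[float, float]:
    """Nonparametric weights w(p) = (CE/x)^alpha for the zero-floor gambles.

    Raises :class:`EstimationError` if a CE magnitude exceeds its gamble's
    x (a probability-monotonicity violation the caller turns into an
    exclusion).
    """
    ces = _as_magnitudes(ce_table)
    missing = [i for i in STEP2_INDICES if i not in ces]
    if missing:
        raise EstimationError(f"step 2 needs CEs for gambles {STEP2_INDICES}; missing {missing}")
    weights: dict[float, float] = {}
    for i in STEP2_INDICES:
        g = _MENU[i]
        try:
            weights[_STEP2_P[i]] = weight_from_ce(ces[i], g.x, alpha)
        except ValueError as err:
            raise EstimationError(f"gamble {i}: {err}") from err
    return weights


def fit_weighting(
    weights: Mapping[float, float],
    form: WeightingForm = "lattimore",
    start: tuple[float, float] = (1.0, 1.0),
) -> tuple[float, float, float]:
    """Least-squares fit of a two-parameter weighting function to (p, w) points.

    Returns (delta, gamma, resnorm) with resnorm on the squared-weight scale.
    """
    if len(weights) < 2:
        raise EstimationError("need at least 2 probability weights to fit")
    ps = np.array(sorted(weights))
    ws = np.array([weights[p] for p in ps])
    d0 = min(max(start[0], DG_BOUNDS[0]), DG_BOUNDS[1])
    g0 = min(max(start[1], DG_BOUNDS[0]), DG_BOUNDS[1])
    res = least_squares(
        lambda th: weighting_function(ps, th[0], th[1], form) - ws,
        x0=[d0, g0],
        bounds=([DG_BOUNDS[0]] * 2, [DG_BOUNDS[1]] * 2),
        **_LSQ_KW,
    )
    if not res.success:
        raise EstimationError(f"weighting fit failed: {res.message}")
    return float(res.x[0]), float(res.x[1]), float(2.0 * res.cost)


def estimate_participant(
    ce_table: Mapping[int, float],
    form: WeightingForm = "lattimore",
    n_restarts: int = 200,
    seed: int | np.random.Generator = 0,
    fix_alpha: bool = False,
) -> PTEstimate:
    """Full two-step estimation with random restarts for one cell.

    Starting values are drawn uniformly from [0, 5] for alpha, delta, gamma
    and [0, 1] for w26 (the neutral start is always tried first); among
    restarts the fit with the smallest resnorm wins, ties going to the first
    encountered.  Reproducible from ``seed``.
    """
    if n_restarts < 1:
        raise EstimationError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    starts1 = [(1.0, 1.0 / 3.0)] + [
        (rng.uniform(0, 5), rng.uniform(0, 1)) for _ in range(n_restarts - 1)
    ]
    starts2 = [(1.0, 1.0)] + [
        (rng.uniform(0, 5), rng.uniform(0, 5)) for _ in range(n_restarts - 1)
    ]

    best1 = None
    n_used = 0
    last_err: Exception | None = None
    for s in starts1:
        try:
            fit = estimate_step1(ce_table, fix_alpha=fix_alpha, start=s)
        except EstimationError as err:
            last_err = err
            continue
        n_used += 1
        if best1 is None or fit[2] < best1[2]:
            best1 = fit
    if best1 is None:
        raise EstimationError(f"all step-1 restarts failed: {last_err}")
    alpha, w26, resnorm1 = best1

    nonparam = estimate_step2(ce_table, alpha)
    all_weights = dict(nonparam)
    all_weights[2.0 / 6.0] = w26

    best2 = None
    for s in starts2:
        try:
            fit = fit_weighting(all_weights, form=form, start=s)
        except EstimationError as err:
            last_err = err
            continue
        if best2 is None or fit[2] < best2[2]:
            best2 = fit
    if best2 is None:
        raise EstimationError(f"all weighting-fit restarts failed: {last_err}")
    delta, gamma, resnorm2 = best2

    return PTEstimate(
        alpha=alpha,
        w26=w26,
        nonparam_weights=nonparam,
        delta=delta,
        gamma=gamma,
        weighting_form=form,
        resnorm_step1=resnorm1,
        resnorm_step2=resnorm2,
        n_restarts_used=n_used,
    )


def check_monotonicity(ce_table: pd.DataFrame) -> pd.DataFrame:
    """Flag participants violating probability monotonicity.

    A participant is excluded when the absolute CE of gamble 1 (p = 1/6)
    exceeds that of gamble 10 (p = 5/6) in *any* drug x domain condition —
    strictly higher weight on the rarer outcome violates the basic ordering
    the estimation assumes.  Returns a DataFrame (participant_id, include,
    reason).
    """
    need = {"participant_id", "drug", "domain", "gamble_index", "ce"}
    if not need.issubset(ce_table.columns):
        raise EstimationError(f"CE table must have columns {sorted(need)}")
    out = []
    for pid, sub in ce_table.groupby("participant_id", sort=True):
        reasons = []
        for (drug, domain), cell in sub.groupby(["drug", "domain"], sort=True):
            ces = cell.set_index("gamble_index")["ce"].abs()
            if 1 not in ces.index or 10 not in ces.index:
                raise EstimationError(
                    f"participant {pid} {drug}/{domain}: gambles 1 and 10 required"
                )
            if ces[1] > ces[10]:
                reasons.append(f"{drug}/{domain}")
        out.append(
            {
                "participant_id": pid,
                "include": not reasons,
                "reason": "" if not reasons else "monotonicity: " + ",".join(reasons),
            }
        )
    return pd.DataFrame(out)


def check_alpha_outlier(alphas: Mapping[str, float] | pd.Series, k: float = 3.0) -> pd.Series:
    """Flag alpha values more than ``k`` SDs from the sample mean.

    With fewer than 3 values or zero dispersion nothing is flagged.  Returns
    a boolean Series indexed like the input (True = outlier).
    """
    s = pd.Series(alphas, dtype=float)
    if len(s) < 3:
        return pd.Series(False, index=s.index)
    sd = s.std(ddof=1)
    if not np.isfinite(sd) or sd == 0 or not np.isfinite(k):
        return pd.Series(False, index=s.index)
    return (s - s.mean()).abs() > k * sd


def estimate_table(
    ce_table: pd.DataFrame,
    form: WeightingForm = "lattimore",
    n_restarts: int = 200,
    seed: int = 0,
    fix_alpha: bool = False,
    alpha_outlier_k: float = 3.0,
) -> pd.DataFrame:
    """Estimate every participant x drug x domain cell of a CE table.

    Returns the long parameter table with exclusion flags.  Exclusions do
    not suppress estimation (all cells are fitted); they mark participants
    the inferential stage should drop.  Per-cell restart streams are derived
    deterministically from ``seed`` and the cell's identity.
    """
    import zlib

    mono = check_monotonicity(ce_table).set_index("participant_id")
    rows = []
    for (pid, drug, domain), cell in ce_table.groupby(
        ["participant_id", "drug", "domain"], sort=True
    ):
        ces = dict(zip(cell["gamble_index"].astype(int), cell["ce"]))
        cell_seed = np.random.SeedSequence(
            [int(seed), zlib.crc32(f"{pid}|{drug}|{domain}".encode())]
        )
        row = {
            "participant_id": pid,
            "group": cell["group"].iloc[0] if "group" in cell else "",
            "drug_order": cell["drug_order"].iloc[0] if "drug_order" in cell else "",
            "drug": drug,
            "domain": domain,
        }
        try:
            est = estimate_participant(
                ces,
                form=form,
                n_restarts=n_restarts,
                seed=np.random.default_rng(cell_seed),
                fix_alpha=fix_alpha,
            )
        except EstimationError as err:
            row.update(
                alpha=np.nan, w26=np.nan, w16=np.nan, w36=np.nan, w46=np.nan,
                w56=np.nan, delta=np.nan, gamma=np.nan, resnorm1=np.nan,
                resnorm2=np.nan, excluded=True, exclusion_reason=f"estimation: {err}",
            )
            rows.append(row)
            continue
        row.update(
            alpha=est.alpha,
            w26=est.w26,
            w16=est.nonparam_weights[1.0 / 6.0],
            w36=est.nonparam_weights[3.0 / 6.0],
            w46=est.nonparam_weights[4.0 / 6.0],
            w56=est.nonparam_weights[5.0 / 6.0],
            delta=est.delta,
            gamma=est.gamma,
            resnorm1=est.resnorm_step1,
            resnorm2=est.resnorm_step2,
            excluded=not mono.loc[pid, "include"],
            exclusion_reason=mono.loc[pid, "reason"],
        )
        rows.append(row)
    table = pd.DataFrame(rows)

    # alpha-outlier screen, per drug x domain condition over the sample
    # still standing after the monotonicity screen
    ok = ~table["excluded"] & table["alpha"].notna()
    flagged: set[str] = set()
    for (drug, domain), cond in table[ok].groupby(["drug", "domain"], sort=True):
        out = check_alpha_outlier(
            cond.set_index("participant_id")["alpha"], k=alpha_outlier_k
        )
        flagged.update(out[out].index)
    if flagged:
        hit = table["participant_id"].isin(flagged) & ~table["excluded"]
        table.loc[hit, "excluded"] = True
        table.loc[hit, "exclusion_reason"] = "alpha_outlier"
    return table
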