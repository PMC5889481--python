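"""Nonparametric group x drug inference on prospect-theory parameters.

The analysis layer mirrors a 2 (group: control/gambler) x 2 (drug:
placebo/sulpiride) design evaluated separately for gains and losses and for
each parameter (alpha, delta, gamma):

* drug main effect — Wilcoxon signed-rank on the paired sulpiride/placebo
  values across all participants;
* group main effect — Mann–Whitney U on drug-averaged values;
* drug x group and drug x drug-order interactions — Mann–Whitney U on the
  sulpiride-minus-placebo differences between groups / order arms;
* the placebo-only group contrast reported for the loss-domain elevation.

Conventions: zero differences are dropped before ranking, no continuity
correction, z from the normal approximation (tie-corrected variance for
Mann–Whitney); positive z means sulpiride > placebo (drug effects) or
gamblers > controls (group effects).  Exact p-values by enumeration of the
null distribution are available for small samples.  Effect sizes are
common-language effect sizes (CLE): U/(n1*n2) for Mann–Whitney, the share
of positive differences for Wilcoxon; 0.5 means no effect.  Family-wise
error is controlled by Bonferroni multiplication (x6 per dependent
variable: two main effects plus interaction, times two domains).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, spearmanr  # noqa: F401  (spearmanr used by recovery)

__all__ = [
    "StatResult",
    "StatsError",
    "wilcoxon_paired",
    "mannwhitney_groups",
    "cle_mw",
    "cle_wilcoxon",
    "bonferroni",
    "run_full_analysis",
    "medians_iqr_table",
]

PARAMS = ("alpha", "delta", "gamma")
BONFERRONI_M = 6


class StatsError(ValueError):
    """Degenerate or malformed data for a statistical test."""


@dataclass
class StatResult:
    contrast: str
    z: float
    p_uncorr: float
    p_corr: float
    cle: float
    n: str


def _exact_p_from_null(null: np.ndarray, observed: float) -> float:
    """Two-sided exact p for a statistic symmetric about its null mean."""
    mu = null.mean()
    return float(np.mean(np.abs(null - mu) >= np.abs(observed - mu) - 1e-12))


def wilcoxon_paired(
    x_sulpiride: Sequence[float],
    x_placebo: Sequence[float],
    tie_correction: bool = False,
    continuity: bool = False,
    method: str = "normal",
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped before ranking.  Returns ``(z, p)`` where
    z > 0 indicates the first sample (sulpiride) tends higher.  With
    ``method="exact"`` the p-value is computed by enumerating all 2^n sign
    patterns of the observed absolute-difference ranks (n <= 20), while z is
    still the normal-approximation statistic.
    """
    d = np.asarray(x_sulpiride, dtype=float) - np.asarray(x_placebo, dtype=float)
    if d.ndim != 1 or len(d) == 0:
        raise StatsError("need one-dimensional, non-empty paired samples")
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise StatsError("all paired differences are zero")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    if tie_correction:
        _, counts = np.unique(np.abs(d), return_counts=True)
        var -= np.sum(counts**3 - counts) / 48.0
    if var <= 0:
        raise StatsError("zero variance in signed-rank statistic")
    num = w_plus - mu
    if continuity:
        num -= 0.5 * np.sign(num)
    z = num / np.sqrt(var)
    if method == "normal":
        p = 2.0 * norm.sf(abs(z))
    elif method == "exact":
        if n > 20:
            raise StatsError("exact enumeration limited to n <= 20")
        signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        null = signs @ ranks
        p = _exact_p_from_null(null, w_plus)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(z), float(min(p, 1.0))


def mannwhitney_groups(
    controls: Sequence[float],
    gamblers: Sequence[float],
    method: str = "normal",
) -> tuple[float, float, float]:
    """Mann–Whitney U test between two independent samples.

    Returns ``(z, p, u)`` where ``u`` counts pairs in which a value from the
    *second* sample exceeds one from the first (ties count 1/2), so z > 0
    and CLE > 0.5 both mean the second sample tends higher.  The normal
    approximation uses the average-rank tie correction; ``method="exact"``
    enumerates all rank assignments (n1 + n2 <= 14).
    """
    a = np.asarray(controls, dtype=float)
    b = np.asarray(gamblers, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise StatsError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    ranks = rankdata(combined)
    r2 = ranks[n1:].sum()
    u = float(r2 - n2 * (n2 + 1) / 2.0)  # pairs with gambler > control
    mu = n1 * n2 / 2.0
    nt = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (nt * (nt - 1))
    var = n1 * n2 / 12.0 * (nt + 1 - tie_term)
    if var <= 0:
        raise StatsError("zero variance in U statistic (all values tied)")
    z = (u - mu) / np.sqrt(var)
    if method == "normal":
        p = 2.0 * norm.sf(abs(z))
    elif method == "exact":
        if nt > 14:
            raise StatsError("exact enumeration limited to n1 + n2 <= 14")
        null = np.array(
            [
                ranks[list(idx)].sum() - n2 * (n2 + 1) / 2.0
                for idx in combinations(range(nt), n2)
            ]
        )
        p = _exact_p_from_null(null, u)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(z), float(min(p, 1.0)), u


def cle_mw(u: float, n1: int, n2: int) -> float:
    """Common-language effect size for Mann–Whitney: U / (n1 * n2)."""
    if not (0 <= u <= n1 * n2):
        raise ValueError(f"U={u} outside [0, {n1 * n2}]")
    return float(u) / (n1 * n2)


def cle_wilcoxon(differences: Sequence[float]) -> float:
    """Share of positive paired differences (zeros count in the denominator)."""
    d = np.asarray(differences, dtype=float)
    if len(d) == 0:
        raise StatsError("need at least one difference")
    return float((d > 0).sum()) / len(d)


def bonferroni(p_uncorr: float, m: int = BONFERRONI_M) -> float:
    """Bonferroni-corrected p: min(1, m * p)."""
    if not (0 <= p_uncorr <= 1):
        raise ValueError(f"p must lie in [0, 1], got {p_uncorr}")
    return min(1.0, m * p_uncorr)


def _wide_cell(table: pd.DataFrame, domain: str, param: str) -> pd.DataFrame:
    """Participant-indexed wide frame with placebo/sulpiride columns."""
    sub = table[(table["domain"] == domain) & (~table["excluded"])]
    wide = sub.pivot_table(index="participant_id", columns="drug", values=param)
    meta = sub.drop_duplicates("participant_id").set_index("participant_id")
    wide = wide.join(meta[["group"] + (["drug_order"] if "drug_order" in meta else [])])
    wide = wide.dropna(subset=["placebo", "sulpiride"])
    return wide


def run_full_analysis(
    param_table: pd.DataFrame, m_correction: int = BONFERRONI_M
) -> pd.DataFrame:
    """All preregistered-style contrasts on an exclusion-filtered parameter table.

    For each parameter x domain: drug main effect (Wilcoxon), group main
    effect (Mann–Whitney on drug-averaged values), drug x group and (when a
    drug_order column is present) drug x order interactions on the
    sulpiride - placebo differences, and the placebo-only group contrast.
    Returns one StatResult row per contrast.
    """
    results: list[StatResult] = []
    for param in PARAMS:
        for domain in ("gain", "loss"):
            wide = _wide_cell(param_table, domain, param)
            if len(wide) < 3:
                raise StatsError(f"too few complete cases for {param}/{domain}")
            label = f"{param}_{domain}"
            sulp, plac = wide["sulpiride"].to_numpy(), wide["placebo"].to_numpy()

            z, p = wilcoxon_paired(sulp, plac)
            results.append(
                StatResult(
                    f"drug:{label}", z, p, bonferroni(p, m_correction),
                    cle_wilcoxon(sulp - plac), f"{len(wide)}",
                )
            )

            grp = wide["group"]
            ctrl, gmb = wide[grp == "control"], wide[grp == "gambler"]
            if len(ctrl) and len(gmb):
                avg_c = ctrl[["placebo", "sulpiride"]].mean(axis=1)
                avg_g = gmb[["placebo", "sulpiride"]].mean(axis=1)
                z, p, u = mannwhitney_groups(avg_c, avg_g)
                results.append(
                    StatResult(
                        f"group:{label}", z, p, bonferroni(p, m_correction),
                        cle_mw(u, len(avg_c), len(avg_g)), f"{len(avg_c)}+{len(avg_g)}",
                    )
                )

                diff_c = (ctrl["sulpiride"] - ctrl["placebo"]).to_numpy()
                diff_g = (gmb["sulpiride"] - gmb["placebo"]).to_numpy()
                z, p, u = mannwhitney_groups(diff_c, diff_g)
                results.append(
                    StatResult(
                        f"drug_x_group:{label}", z, p, bonferroni(p, m_correction),
                        cle_mw(u, len(diff_c), len(diff_g)), f"{len(diff_c)}+{len(diff_g)}",
                    )
                )

                z, p, u = mannwhitney_groups(ctrl["placebo"], gmb["placebo"])
                results.append(
                    StatResult(
                        f"group_placebo:{label}", z, p, bonferroni(p, m_correction),
                        cle_mw(u, len(ctrl), len(gmb)), f"{len(ctrl)}+{len(gmb)}",
                    )
                )

            if "drug_order" in wide.columns and wide["drug_order"].nunique() == 2:
                orders = sorted(wide["drug_order"].unique())
                o1 = wide[wide["drug_order"] == orders[0]]
                o2 = wide[wide["drug_order"] == orders[1]]
                d1 = (o1["sulpiride"] - o1["placebo"]).to_numpy()
                d2 = (o2["sulpiride"] - o2["placebo"]).to_numpy()
                z, p, u = mannwhitney_groups(d1, d2)
                results.append(
                    StatResult(
                        f"drug_x_order:{label}", z, p, bonferroni(p, m_correction),
                        cle_mw(u, len(d1), len(d2)), f"{len(d1)}+{len(d2)}",
                    )
                )
    return pd.DataFrame([r.__dict__ for r in results])


def medians_iqr_table(param_table: pd.DataFrame) -> pd.DataFrame:
    """Per group x drug x domain medians and interquartile ranges.

    IQR = Q3 - Q1 with linear-interpolation quantiles; excluded participants
    are dropped.  One row per parameter x cell.
    """
    sub = param_table[~param_table["excluded"]]
    rows = []
    for (group, drug, domain), cell in sub.groupby(["group", "drug", "domain"], sort=True):
        for param in PARAMS:
            v = cell[param].dropna()
            q1, q3 = v.quantile([0.25, 0.75], interpolation="linear")
            rows.append(
                {
                    "group": group,
                    "drug": drug,
                    "domain": domain,
                    "parameter": param,
                    "median": v.median(),
                    "iqr": q3 - q1,
                    "n": len(v),
                }
            )
    return pd.DataFrame(rows)
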