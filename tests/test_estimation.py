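"""Two-step estimation: self-consistency oracles, restarts, exclusions."""

import numpy as np
import pandas as pd
import pytest

from conftest import lattimore_ce_table
from prospectfit.cohort import CohortSpec, sample_cohort, simulate_ce_table
from prospectfit.estimation import (
    STEP1_INDICES,
    EstimationError,
    check_alpha_outlier,
    check_monotonicity,
    estimate_participant,
    estimate_step1,
    estimate_step2,
    estimate_table,
    fit_weighting,
)
from prospectfit.model import gamble_menu, predicted_ce, w_lattimore, w_prelec


def step1_ces(alpha, w26):
    return {
        i: predicted_ce(gamble_menu("gain")[i - 1], alpha, w26)
        for i in STEP1_INDICES
    }


class TestStep1:
    @pytest.mark.parametrize("alpha, w26", [(0.8, 0.4), (1.5, 0.25), (1.0, 1 / 3)])
    def test_noiseless_self_consistency(self, alpha, w26):
        a, w, resnorm = estimate_step1(step1_ces(alpha, w26))
        assert a == pytest.approx(alpha, abs=1e-6)
        assert w == pytest.approx(w26, abs=1e-6)
        assert resnorm < 1e-12

    def test_ev_table_yields_risk_neutral_parameters(self):
        ces = {i: gamble_menu("gain")[i - 1].expected_value() for i in STEP1_INDICES}
        a, w, _ = estimate_step1(ces)
        assert a == pytest.approx(1.0, abs=1e-6)
        assert w == pytest.approx(1 / 3, abs=1e-6)

    def test_fix_alpha_pins_linear_value(self):
        ces = step1_ces(1.0, 0.4)
        a, w, _ = estimate_step1(ces, fix_alpha=True)
        assert a == 1.0
        assert w == pytest.approx(0.4, abs=1e-8)

    def test_missing_ces_rejected(self):
        with pytest.raises(EstimationError, match="missing"):
            estimate_step1({2: 300.0, 3: 200.0})

    def test_loss_magnitude_convention(self):
        # signed loss CEs estimate identically to their magnitudes
        ces = step1_ces(0.9, 0.35)
        signed = {i: -v for i, v in ces.items()}
        assert estimate_step1(signed) == pytest.approx(estimate_step1(ces))


class TestStep2:
    def test_ev_agent_weights_equal_probabilities(self):
        ces = {1: 200.0, 8: 600.0, 9: 800.0, 10: 1000.0}
        w = estimate_step2(ces, alpha=1.0)
        assert w[1 / 6] == pytest.approx(1 / 6)
        assert w[3 / 6] == pytest.approx(3 / 6)
        assert w[4 / 6] == pytest.approx(4 / 6)
        assert w[5 / 6] == pytest.approx(5 / 6)

    def test_power_inversion(self):
        w = estimate_step2({1: 600.0, 8: 600.0, 9: 600.0, 10: 600.0}, alpha=0.74)
        assert w[1 / 6] == pytest.approx(0.5**0.74, abs=1e-10)

    def test_monotonicity_violation_propagates(self):
        with pytest.raises(EstimationError, match="gamble 1"):
            estimate_step2({1: 1300.0, 8: 600.0, 9: 700.0, 10: 900.0}, alpha=1.0)


class TestWeightingFit:
    @pytest.mark.parametrize(
        "form, fn, delta, gamma",
        [
            ("lattimore", w_lattimore, 0.9, 0.6),
            ("prelec", w_prelec, 1.2, 0.5),
            ("lattimore", w_lattimore, 1.5, 1.2),
        ],
    )
    def test_noiseless_self_consistency(self, form, fn, delta, gamma):
        ps = [k / 6 for k in range(1, 6)]
        weights = {p: fn(p, delta, gamma) for p in ps}
        d, g, resnorm = fit_weighting(weights, form=form)
        assert d == pytest.approx(delta, abs=1e-6)
        assert g == pytest.approx(gamma, abs=1e-6)
        assert resnorm < 1e-12

    @pytest.mark.parametrize("form", ["lattimore", "prelec"])
    def test_identity_weights_give_unit_parameters(self, form):
        weights = {k / 6: k / 6 for k in range(1, 6)}
        d, g, _ = fit_weighting(weights, form=form)
        assert d == pytest.approx(1.0, abs=1e-6)
        assert g == pytest.approx(1.0, abs=1e-6)

    def test_cross_form_fits_agree_on_the_probability_grid(self):
        # Prelec fitted to noiseless Lattimore data reproduces the curve at
        # the 5 design points to within its reported resnorm
        ps = np.array([k / 6 for k in range(1, 6)])
        target = {p: w_lattimore(p, 0.9, 0.6) for p in ps}
        d, g, resnorm = fit_weighting(target, form="prelec")
        achieved = w_prelec(ps, d, g)
        sq = float(np.sum((achieved - np.array(list(target.values()))) ** 2))
        assert sq == pytest.approx(resnorm, rel=1e-6, abs=1e-12)


class TestEstimateParticipant:
    def test_noiseless_lattimore_agent_recovered(self):
        ces = lattimore_ce_table(0.8, 0.9, 0.6)
        est = estimate_participant(ces, n_restarts=50, seed=0)
        assert est.alpha == pytest.approx(0.8, abs=1e-6)
        assert est.w26 == pytest.approx(w_lattimore(1 / 3, 0.9, 0.6), abs=1e-6)
        assert est.delta == pytest.approx(0.9, abs=1e-6)
        assert est.gamma == pytest.approx(0.6, abs=1e-6)
        assert est.resnorm_step1 < 1e-10 and est.resnorm_step2 < 1e-10

    def test_more_restarts_never_worse(self, rng):
        ces = lattimore_ce_table(0.8, 0.9, 0.6)
        noisy = {i: max(1.0, v + rng.normal(0, 30)) for i, v in ces.items()}
        r1 = estimate_participant(noisy, n_restarts=1, seed=5)
        r50 = estimate_participant(noisy, n_restarts=50, seed=5)
        assert r50.resnorm_step1 <= r1.resnorm_step1 + 1e-12
        assert r50.resnorm_step2 <= r1.resnorm_step2 + 1e-12

    def test_same_seed_is_bit_identical(self, rng):
        ces = lattimore_ce_table(1.1, 0.8, 0.7)
        noisy = {i: max(1.0, v + rng.normal(0, 20)) for i, v in ces.items()}
        a = estimate_participant(noisy, n_restarts=25, seed=9)
        b = estimate_participant(noisy, n_restarts=25, seed=9)
        assert (a.alpha, a.w26, a.delta, a.gamma) == (b.alpha, b.w26, b.delta, b.gamma)


class TestExclusions:
    @staticmethod
    def ce_frame(ce1, ce10, n_participants=1):
        rows = []
        for p in range(n_participants):
            for drug in ("placebo", "sulpiride"):
                for domain in ("gain", "loss"):
                    sign = 1 if domain == "gain" else -1
                    for g in gamble_menu(domain):
                        ce = {1: ce1, 10: ce10}.get(g.index, g.expected_value() * 0.9)
                        rows.append(
                            {
                                "participant_id": f"p{p}",
                                "drug": drug,
                                "domain": domain,
                                "gamble_index": g.index,
                                "ce": sign * ce,
                            }
                        )
        return pd.DataFrame(rows)

    def test_monotone_participant_included(self):
        out = check_monotonicity(self.ce_frame(250.0, 900.0))
        assert out["include"].all()

    def test_violation_in_one_condition_excludes(self):
        df = self.ce_frame(250.0, 900.0)
        sel = (df.drug == "sulpiride") & (df.domain == "loss") & (df.gamble_index == 1)
        df.loc[sel, "ce"] = -950.0  # |CE1| > |CE10| in a single condition
        out = check_monotonicity(df)
        assert not out["include"].iloc[0]
        assert "sulpiride/loss" in out["reason"].iloc[0]

    def test_equal_ces_kept_by_strict_rule(self):
        out = check_monotonicity(self.ce_frame(900.0, 900.0))
        assert out["include"].all()

    def test_alpha_outlier_flags_extreme_value(self):
        # a 3-SD rule can only bind when n is large enough that one point
        # cannot dominate the SD (max sample z is (n-1)/sqrt(n))
        values = pd.Series(
            {f"p{i}": v for i, v in enumerate([0.8, 0.9, 1.0, 1.1] * 5 + [15.0])}
        )
        flags = check_alpha_outlier(values)
        assert flags["p20"] and flags.sum() == 1

    def test_no_dispersion_and_infinite_k_flag_nothing(self):
        same = pd.Series({"a": 1.0, "b": 1.0, "c": 1.0})
        assert not check_alpha_outlier(same).any()
        spread = pd.Series({"a": 0.5, "b": 1.0, "c": 9.0})
        assert not check_alpha_outlier(spread, k=np.inf).any()


def test_estimate_table_end_to_end_recovers_truth():
    spec = CohortSpec(n_controls=2, n_gamblers=2, temperature=0.0, seed=21)
    truth = sample_cohort(spec)
    ce = simulate_ce_table(truth, temperature=0.0, seed=21)
    est = estimate_table(ce, n_restarts=15, seed=21)
    assert len(est) == 4 * 2 * 2
    assert {"alpha", "w26", "w16", "w36", "w46", "w56", "delta", "gamma",
            "resnorm1", "resnorm2", "excluded", "exclusion_reason"} <= set(est.columns)
    merged = truth.merge(est, on=["participant_id", "drug", "domain"],
                         suffixes=("_true", "_est"))
    ok = ~merged["excluded"]
    # staircase quantization bounds the parameter error loosely but surely
    assert (merged.loc[ok, "alpha_true"] - merged.loc[ok, "alpha_est"]).abs().median() < 0.2
    r = np.corrcoef(merged.loc[ok, "gamma_true"], merged.loc[ok, "gamma_est"])[0, 1]
    assert r > 0.9
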