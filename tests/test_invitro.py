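"""Viability, 4PL fitting, selectivity, apoptosis, cell cycle and wounds."""
import numpy as np
import pytest

from phytonet import (DoseResponse, FitError, FourPL, QuadrantFractions,
                      ValidationError, WoundSeries, cycle_fractions,
                      cytotoxicity_profile, death_summary, fit_4pl,
                      gen_cell_cycle, gen_dose_response, gen_flow_events,
                      nci_classify, quadrant_fractions, round_half_up,
                      selectivity_index, two_group_test, viability_percent,
                      wound_metrics)
from phytonet.invitro import CellCycleHistogram, FlowEventSet


class TestViability:
    @pytest.mark.parametrize("treated,control,expected", [
        (0.84, 0.84, 100.0), (0.0, 0.84, 0.0), (0.42, 0.84, 50.0),
    ])
    def test_normalization(self, treated, control, expected):
        assert viability_percent(treated, control) == pytest.approx(expected)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValidationError):
            viability_percent(0.4, 0.0)


class TestFourPL:
    TRUE = dict(top=100.0, bottom=0.0, hill=1.5, ic50=18.09)

    def test_noiseless_recovery_to_machine_precision(self):
        dr = gen_dose_response(**self.TRUE, noise_sd=0.0, reps=3, seed=0)
        res = fit_4pl(dr)
        for name, truth in self.TRUE.items():
            est = getattr(res, name)
            assert est == pytest.approx(truth, rel=1e-6, abs=1e-6)

    def test_fitted_curve_midpoint_identity(self):
        dr = gen_dose_response(**self.TRUE, noise_sd=2.0, reps=3, seed=1)
        res = fit_4pl(dr)
        mid = res.predict([res.ic50])[0]
        assert mid == pytest.approx((res.top + res.bottom) / 2, abs=1e-8)
        assert res.icq(50) == pytest.approx(res.ic50)

    def test_noisy_median_ic50_error_within_ten_percent(self):
        errs = []
        for seed in range(100):
            dr = gen_dose_response(**self.TRUE, noise_sd=3.0, reps=3,
                                   seed=seed)
            res = fit_4pl(dr)
            errs.append(abs(res.ic50 - self.TRUE["ic50"]) / self.TRUE["ic50"])
        assert np.median(errs) <= 0.10

    def test_low_noise_ic50_bias_small(self):
        ests = []
        for seed in range(200):
            dr = gen_dose_response(**self.TRUE, noise_sd=2.0, reps=3,
                                   seed=seed)
            ests.append(fit_4pl(dr).ic50)
        bias = abs(np.mean(ests) - self.TRUE["ic50"]) / self.TRUE["ic50"]
        assert bias < 0.05

    def test_flat_response_rejected(self):
        dr = DoseResponse([100, 50, 25, 12.5], np.full((4, 3), 80.0))
        with pytest.raises(FitError):
            fit_4pl(dr)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValidationError):
            FourPL([10, 5, 2.5], np.array([[10.0], [50.0], [90.0]]))

    def test_icq_is_analytic_inverse(self):
        dr = gen_dose_response(**self.TRUE, noise_sd=0.0, reps=1, seed=0)
        res = fit_4pl(dr)
        c25 = res.icq(25)
        v = res.predict([c25])[0]
        assert v == pytest.approx(res.top - 0.25 * (res.top - res.bottom),
                                  abs=1e-6)

    def test_si_invariant_under_unit_rescaling(self):
        ic = gen_dose_response(ic50=18.0, noise_sd=0.0, reps=1, seed=0)
        cc = gen_dose_response(ic50=77.0, noise_sd=0.0, reps=1, seed=0)
        si = fit_4pl(cc).ic50 / fit_4pl(ic).ic50
        scale = 1000.0  # ug/mL -> ng/mL applied to both datasets
        ic2 = DoseResponse(ic.concentrations * scale, ic.viability)
        cc2 = DoseResponse(cc.concentrations * scale, cc.viability)
        si2 = fit_4pl(cc2).ic50 / fit_4pl(ic2).ic50
        assert si2 == pytest.approx(si, rel=1e-6)

    def test_summary_and_intervals_cover_truth_noiseless(self):
        dr = gen_dose_response(**self.TRUE, noise_sd=1.0, reps=3, seed=5)
        res = fit_4pl(dr)
        text = res.summary()
        assert "ic50" in text and "hill" in text
        ci = res.conf_int()
        assert ci.loc["ic50", "lower"] < res.ic50 < ci.loc["ic50", "upper"]


class TestSelectivity:
    @pytest.mark.parametrize("cc50,ic50,expected", [
        (77.76, 18.09, 4.30), (77.76, 27.74, 2.80), (77.76, 66.04, 1.18),
        (5.0, 5.0, 1.00),
    ])
    def test_reported_at_two_decimals(self, cc50, ic50, expected):
        assert selectivity_index(cc50, ic50) == expected

    def test_zero_ic50_rejected(self):
        with pytest.raises(ValidationError):
            selectivity_index(10.0, 0.0)

    @pytest.mark.parametrize("ic50,si,active,selective", [
        (18.09, 4.30, True, True),
        (27.74, 2.80, True, False),
        (66.04, 1.18, False, False),
        (30.0, 3.0, True, False),  # boundary: <= for activity, > for SI
    ])
    def test_nci_classification(self, ic50, si, active, selective):
        assert nci_classify(ic50, si) == (active, selective)

    def test_nci_monotone(self):
        for ic50 in (5, 15, 29, 30):
            assert nci_classify(ic50, 1.0).active
        for si in (3.01, 5, 50):
            assert nci_classify(50.0, si).selective

    def test_profile_report(self):
        prof = cytotoxicity_profile(77.76, {"A-549": 18.09, "MCF-7": 27.74,
                                            "HepG-2": 66.04})
        assert prof.loc["A-549", "si"] == 4.30
        assert bool(prof.loc["A-549", "nci_selective"])
        assert not bool(prof.loc["HepG-2", "nci_active"])


class TestQuadrants:
    def test_all_viable(self):
        events = np.full((100, 2), 1.0)
        q = quadrant_fractions(events, gates=(2.0, 2.0))
        assert q.viable == 100.0
        assert q.early_apoptotic == q.late_apoptotic == q.necrotic == 0.0

    def test_on_gate_counts_positive(self):
        events = np.array([[2.0, 1.0], [1.0, 2.0], [2.0, 2.0], [1.0, 1.0]])
        q = quadrant_fractions(events, gates=(2.0, 2.0))
        assert q.as_series().tolist() == [25.0, 25.0, 25.0, 25.0]

    def test_generated_weights_recovered(self):
        weights = (0.7239, 0.1502, 0.093, 0.0329)
        ev = gen_flow_events(weights, n_events=50_000, seed=8)
        q = quadrant_fractions(ev)
        for got, want in zip(q.as_series(), weights):
            assert abs(got - 100 * want) <= 1.0

    def test_fractions_partition(self, rng):
        ev = FlowEventSet(rng.normal(2.0, 1.0, size=(500, 2)))
        q = quadrant_fractions(ev)
        assert sum(q.as_series()) == pytest.approx(100.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            quadrant_fractions(np.empty((0, 2)), gates=(2, 2))


class TestDeathSummary:
    TREATED = QuadrantFractions(72.39, 15.02, 9.30, 3.29)
    CONTROL = QuadrantFractions(97.39, 0.52, 0.18, 1.91)

    def test_totals_and_fold_induction(self):
        d = death_summary(self.TREATED, self.CONTROL)
        assert d.total_treated == pytest.approx(27.61)
        assert d.total_control == pytest.approx(2.61)
        assert d.fold_1dp == 10.6

    def test_apoptotic_only_totals(self):
        d = death_summary(self.TREATED, self.CONTROL)
        assert d.apoptotic_treated == pytest.approx(24.32)
        assert d.apoptotic_control == pytest.approx(0.70)

    def test_identical_fractions_fold_one(self):
        d = death_summary(self.TREATED, self.TREATED)
        assert d.fold_1dp == 1.0

    def test_zero_control_death_flagged(self):
        clean = QuadrantFractions(100.0, 0.0, 0.0, 0.0)
        d = death_summary(self.TREATED, clean)
        assert d.undefined_fold
        assert np.isnan(d.fold)


class TestCellCycle:
    GATES = (0.6, 1.4, 1.7, 2.5)

    def test_all_in_g0g1_gate(self):
        hist = CellCycleHistogram(np.full(50, 1.0), self.GATES)
        cf = cycle_fractions(hist)
        assert (cf.g0g1, cf.s, cf.g2m) == (100.0, 0.0, 0.0)

    def test_empty_phase_zero(self):
        hist = CellCycleHistogram(np.array([1.0, 1.0, 2.0]), self.GATES)
        cf = cycle_fractions(hist)
        assert cf.s == 0.0

    def test_sub_g1_excluded_from_phase_normalization(self):
        hist = gen_cell_cycle((0.5, 0.3, 0.2), n_events=20_000, seed=2,
                              sub_g1_frac=0.1)
        cf = cycle_fractions(hist)
        assert cf.g0g1 + cf.s + cf.g2m == pytest.approx(100.0)
        assert cf.sub_g1_pct == pytest.approx(10.0, abs=0.5)
        assert abs(cf.g0g1 - 50.0) <= 1.0

    def test_unordered_gates_rejected(self):
        with pytest.raises(ValidationError):
            CellCycleHistogram(np.array([1.0]), (1.4, 0.6, 1.7, 2.5))


class TestWound:
    def test_no_healing_and_full_healing(self):
        ws = WoundSeries([0, 24], [100.0, 100.0], [100.0, 0.0])
        m = wound_metrics(ws)
        assert m.loc[24, "closure_treated"] == 0.0
        assert m.loc[24, "closure_control"] == 100.0

    def test_relative_closure_matches_hand_arithmetic(self):
        ws = WoundSeries([0, 24], [100.0, 44.2], [100.0, 10.0])
        m = wound_metrics(ws)
        # treated closure 55.8 vs control 90 -> 62% of control
        assert m.loc[24, "closure_treated"] == pytest.approx(55.8)
        assert m.loc[24, "relative_closure"] == pytest.approx(62.0)

    def test_negative_closure_flagged(self):
        ws = WoundSeries([0, 24], [100.0, 120.0], [100.0, 50.0])
        m = wound_metrics(ws)
        assert bool(m.loc[24, "negative_closure"])
        assert m.loc[24, "closure_treated"] == pytest.approx(-20.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValidationError):
            WoundSeries([0, 24], [0.0, 1.0], [100.0, 50.0])


class TestWelch:
    def test_identical_groups(self):
        t, p, _ = two_group_test([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert (t, p) == (0.0, 1.0)

    def test_clear_separation(self):
        t, p, _ = two_group_test([0.0, 0.01, -0.01], [10.0, 10.01, 9.99])
        assert p < 1e-3

    def test_matches_textbook_formula(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (va**2 / (a.size - 1)
                                    + vb**2 / (b.size - 1))
        t, p, df = two_group_test(a, b)
        assert t == pytest.approx(t_hand)
        assert df == pytest.approx(df_hand)
        assert 0 < p < 1

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValidationError):
            two_group_test([1.0], [2.0, 3.0])
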