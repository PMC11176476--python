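import math

import numpy as np
import pandas as pd
import pytest

from recurcor import (
    ClassMap,
    ComboScreenTable,
    DoseResponseMatrix,
    FourPLFit,
    ValidationError,
    combination_index_at_effect,
    fit_four_parameter_logistic,
    generate_dose_matrix,
    hsa_score,
    loewe_score,
    median_effect_fit,
    percentile_cutoff,
    score_matrix,
)
from recurcor.synergy import call_synergy, read_dose_matrix, write_dose_matrix

FIT_A = FourPLFit(bottom=0.0, top=1.0, ec50=1e-7, hill=1.2)
FIT_B = FourPLFit(bottom=0.0, top=1.0, ec50=3e-8, hill=0.9)


class TestPercentileCutoff:
    def test_linear_interpolation_oracle(self):
        # hand-applied: 90th percentile of 1..10 sits 0.1 of the way
        # between the 9th and 10th order statistics
        assert percentile_cutoff(range(1, 11), 90) == pytest.approx(9.1)

    def test_constant_scores(self):
        assert percentile_cutoff([4.2] * 7, 90) == pytest.approx(4.2)

    def test_monotone_in_percentile(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=100)
        cuts = [percentile_cutoff(s, p) for p in (50, 75, 90, 99)]
        assert all(a <= b for a, b in zip(cuts, cuts[1:]))

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            percentile_cutoff([])


class TestCallSynergy:
    cm = ClassMap(assignments={"p1": "PX", "p2": "PX", "q1": "QX", "r1": "RX"})

    def _screen(self, scores):
        rows = [
            ("p1", "q1", f"cl{i}", s) for i, s in enumerate(scores["pq"])
        ] + [("p2", "r1", f"cl{i}", s) for i, s in enumerate(scores["pr"])]
        return ComboScreenTable(
            pd.DataFrame(rows, columns=["drug_a", "drug_b", "cell_line", "loewe_score"])
        )

    def test_single_cell_line_above_cutoff_suffices(self):
        screen = self._screen({"pq": [0, 0, 12], "pr": [0, 0, 0]})
        calls = call_synergy(screen, 10.0, self.cm, ["PX-QX", "PX-RX"])
        assert calls.class_calls == {"PX-QX": True, "PX-RX": False}
        assert calls.fraction_synergistic == pytest.approx(0.5)

    def test_strict_comparison_at_cutoff(self):
        screen = self._screen({"pq": [10.0], "pr": [9.9]})
        calls = call_synergy(screen, 10.0, self.cm)
        assert not calls.pair_calls["synergistic"].any()

    def test_call_sets_monotone_in_cutoff(self):
        screen = self._screen({"pq": [3, 8, 12], "pr": [1, 5, 9]})
        lo = call_synergy(screen, 4.0, self.cm).pair_calls["synergistic"].sum()
        hi = call_synergy(screen, 11.0, self.cm).pair_calls["synergistic"].sum()
        assert hi <= lo


class TestFourPL:
    conc = 8e-6 / 5.0 ** np.arange(7, -1, -1)

    def test_zero_residual_recovery(self):
        truth = FourPLFit(bottom=0.0, top=1.0, ec50=1e-7, hill=1.0)
        fit = fit_four_parameter_logistic(self.conc, truth.predict(self.conc))
        assert fit.converged
        assert fit.ec50 == pytest.approx(1e-7, rel=1e-6)
        assert fit.hill == pytest.approx(1.0, abs=1e-6)
        assert fit.bottom == pytest.approx(0.0, abs=1e-6)
        assert fit.top == pytest.approx(1.0, abs=1e-6)

    def test_flat_response_flagged_degenerate(self):
        fit = fit_four_parameter_logistic(self.conc, np.full(8, 0.4))
        assert not fit.converged
        assert "unidentifiable" in fit.message

    def test_noisy_ec50_recovery_within_15_percent(self):
        # simulation-calibrated tolerance: sigma=0.02 noise on an 8-point
        # curve leaves EC50 recoverable within 15% in the bulk of draws
        truth = FourPLFit(bottom=0.0, top=1.0, ec50=1e-7, hill=1.2)
        errors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            resp = truth.predict(self.conc) + rng.normal(0, 0.02, len(self.conc))
            fit = fit_four_parameter_logistic(self.conc, resp)
            errors.append(abs(fit.ec50 - truth.ec50) / truth.ec50)
        assert np.median(errors) < 0.15
        assert np.mean(np.array(errors) < 0.15) > 0.9


class TestMedianEffect:
    def test_exact_recovery(self):
        conc = np.array([1e-8, 1e-7, 1e-6, 1e-5])
        fa = 1 / (1 + (1e-6 / conc) ** 1.0)
        fit = median_effect_fit(conc, fa)
        assert fit.m == pytest.approx(1.0, abs=1e-12)
        assert fit.dm == pytest.approx(1e-6, rel=1e-9)

    def test_dm_is_half_effect_dose(self):
        fit = median_effect_fit([1e-7, 1e-6, 1e-5], [0.24, 0.5, 0.9])
        assert 1 / (1 + (fit.dm / fit.dm) ** fit.m) == pytest.approx(0.5)
        assert fit.dose_at(0.5) == pytest.approx(fit.dm)

    def test_all_extreme_fa_rejected(self):
        with pytest.raises(ValidationError):
            median_effect_fit([1e-8, 1e-7], [0.0, 1.0])


class TestScores:
    def test_hsa_zero_on_own_reference(self):
        m = generate_dose_matrix(FIT_A, FIT_B, "hsa_null")
        assert hsa_score(m) == pytest.approx(0.0, abs=1e-6)

    def test_hsa_constant_excess(self):
        m = generate_dose_matrix(FIT_A, FIT_B, "hsa_null", boost=0.15)
        assert hsa_score(m) == pytest.approx(15.0, abs=1e-9)

    def test_loewe_zero_on_own_reference(self):
        m = generate_dose_matrix(FIT_A, FIT_B, "loewe_additive")
        assert loewe_score(m, FIT_A, FIT_B) == pytest.approx(0.0, abs=1e-6)

    def test_sham_combination_matches_double_dose(self):
        from recurcor.synergy import loewe_expected

        for d in (1e-8, 1e-7, 1e-6):
            expected = loewe_expected(d, d, FIT_A, FIT_A)
            assert expected == pytest.approx(FIT_A.predict(2 * d), rel=1e-7)

    def test_both_scores_shift_by_constant(self):
        m0 = generate_dose_matrix(FIT_A, FIT_B, "loewe_additive")
        m1 = DoseResponseMatrix(
            m0.conc_a, m0.conc_b, m0.inhibition + 0.07, m0.mono_a, m0.mono_b
        )
        assert hsa_score(m1) - hsa_score(m0) == pytest.approx(7.0, abs=1e-9)
        assert loewe_score(m1, FIT_A, FIT_B) - loewe_score(
            m0, FIT_A, FIT_B
        ) == pytest.approx(7.0, abs=1e-9)


class TestCombinationIndex:
    def test_sham_ci_is_one(self):
        m = generate_dose_matrix(FIT_A, FIT_A, "loewe_additive")
        ci, extrapolated = combination_index_at_effect(m)
        assert not extrapolated
        assert ci == pytest.approx(1.0, abs=1e-3)

    def test_nearest_fa_flagged_when_unbracketed(self):
        weak = FourPLFit(bottom=0.0, top=0.45, ec50=1e-7, hill=1.0)
        m = generate_dose_matrix(weak, weak, "loewe_additive")
        ci, extrapolated = combination_index_at_effect(m, effect=0.75)
        assert extrapolated

    def test_synergistic_surface_scores_below_threshold(self):
        m = generate_dose_matrix(FIT_A, FIT_B, "loewe_additive", boost=0.2)
        report = score_matrix(m)
        assert report.loewe_score == pytest.approx(20.0, abs=1e-6)
        assert report.calls["loewe"] and report.calls["hsa"]


class TestDoseMatrixIO:
    def test_round_trip(self, tmp_path):
        m = generate_dose_matrix(FIT_A, FIT_B, "loewe_additive")
        path = tmp_path / "matrix.csv"
        write_dose_matrix(m, path)
        back = read_dose_matrix(path)
        np.testing.assert_allclose(back.inhibition, m.inhibition, rtol=1e-12)
        np.testing.assert_allclose(back.conc_a, m.conc_a)
        np.testing.assert_allclose(back.mono_b, m.mono_b)

    def test_missing_zero_dose_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame(np.ones((4, 4))).to_csv(path, header=False, index=False)
        with pytest.raises(ValidationError, match="zero-dose"):
            read_dose_matrix(path)

    def test_unsorted_concentrations_rejected(self):
        with pytest.raises(ValidationError):
            DoseResponseMatrix(
                conc_a=[2e-6, 1e-6],
                conc_b=[1e-6, 2e-6],
                inhibition=np.zeros((2, 2)),
                mono_a=[0.1, 0.2],
                mono_b=[0.1, 0.2],
            )
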