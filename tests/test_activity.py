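"""Scoring: fractional conversion, hit calling, Z-factor, titration fit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oximsi.activity import (
    ConversionRecord,
    InsufficientControlsError,
    call_hits,
    control_stats,
    dose_response_fit,
    fractional_conversion,
    hit_table,
    records_from_intensities,
    summarize_screen,
    z_factor,
)
from oximsi.profiles import truth_from_observed_ratios
from oximsi.simulate import NoiseModel, ion_amounts, make_design, simulate_intensities


def _rec(donor, acceptor, replicate, ratio, enzyme="E", evaluable=True):
    return ConversionRecord(
        well_id=f"{enzyme}|{donor}|{acceptor}|r{replicate}",
        enzyme=enzyme, donor=donor, acceptor=acceptor, replicate=replicate,
        I_product=math.nan, I_acceptor=math.nan, ratio=ratio,
        evaluable=evaluable,
    )


class TestFractionalConversion:
    @pytest.mark.parametrize("ip,ia,expected", [
        (0.0, 100.0, 0.0),
        (50.0, 50.0, 0.5),
        (3.0, 3.0, 0.5),
        (100.0, 0.0, 1.0),
    ])
    def test_examples(self, ip, ia, expected):
        assert fractional_conversion(ip, ia) == pytest.approx(expected)

    def test_both_zero_is_undefined_not_zero(self):
        assert math.isnan(fractional_conversion(0.0, 0.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fractional_conversion(-1.0, 2.0)

    @settings(max_examples=200, deadline=None)
    @given(
        ip=st.floats(0.0, 1e6),
        ia=st.floats(1e-6, 1e6),
        k=st.floats(1e-6, 1e6),
    )
    def test_scale_invariance(self, ip, ia, k):
        r1 = fractional_conversion(ip, ia)
        r2 = fractional_conversion(k * ip, k * ia)
        assert r2 == pytest.approx(r1, rel=1e-9, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(ia=st.floats(1e-3, 1e3), ip=st.floats(0.0, 1e3),
           delta=st.floats(1e-3, 1e3))
    def test_strictly_increasing_in_product(self, ia, ip, delta):
        assert fractional_conversion(ip + delta, ia) > fractional_conversion(ip, ia)


class TestControlStats:
    def test_constant_and_hand_computed(self):
        recs = [_rec("none", "akg", i, r) for i, r in enumerate([0.02, 0.02, 0.02])]
        assert control_stats(recs) == (pytest.approx(0.02), pytest.approx(0.0), 3)
        recs = [_rec("none", "akg", i, r) for i, r in enumerate([0.01, 0.02, 0.03])]
        mean, sd, n = control_stats(recs)
        assert (mean, sd, n) == (pytest.approx(0.02), pytest.approx(0.01), 3)

    def test_undefined_ratio_dropped_with_warning(self):
        recs = [_rec("none", "akg", 1, 0.01), _rec("none", "akg", 2, math.nan),
                _rec("none", "akg", 3, 0.03)]
        with pytest.warns(UserWarning, match="undefined ratio"):
            mean, sd, n = control_stats(recs)
        assert n == 2
        assert mean == pytest.approx(0.02)

    def test_insufficient_controls(self):
        with pytest.raises(InsufficientControlsError):
            control_stats([_rec("none", "akg", 1, 0.01)])


class TestZFactor:
    def test_zero_variance_gives_one(self):
        assert z_factor([0.5, 0.5, 0.5], [0.02, 0.02, 0.02]) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        """means 0.5/0.02, SDs 0.02/0.01 -> 1 - 3(0.03)/0.48 = 0.8125."""
        pos = [0.48, 0.50, 0.52]  # mean 0.5, sample SD 0.02
        neg = [0.01, 0.02, 0.03]  # mean 0.02, sample SD 0.01
        assert z_factor(pos, neg) == pytest.approx(0.8125)

    def test_negative_for_noisy_assay(self):
        assert z_factor([0.5, 0.1, 0.9], [0.0, 0.4, 0.2]) < 0

    def test_equal_means_undefined(self):
        with pytest.warns(UserWarning, match="coincide"):
            assert math.isnan(z_factor([0.1, 0.3], [0.3, 0.1]))

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=8),
           st.lists(st.floats(0, 1), min_size=2, max_size=8))
    def test_matches_closed_form(self, pos, neg):
        p, n = np.array(pos), np.array(neg)
        if abs(p.mean() - n.mean()) < 1e-12:
            return
        expected = 1 - 3 * (p.std(ddof=1) + n.std(ddof=1)) / abs(p.mean() - n.mean())
        assert z_factor(pos, neg) == pytest.approx(expected, rel=1e-12, abs=1e-12)
        assert z_factor(pos, neg) <= 1.0


class TestCallHits:
    def _controls(self, ratios=(0.02, 0.02, 0.02), acceptor="akg"):
        return [_rec("none", acceptor, i + 1, r) for i, r in enumerate(ratios)]

    def test_clear_hit(self):
        recs = self._controls((0.01, 0.02, 0.03)) + [
            _rec("Leu", "akg", i, r) for i, r in enumerate([0.49, 0.5, 0.51])
        ]
        calls = call_hits(recs)
        call = calls[0]
        assert call.active and call.passes_ratio_threshold and call.passes_sd_threshold
        assert call.mean_ratio == pytest.approx(0.5)
        assert not math.isnan(call.z_factor)

    def test_fails_ratio_threshold(self):
        recs = self._controls((0.0, 0.0, 0.0)) + [
            _rec("Gly", "akg", i, 0.09) for i in range(3)
        ]
        call = call_hits(recs)[0]
        assert call.passes_sd_threshold and not call.passes_ratio_threshold
        assert not call.active

    def test_fails_sd_threshold(self):
        """mean 0.15 vs control (0.10, 0.01): 0.15 < 0.10 + 10 x 0.01."""
        recs = self._controls((0.09, 0.10, 0.11)) + [
            _rec("Gly", "akg", i, 0.15) for i in range(3)
        ]
        call = call_hits(recs)[0]
        assert call.passes_ratio_threshold and not call.passes_sd_threshold
        assert not call.active

    def test_strict_inequalities(self):
        # 0.125 is exactly representable, so mean == threshold exactly
        recs = self._controls((0.0, 0.0, 0.0)) + [
            _rec("Gly", "akg", i, 0.125) for i in range(3)
        ]
        assert not call_hits(recs, ratio_threshold=0.125)[0].active

    def test_degenerate_combination_reported_not_called(self):
        recs = self._controls() + [
            _rec("Glu", "akg", i, math.nan, evaluable=False) for i in range(3)
        ]
        call = call_hits(recs)[0]
        assert not call.evaluable and not call.active
        assert call.reason == "not_evaluable"

    def test_too_few_replicates_is_missing_not_inactive(self):
        recs = self._controls() + [_rec("Gly", "akg", 1, 0.5)]
        call = call_hits(recs)[0]
        assert not call.evaluable
        assert call.reason == "insufficient_replicates"

    def test_threshold_sensitivity_recall(self):
        """Re-calling at 0.05 surfaces borderline combinations separately."""
        recs = self._controls((0.001, 0.002, 0.003)) + [
            _rec("Val", "akg", i, r) for i, r in enumerate([0.07, 0.08, 0.07])
        ] + [_rec("Leu", "akg", i, r) for i, r in enumerate([0.5, 0.5, 0.5])]
        strict = {(c.donor, c.acceptor): c.active for c in call_hits(recs, 0.1)}
        relaxed = {(c.donor, c.acceptor): c.active for c in call_hits(recs, 0.05)}
        assert strict[("Leu", "akg")] and relaxed[("Leu", "akg")]
        assert not strict[("Val", "akg")] and relaxed[("Val", "akg")]


class TestFalsePositiveControl:
    def test_zero_planted_activity_zero_hits_100_seeds(self, panel, probe):
        """Default noise, no activity: the dual rule never fires."""
        from oximsi.chem import build_target_panel
        from oximsi.simulate import TruthProfile

        donors = ["Leu", "Gly", "Thr", "Val"]
        targets = build_target_panel([panel[d] for d in donors],
                                     [panel["alpha-KG"]], probe)
        design = make_design(["E"], donors, ["alpha-KG"])
        amounts = ion_amounts(design, TruthProfile(), targets)
        n_active = 0
        for seed in range(100):
            table = simulate_intensities(design, amounts, NoiseModel(seed=seed))
            records = records_from_intensities(table, design, targets, amounts)
            n_active += sum(c.active for c in call_hits(records))
        assert n_active == 0


class TestSummarize:
    def test_counts(self):
        controls = [_rec("none", a, i + 1, 0.01)
                    for a in ("akg", "pyr") for i in range(3)]
        recs = controls
        recs += [_rec("Trp", "akg", i, 0.5) for i in range(3)]
        recs += [_rec("Trp", "pyr", i, 0.4) for i in range(3)]
        recs += [_rec("Gly", "akg", i, 0.01) for i in range(3)]
        calls = call_hits(recs)
        summary = summarize_screen(calls)["E"]
        assert summary["n_active_donors"] == 1
        assert summary["n_active_acceptors"] == 2
        assert summary["active_donors"] == ["Trp"]

    def test_no_hits(self):
        recs = [_rec("none", "akg", i + 1, 0.01) for i in range(3)]
        recs += [_rec("Gly", "akg", i, 0.02) for i in range(3)]
        summary = summarize_screen(call_hits(recs))["E"]
        assert summary["n_active_donors"] == 0
        assert summary["n_active_acceptors"] == 0


class TestDoseResponseFit:
    def test_noiseless_self_consistency(self):
        x = np.array([0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 10.0])
        y = 0.1705 * x / (0.8468 + x)
        fit = dose_response_fit(x, y)
        assert fit.vmax == pytest.approx(0.1705, abs=1e-6)
        assert fit.km == pytest.approx(0.8468, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_noisy_titration_recovery(self):
        """Noise SD 0.02 on the hyperbola: Vmax recovered within 0.03."""
        rng = np.random.default_rng(2023)
        x = np.repeat([0.0, 0.1, 0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0], 3)
        y = np.clip(0.1705 * x / (0.8468 + x) + rng.normal(0, 0.02, x.size), 0, None)
        fit = dose_response_fit(x, y)
        assert abs(fit.vmax - 0.1705) <= 0.03
        assert 0.0 <= fit.r_squared <= 1.0

    def test_all_zero_flagged(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        fit = dose_response_fit(x, np.zeros_like(x))
        assert fit.vmax == 0.0 and fit.flagged

    def test_too_few_concentrations(self):
        with pytest.raises(ValueError):
            dose_response_fit([1.0, 1.0, 2.0], [0.1, 0.1, 0.2])

    def test_fitted_curve_monotone(self):
        rng = np.random.default_rng(5)
        x = np.array([0.0, 0.5, 1.0, 2.0, 5.0, 10.0])
        y = 0.3 * x / (1.0 + x) + rng.normal(0, 0.01, x.size)
        fit = dose_response_fit(x, np.clip(y, 0, None))
        grid_x = np.linspace(0, 10, 50)
        curve = fit.vmax * grid_x / (fit.km + grid_x)
        assert (np.diff(curve) >= 0).all()


class TestRecordsFromIntensities:
    def test_simulated_screen_scores_planted_pattern(self, panel, probe):
        from oximsi.chem import build_target_panel

        donors = ["Leu", "Gly", "Ala"]
        targets = build_target_panel([panel[d] for d in donors],
                                     [panel["alpha-KG"]], probe)
        design = make_design(["E"], donors, ["alpha-KG"])
        truth = truth_from_observed_ratios("E", {("Leu", "alpha-KG"): 0.5})
        amounts = ion_amounts(design, truth, targets)
        table = simulate_intensities(design, amounts, NoiseModel(seed=1))
        records = records_from_intensities(table, design, targets, amounts)
        calls = {c.donor: c for c in call_hits(records)}
        assert calls["Leu"].active
        assert calls["Leu"].mean_ratio == pytest.approx(0.5, abs=0.05)
        assert not calls["Gly"].active and not calls["Ala"].active
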