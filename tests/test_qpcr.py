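import numpy as np
import pandas as pd
import pytest

from perconet import (
    efficiency_from_slope,
    enrichment_test,
    fit_standard_curve,
    generate_qpcr,
    quantify,
)

CANONICAL_SLOPE = -3.3219  # perfect doubling per cycle


def perfect_ladder(slope=CANONICAL_SLOPE, intercept=38.0):
    return generate_qpcr({}, ct_sd=0.0, replicates=2, seed=0,
                         slope=slope, intercept=intercept).standards


class TestStandardCurve:
    def test_perfect_doubling_efficiency(self):
        curve = fit_standard_curve(perfect_ladder())
        assert curve.efficiency == pytest.approx(1.0, abs=1e-4)
        assert curve.r2 == pytest.approx(1.0, abs=1e-12)
        assert curve.qc_passed

    def test_low_efficiency_fails_gate(self):
        curve = fit_standard_curve(perfect_ladder(slope=-3.9))
        assert curve.efficiency == pytest.approx(10 ** (1 / 3.9) - 1, abs=1e-12)
        assert not curve.qc["efficiency_ok"]
        assert curve.qc["r2_ok"]

    def test_noisy_series_recovers_efficiency_within_two_points(self):
        run = generate_qpcr({}, ct_sd=0.1, replicates=3, seed=11,
                            slope=CANONICAL_SLOPE, intercept=38.0,
                            ladder_log10=(1, 2, 3, 4, 5, 6))
        curve = fit_standard_curve(run.standards)
        assert abs(curve.efficiency - 1.0) <= 0.02

    def test_efficiency_recomputable_from_slope(self):
        curve = fit_standard_curve(perfect_ladder(slope=-3.5))
        assert curve.efficiency == pytest.approx(
            efficiency_from_slope(curve.slope), abs=1e-12
        )

    def test_positive_slope_rejected(self):
        std = perfect_ladder()
        std["ct"] = -std["ct"]
        with pytest.raises(ValueError, match="invalid standard curve"):
            fit_standard_curve(std)

    def test_too_few_concentrations_rejected(self):
        std = pd.DataFrame({"known_log10_copies": [2, 2, 4, 4],
                            "ct": [31, 31, 24.4, 24.4]})
        with pytest.raises(ValueError, match="3 distinct"):
            fit_standard_curve(std)

    def test_summary_mentions_verdict(self):
        assert "PASS" in fit_standard_curve(perfect_ladder()).summary()


def unknowns_frame(ct, dilution=1.0, mass=1.0):
    return pd.DataFrame({
        "sample_id": ["x"], "timepoint": [0], "ct": [ct], "replicate": [0],
        "dilution_factor": [dilution], "mass_or_volume": [mass],
        "units": ["g"],
    })


class TestQuantify:
    def _curve(self, slope=-3.5, intercept=38.0):
        return fit_standard_curve(perfect_ladder(slope=slope, intercept=intercept))

    def test_worked_example(self):
        curve = self._curve(slope=-3.5, intercept=38.0)
        res = quantify(curve, unknowns_frame(20.0), force=True)
        assert res.replicates["copies_per_unit"].iloc[0] == pytest.approx(
            10 ** (18 / 3.5), rel=1e-9
        )

    def test_dilution_and_mass_scaling(self):
        curve = self._curve(slope=-3.5)
        res = quantify(curve, unknowns_frame(20.0, dilution=10.0, mass=0.5),
                       force=True)
        assert res.replicates["copies_per_unit"].iloc[0] == pytest.approx(
            10 ** (18 / 3.5) * 10 / 0.5, rel=1e-9
        )

    def test_relevance_flag_below_threshold(self):
        curve = self._curve(slope=CANONICAL_SLOPE)
        # Ct of 5e2 copies: 38 + slope*log10(500)
        ct = 38.0 + CANONICAL_SLOPE * np.log10(500)
        res = quantify(curve, unknowns_frame(ct))
        assert not res.means["relevance_flag"].iloc[0]
        ct_hot = 38.0 + CANONICAL_SLOPE * np.log10(2e3)
        res2 = quantify(curve, unknowns_frame(ct_hot))
        assert res2.means["relevance_flag"].iloc[0]

    def test_late_ct_flagged(self):
        curve = self._curve(slope=CANONICAL_SLOPE)
        res = quantify(curve, unknowns_frame(31.0))
        assert res.replicates["ct_flagged"].iloc[0]
        res_ok = quantify(curve, unknowns_frame(30.0))
        assert not res_ok.replicates["ct_flagged"].iloc[0]

    def test_failed_qc_requires_force(self):
        curve = self._curve(slope=-3.9)
        with pytest.raises(ValueError, match="failed QC"):
            quantify(curve, unknowns_frame(20.0))
        assert quantify(curve, unknowns_frame(20.0), force=True)

    def test_noiseless_round_trip_exact(self):
        truth = {("PENF", 2): 5.0e1, ("PENF", 8): 2.35e6}
        run = generate_qpcr(truth, ct_sd=0.0, replicates=3, seed=0)
        curve = fit_standard_curve(run)
        res = quantify(curve, run)
        for (_, t), copies in truth.items():
            got = res.means.loc[res.means["timepoint"] == t,
                                "copies_per_unit"].iloc[0]
            assert got == pytest.approx(copies, rel=1e-9)

    def test_noisy_round_trip_within_fifteen_percent(self):
        truth = {("PENF", t): 10.0 ** (2 + 0.5 * t) for t in range(6)}
        run = generate_qpcr(truth, ct_sd=0.1, replicates=3, seed=4)
        curve = fit_standard_curve(run)
        res = quantify(curve, run)
        for (_, t), copies in truth.items():
            got = res.means.loc[res.means["timepoint"] == t,
                                "copies_per_unit"].iloc[0]
            assert abs(got - copies) / copies <= 0.15


class TestEnrichmentTest:
    def test_identical_timepoints_are_null(self):
        frame = pd.DataFrame({
            "sample_id": "x", "timepoint": [0, 0, 0, 1, 1, 1],
            "copies_per_unit": [1e4, 2e4, 1.5e4, 1e4, 2e4, 1.5e4],
        })
        res = enrichment_test(frame)
        assert res["log10_fold_change"] == 0.0
        assert res["p_ttest"] == pytest.approx(1.0, abs=0.05)

    def test_five_log_increase_detected(self):
        rng = np.random.default_rng(3)
        rows = []
        for t, mean in ((2, 5.00e1), (8, 2.35e6)):
            logs = np.log10(mean) + rng.normal(0, 0.1, 3)
            for c in 10.0 ** logs:
                rows.append({"sample_id": "PENF", "timepoint": t,
                             "copies_per_unit": c})
        res = enrichment_test(pd.DataFrame(rows))
        assert res["log10_fold_change"] == pytest.approx(
            np.log10(2.35e6 / 5.00e1), abs=0.15
        )
        assert res["p_ttest"] < 1e-4
        assert res["p_anova"] < 1e-4

    def test_single_replicate_rejected(self):
        frame = pd.DataFrame({
            "sample_id": "x", "timepoint": [0, 1],
            "copies_per_unit": [1e2, 1e6],
        })
        with pytest.raises(ValueError, match="2 replicates"):
            enrichment_test(frame)

    def test_zero_baseline_warns_infinite_fold(self):
        frame = pd.DataFrame({
            "sample_id": "x", "timepoint": [0, 0, 1, 1],
            "copies_per_unit": [0.0, 0.0, 1e5, 2e5],
        })
        with pytest.warns(UserWarning, match="infinite"):
            res = enrichment_test(frame)
        assert np.isinf(res["log10_fold_change"])
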