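import io
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import hmcpeaks as h
from hmcpeaks.qpcr import AssayDefinition, QpcrAssay


def make_curve(efficiency=1.0, ct0=20.0, dilutions=(1.0, 0.1, 0.01)):
    slope = -1.0 / math.log10(1.0 + efficiency)
    points = [(d, ct0 + slope * math.log10(d)) for d in dilutions]
    return h.fit_standard_curve(points)


def make_assay(delta_ct, efficiency=1.0, n_reps=4, locus="Cox4",
               pair="MspI/HpaII", stage=None):
    curve = make_curve(efficiency)
    return QpcrAssay(
        AssayDefinition(pair, pair), locus,
        tuple(24.0 + delta_ct for _ in range(n_reps)),
        tuple(24.0 for _ in range(n_reps)),
        curve, stage,
    )


class TestStandardCurve:
    def test_perfect_doubling(self):
        curve = h.fit_standard_curve(
            [(1, 20.0), (0.1, 23.3219), (0.01, 26.6439)]
        )
        assert curve.slope == pytest.approx(-3.3219, abs=5e-4)
        assert curve.efficiency == pytest.approx(1.00, abs=2e-4)

    def test_slope_minus_3_9(self):
        curve = make_curve(efficiency=10 ** (1 / 3.9) - 1)
        assert curve.slope == pytest.approx(-3.9, rel=1e-9)
        assert curve.efficiency == pytest.approx(10 ** (1 / 3.9) - 1, rel=1e-9)
        assert round(curve.efficiency, 3) == 0.805

    def test_two_dilutions_rejected(self):
        with pytest.raises(h.ValidationError):
            h.fit_standard_curve([(1, 20.0), (0.1, 23.3)])

    def test_positive_slope_rejected(self):
        with pytest.raises(h.ValidationError, match="slope"):
            h.fit_standard_curve([(1, 26.0), (0.1, 23.0), (0.01, 20.0)])

    def test_out_of_range_efficiency_flagged(self):
        curve = make_curve(efficiency=0.3)
        assert curve.warnings

    @given(st.floats(0.6, 1.2))
    @settings(max_examples=30, deadline=None)
    def test_noiseless_fit_recovers_efficiency(self, efficiency):
        curve = make_curve(efficiency)
        assert curve.efficiency == pytest.approx(efficiency, rel=1e-9)


class TestModificationPercent:
    def test_zero_delta_ct_is_100(self):
        for e in (0.7, 1.0, 1.2):
            assert h.modification_percent(make_assay(0.0, e)).percent == 100.0

    def test_one_perfect_doubling_is_50(self):
        assert h.modification_percent(make_assay(1.0, 1.0)).percent == pytest.approx(
            50.0, rel=1e-12
        )

    def test_ten_percent_anchor(self):
        r = h.modification_percent(make_assay(3.3219, 1.0))
        assert round(r.percent, 1) == 10.0

    def test_negative_delta_ct_clamped_with_flag(self):
        r = h.modification_percent(make_assay(-0.8, 1.0))
        assert r.percent == 100.0
        assert any("negative delta-CT" in f for f in r.flags)

    def test_few_replicates_flagged(self):
        r = h.modification_percent(make_assay(1.0, 1.0, n_reps=3))
        assert any("replicates" in f for f in r.flags)

    def test_missing_curve_rejected(self):
        assay = QpcrAssay(
            AssayDefinition("x", "MspI/HpaII"), "Cox4",
            (24.0,), (23.0,), None,
        )
        with pytest.raises(h.ValidationError, match="curve"):
            h.modification_percent(assay)

    @given(
        st.floats(0.6, 1.2),
        st.floats(0.1, 6.0),
        st.floats(0.1, 6.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_strictly_decreasing_in_delta_ct(self, e, d1, d2):
        if abs(d1 - d2) < 1e-9:
            return
        lo, hi = sorted((d1, d2))
        p_lo = h.modification_percent(make_assay(hi, e)).percent
        p_hi = h.modification_percent(make_assay(lo, e)).percent
        assert p_lo < p_hi

    def test_decreasing_in_efficiency_for_positive_delta(self):
        percents = [
            h.modification_percent(make_assay(2.0, e)).percent
            for e in (0.6, 0.8, 1.0, 1.2)
        ]
        assert percents == sorted(percents, reverse=True)

    @given(st.floats(0.6, 1.2), st.floats(0.001, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_inverts_generation_model(self, e, fraction):
        delta = h.invert_fraction_to_delta_ct(fraction, e)
        r = h.modification_percent(make_assay(delta, e))
        assert r.percent == pytest.approx(100 * fraction, rel=1e-9)


class TestBatchReport:
    def test_identical_cts_have_zero_sd(self):
        assays = [make_assay(1.0, 1.0, stage="adults") for _ in range(4)]
        report = h.batch_report(assays)
        assert len(report) == 1
        assert report.loc[0, "percent_sd"] == 0.0
        assert report.loc[0, "n"] == 4

    def test_empty_input(self):
        report = h.batch_report([])
        assert report.empty

    def test_simulated_replicates_recover_true_percent(self):
        true_fraction = 0.4
        spec = h.QpcrSimSpec(
            true_fraction={
                ("Cox4", "MspI/HpaII", f"s{i}"): true_fraction
                for i in range(40)
            },
            efficiency=1.0,
            ct_noise_sd=0.1,
            seed=6,
        )
        ct_csv, curve_csv = h.simulate_qpcr(spec)
        assays = h.assays_from_frames(
            pd.read_csv(io.StringIO(ct_csv)), pd.read_csv(io.StringIO(curve_csv))
        )
        report = h.batch_report(assays)
        percents = report["percent_mean"].to_numpy()
        spread = percents.std(ddof=1)
        assert abs(percents.mean() - 100 * true_fraction) <= 3 * spread / np.sqrt(
            len(percents)
        ) + 1e-9


class TestAssayTable:
    def test_known_pairs(self):
        assert h.ASSAY_TABLE["MspI/HpaII"] == ("CCGG", "5mC_CpG_CCGG")
        assert h.ASSAY_TABLE["TaqI/HpyF30I"] == ("TCGA", "5mC_CpG_TCGA")
        assert h.ASSAY_TABLE["T4-BGT+EpiMspI"] == ("CCGG", "5hmC_CCGG")

    def test_unknown_pair_rejected(self):
        with pytest.raises(h.ValidationError):
            AssayDefinition("x", "EcoRI/BamHI")

    def test_ct_out_of_range_rejected(self):
        with pytest.raises(h.ValidationError):
            QpcrAssay(
                AssayDefinition("x", "MspI/HpaII"), "Cox4",
                (50.0,), (24.0,), make_curve(),
            )
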