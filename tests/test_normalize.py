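"""Background subtraction, standard-curve fitting, fold changes and the
per-gene summary."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from glycoscreen import (
    DegenerateStatError,
    PlateQCError,
    ScreenDataset,
    delta_t48,
    fit_standard_curve,
    fold_change_vs_plate_control,
    lactate_per_cell,
    normalize_wells,
    subtract_background,
    summarize_genes,
)
from glycoscreen.normalize import plate_control_stats


class TestSubtractBackground:
    def test_subtracts_mean_of_background_wells(self):
        assert subtract_background([0.50], [0.09, 0.11])[0] == pytest.approx(0.40)

    def test_raw_equal_to_background_gives_zero(self):
        assert subtract_background([0.10], [0.10])[0] == 0.0

    def test_negative_values_retained_not_clamped(self):
        out = subtract_background([0.05], [0.10])
        assert out[0] == pytest.approx(-0.05)

    def test_no_background_wells_is_an_error(self):
        with pytest.raises(PlateQCError, match="background"):
            subtract_background([0.5], [])


class TestStandardCurve:
    def test_two_point_line_maps_midpoint(self):
        pts = pd.DataFrame({"concentration_nM": [0.0, 1000.0], "absorbance": [0.0, 0.8]})
        curve = fit_standard_curve(pts)
        assert curve.to_concentration(0.4) == pytest.approx(500.0)

    def test_collinear_points_have_unit_r_squared(self):
        pts = pd.DataFrame({"concentration_nM": [0, 500, 1000],
                            "absorbance": [0.1, 0.5, 0.9]})
        assert fit_standard_curve(pts).r_squared == pytest.approx(1.0)

    def test_single_concentration_rejected(self):
        pts = pd.DataFrame({"concentration_nM": [500, 500], "absorbance": [0.4, 0.5]})
        with pytest.raises(DegenerateStatError, match="distinct"):
            fit_standard_curve(pts)

    def test_negative_slope_rejected(self):
        pts = pd.DataFrame({"concentration_nM": [0, 1000], "absorbance": [0.8, 0.1]})
        with pytest.raises(DegenerateStatError, match="slope"):
            fit_standard_curve(pts)

    def test_noisy_generated_curve_recovers_configured_slope(self, small_screen):
        cfg, ds, _ = small_screen
        curve = fit_standard_curve(ds.standard_curve)
        assert abs(curve.slope - cfg.baseline.curve_slope) < 2 * curve.slope_stderr + 1e-12


class TestPerWellMetrics:
    def test_lactate_per_cell_arithmetic(self):
        assert lactate_per_cell(500.0, 1000) == pytest.approx(0.5)
        assert lactate_per_cell(0.0, 1000) == 0.0

    def test_zero_count_flagged_as_nan(self):
        assert np.isnan(lactate_per_cell(500.0, 0))

    @pytest.mark.parametrize(
        "t48,t0,expected", [(900, 450, 450), (450, 450, 0), (300, 450, -150)]
    )
    def test_delta_t48_signed(self, t48, t0, expected):
        assert delta_t48(t48, t0) == expected

    def test_fold_change_examples(self):
        assert fold_change_vs_plate_control(100.0, [90, 100, 110])[()] == pytest.approx(1.0)
        assert fold_change_vs_plate_control(50.0, [90, 100, 110])[()] == pytest.approx(0.5)

    def test_negative_delta_keeps_sign(self):
        # dying well against proliferating controls: FC is legitimately negative
        fc = fold_change_vs_plate_control(-150.0, [450.0, 450.0], signed=True)
        assert fc[()] == pytest.approx(-1 / 3)

    def test_nonpositive_control_mean_fails_plate_qc(self):
        with pytest.raises(PlateQCError, match="QC"):
            fold_change_vs_plate_control(100.0, [-10.0, 5.0], signed=True)


class TestSummarizeGenes:
    def test_control_fold_changes_center_at_one_exactly(self, small_screen):
        _, ds, _ = small_screen
        wells = normalize_wells(ds)
        otp = wells[wells["content_class"] == "control_OTP"]
        means = otp.groupby(["plate_id", "replicate", "arm"])[
            ["fc_t48", "fc_dt48", "fc_lactate"]
        ].mean()
        assert np.allclose(means.to_numpy(), 1.0, atol=1e-12)

    def test_replicate_averaging_is_arithmetic_mean(self, small_screen):
        _, ds, _ = small_screen
        wells = normalize_wells(ds)
        summ, _ = summarize_genes(ds)
        g = wells[wells["gene_id"] == "GENE00000"]
        expect = g[g["arm"] == "DMSO"]["fc_t48"].mean()
        got = summ.loc[summ["gene_id"] == "GENE00000", "fc_t48_dmso"].iloc[0]
        assert got == pytest.approx(expect, rel=1e-12)

    def test_fold_changes_invariant_to_plate_scale(self, small_screen):
        """Multiplying every count on one plate by c leaves FCs unchanged."""
        _, ds, _ = small_screen
        before = normalize_wells(ds)
        m = ds.measurements.copy()
        sel = m["plate_id"] == "P01"
        m.loc[sel, "cell_count"] = (m.loc[sel, "cell_count"] * 3).astype(int)
        after = normalize_wells(ScreenDataset(ds.plate_maps, m, ds.standard_curve))
        for col in ("fc_t48", "fc_dt48"):
            np.testing.assert_allclose(after[col], before[col], rtol=1e-12)

    def test_pdk1_control_recovers_low_lactate_archetype(self, small_summary):
        summ, _ = small_summary
        pdk1 = summ[summ["content_class"] == "control_PDK1"].iloc[0]
        assert pdk1["fc_lactate_dmso"] < 1.0
        assert pdk1["fc_lactate_vem"] < 1.0

    def test_plk1_control_shows_cell_death(self, small_summary):
        summ, _ = small_summary
        plk1 = summ[summ["content_class"] == "control_PLK1"].iloc[0]
        assert plk1["fc_dt48_dmso"] < 0  # net cell loss vs growing controls

    def test_low_count_flag_is_per_arm(self, small_summary):
        summ, _ = small_summary
        lib = summ[summ["content_class"] == "library"]
        for arm in ("dmso", "vem"):
            expect = lib[f"fc_t48_{arm}"] < 0.2
            assert (lib[f"qc_low_count_{arm}"] == expect).all()

    def test_gene_on_two_plates_rejected(self, small_screen):
        _, ds, _ = small_screen
        pm = ds.plate_maps.copy()
        # clone a P01 gene onto P02
        g = pm[(pm.plate_id == "P01") & (pm.content_class == "library")].iloc[0]
        tgt = (pm.plate_id == "P02") & (pm.content_class == "library")
        pm.loc[pm.index[tgt][0], "gene_id"] = g["gene_id"]
        ds2 = ScreenDataset(pm, ds.measurements, ds.standard_curve)
        with pytest.raises(Exception, match="multiple plates"):
            summarize_genes(ds2)

    def test_control_stats_counts_match_layout(self, small_screen):
        _, ds, _ = small_screen
        stats = plate_control_stats(normalize_wells(ds))
        n = stats.set_index("content_class")["n"]
        assert set(n.loc["control_OTP"]) == {16}
        assert set(n.loc["control_PLK1"]) == {8}
        assert set(n.loc["control_PDK1"]) == {8}

    def test_noiseless_lactate_round_trip(self, zero_noise_neutral_screen):
        """curve inversion recovers the configured true lactate exactly."""
        cfg, ds, _ = zero_noise_neutral_screen
        wells = normalize_wells(ds)
        lib = wells[(wells["content_class"] == "library") & (wells["arm"] == "DMSO")]
        true = cfg.baseline.lactate_per_cell_nM * lib["cell_count"]
        np.testing.assert_allclose(lib["lactate_nM"], true, rtol=1e-9)


@given(c=st.floats(0.5, 20.0))
def test_fold_change_scale_invariance_property(c):
    vals = np.array([50.0, 100.0, 200.0])
    ctrl = np.array([90.0, 100.0, 110.0])
    np.testing.assert_allclose(
        fold_change_vs_plate_control(vals * c, ctrl * c),
        fold_change_vs_plate_control(vals, ctrl),
        rtol=1e-12,
    )
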