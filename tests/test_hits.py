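"""Robust z-scores, hit predicates and enhancer binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from glycoscreen import (
    DegenerateStatError,
    SchemaError,
    ThresholdConfig,
    bin_enhancers,
    call_hits,
    call_primary_hits,
    hit_report,
    robust_z,
    robust_z_scores,
    zscore_table,
)


def brute_force_robust_z(values, x):
    """Independent oracle: explicit sort-based median and MAD."""
    v = sorted(float(u) for u in values if np.isfinite(u))

    def median(s):
        n = len(s)
        s = sorted(s)
        return s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2

    med = median(v)
    mad = median([abs(u - med) for u in v])
    return (x - med) / (1.4826 * mad)


class TestRobustZ:
    def test_worked_example(self):
        # median 1.0, MAD 0.1 -> z = -0.9 / 0.14826
        values = [0.1, 0.9, 1.0, 1.0, 1.1, 2.0]
        assert robust_z(values, 0.1) == pytest.approx(-6.0704, abs=1e-3)

    def test_value_at_median_scores_zero(self):
        assert robust_z([0.5, 1.0, 1.5, 2.0, 4.0], 1.5) == 0.0

    def test_zero_mad_is_degenerate(self):
        with pytest.raises(DegenerateStatError, match="MAD"):
            robust_z([1, 1, 1, 1, 2], 1.0)

    def test_too_few_values_rejected(self):
        with pytest.raises(DegenerateStatError):
            robust_z([1.0, 2.0], 1.0)

    def test_nan_values_excluded_from_population(self):
        vals = [0.1, 0.9, 1.0, np.nan, 1.0, 1.1, 2.0, np.nan]
        assert robust_z(vals, 0.1) == pytest.approx(brute_force_robust_z(vals, 0.1))

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            v = rng.normal(1.0, 0.3, rng.integers(5, 60))
            x = float(rng.normal(1.0, 0.5))
            assert abs(robust_z(v, x) - brute_force_robust_z(v, x)) < 1e-12

    @given(st.lists(st.floats(-1e3, 1e3), min_size=5, max_size=40, unique=True))
    def test_vectorized_agrees_with_scalar(self, vals):
        z = robust_z_scores(vals)
        for i, v in enumerate(vals):
            assert z[i] == pytest.approx(robust_z(vals, v), abs=1e-12)


def make_summary(**cols):
    """Minimal library gene_summary with a wide-noise neutral population
    so a single probe gene's z-score is controlled by its own FC."""
    rng = np.random.default_rng(0)
    n = 200
    base = {
        "content_class": "library",
        "gene_id": [f"G{i:03d}" for i in range(n)],
        "reagent_id": "pool",
    }
    df = pd.DataFrame(base)
    for c in ("fc_t48_dmso", "fc_t48_vem", "fc_dt48_dmso", "fc_dt48_vem",
              "fc_lactate_dmso", "fc_lactate_vem"):
        df[c] = rng.normal(1.0, 0.1, n)
    for c, v in cols.items():
        df.loc[0, c] = v
    for arm in ("dmso", "vem"):
        df[f"qc_low_count_{arm}"] = df[f"fc_t48_{arm}"] < 0.2
    return df


class TestPrimaryHits:
    @pytest.mark.parametrize(
        "fc_dt48,expected", [(0.05, True), (0.10, False)],
        ids=["fc_passes", "fc_fails"],
    )
    def test_viability_predicate_needs_both_z_and_fc(self, fc_dt48, expected):
        summ = make_summary(fc_dt48_dmso=fc_dt48)
        ht, z = call_hits(summ)
        assert z.loc[0, "z_dt48_dmso"] < -1.5  # z criterion holds either way
        assert bool(ht.loc[0, "viability_hit"]) is expected

    def test_low_count_filter_vetoes_glycolysis_hit(self):
        summ = make_summary(fc_lactate_dmso=0.20, fc_t48_dmso=0.15)
        ht, z = call_hits(summ)
        assert z.loc[0, "z_lactate_dmso"] < -1.66
        assert not ht.loc[0, "glycolysis_hit"]
        # same lactate phenotype with enough cells is a hit
        summ2 = make_summary(fc_lactate_dmso=0.20, fc_t48_dmso=0.5)
        ht2, _ = call_hits(summ2)
        assert ht2.loc[0, "glycolysis_hit"]

    def test_cell_number_predicate(self):
        ht, _ = call_hits(make_summary(fc_t48_dmso=0.1))
        assert ht.loc[0, "cell_number_hit"]
        ht, _ = call_hits(make_summary(fc_t48_dmso=0.35))
        assert not ht.loc[0, "cell_number_hit"]

    def test_negative_dt48_fc_is_a_viability_hit(self):
        # net cell death is the strongest viability phenotype
        ht, _ = call_hits(make_summary(fc_dt48_dmso=-0.4))
        assert ht.loc[0, "viability_hit"]

    def test_missing_metric_column_is_schema_error(self):
        summ = make_summary().drop(columns=["fc_lactate_dmso"])
        with pytest.raises(SchemaError, match="fc_lactate_dmso"):
            call_hits(summ)

    def test_thresholds_are_strict_inequalities(self):
        cfg = ThresholdConfig()
        summ = make_summary(fc_dt48_dmso=cfg.viability_fc_max)  # exactly on boundary
        ht, _ = call_hits(summ, cfg)
        assert not ht.loc[0, "viability_hit"]

    def test_relaxing_thresholds_yields_superset(self, small_summary):
        summ, _ = small_summary
        tight, _ = call_hits(summ, ThresholdConfig())
        loose, _ = call_hits(
            summ,
            ThresholdConfig(cell_number_z_max=-1.0, cell_number_fc_max=0.5,
                            viability_z_max=-1.0, viability_fc_max=0.2,
                            glycolysis_z_max=-1.2, glycolysis_fc_max=0.7),
        )
        for flag in ("cell_number_hit", "viability_hit", "glycolysis_hit"):
            assert (loose[flag] | ~tight[flag]).all()  # tight => loose


class TestEnhancerBinning:
    def test_methods_scheme_example(self):
        summ = make_summary(fc_dt48_dmso=0.5, fc_dt48_vem=0.4,
                            fc_lactate_dmso=0.9, fc_lactate_vem=0.3)
        enh = bin_enhancers(summ)
        assert enh.loc[0, "enhancer_lactate"]
        assert enh.loc[0, "bin_label"] == "dt48=HH|lact=HL"

    def test_vem_lactate_guard(self):
        summ = make_summary(fc_dt48_dmso=0.5, fc_dt48_vem=0.4,
                            fc_lactate_dmso=0.9, fc_lactate_vem=0.6)
        assert not bin_enhancers(summ).loc[0, "enhancer_lactate"]

    def test_constitutive_glycolysis_gene_excluded_by_dmso_guard(self):
        summ = make_summary(fc_dt48_dmso=0.5, fc_dt48_vem=0.4,
                            fc_lactate_dmso=0.3, fc_lactate_vem=0.3)
        assert not bin_enhancers(summ).loc[0, "enhancer_lactate"]

    def test_figure1c_scheme_reverses_lactate_direction(self):
        summ = make_summary(fc_dt48_dmso=0.6, fc_dt48_vem=0.6,
                            fc_lactate_dmso=0.3, fc_lactate_vem=0.9)
        assert not bin_enhancers(summ, scheme="methods").loc[0, "enhancer_lactate"]
        assert bin_enhancers(summ, scheme="figure1c").loc[0, "enhancer_lactate"]

    def test_unknown_scheme_rejected(self):
        with pytest.raises(SchemaError, match="scheme"):
            bin_enhancers(make_summary(), scheme="fig9")


class TestHitReport:
    def test_empty_table_all_zero(self):
        empty = pd.DataFrame(
            {f: pd.Series(dtype=bool) for f in
             ("cell_number_hit", "viability_hit", "glycolysis_hit")}
        )
        rep = hit_report(empty)
        assert all(v == 0 for v in rep["counts"].values())

    def test_overlap_bounded_by_marginals_and_symmetric(self, small_summary):
        summ, _ = small_summary
        ht, _ = call_hits(summ)
        rep = hit_report(ht)
        ov = rep["overlap"]
        assert (ov.to_numpy() == ov.to_numpy().T).all()
        for a in ov.index:
            for b in ov.columns:
                assert ov.loc[a, b] <= min(rep["counts"][a], rep["counts"][b])
            assert ov.loc[a, a] == rep["counts"][a]

    def test_planted_lethal_recovery_within_binomial_ci(self, small_screen, small_summary):
        _, _, truth = small_screen
        summ, _ = small_summary
        ht, _ = call_hits(summ)
        t = ht.merge(truth, on="gene_id")
        n_lethal = int((t["class_name"] == "lethal").sum())
        got = int(t.loc[t["class_name"] == "lethal", "viability_hit"].sum())
        assert got >= n_lethal - max(3, int(3 * np.sqrt(n_lethal * 0.05)))
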