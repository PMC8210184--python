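"""Fold-change quantification, two-way ANOVA and concordance classification."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf
from hypothesis import given, settings
from hypothesis import strategies as st

from prcdeconv import (
    EmptyDesignError,
    aggregate_replicates,
    anova_genotype_p,
    classify_concordance,
    compute_log2fc,
    concordance_benchmark_config,
    normalize_samples,
    quantify_modulation,
    simulate_interactome,
)

from conftest import make_matrix


def two_sample_matrix(v1, v2):
    meta = [
        ("s1", "L1", "BMI1", "control", 1, 1, 0),
        ("s2", "L1", "BMI1", "control", 1, 2, 0),
    ]
    values = {f"P{i}": {"s1": a, "s2": b} for i, (a, b) in enumerate(zip(v1, v2))}
    return make_matrix(values, meta)


class TestNormalize:
    def test_none_is_identity(self, four_run_matrix):
        out = normalize_samples(four_run_matrix, "none")
        pd.testing.assert_frame_equal(out.values, four_run_matrix.values)

    def test_total_equalizes_sums_two_sample_case(self):
        m = two_sample_matrix([40.0, 60.0], [80.0, 120.0])  # totals 100 vs 200
        out = normalize_samples(m, "total")
        sums = out.values.sum()
        assert sums["s1"] == pytest.approx(sums["s2"]) == pytest.approx(150.0)
        # second sample halved relative to the first after scaling
        ratio = out.values["s2"] / out.values["s1"]
        assert np.allclose(ratio, (m.values["s2"] / m.values["s1"]) / 2)

    def test_median_equalizes_medians(self, default_sim):
        _, matrix, _ = default_sim
        out = normalize_samples(matrix, "median")
        med = out.values.median()
        assert np.allclose(med, med.iloc[0], atol=1e-9)
        pd.testing.assert_frame_equal(
            out.values.notna(), matrix.values.notna()
        )  # missingness unchanged

    def test_sample_with_no_values_is_an_error(self):
        m = two_sample_matrix([40.0, 60.0], [np.nan, np.nan])
        with pytest.raises(EmptyDesignError, match="s2"):
            normalize_samples(m, "total")


class TestAggregate:
    def test_two_point_mean(self):
        m = two_sample_matrix([100.0], [200.0])
        assert aggregate_replicates(m, "BMI1", "L1", "control")["P0"] == 150.0

    def test_all_missing_aggregates_to_missing(self):
        m = two_sample_matrix([np.nan, 1.0], [np.nan, 2.0])
        assert np.isnan(aggregate_replicates(m, "BMI1", "L1", "control")["P0"])

    def test_impute_floor_policy(self):
        m = two_sample_matrix([100.0, 1.0], [np.nan, 1.0])
        agg = aggregate_replicates(m, "BMI1", "L1", "control", "impute_floor", floor=1.0)
        assert agg["P0"] == pytest.approx(50.5)

    def test_ignore_missing_policy(self):
        m = two_sample_matrix([100.0, 1.0], [np.nan, 1.0])
        agg = aggregate_replicates(m, "BMI1", "L1", "control", "ignore_missing")
        assert agg["P0"] == pytest.approx(100.0)


class TestLog2FC:
    def test_doubling_is_one(self):
        assert compute_log2fc(200.0, 100.0, pseudo=0.0) == pytest.approx(1.0)

    def test_equal_means_is_zero(self):
        assert compute_log2fc(123.0, 123.0, pseudo=1.0) == pytest.approx(0.0)

    def test_negative_means_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            compute_log2fc(-1.0, 5.0)

    @given(
        a=st.floats(0.0, 1e9, allow_nan=False),
        b=st.floats(0.0, 1e9, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_antisymmetric_under_argument_exchange(self, a, b):
        assert compute_log2fc(a, b, 1.0) == pytest.approx(
            -compute_log2fc(b, a, 1.0), abs=1e-9
        )


class TestAnova:
    def test_degenerate_variance_flagged_not_silent(self):
        y = np.full(8, 3.0)
        line = np.repeat(["A", "B"], 4)
        geno = np.tile(np.repeat(["c", "m"], 2), 2)
        r = anova_genotype_p(y, line, geno)
        assert not r.defined
        assert np.isnan(r.p_value)
        assert "variance" in r.reason

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_statsmodels_type_two_anova(self, seed):
        rng = np.random.default_rng(seed)
        n_per = int(rng.integers(2, 5))
        rows = []
        for line in ("A", "B"):
            for geno in ("ctrl", "mod"):
                mu = 0.3 * (line == "A") + 0.5 * (geno == "mod")
                rows += [(line, geno, rng.normal(mu, 1.0)) for _ in range(n_per)]
        df = pd.DataFrame(rows, columns=["line", "geno", "y"])
        fit = smf.ols("y ~ C(line)*C(geno)", data=df).fit()
        p_ref = sm.stats.anova_lm(fit, typ=2).loc["C(geno)", "PR(>F)"]
        r = anova_genotype_p(df["y"], df["line"], df["geno"])
        assert r.defined
        assert r.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_planted_fourfold_effect_is_detected(self):
        """A 4-fold genotype effect at log-noise sd 0.1 reaches p < 0.05
        in >= 95% of simulations at the 2x2x4 replicate design."""
        rng = np.random.default_rng(7)
        line = np.repeat(["A", "B"], 8)
        geno = np.tile(np.repeat(["c", "m"], 4), 2)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            y = rng.normal(0.0, 0.1, 16) + np.log(4.0) * (geno == "m")
            hits += anova_genotype_p(y, line, geno).p_value < 0.05
        assert hits / n_sim >= 0.95


class TestClassify:
    @pytest.mark.parametrize(
        "up, down, expect",
        [
            (1.0, -1.0, "concordant"),
            (1.0, 1.0, "discordant"),
            (-1.0, -1.0, "discordant"),
            (0.5, 0.2, "discordant"),      # both up counts as discordant
            (0.0, -1.0, "unchanged"),      # tie at fc_min resolves conservatively
            (0.0, 0.0, "unchanged"),
            (np.nan, -1.0, "unchanged"),   # missing fold-change
        ],
    )
    def test_sign_patterns(self, up, down, expect):
        assert classify_concordance(up, down, fc_min=0.0) == expect

    def test_alpha_gating(self):
        assert classify_concordance(1.0, -1.0, p_value=0.2, alpha=0.05) == "unchanged"
        assert classify_concordance(1.0, -1.0, p_value=0.01, alpha=0.05) == "concordant"
        assert classify_concordance(1.0, -1.0, p_value=np.nan, alpha=0.05) == "unchanged"

    def test_fc_min_threshold(self):
        assert classify_concordance(0.8, -0.8, fc_min=1.0) == "unchanged"
        assert classify_concordance(1.2, -1.2, fc_min=1.0) == "concordant"


def test_classification_invariant_to_global_rescaling():
    """Multiplying every sample by a constant, then normalizing, leaves the
    concordance classes unchanged."""
    from prcdeconv import default_config

    cfg = default_config(seed=5)
    matrix, _ = simulate_interactome(cfg)
    up, down = cfg.cell_lines
    base = quantify_modulation(
        matrix, matrix.proteins, "BMI1", up_line=up, down_line=down,
        normalize="total", run_tests=False,
    )
    scaled = matrix
    scaled.values *= 37.0
    rescaled = quantify_modulation(
        scaled, matrix.proteins, "BMI1", up_line=up, down_line=down,
        normalize="total", run_tests=False,
    )
    assert (base["concordance"] == rescaled["concordance"]).all()


def test_concordance_benchmark_recovers_planted_coupling():
    """218 interactors, 105 planted concordant: all and only those classified."""
    cfg = concordance_benchmark_config(seed=2)
    matrix, truth = simulate_interactome(cfg)
    up, down = cfg.cell_lines
    q = quantify_modulation(
        matrix, matrix.proteins, "BMI1", up_line=up, down_line=down, run_tests=False
    )
    concordant = set(q.index[q["concordance"] == "concordant"])
    assert concordant == set(truth.coupled)
    assert len(concordant) == 105
    assert (q["concordance"] != "concordant").sum() == 113
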