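"""Repeatability (CR) and independence (Spearman) filters."""

import numpy as np
import pandas as pd
import pytest

from petrad.features.registry import ALIASES, ExtractionConfig, enumerate_feature_space
from petrad.selection import (
    coefficient_of_repeatability,
    elbow_cluster_validation,
    independence_filter,
    percent_cr,
    repeatability_table,
    select_features,
)


class TestCoefficientOfRepeatability:
    def test_identical_pairs_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert coefficient_of_repeatability(a, a) == 0.0

    def test_two_pair_hand_computation(self):
        """Differences {-1, +1}: CR = 1.96 * sample SD = 1.96 * sqrt(2)."""
        cr = coefficient_of_repeatability(np.array([0.0, 1.0]), np.array([1.0, 0.0]))
        assert cr == pytest.approx(1.96 * np.sqrt(2.0))

    def test_monte_carlo_calibration(self):
        """Gaussian differences: CR estimate converges to 1.96*sigma.

        At n=1000 a single sample SD carries ~2.2% sampling error, so each
        replicate is held to 10% and the 20-replicate mean to 5%.
        """
        sigma = 0.7
        estimates = []
        for rep in range(20):
            rng = np.random.default_rng(500 + rep)
            base = rng.uniform(5, 10, size=1000)
            a = base + rng.normal(0, sigma / np.sqrt(2), 1000)
            b = base + rng.normal(0, sigma / np.sqrt(2), 1000)
            cr = coefficient_of_repeatability(a, b)
            assert cr == pytest.approx(1.96 * sigma, rel=0.10)
            estimates.append(cr)
        assert np.mean(estimates) == pytest.approx(1.96 * sigma, rel=0.05)

    def test_translation_invariant_scale_linear(self, rng):
        a = rng.normal(10, 2, 50)
        b = rng.normal(10, 2, 50)
        cr = coefficient_of_repeatability(a, b)
        assert coefficient_of_repeatability(a + 5, b + 5) == pytest.approx(cr)
        assert coefficient_of_repeatability(3 * a, 3 * b) == pytest.approx(3 * cr)

    def test_within_subject_convention(self, rng):
        a, b = rng.normal(0, 1, 100), rng.normal(0, 1, 100)
        ba = coefficient_of_repeatability(a, b, "bland_altman")
        ws = coefficient_of_repeatability(a, b, "within_subject")
        assert ws == pytest.approx(ba * 2.77 / (1.96 * np.sqrt(2)))

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match="2 pairs"):
            coefficient_of_repeatability(np.array([1.0]), np.array([2.0]))


class TestPercentCR:
    def test_zero_cr_passes(self):
        pct, passed = percent_cr(0.0, 5.0)
        assert pct == 0.0 and passed

    def test_455_percent_fails_30(self):
        pct, passed = percent_cr(45.5, 100.0)
        assert pct == pytest.approx(45.5) and not passed

    def test_132_percent_passes_30_and_15(self):
        for threshold in (30.0, 15.0):
            pct, passed = percent_cr(13.2, 100.0, threshold=threshold)
            assert pct == pytest.approx(13.2) and passed

    def test_zero_mean_not_assessable(self):
        pct, passed = percent_cr(1.0, 0.0)
        assert np.isnan(pct) and not passed

    def test_scale_invariant(self, rng):
        a = rng.normal(10, 1, 200)
        b = a + rng.normal(0, 0.5, 200)
        cr = coefficient_of_repeatability(a, b)
        pct1, _ = percent_cr(cr, np.mean((a + b) / 2))
        cr2 = coefficient_of_repeatability(7 * a, 7 * b)
        pct2, _ = percent_cr(cr2, np.mean(7 * (a + b) / 2))
        assert pct1 == pytest.approx(pct2)

    def test_threshold_monotonicity(self, rng):
        """Lowering the cut-off never enlarges the pass set."""
        a = pd.DataFrame(rng.normal(10, 1, (40, 6)), columns=list("abcdef"))
        b = a + rng.normal(0, 1.5, (40, 6))
        loose = repeatability_table(a, b, threshold=30.0)
        strict = repeatability_table(a, b, threshold=15.0)
        assert set(strict.index[strict["repeatable"]]) <= set(loose.index[loose["repeatable"]])


def _independence_table(n, rng, extra=None):
    """Minimal registry-plus-extras table with the reference columns."""
    data = {
        ALIASES["SUVmax"]: rng.lognormal(2.5, 0.4, n),
        ALIASES["MTV2.5"]: rng.lognormal(4.0, 0.8, n),
        ALIASES["MTV40"]: rng.lognormal(3.3, 0.8, n),
    }
    if extra:
        data.update(extra)
    return pd.DataFrame(data)


class TestIndependence:
    def test_monotone_transform_of_mtv_discarded(self, rng):
        n = 100
        table = _independence_table(n, rng)
        table["shape_SurfaceArea__MTV25"] = table[ALIASES["MTV2.5"]] ** 2
        result = independence_filter(table)
        row = result.loc["shape_SurfaceArea__MTV25"]
        assert row["rho_mtv"] == pytest.approx(1.0)
        assert not row["independent"]

    def test_exact_boundary_rho_half_discarded(self):
        """|rho| exactly 0.5 is inclusive for discarding."""
        mtv = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        feat = np.array([1.0, 4.0, 2.0, 5.0, 3.0])  # rank perm with sum d^2 = 10
        table = pd.DataFrame(
            {
                ALIASES["SUVmax"]: [5.0, 6.0, 4.0, 7.0, 3.0],
                ALIASES["MTV2.5"]: mtv,
                ALIASES["MTV40"]: [2.0, 1.0, 3.0, 5.0, 4.0],
                "firstorder_Kurtosis__MTV25": feat,
            }
        )
        result = independence_filter(table)
        row = result.loc["firstorder_Kurtosis__MTV25"]
        assert row["rho_mtv"] == pytest.approx(0.5)
        assert not row["independent"]

    def test_independent_feature_kept_at_n_252(self, rng):
        table = _independence_table(252, rng)
        table["firstorder_Kurtosis__MTV25"] = rng.normal(3, 1, 252)
        result = independence_filter(table)
        assert result.loc["firstorder_Kurtosis__MTV25", "independent"]

    def test_references_are_exempt(self, rng):
        result = independence_filter(_independence_table(50, rng))
        for alias in ("SUVmax", "MTV2.5", "MTV40"):
            assert result.loc[ALIASES[alias], "independent"]
            assert result.loc[ALIASES[alias], "reason"] == "reference metric"

    def test_constant_feature_fails_with_warning(self, rng):
        table = _independence_table(30, rng)
        table["firstorder_Kurtosis__MTV25"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            result = independence_filter(table)
        assert not result.loc["firstorder_Kurtosis__MTV25", "independent"]

    def test_feature_tested_against_own_mask_mtv(self, rng):
        """An MTV40-configuration feature is screened against MTV40, not MTV2.5."""
        n = 120
        table = _independence_table(n, rng)
        table["glszm_ZoneEntropy__MTV40__bincount64"] = (
            np.log(table[ALIASES["MTV40"]]) + rng.normal(0, 1e-6, n)
        )
        result = independence_filter(table)
        row = result.loc["glszm_ZoneEntropy__MTV40__bincount64"]
        assert abs(row["rho_mtv"]) > 0.99
        assert not row["independent"]

    def test_cutoff_monotonicity(self, rng):
        table = _independence_table(80, rng)
        table["firstorder_Kurtosis__MTV25"] = (
            0.4 * np.log(table[ALIASES["MTV2.5"]]) + rng.normal(0, 1, 80)
        )
        loose = independence_filter(table, cutoff=0.7)
        strict = independence_filter(table, cutoff=0.3)
        assert set(strict.index[strict["independent"]]) <= set(
            loose.index[loose["independent"]]
        )


class TestElbow:
    def test_two_perfect_blocks(self):
        c = np.eye(10)
        c[:5, :5] = 1.0
        c[5:, 5:] = 1.0
        k, labels = elbow_cluster_validation(c)
        assert k == 2
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1

    def test_identity_matrix_all_singletons(self):
        k, _ = elbow_cluster_validation(np.eye(8))
        assert k == 8

    def test_three_planted_blocks_recovered(self):
        blocks = [10, 10, 10]
        c = np.full((30, 30), 0.1)
        start = 0
        for size in blocks:
            c[start : start + size, start : start + size] = 0.9
            start += size
        np.fill_diagonal(c, 1.0)
        k, labels = elbow_cluster_validation(c)
        assert k == 3
        assert len({tuple(labels[i : i + 10]) for i in (0, 10, 20)}) == 3

    def test_tiny_input_returns_feature_count(self):
        k, _ = elbow_cluster_validation(np.eye(2))
        assert k == 2


class TestSelectFeatures:
    def _results(self, flags_rep, flags_ind):
        idx = [f"f{i}" for i in range(len(flags_rep))]
        rep = pd.DataFrame(
            {"repeatable": flags_rep, "reason": ["" if f else "percentCR > 30" for f in flags_rep]},
            index=idx,
        )
        ind = pd.DataFrame(
            {"independent": flags_ind, "reason": ["" if f else "|rho| >= 0.5 vs MTV" for f in flags_ind]},
            index=idx,
        )
        return rep, ind

    def test_intersection_equals_set_algebra_oracle(self, rng):
        flags_rep = rng.random(40) < 0.6
        flags_ind = rng.random(40) < 0.5
        rep, ind = self._results(flags_rep, flags_ind)
        audit = select_features(rep, ind)
        expected = {f"f{i}" for i in range(40) if flags_rep[i] and flags_ind[i]}
        assert set(audit.index[audit["selected"]]) == expected

    def test_repeatability_failure_blocks_selection(self):
        rep, ind = self._results([False, True], [True, True])
        audit = select_features(rep, ind)
        assert not audit.loc["f0", "selected"]
        assert "repeatability" in audit.loc["f0", "reason"]
        assert audit.loc["f1", "selected"]

    def test_empty_selection_warns_but_is_legal(self):
        rep, ind = self._results([True, False], [False, True])
        with pytest.warns(UserWarning, match="no feature passed"):
            audit = select_features(rep, ind)
        assert not audit["selected"].any()
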