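import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from cnspanel import (
    CellTypePanel,
    assign_tier,
    one_sample_t,
    pair_correlation,
    panel_shift,
    shared_genes,
    winsorize,
    winsorized_correlation,
)
from cnspanel.differential import PanelRatioVector
from cnspanel.stats import MAD_TO_SD


class TestOneSampleT:
    def test_symmetric_sample_gives_t_zero_p_one(self):
        t, p, mean, n = one_sample_t([-0.4, 0.4])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert mean == pytest.approx(0.0)
        assert n == 2

    def test_matches_closed_form_oracle(self):
        x = np.array([0.5, 0.7, 0.9])
        # textbook: t = mean / (sd / sqrt(n)), p two-sided on n-1 df
        t_exp = x.mean() / (x.std(ddof=1) / np.sqrt(3))
        p_exp = 2 * sps.t.sf(abs(t_exp), 2)
        t, p, mean, n = one_sample_t(x)
        assert t == pytest.approx(t_exp, abs=1e-12)
        assert p == pytest.approx(p_exp, abs=1e-12)

    def test_agrees_with_scipy_reference(self, rng):
        x = rng.normal(0.3, 1.0, size=40)
        t, p, _, _ = one_sample_t(x)
        ref = sps.ttest_1samp(x, 0.0)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_small_and_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            one_sample_t([1.0])
        with pytest.raises(ValueError, match="zero variance"):
            one_sample_t([2.0, 2.0, 2.0])


class TestWinsorize:
    def test_inliers_untouched(self):
        x = np.array([-0.5, -0.2, 0.0, 0.3, 0.6])
        np.testing.assert_allclose(winsorize(x, c=3.0), x)

    def test_outlier_clipped_to_oracle_boundary(self):
        x = np.array([0.0, 0.1, -0.1, 0.2, -0.2, 50.0])
        med = np.median(x)
        mad = np.median(np.abs(x - med)) * MAD_TO_SD
        boundary = med + 2.0 * mad
        out = winsorize(x, c=2.0)
        assert out[-1] == pytest.approx(boundary, abs=1e-12)
        np.testing.assert_allclose(out[:-1], x[:-1])  # inliers unchanged

    def test_infinite_c_is_identity(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_allclose(winsorize(x, c=np.inf), x)

    def test_zero_mad_warns_and_skips(self):
        x = np.array([1.0, 1.0, 1.0, 9.0])
        with pytest.warns(UserWarning, match="MAD"):
            out = winsorize(x, c=2.0)
        np.testing.assert_allclose(out, x)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            winsorize([1.0], c=2.0)
        with pytest.raises(ValueError):
            winsorize([1.0, 2.0], c=0.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=40, unique=True),
           st.floats(0.5, 5.0))
    def test_preserves_order_and_length(self, values, c):
        x = np.array(values)
        out = winsorize(x, c)
        assert out.shape == x.shape
        # clipping is a monotone nondecreasing transform of the input
        assert (np.diff(out[np.argsort(x, kind="mergesort")]) >= -1e-12).all()


class TestWinsorizedCorrelation:
    def test_affine_relation_gives_r_one(self):
        x = np.linspace(-1, 1, 20)
        r, p, n = winsorized_correlation(x, 2 * x + 1, c=2.0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0)

    def test_negation_gives_r_minus_one(self):
        x = np.linspace(-1, 1, 20)
        r, _, _ = winsorized_correlation(x, -x, c=2.0)
        assert r == pytest.approx(-1.0)

    def test_matches_two_step_oracle(self, rng):
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(size=200)
        x[:5] += 20.0  # contamination
        y[-5:] -= 15.0
        r, p, n = winsorized_correlation(x, y, c=2.0)
        r_exp, p_exp = sps.pearsonr(winsorize(x, 2.0), winsorize(y, 2.0))
        assert r == pytest.approx(r_exp, abs=1e-12)
        assert p == pytest.approx(p_exp, abs=1e-12)

    def test_infinite_c_equals_plain_pearson(self, rng):
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        r, p, _ = winsorized_correlation(x, y, c=np.inf)
        r_exp, p_exp = sps.pearsonr(x, y)
        assert r == pytest.approx(r_exp, abs=1e-12)
        assert p == pytest.approx(p_exp, abs=1e-12)

    def test_antisymmetric_under_negation(self, rng):
        x = rng.normal(size=60)
        y = rng.normal(size=60)
        r1, _, _ = winsorized_correlation(x, y, c=2.0)
        r2, _, _ = winsorized_correlation(x, -y, c=2.0)
        assert r2 == pytest.approx(-r1, abs=1e-12)

    def test_affine_invariance_of_arguments(self, rng):
        x = rng.normal(size=60)
        y = rng.normal(size=60)
        r1, _, _ = winsorized_correlation(x, y, c=2.0)
        r2, _, _ = winsorized_correlation(3.0 * x + 7.0, y, c=2.0)
        assert r2 == pytest.approx(r1, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            winsorized_correlation([1, 2, 3], [1, 2])
        with pytest.raises(ValueError, match="n >= 3"):
            winsorized_correlation([1, 2], [3, 4])
        with pytest.raises(ValueError, match="constant"):
            winsorized_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], c=np.inf)


class TestAssignTier:
    @pytest.mark.parametrize("p,tier", [
        (0.5, "ns"), (0.02, "ns"),
        (0.005, "*"), (0.0099, "*"),
        (0.0005, "**"),
        (5e-5, "***"), (0.0, "***"),
    ])
    def test_tier_assignment(self, p, tier):
        assert assign_tier(p) == tier

    def test_invalid_p_or_cutpoints(self):
        with pytest.raises(ValueError):
            assign_tier(1.5)
        with pytest.raises(ValueError):
            assign_tier(0.5, cutpoints=(0.001, 0.01, 0.0001))


class TestPanelStats:
    def _vec(self, ratios, ct="microglia", cohort="MS"):
        return PanelRatioVector(ct, cohort, pd.DataFrame({
            "gene": [f"G{i}" for i in range(len(ratios))], "ratio": ratios}),
            len(ratios))

    def test_panel_shift_summary(self, rng):
        vals = rng.normal(0.5, 0.2, size=100)
        res = panel_shift(self._vec(vals))
        assert res.mean_ratio == pytest.approx(vals.mean())
        assert res.n == 100
        assert res.tier == "***"

    def test_pair_correlation_joins_on_gene(self, rng):
        base = rng.normal(size=50)
        a = self._vec(base, cohort="MS")
        b = self._vec(base + rng.normal(0, 0.1, size=50), cohort="PD")
        res = pair_correlation(a, b)
        assert res.n == 50
        assert res.r > 0.9

    def test_pair_correlation_mismatched_cell_types_rejected(self, rng):
        a = self._vec(rng.normal(size=10), ct="microglia")
        b = self._vec(rng.normal(size=10), ct="neuron")
        with pytest.raises(ValueError, match="different cell types"):
            pair_correlation(a, b)


class TestSharedGenes:
    def _tables(self, genes, by_cohort):
        return {c: pd.DataFrame({"gene": genes, "ratio": v, "cohort": c})
                for c, v in by_cohort.items()}

    def test_membership_matches_brute_force(self):
        genes = ["A", "B", "C", "D", "E"]
        by_cohort = {
            "MS": [0.6, 0.4, 0.51, 0.9, 0.5],
            "PD": [0.7, 0.8, 0.49, 0.6, 0.55],
        }
        tables = self._tables(genes, by_cohort)
        panel = CellTypePanel("astrocyte", genes)
        out = shared_genes(tables, panel, threshold=0.5, required={"MS", "PD"})
        # exhaustive oracle (inclusive boundary)
        expected = [g for i, g in enumerate(genes)
                    if all(by_cohort[c][i] >= 0.5 for c in ("MS", "PD"))]
        assert out["gene"].tolist() == sorted(expected)

    def test_strict_boundary_option(self):
        tables = self._tables(["A"], {"MS": [0.5], "PD": [0.7]})
        panel = CellTypePanel("astrocyte", ["A"])
        assert len(shared_genes(tables, panel, 0.5, inclusive=True)) == 1
        assert len(shared_genes(tables, panel, 0.5, inclusive=False)) == 0

    def test_all_zero_ratios_give_empty_table(self):
        tables = self._tables(["A", "B"], {"MS": [0.0, 0.0], "PD": [0.0, 0.0]})
        out = shared_genes(tables, CellTypePanel("astrocyte", ["A", "B"]), 0.5)
        assert out.empty

    def test_nonrequired_cohort_ratios_still_reported(self):
        tables = self._tables(["A"], {"MS": [0.8], "PD": [0.9], "AD": [0.1]})
        out = shared_genes(tables, CellTypePanel("astrocyte", ["A"]),
                           0.5, required={"MS", "PD"})
        assert out["AD"].iloc[0] == pytest.approx(0.1)
        assert out["membership"].iloc[0] == "MS+PD"

    def test_monotone_in_threshold(self, rng):
        genes = [f"G{i}" for i in range(30)]
        tables = self._tables(genes, {"MS": rng.uniform(0, 1.5, 30),
                                      "PD": rng.uniform(0, 1.5, 30)})
        panel = CellTypePanel("astrocyte", genes)
        prev = set(shared_genes(tables, panel, 0.2)["gene"])
        for thr in (0.4, 0.6, 0.8, 1.0):
            cur = set(shared_genes(tables, panel, thr)["gene"])
            assert cur <= prev
            prev = cur

    def test_unknown_required_cohort_rejected(self):
        tables = self._tables(["A"], {"MS": [0.8]})
        with pytest.raises(ValueError, match="not supplied"):
            shared_genes(tables, CellTypePanel("astrocyte", ["A"]),
                         0.5, required={"MS", "AD"})
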