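import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from oracles import bh_step_up, brute_force_calls, fisher_enumeration
from conftest import make_normalized, make_phenotype
from spliceoutlier.core import CALL_NONE, CALL_OVER, CALL_UNDER, CALL_UNDEFINED
from spliceoutlier.outliers import (
    OutlierConfig,
    bh_fdr,
    call_outliers,
    detect_events,
    filter_sex_chromosomes,
    fisher_test_junction,
)


class TestFisher:
    def test_no_outliers_anywhere_gives_one(self):
        assert fisher_test_junction(0, 40, 0, 25) == pytest.approx(1.0)

    def test_most_extreme_table_is_point_mass(self):
        p = fisher_test_junction(40, 40, 0, 25)
        assert p == pytest.approx(fisher_enumeration(40, 40, 0, 25), abs=1e-12)
        assert p < 1e-10

    def test_against_enumeration_oracle(self):
        p = fisher_test_junction(20, 40, 0, 25)
        assert p == pytest.approx(fisher_enumeration(20, 40, 0, 25), abs=1e-12)

    @given(
        tn=st.integers(1, 15),
        nn=st.integers(1, 15),
        data=st.data(),
    )
    def test_matches_scipy_fisher_exact(self, tn, nn, data):
        to = data.draw(st.integers(0, tn))
        no = data.draw(st.integers(0, nn))
        table = [[to, tn - to], [no, nn - no]]
        expected = stats.fisher_exact(table, alternative="greater")[1]
        assert fisher_test_junction(to, tn, no, nn) == pytest.approx(expected, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fisher_test_junction(0, 0, 0, 5)

    def test_invariant_to_group_scaling_direction(self):
        # enrichment in tumors: moving an outlier from normals to tumors
        # can only decrease the one-sided p
        p_weak = fisher_test_junction(5, 10, 3, 10)
        p_strong = fisher_test_junction(6, 10, 2, 10)
        assert p_strong < p_weak


BH_CASES = [
    ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
    ([0.5], [0.5]),
    ([0.2, 0.1], [0.2, 0.2]),
    ([0.01, 0.5, 1.0], [0.03, 0.75, 1.0]),
    ([0.001, 0.01, 0.02, 0.9, 1.0], [0.005, 0.025, 1.0 / 30, 1.0, 1.0]),
]


class TestBH:
    @pytest.mark.parametrize("p,expected", BH_CASES)
    def test_hand_computed_step_up_vectors(self, p, expected):
        assert bh_fdr(p) == pytest.approx(expected)

    @pytest.mark.parametrize("p,_", BH_CASES)
    def test_matches_independent_oracle(self, p, _):
        assert bh_fdr(p) == pytest.approx(bh_step_up(p))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_permutation_equivariance_and_range(self, p):
        adjusted = bh_fdr(p)
        assert np.all((adjusted >= 0) & (adjusted <= 1))
        perm = np.random.default_rng(0).permutation(len(p))
        assert bh_fdr(np.asarray(p)[perm]) == pytest.approx(adjusted[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestCallOutliers:
    def _cohort(self, normals, tumor, **cfg):
        samples = [f"N{i}" for i in range(len(normals))] + ["T1"]
        matrix = make_normalized([normals + [tumor]], samples)
        pheno = make_phenotype(samples, ["normal"] * len(normals) + ["tumor"])
        calls = call_outliers(matrix, pheno, OutlierConfig(**cfg))
        return calls.calls.iloc[0]["T1"]

    def test_twenty_fold_over_constant_normals(self):
        assert self._cohort([1e-4] * 4, 2e-3) == CALL_OVER

    def test_expression_floor_blocks_low_cells(self):
        # 5e-6 sits below the 0.00001 floor: never an outlier despite the fold change
        assert self._cohort([1e-7] * 4, 5e-6, fold_change_cutoff=2.0) == CALL_NONE

    def test_fold_change_cutoff_two_vs_ten(self):
        assert self._cohort([1e-4] * 4, 5e-4) == CALL_NONE  # default cutoff 10
        assert self._cohort([1e-4] * 4, 5e-4, fold_change_cutoff=2.0) == CALL_OVER

    def test_under_outlier_against_expressed_normals(self):
        assert self._cohort([1e-3] * 4, 1e-6, fold_change_cutoff=2.0) == CALL_UNDER

    def test_constant_junction_produces_no_outliers(self):
        assert self._cohort([1e-4] * 4, 1e-4, fold_change_cutoff=1.0) == CALL_NONE

    def test_undefined_cells_stay_undefined(self):
        samples = ["N1", "N2", "N3", "T1"]
        matrix = make_normalized([[1e-4, 1e-4, 1e-4, np.nan]], samples)
        pheno = make_phenotype(samples, ["normal"] * 3 + ["tumor"])
        calls = call_outliers(matrix, pheno)
        assert calls.calls.iloc[0]["T1"] == CALL_UNDEFINED

    def test_junction_with_one_defined_normal_all_undefined(self):
        samples = ["N1", "N2", "T1"]
        matrix = make_normalized([[1e-4, np.nan, 5e-3]], samples)
        pheno = make_phenotype(samples, ["normal", "normal", "tumor"])
        calls = call_outliers(matrix, pheno)
        assert set(calls.calls.iloc[0]) == {CALL_UNDEFINED}

    def test_normal_outlier_called_leave_one_out(self):
        # N4 is 100x the other normals; with itself excluded from the fences
        # it must be an over-outlier
        samples = ["N1", "N2", "N3", "N4", "T1"]
        matrix = make_normalized([[1e-4, 1.1e-4, 0.9e-4, 1e-2, 1e-4]], samples)
        pheno = make_phenotype(samples, ["normal"] * 4 + ["tumor"])
        calls = call_outliers(matrix, pheno)
        assert calls.calls.iloc[0]["N4"] == CALL_OVER
        assert calls.calls.iloc[0]["T1"] == CALL_NONE

    def test_zero_normal_median_any_expressed_tumor_is_over(self):
        assert self._cohort([0.0] * 4, 1e-4) == CALL_OVER

    @given(
        data=st.data(),
        n_junctions=st.integers(1, 5),
        n_normals=st.integers(2, 4),
        n_tumors=st.integers(1, 2),
        fc=st.sampled_from([1.0, 2.0, 10.0]),
    )
    def test_matches_brute_force_rule_application(self, data, n_junctions, n_normals, n_tumors, fc):
        """Vectorized calls agree with literal per-cell rule application."""
        n_samples = n_normals + n_tumors
        cell = st.one_of(
            st.just(float("nan")),
            st.sampled_from([0.0, 1e-6, 1e-5, 1e-4, 5e-4, 1e-3, 2e-3, 1e-2]),
        )
        values = np.array(
            [
                [data.draw(cell) for _ in range(n_samples)]
                for _ in range(n_junctions)
            ]
        )
        samples = [f"S{i}" for i in range(n_samples)]
        groups = ["normal"] * n_normals + ["tumor"] * n_tumors
        config = OutlierConfig(fold_change_cutoff=fc)
        matrix = make_normalized(values, samples)
        pheno = make_phenotype(samples, groups)
        got = call_outliers(matrix, pheno, config).calls.to_numpy(dtype=object)
        expected = brute_force_calls(values, groups, config)
        assert (got == expected).all()

    @given(
        floor=st.sampled_from([0.0, 1e-5, 1e-4]),
        fc_low=st.sampled_from([1.0, 2.0]),
    )
    def test_monotone_in_thresholds(self, floor, fc_low):
        """Raising the floor or fold-change cutoff never adds outlier calls."""
        rng = np.random.default_rng(42)
        values = rng.gamma(1.0, 1e-4, size=(6, 8))
        samples = [f"S{i}" for i in range(8)]
        groups = ["normal"] * 5 + ["tumor"] * 3
        matrix = make_normalized(values, samples)
        pheno = make_phenotype(samples, groups)

        def n_calls(**kw):
            calls = call_outliers(matrix, pheno, OutlierConfig(**kw)).calls.to_numpy()
            return int(np.isin(calls, [CALL_OVER, CALL_UNDER]).sum())

        assert n_calls(min_norm_expr=floor, fold_change_cutoff=fc_low) >= n_calls(
            min_norm_expr=floor * 10 + 1e-5, fold_change_cutoff=fc_low
        )
        assert n_calls(min_norm_expr=floor, fold_change_cutoff=fc_low) >= n_calls(
            min_norm_expr=floor, fold_change_cutoff=fc_low * 5
        )

    def test_tumor_at_normal_median_never_an_outlier(self):
        rng = np.random.default_rng(3)
        values = rng.gamma(2.0, 1e-4, size=(5, 6))
        samples = [f"S{i}" for i in range(6)]
        groups = ["normal"] * 5 + ["tumor"]
        matrix = make_normalized(values, samples)
        base = call_outliers(matrix, make_phenotype(samples, groups))
        medians = np.median(values[:, :5], axis=1)
        values2 = np.column_stack([values, medians])
        samples2 = samples + ["T_med"]
        matrix2 = make_normalized(values2, samples2)
        calls2 = call_outliers(matrix2, make_phenotype(samples2, groups + ["tumor"]))
        assert set(calls2.calls["T_med"]) <= {CALL_NONE}
        # existing tumor counts unchanged
        pd.testing.assert_frame_equal(
            base.calls, calls2.calls[base.calls.columns]
        )


class TestFilterSexChromosomes:
    def _matrix(self):
        values = np.ones((4, 3))
        samples = ["N1", "N2", "T1"]
        m = make_normalized(values, samples)
        idx = pd.MultiIndex.from_tuples(
            [
                ("chr1", 1, 5, "+"),
                ("chrX", 1, 5, "+"),
                ("chrY", 1, 5, "+"),
                ("chr2", 1, 5, "+"),
            ],
            names=m.values.index.names,
        )
        m.values.index = idx
        m.gene.index = idx
        m.no_gene.index = idx
        return m

    def test_removes_only_sex_chromosomes(self):
        out = filter_sex_chromosomes(self._matrix())
        chroms = set(out.values.index.get_level_values("chromosome"))
        assert chroms == {"chr1", "chr2"}

    def test_flag_off_is_identity(self):
        m = self._matrix()
        out = filter_sex_chromosomes(m, OutlierConfig(exclude_sex_chromosomes=False))
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_empty_matrix_passes_through(self):
        m = self._matrix()
        empty = filter_sex_chromosomes(
            make_normalized(np.empty((0, 3)), ["N1", "N2", "T1"])
        )
        assert len(empty.values) == 0


class TestDetectEvents:
    def _cohort(self, n_over_tumors=20, n_tumors=40, n_normals=25):
        rng = np.random.default_rng(0)
        base = rng.normal(1e-4, 1e-6, size=n_normals + n_tumors).clip(min=1e-5)
        values = np.array([base])
        values[0, n_normals : n_normals + n_over_tumors] = 5e-3
        samples = [f"N{i}" for i in range(n_normals)] + [f"T{i}" for i in range(n_tumors)]
        groups = ["normal"] * n_normals + ["tumor"] * n_tumors
        return make_normalized(values, samples), make_phenotype(samples, groups)

    def test_single_enriched_junction_is_significant(self):
        matrix, pheno = self._cohort()
        results = detect_events(matrix, pheno, OutlierConfig())
        over = [r for r in results if r.direction == CALL_OVER][0]
        assert over.tumor_outliers == 20
        assert over.normal_outliers == 0
        assert over.fdr <= 0.05
        assert over.p_value == pytest.approx(
            fisher_enumeration(20, 40, 0, 25), abs=1e-12
        )

    def test_group_relabeling_breaks_significance(self):
        """The one-sided test targets tumor enrichment only."""
        matrix, pheno = self._cohort()
        flipped = pheno.map({"tumor": "normal", "normal": "tumor"})
        results = detect_events(matrix, flipped, OutlierConfig())
        assert all(r.fdr > 0.05 for r in results)

    def test_all_zero_matrix_yields_no_significant_events(self):
        samples = ["N1", "N2", "N3", "T1", "T2"]
        matrix = make_normalized(np.zeros((3, 5)), samples)
        pheno = make_phenotype(samples, ["normal"] * 3 + ["tumor"] * 2)
        results = detect_events(matrix, pheno)
        assert all(r.fdr > 0.05 for r in results)
        assert all(r.tumor_outliers == 0 for r in results)

    def test_sample_order_invariance_of_p_values(self):
        matrix, pheno = self._cohort()
        perm = np.random.default_rng(1).permutation(len(matrix.samples))
        shuffled = make_normalized(
            matrix.values.to_numpy()[:, perm], [matrix.samples[i] for i in perm]
        )
        a = detect_events(matrix, pheno)
        b = detect_events(shuffled, pheno)
        pa = {(r.junction, r.direction): r.p_value for r in a}
        pb = {(r.junction, r.direction): r.p_value for r in b}
        assert pa == pytest.approx(pb)

    def test_fdr_pooled_across_directions(self):
        matrix, pheno = self._cohort()
        results = detect_events(matrix, pheno)
        # one junction tested in both directions -> two results, one BH family
        assert len(results) == 2
        assert {r.direction for r in results} == {CALL_OVER, CALL_UNDER}
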