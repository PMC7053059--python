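import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dopanet.io_model import ExpressionExperiment
from dopanet.rotation_gsa import (
    filter_by_detection,
    filter_by_signal,
    moderated_t,
    quantile_normalize,
    rotation_set_test,
)
from dopanet.synthetic_data import SyntheticSpec, make_expression


def experiment(values, groups=None, detection_p=None):
    values = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(len(values))],
        columns=[f"s{i}" for i in range(len(values[0]))],
    )
    if groups is None:
        half = values.shape[1] // 2
        groups = ["a"] * half + ["b"] * (values.shape[1] - half)
    groups = pd.Series(groups, index=values.columns)
    dp = None
    if detection_p is not None:
        dp = pd.DataFrame(detection_p, index=values.index, columns=values.columns)
    return ExpressionExperiment(values, groups, dp)


class TestFilters:
    def test_detection_filter_keeps_any_detected(self):
        e = experiment(
            [[7.0, 7.0, 7.0, 7.0], [7.0, 7.0, 7.0, 7.0]],
            detection_p=[[0.5, 0.5, 0.5, 0.5], [0.5, 0.005, 0.5, 0.5]],
        )
        out, report = filter_by_detection(e)
        assert out.genes == ["G1"]
        assert (report.n_probes_in, report.n_probes_kept) == (2, 1)

    def test_detection_filter_pcut_one_keeps_all(self):
        e = experiment([[7.0, 7.0]], detection_p=[[0.5, 0.9]])
        out, _ = filter_by_detection(e, p_cut=1.0)
        assert out.genes == ["G0"]

    def test_detection_filter_requires_detection_p(self):
        e = experiment([[7.0, 7.0]])
        with pytest.raises(ValueError, match="filter_by_signal"):
            filter_by_detection(e)

    def test_signal_floor_is_inclusive(self):
        e = experiment([[5.99, 5.2], [6.0, 5.0], [8.0, 3.0]])
        out, report = filter_by_signal(e, floor=6.0)
        assert out.genes == ["G1", "G2"]
        assert report.n_probes_kept == 2

    def test_signal_floor_minus_inf_is_identity(self):
        e = experiment([[1.0, 2.0], [3.0, 4.0]])
        out, _ = filter_by_signal(e, floor=-np.inf)
        assert out.genes == ["G0", "G1"]


class TestQuantileNormalize:
    def test_identical_samples_unchanged(self):
        e = experiment([[1.0, 1.0], [5.0, 5.0], [3.0, 3.0]])
        out = quantile_normalize(e)
        assert np.allclose(out.values, e.values)

    def test_hand_computed_two_samples(self):
        e = experiment([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]])
        out = quantile_normalize(e)
        assert np.allclose(out.values.to_numpy(), [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])

    def test_constant_sample_maps_to_reference_mean(self):
        e = experiment([[1.0, 7.0], [2.0, 7.0], [3.0, 7.0]])
        out = quantile_normalize(e)
        reference_mean = out.values.iloc[:, 0].mean()
        assert np.allclose(out.values.iloc[:, 1], reference_mean)

    def test_sorted_columns_identical_on_random_input(self):
        rng = np.random.default_rng(0)
        e = experiment(rng.normal(size=(50, 6)).tolist())
        out = quantile_normalize(e).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(out.shape[1]):
            assert np.allclose(np.sort(out[:, j]), ref, atol=1e-9)


class TestModeratedT:
    def test_zero_between_group_difference_gives_zero(self):
        e = experiment([[1.0, 2.0, 1.0, 2.0], [4.0, 6.0, 5.0, 5.0]])
        t = moderated_t(e)
        assert t[0] == pytest.approx(0.0, abs=1e-12)

    def test_equal_variances_reduce_to_pooled_t(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=8)
        # same residuals for every gene: shrinkage must be a no-op
        values = [list(base + shift) for shift in (0.0, 1.0, -2.0, 0.5)]
        e = experiment(values)
        t = moderated_t(e)
        for row, tm in zip(values, t):
            ts, _ = stats.ttest_ind(row[4:], row[:4], equal_var=True)
            assert tm == pytest.approx(ts, rel=1e-9)

    def test_group_with_one_sample_is_error(self):
        e = experiment([[1.0, 2.0, 3.0]], groups=["a", "b", "b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            moderated_t(e)

    def test_null_statistic_scale_matches_t_prediction(self):
        spec = SyntheticSpec(seed=9, n_genes=2000, n_samples_per_group=5, delta=0.0)
        t = moderated_t(make_expression(spec))
        # moderated t approaches t with d0 + d df; for unit gene variances the
        # prior df is large, so var should be near d/(d-2) at most
        d = 8
        predicted = d / (d - 2)
        assert abs(t.var() - 1.0) < 0.1 * predicted


class TestRotationSetTest:
    def setup_method(self):
        self.spec = SyntheticSpec(seed=77, n_genes=100, n_samples_per_group=5, delta=0.0)
        self.e = make_expression(self.spec)
        self.set10 = [f"G{i:04d}" for i in range(1, 11)]

    def test_seeded_run_is_reproducible(self):
        a = rotation_set_test(self.e, self.set10, n_rotations=99, seed=1)
        b = rotation_set_test(self.e, self.set10, n_rotations=99, seed=1)
        assert a.to_dict() == b.to_dict()

    def test_p_is_valid_add_one_fraction(self):
        r = rotation_set_test(self.e, self.set10, n_rotations=99, seed=2)
        b = round(r.p_mixed * 100 - 1)
        assert 0 <= b <= 99
        assert r.p_mixed == pytest.approx((b + 1) / 100)
        assert r.n_genes_in_set == len(r.per_gene_stats) == 10

    def test_mixed_statistic_invariant_under_sign_flip(self):
        flipped = self.e.values.copy()
        flipped.loc["G0001"] = -flipped.loc["G0001"]
        e2 = ExpressionExperiment(flipped, self.e.groups)
        a = rotation_set_test(self.e, self.set10, n_rotations=99, seed=3)
        b = rotation_set_test(e2, self.set10, n_rotations=99, seed=3)
        assert b.set_statistic_observed == pytest.approx(a.set_statistic_observed)
        assert b.p_mixed == a.p_mixed

    def test_single_gene_msq_matches_two_sided_directional(self):
        a = rotation_set_test(self.e, ["G0001"], n_rotations=199, seed=5, statistic="msq")
        b = rotation_set_test(self.e, ["G0001"], n_rotations=199, seed=5, statistic="mean")
        assert a.p_mixed == b.p_mixed

    def test_constant_matrix_is_error(self):
        e = experiment([[5.0] * 6, [5.0] * 6])
        with pytest.raises(ValueError, match="zero residual"):
            rotation_set_test(e, ["g0", "g1"], n_rotations=10, seed=0)

    def test_disjoint_set_error_lists_missing(self):
        with pytest.raises(ValueError, match="ZZZ9"):
            rotation_set_test(self.e, ["ZZZ9"], n_rotations=10, seed=0)

    def test_planted_bidirectional_signal_detected(self):
        spec = SyntheticSpec(seed=21, n_genes=200, delta=1.5)
        genes = [f"G{i:04d}" for i in range(1, 21)]
        e = make_expression(spec, {"S": genes})
        mixed = rotation_set_test(e, genes, n_rotations=199, seed=7, statistic="msq")
        directional = rotation_set_test(e, genes, n_rotations=199, seed=7, statistic="mean")
        assert mixed.p_mixed <= 0.05
        assert directional.p_mixed > mixed.p_mixed
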