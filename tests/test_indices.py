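import numpy as np
import pandas as pd
import pytest

from conftest import tensor_from_array
from oracles import (
    exact_two_gene_bootstrap_sd,
    mannwhitney_two_sided_exact,
    weighted_mean_direct,
)
from phylotrx.datamodel import (
    AnalysisConfig,
    DivergenceTable,
    PhylostratumMap,
    UndefinedIndexError,
)
from phylotrx.indices import (
    OrganIndex,
    IndexResult,
    bootstrap_index,
    compare_organs,
    compute_tai,
    compute_tdi,
    partial_concentrations,
    weighted_index,
    weighted_index_concentration_form,
)


def one_sample_tensor(expr, genes, accession="acc"):
    """Tensor with the given sense expression replicated across organs."""
    arr = np.zeros((len(genes), 1, 3, 2))
    arr[:, 0, :, 0] = np.asarray(expr)[:, None]
    return tensor_from_array(arr, genes, [accession])


def ps_map(mapping):
    return PhylostratumMap(pd.Series(mapping))


def div_table(mapping):
    df = pd.DataFrame(
        {"dN": [r * 1.0 for r in mapping.values()],
         "dS": [1.0] * len(mapping),
         "ratio": list(mapping.values())},
        index=list(mapping),
    )
    return DivergenceTable(df, "A_lyrata")


class TestPointEstimates:
    def test_tai_equal_weights_is_unweighted_mean(self):
        t = one_sample_tensor([1.0, 1.0, 1.0], ["g1", "g2", "g3"])
        assert compute_tai(t, ps_map({"g1": 1, "g2": 2, "g3": 3}), "acc", "root") == 2.0

    def test_tai_weighted_two_genes(self):
        t = one_sample_tensor([3.0, 1.0], ["g1", "g2"])
        assert compute_tai(t, ps_map({"g1": 1, "g2": 12}), "acc", "root") == 3.75

    def test_tdi_equal_weights(self):
        t = one_sample_tensor([1.0, 1.0], ["g1", "g2"])
        assert compute_tdi(
            t, div_table({"g1": 0.1, "g2": 0.3}), "acc", "root"
        ) == pytest.approx(0.2)

    def test_tdi_single_gene_returns_its_ratio(self):
        t = one_sample_tensor([7.3], ["g1"])
        assert compute_tdi(t, div_table({"g1": 0.42}), "acc", "root") == pytest.approx(
            0.42
        )

    def test_genes_without_annotation_are_excluded(self):
        t = one_sample_tensor([1.0, 1.0, 100.0], ["g1", "g2", "g3"])
        # g3 has no stratum: its large expression must not matter
        assert compute_tai(t, ps_map({"g1": 1, "g2": 3}), "acc", "root") == 2.0

    def test_zero_expression_is_undefined(self):
        t = one_sample_tensor([0.0, 0.0], ["g1", "g2"])
        with pytest.raises(UndefinedIndexError):
            compute_tai(t, ps_map({"g1": 1, "g2": 2}), "acc", "root")

    def test_matches_direct_oracle_on_random_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 60))
            ann = pd.Series(rng.integers(1, 13, n).astype(float),
                            index=[f"g{i}" for i in range(n)])
            e = pd.Series(rng.uniform(0.01, 50, n), index=ann.index)
            expected = weighted_mean_direct(ann.tolist(), e.tolist())
            assert weighted_index(e, ann) == pytest.approx(expected, rel=1e-12)


class TestFormulaEquivalence:
    def test_ratio_and_concentration_forms_agree(self, rng):
        # 100 random instances; the two algebraic forms agree to 1e-12
        for _ in range(100):
            n = int(rng.integers(2, 200))
            ann = pd.Series(rng.uniform(0.01, 12, n),
                            index=[f"g{i}" for i in range(n)])
            e = pd.Series(rng.uniform(0.0, 100, n), index=ann.index)
            e.iloc[0] = max(e.iloc[0], 0.1)  # keep the total positive
            a = weighted_index(e, ann)
            b = weighted_index_concentration_form(e, ann)
            assert a == pytest.approx(b, abs=1e-12, rel=1e-12)

    def test_scale_invariance(self, rng):
        n = 50
        ann = pd.Series(rng.integers(1, 13, n).astype(float),
                        index=[f"g{i}" for i in range(n)])
        e = pd.Series(rng.uniform(0.01, 10, n), index=ann.index)
        base = weighted_index(e, ann)
        for c in (1e-6, 0.5, 3.0, 1e6):
            assert weighted_index(c * e, ann) == pytest.approx(base, rel=1e-12)

    def test_bounds_by_contributing_values(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 40))
            ann = pd.Series(rng.uniform(0, 2, n), index=[f"g{i}" for i in range(n)])
            e = pd.Series(rng.uniform(0.01, 5, n), index=ann.index)
            val = weighted_index(e, ann)
            assert ann.min() - 1e-12 <= val <= ann.max() + 1e-12

    def test_concentrations_sum_to_one(self, rng):
        e = pd.Series(rng.uniform(0, 10, 30))
        e.iloc[0] = 1.0
        assert partial_concentrations(e).sum() == pytest.approx(1.0, abs=1e-9)


class TestBootstrap:
    def test_identical_genes_have_exactly_zero_se(self):
        t = one_sample_tensor([2.0, 2.0, 2.0], ["g1", "g2", "g3"])
        m = ps_map({"g1": 4, "g2": 4, "g3": 4})
        res = bootstrap_index(t, m, "acc", AnalysisConfig(n_bootstrap=200, rng_seed=1))
        assert res.per_organ["root"].boot_se == 0.0
        assert res.per_organ["root"].boot_mean == 4.0

    def test_fixed_seed_gives_bit_identical_draws(self):
        t = one_sample_tensor([1.0, 2.0, 4.0], ["g1", "g2", "g3"])
        m = ps_map({"g1": 1, "g2": 5, "g3": 9})
        cfg = AnalysisConfig(n_bootstrap=100, rng_seed=77)
        r1 = bootstrap_index(t, m, "acc", cfg)
        r2 = bootstrap_index(t, m, "acc", cfg)
        np.testing.assert_array_equal(
            r1.per_organ["flower"].draws, r2.per_organ["flower"].draws
        )

    def test_two_gene_se_matches_exact_enumeration(self):
        # 3 distinct resample outcomes with binomial weights 1/4, 1/2, 1/4
        t = one_sample_tensor([3.0, 1.0], ["g1", "g2"])
        m = ps_map({"g1": 1, "g2": 12})
        exact = exact_two_gene_bootstrap_sd((1.0, 12.0), (3.0, 1.0))
        res = bootstrap_index(
            t, m, "acc", AnalysisConfig(n_bootstrap=10000, rng_seed=3)
        )
        assert res.per_organ["root"].boot_se == pytest.approx(exact, rel=0.05)

    def test_bootstrap_mean_converges_to_point_estimate(self, sim_data):
        cfg = AnalysisConfig(n_bootstrap=1000, rng_seed=9)
        res = bootstrap_index(sim_data.tensor, sim_data.ps_map, "Col-0", cfg)
        for organ, oi in res.per_organ.items():
            assert abs(oi.boot_mean - oi.estimate) < 3 * oi.boot_se / np.sqrt(1000) + \
                5e-3 * oi.boot_se  # allowance for the ratio-estimator bias

    def test_same_resample_shared_across_organs(self):
        # With per-organ expression proportional between organs, shared
        # resampling makes the organ draws perfectly correlated.
        arr = np.zeros((3, 1, 3, 2))
        arr[:, 0, 0, 0] = [1.0, 2.0, 4.0]
        arr[:, 0, 1, 0] = [2.0, 4.0, 8.0]
        arr[:, 0, 2, 0] = [0.5, 1.0, 2.0]
        t = tensor_from_array(arr, ["g1", "g2", "g3"], ["acc"])
        m = ps_map({"g1": 1, "g2": 6, "g3": 11})
        res = bootstrap_index(t, m, "acc", AnalysisConfig(n_bootstrap=50, rng_seed=2))
        np.testing.assert_allclose(
            res.per_organ["root"].draws, res.per_organ["seedling"].draws, rtol=1e-12
        )


class TestCompareOrgans:
    def _result(self, draws_by_organ):
        per_organ = {
            o: OrganIndex(
                estimate=float(np.mean(d)), draws=np.asarray(d, dtype=float),
                boot_mean=float(np.mean(d)), boot_se=float(np.std(d)), n_genes=10,
            )
            for o, d in draws_by_organ.items()
        }
        return IndexResult("TAI", "acc", "sense", per_organ)

    def test_identical_draws_give_p_near_one(self):
        d = np.linspace(1, 2, 100)
        comp = compare_organs(self._result({"root": d, "seedling": d.copy()}))
        assert comp.tests["p"].iloc[0] > 0.9

    def test_small_sample_exact_p_matches_enumeration(self):
        comp = compare_organs(
            self._result({"root": [1.0, 2.0, 3.0], "seedling": [4.0, 5.0, 6.0]})
        )
        u_oracle, p_oracle = mannwhitney_two_sided_exact(
            [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        )
        row = comp.tests.iloc[0]
        assert row["U"] == u_oracle == 0.0
        assert row["p"] == pytest.approx(p_oracle) == pytest.approx(0.1)

    def test_planted_shift_is_overwhelmingly_significant(self, rng):
        a = rng.normal(0.0, 1.0, 1000)
        b = rng.normal(3.0, 1.0, 1000)  # 3 SE shift
        comp = compare_organs(self._result({"root": a, "flower": b}))
        assert comp.tests["p"].iloc[0] < 1e-10

    def test_all_three_pairs_reported(self):
        d = {o: np.arange(10) + i for i, o in enumerate(["root", "seedling", "flower"])}
        comp = compare_organs(self._result(d))
        assert len(comp.tests) == 3
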