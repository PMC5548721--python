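import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import tensor_from_array
from phylotrx import io as pio
from phylotrx.classify import (
    call_expression,
    organ_cluster_agreement,
    partition_groups,
    sample_similarity,
)
from phylotrx.datamodel import GROUP_NAMES, AnalysisConfig, ValidationError
from phylotrx.simulate import default_scenario, simulate


@pytest.fixture(scope="module")
def tiny_calls():
    tensor, _ = pio.read_expression(
        pio.expression_paths(__import__("conftest").TINY_DIR)
    )
    return call_expression(tensor, AnalysisConfig())


class TestCallExpression:
    def test_boundary_value_in_exactly_min_accessions_is_expressed(self, tiny_calls):
        # 0.8 RPM in exactly 5 accessions: the rule is inclusive on both counts
        assert bool(tiny_calls.expressed.sel(gene="g08", organ="root", strand="sense"))

    def test_just_below_threshold_everywhere_is_not_expressed(self, tiny_calls):
        assert not bool(
            tiny_calls.expressed.sel(gene="g09", organ="root", strand="sense")
        )

    def test_high_value_in_too_few_accessions_is_not_expressed(self, tiny_calls):
        assert not bool(
            tiny_calls.expressed.sel(gene="g10", organ="root", strand="sense")
        )

    def test_support_counts_match_rule(self, tiny_calls):
        support = tiny_calls.support.sel(gene="g11", organ="root", strand="sense")
        assert int(support) == 4  # four cells at 0.8, three at 0.79

    def test_min_accessions_larger_than_accession_count_rejected(self):
        arr = np.ones((2, 3, 3, 2))
        t = tensor_from_array(arr, ["g1", "g2"], ["a", "b", "c"])
        with pytest.raises(ValidationError, match="min_accessions"):
            call_expression(t, AnalysisConfig(min_accessions=4))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.floats(0.0, 5.0))
    def test_monotone_raising_expression_never_unexpresses(self, seed, bump):
        rng = np.random.default_rng(seed)
        arr = rng.uniform(0, 2, size=(5, 6, 3, 2))
        t = tensor_from_array(arr, [f"g{i}" for i in range(5)], list("abcdef"))
        cfg = AnalysisConfig(min_accessions=3)
        before = call_expression(t, cfg).expressed
        i = rng.integers(0, 5)
        arr2 = arr.copy()
        arr2[i] += bump
        after = call_expression(
            tensor_from_array(arr2, [f"g{i}" for i in range(5)], list("abcdef")), cfg
        ).expressed
        assert bool((after | ~before).all())


class TestPartitionGroups:
    def test_seven_profiles_give_seven_singleton_groups(self):
        # genes constructed with each of the 2^3 - 1 nonempty organ profiles
        profiles = [p for p in itertools.product([0, 1], repeat=3) if any(p)]
        arr = np.zeros((7, 5, 3, 2))
        for g, profile in enumerate(profiles):
            for o, present in enumerate(profile):
                if present:
                    arr[g, :, o, 0] = 1.0
        t = tensor_from_array(arr, [f"g{i}" for i in range(7)], list("abcde"))
        calls = call_expression(t, AnalysisConfig(min_accessions=5))
        groups = partition_groups(calls, "sense")
        assert dict(groups.sizes()) == {g: 1 for g in GROUP_NAMES}

    def test_tiny_fixture_group_membership(self, tiny_calls):
        groups = partition_groups(tiny_calls, "sense")
        assert sorted(groups.groups["R"]) == ["g01", "g08", "g14", "g19"]
        assert sorted(groups.groups["RSF"]) == ["g07", "g12"]
        anti = partition_groups(tiny_calls, "antisense")
        assert anti.groups["R"] == ["g20"]
        assert int(anti.sizes().sum()) == 1

    def test_groups_partition_the_expressed_set(self, sim_data):
        calls = call_expression(sim_data.tensor, AnalysisConfig())
        groups = partition_groups(calls, "sense")
        members = groups.membership()
        expressed_any = (
            calls.expressed.sel(strand="sense").any("organ").values.sum()
        )
        assert len(members) == int(expressed_any)
        assert not members.index.has_duplicates

    def test_partition_invariant_to_gene_order(self, rng):
        arr = rng.uniform(0, 3, size=(20, 6, 3, 2))
        genes = [f"g{i:02d}" for i in range(20)]
        t1 = tensor_from_array(arr, genes, list("abcdef"))
        perm = rng.permutation(20)
        t2 = tensor_from_array(arr[perm], [genes[i] for i in perm], list("abcdef"))
        cfg = AnalysisConfig(min_accessions=3)
        g1 = partition_groups(call_expression(t1, cfg), "sense")
        g2 = partition_groups(call_expression(t2, cfg), "sense")
        assert {k: set(v) for k, v in g1.groups.items()} == {
            k: set(v) for k, v in g2.groups.items()
        }


class TestSampleSimilarity:
    def test_identical_samples_correlate_perfectly(self):
        arr = np.zeros((4, 2, 3, 2))
        profile = np.array([1.0, 2.0, 3.0, 4.0])
        arr[:, 0, 0, 0] = profile
        arr[:, 1, 0, 0] = profile
        arr[:, :, 1, 0] = 5.0 - profile[:, None]  # anti-correlated organ
        arr[:, :, 2, 0] = rngless = np.array([2.0, 1.0, 4.0, 3.0])[:, None]
        t = tensor_from_array(arr, list("wxyz"), ["a1", "a2"])
        sim = sample_similarity(t, "sense")
        assert sim.correlation.loc["a1:root", "a2:root"] == pytest.approx(1.0)
        assert sim.correlation.loc["a1:root", "a1:seedling"] == pytest.approx(-1.0)

    def test_zero_variance_sample_excluded_with_warning(self):
        arr = np.ones((3, 2, 3, 2))
        arr[:, 0, 0, 0] = [1.0, 2.0, 3.0]
        arr[:, 1, 0, 0] = [1.0, 2.5, 3.0]
        arr[:, :, 1, 0] = [[1, 1], [2, 2], [3.2, 3.2]]
        # flower samples stay constant -> zero variance
        with pytest.warns(UserWarning, match="zero-variance"):
            sim = sample_similarity(t := tensor_from_array(arr, "pqr", ["a1", "a2"]),
                                    "sense")
        assert "a1:flower" in sim.excluded
        assert np.isnan(sim.correlation.loc["a1:flower", "a1:root"])
        assert "a1:flower" not in sim.clustered_labels

    def test_organ_effect_groups_samples_by_organ(self):
        # organ effect far larger than accession noise -> organ-major clusters
        data = simulate(default_scenario(n_genes=300, rng_seed=5), seed=5)
        sim = sample_similarity(data.tensor, "sense")
        assert organ_cluster_agreement(sim) == 1.0

    def test_newick_has_all_leaves(self, sim_data):
        sim = sample_similarity(sim_data.tensor, "sense")
        nwk = sim.to_newick()
        assert nwk.endswith(";")
        assert all(lbl in nwk for lbl in sim.clustered_labels)
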