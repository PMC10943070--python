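"""Profiles, Jaccard clustering, maturation categories, heatmap and scatter."""

import numpy as np
import pandas as pd
import pytest
from itertools import combinations

from desmoprox.errors import InputError, ParameterError, StatisticsError
from desmoprox.maturation import (
    ProfileSet,
    binarize_profiles,
    categorize_maturation,
    cluster_preys,
    dataset_order,
    heatmap_matrix,
    jaccard_distance,
    scatter_pairs,
)

from conftest import random_scores

BAITS = ("Dsc2a", "PG-N", "PG-C", "Pkp2a")
CONDITIONS = ("ca_dependent", "hyper_adhesive")


def profile_set(vectors: dict) -> ProfileSet:
    order = dataset_order(BAITS, CONDITIONS)
    binary = pd.DataFrame.from_dict(vectors, orient="index", columns=order).astype(int)
    fc = binary.astype(float).where(binary > 0)
    return ProfileSet(binary=binary, log2fc=fc, baits=BAITS, conditions=CONDITIONS)


class TestBinarize:
    def test_single_call_vector(self, rng):
        scores = pd.DataFrame(
            [
                dict(bait=b, condition=c, prey="STX7", avg_p=0.0,
                     bfdr=0.01 if (b == "Dsc2a" and c == "ca_dependent") else 0.9,
                     log2fc=1.0)
                for b in BAITS
                for c in CONDITIONS
            ]
        )
        profiles = binarize_profiles(scores, 0.05, BAITS, CONDITIONS)
        assert profiles.binary.loc["STX7"].tolist() == [1, 0, 0, 0, 0, 0, 0, 0]

    def test_never_significant_prey_excluded(self, rng):
        scores = random_scores(rng, n_preys=60)
        profiles = binarize_profiles(scores, 0.05, BAITS, CONDITIONS)
        brute = set(scores.loc[scores["bfdr"] <= 0.05, "prey"])
        assert set(profiles.preys) == brute
        assert (profiles.binary.sum(axis=1) >= 1).all()


class TestJaccard:
    def test_identical_and_disjoint(self):
        assert jaccard_distance([1, 1, 0], [1, 1, 0]) == 0.0
        assert jaccard_distance([1, 0, 0], [0, 1, 1]) == 1.0

    def test_half_overlap(self):
        assert jaccard_distance([1, 1, 0, 0], [1, 0, 0, 0]) == pytest.approx(0.5)

    def test_all_zero_vector_rejected(self):
        with pytest.raises(InputError):
            jaccard_distance([0, 0, 0], [1, 0, 0])

    def test_metric_axioms_on_random_vectors(self, rng):
        vectors = [
            rng.integers(0, 2, size=8) for _ in range(25)
        ]
        vectors = [v if v.any() else np.eye(8, dtype=int)[0] for v in vectors]
        for a, b in combinations(range(len(vectors)), 2):
            dab = jaccard_distance(vectors[a], vectors[b])
            dba = jaccard_distance(vectors[b], vectors[a])
            assert dab == dba
            assert 0.0 <= dab <= 1.0
            if np.array_equal(vectors[a], vectors[b]):
                assert dab == 0.0
        for a, b, c in combinations(range(12), 3):
            dab = jaccard_distance(vectors[a], vectors[b])
            dbc = jaccard_distance(vectors[b], vectors[c])
            dac = jaccard_distance(vectors[a], vectors[c])
            assert dac <= dab + dbc + 1e-12


class TestCluster:
    def test_two_identical_groups_recovered(self):
        vectors = {f"a{i}": [1, 1, 0, 0, 0, 0, 0, 0] for i in range(4)}
        vectors.update({f"b{i}": [0, 0, 0, 0, 0, 0, 1, 1] for i in range(3)})
        assignment = cluster_preys(profile_set(vectors), k=2)
        labels = assignment.labels
        assert len(set(labels[[f"a{i}" for i in range(4)]])) == 1
        assert len(set(labels[[f"b{i}" for i in range(3)]])) == 1
        assert labels["a0"] != labels["b0"]

    def test_three_block_structure_recovered(self):
        blocks = {
            "x": [1, 1, 1, 1, 0, 0, 0, 0],
            "y": [0, 0, 0, 0, 1, 1, 0, 0],
            "z": [0, 0, 0, 0, 0, 0, 1, 1],
        }
        vectors = {}
        for name, base in blocks.items():
            for i in range(4):
                vectors[f"{name}{i}"] = base
        assignment = cluster_preys(profile_set(vectors), k=3)
        for name in blocks:
            members = [f"{name}{i}" for i in range(4)]
            assert len(set(assignment.labels[members])) == 1
        assert len(set(assignment.labels)) == 3

    def test_cluster_indices_contiguous_and_leaf_ordered(self):
        vectors = {f"p{i}": [1, 1, 0, 0, 0, 0, 0, 0] for i in range(3)}
        vectors.update({f"q{i}": [0, 0, 0, 0, 0, 1, 1, 1] for i in range(3)})
        assignment = cluster_preys(profile_set(vectors), k=2)
        assert sorted(set(assignment.labels)) == [1, 2]
        first_leaf = assignment.leaf_order[0]
        assert assignment.labels[first_leaf] == 1

    def test_input_order_invariance(self, rng):
        vectors = {}
        for i in range(15):
            v = rng.integers(0, 2, 8)
            if not v.any():
                v = np.eye(8, dtype=int)[i % 8]
            vectors[f"p{i}"] = v
        base = profile_set({k: list(v) for k, v in vectors.items()})
        shuffled_keys = list(vectors)
        rng.shuffle(shuffled_keys)
        shuffled = profile_set({k: list(vectors[k]) for k in shuffled_keys})
        a = cluster_preys(base, k=4).labels
        b = cluster_preys(shuffled, k=4).labels
        assert (a.sort_index() == b.sort_index()).all()

    def test_k_larger_than_n_rejected(self):
        vectors = {"a": [1, 0, 0, 0, 0, 0, 0, 0], "b": [0, 1, 0, 0, 0, 0, 0, 0]}
        with pytest.raises(ParameterError):
            cluster_preys(profile_set(vectors), k=5)


class TestCategorize:
    def test_pan_bait_constant_prey(self):
        profiles = profile_set({"KIAA1217": [1] * 8})
        calls = categorize_maturation(profiles).set_index("prey")
        assert calls.loc["KIAA1217", "category"] == "constant"
        assert calls.loc["KIAA1217", "n_baits"] == 3  # PG termini merged

    def test_single_bait_calcium_prey(self):
        profiles = profile_set({"STX7": [1, 0, 0, 0, 0, 0, 0, 0]})
        calls = categorize_maturation(profiles).set_index("prey")
        assert calls.loc["STX7", "category"] == "calcium_dependent"
        assert calls.loc["STX7", "n_baits"] == 1

    def test_pg_hyper_only_prey(self):
        profiles = profile_set({"CLSTN1": [0, 0, 0, 1, 0, 1, 0, 0]})
        calls = categorize_maturation(profiles).set_index("prey")
        assert calls.loc["CLSTN1", "category"] == "hyper_adhesive"
        assert calls.loc["CLSTN1", "n_baits"] == 1  # both hits are PG termini

    def test_categories_partition_preys(self, rng):
        scores = random_scores(rng, n_preys=80)
        profiles = binarize_profiles(scores, 0.05, BAITS, CONDITIONS)
        calls = categorize_maturation(profiles)
        counts = calls["category"].value_counts()
        assert counts.sum() == len(profiles.preys)
        ca = len(profiles.significant_in_condition("ca_dependent"))
        hyper = len(profiles.significant_in_condition("hyper_adhesive"))
        assert counts.get("constant", 0) + counts.get("calcium_dependent", 0) == ca
        assert counts.get("constant", 0) + counts.get("hyper_adhesive", 0) == hyper


class TestHeatmap:
    def test_rows_are_leaf_ordered_permutation_with_nd(self, rng):
        scores = random_scores(rng, n_preys=40)
        # make some fold changes undetected
        scores.loc[scores.sample(frac=0.1, random_state=1).index, "log2fc"] = np.nan
        profiles = binarize_profiles(scores, 0.05, BAITS, CONDITIONS)
        clusters = cluster_preys(profiles, k=4)
        hm = heatmap_matrix(profiles, clusters)
        assert sorted(hm.index) == sorted(profiles.preys)
        assert list(hm.index) == clusters.leaf_order
        # pass-through of the scored fold changes
        for prey in profiles.preys[:5]:
            for ds in hm.columns:
                bait, condition = ds.split("|")
                row = scores[(scores["bait"] == bait) & (scores["condition"] == condition)
                             & (scores["prey"] == prey)]
                expected = row["log2fc"].iloc[0]
                got = hm.at[prey, ds]
                assert (np.isnan(expected) and np.isnan(got)) or got == expected


class TestScatter:
    def make_scores(self, pairs, bait="Dsc2a"):
        rows = []
        for i, (x, y) in enumerate(pairs):
            rows.append(dict(bait=bait, condition="ca_dependent", prey=f"p{i}",
                             avg_p=1.0, bfdr=0.0, log2fc=x, significant=True))
            rows.append(dict(bait=bait, condition="hyper_adhesive", prey=f"p{i}",
                             avg_p=1.0, bfdr=0.0, log2fc=y, significant=True))
        return pd.DataFrame(rows)

    def test_closed_form_ols(self):
        fit = scatter_pairs(self.make_scores([(1, 2), (2, 4), (3, 6)]), "Dsc2a")
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)

    def test_exact_fit_has_zero_width_band(self):
        fit = scatter_pairs(self.make_scores([(1, 1), (2, 2), (3, 3), (4, 4)]), "Dsc2a")
        assert np.allclose(fit.conf_upper - fit.conf_lower, 0.0, atol=1e-8)

    def test_band_narrowest_at_mean_x(self, rng):
        pairs = [(x, 2 * x + rng.normal(0, 0.5)) for x in rng.uniform(0, 5, 30)]
        fit = scatter_pairs(self.make_scores(pairs), "Dsc2a")
        widths = fit.conf_upper - fit.conf_lower
        xbar = fit.points["x"].mean()
        nearest = np.argmin(np.abs(fit.x_sorted - xbar))
        assert widths[nearest] == pytest.approx(widths.min(), rel=1e-6)

    def test_too_few_shared_preys_raises(self):
        with pytest.raises(StatisticsError):
            scatter_pairs(self.make_scores([(1, 2), (2, 4)]), "Dsc2a")


def test_linkage_method_is_configurable():
    vectors = {f"a{i}": [1, 1, 0, 0, 0, 0, 0, 0] for i in range(3)}
    vectors.update({f"b{i}": [0, 0, 0, 0, 0, 0, 1, 1] for i in range(3)})
    profiles = profile_set(vectors)
    for method in ("average", "complete", "single"):
        assignment = cluster_preys(profiles, k=2, method=method)
        assert len(set(assignment.labels[[f"a{i}" for i in range(3)]])) == 1
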