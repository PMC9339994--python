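"""Alpha diversity closed forms, phylum abundance, Venn regions."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ashcarbon.diversity import (
    AsvTable,
    alpha_diversity,
    diversity_property_correlations,
    phylum_abundance,
    rarefy,
    venn_counts,
)


def make_table(counts, treatments=None, phyla=None):
    counts = np.atleast_2d(np.asarray(counts))
    n, t = counts.shape
    samples = [f"s{i}" for i in range(n)]
    taxa = [f"t{j}" for j in range(t)]
    if treatments is None:
        treatments = ["Control"] * n
    metadata = pd.DataFrame(
        {"treatment": treatments, "replicate": list(range(1, n + 1))}, index=samples
    )
    taxonomy = pd.Series(phyla if phyla is not None else ["P1"] * t, index=taxa)
    return AsvTable(pd.DataFrame(counts, index=samples, columns=taxa), metadata, taxonomy)


class TestAlphaDiversity:
    def test_uniform_profile_shannon_is_log2_richness(self):
        out = alpha_diversity(make_table([[10, 10, 10, 10]]))
        assert out["shannon"].iloc[0] == pytest.approx(2.0)
        assert out["observed_features"].iloc[0] == 4

    def test_hand_computed_toy(self):
        # counts (1,1,2): H=1.5 bits, F1=2, F2=1 -> chao1=3.5, goods=0.5
        out = alpha_diversity(make_table([[1, 1, 2]]))
        assert out["shannon"].iloc[0] == pytest.approx(1.5)
        assert out["chao1"].iloc[0] == pytest.approx(3.5)
        assert out["goods_coverage"].iloc[0] == pytest.approx(0.5)

    def test_no_singletons_collapses_estimators(self):
        out = alpha_diversity(make_table([[5, 9, 2, 7]]))
        assert out["chao1"].iloc[0] == out["observed_features"].iloc[0]
        assert out["goods_coverage"].iloc[0] == 1.0

    def test_single_taxon_zero_entropy(self):
        out = alpha_diversity(make_table([[100]]))
        assert out["shannon"].iloc[0] == 0.0

    def test_shannon_maximal_iff_uniform(self, rng):
        k = 8
        uneven = rng.integers(1, 50, k) * np.array([1, 1, 1, 1, 1, 1, 1, 10])
        h_uneven = alpha_diversity(make_table([uneven]))["shannon"].iloc[0]
        h_uniform = alpha_diversity(make_table([[20] * k]))["shannon"].iloc[0]
        assert h_uniform == pytest.approx(np.log2(k))
        assert h_uneven < h_uniform

    def test_chao1_at_least_observed(self, rng):
        counts = rng.integers(0, 6, size=(10, 40))
        counts[:, 0] = 1  # guarantee non-empty samples
        out = alpha_diversity(make_table(counts.tolist()))
        assert (out["chao1"] >= out["observed_features"] - 1e-9).all()
        assert out["goods_coverage"].between(0, 1).all()

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            alpha_diversity(make_table([[1.5, 2.2]]))


class TestPhylumAbundance:
    def test_single_phylum(self):
        out = phylum_abundance(make_table([[3, 7]]))
        assert out["per_sample"].iloc[0, 0] == 1.0

    def test_two_phyla_proportions(self):
        out = phylum_abundance(make_table([[300, 700]], phyla=["A", "B"]))
        assert out["per_sample"].loc["s0", "A"] == pytest.approx(0.3)
        assert out["per_sample"].loc["s0", "B"] == pytest.approx(0.7)

    def test_rows_sum_to_one(self, noisy_dataset):
        per_sample = phylum_abundance(noisy_dataset.asv)["per_sample"]
        assert np.allclose(per_sample.sum(axis=1), 1.0, atol=1e-9)

    def test_invariant_to_relabeling_within_phylum(self):
        t1 = make_table([[10, 20, 30]], phyla=["A", "A", "B"])
        # swap counts of the two A-taxa: phylum totals unchanged
        t2 = make_table([[20, 10, 30]], phyla=["A", "A", "B"])
        pd.testing.assert_frame_equal(
            phylum_abundance(t1)["per_sample"], phylum_abundance(t2)["per_sample"]
        )


def venn_oracle(presence_sets: dict[str, set]) -> dict[str, int]:
    """Brute-force region counts by enumerating every feature's membership."""
    groups = list(presence_sets)
    regions: dict[str, int] = {}
    all_features = set().union(*presence_sets.values())
    for k in range(1, len(groups) + 1):
        for combo in itertools.combinations(groups, k):
            count = 0
            for f in all_features:
                member = {g for g in groups if f in presence_sets[g]}
                if member == set(combo):
                    count += 1
            regions["&".join(combo)] = count
    regions["total"] = len(all_features)
    return regions


class TestVenn:
    def test_identical_groups_all_central(self):
        counts = [[1, 2, 3]] * 4
        table = make_table(counts, treatments=["Control", "W", "S", "SW"])
        out = venn_counts(table)
        assert out["Control&W&S&SW"] == 3
        assert out["total"] == 3
        assert sum(v for k, v in out.items() if k != "total") == 3

    def test_disjoint_groups_only_exclusive_regions(self):
        counts = np.zeros((4, 8), dtype=int)
        for i in range(4):
            counts[i, 2 * i : 2 * i + 2] = 5
        table = make_table(counts.tolist(), treatments=["Control", "W", "S", "SW"])
        out = venn_counts(table)
        for g in ("Control", "W", "S", "SW"):
            assert out[g] == 2
        assert all(v == 0 for k, v in out.items() if "&" in k)

    def test_matches_brute_force_on_random_toy(self, rng):
        counts = rng.integers(0, 2, size=(8, 20)) * rng.integers(1, 9, size=(8, 20))
        treatments = ["Control", "Control", "W", "W", "S", "S", "SW", "SW"]
        counts[:, 0] = 1
        table = make_table(counts.tolist(), treatments=treatments)
        got = venn_counts(table)
        presence = {
            g: {
                j
                for j in range(20)
                if counts[[i for i, t in enumerate(treatments) if t == g]][:, j].sum() > 0
            }
            for g in ("Control", "W", "S", "SW")
        }
        want = venn_oracle(presence)
        assert got == want

    def test_region_counts_sum_to_total(self, noisy_dataset):
        out = venn_counts(noisy_dataset.asv)
        assert sum(v for k, v in out.items() if k != "total") == out["total"]


class TestPropertyCorrelations:
    def test_duplicated_vector_correlates_perfectly(self, rng):
        counts = rng.integers(1, 50, size=(12, 30))
        treatments = np.repeat(["Control", "W", "S", "SW"], 3)
        table = make_table(counts.tolist(), treatments=list(treatments))
        table.metadata["replicate"] = list(np.tile([1, 2, 3], 4))
        alpha = alpha_diversity(table)
        pools = alpha.reset_index()[["treatment", "replicate"]].copy()
        pools["mirror"] = alpha["shannon"].to_numpy()
        pools["anti"] = -alpha["shannon"].to_numpy()
        out = diversity_property_correlations(alpha, pools)
        assert out["r"].loc["shannon", "mirror"] == pytest.approx(1.0)
        assert out["r"].loc["shannon", "anti"] == pytest.approx(-1.0)

    def test_matches_numpy_pearson(self, rng):
        counts = rng.integers(1, 80, size=(12, 25))
        treatments = np.repeat(["Control", "W", "S", "SW"], 3)
        table = make_table(counts.tolist(), treatments=list(treatments))
        table.metadata["replicate"] = list(np.tile([1, 2, 3], 4))
        alpha = alpha_diversity(table)
        pools = alpha.reset_index()[["treatment", "replicate"]].copy()
        pools["doc"] = rng.normal(70, 10, 12)
        out = diversity_property_correlations(alpha, pools)
        want = np.corrcoef(alpha["shannon"], pools["doc"])[0, 1]
        assert out["r"].loc["shannon", "doc"] == pytest.approx(want, abs=1e-12)


def test_rarefy_even_depth(noisy_dataset):
    table = noisy_dataset.asv
    depth = int(table.counts.sum(axis=1).min() // 2)
    sub = rarefy(table, depth, seed=1)
    assert (sub.counts.sum(axis=1) == depth).all()
    assert (sub.counts <= table.counts).all().all()
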