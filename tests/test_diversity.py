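"""Alpha indices, Venn partitions, Bray-Curtis, and PERMANOVA behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from skbio.diversity.alpha import ace as skbio_ace
from skbio.diversity.alpha import chao1 as skbio_chao1
from skbio.diversity.alpha import shannon as skbio_shannon
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from rumenbatch import diversity as dv
from rumenbatch import presets, synthetic
from rumenbatch.errors import InvalidInputError, UndefinedValueError

counts_strategy = st.lists(st.integers(min_value=0, max_value=200),
                           min_size=2, max_size=40).filter(lambda c: sum(c) > 1)


class TestAlpha:
    def test_uniform_community_maximum_entropy(self):
        a = dv.alpha_indices([1000] * 10)
        assert a.shannon == pytest.approx(np.log(10), rel=1e-9)

    def test_single_taxon(self):
        a = dv.alpha_indices([50])
        assert a.shannon == 0.0
        assert a.simpson == 1.0
        assert a.chao1 == a.observed_otus == 1

    def test_hand_evaluated_sample(self):
        # counts {5,3,1,1}: F1=2, F2=0 -> bias-corrected Chao1 = 5;
        # coverage = 1 - 2/10 = 0.8
        a = dv.alpha_indices([5, 3, 1, 1])
        assert a.chao1 == pytest.approx(5.0)
        assert a.goods_coverage == pytest.approx(0.8)
        assert a.observed_otus == 4
        n = 10
        simpson = (5 * 4 + 3 * 2 + 0 + 0) / (n * (n - 1))
        assert a.simpson == pytest.approx(simpson)

    def test_empty_sample_undefined(self):
        with pytest.raises(UndefinedValueError):
            dv.alpha_indices([0, 0])

    @given(counts=counts_strategy)
    def test_oracle_agreement_with_skbio(self, counts):
        c = np.asarray(counts)
        if c.sum() == 0:
            return
        a = dv.alpha_indices(c)
        assert a.shannon == pytest.approx(skbio_shannon(c, base=np.e),
                                          rel=1e-9, abs=1e-12)
        assert a.chao1 == pytest.approx(skbio_chao1(c, bias_corrected=False),
                                        rel=1e-9)
        pos = c[c > 0]
        rare = pos[pos <= 10]
        # skbio's ACE rejects edge cases our implementation handles by
        # falling back to Chao1; compare only where both are defined
        if rare.size and (rare == 1).sum() not in (0, rare.sum()):
            assert a.ace == pytest.approx(skbio_ace(c, rare_threshold=10),
                                          rel=1e-9)

    @given(counts=counts_strategy)
    def test_richness_estimators_bound_observed(self, counts):
        c = np.asarray(counts)
        if c.sum() == 0:
            return
        a = dv.alpha_indices(c)
        assert a.chao1 >= a.observed_otus - 1e-9
        assert a.ace >= a.observed_otus - 1e-9
        assert 0.0 <= a.goods_coverage <= 1.0
        assert 0.0 <= a.simpson <= 1.0
        assert a.shannon >= 0.0


class TestVenn:
    def frame(self, rows, taxa):
        df = pd.DataFrame(rows, columns=taxa)
        df.index = [f"s{i}" for i in range(len(rows))]
        return df

    def test_identical_groups_all_shared(self):
        counts = self.frame([[3, 1, 0], [3, 1, 0]], ["a", "b", "c"])
        venn = dv.otu_venn(counts, ["G1", "G2"])
        assert venn[("G1", "G2")] == 2
        assert venn[("G1",)] == venn[("G2",)] == 0

    def test_disjoint_groups(self):
        counts = self.frame([[5, 0], [0, 5]], ["a", "b"])
        venn = dv.otu_venn(counts, ["G1", "G2"])
        assert venn[("G1", "G2")] == 0
        assert venn[("G1",)] == venn[("G2",)] == 1

    def test_constructed_four_group_partition(self):
        """Recover a known partition: 2079 OTUs shared by all four groups and
        13/11/10/7 unique to SN/Control/CSN/CS."""
        unique = {"SN": 13, "Control": 11, "CSN": 10, "CS": 7}
        groups = ["Control", "SN", "CS", "CSN"]
        n_shared = 2079
        taxa = [f"OTU{i}" for i in range(n_shared + sum(unique.values()))]
        rows = []
        start = {}
        offset = n_shared
        for g in groups:
            start[g] = offset
            offset += unique[g]
        for g in groups:
            row = np.zeros(len(taxa), dtype=int)
            row[:n_shared] = 1
            row[start[g]:start[g] + unique[g]] = 1
            rows.append(row)
        counts = self.frame(rows, taxa)
        venn = dv.otu_venn(counts, groups)
        assert venn[tuple(groups)] == 2079
        for g in groups:
            assert venn[(g,)] == unique[g]

    def test_requires_two_groups(self):
        counts = self.frame([[1]], ["a"])
        with pytest.raises(InvalidInputError):
            dv.otu_venn(counts, ["only"])


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        counts = pd.DataFrame([[4, 6], [4, 6]])
        assert dv.bray_curtis(counts).data[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        counts = pd.DataFrame([[4, 0], [0, 9]])
        assert dv.bray_curtis(counts).data[0, 1] == 1.0

    def test_hand_arithmetic(self):
        counts = pd.DataFrame([[6, 2], [2, 2]])
        assert dv.bray_curtis(counts).data[0, 1] == pytest.approx(1 / 3)

    def test_two_all_zero_samples_undefined(self):
        counts = pd.DataFrame([[0, 0], [0, 0], [1, 1]])
        with pytest.raises(UndefinedValueError):
            dv.bray_curtis(counts)

    @given(x=st.lists(st.integers(0, 100), min_size=3, max_size=10),
           y=st.lists(st.integers(0, 100), min_size=3, max_size=10))
    def test_bounds_symmetry_zero_taxon_invariance(self, x, y):
        k = min(len(x), len(y))
        x, y = x[:k], y[:k]
        if sum(x) == 0 and sum(y) == 0:
            return
        dm = dv.bray_curtis(pd.DataFrame([x, y]))
        d = dm.data[0, 1]
        assert 0.0 <= d <= 1.0
        assert dm.data[1, 0] == d
        padded = dv.bray_curtis(pd.DataFrame([x + [0], y + [0]]))
        assert padded.data[0, 1] == pytest.approx(d, abs=1e-12)


class TestPermanova:
    def dataset(self, seed=0, n_per=6, distinct=True):
        cfg = synthetic.SyntheticConfig(seed=seed)
        comps = presets.group_compositions()
        chosen = {"Control": comps["Control"],
                  "SN": comps["SN"] if distinct else comps["Control"]}
        table = synthetic.generate_otu_table(cfg, chosen, depth=2000,
                                             n_samples_per_group=n_per)
        counts = table.drop(columns=["sample_id", "group"])
        return dv.bray_curtis(counts), table["group"].to_numpy()

    def test_pseudo_f_matches_skbio(self):
        dm, groups = self.dataset()
        ours = dv.permanova(dm, groups, n_permutations=99, seed=1)
        theirs = skbio_permanova(DistanceMatrix(dm.data, ids=dm.ids),
                                 grouping=list(groups), permutations=99)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"],
                                              rel=1e-9)

    def test_power_on_distinct_compositions(self):
        cfg = synthetic.SyntheticConfig(seed=5)
        comps = presets.group_compositions()
        table = synthetic.generate_otu_table(
            cfg, {"Control": comps["Control"], "SN": comps["SN"]},
            depth=10_000, n_samples_per_group=10)
        counts = table.drop(columns=["sample_id", "group"])
        res = dv.permanova(dv.bray_curtis(counts), table["group"].to_numpy(),
                           n_permutations=999, seed=2)
        assert res.p_value <= 0.01

    def test_no_structure_when_samples_identical(self):
        counts = pd.DataFrame([[5, 5, 1]] * 8)
        res = dv.permanova(dv.bray_curtis(counts), ["A"] * 4 + ["B"] * 4,
                           n_permutations=99, seed=0)
        assert res.pseudo_f == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_reordering_invariance(self):
        dm, groups = self.dataset(seed=3)
        base = dv.permanova(dm, groups, n_permutations=199, seed=7)
        order = np.arange(len(groups))[::-1]
        d2 = dm.data[np.ix_(order, order)]
        re = dv.permanova(d2, groups[order], n_permutations=199, seed=7)
        assert re.pseudo_f == pytest.approx(base.pseudo_f, rel=1e-9)
        assert re.r_squared == pytest.approx(base.r_squared, rel=1e-9)

    def test_minimum_attainable_p(self):
        dm, groups = self.dataset(seed=1, n_per=10)
        res = dv.permanova(dm, groups, n_permutations=199, seed=0)
        assert res.p_value >= 1.0 / 200.0

    def test_determinism_under_seed(self):
        dm, groups = self.dataset(seed=2)
        a = dv.permanova(dm, groups, n_permutations=199, seed=11)
        b = dv.permanova(dm, groups, n_permutations=199, seed=11)
        assert a == b

    def test_singleton_group_warns(self):
        counts = pd.DataFrame(np.arange(12).reshape(4, 3))
        dm = dv.bray_curtis(counts)
        with pytest.warns(UserWarning):
            dv.permanova(dm, ["A", "A", "A", "B"], n_permutations=19, seed=0)

    def test_invalid_permutation_count(self):
        counts = pd.DataFrame(np.arange(12).reshape(4, 3))
        dm = dv.bray_curtis(counts)
        with pytest.raises(InvalidInputError):
            dv.permanova(dm, ["A", "A", "B", "B"], n_permutations=0)


def test_rarefy_preserves_depth_and_support():
    counts = np.array([100, 50, 0, 7])
    out = dv.rarefy(counts, 80, seed=4)
    assert out.sum() == 80
    assert out[2] == 0
    assert np.all(out <= counts)
    with pytest.raises(InvalidInputError):
        dv.rarefy(counts, 1000)
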