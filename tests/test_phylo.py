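"""Faith's PD, MNTD and the SES/NTI machinery against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from skbio.diversity.alpha import faith_pd as skbio_faith_pd

import phylosalt as ps
from conftest import brute_faith_pd, brute_mntd, random_tree


class TestFaithPD:
    def test_full_tree_identity(self, quartet_tree):
        total = sum(n.length for n in
                    quartet_tree.traverse(include_self=False))
        for flag in (True, False):
            assert ps.faith_pd(quartet_tree, list("ABCD"),
                               include_root=flag) == pytest.approx(total)

    def test_quartet_pair(self, quartet_tree):
        assert ps.faith_pd(quartet_tree, ["A", "B"],
                           include_root=True) == pytest.approx(3.0)
        assert ps.faith_pd(quartet_tree, ["A", "B"],
                           include_root=False) == pytest.approx(2.0)

    def test_single_tip_root_path(self, quartet_tree):
        assert ps.faith_pd(quartet_tree, ["A"],
                           include_root=True) == pytest.approx(2.0)

    def test_unknown_tip_named(self, quartet_tree):
        with pytest.raises(KeyError, match="Z"):
            ps.faith_pd(quartet_tree, ["A", "Z"])

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_and_skbio(self, seed):
        tree = random_tree(int(5 + seed % 10), seed)
        tips = [t.name for t in tree.tips()]
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, len(tips)))
        subset = list(rng.choice(tips, size=k, replace=False))
        for flag in (True, False):
            assert ps.faith_pd(tree, subset, include_root=flag) == \
                pytest.approx(brute_faith_pd(tree, subset, flag), abs=1e-9)
        counts = np.array([1 if t in subset else 0 for t in tips])
        assert ps.faith_pd(tree, subset, include_root=True) == \
            pytest.approx(skbio_faith_pd(counts, tips, tree), abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_in_tip_set(self, seed):
        tree = random_tree(10, seed)
        tips = [t.name for t in tree.tips()]
        rng = np.random.default_rng(seed)
        rng.shuffle(tips)
        last = 0.0
        for k in range(1, len(tips) + 1):
            pd_k = ps.faith_pd(tree, tips[:k])
            assert pd_k >= last - 1e-12
            last = pd_k


class TestMNTD:
    def test_sister_pair(self, quartet_tree):
        assert ps.mntd(quartet_tree, ["A", "B"]) == pytest.approx(2.0)

    def test_equidistant_set(self):
        star = ps.parse_tree("(A:1.5,B:1.5,C:1.5,D:1.5);")
        assert ps.mntd(star, list("ABCD")) == pytest.approx(3.0)

    def test_needs_two_tips(self, quartet_tree):
        with pytest.raises(ValueError):
            ps.mntd(quartet_tree, ["A"])

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force(self, seed):
        tree = random_tree(int(5 + seed % 12), seed + 100)
        tips = [t.name for t in tree.tips()]
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, len(tips) + 1))
        subset = list(rng.choice(tips, size=k, replace=False))
        assert ps.mntd(tree, subset) == pytest.approx(
            brute_mntd(tree, subset), abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_at_most_mean_pairwise(self, seed):
        tree = random_tree(12, seed + 200)
        tips = [t.name for t in tree.tips()]
        rng = np.random.default_rng(seed)
        subset = list(rng.choice(tips, size=6, replace=False))
        dm = tree.tip_tip_distances()
        pairs = [dm[a, b] for i, a in enumerate(subset)
                 for b in subset[i + 1:]]
        assert ps.mntd(tree, subset) <= np.mean(pairs) + 1e-12


class TestSesStatistic:
    def test_degenerate_full_pool(self, quartet_tree):
        res = ps.ses_statistic(quartet_tree, list("ABCD"), metric="PD",
                               null=ps.NullModelSpec(runs=99, seed=0))
        assert np.isnan(res.ses)
        assert "degenerate" in res.note
        assert 0 < res.p_lower <= 1 and 0 < res.p_upper <= 1

    def test_seed_reproducibility(self):
        tree = random_tree(30, 5, ultrametric=True)
        tips = [t.name for t in tree.tips()][:10]
        a = ps.ses_statistic(tree, tips, "MNTD",
                             ps.NullModelSpec(runs=199, seed=4))
        b = ps.ses_statistic(tree, tips, "MNTD",
                             ps.NullModelSpec(runs=199, seed=4))
        assert a == b

    def test_perfect_clade_is_clustered(self):
        # one 8-tip clade of a 64-tip balanced unit-branch-length tree
        counter = iter(range(64))
        def balanced(depth):
            if depth == 0:
                return f"L{next(counter)}:1"
            return f"({balanced(depth - 1)},{balanced(depth - 1)}):1"
        newick = balanced(6) + ";"
        tree = ps.parse_tree(newick, missing_length="zero")
        clade_tips = [t.name for t in tree.children[0].children[0]
                      .children[0].tips()]
        assert len(clade_tips) == 8
        runs = 199
        res_pd = ps.ses_statistic(tree, clade_tips, "PD",
                                  ps.NullModelSpec(runs=runs, seed=0))
        res_mntd = ps.ses_statistic(tree, clade_tips, "MNTD",
                                    ps.NullModelSpec(runs=runs, seed=0))
        assert res_pd.ses < 0
        assert res_mntd.nti > 0
        # a random 8-subset essentially never reaches this clade's tightness
        assert res_pd.p_lower == pytest.approx(1 / (runs + 1))
        assert res_mntd.p_lower == pytest.approx(1 / (runs + 1))

    def test_rank_p_plus_one_convention(self):
        tree = random_tree(20, 7, ultrametric=True)
        tips = [t.name for t in tree.tips()][:6]
        res = ps.ses_statistic(tree, tips, "PD",
                               ps.NullModelSpec(runs=99, seed=1))
        assert res.p_lower >= 1 / 100
        assert res.p_upper >= 1 / 100
        # lower and upper ranks overlap on ties, so they sum to > 1
        assert res.p_lower + res.p_upper > 1 / 100


class TestSignalReport:
    def test_relabeling_invariance(self):
        tree_a = random_tree(24, 3, ultrametric=True)
        newick = str(tree_a)
        mapping = {t.name: f"x_{t.name}" for t in tree_a.tips()}
        tree_b = ps.parse_tree(newick)
        for tip in tree_b.tips():
            tip.name = mapping[tip.name]
        rng = np.random.default_rng(0)
        labels = rng.choice(["fresh", "salt", "none"],
                            size=len(mapping))
        asg_a = pd.DataFrame({"preference": labels},
                             index=list(mapping.keys()))
        asg_b = pd.DataFrame({"preference": labels},
                             index=[mapping[k] for k in mapping])
        null = ps.NullModelSpec(runs=199, seed=11)
        rep_a = ps.signal_report(tree_a, asg_a, null=null)
        rep_b = ps.signal_report(tree_b, asg_b, null=null)
        num = ["observed", "null_mean", "null_sd", "ses", "p_lower"]
        assert np.allclose(rep_a[num].to_numpy(), rep_b[num].to_numpy(),
                           equal_nan=True)

    def test_small_groups_skipped(self):
        tree = random_tree(10, 1, ultrametric=True)
        tips = [t.name for t in tree.tips()]
        asg = pd.DataFrame(
            {"preference": ["fresh"] + ["salt"] * (len(tips) - 1)},
            index=tips)
        rep = ps.signal_report(tree, asg,
                               null=ps.NullModelSpec(runs=99, seed=0))
        assert set(rep["group"]) == {"salt"}

    def test_nti_is_negated_mntd_ses(self, small_dataset):
        pres = ps.collapse_presence(small_dataset["table"],
                                    small_dataset["metadata"])
        asg = ps.classify_preference(pres)
        tab, tree = ps.align_inputs(small_dataset["table"],
                                    small_dataset["tree"])
        rep = ps.signal_report(tree, asg,
                               null=ps.NullModelSpec(runs=199, seed=2))
        mntd_rows = rep[rep["metric"] == "MNTD"]
        assert np.allclose(mntd_rows["nti"], -mntd_rows["ses"],
                           equal_nan=True)
        pd_rows = rep[rep["metric"] == "PD"]
        assert pd_rows["nti"].isna().all()
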