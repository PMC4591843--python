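"""Filtering, rarefaction, presence collapsing and Venn membership."""

import itertools

import numpy as np
import pandas as pd
import pytest

import phylosalt as ps


def table_from_counts(counts, taxa=None, samples=None):
    counts = np.asarray(counts)
    taxa = taxa or [f"t{i}" for i in range(counts.shape[0])]
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    return ps.TaxonCountTable(pd.DataFrame(counts, index=taxa, columns=samples))


class TestFilterRareTaxa:
    def test_strict_threshold_boundary(self):
        # grand total 1,000,000; 0.005% = 50 reads: 49 removed, 50 retained
        counts = np.array([[49], [50], [1_000_000 - 99]])
        table = table_from_counts(counts, taxa=["below", "at", "big"])
        out = ps.filter_rare_taxa(table, 5e-5)
        assert out.taxon_ids == ["at", "big"]

    def test_zero_fraction_is_identity(self, toy_table):
        assert ps.filter_rare_taxa(toy_table, 0.0) == toy_table

    def test_order_stable_and_nonnegative(self):
        rng = np.random.default_rng(0)
        table = table_from_counts(rng.integers(0, 100, (30, 4)) + 1)
        out = ps.filter_rare_taxa(table, 0.01)
        kept = [t for t in table.taxon_ids if t in set(out.taxon_ids)]
        assert out.taxon_ids == kept
        assert (out.counts >= 0).all()

    def test_all_removed_fatal(self, toy_table):
        with pytest.raises(ValueError, match="every taxon"):
            ps.filter_rare_taxa(toy_table, 0.99)


class TestRarefy:
    def test_exact_depth_column_unchanged(self):
        table = table_from_counts([[3, 10], [7, 0]])
        out = ps.rarefy_counts(table, 10, seed=0)
        assert out.data["s0"].tolist() == [3, 7]
        assert out.data["s1"].sum() == 10

    def test_columns_sum_to_depth(self):
        rng = np.random.default_rng(1)
        table = table_from_counts(rng.integers(0, 500, (20, 6)) + 10)
        out = ps.rarefy_counts(table, 150, seed=3)
        assert (out.sample_totals == 150).all()
        assert (out.counts <= table.counts).all()  # without replacement

    def test_shallow_samples_listed(self):
        table = table_from_counts([[5, 100]], samples=["shallow", "deep"])
        with pytest.raises(ValueError, match="shallow"):
            ps.rarefy_counts(table, 50)

    def test_seeded_bit_identical(self):
        rng = np.random.default_rng(2)
        table = table_from_counts(rng.integers(0, 300, (15, 4)) + 5)
        a = ps.rarefy_counts(table, 100, seed=9)
        b = ps.rarefy_counts(table, 100, seed=9)
        assert a == b
        assert a != ps.rarefy_counts(table, 100, seed=10)

    def test_hypergeometric_mean(self):
        # expected rarefied count is depth * count / total per taxon
        counts = np.array([[40], [25], [10], [25]])
        table = table_from_counts(counts)
        depth, total, reps = 30, 100, 2000
        draws = np.stack([
            ps.rarefy_counts(table, depth, seed=s).counts[:, 0]
            for s in range(reps)
        ])
        expect = depth * counts[:, 0] / total
        p = counts[:, 0] / total
        var = depth * p * (1 - p) * (total - depth) / (total - 1)
        se = np.sqrt(var / reps)
        assert (np.abs(draws.mean(axis=0) - expect) <= 3 * se + 1e-12).all()


class TestCollapsePresence:
    def make(self, detections_per_treatment, replicates=5):
        """Single-taxon table with the given detection count per treatment."""
        rows = []
        cols = {}
        for trt, ndet in detections_per_treatment.items():
            origin = "fresh" if trt[0] == "F" else "salt"
            host = "fresh" if trt[1] == "F" else "salt"
            for rep in range(1, replicates + 1):
                sid = f"{trt}_{rep}"
                rows.append({"sample_id": sid, "origin": origin, "host": host,
                             "replicate": rep})
                cols[sid] = [1 if rep <= ndet else 0]
        meta = ps.SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))
        table = ps.TaxonCountTable(pd.DataFrame(cols, index=["tax"]))
        return table, meta

    @pytest.mark.parametrize("ndet,present", [(3, True), (2, False),
                                              (5, True), (0, False)])
    def test_majority_of_five(self, ndet, present):
        table, meta = self.make({"FF": ndet, "FS": 0, "SF": 0, "SS": 0})
        pres = ps.collapse_presence(table, meta)
        assert bool(pres.presence.loc["tax", "FF"]) is present

    def test_even_replicates_tie_is_absent(self):
        table, meta = self.make({"FF": 2, "FS": 0, "SF": 0, "SS": 0},
                                replicates=4)
        pres = ps.collapse_presence(table, meta)
        assert not pres.presence.loc["tax", "FF"]

    def test_column_order_invariance(self, design_metadata, small_dataset):
        table = small_dataset["table"]
        meta = small_dataset["metadata"]
        shuffled = ps.TaxonCountTable(
            table.data[list(reversed(table.sample_ids))])
        a = ps.collapse_presence(table, meta)
        b = ps.collapse_presence(shuffled, meta)
        assert a.presence.equals(b.presence)

    def test_min_count_floor(self):
        table, meta = self.make({"FF": 5, "FS": 0, "SF": 0, "SS": 0})
        table = ps.TaxonCountTable(table.data * 2)  # counts of 2
        assert ps.collapse_presence(table, meta, min_count=3).presence.loc[
            "tax", "FF"] == False  # noqa: E712

    def test_missing_metadata_fatal(self, small_dataset):
        table = small_dataset["table"]
        meta = small_dataset["metadata"]
        trimmed = ps.SampleMetadata(meta.data.iloc[:-1])
        with pytest.raises(ValueError, match="missing"):
            ps.collapse_presence(table, trimmed)


class TestSharedMembership:
    def test_all_treatments_region(self, small_dataset):
        pres = ps.collapse_presence(small_dataset["table"],
                                    small_dataset["metadata"])
        venn = ps.shared_membership(pres)
        row = venn[(venn[["FF", "FS", "SF", "SS"]] == 1).all(axis=1)]
        everywhere = pres.presence.all(axis=1).sum()
        assert row["n_taxa"].iloc[0] == everywhere

    def test_conservation(self, small_dataset):
        pres = ps.collapse_presence(small_dataset["table"],
                                    small_dataset["metadata"])
        venn = ps.shared_membership(pres)
        assert venn["n_taxa"].sum() == len(pres.taxon_ids)
        assert len(venn) == 16  # 2^4 regions incl. absent-everywhere

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed, design_metadata):
        rng = np.random.default_rng(seed)
        pres_df = pd.DataFrame(rng.random((40, 4)) < 0.5,
                               index=[f"t{i}" for i in range(40)],
                               columns=["FF", "FS", "SF", "SS"])
        det = pres_df.astype(int) * 3  # 3-of-5 support consistent with calls
        pres = ps.PresenceMatrix(pres_df, det,
                                 pd.Series(5, index=pres_df.columns))
        venn = ps.shared_membership(pres).set_index(["FF", "FS", "SF", "SS"])
        # brute force: assign each taxon to its unique region
        tally = {}
        for key in itertools.product([0, 1], repeat=4):
            tally[key] = 0
        for _, row in pres_df.iterrows():
            tally[tuple(int(v) for v in row)] += 1
        for key, n in tally.items():
            assert venn.loc[key, "n_taxa"] == n
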