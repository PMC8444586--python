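"""Fractional counting, normalization and support-based aggregation."""

import numpy as np
import pandas as pd
import pytest

from metage.containers import FeatureTable
from metage.profiling import (
    FunctionalHierarchy,
    UnnormalizableSampleError,
    aggregate_support,
    gene_counts_to_ko_counts,
    normalize_single_copy,
    profile_sample,
    reads_to_gene_counts,
)
from metage.simulate import SyntheticConfig, generate_hit_table


def hits_df(pairs):
    return pd.DataFrame(pairs, columns=["read_id", "gene_id"])


class TestReadCounting:
    def test_tied_read_splits_evenly(self):
        counts = reads_to_gene_counts(
            hits_df([("r1", "gA"), ("r2", "gA"), ("r2", "gB")])
        )
        assert counts["gA"] == pytest.approx(1.5)
        assert counts["gB"] == pytest.approx(0.5)

    def test_single_hit_reads_conserve_mass(self):
        pairs = [(f"r{i}", f"g{i % 7}") for i in range(100)]
        counts = reads_to_gene_counts(hits_df(pairs))
        assert counts.sum() == pytest.approx(100.0)

    def test_four_way_tie(self):
        counts = reads_to_gene_counts(
            hits_df([("r1", g) for g in ("g1", "g2", "g3", "g4")])
        )
        assert (counts == 0.25).all()
        assert counts.sum() == pytest.approx(1.0)

    def test_rejects_malformed(self):
        with pytest.raises(ValueError):
            reads_to_gene_counts(hits_df([]))
        with pytest.raises(ValueError):
            reads_to_gene_counts(hits_df([("r1", "gA"), ("r1", "gA")]))
        with pytest.raises(ValueError):
            reads_to_gene_counts(hits_df([("r1", None)]))

    def test_read_order_invariance(self):
        pairs = [("r1", "gA"), ("r2", "gA"), ("r2", "gB"), ("r3", "gC")]
        a = reads_to_gene_counts(hits_df(pairs))
        b = reads_to_gene_counts(hits_df(pairs[::-1]))
        pd.testing.assert_series_equal(a, b)


class TestKOCounting:
    def test_gene_split_over_three_kos(self):
        gene_counts = pd.Series({"g": 1.5})
        gmap = pd.DataFrame(
            {"gene_id": ["g", "g", "g"], "ko_id": ["K1", "K2", "K3"]}
        )
        ko, loss = gene_counts_to_ko_counts(gene_counts, gmap)
        assert (ko == 0.5).all() and loss == 0.0

    def test_all_unannotated(self):
        ko, loss = gene_counts_to_ko_counts(
            pd.Series({"g1": 2.0, "g2": 1.0}),
            pd.DataFrame({"gene_id": [], "ko_id": []}),
        )
        assert ko.empty and loss == pytest.approx(3.0)

    def test_conservation_with_partial_annotation(self):
        gene_counts = pd.Series({"g1": 2.0, "g2": 1.5, "g3": 0.5})
        gmap = pd.DataFrame(
            {"gene_id": ["g1", "g1", "g2"], "ko_id": ["K1", "K2", "K1"]}
        )
        ko, loss = gene_counts_to_ko_counts(gene_counts, gmap)
        assert ko.sum() + loss == pytest.approx(gene_counts.sum())
        assert loss == pytest.approx(0.5)

    def test_end_to_end_matches_generator_oracle(self):
        cfg = SyntheticConfig(n_features_ko=40, seed=3)
        hits, gmap, expected = generate_hit_table(cfg, n_reads=500)
        ko, loss = profile_sample(hits, gmap)
        n_reads = hits["read_id"].nunique()
        assert ko.sum() + loss == pytest.approx(n_reads, abs=1e-9)
        nonzero = expected[expected > 0]
        np.testing.assert_allclose(
            ko.reindex(nonzero.index, fill_value=0.0), nonzero, atol=1e-9
        )


def table_from(values, ids, samples=("s1",)):
    return FeatureTable(
        pd.DataFrame(
            np.asarray(values, float).reshape(len(ids), len(samples)),
            index=list(ids),
            columns=list(samples),
        ),
        level="ko",
    )


class TestNormalization:
    def test_median_scaling(self):
        t = table_from([8.0, 2.0, 4.0, 6.0], ["K9", "U1", "U2", "U3"])
        norm = normalize_single_copy(t, ["U1", "U2", "U3"])
        assert norm.data.loc["K9", "s1"] == pytest.approx(2.0)
        assert norm.data.loc[["U1", "U2", "U3"], "s1"].median() == pytest.approx(1.0)

    def test_scale_invariance_and_idempotence(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 10, size=(6, 3))
        ids = ["K1", "K2", "K3", "U1", "U2", "U3"]
        t1 = FeatureTable(pd.DataFrame(vals, index=ids, columns=list("abc")), "ko")
        t2 = FeatureTable(
            pd.DataFrame(vals * 17.3, index=ids, columns=list("abc")), "ko"
        )
        n1 = normalize_single_copy(t1, ["U1", "U2", "U3"])
        n2 = normalize_single_copy(t2, ["U1", "U2", "U3"])
        pd.testing.assert_frame_equal(n1.data, n2.data)
        again = normalize_single_copy(n1, ["U1", "U2", "U3"])
        assert np.max(np.abs(again.data.to_numpy() - n1.data.to_numpy())) < 1e-12

    def test_zero_median_names_sample(self):
        t = table_from([5.0, 0.0, 0.0, 1.0], ["K1", "U1", "U2", "U3"])
        with pytest.raises(UnnormalizableSampleError, match="s1"):
            normalize_single_copy(t, ["U1", "U2", "U3"])


def two_module_hierarchy():
    """M1 = {k1..k4, ks}, M2 = {m1..m4, ks}; ks is shared."""
    k2m = {f"k{i}": {"M1"} for i in range(1, 5)}
    k2m.update({f"m{i}": {"M2"} for i in range(1, 5)})
    k2m["ks"] = {"M1", "M2"}
    k2p = {k: {"P1"} for k in k2m}
    return FunctionalHierarchy.from_memberships(k2m, k2p)


class TestAggregation:
    def test_single_group_ko_gives_full_abundance(self):
        hier = two_module_hierarchy()
        t = table_from([3.0] + [0.0] * 8, ["k1", "k2", "k3", "k4", "ks"] + [f"m{i}" for i in range(1, 5)])
        agg, unmapped = aggregate_support(t, hier, "module")
        assert agg.data.loc["M1", "s1"] == pytest.approx(3.0)
        assert agg.data.loc["M2", "s1"] == 0.0
        assert unmapped["s1"] == 0.0

    def test_proportional_to_support(self):
        # detected: k1..k3 and ks -> M1 support 4/5; only ks in M2 -> 1/5
        hier = two_module_hierarchy()
        ids = ["k1", "k2", "k3", "k4", "ks", "m1", "m2", "m3", "m4"]
        vals = [2.0, 2.0, 2.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0]
        agg, _ = aggregate_support(table_from(vals, ids), hier, "module")
        assert agg.data.loc["M1", "s1"] == pytest.approx(6.0 + 0.8)
        assert agg.data.loc["M2", "s1"] == pytest.approx(0.2)

    def test_unmapped_tally_and_conservation(self):
        hier = two_module_hierarchy()
        ids = ["k1", "ks", "zzz"]  # zzz absent from the hierarchy
        agg, unmapped = aggregate_support(table_from([1.0, 2.0, 5.0], ids), hier, "module")
        assert unmapped["s1"] == pytest.approx(5.0)
        assert agg.data["s1"].sum() + unmapped["s1"] == pytest.approx(8.0)

    def test_sample_and_feature_order_invariance(self):
        rng = np.random.default_rng(4)
        hier = two_module_hierarchy()
        ids = ["k1", "k2", "k3", "k4", "ks", "m1", "m2", "m3", "m4"]
        vals = rng.uniform(0, 3, size=(9, 4)) * (rng.random((9, 4)) > 0.3)
        t = FeatureTable(pd.DataFrame(vals, index=ids, columns=list("wxyz")), "ko")
        perm_r = rng.permutation(9)
        perm_c = rng.permutation(4)
        t_perm = FeatureTable(t.data.iloc[perm_r, perm_c], "ko")
        a1, u1 = aggregate_support(t, hier, "module")
        a2, u2 = aggregate_support(t_perm, hier, "module")
        pd.testing.assert_frame_equal(a1.data, a2.data[a1.data.columns])
        pd.testing.assert_series_equal(u1, u2[u1.index])

    def test_inconsistent_hierarchy_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            FunctionalHierarchy(
                ko_to_modules={"k1": frozenset({"M1"})},
                ko_to_pathways={"k1": frozenset()},
                module_to_kos={"M1": frozenset()},
                pathway_to_kos={},
            )

    def test_tsv_round_trip(self, tmp_path):
        hier = two_module_hierarchy()
        path = tmp_path / "hier.tsv"
        hier.to_tsv(path)
        back = FunctionalHierarchy.from_tsv(path)
        assert back.ko_to_modules == hier.ko_to_modules
        assert back.pathway_to_kos == hier.pathway_to_kos
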