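"""Structural connectomes: validation, sparsity, quartiles, edge classes."""

import numpy as np
import pytest

from scfc.fc import THETA, FCMatrix
from scfc.sc import (
    EdgeClassMask,
    RangeThresholds,
    StructuralConnectome,
    classify_edges,
    count_range_connections,
    mask_fc_by_structure,
    mean_sc,
    quartile_thresholds,
    read_connectome,
    sparsity,
    write_connectome,
)


def build(fa_edges, len_edges, n):
    iu = np.triu_indices(n, k=1)
    F = np.zeros((n, n))
    L = np.zeros((n, n))
    F[iu] = fa_edges
    L[iu] = len_edges
    return StructuralConnectome(
        fa=F + F.T, lengths=L + L.T, node_labels=[f"n{i}" for i in range(n)]
    )


class TestValidation:
    def test_full_size_connectome_edge_count(self, make_connectome):
        sc = make_connectome(n_nodes=78)
        assert sc.n_edges == 3003

    def test_fa_out_of_range_names_cell(self):
        n = 3
        fa = np.zeros((n, n))
        fa[0, 1] = fa[1, 0] = 1.2
        L = np.ones((n, n)) - np.eye(n)
        with pytest.raises(ValueError, match=r"FA out of \[0, 1\] at \(n0, n1\)"):
            StructuralConnectome(fa=fa, lengths=L, node_labels=["n0", "n1", "n2"])

    def test_negative_lengths_rejected(self):
        n = 3
        L = -np.ones((n, n)) + np.eye(n)
        with pytest.raises(ValueError, match="non-negative"):
            StructuralConnectome(fa=np.zeros((n, n)), lengths=L, node_labels=list("abc"))

    def test_present_edge_needs_positive_length(self):
        n = 3
        fa = np.zeros((n, n))
        fa[0, 1] = fa[1, 0] = 0.5
        with pytest.raises(ValueError, match="positive tract length"):
            StructuralConnectome(fa=fa, lengths=np.zeros((n, n)), node_labels=list("abc"))


class TestIO:
    def test_roundtrip(self, make_connectome, tmp_path):
        sc = make_connectome(n_nodes=7)
        write_connectome(sc, tmp_path / "fa.tsv", tmp_path / "len.tsv")
        back = read_connectome(tmp_path / "fa.tsv", tmp_path / "len.tsv")
        np.testing.assert_allclose(back.fa, sc.fa)
        np.testing.assert_allclose(back.lengths, sc.lengths)
        assert back.node_labels == sc.node_labels

    def test_label_mismatch_rejected(self, make_connectome, tmp_path):
        import pandas as pd

        sc = make_connectome(n_nodes=4)
        write_connectome(sc, tmp_path / "fa.tsv", tmp_path / "len.tsv")
        df = pd.read_csv(tmp_path / "len.tsv", sep="\t", index_col=0)
        df.index = df.columns = ["x0", "x1", "x2", "x3"]
        df.to_csv(tmp_path / "len.tsv", sep="\t")
        with pytest.raises(ValueError, match="node labels differ"):
            read_connectome(tmp_path / "fa.tsv", tmp_path / "len.tsv")

    def test_asymmetric_input_symmetrized_with_warning(self, make_connectome, tmp_path):
        import pandas as pd

        sc = make_connectome(n_nodes=4)
        write_connectome(sc, tmp_path / "fa.tsv", tmp_path / "len.tsv")
        df = pd.read_csv(tmp_path / "fa.tsv", sep="\t", index_col=0)
        df.iloc[0, 1] += 1e-3
        df.to_csv(tmp_path / "fa.tsv", sep="\t")
        with pytest.warns(RuntimeWarning, match="asymmetric"):
            back = read_connectome(tmp_path / "fa.tsv", tmp_path / "len.tsv")
        np.testing.assert_allclose(back.fa, back.fa.T)


class TestSparsity:
    def test_all_present(self):
        sc = build(np.full(6, 0.5), np.full(6, 50.0), 4)
        assert sparsity(sc) == 0.0

    def test_half_absent(self):
        fa = np.array([0.5, 0.5, 0.5, 0.0, 0.0, 0.0])
        sc = build(fa, np.full(6, 50.0), 4)
        assert sparsity(sc) == pytest.approx(0.5)

    def test_matches_bruteforce_count(self, make_connectome):
        sc = make_connectome(n_nodes=12)
        n = sc.n_nodes
        absent = sum(
            1 for i in range(n) for j in range(i + 1, n) if sc.fa[i, j] == 0.0
        )
        assert sparsity(sc) == pytest.approx(absent / (n * (n - 1) / 2))


class TestQuartileThresholds:
    def test_pooled_interpolated_quantiles(self):
        lengths = np.arange(1.0, 9.0)  # {1..8}
        # connectome whose present-edge lengths are exactly {1..8}
        fa = np.zeros(28)
        fa[:8] = 0.5
        lens = np.ones(28)
        lens[:8] = lengths
        sc = build(fa, lens, 8)
        thr = quartile_thresholds([sc])
        assert thr.q1 == pytest.approx(2.75)
        assert thr.q3 == pytest.approx(6.25)

    def test_matches_sort_interpolation_oracle(self, make_connectome):
        scs = [make_connectome(n_nodes=10) for _ in range(4)]
        pooled = np.concatenate(
            [s.edge_lengths()[s.present_edges()] for s in scs]
        )
        srt = np.sort(pooled)

        def interp_quantile(p):
            h = (srt.size - 1) * p
            lo = int(np.floor(h))
            hi = min(lo + 1, srt.size - 1)
            return srt[lo] + (h - lo) * (srt[hi] - srt[lo])

        thr = quartile_thresholds(scs)
        assert thr.q1 == pytest.approx(interp_quantile(0.25), abs=1e-12)
        assert thr.q3 == pytest.approx(interp_quantile(0.75), abs=1e-12)

    def test_all_equal_lengths_degenerate(self):
        sc = build(np.full(6, 0.5), np.full(6, 42.0), 4)
        thr = quartile_thresholds([sc])
        assert thr.q1 == thr.q3 == 42.0
        mask = classify_edges(sc, thr)
        assert count_range_connections(mask) == (0, 0)

    def test_no_present_edges_rejected(self):
        sc = build(np.zeros(6), np.ones(6), 4)
        with pytest.raises(ValueError, match="no present edges"):
            quartile_thresholds([sc])

    def test_fixed_overrides_reproduce_reference_thresholds(self):
        """Supplied fixed thresholds define short (<96.765) / long (>172.056)."""
        thr = RangeThresholds(q1=96.765, q3=172.056)
        fa = np.full(6, 0.5)
        lens = np.array([90.0, 96.765, 100.0, 172.056, 180.0, 250.0])
        mask = classify_edges(build(fa, lens, 4), thr)
        assert mask.short_mask.tolist() == [True, False, False, False, False, False]
        assert mask.long_mask.tolist() == [False, False, False, False, True, True]


class TestClassifyEdges:
    def test_strict_boundaries_unclassified(self):
        thr = RangeThresholds(q1=10.0, q3=20.0)
        fa = np.full(3, 0.5)
        lens = np.array([10.0, 15.0, 20.0])
        mask = classify_edges(build(fa, lens, 3), thr)
        assert not mask.short_mask.any()
        assert not mask.long_mask.any()
        assert mask.present_mask.all()

    def test_absent_edges_in_no_class(self):
        thr = RangeThresholds(q1=50.0, q3=100.0)
        fa = np.array([0.0, 0.5, 0.0])
        lens = np.array([10.0, 20.0, 150.0])
        mask = classify_edges(build(fa, lens, 3), thr)
        assert count_range_connections(mask) == (1, 0)

    def test_counts_match_enumeration(self, rng, make_connectome):
        for _ in range(20):
            sc = make_connectome(n_nodes=9)
            thr = RangeThresholds(q1=60.0, q3=140.0)
            mask = classify_edges(sc, thr)
            n_short = n_long = 0
            n = sc.n_nodes
            for i in range(n):
                for j in range(i + 1, n):
                    if sc.fa[i, j] > 0:
                        if sc.lengths[i, j] < 60.0:
                            n_short += 1
                        elif sc.lengths[i, j] > 140.0:
                            n_long += 1
            assert count_range_connections(mask) == (n_short, n_long)

    def test_node_relabeling_invariance(self, make_connectome):
        sc = make_connectome(n_nodes=8)
        thr = RangeThresholds(q1=60.0, q3=140.0)
        perm = np.random.default_rng(3).permutation(8)
        sc_p = StructuralConnectome(
            fa=sc.fa[np.ix_(perm, perm)],
            lengths=sc.lengths[np.ix_(perm, perm)],
            node_labels=[sc.node_labels[i] for i in perm],
        )
        c1 = count_range_connections(classify_edges(sc, thr))
        c2 = count_range_connections(classify_edges(sc_p, thr))
        assert c1 == c2


class TestMaskFC:
    def fc_for(self, sc, rng):
        n = sc.n_nodes
        m = rng.uniform(0, 1, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        return FCMatrix(values=m, band=THETA, rescaled=True, node_labels=sc.node_labels)

    def test_whole_selects_all_present(self, make_connectome, rng):
        sc = make_connectome(n_nodes=10, absent_fraction=0.0)
        fc = self.fc_for(sc, rng)
        mask = classify_edges(sc, RangeThresholds(q1=60.0, q3=140.0))
        vec = mask_fc_by_structure(fc, mask, "whole")
        assert vec.size == sc.n_edges

    def test_values_match_elementwise_lookup(self, make_connectome, rng):
        sc = make_connectome(n_nodes=10)
        fc = self.fc_for(sc, rng)
        mask = classify_edges(sc, RangeThresholds(q1=60.0, q3=140.0))
        vec = mask_fc_by_structure(fc, mask, "short")
        expected = []
        n = sc.n_nodes
        for i in range(n):
            for j in range(i + 1, n):
                if sc.fa[i, j] > 0 and sc.lengths[i, j] < 60.0:
                    expected.append(fc.values[i, j])
        np.testing.assert_allclose(vec, expected)

    def test_empty_class_rejected(self, make_connectome, rng):
        sc = make_connectome(n_nodes=6)
        fc = self.fc_for(sc, rng)
        mask = classify_edges(sc, RangeThresholds(q1=0.0, q3=1e9))
        with pytest.raises(ValueError, match="no edges in class 'long'"):
            mask_fc_by_structure(fc, mask, "long")

    def test_whole_mean_equals_masked_mean_sc_analogue(self, make_connectome, rng):
        """Mean of the whole-class FC vector equals FC averaged on present edges."""
        sc = make_connectome(n_nodes=10)
        fc = self.fc_for(sc, rng)
        mask = classify_edges(sc, RangeThresholds(q1=60.0, q3=140.0))
        vec = mask_fc_by_structure(fc, mask, "whole")
        iu = np.triu_indices(10, 1)
        present = sc.fa[iu] > 0
        assert vec.mean() == pytest.approx(fc.values[iu][present].mean())


class TestMeanSC:
    def test_present_only_excludes_absent(self, make_connectome):
        sc = make_connectome(n_nodes=10)
        iu = np.triu_indices(10, 1)
        fa = sc.fa[iu]
        assert mean_sc(sc) == pytest.approx(fa[fa > 0].mean())
        assert mean_sc(sc, present_only=False) == pytest.approx(fa.mean())


class TestEdgeClassMaskInvariants:
    def test_disjoint_and_subset_enforced(self):
        with pytest.raises(ValueError, match="both short- and long-range"):
            EdgeClassMask(
                short_mask=[True], long_mask=[True], present_mask=[True], node_labels=[]
            )
        with pytest.raises(ValueError, match="structurally present"):
            EdgeClassMask(
                short_mask=[True], long_mask=[False], present_mask=[False], node_labels=[]
            )

    def test_quartile_fraction_bounds(self, make_connectome):
        """At most a quarter of pooled lengths fall strictly below q1."""
        scs = [make_connectome(n_nodes=12) for _ in range(3)]
        thr = quartile_thresholds(scs)
        pooled = np.concatenate([s.edge_lengths()[s.present_edges()] for s in scs])
        assert (pooled < thr.q1).mean() <= 0.25 <= (pooled <= thr.q1).mean()
        assert (pooled < thr.q3).mean() <= 0.75 <= (pooled <= thr.q3).mean()
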