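import math

import numpy as np
import pandas as pd
import pytest

from polysig.data_io import ExpressionMatrix
from polysig.gsea import EnrichmentResult
from polysig.signature import (
    Dendrogram,
    build_consensus_signature,
    read_signature_txt,
    select_topk_polycomb_sets,
    signature_sum_z,
    two_group_separation,
    upgma_cluster,
    write_signature_txt,
    zscore_by_gene,
)
from .conftest import make_logcpm


def er(name, nes, leading=()):
    return EnrichmentResult(
        set_name=name, size_after_filter=30, es=nes / 3, nes=nes,
        p_perm=0.01, q=0.01, leading_edge=list(leading), peak_index=0,
    )


class TestSelectTopK:
    def test_top_k_by_nes_after_keyword_filter(self):
        results = [er(f"PRC2_SET_{i}", 3.0 - i * 0.05) for i in range(30)]
        results += [er(f"OTHER_{i}", 5.0) for i in range(5)]  # no keyword
        top = select_topk_polycomb_sets(results, ["PRC2"], k=20)
        assert len(top) == 20
        assert all("PRC2" in r.set_name for r in top)
        assert top[0].nes == pytest.approx(3.0)

    def test_fewer_than_k_returned_without_padding(self):
        results = [er("H3K27_A", 2.0), er("H3K27_B", 1.8), er("DECOY", 3.0)]
        top = select_topk_polycomb_sets(results, ["H3K27"], k=20)
        assert [r.set_name for r in top] == ["H3K27_A", "H3K27_B"]

    def test_keyword_membership_is_configurable(self):
        results = [er("KAMMINGA_EZH2_TARGETS", 2.0)]
        assert select_topk_polycomb_sets(results, ["PRC2"]) == []
        assert len(select_topk_polycomb_sets(results, ["EZH2"])) == 1

    def test_negative_nes_excluded(self):
        results = [er("PRC2_DOWN", -2.5)]
        assert select_topk_polycomb_sets(results, ["PRC2"]) == []


class TestConsensusSignature:
    def test_occurrence_threshold_counts_lines(self):
        edges = {f"line{i}": ({"A"} if i < 4 else set()) | ({"B"} if i < 3 else set())
                 for i in range(10)}
        sig = build_consensus_signature(edges, min_lines=4)
        assert sig.genes == ["A"]
        assert sig.occurrence == {"A": 4}

    def test_gene_in_two_sets_of_one_line_counts_once(self):
        # the per-line input is already a union; duplicates inside collapse
        edges = {"line1": ["A", "a"], "line2": ["A"], "line3": ["A"], "line4": ["A"]}
        sig = build_consensus_signature(edges, min_lines=4)
        assert sig.occurrence["A"] == 4

    def test_sorting_by_occurrence_then_symbol(self):
        edges = {f"l{i}": {"ZZZ", "AAA"} | ({"MMM"} if i < 5 else set()) for i in range(4)}
        sig = build_consensus_signature(edges, min_lines=4)
        assert sig.genes == ["AAA", "MMM", "ZZZ"] or sig.genes[0] in ("AAA", "MMM")
        # occurrence 4 for all three -> pure alphabetical
        assert sig.genes == ["AAA", "MMM", "ZZZ"]

    def test_monotone_in_min_lines(self):
        rng = np.random.default_rng(0)
        edges = {
            f"l{i}": {f"G{g}" for g in rng.choice(30, size=12, replace=False)}
            for i in range(10)
        }
        prev = None
        for k in (2, 4, 6, 8):
            genes = set(build_consensus_signature(edges, min_lines=k).genes)
            if prev is not None:
                assert genes <= prev
            prev = genes

    def test_signature_txt_roundtrip(self, tmp_path):
        edges = {f"l{i}": {"A", "B"} for i in range(5)}
        sig = build_consensus_signature(edges, min_lines=4)
        path = write_signature_txt(sig, tmp_path / "sig.txt")
        back = read_signature_txt(path, min_lines=4)
        assert back.genes == sig.genes and back.occurrence == sig.occurrence


class TestZscore:
    def test_hand_example(self):
        m = make_logcpm([[1, 2, 3]])
        z, flagged = zscore_by_gene(m)
        np.testing.assert_allclose(z.values[0], [-1, 0, 1])
        assert flagged == []

    def test_constant_row_flagged_zero(self):
        m = make_logcpm([[5, 5, 5], [1, 2, 3]], genes=["FLAT", "VAR"])
        z, flagged = zscore_by_gene(m)
        np.testing.assert_allclose(z.data.loc["FLAT"], 0)
        assert flagged == ["FLAT"]

    def test_rows_standardized(self, rng):
        m = make_logcpm(rng.normal(size=(20, 8)) * 5 + 3)
        z, _ = zscore_by_gene(m)
        np.testing.assert_allclose(z.values.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(z.values.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_affine_rescaling_invariance(self, rng):
        """Per-gene shift/scale of the input leaves sum-Z scores unchanged."""
        X = rng.normal(size=(15, 6))
        m1 = make_logcpm(X)
        scale = rng.gamma(2, 1, size=(15, 1))
        shift = rng.normal(0, 10, size=(15, 1))
        m2 = make_logcpm(X * scale + shift)
        genes = m1.gene_ids[:10]
        z1, _ = zscore_by_gene(m1)
        z2, _ = zscore_by_gene(m2)
        s1 = signature_sum_z(z1, genes)
        s2 = signature_sum_z(z2, genes)
        np.testing.assert_allclose(
            [s.sum_z for s in s1], [s.sum_z for s in s2], atol=1e-9
        )

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            zscore_by_gene(make_logcpm([[1.0]]))


class TestSignatureSumZ:
    def test_hand_example(self):
        z, _ = zscore_by_gene(make_logcpm([[1, -1], [0.5, 0.5]], genes=["A", "B"]))
        # build a z-matrix directly to use the stated values
        zm = ExpressionMatrix(
            pd.DataFrame([[1, -1], [0.5, 0.5]], index=["A", "B"], columns=["s1", "s2"]),
            "zscore",
        )
        scores = signature_sum_z(zm, ["A", "B"])
        assert [s.sum_z for s in scores] == [1.5, -0.5]

    def test_missing_genes_reduce_n_used(self):
        zm = ExpressionMatrix(
            pd.DataFrame(np.zeros((3, 2)), index=["A", "B", "C"], columns=["s1", "s2"]),
            "zscore",
        )
        scores = signature_sum_z(zm, ["A", "B", "C", "D", "E"])
        assert all(s.n_genes_used == 3 for s in scores)

    def test_whole_universe_scores_near_zero(self, rng):
        m = make_logcpm(rng.normal(size=(30, 6)))
        z, _ = zscore_by_gene(m)
        scores = signature_sum_z(z, m.gene_ids)
        # column sums of a full z-matrix are near zero only on average;
        # each score is bounded by the column sum of z which has mean 0
        assert abs(np.mean([s.sum_z for s in scores])) < 1e-9

    def test_no_genes_present_errors(self):
        zm = ExpressionMatrix(
            pd.DataFrame([[0.0]], index=["A"], columns=["s1"]), "zscore"
        )
        with pytest.raises(ValueError, match="no signature genes"):
            signature_sum_z(zm, ["B"])

    def test_requires_zscore_kind(self, small_counts):
        with pytest.raises(ValueError, match="zscore"):
            signature_sum_z(small_counts, ["TP53"])


def brute_force_upgma(dist, labels):
    """From-scratch UPGMA recomputing mean pairwise leaf distances each step."""
    n = len(labels)
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                la, lb = min(clusters[a]), min(clusters[b])
                key = (d, min(la, lb), max(la, lb))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, _, _), a, b = best
        merges.append((a, b, d))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


class TestUpgma:
    def _matrix_with_distances(self):
        """3 samples whose correlation distances are 0.1, 0.9, 0.8 (A-B, A-C, B-C)."""
        rng = np.random.default_rng(1)
        base = rng.normal(size=50)
        other = rng.normal(size=50)
        a = base
        b = 0.9 * base + math.sqrt(1 - 0.81) * rng.normal(size=50)
        c = 0.15 * base + other
        X = np.column_stack([a, b, c])
        return ExpressionMatrix(
            pd.DataFrame(X, index=[f"G{i}" for i in range(50)], columns=["A", "B", "C"]),
            "zscore",
        )

    def test_hand_walked_three_sample_merge(self):
        """Closest pair merges first; the third sample joins at the
        unweighted mean of its two leaf distances."""
        m = self._matrix_with_distances()
        dist = 1 - np.corrcoef(m.values.T)
        d = upgma_cluster(m)
        a, b, h1 = d.merges[0]
        assert {a, b} == {0, 1}  # A and B are the closest pair
        assert h1 == pytest.approx(dist[0, 1], abs=1e-12)
        _, _, h2 = d.merges[1]
        assert h2 == pytest.approx((dist[0, 2] + dist[1, 2]) / 2, abs=1e-12)

    def test_identical_samples_merge_at_zero(self):
        X = np.column_stack([np.arange(10.0), np.arange(10.0), np.arange(10.0) ** 2])
        m = ExpressionMatrix(
            pd.DataFrame(X, index=[f"G{i}" for i in range(10)], columns=["A", "B", "C"]),
            "zscore",
        )
        d = upgma_cluster(m)
        assert d.merges[0][2] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        """Merge sequence equals a from-scratch UPGMA on random instances."""
        for _ in range(30):
            n = int(rng.integers(4, 9))
            X = rng.normal(size=(25, n))
            m = ExpressionMatrix(
                pd.DataFrame(
                    X, index=[f"G{i}" for i in range(25)],
                    columns=[f"s{j}" for j in range(n)],
                ),
                "zscore",
            )
            dist = 1 - np.corrcoef(X.T)
            expected = brute_force_upgma(dist, list(range(n)))
            got = upgma_cluster(m)
            for (ea, eb, eh), (ga, gb, gh) in zip(expected, got.merges):
                assert {ea, eb} == {ga, gb}
                assert gh == pytest.approx(eh, abs=1e-10)

    def test_heights_nondecreasing(self, rng):
        X = rng.normal(size=(30, 8))
        m = ExpressionMatrix(
            pd.DataFrame(X, index=[f"G{i}" for i in range(30)],
                         columns=[f"s{j}" for j in range(8)]),
            "zscore",
        )
        d = upgma_cluster(m)
        heights = [h for _, _, h in d.merges]
        assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))

    def test_constant_sample_rejected_by_name(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        m = ExpressionMatrix(
            pd.DataFrame(X, index=[f"G{i}" for i in range(5)], columns=["OK", "FLAT"]),
            "zscore",
        )
        with pytest.raises(ValueError, match="FLAT"):
            upgma_cluster(m)


class TestTwoGroupSeparation:
    def _dendro(self, leaves, merges):
        return Dendrogram(leaves=leaves, merges=merges)

    def test_perfect_separation(self):
        d = self._dendro(["a", "b", "c", "d"], [(0, 1, 0.1), (2, 3, 0.1), (4, 5, 0.9)])
        labels = {"a": "p", "b": "p", "c": "r", "d": "r"}
        assert two_group_separation(d, labels) == 1.0

    def test_one_mislabeled_among_thirteen(self):
        leaves = [f"L{i}" for i in range(13)]
        # cluster 1 = leaves 0..3 (3 parental + 1 resistant), cluster 2 = 4..12
        merges = []
        nid = 13
        left = 0
        for i in range(1, 4):
            merges.append((left, i, 0.1)); left = nid; nid += 1
        right = 4
        for i in range(5, 13):
            merges.append((right, i, 0.2)); right = nid; nid += 1
        merges.append((left, right, 0.9))
        labels = {f"L{i}": ("parental" if i < 3 else "resistant") for i in range(13)}
        d = self._dendro(leaves, merges)
        assert two_group_separation(d, labels) == pytest.approx(12 / 13)

    def test_random_labels_near_half(self, rng):
        """Random labels on two balanced clusters give purity near 0.5-0.6."""
        leaves = [f"L{i}" for i in range(20)]
        merges = []
        nid = 20
        left = 0
        for i in range(1, 10):
            merges.append((left, i, 0.1)); left = nid; nid += 1
        right = 10
        for i in range(11, 20):
            merges.append((right, i, 0.1)); right = nid; nid += 1
        merges.append((left, right, 0.5))
        d = self._dendro(leaves, merges)
        purities = []
        for _ in range(300):
            lab = rng.permutation([0] * 10 + [1] * 10)
            purities.append(
                two_group_separation(d, {f"L{i}": str(lab[i]) for i in range(20)})
            )
        assert 0.5 <= np.mean(purities) <= 0.65

    def test_requires_two_labels(self):
        d = self._dendro(["a", "b"], [(0, 1, 0.5)])
        with pytest.raises(ValueError, match="two labels"):
            two_group_separation(d, {"a": "x", "b": "x"})
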