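"""Allele-sharing distance and neighbor-joining trees."""

from io import StringIO

import numpy as np
import pandas as pd
import pytest

from snppop import MISSING, PanelError, distance_matrix, ibs_distance, nj_newick
from snppop.distance import neighbor_joining
from conftest import make_panel


class TestIbsDistance:
    def test_identical_vectors(self):
        panel = make_panel([[0, 1, 2], [0, 1, 2]])
        counts, d = ibs_distance(panel, 0, 1)
        assert counts.dst == 1.0 and d == 0.0

    def test_opposite_homozygotes(self):
        panel = make_panel([[0, 0], [2, 2]])
        counts, d = ibs_distance(panel, 0, 1)
        assert counts.dst == 0.0 and d == 1.0

    def test_mixed_sharing_hand_value(self):
        # locus 1: IBS2, locus 2: IBS1 -> Dst = 1.5/2
        panel = make_panel([[1, 0], [1, 1]])
        counts, d = ibs_distance(panel, 0, 1)
        assert (counts.ibs2, counts.ibs1, counts.ibs0) == (1, 1, 0)
        assert counts.dst == 0.75 and d == 0.25

    def test_missing_loci_excluded(self):
        panel = make_panel([[1, MISSING, 0], [1, 2, MISSING]])
        counts, _ = ibs_distance(panel, 0, 1)
        assert counts.n == 1

    def test_no_overlap_errors(self):
        panel = make_panel([[1, MISSING], [MISSING, 2]])
        with pytest.raises(PanelError, match="overlap"):
            ibs_distance(panel, 0, 1)


class TestDistanceMatrix:
    def test_identical_samples_zero_matrix(self):
        panel = make_panel([[0, 1], [0, 1], [0, 1]])
        assert (distance_matrix(panel).to_numpy() == 0).all()

    def test_duplicated_sample_row_matches_original(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, (3, 25)).astype(np.int8)
        d = np.vstack([d, d[0]])
        mat = distance_matrix(make_panel(d)).to_numpy()
        assert mat[0, 3] == 0
        assert mat[3, 1] == pytest.approx(mat[0, 1])

    def test_matches_per_pair_brute_force(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, (4, 30)).astype(np.int8)
        d[rng.uniform(size=d.shape) < 0.1] = MISSING
        panel = make_panel(d)
        mat = distance_matrix(panel)
        for i in range(4):
            for j in range(i + 1, 4):
                _, dij = ibs_distance(panel, i, j)
                assert mat.iloc[i, j] == pytest.approx(dij)
                assert mat.iloc[j, i] == pytest.approx(dij)


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        tree = neighbor_joining(np.array([[0.0, 3.0], [3.0, 0.0]]), ["A", "B"])
        total = sum(l for _, l in tree.children)
        assert total == pytest.approx(3.0)

    def test_three_taxa_branch_lengths(self):
        # d(AB)=2, d(AC)=4, d(BC)=4 -> a=1, b=1, c=3
        D = pd.DataFrame(
            [[0, 2, 4], [2, 0, 4], [4, 4, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        tree = neighbor_joining(D)
        lengths = {c.label: l for c, l in tree.children}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(PanelError, match="symmetric"):
            neighbor_joining(np.array([[0.0, 1.0], [2.0, 0.0]]), ["A", "B"])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize("n_leaves", [5, 8, 12])
    def test_additive_matrix_recovers_topology(self, seed, n_leaves):
        """NJ consistency: path-length matrices of random trees map back
        to the generating topology (Robinson-Foulds distance 0)."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(100 * n_leaves + seed)
        truth = _random_tree(n_leaves, rng)
        names = [f"t{i}" for i in range(n_leaves)]
        true_tree = skbio.TreeNode.read(StringIO(truth))
        D = np.zeros((n_leaves, n_leaves))
        for i in range(n_leaves):
            for j in range(i + 1, n_leaves):
                D[i, j] = D[j, i] = true_tree.find(names[i]).distance(
                    true_tree.find(names[j])
                )
        mine = skbio.TreeNode.read(StringIO(nj_newick(D, names)))
        assert mine.compare_rfd(true_tree) == 0.0

    def test_two_diverged_groups_cluster_separately(self):
        """Two simulated diverged populations form two clades (unrooted):
        some bipartition of the NJ tree splits the groups exactly."""
        from snppop import PopulationSpec, SimulationConfig, simulate_genotypes

        cfg = SimulationConfig(
            seed=6, n_snps=600,
            populations=[PopulationSpec("A", 8, 0.25), PopulationSpec("B", 8, 0.25)],
        )
        panel = simulate_genotypes(cfg)
        tree = neighbor_joining(distance_matrix(panel))
        a_names = {s for s in panel.samples if s.startswith("A")}
        all_names = set(panel.samples)

        def tips(node):
            if node.is_leaf:
                return {node.label}
            out = set()
            for child, _ in node.children:
                out |= tips(child)
            return out

        splits = []

        def collect(node):
            for child, _ in node.children:
                splits.append(frozenset(tips(child)))
                collect(child)

        collect(tree)
        assert any(
            s == a_names or s == (all_names - a_names) for s in splits
        )


def _random_tree(n_leaves: int, rng: np.random.Generator) -> str:
    """Random binary tree Newick with positive branch lengths."""
    nodes = [f"t{i}:{rng.uniform(0.1, 1.0):.4f}" for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.1, 1.0):.4f}"
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [merged]
    return "(" + ",".join(nodes) + ");"
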