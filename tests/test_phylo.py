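"""Distances, neighbor joining, and bootstrap supports."""

import numpy as np
import pytest

from pseudoquant.phylo import (
    DistanceMatrix,
    TreeNode,
    bootstrap_support,
    distance_matrix,
    nj_tree,
    pairwise_distance,
)


def _random_tree(rng, taxa):
    """Random unrooted binary tree with positive branch lengths; returns
    leaf-to-leaf path distances (an additive matrix) and its bipartitions."""
    nodes = [TreeNode(name=t) for t in taxa]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = TreeNode()
        a.length = float(rng.uniform(0.05, 1.0))
        b.length = float(rng.uniform(0.05, 1.0))
        parent.children = [b, a]
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    for n in nodes:
        n.length = float(rng.uniform(0.05, 1.0))
    root.children = nodes
    # path distances via leaf depths and lowest common ancestors
    paths = {}

    def walk(node, acc):
        if node.is_leaf:
            paths[node.name] = acc
            return
        for c in node.children:
            walk(c, acc + [(c, c.length)])

    walk(root, [])
    n = len(taxa)
    d = np.zeros((n, n))
    for x in range(n):
        for y in range(x + 1, n):
            px = paths[taxa[x]]
            py = paths[taxa[y]]
            shared = 0
            for (nx, _), (ny, _) in zip(px, py):
                if nx is ny:
                    shared += 1
                else:
                    break
            dist = sum(l for _, l in px[shared:]) + sum(l for _, l in py[shared:])
            d[x, y] = d[y, x] = dist
    return DistanceMatrix(tuple(taxa), d), set(root.bipartitions())


class TestPairwiseDistance:
    def test_identical_zero(self):
        assert pairwise_distance("ACGT", "ACGT", "p") == 0.0
        assert pairwise_distance("ACGT", "ACGT", "jc69") == 0.0

    def test_jc69_closed_form(self):
        a = "A" * 90 + "C" * 10
        b = "A" * 90 + "G" * 10
        assert pairwise_distance(a, b, "p") == pytest.approx(0.10)
        assert pairwise_distance(a, b, "jc69") == pytest.approx(0.1073, abs=1e-4)

    def test_gap_columns_excluded(self):
        assert pairwise_distance("AC-T", "ACG-", "p") == 0.0

    def test_all_gap_overlap_is_error(self):
        with pytest.raises(ValueError, match="comparable"):
            pairwise_distance("--AA", "GG--", "p")

    def test_jc69_saturation_error(self):
        with pytest.raises(ValueError, match="undefined"):
            pairwise_distance("AAAA", "CCCC", "jc69")


class TestNjTree:
    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(("A", "B", "C"), np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]]))
        tree = nj_tree(d)
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths["A"] == pytest.approx((3 + 5 - 6) / 2)
        assert lengths["B"] == pytest.approx((3 + 6 - 5) / 2)
        assert lengths["C"] == pytest.approx((5 + 6 - 3) / 2)

    def test_additive_five_taxon_recovery(self):
        rng = np.random.default_rng(5)
        dm, true_bp = _random_tree(rng, [f"t{i}" for i in range(5)])
        tree = nj_tree(dm)
        assert set(tree.bipartitions()) == true_bp

    def test_branch_lengths_recovered_on_additive_matrix(self):
        rng = np.random.default_rng(8)
        dm, _ = _random_tree(rng, [f"t{i}" for i in range(6)])
        tree = nj_tree(dm)
        # reconstructed tree must reproduce the additive distances exactly
        dist = {}

        def walk(node, acc):
            if node.is_leaf:
                dist[node.name] = acc
                return
            for c in node.children:
                walk(c, acc + [(id(c), c.length)])

        walk(tree, [])
        for i, a in enumerate(dm.taxa):
            for b in dm.taxa[i + 1 :]:
                pa, pb = dist[a], dist[b]
                shared = 0
                for (na, _), (nb, _) in zip(pa, pb):
                    if na == nb:
                        shared += 1
                    else:
                        break
                d = sum(l for _, l in pa[shared:]) + sum(l for _, l in pb[shared:])
                assert d == pytest.approx(dm.get(a, b), abs=1e-9)

    def test_tie_case_deterministic(self):
        n = 5
        d = np.ones((n, n)) - np.eye(n)
        taxa = tuple("ABCDE")
        t1 = nj_tree(DistanceMatrix(taxa, d)).newick()
        t2 = nj_tree(DistanceMatrix(taxa, d.copy())).newick()
        assert t1 == t2

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("A", "B"), np.array([[0, 1], [2, 0]]))

    def test_matches_independent_nj_implementation(self):
        """Topology agrees with Biopython's NJ on an additive instance."""
        from Bio.Phylo.TreeConstruction import DistanceMatrix as BioDM
        from Bio.Phylo.TreeConstruction import DistanceTreeConstructor

        rng = np.random.default_rng(21)
        taxa = [f"t{i}" for i in range(6)]
        dm, _ = _random_tree(rng, taxa)
        mine = set(nj_tree(dm).bipartitions())
        lower = [[float(dm.values[i, j]) for j in range(i + 1)] for i in range(6)]
        bio_tree = DistanceTreeConstructor().nj(BioDM(names=taxa, matrix=lower))
        all_taxa = frozenset(taxa)
        bio_bp = set()
        for clade in bio_tree.get_nonterminals():
            side = frozenset(l.name for l in clade.get_terminals())
            if 2 <= len(side) <= len(taxa) - 2:
                bio_bp.add(min(side, all_taxa - side, key=sorted))
        assert mine == bio_bp


class TestBootstrap:
    def _alignment(self, seed=0, cols=300):
        """Four taxa with clean, conflict-free signal: t0/t1 share one
        diagnostic column set, t2/t3 another."""
        rng = np.random.default_rng(seed)
        base = rng.choice(list("ACGT"), cols)
        a = base.copy()
        b = base.copy()
        idx = rng.choice(cols, 60, replace=False)
        for i in idx[:30]:
            a[i] = "A" if base[i] != "A" else "C"
        for i in idx[30:]:
            b[i] = "G" if base[i] != "G" else "T"
        return {
            "t0": "".join(base),
            "t1": "".join(base),
            "t2": "".join(a),
            "t3": "".join(a),
        }

    def test_clean_signal_full_support(self):
        tree = bootstrap_support(self._alignment(), n_replicates=50, seed=1)
        supports = [
            n.support for n in _internal_nodes(tree) if n.support is not None
        ]
        assert supports and all(s == 100.0 for s in supports)

    def test_single_replicate_support_binary(self):
        tree = bootstrap_support(self._alignment(), n_replicates=1, seed=2)
        for n in _internal_nodes(tree):
            if n.support is not None:
                assert n.support in (0.0, 100.0)

    def test_seeded_reproducibility(self):
        t1 = bootstrap_support(self._alignment(), n_replicates=25, seed=7)
        t2 = bootstrap_support(self._alignment(), n_replicates=25, seed=7)
        assert t1.newick() == t2.newick()

    def test_near_identical_copy_is_sister_to_parent(self):
        """A nearly parent-identical processed copy clusters as sister to
        the parent cDNA in the family tree — the same signal that explains
        why its allele-specific primers stay leaky on the parent."""
        from pseudoquant.discrimination import align_to_target
        from pseudoquant.synthetic import (
            LocusSetConfig,
            PseudogeneSpec,
            generate_locus_set,
        )

        cfg = LocusSetConfig(
            seed=4,
            exon_lengths=(200, 250, 200, 250),
            intron_lengths=(150, 200, 150),
            pseudogenes=tuple(
                PseudogeneSpec(n, d)
                for n, d in (("P1", 0.005), ("Pa", 0.06), ("Pb", 0.08), ("Pc", 0.10))
            ),
        )
        ls = generate_locus_set(cfg)
        names = [s.name for s in cfg.pseudogenes]
        table = align_to_target(ls.cdna, [ls.planted_sequence(n) for n in names])
        aln = {ls.cdna.id: ls.cdna.seq}
        for n in names:
            aln[n] = "".join(table.columns[n].values)
        tree = bootstrap_support(aln, n_replicates=25, seed=3)
        taxa = frozenset(aln)
        cherry = frozenset({ls.cdna.id, "P1"})
        canonical = min(cherry, taxa - cherry, key=sorted)
        assert canonical in set(tree.bipartitions())


def _internal_nodes(tree):
    out = []

    def walk(n):
        for c in n.children:
            if not c.is_leaf:
                out.append(c)
            walk(c)

    walk(tree)
    return out
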