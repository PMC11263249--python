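"""Alignment, supermatrix construction, NJ, bootstrap, parsimony, monophyly."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from mitocomp.align import (Msa, align_codon, align_progressive,
                            pairwise_global, trim_columns, NT_SCORES)
from mitocomp.phylogeny import (build_supermatrix, bootstrap_support,
                                is_monophyletic, k2p_matrix_from_rows, nj_tree,
                                parsimony_score, read_newick, robinson_foulds,
                                tree_splits)
from tests.conftest import random_dna


def nw_oracle(a, b, match=1.0, mismatch=-1.0, gap_open=-2.0, gap_ext=-1.0):
    """Independent affine-gap Needleman-Wunsch (Gotoh) optimal score."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_ext * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_ext * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_ext,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_ext,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


class TestAlign:
    def test_identical_sequences_gap_free(self):
        msa = align_progressive({c: "ACGTACGT" for c in "abc"})
        assert set(msa.rows.values()) == {"ACGTACGT"}

    def test_single_gap_matches_dp_oracle(self):
        r1, r2, score = pairwise_global("ACGT", "ACGGT")
        assert score == nw_oracle("ACGT", "ACGGT")
        assert r1.count("-") == 1 and r2.count("-") == 0

    def test_pairwise_score_matches_oracle_random(self, rng):
        for _ in range(10):
            a = random_dna(rng, int(rng.integers(5, 25)))
            b = random_dna(rng, int(rng.integers(5, 25)))
            _, _, score = pairwise_global(a, b)
            assert score == pytest.approx(nw_oracle(a, b))

    def test_codon_mode_gaps_in_triples(self):
        msa = align_codon({"a": "ATGAAACCCTAA", "b": "ATGCCCTAA",
                           "c": "ATGAAACCGTAA"})
        for row in msa.rows.values():
            assert len(row) % 3 == 0
            # gaps only as whole codons
            for i in range(0, len(row), 3):
                codon = row[i:i + 3]
                assert codon == "---" or "-" not in codon

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            align_progressive({"a": "", "b": "ACGT"})


class TestTrim:
    def test_gap_free_unchanged(self):
        msa = Msa("x", {"a": "ACGT", "b": "ACGA"})
        assert trim_columns(msa).rows == msa.rows

    def test_majority_gap_column_removed(self):
        rows = {f"s{i}": ("-" if i < 9 else "A") + "CGT" for i in range(16)}
        trimmed = trim_columns(Msa("x", rows), max_gap_fraction=0.5)
        assert trimmed.length == 3

    def test_matches_column_scan_oracle(self, rng):
        nrow, L = 8, 60
        rows = {}
        for i in range(nrow):
            rows[f"s{i}"] = "".join(
                "-" if rng.random() < 0.3 else "ACGT"[int(rng.integers(4))]
                for _ in range(L))
        msa = Msa("x", rows)
        keep = [j for j in range(L)
                if sum(rows[n][j] == "-" for n in rows) / nrow <= 0.5]
        trimmed = trim_columns(msa, 0.5)
        assert trimmed.length == len(keep)
        for n in rows:
            assert trimmed.rows[n] == "".join(rows[n][j] for j in keep)

    def test_all_removed_errors(self):
        msa = Msa("x", {"a": "--", "b": "--"})
        with pytest.raises(ValueError):
            trim_columns(msa)


class TestSupermatrix:
    @pytest.fixture()
    def msas(self, rng):
        genes = {}
        from mitocomp.genome_io import CONSERVED_PCGS
        for g in CONSERVED_PCGS:
            L = int(rng.integers(4, 10)) * 3
            genes[g] = Msa(g, {sp: random_dna(rng, L) for sp in "abcd"})
        for g in ("rnl", "rns"):
            genes[g] = Msa(g, {sp: random_dna(rng, 30) for sp in "abcd"})
        return genes

    def test_pcg12_is_two_thirds(self, msas):
        pcg = build_supermatrix(msas, "PCG")
        pcg12 = build_supermatrix(msas, "PCG12")
        assert pcg12.length * 3 == pcg.length * 2

    def test_rrna_block_consistency(self, msas):
        pcg = build_supermatrix(msas, "PCG")
        pcg12 = build_supermatrix(msas, "PCG12")
        pcgr = build_supermatrix(msas, "PCGR")
        pcg12r = build_supermatrix(msas, "PCG12R")
        assert pcgr.length - pcg.length == pcg12r.length - pcg12.length

    def test_partitions_tile_columns(self, msas):
        for kind in ("PCG", "PCG12", "PCGR", "PCG12R", "AA"):
            sm = build_supermatrix(msas, kind)
            covered = sorted(sm.partitions.values())
            assert covered[0][0] == 0
            assert covered[-1][1] == sm.length
            for (s1, e1), (s2, e2) in zip(covered, covered[1:]):
                assert e1 == s2

    def test_pcg12_deletes_third_positions_columnwise(self, msas):
        pcg = build_supermatrix(msas, "PCG")
        pcg12 = build_supermatrix(msas, "PCG12")
        for sp in "abcd":
            expect = "".join(ch for i, ch in enumerate(pcg.rows[sp])
                             if i % 3 != 2)
            assert pcg12.rows[sp] == expect

    def test_missing_species_padded(self, msas):
        msas["cox1"] = Msa("cox1", {sp: msas["cox1"].rows[sp] for sp in "abc"})
        sm = build_supermatrix(msas, "PCG")
        s, e = sm.partitions["cox1"]
        assert sm.rows["d"][s:e] == "-" * (e - s)

    def test_unknown_kind(self, msas):
        with pytest.raises(ValueError):
            build_supermatrix(msas, "BOGUS")


class TestNJ:
    def test_three_taxon_closed_form(self):
        D = pd.DataFrame([[0, 3, 4], [3, 0, 5], [4, 5, 0]],
                         index=list("ABC"), columns=list("ABC"), dtype=float)
        tree = nj_tree(D)
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.leaf_node_iter()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_additive_four_taxon(self):
        # tree ((A:1,B:1):1,(C:1,D:1))
        D = pd.DataFrame([[0, 2, 3, 3], [2, 0, 3, 3],
                          [3, 3, 0, 2], [3, 3, 2, 0]],
                         index=list("ABCD"), columns=list("ABCD"), dtype=float)
        tree = nj_tree(D)
        assert tree_splits(tree) == {frozenset({"C", "D"})}
        internal = [e.length for e in tree.preorder_edge_iter()
                    if e.head_node and not e.head_node.is_leaf()
                    and e.head_node.parent_node is not None]
        assert internal == [pytest.approx(1.0)]

    def test_recovers_random_additive_trees(self):
        taxa = [f"t{i}" for i in range(6)]
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ns = dendropy.TaxonNamespace(taxa)
            true = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, taxon_namespace=ns,
                num_extant_tips=6, rng=__import__("random").Random(seed))
            for e in true.preorder_edge_iter():
                if e.length is not None:
                    e.length = float(rng.uniform(0.05, 1.0))
            pdm = true.phylogenetic_distance_matrix()
            names = sorted(t.label for t in ns)
            D = pd.DataFrame(0.0, index=names, columns=names)
            for t1, t2 in itertools.combinations(ns, 2):
                d = pdm.patristic_distance(t1, t2)
                D.loc[t1.label, t2.label] = D.loc[t2.label, t1.label] = d
            true.is_rooted = False
            assert robinson_foulds(nj_tree(D), true) == 0

    def test_asymmetric_matrix_errors(self):
        D = pd.DataFrame([[0, 1], [2, 0]], index=list("AB"),
                         columns=list("AB"), dtype=float)
        with pytest.raises(ValueError):
            nj_tree(D)


class TestBootstrap:
    def _sm(self, rng, L=300):
        from mitocomp.simulate import SimulationSpec, simulate_alignment_on_tree
        from tests.conftest import SMALL_TREE
        spec = SimulationSpec(seed=int(rng.integers(1000)), tree=SMALL_TREE)
        genes, _ = simulate_alignment_on_tree(spec)
        msas = {g: Msa(g, genes[g]) for g in ("cox1", "cob", "nad5")}
        return build_supermatrix(msas, "PCG", pcg_markers=("cox1", "cob", "nad5"))

    def test_single_replicate_supports_binary(self, rng):
        sm = self._sm(rng)
        _, supports = bootstrap_support(sm, n_replicates=1, seed=5)
        assert set(supports.values()) <= {0.0, 100.0}

    def test_same_seed_identical(self, rng):
        sm = self._sm(rng)
        _, s1 = bootstrap_support(sm, n_replicates=10, seed=3)
        _, s2 = bootstrap_support(sm, n_replicates=10, seed=3)
        assert s1 == s2

    def test_duplicated_signal_similar_supports(self, rng):
        sm = self._sm(rng)
        doubled = type(sm)(kind=sm.kind,
                           rows={k: v + v for k, v in sm.rows.items()})
        _, s1 = bootstrap_support(sm, n_replicates=50, seed=1)
        _, s2 = bootstrap_support(doubled, n_replicates=50, seed=2)
        common = set(s1) & set(s2)
        assert common
        for key in common:
            assert abs(s1[key] - s2[key]) <= 25.0

    def test_supports_in_range(self, rng):
        sm = self._sm(rng)
        _, supports = bootstrap_support(sm, n_replicates=20, seed=0)
        assert all(0.0 <= v <= 100.0 for v in supports.values())


def brute_force_parsimony(tree, msa):
    """Exhaustive minimum over all internal-state assignments, per column."""
    rooted = tree.clone(depth=1)
    internals = [n for n in rooted.preorder_node_iter() if not n.is_leaf()]
    edges = [(n, c) for n in internals for c in n.child_nodes()]
    symbols = sorted({ch for row in msa.rows.values() for ch in row})
    total = 0
    for col in range(msa.length):
        leaf_state = {n.taxon.label: row[col]
                      for n, row in ((lf, msa.rows[lf.taxon.label])
                                     for lf in rooted.leaf_node_iter())}
        best = None
        for combo in itertools.product(symbols, repeat=len(internals)):
            assign = {id(n): s for n, s in zip(internals, combo)}
            cost = 0
            for parent, child in edges:
                ps = assign[id(parent)]
                cs = (leaf_state[child.taxon.label] if child.is_leaf()
                      else assign[id(child)])
                cost += ps != cs
            best = cost if best is None else min(best, cost)
        total += best
    return total


class TestParsimony:
    def test_invariant_column_zero(self):
        tree = read_newick("((A,B),(C,D));")
        msa = Msa("x", {n: "A" for n in "ABCD"})
        assert parsimony_score(tree, msa) == 0

    def test_single_column_split_dependence(self):
        msa = Msa("x", {"A": "A", "B": "A", "C": "C", "D": "C"})
        assert parsimony_score(read_newick("((A,B),(C,D));"), msa) == 1
        assert parsimony_score(read_newick("((A,C),(B,D));"), msa) == 2

    def test_matches_exhaustive_oracle(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            rows = {n: random_dna(r, 8) for n in "ABCDE"}
            msa = Msa("x", rows)
            tree = read_newick("((A,B),(C,(D,E)));")
            assert parsimony_score(tree, msa) == brute_force_parsimony(tree, msa)

    def test_leaf_order_invariant(self, rng):
        rows = {n: random_dna(rng, 20) for n in "ABCD"}
        msa = Msa("x", rows)
        s1 = parsimony_score(read_newick("((A,B),(C,D));"), msa)
        s2 = parsimony_score(read_newick("((D,C),(B,A));"), msa)
        assert s1 == s2

    def test_leaf_set_mismatch(self):
        msa = Msa("x", {"A": "A", "B": "A"})
        with pytest.raises(ValueError):
            parsimony_score(read_newick("((A,B),(C,D));"), msa)


class TestMonophyly:
    TREE = read_newick("((A,B),((C,D),E));")

    def test_full_leaf_set_true(self):
        assert is_monophyletic(self.TREE, set("ABCDE"))

    def test_non_clade_false(self):
        assert not is_monophyletic(read_newick("((A,B),(C,D));"), {"A", "C"})

    def test_clade_true(self):
        assert is_monophyletic(self.TREE, {"C", "D"})
        assert is_monophyletic(self.TREE, {"A", "B"})
        assert is_monophyletic(self.TREE, {"C", "D", "E"})

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            is_monophyletic(self.TREE, set())

    def test_unknown_taxa_errors(self):
        with pytest.raises(ValueError):
            is_monophyletic(self.TREE, {"Z"})

    def test_expected_clade_structure_on_simulated_data(self, small_cohort):
        """NJ on the PCG supermatrix of the synthetic cohort isolates the
        Sanghuangporus-like trio nested with the Inonotus-like pair."""
        from mitocomp.pipeline import aligned_core_genes
        from tests.conftest import TRIO
        msas = aligned_core_genes(small_cohort.genomes)
        sm = build_supermatrix(msas, "PCG")
        tree = nj_tree(k2p_matrix_from_rows(sm.rows))
        assert is_monophyletic(tree, set(TRIO))
        assert is_monophyletic(tree, {"S_vaninii", "P_gilvus"})
        assert is_monophyletic(tree, {"I_hispidus", "I_obliquus"})
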