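"""Gene-order extraction, breakpoint distance, synteny blocks."""

import numpy as np
import pytest

from mitocomp.gene_order import (GeneOrder, breakpoint_distance,
                                 extract_gene_order, find_synteny_blocks,
                                 order_groups)
from mitocomp.genome_io import GeneFeature, Mitogenome
from tests.conftest import random_dna


def order(markers, species="sp"):
    return GeneOrder(species=species, markers=list(markers))


def oracle_distance(a, b):
    """Independent adjacency-enumeration oracle for signed circular orders."""
    def flip(m):
        return ("-" if m[0] == "+" else "+") + m[1:]

    def occurs(x, y, markers):
        n = len(markers)
        for i in range(n):
            p, q = markers[i], markers[(i + 1) % n]
            if (p, q) == (x, y) or (flip(q), flip(p)) == (x, y):
                return True
        return False

    n = len(a)
    return sum(0 if occurs(a[i], a[(i + 1) % n], b) else 1 for i in range(n))


def canonical(markers):
    """Minimal rotation/reflection form of a signed circular order."""
    def flip(m):
        return ("-" if m[0] == "+" else "+") + m[1:]
    variants = []
    rev = [flip(m) for m in reversed(markers)]
    for seq in (markers, rev):
        for r in range(len(seq)):
            variants.append(tuple(seq[r:] + seq[:r]))
    return min(variants)


def random_signed_order(rng, labels="abcde"):
    perm = list(labels)
    rng.shuffle(perm)
    return [("+" if rng.random() < 0.5 else "-") + m for m in perm]


class TestBreakpointDistance:
    def test_identical_orders(self):
        o = order(["+a", "-b", "+c", "+d"])
        assert breakpoint_distance(o, o) == 0

    def test_inversion_creates_two_breakpoints(self):
        a = order(["+a", "+b", "+c", "+d", "+e"])
        b = order(["+a", "-c", "-b", "+d", "+e"])
        assert breakpoint_distance(a, b) == 2
        assert oracle_distance(a.markers, b.markers) == 2

    def test_matches_oracle_on_random_signed_orders(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a = random_signed_order(rng)
            b = random_signed_order(rng)
            oa, ob = order(a, "x"), order(b, "y")
            assert breakpoint_distance(oa, ob) == oracle_distance(a, b)

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b, c = (random_signed_order(rng) for _ in range(3))
            d = lambda x, y: breakpoint_distance(order(x), order(y))
            assert d(a, b) == d(b, a)
            assert d(a, c) <= d(a, b) + d(b, c)

    def test_zero_iff_same_circular_order(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            a = random_signed_order(rng)
            b = random_signed_order(rng)
            same = canonical(a) == canonical(b)
            assert (breakpoint_distance(order(a), order(b)) == 0) == same

    def test_too_few_shared_markers(self):
        with pytest.raises(ValueError):
            breakpoint_distance(order(["+a", "+b"]), order(["+c", "+d"]))


class TestExtractOrder:
    def _genome(self, genes, length=20_000, gid="g"):
        feats = []
        for name, start, strand in genes:
            kind = "rRNA" if name in ("rnl", "rns") else "CDS"
            feats.append(GeneFeature(kind, name, strand, [(start, start + 300)]))
        return Mitogenome(id=gid, species=gid, sequence="A" * length,
                          features=feats)

    def test_rotation_starts_at_cox1(self):
        g = self._genome([("nad1", 100, "+"), ("cox1", 5000, "+"),
                          ("rnl", 9000, "-")])
        assert extract_gene_order(g).markers == ["+cox1", "-rnl", "+nad1"]

    def test_rotation_invariance(self, small_cohort):
        g = small_cohort.genomes[0]
        k = 10_000
        # rotate within a region covered by no feature spanning k
        feats = []
        for f in g.features:
            segs = [((s - k) % g.length, ((e - k - 1) % g.length) + 1)
                    for s, e in f.segments]
            if any(s >= e for s, e in segs):
                continue  # feature split by rotation point: drop for the test
            feats.append(GeneFeature(f.kind, f.gene, f.strand, segs, f.qualifiers))
        g2 = Mitogenome(id=g.id, species=g.species,
                        sequence=g.sequence[k:] + g.sequence[:k],
                        features=feats)
        o1 = extract_gene_order(g)
        o2 = extract_gene_order(g2)
        shared = set(o1.unsigned()) & set(o2.unsigned())
        assert breakpoint_distance(o1, o2) == 0 or len(shared) < 17

    def test_minus_strand_cox1_reflected(self):
        g = self._genome([("cox1", 100, "-"), ("nad1", 5000, "+"),
                          ("rnl", 9000, "-")])
        got = extract_gene_order(g).markers
        assert got[0] == "+cox1"
        assert got == ["+cox1", "+rnl", "-nad1"]

    def test_duplicate_marker_errors(self):
        g = self._genome([("cox1", 100, "+"), ("cox1", 5000, "+")])
        with pytest.raises(ValueError, match="duplicate"):
            extract_gene_order(g)

    def test_planted_orders_recovered(self, small_cohort):
        for g in small_cohort.genomes:
            got = extract_gene_order(g).markers
            assert got == small_cohort.truth.gene_orders[g.species]


class TestOrderGroups:
    def test_three_plus_one(self):
        a = ["+cox1", "+nad1", "+rnl"]
        orders = [order(a, f"s{i}") for i in range(3)]
        orders.append(order(["+cox1", "-nad1", "+rnl"], "s3"))
        groups = order_groups(orders)
        assert sorted(len(g) for g in groups) == [1, 3]

    def test_all_distinct(self):
        orders = [order(["+cox1", "+nad1", "+rnl"], "a"),
                  order(["+cox1", "+rnl", "+nad1"], "b"),
                  order(["+cox1", "-rnl", "+nad1"], "c")]
        assert all(len(g) == 1 for g in order_groups(orders))

    def test_planted_groups_recovered(self, small_cohort):
        orders = [extract_gene_order(g) for g in small_cohort.genomes]
        groups = {tuple(g) for g in order_groups(orders)}
        assert ("P_gilvus", "S_sanghuang", "S_vaninii") in groups
        assert ("I_hispidus", "I_obliquus") in groups


class TestSynteny:
    def test_identical_genomes_single_full_block(self):
        rng = np.random.default_rng(4)
        seq = random_dna(rng, 20_000)
        a = Mitogenome(id="a", species="a", sequence=seq)
        b = Mitogenome(id="b", species="b", sequence=seq)
        blocks = find_synteny_blocks(a, b)
        assert len(blocks) == 1
        blk = blocks[0]
        assert blk.identity == 100.0
        assert blk.length >= 0.99 * 20_000

    def test_planted_shared_segment(self):
        rng = np.random.default_rng(9)
        shared = random_dna(rng, 2000)
        # ~90% identity copy in genome b
        mutated = list(shared)
        for i in rng.choice(2000, size=200, replace=False):
            mutated[i] = "ACGT"[(("ACGT".index(mutated[i]) + 1) % 4)]
        a = Mitogenome(id="a", species="a",
                       sequence=random_dna(rng, 9000) + shared + random_dna(rng, 9000))
        b = Mitogenome(id="b", species="b",
                       sequence=random_dna(rng, 5000) + "".join(mutated) + random_dna(rng, 13000))
        blocks = find_synteny_blocks(a, b)
        assert len(blocks) == 1
        blk = blocks[0]
        assert blk.identity >= 70.0
        # overlaps the planted interval in genome a
        assert blk.locus1[0] < 11_000 and blk.locus1[1] > 9_000

    def test_unrelated_genomes_no_blocks(self):
        for seed in range(5):
            rng = np.random.default_rng(50 + seed)
            a = Mitogenome(id="a", species="a", sequence=random_dna(rng, 15_000))
            b = Mitogenome(id="b", species="b", sequence=random_dna(rng, 15_000))
            assert find_synteny_blocks(a, b) == []
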