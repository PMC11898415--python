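"""Signed circular gene orders: normalisation, breakpoints, moved genes."""

import io
import itertools

import numpy as np
import pytest

from mitocomp import model
from mitocomp.gene_order import (
    GROUND_PATTERN,
    GeneOrder,
    breakpoint_distance,
    detect_moved_genes,
    distance_matrix,
    group_patterns,
    nj_from_orders,
    normalize,
    order_from_annotation,
    read_orders,
    write_orders,
)
from mitocomp.synthetic import simulate_translocation


def brute_force_breakpoints(a: GeneOrder, b: GeneOrder) -> int:
    """Oracle: adjacency comparison by direct scan of both readings of b."""
    def pairs(o):
        e = o.elements
        return [(e[i], e[(i + 1) % len(e)]) for i in range(len(e))]

    b_pairs = set()
    for (g1, s1), (g2, s2) in pairs(b):
        b_pairs.add(((g1, s1), (g2, s2)))
        b_pairs.add(((g2, -s2), (g1, -s1)))  # other-strand reading
    return sum(1 for p in pairs(a) if p not in b_pairs)


def brute_force_minimal_sets(a: GeneOrder, b: GeneOrder):
    """Oracle for small orders: exhaust all subsets, smallest first."""
    genes = sorted(a.genes)
    for k in range(len(genes)):
        found = [set(S) for S in itertools.combinations(genes, k)
                 if _circ_names_equal(a.without(S), b.without(S))]
        if found:
            return found
    return []


def _circ_names_equal(a: GeneOrder, b: GeneOrder) -> bool:
    na = tuple(g for g, _ in a.elements)
    nb = tuple(g for g, _ in b.elements)
    if len(na) != len(nb):
        return False
    doubled = nb + nb
    fwd = any(doubled[i:i + len(na)] == na for i in range(len(nb)))
    rev_names = tuple(reversed(nb))
    doubled_r = rev_names + rev_names
    rev = any(doubled_r[i:i + len(na)] == na for i in range(len(nb)))
    return fwd or rev


def rotated(order: GeneOrder, k: int) -> GeneOrder:
    e = order.elements
    k %= len(e)
    return GeneOrder(order.taxon, e[k:] + e[:k])


def reflected(order: GeneOrder) -> GeneOrder:
    return GeneOrder(order.taxon, tuple((g, -s) for g, s in reversed(order.elements)))


class TestGroundPattern:
    def test_complete_gene_complement(self):
        assert len(GROUND_PATTERN.elements) == 38
        names = {g for g, _ in GROUND_PATTERN.elements}
        assert names == set(model.ALL_GENE_NAMES)

    def test_strand_assignment_matches_conserved_pattern(self):
        light = {g for g, s in GROUND_PATTERN.elements if s < 0}
        assert "trnH" in light and "nad5" in light and "cox1" not in light
        assert len(light) == 14


class TestConstruction:
    def test_order_from_published_annotation(self, table2):
        order = order_from_annotation(table2)
        head = [g for g, _ in order.elements[:7]]
        assert head == ["cox1", "trnL2", "cox2", "trnK", "trnD", "atp8", "atp6"]
        assert order.sign_of("nad5") == -1

    def test_single_gene_annotation(self):
        ann = model.MitoAnnotation(1000, [
            model.GeneFeature("cox1", model.HEAVY, 1, 900)])
        assert order_from_annotation(ann).elements == (("cox1", 1),)

    def test_duplicate_names_rejected(self):
        with pytest.raises(model.MitoError):
            GeneOrder("x", (("cox1", 1), ("cox1", -1)))


class TestNormalize:
    def test_rotation_invariance(self):
        assert normalize(rotated(GROUND_PATTERN, 5)).elements == \
            normalize(GROUND_PATTERN).elements

    def test_reflection_invariance(self):
        assert normalize(reflected(GROUND_PATTERN)).elements == \
            normalize(GROUND_PATTERN).elements

    def test_idempotent_on_random_transforms(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            o = rotated(GROUND_PATTERN, int(rng.integers(38)))
            if rng.integers(2):
                o = reflected(o)
            once = normalize(o)
            assert normalize(once).elements == once.elements
            assert once.elements[0] == ("cox1", 1)

    def test_missing_anchor_is_error(self):
        with pytest.raises(model.MitoError, match="cox1"):
            normalize(GeneOrder("x", (("trnA", 1), ("trnB", 1))))


class TestBreakpointDistance:
    def test_identity_is_zero(self):
        assert breakpoint_distance(GROUND_PATTERN, rotated(GROUND_PATTERN, 9)) == 0
        assert breakpoint_distance(GROUND_PATTERN, reflected(GROUND_PATTERN)) == 0

    def test_single_translocation_costs_three(self, albolineatus_order):
        assert breakpoint_distance(GROUND_PATTERN, albolineatus_order) == 3

    def test_matches_brute_force_and_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            e = list(GROUND_PATTERN.elements)
            rng.shuffle(e)
            a = GeneOrder("a", tuple(e))
            rng.shuffle(e)
            b = GeneOrder("b", tuple(e))
            d = breakpoint_distance(a, b)
            assert d == brute_force_breakpoints(a, b)
            assert d == breakpoint_distance(b, a)

    def test_zero_iff_normalized_equal(self):
        new, _ = simulate_translocation(GROUND_PATTERN, "trnD", 20)
        assert breakpoint_distance(GROUND_PATTERN, new) > 0
        assert normalize(new).elements != normalize(GROUND_PATTERN).elements

    def test_disjoint_gene_sets_error(self):
        a = GeneOrder("a", (("cox1", 1),))
        b = GeneOrder("b", (("cox2", 1),))
        with pytest.raises(model.MitoError):
            breakpoint_distance(a, b)


class TestDetectMovedGenes:
    def test_published_order_differs_by_trnh_only(self, table2):
        diff = detect_moved_genes(GROUND_PATTERN, order_from_annotation(table2))
        assert set(diff.moved_genes) == {"trnH"}
        assert not diff.inverted_genes and not diff.complex

    def test_identical_orders(self):
        diff = detect_moved_genes(GROUND_PATTERN, rotated(GROUND_PATTERN, 3))
        assert not diff.moved_genes and not diff.inverted_genes
        assert diff.breakpoints == 0

    def test_two_simulated_translocations_recovered(self):
        o1, _ = simulate_translocation(GROUND_PATTERN, "trnD", 25)
        o2, _ = simulate_translocation(o1, "trnW", 5)
        diff = detect_moved_genes(GROUND_PATTERN, o2)
        assert set(diff.moved_genes) == {"trnD", "trnW"}

    def test_complex_rearrangement_flagged(self):
        rng = np.random.default_rng(3)
        e = list(GROUND_PATTERN.elements)
        rng.shuffle(e)
        diff = detect_moved_genes(GROUND_PATTERN, GeneOrder("shuffled", tuple(e)),
                                  max_set=2)
        assert diff.complex and diff.breakpoints > 0

    def test_agrees_with_exhaustive_search_on_small_orders(self):
        base = GeneOrder("small", tuple(GROUND_PATTERN.elements[:8]))
        rng = np.random.default_rng(7)
        for _ in range(30):
            e = list(base.elements)
            rng.shuffle(e)
            other = GeneOrder("perm", tuple(e))
            diff = detect_moved_genes(base, other, max_set=6)
            oracle = brute_force_minimal_sets(base, other)
            if diff.complex:
                assert all(len(S) > 6 for S in oracle) or not oracle
            else:
                assert set(diff.moved_genes) in oracle
                assert min(len(S) for S in oracle) == len(diff.moved_genes)


class TestGrouping:
    def test_three_identical_one_distinct(self, albolineatus_order):
        a = GeneOrder("t1", GROUND_PATTERN.elements)
        b = GeneOrder("t2", rotated(GROUND_PATTERN, 4).elements)
        c = GeneOrder("t3", reflected(GROUND_PATTERN).elements)
        groups = group_patterns([a, b, c, albolineatus_order])
        sizes = sorted(len(g.members) for g in groups)
        assert sizes == [1, 3]

    def test_partition_independent_of_input_order(self, albolineatus_order):
        a = GeneOrder("t1", GROUND_PATTERN.elements)
        b = GeneOrder("t2", rotated(GROUND_PATTERN, 4).elements)
        g1 = group_patterns([a, b, albolineatus_order])
        g2 = group_patterns([albolineatus_order, b, a])
        p1 = sorted(frozenset(g.members) for g in g1)
        p2 = sorted(frozenset(g.members) for g in g2)
        assert sorted(map(sorted, p1)) == sorted(map(sorted, p2))

    def test_k_source_patterns_give_k_groups(self):
        rng = np.random.default_rng(11)
        sources = [GROUND_PATTERN]
        for k, gene in enumerate(["trnD", "trnW", "trnT"]):
            new, _ = simulate_translocation(GROUND_PATTERN, gene, 30)
            sources.append(new)
        orders = []
        for i, src in enumerate(sources):
            for j in range(3):
                orders.append(GeneOrder(f"s{i}_{j}",
                                        rotated(src, int(rng.integers(38))).elements))
        assert len(group_patterns(orders)) == len(sources)


class TestNeighborJoining:
    def test_zero_distance_pair_are_siblings(self, albolineatus_order):
        import dendropy
        a = GeneOrder("alpha", GROUND_PATTERN.elements)
        b = GeneOrder("beta", rotated(GROUND_PATTERN, 2).elements)
        newick = nj_from_orders([a, b, albolineatus_order])
        tree = dendropy.Tree.get(data=newick, schema="newick")
        taxa = {t.label for t in tree.taxon_namespace}
        assert taxa == {"alpha", "beta", "G_albolineatus"}
        pdm = tree.phylogenetic_distance_matrix()
        t = {x.label: x for x in tree.taxon_namespace}
        assert pdm.distance(t["alpha"], t["beta"]) <= \
            pdm.distance(t["alpha"], t["G_albolineatus"])

    def test_newick_round_trip_on_random_orders(self):
        import dendropy
        rng = np.random.default_rng(5)
        orders = []
        for i in range(5):
            e = list(GROUND_PATTERN.elements)
            rng.shuffle(e)
            orders.append(GeneOrder(f"tax{i}", tuple(e)))
        newick = nj_from_orders(orders)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert {t.label for t in tree.taxon_namespace} == \
            {o.taxon for o in orders}

    def test_fewer_than_three_is_error(self):
        with pytest.raises(model.MitoError):
            nj_from_orders([GROUND_PATTERN, GROUND_PATTERN])

    def test_distance_matrix_symmetric(self, fixture_orders):
        labels, d = distance_matrix(fixture_orders)
        assert d[0][1] == d[1][0] == 3


class TestOrderIO:
    def test_fixture_round_trip(self, fixture_orders):
        buf = io.StringIO()
        write_orders(fixture_orders, buf)
        buf.seek(0)
        again = read_orders(buf)
        assert [(o.taxon, o.elements) for o in again] == \
            [(o.taxon, o.elements) for o in fixture_orders]

    def test_unknown_gene_rejected(self):
        with pytest.raises(model.MitoError, match="unknown gene"):
            read_orders(io.StringIO("t: cox1 nonsense\n"))
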