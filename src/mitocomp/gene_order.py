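"""Signed circular gene orders and rearrangement comparison.

A mitogenome's gene order is modelled as a signed circular permutation over
the 37 genes plus the control region: each element is a gene name with a sign
(+ heavy strand, − light strand).  Orders are compared against the
Pancrustacean ground pattern — the ancestral crustacean+hexapod arrangement —
to detect translocations and inversions, to count breakpoints, and to group
taxa sharing an arrangement.  Because tRNA translocations carry phylogenetic
signal at the family level, the module also emits a neighbor-joining summary
tree from the pairwise breakpoint-distance matrix (a distance summary of order
similarity, not a substitute for sequence-based phylogenetics).
"""

from __future__ import annotations

import io
import itertools
import warnings
from dataclasses import dataclass
from typing import IO, Iterable, Sequence, Union

from .model import CR_NAME, LIGHT, TRNA, MitoAnnotation, MitoError, canonical_name, gene_class_of

Element = tuple[str, int]  # (gene name, +1 heavy / -1 light)


class OrderWarning(UserWarning):
    pass


@dataclass(frozen=True)
class GeneOrder:
    """A taxon's signed circular gene order."""

    taxon: str
    elements: tuple[Element, ...]

    def __post_init__(self) -> None:
        names = [g for g, _ in self.elements]
        if len(set(names)) != len(names):
            raise MitoError(f"{self.taxon}: duplicate gene names in order")
        if len(names) > 38:
            raise MitoError(f"{self.taxon}: more than 38 orderable elements")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.elements)

    def without(self, drop: Iterable[str]) -> "GeneOrder":
        drop = set(drop)
        return GeneOrder(self.taxon,
                         tuple(e for e in self.elements if e[0] not in drop))

    def sign_of(self, gene: str) -> int:
        for g, s in self.elements:
            if g == gene:
                return s
        raise KeyError(gene)


def _signed(names_signs: str) -> tuple[Element, ...]:
    out = []
    for tok in names_signs.split():
        sign = -1 if tok.startswith("-") else 1
        out.append((tok.lstrip("-"), sign))
    return tuple(out)


#: The Pancrustacean ground pattern: the ancestral arrangement used as the
#: comparison baseline, with the conserved arthropod strand assignment.
GROUND_PATTERN = GeneOrder("pancrustacean_ground", _signed(
    "cox1 trnL2 cox2 trnK trnD atp8 atp6 cox3 trnG nad3 trnA trnR trnN trnS1 "
    "trnE -trnF -nad5 -trnH -nad4 -nad4L trnT -trnP nad6 cytb trnS2 -nad1 "
    "-trnL1 -rrnL -trnV -rrnS CR trnI -trnQ trnM nad2 trnW -trnC -trnY"))


@dataclass
class OrderDiff:
    """Result of reconciling two orders by excising a minimal gene set.

    ``candidates`` lists every reconciling set of the minimal cardinality:
    some rearrangements are genuinely ambiguous (moving gene X in front of
    its neighbour Y is the identical permutation to moving Y behind X), and
    then more than one minimal explanation exists.  ``moved_genes`` is the
    tie-break choice among them (tRNA-only sets first, then lexicographic).
    """

    moved_genes: frozenset[str]
    inverted_genes: frozenset[str]
    breakpoints: int
    complex: bool = False  # no reconciling set within the search cap
    candidates: tuple[frozenset[str], ...] = ()


@dataclass
class PatternGroup:
    pattern_id: int
    representative: GeneOrder
    members: list[str]


# ---------------------------------------------------------------------------
# Construction and canonicalisation
# ---------------------------------------------------------------------------

def order_from_annotation(annotation: MitoAnnotation,
                          include_cr: bool = True) -> GeneOrder:
    """Gene order in circular positional order of feature starts."""
    elements: list[Element] = []
    for f in annotation.features:
        if not include_cr and f.name == CR_NAME:
            continue
        elements.append((f.name, -1 if f.strand == LIGHT else 1))
    return GeneOrder(annotation.taxon or "unnamed", tuple(elements))


def _reflect(elements: Sequence[Element]) -> tuple[Element, ...]:
    return tuple((g, -s) for g, s in reversed(elements))


def normalize(order: GeneOrder) -> GeneOrder:
    """Canonical linearisation: rotate so cox1 is first, in the + frame.

    If cox1 carries a negative sign the whole order is reflected and
    sign-flipped first, so two annotations of the same molecule read off
    opposite strands normalise identically.
    """
    elements = order.elements
    try:
        idx = [g for g, _ in elements].index("cox1")
    except ValueError:
        raise MitoError(f"{order.taxon}: cox1 absent; cannot anchor the order") from None
    if elements[idx][1] < 0:
        elements = _reflect(elements)
        idx = [g for g, _ in elements].index("cox1")
    return GeneOrder(order.taxon, elements[idx:] + elements[:idx])


def circular_equal(a: Sequence, b: Sequence) -> bool:
    """True if b is a rotation of a (elements compared exactly)."""
    if len(a) != len(b):
        return False
    if not a:
        return True
    a2, b = tuple(a) + tuple(a), tuple(b)
    return any(a2[i:i + len(b)] == b for i in range(len(a)))


# ---------------------------------------------------------------------------
# Breakpoint distance
# ---------------------------------------------------------------------------

def _adjacency_set(elements: Sequence[Element]) -> set[tuple]:
    """Signed circular adjacencies, canonicalised for reading direction.

    The adjacency x→y read on one strand is y'→x' on the other, so each pair
    is stored as the lexicographic minimum of the two readings.
    """
    adj = set()
    n = len(elements)
    for i in range(n):
        (g1, s1), (g2, s2) = elements[i], elements[(i + 1) % n]
        adj.add(min((g1, s1, g2, s2), (g2, -s2, g1, -s1)))
    return adj


def _restrict_common(a: GeneOrder, b: GeneOrder) -> tuple[GeneOrder, GeneOrder]:
    common = a.genes & b.genes
    if not common:
        raise MitoError(f"{a.taxon} and {b.taxon} share no genes")
    if common != a.genes or common != b.genes:
        warnings.warn(
            f"{a.taxon}/{b.taxon}: gene sets differ; comparison restricted to "
            f"{len(common)} shared genes", OrderWarning, stacklevel=3)
        a, b = a.without(a.genes - common), b.without(b.genes - common)
    return a, b


def breakpoint_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Number of signed circular adjacencies of ``a`` absent from ``b``.

    Symmetric (both orders carry the same number of adjacencies over the
    shared gene set); zero exactly when the normalised orders coincide.
    """
    a, b = _restrict_common(a, b)
    return len(_adjacency_set(a.elements) - _adjacency_set(b.elements))


# ---------------------------------------------------------------------------
# Moved-gene detection
# ---------------------------------------------------------------------------

def _names(elements: Sequence[Element]) -> tuple[str, ...]:
    return tuple(g for g, _ in elements)


def _is_trna(gene: str) -> bool:
    return gene_class_of(gene) == TRNA


def detect_moved_genes(a: GeneOrder, b: GeneOrder, max_set: int = 3) -> OrderDiff:
    """Find the smallest gene set whose excision reconciles two orders.

    Searches subsets in increasing cardinality (exhaustively up to
    ``max_set``) for a set S such that deleting S from both orders leaves
    identical circular gene sequences; ties are broken by preferring sets of
    tRNAs only, then lexicographically.  Genes at reconciled positions whose
    strand sign differs are reported as ``inverted_genes``.  If no set of at
    most ``max_set`` genes reconciles the orders the result is flagged
    ``complex`` and carries the breakpoint distance only.
    """
    a, b = _restrict_common(a, b)
    bp = len(_adjacency_set(a.elements) - _adjacency_set(b.elements))
    try:
        a_n, b_n = normalize(a), normalize(b)
    except MitoError:
        a_n, b_n = a, b  # anchor-free comparison still works via rotation search
    genes = sorted(a_n.genes)
    for k in range(0, min(max_set, len(genes) - 1) + 1):
        hits = []
        for S in itertools.combinations(genes, k):
            ra = a_n.without(S)
            rb = b_n.without(S)
            if circular_equal(_names(ra.elements), _names(rb.elements)) or \
               circular_equal(_names(ra.elements), _names(_reflect(rb.elements))):
                hits.append(S)
        if hits:
            hits.sort(key=lambda S: (not all(_is_trna(g) for g in S), S))
            S = hits[0]
            inverted = _inverted_at_aligned_positions(a_n.without(S), b_n.without(S))
            inverted |= {g for g in S if a_n.sign_of(g) != b_n.sign_of(g)}
            return OrderDiff(frozenset(S), frozenset(inverted), bp,
                             candidates=tuple(frozenset(h) for h in hits))
    return OrderDiff(frozenset(), frozenset(), bp, complex=True)


def _inverted_at_aligned_positions(ra: GeneOrder, rb: GeneOrder) -> set[str]:
    """Signs differing between two circularly identical gene sequences."""
    na, nb = _names(ra.elements), _names(rb.elements)
    if not na:
        return set()
    candidates = [rb.elements]
    if not circular_equal(na, nb):
        candidates = [_reflect(rb.elements)]
    for eb in candidates:
        doubled = eb + eb
        for i in range(len(eb)):
            window = doubled[i:i + len(na)]
            if tuple(g for g, _ in window) == na:
                return {g for (g, sa), (_, sb) in zip(ra.elements, window) if sa != sb}
    return set()


# ---------------------------------------------------------------------------
# Pattern grouping and tree emission
# ---------------------------------------------------------------------------

def group_patterns(orders: Sequence[GeneOrder]) -> list[PatternGroup]:
    """Partition taxa by equality of normalised orders (stable numbering)."""
    if not orders:
        raise MitoError("no orders")
    groups: list[PatternGroup] = []
    index: dict[tuple, int] = {}
    for o in orders:
        key = normalize(o).elements
        if key not in index:
            index[key] = len(groups)
            groups.append(PatternGroup(len(groups) + 1, o, []))
        groups[index[key]].members.append(o.taxon)
    return groups


def distance_matrix(orders: Sequence[GeneOrder]) -> tuple[list[str], list[list[int]]]:
    labels = [o.taxon for o in orders]
    if len(set(labels)) != len(labels):
        raise MitoError("taxon labels must be unique for a distance matrix")
    n = len(orders)
    d = [[0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d[i][j] = d[j][i] = breakpoint_distance(orders[i], orders[j])
    return labels, d


def nj_from_orders(orders: Sequence[GeneOrder]) -> str:
    """Neighbor-joining newick tree on the breakpoint-distance matrix.

    Taxa are sorted by label before matrix construction so ties resolve
    deterministically.
    """
    if len(orders) < 3:
        raise MitoError("neighbor joining needs at least three orders")
    from skbio import DistanceMatrix
    from skbio.tree import nj

    ordered = sorted(orders, key=lambda o: o.taxon)
    labels, d = distance_matrix(ordered)
    tree = nj(DistanceMatrix(d, ids=labels))
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def write_distance_matrix(orders: Sequence[GeneOrder], dest: IO[str]) -> None:
    labels, d = distance_matrix(orders)
    dest.write("taxon\t" + "\t".join(labels) + "\n")
    for lab, row in zip(labels, d):
        dest.write(lab + "\t" + "\t".join(map(str, row)) + "\n")


# ---------------------------------------------------------------------------
# Text format: "taxon: g1 -g2 g3 ..."
# ---------------------------------------------------------------------------

def read_orders(source: Union[str, IO[str]]) -> list[GeneOrder]:
    if hasattr(source, "read"):
        text = source.read()  # type: ignore[union-attr]
    else:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    orders = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise MitoError(f"line {lineno}: expected 'taxon: gene gene ...'")
        taxon, rest = line.split(":", 1)
        elements = []
        for tok in rest.replace("−", "-").split():
            sign = -1 if tok.startswith("-") else 1
            name = canonical_name(tok.lstrip("-+"))
            if name is None:
                raise MitoError(f"line {lineno}: unknown gene {tok!r}")
            elements.append((name, sign))
        orders.append(GeneOrder(taxon.strip(), tuple(elements)))
    if not orders:
        raise MitoError("no orders in input")
    return orders


def write_orders(orders: Sequence[GeneOrder], dest: IO[str]) -> None:
    for o in orders:
        toks = [("-" if s < 0 else "") + g for g, s in o.elements]
        dest.write(f"{o.taxon}: {' '.join(toks)}\n")
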