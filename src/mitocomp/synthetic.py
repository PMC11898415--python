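"""Synthetic circular mitogenomes with controlled composition, codon usage
and gene order, plus rearrangement simulators with recorded ground truth.

The generator emulates the structure of a brachyuran crab mitogenome: a
~15.6 kb circle carrying 13 PCGs, 22 tRNAs, 2 rRNAs and one control region,
laid out along a chosen signed gene order (default: the Pancrustacean ground
pattern), with first-order base composition solved from (A+T content, AT
skew, GC skew) targets and protein-coding genes assembled codon-by-codon
under the invertebrate mitochondrial code.  Default targets and gene lengths
mirror the published *Grapsus albolineatus* record (A+T 67.4%, AT skew −0.01,
GC skew −0.26, 15,580 bp; cox1/cox2/cytb with truncated stops).

Rearrangement events — tandem duplication–random loss (TDRL), single-gene
translocation, and span inversion — operate on :class:`GeneOrder` values and
return the event applied, so detector code can be tested against known truth.

All randomness flows from one explicit seed; there is no global RNG state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import IO, Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .codon_usage import ALL_CODONS, INVERTEBRATE_MITO, GeneticCode
from .gene_order import GROUND_PATTERN, Element, GeneOrder, circular_equal
from .model import (
    CONTROL_REGION, CR_NAME, HEAVY, LIGHT, PCG, RRNA, TRNA,
    GeneFeature, MitoAnnotation, MitoError, Mitogenome, gene_class_of,
)

#: PCG lengths (nt) of the G. albolineatus record; lengths with a remainder
#: mod 3 get truncated stop codons (cox1, cox2, cytb).
DEFAULT_PCG_LENGTHS: dict[str, int] = {
    "cox1": 1534, "cox2": 688, "atp8": 159, "atp6": 675, "cox3": 792,
    "nad3": 351, "nad5": 1731, "nad4": 1338, "nad4L": 303, "nad6": 504,
    "cytb": 1135, "nad1": 966, "nad2": 1011,
}

DEFAULT_START_CODONS: dict[str, str] = {
    "cox1": "ATG", "cox2": "ATG", "atp8": "GTG", "atp6": "ATT", "cox3": "ATG",
    "nad3": "ATC", "nad5": "ATG", "nad4": "ATG", "nad4L": "ATG",
    "nad6": "ATT", "cytb": "ATG", "nad1": "ATT", "nad2": "ATG",
}

DEFAULT_RRNA_LENGTHS: dict[str, int] = {"rrnL": 1328, "rrnS": 827}


@dataclass
class GenomeSpec:
    """Parameters of a synthetic mitogenome.

    ``codon_bias`` (codon → weight, RNA keys, coding frame) overrides the
    composition-derived codon model when given; stop codons never appear
    inside a CDS body regardless.  ``spacer`` nt separate consecutive
    features; the control region absorbs the remaining length, so the
    molecule length target is met exactly.
    """

    molecule_length: int = 15580
    at_content: float = 0.674
    at_skew: float = -0.01
    gc_skew: float = -0.26
    gene_order: GeneOrder = field(default_factory=lambda: GROUND_PATTERN)
    pcg_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PCG_LENGTHS))
    start_codons: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_START_CODONS))
    rrna_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_RRNA_LENGTHS))
    trna_length_range: tuple[int, int] = (60, 75)
    codon_bias: Optional[dict[str, float]] = None
    spacer: int = 0
    taxon: str = "synthetic"
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.at_content < 1.0:
            raise MitoError("at_content must lie in (0, 1)")
        for name, v in (("at_skew", self.at_skew), ("gc_skew", self.gc_skew)):
            if not -1.0 < v < 1.0:
                raise MitoError(f"{name} must lie in (-1, 1)")
        for g, n in self.pcg_lengths.items():
            if n < 6:
                raise MitoError(f"{g}: PCG length {n} < 6")

    def base_probs(self) -> dict[str, float]:
        """Per-base probabilities solved from the content/skew targets."""
        at, gc = self.at_content, 1.0 - self.at_content
        return {
            "A": at * (1 + self.at_skew) / 2, "T": at * (1 - self.at_skew) / 2,
            "G": gc * (1 + self.gc_skew) / 2, "C": gc * (1 - self.gc_skew) / 2,
        }


@dataclass
class RearrangementEvent:
    """A simulated rearrangement, with enough detail to replay it."""

    kind: str  # "TDRL" | "translocation" | "inversion"
    parameters: dict
    seed: Optional[int] = None

    def to_json(self) -> str:
        return json.dumps({"kind": self.kind, "parameters": self.parameters,
                           "seed": self.seed}, sort_keys=True)


def write_event_log(events: Sequence[RearrangementEvent], dest: IO[str]) -> None:
    for e in events:
        dest.write(e.to_json() + "\n")


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _match_marginals(p_rna: dict[str, float], stops: set[str],
                     iterations: int = 80) -> dict[str, float]:
    """Adjust base weights so the stop-free codon model keeps target marginals.

    Dropping the AT-rich stop codons from an independent-base codon model
    shifts its per-base marginal away from the composition target.  A short
    fixed-point iteration (multiply each base weight by target/achieved and
    renormalise) restores the marginal to the target to high precision.
    """
    q = dict(p_rna)
    for _ in range(iterations):
        w = {c: q[c[0]] * q[c[1]] * q[c[2]] for c in ALL_CODONS if c not in stops}
        tot = sum(w.values())
        m = dict.fromkeys(q, 0.0)
        for c, v in w.items():
            for b in c:
                m[b] += v / (3 * tot)
        q = {b: q[b] * p_rna[b] / m[b] if m[b] > 0 else 0.0 for b in q}
        s = sum(q.values())
        q = {b: v / s for b, v in q.items()}
    return q


def _codon_probs(spec: GenomeSpec, strand: str,
                 code: GeneticCode = INVERTEBRATE_MITO) -> np.ndarray:
    """Coding-frame codon probabilities for a gene on the given strand.

    Without an explicit ``codon_bias`` the codon model is the base-composition
    model read in coding orientation: heavy-strand genes use the genome-strand
    base probabilities directly, light-strand genes the complemented ones, so
    that after reverse-complementing into the molecule every gene contributes
    the target composition on the heavy strand.  Stop codons are excluded and
    the base weights moment-matched so the exclusion does not bias the
    genome-wide composition.
    """
    stops = set(code.families["*"])
    if spec.codon_bias is not None:
        w = np.array([max(spec.codon_bias.get(c, 0.0), 0.0) for c in ALL_CODONS])
    else:
        p = spec.base_probs()
        if strand == LIGHT:
            p = {b: p[_COMPLEMENT[b]] for b in p}
        prna = _match_marginals({"U" if b == "T" else b: v for b, v in p.items()},
                                stops)
        w = np.array([prna[c[0]] * prna[c[1]] * prna[c[2]] for c in ALL_CODONS])
    for i, c in enumerate(ALL_CODONS):
        if c in stops:
            w[i] = 0.0
    if w.sum() <= 0:
        raise MitoError("codon bias assigns zero weight to every sense codon")
    return w / w.sum()


def _quota_counts(p: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of ``n`` draws to probabilities ``p``."""
    exact = p / p.sum() * n
    counts = np.floor(exact).astype(int)
    short = n - counts.sum()
    if short:
        counts[np.argsort(-(exact - counts), kind="stable")[:short]] += 1
    return counts


def _random_bases(rng: np.random.Generator, n: int, probs: dict[str, float]) -> str:
    """A shuffled sequence whose base counts match ``probs`` exactly.

    Stratified (quota) sampling rather than i.i.d. draws: the generator's
    contract is *controlled* composition, so per-region base counts follow
    largest-remainder apportionment and only the arrangement is random.
    """
    bases = "ATGC"
    counts = _quota_counts(np.array([probs[b] for b in bases]), n)
    arr = np.array(list("".join(b * k for b, k in zip(bases, counts))))
    rng.shuffle(arr)
    return "".join(arr)


def _pcg_sequence(rng: np.random.Generator, spec: GenomeSpec, gene: str,
                  strand: str, length: int) -> str:
    """Genome-strand sequence of one PCG of exactly ``length`` nt."""
    rem = length % 3
    stop = "T" * (rem == 1) + "TA" * (rem == 2) or "TAA"
    n_body = (length - rem) // 3 - 1 - (0 if rem else 1)
    if n_body < 0:
        raise MitoError(f"{gene}: length {length} too short for start+stop")
    probs = _codon_probs(spec, strand)
    counts = _quota_counts(probs, n_body)
    codons = np.repeat(np.arange(len(ALL_CODONS)), counts)
    rng.shuffle(codons)
    body = "".join(ALL_CODONS[i] for i in codons).replace("U", "T")
    coding = spec.start_codons.get(gene, "ATG") + body + stop
    assert len(coding) == length
    if strand == LIGHT:
        return str(Seq(coding).reverse_complement())
    return coding


def generate_genome(spec: GenomeSpec) -> Mitogenome:
    """Build a seeded synthetic :class:`Mitogenome` from a :class:`GenomeSpec`.

    Features are laid out along ``spec.gene_order`` starting at position 1;
    the control region absorbs whatever length remains after all genes and
    spacers, and an infeasible layout (no room left) raises
    :class:`MitoError`.  The same spec (same seed) always yields the identical
    genome.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    probs = spec.base_probs()
    order = spec.gene_order

    lengths: dict[str, int] = {}
    lo, hi = spec.trna_length_range
    for gene, _sign in order.elements:
        cls = gene_class_of(gene)
        if cls == PCG:
            lengths[gene] = spec.pcg_lengths[gene]
        elif cls == TRNA:
            lengths[gene] = int(rng.integers(lo, hi + 1))
        elif cls == RRNA:
            lengths[gene] = spec.rrna_lengths[gene]
    n_feats = len(order.elements)
    fixed = sum(lengths.values()) + spec.spacer * n_feats
    if CR_NAME in order.genes:
        cr_len = spec.molecule_length - fixed
        if cr_len < 50:
            raise MitoError(
                f"infeasible layout: {fixed} nt of genes/spacers leaves {cr_len} nt "
                f"for the control region (minimum 50)")
        lengths[CR_NAME] = cr_len
    elif fixed != spec.molecule_length:
        raise MitoError("gene order lacks CR and lengths do not tile the molecule")

    chunks: list[str] = []
    features: list[GeneFeature] = []
    pos = 1
    for gene, sign in order.elements:
        cls = gene_class_of(gene)
        strand = LIGHT if sign < 0 else HEAVY
        length = lengths[gene]
        if cls == PCG:
            seq = _pcg_sequence(rng, spec, gene, strand, length)
            rem = length % 3
            stop = "T" * (rem == 1) + "TA" * (rem == 2) or "TAA"
            feat = GeneFeature(gene, strand, pos, pos + length - 1,
                               start_codon=spec.start_codons.get(gene, "ATG"),
                               stop_codon=stop)
        else:
            seq = _random_bases(rng, length, probs)
            feat = GeneFeature(gene, HEAVY if cls == CONTROL_REGION else strand,
                               pos, pos + length - 1)
        chunks.append(seq)
        features.append(feat)
        pos += length
        if spec.spacer:
            chunks.append(_random_bases(rng, spec.spacer, probs))
            pos += spec.spacer
    sequence = "".join(chunks)
    assert len(sequence) == spec.molecule_length
    ann = MitoAnnotation(molecule_length=spec.molecule_length, features=features,
                         taxon=spec.taxon)
    return Mitogenome(annotation=ann, sequence=sequence)


# ---------------------------------------------------------------------------
# Rearrangement simulators
# ---------------------------------------------------------------------------

def _span_start(order: GeneOrder, span: Sequence[str]) -> int:
    """Index where ``span`` begins as a contiguous circular block, or raise."""
    names = [g for g, _ in order.elements]
    n = len(names)
    span = list(span)
    if not span or len(span) > n:
        raise MitoError("span must be a non-empty block of the order")
    doubled = names + names
    for i in range(n):
        if doubled[i:i + len(span)] == span:
            return i
    raise MitoError(f"span {span} is not a contiguous block of {order.taxon}")


def simulate_tdrl(order: GeneOrder, span: Sequence[str],
                  loss_mask: Optional[Sequence[int]] = None,
                  seed: Optional[int] = None,
                  ) -> tuple[GeneOrder, RearrangementEvent]:
    """Tandem duplication–random loss of a contiguous gene block.

    The block is duplicated in tandem; then, for each duplicated gene, one of
    its two copies is deleted according to ``loss_mask`` (1 = keep the first
    copy, 2 = keep the second, aligned with ``span``).  When no mask is given
    a random one is drawn from ``seed``.  Strand signs are never changed:
    TDRL is a same-strand mechanism, which is why strand-preserving tRNA
    relocations are its classic signature.
    """
    i = _span_start(order, span)
    k = len(span)
    if loss_mask is None:
        rng = np.random.default_rng(seed)
        loss_mask = [int(rng.integers(1, 3)) for _ in range(k)]
    if len(loss_mask) != k or any(m not in (1, 2) for m in loss_mask):
        raise MitoError("loss mask must assign 1 (first copy) or 2 (second copy) "
                        "to every duplicated gene")
    rotated = list(order.elements[i:] + order.elements[:i])  # span is now a prefix
    block = rotated[:k]
    tandem = block + block + rotated[k:]
    keep: list[Element] = []
    seen_copy = {g: 0 for g in span}
    mask = dict(zip(span, loss_mask))
    for g, s in tandem:
        if g in mask:
            seen_copy[g] += 1
            if seen_copy[g] != mask[g]:
                continue
        keep.append((g, s))
    # undo the working rotation so unmoved genes keep their linear positions
    if i:
        keep = keep[-i:] + keep[:-i]
    new = GeneOrder(order.taxon, tuple(keep))
    event = RearrangementEvent("TDRL", {
        "span": list(span), "loss_mask": list(loss_mask)}, seed)
    return new, event


def simulate_translocation(order: GeneOrder, gene: str, insertion_point: int,
                           ) -> tuple[GeneOrder, RearrangementEvent]:
    """Excise one gene and reinsert it, strand sign unchanged.

    ``insertion_point`` is the index (0-based, modulo n−1) the gene occupies
    in the resulting element list after removal.  A reinsertion that leaves
    the circular order unchanged raises :class:`MitoError`.
    """
    names = [g for g, _ in order.elements]
    if gene not in names:
        raise MitoError(f"{gene} not in order {order.taxon}")
    idx = names.index(gene)
    element = order.elements[idx]
    rest = [e for e in order.elements if e[0] != gene]
    j = insertion_point % len(order.elements)
    if j > len(rest):
        j = j % (len(rest) + 1)
    new_elements = tuple(rest[:j] + [element] + rest[j:])
    if circular_equal(new_elements, order.elements):
        raise MitoError(f"translocation of {gene} to {insertion_point} is a no-op")
    new = GeneOrder(order.taxon, new_elements)
    event = RearrangementEvent("translocation",
                               {"gene": gene, "insertion_point": insertion_point})
    return new, event


def simulate_inversion(order: GeneOrder, span: Sequence[str],
                       ) -> tuple[GeneOrder, RearrangementEvent]:
    """Reverse a contiguous span in place, flipping every strand sign."""
    if len(span) >= len(order.elements):
        raise MitoError("inverting the whole circle is a no-op")
    i = _span_start(order, span)
    k = len(span)
    rotated = list(order.elements[i:] + order.elements[:i])
    inverted = [(g, -s) for g, s in reversed(rotated[:k])]
    new_rotated = inverted + rotated[k:]
    # rotate back so unmoved genes keep their original linear positions
    new_elements = tuple(new_rotated[-i:] + new_rotated[:-i]) if i else tuple(new_rotated)
    new = GeneOrder(order.taxon, new_elements)
    event = RearrangementEvent("inversion", {"span": list(span)})
    return new, event
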