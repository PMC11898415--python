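"""Nucleotide composition and strand-asymmetry (skew) statistics.

Mitochondrial genomes replicate asynchronously, which leaves the two strands
compositionally asymmetric.  The standard summary statistics are

    AT skew = (A - T) / (A + T)        GC skew = (G - C) / (G + C)

computed over base counts (or, equivalently, percentages — the statistics are
scale-invariant).  Crustacean mitogenomes typically show a strong negative GC
skew and a near-zero AT skew on the heavy strand, together with a pronounced
A+T bias (~60-78%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Optional, Sequence, Union

from .model import Mitogenome


class SkewUndefinedError(ArithmeticError):
    """Raised when a skew denominator (A+T or G+C) is zero."""


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (the convention of printed genome tables)."""
    m = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * m + 0.5) / m, x)


@dataclass
class CompositionStats:
    """Base counts, percentages, A+T content and skews of one sequence.

    Percentages are of counted (unambiguous) bases; symbols outside A/C/G/T
    are excluded from every denominator and tallied in ``n_ambiguous``.
    A skew whose denominator is zero is ``None`` rather than a silent 0.
    """

    count_A: int
    count_C: int
    count_G: int
    count_T: int
    n_ambiguous: int = 0

    @property
    def total(self) -> int:
        return self.count_A + self.count_C + self.count_G + self.count_T

    @property
    def pct_A(self) -> float:
        return 100.0 * self.count_A / self.total

    @property
    def pct_C(self) -> float:
        return 100.0 * self.count_C / self.total

    @property
    def pct_G(self) -> float:
        return 100.0 * self.count_G / self.total

    @property
    def pct_T(self) -> float:
        return 100.0 * self.count_T / self.total

    @property
    def at_content(self) -> float:
        return self.pct_A + self.pct_T

    @property
    def at_skew(self) -> Optional[float]:
        try:
            return at_skew(self.count_A, self.count_T)
        except SkewUndefinedError:
            return None

    @property
    def gc_skew(self) -> Optional[float]:
        try:
            return gc_skew(self.count_G, self.count_C)
        except SkewUndefinedError:
            return None


def at_skew(a: float, t: float) -> float:
    """``(A - T) / (A + T)`` from counts or percentages (scale-invariant)."""
    if a + t == 0:
        raise SkewUndefinedError("A + T is zero; AT skew undefined")
    return (a - t) / (a + t)


def gc_skew(g: float, c: float) -> float:
    """``(G - C) / (G + C)`` from counts or percentages (scale-invariant)."""
    if g + c == 0:
        raise SkewUndefinedError("G + C is zero; GC skew undefined")
    return (g - c) / (g + c)


def composition_stats(sequence: str) -> CompositionStats:
    """Tally A/C/G/T over a sequence; other IUPAC symbols count as ambiguous."""
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
    return CompositionStats(a, c, g, t, n_ambiguous=len(s) - (a + c + g + t))


GenomeLike = Union[Mitogenome, tuple[str, str]]


def composition_report(
    genomes: Sequence[GenomeLike],
    pct_digits: int = 1,
    skew_digits: int = 2,
) -> list[dict]:
    """One record per genome with the columns of a published composition table.

    ``genomes`` may mix :class:`Mitogenome` objects and ``(taxon, sequence)``
    pairs; input order is preserved.  Percentages and skews are rounded
    half-away-from-zero to the requested precisions (full precision is a
    property of :func:`composition_stats`, not of this report).
    """
    if not genomes:
        raise ValueError("no genomes")
    records = []
    for g in genomes:
        if isinstance(g, Mitogenome):
            taxon, seq = g.annotation.taxon, g.sequence
        else:
            taxon, seq = g
        st = composition_stats(seq)
        records.append({
            "Species": taxon,
            "Size(bp)": len(seq),
            "A": round_half_away(st.pct_A, pct_digits),
            "T": round_half_away(st.pct_T, pct_digits),
            "C": round_half_away(st.pct_C, pct_digits),
            "G": round_half_away(st.pct_G, pct_digits),
            "A+T": round_half_away(st.at_content, pct_digits),
            "AT skew": None if st.at_skew is None
            else round_half_away(st.at_skew, skew_digits),
            "GC skew": None if st.gc_skew is None
            else round_half_away(st.gc_skew, skew_digits),
        })
    return records


REPORT_COLUMNS = ["Species", "Size(bp)", "A", "T", "C", "G", "A+T", "AT skew", "GC skew"]


def write_composition_table(records: Sequence[dict], dest: IO[str]) -> None:
    """TSV writer with the canonical composition-table column order."""
    dest.write("\t".join(REPORT_COLUMNS) + "\n")
    for r in records:
        dest.write("\t".join("" if r.get(c) is None else str(r.get(c, ""))
                             for c in REPORT_COLUMNS) + "\n")
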