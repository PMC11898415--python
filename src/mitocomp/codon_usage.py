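"""Codon counting and relative synonymous codon usage (RSCU).

Protein-coding genes are extracted strand-aware from the circular molecule,
split into codons under the invertebrate mitochondrial genetic code
(AUA = Met, UGA = Trp, AGA/AGG = Ser — giving an eight-codon serine family;
stops UAA/UAG), and pooled into a 64-codon usage table.  RSCU for a codon c in
synonymous family F with counts n is

    RSCU_c = |F| * n_c / sum_{c' in F} n_{c'}

so an unbiased family has RSCU 1 for every member.  Conventions for the
bookkeeping corner cases of mitochondrial annotations:

* Truncated stop codons ("T"/"TA", completed to UAA by polyadenylation) are
  not codons and are excluded from counts and RSCU.
* Full stop codons are counted and form their own two-codon family.

Codon keys use the RNA alphabet (U, not T); DNA→RNA conversion happens at
extraction time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Sequence

from Bio.Data import CodonTable

from .model import PCG, GeneFeature, MitoError, Mitogenome

RNA_BASES = "UCAG"
ALL_CODONS = tuple(a + b + c for a in RNA_BASES for b in RNA_BASES for c in RNA_BASES)


class AmbiguousCodonWarning(UserWarning):
    pass


class InternalStopWarning(UserWarning):
    pass


@dataclass(frozen=True)
class GeneticCode:
    """A codon→amino-acid map plus its synonymous-family partition.

    ``families`` partitions all 64 codons by translated symbol; the stop
    family is keyed ``"*"``.
    """

    name: str
    forward: dict[str, str]
    families: dict[str, tuple[str, ...]]

    @classmethod
    def from_ncbi_id(cls, table_id: int) -> "GeneticCode":
        t = CodonTable.unambiguous_rna_by_id[table_id]
        forward = dict(t.forward_table)
        for stop in t.stop_codons:
            forward[stop] = "*"
        fams: dict[str, list[str]] = {}
        for codon in ALL_CODONS:
            fams.setdefault(forward[codon], []).append(codon)
        return cls(name=t.names[0], forward=forward,
                   families={aa: tuple(cs) for aa, cs in fams.items()})

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families[self.forward[codon]]


#: NCBI translation table 5.
INVERTEBRATE_MITO = GeneticCode.from_ncbi_id(5)


@dataclass
class CodonUsage:
    """Counts (and optionally RSCU) over the 64 RNA codons."""

    counts: dict[str, int] = field(default_factory=lambda: dict.fromkeys(ALL_CODONS, 0))
    rscu: Optional[dict[str, float]] = None
    n_ambiguous: int = 0

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())


@dataclass
class PcgSummary:
    """Per-gene translation bookkeeping."""

    name: str
    length: int
    start_codon: str
    stop_codon: str  # full trinucleotide, or truncated "T"/"TA"
    n_complete_codons: int

    @property
    def truncated_stop(self) -> bool:
        return len(self.stop_codon) < 3


def extract_cds(genome: Mitogenome, feat: GeneFeature,
                code: GeneticCode = INVERTEBRATE_MITO,
                ) -> tuple[list[str], PcgSummary]:
    """Split a PCG into RNA codons, strand- and wrap-aware.

    Light-strand genes are reverse-complemented before codon splitting.  A
    trailing 1–2 nt remainder is a truncated stop: it is excluded from the
    codon list and reported (as DNA, "T"/"TA") in the summary.  A stop codon
    before the final codon triggers :class:`InternalStopWarning` with its
    position.
    """
    if feat.gene_class != PCG:
        raise MitoError(f"{feat.name} is not a protein-coding gene")
    dna = genome.coding_sequence(feat)
    if len(dna) < 6:
        raise MitoError(f"{feat.name}: CDS of {len(dna)} nt is too short")
    rem = len(dna) % 3
    trailer = dna[len(dna) - rem:] if rem else ""
    rna = dna[:len(dna) - rem].replace("T", "U")
    codons = [rna[i:i + 3] for i in range(0, len(rna), 3)]
    stop_family = code.families["*"]
    for i, c in enumerate(codons[:-1]):
        if c in stop_family:
            warnings.warn(
                f"{feat.name}: internal stop codon {c} at codon {i + 1}",
                InternalStopWarning, stacklevel=2)
    summary = PcgSummary(
        name=feat.name, length=len(dna), start_codon=dna[:3],
        stop_codon=trailer if rem else dna[-3:],
        n_complete_codons=len(codons),
    )
    return codons, summary


def count_codons(cds_lists: Iterable[Sequence[str]]) -> CodonUsage:
    """Pool codon counts over one or more codon lists (stop codons included)."""
    usage = CodonUsage()
    for codons in cds_lists:
        for c in codons:
            c = c.upper().replace("T", "U")
            if c in usage.counts:
                usage.counts[c] += 1
            else:
                usage.n_ambiguous += 1
    if usage.n_ambiguous:
        warnings.warn(f"{usage.n_ambiguous} codons with ambiguity symbols excluded",
                      AmbiguousCodonWarning, stacklevel=2)
    return usage


def rscu(usage: CodonUsage, code: GeneticCode = INVERTEBRATE_MITO) -> CodonUsage:
    """Fill in RSCU values; returns the same object for chaining.

    A family observed zero times gets RSCU 0 for all members (there is no
    usage to normalise) and a warning naming the family.
    """
    values: dict[str, float] = {}
    for aa, fam in code.families.items():
        tot = sum(usage.counts[c] for c in fam)
        if tot == 0:
            warnings.warn(f"family {aa} has zero total count; RSCU set to 0",
                          AmbiguousCodonWarning, stacklevel=2)
            values.update({c: 0.0 for c in fam})
        else:
            values.update({c: len(fam) * usage.counts[c] / tot for c in fam})
    usage.rscu = values
    return usage


def format_rscu(value: float) -> str:
    """Two decimals, half away from zero, trailing zeros trimmed ("1.5", "0.85")."""
    import math
    s = f"{math.copysign(math.floor(abs(value) * 100 + 0.5) / 100, value):.2f}"
    s = s.rstrip("0").rstrip(".")
    return s or "0"


def codon_report(usage: CodonUsage, code: GeneticCode = INVERTEBRATE_MITO) -> list[dict]:
    """64 rows of codon, amino-acid letter ("*" for stops), count and RSCU."""
    if usage.rscu is None:
        raise MitoError("RSCU not computed; call rscu() first")
    return [{"Codon": c, "AA": code.forward[c], "Count": usage.counts[c],
             "RSCU": format_rscu(usage.rscu[c])} for c in ALL_CODONS]


def genome_codon_usage(genome: Mitogenome, code: GeneticCode = INVERTEBRATE_MITO,
                       ) -> tuple[CodonUsage, list[PcgSummary]]:
    """Extract all annotated PCGs, pool their codons, and compute RSCU."""
    lists, summaries = [], []
    for feat in genome.annotation.features:
        if feat.gene_class == PCG:
            codons, summary = extract_cds(genome, feat, code)
            lists.append(codons)
            summaries.append(summary)
    if not lists:
        raise MitoError("genome has no protein-coding genes")
    return rscu(count_codons(lists), code), summaries


def write_codon_table(usage: CodonUsage, dest: IO[str],
                      code: GeneticCode = INVERTEBRATE_MITO) -> None:
    dest.write("Codon\tAA\tCount\tRSCU\n")
    for row in codon_report(usage, code):
        dest.write(f"{row['Codon']}\t{row['AA']}\t{row['Count']}\t{row['RSCU']}\n")
    dest.write(f"# total_codons={usage.total_codons}\n")


def read_codon_counts(source: IO[str]) -> CodonUsage:
    """Read a codon-count TSV (columns Codon and Count; extras ignored).

    Lets downstream RSCU analysis run directly from a published codon table
    without any sequence.
    """
    usage = CodonUsage()
    header: Optional[dict[str, int]] = None
    for line in source.read().splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cells = [c.strip() for c in line.split("\t")]
        if header is None:
            header = {c.lower(): i for i, c in enumerate(cells)}
            if "codon" not in header or "count" not in header:
                raise MitoError("codon table needs Codon and Count columns")
            continue
        codon = cells[header["codon"]].upper().replace("T", "U")
        if codon not in usage.counts:
            raise MitoError(f"unknown codon {codon!r}")
        usage.counts[codon] = int(cells[header["count"]])
    if header is None:
        raise MitoError("empty codon table")
    return usage
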