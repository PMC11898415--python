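"""Domain model for annotated circular mitochondrial genomes.

A metazoan mitogenome is a circular molecule of roughly 15--17 kb carrying 13
protein-coding genes (PCGs), 22 tRNAs, 2 rRNAs and one non-coding control
region (the AT-rich region of invertebrates).  This module provides the
in-memory types for such annotations, readers/writers for the three exchange
formats used throughout the package (GenBank flat file, feature-table TSV,
FASTA), and the circular-coordinate arithmetic everything else builds on.

Conventions
-----------
* Coordinates are 1-based inclusive, as in GenBank feature tables.  The only
  half-open arithmetic happens inside the Biopython interop layer.
* Genes are transcribed from the *heavy* or the *light* strand; published
  tables usually print these as directions F and R respectively.
* At most one feature may wrap the origin of the circle; it is stored with
  ``end < start`` and placed by its start position.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import IO, Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

HEAVY = "heavy"
LIGHT = "light"

PCG = "PCG"
TRNA = "tRNA"
RRNA = "rRNA"
CONTROL_REGION = "control_region"


class MitoError(Exception):
    """Base class for this package's errors."""


class ParseError(MitoError):
    """Malformed input that cannot be interpreted."""


class ValidationError(MitoError):
    """Structurally parseable input that violates an annotation invariant."""


class AnnotationWarning(UserWarning):
    """Recoverable inconsistency in an annotation (lenient mode)."""


# ---------------------------------------------------------------------------
# Canonical gene vocabulary
# ---------------------------------------------------------------------------

PCG_NAMES = (
    "cox1", "cox2", "cox3", "atp6", "atp8",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "cytb",
)
TRNA_NAMES = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI", "trnK",
    "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR", "trnS1",
    "trnS2", "trnT", "trnV", "trnW", "trnY",
)
RRNA_NAMES = ("rrnL", "rrnS")
CR_NAME = "CR"

ALL_GENE_NAMES = PCG_NAMES + TRNA_NAMES + RRNA_NAMES + (CR_NAME,)

_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C", "gln": "Q",
    "glu": "E", "gly": "G", "his": "H", "ile": "I", "leu": "L", "lys": "K",
    "met": "M", "phe": "F", "pro": "P", "ser": "S", "thr": "T", "trp": "W",
    "tyr": "Y", "val": "V",
}

_ALIASES: dict[str, str] = {}
for _n in ALL_GENE_NAMES:
    _ALIASES[_n.lower()] = _n
_ALIASES.update({
    "coi": "cox1", "coii": "cox2", "coiii": "cox3",
    "co1": "cox1", "co2": "cox2", "co3": "cox3",
    "coxi": "cox1", "coxii": "cox2", "coxiii": "cox3",
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4L", "nd5": "nad5", "nd6": "nad6", "ndl4": "nad4L",
    "cob": "cytb", "cyt b": "cytb", "cytochrome b": "cytb",
    "atpase6": "atp6", "atpase8": "atp8", "atpase 6": "atp6", "atpase 8": "atp8",
    "12s": "rrnS", "12s rrna": "rrnS", "rrn12": "rrnS", "srrna": "rrnS",
    "s-rrna": "rrnS", "small subunit ribosomal rna": "rrnS", "12s ribosomal rna": "rrnS",
    "16s": "rrnL", "16s rrna": "rrnL", "rrn16": "rrnL", "lrrna": "rrnL",
    "l-rrna": "rrnL", "large subunit ribosomal rna": "rrnL", "16s ribosomal rna": "rrnL",
    "d-loop": "CR", "dloop": "CR", "control region": "CR",
    "at-rich region": "CR", "a+t-rich region": "CR", "at rich region": "CR",
    "tranv": "trnV",  # recurrent typo for trnV in published tables
})
# single-letter tRNA shorthand used in gene-order listings (L1/L2, S1/S2
# disambiguate the leucine and serine isoacceptors)
for _l in "ACDEFGHIKMNPQRTVWY":
    _ALIASES[_l.lower()] = "trn" + _l
for _l in ("l1", "l2", "s1", "s2"):
    _ALIASES[_l] = "trn" + _l.upper()

_TRNA_CODON_CLASS = {"uur": "trnL2", "cun": "trnL1", "agn": "trnS1", "ucn": "trnS2"}


def canonical_name(raw: str) -> Optional[str]:
    """Map a raw gene label to the canonical vocabulary, or ``None``.

    Accepts the spellings commonly found in GenBank records and published
    annotation tables: ``COI``, ``ND4L``, ``16S``, ``tRNA-Leu (UUR)``,
    single-letter tRNA shorthand, and so on.  Bare ``tRNA-Leu`` / ``tRNA-Ser``
    without an isoacceptor qualifier are ambiguous and map to ``None``.
    """
    key = raw.strip().strip("*").lower()
    key = key.replace("_", " ")
    if key in _ALIASES:
        return _ALIASES[key]
    m = re.match(r"^trna[- ]?([a-z]{3})\s*(?:\(([a-z]{3})\))?$", key)
    if m:
        aa3, codon_class = m.group(1), m.group(2)
        if codon_class and codon_class in _TRNA_CODON_CLASS:
            return _TRNA_CODON_CLASS[codon_class]
        letter = _AA3_TO_1.get(aa3)
        if letter in ("L", "S") or letter is None:
            return None  # isoacceptor ambiguity must be resolved by the caller
        return "trn" + letter
    m = re.match(r"^trn([a-z])([12])?$", key)
    if m:
        name = "trn" + m.group(1).upper() + (m.group(2) or "")
        return name if name in TRNA_NAMES else None
    return None


def gene_class_of(name: str) -> str:
    if name in PCG_NAMES:
        return PCG
    if name in TRNA_NAMES:
        return TRNA
    if name in RRNA_NAMES:
        return RRNA
    if name == CR_NAME:
        return CONTROL_REGION
    raise ValueError(f"unknown gene name {name!r}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneFeature:
    """One annotated gene on a circular molecule (one row of a feature table).

    ``end < start`` is permitted only for the single feature allowed to wrap
    the origin.  ``size`` is the nucleotide count the annotation believes;
    ``stated_size`` preserves a printed value when it disagrees with the
    coordinate span (published tables occasionally contain such rows).
    """

    name: str
    strand: str
    start: int
    end: int
    size: int = 0
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None
    stated_size: Optional[int] = None
    stated_spacer: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in (HEAVY, LIGHT):
            raise ValueError(f"strand must be {HEAVY!r} or {LIGHT!r}")
        if self.size == 0 and self.end >= self.start:
            self.size = self.end - self.start + 1

    @property
    def gene_class(self) -> str:
        return gene_class_of(self.name)

    @property
    def wraps(self) -> bool:
        return self.end < self.start


@dataclass
class IntergenicRecord:
    """Signed spacer between two circularly adjacent genes (negative = overlap)."""

    upstream: str
    downstream: str
    spacer: int


@dataclass
class MitoAnnotation:
    """Ordered gene features on a circular mitochondrial molecule."""

    molecule_length: int
    features: list[GeneFeature] = field(default_factory=list)
    taxon: str = ""
    accession: Optional[str] = None
    circular: bool = True

    def __post_init__(self) -> None:
        self.features.sort(key=lambda f: f.start)

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    def counts_by_class(self) -> dict[str, int]:
        out = {PCG: 0, TRNA: 0, RRNA: 0, CONTROL_REGION: 0}
        for f in self.features:
            out[f.gene_class] += 1
        return out

    def validate(self, strict: bool = False, complete: bool = False) -> list[str]:
        """Check annotation invariants; return warning strings.

        In strict mode the first violated invariant raises
        :class:`ValidationError`; the default lenient mode collects problems
        and emits them as :class:`AnnotationWarning`.  ``complete`` also
        enforces the full 13 PCG / 22 tRNA / 2 rRNA / 1 CR gene complement.
        """
        problems: list[str] = []
        if not self.features:
            raise ValidationError("no features")
        seen: set[str] = set()
        n_wrapping = 0
        for f in self.features:
            if f.name in seen:
                raise ValidationError(f"duplicate gene name {f.name!r}")
            seen.add(f.name)
            if f.wraps:
                n_wrapping += 1
            for pos, label in ((f.start, "start"), (f.end, "end")):
                if not 1 <= pos <= self.molecule_length:
                    problems.append(
                        f"{f.name}: {label} {pos} outside [1, {self.molecule_length}]")
            span = feature_length(f, self.molecule_length, check=False)
            if f.stated_size is not None and f.stated_size != span:
                problems.append(
                    f"{f.name}: coordinate span ({span}) != stated size ({f.stated_size})")
            if f.gene_class == TRNA and not 50 <= span <= 100:
                problems.append(f"{f.name}: tRNA span {span} outside [50, 100]")
            if f.gene_class == PCG and span < 150:
                problems.append(f"{f.name}: PCG span {span} < 150")
            if f.gene_class != PCG and (f.start_codon or f.stop_codon):
                problems.append(f"{f.name}: start/stop codon on a non-PCG feature")
        if n_wrapping > 1:
            problems.append(f"{n_wrapping} features wrap the origin (at most 1 allowed)")
        if complete:
            counts = self.counts_by_class()
            expected = {PCG: 13, TRNA: 22, RRNA: 2, CONTROL_REGION: 1}
            for cls, n in expected.items():
                if counts[cls] != n:
                    problems.append(f"expected {n} {cls} features, found {counts[cls]}")
        if problems and strict:
            raise ValidationError("; ".join(problems))
        for p in problems:
            warnings.warn(p, AnnotationWarning, stacklevel=2)
        return problems


@dataclass
class Mitogenome:
    """A circular sequence together with its annotation."""

    annotation: MitoAnnotation
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) != self.annotation.molecule_length:
            raise ValidationError(
                f"sequence length {len(self.sequence)} != molecule_length "
                f"{self.annotation.molecule_length}")

    def feature_sequence(self, feat: GeneFeature) -> str:
        """Genome-strand (heavy-strand) subsequence of a feature, wrap-aware."""
        if feat.wraps:
            return self.sequence[feat.start - 1:] + self.sequence[:feat.end]
        return self.sequence[feat.start - 1:feat.end]

    def coding_sequence(self, feat: GeneFeature) -> str:
        """Feature sequence in transcription orientation (revcomp for light)."""
        s = self.feature_sequence(feat)
        if feat.strand == LIGHT:
            s = str(Seq(s).reverse_complement())
        return s


# ---------------------------------------------------------------------------
# Coordinate arithmetic
# ---------------------------------------------------------------------------

def feature_length(feat: GeneFeature, molecule_length: int, check: bool = True) -> int:
    """Inclusive span length of a feature on a circle of ``molecule_length``."""
    if check:
        for pos in (feat.start, feat.end):
            if not 1 <= pos <= molecule_length:
                raise ValidationError(
                    f"{feat.name}: position {pos} outside [1, {molecule_length}]")
    if feat.wraps:
        return (molecule_length - feat.start + 1) + feat.end
    return feat.end - feat.start + 1


def intergenic_table(annotation: MitoAnnotation) -> list[IntergenicRecord]:
    """Signed spacers between circularly adjacent features, in start order.

    The linearisation starts at position 1; the final record wraps from the
    last feature back to the first.  ``spacer`` is
    ``downstream.start − upstream.end − 1``: zero for abutting genes,
    negative for overlaps.
    """
    feats = annotation.features
    if len(feats) < 2:
        raise ValidationError("need at least two features for an intergenic table")
    out = []
    for a, b in zip(feats, feats[1:]):
        out.append(IntergenicRecord(a.name, b.name, b.start - a.end - 1))
    last, first = feats[-1], feats[0]
    wrap_spacer = (annotation.molecule_length - last.end) + first.start - 1
    out.append(IntergenicRecord(last.name, first.name, wrap_spacer))
    return out


# ---------------------------------------------------------------------------
# Feature-table TSV
# ---------------------------------------------------------------------------

_DASHES = "–—‑−"  # en dash, em dash, non-breaking hyphen, unicode minus
_RANGE_RE = re.compile(r"^(\d+)\s*[-" + _DASHES + r"]\s*(\d+)$")


def _ascii_minus(s: str) -> str:
    for d in _DASHES:
        s = s.replace(d, "-")
    return s


def _parse_int(s: str) -> int:
    return int(_ascii_minus(s).replace(",", "").replace(" ", ""))


def _open_maybe(source: Union[str, IO[str]], mode: str = "r") -> tuple[IO[str], bool]:
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False  # type: ignore[return-value]
    return open(source, mode, encoding="utf-8"), True


def parse_feature_table(
    source: Union[str, IO[str]],
    strict: bool = False,
    molecule_length: Optional[int] = None,
    taxon: Optional[str] = None,
) -> MitoAnnotation:
    """Read a Table-2-style TSV of gene features into a :class:`MitoAnnotation`.

    The dialect has a header row with at least Gene, Direction and either a
    Location column (``start–end``, thousands separators allowed, any common
    dash) or separate Start/End columns; optional Size, IntergenicNt,
    StartCodon and StopCodon columns.  ``# key=value`` comment lines may carry
    ``molecule_length``, ``taxon`` and ``accession``.

    Published tables are not always internally consistent (a stated size that
    contradicts the coordinate span, a gene nested inside the stated control
    region).  The default lenient mode keeps such rows, records the printed
    value in ``stated_size`` and emits :class:`AnnotationWarning`; strict mode
    raises :class:`ValidationError` instead.
    """
    fh, close = _open_maybe(source)
    try:
        lines = fh.read().splitlines()
    finally:
        if close:
            fh.close()

    meta: dict[str, str] = {}
    header: Optional[list[str]] = None
    rows: list[list[str]] = []
    for line in lines:
        if not line.strip():
            continue
        if line.lstrip().startswith("#"):
            m = re.match(r"#\s*([\w.]+)\s*=\s*(.+)$", line.lstrip())
            if m:
                meta[m.group(1).lower()] = m.group(2).strip()
            continue
        cells = [c.strip() for c in line.split("\t")]
        if header is None:
            header = [re.sub(r"[\s()_-]", "", c).lower() for c in cells]
            continue
        rows.append(cells)
    if header is None or not rows:
        raise ValidationError("no features")

    def col(*names: str) -> Optional[int]:
        for n in names:
            if n in header:
                return header.index(n)
        return None

    i_gene = col("gene")
    i_dir = col("direction", "strand")
    i_loc = col("location")
    i_start = col("start")
    i_end = col("end")
    i_size = col("size", "sizebp")
    i_spacer = col("intergenicnt", "intergenicnucleotides")
    i_startc = col("startcodon")
    i_stopc = col("stopcodon")
    if i_gene is None or (i_loc is None and (i_start is None or i_end is None)):
        raise ParseError("header must contain Gene and Location (or Start/End) columns")

    feats: list[GeneFeature] = []
    pending: list[str] = []
    for cells in rows:
        def cell(i: Optional[int]) -> str:
            return cells[i] if i is not None and i < len(cells) else ""

        raw_name = cell(i_gene)
        name = canonical_name(raw_name)
        if name is None:
            msg = f"row {raw_name!r}: unmappable gene name"
            if strict:
                raise ValidationError(msg)
            pending.append(msg + "; row skipped")
            continue
        if i_loc is not None and cell(i_loc):
            m = _RANGE_RE.match(cell(i_loc).replace(",", "").replace(" ", ""))
            if not m:
                raise ParseError(f"row {raw_name!r}: malformed location {cell(i_loc)!r}")
            start, end = int(m.group(1)), int(m.group(2))
        else:
            try:
                start, end = _parse_int(cell(i_start)), _parse_int(cell(i_end))
            except ValueError as exc:
                raise ParseError(f"row {raw_name!r}: malformed coordinates") from exc
        direction = cell(i_dir).upper()
        strand = LIGHT if direction == "R" else HEAVY
        stated_size = _parse_int(cell(i_size)) if cell(i_size) else None
        stated_spacer = _parse_int(cell(i_spacer)) if cell(i_spacer) else None
        feats.append(GeneFeature(
            name=name, strand=strand, start=start, end=end,
            start_codon=cell(i_startc) or None, stop_codon=cell(i_stopc) or None,
            stated_size=stated_size, stated_spacer=stated_spacer,
        ))

    if not feats:
        raise ValidationError("no features")
    length = molecule_length or (int(meta["molecule_length"]) if "molecule_length" in meta
                                 else max(f.end for f in feats))
    for f in feats:
        f.size = feature_length(f, length, check=False)
    ann = MitoAnnotation(
        molecule_length=length, features=feats,
        taxon=taxon or meta.get("taxon", ""), accession=meta.get("accession"),
    )
    for msg in pending:
        warnings.warn(msg, AnnotationWarning, stacklevel=2)
    ann.validate(strict=strict)
    return ann


def write_feature_table(annotation: MitoAnnotation, dest: Union[str, IO[str]]) -> None:
    """Write a feature-table TSV (ASCII minus, zero spacers left blank)."""
    fh, close = _open_maybe(dest, "w")
    try:
        fh.write(f"# taxon={annotation.taxon}\n" if annotation.taxon else "")
        if annotation.accession:
            fh.write(f"# accession={annotation.accession}\n")
        fh.write(f"# molecule_length={annotation.molecule_length}\n")
        fh.write("Gene\tDirection\tLocation\tSize\tIntergenicNt\tStartCodon\tStopCodon\n")
        spacers = {r.upstream: r.spacer for r in intergenic_table(annotation)} \
            if len(annotation.features) >= 2 else {}
        for i, f in enumerate(annotation.features):
            direction = "-" if f.gene_class == CONTROL_REGION else (
                "R" if f.strand == LIGHT else "F")
            spacer = ""
            if i > 0:
                prev = annotation.features[i - 1]
                s = spacers.get(prev.name, 0)
                spacer = str(s) if s != 0 else ""
            fh.write("\t".join([
                f.name, direction, f"{f.start}-{f.end}",
                str(f.stated_size if f.stated_size is not None else f.size),
                spacer, f.start_codon or "", f.stop_codon or "",
            ]).rstrip() + "\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# GenBank / FASTA interop (Biopython boundary: 0-based half-open inside only)
# ---------------------------------------------------------------------------

_CLASS_TO_GB = {PCG: "CDS", TRNA: "tRNA", RRNA: "rRNA", CONTROL_REGION: "D-loop"}
_GB_TYPES = ("CDS", "tRNA", "rRNA", "D-loop", "misc_feature")


def parse_genbank(source: Union[str, IO[str]], strict: bool = False) -> Mitogenome:
    """Read a single-record GenBank flat file into a :class:`Mitogenome`.

    Feature names are mapped to the canonical vocabulary through the alias
    table (COI→cox1, ND5→nad5, 12S→rrnS, ...); ``complement()`` locations
    become light-strand features; a ``join()`` spanning the origin becomes the
    wrapping feature.  A CDS whose length is not a multiple of three has its
    trailing 1–2 nt recorded as a truncated stop codon ("T"/"TA", completed to
    UAA by transcript polyadenylation in vivo).  Unmappable features are
    skipped with a warning (strict mode: error).
    """
    fh, close = _open_maybe(source)
    try:
        records = list(SeqIO.parse(fh, "genbank"))
    finally:
        if close:
            fh.close()
    if len(records) != 1:
        raise ParseError(f"expected exactly one GenBank record, found {len(records)}")
    rec = records[0]
    length = len(rec.seq)
    seen_leu_ser: set[str] = set()
    feats: list[GeneFeature] = []
    for gbf in rec.features:
        if gbf.type not in _GB_TYPES:
            continue
        raw = (gbf.qualifiers.get("gene") or gbf.qualifiers.get("product") or [""])[0]
        name = canonical_name(raw)
        if name is None:
            name = _resolve_ambiguous_trna(raw, seen_leu_ser)
        if name is None:
            msg = f"feature {raw!r}: unmappable gene name"
            if strict:
                raise ValidationError(msg)
            warnings.warn(msg + "; feature skipped", AnnotationWarning, stacklevel=2)
            continue
        if name in ("trnL1", "trnL2", "trnS1", "trnS2"):
            seen_leu_ser.add(name)
        parts = gbf.location.parts
        if len(parts) > 1 and int(parts[0].start) > int(parts[-1].start):
            start, end = int(parts[0].start) + 1, int(parts[-1].end)  # origin wrap
        else:
            start, end = int(gbf.location.start) + 1, int(gbf.location.end)
        strand = LIGHT if gbf.location.strand == -1 else HEAVY
        start_codon = stop_codon = None
        if gbf.type == "CDS":
            cds = str(gbf.extract(rec.seq)).upper()
            start_codon = cds[:3]
            rem = len(cds) % 3
            stop_codon = cds[-rem:] if rem else cds[-3:]
        feats.append(GeneFeature(name=name, strand=strand, start=start, end=end,
                                 start_codon=start_codon, stop_codon=stop_codon))
    ann = MitoAnnotation(
        molecule_length=length, features=feats,
        taxon=rec.annotations.get("organism", "") or rec.description.strip(),
        accession=rec.id if rec.id and rec.id != "<unknown id>" else None,
    )
    for f in ann.features:
        f.size = feature_length(f, length, check=False)
    return Mitogenome(annotation=ann, sequence=str(rec.seq))


def _resolve_ambiguous_trna(raw: str, seen: set[str]) -> Optional[str]:
    """Assign a bare tRNA-Leu / tRNA-Ser to the first unused isoacceptor slot."""
    key = raw.strip().lower()
    for aa, slots in (("leu", ("trnL1", "trnL2")), ("ser", ("trnS1", "trnS2"))):
        if aa in key:
            for slot in slots:
                if slot not in seen:
                    warnings.warn(
                        f"feature {raw!r}: isoacceptor unspecified, assigned {slot}",
                        AnnotationWarning, stacklevel=3)
                    return slot
    return None


def write_genbank(genome: Mitogenome, dest: Union[str, IO[str]]) -> None:
    """Write a single circular-topology GenBank record."""
    ann = genome.annotation
    name = re.sub(r"\W", "", ann.accession or "SYNMITO")[:16] or "SYNMITO"
    rec = SeqRecord(
        Seq(genome.sequence), id=ann.accession or name, name=name,
        description=f"{ann.taxon} mitochondrion, complete genome".strip(),
        annotations={"molecule_type": "DNA", "topology": "circular",
                     "organism": ann.taxon, "source": ann.taxon},
    )
    L = ann.molecule_length
    for f in ann.features:
        strand = -1 if f.strand == LIGHT else 1
        if f.wraps:
            loc = CompoundLocation([
                SimpleLocation(f.start - 1, L, strand=strand),
                SimpleLocation(0, f.end, strand=strand),
            ])
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand=strand)
        rec.features.append(SeqFeature(loc, type=_CLASS_TO_GB[f.gene_class],
                                       qualifiers={"gene": [f.name]}))
    fh, close = _open_maybe(dest, "w")
    try:
        SeqIO.write(rec, fh, "genbank")
    finally:
        if close:
            fh.close()


def read_fasta(source: Union[str, IO[str]]) -> tuple[str, str]:
    """Read the first record of a FASTA file; returns (id, sequence)."""
    fh, close = _open_maybe(source)
    try:
        rec = next(SeqIO.parse(fh, "fasta"))
    except StopIteration:
        raise ParseError("empty FASTA input") from None
    finally:
        if close:
            fh.close()
    return rec.id, str(rec.seq).upper()


def write_fasta(name: str, sequence: str, dest: Union[str, IO[str]]) -> None:
    fh, close = _open_maybe(dest, "w")
    try:
        SeqIO.write(SeqRecord(Seq(sequence), id=name, description=""), fh, "fasta")
    finally:
        if close:
            fh.close()
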