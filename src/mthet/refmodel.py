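"""Reference model for the circular human mitochondrial genome.

Holds the rCRS-coordinate sequence (16,569 bases, ``m.`` numbering, 1-based
inclusive), the gene/region map, and the vertebrate mitochondrial genetic code
(translation table 2), and annotates single-nucleotide substitutions with their
gene, feature class and coding consequence.

Conventions
-----------
* Coordinates are 1-based inclusive throughout; BED (0-based half-open) is
  converted explicitly at the IO boundary.
* Regions may wrap the origin: ``start > end`` means the region crosses
  position L -> 1, as the control region does (m.16024-576).
* When annotated features overlap, the primary feature of a position is chosen
  by the precedence tRNA > rRNA > protein-coding > control (smallest-feature
  wins, the convention of mtDNA annotators); positions covered by no feature
  (short intergenic spacers) are treated as control/noncoding.
* Position 3107 is the historic rCRS placeholder ('N' in the packaged
  sequence) and is never a callable or annotatable site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data import CodonTable

from .errors import ConfigError, DataError

PLACEHOLDER_POSITION = 3107
POLYC_LABEL = "polyC"

#: vertebrate mitochondrial code (NCBI translation table 2)
MT_CODON_TABLE = CodonTable.unambiguous_dna_by_id[2]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FEATURE_CLASSES = ("tRNA", "rRNA", "protein-coding", "control")
#: lower value wins when features overlap
_PRECEDENCE = {cls: i for i, cls in enumerate(FEATURE_CLASSES)}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon under the mitochondrial code; '*' for stop."""
    if codon in MT_CODON_TABLE.stop_codons:
        return "*"
    return MT_CODON_TABLE.forward_table[codon]


@dataclass(frozen=True)
class GenomeRegion:
    """A 1-based inclusive region of a circular genome.

    ``start > end`` denotes a region wrapping the origin (L -> 1).
    """

    start: int
    end: int
    label: str
    feature_class: str = "control"
    strand: str = "+"

    def validate(self, genome_length: int) -> None:
        if not (1 <= self.start <= genome_length and 1 <= self.end <= genome_length):
            raise ConfigError(
                f"region {self.label!r} ({self.start}-{self.end}) out of bounds "
                f"for genome of length {genome_length}"
            )

    def width(self, genome_length: int) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        return (genome_length - self.start + 1) + self.end

    def contains(self, position: int, genome_length: int) -> bool:
        if self.start <= self.end:
            return self.start <= position <= self.end
        return position >= self.start or position <= self.end

    def positions(self, genome_length: int) -> Iterable[int]:
        if self.start <= self.end:
            return range(self.start, self.end + 1)
        return list(range(self.start, genome_length + 1)) + list(range(1, self.end + 1))


@dataclass(frozen=True)
class VariantAnnotation:
    gene: str
    feature_class: str
    consequence: str  # synonymous | nonsynonymous | stop-loss | stop-gain | noncoding
    in_polyC: bool
    codon_ref: str | None = None
    codon_alt: str | None = None


@dataclass
class ReferenceModel:
    """A mitochondrial reference sequence plus its gene/region map."""

    name: str
    sequence: str
    genes: list[GenomeRegion] = field(default_factory=list)
    special_regions: dict[str, GenomeRegion] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        for g in self.genes:
            g.validate(self.length)
            if g.feature_class not in FEATURE_CLASSES:
                raise ConfigError(f"unknown feature class {g.feature_class!r} for {g.label!r}")
        for r in self.special_regions.values():
            r.validate(self.length)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        if not 1 <= position <= self.length:
            raise DataError(f"position {position} outside [1, {self.length}]")
        return self.sequence[position - 1]

    @property
    def polyc_region(self) -> GenomeRegion:
        return self.special_regions[POLYC_LABEL]

    def in_polyc(self, position: int) -> bool:
        return self.polyc_region.contains(position, self.length)

    def feature_at(self, position: int) -> GenomeRegion | None:
        """Primary feature at a position under the documented precedence."""
        hits = [g for g in self.genes if g.contains(position, self.length)]
        if not hits:
            return None
        return min(hits, key=lambda g: (_PRECEDENCE[g.feature_class], g.width(self.length)))


def _parse_annotation_table(source) -> tuple[list[GenomeRegion], dict[str, GenomeRegion], int | None]:
    """Parse the tab-separated region table (start, end, label, class, strand).

    Rows of class ``special`` become named special regions. A comment line
    ``#length=N`` declares the expected genome length.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    genes: list[GenomeRegion] = []
    special: dict[str, GenomeRegion] = {}
    declared_length: int | None = None
    for lineno, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("length="):
                declared_length = int(body.split("=", 1)[1])
            continue
        parts = line.split("\t")
        if len(parts) == 1:
            parts = line.split()
        if len(parts) < 5:
            raise ConfigError(f"annotation line {lineno}: expected 5 columns, got {len(parts)}")
        start_s, end_s, label, cls, strand = parts[:5]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ConfigError(f"annotation line {lineno}: non-integer coordinates") from exc
        if strand not in "+-":
            raise ConfigError(f"annotation line {lineno}: strand must be + or -")
        region = GenomeRegion(start, end, label, cls if cls != "special" else "control", strand)
        if cls == "special":
            special[label] = region
        else:
            genes.append(region)
    return genes, special, declared_length


def load_reference(fasta_source, annotation_source) -> ReferenceModel:
    """Build a validated :class:`ReferenceModel` from a FASTA and a region table.

    The FASTA must contain exactly one record; the annotation must declare the
    poly-C special region and (if it carries a ``#length=`` line) agree with
    the sequence length.
    """
    records = list(SeqIO.parse(fasta_source, "fasta"))
    if len(records) != 1:
        raise ConfigError(f"reference FASTA must contain exactly one sequence, found {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()
    if not seq:
        raise ConfigError("reference FASTA: empty sequence")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ConfigError(f"reference FASTA: unexpected characters {sorted(bad)}")

    genes, special, declared_length = _parse_annotation_table(annotation_source)
    if declared_length is not None and declared_length != len(seq):
        raise ConfigError(
            f"annotation declares length {declared_length} but sequence has {len(seq)} bases"
        )
    if POLYC_LABEL not in special:
        raise ConfigError(f"annotation must define the mandatory {POLYC_LABEL!r} special region")
    return ReferenceModel(name=rec.id, sequence=seq, genes=genes, special_regions=special)


def load_packaged_reference() -> ReferenceModel:
    """Load the packaged synthetic rCRS stand-in with its gene map."""
    from importlib.resources import files

    data = files("mthet.data")
    import io as _io

    fasta = _io.StringIO(data.joinpath("rcrs_synthetic.fasta").read_text())
    ann = _io.StringIO(data.joinpath("rcrs_genes.tsv").read_text())
    return load_reference(fasta, ann)


def _codon_at(ref: ReferenceModel, gene: GenomeRegion, position: int, override: str | None = None):
    """Complete codon containing ``position`` in the gene's reading frame.

    Returns (codon, index_within_codon) on the coding strand, or None when the
    position falls in a trailing partial codon. ``override`` substitutes the
    base at ``position`` before strand handling.
    """
    # packaged protein-coding genes never wrap the origin
    if gene.strand == "+":
        offset = position - gene.start
    else:
        offset = gene.end - position
    codon_idx, within = divmod(offset, 3)
    if 3 * codon_idx + 3 > gene.width(ref.length):
        return None
    if gene.strand == "+":
        s = gene.start + 3 * codon_idx
        genomic = list(ref.sequence[s - 1 : s + 2])
        genomic[position - s] = override if override is not None else genomic[position - s]
        return "".join(genomic), within
    e = gene.end - 3 * codon_idx
    genomic = list(ref.sequence[e - 3 : e])
    genomic[position - (e - 2)] = override if override is not None else genomic[position - (e - 2)]
    return reverse_complement("".join(genomic)), within


def annotate_variant(
    ref_model: ReferenceModel, position: int, ref_allele: str, alt_allele: str
) -> VariantAnnotation:
    """Annotate a single-nucleotide substitution at an rCRS position.

    Gene assignment is by interval lookup under the feature precedence; coding
    consequence is computed by translating the containing codon before and
    after substitution under the vertebrate mitochondrial code, honouring the
    gene strand.
    """
    if not 1 <= position <= ref_model.length:
        raise DataError(f"position {position} outside [1, {ref_model.length}]")
    if position == PLACEHOLDER_POSITION and ref_model.base(position) == "N":
        raise DataError(
            f"position {PLACEHOLDER_POSITION} is the rCRS placeholder base and is not annotatable"
        )
    ref_allele, alt_allele = ref_allele.upper(), alt_allele.upper()
    for name, allele in (("ref", ref_allele), ("alt", alt_allele)):
        if allele not in "ACGT" or len(allele) != 1:
            raise DataError(f"{name} allele {allele!r} is not a single base (SNVs only)")
    actual = ref_model.base(position)
    if actual != ref_allele:
        raise DataError(
            f"reference mismatch at position {position}: expected {actual}, got {ref_allele}"
        )

    feature = ref_model.feature_at(position)
    in_polyc = ref_model.in_polyc(position)
    if feature is None:
        return VariantAnnotation("noncoding", "control", "noncoding", in_polyc)
    if feature.feature_class != "protein-coding":
        return VariantAnnotation(feature.label, feature.feature_class, "noncoding", in_polyc)

    got = _codon_at(ref_model, feature, position)
    if got is None:  # trailing partial codon (incomplete stop completed by polyadenylation)
        return VariantAnnotation(feature.label, "protein-coding", "noncoding", in_polyc)
    codon_ref, _ = got
    codon_alt, _ = _codon_at(ref_model, feature, position, override=alt_allele)
    aa_ref, aa_alt = translate_codon(codon_ref), translate_codon(codon_alt)
    if aa_ref == aa_alt:
        consequence = "synonymous"
    elif aa_alt == "*":
        consequence = "stop-gain"
    elif aa_ref == "*":
        consequence = "stop-loss"
    else:
        consequence = "nonsynonymous"
    return VariantAnnotation(
        feature.label, "protein-coding", consequence, in_polyc, codon_ref, codon_alt
    )


def read_bed_regions(source, genome_length: int) -> list[GenomeRegion]:
    """Read a BED file into 1-based inclusive regions (explicit 0-based half-open conversion)."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    regions = []
    for lineno, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) == 1:
            parts = line.split()
        if len(parts) < 3:
            raise DataError(f"BED line {lineno}: expected at least 3 columns")
        start0, end0 = int(parts[1]), int(parts[2])
        if not 0 <= start0 < end0 <= genome_length:
            raise DataError(f"BED line {lineno}: interval [{start0},{end0}) out of bounds")
        label = parts[3] if len(parts) > 3 else f"bed_{lineno}"
        regions.append(GenomeRegion(start0 + 1, end0, label))
    return regions
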