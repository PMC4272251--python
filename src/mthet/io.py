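"""Readers and writers for the formats the pipeline touches.

* samtools mpileup text (6-column dialect) -> per-position allele counts.
  There is no library parser for mpileup *text* (pysam pileups start from
  BAM), so the dialect is parsed here by hand.
* VCF 4.2 output through pysam, with heteroplasmy fields in INFO and filter
  flags in FILTER.
* Call-set ingestion from VCF (pysam) or plain TSV (position, ref, alt, and
  optionally v, n).

Quality handling: bases below the minimum base quality are removed from both
the counts and the usable depth, so ``n`` is always the denominator actually
used for the heteroplasmy estimate v/n. Deletion placeholders ('*') and 'N'
calls are likewise excluded from the usable counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam

from . import __version__
from .errors import DataError
from .refmodel import PLACEHOLDER_POSITION, ReferenceModel

DEFAULT_MIN_BASE_QUALITY = 20

FILTER_FLAGS = ("low_coverage", "polyC", "recurrent_artifact", "background")


@dataclass
class PileupColumn:
    """Strand-collapsed allele counts at one reference position.

    ``depth`` is the usable read count after quality filtering and equals the
    sum of the A/C/G/T counts.
    """

    position: int
    ref_base: str
    depth: int
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise DataError(f"negative depth at position {self.position}")
        if sum(self.counts.values()) > self.depth:
            raise DataError(f"counts exceed depth at position {self.position}")


@dataclass
class CallRecord:
    """A called SNV with its heteroplasmy estimate and exact 95% CI."""

    position: int
    ref: str
    alt: str
    v: int
    n: int
    vaf: float
    ci_low: float
    ci_high: float
    filter_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.n > 0 and not (0 <= self.ci_low <= self.vaf <= self.ci_high <= 1):
            raise DataError(
                f"CI bounds out of order at position {self.position}: "
                f"{self.ci_low} <= {self.vaf} <= {self.ci_high} violated"
            )


def _parse_bases(bases: str, quals: str, ref: str, min_bq: int, lineno: int) -> dict[str, int]:
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    i = 0
    qi = 0
    ref = ref.upper()
    while i < len(bases):
        c = bases[i]
        if c == "^":  # read start: '^' plus a mapping-quality byte, no base consumed
            i += 2
            continue
        if c == "$":  # read end marker
            i += 1
            continue
        if c in "+-":  # indel block: sign, length, then that many bases; SNVs only
            j = i + 1
            while j < len(bases) and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise DataError(f"pileup line {lineno}: malformed indel block")
            i = j + int(bases[i + 1 : j])
            continue
        # every remaining symbol consumes one quality byte
        if qi >= len(quals):
            raise DataError(f"pileup line {lineno}: more base symbols than quality characters")
        q = ord(quals[qi]) - 33
        qi += 1
        if q >= min_bq:
            if c in ".,":
                counts[ref] += 1
            elif c.upper() in counts:
                counts[c.upper()] += 1
            # '*', 'N'/'n', '<', '>' are excluded from usable counts
        i += 1
    if qi != len(quals):
        raise DataError(f"pileup line {lineno}: {len(quals) - qi} unconsumed quality characters")
    return counts


def read_pileup(
    source,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
    genome_length: int | None = None,
) -> Iterator[PileupColumn]:
    """Parse samtools mpileup text into :class:`PileupColumn` objects.

    Accepts a path or an iterable of lines. Lines must have the 6 mpileup
    columns (chrom, pos, ref, depth, bases, quals); a depth-0 line may omit
    the bases/quals fields.
    """
    if isinstance(source, (str, Path)):
        handle = open(source)
        close = True
    else:
        handle = source
        close = False
    try:
        for lineno, raw in enumerate(handle, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 4:
                raise DataError(f"pileup line {lineno}: expected 6 columns, got {len(parts)}")
            try:
                pos = int(parts[1])
                raw_depth = int(parts[3])
            except ValueError as exc:
                raise DataError(f"pileup line {lineno}: non-integer position or depth") from exc
            if pos < 1 or (genome_length is not None and pos > genome_length):
                raise DataError(f"pileup line {lineno}: position {pos} out of genome bounds")
            ref = parts[2].upper()
            if raw_depth == 0 or len(parts) < 6:
                counts = {"A": 0, "C": 0, "G": 0, "T": 0}
            else:
                counts = _parse_bases(parts[4], parts[5], ref, min_base_quality, lineno)
            yield PileupColumn(pos, ref, sum(counts.values()), counts)
    finally:
        if close:
            handle.close()


def _vcf_header(ref_model: ReferenceModel) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##source=mthet {__version__}")
    header.add_line(f"##reference={ref_model.name}")
    header.contigs.add("MT", length=ref_model.length)
    header.info.add("V", 1, "Integer", "Variant-supporting read count")
    header.info.add("N", 1, "Integer", "Usable total read depth at the site")
    header.info.add("VAF", 1, "Float", "Heteroplasmy point estimate v/n")
    header.info.add("CIL", 1, "Float", "Exact binomial CI lower bound")
    header.info.add("CIH", 1, "Float", "Exact binomial CI upper bound")
    header.filters.add("low_coverage", None, None, "Usable depth below the calling minimum")
    header.filters.add("polyC", None, None, "Inside the poly-C tract m.16184-16193")
    header.filters.add("recurrent_artifact", None, None, "Heteroplasmic at the same position across samples")
    header.filters.add("background", None, None, "Within the background variant-read level")
    return header


def write_vcf(records: Iterable[CallRecord], ref_model: ReferenceModel, path) -> None:
    """Write call records as VCF 4.2. Records must be sorted by position."""
    records = list(records)
    positions = [r.position for r in records]
    if positions != sorted(positions):
        raise DataError("write_vcf: records must be sorted by position")
    header = _vcf_header(ref_model)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in records:
            rec = vcf.new_record(
                contig="MT",
                start=r.position - 1,
                stop=r.position,
                alleles=(r.ref, r.alt),
            )
            rec.info["V"] = r.v
            rec.info["N"] = r.n
            rec.info["VAF"] = r.vaf
            rec.info["CIL"] = r.ci_low
            rec.info["CIH"] = r.ci_high
            if r.filter_flags:
                for f in sorted(r.filter_flags):
                    rec.filter.add(f)
            else:
                rec.filter.add("PASS")
            vcf.write(rec)


@dataclass
class CallSet:
    """Ingested call set: SNV sites with optional read counts."""

    records: list[CallRecord]
    skipped_non_snv: int = 0

    @property
    def sites(self) -> set[tuple[int, str, str]]:
        return {(r.position, r.ref, r.alt) for r in self.records}

    @property
    def positions(self) -> set[int]:
        return {r.position for r in self.records}


def _mk_record(pos: int, ref: str, alt: str, v, n, flags=()) -> CallRecord:
    from .stats import clopper_pearson

    ref, alt = ref.upper(), alt.upper()
    if pos == PLACEHOLDER_POSITION:
        raise DataError(f"position {PLACEHOLDER_POSITION} (rCRS placeholder) is not a callable site")
    if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
        raise DataError(f"non-SNV alleles {ref}>{alt} at position {pos}")
    if v is not None and n:
        ci = clopper_pearson(int(v), int(n))
        return CallRecord(pos, ref, alt, int(v), int(n), int(v) / int(n), ci.low, ci.high, set(flags))
    return CallRecord(pos, ref, alt, 0, 0, 0.0, 0.0, 0.0, set(flags))


def read_callset(path) -> CallSet:
    """Read a call set from VCF or TSV (position, ref, alt[, v, n]).

    Non-SNV records are skipped (counted); duplicate (position, alt) pairs and
    records at the rCRS placeholder position are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    is_vcf = path.suffix.lower() == ".vcf" or first.startswith("##fileformat")
    records: list[CallRecord] = []
    skipped = 0
    seen: set[tuple[int, str]] = set()

    def add(pos, ref, alt, v=None, n=None, flags=()):
        key = (pos, alt)
        if key in seen:
            raise DataError(f"duplicate call at position {pos} alt {alt}")
        seen.add(key)
        records.append(_mk_record(pos, ref, alt, v, n, flags))

    if is_vcf:
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                if rec.pos == PLACEHOLDER_POSITION:
                    raise DataError(
                        f"position {PLACEHOLDER_POSITION} (rCRS placeholder) is not a callable site"
                    )
                alts = rec.alts or ()
                if len(rec.ref) != 1 or len(alts) != 1 or len(alts[0]) != 1 or alts[0] not in "ACGT":
                    skipped += 1
                    continue
                flags = [f for f in rec.filter.keys() if f != "PASS"]
                v = rec.info.get("V")
                n = rec.info.get("N")
                add(rec.pos, rec.ref, alts[0], v, n, flags)
    else:
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) == 1:
                    parts = line.split()
                if len(parts) < 3:
                    raise DataError(f"call TSV line {lineno}: expected >= 3 columns")
                if not parts[0].lstrip("-").isdigit():
                    continue  # header row
                pos = int(parts[0])
                if pos == PLACEHOLDER_POSITION:
                    raise DataError(
                        f"position {PLACEHOLDER_POSITION} (rCRS placeholder) is not a callable site"
                    )
                ref, alt = parts[1], parts[2]
                if len(ref) != 1 or len(alt) != 1 or ref.upper() not in "ACGT" or alt.upper() not in "ACGT":
                    skipped += 1
                    continue
                v = int(parts[3]) if len(parts) > 4 else None
                n = int(parts[4]) if len(parts) > 4 else None
                add(pos, ref, alt, v, n)
    return CallSet(records=records, skipped_non_snv=skipped)


def write_coverage_tsv(depth, path, sample_id: str = "sample") -> None:
    """Write a per-position coverage profile as TSV (position, depth)."""
    with open(path, "w") as fh:
        fh.write(f"# mthet {__version__} coverage profile sample={sample_id}\n")
        fh.write("position\tdepth\n")
        for i, d in enumerate(depth, 1):
            fh.write(f"{i}\t{int(d)}\n")


def read_coverage_tsv(path):
    """Read a coverage profile TSV back into a depth array."""
    import numpy as np
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"position", "depth"} <= set(df.columns):
        raise DataError("coverage TSV must have 'position' and 'depth' columns")
    if df["position"].duplicated().any():
        raise DataError("coverage TSV has duplicate positions")
    depth = np.zeros(int(df["position"].max()), dtype=int)
    depth[df["position"].to_numpy() - 1] = df["depth"].to_numpy()
    return depth
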