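"""Coordinate and allele liftover between mitochondrial references.

Variants called against a non-rCRS mitochondrial reference (e.g. hg19's chrM)
are converted to rCRS coordinates with re-referenced alleles. The position map
is derived at run time from a global (Needleman-Wunsch) alignment of the two
sequences computed with edlib — exact, deterministic unit-cost edit-distance
alignment, which for two >95%-identical mitochondrial genomes yields the same
block structure as affine-gap scoring at a fraction of the memory. A
precomputed block table can be supplied instead.

Allele handling at a mapped position, given source_ref -> source_alt:

* target reference base == source_alt: the "variant" is a reference-strain
  difference and vanishes (dropped_ref_equals_alt);
* target reference base == source_ref: ordinary mapped variant;
* target reference differs from both: emitted against the target reference
  base with status re_referenced.

SNVs only; unmapped source positions go to the drop log, never silently away.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

import edlib

from .errors import ConfigError, DataError

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

STATUSES = ("mapped", "re_referenced", "dropped_ref_equals_alt", "dropped_unmapped")


@dataclass
class BlockMap:
    """Monotone 1-based block mapping between two sequences of the same genome."""

    source_name: str
    target_name: str
    blocks: list[tuple[int, int, int]]  # (source_start, target_start, length)
    unmapped_source: list[int]
    unmapped_target: list[int]
    source_length: int
    target_length: int

    def __post_init__(self) -> None:
        prev_s = prev_t = 0
        mapped = 0
        for s, t, ln in self.blocks:
            if s <= prev_s or t <= prev_t or ln < 1:
                raise ConfigError("block map is not strictly increasing and non-overlapping")
            prev_s, prev_t = s + ln - 1, t + ln - 1
            mapped += ln
        if mapped + len(self.unmapped_source) != self.source_length:
            raise ConfigError("block map does not cover the source genome")
        if mapped + len(self.unmapped_target) != self.target_length:
            raise ConfigError("block map does not cover the target genome")

    def lift_position(self, source_position: int) -> int | None:
        """Map a source position to the target, or None when unmapped."""
        for s, t, ln in self.blocks:
            if s <= source_position < s + ln:
                return t + (source_position - s)
        return None

    def invert(self) -> "BlockMap":
        return BlockMap(
            source_name=self.target_name,
            target_name=self.source_name,
            blocks=[(t, s, ln) for s, t, ln in self.blocks],
            unmapped_source=list(self.unmapped_target),
            unmapped_target=list(self.unmapped_source),
            source_length=self.target_length,
            target_length=self.source_length,
        )


def build_block_map(
    source_seq: str,
    target_seq: str,
    source_name: str = "source",
    target_name: str = "target",
    min_identity: float = 0.95,
) -> BlockMap:
    """Derive the block map from a global pairwise alignment of two sequences."""
    source_seq, target_seq = source_seq.upper(), target_seq.upper()
    for name, seq in ((source_name, source_seq), (target_name, target_seq)):
        if not seq:
            raise ConfigError(f"{name}: empty sequence")
        if set(seq) - set("ACGTN"):
            raise ConfigError(f"{name}: alphabet must be ACGTN")
    # N matches any base so the rCRS placeholder does not count as a mismatch
    equalities = [(("N", b)) for b in "ACGT"] + [(b, "N") for b in "ACGT"]
    aln = edlib.align(source_seq, target_seq, mode="NW", task="path",
                      additionalEqualities=equalities)
    cigar = aln["cigar"]
    if cigar is None:
        raise ConfigError("alignment failed")
    blocks: list[tuple[int, int, int]] = []
    unmapped_source: list[int] = []
    unmapped_target: list[int] = []
    s = t = 1
    for length_s, op in _CIGAR_RE.findall(cigar):
        ln = int(length_s)
        if op in "=XM":
            if blocks and blocks[-1][0] + blocks[-1][2] == s and blocks[-1][1] + blocks[-1][2] == t:
                ps, pt, pl = blocks[-1]
                blocks[-1] = (ps, pt, pl + ln)
            else:
                blocks.append((s, t, ln))
            s += ln
            t += ln
        elif op == "I":  # consumes source only: insertion relative to the target
            unmapped_source.extend(range(s, s + ln))
            s += ln
        elif op == "D":  # consumes target only
            unmapped_target.extend(range(t, t + ln))
            t += ln
    aln_len = max(len(source_seq), len(target_seq))
    identity = 1 - aln["editDistance"] / aln_len
    if identity < min_identity:
        raise ConfigError(
            f"alignment identity {identity:.3f} below the floor {min_identity}: "
            "these do not look like the same genome"
        )
    return BlockMap(
        source_name=source_name,
        target_name=target_name,
        blocks=blocks,
        unmapped_source=unmapped_source,
        unmapped_target=unmapped_target,
        source_length=len(source_seq),
        target_length=len(target_seq),
    )


@dataclass(frozen=True)
class LiftedVariant:
    source_position: int
    source_ref: str
    source_alt: str
    status: str
    target_position: int | None = None
    target_ref: str | None = None
    target_alt: str | None = None


def lift_variant(
    block_map: BlockMap,
    source_seq: str,
    target_seq: str,
    source_position: int,
    source_ref: str,
    source_alt: str,
) -> LiftedVariant:
    """Lift one SNV through the block map, re-referencing its alleles."""
    source_ref, source_alt = source_ref.upper(), source_alt.upper()
    if len(source_ref) != 1 or len(source_alt) != 1 or {source_ref, source_alt} - set("ACGT"):
        raise DataError(
            f"position {source_position}: only single-base SNVs are lifted "
            f"(got {source_ref}>{source_alt})"
        )
    if not 1 <= source_position <= block_map.source_length:
        raise DataError(f"source position {source_position} out of bounds")
    actual = source_seq[source_position - 1].upper()
    if actual != source_ref:
        raise DataError(
            f"reference mismatch at source position {source_position}: "
            f"sequence has {actual}, variant says {source_ref}"
        )
    tpos = block_map.lift_position(source_position)
    if tpos is None:
        return LiftedVariant(source_position, source_ref, source_alt, "dropped_unmapped")
    tref = target_seq[tpos - 1].upper()
    if tref == source_alt:
        return LiftedVariant(
            source_position, source_ref, source_alt, "dropped_ref_equals_alt",
            target_position=tpos, target_ref=tref,
        )
    status = "mapped" if tref == source_ref else "re_referenced"
    return LiftedVariant(
        source_position, source_ref, source_alt, status,
        target_position=tpos, target_ref=tref, target_alt=source_alt,
    )


def lift_callset(
    block_map: BlockMap, source_seq: str, target_seq: str,
    variants: Iterable[tuple[int, str, str]],
) -> tuple[list[LiftedVariant], list[LiftedVariant]]:
    """Lift many SNVs; returns (lifted, dropped) with the drop log kept."""
    lifted, dropped = [], []
    for pos, ref, alt in variants:
        lv = lift_variant(block_map, source_seq, target_seq, pos, ref, alt)
        (lifted if lv.status in ("mapped", "re_referenced") else dropped).append(lv)
    return lifted, dropped


def write_block_map(block_map: BlockMap, path) -> None:
    """Serialize a block map as chain-like TSV (source_start, target_start, length)."""
    with open(path, "w") as fh:
        fh.write(f"# block map {block_map.source_name} -> {block_map.target_name}\n")
        fh.write(f"#source_length={block_map.source_length}\n")
        fh.write(f"#target_length={block_map.target_length}\n")
        for s, t, ln in block_map.blocks:
            fh.write(f"{s}\t{t}\t{ln}\n")


def read_block_map(path, source_name: str = "source", target_name: str = "target") -> BlockMap:
    """Read a chain-like TSV block map written by :func:`write_block_map`."""
    blocks = []
    source_length = target_length = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("source_length="):
                    source_length = int(body.split("=", 1)[1])
                elif body.startswith("target_length="):
                    target_length = int(body.split("=", 1)[1])
                continue
            s, t, ln = (int(x) for x in line.split("\t"))
            blocks.append((s, t, ln))
    if source_length is None or target_length is None:
        raise ConfigError("block map file lacks source_length/target_length headers")
    mapped_s = {p for s, _t, ln in blocks for p in range(s, s + ln)}
    mapped_t = {p for _s, t, ln in blocks for p in range(t, t + ln)}
    return BlockMap(
        source_name=source_name,
        target_name=target_name,
        blocks=blocks,
        unmapped_source=sorted(set(range(1, source_length + 1)) - mapped_s),
        unmapped_target=sorted(set(range(1, target_length + 1)) - mapped_t),
        source_length=source_length,
        target_length=target_length,
    )
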