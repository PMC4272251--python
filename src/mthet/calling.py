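"""SNV calling from pileup columns.

The caller applies Varscan-style thresholds — minimum usable depth 5, minimum
variant reads 3, minimum variant allele fraction 0.10 — attaches an exact 95%
binomial confidence interval to every heteroplasmy estimate v/n, classifies
calls into background / heteroplasmic (10-90% band) / homoplasmic, and flags
cross-sample recurrent artifacts and poly-C tract calls.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import ConfigError
from .io import CallRecord, PileupColumn
from .refmodel import PLACEHOLDER_POSITION, GenomeRegion, ReferenceModel
from .stats import clopper_pearson


@dataclass(frozen=True)
class CallingThresholds:
    """Calling, classification and QC thresholds.

    Defaults: calls need >= 5 usable reads with >= 3 variant reads at >= 10%
    allele fraction; heteroplasmy is the 10-90% band; samples are screened
    for heteroplasmy only above 30-fold mean depth; 20-fold mean depth is the
    coverage-QC floor; <= 2 variant reads is background noise; a position
    heteroplasmic in >= 3 samples is a recurrent artifact.
    """

    min_total_depth: int = 5
    min_variant_reads: int = 3
    min_vaf: float = 0.10
    het_band: tuple[float, float] = (0.10, 0.90)
    het_screen_mean_depth: float = 30.0
    qc_mean_depth: float = 20.0
    background_max_reads: int = 2
    recurrent_min_samples: int = 3
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        lo, hi = self.het_band
        if not (0 < self.min_vaf <= lo <= hi < 1):
            raise ConfigError(
                f"thresholds must satisfy 0 < min_vaf <= het_band low <= high < 1; "
                f"got min_vaf={self.min_vaf}, het_band={self.het_band}"
            )
        if self.min_total_depth < 1 or self.min_variant_reads < 1:
            raise ConfigError("depth thresholds must be positive")


@dataclass
class SampleCalls:
    """Calls for one sample plus the per-site ledger of non-call flags."""

    sample_id: str
    records: list[CallRecord]
    low_coverage_positions: set[int] = field(default_factory=set)
    secondary_alleles: list[tuple[int, str, int]] = field(default_factory=list)


def call_column(column: PileupColumn, thresholds: CallingThresholds) -> CallRecord | None:
    """Call the top non-reference allele at one position, or None.

    A call is emitted iff n >= min_total_depth, v >= min_variant_reads and
    v/n >= min_vaf, where v counts the most frequent non-reference base (ties
    broken alphabetically). Absence of a call is a value, not an error.
    """
    n = column.depth
    ref = column.ref_base
    alts = {b: c for b, c in column.counts.items() if b != ref and c > 0}
    if not alts:
        return None
    # alphabetical tie-break: max over (-count, base)
    alt = min(alts, key=lambda b: (-alts[b], b))
    v = alts[alt]
    if n < thresholds.min_total_depth or v < thresholds.min_variant_reads:
        return None
    vaf = v / n
    if vaf < thresholds.min_vaf:
        return None
    ci = clopper_pearson(v, n, thresholds.ci_level)
    return CallRecord(column.position, ref, alt, v, n, vaf, ci.low, ci.high)


def classify_heteroplasmy(record: CallRecord, thresholds: CallingThresholds) -> str:
    """Classify a call as 'background', 'heteroplasmic' or 'homoplasmic'.

    Classification uses the point estimate v/n, with the CI reported as its
    uncertainty: background iff v <= background_max_reads, heteroplasmic iff
    the point estimate lies in the het band, homoplasmic otherwise.
    """
    if record.n <= 0:
        raise ConfigError("classify_heteroplasmy requires n > 0")
    if record.v <= thresholds.background_max_reads:
        return "background"
    lo, hi = thresholds.het_band
    if lo <= record.vaf <= hi:
        return "heteroplasmic"
    return "homoplasmic"


def call_sample(
    columns: Iterable[PileupColumn],
    thresholds: CallingThresholds,
    sample_id: str = "sample",
    ref_model: ReferenceModel | None = None,
    masked_positions: set[int] | None = None,
) -> SampleCalls:
    """Run the caller across a sample's pileup.

    The rCRS placeholder position and any user-masked positions are excluded
    before calling; columns below the depth minimum are recorded in the
    low-coverage ledger even when no call is made; secondary alternate
    alleles at multi-allelic columns are logged, not called.
    """
    masked = masked_positions or set()
    out = SampleCalls(sample_id=sample_id, records=[])
    for col in columns:
        if col.position == PLACEHOLDER_POSITION or col.position in masked:
            continue
        if col.depth < thresholds.min_total_depth:
            out.low_coverage_positions.add(col.position)
        rec = call_column(col, thresholds)
        if rec is None:
            continue
        others = {
            b: c
            for b, c in col.counts.items()
            if b not in (col.ref_base, rec.alt) and c >= thresholds.min_variant_reads
        }
        for b, c in sorted(others.items()):
            out.secondary_alleles.append((col.position, b, c))
        if ref_model is not None and ref_model.in_polyc(col.position):
            rec.filter_flags.add("polyC")
        out.records.append(rec)
    return out


def flag_recurrent_artifacts(
    callsets: Mapping[str, SampleCalls] | Mapping[str, list[CallRecord]],
    thresholds: CallingThresholds,
    polyc_region: GenomeRegion | None = None,
    genome_length: int | None = None,
) -> list[int]:
    """Flag positions heteroplasmic in >= recurrent_min_samples samples.

    Mutates the records in place (adding 'recurrent_artifact' in every sample
    carrying the position, and 'polyC' unconditionally inside the poly-C
    region when one is supplied). Returns the sorted artifact position list.
    """
    if len(callsets) < 2:
        raise ConfigError("recurrent-artifact flagging needs >= 2 samples")
    per_sample_records = {
        s: (c.records if isinstance(c, SampleCalls) else c) for s, c in callsets.items()
    }
    het_samples: Counter[int] = Counter()
    for records in per_sample_records.values():
        het_positions = {
            r.position for r in records if classify_heteroplasmy(r, thresholds) == "heteroplasmic"
        }
        het_samples.update(het_positions)
    artifacts = sorted(
        pos for pos, k in het_samples.items() if k >= thresholds.recurrent_min_samples
    )
    artifact_set = set(artifacts)
    for records in per_sample_records.values():
        for r in records:
            if r.position in artifact_set:
                r.filter_flags.add("recurrent_artifact")
            if polyc_region is not None and polyc_region.contains(
                r.position, genome_length or 16569
            ):
                r.filter_flags.add("polyC")
    return artifacts


def screen_sample_for_het(
    records: Iterable[CallRecord],
    coverage_profile,
    thresholds: CallingThresholds,
) -> tuple[bool, list[CallRecord]]:
    """Screen one sample for credible heteroplasmic variants.

    Samples qualify only with mean per-base depth strictly above the screen
    threshold (default 30-fold); candidates are heteroplasmic calls carrying
    no filter flag.
    """
    eligible = float(coverage_profile.mean_depth) > thresholds.het_screen_mean_depth
    if not eligible:
        return False, []
    candidates = [
        r
        for r in records
        if not r.filter_flags and classify_heteroplasmy(r, thresholds) == "heteroplasmic"
    ]
    return True, candidates
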