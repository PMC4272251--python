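"""Base-wise concordance between two call sets across a cohort.

Every (sample, base) pair is assigned exactly one category — codetected,
a_only, b_only, low_coverage or concordant_ref — so category counts always
partition n_samples x genome_length sample-bases. Error rates count
replicate-unconfirmed discordant bases over per-base denominators (optionally
after excluding regions such as the poly-C tract from every sample), and the
two platforms' rates are compared with the exact Poisson rate-ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .refmodel import GenomeRegion
from .stats import RateRatioTest, poisson_ratio_test

CATEGORIES = ("codetected", "a_only", "b_only", "low_coverage", "concordant_ref")


@dataclass
class SampleComparison:
    sample_id: str
    codetected: set[int]
    a_only: set[int]
    b_only: set[int]
    low_coverage: set[int]
    genome_length: int

    def counts(self) -> dict[str, int]:
        c = {
            "codetected": len(self.codetected),
            "a_only": len(self.a_only),
            "b_only": len(self.b_only),
            "low_coverage": len(self.low_coverage),
        }
        c["concordant_ref"] = self.genome_length - sum(c.values())
        return c


@dataclass
class ComparisonLedger:
    """Cohort-wide base-category bookkeeping for two platforms."""

    genome_length: int
    samples: list[SampleComparison] = field(default_factory=list)
    excluded_regions: list[GenomeRegion] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def total_bases(self) -> int:
        return self.n_samples * self.genome_length

    def category_totals(self) -> dict[str, int]:
        totals = dict.fromkeys(CATEGORIES, 0)
        for s in self.samples:
            for k, v in s.counts().items():
                totals[k] += v
        return totals

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"sample_id": s.sample_id, **s.counts()} for s in self.samples]
        )


def _positions(calls) -> list[int]:
    if hasattr(calls, "positions"):  # CallSet
        return sorted(calls.positions)
    out = []
    for item in calls:
        out.append(item.position if hasattr(item, "position") else int(item))
    return out


def compare_callsets(
    calls_a: Mapping[str, object],
    calls_b: Mapping[str, object],
    depth_a: Mapping[str, np.ndarray],
    genome_length: int,
    min_depth: int = 5,
) -> ComparisonLedger:
    """Compare per-sample call sets from platform A (with per-base depth) and B.

    Discordant sites at bases where the platform-A depth is below
    ``min_depth`` are reassigned to low_coverage: such bases were never
    assessable by platform A, so they measure coverage, not calling error.
    """
    if set(calls_a) != set(calls_b):
        raise DataError("compare_callsets: the two call-set collections name different samples")
    ledger = ComparisonLedger(genome_length=genome_length)
    for sample in sorted(calls_a):
        pa = _positions(calls_a[sample])
        pb = _positions(calls_b[sample])
        for name, plist in (("A", pa), ("B", pb)):
            if len(plist) != len(set(plist)):
                raise DataError(f"sample {sample}: duplicate sites in call set {name}")
            if plist and not (1 <= min(plist) and max(plist) <= genome_length):
                raise DataError(f"sample {sample}: call set {name} positions out of bounds")
        a, b = set(pa), set(pb)
        depth = np.asarray(depth_a[sample])
        if depth.size != genome_length:
            raise DataError(f"sample {sample}: depth vector length {depth.size} != {genome_length}")
        discordant = a ^ b
        low = {p for p in discordant if depth[p - 1] < min_depth}
        ledger.samples.append(
            SampleComparison(
                sample_id=sample,
                codetected=a & b,
                a_only=(a - b) - low,
                b_only=(b - a) - low,
                low_coverage=low,
                genome_length=genome_length,
            )
        )
    return ledger


@dataclass(frozen=True)
class ErrorRateReport:
    label: str
    discordant_count: int
    denominator: int
    rate: float

    @property
    def percent(self) -> float:
        return 100.0 * self.rate


def _excluded_width(regions: Sequence[GenomeRegion], genome_length: int) -> int:
    return sum(r.width(genome_length) for r in regions)


def _count_outside(sites: Iterable[tuple[str, int]], regions, genome_length: int) -> int:
    n = 0
    for _sample, pos in sites:
        if not any(r.contains(pos, genome_length) for r in regions):
            n += 1
    return n


def error_rates(
    ledger: ComparisonLedger,
    false_calls_a: Iterable[tuple[str, int]],
    false_calls_b: Iterable[tuple[str, int]],
    exclude: Sequence[GenomeRegion] = (),
) -> tuple[ErrorRateReport, ErrorRateReport, RateRatioTest | None]:
    """Per-platform false-call rates over per-base denominators, plus the exact test.

    ``false_calls_{a,b}`` are the (sample, position) discordances that failed
    replicate confirmation — confirmation status is an input, not something
    this tool can re-measure. Excluded regions shrink the denominator by
    n_samples x width and drop false calls inside them. Returns None for the
    test when there are no false calls at all (test undefined).
    """
    if ledger.total_bases == 0:
        raise ConfigError("error_rates: empty ledger")
    denominator = ledger.total_bases - ledger.n_samples * _excluded_width(exclude, ledger.genome_length)
    if denominator <= 0:
        raise ConfigError("error_rates: exclusion removes the whole denominator")
    count_a = _count_outside(false_calls_a, exclude, ledger.genome_length)
    count_b = _count_outside(false_calls_b, exclude, ledger.genome_length)
    rep_a = ErrorRateReport("A", count_a, denominator, count_a / denominator)
    rep_b = ErrorRateReport("B", count_b, denominator, count_b / denominator)
    test = None
    if count_a + count_b >= 1:
        test = poisson_ratio_test(count_a, count_b, denominator, denominator)
    return rep_a, rep_b, test


def coverage_threshold_report(
    profiles: Mapping[str, object],
    gold_sets: Mapping[str, object],
    min_depth: int = 5,
    mean_threshold: float = 20.0,
) -> pd.DataFrame:
    """Per-sample coverage QC against a gold-standard call set.

    One row per sample: mean depth, fraction of bases at or above the calling
    minimum, pass/fail at the mean-coverage threshold, and how many gold
    sites fall below the calling minimum (hence undetectable).
    """
    rows = []
    for sample in sorted(profiles):
        prof = profiles[sample]
        depth = np.asarray(prof.depth)
        gold = _positions(gold_sets[sample]) if sample in gold_sets else []
        lost = sum(1 for p in gold if depth[p - 1] < min_depth)
        rows.append(
            {
                "sample_id": sample,
                "mean_depth": float(depth.mean()),
                f"frac_ge_{min_depth}x": float((depth >= min_depth).mean()),
                "passes_mean_threshold": bool(depth.mean() >= mean_threshold),
                "gold_sites": len(gold),
                "gold_sites_lost_low_coverage": lost,
            }
        )
    return pd.DataFrame(rows)
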