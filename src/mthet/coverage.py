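"""Per-base coverage profiling and correlation with mtDNA copy number.

Mean depth is taken over every base of the genome, uncovered bases included
(so samples with coverage holes are penalised, as a per-mtDNA-base mean
should be). Correlation of mean depth against qPCR-derived relative copy
number is reported as R^2 per subgroup (tissue x capture kit x aligner),
with optional config-driven outlier exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .io import PileupColumn
from .stats import pearson

REPORTED_THRESHOLDS = (5, 20, 30)


@dataclass
class CoverageProfile:
    """Dense per-base depth over the genome for one sample."""

    sample_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if (self.depth < 0).any():
            raise DataError(f"sample {self.sample_id}: negative depths")

    @property
    def genome_length(self) -> int:
        return int(self.depth.size)

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean())

    def fraction_at_least(self, threshold: float) -> float:
        return float((self.depth >= threshold).mean())

    def summary(self) -> dict[str, float]:
        out = {"mean_depth": self.mean_depth}
        for t in REPORTED_THRESHOLDS:
            out[f"frac_ge_{t}x"] = self.fraction_at_least(t)
        return out


def profile_from_pileup(
    columns: Iterable[PileupColumn], genome_length: int, sample_id: str = "sample"
) -> CoverageProfile:
    """Build a dense coverage profile; absent positions mean depth 0."""
    depth = np.zeros(genome_length, dtype=np.int64)
    seen = np.zeros(genome_length, dtype=bool)
    for col in columns:
        if not 1 <= col.position <= genome_length:
            raise DataError(f"pileup position {col.position} out of bounds [1, {genome_length}]")
        if seen[col.position - 1]:
            raise DataError(f"duplicate pileup position {col.position}")
        seen[col.position - 1] = True
        depth[col.position - 1] = col.depth
    return CoverageProfile(sample_id=sample_id, depth=depth)


def correlate_copy_number(
    profiles: Mapping[str, CoverageProfile] | Sequence[CoverageProfile],
    copy_number_table: pd.DataFrame,
    by: Sequence[str] = (),
    max_mean_depth: float | None = None,
    max_copy_number: float | None = None,
) -> pd.DataFrame:
    """Correlate mean read depth with relative mtDNA copy number.

    ``copy_number_table`` needs columns sample_id and copy_number plus any
    grouping columns named in ``by`` (e.g. tissue, kit, aligner). Outlier
    exclusion is explicit: samples above ``max_mean_depth`` or above
    ``max_copy_number`` are dropped before any correlation. Subgroups with
    fewer than 3 matched samples are reported as skipped (NaN statistics).
    """
    if not isinstance(profiles, Mapping):
        profiles = {p.sample_id: p for p in profiles}
    tbl = copy_number_table.copy()
    required = {"sample_id", "copy_number"}
    if not required <= set(tbl.columns):
        raise DataError(f"copy-number table must have columns {sorted(required)}")
    if (tbl["copy_number"] <= 0).any():
        raise DataError("copy numbers must be positive")
    tbl = tbl[tbl["sample_id"].isin(profiles)]
    tbl["mean_depth"] = [profiles[s].mean_depth for s in tbl["sample_id"]]
    if max_mean_depth is not None:
        tbl = tbl[tbl["mean_depth"] <= max_mean_depth]
    if max_copy_number is not None:
        tbl = tbl[tbl["copy_number"] <= max_copy_number]

    groups: list[tuple[str, pd.DataFrame]] = [("all", tbl)]
    for cols_spec in by:
        cols = [c.strip() for c in (cols_spec.split(",") if isinstance(cols_spec, str) else cols_spec)]
        for key, sub in tbl.groupby(cols, sort=True):
            key = key if isinstance(key, tuple) else (key,)
            groups.append(("/".join(str(k) for k in key), sub))

    rows = []
    for label, sub in groups:
        if len(sub) < 3:
            rows.append({"group": label, "r_squared": np.nan, "p_value": np.nan,
                         "n": len(sub), "skipped": True})
            continue
        try:
            r2, p, n = pearson(sub["mean_depth"].to_numpy(), sub["copy_number"].to_numpy())
        except DataError:
            rows.append({"group": label, "r_squared": np.nan, "p_value": np.nan,
                         "n": len(sub), "skipped": True})
            continue
        rows.append({"group": label, "r_squared": r2, "p_value": p, "n": n, "skipped": False})
    return pd.DataFrame(rows)
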