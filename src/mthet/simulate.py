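"""Synthetic cohort generator.

Emulates the statistical structure of off-target mtDNA exome data so every
other module is testable without sequencing data:

* smooth per-base coverage profiles with a kit-specific shape, log-normal
  multiplicative noise, Poisson-realized integer depths, and a coverage dip
  at the light-strand replication origin;
* binomial sampling of variant reads at programmed heteroplasmy fractions
  (v ~ Binomial(depth, true fraction));
* a base-error process with an elevated error rate inside the poly-C tract;
* recurrent artifact positions shared across samples (the cross-sample false
  heteroplasmy signature);
* gold-standard call sets emulating Sanger sequencing: all true homoplasmic
  and heteroplasmic sites plus rare per-base false positives.

All randomness flows from a single integer seed through numpy SeedSequence
spawn keys — key (0,) for cohort-level draws, (1, kit_index) for kit shapes,
(2, sample_index) for each sample — so a cohort can be extended with more
samples without disturbing the earlier ones, and identical seeds reproduce
identical cohorts bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calling import CallingThresholds, call_column
from .errors import ConfigError
from .io import PileupColumn
from .refmodel import PLACEHOLDER_POSITION, GenomeRegion, ReferenceModel

_BASES = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class CoverageModel:
    """Per-kit smooth coverage shape with dips and optional NUMT-like peaks."""

    baseline_mean: float = 25.7
    lognormal_sigma: float = 0.25  # per-base multiplicative noise (mean 1)
    sample_sigma: float = 0.6  # between-sample depth scatter (mean 1)
    shape_scale: float = 0.5  # amplitude of the kit-specific smooth shape
    n_knots: int = 24
    dip_regions: list[tuple[GenomeRegion, float]] = field(
        default_factory=lambda: [(GenomeRegion(5721, 5798, "OriL"), 0.35)]
    )
    numt_regions: list[tuple[GenomeRegion, float]] = field(default_factory=list)


@dataclass
class ErrorModel:
    rate: float = 1e-3
    polyc_multiplier: float = 20.0


@dataclass
class VariantModel:
    homoplasmic_per_sample: int = 25
    heteroplasmic_per_sample: int = 2
    het_vaf_range: tuple[float, float] = (0.10, 0.90)
    shared_heteroplasmic_sites: list[tuple[int, float]] = field(default_factory=list)
    n_artifact_positions: int = 9
    artifact_positions: list[int] | None = None
    artifact_vaf_range: tuple[float, float] = (0.12, 0.35)
    sanger_fp_rate: float = 1.3e-5  # per base, the Sanger false-positive rate


@dataclass
class SimConfig:
    reference: ReferenceModel
    seed: int = 0
    n_samples: int = 46
    kits: tuple[str, ...] = ("sureselect-50mb", "truseq-62mb", "seqcap-v2")
    coverage: CoverageModel = field(default_factory=CoverageModel)
    error: ErrorModel = field(default_factory=ErrorModel)
    variants: VariantModel = field(default_factory=VariantModel)

    def __post_init__(self) -> None:
        L = self.reference.length
        if not 0 <= self.error.rate <= 1:
            raise ConfigError("error rate must be in [0, 1]")
        for region, m in self.coverage.dip_regions:
            region.validate(L)
            if not 0 < m <= 1:
                raise ConfigError("dip multipliers must be in (0, 1]")
        for pos, vaf in self.variants.shared_heteroplasmic_sites:
            if not 1 <= pos <= L:
                raise ConfigError(f"heteroplasmic site {pos} outside the genome")
            if not 0 <= vaf <= 1:
                raise ConfigError("true fractions must be in [0, 1]")
        if self.variants.artifact_positions is not None:
            for pos in self.variants.artifact_positions:
                if not 1 <= pos <= L:
                    raise ConfigError(f"artifact position {pos} outside the genome")


@dataclass
class SimSample:
    sample_id: str
    kit: str
    depth: np.ndarray  # usable per-base depth
    counts: np.ndarray  # 4 x L, rows A/C/G/T
    truth: pd.DataFrame
    gold: list[tuple[int, str, str]]
    gold_false: list[tuple[int, str, str]]

    def pileup_columns(self, ref_seq: str):
        for i in np.flatnonzero(self.depth > 0):
            pos = int(i) + 1
            c = self.counts[:, i]
            yield PileupColumn(
                pos, ref_seq[i], int(c.sum()), {b: int(c[j]) for j, b in enumerate("ACGT")}
            )

    def to_mpileup(self, ref_seq: str, chrom: str = "MT") -> str:
        lines = []
        for i in range(self.depth.size):
            d = int(self.depth[i])
            if d == 0:
                continue
            ref = ref_seq[i]
            if ref == "N":
                bases = "N" * d
            else:
                parts = []
                for j, b in enumerate("ACGT"):
                    c = int(self.counts[j, i])
                    if c == 0:
                        continue
                    parts.append("." * c if b == ref else b * c)
                bases = "".join(parts)
            lines.append(f"{chrom}\t{i + 1}\t{ref}\t{d}\t{bases}\t{'I' * d}")
        return "\n".join(lines) + "\n"


@dataclass
class SimCohort:
    config: SimConfig
    samples: list[SimSample]
    artifact_positions: list[int]

    @property
    def truth(self) -> pd.DataFrame:
        return pd.concat([s.truth for s in self.samples], ignore_index=True)

    def gold_sets(self) -> dict[str, list[tuple[int, str, str]]]:
        return {s.sample_id: s.gold for s in self.samples}


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _kit_shape(config: SimConfig, kit_index: int) -> np.ndarray:
    """Smooth positive per-base shape with mean 1, fixed per kit."""
    L = config.reference.length
    cov = config.coverage
    rng = _rng(config.seed, 1, kit_index)
    # periodic piecewise-linear curve over the circular genome
    knots_x = np.linspace(0, L, cov.n_knots + 1)
    knots_y = rng.normal(0.0, 1.0, cov.n_knots + 1)
    knots_y[-1] = knots_y[0]
    curve = np.interp(np.arange(L), knots_x, knots_y)
    shape = np.exp(cov.shape_scale * curve)
    return shape / shape.mean()


def _adjustment(config: SimConfig, kit_index: int) -> np.ndarray:
    L = config.reference.length
    adj = _kit_shape(config, kit_index)
    mult = np.ones(L)
    for region, m in config.coverage.dip_regions + config.coverage.numt_regions:
        idx = np.fromiter(region.positions(L), dtype=int) - 1
        mult[idx] *= m
    return adj * mult


def _draw_alt(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in "ACGT" if b != ref]
    return choices[rng.integers(len(choices))]


def simulate_cohort(config: SimConfig) -> SimCohort:
    """Generate the cohort: per-sample counts, truth table and gold call sets."""
    ref = config.reference
    L = ref.length
    seq = ref.sequence
    cohort_rng = _rng(config.seed, 0)

    callable_pos = np.array(
        [p for p in range(1, L + 1) if seq[p - 1] != "N"], dtype=int
    )
    vm = config.variants
    if vm.artifact_positions is not None:
        artifacts = sorted(vm.artifact_positions)
    else:
        artifacts = sorted(
            cohort_rng.choice(callable_pos, size=vm.n_artifact_positions, replace=False).tolist()
        )
    artifact_alts = {p: _draw_alt(cohort_rng, seq[p - 1]) for p in artifacts}

    err_rate = np.full(L, config.error.rate)
    polyc = ref.special_regions.get("polyC")
    if polyc is not None:
        idx = np.fromiter(polyc.positions(L), dtype=int) - 1
        err_rate[idx] = np.minimum(1.0, err_rate[idx] * config.error.polyc_multiplier)
    ref_is_base = np.array([b in _BASE_INDEX for b in seq])
    err_rate[~ref_is_base] = 0.0  # no substitution calls on the placeholder base

    adjustments = {k: _adjustment(config, i) for i, k in enumerate(config.kits)}

    samples = []
    for i in range(config.n_samples):
        rng = _rng(config.seed, 2, i)
        kit = config.kits[i % len(config.kits)]
        sample_id = f"S{i + 1:02d}"

        # ---- depth process
        scale = 1.0
        if config.coverage.sample_sigma > 0:
            s = config.coverage.sample_sigma
            scale = float(rng.lognormal(-s * s / 2, s))
        mu = config.coverage.baseline_mean * scale * adjustments[kit]
        if config.coverage.lognormal_sigma > 0:
            s = config.coverage.lognormal_sigma
            mu = mu * rng.lognormal(-s * s / 2, s, L)
        depth = rng.poisson(mu)

        # ---- programmed variants
        vaf = np.zeros(L)
        alt_idx = np.zeros(L, dtype=int)
        truth_rows = []

        def program(pos: int, frac: float, alt: str, kind: str) -> None:
            vaf[pos - 1] = frac
            alt_idx[pos - 1] = _BASE_INDEX[alt]
            truth_rows.append(
                {"sample_id": sample_id, "position": pos, "ref": seq[pos - 1],
                 "alt": alt, "true_vaf": frac, "kind": kind}
            )

        taken = set(artifacts) | {PLACEHOLDER_POSITION}
        free = np.array([p for p in callable_pos if p not in taken])
        chosen = rng.choice(free, size=vm.homoplasmic_per_sample + vm.heteroplasmic_per_sample,
                            replace=False)
        homo = sorted(int(p) for p in chosen[: vm.homoplasmic_per_sample])
        het_rand = sorted(int(p) for p in chosen[vm.homoplasmic_per_sample :])
        for p in homo:
            program(p, 1.0, _draw_alt(rng, seq[p - 1]), "homoplasmic")
        lo, hi = vm.het_vaf_range
        for p in het_rand:
            program(p, float(rng.uniform(lo, hi)), _draw_alt(rng, seq[p - 1]), "heteroplasmic")
        for p, frac in vm.shared_heteroplasmic_sites:
            program(p, frac, _draw_alt(rng, seq[p - 1]), "heteroplasmic")
        alo, ahi = vm.artifact_vaf_range
        for p in artifacts:
            program(p, float(rng.uniform(alo, ahi)), artifact_alts[p], "artifact")

        # ---- read sampling: variant reads, then errors among the rest
        v = rng.binomial(depth, vaf)
        e = rng.binomial(depth - v, err_rate)
        counts = np.zeros((4, L), dtype=np.int64)
        ref_idx = np.array([_BASE_INDEX.get(b, -1) for b in seq])
        valid = ref_idx >= 0
        counts[ref_idx[valid], np.flatnonzero(valid)] = (depth - v - e)[valid]
        var_sites = np.flatnonzero(v > 0)
        counts[alt_idx[var_sites], var_sites] += v[var_sites]
        for j in np.flatnonzero(e > 0):
            others = [k for k in range(4) if k != ref_idx[j]]
            split = rng.multinomial(e[j], [1 / 3] * 3)
            for k, c in zip(others, split):
                counts[k, j] += c
        depth_usable = counts.sum(axis=0)

        # ---- gold standard (Sanger-like): truth sites plus rare false positives
        gold = [(r["position"], r["ref"], r["alt"]) for r in truth_rows
                if r["kind"] in ("homoplasmic", "heteroplasmic")]
        n_fp = rng.binomial(L, vm.sanger_fp_rate)
        gold_false = []
        if n_fp:
            used = {g[0] for g in gold} | taken
            pool = np.array([p for p in callable_pos if p not in used])
            for p in rng.choice(pool, size=min(n_fp, pool.size), replace=False):
                p = int(p)
                gold_false.append((p, seq[p - 1], _draw_alt(rng, seq[p - 1])))
        gold_all = sorted(gold + gold_false)

        truth = pd.DataFrame(
            truth_rows, columns=["sample_id", "position", "ref", "alt", "true_vaf", "kind"]
        ).sort_values("position", ignore_index=True)
        samples.append(
            SimSample(sample_id, kit, depth_usable, counts, truth, gold_all, sorted(gold_false))
        )
    return SimCohort(config=config, samples=samples, artifact_positions=artifacts)


def write_cohort(cohort: SimCohort, out_dir) -> None:
    """Write per-sample mpileup text, truth TSV and gold-standard TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seq = cohort.config.reference.sequence
    for s in cohort.samples:
        (out / f"{s.sample_id}.pileup").write_text(s.to_mpileup(seq))
        with open(out / f"{s.sample_id}.gold.tsv", "w") as fh:
            for pos, ref, alt in s.gold:
                fh.write(f"{pos}\t{ref}\t{alt}\n")
    cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    with open(out / "artifact_positions.tsv", "w") as fh:
        for p in cohort.artifact_positions:
            fh.write(f"{p}\n")


def recovery_experiment(
    thresholds: CallingThresholds,
    vaf_grid: Sequence[float] = (0.10, 0.20, 0.35, 0.50, 0.75, 0.90),
    depth_grid: Sequence[int] = (10, 20, 30, 50, 100),
    n_sites: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Detection and CI-coverage rates over a (true fraction x depth) grid.

    Simulates ``n_sites`` independent sites per cell (v ~ Binomial(depth,
    true fraction), reference A, variant G), runs the caller on each, and
    reports per cell the detection rate and, among detected sites, how often
    the exact 95% CI covers the true fraction.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(3,)))
    rows = []
    for true_vaf in vaf_grid:
        for depth in depth_grid:
            vs = rng.binomial(depth, true_vaf, size=n_sites)
            detected = 0
            covered = 0
            for v in vs:
                col = PileupColumn(100, "A", int(depth), {"A": int(depth - v), "C": 0,
                                                          "G": int(v), "T": 0})
                rec = call_column(col, thresholds)
                if rec is not None and rec.alt == "G":
                    detected += 1
                    if rec.ci_low <= true_vaf <= rec.ci_high:
                        covered += 1
            rows.append(
                {
                    "true_vaf": true_vaf,
                    "depth": depth,
                    "n_sites": n_sites,
                    "detection_rate": detected / n_sites,
                    "ci_coverage": covered / detected if detected else np.nan,
                    "n_detected": detected,
                }
            )
    return pd.DataFrame(rows)
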