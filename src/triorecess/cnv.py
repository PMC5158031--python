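"""Depth-of-coverage CNV screening against a reference sample pool.

Exome read depth at each capture target is roughly proportional to copy
number once library size is normalized out. Each sample is first validated
against the pool (Pearson correlation of its depth vector with the
per-target pool median must exceed a gate, default 0.97 — a poorly
correlated sample cannot be scored); then every target receives a copy
score, the double-normalized depth ratio whose diploid expectation is 1.0
(~0.5 for a heterozygous deletion, ~1.5 for a heterozygous duplication).
Targets with score <= 0.5 or >= 1.5 are flagged, and flags overlapping
common population CNVs (frequency > 0.005) are excluded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import PipelineConfig

logger = logging.getLogger(__name__)

#: A capture target: (chromosome, start, end), 0-based half-open.
Target = tuple[str, int, int]


@dataclass
class DepthProfile:
    """Mean read depth per capture target for one sample."""

    sample_id: str
    targets: Sequence[Target]
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if len(self.targets) != self.depths.shape[0]:
            raise ValueError("targets and depths differ in length")
        if np.any(self.depths < 0):
            raise ValueError("depths must be non-negative")

    def __len__(self) -> int:
        return len(self.targets)

    @property
    def target_lengths(self) -> np.ndarray:
        return np.array([e - s for _, s, e in self.targets], dtype=float)


@dataclass(frozen=True)
class CnvCall:
    target: Target
    score: float
    call: str  # "deletion" | "duplication"
    population_freq: Optional[float] = None


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    valid: bool


def _check_shared_targets(sample: DepthProfile, pool: Sequence[DepthProfile]) -> None:
    if not pool:
        raise ValueError("reference pool must be non-empty")
    for p in pool:
        if list(p.targets) != list(sample.targets):
            raise ValueError(
                f"pool sample {p.sample_id} has a different target list"
            )


def pool_median(pool: Sequence[DepthProfile]) -> np.ndarray:
    """Per-target median depth across the reference pool (robust to CNVs
    carried by individual pool members)."""
    return np.median(np.vstack([p.depths for p in pool]), axis=0)


def reference_correlation(
    sample: DepthProfile,
    pool: Sequence[DepthProfile],
    corr_min: float = 0.97,
) -> CorrelationResult:
    """Pearson correlation of the sample against the pool median.

    The comparison is valid iff r > ``corr_min``. A zero-variance depth
    vector has undefined correlation and is reported invalid (r = nan).
    """
    _check_shared_targets(sample, pool)
    ref = pool_median(pool)
    if np.std(sample.depths) == 0.0 or np.std(ref) == 0.0:
        return CorrelationResult(r=float("nan"), valid=False)
    r = float(np.corrcoef(sample.depths, ref)[0, 1])
    return CorrelationResult(r=r, valid=r > corr_min)


def copy_score(sample: DepthProfile, pool: Sequence[DepthProfile]) -> np.ndarray:
    """Per-target copy score: the double-normalized depth ratio.

    score_t = (sample_t / sum(sample)) / (median_t / sum(median)), so a
    diploid target scores ~1.0 regardless of library size. Targets where
    the pool median is zero are undefined (nan) and excluded from calling.
    """
    _check_shared_targets(sample, pool)
    ref = pool_median(pool)
    s_total = sample.depths.sum()
    r_total = ref.sum()
    if s_total == 0 or r_total == 0:
        raise ValueError("cannot score an all-zero depth profile")
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = (sample.depths / s_total) / (ref / r_total)
    undefined = ref == 0
    if undefined.any():
        logger.warning(
            "%d targets with zero pool-median depth excluded from CNV scoring",
            int(undefined.sum()),
        )
        scores = np.where(undefined, np.nan, scores)
    return scores


def call_cnv(
    scores: np.ndarray,
    targets: Sequence[Target],
    config: Optional[PipelineConfig] = None,
) -> list[CnvCall]:
    """Flag targets with score <= deletion threshold or >= duplication
    threshold (both inclusive, defaults 0.5 and 1.5)."""
    config = config or PipelineConfig()
    if len(scores) != len(targets):
        raise ValueError("scores and targets differ in length")
    calls: list[CnvCall] = []
    for t, s in zip(targets, scores):
        if math.isnan(s):
            continue
        if s <= config.cnv_del_threshold:
            calls.append(CnvCall(target=t, score=float(s), call="deletion"))
        elif s >= config.cnv_dup_threshold:
            calls.append(CnvCall(target=t, score=float(s), call="duplication"))
    return calls


#: Population CNV row: (chromosome, start, end, frequency), 0-based half-open.
PopulationCnv = tuple[str, int, int, float]


def _overlaps(a: Target, b: tuple[str, int, int]) -> bool:
    return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]


def filter_common_cnv(
    calls: Iterable[CnvCall],
    population_table: Sequence[PopulationCnv],
    max_freq: float = 0.005,
) -> list[CnvCall]:
    """Drop calls overlapping a population CNV with frequency > ``max_freq``.

    Calls overlapping only rare or unannotated population CNVs are kept,
    annotated with the highest overlapping frequency when one exists.
    """
    kept: list[CnvCall] = []
    for call in calls:
        freqs = [
            f
            for chrom, s, e, f in population_table
            if _overlaps(call.target, (chrom, s, e))
        ]
        top = max(freqs) if freqs else None
        if top is not None and top > max_freq:
            continue
        kept.append(
            CnvCall(
                target=call.target,
                score=call.score,
                call=call.call,
                population_freq=top,
            )
        )
    return kept


def depth_qc_summary(
    profile: DepthProfile, thresholds: Sequence[int] = (10, 25)
) -> dict:
    """Length-weighted coverage QC for one sample.

    Returns the fraction of targeted bases at or above each depth threshold
    and the length-weighted mean depth (a target's mean depth is taken to
    apply to all its bases). Empty profiles have no defined QC.
    """
    if len(profile) == 0:
        raise ValueError("QC undefined for an empty depth profile")
    lengths = profile.target_lengths
    total = lengths.sum()
    if total == 0:
        raise ValueError("QC undefined: all targets have zero length")
    fractions = {
        int(t): float(lengths[profile.depths >= t].sum() / total) for t in thresholds
    }
    return {
        "mean_depth": float((profile.depths * lengths).sum() / total),
        "fraction_ge": fractions,
    }
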