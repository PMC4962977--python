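"""Per-stage sequencing-run summaries.

Reproduces the arithmetic of a standard run-summary table: per-run raw read
counts (in millions), their per-stage totals, mapped read counts, mapped
percentage against the stage total, and uniquely mapped counts.  Derived
cells are rounded half-up at one decimal, the presentation convention of such
tables.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import pandas as pd
import pysam

from .io_formats import UniquenessPolicy


def _round1(x: float) -> float:
    """Half-up rounding at one decimal (3.25 -> 3.3), unlike banker's round."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def total_reads(per_run: Sequence[float]) -> float:
    """Sum of per-run read counts (millions), reported at one decimal."""
    if len(per_run) == 0:
        raise ValueError("at least one run is required")
    if any(x < 0 for x in per_run):
        raise ValueError("read counts must be non-negative")
    return _round1(float(sum(per_run)))


def mapped_pct(mapped: float, total: float) -> float:
    """Mapped reads as a percentage of the stage total, one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= mapped <= total:
        raise ValueError("mapped must lie in [0, total]")
    return _round1(100.0 * mapped / total)


@dataclass
class StageSummary:
    """One stage's row set of the summary table (all counts in millions)."""

    stage: str
    per_run_reads: list[float]
    mapped_reads: float
    unique_reads: float

    @property
    def total_reads(self) -> float:
        return total_reads(self.per_run_reads)

    @property
    def mapped_pct(self) -> float:
        return mapped_pct(self.mapped_reads, self.total_reads)

    def validate(self) -> None:
        if not self.unique_reads <= self.mapped_reads <= self.total_reads:
            raise ValueError(
                f"{self.stage}: expected unique <= mapped <= total reads"
            )


def summarize_bam(path: str | os.PathLike, stage: str,
                  policy: Optional[UniquenessPolicy] = None) -> StageSummary:
    """Count total / mapped / uniquely mapped primary records of one BAM.

    Counts are converted to millions to match the table convention; the
    uniqueness policy mirrors the discovery side (NH tag, else MAPQ).
    """
    policy = policy or UniquenessPolicy()
    n_total = n_mapped = n_unique = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            n_total += 1
            if rec.is_unmapped:
                continue
            n_mapped += 1
            if policy.accepts(rec):
                n_unique += 1
    return StageSummary(
        stage=stage,
        per_run_reads=[n_total / 1e6],
        mapped_reads=n_mapped / 1e6,
        unique_reads=n_unique / 1e6,
    )


def summary_table(stages: Sequence[StageSummary]) -> pd.DataFrame:
    """Assemble the per-stage table with derived total and percentage rows."""
    for s in stages:
        s.validate()
    return pd.DataFrame(
        {
            s.stage: {
                **{
                    f"run{i + 1}_reads": r
                    for i, r in enumerate(s.per_run_reads)
                },
                "total_reads": s.total_reads,
                "mapped_reads": s.mapped_reads,
                "mapped_pct": s.mapped_pct,
                "unique_reads": s.unique_reads,
            }
            for s in stages
        }
    )


def recompute_from_table(path: str | os.PathLike) -> pd.DataFrame:
    """Recompute derived cells (totals, percentages) from the raw cells of a
    TSV whose rows are run1_reads.., mapped_reads, unique_reads per stage."""
    raw = pd.read_csv(path, sep="\t", index_col=0)
    stages = []
    for stage in raw.columns:
        col = raw[stage]
        runs = [col[i] for i in col.index if i.startswith("run")]
        stages.append(
            StageSummary(
                stage=stage,
                per_run_reads=runs,
                mapped_reads=float(col["mapped_reads"]),
                unique_reads=float(col["unique_reads"]),
            )
        )
    return summary_table(stages)
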