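"""Expression profiling of called NTRs across developmental stages.

Expression is quantified as FPKM — fragments per kilobase of transcript per
million mapped reads — computed directly from read counts, the call's merged
exonic length and the stage's mapped-read library size:

    FPKM = count / ((exonic_length / 1e3) * (library_size / 1e6))

Fold changes are taken against a baseline stage (the earliest stage in the
zebrafish setting, 1-cell); rows whose baseline FPKM is zero are flagged as
undefined rather than reported as infinite ratios.  Per-row z-scaling
(subtract the row mean, divide by the row standard deviation) prepares
profiles for heatmap-style clustering across stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .discovery import NTRCall
from .io_formats import AlignedRead


@dataclass
class ExpressionMatrix:
    """FPKM values (rows: NTR ids, columns: ordered stage labels) together
    with per-stage mapped-read library sizes."""

    fpkm: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        if list(self.fpkm.columns) != list(self.library_sizes.index):
            raise ValueError("one library size per stage column is required")
        if (self.fpkm.values < 0).any():
            raise ValueError("FPKM values must be non-negative")

    @property
    def stages(self) -> list[str]:
        return list(self.fpkm.columns)


def count_reads(call: NTRCall, alignments: Iterable[AlignedRead]) -> int:
    """Reads whose span overlaps the call span by >= 1 bp on the same strand."""
    span = call.span
    n = 0
    for r in alignments:
        iv = r.interval
        if iv.strand == span.strand and iv.overlaps(span):
            n += 1
    return n


def fpkm(count: int, exonic_length: int, library_size: int) -> float:
    if exonic_length <= 0:
        raise ValueError("exonic_length must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return count / ((exonic_length / 1e3) * (library_size / 1e6))


def expression_matrix(
    calls: Sequence[NTRCall],
    stage_alignments: dict[str, Sequence[AlignedRead]],
) -> ExpressionMatrix:
    """FPKM matrix over stages; library size = mapped reads in each stage."""
    sizes = pd.Series(
        {stage: len(reads) for stage, reads in stage_alignments.items()}
    )
    values = {
        stage: [
            fpkm(count_reads(c, reads), c.exonic_length, max(len(reads), 1))
            for c in calls
        ]
        for stage, reads in stage_alignments.items()
    }
    frame = pd.DataFrame(values, index=[c.ntr_id for c in calls])
    return ExpressionMatrix(fpkm=frame, library_sizes=sizes)


def fold_change(
    matrix: ExpressionMatrix, baseline_stage: str
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-row ratios against the baseline stage.

    Returns (ratios, undefined): rows with baseline FPKM 0 carry NaN ratios
    and are flagged True in ``undefined`` — never reported as infinities.
    """
    if baseline_stage not in matrix.fpkm.columns:
        raise KeyError(f"unknown baseline stage {baseline_stage!r}")
    base = matrix.fpkm[baseline_stage]
    undefined = base == 0
    ratios = matrix.fpkm.div(base.where(~undefined), axis=0)
    ratios[undefined] = np.nan
    return ratios, undefined


def scale_rows(matrix: ExpressionMatrix, ddof: int = 1) -> pd.DataFrame:
    """Row-wise z-scaling; constant rows map to all-zero rows.

    The sample standard deviation (n-1 denominator) is the default,
    matching the scaling convention of R's heatmap utilities.
    """
    if matrix.fpkm.shape[1] < 2:
        raise ValueError("row scaling needs at least two stage columns")
    values = matrix.fpkm.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (values - mean) / sd
    scaled[np.repeat(sd == 0, values.shape[1], axis=1)] = 0.0
    return pd.DataFrame(scaled, index=matrix.fpkm.index, columns=matrix.fpkm.columns)


PROFILE_CLASSES = ("maternal_decay", "post_mbt_up", "mbt_peak", "low_flat", "other")


def classify_profile(
    row: Sequence[float], low_threshold: float = 1.0, tolerance: float = 0.10
) -> str:
    """Classify a four-stage FPKM profile (1-cell, 16-cell, 512-cell/MBT,
    post-MBT) into one of the qualitative developmental patterns.

    Rules, applied in priority order:
      post_mbt_up    final stage exceeds the MBT (third) stage;
      mbt_peak       third stage is the strict maximum;
      maternal_decay first stage is the strict maximum and the profile is
                     non-increasing within a relative tolerance;
      low_flat       all values below ``low_threshold`` with relative range
                     below tolerance;
      other          anything else.
    """
    v = [float(x) for x in row]
    if len(v) != 4:
        raise ValueError("exactly 4 ordered stages are required")
    if any(x < 0 for x in v):
        raise ValueError("FPKM values must be non-negative")
    if v[3] > v[2]:
        return "post_mbt_up"
    if v[2] > max(v[0], v[1], v[3]):
        return "mbt_peak"
    non_increasing = all(v[i + 1] <= v[i] * (1 + tolerance) for i in range(3))
    if v[0] > max(v[1:]) and non_increasing:
        return "maternal_decay"
    vmax, vmin = max(v), min(v)
    if vmax < low_threshold and (vmax - vmin) <= tolerance * max(vmax, 1e-300):
        return "low_flat"
    return "other"


def classify_matrix(
    matrix: ExpressionMatrix, low_threshold: float = 1.0, tolerance: float = 0.10
) -> pd.Series:
    return pd.Series(
        {
            ntr: classify_profile(matrix.fpkm.loc[ntr], low_threshold, tolerance)
            for ntr in matrix.fpkm.index
        },
        dtype="object",
    )
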