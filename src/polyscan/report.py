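"""Normalisation, orientation asymmetry, spike-in bias calibration and TPM.

Pattern-containing read counts are normalised per million filtered reads
(count / total_filtered_reads * 1e6). The dA10->dT10 vs dT10->dA10 orientation
contrast is summarised as a Haldane-Anscombe-corrected ratio. The spike-in
capture bias beta is estimated from a two-species design as the observed
dA:dT read-count ratio divided by the molar input ratio, and a corrected
count table divides dA-derived classes by beta_hat. TPM follows the standard
length-then-depth normalisation: counts divided by feature length, rescaled
to one million per sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import SpikeInDesign

__all__ = [
    "CountsSummary",
    "BiasEstimate",
    "CorrectedCounts",
    "ExpressionRecord",
    "normalize_counts",
    "orientation_asymmetry",
    "estimate_capture_bias",
    "correct_counts",
    "tpm",
    "compare_conditions",
]

# classes divided by beta_hat in correct_counts: homopolymer_A plus the chimera
# classes, whose captured molecule carries a dA block
DA_CLASSES = ("homopolymer_A", "chimera_AT", "chimera_TA")

LOG2FC_PSEUDOCOUNT = 0.1  # per-million pseudocount for fold changes


def normalize_counts(
    class_counts: Mapping[str, int], total_filtered_reads: int
) -> dict[str, float]:
    """Reads-per-million-filtered-reads for each pattern class.

    Computed with exact rational arithmetic before conversion to float.
    """
    if total_filtered_reads < 1:
        raise ValueError("total_filtered_reads must be >= 1")
    return {
        cls: float(Fraction(int(count) * 10**6, total_filtered_reads))
        for cls, count in class_counts.items()
    }


@dataclass
class CountsSummary:
    """Per-sample totals and their per-million normalisations."""

    sample_id: str
    total_filtered_reads: int
    unmapped_reads: int
    class_counts: dict[str, int]
    class_per_million: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.unmapped_reads > self.total_filtered_reads:
            raise ValueError("unmapped_reads cannot exceed total_filtered_reads")
        if not self.class_per_million:
            self.class_per_million = normalize_counts(
                self.class_counts, self.total_filtered_reads
            )

    @property
    def chimera_AT(self) -> int:
        return self.class_counts.get("chimera_AT", 0)

    @property
    def chimera_TA(self) -> int:
        return self.class_counts.get("chimera_TA", 0)

    @property
    def unmapped_fraction(self) -> float:
        return self.unmapped_reads / self.total_filtered_reads


def orientation_asymmetry(
    chimera_AT: int, chimera_TA: int
) -> tuple[float, float, bool]:
    """Continuity-corrected dA->dT : dT->dA abundance ratio.

    Returns ``(ratio, log2_ratio, flagged)`` with the Haldane-Anscombe
    correction (0.5 added to both counts); ``flagged`` marks a zero raw count.
    """
    if chimera_AT < 0 or chimera_TA < 0:
        raise ValueError("counts must be nonnegative")
    ratio = (chimera_AT + 0.5) / (chimera_TA + 0.5)
    return ratio, math.log2(ratio), chimera_AT == 0 or chimera_TA == 0


@dataclass
class BiasEstimate:
    """Estimated dA:dT capture-efficiency ratio from a spike-in experiment."""

    observed_dA: int
    observed_dT: int
    input_ratio: Optional[float]
    beta_hat: Optional[float]
    reason: Optional[str] = None


def estimate_capture_bias(
    observed_dA: int, observed_dT: int, design: SpikeInDesign
) -> BiasEstimate:
    """beta_hat = (observed dA/dT) / (input dA/dT fmol ratio).

    Single-species designs (specificity controls) and zero dT observations
    yield a no-estimate result carrying the observed counts and a reason.
    """
    if design.input_dA_fmol <= 0 or design.input_dT_fmol <= 0:
        return BiasEstimate(
            observed_dA, observed_dT, None, None, reason="single-species design"
        )
    input_ratio = design.input_dA_fmol / design.input_dT_fmol
    if observed_dT < 1:
        return BiasEstimate(
            observed_dA, observed_dT, input_ratio, None, reason="no dT reads observed"
        )
    beta_hat = (observed_dA / observed_dT) / input_ratio
    return BiasEstimate(observed_dA, observed_dT, input_ratio, beta_hat)


@dataclass
class CorrectedCounts:
    """Bias-corrected per-million values and the beta they were divided by."""

    values: dict[str, float]
    beta_hat: float
    corrected_classes: tuple[str, ...] = DA_CLASSES


def correct_counts(
    per_million: Mapping[str, float], beta_hat: float
) -> CorrectedCounts:
    """Divide dA-derived class values by beta_hat; other classes unchanged."""
    if beta_hat <= 0:
        raise ValueError("beta_hat must be > 0")
    values = {
        cls: (v / beta_hat if cls in DA_CLASSES else float(v))
        for cls, v in per_million.items()
    }
    return CorrectedCounts(values, beta_hat)


@dataclass(frozen=True)
class ExpressionRecord:
    """A feature's read count and length, the TPM inputs."""

    feature_id: str
    count: int
    length: int


def tpm(records: Sequence[ExpressionRecord]) -> dict[str, float]:
    """Transcripts per million: counts / length, rescaled to 1e6 per sample."""
    if not records:
        raise ValueError("empty expression table")
    for r in records:
        if r.length <= 0:
            raise ValueError(f"{r.feature_id}: length must be > 0")
        if r.count < 0:
            raise ValueError(f"{r.feature_id}: count must be >= 0")
    rates = np.array([r.count / r.length for r in records], dtype=np.float64)
    total = rates.sum()
    if total == 0:
        raise ValueError("all counts are zero")
    values = rates / total * 1e6
    return {r.feature_id: float(v) for r, v in zip(records, values)}


def compare_conditions(
    summaries: Sequence[CountsSummary], grouping: Mapping[str, str]
) -> pd.DataFrame:
    """Two-condition per-class contrast of per-million values.

    Returns one row per pattern class with the per-condition means, the
    log2 fold change (pseudocount 0.1 per million on both sides), and the
    per-replicate values for dispersion inspection.
    """
    for s in summaries:
        if s.sample_id not in grouping:
            raise ValueError(f"sample {s.sample_id!r} missing from grouping")
    conditions = sorted(set(grouping[s.sample_id] for s in summaries))
    if len(conditions) != 2:
        raise ValueError(f"need exactly 2 conditions, got {conditions}")
    a, b = conditions
    classes = sorted({cls for s in summaries for cls in s.class_per_million})
    rows = []
    for cls in classes:
        per_cond = {
            cond: [
                s.class_per_million.get(cls, 0.0)
                for s in summaries
                if grouping[s.sample_id] == cond
            ]
            for cond in (a, b)
        }
        mean_a = float(np.mean(per_cond[a]))
        mean_b = float(np.mean(per_cond[b]))
        log2fc = math.log2(
            (mean_a + LOG2FC_PSEUDOCOUNT) / (mean_b + LOG2FC_PSEUDOCOUNT)
        )
        rows.append(
            {
                "pattern_class": cls,
                "condition_a": a,
                "condition_b": b,
                f"mean_per_million_{a}": mean_a,
                f"mean_per_million_{b}": mean_b,
                "log2_fold_change": log2fc,
                f"replicates_{a}": per_cond[a],
                f"replicates_{b}": per_cond[b],
            }
        )
    return pd.DataFrame(rows)
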