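"""Parental differentiality calling.

For every hybrid of the mating design and every marker, decide whether the
marker discriminates the two parents.  These boolean calls are the sole
input to the association test and to the binary distances.

Rules per data type:

* SNP: discriminative when both parental allele calls are observed and
  unequal (a missing call makes the pair non-differential for that marker).
* sRNA (rpmqn): differential when the lower-expressed parent reaches at
  least 0.5 rpmqn and the higher parent shows at least a two-fold change;
  when the lower parent is below 0.5 rpmqn the higher parent must reach at
  least 1 rpmqn.  All thresholds inclusive.
* mRNA: configurable fold-change rule with a minimum-intensity floor on the
  higher parent; the default (two-fold, no floor) parallels the sRNA fold
  branch.  The microarray pipeline that produced the original intensities
  has its own criterion, so the rule is a config object rather than a
  constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    SNP_MISSING,
    DataType,
    DifferentialCalls,
    MarkerMatrix,
    MatingDesign,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialRule",
    "call_snp_discriminative",
    "call_srna_differential",
    "call_mrna_differential",
    "call_differential",
    "SRNA_MIN_LOW",
    "SRNA_MIN_HIGH",
    "SRNA_FOLD",
]

SRNA_MIN_LOW = 0.5   # rpmqn floor for the lower-expressed parent
SRNA_MIN_HIGH = 1.0  # rpmqn floor for the higher parent when the lower is silent
SRNA_FOLD = 2.0


@dataclass(frozen=True)
class DifferentialRule:
    """Fold-change rule for expression data: higher >= fold * lower, higher >= floor."""

    fold: float = 2.0
    floor: float = 0.0

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValidationError("fold threshold must be >= 1")
        if self.floor < 0:
            raise ValidationError("intensity floor must be >= 0")


def _parent_value_arrays(matrix: MarkerMatrix, design: MatingDesign):
    """(n_hybrids, n_markers) arrays of flint-parent and dent-parent values."""
    missing = [
        line
        for pair in design.hybrids
        for line in pair
        if line not in matrix.values.index
    ]
    if missing:
        raise ValidationError(f"lines missing from marker matrix: {sorted(set(missing))}")
    flint_idx = [f for f, _ in design.hybrids]
    dent_idx = [d for _, d in design.hybrids]
    fvals = matrix.values.loc[flint_idx].to_numpy()
    dvals = matrix.values.loc[dent_idx].to_numpy()
    return fvals, dvals


def _wrap(matrix: MarkerMatrix, design: MatingDesign, calls: np.ndarray) -> DifferentialCalls:
    df = pd.DataFrame(
        calls, index=design.hybrid_index(), columns=matrix.values.columns
    )
    result = DifferentialCalls(matrix.data_type, df)
    n_cand = len(result.candidate_markers)
    logger.info(
        "%s: %d/%d candidate markers (%.1f%%) differential in >=1 line combination",
        matrix.data_type.value, n_cand, matrix.n_markers,
        100.0 * n_cand / max(matrix.n_markers, 1),
    )
    return result


def call_snp_discriminative(
    matrix: MarkerMatrix, design: MatingDesign
) -> DifferentialCalls:
    """Polymorphic SNPs where the parental alleles are observed and unequal."""
    if matrix.data_type is not DataType.SNP:
        raise ValidationError("call_snp_discriminative expects a SNP matrix")
    fvals, dvals = _parent_value_arrays(matrix, design)
    f_obs = _observed(fvals)
    d_obs = _observed(dvals)
    calls = f_obs & d_obs & (fvals != dvals)
    all_missing = ~_observed(matrix.values.to_numpy()).any(axis=0)
    if all_missing.any():
        logger.warning(
            "%d SNP markers are missing in every line; excluded from candidates",
            int(all_missing.sum()),
        )
    return _wrap(matrix, design, calls)


def _observed(allele_array: np.ndarray) -> np.ndarray:
    arr = allele_array.astype(object)
    return ~(pd.isna(arr) | (arr == SNP_MISSING))


def call_srna_differential(
    matrix: MarkerMatrix,
    design: MatingDesign,
    min_low: float = SRNA_MIN_LOW,
    min_high: float = SRNA_MIN_HIGH,
    fold: float = SRNA_FOLD,
) -> DifferentialCalls:
    """Threshold rule on quantile-normalized sRNA read counts (rpmqn)."""
    if matrix.data_type is not DataType.SRNA:
        raise ValidationError("call_srna_differential expects an sRNA matrix")
    fvals, dvals = _parent_value_arrays(matrix, design)
    lo = np.minimum(fvals, dvals).astype(float)
    hi = np.maximum(fvals, dvals).astype(float)
    calls = np.where(lo >= min_low, hi >= fold * lo, hi >= min_high)
    return _wrap(matrix, design, calls)


def call_mrna_differential(
    matrix: MarkerMatrix,
    design: MatingDesign,
    rule: DifferentialRule | None = None,
) -> DifferentialCalls:
    """Fold-change rule on normalized microarray intensities."""
    if matrix.data_type is not DataType.MRNA:
        raise ValidationError("call_mrna_differential expects an mRNA matrix")
    rule = rule or DifferentialRule()
    fvals, dvals = _parent_value_arrays(matrix, design)
    lo = np.minimum(fvals, dvals).astype(float)
    hi = np.maximum(fvals, dvals).astype(float)
    calls = (hi > lo) & (hi >= rule.fold * lo) & (hi >= rule.floor)
    return _wrap(matrix, design, calls)


def call_differential(
    matrix: MarkerMatrix, design: MatingDesign, **kwargs
) -> DifferentialCalls:
    """Dispatch on the matrix data type."""
    if matrix.data_type is DataType.SNP:
        return call_snp_discriminative(matrix, design)
    if matrix.data_type is DataType.SRNA:
        return call_srna_differential(matrix, design, **kwargs)
    return call_mrna_differential(matrix, design, **kwargs)
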