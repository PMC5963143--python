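"""Per-hybrid distance measures and regression predictors.

Euclidean parental distance over candidate markers::

    D_e(i,j) = sqrt( sum_s d_s(i,j) )

with d_s = (c_s(i) - c_s(j))^2 for expression data and an allele-difference
indicator for SNPs.  Binary distance over a set of n trait-associated
markers::

    D_b(i,j) = sqrt( (1/n) sum_s x_s )

with x_s = 1 when marker s is differential between the parents.  The
combined binary distance integrates the n_pos positively and n_neg
negatively associated markers::

    D_b,com = ( D_b,pos * n_pos + (1 - D_b,neg) * n_neg ) / (n_pos + n_neg)

Two count-based predictors complement the multivariate regression:
m_f = n_pos(i,j) / (n_pos(i,j) + n_neg(i,j)), the fraction of differential
associated markers that are positively associated, and
m_d = (n_pos(i,j) - n_neg(i,j)) / (n_pos - n_neg + 0.1), the dominance of
positive over negative differentials relative to the global set sizes (the
0.1 guards against a zero denominator and is kept exactly as defined, also
when n_neg > n_pos makes the denominator negative).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    DataType,
    DifferentialCalls,
    MarkerMatrix,
    MatingDesign,
    TraitTable,
    ValidationError,
)
from .differential import _observed, _parent_value_arrays

logger = logging.getLogger(__name__)

__all__ = [
    "euclidean_distance",
    "correlate_distance_with_trait",
    "binary_distance",
    "binary_distances",
    "combined_binary_distance",
    "predictor_mf",
    "predictor_md",
    "predictor_table",
    "MF_UNDEFINED_FILL",
]

#: m_f for hybrids with no differential associated marker in either
#: direction: the uninformative midpoint.
MF_UNDEFINED_FILL = 0.5


def euclidean_distance(
    matrix: MarkerMatrix,
    calls: DifferentialCalls,
    design: MatingDesign,
    snp_distance_convention: str = "difference",
) -> pd.Series:
    """Per-hybrid Euclidean parental distance over the candidate markers.

    ``snp_distance_convention='difference'`` scores d_s = 1 when the parental
    alleles differ (the convention consistent with a positive correlation of
    parental difference with hybrid performance); ``'as_printed'`` scores the
    complementary indicator (d_s = 1 when alleles are equal).
    """
    candidates = calls.candidate_markers
    if not candidates:
        raise ValidationError("no candidate markers")
    sub = MarkerMatrix(matrix.data_type, matrix.values[candidates])
    fvals, dvals = _parent_value_arrays(sub, design)
    if matrix.data_type is DataType.SNP:
        if snp_distance_convention not in ("difference", "as_printed"):
            raise ValidationError(
                f"unknown snp_distance_convention {snp_distance_convention!r}"
            )
        observed = _observed(fvals) & _observed(dvals)
        differ = observed & (fvals != dvals)
        d_s = differ if snp_distance_convention == "difference" else (observed & ~differ)
        total = d_s.sum(axis=1).astype(float)
    else:
        diff = fvals.astype(float) - dvals.astype(float)
        total = (diff**2).sum(axis=1)
    return pd.Series(np.sqrt(total), index=design.hybrid_index(), name="D_e")


def correlate_distance_with_trait(
    distances: pd.Series, traits: TraitTable
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) of per-hybrid distances with the trait."""
    common = distances.index.intersection(traits.values.index)
    if len(common) < 3:
        raise ValidationError("need >=3 hybrids with both distance and trait")
    x = distances.loc[common].to_numpy(float)
    y = traits.values.loc[common].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def binary_distance(
    calls: DifferentialCalls,
    marker_set: Sequence[str],
    hybrid: tuple[str, str],
) -> float:
    """D_b for one hybrid: sqrt of the fraction of ``marker_set`` differential."""
    if len(marker_set) == 0:
        raise ValidationError("empty marker set")
    x = calls.calls.loc[hybrid, list(marker_set)].to_numpy(bool)
    return float(np.sqrt(x.mean()))


def binary_distances(
    calls: DifferentialCalls, marker_set: Sequence[str]
) -> pd.Series:
    """Vectorized D_b over all hybrids of the calls table."""
    if len(marker_set) == 0:
        raise ValidationError("empty marker set")
    x = calls.calls[list(marker_set)].to_numpy(bool)
    return pd.Series(np.sqrt(x.mean(axis=1)), index=calls.calls.index, name="D_b")


def combined_binary_distance(d_b_pos, d_b_neg, n_pos: int, n_neg: int):
    """Count-weighted combination of the two direction-specific distances."""
    if n_pos < 0 or n_neg < 0:
        raise ValidationError("marker counts must be nonnegative")
    if n_pos + n_neg == 0:
        raise ValidationError("no associated markers in either direction")
    if n_neg == 0:  # limit cases are exact
        out = np.asarray(d_b_pos, dtype=float)
    elif n_pos == 0:
        out = 1.0 - np.asarray(d_b_neg, dtype=float)
    else:
        pos_term = np.asarray(d_b_pos, dtype=float)
        neg_term = 1.0 - np.asarray(d_b_neg, dtype=float)
        out = (pos_term * n_pos + neg_term * n_neg) / (n_pos + n_neg)
    return float(out) if out.ndim == 0 else out


def predictor_mf(n_pos_ij, n_neg_ij, fill: float = MF_UNDEFINED_FILL):
    """Fraction of differential associated markers that are positively associated."""
    n_pos_ij = np.asarray(n_pos_ij, dtype=float)
    n_neg_ij = np.asarray(n_neg_ij, dtype=float)
    total = n_pos_ij + n_neg_ij
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, n_pos_ij / np.where(total > 0, total, 1.0), fill)
    return float(out) if out.ndim == 0 else out


def predictor_md(n_pos_ij, n_neg_ij, n_pos: int, n_neg: int):
    """Dominance of positive over negative differentials; denominator offset 0.1."""
    n_pos_ij = np.asarray(n_pos_ij, dtype=float)
    n_neg_ij = np.asarray(n_neg_ij, dtype=float)
    out = (n_pos_ij - n_neg_ij) / (n_pos - n_neg + 0.1)
    return float(out) if out.ndim == 0 else out


def predictor_table(
    calls: DifferentialCalls,
    positive_markers: Sequence[str],
    negative_markers: Sequence[str],
    mf_fill: float = MF_UNDEFINED_FILL,
) -> pd.DataFrame:
    """All five regression predictors per hybrid.

    Columns: D_b_pos, D_b_neg, D_b_com, m_f, m_d plus the per-hybrid counts
    n_pos_ij / n_neg_ij.  A direction with no associated markers yields NaN
    for its own distance; D_b_com then reduces to the other direction's term.
    """
    pos = list(positive_markers)
    neg = list(negative_markers)
    n_pos, n_neg = len(pos), len(neg)
    if n_pos + n_neg == 0:
        raise ValidationError("no associated markers in either direction")
    index = calls.calls.index
    n_pos_ij = (
        calls.calls[pos].to_numpy(bool).sum(axis=1) if pos else np.zeros(len(index))
    )
    n_neg_ij = (
        calls.calls[neg].to_numpy(bool).sum(axis=1) if neg else np.zeros(len(index))
    )
    d_pos = np.sqrt(n_pos_ij / n_pos) if n_pos else np.full(len(index), np.nan)
    d_neg = np.sqrt(n_neg_ij / n_neg) if n_neg else np.full(len(index), np.nan)
    d_com = combined_binary_distance(d_pos, d_neg, n_pos, n_neg)
    return pd.DataFrame(
        {
            "D_b_pos": d_pos,
            "D_b_neg": d_neg,
            "D_b_com": d_com,
            "m_f": predictor_mf(n_pos_ij, n_neg_ij, fill=mf_fill),
            "m_d": predictor_md(n_pos_ij, n_neg_ij, n_pos, n_neg),
            "n_pos_ij": n_pos_ij.astype(int),
            "n_neg_ij": n_neg_ij.astype(int),
        },
        index=index,
    )
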