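"""Direction-aware binomial marker-trait association.

Hybrids are split into equally sized low (L) and high (H) trait classes.
For every candidate marker the number of hybrids with differential parents
is counted in each class (o_L, o_H).  Under the null hypothesis that
parental differentiality is equally probable in both classes, the count in
the enriched class is binomial with n = o_L + o_H and p = 0.5, giving the
upper-tail probability

    P_s = sum_{k = k_min}^{n} Bin_{n, 1/2}(k),    k_min = max(o_L, o_H).

Markers passing Benjamini-Hochberg FDR control (one family per data type)
are called trait-associated; the direction is *positive* when
differentiality is enriched among high-trait hybrids (o_H > o_L) and
*negative* otherwise.  A trait-permutation test (shuffling trait values
across hybrids and re-running the full analysis) provides an empirical
check that the associations are not artifacts of the marker structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .datatypes import DifferentialCalls, TraitTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ClassSplit",
    "AssociationResult",
    "split_classes",
    "binomial_association",
    "association_table",
    "fdr_select",
    "permutation_test",
    "BinomialTraitAssociation",
]


@dataclass
class ClassSplit:
    """Equal-sized low/high trait classes; the median hybrid of an odd count is excluded."""

    low: list[tuple[str, str]]
    high: list[tuple[str, str]]
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.low) != len(self.high):
            raise ValidationError("low and high classes must have equal size")


def split_classes(
    traits: TraitTable, hybrids: list[tuple[str, str]] | None = None
) -> ClassSplit:
    """Sort hybrids by trait value (ties broken by hybrid id) and halve."""
    values = traits.values
    if hybrids is not None:
        values = values.loc[pd.MultiIndex.from_tuples(list(hybrids))]
    if len(values) < 2:
        raise ValidationError("need >=2 hybrids with trait values to split")
    order = sorted(values.index, key=lambda h: (values.loc[h], h))
    if values.nunique() == 1:
        logger.warning("all trait values equal; class split determined by id tie-break")
    half = len(order) // 2
    if len(order) % 2:
        return ClassSplit(low=order[:half], high=order[half + 1 :], excluded=[order[half]])
    return ClassSplit(low=order[:half], high=order[half:])


def _binomial_upper_tail(k_min: np.ndarray, n: np.ndarray) -> np.ndarray:
    """P(X >= k_min) for X ~ Bin(n, 1/2); defined as 1 when n = 0."""
    p = stats.binom.sf(np.asarray(k_min) - 1, np.asarray(n), 0.5)
    return np.where(np.asarray(n) == 0, 1.0, p)


def association_table(calls: DifferentialCalls, split: ClassSplit) -> pd.DataFrame:
    """Association records for every candidate marker.

    Columns: o_L, o_H, n, k_min, p_value, direction ('positive'/'negative').
    """
    candidates = calls.candidate_markers
    if not candidates:
        raise ValidationError("no candidate markers to test")
    sub = calls.calls[candidates]
    lo = sub.loc[pd.MultiIndex.from_tuples(split.low)].to_numpy(bool)
    hi = sub.loc[pd.MultiIndex.from_tuples(split.high)].to_numpy(bool)
    o_l = lo.sum(axis=0)
    o_h = hi.sum(axis=0)
    n = o_l + o_h
    k_min = np.maximum(o_l, o_h)
    p = _binomial_upper_tail(k_min, n)
    direction = np.where(o_h > o_l, "positive", "negative")
    return pd.DataFrame(
        {
            "o_L": o_l,
            "o_H": o_h,
            "n": n,
            "k_min": k_min,
            "p_value": p,
            "direction": direction,
        },
        index=pd.Index(candidates, name="marker"),
    )


def binomial_association(
    calls: DifferentialCalls, split: ClassSplit, marker: str
) -> pd.Series:
    """Association record for a single candidate marker."""
    if marker not in calls.candidate_markers:
        raise ValidationError(f"{marker!r} is not a candidate marker")
    return association_table(calls, split).loc[marker]


@dataclass
class AssociationResult:
    """FDR-selected associated markers split by direction."""

    records: pd.DataFrame
    positive: list[str]
    negative: list[str]
    fdr_level: float

    @property
    def n_positive(self) -> int:
        return len(self.positive)

    @property
    def n_negative(self) -> int:
        return len(self.negative)

    def summary(self) -> dict:
        total = self.n_positive + self.n_negative
        return {
            "n_candidates": int(len(self.records)),
            "n_associated": total,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "fraction_positive": self.n_positive / total if total else float("nan"),
            "fdr_level": self.fdr_level,
        }


def fdr_select(
    records: pd.DataFrame,
    level: float = 0.05,
    direction_convention: str = "high_enriched",
) -> AssociationResult:
    """Benjamini-Hochberg selection over all candidate markers of one data type.

    ``direction_convention='high_enriched'`` labels markers enriched in the
    high class as positively associated; ``'low_enriched'`` swaps the labels.
    """
    if len(records) == 0:
        raise ValidationError("no association records")
    if direction_convention not in ("high_enriched", "low_enriched"):
        raise ValidationError(f"unknown direction convention {direction_convention!r}")
    reject, _, _, _ = multipletests(
        records["p_value"].to_numpy(), alpha=level, method="fdr_bh"
    )
    positive_label = "positive" if direction_convention == "high_enriched" else "negative"
    selected = records.index[reject]
    is_pos = records.loc[selected, "direction"] == positive_label
    return AssociationResult(
        records=records,
        positive=list(selected[is_pos]),
        negative=list(selected[~is_pos]),
        fdr_level=level,
    )


def permutation_test(
    calls: DifferentialCalls,
    traits: TraitTable,
    n_perm: int = 100,
    seed: int | np.random.SeedSequence | None = None,
    level: float = 0.05,
) -> pd.DataFrame:
    """Re-run the full association with trait values shuffled across hybrids.

    Returns one row per permutation with the minimum binomial p-value and
    the number of FDR-significant markers.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    hybrids = [h for h in calls.hybrids if h in traits.values.index]
    base = traits.values.loc[pd.MultiIndex.from_tuples(hybrids)]
    rows = []
    for i in range(n_perm):
        shuffled = pd.Series(
            rng.permutation(base.to_numpy()), index=base.index, name=base.name
        )
        table = TraitTable(traits.trait_name, shuffled)
        split = split_classes(table, hybrids)
        records = association_table(calls, split)
        result = fdr_select(records, level=level)
        rows.append(
            {
                "permutation": i,
                "min_p": float(records["p_value"].min()),
                "n_significant": result.n_positive + result.n_negative,
            }
        )
    return pd.DataFrame(rows).set_index("permutation")


class BinomialTraitAssociation(BaseEstimator):
    """Marker selector: binomial trait association with BH-FDR control.

    Parameters
    ----------
    fdr_level : float, default 0.05
        Benjamini-Hochberg false discovery rate for calling a marker
        trait-associated.
    direction_convention : {'high_enriched', 'low_enriched'}
        Which class enrichment is labelled a positive association.

    Attributes (after ``fit``)
    --------------------------
    split_ : ClassSplit
    records_ : DataFrame of per-marker counts and p-values
    positive_, negative_ : lists of associated marker ids
    candidate_markers_ : markers differential in >=1 training hybrid
    """

    def __init__(self, fdr_level: float = 0.05, direction_convention: str = "high_enriched"):
        self.fdr_level = fdr_level
        self.direction_convention = direction_convention

    def fit(self, X: DifferentialCalls | pd.DataFrame, y) -> "BinomialTraitAssociation":
        calls = _as_calls(X)
        traits = _as_traits(y, calls)
        self.split_ = split_classes(traits, calls.hybrids)
        self.records_ = association_table(calls, self.split_)
        result = fdr_select(
            self.records_, level=self.fdr_level,
            direction_convention=self.direction_convention,
        )
        self.positive_ = result.positive
        self.negative_ = result.negative
        self.candidate_markers_ = list(self.records_.index)
        self.feature_names_in_ = np.asarray(calls.markers, dtype=object)
        self.n_features_in_ = len(calls.markers)
        return self

    def get_support(self, direction: str | None = None) -> np.ndarray:
        """Boolean mask over the input markers (optionally one direction only)."""
        selected = {
            None: set(self.positive_) | set(self.negative_),
            "positive": set(self.positive_),
            "negative": set(self.negative_),
        }[direction]
        return np.asarray([m in selected for m in self.feature_names_in_])

    def transform(self, X: DifferentialCalls | pd.DataFrame) -> pd.DataFrame:
        calls = _as_calls(X)
        keep = [m for m in calls.markers if m in set(self.positive_) | set(self.negative_)]
        return calls.calls[keep]


def _as_calls(X) -> DifferentialCalls:
    if isinstance(X, DifferentialCalls):
        return X
    if isinstance(X, pd.DataFrame):
        return DifferentialCalls("sRNA", X)
    raise ValidationError(
        "X must be a DifferentialCalls object or a boolean DataFrame indexed by hybrid"
    )


def _as_traits(y, calls: DifferentialCalls) -> TraitTable:
    if isinstance(y, TraitTable):
        return y
    values = pd.Series(np.asarray(y, dtype=float), index=calls.calls.index, name="trait")
    return TraitTable("trait", values)
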