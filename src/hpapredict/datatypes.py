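"""In-memory containers shared by all analysis stages.

The study design is a factorial cross between two maize heterotic groups
(Flint x Dent).  Parental lines are profiled with one or more marker data
types (SNP genotype calls, mRNA microarray intensities, sRNA expression in
rpmqn = reads per million, quantile normalized); hybrids carry a single
quantitative trait value (grain yield, Mg/ha).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataType",
    "MarkerMatrix",
    "MatingDesign",
    "TraitTable",
    "MappingRecord",
    "AnnotationTrack",
    "DifferentialCalls",
    "ValidationError",
    "FormatError",
]

#: allele alphabet for SNP matrices; anything else (or NaN) is missing
SNP_ALLELES = frozenset("ACGT")
SNP_MISSING = "N"


class ValidationError(ValueError):
    """Input violates a domain invariant (negative expression, bad alleles ...)."""


class FormatError(ValueError):
    """File is structurally malformed (duplicates, non-rectangular, bad coordinates)."""


class DataType(str, enum.Enum):
    SNP = "SNP"
    MRNA = "mRNA"
    SRNA = "sRNA"

    @classmethod
    def coerce(cls, value: "DataType | str") -> "DataType":
        if isinstance(value, cls):
            return value
        for member in cls:
            if member.value.lower() == str(value).lower():
                return member
        raise ValidationError(f"unknown data type {value!r}")


@dataclass
class MarkerMatrix:
    """Lines x markers value table for one data type.

    ``values`` is a pandas DataFrame with line identifiers as index and
    marker identifiers as columns.  Expression types (mRNA, sRNA) hold
    nonnegative floats; SNP matrices hold single-letter allele calls with
    ``N``/NaN for missing.
    """

    data_type: DataType
    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.data_type = DataType.coerce(self.data_type)
        if self.values.index.has_duplicates:
            raise FormatError("duplicate line identifiers")
        if self.values.columns.has_duplicates:
            raise FormatError("duplicate marker identifiers")
        if self.data_type is DataType.SNP:
            self._validate_snp()
        else:
            self._validate_expression()

    def _validate_snp(self) -> None:
        vals = self.values.to_numpy(dtype=object)
        flat = pd.unique(vals.ravel())
        allowed = SNP_ALLELES | {SNP_MISSING}
        for v in flat:
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue
            if str(v) not in allowed:
                raise ValidationError(f"invalid SNP allele call {v!r}")

    def _validate_expression(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite")
        if (arr < 0).any():
            raise ValidationError("expression values must be nonnegative")

    @property
    def lines(self) -> list[str]:
        return list(self.values.index)

    @property
    def markers(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]


@dataclass
class MatingDesign:
    """Factorial Flint x Dent crossing scheme."""

    flint_lines: tuple[str, ...]
    dent_lines: tuple[str, ...]
    hybrids: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        self.flint_lines = tuple(self.flint_lines)
        self.dent_lines = tuple(self.dent_lines)
        self.hybrids = tuple((str(f), str(d)) for f, d in self.hybrids)
        flint, dent = set(self.flint_lines), set(self.dent_lines)
        if flint & dent:
            raise ValidationError(f"lines in both groups: {sorted(flint & dent)}")
        if len(set(self.hybrids)) != len(self.hybrids):
            raise ValidationError("duplicate hybrid pairs")
        for f, d in self.hybrids:
            if f not in flint:
                raise ValidationError(f"hybrid parent {f!r} is not a Flint line")
            if d not in dent:
                raise ValidationError(f"hybrid parent {d!r} is not a Dent line")

    @classmethod
    def full_factorial(
        cls, flint_lines: Sequence[str], dent_lines: Sequence[str]
    ) -> "MatingDesign":
        hybrids = tuple((f, d) for f in flint_lines for d in dent_lines)
        return cls(tuple(flint_lines), tuple(dent_lines), hybrids)

    @property
    def n_hybrids(self) -> int:
        return len(self.hybrids)

    def hybrid_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_tuples(self.hybrids, names=["flint", "dent"])


@dataclass
class TraitTable:
    """Hybrid trait observations (grain yield in Mg/ha for the motivating study)."""

    trait_name: str
    values: pd.Series  # MultiIndex (flint, dent) -> float

    def __post_init__(self) -> None:
        if not isinstance(self.values.index, pd.MultiIndex):
            raise ValidationError("trait values must be indexed by (flint, dent) pairs")
        if self.values.index.has_duplicates:
            raise ValidationError("hybrid listed more than once in trait table")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("trait values must be finite")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class MappingRecord:
    """One genomic mapping position of an sRNA (0-based, half-open)."""

    srna_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} for {self.srna_id}"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"invalid strand {self.strand!r}")


@dataclass
class AnnotationTrack:
    """Genomic intervals of one annotation category (gene or repeat).

    Intergenic is not a track: it is the complement of both tracks.
    """

    category: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    VALID_CATEGORIES = ("gene", "repeat")

    def __post_init__(self) -> None:
        if self.category not in self.VALID_CATEGORIES:
            raise ValidationError(
                f"annotation category must be one of {self.VALID_CATEGORIES}"
            )
        for chrom, start, end in self.intervals:
            if not (0 <= start < end):
                raise FormatError(f"invalid interval {chrom}:{start}-{end}")


@dataclass
class DifferentialCalls:
    """Per-hybrid, per-marker parental-differentiality booleans.

    ``calls`` is a boolean DataFrame whose index is the hybrid MultiIndex
    (flint, dent) of the mating design and whose columns are marker ids.
    A marker is a *candidate* when it is differential in at least one
    Flint x Dent line combination (nonzero column support).
    """

    data_type: DataType
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        self.data_type = DataType.coerce(self.data_type)
        if not isinstance(self.calls.index, pd.MultiIndex):
            raise ValidationError("calls must be indexed by (flint, dent) pairs")
        if self.calls.dtypes.ne(bool).any():
            self.calls = self.calls.astype(bool)

    @property
    def hybrids(self) -> list[tuple[str, str]]:
        return list(self.calls.index)

    @property
    def markers(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def candidate_markers(self) -> list[str]:
        support = self.calls.to_numpy().any(axis=0)
        return list(self.calls.columns[support])

    def restrict(self, hybrids: Iterable[tuple[str, str]]) -> "DifferentialCalls":
        """Subset to the given hybrids (e.g. a cross-validation training set)."""
        idx = pd.MultiIndex.from_tuples(list(hybrids), names=self.calls.index.names)
        return DifferentialCalls(self.data_type, self.calls.loc[idx])


def trait_table_from_mapping(
    trait_name: str, mapping: Mapping[tuple[str, str], float]
) -> TraitTable:
    idx = pd.MultiIndex.from_tuples(list(mapping), names=["flint", "dent"])
    return TraitTable(trait_name, pd.Series(list(mapping.values()), index=idx, dtype=float))
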