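"""Characterization of an associated-sRNA set against its background.

Enrichment is assessed by bootstrap: B random subsets of the background,
of the same cardinality as the target set and drawn without replacement,
give the null distribution of the per-stratum statistic (fraction of a
length class, or count in a genomic 1-Mb bin).  Empirical p-values use the
add-one convention, p = (1 + #{replicates at least as extreme}) / (B + 1),
so they are never exactly zero and bottom out at 1/(B+1).

Multi-mapping sRNAs contribute one count per mapping position in the bin
analyses but one unit per sRNA in the length analysis.  Strand is ignored
throughout.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .datatypes import AnnotationTrack, MappingRecord, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "length_enrichment",
    "bin_enrichment",
    "annotation_overlap",
    "binned_density_correlation",
    "DEFAULT_BIN_SIZE",
]

DEFAULT_BIN_SIZE = 1_000_000


def _bootstrap_indices(rng, n_background: int, k: int, B: int) -> np.ndarray:
    """(B, k) index matrix; each row a without-replacement subsample."""
    r = rng.random((B, n_background))
    return np.argpartition(r, k - 1, axis=1)[:, :k]


def _empirical_p(replicates: np.ndarray, observed: np.ndarray):
    """Add-one empirical p-values: enriched (>= observed) and depleted (<= observed)."""
    B = replicates.shape[0]
    p_enr = (1 + (replicates >= observed).sum(axis=0)) / (B + 1)
    p_dep = (1 + (replicates <= observed).sum(axis=0)) / (B + 1)
    return p_enr, p_dep


def length_enrichment(
    target_ids: Iterable[str],
    lengths: Mapping[str, int],
    B: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-length bootstrap enrichment of the target set within the background.

    ``lengths`` maps every background sRNA id to its nt length; the target
    must be a subset of the background.  Returns one row per length class
    with the observed target fraction and empirical p-values.
    """
    if B < 100:
        raise ValidationError("B must be >= 100")
    target = list(dict.fromkeys(target_ids))
    bg_ids = list(lengths)
    missing = set(target) - set(bg_ids)
    if missing:
        raise ValidationError(f"target ids not in background: {sorted(missing)[:5]}")
    k = len(target)
    if k == 0 or k > len(bg_ids):
        raise ValidationError("target must be nonempty and no larger than background")
    rng = np.random.default_rng(seed)

    bg_lengths = np.array([lengths[i] for i in bg_ids])
    classes, codes = np.unique(bg_lengths, return_inverse=True)
    n_classes = len(classes)
    pos = {sid: i for i, sid in enumerate(bg_ids)}
    target_codes = codes[[pos[t] for t in target]]
    observed = np.bincount(target_codes, minlength=n_classes) / k

    idx = _bootstrap_indices(rng, len(bg_ids), k, B)
    rep_codes = codes[idx]  # (B, k)
    flat = (np.arange(B)[:, None] * n_classes + rep_codes).ravel()
    rep_counts = np.bincount(flat, minlength=B * n_classes).reshape(B, n_classes) / k
    p_enr, p_dep = _empirical_p(rep_counts, observed)
    return pd.DataFrame(
        {
            "length": classes,
            "observed_fraction": observed,
            "background_fraction": np.bincount(codes, minlength=n_classes) / len(bg_ids),
            "n_replicates": B,
            "p_enriched": p_enr,
            "p_depleted": p_dep,
        }
    ).set_index("length")


def genome_bins(genome: Mapping[str, int], bin_size: int = DEFAULT_BIN_SIZE) -> pd.DataFrame:
    """Tile each chromosome with fixed-size bins; the last partial bin is kept."""
    rows = []
    for chrom, clen in genome.items():
        for start in range(0, clen, bin_size):
            rows.append((chrom, start, min(start + bin_size, clen)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _bin_index(
    mappings: Sequence[MappingRecord],
    genome: Mapping[str, int],
    bin_size: int,
    offsets: Mapping[str, int],
) -> np.ndarray:
    out = np.empty(len(mappings), dtype=int)
    for i, m in enumerate(mappings):
        if m.chrom not in genome:
            raise ValidationError(f"unknown chromosome {m.chrom!r}")
        if m.end > genome[m.chrom]:
            raise ValidationError(
                f"mapping {m.srna_id} beyond end of {m.chrom} ({m.end} > {genome[m.chrom]})"
            )
        out[i] = offsets[m.chrom] + m.start // bin_size
    return out


def bin_enrichment(
    target_mappings: Sequence[MappingRecord],
    background_mappings: Sequence[MappingRecord],
    genome: Mapping[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    B: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-bin bootstrap enrichment of target mapping counts vs the background."""
    if B < 100:
        raise ValidationError("B must be >= 100")
    if not target_mappings or len(target_mappings) > len(background_mappings):
        raise ValidationError("target must be nonempty and no larger than background")
    bins = genome_bins(genome, bin_size)
    n_chrom_bins = {c: int(-(-l // bin_size)) for c, l in genome.items()}
    offsets, acc = {}, 0
    for chrom in genome:
        offsets[chrom] = acc
        acc += n_chrom_bins[chrom]
    n_bins = acc
    rng = np.random.default_rng(seed)

    target_bins = _bin_index(target_mappings, genome, bin_size, offsets)
    bg_bins = _bin_index(background_mappings, genome, bin_size, offsets)
    k = len(target_bins)
    observed = np.bincount(target_bins, minlength=n_bins).astype(float)

    idx = _bootstrap_indices(rng, len(bg_bins), k, B)
    rep_bins = bg_bins[idx]
    flat = (np.arange(B)[:, None] * n_bins + rep_bins).ravel()
    rep_counts = np.bincount(flat, minlength=B * n_bins).reshape(B, n_bins).astype(float)
    p_enr, p_dep = _empirical_p(rep_counts, observed)
    bins["observed_count"] = observed
    bins["expected_count"] = rep_counts.mean(axis=0)
    bins["n_replicates"] = B
    bins["p_enriched"] = p_enr
    bins["p_depleted"] = p_dep
    return bins


def _build_trees(tracks: Mapping[str, AnnotationTrack]) -> dict[str, dict[str, IntervalTree]]:
    trees: dict[str, dict[str, IntervalTree]] = {}
    for category, track in tracks.items():
        per_chrom: dict[str, IntervalTree] = {}
        for chrom, start, end in track.intervals:
            per_chrom.setdefault(chrom, IntervalTree()).addi(start, end)
        trees[category] = per_chrom
    return trees


def annotation_overlap(
    mappings: Sequence[MappingRecord],
    tracks: Mapping[str, AnnotationTrack],
    lengths: Mapping[str, int] | None = None,
) -> tuple[dict[str, frozenset], pd.DataFrame]:
    """Classify each sRNA by the union of annotation categories it maps to.

    A mapping position overlaps a category when it shares at least one base
    with an interval (half-open intersection); positions overlapping
    neither gene nor repeat count as intergenic.  Returns the per-sRNA
    category sets and an aggregated count table per category combination
    (by nt length when ``lengths`` is given).
    """
    trees = _build_trees(tracks)
    per_srna: dict[str, set] = {}
    for m in mappings:
        cats = {
            category
            for category, per_chrom in trees.items()
            if m.chrom in per_chrom and per_chrom[m.chrom].overlaps(m.start, m.end)
        }
        if not cats:
            cats = {"intergenic"}
        per_srna.setdefault(m.srna_id, set()).update(cats)
    combos = {sid: frozenset(cats) for sid, cats in per_srna.items()}
    rows = []
    for sid, cats in combos.items():
        rows.append(
            {
                "srna_id": sid,
                "combination": "/".join(sorted(cats)),
                "length": lengths.get(sid) if lengths else None,
            }
        )
    table = (
        pd.DataFrame(rows)
        .groupby(["combination"] + (["length"] if lengths else []))
        .size()
        .rename("n_srnas")
        .reset_index()
    )
    return combos, table


def binned_density_correlation(
    mappings: Sequence[MappingRecord],
    track: Mapping[str, Sequence[float]],
    bin_size: int = DEFAULT_BIN_SIZE,
) -> pd.DataFrame:
    """Per-chromosome Pearson correlation of binned mapping counts with a track.

    ``track`` maps each chromosome to its per-bin values (e.g. local
    recombination rate); chromosome length is implied by the track length.
    Chromosomes with fewer than 3 bins are skipped with a warning.
    """
    rows = []
    for chrom, values in track.items():
        values = np.asarray(values, dtype=float)
        if len(values) < 3:
            logger.warning("%s has <3 bins; skipped", chrom)
            continue
        counts = np.zeros(len(values))
        for m in mappings:
            if m.chrom == chrom:
                b = m.start // bin_size
                if b >= len(values):
                    raise ValidationError(
                        f"mapping {m.srna_id} beyond binned track on {chrom}"
                    )
                counts[b] += 1
        if np.ptp(counts) == 0 or np.ptp(values) == 0:
            r, p = float("nan"), float("nan")
        else:
            r, p = stats.pearsonr(counts, values)
        rows.append({"chrom": chrom, "n_bins": len(values), "r": r, "p_value": p})
    frame = pd.DataFrame(rows, columns=["chrom", "n_bins", "r", "p_value"])
    return frame.set_index("chrom")
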