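"""Synthetic Flint x Dent datasets with planted trait-associated markers.

The generator emulates the shape of the motivating study: 7 Flint and 14
Dent inbred lines, the complete 98-hybrid factorial, parental marker
matrices for SNP genotypes, mRNA intensities and sRNA expression (rpmqn),
and one quantitative hybrid trait (grain yield, Mg/ha).

Trait construction.  A configurable number of *planted* markers in one
data type carry positive or negative effects: the trait of hybrid (i,j) is

    baseline + e_pos * #diff_pos(i,j) - e_neg * #diff_neg(i,j) + N(0, noise_sd)

where #diff_pos / #diff_neg count the planted markers whose parents are
differential, evaluated with exactly the same calling rules the analysis
uses.  Planted markers are organized into a small number of *blocks*:
each block carries a latent line profile (balanced within each heterotic
group) and every marker in the block thresholds a mixture of that profile
and marker-specific noise (``pattern_corr`` is the mixture weight),
mimicking co-regulated sRNA families.  With independent planted markers no
single marker could explain enough trait variance to be detectable in a
98-hybrid factorial.

Null (non-planted) expression markers are zero-inflated log-normal: each
variable marker is "on" in a random subset of lines (sparse, Beta-drawn
on-probability, matching the observation that most sRNAs are expressed in
few lines) and silent otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datatypes import (
    DataType,
    DifferentialCalls,
    MappingRecord,
    AnnotationTrack,
    MarkerMatrix,
    MatingDesign,
    TraitTable,
    ValidationError,
)
from .differential import call_differential

logger = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_dataset", "simulate_srna_features"]


@dataclass
class SimulationConfig:
    """Study-shaped generator settings.

    Marker counts are desk-scale stand-ins for the study's tens of
    thousands; effect sizes are in trait units (Mg/ha) per differential
    planted marker.
    """

    n_flint: int = 7
    n_dent: int = 14
    n_snp: int = 2000
    n_mrna: int = 2000
    n_srna: int = 5000
    fraction_polymorphic: float = 0.2
    planted_data_type: str = "sRNA"
    n_pos_planted: int = 200
    n_neg_planted: int = 100
    n_pos_blocks: int = 1
    n_neg_blocks: int = 1
    pattern_corr: float = 0.99
    effect_size_pos: float = 0.01
    effect_size_neg: float = 0.02
    baseline: float = 10.0
    noise_sd: float = 0.25
    # zero-inflated log-normal expression model
    log_mean_on: float = np.log(4.0)
    log_sd_on: float = 0.25
    on_prob_alpha: float = 0.3
    on_prob_beta: float = 2.7
    # SNP model
    snp_missing_rate: float = 0.02
    group_divergence: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_flint, self.n_dent, self.n_snp, self.n_mrna, self.n_srna)
        if any(c <= 0 for c in counts):
            raise ValidationError("counts must be positive")
        if not 0 <= self.fraction_polymorphic <= 1:
            raise ValidationError("fraction_polymorphic must be in [0, 1]")
        n_planted_type = {"SNP": self.n_snp, "mRNA": self.n_mrna, "sRNA": self.n_srna}[
            DataType.coerce(self.planted_data_type).value
        ]
        if self.n_pos_planted + self.n_neg_planted > n_planted_type:
            raise ValidationError("more planted markers than markers of the planted type")
        if self.n_pos_planted and self.n_pos_blocks < 1:
            raise ValidationError("need >=1 positive block")
        if self.n_neg_planted and self.n_neg_blocks < 1:
            raise ValidationError("need >=1 negative block")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    planted_positive: list[str]
    planted_negative: list[str]
    genetic_values: pd.Series  # trait minus noise, per hybrid
    config: SimulationConfig = field(repr=False, default=None)


def simulate_dataset(
    config: SimulationConfig | None = None,
) -> tuple[dict[str, MarkerMatrix], MatingDesign, TraitTable, SimulationTruth]:
    """Generate matrices for all three data types, the design, traits and truth."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    flint = [f"F{i + 1:02d}" for i in range(config.n_flint)]
    dent = [f"D{i + 1:02d}" for i in range(config.n_dent)]
    design = MatingDesign.full_factorial(flint, dent)
    lines = flint + dent

    planted_type = DataType.coerce(config.planted_data_type).value
    matrices: dict[str, MarkerMatrix] = {}
    planted_pos: list[str] = []
    planted_neg: list[str] = []
    for dtype, n_markers in (
        ("SNP", config.n_snp), ("mRNA", config.n_mrna), ("sRNA", config.n_srna)
    ):
        planted = (config.n_pos_planted, config.n_neg_planted) if dtype == planted_type else (0, 0)
        matrix, pos_ids, neg_ids = _simulate_matrix(dtype, n_markers, lines, planted, config, rng)
        matrices[dtype] = matrix
        if dtype == planted_type:
            planted_pos, planted_neg = pos_ids, neg_ids

    calls = call_differential(matrices[planted_type], design)
    genetic = pd.Series(config.baseline, index=design.hybrid_index(), dtype=float)
    if planted_pos:
        genetic += config.effect_size_pos * calls.calls[planted_pos].to_numpy().sum(axis=1)
    if planted_neg:
        genetic -= config.effect_size_neg * calls.calls[planted_neg].to_numpy().sum(axis=1)
    noise = rng.normal(0.0, config.noise_sd, size=len(genetic)) if config.noise_sd > 0 else 0.0
    traits = TraitTable("GY", genetic + noise)
    truth = SimulationTruth(planted_pos, planted_neg, genetic, config)
    logger.info(
        "simulated %d hybrids; planted %d positive / %d negative %s markers",
        design.n_hybrids, len(planted_pos), len(planted_neg), planted_type,
    )
    return matrices, design, traits, truth


def _simulate_matrix(dtype, n_markers, lines, planted, config, rng):
    if dtype == "SNP":
        return _simulate_snp(n_markers, lines, config, rng), [], []
    return _simulate_expression(dtype, n_markers, lines, planted, config, rng)


def _simulate_snp(n_markers, lines, config, rng) -> MarkerMatrix:
    n_lines = len(lines)
    n_flint = config.n_flint
    alleles = np.array(list("ACGT"))
    pair = alleles[np.argsort(rng.random((n_markers, 4)), axis=1)[:, :2]]  # ref/alt
    p_anc = rng.uniform(0.05, 0.95, n_markers)
    shift = rng.normal(0.0, config.group_divergence, n_markers)
    p_flint = np.clip(p_anc + shift, 0.0, 1.0)
    p_dent = np.clip(p_anc - shift, 0.0, 1.0)
    polymorphic = rng.random(n_markers) < config.fraction_polymorphic
    geno = np.empty((n_lines, n_markers), dtype=object)
    freq = np.vstack([np.tile(p_flint, (n_flint, 1)),
                      np.tile(p_dent, (n_lines - n_flint, 1))])
    is_ref = rng.random((n_lines, n_markers)) < freq
    is_ref[:, ~polymorphic] = True
    geno[:] = np.where(is_ref, pair[:, 0], pair[:, 1])
    missing = rng.random((n_lines, n_markers)) < config.snp_missing_rate
    geno[missing] = "N"
    df = pd.DataFrame(geno, index=lines, columns=[f"snp{i}" for i in range(n_markers)])
    return MarkerMatrix(DataType.SNP, df)


def _simulate_expression(dtype, n_markers, lines, planted, config, rng):
    n_lines = len(lines)
    n_pos, n_neg = planted
    n_planted = n_pos + n_neg
    prefix = "m" if dtype == "mRNA" else "s"
    ids = [f"{prefix}rna{i}" for i in range(n_markers)]

    # line "on" states: planted markers copy a block pattern with flips,
    # null variable markers draw a sparse per-marker on-probability
    states = np.zeros((n_lines, n_markers), dtype=bool)
    block_of = _assign_blocks(n_pos, config.n_pos_blocks, n_neg, config.n_neg_blocks)
    n_blocks = config.n_pos_blocks + config.n_neg_blocks if n_planted else 0
    if n_planted:
        # each block has a latent line profile, centered per heterotic group
        # so the family segregates in the factorial; marker states threshold
        # a mixture of the block profile and marker-specific noise
        latent = rng.normal(size=(n_lines, n_blocks))
        for lo, hi in ((0, config.n_flint), (config.n_flint, n_lines)):
            latent[lo:hi] -= np.median(latent[lo:hi], axis=0)
        a = np.sqrt(config.pattern_corr)
        eps = rng.normal(size=(n_lines, n_planted))
        states[:, :n_planted] = (
            a * latent[:, block_of] + np.sqrt(1 - config.pattern_corr) * eps > 0
        )
    if n_markers > n_planted:
        n_null = n_markers - n_planted
        on_prob = rng.beta(config.on_prob_alpha, config.on_prob_beta, n_null)
        variable = rng.random(n_null) < config.fraction_polymorphic
        null_states = rng.random((n_lines, n_null)) < on_prob
        constant_on = rng.random(n_null) < 0.5
        null_states[:, ~variable] = constant_on[~variable]
        states[:, n_planted:] = null_states

    values = np.where(
        states,
        np.exp(rng.normal(config.log_mean_on, config.log_sd_on, (n_lines, n_markers))),
        0.0,
    )
    if dtype == "mRNA":
        # microarray intensities have an additive background, no true zeros
        values = values * 20.0 + np.exp(rng.normal(1.0, 0.2, (n_lines, n_markers)))
    if n_markers > n_planted:
        # non-polymorphic markers are exactly constant across lines
        const_cols = n_planted + np.flatnonzero(~variable)
        values[:, const_cols] = values[0, const_cols]
    df = pd.DataFrame(values, index=lines, columns=ids)
    matrix = MarkerMatrix(DataType.coerce(dtype), df)
    return matrix, ids[:n_pos], ids[n_pos : n_pos + n_neg]


def _assign_blocks(n_pos, n_pos_blocks, n_neg, n_neg_blocks) -> np.ndarray:
    parts = []
    if n_pos:
        parts.append(np.arange(n_pos) % n_pos_blocks)
    if n_neg:
        parts.append(n_pos_blocks + (np.arange(n_neg) % n_neg_blocks))
    return np.concatenate(parts).astype(int) if parts else np.empty(0, dtype=int)


def recompute_genetic_values(
    matrices: dict[str, MarkerMatrix],
    design: MatingDesign,
    truth: SimulationTruth,
) -> pd.Series:
    """Rebuild the noise-free trait from the matrices and the planted sets."""
    config = truth.config
    planted_type = DataType.coerce(config.planted_data_type).value
    calls = call_differential(matrices[planted_type], design)
    genetic = pd.Series(config.baseline, index=design.hybrid_index(), dtype=float)
    if truth.planted_positive:
        genetic += config.effect_size_pos * calls.calls[truth.planted_positive].sum(axis=1)
    if truth.planted_negative:
        genetic -= config.effect_size_neg * calls.calls[truth.planted_negative].sum(axis=1)
    return genetic


def simulate_srna_features(
    n_srnas: int,
    length_distribution: dict[int, float],
    genome: dict[str, int],
    annotation_density: dict | None = None,
    seed: int | None = None,
    enriched_region: tuple[str, int, int] | None = None,
    enrichment_factor: float = 1.0,
    multi_mapping_prob: float = 0.0,
) -> tuple[list[MappingRecord], dict[str, AnnotationTrack], dict[str, int]]:
    """Random sRNA lengths, genomic mapping positions and annotation tracks.

    Positions are uniform over the genome unless an ``enriched_region``
    with an ``enrichment_factor`` > 1 is configured.  ``annotation_density``
    gives the covered genome fraction and mean interval length per category,
    e.g. ``{"gene": (0.3, 3000), "repeat": (0.4, 5000)}``.
    """
    if n_srnas <= 0:
        raise ValidationError("n_srnas must be positive")
    if not genome or any(l <= 0 for l in genome.values()):
        raise ValidationError("genome must have chromosomes of positive length")
    probs = np.array(list(length_distribution.values()), dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValidationError("length probabilities must sum to 1")
    rng = np.random.default_rng(seed)
    length_choices = np.array(list(length_distribution.keys()), dtype=int)
    chroms = list(genome)
    chrom_len = np.array([genome[c] for c in chroms], dtype=float)

    lengths = rng.choice(length_choices, size=n_srnas, p=probs)
    records: list[MappingRecord] = []
    length_map: dict[str, int] = {}
    extra_mass = 0.0
    if enriched_region is not None and enrichment_factor > 1.0:
        rchrom, rstart, rend = enriched_region
        extra_mass = (enrichment_factor - 1.0) * (rend - rstart)
    total_mass = chrom_len.sum() + extra_mass

    for i in range(n_srnas):
        sid = f"srna{i}"
        length_map[sid] = int(lengths[i])
        n_maps = 1 + rng.geometric(1 - multi_mapping_prob) - 1 if multi_mapping_prob else 1
        for _ in range(max(1, n_maps)):
            records.append(_sample_position(
                sid, int(lengths[i]), chroms, chrom_len, genome,
                enriched_region, extra_mass, total_mass, rng,
            ))
    tracks = _simulate_annotation(genome, annotation_density or {}, rng)
    return records, tracks, length_map


def _sample_position(sid, length, chroms, chrom_len, genome,
                     enriched_region, extra_mass, total_mass, rng) -> MappingRecord:
    if extra_mass and rng.random() < extra_mass / total_mass:
        chrom, rstart, rend = enriched_region
        start = int(rng.integers(rstart, max(rend - length, rstart + 1)))
    else:
        chrom = chroms[rng.choice(len(chroms), p=chrom_len / chrom_len.sum())]
        start = int(rng.integers(0, max(genome[chrom] - length, 1)))
    end = min(start + length, genome[chrom])
    return MappingRecord(sid, chrom, start, end)


def _simulate_annotation(genome, density, rng) -> dict[str, AnnotationTrack]:
    tracks = {}
    for category in ("gene", "repeat"):
        fraction, mean_len = density.get(category, (0.0, 0))
        intervals = []
        for chrom, clen in genome.items():
            covered = 0
            target = fraction * clen
            while covered < target:
                ilen = max(50, int(rng.exponential(mean_len))) if mean_len else 0
                if ilen == 0:
                    break
                start = int(rng.integers(0, max(clen - ilen, 1)))
                intervals.append((chrom, start, min(start + ilen, clen)))
                covered += ilen
        tracks[category] = AnnotationTrack(category, intervals)
    return tracks
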