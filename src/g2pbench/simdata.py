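"""Synthetic genotype and phenotype simulation.

Generates diploid biallelic SNP panels with the statistical structure the
downstream analysis assumes: a genome map across several chromosomes with
base-pair positions, a configurable MAF spectrum, local LD blocks with
tunable within-block correlation, sporadic missing calls, and an optional
two-subpopulation mode with divergent allele frequencies (to exercise
principal-component covariates in association scans).

Traits come in two flavours mirroring classic plant phenotypes:

* categorical traits controlled by one or two major loci through a
  penetrance table (e.g. flower or seed coat colour), and
* polygenic continuous traits (e.g. seed oil or protein content) built as
  an additive dosage model plus Gaussian noise scaled to hit a target
  narrow-sense heritability.

The LD model tiles each chromosome into blocks of a fixed bp span; within
a block each haplotype carries a latent uniform draw, and each SNP copies
the latent signal with probability ``within_block_correlation`` or draws a
fresh allele otherwise. Per-SNP marginal allele frequencies are exact
under this scheme, while neighbouring SNPs in a block are correlated.
Genotypes are two independent allele draws per line (near Hardy-Weinberg);
there is no coalescent machinery and no recombination map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genotype_io import GenotypeCall, GenotypeTable, PhenotypeTable, SNPRecord

__all__ = [
    "GenomeMap",
    "TraitModel",
    "SimConfig",
    "simulate_genome_map",
    "simulate_genotypes",
    "simulate_categorical_trait",
    "simulate_continuous_trait",
    "dominant_penetrance",
    "codominant_penetrance",
]

_BASES = np.array(list("ACGT"))


@dataclass
class GenomeMap:
    """Chromosome lengths plus an ordered SNP map (positions 1-based, strictly increasing)."""

    chromosomes: list[tuple[str, int]]
    snps: list[SNPRecord]

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        last: dict[str, int] = {}
        seen_ids: set[str] = set()
        for s in self.snps:
            if s.chrom not in lengths:
                raise ValueError(f"SNP {s.id} on unknown chromosome {s.chrom}")
            if not 1 <= s.pos <= lengths[s.chrom]:
                raise ValueError(f"SNP {s.id} position {s.pos} outside chromosome")
            if s.chrom in last and s.pos <= last[s.chrom]:
                raise ValueError(f"positions not strictly increasing at {s.id}")
            if s.ref == s.alt:
                raise ValueError(f"SNP {s.id} has ref == alt")
            if s.id in seen_ids:
                raise ValueError(f"duplicate SNP id {s.id}")
            last[s.chrom] = s.pos
            seen_ids.add(s.id)

    @property
    def n_snps(self) -> int:
        return len(self.snps)


@dataclass
class TraitModel:
    """Genetic architecture of a simulated trait.

    ``kind`` is one of ``monogenic-categorical``, ``oligogenic-categorical``
    or ``polygenic-continuous``. For categorical kinds ``penetrance`` maps a
    tuple of genotype calls at the causal loci (in ``causal_loci`` order) to
    a probability vector over the ``n_classes`` classes; every reachable
    genotype combination must have a row and rows must sum to 1. For
    continuous traits ``effects`` gives the additive effect per alt-allele
    dosage of each causal locus and ``heritability`` the target fraction of
    phenotypic variance explained by the genetic value. ``baseline`` shifts
    the continuous trait so its mean is strictly positive (the regression
    metric divides by the trait mean).
    """

    kind: str
    causal_loci: list[str]
    penetrance: Mapping[tuple[int, ...], Sequence[float]] | None = None
    n_classes: int | None = None
    class_labels: list[str] | None = None
    effects: list[float] | None = None
    heritability: float | None = None
    baseline: float = 50.0
    name: str = "trait"

    def __post_init__(self) -> None:
        kinds = ("monogenic-categorical", "oligogenic-categorical", "polygenic-continuous")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")
        if self.is_categorical:
            if self.penetrance is None or self.n_classes is None:
                raise ValueError("categorical trait requires penetrance and n_classes")
            if self.n_classes < 2:
                raise ValueError("n_classes must be >= 2")
            if self.kind == "monogenic-categorical" and len(self.causal_loci) != 1:
                raise ValueError("monogenic trait takes exactly one causal locus")
            for key, row in self.penetrance.items():
                if len(key) != len(self.causal_loci):
                    raise ValueError(f"penetrance key {key} does not match causal loci")
                if len(row) != self.n_classes or abs(sum(row) - 1.0) > 1e-9:
                    raise ValueError(f"penetrance row for {key} must sum to 1")
            if self.class_labels is None:
                self.class_labels = [f"class{i}" for i in range(self.n_classes)]
        else:
            if self.effects is None or len(self.effects) != len(self.causal_loci):
                raise ValueError("continuous trait requires one effect per causal locus")
            if self.heritability is None or not 0.0 <= self.heritability <= 1.0:
                raise ValueError("heritability must be in [0, 1]")

    @property
    def is_categorical(self) -> bool:
        return self.kind.endswith("categorical")


@dataclass
class SimConfig:
    """Population-level simulation parameters; ``seed`` fixes all randomness."""

    n_lines: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_span_bp: int = 100_000
    within_block_correlation: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    n_subpops: int = 1
    subpop_divergence: float = 0.0  # +/- shift applied to per-SNP allele freq per subpopulation

    def __post_init__(self) -> None:
        low, high = self.maf_range
        if not (0.0 < low <= high <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")
        if not 0.0 <= self.within_block_correlation < 1.0:
            raise ValueError("within_block_correlation must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 0.1:
            raise ValueError("missing_rate must be in [0, 0.1)")
        if self.ld_block_span_bp < 1:
            raise ValueError("ld_block_span_bp must be positive")
        if self.n_lines < 1:
            raise ValueError("n_lines must be positive")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")


# ---------------------------------------------------------------------------
# genome map
# ---------------------------------------------------------------------------


def simulate_genome_map(
    n_chrom: int, snps_per_chrom: int, chrom_length_bp: int, seed: int
) -> GenomeMap:
    """Draw a genome map with ``snps_per_chrom`` uniformly placed SNPs per chromosome."""
    if n_chrom < 1 or snps_per_chrom < 1 or chrom_length_bp < 1:
        raise ValueError("n_chrom, snps_per_chrom and chrom_length_bp must all be >= 1")
    if snps_per_chrom > chrom_length_bp:
        raise ValueError("more SNPs than base pairs on a chromosome")
    rng = np.random.default_rng(seed)
    chromosomes = [(f"chr{i + 1}", chrom_length_bp) for i in range(n_chrom)]
    snps: list[SNPRecord] = []
    for chrom, length in chromosomes:
        positions = np.sort(rng.choice(length, size=snps_per_chrom, replace=False)) + 1
        ref_idx = rng.integers(0, 4, size=snps_per_chrom)
        alt_idx = (ref_idx + rng.integers(1, 4, size=snps_per_chrom)) % 4
        for k, pos in enumerate(positions):
            snps.append(
                SNPRecord(chrom, int(pos), f"{chrom}_{pos}", _BASES[ref_idx[k]], _BASES[alt_idx[k]])
            )
    return GenomeMap(chromosomes, snps)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _block_index(genome: GenomeMap, span_bp: int) -> np.ndarray:
    """Assign each SNP a global LD-block id by tiling chromosomes into span_bp windows."""
    block = np.empty(genome.n_snps, dtype=np.int64)
    offset = 0
    chrom_of = {}
    for i, s in enumerate(genome.snps):
        if s.chrom not in chrom_of:
            chrom_of[s.chrom] = offset
            offset += 1_000_000  # disjoint block-id ranges per chromosome
        block[i] = chrom_of[s.chrom] + (s.pos - 1) // span_bp
    return block


def simulate_genotypes(genome: GenomeMap, cfg: SimConfig) -> GenotypeTable:
    """Simulate an n_lines x n_snps call table under the block-LD model.

    Each line is two independent haplotypes. Within an LD block each
    haplotype holds a latent uniform variate ``z``; a SNP with target alt
    frequency ``p`` copies the latent indicator ``z < p`` with probability
    ``within_block_correlation`` and otherwise draws Bernoulli(p) afresh,
    so the marginal frequency stays exactly ``p`` while SNPs sharing a
    block are positively correlated. Missing calls are uniform at random.
    """
    if genome.n_snps == 0:
        raise ValueError("empty genome map")
    rng = np.random.default_rng(cfg.seed)
    m = genome.n_snps
    n = cfg.n_lines
    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    # target MAF -> alt-allele frequency; a coin flip decides which allele is minor
    flip = rng.random(m) < 0.5
    p = np.where(flip, 1.0 - p, p)

    if cfg.n_subpops > 1:
        subpop = rng.integers(0, cfg.n_subpops, size=n)
        shift = rng.uniform(-cfg.subpop_divergence, cfg.subpop_divergence, size=(cfg.n_subpops, m))
        pmat = np.clip(p[None, :] + shift, 0.01, 0.99)[subpop, :]  # n x m
    else:
        pmat = np.broadcast_to(p, (n, m))

    block = _block_index(genome, cfg.ld_block_span_bp)
    _, block_pos = np.unique(block, return_inverse=True)
    n_blocks = block_pos.max() + 1
    c = cfg.within_block_correlation

    haplotypes = np.empty((2, n, m), dtype=bool)
    for h in range(2):
        z = rng.random((n, n_blocks))[:, block_pos]  # latent per (line, block), expanded to SNPs
        copy = rng.random((n, m)) < c
        fresh = rng.random((n, m)) < pmat
        haplotypes[h] = np.where(copy, z < pmat, fresh)
    calls = (haplotypes[0].astype(np.int8) + haplotypes[1].astype(np.int8))

    if cfg.missing_rate > 0:
        miss = rng.random((n, m)) < cfg.missing_rate
        calls[miss] = GenotypeCall.MISSING

    line_ids = [f"line{i + 1:04d}" for i in range(n)]
    return GenotypeTable(line_ids, list(genome.snps), calls)


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------


def _causal_calls(genotypes: GenotypeTable, trait: TraitModel) -> np.ndarray:
    """Calls at the causal loci (n_lines x n_loci); missing imputed to the SNP's modal call."""
    ids = {s.id: j for j, s in enumerate(genotypes.snps)}
    cols = []
    for locus in trait.causal_loci:
        if locus not in ids:
            raise KeyError(f"causal locus {locus!r} absent from genotype table")
        col = genotypes.calls[:, ids[locus]].astype(int)
        if (col == GenotypeCall.MISSING).any():
            observed = col[col != GenotypeCall.MISSING]
            mode = np.bincount(observed, minlength=3).argmax() if observed.size else 0
            col = np.where(col == GenotypeCall.MISSING, mode, col)
        cols.append(col)
    return np.stack(cols, axis=1)


def simulate_categorical_trait(
    genotypes: GenotypeTable, trait: TraitModel, seed: int
) -> PhenotypeTable:
    """Draw one class label per line from the penetrance row of its causal genotype."""
    if not trait.is_categorical:
        raise ValueError("trait.kind must be categorical")
    causal = _causal_calls(genotypes, trait)
    rng = np.random.default_rng(seed)
    labels = np.empty(genotypes.n_lines, dtype=int)
    for i in range(genotypes.n_lines):
        key = tuple(int(v) for v in causal[i])
        if key not in trait.penetrance:
            raise KeyError(f"no penetrance row for causal genotype {key}")
        labels[i] = rng.choice(trait.n_classes, p=np.asarray(trait.penetrance[key], dtype=float))
    trait_type = "binary" if trait.n_classes == 2 else "multiclass"
    return PhenotypeTable(
        list(genotypes.line_ids), labels, trait.name, trait_type, list(trait.class_labels)
    )


def simulate_continuous_trait(
    genotypes: GenotypeTable, trait: TraitModel, seed: int
) -> PhenotypeTable:
    """Additive dosage model plus Gaussian noise scaled to the target heritability.

    The genetic value is ``g = sum_k effect_k * dosage_k``; noise variance is
    ``var(g) * (1 - h2) / h2`` so the realised variance explained matches
    ``h2`` up to sampling error. At ``h2 = 0`` the phenotype is pure noise
    with unit variance. ``trait.baseline`` is added so the mean is positive.
    """
    if trait.is_categorical:
        raise ValueError("trait.kind must be polygenic-continuous")
    h2 = float(trait.heritability)
    dosage = _causal_calls(genotypes, trait).astype(float)
    g = dosage @ np.asarray(trait.effects, dtype=float)
    rng = np.random.default_rng(seed)
    var_g = float(np.var(g))
    if h2 == 0.0 or var_g == 0.0:
        noise_sd = 1.0
        g = np.zeros_like(g)
    elif h2 == 1.0:
        noise_sd = 0.0
    else:
        noise_sd = np.sqrt(var_g * (1.0 - h2) / h2)
    values = trait.baseline + g + rng.normal(0.0, noise_sd, size=g.shape[0])
    if values.mean() <= 0:
        values = values - values.mean() + 1.0  # metric divides by the mean
    return PhenotypeTable(list(genotypes.line_ids), values, trait.name, "continuous")


# ---------------------------------------------------------------------------
# penetrance helpers
# ---------------------------------------------------------------------------


def dominant_penetrance(p_case_carrier: float = 1.0, p_case_ref: float = 0.0) -> dict:
    """Two-class penetrance for a dominant monogenic locus (carrier = HET or ALT_HOM)."""
    return {
        (int(GenotypeCall.REF_HOM),): [1.0 - p_case_ref, p_case_ref],
        (int(GenotypeCall.HET),): [1.0 - p_case_carrier, p_case_carrier],
        (int(GenotypeCall.ALT_HOM),): [1.0 - p_case_carrier, p_case_carrier],
    }


def codominant_penetrance() -> dict:
    """Three-class penetrance where each genotype maps deterministically to its own class."""
    return {
        (int(GenotypeCall.REF_HOM),): [1.0, 0.0, 0.0],
        (int(GenotypeCall.HET),): [0.0, 1.0, 0.0],
        (int(GenotypeCall.ALT_HOM),): [0.0, 0.0, 1.0],
    }
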