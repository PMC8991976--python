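"""Genotype containers, VCF/phenotype I/O, preprocessing filters and one-hot encoding.

This module owns the in-memory representation of a diploid biallelic SNP
call matrix (:class:`GenotypeTable`), reads and writes the VCFv4.2 subset
the pipeline exchanges (GT-only records), applies the standard genomic
selection preprocessing filters (per-line missingness, per-SNP MAF and
missingness, sequential thinning), and produces the one-hot encoded design
matrix used by every downstream model, together with an invertible
feature index so any model feature can be traced back to a SNP and a
genotype class.

Conventions: positions are 1-based, region intervals are closed on both
ends (VCF convention), and MAF is always computed over non-missing calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger("g2pbench")

__all__ = [
    "GenotypeCall",
    "SNPRecord",
    "GenotypeTable",
    "PhenotypeTable",
    "FeatureIndex",
    "FeatureMatrix",
    "Split",
    "RegionSet",
    "read_vcf_to_table",
    "write_vcf",
    "filter_lines",
    "filter_snps",
    "thin_sequential",
    "one_hot_encode",
    "decode_feature",
    "holdout_split",
    "extract_regions",
    "write_genotype_csv",
    "write_phenotypes",
    "read_phenotypes",
    "write_regions",
    "read_regions",
]


class GenotypeCall(IntEnum):
    """Diploid biallelic call codes; MISSING sorts outside the 0..2 dosage scale."""

    MISSING = -1
    REF_HOM = 0
    HET = 1
    ALT_HOM = 2


class SNPRecord(NamedTuple):
    chrom: str
    pos: int  # 1-based
    id: str
    ref: str
    alt: str


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeTable:
    """Lines x SNPs matrix of diploid calls plus the SNP map.

    ``calls`` is an int8 array with values from :class:`GenotypeCall`;
    column ``j`` corresponds to ``snps[j]`` and row ``i`` to ``line_ids[i]``.
    """

    line_ids: list[str]
    snps: list[SNPRecord]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.line_ids), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.snps)} SNPs"
            )
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicate line ids")
        if len({s.id for s in self.snps}) != len(self.snps):
            raise ValueError("duplicate SNP ids")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.snps, columns=["chrom", "pos", "id", "ref", "alt"])

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency over non-missing calls (NaN if all missing)."""
        missing = self.calls == GenotypeCall.MISSING
        dosage = np.where(missing, 0, self.calls).astype(float)
        n_called = (~missing).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            alt_freq = dosage.sum(axis=0) / (2.0 * n_called)
        maf = np.minimum(alt_freq, 1.0 - alt_freq)
        maf[n_called == 0] = np.nan
        return maf

    def line_missing_fraction(self) -> np.ndarray:
        return (self.calls == GenotypeCall.MISSING).mean(axis=1)

    def snp_missing_fraction(self) -> np.ndarray:
        return (self.calls == GenotypeCall.MISSING).mean(axis=0)

    def dosage(self, impute_mean: bool = False) -> np.ndarray:
        """Alt-allele dosage matrix (float); missing -> NaN, or per-SNP mean if requested."""
        d = self.calls.astype(float)
        d[self.calls == GenotypeCall.MISSING] = np.nan
        if impute_mean:
            col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
            col_mean = np.nan_to_num(col_mean, nan=0.0)
            idx = np.where(np.isnan(d))
            d[idx] = col_mean[idx[1]]
        return d

    def subset_lines(self, keep: Sequence[int] | np.ndarray) -> "GenotypeTable":
        keep = np.asarray(keep)
        return GenotypeTable(
            [self.line_ids[i] for i in keep], list(self.snps), self.calls[keep, :]
        )

    def subset_snps(self, keep: Sequence[int] | np.ndarray) -> "GenotypeTable":
        keep = np.asarray(keep)
        return GenotypeTable(
            list(self.line_ids), [self.snps[j] for j in keep], self.calls[:, keep]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.line_ids == other.line_ids
            and self.snps == other.snps
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class PhenotypeTable:
    """One trait observed on a set of lines.

    ``trait_type`` is one of ``binary``, ``multiclass``, ``continuous``.
    Categorical values are stored as integer class indices into
    ``class_labels``; continuous values as floats.
    """

    line_ids: list[str]
    values: np.ndarray
    trait_name: str
    trait_type: str
    class_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "multiclass", "continuous"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicate line ids in phenotype table")
        self.values = np.asarray(self.values)
        if self.trait_type != "continuous" and self.class_labels is None:
            raise ValueError("categorical trait requires class_labels")

    @property
    def n_classes(self) -> int:
        if self.class_labels is None:
            raise ValueError("continuous trait has no classes")
        return len(self.class_labels)

    def value_for(self, line_id: str) -> float | int:
        return self.values[self.line_ids.index(line_id)]

    def aligned_to(self, line_ids: Sequence[str]) -> np.ndarray:
        pos = {lid: i for i, lid in enumerate(self.line_ids)}
        return self.values[[pos[lid] for lid in line_ids]]


class FeatureIndex:
    """Invertible map column index -> (SNP record, genotype class).

    A feature id is the 0-based column position in the matrix its encoder
    emitted. Decoding an id that was not emitted by this particular
    encoding raises rather than returning a silently wrong answer.
    """

    def __init__(self, entries: list[tuple[SNPRecord, GenotypeCall]]):
        self._entries = entries

    @property
    def n_features(self) -> int:
        return len(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def entry(self, feature_id: int) -> tuple[SNPRecord, GenotypeCall]:
        if not (0 <= int(feature_id) < len(self._entries)):
            raise KeyError(
                f"feature id {feature_id} was not emitted by this encoding "
                f"(valid range 0..{len(self._entries) - 1})"
            )
        return self._entries[int(feature_id)]

    def columns_for_snp(self, snp_id: str) -> list[int]:
        return [j for j, (snp, _) in enumerate(self._entries) if snp.id == snp_id]


@dataclass
class FeatureMatrix:
    """One-hot design matrix with its feature index; rows follow the source table."""

    values: np.ndarray  # lines x features, float32 in {0, 1}
    feature_index: FeatureIndex
    line_ids: list[str]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class Split:
    train_line_ids: tuple[str, ...]
    holdout_line_ids: tuple[str, ...]
    seed: int


@dataclass
class RegionSet:
    """Closed genomic intervals, 1-based, as (chrom, start_bp, end_bp)."""

    regions: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        for chrom, start, end in self.regions:
            if start > end:
                raise ValueError(f"region {chrom}:{start}-{end} has start > end")
            if start < 1:
                raise ValueError(f"region {chrom}:{start}-{end} has start < 1")

    def __len__(self) -> int:
        return len(self.regions)

    def merged(self) -> "RegionSet":
        """Union of intervals: overlapping or book-ended regions coalesce."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.regions:
            by_chrom.setdefault(chrom, []).append((start, end))
        out: list[tuple[str, int, int]] = []
        for chrom in sorted(by_chrom):
            ivals = sorted(by_chrom[chrom])
            cur_s, cur_e = ivals[0]
            for s, e in ivals[1:]:
                if s <= cur_e + 1:
                    cur_e = max(cur_e, e)
                else:
                    out.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            out.append((chrom, cur_s, cur_e))
        return RegionSet(out)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

# cyvcf2 gt_types codes
_GT_HOM_REF, _GT_HET, _GT_UNKNOWN, _GT_HOM_ALT = 0, 1, 2, 3
_BASES = frozenset("ACGT")


def read_vcf_to_table(vcf_path: str | Path) -> GenotypeTable:
    """Read a VCF of diploid biallelic SNPs into a :class:`GenotypeTable`.

    GT values map 0/0 -> REF_HOM, 0/1 or 1/0 -> HET, 1/1 -> ALT_HOM and
    ./. -> MISSING; SNP order follows file order. Multi-allelic or
    non-SNP records are rejected with a message identifying the record.
    """
    vcf = VCF(str(vcf_path))
    line_ids = list(vcf.samples)
    snps: list[SNPRecord] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        where = f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1:
            raise ValueError(f"record {where} is not biallelic (ALT={var.ALT})")
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            raise ValueError(f"record {where} is not a SNP (REF={ref}, ALT={alt})")
        gt = np.asarray(var.gt_types)
        if not np.isin(gt, [_GT_HOM_REF, _GT_HET, _GT_UNKNOWN, _GT_HOM_ALT]).all():
            raise ValueError(f"record {where} has malformed genotypes")
        col = np.empty(gt.shape[0], dtype=np.int8)
        col[gt == _GT_HOM_REF] = GenotypeCall.REF_HOM
        col[gt == _GT_HET] = GenotypeCall.HET
        col[gt == _GT_HOM_ALT] = GenotypeCall.ALT_HOM
        col[gt == _GT_UNKNOWN] = GenotypeCall.MISSING
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        snps.append(SNPRecord(var.CHROM, var.POS, snp_id, ref, alt))
        columns.append(col)
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(line_ids), 0), dtype=np.int8)
    )
    return GenotypeTable(line_ids, snps, calls)


_VCF_GT = {
    int(GenotypeCall.REF_HOM): "0/0",
    int(GenotypeCall.HET): "0/1",
    int(GenotypeCall.ALT_HOM): "1/1",
    int(GenotypeCall.MISSING): "./.",
}


def write_vcf(
    table: GenotypeTable,
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write a GT-only VCFv4.2 file, one sample column per line, "./." for missing."""
    chrom_order: list[str] = []
    for s in table.snps:
        if s.chrom not in chrom_order:
            chrom_order.append(s.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=g2pbench\n")
        for chrom in chrom_order:
            length = (contig_lengths or {}).get(
                chrom, max(s.pos for s in table.snps if s.chrom == chrom)
            )
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.line_ids)
            + "\n"
        )
        for j, snp in enumerate(table.snps):
            gts = "\t".join(_VCF_GT[int(c)] for c in table.calls[:, j])
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t{snp.id}\t{snp.ref}\t{snp.alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# preprocessing filters
# ---------------------------------------------------------------------------


def filter_lines(table: GenotypeTable, max_missing: float = 0.01) -> GenotypeTable:
    """Drop lines whose missing-call fraction exceeds ``max_missing`` (strictly)."""
    frac = table.line_missing_fraction()
    keep = np.where(frac <= max_missing)[0]
    removed = table.n_lines - keep.size
    if removed:
        logger.info("filter_lines: removed %d of %d lines", removed, table.n_lines)
    return table.subset_lines(keep)


def filter_snps(
    table: GenotypeTable, maf_min: float = 0.05, max_missing_rate: float = 0.10
) -> GenotypeTable:
    """Keep SNPs with MAF >= ``maf_min`` and missing rate strictly below ``max_missing_rate``.

    MAF is computed on non-missing calls only. A SNP with every call
    missing has no defined MAF and is removed (and flagged in the log).
    """
    maf = table.maf()
    miss = table.snp_missing_fraction()
    all_missing = np.isnan(maf)
    if all_missing.any():
        for j in np.where(all_missing)[0]:
            logger.warning("filter_snps: SNP %s has all calls missing; removed", table.snps[j].id)
    keep = np.where((~all_missing) & (maf >= maf_min) & (miss < max_missing_rate))[0]
    removed = table.n_snps - keep.size
    if removed:
        logger.info("filter_snps: removed %d of %d SNPs", removed, table.n_snps)
    return table.subset_snps(keep)


def thin_sequential(table: GenotypeTable, keep_every: int = 20) -> GenotypeTable:
    """Keep SNPs at ordinal positions 0, keep_every, 2*keep_every, ... in genome order.

    The default keeps 1 in 20 markers, a 95% reduction of the panel.
    """
    if keep_every < 1:
        raise ValueError(f"keep_every must be >= 1, got {keep_every}")
    return table.subset_snps(np.arange(0, table.n_snps, keep_every))


# ---------------------------------------------------------------------------
# one-hot encoding
# ---------------------------------------------------------------------------


def one_hot_encode(table: GenotypeTable) -> FeatureMatrix:
    """Encode each SNP as one binary column per genotype class observed at that SNP.

    Classes never observed at a SNP emit no column (they would be constant
    zero); a missing call encodes as all-zero across that SNP's columns.
    The returned feature index is a bijection onto the emitted columns.
    """
    entries: list[tuple[SNPRecord, GenotypeCall]] = []
    columns: list[np.ndarray] = []
    for j, snp in enumerate(table.snps):
        col = table.calls[:, j]
        for cls in (GenotypeCall.REF_HOM, GenotypeCall.HET, GenotypeCall.ALT_HOM):
            mask = col == cls
            if mask.any():
                entries.append((snp, cls))
                columns.append(mask.astype(np.float32))
    values = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((table.n_lines, 0), dtype=np.float32)
    )
    return FeatureMatrix(values, FeatureIndex(entries), list(table.line_ids))


def decode_feature(index: FeatureIndex, feature_id: int) -> tuple[str, GenotypeCall, str]:
    """Invert the one-hot encoding: feature id -> (SNP id, genotype class, allele pair).

    The allele pair is rendered from the SNP's ref/alt, e.g. ALT_HOM at
    ref=A, alt=T renders as "T/T" and HET as "A/T".
    """
    snp, cls = index.entry(feature_id)
    if cls == GenotypeCall.REF_HOM:
        allele = f"{snp.ref}/{snp.ref}"
    elif cls == GenotypeCall.HET:
        allele = f"{snp.ref}/{snp.alt}"
    else:
        allele = f"{snp.alt}/{snp.alt}"
    return snp.id, cls, allele


# ---------------------------------------------------------------------------
# holdout split and region extraction
# ---------------------------------------------------------------------------


def holdout_split(
    line_ids: Sequence[str],
    fraction: float = 0.2,
    seed: int = 0,
    stratify_by: np.ndarray | None = None,
) -> Split:
    """Randomly set aside ``fraction`` of lines as a holdout set.

    The holdout size is round-half-up of fraction x n. Sampling is uniform
    without replacement (optionally stratified by class label) and
    deterministic under ``seed``.
    """
    n = len(line_ids)
    if n < 5:
        raise ValueError(f"need at least 5 lines, got {n}")
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    n_holdout = int(np.floor(fraction * n + 0.5))
    if n_holdout == 0 or n_holdout == n:
        raise ValueError(
            f"fraction {fraction} yields an empty train or holdout set for n={n}"
        )
    rng = np.random.default_rng(seed)
    if stratify_by is None:
        perm = rng.permutation(n)
        hold_idx = set(perm[:n_holdout].tolist())
    else:
        stratify_by = np.asarray(stratify_by)
        hold: list[int] = []
        for cls in np.unique(stratify_by):
            members = np.where(stratify_by == cls)[0]
            k = int(np.floor(fraction * members.size + 0.5))
            hold.extend(rng.permutation(members)[:k].tolist())
        hold_idx = set(hold)
    train = tuple(lid for i, lid in enumerate(line_ids) if i not in hold_idx)
    holdout = tuple(lid for i, lid in enumerate(line_ids) if i in hold_idx)
    return Split(train, holdout, seed)


def extract_regions(table: GenotypeTable, regions: RegionSet) -> GenotypeTable:
    """Retain exactly the SNPs whose (chrom, pos) falls inside any closed interval."""
    if len(regions) == 0:
        raise ValueError("empty region set")
    known = {s.chrom for s in table.snps}
    for chrom, start, end in regions.regions:
        if chrom not in known:
            raise ValueError(f"region on unknown chromosome {chrom!r}")
    keep = []
    for j, snp in enumerate(table.snps):
        if any(
            snp.chrom == chrom and start <= snp.pos <= end
            for chrom, start, end in regions.regions
        ):
            keep.append(j)
    frac = len(keep) / table.n_snps if table.n_snps else 0.0
    logger.info(
        "extract_regions: retained %d of %d SNPs (%.1f%%)",
        len(keep), table.n_snps, 100 * frac,
    )
    return table.subset_snps(keep)


# ---------------------------------------------------------------------------
# tabular interfaces
# ---------------------------------------------------------------------------

_ALLELE_RENDER = {
    int(GenotypeCall.REF_HOM): lambda s: f"{s.ref}/{s.ref}",
    int(GenotypeCall.HET): lambda s: f"{s.ref}/{s.alt}",
    int(GenotypeCall.ALT_HOM): lambda s: f"{s.alt}/{s.alt}",
    int(GenotypeCall.MISSING): lambda s: "./.",
}


def write_genotype_csv(table: GenotypeTable, path: str | Path) -> None:
    """Structured CSV of the call matrix: lines as rows, SNP ids as headers, calls as allele pairs."""
    data = {
        snp.id: [_ALLELE_RENDER[int(c)](snp) for c in table.calls[:, j]]
        for j, snp in enumerate(table.snps)
    }
    pd.DataFrame(data, index=pd.Index(table.line_ids, name="line_id")).to_csv(path)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    """Headered CSV with columns line_id, trait_name, value."""
    if pheno.trait_type == "continuous":
        values: Iterable = (f"{v}" for v in pheno.values)
    else:
        values = (pheno.class_labels[int(v)] for v in pheno.values)
    pd.DataFrame(
        {
            "line_id": pheno.line_ids,
            "trait_name": pheno.trait_name,
            "value": list(values),
        }
    ).to_csv(path, index=False)


def read_phenotypes(
    path: str | Path, trait_type: str, trait_name: str | None = None
) -> PhenotypeTable:
    df = pd.read_csv(path, dtype={"line_id": str, "value": str})
    if trait_name is not None:
        df = df[df["trait_name"] == trait_name]
    else:
        names = df["trait_name"].unique()
        if len(names) != 1:
            raise ValueError(f"file holds multiple traits {list(names)}; pass trait_name")
        trait_name = str(names[0])
    if df["line_id"].duplicated().any():
        raise ValueError("duplicate line ids in phenotype file")
    if trait_type == "continuous":
        return PhenotypeTable(
            df["line_id"].tolist(),
            df["value"].astype(float).to_numpy(),
            trait_name,
            trait_type,
        )
    labels = sorted(df["value"].unique())
    lut = {lab: i for i, lab in enumerate(labels)}
    return PhenotypeTable(
        df["line_id"].tolist(),
        np.array([lut[v] for v in df["value"]], dtype=int),
        trait_name,
        trait_type,
        class_labels=labels,
    )


_REGION_HEADER = "# 1-based closed intervals: chrom\tstart\tend"


def write_regions(regions: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_REGION_HEADER + "\n")
        for chrom, start, end in regions.regions:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_regions(path: str | Path) -> RegionSet:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end = line.rstrip("\n").split("\t")
            out.append((chrom, int(start), int(end)))
    return RegionSet(out)
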