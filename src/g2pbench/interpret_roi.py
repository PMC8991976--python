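"""Gain-based model interpretation: SNP ranking and Regions of Importance.

A fitted gradient-boosted tree model attributes to each one-hot feature a
gain score — the total training-objective improvement of the splits that
used the feature. Decoding those features through the feature index gives
a ranking of SNPs (one entry per encoded genotype class, as the model
ranks encoded features, not SNPs). Top-ranked SNPs that sit close
together on a chromosome are clustered into Regions of Importance (ROIs):
maximal single-linkage chains in which every SNP is within ``max_gap_bp``
of its nearest neighbour, kept when they contain at least ``min_size``
distinct SNPs. ROIs (optionally flanked, with a fixed window around each
top SNP as a fallback when no ROI exists) become the target regions used
to build reduced marker panels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .genotype_io import FeatureIndex, GenotypeCall, RegionSet, decode_feature

__all__ = [
    "RankedSNP",
    "ROI",
    "rank_features_by_gain",
    "cluster_rois",
    "define_target_regions",
    "write_ranking",
    "write_rois",
]


@dataclass(frozen=True)
class RankedSNP:
    """One ranked one-hot feature, decoded back to its SNP and genotype class."""

    rank: int  # 1-based, gain non-increasing with rank
    snp_id: str
    chrom: str
    pos: int
    genotype_class: GenotypeCall
    allele: str
    gain: float


@dataclass
class ROI:
    """Genomic interval spanned by >= min_size clustered top-ranked SNPs."""

    chrom: str
    start: int
    end: int
    members: list[RankedSNP]
    summed_gain: float

    @property
    def snp_ids(self) -> set[str]:
        return {m.snp_id for m in self.members}


def _booster_gain(model) -> dict[int, float]:
    """Per-feature gain from an XGBoost-style model, keyed by column position."""
    booster = model.get_booster()
    raw = booster.get_score(importance_type="gain")
    return {int(key.lstrip("f")): float(val) for key, val in raw.items()}


def rank_features_by_gain(
    model, feature_index: FeatureIndex, top_n: int = 20, aggregate_per_snp: bool = False
) -> list[RankedSNP]:
    """Rank the model's features by gain and decode them to SNPs.

    Each one-hot column used by the model yields its own ranked entry, so
    one SNP can appear more than once (under different genotype classes).
    With ``aggregate_per_snp`` the gains of a SNP's columns are summed into
    a single entry instead. If the model saw fewer than ``top_n`` features,
    all used features are returned. Gain ties break by (chrom, pos).
    """
    n_model = getattr(model, "n_features_in_", None)
    if n_model is not None and int(n_model) != feature_index.n_features:
        raise ValueError(
            f"model was trained on {n_model} features but the index describes "
            f"{feature_index.n_features}; refusing to decode"
        )
    gains = _booster_gain(model)
    decoded = []
    for col, gain in gains.items():
        snp_id, cls, allele = decode_feature(feature_index, col)
        snp, _ = feature_index.entry(col)
        decoded.append((snp_id, snp.chrom, snp.pos, cls, allele, gain))
    if aggregate_per_snp:
        by_snp: dict[str, list] = {}
        for snp_id, chrom, pos, cls, allele, gain in decoded:
            if snp_id in by_snp:
                by_snp[snp_id][5] += gain
            else:
                # class/allele lose meaning once columns are pooled per SNP
                by_snp[snp_id] = [snp_id, chrom, pos, GenotypeCall.MISSING, "*", gain]
        decoded = [tuple(v) for v in by_snp.values()]
    decoded.sort(key=lambda t: (-t[5], t[1], t[2]))
    return [
        RankedSNP(rank, snp_id, chrom, pos, cls, allele, gain)
        for rank, (snp_id, chrom, pos, cls, allele, gain) in enumerate(
            decoded[:top_n], start=1
        )
    ]


def cluster_rois(
    ranked: Sequence[RankedSNP], max_gap_bp: int = 100_000, min_size: int = 3
) -> list[ROI]:
    """Chain ranked SNPs into ROIs by nearest-neighbour proximity.

    Per chromosome, distinct SNP positions are sorted and joined whenever
    the gap to the next position is <= ``max_gap_bp`` (single linkage);
    each resulting run with at least ``min_size`` distinct SNPs becomes an
    ROI spanning its min and max member positions. Duplicate entries of a
    SNP (several genotype classes of one SNP in the ranking) count once
    toward the size but all contribute to the summed gain. ROIs are
    returned sorted by summed gain, descending.
    """
    by_chrom: dict[str, dict[int, list[RankedSNP]]] = {}
    for entry in ranked:
        by_chrom.setdefault(entry.chrom, {}).setdefault(entry.pos, []).append(entry)
    rois: list[ROI] = []
    for chrom, at_pos in by_chrom.items():
        positions = sorted(at_pos)
        run: list[int] = [positions[0]]
        for pos in positions[1:]:
            if pos - run[-1] <= max_gap_bp:
                run.append(pos)
            else:
                rois.extend(_emit(chrom, run, at_pos, min_size))
                run = [pos]
        rois.extend(_emit(chrom, run, at_pos, min_size))
    rois.sort(key=lambda r: (-r.summed_gain, r.chrom, r.start))
    return rois


def _emit(chrom: str, run: list[int], at_pos: dict[int, list[RankedSNP]],
          min_size: int) -> list[ROI]:
    distinct = {m.snp_id for p in run for m in at_pos[p]}
    if len(distinct) < min_size:
        return []
    members = [m for p in run for m in at_pos[p]]
    members.sort(key=lambda m: m.rank)
    return [ROI(chrom, min(run), max(run), members, sum(m.gain for m in members))]


def define_target_regions(
    rois: Sequence[ROI],
    ranked: Sequence[RankedSNP],
    flank_bp: int = 0,
    fallback_window_bp: int = 250_000,
) -> RegionSet:
    """Turn ROIs into the region set used to build a reduced marker panel.

    Each ROI span is extended by ``flank_bp`` on both sides (clipped at
    position 1). When no ROI exists for the trait, a window of
    +/- ``fallback_window_bp`` around each top-ranked SNP is used instead.
    Overlapping intervals are merged.
    """
    if not ranked:
        raise ValueError("empty ranking: nothing to define regions from")
    if rois:
        raw = [
            (r.chrom, max(1, r.start - flank_bp), r.end + flank_bp) for r in rois
        ]
    else:
        raw = [
            (s.chrom, max(1, s.pos - fallback_window_bp), s.pos + fallback_window_bp)
            for s in ranked
        ]
    return RegionSet(raw).merged()


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------


def write_ranking(ranked: Sequence[RankedSNP], path: str | Path) -> None:
    """TSV of the ranking (bar-chart-ready: one row per ranked feature)."""
    pd.DataFrame(
        [
            {
                "rank": r.rank,
                "snp": r.snp_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "class": r.genotype_class.name,
                "allele": r.allele,
                "gain": r.gain,
            }
            for r in ranked
        ]
    ).to_csv(path, sep="\t", index=False)


def write_rois(rois: Sequence[ROI], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "n_snps": len(r.snp_ids),
                "summed_gain": r.summed_gain,
                "snps": ",".join(sorted(r.snp_ids)),
            }
            for r in rois
        ]
    ).to_csv(path, sep="\t", index=False)
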