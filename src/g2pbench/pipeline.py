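"""End-to-end experiment orchestration.

Runs the whole benchmark for a list of traits: simulate (or load)
genotypes, apply the preprocessing filters, train the four model families
on the full one-hot input, interpret the fitted XGBoost model into
Regions of Importance, cross-validate the regions against a GWAS scan,
reduce the marker panel to the target regions, re-train on the reduced
input and compare. Every stage seed derives from the master seed by a
fixed offset so stages are independently reproducible, and the report
carries the in/out counts of every filter so each number is recomputable
from stored intermediates.

Deep-learning stages are optional (``include_dl``); when switched off the
comparisons cover XGBoost and random forest only and the report says so.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import genotype_io as gio
from . import gwas_scan, interpret_roi, model_suite, simdata

logger = logging.getLogger("g2pbench")

__all__ = ["ExperimentConfig", "TraitResult", "ExperimentReport",
           "run_full_experiment", "summarize_best_models", "make_demo_config"]

# per-stage seed offsets from the master seed
_SEED_MAP = 1
_SEED_GENO = 2
_SEED_SPLIT = 3
_SEED_CV = 4
_SEED_TUNE = 5
_SEED_TRAIT = 100  # + trait index


@dataclass
class ExperimentConfig:
    """Resolved configuration of one benchmark run; serialisable to YAML."""

    # genome + population (used when no VCF is supplied)
    n_chrom: int = 4
    snps_per_chrom: int = 100
    chrom_length_bp: int = 10_000_000
    n_lines: int = 300
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_span_bp: int = 150_000
    within_block_correlation: float = 0.8
    missing_rate: float = 0.002
    n_subpops: int = 1
    subpop_divergence: float = 0.0
    # alternatively: load genotypes/phenotypes from files
    vcf_path: str | None = None
    phenotype_paths: dict[str, str] = field(default_factory=dict)
    # traits to simulate (ignored when phenotype_paths given)
    traits: list[simdata.TraitModel] = field(default_factory=list)
    # preprocessing
    line_max_missing: float = 0.01
    maf_min: float = 0.05
    snp_max_missing: float = 0.10
    keep_every: int = 1
    holdout_fraction: float = 0.2
    # model building
    cv_k: int = 10
    tune_iterations: int = 0  # 0 skips hyperparameter search (default XGBoost settings)
    include_dl: bool = True
    dl_max_epochs: int = 200
    dl_patience: int = 20
    # interpretation
    top_n: int = 20
    roi_max_gap_bp: int = 100_000
    roi_min_size: int = 3
    flank_bp: int = 0
    fallback_window_bp: int = 250_000
    # GWAS
    n_pcs: int = 3
    alpha: float = 0.05
    overlap_proximity_bp: int = 250_000
    master_seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["traits"] = [_trait_to_dict(t) for t in self.traits]
        d["maf_range"] = list(self.maf_range)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ExperimentConfig":
        d = dict(d)
        d["traits"] = [_trait_from_dict(t) for t in d.get("traits", [])]
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _trait_to_dict(t: simdata.TraitModel) -> dict[str, Any]:
    d: dict[str, Any] = {
        "kind": t.kind, "causal_loci": list(t.causal_loci), "name": t.name,
    }
    if t.is_categorical:
        d["n_classes"] = t.n_classes
        d["class_labels"] = list(t.class_labels)
        d["penetrance"] = {
            ",".join(map(str, key)): list(map(float, row))
            for key, row in t.penetrance.items()
        }
    else:
        d["effects"] = list(map(float, t.effects))
        d["heritability"] = float(t.heritability)
        d["baseline"] = float(t.baseline)
    return d


def _trait_from_dict(d: dict[str, Any]) -> simdata.TraitModel:
    d = dict(d)
    if "penetrance" in d:
        d["penetrance"] = {
            tuple(int(x) for x in key.split(",")): row
            for key, row in d["penetrance"].items()
        }
    return simdata.TraitModel(**d)


# ---------------------------------------------------------------------------
# report containers
# ---------------------------------------------------------------------------


@dataclass
class TraitResult:
    trait_name: str
    task: model_suite.TaskSpec
    metrics: dict[tuple[str, str], model_suite.Metrics]  # (dataset, family) -> metrics
    ranking: list[interpret_roi.RankedSNP]
    rois: list[interpret_roi.ROI]
    target_regions: gio.RegionSet
    fallback_used: bool
    sals: list[gwas_scan.SAL]
    overlap: gwas_scan.OverlapReport
    retained_snps: int
    retained_fraction: float
    tuned_params: dict[str, Any] | None


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    provenance: dict[str, Any]
    trait_results: list[TraitResult]
    families: tuple[str, ...]

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for tr in self.trait_results:
            for (dataset, family), m in tr.metrics.items():
                rows.append(
                    {
                        "trait": tr.trait_name,
                        "dataset": dataset,
                        "family": family,
                        "task_type": (
                            "regression" if tr.task.trait_type == "regression"
                            else tr.task.trait_type
                        ),
                        "metric": m.metric_name,
                        "value": m.holdout,
                    }
                )
        return pd.DataFrame(rows)

    def comparison(self, dataset: str | None = None) -> model_suite.ComparisonSummary:
        """Cross-model summary; requires all four families (include_dl=True runs)."""
        df = self.metrics_frame()
        if dataset is not None:
            df = df[df.dataset == dataset]
        return model_suite.compare_models(df)

    def best_model_tally(self) -> dict[str, int]:
        """Best family per trait x dataset cell over the families actually run."""
        df = self.metrics_frame()
        tally = {f: 0 for f in self.families}
        for (_, _), cell in df.groupby(["trait", "dataset"]):
            regression = (cell.task_type == "regression").all()
            ordered = [cell[cell.family == f].value.iloc[0] for f in self.families]
            best = min(ordered) if regression else max(ordered)
            tally[self.families[ordered.index(best)]] += 1
        return tally

    def non_dl_sections(self) -> dict[str, Any]:
        """Everything in the report that excludes CNN/DNN training (deterministic)."""
        df = self.metrics_frame()
        df = df[~df.family.isin(("CNN", "DNN"))]
        return {
            "provenance": self.provenance,
            "metrics": df.to_dict("records"),
            "rois": [
                (tr.trait_name, r.chrom, r.start, r.end, sorted(r.snp_ids))
                for tr in self.trait_results
                for r in tr.rois
            ],
            "sals": [
                (tr.trait_name, s.snp_id, s.chrom, s.pos, s.p_value)
                for tr in self.trait_results
                for s in tr.sals
            ],
            "regions": [
                (tr.trait_name, tr.target_regions.regions) for tr in self.trait_results
            ],
            "retained": [
                (tr.trait_name, tr.retained_snps, tr.retained_fraction)
                for tr in self.trait_results
            ],
            "rankings": [
                (tr.trait_name, [(r.snp_id, r.rank, r.gain) for r in tr.ranking])
                for tr in self.trait_results
            ],
        }

    def to_markdown(self) -> str:
        lines = ["# Benchmark report", ""]
        lines.append(f"Families compared: {', '.join(self.families)}")
        if "CNN" not in self.families:
            lines.append("(deep-learning stages disabled; comparisons cover XGB/RF only)")
        lines.append("")
        lines.append("## Filter provenance")
        for key, val in self.provenance.items():
            lines.append(f"- {key}: {val}")
        lines.append("")
        lines.append("## Holdout metrics (full vs reduced input)")
        df = self.metrics_frame()
        wide = df.pivot_table(index=["trait", "dataset", "metric"],
                              columns="family", values="value")
        lines.append(wide.round(2).to_markdown())
        lines.append("")
        lines.append("## Best-model tally")
        for fam, count in self.best_model_tally().items():
            lines.append(f"- {fam}: {count}")
        lines.append("")
        for tr in self.trait_results:
            lines.append(f"## Trait {tr.trait_name}")
            lines.append(
                f"- reduced panel: {tr.retained_snps} SNPs "
                f"({100 * tr.retained_fraction:.1f}% of full panel)"
                + ("; fallback windows used (no ROI)" if tr.fallback_used else "")
            )
            for roi in tr.rois:
                lines.append(
                    f"- ROI {roi.chrom}:{roi.start}-{roi.end} "
                    f"({len(roi.snp_ids)} SNPs, gain {roi.summed_gain:.1f})"
                )
            lines.append(f"- significant GWAS loci: {len(tr.sals)}")
            lines.append(
                f"- ROIs with a SAL within {tr.overlap.proximity_bp} bp: "
                f"{tr.overlap.n_rois_with_sal}/{tr.overlap.n_rois}"
            )
            lines.append("")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# the experiment
# ---------------------------------------------------------------------------


def _train_all(
    families: tuple[str, ...],
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_hold: np.ndarray,
    y_hold: np.ndarray,
    task: model_suite.TaskSpec,
    cfg: ExperimentConfig,
    split: gio.Split,
    reference_mean: float | None,
    tuned: dict[str, Any] | None,
) -> tuple[dict[str, model_suite.Metrics], dict[str, model_suite.CrossValResult]]:
    metrics: dict[str, model_suite.Metrics] = {}
    fitted: dict[str, model_suite.CrossValResult] = {}
    cv = model_suite.CVConfig(k=cfg.cv_k, seed=cfg.master_seed + _SEED_CV)
    for family in families:
        result = model_suite.crossval_fit(
            family, X_train, y_train, cv, task,
            params=tuned if family == "XGB" else None,
            max_epochs=cfg.dl_max_epochs, patience=cfg.dl_patience,
        )
        metrics[family] = model_suite.evaluate(
            result.model, X_hold, y_hold, task,
            split.train_line_ids, split.holdout_line_ids,
            reference_mean=reference_mean, fold_scores=result.fold_scores,
        )
        fitted[family] = result
    return metrics, fitted


def run_full_experiment(
    cfg: ExperimentConfig, outdir: str | Path | None = None
) -> ExperimentReport:
    """Execute every stage for every trait and assemble the report.

    The reduced-input stage of each trait uses the target regions derived
    from that trait's full-input XGBoost model. Any stage failure aborts
    with the stage name; partial provenance is persisted when ``outdir``
    is given.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    provenance: dict[str, Any] = {"master_seed": cfg.master_seed}
    stage = "setup"

    def _persist_partial() -> None:
        if out is not None:
            with open(out / "provenance.partial.json", "w") as fh:
                json.dump(provenance, fh, indent=2, default=str)

    try:
        stage = "simulate"
        t0 = time.perf_counter()
        if cfg.vcf_path is not None:
            table = gio.read_vcf_to_table(cfg.vcf_path)
        else:
            genome = simdata.simulate_genome_map(
                cfg.n_chrom, cfg.snps_per_chrom, cfg.chrom_length_bp,
                seed=cfg.master_seed + _SEED_MAP,
            )
            sim = simdata.SimConfig(
                n_lines=cfg.n_lines, maf_range=cfg.maf_range,
                ld_block_span_bp=cfg.ld_block_span_bp,
                within_block_correlation=cfg.within_block_correlation,
                missing_rate=cfg.missing_rate, seed=cfg.master_seed + _SEED_GENO,
                n_subpops=cfg.n_subpops, subpop_divergence=cfg.subpop_divergence,
            )
            table = simdata.simulate_genotypes(genome, sim)
        provenance["lines_in"] = table.n_lines
        provenance["snps_in"] = table.n_snps
        logger.info("[simulate] %d lines x %d SNPs (%.1fs)",
                    table.n_lines, table.n_snps, time.perf_counter() - t0)

        stage = "phenotypes"
        phenos: dict[str, gio.PhenotypeTable] = {}
        tasks: dict[str, model_suite.TaskSpec] = {}
        if cfg.phenotype_paths:
            for name, path in cfg.phenotype_paths.items():
                trait_type = _infer_trait_type(path)
                phenos[name] = gio.read_phenotypes(path, trait_type, name)
        else:
            for i, trait in enumerate(cfg.traits):
                seed = cfg.master_seed + _SEED_TRAIT + i
                if trait.is_categorical:
                    phenos[trait.name] = simdata.simulate_categorical_trait(
                        table, trait, seed
                    )
                else:
                    phenos[trait.name] = simdata.simulate_continuous_trait(
                        table, trait, seed
                    )
        for name, ph in phenos.items():
            if ph.trait_type == "continuous":
                tasks[name] = model_suite.TaskSpec("regression")
            elif ph.n_classes == 2:
                tasks[name] = model_suite.TaskSpec("binary")
            else:
                tasks[name] = model_suite.TaskSpec("multiclass", n_classes=ph.n_classes)

        stage = "preprocess"
        after_lines = gio.filter_lines(table, cfg.line_max_missing)
        provenance["lines_after_missing_filter"] = after_lines.n_lines
        after_snps = gio.filter_snps(after_lines, cfg.maf_min, cfg.snp_max_missing)
        provenance["snps_after_maf_missing_filter"] = after_snps.n_snps
        pre = gio.thin_sequential(after_snps, cfg.keep_every)
        provenance["snps_after_thinning"] = pre.n_snps
        provenance["filters_reconcile"] = {
            "lines_removed": table.n_lines - after_lines.n_lines,
            "snps_removed_filters": after_lines.n_snps - after_snps.n_snps,
            "snps_removed_thinning": after_snps.n_snps - pre.n_snps,
        }

        families: tuple[str, ...] = ("XGB", "RF", "CNN", "DNN") if cfg.include_dl else ("XGB", "RF")
        trait_results: list[TraitResult] = []
        for i, (name, pheno) in enumerate(phenos.items()):
            stage = f"trait:{name}"
            task = tasks[name]
            logger.info("[%s] task=%s", name, task.trait_type)
            y_all = pheno.aligned_to(pre.line_ids)
            reference_mean = (
                float(np.asarray(y_all, dtype=float).mean())
                if task.trait_type == "regression" else None
            )
            split = gio.holdout_split(
                pre.line_ids, cfg.holdout_fraction,
                seed=cfg.master_seed + _SEED_SPLIT + i,
            )
            features = gio.one_hot_encode(pre)
            row_of = {lid: r for r, lid in enumerate(pre.line_ids)}
            tr_rows = [row_of[lid] for lid in split.train_line_ids]
            ho_rows = [row_of[lid] for lid in split.holdout_line_ids]
            X_train, X_hold = features.values[tr_rows], features.values[ho_rows]
            y_train, y_hold = y_all[tr_rows], y_all[ho_rows]

            tuned = None
            if cfg.tune_iterations > 0:
                stage = f"tune:{name}"
                tuned = model_suite.tune_xgboost(
                    X_train, y_train,
                    model_suite.TuneSpace(
                        n_search_iterations=cfg.tune_iterations,
                        seed=cfg.master_seed + _SEED_TUNE,
                    ),
                    task,
                )

            stage = f"train_full:{name}"
            metrics_full, fitted = _train_all(
                families, X_train, y_train, X_hold, y_hold, task, cfg, split,
                reference_mean, tuned,
            )

            stage = f"interpret:{name}"
            ranking = interpret_roi.rank_features_by_gain(
                fitted["XGB"].model, features.feature_index, top_n=cfg.top_n
            )
            rois = interpret_roi.cluster_rois(
                ranking, cfg.roi_max_gap_bp, cfg.roi_min_size
            )
            regions = interpret_roi.define_target_regions(
                rois, ranking, cfg.flank_bp, cfg.fallback_window_bp
            )
            fallback_used = not rois

            stage = f"gwas:{name}"
            dosage = pre.dosage(impute_mean=True)
            pcs = gwas_scan.compute_pcs(dosage, cfg.n_pcs)
            scan_cfg = gwas_scan.ScanConfig(n_pcs=cfg.n_pcs, alpha=cfg.alpha)
            results = gwas_scan.assoc_scan(
                dosage, y_all, pcs,
                [(s.id, s.chrom, s.pos) for s in pre.snps],
                categorical=task.is_classification,
            )
            sals = gwas_scan.significant_loci(results, scan_cfg)
            overlap = gwas_scan.overlap_roi_sal(rois, sals, cfg.overlap_proximity_bp)

            stage = f"reduce:{name}"
            reduced = gio.extract_regions(pre, regions)
            retained_fraction = reduced.n_snps / pre.n_snps if pre.n_snps else 0.0
            red_features = gio.one_hot_encode(reduced)
            Xr_train = red_features.values[tr_rows]
            Xr_hold = red_features.values[ho_rows]

            stage = f"train_reduced:{name}"
            red_families = families
            if cfg.include_dl and red_features.n_features < model_suite.cnn_min_features():
                logger.warning(
                    "[%s] reduced panel too narrow for the CNN; skipping CNN on reduced input",
                    name,
                )
                red_families = tuple(f for f in families if f != "CNN")
            metrics_red, _ = _train_all(
                red_families, Xr_train, y_train, Xr_hold, y_hold, task, cfg, split,
                reference_mean, tuned,
            )

            metrics = {("full", fam): m for fam, m in metrics_full.items()}
            metrics.update({("reduced", fam): m for fam, m in metrics_red.items()})
            trait_results.append(
                TraitResult(
                    trait_name=name, task=task, metrics=metrics, ranking=ranking,
                    rois=rois, target_regions=regions, fallback_used=fallback_used,
                    sals=sals, overlap=overlap, retained_snps=reduced.n_snps,
                    retained_fraction=retained_fraction, tuned_params=tuned,
                )
            )
            provenance[f"trait:{name}"] = {
                "n_rois": len(rois),
                "n_sals": len(sals),
                "fallback_used": fallback_used,
                "retained_snps": reduced.n_snps,
                "retained_fraction": retained_fraction,
            }
    except Exception as exc:
        _persist_partial()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = ExperimentReport(cfg, provenance, trait_results, families)
    if out is not None:
        cfg.to_yaml(out / "config.resolved.yaml")
        report.metrics_frame().to_csv(out / "metrics.tsv", sep="\t", index=False)
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2, default=str)
        with open(out / "report.md", "w") as fh:
            fh.write(report.to_markdown())
        for tr in trait_results:
            interpret_roi.write_ranking(tr.ranking, out / f"ranking_{tr.trait_name}.tsv")
            interpret_roi.write_rois(tr.rois, out / f"rois_{tr.trait_name}.tsv")
            gio.write_regions(tr.target_regions, out / f"regions_{tr.trait_name}.tsv")
    return report


def make_demo_config(master_seed: int = 7, n_lines: int = 200,
                     snps_per_chrom: int = 80, include_dl: bool = False,
                     continuous_trait: bool = False) -> ExperimentConfig:
    """Small ready-to-run configuration: a monogenic colour-like trait.

    The causal locus is the common-allele SNP with the highest minor allele
    frequency in the simulated panel, so all three genotype classes are
    well represented and stratified 10-fold cross-validation is feasible at
    desk-scale sample sizes. With ``continuous_trait`` a polygenic
    oil-content-like trait (two QTL, h2 = 0.6) is added.
    """
    cfg = ExperimentConfig(
        n_chrom=2, snps_per_chrom=snps_per_chrom, chrom_length_bp=8_000_000,
        n_lines=n_lines, maf_range=(0.15, 0.5), ld_block_span_bp=200_000,
        within_block_correlation=0.85, missing_rate=0.002,
        include_dl=include_dl, tune_iterations=0, cv_k=10,
        master_seed=master_seed,
    )
    genome = simdata.simulate_genome_map(
        cfg.n_chrom, cfg.snps_per_chrom, cfg.chrom_length_bp,
        seed=cfg.master_seed + _SEED_MAP,
    )
    sim = simdata.SimConfig(
        n_lines=cfg.n_lines, maf_range=cfg.maf_range,
        ld_block_span_bp=cfg.ld_block_span_bp,
        within_block_correlation=cfg.within_block_correlation,
        missing_rate=cfg.missing_rate, seed=cfg.master_seed + _SEED_GENO,
    )
    table = simdata.simulate_genotypes(genome, sim)
    maf = table.maf()
    causal = table.snps[int(np.nanargmax(maf))]
    cfg.traits = [
        simdata.TraitModel(
            "monogenic-categorical", [causal.id],
            penetrance=simdata.codominant_penetrance(), n_classes=3,
            name="flower_colour",
        )
    ]
    if continuous_trait:
        order = np.argsort(np.nan_to_num(maf))
        qtl = [table.snps[int(j)].id for j in order[-6::4]]  # two well-spread QTL
        cfg.traits.append(
            simdata.TraitModel(
                "polygenic-continuous", qtl, effects=[1.0, 0.8],
                heritability=0.6, name="seed_oil",
            )
        )
    return cfg


def _infer_trait_type(path: str | Path) -> str:
    """Continuous if every value parses as a float, else categorical."""
    df = pd.read_csv(path)
    try:
        df["value"].astype(float)
        return "continuous"
    except (ValueError, TypeError):
        return "multiclass" if df["value"].nunique() > 2 else "binary"


def summarize_best_models(
    full: pd.DataFrame, reduced: pd.DataFrame,
    families: tuple[str, ...] = model_suite.FAMILY_ORDER,
) -> pd.DataFrame:
    """Best family per trait x dataset cell, plus per-family totals.

    Both frames need columns trait, family, task_type, value (holdout
    accuracy or RMSE%%); they must cover the same traits. Returns a tidy
    frame with one row per cell plus a ``total`` row per family; tie goes
    to the earlier family in ``families``.
    """
    traits_full = set(full.trait.unique())
    traits_red = set(reduced.trait.unique())
    if traits_full != traits_red:
        raise ValueError(
            f"trait mismatch between reports: {sorted(traits_full ^ traits_red)}"
        )
    rows = []
    totals = {f: 0 for f in families}
    for dataset, df in (("full", full), ("reduced", reduced)):
        for trait, cell in df.groupby("trait"):
            regression = (cell.task_type == "regression").all()
            values = []
            for fam in families:
                sub = cell[cell.family == fam]
                if sub.empty:
                    raise ValueError(f"missing {fam} metric for trait {trait!r}")
                values.append(float(sub.value.iloc[0]))
            best = min(values) if regression else max(values)
            winner = families[values.index(best)]
            totals[winner] += 1
            rows.append({"trait": trait, "dataset": dataset, "best_family": winner,
                         "best_value": best})
    tally = pd.DataFrame(rows)
    tally.attrs["totals"] = totals
    tally.attrs["n_cells"] = len(rows)
    return tally
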