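"""End-to-end scan orchestration: Fst -> iHS -> XP-EHH -> regions -> concordance.

`run_scan` composes the stage functions on in-memory objects and returns the
per-stage tables; `run_pipeline` wraps it with file input/output, a YAML
config, structured logging and a JSON manifest recording thresholds, seeds,
multiple-testing denominators and per-stage SNP counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fst_scan import fst_scan, select_significant
from .genomic_io import (
    GeneAnnotation,
    GeneticMap,
    GenotypeMatrix,
    HaplotypePanel,
    interpolate_cM,
    read_bed,
    read_genetic_map,
    read_genotypes,
    read_haplotypes,
)
from .haplotype_stats import (
    ihs_scan,
    normalize_xpehh,
    standardize_ihs,
    xpehh_scan,
    xpehh_threshold,
)
from .region_detection import (
    assign_population,
    clusters_to_regions,
    concordant_regions,
    ihs_window_scan,
    ld_cluster,
    merge_overlapping,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable of the scan in one place; echoed into the manifest."""

    genotypes_path: str = ""
    labels_path: str = ""
    hap_test_path: str = ""
    hap_ref_path: str = ""
    map_path: str = ""
    genes_path: str = ""
    pop_test: str = "test"
    pop_ref: str = "ref"
    out_dir: str = "sweepscan_run"
    seed: int = 0
    maf_fst: float = 0.05
    maf_ihs: float = 0.10
    hwe_alpha: float = 0.05
    p_B_max: float = 8.6e-6
    p_E_max: float = 1e-3
    ihs_abs_min: float = 2.0
    window: int = 50
    top_fraction: float = 2e-4
    r2_min: float = 0.25
    xpehh_assign: float = 3.0
    xpehh_alpha: float = 0.05
    intergenic_margin_bp: int = 50_000
    ehh_cutoff: float = 0.05
    daf_bins: int = 20

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**data)


def _attach_cM(panel: HaplotypePanel, gmap: GeneticMap) -> HaplotypePanel:
    """Return a panel whose sites carry interpolated genetic positions."""
    sites = [
        dataclasses.replace(s, genetic_pos_cM=float(interpolate_cM(gmap, s.position_bp)))
        for s in panel.sites
    ]
    return HaplotypePanel(
        sites=sites, haplotypes=panel.haplotypes, sample_ids=panel.sample_ids,
        allow_odd=panel.allow_odd,
    )


def run_scan(
    genotypes: GenotypeMatrix,
    panel_test: HaplotypePanel,
    panel_ref: HaplotypePanel,
    genetic_map: GeneticMap,
    annotation: GeneAnnotation | None,
    config: PipelineConfig,
) -> dict:
    """Run all stages on in-memory inputs; returns the per-stage tables.

    The returned dict has keys ``fst``, ``ihs``, ``xpehh``,
    ``regions_by_metric``, ``concordant`` and ``manifest``.
    """
    panel_test = _attach_cM(panel_test, genetic_map)
    panel_ref = _attach_cM(panel_ref, genetic_map)

    # --- Fst stage
    fst = fst_scan(
        genotypes,
        config.pop_test,
        config.pop_ref,
        annotation=annotation,
        maf=config.maf_fst,
        hwe_alpha=config.hwe_alpha,
        p_B_max=config.p_B_max,
        p_E_max=config.p_E_max,
        intergenic_margin_bp=config.intergenic_margin_bp,
    )
    fst_sig = select_significant(fst, p_B_max=config.p_B_max, p_E_max=config.p_E_max)

    # --- iHS stage
    ihs = standardize_ihs(
        ihs_scan(panel_test, cutoff=config.ehh_cutoff, maf=config.maf_ihs),
        n_bins=config.daf_bins,
        maf=config.maf_ihs,
    )

    # --- XP-EHH stage
    xp = normalize_xpehh(xpehh_scan(panel_test, panel_ref, cutoff=config.ehh_cutoff))
    m_xp = int(xp["xpehh_norm"].notna().sum())
    xp_thresh = xpehh_threshold(m_xp, alpha=config.xpehh_alpha)
    xpehh_by_snp = dict(zip(xp["snp_id"], xp["xpehh_norm"]))

    genotypes_test = genotypes.subset_population(config.pop_test)
    regions_by_metric: dict[str, pd.DataFrame] = {}

    # Fst regions: LD-cluster the significant SNPs, attribute by XP-EHH > assign
    fst_by_snp = dict(zip(fst["snp_id"], fst["fst"]))
    clusters = ld_cluster(list(fst_sig["snp_id"]), genotypes_test, r2_min=config.r2_min)
    for c in clusters:
        c.max_fst = max(fst_by_snp.get(s, np.nan) for s in c.snp_ids)
        c.n_significant = c.size
        assign_population(c, xpehh_by_snp, xpehh_min=config.xpehh_assign)
    assigned = [c for c in clusters if c.assigned]
    regions_by_metric["Fst"] = merge_overlapping(clusters_to_regions(assigned, "Fst"))

    # iHS regions: top windows -> candidate SNPs -> LD clusters
    windows, ihs_snps = ihs_window_scan(
        ihs,
        window=config.window,
        score_min=config.ihs_abs_min,
        top_fraction=config.top_fraction,
    )
    ihs_by_snp = dict(zip(ihs["snp_id"], ihs["ihs_std"].abs()))
    ihs_clusters = ld_cluster(ihs_snps, genotypes_test, r2_min=config.r2_min)
    for c in ihs_clusters:
        c.max_abs_ihs = max(ihs_by_snp.get(s, np.nan) for s in c.snp_ids)
    regions_by_metric["iHS"] = merge_overlapping(
        clusters_to_regions(ihs_clusters, "iHS")
    )

    # XP-EHH regions: positive genome-wide-significant SNPs -> LD clusters
    xp_sig = xp[(xp["xpehh_norm"] >= xp_thresh)]
    xp_clusters = ld_cluster(list(xp_sig["snp_id"]), genotypes_test, r2_min=config.r2_min)
    for c in xp_clusters:
        c.max_xpehh = max(xpehh_by_snp.get(s, np.nan) for s in c.snp_ids)
    regions_by_metric["XP-EHH"] = merge_overlapping(
        clusters_to_regions(xp_clusters, "XP-EHH")
    )

    concordant = concordant_regions(regions_by_metric, min_methods=2)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "n_snps_input": genotypes.n_sites,
        "n_snps_fst_scan": int(fst["pass_filters"].sum()),
        "bonferroni_m_fst": int(fst.attrs.get("bonferroni_m", 0)),
        "n_snps_fst_significant": int(len(fst_sig)),
        "n_snps_ihs_scored": int(ihs["ihs_std"].notna().sum()),
        "n_ihs_candidate_snps": len(ihs_snps),
        "n_ihs_windows_selected": int(len(windows)),
        "n_snps_xpehh_scored": m_xp,
        "xpehh_threshold": xp_thresh,
        "n_snps_xpehh_significant": int(len(xp_sig)),
        "n_regions": {k: int(len(v)) for k, v in regions_by_metric.items()},
        "n_concordant_regions": int(len(concordant)),
    }
    return {
        "fst": fst,
        "fst_significant": fst_sig,
        "ihs": ihs,
        "ihs_windows": windows,
        "xpehh": xp,
        "regions_by_metric": regions_by_metric,
        "concordant": concordant,
        "manifest": manifest,
    }


def _write_regions(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    if "metrics" in out.columns:
        out["metrics"] = out["metrics"].map(lambda s: ",".join(sorted(s)))
    if "snp_counts" in out.columns:
        out["snp_counts"] = out["snp_counts"].map(json.dumps)
    out.to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> Path:
    """File-level entry point: read inputs, run the scan, write a run directory.

    Emits fst.tsv, ihs.tsv, xpehh.tsv, per-metric region tables, the
    concordant-region table, a BED export of concordant regions and
    manifest.json. Stage failures abort with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read_inputs"
    try:
        genotypes = read_genotypes(config.genotypes_path, config.labels_path)
        panel_test = read_haplotypes(config.hap_test_path)
        panel_ref = read_haplotypes(config.hap_ref_path)
        gmap = read_genetic_map(config.map_path)
        annotation = read_bed(config.genes_path) if config.genes_path else None
        stage = "scan"
        result = run_scan(genotypes, panel_test, panel_ref, gmap, annotation, config)
        stage = "write_outputs"
        fmt = {"float_format": "%.6g"}
        result["fst"].to_csv(out / "fst.tsv", sep="\t", index=False, **fmt)
        result["ihs"].to_csv(out / "ihs.tsv", sep="\t", index=False, **fmt)
        result["xpehh"].to_csv(out / "xpehh.tsv", sep="\t", index=False, **fmt)
        for metric, df in result["regions_by_metric"].items():
            name = metric.lower().replace("-", "")
            _write_regions(df, out / f"regions_{name}.tsv")
        _write_regions(result["concordant"], out / "concordant_regions.tsv")
        with open(out / "concordant_regions.bed", "w") as fh:
            for r in result["concordant"].itertuples():
                fh.write(f"{r.chromosome}\t{r.start_bp - 1}\t{r.end_bp}\tconcordant\n")
        with open(out / "manifest.json", "w") as fh:
            json.dump(result["manifest"], fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    logger.info("pipeline run complete: %s", out)
    return out
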