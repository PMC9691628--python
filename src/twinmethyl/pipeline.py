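"""End-to-end orchestration: per-sex, per-comparison DMR analysis and the
correlation-network stage, with a manifest of every artifact.

Every study parameter surfaces as a named configuration key with its
standard value as default: 1000 bp windows, seed threshold 1e-4, extension
threshold 0.1 within 1000 bp, 10 kb gene flank, 150 MVPA min/week, 5 kg/m^2
BMI discordance, mapping QC at 70%, soft-threshold power 6 (female) / 9
(male), top 100,000 windows, minimum module size 30, merge cut height 0.25.

Sex partition is enforced before any statistic touches data: a comparison
or network run always starts by subsetting to one sex.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from . import annotation, cohort, dmr_caller, network, overlap_analysis
from .diff_methylation import estimate_common_dispersion, test_all_windows
from .synthetic_data import SyntheticStudy
from .window_counts import rpkm_normalize, select_top_windows

logger = logging.getLogger(__name__)

COMPARISONS = ("pa", "walkability", "bmi")
SEXES = ("M", "F")


class PipelineError(RuntimeError):
    """Raised for clean validation aborts (no discordant pairs etc.)."""


@dataclass
class PipelineConfig:
    window_size: int = 1000
    p_seed: float = 1e-4
    p_extend: float = 0.1
    gap_bp: int = 1000
    thresholds: tuple[float, ...] = dmr_caller.DEFAULT_THRESHOLDS
    gene_flank_bp: int = 10_000
    mapping_min: float = 0.70
    power_female: float = 6.0
    power_male: float = 9.0
    top_n: int = 100_000
    min_module_size: int = 30
    merge_cut_height: float = 0.25
    max_block_size: int = 15_000
    p_filter: float = 0.001
    p_relaxed: float = 0.05
    cluster_window_mb: float = 2.0
    cluster_min_count: int = 3
    dispersion_override: float | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "thresholds" in raw:
            raw["thresholds"] = tuple(raw["thresholds"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["thresholds"] = list(d["thresholds"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def power_for_sex(self, sex: str) -> float:
        return self.power_male if sex == "M" else self.power_female


def pca_dmr_features(
    rpkm: pd.DataFrame,
    dmrs: pd.DataFrame,
    grid: pd.DataFrame,
    low_ids: list[str],
    high_ids: list[str],
) -> dict:
    """PCA of samples over per-DMR mean RPKM, with arm separation score.

    Features are the mean RPKM over each DMR's member windows per sample;
    the mean-centered PCA coordinates on PC1/PC2 are returned together with
    variance explained and the silhouette score of the low/high arms in the
    PC1-2 plane (NaN when undefined).
    """
    samples = list(low_ids) + list(high_ids)
    if len(samples) < 2 or len(dmrs) < 1:
        raise PipelineError("PCA needs >=2 samples and >=1 DMR")
    feats = np.zeros((len(samples), len(dmrs)))
    gw = grid.set_index("window")
    for j, row in enumerate(dmrs.itertuples()):
        members = grid[
            (grid["chrom"] == row.chrom)
            & (grid["start"] >= row.start)
            & (grid["end"] <= row.end)
        ]["window"]
        feats[:, j] = rpkm.loc[members, samples].mean(axis=0).to_numpy()
    n_comp = min(2, len(dmrs), len(samples) - 1)
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(feats - feats.mean(axis=0))
    if n_comp < 2:
        coords = np.column_stack([coords, np.full(len(samples), np.nan)])
    var = list(pca.explained_variance_ratio_) + [np.nan] * (2 - n_comp)
    arm = np.array([0] * len(low_ids) + [1] * len(high_ids))
    sil = np.nan
    if len(set(arm)) == 2 and min((arm == 0).sum(), (arm == 1).sum()) >= 2:
        sil = float(silhouette_score(coords[:, :n_comp], arm))
    return {
        "samples": samples,
        "coords": coords,
        "variance_explained": var,
        "silhouette": sil,
    }


def run_comparison(
    study: SyntheticStudy,
    comparison: str,
    sex: str,
    params: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """One discordance comparison for one sex: QC -> arms -> window tests ->
    DMR calling -> annotation -> per-threshold table -> feature PCA.

    Returns a report bundle (dict); when ``outdir`` is given every table is
    written as TSV and listed in a JSON manifest.
    """
    params = params or PipelineConfig()
    if comparison not in COMPARISONS:
        raise PipelineError(f"unknown comparison {comparison!r}")
    if sex not in SEXES:
        raise PipelineError(f"unknown sex {sex!r}")
    traits = cohort.apply_mapping_qc(study.cohort, params.mapping_min)
    traits = traits[traits["sex"] == sex]
    low_ids, high_ids = cohort.discordant_arms(traits, comparison)
    if not low_ids:
        raise PipelineError(f"no {sex} pairs discordant for {comparison}")
    logger.info(
        "%s/%s: %d discordant pairs", comparison, sex, len(low_ids)
    )
    cm = study.counts.subset_samples(low_ids + high_ids)
    model = estimate_common_dispersion(
        cm, (low_ids, high_ids), phi_override=params.dispersion_override
    )
    results = test_all_windows(cm, (low_ids, high_ids), model, grid=study.grid)
    dmrs = dmr_caller.seed_and_extend(
        results,
        p_seed=params.p_seed,
        p_extend=params.p_extend,
        gap_bp=params.gap_bp,
        grid=study.grid,
    )
    dmrs = annotation.annotate_dmrs(
        dmrs,
        study.genes,
        reference=study.reference,
        flank=params.gene_flank_bp,
        cluster_window_mb=params.cluster_window_mb,
        cluster_min_count=params.cluster_min_count,
    )
    table = dmr_caller.threshold_table(
        results, params.thresholds, params.p_extend, params.gap_bp
    )
    gene_ids = [g for row in dmrs["genes"] for g in row.split(";") if g]
    categories = annotation.assign_categories(gene_ids, study.gene_categories)
    rpkm = rpkm_normalize(cm, study.grid)
    pca = None
    if len(dmrs) >= 1:
        pca = pca_dmr_features(rpkm, dmrs, study.grid, low_ids, high_ids)
    report = {
        "comparison": comparison,
        "sex": sex,
        "n_pairs": len(low_ids),
        "low_ids": low_ids,
        "high_ids": high_ids,
        "dispersion": model.phi,
        "results": results,
        "dmrs": dmrs,
        "threshold_table": table,
        "counts": dmr_caller.classify_multi_window(dmrs),
        "categories": categories,
        "pca": pca,
    }
    if outdir is not None:
        _write_comparison(report, params, Path(outdir))
    return report


def _write_comparison(report: dict, params: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"{report['comparison']}_{report['sex']}"
    artifacts = {}

    def save(name: str, df: pd.DataFrame) -> None:
        path = outdir / f"{tag}_{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        artifacts[name] = path.name

    save("window_results", report["results"])
    save("dmrs", report["dmrs"])
    save("threshold_table", report["threshold_table"])
    save("categories", report["categories"].rename("count").reset_index())
    if report["pca"] is not None:
        coords = pd.DataFrame(
            report["pca"]["coords"], columns=["PC1", "PC2"]
        ).assign(sample=report["pca"]["samples"])
        save("pca_coords", coords)
    manifest = {
        "comparison": report["comparison"],
        "sex": report["sex"],
        "n_pairs": report["n_pairs"],
        "dispersion": report["dispersion"],
        "dmr_counts": report["counts"],
        "silhouette": None if report["pca"] is None else report["pca"]["silhouette"],
        "parameters": {**asdict(params), "thresholds": list(params.thresholds)},
        "artifacts": artifacts,
    }
    (outdir / f"{tag}_manifest.json").write_text(json.dumps(manifest, indent=2))


def run_network(
    study: SyntheticStudy,
    sex: str,
    params: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Correlation-network stage for one sex: top-N window selection ->
    module detection -> module-trait correlation with p < 0.001 summary."""
    params = params or PipelineConfig()
    traits = cohort.apply_mapping_qc(study.cohort, params.mapping_min)
    traits = traits[traits["sex"] == sex]
    samples = traits["participant_id"].tolist()
    if len(samples) < 4:
        raise PipelineError(f"need >=4 {sex} samples for the network stage")
    cm = study.counts.subset_samples(samples)
    rpkm = rpkm_normalize(cm, study.grid)
    top = select_top_windows(rpkm, params.top_n)
    profiles = rpkm.loc[top, samples].to_numpy().T  # samples x windows
    cfg = network.NetworkConfig(
        power=params.power_for_sex(sex),
        min_module_size=params.min_module_size,
        merge_cut_height=params.merge_cut_height,
        max_block_size=params.max_block_size,
        top_n=params.top_n,
        random_state=params.seed,
    )
    labels = network.blockwise_modules(profiles, cfg)
    colors = network.module_colors(labels)
    n_modules = len(set(labels) - {network.GREY})
    names = [
        network.MODULE_COLORS[m] if m < len(network.MODULE_COLORS) else f"module_{m}"
        for m in range(n_modules)
    ]
    numeric = cohort.numeric_trait_frame(traits).loc[samples]
    report: dict = {
        "sex": sex,
        "power": cfg.power,
        "samples": samples,
        "top_windows": top,
        "labels": labels,
        "colors": colors,
        "n_modules": n_modules,
    }
    if n_modules:
        eig = network.eigengene_matrix(profiles, labels, names=names)
        eig.index = pd.Index(samples, name="sample")
        full, filtered = network.module_trait_correlation(
            eig, numeric, p_filter=params.p_filter
        )
        report.update(eigengenes=eig, module_trait=full, module_trait_filtered=filtered)
        if filtered.r.empty:
            logger.info("no module-trait correlation at p < %g", params.p_filter)
    else:
        logger.warning("no modules detected for sex %s", sex)
        report.update(eigengenes=None, module_trait=None, module_trait_filtered=None)
    if outdir is not None:
        _write_network(report, study, params, Path(outdir))
    return report


def _write_network(
    report: dict, study: SyntheticStudy, params: PipelineConfig, outdir: Path
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"network_{report['sex']}"
    artifacts = {}
    gw = study.grid.set_index("window")
    assign = gw.loc[report["top_windows"], ["chrom", "start", "end"]].reset_index()
    assign["module"] = report["colors"]
    path = outdir / f"{tag}_modules.tsv"
    assign.to_csv(path, sep="\t", index=False)
    artifacts["modules"] = path.name
    if report["eigengenes"] is not None:
        p = outdir / f"{tag}_eigengenes.tsv"
        report["eigengenes"].to_csv(p, sep="\t", float_format="%.6g")
        artifacts["eigengenes"] = p.name
        for key, res in (
            ("module_trait", report["module_trait"]),
            ("module_trait_filtered", report["module_trait_filtered"]),
        ):
            p = outdir / f"{tag}_{key}.tsv"
            merged = res.r.round(4).astype(str) + " (p=" + res.p.map(
                lambda v: f"{v:.2e}" if pd.notna(v) else "NA"
            ) + ")"
            merged.to_csv(p, sep="\t")
            artifacts[key] = p.name
    manifest = {
        "sex": report["sex"],
        "power": report["power"],
        "n_modules": report["n_modules"],
        "top_n": params.top_n,
        "n_top_windows_used": int(len(report["top_windows"])),
        "parameters": {**asdict(params), "thresholds": list(params.thresholds)},
        "artifacts": artifacts,
    }
    (outdir / f"{tag}_manifest.json").write_text(json.dumps(manifest, indent=2))


def run_all(
    study: SyntheticStudy,
    params: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """All six comparisons (3 traits x 2 sexes), cross-trait overlaps per
    sex, and the per-sex network stage."""
    params = params or PipelineConfig()
    reports: dict = {"comparisons": {}, "overlaps": {}, "networks": {}}
    for sex in SEXES:
        dmr_sets = {}
        result_sets = {}
        for comp in COMPARISONS:
            try:
                rep = run_comparison(study, comp, sex, params, outdir)
            except PipelineError as exc:
                logger.warning("skipping %s/%s: %s", comp, sex, exc)
                continue
            reports["comparisons"][(comp, sex)] = rep
            dmr_sets[comp] = rep["dmrs"]
            result_sets[comp] = rep["results"]
        if len(dmr_sets) == 3:
            venn = overlap_analysis.venn3(*(dmr_sets[c] for c in COMPARISONS))
            table = overlap_analysis.overlap_report(
                dmr_sets, result_sets, p_relaxed=params.p_relaxed
            )
            reports["overlaps"][sex] = {"venn": venn, "table": table}
            if outdir is not None:
                out = Path(outdir)
                out.mkdir(parents=True, exist_ok=True)
                (out / f"overlap_{sex}_venn.json").write_text(json.dumps(venn, indent=2))
                table.to_csv(out / f"overlap_{sex}.tsv", sep="\t", index=False)
        try:
            reports["networks"][sex] = run_network(study, sex, params, outdir)
        except PipelineError as exc:
            logger.warning("skipping network for %s: %s", sex, exc)
    return reports
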