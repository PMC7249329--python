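"""End-to-end orchestration over a self-contained input directory.

Stage order follows the analysis skeleton: probe filtering ->
differential methylation -> probe clusters -> consensus subtyping ->
enrichment suite -> age estimation -> multi-omic integration -> report.
Every stage is a pure function of (files, config, seed): it reads the
raw inputs and/or the files written by earlier stages, writes its own
TSV/BED/JSON outputs plus a summary fragment, and can therefore be
re-run standalone on prior-stage files.  The assembled summary JSON is
deterministic (byte-stable across reruns with the same config and seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clock import ClockModel, EpigeneticClock, age_acceleration, passage_factor
from .clusters import (
    bounded_cluster,
    clusters_to_bed_frame,
    summarize_clusters,
    top_variable_clusters,
)
from .diffmeth import BetaMatrix, filter_probes, fit_moderated_f
from .enrichment import (
    fisher_enrichment,
    fold_enrichment,
    peak_feature_distribution,
    probe_track_membership,
    stratified_delta_beta,
)
from .integrate import (
    assign_features_to_genes,
    expression_correlation,
    geneset_lad_distance_test,
    multiomic_overlap,
)
from .intervals import AnnotationTrack, GenomicInterval, read_bed
from .subtype import ConsensusClustering, pca_embed
from .tracksig import call_poised_enhancers, lad_signal_enrichment, read_signal_tsv

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "run_stage",
    "STAGES",
    "SUMMARY_SCHEMA_VERSION",
]

SUMMARY_SCHEMA_VERSION = 1

log = logging.getLogger("ladomics")


@dataclass
class PipelineConfig:
    """Validated paths and parameter blocks for a pipeline run."""

    input_dir: str
    output_dir: str
    seed: int = 0
    det_threshold: float = 0.01
    shrink: bool = True
    use_mvalues: bool = False
    q_threshold: float = 0.05
    max_gap: int = 500
    max_width: int = 1500
    n_top_clusters: int = 5000
    max_k: int = 6
    reps: int = 1000
    p_item: float = 0.8
    p_feature: float = 1.0
    promoter_window: int = 2000
    poised_max_gap: int = 1500
    pseudocount: float = 0.5

    REQUIRED_FILES = (
        "beta.tsv",
        "detection_p.tsv",
        "probe_annotation.tsv",
        "sample_sheet.tsv",
        "genes.tsv",
        "diff_peaks.tsv",
        "expression.tsv",
        "clock.tsv",
        "clock.yaml",
        "tracks/laminA_LAD.bed",
        "tracks/laminB_LAD.bed",
    )

    def validate(self) -> "PipelineConfig":
        indir = Path(self.input_dir)
        missing = [f for f in self.REQUIRED_FILES if not (indir / f).exists()]
        if missing:
            raise FileNotFoundError(f"input directory {indir} is missing: {missing}")
        return self

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    # -- path helpers --------------------------------------------------------
    @property
    def indir(self) -> Path:
        return Path(self.input_dir)

    @property
    def outdir(self) -> Path:
        return Path(self.output_dir)

    def fragment_path(self, stage: str) -> Path:
        return self.outdir / "fragments" / f"{stage}.json"

    def write_fragment(self, stage: str, fragment: dict) -> None:
        self.fragment_path(stage).parent.mkdir(parents=True, exist_ok=True)
        self.fragment_path(stage).write_text(
            json.dumps(fragment, indent=1, sort_keys=True)
        )

    def read_fragment(self, stage: str) -> dict:
        path = self.fragment_path(stage)
        if not path.exists():
            raise FileNotFoundError(
                f"stage {stage!r} has not been run (missing {path})"
            )
        return json.loads(path.read_text())


def _round(x: float, nd: int = 6) -> float:
    return float(np.round(float(x), nd))


# -- shared loaders ----------------------------------------------------------

def _load_annot(cfg: PipelineConfig) -> pd.DataFrame:
    return pd.read_csv(cfg.indir / "probe_annotation.tsv", sep="\t", index_col=0)


def _load_sheet(cfg: PipelineConfig) -> pd.DataFrame:
    return pd.read_csv(cfg.indir / "sample_sheet.tsv", sep="\t", index_col=0)


def _load_genes(cfg: PipelineConfig) -> pd.DataFrame:
    return pd.read_csv(cfg.indir / "genes.tsv", sep="\t", index_col=0)


def _load_peaks(cfg: PipelineConfig) -> pd.DataFrame:
    return pd.read_csv(cfg.indir / "diff_peaks.tsv", sep="\t")


def _load_filtered(cfg: PipelineConfig) -> BetaMatrix:
    return BetaMatrix.from_tsv(cfg.outdir / "beta_filtered.tsv")


def _load_diff_table(cfg: PipelineConfig) -> pd.DataFrame:
    return pd.read_csv(cfg.outdir / "diffmeth.tsv", sep="\t", index_col=0)


def _load_tracks(cfg: PipelineConfig) -> dict[str, AnnotationTrack]:
    tracks = {
        "laminA_LAD": read_bed(cfg.indir / "tracks" / "laminA_LAD.bed"),
        "laminB_LAD": read_bed(cfg.indir / "tracks" / "laminB_LAD.bed"),
    }
    for p in sorted((cfg.indir / "tracks").glob("H3K*.bed")):
        tracks[p.stem] = read_bed(p, name=p.stem)
    return tracks


def _peaks_track(peaks: pd.DataFrame) -> AnnotationTrack:
    return AnnotationTrack(
        (
            GenomicInterval(r.chrom, int(r.start), int(r.end), name=r.name)
            for r in peaks.itertuples()
        ),
        name="peaks",
    )


# -- stages ------------------------------------------------------------------

def stage_filter(cfg: PipelineConfig) -> dict:
    """Detection and annotation-flag probe filtering."""
    beta = BetaMatrix.from_tsv(cfg.indir / "beta.tsv")
    det = pd.read_csv(cfg.indir / "detection_p.tsv", sep="\t", index_col=0)
    annot = _load_annot(cfg)
    log.info(
        "filtering %d probes (detection p > %.3g in any of %d samples)",
        beta.shape[0], cfg.det_threshold, beta.shape[1],
    )
    filtered, removal_log = filter_probes(beta, det, annot, cfg.det_threshold)
    filtered.to_tsv(cfg.outdir / "beta_filtered.tsv")
    return removal_log


def stage_diffmeth(cfg: PipelineConfig) -> dict:
    """Moderated F-test of case vs control per probe."""
    filtered = _load_filtered(cfg)
    sheet = _load_sheet(cfg)
    table = fit_moderated_f(
        filtered, sheet, shrink=cfg.shrink,
        use_mvalues=cfg.use_mvalues, q_threshold=cfg.q_threshold,
    )
    table.to_csv(cfg.outdir / "diffmeth.tsv", sep="\t", float_format="%.6g")
    n_sig = int(table["significant"].sum())
    log.info(
        "differential methylation: %d/%d significant at q < %g",
        n_sig, len(table), cfg.q_threshold,
    )
    return {
        "n_tested": int(len(table)),
        "n_significant": n_sig,
        "median_delta_beta": _round(table["delta_beta"].median()),
    }


def stage_clusters(cfg: PipelineConfig) -> dict:
    """Bounded probe clustering and top-variable-cluster selection."""
    filtered = _load_filtered(cfg)
    annot = _load_annot(cfg).loc[filtered.probe_ids]
    clusters = summarize_clusters(
        bounded_cluster(annot, cfg.max_gap, cfg.max_width), filtered
    )
    top = top_variable_clusters(clusters, cfg.n_top_clusters)
    clusters_to_bed_frame(top).to_csv(
        cfg.outdir / "top_clusters.bed", sep="\t", index=False, header=False,
        float_format="%.6g",
    )
    feat = np.vstack([c.cluster_values for c in top])  # clusters x samples
    pd.DataFrame(
        feat, index=[c.cluster_id for c in top], columns=filtered.sample_ids
    ).to_csv(cfg.outdir / "cluster_values.tsv", sep="\t", float_format="%.6g")
    return {"n_clusters": len(clusters), "n_top": len(top)}


def stage_subtype(cfg: PipelineConfig) -> dict:
    """Consensus clustering of samples over the top clusters, plus PCA."""
    feat = pd.read_csv(cfg.outdir / "cluster_values.tsv", sep="\t", index_col=0)
    sample_ids = feat.columns
    cc = ConsensusClustering(
        max_k=cfg.max_k, reps=cfg.reps, p_item=cfg.p_item,
        p_feature=cfg.p_feature, random_state=cfg.seed,
    ).fit(feat.to_numpy().T)
    res = cc.result_
    for k, mat in res.consensus.items():
        pd.DataFrame(mat, index=sample_ids, columns=sample_ids).to_csv(
            cfg.outdir / f"consensus_k{k}.tsv", sep="\t", float_format="%.6g"
        )
    assign = pd.DataFrame(
        {f"k{k}": res.assignments[k] for k in res.assignments}, index=sample_ids
    )
    assign.to_csv(cfg.outdir / "assignments.tsv", sep="\t")
    emb = pca_embed(feat.to_numpy(), n_components=2)
    pd.DataFrame(
        emb["coordinates"], index=sample_ids, columns=["PC1", "PC2"]
    ).to_csv(cfg.outdir / "pca.tsv", sep="\t", float_format="%.6g")
    log.info("consensus clustering: chosen_k=%d (reps=%d, p_item=%g)",
             res.chosen_k, cfg.reps, cfg.p_item)
    return {
        "chosen_k": int(res.chosen_k),
        "delta_area": {str(k): _round(v) for k, v in res.delta_area.items()},
        "pac": {str(k): _round(v) for k, v in res.pac.items()},
        "pc1_variance_fraction": _round(emb["explained_variance_ratio"][0]),
    }


def stage_enrich(cfg: PipelineConfig) -> dict:
    """Stratified delta-beta, probe and peak enrichment, signal ratios."""
    filtered = _load_filtered(cfg)
    table = _load_diff_table(cfg)
    sheet = _load_sheet(cfg)
    genes = _load_genes(cfg)
    peaks = _load_peaks(cfg)
    tracks = _load_tracks(cfg)
    lamin_a = tracks["laminA_LAD"]
    histone = {n: t for n, t in tracks.items() if n.startswith("H3K")}
    annot = _load_annot(cfg).loc[filtered.probe_ids]

    membership = probe_track_membership(annot, tracks)
    strata = {
        "all": np.ones(len(annot), dtype=bool),
        "non_LAD": ~membership["laminA_LAD"].to_numpy(),
        "laminA_LAD": membership["laminA_LAD"].to_numpy(),
        "soloWCGW_PMD": (annot["solo_wcgw"] & annot["in_pmd"]).to_numpy(),
        "soloWCGW_HMD": (annot["solo_wcgw"] & annot["in_hmd"]).to_numpy(),
        **{m: membership[m].to_numpy() for m in histone},
    }
    strata_table = stratified_delta_beta(filtered, sheet, strata)
    strata_table.to_csv(cfg.outdir / "strata_delta_beta.tsv", sep="\t",
                        float_format="%.6g")

    sig = table["significant"].to_numpy()
    hyper = sig & (table["delta_beta"].to_numpy() > 0)
    hypo = sig & (table["delta_beta"].to_numpy() < 0)
    enr_rows = []
    for tname in tracks:
        in_track = membership[tname].to_numpy()
        for sel_name, sel in (("all", sig), ("hyper", hyper), ("hypo", hypo)):
            if sel.sum() == 0:
                continue
            r = fold_enrichment(sel, in_track, track_name=tname)
            enr_rows.append(
                {
                    "track": tname, "selection": sel_name,
                    "observed": r.observed, "expected": _round(r.expected),
                    "signed_fold": _round(r.signed_fold), "fold": _round(r.fold),
                    "chi2": _round(r.statistic), "p": r.p_value,
                }
            )
    enr = pd.DataFrame(enr_rows)
    enr.to_csv(cfg.outdir / "probe_enrichment.tsv", sep="\t", index=False,
               float_format="%.6g")

    sig_peaks = peaks[peaks["significant"]]
    promoters = AnnotationTrack(
        (
            GenomicInterval(
                r.chrom, max(int(r.tss) - cfg.promoter_window, 0),
                int(r.tss) + cfg.promoter_window,
            )
            for r in genes.itertuples()
        ),
        name="promoters",
    )
    gene_track = AnnotationTrack(
        (
            GenomicInterval(r.chrom, int(r.start), int(r.end), name=r.Index)
            for r in genes.itertuples()
        ),
        name="genes",
    )
    feature_tracks = {
        "genes": gene_track, "promoters": promoters,
        "laminA_LAD": lamin_a, "laminB_LAD": tracks["laminB_LAD"],
    }
    enh_path = cfg.indir / "tracks" / "active_enhancers.bed"
    if enh_path.exists():
        feature_tracks["active_enhancers"] = read_bed(enh_path)
    if "H3K4me1" in histone:
        feature_tracks["poised_enhancers"] = call_poised_enhancers(
            histone["H3K4me1"], cfg.poised_max_gap
        )
    dist = peak_feature_distribution(
        _peaks_track(sig_peaks), feature_tracks,
        lad_track_names=("laminA_LAD", "laminB_LAD"),
    )
    dist.to_csv(cfg.outdir / "peak_distribution.tsv", sep="\t",
                float_format="%.6g")

    in_lad_all = np.array(
        [lamin_a.overlaps(r.chrom, int(r.start), int(r.end))
         for r in peaks.itertuples()]
    )
    sel_all = peaks["significant"].to_numpy()
    peak_enr = fold_enrichment(sel_all, in_lad_all, track_name="laminA_LAD")
    fisher = fisher_enrichment(
        np.array(
            [
                [peak_enr.observed, peak_enr.n_selected - peak_enr.observed],
                [
                    peak_enr.n_universe_in_track - peak_enr.observed,
                    peak_enr.n_universe - peak_enr.n_selected
                    - peak_enr.n_universe_in_track + peak_enr.observed,
                ],
            ]
        )
    )
    fragment = {
        "lad_stratum_median_delta_beta": _round(
            strata_table.loc["laminA_LAD", "median_delta_beta"]
        ),
        "lad_probe_signed_fold": _round(
            enr.set_index(["track", "selection"]).loc[
                ("laminA_LAD", "all"), "signed_fold"
            ]
        ),
        "peak_lad_signed_fold": _round(peak_enr.signed_fold),
        "peak_lad_fisher_p": fisher["p_two_sided"],
        "n_significant_peaks": int(sel_all.sum()),
    }

    chip_path = cfg.indir / "chip_signal.tsv"
    if chip_path.exists():
        chip = read_signal_tsv(chip_path)
        inp = read_signal_tsv(cfg.indir / "input_signal.tsv")
        sig_res = lad_signal_enrichment(chip, inp, cfg.pseudocount)
        sig_res["per_region"].to_csv(
            cfg.outdir / "lad_signal_ratios.tsv", sep="\t", index=False,
            float_format="%.6g",
        )
        fragment["track_signal"] = {
            "median_log2_ratio": {k: _round(v) for k, v in sig_res["medians"].items()},
            "wilcoxon_p": sig_res["p"],
        }
    return fragment


def stage_age(cfg: PipelineConfig) -> dict:
    """Clock application, passage factor, subgroup age acceleration."""
    beta = BetaMatrix.from_tsv(cfg.indir / "beta.tsv")  # keeps clock probes
    sheet = _load_sheet(cfg)
    model = ClockModel.from_files(cfg.indir / "clock.tsv", cfg.indir / "clock.yaml")
    est = EpigeneticClock(model, missing_policy="error")
    X = beta.values.T
    ages = pd.DataFrame(
        {
            "linear_score": est.score_samples(X),
            "dnam_age": est.predict(X),
            "chronological_age": sheet.loc[X.index, "age_years"],
        },
        index=X.index,
    )
    ages["delta_age"] = ages["dnam_age"] - ages["chronological_age"]
    ages["rho"] = [
        passage_factor(int(p), float(h), float(s))
        for p, h, s in zip(sheet["passage"], sheet["harvested"], sheet["seeded"])
    ]
    ages.to_csv(cfg.outdir / "age_estimates.tsv", sep="\t", float_format="%.6g")

    # subgroup labels: consensus assignment at the chosen K
    assign = pd.read_csv(cfg.outdir / "assignments.tsv", sep="\t", index_col=0)
    chosen_k = cfg.read_fragment("subtype")["chosen_k"]
    labels = assign.loc[ages.index, f"k{chosen_k}"].astype(str)
    accel = age_acceleration(ages, labels, adjust_rho=True)
    accel.to_csv(cfg.outdir / "age_acceleration.tsv", sep="\t",
                 float_format="%.6g")
    return {
        "median_delta_age_by_subgroup": {
            str(k): _round(v) for k, v in accel["median_delta_age"].items()
        },
    }


def stage_integrate(cfg: PipelineConfig) -> dict:
    """Multi-omic gene-set overlaps and the LAD-distance test."""
    table = _load_diff_table(cfg)
    genes = _load_genes(cfg)
    peaks = _load_peaks(cfg)
    expr = pd.read_csv(cfg.indir / "expression.tsv", sep="\t", index_col=0)
    annot = _load_annot(cfg)
    tracks = _load_tracks(cfg)

    de_genes = set(expr.index[expr["significant"]])
    sig_peaks = peaks[peaks["significant"]]
    peak_gene_map = assign_features_to_genes(_peaks_track(sig_peaks), genes)
    accessible_genes = set().union(*peak_gene_map.values()) if peak_gene_map else set()
    sig_probe_ids = table.index[table["significant"]]
    sig_annot = annot.loc[sig_probe_ids]
    probe_ivs = AnnotationTrack(
        (
            GenomicInterval(c, int(p) - 1, int(p), name=str(pid))
            for pid, (c, p) in sig_annot[["chrom", "pos"]].iterrows()
        ),
        name="sig_probes",
    )
    probe_gene_map = assign_features_to_genes(probe_ivs, genes)
    methylated_genes = set().union(*probe_gene_map.values()) if probe_gene_map else set()
    overlap = multiomic_overlap(de_genes, accessible_genes, methylated_genes)
    (cfg.outdir / "multiomic_overlap.json").write_text(
        json.dumps(overlap, indent=1, sort_keys=True)
    )

    lad_union = AnnotationTrack(
        list(tracks["laminA_LAD"]) + list(tracks["laminB_LAD"]), name="LAD_union"
    )
    de_acc = overlap["members"]["de_and_accessible"]
    gene_sets = {"all_genes": list(genes.index), "de_genes": sorted(de_genes)}
    if len(de_acc) >= 2:
        gene_sets["de_and_accessible"] = de_acc
    lad_dist = geneset_lad_distance_test(gene_sets, genes, lad_union)
    corr = expression_correlation(expr["mean_fpkm_case"], expr["mean_fpkm_control"])
    return {
        "n_de_genes": len(de_genes),
        "overlap_counts": {
            k: overlap["counts"][k]
            for k in ("de_and_accessible", "de_and_methylated", "all_three")
        },
        "lad_distance_medians": {k: _round(v) for k, v in lad_dist["medians"].items()},
        "lad_distance_p": {
            f"{a}_vs_{b}": p for (a, b), p in lad_dist["pairwise_p"].items()
        },
        "case_control_expression_r2": _round(corr["r_squared"]),
    }


def stage_report(cfg: PipelineConfig) -> dict:
    """Assemble the versioned summary JSON from the stage fragments."""
    summary: dict[str, Any] = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "package_version": __version__,
        "seed": cfg.seed,
        "settings": {
            "detection_threshold": cfg.det_threshold,
            "variance_moderation": bool(cfg.shrink),
            "value_scale": "M" if cfg.use_mvalues else "beta",
            "q_threshold": cfg.q_threshold,
            "welch_variant": "unpaired",
            "yates_correction": "capped",
        },
    }
    for stage in ("filter", "diffmeth", "clusters", "subtype", "enrich",
                  "age", "integrate"):
        fragment = cfg.read_fragment(stage)
        if stage == "enrich" and "track_signal" in fragment:
            summary["track_signal"] = fragment.pop("track_signal")
        summary[stage] = fragment
    (cfg.outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True)
    )
    with (cfg.outdir / "run.log").open("w") as fh:
        fh.write(
            f"ladomics {__version__}\nseed {cfg.seed}\n"
            f"settings {json.dumps(summary['settings'], sort_keys=True)}\n"
        )
    return summary


STAGES: dict[str, Callable[[PipelineConfig], dict]] = {
    "filter": stage_filter,
    "diffmeth": stage_diffmeth,
    "clusters": stage_clusters,
    "subtype": stage_subtype,
    "enrich": stage_enrich,
    "age": stage_age,
    "integrate": stage_integrate,
    "report": stage_report,
}


def run_stage(cfg: PipelineConfig, stage: str) -> dict:
    """Run one named stage; prerequisite files must already exist."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; one of {list(STAGES)}")
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    result = STAGES[stage](cfg)
    if stage != "report":
        cfg.write_fragment(stage, result)
    return result


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the assembled summary dict.

    Raises on the first failing stage; outputs of completed stages are
    retained in the output directory.
    """
    config.validate()
    summary: dict | None = None
    for stage in STAGES:
        try:
            result = run_stage(config, stage)
        except Exception:
            log.error("stage %r failed", stage)
            raise
        if stage == "report":
            summary = result
    assert summary is not None
    return summary
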