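"""End-to-end orchestration: simulate -> smooth -> call -> combine ->
binarize -> learn -> segment -> enrich -> profile -> stats.

Every stage writes plain files into the run directory so any stage can be
re-run independently; a manifest records the config snapshot, per-stage
outputs with checksums, and wall-clock times.  Stage parameters default
to the study conventions (null quantiles 0.75/0.95/0.99, 50-bp windows,
15 states, 400-bp promoters, 1000-bp profile windows, specificity cuts
0.2/0.9, GO gates 50/10, dendrogram cut 1.0).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import annotate, cher, hmm, io, preprocess, sim, stats
from .containers import BinaryMatrix, Segmentation

log = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate",
    "smooth",
    "callchers",
    "combine",
    "binarize",
    "learn",
    "segment",
    "enrich",
    "profile",
    "stats",
)


@dataclass
class PipelineConfig:
    outdir: str = "tilechrom_run"
    seed: int = 0
    stages: Sequence[str] = ALL_STAGES
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    # preprocess
    smooth_window_bp: int = 150
    smooth_min_nonzero: int = 3
    biweight_c: float = 5.0
    # cher calling
    quantiles: Sequence[float] = (0.75, 0.95, 0.99)
    min_probes: int = 2
    merge_gap_bp: int = 50
    min_null_probes: int = 1000
    fixed_threshold: Optional[float] = None  # bypass null estimation when set
    broad_marks: Sequence[str] = ("H3K27me3",)
    broad_quantile: float = 0.75
    broad_mode: str = "union"  # union | replace | off
    # state model
    n_states: int = 15
    n_restarts: int = 5
    em_tol: float = 1e-4
    em_max_iter: int = 500
    # annotation / profiles
    promoter_bp: int = 400
    profile_window_bp: int = 1000
    min_gene_bp: int = 1000
    min_intergenic_bp: int = 1100
    profile_marks: Sequence[str] = ()
    # downstream stats
    specificity_low: float = 0.2
    specificity_high: float = 0.9
    go_min_parent: int = 50
    go_min_subset: int = 10
    cluster_cut: float = 1.0
    width_resolution: int = 200
    silent_threshold: float = 0.0

    def validate(self) -> List[str]:
        problems = []
        for s in self.stages:
            if s not in ALL_STAGES:
                problems.append(f"unknown stage {s!r}")
        for q in list(self.quantiles) + [self.broad_quantile]:
            if not 0 < q < 1:
                problems.append(f"quantile {q} outside (0, 1)")
        if self.n_states < 1:
            problems.append("n_states must be >= 1")
        if self.min_probes < 1:
            problems.append("min_probes must be >= 1")
        if self.promoter_bp <= 0:
            problems.append("promoter_bp must be positive")
        if not (0 <= self.specificity_low <= self.specificity_high <= 1):
            problems.append("specificity cuts must satisfy 0 <= low <= high <= 1")
        if self.broad_mode not in ("union", "replace", "off"):
            problems.append(f"broad_mode {self.broad_mode!r} not in union/replace/off")
        if self.width_resolution <= 0:
            problems.append("width_resolution must be positive")
        return problems


def validate_config(raw: dict) -> PipelineConfig:
    """Build a config from a plain dict, filling study defaults.

    Unknown keys anywhere are an error (guards against silent typos);
    out-of-range values raise with every problem listed.
    """
    raw = dict(raw or {})
    sim_raw = raw.pop("sim", {})
    known = {f.name for f in dataclasses.fields(PipelineConfig)} - {"sim"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    sim_known = {f.name for f in dataclasses.fields(sim.SimConfig)}
    sim_unknown = set(sim_raw) - sim_known
    if sim_unknown:
        raise ValueError(f"unknown sim config keys: {sorted(sim_unknown)}")
    for key in ("chrom_names", "chrom_lengths", "chrom_classes", "mark_names", "tissues"):
        if key in sim_raw and sim_raw[key] is not None:
            sim_raw[key] = tuple(sim_raw[key])
    cfg = PipelineConfig(sim=sim.SimConfig(**sim_raw), **raw)
    problems = cfg.validate()
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    return cfg


def config_report(cfg: PipelineConfig) -> dict:
    """Echo the fully resolved config (defaults filled) as plain data."""
    d = dataclasses.asdict(cfg)
    d["sim"] = cfg.sim.to_dict()
    d["stages"] = list(cfg.stages)
    for k in ("quantiles", "broad_marks", "profile_marks"):
        d[k] = list(d[k])
    return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    outputs: Dict[str, List[str]] = field(default_factory=dict)
    checksums: Dict[str, str] = field(default_factory=dict)
    seconds: Dict[str, float] = field(default_factory=dict)

    def record(self, stage: str, paths: Sequence[Path], dt: float) -> None:
        self.outputs[stage] = [str(p) for p in paths]
        for p in paths:
            self.checksums[str(p)] = _sha256(Path(p))
        self.seconds[stage] = round(dt, 3)

    def write(self, path) -> None:
        io.write_json(
            {
                "config": self.config,
                "outputs": self.outputs,
                "checksums": self.checksums,
                "seconds": self.seconds,
            },
            path,
        )


class PipelineError(RuntimeError):
    pass


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in dependency order.

    Fails fast with the offending stage named; a stage whose inputs were
    produced by a disabled earlier stage raises a dependency error naming
    the stage to enable.
    """
    problems = cfg.validate()
    if problems:
        raise PipelineError("invalid config: " + "; ".join(problems))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config_report(cfg))
    enabled = list(cfg.stages)

    def need(stage: str, dep: str) -> None:
        if dep not in enabled:
            raise PipelineError(
                f"stage '{stage}' requires outputs of disabled stage '{dep}'; enable '{dep}' first"
            )

    scfg = cfg.sim
    annotation = None
    truths: Dict[str, sim.PlantedTruth] = {}
    tracks: Dict[str, dict] = {}
    expression = None
    go_table = None

    if "simulate" in enabled:
        t0 = time.perf_counter()
        annotation = sim.generate_genome(scfg)
        paths = []
        io.write_gff3(annotation, outdir / "annotation.gff3")
        io.write_chrom_table(annotation, outdir / "chromosomes.tsv")
        paths += [outdir / "annotation.gff3", outdir / "chromosomes.tsv"]
        stage_names = list(scfg.tissues) + [
            f"D{i}" for i in range(1, 9 - len(scfg.tissues))
        ]
        expression = sim.simulate_expression(
            annotation, n_stages=len(stage_names), stage_names=stage_names, seed=scfg.seed
        )
        io.write_expression(expression, outdir / "expression.tsv")
        paths.append(outdir / "expression.tsv")
        go_table = sim.simulate_go_annotation(annotation, seed=scfg.seed)
        go_table.to_csv(outdir / "go_annotation.tsv", sep="\t", index=False)
        paths.append(outdir / "go_annotation.tsv")
        for ti, tissue in enumerate(scfg.tissues):
            truth = sim.plant_states(scfg, tissue_index=ti)
            truths[tissue] = truth
            io.write_truth_bed(truth, outdir / f"truth_{tissue}.bed")
            paths.append(outdir / f"truth_{tissue}.bed")
            tissue_tracks = sim.simulate_tracks(truth, scfg, tissue_index=ti)
            tracks[tissue] = tissue_tracks
            for (mark, rep), tr in tissue_tracks.items():
                p = outdir / f"track_{tissue}_{mark}_rep{rep + 1}.tsv"
                io.write_track(tr, p)
                paths.append(p)
        manifest.record("simulate", paths, time.perf_counter() - t0)

    if "smooth" in enabled:
        need("smooth", "simulate")
        t0 = time.perf_counter()
        paths = []
        for tissue, tissue_tracks in tracks.items():
            for key, tr in list(tissue_tracks.items()):
                sm = preprocess.smooth_running_median(
                    tr, window_bp=cfg.smooth_window_bp, min_nonzero=cfg.smooth_min_nonzero
                )
                tissue_tracks[key] = sm
                p = outdir / f"smooth_{sm.sample_id}.tsv"
                io.write_track(sm, p)
                paths.append(p)
        manifest.record("smooth", paths, time.perf_counter() - t0)

    calls: Dict[str, Dict[str, Dict[int, Dict[float, list]]]] = {}
    if "callchers" in enabled:
        need("callchers", "simulate")
        t0 = time.perf_counter()
        paths = []
        quantiles = sorted(set(list(cfg.quantiles) + [cfg.broad_quantile]))
        for tissue, tissue_tracks in tracks.items():
            calls[tissue] = {}
            for (mark, rep), tr in tissue_tracks.items():
                per_q = {}
                if cfg.fixed_threshold is not None:
                    thresholds = {q: float(cfg.fixed_threshold) for q in quantiles}
                else:
                    null = cher.estimate_null(
                        tr, quantiles=quantiles, min_probes=cfg.min_null_probes
                    )
                    thresholds = null.thresholds
                for q in quantiles:
                    per_q[q] = cher.call_chers(
                        tr,
                        y0=thresholds[q],
                        min_probes=cfg.min_probes,
                        merge_gap_bp=cfg.merge_gap_bp,
                        quantile_level=q,
                    )
                calls[tissue].setdefault(mark, {})[rep] = per_q
                p = outdir / f"chers_{tissue}_{mark}_rep{rep + 1}.tsv"
                io.write_chers(
                    [c for lst in per_q.values() for c in lst],
                    outdir / f"chers_{tissue}_{mark}_rep{rep + 1}.bed",
                    p,
                )
                paths.append(p)
        manifest.record("callchers", paths, time.perf_counter() - t0)

    final_chers: Dict[str, Dict[str, list]] = {}
    if "combine" in enabled:
        need("combine", "callchers")
        t0 = time.perf_counter()
        paths = []
        for tissue, by_mark in calls.items():
            final_chers[tissue] = {}
            for mark, by_rep in by_mark.items():
                combined = cher.combine_replicates(
                    {f"rep{r + 1}": {0.95: pq.get(0.95, []), 0.99: pq.get(0.99, [])} for r, pq in by_rep.items()}
                )
                if mark in cfg.broad_marks and cfg.broad_mode != "off":
                    broad = [
                        c
                        for pq in by_rep.values()
                        for c in pq.get(cfg.broad_quantile, [])
                    ]
                    if cfg.broad_mode == "replace":
                        combined = cher.union_chers(broad, [], sample_id=f"{tissue}_{mark}") if broad else combined
                    else:  # union
                        combined = cher.union_chers(combined, broad, sample_id=f"{tissue}_{mark}") if broad else combined
                final_chers[tissue][mark] = combined
                p = outdir / f"final_chers_{tissue}_{mark}.tsv"
                io.write_chers(combined, outdir / f"final_chers_{tissue}_{mark}.bed", p)
                paths.append(p)
        manifest.record("combine", paths, time.perf_counter() - t0)

    matrices: Dict[str, BinaryMatrix] = {}
    if "binarize" in enabled:
        need("binarize", "combine")
        t0 = time.perf_counter()
        paths = []
        for tissue, by_mark in final_chers.items():
            matrix = hmm.binarize(
                by_mark,
                annotation,
                window_bp=scfg.window_bp,
                tissue=tissue,
                mark_names=list(scfg.mark_names),
            )
            matrices[tissue] = matrix
            paths += io.write_binary_matrix(matrix, outdir / "binary")
        manifest.record("binarize", paths, time.perf_counter() - t0)

    results = None
    if "learn" in enabled:
        need("learn", "binarize")
        t0 = time.perf_counter()
        results = hmm.learn_hmm(
            list(matrices.values()),
            n_states=cfg.n_states,
            seed=cfg.seed,
            n_restarts=cfg.n_restarts,
            tol=cfg.em_tol,
            max_iter=cfg.em_max_iter,
        )
        io.write_model(results, outdir / "model.json", outdir / "model.txt")
        manifest.record("learn", [outdir / "model.json", outdir / "model.txt"], time.perf_counter() - t0)

    segs: Dict[str, Segmentation] = {}
    if "segment" in enabled:
        need("segment", "learn")
        t0 = time.perf_counter()
        paths = []
        for tissue, matrix in matrices.items():
            seg = results.segment(matrix)
            segs[tissue] = seg
            p = outdir / f"segmentation_{tissue}.bed"
            io.write_segmentation(seg, p)
            paths.append(p)
            cov = hmm.state_coverage(seg)
            io.write_json(
                {f"E{k + 1}": float(v) for k, v in enumerate(cov)},
                outdir / f"state_coverage_{tissue}.json",
            )
            paths.append(outdir / f"state_coverage_{tissue}.json")
        manifest.record("segment", paths, time.perf_counter() - t0)

    if "enrich" in enabled:
        need("enrich", "segment")
        t0 = time.perf_counter()
        paths = []
        features = _feature_universe(annotation, cfg)
        for tissue, seg in segs.items():
            fold = hmm.fold_enrichment(seg, features, annotation)
            p = outdir / f"fold_enrichment_{tissue}.tsv"
            fold.to_csv(p, sep="\t", float_format="%.4g")
            paths.append(p)
            summ = hmm.emission_summary(results, fold)
            p2 = outdir / f"state_summary_{tissue}.tsv"
            summ.to_csv(p2, sep="\t")
            paths.append(p2)
        manifest.record("enrich", paths, time.perf_counter() - t0)

    if "profile" in enabled:
        need("profile", "simulate")
        t0 = time.perf_counter()
        paths = []
        marks = list(cfg.profile_marks) or [scfg.mark_names[0]]
        for tissue, tissue_tracks in tracks.items():
            for mark in marks:
                tr = tissue_tracks.get((mark, 0))
                if tr is None:
                    continue
                for anchor in ("TSS", "TES"):
                    try:
                        prof = annotate.metaprofile(
                            tr,
                            annotation,
                            anchor=anchor,
                            window_bp=cfg.profile_window_bp,
                            min_gene_bp=cfg.min_gene_bp,
                            min_intergenic_bp=cfg.min_intergenic_bp,
                            bin_bp=scfg.probe_spacing,
                        )
                    except ValueError as exc:
                        log.warning("profile %s/%s/%s skipped: %s", tissue, mark, anchor, exc)
                        continue
                    p = outdir / f"profile_{tissue}_{mark}_{anchor}.tsv"
                    prof.to_frame().to_csv(p, sep="\t", index=False, float_format="%.5g")
                    paths.append(p)
        manifest.record("profile", paths, time.perf_counter() - t0)

    if "stats" in enabled:
        need("stats", "segment")
        t0 = time.perf_counter()
        paths = []
        spec_scores = stats.specificity_scores(expression)
        spec_classes = stats.classify_specificity(
            spec_scores.dropna(), cfg.specificity_low, cfg.specificity_high
        )
        pd.DataFrame({"specificity": spec_scores, "class": spec_classes}).to_csv(
            outdir / "specificity.tsv", sep="\t", float_format="%.4g"
        )
        paths.append(outdir / "specificity.tsv")

        chrom_class = annotation.genes["chrom"].map(annotation.chromosomes["chrom_class"])
        summary = {}
        for tissue in segs:
            if tissue in expression.columns:
                summary[f"xa_ratio_{tissue}"] = stats.xa_ratio(expression, chrom_class, tissue=tissue)
        widths_by_tissue = {}
        for tissue, seg in segs.items():
            widths = np.concatenate(
                [w for w in seg.domain_widths().values() if w.size] or [np.empty(0, np.int64)]
            )
            widths_by_tissue[tissue] = stats.adjust_widths(widths, cfg.width_resolution)
        if len(widths_by_tissue) == 2:
            a, b = widths_by_tissue.values()
            cmpres = stats.compare_width_distributions(a, b)
            summary["width_mannwhitney_u"] = cmpres.u_statistic
            summary["width_mannwhitney_p"] = cmpres.p_value
            summary["width_median_ratio"] = cmpres.median_ratio
        # TE bimodal test on the Y chromosome, when the marks exist
        marks = set(scfg.mark_names)
        het_mark = "H3K9me3" if "H3K9me3" in marks else None
        act_marks = [m for m in ("H3K4me3", "H3K36me3") if m in marks]
        if het_mark and act_marks and len(annotation.transposons):
            for tissue, by_mark in final_chers.items():
                try:
                    res, table = stats.te_bimodal_test(
                        annotation.transposons,
                        by_mark.get(het_mark, []),
                        [c for m in act_marks for c in by_mark.get(m, [])],
                        genome=annotation,
                    )
                except ValueError as exc:
                    log.warning("TE bimodal test skipped for %s: %s", tissue, exc)
                    continue
                summary[f"te_bimodal_chi2_{tissue}"] = res.statistic
                summary[f"te_bimodal_df_{tissue}"] = res.df
                table.to_csv(outdir / f"te_bimodal_{tissue}.tsv", sep="\t", float_format="%.4g")
                paths.append(outdir / f"te_bimodal_{tissue}.tsv")
        # GO-subset state enrichment clustering
        if go_table is not None and len(go_table):
            activity = {}
            for tissue in segs:
                if tissue not in expression.columns:
                    continue
                cats = annotate.categorize_genes(
                    expression[tissue], annotation, silent_threshold=cfg.silent_threshold
                )
                activity[tissue] = {
                    "active": set(cats.index[cats["expression_class"] == "high"]),
                    "silent": set(cats.index[cats["expression_class"] == "silent"]),
                }
            subsets = stats.build_go_subsets(
                go_table, activity, cfg.go_min_parent, cfg.go_min_subset
            )
            if subsets:
                enr = stats.go_state_enrichment(subsets, segs, annotation)
                enr.to_csv(outdir / "go_state_enrichment.tsv", sep="\t", float_format="%.4g")
                paths.append(outdir / "go_state_enrichment.tsv")
                if len(enr) >= 2:
                    clusters = stats.cluster_enrichments(enr, cut_height=cfg.cluster_cut)
                    clusters.to_csv(outdir / "go_clusters.tsv", sep="\t")
                    paths.append(outdir / "go_clusters.tsv")
        io.write_json(summary, outdir / "stats_summary.json")
        paths.append(outdir / "stats_summary.json")
        manifest.record("stats", paths, time.perf_counter() - t0)

    manifest.write(outdir / "manifest.json")
    return manifest


def _feature_universe(annotation, cfg: PipelineConfig) -> dict:
    """Named interval sets for fold-enrichment: genes, promoters, TSS/TES
    windows, TEs, and the X/Y chromosomes."""
    feats: Dict[str, Dict[str, list]] = {"genome": {}}
    lengths = annotation.chromosomes["length"]
    for chrom, L in lengths.items():
        feats["genome"][chrom] = [(0, int(L))]
    feats["gene_body"] = {}
    for r in annotation.genes.itertuples():
        feats["gene_body"].setdefault(r.chrom, []).append((int(r.start), int(r.end)))
    proms = annotate.define_promoters(annotation.genes, annotation.chromosomes, cfg.promoter_bp)
    feats["promoter"] = {}
    for r in proms.itertuples():
        feats["promoter"].setdefault(r.chrom, []).append((int(r.start), int(r.end)))
    for name, col in (("TSS", "tss"), ("TES", "tes")):
        feats[name] = {}
        for r in annotation.genes.itertuples():
            p = int(getattr(r, col))
            s, e = max(0, p - 25), min(int(lengths[r.chrom]), p + 26)
            feats[name].setdefault(r.chrom, []).append((s, e))
    if len(annotation.transposons):
        feats["TE"] = {}
        for r in annotation.transposons.itertuples():
            feats["TE"].setdefault(r.chrom, []).append((int(r.start), int(r.end)))
    for cls in ("X", "Y"):
        chroms = annotation.chromosomes.index[annotation.chromosomes["chrom_class"] == cls]
        if len(chroms):
            feats[f"chr{cls}"] = {c: [(0, int(lengths[c]))] for c in chroms}
    operon_genes = annotation.genes[annotation.genes["operon_id"].notna()]
    if len(operon_genes):
        feats["operon"] = {}
        for r in operon_genes.itertuples():
            feats["operon"].setdefault(r.chrom, []).append((int(r.start), int(r.end)))
    return feats
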