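"""End-to-end orchestration of the design and analysis pipelines.

Each stage writes its outputs plus a manifest entry carrying the stage
name, config hash and seed; a stage whose outputs already exist under
the same config hash is skipped on re-run (per-stage resumability).
Failures abort with the stage named in the error.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import (
    array_qc,
    crosshyb,
    downstream,
    fixtures,
    normalize_de,
    power,
    probe_design,
    precluster as pc,
)
from .config import PipelineConfig, config_hash

logger = logging.getLogger("oligochip")

__all__ = ["run_design_pipeline", "run_analysis_pipeline", "simulate_inputs"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


class _Manifest:
    def __init__(self, outdir: Path, config: PipelineConfig):
        self.path = outdir / "manifest.json"
        self.config_hash = config_hash(config)
        self.seed = config.seed
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
            if self.data.get("config_hash") != self.config_hash:
                self.data = {"config_hash": self.config_hash, "seed": self.seed, "stages": {}}
        else:
            self.data = {"config_hash": self.config_hash, "seed": self.seed, "stages": {}}

    def done(self, stage: str, outputs) -> bool:
        rec = self.data["stages"].get(stage)
        return bool(rec) and all(Path(p).exists() for p in rec["outputs"]) and set(
            rec["outputs"]
        ) == {str(p) for p in outputs}

    def record(self, stage: str, outputs, elapsed: float) -> None:
        self.data["stages"][stage] = {
            "outputs": [str(p) for p in outputs],
            "seconds": round(elapsed, 3),
        }
        self.path.write_text(json.dumps(self.data, indent=2))


def _stage(manifest: _Manifest, name: str, outputs, fn) -> None:
    outputs = [str(p) for p in outputs]
    if manifest.done(name, outputs):
        logger.info("stage %s: up to date, skipped", name)
        return
    t0 = time.monotonic()
    try:
        fn()
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(name, exc) from exc
    elapsed = time.monotonic() - t0
    manifest.record(name, outputs, elapsed)
    logger.info("stage %s: %.2fs", name, elapsed)


def _header_comment(config: PipelineConfig, stage: str) -> str:
    return (
        f"# stage={stage} config_hash={config_hash(config)} seed={config.seed}\n"
    )


def _write_with_header(df: pd.DataFrame, path: Path, config: PipelineConfig, stage: str) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(config, stage))
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Simulation (fixtures to disk)
# ---------------------------------------------------------------------------

def simulate_inputs(config: PipelineConfig, outdir) -> dict:
    """Write fixture FASTA, slide tables, Ct table and term map; returns
    the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fx = config.fixtures
    spec = fixtures.FixtureSpec(
        seed=config.seed,
        n_unigenes=fx.n_unigenes,
        n_spots=fx.n_spots,
        n_negative_controls=fx.n_negative_controls,
        n_de_genes=fx.n_de_genes,
        de_log2_fold=fx.de_log2_fold,
        dye_bias_amplitude=fx.dye_bias_amplitude,
        m_noise_sd=fx.m_noise_sd,
    )
    unigenes, homology = fixtures.generate_unigenes(spec)
    fixtures.write_unigenes_fasta(unigenes, outdir / "unigenes.fasta")
    homology.to_csv(outdir / "unigenes.truth.tsv", sep="\t", index=False)
    slides, truth, layout = fixtures.generate_two_color_slides(spec)
    for slide_id, df in slides.items():
        array_qc.write_spot_table(df, outdir / f"{slide_id}.tsv")
    truth.to_csv(outdir / "slides.truth.tsv", sep="\t", index=False)
    layout.to_csv(outdir / "layout.tsv", sep="\t", index=False)
    ct, ct_truth = fixtures.generate_ct_table(spec)
    ct.to_csv(outdir / "ct.tsv", sep="\t", index=False)
    ct_truth.to_csv(outdir / "ct.truth.tsv", sep="\t", index=False)
    term_map = fixtures.generate_term_map(spec)
    term_map.to_csv(outdir / "term_map.tsv", sep="\t", index=False)
    return {
        "fasta": outdir / "unigenes.fasta",
        "layout": outdir / "layout.tsv",
        "slides": sorted(outdir.glob("slide[0-9][0-9].tsv")),
        "ct": outdir / "ct.tsv",
        "term_map": outdir / "term_map.tsv",
    }


# ---------------------------------------------------------------------------
# Design pipeline: precluster -> probe design -> cross-hyb screen
# ---------------------------------------------------------------------------

def run_design_pipeline(config: PipelineConfig, fasta_path=None) -> dict:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta_path = Path(fasta_path or config.input_fasta or "")
    if not fasta_path.is_file():
        raise FileNotFoundError(f"input FASTA not found: {fasta_path}")
    manifest = _Manifest(outdir, config)
    reads = pc.read_fasta(fasta_path)

    cluster_path = outdir / "clusters.tsv"
    design_path = outdir / "design_report.tsv"
    missing_path = outdir / "missing_genes.tsv"
    probes_path = outdir / "probes.fasta"
    screen_path = outdir / "crosshyb.tsv"

    pcfg = config.precluster

    def do_precluster():
        masked = [
            pc.low_complexity_mask(r, window=pcfg.mask_window,
                                   entropy_threshold=pcfg.mask_entropy_threshold,
                                   dinucleotide=pcfg.mask_dinucleotide)
            for r in reads
        ]
        clusters = pc.precluster(masked, min_identity=pcfg.min_identity,
                                 min_length=pcfg.min_length)
        with open(cluster_path, "w") as fh:
            fh.write(_header_comment(config, "precluster"))
            fh.write("cluster_id\tmember_id\n")
            for c in clusters:
                for m in sorted(c.member_ids):
                    fh.write(f"{c.cluster_id}\t{m}\n")

    _stage(manifest, "precluster", [cluster_path], do_precluster)

    d = config.design
    constraints = probe_design.ProbeConstraints(
        tm_target=d.tm_target, tm_tol=d.tm_tol, length_target=d.length_target,
        length_tol=d.length_tol, gc_target=d.gc_target, gc_tol=d.gc_tol,
        max_dist_3prime=d.max_dist_3prime, max_stem=d.max_stem,
        max_selfdimer=d.max_selfdimer, min_loop=d.min_loop,
        na_mM=d.na_mM, oligo_nM=d.oligo_nM,
    )
    outcomes_holder = {}

    def do_design():
        outcomes = probe_design.design_all(reads, constraints)
        outcomes_holder["outcomes"] = outcomes
        with open(design_path, "w") as fh:
            fh.write(_header_comment(config, "design"))
        _append_design_report(outcomes, design_path)
        probe_design.write_missing_genes_tsv(outcomes, missing_path)
        probe_design.write_probes_fasta(outcomes, probes_path)

    _stage(manifest, "design", [design_path, missing_path, probes_path], do_design)

    def do_screen():
        if "outcomes" not in outcomes_holder:
            outcomes_holder["outcomes"] = probe_design.design_all(reads, constraints)
        outcomes = outcomes_holder["outcomes"]
        probes = {o.unigene_id: o.probe.sequence for o in outcomes if o.probe}
        unigenes = {r.id: r.sequence for r in reads}
        hits = crosshyb.screen(probes, unigenes,
                               id_threshold=config.screen.id_threshold,
                               lcs_threshold=config.screen.lcs_threshold)
        with open(screen_path, "w") as fh:
            fh.write(_header_comment(config, "screen"))
            fh.write("probe_id\ttarget_id\tidentity\tlcs\tflagged\n")
            for h in hits:
                fh.write(
                    f"{h.probe_id}\t{h.target_unigene_id}\t{h.overall_identity:.3f}\t"
                    f"{h.lcs_length}\t{int(h.flagged)}\n"
                )

    _stage(manifest, "screen", [screen_path], do_screen)
    return {
        "clusters": cluster_path, "design": design_path,
        "missing": missing_path, "probes": probes_path, "crosshyb": screen_path,
    }


def _append_design_report(outcomes, path) -> None:
    with open(path, "a") as fh:
        fh.write("unigene_id\tstart\tlength\ttm\tgc\tstem\tselfdimer\tdist_3prime\toutcome\treason\n")
        for o in outcomes:
            if o.probe is not None:
                p = o.probe
                fh.write(
                    f"{o.unigene_id}\t{p.start}\t{p.length}\t{p.tm:.3f}\t{p.gc:.3f}\t"
                    f"{p.stem_score}\t{p.selfdimer_score}\t{p.dist_3prime}\tdesigned\t-\n"
                )
            else:
                fh.write(f"{o.unigene_id}\t-\t-\t-\t-\t-\t-\t-\tmissing\t{o.missing_reason.value}\n")


# ---------------------------------------------------------------------------
# Analysis pipeline: qc -> normalize -> DE -> power -> downstream
# ---------------------------------------------------------------------------

def run_analysis_pipeline(config: PipelineConfig, slide_paths, layout_path,
                          term_map_path=None) -> dict:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config)

    layout = pd.read_csv(layout_path, sep="\t")
    slides = {}
    for p in slide_paths:
        df = array_qc.read_spot_table(p)
        for slide_id, sub in df.groupby("Slide"):
            slides[slide_id] = sub.reset_index(drop=True)
    known = set(layout["slide_id"])
    stray = set(slides) - known
    if stray:
        raise ValueError(f"slide(s) not in layout: {sorted(stray)}")

    qc_path = outdir / "qc_report.tsv"
    matrix_path = outdir / "normalized_matrix.tsv"
    de_path = outdir / "de_results.tsv"
    power_path = outdir / "power_report.tsv"

    state: dict = {}

    def do_qc():
        rows = []
        state["filtered"] = {}
        for slide_id, df in slides.items():
            thr = array_qc.expression_threshold(
                df, sd_multiplier=config.qc.sd_multiplier,
                filter_percentile=config.qc.filter_percentile,
            )
            retained = array_qc.filter_spots(df, thr)
            state["filtered"][slide_id] = retained
            rows.append(
                {
                    "slide_id": slide_id,
                    "nc_median_red": thr.nc_median["red"],
                    "nc_sd_red": thr.nc_sd["red"],
                    "expr_threshold_red": thr.expression_threshold["red"],
                    "filter_threshold_red": thr.filter_threshold["red"],
                    "nc_median_green": thr.nc_median["green"],
                    "nc_sd_green": thr.nc_sd["green"],
                    "expr_threshold_green": thr.expression_threshold["green"],
                    "filter_threshold_green": thr.filter_threshold["green"],
                    "n_retained": len(retained),
                }
            )
        _write_with_header(pd.DataFrame(rows), qc_path, config, "qc")

    _stage(manifest, "qc", [qc_path], do_qc)
    if "filtered" not in state:
        do_qc()

    def do_normalize():
        normalized = {
            sid: normalize_de.normalize_slide(df, span=config.normalize.span,
                                              iterations=config.normalize.iterations)
            for sid, df in state["filtered"].items()
        }
        mat = normalize_de.build_expression_matrix(normalized, layout)
        state["matrix"] = mat
        out = mat.values.copy()
        out.insert(0, "gene_id", out.index)
        _write_with_header(out, matrix_path, config, "normalize")

    _stage(manifest, "normalize", [matrix_path], do_normalize)
    if "matrix" not in state:
        do_normalize()

    def do_de():
        mat = state["matrix"]
        fit = normalize_de.per_gene_linear_fit(mat)
        sam = normalize_de.sam_test(
            mat, n_permutations=config.de.n_permutations, seed=config.seed,
            s0_percentile=config.de.s0_percentile,
            fdr_threshold=config.de.alpha,
        )
        table = fit.join(sam.table[["d", "fdr"]])
        table.insert(0, "gene_id", table.index)
        table["linear_sig"] = table["p_adj"] <= config.de.alpha
        table["sam_sig"] = table["fdr"] <= config.de.alpha
        table["consensus_sig"] = table["linear_sig"] & table["sam_sig"]
        state["de"] = table
        _write_with_header(table, de_path, config, "de")

    _stage(manifest, "de", [de_path], do_de)

    def do_power():
        raw = pd.concat(slides.values())
        probes = raw[(raw["ControlClass"] == "probe") & (raw["Flag"] == "ok")]
        mean_intensity = probes.groupby("ID")[["F_red", "F_green"]].mean().mean(axis=1)
        per_slide = probes.pivot_table(index="ID", values="F_red", columns="Slide")
        records = []
        for gid, row in per_slide.iterrows():
            vals = row.dropna()
            if len(vals) >= 2 and vals.mean() > 0:
                records.append(power.cv_per_feature(gid, vals))
        records = power.cv_rank_scale(records)
        p90 = power.cv_p90(records)
        pw = config.power
        spec = power.PowerSpec(n_per_group=pw.n_per_group, cv=p90, fold=2.0,
                               alpha=pw.alpha, noise_model=pw.noise_model)
        rows = [
            {
                "metric": "cv_p90", "value": p90},
            {
                "metric": "power_2fold_at_p90_cv",
                "value": power.power_two_sample_t(spec),
            },
            {
                "metric": "min_detectable_fold_at_p90_cv",
                "value": power.min_detectable_fold(
                    pw.n_per_group, p90, pw.alpha, pw.target_power, pw.noise_model
                ),
            },
        ]
        _write_with_header(pd.DataFrame(rows), power_path, config, "power")

    _stage(manifest, "power", [power_path], do_power)
    return {
        "qc": qc_path, "matrix": matrix_path, "de": de_path, "power": power_path,
    }
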