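"""End-to-end orchestration: config validation, staged execution, manifest.

Stages communicate exclusively through serialized files in the output
directory, so any stage can be re-run or executed in a separate process.
The manifest records the config snapshot, package version, per-stage output
checksums and wall-clock times; deterministic stages reproduce identical
checksums under an identical config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from . import diffexpr as de
from . import enrichment as enr
from . import expression as ex
from . import mutability as mut
from . import structure as st
from . import synthetic as syn
from .errors import ConfigError, FpkmKitError

log = logging.getLogger("fpkmkit")

STAGES = ("simulate", "ingest", "diffexpr", "structure", "enrichment", "mutability", "report")


@dataclass
class RunManifest:
    config: dict[str, Any]
    version: str = __version__
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    def record(self, stage: str, outputs: list[Path], seconds: float) -> None:
        self.stages[stage] = {
            "outputs": {p.name: _sha256(p) for p in outputs},
            "wall_clock_s": round(seconds, 4),
        }

    def write(self, path: Path) -> None:
        path.write_text(json.dumps({"version": self.version, "config": self.config, "stages": self.stages}, indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_config(config: dict[str, Any]) -> None:
    """Fail before any stage runs: unknown stages, missing inputs, bad values."""
    if "outdir" not in config:
        raise ConfigError("config needs an 'outdir'")
    stages = config.get("stages", [])
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigError(f"unknown stages {unknown}; valid: {list(STAGES)}")
    if "simulate" not in stages:
        for key in ("matrix", "metadata"):
            if any(s in stages for s in ("ingest", "diffexpr", "structure", "enrichment")):
                path = config.get("inputs", {}).get(key)
                if not path:
                    raise ConfigError(f"config inputs.{key} required without a simulate stage")
                if not Path(path).exists():
                    raise ConfigError(f"input file not found: {path}")
    if "enrichment" in stages and "simulate" not in stages:
        gmt = config.get("inputs", {}).get("gene_sets")
        if not gmt or not Path(gmt).exists():
            raise ConfigError("enrichment stage requires inputs.gene_sets (GMT)")
    if "mutability" in stages:
        for key in ("loci", "chrom_lengths", "fasta"):
            path = config.get("inputs", {}).get(key)
            if not path or not Path(path).exists():
                raise ConfigError(f"mutability stage requires inputs.{key}")
    seed = config.get("seed")
    if any(s in stages for s in ("simulate", "enrichment")) and seed is None:
        raise ConfigError("a 'seed' is required when random stages are enabled")
    thr = config.get("mutability_options", {})
    if thr.get("threshold_i_mb", 50.0) <= 0 or not 0 < thr.get("threshold_ii", 0.59) < 1:
        raise ConfigError("mutability thresholds out of range")


def run_pipeline(config: dict[str, Any]) -> RunManifest:
    """Execute the configured stages in order, writing all outputs to disk.

    A stage failure propagates with the stage name attached; the manifest
    written so far stays on disk so the run can be diagnosed and resumed.
    """
    validate_config(config)
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", [])
    manifest = RunManifest(config=config)
    manifest_path = outdir / "manifest.json"

    matrix: ex.ExpressionMatrix | None = None
    meta: ex.SampleTable | None = None

    for stage in STAGES:
        if stage not in stages:
            continue
        log.info("[%s] starting", stage)
        t0 = time.perf_counter()
        try:
            if stage == "simulate":
                outputs = _stage_simulate(config, outdir)
            elif stage == "ingest":
                matrix, meta, outputs = _stage_ingest(config, outdir)
            elif stage == "diffexpr":
                matrix, meta = _ensure_loaded(config, outdir, matrix, meta)
                outputs = _stage_diffexpr(config, outdir, matrix, meta)
            elif stage == "structure":
                matrix, meta = _ensure_loaded(config, outdir, matrix, meta)
                outputs = _stage_structure(config, outdir, matrix)
            elif stage == "enrichment":
                matrix, meta = _ensure_loaded(config, outdir, matrix, meta)
                outputs = _stage_enrichment(config, outdir, matrix, meta)
            elif stage == "mutability":
                outputs = _stage_mutability(config, outdir)
            elif stage == "report":
                outputs = _stage_report(config, outdir)
        except FpkmKitError as exc:
            manifest.write(manifest_path)
            raise FpkmKitError(f"stage {stage!r} failed: {exc}") from exc
        manifest.record(stage, outputs, time.perf_counter() - t0)
        log.info("[%s] done (%.2fs)", stage, manifest.stages[stage]["wall_clock_s"])
    manifest.write(manifest_path)
    return manifest


# ---------------------------------------------------------------------------
# Stage bodies
# ---------------------------------------------------------------------------

def _stage_simulate(config: dict, outdir: Path) -> list[Path]:
    opts = config.get("simulate_options", {})
    spec = syn.ExpressionSimSpec(
        n_genes=opts.get("n_genes", 1000),
        group_sizes=opts.get("group_sizes", dict(syn.DEFAULT_GROUP_SIZES)),
        baseline_log_mean=opts.get("baseline_log_mean", 4.0),
        baseline_log_sd=opts.get("baseline_log_sd", 2.0),
        batch_effect_sd=opts.get("batch_effect_sd", 0.0),
        noise_log_sd=opts.get("noise_log_sd", 0.5),
        outlier_control_index=opts.get("outlier_control_index"),
        seed=config["seed"],
    )
    for sp in opts.get("spikes", []):
        spec.spike_table.append(
            syn.Spike(
                gene_index=sp["gene_index"],
                group=sp["group"],
                fold=sp["fold"],
                direction=sp["direction"],
            )
        )
    truths: list[syn.TruthRecord] = []
    outputs: list[Path] = []
    if opts.get("gene_sets"):
        gs_opts = opts["gene_sets"]
        sets, set_truth = syn.simulate_gene_sets(
            n_sets=gs_opts.get("n_sets", 10),
            set_size=gs_opts.get("set_size", 25),
            enriched_set_fold=gs_opts.get("enriched_set_fold", 4.0),
            matrix_spec=spec,
            seed=config["seed"],
        )
        enr.write_gmt(sets, outdir / "gene_sets.gmt")
        outputs.append(outdir / "gene_sets.gmt")
        truths.append(set_truth)
    matrix, meta, expr_truths = syn.simulate_fpkm(spec)
    truths.extend(expr_truths)
    ex.write_fpkm_table(matrix, outdir / "fpkm.tsv")
    ex.write_sample_table(meta, outdir / "metadata.tsv")
    syn.write_truth(truths, outdir / "truth.json")
    outputs += [outdir / "fpkm.tsv", outdir / "metadata.tsv", outdir / "truth.json"]
    return outputs


def _input_paths(config: dict, outdir: Path) -> tuple[Path, Path]:
    stages = config.get("stages", [])
    if "simulate" in stages:
        return outdir / "fpkm.tsv", outdir / "metadata.tsv"
    inputs = config.get("inputs", {})
    return Path(inputs["matrix"]), Path(inputs["metadata"])


def _stage_ingest(config: dict, outdir: Path):
    mpath, spath = _input_paths(config, outdir)
    matrix = ex.read_fpkm_table(mpath)
    meta = ex.read_sample_table(spath)
    meta.validate_against(matrix)
    min_nonzero = config.get("filter", {}).get("min_samples_nonzero", 1)
    matrix = ex.filter_expressed(matrix, min_nonzero)
    ex.write_fpkm_table(matrix, outdir / "filtered.tsv")
    return matrix, meta, [outdir / "filtered.tsv"]


def _ensure_loaded(config, outdir, matrix, meta):
    if matrix is None or meta is None:
        filtered = outdir / "filtered.tsv"
        mpath, spath = _input_paths(config, outdir)
        matrix = ex.read_fpkm_table(filtered if filtered.exists() else mpath)
        meta = ex.read_sample_table(spath)
        meta.validate_against(matrix)
    return matrix, meta


def _stage_diffexpr(config: dict, outdir: Path, matrix, meta) -> list[Path]:
    outputs = []
    contrasts = config.get("contrasts", [{"a": "control", "b": "AD"}])
    for c in contrasts:
        table = de.compare_groups(
            matrix,
            meta,
            group_a=c.get("a", "control"),
            group_b=c.get("b", "AD"),
            test=c.get("test", config.get("test", "welch")),
            adjust=config.get("adjust", "none"),
        )
        ranked = de.rank_genes(table)
        path = outdir / f"diffexpr_{c.get('b', 'AD')}-vs-{c.get('a', 'control')}.tsv"
        de.write_results(ranked, path)
        outputs.append(path)
    return outputs


def _stage_structure(config: dict, outdir: Path, matrix) -> list[Path]:
    opts = config.get("structure_options", {})
    space = (
        ex.log_transform(matrix, opts.get("pseudocount", 1.0))
        if opts.get("log_space", True)
        else matrix
    )
    res = st.pca(space, standardize=opts.get("standardize", True))
    res.scores_frame().rename_axis("gene_id").to_csv(outdir / "pca_scores.tsv", sep="\t")
    res.loadings_frame().rename_axis("sample_id").to_csv(outdir / "pca_loadings.tsv", sep="\t")
    pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(res.n_components)],
            "variance_proportion": res.variance_proportion,
        }
    ).to_csv(outdir / "pca_variance.tsv", sep="\t", index=False)
    tree = st.hierarchical_cluster(
        space, metric=opts.get("metric", "euclidean"), linkage=opts.get("linkage", "ward")
    )
    (outdir / "samples.nwk").write_text(tree.to_newick() + "\n")
    k = opts.get("k_gene_clusters", 8)
    clusters = st.gene_clusters(space, k=min(k, space.n_genes), seed=config.get("seed", 0))
    clusters.to_csv(outdir / "gene_clusters.tsv", sep="\t", index=False)
    return [
        outdir / "pca_scores.tsv",
        outdir / "pca_loadings.tsv",
        outdir / "pca_variance.tsv",
        outdir / "samples.nwk",
        outdir / "gene_clusters.tsv",
    ]


def _stage_enrichment(config: dict, outdir: Path, matrix, meta) -> list[Path]:
    opts = config.get("enrichment_options", {})
    gmt_path = (
        outdir / "gene_sets.gmt"
        if "simulate" in config.get("stages", [])
        else Path(config["inputs"]["gene_sets"])
    )
    sets = enr.read_gmt(gmt_path)
    results = enr.es_profile(
        matrix,
        meta,
        sets,
        group_a=opts.get("group_a", "control"),
        group_b=opts.get("group_b", "AD"),
        weight_p=opts.get("weight_p", 1.0),
        n_perm=opts.get("n_perm", 1000),
        seed=config["seed"],
    )
    enr.results_table(results).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    return [outdir / "enrichment.tsv"]


def _stage_mutability(config: dict, outdir: Path) -> list[Path]:
    inputs = config["inputs"]
    opts = config.get("mutability_options", {})
    species = opts.get("species", "synthetic")
    chroms = mut.read_chromosome_lengths(inputs["chrom_lengths"], species=species)
    loci_path = Path(inputs["loci"])
    if loci_path.suffix == ".bed":
        loci = mut.read_loci_bed(loci_path, species=species)
    else:
        loci = mut.read_loci_gff3(loci_path, species=species)
    fasta = mut.open_fasta(inputs["fasta"])
    mut.check_fasta_lengths(chroms, fasta)
    calls = mut.factor_calls(
        loci,
        chroms,
        fasta,
        threshold_i_mb=opts.get("threshold_i_mb", mut.F_I_THRESHOLD_MB),
        threshold_ii=opts.get("threshold_ii", mut.F_II_THRESHOLD),
    )
    mut.calls_table(calls).to_csv(outdir / "factor_calls.tsv", sep="\t", index=False)
    mut.matching_rate_table(calls).to_csv(outdir / "matching_rates.tsv", sep="\t", index=False)
    outputs = [outdir / "factor_calls.tsv", outdir / "matching_rates.tsv"]
    if inputs.get("transcripts"):
        records = mut.read_transcript_lengths(inputs["transcripts"])
        ref = mut.ReferenceSizeRange(
            panel_name=opts.get("reference_panel", "reference"),
            min_bp=opts.get("reference_min_bp", 1000),
            max_bp=opts.get("reference_max_bp", 8000),
        )
        rows = []
        for gene in sorted({r.gene_id for r in records}):
            sub = [r for r in records if r.gene_id == gene]
            if len(sub) < 2:
                continue
            res = mut.size_conservation(sub, ref)
            for sp_name, flag in res.flags.items():
                rows.append(
                    {
                        "gene_id": gene,
                        "species": sp_name,
                        "flag": flag,
                        "length_ratio": res.length_ratio,
                    }
                )
        pd.DataFrame(rows).to_csv(outdir / "size_conservation.tsv", sep="\t", index=False)
        outputs.append(outdir / "size_conservation.tsv")
    return outputs


def _stage_report(config: dict, outdir: Path) -> list[Path]:
    report = build_report(outdir, alpha=config.get("alpha", 0.05), top_n=config.get("top_n", 10))
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    (outdir / "report.txt").write_text(render_report(report))
    return [outdir / "report.json", outdir / "report.txt"]


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def build_report(outdir: Path, alpha: float = 0.05, top_n: int = 10) -> dict[str, Any]:
    """Summarize whatever stage outputs exist in ``outdir`` (empty is valid)."""
    report: dict[str, Any] = {"alpha": alpha}
    de_tables = sorted(outdir.glob("diffexpr_*.tsv"))
    contrasts = {}
    for path in de_tables:
        table = pd.read_csv(path, sep="\t")
        summary = de.significance_summary(table["p_value"].tolist(), alpha=alpha)
        top = table.nsmallest(top_n, "rank")[
            ["gene_id", "fold_change", "direction", "p_value", "star_label", "rank"]
        ]
        top = top.where(pd.notna(top), None)
        contrasts[path.stem.removeprefix("diffexpr_")] = {
            "n_total": summary.n_total,
            "n_significant": summary.n_significant,
            "proportion_percent": summary.proportion_percent,
            "top_genes": top.to_dict(orient="records"),
        }
    report["contrasts"] = contrasts
    var_path = outdir / "pca_variance.tsv"
    if var_path.exists():
        report["pca_variance"] = pd.read_csv(var_path, sep="\t").to_dict(orient="records")
    es_path = outdir / "enrichment.tsv"
    if es_path.exists():
        report["enrichment"] = pd.read_csv(es_path, sep="\t")[
            ["set_name", "es", "p_permutation"]
        ].to_dict(orient="records")
    mr_path = outdir / "matching_rates.tsv"
    if mr_path.exists():
        report["matching_rates"] = pd.read_csv(mr_path, sep="\t").to_dict(orient="records")
    return report


def render_report(report: dict[str, Any]) -> str:
    lines = ["# fpkmkit run summary", ""]
    for name, c in report.get("contrasts", {}).items():
        lines.append(
            f"contrast {name}: {c['n_significant']}/{c['n_total']} genes "
            f"significant at alpha={report['alpha']} ({c['proportion_percent']}%)"
        )
        for g in c["top_genes"]:
            fc = g["fold_change"]
            fc_txt = f"{fc:.2f}x" if fc is not None else "undefined"
            lines.append(
                f"  #{g['rank']} {g['gene_id']}: {fc_txt} {g['direction']} "
                f"p={g['p_value']:.3g} {g['star_label'] or ''}".rstrip()
            )
    if "pca_variance" in report:
        lines.append("")
        lines.append("PCA variance proportions:")
        for row in report["pca_variance"]:
            lines.append(f"  {row['component']}: {row['variance_proportion']:.4f}")
    if "enrichment" in report:
        lines.append("")
        lines.append("enrichment (ES, permutation p):")
        for row in report["enrichment"]:
            lines.append(f"  {row['set_name']}: ES={row['es']:.3f} p={row['p_permutation']:.4f}")
    if "matching_rates" in report:
        lines.append("")
        lines.append("mutability matching rates:")
        for row in report["matching_rates"]:
            lines.append(
                f"  {row['species']} {row['factor']}: {row['n_matching']}/{row['n_genes']}"
                f" = {row['rate_percent']}%"
            )
    return "\n".join(lines) + "\n"
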