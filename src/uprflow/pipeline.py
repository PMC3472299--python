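"""End-to-end orchestration: summarize -> DE -> sets -> motif -> GO -> kinetics.

A run consumes the pipeline's plain-text inputs (probe matrix + map,
design, promoter FASTA, GO DAG + annotations, culture CSV), executes
each stage with parameters from a single :class:`PipelineConfig`, and
leaves TSV/JSON artifacts plus a manifest (inputs, parameters, output
checksums) in the run directory.  All randomness flows from one root
seed, fanned out per stage by a counter-based derivation so stages are
individually re-runnable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as uio
from .de import de_summary, run_de
from .go import propagate_annotations, term_enrichment, enrichment_network, validate_go_graph
from .kinetics import compute_yield, detect_breakpoint
from .motif import motif_enrichment, parse_iupac
from .sets import GeneSet, consistent_de_sets, venn_partition
from .simulate import (
    default_design,
    generate_culture,
    generate_go_universe,
    generate_probe_data,
    generate_promoters,
)
from .summarize import median_polish_summarize, background_correct, replicate_cv

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "stage_seed", "run_pipeline", "simulate_inputs", "run_demo"]

DEFAULT_MOTIF = "CANRNTGKCCT"


@dataclass
class PipelineConfig:
    probe_matrix: str | None = None
    probe_map: str | None = None
    design: str | None = None
    promoter_fasta: str | None = None
    go_graph: str | None = None
    go_annotations: str | None = None
    culture_csv: str | None = None
    out_dir: str = "uprflow_run"
    fdr_de: float = 0.005
    fdr_go: float = 0.05
    motif: str = DEFAULT_MOTIF
    window: int = 400
    strands: str = "both"
    background_correction: bool = False
    seed: int = 42

    def validate(self) -> None:
        for thr, name in [(self.fdr_de, "fdr_de"), (self.fdr_go, "fdr_go")]:
            if not 0 < thr < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {thr}")
        for attr in ("probe_matrix", "probe_map", "design", "promoter_fasta",
                     "go_graph", "go_annotations", "culture_csv"):
            path = getattr(self, attr)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"config field {attr}: no such file {path!r}")


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def simulate_inputs(out_dir: str | Path, seed: int = 42, n_genes: int = 1000,
                    probes_per_gene: int = 8) -> dict[str, str]:
    """Generate a complete synthetic input bundle and return its paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = default_design()
    probes, truth_de = generate_probe_data(
        design, n_genes=n_genes, probes_per_gene=probes_per_gene,
        seed=stage_seed(seed, "probes"),
    )
    motif = parse_iupac(DEFAULT_MOTIF)
    up_planted = {
        g for g, eff in truth_de.de_genes.items() if min(eff.values()) > 0
    }
    promoters, truth_prom = generate_promoters(
        n_genes=n_genes, gene_ids=[f"g{i:04d}" for i in range(1, n_genes + 1)],
        planted_genes=up_planted, motif=motif, seed=stage_seed(seed, "promoters"),
    )
    go_graph, annotations, truth_go = generate_go_universe(
        n_genes=n_genes, study_set=up_planted, seed=stage_seed(seed, "go"),
    )
    culture, truth_cult = generate_culture(
        noise_cv=0.03, seed=stage_seed(seed, "culture")
    )
    paths = {
        "probe_matrix": str(out / "probes.tsv"),
        "probe_map": str(out / "probe_map.tsv"),
        "design": str(out / "design.tsv"),
        "promoter_fasta": str(out / "promoters.fasta"),
        "go_graph": str(out / "go_dag.tsv"),
        "go_annotations": str(out / "go_annotations.tsv"),
        "culture_csv": str(out / "culture.csv"),
    }
    uio.write_probe_matrix(probes, paths["probe_matrix"], paths["probe_map"])
    uio.write_design(design, paths["design"])
    uio.write_promoters_fasta(promoters, paths["promoter_fasta"])
    uio.write_go_graph(go_graph, paths["go_graph"])
    uio.write_annotations(annotations, paths["go_annotations"])
    uio.write_culture_csv(culture, paths["culture_csv"])
    truth = dataclasses.replace(
        truth_de, motif_genes=truth_prom.motif_genes,
        enriched_term=truth_go.enriched_term,
        kinetic_params=truth_cult.kinetic_params,
    )
    truth.to_json(out / "truth.json")
    return paths


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every configured stage; returns the manifest dict."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setLevel(logging.INFO)
    root_logger = logging.getLogger("uprflow")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)
    outputs: list[Path] = []
    summary: dict = {}
    try:
        if cfg.probe_matrix:
            _stage_expression(cfg, out, outputs, summary)
        if cfg.promoter_fasta and "up_all" in summary:
            _stage_motif(cfg, out, outputs, summary)
        if cfg.go_graph and "up_all" in summary:
            _stage_go(cfg, out, outputs, summary)
        if cfg.culture_csv:
            _stage_kinetics(cfg, out, outputs, summary)
    except Exception as exc:
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        root_logger.removeHandler(handler)
        handler.close()
    manifest = {
        "parameters": {
            k: v for k, v in dataclasses.asdict(cfg).items() if v is not None
        },
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
        "summary": {k: v for k, v in summary.items() if k not in ("up_all", "down_all")},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _stage_expression(cfg, out, outputs, summary):
    logger.info("stage summarize: %s", cfg.probe_matrix)
    if not (cfg.probe_map and cfg.design):
        raise ValueError("probe_matrix requires probe_map and design")
    probes = uio.read_probe_matrix(cfg.probe_matrix, cfg.probe_map)
    design = uio.read_design(cfg.design)
    if cfg.background_correction:
        probes = background_correct(probes)
    from .summarize import quantile_normalize, ProbeIntensityMatrix

    normalized = ProbeIntensityMatrix(
        quantile_normalize(probes.values), probes.probe_to_probeset
    )
    expr = median_polish_summarize(normalized)
    expr_path = out / "expression.tsv"
    uio.write_expression(expr, expr_path)
    outputs.append(expr_path)
    cvs = {}
    for cond in design["condition"].unique():
        _, mean_cv = replicate_cv(expr, design, cond)
        cvs[cond] = round(mean_cv, 4)
    summary["replicate_mean_cv"] = cvs
    logger.info("stage de: fdr=%g", cfg.fdr_de)
    results = run_de(expr, design, q_threshold=cfg.fdr_de)
    for label, df in results.items():
        path = out / f"de_{label}.tsv"
        df.rename_axis("gene").to_csv(path, sep="\t")
        outputs.append(path)
    summary["de_counts"] = de_summary(results)
    up_all, down_all = consistent_de_sets(results)
    summary["up_all"] = up_all
    summary["down_all"] = down_all
    summary["consistent_counts"] = {"up_all": len(up_all), "down_all": len(down_all)}
    up_sets = [
        GeneSet(label, frozenset(df.index[df["direction"] == 1]))
        for label, df in results.items()
    ]
    venn = venn_partition(up_sets)
    venn_path = out / "venn_up.json"
    venn_path.write_text(json.dumps(
        {"".join("1" if b else "0" for b in sig): count
         for sig, (count, _) in sorted(venn.items())},
        indent=1,
    ))
    outputs.append(venn_path)
    for name, gs in (("up_all", up_all), ("down_all", down_all)):
        path = out / f"{name}.txt"
        uio.write_gene_list(set(gs.members), path)
        outputs.append(path)


def _stage_motif(cfg, out, outputs, summary):
    logger.info("stage upre-scan: motif=%s window=%d", cfg.motif, cfg.window)
    promoters = uio.read_promoters_fasta(cfg.promoter_fasta)
    study = set(summary["up_all"].members) & promoters.genes
    if not study:
        logger.warning("no up-regulated genes with promoters; motif stage skipped")
        summary["motif"] = None
        return
    result = motif_enrichment(promoters, study, parse_iupac(cfg.motif),
                              strands=cfg.strands)
    hits_path = out / "upre_hits.tsv"
    pd.DataFrame(
        [(h.gene, h.offset, h.strand, h.matched) for h in result.hits],
        columns=["gene", "offset", "strand", "matched"],
    ).to_csv(hits_path, sep="\t", index=False)
    outputs.append(hits_path)
    summary["motif"] = {
        "table": dataclasses.asdict(result.table),
        "p_value": result.p_value,
        "odds_ratio": result.odds_ratio,
        "positives_in_set": result.positives_in_set,
    }
    enr_path = out / "upre_enrichment.json"
    enr_path.write_text(json.dumps(summary["motif"], indent=1))
    outputs.append(enr_path)


def _stage_go(cfg, out, outputs, summary):
    logger.info("stage go-enrich: fdr=%g", cfg.fdr_go)
    g = uio.read_go_graph(cfg.go_graph)
    validate_go_graph(g)
    direct = uio.read_annotations(cfg.go_annotations)
    propagated = propagate_annotations(g, direct)
    population = set(propagated)
    study = set(summary["up_all"].members) & population
    if not study:
        logger.warning("no annotated up-regulated genes; GO stage skipped")
        summary["go"] = None
        return
    table = term_enrichment(study, population, propagated, fdr=cfg.fdr_go)
    go_path = out / "go_enrichment.tsv"
    table.to_csv(go_path, sep="\t")
    outputs.append(go_path)
    enriched = set(table.index[table["enriched"]])
    edges = enrichment_network(enriched, g)
    net_path = out / "go_network.tsv"
    pd.DataFrame(edges, columns=["term", "ancestor"]).to_csv(
        net_path, sep="\t", index=False
    )
    outputs.append(net_path)
    summary["go"] = {
        "tested_terms": int(len(table)),
        "enriched_terms": sorted(enriched),
    }


def _stage_kinetics(cfg, out, outputs, summary):
    logger.info("stage kinetics: %s", cfg.culture_csv)
    ts = uio.read_culture_csv(cfg.culture_csv)
    fit = detect_breakpoint(ts, signal="biomass")
    t, _ = ts.observed("glucose")
    window_end = fit.t_break if fit.t_break is not None else float(t[-1])
    try:
        fit.yield_xs = compute_yield(ts, (float(t[0]), window_end))
    except ValueError as exc:
        logger.warning("yield not computable: %s", exc)
    kin_path = out / "growth_fit.json"
    kin_path.write_text(json.dumps(fit.to_dict(), indent=1))
    outputs.append(kin_path)
    summary["kinetics"] = fit.to_dict()


def run_demo(out_dir: str | Path, seed: int = 42, n_genes: int = 1000) -> dict:
    """One-command all-synthetic end-to-end run."""
    out = Path(out_dir)
    inputs = simulate_inputs(out / "inputs", seed=seed, n_genes=n_genes)
    cfg = PipelineConfig(out_dir=str(out / "results"), seed=seed, **inputs)
    return run_pipeline(cfg)
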