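"""End-to-end pipeline driver.

Stage order: gene screen -> pair screen -> correlated-gene discovery ->
enrichment -> overlap -> report.  Every stage logs its thresholds and
counts; a stage failure aborts with the stage name and cause.  All
outputs are deterministic for a fixed input (no timestamps).
"""
from __future__ import annotations

import logging
from pathlib import Path

from . import io as psio
from .cohort import Cohort
from .config import PipelineConfig
from .enrichment import (correlated_genes, enrich, enrichment_to_frame,
                         overlap_sets, overlap_to_frame)
from .gene_screen import GeneScreenCriteria, results_to_frame, run_gene_screen
from .pair_screen import (grids_to_json_payload, run_pair_screen,
                          verdicts_to_frame)

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("pairsurv")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _configure_file_log(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "pipeline.log", mode="w",
                                  encoding="utf-8")
    # no timestamps: output must be byte-identical across reruns
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    return handler


def _pair_key(pair) -> str:
    return "|".join(sorted(pair))


def run_pipeline(config: PipelineConfig,
                 cohort: Cohort | None = None) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    ``cohort`` may be passed directly (e.g. freshly simulated); otherwise
    it is loaded from the configured paths.  Returns the machine-readable
    summary that is also written to ``summary.json``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = _configure_file_log(out_dir)
    try:
        return _run(config, cohort, out_dir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, cohort: Cohort | None, out_dir: Path) -> dict:
    for key, value in sorted(config.thresholds().items()):
        log.info("threshold %s = %r", key, value)

    if cohort is None:
        try:
            cohort = psio.read_cohort(config.expression, config.clinical,
                                      config.classes)
        except Exception as exc:
            raise PipelineError("load", exc) from exc
    log.info("cohort: %d genes, %d patients, %d normal samples",
             len(cohort.genes), cohort.n_patients,
             len(cohort.normal_samples))
    if not cohort.has_normals:
        log.info("no normal samples: DE stage skipped, regulation tags "
                 "fall back to correlation sign")

    # ---- gene screen --------------------------------------------------
    try:
        criteria = GeneScreenCriteria(
            de_alpha=config.de_alpha, surv_alpha=config.surv_alpha,
            hr_low=config.hr_low, hr_high=config.hr_high,
            cutoffs=tuple(config.cutoffs),
            force_include=tuple(config.force_include))
        gene_results = run_gene_screen(cohort.genes, cohort, criteria)
    except Exception as exc:
        raise PipelineError("gene_screen", exc) from exc
    gene_frame = results_to_frame(gene_results)
    psio.write_tsv(gene_frame, out_dir / "genes.tsv")
    passed_genes = [r.gene for r in gene_results if r.passed]
    log.info("gene screen: %d/%d genes passed",
             len(passed_genes), len(gene_results))

    # ---- pair screen --------------------------------------------------
    summary: dict = {
        "n_genes_screened": len(gene_results),
        "n_genes_passed": len(passed_genes),
    }
    verdicts = []
    if len(passed_genes) >= 2:
        try:
            verdicts = run_pair_screen(
                passed_genes, cohort, horizon=config.horizon_days,
                min_cell_n=config.min_cell_n,
                hr_diff_threshold=config.hr_diff_threshold,
                hr_diff_mode=config.hr_diff_mode,
                trend_tol=config.trend_tol)
        except Exception as exc:
            raise PipelineError("pair_screen", exc) from exc
    else:
        log.info("pair screen skipped: fewer than 2 passed genes")
    pair_frame = verdicts_to_frame(verdicts)
    psio.write_tsv(pair_frame, out_dir / "pairs.tsv")
    psio.write_json(grids_to_json_payload(verdicts),
                    out_dir / "pairs_grids.json")
    selected = [v for v in verdicts if v.selected]
    n_reduced = sum(v.survival_direction == "reduced" for v in selected)
    n_increased = sum(v.survival_direction == "increased" for v in selected)
    log.info("pair screen: %d pairs evaluated, %d selected "
             "(%d reduced / %d increased survival)",
             len(verdicts), len(selected), n_reduced, n_increased)
    summary.update(n_pairs_evaluated=len(verdicts),
                   n_pairs_selected=len(selected),
                   n_pairs_reduced_survival=n_reduced,
                   n_pairs_increased_survival=n_increased)

    # ---- correlated genes ---------------------------------------------
    sets_dir = out_dir / "sets"
    sets_dir.mkdir(exist_ok=True)
    corr_sets = []
    try:
        for v in selected:
            cs = correlated_genes(v.pair, cohort,
                                  r_threshold=config.r_threshold,
                                  same_sign=config.same_sign)
            corr_sets.append(cs)
            frame = _correlated_frame(cs)
            psio.write_tsv(frame, sets_dir / f"{_pair_key(v.pair)}.tsv")
            log.info("correlated set %s: %d genes (%d zero-variance skipped)",
                     _pair_key(v.pair), len(cs.members),
                     cs.n_skipped_zero_variance)
    except Exception as exc:
        raise PipelineError("correlate", exc) from exc
    summary["n_correlated_sets"] = len(corr_sets)
    summary["correlated_set_sizes"] = {
        _pair_key(cs.pair): len(cs.members) for cs in corr_sets}

    # ---- enrichment ---------------------------------------------------
    enrich_dir = out_dir / "enrich"
    enrich_dir.mkdir(exist_ok=True)
    n_enriched = 0
    if config.gmt:
        try:
            annotation = psio.read_gmt(config.gmt)
            background = _background(cohort)
            for cs in corr_sets:
                query = set(cs.gene_names) & background
                if not query:
                    log.info("enrichment %s: empty query, skipped",
                             _pair_key(cs.pair))
                    continue
                rows = enrich(query, annotation, background,
                              min_set=config.min_set, fdr_cut=config.fdr_cut,
                              top=config.top_sets)
                psio.write_tsv(enrichment_to_frame(rows),
                               enrich_dir / f"{_pair_key(cs.pair)}.tsv")
                n_enriched += len(rows)
                log.info("enrichment %s: %d sets pass fdr < %g",
                         _pair_key(cs.pair), len(rows), config.fdr_cut)
        except Exception as exc:
            raise PipelineError("enrich", exc) from exc
    else:
        log.info("no GMT annotation supplied: enrichment skipped")
    summary["n_enriched_rows"] = n_enriched

    # ---- overlap ------------------------------------------------------
    groups = []
    if len(corr_sets) >= config.min_pairs:
        try:
            groups = overlap_sets(corr_sets, min_pairs=config.min_pairs)
        except Exception as exc:
            raise PipelineError("overlap", exc) from exc
    else:
        log.info("overlap skipped: fewer than min_pairs=%d correlated sets",
                 config.min_pairs)
    overlap_frame = overlap_to_frame(groups)
    psio.write_tsv(overlap_frame, out_dir / "overlap.tsv")
    summary["n_overlap_groups"] = len(groups)
    summary["n_overlap_rows"] = len(overlap_frame)
    log.info("overlap: %d groups, %d gene rows",
             len(groups), len(overlap_frame))

    summary["thresholds"] = {k: v for k, v in
                             sorted(config.thresholds().items())}
    psio.write_json(summary, out_dir / "summary.json")
    return summary


def _background(cohort: Cohort) -> set[str]:
    """All genes with non-zero variance across tumor samples."""
    expr = cohort.expression[cohort.tumor_samples]
    variable = expr.std(axis=1) > 0
    return set(expr.index[variable])


def _correlated_frame(cs):
    import pandas as pd
    return pd.DataFrame([{
        "gene": m.gene,
        "r_with_first": m.r_with_first,
        "r_with_second": m.r_with_second,
        "regulation": m.regulation,
        "regulation_source": m.regulation_source,
    } for m in cs.members],
        columns=["gene", "r_with_first", "r_with_second",
                 "regulation", "regulation_source"])
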