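"""Single-gene candidate filters.

A gene passes the screen when it is differentially expressed between
tumor and normal tissue AND its expression splits survival under at
least one cutoff (median or extreme quartiles) with a hazard ratio
outside the configured indifference band.  Genes on the force-include
list pass regardless.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from math import isnan, nan

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortError
from .survstats import (HazardRatioResult, ZeroVarianceError, hazard_ratio_oe,
                        logrank, mann_whitney, median_split, quartile_bins)

__all__ = ["GeneScreenCriteria", "GeneScreenResult", "de_test",
           "survival_association", "run_gene_screen", "evaluate_gene",
           "results_to_frame"]

CUTOFFS = ("median", "quartile")


@dataclass(frozen=True)
class GeneScreenCriteria:
    """Thresholds of the single-gene screen.

    ``(hr_low, hr_high)`` is the indifference band: a cutoff qualifies
    only when its hazard ratio is <= hr_low or >= hr_high (bounds
    inclusive on the passing side).
    """

    de_alpha: float = 0.001
    surv_alpha: float = 0.05
    hr_low: float = 0.8
    hr_high: float = 1.2
    cutoffs: tuple[str, ...] = CUTOFFS
    force_include: tuple[str, ...] = ()

    def __post_init__(self):
        if not 0 < self.de_alpha < 1 or not 0 < self.surv_alpha < 1:
            raise ValueError("alpha thresholds must lie in (0, 1)")
        if not 0 < self.hr_low < 1 < self.hr_high:
            raise ValueError("require 0 < hr_low < 1 < hr_high")
        unknown = set(self.cutoffs) - set(CUTOFFS)
        if unknown:
            raise ValueError(f"unknown cutoffs: {sorted(unknown)}")
        if not self.cutoffs:
            raise ValueError("at least one cutoff must be enabled")


@dataclass
class GeneScreenResult:
    gene: str
    de_p: float
    de_direction: int            # +1 up in tumor, -1 down, 0 undetermined
    surv_p_median: float
    hr_median: float
    surv_p_quartile: float
    hr_quartile: float
    passed: bool
    forced: bool
    degenerate: bool = False     # constant expression etc.


def de_test(gene: str, cohort: Cohort) -> tuple[float, int]:
    """Tumor-vs-normal differential expression (Mann-Whitney).

    Returns ``(p, direction)`` with direction the sign of
    (tumor median - normal median).
    """
    tumor = cohort.tumor_values(gene)
    normal = cohort.normal_values(gene)
    if tumor.size < 3 or normal.size < 3:
        raise CohortError(
            f"gene {gene}: need >= 3 tumor and >= 3 normal samples for DE")
    _, p = mann_whitney(tumor, normal)
    direction = int(np.sign(np.median(tumor) - np.median(normal)))
    return p, direction


def survival_association(gene: str, cohort: Cohort,
                         cutoff: str) -> tuple[float, HazardRatioResult]:
    """Log-rank p and HR(high vs low) for one expression cutoff.

    ``median``: patients split at the gene's median (ties to the low
    group).  ``quartile``: only the extreme quartiles are compared
    (Q1 high vs Q4 low); the middle half is excluded.
    """
    if cutoff not in CUTOFFS:
        raise ValueError(f"unknown cutoff {cutoff!r}")
    values = cohort.patient_values(gene)
    times, status = cohort.survival_arrays()
    if values.size < 8:
        raise CohortError("survival association needs >= 8 patients")
    if cutoff == "median":
        high = median_split(values)
        low = ~high
    else:
        qa = quartile_bins(values, gene)
        high = qa.bins == "Q1"
        low = qa.bins == "Q4"
    if not status[high].any() and not status[low].any():
        return 1.0, HazardRatioResult(nan, nan, "high", "low",
                                      0.0, 0.0, 0.0, 0.0, defined=False)
    mask = high | low
    groups = np.where(high[mask], "high", "low")
    lr = logrank(groups, times[mask], status[mask])
    hr = hazard_ratio_oe(times[high], status[high], times[low], status[low],
                         "high", "low")
    return lr.p_value, hr


def evaluate_gene(result: GeneScreenResult, criteria: GeneScreenCriteria,
                  de_available: bool = True) -> bool:
    """Pure verdict rule given the computed statistics.

    DE must be significant (when normals exist) and at least one enabled
    cutoff must combine a significant log-rank p with an HR outside the
    indifference band.
    """
    if result.forced:
        return True
    if result.degenerate:
        return False
    de_ok = True
    if de_available:
        de_ok = (not isnan(result.de_p)) and result.de_p < criteria.de_alpha
    surv_ok = False
    stats = {"median": (result.surv_p_median, result.hr_median),
             "quartile": (result.surv_p_quartile, result.hr_quartile)}
    for cutoff in criteria.cutoffs:
        p, hr = stats[cutoff]
        if isnan(p) or isnan(hr):
            continue
        if p < criteria.surv_alpha and (hr <= criteria.hr_low
                                        or hr >= criteria.hr_high):
            surv_ok = True
    return de_ok and surv_ok


def run_gene_screen(genes, cohort: Cohort,
                    criteria: GeneScreenCriteria | None = None
                    ) -> list[GeneScreenResult]:
    """Screen a list of genes, returning one result per gene.

    Force-include genes carry ``forced=True`` and ``passed=True``
    regardless of the filters.  When the cohort has no normal samples the
    DE criterion is skipped (degraded mode; ``de_p`` is NaN).
    """
    criteria = criteria or GeneScreenCriteria()
    genes = list(genes)
    cohort.require_genes(genes)
    de_available = cohort.has_normals
    forced = set(criteria.force_include)
    results = []
    for gene in genes:
        degenerate = False
        if de_available:
            try:
                de_p, de_dir = de_test(gene, cohort)
            except ZeroVarianceError:
                de_p, de_dir, degenerate = nan, 0, True
        else:
            de_p, de_dir = nan, 0
        stats = {}
        for cutoff in CUTOFFS:
            try:
                p, hr = survival_association(gene, cohort, cutoff)
                stats[cutoff] = (p, hr.hr if hr.defined else nan)
            except ZeroVarianceError:
                stats[cutoff] = (nan, nan)
                degenerate = True
        result = GeneScreenResult(
            gene=gene, de_p=de_p, de_direction=de_dir,
            surv_p_median=stats["median"][0], hr_median=stats["median"][1],
            surv_p_quartile=stats["quartile"][0],
            hr_quartile=stats["quartile"][1],
            passed=False, forced=gene in forced, degenerate=degenerate)
        result.passed = evaluate_gene(result, criteria, de_available)
        results.append(result)
    return results


def results_to_frame(results: list[GeneScreenResult]) -> pd.DataFrame:
    rows = [{
        "gene": r.gene, "de_p": r.de_p, "de_direction": r.de_direction,
        "surv_p_median": r.surv_p_median, "hr_median": r.hr_median,
        "surv_p_quartile": r.surv_p_quartile, "hr_quartile": r.hr_quartile,
        "passed": int(r.passed), "forced": int(r.forced),
        "degenerate": int(r.degenerate),
    } for r in results]
    return pd.DataFrame(rows)
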