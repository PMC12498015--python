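"""Quartile-within-strata gene-pair survival screen.

For an ordered pair, the *factor* gene's quartiles define the compared
survival curves while the *strata* gene's extreme quartiles define the
subpopulations analyzed.  The endpoint per cell is the cumulative
survival proportion at a fixed horizon (default five years = 1825 days).
A pair is selected when both orderings imply the same survival direction
(bidirectional concordance) and the strata-conditional Q1-vs-Q4 hazard
ratios differ by at least the configured fraction.

Direction/scenario classification
---------------------------------
Within a qualifying stratum (one whose four factor-quartile survival
values move strictly in one direction), the trend's extreme ends mark
the corner cells of the 4x4 grid implicated by the pattern.  Each
candidate corner is compared against the reference corner — low
expression of both genes (factor Q4, strata Q4) — and the corner with
the largest departure from that reference determines the direction
(reduced/increased survival) and scenario:

=========  =======================  ==========
direction  corner vs reference      scenario
=========  =======================  ==========
reduced    one low / one high       i
reduced    both high                ii
increased  one low / one high       iii
increased  both high                iv
=========  =======================  ==========

Strata whose readings disagree on direction yield ``none`` (conflicting
trends).  Middle strata (Q2/Q3 of the second gene) are computed in the
grid but never used for selection.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import isnan, nan

import numpy as np
import pandas as pd

from .cohort import Cohort
from .survstats import (HazardRatioResult, QUARTILE_LABELS, ZeroVarianceError,
                        hazard_ratio_oe, km_fit, quartile_bins, survival_at)

__all__ = ["PairGrid", "PairVerdict", "pair_grid", "classify_trend",
           "classify_ordering", "hr_difference", "hr_diff_value",
           "run_pair_screen",
           "verdicts_to_frame", "DEFAULT_HORIZON_DAYS"]

DEFAULT_HORIZON_DAYS = 1825.0  # five years
DEFAULT_MIN_CELL_N = 5

_Q1, _Q4 = 0, 3  # row/column indices of the extreme quartiles


@dataclass
class PairGrid:
    """Survival-at-horizon grid for one ordered (factor, strata) pair.

    ``s5``, ``cell_n`` and ``defined`` are 4x4 arrays indexed
    [factor quartile Q1..Q4, strata quartile Q1..Q4].  Selection uses
    only the strata-Q1 and strata-Q4 columns; the full grid is kept for
    transposition checks and export.
    """

    factor_gene: str
    strata_gene: str
    s5: np.ndarray
    cell_n: np.ndarray
    defined: np.ndarray
    horizon: float
    min_cell_n: int


@dataclass
class PairVerdict:
    gene_a: str
    gene_b: str
    trend_ab: dict          # stratum label -> trend, ordering (a=factor, b=strata)
    trend_ba: dict
    scenario: str           # "i".."iv" or "none"
    hr_q1: HazardRatioResult | None
    hr_q4: HazardRatioResult | None
    hr_rel_diff: float
    concordant: bool
    selected: bool
    survival_direction: str  # "reduced", "increased" or "none"
    grid_ab: PairGrid | None = None
    grid_ba: PairGrid | None = None
    exclusion_reason: str | None = None

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def pair_grid(factor: str, strata: str, cohort: Cohort,
              horizon: float = DEFAULT_HORIZON_DAYS,
              min_cell_n: int = DEFAULT_MIN_CELL_N) -> PairGrid:
    """Fit the 4x4 survival-at-horizon grid for one ordered pair.

    Each cell is the Kaplan-Meier survival at ``horizon`` among patients
    in the intersection of one factor quartile and one strata quartile.
    Cells with fewer than ``min_cell_n`` patients, or whose estimate
    requires carrying the curve beyond its own follow-up, are flagged
    undefined (a cell that reached zero survival stays defined).
    """
    fv = quartile_bins(cohort.patient_values(factor), factor)
    sv = quartile_bins(cohort.patient_values(strata), strata)
    times, status = cohort.survival_arrays()
    s5 = np.full((4, 4), nan)
    cell_n = np.zeros((4, 4), dtype=int)
    defined = np.zeros((4, 4), dtype=bool)
    for i, fq in enumerate(QUARTILE_LABELS):
        fmask = fv.bins == fq
        for j, sq in enumerate(QUARTILE_LABELS):
            mask = fmask & (sv.bins == sq)
            n = int(mask.sum())
            cell_n[i, j] = n
            if n == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # zero-event cells are legal
                curve = km_fit(times[mask], status[mask])
            value, ok = survival_at(curve, horizon)
            s5[i, j] = value
            defined[i, j] = n >= min_cell_n and (ok or value == 0.0)
    return PairGrid(factor, strata, s5, cell_n, defined, horizon, min_cell_n)


def classify_trend(s5_column, tol: float = 0.0,
                   defined=None) -> str:
    """Direction of a four-point survival column (factor Q1 -> Q4).

    Returns ``"decreasing"`` when every successive value drops by more
    than ``tol``, ``"increasing"`` when every one rises by more than
    ``tol``, else ``"none"``.  Any undefined cell forces ``"none"``.
    """
    col = np.asarray(s5_column, dtype=float)
    if col.shape != (4,):
        raise ValueError("expected exactly four survival values")
    if defined is not None and not np.all(defined):
        return "none"
    if np.any(np.isnan(col)):
        return "none"
    diffs = np.diff(col)
    if np.all(diffs < -tol):
        return "decreasing"
    if np.all(diffs > tol):
        return "increasing"
    return "none"


# corner cells of the 4x4 grid, excluding the (low, low) reference
_CORNERS = ((_Q1, _Q1), (_Q4, _Q1), (_Q1, _Q4))
_REFERENCE = (_Q4, _Q4)


def _corner_scenario(corner: tuple[int, int], direction: str) -> str:
    both_high = corner == (_Q1, _Q1)
    if direction == "reduced":
        return "ii" if both_high else "i"
    return "iv" if both_high else "iii"


def classify_ordering(grid: PairGrid, tol: float = 0.0
                      ) -> tuple[str, str, dict]:
    """Classify one ordering's direction and scenario from its grid.

    Returns ``(direction, scenario, trends)`` where ``trends`` maps the
    strata label ("Q1"/"Q4") to its trend.  Direction is ``none`` when no
    stratum shows a qualifying trend, when the reference corner (both
    genes low) is undefined, or when the two strata imply conflicting
    directions.
    """
    trends = {}
    for j, label in ((_Q1, "Q1"), (_Q4, "Q4")):
        trends[label] = classify_trend(grid.s5[:, j], tol,
                                       defined=grid.defined[:, j])
    if not grid.defined[_REFERENCE]:
        return "none", "none", trends
    ref = grid.s5[_REFERENCE]
    readings = []  # (|delta|, priority, direction, scenario) per stratum
    for j, label in ((_Q1, "Q1"), (_Q4, "Q4")):
        trend = trends[label]
        if trend == "none":
            continue
        # extreme ends of the trend within this stratum
        candidates = [(row, j) for row in (_Q1, _Q4)
                      if (row, j) != _REFERENCE and grid.defined[row, j]]
        best = None
        for corner in candidates:
            delta = grid.s5[corner] - ref
            if delta == 0:
                continue
            key = (abs(delta), -_CORNERS.index(corner))
            if best is None or key > best[0]:
                direction = "reduced" if delta < 0 else "increased"
                best = (key, direction, _corner_scenario(corner, direction))
        if best is not None:
            readings.append(best)
    if not readings:
        return "none", "none", trends
    directions = {r[1] for r in readings}
    if len(directions) > 1:
        return "none", "none", trends  # conflicting trends across strata
    best = max(readings, key=lambda r: r[0])
    return best[1], best[2], trends


def hr_diff_value(hr_a: float, hr_b: float, mode: str = "relative") -> float:
    """Difference between two strata-conditional hazard ratios.

    ``relative``: |hr_a - hr_b| / min(hr_a, hr_b); ``absolute``:
    |hr_a - hr_b|.  Symmetric in its arguments.
    """
    if mode not in ("relative", "absolute"):
        raise ValueError(f"unknown hr difference mode {mode!r}")
    if isnan(hr_a) or isnan(hr_b):
        return nan
    diff = abs(hr_a - hr_b)
    return diff / min(hr_a, hr_b) if mode == "relative" else diff


def hr_difference(grid: PairGrid, cohort: Cohort, mode: str = "relative"
                  ) -> tuple[HazardRatioResult, HazardRatioResult, float]:
    """Strata-conditional Q1-vs-Q4 hazard ratios and their difference.

    Within each stratum (strata gene Q1 and Q4) the factor gene's Q1
    patients are compared against its Q4 patients.  ``relative`` mode
    returns ``|hr_q1 - hr_q4| / min(hr_q1, hr_q4)``; ``absolute`` mode
    returns ``|hr_q1 - hr_q4]``.  The difference is NaN when either HR is
    undefined.
    """
    if mode not in ("relative", "absolute"):
        raise ValueError(f"unknown hr difference mode {mode!r}")
    fv = quartile_bins(cohort.patient_values(grid.factor_gene), grid.factor_gene)
    sv = quartile_bins(cohort.patient_values(grid.strata_gene), grid.strata_gene)
    times, status = cohort.survival_arrays()
    hrs = {}
    for label in ("Q1", "Q4"):
        smask = sv.bins == label
        a = smask & (fv.bins == "Q1")
        b = smask & (fv.bins == "Q4")
        if a.sum() == 0 or b.sum() == 0 or not (status[a | b]).any():
            hrs[label] = HazardRatioResult(nan, nan, "factor-Q1", "factor-Q4",
                                           0.0, 0.0, 0.0, 0.0, defined=False)
            continue
        hrs[label] = hazard_ratio_oe(times[a], status[a], times[b], status[b],
                                     "factor-Q1", "factor-Q4")
    hr1, hr4 = hrs["Q1"], hrs["Q4"]
    if not (hr1.defined and hr4.defined):
        return hr1, hr4, nan
    return hr1, hr4, hr_diff_value(hr1.hr, hr4.hr, mode)


def _evaluate_pair(gene_a: str, gene_b: str, cohort: Cohort, horizon: float,
                   min_cell_n: int, hr_diff_threshold: float,
                   hr_diff_mode: str, trend_tol: float,
                   keep_grids: bool) -> PairVerdict:
    grid_ab = pair_grid(gene_a, gene_b, cohort, horizon, min_cell_n)
    grid_ba = pair_grid(gene_b, gene_a, cohort, horizon, min_cell_n)
    dir_ab, scen_ab, trends_ab = classify_ordering(grid_ab, trend_tol)
    dir_ba, scen_ba, trends_ba = classify_ordering(grid_ba, trend_tol)
    concordant = dir_ab != "none" and dir_ab == dir_ba

    hr1_ab, hr4_ab, diff_ab = hr_difference(grid_ab, cohort, hr_diff_mode)
    _, _, diff_ba = hr_difference(grid_ba, cohort, hr_diff_mode)
    diffs = [d for d in (diff_ab, diff_ba) if not isnan(d)]
    hr_rel_diff = max(diffs) if diffs else nan

    reason = None
    if isnan(hr_rel_diff):
        reason = "undefined hazard ratio in both orderings"
    selected = (concordant and not isnan(hr_rel_diff)
                and hr_rel_diff >= hr_diff_threshold)
    return PairVerdict(
        gene_a=gene_a, gene_b=gene_b,
        trend_ab=trends_ab, trend_ba=trends_ba,
        scenario=scen_ab if concordant else "none",
        hr_q1=hr1_ab, hr_q4=hr4_ab, hr_rel_diff=hr_rel_diff,
        concordant=concordant, selected=selected,
        survival_direction=dir_ab if concordant else "none",
        grid_ab=grid_ab if keep_grids else None,
        grid_ba=grid_ba if keep_grids else None,
        exclusion_reason=reason)


def run_pair_screen(genes, cohort: Cohort,
                    horizon: float = DEFAULT_HORIZON_DAYS,
                    min_cell_n: int = DEFAULT_MIN_CELL_N,
                    hr_diff_threshold: float = 0.10,
                    hr_diff_mode: str = "relative",
                    trend_tol: float = 0.0,
                    keep_grids: bool = True) -> list[PairVerdict]:
    """Screen every unordered pair of ``genes`` in both orderings.

    Output is ordered lexicographically by the (sorted) gene ids of each
    pair and is invariant to the input gene order.  ``hr_rel_diff`` is
    the larger of the two orderings' HR differences; the stored
    ``hr_q1``/``hr_q4`` come from the lexicographic-first ordering.
    """
    genes = sorted(set(genes))
    if len(genes) < 2:
        raise ValueError("pair screen requires at least two usable genes")
    cohort.require_genes(genes)
    verdicts = []
    for gene_a, gene_b in combinations(genes, 2):
        try:
            verdicts.append(_evaluate_pair(
                gene_a, gene_b, cohort, horizon, min_cell_n,
                hr_diff_threshold, hr_diff_mode, trend_tol, keep_grids))
        except ZeroVarianceError as exc:
            verdicts.append(PairVerdict(
                gene_a=gene_a, gene_b=gene_b, trend_ab={}, trend_ba={},
                scenario="none", hr_q1=None, hr_q4=None, hr_rel_diff=nan,
                concordant=False, selected=False, survival_direction="none",
                exclusion_reason=str(exc)))
    return verdicts


def verdicts_to_frame(verdicts: list[PairVerdict]) -> pd.DataFrame:
    rows = []
    for v in verdicts:
        rows.append({
            "gene_a": v.gene_a, "gene_b": v.gene_b,
            "trend_ab_q1": v.trend_ab.get("Q1", "none"),
            "trend_ab_q4": v.trend_ab.get("Q4", "none"),
            "trend_ba_q1": v.trend_ba.get("Q1", "none"),
            "trend_ba_q4": v.trend_ba.get("Q4", "none"),
            "scenario": v.scenario,
            "hr_q1": v.hr_q1.hr if v.hr_q1 is not None else nan,
            "hr_q4": v.hr_q4.hr if v.hr_q4 is not None else nan,
            "hr_rel_diff": v.hr_rel_diff,
            "concordant": int(v.concordant),
            "selected": int(v.selected),
            "survival_direction": v.survival_direction,
            "exclusion_reason": v.exclusion_reason or "",
        })
    return pd.DataFrame(rows)


def grids_to_json_payload(verdicts: list[PairVerdict]) -> dict:
    """Full grids of every pair as a JSON-serializable mapping."""
    payload = {}
    for v in verdicts:
        if v.grid_ab is None:
            continue
        key = f"{v.gene_a}|{v.gene_b}"
        payload[key] = {}
        for tag, grid in (("ab", v.grid_ab), ("ba", v.grid_ba)):
            payload[key][tag] = {
                "factor_gene": grid.factor_gene,
                "strata_gene": grid.strata_gene,
                "s5": [[None if isnan(x) else round(float(x), 10)
                        for x in row] for row in grid.s5],
                "cell_n": grid.cell_n.tolist(),
                "defined": grid.defined.astype(bool).tolist(),
            }
    return payload
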