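"""Correlated-gene discovery, gene-set enrichment and multi-pair overlap."""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .cohort import Cohort
from .survstats import bh_fdr, hypergeom_enrichment, pearson_r

__all__ = ["CorrelatedSet", "CorrelatedGene", "EnrichmentRow", "OverlapGroup",
           "correlated_genes", "enrich", "overlap_sets",
           "enrichment_to_frame", "overlap_to_frame"]


@dataclass(frozen=True)
class CorrelatedGene:
    gene: str
    r_with_first: float
    r_with_second: float
    regulation: str          # "up" | "down" | "none"
    regulation_source: str   # "de" | "correlation"


@dataclass
class CorrelatedSet:
    """Genes correlated with both members of a selected pair."""

    pair: tuple[str, str]
    members: list[CorrelatedGene]
    n_skipped_zero_variance: int = 0

    @property
    def gene_names(self) -> list[str]:
        return [m.gene for m in self.members]

    def regulation_of(self, gene: str) -> str:
        for m in self.members:
            if m.gene == gene:
                return m.regulation
        raise KeyError(gene)


@dataclass(frozen=True)
class EnrichmentRow:
    set_name: str
    k: int               # overlap with query
    n_query: int
    K: int               # set size within the background
    N: int               # background size
    fold_enrichment: float
    p: float
    fdr: float


@dataclass(frozen=True)
class OverlapGroup:
    """Genes shared by one exact combination of pairs."""

    pairs: tuple[str, ...]            # "A|B" keys, sorted
    members: tuple[tuple[str, str], ...]  # (gene, regulation or "discordant")


def _regulation_from_de(gene: str, cohort: Cohort) -> str:
    d = np.sign(np.median(cohort.tumor_values(gene))
                - np.median(cohort.normal_values(gene)))
    return {1: "up", -1: "down", 0: "none"}[int(d)]


def correlated_genes(pair: tuple[str, str], cohort: Cohort,
                     r_threshold: float = 0.3,
                     same_sign: bool = False) -> CorrelatedSet:
    """Scan the matrix for genes correlated with both members of a pair.

    A gene is kept when its Pearson correlation with each pair member
    exceeds ``r_threshold`` in absolute value (strictly), computed over
    tumor samples only.  With ``same_sign=True`` the two correlations
    must additionally share a sign.  Regulation tags come from the
    tumor-vs-normal median direction when normal samples exist, otherwise
    from the sign of the mean correlation (flagged as such).
    """
    gene_a, gene_b = pair
    cohort.require_genes([gene_a, gene_b])
    if not 0 < r_threshold < 1:
        raise ValueError("r_threshold must lie in (0, 1)")
    samples = cohort.tumor_samples
    if len(samples) < 3:
        raise ValueError("need at least 3 tumor samples for correlation")
    expr = cohort.expression[samples]
    va = expr.loc[gene_a].to_numpy(dtype=float)
    vb = expr.loc[gene_b].to_numpy(dtype=float)
    use_de = cohort.has_normals
    members = []
    skipped = 0
    for gene in expr.index:
        if gene in (gene_a, gene_b):
            continue
        v = expr.loc[gene].to_numpy(dtype=float)
        if np.ptp(v) == 0 or np.ptp(va) == 0 or np.ptp(vb) == 0:
            skipped += 1
            continue
        ra = pearson_r(v, va)
        rb = pearson_r(v, vb)
        if abs(ra) <= r_threshold or abs(rb) <= r_threshold:
            continue
        if same_sign and np.sign(ra) != np.sign(rb):
            continue
        if use_de:
            reg, src = _regulation_from_de(gene, cohort), "de"
        else:
            reg = "up" if ra + rb > 0 else "down"
            src = "correlation"
        members.append(CorrelatedGene(gene, ra, rb, reg, src))
    return CorrelatedSet((gene_a, gene_b), members, skipped)


def enrich(query, annotation: dict[str, list[str]], background,
           min_set: int = 10, fdr_cut: float = 0.05,
           top: int | None = 10, apply_filters: bool = True
           ) -> list[EnrichmentRow]:
    """Hypergeometric over-representation test against a GMT collection.

    Sets with fewer than ``min_set`` members inside the background are
    dropped before testing; BH FDR is computed across the tested sets.
    With ``apply_filters`` the survivors are filtered at
    ``fdr < fdr_cut``, the ``top`` most significant by FDR retained, and
    the result sorted by fold enrichment (descending).  With
    ``apply_filters=False`` the full tested table is returned sorted by
    p-value.
    """
    query = set(query)
    background = set(background)
    stray = sorted(query - background)
    if stray:
        raise ValueError(f"query genes outside the background: {stray[:10]}")
    if not annotation:
        raise ValueError("annotation collection is empty")
    if not query:
        warnings.warn("empty query; no enrichment computed", stacklevel=2)
        return []
    N = len(background)
    n_query = len(query)
    tested = []
    for name in sorted(annotation):
        in_bg = set(annotation[name]) & background
        K = len(in_bg)
        if K < min_set:
            continue
        k = len(in_bg & query)
        p, fold = hypergeom_enrichment(k, n_query, K, N)
        tested.append((name, k, K, p, fold))
    if not tested:
        return []
    fdrs = bh_fdr([t[3] for t in tested])
    rows = [EnrichmentRow(name, k, n_query, K, N, fold, p, float(q))
            for (name, k, K, p, fold), q in zip(tested, fdrs)]
    if not apply_filters:
        return sorted(rows, key=lambda r: (r.p, r.set_name))
    rows = [r for r in rows if r.fdr < fdr_cut]
    rows.sort(key=lambda r: (r.fdr, r.p, r.set_name))
    if top is not None:
        rows = rows[:top]
    rows.sort(key=lambda r: (-r.fold_enrichment, r.set_name))
    return rows


def overlap_sets(correlated_sets: list[CorrelatedSet],
                 min_pairs: int = 3) -> list[OverlapGroup]:
    """Group genes shared by at least ``min_pairs`` correlated sets.

    Genes are keyed by the exact combination of pairs containing them.
    A gene whose regulation tags disagree across sets is reported as
    ``"discordant"`` rather than silently resolved.  Ordering is
    deterministic: combinations sorted by decreasing size then name,
    genes alphabetically within each group.
    """
    if len(correlated_sets) < min_pairs:
        raise ValueError(
            f"need at least min_pairs={min_pairs} correlated sets")
    containing: dict[str, list[str]] = {}
    regulation: dict[str, set[str]] = {}
    for cs in correlated_sets:
        key = "|".join(sorted(cs.pair))
        for member in cs.members:
            containing.setdefault(member.gene, []).append(key)
            regulation.setdefault(member.gene, set()).add(member.regulation)
    groups: dict[tuple[str, ...], list[tuple[str, str]]] = {}
    for gene, keys in containing.items():
        if len(set(keys)) < min_pairs:
            continue
        combo = tuple(sorted(set(keys)))
        tags = regulation[gene]
        tag = tags.pop() if len(tags) == 1 else "discordant"
        groups.setdefault(combo, []).append((gene, tag))
    out = [OverlapGroup(combo, tuple(sorted(members)))
           for combo, members in groups.items()]
    out.sort(key=lambda g: (-len(g.pairs), g.pairs))
    return out


def enrichment_to_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "set_name": r.set_name, "k": r.k, "n_query": r.n_query,
        "K": r.K, "N": r.N, "fold_enrichment": r.fold_enrichment,
        "p": r.p, "fdr": r.fdr} for r in rows])


def overlap_to_frame(groups: list[OverlapGroup]) -> pd.DataFrame:
    records = []
    for g in groups:
        for gene, reg in g.members:
            records.append({"pair_combination": "+".join(g.pairs),
                            "n_pairs": len(g.pairs),
                            "gene": gene, "regulation": reg})
    return pd.DataFrame(records,
                        columns=["pair_combination", "n_pairs",
                                 "gene", "regulation"])
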