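"""Synthetic cohort generation with planted, recoverable effects.

Generates expression/survival cohorts carrying the statistical structure
the screens assume: log-normal expression with block latent correlation,
tumor-vs-normal location shifts for designated genes, and event times
whose log-hazard contains marginal per-gene effects and pairwise
interaction effects, under independent exponential plus administrative
censoring.  A :class:`TruthRecord` captures everything planted so tests
can measure recovery.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import inf

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = ["SimConfig", "TruthRecord", "SimConfigError",
           "generate_cohort", "generate_annotation", "gene_names"]


class SimConfigError(ValueError):
    """Raised for invalid simulation configurations."""


def gene_names(n_genes: int) -> list[str]:
    width = max(4, len(str(max(n_genes - 1, 0))))
    return [f"G{i:0{width}d}" for i in range(n_genes)]


@dataclass
class SimConfig:
    """Parameters of one simulated cohort.

    Effects are expressed on the latent z-score scale: ``marginal_effects``
    maps a gene to the log-hazard increment per 1 SD of its latent
    expression; ``interaction_effects`` maps an unordered gene pair to the
    log-hazard increment per unit product of the two latent z-scores.
    ``de_effects`` gives the tumor-minus-normal shift on the log
    expression scale.  Gene keys may be integer indices or generated names.
    """

    n_patients: int
    n_genes: int
    n_normal: int = 0
    baseline_hazard: float = 1.0 / 1500.0   # per day
    censor_hazard: float = 1.0 / 4000.0     # per day; 0 disables
    admin_cutoff: float = 3650.0            # days; inf disables
    expr_location: float | np.ndarray = 6.0
    expr_scale: float | np.ndarray = 1.0
    corr_blocks: list[tuple[list[int], float]] = field(default_factory=list)
    de_effects: dict = field(default_factory=dict)
    marginal_effects: dict = field(default_factory=dict)
    interaction_effects: dict = field(default_factory=dict)
    weibull_shape: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 16:
            raise SimConfigError("n_patients must be >= 16 for quartiles")
        if self.n_genes < 1:
            raise SimConfigError("n_genes must be >= 1")
        if self.n_normal < 0:
            raise SimConfigError("n_normal must be >= 0")
        if self.baseline_hazard <= 0:
            raise SimConfigError("baseline_hazard must be > 0")
        if self.censor_hazard < 0:
            raise SimConfigError("censor_hazard must be >= 0")
        if self.admin_cutoff <= 0:
            raise SimConfigError("admin_cutoff must be > 0")
        if self.weibull_shape <= 0:
            raise SimConfigError("weibull_shape must be > 0")
        seen: set[int] = set()
        for bi, (idx, rho) in enumerate(self.corr_blocks):
            idx = list(idx)
            if not -1.0 < rho < 1.0:
                raise SimConfigError(
                    f"correlation block {bi}: rho must be in (-1, 1)")
            if any(i < 0 or i >= self.n_genes for i in idx):
                raise SimConfigError(
                    f"correlation block {bi}: gene index out of range")
            if seen & set(idx):
                raise SimConfigError(
                    f"correlation block {bi}: overlaps an earlier block")
            seen |= set(idx)

    # -- effect-map helpers ---------------------------------------------

    @property
    def gene_names(self) -> list[str]:
        return gene_names(self.n_genes)

    def _gene_index(self, key) -> int:
        names = self.gene_names
        if isinstance(key, (int, np.integer)):
            i = int(key)
            if not 0 <= i < self.n_genes:
                raise SimConfigError(f"gene index {i} out of range")
            return i
        try:
            return names.index(str(key))
        except ValueError:
            raise SimConfigError(f"unknown gene key {key!r}") from None

    def marginal_vector(self) -> np.ndarray:
        beta = np.zeros(self.n_genes)
        for key, value in self.marginal_effects.items():
            beta[self._gene_index(key)] = float(value)
        return beta

    def de_vector(self) -> np.ndarray:
        delta = np.zeros(self.n_genes)
        for key, value in self.de_effects.items():
            delta[self._gene_index(key)] = float(value)
        return delta

    def interaction_items(self) -> list[tuple[int, int, float]]:
        out = []
        for pair, gamma in self.interaction_effects.items():
            a, b = pair
            ia, ib = self._gene_index(a), self._gene_index(b)
            if ia == ib:
                raise SimConfigError("interaction pair must be two distinct genes")
            out.append((min(ia, ib), max(ia, ib), float(gamma)))
        return out


@dataclass
class TruthRecord:
    """Ground truth planted by :func:`generate_cohort`."""

    de_genes: set[str]
    marginal_genes: dict[str, float]
    interacting_pairs: dict[tuple[str, str], float]
    latent_z: np.ndarray  # n_patients x n_genes

    def to_json(self) -> str:
        payload = {
            "de_genes": sorted(self.de_genes),
            "marginal_genes": dict(sorted(self.marginal_genes.items())),
            "interacting_pairs": {
                "|".join(p): g
                for p, g in sorted(self.interacting_pairs.items())},
            "latent_z_shape": list(self.latent_z.shape),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _latent_cholesky(config: SimConfig) -> np.ndarray | None:
    """Cholesky factor of the latent gene-gene correlation matrix.

    Returns None for the identity (no blocks), avoiding an O(p^3)
    factorization in the common case.
    """
    if not config.corr_blocks:
        return None
    sigma = np.eye(config.n_genes)
    for bi, (idx, rho) in enumerate(config.corr_blocks):
        idx = np.asarray(list(idx), dtype=int)
        block = np.full((idx.size, idx.size), rho)
        np.fill_diagonal(block, 1.0)
        sigma[np.ix_(idx, idx)] = block
        try:
            np.linalg.cholesky(block)
        except np.linalg.LinAlgError:
            raise SimConfigError(
                f"correlation block {bi} (genes {idx.tolist()}, rho={rho}) "
                "implies a non-positive-definite latent covariance") from None
    return np.linalg.cholesky(sigma)


def _draw_latent(rng: np.random.Generator, n: int, chol, n_genes: int) -> np.ndarray:
    z = rng.standard_normal((n, n_genes))
    if chol is not None:
        z = z @ chol.T
    return z


def generate_cohort(config: SimConfig) -> tuple[Cohort, TruthRecord]:
    """Simulate one cohort plus its truth record.

    The latent z-matrix is multivariate normal with unit variances and
    the configured block correlations.  Observed tumor expression is
    ``exp(mu_g + sigma_g * z)``; normal samples are shifted by ``-delta_g``
    on the log scale for DE genes.  Event times follow a proportional
    hazards model with baseline hazard ``baseline_hazard`` (Weibull shape
    configurable, default exponential) and linear predictor
    ``sum(beta_g z_g) + sum(gamma_gh z_g z_h)``.  Censoring is the minimum
    of an exponential draw and the administrative cutoff.  The same seed
    always yields bit-identical output.
    """
    chol = _latent_cholesky(config)
    names = config.gene_names
    ss = np.random.SeedSequence(config.seed)
    rng_tumor, rng_normal, rng_event, rng_censor = (
        np.random.default_rng(s) for s in ss.spawn(4))

    mu = np.broadcast_to(np.asarray(config.expr_location, dtype=float),
                         (config.n_genes,))
    sd = np.broadcast_to(np.asarray(config.expr_scale, dtype=float),
                         (config.n_genes,))

    z = _draw_latent(rng_tumor, config.n_patients, chol, config.n_genes)
    tumor_expr = np.exp(mu + sd * z)  # n_patients x n_genes

    delta = config.de_vector()
    if config.n_normal > 0:
        zn = _draw_latent(rng_normal, config.n_normal, chol, config.n_genes)
        normal_expr = np.exp(mu + sd * zn - delta)
    else:
        normal_expr = np.empty((0, config.n_genes))

    beta = config.marginal_vector()
    lp = z @ beta
    interactions = config.interaction_items()
    for ia, ib, gamma in interactions:
        lp = lp + gamma * z[:, ia] * z[:, ib]

    # inverse-transform sampling of the Weibull PH model;
    # shape 1 reduces to Exponential(baseline * exp(lp))
    e = rng_event.exponential(1.0, size=config.n_patients)
    t_event = np.power(e * np.exp(-lp), 1.0 / config.weibull_shape) \
        / config.baseline_hazard
    if config.censor_hazard > 0:
        t_cens = rng_censor.exponential(1.0 / config.censor_hazard,
                                        size=config.n_patients)
    else:
        rng_censor.exponential(1.0, size=config.n_patients)  # keep streams aligned
        t_cens = np.full(config.n_patients, inf)
    t_cens = np.minimum(t_cens, config.admin_cutoff)
    time = np.minimum(t_event, t_cens)
    status = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-9)  # guard the measure-zero exact-0 draw

    patient_ids = [f"P{i:05d}" for i in range(config.n_patients)]
    normal_ids = [f"N{i:05d}" for i in range(config.n_normal)]
    expression = pd.DataFrame(
        np.hstack([tumor_expr.T, normal_expr.T]),
        index=pd.Index(names, name="gene"),
        columns=patient_ids + normal_ids)
    clinical = pd.DataFrame({
        "patient_id": patient_ids,
        "time_days": time,
        "status": status,
    })
    sample_class = pd.Series(
        ["tumor"] * config.n_patients + ["normal"] * config.n_normal,
        index=patient_ids + normal_ids, name="class")

    truth = TruthRecord(
        de_genes={names[i] for i in np.flatnonzero(delta != 0)},
        marginal_genes={names[i]: float(beta[i])
                        for i in np.flatnonzero(beta != 0)},
        interacting_pairs={(names[ia], names[ib]): gamma
                           for ia, ib, gamma in interactions},
        latent_z=z)
    return Cohort(expression, clinical, sample_class), truth


def generate_annotation(n_genes: int, n_sets: int,
                        set_size_range: tuple[int, int], seed: int, *,
                        enriched_genes: list[str] | None = None,
                        enrichment_bias: float = 0.0,
                        enriched_set_size: int | None = None,
                        ) -> dict[str, list[str]]:
    """Random GMT-writable gene-set collection over the simulated universe.

    When ``enriched_genes`` is given, one extra planted set named
    ``SET_PLANTED`` is added whose members are drawn preferentially from
    that list: a fraction ``enrichment_bias`` of its size comes from the
    list, the remainder from the rest of the universe.  Bias 1.0 with a
    matching size reproduces the designated list exactly.
    """
    lo, hi = set_size_range
    if lo > hi:
        raise SimConfigError(f"set_size_range inverted: ({lo}, {hi})")
    if hi > n_genes:
        raise SimConfigError("max set size exceeds the gene universe")
    if not 0.0 <= enrichment_bias <= 1.0:
        raise SimConfigError("enrichment_bias must be in [0, 1]")
    rng = np.random.default_rng(seed)
    universe = np.array(gene_names(n_genes))
    collection: dict[str, list[str]] = {}
    for si in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        collection[f"SET{si:04d}"] = sorted(members.tolist())
    if enriched_genes is not None:
        pool = [g for g in enriched_genes]
        size = enriched_set_size if enriched_set_size is not None else len(pool)
        if size > n_genes:
            raise SimConfigError("enriched set larger than the gene universe")
        n_from = min(round(enrichment_bias * size), len(pool), size)
        chosen = list(rng.choice(np.array(pool), size=n_from, replace=False))
        rest = np.array(sorted(set(universe) - set(pool)))
        n_rest = size - n_from
        if n_rest > rest.size:
            raise SimConfigError(
                "enriched set size exceeds genes available outside the list")
        chosen += list(rng.choice(rest, size=n_rest, replace=False))
        collection["SET_PLANTED"] = sorted(chosen)
    return collection
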