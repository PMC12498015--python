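"""Cohort container: expression matrix, clinical outcomes, sample classes."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Cohort", "CohortError"]

TUMOR = "tumor"
NORMAL = "normal"


class CohortError(ValueError):
    """Raised when cohort components are inconsistent."""


@dataclass
class Cohort:
    """A gene-expression cohort with survival outcomes.

    Parameters
    ----------
    expression : DataFrame
        Genes (rows) by samples (columns); non-negative continuous values
        on an RSEM-like scale.
    clinical : DataFrame
        One row per patient with columns ``patient_id``, ``time_days``
        (follow-up in days, > 0) and ``status`` (1 = death observed,
        0 = censored/alive).  Every patient id must be an expression
        column.
    sample_class : Series, optional
        Maps sample id to ``"tumor"`` or ``"normal"``.  When absent all
        expression columns are treated as tumor samples.
    """

    expression: pd.DataFrame
    clinical: pd.DataFrame
    sample_class: pd.Series | None = None

    def __post_init__(self):
        expr = self.expression
        clin = self.clinical
        if expr.index.has_duplicates:
            dups = expr.index[expr.index.duplicated()].unique().tolist()
            raise CohortError(f"duplicate gene ids: {dups[:10]}")
        if expr.columns.has_duplicates:
            raise CohortError("duplicate sample ids in expression matrix")
        required = {"patient_id", "time_days", "status"}
        missing = required - set(clin.columns)
        if missing:
            raise CohortError(f"clinical table missing columns: {sorted(missing)}")
        ids = clin["patient_id"]
        if ids.duplicated().any():
            raise CohortError("duplicate patient ids in clinical table")
        orphans = sorted(set(ids) - set(expr.columns))
        if orphans:
            raise CohortError(
                f"clinical patients missing from expression matrix: {orphans[:10]}")
        t = clin["time_days"].to_numpy(dtype=float)
        if not np.all(np.isfinite(t)) or np.any(t <= 0):
            raise CohortError("time_days must be finite and > 0")
        st = clin["status"].to_numpy()
        if not np.isin(st, [0, 1]).all():
            raise CohortError("status must be 0 (censored) or 1 (event)")
        vals = expr.to_numpy(dtype=float)
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise CohortError("expression values must be finite and >= 0")
        if self.sample_class is not None:
            sc = self.sample_class
            unknown = sorted(set(sc.unique()) - {TUMOR, NORMAL})
            if unknown:
                raise CohortError(f"unknown sample classes: {unknown}")
            unlabeled = sorted(set(expr.columns) - set(sc.index))
            if unlabeled:
                raise CohortError(f"unlabeled samples: {unlabeled[:10]}")

    # -- convenience accessors ------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.expression.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.clinical["patient_id"])

    @property
    def n_patients(self) -> int:
        return len(self.clinical)

    @property
    def tumor_samples(self) -> list[str]:
        if self.sample_class is None:
            return list(self.expression.columns)
        return [s for s in self.expression.columns
                if self.sample_class.get(s) == TUMOR]

    @property
    def normal_samples(self) -> list[str]:
        if self.sample_class is None:
            return []
        return [s for s in self.expression.columns
                if self.sample_class.get(s) == NORMAL]

    @property
    def has_normals(self) -> bool:
        return len(self.normal_samples) > 0

    def require_genes(self, genes) -> None:
        missing = sorted(set(genes) - set(self.expression.index))
        if missing:
            raise CohortError(f"unknown gene ids: {missing}")

    def patient_values(self, gene: str) -> np.ndarray:
        """Expression of ``gene`` across clinical patients, clinical order."""
        self.require_genes([gene])
        return self.expression.loc[gene, self.clinical["patient_id"]].to_numpy(
            dtype=float)

    def survival_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, status) aligned with the clinical table order."""
        return (self.clinical["time_days"].to_numpy(dtype=float),
                self.clinical["status"].to_numpy(dtype=int).astype(bool))

    def tumor_values(self, gene: str) -> np.ndarray:
        self.require_genes([gene])
        return self.expression.loc[gene, self.tumor_samples].to_numpy(dtype=float)

    def normal_values(self, gene: str) -> np.ndarray:
        self.require_genes([gene])
        return self.expression.loc[gene, self.normal_samples].to_numpy(dtype=float)
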