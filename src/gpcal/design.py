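"""Predictor blocks shared by the deep-learning models and ridge-form GBLUP.

For record r observed on line j(r) in environment i(r):

- ``XE`` is the full one-hot environment incidence (no reference level is
  dropped; the models downstream carry their own intercepts or use
  environment cell means).
- ``XG`` is the line incidence post-multiplied by the lower Cholesky
  factor L of the genomic relationship matrix, so XG row r is row j(r)
  of L and XG XG' reproduces Z (G + jitter I) Z'.
- ``XGE`` is the row-wise (Khatri-Rao) product of XE and XG, ordered
  environment-major: column (i, j) is XE[:, i] * XG[:, j]. Its
  cross-product realizes the Kronecker covariance I (x) G of independent
  per-environment genomic deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import PhenotypeTable
from .kinship import GenomicRelationship

__all__ = ["DesignSet", "build_design"]


@dataclass
class DesignSet:
    """Concatenable predictor blocks for one ordered set of records."""

    XE: np.ndarray
    XG: np.ndarray
    XGE: np.ndarray | None
    env_ids: list[str]
    line_ids: list[str]
    include_ge: bool

    @property
    def n_records(self) -> int:
        return self.XE.shape[0]

    @property
    def n_env(self) -> int:
        return self.XE.shape[1]

    @property
    def n_lines(self) -> int:
        return self.XG.shape[1]

    def matrix(self) -> np.ndarray:
        """The concatenated predictor (XE, XG[, XGE])."""
        blocks = [self.XE, self.XG]
        if self.include_ge:
            blocks.append(self.XGE)
        return np.hstack(blocks)

    def take(self, indices: np.ndarray) -> "DesignSet":
        """Row subset (same columns); used to slice train/test folds."""
        idx = np.asarray(indices)
        return DesignSet(
            XE=self.XE[idx],
            XG=self.XG[idx],
            XGE=self.XGE[idx] if self.XGE is not None else None,
            env_ids=list(self.env_ids),
            line_ids=list(self.line_ids),
            include_ge=self.include_ge,
        )


def build_design(
    pheno: PhenotypeTable,
    relationship: GenomicRelationship,
    include_ge: bool = True,
) -> DesignSet:
    """Assemble XE, XG and (optionally) XGE for the records of ``pheno``.

    Environment columns follow ``pheno.env_ids`` order; line columns
    follow the relationship matrix's line order; XGE columns are
    environment-major. Every record's line must be present in the
    relationship matrix, whose ``chol_factor`` must already be populated.
    """
    if pheno.n_records == 0:
        raise ValueError("empty phenotype table")
    if relationship.chol_factor is None:
        raise ValueError(
            "relationship has no Cholesky factor; call stabilized_cholesky first"
        )
    L = relationship.chol_factor
    line_pos = {lid: k for k, lid in enumerate(relationship.line_ids)}
    unknown = [l for l in pheno.line_ids if l not in line_pos]
    if unknown:
        raise ValueError(f"phenotype lines absent from marker data: {unknown[:5]}")

    env_pos = {e: i for i, e in enumerate(pheno.env_ids)}
    env_idx = np.array([env_pos[e] for e in pheno.record_envs])
    row_idx = np.array([line_pos[l] for l in pheno.record_lines])

    n_rec = pheno.n_records
    n_env = len(pheno.env_ids)
    XE = np.zeros((n_rec, n_env))
    XE[np.arange(n_rec), env_idx] = 1.0
    XG = L[row_idx, :]

    XGE = None
    if include_ge:
        n_lines = L.shape[1]
        XGE = np.zeros((n_rec, n_env * n_lines))
        for i in range(n_env):
            XGE[:, i * n_lines : (i + 1) * n_lines] = XE[:, [i]] * XG

    return DesignSet(
        XE=XE,
        XG=XG,
        XGE=XGE,
        env_ids=list(pheno.env_ids),
        line_ids=list(relationship.line_ids),
        include_ge=include_ge,
    )
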