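"""VanRaden genomic relationship matrix and its stabilized Cholesky factor.

The realized genomic kinship between lines is estimated as

    G = W W' / (2 * sum_k p_k (1 - p_k))

where W is the allele-count matrix column-centered by twice the allele
frequency (W_jk = x_jk - 2 p_k) and p_k is estimated from the sample.
Downstream, the genotype predictor block is the line-incidence matrix
post-multiplied by a lower Cholesky factor L of G, so that the implied
covariance of the line effects is proportional to G. Because G from a
finite marker panel is routinely rank-deficient, the factorization adds
the smallest diagonal jitter from an escalation schedule that makes it
succeed, and records the jitter actually used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import MarkerMatrix

__all__ = [
    "GenomicRelationship",
    "vanraden_relationship",
    "stabilized_cholesky",
    "genomic_relationship",
]

logger = logging.getLogger(__name__)

_SYM_TOL = 1e-8
_RECON_TOL = 1e-8


@dataclass
class GenomicRelationship:
    """G matrix with line identifiers and (optionally) its Cholesky factor.

    ``chol_factor`` is ``None`` until :func:`stabilized_cholesky` has been
    applied; ``jitter`` is the diagonal inflation actually used there.
    """

    line_ids: list[str]
    G: np.ndarray
    chol_factor: np.ndarray | None = None
    jitter: float | None = None

    @property
    def n_lines(self) -> int:
        return self.G.shape[0]


def vanraden_relationship(markers: MarkerMatrix) -> GenomicRelationship:
    """Compute the VanRaden G matrix from 0/1/2 allele counts.

    Allele frequencies are estimated from the sample. Monomorphic markers
    (estimated p of exactly 0 or 1) contribute nothing to either the
    numerator or the denominator; they are dropped with a warning. If every
    marker is monomorphic the denominator is zero and an error is raised.

    Returns a :class:`GenomicRelationship` whose ``chol_factor`` is not yet
    populated.
    """
    p = markers.allele_freqs
    poly = (p > 0.0) & (p < 1.0)
    n_dropped = int((~poly).sum())
    if n_dropped == markers.n_markers:
        raise ValueError(
            "all markers are monomorphic: VanRaden denominator 2*sum p(1-p) is zero"
        )
    if n_dropped:
        logger.warning(
            "dropping %d monomorphic marker(s) before computing G", n_dropped
        )
    geno = markers.genotypes[:, poly].astype(float)
    pk = p[poly]
    W = geno - 2.0 * pk  # column-centered allele counts
    denom = 2.0 * float(np.sum(pk * (1.0 - pk)))
    G = (W @ W.T) / denom
    G = (G + G.T) / 2.0  # enforce exact symmetry
    return GenomicRelationship(line_ids=list(markers.line_ids), G=G)


def stabilized_cholesky(
    G: np.ndarray, base_jitter: float = 1e-8
) -> tuple[np.ndarray, float]:
    """Lower Cholesky factor of ``G + jitter*I`` with escalating jitter.

    Tries jitter 0 first, then ``base_jitter`` scaled by successive powers
    of 10 (8 escalations). Returns ``(L, jitter_used)`` with
    ``L L' = G + jitter_used * I`` to within 1e-8 elementwise.

    Raises
    ------
    ValueError
        If ``G`` is not symmetric.
    np.linalg.LinAlgError
        If factorization still fails at the largest jitter.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("G must be a square matrix")
    scale = max(1.0, float(np.abs(G).max()) if G.size else 1.0)
    if float(np.abs(G - G.T).max()) > _SYM_TOL * scale:
        raise ValueError("G is not symmetric")
    Gs = (G + G.T) / 2.0
    n = Gs.shape[0]
    schedule = [0.0] + [base_jitter * 10.0**k for k in range(8)]
    for jitter in schedule:
        try:
            L = np.linalg.cholesky(Gs + jitter * np.eye(n))
        except np.linalg.LinAlgError:
            continue
        recon = float(np.abs(L @ L.T - (Gs + jitter * np.eye(n))).max())
        if recon < _RECON_TOL * scale:
            if jitter > 0.0:
                logger.info("Cholesky required diagonal jitter %.3g", jitter)
            return L, jitter
    raise np.linalg.LinAlgError(
        "Cholesky factorization failed after 8 jitter escalations "
        f"(base {base_jitter:g})"
    )


def genomic_relationship(
    markers: MarkerMatrix, base_jitter: float = 1e-8
) -> GenomicRelationship:
    """VanRaden G with its stabilized Cholesky factor populated."""
    rel = vanraden_relationship(markers)
    L, jitter = stabilized_cholesky(rel.G, base_jitter=base_jitter)
    rel.chol_factor = L
    rel.jitter = jitter
    return rel
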