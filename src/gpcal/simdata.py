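"""Synthetic multi-environment trial generator with known truth.

Emulates a balanced genomic-selection trial: lines genotyped at
independent biallelic SNPs under Hardy-Weinberg proportions, and a trait
generated record-wise as

    Y_ij = Loc_i + g_j + gL_ij + eps_ij

with additive genetic values g_j = sum_k W_jk beta_k built from centered
genotypes, environment-specific genomic interaction deviations gL_ij, and
Gaussian noise. Marker effects are rescaled so the *realized* genetic
variance hits the requested heritability exactly on each dataset, which
makes variance-component recovery targets sharp rather than approximate.

Linkage disequilibrium, dominance/epistasis and pedigree structure are
deliberately not simulated; the prediction methods under study do not
depend on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MarkerMatrix, PhenotypeTable

__all__ = ["SimConfig", "TruthRecord", "simulate_markers", "simulate_trial"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic trial.

    h2 is the narrow-sense heritability target Var(g)/Var(Y) within an
    environment when ge_ratio=0; ge_ratio is sigma2_gL / sigma2_g, the
    size of genotype-by-environment deviations relative to the main
    genetic variance. env_means are the fixed environment effects in
    trait units (default: equally spaced, unit step, centered at 0).
    """

    n_lines: int
    n_markers: int
    n_env: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2: float = 0.5
    ge_ratio: float = 0.0
    env_means: tuple[float, ...] | None = None
    residual_var: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        if self.n_env < 1:
            raise ValueError("n_env must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be ordered and within (0, 0.5]")
        if not (0.0 < self.h2 < 1.0):
            raise ValueError("h2 must be in (0, 1)")
        if self.ge_ratio < 0.0:
            raise ValueError("ge_ratio must be >= 0")
        if self.h2 * (1.0 + self.ge_ratio) >= 1.0:
            raise ValueError(
                "h2 * (1 + ge_ratio) must be < 1 for a positive residual share"
            )
        if self.residual_var < 0.0:
            raise ValueError("residual_var must be >= 0")
        if self.env_means is not None and len(self.env_means) != self.n_env:
            raise ValueError("env_means length must equal n_env")

    def resolved_env_means(self) -> np.ndarray:
        if self.env_means is not None:
            return np.asarray(self.env_means, dtype=float)
        if self.n_env == 1:
            return np.zeros(1)
        half = (self.n_env - 1) / 2.0
        return np.linspace(-half, half, self.n_env)


@dataclass
class TruthRecord:
    """Ground truth retained from a simulation for oracle checks."""

    marker_effects: np.ndarray          # per-allele-copy trait effects
    true_genetic_values: np.ndarray     # lines x envs, g_j + gL_ij
    env_means: np.ndarray
    sigma2_g: float                     # realized Var(g)
    sigma2_gL: float                    # realized mean per-env Var(gL)
    sigma2_e: float                     # realized Var(eps)

    def __post_init__(self) -> None:
        if min(self.sigma2_g, self.sigma2_gL, self.sigma2_e) < 0:
            raise ValueError("realized variances must be nonnegative")


def _rngs(config: SimConfig) -> tuple[np.random.Generator, np.random.Generator]:
    marker_ss, trial_ss = np.random.SeedSequence(config.seed).spawn(2)
    return np.random.default_rng(marker_ss), np.random.default_rng(trial_ss)


def simulate_markers(config: SimConfig) -> MarkerMatrix:
    """Draw a lines x markers 0/1/2 genotype matrix.

    Per-marker allele frequencies are uniform on ``maf_range``; each
    genotype is Binomial(2, p_k) independently across lines and markers
    (Hardy-Weinberg, no linkage disequilibrium). Deterministic for a
    given ``config.seed``.
    """
    rng, _ = _rngs(config)
    lo, hi = config.maf_range
    p = rng.uniform(lo, hi, size=config.n_markers)
    geno = rng.binomial(2, p, size=(config.n_lines, config.n_markers))
    line_ids = [f"L{j + 1:04d}" for j in range(config.n_lines)]
    return MarkerMatrix(line_ids=line_ids, genotypes=geno)


def _scaled_genomic_values(
    W: np.ndarray, raw_effects: np.ndarray, target_var: float
) -> tuple[np.ndarray, np.ndarray]:
    """Scale raw marker effects so Var(W beta) equals target_var exactly."""
    raw = W @ raw_effects
    v = float(np.var(raw))
    if target_var == 0.0 or v == 0.0:
        if target_var > 0.0 and v == 0.0:
            raise ValueError(
                "genotypes carry no variance; cannot reach a positive "
                "genetic-variance target"
            )
        return np.zeros(W.shape[0]), np.zeros(raw_effects.shape)
    c = np.sqrt(target_var / v)
    return raw * c, raw_effects * c


def simulate_trial(
    markers: MarkerMatrix, config: SimConfig
) -> tuple[PhenotypeTable, TruthRecord]:
    """Generate a balanced phenotype table plus its ground truth.

    Produces exactly ``n_lines * n_env`` records (environment-major
    order). The realized variance components are

    - sigma2_g = h2 * residual_var / (1 - h2 * (1 + ge_ratio)),
    - sigma2_gL = ge_ratio * sigma2_g (per environment),

    both enforced exactly by empirical rescaling, so that
    Var(g) / (Var(g) + Var(gL) + sigma2) = h2.
    """
    if markers.n_lines != config.n_lines or markers.n_markers != config.n_markers:
        raise ValueError(
            f"marker matrix {markers.n_lines}x{markers.n_markers} does not match "
            f"config {config.n_lines}x{config.n_markers}"
        )
    _, rng = _rngs(config)
    denom = 1.0 - config.h2 * (1.0 + config.ge_ratio)
    sigma2_g = config.h2 * config.residual_var / denom if config.residual_var > 0 else (
        config.h2 / denom  # unit-scale genetic signal when noise is off
    )
    sigma2_gl = config.ge_ratio * sigma2_g

    W = markers.genotypes.astype(float)
    W -= W.mean(axis=0)
    raw_beta = rng.standard_normal(config.n_markers)
    g, beta = _scaled_genomic_values(W, raw_beta, sigma2_g)

    gl = np.zeros((config.n_lines, config.n_env))
    if sigma2_gl > 0.0:
        for i in range(config.n_env):
            gl[:, i], _ = _scaled_genomic_values(
                W, rng.standard_normal(config.n_markers), sigma2_gl
            )

    eps = (
        rng.normal(0.0, np.sqrt(config.residual_var),
                   size=(config.n_lines, config.n_env))
        if config.residual_var > 0.0
        else np.zeros((config.n_lines, config.n_env))
    )

    env_means = config.resolved_env_means()
    env_ids = [f"ENV{i + 1}" for i in range(config.n_env)]
    genetic = g[:, None] + gl
    Y = env_means[None, :] + genetic + eps

    rows = []
    for i, env in enumerate(env_ids):
        for j, line in enumerate(markers.line_ids):
            rows.append((line, env, Y[j, i]))
    pheno = PhenotypeTable(
        pd.DataFrame(rows, columns=["line_id", "env_id", "value"]),
        env_ids=env_ids,
        line_ids=list(markers.line_ids),
    )
    truth = TruthRecord(
        marker_effects=beta,
        true_genetic_values=genetic,
        env_means=env_means,
        sigma2_g=float(np.var(g)),
        sigma2_gL=float(np.mean(np.var(gl, axis=0))) if config.n_env else 0.0,
        sigma2_e=float(np.var(eps)),
    )
    return pheno, truth
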