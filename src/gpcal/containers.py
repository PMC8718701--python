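"""Core in-memory containers shared across the package.

`MarkerMatrix` holds genotypes of inbred/DH lines coded as allele counts
0/1/2 (the coding of the released trial datasets after quality control).
`PhenotypeTable` holds record-level observations of one trait across
environments, one row per (line, environment) assessment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MarkerMatrix", "PhenotypeTable"]


class ValidationError(ValueError):
    """Raised when an input container violates its contract."""


@dataclass
class MarkerMatrix:
    """Lines x markers genotype counts with line identifiers.

    Parameters
    ----------
    line_ids
        Ordered, unique line identifiers (one per genotype row).
    genotypes
        Integer matrix of shape ``(n_lines, n_markers)`` with entries in
        ``{0, 1, 2}`` counting copies of the reference allele. Missing
        values are not accepted: imputation belongs upstream.
    marker_ids
        Optional marker column names; generated as ``m0001...`` if absent.
    """

    line_ids: list[str]
    genotypes: np.ndarray
    marker_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.ndim != 2:
            raise ValidationError("genotypes must be a 2-D lines x markers matrix")
        n, m = self.genotypes.shape
        if n < 1 or m < 1:
            raise ValidationError("genotype matrix must be non-empty")
        if len(self.line_ids) != n:
            raise ValidationError(
                f"{len(self.line_ids)} line ids for {n} genotype rows"
            )
        if len(set(self.line_ids)) != n:
            raise ValidationError("duplicate line ids in marker matrix")
        if not np.isfinite(self.genotypes.astype(float)).all():
            raise ValidationError("genotypes contain missing/non-finite cells")
        bad = ~np.isin(self.genotypes, (0, 1, 2))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"genotype value {self.genotypes[r, c]!r} at line "
                f"{self.line_ids[r]!r}, marker column {c} is not in {{0,1,2}}"
            )
        self.genotypes = self.genotypes.astype(np.int8)
        if self.marker_ids is None:
            width = max(4, len(str(m)))
            self.marker_ids = [f"m{j + 1:0{width}d}" for j in range(m)]
        elif len(self.marker_ids) != m:
            raise ValidationError("marker_ids length does not match columns")

    @property
    def n_lines(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    @property
    def allele_freqs(self) -> np.ndarray:
        """Per-marker reference-allele frequency p_k = column mean / 2."""
        return self.genotypes.mean(axis=0) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.genotypes, index=pd.Index(self.line_ids, name="line_id"),
            columns=self.marker_ids,
        )


@dataclass
class PhenotypeTable:
    """Record-level trait observations Y_ij across environments.

    One row per assessment of a line j in an environment i. The table may
    be balanced (every line in every environment) or not; balance is never
    required downstream.
    """

    records: pd.DataFrame  # columns line_id, env_id, value
    env_ids: list[str] = field(default_factory=list)
    line_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.records
        required = ["line_id", "env_id", "value"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"phenotype table missing columns: {missing}")
        if len(df) == 0:
            raise ValidationError("phenotype table has no records")
        values = pd.to_numeric(df["value"], errors="coerce")
        if not np.isfinite(values.to_numpy(dtype=float)).all():
            bad = df.loc[~np.isfinite(values.to_numpy(dtype=float))]
            raise ValidationError(
                f"non-finite/non-numeric trait values at rows {list(bad.index[:5])}"
            )
        dup = df.duplicated(subset=["line_id", "env_id"])
        if dup.any():
            pair = df.loc[dup.idxmax(), ["line_id", "env_id"]].tolist()
            raise ValidationError(
                f"duplicated (line, environment) record: {tuple(pair)}; "
                "expected one assessment per line per environment"
            )
        df = df[required].copy()
        df["line_id"] = df["line_id"].astype(str)
        df["env_id"] = df["env_id"].astype(str)
        df["value"] = values.astype(float).to_numpy()
        df = df.reset_index(drop=True)
        self.records = df
        # first-appearance order, stable across runs
        if not self.env_ids:
            self.env_ids = list(dict.fromkeys(df["env_id"]))
        if not self.line_ids:
            self.line_ids = list(dict.fromkeys(df["line_id"]))

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def y(self) -> np.ndarray:
        return self.records["value"].to_numpy()

    @property
    def record_envs(self) -> np.ndarray:
        return self.records["env_id"].to_numpy()

    @property
    def record_lines(self) -> np.ndarray:
        return self.records["line_id"].to_numpy()

    def take(self, indices: np.ndarray) -> "PhenotypeTable":
        """Row subset preserving the parent's env/line ordering."""
        sub = self.records.iloc[np.asarray(indices)].reset_index(drop=True)
        return PhenotypeTable(sub, env_ids=list(self.env_ids),
                              line_ids=list(self.line_ids))
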