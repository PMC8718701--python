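"""CSV readers/writers and run-configuration loading.

Interchange dialect: comma-separated by default with tab auto-detected.
Genotypes travel as small integers; relationship matrices and design
blocks as floating point.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import MarkerMatrix, PhenotypeTable, ValidationError
from .kinship import GenomicRelationship

__all__ = [
    "read_markers", "write_markers", "read_phenotypes", "write_phenotypes",
    "write_relationship", "load_config",
]


def _read_table(path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # sniff comma vs tab on the first line
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") > first.count(",") else ","
    return pd.read_csv(path, sep=sep, **kwargs)


def read_markers(path) -> MarkerMatrix:
    """Read a lines x markers CSV (line IDs in the first column).

    Cells must be 0, 1 or 2 with nothing missing; offending cells are
    named in the error.
    """
    df = _read_table(path, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"{path}: no genotype data (header-only file?)")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate line id {dup!r}")
    values = df.to_numpy()
    numeric = pd.to_numeric(pd.Series(values.ravel()), errors="coerce")
    arr = numeric.to_numpy(dtype=float).reshape(values.shape)
    bad = ~np.isin(arr, (0.0, 1.0, 2.0)) | ~np.isfinite(arr)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: invalid genotype {values[r, c]!r} at line "
            f"{df.index[r]!r}, marker {df.columns[c]!r} (expected 0/1/2)"
        )
    return MarkerMatrix(
        line_ids=[str(i) for i in df.index],
        genotypes=arr.astype(np.int8),
        marker_ids=[str(c) for c in df.columns],
    )


def write_markers(markers: MarkerMatrix, path) -> None:
    markers.to_frame().to_csv(path)


def read_phenotypes(path) -> PhenotypeTable:
    """Read a long-format phenotype CSV with columns line_id, env_id, value."""
    df = _read_table(path)
    missing = [c for c in ("line_id", "env_id", "value") if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.records.to_csv(path, index=False)


def write_relationship(rel: GenomicRelationship, path) -> None:
    pd.DataFrame(rel.G, index=rel.line_ids, columns=rel.line_ids).to_csv(path)


def load_config(path) -> dict:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
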