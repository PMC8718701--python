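import numpy as np
import pandas as pd
import pytest

from gpcal import (MarkerMatrix, PhenotypeTable, SimConfig, build_design,
                   genomic_relationship, simulate_markers, simulate_trial)


@pytest.fixture(scope="session")
def toy_markers():
    """3 lines x 2 markers with hand-computable VanRaden G."""
    return MarkerMatrix(
        line_ids=["a", "b", "c"],
        genotypes=np.array([[0, 2], [2, 0], [1, 1]]),
    )


@pytest.fixture(scope="session")
def small_trial():
    """60 lines x 3 environments with moderate heritability and G x E."""
    cfg = SimConfig(n_lines=60, n_markers=120, n_env=3, h2=0.4,
                    ge_ratio=0.5, residual_var=1.0, seed=11)
    markers = simulate_markers(cfg)
    pheno, truth = simulate_trial(markers, cfg)
    rel = genomic_relationship(markers)
    return {"config": cfg, "markers": markers, "pheno": pheno,
            "truth": truth, "rel": rel}


@pytest.fixture(scope="session")
def small_design(small_trial):
    return build_design(small_trial["pheno"], small_trial["rel"],
                        include_ge=True)


@pytest.fixture
def tiny_pheno():
    """12 unbalanced records over 2 environments and 4 lines."""
    rows = []
    rng = np.random.default_rng(5)
    for line in "abcd":
        for env in ("E1", "E2"):
            rows.append((line, env, float(rng.normal())))
    for line in "abcd":
        rows.append((line, "E3", float(rng.normal())))
    return PhenotypeTable(pd.DataFrame(rows,
                                       columns=["line_id", "env_id", "value"]))
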