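"""Shared fixtures: tiny count matrices and DGE-result builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pkdcore import CountMatrix, RunConfig


@pytest.fixture
def cfg() -> RunConfig:
    return RunConfig(seed=1)


@pytest.fixture
def tiny_cm() -> CountMatrix:
    """2 genes x 2 samples, one WT and one KO."""
    counts = pd.DataFrame(
        [[1, 2], [3, 4]], index=["g1", "g2"], columns=["s1", "s2"], dtype=np.int64
    )
    genotype = pd.Series(["WT", "KO1"], index=["s1", "s2"], name="genotype")
    return CountMatrix(counts, genotype, reference="WT")


def make_dge_frame(genes, lfc, fdr, de_flag=None, cfg: RunConfig | None = None) -> pd.DataFrame:
    """Assemble a DGE-result-shaped frame; the DE flag follows the thresholds
    unless given explicitly."""
    cfg = cfg or RunConfig()
    lfc = np.asarray(lfc, dtype=float)
    fdr = np.asarray(fdr, dtype=float)
    if de_flag is None:
        de_flag = (fdr < cfg.fdr_max) & (np.abs(lfc) >= cfg.lfc_min)
    return pd.DataFrame(
        {
            "base_mean": np.full(len(genes), 100.0),
            "lfc": lfc,
            "se": np.full(len(genes), 0.1),
            "p": fdr / 2.0,
            "fdr": fdr,
            "de_flag": np.asarray(de_flag, dtype=bool),
            "tested": np.ones(len(genes), dtype=bool),
            "converged": np.ones(len(genes), dtype=bool),
        },
        index=pd.Index(genes, name="gene"),
    )
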