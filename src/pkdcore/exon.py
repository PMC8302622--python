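"""Differential exon usage (DEU) and cross-genotype overlap.

For each exon the focal count is modelled against the rest of its gene
(gene total minus the exon) as an overdispersed binomial with
logit(pi) = beta0 + beta1 * genotype. The Wald test on beta1, with the
standard error inflated by the square root of the Pearson overdispersion
(floored at 1), asks whether the exon's share of its gene's expression
depends on genotype — the same null hypothesis as per-exon GLM packages,
in a self-contained quasi-binomial form. BH adjustment runs across all
tested exons; an exon is significant at fdr < 0.05.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError

__all__ = ["deu_test", "overlap_deu"]

log = logging.getLogger(__name__)

MIN_EXON_MEAN = 5.0  # mean count across samples required to test an exon


def _check_exon_table(exon_counts: pd.DataFrame, samples: list[str]) -> None:
    for col in ("gene_id", "exon_id"):
        if col not in exon_counts.columns:
            raise AnalysisError(f"exon table missing column {col!r}")
    missing = [s for s in samples if s not in exon_counts.columns]
    if missing:
        raise AnalysisError(f"exon table missing sample columns: {missing}")


def _quasibin_irls(
    y: np.ndarray, n: np.ndarray, x: np.ndarray, max_iter: int = 100, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-parameter logistic IRLS over exons.

    y: exon counts (E x S); n: gene totals (E x S); x: genotype indicator (S,).
    Returns (b1, se_b1, phi, converged); samples with n = 0 carry zero weight.
    """
    E, S = y.shape
    valid = n > 0
    eps = 0.5
    p0 = (np.where(valid & (x == 0), y, 0).sum(1) + eps) / (
        np.where(valid & (x == 0), n, 0).sum(1) + 2 * eps
    )
    p1 = (np.where(valid & (x == 1), y, 0).sum(1) + eps) / (
        np.where(valid & (x == 1), n, 0).sum(1) + 2 * eps
    )
    b0 = np.log(p0 / (1 - p0))
    b1 = np.log(p1 / (1 - p1)) - b0
    converged = np.zeros(E, dtype=bool)
    for _ in range(max_iter):
        eta = np.clip(b0[:, None] + b1[:, None] * x[None, :], -30, 30)
        pi = 1.0 / (1.0 + np.exp(-eta))
        w = np.where(valid, n * pi * (1 - pi), 0.0)
        w = np.maximum(w, 1e-12) * valid
        z = eta + np.where(valid, (y - n * pi) / np.maximum(w, 1e-12), 0.0)
        sw = w.sum(1)
        swx = (w * x).sum(1)
        swz = (w * z).sum(1)
        swxz = (w * z * x).sum(1)
        det = swx * (sw - swx)
        det = np.where(det > 0, det, np.nan)
        nb0 = (swx * swz - swx * swxz) / det
        nb1 = (sw * swxz - swx * swz) / det
        delta = np.maximum(np.abs(nb0 - b0), np.abs(nb1 - b1))
        upd = ~converged & np.isfinite(nb0) & np.isfinite(nb1)
        b0 = np.where(upd, nb0, b0)
        b1 = np.where(upd, nb1, b1)
        converged |= upd & (delta < tol)
        if converged.all():
            break
    eta = np.clip(b0[:, None] + b1[:, None] * x[None, :], -30, 30)
    pi = 1.0 / (1.0 + np.exp(-eta))
    w = np.where(valid, n * pi * (1 - pi), 0.0)
    sw = w.sum(1)
    swx = (w * x).sum(1)
    det = swx * (sw - swx)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.where(det > 0, sw / det, np.nan))
        pearson = np.where(valid, (y - n * pi) ** 2 / np.maximum(n * pi * (1 - pi), 1e-12), 0.0)
    df = valid.sum(1) - 2
    phi = np.where(df > 0, pearson.sum(1) / np.maximum(df, 1), 1.0)
    phi = np.maximum(phi, 1.0)
    converged &= np.abs(b1) < 25.0
    return b1, se, phi, converged


def deu_test(
    exon_counts: pd.DataFrame,
    genotype: pd.Series,
    contrast: tuple[str, str],
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Overdispersed-binomial Wald test of exon usage, one contrast.

    ``exon_counts`` is long format (``gene_id``, ``exon_id``, one column per
    sample). Exons are tested only when their gene has >= 2 exons, the exon's
    mean count is >= 5 across all samples, and the gene total is non-zero in
    >= 2 samples of each group; others are reported untested. Single-exon
    genes are skipped with a log entry.
    """
    ko, ref = contrast
    samples = [s for s in genotype.index if genotype[s] in (ko, ref)]
    _check_exon_table(exon_counts, samples)
    x = np.array([1.0 if genotype[s] == ko else 0.0 for s in samples])
    if (x == 1).sum() < 2 or (x == 0).sum() < 2:
        raise AnalysisError("each contrast group needs >= 2 samples")

    y_all = exon_counts[samples].to_numpy(dtype=float)
    gene_ids = exon_counts["gene_id"].to_numpy()
    totals = (
        exon_counts[["gene_id"]]
        .assign(**{s: exon_counts[s] for s in samples})
        .groupby("gene_id", sort=False)[samples]
        .transform("sum")
        .to_numpy(dtype=float)
    )
    n_exons_per_gene = exon_counts.groupby("gene_id", sort=False)["exon_id"].transform("count").to_numpy()

    single = n_exons_per_gene < 2
    if single.any():
        log.info("skipping %d exons of single-exon genes", int(single.sum()))
    rest = totals  # 'n' in the binomial is the gene total; y is the focal exon
    ok_totals = np.zeros(len(exon_counts), dtype=bool)
    for grp_val in (0.0, 1.0):
        cols = x == grp_val
        ok_totals_grp = (rest[:, cols] > 0).sum(axis=1) >= 2
        ok_totals = ok_totals_grp if grp_val == 0.0 else (ok_totals & ok_totals_grp)
    testable = (~single) & ok_totals & (y_all.mean(axis=1) >= MIN_EXON_MEAN)

    b1 = np.full(len(exon_counts), np.nan)
    se = np.full(len(exon_counts), np.nan)
    phi = np.full(len(exon_counts), np.nan)
    conv = np.zeros(len(exon_counts), dtype=bool)
    if testable.any():
        b1_t, se_t, phi_t, conv_t = _quasibin_irls(y_all[testable], rest[testable], x)
        b1[testable], se[testable], phi[testable], conv[testable] = b1_t, se_t, phi_t, conv_t

    with np.errstate(divide="ignore", invalid="ignore"):
        wald = b1 / (se * np.sqrt(phi))
    p = 2.0 * stats.norm.sf(np.abs(wald))
    p = np.where(testable & conv, p, np.nan)

    from .dge import bh_adjust

    fdr = bh_adjust(p)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = y_all / np.maximum(rest, 1.0)
    prop_ref = prop[:, x == 0].mean(axis=1)
    prop_ko = prop[:, x == 1].mean(axis=1)

    return pd.DataFrame(
        {
            "gene_id": exon_counts["gene_id"].to_numpy(),
            "exon_id": exon_counts["exon_id"].to_numpy(),
            "prop_ref": prop_ref,
            "prop_ko": prop_ko,
            "log_odds_shift": b1,
            "se": se,
            "phi": phi,
            "p": p,
            "fdr": fdr,
            "significant": np.nan_to_num(fdr, nan=1.0) < fdr_max,
            "tested": testable & conv,
        }
    )


def overlap_deu(r1: pd.DataFrame, r2: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Exons significant in BOTH contrasts, plus the distinct-gene count."""
    key = ["gene_id", "exon_id"]
    u1 = set(map(tuple, r1[key].to_numpy()))
    u2 = set(map(tuple, r2[key].to_numpy()))
    if u1 != u2:
        raise AnalysisError("DEU results cover different exon universes")
    sig1 = r1.loc[r1["significant"], key]
    sig2 = set(map(tuple, r2.loc[r2["significant"], key].to_numpy()))
    both = sig1[[tuple(row) in sig2 for row in sig1.to_numpy()]].reset_index(drop=True)
    n_genes = both["gene_id"].nunique()
    return both, int(n_genes)
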