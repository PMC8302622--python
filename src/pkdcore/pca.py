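"""Variance-ranked gene filtering and PCA loading–based gene selection.

Genes are ranked by the variance of log2(normalized count + 1) across samples
and the top fraction (default 10%, floor rounding) enters the PCA. The
centered sample × gene matrix is decomposed by SVD; loadings are the right
singular vectors and a gene's contribution to a component is its squared
loading. Genes are ranked by contribution on the selection component
(default PC2, which in the two-knockout design discriminates both knockouts
from wild type while PC1 captures inter-clone variation) and the top fraction
(default 20%, floor) is selected. With the study's printed sizes this
reproduces floor(0.10 x 25,062) = 2,506 PCA-input genes and
floor(0.20 x 2,506) = 501 selected genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError

__all__ = [
    "PCASelection",
    "select_variable_genes",
    "pca_loadings",
    "select_by_loading",
    "auto_select_component",
]


@dataclass
class PCASelection:
    """PCA of samples over a variable-gene subset.

    ``loadings``: genes × components (orthonormal columns, each oriented so
    its largest-magnitude entry is positive). ``scores``: samples ×
    components. ``variance_explained``: per-component fraction of total
    variance, non-increasing.
    """

    variable_genes: list[str]
    loadings: pd.DataFrame
    scores: pd.DataFrame
    variance_explained: np.ndarray
    selection_component: int = 2
    selected_genes: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def contributions(self, component: int) -> pd.Series:
        """Squared loadings on a 1-based component."""
        if not (1 <= component <= self.n_components):
            raise AnalysisError(
                f"component {component} out of range 1..{self.n_components}"
            )
        col = self.loadings.iloc[:, component - 1]
        return (col**2).rename(f"contribution_pc{component}")


def select_variable_genes(
    normalized: pd.DataFrame, fraction: float, dispersions=None
) -> list[str]:
    """Top ``floor(fraction * n_genes)`` genes by log-expression variance.

    Variance is computed across samples on log2(normalized + 1), or — when
    dispersion estimates are supplied — on the variance-stabilized scale of
    :func:`pkdcore.dge.vst`, under which shot noise contributes equally for
    every gene and the ranking reflects excess variance. Ties are broken
    lexicographically by gene id.
    """
    if not (0.0 < fraction <= 1.0):
        raise AnalysisError(f"fraction must be in (0, 1], got {fraction}")
    if normalized.shape[1] < 2:
        raise AnalysisError("variance requires at least 2 samples")
    if dispersions is not None:
        from .dge import vst

        logx = vst(normalized, dispersions).to_numpy()
    else:
        logx = np.log2(normalized.to_numpy(dtype=float) + 1.0)
    var = logx.var(axis=1, ddof=1)
    order = sorted(range(len(var)), key=lambda i: (-var[i], str(normalized.index[i])))
    k = int(np.floor(fraction * normalized.shape[0]))
    return [str(normalized.index[i]) for i in order[:k]]


def pca_loadings(
    normalized: pd.DataFrame,
    selection_component: int = 2,
    log_transform: bool = True,
    dispersions=None,
) -> PCASelection:
    """SVD of the gene-centered sample × gene matrix.

    The expression scale is log2(normalized + 1) by default, the
    variance-stabilized scale when dispersion estimates are supplied, or the
    raw input with ``log_transform=False``. Each gene's mean across samples
    is subtracted; no per-gene scaling is applied. Components with
    numerically zero singular value are dropped.
    """
    if normalized.shape[1] < 2:
        raise AnalysisError("PCA requires at least 2 samples")
    X = normalized.to_numpy(dtype=float)
    if dispersions is not None:
        from .dge import vst

        X = vst(normalized, dispersions).to_numpy()
    elif log_transform:
        X = np.log2(X + 1.0)
    centered = X - X.mean(axis=1, keepdims=True)
    A = centered.T  # samples x genes
    U, sing, Vt = np.linalg.svd(A, full_matrices=False)
    total = float((sing**2).sum())
    if total <= 0:
        raise AnalysisError("matrix is constant across samples; zero total variance")
    keep = sing > max(1e-12 * sing[0], 0.0)
    U, sing, Vt = U[:, keep], sing[keep], Vt[keep]
    # orient: largest-magnitude loading entry positive
    for k in range(sing.size):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]
    comp_names = [f"PC{i + 1}" for i in range(sing.size)]
    loadings = pd.DataFrame(Vt.T, index=normalized.index, columns=comp_names)
    scores = pd.DataFrame(U * sing, index=normalized.columns, columns=comp_names)
    return PCASelection(
        variable_genes=[str(g) for g in normalized.index],
        loadings=loadings,
        scores=scores,
        variance_explained=sing**2 / total,
        selection_component=selection_component,
    )


def select_by_loading(p: PCASelection, component: int, fraction: float) -> list[str]:
    """Top ``floor(fraction * n_variable_genes)`` genes by squared loading.

    Ties are broken lexicographically by gene id. The selection is stored on
    the :class:`PCASelection` and also returned.
    """
    if not (0.0 < fraction <= 1.0):
        raise AnalysisError(f"fraction must be in (0, 1], got {fraction}")
    contrib = p.contributions(component)  # validates the component index
    vals = contrib.to_numpy()
    order = sorted(range(len(vals)), key=lambda i: (-vals[i], str(contrib.index[i])))
    k = int(np.floor(fraction * len(p.variable_genes)))
    selected = [str(contrib.index[i]) for i in order[:k]]
    p.selection_component = component
    p.selected_genes = selected
    return selected


def auto_select_component(
    p: PCASelection, genotype: pd.Series, reference: str
) -> int:
    """1-based component whose scores best separate knockouts from reference.

    Separation is measured by the absolute point-biserial correlation of the
    sample scores with the knockout-vs-reference indicator.
    """
    indicator = np.array(
        [0.0 if genotype[s] == reference else 1.0 for s in p.scores.index]
    )
    if indicator.std() == 0:
        raise AnalysisError("all samples share one genotype; no contrast to separate")
    best, best_r = 1, -1.0
    for k in range(p.n_components):
        sc = p.scores.iloc[:, k].to_numpy()
        if sc.std() == 0:
            continue
        r = abs(float(np.corrcoef(sc, indicator)[0, 1]))
        if r > best_r:
            best, best_r = k + 1, r
    return best
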