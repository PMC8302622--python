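"""Cross-study replication, hypergeometric over-representation, TF cascades.

Replication counts in how many external study lists a core gene appears (in
any direction) and classes each gene: ``new`` (0 studies), ``described``
(1..threshold-1) or ``replicated`` (>= threshold, default 3). Direction
agreement across studies is assessed separately: a gene is concordant when
every study reporting a non-zero direction agrees with the core direction.

Over-representation analysis (ORA) tests each gene set by the hypergeometric
upper tail P(X >= k) for an overlap of k between an n-gene query and a K-gene
set inside an N-gene universe, with BH adjustment across the collection.
TF→gene cascade edges join enriched transcription factors to their core-set
targets, annotated with network-cluster labels supplied as an input table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coreset import CoreSet
from .dge import bh_adjust
from .errors import AnalysisError
from .io import GeneSetCollection, StudyList

__all__ = [
    "replication_classify",
    "study_concordance",
    "hypergeom_p",
    "ora_enrich",
    "tf_gene_links",
    "CascadeEdge",
]

log = logging.getLogger(__name__)


def replication_classify(
    core: CoreSet, studies: Sequence[StudyList], threshold: int = 3
) -> pd.DataFrame:
    """Per-core-gene presence count across studies and replication class.

    Returns a DataFrame indexed by gene with ``n_studies_present`` and
    ``rep_class`` in {new, described, replicated}; the three classes
    partition the core set.
    """
    if threshold < 1:
        raise AnalysisError("replication threshold must be >= 1")
    if not studies:
        log.warning("no external studies supplied; every core gene is classed 'new'")
    genes = core.genes
    counts = []
    for g in genes:
        counts.append(sum(1 for s in studies if g in s.entries))
    counts = np.array(counts, dtype=int)
    cls = np.where(
        counts == 0, "new", np.where(counts >= threshold, "replicated", "described")
    )
    df = pd.DataFrame(
        {"n_studies_present": counts, "rep_class": cls},
        index=pd.Index(genes, name="gene"),
    )
    return df


def study_concordance(core: CoreSet, studies: Sequence[StudyList]) -> pd.Series:
    """Cross-study direction class per core gene.

    ``concordant_up`` / ``concordant_down``: every study containing the gene
    reports the same non-zero direction and it matches the core direction;
    ``discordant``: any disagreement; ``unknown``: the gene appears nowhere
    or all reporting studies give direction 0.
    """
    out = {}
    for gene, core_dir in core.members.items():
        core_sign = 1 if core_dir == "up" else -1
        dirs = [s.entries[gene] for s in studies if gene in s.entries]
        nonzero = [d for d in dirs if d != 0]
        if not nonzero:
            out[gene] = "unknown"
        elif all(d == core_sign for d in nonzero):
            out[gene] = "concordant_up" if core_sign > 0 else "concordant_down"
        else:
            out[gene] = "discordant"
    return pd.Series(out, name="cross_study_direction", dtype=object)


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` overlapping genes between an ``n``-gene query and a ``K``-gene set
    in an ``N``-gene universe; evaluated through the log-space-stable
    survival function.
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(k, K, n, N) < 0:
        raise AnalysisError(f"inconsistent hypergeometric arguments k={k} K={K} n={n} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ora_enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query set against a collection.

    Query genes outside the universe are dropped (with a logged count); each
    set is intersected with the universe before its size K is computed and
    empty sets are skipped. Returns one row per set with k, K, n, N, p, fdr,
    significance flag and the overlapping genes.
    """
    uni = set(universe)
    q = set(query)
    dropped = q - uni
    if dropped:
        log.info("dropping %d query genes outside the universe", len(dropped))
    q &= uni
    if not q:
        raise AnalysisError("query is empty after restriction to the universe")
    N, n = len(uni), len(q)
    rows = []
    for name, members in collection.sets.items():
        in_uni = members & uni
        K = len(in_uni)
        if K == 0:
            continue
        overlap = sorted(q & in_uni)
        k = len(overlap)
        p = hypergeom_p(k, K, n, N)
        rows.append((name, k, K, n, N, p, ",".join(overlap)))
    df = pd.DataFrame(
        rows, columns=["set", "k", "K", "n", "N", "p", "overlap_genes"]
    ).set_index("set")
    df["fdr"] = bh_adjust(df["p"].to_numpy()) if len(df) else np.array([])
    df["significant"] = df["fdr"] < fdr_max
    return df.sort_values("p")


@dataclass(frozen=True)
class CascadeEdge:
    """One enriched-TF → core-gene regulatory edge with its cluster label."""

    tf: str
    target: str
    cluster: str | None


def tf_gene_links(
    enriched_tfs: Sequence[str],
    tf_targets: GeneSetCollection,
    core: CoreSet,
    clusters: Mapping[str, str] | None = None,
) -> tuple[list[CascadeEdge], dict[str, int]]:
    """Join enriched TFs to the core genes they target.

    Returns the edge list and summary counts: core genes regulated by more
    than one enriched TF, and TFs regulating more than one core gene.
    """
    clusters = clusters or {}
    core_genes = set(core.members)
    edges: list[CascadeEdge] = []
    for tf in enriched_tfs:
        targets = tf_targets.sets.get(tf, frozenset())
        for gene in sorted(targets & core_genes):
            edges.append(CascadeEdge(tf, gene, clusters.get(gene)))
    per_gene: dict[str, int] = {}
    per_tf: dict[str, int] = {}
    for e in edges:
        per_gene[e.target] = per_gene.get(e.target, 0) + 1
        per_tf[e.tf] = per_tf.get(e.tf, 0) + 1
    summary = {
        "n_edges": len(edges),
        "genes_multi_tf": sum(1 for v in per_gene.values() if v > 1),
        "tfs_multi_gene": sum(1 for v in per_tf.values() if v > 1),
    }
    return edges, summary
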