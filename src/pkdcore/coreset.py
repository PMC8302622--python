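"""Concordance filtering across the two knockouts and core-set construction.

A gene is concordantly regulated when it carries the DE flag in BOTH
knockout-vs-reference contrasts with the same fold-change sign; the core set
is the intersection of the concordant set with the PCA loading selection,
inheriting the concordant direction. Genes untested or unconverged in either
contrast are excluded (conservative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import AnalysisError

__all__ = ["CoreSet", "concordant_dge", "intersect_core", "fold_change_percent"]

log = logging.getLogger(__name__)


@dataclass
class CoreSet:
    """A direction-annotated gene set with per-contrast provenance.

    ``origin`` is one of ``concordant_dge``, ``pca_selected`` or ``core``;
    ``members`` maps gene → "up"/"down"; ``provenance`` holds lfc/fdr pairs
    from both contrasts for every member.
    """

    origin: str
    members: dict[str, str] = field(default_factory=dict)
    provenance: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.members)

    @property
    def n_up(self) -> int:
        return sum(1 for d in self.members.values() if d == "up")

    @property
    def n_down(self) -> int:
        return sum(1 for d in self.members.values() if d == "down")

    @property
    def genes(self) -> list[str]:
        return list(self.members)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"direction": pd.Series(self.members, dtype=object)}
        )
        df.index.name = "gene"
        if self.provenance is not None:
            df = df.join(self.provenance, how="left")
        return df


def concordant_dge(r1: pd.DataFrame, r2: pd.DataFrame, cfg: RunConfig) -> CoreSet:
    """Genes DE-flagged in both contrasts with matching fold-change sign.

    ``r1`` and ``r2`` are :func:`pkdcore.dge.dge_test` result frames over the
    same gene universe.
    """
    missing = r1.index.symmetric_difference(r2.index)
    if len(missing):
        raise AnalysisError(
            f"contrast results cover different gene universes; "
            f"{len(missing)} mismatched genes, e.g. {list(missing[:5])}"
        )
    r2 = r2.reindex(r1.index)
    de_both = r1["de_flag"].to_numpy() & r2["de_flag"].to_numpy()
    sign1 = np.sign(np.nan_to_num(r1["lfc"].to_numpy(), nan=0.0))
    sign2 = np.sign(np.nan_to_num(r2["lfc"].to_numpy(), nan=0.0))
    keep = de_both & (sign1 == sign2) & (sign1 != 0)
    members = {
        str(g): ("up" if sgn > 0 else "down")
        for g, sgn in zip(r1.index[keep], sign1[keep])
    }
    prov = pd.DataFrame(
        {
            "lfc1": r1.loc[keep, "lfc"],
            "fdr1": r1.loc[keep, "fdr"],
            "lfc2": r2.loc[keep, "lfc"],
            "fdr2": r2.loc[keep, "fdr"],
        }
    )
    prov.index = prov.index.astype(str)
    cs = CoreSet("concordant_dge", members, prov)
    log.info(
        "concordant DGE set: %d genes (%d up, %d down)", len(cs), cs.n_up, cs.n_down
    )
    return cs


def intersect_core(dge_set: CoreSet, pca_genes: list[str]) -> CoreSet:
    """Intersect the concordant set with the PCA selection (directions kept)."""
    chosen = set(pca_genes)
    members = {g: d for g, d in dge_set.members.items() if g in chosen}
    prov = None
    if dge_set.provenance is not None:
        prov = dge_set.provenance.loc[[g for g in members]]
    if not members:
        log.warning("core set is empty: concordant and PCA selections are disjoint")
    return CoreSet("core", members, prov)


def fold_change_percent(reference_mean: float, other_mean: float) -> float:
    """Signed percent change of ``other_mean`` relative to ``reference_mean``.

    Reported to one decimal, matching the convention of quoting e.g. a rise
    from 782.25 to 1,209 mean normalized counts as +54.6%.
    """
    if reference_mean <= 0:
        raise AnalysisError(f"reference mean must be positive, got {reference_mean}")
    if other_mean < 0:
        raise AnalysisError(f"other mean must be non-negative, got {other_mean}")
    return round(100.0 * (other_mean - reference_mean) / reference_mean, 1)
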