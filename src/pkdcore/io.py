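"""Readers and writers for the external table formats.

Count matrices are accepted as TSV (genes as rows, first column the gene id)
or as MatrixMarket coordinate files with ``.rows`` / ``.cols`` sidecar files
naming the genes and samples. Gene sets use the GMT interchange format.
External study gene lists, TF→target tables, gene→cluster tables and ortholog
maps are plain TSV.

Gene symbols are harmonized by uppercasing (after applying an optional
ortholog/synonym map), so that mouse-cased and human-cased symbols compare
equal across studies.

All writers emit a leading ``#`` comment line recording the package version
and, when available, the run-config hash; all readers skip ``#`` lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import FormatError, MetadataError

__all__ = [
    "CountMatrix",
    "GeneSetCollection",
    "StudyList",
    "harmonize_symbols",
    "read_count_matrix",
    "write_count_matrix",
    "read_gmt",
    "write_gmt",
    "read_study_lists",
    "write_study_lists",
    "read_tf_targets",
    "read_clusters",
    "read_ortholog_map",
    "write_table",
    "read_table",
]


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Gene × sample non-negative integer counts with per-sample genotypes.

    Attributes
    ----------
    counts
        DataFrame, index = gene ids, columns = sample ids, integer counts.
    genotype
        Series indexed by sample id giving each sample's genotype label.
    reference
        The genotype label treated as the reference (wild type).
    """

    counts: pd.DataFrame
    genotype: pd.Series
    reference: str = "WT"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("count matrix contains non-numeric entries")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at gene {c.index[g]!r}, sample {c.columns[s]!r}"
            )
        missing = [s for s in c.columns if s not in self.genotype.index]
        if missing:
            raise MetadataError(f"samples missing from sample sheet: {missing}")
        if self.reference not in set(self.genotype.loc[list(c.columns)]):
            raise MetadataError(
                f"reference genotype {self.reference!r} absent from sample sheet"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_of(self, genotype: str) -> list[str]:
        return [s for s in self.samples if self.genotype[s] == genotype]

    @property
    def genotypes(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.genotype[s], None)
        return list(seen)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics) with harmonized uppercase members."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)

    def restricted(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with ``universe``; empty sets are dropped."""
        uni = set(universe)
        sets = {}
        for name, members in self.sets.items():
            kept = members & uni
            if kept:
                sets[name] = frozenset(kept)
        return GeneSetCollection(sets, {n: self.descriptions.get(n, "") for n in sets})


@dataclass
class StudyList:
    """One external study's differential-expression gene list.

    ``entries`` maps harmonized gene symbol to direction: +1 up, -1 down,
    0 direction unknown.
    """

    study_id: str
    species: str
    entries: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g: d for g, d in self.entries.items() if d not in (-1, 0, 1)}
        if bad:
            raise FormatError(f"study {self.study_id}: invalid directions {bad}")

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries


# ---------------------------------------------------------------------------
# symbol harmonization
# ---------------------------------------------------------------------------

def harmonize_symbols(
    symbols: Iterable[str], ortholog_map: Mapping[str, str] | None = None
) -> list[str]:
    """Map symbols through an optional ortholog/synonym table, then uppercase."""
    if ortholog_map:
        lowered = {k.upper(): v for k, v in ortholog_map.items()}
        return [lowered.get(s.upper(), s).upper() for s in symbols]
    return [s.upper() for s in symbols]


# ---------------------------------------------------------------------------
# generic TSV helpers
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, comment: str | None = None,
                index: bool = True) -> None:
    """Write a TSV with a provenance comment line."""
    from . import __version__

    path = Path(path)
    with open(path, "w") as fh:
        line = f"# pkdcore {__version__}"
        if comment:
            line += f" {comment}"
        fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def _counts_from_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene ids {dups[:5]}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().argmax()]
            raise FormatError(
                f"{path}: non-numeric count at gene {gene!r}, sample {col!r}: "
                f"{df.loc[gene, col]!r}"
            )
        df[col] = vals
    arr = df.to_numpy(dtype=float)
    if np.isnan(arr).any():
        g, s = np.argwhere(np.isnan(arr))[0]
        raise FormatError(f"{path}: missing count at gene {df.index[g]!r}, sample {df.columns[s]!r}")
    if (arr < 0).any():
        g, s = np.argwhere(arr < 0)[0]
        raise FormatError(
            f"{path}: negative count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    if (np.mod(arr, 1) != 0).any():
        g, s = np.argwhere(np.mod(arr, 1) != 0)[0]
        raise FormatError(
            f"{path}: non-integer count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    return df.astype(np.int64)


def _sidecars(path: Path) -> tuple[Path, Path]:
    return path.with_suffix(".rows"), path.with_suffix(".cols")


def _counts_from_mtx(path: Path) -> pd.DataFrame:
    rows_path, cols_path = _sidecars(path)
    for p in (rows_path, cols_path):
        if not p.exists():
            raise FormatError(f"MatrixMarket sidecar file missing: {p}")
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    genes = [l.strip() for l in rows_path.read_text().splitlines() if l.strip()]
    samples = [l.strip() for l in cols_path.read_text().splitlines() if l.strip()]
    if mat.shape != (len(genes), len(samples)):
        raise FormatError(
            f"{path}: matrix shape {mat.shape} does not match sidecars "
            f"({len(genes)} rows, {len(samples)} cols)"
        )
    arr = np.asarray(mat)
    if (arr < 0).any():
        g, s = np.argwhere(arr < 0)[0]
        raise FormatError(f"{path}: negative count at gene {genes[g]!r}, sample {samples[s]!r}")
    df = pd.DataFrame(arr, index=genes, columns=samples)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene ids {dups[:5]}")
    return df.astype(np.int64)


def read_count_matrix(
    path: str | Path, sample_sheet: str | Path, reference: str = "WT"
) -> CountMatrix:
    """Read a count matrix (TSV or ``.mtx``) plus its sample sheet.

    The sample sheet is a TSV with columns ``sample_id`` and ``genotype``;
    samples are ordered as in the sheet.
    """
    path = Path(path)
    counts = _counts_from_mtx(path) if path.suffix == ".mtx" else _counts_from_tsv(path)

    sheet = pd.read_csv(sample_sheet, sep="\t", comment="#", dtype=str)
    for col in ("sample_id", "genotype"):
        if col not in sheet.columns:
            raise FormatError(f"{sample_sheet}: missing column {col!r}")
    if sheet["sample_id"].duplicated().any():
        raise MetadataError(f"{sample_sheet}: duplicate sample ids")
    sheet_samples = sheet["sample_id"].tolist()
    missing = [s for s in counts.columns if s not in set(sheet_samples)]
    if missing:
        raise MetadataError(f"samples in matrix missing from sample sheet: {missing}")
    absent = [s for s in sheet_samples if s not in set(counts.columns)]
    if absent:
        raise MetadataError(f"samples in sheet missing from matrix: {absent}")
    counts = counts[sheet_samples]
    genotype = pd.Series(sheet["genotype"].to_numpy(), index=sheet_samples, name="genotype")
    return CountMatrix(counts, genotype, reference=reference)


def write_count_matrix(
    cm: CountMatrix, path: str | Path, sample_sheet: str | Path | None = None
) -> None:
    """Write counts as TSV or MatrixMarket (chosen by suffix) + sample sheet."""
    path = Path(path)
    if path.suffix == ".mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(cm.counts.to_numpy()))
        rows_path, cols_path = _sidecars(path)
        rows_path.write_text("\n".join(cm.genes) + "\n")
        cols_path.write_text("\n".join(cm.samples) + "\n")
    else:
        write_table(cm.counts, path)
    if sample_sheet is not None:
        sheet = pd.DataFrame(
            {"sample_id": cm.samples, "genotype": [cm.genotype[s] for s in cm.samples]}
        )
        write_table(sheet, sample_sheet, index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, ortholog_map: Mapping[str, str] | None = None) -> GeneSetCollection:
    """Parse a GMT file: per line ``name<TAB>description<TAB>member...``."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = [m for m in members if m.strip()]
            sets[name] = frozenset(harmonize_symbols(members, ortholog_map))
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# study lists and small tables
# ---------------------------------------------------------------------------

_DIRECTION_TOKENS = {"up": 1, "down": -1, "na": 0}
_DIRECTION_NAMES = {1: "up", -1: "down", 0: "na"}


def read_study_lists(
    path: str | Path, ortholog_map: Mapping[str, str] | None = None
) -> list[StudyList]:
    """Read external study gene lists from a long TSV.

    Columns: ``study_id``, ``species``, ``gene``, ``direction`` (up/down/na).
    Returns one :class:`StudyList` per distinct study id, in file order.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("study_id", "species", "gene", "direction"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    unknown = set(df["direction"].str.lower()) - set(_DIRECTION_TOKENS)
    if unknown:
        raise FormatError(f"{path}: unknown direction tokens {sorted(unknown)}")
    out: list[StudyList] = []
    for study_id in df["study_id"].unique():
        sub = df[df["study_id"] == study_id]
        species = sub["species"].iloc[0]
        entries: dict[str, int] = {}
        genes = harmonize_symbols(sub["gene"], ortholog_map)
        dirs = [_DIRECTION_TOKENS[d.lower()] for d in sub["direction"]]
        for gene, d in zip(genes, dirs):
            if gene in entries and entries[gene] != d:
                raise FormatError(
                    f"{path}: study {study_id!r} lists gene {gene!r} with "
                    f"conflicting directions"
                )
            entries[gene] = d
        out.append(StudyList(str(study_id), str(species), entries))
    return out


def write_study_lists(studies: Sequence[StudyList], path: str | Path) -> None:
    rows = [
        (s.study_id, s.species, gene, _DIRECTION_NAMES[d])
        for s in studies
        for gene, d in s.entries.items()
    ]
    df = pd.DataFrame(rows, columns=["study_id", "species", "gene", "direction"])
    write_table(df, path, index=False)


def read_tf_targets(
    path: str | Path, ortholog_map: Mapping[str, str] | None = None
) -> GeneSetCollection:
    """Read a TF→target TSV (columns ``tf``, ``target``) as a gene-set collection."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("tf", "target"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    sets: dict[str, frozenset[str]] = {}
    for tf in df["tf"].unique():
        targets = df.loc[df["tf"] == tf, "target"]
        sets[str(tf)] = frozenset(harmonize_symbols(targets, ortholog_map))
    return GeneSetCollection(sets, {tf: "tf targets" for tf in sets})


def read_clusters(
    path: str | Path, ortholog_map: Mapping[str, str] | None = None
) -> dict[str, str]:
    """Read a gene→cluster label TSV (columns ``gene``, ``cluster``)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("gene", "cluster"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    genes = harmonize_symbols(df["gene"], ortholog_map)
    return dict(zip(genes, df["cluster"]))


def read_ortholog_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping source symbol → harmonized symbol."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, header=None)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: ortholog map needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
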